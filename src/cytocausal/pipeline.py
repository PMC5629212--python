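"""End-to-end orchestration: simulate -> mine -> estimate -> score -> evaluate.

A single YAML config drives all stages; every stage writes its outputs
under the run directory and a manifest records seeds, parameters and
content hashes so a rerun with the same config is bit-identical for
the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backshift import (
    ModelViolationError,
    StabilityConfig,
    environment_covariances,
    estimate_backshift,
    stability_select,
)
from .bge import consistency_analysis
from .ci_tests import DecisionThresholds
from .clcd import predictions_to_frame, run_clcd
from .evaluation import all_ordered_pairs, load_truth, precision_at_rank, random_baseline_test
from .clcd import rank_predictions
from .synthetic import (
    make_random_model,
    make_study_design,
    read_study,
    simulate_study,
    write_study,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 at the CLI)."""


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    # synthetic model / design
    p: int = 5
    edge_density: float = 0.25
    confounder_density: float = 0.0
    cyclic: bool = False
    activator_out_degree: int = 1
    n_inhibitors: int = 27
    n_dosages: int = 8
    n_per_condition: int = 200
    activators: list[str] = field(default_factory=lambda: ["act1"])
    # CLCD
    alpha: float = 0.001
    beta: float = 0.15
    min_support: int = 10
    # stability selection
    ev: float = 5.0
    n_sim: int = 100
    pi_thr: float = 0.75
    min_success: int = 75
    # consistency scoring
    n_random: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.alpha < self.beta < 1):
            raise ConfigError(f"need 0 < alpha < beta < 1, got {self.alpha}, {self.beta}")
        if self.p < 2 or self.n_inhibitors < 1 or self.n_dosages < 1:
            raise ConfigError("p >= 2 and at least one inhibitor/dosage required")
        if self.seed < 0:
            raise ConfigError("seed must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dictionary.

    Stages: simulate the study and an independent replica, mine CLCD
    predictions, estimate one connectivity matrix with stability
    selection, score prediction consistency on the independent replica,
    and evaluate ranked precision against the generating model's
    ancestral ground truth.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    def record(stage: str, files: list[Path], extra: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "files": {f.name: _file_hash(f) for f in files},
            **(extra or {}),
        }

    # -- simulate -----------------------------------------------------
    try:
        model = make_random_model(
            config.p,
            edge_density=config.edge_density,
            confounder_density=config.confounder_density,
            cyclic=config.cyclic,
            activator_out_degree=config.activator_out_degree,
            seed=config.seed,
        )
        design = make_study_design(
            model,
            n_inhibitors=config.n_inhibitors,
            n_dosages=config.n_dosages,
            activators=config.activators,
            n_per_condition=config.n_per_condition,
            seed=config.seed + 1,
        )
        study_dir = out / "study"
        write_study(simulate_study(model, design, seed=config.seed + 2), study_dir)
        indep_dir = out / "independent"
        write_study(simulate_study(model, design, seed=config.seed + 3), indep_dir)
        truth_path = out / "truth_edges.tsv"
        with truth_path.open("w") as fh:
            for u, v in sorted(model.ancestral_pairs()):
                fh.write(f"{u}\t{v}\n")
        record("simulate", [study_dir / "manifest.json", indep_dir / "manifest.json", truth_path])
    except Exception as exc:
        raise StageError(f"stage 'simulate' failed: {exc}") from exc

    # -- clcd ---------------------------------------------------------
    try:
        bundle = read_study(study_dir)
        thresholds = DecisionThresholds(config.alpha, config.beta)
        predictions = run_clcd(bundle, thresholds, config.min_support)
        pred_path = out / "predictions.csv"
        predictions_to_frame(predictions).to_csv(pred_path, index=False)
        record("clcd", [pred_path], {"n_predictions": len(predictions)})
    except Exception as exc:
        raise StageError(f"stage 'clcd' failed: {exc}") from exc

    # -- backshift ----------------------------------------------------
    try:
        subpop = bundle.subpopulations[0]
        activator = bundle.activators[0]
        inhibitor = bundle.inhibitors[0]
        env_set = environment_covariances(bundle.environments(subpop, activator, inhibitor))
        estimate = estimate_backshift(env_set)
        stab_cfg = StabilityConfig(config.ev, config.n_sim, config.pi_thr, config.min_success)
        rows = []
        try:
            stable = stability_select(env_set, stab_cfg, seed=config.seed + 4)
            rows = [
                {"from": u, "to": v, "coefficient": estimate.B_hat[
                    bundle.labels.index(v), bundle.labels.index(u)
                ], "selection_frequency": f}
                for u, v, f in stable.stable_edges
            ]
            stab_note = f"{stable.n_success}/{config.n_sim} successful refits"
        except ModelViolationError as exc:
            stab_note = str(exc)
        edges_path = out / "edges.csv"
        pd.DataFrame(rows, columns=["from", "to", "coefficient", "selection_frequency"]).to_csv(
            edges_path, index=False
        )
        record(
            "backshift",
            [edges_path],
            {
                "inhibitor": inhibitor,
                "activator": activator,
                "residual": estimate.diagonalization_residual,
                "stability": stab_note,
            },
        )
    except Exception as exc:
        raise StageError(f"stage 'backshift' failed: {exc}") from exc

    # -- score-consistency -------------------------------------------
    try:
        if predictions:
            indep = read_study(indep_dir)
            report = consistency_analysis(
                predictions, indep, n_random=config.n_random, seed=config.seed + 5
            )
            verdict_path = out / "verdicts.csv"
            pd.DataFrame(
                [
                    {"cause": p.cause, "effect": p.effect, "activator": p.activator,
                     "subpopulation": p.subpopulation, "verdict": v}
                    for p, v in report.verdicts
                ]
            ).to_csv(verdict_path, index=False)
            record(
                "score_consistency",
                [verdict_path],
                {
                    "fraction_consistent": report.fraction_consistent,
                    "fraction_conflicted": report.fraction_conflicted,
                    "p_value": report.p_value,
                },
            )
        else:
            manifest["stages"]["score_consistency"] = {"skipped": "no predictions"}
    except Exception as exc:
        raise StageError(f"stage 'score-consistency' failed: {exc}") from exc

    # -- evaluate ------------------------------------------------------
    try:
        metrics_path = out / "metrics.json"
        if predictions:
            truth = load_truth(truth_path)
            ranked = [pair for pair, _ in rank_predictions(predictions)]
            curve = precision_at_rank(ranked, truth)
            universe = all_ordered_pairs(list(bundle.labels))
            baseline = random_baseline_test(
                ranked, truth, universe, n_rep=config.n_random, seed=config.seed + 6
            )
            metrics = {
                "n_unique_pairs": len(ranked),
                "precision_full": curve.precision[-1],
                "reversed_precision_full": curve.reversed_precision[-1],
                "baseline_mean": baseline.baseline_mean,
                "z": baseline.z,
                "p_value": baseline.p_value,
            }
        else:
            metrics = {"n_unique_pairs": 0}
        metrics_path.write_text(json.dumps(metrics, indent=1))
        record("evaluate", [metrics_path], metrics)
    except Exception as exc:
        raise StageError(f"stage 'evaluate' failed: {exc}") from exc

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
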