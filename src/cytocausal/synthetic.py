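"""Synthetic single-cell signaling data from known linear causal models.

This module emulates the study design of a mass-cytometry perturbation
experiment: single cells from one gated subpopulation are stimulated (or
not) with an extracellular activator and treated with one of several
inhibitors at increasing dosages.  Each (subpopulation, activator,
inhibitor, dosage) combination yields one table of cells x phosphoprotein
markers.  The zero dosage of every inhibitor is a technical replicate of
the same unperturbed distribution, and the dosage series of one inhibitor
provides a set of shift-intervention environments.

The generating model is a linear structural equation system at
equilibrium::

    x = B x + a A + c + eps

where ``B`` holds the direct causal coefficients (``B[i, j] != 0`` iff
marker ``j`` directly causes marker ``i``), ``A`` is the binary exogenous
activation indicator, ``c`` is a mean-zero shift intervention with
diagonal covariance (the inhibitor dosage), and ``eps`` is correlated
noise whose off-diagonal covariance encodes latent confounding.  Cells
are i.i.d. draws of ``x = (I - B)^{-1} (a A + c + eps)``; for cyclic
``B`` this is the equilibrium distribution, which exists whenever the
spectral radius of ``B`` is below one.

Values are generated directly on a transformed (arcsinh-like) scale; no
raw ion-count model is used.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REFERENCE = "reference"

__all__ = [
    "REFERENCE",
    "CausalModel",
    "InterventionSpec",
    "ConditionKey",
    "CellTable",
    "StudyDesign",
    "StudyBundle",
    "make_random_model",
    "make_chain_model",
    "make_study_design",
    "simulate_condition",
    "simulate_study",
    "write_study",
    "read_study",
]


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CausalModel:
    """Ground-truth linear causal model over ``p`` protein markers.

    Attributes
    ----------
    B
        ``p x p`` connectivity matrix; ``B[i, j] != 0`` iff marker ``j``
        directly causes marker ``i``.  Zero diagonal (no self-loops).
    Sigma_eps
        ``p x p`` symmetric positive semi-definite noise covariance;
        off-diagonal entries encode latent confounders.
    a
        Length-``p`` activator effect vector; marker ``i`` is a direct
        target of the activator iff ``a[i] != 0``.
    labels
        Marker names, length ``p``.
    """

    B: np.ndarray
    Sigma_eps: np.ndarray
    a: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        B = np.asarray(self.B, dtype=float)
        S = np.asarray(self.Sigma_eps, dtype=float)
        a = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "Sigma_eps", S)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "labels", tuple(self.labels))
        p = B.shape[0]
        if B.shape != (p, p) or S.shape != (p, p) or a.shape != (p,):
            raise ValueError("inconsistent model dimensions")
        if len(self.labels) != p:
            raise ValueError("labels length must match number of markers")
        if np.any(np.diag(B) != 0):
            raise ValueError("B must have zero diagonal (no self-loops)")
        if not np.allclose(S, S.T):
            raise ValueError("Sigma_eps must be symmetric")
        eig = np.linalg.eigvalsh(S)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValueError("Sigma_eps must be positive semi-definite")
        if self.spectral_radius >= 1.0:
            raise ValueError(
                "spectral radius of B must be < 1 for an equilibrium "
                f"distribution (got {self.spectral_radius:.3f})"
            )

    @property
    def p(self) -> int:
        return self.B.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.B))))

    def mixing(self) -> np.ndarray:
        """Return ``(I - B)^{-1}``, mapping exogenous inputs to markers."""
        return np.linalg.inv(np.eye(self.p) - self.B)

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph())

    def graph(self) -> nx.DiGraph:
        """Directed graph with an edge cause -> effect per nonzero B entry."""
        g = nx.DiGraph()
        g.add_nodes_from(self.labels)
        rows, cols = np.nonzero(self.B)
        g.add_edges_from((self.labels[j], self.labels[i]) for i, j in zip(rows, cols))
        return g

    def direct_edges(self) -> set[tuple[str, str]]:
        return set(self.graph().edges())

    def ancestral_pairs(self) -> set[tuple[str, str]]:
        """All (cause, effect) pairs connected by a directed path."""
        closure = nx.transitive_closure(self.graph(), reflexive=False)
        return {(u, v) for u, v in closure.edges() if u != v}

    def activator_targets(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in np.nonzero(self.a)[0])

    def population_covariance(
        self,
        intervention_variances: np.ndarray | None = None,
        activation_var: float = 0.0,
    ) -> np.ndarray:
        """Closed-form marker covariance at equilibrium.

        ``Cov(x) = M (Sigma_eps + Sigma_c + activation_var * a a^T) M^T``
        with ``M = (I - B)^{-1}``; ``activation_var`` is the variance of
        the binary activation indicator when it varies in the sample
        (``pi * (1 - pi)`` for activation probability ``pi``), zero for a
        fixed activation status.
        """
        v = np.zeros(self.p) if intervention_variances is None else np.asarray(
            intervention_variances, dtype=float
        )
        inner = self.Sigma_eps + np.diag(v) + activation_var * np.outer(self.a, self.a)
        M = self.mixing()
        return M @ inner @ M.T

    def content_hash(self) -> str:
        h = zlib.crc32(np.round(self.B, 12).tobytes())
        h = zlib.crc32(np.round(self.Sigma_eps, 12).tobytes(), h)
        h = zlib.crc32(np.round(self.a, 12).tobytes(), h)
        h = zlib.crc32("|".join(self.labels).encode(), h)
        return f"{h:08x}"


@dataclass(frozen=True)
class InterventionSpec:
    """Ordered shift-intervention environments.

    ``variances[e]`` is the length-``p`` diagonal of the intervention
    covariance in environment ``e``; an all-zero row is a purely
    observational environment.
    """

    variances: np.ndarray  # n_env x p

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if np.any(v < 0):
            raise ValueError("intervention variances must be nonnegative")
        object.__setattr__(self, "variances", v)

    @property
    def n_environments(self) -> int:
        return self.variances.shape[0]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class ConditionKey:
    """Identity of one experimental condition (one table of cells)."""

    subpopulation: str
    activator: str  # activator name, or REFERENCE for unstimulated cells
    inhibitor: str
    dosage: int
    replicate: int = 0

    def filename(self) -> str:
        return (
            f"{self.subpopulation}__{self.activator}__{self.inhibitor}"
            f"__d{self.dosage}__r{self.replicate}.csv"
        )


@dataclass
class CellTable:
    """Cells x markers for one experimental condition."""

    values: np.ndarray
    labels: tuple[str, ...]
    meta: ConditionKey
    activation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = tuple(self.labels)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("values must be a nonempty 2-D array")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("marker count must match labels")
        if self.activation is not None:
            self.activation = np.asarray(self.activation, dtype=int)
            if self.activation.shape != (self.values.shape[0],):
                raise ValueError("activation column must have one entry per cell")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.labels))
        if self.activation is not None:
            df["activation"] = self.activation
        return df


@dataclass
class StudyBundle:
    """Collection of :class:`CellTable` keyed by experimental condition."""

    tables: dict[ConditionKey, CellTable]
    labels: tuple[str, ...]
    model_hash: str | None = None

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        for key, table in self.tables.items():
            if table.meta != key:
                raise ValueError(f"table metadata does not match its key: {key}")
            if table.labels != self.labels:
                raise ValueError(f"marker labels mismatch for {key}")

    def __len__(self) -> int:
        return len(self.tables)

    def keys(self) -> list[ConditionKey]:
        return sorted(self.tables)

    @property
    def subpopulations(self) -> list[str]:
        return sorted({k.subpopulation for k in self.tables})

    @property
    def activators(self) -> list[str]:
        return sorted({k.activator for k in self.tables} - {REFERENCE})

    @property
    def inhibitors(self) -> list[str]:
        return sorted({k.inhibitor for k in self.tables})

    def dose0_plates(
        self, subpopulation: str, activator: str
    ) -> list[tuple[CellTable, CellTable]]:
        """(reference, activated) table pairs at dosage zero.

        One pair per replicate plate, i.e. per (inhibitor, replicate);
        plates missing either member are skipped with a log entry.
        """
        plates = []
        plate_ids = sorted(
            {
                (k.inhibitor, k.replicate)
                for k in self.tables
                if k.subpopulation == subpopulation and k.dosage == 0
            }
        )
        for inhibitor, rep in plate_ids:
            ref_key = ConditionKey(subpopulation, REFERENCE, inhibitor, 0, rep)
            act_key = ConditionKey(subpopulation, activator, inhibitor, 0, rep)
            if ref_key in self.tables and act_key in self.tables:
                plates.append((self.tables[ref_key], self.tables[act_key]))
            else:
                logger.info("plate %s/%s lacks a reference/activated pair", inhibitor, rep)
        return plates

    def environments(
        self, subpopulation: str, activator: str, inhibitor: str, replicate: int = 0
    ) -> list[CellTable]:
        """Tables for one inhibitor across its dosages (the environments)."""
        keys = sorted(
            k
            for k in self.tables
            if k.subpopulation == subpopulation
            and k.activator == activator
            and k.inhibitor == inhibitor
            and k.replicate == replicate
        )
        return [self.tables[k] for k in keys]


# ---------------------------------------------------------------------------
# model generation
# ---------------------------------------------------------------------------


def _default_labels(p: int) -> tuple[str, ...]:
    return tuple(f"pP{i + 1:02d}" for i in range(p))


def make_random_model(
    p: int,
    edge_density: float = 0.3,
    confounder_density: float = 0.0,
    cyclic: bool = False,
    activator_out_degree: int = 1,
    seed: int | np.random.Generator | None = None,
    coef_range: tuple[float, float] = (0.3, 0.9),
    activator_strength: float = 1.0,
    labels: Sequence[str] | None = None,
    max_retries: int = 50,
) -> CausalModel:
    """Draw a random linear causal model.

    Coefficient magnitudes are bounded away from zero (default
    ``|b| in [0.3, 0.9]``, random sign) so that faithfulness violations
    are improbable.  Acyclic models are strictly lower-triangular under a
    random permutation; cyclic models are resampled (with shrinking
    coefficients) until the spectral radius falls below one.
    """
    if p < 2:
        raise ValueError("need at least two markers (p >= 2)")
    if not (0 <= edge_density <= 1 and 0 <= confounder_density <= 1):
        raise ValueError("densities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lab = tuple(labels) if labels is not None else _default_labels(p)
    lo, hi = coef_range

    for attempt in range(max_retries):
        B = np.zeros((p, p))
        order = rng.permutation(p)
        rank = np.empty(p, dtype=int)
        rank[order] = np.arange(p)
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                allowed = True if cyclic else rank[j] < rank[i]
                if allowed and rng.random() < edge_density:
                    B[i, j] = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        shrink = 0.8**attempt
        B *= shrink if cyclic else 1.0
        if np.max(np.abs(np.linalg.eigvals(B))) < 1.0:
            break
    else:
        raise RuntimeError(
            f"could not draw a stable connectivity matrix in {max_retries} tries "
            f"(p={p}, edge_density={edge_density}, cyclic={cyclic})"
        )

    Sigma = np.eye(p)
    n_pairs = p * (p - 1) // 2
    n_conf = int(round(confounder_density * n_pairs))
    if n_conf > 0:
        all_pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
        chosen = rng.choice(len(all_pairs), size=n_conf, replace=False)
        for idx in np.atleast_1d(chosen):
            i, j = all_pairs[int(idx)]
            v = np.zeros(p)
            v[i] = 1.0
            v[j] = rng.choice([-1.0, 1.0])
            Sigma += rng.uniform(0.3, 0.6) * np.outer(v, v)  # PSD by construction

    a = np.zeros(p)
    k = min(activator_out_degree, p)
    targets = rng.choice(p, size=k, replace=False)
    a[targets] = activator_strength * rng.uniform(0.8, 1.2, size=k)

    return CausalModel(B=B, Sigma_eps=Sigma, a=a, labels=lab)


def make_chain_model(
    p: int = 3,
    chain_coef: float = 0.8,
    activator_effect: float = 1.0,
    chain_length: int = 2,
    labels: Sequence[str] | None = None,
) -> CausalModel:
    """Model with the canonical trio structure A -> x1 -> x2 (-> ...).

    The activator targets the first marker; markers beyond
    ``chain_length`` are isolated.  Handy as a known ground truth for the
    trio-mining and scoring stages.
    """
    B = np.zeros((p, p))
    for i in range(1, min(chain_length, p)):
        B[i, i - 1] = chain_coef
    a = np.zeros(p)
    a[0] = activator_effect
    lab = tuple(labels) if labels is not None else _default_labels(p)
    return CausalModel(B=B, Sigma_eps=np.eye(p), a=a, labels=lab)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_condition(
    model: CausalModel,
    intervention_variances: np.ndarray | None = None,
    activation_on: bool = False,
    n: int = 100,
    seed: int | np.random.Generator | None = None,
    meta: ConditionKey | None = None,
) -> CellTable:
    """Draw ``n`` i.i.d. cells from one experimental condition.

    Every cell solves the equilibrium equation
    ``x = (I - B)^{-1} (a A + c + eps)`` with ``A`` fixed to 0/1 for the
    whole table, ``c ~ N(0, diag(v))`` and ``eps ~ N(0, Sigma_eps)``.
    """
    if n < 1:
        raise ValueError("need at least one cell (n >= 1)")
    p = model.p
    v = np.zeros(p) if intervention_variances is None else np.asarray(
        intervention_variances, dtype=float
    )
    if v.shape != (p,) or np.any(v < 0):
        raise ValueError("intervention_variances must be length-p and nonnegative")
    rng = np.random.default_rng(seed)
    # Cholesky with a PSD-safe fallback for rank-deficient noise covariances.
    try:
        L = np.linalg.cholesky(model.Sigma_eps)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(model.Sigma_eps)
        L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    eps = rng.standard_normal((n, p)) @ L.T
    shift = rng.standard_normal((n, p)) * np.sqrt(v)
    A = 1 if activation_on else 0
    exo = eps + shift + A * model.a
    values = np.linalg.solve(np.eye(p) - model.B, exo.T).T
    if meta is None:
        meta = ConditionKey("pop", "act" if activation_on else REFERENCE, "none", 0, 0)
    return CellTable(
        values=values,
        labels=model.labels,
        meta=meta,
        activation=np.full(n, A, dtype=int),
    )


@dataclass
class StudyDesign:
    """Experimental layout: which conditions exist and how large they are.

    ``inhibitors`` maps each inhibitor name to its dosage schedule, an
    ``n_dosages x p`` array of intervention variances whose first row
    (dose zero) must be all zero so that the dose-zero plates of all
    inhibitors are i.i.d. replicates of the same distribution.
    ``n_per_condition`` is an int, a mapping keyed by
    :class:`ConditionKey`, or a callable ``key -> int``; a size of zero
    drops that condition from the bundle (logged).
    """

    activators: Sequence[str]
    inhibitors: Mapping[str, np.ndarray]
    n_per_condition: int | Mapping[ConditionKey, int] | Callable[[ConditionKey], int] = 200
    subpopulations: Sequence[str] = ("pop1",)

    def __post_init__(self) -> None:
        if not self.inhibitors or not self.subpopulations:
            raise ValueError("design must list at least one inhibitor and subpopulation")
        self.inhibitors = {k: np.atleast_2d(np.asarray(v, float)) for k, v in self.inhibitors.items()}
        n_dosages = {v.shape[0] for v in self.inhibitors.values()}
        if len(n_dosages) != 1:
            raise ValueError("all inhibitors must share the same dosage count")
        for name, sched in self.inhibitors.items():
            if np.any(sched < 0):
                raise ValueError(f"negative intervention variance for inhibitor {name}")
            if np.any(sched[0] != 0):
                raise ValueError(
                    f"dose-zero schedule of inhibitor {name} must be all zero "
                    "(dose-zero plates are replicates of one distribution)"
                )

    @property
    def n_dosages(self) -> int:
        return next(iter(self.inhibitors.values())).shape[0]

    def size_for(self, key: ConditionKey) -> int:
        if callable(self.n_per_condition):
            return int(self.n_per_condition(key))
        if isinstance(self.n_per_condition, Mapping):
            return int(self.n_per_condition.get(key, 0))
        return int(self.n_per_condition)


def make_study_design(
    model: CausalModel,
    n_inhibitors: int = 27,
    n_dosages: int = 8,
    activators: Sequence[str] = ("act1",),
    n_per_condition: int | Mapping | Callable = 200,
    targets_per_inhibitor: int = 2,
    max_dose_variance: float = 2.0,
    seed: int | np.random.Generator | None = None,
    subpopulations: Sequence[str] = ("pop1",),
) -> StudyDesign:
    """Random dosage schedules mirroring the reference study layout.

    Defaults follow the emulated design: 27 inhibitor plates, 8 dosages
    each, dose zero carrying no intervention.  Each inhibitor acts on a
    random set of markers with variance ramping linearly in dosage up to
    ``max_dose_variance``.
    """
    rng = np.random.default_rng(seed)
    inhibitors = {}
    for i in range(n_inhibitors):
        sched = np.zeros((n_dosages, model.p))
        k = min(targets_per_inhibitor, model.p)
        targets = rng.choice(model.p, size=k, replace=False)
        strength = rng.uniform(0.5, 1.0, size=k) * max_dose_variance
        for d in range(1, n_dosages):
            sched[d, targets] = strength * d / max(n_dosages - 1, 1)
        inhibitors[f"inh{i + 1:02d}"] = sched
    return StudyDesign(
        activators=tuple(activators),
        inhibitors=inhibitors,
        n_per_condition=n_per_condition,
        subpopulations=tuple(subpopulations),
    )


def _condition_seed(master: int | None, key: ConditionKey) -> np.random.SeedSequence:
    crc = zlib.crc32(repr(key).encode())
    return np.random.SeedSequence((0 if master is None else int(master), crc))


def simulate_study(
    model: CausalModel,
    design: StudyDesign,
    seed: int | None = None,
) -> StudyBundle:
    """Simulate every condition of ``design`` from ``model``.

    One master seed; each condition uses a seed derived deterministically
    from the master seed and the condition key, so any sub-table is
    reproducible in isolation.
    """
    tables: dict[ConditionKey, CellTable] = {}
    for subpop in design.subpopulations:
        for inhibitor, schedule in design.inhibitors.items():
            for dosage in range(design.n_dosages):
                for activator in (REFERENCE, *design.activators):
                    key = ConditionKey(subpop, activator, inhibitor, dosage, 0)
                    n = design.size_for(key)
                    if n < 1:
                        logger.info("condition %s has n=0; dropped", key)
                        continue
                    tables[key] = simulate_condition(
                        model,
                        intervention_variances=schedule[dosage],
                        activation_on=activator != REFERENCE,
                        n=n,
                        seed=np.random.default_rng(_condition_seed(seed, key)),
                        meta=key,
                    )
    if not tables:
        raise ValueError("design produced no conditions")
    return StudyBundle(tables=tables, labels=model.labels, model_hash=model.content_hash())


# ---------------------------------------------------------------------------
# on-disk format: one CSV per condition + a JSON manifest
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.9g"


def write_study(bundle: StudyBundle, directory: str | Path) -> Path:
    """Write one CSV per condition plus ``manifest.json``.

    Floats are written with 9 significant digits; the manifest records
    keys, sizes, marker labels and the generating-model hash.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for key in bundle.keys():
        table = bundle.tables[key]
        fname = key.filename()
        table.to_frame().to_csv(directory / fname, index=False, float_format=_FLOAT_FMT)
        entries.append(
            {
                "file": fname,
                "subpopulation": key.subpopulation,
                "activator": key.activator,
                "inhibitor": key.inhibitor,
                "dosage": key.dosage,
                "replicate": key.replicate,
                "n": table.n,
            }
        )
    manifest = {
        "labels": list(bundle.labels),
        "model_hash": bundle.model_hash,
        "conditions": entries,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def read_study(directory: str | Path) -> StudyBundle:
    """Read a study written by :func:`write_study`; validates each file."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}: not a study directory")
    manifest = json.loads(manifest_path.read_text())
    labels = tuple(manifest["labels"])
    if not manifest["conditions"]:
        raise ValueError(f"study in {directory} lists no conditions")
    tables: dict[ConditionKey, CellTable] = {}
    for entry in manifest["conditions"]:
        path = directory / entry["file"]
        df = pd.read_csv(path)
        has_act = "activation" in df.columns
        markers = tuple(c for c in df.columns if c != "activation")
        if markers != labels:
            raise ValueError(
                f"{path.name}: marker columns {markers} do not match manifest labels {labels}"
            )
        if len(df) != entry["n"]:
            raise ValueError(f"{path.name}: row count {len(df)} != manifest n {entry['n']}")
        key = ConditionKey(
            entry["subpopulation"],
            entry["activator"],
            entry["inhibitor"],
            int(entry["dosage"]),
            int(entry["replicate"]),
        )
        tables[key] = CellTable(
            values=df[list(labels)].to_numpy(float),
            labels=labels,
            meta=key,
            activation=df["activation"].to_numpy(int) if has_act else None,
        )
    return StudyBundle(tables=tables, labels=labels, model_hash=manifest.get("model_hash"))
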