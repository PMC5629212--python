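"""Conservative local causal discovery (CLCD) over activation trios.

For every (activator, subpopulation, marker pair) trio the activated and
reference cells of one replicate plate are pooled with a binary
activation column ``A``.  Because ``A`` is set by the experimenter it
has no causes among the markers, so the conditional-(in)dependence
pattern

    S ~ A,  T ~ A,  S ~ T,  S ~ T | A,  S ~ A | T   all dependent
    T _||_ A | S                                    independent

identifies the chain ``A -> S -> T`` and licenses the prediction
"S causes T" — even under latent confounding or an S-T feedback loop,
where the conditional independence of A and T given S would fail.

All six tests are run with dual thresholds (reject below ``alpha``,
accept above ``beta``); a trio only counts when every required verdict
is decisive.  Predictions additionally require the same pattern in at
least ``min_support`` of the replicate dose-zero plates (default 10 of
27), which guards against single-plate artifacts.

Label semantics
---------------
The four shared dependence tests (S~A, T~A, S~T, S~T|A) are necessary
for a chain in either direction, so they are evaluated first: if any is
accepted independent the trio is ``no_pattern``; if any is in the
uncertain band the trio is ``uncertain``; only when all four reject
independence are the two conditional tests involving ``A`` consulted to
orient the pair (or declare it uncertain/no_pattern).  This hierarchy
also means the two logistic tests are skipped whenever they cannot
change the outcome.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ci_tests import (
    MIN_CELLS,
    CITestError,
    Decision,
    DecisionThresholds,
    decide,
    fisher_z_test,
    logistic_lr_test,
    t_test_marginal,
)
from .synthetic import CellTable, ConditionKey, StudyBundle

logger = logging.getLogger(__name__)

__all__ = [
    "TrioLabel",
    "TrioOutcome",
    "CLCDPrediction",
    "UndersizedTableError",
    "pool_activation",
    "evaluate_trio",
    "aggregate_replicates",
    "run_clcd",
    "rank_predictions",
    "threshold_sensitivity",
]


class UndersizedTableError(ValueError):
    """A table has fewer cells than the minimum usable count."""


class TrioLabel(enum.Enum):
    CHAIN_S_TO_T = "chain_S_to_T"
    CHAIN_T_TO_S = "chain_T_to_S"
    NO_PATTERN = "no_pattern"
    UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class TrioOutcome:
    """Verdict for one (S, T) pair on one pooled replicate plate.

    ``p_values`` holds up to six entries keyed ``pSA, pTA, pST, pST.A,
    pSA.T, pTA.S``; the last two are absent when the shared tests
    already settled the label.
    """

    S: str
    T: str
    label: TrioLabel
    p_values: dict[str, float | None]


@dataclass(frozen=True)
class CLCDPrediction:
    cause: str
    effect: str
    activator: str
    subpopulation: str
    support: int
    total_replicates: int

    def __post_init__(self) -> None:
        if not (0 < self.support <= self.total_replicates):
            raise ValueError("support must lie in (0, total_replicates]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.cause, self.effect)


def pool_activation(reference: CellTable, activated: CellTable) -> CellTable:
    """Pool reference and activated cells with a binary activation column.

    Markers are aligned by label; either table with fewer than
    ``MIN_CELLS`` cells aborts the pooling (the caller skips the plate).
    """
    if set(reference.labels) != set(activated.labels):
        raise ValueError("cannot pool tables with different marker sets")
    if reference.n < MIN_CELLS or activated.n < MIN_CELLS:
        raise UndersizedTableError(
            f"plate {activated.meta.inhibitor}/{activated.meta.replicate}: "
            f"n_ref={reference.n}, n_act={activated.n} < {MIN_CELLS}"
        )
    order = [reference.labels.index(lbl) for lbl in activated.labels]
    values = np.vstack([reference.values[:, order], activated.values])
    activation = np.concatenate(
        [np.zeros(reference.n, dtype=int), np.ones(activated.n, dtype=int)]
    )
    return CellTable(
        values=values,
        labels=activated.labels,
        meta=activated.meta,
        activation=activation,
    )


_PV_KEYS = ("pSA", "pTA", "pST", "pST.A", "pSA.T", "pTA.S")


def _label_from_pvalues(
    pv: dict[str, float | None], thresholds: DecisionThresholds
) -> TrioLabel:
    shared = [pv["pSA"], pv["pTA"], pv["pST"], pv["pST.A"]]
    verdicts = [decide(p, thresholds) for p in shared]
    if Decision.UNCERTAIN in verdicts:
        return TrioLabel.UNCERTAIN
    if Decision.INDEPENDENT in verdicts:
        return TrioLabel.NO_PATTERN
    # all four shared dependencies reject independence; orient via A
    p_sa_t, p_ta_s = pv["pSA.T"], pv["pTA.S"]
    if p_sa_t is None or p_ta_s is None:
        return TrioLabel.UNCERTAIN
    d_sa_t = decide(p_sa_t, thresholds)
    d_ta_s = decide(p_ta_s, thresholds)
    if d_sa_t is Decision.DEPENDENT and d_ta_s is Decision.INDEPENDENT:
        return TrioLabel.CHAIN_S_TO_T
    if d_ta_s is Decision.DEPENDENT and d_sa_t is Decision.INDEPENDENT:
        return TrioLabel.CHAIN_T_TO_S
    if Decision.UNCERTAIN in (d_sa_t, d_ta_s):
        return TrioLabel.UNCERTAIN
    return TrioLabel.NO_PATTERN


def evaluate_trio(
    pooled: CellTable,
    S: str,
    T: str,
    thresholds: DecisionThresholds = DecisionThresholds(),
    compute_all: bool = False,
) -> TrioOutcome:
    """Run the six-test pattern for one pooled plate and one marker pair.

    Both orientations are judged from the same six p-values; the label
    follows the hierarchy documented in the module docstring.  With
    ``compute_all`` the logistic tests are computed even when the shared
    tests already decided the label (needed to re-threshold outcomes).
    Degenerate columns yield an ``uncertain`` outcome with the cause
    logged rather than an exception.
    """
    if S == T:
        raise ValueError("S and T must differ")
    if pooled.activation is None:
        raise ValueError("pooled table lacks an activation column")
    s = pooled.column(S)
    t = pooled.column(T)
    a = pooled.activation
    pv: dict[str, float | None] = dict.fromkeys(_PV_KEYS)
    try:
        pv["pSA"] = t_test_marginal(s, a).p_value
        pv["pTA"] = t_test_marginal(t, a).p_value
        pv["pST"] = fisher_z_test(s, t).p_value
        pv["pST.A"] = fisher_z_test(s, t, z=a.astype(float), conditioning_labels=("A",)).p_value
        shared = [pv["pSA"], pv["pTA"], pv["pST"], pv["pST.A"]]
        need_logistic = compute_all or all(
            decide(p, thresholds) is Decision.DEPENDENT for p in shared
        )
        if need_logistic:
            pv["pSA.T"] = logistic_lr_test(a, s, z=t, conditioning_labels=(T,)).p_value
            pv["pTA.S"] = logistic_lr_test(a, t, z=s, conditioning_labels=(S,)).p_value
    except CITestError as exc:
        logger.info("trio (%s, %s) on %s: degenerate input (%s)", S, T, pooled.meta, exc)
        return TrioOutcome(S, T, TrioLabel.UNCERTAIN, pv)
    return TrioOutcome(S, T, _label_from_pvalues(pv, thresholds), pv)


def aggregate_replicates(
    outcomes: list[TrioOutcome],
    min_support: int = 10,
    activator: str = "",
    subpopulation: str = "",
) -> CLCDPrediction | None:
    """Turn per-replicate trio outcomes into at most one prediction.

    A direction is emitted iff its chain label appears in at least
    ``min_support`` replicates; if both directions reach support the
    plates contradict each other and nothing is emitted (logged).
    """
    if not outcomes:
        raise ValueError("no trio outcomes to aggregate")
    S, T = outcomes[0].S, outcomes[0].T
    n_s2t = sum(o.label is TrioLabel.CHAIN_S_TO_T for o in outcomes)
    n_t2s = sum(o.label is TrioLabel.CHAIN_T_TO_S for o in outcomes)
    total = len(outcomes)
    if n_s2t >= min_support and n_t2s >= min_support:
        logger.warning(
            "conflicting support for (%s, %s) in %s/%s: %d vs %d replicates",
            S, T, activator, subpopulation, n_s2t, n_t2s,
        )
        return None
    if n_s2t >= min_support:
        return CLCDPrediction(S, T, activator, subpopulation, n_s2t, total)
    if n_t2s >= min_support:
        return CLCDPrediction(T, S, activator, subpopulation, n_t2s, total)
    return None


def _collect_outcomes(
    bundle: StudyBundle,
    thresholds: DecisionThresholds,
    compute_all: bool = False,
) -> dict[tuple[str, str, str, str], list[TrioOutcome]]:
    """Six-test outcomes for every (subpopulation, activator, S, T) trio."""
    out: dict[tuple[str, str, str, str], list[TrioOutcome]] = {}
    for subpop in bundle.subpopulations:
        for activator in bundle.activators:
            pooled_plates = []
            for ref, act in bundle.dose0_plates(subpop, activator):
                try:
                    pooled_plates.append(pool_activation(ref, act))
                except UndersizedTableError as exc:
                    logger.info("skipping undersized plate: %s", exc)
            if not pooled_plates:
                continue
            for S, T in itertools.combinations(sorted(bundle.labels), 2):
                out[(subpop, activator, S, T)] = [
                    evaluate_trio(p, S, T, thresholds, compute_all=compute_all)
                    for p in pooled_plates
                ]
    return out


def run_clcd(
    bundle: StudyBundle,
    thresholds: DecisionThresholds = DecisionThresholds(),
    min_support: int = 10,
) -> list[CLCDPrediction]:
    """Mine all activation trios of a study bundle.

    Iterates activators x subpopulations x unordered marker pairs over
    the dose-zero replicate plates; output order is deterministic
    (sorted keys).
    """
    predictions = []
    for (subpop, activator, S, T), outcomes in sorted(_collect_outcomes(bundle, thresholds).items()):
        pred = aggregate_replicates(outcomes, min_support, activator, subpop)
        if pred is not None:
            predictions.append(pred)
    return predictions


def rank_predictions(
    predictions: list[CLCDPrediction],
) -> list[tuple[tuple[str, str], int]]:
    """Unique (cause, effect) pairs ranked by context frequency.

    Contexts are the (activator, subpopulation) combinations in which a
    pair was predicted; ties are broken lexicographically so the ranking
    is stable across runs.
    """
    counts: dict[tuple[str, str], int] = {}
    for pred in predictions:
        counts[pred.pair] = counts.get(pred.pair, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def predictions_to_frame(predictions: list[CLCDPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cause": p.cause,
                "effect": p.effect,
                "activator": p.activator,
                "subpopulation": p.subpopulation,
                "support": p.support,
                "total": p.total_replicates,
            }
            for p in predictions
        ],
        columns=["cause", "effect", "activator", "subpopulation", "support", "total"],
    )


def threshold_sensitivity(
    bundle: StudyBundle,
    alpha_grid: list[float],
    beta_grid: list[float],
    min_support_grid: list[int] | None = None,
    default_thresholds: DecisionThresholds = DecisionThresholds(),
    default_min_support: int = 10,
) -> pd.DataFrame:
    """Prediction counts and overlap with the default setting on a grid.

    All six p-values are computed once per trio and replicate and then
    re-thresholded, so rows differ only through the decision rule.  The
    overlap column is the Jaccard index of each setting's prediction set
    (cause, effect, activator, subpopulation) against the default's.
    """
    if not alpha_grid or not beta_grid:
        raise ValueError("alpha and beta grids must be nonempty")
    if max(alpha_grid) >= min(beta_grid):
        raise ValueError("every alpha in the grid must be below every beta")
    if min_support_grid is None:
        min_support_grid = [default_min_support]
    outcomes = _collect_outcomes(bundle, default_thresholds, compute_all=True)

    def prediction_set(th: DecisionThresholds, min_support: int) -> set[tuple]:
        preds = set()
        for (subpop, activator, S, T), olist in outcomes.items():
            relabeled = [
                TrioOutcome(o.S, o.T, _label_from_pvalues(o.p_values, th), o.p_values)
                for o in olist
            ]
            pred = aggregate_replicates(relabeled, min_support, activator, subpop)
            if pred is not None:
                preds.add((pred.cause, pred.effect, activator, subpop))
        return preds

    default_set = prediction_set(default_thresholds, default_min_support)
    rows = []
    for alpha in sorted(alpha_grid):
        for beta in sorted(beta_grid):
            for ms in min_support_grid:
                pset = prediction_set(DecisionThresholds(alpha, beta), ms)
                union = pset | default_set
                jac = len(pset & default_set) / len(union) if union else 1.0
                rows.append(
                    {
                        "alpha": alpha,
                        "beta": beta,
                        "min_support": ms,
                        "n_predictions": len(pset),
                        "jaccard_vs_default": jac,
                    }
                )
    return pd.DataFrame(rows)
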