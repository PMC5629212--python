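"""Exact BGe scoring of candidate trio networks for consistency testing.

A trio prediction ``A -> S -> T`` made in one dataset can be checked in
an independent dataset by scoring *all* candidate Bayesian networks
over ``{A, S, T}`` — with the activation indicator ``A`` restricted to
be a source (no incoming edges) — and asking which network the data
prefer.  With the source restriction there are 12 candidate DAGs
(presence of A->S, presence of A->T, and S/T relation in
{none, S->T, T->S}).

Scoring uses the Bayesian Gaussian equivalent (BGe) marginal
likelihood: a Normal-Wishart prior over the mean and precision of a
joint Gaussian, integrated in closed form, which decomposes over nodes
and assigns equal scores to Markov-equivalent DAGs.  The binary
activation indicator is scored as a 0/1-coded continuous variable
inside the Gaussian framework — a deliberate simplification (no
conditional-Gaussian variant), acceptable because only the relative
ranking of networks sharing the same data enters the verdict.

A prediction is *consistent* when the top-scoring network is exactly
the predicted chain ``{A->S, S->T}``, *conflicted* when the top network
contains the reversed edge ``T -> S``, and *other* otherwise (including
score ties, resolved conservatively).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .clcd import CLCDPrediction, pool_activation, UndersizedTableError
from .synthetic import REFERENCE, CellTable, StudyBundle

logger = logging.getLogger(__name__)

__all__ = [
    "NODES",
    "CandidateNetwork",
    "ScoredNetwork",
    "ConsistencyVerdict",
    "ConsistencyReport",
    "BGePriorParams",
    "enumerate_candidate_networks",
    "bge_score",
    "score_all_networks",
    "classify_prediction",
    "consistency_analysis",
]

NODES = ("A", "S", "T")
CHAIN_EDGES = frozenset({("A", "S"), ("S", "T")})


@dataclass(frozen=True)
class CandidateNetwork:
    """A DAG over (A, S, T) with A constrained to have no incoming edges."""

    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in NODES or v not in NODES or u == v:
                raise ValueError(f"invalid edge {(u, v)}")
            if v == "A":
                raise ValueError("A must be a source variable (no incoming edges)")
        if ("S", "T") in self.edges and ("T", "S") in self.edges:
            raise ValueError("network must be acyclic")

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.edges if v == node))

    @property
    def name(self) -> str:
        if not self.edges:
            return "empty"
        return "+".join(f"{u}>{v}" for u, v in sorted(self.edges))


@dataclass(frozen=True)
class ScoredNetwork:
    network: CandidateNetwork
    log_score: float


@dataclass(frozen=True)
class ConsistencyVerdict:
    label: str  # consistent | conflicted | other
    best: CandidateNetwork
    scores: tuple[ScoredNetwork, ...]


def enumerate_candidate_networks() -> list[CandidateNetwork]:
    """All 12 source-restricted DAGs over (A, S, T), deterministic order."""
    nets = []
    for a_s in (False, True):
        for a_t in (False, True):
            for st in ("none", "S>T", "T>S"):
                edges = set()
                if a_s:
                    edges.add(("A", "S"))
                if a_t:
                    edges.add(("A", "T"))
                if st == "S>T":
                    edges.add(("S", "T"))
                elif st == "T>S":
                    edges.add(("T", "S"))
                nets.append(CandidateNetwork(frozenset(edges)))
    nets.sort(key=lambda n: (len(n.edges), n.name))
    return nets


@dataclass(frozen=True)
class BGePriorParams:
    """Normal-Wishart hyperparameters for the BGe score.

    ``alpha_mu`` weights the prior mean (taken at the sample mean, so
    the mean-shift term vanishes); ``alpha_w`` is the Wishart degrees of
    freedom, defaulting to ``p + 2 = 5`` for the 3-variable trio; the
    prior scale matrix is ``t * I``.
    """

    alpha_mu: float = 1.0
    alpha_w: float = 5.0
    t: float = 1.0


def _log_subset_marginal(
    R: np.ndarray, subset: tuple[int, ...], n: int, p: int, prior: BGePriorParams
) -> float:
    """Log marginal likelihood of the data restricted to ``subset``.

    ``R`` is the posterior scale matrix ``T0 + S_n`` (prior mean at the
    sample mean).  The degrees of freedom carry the standard
    ``alpha_w - p + l`` adjustment for a subset of size ``l``, which is
    what makes the node-wise ratio score Markov equivalent.
    """
    l = len(subset)
    if l == 0:
        return 0.0
    idx = np.ix_(subset, subset)
    df_prior = prior.alpha_w - p + l
    df_post = df_prior + n
    sign_post, logdet_post = np.linalg.slogdet(R[idx])
    if sign_post <= 0:
        raise ValueError("posterior scale matrix not positive definite (singular data?)")
    logdet_prior = l * np.log(prior.t)
    out = -0.5 * l * n * np.log(np.pi)
    out += 0.5 * l * np.log(prior.alpha_mu / (prior.alpha_mu + n))
    out += _multigammaln_half(df_post, l) - _multigammaln_half(df_prior, l)
    out += 0.5 * df_prior * logdet_prior - 0.5 * df_post * logdet_post
    return out


def _multigammaln_half(df: float, l: int) -> float:
    """log Gamma_l(df / 2) (multivariate gamma)."""
    return float(
        0.25 * l * (l - 1) * np.log(np.pi)
        + sum(gammaln((df - i) / 2) for i in range(l))
    )


def bge_score(
    data: np.ndarray,
    network: CandidateNetwork,
    prior: BGePriorParams = BGePriorParams(),
) -> float:
    """Log BGe marginal likelihood of a candidate network.

    ``data`` has columns in :data:`NODES` order (A, S, T) with A coded
    0/1.  The score decomposes over nodes as
    ``sum_v [ log m(family(v)) - log m(parents(v)) ]`` with the subset
    marginals of :func:`_log_subset_marginal`.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if p != len(NODES):
        raise ValueError("data must have exactly the three trio columns (A, S, T)")
    if n < 3:
        raise ValueError("need at least three observations")
    if np.any(X.std(axis=0) == 0):
        bad = NODES[int(np.argmin(X.std(axis=0)))]
        raise ValueError(f"column {bad} is constant; the Gaussian score is singular")
    Xc = X - X.mean(axis=0)
    R = prior.t * np.eye(p) + Xc.T @ Xc
    col = {node: i for i, node in enumerate(NODES)}
    total = 0.0
    for node in NODES:
        fam = tuple(sorted(col[v] for v in (*network.parents(node), node)))
        pa = tuple(sorted(col[v] for v in network.parents(node)))
        total += _log_subset_marginal(R, fam, n, p, prior)
        total -= _log_subset_marginal(R, pa, n, p, prior)
    return float(total)


def score_all_networks(
    data: np.ndarray, prior: BGePriorParams = BGePriorParams()
) -> tuple[ScoredNetwork, ...]:
    return tuple(
        ScoredNetwork(net, bge_score(data, net, prior))
        for net in enumerate_candidate_networks()
    )


def _trio_data(pooled: CellTable, S: str, T: str) -> np.ndarray:
    if pooled.activation is None:
        raise ValueError("pooled table lacks an activation column")
    return np.column_stack(
        [pooled.activation.astype(float), pooled.column(S), pooled.column(T)]
    )


def classify_prediction(
    pooled: CellTable,
    prediction: CLCDPrediction,
    prior: BGePriorParams = BGePriorParams(),
    tie_tol: float = 1e-9,
) -> ConsistencyVerdict:
    """Score the 12 candidate networks on independent data and classify.

    ``consistent``: the strict argmax is exactly the predicted chain
    (A->S and S->T only).  ``conflicted``: the argmax contains the
    reversed edge T->S.  Ties within ``tie_tol`` are classified
    ``other`` (conservative).
    """
    data = _trio_data(pooled, prediction.cause, prediction.effect)
    scored = score_all_networks(data, prior)
    log_scores = np.array([s.log_score for s in scored])
    best_idx = int(np.argmax(log_scores))
    best = scored[best_idx].network
    n_top = int(np.sum(log_scores >= log_scores[best_idx] - tie_tol))
    if n_top > 1:
        label = "other"
    elif best.edges == CHAIN_EDGES:
        label = "consistent"
    elif ("T", "S") in best.edges:
        label = "conflicted"
    else:
        label = "other"
    return ConsistencyVerdict(label, best, scored)


@dataclass(frozen=True)
class ConsistencyReport:
    n_predictions: int
    fraction_consistent: float
    fraction_conflicted: float
    fraction_other: float
    baseline_consistency: tuple[float, ...]
    t_statistic: float
    p_value: float
    verdicts: tuple[tuple[CLCDPrediction, str], ...]


def _pooled_stratum_table(
    bundle: StudyBundle, subpopulation: str, activator: str
) -> CellTable | None:
    """All dose-zero reference/activated cells of one stratum, pooled."""
    plates = bundle.dose0_plates(subpopulation, activator)
    pooled = []
    for ref, act in plates:
        try:
            pooled.append(pool_activation(ref, act))
        except UndersizedTableError:
            continue
    if not pooled:
        return None
    values = np.vstack([t.values for t in pooled])
    activation = np.concatenate([t.activation for t in pooled])
    return CellTable(values, pooled[0].labels, pooled[0].meta, activation)


def consistency_analysis(
    predictions: list[CLCDPrediction],
    independent_bundle: StudyBundle,
    n_random: int = 10,
    seed: int | np.random.Generator | None = None,
    prior: BGePriorParams = BGePriorParams(),
) -> ConsistencyReport:
    """Consistency of predictions in an independent dataset vs chance.

    Every prediction is scored on the pooled dose-zero cells of its
    (subpopulation, activator) stratum in the independent bundle
    (missing strata are skipped with a log entry).  The chance baseline
    re-draws, ``n_random`` times, the same number of random ordered
    marker pairs per stratum and computes their consistency rate.  A
    one-tailed one-sample t-test compares the baseline rates against
    the observed rate (alternative: observed exceeds chance).
    """
    if not predictions:
        raise ValueError("no predictions to analyze")
    if n_random < 1:
        raise ValueError("n_random must be at least 1")
    rng = np.random.default_rng(seed)
    labels = independent_bundle.labels

    strata: dict[tuple[str, str], CellTable | None] = {}
    verdicts: list[tuple[CLCDPrediction, str]] = []
    per_stratum_count: dict[tuple[str, str], int] = {}
    for pred in predictions:
        stratum = (pred.subpopulation, pred.activator)
        if stratum not in strata:
            strata[stratum] = _pooled_stratum_table(independent_bundle, *stratum)
        table = strata[stratum]
        if table is None:
            logger.info("no matching condition for %s; prediction skipped", pred)
            continue
        verdicts.append((pred, classify_prediction(table, pred, prior).label))
        per_stratum_count[stratum] = per_stratum_count.get(stratum, 0) + 1
    if not verdicts:
        raise ValueError("no prediction matched a condition in the independent bundle")

    n = len(verdicts)
    labels_v = [v for _, v in verdicts]
    frac_cons = labels_v.count("consistent") / n
    frac_conf = labels_v.count("conflicted") / n
    frac_other = labels_v.count("other") / n

    baseline = []
    for _ in range(n_random):
        hits = total = 0
        for stratum, count in per_stratum_count.items():
            table = strata[stratum]
            for _ in range(count):
                cause, effect = rng.choice(len(labels), size=2, replace=False)
                fake = CLCDPrediction(
                    labels[cause], labels[effect], stratum[1], stratum[0], 1, 1
                )
                hits += classify_prediction(table, fake, prior).label == "consistent"
                total += 1
        baseline.append(hits / total)
    base = np.asarray(baseline)
    sd = base.std(ddof=1) if n_random > 1 else 0.0
    if sd == 0:
        warnings.warn("zero variance across random baselines; p-value at boundary")
        t_stat = np.inf if frac_cons > base.mean() else -np.inf
        p = 0.0 if frac_cons > base.mean() else 1.0
    else:
        t_stat = float((frac_cons - base.mean()) / (sd / np.sqrt(n_random)))
        p = float(stats.t.sf(t_stat, df=n_random - 1))
    return ConsistencyReport(
        n_predictions=n,
        fraction_consistent=frac_cons,
        fraction_conflicted=frac_conf,
        fraction_other=frac_other,
        baseline_consistency=tuple(base),
        t_statistic=t_stat,
        p_value=p,
        verdicts=tuple(verdicts),
    )
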