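"""Connectivity estimation from shift-intervention environments.

A linear causal system ``x = B x + c^e + eps`` observed under different
environments ``e`` (here: dosages of one inhibitor) satisfies

    (I - B) Sigma_x^e (I - B)^T  =  Sigma_eps + Sigma_c^e

where the noise covariance ``Sigma_eps`` is invariant across
environments and each intervention covariance ``Sigma_c^e`` is
diagonal.  Differencing the observed covariances against their pooled
average therefore cancels ``Sigma_eps``, leaving matrices that
``(I - B)`` must render diagonal simultaneously.  ``B`` is estimated by

1. non-orthogonal joint diagonalization of the covariance differences
   (an FFDIAG-style iterative scheme), which recovers ``I - B`` up to
   row permutation and scaling;
2. resolving that ambiguity with a linear sum assignment maximizing the
   permuted diagonal, then rescaling each row to unit diagonal.

At least three environments (one may be purely observational) are
required for identifiability.  Model violations — interventions on
hidden variables, correlated interventions within an environment —
leave the differences non-diagonalizable, which a parametric bootstrap
on the attained residual detects.  Stability selection over subsample
refits bounds the expected number of falsely selected edges.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .synthetic import CellTable

logger = logging.getLogger(__name__)

__all__ = [
    "EnvironmentSet",
    "ConnectivityEstimate",
    "DiagnosticsReport",
    "StabilityConfig",
    "StabilitySelectionResult",
    "JointDiagonalizationError",
    "ModelViolationError",
    "environment_covariances",
    "joint_diagonalize",
    "resolve_scale_permutation",
    "estimate_backshift",
    "diagnose_model",
    "stability_select",
    "keep_count",
]


class JointDiagonalizationError(RuntimeError):
    """Joint diagonalization failed to converge or is ill-posed."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ModelViolationError(RuntimeError):
    """Diagnostics indicate the shift-intervention model does not hold."""


@dataclass(frozen=True)
class EnvironmentSet:
    """Sample covariances of a common marker set across environments."""

    covariances: tuple[np.ndarray, ...]
    ns: tuple[int, ...]
    labels: tuple[str, ...]
    samples: tuple[np.ndarray, ...] | None = None  # kept for subsampling

    def __post_init__(self) -> None:
        if len(self.covariances) < 3:
            raise ValueError(
                "at least three environments are required for identifiability"
            )
        if len(self.ns) != len(self.covariances):
            raise ValueError("one sample size per environment required")

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def n_environments(self) -> int:
        return len(self.covariances)


@dataclass(frozen=True)
class ConnectivityEstimate:
    B_hat: np.ndarray
    intervention_variances: np.ndarray  # n_env x p
    diagonalization_residual: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(np.diag(self.B_hat) != 0):
            raise ValueError("estimated connectivity must have zero diagonal")
        if self.diagonalization_residual < 0:
            raise ValueError("residual must be nonnegative")

    def edges(self, threshold: float = 0.0) -> list[tuple[str, str, float]]:
        """(cause, effect, coefficient) triples with |coef| > threshold."""
        out = []
        for i, j in itertools.product(range(len(self.labels)), repeat=2):
            if i != j and abs(self.B_hat[i, j]) > threshold:
                out.append((self.labels[j], self.labels[i], float(self.B_hat[i, j])))
        return out


@dataclass(frozen=True)
class DiagnosticsReport:
    observed_residual: float
    ci_lower: float
    ci_upper: float
    success: bool
    n_boot: int
    n_failed: int = 0


@dataclass(frozen=True)
class StabilityConfig:
    """Stability-selection parameters.

    ``ev`` bounds the expected number of falsely selected edges; each of
    ``n_sim`` subsample refits keeps its ``q`` largest-magnitude edges
    with ``q = floor(sqrt(ev * (2 pi_thr - 1) * p (p - 1)))``, and an
    edge is stable when kept in more than ``pi_thr * n_sim`` refits.
    The whole result is discarded unless at least ``min_success`` refits
    diagonalized successfully.
    """

    ev: float = 5.0
    n_sim: int = 100
    pi_thr: float = 0.75
    min_success: int = 75

    def __post_init__(self) -> None:
        if not (0.5 < self.pi_thr < 1.0):
            raise ValueError("pi_thr must lie in (0.5, 1)")
        if self.n_sim < 1:
            raise ValueError("n_sim must be at least 1")


@dataclass(frozen=True)
class StabilitySelectionResult:
    stable_edges: list[tuple[str, str, float]]  # (cause, effect, frequency)
    selection_frequency: np.ndarray  # p x p, fraction of refits selecting B[i, j]
    n_success: int
    config: StabilityConfig


def keep_count(p: int, config: StabilityConfig = StabilityConfig()) -> int:
    """Edges kept per refit from the E(V) <= q^2 / ((2 pi_thr - 1) m) bound.

    Inverting the bound for ``m = p (p - 1)`` candidate edges gives
    ``q = floor(sqrt(ev * (2 pi_thr - 1) * p (p - 1)))``.
    """
    return int(math.floor(math.sqrt(config.ev * (2 * config.pi_thr - 1) * p * (p - 1))))


def environment_covariances(tables: list[CellTable]) -> EnvironmentSet:
    """Unbiased sample covariances, one per environment table."""
    if not tables:
        raise ValueError("no environment tables given")
    labels = tables[0].labels
    p = len(labels)
    covs, ns, samples = [], [], []
    for table in tables:
        if table.labels != labels:
            raise ValueError("environments must share one marker set")
        if table.n < p + 1:
            raise ValueError(
                f"environment {table.meta} has n={table.n} <= p={p}; "
                "covariance would be rank-deficient"
            )
        variances = table.values.var(axis=0)
        if np.any(variances == 0):
            bad = labels[int(np.argmin(variances))]
            raise ValueError(f"marker {bad} is constant in environment {table.meta}")
        covs.append(np.cov(table.values, rowvar=False))
        ns.append(table.n)
        samples.append(table.values)
    return EnvironmentSet(tuple(covs), tuple(ns), labels, tuple(samples))


def _off_fraction(W: np.ndarray, diffs: list[np.ndarray]) -> float:
    """Scale-normalized residual: off-diagonal share of total mass."""
    off = tot = 0.0
    for D in diffs:
        M = W @ D @ W.T
        tot += float(np.sum(M**2))
        off += float(np.sum(M**2) - np.sum(np.diag(M) ** 2))
    return off / tot if tot > 0 else 0.0


def joint_diagonalize(
    cov_differences: list[np.ndarray],
    tol: float = 1e-10,
    max_iter: int = 1000,
    theta: float = 0.9,
) -> tuple[np.ndarray, float]:
    """Simultaneously diagonalize symmetric matrices with one matrix ``W``.

    Minimizes the summed squared off-diagonal mass of ``W D_k W^T`` by
    an FFDIAG-style scheme: each sweep solves, per index pair, the 2x2
    least-squares problem of the linearized update ``W <- (I + U) W``
    (``U`` zero-diagonal), with the update norm capped at ``theta`` to
    keep ``I + U`` invertible and rows renormalized to unit length.
    Deterministic: always initialized at the identity.

    Returns ``(W, residual)`` where the residual is the attained
    off-diagonal fraction of total mass.  Raises
    :class:`JointDiagonalizationError` on non-convergence.
    """
    diffs = [np.asarray(D, float) for D in cov_differences]
    if len(diffs) < 2:
        raise ValueError("need at least two difference matrices (three environments)")
    p = diffs[0].shape[0]
    for D in diffs:
        if D.shape != (p, p) or not np.allclose(D, D.T, atol=1e-8 * max(1.0, np.abs(D).max())):
            raise ValueError("difference matrices must be square and symmetric")
    diffs = [(D + D.T) / 2 for D in diffs]
    W = np.eye(p)
    prev = _off_fraction(W, diffs)
    for _ in range(max_iter):
        Ds = np.stack([W @ D @ W.T for D in diffs])  # K x p x p
        d = np.einsum("kii->ki", Ds)  # K x p diagonals
        # pairwise normal equations: minimize sum_k (D_ij + U_ij d_j + U_ji d_i)^2
        a = d.T @ d  # a[i, j] = sum_k d_i d_j ; a[j, j] etc.
        r = np.einsum("kij,kj->ij", Ds, d)  # r[i, j] = sum_k D_ij d_j
        U = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                A = np.array([[a[j, j], a[i, j]], [a[i, j], a[i, i]]])
                b = -np.array([r[i, j], r[j, i]])
                det = A[0, 0] * A[1, 1] - A[0, 1] ** 2
                if det <= 1e-300:
                    continue
                uij, uji = np.linalg.solve(A, b)
                U[i, j], U[j, i] = uij, uji
        norm = np.linalg.norm(U)
        if norm > theta:
            U *= theta / norm
        # backtracking: the linearized step can overshoot on noisy input,
        # so accept the first damping that strictly improves the residual
        improved = False
        for step in (1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125):
            W_new = (np.eye(p) + step * U) @ W
            W_new /= np.linalg.norm(W_new, axis=1, keepdims=True)
            cur = _off_fraction(W_new, diffs)
            if cur < prev - tol * max(prev, 1e-300):
                W, prev = W_new, cur
                improved = True
                break
        if not improved:  # local minimum to within tol
            return W, prev
    raise JointDiagonalizationError(
        f"joint diagonalization did not converge in {max_iter} iterations "
        f"(last residual {prev:.3e})",
        residual=prev,
    )


def resolve_scale_permutation(W: np.ndarray) -> np.ndarray:
    """Fix the row permutation and scaling of a diagonalizer.

    Joint diagonalization determines ``I - B`` only up to row
    permutation and scaling.  The permutation is chosen by a linear sum
    assignment maximizing ``sum log |W[sigma(i), i]|`` (equivalently the
    product of permuted diagonal magnitudes); rows are then rescaled to
    unit diagonal and ``B_hat = I - W`` has an exactly zero diagonal.
    """
    W = np.asarray(W, float)
    p = W.shape[0]
    absW = np.abs(W)
    if np.any(absW.max(axis=0) == 0):
        raise JointDiagonalizationError("unresolvable permutation: zero column in W")
    with np.errstate(divide="ignore"):
        cost = -np.log(absW)
    cost[np.isinf(cost)] = 1e12
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(p, dtype=int)
    perm[cols] = rows
    Wp = W[perm]
    diag = np.diag(Wp).copy()
    if np.any(np.abs(diag) < 1e-12):
        raise JointDiagonalizationError("unresolvable permutation: zero diagonal entry")
    B_hat = np.eye(p) - Wp / diag[:, None]
    np.fill_diagonal(B_hat, 0.0)
    return B_hat


def _covariance_differences(
    covariances: tuple[np.ndarray, ...], pairwise: bool = False
) -> list[np.ndarray]:
    if pairwise:
        return [
            covariances[i] - covariances[j]
            for i, j in itertools.combinations(range(len(covariances)), 2)
        ]
    pooled = np.mean(covariances, axis=0)
    return [C - pooled for C in covariances]


def estimate_backshift(
    env_set: EnvironmentSet,
    pairwise_differences: bool = False,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> ConnectivityEstimate:
    """Point estimate of the connectivity matrix from >= 3 environments.

    Differences are taken against the pooled-average covariance by
    default (cancelling the invariant noise covariance); pairwise
    differencing is available via the flag.  Per-environment
    intervention-variance estimates are the diagonal of
    ``(I - B_hat) Sigma_x^e (I - B_hat)^T`` minus its environmentwise
    minimum (so the smallest-intervention environment is the baseline),
    clipped at zero.
    """
    diffs = _covariance_differences(env_set.covariances, pairwise_differences)
    W, residual = joint_diagonalize(diffs, tol=tol, max_iter=max_iter)
    B_hat = resolve_scale_permutation(W)
    A = np.eye(env_set.p) - B_hat
    raw = np.stack([np.diag(A @ C @ A.T) for C in env_set.covariances])
    variances = raw - raw.min(axis=0)
    if np.any(variances < 0):
        logger.info("clipped negative intervention-variance estimates at zero")
        variances = np.clip(variances, 0.0, None)
    return ConnectivityEstimate(B_hat, variances, residual, env_set.labels)


def _fitted_noise_covariance(
    env_set: EnvironmentSet, estimate: ConnectivityEstimate
) -> np.ndarray:
    """PSD estimate of Sigma_eps implied by the fitted model."""
    A = np.eye(env_set.p) - estimate.B_hat
    stacks = [
        A @ C @ A.T - np.diag(v)
        for C, v in zip(env_set.covariances, estimate.intervention_variances)
    ]
    S = np.mean(stacks, axis=0)
    S = (S + S.T) / 2
    w, V = np.linalg.eigh(S)
    return V @ np.diag(np.clip(w, 1e-8, None)) @ V.T


def diagnose_model(
    env_set: EnvironmentSet,
    n_boot: int = 100,
    seed: int | np.random.Generator | None = None,
    level: float = 0.95,
) -> DiagnosticsReport:
    """Parametric bootstrap check of the joint-diagonalization residual.

    Datasets are simulated from the fitted model (``B_hat``, estimated
    noise and intervention variances, observed sample sizes) and
    re-diagonalized; the fit is deemed successful when the observed
    residual does not exceed the upper ``level`` quantile of the
    bootstrap residuals, i.e. when the data are no harder to
    diagonalize than data for which the model holds by construction.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    rng = np.random.default_rng(seed)
    estimate = estimate_backshift(env_set)
    Sigma_eps = _fitted_noise_covariance(env_set, estimate)
    L = np.linalg.cholesky(Sigma_eps + 1e-10 * np.eye(env_set.p))
    A = np.eye(env_set.p) - estimate.B_hat
    Ainv = np.linalg.inv(A)
    residuals = []
    n_failed = 0
    for _ in range(n_boot):
        covs = []
        for n_e, v_e in zip(env_set.ns, estimate.intervention_variances):
            eps = rng.standard_normal((n_e, env_set.p)) @ L.T
            shift = rng.standard_normal((n_e, env_set.p)) * np.sqrt(v_e)
            x = (eps + shift) @ Ainv.T
            covs.append(np.cov(x, rowvar=False))
        try:
            _, res = joint_diagonalize(_covariance_differences(tuple(covs)))
            residuals.append(res)
        except JointDiagonalizationError:
            n_failed += 1
    if not residuals:
        raise ModelViolationError("every bootstrap diagonalization failed")
    lo = float(np.quantile(residuals, (1 - level) / 2))
    hi = float(np.quantile(residuals, level))
    observed = estimate.diagonalization_residual
    return DiagnosticsReport(
        observed_residual=observed,
        ci_lower=lo,
        ci_upper=hi,
        success=bool(observed <= hi),
        n_boot=n_boot,
        n_failed=n_failed,
    )


def stability_select(
    env_set: EnvironmentSet,
    config: StabilityConfig = StabilityConfig(),
    seed: int | np.random.Generator | None = None,
) -> StabilitySelectionResult:
    """Stable edge set over half-subsample refits.

    Each refit draws half of every environment without replacement,
    re-estimates ``B`` and keeps its ``q`` largest-magnitude edges; an
    edge is stable when kept in more than ``pi_thr * n_sim`` refits.
    Raises :class:`ModelViolationError` when fewer than ``min_success``
    refits diagonalize successfully; an empty stable set is a valid
    result.
    """
    if env_set.samples is None:
        raise ValueError("stability selection needs the per-environment samples")
    rng = np.random.default_rng(seed)
    p = env_set.p
    q = keep_count(p, config)
    counts = np.zeros((p, p))
    n_success = 0
    for _ in range(config.n_sim):
        covs, ns = [], []
        try:
            for X in env_set.samples:
                half = X.shape[0] // 2
                if half < p + 1:
                    raise ValueError("subsample smaller than p + 1")
                idx = rng.choice(X.shape[0], size=half, replace=False)
                covs.append(np.cov(X[idx], rowvar=False))
                ns.append(half)
            sub = EnvironmentSet(tuple(covs), tuple(ns), env_set.labels)
            est = estimate_backshift(sub)
        except (JointDiagonalizationError, ValueError, np.linalg.LinAlgError):
            continue
        n_success += 1
        mags = np.abs(est.B_hat).copy()
        np.fill_diagonal(mags, -np.inf)
        flat = np.argsort(mags, axis=None)[::-1][:q]
        sel = np.zeros((p, p), dtype=bool)
        sel.flat[flat] = True
        counts += sel
    if n_success < config.min_success:
        raise ModelViolationError(
            f"model violated: joint diagonalization succeeded in only "
            f"{n_success}/{config.n_sim} subsample refits (< {config.min_success})"
        )
    frequency = counts / config.n_sim
    stable = counts > config.pi_thr * config.n_sim
    edges = [
        (env_set.labels[j], env_set.labels[i], float(frequency[i, j]))
        for i, j in zip(*np.nonzero(stable))
    ]
    return StabilitySelectionResult(
        stable_edges=sorted(edges),
        selection_frequency=frequency,
        n_success=n_success,
        config=config,
    )
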