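"""Conditional-independence tests and the dual-threshold decision rule.

Three tests cover the variable types that arise in an activation trio
(binary activation indicator ``A``, continuous markers):

* marker vs ``A`` marginally — Welch two-sample t-test;
* marker vs marker, optionally given ``A`` — Fisher z-test on the
  (partial) correlation, with the binary indicator entering the
  conditioning set as a 0/1 numeric regressor;
* marker vs ``A`` given another marker — likelihood-ratio test between
  nested logistic regressions (Wald variant available).

Decisions use two separate thresholds: independence is *rejected* when
``p < alpha`` (default 0.001) and *accepted* when ``p > beta`` (default
0.15); p-values in between are treated as uncertain, which is more
conservative than a single cutoff.

Tables with fewer than ``MIN_CELLS`` (20) cells are excluded upstream;
the per-condition cell counts of gated single-cell data can drop below
ten, where none of these asymptotic tests is trustworthy.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MIN_CELLS",
    "CITestError",
    "CITestResult",
    "DecisionThresholds",
    "Decision",
    "t_test_marginal",
    "fisher_z_test",
    "logistic_lr_test",
    "decide",
]

MIN_CELLS = 20  # smallest usable table; undersized conditions are skipped


class CITestError(ValueError):
    """A test's preconditions are violated (degenerate or unusable input)."""


@dataclass(frozen=True)
class CITestResult:
    test_name: str
    statistic: float
    p_value: float
    n_effective: int
    conditioning_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass(frozen=True)
class DecisionThresholds:
    """Reject independence below ``alpha``; accept it above ``beta``."""

    alpha: float = 0.001
    beta: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < self.beta < 1.0):
            raise ValueError(f"need 0 < alpha < beta < 1, got {self.alpha}, {self.beta}")


class Decision(enum.Enum):
    DEPENDENT = "dependent"
    INDEPENDENT = "independent"
    UNCERTAIN = "uncertain"


def decide(p_value: float, thresholds: DecisionThresholds) -> Decision:
    """Dual-threshold verdict on a single p-value."""
    if p_value < thresholds.alpha:
        return Decision.DEPENDENT
    if p_value > thresholds.beta:
        return Decision.INDEPENDENT
    return Decision.UNCERTAIN


def _as_binary(a: np.ndarray, context: str) -> np.ndarray:
    a = np.asarray(a)
    levels = np.unique(a)
    if levels.size != 2:
        raise CITestError(f"{context}: degenerate grouping (needs exactly two levels)")
    return (a == levels[1]).astype(float)


def t_test_marginal(x: np.ndarray, a: np.ndarray) -> CITestResult:
    """Welch two-sample t-test of a marker against the binary indicator.

    Welch's unequal-variance form is used because per-condition cell
    counts and variances differ substantially between activated and
    reference cells.
    """
    x = np.asarray(x, dtype=float)
    a01 = _as_binary(a, "t_test_marginal")
    g0, g1 = x[a01 == 0], x[a01 == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise CITestError("t_test_marginal: each group needs at least two observations")
    if np.var(g0) == 0 and np.var(g1) == 0:
        raise CITestError("t_test_marginal: zero within-group variance in both groups")
    res = stats.ttest_ind(g1, g0, equal_var=False)
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(stat):  # identical group means with one zero-variance group
        stat, p = 0.0, 1.0
    return CITestResult("t_test", stat, p, len(x))


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(Z, v, rcond=None)
    if rank < Z.shape[1]:
        raise CITestError("fisher_z_test: collinear conditioning set")
    return v - Z @ coef


def fisher_z_test(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | None = None,
    conditioning_labels: tuple[str, ...] = (),
) -> CITestResult:
    """Fisher z-test of the (partial) correlation of two markers.

    The conditioning set may include a 0/1-coded binary column; it is
    regressed out linearly along with the continuous conditioners.  The
    statistic is ``atanh(r) * sqrt(n - |z| - 3)`` referred to a standard
    normal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if z is None:
        Zmat = np.empty((n, 0))
    else:
        Zmat = np.asarray(z, dtype=float)
        if Zmat.ndim == 1:
            Zmat = Zmat[:, None]
    k = Zmat.shape[1]
    if n - k - 3 < 1:
        raise CITestError("fisher_z_test: sample too small for the conditioning set")
    design = np.column_stack([np.ones(n), Zmat])
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        raise CITestError("fisher_z_test: constant variable after conditioning")
    r = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-15:
        warnings.warn("fisher_z_test: |partial correlation| = 1; p-value is 0")
        return CITestResult("fisher_z", np.inf * np.sign(r), 0.0, n, conditioning_labels)
    stat = float(np.arctanh(r) * np.sqrt(n - k - 3))
    p = float(2.0 * stats.norm.sf(abs(stat)))
    return CITestResult("fisher_z", stat, p, n, conditioning_labels)


def _logit_loglik(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    """Newton-fitted logistic log-likelihood (and coefficients)."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            fit = model.fit(disp=0, method="newton", maxiter=50)
        except Exception as exc:  # singular Hessian, separation, ...
            raise CITestError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise CITestError("logistic fit did not converge")
    if np.abs(fit.params).max() > 50:
        # quasi-complete separation: coefficients diverge
        raise CITestError(
            "logistic fit shows (quasi-)perfect separation; rerun with "
            "allow_separation=True to report p=0"
        )
    return float(fit.llf), np.asarray(fit.params)


def logistic_lr_test(
    a: np.ndarray,
    x: np.ndarray,
    z: np.ndarray | None = None,
    conditioning_labels: tuple[str, ...] = (),
    method: str = "lr",
    allow_separation: bool = False,
) -> CITestResult:
    """Test ``A _||_ x | z`` by nested logistic regressions of ``A``.

    Compares ``A ~ z + x`` against ``A ~ z``; the default statistic is
    the likelihood ratio ``2 (l1 - l0)`` on chi-square(1).  ``method='wald'``
    uses the Wald z-statistic of the ``x`` coefficient instead.
    """
    if method not in ("lr", "wald"):
        raise ValueError("method must be 'lr' or 'wald'")
    a01 = _as_binary(a, "logistic_lr_test")
    x = np.asarray(x, dtype=float)
    n = len(a01)
    if z is None:
        Zmat = np.empty((n, 0))
    else:
        Zmat = np.asarray(z, dtype=float)
        if Zmat.ndim == 1:
            Zmat = Zmat[:, None]
    if np.var(x) == 0:
        return CITestResult(f"logistic_{method}", 0.0, 1.0, n, conditioning_labels)
    X0 = np.column_stack([np.ones(n), Zmat])
    X1 = np.column_stack([X0, x])
    try:
        ll1, params = _logit_loglik(a01, X1)
        ll0, _ = _logit_loglik(a01, X0)
    except CITestError:
        if allow_separation:
            return CITestResult(f"logistic_{method}", np.inf, 0.0, n, conditioning_labels)
        raise
    if method == "lr":
        stat = max(2.0 * (ll1 - ll0), 0.0)
        p = float(stats.chi2.sf(stat, df=1))
    else:
        import statsmodels.api as sm

        fit = sm.Logit(a01, X1).fit(disp=0, method="newton", maxiter=50)
        stat = float(fit.tvalues[-1])
        p = float(2.0 * stats.norm.sf(abs(stat)))
    return CITestResult(f"logistic_{method}", float(stat), p, n, conditioning_labels)
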