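"""Spearman rank correlation with small-sample p-values, Mukaka's
interpretation bands, and an ordinary-least-squares multiple-regression
utility.

At cohort sizes this small the asymptotic p-value for Spearman's rho is
questionable, so for n <= 9 with no ties the two-sided p is computed by
full enumeration of all n! rank permutations; otherwise the conventional
t approximation with n-2 degrees of freedom is used.  The method actually
applied is recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohort import CohortTable
from .errors import ConfigurationError, DegenerateDataError, ValidationError

__all__ = [
    "CorrelationResult",
    "MultiRegressionResult",
    "spearman",
    "mukaka_band",
    "multiple_regression",
    "EXACT_P_MAX_N",
]

#: largest n for which the exact permutation p is enumerated (no ties)
EXACT_P_MAX_N = 9

#: lower-inclusive |rho| band edges of Mukaka's rule
_MUKAKA_EDGES = (
    (0.90, "very_high"),
    (0.70, "high"),
    (0.50, "moderate"),
    (0.30, "low"),
    (0.00, "negligible"),
)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_two_sided: float
    n: int
    method: Literal["exact_permutation", "t_approximation"]
    mukaka_band: str

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "p_two_sided": self.p_two_sided,
            "n": self.n,
            "method": self.method,
            "mukaka_band": self.mukaka_band,
        }


@dataclass(frozen=True)
class MultiRegressionResult:
    """OLS fit: per-predictor (estimate, standard error, two-sided p)."""

    coefficients: dict[str, tuple[float, float, float]]
    r_squared: float
    n: int


def mukaka_band(rho: float) -> str:
    """Verbal size label for a correlation coefficient by |rho|.

    Lower-inclusive edges: [0, .30) negligible, [.30, .50) low,
    [.50, .70) moderate, [.70, .90) high, [.90, 1] very_high.
    """
    if not np.isfinite(rho) or abs(rho) > 1:
        raise ValidationError(f"correlation coefficient must lie in [-1, 1], got {rho!r}")
    a = abs(rho)
    for edge, label in _MUKAKA_EDGES:
        if a >= edge:
            return label
    return "negligible"  # unreachable; edge 0.0 catches everything


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    return float((rxc @ ryc) / denom)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided p by full enumeration of rank permutations (no ties).

    Without ties rho is a monotone function of sum(d²), so the tail count
    uses the classical identity rho = 1 - 6·sum(d²)/(n(n²-1)).
    """
    n = rx.size
    perms = np.array(list(permutations(range(1, n + 1))), dtype=float)
    d = perms - rx[None, :]
    ssd = np.einsum("ij,ij->i", d, d)
    rho_all = 1.0 - 6.0 * ssd / (n * (n * n - 1.0))
    hits = np.count_nonzero(np.abs(rho_all) >= abs(rho_obs) - 1e-12)
    return hits / perms.shape[0]


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Mid-ranks (average ranks) are used for ties.  The p-value is exact
    by permutation enumeration for n <= 9 with no ties, otherwise the
    t approximation t = rho·sqrt((n-2)/(1-rho²)) with df = n-2.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or xa.shape != ya.shape:
        raise ValidationError(
            f"x and y must be equal-length 1-D series, got shapes {xa.shape}, {ya.shape}"
        )
    n = xa.size
    if n < 4:
        raise ValidationError(f"need n >= 4 observations for a correlation, got {n}")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValidationError("x and y must be finite")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateDataError("constant input: Spearman's rho is undefined")

    rx = stats.rankdata(xa, method="average")
    ry = stats.rankdata(ya, method="average")
    rho = _rho_from_ranks(rx, ry)
    rho = float(np.clip(rho, -1.0, 1.0))

    has_ties = (np.unique(xa).size < n) or (np.unique(ya).size < n)
    if n <= EXACT_P_MAX_N and not has_ties:
        p = _exact_permutation_p(rx, ry, rho)
        method = "exact_permutation"
    else:
        if abs(rho) == 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        method = "t_approximation"
    return CorrelationResult(
        rho=rho, p_two_sided=float(p), n=n, method=method,
        mukaka_band=mukaka_band(rho),
    )


def multiple_regression(
    cohort: CohortTable,
    outcome: str,
    predictors: Sequence[str],
) -> MultiRegressionResult:
    """Ordinary least squares of one cohort field on several others.

    Returns estimates, standard errors and two-sided t p-values for the
    intercept and each predictor, plus R².
    """
    predictors = list(predictors)
    if not predictors:
        raise ConfigurationError("at least one predictor is required")
    y = cohort.column(outcome)
    X = np.column_stack([cohort.column(p) for p in predictors])
    n, k = X.shape
    if n <= k + 1:
        raise DegenerateDataError(
            f"n={n} is too small for {k} predictors plus an intercept"
        )
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateDataError(
            f"singular design: predictors {predictors} are collinear"
        )
    fit = sm.OLS(y, design).fit()
    names = ["intercept"] + predictors
    coefficients = {
        name: (float(fit.params[i]), float(fit.bse[i]), float(fit.pvalues[i]))
        for i, name in enumerate(names)
    }
    return MultiRegressionResult(
        coefficients=coefficients, r_squared=float(fit.rsquared), n=n
    )
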