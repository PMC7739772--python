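"""Linear-plateau change-point regression by profiled least squares.

The model is the continuous hinge

    y = beta0 + beta1 * min(x, tau) + eps,

a sloped segment that becomes exactly flat at the change-point ``tau``
(the plateau slope is fixed at zero; a free-slope two-phase model is
deliberately not implemented).  For each candidate ``tau`` on a uniform
grid spanning the observed predictor range, (beta0, beta1) are profiled
out by closed-form OLS on the transformed predictor min(x, tau), so the
grid search is exact per candidate — no iterative optimizer.  The
smallest tau is taken on SSE ties, making the fit deterministic.

Model choice against the simple linear regression uses the Gaussian
profile-likelihood AIC, n·ln(SSE/n) + 2k, with k = 3 for the line
(intercept, slope, error SD) and k = 4 for the hinge (adds tau); the
same formula family is used for both models so the dropped constants
cancel, and a change-point is declared present whenever the hinge AIC
is smaller — sign only, no extra threshold.  Because the grid includes
tau = max(x), the linear model is nested in the search and the hinge SSE
can never exceed the linear SSE.

Uncertainty in tau comes from a nonparametric case bootstrap
(participants resampled with replacement, percentile interval), and
stability from leave-one-out refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "LinearFit",
    "CprmFit",
    "BootstrapCI",
    "LoocvResult",
    "ModelChoice",
    "fit_linear",
    "fit_cprm",
    "compare_models",
    "bootstrap_ci",
    "loocv_stability",
    "profile_curve",
]

#: SSE below this fraction of total y variation is treated as a perfect fit
_PERFECT_FIT_REL = 1e-15


@dataclass(frozen=True)
class LinearFit:
    """Simple regression y = beta0 + beta1·x, with Gaussian AIC (k = 3)."""

    beta0: float
    beta1: float
    sse: float
    sigma_hat: float
    aic: float
    n: int
    perfect_fit: bool = False

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0, "beta1": self.beta1, "sse": self.sse,
            "sigma_hat": self.sigma_hat, "aic": self.aic, "n": self.n,
            "perfect_fit": self.perfect_fit,
        }


@dataclass(frozen=True)
class CprmFit:
    """Fitted hinge model plus the competing linear fit's AIC.

    ``plateau_level`` is the flat sprint time beyond the change-point,
    beta0 + beta1·tau.  ``changepoint_present`` is the AIC decision
    (delta_aic < 0); when either SSE is numerically zero the AICs are
    degenerate and the decision falls back to comparing SSEs directly
    (``aic_degenerate`` is then set).
    """

    tau: float
    beta0: float
    beta1: float
    plateau_level: float
    sse: float
    sigma_hat: float
    aic: float
    aic_linear: float
    delta_aic: float
    changepoint_present: bool
    grid: tuple[float, float, int]
    n: int
    aic_degenerate: bool = False
    linear_fit: LinearFit | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "tau": self.tau, "beta0": self.beta0, "beta1": self.beta1,
            "plateau_level": self.plateau_level, "sse": self.sse,
            "sigma_hat": self.sigma_hat, "aic": self.aic,
            "aic_linear": self.aic_linear, "delta_aic": self.delta_aic,
            "changepoint_present": self.changepoint_present,
            "grid": list(self.grid), "n": self.n,
            "aic_degenerate": self.aic_degenerate,
        }


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap interval for the change-point."""

    lower: float
    upper: float
    level: float
    B: int
    seed: int
    tau_draws: np.ndarray = field(repr=False, compare=False)
    n_redrawn: int = 0

    def to_dict(self) -> dict:
        return {
            "lower": self.lower, "upper": self.upper, "level": self.level,
            "B": self.B, "seed": self.seed, "n_redrawn": self.n_redrawn,
        }


@dataclass(frozen=True)
class LoocvResult:
    """Change-point estimates with each participant left out in turn."""

    tau_by_left_out: dict[str, float]
    tau_range: float
    tau_sd: float
    all_present: bool
    flagged_folds: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "tau_by_left_out": dict(self.tau_by_left_out),
            "tau_range": self.tau_range, "tau_sd": self.tau_sd,
            "all_present": self.all_present,
            "flagged_folds": list(self.flagged_folds),
        }


@dataclass(frozen=True)
class ModelChoice:
    preferred: str              # "changepoint" | "linear"
    delta_aic: float
    by_sse: bool                # True when AICs were degenerate

    def to_dict(self) -> dict:
        return {"preferred": self.preferred, "delta_aic": self.delta_aic,
                "by_sse": self.by_sse}


def _as_xy(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or xa.shape != ya.shape:
        raise ValidationError(
            f"x and y must be equal-length 1-D arrays, got shapes {xa.shape}, {ya.shape}"
        )
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValidationError("x and y must be finite")
    if xa.size < min_n:
        raise DegenerateDataError(f"need at least n={min_n} points, got {xa.size}")
    if np.ptp(xa) == 0:
        raise DegenerateDataError("constant predictor: no regression is identifiable")
    return xa, ya


def _profile_sse(x: np.ndarray, y: np.ndarray, tau_grid: np.ndarray):
    """SSE profile of the hinge over candidate change-points.

    Returns (sse, beta1, beta0) arrays over the grid.  Candidates for
    which min(x, tau) is (numerically) constant get slope 0 and the
    intercept-only SSE.
    """
    z = np.minimum(x[:, None], tau_grid[None, :])
    ybar = y.mean()
    yc = y - ybar
    zc = z - z.mean(axis=0)
    szz = np.einsum("ij,ij->j", zc, zc)
    szy = yc @ zc
    syy = float(yc @ yc)
    sxx = float(np.sum((x - x.mean()) ** 2))
    ok = szz > 1e-12 * sxx
    safe = np.where(ok, szz, 1.0)
    beta1 = np.where(ok, szy / safe, 0.0)
    sse = np.maximum(syy - np.where(ok, szy * szy / safe, 0.0), 0.0)
    beta0 = ybar - beta1 * z.mean(axis=0)
    return sse, beta1, beta0


def _aic(sse: float, n: int, k: int, syy: float) -> tuple[float, bool]:
    """Gaussian AIC n·ln(SSE/n) + 2k; -inf with a flag for a perfect fit."""
    if sse <= _PERFECT_FIT_REL * max(syy, 1.0):
        return float("-inf"), True
    return float(n * np.log(sse / n) + 2 * k), False


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Closed-form OLS line with Gaussian AIC (k = 3)."""
    xa, ya = _as_xy(x, y, min_n=3)
    n = xa.size
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sxx = float(xc @ xc)
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    beta1 = sxy / sxx
    beta0 = float(ya.mean() - beta1 * xa.mean())
    sse = max(syy - sxy * sxy / sxx, 0.0)
    aic, perfect = _aic(sse, n, k=3, syy=syy)
    return LinearFit(
        beta0=beta0, beta1=float(beta1), sse=float(sse),
        sigma_hat=float(np.sqrt(sse / n)), aic=aic, n=n, perfect_fit=perfect,
    )


def _fit_tau(x: np.ndarray, y: np.ndarray, grid_points: int):
    """Fast core: best (tau, sse, beta1, beta0) on the uniform grid.

    Inputs are assumed validated.  First (= smallest-tau) SSE minimizer
    wins ties.
    """
    grid = np.linspace(x.min(), x.max(), grid_points)
    sse, beta1, beta0 = _profile_sse(x, y, grid)
    j = int(np.argmin(sse))
    return float(grid[j]), float(sse[j]), float(beta1[j]), float(beta0[j])


def fit_cprm(
    x: Sequence[float], y: Sequence[float], grid_points: int = 1001
) -> CprmFit:
    """Fit the hinge model by grid search and compare with the line by AIC.

    The grid spans [min(x), max(x)] with endpoints included; because
    tau = max(x) reproduces the linear model exactly, the hinge SSE
    never exceeds the linear SSE.
    """
    xa, ya = _as_xy(x, y, min_n=5)
    if grid_points < 2:
        raise ValidationError(f"grid_points must be >= 2, got {grid_points}")
    n = xa.size
    tau, sse, beta1, beta0 = _fit_tau(xa, ya, grid_points)
    syy = float(np.sum((ya - ya.mean()) ** 2))
    linear = fit_linear(xa, ya)
    aic, degen_cprm = _aic(sse, n, k=4, syy=syy)
    aic_degenerate = degen_cprm or linear.perfect_fit
    if aic_degenerate:
        present = sse < linear.sse
        delta = float("-inf") if present else float("inf")
    else:
        delta = aic - linear.aic
        present = delta < 0
    return CprmFit(
        tau=tau, beta0=beta0, beta1=beta1,
        plateau_level=beta0 + beta1 * tau,
        sse=sse, sigma_hat=float(np.sqrt(sse / n)),
        aic=aic, aic_linear=linear.aic, delta_aic=delta,
        changepoint_present=bool(present),
        grid=(float(xa.min()), float(xa.max()), grid_points),
        n=n, aic_degenerate=aic_degenerate, linear_fit=linear,
    )


def compare_models(cprm: CprmFit) -> ModelChoice:
    """AIC model choice: change-point present iff its AIC is smaller.

    Sign only — no delta-AIC threshold.  With a degenerate (perfect-fit)
    AIC in either model the decision is by SSE, flagged via ``by_sse``.
    """
    return ModelChoice(
        preferred="changepoint" if cprm.changepoint_present else "linear",
        delta_aic=cprm.delta_aic,
        by_sse=cprm.aic_degenerate,
    )


def bootstrap_ci(
    x: Sequence[float],
    y: Sequence[float],
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    grid_points: int = 1001,
) -> BootstrapCI:
    """Percentile bootstrap CI for the change-point.

    Participants are resampled with replacement B times and the hinge is
    refitted on each resample; the interval is the pair of empirical
    quantiles of the tau draws at (1-level)/2 and 1-(1-level)/2.
    Resamples with fewer than 4 distinct predictor values cannot support
    a hinge fit and are redrawn (counted in ``n_redrawn``), with a hard
    cap of 10·B total attempts.
    """
    xa, ya = _as_xy(x, y, min_n=5)
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if B < 1:
        raise ValidationError(f"B must be >= 1, got {B}")
    rng = np.random.default_rng(seed)
    n = xa.size
    draws = np.empty(B)
    attempts = 0
    n_redrawn = 0
    for b in range(B):
        while True:
            attempts += 1
            if attempts > 10 * B:
                raise DegenerateDataError(
                    f"bootstrap exhausted {10 * B} attempts: too few distinct "
                    f"predictor values to resample"
                )
            idx = rng.integers(0, n, size=n)
            xb = xa[idx]
            if np.unique(xb).size >= 4:
                break
            n_redrawn += 1
        draws[b] = _fit_tau(xb, ya[idx], grid_points)[0]
    alpha = 1.0 - level
    lower, upper = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapCI(
        lower=float(lower), upper=float(upper), level=level, B=B,
        seed=seed, tau_draws=draws, n_redrawn=n_redrawn,
    )


def loocv_stability(
    x: Sequence[float],
    y: Sequence[float],
    ids: Sequence[str],
    grid_points: int = 1001,
) -> LoocvResult:
    """Refit the hinge with each participant left out in turn.

    Returns the per-fold change-point estimates, their spread, and
    whether the AIC preferred the change-point model in every fold.
    Degenerate folds (e.g. the removal leaves a constant predictor) are
    flagged by id with a NaN estimate, never silently dropped.
    """
    xa, ya = _as_xy(x, y, min_n=6)
    ids = [str(i) for i in ids]
    if len(ids) != xa.size:
        raise ValidationError(
            f"ids length {len(ids)} does not match data length {xa.size}"
        )
    if len(set(ids)) != len(ids):
        raise ValidationError("ids must be unique")
    taus: dict[str, float] = {}
    flagged: list[str] = []
    present_flags: list[bool] = []
    mask = np.ones(xa.size, dtype=bool)
    for i, pid in enumerate(ids):
        mask[i] = False
        try:
            f = fit_cprm(xa[mask], ya[mask], grid_points=grid_points)
            taus[pid] = f.tau
            present_flags.append(f.changepoint_present)
        except DegenerateDataError:
            taus[pid] = float("nan")
            flagged.append(pid)
        mask[i] = True
    good = np.array([t for t in taus.values() if np.isfinite(t)])
    tau_range = float(good.max() - good.min()) if good.size else float("nan")
    tau_sd = float(np.std(good, ddof=1)) if good.size > 1 else float("nan")
    return LoocvResult(
        tau_by_left_out=taus,
        tau_range=tau_range,
        tau_sd=tau_sd,
        all_present=bool(present_flags) and all(present_flags) and not flagged,
        flagged_folds=tuple(flagged),
    )


def profile_curve(fit: CprmFit, x_grid: np.ndarray | None = None, points: int = 200):
    """(x, fitted y) pairs of the hinge mean profile, for plotting/export."""
    if x_grid is None:
        x_grid = np.linspace(fit.grid[0], fit.grid[1], points)
    x_grid = np.asarray(x_grid, dtype=float)
    return x_grid, fit.beta0 + fit.beta1 * np.minimum(x_grid, fit.tau)
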