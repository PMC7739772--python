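"""Full study workflow: descriptives → correlations → change-point fits.

:func:`run_analysis` reproduces the shape of the original analysis on
any cohort: per-field descriptives (mean, SD, 95% t-interval of the
mean), Spearman correlations of sprint time with each muscle-size
predictor (with Mukaka band labels), and for each predictor — raw and,
when requested, allometrically mass-normalized — the linear-plateau
change-point fit, its AIC comparison against the simple line, a
percentile-bootstrap CI for the change-point, and leave-one-out
stability.  The bootstrap and LOOCV run even when the AIC prefers the
line, so a report can state the absence of a change-point affirmatively
(flagged, not omitted).

Every stochastic stage is seeded from the master seed by a documented
rule: the sub-seed for a stage is derived from
``SeedSequence([master_seed, crc32("stage:predictor:normalized")])``,
so adding a predictor never perturbs another predictor's draws.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from . import __version__
from .changepoint import bootstrap_ci, fit_cprm, loocv_stability, profile_curve
from .cohort import (
    FIELD_UNITS,
    NUMERIC_FIELDS,
    CohortTable,
    allometric_normalize,
)
from .correlations import spearman
from .errors import ConfigurationError, SprintCpError, ValidationError

__all__ = ["AnalysisConfig", "StudyReport", "describe", "run_analysis", "subseed"]

DEFAULT_PREDICTORS = ("ta_thickness_mm", "mm_thickness_cm", "pm_csa_cm2")


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of one analysis run.

    ``normalize_by`` names the mass field used for allometric
    normalization (None disables the normalized pass); ``alpha`` is the
    two-sided significance threshold for correlations.
    """

    outcome: str = "sprint_time_s"
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    normalize_by: str | None = "body_mass_kg"
    alpha: float = 0.05
    boot_B: int = 2000
    boot_level: float = 0.95
    grid_points: int = 1001
    seed: int = 0
    loocv: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if not self.predictors:
            raise ConfigurationError("predictors must be non-empty")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.boot_level < 1.0:
            raise ConfigurationError(
                f"boot_level must be in (0, 1), got {self.boot_level}"
            )

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictors": list(self.predictors),
            "normalize_by": self.normalize_by,
            "alpha": self.alpha,
            "boot_B": self.boot_B,
            "boot_level": self.boot_level,
            "grid_points": self.grid_points,
            "seed": self.seed,
            "loocv": self.loocv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "predictors" in d:
            d["predictors"] = tuple(d["predictors"])
        return cls(**d)


@dataclass(frozen=True)
class StudyReport:
    """Deterministic JSON-serializable result of one analysis run."""

    descriptives: dict
    correlations: dict
    cprm: dict
    provenance: dict
    profiles: dict = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "descriptives": self.descriptives,
            "correlations": self.correlations,
            "cprm": self.cprm,
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(_jsonsafe(self.to_dict()), indent=indent)


def _jsonsafe(obj):
    """Recursively convert numpy scalars and non-finite floats for JSON."""
    if isinstance(obj, dict):
        return {k: _jsonsafe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonsafe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return {float("inf"): "inf", float("-inf"): "-inf"}.get(obj, "nan") \
            if obj == obj else "nan"
    return obj


def subseed(master_seed: int, stage: str, predictor: str, normalized: bool) -> int:
    """Deterministic per-(stage, predictor, normalization) sub-seed."""
    tag = f"{stage}:{predictor}:{'norm' if normalized else 'raw'}"
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def describe(cohort: CohortTable) -> dict:
    """Per-field mean, SD (n-1 denominator) and 95% t-interval of the mean."""
    if cohort.n < 2:
        raise ValidationError("descriptives need n >= 2")
    out = {}
    tq = stats.t.ppf(0.975, df=cohort.n - 1)
    for f in NUMERIC_FIELDS:
        v = cohort.column(f)
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        half = tq * sd / np.sqrt(cohort.n)
        out[f] = {
            "mean": mean, "sd": sd,
            "ci_lower": mean - half, "ci_upper": mean + half,
            "n": cohort.n, "unit": FIELD_UNITS.get(f, ""),
        }
    return out


def _cprm_block(
    x: np.ndarray,
    y: np.ndarray,
    ids: Sequence[str],
    config: AnalysisConfig,
    predictor: str,
    normalized: bool,
    unit: str,
) -> tuple[dict, dict]:
    """One predictor's change-point analysis; returns (report block, profile)."""
    fit = fit_cprm(x, y, grid_points=config.grid_points)
    ci = bootstrap_ci(
        x, y, B=config.boot_B, level=config.boot_level,
        seed=subseed(config.seed, "bootstrap", predictor, normalized),
        grid_points=config.grid_points,
    )
    block = fit.to_dict()
    block["unit"] = unit
    block["ci"] = ci.to_dict()
    block["flagged_no_changepoint"] = not fit.changepoint_present
    if config.loocv:
        block["loocv"] = loocv_stability(
            x, y, ids, grid_points=config.grid_points
        ).to_dict()
    gx, gy = profile_curve(fit)
    profile = {"x": gx.tolist(), "fitted": gy.tolist()}
    return block, profile


def run_analysis(cohort: CohortTable, config: AnalysisConfig) -> StudyReport:
    """Run the complete workflow on one cohort.

    Deterministic given (cohort, config): two runs produce byte-identical
    JSON.  Degenerate-input errors from any stage are re-raised with the
    offending predictor named.
    """
    for p in config.predictors + (config.outcome,):
        if p not in NUMERIC_FIELDS:
            raise ConfigurationError(f"requested field {p!r} is not a cohort column")
    if config.normalize_by is not None and config.normalize_by not in NUMERIC_FIELDS:
        raise ConfigurationError(
            f"normalize_by field {config.normalize_by!r} is not a cohort column"
        )

    y = cohort.column(config.outcome)
    masses = cohort.column(config.normalize_by) if config.normalize_by else None

    descriptives = describe(cohort)

    correlations = {}
    for p in config.predictors:
        try:
            r = spearman(cohort.column(p), y)
        except SprintCpError as exc:
            raise type(exc)(f"correlation for predictor {p!r}: {exc}") from exc
        d = r.to_dict()
        d["significant"] = bool(r.p_two_sided < config.alpha)
        correlations[p] = d

    cprm: dict = {}
    profiles: dict = {}
    for p in config.predictors:
        x = cohort.column(p)
        unit = FIELD_UNITS.get(p, "unit")
        variants = [("raw", x, unit, False)]
        if masses is not None:
            ns = allometric_normalize(x, masses, source_unit=unit)
            variants.append(("normalized", ns.values, ns.unit, True))
        cprm[p] = {}
        for label, xv, u, is_norm in variants:
            try:
                block, prof = _cprm_block(
                    xv, y, cohort.ids, config, p, is_norm, u
                )
            except SprintCpError as exc:
                raise type(exc)(
                    f"change-point analysis for predictor {p!r} ({label}): {exc}"
                ) from exc
            cprm[p][label] = block
            profiles[f"{p}_{label}"] = prof

    cohort_hash = hashlib.sha256(
        "\n".join(
            ",".join([r.id] + [repr(getattr(r, f)) for f in NUMERIC_FIELDS])
            for r in cohort.records
        ).encode()
    ).hexdigest()
    provenance = {
        "cohort": cohort.provenance,
        "cohort_sha256": cohort_hash,
        "n": cohort.n,
        "config": config.to_dict(),
        "software": f"sprintcp {__version__}",
    }
    return StudyReport(
        descriptives=descriptives,
        correlations=correlations,
        cprm=cprm,
        provenance=provenance,
        profiles=profiles,
    )
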