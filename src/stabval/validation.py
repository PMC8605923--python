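"""ICH Q2-style validation battery: system/method linearity, accuracy and
precision, detection and quantification limits, robustness, and the
specificity decision rule, each evaluated against configurable acceptance
criteria.

Every check in a report carries the computed value, the criterion it was
compared against, and the verdict, so a report is fully traceable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .chromatography import PeakRecord
from .regression import LinearFit, XYData, ols_fit, rsd_percent

__all__ = [
    "CalibrationTable",
    "ValidationCriteria",
    "Check",
    "ValidationSection",
    "ValidationReport",
    "SpecificityVerdict",
    "system_linearity",
    "method_linearity",
    "accuracy_precision",
    "lod_loq",
    "robustness_diff",
    "robustness_section",
    "specificity_check",
    "fortification_range",
]

_CAL_KINDS = ("system", "method")


@dataclass(frozen=True)
class CalibrationTable:
    """Long-format calibration data: one response per (level, replicate).

    ``kind`` is ``"system"`` for pure-standard curves and ``"method"`` for
    analyte-fortified placebos.
    """

    levels: np.ndarray
    responses: np.ndarray
    replicates: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        rs = np.asarray(self.responses, dtype=float)
        rep = np.asarray(self.replicates, dtype=int)
        if not (lv.size == rs.size == rep.size):
            raise ValueError("levels, responses, replicates must have equal length")
        if np.unique(lv).size < 3:
            raise ValueError("calibration requires at least 3 distinct levels")
        if np.any(lv <= 0):
            raise ValueError("concentration levels must be > 0")
        if self.kind not in _CAL_KINDS:
            raise ValueError(f"kind must be one of {_CAL_KINDS}, got {self.kind!r}")
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "responses", rs)
        object.__setattr__(self, "replicates", rep)

    @property
    def n_levels(self) -> int:
        return int(np.unique(self.levels).size)

    @property
    def balanced(self) -> bool:
        counts = pd.Series(self.levels).value_counts()
        return bool(counts.nunique() == 1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str | None = None) -> "CalibrationTable":
        required = ["level_ug_ml", "replicate", "area"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"calibration table missing columns: {missing}")
        if kind is None:
            if "kind" not in df.columns:
                raise ValueError("kind column absent and no kind given")
            kinds = df["kind"].unique()
            if len(kinds) != 1:
                raise ValueError(f"mixed kinds in one table: {list(kinds)}")
            kind = str(kinds[0])
        return cls(levels=df["level_ug_ml"].to_numpy(),
                   responses=df["area"].to_numpy(),
                   replicates=df["replicate"].to_numpy(),
                   kind=kind)

    @classmethod
    def read_csv(cls, path, kind: str | None = None) -> "CalibrationTable":
        return cls.from_frame(pd.read_csv(path), kind=kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "level_ug_ml": self.levels,
            "replicate": self.replicates,
            "area": self.responses,
            "kind": self.kind,
        })


@dataclass(frozen=True)
class ValidationCriteria:
    """Acceptance thresholds.

    Recovery bounds are compared inclusively; dispersion thresholds
    (``rsd_max``, ``residual_max``, ``abs_diff_max``) are strict
    upper bounds.
    """

    r_min: float = 0.998
    r2_min: float = 0.995
    recovery_low: float = 98.0
    recovery_high: float = 102.0
    rsd_max: float = 2.0
    residual_max: float = 2.0
    abs_diff_max: float = 2.0
    require_ci_beta0_contains_zero: bool = True
    require_ci_beta1_contains_one: bool = True

    def __post_init__(self) -> None:
        if self.recovery_low > self.recovery_high:
            raise ValueError("recovery bounds out of order")
        for name in ("r_min", "r2_min", "rsd_max", "residual_max", "abs_diff_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ValidationCriteria":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown criteria keys: {sorted(unknown)}")
        return cls(**dict(mapping))


@dataclass
class Check:
    """One criterion evaluation: value, criterion description, verdict."""

    value: float
    criterion: str
    passed: bool


@dataclass
class ValidationSection:
    name: str
    values: dict[str, Any] = field(default_factory=dict)
    checks: dict[str, Check] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks.values())


@dataclass
class ValidationReport:
    sections: list[ValidationSection] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(s.passed for s in self.sections)

    def to_dict(self) -> dict[str, Any]:
        return {"sections": [asdict(s) for s in self.sections],
                "metadata": self.metadata,
                "passed": self.passed}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=_json_default, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ValidationReport":
        sections = []
        for s in d["sections"]:
            checks = {k: Check(**v) for k, v in s["checks"].items()}
            sections.append(ValidationSection(name=s["name"], values=s["values"], checks=checks))
        return cls(sections=sections, metadata=dict(d.get("metadata", {})))

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        return cls.from_dict(json.loads(text))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _contains(ci: tuple[float, float], value: float, atol: float = 0.0) -> bool:
    lo, hi = ci
    return bool(np.isfinite(lo) and np.isfinite(hi)
                and lo - atol <= value <= hi + atol)


def _ci_slack(estimate: float) -> float:
    # numerical slack so exact-data fits (zero-width CIs at float residue
    # scale) are judged correctly
    return 1e-9 * max(1.0, abs(estimate))


def fortification_range(nominal: float, low_pct: float, high_pct: float) -> tuple[float, float]:
    """Concentration range corresponding to a percent span of a working level
    (e.g. 80-120% of nominal)."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be > 0")
    if low_pct > high_pct:
        raise ValueError("percent bounds out of order")
    return nominal * low_pct / 100.0, nominal * high_pct / 100.0


def system_linearity(table: CalibrationTable,
                     criteria: ValidationCriteria | None = None,
                     confidence_level: float = 0.95) -> ValidationSection:
    """Linearity of the system: regression of response on concentration for
    pure-standard calibration, with r, r2, %RSD of response factors, and the
    intercept confidence interval."""
    if table.kind != "system":
        raise ValueError("system_linearity requires a system calibration table")
    criteria = criteria or ValidationCriteria()
    fit = ols_fit(XYData(table.levels, table.responses), confidence_level)
    factors = table.responses / table.levels
    rsd = rsd_percent(factors)

    section = ValidationSection(name="system_linearity")
    section.values = {
        "beta0": fit.beta0, "beta1": fit.beta1,
        "se_beta0": fit.se_beta0, "residual_sd": fit.residual_sd,
        "ci_beta0": list(fit.ci_beta0), "ci_beta1": list(fit.ci_beta1),
        "confidence_level": confidence_level,
        "n": fit.n, "n_levels": table.n_levels,
    }
    section.checks["r"] = Check(fit.r, f"|r| >= {criteria.r_min}", abs(fit.r) >= criteria.r_min)
    section.checks["r2"] = Check(fit.r2, f"r2 >= {criteria.r2_min}", fit.r2 >= criteria.r2_min)
    section.checks["rsd_response_factors"] = Check(
        rsd, f"%RSD < {criteria.rsd_max}", rsd < criteria.rsd_max)
    if criteria.require_ci_beta0_contains_zero:
        section.checks["ci_beta0_contains_zero"] = Check(
            fit.beta0, "CI(beta0) contains 0", _contains(fit.ci_beta0, 0.0, _ci_slack(fit.beta0)))
    return section


def method_linearity(table: CalibrationTable, nominal: float,
                     criteria: ValidationCriteria | None = None,
                     system_fit: LinearFit | None = None,
                     confidence_level: float = 0.95) -> ValidationSection:
    """Linearity of the method on fortified placebos.

    When ``system_fit`` is given, table responses are areas and the found
    concentration is obtained by inverse prediction through the system
    calibration; otherwise responses are taken to be found concentrations
    directly. Regresses found on added and reports per-level recoveries,
    mean recovery +/- sd, %RSD, and whether CI(beta1) contains 1 and
    CI(beta0) contains 0.
    """
    if table.kind != "method":
        raise ValueError("method_linearity requires a method calibration table")
    if nominal <= 0:
        raise ValueError("nominal concentration must be > 0")
    criteria = criteria or ValidationCriteria()
    added = table.levels
    found = (np.asarray(system_fit.inverse_predict(table.responses), dtype=float)
             if system_fit is not None else table.responses)
    fit = ols_fit(XYData(added, found), confidence_level)
    recoveries = 100.0 * found / added
    mean_rec = float(np.mean(recoveries))
    sd_rec = float(np.std(recoveries, ddof=1))
    rsd = rsd_percent(recoveries)

    section = ValidationSection(name="method_linearity")
    section.values = {
        "beta0": fit.beta0, "beta1": fit.beta1,
        "ci_beta0": list(fit.ci_beta0), "ci_beta1": list(fit.ci_beta1),
        "confidence_level": confidence_level,
        "nominal_ug_ml": nominal,
        "range_ug_ml": [float(added.min()), float(added.max())],
        "recovery_mean": mean_rec, "recovery_sd": sd_rec,
        "recoveries": recoveries, "n": fit.n,
    }
    section.checks["r"] = Check(fit.r, f"|r| >= {criteria.r_min}", abs(fit.r) >= criteria.r_min)
    section.checks["r2"] = Check(fit.r2, f"r2 >= {criteria.r2_min}", fit.r2 >= criteria.r2_min)
    section.checks["recovery_mean"] = Check(
        mean_rec, f"{criteria.recovery_low} <= mean <= {criteria.recovery_high}",
        criteria.recovery_low <= mean_rec <= criteria.recovery_high)
    section.checks["rsd"] = Check(rsd, f"%RSD < {criteria.rsd_max}", rsd < criteria.rsd_max)
    if criteria.require_ci_beta1_contains_one:
        section.checks["ci_beta1_contains_one"] = Check(
            fit.beta1, "CI(beta1) contains 1", _contains(fit.ci_beta1, 1.0, _ci_slack(fit.beta1)))
    if criteria.require_ci_beta0_contains_zero:
        section.checks["ci_beta0_contains_zero"] = Check(
            fit.beta0, "CI(beta0) contains 0", _contains(fit.ci_beta0, 0.0, _ci_slack(fit.beta0)))
    return section


def accuracy_precision(recoveries,
                       criteria: ValidationCriteria | None = None) -> ValidationSection:
    """Accuracy and precision from a vector of percent recoveries: mean
    recovery +/- sd, %RSD, and per-observation deviations from 100%."""
    criteria = criteria or ValidationCriteria()
    rec = np.asarray(recoveries, dtype=float)
    if rec.size == 0:
        raise ValueError("no recoveries given")
    if rec.size < 3:
        raise ValueError("accuracy/precision requires at least 3 recoveries")
    mean_rec = float(np.mean(rec))
    sd_rec = float(np.std(rec, ddof=1))
    rsd = rsd_percent(rec)
    residuals = np.abs(rec - 100.0)

    section = ValidationSection(name="accuracy_precision")
    section.values = {
        "recovery_mean": mean_rec, "recovery_sd": sd_rec,
        "residuals_pct": residuals, "n": int(rec.size),
    }
    section.checks["recovery_mean"] = Check(
        mean_rec, f"{criteria.recovery_low} <= mean <= {criteria.recovery_high}",
        criteria.recovery_low <= mean_rec <= criteria.recovery_high)
    section.checks["rsd"] = Check(rsd, f"%RSD < {criteria.rsd_max}", rsd < criteria.rsd_max)
    max_resid = float(residuals.max())
    section.checks["max_residual"] = Check(
        max_resid, f"|recovery - 100| < {criteria.residual_max} per observation",
        max_resid < criteria.residual_max)
    return section


def lod_loq(fit: LinearFit, use_residual_sd: bool = False) -> tuple[float, float]:
    """Detection and quantification limits from a calibration fit:
    ``LOD = 3.3 * s / beta1`` and ``LOQ = 10 * s / beta1`` where ``s`` is the
    standard error of the intercept (default) or the residual standard
    deviation (``use_residual_sd=True``). The ratio LOQ/LOD is 10/3.3 by
    construction.
    """
    if fit.beta1 <= 0:
        raise ValueError("slope must be > 0 for LOD/LOQ")
    s = fit.residual_sd if use_residual_sd else fit.se_beta0
    if not np.isfinite(s) or s < 0:
        raise ValueError("intercept dispersion estimate unavailable")
    return 3.3 * s / fit.beta1, 10.0 * s / fit.beta1


def robustness_diff(mean_normal: float, mean_modified: float) -> float:
    """Absolute difference of mean recoveries between the nominal condition
    and a deliberately perturbed one (|d_i|)."""
    if not (np.isfinite(mean_normal) and np.isfinite(mean_modified)):
        raise ValueError("means must be finite")
    return abs(mean_normal - mean_modified)


def robustness_section(normal_recoveries,
                       modified: Mapping[str, Any],
                       criteria: ValidationCriteria | None = None) -> ValidationSection:
    """Robustness across perturbed conditions.

    ``modified`` maps condition name -> recovery vector. Each condition is
    checked via |d_i| against ``abs_diff_max``.
    """
    criteria = criteria or ValidationCriteria()
    normal = np.asarray(normal_recoveries, dtype=float)
    if normal.size == 0:
        raise ValueError("no normal-condition recoveries")
    mean_normal = float(np.mean(normal))
    section = ValidationSection(name="robustness")
    section.values = {"mean_normal": mean_normal, "conditions": {}}
    for name, rec in modified.items():
        rec = np.asarray(rec, dtype=float)
        if rec.size == 0:
            raise ValueError(f"no recoveries for condition {name!r}")
        mean_mod = float(np.mean(rec))
        di = robustness_diff(mean_normal, mean_mod)
        section.values["conditions"][name] = {
            "mean": mean_mod,
            "sd": float(np.std(rec, ddof=1)) if rec.size > 1 else 0.0,
            "n": int(rec.size),
            "abs_diff": di,
        }
        section.checks[f"abs_diff[{name}]"] = Check(
            di, f"|d_i| < {criteria.abs_diff_max}", di < criteria.abs_diff_max)
    return section


@dataclass
class SpecificityVerdict:
    passed: bool
    interfering: list[PeakRecord] = field(default_factory=list)


def specificity_check(peaks: list[PeakRecord], analyte_tr: float,
                      tolerance: float,
                      analyte_labels: tuple[str, ...] = ("t-RSV",)) -> SpecificityVerdict:
    """Pass if no blank, placebo, or degradant peak falls within
    ``tolerance`` minutes of the analyte retention time. Peaks labelled as
    the analyte itself are exempt."""
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    interfering = [
        p for p in peaks
        if p.label not in analyte_labels and abs(p.t_r - analyte_tr) <= tolerance
    ]
    return SpecificityVerdict(passed=not interfering, interfering=interfering)
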