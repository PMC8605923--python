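"""First-order degradation kinetics, accelerated-stability adjustment of
rate constants across temperatures, and t90 shelf-life estimation.

Rate constants are kept on the natural-log basis internally (k in 1/h such
that recovery(t) = 100 * exp(-k t)); ``log_base="10"`` only changes the
regression scale and is converted back, so t90 is base-invariant. The
temperature adjustment regresses ln(k) on inverse absolute temperature with
the accelerated-life convention ln k = A - E/(B*T), B = 1/11605 K*eV^-1
(E in eV).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .regression import XYData, ols_fit

__all__ = [
    "LN_10_OVER_9",
    "EV_PER_KELVIN",
    "DegradationSeries",
    "FirstOrderFit",
    "ArrheniusModel",
    "ShelfLifeEstimate",
    "fit_first_order",
    "fit_arrhenius",
    "adjusted_rate",
    "t90",
    "shelf_life",
    "stability_table",
    "load_degradation_csv",
    "series_from_frame",
]

#: t90 * k for first-order decay: time to fall to 90% of initial.
LN_10_OVER_9 = math.log(10.0 / 9.0)

#: reciprocal of the 1/11605 K*eV^-1 convention for Boltzmann's constant.
EV_PER_KELVIN = 1.0 / 11605.0

_KELVIN_OFFSET = 273.15


def _to_kelvin(temp_c: float) -> float:
    if temp_c < -_KELVIN_OFFSET:
        raise ValueError(f"temperature below absolute zero: {temp_c} degC")
    return temp_c + _KELVIN_OFFSET


@dataclass(frozen=True)
class DegradationSeries:
    """Percent recovery of the analyte over time at one stress condition.

    ``times`` in hours (nondecreasing, starting at 0), ``recovery`` in
    percent of the initial level (replicate means), ``temperature`` in
    degrees Celsius.
    """

    condition: str
    temperature: float
    times: np.ndarray
    recovery: np.ndarray
    recovery_sd: np.ndarray | None = None
    n_replicates: int = 1
    sample_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.recovery, dtype=float)
        if t.size != r.size:
            raise ValueError("times and recovery must have equal length")
        if t.size < 2:
            raise ValueError("a series needs at least 2 time points")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be nondecreasing")
        if t[0] != 0:
            raise ValueError("times must start at 0")
        _to_kelvin(self.temperature)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "recovery", r)
        if self.recovery_sd is not None:
            sd = np.asarray(self.recovery_sd, dtype=float)
            if sd.size != t.size:
                raise ValueError("recovery_sd length mismatch")
            object.__setattr__(self, "recovery_sd", sd)

    @property
    def temperature_kelvin(self) -> float:
        return _to_kelvin(self.temperature)


@dataclass(frozen=True)
class FirstOrderFit:
    """First-order rate fit. ``k0`` is the unadjusted rate constant in 1/h
    on the natural-log basis (recovery = exp(intercept - k0 * t))."""

    k0: float
    intercept: float
    r2: float
    n_points_used: int
    excluded_points: list[int] = field(default_factory=list)
    anchored: bool = False


@dataclass(frozen=True)
class ArrheniusModel:
    """ln(k) = a_param - e_param / (b_const * T_Kelvin)."""

    a_param: float
    e_param: float
    fitted_temperatures: tuple[float, ...]
    r2: float
    b_const: float = EV_PER_KELVIN

    def __post_init__(self) -> None:
        if len(set(self.fitted_temperatures)) < 2:
            raise ValueError("Arrhenius model requires >= 2 distinct temperatures")

    @property
    def span_kelvin(self) -> tuple[float, float]:
        return min(self.fitted_temperatures), max(self.fitted_temperatures)


@dataclass(frozen=True)
class ShelfLifeEstimate:
    """Adjusted rate constant and t90 at a target temperature.

    ``t90_h * ka == ln(10/9)`` exactly; ``c0`` cancels out of the t90
    expression and is retained only for traceability.
    """

    ka: float
    t90_h: float
    target_temperature: float
    c0: float = 100.0
    extrapolated: bool = False


def fit_first_order(series: DegradationSeries, anchor_t0: bool = False,
                    log_base: str = "e") -> FirstOrderFit:
    """Fit ln(recovery) = intercept - k0 * t by OLS.

    Points with recovery <= 0 are excluded (their indices are recorded).
    ``anchor_t0=True`` forces the line through (0, log 100), i.e. 100%
    recovery at time zero. ``log_base`` selects the regression scale
    ("e" or "10"); k0 is converted back to the natural basis either way.
    """
    if log_base not in ("e", "10"):
        raise ValueError('log_base must be "e" or "10"')
    t = series.times
    rec = series.recovery
    usable = rec > 0
    excluded = [int(i) for i in np.flatnonzero(~usable)]
    t_u, rec_u = t[usable], rec[usable]
    if t_u.size < 2:
        raise ValueError(
            f"fewer than 2 positive-recovery points in series "
            f"{series.condition!r} @ {series.temperature} degC "
            f"(usable: {t_u.size}); series truncated")
    if np.ptp(t_u) == 0:
        raise ValueError("all usable times identical; rate unidentifiable")

    scale = 1.0 if log_base == "e" else math.log(10.0)
    logy = np.log(rec_u) / scale

    if anchor_t0:
        y0 = math.log(100.0) / scale
        # least squares through the fixed point (0, log 100)
        slope = float(np.sum(t_u * (logy - y0)) / np.sum(t_u**2))
        pred = y0 + slope * t_u
        ss_res = float(np.sum((logy - pred) ** 2))
        ss_tot = float(np.sum((logy - np.mean(logy)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
        return FirstOrderFit(k0=-slope * scale, intercept=math.log(100.0),
                             r2=max(min(r2, 1.0), 0.0),
                             n_points_used=int(t_u.size),
                             excluded_points=excluded, anchored=True)

    fit = ols_fit(XYData(t_u, logy))
    return FirstOrderFit(k0=-fit.beta1 * scale, intercept=fit.beta0 * scale,
                         r2=fit.r2 if np.isfinite(fit.r2) else 0.0,
                         n_points_used=int(t_u.size),
                         excluded_points=excluded, anchored=False)


def fit_arrhenius(rates: Mapping[float, float]) -> ArrheniusModel:
    """Fit ln(k) linear in 1/T_Kelvin from {temperature_degC: rate_1_per_h}.

    The slope equals -E/B with B = 1/11605, so ``e_param`` is in eV.
    """
    temps = np.asarray(sorted(rates), dtype=float)
    if np.unique(temps).size < 2:
        raise ValueError("Arrhenius fit requires >= 2 distinct temperatures")
    ks = np.asarray([rates[t] for t in temps], dtype=float)
    if np.any(ks <= 0):
        bad = [float(t) for t, k in zip(temps, ks) if k <= 0]
        raise ValueError(f"nonpositive rate at temperature(s) {bad}; cannot take log")
    inv_t = 1.0 / np.array([_to_kelvin(t) for t in temps])
    fit = ols_fit(XYData(inv_t, np.log(ks)))
    return ArrheniusModel(a_param=fit.beta0,
                          e_param=-fit.beta1 * EV_PER_KELVIN,
                          fitted_temperatures=tuple(_to_kelvin(t) for t in temps),
                          r2=fit.r2 if np.isfinite(fit.r2) else 1.0)


def adjusted_rate(model: ArrheniusModel, target_temperature: float) -> tuple[float, bool]:
    """Rate constant at a target temperature (degC) from a fitted model.

    Returns ``(ka, extrapolated)`` where the flag marks targets outside the
    fitted temperature span.
    """
    t_k = _to_kelvin(target_temperature)
    lo, hi = model.span_kelvin
    extrapolated = not (lo <= t_k <= hi)
    ka = math.exp(model.a_param - model.e_param / (model.b_const * t_k))
    return ka, extrapolated


def t90(ka: float, c0: float = 100.0) -> float:
    """Time for the analyte to fall to 90% of initial: ln(c0/(0.9 c0))/ka =
    ln(10/9)/ka. Independent of c0 (retained for traceability)."""
    if ka <= 0:
        raise ValueError("ka must be > 0 for a finite shelf life")
    if c0 <= 0:
        raise ValueError("c0 must be > 0")
    return LN_10_OVER_9 / ka


def shelf_life(model: ArrheniusModel, target_temperature: float,
               c0: float = 100.0) -> ShelfLifeEstimate:
    ka, extrapolated = adjusted_rate(model, target_temperature)
    return ShelfLifeEstimate(ka=ka, t90_h=t90(ka, c0),
                             target_temperature=target_temperature,
                             c0=c0, extrapolated=extrapolated)


# ---------------------------------------------------------------------------
# Study-level table

def stability_table(series: Iterable[DegradationSeries],
                    target_temperatures: Iterable[float] | None = None,
                    arrhenius: bool = True,
                    anchor_t0: bool = False,
                    log_base: str = "e") -> pd.DataFrame:
    """One row per (sample, condition, temperature) with the unadjusted rate
    k0, the adjusted rate ka, t90, fit quality and last-time-point recovery.

    When a (sample, condition) group spans >= 2 temperatures with positive
    rates and ``arrhenius=True``, ka at each temperature comes from the
    group's Arrhenius fit; otherwise ka = k0. ``target_temperatures`` adds
    extrapolated rows per group where a model exists. ka is also reported
    as ``ka_e3_per_h`` (x10^-3 1/h). Series with fewer than 2 usable points
    yield an annotated row rather than aborting the run.
    """
    series = list(series)
    rows: list[dict] = []
    groups: dict[tuple[str, str], list[DegradationSeries]] = {}
    for s in series:
        groups.setdefault((s.sample_id, s.condition), []).append(s)

    for (sample_id, condition), group in groups.items():
        fits: dict[float, FirstOrderFit] = {}
        notes: dict[float, str] = {}
        for s in sorted(group, key=lambda g: g.temperature):
            note_parts = []
            try:
                fit = fit_first_order(s, anchor_t0=anchor_t0, log_base=log_base)
            except ValueError as exc:
                warnings.warn(f"skipping fit for {sample_id}/{condition}"
                              f"@{s.temperature}degC: {exc}", stacklevel=2)
                notes[s.temperature] = f"unfittable: {exc}"
                fits[s.temperature] = None  # type: ignore[assignment]
                continue
            if fit.excluded_points:
                usable_times = s.times[s.recovery > 0]
                note_parts.append(
                    f"truncated: last usable time {usable_times.max():g} h")
            fits[s.temperature] = fit
            notes[s.temperature] = "; ".join(note_parts)

        model: ArrheniusModel | None = None
        usable_rates = {t: f.k0 for t, f in fits.items()
                        if f is not None and f.k0 > 0}
        if arrhenius and len(usable_rates) >= 2:
            model = fit_arrhenius(usable_rates)

        for s in sorted(group, key=lambda g: g.temperature):
            fit = fits.get(s.temperature)
            note = notes.get(s.temperature, "")
            row = {
                "sample_id": sample_id, "condition": condition,
                "temperature_c": s.temperature,
                "k0_per_h": float("nan"), "ka_per_h": float("nan"),
                "ka_e3_per_h": float("nan"), "t90_h": float("nan"),
                "r2": float("nan"),
                "recovery_last_pct": float(s.recovery[-1]),
                "recovery_last_time_h": float(s.times[-1]),
                "note": note,
            }
            if fit is not None:
                if model is not None:
                    ka, extrapolated = adjusted_rate(model, s.temperature)
                    if extrapolated:
                        row["note"] = "; ".join(filter(None, [note, "extrapolated"]))
                else:
                    ka = fit.k0
                row.update(k0_per_h=fit.k0, ka_per_h=ka, ka_e3_per_h=1e3 * ka,
                           r2=fit.r2,
                           t90_h=t90(ka) if ka > 0 else float("nan"))
                if ka <= 0:
                    row["note"] = "; ".join(filter(None, [row["note"],
                                                          "nonpositive rate; no finite t90"]))
            rows.append(row)

        if model is not None and target_temperatures:
            existing = {s.temperature for s in group}
            for tc in target_temperatures:
                if tc in existing:
                    continue
                est = shelf_life(model, tc)
                rows.append({
                    "sample_id": sample_id, "condition": condition,
                    "temperature_c": float(tc),
                    "k0_per_h": float("nan"), "ka_per_h": est.ka,
                    "ka_e3_per_h": 1e3 * est.ka, "t90_h": est.t90_h,
                    "r2": model.r2,
                    "recovery_last_pct": float("nan"),
                    "recovery_last_time_h": float("nan"),
                    "note": "target temperature"
                            + ("; extrapolated" if est.extrapolated else ""),
                })

    return pd.DataFrame(rows, columns=[
        "sample_id", "condition", "temperature_c", "k0_per_h", "ka_per_h",
        "ka_e3_per_h", "t90_h", "r2", "recovery_last_pct",
        "recovery_last_time_h", "note"])


# ---------------------------------------------------------------------------
# CSV interface

_DEG_COLUMNS = ["sample_id", "condition", "temperature_c", "time_h", "replicate"]


def series_from_frame(df: pd.DataFrame) -> list[DegradationSeries]:
    """Aggregate a long-format degradation table into replicate-mean series.

    Expects columns sample_id, condition, temperature_c, time_h, replicate
    and either recovery_pct or (area, area_ref).
    """
    missing = [c for c in _DEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"degradation table missing columns: {missing}")
    if "recovery_pct" in df.columns:
        rec = df["recovery_pct"].astype(float)
    elif {"area", "area_ref"}.issubset(df.columns):
        ref = df["area_ref"].astype(float)
        if (ref <= 0).any():
            raise ValueError("area_ref must be > 0")
        rec = 100.0 * df["area"].astype(float) / ref
    else:
        raise ValueError("need recovery_pct or area+area_ref columns")
    work = df.assign(_rec=rec)
    out: list[DegradationSeries] = []
    for (sample_id, condition, temp), g in work.groupby(
            ["sample_id", "condition", "temperature_c"], sort=True):
        agg = g.groupby("time_h")["_rec"].agg(["mean", "std", "count"]).sort_index()
        out.append(DegradationSeries(
            condition=str(condition), temperature=float(temp),
            times=agg.index.to_numpy(dtype=float),
            recovery=agg["mean"].to_numpy(),
            recovery_sd=np.nan_to_num(agg["std"].to_numpy()),
            n_replicates=int(agg["count"].max()),
            sample_id=str(sample_id)))
    return out


def load_degradation_csv(path) -> list[DegradationSeries]:
    return series_from_frame(pd.read_csv(path))
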