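"""Seeded generators for every input the pipeline consumes: calibration
tables, fortified-placebo recoveries, robustness condition sets, degradation
time courses, and Gaussian-peak chromatogram traces — each with serialized
ground truth for parameter-recovery testing.

All randomness flows from ``StudyDesign.seed`` through
``numpy.random.default_rng``; the same seed reproduces every output
byte-for-byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .chromatography import Trace
from .kinetics import EV_PER_KELVIN, DegradationSeries, _to_kelvin
from .validation import CalibrationTable

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "DEGRADANT_TR_MIN",
    "ANALYTE_TR_MIN",
    "rate_at",
    "arrhenius_from_anchors",
    "default_arrhenius_truth",
    "gen_calibration",
    "gen_method_table",
    "gen_recoveries",
    "gen_robustness_set",
    "gen_degradation_study",
    "gen_chromatogram",
]

#: retention times (min) of the analyte and its degradation peaks in
#: synthetic chromatograms; six-minute run span.
ANALYTE_TR_MIN = 2.6
DEGRADANT_TR_MIN = (0.7, 1.0, 1.4, 1.8, 3.2, 3.9, 5.0)


@dataclass(frozen=True)
class StudyDesign:
    """Design of a full synthetic study.

    Defaults: a 6-level two-fold dilution calibration series 0.525-16.8
    ug/ml in triplicate, fortified placebos at 80-120% of a 3.5 ug/ml
    working level, and degradation sampled at 0/24/72/120 h at
    4/25/40/60 degC with ~1.5% multiplicative assay noise.
    """

    calibration_levels: tuple[float, ...] = (0.525, 1.05, 2.1, 4.2, 8.4, 16.8)
    method_levels_pct: tuple[float, ...] = (80.0, 90.0, 100.0, 110.0, 120.0)
    nominal_ug_ml: float = 3.5
    times_h: tuple[float, ...] = (0.0, 24.0, 72.0, 120.0)
    temperatures_c: tuple[float, ...] = (4.0, 25.0, 40.0, 60.0)
    replicates: int = 3
    noise_rsd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(lv <= 0 for lv in self.calibration_levels):
            raise ValueError("calibration levels must be positive")
        if any(p <= 0 for p in self.method_levels_pct):
            raise ValueError("method levels must be positive")
        if self.nominal_ug_ml <= 0:
            raise ValueError("nominal concentration must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_rsd < 0:
            raise ValueError("noise_rsd must be >= 0")

    def rng(self, stream: str = "") -> np.random.Generator:
        # independent deterministic streams per generator
        return np.random.default_rng([self.seed, *(ord(c) for c in stream)])


@dataclass
class GroundTruth:
    """True parameters behind a generated dataset."""

    calibration_slope: float | None = None
    calibration_intercept: float | None = None
    true_recovery_pct: float | None = None
    arrhenius: dict[str, dict[str, float]] = field(default_factory=dict)
    degradant_tr_min: tuple[float, ...] = DEGRADANT_TR_MIN
    seed: int | None = None

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["degradant_tr_min"] = tuple(d.get("degradant_tr_min", DEGRADANT_TR_MIN))
        return cls(**d)


def rate_at(a_param: float, e_param: float, temp_c: float) -> float:
    """Closed-form Arrhenius rate k(T) = exp(A - E/(B*T_K)), B = 1/11605."""
    return math.exp(a_param - e_param / (EV_PER_KELVIN * _to_kelvin(temp_c)))


def arrhenius_from_anchors(k1: float, temp1_c: float,
                           k2: float, temp2_c: float) -> tuple[float, float]:
    """Solve (A, E) exactly from two (rate, temperature) anchors."""
    if k1 <= 0 or k2 <= 0:
        raise ValueError("anchor rates must be positive")
    x1 = 1.0 / (EV_PER_KELVIN * _to_kelvin(temp1_c))
    x2 = 1.0 / (EV_PER_KELVIN * _to_kelvin(temp2_c))
    if x1 == x2:
        raise ValueError("anchor temperatures must differ")
    e = (math.log(k1) - math.log(k2)) / (x2 - x1)
    a = math.log(k1) + e * x1
    return a, e


def default_arrhenius_truth() -> dict[str, tuple[float, float]]:
    """Plausible (A, E) per stress condition: basic hydrolysis fastest, heat
    slowest, mirroring the qualitative ordering of a forced-degradation
    study."""
    return {
        # anchors chosen so 60 degC degrades visibly within 120 h while
        # 4 degC stays above ~95% recovery
        "acid": arrhenius_from_anchors(2e-3, 40.0, 9e-3, 60.0),
        "base": arrhenius_from_anchors(4e-2, 40.0, 1.5e-1, 60.0),
        "oxidation": arrhenius_from_anchors(1e-2, 40.0, 5e-2, 60.0),
        "temperature": arrhenius_from_anchors(1.7e-3, 40.0, 5e-3, 60.0),
    }


def _mult_noise(rng: np.random.Generator, shape, rsd_pct: float) -> np.ndarray:
    return 1.0 + rng.standard_normal(shape) * rsd_pct / 100.0


def gen_calibration(design: StudyDesign, slope: float = 50000.0,
                    intercept: float = 0.0) -> tuple[CalibrationTable, GroundTruth]:
    """System calibration: area = slope*conc + intercept with multiplicative
    gaussian noise at ``design.noise_rsd``."""
    rng = design.rng("calibration")
    levels, reps, areas = [], [], []
    for lv in design.calibration_levels:
        for rep in range(1, design.replicates + 1):
            true_area = slope * lv + intercept
            areas.append(true_area * _mult_noise(rng, (), design.noise_rsd))
            levels.append(lv)
            reps.append(rep)
    table = CalibrationTable(levels=np.array(levels), responses=np.array(areas),
                             replicates=np.array(reps), kind="system")
    truth = GroundTruth(calibration_slope=slope, calibration_intercept=intercept,
                        seed=design.seed)
    return table, truth


def gen_method_table(design: StudyDesign, slope: float = 50000.0,
                     intercept: float = 0.0,
                     true_recovery_pct: float = 100.0
                     ) -> tuple[CalibrationTable, GroundTruth]:
    """Fortified placebos at ``method_levels_pct`` of the working level.

    Responses are areas produced through the same detector response as the
    system curve, with the found amount equal to ``true_recovery_pct`` of
    the added amount, so inverse prediction through the system fit recovers
    the recovery."""
    rng = design.rng("method")
    levels, reps, areas = [], [], []
    for pct in design.method_levels_pct:
        added = design.nominal_ug_ml * pct / 100.0
        for rep in range(1, design.replicates + 1):
            found = added * true_recovery_pct / 100.0
            area = (slope * found + intercept) * _mult_noise(rng, (), design.noise_rsd)
            levels.append(added)
            reps.append(rep)
            areas.append(area)
    table = CalibrationTable(levels=np.array(levels), responses=np.array(areas),
                             replicates=np.array(reps), kind="method")
    truth = GroundTruth(calibration_slope=slope, calibration_intercept=intercept,
                        true_recovery_pct=true_recovery_pct, seed=design.seed)
    return table, truth


def gen_recoveries(design: StudyDesign, n: int = 9,
                   true_recovery_pct: float = 100.0,
                   stream: str = "accuracy") -> np.ndarray:
    """Percent recoveries with multiplicative noise around a true level."""
    rng = design.rng(stream)
    return true_recovery_pct * _mult_noise(rng, n, design.noise_rsd)


def gen_robustness_set(design: StudyDesign, n_per_condition: int = 6,
                       conditions: tuple[str, ...] = (
                           "mobile_phase_69_31", "mobile_phase_71_29",
                           "ph_3", "ph_5", "uplc"),
                       true_recovery_pct: float = 100.0
                       ) -> dict[str, np.ndarray]:
    """Recovery vectors for the nominal condition plus each perturbation."""
    out = {"normal": gen_recoveries(design, n_per_condition,
                                    true_recovery_pct, stream="robust_normal")}
    for cond in conditions:
        out[cond] = gen_recoveries(design, n_per_condition, true_recovery_pct,
                                   stream=f"robust_{cond}")
    return out


def gen_degradation_study(design: StudyDesign,
                          arrhenius_truth: Mapping[str, tuple[float, float]] | None = None,
                          sample_ids: tuple[str, ...] = ("STD",),
                          ) -> tuple[pd.DataFrame, GroundTruth]:
    """First-order time courses at every design temperature per condition:
    recovery(t) = 100*exp(-k(T)*t) with multiplicative noise, truncated at 0.

    Returns a long-format frame in the degradation CSV schema plus the
    ground truth holding each condition's (A, E) and implied k(T).
    """
    if arrhenius_truth is None:
        arrhenius_truth = default_arrhenius_truth()
    rng = design.rng("degradation")
    rows = []
    truth = GroundTruth(seed=design.seed)
    for condition, (a, e) in arrhenius_truth.items():
        entry: dict[str, float] = {"a_param": a, "e_param": e}
        for temp in design.temperatures_c:
            k = rate_at(a, e, temp)
            entry[f"k_at_{temp:g}C_per_h"] = k
            for sample_id in sample_ids:
                for t in design.times_h:
                    clean = 100.0 * math.exp(-k * t)
                    for rep in range(1, design.replicates + 1):
                        noisy = clean * _mult_noise(rng, (), design.noise_rsd)
                        rows.append((sample_id, condition, temp, t, rep,
                                     max(float(noisy), 0.0)))
        truth.arrhenius[condition] = entry
    frame = pd.DataFrame(rows, columns=["sample_id", "condition", "temperature_c",
                                        "time_h", "replicate", "recovery_pct"])
    return frame, truth


def gen_chromatogram(degraded_fraction: float,
                     analyte_area: float = 1.0,
                     peak_sd_s: float = 5.25,
                     run_min: float = 6.0,
                     dt_min: float = 0.002,
                     baseline_noise: float = 0.0,
                     rng: np.random.Generator | None = None
                     ) -> tuple[Trace, dict[str, float]]:
    """Synthetic chromatogram over a six-minute run.

    The analyte peak at 2.6 min carries ``analyte_area * (1 - fraction)``;
    the degraded area is split uniformly among the seven degradant peaks.
    Returns the trace and the analytic area of every peak.
    """
    if not 0.0 <= degraded_fraction <= 1.0:
        raise ValueError("degraded_fraction must be in [0, 1]")
    sd_min = peak_sd_s / 60.0
    time = np.arange(0.0, run_min + dt_min / 2, dt_min)
    signal = np.zeros_like(time)
    areas = {"analyte": analyte_area * (1.0 - degraded_fraction)}
    deg_area = analyte_area * degraded_fraction / len(DEGRADANT_TR_MIN)

    def add_peak(center: float, area: float) -> None:
        height = area / (sd_min * math.sqrt(2.0 * math.pi))
        signal_part = height * np.exp(-0.5 * ((time - center) / sd_min) ** 2)
        np.add(signal, signal_part, out=signal)

    add_peak(ANALYTE_TR_MIN, areas["analyte"])
    for tr in DEGRADANT_TR_MIN:
        add_peak(tr, deg_area)
        areas[f"degradant_{tr:g}"] = deg_area
    if baseline_noise > 0:
        if rng is None:
            rng = np.random.default_rng()
        signal += rng.standard_normal(signal.size) * baseline_noise
    return Trace(time=time, signal=signal), areas
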