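"""Peak-table data model, recovery computation, and chromatographic figures
of merit (capacity factor, resolution), plus a trapezoidal integrator for
synthetic traces.

Unit conventions: retention times in minutes, baseline peak widths in
seconds (figures of merit convert internally), areas in arbitrary detector
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PEAK_ROLES",
    "PeakRecord",
    "Trace",
    "recovery_percent",
    "capacity_factor",
    "resolution",
    "integrate_peaks",
    "read_peak_table",
    "write_peak_table",
    "read_trace",
    "write_trace",
]

PEAK_ROLES = frozenset({"standard", "sample", "placebo", "blank"})

_SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class PeakRecord:
    """One integrated chromatographic peak.

    ``t_r`` is in minutes, ``width`` (baseline width) in seconds.
    """

    label: str
    t_r: float
    width: float
    area: float
    sample_id: str = ""
    role: str = "sample"

    def __post_init__(self) -> None:
        if self.t_r <= 0:
            raise ValueError(f"retention time must be > 0, got {self.t_r}")
        if self.width < 0:
            raise ValueError(f"width must be >= 0, got {self.width}")
        if self.area < 0:
            raise ValueError(f"area must be >= 0, got {self.area}")
        if self.role not in PEAK_ROLES:
            raise ValueError(f"role must be one of {sorted(PEAK_ROLES)}, got {self.role!r}")


@dataclass(frozen=True)
class Trace:
    """Detector response on a strictly increasing time grid (minutes)."""

    time: np.ndarray = field(repr=False)
    signal: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.size != s.size:
            raise ValueError("time and signal must have equal length")
        if t.size < 2:
            raise ValueError("trace needs at least two samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)


def recovery_percent(area_sample: float, area_std: float,
                     orientation: str = "sample_over_standard") -> float:
    """Percent recovery from sample and standard peak areas.

    The default orientation is ``100 * area_sample / area_std`` so that
    recovery falls as the analyte degrades. ``orientation=
    "standard_over_sample"`` gives the reciprocal ratio for compatibility
    with sources that print it that way.
    """
    if area_std <= 0:
        raise ValueError("standard area must be > 0")
    if area_sample < 0:
        raise ValueError("sample area must be >= 0")
    if orientation == "sample_over_standard":
        return 100.0 * area_sample / area_std
    if orientation == "standard_over_sample":
        if area_sample == 0:
            raise ZeroDivisionError("sample area is zero in standard/sample orientation")
        return 100.0 * area_std / area_sample
    raise ValueError(f"unknown orientation {orientation!r}")


def capacity_factor(t_r: float, t_0: float) -> float:
    """Capacity (retention) factor k' = (t_r - t_0) / t_0, both in minutes."""
    if t_0 <= 0:
        raise ValueError("void time t_0 must be > 0")
    if t_r < t_0:
        raise ValueError(f"t_r={t_r} precedes void time t_0={t_0}")
    return (t_r - t_0) / t_0


def resolution(t_r1: float, w1: float, t_r2: float, w2: float) -> float:
    """Resolution Rs = 2|t_r2 - t_r1| / (w1 + w2).

    Retention times in minutes, baseline widths in seconds (converted
    internally). Symmetric under swapping the two peaks.
    """
    if w1 < 0 or w2 < 0:
        raise ValueError("widths must be >= 0")
    w_sum_min = (w1 + w2) / _SECONDS_PER_MINUTE
    if w_sum_min == 0:
        raise ValueError("combined peak width is zero")
    return 2.0 * abs(t_r2 - t_r1) / w_sum_min


def integrate_peaks(trace: Trace, windows: list[tuple[float, float]],
                    labels: list[str] | None = None,
                    sample_id: str = "", role: str = "sample") -> list[PeakRecord]:
    """Integrate one peak per window by the trapezoidal rule above a linear
    baseline drawn between the window endpoints.

    Retention time is taken at the signal maximum inside the window; the
    reported width is the window span (seconds). Windows must lie within
    the trace and must not overlap.
    """
    if labels is not None and len(labels) != len(windows):
        raise ValueError("labels must match windows in length")
    t = trace.time
    spans = sorted(windows)
    for (a0, b0), (a1, _b1) in zip(spans, spans[1:]):
        if a1 < b0:
            raise ValueError("windows overlap")
    records: list[PeakRecord] = []
    for i, (start, end) in enumerate(windows):
        if end <= start:
            raise ValueError(f"empty window ({start}, {end})")
        if start < t[0] or end > t[-1]:
            raise ValueError(f"window ({start}, {end}) outside trace span")
        mask = (t >= start) & (t <= end)
        if mask.sum() < 2:
            raise ValueError(f"window ({start}, {end}) contains fewer than two samples")
        tw = t[mask]
        sw = trace.signal[mask]
        baseline = np.interp(tw, [tw[0], tw[-1]], [sw[0], sw[-1]])
        area = float(np.trapezoid(sw - baseline, tw))
        apex = int(np.argmax(sw))
        records.append(PeakRecord(
            label=labels[i] if labels is not None else f"peak{i + 1}",
            t_r=float(tw[apex]),
            width=(end - start) * _SECONDS_PER_MINUTE,
            area=max(area, 0.0),
            sample_id=sample_id,
            role=role,
        ))
    return records


# ---------------------------------------------------------------------------
# CSV interfaces (UTF-8, '.' decimal separator, header required)

_PEAK_COLUMNS = ["sample_id", "role", "label", "t_r_min", "width_s", "area"]


def read_peak_table(path) -> list[PeakRecord]:
    df = pd.read_csv(path)
    missing = [c for c in _PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    return [
        PeakRecord(label=str(row.label), t_r=float(row.t_r_min),
                   width=float(row.width_s), area=float(row.area),
                   sample_id=str(row.sample_id), role=str(row.role))
        for row in df.itertuples()
    ]


def write_peak_table(peaks: list[PeakRecord], path) -> None:
    pd.DataFrame(
        [(p.sample_id, p.role, p.label, p.t_r, p.width, p.area) for p in peaks],
        columns=_PEAK_COLUMNS,
    ).to_csv(path, index=False)


def read_trace(path) -> Trace:
    df = pd.read_csv(path)
    for col in ("time_min", "signal"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing column {col!r}")
    return Trace(time=df["time_min"].to_numpy(), signal=df["signal"].to_numpy())


def write_trace(trace: Trace, path) -> None:
    pd.DataFrame({"time_min": trace.time, "signal": trace.signal}).to_csv(path, index=False)
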