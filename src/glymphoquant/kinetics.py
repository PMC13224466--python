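"""Tracer-kinetic quantification of glymphatic transport from MRI signal intensity.

After intrathecal injection of a gadolinium tracer, the ROI-mean signal
intensity (SI) of the spinal cord gray matter rises from a pre-injection
baseline to a peak and then declines as the tracer is cleared.  From one
animal's SI time course over a 5 h observation window this module derives:

* ``initial_si`` — SI at time 0 (pre-injection baseline),
* ``peak_si`` / ``peak_time`` — the maximum SI and its timepoint (T1),
* ``final_si`` — SI at the last scan (the 5 h endpoint),
* ``t2`` — the clearance interval, ``window − peak_time``,
* ``v1`` — influx (absorption) rate, ``(peak_si − initial_si) / peak_time``,
* ``v2`` — clearance rate, ``(peak_si − final_si) / (window − peak_time)``,
* ``siph`` — a rate-of-change statistic,
  ``(peak_si − final_si) / (siph_constant − peak_time)`` with the constant
  defaulting to 6 (configurable; setting it to the window length makes
  SIPH coincide with ``v2``).

All rates are in SI units per hour and are kept at full precision
internally; rounding to integers happens only in formatted reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Post-injection scan schedule, in hours (time 0 is the pre-injection scan).
SCAN_TIMES_H: tuple[float, ...] = (0.0, 5 / 60, 0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 5.0)

#: Default observation window, hours.
DEFAULT_WINDOW_H = 5.0

#: Default constant in the SIPH denominator.
DEFAULT_SIPH_CONSTANT = 6.0


@dataclass(frozen=True)
class SignalTimeSeries:
    """One animal's ROI-mean signal intensity at each scan timepoint.

    ``times`` must be strictly increasing and start at 0; ``si`` holds one
    finite value per timepoint (arbitrary scanner units).
    """

    animal_id: str
    group: str
    times: tuple[float, ...]
    si: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        si = tuple(float(v) for v in self.si)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "si", si)
        if len(times) == 0:
            raise ValueError("time series is empty")
        if len(times) != len(si):
            raise ValueError(
                f"times ({len(times)}) and si ({len(si)}) differ in length"
            )
        if times[0] != 0.0:
            raise ValueError(f"first timepoint must be 0, got {times[0]}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if not all(np.isfinite(si)):
            raise ValueError("signal intensities must be finite")


@dataclass(frozen=True)
class KineticResult:
    """Derived kinetic parameters for one animal."""

    animal_id: str
    group: str
    initial_si: float
    peak_si: float
    peak_time: float
    final_si: float
    t2: float
    v1: float
    v2: float
    siph: float


def find_peak(series: SignalTimeSeries) -> tuple[float, float]:
    """Return ``(peak_si, peak_time)``; ties are broken to the earliest timepoint."""
    si = np.asarray(series.si)
    idx = int(np.argmax(si))  # argmax returns the first maximum
    return float(si[idx]), float(series.times[idx])


def compute_influx_rate(initial_si: float, peak_si: float, peak_time: float) -> float:
    """Influx rate ``v1 = (peak_si − initial_si) / peak_time`` (SI units/hour)."""
    if peak_time <= 0:
        raise ValueError(f"peak_time must be positive, got {peak_time}")
    return (peak_si - initial_si) / peak_time


def compute_clearance_rate(
    peak_si: float,
    final_si: float,
    peak_time: float,
    window: float = DEFAULT_WINDOW_H,
) -> float:
    """Clearance rate ``v2 = (peak_si − final_si) / (window − peak_time)``."""
    if peak_time >= window:
        raise ValueError(
            f"peak_time ({peak_time}) must precede the window end ({window})"
        )
    return (peak_si - final_si) / (window - peak_time)


def compute_siph(
    series: SignalTimeSeries,
    siph_constant: float = DEFAULT_SIPH_CONSTANT,
) -> float:
    """Rate-of-change statistic ``(peak − final) / (siph_constant − peak_time)``.

    The final-scan SI stands in for the statistic's endpoint term.  With
    ``siph_constant`` equal to the window length this reduces to the
    clearance rate ``v2``.
    """
    peak_si, peak_time = find_peak(series)
    if peak_time >= siph_constant:
        raise ValueError(
            f"peak_time ({peak_time}) must be below the SIPH constant ({siph_constant})"
        )
    return (peak_si - series.si[-1]) / (siph_constant - peak_time)


def estimate_kinetics(
    series: SignalTimeSeries,
    window: float = DEFAULT_WINDOW_H,
    siph_constant: float = DEFAULT_SIPH_CONSTANT,
) -> KineticResult:
    """Derive the full kinetic parameter set from one SI time course.

    ``initial_si`` is the SI at time 0 and ``final_si`` the SI at the last
    scan; the peak is located by :func:`find_peak`.  When the series is
    constant the peak sits at time 0 and both rates are reported as 0 (the
    influx slope is degenerate there, not negative).
    """
    initial_si = series.si[0]
    final_si = series.si[-1]
    peak_si, peak_time = find_peak(series)
    v1 = 0.0 if peak_time == 0 else compute_influx_rate(initial_si, peak_si, peak_time)
    v2 = compute_clearance_rate(peak_si, final_si, peak_time, window)
    siph = compute_siph(series, siph_constant)
    return KineticResult(
        animal_id=series.animal_id,
        group=series.group,
        initial_si=initial_si,
        peak_si=peak_si,
        peak_time=peak_time,
        final_si=final_si,
        t2=window - peak_time,
        v1=v1,
        v2=v2,
        siph=siph,
    )


_PARAM_COLUMNS = ("initial_si", "peak_si", "peak_time", "final_si", "t2", "v1", "v2", "siph")


def results_to_frame(results: Sequence[KineticResult]) -> pd.DataFrame:
    """Tabulate per-animal kinetic results, one row per animal."""
    return pd.DataFrame(
        [
            {"animal_id": r.animal_id, "group": r.group}
            | {c: getattr(r, c) for c in _PARAM_COLUMNS}
            for r in results
        ]
    )


def summarize_groups(results: Sequence[KineticResult]) -> pd.DataFrame:
    """Per-group mean ± SD of every kinetic parameter.

    Rates are computed per animal first, then averaged within group
    (mean of rates, not rate of group means).  Sample SD (n − 1
    denominator); for a single-animal group SD is reported as missing,
    never as zero.  Invariant to the ordering of animals.
    """
    if len(results) == 0:
        raise ValueError("no kinetic results to summarize")
    frame = results_to_frame(results)
    summary = frame.groupby("group", sort=True)[list(_PARAM_COLUMNS)].agg(
        ["mean", "std", "count"]
    )
    summary.columns = [f"{metric}_{stat}" for metric, stat in summary.columns]
    return summary.reset_index()


def read_si_csv(path) -> list[SignalTimeSeries]:
    """Read long-format SI curves from CSV.

    Expected columns: ``animal_id, group, time_h, si`` and optionally
    ``replicate``.  Replicate ROI measurements at the same timepoint are
    averaged before the curve is assembled, mirroring the protocol of
    averaging three ROI readings per scan.
    """
    frame = pd.read_csv(path)
    required = {"animal_id", "group", "time_h", "si"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"input CSV is missing columns: {sorted(missing)}")
    series_list: list[SignalTimeSeries] = []
    for (animal, group), sub in frame.groupby(["animal_id", "group"], sort=True):
        per_time = sub.groupby("time_h", sort=True)["si"].mean()
        series_list.append(
            SignalTimeSeries(
                animal_id=str(animal),
                group=str(group),
                times=tuple(per_time.index),
                si=tuple(per_time.values),
            )
        )
    return series_list


def format_report(summary: pd.DataFrame, round_rates: bool = True) -> pd.DataFrame:
    """Format a group summary for display, rounding rates to integers.

    Rounding happens only here; the underlying summary keeps full
    precision.
    """
    out = summary.copy()
    if round_rates:
        for col in out.columns:
            if col.rsplit("_", 1)[0] in {"initial_si", "peak_si", "final_si", "v1", "v2", "siph"}:
                if col.endswith(("_mean", "_std")):
                    out[col] = out[col].round(0)
    return out
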