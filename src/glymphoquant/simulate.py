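"""Ground-truthed synthetic inputs for every quantification stage.

Three generators, all pure functions of their parameters (including the
seed):

* tracer signal-intensity curves — piecewise-linear rise to a peak and
  decline to the window end, sampled on the nine-point scan schedule,
  with independent Gaussian noise per timepoint.  The generating slopes
  are exactly the influx/clearance rates the estimator should recover;
* two-channel fluorescence images — non-overlapping circular vessel
  cross-sections in the CD31 channel and an AQP4 channel that is a noisy
  parenchymal baseline multiplied by an enrichment factor inside a
  perivascular ring.  Ground truth (masks and the noiseless polarization
  index, computed by brute-force pixel counting) rides along;
* histology grade cohorts — per-feature binomial draws bounded by the
  rubric, so a feature mean at 0 or at its maximum produces exactly
  constant grades.

Defaults for the kinetic cohort presets mirror the printed group means of
the study conditions (baseline ≈ 6,000–7,000 SI units, peak at 1.5–2.2 h,
5 h observation window).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .histology import FEATURE_MAX, FEATURES
from .kinetics import DEFAULT_WINDOW_H, SCAN_TIMES_H, SignalTimeSeries
from .polarization import DualChannelImage, build_perivascular_rois

_MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass(frozen=True)
class KineticSimParams:
    """Generative parameters for one tracer SI curve.

    The noiseless curve is piecewise linear:
    ``SI(t) = initial_si + v_in * t`` for ``t <= t_peak`` and
    ``SI(t) = SI(t_peak) - v_out * (t - t_peak)`` after, so ``v_in`` and
    ``v_out`` are exactly the influx and clearance rates of the curve.
    """

    initial_si: float = 6700.0
    v_in: float = 1500.0  # SI units/hour
    t_peak: float = 1.5  # hours
    v_out: float = 500.0  # SI units/hour
    window: float = DEFAULT_WINDOW_H
    noise_sd: float = 0.0
    timepoints: tuple[float, ...] = SCAN_TIMES_H
    seed: int = 0

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.timepoints)
        object.__setattr__(self, "timepoints", tp)
        if len(tp) < 2:
            raise ValueError("need at least two timepoints")
        if tp[0] != 0.0:
            raise ValueError("first timepoint must be 0")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if tp[-1] != self.window:
            raise ValueError(
                f"last timepoint ({tp[-1]}) must equal the window ({self.window})"
            )
        if not 0 < self.t_peak < self.window:
            raise ValueError(
                f"t_peak ({self.t_peak}) must lie inside (0, {self.window})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ImageSimParams:
    """Generative parameters for one two-channel fluorescence image."""

    height: int = 256
    width: int = 256
    n_vessels: int = 6
    vessel_radius: int = 6  # px
    ring_width: int = 3  # px
    parenchyma_level: float = 60.0
    perivascular_enrichment: float = 3.0  # multiplier inside the ring, >= 1
    vessel_cd31_level: float = 200.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        if self.vessel_radius < 1:
            raise ValueError("vessel_radius must be >= 1 px")
        if self.ring_width < 1:
            raise ValueError("ring_width must be >= 1 px")
        if self.perivascular_enrichment < 1:
            raise ValueError("perivascular_enrichment must be >= 1")
        if min(self.parenchyma_level, self.vessel_cd31_level) < 0:
            raise ValueError("intensity levels must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    vessel_mask: np.ndarray | None = None
    perivascular_mask: np.ndarray | None = None
    true_polarization_index: float | None = None
    true_v1: float | None = None
    true_v2: float | None = None


def simulate_si_curve(params: KineticSimParams) -> SignalTimeSeries:
    """Sample one noisy piecewise-linear tracer curve on the scan grid.

    The generating slopes ``v_in`` and ``v_out`` are by construction the
    true influx and clearance rates of the noiseless curve.  Identical
    parameters, including the seed, give identical output.
    """
    t = np.asarray(params.timepoints)
    peak_si = params.initial_si + params.v_in * params.t_peak
    clean = np.where(
        t <= params.t_peak,
        params.initial_si + params.v_in * t,
        peak_si - params.v_out * (t - params.t_peak),
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        clean = clean + rng.normal(0.0, params.noise_sd, size=clean.shape)
    return SignalTimeSeries(
        animal_id="sim", group="sim", times=tuple(t), si=tuple(clean)
    )


def _place_vessels(params: ImageSimParams, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping disk centers by rejection sampling (bounded attempts)."""
    margin = params.vessel_radius + params.ring_width
    if params.height <= 2 * margin or params.width <= 2 * margin:
        raise ValueError(
            f"image {params.height}x{params.width} too small for vessels of "
            f"radius {params.vessel_radius} with ring width {params.ring_width}"
        )
    min_dist = 2 * (params.vessel_radius + params.ring_width) + 1
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < params.n_vessels:
        attempts += 1
        if attempts > _MAX_PLACEMENT_ATTEMPTS:
            raise RuntimeError(
                f"could not place {params.n_vessels} non-overlapping vessels "
                f"(radius {params.vessel_radius}, ring {params.ring_width}) in a "
                f"{params.height}x{params.width} image within "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
        r = int(rng.integers(margin, params.height - margin))
        c = int(rng.integers(margin, params.width - margin))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_dist**2 for r0, c0 in centers):
            centers.append((r, c))
    mask = np.zeros((params.height, params.width), dtype=bool)
    rr, cc = np.mgrid[0 : params.height, 0 : params.width]
    for r0, c0 in centers:
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= params.vessel_radius**2
    return mask


def simulate_if_image(params: ImageSimParams) -> tuple[DualChannelImage, GroundTruth]:
    """Render one two-channel image with known polarization structure.

    The noiseless AQP4 plane is ``parenchyma_level`` everywhere except the
    perivascular ring, where it is multiplied by the enrichment factor.
    The true polarization index is counted brute-force on that noiseless
    plane against its own perivascular mean; noise (independent Gaussian
    per pixel, clamped at 0) is added only to the emitted channels.
    """
    rng = np.random.default_rng(params.seed)
    vessel_mask = _place_vessels(params, rng)
    ring_mask = (
        build_perivascular_rois(vessel_mask, params.ring_width)
        if vessel_mask.any()
        else np.zeros_like(vessel_mask)
    )

    clean_aqp4 = np.full(vessel_mask.shape, params.parenchyma_level, dtype=np.float64)
    clean_aqp4[ring_mask] *= params.perivascular_enrichment
    clean_cd31 = np.where(vessel_mask, params.vessel_cd31_level, 0.0)

    if ring_mask.any():
        m_pv = clean_aqp4[ring_mask].mean()
        true_index = 100.0 * (clean_aqp4 < m_pv).sum() / clean_aqp4.size
    else:
        true_index = float("nan")

    if params.noise_sd > 0:
        aqp4 = clean_aqp4 + rng.normal(0.0, params.noise_sd, clean_aqp4.shape)
        cd31 = clean_cd31 + rng.normal(0.0, params.noise_sd, clean_cd31.shape)
        aqp4 = np.clip(aqp4, 0.0, None)  # detector floor
        cd31 = np.clip(cd31, 0.0, None)
    else:
        aqp4, cd31 = clean_aqp4, clean_cd31

    image = DualChannelImage(aqp4=aqp4, cd31=cd31)
    truth = GroundTruth(
        vessel_mask=vessel_mask,
        perivascular_mask=ring_mask,
        true_polarization_index=float(true_index),
    )
    return image, truth


def simulate_histology_cohort(
    group_specs: Sequence[tuple[str, Mapping[str, float]]],
    n_per_group: int,
    seed: int = 0,
    sections_per_animal: int = 1,
) -> pd.DataFrame:
    """Draw a per-animal, per-section long table of rubric grades.

    Each subscore for feature ``f`` with target mean ``m`` is drawn as
    ``Binomial(max_f, m / max_f)`` — a bounded integer distribution with
    mean exactly ``m``, collapsing to a constant at either end of the
    rubric range.  Means outside a feature's range are rejected.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    for label, means in group_specs:
        unknown = set(means) - set(FEATURES)
        if unknown:
            raise ValueError(f"group {label!r} has unknown features: {sorted(unknown)}")
        for name, m in means.items():
            if not 0 <= m <= FEATURE_MAX[name]:
                raise ValueError(
                    f"group {label!r}: mean {m} for {name} outside 0..{FEATURE_MAX[name]}"
                )
    rng = np.random.default_rng(seed)
    rows = []
    for label, means in group_specs:
        for i in range(n_per_group):
            for s in range(sections_per_animal):
                row = {
                    "animal_id": f"{label}-{i + 1:02d}",
                    "group": label,
                    "section_id": f"S{s + 1}",
                }
                for name in FEATURES:
                    m = float(means.get(name, 0.0))
                    k = FEATURE_MAX[name]
                    row[name] = int(rng.binomial(k, m / k)) if k else 0
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KineticGroupSpec:
    """Between-animal variation for one cohort group.

    ``t_peak_choices`` are drawn uniformly per animal and should lie on
    the scan grid so the discrete peak is identifiable.
    """

    label: str
    initial_si_mean: float
    initial_si_sd: float
    v_in_mean: float
    v_in_sd: float
    v_out_mean: float
    v_out_sd: float
    t_peak_choices: tuple[float, ...] = (1.5, 2.0)
    noise_sd: float = 25.0


def default_kinetic_groups() -> list[KineticGroupSpec]:
    """Cohort presets matching the study's three printed group means.

    Control (C): brisk influx/clearance; untreated disease (PDN): both
    rates roughly halved with a later peak; treated (PDN+GB): largely
    restored.  Between-animal SDs follow the printed ± spreads.
    """
    return [
        KineticGroupSpec("C", 6154, 123, 1877, 268, 747, 83, (1.5, 2.0), 25.0),
        KineticGroupSpec("PDN", 6697, 54, 974, 152, 308, 36, (2.0, 2.5), 25.0),
        KineticGroupSpec("PDN+GB", 6769, 99, 1730, 243, 547, 101, (1.5,), 25.0),
    ]


def simulate_kinetic_cohort(
    groups: Sequence[KineticGroupSpec] | None = None,
    n_per_group: int = 4,
    seed: int = 0,
) -> tuple[list[SignalTimeSeries], pd.DataFrame]:
    """Simulate a cohort of animals; returns the curves and a truth table.

    Per-animal true rates are Gaussian around the group means (truncated
    at 10% of the mean to keep the curves physiological: rising, then
    falling).
    """
    if groups is None:
        groups = default_kinetic_groups()
    rng = np.random.default_rng(seed)
    series_list: list[SignalTimeSeries] = []
    truth_rows = []
    for spec in groups:
        for i in range(n_per_group):
            v_in = max(0.1 * spec.v_in_mean, rng.normal(spec.v_in_mean, spec.v_in_sd))
            v_out = max(0.1 * spec.v_out_mean, rng.normal(spec.v_out_mean, spec.v_out_sd))
            initial = rng.normal(spec.initial_si_mean, spec.initial_si_sd)
            t_peak = float(rng.choice(spec.t_peak_choices))
            params = KineticSimParams(
                initial_si=initial,
                v_in=v_in,
                t_peak=t_peak,
                v_out=v_out,
                noise_sd=spec.noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            series = simulate_si_curve(params)
            animal = f"{spec.label}-{i + 1:02d}"
            series = replace(series, animal_id=animal, group=spec.label)
            series_list.append(series)
            truth_rows.append(
                {
                    "animal_id": animal,
                    "group": spec.label,
                    "true_v1": v_in,
                    "true_v2": v_out,
                    "true_t_peak": t_peak,
                }
            )
    return series_list, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# writers


def write_curves_csv(series_list: Sequence[SignalTimeSeries], path) -> None:
    """Long-format CSV: animal_id, group, time_h, si."""
    rows = [
        {"animal_id": s.animal_id, "group": s.group, "time_h": t, "si": v}
        for s in series_list
        for t, v in zip(s.times, s.si)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_image(image: DualChannelImage, truth: GroundTruth, out_dir, stem: str) -> None:
    """Write channels as 16-bit TIFFs plus ground-truth masks and JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, plane in (("aqp4", image.aqp4), ("cd31", image.cd31)):
        tifffile.imwrite(
            out_dir / f"{stem}_{name}.tif",
            np.clip(plane, 0, 65535).astype(np.uint16),
        )
    if truth.vessel_mask is not None:
        tifffile.imwrite(
            out_dir / f"{stem}_vessel_mask.tif", truth.vessel_mask.astype(np.uint8)
        )
    if truth.perivascular_mask is not None:
        tifffile.imwrite(
            out_dir / f"{stem}_perivascular_mask.tif",
            truth.perivascular_mask.astype(np.uint8),
        )
    with open(out_dir / f"{stem}_truth.json", "w") as fh:
        json.dump({"true_polarization_index": truth.true_polarization_index}, fh)
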