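"""Perivascular AQP4 polarization quantification from two-channel immunofluorescence.

Aquaporin-4 (AQP4) is normally concentrated at perivascular astrocytic
end-feet; loss of this "polarization" — diffuse AQP4 over the parenchyma —
accompanies glymphatic impairment.  Given a registered AQP4/CD31 image
pair, the pipeline is:

1. constant-percentile background subtraction on the AQP4 channel,
2. vessel segmentation on the CD31 channel (Otsu or a fixed threshold,
   with a minimum component area),
3. perivascular ring ROIs by morphological dilation of the vessel mask,
4. the mean AQP4 intensity over the ring pixels (``M_pv``), and
5. the polarization index: the percentage of analysed pixels whose AQP4
   intensity is *strictly* below ``M_pv``.

A higher index means more of the image sits below the perivascular mean,
i.e. the AQP4 signal is more tightly restricted to the end-feet.  The
index is scale-free: an affine rescaling ``a·I + b`` (a > 0) applied to
both the plane and ``M_pv`` leaves it unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import dilation, disk, remove_small_objects


@dataclass(frozen=True)
class DualChannelImage:
    """Registered AQP4 and CD31 intensity planes (plus optional nuclei).

    Planes must share a shape and contain finite, non-negative values;
    integer inputs are promoted to float64 so all downstream arithmetic is
    in floating point regardless of acquisition bit depth.
    """

    aqp4: np.ndarray
    cd31: np.ndarray
    nuclei: np.ndarray | None = None
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        aqp4 = np.asarray(self.aqp4, dtype=np.float64)
        cd31 = np.asarray(self.cd31, dtype=np.float64)
        object.__setattr__(self, "aqp4", aqp4)
        object.__setattr__(self, "cd31", cd31)
        if aqp4.ndim != 2:
            raise ValueError(f"planes must be 2-D, got {aqp4.ndim}-D")
        if aqp4.shape != cd31.shape:
            raise ValueError(f"channel shapes differ: {aqp4.shape} vs {cd31.shape}")
        if self.nuclei is not None:
            nuclei = np.asarray(self.nuclei, dtype=np.float64)
            if nuclei.shape != aqp4.shape:
                raise ValueError("nuclei plane shape differs from AQP4 plane")
            object.__setattr__(self, "nuclei", nuclei)
        for name, plane in (("aqp4", aqp4), ("cd31", cd31)):
            if not np.all(np.isfinite(plane)):
                raise ValueError(f"{name} plane contains non-finite values")
            if np.any(plane < 0):
                raise ValueError(f"{name} plane contains negative intensities")


@dataclass(frozen=True)
class RegionMasks:
    """Vessel and perivascular masks, plus optional named anatomical regions."""

    vessel_mask: np.ndarray
    perivascular_mask: np.ndarray
    anatomical_regions: Mapping[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        vm = np.asarray(self.vessel_mask, dtype=bool)
        pm = np.asarray(self.perivascular_mask, dtype=bool)
        object.__setattr__(self, "vessel_mask", vm)
        object.__setattr__(self, "perivascular_mask", pm)
        if vm.shape != pm.shape:
            raise ValueError("vessel and perivascular masks differ in shape")
        if np.any(vm & pm):
            raise ValueError("perivascular mask must not intersect the vessel mask")


@dataclass(frozen=True)
class PolarizationResult:
    """Quantification output for one image."""

    perivascular_mean: float
    polarization_index: float
    regional_means: dict[str, float]
    n_vessels: int
    global_threshold: float | None
    valid: bool = True


@dataclass(frozen=True)
class PolarizationConfig:
    """Pipeline settings shared across a batch of images.

    ``global_threshold`` restricts the analysis mask to pixels above a
    batch-wide AQP4 threshold: ``None`` (default) analyses every pixel as
    the index formula states, ``"otsu"`` derives one threshold from the
    pooled AQP4 histogram of the whole batch, and a number is used
    verbatim.  ``exclude_vessel_lumen`` drops CD31-positive pixels from
    the denominator.
    """

    background_percentile: float = 1.0
    vessel_threshold: float | str = "otsu"
    min_vessel_area_px: int = 20
    ring_width_px: int = 3
    global_threshold: float | str | None = None
    exclude_vessel_lumen: bool = False


def subtract_background(plane: np.ndarray, percentile: float = 1.0) -> np.ndarray:
    """Subtract the given intensity percentile as a constant background.

    Negative results are clamped to 0.  Idempotent whenever the percentile
    of the plane is already 0.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.size == 0:
        raise ValueError("cannot subtract background from an empty plane")
    if not 0 <= percentile < 50:
        raise ValueError(f"percentile must lie in [0, 50), got {percentile}")
    background = np.percentile(plane, percentile)
    return np.clip(plane - background, 0.0, None)


def segment_vessels(
    cd31_plane: np.ndarray,
    min_area_px: int = 20,
    threshold: float | str = "otsu",
) -> np.ndarray:
    """Binary vessel mask from the CD31 channel.

    Pixels above the threshold are kept; connected components smaller than
    ``min_area_px`` are discarded.  Automatic (Otsu) thresholding requires
    a non-constant plane.
    """
    plane = np.asarray(cd31_plane, dtype=np.float64)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if np.ptp(plane) == 0:
            raise ValueError(
                "CD31 plane is constant; automatic thresholding is undefined "
                "(pass a fixed threshold instead)"
            )
        thr = threshold_otsu(plane)
    else:
        thr = float(threshold)
    mask = plane > thr
    if min_area_px > 1:
        # keep components of area >= min_area_px
        mask = remove_small_objects(mask, max_size=min_area_px - 1)
    return mask


def build_perivascular_rois(vessel_mask: np.ndarray, ring_width_px: int = 3) -> np.ndarray:
    """Ring ROIs: dilate the vessel mask by ``ring_width_px`` and subtract it.

    Rings of adjacent vessels merge by union, so shared pixels are never
    double-counted.  An empty vessel mask yields an empty ring with a
    warning.
    """
    if ring_width_px < 1:
        raise ValueError(f"ring width must be >= 1 px, got {ring_width_px}")
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if not vessel_mask.any():
        warnings.warn("vessel mask is empty; perivascular ROI is empty", stacklevel=2)
        return np.zeros_like(vessel_mask)
    dilated = dilation(vessel_mask, footprint=disk(ring_width_px))
    return dilated & ~vessel_mask


def mean_perivascular_intensity(aqp4_plane: np.ndarray, perivascular_mask: np.ndarray) -> float:
    """Arithmetic mean of AQP4 intensity over the perivascular ROI pixels."""
    plane = np.asarray(aqp4_plane, dtype=np.float64)
    mask = np.asarray(perivascular_mask, dtype=bool)
    if plane.shape != mask.shape:
        raise ValueError("plane and mask shapes differ")
    if not mask.any():
        raise ValueError("perivascular mask is empty; mean intensity undefined")
    return float(plane[mask].mean())


def polarization_index(
    aqp4_plane: np.ndarray,
    perivascular_mean: float,
    analysis_mask: np.ndarray | None = None,
) -> float:
    """Percentage of analysed pixels strictly below the perivascular mean.

    Pixels exactly equal to ``perivascular_mean`` do not count.  By
    default the whole image is analysed.
    """
    plane = np.asarray(aqp4_plane, dtype=np.float64)
    if not np.isfinite(perivascular_mean):
        raise ValueError("perivascular mean must be finite")
    if analysis_mask is None:
        analysis_mask = np.ones(plane.shape, dtype=bool)
    else:
        analysis_mask = np.asarray(analysis_mask, dtype=bool)
        if analysis_mask.shape != plane.shape:
            raise ValueError("analysis mask shape differs from plane")
    total = int(analysis_mask.sum())
    if total == 0:
        raise ValueError("analysis mask is empty")
    below = int((plane[analysis_mask] < perivascular_mean).sum())
    return 100.0 * below / total


def regional_intensity(
    aqp4_plane: np.ndarray,
    anatomical_regions: Mapping[str, np.ndarray],
) -> dict[str, float]:
    """Mean AQP4 intensity per named region; empty regions are omitted."""
    plane = np.asarray(aqp4_plane, dtype=np.float64)
    means: dict[str, float] = {}
    for name, mask in anatomical_regions.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != plane.shape:
            raise ValueError(f"region {name!r} mask shape differs from plane")
        if mask.any():
            means[name] = float(plane[mask].mean())
    return means


def _resolve_global_threshold(
    config: PolarizationConfig,
    corrected_planes: Sequence[np.ndarray],
) -> float | None:
    """Batch-wide AQP4 analysis threshold (computed once, reused verbatim)."""
    if config.global_threshold is None:
        return None
    if isinstance(config.global_threshold, str):
        if config.global_threshold != "otsu":
            raise ValueError(f"unknown global threshold {config.global_threshold!r}")
        pooled = np.concatenate([p.ravel() for p in corrected_planes])
        if np.ptp(pooled) == 0:
            raise ValueError("pooled AQP4 histogram is constant; Otsu undefined")
        return float(threshold_otsu(pooled))
    return float(config.global_threshold)


def quantify_image(
    image: DualChannelImage,
    config: PolarizationConfig = PolarizationConfig(),
    masks: RegionMasks | None = None,
    _global_threshold: float | None = None,
) -> PolarizationResult:
    """Run the full polarization pipeline on one image.

    User-supplied ``masks`` (mirroring a manual ROI protocol) bypass the
    automatic vessel segmentation and ring construction.  An image with no
    detectable vessel is returned flagged invalid (``valid=False``, NaN
    index) rather than silently scored 0.
    """
    aqp4 = subtract_background(image.aqp4, config.background_percentile)
    if masks is not None:
        vessel_mask = masks.vessel_mask
        ring_mask = masks.perivascular_mask
    else:
        vessel_mask = segment_vessels(
            image.cd31, config.min_vessel_area_px, config.vessel_threshold
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ring_mask = build_perivascular_rois(vessel_mask, config.ring_width_px)
    n_vessels = int(label(vessel_mask).max())

    if _global_threshold is None and config.global_threshold is not None:
        _global_threshold = _resolve_global_threshold(config, [aqp4])

    regions = (
        regional_intensity(aqp4, masks.anatomical_regions)
        if masks is not None and masks.anatomical_regions
        else {}
    )

    if not ring_mask.any():
        return PolarizationResult(
            perivascular_mean=float("nan"),
            polarization_index=float("nan"),
            regional_means=regions,
            n_vessels=n_vessels,
            global_threshold=_global_threshold,
            valid=False,
        )

    m_pv = mean_perivascular_intensity(aqp4, ring_mask)
    analysis_mask = np.ones(aqp4.shape, dtype=bool)
    if config.exclude_vessel_lumen:
        analysis_mask &= ~np.asarray(vessel_mask, dtype=bool)
    if _global_threshold is not None:
        analysis_mask &= aqp4 > _global_threshold
    if not analysis_mask.any():
        return PolarizationResult(
            perivascular_mean=m_pv,
            polarization_index=float("nan"),
            regional_means=regions,
            n_vessels=n_vessels,
            global_threshold=_global_threshold,
            valid=False,
        )
    index = polarization_index(aqp4, m_pv, analysis_mask)
    return PolarizationResult(
        perivascular_mean=m_pv,
        polarization_index=index,
        regional_means=regions,
        n_vessels=n_vessels,
        global_threshold=_global_threshold,
        valid=True,
    )


def quantify_batch(
    images: Sequence[DualChannelImage],
    config: PolarizationConfig = PolarizationConfig(),
    masks: Sequence[RegionMasks | None] | None = None,
) -> list[PolarizationResult]:
    """Quantify a batch with one shared global threshold.

    When ``config.global_threshold == "otsu"`` the threshold is computed
    once from the pooled background-corrected AQP4 histogram of all
    images, then applied verbatim to each, so identical images always
    yield identical results.
    """
    if masks is None:
        masks = [None] * len(images)
    corrected = [
        subtract_background(im.aqp4, config.background_percentile) for im in images
    ]
    thr = _resolve_global_threshold(config, corrected) if config.global_threshold is not None else None
    return [
        quantify_image(im, config, mask, _global_threshold=thr)
        for im, mask in zip(images, masks)
    ]
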