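"""Reading fluorescence images and masks from TIFF/PNG files."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .polarization import DualChannelImage


def read_plane(path) -> np.ndarray:
    """Read one single-channel image plane (TIFF or PNG) as float64."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        plane = tifffile.imread(path)
    else:
        plane = iio.imread(path)
    plane = np.asarray(plane)
    if plane.ndim == 3 and plane.shape[-1] == 1:
        plane = plane[..., 0]
    if plane.ndim != 2:
        raise ValueError(f"{path} is not a single-channel 2-D image: shape {plane.shape}")
    return plane.astype(np.float64)


def read_mask(path) -> np.ndarray:
    """Read a boolean mask image (any nonzero pixel is True)."""
    return read_plane(path) > 0


def read_dual_channel(
    aqp4_path=None,
    cd31_path=None,
    multichannel_path=None,
    aqp4_channel: int = 0,
    cd31_channel: int = 1,
) -> DualChannelImage:
    """Assemble a two-channel image from files.

    Either give two single-channel files, or one multi-page/multi-channel
    TIFF with the channel indices of the AQP4 and CD31 planes (channels
    may be stacked on the first or last axis).
    """
    if multichannel_path is not None:
        stack = np.asarray(tifffile.imread(multichannel_path))
        if stack.ndim != 3:
            raise ValueError(f"expected a 3-D channel stack, got shape {stack.shape}")
        if stack.shape[0] <= 4 < stack.shape[-1]:
            planes = stack
        elif stack.shape[-1] <= 4:
            planes = np.moveaxis(stack, -1, 0)
        else:
            planes = stack
        return DualChannelImage(
            aqp4=planes[aqp4_channel].astype(np.float64),
            cd31=planes[cd31_channel].astype(np.float64),
        )
    if aqp4_path is None or cd31_path is None:
        raise ValueError("need either two single-channel files or a multichannel TIFF")
    return DualChannelImage(aqp4=read_plane(aqp4_path), cd31=read_plane(cd31_path))
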