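"""Maximum-intensity Z-projection and per-channel binarization.

Mirrors the standard ImageJ preprocessing of confocal flow-assay stacks:
each channel of a z-stack is flattened by a maximum-intensity projection and
thresholded into a binary mask.  Thresholds are computed per channel and per
FOV (VWF and CD41 intensity scales are unrelated); a fixed global threshold is
available for strict reproducibility across paired runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .scene import ImageStack


@dataclass
class BinaryMask:
    pixels: np.ndarray  # (y, x) bool
    pixel_size_um: float
    channel_name: str = ""
    threshold: float = 0.0
    degenerate: bool = False  # constant input image; mask is all-false

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size_um**2

    @property
    def fov_area_um2(self) -> float:
        return float(self.pixels.size) * self.pixel_size_um**2


def max_z_projection(stack: ImageStack, channel: str) -> np.ndarray:
    """Per-pixel maximum over z of one channel.

    A single-slice stack projects to that slice unchanged.
    """
    arr = stack.channel(channel)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("channel must be a (z, y, x) array with >= 1 slice")
    return arr.max(axis=0)


def binarize(
    image: np.ndarray,
    method: str = "otsu",
    fixed_value: float | None = None,
    pixel_size_um: float = 1.0,
    channel_name: str = "",
) -> BinaryMask:
    """Threshold a 2-D intensity image into a binary mask.

    ``method`` is ``"otsu"`` (per-image automatic threshold, the ImageJ-style
    default) or ``"fixed"`` (requires ``fixed_value``).  A pixel is foreground
    iff its intensity is strictly greater than the threshold.  A constant
    image under Otsu is degenerate: the mask is all-false and flagged.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("binarize expects a 2-D image")
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        thr = float(fixed_value)
    elif method == "otsu":
        if np.all(image == image.flat[0]):
            return BinaryMask(
                pixels=np.zeros(image.shape, dtype=bool),
                pixel_size_um=pixel_size_um,
                channel_name=channel_name,
                threshold=float(image.flat[0]),
                degenerate=True,
            )
        thr = float(threshold_otsu(image))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return BinaryMask(
        pixels=image > thr,
        pixel_size_um=pixel_size_um,
        channel_name=channel_name,
        threshold=thr,
    )
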