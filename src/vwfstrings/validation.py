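"""Ground-truth matching: score segmentation output against a rendered scene.

A true string counts as recovered when at least half of its rasterized
polyline lies within a small tolerance of some detected string's pixels.
Matching is by coverage, not one-to-one: two true strings merged into one
detected component are both recovered (the count error is scored separately
via the number of detections).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .scene import SceneTruth
from .segmentation import StringRecord


@dataclass
class RecoveryStats:
    n_true: int
    n_recovered: int
    n_detected: int
    true_length_um: float
    measured_length_um: float

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_true if self.n_true else 1.0

    @property
    def length_relative_error(self) -> float:
        if self.true_length_um == 0:
            return 0.0
        return (self.measured_length_um - self.true_length_um) / self.true_length_um


def _raster_polyline(poly: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    iy = np.clip(np.round(poly[:, 0]).astype(int), 0, shape[0] - 1)
    ix = np.clip(np.round(poly[:, 1]).astype(int), 0, shape[1] - 1)
    flat = np.unique(iy * shape[1] + ix)
    return flat // shape[1], flat % shape[1]


def match_truth(
    truth: SceneTruth,
    records: list[StringRecord],
    shape: tuple[int, int],
    min_length_um: float = 5.0,
    tol_px: int = 2,
    coverage: float = 0.5,
) -> RecoveryStats:
    """Score one FOV's detections against its ground truth.

    Only true strings with rendered arclength >= ``min_length_um`` enter the
    recall; measured length sums every detection.
    """
    det = np.zeros(shape, dtype=bool)
    for rec in records:
        det[rec.pixel_set[:, 0], rec.pixel_set[:, 1]] = True
    if tol_px > 0 and det.any():
        det = binary_dilation(det, iterations=tol_px)
    n_true = 0
    n_rec = 0
    true_len = 0.0
    for s in truth.strings:
        if s.arclength_um < min_length_um:
            continue
        n_true += 1
        true_len += s.arclength_um
        yy, xx = _raster_polyline(np.asarray(s.polyline), shape)
        if yy.size and det[yy, xx].mean() >= coverage:
            n_rec += 1
    measured = float(sum(r.skeleton_length_um for r in records))
    return RecoveryStats(n_true, n_rec, len(records), true_len, measured)


def pool_stats(stats: list[RecoveryStats]) -> RecoveryStats:
    """Pool per-FOV recovery stats over a sample."""
    return RecoveryStats(
        n_true=sum(s.n_true for s in stats),
        n_recovered=sum(s.n_recovered for s in stats),
        n_detected=sum(s.n_detected for s in stats),
        true_length_um=sum(s.true_length_um for s in stats),
        measured_length_um=sum(s.measured_length_um for s in stats),
    )
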