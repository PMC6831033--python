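"""Tractogram normalization and display thresholding.

Raw visitation counts fall off roughly exponentially with distance from the
seed, so tractograms are made comparable across tracts, subjects and species
by a log transform followed by calibration to the 75th percentile:

    normalized[v] = log(1 + counts[v]) / P75

where P75 is the 75th percentile (linear-interpolation convention) of
``log(1 + counts)`` over *nonzero-count* voxels.  Zero-count voxels stay 0.
After normalization the nonzero 75th percentile equals 1 exactly.

The percentile is taken over nonzero voxels because including the (typically
vast) zero background would collapse it to 0 on sparse maps; ``log(1 + x)``
rather than ``log(x)`` keeps zero counts finite.  Display thresholding
(defaults 0.5 and 2) is for visualization only — downstream statistics use
unthresholded normalized maps.
"""

from __future__ import annotations

import numpy as np

from .grid import grids_equal
from .tracking import Tractogram

__all__ = ["log_normalize", "threshold_display", "group_average", "NormalizeError"]


class NormalizeError(ValueError):
    pass


def log_normalize(t: Tractogram) -> Tractogram:
    """Log-transform and percentile-calibrate a visitation map."""
    counts = np.asarray(t.counts, dtype=float)
    nonzero = counts > 0
    if not nonzero.any():
        raise NormalizeError(f"tractogram {t.name!r} has no nonzero voxels")
    logged = np.log1p(counts)
    p75 = np.percentile(logged[nonzero], 75)
    normalized = np.where(nonzero, logged / p75, 0.0).astype(np.float32)
    return Tractogram(t.grid, t.counts, normalized=normalized, name=t.name,
                      empty=t.empty)


def threshold_display(t: Tractogram, lo: float = 0.5, hi: float = 2.0) -> Tractogram:
    """Visualization-only thresholding: values below ``lo`` are zeroed, values
    above ``hi`` are clamped to ``hi``, values inside stay unchanged."""
    if t.normalized is None:
        raise NormalizeError("tractogram is not normalized")
    if lo >= hi:
        raise NormalizeError(f"display thresholds need lo < hi, got {lo} >= {hi}")
    v = np.asarray(t.normalized, dtype=np.float32)
    out = np.where(v < lo, 0.0, np.minimum(v, hi)).astype(np.float32)
    return Tractogram(t.grid, t.counts, normalized=out, name=t.name, empty=t.empty)


def group_average(ts: list[Tractogram]) -> Tractogram:
    """Voxelwise arithmetic mean of normalized tractograms (group template).

    The group center is the mean of the individual maps; counts of the result
    are the summed raw counts (kept for bookkeeping, not used downstream).
    """
    if not ts:
        raise NormalizeError("no tractograms to average")
    ref = ts[0]
    acc = np.zeros(ref.grid.shape, dtype=np.float64)
    counts = np.zeros(ref.grid.shape, dtype=np.int64)
    for t in ts:
        grids_equal(ref.grid, t.grid, what="group tractograms")
        if t.normalized is None:
            raise NormalizeError(f"tractogram {t.name!r} is not normalized")
        acc += t.normalized
        counts += t.counts
    return Tractogram(ref.grid, counts, normalized=(acc / len(ts)).astype(np.float32),
                      name=ref.name)
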