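"""Connectivity fingerprints and cross-species Manhattan-distance matching.

A tract's fingerprint is the vector of its average streamline visitation per
ROI: for each ROI, the mean of the raw visitation counts over the ROI's
voxels ("the average number of streamlines hitting the voxels of each ROI").
Fingerprints are max-normalized per tract so that profiles are comparable
across tracts and species, and two sets of fingerprints are compared by the
Manhattan (L1) distance between every pair, giving a dissimilarity matrix
whose diagonal holds the homolog pairs.  The diagonal best-match rate — the
fraction of tracts whose strict minimum distance is their own homolog — is
the summary statistic of cross-species correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import grids_equal
from .phantom import ROIAtlas
from .tracking import Tractogram

__all__ = [
    "Fingerprint",
    "DissimilarityMatrix",
    "FingerprintError",
    "roi_counts",
    "normalize_fingerprint",
    "group_fingerprint",
    "manhattan",
    "dissimilarity_matrix",
    "diagonal_match_rate",
]


class FingerprintError(ValueError):
    pass


@dataclass(frozen=True)
class Fingerprint:
    tract: str
    roi_names: tuple[str, ...]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) != len(self.roi_names):
            raise FingerprintError("one value per ROI required")
        if np.any(values < 0):
            raise FingerprintError("fingerprint values must be non-negative")
        if self.normalized and (values.max(initial=0.0) > 1.0 + 1e-9):
            raise FingerprintError("normalized fingerprint values must be in [0, 1]")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Pairwise Manhattan distances: rows = species A tracts, cols = species B."""

    row_tracts: tuple[str, ...]
    col_tracts: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.row_tracts), len(self.col_tracts)):
            raise FingerprintError("matrix shape does not match tract labels")
        if np.any(m < 0):
            raise FingerprintError("dissimilarities must be non-negative")
        object.__setattr__(self, "matrix", m)


def roi_counts(t: Tractogram, atlas: ROIAtlas) -> Fingerprint:
    """Raw fingerprint: per ROI, the mean visitation count over its voxels."""
    grids_equal(t.grid, atlas.grid, what="tractogram and atlas")
    values = []
    for label in sorted(atlas.names):
        roi = atlas.labels == label
        if not roi.any():
            raise FingerprintError(f"ROI {atlas.names[label]!r} is empty")
        values.append(float(np.asarray(t.counts)[roi].mean()))
    return Fingerprint(t.name, tuple(atlas.roi_names), np.asarray(values))


def normalize_fingerprint(fp: Fingerprint) -> Fingerprint:
    """Divide by the maximum value; the maximum becomes exactly 1."""
    mx = fp.values.max(initial=0.0)
    if mx <= 0:
        raise FingerprintError(f"tract {fp.tract!r} reaches no ROI (all-zero fingerprint)")
    return replace(fp, values=fp.values / mx, normalized=True)


def group_fingerprint(fps: list[Fingerprint]) -> Fingerprint:
    """Elementwise mean of normalized fingerprints (the group center).

    The mean of max-normalized profiles may have maximum < 1; it is *not*
    renormalized.
    """
    if not fps:
        raise FingerprintError("no fingerprints to average")
    ref = fps[0]
    for fp in fps[1:]:
        if fp.roi_names != ref.roi_names:
            raise FingerprintError("fingerprints have mismatched ROI sets")
    mean = np.mean([fp.values for fp in fps], axis=0)
    return Fingerprint(ref.tract, ref.roi_names, mean,
                       normalized=all(fp.normalized for fp in fps))


def manhattan(a: Fingerprint, b: Fingerprint) -> float:
    """Manhattan (L1) distance between two fingerprints over matched ROIs."""
    if a.roi_names != b.roi_names:
        raise FingerprintError(
            f"ROI mismatch between {a.tract!r} and {b.tract!r}"
        )
    return float(np.abs(a.values - b.values).sum())


def dissimilarity_matrix(A: list[Fingerprint], B: list[Fingerprint]) -> DissimilarityMatrix:
    """All-pairs Manhattan distances between two species' fingerprints.

    Both lists must cover the same tract-name set; columns are reordered to
    the row (species A) tract order so homolog pairs lie on the diagonal.
    """
    names_a = [fp.tract for fp in A]
    by_name_b = {fp.tract: fp for fp in B}
    if set(names_a) != set(by_name_b) or len(names_a) != len(B):
        raise FingerprintError(
            f"tract name sets differ: {sorted(names_a)} vs {sorted(by_name_b)}"
        )
    b_ordered = [by_name_b[n] for n in names_a]
    m = np.array([[manhattan(fa, fb) for fb in b_ordered] for fa in A])
    return DissimilarityMatrix(tuple(names_a), tuple(names_a), m)


def diagonal_match_rate(m: DissimilarityMatrix) -> float:
    """Fraction of rows whose strict minimum sits on the diagonal.

    Ties count as non-matches.  Requires a square matrix with matched
    row/column tract order.
    """
    mat = m.matrix
    if mat.shape[0] != mat.shape[1]:
        raise FingerprintError("diagonal match rate needs a square matrix")
    if m.row_tracts != m.col_tracts:
        raise FingerprintError("row/column tract order must match")
    hits = 0
    for i, row in enumerate(mat):
        diag = row[i]
        off = np.delete(row, i)
        if off.size == 0 or diag < off.min():
            hits += 1
    return hits / mat.shape[0]
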