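"""On-disk formats: NIfTI volumes, TCK streamlines, TSV tables, YAML specs.

Every writer/reader pair is a lossless round-trip at stated precision:
volumes and affines through NIfTI-1 to float precision, streamline
coordinates through TCK to 1e-4 mm, fingerprints and dissimilarity matrices
through TSV exactly as printed.  Validation is strict — unexpected grids,
singular affines, or non-binary masks are rejected, never guessed around.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .fingerprint import DissimilarityMatrix, Fingerprint, FingerprintError
from .grid import GridError, VoxelGrid
from .phantom import (
    MAX_POPULATIONS,
    BundleSpec,
    FiberField,
    MaskRecipe,
    PhantomSpec,
    ROIAtlas,
    ROISpec,
    SourceSpec,
)
from .tracking import Streamline, StreamlineSet, TrackingError

__all__ = [
    "VolumeImage",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_atlas",
    "write_atlas",
    "write_fiber_field",
    "read_fiber_field",
    "write_streamlines",
    "read_streamlines",
    "write_fingerprint_table",
    "read_fingerprint_table",
    "write_dissimilarity",
    "read_dissimilarity",
    "write_phantom_spec",
    "read_phantom_spec",
]


class FormatError(ValueError):
    pass


@dataclass
class VolumeImage:
    """A scalar or vector array on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        if tuple(self.data.shape[:3]) != self.grid.shape:
            raise FormatError(
                f"data shape {self.data.shape} inconsistent with grid {self.grid.shape}"
            )


# --------------------------------------------------------------------------
# NIfTI volumes


def _load_nifti(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises assorted types on bad payloads
        raise FormatError(f"{path} is not a readable NIfTI file: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise FormatError(f"{path}: expected NIfTI, got {type(img).__name__}")
    return img


def read_volume(path, expected_grid: VoxelGrid | None = None) -> VolumeImage:
    img = _load_nifti(path)
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GridError(f"{path}: singular affine")
    grid = VoxelGrid(tuple(img.shape[:3]), affine)
    if expected_grid is not None and grid != expected_grid:
        raise GridError(
            f"{path}: grid {grid.shape} does not match expected {expected_grid.shape}"
        )
    data = np.asanyarray(img.dataobj)
    return VolumeImage(grid, np.asarray(data))


def write_volume(vol: VolumeImage | tuple, path) -> Path:
    if isinstance(vol, tuple):
        vol = VolumeImage(*vol)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.Nifti1Image(np.asarray(vol.data), vol.grid.affine).to_filename(str(path))
    return path


def read_mask(path, expected_grid: VoxelGrid | None = None) -> np.ndarray:
    """Read a binary mask; any value outside {0, 1} is an error."""
    vol = read_volume(path, expected_grid)
    values = np.unique(vol.data)
    bad = sorted(set(values.tolist()) - {0, 1})
    if bad:
        raise FormatError(f"{path}: mask contains non-binary values {bad}")
    return vol.data.astype(bool)


def write_mask(mask: np.ndarray, grid: VoxelGrid, path) -> Path:
    return write_volume(VolumeImage(grid, np.asarray(mask, dtype=np.uint8)), path)


def write_atlas(atlas: ROIAtlas, path) -> tuple[Path, Path]:
    """Write the label volume plus a ``label<TAB>name`` table alongside it."""
    path = Path(path)
    vol_path = write_volume(
        VolumeImage(atlas.grid, atlas.labels.astype(np.uint16)), path
    )
    names_path = vol_path.with_name(vol_path.name.split(".")[0] + "_labels.tsv")
    pd.DataFrame(
        {"label": sorted(atlas.names), "name": [atlas.names[l] for l in sorted(atlas.names)]}
    ).to_csv(names_path, sep="\t", index=False)
    return vol_path, names_path


def read_atlas(vol_path, names_path) -> ROIAtlas:
    vol = read_volume(vol_path)
    table = pd.read_csv(names_path, sep="\t")
    names = {int(r.label): str(r.name) for r in table.itertuples()}
    return ROIAtlas(vol.grid, vol.data.astype(np.int16), names)


# --------------------------------------------------------------------------
# fiber fields


def write_fiber_field(field: FiberField, stem) -> dict[str, Path]:
    """Serialize a fiber field as NIfTI volumes under a path stem.

    ``<stem>_samples.nii.gz`` holds a 5-D array (x, y, z, population,
    3 * n_samples orientation channels); fractions, means and dispersions go
    to sibling files.  Voxels without a population carry zeros.
    """
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    grid = field.grid
    shape = grid.shape
    K = field.n_orientation_samples
    ptr = field.index_volume  # (*shape, MAX_POPULATIONS)
    has = ptr >= 0
    safe = np.clip(ptr, 0, None)

    samples = np.where(
        has[..., None, None], field.samples[safe], 0.0
    ).reshape(*shape, MAX_POPULATIONS, 3 * K).astype(np.float32)
    fractions = np.where(has, field.fractions[safe], 0.0).astype(np.float32)
    means = np.where(has[..., None], field.means[safe], 0.0).astype(np.float32)
    dispersions = np.where(has, field.dispersions_deg[safe], -1.0).astype(np.float32)

    paths = {}
    for tag, arr in [
        ("samples", samples),
        ("fractions", fractions),
        ("means", means.reshape(*shape, MAX_POPULATIONS * 3)),
        ("dispersions", dispersions),
    ]:
        p = stem.parent / f"{stem.name}_{tag}.nii.gz"
        write_volume(VolumeImage(grid, arr), p)
        paths[tag] = p
    return paths


def read_fiber_field(stem) -> FiberField:
    """Inverse of :func:`write_fiber_field`.

    Samples are stored as float32, so they are renormalized to unit length
    on read to restore the exact-unit-norm invariant.
    """
    stem = Path(stem)
    vols = {
        tag: read_volume(stem.parent / f"{stem.name}_{tag}.nii.gz")
        for tag in ("samples", "fractions", "means", "dispersions")
    }
    grid = vols["fractions"].grid
    shape = grid.shape
    fr = np.asarray(vols["fractions"].data, dtype=np.float64)
    disp = np.asarray(vols["dispersions"].data, dtype=np.float64)
    means = np.asarray(vols["means"].data, dtype=np.float64).reshape(
        *shape, MAX_POPULATIONS, 3
    )
    samp = np.asarray(vols["samples"].data, dtype=np.float64)
    K = samp.shape[-1] // 3
    samp = samp.reshape(*shape, MAX_POPULATIONS, K, 3)

    has = disp >= 0
    index = np.full((*shape, MAX_POPULATIONS), -1, dtype=np.int32)
    flat_has = has.reshape(-1, MAX_POPULATIONS)
    counter = 0
    rows = []
    for v in np.flatnonzero(flat_has.any(axis=1)):
        for slot in range(MAX_POPULATIONS):
            if flat_has[v, slot]:
                index.reshape(-1, MAX_POPULATIONS)[v, slot] = counter
                rows.append((v, slot))
                counter += 1
    if rows:
        vi = np.array([r[0] for r in rows])
        si = np.array([r[1] for r in rows])
        means_t = means.reshape(-1, MAX_POPULATIONS, 3)[vi, si]
        means_t /= np.linalg.norm(means_t, axis=-1, keepdims=True)
        fr_t = fr.reshape(-1, MAX_POPULATIONS)[vi, si]
        disp_t = disp.reshape(-1, MAX_POPULATIONS)[vi, si]
        samp_t = samp.reshape(-1, MAX_POPULATIONS, K, 3)[vi, si]
        samp_t /= np.linalg.norm(samp_t, axis=-1, keepdims=True)
    else:
        means_t = np.empty((0, 3))
        fr_t = disp_t = np.empty(0)
        samp_t = np.empty((0, K, 3))
    return FiberField(grid, index, means_t, fr_t, disp_t, samp_t)


# --------------------------------------------------------------------------
# streamlines (TCK)


def write_streamlines(sset: StreamlineSet, path) -> Path:
    """Write a streamline set as TCK (world-mm coordinates, order preserved)."""
    if len(sset) == 0:
        raise FormatError("refusing to write an empty streamline set")
    for s in sset.streamlines:
        if len(s) < 2:
            raise FormatError("a streamline has >= 2 points")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tractogram = nib.streamlines.Tractogram(
        [s.points for s in sset.streamlines], affine_to_rasmm=np.eye(4)
    )
    tck = nib.streamlines.TckFile(
        tractogram,
        header={
            "tract": sset.tract,
            "config_hash": sset.config_hash,
            "rng_seed": str(sset.rng_seed),
        },
    )
    tck.save(str(path))
    return path


def read_streamlines(path) -> StreamlineSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tck = nib.streamlines.load(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: corrupt or non-TCK streamline file: {exc}") from exc
    header = tck.header
    streamlines = [Streamline(np.asarray(pts, dtype=float))
                   for pts in tck.tractogram.streamlines]
    return StreamlineSet(
        streamlines,
        tract=str(header.get("tract", "tract")),
        config_hash=str(header.get("config_hash", "")),
        rng_seed=int(header.get("rng_seed", 0)),
    )


# --------------------------------------------------------------------------
# fingerprint / dissimilarity tables


def write_fingerprint_table(fps: list[Fingerprint], path) -> Path:
    """TSV with one row per tract and one column per ROI (stable ROI order)."""
    if not fps:
        raise FingerprintError("no fingerprints to write")
    ref = fps[0]
    for fp in fps:
        if fp.roi_names != ref.roi_names:
            raise FingerprintError("fingerprints have mismatched ROI sets")
    for name in ref.roi_names + tuple(fp.tract for fp in fps):
        if "\t" in name or "\n" in name:
            raise FormatError(f"name {name!r} contains a tab or newline")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [fp.values for fp in fps],
        index=pd.Index([fp.tract for fp in fps], name="tract"),
        columns=list(ref.roi_names),
    )
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_fingerprint_table(path, normalized: bool = True) -> list[Fingerprint]:
    df = pd.read_csv(path, sep="\t", index_col="tract")
    roi_names = tuple(df.columns)
    return [
        Fingerprint(str(tract), roi_names, row.to_numpy(dtype=float),
                    normalized=normalized)
        for tract, row in df.iterrows()
    ]


def write_dissimilarity(m: DissimilarityMatrix, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        m.matrix,
        index=pd.Index(m.row_tracts, name="tract"),
        columns=list(m.col_tracts),
    )
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_dissimilarity(path) -> DissimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="tract")
    return DissimilarityMatrix(
        tuple(str(t) for t in df.index),
        tuple(str(c) for c in df.columns),
        df.to_numpy(dtype=float),
    )


# --------------------------------------------------------------------------
# phantom specs (YAML)


def _spec_to_dict(spec: PhantomSpec) -> dict:
    return {
        "shape": list(spec.shape),
        "voxel_size_mm": spec.voxel_size_mm,
        "rng_seed": spec.rng_seed,
        "n_orientation_samples": spec.n_orientation_samples,
        "bundles": [
            {
                "name": b.name,
                "control_points_mm": [list(p) for p in b.control_points_mm],
                "radius_mm": b.radius_mm,
                "dispersion_deg": b.dispersion_deg,
                "volume_fraction": b.volume_fraction,
                "porosity_interval": list(b.porosity_interval)
                if b.porosity_interval
                else None,
                "porosity_factor": b.porosity_factor,
            }
            for b in spec.bundles
        ],
        "sources": [
            {"name": s.name, "center_mm": list(s.center_mm),
             "radius_mm": s.radius_mm, "bundle": s.bundle}
            for s in spec.sources
        ],
        "rois": [
            {"name": r.name, "center_mm": list(r.center_mm), "radius_mm": r.radius_mm}
            for r in spec.rois
        ],
        "recipes": [
            {
                "name": r.name,
                "bundle": r.bundle,
                "seed_x_mm": list(r.seed_x_mm),
                "waypoint_x_mm": list(r.waypoint_x_mm) if r.waypoint_x_mm else None,
                "posterior_exclusion_max_x_mm": r.posterior_exclusion_max_x_mm,
                "csf_rind": r.csf_rind,
            }
            for r in spec.recipes
        ],
    }


def _spec_from_dict(d: dict) -> PhantomSpec:
    return PhantomSpec(
        shape=tuple(d["shape"]),
        voxel_size_mm=float(d["voxel_size_mm"]),
        rng_seed=int(d.get("rng_seed", 0)),
        n_orientation_samples=int(d.get("n_orientation_samples", 32)),
        bundles=tuple(
            BundleSpec(
                name=b["name"],
                control_points_mm=tuple(tuple(p) for p in b["control_points_mm"]),
                radius_mm=float(b["radius_mm"]),
                dispersion_deg=float(b.get("dispersion_deg", 8.0)),
                volume_fraction=float(b.get("volume_fraction", 0.7)),
                porosity_interval=tuple(b["porosity_interval"])
                if b.get("porosity_interval")
                else None,
                porosity_factor=float(b.get("porosity_factor", 0.5)),
            )
            for b in d.get("bundles", [])
        ),
        sources=tuple(
            SourceSpec(s["name"], tuple(s["center_mm"]), float(s["radius_mm"]),
                       s["bundle"])
            for s in d.get("sources", [])
        ),
        rois=tuple(
            ROISpec(r["name"], tuple(r["center_mm"]), float(r["radius_mm"]))
            for r in d.get("rois", [])
        ),
        recipes=tuple(
            MaskRecipe(
                name=r["name"],
                bundle=r["bundle"],
                seed_x_mm=tuple(r["seed_x_mm"]),
                waypoint_x_mm=tuple(r["waypoint_x_mm"]) if r.get("waypoint_x_mm") else None,
                posterior_exclusion_max_x_mm=r.get("posterior_exclusion_max_x_mm"),
                csf_rind=bool(r.get("csf_rind", True)),
            )
            for r in d.get("recipes", [])
        ),
    )


def write_phantom_spec(spec: PhantomSpec, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=False)
    return path


def read_phantom_spec(path) -> PhantomSpec:
    with open(path) as fh:
        return _spec_from_dict(yaml.safe_load(fh))
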