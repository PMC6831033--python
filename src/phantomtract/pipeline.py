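"""End-to-end orchestration: simulate -> track -> normalize -> gradient ->
fingerprint -> compare, from one config, with a manifest of outputs.

A single global seed spawns per-stage substreams (via ``numpy``'s
``SeedSequence`` with fixed spawn keys), so any stage re-run with the same
config reproduces its outputs byte-identically, independent of the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as ptio
from .fingerprint import (
    diagonal_match_rate,
    dissimilarity_matrix,
    normalize_fingerprint,
    roi_counts,
)
from .gradient import gradient_ratio, source_tractograms
from .masks import MaskSet
from .normalize import log_normalize
from .phantom import (
    Phantom,
    PhantomSpec,
    bundle_mask,
    demo_spec,
    make_species_pair,
    source_seed_mask,
)
from .tracking import RETAINED, track_bundle

__all__ = ["RunConfig", "run", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration for a full phantom analysis run.

    ``n_samples`` (streamlines per seed voxel) applies to every tracking
    stage; the protocol default of 10,000 is far more than the phantom needs,
    so demo runs default to a lighter setting.
    """

    out_dir: str = "phantomtract_run"
    rng_seed: int = 0
    spec_path: str | None = None  # YAML PhantomSpec; None -> built-in demo
    n_samples: int = 40
    scale: float = 0.5  # macaque-analog world scale
    dispersion_deg: float = 8.0
    do_track: bool = True
    do_normalize: bool = True
    do_gradient: bool = True
    do_fingerprint: bool = True
    do_compare: bool = True
    save_streamlines: bool = False
    save_field: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _derive_seed(root: int, *key: int) -> int:
    """Deterministic 31-bit substream seed for a (stage, species, tract) slot."""
    ss = np.random.SeedSequence(entropy=root, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "rng_seed": config.rng_seed,
        "config_hash": config.config_hash(),
        "artifacts": [],
        "stats": {},
        "skipped": [],
    }

    def record(path: Path) -> None:
        manifest["artifacts"].append(str(path.relative_to(out)))

    stage = "simulate"
    try:
        if config.spec_path is not None:
            spec = ptio.read_phantom_spec(config.spec_path)
        else:
            spec = demo_spec(
                rng_seed=_derive_seed(config.rng_seed, 0),
                dispersion_deg=config.dispersion_deg,
            )
        human, macaque = make_species_pair(spec, scale=config.scale)
        phantoms: dict[str, Phantom] = {"human": human, "macaque": macaque}
        for si, (species, ph) in enumerate(phantoms.items()):
            sdir = out / species
            record(ptio.write_phantom_spec(ph.spec, sdir / "phantom_spec.yaml"))
            if ph.atlas is not None:
                for p in ptio.write_atlas(ph.atlas, sdir / "atlas.nii.gz"):
                    record(p)
            for tract, masks in ph.masks.items():
                mdir = sdir / "masks" / tract
                record(ptio.write_mask(masks.seed, ph.field.grid, mdir / "seed.nii.gz"))
                for wi, w in enumerate(masks.waypoints):
                    record(ptio.write_mask(w, ph.field.grid, mdir / f"waypoint{wi}.nii.gz"))
                for ei, e in enumerate(masks.exclusions):
                    record(ptio.write_mask(e, ph.field.grid, mdir / f"exclusion{ei}.nii.gz"))
                if masks.csf is not None:
                    record(ptio.write_mask(masks.csf, ph.field.grid, mdir / "csf.nii.gz"))
            if config.save_field:
                for p in ptio.write_fiber_field(ph.field, sdir / "field").values():
                    record(p)

        tractograms: dict[tuple[str, str], object] = {}
        normalized: dict[tuple[str, str], object] = {}

        stage = "track"
        if config.do_track:
            for si, (species, ph) in enumerate(phantoms.items()):
                for ti, (tract, masks) in enumerate(sorted(ph.masks.items())):
                    cfg = replace(
                        ph.tracking,
                        n_samples=config.n_samples,
                        rng_seed=_derive_seed(config.rng_seed, 1, si, ti),
                    )
                    tg, sset = track_bundle(ph.field, masks, cfg, name=tract)
                    tractograms[(species, tract)] = tg
                    n_ret = len(sset.retained())
                    manifest["stats"].setdefault("retained", {})[
                        f"{species}/{tract}"
                    ] = n_ret
                    tdir = out / species / "tractograms"
                    record(
                        ptio.write_volume(
                            (ph.field.grid, tg.counts.astype(np.int32)),
                            tdir / f"{tract}_counts.nii.gz",
                        )
                    )
                    if config.save_streamlines and len(sset):
                        record(
                            ptio.write_streamlines(sset, tdir / f"{tract}.tck")
                        )
        else:
            manifest["skipped"].append("track")

        stage = "normalize"
        if config.do_normalize and config.do_track:
            for (species, tract), tg in tractograms.items():
                norm = log_normalize(tg)
                normalized[(species, tract)] = norm
                record(
                    ptio.write_volume(
                        (norm.grid, norm.normalized),
                        out / species / "tractograms" / f"{tract}_norm.nii.gz",
                    )
                )
        else:
            manifest["skipped"].append("normalize")

        stage = "gradient"
        if config.do_gradient:
            for si, (species, ph) in enumerate(phantoms.items()):
                sspec = ph.spec
                if len(sspec.sources) < 2:
                    manifest["skipped"].append(f"gradient/{species}")
                    continue
                src_masks = {
                    s.name: source_seed_mask(sspec, s) for s in sspec.sources
                }
                for bi, bundle in enumerate(("medial", "lateral")):
                    core = ph.masks[bundle].seed
                    maps = {}
                    for gi, source in enumerate(("amygdala", "temporal_pole")):
                        cfg = replace(
                            ph.tracking,
                            n_samples=config.n_samples,
                            rng_seed=_derive_seed(config.rng_seed, 2, si, bi, gi),
                        )
                        maps[source] = source_tractograms(
                            ph.field,
                            src_masks[source],
                            core,
                            cfg,
                            name=f"{bundle}_{source}",
                            csf=ph.masks[bundle].csf,
                        )
                    gm = gradient_ratio(
                        maps["amygdala"],
                        maps["temporal_pole"],
                        bundle_mask(sspec, bundle),
                        name=bundle,
                    )
                    record(
                        ptio.write_volume(
                            (gm.grid, gm.ratio.astype(np.float32)),
                            out / species / "gradient" / f"{bundle}_ratio.nii.gz",
                        )
                    )
        else:
            manifest["skipped"].append("gradient")

        stage = "fingerprint"
        fps_by_species: dict[str, list] = {}
        if config.do_fingerprint and config.do_track:
            for species, ph in phantoms.items():
                if ph.atlas is None:
                    manifest["skipped"].append(f"fingerprint/{species}")
                    continue
                fps = []
                for tract in sorted(ph.masks):
                    fp = roi_counts(tractograms[(species, tract)], ph.atlas)
                    fps.append(normalize_fingerprint(fp))
                fps_by_species[species] = fps
                record(
                    ptio.write_fingerprint_table(
                        fps, out / species / "fingerprints.tsv"
                    )
                )
        else:
            manifest["skipped"].append("fingerprint")

        stage = "compare"
        if config.do_compare and len(fps_by_species) == 2:
            m = dissimilarity_matrix(
                fps_by_species["human"], fps_by_species["macaque"]
            )
            record(ptio.write_dissimilarity(m, out / "dissimilarity.tsv"))
            manifest["stats"]["diagonal_match_rate"] = diagonal_match_rate(m)
        else:
            manifest["skipped"].append("compare")

    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
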