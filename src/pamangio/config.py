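"""One flat run configuration binding all module defaults, with strict
unknown-key rejection, plus the pipeline orchestrator."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np

from . import io as pio
from .forward import (
    AcquisitionSpec,
    OpticalSpec,
    TransducerSpec,
    simulate_confocal_stack,
    simulate_pam_stack,
)
from .phantom import PhantomSpec, grow_vascular_phantom
from .quantify import (
    DEFAULT_DEPTH_BINS_UM,
    depth_binned_density,
    length_statistics,
    segment_vessels,
    skeletonize_and_trace,
)
from .recon import (
    assemble_volume,
    depth_encoded_projection,
    extract_bscan,
    map_projection,
    median_filter_3d,
)

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "recon", "quantify", "stats")


def _build(cls, doc: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in doc.items()
    }
    return cls(**coerced)


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(volume_size_um=(400.0, 400.0, 300.0))
    )
    optics: OpticalSpec = field(default_factory=OpticalSpec)
    transducer: TransducerSpec = field(default_factory=TransducerSpec)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    min_component_voxels: int = 100
    depth_bins_um: tuple = DEFAULT_DEPTH_BINS_UM
    rng_seed: int = 0
    out_dir: str = "pam_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = pio.load_yaml(path)
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        kwargs = {}
        for key, sub in (("phantom", PhantomSpec), ("optics", OpticalSpec),
                         ("transducer", TransducerSpec),
                         ("acquisition", AcquisitionSpec)):
            if key in doc:
                kwargs[key] = _build(sub, doc[key])
        for key in ("min_component_voxels", "rng_seed", "out_dir"):
            if key in doc:
                kwargs[key] = doc[key]
        if "depth_bins_um" in doc:
            kwargs["depth_bins_um"] = tuple(doc["depth_bins_um"])
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(
            self,
            rng_seed=seed,
            phantom=replace(self.phantom, rng_seed=seed),
            acquisition=replace(self.acquisition, rng_seed=seed),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, stages=ALL_STAGES) -> dict:
    """Execute the requested stages and return (and write) a run manifest.

    Stage order is fixed; later stages read the artifacts earlier stages
    wrote, so requesting a stage without its upstream artifact fails with an
    error naming the missing file.
    """
    stages = tuple(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def require(name: str, path: Path) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"stage needs missing upstream artifact {path}; "
                f"run the producing stage first"
            )
        return path

    if "simulate" in stages:
        phantom = grow_vascular_phantom(config.phantom)
        from .recon import ReconVolume

        truth = ReconVolume(phantom.absorber, config.phantom.voxel_pitch_um,
                            provenance={"kind": "ground_truth_absorber"})
        artifacts["phantom_absorber"] = pio.write_volume(
            truth, out / "phantom_absorber.tiff")
        from .quantify import VesselGraph, VesselSegment

        gt_graph = VesselGraph(
            [VesselSegment(s.points_um, s.length_um, (1, 1))
             for s in phantom.segments],
            config.phantom.voxel_pitch_um,
        )
        artifacts["phantom_graph"] = pio.write_graph_csv(
            gt_graph, out / "phantom_graph.csv")
        frames = simulate_pam_stack(
            phantom, config.optics, config.transducer, config.acquisition)
        artifacts["rf"] = pio.write_rf(frames, out / "frames.rf")
        confocal = simulate_confocal_stack(phantom, config.optics,
                                           config.acquisition)
        artifacts["confocal"] = pio.write_volume(confocal, out / "confocal.tiff")

    if "recon" in stages:
        frames = pio.read_rf(require("rf", out / "frames.rf"))
        volume = median_filter_3d(assemble_volume(frames))
        artifacts["volume"] = pio.write_volume(volume, out / "volume.tiff")
        mip = map_projection(volume)
        np.savetxt(out / "map.csv", mip, delimiter=",")
        artifacts["map"] = out / "map.csv"
        depth = depth_encoded_projection(volume)
        np.savetxt(out / "depth_encoded.csv", depth, delimiter=",")
        artifacts["depth_encoded"] = out / "depth_encoded.csv"
        bscan = extract_bscan(volume, volume.shape[1] // 2)
        np.savetxt(out / "bscan.csv", bscan, delimiter=",")
        artifacts["bscan"] = out / "bscan.csv"

    if "quantify" in stages:
        volume = pio.read_volume(require("volume", out / "volume.tiff"))
        mask = segment_vessels(volume, config.min_component_voxels)
        artifacts["mask"] = pio.write_mask(mask.mask, mask.voxel_pitch_um,
                                           out / "mask.tiff")
        bins = np.asarray(config.depth_bins_um, dtype=float)
        max_depth = volume.shape[2] * volume.voxel_pitch_um[2]
        bins = bins[bins <= max_depth + 1e-9]
        profile = depth_binned_density(mask, bins)
        artifacts["density"] = pio.write_depth_profile_csv(
            profile, out / "density.csv")
        graph = skeletonize_and_trace(mask)
        artifacts["lengths"] = pio.write_graph_csv(graph, out / "lengths.csv")

    if "stats" in stages:
        import pandas as pd

        from .stats import GroupData, dunn_posthoc

        lengths = pio.read_graph_lengths(require("lengths", out / "lengths.csv"))
        if lengths.size >= 2:
            depth_mid = pd.read_csv(out / "lengths.csv")[["z0_um", "z1_um"]] \
                .mean(axis=1).to_numpy()
            median_depth = float(np.median(depth_mid))
            groups = {
                "shallow": lengths[depth_mid <= median_depth],
                "deep": lengths[depth_mid > median_depth],
            }
            if all(v.size >= 1 for v in groups.values()):
                report = dunn_posthoc(GroupData(groups))
                report.pairwise.to_csv(out / "stats.csv", index=False)
                artifacts["stats"] = out / "stats.csv"

    manifest = {
        "config": config.to_dict(),
        "stages": list(stages),
        "seed": config.rng_seed,
        "artifacts": {
            name: {"path": str(p), "sha256": _checksum(Path(p))}
            for name, p in artifacts.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    pio.dump_yaml(config.to_dict(), out / "resolved_config.yaml")
    return manifest
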