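"""File formats: multi-page TIFF volumes with sidecar metadata, CSV tables
for graphs and profiles, raw RF containers, and YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .forward import AcquisitionSpec, OpticalSpec, RFFrameSet, TransducerSpec
from .quantify import DepthProfile, VesselGraph
from .recon import ReconVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_mask",
    "write_graph_csv",
    "read_graph_lengths",
    "write_depth_profile_csv",
    "write_rf",
    "read_rf",
    "load_yaml",
    "dump_yaml",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: ReconVolume, path: str | Path) -> Path:
    """Volume as 32-bit float multi-page TIFF (one page per z-slice) with the
    voxel pitch in the resolution tags and a JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(volume.amplitude.astype(np.float32), 2, 0)  # z, x, y
    px, py, pz = volume.voxel_pitch_um
    tifffile.imwrite(
        path,
        pages,
        resolution=(1e4 / px, 1e4 / py),
        resolutionunit="CENTIMETER",
        metadata={"spacing": pz, "unit": "um", "axes": "ZXY"},
    )
    meta = {
        "voxel_pitch_um": list(volume.voxel_pitch_um),
        "origin_um": list(volume.origin_um),
        "provenance": volume.provenance,
        "shape_xyz": list(volume.shape),
        "dtype": "float32",
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=str))
    return path


def read_volume(path: str | Path) -> ReconVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pages = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot parse TIFF volume {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    amplitude = np.moveaxis(pages, 0, 2)
    pitch = (2.0, 2.0, 3.0)
    origin = (0.0, 0.0, 0.0)
    provenance: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pitch = tuple(meta.get("voxel_pitch_um", pitch))
        origin = tuple(meta.get("origin_um", origin))
        provenance = meta.get("provenance", {})
        expected = tuple(meta.get("shape_xyz", amplitude.shape))
        if tuple(amplitude.shape) != expected:
            raise ValueError(
                f"TIFF shape {amplitude.shape} does not match sidecar {expected}"
            )
    return ReconVolume(amplitude, pitch, origin, provenance)


def write_mask(mask: np.ndarray, voxel_pitch_um, path: str | Path) -> Path:
    """Binary mask as 8-bit multi-page TIFF."""
    vol = ReconVolume(np.asarray(mask, dtype=np.float32), tuple(voxel_pitch_um))
    path = Path(path)
    pages = np.moveaxis((vol.amplitude > 0).astype(np.uint8) * 255, 2, 0)
    tifffile.imwrite(path, pages)
    _sidecar(path).write_text(
        json.dumps({"voxel_pitch_um": list(voxel_pitch_um)}, indent=2)
    )
    return path


def write_graph_csv(graph: VesselGraph, path: str | Path) -> Path:
    rows = []
    for i, seg in enumerate(graph.segments):
        a, b = seg.path_um[0], seg.path_um[-1]
        rows.append({
            "segment_id": i,
            "x0_um": a[0], "y0_um": a[1], "z0_um": a[2],
            "x1_um": b[0], "y1_um": b[1], "z1_um": b[2],
            "length_um": seg.length_um,
        })
    pd.DataFrame(
        rows,
        columns=["segment_id", "x0_um", "y0_um", "z0_um",
                 "x1_um", "y1_um", "z1_um", "length_um"],
    ).to_csv(path, index=False)
    return Path(path)


def read_graph_lengths(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["length_um"].to_numpy()


def write_depth_profile_csv(profile: DepthProfile, path: str | Path,
                            value_name: str = "density") -> Path:
    pd.DataFrame({
        "bin_lo_um": profile.bin_edges_um[:-1],
        "bin_hi_um": profile.bin_edges_um[1:],
        value_name: profile.values,
        "count": profile.counts,
    }).to_csv(path, index=False)
    return Path(path)


def write_rf(frames: RFFrameSet, path: str | Path) -> Path:
    """RF frames as a raw little-endian float32 array plus JSON header."""
    path = Path(path)
    data = frames.samples.astype("<f4")
    data.tofile(path)
    header = {
        "shape": list(data.shape),
        "dtype": "<f4",
        "acquisition": vars(frames.acquisition).copy(),
        "transducer": vars(frames.transducer).copy(),
        "optics": vars(frames.optics).copy(),
    }
    _sidecar(path).write_text(json.dumps(header, indent=2))
    return path


def read_rf(path: str | Path) -> RFFrameSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = json.loads(_sidecar(path).read_text())
    shape = tuple(header["shape"])
    data = np.fromfile(path, dtype=header["dtype"])
    if data.size != int(np.prod(shape)):
        raise ValueError(
            f"RF payload has {data.size} samples, header promises {shape}"
        )
    return RFFrameSet(
        data.reshape(shape).astype(np.float64),
        AcquisitionSpec(**header["acquisition"]),
        TransducerSpec(**header["transducer"]),
        OpticalSpec(**header["optics"]),
    )


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return doc or {}


def dump_yaml(doc: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
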