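"""RF-to-volume reconstruction: envelope extraction, depth mapping, filtering,
and standard projections (MAP, depth-encoded, B-scan)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import hilbert
from skimage.filters import threshold_otsu

from .forward import AcquisitionSpec, RFFrameSet

__all__ = [
    "ReconVolume",
    "extract_envelope",
    "time_to_depth",
    "assemble_volume",
    "median_filter_3d",
    "map_projection",
    "depth_encoded_projection",
    "extract_bscan",
]


@dataclass
class ReconVolume:
    """Nonnegative envelope-amplitude grid indexed (x, y, z)."""

    amplitude: np.ndarray
    voxel_pitch_um: tuple[float, float, float] = (2.0, 2.0, 3.0)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=np.float32)
        if self.amplitude.ndim != 3:
            raise ValueError("amplitude must be a 3D (x, y, z) array")
        if np.any(self.amplitude < 0):
            raise ValueError("envelope amplitude must be nonnegative")
        if any(p <= 0 for p in self.voxel_pitch_um):
            raise ValueError("voxel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.amplitude.shape

    def depth_axis_um(self) -> np.ndarray:
        return self.origin_um[2] + np.arange(self.shape[2]) * self.voxel_pitch_um[2]


def extract_envelope(rf_trace: np.ndarray) -> np.ndarray:
    """Upper envelope of an RF trace as the magnitude of the analytic signal.

    Works on the last axis of an array of any dimensionality.
    """
    rf = np.asarray(rf_trace, dtype=np.float64)
    if rf.size == 0:
        raise ValueError("cannot extract the envelope of an empty trace")
    if not np.all(np.isfinite(rf)):
        raise ValueError("RF samples must be finite")
    return np.abs(hilbert(rf, axis=-1))


def time_to_depth(sample_index, acquisition: AcquisitionSpec):
    """One-way depth (µm) of a time-sample index: depth = v * index / f_s."""
    idx = np.asarray(sample_index)
    if np.any(idx < 0):
        raise ValueError("sample index must be nonnegative")
    return idx * acquisition.depth_per_sample_um


def assemble_volume(
    frames: RFFrameSet, z_pitch_um: float | None = 3.0
) -> ReconVolume:
    """Envelope per A-line resampled onto a uniform axial lattice.

    ``z_pitch_um=None`` keeps the native v/f_s pitch (no resampling);
    otherwise linear interpolation onto the requested pitch (default 3 µm).
    """
    env = extract_envelope(frames.samples)
    native = frames.acquisition.depth_per_sample_um
    if z_pitch_um is None or abs(z_pitch_um - native) < 1e-12:
        amp = env
        pitch_z = native
    else:
        if z_pitch_um <= 0:
            raise ValueError("z pitch must be positive")
        n_t = env.shape[2]
        max_depth = (n_t - 1) * native
        n_z = int(np.floor(max_depth / z_pitch_um)) + 1
        pos = np.arange(n_z) * z_pitch_um / native
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, n_t - 1)
        w = pos - lo
        amp = env[:, :, lo] * (1.0 - w) + env[:, :, hi] * w
        pitch_z = float(z_pitch_um)
    step = frames.acquisition.lateral_step_um
    return ReconVolume(
        amplitude=amp.astype(np.float32),
        voxel_pitch_um=(step, step, pitch_z),
        provenance={
            "sampling_rate_msps": frames.acquisition.sampling_rate_msps,
            "sound_speed_m_s": frames.acquisition.sound_speed_m_s,
            "native_depth_per_sample_um": native,
        },
    )


def median_filter_3d(volume: ReconVolume, window: int = 3) -> ReconVolume:
    """Per-voxel median over an odd cubic window, replicate-padded edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    filtered = median_filter(volume.amplitude, size=window, mode="nearest")
    return ReconVolume(filtered, volume.voxel_pitch_um, volume.origin_um,
                       dict(volume.provenance, median_window=window))


def map_projection(volume: ReconVolume) -> np.ndarray:
    """Maximum amplitude projection over depth."""
    if volume.amplitude.size == 0:
        raise ValueError("cannot project an empty volume")
    return volume.amplitude.max(axis=2)


def depth_encoded_projection(
    volume: ReconVolume, amplitude_floor: float | None = None
) -> np.ndarray:
    """Per-pixel depth (µm) of the amplitude argmax over z; pixels whose MAP
    falls below ``amplitude_floor`` (default: Otsu of the MAP) are NaN."""
    mip = map_projection(volume)
    if amplitude_floor is None:
        amplitude_floor = (
            threshold_otsu(mip) if np.ptp(mip) > 0 else np.inf
        )
    if amplitude_floor < 0:
        raise ValueError("amplitude floor must be nonnegative")
    z_idx = volume.amplitude.argmax(axis=2)
    depth = volume.origin_um[2] + z_idx * volume.voxel_pitch_um[2]
    depth = depth.astype(np.float64)
    depth[mip < amplitude_floor] = np.nan
    return depth


def extract_bscan(volume: ReconVolume, scan_line: int, axis: str = "y") -> np.ndarray:
    """2D (lateral, depth) slice at a fixed y (axis='y') or x (axis='x') index."""
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    n = volume.shape[1] if axis == "y" else volume.shape[0]
    if not 0 <= scan_line < n:
        raise IndexError(f"scan line {scan_line} out of range [0, {n})")
    if axis == "y":
        return volume.amplitude[:, scan_line, :]
    return volume.amplitude[scan_line, :, :]
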