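"""Instrument forward model.

Simulates raster-scanned photoacoustic A-lines through an optically focused
excitation spot and a band-limited ultrasound transducer, plus a confocal-stack
emulator and calibration waveforms (one-way pulse, pulse-echo).

Unit conventions: depths and lateral positions in micrometres, time in
microseconds, frequencies in MHz.  A sound speed of ``v`` m/s equals ``v``
µm/µs, so depth-per-sample = v / f_s with f_s in MS/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

__all__ = [
    "TransducerSpec",
    "OpticalSpec",
    "AcquisitionSpec",
    "RFFrameSet",
    "transducer_impulse_response",
    "simulate_pa_ascan",
    "simulate_pam_stack",
    "simulate_confocal_stack",
    "simulate_pulse_echo",
]

_FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...

# Attenuation defaults follow the 1/e^2 convention I(d) = I0 * exp(-2):
# a fitted 1/e^2 depth of d µm corresponds to a coefficient k = 2/d per µm.
PAM_PENETRATION_DEPTH_UM = 431.0
LSCM_PENETRATION_DEPTH_UM = 262.0


@dataclass(frozen=True)
class TransducerSpec:
    """Band-limited ultrasound detector model.

    ``fractional_bandwidth`` is the -6 dB spectral full width divided by the
    center frequency.
    """

    center_frequency_mhz: float = 19.0
    fractional_bandwidth: float = 0.69
    focal_length_mm: float = 11.6

    def __post_init__(self) -> None:
        if self.center_frequency_mhz <= 0:
            raise ValueError("center frequency must be positive")
        if not 0.0 < self.fractional_bandwidth < 2.0:
            raise ValueError("fractional bandwidth must lie in (0, 2)")

    @property
    def bandwidth_mhz(self) -> float:
        """Absolute -6 dB bandwidth B = B_frac * f_c."""
        return self.fractional_bandwidth * self.center_frequency_mhz


@dataclass(frozen=True)
class OpticalSpec:
    """Excitation optics and per-modality depth attenuation.

    ``psf_fwhm_um`` overrides the diffraction-limited lateral PSF width when
    set; otherwise the FWHM is 0.51 * wavelength / NA.
    """

    wavelength_nm: float = 532.0
    numerical_aperture: float = 0.12
    pam_attenuation_per_um: float = 2.0 / PAM_PENETRATION_DEPTH_UM
    lscm_attenuation_per_um: float = 2.0 / LSCM_PENETRATION_DEPTH_UM
    psf_fwhm_um: float | None = None

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ValueError("numerical aperture must lie in (0, 1)")
        if self.pam_attenuation_per_um < 0 or self.lscm_attenuation_per_um < 0:
            raise ValueError("attenuation coefficients must be nonnegative")
        if self.psf_fwhm_um is not None and self.psf_fwhm_um <= 0:
            raise ValueError("psf_fwhm_um override must be positive")

    @property
    def lateral_psf_fwhm_um(self) -> float:
        if self.psf_fwhm_um is not None:
            return self.psf_fwhm_um
        return 0.51 * (self.wavelength_nm * 1e-3) / self.numerical_aperture


@dataclass(frozen=True)
class AcquisitionSpec:
    sampling_rate_msps: float = 500.0
    sound_speed_m_s: float = 1540.0
    lateral_step_um: float = 2.0
    noise_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_msps <= 0:
            raise ValueError("sampling rate must be positive")
        if self.sound_speed_m_s <= 0:
            raise ValueError("sound speed must be positive")
        if self.lateral_step_um <= 0:
            raise ValueError("lateral step must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")

    @property
    def dt_us(self) -> float:
        return 1.0 / self.sampling_rate_msps

    @property
    def depth_per_sample_um(self) -> float:
        """One-way depth advance per time sample (µm)."""
        return self.sound_speed_m_s / self.sampling_rate_msps

    def check_nyquist(self, transducer: TransducerSpec) -> None:
        limit = 2.0 * transducer.center_frequency_mhz * (
            1.0 + transducer.fractional_bandwidth / 2.0
        )
        if self.sampling_rate_msps <= limit:
            raise ValueError(
                f"sampling rate {self.sampling_rate_msps} MS/s violates Nyquist "
                f"bound {limit:.1f} MS/s for this transducer"
            )


@dataclass
class RFFrameSet:
    """Raster grid of RF A-lines: samples[scan_x, scan_y, time_index]."""

    samples: np.ndarray
    acquisition: AcquisitionSpec
    transducer: TransducerSpec
    optics: OpticalSpec

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 3:
            raise ValueError("samples must be a 3D (x, y, t) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")


def _pulse_sigma_t_us(transducer: TransducerSpec) -> float:
    # Gaussian magnitude spectrum exp(-(f-fc)^2 / (2 sigma_f^2)) has -6 dB
    # (factor 0.5) full width 2*sigma_f*sqrt(2 ln 2); set that equal to B.
    sigma_f = transducer.bandwidth_mhz / _FWHM_SIGMA
    return 1.0 / (2.0 * math.pi * sigma_f)


def transducer_impulse_response(
    transducer: TransducerSpec, acquisition: AcquisitionSpec
) -> np.ndarray:
    """Zero-phase Gaussian-envelope bandpass pulse sampled at f_s.

    Carrier at the center frequency; the Gaussian spectral envelope has a
    -6 dB full width of ``B_frac * f_c``.  Peak amplitude 1 at the center
    sample; the returned array has odd length.
    """
    acquisition.check_nyquist(transducer)
    sigma_t = _pulse_sigma_t_us(transducer)
    half = int(math.ceil(5.0 * sigma_t / acquisition.dt_us))
    t = np.arange(-half, half + 1) * acquisition.dt_us
    envelope = np.exp(-0.5 * (t / sigma_t) ** 2)
    return envelope * np.cos(2.0 * math.pi * transducer.center_frequency_mhz * t)


def _deposit_to_time_axis(
    p0: np.ndarray, dz_um: float, acquisition: AcquisitionSpec, n_samples: int
) -> np.ndarray:
    """Linearly split depth-sampled sources onto the RF time grid (last axis)."""
    nz = p0.shape[-1]
    pos = np.arange(nz) * dz_um / acquisition.depth_per_sample_um
    lo = np.floor(pos).astype(int)
    w_hi = pos - lo
    out = np.zeros(p0.shape[:-1] + (n_samples,), dtype=np.float64)
    valid_lo = lo < n_samples
    valid_hi = (lo + 1) < n_samples
    np.add.at(
        out.reshape(-1, n_samples),
        (slice(None), lo[valid_lo]),
        (p0[..., valid_lo] * (1.0 - w_hi[valid_lo])).reshape(-1, valid_lo.sum()),
    )
    np.add.at(
        out.reshape(-1, n_samples),
        (slice(None), lo[valid_hi] + 1),
        (p0[..., valid_hi] * w_hi[valid_hi]).reshape(-1, valid_hi.sum()),
    )
    return out


def _n_samples_for_depth(depth_um: float, acquisition: AcquisitionSpec, pad: int) -> int:
    return int(math.ceil(depth_um / acquisition.depth_per_sample_um)) + pad


def simulate_pa_ascan(
    absorber_line: np.ndarray,
    dz_um: float,
    optics: OpticalSpec,
    transducer: TransducerSpec,
    acquisition: AcquisitionSpec,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One RF A-line from a depth profile of relative absorption.

    Initial pressure p0(z) = absorber(z) * exp(-k_pam * z); one-way arrival
    time t = z / v; the source train is convolved with the transducer impulse
    response.  Deterministic when ``noise_sigma`` is zero.
    """
    profile = np.asarray(absorber_line, dtype=np.float64)
    if profile.ndim != 1:
        raise ValueError("absorber_line must be 1D")
    if dz_um <= 0:
        raise ValueError("dz_um must be positive")
    if n_samples is None:
        n_samples = _n_samples_for_depth(profile.size * dz_um, acquisition, pad=32)
    if profile.size == 0:
        return np.zeros(n_samples)
    z = np.arange(profile.size) * dz_um
    p0 = profile * np.exp(-optics.pam_attenuation_per_um * z)
    trace = _deposit_to_time_axis(p0[None, :], dz_um, acquisition, n_samples)[0]
    h = transducer_impulse_response(transducer, acquisition)
    rf = fftconvolve(trace, h, mode="same")
    if acquisition.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(acquisition.rng_seed)
        rf = rf + rng.normal(0.0, acquisition.noise_sigma, size=rf.shape)
    return rf


def _blur_lateral(absorber: np.ndarray, pitch_xy_um: tuple[float, float],
                  fwhm_um: float) -> np.ndarray:
    sigma_x = fwhm_um / _FWHM_SIGMA / pitch_xy_um[0]
    sigma_y = fwhm_um / _FWHM_SIGMA / pitch_xy_um[1]
    return gaussian_filter(absorber.astype(np.float64), sigma=(sigma_x, sigma_y, 0.0))


def simulate_pam_stack(
    phantom,
    optics: OpticalSpec,
    transducer: TransducerSpec,
    acquisition: AcquisitionSpec,
) -> RFFrameSet:
    """Raster-scan a phantom: lateral Gaussian blur per z-slice, then an
    A-line per scan position at ``lateral_step_um`` pitch."""
    absorber = np.asarray(phantom.absorber, dtype=np.float64)
    pitch = tuple(float(p) for p in phantom.spec.voxel_pitch_um)
    step_x = acquisition.lateral_step_um / pitch[0]
    step_y = acquisition.lateral_step_um / pitch[1]
    for step, name in ((step_x, "x"), (step_y, "y")):
        if abs(step - round(step)) > 1e-9 or round(step) < 1:
            raise ValueError(
                f"lateral step {acquisition.lateral_step_um} µm is not a positive "
                f"integer multiple of the phantom {name} pitch"
            )
    step_x, step_y = int(round(step_x)), int(round(step_y))
    if absorber.shape[0] < step_x or absorber.shape[1] < step_y:
        raise ValueError("phantom smaller than one scan step")
    acquisition.check_nyquist(transducer)

    blurred = _blur_lateral(absorber, (pitch[0], pitch[1]), optics.lateral_psf_fwhm_um)
    scanned = blurred[::step_x, ::step_y, :]
    z = np.arange(absorber.shape[2]) * pitch[2]
    p0 = scanned * np.exp(-optics.pam_attenuation_per_um * z)

    n_samples = _n_samples_for_depth(absorber.shape[2] * pitch[2], acquisition, pad=32)
    traces = _deposit_to_time_axis(p0, pitch[2], acquisition, n_samples)
    h = transducer_impulse_response(transducer, acquisition)
    rf = fftconvolve(traces, h[None, None, :], mode="same", axes=2)
    if acquisition.noise_sigma > 0:
        rng = np.random.default_rng(acquisition.rng_seed)
        rf = rf + rng.normal(0.0, acquisition.noise_sigma, size=rf.shape)
    return RFFrameSet(rf, acquisition, transducer, optics)


def simulate_confocal_stack(
    phantom,
    optics: OpticalSpec,
    acquisition: AcquisitionSpec,
):
    """Confocal-style intensity stack: blurred absorber attenuated by the
    steeper double-pass coefficient, no RF stage.  Returns a ReconVolume."""
    from .recon import ReconVolume  # local import avoids a module cycle

    absorber = np.asarray(phantom.absorber, dtype=np.float64)
    pitch = tuple(float(p) for p in phantom.spec.voxel_pitch_um)
    blurred = _blur_lateral(absorber, (pitch[0], pitch[1]), optics.lateral_psf_fwhm_um)
    z = np.arange(absorber.shape[2]) * pitch[2]
    intensity = blurred * np.exp(-optics.lscm_attenuation_per_um * z)
    if acquisition.noise_sigma > 0:
        rng = np.random.default_rng(acquisition.rng_seed)
        intensity = intensity + rng.normal(0.0, acquisition.noise_sigma,
                                           size=intensity.shape)
    intensity = np.clip(intensity, 0.0, None)
    return ReconVolume(
        amplitude=intensity.astype(np.float32),
        voxel_pitch_um=pitch,
        provenance={"modality": "lscm",
                    "lscm_attenuation_per_um": optics.lscm_attenuation_per_um},
    )


def simulate_pulse_echo(
    transducer: TransducerSpec, acquisition: AcquisitionSpec
) -> np.ndarray:
    """Two-way waveform: the impulse response convolved with itself,
    normalized to unit peak."""
    h = transducer_impulse_response(transducer, acquisition)
    echo = fftconvolve(h, h, mode="full")
    return echo / np.max(np.abs(echo))
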