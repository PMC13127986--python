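"""Theta-gamma phase-amplitude coupling via the phase-locking value.

Pipeline per channel: band-pass the raw trace in the phase band (theta)
and take its analytic (Hilbert) phase; band-pass in the amplitude band
(gamma), take the analytic amplitude envelope, band-pass the envelope in
the phase band, and take the envelope's analytic phase.  The phase
differences between the two phase series are mapped to unit phasors; the
modulus of their mean is the phase-locking value (mean vector length,
0 = no locking, 1 = perfect locking) and its argument is the preferred
coupling phase.

The envelope is band-pass filtered in the phase band before its Hilbert
phase is taken: without removing the envelope's large DC component its
instantaneous phase is ill-defined.

An edge margin (default 1 s) is trimmed from both ends of every filtered
series before phase statistics, suppressing filter transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .io_formats import LfpRecording
from .preprocess import Band, EDGE_MARGIN_S, THETA, bandpass_array

__all__ = [
    "PacResult",
    "analytic_phase",
    "amplitude_envelope",
    "plv_pac",
    "plv_from_phases",
    "shuffle_null",
]


@dataclass
class PacResult:
    """Coupling strength and preferred phase for one band pair.

    ``plv`` is the mean resultant length in [0, 1]; ``mean_phase`` the
    circular mean of the phase differences in (-pi, pi].  For multichannel
    recordings ``plv`` is the arithmetic mean of per-electrode values (the
    per-animal convention when both electrodes are valid) and the
    per-electrode results are kept in ``per_channel``.
    """

    plv: float
    mean_phase: float
    phase_band: Band
    amp_band: Band
    n_samples: int
    per_channel: list["PacResult"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.plv <= 1.0 + 1e-12:
            raise ValueError(f"plv must lie in [0, 1], got {self.plv}")


def analytic_phase(band_signal: np.ndarray) -> np.ndarray:
    """Instantaneous phase (rad) of a band-limited series.

    The phase is the argument of the analytic (Hilbert) signal; callers
    exclude the edge margin downstream.  A constant input has no defined
    phase and raises.
    """
    x = np.asarray(band_signal, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("phase of a constant signal is undefined")
    return np.angle(hilbert(x))


def amplitude_envelope(band_signal: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude: modulus of the analytic signal."""
    return np.abs(hilbert(np.asarray(band_signal, dtype=float)))


def plv_from_phases(phase_a: np.ndarray, phase_b: np.ndarray) -> tuple[float, float]:
    """Mean vector length and circular mean of the phase differences
    ``phase_a - phase_b``."""
    z = np.exp(1j * (np.asarray(phase_a) - np.asarray(phase_b))).mean()
    return float(np.abs(z)), float(np.angle(z))


def _channel_pac(x: np.ndarray, fs: float, phase_band: Band, amp_band: Band,
                 order: int, margin: int) -> tuple[float, float, int]:
    low = bandpass_array(x, fs, phase_band, order)
    high = bandpass_array(x, fs, amp_band, order)
    env = amplitude_envelope(high)
    env_f = bandpass_array(env, fs, phase_band, order)
    phi_low = analytic_phase(low)
    phi_env = analytic_phase(env_f)
    if margin:
        phi_low = phi_low[margin:-margin]
        phi_env = phi_env[margin:-margin]
    plv, mean_phase = plv_from_phases(phi_low, phi_env)
    return plv, mean_phase, len(phi_low)


def plv_pac(
    rec: LfpRecording,
    amp_band: Band,
    phase_band: Band = THETA,
    order: int = 4,
    margin_s: float = EDGE_MARGIN_S,
) -> PacResult:
    """Phase-locking value between *phase_band* phase and *amp_band* amplitude.

    Requires at least 10 phase-band cycles after edge trimming.  For a
    multichannel recording the reported ``plv`` is the arithmetic mean of
    per-electrode PLVs and ``mean_phase`` the PLV-weighted circular mean of
    per-electrode preferred phases.
    """
    margin = int(round(margin_s * rec.fs))
    n_eff = rec.n_samples - 2 * margin
    min_samples = 10.0 / phase_band.f_lo * rec.fs
    if n_eff < min_samples:
        raise ValueError(
            f"epoch too short: {max(n_eff, 0) / rec.fs:.2f} s after trimming, "
            f"need >= {10.0 / phase_band.f_lo:.2f} s "
            f"(10 cycles at {phase_band.f_lo} Hz)"
        )
    per_channel = []
    for c in range(rec.n_channels):
        plv, mean_phase, n = _channel_pac(
            rec.samples[c], rec.fs, phase_band, amp_band, order, margin)
        per_channel.append(PacResult(plv, mean_phase, phase_band, amp_band, n))
    if len(per_channel) == 1:
        return per_channel[0]
    mean_plv = float(np.mean([r.plv for r in per_channel]))
    z = np.sum([r.plv * np.exp(1j * r.mean_phase) for r in per_channel])
    return PacResult(mean_plv, float(np.angle(z)), phase_band, amp_band,
                     per_channel[0].n_samples, per_channel)


def shuffle_null(
    rec: LfpRecording,
    amp_band: Band,
    phase_band: Band = THETA,
    n_shuffles: int = 100,
    order: int = 4,
    margin_s: float = EDGE_MARGIN_S,
    seed: int = 0,
    channel: int = 0,
) -> np.ndarray:
    """Optional diagnostic: PLV distribution under circularly shifted
    envelopes (breaks the phase-envelope alignment, keeps both spectra)."""
    fs = rec.fs
    margin = int(round(margin_s * fs))
    x = rec.samples[channel]
    low = bandpass_array(x, fs, phase_band, order)
    high = bandpass_array(x, fs, amp_band, order)
    env = amplitude_envelope(high)
    phi_low = analytic_phase(low)[margin:-margin]
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shift = int(rng.integers(margin, len(env) - margin))
        env_s = np.roll(env, shift)
        env_f = bandpass_array(env_s, fs, phase_band, order)
        phi_env = analytic_phase(env_f)[margin:-margin]
        out[i], _ = plv_from_phases(phi_low, phi_env)
    return out
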