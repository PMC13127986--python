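"""Synthetic LFP and trajectory generators with known ground truth.

The LFP model is a theta sinusoid plus one or more gamma sinusoids whose
instantaneous amplitude is modulated by theta phase,

    g(t) = A_g * (1 + kappa * cos(phi_theta(t) - psi0)) / sqrt(1 + kappa^2/2) * sin(2*pi*f_g*t),

plus pink background noise (spectrally shaped white noise, 1/f power
profile above 1 Hz to match a 1 Hz hardware high-pass) and a 50 Hz
line-noise family.  ``kappa`` in [0, 1] is the programmed coupling
strength; dividing the envelope by its RMS ``sqrt(1 + kappa^2/2)`` keeps
mean gamma power exactly kappa-invariant, so power and coupling effects
stay independently controllable.  ``phi_theta`` is the analytic (Hilbert) phase of the theta
component, so a downstream phase-amplitude coupling estimate recovers
``psi0`` directly.

Trajectories come from an Ornstein-Uhlenbeck velocity process reflected at
the enclosure bounds, with an optional drift away from a room-frame sector
(the avoidance agent) and two degenerate modes: a point fixed in the room,
and a point fixed on the rotating disc expressed in room coordinates.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import LfpRecording, Trajectory

__all__ = [
    "LfpSimParams",
    "GammaComponent",
    "WalkParams",
    "Bounds",
    "CohortSpec",
    "generate_coupled_lfp",
    "generate_cohort",
    "generate_walk",
    "replica_cohort_spec",
    "null_cohort_spec",
]


@dataclass(frozen=True)
class GammaComponent:
    """One theta-modulated gamma oscillator."""

    f: float            # Hz, within 30-100
    amp: float          # µV
    kappa: float = 0.0  # coupling strength in [0, 1]
    psi0: float = 0.0   # preferred theta phase of the amplitude peak (rad)

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if not 30.0 <= self.f <= 100.0:
            raise ValueError(f"gamma frequency must be in 30-100 Hz, got {self.f}")


@dataclass
class LfpSimParams:
    """Parameters of a single theta-gamma coupled LFP channel."""

    duration: float                # s
    fs: float = 2000.0             # Hz
    f_theta: float = 7.0           # Hz, within 4-10
    A_theta: float = 50.0          # µV
    f_gamma: float = 75.0          # Hz, within 30-100
    A_gamma: float = 15.0          # µV
    kappa: float = 0.5
    psi0: float = 0.0              # rad
    pink_sigma: float = 30.0       # µV (std of the background noise)
    line_amp: tuple[float, ...] = (5.0, 2.0, 1.0)  # 50, 100, 150 Hz ... µV
    theta_jitter: float = 0.0      # rad^2/s theta phase diffusion (0 = pure tone)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if not 4.0 <= self.f_theta <= 10.0:
            raise ValueError(f"f_theta must be in 4-10 Hz, got {self.f_theta}")
        if not 30.0 <= self.f_gamma <= 100.0:
            raise ValueError(f"f_gamma must be in 30-100 Hz, got {self.f_gamma}")
        f_max = max(self.f_gamma, 50.0 * len(self.line_amp) if self.line_amp else 0.0)
        if self.fs <= 2.0 * f_max:
            raise ValueError(
                f"fs={self.fs} Hz aliases content at {f_max} Hz (need fs > {2 * f_max})"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _pink_noise(n: int, fs: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Shaped white noise with a 1/f power profile above 1 Hz."""
    if sigma == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(freqs)
    above = freqs >= 1.0
    shape[above] = 1.0 / np.sqrt(freqs[above])
    spec *= shape
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (sigma / sd) if sd > 0 else x


def _synthesize_channel(
    fs: float,
    duration: float,
    f_theta: float,
    A_theta: float,
    components: list[GammaComponent],
    pink_sigma: float,
    line_amp: tuple[float, ...],
    rng: np.random.Generator,
    theta_jitter: float = 0.0,
) -> np.ndarray:
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    # slow phase diffusion emulates the frequency wander of real theta
    if theta_jitter > 0:
        wander = np.cumsum(rng.standard_normal(n) * np.sqrt(theta_jitter / fs))
    else:
        wander = 0.0
    # analytic phase of sin(w t + W) is w t + W - pi/2 for slow W
    phi_theta = 2.0 * np.pi * f_theta * t + wander - np.pi / 2.0
    x = A_theta * np.sin(phi_theta + np.pi / 2.0)
    for c in components:
        env = (c.amp * (1.0 + c.kappa * np.cos(phi_theta - c.psi0))
               / np.sqrt(1.0 + c.kappa**2 / 2.0))
        x = x + env * np.sin(2.0 * np.pi * c.f * t)
    x = x + _pink_noise(n, fs, pink_sigma, rng)
    for k, amp in enumerate(line_amp, start=1):
        if amp:
            x = x + amp * np.sin(2.0 * np.pi * 50.0 * k * t + rng.uniform(0, 2 * np.pi))
    return x


def generate_coupled_lfp(params: LfpSimParams) -> LfpRecording:
    """Generate a single-channel theta-gamma coupled LFP recording.

    Deterministic for a fixed ``params.seed``; the declared coupling holds
    by construction (the gamma envelope is exactly
    ``A_gamma*(1 + kappa*cos(phi_theta - psi0))/(1 + kappa)``).
    """
    rng = np.random.default_rng(params.seed)
    comp = GammaComponent(params.f_gamma, params.A_gamma, params.kappa, params.psi0)
    x = _synthesize_channel(
        params.fs, params.duration, params.f_theta, params.A_theta,
        [comp], params.pink_sigma, params.line_amp, rng,
        theta_jitter=params.theta_jitter,
    )
    meta = {"generator": "generate_coupled_lfp", "seed": params.seed,
            "params": asdict(params)}
    return LfpRecording(["sim0"], x[np.newaxis, :], params.fs, 0.0, meta)


# ---------------------------------------------------------------------------
# Cohorts

@dataclass
class CohortSpec:
    """A multi-animal, two-epoch (baseline / post-injection) cohort design.

    Each animal gets parameters drawn once (lognormal between-animal
    variability on amplitudes and noise) and shared between its baseline
    and post epochs; per-group multipliers for low/high-gamma band power
    and coupling strength apply only in the post epoch.  Multiplier keys:
    ``low_gamma_power``, ``high_gamma_power``, ``kappa`` (power multipliers
    act on power, i.e. amplitude is scaled by their square root).

    ``between_sigma`` scales every animal's amplitudes once (stable
    individual differences, cancelled by baseline normalisation);
    ``within_sigma`` jitters each epoch's amplitudes independently
    (state/electrode drift between recordings — the variance that the
    percent-of-baseline statistics actually see).
    """

    groups: list[tuple[str, int]]
    multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    between_sigma: float = 0.2        # lognormal sigma on amplitudes
    within_sigma: float = 0.08        # lognormal sigma per epoch
    window_duration: float = 60.0     # s per epoch
    fs: float = 2000.0
    f_theta: float = 7.0
    A_theta: float = 50.0
    f_low_gamma: float = 40.0
    A_low_gamma: float = 20.0
    kappa_low: float = 0.3
    f_high_gamma: float = 75.0
    A_high_gamma: float = 15.0
    kappa_high: float = 0.6
    psi0: float = 0.0
    pink_sigma: float = 30.0
    line_amp: tuple[float, ...] = (5.0, 2.0, 1.0)
    n_channels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        for label, n in self.groups:
            if n < 1:
                raise ValueError(f"group {label!r} needs n_animals >= 1, got {n}")
        for label, mult in self.multipliers.items():
            for key, val in mult.items():
                if val <= 0:
                    raise ValueError(f"multiplier {key}={val} for {label!r} must be > 0")

    def group_multipliers(self, label: str) -> dict[str, float]:
        base = {"low_gamma_power": 1.0, "high_gamma_power": 1.0, "kappa": 1.0}
        base.update(self.multipliers.get(label, {}))
        return base


@dataclass
class CohortAnimal:
    """One simulated animal: baseline and post epochs plus ground truth."""

    animal: str
    group: str
    baseline: LfpRecording
    post: LfpRecording
    truth: dict


def generate_cohort(spec: CohortSpec) -> tuple[list[CohortAnimal], pd.DataFrame]:
    """Simulate every animal of a cohort.

    Returns the per-animal recordings and a tidy ground-truth table (one
    row per animal with the realised amplitudes, couplings and group
    multipliers) for generator-level oracle checks.
    """
    master = np.random.default_rng(spec.seed)
    animals: list[CohortAnimal] = []
    rows = []
    for g_label, n in spec.groups:
        mult = spec.group_multipliers(g_label)
        for i in range(n):
            a_seed = int(master.integers(0, 2**31 - 1))
            a_rng = np.random.default_rng(a_seed)
            scale = float(np.exp(a_rng.normal(0.0, spec.between_sigma)))
            A_th = spec.A_theta * scale
            A_lg = spec.A_low_gamma * scale
            A_hg = spec.A_high_gamma * scale
            sigma = spec.pink_sigma * scale
            k_lo = spec.kappa_low
            k_hi = spec.kappa_high
            epochs = {}
            for epoch in ("baseline", "post"):
                drift = np.exp(a_rng.normal(0.0, spec.within_sigma, size=2))
                if epoch == "post":
                    a_lg = A_lg * np.sqrt(mult["low_gamma_power"]) * drift[0]
                    a_hg = A_hg * np.sqrt(mult["high_gamma_power"]) * drift[1]
                    kk_lo = min(1.0, k_lo * mult["kappa"])
                    kk_hi = min(1.0, k_hi * mult["kappa"])
                else:
                    a_lg, a_hg = A_lg * drift[0], A_hg * drift[1]
                    kk_lo, kk_hi = k_lo, k_hi
                comps = [
                    GammaComponent(spec.f_low_gamma, a_lg, kk_lo, spec.psi0),
                    GammaComponent(spec.f_high_gamma, a_hg, kk_hi, spec.psi0),
                ]
                chans = [
                    _synthesize_channel(
                        spec.fs, spec.window_duration, spec.f_theta, A_th,
                        comps, sigma, spec.line_amp, a_rng,
                    )
                    for _ in range(spec.n_channels)
                ]
                epochs[epoch] = LfpRecording(
                    [f"ch{c}" for c in range(spec.n_channels)],
                    np.vstack(chans), spec.fs, 0.0,
                    {"generator": "generate_cohort", "epoch": epoch,
                     "group": g_label, "animal_seed": a_seed},
                )
            name = f"{g_label}_{i:02d}"
            animals.append(CohortAnimal(name, g_label, epochs["baseline"],
                                        epochs["post"], {
                "scale": scale, "A_theta": A_th, "A_low_gamma": A_lg,
                "A_high_gamma": A_hg, "kappa_low": k_lo, "kappa_high": k_hi,
                **{f"mult_{k}": v for k, v in mult.items()},
            }))
            rows.append({"animal": name, "group": g_label, "seed": a_seed,
                         **animals[-1].truth})
    return animals, pd.DataFrame(rows)


def replica_cohort_spec(
    seed: int = 0,
    n_per_group: int = 7,
    kappa_multiplier: float = 0.25,
    low_gamma_multiplier: float = 2.0,
    window_duration: float = 60.0,
) -> CohortSpec:
    """Two-group cohort encoding the qualitative treatment effects:
    reduced theta-high-gamma coupling and elevated low-gamma power in the
    treated ("MK") group versus saline ("SAL").

    The programmed effect sizes are free design parameters (the emulated
    findings are reported only as significance statements, not magnitudes).
    The defaults quadruple-reduce the coupling and double the low-gamma
    oscillation power; after dilution by the pink background inside the
    30-55 Hz band the latter lands near a +70 % baseline-normalised change.
    """
    return CohortSpec(
        groups=[("SAL", n_per_group), ("MK", n_per_group)],
        multipliers={"MK": {"kappa": kappa_multiplier,
                            "low_gamma_power": low_gamma_multiplier}},
        window_duration=window_duration,
        seed=seed,
    )


def null_cohort_spec(seed: int = 0, n_per_group: int = 7,
                     window_duration: float = 60.0) -> CohortSpec:
    """Two-group cohort with all multipliers at 1 (no true effect)."""
    return CohortSpec(
        groups=[("SAL", n_per_group), ("MK", n_per_group)],
        multipliers={},
        window_duration=window_duration,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Trajectories

@dataclass(frozen=True)
class Bounds:
    """Enclosure geometry: a square box of side ``size`` or a disc of
    radius ``size``, both centered on the origin."""

    kind: str   # "box" or "disc"
    size: float  # cm: box side, or disc radius

    def __post_init__(self) -> None:
        if self.kind not in ("box", "disc"):
            raise ValueError(f"bounds kind must be 'box' or 'disc', got {self.kind!r}")
        if self.size <= 0:
            raise ValueError("bounds size must be positive")


@dataclass
class WalkParams:
    """Parameters of the synthetic locomotion model."""

    mean_speed: float = 10.0          # cm/s
    persistence: float = 1.0          # s, velocity correlation time
    bounds: Bounds = field(default_factory=lambda: Bounds("box", 70.0))
    avoidance_gain: float = 0.0       # cm/s^2 drift away from the sector
    mode: str = "stochastic"          # stochastic | stationary_room | stationary_arena
    sector_center_deg: float = 0.0    # room-frame azimuth of avoided sector
    sector_halfwidth_deg: float = 30.0
    rotation_period: float = 60.0     # s (for stationary_arena)
    rotation_ccw: bool = True
    start_xy: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be >= 0")
        if self.persistence <= 0:
            raise ValueError("persistence must be positive")
        if self.mode not in ("stochastic", "stationary_room", "stationary_arena"):
            raise ValueError(f"unknown walk mode {self.mode!r}")


def _default_start(bounds: Bounds, rng: np.random.Generator) -> np.ndarray:
    if bounds.kind == "box":
        half = bounds.size / 2.0
        return rng.uniform(-half * 0.8, half * 0.8, size=2)
    r = bounds.size * 0.6 * np.sqrt(rng.uniform())
    phi = rng.uniform(0, 2 * np.pi)
    return np.array([r * np.cos(phi), r * np.sin(phi)])


def _reflect(pos: np.ndarray, vel: np.ndarray, bounds: Bounds) -> None:
    """Reflect position/velocity at the enclosure boundary, in place."""
    if bounds.kind == "box":
        half = bounds.size / 2.0
        for d in range(2):
            if pos[d] > half:
                pos[d] = 2 * half - pos[d]
                vel[d] = -vel[d]
            elif pos[d] < -half:
                pos[d] = -2 * half - pos[d]
                vel[d] = -vel[d]
            pos[d] = np.clip(pos[d], -half, half)
    else:
        r = float(np.hypot(pos[0], pos[1]))
        if r > bounds.size:
            u = pos / r
            pos[:] = u * (2 * bounds.size - r)
            v_rad = float(vel @ u)
            vel -= 2 * v_rad * u
            r2 = float(np.hypot(pos[0], pos[1]))
            if r2 > bounds.size:
                pos[:] = pos / r2 * bounds.size


def _wrap_deg(a: np.ndarray | float) -> np.ndarray | float:
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def generate_walk(params: WalkParams, duration: float, dt: float) -> Trajectory:
    """Simulate a room-frame trajectory.

    ``stochastic`` integrates an Ornstein-Uhlenbeck velocity process whose
    stationary speed distribution has mean ``mean_speed``, reflected at the
    bounds; when ``avoidance_gain > 0`` a tangential drift pushes the agent
    out of the (15 deg dilated) room-frame sector.  ``stationary_room`` is
    a fixed point; ``stationary_arena`` is a disc-fixed point carried by the
    arena rotation and expressed in room coordinates.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(params.seed)
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    start = (np.array(params.start_xy, dtype=float) if params.start_xy is not None
             else _default_start(params.bounds, rng))

    if params.mode == "stationary_room":
        x = np.full(n, start[0])
        y = np.full(n, start[1])
        return Trajectory(t, x, y, frame="room")

    if params.mode == "stationary_arena":
        sign = 1.0 if params.rotation_ccw else -1.0
        theta = sign * 2.0 * np.pi * t / params.rotation_period
        x = start[0] * np.cos(theta) - start[1] * np.sin(theta)
        y = start[0] * np.sin(theta) + start[1] * np.cos(theta)
        return Trajectory(t, x, y, frame="room")

    # OU velocity: per-component stationary std sigma_v gives mean speed
    # sigma_v * sqrt(pi/2) for a 2-D Gaussian velocity.
    sigma_v = params.mean_speed / np.sqrt(np.pi / 2.0)
    tau = params.persistence
    xs = np.empty((n, 2))
    pos = start.copy()
    vel = rng.standard_normal(2) * sigma_v if sigma_v > 0 else np.zeros(2)
    xs[0] = pos
    dilate = params.sector_halfwidth_deg + 15.0
    for i in range(1, n):
        drift = np.zeros(2)
        if params.avoidance_gain > 0:
            az = np.degrees(np.arctan2(pos[1], pos[0]))
            dphi = float(_wrap_deg(az - params.sector_center_deg))
            if abs(dphi) < dilate:
                r = max(float(np.hypot(pos[0], pos[1])), 1e-9)
                tang = np.array([-pos[1], pos[0]]) / r  # ccw tangential unit
                away = np.sign(dphi) if dphi != 0 else (1.0 if rng.uniform() < 0.5 else -1.0)
                drift = params.avoidance_gain * away * tang
        if sigma_v > 0:
            vel = (vel + (-vel / tau + drift) * dt
                   + sigma_v * np.sqrt(2.0 * dt / tau) * rng.standard_normal(2))
        pos = pos + vel * dt
        _reflect(pos, vel, params.bounds)
        xs[i] = pos
    return Trajectory(t, xs[:, 0], xs[:, 1], frame="room")


def spec_to_json(spec) -> str:
    """Stable JSON serialisation of a generator spec (for provenance)."""
    d = asdict(spec)
    return json.dumps(d, sort_keys=True, default=str)
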