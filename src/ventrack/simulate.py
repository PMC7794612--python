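"""Virtual aquarium: ground-truth fish behaviour and electrode-array rendering.

No public recordings exist for the bottom-array ventilatory-signal setup, so
this module generates them.  A fish is a correlated random walk whose speed,
freezing bouts, darts and instantaneous ventilation (opercular) frequency are
controlled by per-emotional-state :class:`BehaviourParams`.  The walk can be
rendered into a 126-channel recording: each electrode carries a sinusoid at
the running ventilation phase whose amplitude decays with distance to the
fish (Gaussian kernel, length-scale one electrode pitch), plus optional white
Gaussian noise.

Three behavioural programmes are provided, calibrated so that the six
evaluation indices separate the states in the directions reported for live
fish:

``normal``
    smooth open-field cruising (Ornstein--Uhlenbeck speed, rare brief stops),
    ventilation ~2.6 Hz with moderate drift.
``fear``
    freeze-dominated: long immobile bouts with occasional darting, low speed,
    elevated (~3.0 Hz) and stabilised ventilation.
``appetitive``
    a mixture of fast cruising and multi-second station-holding (high
    within-window variability of speed and stopping), ventilation at the
    normal rate but with a markedly stabilised rhythm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .arena import ArenaGeometry, default_arena

__all__ = [
    "STATES",
    "BehaviourParams",
    "GroundTruthTrajectory",
    "ElectrodeArrayRecording",
    "FishPlan",
    "CohortConfig",
    "default_params",
    "default_cohort_config",
    "simulate_trajectory",
    "render_signals",
    "generate_cohort",
]

STATES = ("normal", "fear", "appetitive")

#: trajectory simulation rate (Hz); signals are rendered at f_s = 1000 Hz
TRAJ_RATE = 50.0


@dataclass(frozen=True)
class BehaviourParams:
    """State-specific behaviour programme.

    Speeds in mm/s, rates in 1/s, durations in s, frequencies in Hz.
    ``heading_persistence`` in [0, 1): 1 means a straight swimmer.
    A ``freeze_duration`` at least as long as the simulated duration pins the
    fish for the whole run (degenerate always-frozen configuration).
    """

    state: str
    mean_speed: float
    speed_sd: float
    speed_tau: float
    freeze_rate: float
    freeze_duration: float
    dart_rate: float
    dart_speed: float
    dart_duration: float
    vent_base_freq: float
    vent_freq_sd: float
    vent_tau: float
    heading_persistence: float

    def __post_init__(self) -> None:
        for name in (
            "mean_speed", "speed_sd", "freeze_rate", "freeze_duration",
            "dart_rate", "dart_speed", "dart_duration", "vent_freq_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (1.0 < self.vent_base_freq < 10.0):
            raise ValueError("vent_base_freq must lie inside the 1-10 Hz pass band")
        if not (0.0 <= self.heading_persistence < 1.0):
            raise ValueError("heading_persistence must be in [0, 1)")


_DEFAULTS = {
    "normal": BehaviourParams(
        state="normal", mean_speed=22.0, speed_sd=8.0, speed_tau=5.0,
        freeze_rate=0.05, freeze_duration=0.7,
        dart_rate=0.0, dart_speed=60.0, dart_duration=0.3,
        vent_base_freq=2.6, vent_freq_sd=0.45, vent_tau=2.0,
        heading_persistence=0.88,
    ),
    "fear": BehaviourParams(
        state="fear", mean_speed=9.0, speed_sd=2.0, speed_tau=3.0,
        freeze_rate=0.15, freeze_duration=2.5,
        dart_rate=0.02, dart_speed=80.0, dart_duration=0.3,
        vent_base_freq=3.0, vent_freq_sd=0.22, vent_tau=2.0,
        heading_persistence=0.6,
    ),
    "appetitive": BehaviourParams(
        state="appetitive", mean_speed=32.0, speed_sd=8.0, speed_tau=5.0,
        freeze_rate=0.06, freeze_duration=8.0,
        dart_rate=0.03, dart_speed=70.0, dart_duration=0.3,
        vent_base_freq=2.6, vent_freq_sd=0.14, vent_tau=2.0,
        heading_persistence=0.8,
    ),
}


def default_params(state: str) -> BehaviourParams:
    """Calibrated default behaviour programme for one emotional state."""
    try:
        return _DEFAULTS[state]
    except KeyError:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}") from None


@dataclass(eq=False)
class GroundTruthTrajectory:
    """Simulated fish ground truth at the trajectory rate."""

    t: np.ndarray            # (n,) s
    xy: np.ndarray           # (n, 2) mm
    v: np.ndarray            # (n, 2) mm/s, discrete derivative of xy
    fv: np.ndarray           # (n,) Hz, instantaneous ventilation frequency
    state: np.ndarray        # (n,) state label per sample
    fish_id: str
    arena: ArenaGeometry

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.v[:, 0], self.v[:, 1])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def rate(self) -> float:
        return float(1.0 / (self.t[1] - self.t[0]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.xy[:, 0], "y": self.xy[:, 1],
                "vx": self.v[:, 0], "vy": self.v[:, 1],
                "fv": self.fv, "state": self.state,
                "fish_id": self.fish_id,
            }
        )


@dataclass(eq=False)
class ElectrodeArrayRecording:
    """Multichannel recording: channels x time, plus geometry and rate."""

    samples: np.ndarray      # (L, T)
    fs: float
    arena: ArenaGeometry
    truth: GroundTruthTrajectory | None = None
    band: tuple[float, float] | None = None  # set once band-pass filtered

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if self.samples.shape[0] != self.arena.n_electrodes:
            raise ValueError("channel count must equal the electrode count")

    @property
    def n_channels(self) -> int:
        return int(self.samples.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[1])

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _ou_series(n: int, dt: float, mean: float, sd: float, tau: float,
               rng: np.random.Generator) -> np.ndarray:
    """Exact discretisation of an Ornstein-Uhlenbeck process (stationary init)."""
    if sd == 0.0 or tau <= 0.0:
        return np.full(n, mean)
    a = math.exp(-dt / tau)
    innov = rng.standard_normal(n) * (sd * math.sqrt(1.0 - a * a))
    innov[0] = rng.standard_normal() * sd
    x = lfilter([1.0], [1.0, -a], innov)
    return mean + x


def _bout_mask(n: int, dt: float, duration: float, params: BehaviourParams,
               rng: np.random.Generator) -> np.ndarray:
    """Boolean freeze mask from an alternating move/freeze renewal process."""
    if params.freeze_rate <= 0.0 or params.freeze_duration <= 0.0:
        return np.zeros(n, dtype=bool)
    if params.freeze_duration >= duration:
        # documented degenerate convention: the fish never moves
        return np.ones(n, dtype=bool)
    mask = np.zeros(n, dtype=bool)
    t, frozen = 0.0, False
    # start in the stationary mixture of the alternating renewal process
    p_frozen = (params.freeze_rate * params.freeze_duration
                / (1.0 + params.freeze_rate * params.freeze_duration))
    frozen = bool(rng.random() < p_frozen)
    while t < duration:
        if frozen:
            seg = rng.exponential(params.freeze_duration)
        else:
            seg = rng.exponential(1.0 / params.freeze_rate)
        i0, i1 = int(t / dt), min(int((t + seg) / dt) + 1, n)
        if frozen and i1 > i0:
            mask[i0:i1] = True
        t += seg
        frozen = not frozen
    return mask


def _dart_profile(n: int, dt: float, duration: float, params: BehaviourParams,
                  freeze: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Speed override for darting bursts (NaN where no dart is active)."""
    prof = np.full(n, np.nan)
    if params.dart_rate <= 0.0:
        return prof
    n_darts = rng.poisson(params.dart_rate * duration)
    starts = np.sort(rng.uniform(0.0, duration, size=n_darts))
    w = max(int(params.dart_duration / dt), 1)
    for t0 in starts:
        i0 = int(t0 / dt)
        prof[i0:i0 + w] = params.dart_speed
    prof[freeze] = np.nan  # darts interrupt movement segments, not freezes
    return prof


def simulate_trajectory(
    params: BehaviourParams,
    duration: float,
    arena: ArenaGeometry | None = None,
    seed: int = 0,
    fish_id: str = "fish",
    rate: float = TRAJ_RATE,
) -> GroundTruthTrajectory:
    """Simulate one fish for ``duration`` seconds in a rectangular arena.

    The walk is a correlated random walk with reflective walls plus a soft
    wall-avoidance steering term (25 mm margin), state-specific freezing
    bouts, darts, and an Ornstein--Uhlenbeck ventilation-frequency process.
    The same seed reproduces the trajectory bit for bit.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    arena = arena if arena is not None else default_arena()
    if arena.n_electrodes == 0:
        raise ValueError("arena has no electrodes")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate
    n = int(round(duration * rate)) + 1
    t = np.arange(n) * dt

    freeze = _bout_mask(n, dt, duration, params, rng)
    speed = np.clip(
        _ou_series(n, dt, params.mean_speed, params.speed_sd, params.speed_tau, rng),
        0.0, None,
    )
    dart = _dart_profile(n, dt, duration, params, freeze, rng)
    speed = np.where(np.isnan(dart), speed, dart)
    speed[freeze] = 0.0

    # heading: wrapped random walk; diffusion set by (1 - persistence)
    sigma_theta = (1.0 - params.heading_persistence) * 4.0  # rad / sqrt(s)
    dtheta = rng.standard_normal(n) * sigma_theta * math.sqrt(dt)
    theta = rng.uniform(0.0, 2.0 * math.pi)

    wx, wy = arena.width_x, arena.width_y
    margin, k_wall, brake = 50.0, 2.0, 0.6
    x = rng.uniform(margin, wx - margin)
    y = rng.uniform(margin, wy - margin)
    xs = np.empty(n)
    ys = np.empty(n)
    xs[0], ys[0] = x, y
    for i in range(1, n):
        theta += dtheta[i]
        s = speed[i]
        # steer away from nearby walls (torque toward the inward direction,
        # stronger for faster approaches) and brake while inside the margin
        kw = k_wall * (1.0 + s / 25.0)
        slow = 1.0
        if x < margin or x > wx - margin:
            target = 0.0 if x < margin else math.pi
            w = 1.0 - (x if x < margin else wx - x) / margin
            theta += kw * dt * w * math.remainder(target - theta, 2.0 * math.pi)
            slow = min(slow, 1.0 - brake * w)
        if y < margin or y > wy - margin:
            target = math.pi / 2.0 if y < margin else -math.pi / 2.0
            w = 1.0 - (y if y < margin else wy - y) / margin
            theta += kw * dt * w * math.remainder(target - theta, 2.0 * math.pi)
            slow = min(slow, 1.0 - brake * w)
        s *= slow
        x += s * math.cos(theta) * dt
        y += s * math.sin(theta) * dt
        # reflective walls
        if x < 0.0:
            x = -x
            theta = math.pi - theta
        elif x > wx:
            x = 2.0 * wx - x
            theta = math.pi - theta
        if y < 0.0:
            y = -y
            theta = -theta
        elif y > wy:
            y = 2.0 * wy - y
            theta = -theta
        xs[i], ys[i] = x, y

    xy = np.column_stack([xs, ys])
    v = np.gradient(xy, dt, axis=0)
    fv = np.clip(
        _ou_series(n, dt, params.vent_base_freq, params.vent_freq_sd,
                   params.vent_tau, rng),
        1.2, 9.5,
    )
    state = np.full(n, params.state, dtype=object)
    return GroundTruthTrajectory(t=t, xy=xy, v=v, fv=fv, state=state,
                                 fish_id=fish_id, arena=arena)


def render_signals(
    traj: GroundTruthTrajectory,
    arena: ArenaGeometry | None = None,
    snr: float | None = None,
    seed: int = 0,
    fs: float = 1000.0,
    amplitude: float = 1.0,
    kernel_scale: float | None = None,
) -> ElectrodeArrayRecording:
    """Render a trajectory into a multichannel electrode-array recording.

    Channel c carries ``A * exp(-d_c(t)^2 / (2 sigma^2)) * sin(phi(t))`` where
    ``d_c`` is the fish-electrode distance, sigma defaults to one electrode
    pitch and ``phi`` integrates the instantaneous ventilation frequency.
    ``snr`` is the peak-channel signal-to-noise power ratio of the added
    white Gaussian noise; ``None`` (or ``inf``) renders noiselessly.
    """
    arena = arena if arena is not None else traj.arena
    if arena.n_electrodes != traj.arena.n_electrodes:
        raise ValueError("trajectory and arena electrode geometries do not match")
    if (
        traj.xy[:, 0].min() < 0 or traj.xy[:, 0].max() > arena.width_x
        or traj.xy[:, 1].min() < 0 or traj.xy[:, 1].max() > arena.width_y
    ):
        raise ValueError("trajectory leaves the arena bounds")
    if snr is not None and not math.isinf(snr) and snr <= 0:
        raise ValueError("snr must be positive")
    sigma = kernel_scale if kernel_scale is not None else arena.pitch
    rng = np.random.default_rng(seed)

    n_out = int(round(traj.duration * fs)) + 1
    t_out = np.arange(n_out) / fs
    x = np.interp(t_out, traj.t, traj.xy[:, 0])
    y = np.interp(t_out, traj.t, traj.xy[:, 1])
    fv = np.interp(t_out, traj.t, traj.fv)
    phase = 2.0 * math.pi * np.cumsum(fv) / fs + rng.uniform(0.0, 2.0 * math.pi)
    carrier = np.sin(phase)

    ex = arena.electrode_positions[:, 0][:, None]
    ey = arena.electrode_positions[:, 1][:, None]
    sig = np.empty((arena.n_electrodes, n_out))
    chunk = 200_000
    for lo in range(0, n_out, chunk):
        hi = min(lo + chunk, n_out)
        d2 = (ex - x[None, lo:hi]) ** 2 + (ey - y[None, lo:hi]) ** 2
        sig[:, lo:hi] = amplitude * np.exp(-d2 / (2.0 * sigma * sigma)) * carrier[lo:hi]

    if snr is not None and not math.isinf(snr):
        p_sig = (sig ** 2).mean(axis=1).max()
        sig = sig + rng.normal(0.0, math.sqrt(p_sig / snr), size=sig.shape)
    return ElectrodeArrayRecording(samples=sig, fs=fs, arena=arena, truth=traj)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _fish_profile(cv: float, vent_sd_hz: float,
                  rng: np.random.Generator) -> dict:
    """Individual variability: one fish's personal trait multipliers.

    Drawn once per fish and applied to every state's programme, so a fish
    that swims fast swims fast in all its sessions and per-fish baseline
    standardisation can cancel the trait.  Lognormal multipliers with
    coefficient of variation ``cv``; additive Gaussian offset (Hz) on the
    ventilation base rate.
    """
    sig = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    def mult() -> float:
        return float(rng.lognormal(-0.5 * sig * sig, sig)) if sig > 0 else 1.0

    return {
        "mean_speed": mult(),
        "speed_sd": mult(),
        "freeze_rate": mult(),
        "freeze_duration": mult(),
        "dart_rate": mult(),
        "vent_freq_sd": mult(),
        "vent_offset_hz": float(rng.normal(0.0, vent_sd_hz)) if vent_sd_hz > 0 else 0.0,
    }


def _apply_profile(base: BehaviourParams, profile: dict) -> BehaviourParams:
    return replace(
        base,
        mean_speed=base.mean_speed * profile["mean_speed"],
        speed_sd=base.speed_sd * profile["speed_sd"],
        freeze_rate=base.freeze_rate * profile["freeze_rate"],
        freeze_duration=base.freeze_duration * profile["freeze_duration"],
        dart_rate=base.dart_rate * profile["dart_rate"],
        vent_base_freq=float(np.clip(
            base.vent_base_freq + profile["vent_offset_hz"], 1.5, 8.5)),
        vent_freq_sd=base.vent_freq_sd * profile["vent_freq_sd"],
    )

@dataclass(frozen=True)
class FishPlan:
    """One fish: which states it experiences and for how long (analysed s)."""

    fish_id: str
    states: tuple[str, ...]
    duration: float = 300.0
    seed: int = 0


@dataclass(eq=False)
class CohortConfig:
    """A cohort: list of fish plans plus index-extraction settings."""

    fish: list[FishPlan] = field(default_factory=list)
    window: float = 5.0
    sub_window: float = 1.0
    v_stop: float = 3.0
    edge_trim: float = 0.5
    pos_noise_mm: float = 1.5
    fv_noise_hz: float = 0.05
    #: per-fish individual variability: CV of the lognormal jitter applied to
    #: speeds/bout rates, and SD (Hz) of the per-fish ventilation-rate offset
    param_jitter: float = 0.08
    vent_jitter_hz: float = 0.06
    params: dict[str, BehaviourParams] = field(default_factory=lambda: dict(_DEFAULTS))


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """The study-shaped cohort: 15 fish (normal, fear) + 8 fish (normal, appetitive).

    300 analysed seconds per fish-state -> 60 five-second windows each,
    2760 windows in total.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(23) % (2 ** 31)]
    fish = [
        FishPlan(f"fish{i + 1:02d}", ("normal", "fear"), 300.0, seeds[i])
        for i in range(15)
    ] + [
        FishPlan(f"fish{i + 16:02d}", ("normal", "appetitive"), 300.0, seeds[15 + i])
        for i in range(8)
    ]
    return CohortConfig(fish=fish)


def generate_cohort(
    config: CohortConfig,
    arena: ArenaGeometry | None = None,
    standardise: bool = True,
) -> pd.DataFrame:
    """Generate the cohort's index-window table directly from ground truth.

    For every fish-state the trajectory is simulated with 0.5 s padding on
    each side, ground truth is sampled on the 33 Hz analysis grid with small
    measurement-emulation noise, passed through the same smoothing /
    differentiation / windowing chain as electrode-derived tracks, and the
    resulting windows are standardised per fish against its normal-state
    (baseline) windows.
    """
    from .indices import differentiate_positions, standardise as _standardise, windowed_indices
    from .position import F_M, smooth_track

    arena = arena if arena is not None else default_arena()
    ids = [f.fish_id for f in config.fish]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate fish ids in cohort config")

    frames: list[pd.DataFrame] = []
    for plan in config.fish:
        ss = np.random.SeedSequence(plan.seed)
        state_seeds = ss.generate_state(2 * max(len(plan.states), 1)) % (2 ** 31)
        profile = _fish_profile(
            config.param_jitter, config.vent_jitter_hz,
            np.random.default_rng(plan.seed ^ 0x5EED),
        )
        for k, state in enumerate(plan.states):
            params = _apply_profile(config.params[state], profile)
            traj = simulate_trajectory(
                params, plan.duration + 2.0 * config.edge_trim, arena,
                seed=int(state_seeds[2 * k]), fish_id=plan.fish_id,
            )
            rng = np.random.default_rng(int(state_seeds[2 * k + 1]))
            n_ticks = int(math.floor(traj.duration * F_M)) + 1
            t_ticks = np.arange(n_ticks) / F_M
            xy = np.column_stack([
                np.interp(t_ticks, traj.t, traj.xy[:, 0]),
                np.interp(t_ticks, traj.t, traj.xy[:, 1]),
            ])
            xy = xy + rng.normal(0.0, config.pos_noise_mm, size=xy.shape)
            fv = np.interp(t_ticks, traj.t, traj.fv)
            fv = fv + rng.normal(0.0, config.fv_noise_hz, size=fv.shape)
            keep = (t_ticks >= config.edge_trim) & (t_ticks < traj.duration - config.edge_trim)
            track = smooth_track(t_ticks[keep], xy[keep], arena=arena)
            vel = differentiate_positions(track)
            win = windowed_indices(
                vel, fv[keep], window=config.window, v_stop=config.v_stop,
                sub_window=config.sub_window, fish_id=plan.fish_id, state=state,
            )
            frames.append(win)
    if not frames:
        return pd.DataFrame(
            columns=["fish_id", "state", "t0", "v_mean", "p_stop", "fv_mean",
                     "v_sd", "p_stop_sd", "fv_sd", "standardised"]
        )
    table = pd.concat(frames, ignore_index=True)
    if standardise:
        table = _standardise(table, baseline_state="normal")
    return table
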