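"""Synthetic worm data with known ground truth.

Three generators emulate the raw inputs of the quantification pipelines:

* a two-state (roam/dwell) continuous-time Markov chain emitting
  per-interval activity — exponential-mixture activity while dwelling,
  Gaussian activity while roaming — plus rendered difference-movie stacks;
* traveling-wave curvature kymographs with mid-body constraint episodes
  that suppress mid-body amplitude and boost anterior amplitude by a known
  gain;
* censored Weibull lifespan cohorts observed on an every-other-day grid.

Every generator returns a :class:`~nemaquant.datatypes.GroundTruth`
sufficient to predict the downstream pipeline's output, and is
bit-reproducible for a fixed seed.

Activity is piecewise-constant over sub-bouts (mean length
``persistence`` seconds) rather than independent across seconds: real
difference-image activity is autocorrelated on that timescale, and the
persistence keeps the marginal activity distribution — two exponentials
plus a Gaussian — intact through the pipeline's 5 s smoothing kernel, so
the fitted functional form is exactly realizable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import integrate, interpolate
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .datatypes import (
    ActivityTrace,
    ConstraintAnnotation,
    CurvatureKymograph,
    FrameStack,
    GroundTruth,
    Midline,
    SurvivalRecord,
)
from .exceptions import InvalidConfigError

__all__ = [
    "LocomotionSimConfig",
    "WormMovieConfig",
    "ConstraintEpisode",
    "KymographSimConfig",
    "SurvivalSimConfig",
    "simulate_activity_trace",
    "simulate_worm_movie",
    "simulate_kymograph",
    "kymograph_to_midlines",
    "simulate_survival",
]


# --------------------------------------------------------------------------
# locomotion / activity


@dataclass
class LocomotionSimConfig:
    """Two-state roam/dwell activity generator settings.

    ``roam_rate`` is the per-second hazard of switching dwell -> roam,
    ``dwell_rate`` the hazard of roam -> dwell; stationary dwell occupancy
    is ``dwell_rate / (dwell_rate + roam_rate)``. Dwelling activity is an
    exponential mixture (scales ``dwell_scales``, first-component weight
    ``dwell_mix``) with a ``quiescence_prob`` atom at exactly zero;
    roaming activity is Gaussian(roam_mean, roam_sd) clipped at zero.
    Activity is redrawn at state switches and at sub-bout boundaries of
    mean length ``persistence`` seconds.
    """

    duration: float
    frame_interval: float = 1.0
    roam_rate: float = 1.0 / 150.0
    dwell_rate: float = 7.0 / 450.0
    dwell_scales: Tuple[float, float] = (3.0, 12.0)
    dwell_mix: float = 0.5
    roam_mean: float = 60.0
    roam_sd: float = 8.0
    quiescence_prob: float = 0.05
    persistence: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidConfigError("duration must be positive")
        if self.frame_interval <= 0:
            raise InvalidConfigError("frame_interval must be positive")
        if self.roam_rate < 0 or self.dwell_rate < 0:
            raise InvalidConfigError("switch rates must be nonnegative")
        if self.roam_rate == 0 and self.dwell_rate == 0:
            raise InvalidConfigError("at least one switch rate must be positive")
        if min(self.dwell_scales) <= 0:
            raise InvalidConfigError("dwell scales must be positive")
        if not 0 <= self.dwell_mix <= 1:
            raise InvalidConfigError("dwell_mix must be in [0, 1]")
        if self.roam_mean <= max(self.dwell_scales):
            raise InvalidConfigError("roam_mean must exceed both dwell scales")
        if self.roam_sd <= 0:
            raise InvalidConfigError("roam_sd must be positive")
        if not 0 <= self.quiescence_prob < 1:
            raise InvalidConfigError("quiescence_prob must be in [0, 1)")
        if self.persistence <= 0:
            raise InvalidConfigError("persistence must be positive")

    @property
    def dwell_occupancy(self) -> float:
        return self.dwell_rate / (self.dwell_rate + self.roam_rate)


def _positive_activity_density(cfg: LocomotionSimConfig) -> Callable[[float], float]:
    """Unnormalized generating density of positive activity values."""
    p_d = cfg.dwell_occupancy
    p_r = 1.0 - p_d
    l1, l2 = cfg.dwell_scales
    w = cfg.dwell_mix
    q = cfg.quiescence_prob

    def density(a: float) -> float:
        exp_part = p_d * (1 - q) * (
            w / l1 * math.exp(-a / l1) + (1 - w) / l2 * math.exp(-a / l2)
        )
        gauss_part = p_r / (cfg.roam_sd * math.sqrt(2 * math.pi)) * math.exp(
            -((a - cfg.roam_mean) ** 2) / (2 * cfg.roam_sd**2)
        )
        return exp_part + gauss_part

    return density


def true_dwelling_fraction(cfg: LocomotionSimConfig) -> float:
    """Exponential components' share of positive-activity probability mass.

    Computed by numeric integration of the generating density over a > 0,
    mirroring the definition of the fitted dwelling fraction.
    """
    p_d = cfg.dwell_occupancy
    p_r = 1.0 - p_d
    l1, l2 = cfg.dwell_scales
    w = cfg.dwell_mix
    q = cfg.quiescence_prob
    upper = cfg.roam_mean + 12 * cfg.roam_sd

    def exp_dens(a):
        return p_d * (1 - q) * (
            w / l1 * math.exp(-a / l1) + (1 - w) / l2 * math.exp(-a / l2))

    def full_dens(a):
        return _positive_activity_density(cfg)(a)

    exp_mass, _ = integrate.quad(exp_dens, 0, upper, limit=200)
    total_mass, _ = integrate.quad(full_dens, 0, upper, limit=200,
                                   points=[cfg.roam_mean])
    if total_mass == 0:
        return 1.0
    return exp_mass / total_mass


def _simulate_states(cfg: LocomotionSimConfig, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Frame-grid state sequence; 0 = dwell, 1 = roam."""
    dt = cfg.frame_interval
    p_dr = 1.0 - math.exp(-cfg.roam_rate * dt)   # dwell -> roam
    p_rd = 1.0 - math.exp(-cfg.dwell_rate * dt)  # roam -> dwell
    states = np.empty(n, dtype=np.int8)
    state = 0 if rng.random() < cfg.dwell_occupancy else 1
    u = rng.random(n)
    for i in range(n):
        states[i] = state
        if state == 0:
            if u[i] < p_dr:
                state = 1
        else:
            if u[i] < p_rd:
                state = 0
    return states


def _draw_activity(cfg: LocomotionSimConfig, state: int,
                   rng: np.random.Generator) -> float:
    if state == 0:
        if rng.random() < cfg.quiescence_prob:
            return 0.0
        scale = cfg.dwell_scales[0] if rng.random() < cfg.dwell_mix \
            else cfg.dwell_scales[1]
        return float(rng.exponential(scale))
    return float(max(0.0, rng.normal(cfg.roam_mean, cfg.roam_sd)))


def simulate_activity_trace(
    config: LocomotionSimConfig,
) -> Tuple[ActivityTrace, GroundTruth]:
    """Simulate a per-interval activity trace with known dwelling fraction."""
    n = int(round(config.duration / config.frame_interval))
    if n < 1:
        raise InvalidConfigError("duration shorter than one frame interval")
    rng = np.random.default_rng(config.seed)
    states = _simulate_states(config, n, rng)
    p_next = 1.0 - math.exp(-config.frame_interval / config.persistence)
    values = np.empty(n)
    current = _draw_activity(config, int(states[0]), rng)
    for i in range(n):
        if i > 0 and (states[i] != states[i - 1] or rng.random() < p_next):
            current = _draw_activity(config, int(states[i]), rng)
        values[i] = current
    trace = ActivityTrace(values=values, frame_interval=config.frame_interval)
    truth = GroundTruth(
        true_dwelling_fraction=true_dwelling_fraction(config),
        state_sequence=states,
        extra={"dwell_occupancy": config.dwell_occupancy},
    )
    return trace, truth


# --------------------------------------------------------------------------
# worm movies


@dataclass
class WormMovieConfig:
    """Rendered single-worm movie settings.

    The worm is a thick sinusoid curve rendered without anti-aliasing
    (so the changed-pixel ground truth is exact) on a uniform background.
    Its centroid displacement per interval follows the roam/dwell state
    sequence of ``locomotion``: ``step_roam`` pixels while roaming,
    ``step_dwell`` while dwelling, with the undulation phase advancing
    in proportion to the displacement.
    """

    locomotion: LocomotionSimConfig
    image_height: int = 64
    image_width: int = 64
    worm_length: float = 20.0
    worm_thickness: float = 3.0
    undulation_amplitude: Optional[float] = None  # default: 0.15 * length
    background_level: float = 20.0
    worm_level: float = 120.0
    noise_sd: float = 2.0
    step_roam: float = 3.0
    step_dwell: float = 0.5
    heading_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.undulation_amplitude is None:
            self.undulation_amplitude = 0.15 * self.worm_length
        if self.worm_length < 1 or self.worm_thickness < 1:
            raise InvalidConfigError("worm dimensions must be >= 1 pixel")
        if self.worm_level == self.background_level:
            raise InvalidConfigError("worm must contrast with the background")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        margin = self._margin
        if (2 * margin >= min(self.image_height, self.image_width)):
            raise InvalidConfigError("worm does not fit inside the frame")

    @property
    def _margin(self) -> float:
        return (self.worm_length / 2 + self.undulation_amplitude
                + self.worm_thickness / 2 + 2)


def _render_worm(cfg: WormMovieConfig, center: np.ndarray, heading: float,
                 phase: float) -> np.ndarray:
    """Binary worm mask (no anti-aliasing)."""
    mask = np.zeros((cfg.image_height, cfg.image_width), dtype=bool)
    n_samples = max(1, int(cfg.worm_length * 4))
    if cfg.worm_length <= 1:
        u = np.array([0.0])
    else:
        u = np.linspace(-cfg.worm_length / 2, cfg.worm_length / 2, n_samples)
    e_dir = np.array([math.cos(heading), math.sin(heading)])
    e_perp = np.array([-math.sin(heading), math.cos(heading)])
    wavelength = max(cfg.worm_length, 1.0)
    lateral = cfg.undulation_amplitude * np.sin(
        2 * math.pi * u / wavelength + phase)
    pts = center[None, :] + u[:, None] * e_dir[None, :] \
        + lateral[:, None] * e_perp[None, :]
    cols = np.round(pts[:, 0]).astype(int)
    rows = np.round(pts[:, 1]).astype(int)
    inside = (rows >= 0) & (rows < cfg.image_height) \
        & (cols >= 0) & (cols < cfg.image_width)
    mask[rows[inside], cols[inside]] = True
    radius = int(cfg.worm_thickness) // 2
    if radius > 0:
        mask = binary_dilation(mask, disk(radius))
    return mask


def simulate_worm_movie(
    config: WormMovieConfig,
) -> Tuple[FrameStack, GroundTruth]:
    """Render a movie of one moving worm; ground truth holds the per-interval
    changed-pixel counts of the noise-free scene."""
    loc = config.locomotion
    n = int(round(loc.duration / loc.frame_interval)) + 1
    rng = np.random.default_rng(loc.seed)
    states = _simulate_states(loc, n, rng)

    margin = config._margin
    lo = np.array([margin, margin])
    hi = np.array([config.image_width - margin, config.image_height - margin])
    center = 0.5 * (lo + hi)
    heading = rng.uniform(0, 2 * math.pi)
    phase = 0.0

    masks = np.empty((n, config.image_height, config.image_width), dtype=bool)
    for t in range(n):
        masks[t] = _render_worm(config, center, heading, phase)
        step = config.step_roam if states[t] == 1 else config.step_dwell
        if config.heading_noise_sd > 0:
            heading += rng.normal(0.0, config.heading_noise_sd)
        move = step * np.array([math.cos(heading), math.sin(heading)])
        center = center + move
        # reflect off the safe box so the worm always fits in the frame
        for axis in range(2):
            if center[axis] < lo[axis]:
                center[axis] = 2 * lo[axis] - center[axis]
                heading = math.pi - heading if axis == 0 else -heading
            elif center[axis] > hi[axis]:
                center[axis] = 2 * hi[axis] - center[axis]
                heading = math.pi - heading if axis == 0 else -heading
        phase += 2 * math.pi * step / max(config.worm_length, 1.0)

    clean = np.where(masks, config.worm_level, config.background_level).astype(float)
    changed = np.array([(masks[t] != masks[t + 1]).sum() for t in range(n - 1)])
    frames = clean
    if config.noise_sd > 0:
        frames = np.clip(
            clean + rng.normal(0.0, config.noise_sd, size=clean.shape), 0, None)
    stack = FrameStack(frames=frames, frame_interval=loc.frame_interval)
    truth = GroundTruth(
        changed_pixel_counts=changed,
        state_sequence=states,
        true_dwelling_fraction=true_dwelling_fraction(loc),
        extra={"clean_frames": clean},
    )
    return stack, truth


# --------------------------------------------------------------------------
# curvature kymographs


@dataclass
class ConstraintEpisode:
    """One mid-body constraint episode.

    While active, curvature amplitude on the channel interval
    [``start_s``, ``end_s``] is multiplied by ``mid_suppression`` and the
    amplitude anterior to the channel (s < start_s) by
    ``1 + anterior_gain``. Multipliers ramp in and out over a 2-frame
    linear taper to avoid step discontinuities.
    """

    start_s: float
    end_s: float
    start_time: float
    end_time: float
    mid_suppression: float = 0.5
    anterior_gain: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s <= 1:
            raise InvalidConfigError("need 0 <= start_s < end_s <= 1")
        if self.end_time <= self.start_time:
            raise InvalidConfigError("episode must have positive duration")
        if not 0 <= self.mid_suppression <= 1:
            raise InvalidConfigError("mid_suppression must be in [0, 1]")
        if self.anterior_gain < 0:
            raise InvalidConfigError("anterior_gain must be >= 0")


@dataclass
class KymographSimConfig:
    """Traveling-wave curvature kymograph settings.

    K(s, t) = envelope(s) * base_amplitude * sin(2*pi*(t/period -
    s/wavelength)) + noise outside constraint episodes; inside an episode
    the amplitude is modulated as described on :class:`ConstraintEpisode`.
    The default period (1.5 s) and frame rate (30 Hz) put an integer
    number of samples in each undulation cycle, so windowed-maximum
    amplitude estimates are identical across 3 s windows.
    """

    duration: float
    n_body_points: int = 100
    frame_rate: float = 30.0
    base_amplitude: float = 4.0
    wavelength: float = 0.9
    period: float = 1.5
    envelope: Optional[Union[Sequence[float], Callable[[np.ndarray], np.ndarray]]] = None
    constraint_episodes: List[ConstraintEpisode] = field(default_factory=list)
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.frame_rate <= 0:
            raise InvalidConfigError("duration and frame_rate must be positive")
        if self.n_body_points < 5:
            raise InvalidConfigError("n_body_points must be >= 5")
        if self.base_amplitude <= 0 or self.wavelength <= 0 or self.period <= 0:
            raise InvalidConfigError(
                "base_amplitude, wavelength and period must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        eps = sorted(self.constraint_episodes, key=lambda e: e.start_time)
        for a, b in zip(eps, eps[1:]):
            if b.start_time < a.end_time:
                raise InvalidConfigError("constraint episodes overlap in time")

    def envelope_array(self, s_grid: np.ndarray) -> np.ndarray:
        if self.envelope is None:
            return np.ones_like(s_grid)
        if callable(self.envelope):
            return np.asarray(self.envelope(s_grid), dtype=float)
        env = np.asarray(self.envelope, dtype=float)
        if env.shape != s_grid.shape:
            raise InvalidConfigError(
                "envelope array must have n_body_points entries")
        return env


def simulate_kymograph(
    config: KymographSimConfig,
) -> Tuple[CurvatureKymograph, ConstraintAnnotation, GroundTruth]:
    """Simulate K(s, t) with optional mid-body constraint episodes."""
    n_frames = int(round(config.duration * config.frame_rate))
    if n_frames < 2:
        raise InvalidConfigError("duration must cover at least two frames")
    rng = np.random.default_rng(config.seed)
    s = np.linspace(0.0, 1.0, config.n_body_points)
    t = np.arange(n_frames) / config.frame_rate
    env = config.envelope_array(s)
    base = env[:, None] * config.base_amplitude * np.sin(
        2 * math.pi * (t[None, :] / config.period - s[:, None] / config.wavelength)
    )

    multiplier = np.ones((config.n_body_points, n_frames))
    anterior = np.full(n_frames, np.nan)
    posterior = np.full(n_frames, np.nan)
    for ep in config.constraint_episodes:
        frames = np.flatnonzero((t >= ep.start_time) & (t < ep.end_time))
        if frames.size == 0:
            continue
        m_s = np.ones_like(s)
        m_s[(s >= ep.start_s) & (s <= ep.end_s)] = ep.mid_suppression
        m_s[s < ep.start_s] = 1.0 + ep.anterior_gain
        # 2-frame linear taper at each end of the episode
        ramp = np.ones(frames.size)
        for k in range(min(2, frames.size)):
            frac = (k + 1) / 3.0
            ramp[k] = min(ramp[k], frac)
            ramp[-1 - k] = min(ramp[-1 - k], frac)
        multiplier[:, frames] = 1.0 + ramp[None, :] * (m_s[:, None] - 1.0)
        anterior[frames] = ep.start_s
        posterior[frames] = ep.end_s

    K = base * multiplier
    if config.noise_sd > 0:
        K = K + rng.normal(0.0, config.noise_sd, size=K.shape)
    kymo = CurvatureKymograph(K=K, s_grid=s, times=t,
                              body_length=np.ones(n_frames))
    ann = ConstraintAnnotation(anterior=anterior, posterior=posterior)
    gains = {ep.anterior_gain for ep in config.constraint_episodes}
    truth = GroundTruth(
        true_anterior_gain=(gains.pop() if len(gains) == 1 else None),
        extra={"envelope": env, "noise_free_K": base * multiplier},
    )
    return kymo, ann, truth


def kymograph_to_midlines(kymo: CurvatureKymograph,
                          body_length: float = 1000.0) -> List[Midline]:
    """Reconstruct per-frame midlines whose curvature reproduces the kymograph.

    The tangent angle is theta(s) = integral_0^s K(u) du (K = k*L makes the
    body-coordinate integral of K the angle directly); positions follow by
    arc-length integration at length ``body_length``. Integration runs on a
    10x-refined s grid to keep the geometric error well below the curvature
    extraction tolerance; returned points sit on the kymograph's s grid.
    """
    if body_length <= 0:
        raise InvalidConfigError("body_length must be positive")
    s = kymo.s_grid
    fine = np.linspace(0.0, 1.0, 10 * (s.size - 1) + 1)
    midlines = []
    for j in range(kymo.times.size):
        K_interp = interpolate.CubicSpline(s, kymo.K[:, j])
        theta = integrate.cumulative_trapezoid(K_interp(fine), fine, initial=0.0)
        x = integrate.cumulative_trapezoid(np.cos(theta), fine, initial=0.0)
        y = integrate.cumulative_trapezoid(np.sin(theta), fine, initial=0.0)
        pts = body_length * np.column_stack([x, y])
        midlines.append(Midline(points=pts[::10], timestamp=float(kymo.times[j])))
    return midlines


# --------------------------------------------------------------------------
# survival cohorts


@dataclass
class SurvivalSimConfig:
    """Censored Weibull lifespan cohort settings.

    ``groups`` maps group label -> (weibull_shape, weibull_scale in days).
    Lifetimes are rounded UP to the next multiple of
    ``observation_interval`` (a worm found dead on day d died in
    (d - interval, d]); independent censoring is applied at each
    observation day the worm is still alive, with probability
    ``censor_prob`` per observation.
    """

    groups: Dict[str, Tuple[float, float]]
    n_worms: int = 105
    censor_prob: float = 0.0
    observation_interval: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_worms <= 0:
            raise InvalidConfigError("n_worms must be positive")
        if not self.groups:
            raise InvalidConfigError("at least one group is required")
        for g, (shape, scale) in self.groups.items():
            if shape <= 0 or scale <= 0:
                raise InvalidConfigError(f"group {g!r}: shape and scale must be > 0")
        if not 0 <= self.censor_prob < 1:
            raise InvalidConfigError("censor_prob must be in [0, 1)")
        if self.observation_interval <= 0:
            raise InvalidConfigError("observation_interval must be positive")


def simulate_survival(
    config: SurvivalSimConfig,
) -> Tuple[List[SurvivalRecord], GroundTruth]:
    """Simulate per-worm lifespan records on the observation grid."""
    rng = np.random.default_rng(config.seed)
    records: List[SurvivalRecord] = []
    medians = {}
    dt = config.observation_interval
    for group, (shape, scale) in config.groups.items():
        medians[group] = (scale if math.isinf(shape)
                          else scale * math.log(2) ** (1.0 / shape))
        for i in range(config.n_worms):
            lifetime = scale if math.isinf(shape) else scale * rng.weibull(shape)
            death_day = max(dt, math.ceil(lifetime / dt) * dt)
            day, status = death_day, "dead"
            if config.censor_prob > 0:
                obs = dt
                while obs < death_day:
                    if rng.random() < config.censor_prob:
                        day, status = obs, "censored"
                        break
                    obs += dt
            records.append(SurvivalRecord(worm_id=f"{group}-{i}", group=group,
                                          event_day=float(day), status=status))
    truth = GroundTruth(true_median_lifespan=medians)
    return records, truth
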