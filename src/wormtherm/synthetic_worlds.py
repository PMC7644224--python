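"""Generative models for thermotaxis assays and calcium imaging.

This module stands in for raw assay video and imaging data: it simulates

* klinokinesis worm trajectories on a linear thermal gradient — a biased
  random walk whose instantaneous turn rate depends on the heading relative
  to the warm direction, lambda(theta) = lambda0 * (1 + beta * cos(theta)),
  with a post-turn bias that redraws headings from a mixture of a von Mises
  centred on the cold direction (probability ``p``) and a uniform;
* a reduced two-state 1-D version of the same walk whose thermotaxis bias
  has a closed form, used as an analytic oracle for the behavioral
  statistics;
* synthetic GCaMP traces with photobleaching, Gaussian noise and either
  stochastic (inhomogeneous-Poisson, temperature-gated) or deterministic
  (threshold-crossing step response, AFD-style) calcium events.

Every simulation returns its :class:`GroundTruth` alongside the data, and
is a pure function of (parameters, seed).  Named presets package the
fed/starved phenotypes and per-neuron calcium response styles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._angles import wrap_angle
from .calcium_quant import CalciumTrace
from .stimulus import TemperatureRamp, ThermalGradient, short_gradient
from .track_quant import RunSegment, Trajectory, classify_direction

__all__ = [
    "SimulationConfig",
    "CalciumSimParams",
    "GroundTruth",
    "simulate_assay",
    "simulate_two_state_1d",
    "expected_two_state_bias",
    "simulate_calcium",
    "preset",
    "preset_names",
    "default_ramp",
    "short_gradient",
    "ThermalGradient",
    "TemperatureRamp",
]

# jitter concentration for reversal headings (180 deg flip +/- von Mises noise)
_REVERSAL_JITTER_KAPPA = 20.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the klinokinesis random-walk simulator.

    speed_mean / speed_sd
        Forward crawling speed (mm/s); each worm draws one speed.
    heading_diffusion
        Angular diffusion of the heading during runs (deg^2/s).
    base_turn_rate
        lambda0, the heading-independent turn rate (1/s).
    klinokinesis_gain
        beta in lambda(theta) = lambda0 * (1 + beta * cos theta), theta the
        heading relative to the warm direction; beta > 0 suppresses turns
        while moving down the gradient.  |beta| <= 1 keeps the rate >= 0.
    post_turn_bias / post_turn_concentration
        With probability ``p`` a post-turn heading is drawn from a von
        Mises centred on the cold direction with concentration kappa;
        otherwise uniformly.
    reversal_prob
        Probability that a turn is a reversal (heading flip of ~180 deg)
        rather than a fresh heading draw.
    min_turn_angle
        Sharp turns are genuinely sharp: post-turn headings are redrawn
        until they differ from the pre-turn heading by at least this much
        (deg).  Smaller heading changes are within-run weathervaning, not
        scoreable turns.  By symmetry the *marginal* post-turn heading
        distribution is unchanged (uniform stays uniform under the null).
    """

    speed_mean: float = 0.117
    speed_sd: float = 0.015
    heading_diffusion: float = 10.0
    base_turn_rate: float = 1.0 / 30.0
    klinokinesis_gain: float = 0.0
    post_turn_bias: float = 0.0
    post_turn_concentration: float = 2.0
    reversal_prob: float = 0.2
    min_turn_angle: float = 60.0
    assay_duration: float = 2100.0
    frame_rate: float = 1.0
    n_worms: int = 15
    seed: int = 0

    def __post_init__(self):
        if abs(self.klinokinesis_gain) > 1:
            raise ValueError(
                f"|klinokinesis_gain| must be <= 1 so the turn rate stays >= 0, "
                f"got {self.klinokinesis_gain}"
            )
        if not 0 <= self.post_turn_bias <= 1:
            raise ValueError(f"post_turn_bias must lie in [0, 1], got {self.post_turn_bias}")
        if self.post_turn_concentration < 0:
            raise ValueError("post_turn_concentration must be >= 0")
        if not 0 <= self.reversal_prob <= 1:
            raise ValueError("reversal_prob must lie in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.speed_mean <= 0:
            raise ValueError("speed_mean must be > 0")
        if self.n_worms < 1:
            raise ValueError("n_worms must be >= 1")
        if not 0 <= self.min_turn_angle < 180:
            raise ValueError("min_turn_angle must lie in [0, 180)")


@dataclass(frozen=True)
class CalciumSimParams:
    """Parameters of the synthetic GCaMP trace generator.

    Stochastic mode (``deterministic_onset_temp is None``): event onsets
    follow an inhomogeneous Poisson process with rate
    ``r0 + r1 * max(0, T(t) - temp_threshold)``; each event contributes an
    instantaneous-rise, exponential-decay kernel of relative amplitude
    ``event_amplitude``.  Deterministic mode: a single sustained step
    response begins at the first frame where the stimulus reaches
    ``deterministic_onset_temp`` (AFD-style threshold response).

    The noiseless fluorescence is F0 * exp(-t/bleach_tau) * (1 + kernels);
    Gaussian noise of sd ``noise_sd * F0`` is added on top.  Event onsets
    are constrained to fall after the 10-frame dF/F baseline window so the
    baseline stays event-free.
    """

    baseline_F0: float = 100.0
    event_rate_base: float = 0.008
    event_rate_temp_gain: float = 0.0
    temp_threshold: float = 23.0
    event_amplitude: float = 0.25
    event_decay_tau: float = 3.0
    deterministic_onset_temp: Optional[float] = None
    bleach_tau: float = math.inf
    noise_sd: float = 0.02
    duration: float = 240.0
    frame_rate: float = 2.0
    seed: int = 0
    truth_threshold_dff: float = 10.0  # dF/F (%) defining the ground-truth event set

    def __post_init__(self):
        if self.event_rate_base < 0 or self.event_rate_temp_gain < 0:
            raise ValueError("event rates must be >= 0")
        if self.baseline_F0 <= 0:
            raise ValueError("baseline_F0 must be > 0")
        if self.event_decay_tau <= 0:
            raise ValueError("event_decay_tau must be > 0")
        if self.bleach_tau <= 0:
            raise ValueError("bleach_tau must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class GroundTruth:
    """Generative truth emitted alongside every simulation.

    ``turns`` — per-worm reorientation records (worm_id, time, kind,
    pre/post headings).  ``events`` — per-trace true calcium bouts (onset,
    offset, onset temperature).  ``meta`` — scalar truths such as the
    programmed onset temperature.
    """

    turns: List[dict] = field(default_factory=list)
    events: List[dict] = field(default_factory=list)
    meta: Dict[str, object] = field(default_factory=dict)

    def validate(self, duration: Optional[float] = None) -> None:
        by_worm: Dict[object, float] = {}
        for rec in self.turns:
            w, t = rec["worm_id"], rec["time"]
            if w in by_worm and t <= by_worm[w]:
                raise ValueError(f"turn times not strictly increasing for worm {w}")
            by_worm[w] = t
        for rec in self.events:
            if rec["offset_time"] <= rec["onset_time"]:
                raise ValueError("truth event offset must exceed onset")
            if duration is not None and rec["offset_time"] > duration + 1e-9:
                raise ValueError("truth event extends beyond the simulated duration")


def _draw_post_turn_heading(
    rng: np.random.Generator, cold_dir: float, pre_heading: float, cfg: SimulationConfig
) -> float:
    """Mixture draw p*vonMises(cold, kappa) + (1-p)*uniform, rejected until
    the reorientation reaches ``min_turn_angle``."""
    for _ in range(1000):
        if rng.random() < cfg.post_turn_bias:
            jitter = math.degrees(rng.vonmises(0.0, max(cfg.post_turn_concentration, 1e-12)))
            heading = wrap_angle(cold_dir + jitter)
        else:
            heading = wrap_angle(rng.uniform(-180.0, 180.0))
        if abs(wrap_angle(heading - pre_heading)) >= cfg.min_turn_angle:
            return heading
    # pathological concentration: fall back to a reversal-style flip
    return wrap_angle(pre_heading + 180.0)


def _clamp(pos: float, lo: float, hi: float) -> Tuple[float, bool]:
    if pos < lo:
        return lo, True
    if pos > hi:
        return hi, True
    return pos, False


def simulate_assay(
    config: SimulationConfig,
    gradient: Optional[ThermalGradient] = None,
    start_position: Optional[Tuple[float, float]] = None,
) -> Tuple[List[Trajectory], GroundTruth]:
    """Simulate one assay of klinokinesis worms on a thermal gradient.

    Positions are in mm (gradient geometry is specified in cm); worms start
    at ``start_position`` (cm; plate centre by default).  A worm reaching
    the plate edge is censored there: its trajectory ends at the boundary
    contact, mirroring how tracking pipelines terminate tracks when animals
    hit the plate wall or collide and aggregate.  Each worm runs on its own
    child RNG stream spawned from the config seed, so worm i's path is
    unchanged when ``n_worms`` varies.
    """
    g = gradient or short_gradient()
    start_cm = start_position or g.center()
    if not g.contains(*start_cm):
        raise ValueError(f"start position {start_cm} outside plate bounds {g.bounds}")
    xmin, xmax, ymin, ymax = (10.0 * b for b in g.bounds)  # cm -> mm
    x0, y0 = 10.0 * start_cm[0], 10.0 * start_cm[1]
    warm = g.warm_axis_deg
    cold = wrap_angle(warm + 180.0)

    dt = 1.0 / config.frame_rate
    n_frames = int(round(config.assay_duration * config.frame_rate)) + 1
    streams = np.random.SeedSequence(config.seed).spawn(config.n_worms)

    trajectories: List[Trajectory] = []
    truth = GroundTruth(meta={"config": config, "gradient": g})
    for wi in range(config.n_worms):
        rng = np.random.default_rng(streams[wi])
        worm_id = f"worm{wi:03d}"
        speed = max(rng.normal(config.speed_mean, config.speed_sd), 0.1 * config.speed_mean)
        heading = wrap_angle(rng.uniform(-180.0, 180.0))
        x, y = x0, y0
        xs = np.empty(n_frames)
        ys = np.empty(n_frames)
        xs[0], ys[0] = x, y
        n_kept = n_frames
        for fi in range(1, n_frames):
            t = (fi - 1) * dt
            theta = math.radians(wrap_angle(heading - warm))
            lam = config.base_turn_rate * (1.0 + config.klinokinesis_gain * math.cos(theta))
            if rng.random() < lam * dt:
                pre = heading
                if rng.random() < config.reversal_prob:
                    jitter = math.degrees(rng.vonmises(0.0, _REVERSAL_JITTER_KAPPA))
                    heading = wrap_angle(heading + 180.0 + jitter)
                    kind = "reversal"
                else:
                    heading = _draw_post_turn_heading(rng, cold, heading, config)
                    kind = "sharp_turn"
                truth.turns.append(
                    {
                        "worm_id": worm_id,
                        "time": t,
                        "kind": kind,
                        "pre_heading": pre,
                        "post_heading": heading,
                    }
                )
            heading = wrap_angle(
                heading + rng.normal(0.0, math.sqrt(config.heading_diffusion * dt))
            )
            x += speed * dt * math.cos(math.radians(heading))
            y += speed * dt * math.sin(math.radians(heading))
            x, hit_x = _clamp(x, xmin, xmax)
            y, hit_y = _clamp(y, ymin, ymax)
            xs[fi], ys[fi] = x, y
            if hit_x or hit_y:
                # plate edge reached: the track is censored here, as a real
                # tracker loses animals that climb the wall or aggregate
                n_kept = fi + 1
                break
        trajectories.append(
            Trajectory(
                worm_id=worm_id,
                times=np.arange(n_kept) * dt,
                x=xs[:n_kept],
                y=ys[:n_kept],
                frame_rate=config.frame_rate,
            )
        )
        # drop truth turns after censoring
        end_t = (n_kept - 1) * dt
        truth.turns = [
            rec
            for rec in truth.turns
            if rec["worm_id"] != worm_id or rec["time"] <= end_t
        ]
    truth.validate(config.assay_duration)
    return trajectories, truth


def expected_two_state_bias(lam_w: float, lam_c: float, p: float) -> float:
    """Closed-form thermotaxis bias of the reduced two-state walk.

    Runs toward warm/cold end at rates lam_w/lam_c; after each run the next
    direction is cold with probability q = (1 + p) / 2.  The expected bias
    is the normalized difference of expected time per direction:

        bias = (q/lam_c - (1-q)/lam_w) / (q/lam_c + (1-q)/lam_w).
    """
    q = (1.0 + p) / 2.0
    num = q / lam_c - (1.0 - q) / lam_w
    den = q / lam_c + (1.0 - q) / lam_w
    return num / den


def simulate_two_state_1d(
    lam_w: float,
    lam_c: float,
    p: float,
    duration: float,
    n_worms: int,
    seed: int = 0,
) -> List[List[RunSegment]]:
    """Reduced 1-D klinokinesis walk with an analytic bias oracle.

    Each worm alternates exponential-duration runs pointing either warm
    (orientation 0 deg, rate ``lam_w``) or cold (180 deg, rate ``lam_c``);
    after every run the next direction is cold with probability
    q = (1 + p) / 2.  Returns one run list per worm (final run truncated at
    ``duration``); pooled through :func:`~wormtherm.track_quant.thermotaxis_bias`
    the ensemble bias converges to :func:`expected_two_state_bias`.
    """
    if lam_w <= 0 or lam_c <= 0:
        raise ValueError("run termination rates must be > 0")
    if not 0 <= p <= 1:
        raise ValueError("post-turn bias p must lie in [0, 1]")
    if duration <= 0 or n_worms < 1:
        raise ValueError("duration must be > 0 and n_worms >= 1")
    q = (1.0 + p) / 2.0
    streams = np.random.SeedSequence(seed).spawn(n_worms)
    worms: List[List[RunSegment]] = []
    for wi in range(n_worms):
        rng = np.random.default_rng(streams[wi])
        t = 0.0
        runs: List[RunSegment] = []
        first = True
        while t < duration:
            cold = rng.random() < q
            rate = lam_c if cold else lam_w
            length = min(rng.exponential(1.0 / rate), duration - t)
            if length <= 0:
                break
            orientation = 180.0 if cold else 0.0
            runs.append(
                RunSegment(
                    start_time=t,
                    end_time=t + length,
                    orientation=orientation,
                    direction_class=classify_direction(orientation, 0.0),
                    preceded_by_turn=not first,
                    worm_id=f"worm{wi:03d}",
                )
            )
            t += length
            first = False
        worms.append(runs)
    return worms


def simulate_calcium(
    params: CalciumSimParams, stimulus: TemperatureRamp
) -> Tuple[CalciumTrace, GroundTruth]:
    """Generate one synthetic GCaMP trace and its ground truth.

    The ground-truth event list contains the maximal intervals where the
    *noiseless* dF/F trace exceeds ``truth_threshold_dff`` — i.e. what an
    ideal noise-free measurement would classify as responses — plus the raw
    programmed kernel onsets in ``meta['kernel_onsets']``.  With
    ``noise_sd = 0`` the generated trace's suprathreshold set therefore
    equals the truth exactly.
    """
    n = params.n_frames
    dt = 1.0 / params.frame_rate
    times = np.arange(n) * dt
    temps = np.asarray(stimulus.temperature(times), dtype=float)
    rng = np.random.default_rng(params.seed)

    baseline_frames = 10
    kernel = np.zeros(n)
    kernel_onsets: List[float] = []
    if params.deterministic_onset_temp is not None:
        onset_temp = params.deterministic_onset_temp
        lo, hi = min(temps.min(), temps.max()), max(temps.min(), temps.max())
        if not lo <= onset_temp <= hi:
            raise ValueError(
                f"deterministic onset temperature {onset_temp} degC outside the "
                f"stimulus range [{lo:.3g}, {hi:.3g}]"
            )
        onset_idx = int(np.argmax(temps >= onset_temp))
        kernel[onset_idx:] += params.event_amplitude  # sustained step response
        kernel_onsets.append(times[onset_idx])
    else:
        rate = params.event_rate_base + params.event_rate_temp_gain * np.maximum(
            0.0, temps - params.temp_threshold
        )
        # inhomogeneous Poisson thinned to per-frame Bernoulli (rate*dt << 1);
        # onsets restricted to after the baseline window
        hits = rng.random(n) < rate * dt
        hits[:baseline_frames] = False
        for i in np.flatnonzero(hits):
            kernel[i:] += params.event_amplitude * np.exp(
                -(times[i:] - times[i]) / params.event_decay_tau
            )
            kernel_onsets.append(times[i])

    bleach = (
        np.ones(n)
        if math.isinf(params.bleach_tau)
        else np.exp(-times / params.bleach_tau)
    )
    clean = params.baseline_F0 * bleach * (1.0 + kernel)
    noise = (
        rng.normal(0.0, params.noise_sd * params.baseline_F0, n)
        if params.noise_sd > 0
        else np.zeros(n)
    )
    fluor = clean + noise

    # ground truth: suprathreshold set of the noiseless dF/F
    b0 = float(np.mean(clean[:baseline_frames]))
    dff_clean = 100.0 * (clean - b0) / b0
    mask = dff_clean > params.truth_threshold_dff
    truth = GroundTruth(
        meta={
            "params": params,
            "stimulus": stimulus,
            "kernel_onsets": kernel_onsets,
            "programmed_onset_temp": params.deterministic_onset_temp,
        }
    )
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            truth.events.append(
                {
                    "onset_time": float(times[i]),
                    "offset_time": float(times[i] + (j + 1 - i) * dt),
                    "onset_temperature": float(temps[i]),
                }
            )
            i = j + 1
        else:
            i += 1
    truth.validate(params.duration + dt)

    trace = CalciumTrace(
        neuron_id=f"sim{params.seed:06d}",
        times=times,
        fluorescence=fluor,
        temperature=temps,
        frame_rate=params.frame_rate,
    )
    return trace, truth


# --- named presets -------------------------------------------------------

_FED = SimulationConfig(
    speed_mean=0.117,
    base_turn_rate=1.0 / 30.0,
    klinokinesis_gain=0.7,
    post_turn_bias=0.6,
    post_turn_concentration=2.0,
    reversal_prob=0.2,
)
_STARVED = SimulationConfig(
    speed_mean=0.106,
    base_turn_rate=1.0 / 15.0,
    klinokinesis_gain=0.0,
    post_turn_bias=0.0,
    post_turn_concentration=0.0,
    reversal_prob=0.3,
)

_CALCIUM = {
    # AFD: deterministic threshold (step) response slightly above the
    # 20 degC cultivation temperature, large sustained amplitude
    "afd_like": CalciumSimParams(
        deterministic_onset_temp=21.0,
        event_amplitude=1.5,
        noise_sd=0.02,
    ),
    # AWC fed: sparse stochastic transients, indifferent to temperature
    "awc_fed_like": CalciumSimParams(
        event_rate_base=0.008,
        event_rate_temp_gain=0.0,
        event_amplitude=0.25,
        event_decay_tau=3.0,
    ),
    # AWC starved: response probability grows with temperature above the
    # assay range floor, and individual events last longer
    "awc_starved_like": CalciumSimParams(
        event_rate_base=0.008,
        event_rate_temp_gain=0.010,
        temp_threshold=23.0,
        event_amplitude=0.25,
        event_decay_tau=8.0,
    ),
    # AIA fed: frequent events merging into tonic activity
    "aia_fed_like": CalciumSimParams(
        event_rate_base=0.05,
        event_amplitude=0.30,
        event_decay_tau=10.0,
    ),
    # AIA starved: activity suppressed
    "aia_starved_like": CalciumSimParams(
        event_rate_base=0.003,
        event_amplitude=0.20,
        event_decay_tau=3.0,
    ),
}

_PRESETS: Dict[str, Tuple[SimulationConfig, CalciumSimParams]] = {
    "fed": (_FED, _CALCIUM["awc_fed_like"]),
    "starved": (_STARVED, _CALCIUM["awc_starved_like"]),
    # starved worms whose AWC neurons are silenced navigate like fed worms
    "starved_awc_silenced": (
        replace(_STARVED, klinokinesis_gain=0.7, post_turn_bias=0.6,
                post_turn_concentration=2.0, base_turn_rate=1.0 / 30.0),
        _CALCIUM["awc_fed_like"],
    ),
    "afd_like": (_FED, _CALCIUM["afd_like"]),
    "awc_fed_like": (_FED, _CALCIUM["awc_fed_like"]),
    "awc_starved_like": (_STARVED, _CALCIUM["awc_starved_like"]),
    "aia_fed_like": (_FED, _CALCIUM["aia_fed_like"]),
    "aia_starved_like": (_STARVED, _CALCIUM["aia_starved_like"]),
}


def preset_names() -> List[str]:
    return sorted(_PRESETS)


def preset(name: str) -> Tuple[SimulationConfig, CalciumSimParams]:
    """Named (behavior, calcium) parameter bundle for a study condition.

    Behavior-centric presets (``fed``, ``starved``, ``starved_awc_silenced``)
    pair their navigation parameters with the matching AWC calcium style;
    neuron-centric presets pair their calcium parameters with the matching
    feeding-state navigation.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid names: {', '.join(preset_names())}"
        ) from None


def default_ramp(kind: str = "afd") -> TemperatureRamp:
    """Standard imaging stimuli: 0.05 degC/s rising ramps.

    ``afd``: 16 -> 28 degC over the full 4-min trace.  ``awc``: 23 -> 28
    degC (the short-gradient assay range) then plateau.  ``constant``:
    20 degC throughout.
    """
    if kind == "afd":
        return TemperatureRamp(start_temp=16.0, rate=0.05, duration=240.0)
    if kind == "awc":
        return TemperatureRamp(start_temp=23.0, rate=0.05, duration=100.0)
    if kind == "constant":
        return TemperatureRamp(start_temp=20.0, rate=0.0, duration=240.0)
    raise ValueError(f"unknown ramp kind {kind!r}; use 'afd', 'awc' or 'constant'")
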