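"""Seeded synthetic hip/wrist accelerometry for toddler behaviors.

The generator emulates the kind of 30 Hz, ±6 g triaxial recordings an
ActiGraph-style device produces while a toddler performs one of nine
behaviors (run, walk, crawl, climb, ride-on toy, stand, sit, stroller,
carried), plus the auxiliary "bounce" and short "transition" segments.

Signal model
------------
Each bout is a sum-of-harmonics oscillation in a world frame — a vertical
gait component, a fore–aft component and a lateral sway at half the step
frequency — rotated into the device frame by a per-behavior trunk pitch
(``gravity_pitch``), with gravity carried along so a static posture always
averages to 1 g vector magnitude.  White sensor/impact noise is added per
axis, an optional low-pass smooths the result ("carried" rides the
caregiver's gait low-pass filtered through their body), and samples are
clipped to the device range.

Key behavior signatures:

* **carried** — adult-cadence (~1.9 Hz) oscillation low-pass filtered at
  3 Hz plus carrier sway: moderate amplitude, spectrally smooth.
* **crawl** — trunk pitched ~90°, so gravity leaves the vertical device
  axis and the large fore–aft motion appears on it instead.
* **ride-on toy** — a per-bout two-mode mixture: vigorous upper-body
  bouncing vs. quiet feet-propulsion.
* **stand / sit / stroller** — near-quiescent: the dynamic component is the
  noise floor.

The wrist stream is an attenuated copy of the hip dynamic signal plus
independent seeded arm-motion bursts (toy play, wiggling), which makes
wrist data noisier than hip data, as wrist-worn recordings tend to be.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import (
    AccelTrace,
    BehaviorLabel,
    LabelTrack,
    PRESCRIBED_BEHAVIORS,
    UnknownBehaviorError,
    check_behavior,
)

__all__ = [
    "BehaviorParams",
    "SimulationParams",
    "BoutSchedule",
    "default_params",
    "simulate_bout",
    "simulate_session",
    "perturb_labels",
    "study_schedule",
    "CONFUSABLE",
]


@dataclass(frozen=True)
class BehaviorParams:
    """Oscillation settings for one behavior.

    Amplitudes in g, frequencies in Hz, ``gravity_pitch`` in degrees of
    trunk pitch from upright (90° = trunk horizontal, as in crawling).
    ``harmonic_weights`` scale the fundamental and its overtones.
    ``arm_activity`` scales the probability of independent wrist bursts.
    """

    fundamental_freq: float = 0.0
    vertical_amp: float = 0.0
    horizontal_amp: float = 0.0
    harmonic_weights: tuple[float, ...] = (1.0, 0.4, 0.2)
    gravity_pitch: float = 0.0
    noise_sd: float = 0.02
    smoothing_cutoff: float | None = None
    arm_activity: float = 1.0
    fidget_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.fundamental_freq < 0:
            raise ValueError("fundamental_freq must be >= 0")
        if self.vertical_amp < 0 or self.horizontal_amp < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimulationParams:
    """Complete generator configuration.

    ``behaviors`` maps every simulatable label to its
    :class:`BehaviorParams`; ``ride_on_toy`` has a second, quiet
    parameterization under ``ride_on_toy_quiet`` used by the two-mode
    mixture.  ``wrist_coupling`` attenuates the hip dynamic signal at the
    wrist; ``wrist_arm_amp`` sets the independent arm-burst amplitude.
    """

    behaviors: dict[str, BehaviorParams] = field(default_factory=dict)
    wrist_coupling: float = 0.6
    wrist_arm_amp: float = 0.35
    wrist_pitch: float = 40.0
    sample_rate: float = 30.0
    clip_range: float = 6.0
    transition_s: float = 1.0
    ride_on_quiet_prob: float = 0.5
    freq_jitter_cv: float = 0.06
    amp_jitter_cv: float = 0.20
    envelope_depth: float = 0.20
    subject_amp_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.clip_range <= 0:
            raise ValueError("clip_range must be positive")
        if self.wrist_coupling < 0 or self.wrist_arm_amp < 0:
            raise ValueError("wrist coupling parameters must be >= 0")

    def for_behavior(self, behavior: str) -> BehaviorParams:
        check_behavior(behavior)
        try:
            return self.behaviors[behavior]
        except KeyError:
            raise UnknownBehaviorError(behavior) from None


def default_params() -> SimulationParams:
    """Default generator settings for the nine behaviors plus "bounce".

    Amplitudes and cadences are calibrated so that emulated hip vertical
    activity-count medians reproduce the qualitative ordering seen in
    playroom recordings: stand/sit/stroller << walk < carried < crawl,
    with running and bouncing the most energetic.
    """
    behaviors = {
        # Toddler gait: fast cadence, modest vertical excursion.
        "walk": BehaviorParams(2.0, 0.16, 0.10, (1.0, 0.45, 0.2), 0.0, 0.05),
        "run": BehaviorParams(2.4, 0.85, 0.45, (1.0, 0.5, 0.3), 5.0, 0.10),
        # Hands-and-knees: trunk horizontal, large fore-aft rocking.
        "crawl": BehaviorParams(1.0, 0.25, 1.05, (1.0, 0.5, 0.25), 90.0, 0.06),
        "climb": BehaviorParams(1.4, 0.40, 0.30, (1.0, 0.5, 0.25), 15.0, 0.07),
        # Bouncy riding mode (mode 2, quiet feet, is below).
        "ride_on_toy": BehaviorParams(1.2, 0.50, 0.30, (1.0, 0.4, 0.15), 5.0, 0.06),
        "ride_on_toy_quiet": BehaviorParams(1.2, 0.04, 0.06, (1.0, 0.3, 0.0), 5.0, 0.03),
        "stand": BehaviorParams(0.0, 0.0, 0.0, (1.0,), 0.0, 0.015, None, 0.6),
        "sit": BehaviorParams(0.0, 0.0, 0.0, (1.0,), 20.0, 0.012, None, 1.2),
        "stroller": BehaviorParams(0.0, 0.0, 0.0, (1.0,), 30.0, 0.020, None, 0.2),
        # Adult gait transmitted through the carrier's body: adult cadence,
        # low-pass smoothed, spectrally much cleaner than self-ambulation —
        # except when the child fidgets in the carrier's arms (fidget_amp).
        "carried": BehaviorParams(1.9, 0.42, 0.18, (1.0, 0.25, 0.0), 10.0, 0.015, 3.0, 0.5, 0.12),
        "bounce": BehaviorParams(2.2, 1.60, 0.40, (1.0, 0.5, 0.3), 0.0, 0.12),
        "transition": BehaviorParams(1.0, 0.10, 0.10, (1.0, 0.3), 10.0, 0.05),
    }
    return SimulationParams(behaviors=behaviors)


@dataclass(frozen=True)
class BoutSchedule:
    """An ordered plan of (behavior, duration_s) bouts for one participant."""

    participant_id: str
    bouts: tuple[tuple[str, float], ...]
    session_start_time: float = 0.0

    def __post_init__(self) -> None:
        for behavior, duration in self.bouts:
            check_behavior(behavior)
            if duration <= 0:
                raise ValueError(f"bout duration must be > 0, got {duration} for {behavior}")
            if abs(duration - round(duration)) > 1e-9:
                raise ValueError("bout durations must be whole seconds (1-s label resolution)")

    @property
    def total_bout_seconds(self) -> float:
        return float(sum(d for _, d in self.bouts))


def _harmonic_series(
    n: int, sample_rate: float, freq: float, amp: float,
    weights: tuple[float, ...], phases: np.ndarray,
) -> np.ndarray:
    t = np.arange(n) / sample_rate
    out = np.zeros(n)
    if freq <= 0 or amp <= 0:
        return out
    for k, (w, ph) in enumerate(zip(weights, phases), start=1):
        out += w * np.sin(2 * math.pi * k * freq * t + ph)
    return amp * out


def _hip_components(
    n: int, params: SimulationParams, bp: BehaviorParams,
    rng: np.random.Generator, amp_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (static gravity (3,), dynamic signal (n, 3)) in the device frame.

    Each bout draws its own cadence and amplitude around the behavior's
    nominal values (no two walks — or two caregivers — move identically),
    and a slow seeded envelope modulates the amplitude within the bout.
    """
    nharm = len(bp.harmonic_weights)
    ph_v = rng.uniform(0, 2 * math.pi, nharm)
    ph_h = rng.uniform(0, 2 * math.pi, nharm)
    ph_l = rng.uniform(0, 2 * math.pi)
    freq = bp.fundamental_freq * math.exp(rng.normal(0, params.freq_jitter_cv))
    amp_factor = amp_scale * math.exp(rng.normal(0, params.amp_jitter_cv))

    v = _harmonic_series(n, params.sample_rate, freq,
                         amp_factor * bp.vertical_amp, bp.harmonic_weights, ph_v)
    h = _harmonic_series(n, params.sample_rate, freq,
                         amp_factor * bp.horizontal_amp, bp.harmonic_weights, ph_h)
    # Lateral sway alternates with steps: half the step frequency.
    t = np.arange(n) / params.sample_rate
    lat = (0.4 * amp_factor * bp.horizontal_amp
           * np.sin(2 * math.pi * 0.5 * freq * t + ph_l))
    if params.envelope_depth > 0 and n > 1:
        sos = sps.butter(2, 0.3, btype="low", fs=params.sample_rate, output="sos")
        slow = sps.sosfilt(sos, rng.normal(0, 1, n))
        sd = slow.std()
        env = 1.0 + params.envelope_depth * (slow / sd if sd > 0 else slow)
        env = np.clip(env, 0.2, 2.0)
        v, h, lat = v * env, h * env, lat * env

    p = math.radians(bp.gravity_pitch)
    static = np.array([math.cos(p), 0.0, math.sin(p)])  # axis1, axis2, axis3
    dynamic = np.empty((n, 3))
    dynamic[:, 0] = math.cos(p) * v + math.sin(p) * h
    dynamic[:, 1] = lat
    dynamic[:, 2] = math.sin(p) * v - math.cos(p) * h

    dynamic += rng.normal(0.0, bp.noise_sd, size=(n, 3))
    return static, dynamic


def _smooth(x: np.ndarray, cutoff: float | None, sample_rate: float) -> np.ndarray:
    if cutoff is None or cutoff >= sample_rate / 2:
        return x
    sos = sps.butter(4, cutoff, btype="low", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def _arm_bursts(
    n: int, sample_rate: float, amp: float, activity: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent wrist motion: band-limited noise gated second-by-second."""
    if amp <= 0 or activity <= 0:
        return np.zeros((n, 3))
    raw = rng.normal(0.0, 1.0, size=(n, 3))
    sos = sps.butter(2, 4.0, btype="low", fs=sample_rate, output="sos")
    smooth = sps.sosfilt(sos, raw, axis=0)
    rms = np.sqrt(np.mean(smooth**2))
    if rms > 0:
        smooth *= amp / rms
    # On/off envelope per second: toddlers fidget in bursts, not continuously.
    n_sec = int(np.ceil(n / sample_rate))
    gate_prob = min(1.0, 0.35 * activity)
    gate = rng.random(n_sec) < gate_prob
    env = np.repeat(gate.astype(float), int(round(sample_rate)))[:n]
    return smooth * env[:, None]


def _fidget(
    n: int, sample_rate: float, amp: float, rng: np.random.Generator
) -> np.ndarray:
    """Self-motion of a held/seated child: short oscillation at toddler
    cadence, amplitude drawn per bout (often near zero, sometimes vigorous).
    Unlike the carrier's gait it is NOT smoothed by an adult's body."""
    if amp <= 0:
        return np.zeros((n, 3))
    bout_amp = abs(rng.normal(0.0, amp))
    freq = 2.3 * math.exp(rng.normal(0, 0.15))
    phases = rng.uniform(0, 2 * math.pi, 3)
    t = np.arange(n) / sample_rate
    mix = np.array([1.0, 0.5, 0.7])
    sig = bout_amp * mix[None, :] * np.sin(
        2 * math.pi * freq * t[:, None] + phases[None, :]
    )
    return sig + rng.normal(0, 0.25 * bout_amp, size=(n, 3))


def _resolve_bout_params(
    behavior: str, params: SimulationParams, rng: np.random.Generator
) -> BehaviorParams:
    """Per-bout parameter choice; ride-on toy mixes two riding modes."""
    bp = params.for_behavior(behavior)
    if behavior == "ride_on_toy" and "ride_on_toy_quiet" in params.behaviors:
        if rng.random() < params.ride_on_quiet_prob:
            bp = params.behaviors["ride_on_toy_quiet"]
    return bp


def simulate_bout(
    behavior: str,
    duration_s: float,
    site: str,
    params: SimulationParams | None = None,
    seed: int = 0,
    start_time: float = 0.0,
    amp_scale: float = 1.0,
) -> AccelTrace:
    """Simulate one behavior bout at one wear site.

    The same ``seed`` yields sample-aligned hip and wrist traces (the wrist
    is derived from the identical hip core plus an independent arm stream),
    and repeated calls are bit-identical.
    """
    if params is None:
        params = default_params()
    check_behavior(behavior)
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * params.sample_rate))

    ss = np.random.SeedSequence(seed)
    core_ss, arm_ss = ss.spawn(2)
    core_rng = np.random.default_rng(core_ss)

    bp = _resolve_bout_params(behavior, params, core_rng)
    static, dynamic = _hip_components(n, params, bp, core_rng, amp_scale)
    # Drawn from the core stream so hip and wrist calls stay aligned.
    fidget = _fidget(n, params.sample_rate, bp.fidget_amp, core_rng)
    if site == "hip":
        samples = static[None, :] + dynamic
        samples = _smooth(samples, bp.smoothing_cutoff, params.sample_rate)
        samples = samples + fidget
    elif site == "wrist":
        arm_rng = np.random.default_rng(arm_ss)
        p = math.radians(params.wrist_pitch)
        wrist_static = np.array([math.cos(p), 0.0, math.sin(p)])
        arm = _arm_bursts(n, params.sample_rate, params.wrist_arm_amp,
                          bp.arm_activity, arm_rng)
        samples = wrist_static[None, :] + params.wrist_coupling * dynamic
        samples = _smooth(samples, bp.smoothing_cutoff, params.sample_rate)
        samples = samples + params.wrist_coupling * fidget + arm
    else:
        raise ValueError(f"site must be 'hip' or 'wrist', got {site!r}")

    samples = np.clip(samples, -params.clip_range, params.clip_range)
    return AccelTrace(site=site, sample_rate=params.sample_rate,
                      samples=samples, start_time=start_time)


def simulate_session(
    schedule: BoutSchedule,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> tuple[AccelTrace, AccelTrace, LabelTrack]:
    """Simulate a full labeled session: aligned hip and wrist traces.

    Bouts are concatenated with short seeded "transition" segments between
    them (labeled as such, so downstream label filters exercise their
    exclusion path).  The returned label track exactly tiles the session.
    """
    if params is None:
        params = default_params()
    if not schedule.bouts:
        raise ValueError("schedule must contain at least one bout")

    segments: list[tuple[str, float]] = []
    for i, (behavior, duration) in enumerate(schedule.bouts):
        if i > 0 and params.transition_s > 0:
            segments.append(("transition", params.transition_s))
        segments.append((behavior, duration))

    ss = np.random.SeedSequence(seed)
    subject_ss, *children = ss.spawn(len(segments) + 1)
    # Per-subject body-size/vigor factor: smaller toddlers shake the
    # device less at the same behavior.
    subject_rng = np.random.default_rng(subject_ss)
    amp_scale = math.exp(subject_rng.normal(0, params.subject_amp_cv))

    hip_parts, wrist_parts, labels = [], [], []
    t = schedule.session_start_time
    for (behavior, duration), child in zip(segments, children):
        seg_seed = int(child.generate_state(1)[0] % (2**31))
        hip = simulate_bout(behavior, duration, "hip", params, seg_seed,
                            start_time=t, amp_scale=amp_scale)
        wrist = simulate_bout(behavior, duration, "wrist", params, seg_seed,
                              start_time=t, amp_scale=amp_scale)
        hip_parts.append(hip.samples)
        wrist_parts.append(wrist.samples)
        labels.append(BehaviorLabel(behavior, t, t + duration, coder_id="truth"))
        t += duration

    hip_trace = AccelTrace("hip", params.sample_rate, np.vstack(hip_parts),
                           start_time=schedule.session_start_time)
    wrist_trace = AccelTrace("wrist", params.sample_rate, np.vstack(wrist_parts),
                             start_time=schedule.session_start_time)
    track = LabelTrack(schedule.participant_id, labels)
    return hip_trace, wrist_trace, track


#: Which behavior a coder most plausibly confuses each label with.
CONFUSABLE = {
    "stand": "transition",
    "walk": "stand",
    "run": "walk",
    "crawl": "climb",
    "climb": "crawl",
    "sit": "stand",
    "stroller": "sit",
    "carried": "walk",
    "ride_on_toy": "sit",
    "bounce": "run",
    "transition": "stand",
    "other": "transition",
}


def perturb_labels(
    track: LabelTrack,
    shift_sd_s: float,
    confusion_rate: float,
    seed: int = 0,
) -> LabelTrack:
    """Emulate coder error: jitter boundaries, swap a fraction of labels.

    Boundary shifts are Gaussian with SD ``shift_sd_s``, rounded to whole
    seconds (coders annotate at 1-s resolution); each label is swapped to
    its confusable counterpart with probability ``confusion_rate``.
    Interval validity (ordering, non-overlap, positive duration) is
    repaired after jittering.
    """
    if shift_sd_s < 0:
        raise ValueError("shift_sd_s must be >= 0")
    if not 0 <= confusion_rate <= 1:
        raise ValueError("confusion_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)

    new_labels = []
    prev_end = -math.inf
    for label in track:
        if shift_sd_s > 0:
            ds = float(round(rng.normal(0, shift_sd_s)))
            de = float(round(rng.normal(0, shift_sd_s)))
        else:
            ds = de = 0.0
        start = max(label.start_time + ds, prev_end)
        end = max(label.end_time + de, start + 1.0)
        behavior = label.behavior
        if confusion_rate > 0 and rng.random() < confusion_rate:
            behavior = CONFUSABLE[behavior]
        new_labels.append(replace(label, behavior=behavior, start_time=start, end_time=end))
        prev_end = end
    return LabelTrack(track.participant_id, new_labels)


def study_schedule(participant_id: str, seed: int = 0) -> BoutSchedule:
    """A randomized playroom-style session plan for one participant.

    Mirrors the structure of a caregiver-led indoor play trial: walking is
    by far the most frequent behavior, carried/run/crawl/climb occur a few
    times each, and quiescent postures fill the gaps.  Bout durations are
    drawn around typical label durations (roughly 8–15 s) so that most
    bouts survive the minimum-duration filter and yield feature windows,
    with "carried" contributing roughly an eighth of the windows.
    """
    rng = np.random.default_rng(seed)

    def dur(mean: float, lo: int, hi: int) -> int:
        return int(np.clip(round(rng.normal(mean, 2.5)), lo, hi))

    bouts: list[tuple[str, float]] = []
    bouts += [("walk", dur(12, 8, 19)) for _ in range(8)]
    bouts += [("run", dur(12, 8, 17)) for _ in range(2)]
    bouts += [("crawl", dur(12, 8, 17)) for _ in range(2)]
    bouts += [("climb", dur(12, 8, 17)) for _ in range(2)]
    bouts += [("carried", dur(13, 9, 18)) for _ in range(2)]
    bouts += [("ride_on_toy", dur(10, 6, 16)) for _ in range(2)]
    bouts += [("stand", dur(8, 5, 14)) for _ in range(3)]
    bouts += [("sit", dur(12, 6, 20)) for _ in range(3)]
    bouts += [("stroller", dur(11, 6, 18)) for _ in range(2)]
    order = rng.permutation(len(bouts))
    bouts = [bouts[i] for i in order]
    return BoutSchedule(participant_id, tuple((b, float(d)) for b, d in bouts))
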