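"""Core data model shared across the pipeline.

Axis convention (ActiGraph device frame):

* ``axis1`` — vertical (the conventional *y* axis),
* ``axis2`` — horizontal / medio-lateral (*x*),
* ``axis3`` — perpendicular / antero-posterior (*z*).

Times are kept as plain floats in seconds on a single session clock
(0 = session start); the CSV writers translate to ISO-8601 wall-clock
timestamps for interchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The nine prescribed toddler behaviors.
PRESCRIBED_BEHAVIORS = (
    "run",
    "walk",
    "crawl",
    "climb",
    "ride_on_toy",
    "stand",
    "sit",
    "stroller",
    "carried",
)

#: Auxiliary labels the coding scheme also produces.
AUXILIARY_BEHAVIORS = ("bounce", "transition", "other")

#: Full label vocabulary.
BEHAVIOR_VOCABULARY = PRESCRIBED_BEHAVIORS + AUXILIARY_BEHAVIORS

#: Behaviors pooled into the "ambulation" class for the binary classifier.
AMBULATION_BEHAVIORS = ("run", "walk", "crawl", "climb")

#: Behaviors eligible for 5-s feature windows (carried + ambulation).
WINDOW_BEHAVIORS = ("carried",) + AMBULATION_BEHAVIORS

SITES = ("hip", "wrist")


class UnknownBehaviorError(ValueError):
    """Raised when a behavior label is outside the coding vocabulary."""

    def __init__(self, behavior: str):
        super().__init__(
            f"unknown behavior {behavior!r}; expected one of {BEHAVIOR_VOCABULARY}"
        )
        self.behavior = behavior


def check_behavior(behavior: str) -> str:
    if behavior not in BEHAVIOR_VOCABULARY:
        raise UnknownBehaviorError(behavior)
    return behavior


@dataclass
class AccelTrace:
    """A uniformly sampled triaxial acceleration stream for one wear site.

    ``samples`` is an (n, 3) float array in g, columns ordered
    (axis1 vertical, axis2 horizontal, axis3 perpendicular).
    """

    site: str
    sample_rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if len(self.samples) == 0:
            raise ValueError("trace must be non-empty")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        """Per-sample timestamps (seconds, session clock)."""
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def slice_seconds(self, start: float, end: float) -> np.ndarray:
        """Samples in the half-open interval [start, end) of the session clock."""
        i0 = int(round((start - self.start_time) * self.sample_rate))
        i1 = int(round((end - self.start_time) * self.sample_rate))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        return self.samples[i0:i1]


@dataclass(frozen=True)
class BehaviorLabel:
    """One coded behavior interval, half-open [start_time, end_time), whole seconds."""

    behavior: str
    start_time: float
    end_time: float
    coder_id: str = "coder1"
    clipped: bool = False

    def __post_init__(self) -> None:
        check_behavior(self.behavior)
        if self.end_time <= self.start_time:
            raise ValueError(
                f"label {self.behavior!r}: end_time ({self.end_time}) must exceed "
                f"start_time ({self.start_time})"
            )
        for t in (self.start_time, self.end_time):
            if abs(t - round(t)) > 1e-9:
                raise ValueError(f"label times must be whole seconds, got {t}")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    def shifted(self, offset_s: float) -> "BehaviorLabel":
        return replace(
            self, start_time=self.start_time + offset_s, end_time=self.end_time + offset_s
        )


@dataclass
class LabelTrack:
    """Ordered, non-overlapping behavior annotations for one participant/coder."""

    participant_id: str
    labels: list[BehaviorLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = sorted(self.labels, key=lambda l: l.start_time)
        for a, b in zip(self.labels, self.labels[1:]):
            if b.start_time < a.end_time - 1e-9:
                raise ValueError(
                    f"overlapping labels: {a.behavior} [{a.start_time}, {a.end_time}) "
                    f"and {b.behavior} [{b.start_time}, {b.end_time})"
                )

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    @property
    def start_time(self) -> float:
        return self.labels[0].start_time if self.labels else 0.0

    @property
    def end_time(self) -> float:
        return self.labels[-1].end_time if self.labels else 0.0


def trimmed_interval(label: BehaviorLabel) -> tuple[float, float]:
    """Drop the first and last second of a label.

    Coders mark boundaries to the second, so the edge seconds may mix in
    transitional movement; only the interior is treated as pure behavior.
    Returns an empty interval (start >= end) for labels of <= 2 s.
    """
    return label.start_time + 1.0, label.end_time - 1.0
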