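"""Activity counts: an open epoch-count algorithm, per-behavior count
rates, and intensity cut-points.

Commercial actigraphy software computes "activity counts" with a
proprietary pipeline; this module implements a documented open analogue:

1. band-pass Butterworth filter, 0.25–2.5 Hz, per axis (removes the
   gravity/orientation DC component and high-frequency jitter, keeping the
   human-movement band);
2. rectify;
3. dead-band: sub-threshold magnitudes contribute nothing;
4. clip at the dynamic ceiling and quantize to integer sensor steps;
5. sum the per-sample steps within each epoch.

Because quantization is per sample, counts are exactly additive across
epoch boundaries (1-s counts summed in fives equal 5-s counts).  Absolute
values are on this algorithm's own scale — comparisons with counts from
proprietary software are meaningful only ordinally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import AccelTrace, LabelTrack, trimmed_interval

__all__ = [
    "EpochCounts",
    "CutPointSet",
    "compute_counts",
    "behavior_count_rate",
    "convert_cutpoint",
    "classify_intensity",
    "builtin_cutpoints",
    "MEASURES",
]

#: Count measures reported per behavior.
MEASURES = ("axis1", "axis2", "axis3", "vm")

# Band and quantization constants of the open count algorithm.
BAND_HZ = (0.25, 2.5)
DEADBAND_G = 0.05
CEILING_G = 2.13
STEP_G = 1.0 / 64.0  # one count per 1/64 g of rectified filtered signal

MIN_SAMPLE_RATE = 10.0  # Hz; the band-pass design needs Nyquist > 2.5 Hz


@dataclass
class EpochCounts:
    """Per-epoch integer activity counts for the three axes.

    ``counts`` is an (n_epochs, 3) integer array; the vector-magnitude
    series is derived on demand, never stored.
    """

    epoch_length: float
    counts: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise ValueError("counts must be an (n, 3) array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_epochs(self) -> int:
        return len(self.counts)

    @property
    def vm(self) -> np.ndarray:
        """Per-epoch vector magnitude √(axis1² + axis2² + axis3²)."""
        return np.sqrt(np.sum(self.counts.astype(float) ** 2, axis=1))

    def epoch_times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_epochs) * self.epoch_length

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=["axis1", "axis2", "axis3"])
        df.insert(0, "timestamp", self.epoch_times())
        df["vm"] = self.vm
        return df


def compute_counts(trace: AccelTrace, epoch_length_s: float = 5.0) -> EpochCounts:
    """Convert a raw trace to per-epoch activity counts.

    A trailing partial epoch is dropped.  Counts are monotone
    non-decreasing in input oscillation amplitude within the pass band.
    """
    if epoch_length_s <= 0:
        raise ValueError("epoch_length_s must be positive")
    if trace.sample_rate < MIN_SAMPLE_RATE:
        raise ValueError(
            f"sample_rate {trace.sample_rate} Hz unsupported: the "
            f"{BAND_HZ[0]}-{BAND_HZ[1]} Hz band-pass requires >= {MIN_SAMPLE_RATE} Hz"
        )
    sos = sps.butter(4, BAND_HZ, btype="bandpass", fs=trace.sample_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.samples, axis=0)
    rect = np.abs(filtered)
    rect[rect < DEADBAND_G] = 0.0
    rect = np.minimum(rect, CEILING_G)
    steps = np.floor(rect / STEP_G).astype(np.int64)

    per_epoch = int(round(epoch_length_s * trace.sample_rate))
    if per_epoch <= 0:
        raise ValueError("epoch shorter than one sample")
    n_epochs = len(steps) // per_epoch
    trimmed = steps[: n_epochs * per_epoch]
    counts = trimmed.reshape(n_epochs, per_epoch, 3).sum(axis=1)
    return EpochCounts(epoch_length=epoch_length_s, counts=counts,
                       start_time=trace.start_time)


def behavior_count_rate(
    counts: EpochCounts,
    labels: LabelTrack,
    participant_id: str | None = None,
    site: str | None = None,
) -> pd.DataFrame:
    """Per-behavior count rates (counts per 5 s) for one participant.

    For each behavior, epoch counts over all of its labels' trimmed
    intervals (first and last labeled second excluded) are summed, divided
    by the total trimmed seconds, and multiplied by five.  Requires epochs
    that align with whole-second label boundaries (use 1-s epochs).

    Returns a tidy frame with columns
    ``participant, behavior, site, measure, rate, seconds``.
    """
    if participant_id is None:
        participant_id = labels.participant_id
    epoch_starts = counts.epoch_times()
    end_of_counts = counts.start_time + counts.n_epochs * counts.epoch_length

    sums: dict[str, np.ndarray] = {}
    seconds: dict[str, float] = {}
    for label in labels:
        t0, t1 = trimmed_interval(label)
        if t1 <= t0:
            continue
        if label.start_time < counts.start_time - 1e-9 or label.end_time > end_of_counts + 1e-9:
            raise ValueError(
                f"label {label.behavior!r} [{label.start_time}, {label.end_time}) "
                f"outside count range [{counts.start_time}, {end_of_counts})"
            )
        mask = (epoch_starts >= t0 - 1e-9) & (epoch_starts + counts.epoch_length <= t1 + 1e-9)
        sel = counts.counts[mask]
        vm_sel = counts.vm[mask]
        prev = sums.get(label.behavior)
        axis_sum = sel.sum(axis=0)
        vm_sum = vm_sel.sum()
        row = np.append(axis_sum.astype(float), vm_sum)
        sums[label.behavior] = row if prev is None else prev + row
        seconds[label.behavior] = seconds.get(label.behavior, 0.0) + (t1 - t0)

    records = []
    for behavior, row in sums.items():
        secs = seconds[behavior]
        for measure, total in zip(MEASURES, row):
            records.append({
                "participant": participant_id,
                "behavior": behavior,
                "site": site,
                "measure": measure,
                "rate": total / secs * 5.0,
                "seconds": secs,
            })
    return pd.DataFrame.from_records(
        records, columns=["participant", "behavior", "site", "measure", "rate", "seconds"]
    )


def convert_cutpoint(threshold_counts: float, from_epoch_s: float, to_epoch_s: float) -> int:
    """Rescale a count threshold between epoch lengths.

    Counts accumulate linearly with epoch duration, so the threshold
    scales by ``to/from`` and is rounded to the nearest integer count —
    e.g. a 419 counts/15 s bound becomes 140 counts/5 s.
    """
    if from_epoch_s <= 0 or to_epoch_s <= 0:
        raise ValueError("epoch lengths must be positive")
    return int(round(threshold_counts * to_epoch_s / from_epoch_s))


@dataclass(frozen=True)
class CutPointSet:
    """Ordered intensity classes with inclusive lower count bounds."""

    name: str
    epoch_length: float
    thresholds: tuple[tuple[str, float], ...]  # (class, inclusive lower bound)
    axis: str = "vertical"

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        bounds = [b for _, b in self.thresholds]
        if not bounds or bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
            raise ValueError("thresholds must have strictly increasing bounds")
        if bounds[0] != 0:
            raise ValueError("lowest class must start at 0 counts")


def builtin_cutpoints() -> dict[str, CutPointSet]:
    """Published cut-points, normalized to 5-s epochs.

    * ``toddler_hip_va_5s`` — toddler hip vertical axis: MVPA at
      ≥419 counts/15 s → 140 counts/5 s; the light/sedentary boundary is
      set at 5 counts/5 s, the ceiling observed for quiescent postures
      (stand/sit/stroller) in toddler playroom data.
    * ``child_wrist_va_5s`` / ``child_wrist_vm_5s`` — school-age wrist
      sedentary bounds, ≤1756 vertical counts/min → 146/5 s and
      ≤3958 VM counts/min → 330/5 s.
    """
    mvpa_5s = convert_cutpoint(419, 15, 5)
    wrist_va = convert_cutpoint(1756, 60, 5)
    wrist_vm = convert_cutpoint(3958, 60, 5)
    return {
        "toddler_hip_va_5s": CutPointSet(
            "toddler_hip_va_5s", 5.0,
            (("sedentary", 0), ("light", 5), ("mvpa", mvpa_5s)), "vertical"),
        "child_wrist_va_5s": CutPointSet(
            "child_wrist_va_5s", 5.0,
            (("sedentary", 0), ("nonsedentary", wrist_va + 1)), "vertical"),
        "child_wrist_vm_5s": CutPointSet(
            "child_wrist_vm_5s", 5.0,
            (("sedentary", 0), ("nonsedentary", wrist_vm + 1)), "vm"),
    }


def classify_intensity(rate_per_5s: float, cutpoints: CutPointSet) -> str:
    """Map a counts-per-5-s rate to its intensity class.

    Returns the class of the highest lower bound not exceeding the rate; a
    rate equal to a bound belongs to the higher class (">=" semantics).
    """
    if rate_per_5s < 0:
        raise ValueError("rate must be non-negative")
    chosen = cutpoints.thresholds[0][0]
    for cls, bound in cutpoints.thresholds:
        if rate_per_5s >= bound:
            chosen = cls
    return chosen
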