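"""Behavior-label handling: synchronization, filtering, inter-coder
agreement, and label summaries.

Labels are half-open whole-second intervals [start, end) on the session
clock.  Two coders' tracks are compared by interval overlap: a pair of
labels is matched when they overlap by more than half of the shorter
label's duration, and a matched pair is concordant when the behaviors
agree.  Unmatched labels on either side count toward the total as
discordant.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .core import (
    AccelTrace,
    BehaviorLabel,
    LabelTrack,
    PRESCRIBED_BEHAVIORS,
    check_behavior,
)

__all__ = [
    "synchronize",
    "filter_labels",
    "percent_agreement",
    "AgreementResult",
    "agreement_percent",
    "label_summary",
    "LabelSummary",
    "mean_labels_per_class",
    "mean_labels_per_participant",
    "read_label_csv",
    "write_label_csv",
]


def synchronize(trace: AccelTrace, track: LabelTrack, offset_s: float = 0.0) -> LabelTrack:
    """Shift label times by ``offset_s`` into the trace's clock and clip.

    Labels extending past the trace are clipped to the trace span and
    flagged (``label.clipped``); labels entirely outside are dropped.  A
    track with no label overlapping the trace at all is an error.
    """
    shifted = [label.shifted(offset_s) for label in track]
    aligned: list[BehaviorLabel] = []
    for label in shifted:
        start = max(label.start_time, trace.start_time)
        end = min(label.end_time, trace.end_time)
        if end <= start:
            continue
        clipped = (start != label.start_time) or (end != label.end_time)
        aligned.append(replace(label, start_time=start, end_time=end, clipped=clipped))
    if not aligned:
        raise ValueError(
            f"track for {track.participant_id!r} lies entirely outside the trace "
            f"[{trace.start_time}, {trace.end_time})"
        )
    return LabelTrack(track.participant_id, aligned)


def filter_labels(
    track: LabelTrack,
    min_duration_s: float = 5.0,
    behaviors: tuple[str, ...] = PRESCRIBED_BEHAVIORS,
) -> LabelTrack:
    """Keep only labels of the named behaviors lasting at least
    ``min_duration_s`` consecutive seconds (default: the nine prescribed
    behaviors, >= 5 s)."""
    kept = [
        label for label in track
        if label.behavior in behaviors and label.duration >= min_duration_s
    ]
    return LabelTrack(track.participant_id, kept)


@dataclass(frozen=True)
class AgreementResult:
    concordant: int
    total: int

    @property
    def fraction(self) -> float:
        return self.concordant / self.total

    @property
    def percent(self) -> int:
        """Reported percent, rounded to the nearest integer."""
        return agreement_percent(self.concordant, self.total)


def agreement_percent(concordant: int, total: int) -> int:
    """100 x concordant/total rounded to the nearest integer."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round(100.0 * concordant / total))


def _overlap(a: BehaviorLabel, b: BehaviorLabel) -> float:
    return max(0.0, min(a.end_time, b.end_time) - max(a.start_time, b.start_time))


def percent_agreement(
    track_a: LabelTrack,
    track_b: LabelTrack,
    min_overlap_frac: float = 0.5,
) -> AgreementResult:
    """Inter-coder agreement between two tracks of the same session.

    Labels are matched greedily by largest interval overlap; a match
    requires overlap exceeding ``min_overlap_frac`` of the shorter label.
    Matched pairs are concordant when behaviors agree; unmatched labels in
    either track count as discordant.  Symmetric in its arguments.
    """
    if len(track_a) == 0 or len(track_b) == 0:
        raise ValueError("both tracks must be non-empty")

    pairs = []
    for i, a in enumerate(track_a):
        for j, b in enumerate(track_b):
            ov = _overlap(a, b)
            if ov > min_overlap_frac * min(a.duration, b.duration):
                pairs.append((ov, i, j))
    # Greedy by overlap; index tie-break keeps the result order-independent.
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    concordant = 0
    matched = 0
    for ov, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched += 1
        if track_a.labels[i].behavior == track_b.labels[j].behavior:
            concordant += 1
    total = matched + (len(track_a) - matched) + (len(track_b) - matched)
    return AgreementResult(concordant=concordant, total=total)


@dataclass(frozen=True)
class LabelSummary:
    """Per-behavior label frequencies and duration statistics."""

    frequency: dict[str, int]
    mean_duration: dict[str, float]
    median_duration: dict[str, float]
    total_labels: int
    n_participants: int
    mean_per_behavior: int
    mean_per_participant: int


def mean_labels_per_class(total_labels: int, n_classes: int = len(PRESCRIBED_BEHAVIORS)) -> int:
    """Average labels per behavior class, rounded for reporting."""
    if n_classes <= 0:
        raise ValueError("n_classes must be positive")
    return int(round(total_labels / n_classes))


def mean_labels_per_participant(total_labels: int, n_participants: int) -> int:
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    return int(round(total_labels / n_participants))


def label_summary(
    tracks: list[LabelTrack],
    n_behavior_classes: int = len(PRESCRIBED_BEHAVIORS),
) -> LabelSummary:
    """Summarize filtered tracks: per-behavior frequency and duration
    stats, plus reporting means per behavior class and per participant."""
    durations: dict[str, list[float]] = {}
    participants = set()
    for track in tracks:
        participants.add(track.participant_id)
        for label in track:
            durations.setdefault(label.behavior, []).append(label.duration)

    frequency = {b: len(d) for b, d in durations.items()}
    total = sum(frequency.values())
    mean_dur = {b: float(pd.Series(d).mean()) for b, d in durations.items()}
    median_dur = {b: float(pd.Series(d).median()) for b, d in durations.items()}
    n_participants = len(participants)
    return LabelSummary(
        frequency=frequency,
        mean_duration=mean_dur,
        median_duration=median_dur,
        total_labels=total,
        n_participants=n_participants,
        mean_per_behavior=mean_labels_per_class(total, n_behavior_classes) if total else 0,
        mean_per_participant=(
            mean_labels_per_participant(total, n_participants) if n_participants else 0
        ),
    )


LABEL_COLUMNS = ["participant", "coder", "behavior", "start", "end"]


def write_label_csv(tracks: list[LabelTrack], path: str | Path) -> None:
    """Write tracks as ``participant,coder,behavior,start,end`` (seconds)."""
    rows = [
        {
            "participant": track.participant_id,
            "coder": label.coder_id,
            "behavior": label.behavior,
            "start": int(round(label.start_time)),
            "end": int(round(label.end_time)),
        }
        for track in tracks
        for label in track
    ]
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(path, index=False)


def read_label_csv(path: str | Path | io.IOBase) -> list[LabelTrack]:
    """Read a label CSV, validating the vocabulary and interval ordering.

    Returns one track per (participant, coder) pair, ordered by first
    appearance in the file.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label CSV missing columns: {sorted(missing)}")
    tracks = []
    for (participant, coder), group in df.groupby(["participant", "coder"], sort=False):
        labels = [
            BehaviorLabel(
                behavior=check_behavior(str(row.behavior)),
                start_time=float(row.start),
                end_time=float(row.end),
                coder_id=str(coder),
            )
            for row in group.itertuples()
        ]
        tracks.append(LabelTrack(str(participant), labels))
    return tracks
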