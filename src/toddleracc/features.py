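"""5-s window segmentation and the 78 window features.

Windows are non-overlapping 5-s segments (150 samples at 30 Hz) tiled
from the start of each label's trimmed interval, so every window contains
100% of a single behavior.  Each window yields exactly 78 features:

* 30 time-domain — mean, SD, median, min, max, skewness, kurtosis of each
  axis (x = horizontal axis 2, y = vertical axis 1, z = perpendicular
  axis 3; 21); mean, median, min, max, skewness, kurtosis of the
  per-sample vector magnitude (6); and the zero-lag Pearson
  cross-correlation of each axis pair xy, yz, xz (3).
* 48 frequency-domain — per axis, over the magnitude spectrum of the
  mean-subtracted signal excluding the DC bin: mean, SD, median, min,
  max, and spectral centroid (magnitude-weighted mean frequency), plus
  the magnitudes of the first 10 non-DC bins (0.2–2.0 Hz at 5-s windows).

Conventions: SDs are population (ddof=0); kurtosis is excess kurtosis;
skewness/kurtosis of a constant signal are defined as 0; a constant axis
has correlation 0 with anything.  No taper is applied before the FFT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .core import AccelTrace, LabelTrack, WINDOW_BEHAVIORS, trimmed_interval

__all__ = [
    "SignalWindow",
    "segment_windows",
    "time_domain_features",
    "freq_domain_features",
    "extract_features",
    "FEATURE_NAMES",
    "TIME_DOMAIN_NAMES",
    "FREQ_DOMAIN_NAMES",
    "META_COLUMNS",
]

#: conventional axis letters -> sample column (axis1 vertical, axis2
#: horizontal, axis3 perpendicular)
AXIS_COLUMNS = {"x": 1, "y": 0, "z": 2}
_AXES = ("x", "y", "z")

_TD_STATS = ("mean", "sd", "median", "min", "max", "skew", "kurt")
_VM_STATS = ("mean", "median", "min", "max", "skew", "kurt")
_FD_STATS = ("mean", "sd", "median", "min", "max", "centroid")
N_FFT_BINS = 10

TIME_DOMAIN_NAMES: tuple[str, ...] = tuple(
    [f"{stat}_{ax}" for ax in _AXES for stat in _TD_STATS]
    + [f"{stat}_vm" for stat in _VM_STATS]
    + ["corr_xy", "corr_yz", "corr_xz"]
)
FREQ_DOMAIN_NAMES: tuple[str, ...] = tuple(
    [f"fft_{stat}_{ax}" for ax in _AXES for stat in _FD_STATS]
    + [f"fft_bin{k}_{ax}" for ax in _AXES for k in range(1, N_FFT_BINS + 1)]
)
#: Canonical order of all 78 features.
FEATURE_NAMES: tuple[str, ...] = TIME_DOMAIN_NAMES + FREQ_DOMAIN_NAMES

META_COLUMNS = ("participant", "behavior", "site", "window_start")


@dataclass(frozen=True)
class SignalWindow:
    """One single-behavior window of raw samples."""

    participant_id: str
    behavior: str
    site: str
    start_time: float
    samples: np.ndarray  # (n, 3), device-frame axes
    sample_rate: float = 30.0


def segment_windows(
    trace: AccelTrace,
    track: LabelTrack,
    window_s: float = 5.0,
    behaviors: tuple[str, ...] = WINDOW_BEHAVIORS,
) -> list[SignalWindow]:
    """Cut single-behavior windows from a synchronized trace.

    Each eligible label is trimmed by one second at each end, then tiled
    with non-overlapping ``window_s`` windows from the trimmed start; a
    trailing partial window is discarded, as is any window that would
    straddle a label boundary (impossible by construction here, since
    windows never leave the trimmed interval).
    """
    n_per_window = window_s * trace.sample_rate
    if abs(n_per_window - round(n_per_window)) > 1e-9:
        raise ValueError(
            f"window of {window_s} s is not an integral number of samples "
            f"at {trace.sample_rate} Hz"
        )
    n_per_window = int(round(n_per_window))

    windows = []
    for label in track:
        if label.behavior not in behaviors:
            continue
        t0, t1 = trimmed_interval(label)
        t0 = max(t0, trace.start_time)
        t1 = min(t1, trace.end_time)
        n_windows = int((t1 - t0) // window_s) if t1 > t0 else 0
        for k in range(n_windows):
            start = t0 + k * window_s
            samples = trace.slice_seconds(start, start + window_s)
            if len(samples) != n_per_window:
                continue
            windows.append(SignalWindow(
                participant_id=track.participant_id,
                behavior=label.behavior,
                site=trace.site,
                start_time=start,
                samples=samples,
                sample_rate=trace.sample_rate,
            ))
    return windows


def _corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Zero-lag Pearson correlation along axis 1; 0 where an input is constant."""
    ma = a.mean(axis=1, keepdims=True)
    mb = b.mean(axis=1, keepdims=True)
    ac, bc = a - ma, b - mb
    sa = np.sqrt((ac**2).mean(axis=1))
    sb = np.sqrt((bc**2).mean(axis=1))
    ok = ((sa > 1e-12 * np.maximum(1.0, np.abs(ma[:, 0])))
          & (sb > 1e-12 * np.maximum(1.0, np.abs(mb[:, 0]))))
    denom = sa * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).mean(axis=1) / denom
    return np.where(ok, r, 0.0)


def _moment_stats(x: np.ndarray) -> dict[str, np.ndarray]:
    """mean/sd/median/min/max/skew/kurt along axis 1 of a (w, n) array."""
    mean = x.mean(axis=1)
    sd = x.std(axis=1)
    # Effectively-constant signals: rounding can leave sd ~ 1e-16, where
    # the standardized moments are pure noise; define them (and sd) as 0.
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    sd = np.where(constant, 0.0, sd)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant-signal moments
        skew = spstats.skew(x, axis=1, bias=True)
        kurt = spstats.kurtosis(x, axis=1, bias=True)  # excess
    return {
        "mean": mean,
        "sd": sd,
        "median": np.median(x, axis=1),
        "min": x.min(axis=1),
        "max": x.max(axis=1),
        "skew": np.where(constant, 0.0, skew),
        "kurt": np.where(constant, 0.0, kurt),
    }


def _feature_matrix(batch: np.ndarray, sample_rate: float) -> np.ndarray:
    """Compute all 78 features for a (w, n, 3) batch of windows."""
    w, n, _ = batch.shape
    cols: dict[str, np.ndarray] = {}

    axes = {ax: batch[:, :, col] for ax, col in AXIS_COLUMNS.items()}
    for ax, x in axes.items():
        stats = _moment_stats(x)
        for stat in _TD_STATS:
            cols[f"{stat}_{ax}"] = stats[stat]

    vm = np.sqrt(np.sum(batch**2, axis=2))
    vm_stats = _moment_stats(vm)
    for stat in _VM_STATS:
        cols[f"{stat}_vm"] = vm_stats[stat]

    cols["corr_xy"] = _corr(axes["x"], axes["y"])
    cols["corr_yz"] = _corr(axes["y"], axes["z"])
    cols["corr_xz"] = _corr(axes["x"], axes["z"])

    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)[1:]  # non-DC bins
    for ax, x in axes.items():
        detrended = x - x.mean(axis=1, keepdims=True)
        mag = np.abs(np.fft.rfft(detrended, axis=1))[:, 1:]
        total = mag.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            centroid = (mag * freqs).sum(axis=1) / total
        cols[f"fft_mean_{ax}"] = mag.mean(axis=1)
        cols[f"fft_sd_{ax}"] = mag.std(axis=1)
        cols[f"fft_median_{ax}"] = np.median(mag, axis=1)
        cols[f"fft_min_{ax}"] = mag.min(axis=1)
        cols[f"fft_max_{ax}"] = mag.max(axis=1)
        cols[f"fft_centroid_{ax}"] = np.where(total > 0, centroid, 0.0)
        for k in range(1, N_FFT_BINS + 1):
            cols[f"fft_bin{k}_{ax}"] = mag[:, k - 1]

    return np.column_stack([cols[name] for name in FEATURE_NAMES])


def time_domain_features(window: SignalWindow) -> dict[str, float]:
    """The 30 time-domain features of one window."""
    row = _feature_matrix(window.samples[None, :, :], window.sample_rate)[0]
    return {name: float(row[i]) for i, name in enumerate(FEATURE_NAMES)
            if name in TIME_DOMAIN_NAMES}


def freq_domain_features(window: SignalWindow) -> dict[str, float]:
    """The 48 frequency-domain features of one window."""
    row = _feature_matrix(window.samples[None, :, :], window.sample_rate)[0]
    return {name: float(row[i]) for i, name in enumerate(FEATURE_NAMES)
            if name in FREQ_DOMAIN_NAMES}


def extract_features(windows: list[SignalWindow]) -> pd.DataFrame:
    """One row per window: provenance columns then the 78 features, in
    canonical column order.  An empty input yields an empty frame with the
    full header."""
    columns = list(META_COLUMNS) + list(FEATURE_NAMES)
    if not windows:
        return pd.DataFrame(columns=columns)
    rates = {w.sample_rate for w in windows}
    lengths = {len(w.samples) for w in windows}
    if len(rates) != 1 or len(lengths) != 1:
        raise ValueError("all windows must share sample rate and length")
    batch = np.stack([w.samples for w in windows])
    feats = _feature_matrix(batch, rates.pop())
    df = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
    df.insert(0, "window_start", [w.start_time for w in windows])
    df.insert(0, "site", [w.site for w in windows])
    df.insert(0, "behavior", [w.behavior for w in windows])
    df.insert(0, "participant", [w.participant_id for w in windows])
    return df
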