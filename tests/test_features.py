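"""Window segmentation and the 78 features, checked against brute-force
direct-definition oracles."""

import cmath
import math

import numpy as np
import pytest

import toddleracc as ta
from toddleracc.features import (
    AXIS_COLUMNS,
    FEATURE_NAMES,
    FREQ_DOMAIN_NAMES,
    TIME_DOMAIN_NAMES,
)


def _window(samples, behavior="walk"):
    return ta.SignalWindow("P", behavior, "hip", 0.0, np.asarray(samples, float), 30.0)


# ---------------------------------------------------------------- oracles

def _oracle_moments(xs):
    n = len(xs)
    mean = sum(xs) / n
    var = sum((v - mean) ** 2 for v in xs) / n
    sd = math.sqrt(var)
    srt = sorted(xs)
    median = (srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2)
    if sd == 0:
        skew = kurt = 0.0
    else:
        skew = sum((v - mean) ** 3 for v in xs) / n / sd**3
        kurt = sum((v - mean) ** 4 for v in xs) / n / sd**4 - 3.0
    return {"mean": mean, "sd": sd, "median": median, "min": min(xs),
            "max": max(xs), "skew": skew, "kurt": kurt}


def _oracle_corr(xs, ys):
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    sx = math.sqrt(sum((v - mx) ** 2 for v in xs) / n)
    sy = math.sqrt(sum((v - my) ** 2 for v in ys) / n)
    if sx == 0 or sy == 0:
        return 0.0
    return sum((a - mx) * (b - my) for a, b in zip(xs, ys)) / n / (sx * sy)


def _oracle_spectrum(xs, sample_rate):
    """Magnitudes of the non-DC DFT bins of the mean-subtracted signal,
    by direct O(n^2) summation."""
    n = len(xs)
    mean = sum(xs) / n
    centered = [v - mean for v in xs]
    mags, freqs = [], []
    for k in range(1, n // 2 + 1):
        s = sum(v * cmath.exp(-2j * math.pi * k * i / n)
                for i, v in enumerate(centered))
        mags.append(abs(s))
        freqs.append(k * sample_rate / n)
    return mags, freqs


def oracle_features(window):
    out = {}
    cols = {ax: window.samples[:, c].tolist() for ax, c in AXIS_COLUMNS.items()}
    for ax, xs in cols.items():
        for stat, val in _oracle_moments(xs).items():
            out[f"{stat}_{ax}"] = val
    vm = [math.sqrt(sum(v**2 for v in row)) for row in window.samples]
    for stat, val in _oracle_moments(vm).items():
        if stat != "sd":
            out[f"{stat}_vm"] = val
    out["corr_xy"] = _oracle_corr(cols["x"], cols["y"])
    out["corr_yz"] = _oracle_corr(cols["y"], cols["z"])
    out["corr_xz"] = _oracle_corr(cols["x"], cols["z"])
    for ax, xs in cols.items():
        mags, freqs = _oracle_spectrum(xs, window.sample_rate)
        stats = _oracle_moments(mags)
        total = sum(mags)
        out[f"fft_mean_{ax}"] = stats["mean"]
        out[f"fft_sd_{ax}"] = stats["sd"]
        out[f"fft_median_{ax}"] = stats["median"]
        out[f"fft_min_{ax}"] = stats["min"]
        out[f"fft_max_{ax}"] = stats["max"]
        out[f"fft_centroid_{ax}"] = (
            sum(m * f for m, f in zip(mags, freqs)) / total if total else 0.0
        )
        for k in range(1, 11):
            out[f"fft_bin{k}_{ax}"] = mags[k - 1]
    return out


# ------------------------------------------------------------------ tests

class TestSegmentation:
    def _session(self, labels):
        end = max(e for _, _, e in labels)
        trace = ta.AccelTrace("hip", 30.0, np.zeros((int(end * 30), 3)))
        track = ta.LabelTrack("P", [ta.BehaviorLabel(b, s, e) for b, s, e in labels])
        return trace, track

    def test_fourteen_second_label_yields_two_windows(self):
        trace, track = self._session([("carried", 0, 14)])
        windows = ta.segment_windows(trace, track)
        assert len(windows) == 2
        assert [w.start_time for w in windows] == [1.0, 6.0]

    def test_five_second_label_yields_none(self):
        trace, track = self._session([("walk", 0, 5)])
        assert ta.segment_windows(trace, track) == []

    def test_windows_never_cross_behavior_boundaries(self):
        trace, track = self._session([("walk", 0, 9), ("stand", 9, 30)])
        windows = ta.segment_windows(trace, track)
        for w in windows:
            label = next(l for l in track
                         if l.start_time <= w.start_time < l.end_time)
            assert w.behavior == label.behavior
            assert w.start_time >= label.start_time + 1
            assert w.start_time + 5 <= label.end_time - 1

    def test_only_window_behaviors_selected(self):
        trace, track = self._session([("sit", 0, 20), ("run", 20, 40)])
        windows = ta.segment_windows(trace, track)
        assert {w.behavior for w in windows} == {"run"}

    def test_non_integral_window_rejected(self):
        trace, track = self._session([("walk", 0, 10)])
        with pytest.raises(ValueError, match="integral"):
            ta.segment_windows(trace, track, window_s=0.11)


class TestFeatureSchema:
    def test_feature_partition(self):
        assert len(FEATURE_NAMES) == 78
        assert len(TIME_DOMAIN_NAMES) == 30
        assert len(FREQ_DOMAIN_NAMES) == 48
        assert set(TIME_DOMAIN_NAMES) | set(FREQ_DOMAIN_NAMES) == set(FEATURE_NAMES)
        assert not set(TIME_DOMAIN_NAMES) & set(FREQ_DOMAIN_NAMES)

    def test_single_window_apis_match_schema(self, random_windows):
        td = ta.time_domain_features(random_windows[0])
        fd = ta.freq_domain_features(random_windows[0])
        assert set(td) == set(TIME_DOMAIN_NAMES)
        assert set(fd) == set(FREQ_DOMAIN_NAMES)


class TestFeatureValues:
    def test_oracle_equivalence_on_random_windows(self, random_windows):
        """Every feature matches its direct-definition computation."""
        table = ta.extract_features(random_windows)
        for i, window in enumerate(random_windows):
            expected = oracle_features(window)
            for name in FEATURE_NAMES:
                assert table.iloc[i][name] == pytest.approx(
                    expected[name], rel=1e-9, abs=1e-9
                ), name

    def test_pure_sinusoid_peaks_at_its_bin(self):
        """1.0 Hz on x at 0.2 Hz resolution peaks exactly at bin 5."""
        t = np.arange(150) / 30.0
        samples = np.zeros((150, 3))
        samples[:, AXIS_COLUMNS["x"]] = np.sin(2 * np.pi * 1.0 * t)
        fd = ta.freq_domain_features(_window(samples))
        bins = [fd[f"fft_bin{k}_x"] for k in range(1, 11)]
        assert int(np.argmax(bins)) + 1 == 5
        assert fd["fft_max_x"] == pytest.approx(fd["fft_bin5_x"])

    def test_constant_window_degenerate_values(self):
        samples = np.full((150, 3), 0.7)
        td = ta.time_domain_features(_window(samples))
        fd = ta.freq_domain_features(_window(samples))
        for ax in "xyz":
            assert td[f"mean_{ax}"] == pytest.approx(0.7)
            assert td[f"sd_{ax}"] == 0
            assert td[f"skew_{ax}"] == 0
            assert td[f"kurt_{ax}"] == 0
            assert fd[f"fft_sd_{ax}"] == pytest.approx(0, abs=1e-9)
            assert fd[f"fft_max_{ax}"] == pytest.approx(0, abs=1e-9)
        assert td["corr_xy"] == 0  # constant axes: correlation defined as 0

    def test_all_zero_window(self):
        td = ta.time_domain_features(_window(np.zeros((150, 3))))
        for ax in "xyz":
            for stat in ("mean", "sd", "median", "min", "max"):
                assert td[f"{stat}_{ax}"] == 0

    def test_identical_axes_correlate_perfectly(self, rng):
        samples = np.zeros((150, 3))
        sig = rng.normal(0, 1, 150)
        samples[:, AXIS_COLUMNS["x"]] = sig
        samples[:, AXIS_COLUMNS["y"]] = sig
        td = ta.time_domain_features(_window(samples))
        assert td["corr_xy"] == pytest.approx(1.0)

    def test_amplitude_equivariance(self, rng):
        """Scaling by c scales location/spread/spectral magnitudes by c and
        leaves shape statistics and correlations unchanged."""
        samples = rng.normal(0, 0.5, (150, 3))
        c = 3.7
        base = {**ta.time_domain_features(_window(samples)),
                **ta.freq_domain_features(_window(samples))}
        scaled = {**ta.time_domain_features(_window(c * samples)),
                  **ta.freq_domain_features(_window(c * samples))}
        for name in FEATURE_NAMES:
            if (name.startswith(("skew", "kurt", "corr", "fft_centroid"))):
                assert scaled[name] == pytest.approx(base[name], rel=1e-9), name
            else:
                assert scaled[name] == pytest.approx(c * base[name], rel=1e-9), name


class TestExtractFeatures:
    def test_purity(self, random_windows):
        w = random_windows[0]
        table = ta.extract_features([w, w])
        assert table.iloc[0].equals(table.iloc[1])

    def test_empty_batch_keeps_header(self):
        table = ta.extract_features([])
        assert len(table) == 0
        assert list(table.columns) == (
            ["participant", "behavior", "site", "window_start"] + list(FEATURE_NAMES)
        )

    def test_row_shape_and_provenance(self, random_windows):
        table = ta.extract_features(random_windows)
        assert table.shape == (len(random_windows), 4 + 78)
        assert (table.participant == "P").all()
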