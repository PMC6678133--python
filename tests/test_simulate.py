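"""Generator behavior: determinism, gravity handling, behavior
signatures, session assembly, and the coder-error model."""

import math

import numpy as np
import pytest

import toddleracc as ta
from toddleracc.core import UnknownBehaviorError
from toddleracc.simulate import CONFUSABLE


class TestDefaults:
    def test_device_configuration(self, params):
        assert params.sample_rate == 30.0
        assert params.clip_range == 6.0

    def test_defaults_are_deterministic(self):
        assert ta.default_params() == ta.default_params()

    def test_covers_nine_behaviors_plus_bounce(self, params):
        for behavior in ta.PRESCRIBED_BEHAVIORS + ("bounce",):
            assert behavior in params.behaviors


class TestSimulateBout:
    def test_sample_count(self, params):
        trace = ta.simulate_bout("walk", 7, "hip", params, seed=3)
        assert trace.n_samples == round(7 * params.sample_rate)

    def test_seeded_determinism(self, params):
        a = ta.simulate_bout("run", 10, "hip", params, seed=5)
        b = ta.simulate_bout("run", 10, "hip", params, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_different_seeds_differ(self, params):
        a = ta.simulate_bout("run", 10, "hip", params, seed=5)
        b = ta.simulate_bout("run", 10, "hip", params, seed=6)
        assert not np.array_equal(a.samples, b.samples)

    def test_unknown_behavior_rejected(self, params):
        with pytest.raises(UnknownBehaviorError, match="cartwheel"):
            ta.simulate_bout("cartwheel", 5, "hip", params, seed=0)

    def test_sit_is_quiescent(self, params):
        trace = ta.simulate_bout("sit", 10, "hip", params, seed=7)
        dynamic = trace.samples - trace.samples.mean(axis=0)
        rms = np.sqrt((dynamic**2).mean())
        assert rms <= 2 * params.behaviors["sit"].noise_sd

    def test_crawl_gravity_reorientation(self, params):
        """Trunk pitched 90 deg: the vertical device axis loses gravity
        (mean ~ cos 90 = 0) but gains the large fore-aft motion."""
        pitch = params.behaviors["crawl"].gravity_pitch
        trace = ta.simulate_bout("crawl", 10, "hip", params, seed=7)
        mean_axis1 = trace.samples[:, 0].mean()
        assert mean_axis1 == pytest.approx(math.cos(math.radians(pitch)), abs=0.1)
        upright = ta.simulate_bout("stand", 10, "hip", params, seed=7)
        assert trace.samples[:, 0].std() > 10 * upright.samples[:, 0].std()

    @pytest.mark.parametrize("behavior", ["stand", "sit", "stroller"])
    def test_gravity_conservation_static_postures(self, params, behavior):
        trace = ta.simulate_bout(behavior, 10, "hip", params, seed=9)
        vm_of_mean = np.linalg.norm(trace.samples.mean(axis=0))
        assert vm_of_mean == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("behavior", ta.PRESCRIBED_BEHAVIORS + ("bounce",))
    def test_clipping_bound(self, params, behavior):
        for site in ("hip", "wrist"):
            trace = ta.simulate_bout(behavior, 8, site, params, seed=13)
            assert np.all(np.abs(trace.samples) <= params.clip_range)

    def test_energy_monotonicity_via_counts(self, params):
        """More vertical amplitude must mean more axis-1 counts (same seed)."""
        import dataclasses

        bumped = dataclasses.replace(
            params,
            behaviors={**params.behaviors,
                       "walk": dataclasses.replace(params.behaviors["walk"],
                                                   vertical_amp=2 * params.behaviors["walk"].vertical_amp)},
        )
        lo = ta.compute_counts(ta.simulate_bout("walk", 20, "hip", params, seed=21), 5)
        hi = ta.compute_counts(ta.simulate_bout("walk", 20, "hip", bumped, seed=21), 5)
        assert hi.counts[:, 0].sum() > lo.counts[:, 0].sum()


class TestSimulateSession:
    def test_single_bout_schedule(self, params):
        schedule = ta.BoutSchedule("P01", (("walk", 10.0),))
        hip, wrist, track = ta.simulate_session(schedule, params, seed=1)
        assert len(track) == 1
        label = track.labels[0]
        assert (label.behavior, label.duration) == ("walk", 10.0)

    def test_time_conservation_and_tiling(self, params, small_session):
        hip, wrist, track = small_session
        n_bouts = len(ta.PRESCRIBED_BEHAVIORS)
        expected = 12.0 * n_bouts + params.transition_s * (n_bouts - 1)
        assert hip.duration == pytest.approx(expected)
        assert wrist.n_samples == hip.n_samples
        # labels tile the session with no gaps
        t = track.labels[0].start_time
        for label in track:
            assert label.start_time == pytest.approx(t)
            t = label.end_time
        assert t == pytest.approx(expected)

    def test_transitions_are_labeled(self, small_session):
        _, _, track = small_session
        assert sum(1 for l in track if l.behavior == "transition") == len(ta.PRESCRIBED_BEHAVIORS) - 1

    def test_empty_schedule_rejected(self, params):
        with pytest.raises(ValueError, match="at least one bout"):
            ta.simulate_session(ta.BoutSchedule("P01", ()), params, seed=0)

    def test_session_determinism(self, params):
        schedule = ta.study_schedule("P01", seed=4)
        h1, w1, t1 = ta.simulate_session(schedule, params, seed=4)
        h2, w2, t2 = ta.simulate_session(schedule, params, seed=4)
        np.testing.assert_array_equal(h1.samples, h2.samples)
        np.testing.assert_array_equal(w1.samples, w2.samples)
        assert t1.labels == t2.labels


class TestPerturbLabels:
    def _track(self, n=20, behavior="stand"):
        labels = [
            ta.BehaviorLabel(behavior, 10.0 * i, 10.0 * (i + 1), coder_id="a")
            for i in range(n)
        ]
        return ta.LabelTrack("P01", labels)

    def test_identity(self):
        track = self._track()
        out = ta.perturb_labels(track, 0.0, 0.0, seed=0)
        assert out.labels == track.labels

    def test_full_confusion_changes_everything(self):
        track = self._track(behavior="stand")
        out = ta.perturb_labels(track, 0.0, 1.0, seed=0)
        assert all(l.behavior == CONFUSABLE["stand"] for l in out)

    def test_negative_shift_rejected(self):
        with pytest.raises(ValueError, match="shift_sd_s"):
            ta.perturb_labels(self._track(), -1.0, 0.0, seed=0)

    def test_intervals_stay_valid_under_jitter(self):
        track = self._track()
        out = ta.perturb_labels(track, 2.0, 0.3, seed=5)
        for a, b in zip(out.labels, out.labels[1:]):
            assert a.end_time <= b.start_time
            assert a.duration >= 1.0

    def test_confusion_rate_matches_agreement(self):
        """Swapping 25% of labels should leave ~75% agreement on average."""
        track = self._track(n=40)
        percents = []
        for seed in range(30):
            out = ta.perturb_labels(track, 0.0, 0.25, seed=seed)
            percents.append(ta.percent_agreement(track, out).fraction)
        assert np.mean(percents) == pytest.approx(0.75, abs=0.04)
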