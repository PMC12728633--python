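"""Bead detection, screening rules, variance traces, and event calling."""

import numpy as np
import pandas as pd
import pytest

from stackpol import tracking as trk
from stackpol.datatypes import ImageStack
from stackpol.sim import KineticsSimParams, MovieParams, render_bead_movie, \
    sample_dissociation_times
from stackpol.tracking import CallParams, VarianceTrace, call_dissociation


def _candidates(rows):
    return pd.DataFrame(rows, columns=["bead_id", "x", "y", "radius",
                                       "hough_score", "score", "status"])


class TestDetection:
    def test_well_separated_beads_recovered(self):
        """>= 48 of 50 low-noise beads detected within 2 px of truth."""
        ds = sample_dissociation_times(KineticsSimParams(
            k_off=1e-9, n_tethers=50, t_end=100.0, frame_interval=5.0,
            seed=3))
        stack = render_bead_movie(ds, MovieParams(noise_sigma=2.0, seed=7))
        cands = trk.detect_beads(stack.frames[0])
        found = 0
        for obj in stack.sidecar["objects"]:
            d = np.hypot(cands["x"] - obj["x"], cands["y"] - obj["y"])
            found += bool((d <= 2.0).any())
        assert found >= 48

    def test_blank_noise_frame_yields_no_accepted_beads(self, rng):
        frame = rng.normal(200.0, 5.0, size=(128, 128))
        screened = trk.screen_beads(trk.detect_beads(frame))
        accepted = (screened["status"] == "accepted").sum() if len(screened) \
            else 0
        assert accepted == 0

    def test_single_bead_single_detection(self):
        ds = sample_dissociation_times(KineticsSimParams(
            k_off=1e-9, n_tethers=1, t_end=50.0, frame_interval=5.0, seed=4))
        stack = render_bead_movie(ds, MovieParams(noise_sigma=2.0, seed=8))
        screened = trk.screen_beads(trk.detect_beads(stack.frames[0]))
        accepted = screened[screened["status"] == "accepted"]
        assert len(accepted) == 1
        obj = stack.sidecar["objects"][0]
        err = np.hypot(accepted.iloc[0]["x"] - obj["x"],
                       accepted.iloc[0]["y"] - obj["y"])
        assert err <= 1.0

    def test_degenerate_image_rejected(self):
        with pytest.raises(ValueError):
            trk.detect_beads(np.zeros(16))


class TestScreening:
    def test_touching_pair_both_excluded_as_cluster(self):
        cands = _candidates([
            (0, 50.0, 50.0, 4.0, 0.9, 0.95, "candidate"),
            (1, 54.0, 50.0, 4.0, 0.9, 0.95, "candidate"),  # 1 radius apart
            (2, 150.0, 150.0, 4.0, 0.9, 0.95, "candidate"),
        ])
        out = trk.screen_beads(cands)
        assert list(out["status"]) == ["excluded:cluster", "excluded:cluster",
                                       "accepted"]

    def test_generator_debris_excluded_for_shape(self, bead_movie):
        stack, _ = bead_movie
        screened = trk.screen_beads(trk.detect_beads(stack.frames[0]))
        for obj in stack.sidecar["objects"]:
            if obj["kind"] != "debris":
                continue
            d = np.hypot(screened["x"] - obj["x"], screened["y"] - obj["y"])
            near = screened[d <= 6.0]
            assert (near["status"] != "accepted").all()
            assert (near["status"] == "excluded:low_circularity").any()

    def test_empty_candidates_stay_empty(self):
        out = trk.screen_beads(_candidates([]))
        assert out.empty

    def test_order_independent(self, bead_movie, rng):
        stack, _ = bead_movie
        cands = trk.detect_beads(stack.frames[0])
        shuffled = cands.sample(frac=1.0, random_state=1)
        a = trk.screen_beads(cands)
        b = trk.screen_beads(shuffled)
        key = ["x", "y"]
        a = a.sort_values(key).reset_index(drop=True)
        b = b.sort_values(key).reset_index(drop=True)
        assert a["status"].equals(b["status"])

    def test_radius_out_of_range_excluded(self):
        cands = _candidates([(0, 60.0, 60.0, 15.0, 0.9, 0.95, "candidate")])
        out = trk.screen_beads(cands)
        assert out.loc[0, "status"] == "excluded:radius_out_of_range"


class TestVarianceTrace:
    def test_constant_image_zero_variance(self):
        frames = np.full((20, 64, 64), 7.0, dtype=np.float32)
        stack = ImageStack(frames, frame_interval=1.0)
        tr = trk.variance_trace(stack, 32, 32, 5)
        assert np.allclose(tr.values, 0.0)

    def test_pure_noise_variance_matches_sigma_squared(self, rng):
        sigma = 4.0
        frames = rng.normal(0.0, sigma, size=(300, 40, 40)).astype(np.float32)
        stack = ImageStack(frames, frame_interval=1.0)
        tr = trk.variance_trace(stack, 20, 20, 8)
        n_px = trk.disk_mask((40, 40), 20, 20, 8).sum()
        # var of the sample variance of n Gaussians ~ 2 sigma^4 / (n-1)
        sem = np.sqrt(2 * sigma**4 / (n_px - 1) / 300)
        assert abs(tr.values.mean() - sigma**2) < 3 * sem

    def test_disk_outside_frame_rejected(self):
        stack = ImageStack(np.zeros((5, 32, 32), dtype=np.float32), 1.0)
        with pytest.raises(ValueError):
            trk.variance_trace(stack, 2, 2, 6)


class TestEventCalling:
    def _trace(self, values):
        values = np.asarray(values, dtype=float)
        return VarianceTrace(0, values, np.arange(len(values), dtype=float))

    def test_step_called_at_step_frame(self):
        t = np.arange(400)
        v = np.where(t < 200, 100.0, 5.0)
        call = call_dissociation(self._trace(v), time_zero=0.0)
        assert call.outcome == "dissociated"
        assert call.time_s == 200.0

    def test_constant_bound_trace_censored(self):
        call = call_dissociation(self._trace(np.full(300, 80.0)), 0.0)
        assert call.outcome == "censored"

    def test_two_level_drop_excluded_as_multistep(self):
        t = np.arange(450)
        v = np.where(t < 150, 100.0, np.where(t < 300, 50.0, 5.0))
        call = call_dissociation(self._trace(v), 0.0)
        assert call.outcome == "excluded_multistep"

    def test_time_zero_shifts_reported_time(self):
        t = np.arange(400)
        v = np.where(t < 200, 100.0, 5.0)
        call = call_dissociation(self._trace(v), time_zero=50.0)
        assert call.time_s == 150.0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            call_dissociation(self._trace(np.ones(10)), 0.0)


class TestEndToEnd:
    def test_intensity_offset_leaves_event_times_unchanged(self, bead_movie):
        stack, _ = bead_movie
        shifted = ImageStack(stack.frames + 50.0, stack.frame_interval,
                             stack.time_zero, stack.sidecar)
        ev_a, _ = trk.track_stack(stack)
        ev_b, _ = trk.track_stack(shifted)
        merged = ev_a.merge(ev_b, on="bead_id", suffixes=("_a", "_b"))
        assert merged["outcome_a"].equals(merged["outcome_b"])
        pd.testing.assert_series_equal(merged["time_s_a"], merged["time_s_b"],
                                       check_names=False)
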