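"""Decay curves, exponential fits, force model, and free-energy extraction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stackpol import kinetics as kin
from stackpol.datatypes import DissociationDataset
from stackpol.kinetics import DecayCurve
from stackpol.sim import KineticsSimParams, sample_dissociation_times


def _dataset(times, censored=None, t_end=None, dt=0.0):
    times = np.asarray(times, dtype=float)
    if censored is None:
        censored = np.zeros(len(times), dtype=int)
    if t_end is None:
        t_end = float(times.max())
    events = pd.DataFrame({
        "tether_id": np.arange(len(times)),
        "time_s": times,
        "censored": censored,
        "replicate_id": 0,
    })
    return DissociationDataset(events, t_end=t_end, frame_interval=dt)


class TestDecayCurve:
    def test_direct_count_example(self):
        """Times 10/20/30/40 s in 4 bins give fractions 1, .75, .5, .25."""
        curve = kin.build_decay_curve(_dataset([10, 20, 30, 40]), n_bins=4)
        assert np.allclose(curve.edges, [0, 10, 20, 30])
        assert np.allclose(curve.fractions, [1.0, 0.75, 0.5, 0.25])

    def test_all_censored_flat_and_flagged(self):
        ds = _dataset([50, 50, 50], censored=[1, 1, 1], t_end=50.0)
        curve = kin.build_decay_curve(ds, n_bins=5)
        assert curve.all_censored
        assert np.allclose(curve.fractions, 1.0)
        with pytest.raises(ValueError):
            kin.fit_off_rate(curve)

    def test_large_sample_tracks_survival_function(self):
        ds = sample_dissociation_times(KineticsSimParams(
            k_off=0.01, n_tethers=5000, t_end=600.0, frame_interval=0.0,
            seed=13))
        curve = kin.build_decay_curve(ds, n_bins=50)
        expected = np.exp(-0.01 * curve.edges)
        assert np.max(np.abs(curve.fractions - expected)) < 0.03

    def test_fractions_non_increasing(self, small_events):
        curve = kin.build_decay_curve(small_events, n_bins=50)
        assert (np.diff(curve.fractions) <= 1e-12).all()
        assert curve.fractions[0] <= 1.0


class TestOffRateFit:
    def test_noiseless_pure_exponential(self):
        t_end = 500.0
        edges = np.linspace(0, t_end, 50, endpoint=False)
        curve = DecayCurve(edges, np.exp(-0.01 * edges), 100, 0, t_end)
        fit = kin.fit_off_rate(curve)
        assert fit.converged
        assert fit.k == pytest.approx(0.01, abs=1e-6)

    def test_noiseless_with_baseline(self):
        t_end = 200.0
        edges = np.linspace(0, t_end, 80, endpoint=False)
        y = 0.1 + 0.9 * np.exp(-0.05 * edges)
        fit = kin.fit_off_rate(DecayCurve(edges, y, 100, 10, t_end))
        assert fit.k == pytest.approx(0.05, abs=1e-4)
        assert fit.y0 == pytest.approx(0.1, abs=1e-4)
        assert fit.A == pytest.approx(0.9, abs=1e-4)

    def test_replicate_recovery_of_generating_rate(self):
        """Mean fitted k over 3 x 500-tether replicates hits k = 0.02."""
        reps = [sample_dissociation_times(KineticsSimParams(
            k_off=0.02, n_tethers=500, t_end=250.0, frame_interval=1.0,
            seed=100 + i), replicate_id=i) for i in range(3)]
        est = kin.replicate_off_rate(reps, n_bins=50)
        assert abs(est.mean - 0.02) < 3 * max(est.sd, 1e-4)

    def test_bin_robustness_on_well_sampled_data(self):
        ds = sample_dissociation_times(KineticsSimParams(
            k_off=0.01, n_tethers=5000, t_end=500.0, frame_interval=1.0,
            seed=8))
        assert kin.bin_robustness(ds, n_bins=50) < 0.05


class TestCentrifugalForce:
    def test_force_clamp_operating_point(self):
        """1291 rpm at r = 0.119 m on a 6.9 pg bead is ~15 pN."""
        f = kin.centrifugal_force(1291.0, 0.119, 6.9e-12)
        assert f == pytest.approx(15.0, rel=0.03)

    def test_zero_rpm_gives_zero_force(self):
        assert kin.centrifugal_force(0.0, 0.119, 6.9e-12) == 0.0

    def test_direct_formula_evaluation(self):
        # independent evaluation: m * (rpm*2*pi/60)^2 * r, g -> kg, N -> pN
        omega = 2000.0 * 2 * math.pi / 60.0
        expected = 6.9e-15 * omega**2 * 0.119 * 1e12
        assert kin.centrifugal_force(2000.0, 0.119, 6.9e-12) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(36.0, rel=0.01)

    @given(m=st.floats(1e-13, 1e-10), r=st.floats(0.01, 1.0),
           rpm=st.floats(10.0, 5000.0))
    @settings(max_examples=50, deadline=None)
    def test_scaling_linear_in_mass_radius_quadratic_in_rpm(self, m, r, rpm):
        f = kin.centrifugal_force(rpm, r, m)
        assert kin.centrifugal_force(rpm, r, 2 * m) == pytest.approx(2 * f,
                                                                     rel=1e-9)
        assert kin.centrifugal_force(rpm, 2 * r, m) == pytest.approx(2 * f,
                                                                     rel=1e-9)
        assert kin.centrifugal_force(2 * rpm, r, m) == pytest.approx(4 * f,
                                                                     rel=1e-9)


class TestStackingFreeEnergy:
    def test_equal_rates_give_zero(self):
        res = kin.stacking_free_energy((0.01, 0.0), (0.01, 0.0))
        assert res.delta_g == 0.0

    def test_rate_ratio_e_inverse(self):
        """k1/k2 = 1/e at 298.15 K gives dG = -RT = -0.5924 kcal/mol."""
        res = kin.stacking_free_energy((0.01 / math.e, 0.0), (0.01, 0.0),
                                       temperature=298.15)
        assert res.delta_g == pytest.approx(-1.987e-3 * 298.15, rel=1e-9)
        assert res.delta_g == pytest.approx(-0.5924, abs=1e-3)

    def test_strongest_purine_pyrimidine_ratio(self):
        """An off-rate ratio of 0.0289 encodes about -2.1 kcal/mol."""
        res = kin.stacking_free_energy((0.0289, 0.0), (1.0, 0.0),
                                       temperature=298.15)
        assert res.delta_g == pytest.approx(-2.1, abs=0.01)

    def test_error_propagation_first_order(self):
        res = kin.stacking_free_energy((0.01, 0.001), (0.02, 0.004),
                                       temperature=300.0)
        rt = 1.987e-3 * 300.0
        expected = rt * math.sqrt(0.1**2 + 0.2**2)
        assert res.sigma_delta_g == pytest.approx(expected, rel=1e-9)

    @given(k1=st.floats(1e-5, 1.0), k2=st.floats(1e-5, 1.0),
           temp=st.floats(250.0, 400.0))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_under_rate_swap(self, k1, k2, temp):
        a = kin.stacking_free_energy((k1, 0.0), (k2, 0.0), temp).delta_g
        b = kin.stacking_free_energy((k2, 0.0), (k1, 0.0), temp).delta_g
        assert a == -b

    def test_sign_tracks_rate_ordering(self):
        slower = kin.stacking_free_energy((0.001, 0.0), (0.01, 0.0))
        faster = kin.stacking_free_energy((0.02, 0.0), (0.01, 0.0))
        assert slower.delta_g < 0 < faster.delta_g

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            kin.stacking_free_energy((0.0, 0.0), (0.01, 0.0))


class TestPoolReplicates:
    def test_near_equal_sizes_and_conservation(self, small_events):
        groups = kin.pool_replicates(small_events, n_groups=3, seed=0)
        sizes = [g.n_total for g in groups]
        assert max(sizes) - min(sizes) <= 1
        merged = pd.concat([g.events["tether_id"] for g in groups])
        assert sorted(merged) == sorted(small_events.events["tether_id"])

    def test_exact_split_of_300_into_3(self):
        ds = sample_dissociation_times(KineticsSimParams(
            k_off=0.01, n_tethers=300, t_end=500.0, seed=1))
        sizes = [g.n_total for g in kin.pool_replicates(ds, 3, seed=5)]
        assert sizes == [100, 100, 100]

    def test_same_seed_same_partition(self, small_events):
        a = kin.pool_replicates(small_events, 3, seed=9)
        b = kin.pool_replicates(small_events, 3, seed=9)
        for ga, gb in zip(a, b):
            assert ga.events.equals(gb.events)
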