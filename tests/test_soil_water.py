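"""Runoff partitioning, tipping-bucket redistribution, ET extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vegrot.soilwater import (SoilLayer, SoilProfile, SoilWaterState,
                              extract_et, partition_runoff,
                              proportional_allocation, redistribute,
                              report_profile, triangular_root_fractions)


class TestCurveNumberRunoff:
    def test_below_initial_abstraction_no_runoff(self):
        s = 25400.0 / 80 - 254.0
        runoff, infil = partition_runoff(0.9 * 0.2 * s, 80.0)
        assert runoff == 0.0

    def test_cn_100_all_runs_off(self):
        runoff, infil = partition_runoff(12.0, 100.0)
        assert runoff == pytest.approx(12.0)
        assert infil == pytest.approx(0.0)

    def test_standard_relation_hand_value(self):
        # S = 25400/80 - 254 = 63.5; Ia = 12.7;
        # Q = (50 - 12.7)^2 / (50 - 12.7 + 63.5) = 1391.29 / 100.8
        runoff, infil = partition_runoff(50.0, 80.0)
        assert runoff == pytest.approx(13.802480158730158, abs=1e-12)
        assert infil == pytest.approx(50.0 - 13.802480158730158, abs=1e-12)

    @given(water=st.floats(0, 300), cn=st.floats(1, 100))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_partition_conserves_water(self, water, cn):
        runoff, infil = partition_runoff(water, cn)
        assert runoff >= 0 and infil >= 0
        assert runoff + infil == pytest.approx(water, abs=1e-9)


class TestRedistribution:
    def test_at_field_capacity_nothing_moves(self, toy_profile):
        state = SoilWaterState(np.full(3, 0.30))
        new, out = redistribute(state, 0.0, toy_profile, drain_coeff=0.5)
        assert np.allclose(new.theta, 0.30)
        assert np.allclose(out, 0.0)

    def test_saturated_profile_passes_input_through(self, toy_profile):
        state = SoilWaterState(np.full(3, 0.45))
        new, out = redistribute(state, 10.0, toy_profile, drain_coeff=0.0)
        assert out[-1] == pytest.approx(10.0)
        assert np.allclose(new.theta, 0.45)

    def test_hand_bookkeeping_three_layers(self, toy_profile, toy_state):
        # layer 1: 12 mm + 20 mm = 32; cap_sat 45, cap_fc 30 -> drainable 2,
        # half drains -> 31 mm held (theta 0.31), 1 mm passes on
        # layer 2: 20 + 1 = 21 < 30 -> holds all (theta 0.21)
        # layer 3: untouched (theta 0.28); no profile drainage
        new, out = redistribute(toy_state, 20.0, toy_profile, drain_coeff=0.5)
        assert new.theta == pytest.approx([0.31, 0.21, 0.28], abs=1e-12)
        assert out == pytest.approx([1.0, 0.0, 0.0], abs=1e-12)

    def test_mass_conservation_random_states(self, toy_profile):
        rng = np.random.default_rng(42)
        for _ in range(50):
            theta = rng.uniform(0.10, 0.45, size=3)
            state = SoilWaterState(theta.copy())
            infil = float(rng.uniform(0, 60))
            coeff = float(rng.uniform(0, 1))
            new, out = redistribute(state, infil, toy_profile, coeff)
            before = state.storage_mm(toy_profile)
            after = new.storage_mm(toy_profile)
            assert after - before + out[-1] == pytest.approx(infil, abs=1e-9)
            assert (new.theta <= 0.45 + 1e-12).all()

    @given(infil=st.floats(0, 80), extra=st.floats(0, 40))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_drainage_monotone_in_infiltration(self, infil, extra):
        mk = lambda top: SoilLayer(top=top, bottom=top + 10, bulk_density=1.3,
                                   theta_s=0.45, theta_fc=0.30, theta_wp=0.10)
        profile = SoilProfile((mk(0), mk(10), mk(20)))
        state = SoilWaterState(np.array([0.25, 0.30, 0.35]))
        _, out1 = redistribute(state.copy(), infil, profile, 0.5)
        _, out2 = redistribute(state.copy(), infil + extra, profile, 0.5)
        assert out2[-1] >= out1[-1] - 1e-12


def allocation_oracle(demand, weight, cap, tol=1e-12):
    """Bisection on the proportional scaling: take_i = min(lam w_i, cap_i)."""
    weight = np.asarray(weight, float)
    cap = np.asarray(cap, float)
    target = min(demand, cap[weight > 0].sum())
    active = (weight > 0) & (cap > 0)
    if target <= 0 or not active.any():
        return np.zeros_like(cap)
    # beyond hi every active source is capped
    hi = 2.0 * float((cap[active] / weight[active]).max())
    lo = 0.0
    for _ in range(200):
        lam = 0.5 * (lo + hi)
        tot = np.minimum(lam * weight, np.where(weight > 0, cap, 0.0)).sum()
        if tot < target:
            lo = lam
        else:
            hi = lam
    return np.minimum(hi * weight, np.where(weight > 0, cap, 0.0))


class TestETExtraction:
    def test_no_transpiration_at_wilting_point(self, toy_profile):
        state = SoilWaterState(np.full(3, 0.10))
        _, evap, transp = extract_et(state, 0.0, 5.0, 30.0, toy_profile)
        assert transp == 0.0

    def test_full_demand_met_with_ample_water(self, toy_profile):
        state = SoilWaterState(np.full(3, 0.30))
        new, evap, transp = extract_et(state, 0.0, 3.0, 30.0, toy_profile)
        assert transp == pytest.approx(3.0, abs=1e-9)

    def test_evaporation_respects_air_dry_floor(self, toy_profile):
        state = SoilWaterState(np.array([0.12, 0.30, 0.30]))
        # top layer holds 12 mm; air-dry floor 0.5 * 0.10 * 100 = 5 mm
        new, evap, _ = extract_et(state, 100.0, 0.0, 0.0, toy_profile,
                                  air_dry_fraction=0.5)
        assert evap == pytest.approx(7.0, abs=1e-9)
        assert new.theta[0] == pytest.approx(0.05, abs=1e-12)

    def test_allocation_matches_bisection_oracle(self):
        weight = np.array([4.0, 1.0, 0.0])
        cap = np.array([2.0, 4.0, 9.0])
        for demand in (0.5, 3.0, 5.5, 10.0):
            got = proportional_allocation(demand, weight, cap)
            want = allocation_oracle(demand, weight, cap)
            assert got == pytest.approx(want, abs=1e-8)
            assert got.sum() == pytest.approx(min(demand, 6.0), abs=1e-8)

    @given(
        demand=st.floats(0, 20),
        weight=st.lists(st.one_of(st.just(0.0), st.floats(0.01, 5)),
                        min_size=2, max_size=5),
        cap=st.lists(st.one_of(st.just(0.0), st.floats(0.01, 8)),
                     min_size=2, max_size=5),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_allocation_oracle_property(self, demand, weight, cap):
        n = min(len(weight), len(cap))
        w, c = np.array(weight[:n]), np.array(cap[:n])
        got = proportional_allocation(demand, w, c)
        want = allocation_oracle(demand, w, c)
        assert got == pytest.approx(want, abs=1e-6)

    def test_root_fractions_triangular(self, toy_profile):
        fr = triangular_root_fractions(toy_profile, 20.0)
        # density 1 - z/20: layer 0-10 holds 3/4 of the mass, 10-20 holds 1/4
        assert fr == pytest.approx([0.75, 0.25, 0.0], abs=1e-12)
        assert triangular_root_fractions(toy_profile, 0.0).sum() == 0.0


class TestProfileReporting:
    def test_uniform_profile(self, toy_profile):
        state = SoilWaterState(np.full(3, 0.30))
        vals = report_profile(state, toy_profile, [(0, 15), (15, 30)])
        assert vals == pytest.approx([0.30, 0.30])

    def test_weighted_mean_two_layers(self):
        mk = lambda top: SoilLayer(top=top, bottom=top + 15, bulk_density=1.3,
                                   theta_s=0.45, theta_fc=0.30, theta_wp=0.10)
        prof = SoilProfile((mk(0), mk(15)))
        state = SoilWaterState(np.array([0.20, 0.40]))
        assert report_profile(state, prof, [(0, 30)]) == pytest.approx([0.30])

    def test_irregular_layers_match_centimetre_resolution_average(self):
        bounds = [0, 7, 19, 30, 52, 90]
        layers = tuple(
            SoilLayer(top=a, bottom=b, bulk_density=1.4, theta_s=0.45,
                      theta_fc=0.30, theta_wp=0.10)
            for a, b in zip(bounds, bounds[1:]))
        prof = SoilProfile(layers)
        rng = np.random.default_rng(7)
        theta = rng.uniform(0.1, 0.4, size=len(layers))
        state = SoilWaterState(theta)
        intervals = [(0, 15), (15, 30), (30, 60), (60, 90)]
        got = report_profile(state, prof, intervals)
        # brute-force: sample every millimetre of depth
        z = np.arange(0, 90, 0.001) + 0.0005
        by_depth = np.empty_like(z)
        for lay, th in zip(layers, theta):
            by_depth[(z >= lay.top) & (z < lay.bottom)] = th
        for (a, b), val in zip(intervals, got):
            brute = by_depth[(z >= a) & (z < b)].mean()
            assert val == pytest.approx(brute, abs=1e-6)

    def test_interval_outside_domain_rejected(self, toy_profile):
        state = SoilWaterState(np.full(3, 0.3))
        with pytest.raises(ValueError):
            report_profile(state, toy_profile, [(0, 60)])
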