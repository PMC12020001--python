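"""Unit tests for the rose pair potential and its analytic gradients."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rosewater.forces import evaluate, evaluate_numpy, total_energy
from rosewater.params import ModelParams, preset
from rosewater.potential import (PairGeometry, hb_half_energy, hb_pair_energy,
                                 lj_energy, pair_energy, rose_orientational,
                                 switching)


def lj_shift(p):
    # cut-and-shift offset, recomputed by direct arithmetic
    x = (p.sigma_lj / p.lj_cutoff) ** 6
    return 4.0 * p.eps_lj * (x * x - x)


class TestParams:
    def test_preset_parameter_values(self, mb, real):
        assert (mb.eps_lj, mb.sigma_lj, mb.eps_hb) == (0.1, 0.7, 1.0)
        assert (mb.r_hb, mb.r_fwhm, mb.a1, mb.a2) == (1.0, 0.2, 0.6, -0.4)
        assert (real.eps_lj, real.sigma_lj) == (0.2, 0.890899)
        assert real.r_fwhm == 0.41666

    def test_derived_window_limits(self, mb, real):
        for p in (mb, real):
            assert p.r_l == p.r_hb - p.r_fwhm
            assert p.r_u == p.r_hb + p.r_fwhm

    def test_amax_from_brute_force_grid(self, mb, real):
        # a_max is the max magnitude of the unnormalized rose function
        th = np.linspace(0.0, 2.0 * np.pi, 1_000_001)
        for p in (mb, real):
            raw = p.a1 * np.cos(3 * th - np.pi) + p.a2 * np.cos(6 * th)
            assert abs(np.max(np.abs(raw)) - p.a_max) < 1e-9

    def test_serialization_round_trip(self, mb, tmp_path):
        mb.to_json(tmp_path / "p.json")
        assert ModelParams.from_json(tmp_path / "p.json") == mb
        mb.to_toml(tmp_path / "p.toml")
        assert ModelParams.from_toml(tmp_path / "p.toml") == mb

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            preset("nope")


class TestLJ:
    def test_zero_crossing_at_sigma(self, mb):
        # cut-and-shift moves the zero by the (tiny) shift value
        assert abs(lj_energy(mb.sigma_lj, mb)) < 1e-3 * mb.eps_lj
        assert lj_energy(mb.sigma_lj, mb) == pytest.approx(-lj_shift(mb))

    def test_minimum_depth(self, mb):
        r_min = 2 ** (1 / 6) * mb.sigma_lj
        assert lj_energy(r_min, mb) == pytest.approx(-mb.eps_lj - lj_shift(mb))
        assert abs(lj_energy(r_min, mb) + mb.eps_lj) < 1e-3

    def test_decay_beyond_cutoff(self, mb):
        assert lj_energy(10 * mb.sigma_lj, mb) == 0.0
        assert abs(lj_energy(10 * mb.sigma_lj, mb)) < 1e-6

    def test_domain_error(self, mb):
        with pytest.raises(ValueError):
            lj_energy(0.0, mb)


class TestRose:
    def test_minimum_is_exactly_minus_one_at_arm(self, mb, real):
        for p in (mb, real):
            assert rose_orientational(0.0, p) == -1.0

    def test_grid_minimum(self, mb):
        th = np.linspace(0, 2 * np.pi, 1_000_001)
        assert abs(np.min(rose_orientational(th, mb)) + 1.0) < 1e-6

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.floats(-10, 10))
    def test_three_petal_periodicity(self, theta):
        p = preset("mb")
        assert rose_orientational(theta, p) == pytest.approx(
            rose_orientational(theta + 2 * math.pi / 3, p), abs=1e-12)


class TestSwitching:
    def test_peak_limits_and_half_maximum(self, mb, real):
        for p in (mb, real):
            assert switching(p.r_hb, p) == 1.0
            assert switching(p.r_l, p) == pytest.approx(0.0, abs=1e-15)
            assert switching(p.r_u, p) == pytest.approx(0.0, abs=1e-15)
            # full width at half maximum equals r_fwhm
            assert switching(p.r_hb - p.r_fwhm / 2, p) == pytest.approx(0.5)
            assert switching(p.r_hb + p.r_fwhm / 2, p) == pytest.approx(0.5)

    def test_window_support(self, mb):
        r = np.linspace(0.01, 3.0, 500)
        s = switching(r, mb)
        assert np.all(s >= 0) and np.all(s <= 1)
        outside = (r <= mb.r_l) | (r >= mb.r_u)
        assert np.all(s[outside] == 0)

    def test_continuously_differentiable_at_stitches(self, mb):
        from rosewater.potential import switching_d

        h = 1e-7
        for r0 in (mb.r_l, mb.r_hb, mb.r_u):
            num = (switching(r0 + h, mb) - switching(r0 - h, mb)) / (2 * h)
            assert abs(num - switching_d(r0, mb)) < 1e-5


class TestHydrogenBond:
    def test_ideal_pair_energy_is_minus_eps_hb(self, mb, real):
        for p in (mb, real):
            gi = PairGeometry.from_global(p.r_hb, 0.0, 0.0)
            gj = PairGeometry.from_global(-p.r_hb, 0.0, math.pi)
            assert hb_pair_energy(gi, gj, p) == pytest.approx(-p.eps_hb)

    def test_outside_window_is_zero(self, mb):
        gi = PairGeometry.from_global(mb.r_u, 0.0, 0.0)
        gj = PairGeometry.from_global(-mb.r_u, 0.0, math.pi)
        assert hb_pair_energy(gi, gj, mb) == pytest.approx(0.0, abs=1e-15)
        gi = PairGeometry.from_global(1.5 * mb.r_u, 0.0, 0.0)
        gj = PairGeometry.from_global(-1.5 * mb.r_u, 0.0, math.pi)
        assert hb_pair_energy(gi, gj, mb) == 0.0

    def test_half_bond_independent_of_partner(self, mb):
        # molecule i ideally aligned: its half is -eps_hb/2 whatever j does
        assert hb_half_energy(mb.r_hb, 0.0, mb) == -0.5 * mb.eps_hb
        totals = []
        for phi_j in np.linspace(0, 2 * np.pi, 181):
            gi = PairGeometry.from_global(1.0, 0.0, 0.0)
            gj = PairGeometry.from_global(-1.0, 0.0, phi_j)
            totals.append(hb_pair_energy(gi, gj, mb))
        i_half = np.array(totals) - [
            hb_half_energy(1.0, math.atan2(0, -1) - phi_j, mb)
            for phi_j in np.linspace(0, 2 * np.pi, 181)]
        assert np.allclose(i_half, -0.5, atol=1e-12)
        # each half is bounded below by -eps_hb/2
        assert min(totals) >= -mb.eps_hb - 1e-12

    def test_inconsistent_distances_rejected(self, mb):
        with pytest.raises(ValueError):
            hb_pair_energy(PairGeometry(1.0, 0.0), PairGeometry(1.1, 0.0), mb)


class TestPairEnergy:
    def test_additivity_when_hb_window_closed(self, mb):
        r = 1.5  # outside [0.8, 1.2]
        assert pair_energy(r, 0.0, 0.3, 1.2, mb) == pytest.approx(
            float(lj_energy(r, mb)))

    def test_ideal_mb_pair_value(self, mb):
        # oracle: direct arithmetic of the 12-6 form at r = 1
        lj_raw = 4 * 0.1 * (0.7 ** 12 - 0.7 ** 6)
        expected = lj_raw - lj_shift(mb) - 1.0
        assert pair_energy(1.0, 0.0, 0.0, math.pi, mb) == pytest.approx(
            expected, abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(0, 2 * math.pi), st.floats(0.85, 1.6),
           st.floats(0, 2 * math.pi), st.floats(0, 2 * math.pi))
    def test_frame_invariance(self, rot, r, phi_i, phi_j):
        p = preset("mb")
        base = pair_energy(r, 0.0, phi_i, phi_j, p)
        rotated = pair_energy(r * math.cos(rot), r * math.sin(rot),
                              phi_i + rot, phi_j + rot, p)
        assert rotated == pytest.approx(base, abs=1e-12)

    def test_overlap_rejected(self, mb):
        with pytest.raises(ValueError):
            pair_energy(0.0, 0.0, 0.0, 0.0, mb)

    @pytest.mark.parametrize("preset_name", ["mb", "real"])
    def test_global_minimum_by_brute_force(self, preset_name):
        # minimum over (r, theta_i, theta_j) is a full bond at the
        # distance minimizing lj(r) - s(r)
        p = preset(preset_name)
        r_grid = np.linspace(0.6, 1.6, 401)
        th = np.linspace(-math.pi / 3, math.pi / 3, 121)
        best = np.inf
        for r in r_grid:
            u_best_th = (0.5 * p.eps_hb * switching(r, p)
                         * (rose_orientational(th, p).min()) * 2)
            best = min(best, float(lj_energy(r, p)) + u_best_th)
        radial = lj_energy(r_grid, p) - p.eps_hb * switching(r_grid, p)
        assert best == pytest.approx(np.min(radial), abs=1e-9)
        # the full bond sits essentially at r_hb (exactly for "real",
        # within the LJ/switching competition for "mb")
        assert best == pytest.approx(
            float(lj_energy(p.r_hb, p)) - p.eps_hb, abs=1e-3)


class TestForcesAndTorques:
    def test_matches_finite_differences_on_random_dimers(self, mb):
        rng = np.random.default_rng(0)
        box = np.array([10.0, 10.0])
        h = 1e-6
        for _ in range(50):
            pos = rng.random((2, 2)) * 2.0 + 4.0
            phi = rng.random(2) * 2 * np.pi
            ft = evaluate_numpy(pos, phi, box, mb)
            for i in range(2):
                for d in range(2):
                    pp = pos.copy()
                    pp[i, d] += h
                    em = total_energy(pp, phi, box, mb)
                    pp[i, d] -= 2 * h
                    el = total_energy(pp, phi, box, mb)
                    num = -(em - el) / (2 * h)
                    assert abs(num - ft["forces"][i, d]) <= 1e-6 * max(
                        1.0, abs(num))
                ph = phi.copy()
                ph[i] += h
                em = total_energy(pos, ph, box, mb)
                ph[i] -= 2 * h
                el = total_energy(pos, ph, box, mb)
                num = -(em - el) / (2 * h)
                assert abs(num - ft["torques"][i]) <= 1e-6 * max(1, abs(num))

    def test_translation_invariance_total_force(self, mb):
        from rosewater.lattices import make_gas

        conf = make_gas(60, (7.0, 7.0), 0.55, seed=3)
        ft = evaluate(conf.positions, conf.orientations, conf.box, mb)
        assert np.abs(ft["forces"].sum(axis=0)).max() < 1e-10

    def test_torque_vanishes_at_orientational_extremum(self, mb):
        # both molecules arm-aligned: stationary point of the rose term
        pos = np.array([[2.0, 2.0], [3.0, 2.0]])
        phi = np.array([0.0, math.pi])
        ft = evaluate_numpy(pos, phi, np.array([10.0, 10.0]), mb)
        assert np.abs(ft["torques"]).max() < 1e-10

    def test_numba_and_numpy_paths_agree(self, mb):
        from rosewater.lattices import make_gas

        conf = make_gas(50, (7.0, 7.0), 0.5, seed=9)
        a = evaluate(conf.positions, conf.orientations, conf.box, mb)
        b = evaluate_numpy(conf.positions, conf.orientations, conf.box, mb)
        assert a["energy"] == pytest.approx(b["energy"], abs=1e-12)
        assert np.allclose(a["forces"], b["forces"], atol=1e-11)
        assert np.allclose(a["torques"], b["torques"], atol=1e-12)
        assert a["virial"] == pytest.approx(b["virial"], abs=1e-10)

    def test_coincident_centers_rejected(self, mb):
        pos = np.zeros((3, 2))
        pos[2] = [1.0, 1.0]
        with pytest.raises(ValueError):
            evaluate(pos, np.zeros(3), np.array([5.0, 5.0]), mb)


class TestEnergyInvariances:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_relabeling_invariance(self, seed):
        from rosewater.lattices import make_gas

        p = preset("mb")
        conf = make_gas(20, (5.0, 5.0), 0.4, seed=seed)
        rng = np.random.default_rng(seed + 1)
        perm = rng.permutation(20)
        e1 = total_energy(conf.positions, conf.orientations, conf.box, p)
        e2 = total_energy(conf.positions[perm], conf.orientations[perm],
                          conf.box, p)
        assert e1 == pytest.approx(e2, abs=1e-11)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_translation_invariance(self, sx, sy):
        from rosewater.lattices import make_gas

        p = preset("mb")
        conf = make_gas(20, (5.0, 5.0), 0.4, seed=17)
        e1 = total_energy(conf.positions, conf.orientations, conf.box, p)
        shifted = np.mod(conf.positions + [sx, sy], conf.box)
        e2 = total_energy(shifted, conf.orientations, conf.box, p)
        assert e1 == pytest.approx(e2, abs=1e-10)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(0, 2 * math.pi))
    def test_global_rotation_invariance(self, rot):
        # isolated cluster in a huge box so periodic wrapping is inert
        p = preset("mb")
        rng = np.random.default_rng(5)
        pos = rng.random((15, 2)) * 6.0 + 20.0
        phi = rng.random(15) * 2 * np.pi
        box = np.array([100.0, 100.0])
        c, s = math.cos(rot), math.sin(rot)
        rmat = np.array([[c, -s], [s, c]])
        ctr = pos.mean(axis=0)
        pos2 = (pos - ctr) @ rmat.T + ctr
        e1 = total_energy(pos, phi, box, p)
        e2 = total_energy(pos2, phi + rot, box, p)
        assert e1 == pytest.approx(e2, rel=1e-10, abs=1e-10)
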