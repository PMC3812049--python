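"""Binding analysis: RMSD, classification, constraint, free-energy
estimators, profiles, entropies, RMSD-conditioned distributions."""

import numpy as np
import pytest

from pepscreen import (BindingDefinition, ConstraintSpec, ScreenResult,
                       ThermoState, classify_bound, constraint_energy,
                       estimate_delta_f_fixed, estimate_delta_f_screen,
                       merge_screen_results, profile_by_rmsd, rmsd,
                       sequence_entropy)
from pepscreen.chain import ALPHABET


class TestRmsd:
    def test_identical_coordinates_give_zero(self):
        c = np.random.default_rng(0).normal(size=(5, 3))
        assert rmsd(c, c) == 0.0

    def test_single_site_displacement_closed_form(self):
        a = np.zeros((1, 3))
        b = np.array([[3.0, 0.0, 0.0]])
        assert rmsd(a, b) == pytest.approx(3.0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = rng.normal(size=(7, 3))
            b = rng.normal(size=(7, 3))
            acc = 0.0
            for i in range(7):
                for k in range(3):
                    acc += (a[i, k] - b[i, k]) ** 2
            assert rmsd(a, b) == pytest.approx(np.sqrt(acc / 7))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestClassifyBound:
    def test_strict_cutoff(self):
        binding = BindingDefinition(np.zeros((2, 3)), rmsd_cutoff=6.0)
        assert classify_bound(5.99, binding)
        assert not classify_bound(6.0, binding)  # strictly below
        assert classify_bound(0.0, binding)


class TestConstraintEnergy:
    def test_zero_inside_onset(self):
        spec = ConstraintSpec(strength=1.0, onset=10.0)
        assert constraint_energy(0.0, spec) == 0.0
        assert constraint_energy(10.0, spec) == 0.0

    def test_linear_ramp(self):
        spec = ConstraintSpec(strength=2.0, onset=10.0)
        assert constraint_energy(12.0, spec) == pytest.approx(4.0)

    def test_continuity_at_onset(self):
        spec = ConstraintSpec(strength=3.0, onset=10.0)
        eps = 1e-9
        assert constraint_energy(10.0 + eps, spec) == pytest.approx(0.0,
                                                                    abs=1e-8)

    def test_validation(self):
        with pytest.raises(ValueError):
            ConstraintSpec(strength=-1.0)
        with pytest.raises(ValueError):
            ConstraintSpec(onset=0.0)


class TestSequenceEntropy:
    def test_uniform_profile_is_ln20(self):
        assert sequence_entropy(np.full(20, 1 / 20)) == pytest.approx(
            np.log(20.0), rel=1e-12)

    def test_degenerate_profile_is_zero(self):
        p = np.zeros(20)
        p[3] = 1.0
        assert sequence_entropy(p) == 0.0

    def test_two_state_profile_is_ln2(self):
        p = np.zeros(20)
        p[0] = p[1] = 0.5
        assert sequence_entropy(p) == pytest.approx(np.log(2.0))


class TestDeltaFFixed:
    def test_equal_fractions_give_zero(self, thermo):
        flags = np.array([True, False] * 500)
        est = estimate_delta_f_fixed(flags, thermo)
        assert est.delta_f == pytest.approx(0.0)

    def test_closed_form_ratio(self):
        # P_B/P_U = e^{-1} at T = 1 -> dF = +1
        thermo = ThermoState(1.0)
        nb = 1000
        nu = int(round(nb * np.e))
        flags = np.concatenate([np.ones(nb, bool), np.zeros(nu, bool)])
        est = estimate_delta_f_fixed(flags, thermo)
        assert est.delta_f == pytest.approx(1.0, abs=2e-4)

    def test_replicates_give_standard_error(self, thermo):
        rng = np.random.default_rng(3)
        runs = [rng.random(2000) < 0.3 for _ in range(4)]
        est = estimate_delta_f_fixed(runs, thermo)
        assert np.isfinite(est.std_err) and est.std_err > 0

    def test_no_transitions_is_an_error(self, thermo):
        with pytest.raises(ValueError, match="undefined"):
            estimate_delta_f_fixed(np.ones(100, bool), thermo)
        with pytest.raises(ValueError, match="undefined"):
            estimate_delta_f_fixed(np.zeros(100, bool), thermo)


def _result_from_counts(bound_counts, unbound_counts=None, n_var=1, T=1.0):
    unbound_counts = unbound_counts or {}
    n_bins = 40
    bpc = np.zeros((n_var, 20), dtype=int)
    for s, c in bound_counts.items():
        for i, ch in enumerate(s):
            bpc[i, ALPHABET.index(ch)] += c
    upc = np.zeros((n_var, 20), dtype=int)
    for s, c in unbound_counts.items():
        for i, ch in enumerate(s):
            upc[i, ALPHABET.index(ch)] += c
    nb = sum(bound_counts.values())
    nu = sum(unbound_counts.values())
    rbc = np.zeros((n_bins, n_var, 20), dtype=int)
    rbc[2] = bpc
    rbc[15] = upc
    return ScreenResult(variable_positions=np.arange(n_var),
                        bound_counts=bound_counts,
                        unbound_counts=unbound_counts,
                        bound_pos_counts=bpc, unbound_pos_counts=upc,
                        rmsd_bin_counts=rbc, n_bound=nb, n_total=nb + nu,
                        temperature=T)


class TestDeltaFScreen:
    def test_equal_counts_equal_delta_f(self, thermo):
        res = _result_from_counts({"A": 500, "K": 500}, T=thermo.T)
        df = estimate_delta_f_screen(res, thermo)
        assert df["A"] == pytest.approx(df["K"])

    def test_count_ratio_e_gives_unit_difference(self):
        thermo = ThermoState(1.0)
        nb = 10_000
        res = _result_from_counts({"A": int(round(nb * np.e)), "K": nb})
        df = estimate_delta_f_screen(res, thermo)
        assert df["A"] - df["K"] == pytest.approx(-1.0, abs=1e-4)

    def test_weakest_observed_binder_is_reference_zero(self, thermo):
        res = _result_from_counts({"A": 900, "K": 95, "W": 5})
        df = estimate_delta_f_screen(res, thermo, min_count=10)
        assert df["K"] == pytest.approx(0.0)  # weakest well-observed binder
        assert df["W"] > 0.0   # below min_count: reported, cannot anchor
        assert df["A"] < 0.0

    def test_unobserved_sequences_absent(self, thermo):
        res = _result_from_counts({"A": 100})
        df = estimate_delta_f_screen(res, thermo)
        assert list(df.index) == ["A"]

    def test_no_bound_samples_is_an_error(self, thermo):
        res = _result_from_counts({}, {"A": 10})
        with pytest.raises(ValueError, match="no bound samples"):
            estimate_delta_f_screen(res, thermo)


class TestProfiles:
    def test_profiles_normalized(self, thermo):
        res = _result_from_counts({"AK": 60, "WK": 40}, n_var=2)
        prof = res.profiles()
        np.testing.assert_allclose(prof.sum(axis=1), 1.0)

    def test_degenerate_position(self, thermo):
        res = _result_from_counts({"AK": 60, "WK": 40}, n_var=2)
        p1 = res.position_profile(1)
        assert p1[ALPHABET.index("K")] == 1.0
        assert sequence_entropy(p1) == 0.0

    def test_entropy_bounds(self):
        res = _result_from_counts({"AK": 60, "WK": 40}, n_var=2)
        ent = res.entropies()
        assert np.all(ent >= 0) and np.all(ent <= np.log(20) + 1e-12)

    def test_counts_conserved(self):
        res = _result_from_counts({"A": 70}, {"K": 30})
        assert res.n_bound + (res.n_total - res.n_bound) == res.n_total
        assert res.p_bound == pytest.approx(0.7)


class TestProfileByRmsd:
    def test_bins_normalized_and_empty_bins_absent(self):
        res = _result_from_counts({"A": 80, "W": 20}, {"K": 50})
        prof = profile_by_rmsd(res, 0)
        np.testing.assert_allclose(prof.sum(axis=1), 1.0)
        assert set(prof.index) == {2, 15}  # only populated bins reported

    def test_low_bin_reflects_bound_composition(self):
        res = _result_from_counts({"A": 80, "W": 20}, {"K": 50})
        prof = profile_by_rmsd(res, 0)
        assert prof.loc[2, "A"] == pytest.approx(0.8)
        assert prof.loc[15, "K"] == pytest.approx(1.0)


class TestMerge:
    def test_counts_add(self):
        r1 = _result_from_counts({"A": 10, "K": 5}, {"W": 3})
        r2 = _result_from_counts({"A": 7}, {"K": 2})
        merged = merge_screen_results([r1, r2])
        assert merged.bound_counts == {"A": 17, "K": 5}
        assert merged.n_total == r1.n_total + r2.n_total

    def test_incompatible_runs_rejected(self):
        r1 = _result_from_counts({"A": 10})
        r2 = _result_from_counts({"AK": 10}, n_var=2)
        with pytest.raises(ValueError):
            merge_screen_results([r1, r2])
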