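"""Monte Carlo engine: acceptance rule, proposal symmetry, determinism,
and stationary distributions checked against exact enumeration."""

import numpy as np
import pytest

from pepscreen import (MoveSchedule, SequenceState, ThermoState,
                       metropolis_accept, propose_mutation, run, run_toy,
                       make_free_peptide)
from pepscreen.mcmc import MOVE_NAMES


class TestMetropolisAccept:
    def test_zero_delta_always_accepts(self, thermo):
        for u in (0.0, 0.5, 0.999999):
            assert metropolis_accept(0.0, 0.0, thermo, u)

    def test_downhill_always_accepts(self, thermo):
        for u in (0.0, 0.5, 0.999999):
            assert metropolis_accept(-1.0, 0.0, thermo, u)

    def test_gamma_term_enters_joint_weight(self, thermo):
        # uphill in energy exactly compensated by delta_g
        dE = 0.9
        dg = thermo.beta * dE
        assert metropolis_accept(dE, dg, thermo, 0.999999)

    @pytest.mark.parametrize("dE,dg,T", [(0.7, 0.0, 1.0), (1.2, 0.4, 0.6),
                                         (0.3, -0.5, 2.0)])
    def test_empirical_rate_matches_closed_form(self, dE, dg, T):
        """Acceptance frequency over many uniform draws matches
        min(1, exp(-beta dE + dg)) within 3 standard errors."""
        thermo = ThermoState(T)
        rng = np.random.default_rng(12345)
        n = 100_000
        us = rng.random(n)
        acc = np.fromiter((metropolis_accept(dE, dg, thermo, u) for u in us),
                          dtype=bool, count=n)
        p = min(1.0, np.exp(-dE / T + dg))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(acc.mean() - p) < 3 * se + 1e-12


class TestProposeMutation:
    def test_single_variable_position_always_chosen(self):
        seq = SequenceState.from_string("AKLA", "..x.")
        rng = np.random.default_rng(0)
        for _ in range(50):
            pos, _ = propose_mutation(seq, rng)
            assert pos == 2

    def test_fixed_positions_never_proposed(self):
        seq = SequenceState.from_string("AKLAW", "x..x.")
        rng = np.random.default_rng(1)
        positions = {propose_mutation(seq, rng)[0] for _ in range(500)}
        assert positions == {0, 3}

    def test_proposal_uniform_over_positions_and_types(self):
        """Histogram over (positions x 20 types) uniform within 3 SE."""
        seq = SequenceState.from_string("AKA", "xx.")
        rng = np.random.default_rng(2)
        n = 100_000
        counts = np.zeros((2, 20))
        for _ in range(n):
            pos, t = propose_mutation(seq, rng)
            counts[pos, t] += 1
        p = counts / n
        expected = 1.0 / 40
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(p - expected) < 3.5 * se)

    def test_exclude_current_never_self_proposes(self):
        seq = SequenceState.from_string("AAA", ".x.")
        rng = np.random.default_rng(3)
        for _ in range(200):
            _, t = propose_mutation(seq, rng, include_current=False)
            assert t != seq.residues[1]

    def test_no_variable_positions_raises(self):
        seq = SequenceState.from_string("AK")
        with pytest.raises(ValueError):
            propose_mutation(seq, np.random.default_rng(0))


class TestMoveSchedule:
    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            MoveSchedule(pivot=-1.0).cumulative(True, True)

    def test_all_zero_rejected(self):
        s = MoveSchedule(pivot=0, rotamer=0, rigid_rot=0, rigid_trans=0,
                         mutation=0, receptor=0)
        with pytest.raises(ValueError):
            s.cumulative(True, True)

    def test_fixed_sequence_disables_mutation(self):
        s = MoveSchedule().fixed_sequence()
        assert s.mutation == 0.0


class TestToySampler:
    def test_same_seed_identical_counts(self, toy_model, thermo):
        r1 = run_toy(toy_model, thermo, n_steps=20_000, seed=9)
        r2 = run_toy(toy_model, thermo, n_steps=20_000, seed=9)
        np.testing.assert_array_equal(r1.counts, r2.counts)

    def test_fixed_sequence_canonical_sampling(self, toy_model, thermo):
        """With mutations disabled the state histogram matches the
        canonical Boltzmann distribution from exact enumeration."""
        res = run_toy(toy_model, thermo, n_steps=400_000, seed=4,
                      burn_in=20_000, p_conf=1.0)
        p_emp = res.state_marginal()
        seq0 = np.zeros(toy_model.n_var, dtype=int)
        e = np.array([toy_model.total_energy(c, seq0)
                      for c in range(toy_model.n_states)])
        w = np.exp(-thermo.beta * e)
        tv = 0.5 * np.abs(p_emp - w / w.sum()).sum()
        assert tv < 0.01

    def test_joint_marginal_matches_enumeration(self, toy_model, thermo):
        """Full joint run: empirical P(s) matches the exact
        Z_s e^{g_s} normalization."""
        rng = np.random.default_rng(6)
        gamma = rng.normal(0, 0.4, toy_model.n_alpha)
        res = run_toy(toy_model, thermo, n_steps=1_000_000, seed=5,
                      burn_in=50_000, gamma=gamma)
        ex = toy_model.enumerate_exact(thermo.T)
        g = np.array([gamma[toy_model.seq_of_index(s)].sum()
                      for s in range(toy_model.n_seq)])
        w = ex.Z * np.exp(g)
        tv = 0.5 * np.abs(res.p_seq() - w / w.sum()).sum()
        assert tv < 0.02

    def test_ergodicity_all_sequences_visited(self, toy_model, thermo):
        res = run_toy(toy_model, thermo, n_steps=100_000, seed=7)
        assert np.all(res.seq_counts > 0)

    def test_restriction_to_subsets(self, toy_model, thermo):
        rb = run_toy(toy_model, thermo, n_steps=50_000, seed=8, restrict="B")
        assert rb.counts[~toy_model.bound].sum() == 0
        ru = run_toy(toy_model, thermo, n_steps=50_000, seed=8, restrict="U")
        assert ru.counts[toy_model.bound].sum() == 0

    def test_g_independence_of_bound_unbound_ratio(self, toy_model, thermo):
        """Estimated P_B(s)/P_U(s) is invariant across gamma tables
        (within 3 replicate standard errors), per the ratio identity."""
        ex = toy_model.enumerate_exact(thermo.T)
        log_exact = np.log(ex.P_B / ex.P_U)
        rng = np.random.default_rng(10)
        means = []
        ses = []
        for k in range(3):
            gamma = rng.normal(0, 0.6, toy_model.n_alpha) if k else None
            logs = []
            for rep in range(3):
                res = run_toy(toy_model, thermo, n_steps=600_000,
                              seed=30 + 10 * k + rep, burn_in=30_000,
                              gamma=gamma)
                b = res.seq_counts_bound.astype(float)
                u = res.seq_counts_unbound.astype(float)
                with np.errstate(divide="ignore"):
                    logs.append(np.log(b) - np.log(u))
            logs = np.array(logs)
            means.append(logs.mean(axis=0))
            ses.append(logs.std(axis=0, ddof=1) / np.sqrt(3))
        for m, s in zip(means, ses):
            ok = np.isfinite(m) & (s > 0)
            assert ok.sum() >= 5
            z = np.abs(m[ok] - log_exact[ok]) / s[ok]
            # each gamma choice reproduces the exact ratios
            assert np.median(z) < 3.0
        # and the gamma choices agree with each other
        for k in (1, 2):
            s = np.sqrt(ses[0] ** 2 + ses[k] ** 2)
            ok = np.isfinite(means[0]) & np.isfinite(means[k]) & (s > 0)
            z = np.abs(means[0][ok] - means[k][ok]) / s[ok]
            assert np.median(z) < 3.0


class TestConstraintNeutrality:
    def test_reweighting_unbound_states_leaves_conditional_unchanged(
            self, toy_model, thermo):
        """A pocket-constraint-like penalty on unbound states only
        re-weights U; the bound-state conditional P(s|B) is unchanged —
        exactly under enumeration, within sampling error in MC."""
        import copy
        penalized = copy.deepcopy(toy_model)
        penalized.e_state = penalized.e_state.copy()
        penalized.e_state[~penalized.bound] += 1.3
        ex0 = toy_model.enumerate_exact(thermo.T)
        ex1 = penalized.enumerate_exact(thermo.T)
        np.testing.assert_allclose(ex1.p_s_given_B, ex0.p_s_given_B,
                                   rtol=1e-12)
        r0 = run_toy(toy_model, thermo, n_steps=800_000, seed=71,
                     burn_in=40_000)
        r1 = run_toy(penalized, thermo, n_steps=800_000, seed=72,
                     burn_in=40_000)
        tv = 0.5 * np.abs(r0.p_seq_given_bound()
                          - r1.p_seq_given_bound()).sum()
        assert tv < 0.03


class TestChainSampler:
    def test_same_seed_identical_records(self, tripeptide, cg_model, thermo):
        r1 = run(tripeptide, cg_model, thermo, n_steps=20_000, seed=3,
                 record_interval=50)
        r2 = run(tripeptide, cg_model, thermo, n_steps=20_000, seed=3,
                 record_interval=50)
        assert r1.records.equals(r2.records)
        np.testing.assert_array_equal(r1.pos_counts, r2.pos_counts)

    def test_acceptance_counters_consistent(self, tripeptide, cg_model, thermo):
        res = run(tripeptide, cg_model, thermo, n_steps=30_000, seed=4)
        assert res.attempted.sum() == 30_000
        assert np.all(res.accepted <= res.attempted)
        assert set(res.acceptance_rates) == set(MOVE_NAMES)
        # free peptide: no receptor moves possible
        assert res.attempted[5] == 0

    def test_input_system_not_modified(self, tripeptide, cg_model, thermo):
        before = tripeptide.seq.residues.copy()
        phi = tripeptide.dofs.phi.copy()
        run(tripeptide, cg_model, thermo, n_steps=5_000, seed=5)
        np.testing.assert_array_equal(tripeptide.seq.residues, before)
        np.testing.assert_array_equal(tripeptide.dofs.phi, phi)

    def test_rotamer_relaxes_phantom_angles_to_uniform(self, cg_model, thermo):
        """Unused chi angles are random-walked by rotamer moves and tend
        to a uniform distribution."""
        pep = make_free_peptide("AAA", ".x.")
        res = run(pep, cg_model, thermo, n_steps=400_000, seed=6,
                  record_interval=40, record_angles=True)
        chi5 = res.angles["chi"][:, 1, 4]  # always phantom
        hist, _ = np.histogram(chi5, bins=12, range=(-np.pi, np.pi))
        p = hist / hist.sum()
        assert np.max(np.abs(p - 1.0 / 12)) < 0.02
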