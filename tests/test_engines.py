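"""Search engines: selection rules, evaluation accounting, convergence,
and cross-checks between the compiled and pure-Python paths."""

import numpy as np
import pytest

from biors import (ConsensusSpec, EngineConfig, LayoutSpec, mu_lambda_select,
                   run_ga, run_parallel_rmhc, run_rmhc, run_search,
                   sigma_scaling_expected, sus_sample)
from biors.fitness import EncodedProblem


class TestMuLambdaSelect:
    def test_survivors_are_the_fittest(self):
        parents = mu_lambda_select(np.arange(1, 11), mu=4)
        assert set(parents) == {9, 8, 7, 6}

    def test_slot_apportionment_remainder_to_best(self):
        parents = mu_lambda_select(np.arange(1, 11), mu=4)
        counts = {i: int((parents == i).sum()) for i in (9, 8, 7, 6)}
        assert counts == {9: 3, 8: 3, 7: 2, 6: 2}

    def test_mu_equals_lambda_is_identity_selection(self):
        parents = mu_lambda_select(np.array([3, 1, 2]), mu=3)
        assert sorted(parents.tolist()) == [0, 1, 2]

    def test_ties_break_by_stable_order(self):
        parents = mu_lambda_select(np.array([5, 5, 5, 0]), mu=1)
        assert set(parents) == {0}


class TestSigmaScaling:
    def test_zero_variance_gives_unit_expectation(self):
        assert np.allclose(sigma_scaling_expected([5, 5, 5]), 1.0)

    def test_mean_fitness_gives_unit_expectation(self):
        e = sigma_scaling_expected([1.0, 2.0, 3.0])
        assert e[1] == pytest.approx(1.0)

    def test_two_sigma_above_mean_gives_two(self):
        # F = (2,2,2,2,6): mean 2.8, sigma 1.6, so F_5 - mean = 2 sigma
        e = sigma_scaling_expected([2, 2, 2, 2, 6])
        assert e[-1] == pytest.approx(2.0)

    def test_negative_expectation_floored(self):
        e = sigma_scaling_expected([0, 10, 10, 10, 10, 10, 10])
        assert e[0] == pytest.approx(0.1)

    def test_sus_counts_match_expectations_within_one(self, rng):
        e = np.array([2.0, 1.0, 0.5, 0.5])
        idx = sus_sample(e, lam=4, rng=rng)
        assert idx.size == 4
        counts = np.bincount(idx, minlength=4)
        assert all(np.floor(e[i]) <= counts[i] <= np.ceil(e[i]) for i in range(4))


ONE_BASE = ConsensusSpec(1, {1: "A"}, {})
ONE_BASE_LAYOUT = LayoutSpec(n_domains=1, window=1, core_length=1, delta=100)


class TestGA:
    def test_toy_search_always_succeeds(self, toy_spec, toy_layout):
        cfg = EngineConfig(engine="ga", population_size=20, nmut=1.5, eval_cap=500_000)
        out = run_ga(toy_layout, toy_spec, "simple", cfg, rng=3)
        assert out.success
        assert out.best_result.total >= toy_layout.n_domains * toy_layout.delta

    def test_expected_evaluations_match_markov_chain_oracle(self):
        """One unique base, W=1, N=1, P=2, Nmut=0.5: the closed-form expected
        hitting time (absorbing chain over sequential evaluations) is 8.5."""
        # E_init = 1/4 + 2*(3/16) + (9/16)(2 + E_gen), E_gen = 12 for q = p/3 = 1/12
        expected = 8.5
        cfg = EngineConfig(engine="ga", population_size=2, mu_fraction=0.5,
                           nmut=0.5, eval_cap=10_000)
        evs = np.array([run_ga(ONE_BASE_LAYOUT, ONE_BASE, "simple", cfg, rng=s).evaluations
                        for s in range(3000)])
        assert evs.mean() == pytest.approx(expected, abs=3 * evs.std(ddof=1) / np.sqrt(evs.size))

    def test_evaluation_count_audited_by_injected_wrapper(self, toy_spec, toy_layout):
        prob = EncodedProblem(toy_layout, toy_spec, "simple")
        calls = [0]

        def counting(g):
            calls[0] += 1
            return prob.fitness_total(g)

        cfg = EngineConfig(engine="ga", population_size=10, nmut=1.5, eval_cap=50_000)
        out = run_ga(toy_layout, toy_spec, "simple", cfg, rng=11, fitness_fn=counting)
        assert out.success
        assert calls[0] == out.evaluations  # every computed fitness is counted

    def test_python_and_kernel_paths_agree_in_distribution(self, toy_spec, toy_layout):
        prob = EncodedProblem(toy_layout, toy_spec, "simple")
        cfg = EngineConfig(engine="ga", population_size=10, nmut=1.5, eval_cap=100_000)
        fast = np.array([run_ga(toy_layout, toy_spec, "simple", cfg, rng=s).evaluations
                         for s in range(150)])
        slow = np.array([run_ga(toy_layout, toy_spec, "simple", cfg, rng=1000 + s,
                                fitness_fn=prob.fitness_total).evaluations
                         for s in range(150)])
        se = np.hypot(fast.std(ddof=1) / np.sqrt(fast.size),
                      slow.std(ddof=1) / np.sqrt(slow.size))
        assert abs(fast.mean() - slow.mean()) < 4 * se

    def test_crossover_and_local_mutagenesis_paths_run(self, toy_spec, toy_layout):
        for cross, rate in [("single_point", 0.3), ("two_point", 0.3), ("segment", 0.3)]:
            cfg = EngineConfig(engine="ga", population_size=12, nmut=1.5,
                               crossover=cross, crossover_rate=rate, eval_cap=300_000,
                               local_mutagenesis=True)
            assert run_ga(toy_layout, toy_spec, "simple", cfg, rng=7).success

    def test_seed_determinism(self, toy_spec, toy_layout):
        cfg = EngineConfig(engine="ga", population_size=10, nmut=1.5,
                          eval_cap=100_000, seed=42)
        a = run_search(toy_layout, toy_spec, "simple", cfg)
        b = run_search(toy_layout, toy_spec, "simple", cfg)
        assert (a.evaluations, a.best_genome) == (b.evaluations, b.best_genome)

    def test_cap_out_reports_failure(self, toy_spec, toy_layout):
        cfg = EngineConfig(engine="ga", population_size=10, nmut=1.5, eval_cap=40)
        out = run_ga(toy_layout, toy_spec, "simple", cfg, rng=0)
        assert not out.success
        assert out.evaluations <= 40


def _python_rmhc_oracle(layout, spec, nmut, seed, cap=200_000):
    """Independent hill-climbing reference written directly in the test."""
    from biors.fitness import biors_fitness
    from biors.consensus import decode_sequence
    rng = np.random.default_rng(seed)
    L = layout.total_length
    g = rng.integers(0, 4, L, dtype=np.uint8)
    fit = biors_fitness(decode_sequence(g), layout, spec, "simple").total
    target = layout.n_domains * layout.delta
    evals = 1
    while fit < target and evals < cap:
        cand = g.copy()
        hit = rng.random(L) < nmut / L
        cand[hit] = (cand[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        f = biors_fitness(decode_sequence(cand), layout, spec, "simple").total
        evals += 1
        if f >= fit:
            g, fit = cand, f
    return evals


class TestRMHC:
    def test_accepted_fitness_is_monotone(self, toy_spec, toy_layout):
        prob = EncodedProblem(toy_layout, toy_spec, "simple")
        cfg = EngineConfig(engine="rmhc", nmut=2, eval_cap=100_000)
        out = run_rmhc(toy_layout, toy_spec, "simple", cfg, rng=1,
                       fitness_fn=prob.fitness_total)
        fits = [h[2] for h in out.history]
        assert fits == sorted(fits)
        assert out.success

    def test_mean_evaluations_match_independent_oracle(self, toy_spec):
        layout = LayoutSpec(n_domains=1, window=4, core_length=6, delta=100)
        cfg = EngineConfig(engine="rmhc", nmut=2, eval_cap=200_000)
        ours = np.array([run_rmhc(layout, toy_spec, "simple", cfg, rng=s).evaluations
                         for s in range(400)])
        oracle = np.array([_python_rmhc_oracle(layout, toy_spec, 2, 10_000 + s)
                           for s in range(400)])
        se = np.hypot(ours.std(ddof=1) / 20, oracle.std(ddof=1) / 20)
        assert abs(ours.mean() - oracle.mean()) < 4 * se

    def test_evaluation_audit(self, toy_spec, toy_layout):
        prob = EncodedProblem(toy_layout, toy_spec, "simple")
        calls = [0]

        def counting(g):
            calls[0] += 1
            return prob.fitness_total(g)

        cfg = EngineConfig(engine="rmhc", nmut=2, eval_cap=100_000)
        out = run_rmhc(toy_layout, toy_spec, "simple", cfg, rng=5, fitness_fn=counting)
        assert calls[0] == out.evaluations

    def test_epoch_transitions_are_ordered(self, toy_spec):
        layout = LayoutSpec(n_domains=3, window=8, core_length=6, delta=100)
        cfg = EngineConfig(engine="rmhc", nmut=2, eval_cap=2_000_000)
        out = run_rmhc(layout, toy_spec, "simple", cfg, rng=9)
        assert out.success
        ep = list(out.epoch_evals)
        assert ep == sorted(ep) and ep[0] >= 1

    def test_ideal_criterion_enforces_minimum_increments(self, toy_spec, toy_layout):
        cfg = EngineConfig(engine="rmhc", nmut=2, eval_cap=2_000_000,
                           success="ideal", min_increment=toy_spec.n_defined)
        out = run_rmhc(toy_layout, toy_spec, "simple", cfg, rng=2)
        assert out.success
        assert all(d.increment == toy_spec.n_defined for d in out.best_result.per_domain)


class TestParallelRMHC:
    def test_m1_matches_rmhc_in_distribution(self, toy_spec, toy_layout):
        rmhc_cfg = EngineConfig(engine="rmhc", nmut=2, eval_cap=300_000)
        par_cfg = EngineConfig(engine="parallel_rmhc", nmut=2, n_parallel=1,
                               eval_cap=300_000)
        a = np.array([run_rmhc(toy_layout, toy_spec, "simple", rmhc_cfg, rng=s).evaluations
                      for s in range(300)])
        b = np.array([run_parallel_rmhc(toy_layout, toy_spec, "simple", par_cfg,
                                        rng=5000 + s).evaluations for s in range(300)])
        se = np.hypot(a.std(ddof=1) / np.sqrt(a.size), b.std(ddof=1) / np.sqrt(b.size))
        assert abs(a.mean() - b.mean()) < 4 * se

    def test_all_climbers_identical_after_synchronization(self, toy_spec, toy_layout):
        snaps = []
        cfg = EngineConfig(engine="parallel_rmhc", nmut=2, n_parallel=5,
                           eval_cap=500_000)
        out = run_parallel_rmhc(toy_layout, toy_spec, "simple", cfg, rng=3,
                                _capture_syncs=snaps)
        assert out.success and snaps
        for pop in snaps:
            assert (pop == pop[0]).all()

    def test_evaluations_summed_over_climbers(self, toy_spec, toy_layout):
        prob = EncodedProblem(toy_layout, toy_spec, "simple")
        calls = [0]

        def counting(g):
            calls[0] += 1
            return prob.fitness_total(g)

        cfg = EngineConfig(engine="parallel_rmhc", nmut=2, n_parallel=4,
                           eval_cap=300_000)
        out = run_parallel_rmhc(toy_layout, toy_spec, "simple", cfg, rng=8,
                                fitness_fn=counting)
        assert calls[0] == out.evaluations
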