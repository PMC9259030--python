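"""Wright-Fisher dynamics, host switching, treatment statistics, and the
replay-experiment binomial calculation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lambdaseascape.completion import CompleteLandscape
from lambdaseascape.fitness import FitnessLandscape
from lambdaseascape.genotypes import neighbor_matrix
from lambdaseascape.simulate import (
    SimulationConfig,
    TreatmentResult,
    compare_treatments,
    fitness_weights,
    replicate_null_probability,
    run_treatments,
    run_trial,
    summarize_treatments,
    treatment_schedule,
    wf_step,
)


def _cfg(**kw):
    base = dict(N=1000, generations=10, L=3, detection_threshold=10,
                trials=10, batch_size=5, mu_base=0.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestFitnessWeights:
    def test_exponential_of_selection_rate(self):
        w = fitness_weights(np.array([0.0, np.log(2), -1.0]))
        assert w[0] == 1.0
        assert w[1] == pytest.approx(2.0)
        assert np.all(np.diff(w[np.argsort([0.0, np.log(2), -1.0])]) > 0)


class TestWfStep:
    def test_population_size_conserved(self):
        rng = np.random.default_rng(0)
        nbrs = neighbor_matrix(3)
        counts = np.array([500, 300, 150, 50, 0, 0, 0, 0], dtype=np.int64)
        w = np.exp(np.random.default_rng(1).normal(0, 1, 8))
        for _ in range(50):
            counts = wf_step(counts, w, 0.01, rng, nbrs)
            assert counts.sum() == 1000

    def test_neutral_expectation(self):
        """mu=0, equal weights: E[k] = n (checked by averaging many steps)."""
        rng = np.random.default_rng(2)
        nbrs = neighbor_matrix(2)
        counts = np.array([400, 300, 200, 100], dtype=np.int64)
        draws = np.array(
            [wf_step(counts, np.ones(4), 0.0, rng, nbrs) for _ in range(4000)]
        )
        se = np.sqrt(counts * (1 - counts / 1000)) / np.sqrt(4000)
        assert np.all(np.abs(draws.mean(axis=0) - counts) < 5 * se)

    def test_strong_selection_fixes_quickly(self):
        rng = np.random.default_rng(3)
        nbrs = neighbor_matrix(2)
        counts = np.array([900, 100, 0, 0], dtype=np.int64)
        w = np.array([1.0, 50.0, 1.0, 1.0])
        for _ in range(10):
            counts = wf_step(counts, w, 0.0, rng, nbrs)
        assert counts[1] == 1000

    def test_monomorphic_population_cannot_mutate(self):
        """Increment-only rule: a monomorphic census is an absorbing state
        (k = n exactly, so z = 0 and mutation never fires)."""
        rng = np.random.default_rng(4)
        nbrs = neighbor_matrix(3)
        counts = np.zeros(8, dtype=np.int64)
        counts[0] = 1000
        for _ in range(100):
            counts = wf_step(counts, np.ones(8), 0.5, rng, nbrs)
        assert counts[0] == 1000

    def test_mutate_all_offspring_escapes_monomorphism(self):
        rng = np.random.default_rng(5)
        nbrs = neighbor_matrix(3)
        counts = np.zeros(8, dtype=np.int64)
        counts[0] = 1000
        for _ in range(20):
            counts = wf_step(counts, np.ones(8), 0.05, rng, nbrs,
                             mutate_all_offspring=True)
        assert counts[0] < 1000
        assert counts.sum() == 1000

    def test_mutants_go_to_neighbors_only(self):
        """With only genotype 0 growing, mutants appear only at Hamming
        distance 1 after one step."""
        rng = np.random.default_rng(6)
        nbrs = neighbor_matrix(3)
        counts = np.array([100, 900, 0, 0, 0, 0, 0, 0], dtype=np.int64)
        w = np.array([100.0, 1e-9, 1e-9, 1e-9, 1e-9, 1e-9, 1e-9, 1e-9])
        # genotype 0 sweeps: its increment is large and mutates at rate 0.3
        after = wf_step(counts, w, 0.3, rng, nbrs)
        non_neighbors = [3, 5, 6, 7]  # distance >= 2 from genotype 0
        assert after[non_neighbors].sum() == 0
        assert after[[1, 2, 4]].sum() > 0

    def test_monotone_selection(self):
        """Raising one genotype's s increases its expected next-generation
        count (empirical means over 2000 steps, all else fixed)."""
        nbrs = neighbor_matrix(1)
        counts = np.array([500, 500], dtype=np.int64)
        means = []
        for s in (0.0, 0.3):
            rng = np.random.default_rng(12)
            w = np.array([1.0, np.exp(s)])
            draws = [wf_step(counts, w, 0.0, rng, nbrs)[1] for _ in range(2000)]
            means.append(np.mean(draws))
        assert means[1] > means[0] + 5  # expected gap ~ 74 counts

    def test_nonpositive_weight_is_error(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            wf_step(np.array([5, 5]), np.array([1.0, 0.0]), 0.0, rng,
                    neighbor_matrix(1))


class TestExactMutationLaw:
    def test_mutation_counts_binomial_and_uniform_destinations(self):
        """Conditional on an increment z, the number of mutants is
        Binomial(z, 1-e^-mu) and destinations are uniform over the L
        neighbors — checked against exact laws at high replication."""
        rng = np.random.default_rng(8)
        nbrs = neighbor_matrix(2)
        # force deterministic reproduction: genotype 0 at N with w equal ->
        # use two genotypes so z > 0 can occur, with extreme selection making
        # genotype 0 take (nearly) everything.
        counts = np.array([500, 500, 0, 0], dtype=np.int64)
        w = np.array([1e9, 1e-9, 1.0, 1.0])
        pmut = 0.2
        n_rep = 20_000
        mutants = np.empty(n_rep)
        dest1 = np.empty(n_rep)
        for i in range(n_rep):
            after = wf_step(counts, w, pmut, rng, nbrs)
            mutants[i] = 1000 - after[0]
            dest1[i] = after[1]
        # z = 500 new individuals of genotype 0 each replicate
        expected_mean = 500 * pmut
        expected_sd = np.sqrt(500 * pmut * (1 - pmut))
        assert mutants.mean() == pytest.approx(expected_mean,
                                               abs=5 * expected_sd / np.sqrt(n_rep))
        # each mutant picks uniformly between neighbors 1 and 2
        assert dest1.sum() / mutants.sum() == pytest.approx(0.5, abs=0.01)


def _flat_complete(L, value=0.0, host="anc"):
    return CompleteLandscape(host=host, L=L, values=np.full(2**L, value),
                             imputed=np.zeros(2**L, dtype=bool))


class TestRunTrial:
    def test_lethal_nonwt_never_evolves_ompf(self, catalog):
        cfg = SimulationConfig(N=10_000, generations=30, L=10,
                               detection_threshold=10, trials=10, batch_size=5,
                               mu_base=1e-3, mutate_all_offspring=True)
        lethal = CompleteLandscape(
            host="anc", L=10,
            values=np.where(np.arange(1024) == 0, 0.0, -20.0),
            imputed=np.zeros(1024, dtype=bool),
        )
        rec = run_trial(lethal, lethal, 0.5, cfg, np.random.default_rng(0), catalog)
        assert not rec.ompf

    def test_seeded_ompf_detected_at_initialization(self, catalog):
        cfg = SimulationConfig(N=1000, generations=1, L=10, detection_threshold=1,
                               trials=10, batch_size=5, mu_base=0.0)
        init = np.zeros(1024, dtype=np.int64)
        ompf_genotype = catalog.required_mask | (1 << 1)
        init[0], init[ompf_genotype] = 999, 1
        rec = run_trial(
            _flat_complete(10), _flat_complete(10), 1.0, cfg,
            np.random.default_rng(1), catalog, initial_counts=init,
        )
        assert rec.ompf and rec.detection_generation == 0

    def test_latch_never_unsets(self, catalog):
        """Once detected, the flag stays even if the genotype later dies."""
        cfg = SimulationConfig(N=1000, generations=40, L=10, detection_threshold=1,
                               trials=10, batch_size=5, mu_base=0.0)
        init = np.zeros(1024, dtype=np.int64)
        ompf_genotype = catalog.required_mask | (1 << 1)
        init[0], init[ompf_genotype] = 990, 10
        # OmpF+ genotype strongly deleterious: it will be lost, flag stays
        values = np.zeros(1024)
        values[ompf_genotype] = -10.0
        land = CompleteLandscape(host="anc", L=10, values=values,
                                 imputed=np.zeros(1024, dtype=bool))
        rec = run_trial(land, land, 1.0, cfg, np.random.default_rng(2), catalog,
                        initial_counts=init)
        assert rec.ompf
        assert rec.final_counts[ompf_genotype] == 0


class TestTreatments:
    def test_schedule_has_eleven_treatments(self):
        cfg = _cfg()
        sched = treatment_schedule(cfg)
        assert len(sched) == 11
        assert sched[0] == ("ancestral_only", 1.0)
        assert sched[-1] == ("malt_only", 0.0)

    def test_all_positive_trials(self):
        r = TreatmentResult("t", 0.5, np.ones(30, dtype=bool), [1] * 30, 10)
        assert r.frequency == 1.0
        lo, hi = r.confidence_interval()
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_batching_and_t_interval(self):
        """300 trials in batches of 30: 10 batch frequencies, t with 9 df."""
        rng = np.random.default_rng(9)
        flags = rng.random(300) < 0.4
        r = TreatmentResult("t", 0.5, flags, [None] * 300, 30)
        b = r.batch_frequencies
        assert b.shape == (10,)
        lo, hi = r.confidence_interval()
        half = stats.t.ppf(0.975, 9) * b.std(ddof=1) / np.sqrt(10)
        assert hi - lo == pytest.approx(2 * half)
        assert (lo + hi) / 2 == pytest.approx(b.mean())

    def test_run_treatments_deterministic_under_master_seed(self, catalog):
        ls = FitnessLandscape(
            host="anc", L=10,
            records={g: np.array([0.0]) for g in range(0, 1024, 8)},
        )
        cfg = SimulationConfig(N=500, generations=3, L=10, detection_threshold=500,
                               trials=4, batch_size=2, mu_base=1e-3, seed=77)
        sched = [("ancestral_only", 1.0), ("switch_0.5", 0.5)]
        r1 = run_treatments(ls, ls, cfg, catalog, schedule=sched)
        r2 = run_treatments(ls, ls, cfg, catalog, schedule=sched)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.flags, b.flags)
        summary = summarize_treatments(r1)
        assert list(summary["treatment"]) == ["ancestral_only", "switch_0.5"]


class TestCompareTreatments:
    def _result(self, freqs, label):
        flags = np.concatenate([
            np.r_[np.ones(round(f * 10)), np.zeros(10 - round(f * 10))]
            for f in freqs
        ]).astype(bool)
        return TreatmentResult(label, 0.5, flags, [None] * flags.size, 10)

    def test_identical_batches_degenerate(self):
        r1 = self._result([0.5] * 10, "a")
        r2 = self._result([0.5] * 10, "b")
        anova, tukey = compare_treatments([r1, r2])
        assert anova["degenerate"]
        assert anova["F"] == 0.0
        assert tukey.empty

    def test_separated_treatments_significant(self):
        """Batch distributions 0.1 +- 0.1 vs 0.6 +- 0.1: Tukey flags the pair."""
        rng = np.random.default_rng(10)
        f_lo = np.clip(rng.normal(0.1, 0.02, 10), 0, 1)
        f_hi = np.clip(rng.normal(0.6, 0.02, 10), 0, 1)
        lo = self._result(f_lo, "low")
        hi = self._result(f_hi, "high")
        anova, tukey = compare_treatments([lo, hi])
        assert anova["p"] < 0.05
        assert (tukey["p_adj"] < 0.05).all()

    def test_null_calibration_by_permutation(self):
        """Splitting one homogeneous pool of batches into fake treatments
        gives uniform ANOVA p-values."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(200):
            pool = rng.normal(0.3, 0.05, 20)  # one homogeneous population
            f, p = stats.f_oneway(pool[:10], pool[10:])
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3

    def test_unequal_batch_counts_rejected(self):
        r1 = self._result([0.5] * 10, "a")
        r2 = TreatmentResult("b", 0.5, np.zeros(10, dtype=bool), [None] * 10, 5)
        with pytest.raises(ValueError):
            compare_treatments([r1, r2])


class TestReplicateNullProbability:
    def test_replay_power_value(self):
        """P(no OmpF+ in 12 replicates | p = 0.25) = 0.75^12 ~ 0.03167."""
        assert replicate_null_probability(0.25, 12, 0) == pytest.approx(
            0.75**12, rel=1e-12
        )
        # agreement with the printed value 0.03167 at its precision
        # (0.75**12 = 0.0316764..., truncated in print)
        assert abs(replicate_null_probability(0.25, 12, 0) - 0.03167) < 1e-5

    def test_degenerate_probabilities(self):
        assert replicate_null_probability(0.0, 12, 0) == 1.0
        assert replicate_null_probability(1.0, 12, 0) == 0.0

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            replicate_null_probability(1.5, 12, 0)
        with pytest.raises(ValueError):
            replicate_null_probability(0.5, 12, 13)


class TestConfigValidation:
    def test_trials_divisible_by_batch(self):
        with pytest.raises(ValueError):
            _cfg(trials=7, batch_size=5)

    def test_threshold_cannot_exceed_population(self):
        with pytest.raises(ValueError):
            _cfg(N=100, detection_threshold=200)

    def test_mutation_probability_from_per_base_rate(self):
        cfg = _cfg(mu_base=7.7e-8, L=10)
        assert cfg.mu == pytest.approx(7.7e-7)
        assert cfg.mutation_probability == pytest.approx(1 - np.exp(-7.7e-7))
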