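import itertools

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp

from pbtgsi.genotype_io import MISSING, AlleleFrequencies, GenotypeTable
from pbtgsi.gsi import (
    GSIConfig,
    baseline_posterior_freqs,
    genotype_loglik_matrix,
    gsi_gibbs,
    locus_genotype_loglik,
    rollup,
    self_assignment,
)
from pbtgsi.synthetic_data import (
    SimConfig,
    sample_genotypes,
    simulate_baseline_freqs,
)


def make_baseline(freqs, n_per_pop, seed):
    rng = np.random.default_rng(seed)
    return GenotypeTable.concat(
        [
            sample_genotypes(freqs.for_population(p), n_per_pop, rng,
                             loci=freqs.loci, group=p, id_prefix=f"{p}_REF")
            for p in freqs.populations
        ]
    )


class TestBaselinePosteriorFreqs:
    def test_count_formula(self):
        loci = ["L0001"]
        # 10 copies of allele B and 10 of A over 10 diploid fish
        geno = np.array([[1]] * 10, dtype=np.int8)
        t = GenotypeTable([f"i{k}" for k in range(10)], ["p"] * 10, loci, geno)
        f = baseline_posterior_freqs(t, prior=0.5)
        assert f.values[0, 0] == pytest.approx(10.5 / 21)

    def test_prior_mean_with_no_observations(self):
        loci = ["L0001"]
        geno = np.array([[MISSING]], dtype=np.int8)
        t = GenotypeTable(["i0"], ["p"], loci, geno)
        f = baseline_posterior_freqs(t, prior=0.5)
        assert f.values[0, 0] == pytest.approx(0.5)

    def test_monotone_in_counts(self):
        rng = np.random.default_rng(4)
        loci = ["L0001"]
        prev = -1.0
        for n_b in range(0, 21, 5):
            geno = np.array([[2]] * n_b + [[0]] * (20 - n_b), dtype=np.int8)
            t = GenotypeTable([f"i{k}" for k in range(20)], ["p"] * 20, loci, geno)
            f = baseline_posterior_freqs(t).values[0, 0]
            assert f > prev
            prev = f

    def test_empty_population_rejected(self, toy_registry):
        loci = ["L0001"]
        t = GenotypeTable(["i0"], ["popA"], loci, np.array([[1]], dtype=np.int8))
        with pytest.raises(ValueError, match="zero baseline"):
            baseline_posterior_freqs(t, registry=toy_registry)


class TestLocusLoglik:
    def test_het_at_half(self):
        assert locus_genotype_loglik(1, 0.5) == pytest.approx(np.log(0.5))

    def test_missing_is_zero(self):
        assert locus_genotype_loglik(MISSING, 0.3) == 0.0

    def test_classes_sum_to_one(self):
        total = sum(np.exp(locus_genotype_loglik(g, 0.37)) for g in (0, 1, 2))
        assert total == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# brute-force oracle: exact marginal posterior by enumerating all origin
# vectors under the Dirichlet-multinomial mixture
# ---------------------------------------------------------------------------


def brute_force_posterior(loglik, alpha):
    n, K = loglik.shape
    logw, zs = [], []
    for z in itertools.product(range(K), repeat=n):
        counts = np.bincount(z, minlength=K)
        lw = sum(loglik[i, zi] for i, zi in enumerate(z))
        lw += (
            gammaln(alpha.sum())
            - gammaln(alpha.sum() + n)
            + gammaln(alpha + counts).sum()
            - gammaln(alpha).sum()
        )
        logw.append(lw)
        zs.append(z)
    w = np.exp(np.array(logw) - logsumexp(logw))
    indiv = np.zeros((n, K))
    pi = np.zeros(K)
    for wi, z in zip(w, zs):
        for i, zi in enumerate(z):
            indiv[i, zi] += wi
        counts = np.bincount(z, minlength=K)
        pi += wi * (alpha + counts) / (alpha.sum() + n)
    return indiv, pi


class TestGibbs:
    def _two_pop_setup(self, seed=3):
        cfg = SimConfig(n_loci=302, n_cus=2, pops_per_cu=1,
                        fst_between_cu=0.1, fst_within_cu=0.005, seed=seed)
        freqs, reg = simulate_baseline_freqs(cfg)
        base = make_baseline(freqs, 50, seed + 1)
        return freqs, reg, baseline_posterior_freqs(base)

    def test_pure_sample_concentrates(self):
        freqs, _, post = self._two_pop_setup()
        a = freqs.populations[0]
        mix = sample_genotypes(freqs.for_population(a), 100, 7,
                               loci=freqs.loci, group="m", id_prefix="M")
        res = gsi_gibbs(mix, post, GSIConfig(burn_in=1000, keep=300, seed=1))
        assert res.pi_mean[res.populations.index(a)] > 0.95

    def test_seed_determinism(self):
        freqs, _, post = self._two_pop_setup()
        mix = sample_genotypes(freqs.for_population(freqs.populations[0]), 30, 8,
                               loci=freqs.loci, group="m", id_prefix="M")
        cfg = GSIConfig(burn_in=200, keep=100, seed=42)
        r1 = gsi_gibbs(mix, post, cfg)
        r2 = gsi_gibbs(mix, post, cfg)
        assert np.array_equal(r1.pi_trace, r2.pi_trace)
        assert np.array_equal(r1.z_trace, r2.z_trace)

    def test_rows_sum_to_one(self):
        freqs, _, post = self._two_pop_setup()
        mix = sample_genotypes(freqs.for_population(freqs.populations[1]), 40, 9,
                               loci=freqs.loci, group="m", id_prefix="M")
        res = gsi_gibbs(mix, post, GSIConfig(burn_in=100, keep=50, seed=2))
        assert np.allclose(res.indiv_posterior.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(res.pi_trace.sum(axis=1), 1.0, atol=1e-6)
        assert res.pi_mean.sum() == pytest.approx(1.0, abs=1e-6)

    def test_posterior_sd_shrinks_with_n(self):
        freqs, _, post = self._two_pop_setup()
        a = freqs.populations[0]
        sds = []
        for n, seed in ((50, 3), (800, 4)):
            rng = np.random.default_rng(seed)
            mix = GenotypeTable.concat([
                sample_genotypes(freqs.for_population(p), n // 2, rng,
                                 loci=freqs.loci, group="m", id_prefix=f"M{p}")
                for p in freqs.populations
            ])
            res = gsi_gibbs(mix, post, GSIConfig(burn_in=1000, keep=400, seed=seed))
            sds.append(res.pi_sd[res.populations.index(a)])
        assert sds[1] < sds[0]

    def test_small_instance_matches_brute_force(self):
        # 3 populations, 4 loci, 5 individuals: exact enumeration
        rng = np.random.default_rng(12)
        loci = [f"L{i + 1:04d}" for i in range(4)]
        freqs = AlleleFrequencies(
            ["a", "b", "c"], loci, rng.uniform(0.15, 0.85, size=(3, 4))
        )
        geno = rng.integers(0, 3, size=(5, 4)).astype(np.int8)
        mix = GenotypeTable([f"i{k}" for k in range(5)], ["m"] * 5, loci, geno)
        loglik = genotype_loglik_matrix(mix, freqs)
        alpha = np.full(3, 1.0 / 3.0)
        exact_indiv, exact_pi = brute_force_posterior(loglik, alpha)
        res = gsi_gibbs(mix, freqs, GSIConfig(burn_in=2000, keep=30_000, seed=5))
        tv_indiv = 0.5 * np.abs(res.indiv_posterior - exact_indiv).sum(axis=1)
        assert tv_indiv.max() < 0.02
        assert 0.5 * np.abs(res.pi_mean - exact_pi).sum() < 0.02

    def test_empty_mixture_rejected(self, toy_freqs, small_panel):
        t = GenotypeTable([], [], list(small_panel.locus_ids),
                          np.zeros((0, small_panel.n_loci), dtype=np.int8))
        with pytest.raises(ValueError):
            gsi_gibbs(t, toy_freqs)

    def test_single_population_baseline_rejected(self, small_panel):
        f = AlleleFrequencies(["only"], list(small_panel.locus_ids),
                              np.full((1, small_panel.n_loci), 0.5))
        t = GenotypeTable(["x"], ["m"], list(small_panel.locus_ids),
                          np.zeros((1, small_panel.n_loci), dtype=np.int8))
        with pytest.raises(ValueError, match="two populations"):
            gsi_gibbs(t, f)


class TestRollup:
    def test_single_group_is_one(self):
        freqs, reg, post = TestGibbs()._two_pop_setup()
        mix = sample_genotypes(freqs.for_population(freqs.populations[0]), 30, 5,
                               loci=freqs.loci, group="m", id_prefix="M")
        res = gsi_gibbs(mix, post, GSIConfig(burn_in=200, keep=100, seed=3))
        out = rollup(res, reg, level="country")
        assert len(out) == 1
        assert out["mean"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_group_sums_preserve_total(self):
        cfg = SimConfig(n_loci=100, n_cus=3, pops_per_cu=2, seed=6)
        freqs, reg = simulate_baseline_freqs(cfg)
        base = make_baseline(freqs, 30, 7)
        post = baseline_posterior_freqs(base)
        rng = np.random.default_rng(8)
        mix = GenotypeTable.concat([
            sample_genotypes(freqs.for_population(p), 10, rng, loci=freqs.loci,
                             group="m", id_prefix=f"M{p}")
            for p in freqs.populations
        ])
        res = gsi_gibbs(mix, post, GSIConfig(burn_in=300, keep=100, seed=9))
        out = rollup(res, reg, level="cu")
        assert out["mean"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_two_group_recovery_within_2sd(self):
        freqs, reg, post = TestGibbs()._two_pop_setup(seed=10)
        rng = np.random.default_rng(11)
        mix = GenotypeTable.concat([
            sample_genotypes(freqs.for_population(freqs.populations[0]), 70, rng,
                             loci=freqs.loci, group="m", id_prefix="MA"),
            sample_genotypes(freqs.for_population(freqs.populations[1]), 30, rng,
                             loci=freqs.loci, group="m", id_prefix="MB"),
        ])
        res = gsi_gibbs(mix, post, GSIConfig(burn_in=1500, keep=400, seed=12))
        out = rollup(res, reg, level="cu")
        for truth, (_, row) in zip((0.7, 0.3), out.iterrows()):
            assert abs(row["mean"] - truth) <= 2 * max(row["sd"], 1e-3) + 0.02


class TestSelfAssignment:
    def test_identical_populations_chance_level(self):
        loci = [f"L{i + 1:04d}" for i in range(20)]
        freqs = np.full(20, 0.5)
        rng = np.random.default_rng(13)
        tables = [
            sample_genotypes(freqs, 40, rng, loci=loci, group=f"p{k}",
                             id_prefix=f"p{k}")
            for k in range(4)
        ]
        base = GenotypeTable.concat(tables)
        _, weighted = self_assignment(base, thresholds=(0.0,))
        assert abs(weighted[0.0] - 0.25) < 0.12

    def test_diagnostic_loci_perfect(self):
        loci = ["L0001"]
        a = GenotypeTable([f"a{k}" for k in range(20)], ["pa"] * 20, loci,
                          np.zeros((20, 1), dtype=np.int8))
        b = GenotypeTable([f"b{k}" for k in range(20)], ["pb"] * 20, loci,
                          np.full((20, 1), 2, dtype=np.int8))
        base = GenotypeTable.concat([a, b])
        _, weighted = self_assignment(base, thresholds=(0.5,))
        assert weighted[0.5] == 1.0

    def test_default_baseline_calibration_band(self):
        # synthetic defaults should land in a realistic accuracy band
        cfg = SimConfig(seed=3)  # 302 loci, 20 populations
        freqs, _ = simulate_baseline_freqs(cfg)
        base = make_baseline(freqs, 30, 14)
        _, weighted = self_assignment(base, thresholds=(0.5,))
        assert 0.80 <= weighted[0.5] <= 0.95
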