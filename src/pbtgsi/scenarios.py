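"""Canned simulation studies used by the evaluation suite and reports.

Each trial builds its own synthetic world from a seed, runs the
pipeline stages under test, and returns plain-dict metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .combine import combined_composition, composition_error, route
from .fishery_estimation import cwt_expand
from .genotype_io import AlleleFrequencies, GenotypeTable
from .gsi import GSIConfig, baseline_posterior_freqs, gsi_gibbs
from .parentage import ParentPool, ParentageConfig, assign_parentage, pbt_summary
from .synthetic_data import (
    SimConfig,
    corrupt,
    sample_genotypes,
    simulate_baseline_freqs,
    simulate_broodstock,
    simulate_cwt_program,
    simulate_mixture,
)


def _decoy_pool(freqs: AlleleFrequencies, n_decoys: int, brood_year: int, rng) -> ParentPool:
    """Unrelated adults spread round-robin over the baseline populations."""
    pops = freqs.populations
    per_pop = np.bincount(np.arange(n_decoys) % len(pops), minlength=len(pops))
    tables, sexes, years = [], [], []
    for k, pop in enumerate(pops):
        if per_pop[k] == 0:
            continue
        t = sample_genotypes(
            freqs.for_population(pop),
            int(per_pop[k]),
            rng,
            loci=freqs.loci,
            group=pop,
            id_prefix=f"DECOY_{pop}",
        )
        tables.append(t)
        sexes.append(np.where(np.arange(per_pop[k]) % 2 == 0, "F", "M").astype(object))
        years.append(np.full(per_pop[k], brood_year, dtype=np.int64))
    return ParentPool(
        GenotypeTable.concat(tables),
        np.concatenate(sexes),
        np.concatenate(years),
    )


def pbt_accuracy_trial(
    seed: int,
    n_pops: int = 8,
    pairs_per_pop: int = 50,
    n_offspring: int = 600,
    n_decoys: int = 1000,
    n_loci: int = 302,
    error_rate: float = 0.01,
    missing_rate: float = 0.02,
    fst_between_cu: float = 0.08,
    fst_within_cu: float = 0.03,
    accept_prob: float = 0.85,
) -> dict:
    """Known-origin parentage accuracy with complete broodstock sampling.

    Offspring of fully genotyped broodstock pairs are assigned against
    the pooled true parents plus unrelated decoy adults; accuracy counts
    acceptances matching the true population and brood year.
    """
    cfg = SimConfig(
        n_loci=n_loci,
        n_cus=4,
        pops_per_cu=max(1, n_pops // 4),
        fst_between_cu=fst_between_cu,
        fst_within_cu=fst_within_cu,
        genotype_error_rate=error_rate,
        missing_rate=missing_rate,
        seed=seed,
    )
    freqs, _ = simulate_baseline_freqs(cfg)
    pops = freqs.populations[:n_pops]
    rng = np.random.default_rng(seed + 10_000)
    pools = {
        p: simulate_broodstock(
            p, pairs_per_pop, pairs_per_pop, freqs.for_population(p), rng,
            brood_year=2014, loci=freqs.loci,
        )
        for p in pops
    }
    composition = {p: 1.0 / n_pops for p in pops}
    mixture, truth = simulate_mixture(composition, pools, freqs, n_offspring, rng)
    mixture = corrupt(mixture, error_rate, missing_rate, rng)

    pool = ParentPool.concat(
        list(pools.values()) + [_decoy_pool(freqs, n_decoys, 2014, rng)]
    )
    results = assign_parentage(
        mixture, pool, freqs, ParentageConfig(error_rate=error_rate, accept_prob=accept_prob)
    )
    summary = pbt_summary(results, truth)
    return {
        "n_offspring": n_offspring,
        "n_parents": pool.n_parents,
        "n_accepted": summary["n_accepted"],
        "assignment_rate": summary["assignment_rate"],
        "accuracy": summary["accuracy"],
    }


def composition_error_trial(
    seed: int,
    n_pops: int = 20,
    n_present: int = 8,
    n_mixture: int = 600,
    n_baseline_per_pop: int = 50,
    pairs_per_pop: int = 30,
    burn_in: int = 2_500,
    keep: int = 500,
) -> dict:
    """GSI-only versus combined PBT-GSI composition error.

    A mixture drawn from ``n_present`` of ``n_pops`` populations (all
    with complete genotyped broodstocks) is estimated both ways; errors
    are mean absolute deviations from the realised composition.
    """
    cfg = SimConfig(n_cus=4, pops_per_cu=n_pops // 4, seed=seed)
    freqs, registry = simulate_baseline_freqs(cfg)
    pops = freqs.populations
    rng = np.random.default_rng(seed + 20_000)

    baseline = GenotypeTable.concat(
        [
            sample_genotypes(
                freqs.for_population(p), n_baseline_per_pop, rng,
                loci=freqs.loci, group=p, id_prefix=f"{p}_REF",
            )
            for p in pops
        ]
    )
    post_freqs = baseline_posterior_freqs(baseline)

    pools = {
        p: simulate_broodstock(
            p, pairs_per_pop, pairs_per_pop, freqs.for_population(p), rng,
            brood_year=2014, loci=freqs.loci,
        )
        for p in pops
    }
    present = pops[:n_present]
    raw = rng.dirichlet(np.full(n_present, 4.0))
    composition = dict(zip(present, raw / raw.sum()))
    mixture, truth = simulate_mixture(composition, pools, freqs, n_mixture, rng)
    mixture = corrupt(mixture, cfg.genotype_error_rate, cfg.missing_rate, rng)
    realized = truth.table["population"].value_counts() / n_mixture
    truth_comp = {p: float(realized.get(p, 0.0)) for p in pops}

    gcfg = GSIConfig(burn_in=burn_in, keep=keep, seed=seed + 30_000)
    gsi_only = gsi_gibbs(mixture, post_freqs, gcfg)
    gsi_only_comp = dict(zip(gsi_only.populations, gsi_only.pi_mean))

    pool = ParentPool.concat(list(pools.values()))
    pcfg = ParentageConfig()
    presults = assign_parentage(mixture, pool, post_freqs, pcfg)
    records = route(presults, gsi_only, registry, pcfg)
    combined = combined_composition(records, gsi_only)
    combined_comp = dict(zip(combined.populations, combined.pi_mean))

    return {
        "n_mixture": n_mixture,
        "n_pbt": sum(r.method == "PBT" for r in records),
        "gsi_only_mae": composition_error(gsi_only_comp, truth_comp, pops)["mean_abs_error"],
        "combined_mae": composition_error(combined_comp, truth_comp, pops)["mean_abs_error"],
    }


def gsi_recovery_trial(
    seed: int,
    n_mixture: int = 1_000,
    fst: float = 0.1,
    n_loci: int = 302,
    burn_in: int = 2_500,
    keep: int = 500,
) -> dict:
    """50/50 two-population mixture parameter recovery."""
    cfg = SimConfig(
        n_loci=n_loci, n_cus=2, pops_per_cu=1,
        fst_between_cu=fst, fst_within_cu=0.005, seed=seed,
    )
    freqs, _ = simulate_baseline_freqs(cfg)
    rng = np.random.default_rng(seed + 40_000)
    a, b = freqs.populations
    baseline = GenotypeTable.concat(
        [
            sample_genotypes(freqs.for_population(p), 100, rng, loci=freqs.loci,
                             group=p, id_prefix=f"{p}_REF")
            for p in (a, b)
        ]
    )
    post_freqs = baseline_posterior_freqs(baseline)
    half = n_mixture // 2
    mixture = GenotypeTable.concat(
        [
            sample_genotypes(freqs.for_population(a), half, rng, loci=freqs.loci,
                             group="mix", id_prefix="MA"),
            sample_genotypes(freqs.for_population(b), n_mixture - half, rng,
                             loci=freqs.loci, group="mix", id_prefix="MB"),
        ]
    )
    res = gsi_gibbs(mixture, post_freqs, GSIConfig(burn_in=burn_in, keep=keep, seed=seed))
    return {
        "populations": res.populations,
        "pi_mean": res.pi_mean,
        "pi_sd": res.pi_sd,
        "truth": np.array([half / n_mixture, (n_mixture - half) / n_mixture]),
    }


def cwt_unbiasedness_trial(
    seed: int,
    true_catch: int = 2_000,
    mark_rate: float = 0.5,
    tag_loss_rate: float = 0.1,
    sampling_rate: float = 0.4,
    n_reps: int = 1_000,
) -> dict:
    """Expansion of simulated tag counts should recover the true catch."""
    rng = np.random.default_rng(seed)
    estimates = np.array(
        [
            cwt_expand(
                simulate_cwt_program(true_catch, mark_rate, tag_loss_rate, sampling_rate, rng),
                tag_loss_rate, mark_rate, sampling_rate,
            )
            for _ in range(n_reps)
        ]
    )
    p = mark_rate * (1 - tag_loss_rate) * sampling_rate
    mc_sd = np.sqrt(true_catch * p * (1 - p)) / p / np.sqrt(n_reps)
    return {
        "true_catch": true_catch,
        "mean_estimate": float(estimates.mean()),
        "mc_sd_of_mean": float(mc_sd),
        "n_reps": n_reps,
    }
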