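"""Bayesian conditional mixture model for genetic stock identification.

Baseline allele frequencies are fixed at their Dirichlet posterior
means; a Gibbs sampler then alternates between sampling each mixture
individual's population of origin and the mixture proportion vector.
Individuals are always assigned to populations; conservation-unit or
regional numbers arise only by summing population allocations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .genotype_io import MISSING, AlleleFrequencies, BaselineRegistry, GenotypeTable

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class GSIConfig:
    burn_in: int = 25_000
    keep: int = 1_000
    freq_prior: float = 0.5
    proportion_prior: float | None = None  # per-population; default 1/K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.keep < 1:
            raise ValueError("burn_in must be >= 0 and keep >= 1")
        if self.freq_prior <= 0:
            raise ValueError("freq_prior must be positive")


@dataclass
class GSIResult:
    populations: list[str]
    individual_ids: np.ndarray
    indiv_posterior: np.ndarray  # (n, K), rows sum to 1
    pi_mean: np.ndarray  # (K,)
    pi_sd: np.ndarray  # (K,)
    pi_trace: np.ndarray  # (keep, K)
    z_trace: np.ndarray  # (keep, n) sampled origin indices

    def posterior_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.indiv_posterior, columns=self.populations)
        df.insert(0, "indiv", self.individual_ids)
        return df

    def composition_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit": self.populations, "mean": self.pi_mean, "sd": self.pi_sd}
        )


def baseline_posterior_freqs(
    baseline: GenotypeTable,
    registry: BaselineRegistry | None = None,
    prior: float = 0.5,
) -> AlleleFrequencies:
    """Posterior-mean allele frequencies per population and locus.

    For each population and locus the frequency of the second allele is
    ``(count + prior) / (2 * n_called + 2 * prior)``.
    """
    pops = sorted(set(baseline.groups))
    if registry is not None:
        empty = [p for p in registry.populations if p not in pops]
        if empty:
            raise ValueError(f"registry populations with zero baseline individuals: {empty}")
    values = np.empty((len(pops), baseline.n_loci))
    for k, pop in enumerate(pops):
        g = baseline.geno[baseline.groups == pop]
        if g.shape[0] == 0:
            raise ValueError(f"population {pop!r} has zero individuals")
        called = g != MISSING
        count = np.where(called, g, 0).sum(axis=0)
        n_called = called.sum(axis=0)
        values[k] = (count + prior) / (2.0 * n_called + 2.0 * prior)
    return AlleleFrequencies(pops, list(baseline.loci), values)


def locus_genotype_loglik(genotype: int, freq: float) -> float:
    """Log HWE probability of a genotype class; missing contributes 0."""
    if genotype == MISSING:
        return 0.0
    probs = [(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2]
    return float(np.log(max(probs[genotype], _LOG_FLOOR)))


def genotype_loglik_matrix(
    mixture: GenotypeTable, freqs: AlleleFrequencies
) -> np.ndarray:
    """(n, K) matrix of log P(genotype | population)."""
    freqs = freqs.select_loci(mixture.loci)
    p = freqs.values  # (K, L)
    K, L = p.shape
    # class log-probs per population/locus, class 3 (missing) -> 0
    logH = np.zeros((K, L, 4))
    logH[:, :, 0] = np.log(np.maximum((1 - p) ** 2, _LOG_FLOOR))
    logH[:, :, 1] = np.log(np.maximum(2 * p * (1 - p), _LOG_FLOOR))
    logH[:, :, 2] = np.log(np.maximum(p**2, _LOG_FLOOR))
    flat = logH.reshape(K, L * 4)
    g = mixture.geno.astype(np.int64)
    g[g == MISSING] = 3
    idx = np.arange(L) * 4 + g  # (n, L)
    out = np.empty((mixture.n_individuals, K))
    for k in range(K):
        out[:, k] = flat[k][idx].sum(axis=1)
    return out


def gsi_gibbs(
    mixture: GenotypeTable,
    freqs: AlleleFrequencies,
    config: GSIConfig = GSIConfig(),
) -> GSIResult:
    """Run the conditional mixture Gibbs sampler.

    Per-individual posteriors are Rao-Blackwellised means of the
    conditional origin probabilities over the retained iterations;
    mixture proportion means and SDs are taken over the retained
    Dirichlet draws.
    """
    if mixture.n_individuals < 1:
        raise ValueError("mixture must contain at least one individual")
    if len(freqs.populations) < 2:
        raise ValueError("baseline must cover at least two populations")
    n = mixture.n_individuals
    K = len(freqs.populations)
    loglik = genotype_loglik_matrix(mixture, freqs)
    if not np.all(np.isfinite(loglik)):
        raise ValueError("non-finite genotype log-likelihoods")
    alpha = config.proportion_prior if config.proportion_prior is not None else 1.0 / K
    alpha_vec = np.full(K, alpha)
    rng = np.random.default_rng(config.seed)

    pi = np.full(K, 1.0 / K)
    keep = config.keep
    pi_trace = np.empty((keep, K))
    z_trace = np.empty((keep, n), dtype=np.int32)
    post_accum = np.zeros((n, K))

    for it in range(config.burn_in + keep):
        W = loglik + np.log(pi)[None, :]
        W -= W.max(axis=1, keepdims=True)
        W = np.exp(W)
        W /= W.sum(axis=1, keepdims=True)
        u = rng.random(n)
        z = (W.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.int32)
        np.clip(z, 0, K - 1, out=z)
        counts = np.bincount(z, minlength=K)
        pi = rng.dirichlet(alpha_vec + counts)
        t = it - config.burn_in
        if t >= 0:
            pi_trace[t] = pi
            z_trace[t] = z
            post_accum += W

    indiv_posterior = post_accum / keep
    return GSIResult(
        populations=list(freqs.populations),
        individual_ids=mixture.ids.copy(),
        indiv_posterior=indiv_posterior,
        pi_mean=pi_trace.mean(axis=0),
        pi_sd=pi_trace.std(axis=0, ddof=1),
        pi_trace=pi_trace,
        z_trace=z_trace,
    )


def rollup(
    result,
    registry: BaselineRegistry,
    level: str = "cu",
) -> pd.DataFrame:
    """Sum population allocations into CU/region composition with SDs.

    ``result`` may be a :class:`GSIResult` or any object exposing
    ``populations``, ``pi_mean`` and ``pi_trace``. SDs are computed from
    the per-iteration group sums.
    """
    M, units = registry.membership(list(result.populations), level)
    trace = result.pi_trace @ M
    return pd.DataFrame(
        {
            "unit": units,
            "mean": result.pi_mean @ M,
            "sd": trace.std(axis=0, ddof=1),
            "level": level,
        }
    )


def self_assignment(
    baseline: GenotypeTable,
    registry: BaselineRegistry | None = None,
    thresholds: tuple[float, ...] = (0.5, 0.85),
    prior: float = 0.5,
):
    """Leave-one-out self-assignment accuracy at probability cutoffs.

    Each baseline individual is scored against every population with its
    own genotype removed from its population's allele counts; it is
    assigned to the maximum-probability population (flat prior over
    populations). Returns ``(per_population_frame, weighted_accuracy)``
    where the latter maps cutoff -> accuracy among non-excluded fish,
    weighted by population sample size.
    """
    pops = sorted(set(baseline.groups))
    K = len(pops)
    L = baseline.n_loci
    g_all = baseline.geno
    called_all = g_all != MISSING
    count = np.zeros((K, L))
    ncall = np.zeros((K, L))
    for k, pop in enumerate(pops):
        sel = baseline.groups == pop
        gk = g_all[sel]
        ck = called_all[sel]
        count[k] = np.where(ck, gk, 0).sum(axis=0)
        ncall[k] = ck.sum(axis=0)
    pooled = (count + prior) / (2.0 * ncall + 2.0 * prior)

    def loglik_vec(g, freq_matrix):
        # g: (L,), freq_matrix: (K, L) -> (K,)
        out = np.zeros(freq_matrix.shape[0])
        called = g != MISSING
        p = freq_matrix[:, called]
        gc = g[called]
        probs = np.where(
            gc == 0, (1 - p) ** 2, np.where(gc == 1, 2 * p * (1 - p), p**2)
        )
        return np.log(np.maximum(probs, _LOG_FLOOR)).sum(axis=1)

    pop_index = {p: k for k, p in enumerate(pops)}
    n = baseline.n_individuals
    best_pop = np.empty(n, dtype=np.int64)
    best_prob = np.empty(n)
    truth_idx = np.array([pop_index[p] for p in baseline.groups])
    for i in range(n):
        k = truth_idx[i]
        g = g_all[i]
        called = called_all[i]
        fm = pooled.copy()
        adj_count = count[k] - np.where(called, g, 0)
        adj_ncall = ncall[k] - called
        fm[k] = (adj_count + prior) / (2.0 * adj_ncall + 2.0 * prior)
        ll = loglik_vec(g, fm)
        post = np.exp(ll - logsumexp(ll))
        best_pop[i] = int(np.argmax(post))
        best_prob[i] = float(post[best_pop[i]])

    correct = best_pop == truth_idx
    rows = []
    for k, pop in enumerate(pops):
        sel = truth_idx == k
        rec = {"population": pop, "n": int(sel.sum())}
        for thr in thresholds:
            keep = sel & (best_prob >= thr)
            rec[f"accuracy_at_{thr}"] = (
                float(correct[keep].mean()) if keep.any() else np.nan
            )
        rows.append(rec)
    per_pop = pd.DataFrame(rows)
    weighted = {}
    for thr in thresholds:
        keep = best_prob >= thr
        weighted[thr] = float(correct[keep].mean()) if keep.any() else np.nan
    return per_pop, weighted
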