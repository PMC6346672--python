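"""Pairwise-likelihood parentage assignment against pooled broodstocks.

Candidate parents are screened one at a time with a single-parent
log-likelihood ratio against an unrelated-background hypothesis; the
top candidates are then combined into within-population, within-brood-
year parent pairs. The best hypothesis's posterior probability over the
enumerated set {shortlisted pairs, shortlisted singles, unrelated}
gates acceptance. Parental observed genotypes are treated as true;
the genotyping error rate applies to the offspring observation only.

Genotype classes are dosages 0/1/2 of the second allele code; missing
is class index 3 everywhere below and contributes a factor of 1 (log 0)
to every hypothesis, so comparisons are over shared called loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .genotype_io import MISSING, AlleleFrequencies, GenotypeTable

_TIE_TOL = 1e-9
_LOG_FLOOR = 1e-300


@dataclass
class ParentPool:
    """Broodstock genotypes with population, brood-year and sex labels."""

    table: GenotypeTable
    sex: np.ndarray = None  # type: ignore[assignment]
    brood_year: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.table.n_individuals
        if self.sex is None:
            if self.table.meta is None or "sex" not in self.table.meta:
                raise ValueError("pool needs sex labels (array or meta column)")
            self.sex = self.table.meta["sex"].to_numpy(dtype=object)
        if self.brood_year is None:
            if self.table.meta is None or "brood_year" not in self.table.meta:
                raise ValueError("pool needs brood_year labels")
            self.brood_year = self.table.meta["brood_year"].to_numpy(dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=object)
        self.brood_year = np.asarray(self.brood_year, dtype=np.int64)
        if len(self.sex) != n or len(self.brood_year) != n:
            raise ValueError("sex/brood_year must align with the genotype table")
        bad = ~np.isin(self.sex.astype(str), ["F", "M", "U"])
        if bad.any():
            raise ValueError("sex labels must be 'F', 'M' or 'U'")

    @property
    def population(self) -> np.ndarray:
        return self.table.groups

    @property
    def n_parents(self) -> int:
        return self.table.n_individuals

    @staticmethod
    def concat(pools: list["ParentPool"]) -> "ParentPool":
        return ParentPool(
            GenotypeTable.concat([p.table for p in pools]),
            np.concatenate([p.sex for p in pools]),
            np.concatenate([p.brood_year for p in pools]),
        )

    def restrict_brood_years(self, years) -> "ParentPool":
        keep = np.isin(self.brood_year, np.asarray(list(years)))
        idx = np.flatnonzero(keep)
        return ParentPool(self.table.take(idx), self.sex[idx], self.brood_year[idx])


@dataclass(frozen=True)
class ParentageConfig:
    error_rate: float = 0.01
    accept_prob: float = 0.85
    max_candidate_singles: int = 10
    allow_single_parent: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if not 0.0 < self.accept_prob <= 1.0:
            raise ValueError("accept_prob must lie in (0, 1]")
        if self.max_candidate_singles < 1:
            raise ValueError("max_candidate_singles must be >= 1")


@dataclass
class ParentageResult:
    offspring_id: str
    mode: str  # 'pair' | 'single' | 'none'
    parent1: str | None = None
    parent2: str | None = None
    assigned_population: str | None = None
    assigned_brood_year: int | None = None
    posterior_prob: float = 0.0
    n_loci_compared: int = 0
    parent_populations: tuple[str, str] | None = None  # pair mode only


# ---------------------------------------------------------------------------
# Locus-level likelihood primitives
# ---------------------------------------------------------------------------

def obs_given_true(observed: int, true: int, error_rate: float) -> float:
    """P(observed class | true class) under the class-swap error model.

    Missing observations contribute probability 1 (the locus is skipped).
    """
    if observed == MISSING:
        return 1.0
    return 1.0 - error_rate if observed == true else error_rate / 2.0


def _mendel_dist(gm: int, gf: int) -> np.ndarray:
    tm, tf = gm / 2.0, gf / 2.0
    return np.array(
        [(1 - tm) * (1 - tf), tm * (1 - tf) + (1 - tm) * tf, tm * tf]
    )


def _hwe_dist(p: float) -> np.ndarray:
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


def _single_dist(gp: int, p: float) -> np.ndarray:
    tp = gp / 2.0
    return np.array([(1 - tp) * (1 - p), tp * (1 - p) + (1 - tp) * p, tp * p])


def _obs_lik(dist: np.ndarray, observed: int, error_rate: float) -> float:
    if observed == MISSING:
        return 1.0
    return float(
        sum(dist[t] * obs_given_true(observed, t, error_rate) for t in range(3))
    )


def pair_locus_likelihood(
    offspring: int, mother: int, father: int, error_rate: float
) -> float:
    """P(offspring obs | parents' genotypes) at one locus."""
    return _obs_lik(_mendel_dist(mother, father), offspring, error_rate)


def unrelated_locus_likelihood(offspring: int, freq: float, error_rate: float) -> float:
    """P(offspring obs | random HWE member of a population)."""
    return _obs_lik(_hwe_dist(freq), offspring, error_rate)


def single_parent_locus_likelihood(
    offspring: int, parent: int, freq: float, error_rate: float
) -> float:
    """P(offspring obs | one known parent, other drawn from the population)."""
    return _obs_lik(_single_dist(parent, freq), offspring, error_rate)


# ---------------------------------------------------------------------------
# Vectorised hypothesis tables
# ---------------------------------------------------------------------------

def _obs_matrix(error_rate: float) -> np.ndarray:
    """O[true, obs] for obs in {0,1,2,missing}."""
    O = np.full((3, 4), error_rate / 2.0)
    O[:, 3] = 1.0
    for t in range(3):
        O[t, t] = 1.0 - error_rate
    return O


class _LikelihoodTables:
    """Per-population log-likelihood-ratio lookup tables.

    The common denominator for every hypothesis is the unrelated
    hypothesis under the baseline-average allele frequencies, so ratios
    of different hypotheses are directly comparable.
    """

    def __init__(self, freqs: AlleleFrequencies, populations: list[str], error_rate: float):
        self.populations = list(populations)
        self.pop_index = {p: i for i, p in enumerate(self.populations)}
        L = len(freqs.loci)
        self.n_loci = L
        O = _obs_matrix(error_rate)

        bg = freqs.values.mean(axis=0)  # (L,)
        hwe_bg = np.stack([(1 - bg) ** 2, 2 * bg * (1 - bg), bg**2], axis=1)  # (L,3)
        self.log_unrel_bg = np.log(
            np.maximum(hwe_bg @ O, _LOG_FLOOR)
        )  # (L,4); col 3 is log 1 = 0
        self.log_unrel_bg[:, 3] = 0.0

        tau = np.array([0.0, 0.5, 1.0])
        self.single = np.empty((len(self.populations), L * 16))
        self.pair = np.empty((len(self.populations), L * 64))
        for k, pop in enumerate(self.populations):
            p = freqs.values[freqs.pop_index(pop)]  # (L,)
            hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)
            log_unrel = np.log(np.maximum(hwe @ O, _LOG_FLOOR))
            log_unrel[:, 3] = 0.0

            log_unrel_ratio = log_unrel - self.log_unrel_bg  # (L,4)
            log_unrel_ratio[:, 3] = 0.0

            # single-parent ratio S[l, gp, obs]: gp=3 means the parent is
            # uncalled at the locus, falling back to the population HWE term.
            d = np.empty((L, 3, 3))
            for gp in range(3):
                tp = tau[gp]
                d[:, gp, 0] = (1 - tp) * (1 - p)
                d[:, gp, 1] = tp * (1 - p) + (1 - tp) * p
                d[:, gp, 2] = tp * p
            single = np.log(np.maximum(np.einsum("lgt,to->lgo", d, O), _LOG_FLOOR))
            S = np.zeros((L, 4, 4))
            S[:, :3, :] = single - self.log_unrel_bg[:, None, :]
            S[:, 3, :] = log_unrel_ratio
            S[:, :, 3] = 0.0  # offspring missing -> skip locus
            self.single[k] = S.reshape(-1)

            # parent-pair ratio P[l, gm, gf, obs]; an uncalled parent (class 3)
            # degrades the locus to the single-parent term, both uncalled to
            # the population HWE term.
            md = np.empty((3, 3, 3))
            for gm in range(3):
                for gf in range(3):
                    md[gm, gf] = _mendel_dist(gm, gf)
            pair = np.log(np.maximum(np.einsum("mft,to->mfo", md, O), _LOG_FLOOR))
            PT = np.zeros((L, 4, 4, 4))
            PT[:, :3, :3, :] = pair[None, :, :, :] - self.log_unrel_bg[:, None, None, :]
            PT[:, 3, :, :] = S
            PT[:, :, 3, :] = S
            PT[:, 3, 3, :] = log_unrel_ratio
            PT[:, :, :, 3] = 0.0
            self.pair[k] = PT.reshape(-1)


def _classes(geno: np.ndarray) -> np.ndarray:
    """Map MISSING (-1) to class index 3."""
    g = geno.astype(np.int64)
    g[g == MISSING] = 3
    return g


def assign_parentage(
    offspring: GenotypeTable,
    pool: ParentPool,
    freqs: AlleleFrequencies,
    config: ParentageConfig = ParentageConfig(),
) -> list[ParentageResult]:
    """Assign each offspring to a parent pair, single parent, or nobody.

    ``freqs`` must cover every population present in the pool and share
    the offspring/pool locus list. Ties for the best hypothesis are
    broken by rejection.
    """
    results: list[ParentageResult] = []
    if pool.n_parents == 0:
        return [
            ParentageResult(i, "none", n_loci_compared=int(c))
            for i, c in zip(offspring.ids, (offspring.geno != MISSING).sum(axis=1))
        ]
    if offspring.loci != pool.table.loci:
        raise ValueError("offspring and pool must share an identical locus list")
    pool_pops = sorted(set(pool.population))
    missing_pops = [p for p in pool_pops if p not in freqs.populations]
    if missing_pops:
        raise KeyError(f"pool populations without baseline frequencies: {missing_pops}")
    freqs = freqs.select_loci(offspring.loci)

    tables = _LikelihoodTables(freqs, pool_pops, config.error_rate)
    L = tables.n_loci
    GP = _classes(pool.table.geno)  # (P, L)
    pop_of_parent = np.array([tables.pop_index[p] for p in pool.population])
    locus_base = np.arange(L, dtype=np.int64) * 16
    # flat index into the concatenated single-parent tables for each
    # (parent, locus); adding the offspring class completes the lookup
    single_flat = tables.single.reshape(-1)  # (K * L * 16,)
    single_base = (
        pop_of_parent[:, None] * (L * 16) + locus_base[None, :] + GP * 4
    )  # (P, L)

    K_top = min(config.max_candidate_singles, pool.n_parents)

    for oi in range(offspring.n_individuals):
        go = _classes(offspring.geno[oi])  # (L,)
        n_called = int((go != 3).sum())
        if n_called == 0:
            results.append(ParentageResult(offspring.ids[oi], "none"))
            continue
        # single-parent log-LR for every parent in the pool
        llr_single_all = single_flat[single_base + go[None, :]].sum(axis=1)
        top = np.argpartition(llr_single_all, -K_top)[-K_top:]
        top = top[np.argsort(llr_single_all[top])[::-1]]
        llr_singles = llr_single_all[top]

        # enumerate valid pairs among the shortlist
        pair_hyps: list[tuple[int, int, float]] = []
        go_pair_off = go  # (L,)
        for a, b in combinations(range(len(top)), 2):
            i, j = top[a], top[b]
            if pop_of_parent[i] != pop_of_parent[j]:
                continue
            if pool.brood_year[i] != pool.brood_year[j]:
                continue
            si, sj = pool.sex[i], pool.sex[j]
            if si in ("F", "M") and si == sj:
                continue
            k = pop_of_parent[i]
            flat = tables.pair[k]
            pidx = np.arange(L) * 64 + GP[i] * 16 + GP[j] * 4 + go_pair_off
            pair_hyps.append((i, j, float(flat[pidx].sum())))

        logs = np.concatenate(
            [[0.0], llr_singles, [h[2] for h in pair_hyps] if pair_hyps else []]
        )
        post = np.exp(logs - logsumexp(logs))
        best = int(np.argmax(post))
        tie = (np.abs(post - post[best]) < _TIE_TOL).sum() > 1

        n_single = len(top)
        rec = ParentageResult(offspring.ids[oi], "none", n_loci_compared=n_called)
        if not tie and best >= 1 + n_single:
            i, j, _ = pair_hyps[best - 1 - n_single]
            if post[best] >= config.accept_prob:
                rec = ParentageResult(
                    offspring.ids[oi],
                    "pair",
                    parent1=pool.table.ids[i],
                    parent2=pool.table.ids[j],
                    assigned_population=pool.population[i],
                    assigned_brood_year=int(pool.brood_year[i]),
                    posterior_prob=float(post[best]),
                    n_loci_compared=n_called,
                    parent_populations=(pool.population[i], pool.population[j]),
                )
        elif not tie and 1 <= best < 1 + n_single and config.allow_single_parent:
            i = top[best - 1]
            if post[best] >= config.accept_prob:
                rec = ParentageResult(
                    offspring.ids[oi],
                    "single",
                    parent1=pool.table.ids[i],
                    assigned_population=pool.population[i],
                    assigned_brood_year=int(pool.brood_year[i]),
                    posterior_prob=float(post[best]),
                    n_loci_compared=n_called,
                )
        results.append(rec)
    return results


def results_to_frame(results: list[ParentageResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "offspring_id": [r.offspring_id for r in results],
            "mode": [r.mode for r in results],
            "parent1": [r.parent1 for r in results],
            "parent2": [r.parent2 for r in results],
            "population": [r.assigned_population for r in results],
            "brood_year": [r.assigned_brood_year for r in results],
            "posterior_prob": [r.posterior_prob for r in results],
            "n_loci": [r.n_loci_compared for r in results],
        }
    )


def pbt_summary(results: list[ParentageResult], truth=None) -> dict:
    """Assignment rate and, given truth labels, accuracy of acceptances.

    Accuracy is computed only over accepted (pair or single) results;
    with zero acceptances it is reported as ``None``.
    """
    n = len(results)
    accepted = [r for r in results if r.mode != "none"]
    out: dict = {
        "n_genotyped": n,
        "n_accepted": len(accepted),
        "assignment_rate": (len(accepted) / n) if n else 0.0,
        "accuracy": None,
        "per_population": None,
    }
    if truth is None or not accepted:
        return out
    t = truth.table.set_index("individual_id")
    rows = []
    correct = 0
    for r in accepted:
        rec = t.loc[r.offspring_id]
        pop_ok = r.assigned_population == rec["population"]
        by = rec.get("brood_year")
        by_ok = True
        if by is not None and not pd.isna(by) and r.assigned_brood_year is not None:
            by_ok = int(by) == int(r.assigned_brood_year)
        ok = bool(pop_ok and by_ok)
        correct += ok
        rows.append({"population": rec["population"], "correct": ok})
    out["accuracy"] = correct / len(accepted)
    per = (
        pd.DataFrame(rows)
        .groupby("population")["correct"]
        .agg(n_accepted="size", accuracy="mean")
        .reset_index()
    )
    out["per_population"] = per
    return out
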