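"""Synthetic baselines, broodstocks, offspring, mixtures and tag programs.

Allele-frequency divergence follows a two-level F-model: per locus an
ancestral frequency is drawn uniformly, conservation-unit frequencies
are Beta-distributed around it with dispersion ``fst_between_cu``, and
population frequencies are Beta-distributed around their CU frequency
with dispersion ``fst_within_cu``. All generators are deterministic
given their seed, and every simulated individual receives exactly one
truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_io import MISSING, AlleleFrequencies, BaselineRegistry, GenotypeTable

FREQ_CLAMP = 1e-3


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimConfig:
    n_loci: int = 302
    n_cus: int = 4
    pops_per_cu: int = 5
    fst_between_cu: float = 0.08
    fst_within_cu: float = 0.02
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    genotype_error_rate: float = 0.01
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fst_between_cu < 1.0 and 0.0 < self.fst_within_cu < 1.0):
            raise ValueError("fst values must lie in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie inside (0, 1)")
        for r in (self.genotype_error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class TruthLabels:
    """Ground-truth origin, pedigree and marking info per individual."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "individual_id",
                "population",
                "brood_year",
                "mother_id",
                "father_id",
                "clipped",
                "cwt_code",
            ]
        )
    )

    def __post_init__(self) -> None:
        if self.table["individual_id"].duplicated().any():
            raise ValueError("duplicate individual ids in truth labels")

    def lookup(self, individual_id: str) -> pd.Series:
        hit = self.table[self.table["individual_id"] == individual_id]
        if len(hit) != 1:
            raise KeyError(individual_id)
        return hit.iloc[0]

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.table["individual_id"], self.table["population"]))

    @staticmethod
    def concat(parts: list["TruthLabels"]) -> "TruthLabels":
        return TruthLabels(pd.concat([p.table for p in parts], ignore_index=True))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TruthLabels":
        return cls(pd.read_csv(path))


def _beta_around(rng, mean: np.ndarray, fst: float) -> np.ndarray:
    # clamp the mean so Beta shape parameters stay positive even after
    # extreme draws at the level above
    mean = np.clip(mean, FREQ_CLAMP, 1.0 - FREQ_CLAMP)
    scale = (1.0 - fst) / fst
    return rng.beta(mean * scale, (1.0 - mean) * scale)


def simulate_baseline_freqs(config: SimConfig):
    """Hierarchically diverged allele frequencies.

    Returns ``(AlleleFrequencies, BaselineRegistry)`` for
    ``n_cus * pops_per_cu`` populations named ``CU<c>_P<p>``.
    """
    rng = as_rng(config.seed)
    lo, hi = config.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=config.n_loci)
    pops, cus, freqs = [], [], []
    for c in range(config.n_cus):
        cu_name = f"CU{c + 1:02d}"
        cu_freq = _beta_around(rng, p0, config.fst_between_cu)
        for p in range(config.pops_per_cu):
            pops.append(f"{cu_name}_P{p + 1:02d}")
            cus.append(cu_name)
            freqs.append(_beta_around(rng, cu_freq, config.fst_within_cu))
    values = np.clip(np.asarray(freqs), FREQ_CLAMP, 1.0 - FREQ_CLAMP)
    loci = [f"L{i + 1:04d}" for i in range(config.n_loci)]
    registry = BaselineRegistry(
        pd.DataFrame(
            {
                "population": pops,
                "cu": cus,
                "region": [f"R{(int(cu[2:4]) - 1) % 2 + 1}" for cu in cus],
                "country": "SIM",
            }
        )
    )
    return AlleleFrequencies(pops, loci, values), registry


def sample_genotypes(
    freqs: np.ndarray,
    n: int,
    seed,
    loci: list[str] | None = None,
    group: str = "",
    id_prefix: str = "IND",
) -> GenotypeTable:
    """Hardy-Weinberg draws at independent loci for one population."""
    rng = as_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise ValueError("frequencies must lie strictly inside (0, 1)")
    L = len(freqs)
    geno = rng.binomial(2, freqs, size=(n, L)).astype(np.int8)
    if loci is None:
        loci = [f"L{i + 1:04d}" for i in range(L)]
    ids = np.array([f"{id_prefix}_{i + 1:05d}" for i in range(n)], dtype=object)
    return GenotypeTable(ids, np.array([group] * n, dtype=object), list(loci), geno)


def simulate_broodstock(
    population: str,
    n_females: int,
    n_males: int,
    freqs: np.ndarray,
    seed,
    brood_year: int = 2014,
    loci: list[str] | None = None,
):
    """Broodstock genotypes with sex and brood-year labels.

    Returns a :class:`~pbtgsi.parentage.ParentPool` covering one
    population and one brood year.
    """
    from .parentage import ParentPool

    rng = as_rng(seed)
    table = sample_genotypes(
        freqs,
        n_females + n_males,
        rng,
        loci=loci,
        group=population,
        id_prefix=f"{population}_BY{brood_year}",
    )
    sex = np.array(["F"] * n_females + ["M"] * n_males, dtype=object)
    years = np.full(n_females + n_males, brood_year, dtype=np.int64)
    table.sample_type = "broodstock"
    table.meta = pd.DataFrame({"sex": sex, "brood_year": years})
    return ParentPool(table, sex=sex, brood_year=years)


def simulate_offspring(
    pairs: list[tuple[str, str]],
    n_per_pair: int,
    pool,
    seed,
    id_prefix: str = "OFF",
    clipped: bool = True,
):
    """Mendelian offspring of broodstock pairs.

    Each offspring allele is drawn uniformly from the corresponding
    parent's two alleles, per locus, independently; a parent missing at
    a locus makes the offspring missing there. Returns
    ``(GenotypeTable, TruthLabels)``.
    """
    rng = as_rng(seed)
    L = pool.table.n_loci
    rows, recs = [], []
    k = 0
    for mother_id, father_id in pairs:
        gm = pool.table.row(mother_id)
        gf = pool.table.row(father_id)
        pop = pool.table.groups[np.flatnonzero(pool.table.ids == mother_id)[0]]
        by = pool.brood_year[np.flatnonzero(pool.table.ids == mother_id)[0]]
        tm = gm / 2.0
        tf = gf / 2.0
        for _ in range(n_per_pair):
            g = (rng.random(L) < tm).astype(np.int8) + (rng.random(L) < tf).astype(np.int8)
            g[(gm == MISSING) | (gf == MISSING)] = MISSING
            k += 1
            rows.append(g)
            recs.append(
                {
                    "individual_id": f"{id_prefix}_{k:05d}",
                    "population": pop,
                    "brood_year": int(by),
                    "mother_id": mother_id,
                    "father_id": father_id,
                    "clipped": clipped,
                    "cwt_code": None,
                }
            )
    truth = TruthLabels(pd.DataFrame(recs)) if recs else TruthLabels()
    geno = np.asarray(rows, dtype=np.int8).reshape(len(rows), L)
    table = GenotypeTable(
        np.array([r["individual_id"] for r in recs], dtype=object),
        np.array([r["population"] for r in recs], dtype=object),
        list(pool.table.loci),
        geno,
    )
    return table, truth


def corrupt(
    table: GenotypeTable, error_rate: float, missing_rate: float, seed
) -> GenotypeTable:
    """Apply genotype-class errors and missingness cell-wise.

    With probability ``missing_rate`` a call becomes MISSING; otherwise
    with probability ``error_rate`` it is replaced by one of the other
    two genotype classes, uniformly.
    """
    for r in (error_rate, missing_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = as_rng(seed)
    g = table.geno.copy()
    called = g != MISSING
    u = rng.random(g.shape)
    to_miss = called & (u < missing_rate)
    to_err = called & ~to_miss & (rng.random(g.shape) < error_rate)
    shift = 1 + (rng.random(g.shape) < 0.5).astype(np.int8)
    g[to_err] = (g[to_err] + shift[to_err]) % 3
    g[to_miss] = MISSING
    out = table.take(np.arange(table.n_individuals))
    out.geno = g
    return out


def simulate_mixture(
    composition: dict[str, float],
    pools: dict[str, object],
    freqs: AlleleFrequencies,
    n: int,
    seed,
    clipped_pops: set[str] | None = None,
    id_prefix: str = "MIX",
):
    """Fishery mixture with known origins.

    Populations with an entry in ``pools`` yield offspring of randomly
    mated broodstock pairs (recorded in the truth labels); the rest are
    fresh Hardy-Weinberg draws from their baseline frequencies.
    Returns ``(GenotypeTable, TruthLabels)``.
    """
    total = float(sum(composition.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"composition must sum to 1, got {total}")
    rng = as_rng(seed)
    pops = list(composition)
    if clipped_pops is None:
        clipped_pops = set(pools)
    counts = rng.multinomial(n, [composition[p] for p in pops])
    origins = np.repeat(np.arange(len(pops)), counts)
    rng.shuffle(origins)

    L = len(freqs.loci)
    geno = np.empty((n, L), dtype=np.int8)
    recs = []
    for i, oi in enumerate(origins):
        pop = pops[oi]
        iid = f"{id_prefix}_{i + 1:05d}"
        if pop in pools:
            pool = pools[pop]
            mother_id, father_id, by = _draw_pair(pool, rng)
            gm = pool.table.row(mother_id)
            gf = pool.table.row(father_id)
            g = (rng.random(L) < gm / 2.0).astype(np.int8) + (
                rng.random(L) < gf / 2.0
            ).astype(np.int8)
            g[(gm == MISSING) | (gf == MISSING)] = MISSING
            rec = dict(mother_id=mother_id, father_id=father_id, brood_year=int(by))
        else:
            g = rng.binomial(2, freqs.for_population(pop), size=L).astype(np.int8)
            rec = dict(mother_id=None, father_id=None, brood_year=None)
        geno[i] = g
        recs.append(
            {
                "individual_id": iid,
                "population": pop,
                "clipped": pop in clipped_pops,
                "cwt_code": None,
                **rec,
            }
        )
    table = GenotypeTable(
        np.array([r["individual_id"] for r in recs], dtype=object),
        np.array(["mixture"] * n, dtype=object),
        list(freqs.loci),
        geno,
    )
    return table, (TruthLabels(pd.DataFrame(recs)) if recs else TruthLabels())


def _draw_pair(pool, rng) -> tuple[str, str, int]:
    years = np.unique(pool.brood_year)
    by = years[rng.integers(len(years))]
    in_year = pool.brood_year == by
    females = np.flatnonzero(in_year & (pool.sex == "F"))
    males = np.flatnonzero(in_year & (pool.sex == "M"))
    if len(females) == 0 or len(males) == 0:
        raise ValueError("pool needs at least one female and one male per brood year")
    mi = females[rng.integers(len(females))]
    fi = males[rng.integers(len(males))]
    return pool.table.ids[mi], pool.table.ids[fi], int(by)


def simulate_cwt_program(
    true_catch: int,
    mark_rate: float,
    tag_loss_rate: float,
    sampling_rate: float,
    seed,
) -> int:
    """Observed tag count in a fishery sample.

    Each caught fish independently carries a readable tag with
    probability ``mark_rate * (1 - tag_loss_rate)`` and is sampled with
    probability ``sampling_rate``.
    """
    for r in (mark_rate, tag_loss_rate, sampling_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = as_rng(seed)
    p = mark_rate * (1.0 - tag_loss_rate) * sampling_rate
    return int(rng.binomial(int(true_catch), p))
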