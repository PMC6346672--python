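"""PBT-first routing and combined stock-composition estimates.

Accepted parent-pair assignments fix an individual's origin with
probability 1; accepted single-parent assignments are additionally
required to agree with the individual's maximum-posterior conservation
unit from GSI. Everyone else is allocated via their GSI posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import BaselineRegistry
from .gsi import GSIResult
from .parentage import ParentageConfig, ParentageResult


@dataclass
class AssignmentRecord:
    individual_id: str
    method: str  # 'PBT' | 'GSI'
    allocation: np.ndarray  # over the population list; sums to 1
    population: str | None = None  # PBT only
    brood_year: int | None = None  # PBT only


def _gsi_row_index(gsi: GSIResult) -> dict[str, int]:
    return {i: k for k, i in enumerate(gsi.individual_ids)}


def route(
    parentage_results: list[ParentageResult],
    gsi: GSIResult,
    registry: BaselineRegistry,
    config: ParentageConfig = ParentageConfig(),
) -> list[AssignmentRecord]:
    """Give every individual exactly one method: PBT or GSI.

    Pair-mode results at/above the acceptance threshold become PBT
    one-hots. Single-parent results additionally require the assigned
    population to lie in the individual's maximum-posterior CU under
    GSI. Everything else falls back to the individual's GSI posterior.
    """
    populations = list(gsi.populations)
    pop_index = {p: i for i, p in enumerate(populations)}
    registered = set(registry.populations)
    M, units = registry.membership(populations, "cu")
    cu_of = registry.unit_of("cu")
    rows = _gsi_row_index(gsi)

    records: list[AssignmentRecord] = []
    for r in parentage_results:
        if r.mode != "none" and r.assigned_population not in registered:
            raise KeyError(
                f"PBT population {r.assigned_population!r} absent from registry"
            )
        gsi_row = rows.get(r.offspring_id)
        as_pbt = False
        if r.mode == "pair" and r.posterior_prob >= config.accept_prob:
            # both parents must come from the same population
            pp = r.parent_populations
            as_pbt = pp is None or pp[0] == pp[1]
        elif r.mode == "single" and r.posterior_prob >= config.accept_prob:
            if gsi_row is None:
                raise ValueError(
                    f"single-parent result for {r.offspring_id!r} needs a GSI posterior"
                )
            post = gsi.indiv_posterior[gsi_row]
            max_cu = units[int(np.argmax(post @ M))]
            as_pbt = cu_of[r.assigned_population] == max_cu
        if as_pbt:
            if r.assigned_population not in pop_index:
                populations.append(r.assigned_population)
                pop_index[r.assigned_population] = len(populations) - 1
            alloc = np.zeros(len(populations))
            alloc[pop_index[r.assigned_population]] = 1.0
            records.append(
                AssignmentRecord(
                    r.offspring_id, "PBT", alloc, r.assigned_population, r.assigned_brood_year
                )
            )
        else:
            if gsi_row is None:
                raise ValueError(f"no GSI posterior for unassigned {r.offspring_id!r}")
            records.append(
                AssignmentRecord(
                    r.offspring_id, "GSI", gsi.indiv_posterior[gsi_row].copy()
                )
            )
    # pad earlier allocations if PBT introduced extra populations
    K = len(populations)
    for rec in records:
        if len(rec.allocation) < K:
            rec.allocation = np.pad(rec.allocation, (0, K - len(rec.allocation)))
        rec.allocation = rec.allocation / rec.allocation.sum()
    for rec in records:
        rec.populations = populations  # type: ignore[attr-defined]
    return records


@dataclass
class CombinedComposition:
    populations: list[str]
    pi_mean: np.ndarray
    pi_sd: np.ndarray
    pi_trace: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit": self.populations, "mean": self.pi_mean, "sd": self.pi_sd}
        )


def combined_composition(
    records: list[AssignmentRecord],
    gsi: GSIResult,
    registry: BaselineRegistry | None = None,
    level: str = "population",
):
    """Composition mean/SD mixing PBT constants with GSI draws.

    Per retained Gibbs iteration the composition is the average of PBT
    one-hots (iteration-constant) and the GSI individuals' sampled
    origins; means and SDs are taken over iterations. Roll-up to CU or
    region sums member populations within each iteration.
    """
    if not records:
        raise ValueError("no assignment records")
    populations = getattr(records[0], "populations", list(gsi.populations))
    K = len(populations)
    n = len(records)
    keep = gsi.z_trace.shape[0]

    pbt_counts = np.zeros(K)
    gsi_cols = []
    rows = _gsi_row_index(gsi)
    gsi_pop_map = np.array([populations.index(p) for p in gsi.populations])
    for rec in records:
        if rec.method == "PBT":
            alloc = rec.allocation
            if len(alloc) < K:
                alloc = np.pad(alloc, (0, K - len(alloc)))
            pbt_counts += alloc
        else:
            gsi_cols.append(rows[rec.individual_id])

    trace = np.tile(pbt_counts, (keep, 1))
    if gsi_cols:
        z = gsi.z_trace[:, gsi_cols]  # (keep, m) indices into gsi.populations
        z_mapped = gsi_pop_map[z]
        for t in range(keep):
            trace[t] += np.bincount(z_mapped[t], minlength=K)
    trace /= n

    comp = CombinedComposition(
        populations=list(populations),
        pi_mean=trace.mean(axis=0),
        pi_sd=trace.std(axis=0, ddof=1),
        pi_trace=trace,
    )
    if level == "population":
        return comp
    if registry is None:
        raise ValueError("registry required for roll-up")
    M, units = registry.membership(populations, level)
    rolled = trace @ M
    return CombinedComposition(
        populations=list(units),
        pi_mean=rolled.mean(axis=0),
        pi_sd=rolled.std(axis=0, ddof=1),
        pi_trace=rolled,
    )


def composition_error(estimate, truth, units=None) -> dict:
    """Mean absolute error between a composition estimate and truth.

    ``estimate`` and ``truth`` map unit -> proportion (dict or Series);
    missing keys count as 0. Returns the per-unit errors and their mean.
    """
    est = dict(estimate)
    tru = dict(truth)
    if units is None:
        units = sorted(set(est) | set(tru))
    per_unit = {u: abs(est.get(u, 0.0) - tru.get(u, 0.0)) for u in units}
    return {
        "per_unit": per_unit,
        "mean_abs_error": float(np.mean(list(per_unit.values()))) if units else 0.0,
    }


def records_to_frame(records: list[AssignmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "method": [r.method for r in records],
            "population": [r.population for r in records],
            "brood_year": [r.brood_year for r in records],
            "max_allocation": [float(np.max(r.allocation)) for r in records],
        }
    )
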