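"""Downstream fishery estimators.

Seasonal sample weighting, hatchery-origin catch, population-specific
catch, coded-wire-tag expansion, hatchery escapement, exploitation
rates, stray rates, and the PBT-versus-CWT identification comparison.
Counts and reported percents use round-half-away-from-zero; fractions
are kept at full precision internally.
"""

from __future__ import annotations

import math
from collections import namedtuple

import numpy as np
import pandas as pd


def round_half_up(x: float) -> int:
    """Round half away from zero to an integer."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def seasonal_subsample(
    monthly_catch: dict, monthly_available: dict
) -> dict:
    """Subsample sizes weighting monthly genotypes by monthly catch.

    The reference month is the sampled month with the largest catch; all
    of its genotypes are used, and every other sampled month m gets
    ``min(available_m, round(available_ref * catch_m / catch_ref))``.
    """
    sampled = [m for m, a in monthly_available.items() if a > 0]
    if not sampled:
        raise ValueError("no months with available genotypes")
    ref = max(sorted(sampled), key=lambda m: monthly_catch.get(m, 0))
    catch_ref = monthly_catch.get(ref, 0)
    if catch_ref <= 0:
        raise ValueError("reference month has zero catch")
    n_ref = monthly_available[ref]
    out = {}
    for m in sampled:
        if m == ref:
            out[m] = n_ref
        else:
            target = round_half_up(n_ref * monthly_catch.get(m, 0) / catch_ref)
            out[m] = min(monthly_available[m], target)
    return out


def hatchery_origin_catch(total_catch: float, clip_rate: float) -> int:
    """Total catch times the observed adipose-clip rate, to a whole fish."""
    if not 0.0 <= clip_rate <= 1.0:
        raise ValueError("clip_rate must lie in [0, 1]")
    return round_half_up(total_catch * clip_rate)


def population_catch(hatchery_catch: float, composition: dict) -> dict:
    """Hatchery-origin catch apportioned by stock composition, rounded."""
    return {p: round_half_up(hatchery_catch * f) for p, f in composition.items()}


def cwt_expand(
    observed: float,
    no_pin_loss_rate: float,
    mark_rate: float,
    sampling_rate: float,
) -> float:
    """Expand an observed tag count to an estimated catch.

    ``observed / (1 - no_pin_loss) / mark_rate / sampling_rate``.
    """
    if mark_rate <= 0 or sampling_rate <= 0:
        raise ValueError("mark_rate and sampling_rate must be positive")
    if not 0.0 <= no_pin_loss_rate < 1.0:
        raise ValueError("no_pin_loss_rate must lie in [0, 1)")
    return observed / (1.0 - no_pin_loss_rate) / mark_rate / sampling_rate


def cwt_expand_records(records: pd.DataFrame) -> pd.DataFrame:
    """Per-population expansion summed over tag codes.

    ``records`` columns: population, tag_code, count, loss_rate,
    mark_rate, sampling_rate.
    """
    records = records.copy()
    records["expanded"] = [
        cwt_expand(r["count"], r["loss_rate"], r["mark_rate"], r["sampling_rate"])
        for _, r in records.iterrows()
    ]
    return (
        records.groupby("population")["expanded"].sum().reset_index(name="estimated_catch")
    )


def hatchery_escapement(total_escapement: float, clip_proportion: float) -> int:
    """Escapement times the clip proportion observed in the escapement."""
    if not 0.0 <= clip_proportion <= 1.0:
        raise ValueError("clip_proportion must lie in [0, 1]")
    return round_half_up(total_escapement * clip_proportion)


def exploitation_rate(catch: float, escapement: float) -> int:
    """ER = 100 * catch / (catch + escapement), as an integer percent."""
    if catch < 0 or escapement < 0:
        raise ValueError("catch and escapement must be non-negative")
    if catch + escapement <= 0:
        raise ValueError("catch + escapement must be positive")
    return round_half_up(100.0 * catch / (catch + escapement))


StrayRateResult = namedtuple(
    "StrayRateResult", ["rate", "n_strays", "n_accepted", "pair_counts"]
)


def stray_rate(parentage_results, sampled_population: dict) -> StrayRateResult:
    """Strays = accepted assignments whose origin differs from the
    sampled river; rate = strays / accepted.

    ``sampled_population`` maps individual id -> the population whose
    escapement the fish was sampled from.
    """
    accepted = [r for r in parentage_results if r.mode != "none"]
    pairs: dict[tuple[str, str], int] = {}
    strays = 0
    for r in accepted:
        sampled = sampled_population[r.offspring_id]
        if r.assigned_population != sampled:
            strays += 1
            key = (r.assigned_population, sampled)
            pairs[key] = pairs.get(key, 0) + 1
    pair_counts = pd.DataFrame(
        [
            {"from_population": a, "to_population": b, "n_strays": c}
            for (a, b), c in sorted(pairs.items())
        ],
        columns=["from_population", "to_population", "n_strays"],
    )
    rate = strays / len(accepted) if accepted else 0.0
    return StrayRateResult(rate, strays, len(accepted), pair_counts)


def pbt_vs_cwt_comparison(counts: pd.DataFrame) -> dict:
    """Totals and ratios comparing PBT identifications with CWT recoveries.

    ``counts`` has one row per population with columns ``cwts_observed``
    (recovered in fisheries), ``cwts_submitted`` (available for
    genotyping), ``genotyped``, ``pbt_with_cwt`` (PBT assignments among
    CWT-bearing fish) and ``pbt_without_cwt``; populations with no CWT
    program have zeros in the CWT columns.
    """
    tot = counts.sum(numeric_only=True)
    cwt = float(tot["cwts_submitted"])
    pbt_cwt_pops = float(
        counts.loc[counts["cwts_submitted"] > 0, ["pbt_with_cwt", "pbt_without_cwt"]]
        .to_numpy()
        .sum()
    )
    pbt_total = float(tot["pbt_with_cwt"] + tot["pbt_without_cwt"])
    out = {
        "cwts_observed": float(tot["cwts_observed"]),
        "cwts_submitted": cwt,
        "genotyped": float(tot["genotyped"]),
        "pbt_with_cwt": float(tot["pbt_with_cwt"]),
        "pbt_total_cwt_populations": pbt_cwt_pops,
        "pbt_total": pbt_total,
        "pct_of_genotyped_assigned": (
            100.0 * tot["pbt_with_cwt"] / tot["genotyped"] if tot["genotyped"] else np.nan
        ),
        "pct_more_than_cwt": (
            100.0 * (pbt_cwt_pops - cwt) / cwt if cwt else np.nan
        ),
        "pct_of_cwt_total": (100.0 * pbt_total / cwt if cwt else np.nan),
    }
    return out


def cost_per_identification(total_cost: float, n_identified: int) -> int:
    """Tagging cost per identified fish, rounded to a whole dollar."""
    if n_identified <= 0:
        raise ValueError("n_identified must be positive")
    return round_half_up(total_cost / n_identified)
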