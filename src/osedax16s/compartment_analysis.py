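"""Tissue-level summaries of symbiont infections from dissection tables.

Twenty-one large worms were dissected into five tissue compartments (basal
trunk, anterior ovisac, outer ovisac sheath, inner ovisac, posterior
ovisac/root) and each compartment screened for symbiont ribotypes.  This
module computes per-tissue amplification success rates, the frequency of
worms hosting multiple distinct ribotypes, and flags for between-tissue
compartmentalization of strains — kept distinct from within-tissue mixtures,
where two ribotypes co-occur in a single tissue (e.g. a trunk amplifying
two strains at once).

Compartmentalization is assessed, by default, between the outer ovisac
sheath and the inner ovisac: these are the adjacent tissue layers in which
strain segregation is observable in dissection surveys, and a worm is
flagged when both amplified but yielded different ribotype sets.  An
alternative mode flags any worm with two amplified tissues carrying disjoint
ribotype sets.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple, Sequence

from .core_io import TISSUE_LABELS, WormRecord

__all__ = [
    "TissueRate",
    "MultipleInfectionRate",
    "tissue_success_rates",
    "multiple_infection_rate",
    "compartmentalization_flags",
    "within_tissue_mixtures",
]


class TissueRate(NamedTuple):
    successes: int
    denominator: int
    percent: float


_POLICIES = ("dissected", "all_worms")


def tissue_success_rates(
    worms: Sequence[WormRecord],
    denominator_policy: str = "dissected",
) -> dict[str, TissueRate]:
    """Per-tissue amplification success.

    ``denominator_policy="dissected"`` counts only worms in which the tissue
    was dissected (amplified or failed); ``"all_worms"`` uses the full worm
    list, counting undissected tissues as misses.
    """
    if not worms:
        raise ValueError("empty worm list")
    if denominator_policy not in _POLICIES:
        raise ValueError(f"denominator_policy must be one of {_POLICIES}")
    rates: dict[str, TissueRate] = {}
    for tissue in TISSUE_LABELS:
        successes = sum(
            1
            for w in worms
            if tissue in w.tissues and w.tissues[tissue].status == "amplified"
        )
        if denominator_policy == "dissected":
            denom = sum(
                1
                for w in worms
                if tissue in w.tissues
                and w.tissues[tissue].status in ("amplified", "failed")
            )
        else:
            denom = len(worms)
        percent = 100.0 * successes / denom if denom else float("nan")
        rates[tissue] = TissueRate(successes, denom, percent)
    return rates


class MultipleInfectionRate(NamedTuple):
    count: int
    total: int
    percent: float
    worm_ids: tuple[str, ...]


def multiple_infection_rate(worms: Sequence[WormRecord]) -> MultipleInfectionRate:
    """Worms whose tissues together yielded ≥2 distinct ribotypes."""
    if not worms:
        raise ValueError("empty worm list")
    multi = tuple(w.worm_id for w in worms if len(w.ribotype_union) >= 2)
    return MultipleInfectionRate(
        count=len(multi),
        total=len(worms),
        percent=100.0 * len(multi) / len(worms),
        worm_ids=multi,
    )


def compartmentalization_flags(
    worms: Sequence[WormRecord],
    tissue_pair: tuple[str, str] = ("outer_ovisac", "inner_ovisac"),
    mode: str = "tissue_pair",
) -> dict[str, str]:
    """Classify each worm as compartmentalized, uniform, or not assessable.

    A worm with fewer than two amplified tissues is not assessable.  In the
    default ``tissue_pair`` mode, it is compartmentalized when both tissues
    of the configured pair amplified with different ribotype sets; in
    ``any_pair_disjoint`` mode, when any two amplified tissues carry disjoint
    ribotype sets.  Everything else is uniform.  Within-tissue mixtures do
    not count toward compartmentalization (see
    :func:`within_tissue_mixtures`).
    """
    if mode not in ("tissue_pair", "any_pair_disjoint"):
        raise ValueError(f"unknown mode {mode!r}")
    flags: dict[str, str] = {}
    for worm in worms:
        amplified = {
            t: set(r.ribotypes)
            for t, r in worm.tissues.items()
            if r.status == "amplified"
        }
        if len(amplified) < 2:
            flags[worm.worm_id] = "not_assessable"
            continue
        if mode == "tissue_pair":
            a, b = tissue_pair
            hit = a in amplified and b in amplified and amplified[a] != amplified[b]
        else:
            tissues = list(amplified)
            hit = any(
                amplified[tissues[i]].isdisjoint(amplified[tissues[j]])
                for i in range(len(tissues))
                for j in range(i + 1, len(tissues))
            )
        flags[worm.worm_id] = "compartmentalized" if hit else "uniform"
    return flags


def within_tissue_mixtures(
    worms: Sequence[WormRecord],
) -> dict[str, tuple[str, ...]]:
    """Tissues in which a single compartment yielded more than one ribotype."""
    out: dict[str, tuple[str, ...]] = {}
    for worm in worms:
        mixed = tuple(
            tissue
            for tissue, result in worm.tissues.items()
            if result.status == "amplified" and result.has_within_tissue_mixture
        )
        if mixed:
            out[worm.worm_id] = mixed
    return out
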