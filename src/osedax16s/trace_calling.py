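"""Consensus calling from Sanger peak heights and mixed-infection analysis.

A worm is designated multiply infected when, at a polymorphic site, the
secondary peak is at least half the height of the primary peak; the site is
then called with the two-fold IUPAC code for the top two bases.  Lesser
(tertiary) peaks are never considered — they are confounded with background.
"At least half" is inclusive: a secondary peak at exactly 0.5× the primary
calls an ambiguity.

Under this rule and peak heights proportional to template fractions, a
minority strain is detectable iff its fraction f satisfies
f/(1−f) ≥ r, i.e. f ≥ r/(1+r) — one third for the default r = 0.5.  This is
the idealized detection limit behind the observation that minority ribotypes
below ~30% of a mixture go undetected by direct sequencing.

Phases of multi-site mixtures are resolved against clone libraries: clone
haplotypes seen only once are discarded as cloning artifacts, remaining
haplotypes must agree with the consensus ambiguity codes, and ambiguous
positions not supported by two distinct retained bases stay unresolved and
are masked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    IUPAC_TWOFOLD,
    SequenceRecord,
    iupac_code,
    iupac_expand,
)

__all__ = [
    "TraceColumn",
    "ConsensusCall",
    "CloneLibrary",
    "PhaseResolution",
    "DilutionResult",
    "UncallableColumnError",
    "call_base",
    "call_consensus",
    "call_consensus_heights",
    "decompose_single_ambiguity",
    "filter_clone_singletons",
    "resolve_phases",
    "flag_singletons",
    "simulate_dilution_series",
    "detection_threshold",
    "detection_probability",
]

_BASE_ORDER = ("A", "C", "G", "T")


class UncallableColumnError(ValueError):
    """Raised for a trace column with no signal (all peak heights zero)."""


@dataclass(frozen=True)
class TraceColumn:
    """Peak heights for the four bases at one trace position."""

    heights: Mapping[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.heights) - set(_BASE_ORDER)
        if unknown:
            raise ValueError(f"unknown bases in trace column: {sorted(unknown)}")
        if any(h < 0 for h in self.heights.values()):
            raise ValueError("peak heights must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.heights.get(b, 0.0) for b in _BASE_ORDER], dtype=float)


def call_base(column: TraceColumn, ratio_threshold: float = 0.5) -> str:
    """Call one position by the half-height rule.

    Returns the primary base when the secondary peak is below
    ``ratio_threshold`` × the primary height, else the two-fold IUPAC code
    for the top two bases.  Tertiary peaks are ignored.  Ties are broken in
    A<C<G<T order (a 50:50 column is ambiguous regardless).
    """
    h = column.as_array()
    if h.max() <= 0:
        raise UncallableColumnError("all-zero trace column")
    order = np.argsort(-h, kind="stable")
    primary, secondary = int(order[0]), int(order[1])
    if h[secondary] >= ratio_threshold * h[primary]:
        return iupac_code({_BASE_ORDER[primary], _BASE_ORDER[secondary]})
    return _BASE_ORDER[primary]


@dataclass(frozen=True)
class ConsensusCall:
    """A called consensus with the 1-based positions of its ambiguity codes."""

    seq: SequenceRecord
    ambiguous_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        for pos in self.ambiguous_positions:
            if self.seq.seq[pos - 1] not in IUPAC_TWOFOLD:
                raise ValueError(
                    f"position {pos} listed ambiguous but holds "
                    f"{self.seq.seq[pos - 1]!r}"
                )

    @property
    def mixed(self) -> bool:
        return bool(self.ambiguous_positions)


def call_consensus_heights(
    heights: np.ndarray,
    ratio_threshold: float = 0.5,
    id: str = "consensus",
) -> ConsensusCall:
    """Vectorised consensus calling from a (length × 4) peak-height array."""
    heights = np.asarray(heights, dtype=float)
    if heights.ndim != 2 or heights.shape[1] != 4:
        raise ValueError("heights must be a (length, 4) array in A,C,G,T order")
    dead = heights.max(axis=1) <= 0
    if dead.any():
        raise UncallableColumnError(
            f"all-zero trace column at position {int(np.nonzero(dead)[0][0]) + 1}"
        )
    order = np.argsort(-heights, axis=1, kind="stable")
    primary = order[:, 0]
    secondary = order[:, 1]
    rows = np.arange(heights.shape[0])
    ambiguous = heights[rows, secondary] >= ratio_threshold * heights[rows, primary]
    chars = [
        iupac_code({_BASE_ORDER[p], _BASE_ORDER[s]}) if amb else _BASE_ORDER[p]
        for p, s, amb in zip(primary, secondary, ambiguous)
    ]
    positions = tuple(int(i) + 1 for i in np.nonzero(ambiguous)[0])
    return ConsensusCall(
        seq=SequenceRecord(id=id, seq="".join(chars)), ambiguous_positions=positions
    )


def call_consensus(
    trace: Sequence[TraceColumn],
    ratio_threshold: float = 0.5,
    id: str = "consensus",
) -> ConsensusCall:
    """Per-column half-height calling over a whole trace."""
    if not trace:
        raise ValueError("empty trace")
    heights = np.stack([col.as_array() for col in trace])
    return call_consensus_heights(heights, ratio_threshold=ratio_threshold, id=id)


def decompose_single_ambiguity(
    call: ConsensusCall,
) -> tuple[SequenceRecord, SequenceRecord]:
    """Manually phase a consensus with exactly one ambiguity code.

    A single two-fold code forces the two constituent ribotypes.  With zero
    or multiple ambiguous positions the phases are not identifiable this way
    and clone-library resolution is required.
    """
    if len(call.ambiguous_positions) != 1:
        raise ValueError(
            f"manual decomposition needs exactly one ambiguous position, got "
            f"{len(call.ambiguous_positions)}; use clone-library phase resolution"
        )
    (pos,) = call.ambiguous_positions
    code = call.seq.seq[pos - 1]
    first, second = sorted(iupac_expand(code))
    template = call.seq.seq
    return (
        SequenceRecord(id=f"{call.seq.id}|{pos}{first}", seq=template[: pos - 1] + first + template[pos:]),
        SequenceRecord(id=f"{call.seq.id}|{pos}{second}", seq=template[: pos - 1] + second + template[pos:]),
    )


@dataclass(frozen=True)
class CloneLibrary:
    """Haplotype counts from individually sequenced clones of one amplicon."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("clone counts must be non-negative")

    @property
    def n_clones(self) -> int:
        return int(sum(self.counts.values()))


def filter_clone_singletons(lib: CloneLibrary) -> CloneLibrary:
    """Drop haplotypes observed once (treated as cloning artifacts)."""
    return CloneLibrary(counts={h: c for h, c in lib.counts.items() if c >= 2})


@dataclass(frozen=True)
class PhaseResolution:
    """Outcome of clone-library phasing for one mixed consensus."""

    ribotypes: tuple[SequenceRecord, ...]
    unresolved_positions: tuple[int, ...]
    inconsistent_clones: tuple[str, ...]


def resolve_phases(
    call: ConsensusCall,
    lib: CloneLibrary,
    infer_complement: bool = False,
) -> PhaseResolution:
    """Resolve mixed-infection phases against a singleton-filtered clone library.

    Retained clone haplotypes must carry, at every ambiguous consensus
    position, a base within that code's expansion; violators are flagged
    inconsistent and excluded.  Ambiguous positions at which the consistent
    clones do not show two distinct bases remain unresolved and are masked
    with N in the returned ribotypes.  With ``infer_complement`` (off by
    default), a lone consistent haplotype has its complementary phase
    inferred by flipping every ambiguous position to the other base of the
    code — only valid under a strict two-strain assumption.
    """
    if not call.ambiguous_positions:
        return PhaseResolution(
            ribotypes=(call.seq,), unresolved_positions=(), inconsistent_clones=()
        )
    length = len(call.seq.seq)
    consistent: list[str] = []
    inconsistent: list[str] = []
    for hap in lib.counts:
        if len(hap) != length:
            inconsistent.append(hap)
            continue
        ok = all(
            hap[pos - 1] in iupac_expand(call.seq.seq[pos - 1])
            for pos in call.ambiguous_positions
        )
        (consistent if ok else inconsistent).append(hap)

    if infer_complement and len(consistent) == 1:
        hap = consistent[0]
        flipped = list(hap)
        for pos in call.ambiguous_positions:
            (other,) = iupac_expand(call.seq.seq[pos - 1]) - {hap[pos - 1]}
            flipped[pos - 1] = other
        consistent.append("".join(flipped))

    unresolved = tuple(
        pos
        for pos in call.ambiguous_positions
        if len({hap[pos - 1] for hap in consistent}) < 2
    )
    masked: list[str] = []
    for hap in consistent:
        chars = list(hap)
        for pos in unresolved:
            chars[pos - 1] = "N"
        seq = "".join(chars)
        if seq not in masked:
            masked.append(seq)
    ribotypes = tuple(
        SequenceRecord(id=f"{call.seq.id}|phase{i + 1}", seq=seq)
        for i, seq in enumerate(sorted(masked))
    )
    return PhaseResolution(
        ribotypes=ribotypes,
        unresolved_positions=unresolved,
        inconsistent_clones=tuple(inconsistent),
    )


def flag_singletons(ribotype_counts: Mapping[str, int]) -> set[str]:
    """Ribotypes observed exactly once, which require independent confirmation."""
    return {rt for rt, n in ribotype_counts.items() if n == 1}


@dataclass(frozen=True)
class DilutionResult:
    """Calls from a two-template dilution series.

    ``calls`` is indexed by (ratio, replicate) with one column per 1-based
    SNP position; ``ratios`` are fractions of the first template.
    """

    ratios: tuple[float, ...]
    snp_positions: tuple[int, ...]
    calls: pd.DataFrame

    def ambiguous_ratios(self, position: int) -> tuple[float, ...]:
        """Ratios at which every replicate called a two-fold code at ``position``."""
        col = self.calls[position].unstack(level=1)
        amb = col.map(lambda ch: ch in IUPAC_TWOFOLD).all(axis=1)
        return tuple(r for r in self.ratios if amb.loc[r])

    def detected_ratios(self, position: int) -> tuple[float, ...]:
        """Ratios at which any replicate called a two-fold code at ``position``."""
        col = self.calls[position].unstack(level=1)
        amb = col.map(lambda ch: ch in IUPAC_TWOFOLD).any(axis=1)
        return tuple(r for r in self.ratios if amb.loc[r])


DEFAULT_DILUTION_GRID = tuple(r / 10 for r in range(11))


def simulate_dilution_series(
    ribotype_a: SequenceRecord,
    ribotype_b: SequenceRecord,
    ratios: Iterable[float] = DEFAULT_DILUTION_GRID,
    replicates: int = 3,
    efficiency_sd: float = 0.0,
    seed: int = 0,
    ratio_threshold: float = 0.5,
) -> DilutionResult:
    """Mix two ribotypes over a ratio grid and call every SNP position.

    Each (ratio, replicate) builds a peak-height trace with fresh per-strain
    amplification efficiencies and applies the half-height rule at the
    positions where the two templates differ.  Deterministic given ``seed``.
    """
    from .synthetic_data import trace_heights

    if len(ribotype_a.seq) != len(ribotype_b.seq):
        raise ValueError("dilution templates must have equal length")
    snps = tuple(
        i + 1 for i, (a, b) in enumerate(zip(ribotype_a.seq, ribotype_b.seq)) if a != b
    )
    if not snps:
        raise ValueError("dilution templates are identical: no polymorphic site")
    ratios = tuple(float(r) for r in ratios)
    if any(not 0 <= r <= 1 for r in ratios):
        raise ValueError("ratios must be fractions in [0, 1]")

    rng = np.random.default_rng(seed)
    snp_idx = np.array(snps) - 1
    rows = []
    index = []
    for ratio in ratios:
        for rep in range(1, replicates + 1):
            if ratio == 0.0:
                mixture = {ribotype_b: 1.0}
            elif ratio == 1.0:
                mixture = {ribotype_a: 1.0}
            else:
                mixture = {ribotype_a: ratio, ribotype_b: 1.0 - ratio}
            heights = trace_heights(mixture, efficiency_sd, rng)
            call = call_consensus_heights(
                heights[snp_idx], ratio_threshold=ratio_threshold
            )
            rows.append(list(call.seq.seq))
            index.append((ratio, rep))
    calls = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["ratio", "replicate"]),
        columns=list(snps),
    )
    return DilutionResult(ratios=ratios, snp_positions=snps, calls=calls)


def detection_threshold(ratio_threshold: float = 0.5) -> float:
    """Minimum detectable minority fraction under proportional peak heights.

    A minority at fraction f produces a secondary/primary height ratio of
    f/(1−f); the half-height rule fires iff f ≥ r/(1+r).
    """
    if not 0 < ratio_threshold <= 1:
        raise ValueError("ratio_threshold must be in (0, 1]")
    return ratio_threshold / (1.0 + ratio_threshold)


class DetectionProbability(NamedTuple):
    probability: float
    underestimation_factor: float


def detection_probability(
    minority_fraction_distribution,
    threshold: float = 1.0 / 3.0,
) -> DetectionProbability:
    """P(mixture detected) for a distribution of minority fractions on [0, ½].

    Accepts a frozen scipy distribution (its survival function is used), an
    array of sampled fractions, or a single fraction (point mass).  Also
    reports the implied underestimation factor for the frequency of multiple
    infections: true frequency = observed × factor.
    """
    dist = minority_fraction_distribution
    if hasattr(dist, "sf"):
        p = float(dist.sf(threshold))
        # include any point mass exactly at the threshold (detection is inclusive)
        if hasattr(dist, "pmf"):
            p += float(dist.pmf(threshold))
    elif np.isscalar(dist):
        p = 1.0 if float(dist) >= threshold else 0.0
    else:
        samples = np.asarray(dist, dtype=float)
        if samples.size == 0:
            raise ValueError("empty sample of minority fractions")
        p = float((samples >= threshold).mean())
    factor = float("inf") if p == 0 else 1.0 / p
    return DetectionProbability(probability=p, underestimation_factor=factor)
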