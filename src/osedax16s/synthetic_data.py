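"""Synthetic ribotype pools, mixed infections, traces, and survey metadata.

The generators emulate the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without the deposited sequences:

* ribospecies pools — groups of 672-bp ribotypes with within-group p-distance
  bounded by 3% and between-group mean divergence of at least 3.5%, matching
  the empirical within/between divergence regime of the two dominant
  endosymbiont ribospecies;
* mixed infections — 1–9 strains per worm with Dirichlet-distributed
  fractions (the field reports two to nine distinct ribotypes per worm, with
  single-strain calls arising from the ~30% detection limit);
* sequencing traces — per-position peak heights proportional to strain
  fractions times a per-strain log-normal amplification efficiency;
* surveys — worms with date, bone substrate, and host species, and a
  symbiont mixture drawn from date-dependent ribospecies probabilities,
  with marginals cloned from the three-year whale-fall survey (153 worms in
  the contingency analyses).

Divergence guarantees are achieved combinatorially: each species carries a
block of private substitutions relative to a common root sequence, and each
ribotype a smaller private block relative to its species centroid, all blocks
disjoint.  Pair distances are then exact sums of block sizes, so the
within/between post-conditions hold by construction for every draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core_io import SequenceRecord, WormRecord

__all__ = [
    "SimulationConfig",
    "SurveyDesign",
    "RibospeciesPool",
    "SurveyResult",
    "generate_ribospecies_pool",
    "generate_infection",
    "generate_trace",
    "trace_heights",
    "generate_survey",
    "study_survey_design",
    "independence_survey_design",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Sampling periods and worm counts of the three-year survey (N = 153).
STUDY_DATES = ("Oct-06", "Jan-07", "Aug-07", "Dec-07", "Mar-09")
STUDY_WORMS_PER_DATE = (32, 19, 35, 34, 33)
#: Observed ribospecies counts per period (Rs1, Rs2).
STUDY_RIBOSPECIES_COUNTS = ((31, 1), (18, 1), (35, 0), (32, 2), (13, 20))
#: Pooled host-species marginals after lumping rare species into "other".
STUDY_HOST_COUNTS = {
    "O. rubiplumus": 67,
    "O. frankpressi": 34,
    "green-palp": 13,
    "nude-palp A": 12,
    "other": 27,
}
STUDY_BONE_COUNTS = {"whale": 111, "cow": 42}


class ConfigError(ValueError):
    """Raised for infeasible or invalid simulation configurations."""


@dataclass(frozen=True)
class SurveyDesign:
    """Sampling design for a synthetic survey.

    ``ribospecies_counts`` fixes exact per-date species quotas (cloning an
    observed table); ``ribospecies_probs`` draws species per worm instead,
    either date-dependent (mapping) or shared across dates, in which case
    date and symbiont ribospecies are independent.  Host species and bone
    type are always drawn independently of the symbionts.
    """

    dates: tuple[str, ...]
    worms_per_date: tuple[int, ...]
    ribospecies_counts: tuple[tuple[int, ...], ...] | None = None
    ribospecies_probs: Mapping[str, tuple[float, ...]] | tuple[float, ...] | None = None
    host_probs: Mapping[str, float] = field(
        default_factory=lambda: {k: v / 153 for k, v in STUDY_HOST_COUNTS.items()}
    )
    bone_probs: Mapping[str, float] = field(
        default_factory=lambda: {k: v / 153 for k, v in STUDY_BONE_COUNTS.items()}
    )

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.worms_per_date):
            raise ConfigError("dates and worms_per_date differ in length")
        for n in self.worms_per_date:
            if n < 0 or int(n) != n:
                raise ConfigError("worm counts must be non-negative integers")
        if self.ribospecies_counts is not None:
            if len(self.ribospecies_counts) != len(self.dates):
                raise ConfigError("one ribospecies count row per date required")
            for row, n in zip(self.ribospecies_counts, self.worms_per_date):
                if any(c < 0 or int(c) != c for c in row):
                    raise ConfigError("cell targets must be non-negative integers")
                if sum(row) != n:
                    raise ConfigError(
                        f"ribospecies counts {row} do not sum to the date total {n}"
                    )
        elif self.ribospecies_probs is None:
            raise ConfigError("provide ribospecies_counts or ribospecies_probs")

    @property
    def n_worms(self) -> int:
        return int(sum(self.worms_per_date))

    def species_probs_for(self, date: str) -> tuple[float, ...]:
        probs = self.ribospecies_probs
        if isinstance(probs, Mapping):
            return tuple(probs[date])
        return tuple(probs)


def study_survey_design() -> SurveyDesign:
    """The observed survey: per-date Rs1/Rs2 quotas cloned from the study table."""
    return SurveyDesign(
        dates=STUDY_DATES,
        worms_per_date=STUDY_WORMS_PER_DATE,
        ribospecies_counts=STUDY_RIBOSPECIES_COUNTS,
    )


def independence_survey_design() -> SurveyDesign:
    """Null design: pooled ribospecies probabilities shared across all dates."""
    totals = np.sum(STUDY_RIBOSPECIES_COUNTS, axis=0)
    return SurveyDesign(
        dates=STUDY_DATES,
        worms_per_date=STUDY_WORMS_PER_DATE,
        ribospecies_probs=tuple(totals / totals.sum()),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-data generators; ``seed`` fixes every draw."""

    seed: int = 0
    seq_length: int = 672
    n_ribospecies: int = 2
    ribotypes_per_species: int | tuple[int, ...] = (29, 3)
    within_divergence_max: float = 0.03
    between_divergence_min: float = 0.035
    strains_per_worm: tuple[int, int] = (1, 9)
    fraction_model: float = 1.0  # Dirichlet concentration for strain fractions
    efficiency_sd: float = 0.2  # sd of per-strain log amplification efficiency
    survey: SurveyDesign = field(default_factory=study_survey_design)

    def __post_init__(self) -> None:
        if not (0 <= self.within_divergence_max <= 1 and 0 <= self.between_divergence_min <= 1):
            raise ConfigError("divergence parameters must be proportions in [0, 1]")
        if self.within_divergence_max >= self.between_divergence_min:
            raise ConfigError("within_divergence_max must be < between_divergence_min")
        lo, hi = self.strains_per_worm
        if not (1 <= lo <= hi):
            raise ConfigError("strains_per_worm must be a range with 1 ≤ lo ≤ hi")
        if self.fraction_model <= 0:
            raise ConfigError("Dirichlet concentration must be positive")
        if self.efficiency_sd < 0:
            raise ConfigError("efficiency_sd must be non-negative")

    def ribotype_counts(self) -> tuple[int, ...]:
        counts = self.ribotypes_per_species
        if isinstance(counts, int):
            counts = (counts,) * self.n_ribospecies
        if len(counts) != self.n_ribospecies:
            raise ConfigError("one ribotype count per species required")
        if any(c < 1 for c in counts):
            raise ConfigError("each species needs at least one ribotype")
        return tuple(counts)


@dataclass(frozen=True)
class RibospeciesPool:
    """Ribotype sequences grouped by their true (generating) species label."""

    species: Mapping[str, tuple[SequenceRecord, ...]]

    @property
    def records(self) -> tuple[SequenceRecord, ...]:
        return tuple(r for group in self.species.values() for r in group)

    @property
    def true_assignment(self) -> dict[str, str]:
        return {r.id: label for label, group in self.species.items() for r in group}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_ribospecies_pool(config: SimulationConfig) -> RibospeciesPool:
    """Generate ribotype groups with guaranteed divergence structure.

    Within every group, pairwise p-distance ≤ ``within_divergence_max``;
    between every pair of groups, the mean group-to-group p-distance is
    ≥ ``between_divergence_min``.  Deterministic given ``config.seed``.
    """
    rng = _rng(config.seed)
    L = config.seq_length
    counts = config.ribotype_counts()
    k = config.n_ribospecies

    # Private-substitution block sizes giving the divergence guarantees.
    m_between = math.ceil(config.between_divergence_min * L / 2)
    m_within = math.floor(config.within_divergence_max * L / 2)
    multi = [c for c in counts if c > 1]
    if multi and m_within < 1:
        raise ConfigError(
            "sequence length too short to place within-group variation under "
            f"within_divergence_max={config.within_divergence_max}"
        )
    needed = k * m_between + sum(c * m_within for c in counts)
    if needed > L:
        raise ConfigError(
            f"infeasible configuration: {needed} private sites needed but the "
            f"sequence length is only {L}"
        )

    root = rng.choice(_BASES, size=L)
    sites = rng.permutation(L)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        block = sites[cursor : cursor + n]
        cursor += n
        return block

    def mutate(seq: np.ndarray, positions: np.ndarray) -> np.ndarray:
        out = seq.copy()
        for pos in positions:
            choices = _BASES[_BASES != out[pos]]
            out[pos] = rng.choice(choices)
        return out

    species: dict[str, tuple[SequenceRecord, ...]] = {}
    for s in range(k):
        label = f"sp{s + 1}"
        centroid = mutate(root, take(m_between))
        group: list[SequenceRecord] = []
        for t in range(counts[s]):
            if counts[s] == 1:
                ribotype = centroid
            else:
                n_private = int(rng.integers(1, m_within + 1))
                ribotype = mutate(centroid, take(n_private))
            group.append(
                SequenceRecord(
                    id=f"{label}_rt{t + 1}", seq=ribotype.tobytes().decode()
                )
            )
        species[label] = tuple(group)
    return RibospeciesPool(species=species)


def generate_infection(
    pool: Sequence[SequenceRecord],
    config: SimulationConfig,
    seed,
) -> dict[SequenceRecord, float]:
    """Draw a mixed infection: strains from ``pool`` with Dirichlet fractions."""
    if not pool:
        raise ConfigError("empty strain pool")
    rng = _rng(seed)
    lo, hi = config.strains_per_worm
    hi = min(hi, len(pool))
    lo = min(lo, hi)
    n = int(rng.integers(lo, hi + 1))
    chosen = rng.choice(len(pool), size=n, replace=False)
    fractions = rng.dirichlet(np.full(n, config.fraction_model))
    return {pool[int(i)]: float(f) for i, f in zip(chosen, fractions)}


def trace_heights(
    mixture: Mapping[SequenceRecord, float],
    efficiency_sd: float,
    seed,
) -> np.ndarray:
    """Peak-height array (length × 4, base order A,C,G,T) for a strain mixture.

    Height of base b at a position is the sum, over strains carrying b there,
    of strain fraction × amplification efficiency, with efficiency
    exp(Normal(0, efficiency_sd)) drawn once per strain.  Each column is
    scaled so its maximum height is 100.
    """
    if not mixture:
        raise ValueError("empty mixture")
    rng = _rng(seed)
    strains = list(mixture)
    lengths = {len(s.seq) for s in strains}
    if len(lengths) > 1:
        raise ValueError(f"strains have unequal lengths: {sorted(lengths)}")
    enc = np.frombuffer("".join(s.seq for s in strains).encode(), dtype=np.uint8)
    enc = enc.reshape(len(strains), -1)
    if not np.isin(enc, _BASES).all():
        raise ValueError("trace simulation requires plain A/C/G/T strain sequences")
    fractions = np.array([mixture[s] for s in strains], dtype=float)
    efficiency = np.exp(rng.normal(0.0, efficiency_sd, size=len(strains)))
    weights = fractions * efficiency
    heights = np.zeros((enc.shape[1], 4), dtype=float)
    for b, base in enumerate(_BASES):
        heights[:, b] = ((enc == base) * weights[:, None]).sum(axis=0)
    heights *= 100.0 / heights.max(axis=1, keepdims=True)
    return heights


def generate_trace(
    mixture: Mapping[SequenceRecord, float],
    efficiency_sd: float,
    seed,
):
    """Like :func:`trace_heights`, as a list of TraceColumn for per-base calling."""
    from .trace_calling import TraceColumn

    heights = trace_heights(mixture, efficiency_sd, seed)
    return [
        TraceColumn(heights={"A": row[0], "C": row[1], "G": row[2], "T": row[3]})
        for row in heights
    ]


@dataclass(frozen=True)
class SurveyResult:
    """A synthetic survey: worm metadata plus the true underlying mixtures."""

    worms: tuple[WormRecord, ...]
    mixtures: Mapping[str, Mapping[SequenceRecord, float]]
    true_species: Mapping[str, str]
    pool: RibospeciesPool


def generate_survey(config: SimulationConfig) -> SurveyResult:
    """Simulate a dated, bone- and host-structured survey of infected worms.

    Each worm receives a date (per the fixed design cells), a bone type, a
    host species, a true symbiont ribospecies (per exact quotas or
    date-dependent probabilities), and a mixed infection drawn from that
    species' ribotype pool.  Under a shared probability vector the symbionts
    are independent of date and host.  Deterministic given ``config.seed``.
    """
    design = config.survey
    rng = _rng(config.seed)
    pool = generate_ribospecies_pool(
        replace(config, seed=int(rng.integers(2**31)))
    )
    species_labels = list(pool.species)

    hosts = list(design.host_probs)
    host_p = np.array([design.host_probs[h] for h in hosts], dtype=float)
    bones = list(design.bone_probs)
    bone_p = np.array([design.bone_probs[b] for b in bones], dtype=float)

    worms: list[WormRecord] = []
    mixtures: dict[str, dict[SequenceRecord, float]] = {}
    true_species: dict[str, str] = {}
    worm_no = 0
    for d, (date, n_worms) in enumerate(zip(design.dates, design.worms_per_date)):
        if design.ribospecies_counts is not None:
            quotas = design.ribospecies_counts[d]
            if len(quotas) > len(species_labels):
                raise ConfigError(
                    "survey design references more ribospecies than the pool has"
                )
            labels = [
                species_labels[s] for s, q in enumerate(quotas) for _ in range(int(q))
            ]
        else:
            probs = np.asarray(design.species_probs_for(date), dtype=float)
            if probs.size > len(species_labels):
                raise ConfigError(
                    "survey design references more ribospecies than the pool has"
                )
            labels = [
                species_labels[int(i)]
                for i in rng.choice(probs.size, size=n_worms, p=probs / probs.sum())
            ]
        for label in labels:
            worm_no += 1
            worm_id = f"worm{worm_no:03d}"
            worms.append(
                WormRecord(
                    worm_id=worm_id,
                    host_species=hosts[int(rng.choice(len(hosts), p=host_p))],
                    dive=f"dive{d + 1}",
                    date=date,
                    bone_type=bones[int(rng.choice(len(bones), p=bone_p))],
                )
            )
            mixtures[worm_id] = generate_infection(
                pool.species[label], config, int(rng.integers(2**31))
            )
            true_species[worm_id] = label
    return SurveyResult(
        worms=tuple(worms), mixtures=mixtures, true_species=true_species, pool=pool
    )
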