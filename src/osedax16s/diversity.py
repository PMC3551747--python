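"""Sequence diversity statistics and ribospecies clustering.

Distances are uncorrected p-distances with pairwise deletion: any site where
either sequence carries a gap, N, or ambiguity code is excluded from that
pair's comparison.  Ribotypes are clustered into ribospecies (OTU-like groups
of ≥97% identity) by average-linkage agglomeration on the p-distance matrix,
stopping when the smallest between-cluster mean distance exceeds the 3%
threshold.  Average linkage matters here: two empirical ribospecies can
approach within ~1.9% at their closest pair while their mean divergence is
3.5%; single linkage would wrongly merge them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core_io import SequenceRecord

__all__ = [
    "PairwiseDistance",
    "DistanceMatrix",
    "RibospeciesClustering",
    "p_distance",
    "distance_matrix",
    "segregating_sites",
    "nucleotide_diversity",
    "watterson_theta",
    "effective_length",
    "cluster_ribospecies",
    "group_divergence_matrix",
]

# Encoding used for vectorised comparisons: plain bases 0..3, everything else
# (gap, N, ambiguity codes) 255 and excluded pairwise.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seqs: Sequence[SequenceRecord]) -> np.ndarray:
    lengths = {len(s.seq) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    return _CODE[
        np.frombuffer("".join(s.seq for s in seqs).encode(), dtype=np.uint8)
    ].reshape(len(seqs), -1)


class PairwiseDistance(NamedTuple):
    proportion: float
    differences: int
    compared_sites: int


def p_distance(a: SequenceRecord, b: SequenceRecord) -> PairwiseDistance:
    """Uncorrected distance between two equal-length sequences.

    Returns the proportion of differing sites, the raw difference count, and
    the number of pairwise-comparable sites (both plain A/C/G/T).
    """
    enc = _encode([a, b])
    ok = (enc[0] != 255) & (enc[1] != 255)
    compared = int(ok.sum())
    if compared == 0:
        raise ValueError(f"no comparable sites between {a.id!r} and {b.id!r}")
    diffs = int((enc[0][ok] != enc[1][ok]).sum())
    return PairwiseDistance(diffs / compared, diffs, compared)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise p-distances with raw counts for a set of ribotypes."""

    labels: tuple[str, ...]
    proportions: np.ndarray  # (n, n) float
    differences: np.ndarray  # (n, n) int
    compared_sites: np.ndarray  # (n, n) int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.labels, columns=self.labels)


def distance_matrix(seqs: Sequence[SequenceRecord]) -> DistanceMatrix:
    """All pairwise p-distances (pairwise deletion), vectorised."""
    if not seqs:
        raise ValueError("no sequences")
    labels = tuple(s.id for s in seqs)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence ids")
    enc = _encode(seqs)
    valid = enc != 255
    ok = valid[:, None, :] & valid[None, :, :]
    compared = ok.sum(axis=2)
    diffs = ((enc[:, None, :] != enc[None, :, :]) & ok).sum(axis=2)
    off = ~np.eye(len(seqs), dtype=bool)
    if np.any(compared[off] == 0):
        i, j = np.argwhere((compared == 0) & off)[0]
        raise ValueError(f"no comparable sites between {labels[i]!r} and {labels[j]!r}")
    with np.errstate(invalid="ignore"):
        props = np.where(compared > 0, diffs / np.maximum(compared, 1), 0.0)
    return DistanceMatrix(labels, props, diffs, compared)


def segregating_sites(seqs: Sequence[SequenceRecord]) -> int:
    """Number of alignment columns with ≥2 distinct unambiguous bases (S)."""
    if len(seqs) < 2:
        raise ValueError("segregating sites require at least two sequences")
    enc = _encode(seqs)
    count = 0
    for col in enc.T:
        bases = np.unique(col[col != 255])
        if bases.size >= 2:
            count += 1
    return count


class DiversityResult(NamedTuple):
    pi: float
    mean_pairwise_differences: float
    n_pairs: int


def nucleotide_diversity(seqs: Sequence[SequenceRecord]) -> DiversityResult:
    """Mean per-site diversity π and mean pairwise difference count k.

    π averages the pairwise p-distance over all n(n−1)/2 sequence pairs; k
    averages the raw difference counts.
    """
    if len(seqs) < 2:
        raise ValueError("nucleotide diversity requires at least two sequences")
    dm = distance_matrix(seqs)
    iu = np.triu_indices(len(seqs), k=1)
    return DiversityResult(
        pi=float(dm.proportions[iu].mean()),
        mean_pairwise_differences=float(dm.differences[iu].mean()),
        n_pairs=len(iu[0]),
    )


def watterson_theta(S: int, n: int, effective_length: float) -> float:
    """Watterson's θ per site: S / (a · L) with a = Σ_{i=1}^{n−1} 1/i."""
    if n < 2:
        raise ValueError("Watterson's theta requires n ≥ 2 sequences")
    if effective_length <= 0:
        raise ValueError("effective length must be positive")
    if S < 0:
        raise ValueError("segregating-site count cannot be negative")
    a = sum(1.0 / i for i in range(1, n))
    return S / (a * effective_length)


def effective_length(seqs: Sequence[SequenceRecord]) -> int:
    """Columns free of gaps/N/ambiguities in every sequence (default θ_S length)."""
    enc = _encode(seqs)
    return int(np.all(enc != 255, axis=0).sum())


@dataclass(frozen=True)
class RibospeciesClustering:
    """A partition of ribotypes into ribospecies with divergence summaries."""

    assignment: Mapping[str, str]
    threshold: float
    linkage: str
    divergence: pd.DataFrame  # within-group means on the diagonal, between off it

    @property
    def groups(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for ribotype, group in self.assignment.items():
            out.setdefault(group, []).append(ribotype)
        return {g: tuple(sorted(m)) for g, m in sorted(out.items())}

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ribotype": list(self.assignment), "ribospecies": list(self.assignment.values())}
        )


_LINKAGES = ("average", "single", "complete")


def cluster_ribospecies(
    seqs: Sequence[SequenceRecord],
    threshold: float = 0.03,
    linkage: str = "average",
) -> RibospeciesClustering:
    """Agglomerative clustering of ribotypes into ribospecies.

    Merging proceeds while the smallest between-cluster linkage distance is
    ≤ ``threshold``.  Average linkage is the mean p-distance over all
    cross-cluster pairs (maintained exactly via the Lance–Williams update).
    Ties are broken by merging the pair whose (lexicographically smallest
    member id, partner id) key sorts first, which makes the result invariant
    to input order.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if not seqs:
        raise ValueError("no sequences to cluster")
    order = np.argsort([s.id for s in seqs])
    seqs = [seqs[i] for i in order]
    labels = [s.id for s in seqs]
    n = len(seqs)
    dm = distance_matrix(seqs)

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    rep: dict[int, str] = {i: labels[i] for i in range(n)}  # smallest member id
    d = dm.proportions.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    tol = 1e-12

    while len(active) > 1:
        idx = sorted(active)
        sub = d[np.ix_(idx, idx)]
        dmin = sub.min()
        if dmin > threshold:
            break
        cands = []
        for a_pos, b_pos in zip(*np.nonzero(sub <= dmin + tol)):
            if a_pos < b_pos:
                i, j = idx[a_pos], idx[b_pos]
                cands.append((tuple(sorted((rep[i], rep[j]))), i, j))
        _, i, j = min(cands)
        ni, nj = sizes[i], sizes[j]
        for k in active - {i, j}:
            if linkage == "average":
                dnew = (ni * d[i, k] + nj * d[j, k]) / (ni + nj)
            elif linkage == "single":
                dnew = min(d[i, k], d[j, k])
            else:
                dnew = max(d[i, k], d[j, k])
            d[i, k] = d[k, i] = dnew
        members[i].extend(members[j])
        rep[i] = min(rep[i], rep[j])
        sizes[i] = ni + nj
        active.remove(j)

    group_ids = sorted(active, key=lambda i: rep[i])
    assignment: dict[str, str] = {}
    group_members: dict[str, list[int]] = {}
    for g, i in enumerate(group_ids, start=1):
        name = f"Rs{g}"
        group_members[name] = sorted(members[i])
        for m in members[i]:
            assignment[labels[m]] = name
    assignment = {lab: assignment[lab] for lab in sorted(assignment)}

    divergence = _group_divergence(group_members, dm)
    return RibospeciesClustering(
        assignment=assignment, threshold=threshold, linkage=linkage, divergence=divergence
    )


def _group_divergence(
    group_members: Mapping[str, Sequence[int]], dm: DistanceMatrix
) -> pd.DataFrame:
    names = list(group_members)
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for gi, name_i in enumerate(names):
        mi = list(group_members[name_i])
        if len(mi) > 1:
            sub = dm.proportions[np.ix_(mi, mi)]
            iu = np.triu_indices(len(mi), k=1)
            mat.loc[name_i, name_i] = float(sub[iu].mean())
        # singleton groups: within-group divergence not computable (left NaN)
        for name_j in names[gi + 1 :]:
            mj = list(group_members[name_j])
            between = float(dm.proportions[np.ix_(mi, mj)].mean())
            mat.loc[name_i, name_j] = mat.loc[name_j, name_i] = between
    return mat


def group_divergence_matrix(
    clustering: RibospeciesClustering, dm: DistanceMatrix
) -> pd.DataFrame:
    """Within- (diagonal) and between-group (off-diagonal) mean p-distances.

    The diagonal is NaN for singleton groups, mirroring the "n/c" convention
    in divergence tables.
    """
    index = {label: i for i, label in enumerate(dm.labels)}
    missing = set(clustering.assignment) - set(index)
    if missing:
        raise ValueError(f"distance matrix lacks ribotypes: {sorted(missing)}")
    group_members = {
        g: [index[r] for r in ribos] for g, ribos in clustering.groups.items()
    }
    return _group_divergence(group_members, dm)
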