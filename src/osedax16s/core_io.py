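"""Sequence and survey-metadata I/O for the endosymbiont ribotyping pipeline.

The unit of analysis is a trimmed 672-bp 16S amplicon obtained with
Oceanospirillales-specific degenerate primers.  Sequences may carry the six
two-fold IUPAC ambiguity codes (R, Y, S, W, K, M), which downstream modules
interpret as unresolved mixed-infection sites.  Survey metadata describe
individual Osedax worms: host species, dive, sampling date, bone substrate,
and per-tissue amplification results from dissections.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "PrimerPair",
    "TissueResult",
    "WormRecord",
    "FastaFormatError",
    "NoAmpliconError",
    "WormTableError",
    "TISSUE_LABELS",
    "BONE_TYPES",
    "IUPAC_TWOFOLD",
    "iupac_expand",
    "iupac_code",
    "read_fasta",
    "write_fasta",
    "extract_amplicon",
    "parse_tissue_cell",
    "read_worm_table",
    "OCEANOSPIRILLALES_PRIMERS",
]

# Plain bases, alignment characters, and the six two-fold ambiguity codes.
PLAIN_BASES = frozenset("ACGT")
IUPAC_TWOFOLD: Mapping[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}
SEQUENCE_ALPHABET = PLAIN_BASES | frozenset("N-") | frozenset(IUPAC_TWOFOLD)

# Full degenerate alphabet accepted in primers (two-, three- and four-fold).
_PRIMER_EXPANSION: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_CODE_FOR_PAIR = {bases: code for code, bases in IUPAC_TWOFOLD.items()}

TISSUE_LABELS = (
    "basal_trunk",
    "anterior_ovisac",
    "outer_ovisac",
    "inner_ovisac",
    "posterior_ovisac_root",
)
BONE_TYPES = ("whale", "cow")
TISSUE_STATUSES = ("amplified", "failed", "not_dissected")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; the message names the offending line."""


class NoAmpliconError(ValueError):
    """Raised when a primer pair produces no in-silico amplicon on a template."""


class WormTableError(ValueError):
    """Raised for survey metadata tables with invalid labels or structure."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N,-} plus two-fold codes."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate PCR primer pair; reverse is given 5'→3' on the opposite strand."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, primer in (("forward", self.forward), ("reverse", self.reverse)):
            if not primer:
                raise ValueError(f"{name} primer is empty")
            bad = set(primer) - set(_PRIMER_EXPANSION)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC characters: {sorted(bad)}")


#: The 435F/1213R pair designed against Oceanospirillales 16S; amplifies the
#: 672-bp fragment analysed throughout (W = A or T).
OCEANOSPIRILLALES_PRIMERS = PrimerPair(
    forward="CAGCWGTGAGGAAAGGTT", reverse="TGTGTAGCCCAACTCG"
)


@dataclass(frozen=True)
class TissueResult:
    """Amplification outcome for one dissected tissue compartment.

    ``lobe_calls`` preserves the per-lobe raw calls for tissues examined as
    several ovisac lobes; ``ribotypes`` is the set of distinct labels seen in
    any lobe (repeated identical labels collapse).  A ``+`` within one lobe
    call denotes two ribotypes co-occurring in that lobe (a within-tissue
    mixture), which is distinct from between-tissue compartmentalization.
    """

    status: str
    ribotypes: tuple[str, ...] = ()
    lobe_calls: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in TISSUE_STATUSES:
            raise ValueError(f"unknown tissue status {self.status!r}")
        if (self.status == "amplified") != bool(self.ribotypes):
            raise ValueError("ribotypes must be non-empty iff status is 'amplified'")

    @property
    def has_within_tissue_mixture(self) -> bool:
        return any("+" in call for call in self.lobe_calls) or len(self.ribotypes) > 1


@dataclass(frozen=True)
class WormRecord:
    """One surveyed Osedax individual with optional per-tissue dissection results."""

    worm_id: str
    host_species: str = "unidentified"
    dive: str = ""
    date: str = ""
    bone_type: str | None = None
    tissues: Mapping[str, TissueResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bone_type is not None and self.bone_type not in BONE_TYPES:
            raise WormTableError(
                f"worm {self.worm_id!r}: bone type must be one of {BONE_TYPES}, "
                f"got {self.bone_type!r}"
            )
        for label in self.tissues:
            if label not in TISSUE_LABELS:
                raise WormTableError(
                    f"worm {self.worm_id!r}: unknown tissue label {label!r}"
                )

    @property
    def ribotype_union(self) -> frozenset[str]:
        """Distinct ribotype labels amplified from any tissue of this worm."""
        out: set[str] = set()
        for result in self.tissues.values():
            out.update(result.ribotypes)
        return frozenset(out)


def iupac_expand(code: str) -> frozenset[str]:
    """Expand a base or two-fold IUPAC code to its set of plain bases.

    >>> sorted(iupac_expand("Y"))
    ['C', 'T']
    """
    if code in PLAIN_BASES:
        return frozenset((code,))
    if code in IUPAC_TWOFOLD:
        return IUPAC_TWOFOLD[code]
    raise ValueError(f"not a base or two-fold IUPAC code: {code!r}")


def iupac_code(bases: Iterable[str]) -> str:
    """Inverse of :func:`iupac_expand`: the code for a set of one or two bases."""
    key = frozenset(bases)
    if len(key) == 1:
        (base,) = key
        if base in PLAIN_BASES:
            return base
        raise ValueError(f"not a plain base: {base!r}")
    try:
        return _CODE_FOR_PAIR[key]
    except KeyError:
        raise ValueError(f"no two-fold IUPAC code for base set {sorted(key)}") from None


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Identifiers are the header up to the first whitespace; sequences are
    uppercased.  Illegal characters raise :class:`FastaFormatError` naming the
    record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace(" ", "")
        try:
            records.append(SequenceRecord(id=rec.id, seq=seq))
        except ValueError as exc:
            raise FastaFormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


def _primer_regex(primer: str) -> re.Pattern[str]:
    return re.compile(
        "".join(
            base if len(exp := _PRIMER_EXPANSION[base]) == 1 else f"[{exp}]"
            for base in primer
        )
    )


def extract_amplicon(template: SequenceRecord, primers: PrimerPair) -> SequenceRecord:
    """In-silico PCR: the inter-primer region of an oriented template.

    The forward primer is matched on the given strand allowing IUPAC
    degeneracy; the reverse primer (given 5'→3' on the opposite strand) is
    matched as its reverse complement downstream of the forward footprint.
    The leftmost forward hit and its nearest downstream reverse hit delimit
    the amplicon; both primer footprints are excluded.
    """
    if len(template.seq) <= len(primers.forward) + len(primers.reverse):
        raise NoAmpliconError(
            f"template {template.id!r} shorter than the combined primer footprints"
        )
    fwd = _primer_regex(primers.forward).search(template.seq)
    if fwd is None:
        raise NoAmpliconError(f"no forward-primer site in template {template.id!r}")
    rev_site = str(Seq(primers.reverse).reverse_complement())
    rev = _primer_regex(rev_site).search(template.seq, fwd.end())
    if rev is None:
        raise NoAmpliconError(
            f"no reverse-primer site downstream of the forward site in "
            f"template {template.id!r}"
        )
    inner = template.seq[fwd.end() : rev.start()]
    if not inner:
        raise NoAmpliconError(
            f"primers abut on template {template.id!r}: empty amplicon"
        )
    return SequenceRecord(id=f"{template.id}|amplicon", seq=inner)


def parse_tissue_cell(cell: str) -> TissueResult:
    """Parse one dissection-table cell into a :class:`TissueResult`.

    Cell dialect: ``-`` = tissue not dissected; ``na`` = dissected but no
    amplification; comma-separated entries are independently examined ovisac
    lobes; ``+`` within an entry separates co-occurring ribotypes in one lobe.
    Repeated identical labels across lobes collapse to one ribotype.
    """
    text = str(cell).strip()
    if text in {"-", ""}:
        return TissueResult(status="not_dissected")
    lobes = tuple(part.strip() for part in text.split(","))
    labels: list[str] = []
    for lobe in lobes:
        if lobe.lower() == "na":
            continue
        for label in (p.strip() for p in lobe.split("+")):
            if not label:
                raise WormTableError(f"malformed tissue cell {cell!r}")
            if label not in labels:
                labels.append(label)
    if not labels:
        return TissueResult(status="failed", lobe_calls=lobes)
    return TissueResult(status="amplified", ribotypes=tuple(labels), lobe_calls=lobes)


_REQUIRED_COLUMNS = {"worm_id", "dive", "bone", "date", "host_species", "tissue", "ribotypes"}


def read_worm_table(path) -> list[WormRecord]:
    """Read a long-format survey table (one row per worm × tissue) into records.

    Required columns: worm_id, dive, bone, date, host_species, tissue,
    ribotypes.  The ribotypes column uses the dissection-cell dialect of
    :func:`parse_tissue_cell`; an optional ``status`` column, if present, must
    agree with the parsed cell.  Worms without dissection rows may use an
    empty ``tissue`` value.
    """
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    if frame.empty and frame.columns.size == 0:
        return []
    missing = _REQUIRED_COLUMNS - set(frame.columns)
    if missing:
        raise WormTableError(f"{path}: missing required columns {sorted(missing)}")
    frame = frame.fillna("")

    worms: list[WormRecord] = []
    for worm_id, rows in frame.groupby("worm_id", sort=False):
        meta = rows.iloc[0]
        bone = meta["bone"].strip().lower() or None
        if bone is not None and bone not in BONE_TYPES:
            raise WormTableError(f"{path}: worm {worm_id!r} has unknown bone type {bone!r}")
        tissues: dict[str, TissueResult] = {}
        for _, row in rows.iterrows():
            tissue = row["tissue"].strip()
            if not tissue:
                continue
            if tissue not in TISSUE_LABELS:
                raise WormTableError(f"{path}: worm {worm_id!r} has unknown tissue {tissue!r}")
            result = parse_tissue_cell(row["ribotypes"])
            declared = str(row.get("status", "")).strip()
            if declared and declared != result.status:
                raise WormTableError(
                    f"{path}: worm {worm_id!r} tissue {tissue}: declared status "
                    f"{declared!r} conflicts with cell {row['ribotypes']!r} "
                    f"({result.status})"
                )
            tissues[tissue] = result
        worms.append(
            WormRecord(
                worm_id=str(worm_id),
                host_species=meta["host_species"].strip() or "unidentified",
                dive=meta["dive"].strip(),
                date=meta["date"].strip(),
                bone_type=bone,
                tissues=tissues,
            )
        )
    return worms
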