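"""Loaders for the small published survey tables shipped with the package.

Three printed tables travel with the code as plain-text fixtures: the five
two-way contingency tables of the whale-fall survey (observed counts with
the expected values and G statistics as printed), the empirical two-template
dilution-series calls, and the 21-worm tissue-dissection table.  They are
inputs to the analysis, kept verbatim including two printed quirks that the
loaders surface in metadata: the date×ribospecies table prints df=5 for a
5×2 layout (true df is 4), and the host×ribospecies table's Rs1/Rs2 row
labels are swapped relative to the date table's totals.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import NamedTuple

import pandas as pd

from .association_stats import ContingencyTable
from .core_io import WormRecord, parse_tissue_cell
from .trace_calling import DilutionResult

__all__ = [
    "PublishedContingency",
    "load_contingency_tables",
    "load_dilution_calls",
    "load_worm_dissections",
    "worm_dissections_long_frame",
]

_DIVE_DATES = {"T1119": "Aug-07", "DR12": "Mar-09"}


def _data_path(name: str):
    return resources.files(__package__) / "data" / name


class PublishedContingency(NamedTuple):
    """One published two-way table with its printed expected values and G."""

    table: ContingencyTable
    printed_expected: pd.DataFrame
    printed_G: float
    printed_df: int
    printed_P: str
    description: str


def load_contingency_tables() -> dict[str, PublishedContingency]:
    """The five survey contingency tables, keyed by what they cross-tabulate."""
    with _data_path("contingency_tables.json").open() as handle:
        raw = json.load(handle)
    out: dict[str, PublishedContingency] = {}
    for key, spec in raw.items():
        observed = pd.DataFrame(
            spec["observed"], index=spec["row_labels"], columns=spec["col_labels"],
            dtype=float,
        )
        expected = pd.DataFrame(
            spec["printed_expected"], index=spec["row_labels"],
            columns=spec["col_labels"], dtype=float,
        )
        out[key] = PublishedContingency(
            table=ContingencyTable(observed=observed),
            printed_expected=expected,
            printed_G=float(spec["printed_G"]),
            printed_df=int(spec["printed_df"]),
            printed_P=str(spec["printed_P"]),
            description=spec["description"],
        )
    return out


def load_dilution_calls() -> dict[str, DilutionResult]:
    """Empirical dilution-series calls, one result per template mixture."""
    with _data_path("dilution_series.tsv").open() as handle:
        frame = pd.read_csv(handle, sep="\t", comment="#")
    ratio_cols = [c for c in frame.columns if ":" in c]
    ratios = tuple(float(c.split(":")[0]) / 100.0 for c in ratio_cols)
    out: dict[str, DilutionResult] = {}
    for mixture, rows in frame.groupby("mixture", sort=False):
        positions = tuple(int(p) for p in rows["position"].unique())
        records, index = [], []
        for ratio_col, ratio in zip(ratio_cols, ratios):
            for rep, rep_rows in rows.groupby("replicate", sort=True):
                calls = rep_rows.set_index("position")[ratio_col]
                records.append([calls.loc[p] for p in positions])
                index.append((ratio, int(rep)))
        calls = pd.DataFrame(
            records,
            index=pd.MultiIndex.from_tuples(index, names=["ratio", "replicate"]),
            columns=list(positions),
        )
        out[str(mixture)] = DilutionResult(
            ratios=ratios, snp_positions=positions, calls=calls
        )
    return out


def worm_dissections_long_frame() -> pd.DataFrame:
    """The dissection table in the long survey dialect (one row per tissue)."""
    with _data_path("tissue_dissections.tsv").open() as handle:
        wide = pd.read_csv(handle, sep="\t", comment="#", dtype=str).fillna("")
    tissue_cols = [c for c in wide.columns if c not in ("dive", "bone_no", "worm_no")]
    rows = []
    for _, row in wide.iterrows():
        parts = [row["dive"], row["bone_no"].strip(), row["worm_no"].strip()]
        worm_id = ".".join(p for p in parts if p)
        for tissue in tissue_cols:
            rows.append(
                {
                    "worm_id": worm_id,
                    "dive": row["dive"],
                    "bone": "",
                    "date": _DIVE_DATES.get(row["dive"], ""),
                    "host_species": "",
                    "tissue": tissue,
                    "ribotypes": row[tissue],
                }
            )
    return pd.DataFrame(rows)


def load_worm_dissections() -> list[WormRecord]:
    """The 21 dissected worms as validated records."""
    frame = worm_dissections_long_frame()
    worms: list[WormRecord] = []
    for worm_id, rows in frame.groupby("worm_id", sort=False):
        meta = rows.iloc[0]
        tissues = {
            row["tissue"]: parse_tissue_cell(row["ribotypes"])
            for _, row in rows.iterrows()
        }
        worms.append(
            WormRecord(
                worm_id=str(worm_id),
                dive=meta["dive"],
                date=meta["date"],
                tissues=tissues,
            )
        )
    return worms
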