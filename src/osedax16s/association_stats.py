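"""Two-way contingency analysis with the likelihood-ratio G-test.

G = 2 Σ O_ij ln(O_ij / E_ij) with E_ij = R_i C_j / N and 0·ln 0 = 0, referred
to the chi-square distribution with (r−1)(c−1) degrees of freedom.  Zero
cells are allowed; zero margins are not (lump rare categories first, which is
also the standard remedy against sampling-zero artifacts).  No continuity or
Williams correction is applied by default; both are available behind flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "GTestResult",
    "expected_counts",
    "g_test",
    "lump_rare",
    "subset_test",
]


@dataclass(frozen=True)
class ContingencyTable:
    """A labeled observed-count matrix for a two-way test of independence."""

    observed: pd.DataFrame

    def __post_init__(self) -> None:
        obs = self.observed
        if obs.empty:
            raise ValueError("contingency table is empty")
        values = obs.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("observed counts must be numeric")
        if (values < 0).any():
            raise ValueError("observed counts must be non-negative")
        if values.sum() <= 0:
            raise ValueError("contingency table has zero grand total")

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[tuple[str, str], float] | np.ndarray | Sequence[Sequence[float]],
        row_labels: Sequence[str] | None = None,
        col_labels: Sequence[str] | None = None,
    ) -> "ContingencyTable":
        if isinstance(counts, Mapping):
            frame = pd.Series(counts).unstack(fill_value=0)
        else:
            frame = pd.DataFrame(np.asarray(counts, dtype=float))
            if row_labels is not None:
                frame.index = list(row_labels)
            if col_labels is not None:
                frame.columns = list(col_labels)
        return cls(observed=frame.astype(float))

    @property
    def row_totals(self) -> pd.Series:
        return self.observed.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.observed.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.observed.to_numpy().sum())

    @property
    def expected(self) -> pd.DataFrame:
        return expected_counts(self)


def expected_counts(table: ContingencyTable) -> pd.DataFrame:
    """Expected counts under independence: E_ij = R_i C_j / N."""
    r = table.row_totals.to_numpy()
    c = table.col_totals.to_numpy()
    expected = np.outer(r, c) / table.grand_total
    return pd.DataFrame(expected, index=table.observed.index, columns=table.observed.columns)


class GTestResult(NamedTuple):
    G: float
    df: int
    p_value: float


def g_test(
    table: ContingencyTable,
    williams: bool = False,
    yates: bool = False,
) -> GTestResult:
    """Likelihood-ratio test of independence for a two-way table.

    ``williams`` applies Williams' small-sample correction (G divided by q);
    ``yates`` applies the continuity correction (2×2 tables only).  Zero
    margins are rejected with advice to lump categories.
    """
    obs = table.observed.to_numpy(dtype=float)
    r = obs.sum(axis=1)
    c = obs.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        zero_rows = list(table.observed.index[r == 0])
        zero_cols = list(table.observed.columns[c == 0])
        raise ValueError(
            f"degenerate margin (zero rows {zero_rows}, zero columns {zero_cols}); "
            "lump rare categories before testing"
        )
    n = obs.sum()
    exp = np.outer(r, c) / n
    if yates:
        if obs.shape != (2, 2):
            raise ValueError("Yates correction applies to 2×2 tables only")
        obs = obs + 0.5 * np.sign(exp - obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    G = 2.0 * terms.sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if df == 0:
        raise ValueError("table must have at least two rows and two columns")
    if williams:
        q = 1.0 + (n * (1.0 / r).sum() - 1.0) * (n * (1.0 / c).sum() - 1.0) / (6.0 * n * df)
        G /= q
    return GTestResult(G=float(G), df=int(df), p_value=float(stats.chi2.sf(G, df)))


def lump_rare(
    counts: Mapping[str, float],
    keep: Iterable[str] | None = None,
    min_total: float | None = None,
    other_label: str = "other",
) -> dict[str, float]:
    """Collapse rare categories into one "other" bin, conserving the total.

    Either pass an explicit ``keep`` list, or a ``min_total`` threshold below
    which categories are lumped.  Kept categories retain their order.
    """
    if keep is None and min_total is None:
        raise ValueError("provide either keep or min_total")
    if keep is not None:
        keep_set = set(keep)
        unknown = keep_set - set(counts)
        if unknown:
            raise ValueError(f"keep list names unknown categories: {sorted(unknown)}")
    else:
        keep_set = {k for k, v in counts.items() if v >= min_total}
    out: dict[str, float] = {k: v for k, v in counts.items() if k in keep_set}
    other = sum(v for k, v in counts.items() if k not in keep_set)
    if other or len(out) < len(counts):
        out[other_label] = out.get(other_label, 0) + other
    return out


def subset_test(
    table: ContingencyTable,
    row_subset: Sequence[str] | None = None,
    col_subset: Sequence[str] | None = None,
    **kwargs,
) -> GTestResult:
    """G-test on a sub-table, with margins recomputed from the subset only."""
    rows = list(row_subset) if row_subset is not None else list(table.observed.index)
    cols = list(col_subset) if col_subset is not None else list(table.observed.columns)
    missing_r = set(rows) - set(table.observed.index)
    missing_c = set(cols) - set(table.observed.columns)
    if missing_r or missing_c:
        raise ValueError(
            f"subset labels not in table (rows {sorted(missing_r)}, "
            f"columns {sorted(missing_c)})"
        )
    sub = ContingencyTable(observed=table.observed.loc[rows, cols])
    return g_test(sub, **kwargs)
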