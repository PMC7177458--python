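"""Cross-tabulation of commuting status by PRD ranges.

Rows are active / non-active; columns are PRD bins with the convention
(a, b] except the first bin, which is closed at the minimum: [min, e1],
(e1, e2], ..., (ek, max].  Row percentages are kept at full precision
internally and rounded to one decimal only for display.  Independence is
tested with Pearson's chi-square (no continuity correction).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

__all__ = ["CrossTable", "DEFAULT_PRD_EDGES", "build_crosstab", "chi_square",
           "row_percentages", "bin_labels"]

#: interior bin edges; first/last bins run to the observed min/max.
DEFAULT_PRD_EDGES = (1.212, 1.30, 1.40, 1.50)


def bin_labels(edges: Sequence[float]) -> list[str]:
    e = list(edges)
    labels = [f"[Min.-{e[0]}]"]
    labels += [f"({a}-{b}]" for a, b in zip(e[:-1], e[1:])]
    labels.append(f"({e[-1]}-Max.]")
    return labels


@dataclass
class CrossTable:
    counts: pd.DataFrame        # rows: active, non_active; columns: bins
    row_totals: pd.Series
    row_pct: pd.DataFrame       # full precision
    chi2: float
    df: int
    p: float
    edges: tuple[float, ...]

    def display(self) -> pd.DataFrame:
        """One-decimal percentage strings next to counts, report layout."""
        out = self.counts.astype(object).copy()
        for r in out.index:
            for c in out.columns:
                out.loc[r, c] = f"{self.counts.loc[r, c]} ({self.row_pct.loc[r, c]:.1f}%)"
        out.insert(0, "All", [f"{int(t)} (100%)" for t in self.row_totals])
        return out

    def to_dict(self) -> dict:
        return {
            "edges": list(self.edges),
            "counts": {r: self.counts.loc[r].tolist() for r in self.counts.index},
            "row_pct": {r: [round(v, 1) for v in self.row_pct.loc[r]]
                        for r in self.row_pct.index},
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
        }


def row_percentages(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Row percentages (count / row total x 100), full precision."""
    c = pd.DataFrame(counts).astype(float)
    totals = c.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("zero row total")
    return c.div(totals, axis=0) * 100.0


def chi_square(counts: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence from a contingency table.

    Returns (statistic, degrees of freedom, p).  No Yates correction.
    """
    c = np.asarray(counts, dtype=float)
    if c.sum(axis=0).min() <= 0 or c.sum(axis=1).min() <= 0:
        raise ValueError("zero margin in contingency table")
    stat, p, dof, _ = sps.chi2_contingency(c, correction=False)
    return float(stat), int(dof), float(p)


def build_crosstab(records: pd.DataFrame,
                   edges: Sequence[float] = DEFAULT_PRD_EDGES) -> CrossTable:
    """Cross-tabulate dichotomous commuting status by PRD ranges.

    ``records`` needs columns ``prd`` and ``acs_binary``.  ``edges`` are the
    strictly increasing interior cut points; a PRD exactly at an edge falls
    in the bin to its left (right-closed intervals).
    """
    df = records.dropna(subset=["prd", "acs_binary"])
    if df.empty:
        raise ValueError("no records to tabulate")
    e = [float(x) for x in edges]
    if any(b <= a for a, b in zip(e[:-1], e[1:])):
        raise ValueError("edges must be strictly increasing")
    bins = [-np.inf] + e + [np.inf]
    labels = bin_labels(e)
    cat = pd.cut(df["prd"].astype(float), bins=bins, right=True, labels=labels)
    status = np.where(df["acs_binary"].astype(int) == 1, "active", "non_active")
    counts = (pd.crosstab(pd.Series(status, index=df.index, name="status"), cat)
              .reindex(index=["active", "non_active"], columns=labels,
                       fill_value=0))
    # the test of independence only uses occupied rows/columns; a table
    # collapsing to a single occupied row or column has no df left
    occ = counts.loc[counts.sum(axis=1) > 0, counts.columns[counts.sum(axis=0) > 0]]
    if occ.shape[0] >= 2 and occ.shape[1] >= 2:
        stat, dof, p = chi_square(occ)
    else:
        stat, dof, p = math.nan, 0, math.nan
    return CrossTable(
        counts=counts,
        row_totals=counts.sum(axis=1),
        row_pct=row_percentages(counts),
        chi2=stat, df=dof, p=p,
        edges=tuple(e),
    )
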