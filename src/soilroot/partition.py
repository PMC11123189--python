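"""Abundance sub-community partition: abundant / moderate / rare taxa.

OTUs are classified per group (compartment x variety) by mean relative
abundance: abundant taxa (AT) above 1% of total sequences, rare taxa (RT)
below 0.01%, moderate taxa (MT) in between (boundary values inclusive to
MT, since the defining thresholds are strict "above"/"below"). Moderate
plus rare form the "low abundance taxa" view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_tables import RelAbundanceMatrix, SampleMetadata, ValidationError

ABUNDANT_THRESHOLD = 0.01    # proportion; >1% of total sequences
RARE_THRESHOLD = 0.0001      # proportion; <0.01% of total sequences

CLASS_ROWS = {"abundant": "AT OTUs", "moderate": "MT OTUs", "rare": "RT OTUs"}


@dataclass
class PartitionResult:
    """Per-OTU abundance class and Table-style summary for one group."""

    group: str
    classes: pd.Series          # otu_id -> {abundant, moderate, rare, absent}
    mean_abundance: pd.Series   # otu_id -> group-mean relative abundance
    summary: pd.DataFrame       # index class; columns [count, cum_abund_pct]

    @property
    def low_abundance_otus(self) -> pd.Index:
        """Moderate plus rare taxa ("low abundance taxa")."""
        return self.classes.index[self.classes.isin(["moderate", "rare"])]


def _classify(mean_abund: np.ndarray, abundant: float, rare: float) -> np.ndarray:
    cls = np.full(mean_abund.shape, "moderate", dtype=object)
    cls[mean_abund > abundant] = "abundant"
    cls[(mean_abund > 0) & (mean_abund < rare)] = "rare"
    cls[mean_abund == 0] = "absent"
    return cls


def classify_abundance(
    ra: RelAbundanceMatrix,
    md: SampleMetadata,
    abundant_threshold: float = ABUNDANT_THRESHOLD,
    rare_threshold: float = RARE_THRESHOLD,
    basis: str = "group_mean",
    collapse_bulk: bool = True,
    counts=None,
) -> dict[str, PartitionResult]:
    """Partition OTUs into abundance classes within each group.

    ``basis='group_mean'`` averages per-sample proportions (removes depth
    bias between replicates); ``basis='pooled'`` pools raw reads across the
    group's samples before normalizing and requires ``counts`` (the source
    CountMatrix). The two coincide when all depths are equal.
    """
    if rare_threshold >= abundant_threshold:
        raise ValidationError("rare threshold must be below abundant threshold")
    if basis not in {"group_mean", "pooled"}:
        raise ValueError(f"unknown basis {basis!r}")
    if basis == "pooled" and counts is None:
        raise ValueError("basis='pooled' requires the counts table")
    out: dict[str, PartitionResult] = {}
    for group, members in md.groups(collapse_bulk=collapse_bulk).items():
        if not members:
            raise ValidationError(f"group {group!r} has no samples")
        sub = ra.data.loc[members]
        if basis == "group_mean":
            mean_ab = sub.mean(axis=0)
        else:
            pooled = counts.data.loc[members].sum(axis=0)
            mean_ab = pooled / pooled.sum()
        cls = pd.Series(
            _classify(mean_ab.to_numpy(), abundant_threshold, rare_threshold),
            index=mean_ab.index,
        )
        rows = []
        for klass in ("abundant", "moderate", "rare"):
            mask = cls == klass
            rows.append(
                {
                    "class": klass,
                    "count": int(mask.sum()),
                    "cum_abund_pct": float(mean_ab[mask].sum() / mean_ab.sum() * 100.0),
                }
            )
        summary = pd.DataFrame(rows).set_index("class")
        out[group] = PartitionResult(group, cls, mean_ab, summary)
    return out


@dataclass
class PartitionSummary:
    """Cross-group summary of sub-community counts and cumulative abundances.

    ``table`` is indexed by (group, class) with columns ``count`` and
    ``cum_abund_pct``; totals are stored under class ``total``.
    """

    table: pd.DataFrame

    @classmethod
    def from_cells(cls, cells: Mapping[tuple[str, str], tuple[float, float]]) -> "PartitionSummary":
        """Build directly from (count, cumulative %) cells, e.g. a printed table."""
        idx = pd.MultiIndex.from_tuples(cells.keys(), names=["group", "class"])
        df = pd.DataFrame(list(cells.values()), index=idx, columns=["count", "cum_abund_pct"])
        return cls(df)

    def ratio(
        self,
        group_a: str,
        group_b: str,
        klass: str,
        metric: str = "count",
        ndigits: int | None = None,
        mode: str = "round",
    ) -> float:
        """Fold change of a class metric between two groups (a / b).

        ``ndigits`` optionally formats to a fixed number of decimals, with
        ``mode`` 'round' (half-even) or 'truncate' (toward zero); by default
        the full-precision ratio is returned.
        """
        if metric not in {"count", "cum_abund_pct"}:
            raise ValueError(f"unknown metric {metric!r}")
        for g in (group_a, group_b):
            if g not in self.table.index.get_level_values("group"):
                raise KeyError(f"unknown group {g!r}")
        col = "count" if metric == "count" else "cum_abund_pct"
        value = float(self.table.loc[(group_a, klass), col]) / float(
            self.table.loc[(group_b, klass), col]
        )
        if ndigits is None:
            return value
        if mode == "truncate":
            scale = 10 ** ndigits
            return math.trunc(value * scale) / scale
        if mode == "round":
            return round(value, ndigits)
        raise ValueError(f"unknown mode {mode!r}")

    def formatted(self, ndigits: int = 2) -> pd.DataFrame:
        """Table-style layout: rows Total/AT/MT/RT OTUs, columns groups, cells "N (X%)"."""
        groups = list(dict.fromkeys(self.table.index.get_level_values("group")))
        rows: dict[str, dict[str, str]] = {"Total OTUs": {}}
        for klass, label in CLASS_ROWS.items():
            rows[label] = {}
        for g in groups:
            sub = self.table.loc[g]
            present = sub.loc[[k for k in CLASS_ROWS if k in sub.index]]
            rows["Total OTUs"][g] = str(int(present["count"].sum()))
            for klass, label in CLASS_ROWS.items():
                if klass in sub.index:
                    c = int(sub.loc[klass, "count"])
                    pct = sub.loc[klass, "cum_abund_pct"]
                    rows[label][g] = f"{c} ({pct:.{ndigits}f}%)"
        return pd.DataFrame(rows).T[groups]


def partition_summary(parts: Mapping[str, PartitionResult]) -> PartitionSummary:
    """Assemble per-group partition results into one cross-group summary."""
    if not parts:
        raise ValidationError("no groups")
    cells: dict[tuple[str, str], tuple[float, float]] = {}
    for group, pr in parts.items():
        for klass in ("abundant", "moderate", "rare"):
            cells[(group, klass)] = (
                float(pr.summary.loc[klass, "count"]),
                float(pr.summary.loc[klass, "cum_abund_pct"]),
            )
    return PartitionSummary.from_cells(cells)
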