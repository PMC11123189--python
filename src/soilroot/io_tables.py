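"""OTU count tables, sample metadata and taxonomy: containers and TSV/BIOM I/O.

The in-memory orientation is samples x OTUs; TSV files follow the common
QIIME export convention of OTUs as rows and samples as columns, so tables
are transposed on load and on write.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPARTMENTS = ("bulk_soil", "rhizosphere", "endosphere")

RANK_ORDER = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: QIIME-style lineage prefixes, stripped on taxonomy load.
_QIIME_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "d__")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class SampleMetadata:
    """Per-sample design information: compartment niche, host variety, replicate."""

    table: pd.DataFrame  # index = sample_id; columns compartment, variety, replicate

    def __post_init__(self) -> None:
        required = {"compartment", "variety", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        bad = set(self.table["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValidationError(
                f"unknown compartments {sorted(bad)}; expected one of {COMPARTMENTS}"
            )
        if (self.table["variety"].astype(str).str.len() == 0).any():
            raise ValidationError("empty variety label")
        key = self.table[["compartment", "variety", "replicate"]]
        if key.duplicated().any():
            raise ValidationError("(compartment, variety, replicate) must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def group_label(self, sample_id: str, collapse_bulk: bool = False) -> str:
        """`compartment:variety` label; bulk soil may collapse varieties."""
        row = self.table.loc[sample_id]
        if collapse_bulk and row["compartment"] == "bulk_soil":
            return "bulk_soil"
        return f"{row['compartment']}:{row['variety']}"

    def groups(self, collapse_bulk: bool = False) -> dict[str, list[str]]:
        """Map group label -> ordered member sample ids."""
        out: dict[str, list[str]] = {}
        for sid in self.table.index:
            out.setdefault(self.group_label(sid, collapse_bulk), []).append(sid)
        return out


@dataclass
class CountMatrix:
    """Integer read counts, samples x OTUs."""

    data: pd.DataFrame  # index = sample_id, columns = otu_id, integer dtype

    def __post_init__(self) -> None:
        if self.data.shape[1] == 0:
            raise ValidationError("no OTUs")
        if self.data.shape[0] == 0:
            raise ValidationError("no samples")
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate OTU ids")
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
            self.data = self.data.round().astype(np.int64)
            arr = self.data.to_numpy()
        if (arr < 0).any():
            s, o = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.data.index[s]!r}, OTU {self.data.columns[o]!r}"
            )
        self.data.index.name = "sample_id"
        self.data.columns.name = "otu_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def depths(self) -> pd.Series:
        """Reads per sample (row sums)."""
        return self.data.sum(axis=1)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.data.loc[list(sample_ids)].copy())


@dataclass
class RelAbundanceMatrix:
    """Per-sample proportions, same shape as the source CountMatrix; rows sum to 1."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-9)].index.tolist()
            raise ValidationError(f"rows do not sum to 1: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "RelAbundanceMatrix":
        return RelAbundanceMatrix(self.data.loc[list(sample_ids)].copy())


@dataclass
class Taxonomy:
    """OTU -> lineage map (rank name -> taxon), missing ranks allowed."""

    lineages: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # dict keys are unique by construction; validate rank names only
        for otu, ranks in self.lineages.items():
            unknown = set(ranks) - set(RANK_ORDER)
            if unknown:
                raise ValidationError(f"unknown ranks {sorted(unknown)} for OTU {otu!r}")

    def taxon(self, otu_id: str, rank: str) -> str | None:
        return self.lineages.get(otu_id, {}).get(rank)


def read_count_table(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Load an OTU count table.

    TSV dialect: first column OTU id (a leading ``#OTU ID`` header is
    tolerated), remaining columns samples; transposed to samples x OTUs.
    ``biom_json`` reads the BIOM 1.0 JSON layout (dense or sparse).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        df.index.name = "otu_id"
        if df.shape[0] == 0:
            raise ValidationError("no OTUs")
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna()][0]
                raise ValidationError(f"non-numeric cell at OTU {row!r}, sample {col!r}")
            df[col] = coerced
        return CountMatrix(df.T)
    if format == "biom_json":
        with open(path) as fh:
            doc = json.load(fh)
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(otu_ids), len(sample_ids)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        else:
            mat[:] = np.asarray(doc["data"], dtype=float)
        df = pd.DataFrame(mat, index=otu_ids, columns=sample_ids)
        return CountMatrix(df.T)
    raise ValueError(f"unknown format {format!r}")


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    """Write TSV with OTUs as rows (inverse of :func:`read_count_table`)."""
    cm.data.T.rename_axis(index="#OTU ID", columns=None).to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "variety": str})
    if "sample_id" not in df.columns:
        raise ValidationError("metadata must have a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(md: SampleMetadata, path: str | Path) -> None:
    md.table.rename_axis("sample_id").to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> Taxonomy:
    """Taxonomy TSV: otu_id <tab> semicolon-delimited lineage.

    QIIME-style `g__` prefixes are stripped; empty fields become missing ranks.
    Lineage fields are assigned kingdom..species in order.
    """
    lineages: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            otu_id, _, lineage = line.partition("\t")
            if otu_id in lineages:
                raise ValidationError(f"duplicate OTU {otu_id!r} in taxonomy")
            ranks: dict[str, str] = {}
            for level, name in zip(RANK_ORDER, lineage.split(";")):
                name = name.strip()
                for pref in _QIIME_PREFIXES:
                    if name.startswith(pref):
                        name = name[len(pref):]
                        break
                if name:
                    ranks[level] = name
            lineages[otu_id] = ranks
    return Taxonomy(lineages)


def relative_abundance(cm: CountMatrix) -> RelAbundanceMatrix:
    """Per-sample proportions: counts(s, o) / depth(s)."""
    depths = cm.depths
    zero = depths[depths == 0].index.tolist()
    if zero:
        raise ValidationError(f"zero-depth samples cannot be normalized: {zero}")
    return RelAbundanceMatrix(cm.data.div(depths, axis=0))


def aggregate_by_rank(cm: CountMatrix, tax: Taxonomy, rank: str) -> CountMatrix:
    """Sum OTU counts into taxa at a rank; unannotated OTUs pool to "unclassified".

    Total reads per sample are conserved.
    """
    if rank not in RANK_ORDER:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANK_ORDER}")
    labels = []
    n_missing = 0
    for otu in cm.otu_ids:
        taxon = tax.taxon(otu, rank)
        if taxon is None:
            n_missing += 1
            taxon = "unclassified"
        labels.append(taxon)
    if n_missing:
        logger.warning("%d OTUs without %s annotation pooled to 'unclassified'", n_missing, rank)
    agg = cm.data.T.groupby(pd.Index(labels, name=rank), sort=False).sum().T
    return CountMatrix(agg)
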