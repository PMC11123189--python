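"""OTU flow classification between compartments along the soil-root continuum.

Each OTU's transition from an upstream (source) to a downstream (target)
compartment is classed as:

* ``emerging``  — absent from every source sample, present downstream;
* ``filtered``  — present upstream, absent from every target sample;
* ``enriched``  — significantly higher downstream (adjusted p < alpha,
  positive log2 fold change);
* ``depleted``  — significantly lower downstream;
* ``unchanged`` — everything else present in either compartment.

Significance is a two-sided Wilcoxon rank-sum test on per-sample relative
abundances with Benjamini-Hochberg adjustment across tested OTUs; a Welch
t-test on log-transformed abundances is available as an alternative.
The fold-change pseudo-abundance epsilon is half the smallest nonzero
relative abundance in the union of both groups (scale-aware and
deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import RelAbundanceMatrix, SampleMetadata, ValidationError

FLOW_CLASSES = ("enriched", "depleted", "emerging", "filtered", "unchanged")


@dataclass
class FlowResult:
    """Per-OTU transition table for one source -> target comparison."""

    source: str
    target: str
    alpha: float
    table: pd.DataFrame  # index otu_id; mean_source, mean_target, log2fc, pvalue, qvalue, class

    def counts(self) -> pd.Series:
        """Number of OTUs per flow class."""
        return self.table["class"].value_counts().reindex(FLOW_CLASSES, fill_value=0)


def resolve_group(md: SampleMetadata, label: str) -> list[str]:
    """Sample ids for a group label: 'compartment:variety' or a bare compartment."""
    if ":" in label:
        comp, variety = label.split(":", 1)
        mask = (md.table["compartment"] == comp) & (md.table["variety"] == variety)
    else:
        mask = md.table["compartment"] == label
    members = list(md.table.index[mask])
    if not members:
        raise ValidationError(f"no samples match group {label!r}")
    return members


def classify_flow(
    ra: RelAbundanceMatrix,
    md: SampleMetadata,
    source: str,
    target: str,
    alpha: float = 0.05,
    method: str = "wilcoxon",
    adjust: str = "bh",
) -> FlowResult:
    """Classify every OTU's source -> target transition."""
    if method not in {"wilcoxon", "welch_log"}:
        raise ValueError(f"unknown method {method!r}")
    if adjust not in {"bh", "none"}:
        raise ValueError(f"unknown adjustment {adjust!r}")
    src_ids = resolve_group(md, source)
    tgt_ids = resolve_group(md, target)
    X = ra.data.loc[src_ids].to_numpy()
    Y = ra.data.loc[tgt_ids].to_numpy()
    otus = np.asarray(ra.otu_ids)

    present_src = (X > 0).any(axis=0)
    present_tgt = (Y > 0).any(axis=0)
    keep = present_src | present_tgt
    X, Y, otus = X[:, keep], Y[:, keep], otus[keep]
    present_src, present_tgt = present_src[keep], present_tgt[keep]

    emerging = ~present_src & present_tgt
    filtered = present_src & ~present_tgt
    testable = present_src & present_tgt

    if testable.any() and (len(src_ids) < 2 or len(tgt_ids) < 2):
        raise ValidationError(
            "both groups need >= 2 samples for abundance testing; "
            "use presence/absence (emerging/filtered) classification only"
        )

    mean_src = X.mean(axis=0)
    mean_tgt = Y.mean(axis=0)
    nonzero = np.concatenate([X[X > 0].ravel(), Y[Y > 0].ravel()])
    eps = 0.5 * nonzero.min() if nonzero.size else 0.0
    log2fc = np.log2((mean_tgt + eps) / (mean_src + eps))

    pvals = np.full(otus.shape, np.nan)
    for j in np.flatnonzero(testable):
        x, y = X[:, j], Y[:, j]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            pvals[j] = 1.0
            continue
        if method == "wilcoxon":
            pvals[j] = stats.mannwhitneyu(y, x, alternative="two-sided").pvalue
        else:
            pvals[j] = stats.ttest_ind(
                np.log(y + eps), np.log(x + eps), equal_var=False
            ).pvalue

    qvals = np.full(otus.shape, np.nan)
    tested = np.isfinite(pvals)
    if tested.any():
        if adjust == "bh":
            qvals[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
        else:
            qvals[tested] = pvals[tested]

    cls = np.full(otus.shape, "unchanged", dtype=object)
    sig = tested & (qvals < alpha)
    cls[sig & (log2fc > 0)] = "enriched"
    cls[sig & (log2fc < 0)] = "depleted"
    cls[emerging] = "emerging"
    cls[filtered] = "filtered"

    table = pd.DataFrame(
        {
            "mean_source": mean_src,
            "mean_target": mean_tgt,
            "log2fc": log2fc,
            "pvalue": pvals,
            "qvalue": qvals,
            "class": cls,
        },
        index=pd.Index(otus, name="otu_id"),
    )
    return FlowResult(source, target, alpha, table)


def volcano_table(fr: FlowResult) -> pd.DataFrame:
    """Volcano-plot table: log2fc vs -log10 adjusted p, one row per OTU.

    Emerging and filtered OTUs carry an ``infinite_fc`` sentinel instead of
    a numeric fold change (their ratio is unbounded by construction).
    """
    t = fr.table
    infinite = t["class"].isin(["emerging", "filtered"])
    with np.errstate(divide="ignore"):
        neglog_q = -np.log10(t["qvalue"])
    out = pd.DataFrame(
        {
            "log2fc": t["log2fc"].where(~infinite),
            "neglog10_q": neglog_q,
            "class": t["class"],
            "infinite_fc": infinite,
        },
        index=t.index,
    )
    return out
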