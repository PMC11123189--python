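"""Synthetic OTU-table generators with the statistical structure of a
soil-root continuum study.

Three generators:

* a lognormal metacommunity (the skewed species-abundance distribution in
  which a few abundant taxa dominate),
* a compartment gradient (bulk soil -> rhizosphere -> endosphere) with
  controlled enrichment, depletion, emergence and host filtering, sampled
  multinomially at a configurable read depth, with truth labels returned
  for every OTU and transition,
* an individual-based neutral local-community assembly at migration rate
  ``m``, the forward model that the Sloan neutral-model fitter must invert.

All randomness flows from explicit integer seeds; no global state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import CountMatrix, SampleMetadata, ValidationError


@dataclass
class MetacommunityConfig:
    """Lognormal species-abundance distribution for the source pool.

    ``sigma`` controls skew: at sigma >= 2 the top 1% of OTUs jointly carry
    well over 30% of the community, matching the dominance structure of
    field soil communities.
    """

    n_otus: int = 2000
    mu: float = 0.0
    sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 2:
            raise ValidationError("n_otus must be >= 2")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")


@dataclass
class GradientConfig:
    """Effect structure of the bulk soil -> rhizosphere -> endosphere gradient.

    Fractions are proportions of the OTU pool; fold changes are log2.
    Defaults mirror a root-selection regime where enrichment dominates the
    rhizosphere transition, emergence recruits tail taxa, and the host
    filters out more than half of the rhizosphere OTUs at the root surface.
    """

    enrich_frac: float = 0.25
    deplete_frac: float = 0.05
    emerge_frac: float = 0.15
    enrich_log2fc: float = 2.0
    deplete_log2fc: float = -2.0
    host_filter_frac: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("enrich_frac", "deplete_frac", "emerge_frac", "host_filter_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.enrich_log2fc <= 0:
            raise ValidationError("enrich_log2fc must be > 0")
        if self.deplete_log2fc >= 0:
            raise ValidationError("deplete_log2fc must be < 0")
        if self.enrich_frac + self.deplete_frac + self.emerge_frac > 1.0:
            raise ValidationError("effect fractions overlap: sum exceeds 1")


@dataclass
class NeutralAssemblyConfig:
    """Zero-sum neutral assembly of M local communities of N individuals."""

    m: float = 0.1
    N: int = 1000
    M: int = 50
    n_generations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.m <= 1.0:
            raise ValidationError("m must be in (0, 1]")
        if self.N < 10:
            raise ValidationError("N must be >= 10")
        if self.M < 5:
            raise ValidationError("M must be >= 5")
        if self.n_generations < 1:
            raise ValidationError("n_generations must be >= 1")


def _otu_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"OTU_{i + 1:0{width}d}" for i in range(n)]


def simulate_metacommunity(cfg: MetacommunityConfig) -> pd.Series:
    """Draw a lognormal metacommunity; returns proportions summing to 1."""
    rng = np.random.default_rng(cfg.seed)
    raw = rng.lognormal(mean=cfg.mu, sigma=cfg.sigma, size=cfg.n_otus)
    props = raw / raw.sum()
    return pd.Series(props, index=_otu_ids(cfg.n_otus), name="metacommunity")


@dataclass
class GradientTruth:
    """Per-OTU truth for each compartment transition.

    ``table`` carries the construction labels plus the *realized* expected
    log2 fold change computed from the final (renormalized) compartment
    probability vectors: renormalization couples every OTU compositionally,
    so an OTU untouched by the effect sets still shifts by -log2 of the
    normalizing constant. ``profiles`` holds the expected per-compartment
    proportions the samples were drawn from.
    """

    table: pd.DataFrame  # index otu_id; labels + realized log2fc per transition
    profiles: pd.DataFrame  # index otu_id; columns bulk_soil, rhizosphere, endosphere

    def labelled(self, transition: str, label: str) -> pd.Index:
        return self.table.index[self.table[transition] == label]


def simulate_compartment_gradient(
    meta: pd.Series,
    g: GradientConfig,
    depth: int = 50_000,
    n_reps: int = 6,
    varieties: Sequence[str] = ("XLZ61", "XLZ62"),
) -> tuple[CountMatrix, SampleMetadata, GradientTruth]:
    """Sample a full compartment x variety design from a metacommunity.

    Bulk-soil samples are multinomial draws from ``meta`` (with the emerging
    OTUs removed, since those exist only at the root). Rhizosphere samples
    apply the enrichment/depletion fold changes and add the emerging OTUs,
    drawn from the lower half of the abundance ranks (emerging taxa recruit
    as moderate and rare, not abundant). Endosphere samples zero a random
    ``host_filter_frac`` of the rhizosphere-present OTUs and renormalize.
    The same effect sets apply to every variety; sampling noise is
    independent per sample.
    """
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if g.host_filter_frac >= 1.0:
        raise ValidationError("host_filter_frac = 1 leaves the endosphere empty")
    meta = meta / meta.sum()
    n = len(meta)
    rng = np.random.default_rng(g.seed)

    n_emerge = int(round(g.emerge_frac * n))
    n_enrich = int(round(g.enrich_frac * n))
    n_deplete = int(round(g.deplete_frac * n))
    # emerging taxa come from the SAD tail: lower half of abundance ranks
    order = np.argsort(meta.to_numpy())  # ascending abundance
    tail = order[: n // 2]
    emerge_idx = rng.choice(tail, size=min(n_emerge, len(tail)), replace=False)
    remaining = np.setdiff1d(np.arange(n), emerge_idx)
    effect_idx = rng.choice(remaining, size=n_enrich + n_deplete, replace=False)
    enrich_idx = effect_idx[:n_enrich]
    deplete_idx = effect_idx[n_enrich:]

    base = meta.to_numpy().copy()

    bulk = base.copy()
    bulk[emerge_idx] = 0.0
    bulk /= bulk.sum()

    rhizo = base.copy()
    rhizo[enrich_idx] *= 2.0 ** g.enrich_log2fc
    rhizo[deplete_idx] *= 2.0 ** g.deplete_log2fc
    rhizo /= rhizo.sum()

    present_rs = np.flatnonzero(rhizo > 0)
    n_filter = int(round(g.host_filter_frac * len(present_rs)))
    filter_idx = rng.choice(present_rs, size=n_filter, replace=False)
    endo = rhizo.copy()
    endo[filter_idx] = 0.0
    total = endo.sum()
    if total <= 0:
        raise ValidationError("endosphere would be empty")
    endo /= total

    labels_bs_rs = np.full(n, "neutral", dtype=object)
    labels_bs_rs[enrich_idx] = "enriched"
    labels_bs_rs[deplete_idx] = "depleted"
    labels_bs_rs[emerge_idx] = "emerging"
    labels_rs_es = np.full(n, "neutral", dtype=object)
    labels_rs_es[filter_idx] = "filtered"
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc_bs_rs = np.log2(np.where(bulk > 0, rhizo / np.where(bulk > 0, bulk, 1), np.nan))
        lfc_rs_es = np.log2(np.where(rhizo > 0, endo / np.where(rhizo > 0, rhizo, 1), np.nan))
    truth = GradientTruth(
        pd.DataFrame(
            {
                "bulk_to_rhizosphere": labels_bs_rs,
                "rhizosphere_to_endosphere": labels_rs_es,
                "log2fc_bulk_to_rhizosphere": lfc_bs_rs,
                "log2fc_rhizosphere_to_endosphere": lfc_rs_es,
            },
            index=meta.index,
        ),
        pd.DataFrame(
            {"bulk_soil": bulk, "rhizosphere": rhizo, "endosphere": endo},
            index=meta.index,
        ),
    )

    profiles = {"bulk_soil": bulk, "rhizosphere": rhizo, "endosphere": endo}
    rows, sample_ids, meta_rows = [], [], []
    for variety in varieties:
        for comp, prof in profiles.items():
            for rep in range(1, n_reps + 1):
                rows.append(rng.multinomial(depth, prof))
                sample_ids.append(f"{comp[:2].upper()}_{variety}_r{rep}")
                meta_rows.append(
                    {"sample_id": sample_ids[-1], "compartment": comp, "variety": variety, "replicate": rep}
                )
    cm = CountMatrix(pd.DataFrame(np.asarray(rows), index=sample_ids, columns=meta.index))
    md = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return cm, md, truth


def simulate_neutral_assembly(cfg: NeutralAssemblyConfig, meta: pd.Series) -> CountMatrix:
    """Individual-based zero-sum neutral assembly (Hubbell-type).

    Each generation sweeps every slot of every community in random order:
    the resident dies and is replaced, with probability ``m`` by an
    immigrant drawn from the metacommunity and otherwise by the offspring
    of a random current resident. Updates are applied immediately, so
    within-sweep drift matches the sequential (Moran-type) process whose
    stationary relative-abundance law is the Beta(N*m*p, N*m*(1-p))
    distribution underlying the neutral-model fit. At ``m = 1`` one full
    generation reduces to a pure multinomial draw from the metacommunity.
    """
    meta = (meta / meta.sum()).to_numpy() if isinstance(meta, pd.Series) else np.asarray(meta)
    otu_index = _otu_ids(len(meta))
    rng = np.random.default_rng(cfg.seed)
    S, N, M = len(meta), cfg.N, cfg.M
    cum = np.cumsum(meta)
    cum[-1] = 1.0

    def draw_meta(size: int) -> np.ndarray:
        return np.searchsorted(cum, rng.random(size), side="right")

    # labels[c, slot] = OTU index of the individual in that slot
    labels = draw_meta(M * N).reshape(M, N)
    rows = np.arange(M)
    for _ in range(cfg.n_generations):
        orders = np.argsort(rng.random((M, N)), axis=1)  # per-community sweep order
        coins = rng.random((M, N)) < cfg.m
        migrants = draw_meta(M * N).reshape(M, N)
        copy_from = rng.integers(0, N, size=(M, N))
        for t in range(N):
            tgt = orders[:, t]
            local = labels[rows, copy_from[:, t]]
            labels[rows, tgt] = np.where(coins[:, t], migrants[:, t], local)

    counts = np.zeros((M, S), dtype=np.int64)
    for c in range(M):
        counts[c] = np.bincount(labels[c], minlength=S)
    sample_ids = [f"community_{c + 1:03d}" for c in range(M)]
    return CountMatrix(pd.DataFrame(counts, index=sample_ids, columns=otu_index))
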