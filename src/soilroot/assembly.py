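"""Community-assembly statistics: Sloan neutral community model and Levins'
niche breadth.

The neutral community model (NCM) predicts the occupancy frequency of a
taxon — the fraction of local communities in which it is detected — from
its mean relative abundance in the metacommunity, with the migration rate
``m`` as the only free parameter. Under Sloan's beta approximation the
local relative abundance of a taxon with metacommunity abundance ``p`` is
Beta(N*m*p, N*m*(1-p)) distributed, so the expected occupancy above a
detection limit ``d`` is

    F(p) = 1 - I_d(N*m*p, N*m*(1-p))

where I is the regularized incomplete beta function. A high R-squared of
the fitted curve indicates assembly dominated by stochastic dispersal and
drift; Nm = N*m summarizes metacommunity size times immigration.

Levins' niche breadth B_j = 1 / sum_i P_ij^2, with P_ij the proportion of
taxon j's abundance found at site i, ranges from 1 (specialist, single
site) to the number of sites (perfectly even generalist).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io_tables import CountMatrix, RelAbundanceMatrix, ValidationError


def predict_ncm_frequency(p, m: float, N: float, d: float):
    """Expected occupancy frequency F(p) = 1 - I_d(N m p, N m (1-p)).

    ``p`` may be a scalar or array of metacommunity proportions in (0, 1).
    """
    p_arr = np.asarray(p, dtype=float)
    if not 0 < m <= 1:
        raise ValidationError("m must be in (0, 1]")
    if N < 1:
        raise ValidationError("N must be >= 1")
    if not 0 < d < 1:
        raise ValidationError("detection limit d must be in (0, 1)")
    if np.any(p_arr <= 0) or np.any(p_arr >= 1):
        raise ValidationError("p must be in (0, 1)")
    out = 1.0 - special.betainc(N * m * p_arr, N * m * (1.0 - p_arr), d)
    return float(out) if np.isscalar(p) else out


def _wilson_interval(f: np.ndarray, trials: int, conf: float = 0.95):
    """Wilson score interval for a binomial proportion."""
    z = stats.norm.ppf(0.5 + conf / 2.0)
    denom = 1.0 + z * z / trials
    centre = (f + z * z / (2.0 * trials)) / denom
    half = z * np.sqrt(f * (1.0 - f) / trials + z * z / (4.0 * trials * trials)) / denom
    return np.clip(centre - half, 0.0, 1.0), np.clip(centre + half, 0.0, 1.0)


@dataclass
class NCMFit:
    """Fitted neutral-model parameters and per-OTU occupancy partition."""

    m: float
    N: float
    Nm: float
    r_squared: float
    d: float
    n_communities: int
    table: pd.DataFrame  # per OTU: p, f, predicted, ci_low, ci_high, partition

    def partition_counts(self) -> pd.Series:
        return self.table["partition"].value_counts().reindex(
            ["above", "within", "below"], fill_value=0
        )


def fit_ncm(
    cm: CountMatrix,
    N: float | None = None,
    d: float | None = None,
    conf: float = 0.95,
) -> NCMFit:
    """Fit the Sloan neutral model to one group's count table.

    Each sample is treated as a local community. The metacommunity
    abundance of each OTU is its mean relative abundance across samples;
    its occupancy frequency is the fraction of samples where it is
    detected. ``m`` is estimated by bounded least squares on
    sum (f_i - F(p_i))^2; ``N`` defaults to the mean sample depth and the
    detection limit ``d`` to 1/(2N) — the continuity-corrected boundary
    between zero and one individual, which removes the systematic bias the
    uncorrected d = 1/N threshold induces when inverting count occupancies
    (detection means n >= 1, i.e. x above the midpoint 0.5/N, not 1/N).
    The 95% band is the Wilson score
    interval around F(p) with one trial per community, and each OTU is
    partitioned as above / within / below that band.
    """
    M = len(cm.sample_ids)
    if M < 5:
        raise ValidationError("need >= 5 local communities (samples)")
    depths = cm.depths.to_numpy()
    if (depths <= 0).any():
        raise ValidationError("zero-depth sample")
    if N is None:
        N = float(depths.mean())
    if d is None:
        d = 0.5 / N
    props = cm.data.to_numpy() / depths[:, None]
    p = props.mean(axis=0)
    f = (cm.data.to_numpy() > 0).mean(axis=0)
    keep = p > 0
    p, f = p[keep], f[keep]
    otus = np.asarray(cm.otu_ids)[keep]
    # the beta parameters need p strictly inside (0, 1)
    p = np.clip(p, 1e-12, 1 - 1e-12)

    sst = float(((f - f.mean()) ** 2).sum())
    if sst == 0:
        raise ValidationError("no occupancy variation: every OTU has identical frequency")

    def ssr(m: float) -> float:
        pred = 1.0 - special.betainc(N * m * p, N * m * (1.0 - p), d)
        return float(((f - pred) ** 2).sum())

    res = optimize.minimize_scalar(ssr, bounds=(1e-6, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"NCM fit did not converge: {res.message}")
    m_hat = float(res.x)
    pred = 1.0 - special.betainc(N * m_hat * p, N * m_hat * (1.0 - p), d)
    r2 = 1.0 - ssr(m_hat) / sst
    lo, hi = _wilson_interval(pred, M, conf)
    part = np.full(p.shape, "within", dtype=object)
    part[f > hi] = "above"
    part[f < lo] = "below"
    table = pd.DataFrame(
        {"p": p, "f": f, "predicted": pred, "ci_low": lo, "ci_high": hi, "partition": part},
        index=pd.Index(otus, name="otu_id"),
    ).sort_values("p")
    return NCMFit(m_hat, N, N * m_hat, float(r2), d, M, table)


def niche_breadth(ra: RelAbundanceMatrix, sites: pd.Series | None = None) -> pd.Series:
    """Levins' niche breadth B_j = 1 / sum_i P_ij^2 per OTU.

    Sites default to individual samples; passing ``sites`` (sample -> site
    label) first averages relative abundances within each site (e.g. one
    site per compartment group mean). P_ij is taxon j's abundance at site i
    divided by its total across sites. OTUs absent everywhere are excluded
    with a warning.
    """
    data = ra.data
    if sites is not None:
        data = data.groupby(sites.loc[data.index]).mean()
    if data.shape[0] < 2:
        raise ValidationError("need >= 2 sites")
    totals = data.sum(axis=0)
    absent = totals == 0
    if absent.any():
        warnings.warn(f"{int(absent.sum())} OTUs absent from all sites excluded")
    present = data.loc[:, ~absent]
    P = present / present.sum(axis=0)
    b = 1.0 / (P ** 2).sum(axis=0)
    b.name = "niche_breadth"
    return b


def compare_niche_breadth(
    b_by_group: Mapping[str, pd.Series],
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests across OTU-level B values."""
    from .diversity import significance_stars

    names = list(b_by_group)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        x = np.asarray(b_by_group[a], dtype=float)
        y = np.asarray(b_by_group[b], dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ValidationError(f"groups {a!r}, {b!r} need >= 2 B values")
        if np.unique(np.concatenate([x, y])).size == 1:
            warnings.warn(f"all B values tied for {a} vs {b}; p set to 1")
            stat, p = float(len(x) * len(y) / 2), 1.0
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {"group_a": a, "group_b": b, "mean_b_a": float(np.mean(x)),
             "mean_b_b": float(np.mean(y)), "statistic": stat, "pvalue": p,
             "stars": significance_stars(p)}
        )
    return pd.DataFrame(rows)
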