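"""Alpha and beta diversity: Chao1, Shannon, Bray-Curtis, PCoA, PERMANOVA.

Chao1 uses the bias-corrected estimator by default (always defined, even
with no doubletons); Shannon entropy is reported in nats. Ordination is
classical metric scaling on the double-centred squared-distance matrix;
negative eigenvalues are reported but excluded from the variance-explained
denominator. PERMANOVA follows Anderson's distance-based pseudo-F with a
seeded label-permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io_tables import CountMatrix, RelAbundanceMatrix, ValidationError


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness: S_obs + F1(F1-1)/(2(F2+1)), from singletons/doubletons.

    The classic form S_obs + F1^2/(2 F2) is available with
    ``bias_corrected=False`` (falls back to the corrected form when F2=0).
    """
    c = np.asarray(counts)
    if c.size == 0 or (c > 0).sum() == 0:
        raise ValidationError("empty sample: no observed taxa")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs + f1 * f1 / (2.0 * f2)


def shannon(counts) -> float:
    """Shannon entropy in nats: -sum p ln p over nonzero proportions."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValidationError("sample depth must be > 0")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity(cm: CountMatrix) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon."""
    rows = {
        sid: {"chao1": chao1(row), "shannon": shannon(row)}
        for sid, row in zip(cm.sample_ids, cm.data.to_numpy())
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def significance_stars(p: float) -> str:
    """Figure-legend star convention: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 0.01), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


def alpha_compare(
    values: pd.Series,
    groups: pd.Series,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum comparisons of a diversity index.

    ``values`` are per-sample index values; ``groups`` assigns each sample a
    group label. All-tied pairs return p = 1 with a warning.
    """
    labels = groups.loc[values.index]
    if pairs is None:
        uniq = list(dict.fromkeys(labels))
        pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1 :]]
    rows = []
    for a, b in pairs:
        x = values[labels == a].to_numpy()
        y = values[labels == b].to_numpy()
        if len(x) < 2 or len(y) < 2:
            raise ValidationError(f"groups {a!r}, {b!r} need >= 2 samples each")
        if np.unique(np.concatenate([x, y])).size == 1:
            warnings.warn(f"all values tied for {a} vs {b}; p set to 1")
            stat, p = float(len(x) * len(y) / 2), 1.0
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {"group_a": a, "group_b": b, "statistic": stat, "pvalue": p,
             "stars": significance_stars(p)}
        )
    return pd.DataFrame(rows)


def bray_curtis(ra: RelAbundanceMatrix) -> pd.DataFrame:
    """Bray-Curtis dissimilarity: d(a,b) = 1 - sum min(p_a, p_b) on proportions."""
    if len(ra.sample_ids) < 2:
        raise ValidationError("need >= 2 samples")
    d = squareform(pdist(ra.data.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(d, index=ra.sample_ids, columns=ra.sample_ids)


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding with eigenvalues and variance explained."""

    coordinates: pd.DataFrame       # samples x retained axes (PCo1, PCo2, ...)
    eigenvalues: np.ndarray         # all eigenvalues, descending (negatives included)
    variance_explained: np.ndarray  # % per retained (positive) axis


def pcoa(dist: pd.DataFrame, n_axes: int | None = None) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower double-centring of -D^2/2, eigendecomposition, coordinates scaled
    by the square root of each positive eigenvalue. Variance explained is
    relative to the sum of positive eigenvalues only.
    """
    D = np.asarray(dist, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValidationError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals).max(), 1.0) * 1e-12
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    var_pct = eigvals[pos] / eigvals[pos].sum() * 100.0
    if n_axes is not None:
        coords, var_pct = coords[:, :n_axes], var_pct[:n_axes]
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    return OrdinationResult(
        pd.DataFrame(coords, index=index, columns=axes), eigvals, var_pct
    )


@dataclass
class PermanovaResult:
    factor: str
    pseudo_f: float
    r_squared: float
    pvalue: float
    n_permutations: int


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ssw = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size:
            ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ssw


def permanova(
    dist: pd.DataFrame,
    labels: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
    factor: str = "group",
) -> PermanovaResult:
    """One-factor PERMANOVA (distance-based pseudo-F, free label permutation).

    R^2 = SS_between / SS_total; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    D = np.asarray(dist, dtype=float)
    ids = list(dist.index) if isinstance(dist, pd.DataFrame) else list(range(len(D)))
    lab = pd.Series(labels).loc[ids]
    codes, uniq = pd.factorize(lab)
    a = len(uniq)
    if a < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValidationError("every group needs >= 2 samples")
    n = len(codes)
    d2 = D ** 2
    ss_total = d2.sum() / (2.0 * n)
    ssw = _ss_within(d2, codes, a)
    ssb = ss_total - ssw
    f_obs = (ssb / (a - 1)) / (ssw / (n - a))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        ssw_p = _ss_within(d2, perm, a)
        ssb_p = ss_total - ssw_p
        f_p = (ssb_p / (a - 1)) / (ssw_p / (n - a))
        if f_p >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(factor, float(f_obs), float(ssb / ss_total), float(p), n_permutations)


def rarefy(cm: CountMatrix, depth: int, seed: int = 0) -> CountMatrix:
    """Subsample every sample to ``depth`` reads without replacement."""
    rng = np.random.default_rng(seed)
    if (cm.depths < depth).any():
        shallow = cm.depths[cm.depths < depth].index.tolist()
        raise ValidationError(f"samples shallower than {depth}: {shallow}")
    out = np.empty_like(cm.data.to_numpy())
    for i, row in enumerate(cm.data.to_numpy()):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return CountMatrix(pd.DataFrame(out, index=cm.sample_ids, columns=cm.otu_ids))
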