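"""Atlas-level expression statistics.

Transcript-level TPM tables are aggregated to repeat families or genes
by summation, reduced to per-tissue medians, row-standardized, and fed
to hierarchical clustering with plain bootstrap support.  The module
also carries the small-sample statistical tests used downstream: an
exact Mann-Whitney, chi-squared goodness-of-fit/contingency, Kendall
tau-b and Pearson correlation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .io_formats import ExpressionTable

__all__ = [
    "aggregate_expression",
    "TissueProfile",
    "median_profile",
    "row_zscore",
    "ZMatrix",
    "cluster_tissues",
    "ClusterResult",
    "quintile_rank",
    "quintile_bin_sizes",
    "interindividual_sd",
    "mann_whitney_exact",
    "chi_squared",
    "chi_squared_contingency",
    "kendall_tau",
    "pearson",
]


def aggregate_expression(
    transcript_table: ExpressionTable,
    member_map: Mapping[str, str],
) -> tuple[ExpressionTable, list[str]]:
    """Sum member rows into group rows (e.g. transcripts -> ERE family).

    Returns the aggregated table and the list of row ids that had no
    group assignment (dropped, reported, never silently summed).
    """
    df = transcript_table.values
    unmapped = [r for r in df.index if r not in member_map]
    mapped = df.drop(index=unmapped)
    groups = pd.Series({r: member_map[r] for r in mapped.index}, name="group")
    agg = mapped.groupby(groups).sum()
    agg.index.name = None
    return ExpressionTable(agg, unit=transcript_table.unit), unmapped


@dataclass
class TissueProfile:
    """Per-tissue median expression, one row per family/gene."""

    medians: pd.DataFrame  # features x tissues
    sample_to_tissue: dict[str, str]

    @property
    def tissues(self) -> list[str]:
        return list(self.medians.columns)


def median_profile(
    table: ExpressionTable,
    sample_to_tissue: Mapping[str, str],
) -> TissueProfile:
    """Median expression across all samples of each tissue.

    Even sample counts use the mean-of-central-values convention (the
    numpy/pandas default).  Every sample column must carry a tissue
    label; a tissue mapping to zero columns is an error.
    """
    missing = [s for s in table.col_ids if s not in sample_to_tissue]
    if missing:
        raise ValueError(f"samples without tissue assignment: {missing}")
    tissue_of = pd.Series({s: sample_to_tissue[s] for s in table.col_ids})
    declared = set(sample_to_tissue.values())
    present = set(tissue_of.values)
    empty = declared - present
    if empty:
        raise ValueError(f"tissue(s) with zero samples: {sorted(empty)}")
    med = table.values.T.groupby(tissue_of).median().T
    return TissueProfile(med, dict(sample_to_tissue))


@dataclass
class ZMatrix:
    values: pd.DataFrame  # features x tissues, row z-scores
    row_means: pd.Series
    row_sds: pd.Series
    constant_rows: list[str]


def row_zscore(profile: TissueProfile | pd.DataFrame) -> ZMatrix:
    """Per-row (x - mean) / sd with sd on n-1 denominator.

    Constant rows cannot be scaled; they become all-zero and are
    flagged rather than propagating NaN.
    """
    df = profile.medians if isinstance(profile, TissueProfile) else profile
    if df.shape[1] < 2:
        raise ValueError("row z-scores need at least 2 tissues")
    means = df.mean(axis=1)
    sds = df.std(axis=1, ddof=1)
    constant = sds[sds == 0].index.tolist()
    safe_sd = sds.replace(0, 1.0)
    z = df.sub(means, axis=0).div(safe_sd, axis=0)
    return ZMatrix(z, means, sds, constant)


def unscale(z: ZMatrix) -> pd.DataFrame:
    """Inverse of :func:`row_zscore` using the stored means/sds."""
    return z.values.mul(z.row_sds.replace(0, 1.0), axis=0).add(z.row_means, axis=0)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix over tissues
    tissues: list[str]  # leaf order used for the linkage (sorted ids)
    clusters: list[frozenset[str]]  # internal-node tissue sets
    support: dict[frozenset[str], float]  # bootstrap probability per cluster

    def newick(self) -> str:
        """Newick-like text serialization of the dendrogram."""
        n = len(self.tissues)
        labels: dict[int, str] = {i: self.tissues[i] for i in range(n)}
        for k, (a, b, dist, _) in enumerate(self.linkage):
            labels[n + k] = f"({labels[int(a)]},{labels[int(b)]}):{dist:.4g}"
        return labels[2 * n - 2] + ";"


def _clusters_from_linkage(Z: np.ndarray, labels: Sequence[str]) -> list[frozenset[str]]:
    n = len(labels)
    members: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for k, row in enumerate(Z):
        merged = members[int(row[0])] | members[int(row[1])]
        members[n + k] = merged
        out.append(merged)
    return out


def cluster_tissues(
    zmatrix: ZMatrix | pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of tissues with bootstrap support.

    Tissues are clustered on Euclidean distances between their feature
    columns.  Support for each internal cluster is the fraction of
    feature-resampled bootstrap trees that contain exactly that tissue
    set (plain bootstrap probability).  Columns are sorted by tissue id
    before clustering so equidistant merges break ties reproducibly.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = zmatrix.values if isinstance(zmatrix, ZMatrix) else zmatrix
    if df.shape[1] < 3:
        raise ValueError("clustering needs at least 3 tissues")
    df = df[sorted(df.columns)]
    tissues = list(df.columns)
    X = df.to_numpy().T  # tissues x features
    Z = linkage(pdist(X, metric="euclidean"), method=method)
    clusters = _clusters_from_linkage(Z, tissues)
    rng = np.random.default_rng(seed)
    hits = {c: 0 for c in clusters}
    n_feat = X.shape[1]
    for _ in range(n_boot):
        idx = rng.integers(0, n_feat, size=n_feat)
        Zb = linkage(pdist(X[:, idx], metric="euclidean"), method=method)
        for c in _clusters_from_linkage(Zb, tissues):
            if c in hits:
                hits[c] += 1
    support = {c: hits[c] / n_boot for c in clusters}
    return ClusterResult(Z, tissues, clusters, support)


# ---------------------------------------------------------------------------
# quintile ranking


def quintile_bin_sizes(n_tissues: int) -> list[int]:
    """Quintile sizes, lowest to highest expression.

    Equal floor(N/5) per bin with the remainder added to the middle
    bin; N = 32 gives the 6, 6, 8, 6, 6 layout.
    """
    if n_tissues < 5:
        raise ValueError("quintile ranking needs at least 5 tissues")
    base, rem = divmod(n_tissues, 5)
    sizes = [base] * 5
    sizes[2] += rem
    return sizes


def quintile_rank(
    profile: TissueProfile | pd.DataFrame,
) -> tuple[pd.Series, list[str]]:
    """Tally, per tissue, its top-quintile memberships across families.

    For each family the tissues are ranked by median expression and cut
    into five bins; the returned series counts fifth-quintile (highest)
    assignments per tissue, sorted descending.  Families with ranking
    ties are listed in the second return value; ties break by stable
    tissue-id order.
    """
    df = profile.medians if isinstance(profile, TissueProfile) else profile
    sizes = quintile_bin_sizes(df.shape[1])
    top_n = sizes[-1]
    tissues = sorted(df.columns)
    counts = pd.Series(0, index=tissues, dtype=int)
    tied_families: list[str] = []
    for fam, row in df[tissues].iterrows():
        order = sorted(range(len(tissues)), key=lambda i: (-row.iloc[i], tissues[i]))
        vals = row.iloc[order].to_numpy()
        if len(np.unique(vals)) < len(vals):
            tied_families.append(fam)
        for i in order[:top_n]:
            counts[tissues[i]] += 1
    return counts.sort_values(ascending=False, kind="stable"), tied_families


def interindividual_sd(
    table: ExpressionTable,
    sample_to_tissue: Mapping[str, str],
) -> pd.DataFrame:
    """Sample SD (n-1) of each feature across samples within each tissue.

    Single-sample tissues yield NaN (SD undefined, by policy).
    """
    tissue_of = pd.Series({s: sample_to_tissue[s] for s in table.col_ids})
    return table.values.T.groupby(tissue_of).std(ddof=1).T


# ---------------------------------------------------------------------------
# statistical tests


def _rank_sum_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic for sample a via midranks of the pooled values."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(a)].sum()
    return r1 - len(a) * (len(a) + 1) / 2


def mann_whitney_exact(
    a: Sequence[float],
    b: Sequence[float],
    two_sided: bool = True,
) -> tuple[float, float]:
    """Mann-Whitney U with an exact small-sample p.

    For len(a) + len(b) <= 12 the p-value is computed by enumerating
    every group labeling of the pooled values (so it is exact under
    ties as well); larger samples use the normal approximation with tie
    correction.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n, m = len(a), len(b)
    u_obs = _rank_sum_u(a, b)
    if n + m <= 12:
        pooled = np.concatenate([a, b])
        total = comb(n + m, n)
        obs_dev = abs(u_obs - n * m / 2)
        hits = 0
        for idx in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            u = _rank_sum_u(pooled[mask], pooled[~mask])
            dev = abs(u - n * m / 2)
            if two_sided:
                if dev >= obs_dev - 1e-12:
                    hits += 1
            else:
                if u <= u_obs + 1e-12:
                    hits += 1
        return u_obs, hits / total
    alt = "two-sided" if two_sided else "less"
    res = stats.mannwhitneyu(a, b, alternative=alt, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def chi_squared(
    observed: Sequence[float],
    expected_proportions: Sequence[float],
) -> tuple[float, int, float]:
    """Goodness-of-fit chi-squared against expected proportions."""
    obs = np.asarray(list(observed), dtype=float)
    props = np.asarray(list(expected_proportions), dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected shapes differ")
    exp = props / props.sum() * obs.sum()
    if (exp <= 0).any():
        raise ValueError("expected counts must all be > 0")
    statistic = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return statistic, df, p


def chi_squared_contingency(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Chi-squared test of independence on an r x c table, df=(r-1)(c-1)."""
    arr = np.asarray(table, dtype=float)
    res = stats.chi2_contingency(arr, correction=False)
    if (res.expected_freq <= 0).any():
        raise ValueError("expected counts must all be > 0")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall tau-b with tie correction; p via normal approximation."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Kendall tau undefined for a constant vector")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; constant input is an error, not NaN."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("Pearson needs equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)
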