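"""Abundance normalization and community-ecology statistics.

Covers the whole statistics layer of the workflow: RPKM normalization,
log2(x+1) transform, Bray–Curtis dissimilarity, principal-coordinate
analysis, the ANOSIM R permutation test (with a PERMANOVA pseudo-F
alternative), Shannon's H, Wilcoxon rank-sum differential abundance with
Benjamini–Hochberg FDR, between/within-group dissimilarity sets, Welch-t
volcano results, and z-score + complete-linkage heat-map clustering.

Matrices are features x samples DataFrames throughout; the design maps
sample_id -> group label.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 1.0
FDR_ALPHA = 0.05
WILCOXON_EXACT_MAX_N = 12


@dataclass
class TestResult:
    feature_id: str
    contrast: str
    statistic: float
    p: float
    q: float
    direction: str
    effect: float = float("nan")


# ----------------------------------------------------------- normalization


def rpkm(count: float, length_bp: float, total_mapped: float) -> float:
    """Reads per kilobase per million mapped reads: count * 1e9 / (L * N)."""
    if length_bp <= 0 or total_mapped <= 0:
        raise ValueError("length_bp and total_mapped must be positive")
    return count * 1e9 / (length_bp * total_mapped)


def rpkm_matrix(
    counts: pd.DataFrame,
    lengths_bp: Mapping[str, float] | pd.Series,
    total_mapped: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """RPKM for a features x samples count matrix.

    ``total_mapped`` defaults to the per-sample column sums.
    """
    lengths = pd.Series(lengths_bp).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise KeyError(f"missing feature lengths: {missing}")
    totals = counts.sum(axis=0) if total_mapped is None else pd.Series(total_mapped)
    if (totals <= 0).any() or (lengths <= 0).any():
        raise ValueError("lengths and totals must be positive")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def log_transform(matrix: pd.DataFrame, pseudocount: float = PSEUDOCOUNT) -> pd.DataFrame:
    """Elementwise log2(x + pseudocount)."""
    if (matrix.values < 0).any():
        raise ValueError("matrix must be non-negative")
    return np.log2(matrix + pseudocount)


# ------------------------------------------------------------- dissimilarity


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Bray–Curtis dissimilarity of a features x samples matrix."""
    x = matrix.values.T.astype(float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    sums = x.sum(axis=1)
    if (sums == 0).any():
        warnings.warn("all-zero sample(s); their mutual distance is defined as 0")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        denom = sums[i] + sums[j]
        d[i, j] = d[j, i] = np.abs(x[i] - x[j]).sum() / denom if denom > 0 else 0.0
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def pcoa(dm: pd.DataFrame) -> Tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling of a distance matrix.

    Returns sample coordinates on the positive-eigenvalue axes and the full
    eigenvalue spectrum (descending); axes with negative eigenvalues are
    reported in the spectrum but dropped from the coordinates.
    """
    d = dm.values.astype(float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > 1e-9 * max(evals.max(), 1.0)
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=dm.index, columns=cols), evals


# ------------------------------------------------------------- group tests


def _group_indices(samples: Sequence[str], design: Mapping[str, str]) -> Dict[str, List[int]]:
    missing = [s for s in samples if s not in design]
    if missing:
        raise KeyError(f"samples missing from design: {missing}")
    groups: Dict[str, List[int]] = {}
    for i, s in enumerate(samples):
        groups.setdefault(design[s], []).append(i)
    return groups


def _anosim_r(rank_condensed: np.ndarray, labels: np.ndarray, n: int) -> float:
    iu = np.triu_indices(n, 1)
    same = labels[iu[0]] == labels[iu[1]]
    m = rank_condensed.size
    rw = rank_condensed[same].mean()
    rb = rank_condensed[~same].mean()
    return (rb - rw) / (m / 2.0)


def anosim(
    dm: pd.DataFrame,
    design: Mapping[str, str],
    n_perm: int | str = 999,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """ANOSIM R with a permutation p-value.

    ``n_perm`` may be an integer (seeded label permutations, add-one p
    estimator) or ``"exact"`` (exhaustive enumeration of distinct label
    assignments; feasible for tiny designs only).
    """
    samples = list(dm.index)
    groups = _group_indices(samples, design)
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    if any(len(ix) < 2 for ix in groups.values()):
        raise ValueError("every group needs >=2 samples")
    n = len(samples)
    condensed = squareform(dm.values, checks=False)
    ranks = sps.rankdata(condensed)
    labels = np.array([design[s] for s in samples])
    r_obs = _anosim_r(ranks, labels, n)
    if n_perm == "exact":
        perms = sorted({tuple(p) for p in itertools.permutations(labels)})
        r_null = [_anosim_r(ranks, np.array(p), n) for p in perms]
        p = sum(r >= r_obs - 1e-12 for r in r_null) / len(r_null)
        return r_obs, p
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_perm)):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, perm, n) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + int(n_perm))
    return r_obs, p


def permanova(
    dm: pd.DataFrame,
    design: Mapping[str, str],
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """PERMANOVA pseudo-F on a distance matrix (optional alternative to ANOSIM)."""
    samples = list(dm.index)
    groups = _group_indices(samples, design)
    d2 = dm.values.astype(float) ** 2
    n = len(samples)
    a = len(groups)

    def pseudo_f(label_arr: np.ndarray) -> float:
        sst = d2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for g in np.unique(label_arr):
            ix = np.where(label_arr == g)[0]
            if len(ix) > 1:
                sub = d2[np.ix_(ix, ix)]
                ssw += sub[np.triu_indices(len(ix), 1)].sum() / len(ix)
        ssa = sst - ssw
        return (ssa / (a - 1)) / (ssw / (n - a))

    labels = np.array([design[s] for s in samples])
    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    count = sum(
        pseudo_f(rng.permutation(labels)) >= f_obs - 1e-12 for _ in range(n_perm)
    )
    return f_obs, (1 + count) / (1 + n_perm)


def shannon(abundances: Sequence[float] | np.ndarray) -> float:
    """Shannon's H with natural log; zero entries are skipped."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Two-sided rank-sum p: exact enumeration for small tie-free samples,
    midranks + normal approximation otherwise.  Returns (U statistic, p)."""
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(len(x) * len(y) / 2), 1.0
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(pooled) <= WILCOXON_EXACT_MAX_N) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_bh(
    matrix: pd.DataFrame,
    design: Mapping[str, str],
    contrasts: Sequence[Tuple[str, str]],
) -> List[TestResult]:
    """Per-feature two-sided Wilcoxon rank-sum tests with BH FDR per contrast."""
    groups = _group_indices(list(matrix.columns), design)
    results: List[TestResult] = []
    for g1, g2 in contrasts:
        for g in (g1, g2):
            if g not in groups:
                raise KeyError(f"unknown group {g!r}")
            if len(groups[g]) < 2:
                raise ValueError(f"group {g!r} has <2 samples")
        name = f"{g1}_vs_{g2}"
        ps, stats_, effects = [], [], []
        for fid in matrix.index:
            x = matrix.loc[fid].values[groups[g1]].astype(float)
            y = matrix.loc[fid].values[groups[g2]].astype(float)
            u, p = _rank_sum_p(x, y)
            ps.append(p)
            stats_.append(u)
            effects.append(float(np.median(y) - np.median(x)))
        qs = bh_adjust(ps)
        for fid, u, p, q, eff in zip(matrix.index, stats_, ps, qs, effects):
            results.append(
                TestResult(fid, name, u, p, q, g2 if eff > 0 else g1, eff)
            )
    return results


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(pvals, method="fdr_bh")[1]


def group_dissimilarities(
    dm: pd.DataFrame,
    design: Mapping[str, str],
    mode: str,
    groups: Sequence[str],
) -> np.ndarray:
    """Between-group (|g1| x |g2|) or within-group (C(n,2)) distance values."""
    idx = _group_indices(list(dm.index), design)
    for g in groups:
        if g not in idx:
            raise KeyError(f"unknown group {g!r}")
    d = dm.values
    if mode == "between":
        g1, g2 = groups
        return np.array([d[i, j] for i in idx[g1] for j in idx[g2]])
    if mode == "within":
        (g,) = groups
        return np.array([d[i, j] for i, j in itertools.combinations(idx[g], 2)])
    raise ValueError("mode must be 'between' or 'within'")


def t_volcano(
    log_matrix: pd.DataFrame,
    design: Mapping[str, str],
    contrast: Tuple[str, str],
) -> List[TestResult]:
    """Welch two-sample t per feature on log2 abundances, BH-adjusted.

    ``effect`` is mean(group2) - mean(group1); ``direction`` names the
    enriched group.
    """
    groups = _group_indices(list(log_matrix.columns), design)
    g1, g2 = contrast
    ix1, ix2 = groups[g1], groups[g2]
    if len(ix1) < 2 or len(ix2) < 2:
        raise ValueError("each group needs >=2 samples")
    x = log_matrix.values[:, ix1].astype(float)
    y = log_matrix.values[:, ix2].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(y, x, axis=1, equal_var=False)
    eff = y.mean(axis=1) - x.mean(axis=1)
    # degenerate features: zero variance in both groups
    degenerate = np.isnan(p)
    p = np.where(degenerate & (np.abs(eff) < 1e-12), 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    qs = bh_adjust(p)
    name = f"{g1}_vs_{g2}"
    return [
        TestResult(fid, name, float(ti), float(pi), float(qi),
                   g2 if ei > 0 else g1, float(ei))
        for fid, ti, pi, qi, ei in zip(log_matrix.index, t, p, qs, eff)
    ]


# --------------------------------------------------------------- heat maps


def zscore_hclust(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, List[str], np.ndarray]:
    """Row z-scores plus complete-linkage Euclidean clustering of rows.

    Constant rows become all-zero (with a warning).  Returns the normalized
    matrix, the deterministic leaf order, and the linkage matrix.
    """
    if len(matrix) < 2:
        raise ValueError("need >=2 rows")
    x = matrix.values.astype(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    if (sd == 0).any():
        warnings.warn("constant row(s) z-scored to all-zero")
    z = np.where(sd > 0, (x - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    link = hierarchy.linkage(z, method="complete", metric="euclidean")
    order = hierarchy.leaves_list(link)
    zdf = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return zdf, [matrix.index[i] for i in order], link


def linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(link)

    def fmt(node, parent_dist) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_dist - 0.0:.6g}"
        inner = ",".join(fmt(ch, node.dist) for ch in (node.get_left(), node.get_right()))
        return f"({inner}):{parent_dist - node.dist:.6g}"

    return f"({','.join(fmt(ch, tree.dist) for ch in (tree.get_left(), tree.get_right()))});"
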