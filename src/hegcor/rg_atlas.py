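"""Genetic-correlation atlas: r_g matrices, r_pg clustering, meta-traits.

Individual r_g estimates are noisy; correlating two traits' full vectors of
genetic correlations across the atlas (the Pearson genetic correlation,
r_pg) gives a noise-robust similarity.  |r_pg| is converted to a Euclidean
distance, traits are joined by Ward-D2 hierarchical clustering, and the cut
level k is chosen to maximize the mean heritability ratio

    h2_ratio = h2_meta / (0.5 * (h2_sub1 + h2_sub2))

of each cluster's meta-trait over its two child sub-clusters.  Meta-traits
are per-animal means of sign-aligned, z-scored member traits and serve as
the inputs of the mega-analysis genome scans.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .kinship import KinshipMatrix
from .he_core import HEEstimate, RgEstimate, he_h2, he_rg, filter_rg
from .pheno_prep import zscore

logger = logging.getLogger(__name__)

__all__ = [
    "RgMatrix",
    "RpgMatrix",
    "MetaTrait",
    "ClusterSolution",
    "bonferroni_threshold",
    "rg_matrix",
    "rpg_matrix",
    "rpg_to_distance",
    "ward_cluster",
    "h2_ratio",
    "build_meta_trait",
    "sweep_k",
    "group_rg_summary",
    "cluster_summary",
]


@dataclasses.dataclass
class RgMatrix:
    """Pairwise genetic correlations with SEs, p-values and a validity mask."""

    traits: list
    rg: np.ndarray
    se: np.ndarray
    p: np.ndarray
    valid: np.ndarray
    bonferroni: float

    @property
    def n_pairs(self) -> int:
        t = len(self.traits)
        return t * (t - 1) // 2


@dataclasses.dataclass
class RpgMatrix:
    """Pearson correlations of z-scored r_g vectors, with per-cell n_obs."""

    traits: list
    values: np.ndarray
    n_obs: np.ndarray


@dataclasses.dataclass
class MetaTrait:
    """Per-animal mean of sign-aligned z-scored member traits, re-z-scored."""

    values: np.ndarray
    members: list
    signs: dict
    focal: str


@dataclasses.dataclass
class ClusterSolution:
    """Chosen cut level with its mean h2 ratio and the full sweep curve."""

    k: int
    assignments: dict
    mean_h2_ratio: float
    curve: pd.DataFrame
    per_cluster: pd.DataFrame


def bonferroni_threshold(n_traits: int, alpha: float = 0.05) -> tuple[float, int]:
    """Phenome-wide Bonferroni p threshold over all unordered trait pairs."""
    n_pairs = n_traits * (n_traits - 1) // 2
    return alpha / n_pairs, n_pairs


def rg_matrix(
    phenos: pd.DataFrame,
    K: KinshipMatrix,
    h2_estimates: dict[str, HEEstimate],
    alpha: float = 0.05,
) -> RgMatrix:
    """All-pairs genetic correlations for traits that passed filtering.

    Failed or invalid pairs are masked, never fatal.  The Bonferroni p-value
    threshold is alpha divided by the number of unordered pairs.
    """
    traits = list(phenos.columns)
    t = len(traits)
    rg = np.full((t, t), np.nan)
    se = np.full((t, t), np.nan)
    p = np.full((t, t), np.nan)
    valid = np.zeros((t, t), dtype=bool)
    np.fill_diagonal(rg, 1.0)
    np.fill_diagonal(se, 0.0)
    np.fill_diagonal(valid, True)
    for a in range(t):
        for b in range(a + 1, t):
            try:
                est = he_rg(
                    phenos.iloc[:, a].to_numpy(dtype=float),
                    phenos.iloc[:, b].to_numpy(dtype=float),
                    K, h2_estimates[traits[a]], h2_estimates[traits[b]],
                )
            except (ValueError, KeyError) as exc:
                logger.warning("rg(%s, %s) failed: %s", traits[a], traits[b], exc)
                continue
            rg[a, b] = rg[b, a] = est.rg
            se[a, b] = se[b, a] = est.se
            p[a, b] = p[b, a] = est.p
            valid[a, b] = valid[b, a] = est.valid
    threshold, _ = bonferroni_threshold(t, alpha)
    return RgMatrix(traits, rg, se, p, valid, threshold)


def rpg_matrix(R: RgMatrix) -> RpgMatrix:
    """Pearson-correlate z-scored r_g vectors for every trait pair.

    Each trait's r_g vector (over the full trait set) is z-scored across its
    finite valid entries; for a pair (a, b) the entries involving a or b
    themselves are dropped, as are cells invalid in either vector, and the
    remaining paired entries are Pearson-correlated.  Cells with fewer than
    3 shared entries are masked.
    """
    t = len(R.traits)
    if t < 3:
        raise ValueError("need at least 3 traits for r_pg")
    vec = np.where(R.valid, R.rg, np.nan)
    zvec = np.full_like(vec, np.nan)
    for a in range(t):
        row = vec[a].copy()
        row[a] = np.nan  # self-entry excluded from the vector
        m = np.isfinite(row)
        if m.sum() >= 2 and np.nanstd(row[m], ddof=1) > 0:
            zvec[a, m] = (row[m] - row[m].mean()) / row[m].std(ddof=1)
    values = np.full((t, t), np.nan)
    n_obs = np.zeros((t, t), dtype=int)
    np.fill_diagonal(values, 1.0)
    for a in range(t):
        for b in range(a + 1, t):
            va, vb = zvec[a].copy(), zvec[b].copy()
            va[[a, b]] = np.nan
            vb[[a, b]] = np.nan
            m = np.isfinite(va) & np.isfinite(vb)
            n = int(m.sum())
            n_obs[a, b] = n_obs[b, a] = n
            if n < 3:
                continue
            sa, sb = va[m].std(ddof=1), vb[m].std(ddof=1)
            if sa == 0 or sb == 0:
                continue
            r = float(np.corrcoef(va[m], vb[m])[0, 1])
            values[a, b] = values[b, a] = np.clip(r, -1.0, 1.0)
    return RpgMatrix(R.traits, values, n_obs)


def rpg_to_distance(rpg: float | np.ndarray, n_obs: int | np.ndarray) -> float | np.ndarray:
    """Euclidean distance d = sqrt(2 n (1 - |r_pg|)).

    Absolute value is taken because positive and negative genetic
    correlations are equally indicative of a shared genetic basis; the form
    is the non-negative equivalent of d = sqrt(-2 n (|r_pg| - 1)).
    """
    return np.sqrt(2.0 * np.asarray(n_obs, dtype=float) * (1.0 - np.abs(rpg)))


def ward_cluster(D: np.ndarray) -> np.ndarray:
    """Ward-D2 agglomerative clustering of a precomputed distance matrix.

    Returns a scipy linkage matrix; scipy's 'ward' method on a condensed
    distance input implements the Ward-D2 (squared-distance variance)
    update.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite entries")
    return hierarchy.linkage(squareform(D, checks=False), method="ward")


def h2_ratio(h2_meta: float, h2_sub1: float, h2_sub2: float) -> float:
    """Heritability ratio of a meta-trait over its two child sub-clusters."""
    denom = 0.5 * (h2_sub1 + h2_sub2)
    if denom <= 0:
        raise ValueError("mean child heritability must be positive")
    return h2_meta / denom


def build_meta_trait(
    members: list,
    rpg: RpgMatrix,
    h2_estimates: dict[str, HEEstimate],
    phenos: pd.DataFrame,
) -> MetaTrait:
    """Average sign-aligned member traits into a meta-trait.

    The focal member is the trait with the highest h2 estimate; members whose
    r_pg with the focal trait is negative are sign-flipped before averaging.
    The per-animal mean over available members is re-z-scored (so that
    h2 = beta/2 remains valid downstream); animals with no member data stay
    missing.
    """
    if not members:
        raise ValueError("empty cluster")
    focal = max(members, key=lambda tr: h2_estimates[tr].h2)
    idx = {tr: rpg.traits.index(tr) for tr in members}
    signs = {}
    for tr in members:
        if tr == focal:
            signs[tr] = 1
        else:
            r = rpg.values[idx[tr], idx[focal]]
            signs[tr] = -1 if (np.isfinite(r) and r < 0) else 1
    mat = np.column_stack([signs[tr] * phenos[tr].to_numpy(dtype=float) for tr in members])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=1)
    finite = np.isfinite(mean)
    if finite.sum() >= 2 and np.nanstd(mean[finite], ddof=1) > 0:
        out = np.full_like(mean, np.nan)
        out[finite] = (mean[finite] - mean[finite].mean()) / mean[finite].std(ddof=1)
        mean = out
    return MetaTrait(mean, list(members), signs, focal)


def _node_for_leaves(root, leaves: frozenset):
    """Descend from the root to the internal node spanning exactly `leaves`."""
    node = root
    while node.get_count() > len(leaves):
        left = frozenset(node.get_left().pre_order())
        node = node.get_left() if leaves <= left else node.get_right()
    return node


def sweep_k(
    linkage: np.ndarray,
    phenos: pd.DataFrame,
    K: KinshipMatrix,
    rpg: RpgMatrix,
    h2_estimates: dict[str, HEEstimate],
    k_range=None,
) -> ClusterSolution:
    """Choose the cut level k maximizing the mean h2 ratio across clusters.

    At each k the dendrogram is cut; every non-singleton cluster contributes
    the ratio of its meta-trait h2 to the mean h2 of the meta-traits of its
    two child sub-dendrograms.  Singletons (no children) and clusters with a
    non-positive child h2 are skipped.  Ties in the argmax favor the smaller
    k.
    """
    traits = list(phenos.columns)
    root = hierarchy.to_tree(linkage)
    if k_range is None:
        k_range = range(2, len(traits))
    rows, per_cluster_best = [], None
    best = (-np.inf, None, None)
    for k in k_range:
        labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        ratios, cluster_rows = [], []
        for c in np.unique(labels):
            member_idx = np.nonzero(labels == c)[0]
            members = [traits[i] for i in member_idx]
            if len(members) < 2:
                logger.debug("k=%d cluster %d is a singleton; skipped", k, c)
                continue
            node = _node_for_leaves(root, frozenset(member_idx))
            sub1 = [traits[i] for i in node.get_left().pre_order()]
            sub2 = [traits[i] for i in node.get_right().pre_order()]
            try:
                h2_m = _meta_h2(members, rpg, h2_estimates, phenos, K)
                h2_1 = _meta_h2(sub1, rpg, h2_estimates, phenos, K)
                h2_2 = _meta_h2(sub2, rpg, h2_estimates, phenos, K)
                ratio = h2_ratio(h2_m, h2_1, h2_2)
            except ValueError as exc:
                logger.debug("k=%d cluster %d skipped: %s", k, c, exc)
                continue
            ratios.append(ratio)
            cluster_rows.append({"cluster": int(c), "h2_meta": h2_m,
                                 "h2_sub1": h2_1, "h2_sub2": h2_2, "ratio": ratio})
        mean_ratio = float(np.mean(ratios)) if ratios else np.nan
        rows.append({"k": int(k), "mean_h2_ratio": mean_ratio, "n_scored": len(ratios)})
        if ratios and mean_ratio > best[0]:
            best = (mean_ratio, int(k), dict(zip(traits, labels)))
            per_cluster_best = pd.DataFrame(cluster_rows)
    curve = pd.DataFrame(rows)
    if best[1] is None:
        raise ValueError("no cut level produced a scorable cluster")
    return ClusterSolution(best[1], best[2], best[0], curve, per_cluster_best)


def _meta_h2(members, rpg, h2_estimates, phenos, K) -> float:
    meta = build_meta_trait(members, rpg, h2_estimates, phenos)
    return he_h2(meta.values, K).h2


def group_rg_summary(
    group_values: dict[str, pd.Series],
    K: KinshipMatrix,
) -> pd.DataFrame:
    """Intra-trait genetic correlations between measurement groups.

    ``group_values`` maps a group label (time point, diet, ...) to a z-scored
    trait Series indexed by animal id; groups are disjoint cohorts of the
    kinship matrix.  For every group pair the cross-cohort r_g is estimated;
    estimates with |r_g| > 1 + SE are excluded.  Returns one row per group
    pair with rg, se and validity.
    """
    if len(group_values) < 2:
        raise ValueError("need at least 2 groups")
    prepared = {}
    for grp, series in group_values.items():
        idx = K.index_of(series.index)
        prepared[grp] = (series.to_numpy(dtype=float), idx)
    rows = []
    names = sorted(prepared)
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = names[a_i], names[b_i]
            ya, ia = prepared[a]
            yb, ib = prepared[b]
            est_a = he_h2(ya, K, idx=ia)
            est_b = he_h2(yb, K, idx=ib)
            est = he_rg(ya, yb, K, est_a, est_b, idx_M=ia, idx_N=ib)
            rows.append({"group1": a, "group2": b, "rg": est.rg, "se": est.se,
                         "valid": filter_rg(est), "estimable": est.estimable})
    return pd.DataFrame(rows)


def cluster_summary(assignments: dict) -> dict:
    """Counts of traits and clusters, plus the mean cluster size."""
    labels = np.asarray(list(assignments.values()))
    n_traits = len(labels)
    n_clusters = len(np.unique(labels))
    return {
        "n_traits": n_traits,
        "n_clusters": n_clusters,
        "mean_traits_per_cluster": n_traits / n_clusters,
    }
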