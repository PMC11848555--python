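"""Patient stratification by metabolite pattern and phenotype association.

Case fingerprints are z-scored per signal and clustered by Ward-linkage
agglomerative clustering; when the number of groups is not forced it is
chosen by majority vote of silhouette, Calinski-Harabasz and the gap
statistic over k = 2..8 (gap breaks ties).  Cluster-phenotype association
uses rank-sum composites of neuropsychological scales (orientation-aligned
so higher is always better), Kruskal-Wallis tests with tie correction (plus
an exact permutation p at small n), Dunn's post-hoc pairwise comparisons
with Bonferroni adjustment, and an ordinal Kruskal-Wallis test of VCI
status across groups.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, fcluster
from sklearn.metrics import silhouette_score, calinski_harabasz_score

from .synthgen import SCALES, HIGHER_IS_WORSE, VCI_LEVELS

__all__ = [
    "ClusterResult", "PhenotypeAssociation", "hcluster", "rank_sum_scores",
    "kruskal_wallis", "KWResult", "dunn_posthoc", "vci_association",
    "dendrogram_newick",
]


@dataclass
class ClusterResult:
    """Cluster assignment of case samples plus the k-selection audit trail."""

    assignment: np.ndarray  # labels 1..k, one per case sample
    k: int
    linkage: str = "ward"
    distance: str = "euclidean"
    k_selection_votes: dict[str, int] = field(default_factory=dict)
    linkage_matrix: Optional[np.ndarray] = None
    degenerate: bool = False


def _gap_statistic(x: np.ndarray, z: np.ndarray, ks: range,
                   n_ref: int = 10, seed: int = 0) -> int:
    """Tibshirani gap statistic: first k with gap(k) >= gap(k+1) - s(k+1)."""
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)

    def dispersion(data, labels):
        w = 0.0
        for c in np.unique(labels):
            sub = data[labels == c]
            w += ((sub - sub.mean(axis=0)) ** 2).sum()
        return max(w, 1e-300)

    gaps, sks = [], []
    for k in ks:
        obs = fcluster(z, k, criterion="maxclust")
        log_w = np.log(dispersion(x, obs))
        ref_logs = []
        for _ in range(n_ref):
            ref = rng.uniform(lo, hi, size=x.shape)
            zr = linkage(ref, method="ward")
            ref_logs.append(np.log(dispersion(ref, fcluster(zr, k, criterion="maxclust"))))
        ref_logs = np.array(ref_logs)
        gaps.append(ref_logs.mean() - log_w)
        sks.append(ref_logs.std(ddof=1) * np.sqrt(1 + 1 / n_ref))
    for i, k in enumerate(list(ks)[:-1]):
        if gaps[i] >= gaps[i + 1] - sks[i + 1]:
            return k
    return list(ks)[int(np.argmax(gaps))]


def hcluster(case_matrix: np.ndarray, k: int | None = None,
             k_max: int = 8, seed: int = 0) -> ClusterResult:
    """Ward/Euclidean hierarchical clustering of z-scored case fingerprints.

    If ``k`` is omitted it is selected by majority vote of silhouette,
    Calinski-Harabasz and the gap statistic over 2..k_max, with the gap
    statistic breaking ties.  Duplicate-row degenerate inputs report k=1.
    """
    x = np.asarray(case_matrix, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("clustering requires >= 2 case samples")
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")

    sd = x.std(axis=0)
    informative = sd > 0
    if not informative.any():
        return ClusterResult(assignment=np.ones(n, dtype=int), k=1,
                             degenerate=True)
    xz = (x[:, informative] - x[:, informative].mean(axis=0)) / sd[informative]
    z = linkage(xz, method="ward")

    if k == n:
        return ClusterResult(assignment=np.arange(1, n + 1), k=n,
                             linkage_matrix=z)
    if k is not None:
        labels = fcluster(z, k, criterion="maxclust")
        return ClusterResult(assignment=labels, k=int(labels.max()),
                             linkage_matrix=z)

    ks = range(2, min(k_max, n - 1) + 1)
    sil_scores, ch_scores = {}, {}
    for kk in ks:
        labels = fcluster(z, kk, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sil_scores[kk] = silhouette_score(xz, labels)
        ch_scores[kk] = calinski_harabasz_score(xz, labels)
    if not sil_scores:
        return ClusterResult(assignment=np.ones(n, dtype=int), k=1,
                             degenerate=True, linkage_matrix=z)
    votes = {
        "silhouette": max(sil_scores, key=sil_scores.get),
        "calinski_harabasz": max(ch_scores, key=ch_scores.get),
        "gap": _gap_statistic(xz, z, ks, seed=seed),
    }
    counts: dict[int, int] = {}
    for v in votes.values():
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    winners = [kk for kk, c in counts.items() if c == best]
    chosen = votes["gap"] if votes["gap"] in winners else winners[0]
    labels = fcluster(z, chosen, criterion="maxclust")
    return ClusterResult(assignment=labels, k=int(labels.max()),
                         k_selection_votes=votes, linkage_matrix=z)


def rank_sum_scores(phenotypes: pd.DataFrame,
                    scales: tuple[str, ...] = SCALES,
                    higher_is_worse: tuple[str, ...] = HIGHER_IS_WORSE) -> pd.Series:
    """Per-patient composite: sum of within-scale ranks, higher = better.

    Scales listed in ``higher_is_worse`` (completion times) are negated
    before ranking.  Missing values are imputed with the scale's median
    rank (flagged by warning); patients missing every scale are excluded.
    """
    present = [s for s in scales if s in phenotypes.columns]
    if not present:
        raise ValueError("no recognized scale columns in phenotype table")
    sub = phenotypes[present].astype(float)
    all_missing = sub.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(f"excluding {int(all_missing.sum())} patients with no scores")
        sub = sub[~all_missing]

    composite = pd.Series(0.0, index=sub.index)
    for scale in present:
        vals = sub[scale].to_numpy(copy=True)
        if scale in higher_is_worse:
            vals = -vals
        ok = ~np.isnan(vals)
        ranks = np.full(len(vals), np.nan)
        ranks[ok] = stats.rankdata(vals[ok])
        if (~ok).any():
            warnings.warn(f"imputing median rank for missing {scale}")
            ranks[~ok] = np.median(ranks[ok])
        composite += ranks
    return composite


class KWResult(NamedTuple):
    H: float
    p: float
    exact_p: Optional[float] = None


def _kw_h(values: np.ndarray, groups: np.ndarray) -> float:
    """Kruskal-Wallis H with tie correction."""
    n = len(values)
    ranks = stats.rankdata(values)
    h = 0.0
    for g in np.unique(groups):
        r = ranks[groups == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(values, groups, exact_n_max: int = 12) -> KWResult:
    """Kruskal-Wallis test across groups.

    Returns H (tie-corrected), the chi-square p-value on k-1 df, and — when
    total n <= ``exact_n_max`` — an exact p from full enumeration of the
    group-label permutations.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("Kruskal-Wallis requires >= 2 groups")
    for g in uniq:
        if not np.any(groups == g):
            raise ValueError(f"group {g} is empty")
    n = len(values)
    if len(np.unique(values)) == 1:
        return KWResult(0.0, 1.0, 1.0 if n <= exact_n_max else None)
    h = _kw_h(values, groups)
    p = float(stats.chi2.sf(h, df=len(uniq) - 1))

    exact_p = None
    if n <= exact_n_max:
        observed = h
        count = 0
        total = 0
        for perm in _multiset_permutations(tuple(groups)):
            total += 1
            if _kw_h(values, np.array(perm)) >= observed - 1e-12:
                count += 1
        exact_p = count / total
    return KWResult(float(h), p, exact_p)


def _multiset_permutations(items):
    """All distinct orderings of a multiset (label sequence)."""
    def rec(remaining: tuple, prefix: tuple):
        if not remaining:
            yield prefix
            return
        used = set()
        for i, it in enumerate(remaining):
            if it in used:
                continue
            used.add(it)
            yield from rec(remaining[:i] + remaining[i + 1:], prefix + (it,))
    yield from rec(tuple(items), ())


def dunn_posthoc(values, groups, adjust: str = "bonferroni") -> dict[tuple, float]:
    """Dunn's pairwise rank comparisons with Bonferroni adjustment."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = len(values)
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n - 1)) if n > 1 else 0.0
    uniq = list(np.unique(groups))
    m = len(uniq) * (len(uniq) - 1) // 2
    out = {}
    for a, b in itertools.combinations(uniq, 2):
        ra, rb = ranks[groups == a], ranks[groups == b]
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1 / len(ra) + 1 / len(rb)))
        z = (ra.mean() - rb.mean()) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        out[(a, b)] = float(p)
    return out


@dataclass
class PhenotypeAssociation:
    """Cluster vs neuropsychology / VCI association summary."""

    rank_sum_score: pd.Series
    kw_H: float
    kw_p: float
    pairwise_p: dict[tuple, float]
    median_by_group: dict[int, float]
    vci_kw: Optional[KWResult] = None
    vci_proportions: Optional[pd.DataFrame] = None


def vci_association(assignment, vci_labels) -> tuple[KWResult, pd.DataFrame]:
    """Ordinal association of VCI status (none < mild VCI < VaD) with clusters."""
    codes = []
    for lab in vci_labels:
        if lab not in VCI_LEVELS:
            raise ValueError(f"unknown VCI label {lab!r}; expected one of {VCI_LEVELS}")
        codes.append(VCI_LEVELS.index(lab))
    codes = np.asarray(codes, dtype=float)
    assignment = np.asarray(assignment)
    kw = kruskal_wallis(codes, assignment)
    counts = (pd.crosstab(pd.Series(assignment, name="cluster"),
                          pd.Categorical(vci_labels, categories=VCI_LEVELS))
              .reindex(columns=VCI_LEVELS, fill_value=0))
    return kw, counts


def associate_phenotypes(assignment, phenotypes: pd.DataFrame) -> PhenotypeAssociation:
    """Full cluster-phenotype association: rank-sum KW + Dunn + VCI."""
    comp = rank_sum_scores(phenotypes)
    groups = np.asarray(assignment)[:len(comp)]
    kw = kruskal_wallis(comp.to_numpy(), groups)
    pair = dunn_posthoc(comp.to_numpy(), groups)
    medians = {int(g): float(np.median(comp.to_numpy()[groups == g]))
               for g in np.unique(groups)}
    vci_kw, vci_prop = (None, None)
    if "VCI" in phenotypes.columns:
        vci_kw, vci_prop = vci_association(groups, list(phenotypes["VCI"]))
    return PhenotypeAssociation(rank_sum_score=comp, kw_H=kw.H, kw_p=kw.p,
                                pairwise_p=pair, median_by_group=medians,
                                vci_kw=vci_kw, vci_proportions=vci_prop)


def dendrogram_newick(result: ClusterResult, labels: list[str] | None = None) -> str:
    """Export the clustering dendrogram in Newick format."""
    z = result.linkage_matrix
    if z is None:
        raise ValueError("no linkage matrix stored (degenerate or forced-k run)")
    n = len(z) + 1
    names = labels or [f"S{i+1}" for i in range(n)]

    def node(i: int, parent_h: float) -> str:
        if i < n:
            return f"{names[i]}:{parent_h:.6g}"
        row = z[i - n]
        h = row[2]
        left = node(int(row[0]), h - (z[int(row[0]) - n][2] if row[0] >= n else 0.0))
        right = node(int(row[1]), h - (z[int(row[1]) - n][2] if row[1] >= n else 0.0))
        return f"({left},{right}):{max(parent_h - h, 0.0):.6g}"

    root = node(2 * n - 2, z[-1][2])
    return root + ";"
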