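"""Unsupervised structure analysis.

Pearson-correlation distances between samples, average-linkage (UPGMA)
hierarchical clustering, PCA with variance accounting, matched/unmatched
sample-correlation summaries for lobe pairs, and a one-way random-effects
intraclass correlation for within-patient agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ExpressionMatrix, PhenotypeTable

__all__ = [
    "Dendrogram", "PCAResult", "ICCResult",
    "pearson_distance_matrix", "average_linkage_cluster", "pca",
    "paired_correlation_summary", "icc_one_way",
]


@dataclass
class Dendrogram:
    """UPGMA merge history: (node_a, node_b, height) per step.

    Nodes 0..n-1 are leaves (in ``labels`` order); merge i creates node n+i.
    """

    merges: list[tuple[int, int, float]]
    labels: list[str]

    def to_newick(self) -> str:
        """Newick with branch lengths = difference of merge heights."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for i, (a, b, h) in enumerate(self.merges):
            half = h / 2.0
            node[n + i] = (f"({node[a]}:{half - height[a] / 2:.10g},"
                           f"{node[b]}:{half - height[b] / 2:.10g})")
            height[n + i] = h
        return node[n + len(self.merges) - 1] + ";"


@dataclass
class PCAResult:
    loadings: np.ndarray           # features x r
    scores: np.ndarray             # samples x r
    variance_explained: np.ndarray # length r, fractions of total variance
    feature_means: np.ndarray


@dataclass
class ICCResult:
    icc: float
    f_statistic: float
    p_value: float


def pearson_distance_matrix(X: ExpressionMatrix) -> np.ndarray:
    """d(i, j) = 1 - Pearson r between sample columns i and j."""
    if X.n_samples < 2:
        raise ValueError("need at least two samples")
    sds = X.values.std(axis=0)
    if np.any(sds == 0):
        bad = X.sample_ids[int(np.argmax(sds == 0))]
        raise ValueError(f"zero-variance sample {bad!r}")
    R = np.corrcoef(X.values, rowvar=False)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    return D


def average_linkage_cluster(D: np.ndarray, labels: list[str]) -> Dendrogram:
    """UPGMA clustering of a symmetric distance matrix.

    Cluster distance is the unweighted mean of cross-pair leaf distances
    (Lance-Williams size-weighted update).  Tied minimum distances are
    broken toward the lexicographically smallest pair of member-label
    minima, which makes the merge sequence deterministic.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if len(labels) != n:
        raise ValueError("labels length mismatch")

    # active clusters: node id -> (size, min member label, row index)
    dist = {}
    active = list(range(n))
    size = {i: 1 for i in range(n)}
    minlab = {i: labels[i] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]

    def d(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                key = (d(a, b),) + tuple(sorted((minlab[a], minlab[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        h = d(a, b)
        new = next_id
        next_id += 1
        for c in active:
            if c in (a, b):
                continue
            dac, dbc = d(a, c), d(b, c)
            dn = (size[a] * dac + size[b] * dbc) / (size[a] + size[b])
            dist[(min(new, c), max(new, c))] = dn
        size[new] = size[a] + size[b]
        minlab[new] = min(minlab[a], minlab[b])
        lo, hi = (a, b) if minlab[a] <= minlab[b] else (b, a)
        merges.append((lo, hi, float(h)))
        active = [c for c in active if c not in (a, b)] + [new]
    return Dendrogram(merges, list(labels))


def pca(X: ExpressionMatrix, n_components: int) -> PCAResult:
    """PCA of the feature-centered matrix by SVD.

    Samples are observations; each feature is centered by its mean across
    samples (no scaling).  variance_explained_i = sigma_i^2 / sum sigma_j^2.
    """
    max_r = min(X.n_features, X.n_samples - 1)
    if n_components > max_r:
        raise ValueError(f"n_components={n_components} exceeds {max_r}")
    means = X.values.mean(axis=1)
    centered = X.values - means[:, None]
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s ** 2))
    var_exp = (s ** 2 / total) if total > 0 else np.zeros_like(s)
    r = n_components
    scores = (Vt[:r].T * s[:r])  # samples x r
    return PCAResult(U[:, :r], scores, var_exp[:r], means)


def paired_correlation_summary(X: ExpressionMatrix, pheno: PhenotypeTable
                               ) -> dict[str, float]:
    """Mean Pearson correlation of matched (same-patient) vs unmatched case pairs."""
    df = pheno.table
    cases = df[df["phenotype"] == 1]
    col = {s: i for i, s in enumerate(X.sample_ids)}
    case_ids = [s for s in cases["sample_id"] if s in col]
    patient = dict(zip(cases["sample_id"], cases["patient_id"]))
    R = np.corrcoef(X.values[:, [col[s] for s in case_ids]], rowvar=False)
    matched, unmatched = [], []
    for i in range(len(case_ids)):
        for j in range(i + 1, len(case_ids)):
            r = R[i, j]
            if patient[case_ids[i]] == patient[case_ids[j]]:
                matched.append(r)
            else:
                unmatched.append(r)
    if not matched:
        raise ValueError("no same-patient lobe pairs present")
    return {"mean_matched_r": float(np.mean(matched)),
            "mean_unmatched_r": float(np.mean(unmatched))}


def icc_one_way(values: np.ndarray, groups: list[str]) -> ICCResult:
    """One-way random-effects ICC(1) with its F test.

    Requires a balanced design (every group the same size k >= 2, here
    lobe pairs with k = 2).  ICC(1) = (MSB - MSW) / (MSB + (k-1) MSW);
    the p-value is P(F >= MSB/MSW) with (n_groups - 1, n_groups (k-1)) df.
    """
    values = np.asarray(values, dtype=float)
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    sizes = {g: sum(1 for x in groups if x == g) for g in uniq}
    k = sizes[uniq[0]]
    if k < 2 or len(set(sizes.values())) != 1:
        raise ValueError("groups must be balanced with >= 2 members each")
    m = len(uniq)
    grand = values.mean()
    group_means = {g: values[[i for i, gg in enumerate(groups) if gg == g]].mean()
                   for g in uniq}
    ssb = k * sum((group_means[g] - grand) ** 2 for g in uniq)
    ssw = sum((values[i] - group_means[groups[i]]) ** 2
              for i in range(len(values)))
    msb = ssb / (m - 1)
    msw = ssw / (m * (k - 1))
    if msw == 0:
        return ICCResult(1.0, np.inf, 0.0)
    f = msb / msw
    icc = (msb - msw) / (msb + (k - 1) * msw)
    p = float(stats.f.sf(f, m - 1, m * (k - 1)))
    return ICCResult(float(icc), float(f), p)
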