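"""Comparison methods: Monti-style consensus clustering and PCA embedding.

Consensus clustering repeatedly subsamples the cohort, clusters each
subsample, and records for every sample pair the proportion of runs in
which they co-clustered out of the runs in which both were drawn.  The
area under the empirical CDF of these consensus values, as a function of
k, drives the classical choice of the cluster count: stop at the largest k
whose relative area increase is still ≥ 0.1.

PCA embedding provides the top-principal-component space used for
visualization parity with the consensus-clustering workflow.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .cluster_select import SubtypeAssignment, _canonical_relabel
from .elm_core import FeatureMatrix
from .expr_io import ExpressionMatrix

__all__ = ["ConsensusResult", "consensus_cluster", "cdf_area", "pca_embed"]


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, final assignments, and the tally counts."""

    sample_ids: list[str]
    k_values: list[int]
    matrices: dict[int, np.ndarray]
    assignments: dict[int, SubtypeAssignment]
    co_cluster: dict[int, np.ndarray]
    co_sampled: np.ndarray
    reps: int
    p_item: float
    base: str
    never_cosampled: int = 0


def _include_mask(master_seed: int, rep: int, sample_ids: list[str], p_item: float) -> np.ndarray:
    """Per-sample Bernoulli(p_item) inclusion keyed by (seed, rep, sample ID).

    Keying the draw to the sample ID rather than its position makes the
    consensus matrix exactly equivariant under sample permutation.
    """
    u = np.array(
        [
            np.random.default_rng(
                [master_seed & 0x7FFFFFFF, rep, zlib.crc32(s.encode())]
            ).random()
            for s in sample_ids
        ]
    )
    return u < p_item


def _base_cluster(X: np.ndarray, k: int, base: str, seed: int) -> np.ndarray:
    """Cluster samples (rows of X) into k groups; returns 0-based labels."""
    if base == "kmeans":
        km = KMeans(n_clusters=k, n_init=5, random_state=seed % (2**32)).fit(X)
        return km.labels_
    if base == "hclust_pearson_average":
        # Pearson distance = 1 - correlation across genes
        d = pdist(X, metric="correlation")
        return fcluster(average(d), t=k, criterion="maxclust") - 1
    raise ValueError(f"unknown base clusterer {base!r}")


def consensus_cluster(
    m: ExpressionMatrix,
    k_range,
    reps: int = 1000,
    p_item: float = 0.8,
    base: str = "hclust_pearson_average",
    seed: int = 0,
) -> ConsensusResult:
    """Subsample–cluster–tally consensus clustering over a range of k.

    M_k[i, j] = (#runs where i, j co-clustered) / (#runs where both drawn);
    the final per-k partition comes from average-linkage hierarchical
    clustering of 1 − M_k cut at k, with canonical size-ordered labels.
    """
    k_range = [int(k) for k in k_range]
    if reps < 10:
        raise ValueError("reps must be >= 10")
    if not (0 < p_item <= 1):
        raise ValueError("p_item must be in (0, 1]")
    n = m.n_samples
    X = m.values.T  # samples x genes
    sample_ids = list(m.sample_ids)

    masks = np.stack(
        [_include_mask(seed, r, sample_ids, p_item) for r in range(reps)]
    )
    if not masks.any(axis=0).all():
        missing = [sample_ids[i] for i in np.flatnonzero(~masks.any(axis=0))]
        raise ValueError(
            f"p_item={p_item} so small that samples were never drawn: {missing[:5]}"
        )
    co_sampled = masks.astype(float).T @ masks.astype(float)  # pair draw counts

    matrices: dict[int, np.ndarray] = {}
    assignments: dict[int, SubtypeAssignment] = {}
    co_cluster: dict[int, np.ndarray] = {}
    never = int((co_sampled[np.triu_indices(n, 1)] == 0).sum())
    if never:
        warnings.warn(f"{never} sample pairs were never co-sampled; consensus set to 0")

    for k in k_range:
        cc = np.zeros((n, n))
        for r in range(reps):
            idx = np.flatnonzero(masks[r])
            if len(idx) < k:
                continue
            lab = _base_cluster(X[idx], k, base, seed + 7919 * r + k)
            same = (lab[:, None] == lab[None, :]).astype(float)
            cc[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(co_sampled > 0, cc / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(M, np.where(np.diag(co_sampled) > 0, 1.0, 0.0))
        M = (M + M.T) / 2  # exact symmetry against float noise
        matrices[k] = M
        co_cluster[k] = cc
        d = squareform(np.clip(1.0 - M, 0.0, None), checks=False)
        raw = fcluster(average(d), t=k, criterion="maxclust") - 1
        kk = len(set(raw.tolist()))
        labels = _canonical_relabel(raw, max(kk, k))
        assignments[k] = SubtypeAssignment(sample_ids, labels, kk, space="expression")

    return ConsensusResult(
        sample_ids=sample_ids,
        k_values=k_range,
        matrices=matrices,
        assignments=assignments,
        co_cluster=co_cluster,
        co_sampled=co_sampled,
        reps=reps,
        p_item=p_item,
        base=base,
        never_cosampled=never,
    )


def cdf_area(r: ConsensusResult) -> tuple[dict[int, float], dict[int, float], int]:
    """Area under the consensus-value CDF per k, relative increases, choice.

    A(k) integrates the empirical CDF of the upper-triangle consensus values
    over [0, 1].  Δ(k) is A(k) itself at the smallest k, else
    (A(k) − A(k−1)) / A(k−1); the chosen k is the largest with Δ(k) ≥ 0.1,
    falling back (with a warning) to the smallest k when none qualifies.
    """
    if len(r.k_values) < 2:
        raise ValueError("need at least 2 k values to apply the CDF-area rule")
    n = len(r.sample_ids)
    iu = np.triu_indices(n, 1)
    areas: dict[int, float] = {}
    for k in r.k_values:
        v = np.sort(r.matrices[k][iu])
        # stepwise integral of the empirical CDF over [0, 1]
        mvals = len(v)
        area = 0.0
        prev = 0.0
        for i, x in enumerate(v):
            area += (x - prev) * (i / mvals)
            prev = x
        area += (1.0 - prev) * 1.0
        areas[k] = float(area)

    deltas: dict[int, float] = {}
    ks = sorted(r.k_values)
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev_a = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev_a) / prev_a if prev_a > 0 else 0.0

    qualifying = [k for k in ks if deltas[k] >= 0.1]
    if qualifying:
        chosen = max(qualifying)
    else:
        chosen = ks[0]
        warnings.warn("no k met the relative-increase >= 0.1 rule; returning smallest k")
    return areas, deltas, int(chosen)


def pca_embed(m: ExpressionMatrix, n_components: int) -> FeatureMatrix:
    """Project samples onto the top principal components of gene-centered data.

    Components are ordered by decreasing explained variance, with the sign
    convention that each component's largest-magnitude gene loading is
    positive, making the embedding deterministic.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(m.n_genes, m.n_samples):
        raise ValueError("n_components exceeds matrix rank bound")
    X = m.values.T  # samples x genes; PCA centers each gene
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    flip = np.ones(n_components)
    for i in range(n_components):
        j = int(np.argmax(np.abs(pca.components_[i])))
        if pca.components_[i, j] < 0:
            flip[i] = -1.0
    return FeatureMatrix(
        sample_ids=list(m.sample_ids),
        F=scores * flip,
        explained_variance=pca.explained_variance_.copy(),
    )
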