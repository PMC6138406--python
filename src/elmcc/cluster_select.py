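"""Clustering of the reduced feature space and choice of the cluster count.

k-means partitions the samples in feature space; the gap statistic compares
the log within-cluster dispersion against its expectation under a uniform
reference to pick k; silhouette widths quantify how tight and well separated
the resulting subtypes are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .elm_core import FeatureMatrix

__all__ = [
    "SubtypeAssignment",
    "GapResult",
    "kmeans_cluster",
    "gap_statistic",
    "silhouette_width",
    "write_assignment",
    "read_assignment",
]


@dataclass
class SubtypeAssignment:
    """Sample → subtype labels in {1..k}, tagged with the space they came from."""

    sample_ids: list[str]
    labels: np.ndarray
    k: int
    space: str = "elm_features"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("one label per sample required")
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=self.k) > self.k:
            raise ValueError(f"labels must lie in 1..{self.k}")
        # clusterings occupy every class; classifier predictions on a new
        # cohort may legitimately leave a class empty, so membership of
        # {1..k} is the hard invariant here and clusterers enforce fullness

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "class": self.labels})


@dataclass
class GapResult:
    """Gap curve over candidate k plus the simulation SEs and the choice."""

    k_values: list[int]
    gap: np.ndarray
    s_k: np.ndarray
    log_Wk: np.ndarray
    chosen_k: int
    B: int
    rule: str


def _canonical_relabel(raw: np.ndarray, k: int) -> np.ndarray:
    """Renumber clusters by descending size; ties by smallest member index."""
    sizes = np.bincount(raw, minlength=k)
    first = np.full(k, np.iinfo(np.int64).max)
    for i, c in enumerate(raw):
        if i < first[c]:
            first[c] = min(first[c], i)
    # np.argsort is stable on the composite key via lexsort
    order = sorted(range(k), key=lambda c: (-sizes[c], first[c]))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new + 1
    return remap[raw]


def _as_F(F) -> tuple[list[str], np.ndarray]:
    if isinstance(F, FeatureMatrix):
        return list(F.sample_ids), F.F
    X = np.asarray(F, dtype=float)
    return [f"sample_{i + 1}" for i in range(X.shape[0])], X


def kmeans_cluster(
    F,
    k: int,
    n_init: int = 25,
    seed: int = 0,
    space: str = "elm_features",
) -> SubtypeAssignment:
    """Best-of-``n_init`` k-means with canonical label numbering.

    Labels are renumbered by descending cluster size (ties broken by the
    smallest member index) so repeated runs are directly comparable.
    """
    sample_ids, X = _as_F(F)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    if k == 1:
        return SubtypeAssignment(sample_ids, np.ones(n, dtype=int), 1, space)
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        max_iter=300,
        tol=1e-6,
        init="k-means++",
        random_state=seed % (2**32),
    ).fit(X)
    if len(set(km.labels_.tolist())) < k:
        raise RuntimeError(f"k-means produced an empty cluster after {n_init} restarts")
    return SubtypeAssignment(sample_ids, _canonical_relabel(km.labels_, k), k, space)


def _within_dispersion(X: np.ndarray, k: int, n_init: int, seed: int) -> float:
    """Total within-cluster sum of squares about centroids (k-means W_k)."""
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    km = KMeans(
        n_clusters=k, n_init=n_init, max_iter=300, tol=1e-6,
        init="k-means++", random_state=seed % (2**32),
    ).fit(X)
    return float(km.inertia_)


def gap_statistic(
    F,
    k_range,
    B: int = 50,
    seed: int = 0,
    rule: str = "global_max",
    n_init: int = 10,
) -> GapResult:
    """Tibshirani's gap statistic with a uniform-box reference.

    Gap(k) = (1/B) Σ_b log W*_kb − log W_k, with W_k the within-cluster
    dispersion of k-means at k and B reference sets drawn uniformly over the
    observed per-feature range.  s_k = sd_b(log W*) · √(1 + 1/B).

    ``rule`` is ``global_max`` (the k with the largest Gap over the scanned
    range — the "peak") or ``tibshirani_1se`` (smallest k with
    Gap(k) ≥ Gap(k+1) − s_{k+1}).
    """
    _, X = _as_F(F)
    k_range = [int(k) for k in k_range]
    if any(b <= a for a, b in zip(k_range, k_range[1:])) or not k_range:
        raise ValueError("k_range must be non-empty and strictly increasing")
    if max(k_range) > X.shape[0] - 1:
        raise ValueError("max(k_range) must be <= N-1")
    if B < 10:
        raise ValueError("B must be >= 10")
    if rule not in ("global_max", "tibshirani_1se"):
        raise ValueError(f"unknown rule {rule!r}")

    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_Wk = np.array(
        [np.log(_within_dispersion(X, k, n_init, seed + 1000 + k)) for k in k_range]
    )
    log_Wstar = np.empty((B, len(k_range)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        for j, k in enumerate(k_range):
            log_Wstar[b, j] = np.log(
                _within_dispersion(ref, k, n_init, seed + 2000 + b * 101 + k)
            )
    gap = log_Wstar.mean(axis=0) - log_Wk
    s_k = log_Wstar.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    if rule == "global_max":
        chosen = k_range[int(np.argmax(gap))]
    else:
        chosen = k_range[-1]
        for j in range(len(k_range) - 1):
            if gap[j] >= gap[j + 1] - s_k[j + 1]:
                chosen = k_range[j]
                break
    return GapResult(
        k_values=k_range, gap=gap, s_k=s_k, log_Wk=log_Wk,
        chosen_k=int(chosen), B=B, rule=rule,
    )


def silhouette_width(F, a: SubtypeAssignment) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths s(i) = (b−a)/max(a,b) and their mean.

    Euclidean metric in the given space; samples in singleton clusters get
    s(i) = 0; the average is the unweighted mean over all samples.
    """
    sample_ids, X = _as_F(F)
    if a.k < 2:
        raise ValueError("silhouette requires k >= 2")
    if len(sample_ids) != len(a.sample_ids):
        raise ValueError("feature matrix and assignment disagree on sample count")
    widths = silhouette_samples(X, a.labels, metric="euclidean")
    return widths, float(widths.mean())


def write_assignment(a: SubtypeAssignment, path, delimiter: str = "\t") -> None:
    a.to_frame().to_csv(path, sep=delimiter, index=False)


def read_assignment(path, delimiter: str = "\t", space: str = "expression") -> SubtypeAssignment:
    df = pd.read_csv(path, sep=delimiter, comment="#")
    labels = df["class"].to_numpy(dtype=int)
    return SubtypeAssignment(
        sample_ids=[str(s) for s in df["sample_id"]],
        labels=labels,
        k=int(labels.max()),
        space=space,
    )
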