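"""Statistical evaluation of subtype assignments.

Covers: SigClust Monte-Carlo tests of pairwise cluster significance,
Kaplan–Meier curves and the g-group log-rank test for survival association,
partition concordance (adjusted Rand index + hypergeometric overlap tests),
and simple signature scores (mean expression over a gene list, e.g. the
two-gene TP53 activity score over CDKN1A and MDM2).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .cluster_select import SubtypeAssignment
from .elm_core import FeatureMatrix
from .expr_io import ClinicalTable, ExpressionMatrix

__all__ = [
    "SurvivalTable",
    "SigClustResult",
    "LogrankResult",
    "KaplanMeierCurve",
    "make_survival_table",
    "sigclust_pair",
    "pairwise_sigclust",
    "logrank_test",
    "km_estimate",
    "concordance",
    "signature_score",
]


@dataclass
class SurvivalTable:
    """Per-sample (time, event, group) records for survival comparison."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "time", "event", "group"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"survival table missing columns: {sorted(missing)}")
        self.data = self.data.copy()
        self.data["time"] = self.data["time"].astype(float)
        self.data["event"] = self.data["event"].astype(int)
        self.data["group"] = self.data["group"].astype(int)
        if (self.data["time"] <= 0).any():
            raise ValueError("survival times must be > 0")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def groups(self) -> list[int]:
        return sorted(self.data["group"].unique().tolist())


@dataclass
class SigClustResult:
    """One pairwise SigClust test: observed cluster index vs Gaussian null."""

    pair: tuple[int, int]
    cluster_index: float
    null_indices: np.ndarray
    p_value: float
    eigenvalue_floor: float
    variant: str = "soft"


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float
    group_sizes: dict[int, int]


@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate: right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray

    def evaluate(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def make_survival_table(
    clinical: ClinicalTable, a: SubtypeAssignment, drop_zero_times: bool = True
) -> SurvivalTable:
    """Join clinical records to subtype labels on sample ID (join reported)."""
    labels = pd.DataFrame({"sample_id": a.sample_ids, "group": a.labels})
    joined = clinical.data.merge(labels, on="sample_id", how="inner")
    n_lost = len(clinical.data) - len(joined)
    if n_lost:
        warnings.warn(f"{n_lost} clinical records had no subtype label and were dropped")
    if drop_zero_times:
        nz = joined["time"] > 0
        if (~nz).any():
            warnings.warn(f"dropped {(~nz).sum()} records with time <= 0")
        joined = joined[nz]
    return SurvivalTable(joined[["sample_id", "time", "event", "group"]])


# ---------------------------------------------------------------------------
# SigClust

def _cluster_index(X: np.ndarray, seed: int, n_init: int = 10) -> float:
    """2-means within-cluster SS divided by total SS about the grand mean."""
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed % (2**32)).fit(X)
    return float(km.inertia_) / total


def _soft_threshold(lam: np.ndarray, sigma2: float) -> np.ndarray:
    """Shift eigenvalues down by τ ≥ 0, floored at sigma2, preserving Σλ.

    Hard flooring adds variance to the small eigenvalues while keeping the
    (overestimated) large ones, which makes the Gaussian null more
    anisotropic than the data and the test conservative; the soft variant
    removes the added variance from the top eigenvalues instead.
    """
    total = float(lam.sum())
    if total <= len(lam) * sigma2:
        return np.full_like(lam, sigma2)
    lo, hi = 0.0, float(lam.max())
    for _ in range(200):
        mid = (lo + hi) / 2
        if np.maximum(lam - mid, sigma2).sum() > total:
            lo = mid
        else:
            hi = mid
    return np.maximum(lam - hi, sigma2)


def sigclust_pair(
    X: np.ndarray, nsim: int = 100, seed: int = 0, variant: str = "soft"
) -> SigClustResult:
    """Monte-Carlo test of whether a 2-means split is sharper than chance.

    The cluster index CI = (best 2-means within-SS) / (total SS) is compared
    with its distribution under a single multivariate Gaussian null whose
    covariance eigenvalues are floored at the background noise variance
    σ²_N = (MAD(mean-centered entries) / 0.6745)².  ``variant`` selects how
    eigenvalues meet the floor: ``soft`` (default) shifts the large ones
    down to preserve total variance — the better-calibrated choice at
    moderate dimension; ``hard`` floors in place.  p is the add-one
    Monte-Carlo proportion of null CIs at or below the observed one, so
    p ∈ (0, 1].
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    if nsim < 20:
        raise ValueError("nsim must be >= 20 for a stable p-value")
    if variant not in ("soft", "hard"):
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(seed)

    centered = X - X.mean(axis=0)
    e = centered.ravel()
    mad = np.median(np.abs(e - np.median(e)))
    sigma2_bg = (mad / 0.6745) ** 2

    cov = np.cov(centered, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    lam = np.linalg.eigvalsh(cov)
    if variant == "hard":
        lam_t = np.maximum(lam, sigma2_bg)
    else:
        lam_t = _soft_threshold(lam, sigma2_bg)

    observed = _cluster_index(X, seed=seed)
    null = np.empty(nsim)
    sd = np.sqrt(lam_t)
    for b in range(nsim):
        Z = rng.standard_normal((n, d)) * sd
        null[b] = _cluster_index(Z, seed=seed + 1 + b)
    p = (1.0 + float((null <= observed).sum())) / (1.0 + nsim)
    return SigClustResult(
        pair=(0, 0),
        cluster_index=observed,
        null_indices=null,
        p_value=p,
        eigenvalue_floor=float(sigma2_bg),
        variant=variant,
    )


def pairwise_sigclust(
    data, a: SubtypeAssignment, nsim: int = 100, seed: int = 0, variant: str = "soft"
) -> tuple[dict[tuple[int, int], SigClustResult], int]:
    """Run sigclust_pair for every unordered pair of subtypes.

    ``data`` may be an ExpressionMatrix (samples = columns) or a
    FeatureMatrix; the test runs in that space restricted to each pair.
    Returns the per-pair results and the count of pairs with p < 0.05.
    """
    if isinstance(data, ExpressionMatrix):
        ids, X = list(data.sample_ids), data.values.T
    elif isinstance(data, FeatureMatrix):
        ids, X = list(data.sample_ids), data.F
    else:
        X = np.asarray(data, dtype=float)
        ids = None  # bare arrays carry no IDs to cross-check
    if a.k < 2:
        raise ValueError("need at least 2 subtypes")
    if ids is not None and ids != list(a.sample_ids):
        raise ValueError("data and assignment sample IDs disagree")
    if X.shape[0] != len(a.sample_ids):
        raise ValueError("data and assignment disagree on sample count")

    results: dict[tuple[int, int], SigClustResult] = {}
    for ca, cb in itertools.combinations(range(1, a.k + 1), 2):
        mask = (a.labels == ca) | (a.labels == cb)
        if (a.labels == ca).sum() < 2 or (a.labels == cb).sum() < 2:
            warnings.warn(f"pair ({ca},{cb}) skipped: a class has < 2 members")
            continue
        res = sigclust_pair(X[mask], nsim=nsim, seed=seed + striding(ca, cb),
                            variant=variant)
        res.pair = (ca, cb)
        results[(ca, cb)] = res
    n_sig = sum(1 for r in results.values() if r.p_value < 0.05)
    return results, n_sig


def striding(ca: int, cb: int) -> int:
    """Deterministic per-pair seed offset."""
    return 10007 * ca + 101 * cb


# ---------------------------------------------------------------------------
# survival

def logrank_test(t: SurvivalTable) -> LogrankResult:
    """Standard (unweighted) g-group log-rank test.

    At each distinct event time, observed events per group are compared to
    their hypergeometric expectation given the risk sets; the statistic is
    chi-square with g − 1 degrees of freedom.
    """
    groups = t.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if t.data["event"].sum() < 1:
        raise ValueError("need at least one observed event")
    res = multivariate_logrank_test(
        t.data["time"], t.data["group"], t.data["event"]
    )
    sizes = t.data["group"].value_counts().to_dict()
    return LogrankResult(
        chi2=float(res.test_statistic),
        df=len(groups) - 1,
        p=float(res.p_value),
        group_sizes={int(g): int(c) for g, c in sizes.items()},
    )


def km_estimate(t: SurvivalTable, group: int) -> KaplanMeierCurve:
    """Kaplan–Meier product-limit survival curve for one group."""
    sub = t.data[t.data["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"no records in group {group}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    sf = kmf.survival_function_
    return KaplanMeierCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# concordance and signatures

def concordance(a: SubtypeAssignment, b) -> tuple[float, pd.DataFrame]:
    """Agreement with a reference labeling: ARI plus per-pair overlap tests.

    The hypergeometric upper-tail p for (class_i, reference_j) is the
    probability of an overlap at least as large as observed, drawing
    |class_i| samples without replacement from a population of N containing
    |reference_j| marked ones.
    """
    if isinstance(b, SubtypeAssignment):
        if set(a.sample_ids) != set(b.sample_ids):
            raise ValueError("assignments cover different sample sets")
        order = {s: i for i, s in enumerate(b.sample_ids)}
        ref = np.asarray(b.labels)[[order[s] for s in a.sample_ids]]
    else:
        ref = np.asarray(b)
        if ref.shape != (len(a.sample_ids),):
            raise ValueError("reference labels must match the sample set")
    ari = float(adjusted_rand_score(ref, a.labels))
    n = len(a.sample_ids)
    cls = sorted(set(a.labels.tolist()))
    refs = sorted(set(ref.tolist()))
    pmat = pd.DataFrame(index=cls, columns=refs, dtype=float)
    for ci in cls:
        for rj in refs:
            k_obs = int(((a.labels == ci) & (ref == rj)).sum())
            K = int((ref == rj).sum())
            m_draw = int((a.labels == ci).sum())
            pmat.loc[ci, rj] = float(stats.hypergeom.sf(k_obs - 1, n, K, m_draw))
    return ari, pmat


def signature_score(m: ExpressionMatrix, genes: list[str]) -> pd.Series:
    """Per-sample mean expression over the listed genes.

    Missing symbols are reported by warning; at least one must be present.
    The two-gene TP53 activity score is ``signature_score(m, ["CDKN1A", "MDM2"])``.
    """
    present = [g for g in genes if g in set(m.gene_ids)]
    absent = [g for g in genes if g not in set(m.gene_ids)]
    if not present:
        raise ValueError(f"none of the signature genes are present: {genes}")
    if absent:
        warnings.warn(f"signature genes absent from the matrix: {absent}")
    sub = m.subset_genes(present)
    return pd.Series(sub.values.mean(axis=0), index=m.sample_ids, name="score")
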