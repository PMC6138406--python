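"""Expression-matrix and clinical-table I/O, filtering, and cohort harmonization.

The universal currency of the pipeline is a genes × samples matrix of
log-scale expression (log2-TPM for RNA-Seq, normalized intensity for
microarrays).  Everything downstream — random-projection features,
clustering, consensus baselines, survival association — consumes this
container or tables joined to it by sample ID.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("elmcc")

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "MadFilterReport",
    "read_expression",
    "write_expression",
    "read_clinical",
    "rsem_to_log2tpm",
    "mad_filter",
    "harmonize_cohorts",
    "scaled_mad",
]

#: R-compatible consistency constant: scaled MAD of a Gaussian estimates its SD.
MAD_CONSISTENCY = 1.4826


@dataclass
class ExpressionMatrix:
    """Genes × samples real-valued expression with string IDs.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers (gene symbols).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Log-scale expression; finite, no missing entries.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing or non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])


@dataclass
class ClinicalTable:
    """Per-sample survival records: time-to-event plus optional covariates.

    ``time`` is non-negative (unit recorded in ``time_unit``); ``event`` is 1
    when the endpoint (death / recurrence) was observed, 0 when censored.
    """

    data: pd.DataFrame
    time_unit: str = "months"

    def __post_init__(self) -> None:
        required = {"sample_id", "time", "event"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        self.data = self.data.copy()
        self.data["sample_id"] = self.data["sample_id"].astype(str)
        self.data["time"] = self.data["time"].astype(float)
        self.data["event"] = self.data["event"].astype(int)
        if (self.data["time"] < 0).any():
            raise ValueError("survival times must be >= 0")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample IDs in clinical table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])


@dataclass
class MadFilterReport:
    """What the variability filter did: counts in/out plus its settings."""

    n_in: int
    n_out: int
    threshold: float
    consistency_constant: float

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_out": self.n_out,
            "threshold": self.threshold,
            "consistency_constant": self.consistency_constant,
        }


def scaled_mad(values: np.ndarray, constant: float = MAD_CONSISTENCY, axis: int = -1) -> np.ndarray:
    """Median absolute deviation about the median, scaled by ``constant``."""
    med = np.median(values, axis=axis, keepdims=True)
    return constant * np.median(np.abs(values - med), axis=axis)


def read_expression(
    path,
    orientation: str = "genes_in_rows",
    delimiter: str = "\t",
    drop_na_genes: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression matrix into canonical genes × samples form.

    The file must have a header row and the row identifier in its first
    column.  ``orientation`` says which axis the *file* puts genes on; the
    returned matrix is always genes × samples.  Duplicate gene rows are
    collapsed by keeping the row with the highest scaled MAD; duplicate
    sample IDs are an error.  Rows with missing values are rejected unless
    ``drop_na_genes`` is set, in which case they are dropped and counted.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    header_ids = header.rstrip("\n").split(delimiter)[1:]
    df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    df.columns = header_ids  # undo pandas' mangling of duplicate header names
    if orientation == "samples_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if df.columns.duplicated().any():
        dupes = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicate sample IDs: {dupes}")

    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    for col in non_numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric value in column {col!r}, row {row!r}: "
                f"{df.loc[row, col]!r}"
            )
        df[col] = coerced

    n_na = int(df.isna().any(axis=1).sum())
    if n_na:
        if not drop_na_genes:
            raise ValueError(
                f"{n_na} gene rows contain missing values; "
                "pass drop_na_genes=True to drop them"
            )
        df = df.dropna(axis=0)
        log.info('{"event": "drop_na_genes", "n_dropped": %d}', n_na)

    if df.index.duplicated().any():
        # keep the most variable row per duplicated symbol
        first_seen = list(dict.fromkeys(df.index))
        mads = scaled_mad(df.to_numpy(dtype=float), axis=1)
        order = np.argsort(-mads, kind="stable")
        n_before = len(df)
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
        df = df.loc[first_seen]  # first-appearance order, deterministic
        log.info(
            '{"event": "collapse_duplicate_genes", "n_collapsed": %d, '
            '"policy": "max_mad"}',
            n_before - len(df),
        )
    return ExpressionMatrix.from_frame(df)


def write_expression(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write in the canonical layout (header = sample IDs, column 1 = gene)."""
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def read_clinical(path, delimiter: str = "\t", time_unit: str = "months") -> ClinicalTable:
    """Read a clinical TSV with mandatory columns sample_id, time, event."""
    df = pd.read_csv(path, sep=delimiter, comment="#")
    return ClinicalTable(df, time_unit=time_unit)


def rsem_to_log2tpm(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Convert RSEM scaled estimates to log2-TPM.

    Scaled estimates (gene fractions in [0, 1]) are multiplied by 10^6 to
    give TPM, then log2-transformed after adding ``pseudocount``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if (m.values < 0).any():
        raise ValueError("RSEM scaled estimates must be non-negative")
    vals = np.log2(m.values * 1e6 + pseudocount)
    if not np.all(np.isfinite(vals)):
        raise ValueError("log2 produced non-finite values; use a positive pseudocount")
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), vals)


def mad_filter(
    m: ExpressionMatrix,
    threshold: float,
    consistency_constant: float = MAD_CONSISTENCY,
) -> tuple[ExpressionMatrix, MadFilterReport]:
    """Drop low-variability genes: keep rows with scaled MAD > ``threshold``.

    The scaled MAD of row x is ``consistency_constant * median(|x - median(x)|)``;
    with the default constant 1.4826 it is a robust estimate of the SD.
    Pass ``consistency_constant=1.0`` for the raw (unscaled) MAD.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples to measure variability")
    mads = scaled_mad(m.values, constant=consistency_constant, axis=1)
    keep = mads > threshold
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    report = MadFilterReport(
        n_in=m.n_genes,
        n_out=int(keep.sum()),
        threshold=float(threshold),
        consistency_constant=float(consistency_constant),
    )
    log.info(
        '{"event": "mad_filter", "n_in": %d, "n_out": %d, "threshold": %g, '
        '"constant": %g}',
        report.n_in, report.n_out, report.threshold, report.consistency_constant,
    )
    out = ExpressionMatrix(genes, list(m.sample_ids), m.values[keep])
    return out, report


def harmonize_cohorts(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    standardize: bool = False,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two cohorts to their shared genes, in identical row order.

    With ``standardize`` each gene row is z-scored within its own cohort so a
    classifier trained on one platform transfers to the other; zero-variance
    rows (in either cohort) are dropped from both and counted in the log.
    """
    shared = [g for g in train.gene_ids if g in set(test.gene_ids)]
    if not shared:
        raise ValueError("no shared gene IDs between cohorts")
    tr = train.subset_genes(shared)
    te = test.subset_genes(shared)
    if standardize:
        sd_tr = tr.values.std(axis=1, ddof=0)
        sd_te = te.values.std(axis=1, ddof=0)
        ok = (sd_tr > 0) & (sd_te > 0)
        n_dropped = int((~ok).sum())
        if n_dropped:
            log.info('{"event": "drop_zero_variance_genes", "n_dropped": %d}', n_dropped)
            warnings.warn(f"dropped {n_dropped} zero-variance genes during standardization")
        genes = [g for g, k in zip(shared, ok) if k]
        if not genes:
            raise ValueError("no genes left after dropping zero-variance rows")
        tr = tr.subset_genes(genes)
        te = te.subset_genes(genes)

        def _z(v: np.ndarray) -> np.ndarray:
            return (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, ddof=0, keepdims=True)

        tr = ExpressionMatrix(genes, list(tr.sample_ids), _z(tr.values))
        te = ExpressionMatrix(genes, list(te.sample_ids), _z(te.values))
    return tr, te
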