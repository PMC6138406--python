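"""Extreme-learning-machine core: random hidden layer, features, training.

An ELM is a single-hidden-layer feedforward network whose input weights W
and biases b are drawn at random and never trained; only the output weights
β are fit, analytically, as the minimum-norm least-squares solution
β = H⁺T where H is the hidden-layer output matrix and ⁺ the Moore–Penrose
pseudoinverse.

For dimension reduction the hidden layer is deliberately small (Ñ = 3 in
the tumor-subtyping workflow): the per-sample hidden pre-activations

    F[j, i] = w_i · x_j + b_i

form a random projection of each sample's expression vector x_j onto an
Ñ-dimensional feature space, which is what gets clustered downstream.  For
classification the hidden layer uses the hard-limit step activation and the
number of output nodes equals the number of subtypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .expr_io import ExpressionMatrix

__all__ = [
    "ElmWeights",
    "ElmModel",
    "FeatureMatrix",
    "init_elm",
    "hidden_features",
    "fit_regression",
    "fit_classifier",
    "predict",
    "save_model",
    "load_model",
    "write_features",
    "read_features",
]

#: singular values below RCOND × s_max are treated as zero in the pseudoinverse
RCOND = 1e-10


@dataclass
class ElmWeights:
    """Random input weights W (n_hidden × n_input) and biases b (n_hidden)."""

    W: np.ndarray
    b: np.ndarray
    seed: int
    distribution: str = "uniform"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.b.ndim != 1 or self.W.shape[0] != self.b.shape[0]:
            raise ValueError("W must be n_hidden x n_input and b length n_hidden")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b))):
            raise ValueError("weights must be finite")

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_input(self) -> int:
        return self.W.shape[1]


@dataclass
class FeatureMatrix:
    """Samples × n_hidden hidden-layer observations (the reduced space)."""

    sample_ids: list[str]
    F: np.ndarray
    explained_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2 or self.F.shape[0] != len(self.sample_ids):
            raise ValueError("F must have one row per sample")

    @property
    def n_samples(self) -> int:
        return self.F.shape[0]

    @property
    def n_features(self) -> int:
        return self.F.shape[1]


@dataclass
class ElmModel:
    """Trained ELM: random weights plus least-squares output weights β."""

    weights: ElmWeights
    beta: np.ndarray
    activation: str
    n_output: int
    train_rmse: float | None = None
    gene_ids: list[str] | None = None
    classes: list[int] | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.weights.n_hidden, self.n_output):
            raise ValueError(
                f"beta shape {self.beta.shape} inconsistent with "
                f"({self.weights.n_hidden}, {self.n_output})"
            )
        if self.activation not in ("linear", "sigmoid", "hardlim"):
            raise ValueError(f"unknown activation {self.activation!r}")


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "linear":
        return z
    if activation == "sigmoid":
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-z))
    if activation == "hardlim":
        return (z >= 0).astype(float)
    raise ValueError(f"unknown activation {activation!r}")


def init_elm(
    n_input: int,
    n_hidden: int,
    seed: int,
    distribution: str = "uniform",
) -> ElmWeights:
    """Draw random input weights and biases, reproducibly from ``seed``.

    ``distribution`` is ``uniform`` for i.i.d. U(−1, 1) (the ELM-literature
    convention) or ``gaussian`` for i.i.d. N(0, 1).
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if n_input < 1:
        raise ValueError("n_input must be >= 1")
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        W = rng.uniform(-1.0, 1.0, size=(n_hidden, n_input))
        b = rng.uniform(-1.0, 1.0, size=n_hidden)
    elif distribution == "gaussian":
        W = rng.standard_normal(size=(n_hidden, n_input))
        b = rng.standard_normal(size=n_hidden)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return ElmWeights(W=W, b=b, seed=seed, distribution=distribution)


def _as_sample_matrix(m) -> tuple[list[str], np.ndarray]:
    """Return (sample_ids, X) with samples in rows."""
    if isinstance(m, ExpressionMatrix):
        return list(m.sample_ids), m.values.T
    if isinstance(m, FeatureMatrix):
        return list(m.sample_ids), m.F
    X = np.asarray(m, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return [f"sample_{i + 1}" for i in range(X.shape[0])], X


def hidden_features(
    w: ElmWeights,
    m: ExpressionMatrix,
    apply_activation: bool = False,
    activation: str = "sigmoid",
) -> FeatureMatrix:
    """Project every sample onto the hidden layer: F[j, i] = w_i·x_j + b_i.

    By default the literal pre-activations are returned (a linear random
    projection); ``apply_activation=True`` passes them through ``activation``
    for the conventional ELM hidden output.
    """
    if w.n_input != m.n_genes:
        raise ValueError(
            f"weight input dimension {w.n_input} does not match "
            f"gene count {m.n_genes}"
        )
    F = m.values.T @ w.W.T + w.b  # (N, n_hidden)
    if apply_activation:
        F = _activate(F, activation)
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite hidden features; rescale the input")
    return FeatureMatrix(sample_ids=list(m.sample_ids), F=F)


def _hidden_matrix(w: ElmWeights, X: np.ndarray, activation: str) -> np.ndarray:
    H = _activate(X @ w.W.T + w.b, activation)
    if not np.all(np.isfinite(H)):
        raise ValueError(
            "non-finite hidden-layer output (activation overflow); "
            "scale or standardize the input"
        )
    return H


def fit_regression(
    w: ElmWeights,
    m: ExpressionMatrix,
    activation: str = "linear",
) -> ElmModel:
    """Train the ELM in autoencoding mode: targets equal the inputs.

    β = H⁺T with T = Xᵀ (one target row per sample), so β is the
    minimum-norm least-squares solution of min‖Hβ − T‖_F.  The training
    reconstruction RMSE is recorded on the model.
    """
    if w.n_input != m.n_genes:
        raise ValueError(
            f"weight input dimension {w.n_input} != gene count {m.n_genes}"
        )
    X = m.values.T  # (N, n_genes)
    H = _hidden_matrix(w, X, activation)
    T = X
    beta = np.linalg.pinv(H, rcond=RCOND) @ T
    resid = H @ beta - T
    rmse = float(np.sqrt(np.mean(resid**2)))
    return ElmModel(
        weights=w,
        beta=beta,
        activation=activation,
        n_output=T.shape[1],
        train_rmse=rmse,
        gene_ids=list(m.gene_ids),
    )


def fit_classifier(w: ElmWeights, features_or_expr, labels) -> ElmModel:
    """Train a hard-limit ELM classifier on labeled samples.

    Targets are one-hot rows with one output node per subtype; the hidden
    layer uses the step activation g(z) = 1[z ≥ 0] and β = H⁺T.  ``labels``
    is a SubtypeAssignment or an integer vector over {1..k}; every class
    must be represented.
    """
    sample_ids, X = _as_sample_matrix(features_or_expr)
    y = np.asarray(getattr(labels, "labels", labels), dtype=int)
    if y.shape != (X.shape[0],):
        raise ValueError("one label per sample required")
    classes = sorted(set(int(v) for v in y))
    k = len(classes)
    if k < 2:
        raise ValueError("need at least 2 distinct classes")
    if classes != list(range(1, k + 1)):
        raise ValueError(f"labels must cover {{1..k}} with no gaps, got {classes}")
    H = _hidden_matrix(w, X, "hardlim")
    T = np.zeros((X.shape[0], k))
    T[np.arange(X.shape[0]), y - 1] = 1.0
    beta = np.linalg.pinv(H, rcond=RCOND) @ T
    gene_ids = (
        list(features_or_expr.gene_ids)
        if isinstance(features_or_expr, ExpressionMatrix)
        else None
    )
    return ElmModel(
        weights=w,
        beta=beta,
        activation="hardlim",
        n_output=k,
        gene_ids=gene_ids,
        classes=classes,
    )


def predict(model: ElmModel, m):
    """Assign each sample to the subtype with the largest output-node value.

    Ties break toward the smallest class index, so predictions are
    deterministic.  Returns a ``SubtypeAssignment``.
    """
    from .cluster_select import SubtypeAssignment

    if model.classes is None:
        raise ValueError("model was not trained as a classifier")
    sample_ids, X = _as_sample_matrix(m)
    if isinstance(m, ExpressionMatrix) and model.gene_ids is not None:
        if list(m.gene_ids) != model.gene_ids:
            if set(m.gene_ids) >= set(model.gene_ids):
                m2 = m.subset_genes(model.gene_ids)
                sample_ids, X = list(m2.sample_ids), m2.values.T
            else:
                raise ValueError("input is missing genes the model was trained on")
    if X.shape[1] != model.weights.n_input:
        raise ValueError(
            f"input dimension {X.shape[1]} does not match model "
            f"input dimension {model.weights.n_input}"
        )
    H = _hidden_matrix(model.weights, X, model.activation)
    scores = H @ model.beta
    labels = np.argmax(scores, axis=1) + 1  # argmax takes the first maximum
    return SubtypeAssignment(
        sample_ids=sample_ids,
        labels=labels,
        k=model.n_output,
        space="expression" if isinstance(m, ExpressionMatrix) else "elm_features",
    )


# ---------------------------------------------------------------------------
# serialization: models as JSON, feature matrices as TSV

def _fmt(a: np.ndarray) -> list:
    return [f"{v:.17g}" for v in np.asarray(a, dtype=float).ravel()]


def save_model(model: ElmModel, path) -> None:
    """Serialize a trained model (weights, β, vocabulary) as portable JSON."""
    w = model.weights
    doc = {
        "seed": w.seed,
        "distribution": w.distribution,
        "n_hidden": w.n_hidden,
        "n_input": w.n_input,
        "W": _fmt(w.W),
        "b": _fmt(w.b),
        "beta": _fmt(model.beta),
        "n_output": model.n_output,
        "activation": model.activation,
        "train_rmse": model.train_rmse,
        "gene_ids": model.gene_ids,
        "classes": model.classes,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> ElmModel:
    with open(path) as fh:
        doc = json.load(fh)
    nh, ni, no = doc["n_hidden"], doc["n_input"], doc["n_output"]
    w = ElmWeights(
        W=np.array(doc["W"], dtype=float).reshape(nh, ni),
        b=np.array(doc["b"], dtype=float),
        seed=doc["seed"],
        distribution=doc["distribution"],
    )
    return ElmModel(
        weights=w,
        beta=np.array(doc["beta"], dtype=float).reshape(nh, no),
        activation=doc["activation"],
        n_output=no,
        train_rmse=doc.get("train_rmse"),
        gene_ids=doc.get("gene_ids"),
        classes=doc.get("classes"),
    )


def write_features(fm: FeatureMatrix, path, delimiter: str = "\t") -> None:
    """Write as TSV: sample_id then F1..Fd columns."""
    import pandas as pd

    cols = [f"F{i + 1}" for i in range(fm.n_features)]
    df = pd.DataFrame(fm.F, index=fm.sample_ids, columns=cols)
    df.index.name = "sample_id"
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def read_features(path, delimiter: str = "\t") -> FeatureMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    return FeatureMatrix(sample_ids=[str(s) for s in df.index], F=df.to_numpy(dtype=float))
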