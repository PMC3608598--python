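"""Fitting, prediction and feature extraction for the LP-SVM models.

The binary model is the classic linear decision rule
``f(x) = beta0 + beta . x`` trained with hinge loss and an L1 penalty; the
multiclass model trains c - 1 such rules jointly under the L-infinity,1
penalty, with one reference class whose parameters are pinned at zero for
identifiability.  Class probabilities follow the multinomial-logit form
with the reference score fixed at 0, and the predicted class is the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lp_core
from .io_tables import LabelSet

#: Relative magnitude below which an LP coefficient is reported as zero.
#: Interior-point solutions are only approximately sparse.
SNAP_THRESHOLD = 1e-6


@dataclass
class ClassEncoding:
    """One-against-rest +/-1 encoding with the reference class dropped."""

    classes: list[str]  # reference class last
    Y: np.ndarray  # n x (c-1); column k: +1 iff sample in classes[k]

    @property
    def reference(self) -> str:
        return self.classes[-1]


@dataclass
class BinaryModel:
    """L1 LP-SVM: intercept beta0 and m sparse coefficients beta."""

    beta0: float
    beta: np.ndarray
    lam: float
    transform: str
    feature_ids: list[str]
    classes: list[str] = field(default_factory=lambda: ["+1", "-1"])

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)) or not np.isfinite(self.beta0):
            raise ValueError("model parameters must be finite")


@dataclass
class MulticlassModel:
    """Joint L-infinity,1 LP-SVM over c classes (last = reference).

    ``B`` is m x (c-1); the reference class has an implicit zero column and
    zero intercept.
    """

    classes: list[str]
    beta0: np.ndarray  # c-1 intercepts
    B: np.ndarray  # m x (c-1)
    lam: float
    transform: str
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        c = len(self.classes)
        if self.B.shape != (len(self.feature_ids), c - 1):
            raise ValueError("B must be m x (c-1)")
        if self.beta0.shape != (c - 1,):
            raise ValueError("beta0 must have c-1 entries")
        if not (np.all(np.isfinite(self.B)) and np.all(np.isfinite(self.beta0))):
            raise ValueError("model parameters must be finite")


def encode_labels(labels: LabelSet, reference: str | None = None) -> ClassEncoding:
    """Encode c-class labels into an n x (c-1) sign matrix.

    ``y_ik = +1`` iff sample i belongs to class k, else -1.  The reference
    class (default: last in first-appearance order) gets no column.
    """
    if labels.n_classes < 2:
        raise ValueError("need at least 2 classes to encode")
    classes = list(labels.classes)
    if reference is not None:
        if reference not in classes:
            raise ValueError(f"reference class {reference!r} not among {classes}")
        classes = [c for c in classes if c != reference] + [reference]
    present = set(labels.labels)
    empty = [c for c in classes if c not in present]
    if empty:
        raise ValueError(f"classes with no samples: {empty}")
    y = labels.as_array()
    Y = np.where(y[:, None] == np.asarray(classes[:-1], dtype=object), 1.0, -1.0)
    return ClassEncoding(classes=classes, Y=Y)


def hinge_loss(Xt: np.ndarray, y: np.ndarray, beta0: float, beta: np.ndarray) -> float:
    """Soft-margin loss sum_i max(0, 1 - y_i f(x_i))."""
    scores = Xt @ beta + beta0
    return float(np.maximum(0.0, 1.0 - y * scores).sum())


def binary_objective(
    Xt: np.ndarray, y: np.ndarray, beta0: float, beta: np.ndarray, lam: float
) -> float:
    """Hinge loss plus lam * ||beta||_1 (the quantity the LP minimizes)."""
    return hinge_loss(Xt, y, beta0, beta) + lam * float(np.abs(beta).sum())


def multiclass_objective(
    Xt: np.ndarray, Y: np.ndarray, beta0: np.ndarray, B: np.ndarray, lam: float
) -> float:
    """Summed hinge over subproblems plus lam * sum_j max_k |B_jk|."""
    total = sum(
        hinge_loss(Xt, Y[:, k], float(beta0[k]), B[:, k])
        for k in range(Y.shape[1])
    )
    return float(total) + lam * float(np.abs(B).max(axis=1).sum())


def fit_binary(
    Xt: np.ndarray,
    y: np.ndarray,
    lam: float,
    *,
    transform: str = "arcsine",
    feature_ids: list[str] | None = None,
    backend: str = lp_core.DEFAULT_BACKEND,
) -> BinaryModel:
    """Fit the binary L1 LP-SVM at regularization weight ``lam``."""
    Xt = np.asarray(Xt, dtype=float)
    y = np.asarray(y, dtype=float)
    lp = lp_core.assemble_binary_lp(Xt, y, lam)
    sol = lp_core.solve_lp(lp, backend=backend)
    if sol.status != "optimal":
        raise RuntimeError(f"LP solver failed with status {sol.status!r}")
    vm = lp.var_map
    beta = sol.variables[vm["u"]] - sol.variables[vm["v"]]
    beta0 = float(
        sol.variables[vm["intercept_pos"]][0]
        - sol.variables[vm["intercept_neg"]][0]
    )
    m = Xt.shape[1]
    if feature_ids is None:
        feature_ids = [f"f{j + 1}" for j in range(m)]
    return BinaryModel(
        beta0=beta0, beta=beta, lam=lam, transform=transform,
        feature_ids=list(feature_ids),
    )


def decision_binary(model: BinaryModel, Xt: np.ndarray) -> np.ndarray:
    """Decision scores f(x) = beta0 + beta . x, one per sample."""
    Xt = np.asarray(Xt, dtype=float)
    if Xt.shape[1] != model.beta.size:
        raise ValueError(
            f"feature mismatch: model has {model.beta.size} features, "
            f"data has {Xt.shape[1]}"
        )
    return Xt @ model.beta + model.beta0


def predict_binary(model: BinaryModel, Xt: np.ndarray) -> np.ndarray:
    """+1 where the score is >= 0 (ties at exactly 0 go to +1), else -1."""
    scores = decision_binary(model, Xt)
    return np.where(scores >= 0, 1.0, -1.0)


def fit_multiclass(
    Xt: np.ndarray,
    labels: LabelSet,
    lam: float,
    *,
    reference: str | None = None,
    transform: str = "arcsine",
    feature_ids: list[str] | None = None,
    backend: str = lp_core.DEFAULT_BACKEND,
) -> MulticlassModel:
    """Fit the joint L-infinity,1 multiclass LP-SVM.

    All c - 1 one-against-rest subproblems are solved in a single LP whose
    penalty couples them through the per-feature bound t_j, so the
    subproblems select a common feature set.
    """
    Xt = np.asarray(Xt, dtype=float)
    enc = encode_labels(labels, reference=reference)
    lp = lp_core.assemble_multiclass_lp(Xt, enc.Y, lam)
    sol = lp_core.solve_lp(lp, backend=backend)
    if sol.status != "optimal":
        raise RuntimeError(f"LP solver failed with status {sol.status!r}")
    vm = lp.var_map
    n, m = Xt.shape
    K = enc.Y.shape[1]
    beta = sol.variables[vm["u"]] - sol.variables[vm["v"]]
    B = beta.reshape(K, m).T  # k-th block of u/v is subproblem k
    beta0 = (
        sol.variables[vm["intercept_pos"]] - sol.variables[vm["intercept_neg"]]
    )
    if feature_ids is None:
        feature_ids = [f"f{j + 1}" for j in range(m)]
    return MulticlassModel(
        classes=enc.classes, beta0=beta0, B=B, lam=lam,
        transform=transform, feature_ids=list(feature_ids),
    )


def decision_multiclass(model: MulticlassModel, Xt: np.ndarray) -> np.ndarray:
    """Raw scores f_k for all c classes (reference column fixed at 0)."""
    Xt = np.asarray(Xt, dtype=float)
    if Xt.shape[1] != model.B.shape[0]:
        raise ValueError(
            f"feature mismatch: model has {model.B.shape[0]} features, "
            f"data has {Xt.shape[1]}"
        )
    scores = Xt @ model.B + model.beta0
    return np.column_stack([scores, np.zeros(Xt.shape[0])])


def predict_proba(model: MulticlassModel, Xt: np.ndarray) -> np.ndarray:
    """Class probabilities p_k = exp(f_k) / sum_l exp(f_l), rows sum to 1.

    The reference class's score is 0; the softmax is max-shifted so finite
    scores never overflow.
    """
    f = decision_multiclass(model, Xt)
    f = f - f.max(axis=1, keepdims=True)
    e = np.exp(f)
    return e / e.sum(axis=1, keepdims=True)


def predict_class(model: MulticlassModel, Xt: np.ndarray) -> np.ndarray:
    """argmax_k p_k; ties broken by earliest class in ``model.classes``."""
    proba = predict_proba(model, Xt)
    idx = np.argmax(proba, axis=1)
    return np.asarray([model.classes[i] for i in idx], dtype=object)


def coefficient_magnitudes(model: BinaryModel | MulticlassModel) -> np.ndarray:
    """Per-feature magnitude: |beta_j| (binary) or max_k |beta_jk|."""
    if isinstance(model, BinaryModel):
        return np.abs(model.beta)
    return np.abs(model.B).max(axis=1)


def selected_features(
    model: BinaryModel | MulticlassModel, threshold: float = SNAP_THRESHOLD
) -> list[str]:
    """Features with coefficient magnitude above the snap threshold.

    The cutoff is ``threshold * max(1, max magnitude)``; the list is
    ordered by magnitude, largest first.
    """
    mags = coefficient_magnitudes(model)
    cutoff = threshold * max(1.0, float(mags.max(initial=0.0)))
    idx = np.nonzero(mags > cutoff)[0]
    order = idx[np.argsort(-mags[idx], kind="stable")]
    return [model.feature_ids[j] for j in order]
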