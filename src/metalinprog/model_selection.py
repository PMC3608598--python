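"""Regularization selection and the repeated-random-split protocol.

The weight lambda trades training hinge loss against sparsity: too small
overfits with little sparsity, too large empties the model.  It is chosen
by stratified k-fold cross-validation minimizing held-out
misclassification, ties going to the largest (sparsest) lambda.  The
evaluation protocol repeatedly splits the data into stratified
training/test parts, selects lambda on the training part only, fits, and
records per-feature relevance counts (how often each feature is selected)
together with test error and AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from . import evaluation, lp_core, models, preprocess, simdata
from .io_tables import LabelSet


@dataclass
class CVReport:
    """Per-lambda cross-validated error and the selected optimum."""

    lam_grid: list[float]
    mean_error: list[float]
    se_error: list[float]
    best_lam: float
    folds: int
    seed: int


@dataclass
class RelevanceReport:
    """Aggregate of the repeated-split protocol.

    ``counts[f]`` is the number of repeats in which feature f received a
    nonzero coefficient (0 <= count <= repeats).
    """

    counts: dict[str, int]
    repeats: int
    split_fraction: float
    mean_test_error: float
    mean_test_auc: float
    seed: int
    lam_used: list[float] = field(default_factory=list)
    n_selected: list[int] = field(default_factory=list)
    test_errors: list[float] = field(default_factory=list)
    test_aucs: list[float] = field(default_factory=list)


def _subset_labels(labels: LabelSet, idx: np.ndarray) -> LabelSet:
    return LabelSet(
        sample_ids=[labels.sample_ids[i] for i in idx],
        labels=[labels.labels[i] for i in idx],
        classes=list(labels.classes),
    )


def _binary_signs(labels: LabelSet) -> np.ndarray:
    """+1 for the first class, -1 for the second (c must equal 2)."""
    if labels.n_classes != 2:
        raise ValueError("binary encoding needs exactly 2 classes")
    return np.where(labels.as_array() == labels.classes[0], 1.0, -1.0)


def effective_lambda(lam: float, n: int, m: int) -> float:
    """Convert a size-normalized sparsity level into the raw LP weight.

    The LP objective is a raw sum of n hinge slacks against a raw sum of m
    coefficient magnitudes, so the weight at which the penalty starts
    emptying the model grows with n and shrinks with m.  Expressing the
    user-facing grid on the per-sample-per-feature scale
    ``lp_weight = lam * n / m`` makes the same ladder (e.g. 1..10)
    meaningful across problem sizes; the selection machinery uses this
    convention throughout, while :func:`metalinprog.models.fit_binary` and
    ``fit_multiclass`` always take the raw weight.
    """
    return float(lam) * n / m


def fit_model(
    Xt: np.ndarray,
    labels: LabelSet,
    lam: float,
    *,
    normalized: bool = False,
    reference: str | None = None,
    feature_ids: list[str] | None = None,
    backend: str = lp_core.DEFAULT_BACKEND,
    transform: str = "arcsine",
):
    """Fit the binary model when c = 2, the joint multiclass model otherwise.

    With ``normalized=True``, ``lam`` is a size-normalized sparsity level
    (see :func:`effective_lambda`) rather than the raw LP weight.
    ``reference`` picks the multiclass reference class (default: last).
    """
    if labels.n_classes < 2:
        raise ValueError("model fitting requires at least 2 classes")
    if normalized:
        lam = effective_lambda(lam, *np.asarray(Xt).shape)
    if labels.n_classes == 2:
        y = _binary_signs(labels)
        model = models.fit_binary(
            Xt, y, lam, transform=transform, feature_ids=feature_ids,
            backend=backend,
        )
        model.classes = list(labels.classes)
        return model
    return models.fit_multiclass(
        Xt, labels, lam, reference=reference, transform=transform,
        feature_ids=feature_ids, backend=backend,
    )


def predict_labels(model, Xt: np.ndarray) -> np.ndarray:
    """Predicted class names for either model kind."""
    if isinstance(model, models.BinaryModel):
        signs = models.predict_binary(model, Xt)
        return np.where(signs > 0, model.classes[0], model.classes[1]).astype(
            object
        )
    return models.predict_class(model, Xt)


def test_auc(model, Xt: np.ndarray, labels: LabelSet) -> float:
    """Held-out AUC: binary decision-score AUC, or macro one-vs-rest AUC."""
    if isinstance(model, models.BinaryModel):
        scores = models.decision_binary(model, Xt)
        y = np.where(labels.as_array() == model.classes[0], 1.0, -1.0)
        return evaluation.roc_auc(scores, y).auc
    proba = models.predict_proba(model, Xt)
    return evaluation.multiclass_auc(proba, labels.as_array(), model.classes)


def _folds(labels: LabelSet, k: int, seed: int):
    n = len(labels.labels)
    y = labels.as_array()
    if k == n:
        return list(LeaveOneOut().split(np.zeros(n)))
    min_count = min(labels.labels.count(c) for c in labels.classes)
    if min_count < k:
        raise ValueError(
            f"smallest class has {min_count} samples < {k} folds; "
            f"use k <= {min_count}"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(n), y))


def cv_lambda(
    Xt: np.ndarray,
    labels: LabelSet,
    lam_grid,
    k: int = 10,
    seed: int = 0,
    *,
    backend: str = lp_core.DEFAULT_BACKEND,
) -> CVReport:
    """Choose lambda by stratified k-fold CV (k = n gives leave-one-out).

    For each lambda the model is fitted on k-1 folds and scored by
    misclassification on the held-out fold; the best lambda minimizes the
    mean error, ties broken toward the largest (sparsest) value.
    """
    lam_grid = [float(l) for l in lam_grid]
    if not lam_grid:
        raise ValueError("lam_grid must be nonempty")
    if any(l < 0 for l in lam_grid):
        raise ValueError("lambda values must be >= 0")
    if k < 2:
        raise ValueError("need at least 2 folds")
    Xt = np.asarray(Xt, dtype=float)
    splits = _folds(labels, k, seed)
    fold_errors = np.empty((len(lam_grid), len(splits)))
    for f, (train, test) in enumerate(splits):
        lab_tr = _subset_labels(labels, train)
        lab_te = _subset_labels(labels, test)
        for g, lam in enumerate(lam_grid):
            model = fit_model(
                Xt[train], lab_tr, lam, normalized=True, backend=backend
            )
            pred = predict_labels(model, Xt[test])
            fold_errors[g, f] = evaluation.predictive_error(
                pred, lab_te.as_array()
            )
    mean_error = fold_errors.mean(axis=1)
    se_error = fold_errors.std(axis=1, ddof=1) / np.sqrt(len(splits))
    best = max(
        (lam for lam, e in zip(lam_grid, mean_error) if e == mean_error.min()),
    )
    return CVReport(
        lam_grid=lam_grid,
        mean_error=[float(e) for e in mean_error],
        se_error=[float(e) for e in se_error],
        best_lam=float(best),
        folds=k,
        seed=seed,
    )


def _stratified_split(labels: LabelSet, train_fraction: float, rng):
    """Index split keeping every class on both sides."""
    y = labels.as_array()
    train_idx, test_idx = [], []
    for cls in labels.classes:
        members = np.nonzero(y == cls)[0]
        perm = rng.permutation(members)
        n_train = int(round(train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


def repeated_split_eval(
    Xt: np.ndarray,
    labels: LabelSet,
    lam,
    repeats: int = 100,
    split_fraction: float = 0.5,
    seed: int = 0,
    *,
    lam_grid=None,
    folds: int = 10,
    feature_ids: list[str] | None = None,
    backend: str = lp_core.DEFAULT_BACKEND,
) -> RelevanceReport:
    """Repeated stratified random-split evaluation with relevance counts.

    ``lam`` may be a number (fixed), ``"cv"`` (re-selected on each repeat's
    training part) or ``"cv_once"`` (selected on the first repeat's
    training part, then reused).  The test part never enters lambda
    selection or fitting.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    Xt = np.asarray(Xt, dtype=float)
    if feature_ids is None:
        feature_ids = [f"f{j + 1}" for j in range(Xt.shape[1])]
    if lam in ("cv", "cv_once") and lam_grid is None:
        lam_grid = DEFAULT_LAM_GRID
    rng = np.random.default_rng(seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=repeats)
    counts = {f: 0 for f in feature_ids}
    report = RelevanceReport(
        counts=counts, repeats=repeats, split_fraction=split_fraction,
        mean_test_error=np.nan, mean_test_auc=np.nan, seed=seed,
    )
    fixed_lam = None if lam in ("cv", "cv_once") else float(lam)
    for r in range(repeats):
        r_rng = np.random.default_rng(repeat_seeds[r])
        train, test = _stratified_split(labels, split_fraction, r_rng)
        lab_tr = _subset_labels(labels, train)
        lab_te = _subset_labels(labels, test)
        if fixed_lam is None:
            cv = cv_lambda(
                Xt[train], lab_tr, lam_grid, k=folds,
                seed=int(repeat_seeds[r]), backend=backend,
            )
            lam_r = cv.best_lam
            if lam == "cv_once":
                fixed_lam = lam_r
        else:
            lam_r = fixed_lam
        model = fit_model(
            Xt[train], lab_tr, lam_r, normalized=True,
            feature_ids=feature_ids, backend=backend,
        )
        chosen = models.selected_features(model)
        for f in chosen:
            counts[f] += 1
        pred = predict_labels(model, Xt[test])
        report.lam_used.append(float(lam_r))
        report.n_selected.append(len(chosen))
        report.test_errors.append(
            evaluation.predictive_error(pred, lab_te.as_array())
        )
        report.test_aucs.append(test_auc(model, Xt[test], lab_te))
    report.mean_test_error = float(np.mean(report.test_errors))
    report.mean_test_auc = float(np.mean(report.test_aucs))
    # relevance counts are reported largest-first (stable within ties)
    report.counts = dict(
        sorted(counts.items(), key=lambda kv: -kv[1])
    )
    return report


#: Default lambda ladder bracketing the reference optima (5 and 7).
DEFAULT_LAM_GRID = (0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20)

#: Grid used by the simulation study (integer ladder 1..10).
STUDY_LAM_GRID = tuple(float(v) for v in range(1, 11))


@dataclass
class SimulationStudyResult:
    """Aggregate of the planted-feature recovery study."""

    mean_auc: float
    mean_n_selected: float
    recovery: dict[str, int]  # planted feature -> repeats recovered in
    repeats: int
    folds: int
    lam_used: list[float]
    aucs: list[float]
    n_selected: list[int]
    test_errors: list[float]
    seed: int


def run_simulation_study(
    spec: simdata.SimulationSpec,
    repeats: int = 20,
    lam_grid=STUDY_LAM_GRID,
    folds: int | None = None,
    seed: int = 0,
    *,
    lam_mode: str | None = None,
    backend: str = lp_core.DEFAULT_BACKEND,
) -> SimulationStudyResult:
    """Planted-feature recovery under repeated fresh simulations.

    Each repeat draws a fresh dataset from ``spec``, arcsine-transforms the
    proportions, splits it 50/50 stratified, fits on the training half and
    scores the held-out half.  Lambda is selected on training data only by
    stratified CV over ``lam_grid``.  ``lam_mode="cv_each"`` re-selects
    lambda on every repeat's training half (default for binary designs,
    where selection noise would otherwise dominate the model-size
    estimate); ``"cv_once"`` selects on the first repeat only and reuses
    the value (default for multiclass designs, whose joint LP makes
    per-repeat re-selection an order of magnitude costlier and whose
    selection is insensitive across repeats).  ``folds`` defaults to 5
    for binary and 3 for multiclass designs (the scaled-down stand-in
    for leave-one-out selection).
    """
    if lam_mode is None:
        lam_mode = "cv_each" if spec.n_classes == 2 else "cv_once"
    if lam_mode not in ("cv_once", "cv_each"):
        raise ValueError("lam_mode must be 'cv_once' or 'cv_each'")
    if folds is None:
        folds = 5 if spec.n_classes == 2 else 3
    rng = np.random.default_rng(seed)
    dataset_seeds = rng.integers(0, 2**31 - 1, size=repeats)
    split_seeds = rng.integers(0, 2**31 - 1, size=repeats)
    recovery: dict[str, int] = {}
    aucs, n_sel, lam_used, errors = [], [], [], []
    lam_fixed: float | None = None
    for r in range(repeats):
        ds = simdata.simulate_counts(
            simdata.with_seed(spec, int(dataset_seeds[r]))
        )
        rel = preprocess.to_relative_abundance(ds.counts)
        Xt = preprocess.transform_arcsine(rel).values
        if not recovery:
            recovery = {f: 0 for f in ds.true_features}
        r_rng = np.random.default_rng(split_seeds[r])
        train, test = _stratified_split(ds.labels, 0.5, r_rng)
        lab_tr = _subset_labels(ds.labels, train)
        lab_te = _subset_labels(ds.labels, test)
        if lam_fixed is None:
            cv = cv_lambda(
                Xt[train], lab_tr, lam_grid, k=folds,
                seed=int(split_seeds[r]), backend=backend,
            )
            lam_r = cv.best_lam
            if lam_mode == "cv_once":
                lam_fixed = lam_r
        else:
            lam_r = lam_fixed
        model = fit_model(
            Xt[train], lab_tr, lam_r, normalized=True,
            feature_ids=ds.counts.features, backend=backend,
        )
        chosen = models.selected_features(model)
        for f in ds.true_features:
            if f in chosen:
                recovery[f] += 1
        pred = predict_labels(model, Xt[test])
        lam_used.append(float(lam_r))
        n_sel.append(len(chosen))
        errors.append(evaluation.predictive_error(pred, lab_te.as_array()))
        aucs.append(test_auc(model, Xt[test], lab_te))
    return SimulationStudyResult(
        mean_auc=float(np.mean(aucs)),
        mean_n_selected=float(np.mean(n_sel)),
        recovery=recovery,
        repeats=repeats,
        folds=folds,
        lam_used=lam_used,
        aucs=aucs,
        n_selected=n_sel,
        test_errors=errors,
        seed=seed,
    )
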