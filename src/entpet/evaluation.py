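"""Metrics, fold aggregation, the 15-subset feature ablation, and
group-wise sampling Shapley importance.

Per-class discrimination is measured one-vs-rest: ROC-AUC from class
probabilities, F1 from argmax decisions.  Fold ROC curves are vertically
averaged on a fixed 101-point false-positive-rate grid.  Feature-group
importance uses a permutation-sampling approximation of Shapley values
over the four named column groups (group "absent" = replaced by the
training-set post-scale means), attributing the model's predicted-class
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from entpet import classifier as clf
from entpet import features as feat

__all__ = [
    "FoldMetrics",
    "AblationReport",
    "ImportanceReport",
    "roc_auc_one_vs_rest",
    "f1_per_class",
    "fold_metrics",
    "aggregate_folds",
    "cross_validate_subset",
    "run_ablation",
    "shapley_group_importance",
]

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class FoldMetrics:
    fold: int
    auc: dict[int, float]
    f1: dict[int, float]
    roc_tpr: dict[int, np.ndarray]  # on FPR_GRID


@dataclass
class AblationReport:
    """mean +/- std AUC and F1 per feature subset per class."""

    subsets: list[tuple[str, ...]]
    auc_mean: dict[tuple[str, ...], np.ndarray]
    auc_std: dict[tuple[str, ...], np.ndarray]
    f1_mean: dict[tuple[str, ...], np.ndarray]
    f1_std: dict[tuple[str, ...], np.ndarray]
    fold_hash: str = ""

    def to_frame(self):
        import pandas as pd

        rows = []
        for s in self.subsets:
            name = "+".join(s)
            for c in range(len(self.auc_mean[s])):
                rows.append({"subset": name, "class": c,
                             "auc_mean": self.auc_mean[s][c],
                             "auc_std": self.auc_std[s][c],
                             "f1_mean": self.f1_mean[s][c],
                             "f1_std": self.f1_std[s][c]})
        return pd.DataFrame(rows)


@dataclass
class ImportanceReport:
    groups: list[str]
    per_fold: np.ndarray      # (n_folds, n_groups) mean |attribution|
    mean: np.ndarray          # (n_groups,)
    std: np.ndarray           # (n_groups,)


def roc_auc_one_vs_rest(scores, labels, class_c: int) -> float:
    """One-vs-rest ROC-AUC of class ``class_c``.

    ``scores``: (n, n_classes) probabilities or (n,) scores for the class.
    Equals the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int) == class_c
    if y.all() or not y.any():
        raise ValueError("AUC undefined: labels contain a single class")
    sc = s[:, class_c] if s.ndim == 2 else s
    return float(roc_auc_score(y, sc))


def f1_per_class(predictions, labels, class_c: int) -> float:
    """One-vs-rest F1 = 2TP / (2TP + FP + FN); 0 when the denominator is 0."""
    pred = np.asarray(predictions, dtype=int) == class_c
    true = np.asarray(labels, dtype=int) == class_c
    tp = int(np.count_nonzero(pred & true))
    fp = int(np.count_nonzero(pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2.0 * tp / denom


def fold_metrics(fold: int, probs, labels, n_classes: int = 5) -> FoldMetrics:
    """Per-class AUC/F1 and interpolated ROC curves for one fold."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    preds = probs.argmax(axis=1)
    auc, f1, rocs = {}, {}, {}
    for c in range(n_classes):
        auc[c] = roc_auc_one_vs_rest(probs, labels, c)
        f1[c] = f1_per_class(preds, labels, c)
        fpr, tpr, _ = roc_curve(labels == c, probs[:, c])
        rocs[c] = np.interp(FPR_GRID, fpr, tpr)
    return FoldMetrics(fold=fold, auc=auc, f1=f1, roc_tpr=rocs)


def aggregate_folds(folds: list[FoldMetrics]):
    """Mean and sample std (ddof=1) of per-class AUC/F1, plus the mean ROC.

    Returns a dict with arrays indexed by class.
    """
    if len(folds) < 2:
        raise ValueError("need at least two folds to aggregate")
    classes = sorted(folds[0].auc)
    auc = np.array([[f.auc[c] for c in classes] for f in folds])
    f1 = np.array([[f.f1[c] for c in classes] for f in folds])
    mean_roc = {c: np.mean([f.roc_tpr[c] for f in folds], axis=0) for c in classes}
    return {
        "auc_mean": auc.mean(axis=0), "auc_std": auc.std(axis=0, ddof=1),
        "f1_mean": f1.mean(axis=0), "f1_std": f1.std(axis=0, ddof=1),
        "mean_roc": mean_roc, "fpr_grid": FPR_GRID,
    }


# ---------------------------------------------------------------------------
# cross-validation / ablation
# ---------------------------------------------------------------------------

def cross_validate_subset(X, y, subset, folds, model_spec=None, train_spec=None,
                          return_models: bool = False):
    """Full k-fold CV of one feature subset; scaler fit per training fold.

    ``X``: (n, 4, 21) unscaled feature matrices; ``folds``: FoldSplit list
    (shared across subsets for paired comparisons).
    """
    model_spec = model_spec or clf.ModelSpec()
    train_spec = train_spec or clf.TrainSpec()
    Xs = feat.select_columns(X, subset)
    out_folds = []
    models = []
    for split in folds:
        scaler = feat.fit_scaler(Xs[split.train_idx])
        Xtr = feat.apply_scaler(Xs[split.train_idx], scaler)
        Xva = feat.apply_scaler(Xs[split.val_idx], scaler)
        ytr, yva = y[split.train_idx], y[split.val_idx]
        weights = clf.class_weights_from_labels(ytr, model_spec.n_classes)
        model = clf.build_model(model_spec, Xs.shape[-1],
                                rng_seed=train_spec.seed + split.fold)
        spec = clf.TrainSpec(**{**train_spec.__dict__,
                                "seed": train_spec.seed + split.fold})
        model, hist = clf.train_fold(model, Xtr, ytr, Xva, yva, spec, weights)
        probs = clf.predict(model, Xva)
        out_folds.append(fold_metrics(split.fold, probs, yva, model_spec.n_classes))
        if return_models:
            models.append((model, scaler, hist))
    agg = aggregate_folds(out_folds)
    if return_models:
        return out_folds, agg, models
    return out_folds, agg


def _fold_hash(folds) -> str:
    import hashlib

    h = hashlib.sha256()
    for f in folds:
        h.update(np.ascontiguousarray(f.train_idx).tobytes())
        h.update(np.ascontiguousarray(f.val_idx).tobytes())
    return h.hexdigest()[:16]


def run_ablation(X, y, subsets=None, model_spec=None, train_spec=None,
                 k: int = 5, fold_seed: int = 0) -> AblationReport:
    """Train one model per feature subset with identical fold splits.

    Default subsets: the 15 non-empty subsets of {dphi, theta, xyz, E}.
    """
    subsets = [tuple(s) for s in (subsets or feat.feature_subsets())]
    folds = clf.make_folds(y, k=k, rng_seed=fold_seed)
    rep = AblationReport(subsets=subsets, auc_mean={}, auc_std={},
                         f1_mean={}, f1_std={}, fold_hash=_fold_hash(folds))
    for s in subsets:
        _, agg = cross_validate_subset(X, y, s, folds, model_spec, train_spec)
        rep.auc_mean[s] = agg["auc_mean"]
        rep.auc_std[s] = agg["auc_std"]
        rep.f1_mean[s] = agg["f1_mean"]
        rep.f1_std[s] = agg["f1_std"]
    return rep


# ---------------------------------------------------------------------------
# sampling Shapley importance over feature groups
# ---------------------------------------------------------------------------

def shapley_group_importance(model, X_scaled, groups: dict[str, list[int]],
                             baseline, n_permutations: int = 200,
                             rng_seed: int = 0) -> np.ndarray:
    """Permutation-sampling Shapley attribution of the predicted-class
    probability over feature column groups.

    ``X_scaled``: (n, 4, d) scaled inputs; ``baseline``: (d,) or (4, d)
    reference values (training-set post-scale means).  A group outside the
    coalition has its columns replaced by the baseline.  Returns an (n,
    n_groups) array of signed attributions; ``mean(|.|, axis=0)`` is the
    reported importance.  The attributions of each sample sum to
    f(x) - f(baseline) up to Monte-Carlo error (efficiency).
    """
    if n_permutations < 10:
        import warnings

        warnings.warn("n_permutations < 10: Shapley estimates will be noisy",
                      stacklevel=2)
    rng = np.random.default_rng(rng_seed)
    X = np.asarray(X_scaled, dtype=np.float32)
    names = list(groups)
    base = np.broadcast_to(np.asarray(baseline, dtype=np.float32), X.shape[1:])
    n, g = X.shape[0], len(names)
    pred_class = clf.predict(model, X).argmax(axis=1)
    rows = np.arange(n)

    def value(mask_groups: np.ndarray) -> np.ndarray:
        """f for coalitions given per-group in/out mask (g,) shared by all."""
        Z = np.broadcast_to(base, X.shape).copy()
        for j, name in enumerate(names):
            if mask_groups[j]:
                Z[:, :, groups[name]] = X[:, :, groups[name]]
        return clf.predict(model, Z)[rows, pred_class]

    attrib = np.zeros((n, g))
    for _ in range(n_permutations):
        order = rng.permutation(g)
        mask = np.zeros(g, dtype=bool)
        prev = value(mask)
        for j in order:
            mask[j] = True
            cur = value(mask)
            attrib[:, j] += cur - prev
            prev = cur
    return attrib / n_permutations


def importance_report(models_scalers, X, y, groups_subset, folds,
                      n_permutations: int = 50, rng_seed: int = 0,
                      n_samples: int = 256) -> ImportanceReport:
    """Per-fold mean |Shapley attribution| per feature group.

    ``models_scalers``: list of (model, scaler, history) from
    :func:`cross_validate_subset` with ``return_models=True`` on the same
    folds; importance is evaluated on a deterministic slice of each
    validation fold.
    """
    Xs = feat.select_columns(X, groups_subset)
    # column indices of each group within the reduced matrix
    cols = sorted(c for gname in groups_subset for c in feat.FEATURE_GROUPS[gname])
    groups = {gname: [cols.index(c) for c in feat.FEATURE_GROUPS[gname]]
              for gname in groups_subset}
    per_fold = []
    for (model, scaler, _), split in zip(models_scalers, folds):
        idx = split.val_idx[:n_samples]
        Z = feat.apply_scaler(Xs[idx], scaler)
        Ztr = feat.apply_scaler(Xs[split.train_idx], scaler)
        baseline = Ztr.reshape(-1, Ztr.shape[-1]).mean(axis=0)
        att = shapley_group_importance(model, Z, groups, baseline,
                                       n_permutations, rng_seed)
        per_fold.append(np.abs(att).mean(axis=0))
    per_fold = np.array(per_fold)
    return ImportanceReport(groups=list(groups), per_fold=per_fold,
                            mean=per_fold.mean(axis=0),
                            std=per_fold.std(axis=0, ddof=1) if len(per_fold) > 1
                            else np.zeros(per_fold.shape[1]))
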