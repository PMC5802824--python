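"""Biomarker screening of the subject parameters.

Implements the repeated random-forest protocol: for each pair of
response classes the eight subject parameters are used to predict class
membership over 100 random 75/25 stratified splits, with fold-wise
cross-validated tuning on the training portion, held-out accuracy on
the rest, and per-repeat importance scaling to a 0-100 scale.  A
scrambled-label control estimates the chance-level baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from cpttrial.model import PARAM_NAMES
from cpttrial.trial import RECORDED_DAYS

__all__ = [
    "RFSettings",
    "PairwiseRFResult",
    "spearman_matrix",
    "feature_table",
    "rf_pairwise",
    "select_predictors",
    "scrambled_control",
    "roc_curve",
    "class_summaries",
]

log = logging.getLogger(__name__)

IMPORTANCE_THRESHOLD = 50.0
MIN_CLASS_SIZE = 4


@dataclass(frozen=True)
class RFSettings:
    """Protocol knobs for the repeated random-forest screen.

    The tree count is held fixed; cross-validation tunes only the number
    of candidate features per split.  Defaults are sized so a 100-repeat
    run on a ~150-subject class pair stays within a few minutes on one
    CPU.
    """

    repeats: int = 100
    train_frac: float = 0.75
    cv_folds: int = 10
    n_estimators: int = 200
    max_features_grid: tuple[int, ...] = (2, 3)
    importance: str = "permutation"  # or "impurity"
    permutation_repeats: int = 5


@dataclass(frozen=True)
class PairwiseRFResult:
    classes: tuple[str, str]
    mean_accuracy: float
    sd_accuracy: float
    mean_importances: dict[str, float]          # scaled 0-100
    selected_predictors: list[str]
    accuracies: np.ndarray = field(repr=False)
    roc_points: list[tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=list)
    aucs: np.ndarray = field(repr=False, default=None)


def feature_table(trial: pd.DataFrame) -> pd.DataFrame:
    """Numeric screening table: parameters, tissue fractions, severity."""
    cols = list(PARAM_NAMES)
    for day in RECORDED_DAYS:
        for tissue in ("fib", "cart", "bone"):
            for sfx in ("u", "t"):
                col = f"{tissue}_d{day}_{sfx}"
                if col in trial.columns:
                    cols.append(col)
    cols += [c for c in ("ci_u", "ci_t") if c in trial.columns]
    return trial[cols]


def spearman_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Rank correlation matrix with average ranks for ties.

    Constant columns yield undefined correlations, reported as NaN with
    a warning rather than silently as 0.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 rows for a rank correlation")
    constant = [c for c in features.columns if features[c].nunique() <= 1]
    if constant:
        log.warning("constant columns have undefined correlations: %s", constant)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # spearmanr warns on constant input
        rho = spearmanr(features.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the two-column case
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    mat = pd.DataFrame(rho, index=features.columns, columns=features.columns)
    np.fill_diagonal(mat.values, 1.0)
    mat.loc[constant, :] = np.nan
    mat.loc[:, constant] = np.nan
    for c in constant:
        mat.loc[c, c] = np.nan
    return mat


def _check_two_classes(y: np.ndarray) -> tuple[str, str]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    for cls, cnt in zip(classes, counts):
        if cnt < MIN_CLASS_SIZE:
            raise ValueError(
                f"class {cls!r} has only {cnt} members (< {MIN_CLASS_SIZE}); "
                "insufficient n for the split protocol"
            )
    return tuple(classes)


def _one_repeat(
    X: np.ndarray,
    y: np.ndarray,
    settings: RFSettings,
    rs: int,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """One stratified split + CV-tuned fit; returns accuracy, scaled
    importances, held-out scores and held-out labels."""
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=settings.train_frac, stratify=y, random_state=rs
    )
    smallest = np.unique(y_tr, return_counts=True)[1].min()
    folds = int(min(settings.cv_folds, smallest))
    rf = RandomForestClassifier(
        n_estimators=settings.n_estimators, random_state=rs
    )
    grid = [m for m in settings.max_features_grid if m <= X.shape[1]]
    if folds >= 2 and len(grid) > 1:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small-fold class warnings
            search = GridSearchCV(rf, {"max_features": grid}, cv=cv).fit(X_tr, y_tr)
        model = search.best_estimator_
    else:
        model = rf.fit(X_tr, y_tr)
    acc = float(model.score(X_te, y_te))
    if settings.importance == "impurity":
        imp = model.feature_importances_
    else:
        # Held-out permutation importance: ~0 for uninformative features,
        # so a noise-only model yields no predictors above threshold.
        perm = permutation_importance(
            model, X_te, y_te,
            n_repeats=settings.permutation_repeats, random_state=rs,
        )
        imp = np.clip(perm.importances_mean, 0.0, None)
    top = imp.max()
    scaled = imp / top * 100.0 if top > 0 else np.zeros_like(imp)
    scores = model.predict_proba(X_te)[:, 1]
    return acc, scaled, scores, y_te


def rf_pairwise(
    features: pd.DataFrame,
    labels,
    settings: RFSettings | None = None,
    seed: int = 0,
) -> PairwiseRFResult:
    """Repeated random-forest binary classification of two classes.

    Each repeat draws a fresh stratified 75/25 split, tunes the
    per-split feature count by cross-validation on the training portion,
    and measures accuracy on the held-out quarter.  Importances are
    scaled to max=100 per trained model, then averaged.  Deterministic
    given ``seed``.
    """
    settings = settings or RFSettings()
    if settings.repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {settings.repeats}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = _check_two_classes(y)

    seeds = np.random.SeedSequence(seed).generate_state(settings.repeats)
    accs, imps, rocs, aucs = [], [], [], []
    positive = classes[1]
    for rs in seeds:
        rs = int(rs % (2**31 - 1))
        acc, scaled, scores, y_te = _one_repeat(X, y, settings, rs)
        accs.append(acc)
        imps.append(scaled)
        fpr, tpr, auc_val = roc_curve(scores, (y_te == positive).astype(int))
        rocs.append((fpr, tpr))
        aucs.append(auc_val)

    mean_imp = np.mean(imps, axis=0)
    names = list(features.columns)
    importances = dict(zip(names, mean_imp.tolist()))
    return PairwiseRFResult(
        classes=classes,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        mean_importances=importances,
        selected_predictors=select_predictors(importances),
        accuracies=np.array(accs),
        roc_points=rocs,
        aucs=np.array(aucs),
    )


def select_predictors(
    mean_importances: dict[str, float], threshold: float = IMPORTANCE_THRESHOLD
) -> list[str]:
    """Parameters whose mean scaled importance strictly exceeds the
    threshold, sorted by decreasing importance."""
    for name, val in mean_importances.items():
        if not 0.0 <= val <= 100.0:
            raise ValueError(f"importance {name}={val} outside [0, 100]")
    chosen = [(v, n) for n, v in mean_importances.items() if v > threshold]
    return [n for v, n in sorted(chosen, reverse=True)]


def scrambled_control(
    features: pd.DataFrame,
    labels,
    settings: RFSettings | None = None,
    seed: int = 0,
) -> PairwiseRFResult:
    """Null-model control: the full protocol on freshly permuted labels.

    Each repeat permutes the labels uniformly at random (seed-derived)
    before splitting, so the expected held-out accuracy is the majority
    class frequency (0.5 for balanced classes) and no predictor should
    pass selection.
    """
    settings = settings or RFSettings()
    if settings.repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {settings.repeats}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = _check_two_classes(y)

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    seeds = ss.generate_state(settings.repeats)
    accs, imps = [], []
    for rs in seeds:
        rs = int(rs % (2**31 - 1))
        y_perm = rng.permutation(y)
        acc, scaled, _, _ = _one_repeat(X, y_perm, settings, rs)
        accs.append(acc)
        imps.append(scaled)
    mean_imp = np.mean(imps, axis=0)
    importances = dict(zip(features.columns, mean_imp.tolist()))
    return PairwiseRFResult(
        classes=classes,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        mean_importances=importances,
        selected_predictors=select_predictors(importances),
        accuracies=np.array(accs),
    )


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points by threshold sweep and AUC by the trapezoid rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"ROC needs both classes present, got {list(uniq)}")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, pos_label=uniq.max())
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def class_summaries(stratified: pd.DataFrame) -> dict[str, dict]:
    """Per-class day-49 treated-arm fibrous-tissue quartiles and
    non-union fraction.  Empty classes are flagged, not an error."""
    from cpttrial.stratify import CLASS_NAMES

    out: dict[str, dict] = {}
    for cls in CLASS_NAMES:
        sub = stratified[stratified["manual_class"] == cls]
        if len(sub) == 0:
            out[cls] = {"n": 0, "missing": True}
            continue
        fib = sub["fib_d49_t"]
        out[cls] = {
            "n": int(len(sub)),
            "fibrous_day49_treated": {
                "q1": float(fib.quantile(0.25)),
                "median": float(fib.quantile(0.5)),
                "q3": float(fib.quantile(0.75)),
            },
            "nonunion_fraction_treated": float(1.0 - sub["union_t"].mean()),
        }
    return out
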