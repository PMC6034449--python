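"""Crop/weed region classification: max-margin classifier with rejection.

The two-class problem is solved by a support vector machine with probability
outputs (p_crop = 1 - p_weed).  Regions labelled *mixed* (both crop and weed
vegetation) are presented to the classifier twice at training time — once as
crop, once as weed — and the minority class is oversampled to exact balance.
Predictions below a confidence threshold ``c`` are rejected, which trades
recall for precision; sweeping ``c`` yields a precision-recall curve.

Evaluation uses image-level k-fold cross validation: whole images (and hence
all their regions) are assigned to folds, so no test-image region ever leaks
into training, including through normalization statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .evaluation import EvalResult
from .features import FeatureNormalizer

__all__ = [
    "CROP", "WEED", "MIXED", "REJECTED",
    "default_grid",
    "ClassifierConfig",
    "split_by_image",
    "prepare_training",
    "CropWeedSVC",
    "grid_search_train",
    "predict_with_rejection",
    "cross_validate",
    "pr_over_confidence",
]

CROP = "crop"
WEED = "weed"
MIXED = "mixed"
REJECTED = "rejected"


def default_grid() -> list[dict]:
    """The kernel/parameter grid explored during validation.

    Linear with C in {1, 10, 100, 1000}; RBF with the same C values crossed
    with gamma in {1e-3, 1e-4}; polynomial with degree in {2, 3, 4} (C fixed
    at 1, no cost value being prescribed for that kernel).
    """
    grid: list[dict] = []
    grid += [{"kernel": "linear", "C": c} for c in (1, 10, 100, 1000)]
    grid += [
        {"kernel": "rbf", "C": c, "gamma": g}
        for c in (1, 10, 100, 1000)
        for g in (0.001, 0.0001)
    ]
    grid += [{"kernel": "poly", "degree": d, "C": 1} for d in (2, 3, 4)]
    return grid


@dataclass
class ClassifierConfig:
    """Cross-validation protocol parameters."""

    grid: list[dict] = field(default_factory=default_grid)
    confidence: float = 0.5
    train_fraction: float = 0.70
    k_folds: int = 10
    seed: int = 0
    strict_mixed: bool = False

    def __post_init__(self):
        if not self.grid:
            raise ValueError("parameter grid must be non-empty")
        if not (0.5 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0.5, 1]")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def split_by_image(image_ids, k: int, seed: int = 0) -> list[np.ndarray]:
    """Partition the distinct image ids into k folds of near-equal size.

    All regions of an image land in one fold; fold sizes differ by at most
    one; the same seed reproduces the same folds.
    """
    unique = np.unique(np.asarray(image_ids))
    if unique.size < k:
        raise ValueError(f"need at least {k} images, got {unique.size}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def prepare_training(X, y, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate mixed samples into both classes and balance by oversampling.

    Every mixed region contributes one crop-labelled and one weed-labelled
    copy; the minority class is then oversampled with replacement (seeded) to
    the majority size, so the returned classes are exactly balanced.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=object)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths differ")
    bad = ~np.isin(y, (CROP, WEED, MIXED))
    if bad.any():
        raise ValueError(f"unknown labels: {sorted(set(y[bad]))}")

    mixed = y == MIXED
    X_parts = [X[~mixed], X[mixed], X[mixed]]
    y_parts = [
        y[~mixed],
        np.full(int(mixed.sum()), CROP, dtype=object),
        np.full(int(mixed.sum()), WEED, dtype=object),
    ]
    Xa = np.concatenate(X_parts)
    ya = np.concatenate(y_parts)

    n_crop = int((ya == CROP).sum())
    n_weed = int((ya == WEED).sum())
    if n_crop == 0 or n_weed == 0:
        raise ValueError("both classes must be non-empty after duplication")
    if n_crop != n_weed:
        minority = CROP if n_crop < n_weed else WEED
        need = abs(n_crop - n_weed)
        pool = np.flatnonzero(ya == minority)
        rng = np.random.default_rng(seed)
        extra = rng.choice(pool, size=need, replace=True)
        Xa = np.concatenate([Xa, Xa[extra]])
        ya = np.concatenate([ya, ya[extra]])
    return Xa, ya


class CropWeedSVC(BaseEstimator, ClassifierMixin):
    """SVM crop/weed classifier with internal grid selection and rejection.

    ``fit`` splits its input 70/30 (stratified, seeded) into training and
    validation parts, fits every grid point on the training part, scores each
    by crop-F1 on the validation part and keeps the best model (first grid
    point wins ties, so the choice is deterministic for a fixed seed).

    ``predict`` returns 'crop'/'weed', overridden to 'rejected' whenever the
    winning probability falls below ``confidence``.
    """

    def __init__(self, grid: list[dict] | None = None, confidence: float = 0.5,
                 train_fraction: float = 0.70, random_state: int = 0):
        self.grid = grid
        self.confidence = confidence
        self.train_fraction = train_fraction
        self.random_state = random_state

    def fit(self, X, y) -> "CropWeedSVC":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=object)
        grid = self.grid if self.grid is not None else default_grid()
        if not grid:
            raise ValueError("parameter grid must be non-empty")
        X_tr, X_val, y_tr, y_val = train_test_split(
            X, y, train_size=self.train_fraction, stratify=y,
            random_state=self.random_state,
        )
        best = None
        for params in grid:
            model = SVC(probability=True, random_state=self.random_state,
                        **params)
            with warnings.catch_warnings():
                # Platt-scaled SVC probabilities are the intended behaviour;
                # sklearn >= 1.9 flags the parameter as deprecated.
                warnings.simplefilter("ignore", FutureWarning)
                model.fit(X_tr, y_tr)
            # Score the probability-based decision actually used at
            # prediction time (the rejection rule thresholds p_crop), not
            # the raw decision function: the two can disagree when Platt
            # calibration degenerates on a near-constant kernel.
            p_crop = model.predict_proba(X_val)[
                :, list(model.classes_).index(CROP)]
            decision = np.where(p_crop >= 0.5, CROP, WEED)
            score = f1_score(y_val, decision, pos_label=CROP,
                             zero_division=0)
            if best is None or score > best[0]:
                best = (score, params, model)
        self.validation_f1_, self.best_params_, self.model_ = best
        self.classes_ = self.model_.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Probabilities in the fixed column order (p_crop, p_weed)."""
        proba = self.model_.predict_proba(np.asarray(X, dtype=np.float64))
        order = [list(self.model_.classes_).index(c) for c in (CROP, WEED)]
        return proba[:, order]

    def predict(self, X, confidence: float | None = None) -> np.ndarray:
        c = self.confidence if confidence is None else confidence
        proba = self.predict_proba(X)
        return predict_with_rejection(proba[:, 0], c)

    def save(self, path) -> None:
        """Persist the fitted classifier to a single file (joblib)."""
        import joblib

        if not hasattr(self, "model_"):
            raise ValueError("classifier is not fitted")
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "CropWeedSVC":
        import joblib

        clf = joblib.load(path)
        if not isinstance(clf, CropWeedSVC):
            raise ValueError("file does not contain a CropWeedSVC")
        return clf


def predict_with_rejection(p_crop, c: float) -> np.ndarray:
    """Decision per sample: crop/weed by majority probability, or rejected.

    A sample is rejected when its winning probability max(p_crop, 1-p_crop)
    is strictly below ``c``; with c = 0.5 nothing is ever rejected.
    """
    p_crop = np.asarray(p_crop, dtype=np.float64)
    decision = np.where(p_crop >= 0.5, CROP, WEED).astype(object)
    decision[np.maximum(p_crop, 1.0 - p_crop) < c] = REJECTED
    return decision


def grid_search_train(X, y, config: ClassifierConfig | None = None
                      ) -> CropWeedSVC:
    """Fit a :class:`CropWeedSVC` on prepared (balanced) training samples."""
    config = config or ClassifierConfig()
    clf = CropWeedSVC(grid=config.grid, confidence=config.confidence,
                      train_fraction=config.train_fraction,
                      random_state=config.seed)
    return clf.fit(X, y)


def _score_fold(y_true, decision, strict_mixed: bool) -> tuple[int, int, int]:
    """Crop-positive confusion counts with mixed-aware scoring.

    By default a mixed ground-truth region is counted correct under either
    crop or weed decision (it genuinely contains both); under strict scoring
    it is counted wrong under both.  Rejected samples count as missed
    positives (false negatives) but never as false positives.
    """
    y_true = np.asarray(y_true, dtype=object)
    decision = np.asarray(decision, dtype=object)
    pred_crop = decision == CROP
    if strict_mixed:
        tp = int((pred_crop & (y_true == CROP)).sum())
        fp = int((pred_crop & (y_true != CROP)).sum())
    else:
        tp = int((pred_crop & np.isin(y_true, (CROP, MIXED))).sum())
        fp = int((pred_crop & (y_true == WEED)).sum())
    fn = int(((~pred_crop) & (y_true == CROP)).sum())
    return tp, fp, fn


@dataclass
class CrossValResult:
    folds: list[EvalResult]
    pooled: EvalResult
    fold_images: list[np.ndarray]
    chosen_params: list[dict]
    # Held-out per-sample outputs pooled over folds (for PR-over-c curves).
    y_true: np.ndarray = None
    p_crop: np.ndarray = None


def cross_validate(X, y, image_ids, config: ClassifierConfig | None = None
                   ) -> CrossValResult:
    """Image-level k-fold protocol with per-fold normalization and training.

    For each fold: the other k-1 folds' regions are normalized (statistics
    from those regions only), mixed-duplicated, balanced, and used to select
    and fit the SVM; the held-out fold is transformed with the training
    statistics and scored with mixed ground truth accepted for either
    decision (or strictly, per config).
    """
    config = config or ClassifierConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=object)
    image_ids = np.asarray(image_ids)
    folds = split_by_image(image_ids, config.k_folds, seed=config.seed)

    fold_results: list[EvalResult] = []
    chosen: list[dict] = []
    held_y: list[np.ndarray] = []
    held_p: list[np.ndarray] = []
    tp = fp = fn = 0
    for i, test_images in enumerate(folds):
        test = np.isin(image_ids, test_images)
        norm = FeatureNormalizer().fit(X[~test])
        X_tr, y_tr = prepare_training(norm.transform(X[~test]), y[~test],
                                      seed=config.seed + i)
        clf = CropWeedSVC(grid=config.grid, confidence=config.confidence,
                          train_fraction=config.train_fraction,
                          random_state=config.seed + i)
        clf.fit(X_tr, y_tr)
        proba = clf.predict_proba(norm.transform(X[test]))
        decision = predict_with_rejection(proba[:, 0], config.confidence)
        t, f, n = _score_fold(y[test], decision, config.strict_mixed)
        fold_results.append(EvalResult.from_counts(t, f, n))
        chosen.append(clf.best_params_)
        held_y.append(y[test])
        held_p.append(proba[:, 0])
        tp, fp, fn = tp + t, fp + f, fn + n
    return CrossValResult(
        folds=fold_results,
        pooled=EvalResult.from_counts(tp, fp, fn),
        fold_images=folds,
        chosen_params=chosen,
        y_true=np.concatenate(held_y),
        p_crop=np.concatenate(held_p),
    )


def pr_over_confidence(y_true, p_crop, confidences=None, strict_mixed=False
                       ) -> "pd.DataFrame":
    """Precision/recall of the crop decision as the rejection level sweeps."""
    import pandas as pd

    if confidences is None:
        confidences = np.round(np.arange(0.5, 1.0, 0.025), 4)
    records = []
    for c in confidences:
        decision = predict_with_rejection(p_crop, float(c))
        tp, fp, fn = _score_fold(y_true, decision, strict_mixed)
        res = EvalResult.from_counts(tp, fp, fn)
        records.append(dict(confidence=float(c), precision=res.precision,
                            recall=res.recall, f1=res.f1,
                            rejected=int((decision == REJECTED).sum())))
    return pd.DataFrame(records)
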