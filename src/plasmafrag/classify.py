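"""Integrated gradient-boosted classification of DN vs DM from cfDNA
features.

Workflow: assemble the informative feature vector (medium/long size
fractions, top-5 increased and decreased short-DNA motif frequencies, top-1
to top-5 motif ratios, MDS of short cfDNA), stratified 8:2 train/test split,
randomized hyperparameter search with 5-fold cross-validation and balanced
class weights, 100-iteration bootstrap evaluation of the held-out test set,
and a Youden-threshold confusion matrix. An early-stage experiment
(kidney-disease stages 1-3) uses a fixed 15 DN + 20 DM random test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint, uniform
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from xgboost import XGBClassifier

from .features import MotifRatioSet
from .stats import auc_mann_whitney

DEFAULT_SEARCH_SPACE = {
    "max_depth": randint(2, 7),
    "learning_rate": loguniform(0.01, 0.3),
    "n_estimators": randint(50, 501),
    "subsample": uniform(0.5, 0.5),
    "colsample_bytree": uniform(0.5, 0.5),
}


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


def assemble_features(
    table: pd.DataFrame,
    ratio_set: MotifRatioSet,
    include_concentration: bool = False,
    motif_prefix: str = "short_",
) -> pd.DataFrame:
    """Build the model matrix with a fixed column order.

    ``table`` must carry frac_medium, frac_long, mds_short, ratio_1..5 and
    per-motif short-stratum frequency columns named
    ``{motif_prefix}{MOTIF}``. Samples with any missing feature are dropped
    with a warning. The index of the returned frame is the sample id.
    """
    cols = ["frac_medium", "frac_long"]
    cols += [motif_prefix + m for m in ratio_set.up_motifs]
    cols += [motif_prefix + m for m in ratio_set.down_motifs]
    n_ratio = min(len(ratio_set.up_motifs), len(ratio_set.down_motifs), 5)
    cols += [f"ratio_{i}" for i in range(1, n_ratio + 1)]
    cols += ["mds_short"]
    if include_concentration:
        cols += ["concentration"]
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise KeyError(f"feature table lacks columns: {missing_cols}")
    X = table[cols].astype(float)
    ok = X.notna().all(axis=1)
    if not ok.all():
        import warnings

        warnings.warn(
            f"dropping {int((~ok).sum())} samples with missing features",
            stacklevel=2,
        )
    return X[ok]


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    train_ids: list
    test_ids: list
    test_counts: dict
    seed: int


def stratified_split(
    labels: pd.Series, test_fraction: float = 0.2, seed: int = 0
) -> SplitPlan:
    """Per-class test count = round(n * fraction) (half rounds up); the
    split is a seeded permutation within each class."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    train_ids: list = []
    test_ids: list = []
    test_counts = {}
    for cls in classes:
        ids = np.array(sorted(labels.index[labels == cls]), dtype=object)
        n = len(ids)
        n_test = int(np.floor(n * test_fraction + 0.5))
        if n_test == 0 or n_test == n:
            raise ValueError(
                f"class {cls!r} too small for a non-trivial test stratum"
            )
        perm = rng.permutation(n)
        test_ids.extend(ids[perm[:n_test]])
        train_ids.extend(ids[perm[n_test:]])
        test_counts[cls] = n_test
    return SplitPlan(
        train_ids=sorted(train_ids),
        test_ids=sorted(test_ids),
        test_counts=test_counts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def class_weights(y: np.ndarray) -> np.ndarray:
    """Balanced per-sample weights: n_total / (n_classes * n_class)."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    w = {c: len(y) / (len(classes) * n) for c, n in zip(classes, counts)}
    return np.array([w[v] for v in y])


@dataclass
class ModelBundle:
    model: XGBClassifier
    best_params: dict
    cv_auc: float
    feature_columns: list[str]
    train_ids: list
    seed: int

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        import xgboost as xgb

        Xs = X[self.feature_columns]
        if isinstance(self.model, xgb.Booster):
            return self.model.predict(xgb.DMatrix(Xs))
        return self.model.predict_proba(Xs)[:, 1]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        # serialize the underlying booster (text JSON, stable across the
        # sklearn wrapper's API churn)
        self.model.get_booster().save_model(path / "model.json")
        meta = dict(
            best_params={k: (v.item() if isinstance(v, np.generic) else v)
                         for k, v in self.best_params.items()},
            cv_auc=self.cv_auc,
            feature_columns=self.feature_columns,
            train_ids=list(map(str, self.train_ids)),
            seed=self.seed,
        )
        (path / "bundle.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        path = Path(path)
        import xgboost as xgb

        meta = json.loads((path / "bundle.json").read_text())
        model = xgb.Booster()
        model.load_model(str(path / "model.json"))
        return cls(model=model, best_params=meta["best_params"],
                   cv_auc=meta["cv_auc"],
                   feature_columns=meta["feature_columns"],
                   train_ids=meta["train_ids"], seed=meta["seed"])


def train_model(
    X: pd.DataFrame,
    y: np.ndarray,
    search_budget: int = 50,
    seed: int = 0,
    cv_folds: int = 5,
    search_space: Mapping | None = None,
) -> ModelBundle:
    """Randomized hyperparameter search (5-fold stratified CV, AUC scoring)
    over an XGBoost classifier with balanced class weights; the best
    configuration is refit on the full training set."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are single-class")
    est = XGBClassifier(
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    search = RandomizedSearchCV(
        est,
        dict(search_space or DEFAULT_SEARCH_SPACE),
        n_iter=search_budget,
        scoring="roc_auc",
        cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
        random_state=seed,
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y, sample_weight=class_weights(y))
    return ModelBundle(
        model=search.best_estimator_,
        best_params=dict(search.best_params_),
        cv_auc=float(search.best_score_),
        feature_columns=list(X.columns),
        train_ids=list(X.index),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def youden_threshold(y_true, scores) -> float:
    """Score threshold maximizing Youden's J = sensitivity + specificity - 1
    (predict positive when score >= threshold); ties resolve to the largest
    threshold."""
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, dtype=float)
    cand = np.unique(s)[::-1]  # descending: ties pick the largest threshold
    best_j, best_t = -np.inf, cand[0]
    n_pos, n_neg = y.sum(), (~y).sum()
    for t in cand:
        pred = s >= t
        tpr = (pred & y).sum() / n_pos
        fpr = (pred & ~y).sum() / n_neg
        j = tpr - fpr
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def confusion_at(y_true, scores, threshold: float) -> dict:
    y = np.asarray(y_true).astype(bool)
    pred = np.asarray(scores, dtype=float) >= threshold
    return dict(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        tn=int((~pred & ~y).sum()),
        fn=int((~pred & y).sum()),
    )


def _metrics_at(y, s, threshold):
    c = confusion_at(y, s, threshold)
    sens = c["tp"] / (c["tp"] + c["fn"]) if c["tp"] + c["fn"] else np.nan
    spec = c["tn"] / (c["tn"] + c["fp"]) if c["tn"] + c["fp"] else np.nan
    ppv = c["tp"] / (c["tp"] + c["fp"]) if c["tp"] + c["fp"] else np.nan
    npv = c["tn"] / (c["tn"] + c["fn"]) if c["tn"] + c["fn"] else np.nan
    return sens, spec, npv, ppv


@dataclass
class EvaluationReport:
    """Bootstrap distributions of the test metrics plus the full-test-set
    Youden operating point."""

    auc: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    npv: np.ndarray
    ppv: np.ndarray
    youden_threshold: float
    confusion: dict
    n_test: int

    def summary(self) -> dict:
        def ms(a):
            return dict(mean=float(np.nanmean(a)), sd=float(np.nanstd(a, ddof=1)))

        return dict(
            auc=ms(self.auc),
            sensitivity=ms(self.sensitivity),
            specificity=ms(self.specificity),
            npv=ms(self.npv),
            ppv=ms(self.ppv),
            youden_threshold=self.youden_threshold,
            confusion=self.confusion,
            n_test=self.n_test,
        )


def bootstrap_evaluate(
    scores: np.ndarray,
    y_test: np.ndarray,
    iterations: int = 100,
    seed: int = 0,
) -> EvaluationReport:
    """Evaluate held-out scores by bootstrap resampling with replacement.

    Each iteration resamples the test set (redrawn if it lacks a class) and
    computes AUC plus sensitivity/specificity/NPV/PPV at that iteration's
    own Youden threshold. A single confusion matrix at the full-test-set
    Youden threshold is also reported.
    """
    if iterations <= 0:
        raise ValueError("iterations must be positive")
    y = np.asarray(y_test).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("test set must contain both classes")
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs, sens, spec, npvs, ppvs = ([] for _ in range(5))
    for _ in range(iterations):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.any() and not yb.all():
                break
        sb = s[idx]
        aucs.append(auc_mann_whitney(yb, sb))
        t = youden_threshold(yb, sb)
        se, sp, npv, ppv = _metrics_at(yb, sb, t)
        sens.append(se)
        spec.append(sp)
        npvs.append(npv)
        ppvs.append(ppv)
    t_full = youden_threshold(y, s)
    return EvaluationReport(
        auc=np.array(aucs),
        sensitivity=np.array(sens),
        specificity=np.array(spec),
        npv=np.array(npvs),
        ppv=np.array(ppvs),
        youden_threshold=t_full,
        confusion=confusion_at(y, s, t_full),
        n_test=n,
    )


def evaluate_bundle(
    bundle: ModelBundle,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    iterations: int = 100,
    seed: int = 0,
) -> EvaluationReport:
    return bootstrap_evaluate(
        bundle.predict_scores(X_test), y_test, iterations=iterations, seed=seed
    )


# ---------------------------------------------------------------------------
# early-stage experiment
# ---------------------------------------------------------------------------


def early_stage_experiment(
    X: pd.DataFrame,
    y: pd.Series,
    stages: Mapping,
    n_dn_test: int = 15,
    n_dm_test: int = 20,
    early_stages: Sequence[int] = (1, 2, 3),
    seed: int = 0,
    search_budget: int = 50,
    iterations: int = 100,
    positive: str = "DN",
    negative: str = "DM",
) -> tuple[ModelBundle, EvaluationReport]:
    """Early-disease test: a seeded random test set of ``n_dn_test`` DN
    samples at stages 1-3 plus ``n_dm_test`` DM samples; the remaining
    samples train the model; evaluation uses the same bootstrap protocol."""
    y = pd.Series(np.asarray(y), index=X.index)
    early_dn = sorted(
        sid for sid in X.index
        if y[sid] == positive and stages.get(sid) in set(early_stages)
    )
    dm_ids = sorted(sid for sid in X.index if y[sid] == negative)
    if len(early_dn) < n_dn_test:
        raise ValueError(
            f"need >= {n_dn_test} early-stage {positive} samples, "
            f"got {len(early_dn)}"
        )
    if len(dm_ids) < n_dm_test:
        raise ValueError(
            f"need >= {n_dm_test} {negative} samples, got {len(dm_ids)}"
        )
    rng = np.random.default_rng(seed)
    test_ids = sorted(
        list(rng.choice(early_dn, size=n_dn_test, replace=False))
        + list(rng.choice(dm_ids, size=n_dm_test, replace=False))
    )
    train_ids = sorted(set(X.index) - set(test_ids))
    y_num = (y == positive).astype(int)
    bundle = train_model(
        X.loc[train_ids], y_num.loc[train_ids].to_numpy(),
        search_budget=search_budget, seed=seed,
    )
    report = evaluate_bundle(
        bundle, X.loc[test_ids], y_num.loc[test_ids].to_numpy(),
        iterations=iterations, seed=seed,
    )
    return bundle, report
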