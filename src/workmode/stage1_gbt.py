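"""Stage 1: per-participant gradient-boosted trees on window features.

Extreme gradient boosted trees turn the 5-features-per-app window vectors
into a provisional work-mode probability (two-class softmax, equivalent to
a sigmoid on the logit).  Training uses 5-fold cross-validation with folds
blocked by day — all windows of one day share a fold — so the out-of-fold
probabilities that feed stage 2 are free of within-day temporal leakage.

Missing values (reaction features in windows without notification-triggered
episodes) are imputed by sampling with replacement from the non-missing
values of each column, with the sampler fitted on training folds only.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from xgboost import XGBClassifier

from .featurization import SamplingImputer


@dataclass(frozen=True)
class Stage1Config:
    """Boosting hyperparameters (none are dictated by the method itself)."""

    max_depth: int = 4
    learning_rate: float = 0.1
    n_estimators: int = 400
    early_stopping_rounds: int = 30
    importance_type: str = "total_gain"


@dataclass
class Stage1Model:
    """Fitted stage-1 ensemble plus everything inference needs."""

    booster: XGBClassifier
    feature_names: list[str]
    imputer: SamplingImputer
    importances: pd.Series
    seed: int
    config: Stage1Config
    fold_models: list = field(default_factory=list)     # (booster, imputer)
    day_fold: dict = field(default_factory=dict)        # day id -> fold
    cv_best_iters: list = field(default_factory=list)


def _make_xgb(cfg: Stage1Config, seed: int, n_estimators: int,
              early_stopping: bool) -> XGBClassifier:
    return XGBClassifier(
        max_depth=cfg.max_depth,
        learning_rate=cfg.learning_rate,
        n_estimators=n_estimators,
        early_stopping_rounds=cfg.early_stopping_rounds if early_stopping else None,
        eval_metric="logloss",
        objective="binary:logistic",
        n_jobs=1,
        random_state=seed,
        tree_method="hist",
        verbosity=0,
    )


def _day_folds(day_ids, y, k: int, rng: np.random.Generator) -> dict:
    """Assign whole days to folds, round-robin after a shuffle."""
    days = sorted(set(day_ids))
    if len(days) < k:
        raise ValueError(f"need at least {k} distinct days for {k}-fold CV")
    order = rng.permutation(len(days))
    return {days[j]: i % k for i, j in enumerate(order)}


def train_stage1(X: pd.DataFrame, y, day_ids=None, k: int = 5, seed: int = 0,
                 cfg: Stage1Config | None = None):
    """Cross-validated training of the stage-1 classifier.

    Returns ``(model, oof_probs)``: every row receives a probability from
    the fold model that did not see its day.  The final booster is refit on
    all rows with the mean early-stopped round count of the folds.

    ``day_ids`` groups rows into days for blocked folds; when None, rows
    are treated as independent (plain stratified folds) — useful for
    synthetic matrices without temporal structure.
    """
    cfg = cfg or Stage1Config()
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present in the training data")
    n = len(y)
    if day_ids is None:
        day_ids = np.arange(n)
    day_ids = np.asarray(day_ids)
    rng = np.random.default_rng(seed)
    fold_of_day = _day_folds(day_ids, y, k, rng)
    fold = np.array([fold_of_day[d] for d in day_ids])
    for f in range(k):
        if len(np.unique(y[fold != f])) < 2:
            raise ValueError("a CV fold lost one of the classes; need more days")

    oof = np.full(n, np.nan)
    fold_models, best_iters = [], []
    for f in range(k):
        tr, va = fold != f, fold == f
        imp = SamplingImputer().fit(X.loc[tr])
        r = np.random.default_rng([seed, f])
        Xtr = imp.transform(X.loc[tr], r)
        Xva = imp.transform(X.loc[va], r)
        clf = _make_xgb(cfg, seed + f, cfg.n_estimators, early_stopping=True)
        clf.fit(Xtr, y[tr], eval_set=[(Xva, y[va])], verbose=False)
        best = clf.best_iteration if clf.best_iteration is not None else cfg.n_estimators
        best_iters.append(int(best) + 1)
        if va.any():
            oof[va] = clf.predict_proba(Xva)[:, 1]
        fold_models.append((clf, imp))

    final_rounds = max(1, int(round(np.mean(best_iters))))
    imp_all = SamplingImputer().fit(X)
    X_all = imp_all.transform(X, np.random.default_rng([seed, k]))
    final = _make_xgb(cfg, seed, final_rounds, early_stopping=False)
    final.fit(X_all, y, verbose=False)

    booster = final.get_booster()
    booster.feature_names = list(X.columns)
    scores = booster.get_score(importance_type=cfg.importance_type)
    importances = pd.Series({c: scores.get(c, 0.0) for c in X.columns}).sort_values(
        ascending=False)

    model = Stage1Model(final, list(X.columns), imp_all, importances, seed, cfg,
                        fold_models, fold_of_day, best_iters)
    return model, oof


def predict_proba(model: Stage1Model, X: pd.DataFrame, fold: int | None = None) -> np.ndarray:
    """Work-mode probability for feature vectors (deterministic given the
    model's seed).  ``fold`` selects a CV fold model for out-of-fold use."""
    if list(X.columns) != model.feature_names:
        raise ValueError("feature columns do not match the model's feature space")
    if fold is None:
        clf, imp = model.booster, model.imputer
    else:
        clf, imp = model.fold_models[fold]
    Xi = imp.transform(X, np.random.default_rng(model.seed))
    return clf.predict_proba(Xi)[:, 1]


@dataclass
class GreedyResult:
    features: list[str]
    auc_trace: list[float]
    full_auc: float


def greedy_minimal_features(X: pd.DataFrame, y, day_ids=None, delta: float = 0.01,
                            seed: int = 0, k: int = 5,
                            cfg: Stage1Config | None = None) -> GreedyResult:
    """Smallest importance-ranked feature prefix whose out-of-fold AUC is
    within ``delta`` of the all-features AUC.

    Features are added in descending importance order; the search stops at
    the first subset with (full AUC - subset AUC) < delta.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    model, oof = train_stage1(X, y, day_ids, k=k, seed=seed, cfg=cfg)
    full_auc = roc_auc_score(y, oof)
    ranked = list(model.importances.index)
    trace: list[float] = []
    for m in range(1, len(ranked) + 1):
        sub = ranked[:m]
        _, oof_sub = train_stage1(X[sub], y, day_ids, k=k, seed=seed, cfg=cfg)
        auc = roc_auc_score(y, oof_sub)
        trace.append(float(auc))
        if full_auc - auc < delta:
            return GreedyResult(sub, trace, float(full_auc))
    return GreedyResult(ranked, trace, float(full_auc))


def importance_table(model: Stage1Model) -> pd.DataFrame:
    """feature, score, rank — ready for CSV export."""
    return pd.DataFrame({
        "feature": model.importances.index,
        "score": model.importances.to_numpy(),
        "rank": np.arange(1, len(model.importances) + 1),
    })


def save_stage1(model: Stage1Model, path) -> None:
    """Serialize to one portable JSON file (booster + imputer + metadata)."""
    payload = {
        "xgb_raw": base64.b64encode(model.booster.get_booster().save_raw("json")).decode(),
        "feature_names": model.feature_names,
        "observed": {c: v.tolist() for c, v in model.imputer.observed_.items()},
        "importances": model.importances.to_dict(),
        "seed": model.seed,
        "config": model.config.__dict__,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_stage1(path) -> Stage1Model:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    cfg = Stage1Config(**payload["config"])
    clf = _make_xgb(cfg, payload["seed"], cfg.n_estimators, early_stopping=False)
    clf.load_model(bytearray(base64.b64decode(payload["xgb_raw"])))
    imp = SamplingImputer()
    imp.observed_ = {c: np.asarray(v, dtype=float)
                     for c, v in payload["observed"].items()}
    importances = pd.Series(payload["importances"]).sort_values(ascending=False)
    return Stage1Model(clf, payload["feature_names"], imp, importances,
                       payload["seed"], cfg)
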