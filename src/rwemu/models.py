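"""Prognostic survival model zoo: gradient-boosted Cox ensemble, random
survival forest, linear survival SVM, penalized Cox variants, and an
unpenalized benchmark Cox — tuned by grid search + event-stratified k-fold CV
to maximize the IPCW time-dependent AUC at the cancer-specific horizon
(12 months for aNSCLC-like, 24 months otherwise).

Risk scores follow a single orientation contract: higher score = higher
mortality risk. Orientation is verified after fitting (training AUC at the
horizon must be >= 0.5); sign-ambiguous families (the SVM) are negated and
flagged if necessary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sksurv.ensemble import GradientBoostingSurvivalAnalysis, RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.svm import FastSurvivalSVM
from sksurv.util import Surv

from . import tdauc
from .features import model_feature_columns
from .utils import child_seed

HORIZON_BY_PRESET = {"aNSCLC-like": 12.0, "mBC-like": 24.0, "mPC-like": 24.0, "mCRC-like": 24.0}

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "gbm": {"learning_rate": [0.1, 0.2], "max_depth": [2, 3]},
    "rsf": {"min_samples_leaf": [10, 30]},
    "ssvm": {"alpha": [0.0625, 1.0]},
    "pcox_ridge": {"alpha": [0.1, 1.0, 10.0]},
    "pcox_lasso": {"alpha": [0.005, 0.05]},
    "pcox_elastic": {"alpha": [0.005, 0.05]},
    "cox_benchmark": {"alpha": [0.0]},
}

FAMILIES = tuple(DEFAULT_GRIDS)


class ModelSpecError(ValueError):
    pass


@dataclass
class ModelSpec:
    family: str
    horizon_months: float = 12.0
    grid: dict[str, list] = field(default_factory=dict)
    cv_folds: int = 5
    early_stopping: bool = True
    max_learners: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelSpecError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
        if any(len(v) == 0 for v in self.grid.values()):
            raise ModelSpecError("hyperparameter grid must be non-empty")

    @classmethod
    def for_preset(cls, family: str, cancer_preset: str, **kw) -> "ModelSpec":
        return cls(family=family, horizon_months=HORIZON_BY_PRESET[cancer_preset], **kw)


# ---------------------------------------------------------------------------
# preprocessing fit within CV folds (one-hot, median impute + flags, z-score)


class Preprocessor:
    """Impute-flag-standardize-encode transformer fit on training rows only."""

    def __init__(self) -> None:
        self.medians_: dict[str, float] = {}
        self.means_: dict[str, float] = {}
        self.sds_: dict[str, float] = {}
        self.categories_: dict[str, list] = {}
        self.numeric_: list[str] = []
        self.categorical_: list[str] = []
        self.dropped_: list[str] = []

    def fit(self, matrix: pd.DataFrame) -> "Preprocessor":
        numeric, categorical = model_feature_columns(matrix)
        self.numeric_, self.categorical_ = numeric, categorical
        self.dropped_ = []
        for c in numeric:
            col = matrix[c]
            med = col.median()
            self.medians_[c] = 0.0 if pd.isna(med) else float(med)
            filled = col.fillna(self.medians_[c])
            sd = float(filled.std())
            if not np.isfinite(sd) or sd == 0:
                self.dropped_.append(c)
                warnings.warn(f"dropping all-constant feature {c!r}", stacklevel=2)
                continue
            self.means_[c] = float(filled.mean())
            self.sds_[c] = sd
        for c in categorical:
            self.categories_[c] = [str(v) for v in pd.Series(matrix[c]).astype(str).unique()]
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for c in self.numeric_:
            if c in self.dropped_:
                continue
            col = matrix[c].astype(float)
            missing = col.isna()
            if missing.any() or f"{c}_missing" in matrix.columns:
                out[f"{c}_missing"] = missing.astype(float)
            filled = col.fillna(self.medians_[c])
            out[c] = (filled - self.means_[c]) / self.sds_[c]
        for c in self.categorical_:
            vals = pd.Series(matrix[c]).astype(str)
            # unseen levels map to the all-zero reference with a warning
            unseen = set(vals.unique()) - set(self.categories_[c])
            if unseen:
                warnings.warn(
                    f"unseen categorical level(s) {sorted(unseen)} in {c!r} mapped to reference",
                    stacklevel=2,
                )
            for lev in self.categories_[c][1:]:
                out[f"{c}={lev}"] = (vals == lev).astype(float)
        return pd.DataFrame(out, index=matrix.index)

    def fit_transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return self.fit(matrix).transform(matrix)


def _make_estimator(family: str, params: dict, seed: int, n_estimators: int | None):
    if family == "gbm":
        return GradientBoostingSurvivalAnalysis(
            n_estimators=n_estimators or 100, random_state=seed, **params
        )
    if family == "rsf":
        return RandomSurvivalForest(
            n_estimators=n_estimators or 100, random_state=seed, n_jobs=1, **params
        )
    if family == "ssvm":
        return FastSurvivalSVM(max_iter=100, random_state=seed, **params)
    if family == "pcox_ridge":
        return CoxPHSurvivalAnalysis(alpha=params.get("alpha", 1.0), n_iter=200)
    if family == "pcox_lasso":
        return CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[params.get("alpha", 0.01)])
    if family == "pcox_elastic":
        return CoxnetSurvivalAnalysis(l1_ratio=0.5, alphas=[params.get("alpha", 0.01)])
    if family == "cox_benchmark":
        # tiny ridge for numerical stability of the "unpenalized" benchmark
        return CoxPHSurvivalAnalysis(alpha=1e-6, n_iter=200)
    raise ModelSpecError(family)


@dataclass
class FittedSurvivalModel:
    family: str
    estimator: object
    preprocessor: Preprocessor
    feature_columns: list[str]
    horizon_months: float
    chosen_params: dict
    cv_results: pd.DataFrame
    fold_aucs: list[float]
    orientation_flipped: bool = False
    n_estimators_: int | None = None

    def predict_risk(self, matrix: pd.DataFrame) -> np.ndarray:
        """Scalar mortality risk score per row; higher = worse prognosis."""
        X = self.preprocessor.transform(matrix[self.feature_columns])
        score = np.asarray(self.estimator.predict(X.to_numpy()), dtype=float)
        return -score if self.orientation_flipped else score

    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump({"estimator": self.estimator, "preprocessor": self.preprocessor}, path)
        meta = {
            "family": self.family,
            "feature_columns": self.feature_columns,
            "horizon_months": self.horizon_months,
            "chosen_params": self.chosen_params,
            "fold_aucs": self.fold_aucs,
            "orientation_flipped": self.orientation_flipped,
            "n_estimators": self.n_estimators_,
            "format_version": 1,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def _fold_auc(model, pre, train_m, val_m, horizon) -> float:
    Xv = pre.transform(val_m.drop(columns=["time", "event"]))
    scores = np.asarray(model.predict(Xv.to_numpy()), dtype=float)
    return tdauc.td_auc(
        val_m["time"].to_numpy(), val_m["event"].to_numpy(), scores, horizon
    )


def _early_stop_n_estimators(matrix, spec, params) -> int:
    """Learner count for ensembles via internal validation early stopping."""
    pre = Preprocessor()
    X = pre.fit_transform(matrix.drop(columns=["time", "event"]))
    y = Surv.from_arrays(matrix["event"].astype(bool), matrix["time"])
    est = GradientBoostingSurvivalAnalysis(
        n_estimators=spec.max_learners,
        validation_fraction=0.2,
        n_iter_no_change=10,
        random_state=child_seed(spec.seed, "early-stop"),
        **params,
    )
    est.fit(X.to_numpy(), y)
    return int(est.n_estimators_)


def tune_and_fit(train_matrix: pd.DataFrame, spec: ModelSpec) -> FittedSurvivalModel:
    """Grid search x event-stratified k-fold CV maximizing horizon AUC.

    Preprocessing (median impute + flags, standardization, one-hot) is fit
    inside each fold on the fold-training rows only. For the boosted
    ensemble, the learner count is fixed first by early stopping on an
    internal validation split, then the remaining grid is searched. The final
    model is refit on the full training matrix with the selected settings.
    """
    if train_matrix["event"].sum() < spec.cv_folds:
        raise ModelSpecError("need at least cv_folds events in the training set")
    feat = train_matrix.drop(columns=["time", "event"])
    if "patient_id" in feat.columns:
        feat = feat.drop(columns=["patient_id"])
        train_matrix = train_matrix.drop(columns=["patient_id"])
    feature_columns = list(feat.columns)

    n_estimators = None
    if spec.family == "gbm" and spec.early_stopping:
        first_point = {k: v[0] for k, v in spec.grid.items()}
        n_estimators = _early_stop_n_estimators(train_matrix, spec, first_point)

    skf = StratifiedKFold(
        n_splits=spec.cv_folds, shuffle=True, random_state=child_seed(spec.seed, "cv")
    )
    folds = list(skf.split(train_matrix, train_matrix["event"]))

    names = list(spec.grid)
    records = []
    for combo in product(*(spec.grid[k] for k in names)):
        params = dict(zip(names, combo))
        aucs = []
        for tr_idx, va_idx in folds:
            tr, va = train_matrix.iloc[tr_idx], train_matrix.iloc[va_idx]
            pre = Preprocessor()
            Xtr = pre.fit_transform(tr.drop(columns=["time", "event"]))
            ytr = Surv.from_arrays(tr["event"].astype(bool), tr["time"])
            est = _make_estimator(spec.family, params, child_seed(spec.seed, "fit"), n_estimators)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Xtr.to_numpy(), ytr)
            try:
                aucs.append(_fold_auc(est, pre, tr, va, spec.horizon_months))
            except tdauc.UndefinedAUCError:
                aucs.append(np.nan)
        records.append({**params, "mean_cv_auc": float(np.nanmean(aucs)), "fold_aucs": aucs})
    cv_results = pd.DataFrame(records)
    best = cv_results.loc[cv_results["mean_cv_auc"].idxmax()]
    chosen = {k: best[k] for k in names}

    pre = Preprocessor()
    X = pre.fit_transform(train_matrix.drop(columns=["time", "event"]))
    y = Surv.from_arrays(train_matrix["event"].astype(bool), train_matrix["time"])
    est = _make_estimator(spec.family, chosen, child_seed(spec.seed, "final"), n_estimators)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X.to_numpy(), y)

    model = FittedSurvivalModel(
        family=spec.family,
        estimator=est,
        preprocessor=pre,
        feature_columns=feature_columns,
        horizon_months=spec.horizon_months,
        chosen_params={k: (v.item() if hasattr(v, "item") else v) for k, v in chosen.items()},
        cv_results=cv_results,
        fold_aucs=list(best["fold_aucs"]),
        n_estimators_=n_estimators,
    )
    # orientation contract: training AUC at horizon must be >= 0.5
    try:
        train_auc = tdauc.td_auc(
            train_matrix["time"].to_numpy(),
            train_matrix["event"].to_numpy(),
            model.predict_risk(train_matrix),
            spec.horizon_months,
        )
        if train_auc < 0.5:
            model.orientation_flipped = True
            warnings.warn(
                f"{spec.family}: risk-score orientation flipped (training AUC {train_auc:.3f})",
                stacklevel=2,
            )
    except tdauc.UndefinedAUCError:
        pass
    return model


def predict_risk(model: FittedSurvivalModel, matrix: pd.DataFrame) -> np.ndarray:
    return model.predict_risk(matrix)


# ---------------------------------------------------------------------------
# benchmark Cox on a published-style covariate list


class CollinearityError(ValueError):
    pass


def fit_benchmark_cox(
    train_matrix: pd.DataFrame,
    covariates: list[str],
    horizon_months: float = 12.0,
    seed: int = 0,
) -> FittedSurvivalModel:
    """Unpenalized Cox on a fixed covariate list (retrospective-index style).

    Raises :class:`CollinearityError` listing the offending columns if the
    one-hot-expanded design is rank deficient.
    """
    missing = [c for c in covariates if c not in train_matrix.columns]
    if missing:
        raise KeyError(f"covariates not in matrix: {missing}")
    sub = train_matrix[covariates + ["time", "event"]]
    pre = Preprocessor()
    X = pre.fit_transform(sub.drop(columns=["time", "event"]))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for c in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank:
                bad.append(c)
        raise CollinearityError(f"singular design; collinear columns: {bad}")
    y = Surv.from_arrays(sub["event"].astype(bool), sub["time"])
    est = CoxPHSurvivalAnalysis(alpha=1e-9, n_iter=200)
    est.fit(X.to_numpy(), y)
    spec_cols = covariates
    model = FittedSurvivalModel(
        family="cox_benchmark",
        estimator=est,
        preprocessor=pre,
        feature_columns=spec_cols,
        horizon_months=horizon_months,
        chosen_params={},
        cv_results=pd.DataFrame(),
        fold_aucs=[],
    )
    return model


def load_model(path: str | Path) -> FittedSurvivalModel:
    path = Path(path)
    blob = joblib.load(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FittedSurvivalModel(
        family=meta["family"],
        estimator=blob["estimator"],
        preprocessor=blob["preprocessor"],
        feature_columns=meta["feature_columns"],
        horizon_months=meta["horizon_months"],
        chosen_params=meta["chosen_params"],
        cv_results=pd.DataFrame(),
        fold_aucs=meta["fold_aucs"],
        orientation_flipped=meta["orientation_flipped"],
        n_estimators_=meta["n_estimators"],
    )
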