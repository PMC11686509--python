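"""Multitask regression from corrected spectral features to concentrations.

Six per-biomarker regressors share one selected-feature input vector.  The
four model families — linear, ridge, lasso, bayesian (evidence-maximized
Gaussian linear regression) — are all linear *in their parameters*; the
channel responses themselves are not linear in concentration (Stern-Volmer
quenching is 1/(1+kc), the binding curves are sigmoids), so the regressors
act on a deterministic chemometric linearization basis: polynomial cross
terms up to degree 3 over the channel height features and their
reciprocals, with the remaining selected features appended untransformed.
Reciprocal heights make the quenched channels exactly linear; the cross
terms let the model unmix the overlapped 405 nm peaks and absorb the
temperature quench.

Hyperparameters are tuned per biomarker by k-fold cross-validated MSE on
the training split (default 10 folds), then each model is refitted on the
full training set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import BayesianRidge, Lasso, LinearRegression, Ridge
from sklearn.model_selection import KFold

from .channels import BIOMARKERS, BiomarkerState, STATE_RANGES
from .errors import InputError, ParameterError, StateError

SCHEMA_VERSION = 1

FAMILIES: Tuple[str, ...] = ("linear", "ridge", "lasso", "bayesian")

#: Default penalty grid for ridge/lasso (log-spaced, 7 values).
DEFAULT_PENALTY_GRID: Tuple[float, ...] = tuple(
    float(v) for v in np.logspace(-4, 2, 7))

_EPS = 1e-9


@dataclass(frozen=True)
class FeatureBasis:
    """Deterministic linearization basis applied before the linear families.

    Channel height columns are grouped by excitation laser (peaks on one
    laser overlap and must be unmixed jointly); each group is expanded into
    all polynomial cross terms up to ``degree`` over the group's heights
    and their reciprocals, with the reciprocal temperature height appended
    to every group so the models can absorb the temperature quench.  The
    reciprocals make the Stern-Volmer (quenched) channels linear; the cross
    terms compose peak unmixing with the sigmoid inversions.  Non-height
    columns are appended untransformed.  The expansion depends only on the
    column names, so it is reproducible from the persisted bundle.
    """

    degree: int = 3
    uni_degree: int = 5
    reciprocal: bool = True
    logs: bool = True
    height_suffix: str = "_height"
    exposure_prefix: str = "exposure_"

    def _kinds(self) -> List[str]:
        kinds = ["h"]
        if self.reciprocal:
            kinds.append("r")
        if self.logs:
            kinds.append("l")
        return kinds

    def _groups(self, X_cols: List[str]) -> List[List[Tuple[str, str]]]:
        """Per-laser variable groups as (kind, column) pairs.

        kind is ``h`` (height), ``r`` (reciprocal), ``l`` (log height;
        additive in the multiplicative bleach/quench factors) or ``t``
        (the laser's exposure, which enters the neighbour-tail bleach
        mismatch of overlapped peaks).  The 488 nm group keeps all
        orientations of the temperature height; other groups carry the
        reciprocal/log temperature height as quench references.
        """
        from .channels import CHANNEL_LASER
        height_cols = [c for c in X_cols if c.endswith(self.height_suffix)]
        by_laser: Dict[int, List[str]] = {}
        for col in height_cols:
            name = col[: -len(self.height_suffix)]
            laser = CHANNEL_LASER.get(name)
            by_laser.setdefault(laser, []).append(col)
        t_col = f"temperature{self.height_suffix}"
        groups = []
        for laser, cols in sorted(by_laser.items(),
                                  key=lambda kv: str(kv[0])):
            group = []
            for kind in self._kinds():
                group += [(kind, c) for c in cols]
            if t_col in height_cols and t_col not in cols:
                group.append(("r", t_col))
                if self.logs:
                    group.append(("l", t_col))
            for c in cols:
                exp_col = (self.exposure_prefix
                           + c[: -len(self.height_suffix)])
                if exp_col in X_cols:
                    group.append(("t", exp_col))
                    break  # one laser, one exposure
            groups.append(group)
        return groups

    @staticmethod
    def _label(kind: str, col: str) -> str:
        return {"h": col, "r": f"inv({col})", "l": f"log({col})",
                "t": col}[kind]

    def expand(self, X: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
        height_cols = [c for c in X.columns if c.endswith(self.height_suffix)]
        groups = self._groups(list(X.columns))
        grouped_cols = {c for g in groups for _, c in g}
        other_cols = [c for c in X.columns
                      if c not in height_cols and c not in grouped_cols]
        raw: Dict[Tuple[str, str], np.ndarray] = {}
        for c in height_cols:
            h = np.maximum(X[c].to_numpy(dtype=float), _EPS)
            raw[("h", c)] = h
            raw[("r", c)] = 1.0 / h
            raw[("l", c)] = np.log(h)
        for c in X.columns:
            if c.startswith(self.exposure_prefix):
                raw[("t", c)] = X[c].to_numpy(dtype=float)
        terms: Dict[str, np.ndarray] = {}

        def add_term(combo) -> None:
            name = "*".join(lbl for lbl, _ in combo)
            if name not in terms:
                term = raw[combo[0][1]].copy()
                for _, key in combo[1:]:
                    term = term * raw[key]
                terms[name] = term

        for group in groups:
            labels = [(self._label(kind, c), (kind, c)) for kind, c in group]
            for deg in range(1, self.degree + 1):
                for combo in combinations_with_replacement(labels, deg):
                    add_term(combo)
        # deeper pure powers resolve saturating response levels exactly
        for c in height_cols:
            for kind in self._kinds():
                lbl = (self._label(kind, c), (kind, c))
                for deg in range(self.degree + 1, self.uni_degree + 1):
                    add_term((lbl,) * deg)
        names = list(terms)
        cols = [terms[n] for n in names]
        for c in other_cols:
            cols.append(X[c].to_numpy(dtype=float))
            names.append(c)
        if not cols:
            raise InputError("empty feature matrix after expansion")
        return np.column_stack(cols), names


def _make_estimator(family: str, penalty: Optional[float]):
    if family == "linear":
        return LinearRegression()
    if family == "ridge":
        return Ridge(alpha=penalty)
    if family == "lasso":
        return Lasso(alpha=penalty, max_iter=2000, tol=1e-3)
    if family == "bayesian":
        return BayesianRidge()
    raise ParameterError(f"unknown family {family!r}; choose from {FAMILIES}")


@dataclass
class _TargetModel:
    """Fitted per-biomarker linear-in-basis model (persistable)."""

    coef: np.ndarray
    intercept: float
    penalty: Optional[float]
    cv_mse: List[float]
    cv_mae: List[float]
    cv_r2: List[float]

    def predict(self, Xb_std: np.ndarray) -> np.ndarray:
        return Xb_std @ self.coef + self.intercept


@dataclass
class RegressionBundle:
    """Trained multitask regressor: family, basis, scaling, six models."""

    family: str
    feature_names: List[str]            # selected raw feature columns
    basis: FeatureBasis
    basis_names: List[str]
    scale_mean: np.ndarray
    scale_std: np.ndarray
    models: Dict[str, _TargetModel]
    split_seed: int = 42
    test_scores: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise InputError(f"missing feature columns: {missing}")
        Xb, _ = self.basis.expand(X[self.feature_names])
        return (Xb - self.scale_mean) / self.scale_std

    def predict_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        Xs = self._design(X)
        out = {b: self.models[b].predict(Xs) for b in BIOMARKERS}
        return pd.DataFrame(out, index=X.index)

    def cv_summary(self) -> pd.DataFrame:
        rows = {b: {"cv_mse": float(np.mean(m.cv_mse)),
                    "cv_mae": float(np.mean(m.cv_mae)),
                    "cv_r2": float(np.mean(m.cv_r2))}
                for b, m in self.models.items()}
        return pd.DataFrame(rows).T

    # ---- persistence ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "family": self.family,
            "feature_names": self.feature_names,
            "basis": {"degree": self.basis.degree,
                      "uni_degree": self.basis.uni_degree,
                      "reciprocal": self.basis.reciprocal,
                      "logs": self.basis.logs},
            "scale_mean": self.scale_mean.tolist(),
            "scale_std": self.scale_std.tolist(),
            "split_seed": self.split_seed,
            "test_scores": self.test_scores,
            "models": {
                b: {"coef": m.coef.tolist(), "intercept": m.intercept,
                    "penalty": m.penalty, "cv_mse": m.cv_mse,
                    "cv_mae": m.cv_mae, "cv_r2": m.cv_r2}
                for b, m in self.models.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RegressionBundle":
        if data.get("schema_version") != SCHEMA_VERSION:
            raise InputError(
                f"unsupported bundle schema {data.get('schema_version')}")
        basis = FeatureBasis(degree=data["basis"]["degree"],
                             uni_degree=data["basis"].get("uni_degree", 5),
                             reciprocal=data["basis"]["reciprocal"],
                             logs=data["basis"].get("logs", True))
        models = {
            b: _TargetModel(coef=np.asarray(d["coef"], float),
                            intercept=float(d["intercept"]),
                            penalty=d["penalty"], cv_mse=d["cv_mse"],
                            cv_mae=d["cv_mae"], cv_r2=d["cv_r2"])
            for b, d in data["models"].items()
        }
        return cls(family=data["family"],
                   feature_names=list(data["feature_names"]),
                   basis=basis, basis_names=[],
                   scale_mean=np.asarray(data["scale_mean"], float),
                   scale_std=np.asarray(data["scale_std"], float),
                   models=models, split_seed=data["split_seed"],
                   test_scores=data.get("test_scores", {}))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "RegressionBundle":
        return cls.from_dict(json.loads(Path(path).read_text()))


def split_train_test(dataset: Sequence, fraction: float = 0.75,
                     seed: int = 42) -> Tuple[list, list]:
    """Deterministic shuffled split; disjoint and exhaustive."""
    if not 0.0 < fraction < 1.0:
        raise ParameterError("fraction must lie in (0, 1)")
    n = len(dataset)
    if n < 8:
        raise InputError("dataset must have at least 8 samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fraction * n))
    train_idx = set(order[:n_train].tolist())
    train = [dataset[i] for i in range(n) if i in train_idx]
    test = [dataset[i] for i in range(n) if i not in train_idx]
    return train, test


def tune_and_train(train_X: pd.DataFrame, train_Y: pd.DataFrame,
                   family: str,
                   grid: Optional[Sequence[float]] = None,
                   folds: int = 10, seed: int = 42,
                   basis: Optional[FeatureBasis] = None) -> RegressionBundle:
    """Cross-validated hyperparameter search + refit on the full train set.

    Per biomarker the penalty minimizing mean CV MSE is selected; all fold
    scores are recorded in the bundle.
    """
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    if len(train_X) < folds:
        raise ParameterError("more folds than samples")
    if family in ("ridge", "lasso"):
        grid = list(grid) if grid is not None else list(DEFAULT_PENALTY_GRID)
        if not grid:
            raise ParameterError("hyperparameter grid must be non-empty")
    else:
        grid = [None]
    basis = basis or FeatureBasis()
    Xb, basis_names = basis.expand(train_X)
    mean = Xb.mean(axis=0)
    std = Xb.std(axis=0)
    std[std == 0] = 1.0
    Xs = (Xb - mean) / std
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_idx = list(kf.split(Xs))
    models: Dict[str, _TargetModel] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for target in train_Y.columns:
            y = train_Y[target].to_numpy(dtype=float)
            best = None
            for penalty in grid:
                mses, maes, r2s = [], [], []
                for tr, va in fold_idx:
                    est = _make_estimator(family, penalty)
                    est.fit(Xs[tr], y[tr])
                    pred = est.predict(Xs[va])
                    resid = y[va] - pred
                    mses.append(float(np.mean(resid ** 2)))
                    maes.append(float(np.mean(np.abs(resid))))
                    sstot = float(np.sum((y[va] - y[va].mean()) ** 2))
                    r2s.append(1.0 - float(np.sum(resid ** 2)) / sstot
                               if sstot > 0 else float("nan"))
                candidate = (float(np.mean(mses)), penalty, mses, maes, r2s)
                if best is None or candidate[0] < best[0]:
                    best = candidate
            _, penalty, mses, maes, r2s = best
            est = _make_estimator(family, penalty)
            est.fit(Xs, y)
            models[target] = _TargetModel(
                coef=np.asarray(est.coef_, float),
                intercept=float(est.intercept_), penalty=penalty,
                cv_mse=mses, cv_mae=maes, cv_r2=r2s)
    return RegressionBundle(family=family,
                            feature_names=list(train_X.columns),
                            basis=basis, basis_names=basis_names,
                            scale_mean=mean, scale_std=std,
                            models=models, split_seed=seed)


def predict(bundle: RegressionBundle, features) -> "PredictionResult":
    """Predict the six concentrations from corrected features.

    ``features`` may be a FeatureVector, a sequence of them, or a feature
    DataFrame.  Uncorrected feature vectors are rejected (the photobleach
    contract guards the exposure-0 semantics the model was trained on).
    """
    from .features import FeatureVector, feature_frame
    if isinstance(features, FeatureVector):
        vectors = [features]
    elif isinstance(features, pd.DataFrame):
        vectors = None
    else:
        vectors = list(features)
    if vectors is not None:
        for fv in vectors:
            if not fv.corrected:
                raise StateError(
                    "features must be photobleach-corrected before predict")
        X, _ = feature_frame(vectors, with_labels=False)
    else:
        X = features
    pred = bundle.predict_frame(X)
    flags = pd.DataFrame({
        b: (pred[b] < STATE_RANGES[b][0]) | (pred[b] > STATE_RANGES[b][1])
        for b in BIOMARKERS})
    return PredictionResult(values=pred, out_of_range=flags)


@dataclass
class PredictionResult:
    """Predicted concentrations plus out-of-admissible-range flags."""

    values: pd.DataFrame
    out_of_range: pd.DataFrame

    def states(self) -> List[BiomarkerState]:
        return [BiomarkerState.from_array(row)
                for row in self.values[list(BIOMARKERS)].to_numpy()]

    def single(self) -> BiomarkerState:
        if len(self.values) != 1:
            raise InputError("single() requires exactly one prediction")
        return self.states()[0]


def score(predictions, truths) -> pd.DataFrame:
    """Per-biomarker MSE, MAE and R^2.

    MSE = mean squared residual, MAE = mean absolute residual,
    R^2 = 1 - SSres/SStot.  Constant truths make R^2 undefined (NaN with a
    warning).
    """
    pred = pd.DataFrame(predictions)
    truth = pd.DataFrame(truths)
    if len(pred) != len(truth) or len(pred) == 0:
        raise InputError("predictions and truths must have equal length >= 1")
    rows = {}
    for col in truth.columns:
        resid = pred[col].to_numpy(float) - truth[col].to_numpy(float)
        mse = float(np.mean(resid ** 2))
        mae = float(np.mean(np.abs(resid)))
        sstot = float(np.sum(
            (truth[col] - truth[col].mean()) ** 2))
        if len(truth) < 2 or sstot == 0:
            warnings.warn(f"R^2 undefined for constant truth {col!r}",
                          RuntimeWarning, stacklevel=2)
            r2 = float("nan")
        else:
            r2 = 1.0 - float(np.sum(resid ** 2)) / sstot
        rows[col] = {"mse": mse, "mae": mae, "r2": r2}
    return pd.DataFrame(rows).T
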