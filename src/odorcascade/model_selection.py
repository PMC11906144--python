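"""Method panels, hyperparameter grids and nested (double) cross-validation.

The classification panel covers logistic regression, linear discriminant
analysis, Gaussian naive Bayes, k-nearest neighbours, linear and RBF support
vector machines, a decision tree, random forest, LightGBM, XGBoost and
gradient-boosted trees; the regression panel covers PLS, ridge, LASSO,
elastic net, linear and RBF support vector regression, random forest,
LightGBM, XGBoost, a decision tree, ordinary least squares, gradient-boosted
trees and Gaussian-process regression. SVM-family, linear-shrinkage and PLS
methods carry hyperparameter grids tuned by 5-fold grid-search
cross-validation; tree ensembles and the remaining methods run at library
defaults.

Model assessment uses nested cross-validation: the outer loop holds out one
fold for evaluation while the inner loop selects the method and its
hyperparameters on the remaining folds only, so the reported (pooled
out-of-fold) metrics are never contaminated by the tuning step. An optional
cluster-undersampling step rebalances each outer training fold — never the
evaluation fold.

A ``fast`` profile restricts each panel to a logistic/linear-SVM/forest (or
ridge/linear-SVR/forest) trio with coarse grids for cheap end-to-end runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.linear_model import (
    ElasticNet,
    Lasso,
    LinearRegression,
    LogisticRegression,
    Ridge,
)
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR, LinearSVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .imbalance import cluster_undersample
from .metrics import (
    MetricResult,
    classification_metrics,
    confusion_from_predictions,
    regression_metrics,
)

logger = logging.getLogger(__name__)

try:  # pragma: no cover - both present in the supported environment
    from lightgbm import LGBMClassifier, LGBMRegressor
except ImportError:  # pragma: no cover
    LGBMClassifier = LGBMRegressor = None
try:  # pragma: no cover
    from xgboost import XGBClassifier, XGBRegressor
except ImportError:  # pragma: no cover
    XGBClassifier = XGBRegressor = None

# wide log-scale grids for the tuned methods; coarse variants for `fast`
C_GRID = [2.0**e for e in range(-5, 11)]
GAMMA_GRID = [2.0**e for e in range(-20, 11, 2)]
EPSILON_GRID = [2.0**e for e in range(-10, 1)]
ALPHA_GRID = [10.0**e for e in range(-3, 3)]
L1_RATIO_GRID = [0.1, 0.3, 0.5, 0.7, 0.9]

GridSpec = Callable[[np.ndarray, np.ndarray], dict]


@dataclass
class MethodSpec:
    """One candidate method: a seeded estimator factory and its search grid."""

    name: str
    factory: Callable[[int], object]
    grid: dict | GridSpec = field(default_factory=dict)

    def grid_for(self, x: np.ndarray, y: np.ndarray) -> dict:
        return self.grid(x, y) if callable(self.grid) else dict(self.grid)


def _scaled(estimator) -> Pipeline:
    # distance/margin-based methods need standardized inputs
    return Pipeline([("scale", StandardScaler()), ("model", estimator)])


def _pls_grid(x: np.ndarray, y: np.ndarray) -> dict:
    cap = max(1, min(30, x.shape[1], x.shape[0] - 2))
    return {"model__n_components": list(range(1, cap + 1))}


def classification_panel(fast: bool = False) -> list[MethodSpec]:
    """Candidate classifiers; ``fast`` keeps a cheap representative trio."""
    if fast:
        return [
            MethodSpec(
                "logistic",
                lambda s: _scaled(LogisticRegression(max_iter=5000, random_state=s)),
                {"model__C": [1.0, 10.0]},
            ),
            MethodSpec(
                "linear_svm",
                lambda s: _scaled(
                    SVC(kernel="linear", cache_size=500, random_state=s)
                ),
                {"model__C": [0.1, 1.0]},
            ),
            MethodSpec(
                "random_forest",
                lambda s: RandomForestClassifier(
                    n_estimators=200, random_state=s, n_jobs=1
                ),
            ),
        ]
    panel = [
        MethodSpec(
            "logistic",
            lambda s: _scaled(LogisticRegression(max_iter=5000, random_state=s)),
        ),
        MethodSpec("lda", lambda s: LinearDiscriminantAnalysis()),
        MethodSpec("naive_bayes", lambda s: GaussianNB()),
        MethodSpec("knn", lambda s: _scaled(KNeighborsClassifier())),
        MethodSpec(
            # the linear-kernel dual solver: with descriptor dimension far
            # above the sample count the primal coordinate solver stalls
            "linear_svm",
            lambda s: _scaled(SVC(kernel="linear", cache_size=500, random_state=s)),
            {"model__C": C_GRID},
        ),
        MethodSpec(
            "svm_rbf",
            lambda s: _scaled(SVC(kernel="rbf", random_state=s)),
            {"model__C": C_GRID, "model__gamma": GAMMA_GRID},
        ),
        MethodSpec("decision_tree", lambda s: DecisionTreeClassifier(random_state=s)),
        MethodSpec(
            "random_forest",
            lambda s: RandomForestClassifier(random_state=s, n_jobs=1),
        ),
        MethodSpec(
            "gbdt", lambda s: GradientBoostingClassifier(random_state=s)
        ),
    ]
    if LGBMClassifier is not None:
        panel.append(
            MethodSpec(
                "lgbm",
                lambda s: LGBMClassifier(random_state=s, n_jobs=1, verbose=-1),
            )
        )
    if XGBClassifier is not None:
        panel.append(
            MethodSpec(
                "xgb", lambda s: XGBClassifier(random_state=s, n_jobs=1)
            )
        )
    return panel


def regression_panel(fast: bool = False) -> list[MethodSpec]:
    """Candidate regressors; ``fast`` keeps a cheap representative trio."""
    if fast:
        return [
            MethodSpec(
                "ridge",
                lambda s: _scaled(Ridge(random_state=s)),
                {"model__alpha": [0.01, 0.1, 1.0, 10.0, 100.0]},
            ),
            MethodSpec(
                "linear_svr",
                lambda s: _scaled(LinearSVR(max_iter=20000, random_state=s)),
                {"model__C": [0.1, 1.0, 10.0], "model__epsilon": [0.01, 0.1]},
            ),
            MethodSpec(
                "random_forest",
                lambda s: RandomForestRegressor(
                    n_estimators=300, random_state=s, n_jobs=1
                ),
            ),
        ]
    panel = [
        MethodSpec("pls", lambda s: _scaled(PLSRegression()), _pls_grid),
        MethodSpec(
            "ridge",
            lambda s: _scaled(Ridge(random_state=s)),
            {"model__alpha": ALPHA_GRID},
        ),
        MethodSpec(
            "lasso",
            lambda s: _scaled(Lasso(random_state=s, max_iter=50000)),
            {"model__alpha": ALPHA_GRID},
        ),
        MethodSpec(
            "elastic_net",
            lambda s: _scaled(ElasticNet(random_state=s, max_iter=50000)),
            {"model__alpha": ALPHA_GRID, "model__l1_ratio": L1_RATIO_GRID},
        ),
        MethodSpec(
            "linear_svr",
            lambda s: _scaled(LinearSVR(max_iter=20000, random_state=s)),
            {"model__C": C_GRID, "model__epsilon": EPSILON_GRID},
        ),
        MethodSpec(
            "svr_rbf",
            lambda s: _scaled(SVR(kernel="rbf")),
            {
                "model__C": C_GRID,
                "model__epsilon": EPSILON_GRID,
                "model__gamma": GAMMA_GRID,
            },
        ),
        MethodSpec(
            "random_forest",
            lambda s: RandomForestRegressor(random_state=s, n_jobs=1),
        ),
        MethodSpec("decision_tree", lambda s: DecisionTreeRegressor(random_state=s)),
        MethodSpec("ols", lambda s: LinearRegression()),
        MethodSpec("gbdt", lambda s: GradientBoostingRegressor(random_state=s)),
        MethodSpec(
            "gpr",
            lambda s: _scaled(
                GaussianProcessRegressor(normalize_y=True, random_state=s)
            ),
        ),
    ]
    if LGBMRegressor is not None:
        panel.append(
            MethodSpec(
                "lgbm", lambda s: LGBMRegressor(random_state=s, n_jobs=1, verbose=-1)
            )
        )
    if XGBRegressor is not None:
        panel.append(
            MethodSpec("xgb", lambda s: XGBRegressor(random_state=s, n_jobs=1))
        )
    return panel


@dataclass
class SelectionResult:
    method: str
    params: dict
    cv_score: float
    estimator: object  # fitted on the full data passed in
    spec: Optional["MethodSpec"] = None  # to re-instantiate the winner

    def fresh_estimator(self, seed: int):
        est = self.spec.factory(seed)
        est.set_params(**self.params)
        return est


def _inner_cv(task: str, folds: int, seed: int):
    if task == "classification":
        return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return KFold(n_splits=folds, shuffle=True, random_state=seed)


def select_method(
    x: np.ndarray,
    y: np.ndarray,
    panel: Sequence[MethodSpec],
    task: str,
    folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Pick the best (method, hyperparameters) by grid-search CV and refit.

    Classification is scored by F-measure, regression by r². Ties go to the
    earlier panel entry.
    """
    if task not in ("classification", "regression"):
        raise ValueError(f"unknown task {task!r}")
    scoring = "f1" if task == "classification" else "r2"
    if task == "classification":
        class_min = int(np.unique(y, return_counts=True)[1].min())
        if class_min < 2:
            # too few samples of one class to cross-validate at all:
            # fall back to the first panel method at default parameters
            logger.warning(
                "a class has %d sample(s); skipping method selection",
                class_min,
            )
            est = panel[0].factory(seed)
            est.fit(x, y)
            return SelectionResult(panel[0].name, {}, float("nan"), est,
                                   panel[0])
        folds = min(folds, class_min)
    cv = _inner_cv(task, folds, seed)
    best: Optional[SelectionResult] = None
    for spec in panel:
        grid = spec.grid_for(x, y)
        search = GridSearchCV(
            spec.factory(seed),
            param_grid=grid or {},
            scoring=scoring,
            cv=cv,
            n_jobs=1,
            refit=False,
            error_score="raise",
        )
        search.fit(x, y)
        score = float(search.best_score_)
        if best is None or score > best.cv_score:
            best = SelectionResult(
                spec.name, dict(search.best_params_), score, None, spec
            )
            best_spec = spec
    est = best_spec.factory(seed)
    est.set_params(**best.params)
    est.fit(x, y)
    best.estimator = est
    return best


@dataclass
class NestedCVResult:
    """Pooled out-of-fold predictions and the per-fold selection record."""

    oof_predictions: np.ndarray
    fold_of: np.ndarray  # outer-fold index per sample
    fold_methods: list[str]
    fold_params: list[dict]
    metrics: MetricResult

    def to_report(self) -> dict:
        return {
            "pooled_metrics": self.metrics.values,
            "undefined_metrics": sorted(self.metrics.undefined),
            "fold_methods": self.fold_methods,
            "fold_params": [
                {k: repr(v) for k, v in p.items()} for p in self.fold_params
            ],
        }


def nested_cv(
    x: np.ndarray,
    y: np.ndarray,
    panel: Sequence[MethodSpec],
    task: str,
    outer_folds: int = 5,
    inner_folds: int = 5,
    seed: int = 0,
    undersample: bool = False,
) -> NestedCVResult:
    """Nested cross-validation with in-fold method + hyperparameter selection.

    Each outer training fold is (optionally) rebalanced by cluster
    undersampling, the inner grid search selects a method and its
    hyperparameters on that fold alone, the winner is refit on the outer
    training fold and evaluated on the untouched outer test fold. Metrics are
    pooled over all out-of-fold predictions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if task == "classification":
        splitter = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan, dtype=float)
    fold_of = np.full(len(y), -1, dtype=int)
    fold_methods: list[str] = []
    fold_params: list[dict] = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(x, y)):
        assert not set(train_idx) & set(test_idx), "outer folds overlap"
        x_tr, y_tr = x[train_idx], y[train_idx]
        if undersample and task == "classification":
            res = cluster_undersample(x_tr, y_tr, seed=seed + fold)
            x_tr, y_tr = x_tr[res.kept_indices], y_tr[res.kept_indices]
        if task == "classification":
            class_min = int(np.unique(y_tr, return_counts=True)[1].min())
            folds = max(2, min(inner_folds, class_min))
        else:
            folds = max(2, min(inner_folds, len(y_tr) - 1))
        sel = select_method(x_tr, y_tr, panel, task, folds=folds, seed=seed)
        oof[test_idx] = sel.estimator.predict(x[test_idx])
        fold_of[test_idx] = fold
        fold_methods.append(sel.method)
        fold_params.append(sel.params)
    if task == "classification":
        pooled = classification_metrics(
            confusion_from_predictions(y.astype(int), oof.astype(int))
        )
    else:
        pooled = regression_metrics(y, oof)
    return NestedCVResult(oof, fold_of, fold_methods, fold_params, pooled)
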