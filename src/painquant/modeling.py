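"""Predictive models: per-subject RFE-to-5 linear regression and pooled
random-forest regression, one model per pulse-sensor combination.

Individual level: because per-subject data are small, recursive feature
elimination first reduces the (z-scored) feature set to ``n_selected``
features (default 5) and an ordinary least-squares model predicts the pain
score.  RFE refits the linear model at every step and removes exactly one
feature per iteration, ranking by absolute coefficient — the canonical
importance metric for a linear model on standardized features.  Ties are
broken deterministically: the feature occurring later in canonical column
order is removed first.

Population level: a random-forest regressor pools windows across subjects;
each tree is grown on a bootstrap sample with a random feature subset per
split, and the predicted pain score is the mean over trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression

from .core_io import PULSE_SITES


class EmptyDataError(ValueError):
    """No jointly stable windows available for the requested combination."""


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one model.

    ``max_features`` is the per-split feature fraction of the forest;
    ``n_trees`` its size.  All stochastic behaviour is pinned by ``seed``.
    """

    level: str = "population"                 # "individual" | "population"
    sensors: tuple[str, ...] = ("temple",)
    n_selected: int = 5
    n_trees: int = 500
    max_features: float = 1 / 3
    bootstrap: bool = True
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level not in ("individual", "population"):
            raise ValueError(f"unknown model level {self.level!r}")
        if not self.sensors:
            raise ValueError("sensor combination must be non-empty")


@dataclass
class FittedModel:
    spec: ModelSpec
    feature_names: list[str]
    estimator: object
    coefficients: pd.Series | None = None     # individual level only
    fold_id: str = ""

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return predict(self, X)


def enumerate_sensor_combinations(
    sensors: Sequence[str] = PULSE_SITES,
) -> list[tuple[str, ...]]:
    """All non-empty sensor subsets in canonical order (singles first,
    then pairs, then the full set): 7 combinations for 3 sensors."""
    combos: list[tuple[str, ...]] = []
    for k in range(1, len(sensors) + 1):
        combos.extend(itertools.combinations(sensors, k))
    return combos


def _lstsq_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares slopes with intercept; minimum-norm under collinearity."""
    A = np.column_stack([np.ones(len(X)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef[1:]


def rfe_select(X: pd.DataFrame, y: Sequence[float], n_keep: int) -> list[str]:
    """Recursive feature elimination down to ``n_keep`` features.

    Repeatedly fits the linear model on the surviving features, ranks them
    by absolute coefficient, and removes the single least-important one
    (later canonical column on exact ties) until ``n_keep`` remain.
    Deterministic.
    """
    cols = list(X.columns)
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if n_keep > len(cols):
        raise ValueError(f"n_keep={n_keep} exceeds available features ({len(cols)})")
    yv = np.asarray(y, dtype=float)
    if np.ptp(yv) == 0:
        raise ValueError("labels are constant; feature ranking is undefined")
    Xv = X.to_numpy(dtype=float)
    active = list(range(len(cols)))
    while len(active) > n_keep:
        redundant = _redundant_column(Xv, active)
        if redundant is not None:
            # an exactly dependent column (e.g. a derived difference kept
            # alongside both parents) carries no information of its own and
            # makes |coef| meaningless; drop the later canonical one first
            del active[redundant]
            continue
        coef = _lstsq_coef(Xv[:, active], yv)
        imp = np.abs(coef)
        # remove the least important; importances equal up to numerical noise
        # count as tied and the later canonical column is dropped
        tied = np.flatnonzero(imp <= imp.min() * (1 + 1e-9) + 1e-12)
        del active[int(tied[-1])]
    return [cols[i] for i in active]


def _redundant_column(Xv: np.ndarray, active: list[int]) -> int | None:
    """Position (within ``active``) of a linearly dependent column, or None.

    Scans from the end so the later canonical column of a dependent group
    is flagged first; removal of such a column keeps the design's rank.
    """
    A = np.column_stack([np.ones(len(Xv)), Xv[:, active]])
    full_rank = np.linalg.matrix_rank(A)
    if full_rank == len(active) + 1:
        return None
    for pos in range(len(active) - 1, -1, -1):
        without = [a for j, a in enumerate(active) if j != pos]
        B = np.column_stack([np.ones(len(Xv)), Xv[:, without]])
        if np.linalg.matrix_rank(B) == full_rank:
            return pos
    return None


def fit_individual(X: pd.DataFrame, y: Sequence[float], spec: ModelSpec) -> FittedModel:
    """RFE-then-OLS model for one subject's windows."""
    yv = np.asarray(y, dtype=float)
    if len(np.unique(yv)) < 2:
        raise ValueError("need >= 2 distinct label values to fit an individual model")
    n_keep = min(spec.n_selected, X.shape[1])
    selected = rfe_select(X, yv, n_keep)
    Xs = X[selected].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(Xs)), Xs]))
    if rank < len(selected) + 1:
        raise ValueError(f"rank-deficient design after selection; collinear features among {selected}")
    est = LinearRegression().fit(Xs, yv)
    return FittedModel(
        spec=spec,
        feature_names=selected,
        estimator=est,
        coefficients=pd.Series(est.coef_, index=selected),
    )


def fit_population(X: pd.DataFrame, y: Sequence[float], spec: ModelSpec) -> FittedModel:
    """Pooled random-forest regressor over all subjects' windows."""
    if len(X) == 0:
        raise EmptyDataError(
            f"no jointly stable windows for sensor combination {spec.sensors}"
        )
    est = RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_features=spec.max_features,
        bootstrap=spec.bootstrap,
        max_depth=spec.max_depth,
        random_state=spec.seed,
        n_jobs=1,
    )
    est.fit(X.to_numpy(dtype=float), np.asarray(y, dtype=float))
    return FittedModel(spec=spec, feature_names=list(X.columns), estimator=est)


def fit_model(X: pd.DataFrame, y: Sequence[float], spec: ModelSpec) -> FittedModel:
    if spec.level == "individual":
        return fit_individual(X, y, spec)
    return fit_population(X, y, spec)


def predict(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Predict pain scores; feature binding is by column name, so column
    order in ``X`` is irrelevant."""
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    if len(X) == 0:
        return np.empty(0, dtype=float)
    return np.asarray(model.estimator.predict(X[model.feature_names].to_numpy(dtype=float)),
                      dtype=float)
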