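"""Gradient-boosted regression trees under pinball (quantile) loss.

The estimator is the classic boosting recursion: start from the empirical
gamma-quantile of the targets, then at every iteration fit a least-squares
regression tree to the negative gradient of the loss and take an exact
per-leaf line-search step — for pinball loss the optimal leaf value is the
gamma-quantile of the current residuals in that leaf — scaled by a
shrinkage factor (the learning rate). Three ensembles at gamma = 0.05,
0.50, 0.95 give a point BP estimate and a raw 90% quantile band per record;
the band has no finite-sample guarantee on its own and is calibrated
downstream by split conformal prediction.

Pinball loss at level gamma charges ``(1-gamma)|y-f|`` for overestimation
(f >= y) and ``gamma|y-f|`` for underestimation; at gamma = 0.5 it equals
exactly half the mean absolute error, so the 0.5 ensemble is the MAE/median
regressor.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .schema import FEATURES, target_column

logger = logging.getLogger(__name__)

#: Quantile levels trained by default: band edges and the median point estimate.
DEFAULT_GAMMAS = (0.05, 0.50, 0.95)


@dataclass(frozen=True)
class QuantileBoostConfig:
    """Boosting hyperparameters (defaults are the grid-search optimum)."""

    gamma: float = 0.50
    learning_rate: float = 0.01
    n_estimators: int = 800
    max_depth: int = 8
    min_samples_leaf: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if min(self.n_estimators, self.max_depth, self.min_samples_leaf) < 1:
            raise ValueError("counts must be >= 1")


def pinball_loss(y, f, gamma: float) -> float:
    """Mean pinball loss of predictions ``f`` against targets ``y``."""
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape:
        raise ValueError("y and f must have equal length")
    if y.size == 0:
        raise ValueError("empty input")
    diff = np.abs(y - f)
    return float(np.mean(np.where(f >= y, (1.0 - gamma) * diff, gamma * diff)))


def negative_gradient(y, f, gamma: float) -> np.ndarray:
    """Per-sample negative gradient of the pinball loss.

    ``+gamma`` under the prediction (f < y), ``-(1-gamma)`` above it, and 0
    at the measure-zero tie f == y (subgradient choice).
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    return np.where(f < y, gamma, np.where(f > y, -(1.0 - gamma), 0.0))


@dataclass
class BoostedEnsemble:
    """A fitted pinball-loss boosting ensemble.

    Prediction is ``f0 + learning_rate * sum_m tree_m(x)`` where each
    tree's leaf values were replaced by the per-leaf gamma-quantile
    line-search step.
    """

    f0: float
    trees: list[DecisionTreeRegressor]
    gamma: float
    learning_rate: float
    feature_names: tuple[str, ...]
    train_loss_path: np.ndarray = field(repr=False, default=None)

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.feature_names)
        out = np.full(X.shape[0], self.f0)
        for tree in self.trees:
            out += self.learning_rate * tree.predict(X)
        return out


def _as_matrix(X, feature_names) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"feature schema mismatch, missing columns: {missing}")
        X = X[list(feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(feature_names):
            raise ValueError("feature schema mismatch: wrong column count")
    return X


def fit_xy(X, y, config: QuantileBoostConfig,
           feature_names: tuple[str, ...] = FEATURES) -> BoostedEnsemble:
    """Fit a boosting ensemble on a feature matrix and target vector."""
    X = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite feature or target values")
    if len(y) < config.min_samples_leaf:
        raise ValueError("fewer training rows than min_samples_leaf")

    gamma = config.gamma
    f0 = float(np.quantile(y, gamma))
    f = np.full(len(y), f0)
    trees: list[DecisionTreeRegressor] = []
    loss_path = np.empty(config.n_estimators + 1)
    loss_path[0] = pinball_loss(y, f, gamma)
    # splitter="best" is deterministic; the seed only governs tie-breaking.
    rng = np.random.default_rng(config.seed)
    for m in range(config.n_estimators):
        r = negative_gradient(y, f, gamma)
        tree = DecisionTreeRegressor(
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X, r)
        # Exact line search per terminal leaf: the pinball-optimal additive
        # step is the gamma-quantile of the residuals reaching the leaf.
        leaf_ids = tree.apply(X)
        residual = y - f
        values = tree.tree_.value
        for leaf in np.unique(leaf_ids):
            values[leaf, 0, 0] = np.quantile(residual[leaf_ids == leaf], gamma)
        f += config.learning_rate * tree.predict(X)
        trees.append(tree)
        loss_path[m + 1] = pinball_loss(y, f, gamma)
    return BoostedEnsemble(
        f0=f0, trees=trees, gamma=gamma,
        learning_rate=config.learning_rate,
        feature_names=tuple(feature_names),
        train_loss_path=loss_path,
    )


def fit(train: pd.DataFrame, target: str, config: QuantileBoostConfig) -> BoostedEnsemble:
    """Fit one ensemble on a feature table for ``target`` in {'sbp', 'dbp'}."""
    return fit_xy(train, train[target_column(target)].to_numpy(), config)


def fit_triple(train: pd.DataFrame, target: str, config: QuantileBoostConfig,
               gammas: tuple[float, ...] = DEFAULT_GAMMAS) -> dict[float, BoostedEnsemble]:
    """Fit the (lower, point, upper) ensembles for one BP target."""
    return {g: fit(train, target, replace(config, gamma=g)) for g in gammas}


def predict_triple(ensembles: dict[float, BoostedEnsemble], rows,
                   gammas: tuple[float, float, float] = DEFAULT_GAMMAS) -> pd.DataFrame:
    """Per-row (lower, point, upper) quantile triple with crossing repair.

    Raw quantile ensembles can cross; the repair sorts the three values,
    which is monotone and keeps the point estimate's rank. The number of
    repaired rows is logged and stored in ``.attrs['n_crossing_repaired']``.
    """
    lo_g, mid_g, hi_g = gammas
    raw = np.column_stack([
        ensembles[lo_g].predict(rows),
        ensembles[mid_g].predict(rows),
        ensembles[hi_g].predict(rows),
    ])
    repaired = np.sort(raw, axis=1)
    n_repaired = int((raw != repaired).any(axis=1).sum())
    if n_repaired:
        logger.info("predict_triple: repaired quantile crossing on %d rows", n_repaired)
    index = rows.index if isinstance(rows, pd.DataFrame) else None
    out = pd.DataFrame(repaired, columns=["lower", "point", "upper"], index=index)
    out.attrs["n_crossing_repaired"] = n_repaired
    return out


def grid_search(train: pd.DataFrame, validation: pd.DataFrame, target: str,
                grids: dict[str, list], base: QuantileBoostConfig | None = None,
                ) -> QuantileBoostConfig:
    """Exhaustive hyperparameter search by validation MAD of the median model.

    ``grids`` maps config field names to candidate lists. Ties are broken
    toward fewer trees, then smaller depth.
    """
    if len(validation) == 0:
        raise ValueError("empty validation set")
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("grids must be non-empty")
    base = base or QuantileBoostConfig()
    y_val = validation[target_column(target)].to_numpy()
    best = None
    for combo in itertools.product(*grids.values()):
        cfg = replace(base, gamma=0.50, **dict(zip(grids.keys(), combo)))
        model = fit(train, target, cfg)
        mad = float(np.mean(np.abs(model.predict(validation) - y_val)))
        key = (mad, cfg.n_estimators, cfg.max_depth)
        if best is None or key < best[0]:
            best = (key, cfg)
    return best[1]
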