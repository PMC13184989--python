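"""Sequence -> activity/specificity regression.

Workflow mirrors the analysis contract: one-hot encoding (position-major,
base order A,C,G,T), a seeded 80/20 split with nested training-set
downsampling, 3-fold cross-validated grid search over feed-forward network
hyperparameters, and Spearman/R^2/MAE evaluation on the held-out test set,
plus simple per-position / base-pair mean-effect baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from bulgeselect.enrichment import MergedSpecificityTable
from bulgeselect.library_model import BASES, DegenerateLibrarySpec

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


# -- encoding --------------------------------------------------------------


@dataclass
class EncodedDataset:
    """One-hot features with targets, optional weights, and genotype index."""

    X: np.ndarray
    y: np.ndarray
    genotypes: list[str]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y) or self.X.shape[0] != len(self.genotypes):
            raise ValueError("feature/target/genotype row mismatch")
        if self.weights is not None and len(self.weights) != len(self.y):
            raise ValueError("weights length mismatch")

    @property
    def n_positions(self) -> int:
        return self.X.shape[1] // len(BASES)

    def subset(self, idx: np.ndarray) -> "EncodedDataset":
        return EncodedDataset(
            X=self.X[idx],
            y=self.y[idx],
            genotypes=[self.genotypes[i] for i in idx],
            weights=None if self.weights is None else self.weights[idx],
        )


def one_hot_encode(
    genotypes: Sequence[str],
    targets: Sequence[float],
    weights: Sequence[float] | None = None,
) -> EncodedDataset:
    """Encode genotypes as position-major one-hot blocks (A,C,G,T order)."""
    if not genotypes:
        raise ValueError("no genotypes to encode")
    length = len(genotypes[0])
    n = len(genotypes)
    X = np.zeros((n, length * len(BASES)), dtype=np.float64)
    for i, g in enumerate(genotypes):
        if len(g) != length:
            raise ValueError("genotypes must have uniform length")
        for j, sym in enumerate(g):
            try:
                X[i, j * len(BASES) + _BASE_INDEX[sym]] = 1.0
            except KeyError:
                raise ValueError(f"non-ACGT symbol {sym!r} in genotype {g!r}") from None
    return EncodedDataset(
        X=X,
        y=np.asarray(targets, dtype=np.float64),
        genotypes=list(genotypes),
        weights=None if weights is None else np.asarray(weights, dtype=np.float64),
    )


def decode_one_hot(row: np.ndarray) -> str:
    """Inverse of the encoding for a single feature row."""
    blocks = row.reshape(-1, len(BASES))
    return "".join(BASES[int(np.argmax(b))] for b in blocks)


def feature_names(spec: DegenerateLibrarySpec) -> list[str]:
    return [f"pos{p}_{b}" for p in spec.variable_positions for b in BASES]


# -- splitting -------------------------------------------------------------

DEFAULT_FRACTIONS = (1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125)


@dataclass(frozen=True)
class SplitPlan:
    test_fraction: float = 0.20
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0,1)")
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValueError("fractions must be in (0,1]")


@dataclass
class SplitIndices:
    test: np.ndarray
    train_full: np.ndarray
    subsets: dict[float, np.ndarray]  # fraction -> nested subset of train_full


def make_split(n_rows: int, plan: SplitPlan) -> SplitIndices:
    """Seeded 80/20 split with nested downsampled training subsets.

    Each smaller fraction's index set is a prefix of the larger one's, so
    learning-curve points compare like with like.
    """
    if n_rows < 10:
        raise ValueError("need at least 10 rows to split")
    rng = np.random.default_rng(plan.seed)
    perm = rng.permutation(n_rows)
    n_test = max(1, int(round(n_rows * plan.test_fraction)))
    test = np.sort(perm[:n_test])
    train_full = perm[n_test:]
    subsets = {
        float(f): np.array(sorted(train_full[: max(1, int(round(f * len(train_full))))]))
        for f in plan.fractions
    }
    return SplitIndices(test=test, train_full=np.sort(train_full), subsets=subsets)


# -- network ---------------------------------------------------------------


@dataclass(frozen=True)
class NetworkConfig:
    """Feed-forward regressor hyperparameters; defaults are the final model."""

    hidden_layer_sizes: tuple[int, ...] = (200, 200, 200)
    alpha: float = 0.001
    learning_rate_init: float = 0.01
    learning_rate: str = "constant"
    batch_size: int = 100
    early_stopping: bool = True
    max_iter: int = 200

    def build(self, seed: int | None = None) -> MLPRegressor:
        return MLPRegressor(
            hidden_layer_sizes=self.hidden_layer_sizes,
            activation="relu",
            alpha=self.alpha,
            learning_rate_init=self.learning_rate_init,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            early_stopping=self.early_stopping,
            max_iter=self.max_iter,
            random_state=seed,
        )


DEFAULT_GRID: tuple[NetworkConfig, ...] = tuple(
    NetworkConfig(
        hidden_layer_sizes=h,
        alpha=a,
        learning_rate_init=lr,
        batch_size=b,
    )
    for h in ((100,), (200, 200), (200, 200, 200))
    for a in (0.0001, 0.001, 0.01)
    for lr in (0.001, 0.01)
    for b in (100, 200)
)


def fit_network(
    train: EncodedDataset,
    config: NetworkConfig,
    seed: int | None = None,
    weight_mode: str = "none",
) -> MLPRegressor:
    """Fit the network; returns the fitted regressor.

    The backend has no per-sample loss weights, so ``weight_mode`` offers
    "none" (default) or "replicate" (rows duplicated proportionally to
    their weight, capped at 20 copies). Non-convergence warns, not fails.
    """
    import warnings

    X, y = train.X, train.y
    if weight_mode == "replicate":
        if train.weights is None:
            raise ValueError("replicate weighting requires weights")
        w = train.weights / train.weights.mean()
        reps = np.clip(np.round(w).astype(int), 1, 20)
        X = np.repeat(X, reps, axis=0)
        y = np.repeat(y, reps)
    elif weight_mode != "none":
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    model = config.build(seed)
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


# -- evaluation ------------------------------------------------------------


@dataclass
class EvalMetrics:
    spearman_rho: float
    r_squared: float
    mae: float
    n_test: int

    def as_dict(self) -> dict[str, float]:
        return {
            "spearman_rho": self.spearman_rho,
            "r_squared": self.r_squared,
            "mae": self.mae,
            "n_test": self.n_test,
        }


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> EvalMetrics:
    """Spearman rho (average ranks for ties), R^2 about the test mean, MAE."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) < 2:
        raise ValueError("need at least 2 test rows for correlation metrics")
    rho = float(spearmanr(y_true, y_pred).statistic)
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    mae = float(np.mean(np.abs(y_true - y_pred)))
    return EvalMetrics(spearman_rho=rho, r_squared=r2, mae=mae, n_test=len(y_true))


def evaluate(model, test: EncodedDataset) -> EvalMetrics:
    return compute_metrics(test.y, model.predict(test.X))


# -- grid search -----------------------------------------------------------


def grid_search_cv(
    train: EncodedDataset,
    grid: Sequence[NetworkConfig] = DEFAULT_GRID,
    folds: int = 3,
    seed: int = 0,
) -> tuple[NetworkConfig, pd.DataFrame]:
    """Exhaustive grid search by mean CV R^2; ties break by grid order.

    Only the provided training rows participate; the held-out test set is
    never seen here.
    """
    if not grid:
        raise ValueError("empty grid")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    records = []
    for gi, config in enumerate(grid):
        scores = []
        for tr_idx, va_idx in kf.split(train.X):
            model = fit_network(train.subset(tr_idx), config, seed=seed)
            m = compute_metrics(train.y[va_idx], model.predict(train.X[va_idx]))
            scores.append(m.r_squared)
        records.append({"grid_index": gi, "config": config, "mean_cv_r2": float(np.mean(scores))})
    table = pd.DataFrame(records)
    best_idx = int(table["mean_cv_r2"].to_numpy().argmax())  # argmax keeps first on ties
    return grid[best_idx], table


# -- learning curve --------------------------------------------------------


def learning_curve(
    dataset: EncodedDataset,
    plan: SplitPlan,
    config: NetworkConfig,
    weight_mode: str = "none",
) -> pd.DataFrame:
    """Fit at each downsampling fraction; evaluate on the one test set."""
    split = make_split(len(dataset.y), plan)
    test = dataset.subset(split.test)
    rows = []
    for f in sorted(plan.fractions, reverse=True):
        idx = split.subsets[float(f)]
        model = fit_network(dataset.subset(idx), config, seed=plan.seed, weight_mode=weight_mode)
        m = evaluate(model, test)
        rows.append(
            {
                "fraction": float(f),
                "n_train": len(idx),
                "seed": plan.seed,
                **m.as_dict(),
            }
        )
    return pd.DataFrame(rows)


# -- positional baselines --------------------------------------------------


class PositionalBaseline:
    """Additive main-effects predictor from per-position category means.

    prediction = grand mean + sum over positions of (category mean -
    grand mean). In "base-pair" mode the joint duplet identity at each
    pair constraint is added as an extra category. Unseen categories fall
    back to the grand mean.
    """

    def __init__(
        self,
        mode: str = "single-position",
        spec: DegenerateLibrarySpec | None = None,
    ) -> None:
        if mode not in ("single-position", "base-pair"):
            raise ValueError(f"unknown baseline mode {mode!r}")
        if mode == "base-pair" and spec is None:
            raise ValueError("base-pair mode requires a library spec")
        self.mode = mode
        self.spec = spec
        self.grand_mean_: float | None = None
        self.effects_: dict[tuple[int, str], float] = {}
        self.pair_effects_: dict[tuple[int, str], float] = {}

    def _pair_keys(self, genotypes: Sequence[str]) -> list[list[tuple[int, str]]]:
        assert self.spec is not None
        keys = []
        for k, pc in enumerate(self.spec.pair_constraints):
            i5 = self.spec.position_index(pc.pos5)
            i3 = self.spec.position_index(pc.pos3)
            keys.append([(k, g[i5] + g[i3]) for g in genotypes])
        return keys

    def fit(
        self,
        genotypes: Sequence[str],
        y: Sequence[float],
        weights: Sequence[float] | None = None,
    ) -> "PositionalBaseline":
        y = np.asarray(y, dtype=float)
        w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
        self.grand_mean_ = float(np.average(y, weights=w))
        length = len(genotypes[0])
        cols = np.array([list(g) for g in genotypes])
        for j in range(length):
            for base in BASES:
                mask = cols[:, j] == base
                if mask.any():
                    self.effects_[(j, base)] = (
                        float(np.average(y[mask], weights=w[mask])) - self.grand_mean_
                    )
        if self.mode == "base-pair":
            # fit duplet terms on the residual of the single-position part,
            # otherwise marginal components would be counted twice
            residual = y - self._predict_single(genotypes)
            for keyed in self._pair_keys(genotypes):
                arr = np.array([k[1] for k in keyed])
                k = keyed[0][0]
                for duplet in np.unique(arr):
                    mask = arr == duplet
                    self.pair_effects_[(k, str(duplet))] = float(
                        np.average(residual[mask], weights=w[mask])
                    )
        return self

    def _predict_single(self, genotypes: Sequence[str]) -> np.ndarray:
        out = np.full(len(genotypes), self.grand_mean_)
        length = len(genotypes[0])
        for i, g in enumerate(genotypes):
            for j in range(length):
                out[i] += self.effects_.get((j, g[j]), 0.0)
        return out

    def predict(self, genotypes: Sequence[str]) -> np.ndarray:
        if self.grand_mean_ is None:
            raise RuntimeError("baseline not fitted")
        out = self._predict_single(genotypes)
        if self.mode == "base-pair":
            for keyed in self._pair_keys(genotypes):
                for i, (k, duplet) in enumerate(keyed):
                    out[i] += self.pair_effects_.get((k, duplet), 0.0)
        return out


def baseline_positional(
    train: EncodedDataset,
    mode: str = "single-position",
    spec: DegenerateLibrarySpec | None = None,
    weight_mode: str = "none",
) -> PositionalBaseline:
    weights = train.weights if weight_mode == "weighted" else None
    return PositionalBaseline(mode=mode, spec=spec).fit(
        train.genotypes, train.y, weights=weights
    )


# -- high-level regressions ------------------------------------------------


@dataclass
class ModelRun:
    """A fitted regression with its split bookkeeping and test metrics."""

    task: str
    config: NetworkConfig
    plan: SplitPlan
    metrics: EvalMetrics
    predictions: pd.DataFrame  # genotype, observed, predicted
    model: MLPRegressor
    split: SplitIndices
    diagnostics: dict = field(default_factory=dict)


def run_regression(
    genotypes: Sequence[str],
    targets: Sequence[float],
    plan: SplitPlan,
    config: NetworkConfig,
    task: str = "regression",
    weights: Sequence[float] | None = None,
    weight_mode: str = "none",
    log1p_target: bool = False,
) -> ModelRun:
    """Encode, split, fit at the full training fraction, evaluate held-out."""
    y = np.asarray(targets, dtype=float)
    if log1p_target:
        y = np.log1p(y)
    data = one_hot_encode(genotypes, y, weights)
    split = make_split(len(y), plan)
    train = data.subset(split.subsets[1.0]) if 1.0 in split.subsets else data.subset(
        split.train_full
    )
    test = data.subset(split.test)
    model = fit_network(train, config, seed=plan.seed, weight_mode=weight_mode)
    metrics = evaluate(model, test)
    preds = pd.DataFrame(
        {
            "genotype": test.genotypes,
            "observed": test.y,
            "predicted": model.predict(test.X),
        }
    )
    return ModelRun(
        task=task,
        config=config,
        plan=plan,
        metrics=metrics,
        predictions=preds,
        model=model,
        split=split,
    )


def cpm_regression(
    table_frame: pd.DataFrame,
    plan: SplitPlan,
    config: NetworkConfig,
    cpm_column: str = "cpm_a",
    weight_mode: str = "none",
    log1p_target: bool = False,
) -> ModelRun:
    """Regress one arm's CPM on genotype (rows from a merged table)."""
    return run_regression(
        table_frame["genotype"].tolist(),
        table_frame[cpm_column].to_numpy(),
        plan,
        config,
        task="cpm",
        weights=table_frame[cpm_column].to_numpy(),
        weight_mode=weight_mode,
        log1p_target=log1p_target,
    )


def specificity_regression(
    merged: MergedSpecificityTable,
    plan: SplitPlan,
    config: NetworkConfig,
    weight_mode: str = "none",
) -> ModelRun:
    """Regress the log2 CPM-ratio score on genotype.

    Adds a target-skew diagnostic (share of strictly positive scores) to
    document arm imbalance.
    """
    if merged.n_common == 0:
        raise ValueError("empty merged table")
    run = run_regression(
        merged.genotypes(),
        merged.frame["score"].to_numpy(),
        plan,
        config,
        task="score",
        weight_mode=weight_mode,
    )
    run.diagnostics["positive_score_share"] = float(
        (merged.frame["score"] > 0).mean()
    )
    return run


def positive_score_share(merged: MergedSpecificityTable) -> float:
    """Share of merged genotypes with a strictly positive specificity score."""
    return float((merged.frame["score"] > 0).mean())
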