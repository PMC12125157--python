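"""Predictive modelling and exact Shapley attribution of safe-limit drivers.

Species metadata (habitat, feeding class), per-metal concentrations and
per-metal exceedance flags are encoded into a numeric feature matrix; the
per-species safe daily consumption limit is the regression target.  A
linear model and a small feed-forward network trained by penalized
gradient descent are fitted on a 90/10 train/test split, and exact
Shapley values (full coalition enumeration) attribute each prediction to
its features, ranking the metals that drive the safe limit.

The Shapley computation is the classical game-theoretic one: feature i's
value is its marginal contribution f(S u {i}) - f(S) averaged over all
coalitions S with the combinatorial weight |S|! (p-|S|-1)! / p!.  Absent
features are filled from a baseline row (the feature-wise training mean
by default).  Exact enumeration is exponential in the feature count and
is gated at 15 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .harmonize import SpeciesProfile, mpl_flags
from .risk_engine import SafeLimit
from .toxdata import METALS, Feeding, Habitat, Metal, ToxTable

MAX_EXACT_FEATURES = 15

HABITAT_CODES = {h: i for i, h in enumerate(Habitat)}
FEEDING_CODES = {f: i for i, f in enumerate(Feeding)}


@dataclass
class EncodedDataset:
    """Numeric feature matrix + target + split for the modelling stage."""

    X: pd.DataFrame
    y: pd.Series
    encoding: dict[str, dict[str, int]]
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    @property
    def X_train(self) -> pd.DataFrame:
        return self.X.iloc[self.train_idx]

    @property
    def X_test(self) -> pd.DataFrame:
        return self.X.iloc[self.test_idx]

    @property
    def y_train(self) -> pd.Series:
        return self.y.iloc[self.train_idx]

    @property
    def y_test(self) -> pd.Series:
        return self.y.iloc[self.test_idx]


def encode(
    profiles: Sequence[SpeciesProfile],
    safelimits: Mapping[tuple[str, Habitat], SafeLimit] | Sequence[SafeLimit],
    toxref: ToxTable,
    seed: int,
    test_fraction: float = 0.1,
) -> EncodedDataset:
    """Encode profiles into features and split 90/10 train/test.

    Features per species: habitat code, feeding code, nine fresh-weight
    concentrations (missing metal -> 0, meaning no measured burden), and
    nine exceedance flags.  The target is the species' overall safe
    consumption limit (g/day).  The split is a seeded permutation, so
    re-encoding with the same seed reproduces it exactly.
    """
    if not isinstance(safelimits, Mapping):
        limits_list = list(safelimits)
        if len(limits_list) != len(profiles):
            raise ValueError("profiles and safelimits must be keyed identically")
        limits = dict(zip((p.key for p in profiles), limits_list))
    else:
        limits = dict(safelimits)
    missing = [p.key for p in profiles if p.key not in limits]
    if missing:
        raise ValueError(f"no safe limit for profiles: {missing[:5]}")

    rows, targets, index = [], [], []
    for p in profiles:
        flags = mpl_flags(p, toxref)
        row = {"habitat": HABITAT_CODES[p.habitat], "feeding": FEEDING_CODES[p.feeding]}
        for m in METALS:
            row[m.value] = p.conc.get(m, 0.0)
        for m in METALS:
            row[f"{m.value}_flag"] = flags.get(m, 0)
        rows.append(row)
        targets.append(limits[p.key].overall_fir)
        index.append(f"{p.species} [{p.habitat.value}]")

    X = pd.DataFrame(rows, index=index, dtype=float)
    y = pd.Series(targets, index=index, name="safe_fir")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(X))
    n_test = max(1, round(test_fraction * len(X)))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    encoding = {
        "habitat": {h.value: c for h, c in HABITAT_CODES.items()},
        "feeding": {f.value: c for f, c in FEEDING_CODES.items()},
    }
    return EncodedDataset(X, y, encoding, train_idx, test_idx, seed)


# ------------------------------------------------------------ linear model

@dataclass(frozen=True)
class LinearModel:
    """Affine predictor y = w0 + w . x."""

    intercept: float
    coef: np.ndarray
    feature_names: tuple[str, ...] = ()

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        return self.intercept + x @ self.coef


def fit_linear(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    ridge: float | None = None,
) -> LinearModel:
    """Ordinary least squares on an intercept-augmented design matrix.

    Requires more rows than features and full column rank; a
    rank-deficient design raises unless ``ridge`` supplies an L2 penalty
    to regularize the normal equations.
    """
    x = np.asarray(X, dtype=float)
    t = np.asarray(y, dtype=float)
    n, p = x.shape
    design = np.column_stack([np.ones(n), x])
    if ridge is None:
        if n <= p:
            raise ValueError(f"need more rows ({n}) than features ({p}) for OLS")
        if np.linalg.matrix_rank(design) < p + 1:
            raise ValueError("rank-deficient design; pass ridge= to regularize")
        w, *_ = np.linalg.lstsq(design, t, rcond=None)
    else:
        penalty = ridge * np.eye(p + 1)
        penalty[0, 0] = 0.0  # never shrink the intercept
        w = np.linalg.solve(design.T @ design + penalty, design.T @ t)
    names = tuple(X.columns) if isinstance(X, pd.DataFrame) else ()
    return LinearModel(intercept=float(w[0]), coef=w[1:], feature_names=names)


# ------------------------------------------------------------- neural net

@dataclass(frozen=True)
class AnnConfig:
    """Feed-forward network hyperparameters.

    hidden: sizes of hidden tanh layers (empty tuple = a purely linear
    model trained by gradient descent); lr: learning rate eta; alpha: L2
    penalty weight on all weights; epochs: full-batch gradient steps;
    seed: mandatory, fixes the initialization.
    """

    hidden: tuple[int, ...] = (16,)
    lr: float = 1e-3
    alpha: float = 1e-4
    loss: str = "squared_error"
    epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lr > 0:
            raise ValueError("learning rate must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.loss != "squared_error":
            raise ValueError(f"unsupported loss: {self.loss!r}")


@dataclass
class NeuralNet:
    """Minimal fully-connected regressor with tanh hidden units."""

    config: AnnConfig
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    loss_history: list[float] = field(default_factory=list)
    feature_names: tuple[str, ...] = ()

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ w + b)
        return (a @ self.weights[-1] + self.biases[-1]).ravel()


def fit_ann(
    X: pd.DataFrame | np.ndarray, y: pd.Series | np.ndarray, config: AnnConfig
) -> NeuralNet:
    """Full-batch penalized gradient descent on mean squared error.

    Each step applies w <- w - eta * (alpha * dR/dw + dLoss/dw) with
    R = 0.5 ||w||^2 over the connection weights (biases unpenalized).
    Training diverging to NaN raises, naming the learning rate.
    """
    x = np.asarray(X, dtype=float)
    t = np.asarray(y, dtype=float).reshape(-1, 1)
    n, p = x.shape
    sizes = [p, *config.hidden, 1]
    rng = np.random.default_rng(config.seed)
    weights = [
        rng.normal(0.0, np.sqrt(1.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    biases = [np.zeros((1, sizes[i + 1])) for i in range(len(sizes) - 1)]
    net = NeuralNet(
        config=config,
        weights=weights,
        biases=biases,
        feature_names=tuple(X.columns) if isinstance(X, pd.DataFrame) else (),
    )

    for _ in range(config.epochs):
        # forward pass, caching activations
        activations = [x]
        a = x
        for w, b in zip(weights[:-1], biases[:-1]):
            a = np.tanh(a @ w + b)
            activations.append(a)
        out = activations[-1] @ weights[-1] + biases[-1]
        resid = out - t
        loss = float(np.mean(resid**2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged (loss is not finite); reduce lr={config.lr}"
            )
        net.loss_history.append(loss)

        # backward pass: dLoss/dout for mean squared error
        delta = 2.0 * resid / n
        for layer in range(len(weights) - 1, -1, -1):
            grad_w = activations[layer].T @ delta + config.alpha * weights[layer]
            grad_b = delta.sum(axis=0, keepdims=True)
            if layer > 0:
                delta = (delta @ weights[layer].T) * (1.0 - activations[layer] ** 2)
            weights[layer] -= config.lr * grad_w
            biases[layer] -= config.lr * grad_b
    return net


# -------------------------------------------------------------- evaluation

def evaluate(
    model: LinearModel | NeuralNet,
    X_test: pd.DataFrame | np.ndarray,
    y_test: pd.Series | np.ndarray,
    flag_target: bool = False,
) -> dict[str, float]:
    """Held-out error metrics: RMSE and R2, plus accuracy for flag targets.

    For binary (flag) targets predictions are thresholded at 0.5 and the
    fraction correct is reported as ``accuracy``.
    """
    x = np.asarray(X_test, dtype=float)
    t = np.asarray(y_test, dtype=float)
    if len(t) == 0:
        raise ValueError("empty test set")
    pred = model.predict(x)
    resid = pred - t
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    metrics = {"rmse": rmse, "r2": r2, "n_test": float(len(t))}
    if flag_target:
        metrics["accuracy"] = float(np.mean((pred >= 0.5) == (t >= 0.5)))
    return metrics


@dataclass(frozen=True)
class StandardizedModel:
    """Wraps a model trained on z-scored features/target for raw-unit use."""

    inner: "LinearModel | NeuralNet"
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd
        return self.inner.predict(x) * self.y_sd + self.y_mean


def fit_ann_standardized(
    X: pd.DataFrame | np.ndarray, y: pd.Series | np.ndarray, config: AnnConfig
) -> StandardizedModel:
    """Train the network on z-scored data; predictions return raw units.

    Standardization keeps one learning rate workable across features with
    very different scales (ug/g concentrations vs. binary flags).
    """
    x = np.asarray(X, dtype=float)
    t = np.asarray(y, dtype=float)
    x_mean = x.mean(axis=0)
    x_sd = x.std(axis=0, ddof=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    y_mean = float(t.mean())
    y_sd = float(t.std(ddof=0)) or 1.0
    xs = (x - x_mean) / x_sd
    if isinstance(X, pd.DataFrame):
        xs = pd.DataFrame(xs, index=X.index, columns=X.columns)
    net = fit_ann(xs, (t - y_mean) / y_sd, config)
    return StandardizedModel(net, x_mean, x_sd, y_mean, y_sd)


# ---------------------------------------------------------------- Shapley

@dataclass(frozen=True)
class AttributionResult:
    """Exact Shapley attribution of one prediction.

    Satisfies efficiency: sum(values) = f(x) - f(baseline), up to a
    residual reported here for auditing.
    """

    values: Mapping[str, float]
    baseline: Mapping[str, float]
    fx: float
    f_baseline: float

    @property
    def efficiency_residual(self) -> float:
        return (self.fx - self.f_baseline) - sum(self.values.values())


def shapley_exact(
    f: Callable[[np.ndarray], float | np.ndarray],
    x: pd.Series | np.ndarray,
    baseline: pd.Series | np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> AttributionResult:
    """Exact Shapley values by full coalition enumeration.

    ``f`` maps a 2-D row array to predictions.  For each coalition S the
    hybrid row takes coordinates in S from ``x`` and the rest from
    ``baseline``; feature i receives the weighted average of
    f(S u {i}) - f(S) over all S not containing i.
    """
    if feature_names is None:
        feature_names = (
            list(x.index) if isinstance(x, pd.Series) else [f"x{i}" for i in range(len(x))]
        )
    xv = np.asarray(x, dtype=float).ravel()
    bv = np.asarray(baseline, dtype=float).ravel()
    p = len(xv)
    if p > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{p} features exceeds the exact-enumeration gate of "
            f"{MAX_EXACT_FEATURES}; use a sampling approximation instead"
        )

    # evaluate f on all 2^p hybrid rows in one batch
    masks = np.array(
        [[(s >> i) & 1 for i in range(p)] for s in range(1 << p)], dtype=bool
    )
    grid = np.where(masks, xv, bv)
    fvals = np.asarray(f(grid), dtype=float).ravel()
    if fvals.shape != (1 << p,):
        raise ValueError("f must return one prediction per input row")

    import math

    fact = [math.factorial(k) for k in range(p + 1)]
    phi = np.zeros(p)
    for s in range(1 << p):
        size = int(masks[s].sum())
        weight = fact[size] * fact[p - size - 1] / fact[p]
        for i in range(p):
            if not masks[s, i]:
                phi[i] += weight * (fvals[s | (1 << i)] - fvals[s])

    return AttributionResult(
        values=dict(zip(feature_names, phi.tolist())),
        baseline=dict(zip(feature_names, bv.tolist())),
        fx=float(fvals[-1]),
        f_baseline=float(fvals[0]),
    )


def attribute_dataset(
    model: LinearModel | NeuralNet,
    X_rows: pd.DataFrame,
    baseline: pd.Series,
    features: Sequence[str] | None = None,
) -> list[AttributionResult]:
    """Shapley-attribute each row, varying only ``features`` (rest fixed).

    Restricting the coalition game to a feature subset keeps exact
    enumeration tractable; non-varied features are clamped to the row's
    own values in both x and baseline.
    """
    features = list(features) if features is not None else list(X_rows.columns)
    idx = [X_rows.columns.get_loc(c) for c in features]
    results = []
    for _, row in X_rows.iterrows():
        fixed = row.to_numpy(dtype=float)

        def f(sub: np.ndarray) -> np.ndarray:
            full = np.tile(fixed, (len(sub), 1))
            full[:, idx] = sub
            return model.predict(full)

        results.append(
            shapley_exact(
                f,
                row[features],
                baseline[features],
                feature_names=features,
            )
        )
    return results


def rank_drivers(
    attributions: Iterable[AttributionResult],
    features: Sequence[str] | None = None,
) -> list[str]:
    """Features in descending order of mean |Shapley value| across rows.

    Ties break by the fixed metal ordering (then alphabetically for
    non-metal features), so the ranking is deterministic.
    """
    attributions = list(attributions)
    if not attributions:
        raise ValueError("no attributions to rank")
    if features is None:
        features = list(attributions[0].values.keys())
    mean_abs = {
        name: float(np.mean([abs(a.values[name]) for a in attributions]))
        for name in features
    }
    metal_order = {m.value: i for i, m in enumerate(METALS)}

    def tie_break(name: str) -> tuple[int, str]:
        return (metal_order.get(name, len(metal_order)), name)

    return sorted(features, key=lambda n: (-mean_abs[n], tie_break(n)))


def attributions_to_frame(
    attributions: Sequence[AttributionResult], index: Sequence[str] | None = None
) -> pd.DataFrame:
    """Long-format table (row, feature, value) for ``attributions.csv``."""
    rows = []
    for i, a in enumerate(attributions):
        label = index[i] if index is not None else i
        for name, value in a.values.items():
            rows.append({"row": label, "feature": name, "value": value})
    return pd.DataFrame(rows)
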