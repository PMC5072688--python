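"""Linear and power-law fate models fitted by partial least squares.

The linear baseline relates the fate probability directly to protein
activities, P = sum_i alpha_i x_i (+ intercept).  The power-law (S-system)
model is P = e^beta0 * prod_i x_i^beta_i + eps, which becomes log-linear
after the transform ln(P - eps) = beta0 + sum_i beta_i ln(x_i); both are fit
with PLS regression, which tolerates the strong collinearity of signaling
measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .datamodel import ObservationTable

#: Default offset keeping ln(P - eps) defined; must stay below every
#: training fate value.
DEFAULT_EPSILON = 1e-6

_ZERO_VAR_TOL = 1e-12


@dataclass(frozen=True)
class PLSModel:
    """A fitted PLS regression (NIPALS), with back-transformed coefficients.

    ``coef`` has shape (n_features, n_targets) on the *original* variable
    scale, so predictions are ``X @ coef + intercept`` — centering and unit
    scaling of inputs/outputs are folded in.
    """

    n_components: int
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    coef: np.ndarray
    intercept: np.ndarray
    x_rotations: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef + self.intercept

    def transform(self, X) -> np.ndarray:
        """Latent-score coordinates of X (used for discrimination plots)."""
        X = np.asarray(X, dtype=float)
        return ((X - self.x_mean) / self.x_std) @ self.x_rotations


def rank_bound(n_rows: int, n_features: int) -> int:
    """Largest admissible PLS component count for a given problem size."""
    return min(n_features, n_rows - 1)


def fit_pls(X, Y, n_components: int, scale: bool = True) -> PLSModel:
    """Fit a NIPALS PLS regression of Y on X.

    Predictors and responses are mean-centered and (by default) scaled to
    unit variance; the returned coefficients are mapped back to the original
    scale.  Deterministic for fixed input.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values in predictors or responses")
    n, p = X.shape
    bound = rank_bound(n, p)
    if not 1 <= n_components <= bound:
        raise ValueError(
            f"n_components={n_components} outside [1, {bound}] for {n}x{p} problem"
        )
    if scale and (X.std(axis=0) < _ZERO_VAR_TOL).any():
        raise ValueError("zero-variance predictor column with scaling enabled")
    est = PLSRegression(n_components=n_components, scale=scale)
    est.fit(X, Y)
    x_std = est._x_std if scale else np.ones(p)
    y_std = est._y_std if scale else np.ones(Y.shape[1])
    return PLSModel(
        n_components=n_components,
        x_weights=est.x_weights_,
        x_loadings=est.x_loadings_,
        y_loadings=est.y_loadings_,
        x_mean=est._x_mean,
        x_std=np.asarray(x_std, dtype=float),
        y_mean=est._y_mean,
        y_std=np.asarray(y_std, dtype=float),
        coef=est.coef_.T.copy(),
        intercept=est.intercept_ - est._x_mean @ est.coef_.T,
        x_rotations=est.x_rotations_,
    )


@dataclass(frozen=True)
class FateModel:
    """A fitted fate model, linear or power-law.

    For ``kind="powerlaw"`` the prediction is
    ``P = exp(beta0 + sum_i beta_i ln x_i) + epsilon``;
    for ``kind="linear"`` it is ``P = beta0 + sum_i beta_i x_i`` (``beta0``
    is the fitted intercept, zero when intercepts are disabled).
    ``knocked`` records proteins removed by virtual knock-down.
    """

    kind: str
    beta0: float
    beta: np.ndarray
    epsilon: float
    protein_names: tuple[str, ...]
    n_components: int = 0
    knocked: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "powerlaw"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if len(self.beta) != len(self.protein_names):
            raise ValueError("coefficient length does not match protein count")

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "beta0": self.beta0,
                "beta": list(map(float, self.beta)),
                "epsilon": self.epsilon,
                "protein_names": list(self.protein_names),
                "n_components": self.n_components,
                "knocked": sorted(self.knocked),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FateModel":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            beta0=float(d["beta0"]),
            beta=np.asarray(d["beta"], dtype=float),
            epsilon=float(d["epsilon"]),
            protein_names=tuple(d["protein_names"]),
            n_components=int(d.get("n_components", 0)),
            knocked=frozenset(d.get("knocked", ())),
        )


def default_n_components(n_rows: int, n_features: int) -> int:
    return max(1, min(10, rank_bound(n_rows, n_features)))


def fit_fate_model(
    table: ObservationTable,
    fate: str,
    kind: str,
    epsilon: float = DEFAULT_EPSILON,
    n_components: int | None = None,
    fit_intercept: bool = True,
) -> FateModel:
    """Fit a fate model on a filtered observation table.

    The power-law kind regresses ln(P - epsilon) on ln(x) and stores the
    intercept beta0 and exponents beta_i; the linear kind regresses P on x
    directly.  Coefficients are the PLS-implied regression coefficients
    mapped back through the centering/scaling.
    """
    if table.n_obs == 0:
        raise ValueError("empty table")
    if fate not in table.fate_names:
        raise ValueError(f"unknown fate {fate!r}")
    X = table.signals().to_numpy(dtype=float)
    y = table.data[fate].to_numpy(dtype=float)
    if kind == "powerlaw":
        if (X <= 0).any():
            raise ValueError("power-law kind requires strictly positive signals")
        if epsilon >= y.min():
            raise ValueError(
                f"epsilon={epsilon} must be below the minimum fate value {y.min()}"
            )
        Xr = np.log(X)
        yr = np.log(y - epsilon)
    elif kind == "linear":
        Xr, yr = X, y
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    if n_components is None:
        n_components = default_n_components(*Xr.shape)
    if yr.std() < _ZERO_VAR_TOL:
        # Constant response: PLS weights are undefined; the exact fit is
        # an intercept-only model.
        beta = np.zeros(Xr.shape[1])
        beta0 = float(yr.mean()) if fit_intercept else 0.0
    else:
        pls = fit_pls(Xr, yr, n_components=n_components)
        beta = pls.coef[:, 0]
        beta0 = float(pls.intercept[0]) if fit_intercept else 0.0
    return FateModel(
        kind=kind,
        beta0=beta0,
        beta=beta,
        epsilon=epsilon,
        protein_names=table.signal_names,
        n_components=n_components,
    )


def _signal_matrix(model: FateModel, signals) -> np.ndarray:
    """Order-normalised signal matrix (rows x proteins in model order)."""
    if isinstance(signals, ObservationTable):
        signals = signals.signals()
    if isinstance(signals, dict):
        signals = pd.DataFrame([signals])
    if isinstance(signals, pd.DataFrame):
        missing = set(model.protein_names) - set(signals.columns)
        if missing:
            raise ValueError(f"missing proteins: {sorted(missing)}")
        X = signals.loc[:, list(model.protein_names)].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(signals, dtype=float))
        if X.shape[1] != len(model.protein_names):
            raise ValueError("signal vector length does not match model")
    return X


def predict_fate(model: FateModel, signals) -> np.ndarray:
    """Predict fate values for one or more signal vectors.

    ``signals`` may be a dict (protein -> activity), a DataFrame with
    protein-named columns (order-independent), an ObservationTable, or a
    plain array already in model order.  Returns a 1-D array (scalar input
    gives a length-1 array).
    """
    X = _signal_matrix(model, signals)
    if model.kind == "powerlaw":
        if (X <= 0).any():
            raise ValueError("power-law prediction requires positive signals")
        return np.exp(model.beta0 + np.log(X) @ model.beta) + model.epsilon
    return model.beta0 + X @ model.beta


def choose_n_components(
    table: ObservationTable,
    fate: str,
    kind: str,
    epsilon: float = DEFAULT_EPSILON,
    candidates=None,
    n_folds: int = 5,
    seed: int = 0,
) -> int:
    """Pick a component count by inner k-fold CV, maximizing held-out Pearson."""
    from scipy.stats import pearsonr

    n = table.n_obs
    bound = rank_bound(n - n // n_folds, len(table.signal_names))
    if candidates is None:
        candidates = range(1, min(10, bound) + 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    best, best_score = None, -np.inf
    for nc in candidates:
        scores = []
        for f in folds:
            test = np.zeros(n, dtype=bool)
            test[f] = True
            train_tab = table.subset(~test)
            test_tab = table.subset(test)
            try:
                m = fit_fate_model(train_tab, fate, kind, epsilon, n_components=nc)
            except ValueError:
                scores.append(-np.inf)
                continue
            pred = predict_fate(m, test_tab)
            actual = test_tab.data[fate].to_numpy(dtype=float)
            if len(actual) < 3 or np.std(pred) < _ZERO_VAR_TOL or np.std(actual) < _ZERO_VAR_TOL:
                continue
            scores.append(pearsonr(actual, pred).statistic)
        score = np.mean(scores) if scores else -np.inf
        if score > best_score:
            best, best_score = nc, score
    if best is None:
        raise ValueError("no admissible component count")
    return best
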