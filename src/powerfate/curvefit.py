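"""Single-variable least-squares fits of four candidate curve families.

Used to ask which functional family best describes a saturating
signal-to-death trajectory: power y = a*x^b, linear y = a*x + b,
exponential y = a*exp(b*x), or gaussian y = a*exp(-((x-b)/c)^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .metrics import goodness_of_fit

FAMILIES = ("power", "linear", "exponential", "gaussian")

_MODELS = {
    "power": (lambda x, a, b: a * np.power(x, b), 2),
    "linear": (lambda x, a, b: a * x + b, 2),
    "exponential": (lambda x, a, b: a * np.exp(b * x), 2),
    "gaussian": (lambda x, a, b, c: a * np.exp(-(((x - b) / c) ** 2)), 3),
}

_N_RESTARTS = 3


@dataclass(frozen=True)
class CurveFitResult:
    family: str
    params: dict[str, float]
    sse: float
    r2: float
    adj_r2: float
    rmse: float

    @property
    def n_params(self) -> int:
        return len(self.params)


def _initial_guess(x: np.ndarray, y: np.ndarray, family: str) -> np.ndarray:
    """Deterministic starting point; power/exponential from the log-linear
    closed form, gaussian from (max y, argmax x, half-range)."""
    if family == "power":
        pos = (x > 0) & (y > 0)
        if pos.sum() >= 2:
            b, loga = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
            return np.array([np.exp(loga), b])
        return np.array([1.0, 1.0])
    if family == "exponential":
        pos = y > 0
        if pos.sum() >= 2:
            b, loga = np.polyfit(x[pos], np.log(y[pos]), 1)
            return np.array([np.exp(loga), b])
        return np.array([1.0, 0.1])
    if family == "gaussian":
        half_range = (x.max() - x.min()) / 2 or 1.0
        return np.array([y.max(), x[np.argmax(y)], half_range])
    raise ValueError(family)


def fit_family(x, y, family: str) -> CurveFitResult:
    """Least-squares fit of one family; deterministic given the documented
    initialization, with 3 seeded jittered restarts on non-convergence."""
    if family not in _MODELS:
        raise ValueError(f"unknown family {family!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    func, k = _MODELS[family]
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if len(x) < k + 1:
        raise ValueError("need more points than parameters")
    if family == "power" and (x <= 0).any():
        raise ValueError("power family requires x > 0")

    if family == "linear":
        a, b = np.polyfit(x, y, 1)
        params = np.array([a, b])
    else:
        p0 = _initial_guess(x, y, family)
        bounds = (-np.inf, np.inf)
        if family == "gaussian":
            # Monotone data push the peak and width to infinity; generous
            # bounds keep the optimizer (TRF) convergent and the fit
            # effectively unconstrained on realistic trajectories.
            span = (x.max() - x.min()) or 1.0
            ymax = max(abs(y).max(), 1e-12)
            bounds = ([-10 * ymax, x.min() - 10 * span, 1e-12],
                      [10 * ymax, x.max() + 10 * span, 100 * span])
            p0 = np.clip(p0, bounds[0], bounds[1])
        rng = np.random.default_rng(0)
        params = None
        last_err: Exception | None = None
        for attempt in range(_N_RESTARTS + 1):
            start = p0 if attempt == 0 else p0 * rng.normal(1.0, 0.3, size=p0.shape)
            start = np.clip(start, bounds[0], bounds[1])
            try:
                params, _ = curve_fit(func, x, y, p0=start, bounds=bounds,
                                      maxfev=20000)
                break
            except RuntimeError as err:  # pragma: no cover - rare
                last_err = err
        if params is None:
            raise RuntimeError(f"{family} fit failed to converge: {last_err}")
    y_hat = func(x, *params)
    gof = goodness_of_fit(y, y_hat, n_params=k)
    names = ("a", "b", "c")[:k]
    return CurveFitResult(
        family=family,
        params={n: float(v) for n, v in zip(names, params)},
        **gof,
    )


def compare_families(x, y) -> list[CurveFitResult]:
    """Fit all four families; results in canonical family order, with the
    best family (smallest RMSE; ties broken by larger R-squared, then family
    name) listed first by :func:`best_family`."""
    return [fit_family(x, y, fam) for fam in FAMILIES]


def best_family(results: list[CurveFitResult]) -> CurveFitResult:
    return min(results, key=lambda r: (r.rmse, -r.r2, r.family))
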