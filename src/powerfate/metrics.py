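"""Evaluation statistics: correlations, KL loss, AIC, goodness of fit, ANOVA.

The loss used for probability predictions is a base-2 Kullback-Leibler sum
over the prediction list, L(p, p_hat) = sum_i p_i log2(p_i / p_hat_i); the
model-comparison score wraps it as AIC = log2(L) + 2k/m (the base-2 log is
the convention consistent with the base-2 loss; a natural-log variant is
available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Clipping interval applied to predicted probabilities before the KL log;
#: the power-law model can predict values outside (0, 1].
KL_CLIP = (1e-12, 1.0)


@dataclass(frozen=True)
class EvalResult:
    """Per-evaluation summary (one cross-validation fold, or one transfer)."""

    spearman: float
    pearson: float
    rmse: float
    kl: float
    n_predictions: int
    valid: bool = True


def kl_divergence(p, p_hat, clip: tuple[float, float] = KL_CLIP) -> float:
    """Base-2 KL loss over a list of (actual, predicted) probability pairs.

    No renormalization is applied — the sum runs over the m predictions as
    given.  Terms with p_i = 0 contribute exactly 0; predictions are clipped
    to ``clip`` before the log.
    """
    p = np.asarray(p, dtype=float)
    p_hat = np.asarray(p_hat, dtype=float)
    if p.shape != p_hat.shape:
        raise ValueError("length mismatch between p and p_hat")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("actual probabilities must lie in [0, 1]")
    q = np.clip(p_hat, *clip)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def aic(loss: float, k: int, m: int, base: str = "2") -> float:
    """AIC-style score log(L) + 2k/m for a KL loss L with k parameters, m predictions.

    ``base="2"`` (default) matches the base-2 loss; ``base="e"`` uses the
    natural logarithm.
    """
    if loss <= 0:
        raise ValueError("loss must be positive")
    if m <= 0:
        raise ValueError("m must be positive")
    log = np.log2 if base == "2" else np.log
    return float(log(loss) + 2.0 * k / m)


def goodness_of_fit(y, y_hat, n_params: int, rmse_denominator: str = "residual_dof") -> dict:
    """SSE, R-squared, adjusted R-squared and RMSE for a fit.

    ``rmse_denominator="residual_dof"`` divides the SSE by (n - k) as
    curve-fitting tools do (default); ``"n"`` gives the plain prediction RMSE
    sqrt(SSE / n).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    n = len(y)
    sse = float(np.sum((y - y_hat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero total variance: R-squared undefined")
    r2 = 1.0 - sse / sst
    if n > n_params:
        adj_r2 = 1.0 - (sse / (n - n_params)) / (sst / (n - 1))
    else:
        adj_r2 = float("nan")
    if rmse_denominator == "residual_dof":
        dof = n - n_params
        if dof <= 0:
            raise ValueError("no residual degrees of freedom")
        rmse = float(np.sqrt(sse / dof))
    elif rmse_denominator == "n":
        rmse = float(np.sqrt(sse / n))
    else:
        raise ValueError(f"unknown rmse_denominator {rmse_denominator!r}")
    return {"sse": sse, "r2": r2, "adj_r2": adj_r2, "rmse": rmse}


def prediction_rmse(y, y_hat) -> float:
    """Root mean squared prediction error, sqrt(mean((y - y_hat)^2))."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def rank_correlation(y, y_hat) -> dict:
    """Spearman (average-rank ties) and Pearson correlations."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 points for correlations")
    if np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        raise ValueError("zero variance: correlation undefined")
    return {
        "spearman": float(stats.spearmanr(y, y_hat).statistic),
        "pearson": float(stats.pearsonr(y, y_hat).statistic),
    }


def oneway_anova(*groups) -> dict:
    """Classical one-way ANOVA F statistic and upper-tail p value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 values")
    res = stats.f_oneway(*groups)
    f = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(f):  # identical groups: no between- or within-group variance
        f, p = 0.0, 1.0
    return {"F": f, "p": p}


def evaluate_predictions(actual, predicted) -> EvalResult:
    """Bundle the standard prediction metrics; flags degenerate cases.

    Correlations are undefined for fewer than 3 points or zero-variance
    vectors; such evaluations are returned with ``valid=False`` (NaN
    correlations) so callers can exclude them from threshold counts.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    rmse = prediction_rmse(actual, predicted)
    kl = kl_divergence(np.clip(actual, 0.0, 1.0), predicted)
    try:
        corr = rank_correlation(actual, predicted)
        return EvalResult(corr["spearman"], corr["pearson"], rmse, kl, len(actual))
    except ValueError:
        return EvalResult(float("nan"), float("nan"), rmse, kl, len(actual), valid=False)
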