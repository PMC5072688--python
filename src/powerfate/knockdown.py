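"""Influence matrix, virtual protein knock-down and drug-effect ranking.

Each protein's activity is modeled as a power-law function of every other
protein, x_i = e^(lambda_i0) * prod_{j != i} x_j^(lambda_ij) + eps_i.  The
exponents form the influence matrix M (zero diagonal).  A virtual
knock-down of protein k zeroes column k of M (k no longer influences
anyone), zeroes the fate coefficient beta_k, and rewires the remaining fate
coefficients to the influence-mediated values beta'_j = sum_i lambda_ij
beta_i.  Ranking candidate knock-downs by the RMSE of the rewired model
against drugged (or stimulated) observations points at the proteins whose
incoming signal flow the treatment blocked or enhanced.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datamodel import ObservationTable
from .metrics import prediction_rmse
from .regression import FateModel, default_n_components, fit_pls, predict_fate


@dataclass(frozen=True)
class InfluenceMatrix:
    """Protein-on-protein power-law exponents.

    ``lam[i, j]`` is the influence of protein j on protein i; the diagonal is
    identically zero.  Row i holds the coefficients of the regression for
    protein i, with intercept ``lam0[i]`` and offset ``eps[i]``.
    """

    lam: np.ndarray
    lam0: np.ndarray
    eps: np.ndarray
    protein_names: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.protein_names)
        if self.lam.shape != (n, n):
            raise ValueError("lambda must be n x n")
        if not np.allclose(np.diag(self.lam), 0.0):
            raise ValueError("diagonal of lambda must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.lam, index=self.protein_names,
                            columns=self.protein_names)


@dataclass(frozen=True)
class KnockdownReport:
    """Proteins ranked by post-knock-down RMSE against observed fates.

    ``blocked`` mode sorts ascending (small RMSE = knocking the protein out
    reproduces the treated data, i.e. the treatment blocked its incoming
    signal); ``enhanced`` mode is the exact reversal.
    """

    mode: str
    entries: tuple[tuple[str, float], ...]

    def top(self, n: int) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries[:n])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["protein", "rmse"])
        df["rank"] = np.arange(1, len(df) + 1)
        return df


def fit_influence_matrix(
    table: ObservationTable,
    epsilon_vec=None,
    n_components: int | None = None,
) -> InfluenceMatrix:
    """Fit the influence matrix by n independent log-space PLS regressions.

    Protein i is regressed (in log space, after subtracting its offset
    eps_i) on all proteins j != i.  ``epsilon_vec`` defaults to a uniform
    small offset; each eps_i must stay below the minimum observed x_i.
    """
    proteins = table.signal_names
    n = len(proteins)
    if table.n_obs < 2:
        raise ValueError("need at least 2 observations")
    X = table.signals().to_numpy(dtype=float)
    if (X <= 0).any():
        raise ValueError("influence fitting requires strictly positive signals")
    if epsilon_vec is None:
        epsilon_vec = np.full(n, 1e-6)
    epsilon_vec = np.asarray(epsilon_vec, dtype=float)
    mins = X.min(axis=0)
    if (epsilon_vec >= mins).any():
        raise ValueError("every eps_i must be below the minimum observed x_i")
    logX = np.log(X)
    lam = np.zeros((n, n))
    lam0 = np.zeros(n)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        Xi = logX[:, others]
        yi = np.log(X[:, i] - epsilon_vec[i])
        if np.std(Xi, axis=0).min() < 1e-12:
            raise ValueError(f"constant protein column among predictors of {proteins[i]}")
        nc = n_components or default_n_components(len(yi), len(others))
        nc = min(nc, len(others), len(yi) - 1)
        if yi.std() < 1e-12:
            lam0[i] = yi.mean()
            continue
        pls = fit_pls(Xi, yi, n_components=nc)
        lam[i, others] = pls.coef[:, 0]
        lam0[i] = float(pls.intercept[0])
    return InfluenceMatrix(lam=lam, lam0=lam0, eps=epsilon_vec,
                           protein_names=proteins)


def virtual_knockdown(
    M: InfluenceMatrix,
    fate_model: FateModel,
    k: int,
    rule: str = "replace",
) -> FateModel:
    """Return the fate model after an in-silico knock-down of protein k.

    Order of operations: zero column k of a working copy of M (protein k no
    longer influences anyone), zero beta_k, then set every remaining
    coefficient to the influence-mediated value beta'_j = sum_i lambda_ij
    beta_i (``rule="replace"``, the literal rewiring) or add that value to
    the direct coefficient (``rule="additive"``).  beta0 and epsilon are
    unchanged; inputs are not modified.  Knocking an already-knocked protein
    is a no-op, so repeated knock-down of the same protein is idempotent.
    """
    if fate_model.kind != "powerlaw":
        raise ValueError("virtual knock-down requires a power-law fate model")
    if M.protein_names != fate_model.protein_names:
        raise ValueError("model and influence matrix protein order differ")
    n = len(M.protein_names)
    if not 0 <= k < n:
        raise IndexError(f"protein index {k} out of range")
    if rule not in ("replace", "additive"):
        raise ValueError(f"unknown rewiring rule {rule!r}")
    name_k = M.protein_names[k]
    if name_k in fate_model.knocked:
        return replace(fate_model)
    lam = M.lam.copy()
    lam[:, k] = 0.0
    beta = fate_model.beta.copy()
    beta[k] = 0.0
    mediated = lam.T @ beta  # mediated_j = sum_i lambda_ij * beta_i
    new_beta = mediated if rule == "replace" else beta + mediated
    new_beta[k] = 0.0
    return replace(
        fate_model,
        beta=new_beta,
        knocked=fate_model.knocked | {name_k},
    )


def rank_knockdowns(
    fate_model: FateModel,
    M: InfluenceMatrix,
    observed: ObservationTable,
    fate: str,
    mode: str = "blocked",
    rule: str = "replace",
) -> KnockdownReport:
    """Rank candidate knock-downs by fit to the drugged/stimulated data.

    For every protein k, the virtually knocked-down model predicts the
    observed fates and the RMSE against the actual values is recorded.
    ``blocked`` mode sorts ascending by RMSE (ties broken by protein name);
    ``enhanced`` mode is the exact reversal of that ordering.
    """
    if mode not in ("blocked", "enhanced"):
        raise ValueError(f"unknown mode {mode!r}")
    if observed.n_obs == 0:
        raise ValueError("empty observed table")
    actual = observed.data[fate].to_numpy(dtype=float)
    entries = []
    for k, name in enumerate(M.protein_names):
        model_k = virtual_knockdown(M, fate_model, k, rule=rule)
        pred = predict_fate(model_k, observed)
        entries.append((name, prediction_rmse(actual, pred)))
    entries.sort(key=lambda e: (e[1], e[0]))
    if mode == "enhanced":
        entries = entries[::-1]
    return KnockdownReport(mode=mode, entries=tuple(entries))
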