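"""Experiment protocols: cross-validation, transfer, time-staggering, discrimination.

Every protocol is a pure, seeded function of its inputs: running twice with
the same seed gives identical reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import BREAST_CANCER_TIME_GRID, ObservationTable
from .metrics import EvalResult, evaluate_predictions, prediction_rmse
from .regression import (
    DEFAULT_EPSILON,
    FateModel,
    default_n_components,
    fit_fate_model,
    fit_pls,
    predict_fate,
    rank_bound,
)


@dataclass(frozen=True)
class SplitScheme:
    """How to split observations: repeated k-fold, LOOCV or a train fraction."""

    kind: str = "kfold"
    k: int = 5
    repeats: int = 1
    seed: int = 0
    fraction: float = 2 / 3

    def __post_init__(self) -> None:
        if self.kind not in ("kfold", "loocv", "train_test_fraction"):
            raise ValueError(f"unknown split kind {self.kind!r}")


def iter_folds(n: int, scheme: SplitScheme):
    """Yield (train_indices, test_indices) pairs.

    k-fold assignment is a uniform random permutation cut into contiguous
    blocks (no stratification); each observation lands in exactly one test
    fold per repeat.  LOOCV is deterministic.  The train/test-fraction kind
    yields one split per repeat.
    """
    rng = np.random.default_rng(scheme.seed)
    if scheme.kind == "loocv":
        for i in range(n):
            test = np.array([i])
            train = np.concatenate([np.arange(i), np.arange(i + 1, n)])
            yield train, test
        return
    for _ in range(scheme.repeats):
        perm = rng.permutation(n)
        if scheme.kind == "kfold":
            for block in np.array_split(perm, scheme.k):
                mask = np.ones(n, dtype=bool)
                mask[block] = False
                yield np.flatnonzero(mask), np.sort(block)
        else:  # train_test_fraction
            cut = int(round(scheme.fraction * n))
            if cut < 1 or cut >= n:
                raise ValueError("degenerate split sizes")
            yield np.sort(perm[:cut]), np.sort(perm[cut:])


def run_crossval(
    table: ObservationTable,
    fate: str,
    kind: str,
    scheme: SplitScheme,
    epsilon: float = DEFAULT_EPSILON,
    n_components: int | None = None,
) -> list[EvalResult]:
    """Cross-validate a fate model; one EvalResult per test fold.

    Per fold: fit on the training rows, predict the test rows, score
    Spearman/Pearson/RMSE/KL.  Folds with fewer than 3 test rows or
    degenerate variance are returned with ``valid=False`` and are excluded
    from threshold counts downstream.  5-fold x 200 repeats gives exactly
    1000 results.
    """
    results = []
    for train_idx, test_idx in iter_folds(table.n_obs, scheme):
        train = table.subset(train_idx)
        test = table.subset(test_idx)
        model = fit_fate_model(train, fate, kind, epsilon, n_components)
        pred = predict_fate(model, test)
        actual = test.data[fate].to_numpy(dtype=float)
        results.append(evaluate_predictions(actual, pred))
    return results


def count_joint_threshold(results: list[EvalResult], tau: float) -> int:
    """How many results clear tau on both Spearman and Pearson.

    Invalid (degenerate) results never count; the count is monotonically
    non-increasing in tau.
    """
    return sum(1 for r in results
               if r.valid and r.spearman > tau and r.pearson > tau)


def summarize_crossval(results: list[EvalResult],
                       thresholds=(0.7, 0.8, 0.9)) -> dict:
    """Flat report: threshold counts, totals, mean correlations."""
    valid = [r for r in results if r.valid]
    total_kl = float(sum(r.kl for r in results))
    total_pred = int(sum(r.n_predictions for r in results))
    out = {
        "n_results": len(results),
        "n_valid": len(valid),
        "n_excluded": len(results) - len(valid),
        "total_kl": total_kl,
        "total_predictions": total_pred,
        "mean_spearman": float(np.mean([r.spearman for r in valid])) if valid else float("nan"),
        "mean_pearson": float(np.mean([r.pearson for r in valid])) if valid else float("nan"),
    }
    for tau in thresholds:
        out[f"count_tau_{tau}"] = count_joint_threshold(results, tau)
    return out


def cross_cellline(
    train: ObservationTable,
    test: ObservationTable,
    fate: str,
    kind: str,
    epsilon: float = DEFAULT_EPSILON,
    n_components: int | None = None,
) -> EvalResult:
    """Train on one cell line, evaluate on another (single fit, single test)."""
    if set(train.signal_names) != set(test.signal_names):
        raise ValueError("train and test protein sets differ")
    model = fit_fate_model(train, fate, kind, epsilon, n_components)
    pred = predict_fate(model, test)
    actual = test.data[fate].to_numpy(dtype=float)
    return evaluate_predictions(actual, pred)


def _mean_parameter_model(models: list[FateModel]) -> FateModel:
    """Arithmetic mean of back-transformed coefficients across CV folds."""
    first = models[0]
    beta = np.mean([m.beta for m in models], axis=0)
    beta0 = float(np.mean([m.beta0 for m in models]))
    return FateModel(kind=first.kind, beta0=beta0, beta=beta,
                     epsilon=first.epsilon, protein_names=first.protein_names,
                     n_components=first.n_components)


def dream8_protein_cv(
    table: ObservationTable,
    kind: str,
    seed: int = 0,
    n_repeats: int = 100,
    epsilon: float = DEFAULT_EPSILON,
    n_components: int | None = None,
) -> dict:
    """Signals-only protocol: predict each protein from all the others.

    Per repeat: a random 2/3-1/3 split; for each protein as dependent
    variable, leave-one-out CV on the training part, parameters averaged
    over folds, prediction on the test part; RMSE aggregated over proteins
    and repeats.  Returns the mean RMSE plus per-protein means.
    """
    proteins = table.signal_names
    if len(proteins) < 3:
        raise ValueError("need at least 3 proteins")
    n = table.n_obs
    rng = np.random.default_rng(seed)
    per_protein: dict[str, list[float]] = {p: [] for p in proteins}
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        cut = int(round(2 * n / 3))
        if cut < 3 or cut >= n:
            raise ValueError("degenerate split sizes")
        train = table.subset(np.sort(perm[:cut]))
        test = table.subset(np.sort(perm[cut:]))
        for p in proteins:
            others = tuple(q for q in proteins if q != p)
            sub_train = ObservationTable(train.data, others, (p,),
                                         train.metadata_names)
            sub_test = ObservationTable(test.data, others, (p,),
                                        test.metadata_names)
            fold_models = []
            for tr_idx, _ in iter_folds(sub_train.n_obs, SplitScheme(kind="loocv")):
                fold_models.append(
                    fit_fate_model(sub_train.subset(tr_idx), p, kind,
                                   epsilon, n_components)
                )
            model = _mean_parameter_model(fold_models)
            pred = predict_fate(model, sub_test)
            actual = sub_test.data[p].to_numpy(dtype=float)
            per_protein[p].append(prediction_rmse(actual, pred))
    means = {p: float(np.mean(v)) for p, v in per_protein.items()}
    return {"mean_rmse": float(np.mean(list(means.values()))),
            "per_protein": means}


def stagger_index_pairs(input_indices, output_indices, degree: int) -> set[tuple[int, int]]:
    """(input index, output index) pairs for a time-staggered design.

    Every output index o > 0 pairs with input index o - degree when that
    index was measured; output index 0 pairs with input index 0 (baseline
    to baseline).  Unmatched outputs are dropped.
    """
    inputs = set(input_indices)
    pairs = set()
    for o in output_indices:
        if o == 0:
            if 0 in inputs:
                pairs.add((0, 0))
        elif o - degree in inputs:
            pairs.add((o - degree, o))
    if not pairs:
        raise ValueError(f"degree {degree} produces no pairs")
    return pairs


def time_staggered_pairs(
    signals: ObservationTable,
    fates: ObservationTable,
    degree: int,
    time_grid=BREAST_CANCER_TIME_GRID,
    match_on: tuple[str, ...] = ("cell_line", "treatment", "replicate"),
) -> ObservationTable:
    """Join signal rows to fate rows measured ``degree`` grid positions later.

    Time points are mapped to index positions on ``time_grid``; rows are
    matched within each ``match_on`` combination using
    :func:`stagger_index_pairs`.  The result carries the signal vector of
    the input row and the fate vector of the output row; its ``time_point``
    is the output time.
    """
    grid = {t: i for i, t in enumerate(time_grid)}

    def indexed(tab: ObservationTable) -> pd.DataFrame:
        df = tab.data.copy()
        unknown = set(df["time_point"]) - set(grid)
        if unknown:
            raise ValueError(f"time points not on grid: {sorted(unknown)}")
        df["_tidx"] = df["time_point"].map(grid)
        return df

    sig = indexed(signals)
    fat = indexed(fates)
    pairs = stagger_index_pairs(sorted(sig["_tidx"].unique()),
                                sorted(fat["_tidx"].unique()), degree)
    pair_df = pd.DataFrame(sorted(pairs), columns=["_tidx_in", "_tidx_out"])
    keys = list(match_on)
    sig_part = sig[keys + ["_tidx"] + list(signals.signal_names)].rename(
        columns={"_tidx": "_tidx_in"})
    fat_part = fat[keys + ["_tidx", "time_point"] + list(fates.fate_names)].rename(
        columns={"_tidx": "_tidx_out"})
    merged = (sig_part.merge(pair_df, on="_tidx_in")
              .merge(fat_part, on=keys + ["_tidx_out"]))
    merged = merged.drop(columns=["_tidx_in", "_tidx_out"]).reset_index(drop=True)
    return ObservationTable(merged, signals.signal_names, fates.fate_names,
                            tuple(keys) + ("time_point",))


def cellline_scores(
    combined: ObservationTable,
    kind: str,
    label_column: str = "cell_line",
    n_components: int = 2,
    epsilon: float = DEFAULT_EPSILON,
) -> dict:
    """Project observations onto the first two PLS latent components and
    assign each to the nearest cell-line centroid.

    For the power-law kind the signals (and the fate response) are
    log-transformed before the PLS fit.  Returns the score coordinates, the
    true and assigned labels, per-line centroids and the misclassification
    count (observations whose nearest centroid, Euclidean in score space,
    differs from their label).
    """
    if n_components < 2:
        raise ValueError("need at least 2 components for 2-D scores")
    labels = combined.data[label_column].to_numpy()
    X = combined.signals().to_numpy(dtype=float)
    Y = combined.fates().to_numpy(dtype=float)
    if kind == "powerlaw":
        if (X <= 0).any() or (Y <= epsilon).any():
            raise ValueError("power-law kind requires positive signals and fates > epsilon")
        X = np.log(X)
        Y = np.log(Y - epsilon)
    nc = min(n_components, rank_bound(*X.shape))
    if nc < 2:
        raise ValueError("fewer than 2 components available")
    pls = fit_pls(X, Y, n_components=nc)
    scores = pls.transform(X)[:, :2]
    uniq = sorted(pd.unique(labels))
    centroids = {lab: scores[labels == lab].mean(axis=0) for lab in uniq}
    cent_mat = np.stack([centroids[lab] for lab in uniq])
    dists = np.linalg.norm(scores[:, None, :] - cent_mat[None, :, :], axis=2)
    assigned = np.asarray(uniq, dtype=object)[dists.argmin(axis=1)]
    mis = int(np.sum(assigned != labels))
    frame = pd.DataFrame({
        "label": labels,
        "assigned": assigned,
        "score1": scores[:, 0],
        "score2": scores[:, 1],
    })
    return {"scores": frame, "centroids": centroids, "n_misclassified": mis}
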