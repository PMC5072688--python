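"""Observation tables: loading, validation, filtering and feature construction.

The pipeline's universal container is the :class:`ObservationTable`, a tidy
table with one observation per row.  Each observation carries metadata
(cell line, treatment, time point, replicate), a vector of positive
signaling-protein activities (e.g. phosphorylation levels) and one or more
cell-fate readouts (apoptotic fractions, counts, ...).  All downstream
model fitting assumes a table that has passed :func:`filter_valid`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Metadata column roles recognised in schemas, in canonical order.
METADATA_COLUMNS = ("cell_line", "treatment", "time_point", "replicate")

#: Acquisition grid (hours) of the breast-cancer time courses; signaling is
#: measured at index positions 0..7, fates at {0, 6, 7, 8, 9}.
BREAST_CANCER_TIME_GRID = (0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0)


@dataclass(frozen=True)
class ObservationTable:
    """Observations x (metadata, signals, fates) in tidy form.

    Parameters
    ----------
    data
        One row per observation.  Column order is preserved from the source.
    signal_names
        Columns holding protein activities ``x_i`` (positive reals after
        :func:`filter_valid`).
    fate_names
        Columns holding fate values (probabilities in (0, 1) or raw counts).
    metadata_names
        Remaining descriptive columns (cell line, treatment, ...).
    """

    data: pd.DataFrame
    signal_names: tuple[str, ...]
    fate_names: tuple[str, ...]
    metadata_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in (*self.signal_names, *self.fate_names, *self.metadata_names):
            if name not in self.data.columns:
                raise ValueError(f"column {name!r} missing from data")
        if len(set(self.signal_names)) != len(self.signal_names):
            raise ValueError("duplicate protein names")

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def signals(self) -> pd.DataFrame:
        return self.data.loc[:, list(self.signal_names)]

    def fates(self) -> pd.DataFrame:
        return self.data.loc[:, list(self.fate_names)]

    def metadata(self) -> pd.DataFrame:
        return self.data.loc[:, list(self.metadata_names)]

    def with_data(self, data: pd.DataFrame) -> "ObservationTable":
        return replace(self, data=data)

    def subset(self, mask) -> "ObservationTable":
        """Row subset preserving order (mask is boolean or an index array)."""
        return self.with_data(self.data.loc[mask].reset_index(drop=True))

    def to_csv(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class FeatureTable:
    """Derived features (one row per treatment/replicate) for HT-29-style data."""

    data: pd.DataFrame
    feature_names: tuple[str, ...]
    metadata_names: tuple[str, ...] = ()

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def features(self) -> pd.DataFrame:
        return self.data.loc[:, list(self.feature_names)]


def _sniff_delimiter(path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def load_observation_table(path, schema: dict[str, str]) -> ObservationTable:
    """Read a delimited text file into an :class:`ObservationTable`.

    ``schema`` maps each column name to a role: ``"metadata"``, ``"signal"``
    or ``"fate"``.  The delimiter (comma or tab) is auto-detected and a header
    row is required.  Cells that fail numeric parsing in signal or fate
    columns become missing values; they are only dropped by
    :func:`filter_valid`, keeping the filtering step auditable.
    """
    sep = _sniff_delimiter(path)
    data = pd.read_csv(path, sep=sep)
    missing = [c for c in schema if c not in data.columns]
    if missing:
        raise ValueError(f"schema references absent columns: {missing}")
    roles = {"metadata": [], "signal": [], "fate": []}
    for col, role in schema.items():
        if role not in roles:
            raise ValueError(f"unknown role {role!r} for column {col!r}")
        roles[role].append(col)
    if len(set(roles["signal"])) != len(roles["signal"]):
        raise ValueError("duplicate protein names in schema")
    for col in roles["signal"] + roles["fate"]:
        data[col] = pd.to_numeric(data[col], errors="coerce")
    return ObservationTable(
        data=data,
        signal_names=tuple(roles["signal"]),
        fate_names=tuple(roles["fate"]),
        metadata_names=tuple(roles["metadata"]),
    )


def filter_valid(table: ObservationTable) -> ObservationTable:
    """Drop observations with missing, zero or negative signal/fate values.

    Idempotent and order-preserving; the input table is not modified.  An
    empty result is allowed.
    """
    cols = list(table.signal_names) + list(table.fate_names)
    values = table.data.loc[:, cols]
    ok = values.notna().all(axis=1) & (values > 0).all(axis=1)
    return table.subset(ok.to_numpy())


def fate_probability(counts: dict[str, float]) -> dict[str, float]:
    """Convert raw cell counts per fate category to proportions.

    The categories are assumed exhaustive, so the output sums to 1.
    """
    vals = np.asarray(list(counts.values()), dtype=float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    total = vals.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    return {name: v / total for name, v in zip(counts, vals)}


def reverse_dream8_normalization(values, correction_factor: float) -> np.ndarray:
    """Undo the DREAM8 release normalization for one protein series.

    The released values are normalized linear ratios.  The reversal is:
    (i) multiply by the protein's correction factor, recovering the
    median-centered linear ratio; (ii) take log2; (iii) divide the resulting
    (already median-centered by provenance) series by its standard deviation
    (sample SD, n-1 denominator — fixed here for reproducibility).
    """
    values = np.asarray(values, dtype=float)
    if correction_factor <= 0:
        raise ValueError("correction factor must be positive")
    linear = values * correction_factor
    if (linear <= 0).any():
        raise ValueError("non-positive value before log2")
    logged = np.log2(linear)
    sd = logged.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("degenerate series: zero standard deviation")
    return logged / sd


DEFAULT_FEATURE_FAMILIES = ("raw", "derivative", "max", "mean", "steady_state")


def build_ht29_features(
    timecourse: ObservationTable,
    families: tuple[str, ...] = DEFAULT_FEATURE_FAMILIES,
    n_steady_state: int = 3,
    group_by: tuple[str, ...] = ("treatment", "replicate"),
) -> FeatureTable:
    """Build the high-dimensional predictor space from a signaling time course.

    One feature row is produced per ``group_by`` combination (treatment and
    replicate by default).  The table must contain the full acquisition grid
    for every group; the first grid point is the baseline sample.  Families:

    - ``raw``: signal of each protein at each post-baseline time point
      (named ``<protein>@t<k>``); for 19 proteins on the 14-point HT-29
      grid this is 19 x 13 = 247 columns.
    - ``derivative``: (value difference) / (time difference) over each pair
      of adjacent grid points (``<protein>@d<k>``); 13 intervals on the
      14-point grid give another 247 columns.
    - ``max``, ``mean``, ``steady_state``: one column per protein
      (``<protein>@max`` etc.); steady state is the mean of the last
      ``n_steady_state`` time points.
    - ``auc``: optional trapezoidal area under each protein's time course
      (``<protein>@auc``), off by default.

    The column count always equals the sum of the enabled family sizes.
    """
    known = {"raw", "derivative", "max", "mean", "steady_state", "auc"}
    unknown = set(families) - known
    if unknown:
        raise ValueError(f"unknown feature families: {sorted(unknown)}")
    if "time_point" not in timecourse.data.columns:
        raise ValueError("timecourse must carry a 'time_point' column")
    grid = np.sort(timecourse.data["time_point"].unique())
    if len(grid) < 2:
        raise ValueError("need at least two time points")
    proteins = timecourse.signal_names
    rows = []
    meta_rows = []
    for key, grp in timecourse.data.groupby(list(group_by), sort=True):
        grp = grp.sort_values("time_point")
        if not np.array_equal(grp["time_point"].to_numpy(), grid):
            raise ValueError(f"group {key!r} is missing time points")
        feats: dict[str, float] = {}
        times = grp["time_point"].to_numpy(dtype=float)
        for p in proteins:
            series = grp[p].to_numpy(dtype=float)
            if "raw" in families:
                for k in range(1, len(grid)):
                    feats[f"{p}@t{k}"] = series[k]
            if "derivative" in families:
                dt = np.diff(times)
                dv = np.diff(series) / dt
                for k, d in enumerate(dv, start=1):
                    feats[f"{p}@d{k}"] = d
            if "max" in families:
                feats[f"{p}@max"] = series.max()
            if "mean" in families:
                feats[f"{p}@mean"] = series.mean()
            if "steady_state" in families:
                feats[f"{p}@ss"] = series[-n_steady_state:].mean()
            if "auc" in families:
                feats[f"{p}@auc"] = np.trapezoid(series, times)
        rows.append(feats)
        meta_rows.append(dict(zip(group_by, key if isinstance(key, tuple) else (key,))))
    feature_names = tuple(rows[0].keys())
    data = pd.concat([pd.DataFrame(meta_rows), pd.DataFrame(rows)], axis=1)
    return FeatureTable(data=data, feature_names=feature_names,
                        metadata_names=tuple(group_by))


def sigmoid_normalize(matrix) -> np.ndarray:
    """Squash each column into (0, 1) via a z-score + logistic transform.

    Columns are standardized with the population SD (n denominator) and then
    passed through 1/(1+e^-z); the transform is strictly monotone within each
    column, so rank order is preserved.  A zero-variance column maps to 0.5
    everywhere.
    """
    mat = np.asarray(matrix, dtype=float)
    arr = mat.reshape(-1, 1) if mat.ndim == 1 else mat
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0)
    z = np.zeros_like(arr)
    nonzero = sd > 0
    z[:, nonzero] = (arr[:, nonzero] - mean[nonzero]) / sd[nonzero]
    out = 1.0 / (1.0 + np.exp(-z))
    return out.reshape(mat.shape)
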