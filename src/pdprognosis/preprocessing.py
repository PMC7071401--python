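"""Subject exclusion, imputation, outcome labelling and feature scaling.

The rules implemented here sit between the raw cohort table and the
classifiers: subjects missing more than two input features are dropped,
remaining gaps are filled with training-set medians, outcome scores are
thresholded into two categories per modality (MoCA 26/27, MDS-UPDRS-III
32/33, the worse category coded 1), and features are rescaled — by default
min–max onto [0, 1], the range of the autoencoder's logistic-sigmoid
decoder.  Every data-dependent parameter (medians, scaler statistics) is
estimated on training subjects only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable

MOCA_CUTOFF = 26   # score <= 26 -> mild cognitive impairment
UPDRS_CUTOFF = 33  # score >= 33 -> moderate motor impairment
MOCA_MAX = 30


@dataclass(frozen=True)
class BinaryOutcome:
    """A single thresholded outcome: 0 = better category, 1 = worse category."""

    modality: str  # "MoCA" or "UPDRS"
    year: int
    label: int


def label_moca(score) -> int:
    """Binary cognitive category from a MoCA score (0–30).

    Returns 0 for normal cognition (score >= 27) and 1 for mild cognitive
    impairment (score <= 26), i.e. the 26/27 cutoff.
    """
    score = float(score)
    if not (0 <= score <= MOCA_MAX):
        raise ValueError(f"MoCA score must lie in [0, {MOCA_MAX}], got {score}")
    return 1 if score <= MOCA_CUTOFF else 0


def label_updrs(score) -> int:
    """Binary motor category from an MDS-UPDRS-III score.

    Returns 0 for mild motor impairment (score <= 32) and 1 for moderate
    motor impairment (score >= 33), i.e. the 32/33 cutoff.
    """
    score = float(score)
    if score < 0:
        raise ValueError(f"UPDRS score must be non-negative, got {score}")
    return 1 if score >= UPDRS_CUTOFF else 0


def label_scores(scores, modality: str):
    """Vectorized labelling; *scores* may be scalar, array or DataFrame."""
    if modality == "MoCA":
        fn = label_moca
    elif modality == "UPDRS":
        fn = label_updrs
    else:
        raise ValueError(f"unknown modality {modality!r}")
    if isinstance(scores, pd.DataFrame):
        return scores.map(fn)
    if np.isscalar(scores):
        return fn(scores)
    return np.vectorize(fn)(np.asarray(scores))


def exclude_incomplete(table: CohortTable, max_missing: int = 2) -> CohortTable:
    """Drop subjects missing more than *max_missing* input features.

    Row order of the retained subjects is preserved; the operation is
    idempotent.
    """
    if max_missing < 0:
        raise ValueError("max_missing must be non-negative")
    keep = table.n_missing_per_subject() <= max_missing
    return table.subset(list(table.values.index[keep]))


def impute_median(table: CohortTable, train_ids) -> CohortTable:
    """Fill missing cells with per-feature medians of the training subjects.

    Raises if any feature is entirely missing within the training split.
    """
    train_ids = list(train_ids)
    medians = table.values.loc[train_ids].median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"features entirely missing in training split: {bad}")
    out = table.copy()
    out.values = out.values.fillna(medians)
    return out


@dataclass
class ScalerParams:
    """Per-feature affine scaling statistics fitted on training subjects.

    ``minmax`` mode stores the training minimum (``loc``) and range
    (``scale``); ``zscore`` stores mean and SD.  A constant training feature
    has ``scale`` 0 and maps to 0.5 (minmax) or 0.0 (zscore).
    """

    mode: str
    feature_names: list[str]
    loc: np.ndarray
    scale: np.ndarray

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "mode": self.mode,
            "feature_names": list(self.feature_names),
            "loc": self.loc.tolist(),
            "scale": self.scale.tolist(),
        }))

    @classmethod
    def from_json(cls, path) -> "ScalerParams":
        d = json.loads(Path(path).read_text())
        return cls(d["mode"], d["feature_names"], np.asarray(d["loc"]), np.asarray(d["scale"]))


def fit_scaler(table: CohortTable, train_ids, mode: str = "minmax") -> ScalerParams:
    """Estimate scaling statistics from the training rows of *table*."""
    train_ids = list(train_ids)
    if not train_ids:
        raise ValueError("training split is empty")
    if mode not in ("minmax", "zscore"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    X = table.values.loc[train_ids]
    if mode == "minmax":
        lo = X.min(axis=0, skipna=True).to_numpy(float)
        hi = X.max(axis=0, skipna=True).to_numpy(float)
        return ScalerParams(mode, list(table.values.columns), lo, hi - lo)
    mean = X.mean(axis=0, skipna=True).to_numpy(float)
    sd = X.std(axis=0, ddof=0, skipna=True).to_numpy(float)
    return ScalerParams(mode, list(table.values.columns), mean, sd)


def apply_scaler(table: CohortTable, params: ScalerParams) -> CohortTable:
    """Apply fitted scaling; columns must match the fit."""
    if list(table.values.columns) != list(params.feature_names):
        raise ValueError("table columns do not match scaler features")
    out = table.copy()
    scale = np.where(params.scale == 0, 1.0, params.scale)
    scaled = (out.values.to_numpy(float) - params.loc) / scale
    const = params.scale == 0
    if const.any():
        scaled[:, const] = 0.5 if params.mode == "minmax" else 0.0
    out.values = pd.DataFrame(scaled, index=out.values.index, columns=out.values.columns)
    return out


def invert_scaler(values: np.ndarray, params: ScalerParams) -> np.ndarray:
    """Undo :func:`apply_scaler` on a plain array (constant features return loc)."""
    v = np.asarray(values, float)
    out = v * np.where(params.scale == 0, 1.0, params.scale) + params.loc
    const = params.scale == 0
    if const.any():
        out[:, const] = params.loc[const]
    return out


def scale_matrix(values: pd.DataFrame, params: ScalerParams) -> np.ndarray:
    """Scale a plain feature DataFrame (subset of fitted columns allowed,
    given in fitted order) to a numpy matrix."""
    cols = list(values.columns)
    idx = [params.feature_names.index(c) for c in cols]
    loc, sc = params.loc[idx], params.scale[idx]
    scale = np.where(sc == 0, 1.0, sc)
    out = (values.to_numpy(float) - loc) / scale
    const = sc == 0
    if const.any():
        out[:, const] = 0.5 if params.mode == "minmax" else 0.0
    return out
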