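"""Core tabular containers for a baseline-feature cohort and its longitudinal outcomes.

A cohort is a subject-by-feature table of baseline measurements (regional
deformation-based-morphometry atrophy values, striatal binding ratios,
demographics, biospecimen assays, baseline clinical scores) together with
per-feature metadata.  Outcomes are raw MoCA / MDS-UPDRS-III scores at a set
of follow-up years plus the binary categories obtained by thresholding them.

Missing measurements are represented as NaN in the feature table; the
subject identifiers and metadata never carry missingness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical outcome modalities
MODALITIES = ("MoCA", "UPDRS")

#: feature modality vocabulary
FEATURE_MODALITIES = ("DBM", "SBR", "demographic", "biospecimen", "clinical")


@dataclass
class CohortTable:
    """Subject x feature matrix with per-feature metadata.

    Parameters
    ----------
    values
        DataFrame indexed by subject id, one column per feature; missing
        cells are NaN.
    feature_meta
        DataFrame with one row per feature column, columns
        ``name`` (matches a column of ``values``), ``modality`` (one of
        :data:`FEATURE_MODALITIES`) and ``hemisphere`` (``"L"``, ``"R"`` or
        ``"none"``).
    group
        Per-subject label, ``"patient"`` or ``"control"``, aligned with
        ``values.index``.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if list(self.feature_meta["name"]) != list(self.values.columns):
            raise ValueError("feature_meta rows must match value columns one-to-one")
        if self.values.index.has_duplicates:
            raise ValueError("subject ids must be unique")
        bad = set(self.feature_meta["modality"]) - set(FEATURE_MODALITIES)
        if bad:
            raise ValueError(f"unknown feature modalities: {sorted(bad)}")
        self.group = pd.Series(self.group, index=self.values.index)

    # -- convenience ----------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def dbm_columns(self) -> list[str]:
        return list(self.feature_meta.loc[self.feature_meta["modality"] == "DBM", "name"])

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index[self.group == "patient"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.values.index[self.group == "control"])

    def n_missing_per_subject(self) -> pd.Series:
        return self.values.isna().sum(axis=1)

    def copy(self) -> "CohortTable":
        return CohortTable(self.values.copy(), self.feature_meta.copy(), self.group.copy())

    def subset(self, subject_ids) -> "CohortTable":
        """Row subset preserving the given order."""
        return CohortTable(
            self.values.loc[list(subject_ids)].copy(),
            self.feature_meta.copy(),
            self.group.loc[list(subject_ids)].copy(),
        )

    # -- I/O ------------------------------------------------------------
    def to_csv(self, directory) -> None:
        """Write ``features.csv`` (one header row, empty cells = missing)
        and ``feature_meta.csv`` under *directory*."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = self.values.copy()
        out.insert(0, "group", self.group)
        out.to_csv(directory / "features.csv", index_label="subject_id")
        self.feature_meta.to_csv(directory / "feature_meta.csv", index=False)

    @classmethod
    def from_csv(cls, directory) -> "CohortTable":
        directory = Path(directory)
        df = pd.read_csv(directory / "features.csv", index_col="subject_id")
        df.index.name = None
        meta = pd.read_csv(directory / "feature_meta.csv")
        group = df.pop("group")
        return cls(df, meta, group)


@dataclass
class OutcomeLabels:
    """Raw outcome scores and their binary categories per modality.

    ``raw_scores[modality]`` and ``categories[modality]`` are DataFrames
    indexed by subject id with one integer column per follow-up year.
    Categories are fully determined by the raw scores through the modality
    cutoffs (MoCA 26/27, MDS-UPDRS-III 32/33); label 1 is the worse
    (impaired) category.
    """

    raw_scores: dict[str, pd.DataFrame]
    categories: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        for mod in self.raw_scores:
            if list(self.raw_scores[mod].columns) != list(self.categories[mod].columns):
                raise ValueError("raw_scores and categories must cover the same years")

    @property
    def years(self) -> list[int]:
        first = next(iter(self.raw_scores.values()))
        return [int(c) for c in first.columns]

    def to_csv(self, directory) -> None:
        """Long-format CSV: modality, subject_id, year, raw_score, category."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for mod, raw in self.raw_scores.items():
            cat = self.categories[mod]
            for year in raw.columns:
                for sid in raw.index:
                    rows.append((mod, sid, int(year), raw.loc[sid, year], cat.loc[sid, year]))
        pd.DataFrame(rows, columns=["modality", "subject_id", "year", "raw_score", "category"]).to_csv(
            directory / "outcomes.csv", index=False
        )

    @classmethod
    def from_csv(cls, directory) -> "OutcomeLabels":
        df = pd.read_csv(Path(directory) / "outcomes.csv")
        raw: dict[str, pd.DataFrame] = {}
        cat: dict[str, pd.DataFrame] = {}
        for mod, sub in df.groupby("modality", sort=False):
            order = sub["subject_id"].drop_duplicates()
            raw[mod] = sub.pivot(index="subject_id", columns="year",
                                 values="raw_score").reindex(order).rename_axis(None)
            cat[mod] = sub.pivot(index="subject_id", columns="year",
                                 values="category").reindex(order).rename_axis(None)
        return cls(raw, cat)


def save_ground_truth_json(obj: dict, path) -> None:
    """Serialize a ground-truth dictionary (numpy-friendly) to JSON."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return {"index": list(o.index), "columns": [int(c) for c in o.columns], "data": o.to_numpy().tolist()}
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, default=default, indent=1))
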