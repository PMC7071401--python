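"""Synthetic PPMI-like cohort generator with planted, year-varying regional effects.

The generator emulates the structure of a de-novo Parkinson cohort: 116
patients and 42 healthy controls carrying 78 regional deformation-based
morphometry (DBM) atrophy values, striatal binding ratios, demographics,
biospecimen assays and baseline clinical scores, plus longitudinal MoCA and
MDS-UPDRS-III scores at years 1–4.

The statistical model is a single scalar disease-severity latent per
patient (standard normal; fixed at 0 for controls).  Every DBM region loads
mildly on severity — producing the modest cross-feature rank correlations
seen in real baseline tables — and each follow-up score is a linear
combination of the (standardised) DBM columns weighted by a region x year
effect matrix, plus noise, with MoCA decreasing and UPDRS increasing in the
atrophy-driven signal.  Because the effect matrix can change across years,
the ground-truth "most salient region" can move — the oracle against which
the perturbation-saliency pipeline is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MODALITIES, CohortTable, OutcomeLabels, save_ground_truth_json
from .preprocessing import label_scores

# 39 non-cerebellar structures, each present in both hemispheres -> 78 regions.
REGION_STRUCTURES = [
    "Hippocampus",
    "Amygdala",
    "Anterior temporal lobe, medial part",
    "Anterior temporal lobe, lateral part",
    "Parahippocampal and ambient gyri",
    "Superior temporal gyrus, anterior part",
    "Superior temporal gyrus, posterior part",
    "Middle and inferior temporal gyrus",
    "Fusiform (lateral occipitotemporal) gyrus",
    "Insula",
    "Lateral remainder of occipital lobe",
    "Gyrus cinguli, anterior part",
    "Gyrus cinguli, posterior part",
    "Middle frontal gyrus",
    "Posterior temporal lobe",
    "Inferolateral remainder of parietal lobe",
    "Caudate nucleus",
    "Nucleus accumbens",
    "Putamen",
    "Thalamus",
    "Pallidum",
    "Precentral gyrus",
    "Straight gyrus",
    "Anterior orbital gyrus",
    "Inferior frontal gyrus",
    "Superior frontal gyrus",
    "Postcentral gyrus",
    "Superior parietal gyrus",
    "Lingual gyrus",
    "Cuneus",
    "Medial orbital gyrus",
    "Lateral orbital gyrus",
    "Posterior orbital gyrus",
    "Substantia Nigra",
    "Subgenual frontal cortex",
    "Subcallosal area",
    "Pre-subgenual frontal cortex",
    "Red Nucleus",
    "Subthalamic Nucleus",
]


def default_region_names(n_regions: int = 78) -> list[str]:
    """Region labels with hemisphere tags, ``"<structure> (L)"`` / ``"(R)"``.

    For the default 78 the packaged neuroanatomical vocabulary is used;
    other sizes fall back to generic paired labels.
    """
    if n_regions == 2 * len(REGION_STRUCTURES):
        names = []
        for s in REGION_STRUCTURES:
            names.append(f"{s} (L)")
            names.append(f"{s} (R)")
        return names
    names = []
    for k in range(n_regions):
        side = "L" if k % 2 == 0 else "R"
        names.append(f"Region {k // 2 + 1:02d} ({side})")
    return names


def region_hemispheres(region_names) -> list[str]:
    return ["L" if n.endswith("(L)") else "R" if n.endswith("(R)") else "none" for n in region_names]


# Non-DBM baseline covariates: (name, modality, mean, sd, severity loading).
# Means/SDs follow the published cohort summary (age 59.8+-9.5, baseline
# MoCA 27.5+-2.1, baseline UPDRS-III 20.6+-8.6, disease duration 6.26+-6.25
# months); loadings give each covariate a mild association with severity.
COVARIATE_PANEL = [
    ("Age", "demographic", 59.8, 9.5, 2.0),
    ("Sex (male=1)", "demographic", 0.64, 0.48, 0.0),
    ("Education years", "demographic", 15.0, 3.0, 0.0),
    ("Disease duration (months)", "clinical", 6.26, 6.25, 1.0),
    ("MoCA baseline", "clinical", 27.5, 2.1, -0.6),
    ("MDS-UPDRS-III baseline", "clinical", 20.6, 8.6, 3.0),
    ("Hoehn and Yahr", "clinical", 1.8, 0.5, 0.15),
    ("CSF alpha-synuclein", "biospecimen", 1500.0, 300.0, -60.0),
    ("CSF amyloid beta (1-42)", "biospecimen", 900.0, 200.0, -40.0),
]

SBR_PANEL = [
    ("Caudate SBR (L)", 2.0, 0.55, -0.25),
    ("Caudate SBR (R)", 2.0, 0.55, -0.25),
    ("Putamen SBR (L)", 0.85, 0.30, -0.12),
    ("Putamen SBR (R)", 0.85, 0.30, -0.12),
]

# Year-by-year centres of the raw-score distributions, chosen so the
# 26/27 and 32/33 cutoffs split the cohort into two populated categories
# with a mild progressive drift toward impairment.
MOCA_YEAR_CENTER = {1: 26.9, 2: 26.6, 3: 26.3, 4: 26.0}
UPDRS_YEAR_CENTER = {1: 31.5, 2: 32.0, 3: 32.5, 4: 33.0}
MOCA_POINTS_PER_SD = 2.1
UPDRS_POINTS_PER_SD = 7.0


@dataclass
class CohortConfig:
    """Everything that determines a synthetic cohort.

    ``effect_matrix`` maps each modality to an (n_dbm_regions x len(years))
    array of real weights: the contribution of each standardised DBM column
    to that year's outcome score.  ``interaction`` optionally maps a
    modality to ``(region_i, region_j, weight)`` adding a product
    (XOR-style) term to the score signal.
    """

    n_patients: int = 116
    n_controls: int = 42
    n_dbm_regions: int = 78
    region_names: list[str] | None = None
    n_clinical_features: int = 9
    years: tuple[int, ...] = (1, 2, 3, 4)
    effect_matrix: dict[str, np.ndarray] | None = None
    interaction: dict[str, tuple[int, int, float]] | None = None
    severity_loading: float = 0.08
    dbm_baseline_sd: float = 0.05
    noise_sd: float = 0.3
    score_noise_sd: float = 1.0
    missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.n_controls < 0:
            raise ValueError("n_controls must be non-negative")
        if self.noise_sd <= 0 or self.score_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.region_names is None:
            self.region_names = default_region_names(self.n_dbm_regions)
        if len(self.region_names) != self.n_dbm_regions:
            raise ValueError("region_names length must equal n_dbm_regions")
        if self.effect_matrix is None:
            self.effect_matrix = default_effect_matrix(self.region_names, self.years)
        for mod in MODALITIES:
            W = np.asarray(self.effect_matrix[mod], float)
            if W.shape != (self.n_dbm_regions, len(self.years)):
                raise ValueError(
                    f"effect_matrix[{mod!r}] must have shape "
                    f"({self.n_dbm_regions}, {len(self.years)}), got {W.shape}"
                )
            self.effect_matrix[mod] = W


def default_effect_matrix(region_names, years) -> dict[str, np.ndarray]:
    """Planted year-varying effects: one dominant region that switches
    identity midway through follow-up, plus small background weights.

    MoCA: Putamen (R) in years 1–2, Substantia Nigra (R) in years 3–4.
    UPDRS: Pallidum (L) in years 1–2, Caudate nucleus (L) in years 3–4.
    For non-default region lists lacking these labels the matrix is zero.
    """
    years = list(years)
    R = len(region_names)
    half = (len(years) + 1) // 2

    def build(early: str, late: str, minor: list[str]) -> np.ndarray:
        W = np.zeros((R, len(years)))
        if early in region_names and late in region_names:
            W[region_names.index(early), :half] = 0.9
            W[region_names.index(late), half:] = 0.9
            for m in minor:
                if m in region_names:
                    W[region_names.index(m), :] = 0.15
        return W

    return {
        "MoCA": build("Putamen (R)", "Substantia Nigra (R)",
                      ["Hippocampus (R)", "Amygdala (L)"]),
        "UPDRS": build("Pallidum (L)", "Caudate nucleus (L)",
                       ["Subcallosal area (L)"]),
    }


@dataclass
class GroundTruth:
    """What the generator planted, for use as a downstream oracle."""

    severity: pd.Series
    effect_matrix: dict[str, np.ndarray]
    region_names: list[str]
    years: tuple[int, ...]

    @property
    def planted_salient_regions(self) -> dict[str, dict[int, int | None]]:
        """Per modality and year, the index of the region with the largest
        absolute planted weight (ties -> lowest index; all-zero -> None)."""
        out: dict[str, dict[int, int | None]] = {}
        for mod, W in self.effect_matrix.items():
            out[mod] = {}
            for t, year in enumerate(self.years):
                col = np.abs(W[:, t])
                out[mod][year] = None if col.max() == 0 else int(np.argmax(col))
        return out

    def planted_salient_names(self) -> dict[str, dict[int, str | None]]:
        idx = self.planted_salient_regions
        return {
            mod: {y: (None if i is None else self.region_names[i]) for y, i in d.items()}
            for mod, d in idx.items()
        }

    def to_json(self, path) -> None:
        save_ground_truth_json({
            "severity": self.severity,
            "effect_matrix": {m: W for m, W in self.effect_matrix.items()},
            "region_names": self.region_names,
            "years": list(self.years),
            "planted_salient_regions": self.planted_salient_names(),
        }, path)


def generate_cohort(config: CohortConfig) -> tuple[CohortTable, OutcomeLabels, GroundTruth]:
    """Draw one synthetic cohort; identical config + seed is bit-identical.

    Returns the baseline feature table (with sporadic MCAR missingness at
    ``config.missing_rate``), the longitudinal outcomes, and the planted
    ground truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients + cfg.n_controls
    ids = [f"PD{k + 1:03d}" for k in range(cfg.n_patients)] + \
          [f"HC{k + 1:03d}" for k in range(cfg.n_controls)]
    group = pd.Series(["patient"] * cfg.n_patients + ["control"] * cfg.n_controls, index=ids)

    severity = np.concatenate([rng.standard_normal(cfg.n_patients), np.zeros(cfg.n_controls)])

    # DBM: per-region template mean near 1 (Jacobian-determinant scale),
    # shared severity loading, independent measurement noise.
    R = cfg.n_dbm_regions
    mu = 1.0 + cfg.dbm_baseline_sd * rng.standard_normal(R)
    dbm = mu + cfg.severity_loading * severity[:, None] + cfg.noise_sd * rng.standard_normal((n, R))
    sigma_z = np.hypot(cfg.severity_loading, cfg.noise_sd)
    z = (dbm - mu) / sigma_z  # standardised atrophy deviations

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[tuple[str, str, str]] = []
    hemis = region_hemispheres(cfg.region_names)
    for j, name in enumerate(cfg.region_names):
        columns[name] = dbm[:, j]
        meta_rows.append((name, "DBM", hemis[j]))

    for name, m, sd, loading in SBR_PANEL:
        vals = m + loading * severity + sd * rng.standard_normal(n)
        columns[name] = np.clip(vals, 0.05, None)
        meta_rows.append((name, "SBR", "L" if "(L)" in name else "R"))

    panel = list(COVARIATE_PANEL[: cfg.n_clinical_features])
    for k in range(len(COVARIATE_PANEL), cfg.n_clinical_features):
        panel.append((f"Covariate {k + 1:02d}", "clinical", 0.0, 1.0, 0.2))
    for name, modality, m, sd, loading in panel:
        if name == "Sex (male=1)":
            vals = (rng.random(n) < m).astype(float)
        else:
            vals = m + loading * severity + sd * rng.standard_normal(n)
            if name in ("Disease duration (months)", "Hoehn and Yahr"):
                vals = np.clip(vals, 0.0, None)
        columns[name] = vals
        meta_rows.append((name, modality, "none"))

    values = pd.DataFrame(columns, index=ids)
    meta = pd.DataFrame(meta_rows, columns=["name", "modality", "hemisphere"])
    table = CohortTable(values, meta, group)

    # Longitudinal scores: atrophy-weighted signal + optional interaction + noise.
    raw: dict[str, pd.DataFrame] = {}
    cat: dict[str, pd.DataFrame] = {}
    for mod in MODALITIES:
        W = cfg.effect_matrix[mod]
        scores = np.empty((n, len(cfg.years)))
        for t, year in enumerate(cfg.years):
            signal = z @ W[:, t]
            if cfg.interaction and mod in cfg.interaction:
                i, j, w = cfg.interaction[mod]
                signal = signal + w * z[:, i] * z[:, j]
            latent = signal + cfg.score_noise_sd * rng.standard_normal(n)
            if mod == "MoCA":
                center = MOCA_YEAR_CENTER.get(year, 26.9 - 0.3 * (year - 1))
                s = np.clip(np.round(center - MOCA_POINTS_PER_SD * latent), 0, 30)
            else:
                center = UPDRS_YEAR_CENTER.get(year, 31.5 + 0.5 * (year - 1))
                s = np.clip(np.round(center + UPDRS_POINTS_PER_SD * latent), 0, 132)
            scores[:, t] = s
        raw[mod] = pd.DataFrame(scores.astype(int), index=ids, columns=list(cfg.years))
        cat[mod] = label_scores(raw[mod], mod)

    outcomes = OutcomeLabels(raw, cat)
    truth = GroundTruth(pd.Series(severity, index=ids), cfg.effect_matrix, cfg.region_names, tuple(cfg.years))

    if cfg.missing_rate > 0:
        table = inject_missingness(table, cfg.missing_rate, seed=int(rng.integers(2**31 - 1)))
    return table, outcomes, truth


def inject_missingness(table: CohortTable, rate: float, seed: int) -> CohortTable:
    """Set each feature cell missing independently with probability *rate*
    (missing-completely-at-random); metadata and ids are untouched."""
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    out = table.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.values.shape) < rate
    vals = out.values.to_numpy(float)
    vals[mask] = np.nan
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    return out


def write_cohort(directory, table: CohortTable, outcomes: OutcomeLabels, truth: GroundTruth) -> None:
    """Write the cohort as CSV (features, metadata, outcomes) + ground-truth JSON."""
    directory = Path(directory)
    table.to_csv(directory)
    outcomes.to_csv(directory)
    truth.to_json(directory / "ground_truth.json")
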