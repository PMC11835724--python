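"""Feature pipeline: index-window selection, longitudinal summaries,
median imputation with missingness flags, and stratified splitting.

The index date is the metastatic diagnosis (day 0). Baseline values are the
observation closest to the index within the window [-90, +30] days, with ties
broken toward the pre-index observation (pre-treatment information is
preferred). Longitudinal summaries are the percent weight change across the
window (earliest in-window value as baseline), and per-lab minimum, maximum
and ordinary-least-squares slope per day.

The feature-list contract lives here: ``latent_true_risk``, the treatment
indicator and the socio-demographic variables excluded from the prognostic
model (race, ethnicity, insurance) never enter :data:`PROGNOSTIC_FEATURES`,
preventing leakage by construction. Those variables remain in the patient
table for use by the propensity models of the emulation stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import LAB_FEATURES, PatientTable
from .utils import DAYS_PER_MONTH

WINDOW_DAYS = (-90, 30)

ECOG_LEVELS = ["0", "1", "2", "3", "4", "unknown"]

#: numeric columns eligible for prognostic modeling (labs get missing flags)
PROGNOSTIC_NUMERIC = [
    "age",
    "sex_male",
    "creatinine",
    "hemoglobin",
    "total_bilirubin",
    "albumin",
    "weight_pct_change",
    "time_dx_to_met_months",
    "year_of_dx",
    "line_of_therapy",
    "comorbid_chf",
    "comorbid_renal",
    "cns_met",
]
PROGNOSTIC_CATEGORICAL = ["ecog_cat", "histology"]

#: columns that must never reach a model fit
FORBIDDEN_MODEL_COLUMNS = {
    "latent_true_risk",
    "treatment",
    "regimen",
    "first_dose",
    "race",
    "ethnicity",
    "insurance",
    "time",
    "event",
}


class ImputationError(ValueError):
    pass


def select_index_window(
    observations: pd.DataFrame,
    feature: str,
    window: tuple[int, int] = WINDOW_DAYS,
) -> pd.Series:
    """Baseline value per patient: in-window observation closest to day 0.

    Ties in |day| prefer the pre-index observation. Patients with no
    observation inside the window get NaN.
    """
    o = observations.loc[observations["feature"] == feature, ["patient_id", "day", "value"]]
    o = o.loc[(o["day"] >= window[0]) & (o["day"] <= window[1])].copy()
    if o.empty:
        return pd.Series(dtype=float, name=feature)
    # sort key: |day|, then day ascending so the pre-index one wins ties
    o["absday"] = o["day"].abs()
    o = o.sort_values(["patient_id", "absday", "day"], kind="stable")
    best = o.groupby("patient_id", sort=False).first()
    return best["value"].rename(feature)


def _ols_slope(day: np.ndarray, value: np.ndarray) -> float:
    # least-squares slope per day; requires >= 2 points
    if len(day) < 2 or np.ptp(day) == 0:
        return np.nan
    day = day.astype(float)
    return float(np.polyfit(day, value, 1)[0])


def engineer_longitudinal(
    observations: pd.DataFrame, window: tuple[int, int] = WINDOW_DAYS
) -> pd.DataFrame:
    """Derived longitudinal features per patient.

    Returns one row per patient with ``weight_pct_change`` (percent change
    from the earliest to the latest in-window weight) and per-lab ``*_min``,
    ``*_max`` and ``*_slope`` (per day). A single observation yields a missing
    slope, never zero.
    """
    o = observations.loc[
        (observations["day"] >= window[0]) & (observations["day"] <= window[1])
    ]
    out: dict[str, pd.Series] = {}

    w = o.loc[o["feature"] == "weight"].sort_values(["patient_id", "day"], kind="stable")
    if not w.empty:
        g = w.groupby("patient_id", sort=False)["value"]
        first, last = g.first(), g.last()
        counts = g.size()
        pct = ((last - first) / first * 100.0).where(counts >= 2)
        out["weight_pct_change"] = pct

    for lab in LAB_FEATURES:
        lo = o.loc[o["feature"] == lab]
        if lo.empty:
            continue
        g = lo.groupby("patient_id", sort=False)
        out[f"{lab}_min"] = g["value"].min()
        out[f"{lab}_max"] = g["value"].max()
        out[f"{lab}_slope"] = g[["day", "value"]].apply(
            lambda d: _ols_slope(d["day"].to_numpy(), d["value"].to_numpy())
        )
    return pd.DataFrame(out)


def build_feature_matrix(table: PatientTable) -> pd.DataFrame:
    """Model-ready wide matrix: baseline window values + engineered features.

    Lab baselines are re-derived from the observation table through the index
    window (so injected missingness propagates); ECOG becomes an explicit
    categorical with an ``unknown`` level. Outcome columns (time, event) ride
    along; forbidden columns are excluded by the feature-list contract.
    """
    df = table.patients.set_index("patient_id")
    m = pd.DataFrame(index=df.index)
    for col in ["age", "sex_male", "time_dx_to_met_months", "year_of_dx",
                "line_of_therapy", "comorbid_chf", "comorbid_renal", "cns_met",
                "histology"]:
        m[col] = df[col]
    for lab in LAB_FEATURES:
        m[lab] = select_index_window(table.observations, lab).reindex(df.index)
    eng = engineer_longitudinal(table.observations).reindex(df.index)
    m["weight_pct_change"] = eng.get("weight_pct_change")
    for lab in LAB_FEATURES:
        col = f"{lab}_slope"
        if col in eng:
            m[col] = eng[col]
    ecog = select_index_window(table.observations, "ecog").reindex(df.index)
    m["ecog_cat"] = pd.Categorical(
        np.where(ecog.isna(), "unknown", ecog.fillna(-1).astype(int).astype(str)),
        categories=ECOG_LEVELS,
    )
    # biomarker column (preset-dependent) is prognostic if present
    for bm in ("pdl1_positive", "hr_positive", "kras_wild"):
        if bm in df.columns:
            m[bm] = df[bm]
    m["time"] = df["time"]
    m["event"] = df["event"]
    assert not (set(m.columns) - {"time", "event"}) & FORBIDDEN_MODEL_COLUMNS
    return m.reset_index()


def model_feature_columns(matrix: pd.DataFrame) -> tuple[list[str], list[str]]:
    """(numeric, categorical) model columns present in the matrix."""
    numeric = [c for c in matrix.columns
               if c not in ("patient_id", "time", "event")
               and c not in PROGNOSTIC_CATEGORICAL
               and not str(matrix[c].dtype) in ("object", "category")]
    categorical = [c for c in PROGNOSTIC_CATEGORICAL if c in matrix.columns]
    return numeric, categorical


# ---------------------------------------------------------------------------
# imputation


def compute_medians(matrix: pd.DataFrame, columns: list[str]) -> dict[str, float]:
    """Per-column medians on (training) rows; all-missing columns are an error."""
    medians = {}
    for c in columns:
        med = matrix[c].median()
        if pd.isna(med):
            raise ImputationError(f"cannot compute training median: column {c!r} is all-missing")
        medians[c] = float(med)
    return medians


def impute_default(
    matrix: pd.DataFrame,
    medians: dict[str, float],
    flag_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Median imputation with paired binary missingness flags.

    ``medians`` must come from training rows only (leakage-free contract is
    the caller's responsibility and is property-tested). Every imputed column
    named in ``flag_columns`` (default: all imputed columns) gains a
    ``*_missing`` indicator equal to 1 exactly where a value was filled in.
    Categorical ECOG is left untouched: its missingness is the explicit
    ``unknown`` level.
    """
    out = matrix.copy()
    flag_columns = list(medians) if flag_columns is None else flag_columns
    for c, med in medians.items():
        missing = out[c].isna()
        if c in flag_columns:
            out[f"{c}_missing"] = missing.astype(int)
        out[c] = out[c].fillna(med)
    return out


def save_imputation_params(medians: dict[str, float], path: str | Path) -> None:
    Path(path).write_text(json.dumps(medians, indent=2))


def load_imputation_params(path: str | Path) -> dict[str, float]:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitAssignment:
    assignment: pd.Series  # patient_id -> {"train", "test"}
    stratify_by: str
    fraction: float
    seed: int

    @property
    def train_ids(self) -> pd.Index:
        return self.assignment.index[self.assignment == "train"]

    @property
    def test_ids(self) -> pd.Index:
        return self.assignment.index[self.assignment == "test"]


def split_train_test(
    table: pd.DataFrame,
    fraction: float = 0.8,
    stratify_by: str = "year_of_dx",
    seed: int = 0,
) -> SplitAssignment:
    """Seeded stratified split; per-stratum train fraction within 1 patient.

    Strata with fewer than 2 patients go entirely to training with a warning.
    ``stratify_by`` may be a single column name or a list of columns.
    """
    cols = [stratify_by] if isinstance(stratify_by, str) else list(stratify_by)
    for c in cols:
        if c not in table.columns:
            raise KeyError(f"stratification column {c!r} not in table")
    rng = np.random.default_rng(seed)
    assign = pd.Series("train", index=pd.Index(table["patient_id"], name="patient_id"))
    for _, grp in table.groupby(cols, sort=True, dropna=False):
        ids = grp["patient_id"].to_numpy()
        if len(ids) < 2:
            warnings.warn(
                f"stratum of size {len(ids)} assigned entirely to training", stacklevel=2
            )
            continue
        n_train = int(round(fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1) if fraction < 1 else len(ids)
        perm = rng.permutation(len(ids))
        assign.loc[ids[perm[n_train:]]] = "test"
    name = stratify_by if isinstance(stratify_by, str) else "+".join(cols)
    return SplitAssignment(assign, name, fraction, seed)
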