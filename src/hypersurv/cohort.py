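"""Cohort I/O: load, validate, align and encode patient tables.

A cohort couples three tables keyed by ``patient_id``: baseline clinical
variables (nine routinely collected characteristics), censored survival
endpoints (progression-free and overall survival), and an optional radiomics
feature matrix.  The stored patient order is the input order of the clinical
table and every derived matrix inherits it.

The clinical encoder one-hot encodes categoricals (with a dedicated
``missing`` level), z-scores continuous variables with training statistics,
and rescales every row to unit Euclidean norm — the representation the
pairwise association encoder consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .radiomics import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CLINICAL_VARIABLES",
    "CATEGORY_LEVELS",
    "CONTINUOUS_VARIABLES",
    "Cohort",
    "ClinicalScaler",
    "EncodedClinicalMatrix",
    "RiskScores",
    "load_cohort",
    "encode_clinical",
    "save_scores",
    "load_scores",
    "save_graph",
    "load_graph",
]

MISSING = "missing"

#: canonical order of the nine baseline clinical variables
CLINICAL_VARIABLES: tuple[str, ...] = (
    "sex",
    "age",
    "smoking",
    "histology",
    "morphology",
    "longest_diameter",
    "treatment_line",
    "therapy_regimen",
    "dnlr",
)

CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "smoking": ("yes", "no"),
    "histology": ("adenocarcinoma", "squamous", "other"),
    "morphology": ("solid", "ggn", "mixed"),
    "therapy_regimen": ("monotherapy", "combination"),
}

#: age/diameter/dNLR are continuous; treatment line is ordinal {1,2,3+} and is
#: encoded on its numeric rank (lines >= 3 are bucketed as "3+").
CONTINUOUS_VARIABLES: tuple[str, ...] = ("age", "longest_diameter", "dnlr", "treatment_line")

_POSITIVE = ("age", "longest_diameter", "dnlr")


@dataclass
class Cohort:
    """Aligned clinical + survival (+ radiomics) tables in one patient order."""

    clinical: pd.DataFrame
    survival: pd.DataFrame
    radiomics: FeatureMatrix | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        ids = list(self.clinical["patient_id"])
        if len(set(ids)) != len(ids):
            dup = sorted(pd.Index(ids)[pd.Index(ids).duplicated()].unique())
            raise ValueError(f"duplicate patient id(s): {dup}")
        if list(self.survival["patient_id"]) != ids:
            raise ValueError("survival rows not aligned with clinical patient order")
        if self.radiomics is not None and self.radiomics.patient_ids != [str(i) for i in ids]:
            raise ValueError("radiomics rows not aligned with clinical patient order")

    @property
    def patient_ids(self) -> list[str]:
        return [str(i) for i in self.clinical["patient_id"]]

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    def pfs(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.survival["pfs_time"].to_numpy(dtype=float),
            self.survival["pfs_event"].to_numpy(dtype=bool),
        )

    def os(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.survival["os_time"].to_numpy(dtype=float),
            self.survival["os_event"].to_numpy(dtype=bool),
        )

    def subset(self, index: np.ndarray) -> "Cohort":
        index = np.asarray(index)
        clin = self.clinical.iloc[index].reset_index(drop=True)
        surv = self.survival.iloc[index].reset_index(drop=True)
        rad = None
        if self.radiomics is not None:
            rad = FeatureMatrix(
                self.radiomics.values[index],
                self.radiomics.feature_names,
                [self.radiomics.patient_ids[i] for i in index],
            )
        return Cohort(clin, surv, rad)


@dataclass
class ClinicalScaler:
    """Training-cohort statistics reused to encode test cohorts identically."""

    variables: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    medians: dict[str, float]


@dataclass
class EncodedClinicalMatrix:
    matrix: np.ndarray
    column_names: list[str]
    scaler: ClinicalScaler

    @property
    def n_patients(self) -> int:
        return self.matrix.shape[0]


@dataclass
class RiskScores:
    """Per-patient scalar risk score; higher means better predicted survival."""

    patient_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids),):
            raise ValueError("one score per patient required")
        if len(self.values) and not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: no 'patient_id' column")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def _validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [v for v in CLINICAL_VARIABLES if v not in df.columns]
    if missing_cols:
        raise ValueError(f"clinical table missing columns: {missing_cols}")
    df = df.copy()
    # bucket treatment lines >= 3 as "3+" and keep a numeric rank
    tl = df["treatment_line"].astype(str).str.strip()
    tl_num = pd.to_numeric(tl.str.replace("+", "", regex=False), errors="coerce")
    bad = tl[~tl.isin(["1", "2", "3", "3+", MISSING]) & tl_num.isna() & (tl != "nan")]
    if len(bad):
        row = bad.index[0]
        raise ValueError(
            f"unparseable treatment_line {bad.iloc[0]!r} at row {row} (patient "
            f"{df.loc[row, 'patient_id']})"
        )
    df["treatment_line"] = np.where(tl_num >= 3, 3.0, tl_num)
    for var, levels in CATEGORY_LEVELS.items():
        col = df[var].astype(str).str.strip().str.lower()
        col = col.where(~df[var].isna(), MISSING).replace("nan", MISSING)
        bad = col[~col.isin(levels + (MISSING,))]
        if len(bad):
            row = bad.index[0]
            raise ValueError(
                f"unknown level {bad.iloc[0]!r} for column {var!r} at row {row} "
                f"(patient {df.loc[row, 'patient_id']})"
            )
        df[var] = col
    for var in _POSITIVE:
        vals = pd.to_numeric(df[var], errors="coerce")
        neg = vals[vals <= 0]
        if len(neg):
            row = neg.index[0]
            raise ValueError(
                f"non-positive {var} ({neg.iloc[0]}) for patient {df.loc[row, 'patient_id']}"
            )
        df[var] = vals
    return df


def _validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("pfs_time", "pfs_event", "os_time", "os_event"):
        if col not in df.columns:
            raise ValueError(f"survival table missing column {col!r}")
    df = df.copy()
    for col in ("pfs_time", "os_time"):
        df[col] = pd.to_numeric(df[col])
        if (df[col] < 0).any():
            raise ValueError(f"negative {col}")
    for col in ("pfs_event", "os_event"):
        df[col] = df[col].astype(int).astype(bool)
    return df


def load_cohort(clinical_path, survival_path, radiomics_path=None) -> Cohort:
    """Load and align the cohort tables; report and drop unmatched patients.

    Patients must appear in every required table; those missing from any are
    dropped with a logged count.  Duplicate ids are a hard error.
    """
    clin = _validate_clinical(_read_table(clinical_path))
    surv = _validate_survival(_read_table(survival_path))
    for name, df in (("clinical", clin), ("survival", surv)):
        ids = df["patient_id"]
        if ids.duplicated().any():
            dup = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate patient id(s) in {name} table: {dup}")
    rad = None
    tables = [set(clin["patient_id"]), set(surv["patient_id"])]
    if radiomics_path is not None:
        rad_df = _read_table(radiomics_path)
        if rad_df["patient_id"].duplicated().any():
            dup = sorted(rad_df["patient_id"][rad_df["patient_id"].duplicated()].unique())
            raise ValueError(f"duplicate patient id(s) in radiomics table: {dup}")
        rad_df = rad_df.set_index("patient_id")
        tables.append(set(rad_df.index))
    common = set.intersection(*tables)
    keep = clin["patient_id"].isin(common)
    n_dropped = int((~keep).sum()) + sum(len(t - common) for t in tables[1:])
    if n_dropped:
        logger.warning("dropped %d patient row(s) missing from some table", n_dropped)
    clin = clin[keep].reset_index(drop=True)
    order = clin["patient_id"]
    surv = surv.set_index("patient_id").loc[order].reset_index()
    if radiomics_path is not None:
        rad_df = rad_df.loc[order]
        rad = FeatureMatrix.from_frame(rad_df)
    cohort = Cohort(clin, surv, rad)
    cohort.n_dropped = n_dropped
    return cohort


def encode_clinical(
    cohort: Cohort,
    variable_subset: list[str] | None = None,
    scaler: ClinicalScaler | None = None,
) -> EncodedClinicalMatrix:
    """One-hot + z-score encode the clinical table, unit-norm per row.

    Categorical variables become one-hot blocks (plus a ``missing`` level);
    continuous/ordinal variables are median-imputed and z-scored using the
    scaler statistics (fit on this cohort when ``scaler`` is None).  Each row
    is finally rescaled to unit Euclidean norm.
    """
    variables = list(variable_subset) if variable_subset is not None else list(CLINICAL_VARIABLES)
    if not variables:
        raise ValueError("variable_subset must be nonempty")
    unknown = [v for v in variables if v not in CLINICAL_VARIABLES]
    if unknown:
        raise ValueError(f"unknown clinical variable(s): {unknown}")
    fit = scaler is None
    if not fit and scaler.variables != variables:
        raise ValueError("scaler was fit on a different variable subset")
    means: dict[str, float] = {} if fit else scaler.means
    sds: dict[str, float] = {} if fit else scaler.sds
    medians: dict[str, float] = {} if fit else scaler.medians

    cols: list[np.ndarray] = []
    names: list[str] = []
    df = cohort.clinical
    for var in CLINICAL_VARIABLES:  # canonical order, filtered to the subset
        if var not in variables:
            continue
        if var in CONTINUOUS_VARIABLES:
            vals = pd.to_numeric(df[var], errors="coerce").to_numpy(dtype=float)
            if fit:
                finite = vals[np.isfinite(vals)]
                if finite.size == 0:
                    raise ValueError(f"variable {var!r} entirely missing; cannot fit scaler")
                medians[var] = float(np.median(finite))
            vals = np.where(np.isfinite(vals), vals, medians[var])
            if fit:
                means[var] = float(vals.mean())
                sd = float(vals.std(ddof=0))
                sds[var] = sd if sd > 0 else 1.0
            cols.append((vals - means[var]) / sds[var])
            names.append(var)
        else:
            levels = CATEGORY_LEVELS[var] + (MISSING,)
            observed = df[var].astype(str).to_numpy()
            if not fit:
                bad = set(observed) - set(levels)
                if bad:
                    raise ValueError(f"unseen category level(s) {sorted(bad)} for {var!r}")
            for lev in levels:
                cols.append((observed == lev).astype(float))
                names.append(f"{var}={lev}")
    matrix = np.column_stack(cols)
    norms = np.linalg.norm(matrix, axis=1)
    zero = np.where(norms == 0)[0]
    if len(zero):
        raise ValueError(f"zero-norm encoded row for patient {cohort.patient_ids[zero[0]]}")
    matrix = matrix / norms[:, None]
    out_scaler = scaler if scaler is not None else ClinicalScaler(variables, means, sds, medians)
    return EncodedClinicalMatrix(matrix, names, out_scaler)


def save_scores(scores: RiskScores, path) -> None:
    pd.DataFrame({"patient_id": scores.patient_ids, "score": scores.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


def load_scores(path) -> RiskScores:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return RiskScores(list(df["patient_id"]), df["score"].to_numpy(dtype=float))


def save_graph(hypergraph, path_triplets, path_weights) -> None:
    """Persist a hypergraph as sparse triplet text plus a weight file."""
    coo = hypergraph.H.tocoo()
    pd.DataFrame(
        {"node_index": coo.row, "edge_index": coo.col, "value": coo.data}
    ).sort_values(["edge_index", "node_index"]).to_csv(path_triplets, index=False)
    pd.DataFrame({"edge_index": np.arange(len(hypergraph.W)), "weight": hypergraph.W}).to_csv(
        path_weights, index=False, float_format="%.17g"
    )


def load_graph(path_triplets, path_weights, n_nodes: int):
    from scipy import sparse

    from .graphs import Hypergraph

    trip = pd.read_csv(path_triplets)
    w = pd.read_csv(path_weights).sort_values("edge_index")["weight"].to_numpy(dtype=float)
    H = sparse.coo_matrix(
        (trip["value"], (trip["node_index"], trip["edge_index"])),
        shape=(n_nodes, len(w)),
    ).tocsr()
    return Hypergraph(H, w)
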