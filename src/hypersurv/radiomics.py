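"""Radiomics feature handling: reproducibility filtering and standardization.

Radiomics pipelines extract on the order of a thousand texture/shape/intensity
features per tumour segmentation.  Only features that survive repeated
segmentation by independent readers are trustworthy as node attributes, so the
entry point here is an intraclass-correlation filter over replicate feature
tables, followed by per-feature z-scoring with reusable training statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "FeatureScaler",
    "ReproducibilityReport",
    "icc_2_1",
    "icc_filter",
    "standardize_features",
]


@dataclass
class FeatureMatrix:
    """A patients x features numeric table with aligned identifiers."""

    values: np.ndarray
    feature_names: list[str]
    patient_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_names = list(self.feature_names)
        self.patient_ids = list(self.patient_ids)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (patients x features)")
        if self.values.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.patient_ids)} patients / {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            dup = pd.Index(self.feature_names)
            dup = sorted(dup[dup.duplicated()].unique())
            raise ValueError(f"duplicate feature names: {dup}")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.values[:, idx], list(names), self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.feature_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(df.to_numpy(dtype=float), list(map(str, df.columns)), list(map(str, df.index)))


@dataclass
class FeatureScaler:
    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray


@dataclass
class ReproducibilityReport:
    """Per-feature ICC estimates and the resulting selection mask."""

    feature_names: list[str]
    icc: np.ndarray  # NaN where undefined (degenerate variance)
    selected: np.ndarray  # boolean; selected iff ICC defined and >= threshold
    threshold: float
    dropped_constant: list[str] = field(default_factory=list)

    def selected_names(self) -> list[str]:
        return [n for n, s in zip(self.feature_names, self.selected) if s]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_names, "icc": self.icc, "selected": self.selected}
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is subjects x raters.  Computed from the classical two-way
    ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Returns NaN when the design is degenerate (any rater constant across
    subjects, or a non-positive denominator).
    """
    ratings = np.asarray(ratings, dtype=float)
    n, k = ratings.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 subjects and 2 raters")
    if np.any(np.ptp(ratings, axis=0) == 0):
        return float("nan")
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_total = ((ratings - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_filter(
    primary: FeatureMatrix,
    replicates: list[FeatureMatrix],
    threshold: float = 0.75,
) -> ReproducibilityReport:
    """Select features reproducible across replicate readings.

    Each replicate is a re-reading of the same patients/features (e.g. repeat
    segmentation by an independent reader).  A feature is kept iff its
    ICC(2,1) across readers is defined and >= ``threshold``.  Features that
    are constant across patients in any reader have no defined between-subject
    variance and are dropped with a flag.
    """
    if len(replicates) == 0:
        raise ValueError("icc_filter requires at least one replicate table")
    for r, rep in enumerate(replicates):
        if rep.values.shape != primary.values.shape:
            raise ValueError(
                f"replicate {r} shape {rep.values.shape} != primary {primary.values.shape}"
            )
        if rep.feature_names != primary.feature_names:
            raise ValueError(f"replicate {r} feature names differ from primary")
        if rep.patient_ids != primary.patient_ids:
            raise ValueError(f"replicate {r} patient ids differ from primary")
    stack = np.stack([primary.values] + [r.values for r in replicates], axis=2)
    p = primary.n_features
    icc = np.full(p, np.nan)
    for j in range(p):
        icc[j] = icc_2_1(stack[:, j, :])
    defined = np.isfinite(icc)
    selected = defined & (icc >= threshold)
    constant = [
        primary.feature_names[j]
        for j in range(p)
        if not defined[j] and np.any(np.ptp(stack[:, j, :], axis=0) == 0)
    ]
    return ReproducibilityReport(
        feature_names=list(primary.feature_names),
        icc=icc,
        selected=selected,
        threshold=float(threshold),
        dropped_constant=constant,
    )


def standardize_features(
    matrix: FeatureMatrix, scaler: FeatureScaler | None = None
) -> tuple[FeatureMatrix, FeatureScaler]:
    """Per-feature z-scoring with reusable (training) statistics.

    In fit mode (``scaler=None``) zero-variance features are dropped with a
    warning; in transform mode the scaler's feature set is enforced.
    """
    if scaler is None:
        sds = matrix.values.std(axis=0, ddof=0)
        keep = sds > 0
        if not np.all(keep):
            dropped = [n for n, k in zip(matrix.feature_names, keep) if not k]
            warnings.warn(f"dropping {len(dropped)} zero-variance features: {dropped[:5]}...")
        names = [n for n, k in zip(matrix.feature_names, keep) if k]
        vals = matrix.values[:, keep]
        scaler = FeatureScaler(names, vals.mean(axis=0), vals.std(axis=0, ddof=0))
        out = (vals - scaler.means) / scaler.sds
        return FeatureMatrix(out, names, matrix.patient_ids), scaler
    sub = matrix.subset(scaler.feature_names)
    out = (sub.values - scaler.means) / scaler.sds
    return FeatureMatrix(out, list(scaler.feature_names), matrix.patient_ids), scaler
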