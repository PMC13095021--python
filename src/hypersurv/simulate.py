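"""Synthetic cohort generation.

The generator emulates the statistical structure the pipeline assumes: two
latent prognosis classes expressed in the baseline clinical variables,
block-correlated radiomics with a sparse informative signal loaded on the
true risk, exponential proportional-hazards progression-free survival
calibrated to a target median, independent censoring to a target fraction,
and overall survival as progression-free survival plus a positive
class-dependent increment.  Clinical marginals default to a large NSCLC
immunotherapy training cohort (80% male, 64% smokers, median age 63, median
longest diameter 42 mm, median dNLR 2.7, median PFS 9.1 months, 8.5%
censoring).

Class-dependent shifts are symmetric (classes are equiprobable, class 0
shifted one way, class 1 the other), so configured marginals are preserved.

A second generator, :func:`generate_two_class_cohort`, produces an idealized
two-cluster cohort whose PFS classes are (near-)deterministically separated
by the 9-month cutoff; it exists to validate the pairwise encoder, whose
pair labels would otherwise be irreducibly noisy relative to the latent
class under exponential survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .radiomics import FeatureMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_two_class_cohort",
    "generate_replicates",
    "write_cohort",
]


@dataclass
class SyntheticConfig:
    n: int = 300
    seed: int = 0
    # clinical marginals
    p_male: float = 0.80
    p_smoking: float = 0.64
    p_histology: tuple[float, float, float] = (0.51, 0.34, 0.15)
    p_morphology: tuple[float, float, float] = (0.84, 0.01, 0.15)
    p_combination: float = 0.92
    p_line: tuple[float, float, float] = (0.63, 0.26, 0.11)
    age_median: float = 63.0
    age_sd: float = 9.4
    diameter_median: float = 42.0
    diameter_log_sd: float = 0.58
    dnlr_median: float = 2.7
    dnlr_log_sd: float = 0.62
    # latent structure
    n_classes: int = 2
    clinical_shift: float = 2.0  # class shift on continuous vars, in sd / log-sd units
    category_shift: float = 0.25  # symmetric probability shift on binary/first levels
    # which baseline variables express the prognosis class; the rest are
    # class-neutral (not every routinely collected variable is prognostic)
    informative_clinical: tuple[str, ...] = ("age", "smoking", "longest_diameter", "dnlr")
    class_risk: float = 1.0  # log-hazard half-distance between classes
    radiomics_risk: float = 0.8  # log-hazard weight of the idiosyncratic factor
    # radiomics
    n_features: int = 120
    n_informative: int = 5
    informative_loading: float = 0.5
    n_blocks: int = 6
    block_rho: float = 0.3
    # survival
    median_pfs: float = 9.1
    censor_frac: float = 0.085
    os_increment_median: tuple[float, float] = (8.0, 16.0)  # poor class, good class
    os_increment_log_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        for p in (self.p_male, self.p_smoking, self.p_combination, self.censor_frac):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for simplex in (self.p_histology, self.p_morphology, self.p_line):
            if abs(sum(simplex) - 1.0) > 1e-9 or min(simplex) < 0:
                raise ValueError(f"probabilities {simplex} must form a simplex")
        if self.n_classes != 2:
            raise ValueError("only two latent classes are supported")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")


@dataclass
class SyntheticTruth:
    latent_class: np.ndarray  # 1 = good prognosis
    risk: np.ndarray  # true log-hazard (higher = shorter survival)
    event_time: np.ndarray  # PFS time before censoring


def _shifted_p(p: float, delta: float, good: np.ndarray, sign: float = 1.0) -> np.ndarray:
    """Per-patient Bernoulli probability with a marginal-preserving class shift."""
    d = min(delta, p, 1.0 - p)
    return np.where(good, p - sign * d, p + sign * d)


def _categorical(rng, probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw from per-patient probability rows."""
    u = rng.random(probs.shape[0])
    return (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)


def generate_cohort(config: SyntheticConfig | None = None) -> tuple[Cohort, SyntheticTruth]:
    """Draw a full synthetic cohort plus its generating truth.

    Deterministic given ``config.seed``.  Progression-free survival is
    exponential with hazard proportional to exp(risk), rescaled so the
    realized median matches ``config.median_pfs``; censoring is independent
    (per-patient Bernoulli at the target fraction, censoring time uniform on
    the event time).
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    good = rng.random(n) < 0.5  # latent class: True = good prognosis

    # --- clinical variables, marginals preserved under symmetric class shifts;
    # shifts apply only to the configured informative variables
    info = set(cfg.informative_clinical)

    def _s(var: str) -> float:
        return cfg.clinical_shift if var in info else 0.0

    def _d(var: str) -> float:
        return cfg.category_shift if var in info else 0.0

    cls = np.where(good, -1.0, 1.0)
    age = cfg.age_median + cfg.age_sd * (rng.standard_normal(n) + cls * _s("age") / 2)
    age = np.clip(age, 18.0, None)
    diam = np.exp(
        np.log(cfg.diameter_median)
        + cfg.diameter_log_sd * (rng.standard_normal(n) + cls * _s("longest_diameter") / 2)
    )
    dnlr = np.exp(
        np.log(cfg.dnlr_median)
        + cfg.dnlr_log_sd * (rng.standard_normal(n) + cls * _s("dnlr") / 2)
    )
    sex = np.where(rng.random(n) < _shifted_p(cfg.p_male, _d("sex"), good), "male", "female")
    smoking = np.where(
        rng.random(n) < _shifted_p(cfg.p_smoking, _d("smoking"), good), "yes", "no"
    )
    combo = np.where(
        rng.random(n) < _shifted_p(cfg.p_combination, _d("therapy_regimen"), good, sign=-1.0),
        "combination",
        "monotherapy",
    )

    def _simplex_shift(probs: tuple[float, ...], d: float) -> np.ndarray:
        p = np.asarray(probs, dtype=float)
        dd = min(d, p[0], 1.0 - p[0]) if len(p) > 1 else 0.0
        out = np.tile(p, (n, 1))
        # move mass between the first level and the remaining ones, per class
        sign = np.where(good, -1.0, 1.0)
        out[:, 0] = p[0] + sign * dd
        rest = p[1:] / p[1:].sum() if p[1:].sum() > 0 else p[1:]
        out[:, 1:] = (1.0 - out[:, 0])[:, None] * rest[None, :]
        return out

    hist_levels = np.array(["adenocarcinoma", "squamous", "other"])
    morph_levels = np.array(["solid", "ggn", "mixed"])
    line_levels = np.array(["1", "2", "3+"])
    histology = hist_levels[_categorical(rng, _simplex_shift(cfg.p_histology, _d("histology")))]
    morphology = morph_levels[
        _categorical(rng, _simplex_shift(cfg.p_morphology, _d("morphology")))
    ]
    tline = line_levels[_categorical(rng, _simplex_shift(cfg.p_line, _d("treatment_line")))]

    # --- radiomics: block-correlated Gaussian; the sparse informative subset
    # loads on the true risk (tumour phenotype reflects overall aggressiveness,
    # so image features correlate with the clinical class as well)
    u = rng.standard_normal(n)  # idiosyncratic radiomics risk factor
    risk = cfg.class_risk * np.where(good, -1.0, 1.0) + cfg.radiomics_risk * u
    z_risk = risk / np.sqrt(cfg.class_risk**2 + cfg.radiomics_risk**2)
    block = np.repeat(np.arange(cfg.n_blocks), int(np.ceil(cfg.n_features / cfg.n_blocks)))[
        : cfg.n_features
    ]
    shared = rng.standard_normal((n, cfg.n_blocks))
    noise = rng.standard_normal((n, cfg.n_features))
    rho = cfg.block_rho
    rad = np.sqrt(rho) * shared[:, block] + np.sqrt(1 - rho) * noise
    lam = cfg.informative_loading
    for j in range(cfg.n_informative):
        rad[:, j] = lam * z_risk + np.sqrt(1 - lam**2) * rad[:, j]
    feature_names = [f"feat_{j:04d}" for j in range(cfg.n_features)]

    # --- survival: exponential proportional hazards, median-calibrated
    raw = rng.exponential(1.0, size=n) * np.exp(-risk)
    event_time = raw * (cfg.median_pfs / np.median(raw))
    censored = rng.random(n) < cfg.censor_frac
    pfs_time = np.where(censored, rng.random(n) * event_time, event_time)
    pfs_event = ~censored
    achieved = censored.mean()
    if abs(achieved - cfg.censor_frac) > max(0.05, 3 * np.sqrt(cfg.censor_frac / n)):
        warnings.warn(f"achieved censoring fraction {achieved:.3f} vs target {cfg.censor_frac}")
    inc_med = np.where(good, cfg.os_increment_median[1], cfg.os_increment_median[0])
    os_inc = np.exp(np.log(inc_med) + cfg.os_increment_log_sd * rng.standard_normal(n))
    os_time = pfs_time + os_inc
    os_event = pfs_event.copy()
    responder = rng.random(n) < 1.0 / (1.0 + np.exp(risk))

    ids = [f"SP{i:05d}" for i in range(n)]
    clinical = pd.DataFrame(
        {
            "patient_id": ids,
            "sex": sex,
            "age": np.round(age, 1),
            "smoking": smoking,
            "histology": histology,
            "morphology": morphology,
            "longest_diameter": np.round(diam, 1),
            "treatment_line": tline,
            "therapy_regimen": combo,
            "dnlr": np.round(dnlr, 2),
        }
    )
    survival = pd.DataFrame(
        {
            "patient_id": ids,
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
            "os_time": os_time,
            "os_event": os_event,
            "response": np.where(responder, "responder", "nonresponder"),
        }
    )
    from .cohort import _validate_clinical, _validate_survival  # normalize dtypes

    cohort = Cohort(
        _validate_clinical(clinical),
        _validate_survival(survival),
        FeatureMatrix(rad, feature_names, ids),
    )
    truth = SyntheticTruth(good.astype(int), risk, event_time)
    return cohort, truth


def generate_two_class_cohort(
    n: int = 200,
    seed: int = 0,
    cutoff: float = 9.0,
    clinical_shift: float = 2.5,
    category_shift: float = 0.30,
    censor_frac_above: float = 0.2,
) -> tuple[Cohort, SyntheticTruth]:
    """Idealized two-cluster cohort for encoder validation.

    The latent class determines both a wide clinical separation and the side
    of the PFS cutoff: the poor class progresses uniformly before the cutoff
    (all events), the good class survives past it (events or late censoring,
    both unambiguously *above*).  Pair labels derived from the cutoff rule
    therefore coincide with the latent classes.
    """
    from .cohort import CLINICAL_VARIABLES

    cfg = SyntheticConfig(
        n=n,
        seed=seed,
        clinical_shift=clinical_shift,
        category_shift=category_shift,
        censor_frac=0.0,
        informative_clinical=tuple(CLINICAL_VARIABLES),
    )
    cohort, truth = generate_cohort(cfg)
    rng = np.random.default_rng(seed + 1_000_003)
    good = truth.latent_class.astype(bool)
    n_good = int(good.sum())
    n_poor = n - n_good
    pfs = np.empty(n)
    pfs[good] = cutoff + 0.5 + rng.exponential(8.0, size=n_good)
    pfs[~good] = rng.uniform(0.5, cutoff - 0.5, size=n_poor)
    event = np.ones(n, dtype=bool)
    # late censoring above the cutoff keeps the class unambiguous
    cens = good & (rng.random(n) < censor_frac_above)
    event[cens] = False
    surv = cohort.survival.copy()
    surv["pfs_time"] = pfs
    surv["pfs_event"] = event
    surv["os_time"] = pfs + np.where(good, 16.0, 8.0)
    surv["os_event"] = event
    cohort = Cohort(cohort.clinical, surv, cohort.radiomics)
    truth = SyntheticTruth(truth.latent_class, np.where(good, -1.0, 1.0), pfs)
    return cohort, truth


def generate_replicates(
    cohort: Cohort, noise_sd: float, n_replicates: int, seed: int = 0
) -> list[FeatureMatrix]:
    """Replicate radiomics tables: primary + iid Gaussian reader noise.

    With feature variance tau^2 the expected agreement of a replicate with
    the primary reading is ICC = tau^2 / (tau^2 + noise_sd^2).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if cohort.radiomics is None:
        raise ValueError("cohort has no radiomics table")
    rng = np.random.default_rng(seed)
    base = cohort.radiomics
    return [
        FeatureMatrix(
            base.values + noise_sd * rng.standard_normal(base.values.shape),
            base.feature_names,
            base.patient_ids,
        )
        for _ in range(n_replicates)
    ]


def write_cohort(cohort: Cohort, truth: SyntheticTruth | None, out_dir) -> dict[str, Path]:
    """Write the standard CSV tables (clinical, survival, radiomics, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": out / "clinical.csv",
        "survival": out / "survival.csv",
    }
    clin = cohort.clinical.copy()
    # round-trippable treatment line labels
    clin["treatment_line"] = clin["treatment_line"].map(
        lambda x: "3+" if x >= 3 else str(int(x)) if np.isfinite(x) else ""
    )
    clin.to_csv(paths["clinical"], index=False)
    cohort.survival.to_csv(paths["survival"], index=False)
    if cohort.radiomics is not None:
        paths["radiomics"] = out / "radiomics.csv"
        df = cohort.radiomics.to_frame()
        df.insert(0, "patient_id", cohort.radiomics.patient_ids)
        df.to_csv(paths["radiomics"], index=False)
    if truth is not None:
        paths["truth"] = out / "truth.csv"
        pd.DataFrame(
            {
                "patient_id": cohort.patient_ids,
                "latent_class": truth.latent_class,
                "risk": truth.risk,
                "event_time": truth.event_time,
            }
        ).to_csv(paths["truth"], index=False)
    return paths
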