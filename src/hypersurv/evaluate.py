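"""Survival evaluation and comparator models.

Conventions used throughout the package:

* Scores are oriented so that a *higher* score predicts *longer* survival.
* Harrell's C counts comparable pairs under right censoring (the pair is
  comparable when the shorter observed time carries an event); score ties get
  0.5 credit.  Confidence intervals are percentile bootstrap over patients.
* Cox fits maximize the Breslow partial likelihood (lifelines); univariate
  screening retains covariates at Wald P < 0.05.
* Cutpoint optimization emulates the X-tile approach: exhaustive search over
  ordered candidate-cutpoint pairs maximizing the three-group log-rank
  chi-square under a minimum-group-fraction constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import roc_auc_score
from sksurv.metrics import concordance_index_censored

from .cohort import CATEGORY_LEVELS, CLINICAL_VARIABLES, CONTINUOUS_VARIABLES, Cohort, MISSING
from .radiomics import FeatureMatrix

__all__ = [
    "SurvivalCurve",
    "CutpointResult",
    "CoxFit",
    "harrell_c",
    "km_estimate",
    "median_survival",
    "logrank",
    "logrank_chi2",
    "cox_fit",
    "univariate_screen",
    "clinical_design",
    "build_control_models",
    "xtile_cutpoints",
    "quantile_stratify",
    "response_auc",
]


def harrell_c(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float] | None]:
    """Harrell's C-index of higher-score-means-longer-survival, with a
    percentile bootstrap 95% CI over patients (``n_boot=0`` skips the CI)."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)

    def _c(s, t, e):
        c, concordant, discordant, *_ = concordance_index_censored(e, t, -s)
        return float(c)

    try:
        c = _c(scores, times, events)
    except Exception as exc:  # sksurv raises NoComparablePairException
        raise ValueError(f"no comparable pairs for C-index: {exc}") from exc
    if n_boot <= 0:
        return c, None
    rng = np.random.default_rng(seed)
    n = len(scores)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            reps.append(_c(scores[idx], times[idx], events[idx]))
        except Exception:
            continue  # resample without comparable pairs contributes nothing
    if not reps:
        return c, None
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return c, (float(lo), float(hi))


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate, defined at observed event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


def km_estimate(times: np.ndarray, events: np.ndarray) -> SurvivalCurve:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("empty sample")
    if np.any(times < 0):
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    ev_rows = table[table["observed"] > 0]
    ev_times = ev_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(ev_times).to_numpy(dtype=float)
    return SurvivalCurve(
        times=ev_times,
        survival=surv,
        at_risk=ev_rows["at_risk"].to_numpy(dtype=int),
        n_events=ev_rows["observed"].to_numpy(dtype=int),
    )


def median_survival(curve: SurvivalCurve) -> float | None:
    """Earliest time with S(t) <= 0.5; None when the curve never reaches it."""
    below = np.where(curve.survival <= 0.5)[0]
    if len(below) == 0:
        return None
    return float(curve.times[below[0]])


def logrank(groups: list[tuple[np.ndarray, np.ndarray]]) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi-square, p) with df = k - 1."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, (t, e) in enumerate(groups):
        if len(np.asarray(t)) == 0:
            raise ValueError(f"group {g} is empty")
    times = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    events = np.concatenate([np.asarray(e, dtype=bool) for _, e in groups])
    labels = np.concatenate([np.full(len(np.asarray(t)), g) for g, (t, _) in enumerate(groups)])
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


def logrank_chi2(times: np.ndarray, events: np.ndarray, labels: np.ndarray) -> float:
    """Vectorized k-group log-rank chi-square (observed minus expected form).

    Used inside the cutpoint search where calling a fitter per candidate
    would dominate the runtime; agreement with the lifelines test is covered
    by tests.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    gidx = np.searchsorted(uniq, labels)
    ev_times = np.unique(times[events])
    if len(ev_times) == 0 or k < 2:
        return 0.0
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in ev_times:
        at_risk = times >= t
        n_j = at_risk.sum()
        if n_j < 2:
            continue
        n_gj = np.bincount(gidx[at_risk], minlength=k).astype(float)
        died = at_risk & events & (times == t)
        d_j = died.sum()
        d_gj = np.bincount(gidx[died], minlength=k).astype(float)
        O += d_gj
        E += d_j * n_gj / n_j
        frac = n_gj / n_j
        mult = d_j * (n_j - d_j) / (n_j - 1)
        V += mult * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        sol = np.linalg.solve(Vsub, diff)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(Vsub) @ diff
    return float(diff @ sol)


@dataclass
class CoxFit:
    names: list[str]
    coefs: np.ndarray
    hazard_ratios: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    converged: bool
    flags: list[str] = field(default_factory=list)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefs


def cox_fit(
    covariates: pd.DataFrame | np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    penalizer: float = 0.0,
) -> CoxFit:
    """Breslow-ties Cox proportional-hazards fit (Newton-Raphson).

    Non-convergence and monotone-likelihood (perfect separation) are flagged
    on the returned object instead of raising; zero-variance covariates are a
    hard error.
    """
    if isinstance(covariates, np.ndarray):
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] == 1 and len(times) > 1:
            covariates = covariates.T
        covariates = pd.DataFrame(
            covariates, columns=[f"x{i}" for i in range(covariates.shape[1])]
        )
    events = np.asarray(events, dtype=bool)
    if events.sum() == 0:
        raise ValueError("no events; Cox model undefined")
    zero_var = [c for c in covariates.columns if covariates[c].std(ddof=0) == 0]
    if zero_var:
        raise ValueError(f"zero-variance covariate(s): {zero_var}")
    df = covariates.copy().reset_index(drop=True)
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = events.astype(int)
    cph = CoxPHFitter(penalizer=penalizer)
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except ConvergenceError as exc:
            return CoxFit(
                names=list(covariates.columns),
                coefs=np.full(covariates.shape[1], np.nan),
                hazard_ratios=np.full(covariates.shape[1], np.nan),
                se=np.full(covariates.shape[1], np.nan),
                p_values=np.full(covariates.shape[1], np.nan),
                converged=False,
                flags=[f"non-convergence: {exc}"],
            )
    for w in caught:
        msg = str(w.message)
        if "complete separation" in msg or "monotone" in msg.lower() or "convergence" in msg.lower():
            flags.append(msg.splitlines()[0])
    s = cph.summary
    return CoxFit(
        names=list(s.index),
        coefs=s["coef"].to_numpy(dtype=float),
        hazard_ratios=s["exp(coef)"].to_numpy(dtype=float),
        se=s["se(coef)"].to_numpy(dtype=float),
        p_values=s["p"].to_numpy(dtype=float),
        converged=True,
        flags=flags,
    )


def univariate_screen(
    covariates: pd.DataFrame, times: np.ndarray, events: np.ndarray, alpha: float = 0.05
) -> list[str]:
    """Retain covariates whose univariate Cox Wald P-value is below alpha."""
    keep = []
    for col in covariates.columns:
        if covariates[col].std(ddof=0) == 0:
            continue
        try:
            fit = cox_fit(covariates[[col]], times, events)
        except ValueError:
            continue
        if fit.converged and len(fit.p_values) and fit.p_values[0] < alpha:
            keep.append(col)
    return keep


def clinical_design(cohort: Cohort) -> pd.DataFrame:
    """Numeric design matrix of the nine clinical variables for Cox models.

    Continuous/ordinal variables enter as numbers (median-imputed);
    categoricals as reference-dropped dummies; rarely observed ``missing``
    levels become indicator columns only when present.
    """
    df = cohort.clinical
    out: dict[str, np.ndarray] = {}
    for var in CLINICAL_VARIABLES:
        if var in CONTINUOUS_VARIABLES:
            vals = pd.to_numeric(df[var], errors="coerce").to_numpy(dtype=float)
            med = np.nanmedian(vals) if np.isfinite(vals).any() else 0.0
            out[var] = np.where(np.isfinite(vals), vals, med)
        else:
            levels = CATEGORY_LEVELS[var]
            obs = df[var].astype(str).to_numpy()
            for lev in levels[1:]:  # drop first level as reference
                out[f"{var}={lev}"] = (obs == lev).astype(float)
            if (obs == MISSING).any():
                out[f"{var}={MISSING}"] = (obs == MISSING).astype(float)
    return pd.DataFrame(out)


@dataclass
class ControlModel:
    name: str
    selected: list[str]
    fit: CoxFit | None
    degenerate: bool

    def scores(self, design: pd.DataFrame) -> np.ndarray:
        """Survival-oriented scores (negated linear predictor)."""
        if self.degenerate or self.fit is None:
            return np.zeros(len(design))
        cols = design.reindex(columns=self.selected, fill_value=0.0)
        return -self.fit.linear_predictor(cols.to_numpy())


def build_control_models(
    cohort: Cohort,
    radiomics: FeatureMatrix | None = None,
    endpoint: str = "pfs",
    alpha: float = 0.05,
    penalizer: float = 0.0,
) -> dict[str, ControlModel]:
    """The three comparator Cox models: clinical, radiomics, composite.

    Within each covariate block, univariate screening at P < alpha selects
    the covariates for the multivariable fit; the composite model pools both
    blocks' survivors.  A block whose screen retains nothing is reported as a
    degenerate model rather than an error.
    """
    times, events = cohort.pfs() if endpoint == "pfs" else cohort.os()
    clin = clinical_design(cohort)
    rad = (radiomics or cohort.radiomics)
    blocks = {"clinical": clin}
    if rad is not None:
        blocks["radiomics"] = rad.to_frame().reset_index(drop=True)
    out: dict[str, ControlModel] = {}
    selected_union: list[str] = []
    composite_design = pd.concat(list(blocks.values()), axis=1)
    for name, design in blocks.items():
        sel = univariate_screen(design, times, events, alpha)
        selected_union += sel
        if not sel:
            out[name] = ControlModel(name, [], None, degenerate=True)
            continue
        fit = cox_fit(composite_design[sel], times, events, penalizer=penalizer)
        out[name] = ControlModel(name, sel, fit, degenerate=not fit.converged)
    if selected_union:
        fit = cox_fit(composite_design[selected_union], times, events, penalizer=penalizer)
        out["composite"] = ControlModel(
            "composite", selected_union, fit, degenerate=not fit.converged
        )
    else:
        out["composite"] = ControlModel("composite", [], None, degenerate=True)
    return out


@dataclass
class CutpointResult:
    cutpoints: tuple[float, float]
    labels: np.ndarray  # 0 (low) / 1 (medium) / 2 (high), ascending score
    chi2: float


def xtile_cutpoints(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    min_frac: float = 0.10,
    max_candidates: int | None = None,
) -> CutpointResult:
    """Optimal three-group score cutpoints by exhaustive log-rank search.

    Candidates are midpoints between adjacent distinct score values
    (optionally thinned to ``max_candidates`` quantile-spaced ones); the
    ordered pair maximizing the 3-group log-rank chi-square subject to every
    group holding at least ``min_frac`` of patients wins, ties going to the
    smallest first then smallest second cutpoint.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = len(scores)
    uniq = np.unique(scores)
    if len(uniq) < 3:
        raise ValueError("need at least 3 distinct score values")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    if max_candidates is not None and len(mids) > max_candidates:
        take = np.unique(np.linspace(0, len(mids) - 1, max_candidates).round().astype(int))
        mids = mids[take]
    min_count = int(np.ceil(min_frac * n))
    best = None
    for c1, c2 in combinations(mids, 2):
        labels = np.digitize(scores, [c1, c2])
        counts = np.bincount(labels, minlength=3)
        if counts.min() < min_count:
            continue
        chi2 = logrank_chi2(times, events, labels)
        if best is None or chi2 > best[0] + 1e-12:
            best = (chi2, c1, c2, labels)
    if best is None:
        raise ValueError(
            f"no cutpoint pair satisfies the minimum group fraction {min_frac}"
        )
    chi2, c1, c2, labels = best
    return CutpointResult((float(c1), float(c2)), labels, float(chi2))


def quantile_stratify(scores: np.ndarray, proportions: list[float]) -> np.ndarray:
    """Ascending-score groups sized by cumulative-floor rounded proportions.

    ``proportions`` must sum to 100; the last group absorbs the rounding
    remainder.  Ties in score are broken by original order (stable sort).
    """
    scores = np.asarray(scores, dtype=float)
    props = np.asarray(proportions, dtype=float)
    if np.any(props <= 0):
        raise ValueError("proportions must be positive")
    if abs(props.sum() - 100.0) > 1e-6:
        raise ValueError(f"proportions sum to {props.sum()}, not 100")
    n = len(scores)
    bounds = np.floor(np.cumsum(props) / 100.0 * n).astype(int)
    bounds[-1] = n
    order = np.argsort(scores, kind="stable")
    labels = np.empty(n, dtype=int)
    start = 0
    for g, end in enumerate(bounds):
        labels[order[start:end]] = g
        start = end
    return labels


def response_auc(scores: np.ndarray, responders: np.ndarray) -> float | None:
    """Probability a random responder outscores a random non-responder
    (rank-sum AUC, ties at 0.5).  None when either class is absent."""
    scores = np.asarray(scores, dtype=float)
    responders = np.asarray(responders, dtype=bool)
    if responders.all() or (~responders).all():
        return None
    return float(roc_auc_score(responders, scores))
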