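"""End-to-end orchestration: encode -> PAE -> hypergraph -> DHGN -> evaluate.

`run_pipeline` reproduces the full two-step protocol on synthetic or loaded
cohorts: the encoder is trained on progression-free survival pair labels,
its similarities and radiomics k-NN hyperedges form the population
hypergraph, the hypergraph network is trained with the Cox loss under
five-fold transductive cross-validation, and the locked model is applied to
a held-out cohort (its own graph, the trained encoder) and evaluated against
both progression-free and overall survival.

`run_comparison` adds the unsupervised Gower ε-radius graph variant and the
three Cox control models on identical cohorts; `run_variable_sensitivity`
re-runs the encoder/network with clinical-variable subsets of given sizes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from itertools import combinations

import numpy as np

from .cohort import (
    CLINICAL_VARIABLES,
    ClinicalScaler,
    Cohort,
    EncodedClinicalMatrix,
    RiskScores,
    encode_clinical,
)
from .evaluate import build_control_models, clinical_design, harrell_c
from .graphs import (
    HyperedgeGroup,
    Hypergraph,
    adjacency_edge_group,
    assemble_hypergraph,
    default_gower_spec,
    epsilon_radius_network,
    gower_distance,
    knn_hyperedge_group,
    pae_edge_group,
)
from .hgnn import CVResult, DHGNConfig, DHGNModel, cross_validate, dhgn_forward, train_dhgn
from .pae import (
    PAEConfig,
    PAEModel,
    make_pair_labels,
    pae_metrics,
    pair_similarities,
    similarity_matrix,
    train_pae,
)
from .radiomics import FeatureMatrix, FeatureScaler, icc_filter, standardize_features
from .simulate import SyntheticConfig, generate_cohort

__all__ = [
    "GraphConfig",
    "PipelineConfig",
    "FittedPipeline",
    "build_graph",
    "fit_pipeline",
    "score_cohort",
    "run_pipeline",
    "run_comparison",
    "run_variable_sensitivity",
]


@dataclass
class GraphConfig:
    pae_threshold: float = 0.5
    knn_k: int = 10
    use_pae: bool = True
    use_knn: bool = True
    gower_epsilon: float = 0.5  # used only by the unsupervised comparator


@dataclass
class PipelineConfig:
    cutoff_months: float = 9.0
    variables: tuple[str, ...] = CLINICAL_VARIABLES
    endpoint: str = "pfs"
    cv_folds: int = 5
    seed: int = 0
    pae: PAEConfig = field(default_factory=PAEConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    dhgn: DHGNConfig = field(default_factory=DHGNConfig)
    icc_threshold: float = 0.75

    def resolved(self) -> dict:
        return asdict(self)


@dataclass
class FittedPipeline:
    config: PipelineConfig
    clinical_scaler: ClinicalScaler
    feature_scaler: FeatureScaler
    pae_model: PAEModel
    dhgn_model: DHGNModel
    cv: CVResult | None
    train_scores: RiskScores
    pae_history: list[float]
    dhgn_history: list[float]
    n_edges: int


def build_graph(
    config: GraphConfig,
    sim,
    features: FeatureMatrix,
    similarity_for_self=None,
) -> Hypergraph:
    groups: list[HyperedgeGroup] = []
    if config.use_pae:
        groups.append(pae_edge_group(sim, threshold=config.pae_threshold))
    if config.use_knn:
        k = min(config.knn_k, features.n_patients - 1)
        groups.append(knn_hyperedge_group(features, k=k))
    return assemble_hypergraph(
        groups, features.n_patients, add_self_edges=True, sim=similarity_for_self or sim
    )


def _prepare_features(
    cohort: Cohort,
    scaler: FeatureScaler | None,
    replicates=None,
    icc_threshold: float = 0.75,
) -> tuple[FeatureMatrix, FeatureScaler]:
    rad = cohort.radiomics
    if rad is None:
        raise ValueError("cohort has no radiomics table")
    if scaler is None and replicates:
        report = icc_filter(rad, replicates, threshold=icc_threshold)
        rad = rad.subset(report.selected_names())
    return standardize_features(rad, scaler)


def fit_pipeline(
    train_cohort: Cohort,
    config: PipelineConfig | None = None,
    replicates=None,
) -> FittedPipeline:
    """Train encoder + hypergraph network on a cohort (PFS endpoint)."""
    config = config or PipelineConfig()
    encoded = encode_clinical(train_cohort, list(config.variables))
    labels = make_pair_labels(train_cohort, config.cutoff_months)
    pae_model, pae_hist = train_pae(encoded, labels, config.pae)
    feats, feat_scaler = _prepare_features(
        train_cohort, None, replicates, config.icc_threshold
    )
    sim = similarity_matrix(pae_model, encoded)
    hg = build_graph(config.graph, sim, feats)
    times, events = train_cohort.pfs()
    cv = None
    if config.cv_folds and config.cv_folds >= 2:
        cv = cross_validate(
            feats.values, hg, times, events, config.dhgn, k=config.cv_folds, seed=config.seed
        )
    # the locked model is retrained on the full training cohort; CV supplies
    # the validation estimate of its performance
    model, hist = train_dhgn(feats.values, hg, times, events, config.dhgn)
    scores = dhgn_forward(model, feats.values, hg, train_mode=False)
    return FittedPipeline(
        config=config,
        clinical_scaler=encoded.scaler,
        feature_scaler=feat_scaler,
        pae_model=pae_model,
        dhgn_model=model,
        cv=cv,
        train_scores=RiskScores(train_cohort.patient_ids, scores),
        pae_history=pae_hist,
        dhgn_history=hist,
        n_edges=hg.n_edges,
    )


def score_cohort(fitted: FittedPipeline, cohort: Cohort) -> tuple[RiskScores, Hypergraph]:
    """Apply the locked pipeline to a cohort: its own graph, trained weights.

    The cohort is encoded with the training scalers, a population graph is
    built with the trained encoder and the same graph configuration, and the
    locked network is run in evaluation mode.
    """
    encoded = encode_clinical(cohort, list(fitted.config.variables), fitted.clinical_scaler)
    feats, _ = _prepare_features(cohort, fitted.feature_scaler)
    sim = similarity_matrix(fitted.pae_model, encoded)
    hg = build_graph(fitted.config.graph, sim, feats)
    scores = dhgn_forward(fitted.dhgn_model, feats.values, hg, train_mode=False)
    return RiskScores(cohort.patient_ids, scores), hg


def _evaluate_scores(scores: RiskScores, cohort: Cohort, n_boot: int, seed: int) -> dict:
    out = {}
    for endpoint in ("pfs", "os"):
        times, events = getattr(cohort, endpoint)()
        c, ci = harrell_c(scores.values, times, events, n_boot=n_boot, seed=seed)
        out[f"cindex_{endpoint}"] = c
        out[f"cindex_{endpoint}_ci"] = ci
    return out


def _pae_eval(fitted: FittedPipeline, cohort: Cohort) -> dict:
    encoded = encode_clinical(cohort, list(fitted.config.variables), fitted.clinical_scaler)
    labels = make_pair_labels(cohort, fitted.config.cutoff_months)
    sims = pair_similarities(fitted.pae_model, encoded, labels.pairs)
    sens, spec = pae_metrics(sims, labels)
    return {"pae_sensitivity": sens, "pae_specificity": spec, "n_labeled_pairs": len(labels)}


def run_pipeline(
    config: PipelineConfig | None = None,
    train_cohort: Cohort | None = None,
    test_cohort: Cohort | None = None,
    synthetic: SyntheticConfig | None = None,
    n_test: int = 150,
    n_boot: int = 200,
) -> dict:
    """Full protocol; cohorts are simulated when not supplied."""
    config = config or PipelineConfig()
    if train_cohort is None:
        syn = synthetic or SyntheticConfig(seed=config.seed)
        train_cohort, _ = generate_cohort(syn)
        if test_cohort is None:
            test_syn = SyntheticConfig(**{**asdict(syn), "n": n_test, "seed": syn.seed + 10_000})
            test_cohort, _ = generate_cohort(test_syn)
    fitted = fit_pipeline(train_cohort, config)
    report: dict = {
        "config": config.resolved(),
        "n_train": train_cohort.n_patients,
        "n_edges_train": fitted.n_edges,
        "cv_fold_cindex": fitted.cv.fold_cindex if fitted.cv else None,
        "train": _evaluate_scores(fitted.train_scores, train_cohort, n_boot, config.seed),
        "train_pae": _pae_eval(fitted, train_cohort),
    }
    report["train_scores"] = fitted.train_scores
    if test_cohort is not None:
        scores, hg = score_cohort(fitted, test_cohort)
        report.update(
            {
                "n_test": test_cohort.n_patients,
                "n_edges_test": hg.n_edges,
                "test": _evaluate_scores(scores, test_cohort, n_boot, config.seed),
                "test_pae": _pae_eval(fitted, test_cohort),
                "test_scores": scores,
            }
        )
    report["fitted"] = fitted
    return report


def _gower_graph(cohort: Cohort, config: PipelineConfig, feats: FeatureMatrix) -> Hypergraph:
    dist = gower_distance(cohort.clinical, default_gower_spec())
    adj = epsilon_radius_network(dist, config.graph.gower_epsilon)
    groups = [adjacency_edge_group(adj, name="gower")]
    if config.graph.use_knn:
        k = min(config.graph.knn_k, feats.n_patients - 1)
        groups.append(knn_hyperedge_group(feats, k=k))
    return assemble_hypergraph(groups, feats.n_patients, add_self_edges=True, sim=1.0 - dist)


def run_comparison(
    config: PipelineConfig | None = None,
    train_cohort: Cohort | None = None,
    test_cohort: Cohort | None = None,
    n_boot: int = 0,
) -> dict:
    """DHGN (encoder graph) vs DHGN (Gower ε graph) vs three Cox controls.

    All models share the same cohorts; C-indices are reported for both
    endpoints on the held-out cohort (training cohort when none given).
    """
    config = config or PipelineConfig()
    if train_cohort is None:
        train_cohort, _ = generate_cohort(SyntheticConfig(seed=config.seed))
    report = run_pipeline(config, train_cohort=train_cohort, test_cohort=test_cohort,
                          n_boot=n_boot)
    out: dict = {"dhgn_pae": {}}
    eval_cohort = test_cohort if test_cohort is not None else train_cohort
    eval_block = report["test"] if test_cohort is not None else report["train"]
    out["dhgn_pae"] = {k: v for k, v in eval_block.items() if k.startswith("cindex")}

    # Gower-graph variant: same network config and fold protocol, unsupervised edges
    feats_train, feat_scaler = _prepare_features(train_cohort, None)
    hg_g = _gower_graph(train_cohort, config, feats_train)
    times, events = train_cohort.pfs()
    model_g, _ = train_dhgn(feats_train.values, hg_g, times, events, config.dhgn)
    if test_cohort is not None:
        feats_eval, _ = _prepare_features(test_cohort, feat_scaler)
        hg_eval = _gower_graph(test_cohort, config, feats_eval)
    else:
        feats_eval, hg_eval = feats_train, hg_g
    scores_g = dhgn_forward(model_g, feats_eval.values, hg_eval, train_mode=False)
    out["dhgn_gower"] = _evaluate_scores(
        RiskScores(eval_cohort.patient_ids, scores_g), eval_cohort, n_boot, config.seed
    )

    # Cox controls trained on the training cohort, evaluated on the eval cohort
    feats_std_train, _ = _prepare_features(train_cohort, feat_scaler)
    controls = build_control_models(train_cohort, feats_std_train, penalizer=0.1)
    design_eval = clinical_design(eval_cohort)
    rad_eval = feats_eval.to_frame().reset_index(drop=True)
    full_design = design_eval.join(rad_eval)
    for name, ctrl in controls.items():
        entry: dict = {"selected": ctrl.selected, "degenerate": ctrl.degenerate}
        if not ctrl.degenerate:
            scores_c = ctrl.scores(full_design)
            entry.update(
                _evaluate_scores(
                    RiskScores(eval_cohort.patient_ids, scores_c),
                    eval_cohort,
                    n_boot,
                    config.seed,
                )
            )
        out[f"cox_{name}"] = entry
    return out


def run_variable_sensitivity(
    config: PipelineConfig | None = None,
    variable_counts: tuple[int, ...] = (3, 5, 7, 9),
    max_subsets: int = 10,
    train_cohort: Cohort | None = None,
    test_cohort: Cohort | None = None,
    enumerate_all: bool = False,
) -> dict:
    """Average encoder and network performance per clinical-variable count.

    For each count, variable subsets are enumerated (all of them when
    ``enumerate_all`` or there are fewer than ``max_subsets``, otherwise a
    seeded sample), a fresh encoder + network is trained per subset, and the
    metrics are averaged per count.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)
    if train_cohort is None:
        train_cohort, _ = generate_cohort(SyntheticConfig(seed=config.seed))
    eval_cohort = test_cohort if test_cohort is not None else train_cohort
    results: dict[int, dict] = {}
    for count in variable_counts:
        if count > len(CLINICAL_VARIABLES):
            raise ValueError(f"count {count} exceeds the nine clinical variables")
        all_subsets = list(combinations(CLINICAL_VARIABLES, count))
        if not enumerate_all and len(all_subsets) > max_subsets:
            idx = rng.choice(len(all_subsets), size=max_subsets, replace=False)
            subsets = [all_subsets[i] for i in sorted(idx)]
        else:
            subsets = all_subsets
        sens_list, spec_list, c_list = [], [], []
        for sub in subsets:
            sub_config = PipelineConfig(
                cutoff_months=config.cutoff_months,
                variables=tuple(sub),
                cv_folds=0,
                seed=config.seed,
                pae=config.pae,
                graph=config.graph,
                dhgn=config.dhgn,
            )
            fitted = fit_pipeline(train_cohort, sub_config)
            pae_stats = _pae_eval(fitted, eval_cohort)
            if test_cohort is not None:
                scores, _ = score_cohort(fitted, test_cohort)
            else:
                scores = fitted.train_scores
            times, events = eval_cohort.pfs()
            c, _ = harrell_c(scores.values, times, events, n_boot=0)
            if pae_stats["pae_sensitivity"] is not None:
                sens_list.append(pae_stats["pae_sensitivity"])
            if pae_stats["pae_specificity"] is not None:
                spec_list.append(pae_stats["pae_specificity"])
            c_list.append(c)
        results[count] = {
            "n_subsets": len(subsets),
            "mean_pae_sensitivity": float(np.mean(sens_list)) if sens_list else None,
            "mean_pae_specificity": float(np.mean(spec_list)) if spec_list else None,
            "mean_dhgn_cindex_pfs": float(np.mean(c_list)),
        }
    return results
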