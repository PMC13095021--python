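"""Hypergraph convolution network trained with a Cox partial likelihood.

The convolution follows the node-edge-node scheme: node features are
aggregated into hyperedge features (averaged over the hyperedge, De^{-1} H^T),
redistributed to nodes with hyperedge weights (H W), symmetrically normalized
by node degrees, and passed through a learned linear transform:

    X' = sigma( Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2} X Theta )

Training is full-batch and transductive: every node participates in message
passing while the loss — the negative Breslow partial log-likelihood of the
Cox proportional-hazards model on progression-free survival — is evaluated
only on the (training-fold) nodes in the loss mask.  The reported score is
the negated linear head, so higher scores mean better predicted survival.

The training objective is a package design choice: a Cox partial likelihood
was preferred over classifying a dichotomized endpoint because it uses the
full censored time-to-event information; the loss is pluggable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._optim import glorot, make_optimizer
from .graphs import Hypergraph

__all__ = [
    "DHGNConfig",
    "DHGNModel",
    "CVResult",
    "hyperedge_conv",
    "dhgn_forward",
    "cox_loss",
    "train_dhgn",
    "cross_validate",
]


def hyperedge_conv(
    X: np.ndarray,
    hg: Hypergraph,
    theta: np.ndarray,
    activation: str | None = "relu",
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """One node-edge-node hyperedge convolution layer.

    Computed as the two-step aggregation (hyperedge means, then weighted
    node update) which equals the closed form
    Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2} X Theta.
    """
    X = np.asarray(X, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if X.shape[0] != hg.n_nodes:
        raise ValueError(f"X has {X.shape[0]} rows but hypergraph has {hg.n_nodes} nodes")
    if X.shape[1] != theta.shape[0]:
        raise ValueError("theta input dimension mismatch")
    dv = hg.node_degrees
    if np.any(dv <= 0):
        raise ValueError("zero node degree reached hyperedge_conv (upstream contract breach)")
    dv_isqrt = 1.0 / np.sqrt(dv)
    edge_feat = hg.H.T @ (dv_isqrt[:, None] * X) / hg.edge_degrees[:, None]
    out = dv_isqrt[:, None] * (hg.H @ (hg.W[:, None] * edge_feat))
    out = out @ theta
    if bias is not None:
        out = out + bias
    if activation == "relu":
        out = np.maximum(out, 0.0)
    elif activation not in (None, "linear"):
        raise ValueError(f"unknown activation {activation!r}")
    return out


@dataclass
class DHGNConfig:
    hidden: tuple[int, int] = (128, 64)
    dropout: float = 0.5
    lr: float = 1e-3
    weight_decay: float = 5e-4
    epochs: int = 100
    optimizer: str = "adam"
    seed: int = 0


@dataclass
class DHGNModel:
    """Two hyperedge-conv layers plus a linear head; score = -head output."""

    thetas: list[np.ndarray]
    biases: list[np.ndarray]
    head_w: np.ndarray
    head_b: np.ndarray  # shape (1,), kept as an array so optimizers update in place
    config: DHGNConfig = field(default_factory=DHGNConfig)

    @property
    def input_dim(self) -> int:
        return self.thetas[0].shape[0]

    @property
    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for t, b in zip(self.thetas, self.biases):
            out += [t, b]
        return out + [self.head_w, self.head_b]

    def __post_init__(self) -> None:
        self.head_b = np.atleast_1d(np.asarray(self.head_b, dtype=float))
        dims = [t.shape for t in self.thetas]
        for (a, b_), (c, _) in zip(dims, dims[1:]):
            if b_ != c:
                raise ValueError("layer dimensions do not chain")
        if self.head_w.shape[0] != dims[-1][1]:
            raise ValueError("head dimension mismatch")


def _init_dhgn(input_dim: int, config: DHGNConfig, rng: np.random.Generator) -> DHGNModel:
    h1, h2 = config.hidden
    return DHGNModel(
        thetas=[glorot(rng, input_dim, h1), glorot(rng, h1, h2)],
        biases=[np.zeros(h1), np.zeros(h2)],
        head_w=glorot(rng, h2, 1).ravel(),
        head_b=np.zeros(1),
        config=config,
    )


def _forward(
    model: DHGNModel,
    X: np.ndarray,
    G: np.ndarray,
    train_mode: bool,
    rng: np.random.Generator | None,
):
    """Forward pass with caches for backprop; G is the propagation matrix."""
    p = model.config.dropout if train_mode else 0.0
    caches = []
    A = np.asarray(X, dtype=float)
    for li, (theta, b) in enumerate(zip(model.thetas, model.biases)):
        GA = G @ A
        Z = GA @ theta + b
        R = np.maximum(Z, 0.0)
        if p > 0:
            if rng is None:
                raise ValueError("train_mode dropout needs an RNG")
            mask = (rng.random(R.shape) >= p) / (1.0 - p)
            D = R * mask
        else:
            mask = None
            D = R
        if not np.all(np.isfinite(D)):
            raise ValueError(f"non-finite activations at layer {li}")
        caches.append((A, GA, Z, mask))
        A = D
    risk = A @ model.head_w + model.head_b
    if not np.all(np.isfinite(risk)):
        raise ValueError("non-finite activations at head layer")
    return risk, A, caches


def dhgn_forward(
    model: DHGNModel,
    X: np.ndarray,
    hg: Hypergraph | np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Node scores for a cohort; higher score = better predicted survival."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.input_dim:
        raise ValueError(f"X has {X.shape[1]} features but model expects {model.input_dim}")
    G = hg.propagation_matrix() if isinstance(hg, Hypergraph) else np.asarray(hg, dtype=float)
    risk, _, _ = _forward(model, X, G, train_mode, rng)
    return -risk


def _breslow_neg_loglik(risk: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Negative Breslow partial log-likelihood and its gradient w.r.t. risk."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    risk = np.asarray(risk, dtype=float)
    if events.sum() == 0:
        raise ValueError("Cox partial likelihood undefined with zero events")
    order = np.argsort(-times, kind="stable")  # descending time
    r = risk[order]
    shift = r.max()
    exp_r = np.exp(r - shift)
    csum = np.cumsum(exp_r)  # risk-set sums for t >= t_(k) up to position k
    t_sorted = times[order]
    # for ties, every member of a tied block shares the full block's risk set
    block_end = np.arange(len(r))
    for k in range(len(r) - 2, -1, -1):
        if t_sorted[k] == t_sorted[k + 1]:
            block_end[k] = block_end[k + 1]
    S = csum[block_end]  # sum over {j: t_j >= t_i}, exp-shifted
    ev = events[order]
    loglik = np.sum((r - shift)[ev] - np.log(S[ev]))
    # gradient: dL/dr_k = -[event_k - exp(r_k) * sum_{i: event, t_i <= t_k} 1/S_i]
    inv_s = np.where(ev, 1.0 / S, 0.0)
    cum_inv = np.cumsum(inv_s[::-1])[::-1]
    # events tied with t_k sit earlier in descending order but satisfy t_i <= t_k
    block_start = np.arange(len(r))
    for k in range(1, len(r)):
        if t_sorted[k] == t_sorted[k - 1]:
            block_start[k] = block_start[k - 1]
    cum_inv = cum_inv[block_start]
    grad_sorted = -(ev.astype(float) - exp_r * cum_inv)
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return float(-loglik), grad


def cox_loss(scores: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Negative Breslow partial log-likelihood of risk r = -score."""
    loss, _ = _breslow_neg_loglik(-np.asarray(scores, dtype=float), times, events)
    return loss


def train_dhgn(
    X: np.ndarray,
    hg: Hypergraph,
    times: np.ndarray,
    events: np.ndarray,
    config: DHGNConfig | None = None,
    loss_mask: np.ndarray | None = None,
) -> tuple[DHGNModel, list[float]]:
    """Full-batch transductive gradient training of the Cox loss.

    All nodes take part in message passing; the partial likelihood is
    evaluated only over nodes in ``loss_mask`` (default: all).  Deterministic
    given the seed (single-threaded numpy).
    """
    config = config or DHGNConfig()
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if loss_mask is None:
        loss_mask = np.ones(len(times), dtype=bool)
    loss_mask = np.asarray(loss_mask, dtype=bool)
    if events[loss_mask].sum() == 0:
        raise ValueError("Cox partial likelihood undefined with zero events")
    rng = np.random.default_rng(config.seed)
    model = _init_dhgn(X.shape[1], config, rng)
    G = hg.propagation_matrix()
    opt = make_optimizer(
        config.optimizer, model.params, config.lr, weight_decay=config.weight_decay
    )
    midx = np.where(loss_mask)[0]
    history: list[float] = []
    for epoch in range(config.epochs):
        risk, A_last, caches = _forward(model, X, G, train_mode=True, rng=rng)
        loss, dr_m = _breslow_neg_loglik(risk[midx], times[midx], events[midx])
        if not np.isfinite(loss):
            raise ValueError(f"training diverged (non-finite loss) at epoch {epoch}")
        history.append(loss)
        dr = np.zeros_like(risk)
        dr[midx] = dr_m
        # head
        d_head_w = A_last.T @ dr
        d_head_b = np.atleast_1d(dr.sum())
        dA = np.outer(dr, model.head_w)
        layer_grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(caches)
        for li in range(len(caches) - 1, -1, -1):
            A_in, GA, Z, mask = caches[li]
            if mask is not None:
                dA = dA * mask
            dZ = dA * (Z > 0)
            layer_grads[li] = (GA.T @ dZ, dZ.sum(axis=0))
            if li > 0:
                dA = G.T @ (dZ @ model.thetas[li].T)
        flat: list[np.ndarray] = []
        for d_theta, d_b in layer_grads:
            flat += [d_theta, d_b]
        flat += [d_head_w, d_head_b]
        opt.step(flat)
    return model, history


@dataclass
class CVResult:
    fold_assignments: np.ndarray
    fold_cindex: list[float | None]
    fold_scores: list[np.ndarray]
    best_fold: int
    best_model: DHGNModel
    histories: list[list[float]]

    @property
    def mean_cindex(self) -> float:
        vals = [c for c in self.fold_cindex if c is not None]
        return float(np.mean(vals)) if vals else float("nan")


def cross_validate(
    X: np.ndarray,
    hg: Hypergraph,
    times: np.ndarray,
    events: np.ndarray,
    config: DHGNConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """k-fold transductive cross-validation on the training graph.

    Patients are partitioned into k folds; each fold's model trains its loss
    on the other folds' nodes (full-graph message passing) and is scored by
    the validation-fold C-index.  The model from the fold with the highest
    validation C-index is returned as the optimal one.  Folds whose training
    nodes carry no events are skipped with a warning.
    """
    from .evaluate import harrell_c

    config = config or DHGNConfig()
    n = len(times)
    if k < 2 or k > n:
        raise ValueError("k must satisfy 2 <= k <= n")
    rng = np.random.default_rng(seed)
    assignment = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    rng.shuffle(assignment)
    events = np.asarray(events, dtype=bool)
    fold_c: list[float | None] = []
    fold_scores: list[np.ndarray] = []
    histories: list[list[float]] = []
    models: list[DHGNModel | None] = []
    for fold in range(k):
        val = assignment == fold
        train = ~val
        if events[train].sum() == 0:
            warnings.warn(f"fold {fold}: no events in training split; skipped")
            fold_c.append(None)
            fold_scores.append(np.full(int(val.sum()), np.nan))
            histories.append([])
            models.append(None)
            continue
        model, hist = train_dhgn(X, hg, times, events, config, loss_mask=train)
        scores = dhgn_forward(model, X, hg, train_mode=False)
        try:
            c, _ = harrell_c(scores[val], times[val], events[val], n_boot=0)
        except ValueError:
            c = None
        fold_c.append(c)
        fold_scores.append(scores[val])
        histories.append(hist)
        models.append(model)
    trained = [i for i, m in enumerate(models) if m is not None]
    if not trained:
        raise ValueError("no fold could be trained (no events anywhere)")
    scored = [i for i in trained if fold_c[i] is not None]
    if scored:
        best = max(scored, key=lambda i: fold_c[i])
    else:
        warnings.warn("no fold had comparable validation pairs; returning the first fold model")
        best = trained[0]
    return CVResult(assignment, fold_c, fold_scores, best, models[best], histories)
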