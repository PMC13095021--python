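"""Pairwise association encoder (PAE).

Two weight-sharing projection networks map each patient's unit-norm encoded
clinical vector into a latent space; the rescaled cosine similarity
``(cos + 1)/2`` of two projections is trained, with a binary cross-entropy
loss, to predict whether the two patients fall on the same side of a
progression-free-survival cutoff (default 9.0 months, the training-cohort
median).  The resulting [0,1] similarities become the edge weights of the
population graph.

Pair labels under censoring: a patient is *above* the cutoff when the
observed PFS time exceeds it (event or censored — either way survival past
the cutoff is established); a patient is *below* only when progression or
death occurred at or before the cutoff.  Patients censored at or before the
cutoff have an ambiguous class and take part in no labeled pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._optim import glorot, make_optimizer
from .cohort import Cohort, EncodedClinicalMatrix

__all__ = [
    "PairLabelSet",
    "PAEConfig",
    "PAEModel",
    "make_pair_labels",
    "pair_labels_from_survival",
    "pair_similarity",
    "train_pae",
    "project",
    "pair_similarities",
    "similarity_matrix",
    "pae_metrics",
]

_EPS = 1e-7


@dataclass
class PairLabelSet:
    pairs: np.ndarray  # (m, 2) int, i < j, indices into the cohort order
    labels: np.ndarray  # (m,) bool: True iff same side of the cutoff
    cutoff_months: float
    eligible: np.ndarray  # indices of unambiguous patients
    above: np.ndarray  # per-eligible-patient boolean status

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be (m, 2)")
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs/labels length mismatch")
        if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("pairs must satisfy i < j (no self-pairs)")

    def __len__(self) -> int:
        return len(self.pairs)


def pair_labels_from_survival(
    times: np.ndarray, events: np.ndarray, cutoff_months: float = 9.0
) -> PairLabelSet:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    above = times > cutoff_months
    below = (times <= cutoff_months) & events
    unambiguous = above | below
    idx = np.where(unambiguous)[0]
    if len(idx) < 2:
        raise ValueError("fewer than 2 patients with unambiguous cutoff status")
    ii, jj = np.triu_indices(len(idx), k=1)
    pairs = np.column_stack([idx[ii], idx[jj]])
    labels = above[pairs[:, 0]] == above[pairs[:, 1]]
    return PairLabelSet(pairs, labels, float(cutoff_months), idx, above[idx])


def make_pair_labels(cohort: Cohort, cutoff_months: float = 9.0) -> PairLabelSet:
    """All unordered labeled pairs among cutoff-unambiguous patients."""
    times, events = cohort.pfs()
    return pair_labels_from_survival(times, events, cutoff_months)


def pair_similarity(hi: np.ndarray, hj: np.ndarray) -> float:
    """Cosine similarity of two latent vectors rescaled to [0, 1]."""
    hi = np.asarray(hi, dtype=float)
    hj = np.asarray(hj, dtype=float)
    if hi.shape != hj.shape:
        raise ValueError("latent vectors must have equal dimension")
    ni, nj = np.linalg.norm(hi), np.linalg.norm(hj)
    if ni == 0 or nj == 0:
        raise ValueError("zero latent vector has no direction")
    cos = float(hi @ hj / (ni * nj))
    return (np.clip(cos, -1.0, 1.0) + 1.0) / 2.0


@dataclass
class PAEConfig:
    hidden: tuple[int, int] = (64, 32)
    epochs: int = 100
    lr: float = 1e-3
    weight_decay: float = 1e-2  # discourages memorizing noisy pair labels
    optimizer: str = "adam"
    batch_pairs: int | None = 256  # None => full batch (all labeled pairs, one step/epoch)
    max_pairs_per_epoch: int = 50_000
    balanced: bool = True
    # fraction of eligible patients held out; the returned weights are the
    # epoch snapshot with the best validation pair loss (0 disables)
    val_fraction: float = 0.2
    seed: int = 0


@dataclass
class PAEModel:
    """Weight-sharing twin projection network (the sharing is structural:
    there is one parameter set, applied to both members of a pair)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    config: PAEConfig = field(default_factory=PAEConfig)

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]


def _init_model(input_dim: int, config: PAEConfig, rng: np.random.Generator) -> PAEModel:
    h1, h2 = config.hidden
    return PAEModel(
        W1=glorot(rng, input_dim, h1),
        b1=np.zeros(h1),
        W2=glorot(rng, h1, h2),
        b2=np.zeros(h2),
        config=config,
    )


def project(model: PAEModel, X: np.ndarray) -> np.ndarray:
    """Project encoded clinical rows into the shared latent space."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.input_dim:
        raise ValueError(f"input dimension {X.shape[1]} != model dimension {model.input_dim}")
    z1 = X @ model.W1 + model.b1
    return np.maximum(z1, 0.0) @ model.W2 + model.b2


def _forward_cache(model: PAEModel, X: np.ndarray):
    z1 = X @ model.W1 + model.b1
    a1 = np.maximum(z1, 0.0)
    return z1, a1, a1 @ model.W2 + model.b2


def _pair_loss_grad(H: np.ndarray, pairs: np.ndarray, y: np.ndarray):
    """Mean BCE over pairs and its gradient with respect to H."""
    hi, hj = H[pairs[:, 0]], H[pairs[:, 1]]
    ni = np.linalg.norm(hi, axis=1)
    nj = np.linalg.norm(hj, axis=1)
    denom = ni * nj
    if np.any(denom == 0):
        raise ValueError("zero latent vector encountered")
    cos = np.einsum("ij,ij->i", hi, hj) / denom
    s = np.clip((cos + 1.0) / 2.0, _EPS, 1.0 - _EPS)
    yf = y.astype(float)
    loss = float(np.mean(-(yf * np.log(s) + (1 - yf) * np.log(1 - s))))
    # dL/ds averaged over the batch, chained through s = (cos+1)/2
    dc = (s - yf) / (s * (1 - s)) * 0.5 / len(y)
    gi = (hj / denom[:, None] - cos[:, None] * hi / (ni**2)[:, None]) * dc[:, None]
    gj = (hi / denom[:, None] - cos[:, None] * hj / (nj**2)[:, None]) * dc[:, None]
    dH = np.zeros_like(H)
    np.add.at(dH, pairs[:, 0], gi)
    np.add.at(dH, pairs[:, 1], gj)
    return loss, dH


def _full_loss(model: PAEModel, X: np.ndarray, labels: PairLabelSet) -> float:
    H = project(model, X)
    loss, _ = _pair_loss_grad(H, labels.pairs, labels.labels)
    return loss


def train_pae(
    encoded: EncodedClinicalMatrix | np.ndarray,
    labels: PairLabelSet,
    config: PAEConfig | None = None,
) -> tuple[PAEModel, list[float]]:
    """Fit the twin projection network on cutoff-rule pair labels.

    Mini-batches of pairs are sampled with balanced classes (or all pairs are
    used per step when ``batch_pairs`` is None).  Returns the model and the
    per-epoch full-pair-set loss history (entry 0 is the pre-training loss).
    Deterministic given ``config.seed``.
    """
    config = config or PAEConfig()
    X = encoded.matrix if isinstance(encoded, EncodedClinicalMatrix) else np.asarray(encoded)
    if len(labels) == 0:
        raise ValueError("empty PairLabelSet")
    if config.balanced and config.batch_pairs is not None:
        if not labels.labels.any():
            raise ValueError("balanced sampling requested but no positive (same-side) pairs")
        if labels.labels.all():
            raise ValueError("balanced sampling requested but no negative (cross-side) pairs")
    rng = np.random.default_rng(config.seed)

    # patient-level validation split for early-stopping snapshots
    train_pairs, train_y = labels.pairs, labels.labels
    val_pairs = val_y = None
    if config.val_fraction > 0 and len(labels.eligible) >= 10:
        elig = labels.eligible.copy()
        rng.shuffle(elig)
        n_val = max(2, int(round(config.val_fraction * len(elig))))
        val_set = np.zeros(X.shape[0], dtype=bool)
        val_set[elig[:n_val]] = True
        in_val = val_set[labels.pairs[:, 0]] & val_set[labels.pairs[:, 1]]
        in_train = ~val_set[labels.pairs[:, 0]] & ~val_set[labels.pairs[:, 1]]
        if in_val.sum() >= 1 and in_train.sum() >= 2 and train_y[in_train].any() \
                and not train_y[in_train].all():
            train_pairs, train_y = labels.pairs[in_train], labels.labels[in_train]
            val_pairs, val_y = labels.pairs[in_val], labels.labels[in_val]
    pos = np.where(train_y)[0]
    neg = np.where(~train_y)[0]

    model = _init_model(X.shape[1], config, rng)
    opt = make_optimizer(
        config.optimizer, model.params, config.lr, weight_decay=config.weight_decay
    )
    history = [_full_loss(model, X, labels)]
    best = (np.inf, [p.copy() for p in model.params])
    for epoch in range(config.epochs):
        if config.batch_pairs is None:
            batches = [(train_pairs, train_y)]
        else:
            n_draw = min(len(train_y), config.max_pairs_per_epoch)
            n_batches = max(1, n_draw // config.batch_pairs)
            batches = []
            for _ in range(n_batches):
                half = config.batch_pairs // 2
                if config.balanced:
                    sel = np.concatenate(
                        [rng.choice(pos, size=half), rng.choice(neg, size=half)]
                    )
                else:
                    sel = rng.choice(len(train_y), size=config.batch_pairs)
                batches.append((train_pairs[sel], train_y[sel]))
        for bpairs, by in batches:
            z1, a1, H = _forward_cache(model, X)
            loss, dH = _pair_loss_grad(H, bpairs, by)
            if not np.isfinite(loss):
                raise ValueError(f"non-finite PAE loss at epoch {epoch}")
            dW2 = a1.T @ dH
            db2 = dH.sum(axis=0)
            da1 = dH @ model.W2.T
            dz1 = da1 * (z1 > 0)
            dW1 = X.T @ dz1
            db1 = dz1.sum(axis=0)
            opt.step([dW1, db1, dW2, db2])
        history.append(_full_loss(model, X, labels))
        if not np.isfinite(history[-1]):
            raise ValueError(f"non-finite PAE loss at epoch {epoch}")
        if val_pairs is not None:
            vloss, _ = _pair_loss_grad(project(model, X), val_pairs, val_y)
            if vloss < best[0]:
                best = (vloss, [p.copy() for p in model.params])
    if val_pairs is not None and np.isfinite(best[0]):
        for p, b in zip(model.params, best[1]):
            p[...] = b
    return model, history


def pair_similarities(
    model: PAEModel, encoded: EncodedClinicalMatrix | np.ndarray, pairs: np.ndarray
) -> np.ndarray:
    """Rescaled cosine similarity for each (i, j) pair of patients."""
    X = encoded.matrix if isinstance(encoded, EncodedClinicalMatrix) else np.asarray(encoded)
    H = project(model, X)
    pairs = np.asarray(pairs, dtype=int)
    hi, hj = H[pairs[:, 0]], H[pairs[:, 1]]
    denom = np.linalg.norm(hi, axis=1) * np.linalg.norm(hj, axis=1)
    if np.any(denom == 0):
        raise ValueError("zero latent vector encountered")
    cos = np.clip(np.einsum("ij,ij->i", hi, hj) / denom, -1.0, 1.0)
    return (cos + 1.0) / 2.0


@dataclass
class SimilarityMatrix:
    values: np.ndarray  # (n, n) in [0,1], symmetric, unit diagonal

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def similarity_matrix(
    model: PAEModel, encoded: EncodedClinicalMatrix | np.ndarray
) -> SimilarityMatrix:
    """All pairwise rescaled cosine similarities of the projected cohort."""
    X = encoded.matrix if isinstance(encoded, EncodedClinicalMatrix) else np.asarray(encoded)
    H = project(model, X)
    norms = np.linalg.norm(H, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero latent vector encountered")
    Hn = H / norms[:, None]
    S = np.clip((Hn @ Hn.T + 1.0) / 2.0, 0.0, 1.0)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S)


def pae_metrics(
    similarities: np.ndarray,
    labels: np.ndarray | PairLabelSet,
    threshold: float = 0.5,
) -> tuple[float | None, float | None]:
    """Sensitivity and specificity of thresholded similarities vs pair labels.

    Predicted positive iff similarity >= threshold.  An undefined metric (no
    positive or no negative labels) is returned as None rather than 0.
    """
    y = labels.labels if isinstance(labels, PairLabelSet) else np.asarray(labels, dtype=bool)
    similarities = np.asarray(similarities, dtype=float)
    if len(similarities) != len(y):
        raise ValueError("similarities/labels length mismatch")
    pred = similarities >= threshold
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return sens, spec
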