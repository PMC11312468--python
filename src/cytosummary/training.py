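"""Supervised contrastive training of the set aggregator.

The SupCon loss pulls embeddings of views sharing a compound label together
and pushes different-compound embeddings apart, using temperature-scaled
cosine similarities:

    L = sum_i (-1/|P(i)|) sum_{p in P(i)} log( exp(u_i.u_p/tau)
                                               / sum_{a in A(i)} exp(u_i.u_a/tau) )

where u are L2-normalized embeddings. Two variants of the denominator index
set A(i) are provided: ``supcon_standard`` (all samples except the anchor,
the definition of the cited SupCon method — the default) and
``paper_literal`` (different-compound samples only). Training views are
augmented sets of cells: set sizes drawn from a Gaussian, cells sampled with
replacement from one well or, on a coin flip, from a pooled pair of the
compound's wells. Optimization is AdamW with decoupled weight decay; the
checkpoint kept is the one with the best validation replicate-retrieval mAP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import replicate_retrieval_map
from .io import SampleSet, SingleCellTable, WellKey
from .model import AggregatorModel, aggregate_table, backward_view, forward

__all__ = [
    "SupConBatch",
    "AugmentConfig",
    "TrainConfig",
    "supcon_loss",
    "supcon_loss_and_grad",
    "sample_cell_view",
    "make_epoch_batches",
    "train",
]

log = logging.getLogger(__name__)

VARIANTS = ("supcon_standard", "paper_literal")


@dataclass
class SupConBatch:
    """Embeddings with compound labels and a temperature, ready for the loss."""

    embeddings: np.ndarray  # B x L
    labels: np.ndarray      # length B
    temperature: float = 0.1

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        B = self.embeddings.shape[0]
        if B < 4:
            raise ValueError("SupCon batch needs B >= 4")
        if self.labels.shape[0] != B:
            raise ValueError("labels length must match batch size")
        _, counts = np.unique(self.labels, return_counts=True)
        if (counts < 2).any():
            raise ValueError(
                "every label needs >= 2 occurrences (each anchor needs positives)"
            )


@dataclass
class AugmentConfig:
    """Training-view augmentation: Gaussian set sizes and coin-flip well mixing."""

    count_mean: float = 400.0
    count_sd: float = 100.0
    min_count: int = 10
    mix_probability: float = 0.5
    views_per_compound: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.count_mean < self.min_count:
            raise ValueError("count_mean must be >= min_count")
        if not 0.0 <= self.mix_probability <= 1.0:
            raise ValueError("mix_probability must lie in [0, 1]")
        if self.views_per_compound < 2:
            raise ValueError("views_per_compound must be >= 2 (positives impossible otherwise)")


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    weight_decay: float = 1e-2
    epochs: int = 100
    compounds_per_batch: int = 8
    rounds_per_epoch: int = 4  # sets of cells sampled per compound per epoch
    temperature: float = 0.1
    loss_variant: str = "supcon_standard"
    val_every: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("rates must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.rounds_per_epoch < 1:
            raise ValueError("rounds_per_epoch must be >= 1")
        if self.loss_variant not in VARIANTS:
            raise ValueError(f"loss_variant must be one of {VARIANTS}")


# ---------------------------------------------------------------------------
# SupCon loss
# ---------------------------------------------------------------------------

def _supcon_core(
    V: np.ndarray, labels: np.ndarray, tau: float, variant: str
) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the raw (un-normalized) embeddings."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown SupCon variant {variant!r}")
    B = V.shape[0]
    norms = np.linalg.norm(V, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-norm embedding in SupCon batch")
    U = V / norms[:, None]
    S = (U @ U.T) / tau
    same = labels[:, None] == labels[None, :]
    eye = np.eye(B, dtype=bool)
    pos = same & ~eye
    if variant == "supcon_standard":
        denom_mask = ~eye
    else:  # paper_literal: denominator over different-compound samples only
        denom_mask = ~same
    n_pos = pos.sum(axis=1)

    # log-sum-exp over each anchor's denominator set
    loss = 0.0
    G = np.zeros_like(S)  # dL/dS
    for i in range(B):
        d = np.flatnonzero(denom_mask[i])
        p = np.flatnonzero(pos[i])
        s_d = S[i, d]
        m = s_d.max()
        lse = m + np.log(np.exp(s_d - m).sum())
        loss += -(S[i, p].sum() / n_pos[i]) + lse
        soft = np.exp(s_d - lse)
        G[i, d] += soft
        G[i, p] -= 1.0 / n_pos[i]

    dU = (G + G.T) @ U / tau
    # back through L2 normalization: dV_i = (dU_i - (dU_i . U_i) U_i) / ||V_i||
    proj = (dU * U).sum(axis=1, keepdims=True)
    dV = (dU - proj * U) / norms[:, None]
    return float(loss), dV


def supcon_loss(batch: SupConBatch, variant: str = "supcon_standard") -> float:
    """Total SupCon loss of a batch (embeddings L2-normalized internally)."""
    loss, _ = _supcon_core(batch.embeddings, batch.labels, batch.temperature, variant)
    return loss


def supcon_loss_and_grad(
    batch: SupConBatch, variant: str = "supcon_standard"
) -> tuple[float, np.ndarray]:
    """Loss plus its gradient w.r.t. the raw embedding matrix."""
    return _supcon_core(batch.embeddings, batch.labels, batch.temperature, variant)


# ---------------------------------------------------------------------------
# Augmentation and batch construction
# ---------------------------------------------------------------------------

def _draw_count(cfg: AugmentConfig, rng: np.random.Generator) -> int:
    c = int(round(rng.normal(cfg.count_mean, cfg.count_sd)))
    return max(c, cfg.min_count)


def sample_cell_view(
    wells_of_compound: list[SampleSet], cfg: AugmentConfig, rng: np.random.Generator
) -> SampleSet:
    """Draw one augmented view of a compound.

    Set size c ~ round(Normal(count_mean, count_sd)) clipped at min_count.
    A coin flip picks single-well (cells sampled with replacement from one
    randomly chosen well) or mixed (pooled cells of two distinct wells of the
    same compound, sampled with replacement). A single-well compound always
    falls back to single-well.
    """
    if not wells_of_compound:
        raise ValueError("compound has no wells")
    c = _draw_count(cfg, rng)
    mix = rng.random() < cfg.mix_probability and len(wells_of_compound) >= 2
    if mix:
        i, j = rng.choice(len(wells_of_compound), size=2, replace=False)
        pool = np.vstack([wells_of_compound[i].X, wells_of_compound[j].X])
        key = wells_of_compound[i].well_key
    else:
        i = int(rng.integers(len(wells_of_compound)))
        pool = wells_of_compound[i].X
        key = wells_of_compound[i].well_key
    rows = rng.integers(0, pool.shape[0], size=c)
    return SampleSet(well_key=key, X=pool[rows])


def group_wells_by_compound(table: SingleCellTable) -> dict[str, list[SampleSet]]:
    """Compound -> list of that compound's well sample sets."""
    grouped: dict[str, list[SampleSet]] = {}
    for s in table.iter_wells():
        grouped.setdefault(s.well_key.compound_id, []).append(s)
    return grouped


def make_epoch_batches(
    grouped: dict[str, list[SampleSet]],
    cfg: AugmentConfig,
    compounds_per_batch: int,
    rng: np.random.Generator,
    view_rng: np.random.Generator | None = None,
) -> list[list[tuple[SampleSet, str]]]:
    """One epoch's batches: k compounds x v views each, every compound covered.

    Compound order is shuffled per epoch by ``rng``; views are drawn from
    ``view_rng`` (defaults to ``rng``). The final batch is padded with a
    compound re-drawn from earlier ones when the count does not divide evenly,
    so every batch keeps >= 2 distinct labels.
    """
    compounds = sorted(grouped)
    if len(compounds) < 2:
        raise ValueError("need at least two compounds to form contrastive batches")
    view_rng = view_rng if view_rng is not None else rng
    k = min(compounds_per_batch, len(compounds))
    order = list(rng.permutation(compounds))
    batches = []
    for start in range(0, len(order), k):
        chunk = order[start : start + k]
        if len(chunk) < 2:  # pad a trailing singleton batch
            extra = [c for c in order if c not in chunk]
            chunk = chunk + [extra[int(rng.integers(len(extra)))]]
        batch = []
        for comp in chunk:
            for _ in range(cfg.views_per_compound):
                batch.append((sample_cell_view(grouped[comp], cfg, view_rng), comp))
        batches.append(batch)
    return batches


# ---------------------------------------------------------------------------
# AdamW
# ---------------------------------------------------------------------------

class _AdamW:
    """AdamW with decoupled weight decay (decay applied to weights, not biases)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, wd: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.wd, self.betas, self.eps = lr, wd, betas, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if k.startswith("W"):
                params[k] -= self.lr * self.wd * params[k]


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _batch_step(
    model: AggregatorModel,
    batch: list[tuple[SampleSet, str]],
    tau: float,
    variant: str,
) -> tuple[float, dict[str, np.ndarray]]:
    """Forward all views, compute SupCon, backpropagate to parameter grads."""
    states = [forward(model, s, keep_state=True) for s, _ in batch]
    V = np.vstack([st.v for st in states])
    labels = np.array([lab for _, lab in batch])
    loss, dV = _supcon_core(V, labels, tau, variant)
    grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    for st, dv in zip(states, dV):
        g, _ = backward_view(model, st, dv)
        for k in grads:
            grads[k] += g[k]
    return loss, grads


def train(
    model: AggregatorModel,
    train_table: SingleCellTable,
    val_table: SingleCellTable | None,
    train_cfg: TrainConfig,
    aug_cfg: AugmentConfig,
) -> tuple[AggregatorModel, pd.DataFrame]:
    """Train the aggregator; return the best-validation-mAP snapshot + history.

    Validation replicate-retrieval mAP is computed from full wells (no
    augmentation) every ``val_every`` epochs; the returned model is the
    snapshot with the highest validation mAP. Train/validation compound
    disjointness is the caller's responsibility. Fully seeded: the global seed
    feeds separate named streams for augmentation and batch order.
    """
    ss = np.random.SeedSequence(train_cfg.seed)
    aug_child, order_child = ss.spawn(2)
    rng_aug = np.random.default_rng(aug_child)
    rng_order = np.random.default_rng(order_child)

    grouped = group_wells_by_compound(train_table)
    optimizer = _AdamW(model.params, train_cfg.learning_rate, train_cfg.weight_decay)

    best_map = -np.inf
    best_model = model.copy()
    history = []
    for epoch in range(1, train_cfg.epochs + 1):
        batches = [
            b
            for _ in range(train_cfg.rounds_per_epoch)
            for b in make_epoch_batches(
                grouped, aug_cfg, train_cfg.compounds_per_batch, rng_order, rng_aug
            )
        ]
        epoch_loss = 0.0
        for batch in batches:
            loss, grads = _batch_step(
                model, batch, train_cfg.temperature, train_cfg.loss_variant
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite SupCon loss at epoch {epoch} "
                    f"(lr={train_cfg.learning_rate}, tau={train_cfg.temperature})"
                )
            optimizer.step(model.params, grads)
            epoch_loss += loss
        epoch_loss /= max(len(batches), 1)

        val_map = np.nan
        if val_table is not None and epoch % train_cfg.val_every == 0:
            val_profiles = aggregate_table(model, val_table)
            val_map = replicate_retrieval_map(val_profiles).map
            if val_map > best_map:
                best_map = val_map
                best_model = model.copy()
        history.append({"epoch": epoch, "train_loss": epoch_loss, "val_map": val_map})
        log.info("epoch %d: loss %.4f val mAP %s", epoch, epoch_loss,
                 f"{val_map:.4f}" if np.isfinite(val_map) else "-")

    if val_table is None or not np.isfinite(best_map):
        warnings.warn("no validation set; returning final-epoch weights")
        best_model = model.copy()
    return best_model, pd.DataFrame(history)
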