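"""System-wise splitting, smooth-L1 loss, the training loop, and
system-wise evaluation.

The split is by *system* (unordered component pair), never by data point, so
evaluation always measures truly unseen mixtures.  Training minimizes a
smooth-L1 (Huber-like) loss over every available ln gamma label with AdamW,
a reduce-on-plateau learning-rate schedule and early stopping, all keyed on
the validation loss; the checkpoint with the best validation loss is
returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._net import AdamW
from .dataio import GammaRecord
from .embeddings import EmbeddingCache, fit_scalers
from .errors import DivergedLoss, TooFewSystems
from .model import GibbsExcessNet

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "system_key",
    "split_systems",
    "split_records",
    "smooth_l1",
    "TrainingArrays",
    "prepare_arrays",
    "train",
    "evaluate_systemwise",
    "cumulative_fraction",
    "predict_records",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test fractions (by system) and the shuffle seed."""

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class TrainConfig:
    """Optimization hyperparameters; stored verbatim in the checkpoint."""

    lr: float = 0.001
    weight_decay: float = 0.01
    scheduler_factor: float = 0.1
    scheduler_patience: int = 10
    early_stop_patience: int = 30
    batch_size: int = 512
    smooth_l1_beta: float = 0.25
    max_epochs: int = 1000
    seed: int = 0


def system_key(smiles_1: str, smiles_2: str) -> tuple[str, str]:
    """Canonical unordered pair: lexicographically sorted component tags."""
    return tuple(sorted((smiles_1, smiles_2)))


def split_systems(keys, spec: SplitSpec):
    """Seeded uniform shuffle of the distinct systems, partitioned at
    floor(f_train * n) / floor((f_train + f_val) * n).  Disjoint and
    exhaustive by construction."""
    unique = sorted(set(keys))
    n = len(unique)
    if n < 3:
        raise TooFewSystems(f"need >= 3 distinct systems, got {n}")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    f_train, f_val, _ = spec.fractions
    i1 = int(np.floor(f_train * n))
    i2 = int(np.floor((f_train + f_val) * n))
    shuffled = [unique[i] for i in order]
    return set(shuffled[:i1]), set(shuffled[i1:i2]), set(shuffled[i2:])


def split_records(records: list[GammaRecord], spec: SplitSpec):
    """Partition records by their system's split assignment."""
    keys = [system_key(r.smiles_1, r.smiles_2) for r in records]
    tr, va, te = split_systems(keys, spec)
    pick = lambda s: [r for r, k in zip(records, keys) if k in s]  # noqa: E731
    return pick(tr), pick(va), pick(te)


def split_by_composition(records: list[GammaRecord], n_train: int, n_val: int, seed: int = 0):
    """Within-system composition holdout: for every system, shuffle its
    records and assign the first ``n_train`` to train, the next ``n_val`` to
    validation, and the remainder to test.

    This is the complement of the system-wise split: every system is seen
    during training, and evaluation measures interpolation to unseen
    compositions/temperatures of known systems (the setting of the
    parameter-recovery experiment on synthetic data).
    """
    rng = np.random.default_rng(seed)
    by_system: dict = {}
    for r in records:
        by_system.setdefault(system_key(r.smiles_1, r.smiles_2), []).append(r)
    tr, va, te = [], [], []
    for key in sorted(by_system):
        recs = by_system[key]
        for j, i in enumerate(rng.permutation(len(recs))):
            (tr if j < n_train else va if j < n_train + n_val else te).append(recs[i])
    return tr, va, te


def smooth_l1(residual, beta: float = 0.25):
    """Huber-like loss: 0.5 r^2 / beta for |r| <= beta, else |r| - beta/2.
    C1-continuous at |r| = beta."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    r = np.abs(np.asarray(residual, dtype=float))
    out = np.where(r <= beta, 0.5 * r * r / beta, r - 0.5 * beta)
    return out if np.ndim(residual) else float(out)


def _smooth_l1_grad(residual, beta: float):
    r = np.asarray(residual, dtype=float)
    return np.where(np.abs(r) <= beta, r / beta, np.sign(r))


# ----------------------------------------------------------------- data prep


@dataclass
class TrainingArrays:
    """Records flattened to aligned arrays; labels carry NaN where absent."""

    E1: np.ndarray
    E2: np.ndarray
    T: np.ndarray
    x1: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    keys: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.E1.shape[0]

    @property
    def n_labels(self) -> int:
        return int(np.isfinite(self.y1).sum() + np.isfinite(self.y2).sum())


def prepare_arrays(records: list[GammaRecord], cache: EmbeddingCache) -> TrainingArrays:
    """Embed every unique component once and assemble training arrays."""
    e1 = np.stack([cache.get(r.smiles_1).embedding for r in records])
    e2 = np.stack([cache.get(r.smiles_2).embedding for r in records])
    return TrainingArrays(
        E1=e1,
        E2=e2,
        T=np.array([r.T for r in records], dtype=float),
        x1=np.array([r.x1 for r in records], dtype=float),
        y1=np.array([np.nan if r.ln_gamma_1 is None else r.ln_gamma_1 for r in records]),
        y2=np.array([np.nan if r.ln_gamma_2 is None else r.ln_gamma_2 for r in records]),
        keys=[system_key(r.smiles_1, r.smiles_2) for r in records],
    )


def _loss_and_adjoints(cache_fw, y1, y2, beta):
    """Mean smooth-L1 over available label terms, plus the ln-gamma
    adjoints for the backward pass."""
    m1 = np.isfinite(y1)
    m2 = np.isfinite(y2)
    n_terms = int(m1.sum() + m2.sum())
    r1 = np.where(m1, cache_fw["ln_gamma_1"] - np.where(m1, y1, 0.0), 0.0)
    r2 = np.where(m2, cache_fw["ln_gamma_2"] - np.where(m2, y2, 0.0), 0.0)
    loss = (smooth_l1(r1[m1], beta).sum() + smooth_l1(r2[m2], beta).sum()) / n_terms
    g1 = np.where(m1, _smooth_l1_grad(r1, beta), 0.0) / n_terms
    g2 = np.where(m2, _smooth_l1_grad(r2, beta), 0.0) / n_terms
    return float(loss), g1, g2


def _eval_loss(model, arrays: TrainingArrays, beta: float) -> float:
    ln1, ln2 = model.ln_gamma(arrays.E1, arrays.E2, arrays.T, arrays.x1)
    m1, m2 = np.isfinite(arrays.y1), np.isfinite(arrays.y2)
    total = (
        smooth_l1(ln1[m1] - arrays.y1[m1], beta).sum()
        + smooth_l1(ln2[m2] - arrays.y2[m2], beta).sum()
    )
    return float(total / (m1.sum() + m2.sum()))


# -------------------------------------------------------------- the training


def train(
    model: GibbsExcessNet,
    train_arrays: TrainingArrays,
    val_arrays: TrainingArrays,
    config: TrainConfig | None = None,
) -> tuple[GibbsExcessNet, pd.DataFrame]:
    """Fit the model in place and return (best checkpoint, history).

    Standardization is fitted here on the *training* arrays only (embedding
    rows of both component columns, stacked, and the temperatures) and
    attached to the model before optimization.  History columns: epoch,
    train_loss, val_loss, lr.
    """
    config = config or TrainConfig()
    beta = config.smooth_l1_beta
    model.scalers = fit_scalers(
        np.vstack([train_arrays.E1, train_arrays.E2]), train_arrays.T
    )
    model.config = {**model.config, "train": asdict(config)}

    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    opt = AdamW(params, lr=config.lr, weight_decay=config.weight_decay)

    best_val = np.inf
    best_model = model.copy()
    epochs_since_improve = 0
    plateau = 0
    lr = config.lr
    history = []

    n = train_arrays.n
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            fw = model.forward_training(
                train_arrays.E1[idx],
                train_arrays.E2[idx],
                train_arrays.T[idx],
                train_arrays.x1[idx],
            )
            loss, g1, g2 = _loss_and_adjoints(
                fw, train_arrays.y1[idx], train_arrays.y2[idx], beta
            )
            if not np.isfinite(loss):
                raise DivergedLoss(f"training loss became {loss} at epoch {epoch}")
            grads = model.backward_training(fw, g1, g2)
            opt.step(grads)
            epoch_loss += loss
            n_batches += 1

        val_loss = _eval_loss(model, val_arrays, beta)
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / n_batches,
                "val_loss": val_loss,
                "lr": lr,
            }
        )

        if val_loss < best_val:  # strict improvement, no min-delta
            best_val = val_loss
            best_model = model.copy()
            epochs_since_improve = 0
            plateau = 0
        else:
            epochs_since_improve += 1
            plateau += 1
            if plateau > config.scheduler_patience:
                lr *= config.scheduler_factor
                opt.lr = lr
                plateau = 0
                log.info("epoch %d: lr reduced to %.2e", epoch, lr)
            if epochs_since_improve > config.early_stop_patience:
                log.info("early stop at epoch %d (best val %.5f)", epoch, best_val)
                break

    return best_model, pd.DataFrame(history)


# ------------------------------------------------------------------ evaluate


def evaluate_systemwise(model: GibbsExcessNet, arrays: TrainingArrays) -> pd.DataFrame:
    """Per-system mean absolute error of ln gamma over all available labels.

    Every system counts equally regardless of its number of data points.
    Columns: system, n_points, mae.
    """
    ln1, ln2 = model.ln_gamma(arrays.E1, arrays.E2, arrays.T, arrays.x1)
    m1, m2 = np.isfinite(arrays.y1), np.isfinite(arrays.y2)
    err1 = np.where(m1, np.abs(ln1 - np.where(m1, arrays.y1, 0.0)), 0.0)
    err2 = np.where(m2, np.abs(ln2 - np.where(m2, arrays.y2, 0.0)), 0.0)

    by_system: dict = {}
    for i, key in enumerate(arrays.keys):
        agg = by_system.setdefault(key, [0.0, 0])
        agg[0] += err1[i] * m1[i] + err2[i] * m2[i]
        agg[1] += int(m1[i]) + int(m2[i])
    rows = [
        {"system": "|".join(k), "n_points": cnt, "mae": tot / cnt}
        for k, (tot, cnt) in sorted(by_system.items())
    ]
    return pd.DataFrame(rows)


def cumulative_fraction(maes, thresholds) -> np.ndarray:
    """Share of systems whose MAE is below each threshold."""
    maes = np.asarray(maes, dtype=float)
    return np.array([(maes < t).mean() for t in np.asarray(thresholds, dtype=float)])


def predict_records(model: GibbsExcessNet, cache: EmbeddingCache, smiles_1, smiles_2, T, x1_grid):
    """Convenience prediction over an x1 grid for one system; returns a
    DataFrame with x_1, ln_gamma_1, ln_gamma_2, gE_J_per_mol."""
    from .model import GAS_CONSTANT

    c1, c2 = cache.get(smiles_1), cache.get(smiles_2)
    x = np.asarray(x1_grid, dtype=float)
    e1 = np.tile(c1.embedding, (x.size, 1))
    e2 = np.tile(c2.embedding, (x.size, 1))
    g, g1, _ = model.ge_bar_derivatives(e1, e2, T, x)
    return pd.DataFrame(
        {
            "x_1": x,
            "ln_gamma_1": g + (1 - x) * g1,
            "ln_gamma_2": g - x * g1,
            "gE_J_per_mol": g * GAS_CONSTANT * float(T),
        }
    )
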