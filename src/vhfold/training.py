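"""Loss functions, the optimization loop, k-fold cross-validation and transfer retraining.

The total loss is the sum of (a) the mean squared displacement over included
atoms — equivalent to the squared RMSD in the shared reference frame — and
(b) an unnormalized sum over consecutive real residue pairs of
(d(CA_i, CA_{i+1}) - 3.8)^2, which pulls predicted chains toward ideal
peptide CA spacing. Padding rows are masked out of both terms; glycine CB
targets are gated by the CB mask.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import EncodedExample
from .model_core import CoordRegressionNet
from .nn import Adam

IDEAL_CA_SPACING = 3.8
_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 16
    max_epochs: int = 130
    transfer_max_epochs: int = 50
    checkpoint_metric: str = "val_loss"
    seed: int = 0
    patience: int | None = None
    ca_average: bool = False  # per-pair averaging of the CA term (default: printed sum form)

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class LossBreakdown:
    mse_term: float
    ca_term: float
    total: float


def _atom_masks(mask: np.ndarray, cb_mask: np.ndarray) -> np.ndarray:
    """(..., 140, 5) inclusion mask: backbone atoms by mask, CB by mask & cb_mask."""
    atom = np.repeat(mask[..., None], 5, axis=-1)
    atom[..., 4] = mask * cb_mask
    return atom


def loss_mse(y: np.ndarray, yhat: np.ndarray, mask: np.ndarray,
             cb_mask: np.ndarray) -> float:
    """Mean squared atom displacement over included atoms (squared RMSD)."""
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("target/prediction shape mismatch")
    atom = _atom_masks(np.asarray(mask, float), np.asarray(cb_mask, float))
    n_atoms = atom.sum()
    if n_atoms == 0:
        raise ValueError("empty mask")
    sq = ((yhat - y).reshape(*y.shape[:-1], 5, 3) ** 2).sum(-1)
    return float((sq * atom).sum() / n_atoms)


def loss_ca(yhat: np.ndarray, mask: np.ndarray, average: bool = False) -> float:
    """Sum over consecutive masked residue pairs of (d(CA_i, CA_{i+1}) - 3.8)^2.

    With ``average`` the sum is divided by the pair count (config flag;
    default keeps the unnormalized sum). For batches the per-example values
    are averaged.
    """
    yhat = np.asarray(yhat, float)
    mask = np.asarray(mask, float)
    if yhat.ndim == 2:
        yhat, mask = yhat[None], mask[None]
    ca = yhat[..., 3:6]
    pair_mask = mask[:, :-1] * mask[:, 1:]
    n_pairs = pair_mask.sum(axis=1)
    if np.any(n_pairs < 1):
        raise ValueError("need at least 2 masked residues per example")
    d = np.sqrt(((ca[:, 1:] - ca[:, :-1]) ** 2).sum(-1))
    per_example = (((d - IDEAL_CA_SPACING) ** 2) * pair_mask).sum(axis=1)
    if average:
        per_example = per_example / n_pairs
    return float(per_example.mean())


def loss_total(y: np.ndarray, yhat: np.ndarray, mask: np.ndarray,
               cb_mask: np.ndarray, ca_average: bool = False) -> LossBreakdown:
    mse = loss_mse(y, yhat, mask, cb_mask)
    ca = loss_ca(yhat, mask, average=ca_average)
    return LossBreakdown(mse, ca, mse + ca)


def _loss_and_grad(y, yhat, mask, cb_mask, ca_average: bool):
    """Batch loss breakdown plus analytic gradient w.r.t. the prediction."""
    b = y.shape[0]
    atom = _atom_masks(mask, cb_mask)
    n_atoms = atom.sum()
    diff = (yhat - y).reshape(b, -1, 5, 3)
    sq = (diff ** 2).sum(-1)
    mse = float((sq * atom).sum() / n_atoms)
    dmse = (2.0 * diff * atom[..., None] / n_atoms).reshape(yhat.shape)

    ca = yhat[..., 3:6]
    pair_mask = mask[:, :-1] * mask[:, 1:]
    n_pairs = pair_mask.sum(axis=1)
    vec = ca[:, :-1] - ca[:, 1:]
    d = np.sqrt((vec ** 2).sum(-1))
    dev = d - IDEAL_CA_SPACING
    weights = pair_mask / n_pairs[:, None] if ca_average else pair_mask
    per_example = ((dev ** 2) * weights).sum(axis=1)
    ca_term = float(per_example.mean())
    coef = (2.0 * dev / np.maximum(d, _EPS)) * weights / b
    gca = np.zeros_like(ca)
    gca[:, :-1] += coef[..., None] * vec
    gca[:, 1:] -= coef[..., None] * vec
    dout = dmse.copy()
    dout[..., 3:6] += gca
    return LossBreakdown(mse, ca_term, mse + ca_term), dout


def _stack(examples: list[EncodedExample]):
    x = np.stack([e.input for e in examples])
    y = np.stack([e.target for e in examples])
    mask = np.stack([e.mask for e in examples])
    cb = np.stack([e.cb_mask for e in examples])
    return x, y, mask, cb


def evaluate_loss(model: CoordRegressionNet, examples: list[EncodedExample],
                  ca_average: bool = False, batch_size: int = 32) -> LossBreakdown:
    """Dropout-off loss over a set of examples (atom-weighted across batches)."""
    mse_num = ca_sum = 0.0
    n_atoms = 0.0
    n_ex = 0
    for i in range(0, len(examples), batch_size):
        x, y, mask, cb = _stack(examples[i:i + batch_size])
        yhat = model.forward(x, training=False)
        atom = _atom_masks(mask, cb)
        sq = ((yhat - y).reshape(*y.shape[:-1], 5, 3) ** 2).sum(-1)
        mse_num += float((sq * atom).sum())
        n_atoms += atom.sum()
        ca_sum += loss_ca(yhat, mask, average=ca_average) * x.shape[0]
        n_ex += x.shape[0]
    mse = mse_num / n_atoms
    ca = ca_sum / n_ex
    return LossBreakdown(mse, ca, mse + ca)


class DivergenceError(RuntimeError):
    pass


def train(model: CoordRegressionNet, train_set: list[EncodedExample],
          validation_set: list[EncodedExample], config: TrainConfig,
          max_epochs: int | None = None) -> tuple[CoordRegressionNet, pd.DataFrame]:
    """Mini-batch Adam on the total loss with a best-validation checkpoint.

    The returned model carries the parameters of the epoch with minimal
    validation loss (dropout off). History holds per-epoch train/validation
    loss terms.
    """
    config.validate()
    if not train_set or not validation_set:
        raise ValueError("train and validation sets must be non-empty")
    epochs = config.max_epochs if max_epochs is None else max_epochs
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    # the starting state is a checkpoint candidate, so retraining can never
    # return a model worse (on validation) than its initialization
    best_val = evaluate_loss(model, validation_set, config.ca_average).total
    best_state = model.get_state()
    history: list[dict] = []
    since_best = 0

    for epoch in range(epochs):
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[start:start + config.batch_size]]
            x, y, mask, cb = _stack(batch)
            yhat = model.forward(x, training=True, rng=rng)
            breakdown, dout = _loss_and_grad(y, yhat, mask, cb, config.ca_average)
            if not np.isfinite(breakdown.total):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch} (mse={breakdown.mse_term}, "
                    f"ca={breakdown.ca_term}); try a lower learning rate")
            optimizer.zero_grad()
            model.backward(dout)
            optimizer.step()
            epoch_losses.append((breakdown.total, breakdown.mse_term, breakdown.ca_term))
        val = evaluate_loss(model, validation_set, config.ca_average)
        tr = np.mean(np.array(epoch_losses), axis=0)
        history.append({"epoch": epoch, "train_loss": tr[0], "train_mse": tr[1],
                        "train_ca": tr[2], "val_loss": val.total,
                        "val_mse": val.mse_term, "val_ca": val.ca_term})
        if val.total < best_val:
            best_val = val.total
            best_state = model.get_state()
            since_best = 0
        else:
            since_best += 1
            if config.patience is not None and since_best > config.patience:
                break
    model.set_state(best_state)
    return model, pd.DataFrame(history)


def transfer_retrain(pretrained: CoordRegressionNet, train_set: list[EncodedExample],
                     validation_set: list[EncodedExample], config: TrainConfig,
                     max_epochs: int | None = None
                     ) -> tuple[CoordRegressionNet, pd.DataFrame]:
    """Continue optimization from pretrained parameters on a new dataset.

    Same contract as :func:`train`; epochs default to the transfer cap (50).
    """
    model = copy.deepcopy(pretrained)
    epochs = config.transfer_max_epochs if max_epochs is None else max_epochs
    epochs = min(epochs, config.transfer_max_epochs)
    return train(model, train_set, validation_set, config, max_epochs=epochs)


def kfold_cv(examples: list[EncodedExample], model_factory, config: TrainConfig,
             k: int = 5, fold_spec: dict | None = None,
             max_epochs: int | None = None) -> pd.DataFrame:
    """k-fold cross-validation; reports per-fold validation loss/RMSD and mean/sd.

    ``fold_spec`` may carry {"labels": {id: stratum}, "counts": {stratum: n}}
    to fix the per-stratum composition of each validation fold (e.g. 100 mAb
    + 50 Nb per fold). ``model_factory(fold_index)`` must return a fresh model.
    """
    n = len(examples)
    if k < 2 or k > n:
        raise ValueError("k must be in [2, n]")
    rng = np.random.default_rng(config.seed)
    if fold_spec:
        labels = fold_spec["labels"]
        counts = fold_spec["counts"]
        by_stratum: dict[str, list[int]] = {}
        for i, ex in enumerate(examples):
            by_stratum.setdefault(labels[ex.example_id], []).append(i)
        folds: list[list[int]] = [[] for _ in range(k)]
        for stratum, want in counts.items():
            pool = by_stratum.get(stratum, [])
            if want * k > len(pool):
                raise ValueError(f"fold_spec infeasible: stratum {stratum!r} has "
                                 f"{len(pool)} examples, needs {want * k}")
            pool = list(rng.permutation(pool))
            for f in range(k):
                folds[f].extend(pool[f * want:(f + 1) * want])
    else:
        order = list(rng.permutation(n))
        folds = [order[f::k] for f in range(k)]

    rows = []
    for f, val_idx in enumerate(folds):
        val_idx_set = set(val_idx)
        train_set = [examples[i] for i in range(n) if i not in val_idx_set]
        val_set = [examples[i] for i in val_idx]
        model = model_factory(f)
        model, _ = train(model, train_set, val_set, config, max_epochs=max_epochs)
        val = evaluate_loss(model, val_set, config.ca_average)
        rmsds = []
        for ex in val_set:
            x = ex.input
            yhat = model.forward(x, training=False)
            atom = _atom_masks(ex.mask, ex.cb_mask)
            sq = ((yhat - ex.target).reshape(-1, 5, 3) ** 2).sum(-1)
            rmsds.append(float(np.sqrt((sq * atom).sum() / atom.sum())))
        rows.append({"fold": f, "n_val": len(val_set), "val_loss": val.total,
                     "val_rmsd_mean": float(np.mean(rmsds)),
                     "val_rmsd_sd": float(np.std(rmsds, ddof=1)) if len(rmsds) > 1 else 0.0})
    report = pd.DataFrame(rows)
    summary = {"fold": "mean±sd", "n_val": report["n_val"].sum(),
               "val_loss": report["val_loss"].mean(),
               "val_rmsd_mean": report["val_rmsd_mean"].mean(),
               "val_rmsd_sd": report["val_rmsd_mean"].std(ddof=1)}
    return pd.concat([report, pd.DataFrame([summary])], ignore_index=True)
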