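"""Loss construction, AdamW optimization with plateau LR decay, and MAE
evaluation for energy/force models.

Training minimizes ``w_E * MSE(energy) + w_F * MSE(forces)`` (defaults
0.05 / 0.95).  Forces enter the loss as exact negative energy gradients, so
each parameter-gradient evaluation differentiates through the force
computation (second-order reverse mode via autograd).  Frames are collated
into one block-diagonal graph so a full batch costs a single forward/backward.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import autograd.numpy as anp
import numpy as np
from autograd import grad, value_and_grad
from autograd.misc.flatten import flatten

from .network import ModelConfig, _forward_atomwise, predict_energy_forces
from .structures_io import AtomicConfiguration, DatasetSplit, build_neighbor_list

__all__ = [
    "TrainConfig",
    "TrainReport",
    "combined_loss",
    "collate",
    "batch_loss",
    "fit",
    "evaluate_mae",
]


@dataclass
class TrainConfig:
    loss_energy_weight: float = 0.05
    loss_force_weight: float = 0.95
    batch_size: int = 0  # 0 = full batch
    lr: float = 1e-4
    lr_decay_factor: float = 0.8
    plateau_patience_epochs: int = 30
    plateau_min_improvement: float = 1e-7
    early_stop_patience: int = 90  # 3x plateau patience by default
    max_epochs: int = 1000
    seed: int = 0
    weight_decay: float = 0.0
    grad_clip: float = 0.0  # 0 = off; else global-norm clip
    precision: str = "float64"

    def __post_init__(self) -> None:
        if self.loss_energy_weight < 0 or self.loss_force_weight < 0:
            raise ValueError("loss weights must be >= 0")
        if self.loss_energy_weight + self.loss_force_weight <= 0:
            raise ValueError("loss weights must not both be zero")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ValueError("lr_decay_factor must be in (0, 1)")


@dataclass
class TrainReport:
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf
    stopped_reason: str = ""
    energy_mae: float | None = None
    force_mae: float | None = None

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.history:
                fh.write(json.dumps(row) + "\n")


def combined_loss(pred_E, true_E, pred_F, true_F, cfg: TrainConfig):
    """w_E * MSE(E) + w_F * MSE(F); force MSE averaged over all 3N components."""
    pred_E, true_E = anp.ravel(pred_E), anp.ravel(true_E)
    if pred_E.shape != true_E.shape:
        raise ValueError("energy shapes disagree")
    if anp.shape(pred_F) != anp.shape(true_F):
        raise ValueError("force shapes disagree")
    loss = cfg.loss_energy_weight * anp.mean((pred_E - true_E) ** 2)
    loss = loss + cfg.loss_force_weight * anp.mean((pred_F - true_F) ** 2)
    return loss


@dataclass
class _Batch:
    z: np.ndarray
    R0: np.ndarray
    ei: np.ndarray
    ej: np.ndarray
    scat: np.ndarray
    frame_mat: np.ndarray  # (B, N_total) 0/1 per-frame reduction
    E_true: np.ndarray
    F_true: np.ndarray


def collate(configs: Sequence[AtomicConfiguration], mcfg: ModelConfig) -> _Batch:
    """Merge labeled frames into one block-diagonal graph.  Neighbor lists are
    built once per frame from its (fixed) geometry."""
    z_parts, r_parts, ei_parts, ej_parts, e_parts, f_parts = [], [], [], [], [], []
    frame_ids = []
    offset = 0
    for b, cfg in enumerate(configs):
        if cfg.energy is None or cfg.forces is None:
            raise ValueError("training frames need energy and force labels")
        nlist = build_neighbor_list(cfg, mcfg.cutoff)
        z_parts.append(cfg.atomic_numbers)
        r_parts.append(cfg.coordinates)
        ei_parts.append(nlist.source + offset)
        ej_parts.append(nlist.target + offset)
        e_parts.append(cfg.energy)
        f_parts.append(cfg.forces)
        frame_ids.append(np.full(cfg.n_atoms, b))
        offset += cfg.n_atoms
    z = np.concatenate(z_parts)
    ei = np.concatenate(ei_parts)
    ej = np.concatenate(ej_parts)
    scat = np.zeros((offset, ei.size))
    scat[ei, np.arange(ei.size)] = 1.0
    frame_ids = np.concatenate(frame_ids)
    frame_mat = np.zeros((len(configs), offset))
    frame_mat[frame_ids, np.arange(offset)] = 1.0
    return _Batch(
        z=z,
        R0=np.concatenate(r_parts),
        ei=ei,
        ej=ej,
        scat=scat,
        frame_mat=frame_mat,
        E_true=np.array(e_parts),
        F_true=np.concatenate(f_parts),
    )


def batch_loss(params, batch: _Batch, mcfg: ModelConfig, tcfg: TrainConfig):
    """Differentiable (w.r.t. params) combined loss on a collated batch."""

    def frame_energies(R):
        h, _ = _forward_atomwise(
            params, mcfg, batch.z, R, batch.ei, batch.ej, batch.scat
        )
        return batch.frame_mat @ h

    E_pred = frame_energies(batch.R0)
    F_pred = -grad(lambda R: anp.sum(frame_energies(R)))(batch.R0)
    return combined_loss(E_pred, batch.E_true, F_pred, batch.F_true, tcfg)


def fit(
    mcfg: ModelConfig,
    params: dict,
    configs: Sequence[AtomicConfiguration],
    split: DatasetSplit,
    tcfg: TrainConfig,
    verbose: bool = False,
):
    """Train with AdamW; plateau-triggered LR decay and early stopping on the
    validation loss.  Returns (TrainReport, best-validation params)."""
    if not split.train or not split.validation:
        raise ValueError("train and validation splits must be non-empty")
    train_cfgs = [configs[i] for i in split.train]
    val_cfgs = [configs[i] for i in split.validation]
    if tcfg.batch_size and tcfg.batch_size < len(train_cfgs):
        chunks = [
            collate(train_cfgs[k : k + tcfg.batch_size], mcfg)
            for k in range(0, len(train_cfgs), tcfg.batch_size)
        ]
    else:
        chunks = [collate(train_cfgs, mcfg)]
    val_batch = collate(val_cfgs, mcfg)

    flat, unflatten = flatten(params)
    m = np.zeros_like(flat)
    s = np.zeros_like(flat)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = tcfg.lr
    step = 0

    report = TrainReport()
    best_params = copy.deepcopy(params)
    since_improve = 0

    for epoch in range(tcfg.max_epochs):
        train_loss = 0.0
        for batch in chunks:
            loss_val, g = value_and_grad(
                lambda p: batch_loss(p, batch, mcfg, tcfg)
            )(unflatten(flat))
            g_flat, _ = flatten(g)
            if tcfg.grad_clip > 0:
                gnorm = np.linalg.norm(g_flat)
                if gnorm > tcfg.grad_clip:
                    g_flat = g_flat * (tcfg.grad_clip / gnorm)
            step += 1
            m = beta1 * m + (1 - beta1) * g_flat
            s = beta2 * s + (1 - beta2) * g_flat**2
            mhat = m / (1 - beta1**step)
            shat = s / (1 - beta2**step)
            flat = flat - lr * (
                mhat / (np.sqrt(shat) + eps) + tcfg.weight_decay * flat
            )
            train_loss += float(loss_val)
        train_loss /= len(chunks)
        params_now = unflatten(flat)
        val_loss = float(batch_loss(params_now, val_batch, mcfg, tcfg))
        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite loss at epoch {epoch}")
        report.history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": train_loss,
                "val_loss": val_loss,
            }
        )
        if verbose:
            print(f"epoch {epoch:4d} lr {lr:.3e} train {train_loss:.6e} val {val_loss:.6e}")
        if val_loss < report.best_val_loss - tcfg.plateau_min_improvement:
            report.best_val_loss = val_loss
            report.best_epoch = epoch
            best_params = copy.deepcopy(params_now)
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= tcfg.early_stop_patience:
                report.stopped_reason = "early_stop"
                break
            if since_improve % tcfg.plateau_patience_epochs == 0:
                lr *= tcfg.lr_decay_factor
    else:
        report.stopped_reason = "max_epochs"
    return report, best_params


def evaluate_mae(params, mcfg: ModelConfig, configs: Sequence[AtomicConfiguration]):
    """(energy MAE in kcal/mol, force MAE over all components in kcal/mol/A)."""
    e_err, f_err = [], []
    for cfg in configs:
        E, F = predict_energy_forces(params, mcfg, cfg)
        if cfg.energy is not None:
            e_err.append(abs(E - cfg.energy))
        if cfg.forces is not None:
            f_err.append(np.abs(F - cfg.forces).ravel())
    energy_mae = float(np.mean(e_err)) if e_err else np.nan
    force_mae = float(np.mean(np.concatenate(f_err))) if f_err else np.nan
    return energy_mae, force_mae


def plateau_lr_sequence(lr0: float, factor: float, n_decays: int) -> list[float]:
    """The LR values visited after successive plateau events."""
    out = [lr0]
    for _ in range(n_decays):
        out.append(out[-1] * factor)
    return out
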