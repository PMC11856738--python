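"""Training schedule, inference and the end-to-end evaluation harness.

The schedule follows the published recipe: a fixed number of epochs of a
fixed number of SGD iterations (defaults 1000 x 250), Nesterov momentum
0.99, and a poly learning-rate policy (1 - epoch/epoch_max)^0.9 applied
per epoch. Deep supervision uses the decoder heads above the two
lowest-resolution network stages, with per-scale weights halving as the
resolution halves, normalised to sum to one.

Everything is driven by a single seed: phantom sampling, parameter
initialisation and batch sampling, so a run is reproducible on one device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import losses as L
from .data import Volume, make_slices_2d, resample, restore_to_grid, znorm
from .metrics import LabelMask, MetricReport, case_metrics
from .model import MCMUNet, NetworkConfig
from .nn import SGD, Tensor


@dataclass
class TrainConfig:
    """Optimisation schedule and loss settings."""

    epochs: int = 1000
    iters_per_epoch: int = 250
    batch_2d: int = 12
    batch_3d: int = 2
    base_lr: float = 0.01
    momentum: float = 0.99
    poly_power: float = 0.9
    weight_decay: float = 0.0
    dice_weight: float = 1.0
    ce_weight: float = 1.0
    dice_eps: float = L.DICE_EPS
    slice_size: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.momentum < 1.0:
            raise ValueError("momentum must be in (0, 1)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def scaled_preset(seed: int = 0) -> tuple[NetworkConfig, TrainConfig]:
    """A reduced configuration sized for desk-scale CPU experiments:
    4 resolution stages, base 16 channels, 64x64 slices, a 16-entry bank,
    20 epochs of 50 iterations at batch 4."""
    net = NetworkConfig(n_stages=4, base_channels=16, max_channels=128,
                        n_cm_modules=2, bank_capacity=16, seed=seed)
    tr = TrainConfig(epochs=20, iters_per_epoch=50, batch_2d=4,
                     slice_size=64, seed=seed)
    return net, tr


def poly_lr(epoch: int, cfg: TrainConfig) -> float:
    """Poly learning-rate multiplier (1 - epoch/epoch_max)^power."""
    if not 0 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    return float((1.0 - epoch / cfg.epochs) ** cfg.poly_power)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def build_slice_dataset(cases, slice_size: int, target_spacing=None):
    """Preprocess (resample -> Z-score -> slice) a list of
    (case_id, Volume, LabelMask) into stacked 2-D training arrays."""
    xs, ys = [], []
    for _, vol, msk in cases:
        mvol = Volume(msk.grid, msk.spacing)
        if target_spacing is not None and not np.allclose(vol.spacing, target_spacing):
            vol = resample(vol, target_spacing)
            mvol = resample(mvol, target_spacing, is_mask=True)
        vol = znorm(vol)
        for img, m in make_slices_2d(vol, mvol, size=slice_size):
            xs.append(img)
            ys.append(m)
    if not xs:
        raise ValueError("empty dataset: no slices to train on")
    x = np.stack(xs).astype(np.float32)[:, None]      # (M, 1, S, S)
    y = np.stack(ys).astype(np.int64)                 # (M, S, S)
    return x, y


def _downsample_labels(y: np.ndarray, factor: int) -> np.ndarray:
    return y if factor == 1 else y[:, ::factor, ::factor]


def _flatten_probs(p: Tensor) -> Tensor:
    n, k, h, w = p.shape
    return p.reshape(n, k, h * w).swapaxes(1, 2)      # (N, HW, K)


def _scale_loss_pairs(probs: list[Tensor], y: np.ndarray, n_stages: int):
    """(prediction, one-hot target) pairs for the deep-supervision scales:
    every decoder head above the two lowest-resolution network stages."""
    n_active = max(1, n_stages - 2)
    pairs = []
    for s in range(n_active):
        ys = _downsample_labels(y, 2**s)
        v = L.one_hot(ys.reshape(ys.shape[0], -1), probs[s].shape[1])
        pairs.append((_flatten_probs(probs[s]), v))
    return pairs


def _compound_loss(pairs, cfg: TrainConfig) -> Tensor:
    weights = L.halving_weights(len(pairs))
    out = None
    for w, (u, v) in zip(weights, pairs):
        term = (L.dice_loss(u, v, eps=cfg.dice_eps) * cfg.dice_weight
                + L.cross_entropy(u, v) * cfg.ce_weight) * float(w)
        out = term if out is None else out + term
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: MCMUNet
    log: pd.DataFrame
    net_cfg: NetworkConfig
    train_cfg: TrainConfig

    def save(self, path) -> None:
        save_checkpoint(path, self.model, self.net_cfg, self.train_cfg)


def train(net_cfg: NetworkConfig, train_cfg: TrainConfig, dataset,
          log_path=None, progress: bool = False) -> TrainResult:
    """Run the full schedule on a dataset dict with 'train' (and optionally
    'val') lists of (case_id, Volume, LabelMask).

    Logs per-epoch mean loss, learning rate and (if a validation split is
    present) mean validation DSC of the main head.
    """
    if not dataset.get("train"):
        raise ValueError("dataset has no training cases")
    x, y = build_slice_dataset(dataset["train"], train_cfg.slice_size)
    model = MCMUNet(net_cfg)
    opt = SGD(model.parameters(), lr=train_cfg.base_lr,
              momentum=train_cfg.momentum, nesterov=True,
              weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed)
    m = x.shape[0]
    rows = []
    for epoch in range(train_cfg.epochs):
        opt.lr = train_cfg.base_lr * poly_lr(epoch, train_cfg)
        epoch_losses = []
        for it in range(train_cfg.iters_per_epoch):
            idx = rng.integers(0, m, size=train_cfg.batch_2d)
            probs = model.forward(x[idx], train_mode=True)
            pairs = _scale_loss_pairs(probs, y[idx], net_cfg.n_stages)
            loss = _compound_loss(pairs, train_cfg)
            val = float(loss.data)
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} iteration {it}")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(val)
        row = {"epoch": epoch, "lr": opt.lr, "loss": float(np.mean(epoch_losses))}
        if dataset.get("val"):
            dscs = [case_metrics(predict_volume(model, vol, train_cfg),
                                 msk)["dsc_pct"]
                    for _, vol, msk in dataset["val"]]
            row["val_dsc"] = float(np.mean(dscs))
        rows.append(row)
        if progress:
            print(f"epoch {epoch:4d}  lr {row['lr']:.5f}  loss {row['loss']:+.4f}"
                  + (f"  val DSC {row.get('val_dsc', float('nan')):.2f}%"
                     if "val_dsc" in row else ""))
    log = pd.DataFrame(rows)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    return TrainResult(model=model, log=log, net_cfg=net_cfg, train_cfg=train_cfg)


# ---------------------------------------------------------------------------
# Inference and evaluation
# ---------------------------------------------------------------------------

def predict_volume(model: MCMUNet, vol: Volume, train_cfg: TrainConfig,
                   target_spacing=None, batch: int = 8) -> LabelMask:
    """Segment a volume: preprocess, run the main head slice-wise in eval
    mode (bank frozen), argmax, and restore the mask to the input grid."""
    original_shape = vol.shape
    original_spacing = vol.spacing
    work = vol
    resampled = (target_spacing is not None
                 and not np.allclose(vol.spacing, target_spacing))
    if resampled:
        work = resample(vol, target_spacing)
    work = znorm(work)
    slices = [img for img, _ in make_slices_2d(work, None, size=train_cfg.slice_size)]
    x = np.stack(slices).astype(np.float32)[:, None]
    preds = []
    for i in range(0, x.shape[0], batch):
        probs = model.forward(x[i:i + batch], train_mode=False)
        preds.append(np.argmax(probs[0].data, axis=1).astype(np.uint8))
    stack = np.concatenate(preds).transpose(1, 2, 0)   # (S, S, K)
    grid = restore_to_grid(stack, work.shape, train_cfg.slice_size)
    if resampled:
        factors = np.array(original_shape) / np.array(grid.shape)
        from scipy import ndimage
        grid = np.rint(ndimage.zoom(grid.astype(np.float32), factors,
                                    order=0, mode="nearest")).astype(np.uint8)
        if grid.shape != tuple(original_shape):
            raise RuntimeError("geometry mismatch restoring prediction")
    return LabelMask(grid, original_spacing)


def evaluate_in_memory(model: MCMUNet, cases, train_cfg: TrainConfig,
                       target_spacing=None) -> MetricReport:
    rows = []
    for case_id, vol, msk in cases:
        pred = predict_volume(model, vol, train_cfg, target_spacing)
        rows.append({"case_id": case_id, **case_metrics(pred, msk)})
    return MetricReport(pd.DataFrame(rows, columns=MetricReport.COLUMNS))


def ablation_run(dataset, net_cfg: NetworkConfig, train_cfg: TrainConfig,
                 eval_split: str = "val") -> pd.DataFrame:
    """Train and evaluate the four ablation configurations (neither / CM /
    MB / both) under identical seeds; one aggregate row per configuration."""
    rows = []
    for use_cm, use_mb in [(False, False), (True, False), (False, True), (True, True)]:
        cfg = NetworkConfig(**{**net_cfg.to_dict(), "use_cm": use_cm, "use_mb": use_mb})
        result = train(cfg, train_cfg, dataset)
        report = evaluate_in_memory(result.model, dataset[eval_split], train_cfg)
        rows.append({"use_cm": use_cm, "use_mb": use_mb,
                     **report.aggregate.to_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Checkpoints and config files
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: MCMUNet, net_cfg: NetworkConfig,
                    train_cfg: TrainConfig) -> None:
    """Serialise parameters, bank contents and both configs to one .npz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {f"param::{k}": v for k, v in model.state_dict().items()}
    if model.bank is not None and len(model.bank):
        payload["bank::entries"] = np.stack(list(model.bank.entries))
    payload["meta::config"] = np.array(json.dumps(
        {"network": net_cfg.to_dict(), "training": train_cfg.to_dict()}))
    np.savez_compressed(path, **payload)


def load_checkpoint(path) -> tuple[MCMUNet, NetworkConfig, TrainConfig]:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta::config"]))
        net_cfg = NetworkConfig(**meta["network"])
        train_cfg = TrainConfig(**meta["training"])
        model = MCMUNet(net_cfg)
        model.load_state_dict(
            {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")})
        if "bank::entries" in z.files and model.bank is not None:
            for e in z["bank::entries"]:
                model.bank.push(e)
    return model, net_cfg, train_cfg


def load_config(path) -> tuple[NetworkConfig, TrainConfig]:
    """Read a YAML config with optional 'network' and 'training' sections."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return (NetworkConfig(**raw.get("network", {})),
            TrainConfig(**raw.get("training", {})))


def save_config(path, net_cfg: NetworkConfig, train_cfg: TrainConfig) -> None:
    with open(path, "w") as f:
        yaml.safe_dump({"network": net_cfg.to_dict(),
                        "training": train_cfg.to_dict()}, f, sort_keys=False)
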