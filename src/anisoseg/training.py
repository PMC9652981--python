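"""Training protocol: Adam + polynomial LR decay, random-crop training,
GTV-centered validation, and best-checkpoint selection on validation DSC.

Each epoch draws one random crop per training case (augmented), optimizes
the summed Dice + cross-entropy loss, then evaluates the current weights
on deterministic GTV-centered validation crops.  The model is checkpointed
only when the mean validation DSC strictly exceeds every previous epoch's
value.  Validation crops are deliberately easier than training crops
(they are centered on the target), which is why validation curves typically
sit above training curves here.
"""

from __future__ import annotations

import csv
import json
import shutil
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, TrainingError
from .metrics import dsc, evaluate_cases, total_loss
from .models import NetworkConfig, SegNetwork, build_network, predict_volume
from .nd.optim import Adam
from .nd.tensor import Tensor
from .phantom import PhantomCase
from .preprocess import (AugmentConfig, augment, center_crop_on_gtv, normalize,
                         random_crop, window_ct)
from .volume import Mask, Volume

Triple = Tuple[int, int, int]


@dataclass
class TrainConfig:
    batch_size: int = 4
    lr0: float = 1e-3
    weight_decay: float = 1e-4
    poly_power: float = 0.9
    epochs: int = 500
    patch: Triple = (32, 256, 256)
    seed: int = 0
    crops_per_case: int = 1
    augment: Optional[AugmentConfig] = field(default_factory=AugmentConfig)
    decoupled_weight_decay: bool = False

    def validate(self) -> None:
        if self.lr0 <= 0:
            raise ConfigError("lr0 must be positive")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.batch_size < 1 or self.crops_per_case < 1:
            raise ConfigError("batch_size and crops_per_case must be >= 1")


@dataclass
class EpochRow:
    epoch: int
    lr: float
    train_loss: float
    train_dsc: float
    val_loss: float
    val_dsc: float


@dataclass
class TrainHistory:
    rows: List[EpochRow] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dsc: float = -np.inf
    checkpoint_path: Optional[str] = None

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "lr", "train_loss", "train_dsc",
                             "val_loss", "val_dsc"])
            for r in self.rows:
                writer.writerow([r.epoch, r.lr, r.train_loss, r.train_dsc,
                                 r.val_loss, r.val_dsc])


def poly_lr(epoch: int, cfg: TrainConfig) -> float:
    """Polynomial decay: ``lr0 * (1 - epoch/epochs) ** power``."""
    if not 0 <= epoch <= cfg.epochs:
        raise ConfigError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    return cfg.lr0 * (1.0 - epoch / cfg.epochs) ** cfg.poly_power


class CheckpointTracker:
    """Persists the model only on strict validation-DSC improvement."""

    def __init__(self, out_dir: Optional[str | Path] = None):
        self.out_dir = Path(out_dir) if out_dir is not None else None
        self.best_epoch = -1
        self.best_val_dsc = -np.inf
        self.best_state: Optional[Dict[str, np.ndarray]] = None
        self.path: Optional[Path] = None

    def update(self, epoch: int, val_dsc: float, net: SegNetwork) -> bool:
        if val_dsc <= self.best_val_dsc:
            return False
        self.best_val_dsc = val_dsc
        self.best_epoch = epoch
        state = {k: v.copy() for k, v in net.state_dict().items()}
        self.best_state = state
        if self.out_dir is not None:
            self.out_dir.mkdir(parents=True, exist_ok=True)
            self.path = self.out_dir / "best_model.npz"
            np.savez(self.path, **state)
            sidecar = {"epoch": epoch, "val_dsc": val_dsc,
                       "network": _config_to_json(net.cfg)}
            (self.out_dir / "best_model.json").write_text(json.dumps(sidecar, indent=2))
        return True


def _config_to_json(cfg: NetworkConfig) -> dict:
    d = asdict(cfg)
    return d


def load_checkpoint(path: str | Path, net: SegNetwork) -> None:
    state = dict(np.load(path))
    net.load_state_dict(state)


def prepare_case(case: PhantomCase) -> Tuple[Volume, Mask]:
    """Window and normalize a raw-HU phantom into network input domain."""
    return normalize(window_ct(case.volume)), case.mask


def _as_pairs(cases: Sequence) -> List[Tuple[Volume, Mask]]:
    pairs = []
    for c in cases:
        if isinstance(c, PhantomCase):
            pairs.append(prepare_case(c))
        else:
            pairs.append(tuple(c))
    return pairs


def _batch_tensors(patches: List[Tuple[Volume, Mask]]):
    x = np.stack([p[0].data for p in patches])[:, None]
    y = np.stack([p[1].data for p in patches])
    return Tensor(x), y


def _hard_dsc(probs: np.ndarray, target: np.ndarray) -> float:
    """Mean DSC of argmax predictions over a batch (0 where pred misses)."""
    pred = (probs[:, 1] > probs[:, 0])
    vals = []
    for p, t in zip(pred, target):
        if t.sum() == 0 and p.sum() == 0:
            vals.append(1.0)
        elif t.sum() == 0 or p.sum() == 0:
            vals.append(0.0)
        else:
            vals.append(dsc(p.astype(np.uint8), t))
    return float(np.mean(vals))


def validate(net: SegNetwork, val_cases: Sequence, patch: Triple) -> Tuple[float, float]:
    """Mean validation DSC (hardened predictions) and loss on GTV-centered crops.

    Runs in eval mode (frozen normalization statistics); deterministic for
    fixed weights.
    """
    pairs = _as_pairs(val_cases)
    net.eval()
    dscs, losses = [], []
    for vol, msk in pairs:
        v, m = center_crop_on_gtv(vol, msk, patch)
        x, y = _batch_tensors([(v, m)])
        probs = net(x)
        losses.append(total_loss(probs, y).item())
        dscs.append(_hard_dsc(probs.data, y))
    return float(np.mean(dscs)), float(np.mean(losses))


def train(net: SegNetwork, train_cases: Sequence, val_cases: Sequence,
          cfg: TrainConfig, out_dir: Optional[str | Path] = None) -> TrainHistory:
    """Run the full protocol and return the per-epoch history."""
    cfg.validate()
    if not train_cases or not val_cases:
        raise ConfigError("train and validation case lists must be nonempty")
    train_pairs = _as_pairs(train_cases)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.lr0, weight_decay=cfg.weight_decay,
               decoupled=cfg.decoupled_weight_decay)
    tracker = CheckpointTracker(out_dir)
    history = TrainHistory()

    for epoch in range(cfg.epochs):
        lr = poly_lr(epoch, cfg)
        opt.lr = lr
        net.train()
        order = rng.permutation(len(train_pairs) * cfg.crops_per_case)
        epoch_losses, epoch_dscs = [], []
        for b0 in range(0, len(order), cfg.batch_size):
            idxs = order[b0:b0 + cfg.batch_size]
            patches = []
            for i in idxs:
                vol, msk = train_pairs[i % len(train_pairs)]
                crop_seed = int(rng.integers(2 ** 31))
                v, m = random_crop(vol, msk, cfg.patch, seed=crop_seed)
                if cfg.augment is not None:
                    v, m = augment(v, m, cfg.augment, seed=int(rng.integers(2 ** 31)))
                patches.append((v, m))
            x, y = _batch_tensors(patches)
            probs = net(x)
            loss = total_loss(probs, y)
            if not np.isfinite(loss.item()):
                raise TrainingError(f"non-finite loss at epoch {epoch}, "
                                    f"batch {b0 // cfg.batch_size}")
            net.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            epoch_dscs.append(_hard_dsc(probs.data, y))
            del probs, loss
        val_dsc, val_loss = validate(net, val_cases, cfg.patch)
        history.rows.append(EpochRow(epoch, lr, float(np.mean(epoch_losses)),
                                     float(np.mean(epoch_dscs)), val_loss, val_dsc))
        tracker.update(epoch, val_dsc, net)

    history.best_epoch = tracker.best_epoch
    history.best_val_dsc = tracker.best_val_dsc
    history.checkpoint_path = str(tracker.path) if tracker.path else None
    if out_dir is not None:
        history.to_csv(Path(out_dir) / "history.csv")
        plot_history(history, Path(out_dir) / "curves.png")
    # restore the best weights so the returned network is the selected model
    if tracker.best_state is not None:
        net.load_state_dict(tracker.best_state)
    return history


def plot_history(history: TrainHistory, path: str | Path) -> None:
    """Four panels: train loss, train DSC, val loss, val DSC per epoch."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    epochs = [r.epoch for r in history.rows]
    panels = [("train_loss", [r.train_loss for r in history.rows]),
              ("train_dsc", [r.train_dsc for r in history.rows]),
              ("val_loss", [r.val_loss for r in history.rows]),
              ("val_dsc", [r.val_dsc for r in history.rows])]
    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    for ax, (name, values) in zip(axes.ravel(), panels):
        ax.plot(epochs, values)
        ax.set_xlabel("epoch")
        ax.set_title(name)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_comparison(variants: Sequence[str], train_cases: Sequence,
                   val_cases: Sequence, net_cfg: NetworkConfig,
                   train_cfg: TrainConfig,
                   out_csv: Optional[str | Path] = None) -> List[dict]:
    """Train each variant on identical data/seed; evaluate full volumes.

    Returns one row per variant with mean +/- sd whole-volume DSC and HD95
    over the validation cases, using sliding-window inference on the
    best-checkpoint weights.
    """
    rows = []
    for variant in variants:
        cfg_v = replace(net_cfg, variant=variant)
        net = build_network(cfg_v, seed=train_cfg.seed)
        train(net, train_cases, val_cases, train_cfg)
        preds, refs, ids = [], [], []
        for case in val_cases:
            vol, msk = prepare_case(case) if isinstance(case, PhantomCase) else case
            preds.append(predict_volume(net, vol))
            refs.append(msk)
            ids.append(getattr(case, "case_id", f"case_{len(ids):03d}"))
        summary = evaluate_cases(preds, refs, ids)
        rows.append({"variant": variant, "n_parameters": net.n_parameters(),
                     "dsc_mean": summary.dsc_mean, "dsc_sd": summary.dsc_sd,
                     "hd95_mean": summary.hd95_mean, "hd95_sd": summary.hd95_sd})
    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    return rows
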