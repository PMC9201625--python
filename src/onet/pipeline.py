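"""Training, prediction and evaluation orchestration.

Segmentation trains with a weighted sum of pixel cross-entropy and soft
Dice loss (0.4 * CE + 0.6 * (1 - soft Dice) by default, the convention of
the U-shaped transformer segmentation lineage); classification trains with
plain cross-entropy.  Optimizers are SGD with momentum 0.9 / weight decay
1e-4 (default learning rate 5e-2, the multi-organ CT-style setting) or
AdamW at 1e-4 (the dermoscopy-style setting).  Everything is seeded: data
order,
augmentation and parameter initialisation derive from one integer, so a
rerun on the same machine reproduces the loss trace bit for bit.

Checkpoints are a ``.npz`` of parameter/buffer arrays plus a JSON sidecar
holding the architecture configuration.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import nn
from .metrics import confusion_counts, dice, evaluate_case
from .model import ONet, ONetClassifier, ONetConfig, transfer_encoder_weights
from .nn import Tensor
from .synth import augment, load_dataset


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def soft_dice_loss(logits: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """1 - mean soft Dice over foreground classes.

    Soft Dice per class c: 2 sum(p_c * g_c) / (sum p_c + sum g_c), with
    p the softmax probabilities and g the one-hot reference.
    """
    n, k, h, w = logits.shape
    probs = nn.softmax(logits, axis=1)
    total = Tensor(0.0)
    for c in range(1, k):
        g = (np.asarray(target) == c).astype(float)
        pc = probs[:, c]
        inter = (pc * Tensor(g)).sum()
        denom = pc.sum() + Tensor(g.sum())
        total = total + (inter * 2.0 + eps) / (denom + eps)
    return 1.0 - total * (1.0 / max(k - 1, 1))


def seg_loss(logits: Tensor, target: np.ndarray,
             ce_weight: float = 0.4, dice_weight: float = 0.6) -> Tensor:
    """Weighted cross-entropy + soft-Dice segmentation loss."""
    if ce_weight == 0 and dice_weight == 0:
        raise ValueError("at least one loss weight must be non-zero")
    loss = Tensor(0.0)
    if ce_weight:
        loss = loss + ce_weight * nn.cross_entropy_logits(logits, target)
    if dice_weight:
        loss = loss + dice_weight * soft_dice_loss(logits, target)
    return loss


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    task: str = "segmentation"          # or "classification"
    data_dir: str | None = None
    out_dir: str = "runs/onet"
    input_size: int = 224
    batch_size: int = 24
    optimizer: str = "sgd"              # "sgd" | "adamw"
    lr: float = 5e-2
    momentum: float = 0.9
    weight_decay: float = 1e-4
    max_steps: int = 500
    eval_every: int = 25
    val_fraction: float = 0.2
    augment: bool = True
    ce_weight: float = 0.4
    dice_weight: float = 0.6
    seed: int = 0
    target_metric: float | None = None  # early stop when train metric reaches it
    init_from: str | None = None        # segmentation ckpt for encoder transfer

    def __post_init__(self):
        if self.task not in ("segmentation", "classification"):
            raise ValueError("task must be 'segmentation' or 'classification'")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.optimizer not in ("sgd", "adamw"):
            raise ValueError("optimizer must be 'sgd' or 'adamw'")


@dataclass
class TrainResult:
    history: pd.DataFrame
    checkpoint: Path | None
    final_metric: float
    steps_run: int


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: nn.Module, cfg: ONetConfig,
                    train_cfg: TrainConfig | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    if not path.suffix:
        path = path.with_suffix(".npz")
    sidecar = {"config": cfg.to_dict(),
               "task": ("classification" if isinstance(model, ONetClassifier)
                        else "segmentation")}
    if train_cfg is not None:
        sidecar["train_config"] = asdict(train_cfg)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_checkpoint(path) -> tuple[nn.Module, ONetConfig, dict]:
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = ONetConfig.from_dict(sidecar["config"])
    model = (ONetClassifier(cfg) if sidecar["task"] == "classification"
             else ONet(cfg))
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, cfg, sidecar


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def _to_model_input(images: np.ndarray, in_channels: int) -> np.ndarray:
    """uint8 (N,H,W[,3]) -> float (N,C,H,W) in [0,1]."""
    x = images.astype(np.float64) / 255.0
    if x.ndim == 3:
        x = x[:, None]
    else:
        x = x.transpose(0, 3, 1, 2)
    if x.shape[1] != in_channels:
        if in_channels == 1:
            x = x.mean(axis=1, keepdims=True)
        elif x.shape[1] == 1:
            x = np.repeat(x, in_channels, axis=1)
        else:
            raise ValueError(f"cannot map {x.shape[1]}-channel images to "
                             f"{in_channels} model channels")
    return x


def _split(n: int, val_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 80/20-style split by image index (tail is validation)."""
    n_val = int(round(n * val_fraction))
    idx = np.arange(n)
    return idx[:n - n_val], idx[n - n_val:] if n_val else idx[:0]


def _mean_foreground_dice(pred: np.ndarray, masks: np.ndarray, k: int) -> float:
    vals = []
    for p, g in zip(pred, masks):
        per = [dice(confusion_counts(p, g, c)) for c in range(1, k)]
        vals.append(np.mean(per))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _make_optimizer(model: nn.Module, cfg: TrainConfig) -> nn.Optimizer:
    if cfg.optimizer == "sgd":
        return nn.SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                      weight_decay=cfg.weight_decay)
    return nn.AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)


def train(model: nn.Module, cfg: TrainConfig, onet_cfg: ONetConfig,
          data: tuple[np.ndarray, np.ndarray] | None = None,
          verbose: bool = False) -> TrainResult:
    """Optimize ``model`` on (images, masks-or-labels).

    ``data`` defaults to ``cfg.data_dir`` (images/, masks/, labels.csv as
    produced by the synthetic generator).  Returns the metric history and
    the path of the best checkpoint (under ``cfg.out_dir``).
    """
    if data is None:
        if cfg.data_dir is None:
            raise ValueError("either data or cfg.data_dir is required")
        images, masks, labels = load_dataset(cfg.data_dir)
        targets = masks if cfg.task == "segmentation" else \
            labels["label"].to_numpy()
    else:
        images, targets = data
    if images is None or targets is None:
        raise ValueError("dataset lacks the targets needed for this task")

    x_all = _to_model_input(images, onet_cfg.in_channels)
    y_all = np.asarray(targets)
    rng = np.random.default_rng(cfg.seed)

    tr_idx, va_idx = _split(len(x_all), cfg.val_fraction)
    if len(tr_idx) == 0:
        raise ValueError("empty training split")

    opt = _make_optimizer(model, cfg)
    k = onet_cfg.num_classes
    rows = []
    best_metric = -np.inf
    ckpt_path = Path(cfg.out_dir) / "best.npz"
    step = 0
    model.train()
    t0 = time.time()

    def eval_metric(idx: np.ndarray) -> float:
        if len(idx) == 0:
            return float("nan")
        model.eval()
        with nn.no_grad():
            if cfg.task == "segmentation":
                pred = np.concatenate([
                    model(Tensor(x_all[i:i + 1])).argmax_masks() for i in idx])
                m = _mean_foreground_dice(pred, y_all[idx], k)
            else:
                pred = np.concatenate([
                    model(Tensor(x_all[i:i + 1])).argmax_labels() for i in idx])
                m = float((pred == y_all[idx]).mean())
        model.train()
        return m

    stop = False
    while step < cfg.max_steps and not stop:
        order = rng.permutation(tr_idx)
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            xb = x_all[batch]
            yb = y_all[batch]
            if cfg.augment and cfg.task == "segmentation":
                xb = xb.copy()
                yb = yb.copy()
                for j in range(len(batch)):
                    img = xb[j].transpose(1, 2, 0)
                    img, yb[j] = augment(img, yb[j], rng)
                    xb[j] = img.transpose(2, 0, 1)

            out = model(Tensor(xb))
            if cfg.task == "segmentation":
                loss = seg_loss(out.logits, yb, cfg.ce_weight, cfg.dice_weight)
            else:
                loss = nn.cross_entropy_logits(out.logits, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss {loss.data} at step {step}; aborting "
                    f"(lr={cfg.lr}, optimizer={cfg.optimizer})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            step += 1

            row = {"step": step, "loss": float(loss.data),
                   "elapsed_s": round(time.time() - t0, 2)}
            if step % cfg.eval_every == 0 or step == cfg.max_steps:
                row["train_metric"] = eval_metric(tr_idx)
                if len(va_idx):
                    row["val_metric"] = eval_metric(va_idx)
                monitored = row.get("val_metric", row["train_metric"])
                if monitored > best_metric:
                    best_metric = monitored
                    save_checkpoint(ckpt_path, model, onet_cfg, cfg)
                if verbose:
                    print(f"step {step}: loss {row['loss']:.4f} "
                          f"metric {row['train_metric']:.4f}")
                if (cfg.target_metric is not None
                        and row["train_metric"] >= cfg.target_metric):
                    stop = True
            rows.append(row)
            if step >= cfg.max_steps or stop:
                break

    history = pd.DataFrame(rows)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    history.to_csv(out_dir / "history.csv", index=False)
    if not ckpt_path.exists():
        save_checkpoint(ckpt_path, model, onet_cfg, cfg)
    final = eval_metric(tr_idx)
    return TrainResult(history, ckpt_path, final, step)


def train_classification_with_transfer(seg_checkpoint, cfg: TrainConfig,
                                       data=None, verbose=False) -> TrainResult:
    """Build a classifier from a segmentation checkpoint's encoder weights
    and fine-tune it."""
    seg_model, onet_cfg, _ = load_checkpoint(seg_checkpoint)
    nn.manual_seed(cfg.seed)
    cls = ONetClassifier(onet_cfg)
    transfer_encoder_weights(seg_model, cls)
    return train(cls, cfg, onet_cfg, data=data, verbose=verbose)


# ---------------------------------------------------------------------------
# prediction / evaluation
# ---------------------------------------------------------------------------

def predict(checkpoint, images: np.ndarray, out_dir=None,
            filenames: list[str] | None = None):
    """Argmax predictions from a checkpoint.

    Segmentation returns (N, H, W) uint8 index masks (inputs of any size are
    padded to the model's stride and predictions cropped back); classification
    returns a label vector.  With ``out_dir`` set, masks are written as index
    PNGs / labels as predictions.csv.
    """
    model, cfg, sidecar = load_checkpoint(checkpoint)
    model.eval()
    x = _to_model_input(np.asarray(images), cfg.in_channels)
    outs = []
    with nn.no_grad():
        for i in range(x.shape[0]):
            out = model(Tensor(x[i:i + 1]))
            outs.append(out.argmax_masks() if sidecar["task"] == "segmentation"
                        else out.argmax_labels())
    result = np.concatenate(outs)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        names = filenames or [f"img_{i:04d}.png" for i in range(len(result))]
        if sidecar["task"] == "segmentation":
            for mask, name in zip(result, names):
                Image.fromarray(mask.astype(np.uint8)).save(out_dir / name)
        else:
            pd.DataFrame({"filename": names, "label": result}).to_csv(
                out_dir / "predictions.csv", index=False)
    return result


def evaluate_directories(pred_dir, gt_dir, num_classes: int,
                         report_csv=None) -> pd.DataFrame:
    """Per-case, per-class metric report for two directories of index PNGs.

    Columns: case, class, dice, hd, iou, pre, recall, f1, pa.  A final
    'mean' row averages over all (case, class) entries with finite values.
    """
    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    names = sorted(p.name for p in gt_dir.glob("*.png"))
    if not names:
        raise FileNotFoundError(f"no reference masks in {gt_dir}")
    rows = []
    for name in names:
        pp = pred_dir / name
        if not pp.is_file():
            raise FileNotFoundError(f"missing prediction for case {name}")
        pred = np.asarray(Image.open(pp))
        gt = np.asarray(Image.open(gt_dir / name))
        res = evaluate_case(pred, gt, class_ids=list(range(1, num_classes)))
        for cid, m in res["per_class"].items():
            rows.append({"case": name, "class": cid, "dice": m["dice"],
                         "hd": m["hd"], "iou": m["iou"], "pre": m["pre"],
                         "recall": m["recall"], "f1": m["f1"], "pa": m["pa"]})
    df = pd.DataFrame(rows)
    mean_row = {"case": "mean", "class": -1}
    for col in ("dice", "hd", "iou", "pre", "recall", "f1", "pa"):
        vals = df[col].to_numpy(dtype=float)
        mean_row[col] = float(np.nanmean(vals)) if len(vals) else float("nan")
    df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    if report_csv is not None:
        Path(report_csv).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(report_csv, index=False)
    return df
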