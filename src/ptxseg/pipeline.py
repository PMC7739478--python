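"""Training loop, inference, pixel-count diagnosis and end-to-end evaluation.

Training follows the protocol: Adam (beta1 0.9, beta2 0.999) with weight
decay, random horizontal flips, at most ``max_epochs`` epochs with early
stopping on the validation-set lesion Dice (DSC1) and restoration of the
best weights (earliest epoch on ties).  Spatial weight maps are derived
per image from its ground-truth mask and flipped together with it.

Diagnosis applies the pixel-count rule: an image is called lesion-positive
when its predicted mask has strictly more than ``threshold`` positive
pixels (default 50).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arch import SegmentationNetwork
from .config import TrainingConfig
from .loss import compute_weight_map
from .metrics import (
    NON_PTX,
    PTX,
    confusion,
    diagnostic_metrics,
    dice,
    hausdorff_masks,
    pixel_accuracy,
)
from .nn import Adam, softmax
from .synthdata import load_image, load_mask


@dataclass
class DiagnosisRecord:
    image_id: str
    mask: np.ndarray
    positive_pixels: int
    call: str
    threshold: int


def diagnose(mask: np.ndarray, threshold: int = 50, image_id: str = "") -> DiagnosisRecord:
    """Pixel-count diagnosis: lesion-positive iff count > threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    count = int(mask.sum())
    call = PTX if count > threshold else NON_PTX
    return DiagnosisRecord(image_id, mask.astype(np.uint8), count, call, threshold)


def predict_masks(model: SegmentationNetwork, images: np.ndarray,
                  batch_size: int = 8):
    """Binary masks and lesion-probability maps for a stack of images.

    ``images`` is (n, h, w) in [0, 1].  Per-pixel argmax with ties broken
    toward background: a pixel is lesion iff its lesion probability
    strictly exceeds 1/2 (two-class case).
    """
    images = np.asarray(images, dtype=np.float32)
    masks, probs = [], []
    for start in range(0, len(images), batch_size):
        batch = images[start:start + batch_size][:, None]
        p = model.predict_proba(batch)
        pred = np.argmax(p, axis=1)  # first max wins: exact ties resolve to background
        masks.append((pred == 1).astype(np.uint8) if p.shape[1] == 2 else pred.astype(np.uint8))
        probs.append(p[:, 1] if p.shape[1] == 2 else p.max(axis=1))
    return np.concatenate(masks), np.concatenate(probs)


def _val_dsc1(model, images, masks, batch_size=8) -> float:
    pred, _ = predict_masks(model, images, batch_size)
    return dice(list(zip(pred, masks)))["dsc1"]


def train(model: SegmentationNetwork, train_data, val_data,
          config: TrainingConfig, verbose: bool = False):
    """Train ``model`` in place; return the per-epoch history.

    ``train_data`` and ``val_data`` are (images, masks) pairs of arrays
    shaped (n, h, w).  The returned history is a list of dicts with the
    train loss, validation DSC1 and patience counter per epoch.
    """
    x_tr, y_tr = (np.asarray(a) for a in train_data)
    x_va, y_va = (np.asarray(a) for a in val_data)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate, beta1=config.beta1,
               beta2=config.beta2, weight_decay=config.weight_decay)
    wmaps = np.stack([
        compute_weight_map(y, iterations=config.boundary_iterations, mode=config.loss)
        for y in y_tr]).astype(np.float32)

    history = []
    best_dsc, best_epoch, best_state = -np.inf, -1, None
    since_best = 0
    n = len(x_tr)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        flip = rng.random(n) < config.flip_prob
        total_loss, total_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = x_tr[idx].astype(np.float32)
            yb = y_tr[idx].astype(np.intp)
            wb = wmaps[idx]
            fb = flip[idx]
            xb[fb] = xb[fb, :, ::-1]
            yb[fb] = yb[fb, :, ::-1]
            wb[fb] = wb[fb, :, ::-1]

            logits = model.forward(xb[:, None], train=True)
            p = softmax(logits, axis=1)
            onehot = np.zeros_like(p)
            np.put_along_axis(onehot, yb[:, None], 1.0, axis=1)
            p_target = np.take_along_axis(p, yb[:, None], axis=1)[:, 0]
            m = yb.size
            loss = float((wb * -np.log(np.clip(p_target, 1e-7, 1.0))).sum() / m)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            dlogits = wb[:, None] * (p - onehot) / m
            opt.zero_grad()
            model.backward(dlogits.astype(np.float32))
            opt.step()
            total_loss += loss
            total_batches += 1

        val_dsc1 = _val_dsc1(model, x_va, y_va, config.batch_size)
        if val_dsc1 > best_dsc:
            best_dsc, best_epoch, best_state = val_dsc1, epoch, model.get_weights()
            since_best = 0
        else:
            since_best += 1
        history.append({"epoch": epoch, "train_loss": total_loss / total_batches,
                        "val_dsc1": val_dsc1, "since_best": since_best})
        if verbose:
            print(f"epoch {epoch:3d}  loss {total_loss / total_batches:.4f}  "
                  f"val_dsc1 {val_dsc1:.4f}  patience {since_best}/{config.patience}")
        if since_best > 0 and since_best >= config.patience:
            break
    if best_state is not None:
        model.set_weights(best_state)
    return history


def evaluate(model: SegmentationNetwork, images, masks, labels=None, ids=None,
             threshold: int = 50, batch_size: int = 8):
    """Segmentation + diagnostic evaluation; returns (rows, summary).

    ``labels`` default to lesion presence in the ground-truth masks.
    """
    images = np.asarray(images)
    masks = np.asarray(masks)
    if len(images) == 0:
        raise ValueError("evaluation set must be non-empty")
    if labels is None:
        labels = [PTX if m.any() else NON_PTX for m in masks]
    if ids is None:
        ids = [f"img_{i:05d}" for i in range(len(images))]
    pred, _ = predict_masks(model, images, batch_size)
    pairs = list(zip(pred, masks))
    pa = pixel_accuracy(pairs)
    ds = dice(pairs)
    rows, hds, calls = [], [], []
    for i, (pm, gm) in enumerate(pairs):
        hd = hausdorff_masks(pm, gm)
        hds.append(hd)
        rec = diagnose(pm, threshold, image_id=ids[i])
        calls.append(rec.call)
        rows.append({"id": ids[i], "label": labels[i], "call": rec.call,
                     "positive_pixels": rec.positive_pixels,
                     "pa1": pa["per_image"][i, 1], "dsc1": ds["per_image"][i, 1],
                     "hd": hd})
    hds = np.array(hds)
    finite = hds[np.isfinite(hds)]
    cc = confusion(labels, calls)
    summary = {
        "n_images": len(images),
        "mpa": pa["mpa"], "pa1": pa["pa1"], "pa1_std": pa["pa1_std"],
        "dsc": ds["dsc"], "dsc1": ds["dsc1"], "dsc1_std": ds["dsc1_std"],
        "hd_mean": float(finite.mean()) if finite.size else float("nan"),
        "hd_max": float(finite.max()) if finite.size else float("nan"),
        "confusion": {"tp": cc.tp, "fp": cc.fp, "fn": cc.fn, "tn": cc.tn},
        **{f"diag_{k}": v for k, v in diagnostic_metrics(cc).items()},
    }
    return rows, summary


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def load_manifest(path, split: str | None = None):
    """Load a manifest CSV into image/mask arrays.

    Returns ``(images, masks, labels, ids)``.  Missing files are collected
    and reported together in a single error.
    """
    df = pd.read_csv(path, keep_default_na=False)
    if split is not None:
        df = df[df["split"] == split]
    if df.empty:
        raise ValueError(f"manifest {path} has no rows" +
                         (f" for split {split!r}" if split else ""))
    images, masks, labels, ids, errors = [], [], [], [], []
    for _, row in df.iterrows():
        try:
            img = load_image(row["image_path"])
        except FileNotFoundError:
            errors.append(str(row["image_path"]))
            continue
        mask_path = row.get("mask_path", "")
        try:
            mask = load_mask(mask_path, shape=img.shape)
        except FileNotFoundError:
            errors.append(str(mask_path))
            continue
        images.append(img)
        masks.append(mask)
        labels.append(row.get("label", PTX if mask.any() else NON_PTX))
        ids.append(str(row["image_path"]))
    if errors:
        raise FileNotFoundError("missing files:\n" + "\n".join(errors))
    return np.stack(images), np.stack(masks), labels, ids
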