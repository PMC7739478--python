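"""Synthetic chest-phantom generator with ground-truth lesion masks.

The phantoms are stylised, not anatomically realistic: a bright thorax
ellipse with two dark lung fields, periodic rib-like stripes, and Gaussian
noise.  Lesion-positive images carry a crescent (or ellipse) of further
reduced intensity hugging the lung periphery, with the ground-truth mask
equal to its support; lesion-negative images have empty masks.  The point
is a learnable signal — an intensity drop with a sharp boundary — plus the
confounders (ribs, noise) that make boundary-aware losses measurable at
desk scale.

Images are quantised to 8 bits so that a PNG write/read round-trip is
lossless.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .metrics import NON_PTX, PTX


@dataclass
class PhantomSpec:
    size: int = 64
    lesion_prob: float = 0.504
    area_range: tuple[int, int] = (60, 600)
    shape: str = "crescent"  # or "ellipse"
    rib_period: float = 9.0
    rib_amplitude: float = 0.06
    noise: float = 0.03
    #: lesion areas at or below the 50-pixel diagnosis threshold are only
    #: sensible for boundary tests and must be requested explicitly
    subthreshold: bool = False

    def __post_init__(self):
        if self.shape not in ("crescent", "ellipse"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")
        lo, hi = self.area_range
        lung_area = np.pi * (0.30 * self.size) * (0.18 * self.size)
        if lo > hi or hi > lung_area:
            raise ValueError(
                f"lesion area range {self.area_range} infeasible for size {self.size}")
        if lo <= 50 and not self.subthreshold:
            raise ValueError(
                "minimum lesion area must exceed the 50-pixel diagnosis "
                "threshold; pass subthreshold=True for boundary tests")


def _lung_fields(size: int):
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = size * 0.52
    body = ((yy - cy) / (size * 0.46)) ** 2 + ((xx - size * 0.5) / (size * 0.42)) ** 2 <= 1.0
    lungs = []
    for cx in (size * 0.32, size * 0.68):
        lungs.append(((yy - cy) / (size * 0.30)) ** 2 + ((xx - cx) / (size * 0.18)) ** 2 <= 1.0)
    return yy, xx, body, lungs


def _lesion_mask(spec: PhantomSpec, rng: np.random.Generator,
                 yy, xx, lungs) -> np.ndarray:
    """Construct a lesion of the requested shape with area in range."""
    lo, hi = spec.area_range
    target = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    side = rng.integers(0, 2)
    lung = lungs[side]
    rows, cols = np.nonzero(lung)
    cy, cx = rows.mean(), cols.mean()
    # anchor on the lung periphery at a random angle
    theta = rng.uniform(0, 2 * np.pi)
    ry, rx = (rows.max() - rows.min()) / 2.0, (cols.max() - cols.min()) / 2.0
    ay = cy + 0.85 * ry * np.sin(theta)
    ax = cx + 0.85 * rx * np.cos(theta)
    elong = rng.uniform(1.2, 2.2)

    def support(scale: float) -> np.ndarray:
        r = scale
        outer = ((yy - ay) / (r * elong)) ** 2 + ((xx - ax) / r) ** 2 <= 1.0
        if spec.shape == "crescent":
            # subtract an inner ellipse shifted toward the lung centre
            sy = ay + 0.45 * r * np.sign(cy - ay + 1e-9)
            sx = ax + 0.45 * r * np.sign(cx - ax + 1e-9)
            inner = ((yy - sy) / (r * elong)) ** 2 + ((xx - sx) / r) ** 2 <= 0.85
            outer = outer & ~inner
        return outer & lung

    # bisection on the radius: support area is monotone in scale
    s_lo, s_hi = 0.5, float(spec.size)
    for _ in range(40):
        s_mid = 0.5 * (s_lo + s_hi)
        a = support(s_mid).sum()
        if a < target:
            s_lo = s_mid
        else:
            s_hi = s_mid
    mask = support(s_hi)
    if not lo <= mask.sum() <= hi:
        mask = support(s_lo) if mask.sum() > hi else mask
    if not lo <= mask.sum() <= hi:
        # degenerate anchor (e.g. clipped corner); fall back to a centred ellipse
        r = np.sqrt(target / (np.pi * elong))
        mask = (((yy - cy) / (r * elong)) ** 2 + ((xx - cx) / r) ** 2 <= 1.0) & lung
    return mask


def generate_phantom(spec: PhantomSpec, seed: int,
                     force_label: str | None = None):
    """Return ``(image, mask, label)`` for one phantom.

    ``image`` is a float array in [0, 1] quantised to 8 bits, ``mask`` a
    uint8 {0, 1} grid, ``label`` "PTX" or "NonPTX".  Identical (spec, seed)
    pairs produce bit-identical output.
    """
    rng = np.random.default_rng(seed)
    size = spec.size
    yy, xx, body, lungs = _lung_fields(size)
    img = np.full((size, size), 0.12)
    img[body] = 0.55
    for lung in lungs:
        img[lung] = 0.25
    ribs = spec.rib_amplitude * 0.5 * (1.0 + np.sin(2 * np.pi * yy / spec.rib_period))
    img[body] += ribs[body]

    if force_label is None:
        label = PTX if rng.random() < spec.lesion_prob else NON_PTX
    else:
        label = force_label
    mask = np.zeros((size, size), dtype=np.uint8)
    if label == PTX:
        lesion = _lesion_mask(spec, rng, yy, xx, lungs)
        img[lesion] = 0.07
        mask[lesion] = 1

    img += rng.normal(0.0, spec.noise, img.shape)
    img = np.clip(img, 0.0, 1.0)
    img = np.round(img * 255.0) / 255.0  # 8-bit quantisation: PNG round-trips losslessly
    return img, mask, label


def _stratified_split(indices: np.ndarray, fractions, rng) -> list[np.ndarray]:
    """Largest-remainder allocation of shuffled indices to splits."""
    idx = rng.permutation(indices)
    n = len(idx)
    raw = np.array(fractions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[:n - counts.sum()]:
        counts[i] += 1
    out, start = [], 0
    for c in counts:
        out.append(idx[start:start + c])
        start += c
    return out


def generate_dataset(spec: PhantomSpec, n: int, out_dir: str | Path,
                     split_fractions=(0.64, 0.16, 0.20), seed: int = 0) -> pd.DataFrame:
    """Write ``n`` image/mask PNG pairs and a manifest CSV under ``out_dir``.

    The train/val/test split is stratified: the lesion class ratio in each
    split matches the global ratio to within one image.
    """
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if n < len(split_fractions):
        raise ValueError("need at least one image per split")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    records = []
    for i in range(n):
        img, mask, label = generate_phantom(spec, int(seeds[i]))
        img_path = out_dir / "images" / f"phantom_{i:05d}.png"
        Image.fromarray(np.round(img * 255).astype(np.uint8)).save(img_path)
        mask_path = ""
        if label == PTX:
            mask_path = out_dir / "masks" / f"phantom_{i:05d}.png"
            Image.fromarray((mask * 255).astype(np.uint8)).save(mask_path)
        records.append({"image_path": str(img_path), "mask_path": str(mask_path),
                        "label": label, "split": ""})
    df = pd.DataFrame(records)
    split_names = ("train", "val", "test")[:len(split_fractions)]
    for label in (PTX, NON_PTX):
        cls_idx = df.index[df["label"] == label].to_numpy()
        for name, part in zip(split_names, _stratified_split(cls_idx, split_fractions, rng)):
            df.loc[part, "split"] = name
    df.to_csv(out_dir / "manifest.csv", index=False)
    return df


def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG as a float array in [0, 1]."""
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
    return arr / 255.0


def load_mask(path: str | Path, shape=None) -> np.ndarray:
    """Read a 0/255 mask PNG as a {0, 1} uint8 array; empty path -> zeros."""
    if not str(path):
        if shape is None:
            raise ValueError("shape required for empty mask path")
        return np.zeros(shape, dtype=np.uint8)
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def worked_fixtures() -> dict:
    """Small hand-checkable fixtures with their expected values.

    Each entry bundles inputs for the loss/metric primitives together with
    values derived by hand, for use in tests and documentation examples.
    """
    single = np.zeros((4, 4), dtype=np.uint8)
    single[1, 1] = 1
    wmap = np.full((4, 4), 16.0 / 15.0)
    wmap[1, 1] = 32.0

    pred_47 = np.zeros((4, 4), dtype=np.uint8)
    pred_47[0, :3] = 1            # 3 predicted positives
    truth_47 = np.zeros((4, 4), dtype=np.uint8)
    truth_47[0, :2] = 1           # overlap 2
    truth_47[1, :2] = 1           # 4 truth positives

    return {
        "single-pixel-4x4": {
            "mask": single,
            "weight_map_0iter": wmap,
            "center_weight": 32.0,
        },
        "two-point-contour": {
            "pred_points": np.array([[0, 0]]),
            "truth_points": np.array([[3, 4]]),
            "hausdorff": 5.0,
        },
        "dice-4-7": {
            "pred": pred_47,
            "truth": truth_47,
            "dsc1": 4.0 / 7.0,
        },
    }
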