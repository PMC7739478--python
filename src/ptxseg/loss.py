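"""Spatially weighted cross-entropy: boundary bands and per-pixel weights.

Lesion segmentation on radiographs is heavily class-imbalanced, and the
clinically hard part is the lesion contour.  The loss here therefore
supports three modes:

``cel``
    plain cross-entropy (all weights 1);
``wcel``
    inverse class-frequency weights |N| / |T_c| per pixel;
``swcel``
    the class-frequency weight plus a boundary bonus |N| / |B_c| on a band
    obtained by morphologically dilating the lesion contour with a 3x3
    cross, where B_c is the part of the band falling in class c.

A lesion pixel is a contour pixel when at least one of its in-bounds
8-neighbours is background; out-of-bounds neighbours are ignored, so a
full-frame lesion has no contour.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

EPS = 1e-7

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_FULL = np.ones((3, 3), dtype=bool)


def _validate_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    return mask.astype(bool)


def detect_boundary(mask: np.ndarray) -> np.ndarray:
    """Boolean map of lesion pixels with a background 8-neighbour.

    Pixels on the image border whose in-bounds neighbours are all lesion
    are not boundary (out-of-bounds neighbours are ignored).
    """
    m = _validate_binary(mask)
    eroded = ndimage.binary_erosion(m, structure=_FULL, border_value=1)
    return m & ~eroded


def dilate_band(contour: np.ndarray, iterations: int) -> np.ndarray:
    """Iterated dilation of a contour map with a 3x3 cross element."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    contour = np.asarray(contour, dtype=bool)
    if iterations == 0 or not contour.any():
        return contour.copy()
    return ndimage.binary_dilation(contour, structure=_CROSS, iterations=iterations)


def compute_weight_map(mask: np.ndarray, iterations: int = 2,
                       mode: str = "swcel") -> np.ndarray:
    """Per-pixel loss weights for the given ground-truth mask.

    Every pixel of class c weighs |N| / |T_c|; in ``swcel`` mode pixels of
    the dilated boundary band additionally receive |N| / |B_c| where B_c is
    the band restricted to class c.  Absent classes (or empty bands)
    contribute no term.  ``cel`` returns unit weights.
    """
    if mode not in ("cel", "wcel", "swcel"):
        raise ValueError(f"unknown loss mode {mode!r}")
    m = _validate_binary(mask)
    n_total = m.size
    w = np.ones(m.shape, dtype=np.float64)
    if mode == "cel":
        return w
    w[:] = 0.0
    band = dilate_band(detect_boundary(m), iterations) if mode == "swcel" else None
    for cls in (False, True):
        t_c = m == cls
        n_c = t_c.sum()
        if n_c == 0:
            continue
        w[t_c] += n_total / n_c
        if band is not None:
            b_c = band & t_c
            n_b = b_c.sum()
            if n_b:
                w[b_c] += n_total / n_b
    return w


def weighted_cross_entropy(probabilities: np.ndarray, targets: np.ndarray,
                           weights: np.ndarray | None = None,
                           reduction: str = "mean") -> float:
    """Weighted negative log-likelihood of the target class per pixel.

    ``probabilities`` is either a (num_classes, H, W) stack of class
    probabilities or an (H, W) map already holding the probability of each
    pixel's target class.  Probabilities are clamped at 1e-7 before the log.
    """
    if reduction not in ("sum", "mean"):
        raise ValueError(f"unknown reduction {reduction!r}")
    t = _validate_binary(targets).astype(np.intp)
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim == 3:
        p_target = np.take_along_axis(p, t[None], axis=0)[0]
    elif p.shape == t.shape:
        p_target = p
    else:
        raise ValueError("probabilities shape incompatible with targets")
    if weights is None:
        weights = np.ones_like(p_target)
    terms = np.asarray(weights, dtype=np.float64) * -np.log(np.clip(p_target, EPS, 1.0))
    return float(terms.sum() if reduction == "sum" else terms.mean())
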