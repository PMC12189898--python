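"""Scoring an obtained foreground mask against an ideal (ground-truth) mask.

The headline metric is the matching coefficient: the maximum zero-mean
normalized cross-correlation (Pearson correlation of the two binary
images) over translations up to ``max_shift`` pixels.  The camera and
pad are static, so the default is no shift.  Jaccard overlap
(intersection over union) at the best offset is reported alongside as
the standard segmentation metric.

``ideal_mask_from_reference`` builds a reference mask from a single
fully-warmed frame the way a human annotator would start: edge
detection, then a flood fill from a seed bounded by the edges.  (Manual
touch-up is out of scope; synthetic ground truth stands in for it in
tests.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ThermalFrame
from .sdph import ForegroundMask

__all__ = ["MatchResult", "match_coefficient", "ideal_mask_from_reference"]


@dataclass(frozen=True)
class MatchResult:
    """Agreement between an obtained mask and the ideal mask."""

    coefficient: float
    best_offset: tuple[int, int]
    jaccard: float
    method: str = ""


def _shift(mask: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate a binary image by (dx, dy) = (columns, rows), zero-filled."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    ys_src = slice(max(0, -dy), min(h, h - dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    ys_dst = slice(max(0, dy), min(h, h + dy))
    xs_dst = slice(max(0, dx), min(w, w + dx))
    out[ys_dst, xs_dst] = mask[ys_src, xs_src]
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation of two images at alignment.

    Degenerate (constant) images correlate 1.0 with an identical image
    and 0.0 otherwise.
    """
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.sqrt((da**2).sum()), np.sqrt((db**2).sum())
    if na == 0.0 or nb == 0.0:
        return 1.0 if np.array_equal(a, b) else 0.0
    return float((da * db).sum() / (na * nb))


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def match_coefficient(
    ideal: ForegroundMask,
    obtained: ForegroundMask,
    max_shift: int = 0,
    method: str = "",
) -> MatchResult:
    """Best zero-mean normalized cross-correlation between two binary
    masks over translations of the obtained mask up to ``max_shift``
    pixels in each axis (default 0 = aligned), plus Jaccard overlap at
    the best offset.

    Identical masks score 1.0 / 1.0; an exactly complementary mask
    scores -1.0 at zero shift.
    """
    if ideal.shape != obtained.shape:
        raise ValueError(
            f"mask shapes differ: {ideal.shape} vs {obtained.shape}"
        )
    if ideal.area() == 0:
        raise ValueError("ideal mask is empty")
    if max_shift < 0:
        raise ValueError(f"max_shift must be >= 0, got {max_shift}")
    ia = ideal.as_bool()
    ob = obtained.as_bool()
    best_coeff = -np.inf
    best = (0, 0)
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            c = _pearson(ia, _shift(ob, dx, dy))
            if c > best_coeff:
                best_coeff, best = c, (dx, dy)
    jac = _jaccard(ia, _shift(ob, *best))
    return MatchResult(
        coefficient=float(best_coeff), best_offset=best, jaccard=jac, method=method
    )


def ideal_mask_from_reference(
    frame: ThermalFrame,
    seed_point: tuple[int, int],
    gradient_threshold: float,
) -> ForegroundMask:
    """Reference mask from one fully-warmed frame: gradient-magnitude
    edges, then a flood fill from ``seed_point`` (x, y) bounded by them.

    The connected non-edge region containing the seed is returned; seed
    the background and you get the background region (inversion is the
    caller's call).  A seed on an edge pixel raises ``ValueError``; an
    image with no edges at the threshold floods entirely (a warning is
    issued).
    """
    x, y = seed_point
    h, w = frame.shape
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"seed point {seed_point} outside image bounds {w}x{h}")
    img = frame.pixels.astype(np.float64)
    gy, gx = np.gradient(img)
    grad = np.hypot(gx, gy)
    edges = grad >= gradient_threshold
    if edges[y, x]:
        raise ValueError(
            f"seed point {seed_point} lies on an edge pixel; pick a point "
            "inside the intended region"
        )
    if not edges.any():
        warnings.warn(
            "no edges at this gradient threshold; the flood fill covers the "
            "entire image",
            stacklevel=2,
        )
    labels, _ = ndimage.label(~edges)
    region = labels == labels[y, x]
    return ForegroundMask(mask=region, provenance="ideal")
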