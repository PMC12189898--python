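"""Independent brute-force oracles used to check the implementation.

Each oracle evaluates the mathematical definition directly, with
explicit Python loops over pixels and set elements, independently of the
vectorized/library code paths it validates.
"""

from __future__ import annotations

import numpy as np


def naive_pixel_history(volume: np.ndarray, window_n: int):
    """Per-pixel mean and population variance of the last ``window_n``
    slices of a (n, h, w) volume, by explicit loops."""
    window = volume[-window_n:]
    n, h, w = window.shape
    mean = np.zeros((h, w))
    var = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            s = 0.0
            s2 = 0.0
            for i in range(n):
                v = float(window[i, y, x])
                s += v
                s2 += v * v
            m = s / n
            mean[y, x] = m
            var[y, x] = max(s2 / n - m * m, 0.0)
    return mean, var


def element_offsets(element: np.ndarray):
    """(dy, dx) offsets of the element's 1-entries relative to its center."""
    k = element.shape[0] // 2
    return [
        (i - k, j - k)
        for i in range(element.shape[0])
        for j in range(element.shape[1])
        if element[i, j]
    ]


def brute_dilate(mask: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Set-theoretic dilation: 1 at z iff the reflected element placed at
    z overlaps >= 1 foreground pixel; outside the image is background."""
    h, w = mask.shape
    offs = element_offsets(element)
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            hit = False
            for dy, dx in offs:
                yy, xx = y - dy, x - dx  # reflection: z - e in A
                if 0 <= yy < h and 0 <= xx < w and mask[yy, xx]:
                    hit = True
                    break
            out[y, x] = hit
    return out


def brute_erode(
    mask: np.ndarray, element: np.ndarray, border_foreground: bool = False
) -> np.ndarray:
    """Set-theoretic erosion: 1 at z iff the element placed at z fits
    entirely inside the foreground.  Out-of-image pixels count as
    background unless ``border_foreground``."""
    h, w = mask.shape
    offs = element_offsets(element)
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            fits = True
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    if not mask[yy, xx]:
                        fits = False
                        break
                elif not border_foreground:
                    fits = False
                    break
            out[y, x] = fits
    return out


def brute_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation by explicit sums."""
    a = a.astype(float).ravel()
    b = b.astype(float).ravel()
    n = a.size
    ma, mb = sum(a) / n, sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = sum((x - ma) ** 2 for x in a) ** 0.5
    db = sum((y - mb) ** 2 for y in b) ** 0.5
    return num / (da * db)
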