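"""Background subtraction for time-variant thermal image sequences.

Two families are implemented:

* classic frame differencing against a (optionally learned) reference
  background — ``frame_difference`` / ``difference_mask`` /
  ``update_background``;
* SDPH (standard deviation of pixel history): per-pixel mean and
  variance over a temporal window of the sequence, each thresholded, and
  the foreground taken as the logical intersection.  A warming pad is
  simultaneously *hotter* than the ambient background (high mean) and
  *changing* while it warms (high temporal dispersion); the static
  background is neither, so the intersection isolates the pad.

Statistics are computed on raw gray levels, exactly as acquired; the
affine gray->degC calibration makes thresholding equivalent either way,
and integer gray arithmetic is exact.  Temperatures enter only when a
mask is applied to a frame (``apply_mask``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .io import TemperatureScale, ThermalFrame, ThermalSequence, gray_to_temperature

__all__ = [
    "ForegroundMask",
    "MaskedTemperatureField",
    "DifferenceModel",
    "PixelHistoryStats",
    "SdphThresholds",
    "frame_difference",
    "difference_mask",
    "update_background",
    "pixel_history_stats",
    "sdph_mask",
    "apply_mask",
    "auto_thresholds",
]


@dataclass(frozen=True)
class ForegroundMask:
    """Binary image marking pad (foreground) pixels.

    ``mask`` holds {0, 1} as uint8; ``provenance`` records which stage
    produced it ("difference", "sdph", "refined", "baseline:<name>",
    "ideal", "roi", "ground-truth").
    """

    mask: np.ndarray
    provenance: str = "sdph"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {m.shape}")
        if m.dtype == bool:
            m = m.astype(np.uint8)
        uniq = np.unique(m)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0, 1}}, got {uniq[:10]}")
        object.__setattr__(self, "mask", m.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def as_bool(self) -> np.ndarray:
        return self.mask.astype(bool)

    def area(self) -> int:
        """Number of foreground pixels."""
        return int(self.mask.sum())


@dataclass(frozen=True)
class MaskedTemperatureField:
    """A temperature field restricted to a foreground: the active ROI.

    Excluded (background) pixels never enter downstream statistics.
    """

    values: np.ndarray
    include: np.ndarray
    scale: TemperatureScale = field(default_factory=TemperatureScale)
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        inc = np.asarray(self.include).astype(bool)
        if v.shape != inc.shape:
            raise ValueError(
                f"values shape {v.shape} and include shape {inc.shape} differ"
            )
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "include", inc)

    @property
    def n_included(self) -> int:
        return int(self.include.sum())

    def included_values(self) -> np.ndarray:
        """1-D array of the temperatures at included pixels."""
        return self.values[self.include]


@dataclass(frozen=True)
class DifferenceModel:
    """Reference background plus the parameters of classic differencing.

    ``background`` is kept in floating point (never re-quantized) so the
    recursive learning update stays exact.  The learning update is off by
    default (``learning_rate = 0``): the inspection scene is static, so
    the reference only needs adjusting when the background itself drifts.
    """

    background: np.ndarray
    learning_rate: float = 0.0
    diff_threshold: float = 10.0

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.ndim != 2:
            raise ValueError(f"background must be 2-D, got shape {bg.shape}")
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError(f"learning_rate must be in [0, 1], got {self.learning_rate}")
        if self.diff_threshold < 0:
            raise ValueError(f"diff_threshold must be >= 0, got {self.diff_threshold}")
        object.__setattr__(self, "background", bg)


@dataclass(frozen=True)
class PixelHistoryStats:
    """Per-pixel mean and population variance over a temporal window."""

    mean_image: np.ndarray
    var_image: np.ndarray
    window_n: int

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean_image, dtype=float)
        var = np.asarray(self.var_image, dtype=float)
        if mean.shape != var.shape:
            raise ValueError("mean and variance images must share a shape")
        if self.window_n < 1:
            raise ValueError(f"window_n must be >= 1, got {self.window_n}")
        if var.min() < 0:
            raise ValueError("variance image must be nonnegative")
        object.__setattr__(self, "mean_image", mean)
        object.__setattr__(self, "var_image", var)

    def dispersion(self, mode: str) -> np.ndarray:
        if mode == "variance":
            return self.var_image
        if mode == "stddev":
            return np.sqrt(self.var_image)
        raise ValueError(f"mode must be 'variance' or 'stddev', got {mode!r}")


@dataclass(frozen=True)
class SdphThresholds:
    """Dual thresholds for the SDPH intersection mask.

    ``tau_mean`` is in gray levels; ``tau_var`` is in squared gray levels
    when ``mode == "variance"`` (the default — temporal variance is the
    more sensitive statistic) or in gray levels when ``mode == "stddev"``.
    """

    tau_mean: float
    tau_var: float
    mode: Literal["variance", "stddev"] = "variance"

    def __post_init__(self) -> None:
        if self.tau_mean < 0 or self.tau_var < 0:
            raise ValueError("thresholds must be >= 0")
        if self.mode not in ("variance", "stddev"):
            raise ValueError(f"mode must be 'variance' or 'stddev', got {self.mode!r}")


def frame_difference(current: ThermalFrame, model: DifferenceModel) -> np.ndarray:
    """Absolute difference ``D_t = |I_t - B_t|`` between the current frame
    and the reference background, elementwise."""
    if current.shape != model.background.shape:
        raise ValueError(
            f"frame shape {current.shape} does not match background "
            f"shape {model.background.shape}"
        )
    return np.abs(current.pixels.astype(np.float64) - model.background)


def difference_mask(diff: np.ndarray, tau_f: float) -> ForegroundMask:
    """Threshold a difference image: foreground where ``D_t >= tau_f``
    (boundary equality counts as foreground)."""
    if tau_f < 0:
        raise ValueError(f"tau_f must be >= 0, got {tau_f}")
    return ForegroundMask(mask=(np.asarray(diff) >= tau_f), provenance="difference")


def update_background(model: DifferenceModel, current: ThermalFrame) -> DifferenceModel:
    """Recursive background learning
    ``B_t = (1 - alpha) * B_{t-1} + alpha * I_t`` at the model's rate.

    Returns a new model; the background stays in floating point.
    """
    if current.shape != model.background.shape:
        raise ValueError("frame and background shapes differ")
    a = model.learning_rate
    new_bg = (1.0 - a) * model.background + a * current.pixels.astype(np.float64)
    return replace(model, background=new_bg)


def pixel_history_stats(
    sequence: ThermalSequence, t_index: int, window_n: int
) -> PixelHistoryStats:
    """Per-pixel mean and population variance over the ``window_n`` frames
    ending at ``t_index`` (indices ``t_index - window_n + 1 .. t_index``).

    The variance uses the population difference-of-squares form
    ``(1/n) sum I_i**2 - mean**2``, with tiny negative round-off clamped
    to zero.
    """
    if window_n < 1:
        raise ValueError(f"window_n must be >= 1, got {window_n}")
    n_frames = len(sequence)
    if t_index < 0:
        t_index += n_frames
    if not 0 <= t_index < n_frames:
        raise IndexError(f"t_index {t_index} out of range for {n_frames} frames")
    start = t_index - window_n + 1
    if start < 0:
        raise ValueError(
            f"a window of {window_n} frames ending at index {t_index} needs at "
            f"least {window_n} frames of history; the sequence provides "
            f"{t_index + 1}"
        )
    stack = np.stack(
        [sequence[i].pixels for i in range(start, t_index + 1)]
    ).astype(np.float64)
    mean = stack.sum(axis=0) / window_n
    var = (stack**2).sum(axis=0) / window_n - mean**2
    np.maximum(var, 0.0, out=var)
    return PixelHistoryStats(mean_image=mean, var_image=var, window_n=window_n)


def sdph_mask(stats: PixelHistoryStats, thresholds: SdphThresholds) -> ForegroundMask:
    """SDPH foreground: pixels whose history mean **and** history
    dispersion both reach their thresholds (boundary equality counts)."""
    disp = stats.dispersion(thresholds.mode)
    m = (stats.mean_image >= thresholds.tau_mean) & (disp >= thresholds.tau_var)
    return ForegroundMask(mask=m, provenance="sdph")


def apply_mask(mask: ForegroundMask, frame: ThermalFrame) -> MaskedTemperatureField:
    """Restrict a frame's calibrated temperatures to the mask's foreground
    (the logical-AND cropping step).  Background pixels are excluded from
    all downstream statistics, not set to a sentinel value."""
    if mask.shape != frame.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {frame.shape}"
        )
    temps = gray_to_temperature(frame)
    return MaskedTemperatureField(
        values=temps.values,
        include=mask.as_bool(),
        scale=frame.scale,
        timestamp=frame.timestamp,
    )


def auto_thresholds(
    stats: PixelHistoryStats, mode: Literal["variance", "stddev"] = "variance"
) -> SdphThresholds:
    """Choose the SDPH thresholds automatically by Otsu's bimodal
    histogram split, applied independently to the mean image and to the
    dispersion image.  Deterministic for fixed input.

    Raises ``ValueError`` on a constant image (no split exists) — supply
    manual thresholds in that case.
    """
    from skimage.filters import threshold_otsu

    mean = stats.mean_image
    disp = stats.dispersion(mode)
    for name, img in (("mean", mean), ("dispersion", disp)):
        if np.ptp(img) == 0:
            raise ValueError(
                f"the {name} image is constant; automatic thresholding cannot "
                "split it — pass manual SdphThresholds instead"
            )
    return SdphThresholds(
        tau_mean=float(threshold_otsu(mean, nbins=256)),
        tau_var=float(threshold_otsu(disp, nbins=256)),
        mode=mode,
    )
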