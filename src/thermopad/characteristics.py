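"""Thermal characteristics of the masked foreground.

Low-temperature-burn screening of a warming pad needs, per timepoint:

* extreme temperatures ``T_min`` / ``T_max`` over the pad only;
* uniformity: population mean and variance (plus the median) of the pad
  temperatures;
* the dominant temperature ``T_dom`` — the center of the fullest
  histogram bin;
* the full-warming area fraction ``A_h`` — the share of pad pixels at or
  above a policy threshold ``tau_h``.

All statistics run over *included* pixels only; that is the entire point
of replacing a rectangular ROI (which mixes in cool background and drags
the mean, median, minimum and dominant temperature down) with the
shape-adaptive foreground mask.  ``rectangular_roi_stats`` computes the
conventional-ROI baseline for comparison.

Histogram bins default to one bin per representable gray level mapped to
degC, so ``T_dom`` has the camera's quantization resolution.  ``T_dom``
ties break toward the hotter bin: for burn screening, overestimate,
never underestimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .io import ThermalFrame, ThermalSequence
from .sdph import ForegroundMask, MaskedTemperatureField, apply_mask

__all__ = [
    "ThermalCharacteristics",
    "TemperatureHistogram",
    "RectROI",
    "extreme_temperatures",
    "foreground_moments",
    "temperature_histogram",
    "dominant_temperature",
    "area_fraction_above",
    "characterize_field",
    "characterize_sequence",
    "rectangular_roi_stats",
    "characteristics_table",
]

#: Default full-warming threshold (degC).  An inspection-policy knob, not
#: a physical constant: the area fraction at or above it is reported as
#: the "fully warmed" share of the pad.
DEFAULT_TAU_H = 40.0


class EmptyForegroundError(ValueError):
    """Raised when a statistic is requested for an empty foreground mask."""


@dataclass(frozen=True)
class TemperatureHistogram:
    """Counts of included pixels per temperature bin over [t_low, t_high]."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        if edges.ndim != 1 or counts.ndim != 1 or len(edges) != len(counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ThermalCharacteristics:
    """Per-timepoint summary of the foreground's thermal state.

    ``empty`` flags a record whose foreground had no pixels (e.g. before
    warming began); its statistics are NaN and ``n_pixels`` is 0.
    """

    timestamp: float
    t_min: float
    t_max: float
    mean: float
    variance: float
    median: float
    t_dom: float
    area_fraction: float
    n_pixels: int
    empty: bool = False


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle, (x, y) = top-left corner in (column, row)."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("RectROI needs width >= 1 and height >= 1")
        if self.x < 0 or self.y < 0:
            raise ValueError("RectROI origin must be nonnegative")

    def mask_for(self, shape: tuple[int, int]) -> ForegroundMask:
        h, w = shape
        if self.x + self.width > w or self.y + self.height > h:
            raise ValueError(
                f"RectROI {self} exceeds image bounds {w}x{h} (width x height)"
            )
        m = np.zeros(shape, dtype=np.uint8)
        m[self.y : self.y + self.height, self.x : self.x + self.width] = 1
        return ForegroundMask(mask=m, provenance="roi")


def _require_nonempty(fg: MaskedTemperatureField) -> np.ndarray:
    vals = fg.included_values()
    if vals.size == 0:
        raise EmptyForegroundError("empty foreground mask")
    return vals


def extreme_temperatures(fg: MaskedTemperatureField) -> tuple[float, float]:
    """Minimum and maximum temperature over included pixels only."""
    vals = _require_nonempty(fg)
    return float(vals.min()), float(vals.max())


def foreground_moments(fg: MaskedTemperatureField) -> tuple[float, float, float]:
    """Population mean, population variance and median of the included
    temperatures.

    The variance uses the difference-of-squares form
    ``(1/n') sum F**2 - mean**2`` with round-off clamped at zero; the
    median uses the midpoint-of-two rule for even ``n'``.
    """
    vals = _require_nonempty(fg)
    n = vals.size
    mean = float(vals.sum() / n)
    var = float((vals**2).sum() / n - mean**2)
    var = max(var, 0.0)
    median = float(np.median(vals))
    return mean, var, median


def default_bin_edges(fg: MaskedTemperatureField) -> np.ndarray:
    """One bin per representable gray level, covering [t_low, t_high]."""
    s = fg.scale
    n_bins = s.max_gray + 1
    half = s.degrees_per_level / 2.0
    # bin k is centered on the temperature of gray level k
    return np.linspace(s.t_low - half, s.t_high + half, n_bins + 1)


def temperature_histogram(
    fg: MaskedTemperatureField, bin_edges: np.ndarray | None = None
) -> TemperatureHistogram:
    """Histogram of included-pixel temperatures.  Counts sum to ``n'``."""
    vals = _require_nonempty(fg)
    edges = default_bin_edges(fg) if bin_edges is None else np.asarray(bin_edges, float)
    counts, _ = np.histogram(vals, bins=edges)
    return TemperatureHistogram(bin_edges=edges, counts=counts)


def dominant_temperature(hist: TemperatureHistogram) -> float:
    """Center of the fullest bin; ties break toward the hotter bin."""
    counts = hist.counts
    if counts.sum() == 0:
        raise EmptyForegroundError("histogram holds no pixels")
    # argmax of the reversed array finds the last (hottest) maximal bin
    idx = len(counts) - 1 - int(np.argmax(counts[::-1]))
    return float(hist.centers[idx])


def area_fraction_above(hist: TemperatureHistogram, tau_h: float) -> float:
    """Fraction of included pixels in bins at or above ``tau_h``.

    The bin whose center equals ``tau_h`` is included (the full-warming
    area counts pixels *at or above* the threshold).
    """
    n = hist.n_pixels
    if n == 0:
        raise EmptyForegroundError("histogram holds no pixels")
    sel = hist.centers >= tau_h - 1e-9
    return float(hist.counts[sel].sum() / n)


def characterize_field(
    fg: MaskedTemperatureField, tau_h: float = DEFAULT_TAU_H
) -> ThermalCharacteristics:
    """All per-timepoint characteristics of one masked field."""
    if fg.n_included == 0:
        return ThermalCharacteristics(
            timestamp=fg.timestamp,
            t_min=math.nan,
            t_max=math.nan,
            mean=math.nan,
            variance=math.nan,
            median=math.nan,
            t_dom=math.nan,
            area_fraction=math.nan,
            n_pixels=0,
            empty=True,
        )
    t_min, t_max = extreme_temperatures(fg)
    mean, var, median = foreground_moments(fg)
    hist = temperature_histogram(fg)
    return ThermalCharacteristics(
        timestamp=fg.timestamp,
        t_min=t_min,
        t_max=t_max,
        mean=mean,
        variance=var,
        median=median,
        t_dom=dominant_temperature(hist),
        area_fraction=area_fraction_above(hist, tau_h),
        n_pixels=fg.n_included,
    )


def characterize_sequence(
    sequence: ThermalSequence,
    masks: ForegroundMask | TypingSequence[ForegroundMask],
    tau_h: float = DEFAULT_TAU_H,
    start_index: int = 0,
) -> list[ThermalCharacteristics]:
    """Characteristics trace over a sequence: one record per frame from
    ``start_index`` on, timestamps preserved.

    ``masks`` is either one mask applied to every frame (the usual
    inspection protocol: the measurement mask is selected once from the
    mask time sequence) or one mask per characterized frame.  A frame
    with an empty foreground yields a flagged record, never an exception,
    so pre-warming frames cannot abort an inspection run.
    """
    frames = sequence.frames[start_index:]
    if isinstance(masks, ForegroundMask):
        mask_list: list[ForegroundMask] = [masks] * len(frames)
    else:
        mask_list = list(masks)
        if len(mask_list) != len(frames):
            raise ValueError(
                f"got {len(mask_list)} masks for {len(frames)} characterized frames"
            )
    records = []
    for frame, mask in zip(frames, mask_list):
        records.append(characterize_field(apply_mask(mask, frame), tau_h=tau_h))
    return records


def rectangular_roi_stats(
    frame: ThermalFrame, rect: RectROI, tau_h: float = DEFAULT_TAU_H
) -> ThermalCharacteristics:
    """Conventional-ROI baseline: the same statistics over *all* pixels of
    an axis-aligned rectangle, background included."""
    mask = rect.mask_for(frame.shape)
    return characterize_field(apply_mask(mask, frame), tau_h=tau_h)


def characteristics_table(records: Iterable[ThermalCharacteristics]) -> pd.DataFrame:
    """Tidy table of a characteristics trace (one row per timestamp)."""
    return pd.DataFrame(
        [
            {
                "timestamp_min": r.timestamp,
                "t_min_c": r.t_min,
                "t_max_c": r.t_max,
                "mean_c": r.mean,
                "variance_c2": r.variance,
                "median_c": r.median,
                "t_dom_c": r.t_dom,
                "area_fraction": r.area_fraction,
                "n_pixels": r.n_pixels,
                "empty": r.empty,
            }
            for r in records
        ]
    )
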