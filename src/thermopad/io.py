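"""Reading, writing and calibrating quantized grayscale thermal frames.

A thermal camera operating with a fixed temperature span stores each pixel
as a gray level ``g`` in ``[0, 2**bit_depth - 1]``.  The gray level maps
linearly onto the span ``[t_low, t_high]`` (degrees Celsius); the default
span is 25-45 degC, the fixed range used when inspecting skin-contact
warming pads.  Lossless acquisition uses 10-bit TIFF; consumer thermal
cameras emit 8-bit lossy JPEG.  10-bit frames live in 16-bit containers
with values <= 1023, the common TIFF practice.

Image coordinates are ``(x, y) = (column, row)``, 0-based, everywhere in
this package; arrays are indexed ``[row, column]`` as usual for numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence as TypingSequence

import numpy as np

__all__ = [
    "TemperatureScale",
    "ThermalFrame",
    "ThermalSequence",
    "TemperatureField",
    "read_frame",
    "write_frame",
    "write_mask",
    "gray_to_temperature",
    "temperature_to_gray",
    "load_sequence",
]

_VALID_BIT_DEPTHS = (8, 10)


@dataclass(frozen=True)
class TemperatureScale:
    """Fixed linear gray <-> temperature calibration.

    Parameters
    ----------
    t_low, t_high : float
        Temperatures (degC) mapped to gray level 0 and to the maximum
        gray level respectively.  Default 25-45 degC.
    bit_depth : int
        Quantization depth; 8 (lossy consumer cameras) or 10 (lossless
        industrial cameras stored in 16-bit TIFF containers).
    """

    t_low: float = 25.0
    t_high: float = 45.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.bit_depth not in _VALID_BIT_DEPTHS:
            raise ValueError(
                f"bit_depth must be one of {_VALID_BIT_DEPTHS}, got {self.bit_depth}"
            )
        if not self.t_low < self.t_high:
            raise ValueError(
                f"require t_low < t_high, got t_low={self.t_low}, t_high={self.t_high}"
            )

    @property
    def max_gray(self) -> int:
        """Largest representable gray level, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    @property
    def span(self) -> float:
        return self.t_high - self.t_low

    @property
    def degrees_per_level(self) -> float:
        """Temperature resolution of one gray level."""
        return self.span / self.max_gray


@dataclass(frozen=True)
class ThermalFrame:
    """One quantized grayscale thermal image.

    ``pixels`` is a 2-D integer array of gray levels within the scale's
    bit-depth range; ``timestamp`` is minutes since warming started.
    """

    pixels: np.ndarray
    scale: TemperatureScale = field(default_factory=TemperatureScale)
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"pixels must be an integer array, got dtype {px.dtype}")
        lo, hi = int(px.min()), int(px.max())
        if lo < 0 or hi > self.scale.max_gray:
            raise ValueError(
                f"gray levels [{lo}, {hi}] outside the {self.scale.bit_depth}-bit "
                f"range [0, {self.scale.max_gray}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class TemperatureField:
    """Per-pixel temperatures (degC): the calibrated view of a frame."""

    values: np.ndarray
    scale: TemperatureScale = field(default_factory=TemperatureScale)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ThermalSequence:
    """Ordered frames at a fixed interval: the image volume that the
    pixel-history statistics run over.

    Invariants: at least one frame; strictly increasing, uniformly spaced
    timestamps; one scale and one image shape throughout.
    """

    frames: tuple[ThermalFrame, ...]
    interval: float = 5.0

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if len(frames) == 0:
            raise ValueError("a ThermalSequence needs at least one frame")
        shape0, scale0 = frames[0].shape, frames[0].scale
        for f in frames[1:]:
            if f.shape != shape0:
                raise ValueError(
                    f"frame dimensions differ within sequence: {f.shape} vs {shape0}"
                )
            if f.scale != scale0:
                raise ValueError("all frames in a sequence must share one scale")
        ts = np.array([f.timestamp for f in frames], dtype=float)
        if len(ts) > 1:
            steps = np.diff(ts)
            if np.any(steps <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(steps, steps[0]):
                raise ValueError("timestamps must be uniformly spaced")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> ThermalFrame:
        return self.frames[i]

    @property
    def scale(self) -> TemperatureScale:
        return self.frames[0].scale

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)

    def volume(self) -> np.ndarray:
        """Stack the gray levels into a float64 array of shape (n, h, w)."""
        return np.stack([f.pixels for f in self.frames]).astype(np.float64)


def gray_to_temperature(frame: ThermalFrame) -> TemperatureField:
    """Convert a frame's gray levels to temperatures.

    ``T(x, y) = t_low + g(x, y) / (2**bit_depth - 1) * (t_high - t_low)``:
    the affine fixed-span radiometric convention.  Output is bounded by
    ``[t_low, t_high]`` because gray levels are bounded by the depth.
    """
    s = frame.scale
    values = s.t_low + frame.pixels.astype(np.float64) / s.max_gray * s.span
    return TemperatureField(values=values, scale=s)


def temperature_to_gray(values: np.ndarray, scale: TemperatureScale) -> np.ndarray:
    """Quantize temperatures (degC) back to gray levels (round-half-even,
    clipped to the representable range)."""
    v = np.asarray(values, dtype=float)
    g = np.rint((v - scale.t_low) / scale.span * scale.max_gray)
    dtype = np.uint8 if scale.bit_depth == 8 else np.uint16
    return np.clip(g, 0, scale.max_gray).astype(dtype)


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse a multi-channel image to single-channel luminance."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        # ITU-R BT.601 luma weights
        lum = rgb @ np.array([0.299, 0.587, 0.114])
        return np.rint(lum).astype(arr.dtype)
    raise ValueError(f"cannot interpret image of shape {arr.shape} as grayscale")


def read_frame(
    path: str | Path,
    scale: TemperatureScale | None = None,
    timestamp: float = 0.0,
) -> ThermalFrame:
    """Read one thermal frame from a TIFF/PNG/JPEG file.

    Multi-channel inputs are converted to luminance before range checks.
    A gray level outside the declared bit depth raises ``ValueError``;
    an unreadable file raises ``OSError``.
    """
    path = Path(path)
    scale = scale or TemperatureScale()
    if not path.exists():
        raise FileNotFoundError(f"no such thermal frame: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise OSError(f"could not decode {path}: {exc}") from exc
    arr = _to_grayscale(np.asarray(arr))
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: expected integer gray levels, got {arr.dtype}")
    hi = int(arr.max())
    if hi > scale.max_gray:
        raise ValueError(
            f"{path}: gray level {hi} exceeds the declared {scale.bit_depth}-bit "
            f"maximum {scale.max_gray}"
        )
    return ThermalFrame(pixels=arr.astype(np.int64), scale=scale, timestamp=timestamp)


def write_frame(frame: ThermalFrame, path: str | Path) -> Path:
    """Write a frame losslessly (TIFF/PNG).  8-bit frames are stored as
    uint8; 10-bit frames in uint16 containers."""
    path = Path(path)
    dtype = np.uint8 if frame.scale.bit_depth == 8 else np.uint16
    arr = frame.pixels.astype(dtype)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    else:
        raise ValueError(f"lossless output requires .tif/.tiff/.png, got {path.name}")
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit image with values {0, 255}."""
    path = Path(path)
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    return path


def load_sequence(
    paths: TypingSequence[str | Path],
    interval: float = 5.0,
    scale: TemperatureScale | None = None,
) -> ThermalSequence:
    """Load ordered frame files into a sequence with timestamps
    ``0, interval, 2*interval, ...`` (minutes)."""
    paths = list(paths)
    if not paths:
        raise ValueError("load_sequence needs at least one path")
    scale = scale or TemperatureScale()
    frames = [
        read_frame(p, scale=scale, timestamp=i * interval) for i, p in enumerate(paths)
    ]
    return ThermalSequence(frames=tuple(frames), interval=interval)
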