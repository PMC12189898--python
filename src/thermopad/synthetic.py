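"""Synthetic warming-pad thermal sequences with exact ground truth.

The generator emulates the inspection protocol the pipeline is built
for: a static camera over a static pad on a cool floor, frames every
5 minutes for an hour, gray levels on a fixed 25-45 degC span at 8 or
10 bits.  Pad pixels warm along an exponential-saturation curve

    T(t) = ambient + (plateau - ambient) * (1 - exp(-t / tau)),

rising from ambient and flattening at the plateau; an optional
serpentine "circuit" overlay adds a few tenths of a degree along
internal heater lines, scaled by the same warming fraction so the
circuit pattern emerges only as the pad approaches full warming.
Independent Gaussian sensor noise is added per frame before
quantization.  Everything is a deterministic function of the scene seed.

Pad shapes are generated analytically (no image assets): an ellipse
(abdominal pad), a U-shaped band (cervical pad), an annulus (patellar
pad), or an arbitrary polygon.

What this emulates — and what it does not: real pads warm with spatial
gradients, the floor picks up conducted heat near the pad rim, and
lossy-compressed cameras add structured block artifacts.  Only the last
is modeled (``degrade_lossy`` JPEG round-trips each frame); passing
tests on these scenes therefore validates the pipeline's mechanics, not
camera physics.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import numpy as np
from scipy import ndimage

from .io import TemperatureScale, ThermalFrame, ThermalSequence, temperature_to_gray
from .sdph import ForegroundMask

__all__ = ["PadScene", "generate_sequence", "degrade_lossy"]

_SHAPES = ("ellipse", "u_band", "annulus", "polygon")


@dataclass(frozen=True)
class PadScene:
    """Parameters of one synthetic inspection scene.

    Defaults describe the standard bench conditions: 26 degC ambient
    room, pad regulating toward 42 degC, warming time constant 15 min
    (≈98% saturated after an hour), sensor noise 0.3 degC — an order of
    magnitude above industrial thermal cameras' stated accuracy, so the
    pipeline is exercised under harder-than-nameplate noise.
    """

    shape: str = "ellipse"
    size: tuple[int, int] = (120, 160)  # (height, width) pixels
    ambient: float = 26.0
    plateau: float = 42.0
    rise_constant: float = 15.0  # minutes
    noise_sd: float = 0.3  # degC per pixel per frame
    circuit_delta: float = 1.5  # degC added along heater lines at full warming
    scale: TemperatureScale = field(default_factory=TemperatureScale)
    seed: int = 0
    polygon: tuple[tuple[float, float], ...] | None = None  # (x, y) vertices

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}, got {self.shape!r}")
        if not self.ambient < self.plateau:
            raise ValueError("require ambient < plateau")
        if self.plateau + self.circuit_delta > self.scale.t_high:
            raise ValueError(
                f"plateau + circuit_delta = {self.plateau + self.circuit_delta} degC "
                f"exceeds the scale's t_high = {self.scale.t_high} degC"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.rise_constant <= 0:
            raise ValueError("rise_constant must be > 0")
        if self.shape == "polygon" and not self.polygon:
            raise ValueError("shape='polygon' needs polygon vertices")

    # ---- geometry -------------------------------------------------------

    def pad_mask(self) -> np.ndarray:
        """Exact boolean ground-truth pad shape, strictly inside the frame."""
        h, w = self.size
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        if self.shape == "ellipse":
            a, b = 0.32 * w, 0.26 * h  # semi-axes (x, y)
            return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        if self.shape in ("annulus", "u_band"):
            r = np.hypot(xx - cx, yy - cy)
            r_out = 0.35 * min(h, w)
            r_in = 0.18 * min(h, w)
            ring = (r >= r_in) & (r <= r_out)
            if self.shape == "annulus":
                return ring
            # U-band: ring with a wedge opening at the top (the neck gap).
            # Angle measured from +x, with +y pointing up in scene terms.
            theta = np.degrees(np.arctan2(-(yy - cy), xx - cx))
            opening = np.abs(theta - 90.0) < 50.0
            return ring & ~opening
        # polygon
        from matplotlib.path import Path as MplPath

        pts = np.column_stack([xx.ravel(), yy.ravel()])
        inside = MplPath(np.asarray(self.polygon)).contains_points(pts)
        return inside.reshape(h, w)

    def circuit_mask(self) -> np.ndarray:
        """Serpentine heater lines: every 8th pixel row, pad interior only."""
        pad = self.pad_mask()
        interior = ndimage.binary_erosion(pad, iterations=4)
        h, w = self.size
        rows = (np.arange(h) % 8) < 2
        return interior & rows[:, None]

    def warming_fraction(self, t_minutes: float) -> float:
        """Saturation fraction ``1 - exp(-t / tau)`` of the warming curve."""
        return 1.0 - float(np.exp(-t_minutes / self.rise_constant))

    def pad_temperature(self, t_minutes: float) -> float:
        """Nominal (noise-free, non-circuit) pad temperature at time t."""
        return self.ambient + (self.plateau - self.ambient) * self.warming_fraction(
            t_minutes
        )


def generate_sequence(
    scene: PadScene, n_frames: int = 13, interval: float = 5.0
) -> tuple[ThermalSequence, ForegroundMask]:
    """Generate a quantized warming sequence and its exact ground truth.

    Frames are at timestamps 0, interval, ..., (n_frames - 1) * interval
    minutes.  Deterministic: a fixed scene (including its seed) yields a
    bit-identical sequence on every call.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(scene.seed)
    pad = scene.pad_mask()
    circuit = scene.circuit_mask()
    s = scene.scale
    frames = []
    for i in range(n_frames):
        t = i * interval
        f = scene.warming_fraction(t)
        temp = np.full(scene.size, scene.ambient, dtype=np.float64)
        temp[pad] += (scene.plateau - scene.ambient) * f
        temp[circuit] += scene.circuit_delta * f
        if scene.noise_sd > 0:
            temp += rng.normal(0.0, scene.noise_sd, size=scene.size)
        np.clip(temp, s.t_low, s.t_high, out=temp)
        frames.append(
            ThermalFrame(pixels=temperature_to_gray(temp, s), scale=s, timestamp=t)
        )
    truth = ForegroundMask(mask=pad, provenance="ground-truth")
    return ThermalSequence(frames=tuple(frames), interval=interval), truth


def degrade_lossy(sequence: ThermalSequence, quality: int = 75) -> ThermalSequence:
    """Round-trip every frame through JPEG at the given quality (1-100),
    emulating a lossy-compression thermal camera.  8-bit sequences only;
    dimensions and timestamps are preserved.
    """
    if sequence.scale.bit_depth != 8:
        raise ValueError(
            "lossy degradation applies to 8-bit sequences only "
            f"(got {sequence.scale.bit_depth}-bit)"
        )
    if not 1 <= quality <= 100:
        raise ValueError(f"quality must be in 1..100, got {quality}")
    from PIL import Image

    frames = []
    for f in sequence.frames:
        buf = _stdio.BytesIO()
        Image.fromarray(f.pixels.astype(np.uint8), mode="L").save(
            buf, format="JPEG", quality=quality
        )
        buf.seek(0)
        decoded = np.asarray(Image.open(buf).convert("L"))
        frames.append(
            ThermalFrame(
                pixels=decoded.astype(np.int64), scale=f.scale, timestamp=f.timestamp
            )
        )
    return ThermalSequence(frames=tuple(frames), interval=sequence.interval)
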