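"""Adapters for conventional background-subtraction methods.

Six stock BGS algorithms (CNT, GMG, GSOC, LSBP, MOG, KNN) can serve as
drop-in alternatives to SDPH for foreground extraction.  They are
third-party implementations reached through OpenCV's ``cv2`` /
``cv2.bgsegm`` backends and are strictly optional: the core pipeline is
self-contained, and when the backend is not installed every entry point
here fails loudly with ``BaselineUnavailableError`` (callers that sweep
several methods should log and record the skip, never pass silently).

Parameters follow the backend defaults except the decision threshold and
the history length (number of frames the model remembers), which are the
two knobs that matter for a static warming scene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .io import ThermalSequence
from .sdph import ForegroundMask

__all__ = [
    "KNOWN_BASELINES",
    "BaselineSpec",
    "BaselineUnavailableError",
    "available_baselines",
    "run_baseline",
]

logger = logging.getLogger(__name__)

KNOWN_BASELINES = ("CNT", "GMG", "GSOC", "LSBP", "MOG", "KNN")


class BaselineUnavailableError(RuntimeError):
    """The requested BGS backend is not installed or lacks the method."""


@dataclass(frozen=True)
class BaselineSpec:
    """One conventional BGS method plus its overrides.

    ``history`` is the frame-memory length (3-10 is the useful range for
    a 13-frame inspection run); ``params`` passes keyword overrides to
    the backend constructor verbatim.
    """

    name: str
    history: int = 10
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        name = self.name.upper()
        if name not in KNOWN_BASELINES:
            raise ValueError(
                f"unknown baseline {self.name!r}; known: {', '.join(KNOWN_BASELINES)}"
            )
        if self.history < 1:
            raise ValueError("history must be >= 1")
        object.__setattr__(self, "name", name)


def _import_cv2():
    try:
        import cv2  # type: ignore
    except ImportError as exc:
        raise BaselineUnavailableError(
            "conventional BGS baselines need OpenCV (install the 'baselines' "
            "extra: pip install thermopad[baselines])"
        ) from exc
    return cv2


def available_baselines() -> tuple[str, ...]:
    """Names of the baselines the installed backend can actually build."""
    try:
        cv2 = _import_cv2()
    except BaselineUnavailableError:
        return ()
    out = []
    for name in KNOWN_BASELINES:
        try:
            _make_subtractor(cv2, BaselineSpec(name=name))
            out.append(name)
        except BaselineUnavailableError:
            continue
    return tuple(out)


def _make_subtractor(cv2, spec: BaselineSpec):
    bgsegm = getattr(cv2, "bgsegm", None)
    try:
        if spec.name == "KNN":
            sub = cv2.createBackgroundSubtractorKNN(
                history=spec.history, **spec.params
            )
            sub.setShadowValue(0)
            return sub
        if bgsegm is None:
            raise AttributeError("cv2.bgsegm missing (opencv-contrib required)")
        if spec.name == "CNT":
            return bgsegm.createBackgroundSubtractorCNT(**spec.params)
        if spec.name == "GMG":
            return bgsegm.createBackgroundSubtractorGMG(
                initializationFrames=spec.history, **spec.params
            )
        if spec.name == "GSOC":
            return bgsegm.createBackgroundSubtractorGSOC(**spec.params)
        if spec.name == "LSBP":
            return bgsegm.createBackgroundSubtractorLSBP(**spec.params)
        if spec.name == "MOG":
            return bgsegm.createBackgroundSubtractorMOG(
                history=spec.history, **spec.params
            )
    except AttributeError as exc:
        raise BaselineUnavailableError(
            f"backend cannot build {spec.name}: {exc}"
        ) from exc
    raise BaselineUnavailableError(f"no constructor for {spec.name}")


def _to_uint8(pixels: np.ndarray, bit_depth: int) -> np.ndarray:
    if bit_depth == 8:
        return pixels.astype(np.uint8)
    # scale 10-bit gray into the 8-bit range the backends expect
    return (pixels.astype(np.float64) * (255.0 / 1023.0)).round().astype(np.uint8)


def run_baseline(
    sequence: ThermalSequence, spec: BaselineSpec
) -> list[ForegroundMask]:
    """Feed the sequence through one conventional BGS method.

    Returns one binary mask per frame (shadow labels collapsed to
    background), provenance ``baseline:<name>``.  The masks are raw;
    route them through the same morphological refinement as SDPH masks
    before scoring.  Raises ``BaselineUnavailableError`` when the backend
    is missing.
    """
    cv2 = _import_cv2()
    sub = _make_subtractor(cv2, spec)
    depth = sequence.scale.bit_depth
    masks = []
    for frame in sequence.frames:
        fg = sub.apply(_to_uint8(frame.pixels, depth))
        masks.append(
            ForegroundMask(mask=fg > 127, provenance=f"baseline:{spec.name}")
        )
    return masks
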