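"""Binary morphology used to repair raw foreground masks.

A raw SDPH mask has a rough boundary and scattered interior holes where
noise pushed single pixels below threshold.  The repair is a fixed
dilation-erosion-dilation schedule: the leading dilations close the
holes, the erosions delete isolated background speckle and shrink the
inflated shape below its original size, and the trailing dilations
restore the size.  The number of leading plus trailing dilations must
equal the number of erosions for the sizes to cancel; the default
schedule is 3 / 6 / 3 with a 3x3 all-ones element.

Definitions are the set-theoretic ones on a binary image embedded in an
infinite background: dilation marks every displacement where the
reflected element overlaps at least one foreground pixel, erosion marks
every displacement where the element fits entirely inside the
foreground.  By default pixels outside the image count as background for
both (so foreground touching the border erodes inward); pass
``border="replicate"`` for the convention in which erosion treats the
outside as foreground, i.e. a full mask stays full.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .sdph import ForegroundMask

__all__ = [
    "StructuringElement",
    "MorphologySchedule",
    "dilate",
    "erode",
    "refine_mask",
]


@dataclass(frozen=True)
class StructuringElement:
    """Odd-square binary neighborhood operator, anchored at its center."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = (np.asarray(self.grid) > 0).astype(bool)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError(f"element must be square, got shape {g.shape}")
        if g.shape[0] % 2 == 0:
            raise ValueError(f"element side must be odd, got {g.shape[0]}")
        if not g.any():
            raise ValueError("element must contain at least one 1")
        object.__setattr__(self, "grid", g)

    @classmethod
    def square(cls, size: int = 3) -> "StructuringElement":
        """All-ones square element of the given odd side (default 3)."""
        return cls(grid=np.ones((size, size), dtype=bool))

    @property
    def size(self) -> int:
        return self.grid.shape[0]


@dataclass(frozen=True)
class MorphologySchedule:
    """Iteration counts for the dilation-erosion-dilation repair.

    Size restoration requires ``dilate_pre + dilate_post == erode``; a
    schedule violating it is accepted with a warning, since a deliberate
    net grow/shrink can be useful.
    """

    dilate_pre: int = 3
    erode: int = 6
    dilate_post: int = 3

    def __post_init__(self) -> None:
        for name in ("dilate_pre", "erode", "dilate_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dilate_pre + self.dilate_post != self.erode:
            warnings.warn(
                f"schedule {self.dilate_pre}/{self.erode}/{self.dilate_post} does "
                "not satisfy dilate_pre + dilate_post == erode; the refined mask "
                "will not preserve object size",
                stacklevel=2,
            )


def _check_border(border: str) -> int:
    if border == "constant":
        return 0
    if border == "replicate":
        return 1
    raise ValueError(f"border must be 'constant' or 'replicate', got {border!r}")


def dilate(
    mask: ForegroundMask,
    element: StructuringElement | None = None,
    iterations: int = 1,
) -> ForegroundMask:
    """Binary dilation, applied ``iterations`` times (0 = no-op).

    Output is 1 at z iff the reflected element placed at z overlaps at
    least one foreground pixel; pixels outside the image are background.
    """
    if iterations < 0:
        raise ValueError(f"iterations must be >= 0, got {iterations}")
    element = element or StructuringElement.square(3)
    out = mask.as_bool()
    if iterations > 0:
        out = ndimage.binary_dilation(
            out, structure=element.grid, iterations=iterations
        )
    return ForegroundMask(mask=out, provenance=mask.provenance)


def erode(
    mask: ForegroundMask,
    element: StructuringElement | None = None,
    iterations: int = 1,
    border: str = "constant",
) -> ForegroundMask:
    """Binary erosion, applied ``iterations`` times (0 = no-op).

    Output is 1 at z iff the element placed at z fits entirely inside the
    foreground.  ``border="constant"`` (default) counts pixels outside
    the image as background, so foreground touching the border erodes;
    ``border="replicate"`` counts them as foreground (a full mask stays
    full, matching common imaging-library behavior).
    """
    if iterations < 0:
        raise ValueError(f"iterations must be >= 0, got {iterations}")
    border_value = _check_border(border)
    element = element or StructuringElement.square(3)
    out = mask.as_bool()
    if iterations > 0:
        out = ndimage.binary_erosion(
            out,
            structure=element.grid,
            iterations=iterations,
            border_value=border_value,
        )
    return ForegroundMask(mask=out, provenance=mask.provenance)


def refine_mask(
    mask: ForegroundMask,
    element: StructuringElement | None = None,
    schedule: MorphologySchedule | None = None,
    border: str = "constant",
) -> ForegroundMask:
    """Dilation-erosion-dilation repair of a raw foreground mask.

    Fills scattered interior holes (leading dilations), removes isolated
    background speckle and restores the original size (erosions followed
    by trailing dilations).
    """
    element = element or StructuringElement.square(3)
    schedule = schedule or MorphologySchedule()
    out = dilate(mask, element, schedule.dilate_pre)
    out = erode(out, element, schedule.erode, border=border)
    out = dilate(out, element, schedule.dilate_post)
    return ForegroundMask(mask=out.mask, provenance="refined")
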