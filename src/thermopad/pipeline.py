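"""End-to-end inspection: sequence in, report bundle out.

Stage order: pixel-history statistics over the trailing window ->
dual-threshold intersection mask -> dilation-erosion-dilation refinement
-> foreground-restricted characteristics traces.  The per-sequence
*measurement mask* defaults to the refined mask of the last frame (the
pad is fully warmed there); the index is a policy knob, not a law.

The pipeline is deterministic: the same configuration and inputs yield
byte-identical CSV and JSON outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .characteristics import (
    DEFAULT_TAU_H,
    ThermalCharacteristics,
    characteristics_table,
    characterize_sequence,
)
from .io import ThermalSequence, write_mask
from .morphology import MorphologySchedule, StructuringElement, refine_mask
from .sdph import (
    ForegroundMask,
    SdphThresholds,
    auto_thresholds,
    pixel_history_stats,
    sdph_mask,
)

__all__ = ["InspectionConfig", "InspectionResult", "inspect_sequence", "write_report"]


@dataclass(frozen=True)
class InspectionConfig:
    """Everything the inspection pipeline needs beyond the sequence itself.

    ``thresholds=None`` means per-run automatic Otsu selection on the
    mean and dispersion images.  ``mask_frame`` indexes the frame whose
    refined mask becomes the measurement mask (negative indices count
    from the end; default -1 = last frame).
    """

    window_n: int = 10
    thresholds: SdphThresholds | None = None
    dispersion_mode: str = "variance"
    element_size: int = 3
    schedule: MorphologySchedule = field(default_factory=MorphologySchedule)
    tau_h: float = DEFAULT_TAU_H
    mask_frame: int = -1

    def __post_init__(self) -> None:
        if self.window_n < 1:
            raise ValueError("window_n must be >= 1")


@dataclass(frozen=True)
class InspectionResult:
    """Report bundle of one inspection run."""

    raw_masks: list[ForegroundMask]  # one per frame from first_index on
    refined_masks: list[ForegroundMask]
    measurement_mask: ForegroundMask
    thresholds_used: list[SdphThresholds]
    records: list[ThermalCharacteristics]
    first_index: int  # first frame index with enough history
    config: InspectionConfig
    sequence: ThermalSequence

    @property
    def final_record(self) -> ThermalCharacteristics:
        return self.records[-1]


def inspect_sequence(
    sequence: ThermalSequence, config: InspectionConfig | None = None
) -> InspectionResult:
    """Run the full inspection pipeline on one sequence.

    Raw and refined SDPH masks are computed for every frame with a full
    trailing window; the measurement mask (refined mask at
    ``config.mask_frame``) is then applied to *every* frame to produce
    the characteristics traces, so warm-up frames are characterized too.
    """
    config = config or InspectionConfig()
    n = len(sequence)
    if n < config.window_n:
        raise ValueError(
            f"the sequence has {n} frames but the pixel-history window needs "
            f"window_n = {config.window_n}"
        )
    first_index = config.window_n - 1
    element = StructuringElement.square(config.element_size)
    raw_masks: list[ForegroundMask] = []
    refined_masks: list[ForegroundMask] = []
    thresholds_used: list[SdphThresholds] = []
    for t in range(first_index, n):
        stats = pixel_history_stats(sequence, t, config.window_n)
        if config.thresholds is not None:
            thr = config.thresholds
        else:
            thr = auto_thresholds(stats, mode=config.dispersion_mode)
        thresholds_used.append(thr)
        raw = sdph_mask(stats, thr)
        raw_masks.append(raw)
        refined_masks.append(refine_mask(raw, element, config.schedule))
    mask_frame = config.mask_frame
    if mask_frame < 0:
        mask_frame += n
    if not first_index <= mask_frame < n:
        raise ValueError(
            f"mask_frame {config.mask_frame} has no refined mask; valid frames "
            f"are {first_index}..{n - 1}"
        )
    measurement_mask = refined_masks[mask_frame - first_index]
    if measurement_mask.area() == 0:
        raise ValueError("no foreground detected at the measurement frame")
    records = characterize_sequence(sequence, measurement_mask, tau_h=config.tau_h)
    return InspectionResult(
        raw_masks=raw_masks,
        refined_masks=refined_masks,
        measurement_mask=measurement_mask,
        thresholds_used=thresholds_used,
        records=records,
        first_index=first_index,
        config=config,
        sequence=sequence,
    )


def _json_safe(x):
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


def summary_dict(result: InspectionResult) -> dict:
    """JSON-ready summary: config echo plus the final-frame characteristics."""
    final = result.final_record
    cfg = result.config
    return {
        "config": {
            "window_n": cfg.window_n,
            "thresholds": (
                "auto"
                if cfg.thresholds is None
                else asdict(cfg.thresholds)
            ),
            "dispersion_mode": cfg.dispersion_mode,
            "element_size": cfg.element_size,
            "schedule": asdict(cfg.schedule),
            "tau_h": cfg.tau_h,
            "mask_frame": cfg.mask_frame,
        },
        "n_frames": len(result.sequence),
        "first_characterized_index": result.first_index,
        "measurement_mask_area_px": result.measurement_mask.area(),
        "final_frame": {
            "timestamp_min": _json_safe(final.timestamp),
            "t_min_c": _json_safe(final.t_min),
            "t_max_c": _json_safe(final.t_max),
            "mean_c": _json_safe(final.mean),
            "variance_c2": _json_safe(final.variance),
            "median_c": _json_safe(final.median),
            "t_dom_c": _json_safe(final.t_dom),
            "area_fraction": _json_safe(final.area_fraction),
            "n_pixels": final.n_pixels,
        },
    }


def write_report(
    result: InspectionResult, out_dir: str | Path, plots: bool = True
) -> Path:
    """Write the report bundle: per-frame raw + refined masks (TIFF, 0/255),
    the characteristics CSV, a JSON summary, and optional trace plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for offset, (raw, ref) in enumerate(zip(result.raw_masks, result.refined_masks)):
        idx = result.first_index + offset
        write_mask(raw.mask, out / f"mask_raw_{idx:03d}.tif")
        write_mask(ref.mask, out / f"mask_refined_{idx:03d}.tif")
    write_mask(result.measurement_mask.mask, out / "mask_measurement.tif")
    table = characteristics_table(result.records)
    table.to_csv(
        out / "characteristics.csv", index=False, float_format="%.6f",
        lineterminator="\n",
    )
    (out / "summary.json").write_text(
        json.dumps(summary_dict(result), indent=2, sort_keys=True) + "\n"
    )
    if plots:
        _write_trace_plots(result, out)
    return out


def _write_trace_plots(result: InspectionResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    recs = [r for r in result.records if not r.empty]
    t = [r.timestamp for r in recs]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(t, [r.mean for r in recs], label="mean")
    ax1.plot(t, [r.median for r in recs], label="median")
    ax1.fill_between(
        t,
        [r.mean - np.sqrt(r.variance) for r in recs],
        [r.mean + np.sqrt(r.variance) for r in recs],
        alpha=0.2,
        label="±1 sd",
    )
    ax1.set_xlabel("time (min)")
    ax1.set_ylabel("temperature (°C)")
    ax1.set_title("foreground uniformity trace")
    ax1.legend()
    ax2.plot(t, [r.t_min for r in recs], label="T_min")
    ax2.plot(t, [r.t_max for r in recs], label="T_max")
    ax2.plot(t, [r.t_dom for r in recs], label="T_dom")
    ax2.set_xlabel("time (min)")
    ax2.set_ylabel("temperature (°C)")
    ax2.set_title("extreme / dominant temperature trace")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(out / "traces.png", dpi=100)
    plt.close(fig)
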