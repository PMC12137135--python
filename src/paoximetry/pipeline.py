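"""End-to-end analysis: unmix -> threshold -> trace -> kinetics -> maps.

`analyze_recording` runs the whole chain in memory; `run_pipeline` wraps it
with file IO for the command line.  `light_dose` carries the treatment dose
arithmetic (fluence rate times exposure).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as pio
from .exceptions import ValidationError
from .kinetics import (
    PDTTimeline,
    ROIMask,
    StO2Trace,
    build_trace,
    detect_active_pdt_end,
    mean_depletion_rate,
)
from .maps import DeltaMap, delta_sto2, reoxygenation_map, split_roi_lateral
from .unmixing import (
    ExtinctionTable,
    FrameStack,
    OximetryMaps,
    apply_threshold,
    compute_oximetry_stack,
    default_extinction_table,
    estimate_noise_floor,
    load_extinction_table,
)

__all__ = ["RunConfig", "PipelineResult", "light_dose", "analyze_recording", "run_pipeline"]

log = logging.getLogger("paoximetry")


def light_dose(fluence_rate_mw_cm2: float, duration_s: float) -> float:
    """Delivered light dose in J/cm^2: fluence rate (mW/cm^2) x time (s).

    15 min at 100 mW/cm^2 gives 90 J; at 400 mW/cm^2, 360 J.
    """
    if fluence_rate_mw_cm2 <= 0 or duration_s <= 0:
        raise ValidationError("fluence rate and duration must be positive")
    return fluence_rate_mw_cm2 / 1000.0 * duration_s


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run (all defaults per protocol)."""

    stack_path: str | Path
    roi_path: str | Path
    out_dir: str | Path
    extinction_path: str | Path | None = None
    filter_order: int = 15
    slope_window: int = 15
    patch_size: int = 20
    rate_duration_s: float = 300.0
    endpoint_rule: str = "argmin"
    threshold_override: float | None = None
    midline_split: bool = False
    seed: int = 0

    SCHEMA_VERSION = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from a versioned YAML file."""
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        version = data.pop("schema_version", cls.SCHEMA_VERSION)
        if version != cls.SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported config schema version {version}"
            )
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        data = {k: v for k, v in asdict(self).items()}
        for key in ("stack_path", "roi_path", "out_dir", "extinction_path"):
            if data[key] is not None:
                data[key] = str(data[key])
        data["schema_version"] = self.SCHEMA_VERSION
        Path(path).write_text(yaml.safe_dump(data))


@dataclass
class PipelineResult:
    """Everything `analyze_recording` produces."""

    maps: list[OximetryMaps]
    threshold: float
    trace: StO2Trace
    delta_active: DeltaMap
    reox: DeltaMap
    summary: dict


def _frame_at(maps: Sequence[OximetryMaps], t: float) -> OximetryMaps:
    times = np.array([m.t for m in maps])
    return maps[int(np.argmin(np.abs(times - t)))]


def _last_before(maps: Sequence[OximetryMaps], t: float) -> OximetryMaps:
    idx = [i for i, m in enumerate(maps) if m.t < t]
    if not idx:
        raise ValidationError("no frames before requested time")
    return maps[idx[-1]]


def analyze_recording(
    stack: FrameStack,
    roi: ROIMask,
    timeline: PDTTimeline,
    ext: ExtinctionTable | None = None,
    *,
    filter_order: int = 15,
    slope_window: int = 15,
    patch_size: int = 20,
    rate_duration_s: float = 300.0,
    threshold_override: float | None = None,
    midline_split: bool = False,
    endpoint_rule: str = "argmin",
) -> PipelineResult:
    """Run the full oximetry-kinetics-mapping chain on one recording."""
    ext = ext or default_extinction_table()
    maps = compute_oximetry_stack(stack, ext)
    if threshold_override is not None:
        threshold = float(threshold_override)
    else:
        threshold = estimate_noise_floor(
            np.stack([m.hbt for m in maps]), patch_size=patch_size
        )
    maps = [apply_threshold(m, threshold) for m in maps]
    masked_frac = float(np.mean([1.0 - m.mask.mean() for m in maps]))
    log.info("threshold %.4g; mean masked fraction %.2f", threshold, masked_frac)

    trace = build_trace(maps, roi, timeline, filter_order=filter_order)
    rate = mean_depletion_rate(trace, duration_s=rate_duration_s, window=slope_window)
    t_active_end = detect_active_pdt_end(trace, rule=endpoint_rule)
    trace.timeline.t_active_end = t_active_end

    pre_light = _last_before(maps, timeline.t_light_on)
    at_active_end = _frame_at(maps, t_active_end)
    final = maps[-1]
    delta_active = delta_sto2(pre_light, at_active_end)
    reox = reoxygenation_map(at_active_end, final)

    roi_valid = roi.mask & reox.mask
    reox_fraction = (
        float((reox.delta[roi_valid] > 0).mean()) if roi_valid.any() else float("nan")
    )

    midline = stack.frames[0].img_750.shape[1] // 2 if midline_split else None
    left, right = split_roi_lateral(roi, midline=midline)
    half_rates = {}
    for half, half_roi in (("left", left), ("right", right)):
        half_trace = build_trace(maps, half_roi, timeline, filter_order=filter_order)
        half_rates[half] = mean_depletion_rate(
            half_trace, duration_s=rate_duration_s, window=slope_window
        )

    baseline_sel = (trace.t >= timeline.t_baseline_start) & (trace.t < timeline.t_light_on)
    summary = {
        "threshold_hbt": threshold,
        "mean_masked_fraction": masked_frac,
        "baseline_sto2_raw_pct": float(np.nanmean(trace.raw[baseline_sel])),
        "baseline_normalized_mean_pct": float(
            np.nanmean(trace.normalized[baseline_sel])
        ),
        "depletion_rate_pct_per_min": rate,
        "depletion_rate_left_pct_per_min": half_rates["left"],
        "depletion_rate_right_pct_per_min": half_rates["right"],
        "t_active_end_s": t_active_end,
        "reox_area_fraction": reox_fraction,
        "n_frames": len(maps),
    }
    return PipelineResult(
        maps=maps,
        threshold=threshold,
        trace=trace,
        delta_active=delta_active,
        reox=reox,
        summary=summary,
    )


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline: read stack/ROI/extinction, analyze, write outputs.

    Writes the trace CSV, milestone JSON, delta/reoxygenation TIFF+PNG maps
    and a summary JSON under ``config.out_dir``; returns the summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, timeline = pio.load_stack(config.stack_path)
    if timeline is None:
        raise ValidationError("stack sidecar carries no treatment timeline")
    roi = pio.load_roi(config.roi_path)
    ext = (
        load_extinction_table(config.extinction_path)
        if config.extinction_path
        else default_extinction_table()
    )
    result = analyze_recording(
        stack,
        roi,
        timeline,
        ext,
        filter_order=config.filter_order,
        slope_window=config.slope_window,
        patch_size=config.patch_size,
        rate_duration_s=config.rate_duration_s,
        threshold_override=config.threshold_override,
        midline_split=config.midline_split,
        endpoint_rule=config.endpoint_rule,
    )
    pio.save_trace_csv(result.trace, out / "trace.csv")
    pio.save_milestones(
        result.trace.timeline,
        out / "milestones.json",
        threshold_hbt=result.threshold,
    )
    pio.save_delta_map(
        result.delta_active, out / "delta_active.tiff", out / "delta_active.png"
    )
    pio.save_delta_map(
        result.reox, out / "reoxygenation.tiff", out / "reoxygenation.png"
    )
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2))
    return result.summary
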