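"""File formats: wavelength-interleaved TIFF stacks, ROI masks, traces, maps.

A recording is stored as a multi-page TIFF with pages interleaved by
wavelength (750, 850, 750, 850, ...) plus a JSON sidecar carrying the frame
times, wavelengths, pixel spacing and treatment timeline.  ROI masks are 0/255
PNGs or run-length JSON.  Traces export to CSV with one row per frame.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .exceptions import ValidationError
from .kinetics import PDTTimeline, ROIMask, StO2Trace
from .maps import DeltaMap
from .unmixing import FramePair, FrameStack, OximetryMaps

__all__ = [
    "save_stack",
    "load_stack",
    "save_roi",
    "load_roi",
    "save_trace_csv",
    "load_trace_csv",
    "save_milestones",
    "load_milestones",
    "save_oximetry",
    "save_delta_map",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_stack(stack: FrameStack, path: str | Path, timeline: PDTTimeline | None = None) -> None:
    """Write a recording as interleaved multi-page TIFF + JSON sidecar."""
    path = Path(path)
    pages = []
    for f in stack.frames:
        pages.append(np.asarray(f.img_750, np.float32))
        pages.append(np.asarray(f.img_850, np.float32))
    tifffile.imwrite(path, np.stack(pages))
    meta = {
        "times_s": [float(f.t) for f in stack.frames],
        "wavelengths_nm": [750, 850],
        "pixel_spacing_mm": list(stack.pixel_spacing_mm),
    }
    if timeline is not None:
        meta["timeline"] = {
            "t_baseline_start": timeline.t_baseline_start,
            "t_light_on": timeline.t_light_on,
            "t_light_off": timeline.t_light_off,
            "t_end": timeline.t_end,
        }
    _sidecar(path).write_text(json.dumps(meta))


def load_stack(path: str | Path) -> tuple[FrameStack, PDTTimeline | None]:
    """Read an interleaved TIFF recording and its sidecar metadata."""
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    n_wl = len(meta["wavelengths_nm"])
    if pages.shape[0] % n_wl:
        raise ValidationError(
            f"page count {pages.shape[0]} not divisible by wavelength count {n_wl}"
        )
    times = meta["times_s"]
    frames = tuple(
        FramePair(
            img_750=pages[n_wl * i].astype(float),
            img_850=pages[n_wl * i + 1].astype(float),
            t=float(times[i]),
        )
        for i in range(pages.shape[0] // n_wl)
    )
    stack = FrameStack(frames=frames, pixel_spacing_mm=tuple(meta["pixel_spacing_mm"]))
    timeline = None
    if "timeline" in meta:
        timeline = PDTTimeline(**meta["timeline"])
    return stack, timeline


def save_roi(roi: ROIMask, path: str | Path) -> None:
    """Write an ROI as a 0/255 PNG or a run-length JSON (by extension)."""
    path = Path(path)
    if path.suffix == ".png":
        iio.imwrite(path, (roi.mask.astype(np.uint8) * 255))
    elif path.suffix == ".json":
        flat = roi.mask.ravel()
        edges = np.flatnonzero(np.diff(np.concatenate([[0], flat, [0]])))
        runs = [[int(s), int(e - s)] for s, e in zip(edges[::2], edges[1::2])]
        path.write_text(
            json.dumps({"shape": list(roi.mask.shape), "runs": runs, "label": roi.label})
        )
    else:
        raise ValidationError(f"unsupported ROI format {path.suffix!r}")


def load_roi(path: str | Path, label: str = "tumor") -> ROIMask:
    path = Path(path)
    if path.suffix == ".png":
        img = np.asarray(iio.imread(path))
        if img.ndim == 3:
            img = img[..., 0]
        return ROIMask(img > 127, label=label)
    if path.suffix == ".json":
        meta = json.loads(path.read_text())
        flat = np.zeros(int(np.prod(meta["shape"])), dtype=bool)
        for start, length in meta["runs"]:
            flat[start : start + length] = True
        return ROIMask(flat.reshape(meta["shape"]), label=meta.get("label", label))
    raise ValidationError(f"unsupported ROI format {path.suffix!r}")


def _segment(t: float, tl: PDTTimeline) -> str:
    if t < tl.t_light_on:
        return "baseline"
    if t < tl.t_light_off:
        return "light"
    return "post"


def save_trace_csv(trace: StO2Trace, path: str | Path) -> None:
    """Per-frame ROI export: t_s, raw/filtered/normalized StO2, HbT, segment."""
    df = pd.DataFrame(
        {
            "t_s": trace.t,
            "raw_sto2": trace.raw,
            "filtered_sto2": trace.filtered,
            "normalized_sto2": trace.normalized,
            "hbt": trace.hbt_raw,
            "segment": [_segment(t, trace.timeline) for t in trace.t],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def load_trace_csv(path: str | Path, timeline: PDTTimeline) -> StO2Trace:
    df = pd.read_csv(path)
    return StO2Trace(
        t=df["t_s"].to_numpy(float),
        raw=df["raw_sto2"].to_numpy(float),
        filtered=df["filtered_sto2"].to_numpy(float),
        normalized=df["normalized_sto2"].to_numpy(float),
        hbt_raw=df["hbt"].to_numpy(float),
        timeline=timeline,
    )


def save_milestones(timeline: PDTTimeline, path: str | Path, **extra: float) -> None:
    data = {
        "t_baseline_start": timeline.t_baseline_start,
        "t_light_on": timeline.t_light_on,
        "t_light_off": timeline.t_light_off,
        "t_end": timeline.t_end,
        "t_active_end": timeline.t_active_end,
    }
    data.update(extra)
    Path(path).write_text(json.dumps(data, indent=2))


def load_milestones(path: str | Path) -> PDTTimeline:
    data = json.loads(Path(path).read_text())
    return PDTTimeline(
        t_baseline_start=data["t_baseline_start"],
        t_light_on=data["t_light_on"],
        t_light_off=data["t_light_off"],
        t_end=data["t_end"],
        t_active_end=data.get("t_active_end"),
    )


def save_oximetry(maps_seq: Sequence[OximetryMaps], path: str | Path) -> None:
    """Per-frame StO2/HbT/mask triplets as a multi-page float TIFF."""
    pages = []
    for m in maps_seq:
        pages += [
            m.sto2.astype(np.float32),
            m.hbt.astype(np.float32),
            m.mask.astype(np.float32),
        ]
    tifffile.imwrite(Path(path), np.stack(pages))
    _sidecar(Path(path)).write_text(
        json.dumps({"times_s": [float(m.t) for m in maps_seq], "channels": ["sto2", "hbt", "mask"]})
    )


def save_delta_map(
    dmap: DeltaMap,
    path_tiff: str | Path,
    path_png: str | Path | None = None,
    background: np.ndarray | None = None,
) -> None:
    """Signed TIFF, plus an optional diverging-colormap PNG overlay."""
    tifffile.imwrite(
        Path(path_tiff),
        np.stack([dmap.delta.astype(np.float32), dmap.mask.astype(np.float32)]),
    )
    if path_png is None:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    if background is not None:
        ax.imshow(background, cmap="gray")
    lim = max(1.0, float(np.abs(dmap.delta[dmap.mask]).max()) if dmap.mask.any() else 1.0)
    overlay = np.ma.masked_where(~dmap.mask, dmap.delta)
    im = ax.imshow(overlay, cmap="bwr_r", vmin=-lim, vmax=lim, alpha=0.85)
    fig.colorbar(im, ax=ax, label=r"$\Delta$StO$_2$ (%)")
    ax.set_axis_off()
    fig.savefig(path_png, dpi=120, bbox_inches="tight")
    plt.close(fig)
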