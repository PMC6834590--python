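"""Reading video stacks and writing tidy result tables, plots and manifests."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .activity import ActivityTrace
from .config import ExperimentConfig
from .sleep import BoutSet, BoutStatistics

__all__ = ["read_video", "write_video", "write_results", "plot_trace_and_bouts"]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


def read_video(path: str | Path) -> np.ndarray:
    """Load a video stack from a multi-page TIFF or a directory of frames.

    Directory frames are read in name order (zero-padded numeric names
    sort correctly); all frames must share one shape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise ValueError(f"no image files in {path}")
        frames = [iio.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"mixed frame shapes: {shapes}")
        return np.stack(frames)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_video(stack: np.ndarray, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF."""
    tifffile.imwrite(Path(path), np.asarray(stack))


def write_results(
    traces: list[ActivityTrace],
    bout_sets: list[BoutSet],
    stats: list[tuple[str, BoutStatistics]],
    out_dir: str | Path,
    config: ExperimentConfig | None = None,
    make_plots: bool = True,
) -> dict[str, Path]:
    """Write tidy CSV tables, a JSON run manifest, and summary plots.

    ``traces.csv`` has one row per frame pair per animal, ``bouts.csv``
    one row per bout, ``stats.csv`` one row per animal.  Reruns with the
    same inputs produce byte-identical tables.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    trace_rows = [
        {
            "animal_id": tr.animal_id,
            "time_s": i / tr.fps,
            "raw": int(tr.raw[i]),
            "normalized": float(tr.normalized[i]),
        }
        for tr in traces
        for i in range(tr.raw.size)
    ]
    traces_csv = out_dir / "traces.csv"
    pd.DataFrame(trace_rows, columns=["animal_id", "time_s", "raw", "normalized"]).to_csv(
        traces_csv, index=False
    )
    written["traces"] = traces_csv

    bout_rows = [
        {"animal_id": bs.animal_id, "start_s": s, "end_s": e}
        for bs in bout_sets
        for s, e in bs.bouts
    ]
    bouts_csv = out_dir / "bouts.csv"
    pd.DataFrame(bout_rows, columns=["animal_id", "start_s", "end_s"]).to_csv(
        bouts_csv, index=False
    )
    written["bouts"] = bouts_csv

    stat_rows = [
        {
            "animal_id": animal_id,
            "total_sleep_s": st.total_sleep_s,
            "sleep_fraction": st.sleep_fraction,
            "onset_s": st.onset_s,
            "n_bouts": len(st.sleep_bout_lengths_s),
            "mean_sleep_bout_s": (
                float(np.mean(st.sleep_bout_lengths_s)) if st.sleep_bout_lengths_s else None
            ),
            "mean_wake_bout_s": (
                float(np.mean(st.wake_bout_lengths_s)) if st.wake_bout_lengths_s else None
            ),
        }
        for animal_id, st in stats
    ]
    stats_csv = out_dir / "stats.csv"
    pd.DataFrame(
        stat_rows,
        columns=[
            "animal_id",
            "total_sleep_s",
            "sleep_fraction",
            "onset_s",
            "n_bouts",
            "mean_sleep_bout_s",
            "mean_wake_bout_s",
        ],
    ).to_csv(stats_csv, index=False)
    written["stats"] = stats_csv

    from . import __version__

    manifest = {
        "software": "wormstate",
        "version": __version__,
        "config": asdict(config) if config is not None else None,
        "n_animals": len(traces),
    }
    manifest_json = out_dir / "manifest.json"
    manifest_json.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = manifest_json

    if make_plots and traces:
        written["plot"] = plot_trace_and_bouts(traces, bout_sets, out_dir / "raster.png")
    return written


def plot_trace_and_bouts(
    traces: list[ActivityTrace], bout_sets: list[BoutSet], path: str | Path
) -> Path:
    """Activity traces with detected bouts shaded, plus a bout raster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_animal = {bs.animal_id: bs for bs in bout_sets}
    fig, axes = plt.subplots(
        len(traces) + 1, 1, figsize=(8, 1.6 * (len(traces) + 1)), sharex=True
    )
    axes = np.atleast_1d(axes)
    for ax, tr in zip(axes, traces):
        ax.plot(tr.times_s / 60, tr.normalized, lw=0.5, color="k")
        for s, e in by_animal.get(tr.animal_id, BoutSet(tr.animal_id, [], 1, 1, 0, 0)).bouts:
            ax.axvspan(s / 60, e / 60, color="tab:blue", alpha=0.3, lw=0)
        ax.set_ylabel(tr.animal_id, fontsize=8)
    raster = axes[-1]
    for row, tr in enumerate(traces):
        for s, e in by_animal.get(tr.animal_id, BoutSet(tr.animal_id, [], 1, 1, 0, 0)).bouts:
            raster.barh(row, (e - s) / 60, left=s / 60, height=0.8, color="tab:blue")
    raster.set_xlabel("time (min)")
    raster.set_ylabel("animal")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
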