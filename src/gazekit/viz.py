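"""Static visualization of gaze data and detected events.

All renderers are pure functions: the same inputs always produce the same
scene. Each returns a small *scene* dictionary describing what was drawn
(marker coordinates, counts, grids) so tests can assert on structure rather
than raster pixels, and writes a PNG when an output path is given.

Plot kinds
----------
``fixation_plot``       numbered circles at fixation centroids, radius
                        proportional to duration, over an optional stimulus
                        image.
``heatmap``             contour plot of a Gaussian-smoothed 2D histogram of
                        gaze; bin counts are (n_rows/4, n_cols/4) of the
                        image dimensions.
``aggregate_heatmap``   per-subject histograms summed *before* smoothing,
                        with a sidecar text file listing the subjects.
``ms_position_velocity`` x/y position and velocity traces of one fixation
                        with detected microsaccade runs shaded.
``main_sequence``       scatter of peak velocity against amplitude across
                        (micro)saccades.
``dynamic_frames``      a frame-sequence stand-in for the animated
                        gaze-and-pupil view: one PNG per decimated step.

The smoothing sigma (default 2 bins) and the colormap ('jet') are fixed
package choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.ndimage import gaussian_filter

from . import events as ev
from .io_bridge import TrialTable

__all__ = ["HeatmapGrid", "compute_heatmap_grid", "render_plot"]

DEFAULT_SIGMA = 2.0
CMAP = "jet"


@dataclass
class HeatmapGrid:
    counts: np.ndarray  # pre-smoothing 2D histogram (rows = y bins)
    smoothed: np.ndarray
    image_dims: tuple[int, int]  # (n_rows, n_cols)
    n_dropped: int  # off-screen or missing samples excluded


def compute_heatmap_grid(
    x: np.ndarray,
    y: np.ndarray,
    image_dims: tuple[int, int],
    sigma: float = DEFAULT_SIGMA,
) -> HeatmapGrid:
    """2D gaze histogram with floor(n_rows/4) x floor(n_cols/4) bins over
    the image extent, Gaussian-smoothed. Off-screen and missing samples are
    dropped and counted."""
    n_rows, n_cols = image_dims
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("empty gaze trace")
    keep = (
        np.isfinite(x) & np.isfinite(y) & (x >= 0) & (x <= n_cols) & (y >= 0) & (y <= n_rows)
    )
    counts, _, _ = np.histogram2d(
        y[keep],
        x[keep],
        bins=(n_rows // 4, n_cols // 4),
        range=[[0, n_rows], [0, n_cols]],
    )
    smoothed = gaussian_filter(counts, sigma=sigma)
    return HeatmapGrid(counts, smoothed, (n_rows, n_cols), int((~keep).sum()))


def _finish(fig, out_path: str | Path | None) -> None:
    if out_path is not None:
        fig.savefig(out_path, dpi=100)
    plt.close(fig)


def _maybe_image(ax, stimulus_image, dims):
    if stimulus_image is not None:
        ax.imshow(stimulus_image, extent=[0, dims[1], dims[0], 0], alpha=0.7)


def render_plot(
    kind: str,
    out_path: str | Path | None = None,
    *,
    fixations: list[ev.Fixation] | None = None,
    gaze: ev.GazeTrace | None = None,
    gaze_by_subject: dict[str, ev.GazeTrace] | None = None,
    saccades: list[ev.Saccade] | None = None,
    microsaccades: list[ev.Microsaccade] | None = None,
    trial: TrialTable | None = None,
    stimulus_image: np.ndarray | None = None,
    image_dims: tuple[int, int] = (1024, 1280),
    sigma: float = DEFAULT_SIGMA,
    decimation: int = 100,
    max_frames: int = 50,
) -> dict:
    """Render one plot kind; returns the scene model (and writes a PNG
    plus any sidecar files when ``out_path`` is given)."""
    if kind == "fixation_plot":
        if fixations is None:
            raise ValueError("fixation_plot needs fixations")
        fig, ax = plt.subplots(figsize=(8, 6))
        _maybe_image(ax, stimulus_image, image_dims)
        durations = [f.duration for f in fixations]
        dmax = max(durations) if durations else 1.0
        markers = []
        for i, f in enumerate(fixations, start=1):
            r = 8.0 + 30.0 * (f.duration / dmax if dmax else 0.0)
            ax.add_patch(
                plt.Circle(
                    (f.centroid_x, f.centroid_y), r, color="green", alpha=0.4
                )
            )
            ax.annotate(str(i), (f.centroid_x, f.centroid_y), ha="center", va="center")
            markers.append(
                {"number": i, "x": f.centroid_x, "y": f.centroid_y, "radius": r}
            )
        ax.set_xlim(0, image_dims[1])
        ax.set_ylim(image_dims[0], 0)
        ax.set_xlabel("x [px]")
        ax.set_ylabel("y [px]")
        _finish(fig, out_path)
        return {"kind": kind, "markers": markers}

    if kind == "heatmap":
        if gaze is None:
            raise ValueError("heatmap needs gaze")
        grid = compute_heatmap_grid(gaze.x, gaze.y, image_dims, sigma)
        fig, ax = plt.subplots(figsize=(8, 6))
        _maybe_image(ax, stimulus_image, image_dims)
        ax.contourf(
            np.linspace(0, image_dims[1], grid.smoothed.shape[1]),
            np.linspace(0, image_dims[0], grid.smoothed.shape[0]),
            grid.smoothed,
            levels=12,
            cmap=CMAP,
            alpha=0.6,
        )
        ax.set_ylim(image_dims[0], 0)
        _finish(fig, out_path)
        return {"kind": kind, "grid": grid}

    if kind == "aggregate_heatmap":
        if not gaze_by_subject:
            raise ValueError("aggregate_heatmap needs gaze_by_subject")
        total = None
        dropped = 0
        for g in gaze_by_subject.values():
            grid = compute_heatmap_grid(g.x, g.y, image_dims, sigma)
            total = grid.counts if total is None else total + grid.counts
            dropped += grid.n_dropped
        smoothed = gaussian_filter(total, sigma=sigma)
        agg = HeatmapGrid(total, smoothed, image_dims, dropped)
        subjects = sorted(gaze_by_subject)
        fig, ax = plt.subplots(figsize=(8, 6))
        _maybe_image(ax, stimulus_image, image_dims)
        ax.contourf(
            np.linspace(0, image_dims[1], smoothed.shape[1]),
            np.linspace(0, image_dims[0], smoothed.shape[0]),
            smoothed,
            levels=12,
            cmap=CMAP,
            alpha=0.6,
        )
        ax.set_ylim(image_dims[0], 0)
        _finish(fig, out_path)
        if out_path is not None:
            sidecar = Path(out_path).with_suffix(".txt")
            sidecar.write_text("\n".join(subjects) + "\n")
        return {"kind": kind, "grid": agg, "subjects": subjects}

    if kind == "ms_position_velocity":
        if gaze is None or microsaccades is None:
            raise ValueError("ms_position_velocity needs gaze and microsaccades")
        vx = ev.compute_ms_velocity(gaze.x, gaze.sampling_freq)
        vy = ev.compute_ms_velocity(gaze.y, gaze.sampling_freq)
        fig, axes = plt.subplots(2, 2, figsize=(10, 6), sharex=True)
        panels = [
            (gaze.x, "x position [px]"),
            (gaze.y, "y position [px]"),
            (vx, "x velocity"),
            (vy, "y velocity"),
        ]
        shaded = [(m.onset_ms, m.offset_ms) for m in microsaccades]
        for ax, (series, label) in zip(axes.ravel(), panels):
            ax.plot(gaze.t, series, lw=0.8)
            for a, b in shaded:
                ax.axvspan(a, b, color="red", alpha=0.2)
            ax.set_ylabel(label)
        _finish(fig, out_path)
        return {"kind": kind, "shaded_spans": shaded, "n_panels": 4}

    if kind == "main_sequence":
        evs = list(microsaccades or []) + list(saccades or [])
        if not evs:
            raise ValueError("main_sequence needs saccades or microsaccades")
        amp = [e.amplitude for e in evs]
        vpk = [e.peak_velocity for e in evs]
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.loglog(amp, vpk, "o", ms=4)
        ax.set_xlabel("amplitude [px]")
        ax.set_ylabel("peak velocity")
        _finish(fig, out_path)
        return {"kind": kind, "amplitude": amp, "peak_velocity": vpk}

    if kind == "dynamic_frames":
        if trial is None:
            raise ValueError("dynamic_frames needs a trial")
        from .events import DetectionConfig, gaze_trace_from_trial, pupil_trace_from_trial

        cfg = DetectionConfig()
        g = gaze_trace_from_trial(trial, cfg)
        p = pupil_trace_from_trial(trial, cfg)
        steps = list(range(0, len(g.t), max(1, decimation)))[:max_frames]
        files = []
        for k, i in enumerate(steps):
            if out_path is not None:
                out = Path(out_path)
                out.mkdir(parents=True, exist_ok=True)
                fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
                _maybe_image(ax1, stimulus_image, image_dims)
                if np.isfinite(g.x[i]):
                    ax1.plot(g.x[i], g.y[i], "ro", ms=8)
                ax1.set_xlim(0, image_dims[1])
                ax1.set_ylim(image_dims[0], 0)
                ax2.plot(p.t[: i + 1], p.values[: i + 1], lw=0.8)
                ax2.set_xlabel("time [ms]")
                ax2.set_ylabel("pupil size")
                fname = out / f"frame_{k:04d}.png"
                fig.savefig(fname, dpi=80)
                plt.close(fig)
                files.append(fname)
        return {"kind": kind, "n_frames": len(steps), "files": files}

    raise ValueError(f"unknown plot kind {kind!r}")
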