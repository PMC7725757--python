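"""Oculomotor event detection.

Four detectors operating on per-sample gaze and pupil series:

* **Blinks** — noise-based onset/offset refinement: missing-pupil runs give
  initial boundaries; the smoothed pupil signal's monotonic flanks extend
  the blink backward into the descent and forward into the recovery.
* **Fixations** — dispersion-threshold identification (I-DT): a window of at
  least ``W_thresh`` grows while its dispersion
  ``D = sqrt((max x - min x)^2 + (max y - min y)^2)`` stays within
  ``D_thresh``; the grown window (excluding the breaking sample) is a
  fixation.
* **Saccades** — velocity-threshold identification (I-VT): pointwise
  velocity ``V_t = G_t - G_{t-1}`` (converted to px/s by multiplying with
  the sampling frequency); samples faster than the threshold are saccadic,
  consecutive ones merge into a saccade.
* **Microsaccades** — the Engbert-Kliegl median-threshold scheme within a
  fixation: a 5-tap moving-average velocity, a per-axis threshold of
  ``V_fac`` times the median absolute deviation from the median (in the
  root-median-square form), and an elliptic criterion
  ``k = (Vx/Vx_thr)^2 + (Vy/Vy_thr)^2 > 1`` sustained for a minimum run of
  samples.

Saccades and microsaccades both report a peak velocity
``V_peak = max sqrt(Vx^2 + Vy^2)`` and an amplitude equal to the dispersion
of the event's gaze points (one shared implementation).

Eye selection: traces are built from a binocular trial by averaging left and
right where both are valid, falling back to whichever eye is valid
(configurable to a single eye). Samples inside detected blinks are masked
out before gaze-based detection, since lost gaze corrupts dispersion and
velocity estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_bridge import TrialTable

__all__ = [
    "DetectionConfig",
    "GazeTrace",
    "PupilTrace",
    "VelocityTrace",
    "Blink",
    "Fixation",
    "Saccade",
    "Microsaccade",
    "DegenerateVelocityError",
    "gaze_trace_from_trial",
    "pupil_trace_from_trial",
    "smooth_pupil",
    "detect_blinks",
    "compute_dispersion",
    "detect_fixations_idt",
    "detect_saccades_ivt",
    "compute_ms_velocity",
    "compute_ms_threshold",
    "detect_microsaccades",
    "events_to_frame",
]


class DegenerateVelocityError(ValueError):
    """Median velocity threshold is zero; skip microsaccade detection here."""


@dataclass(frozen=True)
class DetectionConfig:
    """Detector thresholds and units.

    w_thresh_ms
        Minimum fixation duration / initial I-DT window, milliseconds.
    d_thresh_px
        I-DT dispersion threshold, pixels (not stated by the method's
        source; repo default 25 px, tune to viewing geometry).
    ivt_vel_thresh
        I-VT point-velocity threshold, pixels/second.
    v_fac
        Multiplier on the median-based velocity spread for the
        microsaccade threshold (unitless).
    ms_min_samples
        Minimum run length of supra-threshold samples for a microsaccade.
    blink_smooth_window_ms
        Moving-average window for the pupil signal before blink boundary
        refinement, milliseconds.
    eye
        'left', 'right' or 'average' (average of valid eyes).
    engbert_units
        If True, scale the moving-average velocity by S_freq^2, restoring
        the original units-per-second convention of the microsaccade
        literature. Detection is unaffected (the criterion is scale-free);
        only reported peak velocities change.
    """

    w_thresh_ms: float = 50.0
    d_thresh_px: float = 25.0
    ivt_vel_thresh: float = 40.0
    v_fac: float = 5.0
    ms_min_samples: int = 6
    blink_smooth_window_ms: float = 10.0
    eye: str = "average"
    engbert_units: bool = False

    def __post_init__(self):
        for name in (
            "w_thresh_ms",
            "d_thresh_px",
            "ivt_vel_thresh",
            "v_fac",
            "ms_min_samples",
            "blink_smooth_window_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.eye not in ("left", "right", "average"):
            raise ValueError("eye must be 'left', 'right' or 'average'")


@dataclass
class GazeTrace:
    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    sampling_freq: float
    eye: str = "average"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.t)):
            raise ValueError("gaze trace arrays must have equal length")


@dataclass
class PupilTrace:
    values: np.ndarray
    t: np.ndarray
    sampling_freq: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if len(self.values) != len(self.t):
            raise ValueError("pupil trace arrays must have equal length")

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass
class VelocityTrace:
    vx: np.ndarray
    vy: np.ndarray
    t: np.ndarray


@dataclass
class Blink:
    onset_index: int
    offset_index: int
    onset_ms: float
    offset_ms: float

    @property
    def duration(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class Fixation:
    onset_index: int
    offset_index: int
    onset_ms: float
    offset_ms: float
    centroid_x: float
    centroid_y: float

    @property
    def duration(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class Saccade:
    onset_index: int
    offset_index: int
    onset_ms: float
    offset_ms: float
    peak_velocity: float
    amplitude: float

    @property
    def duration(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class Microsaccade(Saccade):
    pass


def _combine_eyes(left: np.ndarray, right: np.ndarray, eye: str) -> np.ndarray:
    if eye == "left":
        return left.astype(float)
    if eye == "right":
        return right.astype(float)
    stacked = np.vstack([left, right]).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(stacked, axis=0)


def gaze_trace_from_trial(trial: TrialTable, cfg: DetectionConfig) -> GazeTrace:
    s = trial.samples
    x = _combine_eyes(
        s["gaze_left_x"].to_numpy(float), s["gaze_right_x"].to_numpy(float), cfg.eye
    )
    y = _combine_eyes(
        s["gaze_left_y"].to_numpy(float), s["gaze_right_y"].to_numpy(float), cfg.eye
    )
    return GazeTrace(x, y, trial.timestamps, trial.sampling_freq, cfg.eye)


def pupil_trace_from_trial(trial: TrialTable, cfg: DetectionConfig) -> PupilTrace:
    s = trial.samples
    p = _combine_eyes(
        s["pupil_left"].to_numpy(float), s["pupil_right"].to_numpy(float), cfg.eye
    )
    return PupilTrace(p, trial.timestamps, trial.sampling_freq)


# ---------------------------------------------------------------------------
# blinks
# ---------------------------------------------------------------------------


def smooth_pupil(values: np.ndarray, sampling_freq: float, window_ms: float) -> np.ndarray:
    """Centered moving average over ``window_ms``, ignoring missing samples."""
    win = max(1, int(round(window_ms * sampling_freq / 1000.0)))
    return (
        pd.Series(np.asarray(values, dtype=float))
        .rolling(win, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), stops.tolist()))


def detect_blinks(pupil: PupilTrace, cfg: DetectionConfig) -> list[Blink]:
    """Noise-based blink detection with onset/offset refinement.

    For each missing-pupil run the last valid sample before and first valid
    sample after are the initial onset/offset. The pupil series is smoothed
    with a moving average; the onset then moves backward while the smoothed
    values keep increasing backward in time (the descending flank seen
    forward), and the offset moves forward while the smoothed values keep
    increasing forward (the recovery flank). Refinement only ever widens
    the window. Overlapping refined windows merge.
    """
    miss = pupil.missing
    n = len(pupil.values)
    if not miss.any():
        return []
    if miss.all():
        warnings.warn("pupil trace entirely missing; one blink spans the trace")
        return [Blink(0, n - 1, float(pupil.t[0]), float(pupil.t[-1]))]
    smoothed = smooth_pupil(pupil.values, pupil.sampling_freq, cfg.blink_smooth_window_ms)
    blinks: list[tuple[int, int]] = []
    for a, b in _bool_runs(miss):
        onset = max(a - 1, 0)
        offset = min(b + 1, n - 1)
        j = onset
        while j > 0 and np.isfinite(smoothed[j - 1]) and smoothed[j - 1] > smoothed[j]:
            j -= 1
        onset = j
        j = offset
        while j < n - 1 and np.isfinite(smoothed[j + 1]) and smoothed[j + 1] > smoothed[j]:
            j += 1
        offset = j
        blinks.append((onset, offset))
    blinks.sort()
    merged = [blinks[0]]
    for a, b in blinks[1:]:
        pa, pb = merged[-1]
        if a <= pb:
            merged[-1] = (pa, max(pb, b))
        else:
            merged.append((a, b))
    return [Blink(a, b, float(pupil.t[a]), float(pupil.t[b])) for a, b in merged]


# ---------------------------------------------------------------------------
# fixations (I-DT)
# ---------------------------------------------------------------------------


def compute_dispersion(x: np.ndarray, y: np.ndarray) -> float:
    """Dispersion of a gaze window: root of squared x-range plus squared
    y-range. Doubles as the amplitude of a (micro)saccade's gaze points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("dispersion of an empty window is undefined")
    return float(
        np.sqrt(
            (np.max(x) - np.min(x)) ** 2 + (np.max(y) - np.min(y)) ** 2
        )
    )


def _valid_segments(x: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive index ranges where both coordinates are finite."""
    return _bool_runs(np.isfinite(x) & np.isfinite(y))


def detect_fixations_idt(gaze: GazeTrace, cfg: DetectionConfig) -> list[Fixation]:
    """Dispersion-threshold fixation identification.

    The window starts at ``W_thresh`` samples and grows by one sample while
    its dispersion stays <= ``D_thresh`` (ties grow). When the dispersion
    exceeds the threshold, the window excluding the breaking sample is a
    fixation and the next window starts at that breaking sample. If even
    the initial window exceeds the threshold its start slides by one
    sample. A window reaching the end of the data is emitted as a
    fixation. Runs interrupted by missing gaze (masked blinks) are
    processed independently.
    """
    w = max(2, int(round(cfg.w_thresh_ms * gaze.sampling_freq / 1000.0)))
    x, y, t = gaze.x, gaze.y, gaze.t
    fixations: list[Fixation] = []
    for s0, s1 in _valid_segments(x, y):
        e = s1 + 1  # exclusive
        i = s0
        while i + w <= e:
            if compute_dispersion(x[i : i + w], y[i : i + w]) > cfg.d_thresh_px:
                i += 1
                continue
            j = i + w
            emitted_end = None
            while j < e:
                j += 1
                if compute_dispersion(x[i:j], y[i:j]) > cfg.d_thresh_px:
                    emitted_end = j - 1  # exclude the breaking sample
                    break
            if emitted_end is None:
                emitted_end = e
            fixations.append(
                Fixation(
                    i,
                    emitted_end - 1,
                    float(t[i]),
                    float(t[emitted_end - 1]),
                    float(np.mean(x[i:emitted_end])),
                    float(np.mean(y[i:emitted_end])),
                )
            )
            i = emitted_end
    return fixations


# ---------------------------------------------------------------------------
# saccades (I-VT)
# ---------------------------------------------------------------------------


def detect_saccades_ivt(gaze: GazeTrace, cfg: DetectionConfig) -> list[Saccade]:
    """Velocity-threshold saccade identification.

    The pointwise velocity ``G_t - G_{t-1}`` (px/sample) times the sampling
    frequency gives px/s; samples strictly faster than the threshold are
    saccadic and consecutive saccadic samples merge into one saccade whose
    onset is the sample before the first saccadic one.
    """
    x, y, t = gaze.x, gaze.y, gaze.t
    if len(x) < 2:
        return []
    vx = np.diff(x) * gaze.sampling_freq
    vy = np.diff(y) * gaze.sampling_freq
    speed = np.hypot(vx, vy)  # speed[k] belongs to sample k+1
    # round to 1e-6 px/s, far below any tracker's resolution, so samples
    # moving at exactly the threshold speed are not misclassified by
    # floating-point construction noise
    speed = np.round(speed, 6)
    sacc = np.zeros(speed.shape, dtype=bool)
    finite = np.isfinite(speed)
    sacc[finite] = speed[finite] > cfg.ivt_vel_thresh
    out = []
    for a, b in _bool_runs(sacc):
        i0, i1 = a, b + 1  # gaze sample indices of the movement
        out.append(
            Saccade(
                i0,
                i1,
                float(t[i0]),
                float(t[i1]),
                float(np.max(speed[a : b + 1])),
                compute_dispersion(x[i0 : i1 + 1], y[i0 : i1 + 1]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# microsaccades (median velocity threshold)
# ---------------------------------------------------------------------------


def compute_ms_velocity(
    g: np.ndarray, sampling_freq: float, engbert_units: bool = False
) -> np.ndarray:
    """5-tap moving-average velocity ``(G_{t+2}+G_{t+1}-G_{t-1}-G_{t-2}) /
    (6 S_freq)``; the first and last two samples are zero.

    ``engbert_units=True`` multiplies by S_freq^2, i.e. uses
    ``S_freq/6`` as the stencil scale, the convention of the original
    microsaccade literature. The detection criterion is invariant to this
    uniform rescaling.
    """
    g = np.asarray(g, dtype=float)
    n = len(g)
    if n < 5:
        raise ValueError("moving-average velocity needs at least 5 samples")
    v = np.zeros(n)
    v[2:-2] = (g[4:] + g[3:-1] - g[1:-3] - g[:-4]) / (6.0 * sampling_freq)
    if engbert_units:
        v = v * sampling_freq**2
    return v


def compute_ms_threshold(v: np.ndarray, v_fac: float) -> float:
    """Median-based velocity threshold for one axis:
    ``V_fac * sqrt(median((V - median(V))^2))``."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("empty velocity vector")
    med = np.median(v)
    spread = np.sqrt(np.median((v - med) ** 2))
    thresh = v_fac * spread
    if not np.isfinite(thresh) or thresh <= 0:
        raise DegenerateVelocityError(
            "velocity spread is zero or undefined; skip microsaccade "
            "detection for this fixation"
        )
    return float(thresh)


def detect_microsaccades(gaze: GazeTrace, cfg: DetectionConfig) -> list[Microsaccade]:
    """Median-threshold microsaccade detection within one fixation segment.

    ``k = (Vx/Vx_thr)^2 + (Vy/Vy_thr)^2``; maximal runs with ``k > 1``
    lasting at least ``ms_min_samples`` are microsaccades. A degenerate
    (zero-spread) threshold yields an empty list with a warning.
    """
    x, y, t = gaze.x, gaze.y, gaze.t
    if len(x) < 5 + cfg.ms_min_samples:
        return []
    vx = compute_ms_velocity(x, gaze.sampling_freq, cfg.engbert_units)
    vy = compute_ms_velocity(y, gaze.sampling_freq, cfg.engbert_units)
    try:
        tx = compute_ms_threshold(vx, cfg.v_fac)
        ty = compute_ms_threshold(vy, cfg.v_fac)
    except DegenerateVelocityError as exc:
        warnings.warn(str(exc))
        return []
    k = (vx / tx) ** 2 + (vy / ty) ** 2
    out = []
    for a, b in _bool_runs(k > 1):
        if b - a + 1 < cfg.ms_min_samples:
            continue
        speed = np.hypot(vx[a : b + 1], vy[a : b + 1])
        out.append(
            Microsaccade(
                a,
                b,
                float(t[a]),
                float(t[b]),
                float(np.max(speed)),
                compute_dispersion(x[a : b + 1], y[a : b + 1]),
            )
        )
    return out


def events_to_frame(events: dict[str, list]) -> pd.DataFrame:
    """Flatten detected events into one tidy table (one row per event)."""
    rows = []
    for kind, evs in events.items():
        for ev in evs:
            row = {
                "kind": kind,
                "onset_ms": ev.onset_ms,
                "offset_ms": ev.offset_ms,
                "duration_ms": ev.duration,
            }
            if isinstance(ev, Fixation):
                row["centroid_x"] = ev.centroid_x
                row["centroid_y"] = ev.centroid_y
            if isinstance(ev, Saccade):
                row["peak_velocity"] = ev.peak_velocity
                row["amplitude"] = ev.amplitude
            rows.append(row)
    return pd.DataFrame(rows)
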