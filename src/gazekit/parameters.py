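"""Per-trial parameter extraction.

One trial yields exactly 21 scalar eye-movement parameters spanning five
families — pupillometry (4), blinks (3), fixations (3), saccades (4),
microsaccades (4) and reading behavior (3) — computed from detected events
and the interpolated pupil series. An optional area of interest restricts
the fixation family (membership by centroid) and defines the reading
parameters; control-stimulus normalization subtracts each subject's mean
control value per parameter.

Pupil statistics are computed over the post-stimulus-onset window (onset =
the trial's stimulus-onset message, else the first sample); the area under
the pupil curve is the trapezoidal integral of the raw interpolated series
in pupil-units x ms, with no baseline subtraction — cross-condition
comparability is delegated to control normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, replace

import numpy as np

from . import events as ev
from .aoi import AOISpec, contains_point
from .io_bridge import TrialTable

__all__ = [
    "PARAMETER_NAMES",
    "ParameterSet",
    "interpolate_pupil",
    "pupil_parameters",
    "aggregate_event_parameters",
    "reading_parameters",
    "extract_parameter_set",
    "normalize_with_controls",
]

PARAMETER_NAMES = [
    "pupil_mean",
    "pupil_peak",
    "pupil_time_to_peak",
    "pupil_auc",
    "blink_count",
    "blink_peak_duration",
    "blink_mean_duration",
    "fixation_count",
    "fixation_max_duration",
    "fixation_mean_duration",
    "saccade_count",
    "saccade_mean_duration",
    "saccade_mean_velocity",
    "saccade_mean_amplitude",
    "ms_count",
    "ms_mean_duration",
    "ms_mean_velocity",
    "ms_mean_amplitude",
    "reading_count",
    "first_pass_duration",
    "second_pass_duration",
]


@dataclass
class ParameterSet:
    """The 21 named per-trial scalars plus subject/stimulus labels."""

    subject: str
    stimulus: str
    pupil_mean: float = 0.0
    pupil_peak: float = 0.0
    pupil_time_to_peak: float = 0.0
    pupil_auc: float = 0.0
    blink_count: float = 0.0
    blink_peak_duration: float = 0.0
    blink_mean_duration: float = 0.0
    fixation_count: float = 0.0
    fixation_max_duration: float = 0.0
    fixation_mean_duration: float = 0.0
    saccade_count: float = 0.0
    saccade_mean_duration: float = 0.0
    saccade_mean_velocity: float = 0.0
    saccade_mean_amplitude: float = 0.0
    ms_count: float = 0.0
    ms_mean_duration: float = 0.0
    ms_mean_velocity: float = 0.0
    ms_mean_amplitude: float = 0.0
    reading_count: float = 0.0
    first_pass_duration: float = 0.0
    second_pass_duration: float = 0.0

    def values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


assert [f.name for f in fields(ParameterSet)][2:] == PARAMETER_NAMES


def interpolate_pupil(pupil: ev.PupilTrace, blinks: list[ev.Blink]) -> np.ndarray:
    """Fill blink windows (and any residual gaps) by linear interpolation.

    Inside each blink the values strictly between the refined onset and
    offset samples are replaced by the line joining them; leading/trailing
    gaps take the nearest valid value. The returned series has no missing
    values and equals the raw series outside blink windows.
    """
    p = pupil.values.astype(float).copy()
    for b in blinks:
        p[b.onset_index + 1 : b.offset_index] = np.nan
    valid = np.isfinite(p)
    if not valid.any():
        raise ValueError("no valid pupil samples to interpolate from")
    idx = np.arange(len(p))
    return np.interp(idx, idx[valid], p[valid])


def pupil_parameters(
    interp: np.ndarray, t: np.ndarray, onset_ms: float
) -> tuple[float, float, float, float]:
    """(mean, peak, time-to-peak ms, trapezoidal AUC) over the post-onset
    window."""
    t = np.asarray(t, dtype=float)
    if onset_ms > t[-1]:
        raise ValueError("onset lies after the end of the trace")
    sel = t >= onset_ms
    y, tt = np.asarray(interp, dtype=float)[sel], t[sel]
    mean = float(np.mean(y))
    peak_i = int(np.argmax(y))
    peak = float(y[peak_i])
    time_to_peak = float(tt[peak_i] - onset_ms)
    auc = float(np.trapezoid(y, tt))
    return mean, peak, time_to_peak, auc


def _family_stats(durations: list[float]) -> tuple[float, float, float]:
    """(count, max, mean) with zeros for an empty family."""
    if not durations:
        return 0.0, 0.0, 0.0
    return float(len(durations)), float(max(durations)), float(np.mean(durations))


def aggregate_event_parameters(
    blinks: list[ev.Blink],
    fixations: list[ev.Fixation],
    saccades: list[ev.Saccade],
    microsaccades: list[ev.Microsaccade],
    aoi: AOISpec | None = None,
) -> dict[str, float]:
    """Counts and per-family duration/velocity/amplitude aggregates.

    With an AOI, the fixation family is restricted to fixations whose
    centroid falls inside it. Empty families report zeros.
    """
    if aoi is not None:
        fixations = [
            f for f in fixations if contains_point(aoi, (f.centroid_x, f.centroid_y))
        ]
    out: dict[str, float] = {}
    n, peak, mean = _family_stats([b.duration for b in blinks])
    out.update(blink_count=n, blink_peak_duration=peak, blink_mean_duration=mean)
    n, mx, mean = _family_stats([f.duration for f in fixations])
    out.update(
        fixation_count=n, fixation_max_duration=mx, fixation_mean_duration=mean
    )
    for prefix, evs in (("saccade", saccades), ("ms", microsaccades)):
        n = float(len(evs))
        out[f"{prefix}_count"] = n
        out[f"{prefix}_mean_duration"] = (
            float(np.mean([e.duration for e in evs])) if evs else 0.0
        )
        out[f"{prefix}_mean_velocity"] = (
            float(np.mean([e.peak_velocity for e in evs])) if evs else 0.0
        )
        out[f"{prefix}_mean_amplitude"] = (
            float(np.mean([e.amplitude for e in evs])) if evs else 0.0
        )
    return out


def reading_parameters(
    fixations: list[ev.Fixation], aoi: AOISpec
) -> tuple[float, float, float]:
    """Readings are maximal runs of consecutive fixations whose centroids
    lie inside the AOI. Returns (reading count, first-pass duration,
    second-pass duration), passes summing member fixation durations."""
    if aoi is None:
        raise ValueError("reading parameters require an AOI")
    runs: list[float] = []
    in_run = False
    for f in fixations:
        if contains_point(aoi, (f.centroid_x, f.centroid_y)):
            if not in_run:
                runs.append(0.0)
                in_run = True
            runs[-1] += f.duration
        else:
            in_run = False
    first = runs[0] if len(runs) > 0 else 0.0
    second = runs[1] if len(runs) > 1 else 0.0
    return float(len(runs)), float(first), float(second)


def detect_all_events(
    trial: TrialTable, cfg: ev.DetectionConfig
) -> dict[str, list]:
    """Run the full detection cascade: blinks, blink-masked gaze, fixations,
    saccades, then microsaccades within each fixation."""
    pupil = ev.pupil_trace_from_trial(trial, cfg)
    blinks = ev.detect_blinks(pupil, cfg)
    gaze = ev.gaze_trace_from_trial(trial, cfg)
    for b in blinks:
        gaze.x[b.onset_index : b.offset_index + 1] = np.nan
        gaze.y[b.onset_index : b.offset_index + 1] = np.nan
    fixations = ev.detect_fixations_idt(gaze, cfg)
    saccades = ev.detect_saccades_ivt(gaze, cfg)
    microsaccades: list[ev.Microsaccade] = []
    for f in fixations:
        a, b = f.onset_index, f.offset_index
        if b - a + 1 < 5 + cfg.ms_min_samples:
            continue
        segment = ev.GazeTrace(
            gaze.x[a : b + 1], gaze.y[a : b + 1], gaze.t[a : b + 1],
            gaze.sampling_freq, gaze.eye,
        )
        for m in ev.detect_microsaccades(segment, cfg):
            microsaccades.append(
                replace(m, onset_index=m.onset_index + a, offset_index=m.offset_index + a)
            )
    return {
        "blink": blinks,
        "fixation": fixations,
        "saccade": saccades,
        "microsaccade": microsaccades,
        "_pupil": pupil,
    }


def extract_parameter_set(
    trial: TrialTable,
    cfg: ev.DetectionConfig | None = None,
    aoi: AOISpec | None = None,
) -> ParameterSet:
    """Full pipeline for one trial: detection cascade, pupil interpolation,
    then all 21 parameters. Without an AOI the reading parameters are 0."""
    cfg = cfg or ev.DetectionConfig()
    detected = detect_all_events(trial, cfg)
    pupil: ev.PupilTrace = detected["_pupil"]
    interp = interpolate_pupil(pupil, detected["blink"])
    mean, peak, ttp, auc = pupil_parameters(interp, pupil.t, trial.onset_ms())
    agg = aggregate_event_parameters(
        detected["blink"],
        detected["fixation"],
        detected["saccade"],
        detected["microsaccade"],
        aoi,
    )
    if aoi is not None:
        n_read, first, second = reading_parameters(detected["fixation"], aoi)
    else:
        n_read = first = second = 0.0
    return ParameterSet(
        subject=trial.subject_id,
        stimulus=trial.stimulus_name,
        pupil_mean=mean,
        pupil_peak=peak,
        pupil_time_to_peak=ttp,
        pupil_auc=auc,
        reading_count=n_read,
        first_pass_duration=first,
        second_pass_duration=second,
        **agg,
    )


def normalize_with_controls(
    sets: list[ParameterSet],
    control_stimuli: list[str],
    mode: str = "subtract",
) -> list[ParameterSet]:
    """Normalize each subject's non-control trials against that subject's
    mean over control trials — subtraction by default, ratio behind
    ``mode='ratio'``. Control trials are dropped from the output."""
    if mode not in ("subtract", "ratio"):
        raise ValueError("mode must be 'subtract' or 'ratio'")
    controls = set(control_stimuli)
    by_subject: dict[str, list[ParameterSet]] = {}
    for s in sets:
        by_subject.setdefault(s.subject, []).append(s)
    out: list[ParameterSet] = []
    for subject, trials in by_subject.items():
        ctrl = [s for s in trials if s.stimulus in controls]
        rest = [s for s in trials if s.stimulus not in controls]
        if not ctrl:
            raise ValueError(f"subject {subject!r} has no control trial")
        baseline = {
            name: float(np.mean([getattr(c, name) for c in ctrl]))
            for name in PARAMETER_NAMES
        }
        for s in rest:
            if mode == "subtract":
                normed = {n: getattr(s, n) - baseline[n] for n in PARAMETER_NAMES}
            else:
                normed = {
                    n: (getattr(s, n) / baseline[n]) if baseline[n] != 0 else np.nan
                    for n in PARAMETER_NAMES
                }
            out.append(replace(s, **normed))
    if not out:
        warnings.warn("all trials are controls; normalized output is empty")
    out.sort(key=lambda s: (s.subject, s.stimulus))
    return out
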