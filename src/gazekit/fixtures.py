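"""Synthetic eye-tracking data with planted, recorded ground truth.

This module fabricates trials (gaze + pupil sample series), vendor-dialect
text files, and whole experiment folders so that every other module is
testable without recorded data. Events are *planted* from an explicit plan
and the realized sample indices are echoed back, so detector output can be
scored against known truth.

What the generator emulates:

* fixations — gaze parked at a centroid (plus isotropic Gaussian jitter);
* saccades — a raised-cosine displacement from start to end, so velocity
  peaks mid-movement and larger amplitudes have larger peak velocities
  (main-sequence structure);
* microsaccades — a small out-and-back raised-cosine excursion nested
  inside a fixation, with a configurable amplitude and direction and a
  duration of at least six samples;
* blinks — a missing-pupil (and missing-gaze) gap flanked by a ~20 ms
  monotonic pupil descent before and ascent after, the structure the
  noise-based blink refinement exploits;
* pupil dynamics — a constant baseline, optionally a Gaussian bump (for
  time-to-peak recovery) and additive Gaussian noise.

It does not emulate smooth pursuit, measurement drift, binocular
disconjugacy (both eyes are written identical) or vendor-specific artifact
patterns. Values are quantised (integer-ms timestamps, 4-decimal gaze and
pupil) so text round-trips are lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_bridge import BASE_COLUMNS, ONSET_MARKER, TrialTable, write_base_csv

__all__ = [
    "PlannedEvent",
    "EventPlan",
    "GroundTruth",
    "generate_trial",
    "write_vendor_export",
    "make_synthetic_experiment",
    "default_trial_plan",
]

SUPPORTED_FREQS = (250, 500, 1000)
BLINK_FLANK_MS = 20.0  # pupil descent/ascent on either side of the gap
BLINK_DEPTH = 0.4  # fraction of baseline lost at the gap edge
DEFAULT_SCREEN = (1280, 1024)


@dataclass
class PlannedEvent:
    kind: str  # fixation | saccade | microsaccade | blink
    onset_ms: float
    duration_ms: float
    centroid: tuple[float, float] | None = None  # fixation
    start: tuple[float, float] | None = None  # saccade
    end: tuple[float, float] | None = None  # saccade
    amplitude_px: float | None = None  # microsaccade
    direction_deg: float = 0.0  # microsaccade
    pupil_delta: float = 0.0  # additive pupil modulation during the event

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass
class EventPlan:
    duration_ms: float
    events: list[PlannedEvent] = field(default_factory=list)
    pupil_baseline: float = 1000.0
    pupil_bump: tuple[float, float, float] | None = None  # (time_ms, amp, width_ms)
    gaze_noise_sd: float = 0.5
    pupil_noise_sd: float = 2.0
    start_pos: tuple[float, float] = (640.0, 512.0)

    def validate(self, sampling_freq: float) -> None:
        dt = 1000.0 / sampling_freq
        top = sorted(
            (e for e in self.events if e.kind != "microsaccade"),
            key=lambda e: e.onset_ms,
        )
        for e in self.events:
            if e.onset_ms < 0 or e.offset_ms > self.duration_ms:
                raise ValueError(f"event {e.kind} at {e.onset_ms} ms outside trial")
            if e.kind == "fixation" and e.centroid is None:
                raise ValueError("fixation needs a centroid")
            if e.kind == "saccade" and e.end is None:
                raise ValueError("saccade needs an end position")
            if e.kind == "microsaccade":
                if e.amplitude_px is None:
                    raise ValueError("microsaccade needs an amplitude")
                if e.duration_ms < 6 * dt:
                    raise ValueError("microsaccade must span at least 6 samples")
                host = [
                    f
                    for f in self.events
                    if f.kind == "fixation"
                    and f.onset_ms <= e.onset_ms
                    and e.offset_ms <= f.offset_ms
                ]
                if not host:
                    raise ValueError("microsaccade must nest inside a fixation")
        for a, b in zip(top, top[1:]):
            if b.onset_ms < a.offset_ms:
                raise ValueError(
                    f"overlapping events: {a.kind}@{a.onset_ms} and {b.kind}@{b.onset_ms}"
                )


@dataclass
class GroundTruth:
    """The plan echoed with realized sample index ranges per event."""

    plan: EventPlan
    sampling_freq: float
    events: list[dict] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[dict]:
        return [e for e in self.events if e["kind"] == kind]


def _raised_cosine(n: int) -> np.ndarray:
    """Monotone 0->1 profile over n samples with zero endpoint slope."""
    u = np.linspace(0.0, 1.0, n)
    return (1.0 - np.cos(np.pi * u)) / 2.0


def generate_trial(
    plan: EventPlan,
    sampling_freq: float,
    seed: int,
    subject_id: str = "s01",
    stimulus_name: str = "stim",
) -> tuple[TrialTable, GroundTruth]:
    """Realize a plan as a base-format trial, deterministically per seed."""
    if sampling_freq not in SUPPORTED_FREQS:
        raise ValueError(f"sampling_freq must be one of {SUPPORTED_FREQS}")
    plan.validate(sampling_freq)
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sampling_freq
    n = int(round(plan.duration_ms / dt))
    t = np.arange(n) * dt

    def span(e: PlannedEvent) -> tuple[int, int]:
        a = int(round(e.onset_ms / dt))
        b = a + max(1, int(round(e.duration_ms / dt))) - 1
        return a, min(b, n - 1)

    x = np.empty(n)
    y = np.empty(n)
    pos = np.array(plan.start_pos, dtype=float)
    truth = GroundTruth(plan, sampling_freq)
    # lay down top-level gaze events in temporal order; gaps hold position
    cursor = 0
    for e in sorted(
        (e for e in plan.events if e.kind in ("fixation", "saccade")),
        key=lambda ev: ev.onset_ms,
    ):
        a, b = span(e)
        x[cursor:a] = pos[0]
        y[cursor:a] = pos[1]
        if e.kind == "fixation":
            cx, cy = e.centroid
            x[a : b + 1] = cx
            y[a : b + 1] = cy
            pos = np.array([cx, cy])
        else:
            p0 = np.array(e.start, dtype=float) if e.start is not None else pos
            p1 = np.array(e.end, dtype=float)
            prof = _raised_cosine(b - a + 1)
            x[a : b + 1] = p0[0] + (p1[0] - p0[0]) * prof
            y[a : b + 1] = p0[1] + (p1[1] - p0[1]) * prof
            pos = p1
        cursor = b + 1
        truth.events.append(
            {"kind": e.kind, "onset_index": a, "offset_index": b, "plan": e}
        )
    x[cursor:] = pos[0]
    y[cursor:] = pos[1]

    # nested microsaccades: monotone raised-cosine excursion whose range
    # equals the amplitude; gaze stays displaced until the fixation ends
    for e in (e for e in plan.events if e.kind == "microsaccade"):
        a, b = span(e)
        host_end = next(
            span(f)[1]
            for f in plan.events
            if f.kind == "fixation"
            and f.onset_ms <= e.onset_ms
            and e.offset_ms <= f.offset_ms
        )
        excursion = e.amplitude_px * _raised_cosine(b - a + 1)
        th = np.deg2rad(e.direction_deg)
        x[a : b + 1] += excursion * np.cos(th)
        y[a : b + 1] += excursion * np.sin(th)
        x[b + 1 : host_end + 1] += e.amplitude_px * np.cos(th)
        y[b + 1 : host_end + 1] += e.amplitude_px * np.sin(th)
        truth.events.append(
            {"kind": "microsaccade", "onset_index": a, "offset_index": b, "plan": e}
        )

    # pupil: baseline + bump + per-event modulation
    p = np.full(n, plan.pupil_baseline)
    if plan.pupil_bump is not None:
        bt, amp, width = plan.pupil_bump
        p = p + amp * np.exp(-0.5 * ((t - bt) / width) ** 2)
    for e in plan.events:
        if e.pupil_delta and e.kind != "blink":
            a, b = span(e)
            p[a : b + 1] += e.pupil_delta

    # noise before blink gaps so gaps stay exactly missing
    if plan.gaze_noise_sd > 0:
        x = x + rng.normal(0.0, plan.gaze_noise_sd, n)
        y = y + rng.normal(0.0, plan.gaze_noise_sd, n)
    if plan.pupil_noise_sd > 0:
        p = p + rng.normal(0.0, plan.pupil_noise_sd, n)

    # blinks: monotone flanks then a missing gap (gaze lost too)
    flank = max(1, int(round(BLINK_FLANK_MS / dt)))
    for e in (e for e in plan.events if e.kind == "blink"):
        a, b = span(e)
        fa = max(0, a - flank)
        down = _raised_cosine(a - fa + 1) * BLINK_DEPTH * plan.pupil_baseline
        p[fa : a + 1] = p[fa : a + 1] - down
        fb = min(n - 1, b + flank)
        up = _raised_cosine(fb - b + 1)[::-1] * BLINK_DEPTH * plan.pupil_baseline
        p[b : fb + 1] = p[b : fb + 1] - up
        p[a : b + 1] = np.nan
        x[a : b + 1] = np.nan
        y[a : b + 1] = np.nan
        # physiological blink truth spans the flanks; the gap itself is
        # recorded separately (this is what the refinement should recover)
        truth.events.append(
            {
                "kind": "blink",
                "onset_index": fa,
                "offset_index": fb,
                "gap_onset_index": a,
                "gap_offset_index": b,
                "plan": e,
            }
        )

    x, y, p = (np.round(v, 4) for v in (x, y, p))
    p = np.where(np.isfinite(p), np.maximum(p, 0.0), np.nan)
    messages = [""] * n
    messages[0] = f"{ONSET_MARKER} {stimulus_name}"
    df = pd.DataFrame(
        {
            "timestamp": t,
            "gaze_left_x": x,
            "gaze_left_y": y,
            "gaze_right_x": x,
            "gaze_right_y": y,
            "pupil_left": p,
            "pupil_right": p,
            "event_flag": ["none"] * n,
            "message": messages,
        },
        columns=BASE_COLUMNS,
    )
    truth.events.sort(key=lambda e: e["onset_index"])
    return TrialTable(subject_id, stimulus_name, df, sampling_freq), truth


# ---------------------------------------------------------------------------
# vendor writers (inverse of the format bridge)
# ---------------------------------------------------------------------------


def _fmt(v: float) -> str:
    return "." if not np.isfinite(v) else format(v, ".10g")


def _write_eyelink(trial: TrialTable, fh) -> None:
    fh.write("** EYELINK-STYLE ASCII EXPORT\n")
    s = trial.samples
    t0 = s["timestamp"].iloc[0]
    fh.write(f"MSG {_num(t0)} TRIALID {trial.stimulus_name}\n")
    fh.write(f"START {_num(t0)}\n")
    for _, row in s.iterrows():
        if row["message"]:
            fh.write(f"MSG {_num(row['timestamp'])} {row['message']}\n")
        toks = [
            _num(row["timestamp"]),
            _fmt(row["gaze_left_x"]),
            _fmt(row["gaze_left_y"]),
            _fmt(row["pupil_left"]),
            _fmt(row["gaze_right_x"]),
            _fmt(row["gaze_right_y"]),
            _fmt(row["pupil_right"]),
        ]
        if row["event_flag"] != "none":
            toks.append(str(row["event_flag"]).upper())
        fh.write(" ".join(toks) + "\n")
    fh.write(f"END {_num(s['timestamp'].iloc[-1])}\n")


def _num(v: float) -> str:
    return format(float(v), ".10g")


def _smi_num(v: float) -> str:
    return "0.0000" if not np.isfinite(v) else format(v, ".10g")


def _write_smi(trial: TrialTable, fh) -> None:
    fh.write("## SMI-STYLE TEXT EXPORT\n")
    fh.write(
        "Time\tType\tL POR X [px]\tL POR Y [px]\tR POR X [px]\tR POR Y [px]"
        "\tL Pupil [px]\tR Pupil [px]\n"
    )
    s = trial.samples
    t0 = s["timestamp"].iloc[0]
    fh.write(f"{_num(t0)}\tMSG\t# Message: TRIALID {trial.stimulus_name}\n")
    for _, row in s.iterrows():
        if row["message"]:
            fh.write(f"{_num(row['timestamp'])}\tMSG\t# Message: {row['message']}\n")
        fh.write(
            "\t".join(
                [
                    _num(row["timestamp"]),
                    "SMP",
                    _smi_num(row["gaze_left_x"]),
                    _smi_num(row["gaze_left_y"]),
                    _smi_num(row["gaze_right_x"]),
                    _smi_num(row["gaze_right_y"]),
                    _smi_num(row["pupil_left"]),
                    _smi_num(row["pupil_right"]),
                ]
            )
            + "\n"
        )


_TOBII_FLAG_OUT = {"none": "Unclassified", "fixation": "Fixation", "saccade": "Saccade", "blink": "Blink"}


def _write_tobii(trial: TrialTable, fh) -> None:
    import csv

    writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
    writer.writerow(
        [
            "RecordingTimestamp",
            "GazePointXLeft",
            "GazePointYLeft",
            "GazePointXRight",
            "GazePointYRight",
            "PupilLeft",
            "PupilRight",
            "GazeEventType",
            "StudioEvent",
        ]
    )
    s = trial.samples
    writer.writerow(["", "", "", "", "", "", "", "", f"TRIALID {trial.stimulus_name}"])

    def cell(v):
        return "" if not np.isfinite(v) else format(v, ".10g")

    for _, row in s.iterrows():
        msg = row["message"]
        writer.writerow(
            [
                _num(row["timestamp"]),
                cell(row["gaze_left_x"]),
                cell(row["gaze_left_y"]),
                cell(row["gaze_right_x"]),
                cell(row["gaze_right_y"]),
                cell(row["pupil_left"]),
                cell(row["pupil_right"]),
                _TOBII_FLAG_OUT[row["event_flag"]],
                msg,
            ]
        )


_WRITERS = {"eyelink": _write_eyelink, "smi": _write_smi, "tobii": _write_tobii}


def write_vendor_export(
    trials: TrialTable | list[TrialTable], vendor: str, path: str | Path
) -> Path:
    """Write one or more trials as a vendor-dialect text file, parseable by
    :func:`gazekit.io_bridge.convert_vendor_export` with lossless round-trip."""
    if vendor not in _WRITERS:
        raise ValueError(f"unknown vendor {vendor!r}")
    if isinstance(trials, TrialTable):
        trials = [trials]
    for trial in trials:
        if len(trial.samples) == 0:
            raise ValueError("refusing to write a trial with no samples")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if vendor == "tobii":
            # single shared header; trials delimited by TRIALID rows
            import csv as _csv

            first = True
            for trial in trials:
                if first:
                    _write_tobii(trial, fh)
                    first = False
                else:
                    writer = _csv.writer(fh, delimiter="\t", lineterminator="\n")
                    writer.writerow(
                        ["", "", "", "", "", "", "", "", f"TRIALID {trial.stimulus_name}"]
                    )
                    _write_tobii_body(trial, fh)
        else:
            for trial in trials:
                _WRITERS[vendor](trial, fh)
    return path


def _write_tobii_body(trial: TrialTable, fh) -> None:
    import csv

    writer = csv.writer(fh, delimiter="\t", lineterminator="\n")

    def cell(v):
        return "" if not np.isfinite(v) else format(v, ".10g")

    for _, row in trial.samples.iterrows():
        msg = row["message"]
        writer.writerow(
            [
                _num(row["timestamp"]),
                cell(row["gaze_left_x"]),
                cell(row["gaze_left_y"]),
                cell(row["gaze_right_x"]),
                cell(row["gaze_right_y"]),
                cell(row["pupil_left"]),
                cell(row["pupil_right"]),
                _TOBII_FLAG_OUT[row["event_flag"]],
                msg,
            ]
        )


# ---------------------------------------------------------------------------
# whole experiments
# ---------------------------------------------------------------------------


def default_trial_plan(
    duration_ms: float = 3000.0,
    pupil_baseline: float = 1000.0,
    gaze_noise_sd: float = 0.5,
    with_microsaccade: bool = True,
) -> EventPlan:
    """A standard scene: fixation -> saccade -> fixation (hosting one
    microsaccade) -> blink -> fixation, with a pupil bump at 600 ms."""
    events = [
        PlannedEvent("fixation", 0, 800, centroid=(400, 300)),
        PlannedEvent("saccade", 800, 60, start=(400, 300), end=(800, 600)),
        PlannedEvent("fixation", 860, 1040, centroid=(800, 600)),
        PlannedEvent("blink", 1900, 120),
        PlannedEvent("fixation", 2020, 980, centroid=(800, 600)),
    ]
    if with_microsaccade:
        # hosted by the final fixation: its window has no saccade tail, so
        # the excursion does not push the I-DT dispersion past threshold
        events.append(
            PlannedEvent(
                "microsaccade", 2500, 14, amplitude_px=8.0, direction_deg=30.0
            )
        )
    return EventPlan(
        duration_ms=duration_ms,
        events=events,
        pupil_baseline=pupil_baseline,
        pupil_bump=(600.0, 60.0, 150.0),
        gaze_noise_sd=gaze_noise_sd,
        pupil_noise_sd=2.0,
    )


def make_synthetic_experiment(
    out_dir: str | Path,
    n_subjects_per_group: int = 3,
    groups: tuple[str, ...] = ("group1", "group2"),
    stimuli_per_group: dict[str, list[str]] | None = None,
    control_stimuli: list[str] | None = None,
    seed: int = 0,
    sampling_freq: float = 1000,
    screen: tuple[int, int] = DEFAULT_SCREEN,
    group_pupil_delta: dict[str, float] | None = None,
) -> tuple[Path, Path]:
    """Emit a whole experiment: base-format CSV trials under ``data/`` plus
    an ``experiment.json`` config.

    Every subject sees every stimulus. ``group_pupil_delta`` injects a
    per-group additive shift of the pupil baseline (the recorded group
    effect); ``control_stimuli`` names stimuli used downstream for
    control normalization. Returns (experiment dir, config path).
    """
    out_dir = Path(out_dir)
    data_dir = out_dir / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    if stimuli_per_group is None:
        stimuli_per_group = {
            "type_a": ["stim_a1", "stim_a2", "stim_a3"],
            "type_b": ["stim_b1", "stim_b2", "stim_b3"],
        }
    if not groups or not stimuli_per_group:
        raise ValueError("need at least one subject group and one stimulus")
    control_stimuli = list(control_stimuli or [])
    all_stimuli = [s for stims in stimuli_per_group.values() for s in stims]
    for c in control_stimuli:
        if c not in all_stimuli:
            raise ValueError(f"control stimulus {c!r} not among stimuli")
    group_pupil_delta = group_pupil_delta or {}
    rng = np.random.default_rng(seed)

    subjects: dict[str, dict[str, dict]] = {}
    counter = 1
    for g in groups:
        subjects[g] = {}
        for _ in range(n_subjects_per_group):
            name = f"s{counter:02d}"
            if name in {s for grp in subjects.values() for s in grp}:
                raise ValueError(f"duplicate subject name {name}")
            subjects[g][name] = {
                "Age": int(rng.integers(19, 40)),
                "Eyesight": "normal",
            }
            counter += 1

    for g, subs in subjects.items():
        delta = float(group_pupil_delta.get(g, 0.0))
        for subj in subs:
            for stim in all_stimuli:
                plan = default_trial_plan(pupil_baseline=1000.0 + delta)
                trial_seed = int(
                    rng.integers(0, 2**31 - 1)
                )  # drawn in deterministic order
                trial, _ = generate_trial(
                    plan, sampling_freq, trial_seed, subj, stim
                )
                write_base_csv(trial, data_dir)

    config = {
        "Experiment_name": out_dir.name,
        "Subjects": subjects,
        "Stimuli": stimuli_per_group,
        "Control": control_stimuli,
        "Analysis_Params": {
            "EyeTracker": {
                "Sampling_Freq": sampling_freq,
                "Display_width": screen[0],
                "Display_height": screen[1],
            }
        },
    }
    config_path = out_dir / "experiment.json"
    config_path.write_text(json.dumps(config, indent=2))
    return out_dir, config_path
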