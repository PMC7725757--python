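"""Whole-experiment orchestration from a JSON config.

The experiment config is a single JSON document::

    {
      "Experiment_name": "demo",
      "Subjects": {
        "group1": {"s01": {"Age": 23, "Eyesight": "normal"}, ...},
        "group2": {...}
      },
      "Stimuli": {"type_a": ["stim_a1", ...], "type_b": [...]},
      "Control": ["stim_a1"],
      "Analysis_Params": {
        "EyeTracker": {
          "Sampling_Freq": 1000,
          "Display_width": 1280,
          "Display_height": 1024
        },
        "Detection": {"d_thresh_px": 25, ...}          # optional overrides
      },
      "Store_mode": "csv"                               # optional
    }

Subject attributes (Age, Eyesight, gender, ...) are surfaced as candidate
between-subject factors for the statistics stage. Removing a subject or
stimulus from the JSON removes it from every output.

``run_experiment`` executes the pipeline on a folder of base-format CSV
trials: build store -> extract the 21 parameters for every subject x
stimulus -> optional control normalization -> parameter CSV export ->
statistical tests -> plots, writing a deterministic artifact tree plus a
run log carrying a hash of the config.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

from .aoi import AOISpec
from .events import DetectionConfig
from .io_bridge import build_store, query_trials

__all__ = ["ExperimentConfig", "ConfigError", "load_config", "run_experiment"]

ALL_ACTIONS = ("extract", "normalize", "analyze", "export", "visualize")


class ConfigError(ValueError):
    """Config schema violation; the message names the offending JSON path."""


@dataclass
class ExperimentConfig:
    name: str
    subjects: dict[str, dict[str, dict]]  # group -> subject -> attributes
    stimuli: dict[str, list[str]]  # group -> stimulus names
    control: list[str]
    sampling_freq: float
    screen: tuple[int, int]  # (width, height) px
    store_mode: str = "csv"
    detection_overrides: dict = field(default_factory=dict)

    def all_subjects(self) -> list[str]:
        return sorted(s for grp in self.subjects.values() for s in grp)

    def all_stimuli(self) -> list[str]:
        return sorted(s for stims in self.stimuli.values() for s in stims)

    def subject_group(self, subject: str) -> str:
        for g, subs in self.subjects.items():
            if subject in subs:
                return g
        raise KeyError(subject)

    def stimulus_group(self, stimulus: str) -> str:
        for g, stims in self.stimuli.items():
            if stimulus in stims:
                return g
        raise KeyError(stimulus)

    def subject_attributes(self, subject: str) -> dict:
        return dict(self.subjects[self.subject_group(subject)][subject])

    def detection_config(self) -> DetectionConfig:
        valid = {f.name for f in dc_fields(DetectionConfig)}
        bad = set(self.detection_overrides) - valid
        if bad:
            raise ConfigError(f"Analysis_Params.Detection: unknown key(s) {sorted(bad)}")
        return DetectionConfig(**self.detection_overrides)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "name": self.name,
                "subjects": self.subjects,
                "stimuli": self.stimuli,
                "control": self.control,
                "sampling_freq": self.sampling_freq,
                "screen": list(self.screen),
                "store_mode": self.store_mode,
                "detection": self.detection_overrides,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_KNOWN_KEYS = {
    "Experiment_name",
    "Subjects",
    "Stimuli",
    "Control",
    "Analysis_Params",
    "Store_mode",
    "Path",
}


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate an experiment JSON; errors name the offending
    JSON path, unknown keys warn."""
    path = Path(path)
    raw = json.loads(path.read_text())
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        warnings.warn(f"{path}: ignoring unknown top-level key(s) {sorted(unknown)}")
    for key in ("Subjects", "Stimuli", "Analysis_Params"):
        if key not in raw:
            raise ConfigError(f"{key}: required field missing")
    subjects = raw["Subjects"]
    if not isinstance(subjects, dict) or not subjects:
        raise ConfigError("Subjects: must be a non-empty group mapping")
    seen: dict[str, str] = {}
    for g, subs in subjects.items():
        if not isinstance(subs, dict):
            raise ConfigError(f"Subjects.{g}: must map subject -> attributes")
        for s in subs:
            if s in seen:
                raise ConfigError(
                    f"Subjects.{g}.{s}: duplicate subject (also in {seen[s]})"
                )
            seen[s] = g
    stimuli = raw["Stimuli"]
    if not isinstance(stimuli, dict) or not stimuli:
        raise ConfigError("Stimuli: must be a non-empty group mapping")
    all_stimuli = [s for stims in stimuli.values() for s in stims]
    if len(set(all_stimuli)) != len(all_stimuli):
        raise ConfigError("Stimuli: duplicate stimulus across groups")
    control = raw.get("Control", [])
    for c in control:
        if c not in all_stimuli:
            raise ConfigError(f"Control: stimulus {c!r} not among Stimuli")
    ap = raw["Analysis_Params"]
    tracker = ap.get("EyeTracker")
    if tracker is None:
        raise ConfigError("Analysis_Params.EyeTracker: required field missing")
    if "Sampling_Freq" not in tracker:
        raise ConfigError("Analysis_Params.EyeTracker.Sampling_Freq: required field missing")
    for k in ("Display_width", "Display_height"):
        if k not in tracker:
            raise ConfigError(f"Analysis_Params.EyeTracker.{k}: required field missing")
    return ExperimentConfig(
        name=raw.get("Experiment_name", path.stem),
        subjects=subjects,
        stimuli=stimuli,
        control=list(control),
        sampling_freq=float(tracker["Sampling_Freq"]),
        screen=(int(tracker["Display_width"]), int(tracker["Display_height"])),
        store_mode=raw.get("Store_mode", "csv"),
        detection_overrides=dict(ap.get("Detection", {})),
    )


def run_experiment(
    config: ExperimentConfig | str | Path,
    data_dir: str | Path,
    out_dir: str | Path,
    actions: tuple[str, ...] = ALL_ACTIONS,
    test_spec: dict | None = None,
    aoi: AOISpec | None = None,
) -> dict:
    """Run the pipeline; returns a manifest of produced artifacts.

    ``test_spec`` is ``{"test": ..., "between": [...], "within": [...],
    "parameters": [...]}``; default mixed ANOVA of subject_group (between)
    by stimulus_group (within) over all parameters.
    """
    from . import stats as st
    from .parameters import extract_parameter_set, normalize_with_controls

    if isinstance(config, (str, Path)):
        config = load_config(config)
    bad = set(actions) - set(ALL_ACTIONS)
    if bad:
        raise ConfigError(f"unknown action(s) {sorted(bad)}")
    data_dir = Path(data_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"out_dir": str(out_dir), "artifacts": []}

    store = build_store(data_dir, mode=config.store_mode)
    missing = [
        (s, t)
        for s in config.all_subjects()
        for t in config.all_stimuli()
        if (s, t) not in set(store.index)
    ]
    if missing:
        raise FileNotFoundError(f"missing trial files for (subject, stimulus): {missing}")
    trials = query_trials(store, config.all_subjects(), config.all_stimuli())

    cfg = config.detection_config()
    sets = [extract_parameter_set(trial, cfg, aoi) for trial in trials]

    if "normalize" in actions and config.control:
        sets = normalize_with_controls(sets, config.control)
    if "export" in actions or "extract" in actions:
        p = st.export_parameters_csv(sets, out_dir / "parameters.csv")
        manifest["artifacts"].append(str(p))
    if "analyze" in actions:
        spec = test_spec or {
            "test": "mixed_anova",
            "between": ["subject_group"],
            "within": ["stimulus_group"],
            "parameters": "all",
        }
        table = st.build_long_table(sets, config, spec.get("parameters", "all"))
        results = st.run_statistical_test(
            table,
            spec["test"],
            between=spec.get("between"),
            within=spec.get("within"),
            out_dir=out_dir,
        )
        manifest["artifacts"].append(str(out_dir / f"{spec['test']}_results.csv"))
        manifest["n_results"] = len(results)
    if "visualize" in actions:
        from . import viz
        from .events import gaze_trace_from_trial
        from .parameters import detect_all_events

        plot_dir = out_dir / "plots"
        plot_dir.mkdir(exist_ok=True)
        dims = (config.screen[1], config.screen[0])  # (n_rows, n_cols)
        for trial in trials:
            detected = detect_all_events(trial, cfg)
            stem = f"{trial.subject_id}__{trial.stimulus_name}"
            viz.render_plot(
                "fixation_plot",
                plot_dir / f"{stem}_fixations.png",
                fixations=detected["fixation"],
                image_dims=dims,
            )
            viz.render_plot(
                "heatmap",
                plot_dir / f"{stem}_heatmap.png",
                gaze=gaze_trace_from_trial(trial, cfg),
                image_dims=dims,
            )
        manifest["artifacts"].append(str(plot_dir))

    log = out_dir / "run.log"
    log.write_text(
        f"experiment={config.name}\nconfig_hash={config.config_hash()}\n"
        f"actions={','.join(actions)}\nn_trials={len(trials)}\n"
    )
    manifest["artifacts"].append(str(log))
    manifest["n_trials"] = len(trials)
    manifest["n_parameter_sets"] = len(sets)
    return manifest
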