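"""Format bridge and trial storage.

Eye trackers export recordings as vendor-specific text files. This module
converts three plain-text dialects (EyeLink ASC-style, SMI text, Tobii TSV)
into a single base trial-table format, aggregates trials into a queryable
store (a folder of CSV files or a single SQLite database), and loads them
back with optional conditional filtering on subject and stimulus.

Base format
-----------
One CSV file per trial, named ``<subject>__<stimulus>.csv``, UTF-8, comma
separated, one header row, columns in this frozen order::

    timestamp, gaze_left_x, gaze_left_y, gaze_right_x, gaze_right_y,
    pupil_left, pupil_right, event_flag, message

``timestamp`` is integer milliseconds since recording start and strictly
increasing. Gaze is in screen pixels (origin top-left, y downward), pupil in
vendor arbitrary units. Missing samples (lost tracking, blinks) are empty
fields, canonicalised to NaN in memory; gaze may be missing only where pupil
is missing. ``event_flag`` is one of ``none/fixation/saccade/blink`` as
marked by the recording software; ``message`` is free text (usually empty),
with the stimulus-onset marker ``start_trial <stimulus>`` on its first
occurrence.

Vendor dialect grammars (repo-defined, written by :mod:`gazekit.fixtures`)
--------------------------------------------------------------------------
EyeLink ASC-style: comment lines start with ``**``; ``MSG <ts> <text>``
lines carry messages (``MSG <ts> TRIALID <stim>`` opens a trial);
``START <ts>`` / ``END <ts>`` bracket the samples; sample lines are
whitespace-separated ``<ts> <lx> <ly> <lp> <rx> <ry> <rp> [flag]`` with
missing values written as ``.``.

SMI text: header lines start with ``##``; a tab-separated column header
``Time  Type  L POR X [px] ...``; ``SMP`` rows carry the eight data fields,
``MSG`` rows carry ``# Message: <text>`` (``TRIALID <stim>`` opens a trial);
missing gaze/pupil written as ``0.0000`` (pupil 0 encodes a lost sample).

Tobii TSV: a single header row; tab-separated columns RecordingTimestamp,
GazePointXLeft .. PupilRight, GazeEventType, StudioEvent; missing values are
blank fields; ``StudioEvent`` text ``TRIALID <stim>`` opens a trial. Fields
are csv-quoted, so messages containing tabs round-trip.
"""

from __future__ import annotations

import io
import sqlite3
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BASE_COLUMNS",
    "EVENT_FLAGS",
    "TrialTable",
    "ExperimentStore",
    "ParseError",
    "VendorConfigError",
    "convert_vendor_export",
    "write_base_csv",
    "read_base_csv",
    "build_store",
    "query_trials",
]

BASE_COLUMNS = [
    "timestamp",
    "gaze_left_x",
    "gaze_left_y",
    "gaze_right_x",
    "gaze_right_y",
    "pupil_left",
    "pupil_right",
    "event_flag",
    "message",
]

_NUMERIC_COLUMNS = BASE_COLUMNS[:7]
EVENT_FLAGS = ("none", "fixation", "saccade", "blink")
ONSET_MARKER = "start_trial"


class ParseError(ValueError):
    """Raised when a vendor export or base CSV cannot be parsed."""


class VendorConfigError(ValueError):
    """Raised for an unknown vendor tag or store mode."""


@dataclass
class TrialTable:
    """Per-sample record of one subject x stimulus recording.

    ``samples`` is a DataFrame with exactly the base-format columns.
    """

    subject_id: str
    stimulus_name: str
    samples: pd.DataFrame
    sampling_freq: float

    def __post_init__(self) -> None:
        if set(BASE_COLUMNS) <= set(self.samples.columns):
            self.samples = self.samples[BASE_COLUMNS].reset_index(drop=True)
            for c in _NUMERIC_COLUMNS:
                self.samples[c] = self.samples[c].astype(float)
        self.validate()

    def validate(self) -> None:
        if list(self.samples.columns) != BASE_COLUMNS:
            raise ParseError(
                f"trial table columns must be {BASE_COLUMNS}, "
                f"got {list(self.samples.columns)}"
            )
        if len(self.samples) == 0:
            raise ParseError("trial table must contain at least one sample")
        ts = self.samples["timestamp"].to_numpy(dtype=float)
        if np.any(np.diff(ts) <= 0):
            bad = int(np.argmax(np.diff(ts) <= 0)) + 1
            raise ParseError(
                f"timestamps must be strictly increasing (violation at row {bad})"
            )
        pupil = self.samples[["pupil_left", "pupil_right"]].to_numpy(dtype=float)
        if np.nanmin(pupil, initial=0.0) < 0:
            raise ParseError("pupil values must be >= 0")

    @property
    def timestamps(self) -> np.ndarray:
        return self.samples["timestamp"].to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def onset_ms(self) -> float:
        """Time of the stimulus-onset message, or the first timestamp."""
        msgs = self.samples["message"].astype(str)
        hit = msgs.str.startswith(ONSET_MARKER)
        if hit.any():
            return float(self.samples.loc[hit, "timestamp"].iloc[0])
        return float(self.samples["timestamp"].iloc[0])


def _empty_samples() -> dict:
    return {c: [] for c in BASE_COLUMNS}


def _finish_trial(subject: str, stimulus: str, rows: dict, sfreq: float) -> TrialTable:
    df = pd.DataFrame(rows, columns=BASE_COLUMNS)
    for c in _NUMERIC_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["timestamp"] = df["timestamp"].astype(float)
    df["event_flag"] = df["event_flag"].fillna("none").replace("", "none")
    df["message"] = df["message"].fillna("")
    return TrialTable(subject, stimulus, df, sfreq)


def _infer_sfreq(timestamps: list[float]) -> float:
    if len(timestamps) < 2:
        return 1000.0
    dt = float(np.median(np.diff(np.asarray(timestamps, dtype=float))))
    return round(1000.0 / dt)


# ---------------------------------------------------------------------------
# vendor parsers
# ---------------------------------------------------------------------------


def _parse_number(tok: str, missing: str) -> float:
    if tok == missing or tok == "":
        return np.nan
    return float(tok)


def _parse_eyelink(path: Path) -> list[TrialTable]:
    subject = path.stem
    trials: list[TrialTable] = []
    rows = _empty_samples()
    stimulus = None
    pending_msgs: list[tuple[float, str]] = []
    in_samples = False

    def flush():
        nonlocal rows, stimulus
        if stimulus is not None and rows["timestamp"]:
            trials.append(
                _finish_trial(subject, stimulus, rows, _infer_sfreq(rows["timestamp"]))
            )
        rows = _empty_samples()
        stimulus = None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("**"):
                continue
            parts = line.split(None, 2)
            tag = parts[0]
            if tag == "MSG":
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: malformed MSG line")
                ts, text = float(parts[1]), parts[2]
                if text.startswith("TRIALID"):
                    flush()
                    stimulus = text.split(None, 1)[1].strip()
                else:
                    pending_msgs.append((ts, text))
                continue
            if tag == "START":
                in_samples = True
                continue
            if tag == "END":
                in_samples = False
                continue
            if not in_samples:
                raise ParseError(f"{path}:{lineno}: sample data outside START/END block")
            toks = line.split()
            if len(toks) not in (7, 8):
                raise ParseError(
                    f"{path}:{lineno}: expected 7 or 8 sample fields, got {len(toks)}"
                )
            try:
                ts = float(toks[0])
                lx, ly, lp = (_parse_number(t, ".") for t in toks[1:4])
                rx, ry, rp = (_parse_number(t, ".") for t in toks[4:7])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            flag = toks[7].lower() if len(toks) == 8 else "none"
            msg = ""
            still = []
            for mts, mtext in pending_msgs:
                if mts <= ts and not msg:
                    msg = mtext
                else:
                    still.append((mts, mtext))
            pending_msgs = still
            rows["timestamp"].append(ts)
            rows["gaze_left_x"].append(lx)
            rows["gaze_left_y"].append(ly)
            rows["gaze_right_x"].append(rx)
            rows["gaze_right_y"].append(ry)
            rows["pupil_left"].append(lp)
            rows["pupil_right"].append(rp)
            rows["event_flag"].append(flag)
            rows["message"].append(msg)
    flush()
    if not trials:
        raise ParseError(f"{path}:1: no trials found (empty or header-only file)")
    return trials


_SMI_MISSING = "0.0000"


def _parse_smi(path: Path) -> list[TrialTable]:
    subject = path.stem
    trials: list[TrialTable] = []
    rows = _empty_samples()
    stimulus = None
    pending_msg = ""

    def flush():
        nonlocal rows, stimulus
        if stimulus is not None and rows["timestamp"]:
            trials.append(
                _finish_trial(subject, stimulus, rows, _infer_sfreq(rows["timestamp"]))
            )
        rows = _empty_samples()
        stimulus = None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("##"):
                continue
            if line.startswith("Time\t"):
                continue  # column header
            toks = line.split("\t")
            if len(toks) < 2:
                raise ParseError(f"{path}:{lineno}: expected tab-separated fields")
            typ = toks[1]
            if typ == "MSG":
                rest = "\t".join(toks[2:])
                prefix = "# Message: "
                if not rest.startswith(prefix):
                    raise ParseError(f"{path}:{lineno}: malformed MSG row")
                text = rest[len(prefix):]
                if text.startswith("TRIALID"):
                    flush()
                    stimulus = text.split(None, 1)[1].strip()
                else:
                    pending_msg = text
                continue
            if typ != "SMP":
                raise ParseError(f"{path}:{lineno}: unknown row type {typ!r}")
            if len(toks) != 8:
                raise ParseError(
                    f"{path}:{lineno}: expected 8 fields in SMP row, got {len(toks)}"
                )
            try:
                ts = float(toks[0])
                lp = _parse_number(toks[6], _SMI_MISSING)
                rp = _parse_number(toks[7], _SMI_MISSING)
                lx = _parse_number(toks[2], _SMI_MISSING)
                ly = _parse_number(toks[3], _SMI_MISSING)
                rx = _parse_number(toks[4], _SMI_MISSING)
                ry = _parse_number(toks[5], _SMI_MISSING)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            # pupil 0 encodes a lost sample in this dialect
            if np.isnan(lp):
                lx = ly = np.nan
            if np.isnan(rp):
                rx = ry = np.nan
            rows["timestamp"].append(ts)
            rows["gaze_left_x"].append(lx)
            rows["gaze_left_y"].append(ly)
            rows["gaze_right_x"].append(rx)
            rows["gaze_right_y"].append(ry)
            rows["pupil_left"].append(lp)
            rows["pupil_right"].append(rp)
            rows["event_flag"].append("none")
            rows["message"].append(pending_msg)
            pending_msg = ""
    flush()
    if not trials:
        raise ParseError(f"{path}:1: no trials found (empty or header-only file)")
    return trials


_TOBII_HEADER = [
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

_TOBII_FLAGS = {
    "": "none",
    "Unclassified": "none",
    "Fixation": "fixation",
    "Saccade": "saccade",
    "Blink": "blink",
}


def _parse_tobii(path: Path) -> list[TrialTable]:
    import csv

    subject = path.stem
    trials: list[TrialTable] = []
    rows = _empty_samples()
    stimulus = None

    def flush():
        nonlocal rows, stimulus
        if stimulus is not None and rows["timestamp"]:
            trials.append(
                _finish_trial(subject, stimulus, rows, _infer_sfreq(rows["timestamp"]))
            )
        rows = _empty_samples()
        stimulus = None

    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}:1: empty file") from None
        if header != _TOBII_HEADER:
            raise ParseError(f"{path}:1: unexpected column header {header!r}")
        for lineno, toks in enumerate(reader, start=2):
            if not toks or all(t == "" for t in toks):
                continue
            if len(toks) != len(_TOBII_HEADER):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(_TOBII_HEADER)} fields, "
                    f"got {len(toks)}"
                )
            event = toks[8]
            if event.startswith("TRIALID"):
                flush()
                stimulus = event.split(None, 1)[1].strip()
                if toks[0] == "":
                    continue  # marker-only row
            try:
                ts = float(toks[0])
                vals = [_parse_number(t, "") for t in toks[1:7]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            flag = _TOBII_FLAGS.get(toks[7])
            if flag is None:
                raise ParseError(f"{path}:{lineno}: unknown GazeEventType {toks[7]!r}")
            msg = "" if event.startswith("TRIALID") else event
            rows["timestamp"].append(ts)
            for col, v in zip(BASE_COLUMNS[1:5], vals[:4]):
                rows[col].append(v)
            rows["pupil_left"].append(vals[4])
            rows["pupil_right"].append(vals[5])
            rows["event_flag"].append(flag)
            rows["message"].append(msg)
    flush()
    if not trials:
        raise ParseError(f"{path}:1: no trials found (empty or header-only file)")
    return trials


_PARSERS = {"eyelink": _parse_eyelink, "smi": _parse_smi, "tobii": _parse_tobii}


def convert_vendor_export(path: str | Path, vendor: str) -> list[TrialTable]:
    """Parse one vendor text export into base-format trial tables.

    Trials are delimited by the dialect's TRIALID markers; missing samples
    are canonicalised to NaN; recorder event flags are preserved when the
    dialect carries them.
    """
    path = Path(path)
    if vendor not in _PARSERS:
        raise VendorConfigError(
            f"unknown vendor {vendor!r}; expected one of {sorted(_PARSERS)}"
        )
    if not path.exists():
        raise FileNotFoundError(path)
    return _PARSERS[vendor](path)


# ---------------------------------------------------------------------------
# base CSV and experiment store
# ---------------------------------------------------------------------------


def trial_filename(subject: str, stimulus: str) -> str:
    for name in (subject, stimulus):
        if "__" in name or "/" in name:
            raise ValueError(f"'__' and '/' are reserved in names: {name!r}")
    return f"{subject}__{stimulus}.csv"


def write_base_csv(trial: TrialTable, out_dir: str | Path) -> Path:
    """Write one trial as a base-format CSV; returns the file path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / trial_filename(trial.subject_id, trial.stimulus_name)
    df = trial.samples.copy()
    df["timestamp"] = df["timestamp"].map(lambda v: format(v, ".10g"))
    for c in _NUMERIC_COLUMNS[1:]:
        df[c] = df[c].map(lambda v: "" if pd.isna(v) else format(v, ".10g"))
    df.to_csv(path, index=False)
    return path


def read_base_csv(path: str | Path) -> TrialTable:
    """Read one base-format CSV back into a trial table."""
    path = Path(path)
    stem = path.stem
    if "__" not in stem:
        raise ParseError(f"{path}: file name must be <subject>__<stimulus>.csv")
    subject, stimulus = stem.split("__", 1)
    df = pd.read_csv(path, dtype={"event_flag": str, "message": str})
    missing_cols = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing column(s) {missing_cols}")
    df = df[BASE_COLUMNS]
    for c in _NUMERIC_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["event_flag"] = df["event_flag"].fillna("none")
    df["message"] = df["message"].fillna("")
    return TrialTable(subject, stimulus, df, _infer_sfreq(list(df["timestamp"])))


@dataclass
class ExperimentStore:
    """Queryable aggregation of all trials of an experiment.

    ``mode='csv'`` keeps the folder of per-trial CSVs as the backing;
    ``mode='sql'`` aggregates everything into a single SQLite file with one
    ``samples`` table indexed on (subject_id, stimulus_name). Both modes
    answer every query identically.
    """

    mode: str
    path: Path
    index: list[tuple[str, str]] = field(default_factory=list)


_DB_NAME = "experiment.db"


def build_store(csv_dir: str | Path, mode: str = "csv") -> ExperimentStore:
    csv_dir = Path(csv_dir)
    if mode not in ("csv", "sql"):
        raise VendorConfigError(f"unknown store mode {mode!r}; expected 'csv' or 'sql'")
    files = sorted(p for p in csv_dir.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no base-format CSV files in {csv_dir}")
    index = []
    trials = []
    for p in files:
        trial = read_base_csv(p)
        index.append((trial.subject_id, trial.stimulus_name))
        trials.append(trial)
    index.sort()
    if mode == "csv":
        return ExperimentStore("csv", csv_dir, index)
    db_path = csv_dir / _DB_NAME
    if db_path.exists():
        db_path.unlink()
    con = sqlite3.connect(db_path)
    try:
        con.execute(
            "CREATE TABLE samples (subject_id TEXT, stimulus_name TEXT, "
            "sampling_freq REAL, "
            + ", ".join(f"{c} REAL" for c in _NUMERIC_COLUMNS)
            + ", event_flag TEXT, message TEXT)"
        )
        con.execute("CREATE INDEX idx_trial ON samples (subject_id, stimulus_name)")
        for trial in trials:
            df = trial.samples.copy()
            df.insert(0, "subject_id", trial.subject_id)
            df.insert(1, "stimulus_name", trial.stimulus_name)
            df.insert(2, "sampling_freq", trial.sampling_freq)
            df.to_sql("samples", con, if_exists="append", index=False)
        con.commit()
    finally:
        con.close()
    return ExperimentStore("sql", db_path, index)


def query_trials(
    store: ExperimentStore,
    subjects: list[str] | str = "all",
    stimuli: list[str] | str = "all",
) -> list[TrialTable]:
    """Return the trials matching the subject/stimulus predicate.

    Order is deterministic: subject then stimulus, lexicographic. Unknown
    names yield an empty result with a warning, never an exception.
    """
    want = sorted(
        (s, t)
        for (s, t) in store.index
        if (subjects == "all" or s in subjects) and (stimuli == "all" or t in stimuli)
    )
    if not want:
        warnings.warn(
            "query matched no trials "
            f"(subjects={subjects!r}, stimuli={stimuli!r})",
            stacklevel=2,
        )
        return []
    if store.mode == "csv":
        return [read_base_csv(store.path / trial_filename(s, t)) for (s, t) in want]
    con = sqlite3.connect(store.path)
    try:
        out = []
        for s, t in want:
            df = pd.read_sql_query(
                "SELECT * FROM samples WHERE subject_id = ? AND stimulus_name = ? "
                "ORDER BY timestamp",
                con,
                params=(s, t),
            )
            sfreq = float(df["sampling_freq"].iloc[0])
            df = df[BASE_COLUMNS].copy()
            df["event_flag"] = df["event_flag"].fillna("none")
            df["message"] = df["message"].fillna("")
            out.append(TrialTable(s, t, df, sfreq))
        return out
    finally:
        con.close()
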