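"""Core domain types and file I/O.

The pipeline works on three kinds of objects: continuous multichannel EEG
(``ContinuousRecording``), epoched EEG (``EpochSet``, a trials x channels x
samples tensor in microvolts with per-trial condition labels), and
per-condition trial averages (``ERPSet``).  Behavioral data live in a
validated ``TrialTable``.

External formats:

* BrainVision ``.vhdr/.vmrk/.eeg`` triplets (read; a writer helper exists for
  building test fixtures).  Only the multiplexed binary dialect with INT_16
  or IEEE_FLOAT_32 samples is supported.
* A documented epochs container: a JSON sidecar plus a raw little-endian
  float32 array, so epoched data round-trip without any binary dependency.
* CSV trial tables with schema validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "ContinuousRecording",
    "EpochSet",
    "ERPSet",
    "TrialTable",
    "FormatError",
    "UnsupportedDialectError",
    "IntegrityError",
    "SchemaError",
    "standard_montage_32",
    "read_brainvision",
    "write_brainvision",
    "write_epochs",
    "read_epochs",
    "read_trial_table",
    "validate_trial_table",
]

RESPONSE_DEADLINE_MS = 3000.0

GLOBAL_LEX_LEVELS = ("w", "n")
LOCAL_LEX_LEVELS = ("w", "n")
TASK_LEVELS = ("global", "local")
UNDERLINE_LEVELS = ("full", "first", "last")

TRIAL_TABLE_COLUMNS = (
    "subject",
    "global_lex",
    "local_lex",
    "task",
    "underline_pos",
    "rt_ms",
    "correct",
)


class FormatError(ValueError):
    """A file does not look like the format it was claimed to be."""


class UnsupportedDialectError(FormatError):
    """A recognized format, but a dialect this package does not read."""


class IntegrityError(ValueError):
    """Sidecar metadata and stored payload disagree."""


class SchemaError(ValueError):
    """A tabular input is missing columns or violates an enumeration."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """Electrode layout.

    The number of channels is the dimensionality of a scalp topography: one
    instantaneous amplitude per electrode.
    """

    channel_names: tuple[str, ...]
    reference_label: str = "average"
    eog_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        object.__setattr__(self, "eog_channels", tuple(self.eog_channels))
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if not names:
            raise ValueError("montage needs at least one channel")
        unknown = set(self.eog_channels) - set(names)
        if unknown:
            raise ValueError(f"eog_channels not in montage: {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None


def standard_montage_32() -> Montage:
    """32-channel actiCAP-style 10-20 layout with Fp1/Fp2 monitoring blinks."""
    names = (
        "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3",
        "T7", "TP9", "CP5", "CP1", "Pz", "P3", "P7", "O1",
        "Oz", "O2", "P4", "P8", "TP10", "CP6", "CP2", "Cz",
        "C4", "T8", "FT10", "FC6", "FC2", "F4", "F8", "Fp2",
    )
    return Montage(channel_names=names, reference_label="Cz",
                   eog_channels=("Fp1", "Fp2"))


@dataclass
class ContinuousRecording:
    """Continuous EEG: channels x samples in microvolts, plus events."""

    montage: Montage
    data: np.ndarray
    srate: float
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        n = self.data.shape[1]
        for s, code in self.events:
            if not 0 <= s < n:
                raise ValueError(f"event {code!r} at sample {s} out of bounds")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Epoched EEG for one subject.

    ``data`` is trials x channels x samples in microvolts; ``time_ms`` is the
    shared sample axis with stimulus onset at 0 ms (the standard epoch spans
    [-200, 800) ms, half-open on the right, i.e. 500 samples at 500 Hz).
    """

    montage: Montage
    subject_id: str
    data: np.ndarray
    time_ms: np.ndarray
    condition: np.ndarray
    srate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_tr, n_ch, n_sm = self.data.shape
        if n_ch != self.montage.n_channels:
            raise ValueError("channel axis does not match montage")
        if self.time_ms.shape != (n_sm,):
            raise ValueError("time axis length does not match sample axis")
        if self.condition.shape != (n_tr,):
            raise ValueError("need one condition label per trial")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if n_sm >= 2:
            step = 1000.0 / self.srate
            diffs = np.diff(self.time_ms)
            if not np.allclose(diffs, step, rtol=0, atol=1e-6):
                raise ValueError("time axis must be uniform at 1000/srate ms")
        if n_tr and not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def conditions(self) -> list[str]:
        """Unique condition labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.condition:
            seen.setdefault(str(c), None)
        return list(seen)

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(self, data=self.data[mask],
                       condition=self.condition[mask])


@dataclass
class ERPSet:
    """Per-condition trial-average waveforms (channels x samples, microvolts)."""

    montage: Montage
    erps: dict[str, np.ndarray]
    n_trials_used: dict[str, int]
    time_ms: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        for cond, arr in self.erps.items():
            arr = np.asarray(arr, dtype=float)
            self.erps[cond] = arr
            if arr.shape != (self.montage.n_channels, self.time_ms.size):
                raise ValueError(f"ERP for {cond!r} has shape {arr.shape}, "
                                 "expected channels x samples")
            if self.n_trials_used.get(cond, 0) < 1:
                raise ValueError(f"condition {cond!r} averaged from <1 trial")

    @property
    def conditions(self) -> list[str]:
        return list(self.erps)


@dataclass
class TrialTable:
    """Validated behavioral trial table.

    Columns: subject, global_lex (w/n), local_lex (w/n), task (global/local),
    underline_pos (full/first/last), rt_ms (0 < rt <= 3000 where present),
    correct (0/1).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = validate_trial_table(self.df)

    def __len__(self) -> int:
        return len(self.df)


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    df = df.loc[:, list(TRIAL_TABLE_COLUMNS)].copy()
    bad_rows: list[str] = []

    def check_enum(col: str, levels: tuple[str, ...]) -> None:
        vals = df[col].astype(str)
        bad = ~vals.isin(levels)
        for i in df.index[bad]:
            bad_rows.append(f"row {i}: {col}={df.at[i, col]!r} "
                            f"not in {levels}")
        df[col] = vals

    check_enum("global_lex", GLOBAL_LEX_LEVELS)
    check_enum("local_lex", LOCAL_LEX_LEVELS)
    check_enum("task", TASK_LEVELS)
    check_enum("underline_pos", UNDERLINE_LEVELS)

    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    has_rt = rt.notna()
    for i in df.index[has_rt & (rt <= 0)]:
        bad_rows.append(f"row {i}: rt_ms={rt[i]} must be positive")
    for i in df.index[has_rt & (rt > RESPONSE_DEADLINE_MS)]:
        bad_rows.append(f"row {i}: rt_ms={rt[i]} exceeds the "
                        f"{RESPONSE_DEADLINE_MS:.0f} ms (3 s) response deadline")
    df["rt_ms"] = rt

    corr = pd.to_numeric(df["correct"], errors="coerce")
    for i in df.index[~corr.isin([0, 1])]:
        bad_rows.append(f"row {i}: correct={df.at[i, 'correct']!r} "
                        "must be 0 or 1")
    df["correct"] = corr.astype("Int64")

    if bad_rows:
        raise SchemaError("invalid trial table rows:\n" + "\n".join(bad_rows))
    return df


# ---------------------------------------------------------------------------
# BrainVision reader / fixture writer
# ---------------------------------------------------------------------------

_SUPPORTED_BINARY = {"INT_16", "IEEE_FLOAT_32"}


def _parse_vhdr_sections(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
        elif "=" in line and current is not None:
            key, _, val = line.partition("=")
            current[key.strip()] = val.strip()
    return sections


def _companion(header_path: Path, name: str) -> Path:
    # header entries may use backslash separators regardless of platform
    return header_path.parent / name.replace("\\", "/").split("/")[-1]


def read_brainvision(header_path: str | Path) -> ContinuousRecording:
    """Read a BrainVision triplet into a :class:`ContinuousRecording`.

    Data are returned in microvolts with per-channel resolutions applied;
    events are the verbatim marker descriptions from the ``.vmrk`` file with
    0-based sample indices.  Only multiplexed binary INT_16 / IEEE_FLOAT_32
    files are accepted.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FormatError(f"header not found: {header_path}")
    sections = _parse_vhdr_sections(header_path.read_text(errors="replace"))
    common = sections.get("Common Infos", {})
    binary = sections.get("Binary Infos", {})

    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise UnsupportedDialectError(
            f"unsupported DataFormat {common.get('DataFormat')!r}: "
            "only BINARY is readable")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise UnsupportedDialectError(
            f"unsupported DataOrientation {common.get('DataOrientation')!r}: "
            "only MULTIPLEXED is readable")
    fmt = binary.get("BinaryFormat", "INT_16").upper()
    if fmt not in _SUPPORTED_BINARY:
        raise UnsupportedDialectError(
            f"unsupported BinaryFormat {fmt!r}: "
            f"expected one of {sorted(_SUPPORTED_BINARY)}")

    data_file = _companion(header_path, common.get("DataFile", ""))
    marker_file = _companion(header_path, common.get("MarkerFile", ""))
    if not common.get("DataFile") or not data_file.exists():
        raise FormatError(f"data file missing: {data_file}")
    if common.get("MarkerFile") and not marker_file.exists():
        raise FormatError(f"marker file missing: {marker_file}")

    import mne  # deferred: mne import is slow

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_brainvision(header_path, preload=True,
                                          verbose="error")
    data_uv = raw.get_data() * 1e6
    srate = float(raw.info["sfreq"])

    events: list[tuple[int, str]] = []
    if common.get("MarkerFile"):
        msec = _parse_vhdr_sections(
            marker_file.read_text(errors="replace")).get("Marker Infos", {})
        for key in sorted(msec, key=lambda k: int(k[2:]) if k[2:].isdigit() else 0):
            parts = msec[key].split(",")
            if len(parts) < 3:
                continue
            mtype, desc, pos = parts[0], parts[1], parts[2]
            if mtype == "New Segment":
                continue
            events.append((int(pos) - 1, desc))  # .vmrk positions are 1-based

    montage = Montage(channel_names=tuple(raw.ch_names),
                      reference_label="as-recorded")
    return ContinuousRecording(montage=montage, data=data_uv, srate=srate,
                               events=events)


def write_brainvision(rec: ContinuousRecording, out_dir: str | Path,
                      basename: str = "recording",
                      binary_format: str = "IEEE_FLOAT_32",
                      resolution: float = 1.0) -> Path:
    """Write a BrainVision triplet (fixture/helper; multiplexed binary only).

    With ``IEEE_FLOAT_32`` and resolution 1 the stored samples are the data
    cast to float32, so read(write(x)) is bitwise-stable at float32 precision.
    """
    binary_format = binary_format.upper()
    if binary_format not in _SUPPORTED_BINARY:
        raise UnsupportedDialectError(f"cannot write {binary_format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vhdr = out_dir / f"{basename}.vhdr"
    vmrk = out_dir / f"{basename}.vmrk"
    eeg = out_dir / f"{basename}.eeg"

    scaled = rec.data.T / resolution  # multiplexed: sample-major
    if binary_format == "INT_16":
        stored = np.round(scaled).astype("<i2")
    else:
        stored = scaled.astype("<f4")
    stored.tofile(eeg)

    interval_us = 1e6 / rec.srate
    ch_lines = "\n".join(
        f"Ch{i + 1}={name},,{resolution:g},µV"
        for i, name in enumerate(rec.montage.channel_names))
    vhdr.write_text(
        "Brain Vision Data Exchange Header File Version 1.0\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg.name}\nMarkerFile={vmrk.name}\n"
        "DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n"
        f"NumberOfChannels={rec.montage.n_channels}\n"
        f"SamplingInterval={interval_us:g}\n"
        f"[Binary Infos]\nBinaryFormat={binary_format}\n"
        f"[Channel Infos]\n{ch_lines}\n", encoding="utf-8")

    lines = ["Brain Vision Data Exchange Marker File, Version 1.0",
             "[Common Infos]", "Codepage=UTF-8", f"DataFile={eeg.name}",
             "[Marker Infos]",
             "Mk1=New Segment,,1,1,0,00000000000000000000"]
    for k, (sample, code) in enumerate(rec.events, start=2):
        lines.append(f"Mk{k}=Stimulus,{code},{sample + 1},1,0")
    vmrk.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return vhdr


# ---------------------------------------------------------------------------
# Epochs container (JSON sidecar + raw float32)
# ---------------------------------------------------------------------------

_SIDECAR_NAME = "epochs.json"
_ARRAY_NAME = "epochs.float32"


def write_epochs(e: EpochSet, out_dir: str | Path) -> Path:
    """Write an :class:`EpochSet` as JSON sidecar + raw little-endian float32."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arr = np.ascontiguousarray(e.data, dtype="<f4")
    arr.tofile(out_dir / _ARRAY_NAME)
    sidecar = {
        "format": "chunkdyn-epochs-v1",
        "dtype": "float32",
        "byte_order": "little-endian",
        "shape": list(e.data.shape),
        "subject_id": e.subject_id,
        "srate": e.srate,
        "time_ms": [float(t) for t in e.time_ms],
        "condition": [str(c) for c in e.condition],
        "montage": {
            "channel_names": list(e.montage.channel_names),
            "reference_label": e.montage.reference_label,
            "eog_channels": list(e.montage.eog_channels),
        },
    }
    (out_dir / _SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return out_dir


def read_epochs(in_dir: str | Path) -> EpochSet:
    in_dir = Path(in_dir)
    sidecar_path = in_dir / _SIDECAR_NAME
    if not sidecar_path.exists():
        raise FormatError(f"no epochs sidecar at {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    shape = tuple(meta["shape"])
    raw = np.fromfile(in_dir / _ARRAY_NAME, dtype="<f4")
    if raw.size != int(np.prod(shape)):
        raise IntegrityError(
            f"sidecar declares shape {shape} ({int(np.prod(shape))} values) "
            f"but array holds {raw.size} values")
    if len(meta["condition"]) != shape[0]:
        raise IntegrityError("condition labels do not match trial count")
    montage = Montage(channel_names=tuple(meta["montage"]["channel_names"]),
                      reference_label=meta["montage"]["reference_label"],
                      eog_channels=tuple(meta["montage"]["eog_channels"]))
    return EpochSet(montage=montage, subject_id=meta["subject_id"],
                    data=raw.reshape(shape).astype(float),
                    time_ms=np.asarray(meta["time_ms"], dtype=float),
                    condition=np.asarray(meta["condition"], dtype=object),
                    srate=float(meta["srate"]))


def read_trial_table(csv_path: str | Path) -> TrialTable:
    """Read and validate a behavioral trial table CSV."""
    df = pd.read_csv(csv_path)
    return TrialTable(df)
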