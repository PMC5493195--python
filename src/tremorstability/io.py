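"""Reading, writing and windowing of tremor recordings.

Recordings are interchanged as delimited text (CSV/TSV) with a header row:
either three signal columns ``axis_x, axis_y, axis_z`` (triaxial
accelerometer) or a single ``value`` column (e.g. a velocity-transducing
laser), plus an optional ``time`` column that is validated for uniform
spacing and then discarded.  Sampling rate and units come from a YAML/JSON
sidecar (``<stem>.yaml`` / ``<stem>.json``) or from keyword overrides.

Cohort manifests are CSV tables with columns ``path,label,state,fs,units``
mapping recording files to clinical labels (PD or ET).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    BoundsError,
    ConfigurationError,
    DataError,
    FormatError,
    UnitError,
)

STANDARD_GRAVITY = 9.80665  # m/s^2, exact by definition


class Units(str, enum.Enum):
    """Kinematic units a recording may carry."""

    G = "g"
    MG = "mg"
    MS2 = "m/s^2"
    MS = "m/s"  # velocity (laser transducer)

    @property
    def is_acceleration(self) -> bool:
        return self in (Units.G, Units.MG, Units.MS2)


#: exact conversion factors from each acceleration unit to m/s^2
_ACCEL_TO_MS2 = {
    Units.G: STANDARD_GRAVITY,
    Units.MG: STANDARD_GRAVITY / 1000.0,
    Units.MS2: 1.0,
}

_UNIT_ALIASES = {
    "g": Units.G,
    "mg": Units.MG,
    "m/s^2": Units.MS2,
    "m/s2": Units.MS2,
    "ms2": Units.MS2,
    "m/s": Units.MS,
    "ms": Units.MS,
}


def parse_units(value: Union[str, Units, None], default: Optional[Units] = None) -> Units:
    if value is None:
        if default is None:
            raise ConfigurationError("units not specified")
        return default
    if isinstance(value, Units):
        return value
    try:
        return _UNIT_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ConfigurationError(f"unknown units {value!r}") from None


class RecordingState(str, enum.Enum):
    REST = "rest"
    POSTURE = "posture"
    RE_EMERGENT = "re-emergent"
    UNKNOWN = "unknown"


def parse_state(value) -> RecordingState:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return RecordingState.UNKNOWN
    if isinstance(value, RecordingState):
        return value
    key = str(value).strip().lower().replace("_", "-")
    for state in RecordingState:
        if state.value == key:
            return state
    raise ConfigurationError(f"unknown recording state {value!r}")


def _validate_common(samples: np.ndarray, fs: float) -> None:
    if not (fs > 0):
        raise ConfigurationError(f"sampling rate must be positive, got {fs}")
    if samples.shape[-1] < 2:
        raise DataError("recording must contain at least 2 samples")
    if not np.all(np.isfinite(samples)):
        raise DataError("recording contains non-finite samples")


@dataclass(frozen=True)
class TriaxialRecording:
    """Raw 3-axis kinematic time series with acquisition metadata."""

    samples: np.ndarray  # shape (3, N)
    fs: float
    units: Units = Units.MG
    sensor: str = ""
    state: RecordingState = RecordingState.UNKNOWN
    subject_id: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[0] != 3:
            raise FormatError(f"triaxial samples must be 3xN, got {samples.shape}")
        _validate_common(samples, self.fs)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "units", parse_units(self.units))
        object.__setattr__(self, "state", parse_state(self.state))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def n_axes(self) -> int:
        return 3


@dataclass(frozen=True)
class UniaxialRecording:
    """Single-axis kinematic time series (e.g. velocity laser)."""

    samples: np.ndarray  # shape (N,)
    fs: float
    units: Units = Units.MS
    sensor: str = ""
    state: RecordingState = RecordingState.UNKNOWN
    subject_id: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise FormatError(f"uniaxial samples must be a vector, got {samples.shape}")
        _validate_common(samples, self.fs)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "units", parse_units(self.units))
        object.__setattr__(self, "state", parse_state(self.state))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def n_axes(self) -> int:
        return 1


Recording = Union[TriaxialRecording, UniaxialRecording]

_AXIS_COLUMNS = ("axis_x", "axis_y", "axis_z")
_TIME_COLUMNS = ("time", "time_s", "t")


def _sidecar_path(path: Path) -> Optional[Path]:
    for suffix in (".yaml", ".yml", ".json"):
        candidate = path.with_suffix(suffix)
        if candidate.exists() and candidate != path:
            return candidate
    return None


def _load_sidecar(path: Path) -> dict:
    if path.suffix == ".json":
        return json.loads(path.read_text())
    return yaml.safe_load(path.read_text()) or {}


def read_recording(
    path,
    *,
    fs: Optional[float] = None,
    units=None,
    state=None,
    sensor: Optional[str] = None,
    subject_id: Optional[str] = None,
) -> Recording:
    """Read a recording from delimited text, merging sidecar metadata.

    Keyword overrides take precedence over the sidecar.  The sampling rate
    must be available from one of the two; a ``time`` column, when present,
    is checked for uniform spacing consistent with ``fs`` and dropped.
    """
    path = Path(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar is not None:
        meta.update(_load_sidecar(sidecar))
    overrides = {
        "fs": fs,
        "units": units,
        "state": state,
        "sensor": sensor,
        "subject_id": subject_id,
    }
    meta.update({k: v for k, v in overrides.items() if v is not None})

    if meta.get("fs") is None:
        raise ConfigurationError(
            f"{path}: sampling rate not available from sidecar or override"
        )
    fs_val = float(meta["fs"])

    try:
        with open(path) as handle:
            header = handle.readline()
        sep = "\t" if "\t" in header else (";" if ";" in header else ",")
        table = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed text
        raise FormatError(f"{path}: cannot parse delimited text ({exc})") from exc

    columns = {c.strip().lower(): c for c in table.columns}
    time_col = next((columns[c] for c in _TIME_COLUMNS if c in columns), None)
    signal_cols = [c for c in table.columns if c != time_col]

    if time_col is not None:
        t = table[time_col].to_numpy(dtype=float)
        dt = 1.0 / fs_val
        if len(t) >= 2 and np.max(np.abs(np.diff(t) - dt)) > 1e-6 * dt:
            raise DataError(f"{path}: time column is not uniform at fs={fs_val} Hz")

    if len(signal_cols) == 3:
        values = table[signal_cols].to_numpy(dtype=float).T
        cls, kwargs = TriaxialRecording, {"samples": values}
        default_units = Units.MG
    elif len(signal_cols) == 1:
        values = table[signal_cols[0]].to_numpy(dtype=float)
        cls, kwargs = UniaxialRecording, {"samples": values}
        default_units = Units.MS
    else:
        raise FormatError(
            f"{path}: expected 1 or 3 signal columns, found {len(signal_cols)}"
        )

    if not np.all(np.isfinite(values)):
        raise DataError(f"{path}: non-finite samples")

    return cls(
        fs=fs_val,
        units=parse_units(meta.get("units"), default=default_units),
        state=parse_state(meta.get("state")),
        sensor=str(meta.get("sensor", "")),
        subject_id=str(meta.get("subject_id", path.stem)),
        **kwargs,
    )


def write_recording(path, rec: Recording, *, sidecar: bool = True) -> Path:
    """Write a recording as CSV plus a YAML metadata sidecar.

    Samples are written with ``repr`` round-trip precision so that
    write -> read reproduces the array bit-for-bit.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(rec, TriaxialRecording):
        frame = pd.DataFrame(rec.samples.T, columns=list(_AXIS_COLUMNS))
    else:
        frame = pd.DataFrame({"value": rec.samples})
    frame.to_csv(path, index=False, float_format="%.17g")
    if sidecar:
        meta = {
            "fs": rec.fs,
            "units": rec.units.value,
            "state": rec.state.value,
            "sensor": rec.sensor,
            "subject_id": rec.subject_id,
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def select_segment(rec: Recording, start_s: float = 0.0, duration_s: float = 100.0) -> Recording:
    """Return the contiguous sub-recording ``[start_s, start_s + duration_s)``.

    The default mirrors the convention of analysing the first 100 s of
    tremor; the caller is responsible for choosing a tremor-containing
    start offset.
    """
    if start_s < 0:
        raise BoundsError(f"start_s must be >= 0, got {start_s}")
    i0 = int(round(start_s * rec.fs))
    n = int(round(duration_s * rec.fs))
    if n < 2:
        raise BoundsError(f"segment of {duration_s} s is too short at fs={rec.fs}")
    if i0 + n > rec.n_samples:
        raise BoundsError(
            f"segment [{start_s}, {start_s + duration_s}) s exceeds the "
            f"{rec.duration_s:.3f} s recording"
        )
    if isinstance(rec, TriaxialRecording):
        return dataclasses.replace(rec, samples=rec.samples[:, i0 : i0 + n])
    return dataclasses.replace(rec, samples=rec.samples[i0 : i0 + n])


def convert_units(rec: Recording, target) -> Recording:
    """Rescale samples to ``target`` units using exact conversion constants."""
    target = parse_units(target)
    if rec.units.is_acceleration != target.is_acceleration:
        raise UnitError(f"cannot convert {rec.units.value} to {target.value}")
    if rec.units == target:
        return rec
    factor = _ACCEL_TO_MS2[rec.units] / _ACCEL_TO_MS2[target]
    return dataclasses.replace(rec, samples=rec.samples * factor, units=target)


# ---------------------------------------------------------------------------
# cohort manifests

MANIFEST_COLUMNS = ("path", "label", "state", "fs", "units")
VALID_LABELS = ("PD", "ET")


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    label: str
    state: Optional[str] = None
    fs: Optional[float] = None
    units: Optional[str] = None

    def __post_init__(self):
        if self.label not in VALID_LABELS:
            raise ConfigurationError(
                f"label must be one of {VALID_LABELS}, got {self.label!r}"
            )


@dataclass(frozen=True)
class CohortManifest:
    entries: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))

    def labels(self) -> list:
        return [e.label for e in self.entries]

    def require_both_classes(self) -> None:
        labels = set(self.labels())
        if not {"PD", "ET"} <= labels:
            raise DataError(f"cohort must contain both PD and ET, found {sorted(labels)}")


def read_manifest(path) -> CohortManifest:
    path = Path(path)
    table = pd.read_csv(path)
    missing = {"path", "label"} - set(table.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    entries = []
    for row in table.itertuples(index=False):
        fs = getattr(row, "fs", None)
        units = getattr(row, "units", None)
        state = getattr(row, "state", None)
        entries.append(
            ManifestEntry(
                path=str(row.path),
                label=str(row.label),
                state=None if pd.isna(state) else str(state),
                fs=None if fs is None or pd.isna(fs) else float(fs),
                units=None if units is None or pd.isna(units) else str(units),
            )
        )
    return CohortManifest(entries)


def write_manifest(path, manifest: CohortManifest) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "path": e.path,
            "label": e.label,
            "state": e.state,
            "fs": e.fs,
            "units": e.units,
        }
        for e in manifest.entries
    ]
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, index=False)
    return path


def iter_cohort(manifest: CohortManifest, base_dir=None) -> Iterator[tuple]:
    """Yield ``(recording, label)`` for every manifest entry."""
    base = Path(base_dir) if base_dir is not None else None
    for entry in manifest.entries:
        p = Path(entry.path)
        if base is not None and not p.is_absolute():
            p = base / p
        rec = read_recording(p, fs=entry.fs, units=entry.units, state=entry.state)
        yield rec, entry.label
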