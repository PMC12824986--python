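"""Reading and writing CPMG decay records and study manifests.

Decay records are plain CSV in one of two dialects used by relaxometry
instruments: two columns (time in seconds, echo intensity in arbitrary
units) or three columns (time, real, imaginary) for quadrature
acquisition.  Two-column data is promoted to complex with the imaginary
channel set to zero.  A manifest maps blinded vial codes to sample class,
concentration and freeze/thaw stress flag.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    FormatError,
    InsufficientDataError,
    IntegrityError,
    ParseError,
    VocabularyError,
)

__all__ = [
    "AcquisitionMeta",
    "DecayTrace",
    "ManifestEntry",
    "StudyManifest",
    "SAMPLE_CLASSES",
    "read_decay",
    "write_decay",
    "load_manifest",
    "write_manifest",
]

#: Controlled vocabulary of sample classes in the study kit.
SAMPLE_CLASSES = frozenset({"mAb", "AH", "AP", "ETFE", "buffer", "reference"})

_MODES = frozenset({"time_domain", "frequency_domain"})

_TIME_UNITS = {"s": 1.0, "ms": 1e-3, "us": 1e-6}


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition parameters for one CPMG measurement.

    tau is the CPMG interpulse delay (half the echo spacing), in seconds;
    echo k of the train occurs at t = 2*tau*k after the 90-degree pulse.
    """

    lab_id: str = "unknown"
    tau: float = 500e-6
    n_scans: int = 1
    temperature: float = 25.0
    mode: str = "time_domain"
    sample_code: str = ""

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.n_scans < 1:
            raise ValueError(f"n_scans must be >= 1, got {self.n_scans}")
        if not (0.0 <= self.temperature <= 60.0):
            raise ValueError(
                f"temperature {self.temperature} degC outside sanity window [0, 60]"
            )
        if self.mode not in _MODES:
            raise VocabularyError(f"unknown acquisition mode {self.mode!r}")


@dataclass(frozen=True)
class DecayTrace:
    """A sampled CPMG echo decay: time grid, complex signal, metadata.

    ``time`` is seconds since the 90-degree excitation pulse, strictly
    increasing and positive.  ``signal`` is complex echo intensity in
    arbitrary units; for real-only acquisitions (``is_quadrature=False``)
    the imaginary part is exactly zero.
    """

    time: np.ndarray
    signal: np.ndarray
    is_quadrature: bool = False
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    #: set by read_decay when rows had to be re-sorted into time order
    reordered: bool = False

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        signal = np.asarray(self.signal, dtype=complex)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "signal", signal)
        if time.ndim != 1 or time.size < 3:
            raise InsufficientDataError(
                f"need a 1-D time grid of length >= 3, got shape {time.shape}"
            )
        if signal.shape != time.shape:
            raise ValueError(
                f"signal length {signal.shape} != time length {time.shape}"
            )
        if not np.all(time > 0):
            raise ValueError("time values must be positive")
        if not np.all(np.diff(time) > 0):
            raise ValueError("time values must be strictly increasing")
        if not self.is_quadrature and np.any(signal.imag != 0.0):
            raise ValueError(
                "is_quadrature=False but imaginary components are nonzero"
            )

    @property
    def n_points(self) -> int:
        return int(self.time.size)

    @property
    def real(self) -> np.ndarray:
        return self.signal.real

    @property
    def imag(self) -> np.ndarray:
        return self.signal.imag

    def with_signal(self, signal: np.ndarray, *, is_quadrature: bool | None = None) -> "DecayTrace":
        """Copy of this trace with a replaced signal array."""
        signal = np.asarray(signal, dtype=complex)
        if is_quadrature is None:
            is_quadrature = bool(np.any(signal.imag != 0.0)) or self.is_quadrature
        return replace(self, signal=signal, is_quadrature=is_quadrature)


@dataclass(frozen=True)
class ManifestEntry:
    sample_code: str
    sample_class: str
    concentration: float  # mg/mL for mAb/AH/AP; particle count for ETFE
    stressed: bool = False

    def __post_init__(self):
        if self.sample_class not in SAMPLE_CLASSES:
            raise VocabularyError(
                f"unknown sample_class {self.sample_class!r}; "
                f"expected one of {sorted(SAMPLE_CLASSES)}"
            )
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")


@dataclass(frozen=True)
class StudyManifest:
    """Blinded-code -> sample-content map for one study kit."""

    entries: tuple[ManifestEntry, ...]

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        codes = [e.sample_code for e in self.entries]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise IntegrityError(f"duplicate sample_code(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_code(self, code: str) -> ManifestEntry:
        for e in self.entries:
            if e.sample_code == code:
                return e
        raise KeyError(code)

    def of_class(self, sample_class: str, *, stressed: bool | None = None) -> tuple[ManifestEntry, ...]:
        out = [e for e in self.entries if e.sample_class == sample_class]
        if stressed is not None:
            out = [e for e in out if e.stressed == stressed]
        return tuple(out)


# ---------------------------------------------------------------------------
# decay CSV dialects


def _sniff_delimiter(line: str) -> str:
    for cand in (",", ";", "\t"):
        if cand in line:
            return cand
    # single column would be malformed anyway; default to comma
    return ","


def _is_numeric_row(cells: Sequence[str]) -> bool:
    try:
        for c in cells:
            float(c)
    except ValueError:
        return False
    return True


def read_decay(
    path: str | Path,
    dialect: str = "auto",
    *,
    time_unit: str = "s",
    meta: AcquisitionMeta | None = None,
) -> DecayTrace:
    """Read a decay CSV into a :class:`DecayTrace`.

    Parameters
    ----------
    dialect
        ``two_col`` (time, intensity), ``three_col`` (time, real, imag) or
        ``auto`` to infer from the column count.
    time_unit
        Unit of the file's time column (``s``, ``ms`` or ``us``); values
        are rescaled to seconds on read.
    meta
        Acquisition metadata to attach; if omitted, a placeholder with tau
        inferred from the first echo time (t1 = 2*tau) is used.
    """
    if dialect not in ("auto", "two_col", "three_col"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if time_unit not in _TIME_UNITS:
        raise ValueError(f"time_unit must be one of {sorted(_TIME_UNITS)}")
    path = Path(path)
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise InsufficientDataError(f"{path}: file is empty")

    delim = _sniff_delimiter(lines[0])
    rows = [[c.strip() for c in ln.split(delim)] for ln in lines]

    # optional single header row, detected by non-numeric cells
    start = 0
    if not _is_numeric_row(rows[0]):
        start = 1
    data_rows = rows[start:]
    if len(data_rows) < 3:
        raise InsufficientDataError(
            f"{path}: need at least 3 data rows, got {len(data_rows)}"
        )

    ncols = len(data_rows[0])
    if ncols not in (2, 3):
        raise FormatError(f"{path}: expected 2 or 3 columns, got {ncols}")
    if dialect == "two_col" and ncols != 2:
        raise FormatError(f"{path}: dialect two_col requested but file has {ncols} columns")
    if dialect == "three_col" and ncols != 3:
        raise FormatError(f"{path}: dialect three_col requested but file has {ncols} columns")

    parsed = np.empty((len(data_rows), ncols), dtype=float)
    for i, row in enumerate(data_rows):
        if len(row) != ncols:
            raise FormatError(
                f"{path}: row {i + start} has {len(row)} columns, expected {ncols}"
            )
        for j, cell in enumerate(row):
            try:
                parsed[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at row {i + start}, column {j}",
                    row=i + start,
                ) from None

    time = parsed[:, 0] * _TIME_UNITS[time_unit]
    if ncols == 2:
        signal = parsed[:, 1].astype(complex)
        is_quadrature = False
    else:
        signal = parsed[:, 1] + 1j * parsed[:, 2]
        is_quadrature = True

    reordered = False
    if np.any(np.diff(time) <= 0):
        order = np.argsort(time, kind="stable")
        time, signal = time[order], signal[order]
        reordered = True
        warnings.warn(f"{path}: time column was out of order; rows re-sorted")

    if meta is None:
        meta = AcquisitionMeta(tau=float(time[0]) / 2.0, sample_code=path.stem)
    return DecayTrace(time=time, signal=signal, is_quadrature=is_quadrature,
                      meta=meta, reordered=reordered)


def write_decay(
    trace: DecayTrace,
    path: str | Path,
    dialect: str = "three_col",
    *,
    real_policy: str | None = None,
) -> None:
    """Write a trace as CSV at full float precision (re-readable exactly).

    ``two_col`` output of a quadrature trace requires an explicit
    ``real_policy`` of ``"real"`` or ``"magnitude"`` saying how to collapse
    the complex signal to one column.
    """
    path = Path(path)
    if dialect == "three_col":
        cols = (trace.time, trace.real, trace.imag)
    elif dialect == "two_col":
        if np.any(trace.imag != 0.0):
            if real_policy == "real":
                values = trace.real
            elif real_policy == "magnitude":
                values = np.abs(trace.signal)
            else:
                raise FormatError(
                    "two_col output of a quadrature trace needs "
                    "real_policy='real' or 'magnitude'"
                )
        else:
            values = trace.real
        cols = (trace.time, values)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    with path.open("w", newline="") as fh:
        for row in zip(*cols):
            fh.write(",".join(repr(float(v)) for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# manifests


def _parse_stressed(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n", ""):
        return False
    raise ParseError(f"cannot interpret stressed flag {value!r}")


def load_manifest(path: str | Path) -> StudyManifest:
    """Load a study manifest from JSON or CSV.

    JSON is either a list of entry objects or ``{"entries": [...]}``; CSV
    has the header ``sample_code,sample_class,concentration,stressed``.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise InsufficientDataError(f"{path}: manifest file is empty")

    records: Iterable[dict]
    if path.suffix.lower() == ".json" or text.startswith(("{", "[")):
        obj = json.loads(text)
        records = obj["entries"] if isinstance(obj, dict) else obj
    else:
        reader = csv.DictReader(text.splitlines())
        required = {"sample_code", "sample_class", "concentration", "stressed"}
        if reader.fieldnames is None or not required.issubset(set(reader.fieldnames)):
            raise FormatError(
                f"{path}: manifest CSV must have header columns {sorted(required)}"
            )
        records = list(reader)

    entries = []
    for rec in records:
        entries.append(
            ManifestEntry(
                sample_code=str(rec["sample_code"]),
                sample_class=str(rec["sample_class"]),
                concentration=float(rec["concentration"]),
                stressed=_parse_stressed(rec.get("stressed", False)),
            )
        )
    if not entries:
        raise InsufficientDataError(f"{path}: manifest has no entries")
    return StudyManifest(entries=tuple(entries))


def write_manifest(manifest: StudyManifest, path: str | Path) -> None:
    """Write a manifest as CSV (the dialect load_manifest reads back)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_code", "sample_class", "concentration", "stressed"])
        for e in manifest:
            writer.writerow([e.sample_code, e.sample_class, repr(e.concentration),
                             str(e.stressed).lower()])
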