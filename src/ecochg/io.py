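"""Reading and writing of insertion recordings, drop annotations and feature tables.

Two plain-text dialects are defined:

``ecochg-tsv v1``
    One recording per file.  A ``#``-prefixed ``key: value`` header carries the
    patient id and the stimulus configuration, followed by a tab-separated body
    with columns ``t_index, sample_index, rarefaction_uV, condensation_uV``.

``drops-tsv v1``
    Expert drop annotations, one row per interval, columns
    ``patient_id, start_t, end_t``.  Intervals are inclusive on both ends and
    index 0-based time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusConfig",
    "PolarityWindow",
    "InsertionRecording",
    "DropAnnotation",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
]

RECORDING_DIALECT = "ecochg-tsv v1"
ANNOTATION_DIALECT = "drops-tsv v1"


class ValidationError(ValueError):
    """A structural invariant of a recording or annotation was violated."""


class ParseError(ValueError):
    """A file could not be parsed under the declared dialect."""


@dataclass(frozen=True)
class StimulusConfig:
    """Acoustic stimulus and recording parameters for one insertion.

    Defaults match the standard low-frequency ECochG protocol: a 0.5 kHz tone
    pip of 12 ms with 1 ms linear ramps presented 14 times per second, each
    averaged waveform built from 100 presentations, recorded in 12 ms windows
    at 20 kHz (240 samples).
    """

    frequency_hz: float = 500.0
    duration_ms: float = 12.0
    ramp_ms: float = 1.0
    rate_per_s: float = 14.0
    n_averages: int = 100
    sample_rate_hz: float = 20000.0
    window_ms: float = 12.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValidationError("frequency_hz must be positive")
        if self.duration_ms > self.window_ms:
            raise ValidationError("tone-pip duration cannot exceed the recording window")
        n = self.window_ms * self.sample_rate_hz / 1000.0
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"window_ms x sample_rate_hz must give an integer sample count, got {n}"
            )

    @property
    def n_samples(self) -> int:
        """Number of samples in one recording window (240 at defaults)."""
        return int(round(self.window_ms * self.sample_rate_hz / 1000.0))


@dataclass(frozen=True)
class PolarityWindow:
    """One averaged rarefaction/condensation waveform pair (microvolts)."""

    t_index: int
    rarefaction: np.ndarray
    condensation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rarefaction, dtype=float)
        c = np.asarray(self.condensation, dtype=float)
        object.__setattr__(self, "rarefaction", r)
        object.__setattr__(self, "condensation", c)
        if r.ndim != 1 or c.ndim != 1:
            raise ValidationError("waveforms must be 1-D")
        if r.shape != c.shape:
            raise ValidationError(
                f"t={self.t_index}: rarefaction length {r.size} != condensation length {c.size}"
            )
        if not (np.isfinite(r).all() and np.isfinite(c).all()):
            raise ValidationError(f"t={self.t_index}: waveforms must be finite")


@dataclass(frozen=True)
class InsertionRecording:
    """Ordered sequence of polarity windows for one electrode insertion."""

    patient_id: str
    stimulus: StimulusConfig
    windows: tuple[PolarityWindow, ...]

    def __post_init__(self) -> None:
        ws = tuple(self.windows)
        object.__setattr__(self, "windows", ws)
        if not ws:
            raise ValidationError("a recording requires at least one window")
        for i, w in enumerate(ws):
            if w.t_index != i:
                raise ValidationError(
                    f"t_index must run 0,1,... without gaps; window {i} has t_index {w.t_index}"
                )
            if w.rarefaction.size != self.stimulus.n_samples:
                raise ValidationError(
                    f"t={i}: expected {self.stimulus.n_samples} samples, got {w.rarefaction.size}"
                )

    def __len__(self) -> int:
        return len(self.windows)


@dataclass(frozen=True)
class DropAnnotation:
    """Expert 'drop' intervals for one patient.

    Intervals are inclusive ``(start_t, end_t)`` time-point ranges running from
    the moment a real-time observer would first call the drop to its nadir.
    An empty interval list is a valid 'no drop' annotation.
    """

    patient_id: str
    intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        ivs = tuple((int(a), int(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        for a, b in ivs:
            if a < 0 or b < a:
                raise ValidationError(f"bad interval ({a},{b})")
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 <= b1:
                raise ValidationError(
                    f"intervals ({a1},{b1}) and ({a2},{b2}) overlap or are unsorted"
                )

    @property
    def has_drop(self) -> bool:
        return len(self.intervals) > 0

    def labels(self, n_timepoints: int) -> np.ndarray:
        """Per-time-point boolean drop labels (True inside any interval)."""
        lab = np.zeros(n_timepoints, dtype=bool)
        for a, b in self.intervals:
            if b >= n_timepoints:
                raise ValidationError(
                    f"interval ({a},{b}) exceeds recording length {n_timepoints}"
                )
            lab[a : b + 1] = True
        return lab


# ---------------------------------------------------------------------------
# recording files
# ---------------------------------------------------------------------------

_STIM_FIELDS = (
    "frequency_hz",
    "duration_ms",
    "ramp_ms",
    "rate_per_s",
    "n_averages",
    "sample_rate_hz",
    "window_ms",
)


def write_recording(rec: InsertionRecording, path: str | Path) -> None:
    """Write a recording in the ``ecochg-tsv v1`` dialect.

    Sample values are written with 17 significant digits so a round trip
    through :func:`read_recording` is bit-exact for doubles.
    """
    path = Path(path)
    lines = [f"# dialect: {RECORDING_DIALECT}", f"# patient_id: {rec.patient_id}"]
    for f in _STIM_FIELDS:
        lines.append(f"# {f}: {getattr(rec.stimulus, f)!r}")
    lines.append("t_index\tsample_index\trarefaction_uV\tcondensation_uV")
    for w in rec.windows:
        for i, (r, c) in enumerate(zip(w.rarefaction, w.condensation)):
            lines.append(f"{w.t_index}\t{i}\t{r:.17g}\t{c:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_recording(path: str | Path, format: str = RECORDING_DIALECT) -> InsertionRecording:
    """Read and validate an insertion recording (units are microvolts)."""
    if format != RECORDING_DIALECT:
        raise ParseError(f"unsupported recording dialect {format!r}")
    path = Path(path)
    header: dict[str, str] = {}
    body_start = 0
    with path.open() as fh:
        text = fh.read().splitlines()
    for i, line in enumerate(text):
        if not line.startswith("#"):
            body_start = i
            break
        try:
            key, value = line.lstrip("# ").split(":", 1)
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: malformed header line {line!r}") from exc
        header[key.strip()] = value.strip()
    else:
        raise ParseError(f"{path}: no body found")
    if header.get("dialect") != RECORDING_DIALECT:
        raise ParseError(f"{path}: missing or unknown dialect header")
    try:
        stim = StimulusConfig(
            frequency_hz=float(header["frequency_hz"]),
            duration_ms=float(header["duration_ms"]),
            ramp_ms=float(header["ramp_ms"]),
            rate_per_s=float(header["rate_per_s"]),
            n_averages=int(header["n_averages"]),
            sample_rate_hz=float(header["sample_rate_hz"]),
            window_ms=float(header["window_ms"]),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing header field {exc}") from exc

    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    expected = ["t_index", "sample_index", "rarefaction_uV", "condensation_uV"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    windows = []
    for t, grp in df.groupby("t_index", sort=True):
        grp = grp.sort_values("sample_index")
        if not np.array_equal(grp["sample_index"].to_numpy(), np.arange(len(grp))):
            raise ValidationError(f"{path}: t={t}: sample_index must run 0..n-1")
        windows.append(
            PolarityWindow(
                t_index=int(t),
                rarefaction=grp["rarefaction_uV"].to_numpy(float),
                condensation=grp["condensation_uV"].to_numpy(float),
            )
        )
    return InsertionRecording(header.get("patient_id", path.stem), stim, tuple(windows))


# ---------------------------------------------------------------------------
# annotation files
# ---------------------------------------------------------------------------

def write_annotations(
    annotations: Mapping[str, DropAnnotation] | Iterable[DropAnnotation],
    path: str | Path,
) -> None:
    """Write drop annotations in the ``drops-tsv v1`` dialect.

    Patients with no drops are recorded with an empty interval row
    (``start_t = end_t = -1``) so that 'no drop' recordings stay enumerable.
    """
    if isinstance(annotations, Mapping):
        anns: Sequence[DropAnnotation] = list(annotations.values())
    else:
        anns = list(annotations)
    lines = [f"# dialect: {ANNOTATION_DIALECT}", "patient_id\tstart_t\tend_t"]
    for ann in anns:
        if not ann.intervals:
            lines.append(f"{ann.patient_id}\t-1\t-1")
        for a, b in ann.intervals:
            lines.append(f"{ann.patient_id}\t{a}\t{b}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: str | Path) -> dict[str, DropAnnotation]:
    """Read a ``drops-tsv v1`` file into per-patient annotations.

    Returns a dict keyed by patient id; a ``(-1, -1)`` row denotes a patient
    explicitly annotated as having no drops.  Overlapping or unsorted
    intervals raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"patient_id": str})
    expected = ["patient_id", "start_t", "end_t"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    out: dict[str, DropAnnotation] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        ivs = [
            (int(a), int(b))
            for a, b in zip(grp["start_t"], grp["end_t"])
            if not (a == -1 and b == -1)
        ]
        ivs.sort()
        out[str(pid)] = DropAnnotation(str(pid), tuple(ivs))
    return out
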