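"""Per-time-point feature vectors for drop classification.

Eight primary features are computed from one harmonic pair's CM/ANN
measurements at each time point t:

====  =====================================================================
ft1   baselined CM amplitude (uV)
ft2   sin of the CM phase
ft3   baselined ANN amplitude (uV)
ft4   sin of the ANN phase
ft5   raw CM / raw ANN amplitude ratio
ft6   raw CM amplitude / active-peak CM amplitude
ft7   t_pk - t, time points since the active peak (non-positive)
ft8   coefficient of variation (sample std / mean) of the raw CM amplitude
      over the window t-4..t
====  =====================================================================

Baselining subtracts the mean of a channel's first five raw amplitudes from
every reading, absorbing between-patient differences in overall response
size.  Ratio and variability features (ft5-ft8) use raw amplitudes, since a
subtracted baseline can produce negative values that make ratios ill-defined.
Phases enter through their sine so the feature is continuous across the
principal-value branch cut.

Vectors exist for t >= 4 (the variability window needs five points).  In
extended mode the 8 features are computed for all four harmonic pairs over a
three-point window (t-2, t-1, t), giving 96 values per time point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import DropAnnotation, InsertionRecording
from .peaks import active_peak_series
from .processing import DEFAULT_HARMONIC_PAIRS, HarmonicMeasurement, extract_series

__all__ = [
    "FEATURE_NAMES",
    "NormalizationParams",
    "LabelledSeries",
    "baseline_amplitudes",
    "falling_edge_mask",
    "compute_features",
    "expand_features",
    "fit_minmax",
    "apply_minmax",
    "build_labelled_series",
]

FEATURE_NAMES = ("ft1", "ft2", "ft3", "ft4", "ft5", "ft6", "ft7", "ft8")

#: Points used for the per-series amplitude baseline.
BASELINE_POINTS = 5

#: Points (current + prior) in the ft8 variability window; first valid t.
CV_WINDOW = 5
FIRST_VALID_T = CV_WINDOW - 1

#: ft5 stand-in when the ANN amplitude is exactly zero; min-max clipping
#: bounds it downstream.
RATIO_SENTINEL = 1e6


def baseline_amplitudes(series: Sequence[float] | np.ndarray) -> np.ndarray:
    """Subtract the mean of the first five readings from every reading."""
    x = np.asarray(series, dtype=float)
    if x.size < BASELINE_POINTS + 1:
        raise ValueError(
            f"series of length {x.size} too short to baseline "
            f"(needs > {BASELINE_POINTS} points)"
        )
    return x - x[:BASELINE_POINTS].mean()


def falling_edge_mask(cm_amp: Sequence[float] | np.ndarray) -> np.ndarray:
    """True where the CM amplitude strictly decreased from the previous point.

    Rising or constant points are never drop candidates; index 0 is False.
    """
    x = np.asarray(cm_amp, dtype=float)
    mask = np.zeros(x.size, dtype=bool)
    if x.size > 1:
        mask[1:] = x[1:] < x[:-1]
    return mask


def compute_features(
    measurements: Sequence[HarmonicMeasurement],
    s_a: float = 0.5,
    s_b: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Compute the 8 primary features for one harmonic pair's series.

    The active peak is tracked causally on the raw CM amplitudes with the
    given promotion factors.  Returns ``(F, valid)`` where F has shape
    (n, 8); rows with ``valid`` False (t < 4) are NaN-filled.  Before the
    first active peak, ft6 is 1 and ft7 is 0 (a neutral "at the peak" state);
    a zero-mean variability window yields ft8 = 0.
    """
    cm_raw = np.array([m.cm_amp for m in measurements], dtype=float)
    ann_raw = np.array([m.ann_amp for m in measurements], dtype=float)
    cm_ph = np.array([m.cm_phase for m in measurements], dtype=float)
    ann_ph = np.array([m.ann_phase for m in measurements], dtype=float)
    n = cm_raw.size
    if n < BASELINE_POINTS:
        raise ValueError(f"need at least {BASELINE_POINTS} measurements")
    # inline baseline (first-5 mean) so a causal prefix of length >= 5 works;
    # whole recordings are still required to exceed the baseline window
    cm_base = cm_raw - cm_raw[:BASELINE_POINTS].mean()
    ann_base = ann_raw - ann_raw[:BASELINE_POINTS].mean()
    peaks = active_peak_series(cm_raw, s_a=s_a, s_b=s_b)

    F = np.full((n, 8), np.nan)
    valid = np.zeros(n, dtype=bool)
    for t in range(FIRST_VALID_T, n):
        pk = peaks[t]
        win = cm_raw[t - FIRST_VALID_T : t + 1]
        m = win.mean()
        F[t, 0] = cm_base[t]
        F[t, 1] = np.sin(cm_ph[t])
        F[t, 2] = ann_base[t]
        F[t, 3] = np.sin(ann_ph[t])
        F[t, 4] = cm_raw[t] / ann_raw[t] if ann_raw[t] > 0 else RATIO_SENTINEL
        F[t, 5] = cm_raw[t] / pk[1] if pk is not None else 1.0
        F[t, 6] = float(pk[0] - t) if pk is not None else 0.0
        F[t, 7] = win.std(ddof=1) / m if m != 0 else 0.0
        valid[t] = True
    return F, valid


def expand_features(
    per_pair: Mapping[tuple[float, float], np.ndarray],
    per_pair_valid: Mapping[tuple[float, float], np.ndarray],
    window: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-pair vectors over a trailing time window.

    With the default four harmonic pairs and a window of three time points
    (t-2, t-1, t) this yields 8 x 4 x 3 = 96 values per time point.  A row is
    valid only when every constituent vector exists (t >= 6 at defaults).
    Ordering is window offset (oldest first), then pair, then feature.
    """
    pairs = list(per_pair)
    n = next(iter(per_pair.values())).shape[0]
    width = 8 * len(pairs) * window
    F = np.full((n, width), np.nan)
    valid = np.zeros(n, dtype=bool)
    for t in range(window - 1, n):
        offsets = range(t - window + 1, t + 1)
        if all(per_pair_valid[p][u] for p in pairs for u in offsets):
            F[t] = np.concatenate([per_pair[p][u] for u in offsets for p in pairs])
            valid[t] = True
    return F, valid


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature min/max learned from training data, plus guard for
    degenerate (constant) features, which map to 0."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.maximum < self.minimum):
            raise ValueError("maximum must be >= minimum for every feature")


def fit_minmax(train: np.ndarray) -> NormalizationParams:
    """Learn per-feature min and max from training vectors (rows)."""
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    return NormalizationParams(train.min(axis=0), train.max(axis=0))


def apply_minmax(X: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Scale features into [0, 1] with training min/max; out-of-range test
    values are clipped so the classifier's input domain stays bounded."""
    X = np.asarray(X, dtype=float)
    span = params.maximum - params.minimum
    safe = np.where(span > 0, span, 1.0)
    out = (X - params.minimum) / safe
    out = np.where(span > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class LabelledSeries:
    """One insertion's extracted series with labels and masks, ready for
    training or evaluation.

    ``features`` rows for invalid time points are NaN; classification is
    restricted to ``valid & falling`` points.
    """

    patient_id: str
    cm_amp: np.ndarray  # raw CM amplitude series (primary pair)
    features: np.ndarray  # (n, 8) or (n, 96)
    valid: np.ndarray  # bool, feature row exists
    falling: np.ndarray  # bool, strictly falling edge
    expert: np.ndarray  # bool, expert 'drop' label per time point
    annotation: DropAnnotation

    @property
    def eligible(self) -> np.ndarray:
        """Time points that are classified: valid feature row on a falling edge."""
        return self.valid & self.falling


def build_labelled_series(
    rec: InsertionRecording,
    annotation: DropAnnotation,
    mode: str = "primary",
    s_a: float = 0.5,
    s_b: float = 0.1,
) -> LabelledSeries:
    """Extract harmonics, compute features and align expert labels.

    ``mode`` selects the 8 primary features (fundamental pair only) or the
    96-value extended set (all four pairs over a 3-point window).
    """
    if mode not in ("primary", "extended"):
        raise ValueError(f"unknown feature mode {mode!r}")
    pairs = DEFAULT_HARMONIC_PAIRS if mode == "extended" else DEFAULT_HARMONIC_PAIRS[:1]
    series = extract_series(rec, pairs)
    primary = series[DEFAULT_HARMONIC_PAIRS[0]]
    cm_amp = np.array([m.cm_amp for m in primary], dtype=float)

    per_pair: dict[tuple[float, float], np.ndarray] = {}
    per_valid: dict[tuple[float, float], np.ndarray] = {}
    for p, ms in series.items():
        per_pair[p], per_valid[p] = compute_features(ms, s_a=s_a, s_b=s_b)
    if mode == "primary":
        F, valid = per_pair[DEFAULT_HARMONIC_PAIRS[0]], per_valid[DEFAULT_HARMONIC_PAIRS[0]]
    else:
        F, valid = expand_features(per_pair, per_valid)

    return LabelledSeries(
        patient_id=rec.patient_id,
        cm_amp=cm_amp,
        features=F,
        valid=valid,
        falling=falling_edge_mask(cm_amp),
        expert=annotation.labels(len(cm_amp)),
        annotation=annotation,
    )
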