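"""Online drop detection over a stream of polarity windows.

The whole pipeline is causal, so streaming a recording window-by-window
produces exactly the labels of a batch pass; this module packages that loop
for live use.  Each pushed window yields ``(t, label)`` where the label
already includes the falling-edge restriction and post-processing.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .classifier import ModelBundle, predict
from .features import FIRST_VALID_T, apply_minmax, compute_features, expand_features
from .io import InsertionRecording, PolarityWindow, StimulusConfig
from .postprocess import apply_rules
from .processing import (
    DEFAULT_HARMONIC_PAIRS,
    compute_dif,
    compute_sum,
    harmonic_amplitude_phase,
    HarmonicMeasurement,
)

__all__ = ["StreamingDetector", "detect_recording"]


class StreamingDetector:
    """Consume polarity windows one at a time and emit causal drop labels."""

    def __init__(self, bundle: ModelBundle, stimulus: StimulusConfig) -> None:
        self.bundle = bundle
        self.stimulus = stimulus
        self.pairs = (
            DEFAULT_HARMONIC_PAIRS
            if bundle.feature_mode == "extended"
            else DEFAULT_HARMONIC_PAIRS[:1]
        )
        self._measurements: dict[tuple[float, float], list[HarmonicMeasurement]] = {
            p: [] for p in self.pairs
        }
        self._cm: list[float] = []
        self._falling: list[bool] = []
        self._raw_labels: list[bool] = []

    def push(self, window: PolarityWindow) -> tuple[int, bool]:
        """Process one window; return its time index and corrected label."""
        t = len(self._cm)
        dif = compute_dif(window)
        sm = compute_sum(window)
        for cf, af in self.pairs:
            cm_amp, cm_ph = harmonic_amplitude_phase(dif, cf, self.stimulus)
            ann_amp, ann_ph = harmonic_amplitude_phase(sm, af, self.stimulus)
            self._measurements[(cf, af)].append(
                HarmonicMeasurement(t, cf, af, cm_amp, cm_ph, ann_amp, ann_ph)
            )
        amp = self._measurements[self.pairs[0]][-1].cm_amp
        self._cm.append(amp)
        self._falling.append(t > 0 and amp < self._cm[t - 1])

        label = False
        if self._falling[t] and t >= self._first_valid():
            row = self._feature_row()
            if row is not None:
                X = apply_minmax(row[None, :], self.bundle.norm)
                label = bool(predict(self.bundle.model, X)[0])
        self._raw_labels.append(label)

        corrected = apply_rules(
            np.array(self._cm),
            np.array(self._falling),
            np.array(self._raw_labels),
            s_c=self.bundle.s_c,
        )
        out = bool(corrected[t]) and self._falling[t] and t >= self._first_valid()
        return t, out

    def _first_valid(self) -> int:
        return FIRST_VALID_T if self.bundle.feature_mode == "primary" else FIRST_VALID_T + 2

    def _feature_row(self) -> np.ndarray | None:
        b = self.bundle
        per, val = {}, {}
        for p, ms in self._measurements.items():
            per[p], val[p] = compute_features(ms, s_a=b.s_a, s_b=b.s_b)
        if b.feature_mode == "primary":
            F, valid = per[self.pairs[0]], val[self.pairs[0]]
        else:
            F, valid = expand_features(per, val)
        return F[-1] if valid[-1] else None


def detect_recording(
    bundle: ModelBundle, rec: InsertionRecording
) -> Iterator[tuple[int, bool]]:
    """Stream a full recording through the detector."""
    det = StreamingDetector(bundle, rec.stimulus)
    for w in rec.windows:
        yield det.push(w)
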