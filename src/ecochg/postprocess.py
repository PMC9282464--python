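"""Causal rule-based correction of per-point drop classifications.

Two corrections are applied in a single forward pass, using only the
patient's own recent signal so between-patient amplitude differences cannot
interfere:

Rule 1 (propagation): if the previous point lies on the same contiguous
falling run of the CM amplitude and was (after correction) called a 'drop',
the current falling point is also a 'drop' — a drop does not end while the
amplitude keeps falling.

Rule 2 (flat-region veto): a falling point called a 'drop' whose recent
amplitude window (the point plus up to four predecessors) is nearly flat —
sample standard deviation below ``s_c`` times the window minimum — is
corrected to 'no drop'; genuine drops move the signal far more than that.

Rule 2 is evaluated after Rule 1 at each point, so propagation cannot carry a
'drop' across a flat stretch.  ``s_c = 0.01`` is an empirically chosen
default.
"""

from __future__ import annotations

import numpy as np

__all__ = ["apply_rules", "S_C_DEFAULT"]

S_C_DEFAULT = 0.01

_WINDOW = 5  # current point + 4 predecessors


def apply_rules(
    cm_amp: np.ndarray,
    falling: np.ndarray,
    labels: np.ndarray,
    s_c: float = S_C_DEFAULT,
) -> np.ndarray:
    """Return corrected boolean drop labels.

    Inputs must be aligned per time point: the raw CM amplitude series, the
    strictly-falling-edge mask, and the classifier's labels (True = 'drop').
    The pass is causal — the corrected label at t depends only on indices
    <= t — and idempotent.
    """
    cm_amp = np.asarray(cm_amp, dtype=float)
    falling = np.asarray(falling, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if not (cm_amp.shape == falling.shape == labels.shape):
        raise ValueError("cm_amp, falling mask and labels must be aligned")

    out = labels.copy()
    for t in range(out.size):
        if not falling[t]:
            continue
        # Rule 1: propagate along the same falling run
        if t >= 1 and falling[t - 1] and out[t - 1]:
            out[t] = True
        # Rule 2: veto drops in near-flat windows (needs >= 2 points)
        if out[t] and t >= 1:
            win = cm_amp[max(0, t - _WINDOW + 1) : t + 1]
            if win.std(ddof=1) < s_c * win.min():
                out[t] = False
    return out
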