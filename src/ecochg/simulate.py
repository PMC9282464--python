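"""Synthetic ECochG cohorts with known ground truth.

No public corpus of intra-operative ECochG insertions exists, so the
pipeline is exercised on simulated cohorts.  Each patient gets:

* a positive CM amplitude trajectory — a multiplicative (log-amplitude)
  random walk around a per-patient baseline drawn from ``baseline_cm_range``,
  emulating the slow fluctuation of the response as the electrode advances;
* optionally one injected *drop*: a contiguous, strictly geometric decline of
  relative depth >= ``drop_depth`` (30% is the clinically prognostic loss),
  after which the amplitude stays at the reduced level — trauma does not
  heal mid-insertion;
* an ANN trajectory at a fixed fraction of the CM;
* rendered alternating-polarity waveforms: the CM components flip sign with
  stimulus polarity while the ANN distortion components do not, so the
  DIF/SUM decomposition recovers them exactly at zero noise.  White Gaussian
  noise per averaged waveform stands in for residual noise after
  100-presentation averaging.

Expert-style annotations mark each injected drop from one point after its
onset (a configurable reaction delay, emulating the time a live observer
needs to call a drop) to its nadir.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import DropAnnotation, InsertionRecording, PolarityWindow, StimulusConfig
from .processing import DEFAULT_HARMONIC_PAIRS

__all__ = ["CohortConfig", "GroundTruth", "Cohort", "generate_trajectory",
           "render_waveforms", "generate_recording", "generate_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    Amplitudes are in microvolts.  ``drop_depth`` is the minimum fractional
    CM loss of an injected drop (0.30 = the prognostic threshold);
    ``drop_depth_max`` bounds the sampled depth above.  ``trend_sd`` is the
    standard deviation of the log-amplitude random-walk step; at the default
    0.02 a spurious >= 30% decline within a drop-length window is essentially
    impossible, so injected drops are the only drops.
    """

    n_patients: int = 40
    n_timepoints: int = 100
    baseline_cm_range: tuple[float, float] = (1.0, 30.0)
    ann_fraction: float = 0.2
    noise_sd: float = 0.1
    drop_prob: float = 0.3
    drop_depth: float = 0.30
    drop_depth_max: float = 0.60
    drop_length: tuple[int, int] = (3, 8)
    trend_sd: float = 0.02
    reaction_delay: int = 1
    harmonic_decay: float = 0.15
    seed: int = 0
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.drop_depth < 1:
            raise ValueError("drop_depth must lie in [0, 1)")
        if not self.drop_depth <= self.drop_depth_max < 1:
            raise ValueError("drop_depth_max must lie in [drop_depth, 1)")
        if self.baseline_cm_range[0] <= 0:
            raise ValueError("baseline amplitudes must be positive")
        if self.n_timepoints < 20:
            raise ValueError("need at least 20 time points per insertion")
        if self.noise_sd < 0 or not 0 <= self.drop_prob <= 1:
            raise ValueError("noise_sd must be >= 0 and drop_prob in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """True generating amplitudes and injected drop intervals for one patient."""

    patient_id: str
    cm_amp: np.ndarray
    ann_amp: np.ndarray
    intervals: tuple[tuple[int, int], ...]  # strictly decreasing stretches


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    recordings: tuple[InsertionRecording, ...]
    annotations: dict[str, DropAnnotation]
    truth: dict[str, GroundTruth]

    @property
    def drop_patients(self) -> list[str]:
        return [pid for pid, a in self.annotations.items() if a.has_drop]


def _smooth_walk(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Positive amplitude walk with no spurious drop-sized decline.

    Resamples (rarely needed at default ``trend_sd``) until no point sits
    >= ``drop_depth`` below the running maximum of the preceding
    ``drop_length`` window.
    """
    base = rng.uniform(*cfg.baseline_cm_range)
    lmax = cfg.drop_length[1]
    for _ in range(1000):
        steps = rng.normal(0.0, cfg.trend_sd, cfg.n_timepoints - 1)
        amp = base * np.exp(np.concatenate([[0.0], np.cumsum(steps)]))
        ok = True
        for t in range(1, cfg.n_timepoints):
            recent_max = amp[max(0, t - lmax) : t].max()
            if amp[t] <= (1 - cfg.drop_depth) * recent_max:
                ok = False
                break
        if ok:
            return amp
    raise RuntimeError("could not draw a drop-free trajectory; lower trend_sd")


def generate_trajectory(
    cfg: CohortConfig,
    rng: np.random.Generator,
    with_drop: bool | None = None,
) -> tuple[np.ndarray, tuple[tuple[int, int], ...]]:
    """One CM amplitude trajectory and its injected drop intervals.

    ``with_drop`` forces or forbids a drop; None draws it with probability
    ``drop_prob``.  A drop replaces the walk from its onset with a geometric
    decline to ``1 - depth`` of the onset amplitude over ``length`` points
    (strictly decreasing by construction) and rescales the remainder of the
    walk so the loss persists.  The returned interval covers the strictly
    falling points, onset + 1 through nadir.
    """
    amp = _smooth_walk(cfg, rng)
    if with_drop is None:
        with_drop = bool(rng.random() < cfg.drop_prob)
    if not with_drop:
        return amp, ()
    lo, hi = cfg.drop_length
    length = int(rng.integers(lo, hi + 1))
    # onset after the baseline window, nadir well before the end
    onset = int(rng.integers(8, cfg.n_timepoints - length - 2))
    depth = float(rng.uniform(cfg.drop_depth, cfg.drop_depth_max))
    g = (1.0 - depth) ** (1.0 / length)
    out = amp.copy()
    for i in range(1, length + 1):
        out[onset + i] = amp[onset] * g**i
    tail = slice(onset + length + 1, None)
    out[tail] = amp[tail] * (out[onset + length] / amp[onset + length])
    return out, ((onset + 1, onset + length),)


def render_waveforms(
    cm_amp: np.ndarray,
    ann_amp: np.ndarray,
    phases: tuple[np.ndarray, np.ndarray] | None,
    cfg: CohortConfig,
    rng: np.random.Generator,
    patient_id: str = "P000",
) -> InsertionRecording:
    """Render alternating-polarity windows from amplitude trajectories.

    ``phases`` is a pair of arrays (CM, ANN), one phase per harmonic pair,
    fixed across the insertion; None means all zero.  Harmonic content above
    the fundamental decays geometrically by ``harmonic_decay`` per step so
    all four measurement pairs carry signal.  Components are full-window
    cosines: every frequency used lies on a DFT bin and completes an integer
    number of cycles in the window, so at zero noise the harmonic readout is
    exact.
    """
    cm_amp = np.asarray(cm_amp, dtype=float)
    ann_amp = np.asarray(ann_amp, dtype=float)
    stim = cfg.stimulus
    ns = stim.n_samples
    tt = np.arange(ns) / stim.sample_rate_hz
    if phases is None:
        phases = (np.zeros(len(DEFAULT_HARMONIC_PAIRS)), np.zeros(len(DEFAULT_HARMONIC_PAIRS)))
    cm_ph, ann_ph = phases
    windows = []
    for t in range(cm_amp.size):
        cm_part = np.zeros(ns)
        ann_part = np.zeros(ns)
        for i, (cf, af) in enumerate(DEFAULT_HARMONIC_PAIRS):
            scale = cfg.harmonic_decay**i
            cm_part += cm_amp[t] * scale * np.cos(2 * np.pi * cf * tt + cm_ph[i])
            ann_part += ann_amp[t] * scale * np.cos(2 * np.pi * af * tt + ann_ph[i])
        rar = cm_part + ann_part + rng.normal(0.0, cfg.noise_sd, ns)
        con = -cm_part + ann_part + rng.normal(0.0, cfg.noise_sd, ns)
        windows.append(PolarityWindow(t, rar, con))
    return InsertionRecording(patient_id, stim, tuple(windows))


def generate_recording(
    cfg: CohortConfig,
    rng: np.random.Generator,
    patient_id: str,
    with_drop: bool | None = None,
) -> tuple[InsertionRecording, DropAnnotation, GroundTruth]:
    """One patient: trajectory, rendered recording, annotation, ground truth."""
    cm_amp, intervals = generate_trajectory(cfg, rng, with_drop)
    ann_amp = cfg.ann_fraction * cm_amp
    n_pairs = len(DEFAULT_HARMONIC_PAIRS)
    phases = (rng.uniform(-np.pi, np.pi, n_pairs), rng.uniform(-np.pi, np.pi, n_pairs))
    rec = render_waveforms(cm_amp, ann_amp, phases, cfg, rng, patient_id)
    ann_intervals = tuple(
        (min(a + cfg.reaction_delay, b), b) for a, b in intervals
    )
    annotation = DropAnnotation(patient_id, ann_intervals)
    truth = GroundTruth(patient_id, cm_amp, ann_amp, intervals)
    return rec, annotation, truth


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """A reproducible cohort with ``ceil(n_patients * drop_prob)`` drop patients.

    The drop patients are a fixed-size random subset rather than independent
    Bernoulli draws, so downstream fold constraints (>= 1 drop patient per
    fold) are satisfiable whenever the count allows.
    """
    rng = np.random.default_rng(cfg.seed)
    n_drop = int(np.ceil(cfg.n_patients * cfg.drop_prob))
    droppers = set(rng.choice(cfg.n_patients, size=n_drop, replace=False).tolist())
    recordings, annotations, truth = [], {}, {}
    for i in range(cfg.n_patients):
        pid = f"P{i:03d}"
        rec, ann, gt = generate_recording(cfg, rng, pid, with_drop=i in droppers)
        recordings.append(rec)
        annotations[pid] = ann
        truth[pid] = gt
    return Cohort(cfg, tuple(recordings), annotations, truth)
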