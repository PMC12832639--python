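"""Synthetic resting-state EEG cohorts with planted microstate and spectral effects.

The generator emulates the structure of an eyes-closed clinical EEG
study of post-stroke cognitive impairment (PSCI): two groups whose
recordings differ by (a) elevated slow-wave (delta/theta) power
relative to alpha/beta, i.e. a higher DTABR, and (b) altered microstate
dynamics — longer class-A and class-B mean durations, higher class-A
coverage and fewer class-D occurrences in the impaired-like group.

A recording is rendered as ``x[:, t] = map(label[t]) * e[t] + noise``
where ``label`` is a sampled microstate sequence, ``map`` one of four
canonical topographies and ``e`` a broadband oscillatory envelope whose
amplitude spectrum follows a 1/f^(alpha/2) law shaped by per-band gain
multipliers.  Band gains are *amplitude* multipliers (power scales with
the square).  Amplitude units are arbitrary throughout: every
downstream feature is a power ratio or a label statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import Montage, standard_1020
from .recording import EEGRecording

CLASS_IDS = ("A", "B", "C", "D")

#: Band edges in Hz (half-open intervals).
BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}
BAND_NAMES = tuple(BAND_EDGES)


@dataclass(frozen=True)
class MicrostateTemplates:
    """Four canonical microstate class topographies (A-D).

    Each map is zero-mean across channels and unit Euclidean norm.
    """

    maps: np.ndarray                      # (4, n_channels)
    class_ids: tuple = CLASS_IDS

    def __post_init__(self):
        maps = np.asarray(self.maps, dtype=np.float64)
        if maps.ndim != 2 or maps.shape[0] != len(self.class_ids):
            raise ValueError("one map per class required")
        object.__setattr__(self, "maps", maps)

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class LabelSequence:
    """Per-sample microstate class indices; -1 marks unassigned samples."""

    labels: np.ndarray    # int array, values in {0..3} or -1
    fs: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size == 0:
            raise ValueError("empty label sequence")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.labels.size


def _center_normalize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate (constant) template")
    return v / n


def _gradient_map(montage: Montage, angle_deg: float) -> np.ndarray:
    """Linear scalp gradient along an axis in the horizontal plane.

    ``angle_deg`` is measured from +x (subject's right) toward +y
    (anterior); 45 deg gives the right-frontal / left-posterior
    diagonal of canonical microstate A.
    """
    a = np.deg2rad(angle_deg)
    axis = np.array([np.cos(a), np.sin(a), 0.0])
    return _center_normalize(montage.positions @ axis)


# Defining axis angles of the four canonical maps: A and B are
# mirror-image diagonal gradients, C the anterior-posterior gradient.
# The A/B axes sit 25 degrees off the left-right axis: steeper angles
# make the equal mixture of A and B (which any blurred A<->B transition
# passes through) nearly collinear with C and destroy class
# separability, while shallower angles make A and B themselves too
# strongly anticorrelated.
_CANONICAL_ANGLES = {"A": 25.0, "B": 155.0, "C": 90.0}


def _radial_map(montage: Montage, power: float = 1.0) -> np.ndarray:
    """Circularly symmetric profile decaying with distance from the vertex."""
    z = montage.positions[:, 2]          # cos(inclination), 1 at Cz
    return _center_normalize(((z + 1.0) / 2.0) ** power)


def synth_templates(montage: Montage) -> MicrostateTemplates:
    """Construct the four canonical microstate topographies.

    A and B are mirror-image diagonal gradients (right-left and
    left-right asymmetry), C an anterior-posterior gradient (left-right
    symmetric) and D a circularly symmetric vertex-centred profile.
    Deterministic; maps are centred and unit-normalised.
    """
    maps = np.vstack([
        _gradient_map(montage, _CANONICAL_ANGLES["A"]),
        _gradient_map(montage, _CANONICAL_ANGLES["B"]),
        _gradient_map(montage, _CANONICAL_ANGLES["C"]),
        _radial_map(montage, power=1.0),
    ])
    return MicrostateTemplates(maps=maps)


def candidate_template_bank(montage: Montage,
                            counts=(7, 5, 6, 3)) -> list:
    """Per-class candidate templates for the initialization search.

    Candidates are parametric perturbations of the canonical maps: for
    the gradient classes (A, B, C) the defining axis is rotated over an
    evenly spaced fan of +-30 degrees with the stated number of angles;
    for the radial class D the decay exponent is varied.  Returns a
    list of four arrays, one per class, each (n_candidates, n_channels).
    """
    if len(counts) != 4 or any(c < 1 for c in counts):
        raise ValueError("counts must be four positive integers")

    def fan(center, n):
        if n == 1:
            return np.array([center])
        return center + np.linspace(-30.0, 30.0, n)

    bank = []
    for cls, n in zip("ABC", counts[:3]):
        angles = fan(_CANONICAL_ANGLES[cls], n)
        bank.append(np.vstack([_gradient_map(montage, a) for a in angles]))
    n_d = counts[3]
    powers = np.array([1.0]) if n_d == 1 else np.linspace(0.5, 2.5, n_d)
    bank.append(np.vstack([_radial_map(montage, p) for p in powers]))
    return bank


def sample_label_sequence(mean_durations_ms, occurrence_weights,
                          duration_s: float, fs: float,
                          seed: int) -> LabelSequence:
    """Sample an alternating microstate sequence.

    Segment classes are drawn from ``occurrence_weights`` with no
    immediate self-transition; segment lengths are geometric
    (memoryless, truncated at 1 sample) with per-class means
    ``mean_durations_ms``.  Raises if a successor class cannot be drawn
    (single nonzero weight but more than one segment needed).
    """
    mean_durations_ms = np.asarray(mean_durations_ms, dtype=float)
    weights = np.asarray(occurrence_weights, dtype=float)
    if mean_durations_ms.shape != (4,) or weights.shape != (4,):
        raise ValueError("four classes expected")
    if np.any(mean_durations_ms <= 0):
        raise ValueError("mean durations must be positive")
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("occurrence weights must be non-negative and sum to 1")
    n_total = int(round(duration_s * fs))
    if n_total < 1:
        raise ValueError("at least one sample required")

    rng = np.random.default_rng(seed)
    mean_samples = np.maximum(mean_durations_ms * fs / 1000.0, 1.0)
    labels = np.empty(n_total, dtype=np.int64)
    pos = 0
    prev = -1
    while pos < n_total:
        w = weights.copy()
        if prev >= 0:
            w[prev] = 0.0
        total = w.sum()
        if total == 0:
            raise ValueError(
                "cannot draw a successor class without a self-transition "
                "(only one class has nonzero weight)")
        cls = rng.choice(4, p=w / total)
        length = rng.geometric(1.0 / mean_samples[cls])
        end = min(pos + length, n_total)
        labels[pos:end] = cls
        pos = end
        prev = cls
    return LabelSequence(labels=labels, fs=fs)


def _shaped_envelope(n: int, fs: float, band_gains: dict,
                     one_over_f_alpha: float, rng) -> np.ndarray:
    """Broadband envelope with a band-gain-shaped 1/f amplitude spectrum.

    Returned with unit RMS so sensor-noise SD is interpretable as a
    fraction of signal amplitude.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    # Envelope support 1-40 Hz: inside the PSD analysis range and almost
    # entirely inside the 1-35 Hz microstate band, so band-pass filtering
    # leaves rendered topographies nearly intact at label switches.
    f_lo, f_hi = 1.0, 40.0
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    amp[in_band] = freqs[in_band] ** (-one_over_f_alpha / 2.0)
    gain = np.ones_like(freqs)
    for band, (lo, hi) in BAND_EDGES.items():
        g = float(band_gains.get(band, 1.0))
        if not np.isfinite(g) or g <= 0:
            raise ValueError(f"band gain for {band!r} must be finite and > 0")
        gain[(freqs >= lo) & (freqs < hi)] = g
    spectrum = np.fft.rfft(rng.standard_normal(n)) * amp * gain
    env = np.fft.irfft(spectrum, n=n)
    rms = np.sqrt(np.mean(env ** 2))
    return env / rms if rms > 0 else env


def render_eeg(seq: LabelSequence, templates: MicrostateTemplates,
               montage: Montage, band_gains: dict | None = None,
               noise_sd: float = 0.0, seed: int = 0,
               one_over_f_alpha: float = 1.0,
               subject_id: str = "") -> EEGRecording:
    """Render an EEG recording from a microstate label sequence.

    Every sample is the active class map scaled by a shared broadband
    oscillatory envelope, plus independent Gaussian sensor noise of
    standard deviation ``noise_sd`` (in units of the unit-RMS envelope).
    """
    if templates.n_channels != montage.n_channels:
        raise ValueError("template length must equal montage size")
    band_gains = dict(band_gains or {})
    for g in band_gains.values():
        if not np.isfinite(g):
            raise ValueError("band gains must be finite")
    rng = np.random.default_rng(seed)
    env = _shaped_envelope(seq.n_samples, seq.fs, band_gains,
                           one_over_f_alpha, rng)
    data = templates.maps[seq.labels].T * env          # (n_ch, n_samples)
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return EEGRecording(data=data, fs=seq.fs, montage=montage,
                        subject_id=subject_id)


@dataclass(frozen=True)
class GroupEffect:
    """Per-group generative parameters.

    ``band_gains`` are amplitude multipliers applied to the envelope's
    amplitude spectrum within each canonical band; ``mean_durations_ms``
    and ``occurrence_weights`` parameterise the microstate sequence in
    class order A, B, C, D.
    """

    band_gains: dict = field(default_factory=dict)
    mean_durations_ms: tuple = (45.0, 45.0, 48.0, 43.0)
    occurrence_weights: tuple = (0.253, 0.253, 0.269, 0.225)

    def __post_init__(self):
        if any(d <= 0 for d in self.mean_durations_ms):
            raise ValueError("durations must be positive")
        w = np.asarray(self.occurrence_weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-6):
            raise ValueError("occurrence weights must sum to 1")
        object.__setattr__(self, "occurrence_weights",
                           tuple(w / w.sum()))


# Defaults emulate an eyes-closed clinical cohort: the control group has
# an alpha bump (DTABR near 1), the impaired-like group elevated
# delta/theta, longer A/B microstate durations and fewer D occurrences.
CONTROL_EFFECT = GroupEffect(
    band_gains={"delta": 1.0, "theta": 1.0, "alpha": 1.6, "beta": 1.2,
                "gamma": 0.8},
    mean_durations_ms=(45.0, 45.0, 48.0, 43.0),
    occurrence_weights=(0.253, 0.253, 0.269, 0.225),
)
PSCI_EFFECT = GroupEffect(
    band_gains={"delta": 1.5, "theta": 1.4, "alpha": 1.2, "beta": 1.0,
                "gamma": 0.8},
    mean_durations_ms=(55.0, 53.0, 48.0, 41.0),
    occurrence_weights=(0.28, 0.27, 0.28, 0.17),
)


def strong_effect_pair() -> tuple:
    """(control, impaired) group effects with exaggerated separation:
    delta/theta amplitude gains doubled, A/B mean durations +40% and the
    class-D occurrence weight halved relative to control."""
    ctrl = CONTROL_EFFECT
    w = np.asarray(ctrl.occurrence_weights, dtype=float).copy()
    w[3] *= 0.5
    w /= w.sum()
    psci = GroupEffect(
        band_gains={**ctrl.band_gains,
                    "delta": ctrl.band_gains.get("delta", 1.0) * 2.0,
                    "theta": ctrl.band_gains.get("theta", 1.0) * 2.0},
        mean_durations_ms=tuple(
            d * 1.4 if i < 2 else d
            for i, d in enumerate(ctrl.mean_durations_ms)),
        occurrence_weights=tuple(w),
    )
    return ctrl, psci


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a two-group synthetic cohort.

    ``n_per_group`` is (n_control, n_impaired).  Recording length and
    sampling rate default to the acquisition protocol the pipeline
    targets (3 min at 500 Hz); tests and examples use shorter
    recordings.
    """

    n_per_group: tuple = (87, 87)
    control: GroupEffect = CONTROL_EFFECT
    impaired: GroupEffect = PSCI_EFFECT
    duration_s: float = 180.0
    fs: float = 500.0
    noise_sd: float = 0.05
    one_over_f_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(n < 0 for n in self.n_per_group):
            raise ValueError("group counts must be non-negative")
        if sum(self.n_per_group) == 0:
            raise ValueError("cohort must contain at least one subject")


def simulate_cohort(spec: CohortSpec,
                    montage: Montage | None = None):
    """Simulate a labelled two-group cohort.

    Returns ``(recordings, metadata)`` where ``metadata`` is a
    DataFrame with columns subject_id, group, age, sex, outcome
    (outcome 1 = impaired-like group; sex 1 = male).  Age is drawn
    rounded-normal (mean 64, SD 8) clipped to [40, 80]; sex is
    Bernoulli with 0.68 male — demographics carry no outcome signal.
    Bit-identical output for identical specs.
    """
    montage = montage or standard_1020()
    templates = synth_templates(montage)
    rng = np.random.default_rng(spec.seed)
    recordings, rows = [], []
    idx = 0
    for outcome, (n, eff) in enumerate(
            zip(spec.n_per_group, (spec.control, spec.impaired))):
        for _ in range(n):
            seq_seed, render_seed = rng.integers(0, 2 ** 31, size=2)
            seq = sample_label_sequence(
                eff.mean_durations_ms, eff.occurrence_weights,
                spec.duration_s, spec.fs, seed=int(seq_seed))
            sid = f"S{idx:03d}"
            rec = render_eeg(seq, templates, montage,
                             band_gains=eff.band_gains,
                             noise_sd=spec.noise_sd,
                             seed=int(render_seed),
                             one_over_f_alpha=spec.one_over_f_alpha,
                             subject_id=sid)
            age = int(np.clip(np.round(rng.normal(64.0, 8.0)), 40, 80))
            sex = int(rng.random() < 0.68)
            recordings.append(rec)
            rows.append({"subject_id": sid,
                         "group": "impaired" if outcome else "control",
                         "age": age, "sex": sex, "outcome": outcome})
            idx += 1
    return recordings, pd.DataFrame(rows)


def planted_logistic_table(n: int = 300, n_noise: int = 20,
                           effect: float = 2.0, seed: int = 0,
                           signal_name: str = "signal") -> pd.DataFrame:
    """Tabular benchmark for the selection stage: one standard-normal
    predictor with the given log-odds ``effect`` plus ``n_noise``
    independent pure-noise predictors, with a Bernoulli outcome from
    the logistic model (intercept 0)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    noise = rng.standard_normal((n, n_noise))
    p = 1.0 / (1.0 + np.exp(-effect * x))
    y = (rng.random(n) < p).astype(int)
    table = pd.DataFrame(noise, columns=[f"noise_{i:02d}"
                                         for i in range(n_noise)])
    table.insert(0, signal_name, x)
    table["outcome"] = y
    return table


def null_cohort_spec(n_per_group=(40, 40), **kwargs) -> CohortSpec:
    """A cohort whose two groups share identical generative parameters."""
    return CohortSpec(n_per_group=n_per_group, control=CONTROL_EFFECT,
                      impaired=CONTROL_EFFECT, **kwargs)


def strong_effect_cohort_spec(n_per_group=(40, 40), **kwargs) -> CohortSpec:
    """A cohort with the exaggerated group separation of
    :func:`strong_effect_pair`."""
    ctrl, psci = strong_effect_pair()
    return CohortSpec(n_per_group=n_per_group, control=ctrl, impaired=psci,
                      **kwargs)
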