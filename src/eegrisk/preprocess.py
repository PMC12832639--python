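"""Deterministic signal conditioning and recording-level quality control.

All operations are shape-preserving and deterministic.  Independent
component analysis is intentionally absent: artifact handling enters
only through the per-sample artifact mask consumed by :func:`qc_screen`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.special import eval_legendre

from .recording import EEGRecording

#: Default QC thresholds: reject if MORE than 20% corrupted samples or
#: MORE than 3 nonfunctional channels (boundary values are accepted).
MAX_CORRUPT_FRACTION = 0.20
MAX_BAD_CHANNELS = 3


def bandpass(recording: EEGRecording, low_hz: float,
             high_hz: float, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass filter.

    ``order`` is the designed filter order before forward-backward
    application (the effective magnitude response is squared).
    """
    nyq = recording.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie inside (0, {nyq}) Hz")
    b, a = butter(order, [low_hz / nyq, high_hz / nyq], btype="bandpass")
    return recording.copy_with(filtfilt(b, a, recording.data, axis=1))


def common_average_reference(recording: EEGRecording) -> EEGRecording:
    """Re-reference to the common average: per-sample channel mean is
    subtracted from every channel.  Idempotent."""
    if recording.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return recording.copy_with(data)


def _g_matrix(cosang: np.ndarray, m: int = 4, n_terms: int = 7) -> np.ndarray:
    """Spherical-spline kernel g(cos angle) (Perrin et al. 1989),
    truncated Legendre series."""
    g = np.zeros_like(cosang, dtype=np.float64)
    for n in range(1, n_terms + 1):
        g += (2 * n + 1) / (n ** m * (n + 1) ** m) * eval_legendre(n, cosang)
    return g / (4.0 * np.pi)


def spherical_spline_matrix(good_pos: np.ndarray, bad_pos: np.ndarray,
                            m: int = 4, lam: float = 1e-5,
                            n_terms: int = 7) -> np.ndarray:
    """Interpolation matrix mapping good-channel values to bad-channel
    estimates by a regularized spherical spline on the unit sphere."""
    G = _g_matrix(good_pos @ good_pos.T, m, n_terms)
    G = G + lam * np.eye(G.shape[0])
    Gb = _g_matrix(bad_pos @ good_pos.T, m, n_terms)
    n_good = G.shape[0]
    # Solve [[G, 1], [1^T, 0]] [c; c0] = [v; 0]; estimate = Gb c + c0.
    A = np.zeros((n_good + 1, n_good + 1))
    A[:n_good, :n_good] = G
    A[:n_good, -1] = 1.0
    A[-1, :n_good] = 1.0
    Ainv = np.linalg.pinv(A)
    # Rows of B give [c; c0] as linear functions of v.
    B = Ainv[:, :n_good]
    return Gb @ B[:n_good] + B[-1]


def interpolate_channels(recording: EEGRecording,
                         bad_channels) -> EEGRecording:
    """Replace ``bad_channels`` (names or indices) by spherical-spline
    estimates from the remaining channels; good channels are untouched."""
    if not bad_channels:
        return recording.copy_with(recording.data.copy())
    bad_idx = np.array([
        ch if isinstance(ch, (int, np.integer)) else recording.montage.index(ch)
        for ch in bad_channels])
    good_idx = np.setdiff1d(np.arange(recording.n_channels), bad_idx)
    if good_idx.size == 0:
        raise ValueError("cannot interpolate: all channels marked bad")
    pos = recording.montage.positions
    W = spherical_spline_matrix(pos[good_idx], pos[bad_idx])
    data = recording.data.copy()
    data[bad_idx] = W @ recording.data[good_idx]
    return recording.copy_with(data)


@dataclass
class QCReport:
    """Outcome of the recording-level exclusion rule."""

    corrupted_fraction: float
    bad_channels: list
    accepted: bool
    reasons: list


def qc_screen(recording: EEGRecording,
              artifact_mask: np.ndarray | None = None,
              bad_channels=(),
              max_corrupt_fraction: float = MAX_CORRUPT_FRACTION,
              max_bad_channels: int = MAX_BAD_CHANNELS) -> QCReport:
    """Apply the exclusion rule: reject when more than
    ``max_corrupt_fraction`` of samples are marked corrupted or more
    than ``max_bad_channels`` channels are nonfunctional.  Boundary
    values are accepted."""
    if artifact_mask is None:
        frac = 0.0
    else:
        mask = np.asarray(artifact_mask, dtype=bool)
        if mask.size != recording.n_samples:
            raise ValueError("artifact mask length must equal n_samples")
        frac = float(mask.mean())
    bad = list(bad_channels)
    reasons = []
    if frac > max_corrupt_fraction:
        reasons.append(
            f"corruption: {frac:.1%} of samples exceed the "
            f"{max_corrupt_fraction:.0%} limit")
    if len(bad) > max_bad_channels:
        reasons.append(
            f"channels: {len(bad)} nonfunctional channels exceed the "
            f"limit of {max_bad_channels}")
    return QCReport(corrupted_fraction=frac, bad_channels=bad,
                    accepted=not reasons, reasons=reasons)
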