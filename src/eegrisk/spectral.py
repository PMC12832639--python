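"""Welch power spectra, band powers and regional power-ratio features.

The three clinical ratios are DAR = P_delta/P_alpha, DTR =
P_delta/P_theta and DTABR = (P_delta + P_theta)/(P_alpha + P_beta),
each computed over four electrode regions (global, frontal, central,
posterior) giving 12 dimensionless features per recording.  Regional
aggregation is the mean of channel band powers taken before forming
ratios (ratio of means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .montage import Montage, REGION_NAMES
from .recording import EEGRecording
from .synth import BAND_EDGES

#: Welch parameters: 4 s Hann segments, 50% overlap, density scaling.
SEGMENT_S = 4.0
PSD_RANGE_HZ = (0.5, 40.0)

RATIO_NAMES = ("DAR", "DTR", "DTABR")


@dataclass
class PSDResult:
    """Per-channel power spectral density on a common frequency grid."""

    freqs: np.ndarray          # (n_freqs,) Hz, strictly increasing
    power: np.ndarray          # (n_channels, n_freqs), amplitude^2/Hz

    def __post_init__(self):
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")


def welch_psd(recording: EEGRecording,
              segment_s: float = SEGMENT_S) -> PSDResult:
    """Welch PSD with Hann windows of ``segment_s`` seconds and 50%
    overlap; the frequency resolution is 1/segment_s at any sampling
    rate.  Requires at least one full segment of data."""
    nperseg = int(round(segment_s * recording.fs))
    if recording.n_samples < nperseg:
        raise ValueError(
            f"recording shorter than one {segment_s} s Welch segment")
    freqs, power = welch(recording.data, fs=recording.fs, window="hann",
                         nperseg=nperseg, noverlap=nperseg // 2,
                         scaling="density", axis=1)
    return PSDResult(freqs=freqs, power=power)


def band_power(psd: PSDResult, band) -> np.ndarray:
    """Trapezoidal integral of the PSD over the half-open band
    [low, high) Hz, per channel.  ``band`` is a name from the canonical
    set or an explicit (low, high) pair."""
    lo, hi = BAND_EDGES[band] if isinstance(band, str) else band
    if hi <= lo:
        raise ValueError(f"inverted band ({lo}, {hi})")
    sel = (psd.freqs >= lo) & (psd.freqs < hi)
    if sel.sum() < 2:
        raise ValueError(f"band ({lo}, {hi}) Hz not resolved by the grid")
    return np.trapezoid(psd.power[:, sel], psd.freqs[sel], axis=1)


@dataclass
class BandRatioFeatures:
    """Regional band powers and the 12 ratio features."""

    band_powers: dict          # region -> {band: mean power}
    ratios: dict               # "DAR_global" etc. -> float

    def as_row(self) -> dict:
        return dict(self.ratios)


def regional_ratios(psd: PSDResult, montage: Montage) -> BandRatioFeatures:
    """Band powers averaged over each region's channels, then DAR, DTR
    and DTABR per region: exactly 12 ratio features."""
    per_channel = {b: band_power(psd, b) for b in BAND_EDGES}
    band_powers, ratios = {}, {}
    for region in REGION_NAMES:
        idx = montage.region_indices(region)
        if idx.size == 0:
            raise ValueError(f"region {region!r} has no channels")
        p = {b: float(per_channel[b][idx].mean()) for b in BAND_EDGES}
        band_powers[region] = p
        ratios[f"DAR_{region}"] = p["delta"] / p["alpha"]
        ratios[f"DTR_{region}"] = p["delta"] / p["theta"]
        ratios[f"DTABR_{region}"] = (
            (p["delta"] + p["theta"]) / (p["alpha"] + p["beta"]))
    return BandRatioFeatures(band_powers=band_powers, ratios=ratios)


def spectral_features(recording: EEGRecording) -> dict:
    """Convenience wrapper: Welch PSD then the 12 regional ratios."""
    return regional_ratios(welch_psd(recording), recording.montage).as_row()
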