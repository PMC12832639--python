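"""In-memory containers for multichannel EEG and derived feature tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import Montage

#: Spectral ratio feature names, region-suffixed.
RATIO_COLUMNS = tuple(
    f"{ratio}_{region}"
    for ratio in ("DAR", "DTR", "DTABR")
    for region in ("global", "frontal", "central", "posterior")
)

#: Microstate temporal feature names.
MICROSTATE_COLUMNS = tuple(
    f"{cls}_{stat}" for cls in "ABCD" for stat in ("MMD", "MFO", "MC")
)

#: The 26 candidate predictors of the modelling stage.
FEATURE_COLUMNS = ("age", "sex") + RATIO_COLUMNS + MICROSTATE_COLUMNS

#: Binary outcome column (1 = impaired / positive class).
OUTCOME_COLUMN = "outcome"


@dataclass
class EEGRecording:
    """A resting-state EEG recording: channels x samples plus metadata.

    Amplitude units are arbitrary: every downstream feature is either a
    ratio or a label statistic, so absolute microvolt scaling is
    irrelevant and is not tracked.
    """

    data: np.ndarray        # (n_channels, n_samples)
    fs: float               # sampling rate, Hz
    montage: Montage
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"{self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return EEGRecording(data=data, fs=self.fs, montage=self.montage,
                            subject_id=self.subject_id)


def validate_feature_table(table: pd.DataFrame,
                           require_outcome: bool = True) -> None:
    """Check that a feature table carries the full candidate-predictor set.

    Raises ``ValueError`` naming every missing required column.  Extra
    columns are allowed (and ignored by modelling unless selected).
    """
    required = list(FEATURE_COLUMNS) + ([OUTCOME_COLUMN] if require_outcome else [])
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing required columns: {missing}")
    if table[list(FEATURE_COLUMNS)].isna().any().any():
        raise ValueError("feature table contains missing values")
    if require_outcome:
        vals = set(pd.unique(table[OUTCOME_COLUMN]))
        if not vals <= {0, 1}:
            raise ValueError(f"outcome must be binary 0/1, found {vals}")
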