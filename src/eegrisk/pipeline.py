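"""End-to-end feature extraction and cohort analysis.

Per recording: common-average reference, then (a) Welch spectra on the
broadband referenced signal for the 12 regional band-power ratios and
(b) a 1-35 Hz band-pass for the microstate stack (GFP peaks,
template-combination search, modified K-means, backfitting, 8-120 ms
segment filtering) yielding the 12 temporal statistics.  With age and
sex this gives the 26 candidate predictors per subject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import microstate as ms
from .montage import standard_1020
from .preprocess import bandpass, common_average_reference
from .recording import EEGRecording, FEATURE_COLUMNS, OUTCOME_COLUMN
from .spectral import spectral_features
from .synth import candidate_template_bank, synth_templates

#: Microstate clustering band, Hz.
MICROSTATE_BAND = (1.0, 35.0)

#: Candidate-template bank sizes of the full initialization search.
FULL_BANK_COUNTS = (7, 5, 6, 3)


def subject_features(recording: EEGRecording,
                     candidate_counts=FULL_BANK_COUNTS,
                     peak_kwargs: dict | None = None) -> dict:
    """The 24 EEG-derived features (12 spectral ratios + 12 microstate
    statistics) for one recording."""
    referenced = common_average_reference(recording)
    row = spectral_features(referenced)

    narrow = bandpass(referenced, *MICROSTATE_BAND)
    peaks = ms.extract_peaks(narrow, **(peak_kwargs or {}))
    bank = candidate_template_bank(recording.montage, candidate_counts)
    seg = ms.search_template_combinations(peaks, bank)
    templates = ms.match_templates_to_canonical(
        seg.templates, synth_templates(recording.montage))
    labels = ms.backfit(narrow, templates)
    filtered = ms.filter_segments(labels)
    row.update(ms.microstate_statistics(filtered).as_row())
    row["gev"] = seg.gev
    return row


def extract_features(recordings, metadata: pd.DataFrame | None = None,
                     candidate_counts=FULL_BANK_COUNTS,
                     peak_kwargs: dict | None = None) -> pd.DataFrame:
    """Feature table for a cohort.

    ``metadata`` (subject_id, age, sex and optionally outcome) is
    joined on subject order; without it, age/sex default to zero
    placeholders and no outcome column is emitted.
    """
    rows = []
    for i, rec in enumerate(recordings):
        row = {"subject_id": rec.subject_id or f"S{i:03d}"}
        if metadata is not None:
            meta = metadata.iloc[i]
            row["age"] = meta["age"]
            row["sex"] = meta["sex"]
        else:
            row["age"] = 0
            row["sex"] = 0
        row.update(subject_features(rec, candidate_counts=candidate_counts,
                                    peak_kwargs=peak_kwargs))
        if metadata is not None and OUTCOME_COLUMN in metadata.columns:
            row[OUTCOME_COLUMN] = int(metadata.iloc[i][OUTCOME_COLUMN])
        rows.append(row)
    table = pd.DataFrame(rows)
    ordered = ["subject_id"] + [c for c in FEATURE_COLUMNS] + \
        [c for c in ("gev", OUTCOME_COLUMN) if c in table.columns]
    return table[ordered]
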