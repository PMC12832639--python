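"""EEG microstate analysis.

The stack: global field power (GFP), GFP-peak extraction, a
polarity-invariant modified K-means over peak topographies with a
deterministic template-combination initialization search, global
explained variance (GEV), winner-take-all backfitting of the whole
recording, duration-based segment filtering, and the three per-class
temporal statistics

* MMD — mean duration of a class occurrence, ms;
* MFO — occurrences of the class per second of analysis time, Hz;
* MC  — percentage of analysis time covered by the class.

Under these definitions MC = MMD * MFO / 10 holds exactly per class,
and the MC values sum to the assigned (post-filter) fraction of time.

All topographic comparisons use polarity-invariant spatial correlation:
a map and its negation are the same microstate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .recording import EEGRecording
from .synth import CLASS_IDS, LabelSequence, MicrostateTemplates

UNASSIGNED = -1

#: Segment-duration acceptance window, ms.
MIN_SEGMENT_MS = 8.0
MAX_SEGMENT_MS = 120.0

#: GFP peak picking defaults: per-60-s segments, 10 ms minimum spacing,
#: peaks above mean + 2 SD discarded as outliers.
PEAK_SEGMENT_S = 60.0
MIN_PEAK_SPACING_MS = 10.0
PEAK_SD_MULT = 2.0


@dataclass
class GFPSeries:
    """Global field power: per-sample spatial (population) SD across
    channels."""

    values: np.ndarray
    fs: float


def gfp(recording: EEGRecording) -> GFPSeries:
    """GFP as the population standard deviation of channel amplitudes at
    each sample."""
    if recording.n_channels < 2:
        raise ValueError("GFP requires >= 2 channels")
    return GFPSeries(values=recording.data.std(axis=0, ddof=0),
                     fs=recording.fs)


@dataclass
class PeakSet:
    """Retained GFP peaks: sample indices and their channel vectors."""

    indices: np.ndarray            # strictly increasing sample positions
    maps: np.ndarray               # (n_peaks, n_channels)

    def __post_init__(self):
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return self.indices.size


def find_gfp_peaks(series: GFPSeries,
                   segment_s: float = PEAK_SEGMENT_S,
                   min_spacing_ms: float = MIN_PEAK_SPACING_MS,
                   sd_mult: float = PEAK_SD_MULT) -> np.ndarray:
    """Indices of retained GFP peaks.

    The series is processed in independent ``segment_s`` segments (a
    shorter final segment as-is).  Within a segment, local maxima
    closer than ``min_spacing_ms`` are thinned keeping the larger, and
    maxima exceeding the segment mean + ``sd_mult`` * SD are discarded.
    A constant series yields no peaks.
    """
    fs = series.fs
    spacing = max(int(round(min_spacing_ms * fs / 1000.0)), 1)
    seg_len = max(int(round(segment_s * fs)), 1)
    out = []
    for start in range(0, series.values.size, seg_len):
        seg = series.values[start:start + seg_len]
        idx, _ = find_peaks(seg, distance=spacing)
        if idx.size:
            ceiling = seg.mean() + sd_mult * seg.std(ddof=0)
            idx = idx[seg[idx] <= ceiling]
        out.append(idx + start)
    return np.concatenate(out) if out else np.array([], dtype=int)


def extract_peaks(recording: EEGRecording, **kwargs) -> PeakSet:
    """GFP-peak extraction on a recording: compute GFP, pick peaks,
    collect the channel vectors at the retained samples."""
    idx = find_gfp_peaks(gfp(recording), **kwargs)
    return PeakSet(indices=idx, maps=recording.data[:, idx].T)


def _center_rows(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=1, keepdims=True)


def spatial_correlation(maps: np.ndarray,
                        templates: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels between each map (rows) and
    each template (rows): (n_maps, n_templates).  Zero-GFP maps get
    correlation 0."""
    v = _center_rows(np.atleast_2d(maps))
    t = _center_rows(np.atleast_2d(templates))
    t = t / np.linalg.norm(t, axis=1, keepdims=True)
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    return (v / safe) @ t.T


@dataclass
class MicrostateSegmentation:
    """Result of clustering GFP-peak maps into the four classes."""

    templates: MicrostateTemplates
    peak_labels: np.ndarray          # per-peak class index
    gev: float                       # in [0, 1]
    gev_per_class: np.ndarray        # contributions summing to gev
    gev_trace: list = field(default_factory=list)   # per-iteration GEV
    n_initializations: int = 1

    def __post_init__(self):
        if not 0.0 <= self.gev <= 1.0 + 1e-9:
            raise ValueError(f"GEV {self.gev} outside [0, 1]")


def _gev_terms(centered: np.ndarray, templates: np.ndarray,
               labels: np.ndarray) -> np.ndarray:
    """Per-peak corr^2 * GFP^2 terms for the assigned templates."""
    corr = spatial_correlation(centered, templates)
    picked = corr[np.arange(labels.size), labels]
    gfp2 = centered.var(axis=1, ddof=0)
    return picked ** 2 * gfp2


def modified_kmeans(peaks: PeakSet, init: MicrostateTemplates,
                    max_iter: int = 500,
                    tol: float = 1e-6) -> MicrostateSegmentation:
    """Polarity-invariant modified K-means over GFP-peak maps.

    Alternates (i) assigning each peak to the template with maximal
    squared spatial correlation and (ii) recomputing each template as
    the dominant eigenvector of its assigned (spatially centred) maps.
    Stops when the GEV improvement falls below ``tol`` or after
    ``max_iter`` iterations.  GEV is guaranteed non-decreasing: both
    steps maximise the same GFP^2-weighted squared-correlation
    objective.
    """
    k = init.maps.shape[0]
    if peaks.n_peaks < k:
        raise ValueError(f"need at least {k} peaks, got {peaks.n_peaks}")
    V = _center_rows(peaks.maps.astype(np.float64))
    gfp2 = V.var(axis=1, ddof=0)
    denom = gfp2.sum()
    if denom == 0:
        raise ValueError("all peak maps are spatially constant")

    templates = np.array([
        m - m.mean() for m in init.maps], dtype=np.float64)
    templates /= np.linalg.norm(templates, axis=1, keepdims=True)

    labels = np.argmax(spatial_correlation(V, templates) ** 2, axis=1)
    gev = _gev_terms(V, templates, labels).sum() / denom
    trace = [gev]
    for _ in range(max_iter):
        # Template update: dominant eigenvector of each cluster's
        # scatter matrix (polarity-proof; eigenvectors of centred maps
        # are automatically zero-mean).
        for j in range(k):
            members = V[labels == j]
            if members.shape[0] == 0:
                continue
            scatter = members.T @ members
            w, vecs = np.linalg.eigh(scatter)
            t = vecs[:, -1]
            t = t - t.mean()
            norm = np.linalg.norm(t)
            if norm > 0:
                templates[j] = t / norm
        labels = np.argmax(spatial_correlation(V, templates) ** 2, axis=1)
        gev_new = _gev_terms(V, templates, labels).sum() / denom
        trace.append(gev_new)
        if gev_new - gev < tol:
            gev = gev_new
            break
        gev = gev_new

    per_class = np.array([
        _gev_terms(V, templates, labels)[labels == j].sum() / denom
        for j in range(k)])
    return MicrostateSegmentation(
        templates=MicrostateTemplates(maps=templates,
                                      class_ids=init.class_ids),
        peak_labels=labels, gev=float(gev), gev_per_class=per_class,
        gev_trace=trace)


def search_template_combinations(peaks: PeakSet, candidate_sets,
                                 max_iter: int = 500,
                                 tol: float = 1e-6) -> MicrostateSegmentation:
    """Deterministic initialization search over one-candidate-per-class
    combinations.

    Runs :func:`modified_kmeans` from every combination (Cartesian
    product of per-class candidate banks, e.g. 7 x 5 x 6 x 3 = 630) and
    returns the run with the highest final GEV; ties keep the
    lexicographically smallest candidate-index tuple.
    """
    if any(len(c) == 0 for c in candidate_sets):
        raise ValueError("every class needs at least one candidate template")
    best = None
    n_evaluated = 0
    for combo in itertools.product(*(range(len(c)) for c in candidate_sets)):
        init = MicrostateTemplates(maps=np.vstack([
            np.asarray(candidate_sets[cls][i])
            for cls, i in enumerate(combo)]))
        seg = modified_kmeans(peaks, init, max_iter=max_iter, tol=tol)
        n_evaluated += 1
        if best is None or seg.gev > best.gev:
            best = seg
    best.n_initializations = n_evaluated
    return best


def backfit(recording: EEGRecording,
            templates: MicrostateTemplates) -> LabelSequence:
    """Winner-take-all labelling: every sample gets the class whose
    template has maximal squared spatial correlation with the sample's
    topography (ties break in class order A < B < C < D)."""
    corr = spatial_correlation(recording.data.T, templates.maps)
    return LabelSequence(labels=np.argmax(corr ** 2, axis=1),
                         fs=recording.fs)


def _runs(labels: np.ndarray):
    """Maximal contiguous runs as (start, length, value) triples."""
    if labels.size == 0:
        return
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [labels.size]))
    for s, e in zip(starts, ends):
        yield s, e - s, labels[s]


def filter_segments(seq: LabelSequence,
                    min_ms: float = MIN_SEGMENT_MS,
                    max_ms: float = MAX_SEGMENT_MS) -> LabelSequence:
    """Relabel segments shorter than ``min_ms`` or longer than
    ``max_ms`` as unassigned.  Surviving runs are untouched; runs
    separated by an excluded gap are never merged (the gap stays
    unassigned)."""
    labels = seq.labels.copy()
    for start, length, value in _runs(seq.labels):
        if value == UNASSIGNED:
            continue
        dur_ms = length / seq.fs * 1000.0
        if dur_ms < min_ms or dur_ms > max_ms:
            labels[start:start + length] = UNASSIGNED
    return LabelSequence(labels=labels, fs=seq.fs)


@dataclass
class MicrostateStats:
    """Per-class temporal statistics of a (possibly filtered) label
    sequence."""

    mmd_ms: dict                    # class id -> mean occurrence duration
    mfo_hz: dict                    # class id -> occurrences per second
    mc_pct: dict                    # class id -> % of analysis time
    assigned_fraction: float        # % of samples carrying a class label

    def as_row(self) -> dict:
        row = {}
        for cls in CLASS_IDS:
            row[f"{cls}_MMD"] = self.mmd_ms[cls]
            row[f"{cls}_MFO"] = self.mfo_hz[cls]
            row[f"{cls}_MC"] = self.mc_pct[cls]
        return row


def microstate_statistics(seq: LabelSequence) -> MicrostateStats:
    """MMD, MFO and MC per class.

    Occurrences are maximal contiguous runs of a class; the analysis
    time (denominator of MFO and MC) is the full sequence length
    including unassigned samples, which makes MC = MMD * MFO / 10 an
    exact identity and the MC values sum to the assigned fraction.
    """
    total_s = seq.n_samples / seq.fs
    mmd, mfo, mc = {}, {}, {}
    for j, cls in enumerate(CLASS_IDS):
        lengths = np.array([
            length for _, length, value in _runs(seq.labels) if value == j])
        n_occ = lengths.size
        n_samples = int(lengths.sum())
        mmd[cls] = float(lengths.mean() / seq.fs * 1000.0) if n_occ else 0.0
        mfo[cls] = n_occ / total_s
        mc[cls] = n_samples / seq.n_samples * 100.0
    assigned = float((seq.labels != UNASSIGNED).mean() * 100.0)
    return MicrostateStats(mmd_ms=mmd, mfo_hz=mfo, mc_pct=mc,
                           assigned_fraction=assigned)


def match_templates_to_canonical(fitted: MicrostateTemplates,
                                 canonical: MicrostateTemplates
                                 ) -> MicrostateTemplates:
    """Reorder fitted templates so class j best matches canonical class
    j by polarity-invariant correlation (greedy best-first matching)."""
    corr = np.abs(spatial_correlation(fitted.maps, canonical.maps))
    order = np.full(len(canonical.class_ids), -1)
    used_f, used_c = set(), set()
    for _ in range(len(canonical.class_ids)):
        masked = corr.copy()
        for f in used_f:
            masked[f, :] = -1
        for c in used_c:
            masked[:, c] = -1
        f, c = np.unravel_index(np.argmax(masked), masked.shape)
        order[c] = f
        used_f.add(f)
        used_c.add(c)
    return MicrostateTemplates(maps=fitted.maps[order],
                               class_ids=canonical.class_ids)
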