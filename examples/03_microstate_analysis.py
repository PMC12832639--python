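"""The microstate stack on one rendered recording.

GFP peaks are clustered by polarity-invariant modified K-means with a
deterministic template-combination search; the winning templates are
backfitted to every sample, 8-120 ms segments are kept, and the three
temporal statistics are reported per class (A-D).
"""

import eegrisk as er
from eegrisk import microstate as ms

montage = er.standard_1020()
templates = er.synth_templates(montage)
seq = er.sample_label_sequence((45.0, 45.0, 48.0, 43.0),
                               (0.25, 0.25, 0.27, 0.23),
                               duration_s=60.0, fs=250.0, seed=3)
rec = er.render_eeg(seq, templates, montage, noise_sd=0.05, seed=4)

narrow = er.bandpass(er.common_average_reference(rec), 1.0, 35.0)
peaks = ms.extract_peaks(narrow)
bank = er.candidate_template_bank(montage, (7, 5, 6, 3))
seg = ms.search_template_combinations(peaks, bank)
print(f"{peaks.n_peaks} GFP peaks, {seg.n_initializations} initializations "
      f"searched, best GEV = {seg.gev:.3f}")

fitted = ms.match_templates_to_canonical(seg.templates, templates)
labels = ms.filter_segments(ms.backfit(narrow, fitted))
stats = ms.microstate_statistics(labels)
print(f"assigned fraction after 8-120 ms filter: "
      f"{stats.assigned_fraction:.1f}%")
for cls in "ABCD":
    print(f"  class {cls}: MMD {stats.mmd_ms[cls]:5.1f} ms   "
          f"MFO {stats.mfo_hz[cls]:4.2f} /s   MC {stats.mc_pct[cls]:5.1f} %")
print("\nGEV is the GFP^2-weighted variance fraction the four maps explain;"
      "\nMC = MMD x MFO / 10 holds exactly under these definitions.")
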