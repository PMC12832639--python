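"""Welch band powers and the 12 regional power-ratio features.

Doubling the delta/theta amplitude gains of the rendered EEG raises
DTABR = (P_delta + P_theta) / (P_alpha + P_beta) in every region, the
direction associated with post-stroke cognitive impairment.
"""

import eegrisk as er

montage = er.standard_1020()
templates = er.synth_templates(montage)
seq = er.sample_label_sequence((50.0,) * 4, (0.25,) * 4,
                               duration_s=60.0, fs=500.0, seed=1)

for label, gains in (("flat gains", {}),
                     ("delta/theta x2", {"delta": 2.0, "theta": 2.0})):
    rec = er.render_eeg(seq, templates, montage, band_gains=gains, seed=2)
    ratios = er.regional_ratios(er.welch_psd(rec), montage).ratios
    print(f"{label:16s} "
          + "  ".join(f"DTABR_{r}={ratios[f'DTABR_{r}']:.2f}"
                      for r in ("global", "frontal", "central",
                                "posterior")))
print("\nhigher DTABR = more slow-wave relative to fast activity.")
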