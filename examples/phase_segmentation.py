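"""Segment a severe and a mild synthetic fall into the three fall phases.

A 513-sample frame is cut around the critical point (the record-wide norm
maximum, local index 192).  The impact phase is 21 samples when the peak
exceeds 6 g and 31 samples otherwise; the free-fall phase is always the 32
samples before it; the rest phase runs to the end of the frame.
"""

import fallphase as fp

for name, peak in (("severe (7 g)", 7.0), ("mild (4.5 g)", 4.5)):
    ann = fp.gen_fall(fp.SimConfig(seed=42, impact_peak=peak), "stand")
    frame = fp.record_to_frame(ann.record)
    seg = fp.segment_phases(frame)
    print(f"{name}: situation={seg.situation.value}")
    for phase, span in (("free fall", seg.free_fall), ("impact", seg.impact),
                        ("rest", seg.rest)):
        print(f"  {phase:<10} samples [{span[0]:3d}, {span[1]:3d}]  "
              f"length {span[1] - span[0] + 1}")
    ff, imp, rest = fp.featurize_phases(frame, seg)
    names = fp.feature_names(descriptive=True)
    mean_norm = names.index("mean_a_norm")
    print(f"  mean |a| per phase (g): free fall {ff[mean_norm]:.2f}, "
          f"impact {imp[mean_norm]:.2f}, rest {rest[mean_norm]:.2f}")
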