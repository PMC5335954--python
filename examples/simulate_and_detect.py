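"""Generate labeled data, train the hierarchical detector, classify held-out
records.

Each output row shows the ground-truth activity, the decision, and which
stage decided: ``threshold`` means the frame's norm maxima were conclusive
on their own; ``knowledge`` means the multiphase classifier and the
temporal-order rule (FreeFall -> Impact -> Rest) had to resolve it.
Knowledge-stage routing appears on held-out frames whose peaks land between
the learned threshold pairs — typically mild falls and brisk lie-downs.
"""

import fallphase as fp

train = fp.gen_dataset(n_falls=24, n_adls=24, seed=3)
test = fp.gen_dataset(n_falls=10, n_adls=10, seed=90)

frames = [fp.record_to_frame(ann.record) for ann in train]
labels = [ann.label for ann in train]
thresholds = fp.fit_thresholds(
    [(fp.frame_extrema(f), lab.is_fall) for f, lab in zip(frames, labels)]
)
print(f"learned thresholds (g): fall v>{thresholds.t_fall_xyz:.2f}, w>{thresholds.t_fall_hori:.2f}; "
      f"ADL v<{thresholds.t_adl_xyz:.2f}, w<{thresholds.t_adl_hori:.2f}")

model = fp.train_phase_model(
    [f for f, lab in zip(frames, labels) if lab.is_fall], thresholds
)

print(f"{'activity':<18}{'truth':<7}{'decision':<10}{'stage':<11}phases")
for ann in test:
    d = fp.detect(ann.record, model)
    phases = "->".join(p.value for p in d.prediction.labels) if d.prediction else "-"
    print(f"{ann.label.name:<18}{'fall' if ann.label.is_fall else 'adl':<7}"
          f"{'fall' if d.is_fall else 'adl':<10}{d.stage:<11}{phases}")
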