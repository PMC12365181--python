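# lcsod — relation-biased surgical-object detection

Detecting anatomy and instruments in laparoscopic cholecystectomy frames is
unusual among detection problems: the objects are few, co-occur in
stereotyped spatial arrangements (the gallbladder, the cystic duct and
artery, the hepatocystic triangle, one or two working tools), and their
positional relationships carry real signal — a structure with faint visual
features can often be localized from where the clearly visible structures
are. This package implements, at desk scale and fully testable without any
external data, the ingredients of a relation-based detection pipeline for
such scenes:

* **Macroscopic correlation (MC)** — a per-image statistic quantifying how
  strongly a set of boxes co-varies: the mean absolute Pearson correlation
  over ordered pairs of box 4-vectors `B = [x, y, w, h]`,
  `MC = Σ_a Σ_{b≠a} |PCC(B_a, B_b)| / (N(N−1)) ∈ [0, 1]`, with the
  conventional low/moderate/strong bands at 0.3 and 0.5.
* **A relation-biased detection transformer** — a DETR-style mini detector
  whose decoder self-attention logits receive a learned, clamped per-head
  bias `relation(B, B') = max(ε, W·Embed(e(B, B')) + A)` computed from
  pairwise box geometry `e(B_a, B_b) = [log(|Δx|/w_a + 1), log(|Δy|/h_a + 1),
  log(w_a/w_b), log(h_a/h_b)]` under a sinusoidal embedding
  (`T, d, s = 10000, 16, 100`). Two query streams share the decoder:
  *matching* queries (relation-biased self-attention, one-to-one Hungarian
  assignment, used at inference) and *hybrid* queries (plain self-attention,
  one-to-K repeated-ground-truth assignment for extra positive supervision,
  training only).
* **Per-class top-k postprocessing** — keep the k best-scoring predictions
  per image and class (k = 1, with k = 2 for classes that may appear twice),
  collapsing the over-complete raw per-query output to clinically plausible
  counts.
* **A COCO-protocol evaluator** — per-class AP with 101-point interpolation
  over IoU thresholds 0.50:0.05:0.95, PR-curve export.
* **A synthetic scene generator** — laparoscopy-like layouts with a single
  coupling knob ρ controlling inter-box positional correlation, flat-color
  rendering that a CPU-trained mini model can learn, and fabricated
  over-complete prediction sets for postprocessing experiments.

The detector trains on a small autodiff engine over numpy included in the
package (`lcsod.autodiff`), so everything runs on one CPU with no deep
learning framework.

## Worked example

Contrast the two dataset regimes and run the postprocessing step:

```python
import dataclasses
from lcsod import mc_distribution, topk_filter, reduction_report, KMap
from lcsod.synthetic import (endoscapes_like, m2cai16_like,
                             generate_scene_dataset, generate_prediction_set)

for preset in (endoscapes_like, m2cai16_like):
    cfg = dataclasses.replace(preset(150, seed=0), render_style="none")
    ds = generate_scene_dataset(cfg)
    rep = mc_distribution(ds.annotations)
    print(preset.__name__, rep.band_counts, "undefined:", rep.n_undefined,
          "strong fraction: %.3f" % rep.band_fractions()["strong"])

cfg = dataclasses.replace(endoscapes_like(50, seed=1), render_style="none")
ds = generate_scene_dataset(cfg)
raw = generate_prediction_set(ds.annotations, queries_per_image=100, seed=1)
filtered = topk_filter(raw, KMap(default_k=1, overrides={"tool": 2}),
                       ds.annotations)
rep = reduction_report(raw, filtered, ds.annotations)
print("raw:", rep.totals.n_before, "kept:", rep.totals.n_after,
      "reduction: %.1f%%" % rep.total_count_reduction_percent)
```

prints

```
endoscapes_like {'low': 2, 'moderate': 5, 'strong': 143} undefined: 0 strong fraction: 0.953
m2cai16_like {'low': 25, 'moderate': 20, 'strong': 98} undefined: 7 strong fraction: 0.685
raw: 5000 kept: 350 reduction: 93.0%
```

The anatomy-style preset concentrates 95% of images in the strong MC band
(boxes clustered around a shared anchor with correlated sizes), while the
tool-only preset spreads across bands and reports single-box images as
undefined rather than zero. Top-k filtering collapses 100 raw scored boxes
per image to at most 7 (six classes at k = 1, one at k = 2), a 93%
reduction.

The same flows are available from the shell:

```
lcsod generate --preset endoscapes-like --n 150 --seed 0 --out scenes/
lcsod mc --annotations scenes/annotations.json --out mc.json --plot mc.png
lcsod train --data scenes/ --epochs 10 --seed 0 --out run/
lcsod predict --model run/checkpoint.npz --data scenes/ --out preds.json
lcsod postprocess --pred preds.json --gt scenes/annotations.json \
    --out filtered.json --report reduction.csv
lcsod evaluate --gt scenes/annotations.json --pred filtered.json --out eval.json
```

Training the mini detector (64-d, 2+2 layers, 20 matching + 40 hybrid
queries) for 10 epochs on 200 easy synthetic scenes takes about a minute on
one CPU and reaches a held-out AP@50 in the 70-85 range across seeds; the
end-to-end trainability check in `tests/test_acceptance.py` asserts ≥ 50
for at least 2 of 3 seeds.

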