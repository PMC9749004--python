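# microdet

Micro-domain boundary detection in clustered single-molecule fragment-view
images.

## The problem

Multi-way chromatin contact assays — ChIA-Drop and SPRITE — read out
*single-molecule complexes*: sets of genomic fragments sharing one droplet
barcode (a GEM) or split-pool tag.  Clustering the complexes that fall
inside one TAD or RNAPII-associated interaction domain (RAID) dissects it
into **micro-domains** (micro-TADs / micro-RAIDs).  The clusters are easy
to see in a *fragment view* — fragments drawn at their genomic x positions,
one complex per row, rows grouped by cluster — but their genomic
*boundaries* still have to be delimited.

`microdet` treats boundary calling as object detection on the fragment-view
image.  It:

1. renders clustered complex tables into deterministic fragment-view PNGs
   while recording the exact affine pixel ↔ genomic mapping
   (`render.RenderMap`);
2. trains a two-stage detector (Faster R-CNN contract: anchor grid → region
   proposal network → RoI pooling → classification + box-regression heads)
   on rectangle annotations of micro-domains, either imported from LabelMe
   JSON or generated automatically for synthetic data;
3. merges duplicate detections by **vertical IoU** (IoU of the boxes'
   y-axis projections, threshold 0.8) and transforms the merged boxes'
   left/right edges back to genomic coordinates — the micro-domain calls;
4. evaluates calls with **genomic IoU** — for intervals *a*, *b* on one
   chromosome, gIoU = |a ∩ b| / |a ∪ b| in base pairs — plus greedy TP/FP/FN
   matching, precision/recall/F1, P–R curve with all-point interpolated
   AP/mAP, ROC/AUROC, and k-fold cross-validation splitting.

A synthetic-data generator (`microdet.simulate`) plants disjoint
micro-domain intervals in a region, fills each with a cluster of complexes
whose fragments stay inside it, and adds background complexes — so the
whole pipeline trains, detects and evaluates with no external data.

The detector itself is a compact CPU implementation (numpy, hand-derived
gradients over a fixed ink-density feature backbone) so that a full
train/detect/evaluate cycle finishes in minutes on one core.

## Worked example

Simulate a 25-image corpus (2–4 planted micro-domains per ~200 kb region),
train on 20 images, then call and score micro-domains on the 5 held-out
images:

```python
from pathlib import Path
from microdet import (DetectorConfig, FragmentViewDetector, SyntheticSpec,
                      calls_from_detections, evaluate_calls, make_dataset)
from microdet.render import read_render_map
from microdet.simulate import read_truth_table

spec = SyntheticSpec(seed=100, complexes_per_domain=20)
corpus = make_dataset(spec, 25, out_dir="corpus", n_domains_per_image=[2, 3, 4])
names = sorted(p.name for p in corpus.image_paths)
train_names, test_names = names[:20], names[20:]

model = FragmentViewDetector.from_corpus(
    corpus.out_dir, DetectorConfig(epochs=60, seed=1), image_names=train_names
)
results = model.fit()
print(results.summary())

truth_by_image = read_truth_table(corpus.truth_table)
calls, truths = [], []
for name in test_names:
    rmap = read_render_map(corpus.out_dir / name)
    calls += calls_from_detections(results.detect(corpus.out_dir / name), rmap)
    truths += [iv for iv, _ in truth_by_image[name]]
print(evaluate_calls(calls, truths).summary())
```

which prints:

```
Fragment-view detector training
------------------------------------------
epochs                      60
training images             20
backbone                    tiny
checkpoints saved           60 (final: epoch 60)
total_loss first -> last    1.3055 -> 0.3519
rpn accuracy first -> last  0.920 -> 1.000
Micro-domain evaluation
----------------------------------
TP / FP / FN      15 / 2 / 0
precision         0.882
recall            1.000
F1                0.938
accuracy          0.882
mean gIoU         0.843
```

All 15 held-out micro-domains are recovered (recall 1.0), two spurious
calls overlap nothing (precision 0.88), and the matched calls agree with
the planted intervals to a mean gIoU of 0.84 — i.e. called boundaries
cover 84% of the union of call and truth.  `accuracy` is TP/(TP+FP+FN),
the only sensible definition in a detection setting without true
negatives.

The same pipeline is scriptable from the shell —
`microdet simulate / render / import-annotations / train / detect / call /
evaluate / crossval` — with BED6 output for genome-browser tracks; run
`microdet --help`.

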