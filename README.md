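# herbocr

Ensemble OCR and consensus transcription for herbarium specimen labels.

## The problem

Natural-history collections hold millions of imaged herbarium sheets whose
label text — species, locality, collector, date — still has to become
machine-readable data. No single image-processing recipe or OCR engine
copes with the heterogeneity of labels (aging paper, historic typefaces,
skewed mounts, stains and speckles), so any one configuration fails badly
on some fraction of labels.

`herbocr` implements a label-digitization workflow for collections staff
and informatics developers that treats OCR the way molecular systematics
treats sequencing reads: produce several imperfect observations of the
same underlying text and merge them.

## The method

For each label image, up to **8 OCR streams** are produced — four
cumulative pre-processing variants (V1 unmodified; V2 blur → rescale →
orient upright → deskew; V3 = V2 + Sauvola adaptive binarization
`T = m·(1 + k·(s/R − 1))`; V4 = V3 + despeckle/hole-fill) × two engines
(Tesseract, EasyOCR, or a seeded noise simulator for engine-free testing).
The streams are then merged:

1. **Outlier pruning.** Streams with Levenshtein distance > 128 from both
   members of the globally closest pair are discarded (complete OCR
   failures).
2. **Multiple sequence alignment.** Survivors are progressively aligned
   with a global affine-gap aligner (gap open −3, extension −0.5).
   Instead of PAM/BLOSUM, columns are scored with a **visual similarity
   matrix**: +2 identical glyphs, +1 lookalikes (`l/1/I/|`, `O/0`, case
   pairs, …), down to −2 for grossly different shapes (a period vs. a W).
3. **Consensus.** Each column's plurality symbol is emitted (a winning gap
   emits nothing), giving the raw label text with per-character support.
4. **Post-processing.** Ordered substitution rules, intra-word space
   repair, and lexicon spell correction that only acts on a *unique*
   neighbor within edit distance 1 — abstaining otherwise.

The package also ships the surrounding tooling: crowd-annotation
bounding-box reconciliation (IoU-based outlier removal, corner-mean
averaging, majority-rule typing), correction-click cleaning,
prediction-vs-truth IoU scoring, a synthetic label renderer + OCR-noise
simulator, and an exhaustive sweep of all **(2⁸ − 1) × 2 = 510** pipeline
permutations scored by cumulative Levenshtein error against a verbatim
gold standard.

## Worked example

```python
import numpy as np
from herbocr import *
from herbocr.engines import LabelStyle, SimulatedEngine
from herbocr.pipeline import STREAM_KEYS, compute_streams
from herbocr.preproc import PreprocParams

text = "Flora of Texas\nTravis County\nQuercus alba L.\nCollected 12 May 1967"
img = render_label(text, LabelStyle(skew_deg=3.0), seed=1)

adapters = {
    "easyocr": SimulatedEngine(NoiseModel(0.04, 0.01, 0.02, seed=7), "easyocr"),
    "tesseract": SimulatedEngine(NoiseModel(0.05, 0.01, 0.02, seed=7), "tesseract"),
}
streams = compute_streams(img, adapters, PreprocParams(target_long_side=400))

for key in STREAM_KEYS:
    print(f"{key[0]:12s} {key[1]:10s} errors={levenshtein(streams[key].text, text)}")

perm = Permutation(frozenset(STREAM_KEYS), postprocess=False)
consensus = run_permutation(streams, perm)
print("consensus errors:", levenshtein(consensus.text, text))
print("min column support:", min(consensus.support))
```

prints

```
V1_none      easyocr    errors=4
V1_none      tesseract  errors=6
V2_deskew    easyocr    errors=7
V2_deskew    tesseract  errors=7
V3_binarize  easyocr    errors=3
V3_binarize  tesseract  errors=7
V4_denoise   easyocr    errors=2
V4_denoise   tesseract  errors=5
consensus errors: 0
min column support: 0.625
```

Every individual stream carries 2–7 character errors, yet the aligned
ensemble recovers the label perfectly; the least-supported consensus
column still won 5 of 8 votes.

A CLI wraps the same operations: `herbocr simulate` renders fixtures,
`herbocr ocr` transcribes images, `herbocr sweep` / `herbocr evaluate`
score permutations against a gold TSV, and `herbocr find-labels` handles
box-annotation JSON.

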