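# Methods

This note records the models, defaults, and design decisions behind
`herbocr`, in the spirit of a package reference manual: what each stage
assumes, which knobs matter, and what the synthetic test bed does and does
not demonstrate.

## Box reconciliation

Each physical label is outlined independently by several participants
(three, matching the usual crowd retirement limit). Reconciliation:

* **Outlier removal** is iterative: while any outline's mean IoU against
  the other survivors is below the threshold (default 0.5), the worst
  outline is dropped and means are recomputed. A one-shot rule fails on
  the common case of one grossly wrong outline among three: the two good
  outlines' means are dragged under the threshold by the bad one. IoU is
  used because it is also the evaluation metric, so "very different" is
  judged on the same scale the detector is scored on. If no core of at
  least two mutually consistent outlines remains, reconciliation raises
  and the sheet routes to human review.
* **Averaging** is the arithmetic mean of each of the four box
  coordinates over survivors — the simplest estimator consistent with
  averaging outlines.
* **Typing** is strict majority over surviving votes; ties and
  all-distinct votes return `unresolved` rather than guessing.

Boxes are 0-based pixel rectangles with inclusive-min/exclusive-max
corners (`area = Δx·Δy`); click containment is boundary-inclusive, and a
click inside nested boxes is attributed to the smallest-area box.
Prediction scoring matches greedily in descending IoU (ties: prediction
order), restricted to overlapping pairs; greedy is deterministic and
adequate at the ≤ ~10 labels found on a sheet, where it nearly always
coincides with optimal assignment.

## Pre-processing variants

Four cumulative variants feed the ensemble; every transform appends to a
provenance list so any output image can carry a full report of the steps
that created it.

| parameter | default | notes |
|---|---|---|
| blur sigma | 0.5 px | mild smoothing before rescale |
| target long side | 4096 px | a size most OCR engines handle well |
| Sauvola window | 31 px | local statistics window (odd) |
| Sauvola k | 0.2 | standard document-binarization setting |
| Sauvola R | 128 | dynamic range of std for 8-bit input |
| min speck | 4 px | foreground components below this area are snow |
| min hole | 4 px | enclosed background below this area is filled |
| deskew range / step | ±10° / 0.1° | coarse 1° pass, then fine refinement |

Numerical choices:

* **Orientation** (multiples of 90°) uses a projection-profile heuristic:
  the text-line axis maximizes the variance of row sums, and the upright
  direction within that axis is chosen by bottom-heaviness of line runs
  (Latin type concentrates mass between baseline and x-height, with
  ascenders outnumbering descenders). Engine-based orientation detection
  can be slotted in through the adapter layer; the built-in heuristic
  keeps the core dependency-free. Blank pages return 0° with a
  low-confidence flag.
* **Deskew** maximizes row-projection variance over the angle grid,
  evaluated on a ≤512-px downsampled copy; corner fill uses the mean ink
  value so rotation itself introduces no contrast, and near-ties prefer
  the smallest |angle| (a featureless image deskews to exactly 0°).
* **Sauvola** thresholds `T = m·(1 + k·(s/R − 1))` with mirror-padded
  windows; a window larger than the image is clamped with a warning.
  Foreground is dark-on-light ink; binary images store {0, 1} with 1 =
  ink.
* **Despeckle/fill** removes 8-connected foreground components smaller
  than `min_speck` and fills 4-connected, fully enclosed background
  components smaller than `min_hole`; border-touching background is never
  a hole. The operation is idempotent.

## Ensemble consensus

* **Levenshtein pruning** (cutoff 128, configurable): the anchor is the
  globally closest stream pair; any stream farther than the cutoff from
  both anchors is discarded. This reading guarantees a surviving core of
  two streams while discarding complete OCR failures; a
  k-nearest-neighbour rule is a reasonable alternative and the cutoff is
  exposed for it. With ≤ 2 streams nothing is pruned.
* **Visual similarity matrix**: +2 identical; +1 case pairs and
  within-class lookalikes (`l1I|!`, `O0o`, `S5s`, `Z2z`, `B8`, `G6`,
  `mn`, `E3`, `uv`); 0 otherwise-dissimilar letter–letter, digit–digit or
  punctuation–punctuation pairs; −1 letter vs digit; −2 across gross
  shape categories (whitespace or punctuation vs anything else). Only the
  ±2 endpoints are anchored by the method's definition; the intermediate
  values are a shipped, documented default, loadable/overridable from a
  TSV (membership rows + class-pair score rows, validated for symmetry,
  range, and the +2 diagonal). Space is an ordinary alphabet character:
  it matters in label text.
* **Affine gaps**: open −3, extension −0.5, with the *first* gap symbol
  of a run costing the open penalty (a length-2 gap costs −3.5). The
  aligner is Gotoh-style with three DP layers, vectorized row-wise; the
  in-row horizontal-gap recurrence is resolved with a running-max prefix
  trick, exact because the extension penalty is linear in run length.
  Traceback ties prefer pairing characters over gaps, then a gap in the
  second sequence. Scores are compared with a 1e-9 tolerance (exact for
  the default half-integer scores).
* **Progressive MSA** (center-star-style): the seed is the stream with
  minimum summed Levenshtein distance to the rest; remaining streams
  merge in ascending distance order against the growing profile, scoring
  a character against a column as the mean similarity over the column's
  non-gap symbols. Once introduced, a gap column persists. Exact
  multi-sequence DP is exponential in stream count; progressive alignment
  handles 8 label-length streams in milliseconds, and the pairwise core
  is guarded by an exhaustive-enumeration oracle in the tests.
* **Consensus**: per-column plurality with the gap as a full candidate
  (a winning gap emits nothing); ties prefer the seed row's symbol, then
  the lexicographically smallest leader. Support = winning votes / rows.
* **Pre-alignment substitutions** (per stream, before pruning): drop
  whitespace before `.,;:`, collapse space runs; the character
  substitution list is empty by default and configurable. Applied
  per-stream before alignment; the heavier cleanup runs post-consensus,
  where a single pass serves all streams at once.

## Post-processing

Ordered regex substitution rules (word-scoped or free), split-word repair
(join two fragments when only the join is in the lexicon), and spell
correction with radius 1 that only fires on a *unique* lexicon neighbour
— zero or multiple candidates abstain. Numeral-only tokens are exempt:
labels are dense in dates, elevations and collector numbers that no
wordlist can vouch for. Tokens already in the lexicon are never touched.
Every change is logged as a positional edit; replaying the log reproduces
the output exactly, and the whole pass is idempotent. The bundled starter
lexicon covers the botanical/geographic vocabulary of the synthetic
generator plus common label boilerplate; production use should merge
institution-specific wordlists via `load_lexicon`.

## Evaluation

The error metric is character-level Levenshtein distance between a
pipeline output and the verbatim gold transcription, after stripping
leading/trailing whitespace only (configurable: `none`, `collapse_ws`).
Verbatim gold forbids semantic normalization — errors printed on the
label stay. A missing output counts as the gold text's full length and is
flagged. The sweep computes each of the 8 streams once per label and
reuses them across all 510 permutations (subset of streams ×
post-processing flag); single-stream permutations bypass pruning and
alignment, since the consensus of one text is itself. Reports carry
provenance (tool version, configuration hash).

## The synthetic test bed

`render_label` rasterizes label-like text (herbarium header, scientific
name, locality, habitat, collector/number/date lines) with known skew and
a counted number of isolated single-pixel speckles, returning the ground
truth alongside the image. `simulate_ocr` corrupts truth text with
per-character substitution (biased into the same lookalike classes the
similarity matrix scores +1), insertion and deletion rates, fully
deterministic per seed.

Default study conditions for recovery experiments: 8 streams per label,
total per-character error rates drawn uniformly from 5–10 % per stream
(split 60 % substitutions, 20 % insertions, 20 % deletions — substitutions
dominate real OCR confusions), labels of 200–600 characters. These rates
are in the range where individual streams are clearly degraded but not
useless, which is the regime the ensemble targets.

What the simulator does **not** emulate: correlated errors between
engines (real engines fail on the same smudge), line-reordering and
column-segmentation failures, handwriting, and engine-specific whitespace
conventions. Passing the recovery tests therefore shows the consensus
machinery extracts the shared signal from independently corrupted
streams; it does not bound error rates on real imagery, where stream
errors correlate and gains are smaller.

## Acceptance script

`scripts/acceptance.py` reports, per run: the permutation-space size; a
full 510-permutation sweep over a 6-label synthetic gold standard (best
total error, the single-engine no-post baseline, their ratio, and whether
the best row used post-processing); ensemble recovery statistics over 20
replicates × 20 labels (win rate of the full ensemble + post-processing
against every single-stream configuration, consensus vs mean stream
character error rate); and mean reconciliation IoU over 200 jittered
three-outline fixtures with 20 % planted gross outliers. Problem sizes
are chosen so a run completes in a few minutes on one CPU; the
error-reduction ratio saturates (reported against a floor of one error)
when the best permutation is error-free at this scale. Ties at zero
errors make the "best row" under-determined; rows are then ordered by
configuration name, so the post-processing indicator is not meaningful in
that degenerate case.

## Known limitations

* No detector ships: finding label boxes on full sheets expects an
  external model or precomputed box JSON (the reconciliation and scoring
  tooling is detector-agnostic).
* Real-engine adapters (Tesseract/EasyOCR) are thin optional wrappers;
  engine versions are recorded in provenance but outputs are
  environment-dependent and never anchor tests.
* The orientation heuristic assumes Latin typography; scripts without
  ascender-dominant lines may need the engine-based orientation path.
* Spell correction is lexicon-bound and radius-1; it will not repair
  heavily corrupted tokens, by design.
* Only typewritten labels are OCR-eligible in the label-record JSON;
  handwritten and mixed labels pass through untranscribed.
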