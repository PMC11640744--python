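# Methods

This note documents the model choices, parameters and numerical decisions
behind the package, and what its synthetic benchmarks do and do not show.

## Pipeline and assumptions

The pipeline classifies fixed-length multichannel EEG windows ("segments")
into two classes and explains its feature choices symbolically. It assumes:

- segments are complete numeric matrices (no missing samples); no
  filtering, re-referencing or artifact rejection is applied — the feature
  extractor consumes raw amplitudes;
- segments group into records (one continuous recording), and every record
  carries exactly one class label and one subject;
- the channel order is a fixed montage, because the explanation layer maps
  channel indices to lobe symbols positionally.

### Feature extraction (ChMinMaxPat)

Only the *identities* of the extreme channels at each timepoint enter the
features, never the amplitudes themselves. This makes the features
invariant to any common-mode shift of all channels at a timepoint
(asserted as a property test) and insensitive to global scaling.

Two deviation conventions are implemented for the id3/id4 identities:

- `absolute` (default): distance from the per-timepoint channel mean,
  `|x - mean|`;
- `signed`: the raw deviation `x - mean`. Subtracting the mean is a
  constant shift across channels, so in this mode id3 ≡ id1 and id4 ≡ id2
  identically — tables tt2/tt5 collapse to diagonals and tt3/tt6 duplicate
  tt1. The mode is retained behind a flag because the method's printed
  definition is the signed difference, but a degenerate extractor cannot
  produce 15 distinct per-vector behaviours, so the absolute reading is
  the default. The degeneracy itself is asserted as a theorem-style test.

Tie-breaking for argmax/argmin is lowest channel index. Transition tables
are row-normalized by `row / (rowsum + epsilon)` with `epsilon = 1e-10`
(configurable); all-zero rows stay zero. Map histograms are raw counts
(each sums to the segment length); only tables are normalized. fv1–fv6 use
row-major flattening, which fixes the decoding used by the explanation
layer.

### Feature selection (CWNCA)

Weights come from diagonal-metric NCA feature weighting: dissimilarity
`sum_j w_j^2 |x_ij - x_i'j| / sigma`, stochastic-neighbour probabilities,
objective `sum_i p_i - lambda * sum_j w_j^2`. Defaults: `sigma = 1`,
`lambda = 1/n`, start at `w = 1`, at most 100 iterations, initial step
0.1. Features are z-scored inside the fit; zero-variance columns get
weight 0; negative weights are clipped to 0 on output.

A fixed step size is not stable here — the gradient norm grows with both
the sample count and the feature count — so the ascent uses an
accept/reject rule: an improving step is kept and the step size grows
1.1×, a worsening step is rejected and the step halves; the fit stops
early when the gradient or step becomes negligible. The procedure is
deterministic. The pairwise |difference| table is precomputed once per fit
(float64 up to 2·10⁷ elements, float32 up to 2·10⁸, chunked recomputation
beyond that).

Selection keeps the smallest descending-weight prefix whose cumulative
normalized weight reaches the threshold (default 0.99; ties prefer the
lower feature index; all-zero weights fall back to one feature with a
warning). Note a consequence of the cut semantics: with two equally
informative features and all other weights at zero, a threshold of 0.5
keeps only one of them — low thresholds select *mass*, not *membership*.

Selection is computed once on the full dataset, before cross-validation.
This follows the method's published protocol and is optimistic: test-set
labels influence which features the classifier sees. The consequences are
quantified below.

### Classification (tkNN) and fusion (IMV)

An "outcome" is the out-of-fold prediction vector over all segments for
one configuration, with its accuracy against the true labels. The 60-cell
grid is k = 1..10 × {city-block, Euclidean, cosine} × {inverse, equal}.
Numerical conventions (the method leaves all three open): cosine distance
of a zero vector is 1; inverse-distance weights are `1/max(d, 1e-12)`;
distance ties rank by lower training index, vote ties fall back to the
nearest neighbour's class, and mode ties in voting resolve to the lower
class label. IMV sorts outcomes by accuracy (ties keep list order) and
takes elementwise modes of the top r+2 for r = 1..m-2; the greedy step
takes the earliest maximum. Per feature vector the candidate pool is
exactly 60 + 58 = 118; fusion votes over the 15 per-vector winners and
selects among its 13 voted candidates only.

Sorting and selecting by accuracy against the full label vector is the
"self-organization" of the pipeline, reproduced deliberately; it is a
selection-bias mechanism, not a generalization guarantee.

### Explanation (DLob)

A selected feature index v (1-based) decodes as
`mul = floor((v-1)/nc^2)`, `rem = v - nc^2*mul`,
`first = floor((rem-1)/nc)+1`, `second = ((rem-1) mod nc)+1`, block
`mul+1` — the exact inverse of the map encoding, verified exhaustively.
Histogram-derived features decode identically because bin b encodes the
same channel pair. Entropy is Shannon entropy base 2 (maximum 3 bits over
the 8-symbol alphabet). Transition matrices count consecutive ordered
symbol pairs within each feature vector's string; strings are never
concatenated across feature vectors. Connectome rendering exports raw
directed counts; edge weighting beyond counts is not defined.

### Cross-validation

`kfold` shuffles segments with the run seed and splits into near-equal
parts, unstratified (the protocol does not state stratification; the seed
makes the split reproducible). `loro` makes one fold per record; with one
record per subject this is leave-one-subject-out. Records are never split
across LORO folds (property-tested).

The positive class for sensitivity defaults to the non-control class: the
complement of any class named "control", otherwise the larger label.
Degenerate metric denominators yield NaN plus an `undefined` flag rather
than a silent 0.

## Synthetic data: what it emulates and what it shows

The generator reproduces the *shape* of the private study data — 14
channels, 128 Hz, 15 s windows (L = 1920), records under subjects, two
classes — with defaults of 20 records per class × 4 segments per record
(40 records / 160 segments; four segments per record keeps the NCA
pairwise cache and the full test suite desk-scale). The class signal is a
per-channel amplitude boost (class 0 left-frontal, class 1 right-frontal;
peak 1.5, secondary 0.75, per-sample jitter sd 0.5 around baseline noise
sd 1.0), chosen so the per-timepoint extreme-channel distributions —
the extractor's sufficient statistic — differ strongly between classes. A
per-record per-channel offset (sd 0.25) makes segments of one record more
alike than segments across records, emulating session effects such as
per-electrode impedance differences. Rhythms, 1/f spectra, eye blinks and
other physiology are not emulated, so passing tests demonstrate the
pipeline's mechanics and its behaviour under a known channel-dominance
signal, not performance on real EEG.

Two empirical facts about the pipeline, measured on this generator, are
worth stating because they bound what a "passing" accuracy means:

- **Record leakage under segment-level k-fold.** The record offsets
  fingerprint records in the feature space. Since sibling segments of a
  test segment sit in the training folds, kNN can recover a segment's
  record — and hence its label — even when labels are shuffled across
  records (shuffled-label fused accuracy reaches 1.0 at the defaults).
  This is the synthetic analogue of the method's own 10-fold vs LORO gap
  on real stress data; LORO is the honest protocol when records correlate.
- **Selection/greedy optimism.** With the record effect removed entirely,
  record-shuffled labels still yield fused 10-fold accuracies near 0.72 at
  n = 160: full-dataset NCA selection plus accuracy-driven greedy/IMV
  stages, compounded by fusion voting, inflate apparent accuracy on
  label-free data. A chance-level negative control is therefore *not* an
  expected behaviour of this pipeline at this sample size, and the
  acceptance test that encodes a chance band documents this failure
  rather than hiding it.

The class-signal monotonicity property (more dominance separation never
lowers mean accuracy) and the fused-vs-mean-tkNN improvement property are
asserted on small configurations (10–24 segments, 3 seeds each).

## Problem sizes and runtime

Default test-suite configurations are deliberately small: property tests
use 2–10 channels and tens of timepoints; end-to-end checks use the
40-record default (160 segments × 1920 samples), for which one full
pipeline run (15 NCA fits up to 2352 features, 60-configuration tkNN under
10-fold CV, fusion, explanation) takes well under a minute on one CPU.

## Known limitations

- Selection before CV and accuracy-driven candidate selection make all
  reported cross-validated accuracies optimistic; nested selection is out
  of scope by design.
- The lobe lookup table ships only for the 14-channel montage; other
  montages must supply their own.
- EDF import trusts the file's channel order and errors on montage
  mismatch rather than reordering.
- Binary classification only; the manifest validator enforces exactly two
  classes.
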