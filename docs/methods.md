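# Methods

## The surrogate training objective

Curated pathogenic/benign SV sets are too small and too biased (toward very
large, gene-overlapping events) to train genome-wide models. `svds` therefore
trains on an evolutionary contrast: fixed, species-derived SVs are treated as
proxy-neutral — purifying selection has already removed deleterious events
from that set — and are contrasted with proxy-deleterious sets built by
redistributing the *same* SVs (matched exactly in length and number)
uniformly over the alignable genome. Many shuffled SVs are in truth neutral;
the models only need the *relative* paucity of functional-annotation signal
in the fixed set. Holdout AUROC on this contrast is therefore a measure of
how well the planted distributional difference is recovered, not of
clinical accuracy.

Shuffling places each SV by picking an alignable interval with probability
proportional to its number of valid start positions, then a uniform start
inside it — i.e. uniform over all genome-wide valid placements. Shuffled SVs
may overlap each other and the source SVs (nothing in the contrast requires
otherwise); sex chromosomes are excluded from training placement because
their comparative annotation quality is poor. Both choices are configurable.

## Feature engineering

Coordinates are BED-style 0-based half-open throughout; strand is ignored
(all statistics are strand-symmetric). Insertion rows with `end == start`
are normalised to a 1-bp site window `[pos, pos+1)` at load time — the width
of the site window is a package choice (the integration site is a point; a
1-bp window is its minimal interval representation) and is configurable via
the region extraction.

Per annotation track and region the statistics are: maximum value;
length-weighted mean with uncovered bases counting as zero (this penalises
sparse coverage consistently and keeps mean ≤ max on nonnegative tracks; a
covered-bases-only mean is the documented alternative); sum of
value × covered bases; and the number of bases at or above the track's
90th-percentile value. The percentile is computed genome-wide over the
track's per-base value distribution (length-weighted, linear interpolation —
identical to `numpy.percentile` on the per-base expansion). "High-impact
amount" counts bases, not elements, which is scale-consistent across tracks.

The two 100-bp flanks are pooled into one value per statistic (max of maxes,
pooled mean over the combined flank length, summed sums and counts): the
flank model is a single model of breakpoint context, and up/downstream are
symmetric for the events modelled. Distance features are measured from the
span edges and fed to both span and flank models. A catalog with no element
on the query chromosome yields a large finite sentinel distance (10⁷ by
default) rather than a missing value, so downstream zero imputation cannot
silently turn "far from everything" into "cohort average". All remaining
undefined values (empty overlaps) become 0 before normalisation.

Within one track, overlapping input intervals are resolved to the per-base
maximum — deterministic and conservative toward deleteriousness.

## Normalisation

Every feature is Z-transformed against up to 20,000 same-type SVs from the
reference cohort (sample SD, `ddof=1`, since the reference is a sample;
degenerate features with zero SD map to 0). The same transformation is
applied to both class labels, so it serves interpretability — a transformed
value of 4 is 4 cohort SDs from the cohort mean — without informing the
classifier. Values with |z| ≥ 2 are flagged as outliers for report
highlighting; the threshold is configurable and purely cosmetic.

## Models

Random forests (scikit-learn `RandomForestClassifier`) with
`n_estimators = n_trees`, `min_samples_leaf = min_node_size` and
`max_leaf_nodes` mapped one-to-one from the sweep protocol; logistic
regression is retained as the linear alternative. The raw model output is
the predicted probability of the proxy-deleterious class (the fraction of
trees voting deleterious), oriented so higher = more deleterious. Classes
are balanced by construction (matched counts), so no weighting is applied.

The hyperparameter protocol sweeps one parameter at a time with the other
two fixed at 100: `n_trees ∈ {25, 50, 75, 100, 200, 500, 1000}`,
`min_node_size, max_leaf_nodes ∈ {10, 50, 100, 250, 500, 1000}` — 19
settings. One fixed 10 % holdout (drawn once per search) is reused across
all settings so they are comparable; selection is by holdout AUROC with ties
broken toward the cheaper (smaller) value. The defaults 100/100/100 are the
protocol's anchor values.

## Scoring and Phred calibration

A novel SV's span features go to the routed span model and its flank
features to the routed flank model (DEL → chimp DEL/human DEL,
INS → chimp INS/human INS, DUP → chimp DEL/human INS); the raw score is the
maximum of the two. Phred scaling uses
`p = #(reference ≥ raw)/N`, Phred `= −10 log₁₀ p`, per SV type. The `≥` tie
rule means a variant tying the cohort maximum still receives a finite high
score; a raw score exceeding every reference value is capped at `p = 1/N`,
giving a ceiling of `−10 log₁₀(1/N)` (≈33 for the default 2,000-SV synthetic
cohort; larger cohorts extend the scale). Phred values of different SV types
are ranked against different reference distributions and must not be
compared across types.

## The synthetic world

The generator emulates the statistical structure the framework assumes, not
human genome realism (no sequence, GC, repeats, or calling error). Defaults
(frozen as the package's study conditions):

* genome: 4 chromosomes × 1 Mb; alignable regions cover 92 % with random
  unalignable gaps;
* functional elements: 150 genes (with 2–6 exons each) and 250 enhancers
  covering 45 % of the genome; element lengths are scaled log-normal draws;
* tracks: 8 tracks spanning six feature groups (integrated scores,
  conservation/constraint, population/disease constraint,
  epigenetic/regulatory, 3D architecture, gene/element enrichment) in
  200-bp bins; values are Exponential(1) background plus a
  Gamma(2, scale)·coverage lift inside functional elements — heavy-tailed
  nonnegative values resembling conservation/ChIP signal, which keeps the
  90th-percentile statistic meaningful;
* SV lengths: log-normal, median 7 kb, σ = 0.6 (mean ≈ 8.4 kb, the scale of
  population SV calls), shared between neutral and cohort sets so length is
  not a synthetic confounder; minimum 50 bp;
* proxy-neutral sets: 2,000 SVs per origin; with probability 0.95 a record
  rejects functional overlap (length and position are redrawn together on
  rejection, since long SVs may not fit between elements at all);
* cohort: 2,000 SVs per type, 30 % singletons marginally; 15 % of records
  are placed overlapping functional elements and are 2.5× more likely to be
  singletons, with rarer non-singleton allele counts — the planted
  purifying-selection signature;
* spike-ins: log-normal median 20 kb, centred on genes (mirroring the large,
  gene-anchored character of clinically curated SVs); simulated individuals
  carry 100 neutral-like SVs each.

The functional-overlap geometry was calibrated once, when the defaults were
frozen: with uniform placement the achievable span-model AUROC is capped at
`p(1−q) + ½(1 − p(1−q) − q(1−p))` where `p`/`q` are the functional-overlap
probabilities of shuffled/neutral SVs — non-overlapping members of the two
sets are *identically distributed* and contribute only ties. The default
geometry gives `p ≈ 0.77`, `q ≈ 0.05` (ceiling ≈ 0.86–0.88 across seeds),
and the measured chimp-DEL holdout AUROC on the default benchmark is 0.88.
Consequently, a passing benchmark demonstrates that the pipeline recovers a
planted annotation-depletion contrast of known size; it says nothing about
performance on real annotation stacks, real SV length distributions, or
clinically labelled variants.

All randomness flows from one seed through fixed per-subtask streams
(`SeedSequence([seed, stream])`), so regenerating one output never perturbs
another and every stage is byte-reproducible.

## Numerical and degenerate-input choices

* Percentiles: linear interpolation on the length-weighted distribution;
  verified against per-base expansion.
* AUROC: rank-based Mann–Whitney identity with average ranks (ties = 0.5);
  verified against an all-pairs oracle.
* Spike-in rank: `(1 + #strictly greater)/(n + 1)` — never zero, and ties do
  not penalise the spike-in (no tie convention is canonical here; this one
  is documented and tested).
* AF tail contrast: two-sided Mann–Whitney with normal approximation and tie
  correction; tails need ≥ 2 records each. Type-I error is calibrated to
  ≈ 5 % at α = 0.05 over 500 null simulations in the test suite.
* Holdout split: `ceil(frac · n)` per label, so nonempty inputs always leave
  a nonempty holdout; label-stratified and seed-deterministic.
* Empty tracks, reversed coordinates, unknown SV types, non-numeric scores
  and feature-set mismatches are hard errors with file/line context, never
  silent coercions; flank windows are clipped (not errored) at chromosome
  edges.

## Known limitations

* The feature catalog is a configurable stand-in (~50 features over 8 tracks
  and 4 catalogs), not a reconstruction of any production annotation stack.
* The proxy labels are noisy by design: many "deleterious" training examples
  are neutral, so holdout AUROC under-states separability of truly labelled
  data and the raw score is not a calibrated probability of pathogenicity.
* Only DEL/INS/DUP are scored; inversions and breakends are rejected at the
  input boundary.
* Phred scores depend on the reference cohort's size and composition; the
  synthetic cohort's ceiling (~33) is far below what population-scale
  cohorts would support.
* Insertion models see only the integration site and flanks, never the
  inserted sequence.
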