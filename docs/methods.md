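# Methods

`secscreen` analyses sorted-pool surface-display screens of protein
fragments: libraries of random-primed cDNA fragments are displayed on the
yeast cell wall between a secretory leader and an anchor, displaying
(double-positive) cells are enriched by cell sorting, and deep sequencing of
sorted vs unsorted pools turns display into a per-fragment statistic.  The
package implements the full downstream analysis plus a synthetic screen
generator so every stage can be exercised and validated without sequencing
data.

## Enrichment model

Counts are normalized per sample to FPTM (fragment count per ten million
read pairs; a "fragment" is the set of read pairs sharing start and end
coordinates, identified by `transcript:start-end` in 0-based half-open
convention).  The per-fragment enrichment factor in replicate *r* is

    E_r = log2( FPTM_sorted,r / FPTM_unsorted,merged )

with the merged unsorted sample (replicate unsorted counts summed before
normalization) as the common denominator; a flag switches to per-replicate
denominators for sensitivity analysis.  Fragments are *detected* in a
replicate when their count is positive in that replicate's sorted or
unsorted sample (the merged-unsorted alternative is available behind the
same flag).  Fragments detected in all replicates are classified with
inclusive thresholds at +1/−1 (a minimal two-fold change):

* `enriched` — E ≥ +1 in every replicate (the secretable proxy);
* `depleted` — E ≤ −1 in every replicate;
* `uncertain` — all but one replicate consistent, the odd replicate
  strictly between the thresholds;
* `inconsistent` — anything else.

±∞ E-factors (zero numerator or denominator) participate as the limits of
the log rule.  No pseudocounts are added.  Concordance is the fraction of
commonly detected in-frame fragments classified `enriched` or `depleted`.
The two-of-three-consistent fragments form the independent validation sets:
set A (third replicate between the thresholds) and set B (third replicate
beyond the opposite threshold), labelled by the consistent majority.

## Synthetic screen generator

The generator is a model of the study conditions, not a fit to any dataset:

* **Transcriptome** — 400 genes; CDS lengths ~ Normal(1200 nt, 300 nt)
  truncated to [300, 2400] (rejection-sampled, so no boundary atoms),
  random sense codons with a terminal stop; relative abundances log-uniform
  over 4 decades (the span of transcript abundance in human cell lines).
* **Fragments** — 250 random-primed fragments per transcript; nucleotide
  lengths ~ Normal(240, 60) truncated to [90, 450], giving a 50–100 aa
  coding-length median; both breakpoints lie on the transcript, the start
  uniform over the admissible placements.  Frame flags follow from the
  coordinates (start on a codon boundary inside the CDS; length divisible
  by three), which reproduces the 1/9 dual-frame probability of random
  priming without hard-coding it.  Dual-in-frame fragments whose reading
  frame contains a stop codon keep their counts but have no peptide (the
  stop removes the downstream tag, so they cannot display).
* **Planted signal** — display probability = logistic(β₀ + Σ βᵢ zᵢ) on five
  composition z-scores (D/E fraction, proline fraction, mean
  Kyte–Doolittle hydrophobicity, mean Chou–Fasman helix propensity, mean
  Bhaskaran–Ponnuswamy flexibility), standardized against the background
  implied by uniform sense-codon usage with standard errors at the
  peptide's length.  Defaults β = (−6; +4, +2, −4, −2, +2) plant a strong
  bimodal signal in the direction real screens report (acidic, flexible,
  proline-rich up; hydrophobic, helical down): most in-frame fragments
  display with near-zero probability while a substantial minority display
  strongly.  Out-of-frame fragments display with probability 0.
* **Counts** — three replicates; per sample, counts are one multinomial
  draw of 4×10⁶ reads over fragments, with unsorted weights proportional to
  transcript abundance and sorted weights additionally multiplied by the
  display probability.  An optional Dirichlet overdispersion parameter adds
  replicate-to-replicate biological variance; it defaults to off because
  the pure multinomial keeps FPTM/E behaviour analyzable, and no empirical
  estimate of that variance is available.

Under these defaults the labelled classifier dataset (consistently
enriched/depleted, peptide ≥ 50 aa) holds ~6,600 fragments from ~390 genes,
about 47% positive.  Because sorting renormalizes over the pool, enrichment
is relative: a fragment is enriched when its display probability exceeds
roughly twice the pool's abundance-weighted mean display.  A corollary worth
knowing when constructing nulls: a "no-signal" screen in which only in-frame
fragments display (even all at the same rate) still enriches every in-frame
fragment by about log2(9), because the sorted pool sheds the out-of-frame
majority.  The statistical null for the E statistic is therefore a screen
with one flat display probability across *all* fragments; that is what the
null-screen tests use.

What the generator does not emulate: real codon usage and composition
biases, sequencing error, PCR length bias, cell-sorting gate geometry,
carry-over between sorting rounds, and correlated fragment boundaries
(fragmentation hotspots).  Passing tests therefore demonstrate that the
statistics and learners recover a known signal under clean conditions, not
that they meet any particular accuracy on real screens.

## Consolidation

Fragment-level classes are collapsed to residues per protein: a residue is
`secreted`/`depleted` only when all covering fragments agree, `ambiguous`
when both classes cover it, `uncovered` otherwise.  Input fragments must
match their protein verbatim and be strictly longer than 30 aa; a peptide
matching at several offsets uses the first occurrence and is flagged.
Maximal runs of identically labelled unambiguous residues become
consolidated fragments; per-residue property profiles are condensed as the
unweighted mean over covering fragments (the choice of mean over a
consensus-fragment rule was open; unweighted mean is the simplest faithful
reading).  Representative clustering is greedy longest-first full-containment
at 100% identity: it reproduces the behaviour of containment clustering
tools on exact substrings and is verified against an in-repo all-pairs scan,
not claimed byte-identical to any external tool.

## Property scales and class comparisons

Ten literature scales (polarity, hydrophobicity, average area buried,
fraction of buried residues, bulkiness, molar refractivity, recognition
factors, molecular weight, transmembrane tendency, HPLC retention at pH
7.4) are packaged as TSV with per-scale citation keys; two auxiliary scales
(helix propensity, flexibility) serve only the generator.  Unknown residues
(X, U) map to the scale mean with a warning.  Sequon counting uses the
N-X-S/T (X ≠ P) rule, counts overlapping matches, and requires the
three-residue window to fit.  Class comparisons use two-sided Mann–Whitney
tests (exact for small tie-free samples, tie-corrected normal approximation
otherwise) with Benjamini–Hochberg correction applied when more than ten
comparisons are made (the policy threshold is a parameter).  Signal-peptide
enrichment uses the one-sided Fisher exact (hypergeometric upper tail).

## Gradient-boosting classifier

Per property scale, each peptide maps to 40 features: 20 relative amino-acid
frequencies, length, the scale values of the first and last six residues,
the whole-sequence mean, and six equal-region means with boundaries at
round(i·L/6) (shorter sequences get shorter regions; the minimum length of
12 enforced for the terminus windows never binds because the dataset filter
is 50 aa).  One LightGBM classifier is trained per scale; a second-stage
LightGBM classifier stacks the ten per-scale probabilities.  Evaluation is
10-fold cross-validation grouped by gene (all fragments of a gene share a
fold) with a greedy assignment balancing fold size and class ratio.
Hyperparameters are chosen per fold by a seeded randomized search (3 draws
from a small grid over leaves, learning rate, trees, minimum leaf samples)
scored on a gene-grouped 20% validation split of the training data, then
refit on the full training split; per-scale models are refit per fold
(stacking strictly out of fold) rather than once, to avoid leakage.  For
external data (e.g. sets A/B), per-scale models are refit on the full
dataset and the ensemble is trained on the cross-validated out-of-fold
probabilities, standard stacking practice.

## Convolutional classifier

The CNN consumes one-hot encodings (L×20, alphabetical residue columns;
non-standard residues are all-zero rows) through three blocks of same-padded
convolution → ReLU → dropout → max-pool(2).  Four strategies collapse the
variable length: masked global max pooling (default), k-max pooling (top K
activations per channel in sequence order, K=5), a bidirectional GRU
(concatenated final hidden states, hidden 64), or zero-pad/truncate to 200
residues.  A dense hidden layer feeds a single sigmoid output neuron.
Padding is handled by masking at every pooling step, so appending all-zero
rows never changes the output (tested exactly).  Training is class-weighted
binary cross-entropy with Adam, batches bucketed by length; 12 epochs,
batch 64, learning rate 5×10⁻³, dropout 0.2.  The default width (16 filters
per block, dense 32) is sized so that full 10-fold training on the default
dataset runs in a few minutes on one CPU with the package's own
NumPy-based reverse-mode autodiff engine, while still reaching out-of-fold
AUROC ≈ 0.99 on the default screen; capacity is configurable.  The network
and engine are deterministic given the seed.

The GB+CNN ensemble is the arithmetic mean of the two probability vectors.

## Integrated gradients

Attributions use the right-endpoint Riemann approximation of the path
integral from an all-zeros baseline, batched over the α grid so one forward
and one backward pass per refinement level suffice.  Per-residue
contribution is the channel sum at each position.  The completeness
residual |Σ IG − (F(x) − F(x′))| must stay below 2% of |F(x) − F(x′)|; the
step count starts at m=50 and doubles adaptively.  Because the bound is
relative, sequences whose output is very near the baseline output need fine
grids (the Riemann error is O(1/m) through ReLU kinks), so the cap is
m=6400.  Normalization multiplies all maps by one global constant chosen so
the mean per-sequence sum of absolute contributions is exactly 100;
aggregation reports mean contribution per residue type, or per residue type
within twenty relative-position bins (bin = floor(20·i/L), capped at 19).

## Numerical and degenerate-input conventions

* E-factor edge cases: sorted 0 → −∞, unsorted 0 → +∞, both → NaN
  (undetected), all flagged rather than dropped.
* FPTM requires a positive sample total; zero-total samples are an error.
* Classification thresholds are inclusive (E exactly +1 is enriched-side).
* Diversity, sampling and display formulas validate their domains
  (positive D_max, positive DNA mass, percentage ranges) and report to 3
  significant figures.
* Fixture TSVs are written at full float precision (`%.17g`) and parsed
  with round-trip float conversion, so write→read is lossless and pipeline
  reruns are bit-identical (hash manifests are recorded per stage).
* All randomness flows from explicit integer seeds through NumPy
  generators; no global random state is touched.

## Known limitations

* The containment clustering is exact-substring only; it does not
  approximate clustering at <100% identity.
* Structure/disorder predictions are represented by scale proxies; no
  claim of equivalence with dedicated predictors is made.
* The negative class of a positive-selection screen contains passively
  depleted fragments; as in real screens, "depleted" means
  not-detected-as-secretable, not proven-unsecretable.
* The GRU head is functional but slow in the NumPy engine; it is intended
  for small comparisons, not default-scale training.
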