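# Methods

## The model

A proteome is treated as a bag of protein sequences over the 20-letter
amino-acid alphabet A (nucleotide alphabets are supported through the same
`AlphabetPolicy`). An n-gram is a window of n consecutive residues inside
a single protein; a protein of length L ≥ n contributes L − n + 1 windows,
and windows never cross protein boundaries (concatenation would
manufacture chimeric n-grams at the junctions). Under the default policy
any window containing a non-canonical residue (B, J, O, U, X, Z) is
dropped, keeping the vocabulary at exactly |A|^n; `map_to_nearest`
(B→D, Z→E, J→L, U→C, O→K) and `keep` are available for sensitivity
analysis. Frequencies are reported as percentages of the total n-gram
token count; raw counts are always retained because the entropy
computation needs counts, not percentages.

### Count-ratio language model and perplexity

A model of order n trained on a reference proteome stores the n-gram
counts C(g) and the **directly counted** (n−1)-gram context counts
C(ctx) — counted from the text with the same windowing rules, not derived
by marginalising the n-gram table. The conditional probability of a
window's last residue given its context is the smoothed count ratio

    q(g) = (C(g) + α) / (C(ctx) + α·|A|)        (add-α, default α = 1)

and the cross-entropy of a test proteome with n-gram counts C_test and
N total n-gram tokens is

    E = −(1/N) · Σ_g C_test(g) · log2 q(g),     perplexity B = 2^E.

n = 1 is supported as the context-free special case (the context count is
the total token count). Contexts never seen in training fall back to the
smoothed unigram distribution of the final residue. A `floor_prob` policy
(clip the raw ratio from below, renormalise the context row) is provided
as an alternative.

Two boundary/normalisation facts are deliberate and documented rather
than "fixed":

- Because context counts include each protein's terminal window (which
  has no continuation), the add-α conditional rows are *sub-stochastic*
  by at most one count-unit per protein. The test suite asserts this
  sharp bound; exact row sums of 1 would contradict the count-ratio
  definition itself. `floor_prob` rows are renormalised and sum to 1
  exactly.
- Perplexity is ≥ 1, but cross-perplexity of a *mismatched* non-uniform
  model can exceed |A| (smoothed probabilities fall below 1/|A|); only
  the uniform model pins perplexity at exactly |A|.

### Smoothing caveat for published whole-proteome values

The raw count ratio is undefined whenever a test n-gram is absent from
training — a certainty for 4-grams across divergent proteomes (20^4 =
160,000 types; in the worked example ~4% of test tokens are unseen even
within a genus). Any finite result therefore depends on an unseen-event
policy, and published absolute whole-proteome perplexities (e.g. a
self-perplexity of ~15 and a cross-perplexity range up to ~29.5 on a
~970-organism collection) are reproducible only with the exact policy of
the original tooling, which is not stated. This package treats absolute
values as policy-dependent and the *orderings and trends* — self below
cross, cross-perplexity increasing with divergence — as the testable
surface. Those are what the acceptance tests assert.

### Zipf-like analysis and signatures

n-grams are sorted by descending percentage frequency in a chosen
reference organism (ties broken lexicographically for determinism), and
all other organisms' frequencies are read off in that fixed order.
Defaults: top-40 n-grams for n = 4, all 20 for n = 1. A top-k n-gram is
flagged as a **signature** when the median (configurable quantile) of its
frequency across the comparison organisms is below 10% (configurable) of
the reference's frequency — a declared, reproducible substitute for what
is otherwise a visual judgement. Per-genus conservation is quantified by
the Pearson correlation (Spearman optional) between the reference's top-k
frequency vector and each member species' frequencies at those same
n-grams, averaged per genus; only genera with ≥ 9 species are reported
and the reference itself is excluded from its genus.

### Taxonomy classification

Multinomial logistic regression with a single predictor per model — one
amino acid's percentage frequency, or the organism's score on the first
principal component of the full 20-dimensional composition (sign fixed by
making the largest-magnitude loading positive). With q categories the
model has q − 1 logit equations against a baseline category (the most
frequent label; predictions are baseline-invariant). A small L2 ridge
(default 1e-6) guards against perfect separation, which single-feature
fits on small genera reach easily. Evaluation is stratified, seeded
k-fold cross-validation (default 10) restricted to organisms from genera
with ≥ 9 species; accuracy is the fraction of held-out organisms whose
argmax category is correct.

## The synthetic generator

`simulate` produces collections with a known phylum → class → genus →
species taxonomy. Each taxon's conditional table is its parent's table
with independent Gaussian logit noise (softmax-renormalised), with
per-level magnitudes sigma_phylum ≥ sigma_class ≥ sigma_genus ≥
sigma_species (defaults 0.8 / 0.5 / 0.3 / 0.1). Species proteomes are
sampled from their Markov chain (default order 3, i.e. 4-gram
statistics): ~2,000 proteins per species (uniform 1800–2200), lognormal
lengths with mean ~300 residues — microbial scale, with the default
taxonomy shape (3 phyla × 2 classes × 4 genera × 4 species = 96 species)
mimicking a ~1,000-proteome survey at a tenth of its size. The
ground-truth `branch_distance` between a species and the designated
reference is the sum of perturbation magnitudes along the taxonomy path —
the generator's analogue of phylogenetic tree distance, and the variable
the divergence-recovery experiments correlate against.

Two deliberate realism choices:

- **Root roughness.** The root table is not an i.i.d. letter model: its
  logits carry context-dependent noise (sd 0.5) shared by all taxa,
  because real proteomes use particular residue combinations far in
  excess of the product of letter frequencies. Without it the top-40
  4-gram band would be essentially flat and the comparative analyses
  would have no dynamic range at desk scale.
- **Plantable signatures.** `plant_signatures` multiplies the conditional
  probability of chosen n-grams in one taxon's table by a boost factor
  and renormalises, propagating to the taxon's subtree.
  `choose_plantable_ngrams` selects n-grams the way real signatures look:
  a high-probability context (from the chain's stationary distribution)
  with a rare continuation, so the boost neither saturates (which would
  cap the enrichment ratio) nor leaves the n-gram below the reference's
  top-40.

What the generator does **not** emulate: low-complexity/repeat regions
(the main source of extreme top-4-gram frequencies in real proteomes),
codon-level effects and G+C content, gene gain/loss, and any
host-association signal (host labels are grouping metadata only). Passing
recovery tests therefore demonstrate that the pipeline recovers
divergence and signature structure *of this generative form*, not that
real organisms follow it.

## Experiment sizes and numerical choices

- Divergence-recovery ladder: one genus, a divergence-0 reference plus
  five species at divergences 0.01–0.3 (linearly spaced), 2,000 proteins
  per species, 20 replicate seeds; assertions are on per-level means and
  the mean per-replicate Spearman correlation.
- Signature recovery: four genera × three species, 1,500 proteins per
  species, five planted 4-grams at 50× boost, 20 seeds.
- Correlation structure: four genera × ten species, 2,000 proteins per
  species. At these proteome sizes the top-40 4-gram frequencies
  (~0.02–0.04%) carry counting noise of a few percent, which attenuates
  the plug-in Pearson correlation; within-genus correlations approach
  their counting-noise ceiling (~0.8 here) rather than 1.0 as
  sigma_species → 0. On full-size real proteomes with wide, repeat-driven
  top-40 dynamic range the same statistic reaches ~0.99 within a genus —
  a known limitation of the repeat-free generator, not of the statistic.
- Tolerances: oracle-equivalence checks at 1e-12 relative; probability
  normalisation at 1e-9; logistic fits use lbfgs with ridge 1e-6 and up
  to 1,000 iterations. All randomness flows through explicit integer
  seeds; repeated evaluation of the same model/test pair is bit-identical.
- Degenerate inputs fail loudly: empty proteomes, zero countable
  n-grams, zero-variance feature matrices, and correlation of constant
  vectors raise (or exclude with a warning) rather than returning NaN
  silently.
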