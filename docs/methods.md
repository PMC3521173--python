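# Methods

`enhscan` asks, for each developmental enhancer, whether its sequence has
diverged faster or slower than the neutral expectation set by its local
genomic neighbourhood — and whether apparent acceleration could instead be
GC-biased gene conversion (gBGC). This note records the models, the defaults
and why they were chosen, the numerical decisions, and what the synthetic-data
tests do and do not establish.

## Divergence model

Substitution distances are estimated by maximum likelihood under a general
time-reversible (GTR) nucleotide model with discrete-gamma rate heterogeneity.
The generator is `Q_ij = s_ij * pi_j` (i != j) with six exchangeabilities
`s` (order AC, AG, AT, CG, CT, GT) and stationary frequencies `pi`, scaled so
the expected substitution rate at stationarity is 1 — branch lengths are
expected substitutions per site. Among-site variation uses K equal-probability
gamma categories (default K = 5) with category *mean* rates, renormalized to
average exactly 1; the simulator uses the identical discretization, so the
estimator and generator agree by construction.

Pairwise likelihoods are computed from the 4x4 site-pattern counts (the
sufficient statistic), three-taxon likelihoods by summing over the ancestral
state at the internal node of the unrooted mouse/rat/human tree, mixing over
categories. Transition matrices come from the spectral decomposition of the
reversible generator (a single `eigh` per model, reused for every branch
length), so per-region fits cost microseconds per likelihood evaluation.

Numerical choices:

- **Base frequencies** are fixed at the empirical mean of the aligned
  sequences, never ML-optimized; this stabilizes fits on kb-scale regions.
- **Optimization** is bounded L-BFGS-B on log-transformed parameters
  (t in [1e-9, 10], shape alpha in [0.05, 50], exchangeabilities in
  [1e-4, 1e4], one exchangeability pinned to 1), with three fixed starting
  points (t0 = 0.05, 0.2, 1.0) and a 1e-8 log-likelihood tolerance.
  Fixed-model fits optimize t alone with bounded Brent. Fits never silently
  fail: a `converged` flag is carried through every table.
- **Degenerate inputs**: identical sequences return t = 0 without
  optimization; columns with any gap or ambiguity symbol in any species are
  excluded (complete-case) and tallied; zero usable columns raise a
  "no usable sites" error and the unit is excluded with a reason code.
- **Small units**: below 200 usable sites (configurable) the exchangeabilities
  and shape are frozen at values fit once on the pooled neutral sites and only
  t is optimized. The pipeline default goes further and uses the pooled model
  for *every* per-region fit (`PipelineOptions.model_scope = "pooled"`):
  kilobase-scale regions cannot meaningfully constrain seven model parameters,
  and a shared neutral model makes D and d directly comparable. `"per-unit"`
  restores per-region model fitting above the threshold.

### A caveat on pairwise identifiability

A single pairwise alignment cannot jointly pin the distance and the gamma
shape: parameter sets whose t differs by tens of percent (with alpha and the
exchangeabilities compensating) reproduce the expected site-pattern
distribution to within ~1e-9 log-likelihood units per site. The free joint fit
is therefore only guaranteed to *dominate the true parameters in likelihood*,
not to localize t; `DivergenceEstimate.standard_error()` is documented as
conditional on the fitted model. None of the pipeline's conclusions depend on
the free fit: D/d4 and D/di are computed from t-only fits under one shared
pooled model, where the distance is sharply identified and the shared scale
cancels in the ratio.

## Neutral references

Two site classes of the enhancer's nearest gene *with a one-to-one ortholog*
serve as local neutral references:

- **Fourfold-degenerate sites (d4)**: third positions of codons whose four
  third-base completions are synonymous (the 8 fourfold families), classified
  on the reference (mouse) codon of the longest isoform. "Longest isoform" is
  the greatest summed exon length (ties: longer CDS, then lexicographic id).
  A terminal stop codon is excluded from scanning; genes whose CDS length is
  not a multiple of 3 or that contain an internal stop are excluded with a
  logged reason. A flag to require degeneracy in both aligned species exists
  but defaults off (classification is reference-anchored).
- **Intron sites (di)**: all introns of the longest isoform except the
  5'-most in transcription order (strand-aware), removed because first introns
  are enriched for regulatory elements. Intronless and single-intron genes
  therefore carry only the d4 reference — the intron-referenced testable set
  is smaller by construction.

The nearest gene for covariates (any gene) and the neutral-reference gene
(nearest gene with an ortholog) are assigned independently; they can differ.
Distances are boundary-to-boundary (0 when overlapping), ties broken by
distance, then gene start, then gene id; strand is ignored.

## Selection classification

For each testable enhancer, a 2x2 table — enhancer vs neutral reference by
substituted vs unsubstituted sites — is tested with a two-sided Fisher's exact
test (exact hypergeometric enumeration, no continuity approximation; exact
ties of point probabilities are included with a 1e-7 relative gate).
"Substituted" means an observed mismatching alignment column, not a
model-inferred count: a 2x2 with "sites with no substitution" is only coherent
with per-site observed states. At alpha = 0.05: significant excess ->
positive; significant deficit -> purifying; otherwise neutrality is not
rejected. No multiple-testing correction drives the calls (a
Benjamini-Hochberg q-value column is emitted for transparency). Enhancers
whose neutral reference has zero usable sites are untestable and excluded from
totals. D/d4 and D/di are reported per enhancer; ratios with a zero or
unconverged denominator are excluded with a reason.

Summary tables report, per tissue: testable total, number rejecting
neutrality, number positive, and the three ratios. Percentages are truncated
(floored) toward zero at two decimals — the convention of the published
tables this layout mirrors — using integer arithmetic so formatting can never
be perturbed by float rounding.

## gBGC diagnostics

Mouse-lineage substitutions are polarized by outgroup parsimony: a column is
"ancestrally A/T" when rat and human agree on the same A or T (the strict
reading; a looser any-A/T reading is available behind a flag, taking the rat
allele as ancestor). A differing mouse base is a mouse-lineage event, split
into A/T->G/C vs A/T->A/T; multiple hits count once. Per region the ratio
N_AT->GC / N_substituted_AT is compared across tissues by two-sided
Mann-Whitney U tests (exact for small tie-free samples, tie-corrected normal
approximation otherwise), alongside the recombination rate of the window
containing each region's midpoint. Under gBGC, fast-evolving regions should
show both elevated ratios and elevated recombination.

## Covariates

Essentiality follows the knockout-phenotype rule: essential iff any null
phenotype is premature death or infertility; non-essential iff at least one
other null phenotype is documented; otherwise unknown (excluded from
essentiality contrasts only). Expression is the mean (optionally maximum) of
the 61-tissue signal vector of the *adjacent* gene, binned at [0,200),
[200,400), [400,inf) — 200 belongs to the middle bin, 400 to the top bin.
Continuous associations use Spearman's rank correlation (average ranks for
ties; exact permutation p for n <= 10, t-approximation above). The controlled
comparison keeps only tissue-specific enhancers and contrasts tissues within
each expression bin, which controls pleiotropy and adjacent-gene expression
simultaneously.

## Synthetic-data generator

The generator is the package's ground-truth instrument, not a fixture. One
chromosome is laid out left-to-right with genes and enhancers interleaved and
never overlapping (except deliberate duplicate enhancers placed at identical
coordinates in a second tissue, which exercise consolidation and pleiotropy).
An ancestral sequence is drawn iid from the stationary frequencies; each gene's
longest-isoform CDS is rewritten as a valid reading frame (ATG, sense codons
sampled proportional to frequency products, terminal stop). Three lineages
then evolve independently from the mouse-rat ancestor node under the scaled
GTR generator with per-site discrete-gamma rates; sampling uses exact
transition probabilities per (multiplier, category) pair, so no event-level
approximation is involved.

Selection enters as per-site rate multipliers: each enhancer carries its
hidden class's multiplier (defaults: neutral 1.0, purifying 0.5,
positive 2.0); CDS positions other than fourfold-degenerate thirds evolve at
a purifying 0.05 multiplier so reading frames rarely acquire premature stops
(fourfold thirds always evolve at rate 1 — the validity of d4 as a neutral
reference is by construction, and the caller's exclusion of drift-broken CDS
is exercised by the residual ~10% of genes that do acquire stops). GC-fixation
bias, when enabled, multiplies all off-diagonal rates into G or C by
(1 + bias) genome-wide before rescaling to unit total rate — it changes the
direction composition of substitutions, not the pace, mimicking how gBGC
shifts fixation probabilities rather than mutation rates.

Default study conditions (chosen once, on real-data grounds): mouse/rat/human
lineage lengths 0.09/0.11/0.30 (neutral mouse-rat distance 0.20, roughly the
rodent fourfold-site divergence); base frequencies (0.29, 0.21, 0.21, 0.29);
transition-rich exchangeabilities (AG = 4.0, CT = 4.5 vs ~1 transversions);
gamma shape 1.0, K = 5; enhancers 0.8-2 kb; genes of 5-10 exons of 130-280 bp
(longest-isoform CDS ~0.7-2.5 kb, matching the real mouse median of ~1.5 kb —
intronless and single-intron genes carry the same total coding length in
fewer exons); introns 250-1200 bp; 10% of enhancers duplicated into a second
tissue; 90% of genes with a one-to-one ortholog; lognormal(5.6, 0.9)
expression levels (so the three bins are all populated) with 61 per-tissue
signals; 35% essential genes among the 80% with documented null phenotypes;
recombination rates Gamma(2, 0.3) cM/Mb in 50 kb windows.

Randomness is a single seed with deterministically derived per-feature
sub-streams (`SeedSequence([seed, domain, index])`), so adding features never
reshuffles existing ones and identical configs reproduce byte-identical
output files. Coordinates are 0-based half-open everywhere.

**What the generator does not emulate:** indels and alignment error (gap and
ambiguity injection exist but default off, and gaps are never placed in the
reference), CpG and other context-dependent substitution, regional mutation
rate variation beyond the gamma mixture, linked selection, real enhancer
length/GC distributions, and chromatin data of any kind. Passing tests
demonstrate that the estimators and tests recover truth *under the model they
assume*; they do not certify robustness to alignment artifacts or
context-dependent mutation in real genomes.

## Design choices where the design was open

- Consolidation merges on strictly shared base pairs; bookended intervals
  ([100,200) + [200,300)) stay separate.
- Whether GTR parameters are fit per region or shared is genuinely open; the
  pipeline shares a pooled neutral model (rationale above), and per-unit
  fitting is a switch.
- The Fisher table uses observed mismatch counts (see above); model-inferred
  substitution counts are out of scope.
- Strict rat==human agreement defines the A/T ancestor; the looser reading is
  a flag, not the default, because a rat=A/human=T column leaves the ancestor
  ambiguous.
- Per-region (not pooled per tissue) values enter the tissue comparisons of
  the gBGC ratios.
- Tests are two-sided throughout, since both directions are interpreted.

## Problem sizes used in the shipped tests

The acceptance checks run on deliberately scaled designs: estimator recovery
on 50 kb pairwise simulations across t in {0.05, 0.2, 0.5} x alpha in
{0.5, 1, 2}; classifier calibration and power on one dataset of 2,600
enhancers near 500 genes (>= 1,000 true-neutral testable enhancers, >= 200
per selected class); gBGC monotonicity on paired 120-enhancer runs; the
controlled comparison on 600-enhancer runs (one accelerated-heart scenario,
two exchangeable-null replicates). Fisher p-values are checked against an
independent implementation on >10^4 random tables with margins up to 200, and
interval/fourfold operations against brute-force oracles.

## Known limitations

- Pairwise free GTR+Gamma fits do not localize t (see identifiability note);
  interpret `alpha` from single-region fits with caution.
- Parsimony polarization undercounts events at high divergence (multiple hits
  and convergent outgroup changes); at rodent-primate distances the truth-log
  agreement in the tests quantifies the clean-site behaviour only.
- The Fisher 2x2 treats sites as exchangeable within region and reference;
  site-level rate autocorrelation (not simulated) would make the test
  anticonservative on real data.
- Consolidation semantics against the published region count cannot be
  validated without the original coordinates; strict-overlap is the literal
  reading and is stated as such.
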