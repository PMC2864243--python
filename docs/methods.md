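# Methods

## Preprocessing

Arrays carry linear fluorescence intensities. A gene counts as expressed
only if its unnormalized intensity strictly exceeds a threshold (default
25). How many arrays must exceed it is not uniquely determined by the
protocol being modeled; the default rule is `all_arrays` (the most
conservative), with `any_array` and `median` available. Surviving genes
are natural-log transformed and each array is standardized to mean 0 and
variance 1 (sample variance, n−1). Probes without annotation are dropped
and duplicate probes per gene are resolved by keeping one row chosen
uniformly under a caller-supplied seed. The stage order
filter → normalize → dedupe is enforced through a scale-state flag on the
matrix; running a stage out of order raises a state error rather than
silently producing wrong numbers.

Natural logs are used throughout; the choice is absorbed by the per-array
standardization and makes the enrichment ratio ER = exp(σ̄·NC) read as a
geometric-mean expression ratio (below).

## Per-gene model and normed effect coefficients

For each gene, a balanced fully factorial two-way ANOVA

    y_gti = μ + g + t + gt + e,   e ~ N(0, σ²)

with genotype (Wt vs KO) and treatment (control vs LPS) as fixed factors.
Effects are the cell-mean contrasts, oriented Wt−KO, LPS−control, and
(Wt LPS-induction) − (KO LPS-induction). With r replicates per cell the
residual df is 4(r−1); pooled biological samples mean any per-individual
random effect is confounded with, and treated as part of, the residual.

Per-gene residual variances are noisy at r = 3, but across thousands of
genes they behave like a common σ² times a χ² variate, so effects are
standardized by the *study-wide* scale σ̄ = mean over genes of
√(resid_var): NC = effect ∕ σ̄. `pooled_sd` also reports a
Kolmogorov–Smirnov diagnostic of resid_var·df/σ̂² against χ²(df) so the
equal-variance assumption can be checked on real data.

Significance per effect uses z = NC · c4(df) ∕ √v, where v is the analytic
design variance factor (1/r main effects, 4/r interaction) and
c4(df) = E[√(χ²_df/df)] corrects the known downward bias of σ̄ as an
estimator of σ (≈ 3% at df = 8; without the correction the realized
type-I rate at α = 0.05 is ≈ 5.7% rather than nominal). The correction
can be disabled. Which exact per-gene criterion the original analyses
used is not derivable from their description; the bias-corrected z test
is this package's choice and is validated by simulation (a 7546-gene null
screen yields ≈ 377 chance calls at α = 0.05, matching n·α).
Multiplicity is controlled per effect with Benjamini–Hochberg at
FDR 0.05; raw-α calls are reported alongside.

Rank curves plot sorted NCs against relative rank i/n with a null curve
of Normal(0, v) quantiles at the standard plotting positions (i−0.5)/n.
Under the global null the observed curve stays within a simultaneous
Monte-Carlo envelope of the null curve; signal appears as departure in
the tails (or, for a shifted class, across the whole curve).

## Class enrichment

Classes are contrasted class-vs-rest on the NC vector of one effect:
classical pooled-variance two-sample t test (Welch by flag) and
two-sample KS test, two-sided. The class statistic is the mean member NC,
also expressed as ER = exp(σ̄·NC): since NC·σ̄ is the class's mean
log-scale shift, ER is the implied geometric-mean expression ratio of
members versus the rest. Published class tables of (ER, NC) pairs are
consistent with a single proportionality constant ln(ER)/NC; because
printed values are rounded to two decimals, `fit_er_constant` treats them
as interval-censored — it refines the through-origin least-squares
estimate to the interval of constants compatible with every row's
rounding (plain least squares lands half a rounding unit outside one
row). Classes smaller than `min_class_size` (default 10) are skipped;
BH is applied across classes within one (source, effect) family and raw
p-values are always emitted. Degenerate contrasts (both groups constant
and equal) give p = NaN and are treated as no-calls.

The contingency route (`tfbs_set_enrichment`) tests whether a curated
gene set carries a motif more often than the remaining universe:
two-sided Fisher exact test, with the Haldane–Anscombe +0.5 correction
applied to the odds ratio when a cell is zero. Inclusion criteria
(upstream search length, conservation required or not) are varied by
recomputing the presence map under each setting.

## Motif conservation

5'-upstream regions extend up to 8 kb from the TSS, clipped at the
chromosome edge and truncated before the transcribed region of any
adjacent gene; for alignment, the longer sequence of an ortholog pair is
further truncated (at its distal end) to the shorter one's TSS distance.
3'UTRs are aligned at whatever lengths they have. The bundled aligner is
an optimal affine-gap global pairwise aligner suitable for these short
regions; pre-computed alignments are accepted as aligned FASTA.

Scanning uses a 4-bit IUPAC encoding; a motif matches wherever every
position's base set intersects the sequence's base, with an optional
mismatch budget. `N` in a *subject sequence* never supports a match
(unknown base), while `N` in a motif form is fully permissive. Reverse
complement scanning defaults to on for 5'UR motifs and off for 3'UTR
motifs. An occurrence is conserved when both species have a hit whose
start maps to the same alignment column; the two species may match
different forms or strands, and motif-internal alignment gaps are
tolerated by default (a strict gapless-span mode is available) — only the
start positions are compared, which is the natural reading of
position-based conservation. A gene is positive for a motif if it has at
least one conserved occurrence. Calls are symmetric in species order by
construction. Shortening the search region can only remove positives.

## miRNA annotation

A conserved 3'UTR octamer is associated with a mature miRNA when the
miRNA's distal octamer matches it perfectly. Which terminus "distal"
denotes is ambiguous; the default takes the 5'-terminal 8-mer and
compares its reverse complement to the octamer, consistent with
seed-region target pairing, and the 3'-terminal direct-match reading is
available via `end="three_prime"`. T and U are interchangeable on input.
Associated octamers become gene classes (class identity = octamer, even
when two octamers share a miRNA; miRNA ids ride along as metadata);
unassociated octamers are excluded from the cognate map.

## Synthetic data

`generate_expression` emits linear intensities
exp(ln(background) + μ_gene + g·x + t·z + gt·x·z + noise) with
genotype/treatment codes x, z = ±1/2, so the fitted contrasts equal the
planted effects in expectation and the >25 filter operates on a realistic
linear scale (background default 500). Defaults: 3 replicates per cell,
residual SD 0.1 on the log scale, per-gene baseline SD (`sigma_gene`)
0.5. Class structure is planted as per-gene effects drawn
Normal(class mean, effect SD); the shipped default classes mimic the
motivating biology — immune classes lower in the knockout at baseline and
strongly LPS-induced, metabolic classes higher at baseline and
LPS-suppressed, with interactions. A configured fraction of genes is
emitted entirely below the filter threshold (uniform intensities in
(5, 25)). What the generator does *not* emulate: scanner artifacts,
spatial or probe-level effects, intensity-dependent variance, correlated
residuals between genes. Passing tests therefore demonstrate correctness
of the statistical machinery under the stated model, not robustness to
array-specific artifacts.

`generate_ortholog_pairs` plants concrete realizations of each motif with
probability `plant_rate`, conserved (same ancestral position in both
species) with probability `conserve_rate`, then diverges species B by
per-site substitutions and indels while recording the true alignment as
an edit transcript. Two deliberate constructions keep the planted truth
table exact at zero divergence: chance background occurrences of the
planted motifs are scrubbed (mutated away), and planted spans keep a
buffer of one motif length so the junction of two plants cannot spell an
unscrubable third occurrence. Divergence is applied after planting, so
rising `point_divergence` erodes planted occurrences — the mechanism
behind the expected monotone decline of conserved-call counts.

`generate_mirnas` builds one cognate miRNA per octamer motif (5' end =
reverse complement of the octamer, random tail to 22 nt) plus decoys
re-sampled until their distal octamer matches no motif.

All generators are deterministic given their seed.

## Problem sizes and numerical choices

The validation suites run at desk scale, chosen to keep Monte-Carlo error
well below the tolerances they assert: 7546 genes for the null-screen
count (matching the screen size the analytic 377 refers to), 5000–10000
genes × 20 seeds for effect and scale recovery, 1000 independent null
classes for t-test calibration, 50 seeds × 10000 genes for realized FDR,
200 simulated null curves for the 99% rank-curve envelope, and 200 genes
× 20 octamer motifs for the conservation caller. The realized-FDR
measurement plants 500 strong true effects among 10000 genes because
under a pure global null the false discovery proportion of a BH call set
is degenerate (0 or 1 per dataset); with signal present it concentrates
near π₀·α and measures error control meaningfully. Effect fits are exact
cell-mean contrasts (no iterative optimization); ties in class tables are
broken by class name; q-values within an effect are standard BH step-up
values.

## Known limitations

- Unbalanced or incomplete designs are rejected, not approximated; there
  is no Type II/III sum-of-squares machinery and no empirical-Bayes
  variance moderation.
- GO classes are used as flat sets: no ancestor propagation or
  topology-aware testing, no gene-length or expression-level bias
  correction.
- The aligner is a plain optimal pairwise aligner; large genomic regions
  should be aligned externally and supplied as aligned FASTA.
- Conservation is position-based; it does not score motif quality
  (no PWMs) and cannot distinguish a conserved element from coincidental
  co-occurrence at homologous positions in highly similar sequences.
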