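# Methods

## The inference chain

The pipeline starts from a gene × sample table of raw counts for paired
polysome/total libraries across two cell lines × two treatments ×
triplicates, with ERCC spike-in rows. Upstream alignment and
quantification are out of scope; gene identifiers are opaque strings.

**Normalization.** Size factors are median-of-ratios restricted to
spike-in rows: spikes are added at fixed amounts per library, so their
counts should differ only by depth. Factor for sample *j* is the median
over usable spikes *s* of `counts[s,j] / geomean_samples(counts[s,·])`,
rescaled to geometric mean 1. At least three spikes with nonzero counts
in every sample are required; otherwise the caller falls back to
non-spike library totals. The ERCC Mix1/Mix2 nominal-concentration
design is not modeled — the spikes serve as a shared internal standard,
since nothing downstream uses the mix ratio.

**Enrichment scores.** `E = log2((P + ε)/(T + ε))` on normalized
abundances, with the polysome and total libraries of a condition paired
by replicate index and a pseudocount ε = 0.5 (configurable) keeping
zero counts finite. Spike rows are excluded from all inference.

**Per-condition test.** The null of mean enrichment zero is tested per
gene and condition. Two estimators are provided:

* `moderated=False`: the plain one-sample t-test on n − 1 replicate
  degrees of freedom (the documented closed form; replicates
  (0.9, 1.1, 1.0) give t ≈ 17.32, p ≈ 0.0033). Degenerate inputs are
  resolved deterministically: all-zero scores give p = 1; zero variance
  with nonzero mean gives the smallest positive normal float.
* `moderated=True` (pipeline default): an empirical-Bayes moderated
  t-test. Gene-wise variances are modeled as scaled draws from an
  inverse-chi-square prior whose scale s₀² and degrees of freedom d₀
  are estimated by method of moments on the log sample variances
  (trigamma inversion); posterior variances
  `(d₀ s₀² + (n−1) s²)/(d₀ + n − 1)` feed a t statistic on d₀ + n − 1
  degrees of freedom. This is the standard remedy for triplicate
  designs: with two residual degrees of freedom the plain t
  distribution's heavy tail bounds attainable p-values near 1/t², so
  even sixteen-fold polysomal shifts cannot survive a
  multiple-testing gate across thousands of genes. Borrowing variance
  information across genes restores usable resolution while remaining
  calibrated under the null (the global-null selection rate is checked
  by simulation in the test suite).

**Storey q-values.** π0 is estimated at a single λ = 0.5 by default
(`#{p > λ}/(m(1−λ))`, capped at 1, floored at 1/m; a λ grid averages
the estimates — no spline smoothing). q-values are the step-up tail
minima on sorted p, clipped to [0, 1]. Forcing π0 = 1 reproduces
Benjamini–Hochberg exactly (cross-checked against statsmodels).
q-values are computed within each condition separately.

**Band classifier.** The between-line difference
`d = ΔE(responsive) − ΔE(control)` is computed per gene;
the band is centered on the median of d (the mean is available by
config — both centerings are reported in the literature for this kind
of aggregate comparison) with spread the sample (n−1) standard
deviation over all non-spike genes. A gene is selected iff its minimum
q over the four conditions is below 0.03 and |d − center| ≥ 2 × spread;
class follows the sign of d − center. Zero spread selects nothing and
warns. Which line is "responsive" is configuration
(default MCF10A vs MCF7 control).

## Motif screen

Probabilistic PWM discovery is deliberately not reimplemented; since
the element of interest is a fixed GU-repeat, a deterministic,
oracle-testable screen suffices:

* `find_gre_runs` reports maximal alternating-G/T runs ≥ `gre_min_run`
  (default 10 nt, the canonical GTGTGTGTGT) as 0-based half-open
  intervals; maximal runs cannot overlap.
* `kmer_enrichment` enumerates every k-mer of widths 6–10 observed in
  either UTR set and tests presence/absence per sequence with a
  one-sided hypergeometric (sampling the positive-set size from the
  pooled universe), BH-adjusted within each width, sorted by p with a
  lexicographic tie-break. Presence per sequence (not occurrence
  count) is the enrichment unit because the quantity of interest is
  the fraction of carrier genes; occurrence totals are a separate
  utility. Perfect dinucleotide-repeat k-mers collapse to a repeat
  class (all substrings of (GT)∞ → "GT-repeat"), homopolymers to e.g.
  "A-homopolymer". Sense strand only: 3′-UTR elements act in cis on
  the transcript.

## qPCR and reporter calculators

The RIP chain is bit-exact arithmetic on cycle thresholds:
`ΔCt(norm RIP) = Ct(RIP) − (Ct(Input) − log2 dilution)`,
`% input = 100·2^−ΔCt`, `fold = 2^(ΔCt(NS) − ΔCt(RIP))`. The input
dilution factor is the reciprocal fraction of lysate reserved (10%
input → factor 10). Technical replicates are averaged on the Ct scale
before exponentiation. Percent input above 100% warns rather than
errors (arithmetically valid, experimentally implausible). Relative
expression uses −ΔΔCt against a reference gene; reporter fold changes
normalize tRFP to tGFP (treated over untreated) with a hit call at
fold ≥ 2 — the boundary itself is a hit — and Renilla is normalized to
Firefly against a control construct.

## Paired cohorts and trend tests

`FC = log2((T+1)/(N+1))` per gene and patient; the unit pseudocount
makes zero pairs well-defined. Heat-map ordering: rows by decreasing FC
variance; columns grouped by subtype in a configured order (PAM50
convention, "unknown" last) and by increasing mean FC within groups;
all ties break lexicographically, so the orders are deterministic
permutations.

The Jonckheere–Terpstra statistic sums pairwise Mann–Whitney counts
(+½ ties) over ordered group pairs. With total n ≤ 12 (configurable)
the p-value is exact by complete enumeration of value-to-group
assignments (distinct multiset assignments, vectorized; ties handled
exactly); above that, a normal approximation with the standard
tie-corrected variance. The Wilcoxon signed-rank test drops zero
differences, uses midranks, and is exact via the subset-sum
distribution of W⁺ (doubled ranks keep the DP integral) up to n = 20,
else normal with continuity and tie correction. Two-sided p-values
double the smaller tail, capped at 1. The exact cutoffs are desk-scale
runtime choices; two-group JT reduces to the one-sided rank-sum test
(cross-checked against an independent implementation in the suite).

## Synthetic data

The generators encode the study conditions: 2,000 genes, 25 + 25
implanted effects of |log2 shift| 4, one million expected counts per
library, triplicates, two lines of which only one responds. Choices the
design left open, fixed once here:

* Negative-binomial counts (`var = μ + 0.01 μ²`) around log-normal
  baselines (σ = 1.5); dispersion 0.01 is typical of isogenic
  cell-line triplicates. Per-sample depth jitter is log-normal
  (σ = 0.15), corrected by the spike normalization; 30 spike rows carry
  2% of library mass.
* Effects are implanted only in the responsive line's treated
  condition — an event common to both lines could not mark the
  differential response — and only into genes with ≥ 50 expected
  total-fraction counts: a sixteen-fold polysomal depletion of a gene
  with single-digit counts is informationally unrecoverable by any
  method, and the real candidates were by construction detected
  transcripts.
* UTRs are i.i.d. uniform A/C/G/T of length 200–1,000 nt with one
  (GT)_r implant (2r ≥ 10 nt) at rate 0.3 in the positive class and
  0.01 elsewhere. qPCR records invert the RIP chain exactly before
  Gaussian Ct noise (σ = 0.2). The paired cohort has 111 patients,
  log-normal normal-tissue expression, multiplicative per-cell log2
  noise (σ = 0.25), and subtype labels at breast-cancer-like
  frequencies; ordered groups of sizes (10, 53, 13) — tumour-stage
  cohort sizes — carry a location shift of `trend_shift × group index`.
* Every generator draws from its own RNG stream derived from the master
  seed by hashing the generator name, so generators never perturb each
  other and repeated calls are byte-identical.

What the generator does **not** emulate: gene-length/GC effects,
batch structure, isoform mixing, count correlation between fractions
beyond the shared mean, or heavy-tailed outlier samples. Passing
recovery tests therefore demonstrate correctness of the inference
chain under its own model assumptions, not performance on arbitrary
real data.

## Numerical conventions

All intervals are 0-based half-open. Result tables are TSV with floats
at 9 significant digits (declared in a header comment); round-trips are
exact to that precision. Sorting everywhere uses stable mergesort with
documented tie-breaks, so identical inputs give byte-identical outputs.
Exact-test tail comparisons use a 1e-9 slack to absorb float rank
arithmetic.

## Problem sizes used in the checks

The bundled checks run at the study scale that the defaults encode
(2,000 genes × 24 libraries; 50-sequence motif universes; 10,000
sequences for the scanner oracle; 1,000 null and 200 shifted trend
simulations), which completes in seconds on one CPU.

## Known limitations

The per-condition test treats replicate enrichment scores as the unit
of inference rather than modeling counts directly (a
generalized-linear NB model with an interaction term would be the
heavier alternative). π0 estimation at a single λ is crude for small
m; the band classifier assumes the bulk of genes are unregulated so
that the d spread estimates noise; and the motif screen's
hypergeometric treats sequences as exchangeable, ignoring length
differences between sets.
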