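# ribodelta

Tools for finding translationally regulated genes from polysome-profiling
RNA-seq, built around the analysis that identified GU-rich-element (GRE)
driven translational activation of EMT (epithelial–mesenchymal transition)
drivers in breast epithelial cells.

The scientific question: which mRNAs change their *ribosome loading* —
rather than their abundance — when a cell line undergoes EMT? The design
compares a responsive line (MCF10A, which transitions on TGF-β) against a
non-responsive line (MCF7) so that events common to both lines can be
discounted. The package is aimed at computational biologists who want a
tested, reusable implementation of that inference chain and its companion
calculators, exercised end to end on synthetic data with known ground truth.

## The model

For gene *g*, condition *c* (cell line × treatment) and replicate *r*, the
polyribosomal enrichment score on spike-in-normalized abundances is

```
E_g(c, r) = log2( (P_g,c,r + ε) / (T_g,c,r + ε) )
```

with *P* the polysome-fraction and *T* the total-mRNA abundance and ε a
pseudocount (default 0.5). Per condition, H₀: mean_r E = 0 is tested with a
variance-moderated one-sample t-test (empirical-Bayes shrinkage of the
replicate variance across genes); p-values become Storey q-values with

```
π0 = #{p_i > λ} / (m (1 − λ)),   q_(i) = min_{j ≥ i} π0 · m · p_(j) / j .
```

A gene is **selected** when (i) q < 0.03 in at least one of the four
conditions, and (ii) its between-line difference in the treatment-induced
shift,

```
d_g = ΔE_g(responsive) − ΔE_g(control),    ΔE = E̅(treated) − E̅(untreated),
```

lies at least two standard deviations from the median of the d
distribution. The sign of d − center classifies the gene as a putative
positive or negative regulator of the transition.

Downstream utilities cover: maximal-run GRE scanning (alternating G/T runs
≥ 10 nt, i.e. 5′-GTGTGTGTGT-3′), exhaustive k-mer (width 6–10)
enrichment of positive-class vs negative-class 3′-UTRs with one-sided
hypergeometric tests and BH adjustment, the RIP-qPCR chain
(ΔCt = Ct(RIP) − (Ct(Input) − log2 dilution), % input = 100·2^−ΔCt,
fold enrichment = 2^−ΔΔCt), −ΔΔCt expression, dual-reporter
normalizations (tRFP/tGFP, Renilla/Firefly), paired tumour–normal
fold changes FC = log2((T+1)/(N+1)) with heat-map ordering, and exact
Jonckheere–Terpstra and Wilcoxon signed-rank tests.

## Worked example

```python
from ribodelta import (PipelineConfig, SimConfig, run_diff_translation,
                       simulate_polysome_experiment, selection_counts)

cfg = SimConfig(rng_seed=1)          # 2,000 genes, 50 implanted effects
counts, truth = simulate_polysome_experiment(cfg)
table = run_diff_translation(counts, PipelineConfig())
print(selection_counts(table.summary))
print(round(table.band_spread, 3))
```

prints

```
{'positive': 26, 'negative': 27, 'total': 53}
0.747
```

i.e. 53 genes fall outside the two-s.d. band with q < 0.03 — the 50
implanted regulators (all recovered with the correct sign for this seed)
plus three borderline false calls — and the d distribution has spread
0.747 log2 units. The same objects feed the motif screen:

```python
from ribodelta import simulate_utrs, kmer_enrichment, top_repeat_class
utrs = simulate_utrs(truth, cfg)
rows = kmer_enrichment(utrs.subset(truth.ids_of_class("positive")),
                       utrs.subset(truth.ids_of_class("negative")))
print(top_repeat_class(rows))        # -> GT-repeat
```

A command-line interface mirrors the library
(`ribodelta simulate|difftrans|motif|ripqpcr|reporter|paired|all`); every
run writes a JSON manifest with the config used and input digests.

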