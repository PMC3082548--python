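# dyeswapde

Differential expression for two-color spotted microarrays with a dye-swap
design, plus the companion assay quantifications that typically accompany
such a study (relative qPCR, growth, viability).

The intended user compares patient-derived samples against a pooled
reference on two-channel arrays, each comparison hybridized twice with the
fluorophores exchanged, every probe spotted in duplicate. The package
implements the whole analysis as tested, reusable code:

* **Spot filtering** — per-channel Z-score removal of low-intensity spots.
* **LOWESS balancing** — robust local regression of M = log2(ch1/ch2) on
  A = ½(log2 ch1 + log2 ch2), removing intensity-dependent dye bias per
  slide.
* **Dye-swap concordance** — within each swap pair, genes whose centered
  log2(R1/R2) exceeds 3 SD are discarded as replicate-discordant.
* **Cross-patient consistency** — only genes whose summarized ratio has the
  same sign in every patient are retained; each patient's value is the
  geometric mean of its two replicate ratios.
* **One-class SAM** — per-gene relative difference d = x̄/(se + s0) with an
  automatically selected fudge factor s0, an exhaustive sign-flip
  permutation null, a delta/FDR table (FDR = median permuted false calls /
  genes called), and calling at 0% estimated FDR with an up/down split.
* **Enrichment** — one-sided hypergeometric over-representation of the
  called genes in user-supplied (GMT) gene sets, reported as
  changed/total/p-value rows.
* **Assays** — 2^−ΔCt relative qPCR against a reference gene, Pearson
  concordance of microarray vs qPCR fold changes, exponential doubling time
  from two timepoints, MTT viability percent, cpm/DNA normalization, and
  two-group t / Mann–Whitney tests.

A synthetic-experiment generator (`SimulationConfig`,
`simulate_experiment`) produces complete slide tables, designs, gene sets
and ground truth with planted differential expression, dye bias, dim spots
and discordant replicates, so the full pipeline can be exercised and
validated without any external data.

## Worked example

```python
from dyeswapde import DyeSwapExperiment, SimulationConfig, simulate_experiment

config = SimulationConfig(seed=1)           # 4 patients, 2000 genes, 100 planted DE
slides, design, truth = simulate_experiment(config)

results = DyeSwapExperiment(slides, design).fit(seed=1)
print(results.summary())
```

prints

```
Dye-swap differential expression run
====================================
slides:                   8 (4000 spots each)
low-intensity spots:      652
LOWESS outlier spots:     0
genes on array:           2000
  dropped (concordance):  20
  dropped (missing):      8
  dropped (pattern):      1641
genes into SAM:           331
s0 (fudge factor):        0.159203
called at FDR <= 0:       99 (up 49, down 50)
```

Reading the report: of 2000 genes, 20 failed dye-swap concordance in some
patient, 8 lacked a complete value in every patient, and 1641 did not show
the same direction of change in all four patients, leaving 331
sign-consistent candidates; SAM's 0%-FDR rule then called 99 genes (49 up,
50 down). Against the generator's ground truth this run recovered 98 of
the 100 planted genes with a single false call:

```python
called = set(results.called["gene_id"])
len(called & truth.de_genes), len(called - truth.de_genes)   # (98, 1)
```

`results.sam` carries the fitted SAM model (statistics, delta table,
observed-vs-expected plot via `results.sam.plot()`), `results.ratio_matrix`
the per-gene provenance, and `results.enrichment` the over-representation
table when gene sets are supplied. `results.write_outputs(dir)` saves every
intermediate as TSV plus a JSON run report.

The same stages are scriptable from a shell:

```sh
dyeswapde simulate --n-genes 2000 --seed 1 --outdir exp/
dyeswapde run exp/slide*.tsv --design exp/design.tsv \
    --gene-sets exp/gene_sets.gmt --seed 1 --outdir out/
dyeswapde report out/
```

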