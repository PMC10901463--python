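# melscreen

Analysis toolkit for genome-wide CRISPR screens that use FACS side scatter
(SSC) as a proxy for cellular melanin content, and for the population-genetic
follow-up analyses such screens motivate. It is aimed at groups analyzing
pooled knockout screens sorted into phenotype bins and relating the resulting
hit genes to human pigmentation variation.

Four analysis stages, each paired with a synthetic-data generator so every
statistical claim can be checked against planted ground truth:

1. **Screen gene effects** (`melscreen.screen`). Cells sorted into the low
   and high 10% tails of the SSC distribution give two read counts per sgRNA.
   With `e = log2(f_low / f_high)` the per-guide enrichment and `p0` an
   empirical (kernel-density) null learned from safe-targeting control
   guides, a gene with effect θ contributes per-guide likelihood

   ```
   p_θ(e) = (1/|θ|) ∫₀^θ p0(e − t) dt,          p_0(e) = p0(e)
   ```

   — the guide's realized effect is uniform on [0, θ], reflecting variable
   guide efficacy. The gene effect θ̂ maximizes Σᵢ ln p_θ(eᵢ) over a grid,
   with likelihood-ratio score `S = 2(L(θ̂) − L(0))`, a profile-likelihood
   95% CI, an empirical FDR from control-resampled pseudo-genes, and
   replicate-intersected hit calling (positive effect, FDR < 10% in every
   replicate).

2. **PBS selection scan** (`melscreen.pbs`). Per SNP, Hudson's F_ST between
   three populations is transformed to branch lengths `T = −ln(1 − F)` and
   combined into the population branch statistic
   `PBS_A = (T_AB + T_AC − T_BC)/2`, with genome-wide empirical p-values,
   top-0.01%/0.1% quantile flags, and SNP-to-gene assignment via ±100 kb
   windows around gene bodies.

3. **eQTL–GWAS concordance** (`melscreen.concord`). Lead-eQTL selection
   (p < 0.01, closest on ties), allele harmonization against a GWAS summary
   table, exact two-sided binomial test of sign agreement, Fisher 2×2
   enrichment, and Spearman / stratified Wilcoxon tests relating PBS
   significance to GWAS effect size.

4. **Expression–melanin correlation** (`melscreen.exprcorr`). Per-gene
   Spearman ρ between TPM and donor melanin content (OD400),
   Benjamini–Hochberg q-values, and positive/negative/ns classification at
   q < 0.1.

## Worked example

`python examples/screen_demo.py` simulates two replicates of a 60-gene
screen (10 genes planted at θ = 2, 1,000 safe-targeting controls, 500 reads
per guide per bin) and runs the full analysis:

```
9 genes pass FDR < 10% in both replicates (10 were planted at theta = 2):
  gene_id  min_score  mean_effect
gene00004  66.016673         2.84
gene00000  37.417929         2.62
gene00009  24.859511         2.06
...
9 of 9 called hits are planted positives
```

`min_score` is the smaller of the two replicates' likelihood-ratio scores;
`mean_effect` the average θ̂ in log2 units — positive means the knockout
lowers the melanin proxy, i.e. the gene promotes melanin. Nine of ten
planted genes are recovered with no false positives at this depth.

The other example scripts cover the remaining stages
(`pbs_scan_demo.py`, `concordance_demo.py`, `expression_demo.py`), and the
same stages are scriptable from the shell:

```bash
melscreen simulate-pops --n-snps 10000 --n-selected 10 --seed 7 --out sim/
melscreen pbs --freqs sim/freqs.tsv --target A --out scan/
melscreen run --config pipeline.yaml    # multi-stage run with a manifest
```

## Layout

- `src/melscreen/` — library modules (`synth`, `screen`, `pbs`, `concord`,
  `exprcorr`, `io`, `pipeline`, `cli`)
- `examples/` — one narrative script per capability
- `tests/` — pytest suite (unit, property and end-to-end recovery tests)
- `docs/methods.md` — models, assumptions, parameter choices, limitations
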