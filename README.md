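# localpanel

How much does a small, population-specific reference panel add to genotype
imputation against a large global panel — and for which variants?

Imputation infers untyped genotypes from a sparse genotyping array using a
reference panel of phased haplotypes. For isolated or drifted populations,
a cosmopolitan panel such as 1000 Genomes matches local haplotypes
imperfectly, and less common variants (MAF 1–10%) suffer most. Sequencing
~90 members of the study population and adding them as a second reference
panel measurably improves accuracy; published leave-one-out evaluations in
two European isolates (Korčula, Croatia and Orkney, Scotland) report mean
dosage-r² in the 1–3.2% MAF bin rising from 0.504/0.586 to 0.697/0.753 —
equivalent to a 38%/28% increase in effective GWAS sample size.

`localpanel` is a desk-scale, fully synthetic re-implementation of that
experimental design for methodologists and teaching: a seedable population
simulator, the sequence-QC cascade, a haploid Li–Stephens copying-model
imputation engine with one- or two-panel support, and the drop-one-out
cross-validation analysis, all runnable in minutes on one CPU.

## The model

A target haplotype is modelled as an imperfect mosaic copy of the `H`
reference haplotypes (Li–Stephens). The hidden state is the haplotype
currently copied; across genetic distance `d` Morgans the probability of
continuing to copy the same haplotype is

```
p_ns(d) = exp(−4·Ne·d / H),        Ne = 20,000 by default
```

with the switch mass `1 − p_ns` spread uniformly over all `H` states.
Emissions allow miscopying with probability

```
θ = 1 / Σ_{i=1}^{H−1} 1/i,         λ = θ / (2·(H + θ))
```

(the Watterson-θ parameterisation). The HMM runs over the full site grid,
emitting only at array-typed sites; posterior copying probabilities γ give
the expected alt-allele dosage per site, summed over the subject's two
phased haplotypes. Two reference panels are combined by concatenating
haplotypes over the primary panel's site grid (no consensus merging);
sites absent from the secondary panel emit uninformatively.

Accuracy is the squared Pearson correlation, per SNP across subjects,
between imputed dosage and the gold-standard genotypes, with each subject
imputed against a local panel from which their own two haplotypes were
removed (drop-one-out, avoiding circularity). A proportionate increase in
mean r² acts on association power like the same proportionate increase in
sample size, which is the effective-sample-size (ESS) column.

## Worked example

```python
import localpanel as lp

truth = lp.simulate_populations(lp.SimConfig(seed=1))
table = lp.run_crossval(truth)     # drop-one-out, two panel configurations
print(lp.summarize_bins(table).round(3).to_string(index=False))
```

which prints (seed 1, reference configuration: 500 global haplotypes, 90
local subjects from a drifted bottleneck population, ~190 array sites over
a 3 Mb / 3 cM region):

```
    bin  n_snps  mean_r2_one  mean_r2_two  mean_increase  sd_increase  ess_increase_pct
 1-3.2%      79        0.255        0.591          0.336        0.309               132
3.2-10%     180        0.316        0.756          0.440        0.249               139
 10-32%     134        0.488        0.825          0.337        0.186                69
   >32%      37        0.596        0.860          0.264        0.123                44
```

`mean_r2_one` is accuracy with the global panel alone, `mean_r2_two` with
the global plus leave-one-out local panel. Baseline accuracy rises with
MAF while the ESS gain concentrates in the less common bins — the
qualitative signature of the published cohort results. The rescue
crosstab shows the same thing at the SNP level: with this seed 32.7% of
target SNPs impute poorly (r² < 0.2) from the global panel alone, and
25.5% of those impute well (r² > 0.8) once the local panel is added.

The same pipeline is scriptable from the shell:

```
localpanel run       --config cfg.yaml --seed 1 --out run1/
localpanel simulate  --out sim/ --seed 1
localpanel impute    --gt sim/local_truth.vcf --ref sim/global_panel \
                     --map sim/genetic_map.txt --ne 20000 --out imp/
```

writing VCF, IMPUTE2 `.hap/.legend/.sample`, a 3-column genetic map and
tab-separated report tables (`table1.tsv`, `crosstab.tsv`,
`grid_mean.tsv`, …), every file stamped with version, config hash and
seed.

## Layout

| module | role |
|---|---|
| `localpanel.synthpop` | founder pool, mosaic haplotypes, drifted local cohort, error/quality injection |
| `localpanel.qc` | sequence QC cascade, exact HWE test, array–sequence merge, panel intersection |
| `localpanel.lshmm` | Li–Stephens forward–backward, one/two-panel dosage imputation |
| `localpanel.crossval` | drop-one-out evaluation, per-SNP r², MAF-bin summaries, grids |
| `localpanel.io` / `localpanel.cli` / `localpanel.pipeline` | formats, orchestration, CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
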