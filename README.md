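# exocall

Logistic-regression variant calling for whole-exome capture sequencing
(WECS).  `exocall` streams a coordinate-sorted single-sample SAM/BAM,
compiles the read evidence at every candidate locus, scores each candidate
with a trained logistic regression model, applies heuristic filters,
genotypes passing calls, and writes VCF.  Single-sample VCFs can be merged
into a population VCF with missing coverage filled in.  The package also
contains the full model-building machinery (fitting, stepwise selection,
drop-one significance pruning, bootstrap confidence intervals, repeated
split-half cross-validation) and a synthetic-data generator, so the entire
pipeline is developed, trained and tested without any external data.

It is aimed at people calling SNPs and short (few-bp) INDELs in exome
capture data — where depth is heterogeneous, error patterns differ from
whole-genome data, and quality expectations (coding Ts/Tv of 3–4, depleted
frameshifts) are specific to coding sequence — and at anyone who wants to
retrain the classifiers on their own labeled sites.

## The model

For a candidate site with covariates $x$, the probability that it is a
true variant is

$$p = \frac{1}{1 + e^{-(\beta_0 + \sum_i \beta_i x_i)}}$$

**SNP covariates** (computed over the reads carrying the variant base):
reference/variant reads ratio, strand direction standard (1 iff variant
evidence exists on both strands), mean distance of the variant base to the
3' read end, mean neighboring base quality (NBQ: the variant base plus up
to five flanking bases on each side of the read), mean variant base
quality, and the interactions NBQ × dist3 and strand × dist3.

**INDEL covariates**: normalized variant square (NVS = variant reads² /
total depth, coupling variant depth and variant ratio in one term), mean
NBQ over the gap flanks, mean variation rate of the variant reads
((mismatches + gap events) / read length, a mapping-quality surrogate),
and the read-end ratio (fraction of variant reads with the event within
5 bp of a read end).

Calls must clear heuristic filters: SNPs need $p \ge 0.5$, variant depth
$\ge 2$ and an effective site depth $\ge 6$ (the callable region);
INDELs need $p \ge 0.5$ ($\ge 0.88$ for 1 bp deletions), $\ge 2$ variant
reads, total depth $\ge 2$ and variant ratio $\ge 0.05$.  Passing calls
are genotyped from the adjusted variant ratio
$t = \mathrm{var\ depth} / (\mathrm{total\ depth} - \mathrm{color\ corrected})$:
$t \ge 0.8$ homozygous, $t \ge 0.1$ heterozygous.

The packaged `models/default_snp.json` and `models/default_indel.json`
are trained on the synthetic fixture generator (no published coefficients
exist for this feature set); retrain on your own labeled data with
`exocall train` for production use.

## Worked example

```sh
exocall simulate --seed 4 --n-sites 60 --tp-fraction 0.5 \
    --indel-fraction 0.25 --depth 25 --out-dir sim/
exocall snp   -i sim/reads.sam -r sim/reference.fasta -o s1.vcf \
    --sample-name s1 --callable-out callable.bed
exocall indel -i sim/reads.sam -r sim/reference.fasta -o s1.indel.vcf
exocall evaluate --vcf s1.vcf --callable callable.bed
```

which prints (this exact fixture):

```
wrote 4600 reads, 30 true variants to sim
21 PASS SNPs -> s1.vcf
7 PASS INDELs -> s1.indel.vcf
n_snps  21
n_indels        0
ts_tv   0.9091
snp_density_per_kbp     2.3041
```

The simulated sample plants 30 true variants among 60 candidate sites
(the rest are systematic error sites): 22 SNPs and 8 INDELs.  21 SNP
calls pass all filters (one weakly supported het site scores below the
p ≥ 0.5 cutoff), and 7 of the 8 INDELs pass.  Ts/Tv is ~0.9 rather than the
coding-region 3–4 because simulated alternate alleles are uniform over
substitution types — the metric reports what the call set contains, and
the 3–4 expectation is a property of real coding sequence.  The same
`evaluate` command compares two call sets
(`--compare`, `--shared-region`) or scores rediscovery against a
known-sites list (`--known`).

Model building from a labeled feature table (tab-delimited, one covariate
column per variable plus a TP/FP `label` column):

```sh
exocall train --table train.tsv --stepwise --drop-alpha 0.05 -o model.json
```

prints the coefficient table (estimate, SE, Wald z, p) of the selected
model and writes it as JSON.  The same machinery is available as a
library: `VariantLogit.from_dataframe(df, variables).fit()` returns a
results object with `params`, `bse`, `zvalues`, `pvalues` and
`summary()`; `cross_validate(...)` and `bootstrap_ci(...)` implement the
overfitting diagnostics.

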