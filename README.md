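# equiburden

Estimation of the **predicted genetic burden** in multi-breed whole-genome
cohorts — built for equine genetics, applicable to any diploid cohort with
dual variant-effect annotation.

Healthy individuals carry hundreds of variants that effect predictors call
deleterious. When hunting a disease-causing variant in a sequenced patient,
that background burden is the haystack: knowing its size per breed, and the
baseline frequencies of already-published disease and trait alleles, is what
separates a plausible candidate from population noise.

## What it computes

Given a multi-sample VCF annotated by **both** SnpEff (`INFO/ANN`) and
Ensembl-VEP (`INFO/CSQ`), sample metadata (breed, mean depth of coverage),
and optional breed-Ne and known-variant tables:

- **Consensus burden rule.** Each variant's transcript annotations are
  reduced to one primary (most severe) consequence per annotator. A variant
  is part of the predicted genetic burden iff its impact pair is
  (HIGH, HIGH), (HIGH, MODERATE) or (MODERATE, HIGH) — agreement between two
  independent predictors guards against single-tool overcalls.
- **Loss of function (LOF).** A burden variant is LOF iff *both* primary
  terms are in {frameshift, splice acceptor, splice donor, start lost,
  stop lost, stop gained} (the terms need not be identical; annotator
  spelling dialects are normalized).
- **Per-sample, per-gene and cohort statistics.** Burden / homozygous /
  LOF / private counts per genome; variant frequency VF = alt alleles over
  called alleles; per-gene aggregation and the two downstream gene lists
  (> 5 burden variants; VF > 5%).
- **Breed comparison with DOC adjustment.** Detected variant counts rise
  with sequencing depth, so breed means are reported as estimated marginal
  means (EMMEANs) from `count ~ breed + DOC`, evaluated at the grand-mean
  DOC with t-based 95% CIs. Per-horse burden is correlated with published
  breed effective population sizes (Fisher-z CIs).
- **Known-variant catalog.** OMIA-style entries are matched exactly on
  (chrom, pos, ref, alt); per-breed genotype counts, VF/MAF, category
  detection summaries, and an audit of genotypes that conflict with
  reported inheritance (homozygotes for reported lethals, carriers outside
  reported breeds).
- **Synthetic cohorts with known truth.** A generator plants breed effects,
  a rare-skewed deleterious site frequency spectrum, DOC-dependent genotype
  dropout and catalog variants — so every stage is testable end to end
  without external data.

## Worked example

```bash
python examples/02_burden_statistics.py
```

prints (synthetic cohort, 3,005 sites × 264 horses in 13 breed groups):

```
3005 variants (2485 SNPs, 520 indels)
predicted genetic burden: 1200 variants (39.93% of all variants), 866 LOF
median VF  burden: 3.21%   non-burden: 22.65%
(deleterious variants sit at lower frequencies: purifying selection)
...
per-horse burden: median 191 (IQR 177-203); median homozygous 39
annotators agree on variant type for 885 of 1200 burden variants (73.8%)
```

The burden total always equals the sum of the three qualifying cells of the
SnpEff × VEP impact cross-tabulation; the burden VF median sits below the
non-burden median because the generator (like selection) keeps deleterious
alleles rare. The synthetic burden *fraction* is far higher than in a real
genome-wide callset — the generator enriches coding-like sites on purpose.

Other examples: `01_simulate_cohort.py` (generator + planted truth),
`03_breed_emmeans.py` (DOC-adjusted breed means, Ne correlation),
`04_known_variants.py` (catalog matching and genotype audit).

The same pipeline is scriptable from a shell:

```bash
equiburden simulate --out sim/ --seed 1
equiburden all --vcf sim/cohort.vcf --metadata sim/metadata.tsv --out run/
```

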