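# Methods

## The consensus burden model

Variant-effect predictors overcall: a single tool's HIGH-impact list is
contaminated with annotation artifacts. The burden rule here requires
agreement between two independent annotators — SnpEff and Ensembl-VEP —
on severity: a variant is **predicted genetic burden** iff its
(SnpEff, VEP) primary impact pair is (HIGH, HIGH), (HIGH, MODERATE) or
(MODERATE, HIGH). All other pairs, including (MODERATE, MODERATE), are
excluded; the rule is deliberately asymmetric-tolerant (one tool may
downgrade to MODERATE) but never admits LOW or MODIFIER calls.

**Primary annotation selection.** Each annotator emits one annotation per
transcript. The primary annotation is the one with the most severe impact
class; ties are broken by an explicit consequence-severity table, then by
position in the source field (annotators list most-severe first).
Neither annotator publishes an intra-impact severity ranking, so the
shipped table (`equiburden.impacts.DEFAULT_SEVERITY_RANK`, Ensembl's
consequence ordering with SnpEff-only terms slotted beside their nearest
equivalent) is this package's construction. It is overridable per run
(`--severity-table`); both annotators always use the same table.
Ampersand-joined compound terms keep their order and the first term is
primary.

**Loss of function.** A burden variant is LOF iff *both* primary terms
are in the LOF set — frameshift, splice acceptor, splice donor, start
lost, stop lost, stop gained. The two tools spell these differently
("Splice acceptor" vs `splice_acceptor_variant`); membership is tested
after normalization through an explicit synonym map. The terms need not
be equal (frameshift + splice donor qualifies); a LOF call by one
annotator alone never does. LOF ⊆ burden by construction.

**Frequencies.** "Variant frequency" (VF) is the alternate-allele
frequency — alt alleles over *called* alleles, so missing genotypes
shrink the denominator. MAF = min(VF, 1−VF) is reported separately where
catalog conventions expect it. Quantiles (medians, IQRs) use linear
interpolation throughout.

**Ingestion conventions.** Coordinates are 1-based VCF positions.
Multi-allelic sites are decomposed to one record per alt allele (the
consensus rule is per-allele); annotations are routed to records by
allele match and unroutable annotations are dropped with a count.
Indels longer than 20 bp are excluded (with a count) to match the
variant-calling window of the cohorts modelled. Half-calls (`./1`) are
treated as missing — conservative denominator handling. Chromosome
aliases (with/without `chr`) are applied only through an explicit map,
never silently.

## Breed analysis

The number of variants detected in a genome rises with its mean depth of
coverage (DOC), confounding raw breed means. Breed effects are therefore
estimated from an OLS fit of

    count ~ C(breed) + DOC        (treatment coding, alphabetical reference)

and reported as estimated marginal means: the prediction for each breed
at a single reference DOC, by default the grand mean over included
samples (breeds are *not* equally weighted when forming that reference).
SE comes from the linear form's variance under the coefficient
covariance; 95% CIs use t(residual df) — whether the published analyses
used t or normal quantiles is unstated, and t is the conservative choice.
In a balanced design with identical DOC distributions the EMMEAN reduces
exactly to the raw group mean, and the fit is invariant (to 1e−8) under
DOC centering; both identities are tested. A DOC column with no
variation is dropped with a warning; a singular design raises an error
naming the dependent column. The relationship between counts and DOC is
mildly nonlinear in real data; the inferential model is linear by
design, matching how the published EMMEANs were computed, and no smoother
enters the inferential path.

**Target breeds.** A breed enters the comparison with ≥ 17 samples
(`min_n`, configurable; the looser "> 15" criterion some analyses quote
is `min_n=16`) and breed-mean DOC > 5X; everything else is pooled as
"Other", which enters the model as a level.

**Ne correlation.** Each horse is paired with its breed's published
effective population size, giving n = horses (not breeds); this pairing
is what published CI widths imply. Pearson's r with Fisher-z 95% CIs;
horses of breeds without an Ne estimate are excluded and counted.
Because Ne varies only at the breed level, the effective information is
closer to the number of breeds — the per-horse CI is what the published
analysis reports, not a guard against breed-level clustering (see
`examples/03_breed_emmeans.py`).

**Frequency comparison.** Burden vs non-burden VF distributions are
compared with a Welch two-sample t-test (mean difference, 95% CI), with
medians/IQRs reported alongside; significance threshold 0.05.

## Known-variant catalog

Matching is exact on normalized (chrom, pos, ref, alt) — no positional
windows. Catalog indels must be left-normalized upstream; a near-miss
list (same position, different alleles) surfaces normalization problems.
Entries with alleles > 20 bp are rejected at load, mirroring the
pipeline's indel window. Detection means ≥ 1 alt allele observed.
Per-breed genotype counts, VF and MAF are reported per entry; category
summaries give detection percentages and VF medians/IQRs over detected
entries (absent when nothing is detected). Inheritance audits are
rule-driven per entry (`lethal_homozygote`, `expected_breeds`) and
produce a review list with sample ids — read-level confirmation is out
of scope. Coat-colour entries may carry lethal-homozygote rules (some
white-spotting alleles are thought embryonic lethal when homozygous).

## The synthetic cohort generator

The generator emulates the *statistical structure* a real multi-breed
WGS cohort presents to this pipeline, with recovery — not replication of
any published total — as the test surface:

- **Design**: 12 target breeds × 20 horses + 24 "Other" (264 genomes);
  per-breed DOC means 5.5–17.5X (SD 1–3X), clipped to [1, 22].
- **Sites**: 12,000 by default, 40% deleterious ("burden"), of which 73%
  are LOF-type. Deleterious allele frequencies draw from Beta(0.3, 2.5)
  (median ≈ 4%), neutral from Beta(0.6, 1.4) (median ≈ 24%) — the
  rare-skew purifying selection produces, and the source of the tested
  burden-VF < neutral-VF dominance.
- **Breed effects** multiply deleterious frequencies by a per-breed scale
  (0.80–1.13, ordered as published breed burden differences), giving
  expected per-horse burden roughly 630–860 under the default design.
- **Genotypes** are Hardy–Weinberg draws per (breed, site): p², 2p(1−p),
  (1−p)².
- **Dropout**: each genotype is missing with probability
  max(0, 0.18 − 0.008·DOC). On DOC ∈ [1, 22] this is exactly linear, so
  expected detected counts are linear in DOC — the regime the count
  model assumes. Dropout hits genotypes, not sites, so frequency
  denominators shrink realistically.
- **Annotator labels**: burden sites draw impact pairs from the
  qualifying set (98.5/1.3/0.2%); LOF sites give both annotators LOF
  terms, identical with probability 0.887. Non-LOF burden sites draw
  term pairs with at most one side in the LOF set, so overall type
  concordance among burden variants lands near 74% — the agreement
  parameter governs LOF sites only.
- **Planted catalog entries** (per-breed frequencies, including one at
  frequency 0 that must be reported undetected) exercise the catalog
  stage.

**Truth and planted means.** The `TruthSet` stores realized per-breed
site frequencies, exact pre-dropout per-sample counts (pipeline counts
must match them *exactly* in no-dropout mode — an integer, not a
tolerance, check), and planted breed means: detection(at_doc) ×
Σ_sites (1−(1−p)²) from the realized frequencies. EMMEAN 95% CI coverage
of those means is ≥ 90% over 200 default-config replicates (the small
shortfall from 95% reflects the shared-slope approximation when
breed-specific base counts scale the dropout slope).

Replicate studies count carriage directly from the in-memory genotype
matrix (`observed_sample_counts`); VCF text is rendered only when files
are written. The no-dropout exactness checks run the full
VCF → parser → counting path.

**What passing does not show.** No linkage disequilibrium, pedigree or
population structure beyond breed labels, no reference bias, no
genotype *errors* (only missingness), and annotator labels are sampled,
not computed from sequence — so these tests validate the pipeline's
arithmetic and inference, not SnpEff/VEP themselves.

## Numerical and reporting choices

- Problem sizes: the default test/acceptance studies use 1,200–12,000
  sites and 200 replicates, chosen to give binomial/coverage checks
  adequate resolution at interactive runtimes.
- Thresholds are strict inequalities as printed ("> 5 variants",
  "VF > 5%"); the high-frequency gene list defaults to the
  at-least-one-variant reading, with `vf_mode="mean"` for the mean-VF
  reading (both phrasings appear in published work).
- Determinism: one `numpy` Generator seeded from the config; identical
  config + seed gives byte-identical VCF/metadata/truth files, and
  identical pipeline inputs give byte-identical summary JSON (no
  timestamps).
- Degenerate inputs: all-missing sites, empty annotation lists, constant
  DOC, constant correlation inputs, and sub-minimal test groups raise
  explicit errors rather than returning NaN.

## Known limitations

- The severity table is a documented construction, not an annotator
  output; rankings within an impact class can differ from either tool's
  internal ordering.
- VEP's allele-trimming convention for indels is not re-derived; the
  matcher assumes the CSQ `Allele` field matches the VCF alt (true for
  the generator and for SNVs; complex real indels may need upstream
  normalization).
- The count model is Gaussian OLS, not a count GLM, matching the
  published analysis; for small counts a Poisson/negative-binomial model
  would be preferable.
- Catalog matching is exact; unnormalized representations of the same
  indel are near-misses, not matches.
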