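"""Consensus burden classification and per-sample statistics.

Simulates a cohort, round-trips it through the VCF reader, applies the
dual-annotator consensus rule ((HIGH,HIGH), (HIGH,MODERATE) or
(MODERATE,HIGH) = burden; both primary terms loss-of-function = LOF) and
prints the cohort summary a real analysis would report.
"""

import tempfile

import equiburden as eq

sim = eq.simulate_cohort(eq.default_config(seed=2, n_sites=3000))
with tempfile.TemporaryDirectory() as d:
    paths = sim.write(d)
    meta = eq.read_metadata(paths["metadata"])
    cohort = eq.read_cohort_vcf(paths["vcf"], meta)

calls = eq.build_burden_calls(cohort)
freqs = eq.variant_frequencies(cohort)
summary = eq.burden_summary(calls, freqs)

print(f"{summary['n_variants']} variants ({summary['n_snp']} SNPs, {summary['n_indel']} indels)")
print(f"predicted genetic burden: {summary['n_burden']} variants "
      f"({100 * summary['burden_fraction']:.2f}% of all variants), {summary['n_lof']} LOF")
print(f"median VF  burden: {100 * summary['vf_burden']['median']:.2f}%   "
      f"non-burden: {100 * summary['vf_non_burden']['median']:.2f}%")
print("(deleterious variants sit at lower frequencies: purifying selection)")

crosstab = eq.impact_crosstab(calls)
print("\nSnpEff x VEP impact crosstab:")
print(crosstab)
print(f"sum of the three qualifying cells = {eq.burden_total_from_crosstab(crosstab)}")

psb = eq.per_sample_burden(cohort, calls)
med = psb["n_burden"].median()
q1, q3 = psb["n_burden"].quantile([0.25, 0.75])
print(f"\nper-horse burden: median {med:.0f} (IQR {q1:.0f}-{q3:.0f}); "
      f"median homozygous {psb['n_burden_hom'].median():.0f}")

conc = eq.type_concordance(calls)
print(f"annotators agree on variant type for {conc['n_concordant']} of "
      f"{conc['n_burden']} burden variants ({conc['pct_concordant']:.1f}%)")
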