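"""Match a known-variant catalog and audit unexpected genotypes.

Plants catalog-style variants (a lethal recessive, a breed-restricted
disease allele, common coat-colour and gait alleles) at set per-breed
frequencies, matches them back, and flags genotype patterns that
conflict with the reported inheritance.
"""

import tempfile

import equiburden as eq

cfg = eq.default_config(seed=4, n_sites=1500)
sim = eq.simulate_cohort(cfg)
with tempfile.TemporaryDirectory() as d:
    paths = sim.write(d)
    meta = eq.read_metadata(paths["metadata"])
    cohort = eq.read_cohort_vcf(paths["vcf"], meta)

entries = [pe.entry for pe in cfg.planted_entries]
matches = eq.match_catalog(cohort, entries)

print(eq.match_table(matches).to_string(index=False))
print("\nper-category summary (detection % and VF medians over detected):")
print(eq.summarize_categories(matches).to_string(index=False))

rules = {
    pe.entry.entry_id: {
        "lethal_homozygote": pe.lethal_homozygote,
        **({"expected_breeds": list(pe.expected_breeds)} if pe.expected_breeds else {}),
    }
    for pe in cfg.planted_entries
}
report = eq.flag_unexpected_genotypes(matches, rules)
if report.empty:
    print("\nno unexpected genotypes")
else:
    print("\nunexpected genotypes (candidates for manual read review):")
    print(report.to_string(index=False))
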