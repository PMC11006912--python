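"""Published reference tables from a 605-horse, 48-breed WGS cohort.

These are the printed summary tables of the large public equine cohort
this pipeline models; they serve as inputs for consistency arithmetic
(re-deriving the burden total from the impact cross-tabulation, the
type-concordance percentage, the catalog detection bounds) without
needing the sequence data itself.
"""

from __future__ import annotations

import pandas as pd

from .impacts import IMPACT_ORDER

#: SnpEff impact (rows) x Ensembl-VEP impact (columns) overlap counts for
#: the HIGH/MODERATE/LOW classes of the published cohort.  MODIFIER
#: overlaps were not tabulated and are zero-filled here.
PUBLISHED_IMPACT_CROSSTAB: pd.DataFrame = pd.DataFrame(
    {
        "HIGH": {"HIGH": 25_550, "MODERATE": 58, "LOW": 1, "MODIFIER": 0},
        "MODERATE": {"HIGH": 336, "MODERATE": 179_480, "LOW": 764, "MODIFIER": 0},
        "LOW": {"HIGH": 392, "MODERATE": 2_000, "LOW": 358_514, "MODIFIER": 0},
        "MODIFIER": {"HIGH": 0, "MODERATE": 0, "LOW": 0, "MODIFIER": 0},
    },
    dtype=int,
).reindex(index=[i.name for i in IMPACT_ORDER], columns=[i.name for i in IMPACT_ORDER])
PUBLISHED_IMPACT_CROSSTAB.index.name = "snpeff_impact"
PUBLISHED_IMPACT_CROSSTAB.columns.name = "vep_impact"

#: Variant-type agreement rows among published burden variants:
#: (snpeff_term, vep_term) -> count, for pairs where the two annotators
#: reported the same type.
PUBLISHED_TYPE_AGREEMENT: dict[tuple[str, str], int] = {
    ("Frameshift", "Frameshift"): 15_999,
    ("Splice acceptor", "Splice acceptor"): 1_800,
    ("Splice donor", "Splice donor"): 2_066,
    ("Start lost", "Start lost"): 277,
    ("Stop gained", "Stop gained"): 2_685,
    ("Stop lost", "Stop lost"): 171,
    ("Transcript ablation", "Transcript ablation"): 2,
}

#: Published cohort-wide variant counts.
PUBLISHED_COHORT_COUNTS = {
    "n_snp": 28_913_164,
    "n_indel": 3_905_781,
    "n_total": 32_818_945,
    "n_burden_snp": 18_975,
    "n_burden_indel": 6_969,
}

#: Published known-variant catalog summary: category -> (n_catalog, n_detected).
PUBLISHED_CATALOG_COUNTS: dict[str, tuple[int, int]] = {
    "disease_trait_causing": (36, 21),
    "coat_color": (62, 24),
    "disease_associated": (73, 67),
    "trait_associated": (10, 10),
}
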