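"""Consensus deleterious-variant (burden) classification and statistics.

The predicted genetic burden is the set of variants called HIGH impact by
both annotators, or HIGH by one and MODERATE by the other.  Loss-of-function
(LOF) variants are the subset whose primary consequence term from *both*
annotators is in the LOF term set (frameshift, splice acceptor/donor,
start lost, stop lost, stop gained); a LOF call from one annotator alone
does not qualify.

Variant frequency (VF) here is the alternate-allele frequency — alt
alleles over called (non-missing) alleles — not the folded MAF; MAF is
carried separately where needed.  Quantiles use linear interpolation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .impacts import DEFAULT_LOF_TERMS, IMPACT_ORDER, ImpactClass, normalize_term
from .vcf_io import Cohort, GenotypeVector, select_primary_annotation

#: The three qualifying (SnpEff, VEP) impact pairs of the consensus rule.
BURDEN_IMPACT_PAIRS = frozenset(
    {
        (ImpactClass.HIGH, ImpactClass.HIGH),
        (ImpactClass.HIGH, ImpactClass.MODERATE),
        (ImpactClass.MODERATE, ImpactClass.HIGH),
    }
)


def classify_burden(snpeff_impact: ImpactClass, vep_impact: ImpactClass) -> bool:
    """Dual-annotator consensus rule: (H,H), (H,M) or (M,H) qualify."""
    return (snpeff_impact, vep_impact) in BURDEN_IMPACT_PAIRS


def classify_lof(
    snpeff_term: str,
    vep_term: str,
    lof_terms: frozenset[str] | set[str] = DEFAULT_LOF_TERMS,
) -> bool:
    """True iff both primary terms are loss-of-function (they need not match)."""
    return normalize_term(snpeff_term) in lof_terms and normalize_term(vep_term) in lof_terms


def build_burden_calls(
    cohort: Cohort,
    severity_table: Mapping[str, int] | None = None,
    lof_terms: frozenset[str] = DEFAULT_LOF_TERMS,
) -> pd.DataFrame:
    """Per-variant consensus verdicts for a dual-annotated cohort.

    Returns one row per record (cohort order) with both primary
    term/impact, the burden and LOF flags and the type-concordance flag.
    Records lacking annotations from either annotator are an error: the
    consensus rule is undefined without both.
    """
    rows = []
    n_missing = 0
    for r in cohort.records:
        if not r.snpeff_annotations or not r.vep_annotations:
            n_missing += 1
            continue
        se = select_primary_annotation(r.snpeff_annotations, severity_table)
        ve = select_primary_annotation(r.vep_annotations, severity_table)
        is_burden = classify_burden(se.impact, ve.impact)
        rows.append(
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "variant_class": r.variant_class,
                "snpeff_term": se.term,
                "snpeff_impact": se.impact.name,
                "vep_term": ve.term,
                "vep_impact": ve.impact.name,
                "gene_id": se.gene_id or ve.gene_id,
                "hgnc_symbol": se.hgnc_symbol or ve.hgnc_symbol,
                "is_burden": is_burden,
                "is_lof": is_burden and classify_lof(se.term, ve.term, lof_terms),
                "type_concordant": normalize_term(se.term) == normalize_term(ve.term),
            }
        )
    if n_missing:
        raise ValueError(
            f"{n_missing} records lack annotations from one annotator; "
            "the consensus rule requires both ANN and CSQ"
        )
    return pd.DataFrame(rows)


def impact_crosstab(calls: pd.DataFrame) -> pd.DataFrame:
    """4x4 SnpEff-impact x VEP-impact count table (HIGH..MODIFIER order)."""
    labels = [i.name for i in IMPACT_ORDER]
    table = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    if len(calls):
        counts = calls.groupby(["snpeff_impact", "vep_impact"]).size()
        for (se, ve), n in counts.items():
            table.loc[se, ve] = int(n)
    table.index.name = "snpeff_impact"
    table.columns.name = "vep_impact"
    return table


def burden_total_from_crosstab(table: pd.DataFrame) -> int:
    """Sum of the crosstab cells that satisfy the consensus rule."""
    total = 0
    for se in table.index:
        for ve in table.columns:
            if classify_burden(ImpactClass.from_string(se), ImpactClass.from_string(ve)):
                total += int(table.loc[se, ve])
    return total


@dataclasses.dataclass(frozen=True)
class VariantFrequency:
    alt_count: int
    called_alleles: int

    @property
    def vf(self) -> float:
        return self.alt_count / self.called_alleles

    @property
    def maf(self) -> float:
        return min(self.vf, 1.0 - self.vf)


def site_allele_frequency(genotypes: GenotypeVector | np.ndarray) -> VariantFrequency:
    """Alt-allele frequency of one site from genotype codes.

    Missing genotypes shrink the denominator; a site with no called
    genotype has no defined frequency and raises.
    """
    codes = genotypes.codes if isinstance(genotypes, GenotypeVector) else np.asarray(genotypes)
    called = codes >= 0
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError("all genotypes missing: allele frequency undefined")
    alt = int(codes[called].sum())
    return VariantFrequency(alt_count=alt, called_alleles=2 * n_called)


def variant_frequencies(cohort: Cohort) -> pd.DataFrame:
    """Per-variant VF/MAF table aligned with the cohort's record order."""
    m = cohort.genotype_matrix()
    called = m >= 0
    n_called = called.sum(axis=1)
    if (n_called == 0).any():
        bad = int((n_called == 0).sum())
        raise ValueError(f"{bad} sites have no called genotypes")
    alt = np.where(called, m, 0).sum(axis=1)
    vf = alt / (2 * n_called)
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in cohort.records],
            "pos": [r.pos for r in cohort.records],
            "ref": [r.ref for r in cohort.records],
            "alt_allele": [r.alt for r in cohort.records],
            "alt_count": alt.astype(int),
            "called_alleles": (2 * n_called).astype(int),
            "vf": vf,
            "maf": np.minimum(vf, 1 - vf),
        }
    )
    return df


def per_sample_burden(cohort: Cohort, calls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample burden statistics.

    Counts, for every sample: sites carrying >=1 alt allele, private sites
    (sole alt carrier in the cohort), burden sites carried / homozygous,
    and LOF sites carried / homozygous.  ``calls`` must cover every cohort
    record, in cohort order.
    """
    if len(calls) != len(cohort.records):
        raise ValueError("burden calls must cover every cohort record")
    m = cohort.genotype_matrix()
    carrier = m >= 1
    hom = m == 2
    is_burden = calls["is_burden"].to_numpy()
    is_lof = calls["is_lof"].to_numpy()
    private_site = carrier.sum(axis=1) == 1
    return pd.DataFrame(
        {
            "sample_id": list(cohort.samples),
            "n_variants": carrier.sum(axis=0).astype(int),
            "n_private": (carrier & private_site[:, None]).sum(axis=0).astype(int),
            "n_burden": carrier[is_burden].sum(axis=0).astype(int),
            "n_burden_hom": hom[is_burden].sum(axis=0).astype(int),
            "n_lof": carrier[is_lof].sum(axis=0).astype(int),
            "n_lof_hom": hom[is_lof].sum(axis=0).astype(int),
        }
    )


def _median_iqr(x: np.ndarray) -> dict:
    if len(x) == 0:
        return {"median": None, "q1": None, "q3": None}
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def burden_summary(calls: pd.DataFrame, frequencies: pd.DataFrame) -> dict:
    """Cohort-level burden summary (totals, SNP/indel split, VF medians)."""
    if len(calls) != len(frequencies):
        raise ValueError("calls and frequencies must be keyed identically")
    is_burden = calls["is_burden"].to_numpy()
    is_lof = calls["is_lof"].to_numpy()
    is_snp = (calls["variant_class"] == "SNP").to_numpy()
    vf = frequencies["vf"].to_numpy()
    n_total = len(calls)
    n_burden = int(is_burden.sum())
    return {
        "n_variants": n_total,
        "n_snp": int(is_snp.sum()),
        "n_indel": int((~is_snp).sum()),
        "n_burden": n_burden,
        "n_burden_snp": int((is_burden & is_snp).sum()),
        "n_burden_indel": int((is_burden & ~is_snp).sum()),
        "n_lof": int(is_lof.sum()),
        "burden_fraction": (n_burden / n_total) if n_total else None,
        "vf_burden": _median_iqr(vf[is_burden]),
        "vf_non_burden": _median_iqr(vf[~is_burden]),
    }


def type_concordance(calls: pd.DataFrame) -> dict:
    """Annotator agreement on variant type among burden variants.

    Returns the concordant/discordant counts, the agreement percentage and
    a per-(snpeff_term, vep_term) breakdown table.
    """
    b = calls[calls["is_burden"]]
    pairs = (
        b.groupby(["snpeff_term", "vep_term"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values("count", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    concordant = int(b["type_concordant"].sum())
    n = len(b)
    return {
        "n_burden": n,
        "n_concordant": concordant,
        "n_discordant": n - concordant,
        "pct_concordant": (100.0 * concordant / n) if n else None,
        "pairs": pairs,
    }


def aggregate_by_gene(
    calls: pd.DataFrame, frequencies: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Aggregate burden variants per Ensembl gene id.

    Each burden variant contributes once, to the gene of its primary
    annotation.  Variants without a gene id are returned as the
    ``unassigned`` count.  Returns (per-gene table, n_unassigned).
    """
    if len(calls) != len(frequencies):
        raise ValueError("calls and frequencies must be keyed identically")
    df = calls.copy()
    df["vf"] = frequencies["vf"].to_numpy()
    b = df[df["is_burden"]]
    unassigned = int(b["gene_id"].isna().sum())
    b = b.dropna(subset=["gene_id"])
    if b.empty:
        cols = ["gene_id", "hgnc_symbol", "n_burden_variants", "n_lof_variants",
                "median_vf", "mean_vf", "max_vf"]
        return pd.DataFrame(columns=cols), unassigned
    agg = (
        b.groupby("gene_id")
        .agg(
            hgnc_symbol=("hgnc_symbol", "first"),
            n_burden_variants=("is_burden", "size"),
            n_lof_variants=("is_lof", "sum"),
            median_vf=("vf", "median"),
            mean_vf=("vf", "mean"),
            max_vf=("vf", "max"),
        )
        .reset_index()
    )
    agg["n_lof_variants"] = agg["n_lof_variants"].astype(int)
    return agg, unassigned


def select_gene_sets(
    aggregates: pd.DataFrame,
    min_variants: int = 5,
    vf_threshold: float = 0.05,
    vf_mode: str = "any",
) -> tuple[list[str], list[str]]:
    """Pick the two downstream gene lists.

    List A: genes with strictly more than ``min_variants`` burden
    variants.  List B: genes exceeding ``vf_threshold`` — by their most
    frequent burden variant (``vf_mode="any"``, default) or by the mean VF
    of their burden variants (``vf_mode="mean"``).
    """
    if min_variants <= 0 or vf_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if vf_mode not in ("any", "mean"):
        raise ValueError(f"vf_mode must be 'any' or 'mean', got {vf_mode!r}")
    if aggregates.empty:
        return [], []
    multi = aggregates.loc[aggregates["n_burden_variants"] > min_variants, "gene_id"]
    col = "max_vf" if vf_mode == "any" else "mean_vf"
    high = aggregates.loc[aggregates[col] > vf_threshold, "gene_id"]
    return sorted(multi), sorted(high)
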