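"""Shared fixtures: hand-written VCF snippets and small simulated cohorts."""

from __future__ import annotations

import textwrap

import pandas as pd
import pytest

import equiburden as eq

ANN_HEADER = (
    '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
    "'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | Feature_Type "
    "| Feature_ID'\">"
)
CSQ_HEADER = (
    '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations from '
    'Ensembl VEP. Format: Allele|Consequence|IMPACT|SYMBOL|Gene|Feature">'
)

#: 7-field ANN layout matching ANN_HEADER above.
ANN_FIELDS = (
    "Allele", "Annotation", "Annotation_Impact", "Gene_Name", "Gene_ID",
    "Feature_Type", "Feature_ID",
)


def write_vcf(path, body: str, samples=("S1", "S2"), extra_headers=()):
    """Write a small VCF with the standard dual-annotation headers."""
    lines = ["##fileformat=VCFv4.2", ANN_HEADER, CSQ_HEADER,
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "##contig=<ID=1>", "##contig=<ID=2>", *extra_headers,
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)]
    text = "\n".join(lines) + "\n" + textwrap.dedent(body).strip() + "\n"
    path.write_text(text)
    return path


def ann(alt, term, impact, symbol="GENE1", gene="ENSECAG00000000001", tx="T1"):
    return f"{alt}|{term}|{impact}|{symbol}|{gene}|transcript|{tx}"


def csq(alt, term, impact, symbol="GENE1", gene="ENSECAG00000000001", tx="T1"):
    return f"{alt}|{term}|{impact}|{symbol}|{gene}|{tx}"


def metadata_for(samples, breed="Thoroughbred", doc=12.0):
    return pd.DataFrame(
        {"breed": breed, "doc": doc}, index=pd.Index(list(samples), name="sample")
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small no-dropout simulated cohort used across modules."""
    cfg = eq.default_config(seed=11, dropout=False, n_sites=1200)
    return eq.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_sim_files(small_sim, tmp_path_factory):
    d = tmp_path_factory.mktemp("sim")
    return small_sim.write(d)


@pytest.fixture(scope="session")
def small_cohort(small_sim_files):
    meta = eq.read_metadata(small_sim_files["metadata"])
    return eq.read_cohort_vcf(small_sim_files["vcf"], meta)
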