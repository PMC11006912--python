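"""Reading and writing multi-sample VCFs carrying dual annotations.

A cohort VCF for this pipeline must declare two INFO fields: ``ANN``
(SnpEff-style, positional pipe-delimited blocks) and ``CSQ`` (VEP-style,
with the column layout given by the ``Format:`` clause of its header
Description).  Multi-allelic sites are decomposed to one record per
alternate allele so the downstream consensus rule is per-allele
well-defined; indels longer than 20 bp are excluded (with a count kept)
to match the variant-calling window of the cohorts this models.

Genotypes are encoded per sample as ``0`` hom-ref, ``1`` het, ``2``
hom-alt, ``-1`` missing; half-calls (``./1``) are treated as missing.
Coordinates are 1-based VCF positions throughout.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .impacts import ImpactClass, severity_rank

MAX_INDEL_LEN = 20

#: Default SnpEff ANN sub-field layout (used when the header Description
#: does not spell one out).
DEFAULT_ANN_FIELDS: tuple[str, ...] = (
    "Allele",
    "Annotation",
    "Annotation_Impact",
    "Gene_Name",
    "Gene_ID",
    "Feature_Type",
    "Feature_ID",
    "Transcript_BioType",
    "Rank",
    "HGVS.c",
    "HGVS.p",
    "cDNA.pos / cDNA.length",
    "CDS.pos / CDS.length",
    "AA.pos / AA.length",
    "Distance",
    "ERRORS / WARNINGS / INFO",
)

DEFAULT_CSQ_FORMAT = "Allele|Consequence|IMPACT|SYMBOL|Gene|Feature"


class VcfFormatError(ValueError):
    """The VCF (or a companion table) violates the expected format."""


class AnnotationParseError(ValueError):
    """A single ANN/CSQ block could not be parsed; carries its index."""

    def __init__(self, message: str, block_index: int):
        super().__init__(message)
        self.block_index = block_index


@dataclasses.dataclass(frozen=True)
class ConsequenceAnnotation:
    """One annotator's consequence for one alt allele of one variant."""

    annotator: str  # "snpeff" | "vep"
    allele: str
    terms: tuple[str, ...]  # ampersand-joined compounds kept in order
    impact: ImpactClass
    gene_id: str | None = None
    hgnc_symbol: str | None = None
    transcript_id: str | None = None
    rank_in_field: int = 0

    @property
    def term(self) -> str:
        """Primary term: first of the (ordered) compound list."""
        return self.terms[0]

    def __post_init__(self):
        if not self.terms or not self.terms[0]:
            raise ValueError("annotation must carry a nonempty consequence term")
        if self.rank_in_field < 0:
            raise ValueError("rank_in_field must be >= 0")


@dataclasses.dataclass(eq=False)
class GenotypeVector:
    """Per-sample genotype codes for one (decomposed) alt allele."""

    codes: np.ndarray  # int8: 0 hom_ref, 1 het, 2 hom_alt, -1 missing
    sample_order: tuple[str, ...]

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if len(self.codes) != len(self.sample_order):
            raise ValueError("genotype codes and sample order differ in length")

    def __eq__(self, other):
        return (
            isinstance(other, GenotypeVector)
            and self.sample_order == other.sample_order
            and np.array_equal(self.codes, other.codes)
        )


@dataclasses.dataclass(eq=False)
class VariantRecord:
    """A biallelic (post-decomposition) variant with both annotators' calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    snpeff_annotations: tuple[ConsequenceAnnotation, ...]
    vep_annotations: tuple[ConsequenceAnnotation, ...]
    genotypes: GenotypeVector

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def indel_len(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def variant_class(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __eq__(self, other):
        return (
            isinstance(other, VariantRecord)
            and self.key == other.key
            and self.snpeff_annotations == other.snpeff_annotations
            and self.vep_annotations == other.vep_annotations
            and self.genotypes == other.genotypes
        )


@dataclasses.dataclass
class Cohort:
    """Decomposed variant records plus per-sample metadata, in VCF sample order."""

    records: list[VariantRecord]
    metadata: pd.DataFrame  # indexed by sample id, columns breed & doc
    samples: tuple[str, ...]
    n_excluded_long_indels: int = 0
    n_dropped_allele_mismatch: int = 0

    def genotype_matrix(self) -> np.ndarray:
        """(n_records, n_samples) int8 matrix of genotype codes."""
        if not self.records:
            return np.empty((0, len(self.samples)), dtype=np.int8)
        return np.vstack([r.genotypes.codes for r in self.records])

    def keys(self) -> list[tuple[str, int, str, str]]:
        return [r.key for r in self.records]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (columns ``sample``, ``breed``, ``doc``)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "breed": str})
    required = {"sample", "breed", "doc"}
    missing = required - set(df.columns)
    if missing:
        raise VcfFormatError(f"metadata is missing columns: {sorted(missing)}")
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise VcfFormatError(f"duplicate sample ids in metadata: {dupes}")
    if (df["doc"] <= 0).any() or df["doc"].isna().any():
        raise VcfFormatError("every sample must have depth of coverage > 0")
    if df["breed"].isna().any() or (df["breed"].str.len() == 0).any():
        raise VcfFormatError("every sample must have a nonempty breed label")
    return df.set_index("sample")


def _none_if_blank(s: str) -> str | None:
    return s if s else None


def parse_snpeff_ann(
    info_text: str,
    field_names: Sequence[str] = DEFAULT_ANN_FIELDS,
) -> list[ConsequenceAnnotation]:
    """Parse a SnpEff ``ANN=`` INFO value into annotations.

    ``field_names`` gives the positional sub-field layout (taken from the
    VCF header when available).  Every comma-separated block must have
    exactly that many pipe-separated fields.
    """
    names = [n.strip() for n in field_names]
    idx = {n: i for i, n in enumerate(names)}
    for required in ("Allele", "Annotation", "Annotation_Impact"):
        if required not in idx:
            raise VcfFormatError(f"ANN field layout lacks required column {required!r}")
    out: list[ConsequenceAnnotation] = []
    for i, block in enumerate(info_text.split(",")):
        parts = block.split("|")
        if len(parts) != len(names):
            raise AnnotationParseError(
                f"ANN block {i} has {len(parts)} fields, expected {len(names)}",
                block_index=i,
            )
        terms = tuple(t for t in parts[idx["Annotation"]].split("&"))
        out.append(
            ConsequenceAnnotation(
                annotator="snpeff",
                allele=parts[idx["Allele"]],
                terms=terms,
                impact=ImpactClass.from_string(parts[idx["Annotation_Impact"]]),
                hgnc_symbol=_none_if_blank(parts[idx["Gene_Name"]]) if "Gene_Name" in idx else None,
                gene_id=_none_if_blank(parts[idx["Gene_ID"]]) if "Gene_ID" in idx else None,
                transcript_id=_none_if_blank(parts[idx["Feature_ID"]]) if "Feature_ID" in idx else None,
                rank_in_field=i,
            )
        )
    return out


def parse_vep_csq(info_text: str, format_descriptor: str) -> list[ConsequenceAnnotation]:
    """Parse a VEP ``CSQ=`` INFO value; columns are located by name.

    ``format_descriptor`` is the pipe-separated column list from the header
    ``Format:`` clause and must include ``Consequence`` and ``IMPACT``.
    """
    cols = [c.strip() for c in format_descriptor.split("|")]
    idx = {c: i for i, c in enumerate(cols)}
    for required in ("Consequence", "IMPACT"):
        if required not in idx:
            raise VcfFormatError(
                f"CSQ Format descriptor lacks required column {required!r}: {format_descriptor}"
            )
    out: list[ConsequenceAnnotation] = []
    for i, block in enumerate(info_text.split(",")):
        parts = block.split("|")
        if len(parts) != len(cols):
            raise AnnotationParseError(
                f"CSQ block {i} has {len(parts)} columns, expected {len(cols)}",
                block_index=i,
            )
        terms = tuple(parts[idx["Consequence"]].split("&"))
        out.append(
            ConsequenceAnnotation(
                annotator="vep",
                allele=parts[idx["Allele"]] if "Allele" in idx else "",
                terms=terms,
                impact=ImpactClass.from_string(parts[idx["IMPACT"]]),
                hgnc_symbol=_none_if_blank(parts[idx["SYMBOL"]]) if "SYMBOL" in idx else None,
                gene_id=_none_if_blank(parts[idx["Gene"]]) if "Gene" in idx else None,
                transcript_id=_none_if_blank(parts[idx["Feature"]]) if "Feature" in idx else None,
                rank_in_field=i,
            )
        )
    return out


def select_primary_annotation(
    annotations: Sequence[ConsequenceAnnotation],
    severity_table: Mapping[str, int] | None = None,
) -> ConsequenceAnnotation:
    """Reduce transcript-level annotations to one primary annotation.

    The most severe impact class wins; ties are broken by the consequence
    term's severity rank, then by position in the source field (first
    listed wins).
    """
    if not annotations:
        raise ValueError("cannot select a primary annotation from an empty list")
    return min(
        annotations,
        key=lambda a: (-int(a.impact), severity_rank(a.term, severity_table), a.rank_in_field),
    )


def _ann_layout_from_header(description: str) -> tuple[str, ...]:
    """Extract the ANN sub-field layout from a header Description string."""
    m = re.search(r"'([^']+)'", description)
    if m and "|" in m.group(1):
        return tuple(f.strip() for f in m.group(1).split("|"))
    return DEFAULT_ANN_FIELDS


def _csq_format_from_header(description: str) -> str:
    m = re.search(r"Format:\s*([^\"']+)", description)
    if not m:
        raise VcfFormatError(f"CSQ header Description lacks a Format clause: {description}")
    return m.group(1).strip().strip('"')


def read_cohort_vcf(
    path: str | Path,
    metadata: pd.DataFrame,
    max_indel_len: int = MAX_INDEL_LEN,
    chrom_aliases: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a dual-annotated multi-sample VCF into a decomposed cohort.

    Every VCF sample must appear in ``metadata`` (indexed by sample id).
    Multi-allelic sites yield one record per alt allele with per-allele
    genotype codes; annotations are attached to the record whose alt
    matches their allele field, and annotations matching no alt are
    dropped (counted).  Records whose indel length exceeds
    ``max_indel_len`` are excluded (counted).
    """
    vcf = VCF(str(path))
    try:
        try:
            ann_header = vcf.get_header_type("ANN")
        except KeyError:
            raise VcfFormatError("VCF header lacks the required INFO field 'ANN'") from None
        try:
            csq_header = vcf.get_header_type("CSQ")
        except KeyError:
            raise VcfFormatError("VCF header lacks the required INFO field 'CSQ'") from None

        ann_fields = _ann_layout_from_header(ann_header.get("Description", ""))
        csq_format = _csq_format_from_header(csq_header.get("Description", ""))

        samples = tuple(vcf.samples)
        absent = [s for s in samples if s not in metadata.index]
        if absent:
            raise VcfFormatError(f"VCF samples absent from metadata: {absent}")
        meta = metadata.loc[list(samples)]
        aliases = dict(chrom_aliases or {})

        records: list[VariantRecord] = []
        n_long = 0
        n_mismatch = 0
        for v in vcf:
            gts = np.asarray(v.genotypes, dtype=np.int64)  # (n, ploidy+1)
            alleles = gts[:, :2]
            any_missing = (alleles < 0).any(axis=1)
            ann_raw = v.INFO.get("ANN")
            csq_raw = v.INFO.get("CSQ")
            snpeff_all = parse_snpeff_ann(ann_raw, ann_fields) if ann_raw else []
            vep_all = parse_vep_csq(csq_raw, csq_format) if csq_raw else []
            alt_set = set(v.ALT)
            for a in snpeff_all + vep_all:
                if a.allele and a.allele not in alt_set:
                    n_mismatch += 1
            chrom = aliases.get(v.CHROM, v.CHROM)
            for k, alt in enumerate(v.ALT):
                indel_len = abs(len(v.REF) - len(alt))
                if indel_len > max_indel_len:
                    n_long += 1
                    continue
                count = (alleles == k + 1).sum(axis=1)
                codes = np.where(any_missing, -1, count).astype(np.int8)
                records.append(
                    VariantRecord(
                        chrom=chrom,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        snpeff_annotations=tuple(
                            a for a in snpeff_all if (not a.allele) or a.allele == alt
                        ),
                        vep_annotations=tuple(
                            a for a in vep_all if (not a.allele) or a.allele == alt
                        ),
                        genotypes=GenotypeVector(codes=codes, sample_order=samples),
                    )
                )
        return Cohort(
            records=records,
            metadata=meta,
            samples=samples,
            n_excluded_long_indels=n_long,
            n_dropped_allele_mismatch=n_mismatch,
        )
    finally:
        vcf.close()


_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def _ann_block(a: ConsequenceAnnotation) -> str:
    fields = [""] * len(DEFAULT_ANN_FIELDS)
    fields[0] = a.allele
    fields[1] = "&".join(a.terms)
    fields[2] = a.impact.name
    fields[3] = a.hgnc_symbol or ""
    fields[4] = a.gene_id or ""
    fields[5] = "transcript" if a.transcript_id else ""
    fields[6] = a.transcript_id or ""
    return "|".join(fields)


def _csq_block(a: ConsequenceAnnotation) -> str:
    return "|".join(
        [
            a.allele,
            "&".join(a.terms),
            a.impact.name,
            a.hgnc_symbol or "",
            a.gene_id or "",
            a.transcript_id or "",
        ]
    )


def vcf_header_lines(samples: Iterable[str], contigs: Iterable[str]) -> list[str]:
    """Header lines for a dual-annotated VCF v4.2."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
        "'" + " | ".join(DEFAULT_ANN_FIELDS) + "'\">",
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations '
        f'from Ensembl VEP. Format: {DEFAULT_CSQ_FORMAT}">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    return lines


def write_cohort_vcf(cohort: Cohort, path: str | Path) -> None:
    """Write a decomposed cohort back out as a biallelic VCF v4.2.

    Round-trips: re-reading the written file with :func:`read_cohort_vcf`
    reproduces the cohort's records field-for-field.
    """
    contigs = list(dict.fromkeys(r.chrom for r in cohort.records))
    with open(path, "w") as fh:
        for line in vcf_header_lines(cohort.samples, contigs):
            fh.write(line + "\n")
        for r in cohort.records:
            info_parts = []
            if r.snpeff_annotations:
                info_parts.append("ANN=" + ",".join(_ann_block(a) for a in r.snpeff_annotations))
            if r.vep_annotations:
                info_parts.append("CSQ=" + ",".join(_csq_block(a) for a in r.vep_annotations))
            info = ";".join(info_parts) or "."
            gts = "\t".join(_GT_STRINGS[int(c)] for c in r.genotypes.codes)
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t{info}\tGT\t{gts}\n"
            )


def primary_annotation_table(
    cohort: Cohort, severity_table: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Per-variant table of both annotators' primary term/impact."""
    rows = []
    for r in cohort.records:
        se = select_primary_annotation(r.snpeff_annotations, severity_table) if r.snpeff_annotations else None
        ve = select_primary_annotation(r.vep_annotations, severity_table) if r.vep_annotations else None
        rows.append(
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "snpeff_term": se.term if se else None,
                "snpeff_impact": se.impact.name if se else None,
                "vep_term": ve.term if ve else None,
                "vep_impact": ve.impact.name if ve else None,
                "gene_id": (se.gene_id if se and se.gene_id else (ve.gene_id if ve else None)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt",
            "snpeff_term", "snpeff_impact", "vep_term", "vep_impact", "gene_id",
        ],
    )
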