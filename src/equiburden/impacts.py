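"""Shared consequence/impact vocabulary for the two variant-effect annotators.

Variant-effect predictors (SnpEff, Ensembl-VEP) attach to each variant a
functional consequence term (Sequence Ontology style, e.g. ``stop_gained``)
and a four-level impact class.  The two tools spell several terms
differently ("Splice acceptor" vs ``splice_acceptor_variant``), so all
term-level logic in this package goes through :func:`normalize_term` first.

The severity ranking of terms within an impact class is not standardised
anywhere; :data:`DEFAULT_SEVERITY_RANK` is this package's explicit,
overridable construction (Ensembl's published consequence ordering, with a
few SnpEff-only terms slotted next to their nearest Ensembl equivalent).
"""

from __future__ import annotations

import enum
from typing import Mapping


class ImpactClass(enum.IntEnum):
    """Annotator impact class; larger value = more severe."""

    MODIFIER = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3

    @classmethod
    def from_string(cls, label: str) -> "ImpactClass":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown impact class: {label!r}") from None


IMPACT_ORDER = (ImpactClass.HIGH, ImpactClass.MODERATE, ImpactClass.LOW, ImpactClass.MODIFIER)

# Dialect synonyms -> canonical Sequence Ontology spelling (post snake-casing).
_TERM_SYNONYMS: dict[str, str] = {
    "frameshift": "frameshift_variant",
    "splice_acceptor": "splice_acceptor_variant",
    "splice_donor": "splice_donor_variant",
    "splice_region": "splice_region_variant",
    "stop_gain": "stop_gained",
    "missense": "missense_variant",
    "synonymous": "synonymous_variant",
    "inframe_deletion": "inframe_deletion",
    "inframe_insertion": "inframe_insertion",
    "disruptive_inframe_deletion": "inframe_deletion",
    "disruptive_inframe_insertion": "inframe_insertion",
    "exon_loss": "exon_loss_variant",
    "gene_fusion": "gene_fusion",
    "protein_altering": "protein_altering_variant",
    "initiator_codon_variant": "start_lost",
    "start_loss": "start_lost",
    "stop_loss": "stop_lost",
    "transcript_ablation": "transcript_ablation",
    "5_prime_utr": "5_prime_UTR_variant",
    "3_prime_utr": "3_prime_UTR_variant",
}


def normalize_term(term: str) -> str:
    """Map an annotator's consequence spelling to a canonical term.

    Lower-cases, converts spaces/hyphens to underscores, then applies the
    dialect synonym table (e.g. ``"Splice acceptor"`` and
    ``"splice_acceptor_variant"`` both normalise to
    ``splice_acceptor_variant``).
    """
    t = term.strip().lower().replace(" ", "_").replace("-", "_")
    t = _TERM_SYNONYMS.get(t, t)
    # keep UTR capitalisation canonical but compare case-insensitively
    return t


#: Consequence terms counted as loss of function (after normalisation):
#: frameshift, splice acceptor/donor, start lost, stop lost, stop gained.
DEFAULT_LOF_TERMS: frozenset[str] = frozenset(
    {
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "start_lost",
        "stop_lost",
        "stop_gained",
    }
)

# Ordered most-severe-first; ties between annotators are broken by this rank.
_SEVERITY_ORDER: tuple[str, ...] = (
    "transcript_ablation",
    "exon_loss_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "gene_fusion",
    "transcript_amplification",
    "feature_elongation",
    "feature_truncation",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_donor_5th_base_variant",
    "splice_region_variant",
    "splice_donor_region_variant",
    "splice_polypyrimidine_tract_variant",
    "incomplete_terminal_codon_variant",
    "start_retained_variant",
    "stop_retained_variant",
    "synonymous_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "NMD_transcript_variant",
    "non_coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "TFBS_ablation",
    "TFBS_amplification",
    "TF_binding_site_variant",
    "regulatory_region_ablation",
    "regulatory_region_amplification",
    "regulatory_region_variant",
    "intergenic_variant",
    "sequence_variant",
)

#: term -> rank (0 = most severe).  Unknown terms rank after all known ones.
DEFAULT_SEVERITY_RANK: dict[str, int] = {
    t.lower(): i for i, t in enumerate(_SEVERITY_ORDER)
}


def severity_rank(term: str, table: Mapping[str, int] | None = None) -> int:
    """Rank of a (raw or normalised) term; unknown terms sort last."""
    table = DEFAULT_SEVERITY_RANK if table is None else table
    return table.get(normalize_term(term).lower(), len(DEFAULT_SEVERITY_RANK))
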