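"""Synthetic multi-breed cohort generator with known truth.

Emulates the statistical structure of a large multi-breed WGS cohort:

* diploid Hardy-Weinberg genotypes per site from per-breed allele
  frequencies;
* a rare-skewed site frequency spectrum for deleterious (burden) sites
  relative to neutral sites, as purifying selection produces;
* planted additive breed effects, as multiplicative shifts of the
  per-breed deleterious allele-frequency distribution;
* depth-of-coverage-dependent genotype dropout (low-DOC samples yield
  fewer observed variants, missing genotypes shrink frequency
  denominators);
* dual-annotator ANN/CSQ labels with controlled impact consensus and
  type agreement;
* planted catalog entries at specified per-breed frequencies.

The generator records a :class:`TruthSet` alongside every cohort: true
site classes and frequencies, exact pre-dropout per-sample carriage
counts, and expected per-breed means, so pipeline outputs can be scored
without external data.  Identical config + seed gives byte-identical
output files.

It does not model linkage disequilibrium, pedigree structure, or
sequencing reads.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import CatalogEntry
from .vcf_io import vcf_header_lines

LOF_TERMS_DIST: tuple[tuple[str, float], ...] = (
    ("frameshift_variant", 0.60),
    ("stop_gained", 0.15),
    ("splice_donor_variant", 0.09),
    ("splice_acceptor_variant", 0.08),
    ("start_lost", 0.04),
    ("stop_lost", 0.04),
)

# Term pairs for burden sites that are NOT loss-of-function by the
# both-annotators rule (at most one side in the LOF set).
_NONLOF_TERM_PAIRS: dict[tuple[str, str], tuple[tuple[str, str], ...]] = {
    ("HIGH", "HIGH"): (
        ("transcript_ablation", "transcript_ablation"),
        ("exon_loss_variant", "frameshift_variant"),
        ("gene_fusion", "splice_donor_variant"),
    ),
    ("HIGH", "MODERATE"): (
        ("frameshift_variant", "inframe_deletion"),
        ("stop_gained", "missense_variant"),
        ("splice_donor_variant", "protein_altering_variant"),
    ),
    ("MODERATE", "HIGH"): (
        ("missense_variant", "splice_acceptor_variant"),
        ("inframe_deletion", "frameshift_variant"),
    ),
}

_NEUTRAL_TERM_BY_IMPACT = {
    "HIGH": "exon_loss_variant",
    "MODERATE": "missense_variant",
    "LOW": "synonymous_variant",
    "MODIFIER": "intergenic_variant",
}


@dataclasses.dataclass(frozen=True)
class BreedSpec:
    name: str
    n_samples: int
    doc_mean: float
    doc_sd: float
    burden_scale: float = 1.0  # multiplies deleterious allele frequencies


@dataclasses.dataclass(frozen=True)
class DropoutModel:
    """Per-genotype missingness decreasing linearly with sample DOC.

    rate(doc) = max(0, intercept - slope_per_x * doc); with DOC clipped to
    [1, 22] and the defaults below the rate stays on the linear branch, so
    expected detected counts are exactly linear in DOC.
    """

    intercept: float = 0.18
    slope_per_x: float = 0.008

    def rate(self, doc: np.ndarray | float) -> np.ndarray:
        return np.maximum(0.0, self.intercept - self.slope_per_x * np.asarray(doc, float))


@dataclasses.dataclass(frozen=True)
class AnnotatorModel:
    """Joint distribution of the two annotators' labels at simulated sites."""

    burden_impact_probs: tuple[tuple[tuple[str, str], float], ...] = (
        (("HIGH", "HIGH"), 0.9848),
        (("HIGH", "MODERATE"), 0.0130),
        (("MODERATE", "HIGH"), 0.0022),
    )
    nonburden_impact_probs: tuple[tuple[tuple[str, str], float], ...] = (
        (("MODERATE", "MODERATE"), 0.060),
        (("LOW", "LOW"), 0.120),
        (("MODIFIER", "MODIFIER"), 0.750),
        (("MODERATE", "LOW"), 0.010),
        (("LOW", "MODERATE"), 0.005),
        (("LOW", "MODIFIER"), 0.030),
        (("MODIFIER", "LOW"), 0.025),
    )
    type_agreement: float = 0.887  # P(same primary term | LOF site)
    lof_fraction: float = 0.73  # P(both-annotator LOF | burden site)

    def validate(self) -> None:
        for name, probs in (
            ("burden_impact_probs", self.burden_impact_probs),
            ("nonburden_impact_probs", self.nonburden_impact_probs),
        ):
            p = np.array([w for _, w in probs])
            if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be probabilities summing to 1 (got sum {p.sum()})")
        for val, name in ((self.type_agreement, "type_agreement"), (self.lof_fraction, "lof_fraction")):
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class PlantedEntry:
    """A catalog variant planted at specified per-breed allele frequencies."""

    entry: CatalogEntry
    breed_freqs: Mapping[str, float]
    lethal_homozygote: bool = False
    expected_breeds: tuple[str, ...] | None = None


@dataclasses.dataclass
class SimulationConfig:
    breeds: list[BreedSpec]
    n_sites: int = 12_000
    burden_site_fraction: float = 0.4
    deleterious_sfs: tuple[float, float] = (0.3, 2.5)  # Beta(a, b)
    neutral_sfs: tuple[float, float] = (0.6, 1.4)
    annotator_model: AnnotatorModel = dataclasses.field(default_factory=AnnotatorModel)
    dropout: DropoutModel = dataclasses.field(default_factory=DropoutModel)
    planted_entries: list[PlantedEntry] = dataclasses.field(default_factory=list)
    n_genes: int = 800
    seed: int = 0

    def validate(self) -> None:
        if not self.breeds:
            raise ValueError("at least one breed is required")
        for b in self.breeds:
            if b.n_samples < 1:
                raise ValueError(f"breed {b.name}: n_samples must be >= 1")
            if b.doc_mean <= 0:
                raise ValueError(f"breed {b.name}: doc_mean must be > 0")
        if not 0 <= self.burden_site_fraction <= 1:
            raise ValueError("burden_site_fraction must be in [0, 1]")
        self.annotator_model.validate()
        for pe in self.planted_entries:
            for breed, f in pe.breed_freqs.items():
                if not 0 <= f <= 1:
                    raise ValueError(
                        f"planted entry {pe.entry.entry_id}: frequency for {breed} outside [0, 1]"
                    )


# Default breeds mirror a 12-target-breed + Other design: modest per-breed
# sample sizes, DOC means spanning ~5.5-17.5X, and burden scales ordered as
# published breed burden differences (lowest Thoroughbred, highest Icelandic).
DEFAULT_BREEDS: tuple[BreedSpec, ...] = (
    BreedSpec("Arabian", 20, 17.5, 2.0, 0.93),
    BreedSpec("Belgian", 20, 10.0, 2.0, 1.10),
    BreedSpec("Clydesdale", 20, 9.0, 2.0, 1.05),
    BreedSpec("FranchesMontagnes", 20, 11.0, 2.0, 0.95),
    BreedSpec("Icelandic", 20, 9.5, 2.0, 1.13),
    BreedSpec("Morgan", 20, 10.5, 2.0, 1.06),
    BreedSpec("QuarterHorse", 20, 12.0, 2.0, 0.97),
    BreedSpec("Shetland", 20, 5.5, 1.0, 0.87),
    BreedSpec("Standardbred", 20, 11.5, 2.0, 1.12),
    BreedSpec("Thoroughbred", 20, 14.0, 2.5, 0.80),
    BreedSpec("Warmblood", 20, 12.5, 2.0, 0.91),
    BreedSpec("WelshPony", 20, 8.0, 1.5, 0.99),
    BreedSpec("Other", 24, 10.9, 3.0, 0.85),
)


def default_planted_entries() -> list[PlantedEntry]:
    """A small default catalog: one entry per category plus an absent one."""
    mk = CatalogEntry
    return [
        PlantedEntry(
            mk("E1", "GBED-like", "disease_trait_causing", "25", 1_000_001, "G", "A", gene="GBE1"),
            {"QuarterHorse": 0.028},
            lethal_homozygote=True,
            expected_breeds=("QuarterHorse",),
        ),
        PlantedEntry(
            mk("E2", "MYHM-like", "disease_associated", "11", 2_000_001, "C", "T", gene="MYH1"),
            {"QuarterHorse": 0.071, "Belgian": 0.01},
            expected_breeds=("QuarterHorse",),
        ),
        PlantedEntry(
            mk("E3", "white-spotting-like", "coat_color", "3", 3_000_001, "C", "T", gene="KIT"),
            {"Clydesdale": 0.95, "Belgian": 0.20, "Warmblood": 0.10, "Other": 0.10},
        ),
        PlantedEntry(
            mk("E4", "gait-like", "trait_associated", "23", 4_000_001, "C", "A", gene="DMRT3"),
            {"Icelandic": 0.50, "Standardbred": 0.40, "Morgan": 0.10},
        ),
        PlantedEntry(
            mk("E5", "absent-variant", "disease_trait_causing", "25", 5_000_001, "T", "C"),
            {},
        ),
    ]


def default_config(seed: int = 0, dropout: bool = True, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(
        breeds=list(DEFAULT_BREEDS),
        planted_entries=default_planted_entries(),
        dropout=DropoutModel() if dropout else DropoutModel(0.0, 0.0),
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg


@dataclasses.dataclass
class TruthSet:
    """Generation-time truth for a simulated cohort."""

    seed: int
    sample_ids: tuple[str, ...]
    sample_breeds: np.ndarray
    sample_docs: np.ndarray
    breed_names: tuple[str, ...]
    site_class: np.ndarray  # 'lof' | 'burden' | 'neutral' | 'planted'
    breed_freq: np.ndarray  # (n_breeds, n_sites) true allele frequencies
    sample_counts: pd.DataFrame  # exact pre-dropout per-sample counts
    dropout: DropoutModel
    planted_freqs: dict[str, dict[str, float]]

    def detection(self, doc: float) -> float:
        return float(1.0 - self.dropout.rate(doc))

    def breed_expected_base(self, response: str) -> dict[str, float]:
        """Expected pre-dropout per-sample count by breed, from true frequencies."""
        if response in ("n_burden", "n_burden_hom"):
            mask = np.isin(self.site_class, ("burden", "lof"))
        elif response in ("n_lof", "n_lof_hom"):
            mask = self.site_class == "lof"
        elif response == "n_variants":
            mask = np.ones(len(self.site_class), bool)
        else:
            raise ValueError(f"no planted truth for response {response!r}")
        p = self.breed_freq[:, mask]
        if response.endswith("_hom"):
            per_site = p**2
        else:
            per_site = 1.0 - (1.0 - p) ** 2
        return dict(zip(self.breed_names, per_site.sum(axis=1)))

    def planted_breed_means(self, response: str, at_doc: float) -> dict[str, float]:
        """Expected observed count per sample of each breed at a reference DOC."""
        det = self.detection(at_doc)
        return {b: det * v for b, v in self.breed_expected_base(response).items()}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "sample_ids": list(self.sample_ids),
            "sample_breeds": self.sample_breeds.tolist(),
            "sample_docs": self.sample_docs.tolist(),
            "breed_names": list(self.breed_names),
            "site_class": self.site_class.tolist(),
            "breed_freq": self.breed_freq.tolist(),
            "sample_counts": self.sample_counts.to_dict(orient="list"),
            "dropout": {"intercept": self.dropout.intercept, "slope_per_x": self.dropout.slope_per_x},
            "planted_freqs": self.planted_freqs,
        }
        Path(path).write_text(json.dumps(payload))


@dataclasses.dataclass
class SimulatedCohort:
    """In-memory simulated cohort: site table, genotype codes, metadata, truth."""

    config: SimulationConfig
    site_table: pd.DataFrame
    codes: np.ndarray  # (n_sites, n_samples) int8, post-dropout
    metadata: pd.DataFrame  # indexed by sample id; breed, doc
    truth: TruthSet

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.metadata.index)

    def observed_sample_counts(self) -> pd.DataFrame:
        """Post-dropout per-sample counts, computed directly from codes."""
        carrier = self.codes >= 1
        hom = self.codes == 2
        cls = self.site_table["site_class"].to_numpy()
        is_burden = np.isin(cls, ("burden", "lof"))
        is_lof = cls == "lof"
        private = carrier.sum(axis=1) == 1
        return pd.DataFrame(
            {
                "sample_id": list(self.samples),
                "n_variants": carrier.sum(axis=0).astype(int),
                "n_private": (carrier & private[:, None]).sum(axis=0).astype(int),
                "n_burden": carrier[is_burden].sum(axis=0).astype(int),
                "n_burden_hom": hom[is_burden].sum(axis=0).astype(int),
                "n_lof": carrier[is_lof].sum(axis=0).astype(int),
                "n_lof_hom": hom[is_lof].sum(axis=0).astype(int),
            }
        )

    def write_metadata(self, path: str | Path) -> None:
        out = self.metadata.reset_index()
        out.columns = ["sample", "breed", "doc"]
        out.to_csv(path, sep="\t", index=False, float_format="%.3f")

    def write_vcf(self, path: str | Path) -> None:
        st = self.site_table
        gt_map = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        contigs = list(dict.fromkeys(st["chrom"]))
        n_ann_blanks = 9  # pad ANN blocks to the full default sub-field layout
        with open(path, "w") as fh:
            for line in vcf_header_lines(self.samples, contigs):
                fh.write(line + "\n")
            for i, row in enumerate(st.itertuples(index=False)):
                hgnc = row.hgnc_symbol or ""
                gene = row.gene_id or ""
                tx = f"{gene}.t1" if gene else ""
                ftype = "transcript" if tx else ""
                ann = (
                    f"{row.alt}|{row.snpeff_term}|{row.snpeff_impact}|{hgnc}|{gene}|"
                    f"{ftype}|{tx}" + "|" * n_ann_blanks
                )
                csq = f"{row.alt}|{row.vep_term}|{row.vep_impact}|{hgnc}|{gene}|{tx}"
                gts = "\t".join(gt_map[int(c)] for c in self.codes[i])
                fh.write(
                    f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                    f"ANN={ann};CSQ={csq}\tGT\t{gts}\n"
                )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write VCF + metadata + truth JSON; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf",
            "metadata": out / "metadata.tsv",
            "truth": out / "truth.json",
        }
        self.write_vcf(paths["vcf"])
        self.write_metadata(paths["metadata"])
        self.truth.to_json(paths["truth"])
        return paths


_BASES = np.array(list("ACGT"))


def _draw_alleles(rng: np.random.Generator, terms: np.ndarray) -> tuple[list[str], list[str]]:
    """Ref/alt alleles per site; frameshift sites become short indels."""
    n = len(terms)
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    ins_len = rng.integers(1, 4, size=n)
    extra = rng.integers(0, 4, size=(n, 3))
    refs, alts = [], []
    for i in range(n):
        ref = _BASES[ref_idx[i]]
        if terms[i] == "frameshift_variant":
            tail = "".join(_BASES[extra[i, : ins_len[i]]])
            refs.append(ref)
            alts.append(ref + tail)
        else:
            refs.append(ref)
            alts.append(_BASES[(ref_idx[i] + alt_shift[i]) % 4])
    return refs, alts


def _choice(rng, options: Sequence, weights: Sequence[float], size: int) -> np.ndarray:
    w = np.asarray(weights, float)
    idx = rng.choice(len(options), size=size, p=w / w.sum())
    return idx


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort with known truth (deterministic for a fixed seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    am = config.annotator_model

    # --- samples -----------------------------------------------------------
    sample_ids, sample_breeds, sample_docs = [], [], []
    for b in config.breeds:
        docs = np.clip(rng.normal(b.doc_mean, b.doc_sd, size=b.n_samples), 1.0, 22.0)
        for j in range(b.n_samples):
            sample_ids.append(f"{b.name}_{j:03d}")
            sample_breeds.append(b.name)
            sample_docs.append(round(float(docs[j]), 3))
    sample_breeds = np.array(sample_breeds)
    sample_docs = np.array(sample_docs)
    breed_names = tuple(b.name for b in config.breeds)
    n_samples = len(sample_ids)

    # --- site classes and frequencies -------------------------------------
    n_sites = config.n_sites
    n_burden = int(round(n_sites * config.burden_site_fraction))
    cls = np.array(["neutral"] * n_sites, dtype=object)
    burden_idx = rng.permutation(n_sites)[:n_burden]
    cls[burden_idx] = "burden"
    is_lof_site = rng.random(n_sites) < am.lof_fraction
    cls[(cls == "burden") & is_lof_site] = "lof"
    burden_mask = np.isin(cls, ("burden", "lof"))

    a1, b1 = config.deleterious_sfs
    a2, b2 = config.neutral_sfs
    base_freq = np.empty(n_sites)
    base_freq[burden_mask] = rng.beta(a1, b1, size=int(burden_mask.sum()))
    base_freq[~burden_mask] = rng.beta(a2, b2, size=int((~burden_mask).sum()))
    base_freq = np.clip(base_freq, 5e-4, 0.98)

    scales = np.array([b.burden_scale for b in config.breeds])
    breed_freq = np.tile(base_freq, (len(config.breeds), 1))
    breed_freq[:, burden_mask] = np.clip(
        scales[:, None] * base_freq[burden_mask][None, :], 0.0, 0.98
    )

    # --- annotator labels --------------------------------------------------
    se_term = np.empty(n_sites, dtype=object)
    ve_term = np.empty(n_sites, dtype=object)
    se_imp = np.empty(n_sites, dtype=object)
    ve_imp = np.empty(n_sites, dtype=object)

    lof_mask = cls == "lof"
    n_lof = int(lof_mask.sum())
    lof_terms = [t for t, _ in LOF_TERMS_DIST]
    t_idx = _choice(rng, lof_terms, [w for _, w in LOF_TERMS_DIST], n_lof)
    agree = rng.random(n_lof) < am.type_agreement
    other = (t_idx + 1 + rng.integers(0, len(lof_terms) - 1, size=n_lof)) % len(lof_terms)
    se_term[lof_mask] = np.array(lof_terms, object)[t_idx]
    ve_term[lof_mask] = np.where(
        agree, np.array(lof_terms, object)[t_idx], np.array(lof_terms, object)[other]
    )
    se_imp[lof_mask] = "HIGH"
    ve_imp[lof_mask] = "HIGH"

    bo_mask = cls == "burden"  # burden but not both-annotator LOF
    n_bo = int(bo_mask.sum())
    pairs = [p for p, _ in am.burden_impact_probs]
    p_idx = _choice(rng, pairs, [w for _, w in am.burden_impact_probs], n_bo)
    se_i = np.array([pairs[i][0] for i in p_idx], object)
    ve_i = np.array([pairs[i][1] for i in p_idx], object)
    se_t = np.empty(n_bo, dtype=object)
    ve_t = np.empty(n_bo, dtype=object)
    for pair in pairs:
        sel = np.array([pairs[i] == pair for i in p_idx])
        if not sel.any():
            continue
        options = _NONLOF_TERM_PAIRS[pair]
        o_idx = rng.integers(0, len(options), size=int(sel.sum()))
        se_t[sel] = np.array([options[k][0] for k in o_idx], object)
        ve_t[sel] = np.array([options[k][1] for k in o_idx], object)
    se_imp[bo_mask], ve_imp[bo_mask] = se_i, ve_i
    se_term[bo_mask], ve_term[bo_mask] = se_t, ve_t

    nm = cls == "neutral"
    n_neu = int(nm.sum())
    npairs = [p for p, _ in am.nonburden_impact_probs]
    np_idx = _choice(rng, npairs, [w for _, w in am.nonburden_impact_probs], n_neu)
    se_imp[nm] = np.array([npairs[i][0] for i in np_idx], object)
    ve_imp[nm] = np.array([npairs[i][1] for i in np_idx], object)
    se_term[nm] = np.array([_NEUTRAL_TERM_BY_IMPACT[npairs[i][0]] for i in np_idx], object)
    ve_term[nm] = np.array([_NEUTRAL_TERM_BY_IMPACT[npairs[i][1]] for i in np_idx], object)

    refs, alts = _draw_alleles(rng, se_term)
    gene_idx = rng.integers(0, config.n_genes, size=n_sites)
    gene_ids = [f"ENSECAG{int(g):011d}" for g in gene_idx]
    hgnc = [f"GENE{int(g)}" if g < config.n_genes // 10 else None for g in gene_idx]

    site_table = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 100 + 50 * np.arange(n_sites),
            "ref": refs,
            "alt": alts,
            "snpeff_term": se_term,
            "snpeff_impact": se_imp,
            "vep_term": ve_term,
            "vep_impact": ve_imp,
            "gene_id": gene_ids,
            "hgnc_symbol": hgnc,
            "site_class": cls,
        }
    )

    # --- genotypes (Hardy-Weinberg per breed) ------------------------------
    codes = np.empty((n_sites, n_samples), dtype=np.int8)
    col = 0
    for bi, b in enumerate(config.breeds):
        block = rng.binomial(2, breed_freq[bi], size=(b.n_samples, n_sites)).T
        codes[:, col : col + b.n_samples] = block
        col += b.n_samples

    # --- planted catalog entries -------------------------------------------
    planted_rows = []
    planted_codes = []
    planted_freq_rows = []
    planted_truth: dict[str, dict[str, float]] = {}
    for pe in config.planted_entries:
        e = pe.entry
        freqs = {b.name: float(pe.breed_freqs.get(b.name, 0.0)) for b in config.breeds}
        planted_truth[e.entry_id] = freqs
        row_codes = np.empty(n_samples, dtype=np.int8)
        col = 0
        for b in config.breeds:
            row_codes[col : col + b.n_samples] = rng.binomial(2, freqs[b.name], size=b.n_samples)
            col += b.n_samples
        planted_codes.append(row_codes)
        planted_freq_rows.append([freqs[name] for name in breed_names])
        planted_rows.append(
            {
                "chrom": e.chrom,
                "pos": e.pos,
                "ref": e.ref,
                "alt": e.alt,
                "snpeff_term": "intergenic_variant",
                "snpeff_impact": "MODIFIER",
                "vep_term": "intergenic_variant",
                "vep_impact": "MODIFIER",
                "gene_id": None,
                "hgnc_symbol": None,
                "site_class": "planted",
            }
        )
    if planted_rows:
        site_table = pd.concat(
            [site_table, pd.DataFrame(planted_rows)], ignore_index=True
        )
        codes = np.vstack([codes, np.array(planted_codes, dtype=np.int8)])
        breed_freq = np.hstack([breed_freq, np.array(planted_freq_rows).T])

    # --- exact pre-dropout truth counts ------------------------------------
    truth_cls = site_table["site_class"].to_numpy()
    carrier = codes >= 1
    hom = codes == 2
    t_burden = np.isin(truth_cls, ("burden", "lof"))
    t_lof = truth_cls == "lof"
    private = carrier.sum(axis=1) == 1
    sample_counts = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "n_variants": carrier.sum(axis=0).astype(int),
            "n_private": (carrier & private[:, None]).sum(axis=0).astype(int),
            "n_burden": carrier[t_burden].sum(axis=0).astype(int),
            "n_burden_hom": hom[t_burden].sum(axis=0).astype(int),
            "n_lof": carrier[t_lof].sum(axis=0).astype(int),
            "n_lof_hom": hom[t_lof].sum(axis=0).astype(int),
        }
    )

    # --- dropout ------------------------------------------------------------
    rates = config.dropout.rate(sample_docs)
    if (rates > 0).any():
        miss = rng.random(codes.shape) < rates[None, :]
        codes = np.where(miss, np.int8(-1), codes)

    metadata = pd.DataFrame(
        {"breed": sample_breeds, "doc": sample_docs}, index=pd.Index(sample_ids, name="sample")
    )
    truth = TruthSet(
        seed=config.seed,
        sample_ids=tuple(sample_ids),
        sample_breeds=sample_breeds,
        sample_docs=sample_docs,
        breed_names=breed_names,
        site_class=truth_cls,
        breed_freq=breed_freq,
        sample_counts=sample_counts,
        dropout=config.dropout,
        planted_freqs=planted_truth,
    )
    return SimulatedCohort(
        config=config, site_table=site_table, codes=codes, metadata=metadata, truth=truth
    )


def evaluate_recovery(
    truth: TruthSet,
    sample_burden: pd.DataFrame,
    emmeans: pd.DataFrame | None = None,
    planted_vf: Mapping[str, Mapping[str, float]] | None = None,
) -> dict:
    """Score pipeline outputs against generation-time truth.

    ``sample_burden`` is compared count-for-count (exact agreement is the
    expectation only for no-dropout cohorts).  If an EMMEAN table is
    given, reports the fraction of (breed, response) planted means inside
    their 95% CI.  If per-breed catalog frequencies are given, reports
    errors against the planted frequencies in binomial-SE units.
    """
    got = sample_burden.set_index("sample_id")
    if set(got.index) != set(truth.sample_ids):
        raise ValueError("sample ids do not match the truth set (different cohort?)")
    want = truth.sample_counts.set_index("sample_id").loc[got.index]
    shared = [c for c in want.columns if c in got.columns]
    diffs = (got[shared] - want[shared]).abs()
    report: dict = {
        "n_samples": len(got),
        "counts_exact": bool((diffs.to_numpy() == 0).all()),
        "max_count_abs_error": int(diffs.to_numpy().max()) if len(shared) else 0,
    }
    if emmeans is not None and len(emmeans):
        covered = total = 0
        for resp, g in emmeans.groupby("response"):
            at_doc = float(g["at_doc"].iloc[0])
            planted = truth.planted_breed_means(resp, at_doc)
            for row in g.itertuples():
                mean = planted.get(row.breed)
                if mean is None:
                    continue
                total += 1
                covered += int(row.ci_low <= mean <= row.ci_high)
        report["emmean_ci_covered"] = covered
        report["emmean_ci_total"] = total
    if planted_vf is not None:
        breed_n = pd.Series(truth.sample_breeds).value_counts()
        worst = 0.0
        within = True
        for entry_id, by_breed in planted_vf.items():
            planted = truth.planted_freqs.get(entry_id, {})
            for breed, vf in by_breed.items():
                f = planted.get(breed, 0.0)
                n_alleles = 2 * int(breed_n.get(breed, 0))
                if n_alleles == 0 or vf is None:
                    continue
                err = abs(vf - f)
                worst = max(worst, err)
                se = np.sqrt(max(f * (1 - f), 1e-12) / n_alleles)
                if f > 0 and err > 3 * se:
                    within = False
        report["planted_vf_max_abs_error"] = worst
        report["planted_vf_within_3se"] = within
    return report
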