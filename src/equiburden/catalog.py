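"""Matching a catalog of published phenotype variants against a cohort.

The catalog is OMIA-style: each entry is a reported causal or associated
variant for a disease, coat-colour or other trait, with 1-based
coordinates on the cohort's genome build.  Matching is exact on the
normalized (chrom, pos, ref, alt) key — the catalog coordinates are
assumed already remapped and left-normalized — with an optional
near-miss listing (same position, different alleles) to surface
normalization problems.  Frequencies are reported both as alt-allele
frequency (VF) and folded MAF.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .vcf_io import Cohort

CATEGORIES = (
    "disease_trait_causing",
    "coat_color",
    "disease_associated",
    "trait_associated",
)

MAX_ALLELE_LEN = 20


@dataclasses.dataclass(frozen=True)
class CatalogEntry:
    entry_id: str
    phenotype: str
    category: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str | None = None
    inheritance: str | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"{self.entry_id}: ref and alt must differ")
        if max(len(self.ref), len(self.alt)) > MAX_ALLELE_LEN:
            raise ValueError(
                f"{self.entry_id}: alleles longer than {MAX_ALLELE_LEN} bases are not investigated"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.entry_id}: unknown category {self.category!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def load_catalog(path: str | Path) -> list[CatalogEntry]:
    """Load and validate a tab-separated catalog file.

    Leading ``#`` pragma lines (e.g. ``#build=EquCab3.0``) are skipped.
    Category vocabulary and allele lengths are validated per row (errors
    name the offending row); duplicate coordinates are rejected.
    """
    rows = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                required = {"entry_id", "phenotype", "category", "chrom", "pos", "ref", "alt"}
                missing = required - set(header)
                if missing:
                    raise ValueError(f"catalog header lacks columns: {sorted(missing)}")
                continue
            row = dict(zip(header, fields))
            try:
                rows.append(
                    CatalogEntry(
                        entry_id=row["entry_id"],
                        phenotype=row["phenotype"],
                        category=row["category"],
                        chrom=row["chrom"],
                        pos=int(row["pos"]),
                        ref=row["ref"],
                        alt=row["alt"],
                        gene=row.get("gene") or None,
                        inheritance=row.get("inheritance") or None,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"catalog row {lineno}: {exc}") from exc
    seen: dict[tuple, str] = {}
    for e in rows:
        if e.key in seen:
            raise ValueError(
                f"duplicate catalog coordinates {e.key} ({seen[e.key]} and {e.entry_id})"
            )
        seen[e.key] = e.entry_id
    return rows


@dataclasses.dataclass
class MatchResult:
    entry: CatalogEntry
    detected: bool
    vf: float | None
    maf: float | None
    per_breed: pd.DataFrame  # breed, n_called, het, hom_alt, vf, maf
    carriers: tuple[str, ...]
    carrier_table: pd.DataFrame | None = None  # sample_id, breed, genotype
    near_misses: tuple[tuple[str, int, str, str], ...] = ()


def match_catalog(
    cohort: Cohort,
    catalog: Sequence[CatalogEntry],
    chrom_aliases: Mapping[str, str] | None = None,
) -> list[MatchResult]:
    """Match catalog entries against a decomposed cohort.

    An entry is detected iff a cohort record has the same normalized
    (chrom, pos, ref, alt) and at least one sample carries the alt.
    Unmatched entries are reported with ``detected=False`` (not errors).
    Genotype counts and VF/MAF are computed overall and per breed.
    """
    aliases = dict(chrom_aliases or {})
    index = {r.key: i for i, r in enumerate(cohort.records)}
    by_pos: dict[tuple[str, int], list[tuple[str, int, str, str]]] = {}
    for key in index:
        by_pos.setdefault((key[0], key[1]), []).append(key)
    breeds = cohort.metadata["breed"].to_numpy()
    samples = np.array(cohort.samples)
    results = []
    for entry in catalog:
        chrom = aliases.get(entry.chrom, entry.chrom)
        key = (chrom, entry.pos, entry.ref, entry.alt)
        i = index.get(key)
        near = tuple(k for k in by_pos.get((chrom, entry.pos), []) if k != key)
        if i is None:
            results.append(
                MatchResult(
                    entry=entry, detected=False, vf=None, maf=None,
                    per_breed=pd.DataFrame(
                        columns=["breed", "n_called", "het", "hom_alt", "vf", "maf"]
                    ),
                    carriers=(), near_misses=near,
                )
            )
            continue
        codes = cohort.records[i].genotypes.codes
        called = codes >= 0
        rows = []
        for breed in sorted(set(breeds)):
            in_breed = breeds == breed
            n_called = int((called & in_breed).sum())
            het = int(((codes == 1) & in_breed).sum())
            hom = int(((codes == 2) & in_breed).sum())
            vf_b = (het + 2 * hom) / (2 * n_called) if n_called else None
            rows.append(
                {
                    "breed": breed,
                    "n_called": n_called,
                    "het": het,
                    "hom_alt": hom,
                    "vf": vf_b,
                    "maf": min(vf_b, 1 - vf_b) if vf_b is not None else None,
                }
            )
        alt_total = int(codes[called].sum())
        denom = int(2 * called.sum())
        vf = alt_total / denom if denom else None
        carrier_mask = codes >= 1
        carriers = tuple(samples[carrier_mask])
        carrier_table = pd.DataFrame(
            {
                "sample_id": samples[carrier_mask],
                "breed": breeds[carrier_mask],
                "genotype": np.where(codes[carrier_mask] == 2, "hom_alt", "het"),
            }
        )
        results.append(
            MatchResult(
                entry=entry,
                detected=bool(alt_total > 0),
                vf=vf,
                maf=min(vf, 1 - vf) if vf is not None else None,
                per_breed=pd.DataFrame(rows),
                carriers=carriers,
                carrier_table=carrier_table,
                near_misses=near,
            )
        )
    return results


def match_table(matches: Sequence[MatchResult]) -> pd.DataFrame:
    """Flat per-entry summary table of a catalog match run."""
    return pd.DataFrame(
        {
            "entry_id": [m.entry.entry_id for m in matches],
            "phenotype": [m.entry.phenotype for m in matches],
            "category": [m.entry.category for m in matches],
            "chrom": [m.entry.chrom for m in matches],
            "pos": [m.entry.pos for m in matches],
            "ref": [m.entry.ref for m in matches],
            "alt": [m.entry.alt for m in matches],
            "detected": [m.detected for m in matches],
            "vf": [m.vf for m in matches],
            "maf": [m.maf for m in matches],
            "n_carriers": [len(m.carriers) for m in matches],
            "n_near_misses": [len(m.near_misses) for m in matches],
        }
    )


def breed_genotype_table(matches: Sequence[MatchResult]) -> pd.DataFrame:
    """Long-format per-(entry, breed) genotype count table."""
    frames = []
    for m in matches:
        if not m.detected:
            continue
        pb = m.per_breed.copy()
        pb.insert(0, "entry_id", m.entry.entry_id)
        pb.insert(1, "phenotype", m.entry.phenotype)
        pb.insert(2, "category", m.entry.category)
        frames.append(pb)
    if not frames:
        return pd.DataFrame(
            columns=["entry_id", "phenotype", "category", "breed",
                     "n_called", "het", "hom_alt", "vf", "maf"]
        )
    return pd.concat(frames, ignore_index=True)


def summarize_categories(matches: Sequence[MatchResult]) -> pd.DataFrame:
    """Per-category detection counts and VF medians/IQRs over detected entries.

    Percentages are on the 0-100 scale.  A category with nothing detected
    reports its counts with absent (NaN) frequency summaries.  An extra
    ``all`` row summarises every detected entry.
    """
    df = match_table(matches)
    rows = []
    groups = list(df.groupby("category")) + [("all", df)]
    for cat, g in groups:
        det = g[g["detected"]]
        vf = det["vf"].to_numpy(float)
        if len(vf):
            q1, med, q3 = np.percentile(vf, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        rows.append(
            {
                "category": cat,
                "n_catalog": len(g),
                "n_detected": int(g["detected"].sum()),
                "detection_pct": 100.0 * g["detected"].sum() / len(g) if len(g) else np.nan,
                "median_vf": med,
                "vf_q1": q1,
                "vf_q3": q3,
            }
        )
    return pd.DataFrame(rows)


def flag_unexpected_genotypes(
    matches: Sequence[MatchResult],
    rules: Mapping[str, Mapping],
) -> pd.DataFrame:
    """Flag genotype patterns conflicting with reported inheritance.

    ``rules`` maps entry_id to expectations: ``lethal_homozygote`` (no
    live homozygote expected) and/or ``expected_breeds`` (carriers outside
    this list are flagged).  Returns one row per violation with the
    samples and genotypes supporting it.
    """
    rows = []
    by_id = {m.entry.entry_id: m for m in matches}
    for entry_id, rule in rules.items():
        m = by_id.get(entry_id)
        if m is None or not m.detected:
            continue
        ct = m.carrier_table if m.carrier_table is not None else pd.DataFrame(
            columns=["sample_id", "breed", "genotype"]
        )
        if rule.get("lethal_homozygote"):
            hom = ct[ct["genotype"] == "hom_alt"]
            if len(hom):
                rows.append(
                    {
                        "entry_id": entry_id,
                        "phenotype": m.entry.phenotype,
                        "violation": "homozygote_for_reported_lethal",
                        "detail": "; ".join(
                            f"{r.sample_id} ({r.breed}): hom_alt" for r in hom.itertuples()
                        ),
                    }
                )
        expected = rule.get("expected_breeds")
        if expected is not None:
            outside = ct[~ct["breed"].isin(expected)]
            if len(outside):
                rows.append(
                    {
                        "entry_id": entry_id,
                        "phenotype": m.entry.phenotype,
                        "violation": "carrier_outside_reported_breeds",
                        "detail": "; ".join(
                            f"{r.sample_id} ({r.breed}): {r.genotype}"
                            for r in outside.itertuples()
                        ),
                    }
                )
    return pd.DataFrame(rows, columns=["entry_id", "phenotype", "violation", "detail"])
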