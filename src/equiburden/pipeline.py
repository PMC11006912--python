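"""End-to-end pipeline: ingest -> burden -> breeds -> catalog.

Given a dual-annotated VCF, sample metadata, and optional Ne/catalog
tables, runs every stage and writes a run directory of tab-separated
report tables, a JSON summary, a manifest (config hash and input
checksums), and a log.  Identical inputs and config give identical
outputs (no timestamps in the summary).  A stage failure aborts with a
stage-tagged error and leaves a FAILED marker next to any partial
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import burden as bc
from . import breeds as bs
from . import catalog as cat
from .vcf_io import read_cohort_vcf, read_metadata

logger = logging.getLogger("equiburden")


@dataclasses.dataclass
class RunConfig:
    vcf: Path
    metadata: Path
    out_dir: Path
    ne_table: Path | None = None
    catalog: Path | None = None
    min_n: int = 17
    min_mean_doc: float = 5.0
    gene_min_variants: int = 5
    gene_vf_threshold: float = 0.05
    vf_mode: str = "any"  # "any" | "mean"
    severity_table: Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("vcf", "metadata", "ne_table", "catalog", "severity_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.min_n <= 0 or self.min_mean_doc <= 0:
            raise ValueError("thresholds must be positive")
        if self.gene_min_variants <= 0 or self.gene_vf_threshold <= 0:
            raise ValueError("gene-set thresholds must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_severity_table(path: Path) -> dict[str, int]:
    """Load a term<TAB>rank severity override table."""
    table: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        term, rank = line.split("\t")
        table[term.strip().lower()] = int(rank)
    return table


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the summary dict (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)

    summary: dict = {}
    try:
        # --- ingestion ------------------------------------------------------
        try:
            metadata = read_metadata(config.metadata)
            severity = load_severity_table(config.severity_table) if config.severity_table else None
            cohort = read_cohort_vcf(config.vcf, metadata)
            if not cohort.records:
                raise ValueError("VCF contains no variant records")
            logger.info(
                "ingested %d records, %d samples (excluded %d long indels, "
                "%d allele-mismatched annotations)",
                len(cohort.records), len(cohort.samples),
                cohort.n_excluded_long_indels, cohort.n_dropped_allele_mismatch,
            )
        except Exception as exc:
            raise StageError("ingest", exc) from exc

        # --- burden ---------------------------------------------------------
        try:
            calls = bc.build_burden_calls(cohort, severity_table=severity)
            freqs = bc.variant_frequencies(cohort)
            sample_burden = bc.per_sample_burden(cohort, calls)
            crosstab = bc.impact_crosstab(calls)
            concord = bc.type_concordance(calls)
            run_summary = bc.burden_summary(calls, freqs)
            gene_agg, unassigned = bc.aggregate_by_gene(calls, freqs)
            genes_multi, genes_high = bc.select_gene_sets(
                gene_agg,
                min_variants=config.gene_min_variants,
                vf_threshold=config.gene_vf_threshold,
                vf_mode=config.vf_mode,
            )
            vf_burden = freqs.loc[calls["is_burden"].to_numpy(), "vf"].to_numpy()
            vf_other = freqs.loc[~calls["is_burden"].to_numpy(), "vf"].to_numpy()
            freq_test = (
                bs.compare_frequencies(vf_burden, vf_other)
                if len(vf_burden) >= 2 and len(vf_other) >= 2
                else None
            )
            _write_tsv(calls, out / "burden_calls.tsv")
            _write_tsv(sample_burden, out / "sample_burden.tsv")
            _write_tsv(gene_agg, out / "gene_aggregates.tsv")
            crosstab.to_csv(out / "impact_crosstab.tsv", sep="\t")
            _write_tsv(concord["pairs"], out / "type_concordance_pairs.tsv")
            summary["burden"] = {
                **run_summary,
                "n_unassigned_gene": unassigned,
                "concordance": {k: v for k, v in concord.items() if k != "pairs"},
                "crosstab_burden_total": bc.burden_total_from_crosstab(crosstab),
                "gene_sets": {
                    "multi_variant": genes_multi,
                    "high_frequency": genes_high,
                },
                "frequency_comparison": freq_test,
                "exclusions": {
                    "long_indels": cohort.n_excluded_long_indels,
                    "allele_mismatched_annotations": cohort.n_dropped_allele_mismatch,
                },
            }
            logger.info(
                "burden: %d of %d variants (%d LOF)",
                run_summary["n_burden"], run_summary["n_variants"], run_summary["n_lof"],
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("burden", exc) from exc

        # --- breeds ---------------------------------------------------------
        try:
            emmeans, targets = bs.breed_emmeans(
                sample_burden, cohort.metadata,
                min_n=config.min_n, min_mean_doc=config.min_mean_doc,
            )
            _write_tsv(emmeans, out / "breed_emmeans.tsv")
            summary["breeds"] = {"targets": targets, "n_targets": len(targets)}
            if config.ne_table is not None:
                ne = bs.read_ne_table(config.ne_table)
                corr = bs.correlate_burden_ne(sample_burden, cohort.metadata, ne)
                _write_tsv(corr, out / "ne_correlations.tsv")
                summary["breeds"]["ne_correlations"] = corr.to_dict(orient="records")
            logger.info("breeds: %d targets", len(targets))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("breeds", exc) from exc

        # --- catalog --------------------------------------------------------
        if config.catalog is not None:
            try:
                entries = cat.load_catalog(config.catalog)
                matches = cat.match_catalog(cohort, entries)
                _write_tsv(cat.match_table(matches), out / "catalog_matches.tsv")
                _write_tsv(cat.breed_genotype_table(matches), out / "catalog_breed_genotypes.tsv")
                cat_summary = cat.summarize_categories(matches)
                _write_tsv(cat_summary, out / "catalog_category_summary.tsv")
                summary["catalog"] = {
                    "n_entries": len(entries),
                    "n_detected": int(sum(m.detected for m in matches)),
                    "categories": cat_summary.to_dict(orient="records"),
                }
                logger.info(
                    "catalog: %d of %d entries detected",
                    summary["catalog"]["n_detected"], len(entries),
                )
            except StageError:
                raise
            except Exception as exc:
                raise StageError("catalog", exc) from exc

        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest = {
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "inputs": {
                name: _sha256(Path(p))
                for name, p in (
                    ("vcf", config.vcf), ("metadata", config.metadata),
                    ("ne_table", config.ne_table), ("catalog", config.catalog),
                )
                if p is not None
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return summary
    except Exception:
        failed_marker.write_text("pipeline failed; partial outputs retained\n")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
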