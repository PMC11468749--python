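"""End-to-end orchestration: curate -> composition -> compress -> analyze.

Every run produces, under one output directory, the per-genome analysis
table, the exclusion ledger, AIC comparison tables and fit summaries per
backend, partial-effect grids, and a machine-readable manifest of the
configuration; identical config and seed give byte-identical tables.
Stages exchange TSV (headers mandatory, UTF-8, '.' decimal) so each can
be re-run from cached files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from grc import composition, compression, gam, io_genomes, synthetic

_pkg_version = "0.1.0"

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "export_supplementary",
           "composition_table", "compression_table"]

logger = logging.getLogger("grc")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one input mode: a synthetic cohort spec, or a FASTA directory
    with a metadata TSV (genome_id, species, genus, fasta_path).
    """

    out_dir: str
    cohort: synthetic.CohortSpec | None = None
    metadata_path: str | None = None
    backends: tuple[str, ...] = ("ctx", "ctx-rc")
    ctx_order: int = 8
    kmer_k: int = 4
    outlier_threshold: float = 30.0
    max_per_species: int = 1
    basis_dim: int = 10
    random_intercept: bool = False
    difference_model: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.cohort is None) == (self.metadata_path is None):
            raise ConfigError(
                "exactly one of cohort (synthetic) or metadata_path must be set"
            )
        known = set(compression.list_backends())
        unknown = [b for b in self.backends if b not in known]
        if unknown:
            raise ConfigError(f"unknown backend(s): {unknown}")
        if self.difference_model and len(self.backends) < 2:
            raise ConfigError("difference model requires at least two backends")


@dataclass
class PipelineResult:
    table: pd.DataFrame
    ledger: io_genomes.ExclusionLedger
    comparisons: dict[str, gam.ModelComparison]
    final_fits: dict[str, gam.GAMResults]
    difference_fit: gam.GAMResults | None
    paths: dict[str, Path] = field(default_factory=dict)


def _ctx_config(config: RunConfig, backend: str) -> compression.ContextModelConfig | None:
    if backend == "ctx":
        return compression.ContextModelConfig(order=config.ctx_order)
    if backend == "ctx-rc":
        return compression.ContextModelConfig(order=config.ctx_order, rc_canonical=True)
    return None


def _load_genomes(config: RunConfig, ledger: io_genomes.ExclusionLedger):
    if config.cohort is not None:
        cohort = dataclasses.replace(config.cohort, seed=config.seed)
        records, truth = synthetic.generate_cohort(cohort)
        ledger.n_input = len(records)
        return records, truth
    meta = io_genomes.read_metadata(config.metadata_path)
    ledger.n_input = len(meta)
    records = []
    for row in meta.itertuples(index=False):
        seqs = io_genomes.parse_fasta(row.fasta_path)
        try:
            records.append(
                io_genomes.assemble_genome(seqs, row.genome_id, row.genus, row.species)
            )
        except io_genomes.CurationError:
            ledger.record(row.genome_id, "plasmid_only")
    return records, None


def composition_table(records, k: int = 4) -> pd.DataFrame:
    """Per-genome composition statistics: length, AT content, OUV."""
    import numpy as np

    rows = []
    for rec in records:
        freqs = composition.nucleotide_frequencies(rec.sequence)
        res = composition.ouv(rec.sequence, k=k)
        rows.append(
            {
                "genome_id": rec.genome_id,
                "genus": rec.genus,
                "species": rec.species,
                "length_bases": rec.length_bases,
                "log10_size": float(np.log10(rec.length_bases)),
                "at": composition.at_content(freqs),
                "ouv": res.ouv,
            }
        )
    return pd.DataFrame(rows)


def compression_table(records, backends, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-genome compression ratios, one column per backend."""
    rows = []
    for rec in records:
        stream = compression.sequence_to_stream(rec.sequence)
        row = {"genome_id": rec.genome_id}
        for backend in backends:
            cfg = _ctx_config(config, backend) if config is not None else None
            result = compression.compress_ratio(stream, backend, cfg)
            row[f"ratio_{_safe(backend)}"] = result.ratio
            row[f"bytes_{_safe(backend)}"] = result.compressed_bytes
        rows.append(row)
        logger.debug("compressed %s: %s", rec.genome_id, row)
    return pd.DataFrame(rows)


def _safe(backend: str) -> str:
    return backend.replace("-", "_")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run curate -> composition -> compress -> analyze and write artifacts."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ledger = io_genomes.ExclusionLedger()
    records, truth = _load_genomes(config, ledger)
    records, ledger = io_genomes.dedupe_species(
        records, config.max_per_species, ledger
    )
    logger.info("curated %d genomes (%d removed so far)", len(records),
                len(ledger.removed_ids))

    comp = composition_table(records, k=config.kmer_k)
    ratios = compression_table(records, config.backends, config)
    table = comp.merge(ratios, on="genome_id", validate="one_to_one")

    ratio_cols = [f"ratio_{_safe(b)}" for b in config.backends]
    table, ledger = io_genomes.exclude_ratio_outliers(
        table, ratio_cols, config.outlier_threshold, ledger
    )
    table = table.sort_values("genome_id").reset_index(drop=True)

    paths["analysis_table"] = out / "analysis_table.tsv"
    table.to_csv(paths["analysis_table"], sep="\t", index=False)
    paths["ledger"] = out / "exclusion_ledger.tsv"
    io_genomes.write_ledger(ledger, paths["ledger"])
    if truth is not None:
        paths["truth"] = out / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)

    comparisons: dict[str, gam.ModelComparison] = {}
    final_fits: dict[str, gam.GAMResults] = {}
    for backend in config.backends:
        col = f"ratio_{_safe(backend)}"
        specs = gam.standard_specs(
            col, basis_dim=config.basis_dim, random_intercept=config.random_intercept
        )
        comparison = gam.compare_models(table, specs)
        comparisons[backend] = comparison
        final = gam.fit_gam(table, specs["full"], method="REML")
        final_fits[backend] = final
        aic_path = out / f"aic_{_safe(backend)}.tsv"
        comparison.table().to_csv(aic_path, sep="\t", index=False)
        paths[f"aic_{backend}"] = aic_path
        summary_path = out / f"summary_{_safe(backend)}.txt"
        summary_path.write_text(final.summary() + "\n")
        paths[f"summary_{backend}"] = summary_path
        grids = []
        for term in ("at", "log10_size", "ouv"):
            pe = final.partial_effect(term)
            pe.insert(0, "term", term)
            grids.append(pe)
        grid_path = out / f"partials_{_safe(backend)}.tsv"
        pd.concat(grids).to_csv(grid_path, sep="\t", index=False)
        paths[f"partials_{backend}"] = grid_path

    difference_fit = None
    if config.difference_model:
        outcome = f"ratio_{_safe(config.backends[1])}"
        baseline = f"ratio_{_safe(config.backends[0])}"
        difference_fit = gam.fit_difference_model(
            table, outcome=outcome, baseline=baseline, basis_dim=config.basis_dim
        )
        diff_path = out / "summary_difference_model.txt"
        diff_path.write_text(difference_fit.summary() + "\n")
        paths["summary_difference"] = diff_path

    manifest = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "config": _config_to_json(config),
        "n_genomes_final": int(len(table)),
        "ledger": {
            "n_input": ledger.n_input,
            "n_removed_species_dedup": ledger.n_removed_species_dedup,
            "n_removed_ratio_outliers": ledger.n_removed_ratio_outliers,
            "n_removed_plasmid_only": ledger.n_removed_plasmid_only,
            "n_final": ledger.n_final,
        },
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        table=table,
        ledger=ledger,
        comparisons=comparisons,
        final_fits=final_fits,
        difference_fit=difference_fit,
        paths=paths,
    )


def _config_to_json(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.cohort is not None:
        d["cohort"] = dataclasses.asdict(config.cohort)
    return d


def export_supplementary(table: pd.DataFrame, path: str | Path) -> Path:
    """Export the analysis table as a spreadsheet-compatible CSV: one row
    per genome with every computed quantity."""
    if len(table) == 0:
        raise ValueError("empty analysis table")
    path = Path(path)
    table.to_csv(path, index=False)
    return path
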