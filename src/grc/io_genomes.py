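"""Reading and curating genome cohorts.

Curation mirrors standard comparative-genomics practice for RefSeq-style
cohorts: plasmid records are dropped (identified by header keywords),
multi-chromosome genomes are concatenated into a single sequence,
species are de-duplicated to limit single-species bias, and genomes with
implausibly high compression ratios under every backend are excluded as
model-assumption outliers.  Every removal is logged in an exclusion
ledger so that kept + removed always reconstructs the input.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "GenomeRecord",
    "ExclusionLedger",
    "FastaParseError",
    "CurationError",
    "parse_fasta",
    "assemble_genome",
    "dedupe_species",
    "exclude_ratio_outliers",
    "read_metadata",
    "write_ledger",
]

DEFAULT_PLASMID_KEYWORDS = ("plasmid",)


class FastaParseError(ValueError):
    pass


class CurationError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: a chromosome or plasmid of a genome assembly."""

    record_id: str
    description: str
    sequence: str
    is_plasmid: bool


@dataclass(frozen=True)
class GenomeRecord:
    """A curated genome: all chromosome records concatenated."""

    genome_id: str
    genus: str
    species: str
    sequence: str
    length_bases: int

    def __post_init__(self):
        if self.length_bases != len(self.sequence):
            raise CurationError(
                f"{self.genome_id}: length_bases {self.length_bases} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass
class ExclusionLedger:
    """Bookkeeping of curation removals; conserves genome counts."""

    n_input: int = 0
    n_removed_species_dedup: int = 0
    n_removed_ratio_outliers: int = 0
    n_removed_plasmid_only: int = 0
    removed_ids: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def n_final(self) -> int:
        return (
            self.n_input
            - self.n_removed_species_dedup
            - self.n_removed_ratio_outliers
            - self.n_removed_plasmid_only
        )

    def record(self, genome_id: str, reason: str, detail: str = "") -> None:
        if reason == "species_dedup":
            self.n_removed_species_dedup += 1
        elif reason == "ratio_outlier":
            self.n_removed_ratio_outliers += 1
        elif reason == "plasmid_only":
            self.n_removed_plasmid_only += 1
        else:
            raise CurationError(f"unknown exclusion reason {reason!r}")
        self.removed_ids.append((genome_id, reason, detail))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.removed_ids, columns=["genome_id", "reason", "detail"]
        )


def parse_fasta(
    path: str | Path,
    plasmid_keywords: Sequence[str] = DEFAULT_PLASMID_KEYWORDS,
) -> list[SequenceRecord]:
    """Read a (optionally gzipped) multi-FASTA file.

    Sequences are upper-cased.  A record is flagged as plasmid when its
    description contains any of ``plasmid_keywords`` (case-insensitive).
    Raises :class:`FastaParseError` on duplicate ids or empty sequences.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    keywords = tuple(k.lower() for k in plasmid_keywords)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise FastaParseError(f"{path}: record {rec.id!r} has empty sequence")
            if rec.id in seen:
                raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description
            is_plasmid = any(k in desc.lower() for k in keywords)
            records.append(
                SequenceRecord(
                    record_id=rec.id,
                    description=desc,
                    sequence=seq,
                    is_plasmid=is_plasmid,
                )
            )
    return records


def assemble_genome(
    records: Iterable[SequenceRecord],
    genome_id: str,
    genus: str,
    species: str,
) -> GenomeRecord:
    """Concatenate non-plasmid records, in file order, into one genome.

    Raises :class:`CurationError` if every record is a plasmid (the genome
    is then excluded with ledger reason ``plasmid_only``).
    """
    chromosomes = [r.sequence for r in records if not r.is_plasmid]
    if not chromosomes:
        raise CurationError(f"{genome_id}: plasmid-only genome")
    seq = "".join(chromosomes)
    return GenomeRecord(
        genome_id=genome_id,
        genus=genus,
        species=species,
        sequence=seq,
        length_bases=len(seq),
    )


def dedupe_species(
    genomes: Sequence[GenomeRecord],
    max_per_species: int = 1,
    ledger: ExclusionLedger | None = None,
) -> tuple[list[GenomeRecord], ExclusionLedger]:
    """Keep at most ``max_per_species`` genomes per species.

    Retention is deterministic: within a species, genomes sorted by
    genome_id are kept first.  Kept genomes are returned in their original
    order; removals are logged with reason ``species_dedup``.
    """
    if max_per_species < 1:
        raise CurationError("max_per_species must be >= 1")
    if ledger is None:
        ledger = ExclusionLedger(n_input=len(genomes))
    by_species: dict[str, list[str]] = {}
    for g in genomes:
        by_species.setdefault(g.species, []).append(g.genome_id)
    keep_ids = {
        gid
        for ids in by_species.values()
        for gid in sorted(ids)[:max_per_species]
    }
    kept = [g for g in genomes if g.genome_id in keep_ids]
    for g in genomes:
        if g.genome_id not in keep_ids:
            ledger.record(g.genome_id, "species_dedup", f"species={g.species}")
    return kept, ledger


def exclude_ratio_outliers(
    table: pd.DataFrame,
    ratio_columns: Sequence[str],
    threshold: float = 30.0,
    ledger: ExclusionLedger | None = None,
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Drop genomes whose compression ratio exceeds ``threshold`` under
    EVERY listed backend (the conjunction rule: a genome over the limit
    for one backend but not another is kept).

    ``table`` needs a ``genome_id`` column plus the ratio columns; missing
    ratio values are an error naming the genome.
    """
    if ledger is None:
        ledger = ExclusionLedger(n_input=len(table))
    for col in ratio_columns:
        if col not in table.columns:
            raise CurationError(f"missing ratio column {col!r}")
        bad = table.loc[table[col].isna(), "genome_id"]
        if len(bad):
            raise CurationError(
                f"missing {col} ratio for genome(s): {', '.join(map(str, bad))}"
            )
    if len(table) == 0:
        return table.copy(), ledger
    mask_out = pd.Series(True, index=table.index)
    for col in ratio_columns:
        mask_out &= table[col] > threshold
    removed = table.loc[mask_out]
    for _, row in removed.iterrows():
        detail = ";".join(f"{c}={row[c]:.2f}" for c in ratio_columns)
        ledger.record(str(row["genome_id"]), "ratio_outlier", detail)
    return table.loc[~mask_out].copy(), ledger


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a cohort metadata TSV: genome_id, species, genus, fasta_path."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "species", "genus", "fasta_path"}
    missing = required - set(meta.columns)
    if missing:
        raise CurationError(f"metadata missing column(s): {sorted(missing)}")
    return meta


def write_ledger(ledger: ExclusionLedger, path: str | Path) -> None:
    ledger.to_frame().to_csv(path, sep="\t", index=False)
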