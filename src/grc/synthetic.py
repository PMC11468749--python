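"""Synthetic microbial genome cohorts with controllable statistical structure.

Real microbial cohorts couple genome size, AT content, oligonucleotide
usage variance (OUV) and redundancy in characteristic ways: sizes span
roughly 0.1–10 Mb, AT content roughly 25–85%, AT-rich genomes tend to
have lower OUV, and larger genomes tend to be more repeat-rich (hence
more compressible), with genus-specific strength of that size effect.
This module generates cohorts with exactly those couplings planted, so
the downstream composition, compression and regression stages can be
exercised — and their recovery of the planted structure verified —
without any genome downloads.

Each genome is drawn from an order-3 Markov source: transition weights
start from the single-base distribution implied by the target AT content
(A=T, C=G — Chargaff parity) and are perturbed multiplicatively by
log-normal factors of strength ``bias_strength`` attached to
reverse-complement-canonical 4-mers (so the source stays strand
symmetric and the perturbation directly sculpts tetranucleotide — OUV —
statistics).  Every row's A+T transition mass is rescaled back to the
target, so realized AT content tracks the target even under strong bias.
A ``repeat_fraction`` of the final length is then produced by copying
earlier segments (geometric lengths, mean 500 bases), each copy inserted
reverse-complemented with probability ``inverted_repeat_fraction``.

All randomness derives from the spec seed through numpy SeedSequence
spawning (one child stream per stage); identical specs give identical
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from grc._rangecoder import canonical_word_table
from grc.io_genomes import GenomeRecord

__all__ = [
    "GenomeSpec",
    "CohortSpec",
    "generate_genome",
    "generate_cohort",
    "write_cohort",
]

_BASES = "ACGT"
_MEAN_REPEAT_LEN = 500
_MIN_REPEAT_LEN = 20


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic genome."""

    length: int
    target_at: float = 0.5
    bias_strength: float = 0.0
    repeat_fraction: float = 0.0
    inverted_repeat_fraction: float = 0.0
    seed: int = 0
    chargaff: bool = True

    def __post_init__(self):
        if self.length < 1000:
            raise ValueError("length must be >= 1000")
        if not 0.0 <= self.target_at <= 1.0:
            raise ValueError("target_at must be in [0, 1]")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        if self.target_at in (0.0, 1.0) and self.bias_strength > 0:
            raise ValueError("target_at of 0 or 1 is infeasible with bias")
        if not 0.0 <= self.repeat_fraction < 1.0:
            raise ValueError("repeat_fraction must be in [0, 1)")
        if not 0.0 <= self.inverted_repeat_fraction <= 1.0:
            raise ValueError("inverted_repeat_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a genome cohort with genus structure.

    Defaults emulate the regimes seen in curated RefSeq-style cohorts:
    sizes log-uniform across 0.1–10 Mb, AT content uniform across
    25–85%, a negative AT–OUV coupling (AT-rich genomes get weaker word
    bias), and a positive size–repeat coupling whose slope varies by
    genus with standard deviation ``genus_slope_sd``.
    """

    n_genera: int = 20
    genomes_per_genus: int = 10
    size_range: tuple[float, float] = (1e5, 1e7)
    at_range: tuple[float, float] = (0.25, 0.85)
    at_ouv_coupling: float = -0.15
    bias_base: float = 0.35
    bias_noise_sd: float = 0.05
    repeat_base: float = 0.15
    size_repeat_slope: float = 0.08
    genus_slope_sd: float = 0.05
    repeat_noise_sd: float = 0.02
    inverted_repeat_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_genera < 2:
            raise ValueError("n_genera must be >= 2 (mixed models need groups)")
        if self.genomes_per_genus < 1:
            raise ValueError("genomes_per_genus must be >= 1")
        if not self.size_range[0] < self.size_range[1]:
            raise ValueError("size_range must be ordered (min < max)")
        if not self.at_range[0] < self.at_range[1]:
            raise ValueError("at_range must be ordered (min < max)")


def _transition_cumulatives(spec: GenomeSpec, rng: np.random.Generator) -> np.ndarray:
    """Cumulative next-base probabilities for each of the 64 3-mer contexts."""
    at, gc = spec.target_at, 1.0 - spec.target_at
    base = np.array([at / 2, gc / 2, gc / 2, at / 2])
    weights = np.tile(base, (64, 1))
    if spec.bias_strength > 0:
        if spec.chargaff:
            # one perturbation per canonical 4-mer keeps the source strand
            # symmetric (a word and its reverse complement equally favored)
            canon = np.asarray(canonical_word_table(4))
            z_canon = rng.normal(size=256)
            z = z_canon[canon].reshape(64, 4)
        else:
            z = rng.normal(size=(64, 4))
        weights = weights * np.exp(spec.bias_strength * z)
    # pin each row's A+T transition mass to the target so realized AT
    # content matches target_at regardless of bias strength
    at_mass = weights[:, [0, 3]].sum(axis=1)
    gc_mass = weights[:, [1, 2]].sum(axis=1)
    probs = weights.copy()
    if at > 0:
        probs[:, [0, 3]] = weights[:, [0, 3] ] / at_mass[:, None] * at
    if gc > 0:
        probs[:, [1, 2]] = weights[:, [1, 2]] / gc_mass[:, None] * gc
    probs /= probs.sum(axis=1, keepdims=True)
    return np.cumsum(probs, axis=1)


def _sample_markov(n: int, cum: np.ndarray, rng: np.random.Generator) -> list[int]:
    u = rng.random(n)
    cum_rows = cum.tolist()
    out: list[int] = []
    ap = out.append
    ctx = 0
    for ui in u:
        row = cum_rows[ctx]
        if ui < row[1]:
            s = 0 if ui < row[0] else 1
        else:
            s = 2 if ui < row[2] else 3
        ap(s)
        ctx = ((ctx << 2) | s) & 63
    return out


def generate_genome(
    spec: GenomeSpec,
    genome_id: str = "synthetic",
    genus: str = "Synthgenus",
    species: str = "Synthgenus synthetica",
) -> GenomeRecord:
    """Generate one genome from its spec; fully reproducible from the seed."""
    ss = np.random.SeedSequence(spec.seed)
    rng_trans, rng_core, rng_rep = (np.random.default_rng(c) for c in ss.spawn(3))
    cum = _transition_cumulatives(spec, rng_trans)
    n_core = max(4, int(round(spec.length * (1.0 - spec.repeat_fraction))))
    codes = _sample_markov(n_core, cum, rng_core)
    comp = {0: 3, 1: 2, 2: 1, 3: 0}
    while len(codes) < spec.length:
        seg_len = _MIN_REPEAT_LEN + int(rng_rep.geometric(1.0 / _MEAN_REPEAT_LEN))
        seg_len = min(seg_len, len(codes), spec.length - len(codes) + _MIN_REPEAT_LEN)
        start = int(rng_rep.integers(0, len(codes) - seg_len + 1))
        segment = codes[start : start + seg_len]
        if rng_rep.random() < spec.inverted_repeat_fraction:
            segment = [comp[c] for c in reversed(segment)]
        codes.extend(segment)
    codes = codes[: spec.length]
    seq = "".join(_BASES[c] for c in codes)
    return GenomeRecord(
        genome_id=genome_id,
        genus=genus,
        species=species,
        sequence=seq,
        length_bases=len(seq),
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[GenomeRecord], pd.DataFrame]:
    """Generate a genus-structured cohort plus its latent-parameter truth table.

    Planted structure: bias_strength (the OUV driver) is coupled to AT
    content with slope ``at_ouv_coupling`` per standardized AT unit, and
    repeat_fraction (the compressibility driver) grows with standardized
    log genome size at a genus-specific slope drawn around
    ``size_repeat_slope`` with sd ``genus_slope_sd``.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    genome_seeds = np.random.SeedSequence(spec.seed).generate_state(
        spec.n_genera * spec.genomes_per_genus + 1
    )[1:]

    log_lo, log_hi = np.log(spec.size_range[0]), np.log(spec.size_range[1])
    at_lo, at_hi = spec.at_range
    at_sd = (at_hi - at_lo) / np.sqrt(12.0)  # sd of the uniform draw
    logsize_sd = (log_hi - log_lo) / np.sqrt(12.0)

    genus_slopes = rng.normal(spec.size_repeat_slope, spec.genus_slope_sd, spec.n_genera)

    records: list[GenomeRecord] = []
    rows = []
    idx = 0
    for g in range(spec.n_genera):
        genus = f"Genus{g:02d}"
        for i in range(spec.genomes_per_genus):
            length = int(round(np.exp(rng.uniform(log_lo, log_hi))))
            target_at = rng.uniform(at_lo, at_hi)
            at_std = (target_at - 0.5 * (at_lo + at_hi)) / at_sd
            logsize_std = (np.log(length) - 0.5 * (log_lo + log_hi)) / logsize_sd
            bias = max(
                0.0,
                spec.bias_base
                + spec.at_ouv_coupling * at_std
                + rng.normal(0.0, spec.bias_noise_sd),
            )
            repeat = float(
                np.clip(
                    spec.repeat_base
                    + genus_slopes[g] * logsize_std
                    + rng.normal(0.0, spec.repeat_noise_sd),
                    0.0,
                    0.8,
                )
            )
            genome_id = f"G{g:02d}_{i:02d}"
            species = f"{genus} sp{i:02d}"
            gspec = GenomeSpec(
                length=max(1000, length),
                target_at=target_at,
                bias_strength=bias,
                repeat_fraction=repeat,
                inverted_repeat_fraction=spec.inverted_repeat_fraction,
                seed=int(genome_seeds[idx]) & 0x7FFFFFFF,
            )
            records.append(generate_genome(gspec, genome_id, genus, species))
            rows.append(
                {
                    "genome_id": genome_id,
                    "genus": genus,
                    "species": species,
                    "length": gspec.length,
                    "target_at": target_at,
                    "bias_strength": bias,
                    "repeat_fraction": repeat,
                    "inverted_repeat_fraction": spec.inverted_repeat_fraction,
                    "genus_size_slope": genus_slopes[g],
                    "seed": gspec.seed,
                }
            )
            idx += 1
    return records, pd.DataFrame(rows)


def write_cohort(
    records: list[GenomeRecord], truth: pd.DataFrame, out_dir: str | Path
) -> dict[str, Path]:
    """Write one FASTA per genome plus metadata and truth TSVs.

    Filenames are deterministic; re-running with the same cohort spec
    produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for rec in records:
        fasta = out_dir / f"{rec.genome_id}.fasta"
        with open(fasta, "w") as fh:
            fh.write(f">{rec.genome_id} {rec.species}\n")
            for i in range(0, rec.length_bases, 80):
                fh.write(rec.sequence[i : i + 80] + "\n")
        meta_rows.append(
            {
                "genome_id": rec.genome_id,
                "species": rec.species,
                "genus": rec.genus,
                "fasta_path": str(fasta),
            }
        )
    meta_path = out_dir / "metadata.tsv"
    truth_path = out_dir / "truth.tsv"
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)
    truth.to_csv(truth_path, sep="\t", index=False)
    return {"metadata": meta_path, "truth": truth_path, "dir": out_dir}
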