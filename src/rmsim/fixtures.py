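"""Synthetic input generation: genomes, communities and quality profiles.

These generators stand in for real assemblies and sequencing runs in tests
and examples.  Genomes are i.i.d. base draws at a target GC content;
optionally, exact enzyme recognition sites are planted at fixed spacing
(and accidental occurrences of the same motifs scrubbed) so that expected
fragment lengths are known in closed form.  Everything is driven by one
seed and is byte-reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (
    IUPAC_SETS,
    CommunityProfile,
    EnzymeMotif,
    GenomeRecord,
    reverse_complement,
    write_fasta,
)
from .digestion import _iupac_pattern

__all__ = [
    "FixtureSpec",
    "generate_genome",
    "generate_genomes",
    "generate_community",
    "generate_quality_profile",
    "write_fixture_set",
]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic community."""

    n_genomes: int = 10
    genome_length: int = 100_000
    gc: float = 0.5
    abundance_model: str = "uniform"  # or "lognormal"
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    planted_sites: list[tuple[EnzymeMotif, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if self.abundance_model not in ("uniform", "lognormal"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _motif_realization(motif: EnzymeMotif) -> str:
    # deterministic concrete instance of a (possibly degenerate) motif
    return "".join(sorted(IUPAC_SETS[ch])[0] for ch in motif.recognition)


def _scrub_accidental_sites(
    seq: list[str],
    motifs: list[EnzymeMotif],
    planted: set[tuple[int, int]],
    rng: np.random.Generator,
    max_rounds: int = 20,
) -> None:
    """Mutate bases so that planted-site motifs occur nowhere but at their
    planted positions (both strands)."""
    planted_starts = {s for s, _ in planted}

    def in_planted(pos: int) -> bool:
        return any(s <= pos < e for s, e in planted)

    patterns = []
    for motif in motifs:
        patterns.append(re.compile("(?=" + _iupac_pattern(motif.recognition) + ")"))
        if not motif.palindromic:
            patterns.append(
                re.compile(
                    "(?=" + _iupac_pattern(reverse_complement(motif.recognition)) + ")"
                )
            )
    for _ in range(max_rounds):
        text = "".join(seq)
        dirty = False
        for pattern, motif in zip(
            patterns,
            [m for m in motifs for _ in range(1 if m.palindromic else 2)],
        ):
            m_len = len(motif.recognition)
            for match in pattern.finditer(text):
                s = match.start()
                if s in planted_starts:
                    continue
                targets = [p for p in range(s, s + m_len) if not in_planted(p)]
                if not targets:
                    continue
                pos = targets[len(targets) // 2]
                old = seq[pos]
                choices = [b for b in "ACGT" if b != old]
                seq[pos] = choices[int(rng.integers(3))]
                dirty = True
        if not dirty:
            return
    raise RuntimeError("could not scrub accidental motif occurrences")


def generate_genome(
    length: int,
    gc: float,
    rng: np.random.Generator,
    planted_sites: list[tuple[EnzymeMotif, int]] | None = None,
    genome_id: str = "g",
    contig_id: str | None = None,
) -> GenomeRecord:
    """One synthetic contig: i.i.d. bases at GC content ``gc``; with
    ``planted_sites`` a concrete instance of each motif is inserted every
    ``spacing`` bp (starting at the spacing offset) and accidental
    occurrences of those motifs are removed, so a complete digest yields
    fragments of exactly ``spacing`` bp between consecutive plants."""
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=length, p=probs)
    seq = list(_BASES[draws].tobytes().decode())
    if planted_sites:
        planted: set[tuple[int, int]] = set()
        for motif, spacing in planted_sites:
            realization = _motif_realization(motif)
            if spacing < len(realization):
                raise ValueError(
                    f"{motif.name}: spacing {spacing} shorter than motif"
                )
            for s in range(spacing, length - len(realization) + 1, spacing):
                seq[s : s + len(realization)] = realization
                planted.add((s, s + len(realization)))
        _scrub_accidental_sites(
            seq, [m for m, _ in planted_sites], planted, rng
        )
    return GenomeRecord(
        id=contig_id or genome_id, sequence="".join(seq), genome_id=genome_id
    )


def generate_genomes(spec: FixtureSpec) -> list[GenomeRecord]:
    """One contig per community member, ids g01, g02, ..."""
    rng = np.random.default_rng(spec.seed)
    return [
        generate_genome(
            spec.genome_length,
            spec.gc,
            rng,
            planted_sites=spec.planted_sites,
            genome_id=f"g{k + 1:02d}",
        )
        for k in range(spec.n_genomes)
    ]


def generate_community(spec: FixtureSpec) -> CommunityProfile:
    """Abundances for ``n_genomes`` taxa under the spec's model."""
    if spec.n_genomes < 2:
        raise ValueError("a community needs at least two genomes")
    rng = np.random.default_rng(spec.seed + 1)
    if spec.abundance_model == "uniform":
        values = np.ones(spec.n_genomes)
    else:
        values = rng.lognormal(
            spec.lognormal_mu, spec.lognormal_sigma, size=spec.n_genomes
        )
    return CommunityProfile(
        [(f"g{k + 1:02d}", float(v)) for k, v in enumerate(values)]
    )


def generate_quality_profile(
    path: str | Path,
    read_length: int,
    q_mean: float,
    q_sd: float,
    n_reads: int,
    seed: int,
) -> Path:
    """Synthetic donor FASTQ whose quality strings are per-position Gaussian
    draws clamped to [0, 41]; serves as a stand-in for a real run's quality
    profile."""
    rng = np.random.default_rng(seed)
    path = Path(path)
    with open(path, "w") as handle:
        for k in range(n_reads):
            q = np.clip(
                np.rint(rng.normal(q_mean, q_sd, size=read_length)), 0, 41
            ).astype(int)
            qual = "".join(chr(33 + v) for v in q)
            seq = _BASES[rng.integers(0, 4, size=read_length)].tobytes().decode()
            handle.write(f"@donor_{k}\n{seq}\n+\n{qual}\n")
    return path


def write_fixture_set(
    outdir: str | Path, spec: FixtureSpec
) -> tuple[list[Path], Path]:
    """Write one FASTA per genome plus the abundance TSV; returns
    (fasta paths, abundance path)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes = generate_genomes(spec)
    profile = generate_community(spec)
    fasta_paths = []
    for rec in genomes:
        path = outdir / f"{rec.genome_id}.fasta"
        write_fasta([rec], path)
        fasta_paths.append(path)
    abundance_path = outdir / "abundances.tsv"
    with open(abundance_path, "w") as handle:
        handle.write("# genome_id\tabundance\n")
        for gid, ab in profile.entries:
            handle.write(f"{gid}\t{ab:.10g}\n")
    return fasta_paths, abundance_path
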