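"""Paired-end read construction: adapters, sampled base qualities and
Phred-driven substitution errors.

Read 1 sequences the insert from its 5' end into the read-1 adapter; read 2
sequences the reverse complement of the insert into the read-2 adapter.
Inserts shorter than the read length therefore produce adapter
read-through, exactly as short ddRAD fragments do on an Illumina machine.
Base qualities are sampled from a donor FASTQ profile and each base is
substituted with probability 10^(-Q/10); the error model is substitutions
only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genome_io import reverse_complement

__all__ = [
    "AdapterSet",
    "QualityProfile",
    "ReadPair",
    "load_quality_profile",
    "build_read_pair",
    "sample_quality",
    "apply_errors",
    "mutate_read_matrix",
    "write_fastq",
    "parse_provenance_header",
    "simulate_read_pairs",
]

_PAD_BASE = "A"  # deterministic, visibly artificial padding


@dataclass
class AdapterSet:
    """Adapter sequence appended 3' of the insert on each mate, plus optional
    per-enzyme overhang remnants prepended to the insert."""

    r1_adapter: str = ""
    r2_adapter: str = ""
    overhangs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seq in (self.r1_adapter, self.r2_adapter, *self.overhangs.values()):
            if set(seq) - set("ACGT"):
                raise ValueError(f"adapter sequence must be over A/C/G/T: {seq!r}")


@dataclass
class QualityProfile:
    """Pool of Phred+33 quality strings harvested from a donor FASTQ."""

    pool: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.pool:
            raise ValueError("quality profile pool is empty")


def load_quality_profile(path: str | Path, read_length: int) -> QualityProfile:
    """Harvest quality strings from a FASTQ file; every entry must be at
    least ``read_length`` long."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    pool: list[str] = []
    with opener(path, "rt") as handle:  # type: ignore[operator]
        for title, _seq, qual in FastqGeneralIterator(handle):
            if len(qual) < read_length:
                raise ValueError(
                    f"{path}: quality string of {title.split()[0]!r} is shorter "
                    f"than read length {read_length}"
                )
            pool.append(qual)
    return QualityProfile(pool=pool, source=str(path))


def build_read_pair(
    fragment_seq: str,
    adapters: AdapterSet,
    read_length: int,
    orientation: str = "+",
    left_enzyme: str | None = None,
    right_enzyme: str | None = None,
) -> tuple[str, str]:
    """Read templates (r1, r2) for one insert.

    Orientation '-' swaps which fragment end seeds read 1.  Templates are
    insert + adapter, truncated to ``read_length`` and padded with 'A' when
    still short.
    """
    if not fragment_seq:
        raise ValueError("empty fragment sequence")
    if orientation == "+":
        insert = fragment_seq
        r1_end, r2_end = left_enzyme, right_enzyme
    elif orientation == "-":
        insert = reverse_complement(fragment_seq)
        r1_end, r2_end = right_enzyme, left_enzyme
    else:
        raise ValueError(f"orientation must be '+' or '-', got {orientation!r}")
    over1 = adapters.overhangs.get(r1_end, "") if r1_end else ""
    over2 = adapters.overhangs.get(r2_end, "") if r2_end else ""
    t1 = over1 + insert + adapters.r1_adapter
    t2 = over2 + reverse_complement(insert) + adapters.r2_adapter
    return (
        t1[:read_length].ljust(read_length, _PAD_BASE),
        t2[:read_length].ljust(read_length, _PAD_BASE),
    )


def sample_quality(
    profile: QualityProfile, read_length: int, rng: np.random.Generator
) -> str:
    """One pool entry chosen uniformly, truncated to the read length."""
    return profile.pool[int(rng.integers(len(profile.pool)))][:read_length]


_BASE_TO_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i
_IDX_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def mutate_read_matrix(
    seqs: np.ndarray, quals: np.ndarray, rng: np.random.Generator
) -> None:
    """In-place substitution errors on a uint8 (n_reads, read_length) byte
    matrix: each A/C/G/T base flips to one of the other three with
    probability 10^(-Q/10); N and padding are left untouched."""
    q = quals.astype(np.float64) - 33.0
    p = np.power(10.0, -q / 10.0)
    idx = _BASE_TO_IDX[seqs]
    hit = (rng.random(seqs.shape) < p) & (idx >= 0)
    if not hit.any():
        return
    shift = rng.integers(1, 4, size=int(hit.sum()))
    seqs[hit] = _IDX_TO_BASE[(idx[hit] + shift) % 4]


def apply_errors(seq: str, qual: str, rng: np.random.Generator) -> str:
    """Substitution error model for a single read (see mutate_read_matrix)."""
    if len(seq) != len(qual):
        raise ValueError("sequence and quality lengths differ")
    mat = np.frombuffer(seq.encode(), dtype=np.uint8).copy().reshape(1, -1)
    qmat = np.frombuffer(qual.encode(), dtype=np.uint8).reshape(1, -1)
    mutate_read_matrix(mat, qmat, rng)
    return mat.tobytes().decode()


@dataclass
class ReadPair:
    """A simulated pair with full provenance of its source fragment."""

    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    provenance: tuple[str, str, int, int, str]  # genome, contig, start, end, orientation


def _provenance_id(pair: ReadPair, serial: int) -> str:
    genome, contig, start, end, orientation = pair.provenance
    return f"{genome}:{contig}:{start}:{end}:{orientation}:{serial}"


def parse_provenance_header(title: str) -> tuple[str, str, int, int, str, int]:
    """Invert the simulator's read-name dialect
    ``genome:contig:start:end:orientation:serial[/mate]``."""
    name = title.split()[0].lstrip("@")
    if name.endswith("/1") or name.endswith("/2"):
        name = name[:-2]
    parts = name.split(":")
    if len(parts) != 6:
        raise ValueError(f"not a provenance read name: {title!r}")
    genome, contig, start, end, orientation, serial = parts
    return genome, contig, int(start), int(end), orientation, int(serial)


def write_fastq(
    pairs: Iterable[ReadPair], out_r1: str | Path, out_r2: str | Path
) -> int:
    """Write mates to two FASTQ files (gzip if the path ends in .gz);
    returns the number of pairs written."""
    n = 0
    buf1: list[str] = []
    buf2: list[str] = []
    for serial, pair in enumerate(pairs):
        rid = _provenance_id(pair, serial)
        buf1.append(f"@{rid}/1\n{pair.r1_seq}\n+\n{pair.r1_qual}\n")
        buf2.append(f"@{rid}/2\n{pair.r2_seq}\n+\n{pair.r2_qual}\n")
        n += 1
    for path, buf in ((Path(out_r1), buf1), (Path(out_r2), buf2)):
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as handle:  # type: ignore[operator]
            handle.write("".join(buf))
    return n


def simulate_read_pairs(
    fragment_counts: Sequence[tuple[object, int]],
    sequences: dict[tuple[str, str], str],
    read_length: int,
    rng: np.random.Generator,
    adapters: AdapterSet | None = None,
    quality_profile: QualityProfile | None = None,
    forward_enzyme: str | None = None,
    mutate: bool = True,
) -> list[ReadPair]:
    """Expand (fragment, count) allocations into mutated read pairs.

    Orientation: double-digest fragments read from the forward-enzyme end
    when ``forward_enzyme`` is given; otherwise (and for same-enzyme
    fragments) orientation is uniform random.  Without a quality profile
    every base gets Q40 ('I').  Substitutions are applied to whole read
    matrices at once for speed.
    """
    if adapters is None:
        adapters = AdapterSet()
    r1_seqs: list[str] = []
    r2_seqs: list[str] = []
    r1_quals: list[str] = []
    r2_quals: list[str] = []
    provenance: list[tuple[str, str, int, int, str]] = []
    const_qual = "I" * read_length
    for frag, count in fragment_counts:
        if count <= 0:
            continue
        contig_seq = sequences[(frag.genome_id, frag.contig_id)]
        insert = contig_seq[frag.start : frag.end]
        left, right = frag.left_enzyme, frag.right_enzyme
        fixed_orientation: str | None = None
        if forward_enzyme is not None and left != right:
            fixed_orientation = "+" if forward_enzyme in left.split(",") else "-"
        for _ in range(count):
            orientation = (
                fixed_orientation
                if fixed_orientation is not None
                else ("+", "-")[int(rng.integers(2))]
            )
            r1, r2 = build_read_pair(
                insert,
                adapters,
                read_length,
                orientation=orientation,
                left_enzyme=left,
                right_enzyme=right,
            )
            r1_seqs.append(r1)
            r2_seqs.append(r2)
            if quality_profile is None:
                r1_quals.append(const_qual)
                r2_quals.append(const_qual)
            else:
                r1_quals.append(sample_quality(quality_profile, read_length, rng))
                r2_quals.append(sample_quality(quality_profile, read_length, rng))
            provenance.append(
                (frag.genome_id, frag.contig_id, frag.start, frag.end, orientation)
            )
    if not r1_seqs:
        return []

    def _to_matrix(strings: list[str]) -> np.ndarray:
        return np.frombuffer("".join(strings).encode(), dtype=np.uint8).reshape(
            len(strings), read_length
        )

    mats = [_to_matrix(r1_seqs), _to_matrix(r2_seqs)]
    qmats = [_to_matrix(r1_quals), _to_matrix(r2_quals)]
    if mutate:
        mats = [m.copy() for m in mats]
        for m, qm in zip(mats, qmats):
            mutate_read_matrix(m, qm, rng)
    m1, m2 = mats
    return [
        ReadPair(
            r1_seq=m1[k].tobytes().decode(),
            r1_qual=r1_quals[k],
            r2_seq=m2[k].tobytes().decode(),
            r2_qual=r2_quals[k],
            provenance=provenance[k],
        )
        for k in range(len(provenance))
    ]
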