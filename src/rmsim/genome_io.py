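"""Input handling: genome FASTA files, community abundance tables and
restriction-enzyme motif definitions.

Genomes are plain or gzipped FASTA, one file per community member
(multi-contig assemblies allowed).  The abundance table is a two-column TSV
mapping genome id to a relative genome-copy number; values are normalised to
sum to one.  Enzyme motifs use IUPAC notation with the cut position marked
by ``/`` (e.g. EcoRI is ``G/AATTC``); type IIB enzymes, which excise a
constant-length fragment around their recognition site, instead carry
upstream/downstream excision offsets.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeRecord",
    "CommunityProfile",
    "EnzymeMotif",
    "IUPAC_SETS",
    "iupac_matches",
    "reverse_complement",
    "load_genomes",
    "write_fasta",
    "load_abundance_table",
    "parse_motif",
    "parse_motif_arg",
]

#: degeneracy sets of the IUPAC nucleotide alphabet
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_AMBIGUOUS = frozenset(IUPAC_SETS) - frozenset("ACGTN")
_FASTA_SUFFIXES = (".fa", ".fasta", ".fna", ".fas")


def iupac_matches(code: str, base: str) -> bool:
    """True iff ``base`` (one of A/C/G/T) is in the degeneracy set of ``code``."""
    if code not in IUPAC_SETS:
        raise ValueError(f"invalid IUPAC code: {code!r}")
    if base not in "ACGT":
        raise ValueError(f"base must be one of A/C/G/T, got {base!r}")
    return base in IUPAC_SETS[code]


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (R<->Y, S<->S, W<->W, K<->M, N<->N)."""
    for ch in seq:
        if ch not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC character {ch!r} in {seq!r}")
    return str(Seq(seq).reverse_complement())


@dataclass
class GenomeRecord:
    """One contig: ``id`` is the first whitespace-delimited FASTA header token,
    ``genome_id`` ties the contig to its source assembly file."""

    id: str
    sequence: str
    genome_id: str = ""

    def __post_init__(self) -> None:
        if not self.genome_id:
            self.genome_id = self.id

    @property
    def length(self) -> int:
        return len(self.sequence)


def _normalize_sequence(raw: str, context: str) -> str:
    seq = raw.upper()
    bad = set(seq) - set(IUPAC_SETS)
    if bad:
        raise ValueError(
            f"{context}: sequence contains non-IUPAC character(s) {sorted(bad)}"
        )
    folded = set(seq) & _AMBIGUOUS
    if folded:
        # degenerate bases carry no cut-site information here; treat as N
        warnings.warn(
            f"{context}: ambiguity codes {sorted(folded)} folded to N", stacklevel=3
        )
        seq = "".join("N" if ch in _AMBIGUOUS else ch for ch in seq)
    return seq


def _genome_id_from_path(path: Path) -> str:
    name = path.name
    if name.endswith(".gz"):
        name = name[:-3]
    for suffix in _FASTA_SUFFIXES:
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return Path(name).stem


def load_genomes(paths: list[str | Path]) -> list[GenomeRecord]:
    """Load FASTA files (plain or gzip), one genome per file.

    Each FASTA entry becomes a :class:`GenomeRecord` whose ``genome_id`` is
    derived from the file name; ordering follows the input order.  Empty
    files, duplicate contig ids within a genome and illegal characters raise
    ``ValueError`` naming the offending file/record.
    """
    records: list[GenomeRecord] = []
    seen: set[tuple[str, str]] = set()
    for raw_path in paths:
        path = Path(raw_path)
        genome_id = _genome_id_from_path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:  # type: ignore[operator]
            entries = list(SeqIO.parse(handle, "fasta"))
        if not entries:
            raise ValueError(f"{path}: no FASTA records found")
        for entry in entries:
            key = (genome_id, entry.id)
            if key in seen:
                raise ValueError(f"{path}: duplicate record id {entry.id!r}")
            seen.add(key)
            seq = _normalize_sequence(str(entry.seq), context=f"{path.name}:{entry.id}")
            if not seq:
                raise ValueError(f"{path}: record {entry.id!r} is empty")
            records.append(GenomeRecord(id=entry.id, sequence=seq, genome_id=genome_id))
    return records


def write_fasta(records: list[GenomeRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:  # type: ignore[operator]
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                handle.write(rec.sequence[i : i + width] + "\n")


@dataclass
class CommunityProfile:
    """Relative genome-copy abundances; normalised to sum to 1 on creation."""

    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        ids = [gid for gid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome ids in community profile")
        for gid, ab in self.entries:
            if not ab > 0:
                raise ValueError(f"abundance for {gid!r} must be positive, got {ab}")
        total = sum(ab for _, ab in self.entries)
        self.entries = [(gid, ab / total) for gid, ab in self.entries]

    @property
    def genome_ids(self) -> list[str]:
        return [gid for gid, _ in self.entries]

    def abundance(self, genome_id: str) -> float:
        for gid, ab in self.entries:
            if gid == genome_id:
                return ab
        raise KeyError(genome_id)

    def as_dict(self) -> dict[str, float]:
        return dict(self.entries)


def load_abundance_table(
    path: str | Path, genomes: list[GenomeRecord] | None = None
) -> CommunityProfile:
    """Read a two-column TSV of (genome_id, abundance); '#' lines are comments.

    Values are genome-copy proportions, not read fractions, and are
    normalised to sum to one.  When ``genomes`` is given every id must match
    a loaded genome.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["genome_id", "abundance"],
        dtype={"genome_id": str},
    )
    if frame.shape[0] == 0:
        raise ValueError(f"{path}: empty abundance table")
    abundances = pd.to_numeric(frame["abundance"], errors="coerce")
    if abundances.isna().any():
        bad = frame.loc[abundances.isna(), "genome_id"].tolist()
        raise ValueError(f"{path}: non-numeric abundance for {bad}")
    if genomes is not None:
        known = {rec.genome_id for rec in genomes}
        unknown = [gid for gid in frame["genome_id"] if gid not in known]
        if unknown:
            raise ValueError(f"{path}: unknown genome id(s) {unknown}")
    return CommunityProfile(list(zip(frame["genome_id"], abundances.astype(float))))


@dataclass(frozen=True)
class EnzymeMotif:
    """A restriction enzyme recognition motif with cut geometry.

    ``cut_offset`` is the top-strand cut position derived from the '/' in
    the motif notation.  Type IIB enzymes cut on both sides of the site,
    excising ``iib_upstream + |recognition| + iib_downstream`` bp.
    """

    name: str
    recognition: str
    cut_offset: int = 0
    kind: str = "standard"
    iib_upstream: int = 0
    iib_downstream: int = 0

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError(f"{self.name}: empty recognition sequence")
        for ch in self.recognition:
            if ch not in IUPAC_SETS:
                raise ValueError(f"{self.name}: invalid IUPAC character {ch!r}")
        if self.kind not in ("standard", "type_iib"):
            raise ValueError(f"{self.name}: unknown enzyme kind {self.kind!r}")
        if self.kind == "standard":
            if not 0 <= self.cut_offset <= len(self.recognition):
                raise ValueError(f"{self.name}: cut offset out of range")
        else:
            if self.iib_upstream < 0 or self.iib_downstream < 0:
                raise ValueError(f"{self.name}: negative type IIB offsets")

    @property
    def palindromic(self) -> bool:
        """True iff the motif equals its own IUPAC reverse complement."""
        return self.recognition == reverse_complement(self.recognition)

    @property
    def excision_length(self) -> int:
        """Fixed fragment length produced by a type IIB enzyme."""
        return self.iib_upstream + len(self.recognition) + self.iib_downstream


def parse_motif(
    spec: str,
    name: str | None = None,
    kind: str = "standard",
    iib_offsets: tuple[int, int] | None = None,
) -> EnzymeMotif:
    """Parse a motif string such as ``"G/AATTC"`` into an :class:`EnzymeMotif`.

    Standard motifs must contain exactly one '/' marking the top-strand cut;
    type IIB motifs contain none and require ``iib_offsets`` (upstream bp,
    downstream bp).
    """
    if kind == "standard":
        if spec.count("/") != 1:
            raise ValueError(
                f"standard motif must contain exactly one '/': {spec!r}"
            )
        cut_offset = spec.index("/")
        recognition = spec.replace("/", "")
        return EnzymeMotif(
            name=name or recognition, recognition=recognition, cut_offset=cut_offset
        )
    if kind == "type_iib":
        if "/" in spec:
            raise ValueError(f"type IIB motif must not contain '/': {spec!r}")
        if iib_offsets is None:
            raise ValueError("type IIB motif requires iib_offsets=(upstream, downstream)")
        up, down = iib_offsets
        return EnzymeMotif(
            name=name or spec,
            recognition=spec,
            kind="type_iib",
            iib_upstream=int(up),
            iib_downstream=int(down),
        )
    raise ValueError(f"unknown enzyme kind {kind!r}")


def parse_motif_arg(text: str) -> EnzymeMotif:
    """Parse a CLI motif argument: ``NAME=G/AATTC`` or
    ``NAME=CGANNNNNNTGC;iib=12,12``."""
    if "=" not in text:
        raise ValueError(f"motif argument must look like NAME=G/AATTC: {text!r}")
    name, rest = text.split("=", 1)
    if ";iib=" in rest:
        spec, offsets = rest.split(";iib=", 1)
        up, down = (int(v) for v in offsets.split(","))
        return parse_motif(spec, name=name, kind="type_iib", iib_offsets=(up, down))
    return parse_motif(rest, name=name)
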