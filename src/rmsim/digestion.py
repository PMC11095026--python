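"""In-silico restriction digestion.

Cut sites are found with overlap-tolerant regex scans (a lookahead match at
every offset), so motifs like HhaI's GCGC are detected even when instances
overlap.  Candidate fragments are every ordered pair of cut positions
within the enumeration window; each is assigned the survival probability

    Pr(fragment) = 1                 if c == 1 and i == 0
                   c^2 (1 - c)^i     otherwise

where c is the per-site enzyme cut efficiency and i the number of uncut
internal recognition sites the fragment spans.  Type IIB (isolength)
enzymes excise a constant-length window around each recognition site and
carry p = c^2 with i = 0.

Coordinates are 0-based half-open throughout; a cut at position p separates
bases p-1 and p on the top strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome_io import IUPAC_SETS, EnzymeMotif, GenomeRecord, reverse_complement
from .size_selection import LengthDistribution

__all__ = [
    "CutSite",
    "DigestionParams",
    "Fragment",
    "find_cut_sites",
    "find_all_cut_sites",
    "fragment_probability",
    "enumerate_fragments",
    "digest_type_iib",
    "digest_genome",
    "build_cut_map",
    "fragments_to_frame",
]


@dataclass(frozen=True)
class CutSite:
    """Top-strand cut location: ``position`` indexes the base immediately
    right of the cut."""

    position: int
    enzyme: str
    strand: str = "+"


@dataclass
class DigestionParams:
    """Digestion model parameters.

    c: per-site cut efficiency in (0, 1].
    length_min/length_max: enumeration window in bp (fragments outside it
        are never candidates for size selection).
    ddrad_strict: keep only fragments whose two ends were cut by different
        enzymes (double-digest chemistry).
    max_internal: cap on internal cut sites i; fragments beyond it carry
        negligible probability c^2 (1-c)^i.
    """

    c: float = 0.9
    length_min: int = 1
    length_max: int = 450
    ddrad_strict: bool = False
    max_internal: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.c <= 1:
            raise ValueError(f"cut efficiency c must be in (0, 1], got {self.c}")
        if self.length_min > self.length_max:
            raise ValueError("length_min must be <= length_max")
        if self.max_internal < 0:
            raise ValueError("max_internal must be >= 0")


@dataclass(frozen=True)
class Fragment:
    """A candidate digestion product [start, end) with its end-enzyme labels,
    internal-cut-site count ``i`` and survival probability ``p``."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str
    i: int
    p: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment start must be < end")
        if not 0 <= self.p <= 1:
            raise ValueError("fragment probability must be in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


def fragment_probability(c: float, i: int) -> float:
    """Survival probability of a fragment with ``i`` internal cut sites at
    cut efficiency ``c``: 1 when c == 1 and i == 0, else c^2 (1-c)^i."""
    if not 0 < c <= 1:
        raise ValueError(f"c must be in (0, 1], got {c}")
    if i < 0:
        raise ValueError(f"i must be >= 0, got {i}")
    if c == 1 and i == 0:
        return 1.0
    return c * c * (1.0 - c) ** i


def _iupac_pattern(motif_seq: str) -> str:
    parts = []
    for ch in motif_seq:
        bases = sorted(IUPAC_SETS[ch])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return "".join(parts)


def _match_starts(sequence: str, motif_seq: str) -> list[int]:
    # lookahead regex -> overlap-tolerant scan; genome 'N' never matches
    # because character classes are built from concrete bases only
    pattern = re.compile("(?=" + _iupac_pattern(motif_seq) + ")")
    return [m.start() for m in pattern.finditer(sequence)]


def find_cut_sites(contig: GenomeRecord, motif: EnzymeMotif) -> list[CutSite]:
    """All cut positions of a standard motif on a contig, overlaps allowed.

    Non-palindromic motifs are additionally scanned as their reverse
    complement; a bottom-strand match at offset s cuts the top strand at
    s + (|m| - cut_offset).  Results are sorted and unique per position.
    """
    if motif.kind != "standard":
        raise ValueError(f"{motif.name}: find_cut_sites requires a standard motif")
    m = len(motif.recognition)
    scans = [(motif.recognition, motif.cut_offset, "+")]
    if not motif.palindromic:
        scans.append((reverse_complement(motif.recognition), m - motif.cut_offset, "-"))
    sites: dict[int, CutSite] = {}
    for seq, offset, strand in scans:
        for s in _match_starts(contig.sequence, seq):
            pos = s + offset
            if pos not in sites:
                sites[pos] = CutSite(position=pos, enzyme=motif.name, strand=strand)
    return [sites[pos] for pos in sorted(sites)]


def find_all_cut_sites(
    contig: GenomeRecord, motifs: list[EnzymeMotif]
) -> list[CutSite]:
    """Merged, position-sorted cut sites of several standard motifs."""
    merged: list[CutSite] = []
    for motif in motifs:
        merged.extend(find_cut_sites(contig, motif))
    return sorted(merged, key=lambda s: (s.position, s.enzyme))


def enumerate_fragments(
    sites: list[CutSite],
    params: DigestionParams,
    genome_id: str = "",
    contig_id: str = "",
) -> list[Fragment]:
    """Fragments between every ordered cut pair within the window.

    For cut positions a < b with i sites strictly between them (i <=
    max_internal) and b - a inside [length_min, length_max], emit a fragment
    with p = Pr(fragment).  With ``ddrad_strict`` fragments whose two ends
    carry only one and the same enzyme are discarded.  Contig-terminal
    pieces (before the first / after the last cut) are never emitted: they
    lack one enzyme-generated adapter-boundary site.
    """
    enzymes_at: dict[int, set[str]] = {}
    for site in sites:
        enzymes_at.setdefault(site.position, set()).add(site.enzyme)
    positions = sorted(enzymes_at)
    fragments: list[Fragment] = []
    for ai, a in enumerate(positions):
        for bi in range(ai + 1, len(positions)):
            b = positions[bi]
            i_internal = bi - ai - 1
            if i_internal > params.max_internal:
                break
            length = b - a
            if length > params.length_max:
                break
            if length < params.length_min:
                continue
            if params.ddrad_strict and len(enzymes_at[a] | enzymes_at[b]) < 2:
                continue
            fragments.append(
                Fragment(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=a,
                    end=b,
                    left_enzyme=",".join(sorted(enzymes_at[a])),
                    right_enzyme=",".join(sorted(enzymes_at[b])),
                    i=i_internal,
                    p=fragment_probability(params.c, i_internal),
                )
            )
    return fragments


def digest_type_iib(
    contig: GenomeRecord, motif: EnzymeMotif, c: float
) -> list[Fragment]:
    """Isolength digestion: each recognition match excises a fixed window
    [s - upstream, s + |m| + downstream); windows crossing contig bounds are
    dropped.  Every fragment has i = 0 and p = c^2."""
    if motif.kind != "type_iib":
        raise ValueError(f"{motif.name}: digest_type_iib requires a type IIB motif")
    if not 0 < c <= 1:
        raise ValueError(f"c must be in (0, 1], got {c}")
    m = len(motif.recognition)
    scans = [(motif.recognition, motif.iib_upstream, motif.iib_downstream)]
    if not motif.palindromic:
        # bottom-strand site: upstream/downstream swap in top-strand coordinates
        scans.append(
            (reverse_complement(motif.recognition), motif.iib_downstream, motif.iib_upstream)
        )
    intervals: set[tuple[int, int]] = set()
    for seq, up, down in scans:
        for s in _match_starts(contig.sequence, seq):
            start, end = s - up, s + m + down
            if start < 0 or end > contig.length:
                continue
            intervals.add((start, end))
    p = 1.0 if c == 1 else c * c
    return [
        Fragment(
            genome_id=contig.genome_id,
            contig_id=contig.id,
            start=start,
            end=end,
            left_enzyme=motif.name,
            right_enzyme=motif.name,
            i=0,
            p=p,
        )
        for start, end in sorted(intervals)
    ]


def digest_genome(
    contigs: GenomeRecord | list[GenomeRecord],
    motifs: list[EnzymeMotif],
    params: DigestionParams,
) -> tuple[list[Fragment], LengthDistribution]:
    """Digest one genome (all its contigs, each as a linear molecule).

    Returns the fragment list and the expected per-single-genome-copy
    length distribution D_g(x) = sum of p over fragments of length x.
    """
    if isinstance(contigs, GenomeRecord):
        contigs = [contigs]
    if not motifs:
        raise ValueError("at least one enzyme motif is required")
    kinds = {motif.kind for motif in motifs}
    if kinds == {"type_iib"}:
        if len(motifs) != 1:
            raise ValueError("type IIB digestion supports a single enzyme")
    elif "type_iib" in kinds:
        raise ValueError("cannot mix standard and type IIB enzymes in one digest")
    fragments: list[Fragment] = []
    for contig in contigs:
        if kinds == {"type_iib"}:
            fragments.extend(digest_type_iib(contig, motifs[0], params.c))
        else:
            sites = find_all_cut_sites(contig, motifs)
            fragments.extend(
                enumerate_fragments(
                    sites, params, genome_id=contig.genome_id, contig_id=contig.id
                )
            )
    dist = LengthDistribution()
    for frag in fragments:
        dist.add(frag.length, frag.p)
    return fragments, dist


def build_cut_map(
    contigs: list[GenomeRecord], motifs: list[EnzymeMotif]
) -> dict[tuple[str, str], list[int]]:
    """Sorted unique cut positions per (genome_id, contig_id); for type IIB
    enzymes the excision boundaries serve as the expected endpoints."""
    cut_map: dict[tuple[str, str], list[int]] = {}
    for contig in contigs:
        positions: set[int] = set()
        for motif in motifs:
            if motif.kind == "type_iib":
                for frag in digest_type_iib(contig, motif, c=1.0):
                    positions.add(frag.start)
                    positions.add(frag.end)
            else:
                positions.update(s.position for s in find_cut_sites(contig, motif))
        cut_map[(contig.genome_id, contig.id)] = sorted(positions)
    return cut_map


def fragments_to_frame(fragments: list[Fragment]) -> pd.DataFrame:
    """Fragment table (genome, contig, start, end, length, end enzymes, i, p)."""
    return pd.DataFrame(
        {
            "genome_id": [f.genome_id for f in fragments],
            "contig_id": [f.contig_id for f in fragments],
            "start": [f.start for f in fragments],
            "end": [f.end for f in fragments],
            "length": [f.length for f in fragments],
            "left_enzyme": [f.left_enzyme for f in fragments],
            "right_enzyme": [f.right_enzyme for f in fragments],
            "i": [f.i for f in fragments],
            "p": [f.p for f in fragments],
        }
    )
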