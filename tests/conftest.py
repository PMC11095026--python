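"""Shared fixtures and naive reference implementations (oracles).

The oracles deliberately use the dumbest possible algorithms — test every
offset for a motif match, test every cut pair for a fragment — so they are
independent of the regex/windowed implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from rmsim.digestion import DigestionParams, fragment_probability
from rmsim.genome_io import EnzymeMotif, iupac_matches, parse_motif, reverse_complement


@pytest.fixture
def ecori() -> EnzymeMotif:
    return parse_motif("G/AATTC", name="EcoRI")


@pytest.fixture
def msei() -> EnzymeMotif:
    return parse_motif("T/TAA", name="MseI")


@pytest.fixture
def hhai() -> EnzymeMotif:
    return parse_motif("GCG/C", name="HhaI")


@pytest.fixture
def agei() -> EnzymeMotif:
    return parse_motif("A/CCGGT", name="AgeI")


def oracle_match_starts(sequence: str, motif_seq: str) -> list[int]:
    """Every offset where the motif matches, by per-base IUPAC comparison."""
    m = len(motif_seq)
    starts = []
    for s in range(len(sequence) - m + 1):
        ok = True
        for k in range(m):
            base = sequence[s + k]
            if base not in "ACGT" or not iupac_matches(motif_seq[k], base):
                ok = False
                break
        if ok:
            starts.append(s)
    return starts


def oracle_cut_positions(sequence: str, motif: EnzymeMotif) -> list[int]:
    """All top-strand cut positions, scanning both strands of
    non-palindromic motifs."""
    m = len(motif.recognition)
    positions = {
        s + motif.cut_offset for s in oracle_match_starts(sequence, motif.recognition)
    }
    if not motif.palindromic:
        rc = reverse_complement(motif.recognition)
        positions |= {
            s + (m - motif.cut_offset) for s in oracle_match_starts(sequence, rc)
        }
    return sorted(positions)


def oracle_fragments(
    positions_with_enzymes: dict[int, set[str]], params: DigestionParams
) -> set[tuple[int, int, int, float]]:
    """Brute force over every ordered cut pair: (start, end, i, p)."""
    positions = sorted(positions_with_enzymes)
    out = set()
    for ai, a in enumerate(positions):
        for bi in range(ai + 1, len(positions)):
            b = positions[bi]
            i = bi - ai - 1
            if i > params.max_internal:
                continue
            if not params.length_min <= b - a <= params.length_max:
                continue
            if params.ddrad_strict and len(
                positions_with_enzymes[a] | positions_with_enzymes[b]
            ) < 2:
                continue
            out.add((a, b, i, fragment_probability(params.c, i)))
    return out


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])
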