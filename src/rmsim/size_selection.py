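"""Size selection: combine per-genome digests by abundance, intersect the
combined fragment-length distribution with a Gaussian (or custom) envelope,
and allocate the total read budget across surviving fragments.

The size-selection model follows gel-based selection hardware: the digest
distribution D(x) is intersected with a Gaussian density anchored so that
the curve passes through D at the anchor length (default mu - sigma, i.e.
100 bp for the mu=150/sigma=50 default).  "Intersection" is the pointwise
minimum S(x) = min(D(x), k*phi(x)) — the envelope can only remove
fragments, never inflate a length class beyond what digestion produced.
"""

from __future__ import annotations

import json
import math
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "LengthDistribution",
    "SizeSelectionParams",
    "SimulationConfig",
    "combine_by_abundance",
    "gaussian_envelope",
    "envelope_curve",
    "allocate_reads",
    "largest_remainder",
]


class LengthDistribution(Mapping):
    """Mapping of fragment length (bp) -> non-negative expected count/weight.

    Missing lengths read as 0.  ``support`` lists lengths with positive
    weight in ascending order.
    """

    def __init__(self, weights: Mapping[int, float] | None = None) -> None:
        self._weights: dict[int, float] = {}
        if weights:
            for length, w in weights.items():
                length = int(length)
                w = float(w)
                if w < 0:
                    raise ValueError(f"negative weight {w} at length {length}")
                if not math.isfinite(w):
                    raise ValueError(f"non-finite weight at length {length}")
                if w > 0:
                    self._weights[length] = self._weights.get(length, 0.0) + w

    def __getitem__(self, length: int) -> float:
        return self._weights.get(int(length), 0.0)

    def __iter__(self) -> Iterator[int]:
        return iter(sorted(self._weights))

    def __len__(self) -> int:
        return len(self._weights)

    def __contains__(self, length: object) -> bool:
        return int(length) in self._weights  # type: ignore[arg-type]

    def __eq__(self, other: object) -> bool:
        if isinstance(other, LengthDistribution):
            return self._weights == other._weights
        return NotImplemented

    def __repr__(self) -> str:
        return f"LengthDistribution({len(self._weights)} lengths, total={self.total:.4g})"

    @property
    def support(self) -> list[int]:
        return sorted(self._weights)

    @property
    def total(self) -> float:
        return sum(self._weights.values())

    def add(self, length: int, weight: float) -> None:
        if weight < 0:
            raise ValueError("negative weight")
        if weight > 0:
            self._weights[int(length)] = self._weights.get(int(length), 0.0) + weight

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump({str(k): v for k, v in sorted(self._weights.items())}, handle)

    @classmethod
    def from_json(cls, path: str | Path) -> "LengthDistribution":
        with open(path) as handle:
            raw = json.load(handle)
        return cls({int(k): float(v) for k, v in raw.items()})


@dataclass
class SizeSelectionParams:
    """Gaussian envelope parameters: mean/sd in bp; ``anchor_length`` fixes
    the length where the envelope touches the digest distribution ("auto" =
    round(mean - sd)).  ``custom_weights`` replaces the Gaussian with an
    arbitrary observed length distribution (e.g. a re-simulation from a
    JSON file extracted from real alignments)."""

    mean: float = 150.0
    sd: float = 50.0
    anchor_length: int | str = "auto"
    custom_weights: LengthDistribution | None = None

    def __post_init__(self) -> None:
        if self.custom_weights is None and not self.sd > 0:
            raise ValueError("sd must be positive in Gaussian mode")


@dataclass
class SimulationConfig:
    """Read-budget configuration: ``n`` total read pairs, sequenced read
    length, master seed, and the allocation rounding mode."""

    n: int
    read_length: int = 150
    seed: int = 1
    rounding: str = "multinomial"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.rounding not in ("multinomial", "largest_remainder"):
            raise ValueError(f"unknown rounding mode {self.rounding!r}")


def combine_by_abundance(
    per_genome: Mapping[str, Sequence],
    profile,
) -> tuple[LengthDistribution, list[tuple[object, float]]]:
    """Scale each genome's fragments by its proportional abundance.

    ``per_genome`` maps genome id -> fragment list (objects with ``length``
    and survival probability ``p``).  Returns the combined distribution
    D(x) = sum of p*abundance at each length, plus the flat weighted
    fragment list in input order.
    """
    combined = LengthDistribution()
    weighted: list[tuple[object, float]] = []
    for genome_id, abundance in profile.entries:
        if genome_id not in per_genome:
            raise KeyError(f"genome {genome_id!r} was not digested")
        for frag in per_genome[genome_id]:
            w = frag.p * abundance
            weighted.append((frag, w))
            combined.add(frag.length, w)
    return combined, weighted


def _resolve_anchor(D: LengthDistribution, params: SizeSelectionParams) -> int:
    if params.anchor_length != "auto":
        anchor = int(params.anchor_length)
        if D[anchor] <= 0:
            raise ValueError(f"anchor length {anchor} has no digest weight")
        return anchor
    target = round(params.mean - params.sd)
    if D[target] > 0:
        return target
    support = D.support
    if not support:
        raise ValueError("empty digest distribution")
    return min(support, key=lambda x: (abs(x - target), x))


def envelope_curve(
    D: LengthDistribution, params: SizeSelectionParams
) -> tuple[dict[int, float], int]:
    """Anchored envelope values k*phi(x) (or k*W(x)) on D's support, plus the
    anchor length used."""
    anchor = _resolve_anchor(D, params)
    support = D.support
    if params.custom_weights is not None:
        W = params.custom_weights
        if W[anchor] <= 0:
            raise ValueError(f"custom weights are zero at anchor length {anchor}")
        k = D[anchor] / W[anchor]
        env = {x: k * W[x] for x in support}
    else:
        dens = norm.pdf(np.asarray(support, dtype=float), params.mean, params.sd)
        k = D[anchor] / norm.pdf(float(anchor), params.mean, params.sd)
        env = {x: k * d for x, d in zip(support, dens)}
    return env, anchor


def gaussian_envelope(
    D: LengthDistribution, params: SizeSelectionParams
) -> LengthDistribution:
    """Size-selected distribution S(x) = min(D(x), envelope(x)) on D's support."""
    env, _ = envelope_curve(D, params)
    return LengthDistribution({x: min(D[x], env[x]) for x in D.support})


def largest_remainder(n: int, probs: np.ndarray) -> np.ndarray:
    """Deterministic apportionment of ``n`` among ``probs`` (sum to 1):
    floor(n*q) plus one unit to the largest fractional remainders, ties
    broken by lowest index."""
    exact = n * probs
    base = np.floor(exact).astype(np.int64)
    short = n - int(base.sum())
    if short:
        frac = exact - base
        order = np.argsort(-frac, kind="stable")
        base[order[:short]] += 1
    return base


def allocate_reads(
    S: LengthDistribution,
    weighted_fragments: Sequence[tuple[object, float]],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Divide the read budget ``config.n`` over fragments.

    Each fragment of length x gets sampling probability proportional to
    weight * S(x)/D(x), where D is recomputed from the weighted fragment
    list; counts sum to n exactly in both rounding modes.
    """
    if not weighted_fragments:
        raise ValueError("no fragments to allocate reads to")
    lengths = np.array([f.length for f, _ in weighted_fragments], dtype=np.int64)
    weights = np.array([w for _, w in weighted_fragments], dtype=float)
    D: dict[int, float] = {}
    for x, w in zip(lengths, weights):
        D[int(x)] = D.get(int(x), 0.0) + w
    ratio = np.array(
        [min(1.0, S[int(x)] / D[int(x)]) if D[int(x)] > 0 else 0.0 for x in lengths]
    )
    q = weights * ratio
    Z = q.sum()
    if Z <= 0:
        raise ValueError("size selection removed all fragments (Z = 0)")
    q /= Z
    if config.rounding == "multinomial":
        if rng is None:
            rng = np.random.default_rng(config.seed)
        return rng.multinomial(config.n, q)
    return largest_remainder(config.n, q)
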