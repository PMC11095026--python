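"""Feature extraction from observed fragment counts: enzyme cut-efficiency
estimation and an empirical fragment-length distribution.

Under partial digestion a fully digested fragment [a, b) and the larger
fragment immediately encompassing it ([a', b) or [a, b')) have expected
counts proportional to c^2 and c^2 (1 - c); their count ratio r therefore
satisfies r = 1/(1 - c), inverted as

    c = (r - 1) / r    for 1 < r < inf
    c = 1              for complete digestion (no encompassing fragments)

Many observed pairs are aggregated with a robust statistic (median by
default) before inversion.  Only inner fragments within an estimation
window (default 100-450 bp) are used: lengths there are least distorted by
size selection.
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .size_selection import LengthDistribution

__all__ = [
    "EncompassmentPair",
    "CutEfficiencyEstimate",
    "find_encompassment_pairs",
    "estimate_cut_efficiency",
    "extract_length_distribution",
]

DEFAULT_WINDOW = (100, 450)
DEFAULT_MIN_INNER_COUNT = 5


@dataclass(frozen=True)
class EncompassmentPair:
    """A fully digested fragment and an observed fragment immediately
    encompassing it, with their count ratio r = count(inner)/count(outer)."""

    inner: tuple[str, str, int, int]
    outer: tuple[str, str, int, int]
    r: float


@dataclass(frozen=True)
class CutEfficiencyEstimate:
    """Result of cut-efficiency estimation.

    ``status`` is one of 'estimated', 'complete_digestion' (no
    encompassment pairs observed: c = 1) or 'inestimable' (pairs exist but
    none has r > 1)."""

    c: float
    status: str
    r_hat: float | None
    n_pairs: int


def _fragment_i(cuts: list[int], start: int, end: int, context: str) -> int:
    lo = bisect_left(cuts, start)
    if lo >= len(cuts) or cuts[lo] != start:
        raise ValueError(f"{context}: start {start} is not an expected cut position")
    hi = bisect_left(cuts, end)
    if hi >= len(cuts) or cuts[hi] != end:
        raise ValueError(f"{context}: end {end} is not an expected cut position")
    return hi - lo - 1


def find_encompassment_pairs(
    table: pd.DataFrame,
    cut_map: dict[tuple[str, str], list[int]],
    window: tuple[int, int] = DEFAULT_WINDOW,
    min_inner_count: float = DEFAULT_MIN_INNER_COUNT,
) -> list[EncompassmentPair]:
    """Pair each observed fully digested fragment with its observed
    encompassing fragments.

    ``table`` needs columns genome_id, contig_id, start, end, read_count;
    every endpoint must be a cut position in ``cut_map``.  Inner fragments
    must have no internal cuts, length inside ``window`` and a count of at
    least ``min_inner_count``; outers are the one-cut extensions [a', b)
    and [a, b') with observed count > 0.
    """
    counts: dict[tuple[str, str, int, int], float] = {}
    for row in table.itertuples(index=False):
        counts[(row.genome_id, row.contig_id, int(row.start), int(row.end))] = float(
            row.read_count
        )
    lo_len, hi_len = window
    pairs: list[EncompassmentPair] = []
    for key, count in counts.items():
        genome_id, contig_id, start, end = key
        if (genome_id, contig_id) not in cut_map:
            raise ValueError(f"no cut map for contig {genome_id}:{contig_id}")
        cuts = cut_map[(genome_id, contig_id)]
        i = _fragment_i(cuts, start, end, context=f"{genome_id}:{contig_id}")
        if i != 0 or count < min_inner_count:
            continue
        if not lo_len <= end - start <= hi_len:
            continue
        s_idx = bisect_left(cuts, start)
        e_idx = bisect_left(cuts, end)
        outer_keys = []
        if s_idx > 0:
            outer_keys.append((genome_id, contig_id, cuts[s_idx - 1], end))
        if e_idx + 1 < len(cuts):
            outer_keys.append((genome_id, contig_id, start, cuts[e_idx + 1]))
        for outer in outer_keys:
            outer_count = counts.get(outer, 0.0)
            if outer_count > 0:
                pairs.append(
                    EncompassmentPair(inner=key, outer=outer, r=count / outer_count)
                )
    return pairs


def estimate_cut_efficiency(
    pairs: list[EncompassmentPair], statistic: str = "median"
) -> CutEfficiencyEstimate:
    """Aggregate pair ratios into one r-hat and invert to c = (r-1)/r.

    Only ratios with r > 1 are informative (the model forces the inner
    fragment to be more frequent).  No pairs at all means complete
    digestion and returns c = 1 exactly.
    """
    if not pairs:
        return CutEfficiencyEstimate(
            c=1.0, status="complete_digestion", r_hat=None, n_pairs=0
        )
    ratios = [p.r for p in pairs if p.r > 1]
    if not ratios:
        return CutEfficiencyEstimate(
            c=math.nan, status="inestimable", r_hat=None, n_pairs=len(pairs)
        )
    if statistic == "median":
        r_hat = float(np.median(ratios))
    elif statistic == "mean":
        r_hat = float(np.mean(ratios))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return CutEfficiencyEstimate(
        c=(r_hat - 1.0) / r_hat, status="estimated", r_hat=r_hat, n_pairs=len(pairs)
    )


def extract_length_distribution(table: pd.DataFrame) -> LengthDistribution:
    """Observed fragment-length distribution: weights(x) = total read count
    over fragments of length x.  Export with
    :meth:`LengthDistribution.to_json` to re-simulate from it."""
    if table.shape[0] == 0:
        raise ValueError("empty fragment count table")
    lengths = (table["end"] - table["start"]).astype(int)
    sums = table["read_count"].groupby(lengths).sum()
    if float(sums.sum()) == 0:
        warnings.warn("all fragment counts are zero; empty length distribution")
        return LengthDistribution()
    return LengthDistribution({int(x): float(w) for x, w in sums.items() if w > 0})
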