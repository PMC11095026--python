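"""Fixed-length taxonomic ratio (FLTR) abundance estimation.

Restriction digests give every taxon its own fragment-length profile, and
size selection / amplification bias read depth by length, so raw mean or
median depth misestimates relative abundance.  Within one discrete
fragment length, however, depth ratios between taxa are bias-free.  FLTR
therefore: (1) recreates source fragments from read pairs and keeps only
those whose endpoints coincide exactly with expected cut positions and
which span no internal cut site; (2) computes per-taxon mean depth at each
fragment length; (3) averages pairwise depth ratios over lengths into an
n x n ratio matrix; (4) scales its columns to the taxon with the most
relationships and row-averages into relative abundances.

If depths factor as d(t, L) = a_t * s(L) for any length bias s, FLTR
recovers a exactly, whatever each taxon's length profile looks like.
"""

from __future__ import annotations

import gzip
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .sequencing import parse_provenance_header

__all__ = [
    "recreate_fragments",
    "recreate_from_provenance",
    "recreate_from_sam",
    "depth_by_length",
    "compute_ratio_matrix",
    "FltrResult",
    "fltr_estimate",
    "baseline_estimates",
]

_FRAGMENT_KEY = ["genome_id", "contig_id", "start", "end"]


def _is_expected_interval(
    cuts: list[int], start: int, end: int
) -> tuple[bool, int]:
    """(endpoints are expected cut positions, number of internal cuts)."""
    lo = bisect_left(cuts, start)
    if lo >= len(cuts) or cuts[lo] != start:
        return False, -1
    hi = bisect_left(cuts, end)
    if hi >= len(cuts) or cuts[hi] != end:
        return False, -1
    return True, hi - lo - 1


def _counter_to_table(counter: Counter) -> pd.DataFrame:
    rows = [
        {"genome_id": g, "contig_id": c, "start": s, "end": e, "i": i, "read_count": n}
        for (g, c, s, e, i), n in sorted(counter.items())
    ]
    return pd.DataFrame(
        rows, columns=_FRAGMENT_KEY + ["i", "read_count"]
    )


def recreate_from_provenance(
    r1_path: str | Path,
    cut_map: dict[tuple[str, str], list[int]],
    keep_internal: bool = False,
) -> pd.DataFrame:
    """Recreate source fragments from the simulator's provenance read names.

    Keeps a pair only when both fragment endpoints coincide exactly with
    expected cut positions and (unless ``keep_internal``, used for
    cut-efficiency estimation) the fragment spans no internal cut site.
    """
    path = Path(r1_path)
    opener = gzip.open if path.suffix == ".gz" else open
    counter: Counter = Counter()
    with opener(path, "rt") as handle:  # type: ignore[operator]
        for title, _seq, _qual in FastqGeneralIterator(handle):
            genome, contig, start, end, _orientation, _serial = parse_provenance_header(
                title
            )
            if (genome, contig) not in cut_map:
                raise ValueError(f"unknown reference {genome}:{contig} in {path}")
            ok, i = _is_expected_interval(cut_map[(genome, contig)], start, end)
            if ok and (keep_internal or i == 0):
                counter[(genome, contig, start, end, i)] += 1
    return _counter_to_table(counter)


def recreate_from_sam(
    sam_path: str | Path,
    cut_map: dict[tuple[str, str], list[int]],
    ref_to_genome: Mapping[str, tuple[str, str]] | None = None,
    keep_internal: bool = False,
) -> pd.DataFrame:
    """Recreate source fragments from paired alignments.

    A pair survives when both mates are mapped to the same reference in
    proper (forward/reverse) orientation with MAPQ > 0 on both mates, the
    implied fragment [leftmost start, rightmost end) has both endpoints on
    expected cut positions, and no expected cut lies strictly inside.
    ``ref_to_genome`` maps SAM reference names to (genome_id, contig_id);
    by default the reference name serves as both.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    counter: Counter = Counter()
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for read in sam:
            if read.is_unmapped or not read.is_paired or read.is_secondary or read.is_supplementary:
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            if mate.reference_name != read.reference_name:
                continue
            if read.mapping_quality == 0 or mate.mapping_quality == 0:
                continue
            if read.is_reverse == mate.is_reverse:
                continue  # not forward/reverse oriented
            fwd, rev = (mate, read) if read.is_reverse else (read, mate)
            if fwd.reference_start > rev.reference_start:
                continue  # mates face away from each other
            start = min(read.reference_start, mate.reference_start)
            end = max(read.reference_end, mate.reference_end)
            ref = read.reference_name
            if ref_to_genome is not None:
                if ref not in ref_to_genome:
                    raise ValueError(f"unknown reference name {ref!r}")
                genome, contig = ref_to_genome[ref]
            else:
                genome = contig = ref
            if (genome, contig) not in cut_map:
                raise ValueError(f"no cut map for reference {genome}:{contig}")
            ok, i = _is_expected_interval(cut_map[(genome, contig)], start, end)
            if ok and (keep_internal or i == 0):
                counter[(genome, contig, start, end, i)] += 1
    return _counter_to_table(counter)


def recreate_fragments(
    source: str | Path,
    cut_map: dict[tuple[str, str], list[int]],
    ref_to_genome: Mapping[str, tuple[str, str]] | None = None,
    keep_internal: bool = False,
) -> pd.DataFrame:
    """Dispatch on file type: .sam -> alignment mode, otherwise provenance
    FASTQ mode."""
    name = Path(source).name
    if name.endswith(".sam"):
        return recreate_from_sam(
            source, cut_map, ref_to_genome=ref_to_genome, keep_internal=keep_internal
        )
    return recreate_from_provenance(source, cut_map, keep_internal=keep_internal)


def _merge_expected_observed(
    observed: pd.DataFrame, expected: pd.DataFrame, taxon_of: Mapping[str, str]
) -> pd.DataFrame:
    expected = expected[_FRAGMENT_KEY].drop_duplicates().copy()
    unmapped = sorted(set(expected["genome_id"]) - set(taxon_of))
    if unmapped:
        raise ValueError(f"genome(s) without taxon mapping: {unmapped}")
    if observed.shape[0]:
        merged = expected.merge(
            observed[_FRAGMENT_KEY + ["read_count"]], on=_FRAGMENT_KEY, how="left"
        )
        merged["read_count"] = merged["read_count"].fillna(0.0)
    else:
        merged = expected
        merged["read_count"] = 0.0
    merged["taxon"] = merged["genome_id"].map(taxon_of)
    merged["length"] = merged["end"] - merged["start"]
    return merged


def depth_by_length(
    observed: pd.DataFrame,
    expected: pd.DataFrame,
    taxon_of: Mapping[str, str],
) -> pd.DataFrame:
    """Mean per-fragment read depth per (taxon, length).

    ``expected`` lists the enumerable fully digested fragments (the
    denominator population); expected fragments with no observed reads
    count as zeros.  Returns a taxa x lengths frame with NaN where a taxon
    has no expected fragments of that length.  Observed fragments outside
    the expected set are ignored (they failed recreation filters upstream).
    """
    merged = _merge_expected_observed(observed, expected, taxon_of)
    grouped = merged.groupby(["taxon", "length"])["read_count"].agg(["sum", "size"])
    depth = (grouped["sum"] / grouped["size"]).unstack("length")
    return depth


def compute_ratio_matrix(depth: pd.DataFrame) -> pd.DataFrame:
    """Average pairwise depth ratios over shared lengths.

    R[i, j] = mean over lengths L (both taxa have expected fragments and
    d(j, L) > 0) of d(i, L)/d(j, L); NaN when no such length exists;
    diagonal 1.
    """
    taxa = list(depth.index)
    if len(taxa) < 2:
        raise ValueError("ratio matrix needs at least two taxa")
    R = pd.DataFrame(np.nan, index=taxa, columns=taxa, dtype=float)
    for i in taxa:
        R.loc[i, i] = 1.0
        di = depth.loc[i]
        for j in taxa:
            if i == j:
                continue
            dj = depth.loc[j]
            mask = di.notna() & dj.notna() & (dj > 0)
            if mask.any():
                R.loc[i, j] = float((di[mask] / dj[mask]).mean())
    return R


@dataclass
class FltrResult:
    """FLTR output: normalised abundances over quantified taxa, the taxa
    that could not be placed relative to the reference, the reference taxon
    and the (scaled) ratio matrices."""

    abundances: pd.Series
    unquantified: list[str]
    reference: str
    ratio_matrix: pd.DataFrame
    scaled_matrix: pd.DataFrame


def _impute_reference_row(R: pd.DataFrame, k: str) -> pd.Series:
    """Fill missing R[k, j] by multiplying ratios along a shortest path of
    defined entries from k to j (optional behaviour)."""
    row = R.loc[k].copy()
    dist = {k: 1.0}
    frontier = [k]
    while frontier:
        nxt = []
        for u in frontier:
            for v in R.columns:
                if v in dist or pd.isna(R.loc[u, v]):
                    continue
                # R[k,u] * R[u,v] approximates R[k,v]
                dist[v] = dist[u] * float(R.loc[u, v])
                nxt.append(v)
        frontier = nxt
    for j, val in dist.items():
        if pd.isna(row[j]):
            row[j] = val
    return row


def fltr_estimate(R: pd.DataFrame, impute_paths: bool = False) -> FltrResult:
    """Scale the ratio matrix to the best-connected taxon and row-average.

    The reference k is the taxon with the most defined off-diagonal row
    entries (ties: first in input order).  Each column j with R[k, j]
    defined is divided by R[k, j], putting all entries in units of
    "relative to k"; columns lacking R[k, j] are excluded.  Row means over
    defined scaled entries, normalised to sum 1, are the abundances; taxa
    with no defined scaled entry are reported as unquantified.
    """
    if R.shape[0] == 0:
        raise ValueError("empty ratio matrix")
    relationships = R.notna().sum(axis=1) - 1  # diagonal is always defined
    k = relationships.idxmax()  # idxmax keeps the first maximum -> input order
    ref_row = _impute_reference_row(R, k) if impute_paths else R.loc[k]
    included = [j for j in R.columns if pd.notna(ref_row[j])]
    scaled = R[included].div(ref_row[included].astype(float), axis=1)
    means = scaled.mean(axis=1, skipna=True)
    quantified = means.notna()
    unquantified = list(means.index[~quantified])
    abundances = means[quantified] / means[quantified].sum()
    return FltrResult(
        abundances=abundances,
        unquantified=unquantified,
        reference=str(k),
        ratio_matrix=R,
        scaled_matrix=scaled,
    )


def baseline_estimates(
    observed: pd.DataFrame,
    expected: pd.DataFrame,
    taxon_of: Mapping[str, str],
) -> pd.DataFrame:
    """Mean-depth and median-depth abundance baselines.

    Per taxon, the mean (median) read count over its distinct expected
    fragments, each vector normalised to sum 1.  These are the estimators
    FLTR is designed to outperform when fragment-length bias differs
    between taxa.
    """
    merged = _merge_expected_observed(observed, expected, taxon_of)
    stats = merged.groupby("taxon")["read_count"].agg(["mean", "median"])
    out = pd.DataFrame(
        {
            "mean_depth": stats["mean"] / stats["mean"].sum(),
            "median_depth": stats["median"] / stats["median"].sum()
            if stats["median"].sum() > 0
            else np.nan,
            "n_fragments": merged.groupby("taxon").size(),
        }
    )
    return out
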