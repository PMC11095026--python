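import numpy as np
import pandas as pd
import pysam
import pytest

from rmsim.fltr import (
    baseline_estimates,
    compute_ratio_matrix,
    depth_by_length,
    fltr_estimate,
    recreate_fragments,
    recreate_from_provenance,
    recreate_from_sam,
)

CUT_MAP = {("g1", "c1"): [1, 5, 9]}


def _fastq(tmp_path, headers):
    path = tmp_path / "r1.fastq"
    path.write_text("".join(f"@{h}/1\nACGT\n+\nIIII\n" for h in headers))
    return path


class TestRecreateFromProvenance:
    def test_internal_cut_fragments_dropped(self, tmp_path):
        path = _fastq(tmp_path, ["g1:c1:1:9:+:0"])
        table = recreate_from_provenance(path, CUT_MAP)
        assert table.shape[0] == 0

    def test_clean_fragment_kept_and_counted(self, tmp_path):
        path = _fastq(tmp_path, ["g1:c1:1:5:+:0", "g1:c1:1:5:-:1", "g1:c1:5:9:+:2"])
        table = recreate_from_provenance(path, CUT_MAP)
        counts = {(r.start, r.end): r.read_count for r in table.itertuples()}
        assert counts == {(1, 5): 2, (5, 9): 1}
        assert (table["i"] == 0).all()

    def test_endpoints_off_cut_positions_dropped(self, tmp_path):
        path = _fastq(tmp_path, ["g1:c1:2:5:+:0", "g1:c1:1:6:+:1"])
        table = recreate_from_provenance(path, CUT_MAP)
        assert table.shape[0] == 0

    def test_keep_internal_retains_encompassing_fragments(self, tmp_path):
        path = _fastq(tmp_path, ["g1:c1:1:9:+:0", "g1:c1:1:5:+:1"])
        table = recreate_from_provenance(path, CUT_MAP, keep_internal=True)
        assert set(zip(table["start"], table["end"], table["i"])) == {(1, 9, 1), (1, 5, 0)}

    def test_unknown_reference_rejected(self, tmp_path):
        path = _fastq(tmp_path, ["gX:c1:1:5:+:0"])
        with pytest.raises(ValueError, match="unknown reference"):
            recreate_from_provenance(path, CUT_MAP)

    def test_dispatch_by_extension(self, tmp_path):
        path = _fastq(tmp_path, ["g1:c1:1:5:+:0"])
        assert recreate_fragments(path, CUT_MAP).shape[0] == 1


def _write_sam(path, reads):
    header = {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": [{"SN": "c1", "LN": 1000}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, start, cigar, reverse, mapq, mate_start in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.query_sequence = "A" * 50
            a.query_qualities = pysam.qualitystring_to_array("I" * 50)
            a.reference_id = 0
            a.reference_start = start
            a.cigarstring = cigar
            a.mapping_quality = mapq
            a.is_paired = True
            a.is_reverse = reverse
            a.is_proper_pair = True
            a.next_reference_id = 0
            a.next_reference_start = mate_start
            out.write(a)


class TestRecreateFromSam:
    CUTS = {("c1", "c1"): [100, 250, 400]}

    def test_proper_pair_spanning_cuts_kept(self, tmp_path):
        path = tmp_path / "aln.sam"
        _write_sam(
            path,
            [
                ("p1", 100, "50M", False, 60, 200),
                ("p1", 200, "50M", True, 60, 100),
            ],
        )
        table = recreate_from_sam(path, self.CUTS)
        assert table.shape[0] == 1
        row = table.iloc[0]
        assert (row.start, row.end, row.read_count) == (100, 250, 1)

    def test_mapq_zero_pair_removed(self, tmp_path):
        path = tmp_path / "aln.sam"
        _write_sam(
            path,
            [
                ("p1", 100, "50M", False, 60, 200),
                ("p1", 200, "50M", True, 0, 100),
            ],
        )
        assert recreate_from_sam(path, self.CUTS).shape[0] == 0

    def test_same_strand_pair_removed(self, tmp_path):
        path = tmp_path / "aln.sam"
        _write_sam(
            path,
            [
                ("p1", 100, "50M", False, 60, 200),
                ("p1", 200, "50M", False, 60, 100),
            ],
        )
        assert recreate_from_sam(path, self.CUTS).shape[0] == 0

    def test_fragment_with_internal_cut_removed(self, tmp_path):
        path = tmp_path / "aln.sam"
        _write_sam(
            path,
            [
                ("p1", 100, "50M", False, 60, 350),
                ("p1", 350, "50M", True, 60, 100),
            ],
        )
        # implied fragment [100, 400) spans the cut at 250
        assert recreate_from_sam(path, self.CUTS).shape[0] == 0


def _expected(rows):
    return pd.DataFrame(rows, columns=["genome_id", "contig_id", "start", "end"])


def _observed(rows):
    return pd.DataFrame(
        rows, columns=["genome_id", "contig_id", "start", "end", "read_count"]
    )


IDENTITY = {"x": "x", "y": "y", "z": "z"}


class TestDepthByLength:
    def test_mean_depth_per_expected_fragment(self):
        expected = _expected([("x", "c", 0, 100), ("x", "c", 200, 300)])
        observed = _observed([("x", "c", 0, 100, 8), ("x", "c", 200, 300, 12)])
        depth = depth_by_length(observed, expected, {"x": "x", "y": "y"})
        assert depth.loc["x", 100] == pytest.approx(10.0)

    def test_missing_length_is_nan(self):
        expected = _expected([("x", "c", 0, 100), ("y", "c", 0, 250)])
        observed = _observed([("x", "c", 0, 100, 5), ("y", "c", 0, 250, 5)])
        depth = depth_by_length(observed, expected, {"x": "x", "y": "y"})
        assert np.isnan(depth.loc["x", 250])
        assert np.isnan(depth.loc["y", 100])

    def test_zero_count_expected_fragments_dilute_the_mean(self):
        expected = _expected(
            [("x", "c", 0, 100), ("x", "c", 200, 300), ("x", "c", 400, 500)]
        )
        observed = _observed([("x", "c", 0, 100, 9)])
        depth = depth_by_length(observed, expected, {"x": "x"})
        assert depth.loc["x", 100] == pytest.approx(3.0)

    def test_unmapped_genome_rejected(self):
        expected = _expected([("x", "c", 0, 100)])
        with pytest.raises(ValueError, match="taxon"):
            depth_by_length(_observed([]), expected, {})


class TestRatioMatrix:
    def test_averaged_pairwise_ratios(self):
        depth = pd.DataFrame(
            {100: [10.0, 20.0, 10.0], 200: [5.0, 10.0, np.nan]},
            index=["x", "y", "z"],
        )
        R = compute_ratio_matrix(depth)
        assert R.loc["y", "x"] == pytest.approx(2.0)  # mean(2, 2)
        assert R.loc["x", "z"] == pytest.approx(1.0)
        assert R.loc["x", "x"] == 1.0

    def test_single_shared_length_is_plain_ratio(self):
        depth = pd.DataFrame({100: [4.0, 16.0]}, index=["x", "y"])
        R = compute_ratio_matrix(depth)
        assert R.loc["x", "y"] == pytest.approx(0.25)

    def test_disjoint_supports_leave_nan(self):
        depth = pd.DataFrame(
            {100: [4.0, np.nan], 200: [np.nan, 2.0]}, index=["x", "y"]
        )
        R = compute_ratio_matrix(depth)
        assert np.isnan(R.loc["x", "y"]) and np.isnan(R.loc["y", "x"])


class TestFltrEstimate:
    def test_two_taxa_from_single_ratio(self):
        R = pd.DataFrame(
            [[1.0, 1 / 3], [3.0, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        result = fltr_estimate(R)
        assert result.abundances["a"] == pytest.approx(0.25)
        assert result.abundances["b"] == pytest.approx(0.75)

    def test_one_to_two_to_one_scenario(self):
        # taxa at 1:2:1 with a shared, skewed length bias; z misses a length
        s = {100: 10.0, 200: 1.0}
        a = {"x": 1.0, "y": 2.0, "z": 1.0}
        depth = pd.DataFrame(
            {
                100: [a[t] * s[100] for t in "xyz"],
                200: [a["x"] * s[200], a["y"] * s[200], np.nan],
            },
            index=list("xyz"),
        )
        result = fltr_estimate(compute_ratio_matrix(depth))
        assert result.abundances.values == pytest.approx([0.25, 0.5, 0.25], abs=1e-9)

    def test_isolated_taxon_reported_unquantified(self):
        depth = pd.DataFrame(
            {
                100: [2.0, 4.0, np.nan],
                200: [1.0, 2.0, np.nan],
                300: [np.nan, np.nan, 7.0],
            },
            index=["x", "y", "w"],
        )
        result = fltr_estimate(compute_ratio_matrix(depth))
        assert result.unquantified == ["w"]
        assert result.abundances.sum() == pytest.approx(1.0)
        assert result.abundances["y"] == pytest.approx(2 / 3)

    def test_path_imputation_recovers_chain_taxa(self):
        # co-occurrence chain a-b-c-d-e; reference is b, so the far end e
        # only co-occurs with d, whose column lacks a reference ratio —
        # e is unquantified unless ratios are chained along the path
        depth = pd.DataFrame(
            {
                100: [1.0, 2.0, np.nan, np.nan, np.nan],
                200: [np.nan, 1.0, 3.0, np.nan, np.nan],
                300: [np.nan, np.nan, 1.0, 4.0, np.nan],
                400: [np.nan, np.nan, np.nan, 1.0, 5.0],
            },
            index=list("abcde"),
        )
        R = compute_ratio_matrix(depth)
        plain = fltr_estimate(R)
        assert plain.reference == "b"
        assert plain.unquantified == ["e"]
        imputed = fltr_estimate(R, impute_paths=True)
        assert imputed.unquantified == []
        # chained truth: within-chain abundances scale 1:2:6:24:120
        assert imputed.abundances["e"] / imputed.abundances["d"] == pytest.approx(5.0)

    def test_exact_recovery_under_shared_length_bias(self):
        rng = np.random.default_rng(42)
        taxa = [f"t{k}" for k in range(8)]
        lengths = list(range(100, 400, 20))
        truth = pd.Series(rng.lognormal(0, 1, len(taxa)), index=taxa)
        truth /= truth.sum()
        s = pd.Series(rng.lognormal(0, 0.8, len(lengths)), index=lengths)
        depth = pd.DataFrame(index=taxa, columns=lengths, dtype=float)
        for t in taxa:
            support = rng.choice(lengths, size=8, replace=False)
            for L in support:
                depth.loc[t, L] = truth[t] * s[L]
            depth.loc[t, lengths[0]] = truth[t] * s[lengths[0]]  # shared anchor length
        result = fltr_estimate(compute_ratio_matrix(depth))
        assert result.unquantified == []
        est = result.abundances.reindex(taxa)
        assert est.values == pytest.approx(truth.values, abs=1e-9)

    def test_scale_invariance_at_one_length(self):
        depth = pd.DataFrame(
            {100: [2.0, 4.0], 200: [1.0, 2.0]}, index=["x", "y"]
        )
        scaled = depth.copy()
        scaled[200] *= 37.0
        a = fltr_estimate(compute_ratio_matrix(depth)).abundances
        b = fltr_estimate(compute_ratio_matrix(scaled)).abundances
        assert a.values == pytest.approx(b.values)

    def test_permutation_equivariance(self):
        depth = pd.DataFrame(
            {100: [2.0, 4.0, 6.0], 200: [1.0, 2.0, 3.0]}, index=["x", "y", "z"]
        )
        a = fltr_estimate(compute_ratio_matrix(depth)).abundances
        perm = depth.reindex(["z", "x", "y"])
        b = fltr_estimate(compute_ratio_matrix(perm)).abundances
        for t in "xyz":
            assert b[t] == pytest.approx(a[t])


class TestBaselines:
    def test_mean_and_median_per_taxon(self):
        expected = _expected(
            [("x", "c", 0, 100), ("x", "c", 200, 300), ("y", "c", 0, 50)]
        )
        observed = _observed(
            [("x", "c", 0, 100, 10), ("x", "c", 200, 300, 2), ("y", "c", 0, 50, 6)]
        )
        out = baseline_estimates(observed, expected, {"x": "x", "y": "y"})
        assert out.loc["x", "mean_depth"] == pytest.approx(0.5)
        assert out.loc["x", "median_depth"] == pytest.approx(0.5)
        assert out.loc["x", "n_fragments"] == 2

    def test_fig3_style_bias_breaks_baselines_but_not_fltr(self):
        # shared bias s, different supports: FLTR exact, mean depth off >= 10%
        s = {100: 10.0, 200: 1.0}
        rows_exp, rows_obs = [], []
        specs = {"x": [100, 200], "y": [100, 200], "z": [100]}
        a = {"x": 1.0, "y": 2.0, "z": 1.0}
        for t, supp in specs.items():
            for L in supp:
                rows_exp.append((t, "c", 1000 * L, 1000 * L + L))
                rows_obs.append((t, "c", 1000 * L, 1000 * L + L, a[t] * s[L]))
        expected, observed = _expected(rows_exp), _observed(rows_obs)
        depth = depth_by_length(observed, expected, IDENTITY)
        fltr = fltr_estimate(compute_ratio_matrix(depth)).abundances
        truth = pd.Series(a) / sum(a.values())
        assert fltr.reindex(truth.index).values == pytest.approx(truth.values, abs=1e-9)
        base = baseline_estimates(observed, expected, IDENTITY)
        rel_err = (base["mean_depth"].reindex(truth.index) - truth).abs() / truth
        assert rel_err.max() >= 0.10
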