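"""Alignment ingest, read-window assignment and bias-curve statistics."""

import numpy as np
import pandas as pd
import pytest

from gcbias.coverage import (
    AlignmentSet,
    BiasCurve,
    assign_reads_to_windows,
    bias_curve,
    fold_change,
    load_alignments,
    locus_representation,
    per_base_coverage,
    pool_curves,
    quality_mask,
    reads_per_bin,
    under_coverage_fraction,
)
from gcbias.genome import ReferenceSet, gc_histogram, window_gc


def make_aln(rows):
    """rows: (contig, start, aligned_length[, mean_quality])."""
    recs = pd.DataFrame(
        [
            (r[0], r[1], r[2], 60, r[3] if len(r) > 3 else 35.0,
             True, False, False)
            for r in rows
        ],
        columns=["contig", "start", "aligned_length", "mapq", "mean_quality",
                 "is_mapped", "is_secondary", "is_duplicate"],
    )
    return AlignmentSet(recs)


@pytest.fixture
def stepped_ref():
    """20 tiled 50-bp windows: ten at 30% GC then ten at 50% GC."""
    block30 = "G" * 15 + "A" * 35
    block50 = "G" * 25 + "A" * 25
    return ReferenceSet([("c", block30 * 10 + block50 * 10)])


class TestLoadAlignments:
    def test_sam_cigar_reference_length(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:c\tLN:100\n"
            "r1\t0\tc\t11\t60\t10M1I10M\t*\t0\t0\t"
            + "A" * 21 + "\t" + "I" * 21 + "\n"
        )
        aln = load_alignments(sam)
        rec = aln.records.iloc[0]
        assert rec["aligned_length"] == 20  # insertion consumes no reference
        assert rec["start"] == 10  # SAM 1-based -> internal 0-based

    def test_tsv_row(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "contig\tstart0\taligned_length\tmapq\tmean_qual\n"
            "chr1\t100\t101\t60\t35.0\n"
        )
        aln = load_alignments(p)
        assert len(aln) == 1
        assert aln.records.iloc[0]["start"] == 100
        assert aln.records.iloc[0]["is_mapped"]

    def test_tsv_skips_malformed_rows(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "contig\tstart0\taligned_length\tmapq\tmean_qual\n"
            "chr1\t100\t101\t60\t35.0\n"
            "chr1\tnot_a_number\t101\t60\t35.0\n"
        )
        aln = load_alignments(p)
        assert len(aln) == 1
        assert aln.n_skipped == 1

    def test_flagged_reads_not_usable(self):
        recs = pd.DataFrame(
            {
                "contig": ["c"] * 3,
                "start": [0, 0, 0],
                "aligned_length": [50] * 3,
                "mapq": [60] * 3,
                "mean_quality": [35.0] * 3,
                "is_mapped": [True, True, False],
                "is_secondary": [False, True, False],
                "is_duplicate": [False, False, False],
            }
        )
        assert len(AlignmentSet(recs).usable) == 1


class TestAssignment:
    def test_midpoint_rule_on_tiled_grid(self, stepped_ref):
        wins = window_gc(stepped_ref, 50, 50)
        # read [100, 201): midpoint base 100 + (101-1)//2 = 150 -> window 3
        aln = make_aln([("c", 100, 101)])
        idx, counts, dropped = assign_reads_to_windows(aln, wins)
        assert counts[3] == 1
        assert counts.sum() == 1
        assert dropped == 0

    def test_read_within_single_window(self, stepped_ref):
        wins = window_gc(stepped_ref, 50, 50)
        aln = make_aln([("c", 210, 30)])
        _, counts, _ = assign_reads_to_windows(aln, wins)
        assert counts[4] == 1

    def test_contig_mismatch_reported(self, stepped_ref):
        wins = window_gc(stepped_ref, 50, 50)
        with pytest.raises(ValueError, match="chrX"):
            assign_reads_to_windows(make_aln([("chrX", 0, 50)]), wins)

    @pytest.mark.parametrize("step", [50, 1, 7])
    def test_matches_bruteforce_midpoint_assignment(self, rng, step):
        seq = "".join(rng.choice(list("ACGTN"), size=2000, p=[0.24] * 4 + [0.04]))
        ref = ReferenceSet([("c", seq)])
        wins = window_gc(ref, 50, step)
        n_reads = 10_000
        starts = rng.integers(0, 1900, size=n_reads)
        lengths = rng.integers(30, 102, size=n_reads)
        aln = make_aln([("c", int(s), int(l)) for s, l in zip(starts, lengths)])
        idx, counts, dropped = assign_reads_to_windows(aln, wins)

        wstarts = wins["start"].to_numpy()
        wvalid = wins["valid"].to_numpy()
        brute = np.zeros(len(wins), dtype=int)
        n_drop = 0
        for s, l in zip(starts, lengths):
            mid = s + (l - 1) // 2
            best, best_d = -1, None
            for i, ws in enumerate(wstarts):
                if ws <= mid < ws + 50 and wvalid[i]:
                    d = abs(ws + 24.5 - mid)
                    if best_d is None or d < best_d:
                        best, best_d = i, d
            if best < 0:
                n_drop += 1
            else:
                brute[best] += 1
        assert dropped == n_drop
        np.testing.assert_array_equal(counts, brute)


class TestBiasCurve:
    def test_equal_ratios_give_unity(self):
        obs = pd.Series({40.0: 100, 50.0: 100})
        hist = pd.Series({40.0: 10, 50.0: 10})
        curve = bias_curve(obs, hist, anchor=[50.0])
        assert curve.value(40.0) == 1.0
        assert curve.value(50.0) == 1.0

    def test_hand_arithmetic_example(self):
        obs = pd.Series({20.0: 25, 50.0: 100, 80.0: 10})
        hist = pd.Series({20.0: 5, 50.0: 10, 80.0: 5})
        curve = bias_curve(obs, hist, anchor=[50.0])
        assert curve.value(20.0) == pytest.approx(0.5)
        assert curve.value(50.0) == pytest.approx(1.0)
        assert curve.value(80.0) == pytest.approx(0.2)

    def test_anchor_mean_is_one_exactly(self, rng):
        bins = [float(b) for b in range(0, 102, 2)]
        obs = pd.Series(rng.integers(1, 1000, len(bins)).astype(int), index=bins)
        hist = pd.Series(rng.integers(1, 500, len(bins)).astype(int), index=bins)
        curve = bias_curve(obs, hist)
        anchor_vals = [curve.value(b) for b in (48.0, 50.0, 52.0)]
        assert np.mean(anchor_vals) == pytest.approx(1.0, rel=1e-12)

    def test_zero_read_bins_kept_as_zero(self):
        obs = pd.Series({50.0: 10})
        hist = pd.Series({50.0: 10, 80.0: 5})
        curve = bias_curve(obs, hist, anchor=[50.0])
        assert curve.value(80.0) == 0.0

    def test_empty_anchor_is_error(self):
        obs = pd.Series({50.0: 0, 80.0: 5})
        hist = pd.Series({50.0: 10, 80.0: 5})
        with pytest.raises(ValueError, match="anchor undefined"):
            bias_curve(obs, hist, anchor=[50.0])

    def test_tsv_round_trip(self, tmp_path):
        obs = pd.Series({20.0: 25, 50.0: 100, 80.0: 10})
        hist = pd.Series({20.0: 5, 50.0: 10, 80.0: 5})
        curve = bias_curve(obs, hist, anchor=[50.0])
        p = tmp_path / "c.tsv"
        curve.to_tsv(p, {"seed": 1})
        back = BiasCurve.from_tsv(p)
        assert back.anchor_bins == (50.0,)
        pd.testing.assert_frame_equal(back.table, curve.table)


class TestPerBaseCoverage:
    def test_single_full_read(self):
        ref = ReferenceSet([("c", "ACGTACGTAC")])
        prof = per_base_coverage(make_aln([("c", 0, 10)]), ref)
        assert (prof.counts["c"] == 1).all()
        assert prof.genome_mean == 1.0

    def test_overlapping_reads(self):
        ref = ReferenceSet([("c", "ACGTACGTAC")])
        prof = per_base_coverage(make_aln([("c", 0, 6), ("c", 4, 6)]), ref)
        np.testing.assert_array_equal(
            prof.counts["c"], [1, 1, 1, 1, 2, 2, 1, 1, 1, 1]
        )

    def test_matches_bruteforce_tally(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        ref = ReferenceSet([("c", seq)])
        rows = [
            ("c", int(s), int(l))
            for s, l in zip(rng.integers(0, 400, 100), rng.integers(1, 100, 100))
        ]
        prof = per_base_coverage(make_aln(rows), ref)
        brute = np.zeros(500, dtype=int)
        for _, s, l in rows:
            brute[s : s + l] += 1
        np.testing.assert_array_equal(prof.counts["c"], brute)


class TestUnderCoverage:
    def test_uniform_coverage_has_none(self):
        ref = ReferenceSet([("c", "A" * 100)])
        prof = per_base_coverage(make_aln([("c", 0, 100)] * 10), ref)
        assert under_coverage_fraction(prof) == 0.0

    def test_hand_arithmetic(self):
        # 80 bases at 10x, 20 at 0x: mean 8, threshold 0.8, fraction 0.20
        ref = ReferenceSet([("c", "A" * 100)])
        prof = per_base_coverage(make_aln([("c", 0, 80)] * 10), ref)
        assert prof.genome_mean == 8.0
        assert under_coverage_fraction(prof, 0.1) == pytest.approx(0.20)

    def test_threshold_is_strict(self):
        # every base exactly at threshold -> not under-covered
        ref = ReferenceSet([("c", "A" * 10)])
        prof = per_base_coverage(make_aln([("c", 0, 10)]), ref)
        assert under_coverage_fraction(prof, 1.0) == 0.0

    def test_no_coverage_is_error(self):
        ref = ReferenceSet([("c", "A" * 10)])
        prof = per_base_coverage(make_aln([]), ref)
        with pytest.raises(ValueError, match="no coverage"):
            under_coverage_fraction(prof)

    def test_ambiguous_bases_excluded(self):
        ref = ReferenceSet([("c", "A" * 50 + "N" * 50)])
        prof = per_base_coverage(make_aln([("c", 0, 50)]), ref)
        assert prof.genome_mean == 1.0
        assert under_coverage_fraction(prof) == 0.0


class TestLocusRepresentation:
    def test_uniform_coverage_unity(self):
        ref = ReferenceSet([("c", "A" * 100)])
        prof = per_base_coverage(make_aln([("c", 0, 100)] * 4), ref)
        rep = locus_representation(prof, [("c", 10, 20), ("c", 50, 80)])
        assert (rep == 1.0).all()

    def test_enriched_locus(self):
        # coverage 2 on [0,50), 0 elsewhere: mean 1, locus at 2x the mean
        ref = ReferenceSet([("c", "A" * 100)])
        prof = per_base_coverage(make_aln([("c", 0, 50)] * 2), ref)
        rep = locus_representation(prof, [("c", 0, 50)])
        assert rep.iloc[0] == pytest.approx(2.0)

    def test_pooled_is_length_weighted(self):
        # coverage 2/6/1/2 on [0,10)/[10,20)/[20,60)/[60,100): mean 2.0
        ref = ReferenceSet([("c", "A" * 100)])
        reads = (
            [("c", 0, 10)] * 2 + [("c", 10, 10)] * 6
            + [("c", 20, 40)] + [("c", 60, 40)] * 2
        )
        prof = per_base_coverage(make_aln(reads), ref)
        assert prof.genome_mean == 2.0
        per = locus_representation(prof, [("c", 0, 10), ("c", 10, 20)])
        assert list(per.round(6)) == [1.0, 3.0]
        pooled = locus_representation(
            prof, [("c", 0, 10), ("c", 10, 20)], mode="pooled"
        )
        assert pooled == pytest.approx(2.0)  # equal-length loci: plain mean

    def test_empty_locus_is_error(self):
        ref = ReferenceSet([("c", "A" * 100)])
        prof = per_base_coverage(make_aln([("c", 0, 100)]), ref)
        with pytest.raises(ValueError, match="empty locus"):
            locus_representation(prof, [("c", 5, 5)])


class TestQualityMask:
    def _curve(self, ref, aln):
        wins = window_gc(ref, 50, 50)
        hist = gc_histogram(wins)
        _, counts, _ = assign_reads_to_windows(aln, wins)
        return wins, bias_curve(reads_per_bin(wins, counts), hist, anchor=[30.0])

    def test_good_quality_unmasked(self, stepped_ref):
        aln = make_aln([("c", i * 50, 50, 35.0) for i in range(20)])
        wins, curve = self._curve(stepped_ref, aln)
        masked = quality_mask(aln, wins, curve)
        assert not masked.table["masked"].any()

    def test_boundary_bin_masked(self, stepped_ref):
        # 50%-GC windows get Q19.9 reads: strictly below Q20 -> masked
        aln = make_aln(
            [("c", i * 50, 50, 35.0) for i in range(10)]
            + [("c", 500 + i * 50, 50, 19.9) for i in range(10)]
        )
        wins, curve = self._curve(stepped_ref, aln)
        masked = quality_mask(aln, wins, curve)
        t = masked.table.set_index("bin_percent")
        assert not t.loc[30.0, "masked"]
        assert t.loc[50.0, "masked"]
        assert "Q20" in t.loc[50.0, "mask_reason"]

    def test_zero_read_bin_masked_with_reason(self, stepped_ref):
        aln = make_aln([("c", i * 50, 50, 35.0) for i in range(10)])
        wins, curve = self._curve(stepped_ref, aln)
        masked = quality_mask(aln, wins, curve)
        t = masked.table.set_index("bin_percent")
        assert t.loc[50.0, "masked"]
        assert t.loc[50.0, "mask_reason"] == "no reads"

    def test_mask_matches_bruteforce_bin_means(self, rng, stepped_ref):
        wins = window_gc(stepped_ref, 50, 50)
        rows = []
        for _ in range(500):
            s = int(rng.integers(0, 950))
            rows.append(("c", s, 50, float(rng.uniform(10, 40))))
        aln = make_aln(rows)
        hist = gc_histogram(wins)
        _, counts, _ = assign_reads_to_windows(aln, wins)
        curve = bias_curve(reads_per_bin(wins, counts), hist, anchor=[30.0])
        masked = quality_mask(aln, wins, curve)
        # brute-force per-bin mean of per-read means via the midpoint rule
        sums, ns = {}, {}
        for c, s, l, q in rows:
            mid = s + (l - 1) // 2
            w = mid // 50
            b = 30.0 if w < 10 else 50.0
            sums[b] = sums.get(b, 0.0) + q
            ns[b] = ns.get(b, 0) + 1
        t = masked.table.set_index("bin_percent")
        for b in (30.0, 50.0):
            assert t.loc[b, "mean_quality"] == pytest.approx(sums[b] / ns[b])
            assert t.loc[b, "masked"] == (sums[b] / ns[b] < 20.0)


class TestFoldChangeAndPooling:
    def _simple_curve(self, values, anchor=(50.0,)):
        bins = sorted(values)
        table = pd.DataFrame(
            {
                "bin_percent": bins,
                "observed_reads": 100,
                "expected_windows": 100,
                "relative_value": [values[b] for b in bins],
                "masked": False,
                "mask_reason": "",
                "mean_quality": np.nan,
            }
        )
        return BiasCurve(table, tuple(anchor))

    def test_self_ratio_is_unity(self):
        a = self._simple_curve({50.0: 1.0, 80.0: 0.5})
        fc = fold_change(a, a)
        assert (fc["fold_change"] == 1.0).all()

    def test_hand_example(self):
        a = self._simple_curve({50.0: 1.0, 80.0: 0.5})
        b = self._simple_curve({50.0: 1.0, 80.0: 0.25})
        fc = fold_change(a, b).set_index("bin_percent")
        assert fc.loc[80.0, "fold_change"] == pytest.approx(2.0)

    def test_zero_denominator_flagged(self):
        a = self._simple_curve({50.0: 1.0, 80.0: 0.5})
        b = self._simple_curve({50.0: 1.0, 80.0: 0.0})
        fc = fold_change(a, b).set_index("bin_percent")
        assert fc.loc[80.0, "undefined"]

    def test_disjoint_bins_error(self):
        a = self._simple_curve({40.0: 1.0}, anchor=(40.0,))
        b = self._simple_curve({60.0: 1.0}, anchor=(40.0,))
        with pytest.raises(ValueError, match="disjoint"):
            fold_change(a, b)

    def test_anchor_mismatch_error(self):
        a = self._simple_curve({50.0: 1.0})
        b = self._simple_curve({50.0: 1.0}, anchor=(48.0, 50.0, 52.0))
        with pytest.raises(ValueError, match="anchor"):
            fold_change(a, b)

    def test_pooling_set_with_itself_is_identity(self, stepped_ref):
        wins = window_gc(stepped_ref, 50, 50)
        hist = gc_histogram(wins)
        aln = make_aln(
            [("c", i * 50, 50) for i in range(10)]
            + [("c", 500 + i * 50, 50) for i in range(5)]
        )
        _, counts, _ = assign_reads_to_windows(aln, wins)
        single = bias_curve(reads_per_bin(wins, counts), hist, anchor=[30.0])
        pooled = pool_curves([aln, aln], wins, hist, anchor=[30.0])
        np.testing.assert_allclose(
            pooled.table["relative_value"], single.table["relative_value"]
        )
        fc = fold_change(pooled, single)
        np.testing.assert_allclose(fc["fold_change"], 1.0)

    def test_pooling_is_count_level_not_curve_average(self, stepped_ref):
        # A: bins {30%:0.2, 50%:1.0}; B: {1.0, 1.0} at equal anchor depth
        # pooled counts give 120/200 = 0.6, not the curve average 0.6...
        wins = window_gc(stepped_ref, 50, 50)
        hist = gc_histogram(wins)

        def spread(n, offset):
            # n reads spread over the ten windows starting at offset
            return [("c", offset + (i % 10) * 50, 50) for i in range(n)]

        a = make_aln(spread(20, 0) + spread(100, 500))
        b = make_aln(spread(100, 0) + spread(100, 500))
        curve_a = pool_curves([a, a], wins, hist, anchor=[50.0])  # sanity only
        pooled = pool_curves([a, b], wins, hist, anchor=[50.0])
        assert pooled.value(30.0) == pytest.approx(0.6)
        assert pooled.value(50.0) == pytest.approx(1.0)
        # pooled value lies between the inputs' values
        assert 0.2 <= pooled.value(30.0) <= 1.0
        assert curve_a.value(30.0) == pytest.approx(0.2)

    def test_dialect_equivalence_sam_vs_tsv(self, tmp_path, rng):
        from gcbias.simulate import (
            SimConfig,
            emit_reads,
            fragment_genome,
            scaled_per_reference,
            write_sam,
            write_truth_tsv,
        )

        ref = scaled_per_reference(0.002, rng)
        pool = fragment_genome(ref, 3000, rng_seed=rng)
        cfg = SimConfig(rng_seed=5, n_reads=2000)
        _, truth = emit_reads(pool[pool["length"] >= 101], ref, cfg, rng)
        write_truth_tsv(truth, tmp_path / "r.tsv")
        write_sam(truth, ref, tmp_path / "r.sam")
        wins = window_gc(ref, 50, 50)
        hist = gc_histogram(wins)
        curves = []
        for name in ("r.tsv", "r.sam"):
            aln = load_alignments(tmp_path / name)
            _, counts, _ = assign_reads_to_windows(aln, wins)
            curves.append(bias_curve(reads_per_bin(wins, counts), hist))
        pd.testing.assert_frame_equal(curves[0].table, curves[1].table)
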