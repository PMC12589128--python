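import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from screg import peaks as pk
from screg import synth
from screg._types import FragmentTable, PeakSet


def _frags(rows):
    return FragmentTable(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])
    )


class TestPrecluster:
    def test_recovers_planted_clusters(self, small_world):
        genome, truth, frags = small_world
        cl = dict(zip(genome.chrom_names, genome.chrom_lengths))
        labels = pk.precluster(frags, bin_size=2000, chrom_lengths=cl, seed=0)
        barcodes = sorted(frags.records["barcode"].unique())
        true = [truth.cluster_of_nucleus[b] for b in barcodes]
        assert len(set(labels)) >= 3
        assert adjusted_rand_score(true, labels) > 0.8

    def test_high_detection_bins_excluded(self):
        # a bin detected in 70% of nuclei is over the 60% ceiling
        rng = np.random.default_rng(0)
        rows = []
        for i in range(20):
            # bin 0 (0-1000) hit by 70% of nuclei; bin 5 hit by half
            if i < 14:
                rows.append(("chr1", 100, 200, f"B{i}", 1))
            if i % 2 == 0:
                rows.append(("chr1", 5100, 5200, f"B{i}", 1))
            rows.append(("chr1", 9000 + i * 7, 9050 + i * 7, f"B{i}", 1))
        frags = _frags(rows)
        mat = synth.bin_matrix(frags, 1000, {"chr1": 10_000})
        det = np.asarray((mat.values > 0).mean(axis=0)).ravel()
        assert det[0] == pytest.approx(0.7)
        cov = np.asarray(mat.values.sum(axis=0)).ravel()
        eligible = (det <= 0.60) & (cov > 0)
        assert not eligible[0] and eligible[5]

    def test_sex_chromosome_bins_excluded(self, small_world):
        # features used for preclustering never come from chrX/chrY
        from screg.dimred import SEX_CHROMS, select_top_coverage

        genome, _, frags = small_world
        df = frags.records.copy()
        df.loc[df.index[:100], "chrom"] = "chrX"
        mat = synth.bin_matrix(
            FragmentTable(df), 2000, {"chr1": 300_000, "chr2": 300_000, "chrX": 300_000}
        )
        idx = select_top_coverage(mat, 50)
        assert all(mat.features[i].rsplit(":", 1)[0] not in SEX_CHROMS for i in idx)

    def test_needs_two_nuclei(self):
        with pytest.raises(ValueError):
            pk.precluster(_frags([("chr1", 0, 50, "B0", 1)]))


class TestPseudobulks:
    def test_even_split(self):
        rows = [("chr1", i * 10, i * 10 + 5, f"B{i}", 1) for i in range(10)]
        pools = pk.make_pseudobulks(_frags(rows), {f"B{i}": 0 for i in range(10)}, seed=0)
        r1, r2 = pools[0]
        assert r1.records["barcode"].nunique() == 5
        assert r2.records["barcode"].nunique() == 5
        assert set(r1.records["barcode"]) | set(r2.records["barcode"]) == {f"B{i}" for i in range(10)}

    def test_cap_downsamples_exactly(self):
        rows = [("chr1", i, i + 5, "B0", 1) for i in range(300)]
        rows += [("chr1", i, i + 5, "B1", 1) for i in range(300)]
        pools = pk.make_pseudobulks(_frags(rows), {"B0": 0, "B1": 0}, cap=100, seed=0)
        assert len(pools[0][0]) == 100 and len(pools[0][1]) == 100

    def test_seed_reproducible(self):
        rows = [("chr1", i * 10, i * 10 + 5, f"B{i % 6}", 1) for i in range(60)]
        labels = {f"B{i}": 0 for i in range(6)}
        a = pk.make_pseudobulks(_frags(rows), labels, seed=5)
        b = pk.make_pseudobulks(_frags(rows), labels, seed=5)
        pd.testing.assert_frame_equal(a[0][0].records, b[0][0].records)

    def test_singleton_cluster_warns(self):
        rows = [("chr1", 0, 5, "B0", 1)]
        with pytest.warns(UserWarning, match="one nucleus"):
            pools = pk.make_pseudobulks(_frags(rows), {"B0": 0})
        assert len(pools[0][0]) == 1 and len(pools[0][1]) == 1


class TestCallPeaks:
    def test_planted_region_called(self):
        # Poisson tail oracle: uniform background plus one 10-kb region with
        # 50x insertion rate in a 1-Mb genome; only that region is called
        rng = np.random.default_rng(0)
        bg = np.arange(0, 1_000_000, 200)  # flat background pileup
        sig = rng.integers(500_000, 510_000, size=5_000)
        pos = np.concatenate([bg, sig])
        frags = _frags([("chr1", int(p), int(p) + 50, "B0", 1) for p in pos])
        ps = pk.call_peaks(frags, 1_000_000)
        assert len(ps) >= 1
        # all peaks inside the (shift-smeared) planted region
        assert (ps.peaks["start"] > 498_000).all() and (ps.peaks["end"] < 512_000).all()
        covered = sum(
            max(0, min(e, 510_000) - max(s, 500_000))
            for s, e in zip(ps.peaks["start"], ps.peaks["end"])
        )
        assert covered > 8_000

    def test_empty_pool(self):
        empty = FragmentTable(
            pd.DataFrame(columns=["chrom", "start", "end", "barcode", "count"])
        )
        assert len(pk.call_peaks(empty, 1000)) == 0

    def test_qval_one_calls_almost_everything(self):
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 10_000, size=2_000)
        frags = _frags([("chr1", int(p), int(p) + 50, "B0", 1) for p in pos])
        ps = pk.call_peaks(frags, 10_000, qval=1.0)
        total = (ps.peaks["end"] - ps.peaks["start"]).sum()
        assert total > 9_000

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            pk.call_peaks(_frags([("chr1", 0, 5, "B", 1)]), 0)


class TestReproduciblePeaks:
    def _ps(self, rows):
        return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "summit"]))

    def test_identical_replicates_kept(self):
        a = self._ps([("chr1", 1000, 1600, 1300)])
        out = pk.reproducible_peaks(a, a)
        assert len(out) == 1

    def test_disjoint_replicates_empty(self):
        a = self._ps([("chr1", 1000, 1600, 1300)])
        b = self._ps([("chr1", 50_000, 50_600, 50_300)])
        assert len(pk.reproducible_peaks(a, b)) == 0

    def test_all_retained_are_400bp_around_summit(self):
        a = self._ps([("chr1", 1000, 1900, 1200), ("chr1", 5000, 5100, 5050)])
        b = self._ps([("chr1", 1100, 1300, 1200), ("chr1", 5040, 5090, 5060)])
        out = pk.reproducible_peaks(a, b)
        w = out.peaks["end"] - out.peaks["start"]
        assert (w == 400).all()
        assert (out.peaks["start"] == out.peaks["summit"] - 200).all()


class TestConsensusPeaks:
    def test_single_peak_recentred_identity(self):
        ps = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [1400],
                                   "summit": [1200]}))
        out = pk.consensus_peaks([ps])
        assert list(out.peaks[["start", "end"]].iloc[0]) == [1000, 1400]

    def test_two_overlapping_hand_trace(self):
        # [0,400) + [200,600): merged span [0,600), centre 300 -> [100,500)
        a = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [400], "summit": [200]}))
        b = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [600], "summit": [400]}))
        out = pk.consensus_peaks([a, b])
        assert len(out) == 1
        assert list(out.peaks[["start", "end"]].iloc[0]) == [100, 500]
        assert out.source_clusters == [[0, 1]]

    def test_blacklist_removes(self):
        ps = PeakSet(pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [1000, 9000],
                                   "end": [1400, 9400], "summit": [1200, 9200]}))
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [1100], "end": [1200]})
        out = pk.consensus_peaks([ps], blacklist=bl)
        assert len(out) == 1 and out.peaks["start"].iloc[0] == 9000

    def test_widths_exactly_400_and_in_bounds(self, small_world):
        genome, truth, frags = small_world
        cl = dict(zip(genome.chrom_names, genome.chrom_lengths))
        labels = pk.precluster(frags, bin_size=2000, chrom_lengths=cl, seed=0)
        barcodes = sorted(frags.records["barcode"].unique())
        pools = pk.make_pseudobulks(frags, dict(zip(barcodes, labels.tolist())), seed=0)
        gsize = sum(genome.chrom_lengths)
        sets = [
            pk.reproducible_peaks(pk.call_peaks(r1, gsize), pk.call_peaks(r2, gsize), cl)
            for r1, r2 in pools.values()
        ]
        cons = pk.consensus_peaks(sets, None, cl)
        w = cons.peaks["end"] - cons.peaks["start"]
        assert (w == 400).all()
        assert (cons.peaks["start"] >= 0).all()
        for chrom, grp in cons.peaks.groupby("chrom"):
            assert (grp["end"] <= cl[chrom]).all()

    def test_end_to_end_recovery(self, small_world):
        # >= 90% of planted regions recovered within +-200 bp of centre and
        # < 10% false-positive consensus peaks (planted-truth oracle)
        genome, truth, frags = small_world
        cl = dict(zip(genome.chrom_names, genome.chrom_lengths))
        labels = pk.precluster(frags, bin_size=2000, chrom_lengths=cl, seed=0)
        barcodes = sorted(frags.records["barcode"].unique())
        pools = pk.make_pseudobulks(frags, dict(zip(barcodes, labels.tolist())), seed=0)
        gsize = sum(genome.chrom_lengths)
        sets = [
            pk.reproducible_peaks(pk.call_peaks(r1, gsize), pk.call_peaks(r2, gsize), cl)
            for r1, r2 in pools.values()
        ]
        cons = pk.consensus_peaks(sets, None, cl)
        reg = truth.regions
        centres = ((reg["start"] + reg["end"]) // 2).to_numpy()
        pc = ((cons.peaks["start"] + cons.peaks["end"]) // 2).to_numpy()
        recovered = 0
        for chrom, c in zip(reg["chrom"], centres):
            m = (cons.peaks["chrom"] == chrom).to_numpy()
            if m.any() and np.min(np.abs(pc[m] - c)) <= 200:
                recovered += 1
        assert recovered / len(reg) >= 0.9
        false_pos = 0
        for chrom, c in zip(cons.peaks["chrom"], pc):
            m = (reg["chrom"] == chrom).to_numpy()
            if not m.any() or np.min(np.abs(centres[m] - c)) > 200:
                false_pos += 1
        assert false_pos / len(cons) < 0.1


class TestAnnotatePeaks:
    def _cons(self, starts, chrom="chr1"):
        from screg._types import ConsensusPeakSet

        df = pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": [s + 400 for s in starts],
             "name": [f"p{i}" for i in range(len(starts))]}
        )
        return ConsensusPeakSet(df)

    def test_promoter_distal_boundary(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [10_001],
                            "name": ["t"]})
        # centres at 11,500 (promoter, 1,500 bp) and 12,201 (distal, 2,201 bp)
        ann = annotate = pk.annotate_peaks(self._cons([11_300, 12_001]), tss)
        assert list(ann["promoter_distal"]) == ["promoter", "distal"]

    def test_exact_2kb_is_promoter(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [10_001],
                            "name": ["t"]})
        ann = pk.annotate_peaks(self._cons([11_800]), tss)  # centre 12,000
        assert ann["promoter_distal"].iloc[0] == "promoter"

    def test_genic_precedence(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1], "name": ["t"]})
        gm = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [100_000, 100_000],
                "end": [100_050, 101_000],
                "kind": ["exon", "intron"],
            }
        )
        ann = pk.annotate_peaks(self._cons([100_000, 100_500, 200_000]), tss, gm)
        assert list(ann["genic"]) == ["exonic", "intronic", "intergenic"]

    def test_no_tss_all_distal(self):
        with pytest.warns(UserWarning):
            ann = pk.annotate_peaks(self._cons([100]), None)
        assert (ann["promoter_distal"] == "distal").all()
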