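"""Fragment counting, moderated statistics, peak merging and annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tadakit.damid import (
    FragmentCountMatrix,
    GeneModel,
    annotate_peak_features,
    assign_peaks_to_genes,
    count_reads_per_fragment,
    fragment_differential,
    fragments_frame,
    merge_fragments_to_peaks,
    normalize_log2,
    peak_fdr_filter,
    read_gff3_genes,
    simes,
    tss_metaprofile,
)
from tadakit.gatc import GatcFragmentMap


def _fmap():
    return GatcFragmentMap({"c": np.array([[2, 12], [12, 22]])})


def _reads(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


class TestCounting:
    def test_midpoint_assignment(self):
        m = count_reads_per_fragment(
            {"s1": _reads([("c", 14, 20)])}, _fmap(), {"s1": "control"}
        )
        assert m.counts["s1"].tolist() == [0, 1]  # midpoint 17 -> [12,22)

    def test_boundary_midpoint_goes_to_right_fragment(self):
        m = count_reads_per_fragment(
            {"s1": _reads([("c", 8, 16)])}, _fmap(), {"s1": "control"}
        )
        assert m.counts["s1"].tolist() == [0, 1]  # midpoint 12, half-open

    def test_no_reads_gives_zero_matrix(self):
        m = count_reads_per_fragment(
            {"s1": _reads([])}, _fmap(), {"s1": "control"}
        )
        assert m.counts["s1"].sum() == 0
        assert m.library_sizes["s1"] == 0

    def test_unknown_sample_label_errors(self):
        with pytest.raises(ValueError):
            count_reads_per_fragment({"s1": _reads([])}, _fmap(), {})

    def test_count_conservation(self):
        reads = _reads(
            [("c", 0, 4), ("c", 5, 9), ("c", 30, 40), ("x", 0, 10), ("c", 13, 15)]
        )
        m = count_reads_per_fragment({"s1": reads}, _fmap(), {"s1": "control"})
        assert m.counts["s1"].sum() + m.dropped["s1"] == len(reads)


class TestNormalization:
    def test_log2_cpm_closed_form(self):
        frag = pd.DataFrame({"contig": ["c"], "start": [0], "end": [10]})
        counts = pd.DataFrame({"s1": [0], "s2": [10**6]})
        # force library sizes via a second fragment is unnecessary: test the
        # formula on a one-fragment matrix where library = count
        m = FragmentCountMatrix(frag, counts, {"s1": "a", "s2": "b"}, {})
        norm = normalize_log2(m)
        # s1 excluded (zero library); s2: log2((1e6 + .5)/1e6 * 1e6)
        assert "s1" not in norm.columns
        assert norm["s2"].iloc[0] == pytest.approx(np.log2(10**6 + 0.5))

    def test_doubling_library_lowers_value_one_bit(self):
        frag = pd.DataFrame(
            {"contig": ["c", "c"], "start": [0, 10], "end": [10, 20]}
        )
        counts = pd.DataFrame({"s1": [100, 900], "s2": [100, 1900]})
        m = FragmentCountMatrix(frag, counts, {"s1": "a", "s2": "b"}, {})
        norm = normalize_log2(m)
        assert norm["s1"].iloc[0] - norm["s2"].iloc[0] == pytest.approx(1.0)


class TestDifferential:
    def _norm_two_groups(self, ctrl, dn, lib=10**6, pc=0.5):
        vals = {}
        design = {}
        for i, c in enumerate(ctrl):
            name = f"c{i}"
            vals[name] = np.log2((np.asarray(c, float) + pc) / lib * 1e6)
            design[name] = "control"
        for i, c in enumerate(dn):
            name = f"d{i}"
            vals[name] = np.log2((np.asarray(c, float) + pc) / lib * 1e6)
            design[name] = "dn"
        return pd.DataFrame(vals), design

    def test_identical_values_give_null_result(self):
        norm, design = self._norm_two_groups([[5, 5], [5, 5]], [[5, 5], [5, 5]])
        out = fragment_differential(norm, design)
        assert out["log2fc"].abs().max() == 0
        assert (out["p"] == 1.0).all()

    def test_hand_computed_log2fc(self):
        # control counts (10,10), dn counts (40,40), equal libraries:
        # log2FC = log2(40.5 / 10.5)
        norm, design = self._norm_two_groups([[10], [10]], [[40], [40]])
        out = fragment_differential(norm, design)
        assert out["log2fc"].iloc[0] == pytest.approx(np.log2(40.5 / 10.5))

    def test_prior_df_zero_matches_plain_t_test(self):
        rng = np.random.default_rng(0)
        norm = pd.DataFrame(
            rng.normal(size=(50, 6)), columns=[f"s{i}" for i in range(6)]
        )
        design = {f"s{i}": ("control" if i < 3 else "dn") for i in range(6)}
        out = fragment_differential(norm, design, prior_df=0)
        ctrl = norm[[c for c in norm if design[c] == "control"]].to_numpy()
        dn = norm[[c for c in norm if design[c] == "dn"]].to_numpy()
        ref = sps.ttest_ind(dn, ctrl, axis=1, equal_var=True)
        np.testing.assert_allclose(out["p"].to_numpy(), ref.pvalue, atol=1e-12)

    def test_single_replicate_condition_rejected(self):
        norm = pd.DataFrame(np.zeros((3, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            fragment_differential(
                norm, {"a": "control", "b": "control", "c": "dn"}
            )


class TestPeakMerging:
    def _stats(self, rows):
        """rows: (start, end, p, log2fc) on one contig."""
        frag = pd.DataFrame(
            {
                "contig": ["c"] * len(rows),
                "start": [r[0] for r in rows],
                "end": [r[1] for r in rows],
            }
        )
        stats = pd.DataFrame(
            {
                "p": [r[2] for r in rows],
                "log2fc": [r[3] for r in rows],
                "s2_mod": 0.1,
                "mean_abund": 5.0,
            }
        )
        return stats, frag

    def test_gap_tolerance_boundary(self):
        # 100 bp gap -> one peak; 196 bp gap -> two peaks (tol = 195)
        stats, frag = self._stats(
            [(0, 100, 1e-7, -3), (200, 300, 1e-7, -3)]
        )
        assert len(merge_fragments_to_peaks(stats, frag)) == 1
        stats, frag = self._stats(
            [(0, 100, 1e-7, -3), (296, 400, 1e-7, -3)]
        )
        assert len(merge_fragments_to_peaks(stats, frag)) == 2

    def test_simes_hand_value(self):
        assert simes(np.array([0.01, 0.04])) == pytest.approx(0.02)
        stats, frag = self._stats(
            [(0, 100, 0.01, -3), (150, 250, 0.04, -3)]
        )
        peaks = merge_fragments_to_peaks(stats, frag, site_p_threshold=0.05)
        assert peaks["p"].iloc[0] == pytest.approx(0.02)

    def test_single_fragment_peak(self):
        stats, frag = self._stats([(0, 100, 1e-7, -2.5)])
        peaks = merge_fragments_to_peaks(stats, frag)
        assert len(peaks) == 1
        assert peaks["p"].iloc[0] == pytest.approx(1e-7)
        assert (peaks["start"].iloc[0], peaks["end"].iloc[0]) == (0, 100)
        assert peaks["direction"].iloc[0] == "down"

    def test_max_width_split(self):
        rows = [(i * 1000, i * 1000 + 900, 1e-7, -3) for i in range(7)]
        stats, frag = self._stats(rows)
        peaks = merge_fragments_to_peaks(stats, frag, tol=200, max_width=5000)
        assert len(peaks) > 1
        assert ((peaks["end"] - peaks["start"]) <= 5000).all()

    def test_no_qualifying_fragments(self):
        stats, frag = self._stats([(0, 100, 0.5, -3)])
        assert merge_fragments_to_peaks(stats, frag).empty


class TestPeakFilter:
    def _peaks(self, ps, lfcs):
        return pd.DataFrame(
            {
                "contig": "c",
                "start": range(len(ps)),
                "end": [s + 1 for s in range(len(ps))],
                "n_fragments": 1,
                "members": [[i] for i in range(len(ps))],
                "p": ps,
                "log2fc": lfcs,
                "direction": ["up" if l > 0 else "down" for l in lfcs],
            }
        )

    def test_bh_hand_values(self):
        peaks = self._peaks([0.01, 0.02, 0.9], [-3, -3, -3])
        allp, kept = peak_fdr_filter(peaks)
        assert allp["q"].tolist() == pytest.approx([0.03, 0.03, 0.9])
        assert len(kept) == 2

    def test_effect_size_gate(self):
        peaks = self._peaks([0.001, 0.001], [-1, -1])
        _, kept = peak_fdr_filter(peaks, min_abs_log2fc=2)
        assert kept.empty

    def test_direction_gate(self):
        peaks = self._peaks([0.001, 0.001], [-3, 3])
        _, down = peak_fdr_filter(peaks, direction="down")
        _, up = peak_fdr_filter(peaks, direction="up")
        _, both = peak_fdr_filter(peaks, direction="any")
        assert len(down) == 1 and len(up) == 1 and len(both) == 2

    def test_empty_input(self):
        allp, kept = peak_fdr_filter(self._peaks([], []))
        assert kept.empty


def _gene(gid="g1", contig="c", strand="+", start=1000, end=2000, **kw):
    return GeneModel(gid, contig, strand, start, end, **kw)


class TestGeneAssignment:
    def _peak(self, start, end, q=0.01, lfc=-3.0):
        return pd.DataFrame(
            {
                "contig": ["c"],
                "start": [start],
                "end": [end],
                "p": [q / 2],
                "q": [q],
                "log2fc": [lfc],
            }
        )

    def test_peak_inside_single_gene(self):
        table = assign_peaks_to_genes(self._peak(1200, 1400), [_gene()])
        assert table["gene_id"].tolist() == ["g1"]

    def test_peak_spanning_two_genes(self):
        genes = [_gene("g1", end=1500), _gene("g2", start=1500, end=2500)]
        table = assign_peaks_to_genes(self._peak(1400, 1600), genes)
        assert sorted(table["gene_id"]) == ["g1", "g2"]

    def test_unassigned_peak_recorded(self):
        table = assign_peaks_to_genes(self._peak(5000, 5100), [_gene()])
        assert table.empty
        assert table.attrs["unassigned_peaks"] == [0]


class TestFeatureAnnotation:
    def _peaks(self, mids):
        return pd.DataFrame(
            {
                "contig": "c",
                "start": [m - 10 for m in mids],
                "end": [m + 10 for m in mids],
            }
        )

    def test_promoter_windows_plus_strand(self):
        gene = _gene(start=10_000, end=12_000)
        table = annotate_peak_features(self._peaks([9500, 8500, 7500]), [gene])
        labels = table.attrs["peak_labels"]
        assert labels == [
            "Promoter (<=1kb)", "Promoter (1-2kb)", "Promoter (2-3kb)"
        ]

    def test_promoter_is_strand_aware(self):
        gene = _gene(strand="-", start=10_000, end=12_000)
        table = annotate_peak_features(self._peaks([12_500]), [gene])
        assert table.attrs["peak_labels"] == ["Promoter (<=1kb)"]

    def test_exon_intron_utr(self):
        gene = _gene(
            start=1000, end=3000,
            exons=[(1000, 1500), (2500, 3000)],
            utr5=[(1000, 1100)], utr3=[(2900, 3000)],
        )
        table = annotate_peak_features(
            self._peaks([1050, 1300, 2000, 2950]), [gene]
        )
        assert table.attrs["peak_labels"] == ["5' UTR", "Exon", "Intron", "3' UTR"]

    def test_distal_and_downstream(self):
        gene = _gene(start=1000, end=2000)
        table = annotate_peak_features(self._peaks([3000, 50_000]), [gene])
        assert table.attrs["peak_labels"] == [
            "Downstream (<=3kb)", "Distal Intergenic"
        ]
        assert table["percent"].sum() == pytest.approx(100.0)


class TestTssMetaprofile:
    def test_strand_flip(self):
        # signal 100 bp 5' of a minus-strand TSS must appear at -100
        frag = pd.DataFrame(
            {"contig": ["c"], "start": [2075], "end": [2125]}  # mid 2100
        )
        signal = pd.Series([7.0], index=frag.index)
        gene = _gene(strand="-", start=1000, end=2001)  # TSS at 2000
        prof = tss_metaprofile(signal, frag, [gene], window_bp=500, bin_bp=50)
        hit = prof.dropna(subset=["signal"])
        assert len(hit) == 1
        assert hit["distance"].iloc[0] == -75.0  # bin [-100, -50)

    def test_uniform_signal_flat_profile(self):
        frag = pd.DataFrame(
            {
                "contig": "c",
                "start": np.arange(0, 4000, 100),
                "end": np.arange(100, 4100, 100),
            }
        )
        signal = pd.Series(3.0, index=frag.index)
        prof = tss_metaprofile(signal, frag, [_gene(start=2000, end=3000)],
                               window_bp=1000, bin_bp=100)
        assert np.allclose(prof["signal"].dropna(), 3.0)


def test_gff3_round_trip(tmp_path, small_genome):
    from tadakit.synthetic import write_gff3

    _, genes, _ = small_genome
    path = tmp_path / "genes.gff3"
    write_gff3(genes, path)
    back = read_gff3_genes(path)
    assert len(back) == len(genes)
    by_id = {g.gene_id: g for g in back}
    for g in genes:
        b = by_id[g.gene_id]
        assert (b.contig, b.strand, b.start, b.end) == (
            g.contig, g.strand, g.start, g.end
        )
        assert b.exons == sorted(g.exons)
        assert b.utr5 == sorted(g.utr5)
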