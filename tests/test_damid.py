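"""GATC fragment map, fragment counting, enrichment calling, peaks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from damtarget.countmodel import CountMatrix
from damtarget.damid import (
    annotate_peaks,
    call_binding,
    count_fragments,
    gatc_fragment_map,
    merge_peaks,
    replicate_correlation,
)
from damtarget.synthetic import SimulationConfig, simulate_damid


class TestFragmentMap:
    def test_nineteen_bp_toy(self):
        # GATC at 3 and 12 cuts [0,19) into [0,3), [3,12), [12,19)
        fmap = gatc_fragment_map({"chr1": "AAAGATCAAAAAGATCAAA"})
        spans = fmap.table[["start", "end"]].to_numpy().tolist()
        assert spans == [[0, 3], [3, 12], [12, 19]]

    def test_no_gatc_single_fragment(self):
        fmap = gatc_fragment_map({"chr1": "AAATTTCCC"})
        assert fmap.table[["start", "end"]].to_numpy().tolist() == [[0, 9]]

    def test_gatc_at_origin_emits_no_empty_fragment(self):
        fmap = gatc_fragment_map({"chr1": "GATCAAAA"})
        assert fmap.table[["start", "end"]].to_numpy().tolist() == [[0, 8]]

    def test_case_insensitive_and_tiling(self):
        fmap = gatc_fragment_map({"chr1": "aaagatcAAAA"})
        tab = fmap.table
        assert tab["start"].iloc[1] == 3
        assert (tab["end"] - tab["start"]).sum() == 11

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError, match="empty"):
            gatc_fragment_map({"chr1": ""})

    def test_map_tiles_simulated_genome(self, genome_sim):
        genome, _, _ = genome_sim
        fmap = gatc_fragment_map(genome)
        tab = fmap.table
        assert (tab["end"] - tab["start"]).sum() == len(genome["chr1"])
        assert tab["start"].is_monotonic_increasing


class TestCountFragments:
    @pytest.fixture
    def two_fragment_map(self):
        return gatc_fragment_map({"chr1": "AAAAAAAAAA" + "GATC" + "AAAAAAAAAA"})

    def test_five_prime_start_rule(self, two_fragment_map):
        # interval starting in fragment 0 but ending in fragment 1 counts to 0
        bed = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [2, 8], "end": [6, 16]})
        cm = count_fragments({"s1": bed}, two_fragment_map)
        assert cm.counts["s1"].tolist() == [2, 0]

    def test_interval_inside_fragment(self, two_fragment_map):
        bed = pd.DataFrame({"chrom": ["chr1"], "start": [12], "end": [18]})
        cm = count_fragments({"s1": bed}, two_fragment_map)
        assert cm.counts["s1"].tolist() == [0, 1]

    def test_empty_bed_and_unknown_chrom(self, two_fragment_map):
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        stray = pd.DataFrame({"chrom": ["chrX"], "start": [5], "end": [9]})
        cm = count_fragments({"s1": empty, "s2": stray}, two_fragment_map)
        assert (cm.counts.to_numpy() == 0).all()
        assert cm.n_unassigned == 1


class TestReplicateCorrelation:
    def test_duplicated_sample_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(100, 50)
        counts = pd.DataFrame({"a": col, "b": col, "c": rng.poisson(100, 50)})
        cm = CountMatrix(counts, pd.Series({"a": "f", "b": "f", "c": "d"}))
        corr = replicate_correlation(cm)
        assert np.isclose(corr.loc["a", "b"], 1.0)
        assert corr.loc["a", "c"] < 1.0

    def test_groups_separate_on_simulation(self, damid_sim):
        cm, _, _ = damid_sim
        corr = replicate_correlation(cm)
        cond = cm.groups
        within, between = [], []
        for a, b in itertools.combinations(corr.index, 2):
            (within if cond[a] == cond[b] else between).append(corr.loc[a, b])
        assert min(within) > max(between)


class TestCallBinding:
    def test_identical_conditions_give_empty_set(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(100, (200, 5)),
            columns=["f1", "f2", "d1", "d2", "d3"],
        )
        cm = CountMatrix(counts, pd.Series(
            {"f1": "fusion", "f2": "fusion", "d1": "dam_only", "d2": "dam_only", "d3": "dam_only"}
        ))
        sig, _ = call_binding(cm)
        assert len(sig) <= 2  # chance-level leakage only

    def test_boundary_log2fc_excluded(self):
        de = pd.DataFrame(
            {"log2fc": [1.0, 1.1], "padj": [1e-6, 1e-6], "base_mean": [100, 100.0]},
            index=["at_one", "above_one"],
        )
        sig = set(de.index[(de["log2fc"] > 1.0) & (de["padj"] < 0.01)])
        assert sig == {"above_one"}

    def test_planted_fragments_recovered(self, damid_sim):
        cm, _, truth = damid_sim
        sig, de = call_binding(cm)
        planted = set(truth.planted_bound_fragments)
        assert len(sig & planted) / len(planted) >= 0.9
        assert len(sig & planted) / len(sig) >= 0.9

    def test_null_false_fragment_rate(self, genome_sim):
        genome, genes, _ = genome_sim
        rates = []
        for seed in range(3):
            cfg = SimulationConfig(seed=seed, damid_enrichment=1.0)
            cm, _, _ = simulate_damid(genome, genes, cfg)
            sig, de = call_binding(cm)
            rates.append(len(sig) / len(de))
        assert np.mean(rates) <= 0.02


class TestPeaks:
    @pytest.fixture
    def five_fragment_map(self):
        seq = "A" * 10 + "GATC" + "A" * 10 + "GATC" + "A" * 10 + "GATC" + "A" * 10 + "GATC" + "A" * 10
        return gatc_fragment_map({"chr1": seq})

    @pytest.fixture
    def de_stub(self, five_fragment_map):
        ids = five_fragment_map.table["fragment_id"]
        return pd.DataFrame(
            {"base_mean": 100.0, "log2fc": 2.0, "padj": 1e-5}, index=ids
        )

    def test_adjacent_fragments_merge(self, five_fragment_map, de_stub):
        ids = five_fragment_map.table["fragment_id"].tolist()
        peaks = merge_peaks({ids[1], ids[2]}, five_fragment_map, de_stub)
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end) == (10, 38)

    def test_gap_parameter_controls_merging(self, five_fragment_map, de_stub):
        ids = five_fragment_map.table["fragment_id"].tolist()
        sig = {ids[1], ids[3]}  # separated by one non-significant fragment
        assert len(merge_peaks(sig, five_fragment_map, de_stub, max_gap_fragments=0)) == 2
        merged = merge_peaks(sig, five_fragment_map, de_stub, max_gap_fragments=1)
        assert len(merged) == 1
        assert merged[0].fragment_ids == [ids[1], ids[3]]

    def test_empty_input_empty_output(self, five_fragment_map, de_stub):
        assert merge_peaks(set(), five_fragment_map, de_stub) == []


class TestAnnotatePeaks:
    @pytest.fixture
    def genes(self):
        return pd.DataFrame(
            {
                "gene_id": ["plus_gene", "minus_gene"],
                "chrom": ["chr1", "chr1"],
                "tss": [10000, 30000],
                "strand": ["+", "-"],
                "length": [2000, 2000],
            }
        )

    def _peak(self, start, end):
        from damtarget.damid import DamPeak

        return DamPeak("chr1", start, end, [], 2.0, 1e-5)

    def test_peak_in_gene_body(self, genes):
        peaks, n = annotate_peaks([self._peak(10500, 10600)], genes)
        assert peaks[0].gene_ids == ["plus_gene"]
        assert n == 1

    def test_upstream_window_is_bounded(self, genes):
        near, _ = annotate_peaks([self._peak(8400, 8500)], genes)  # 1.5 kb upstream
        far, _ = annotate_peaks([self._peak(7400, 7500)], genes)  # 2.5 kb upstream
        assert near[0].gene_ids == ["plus_gene"]
        assert far[0].gene_ids == []

    def test_minus_strand_upstream_is_rightward(self, genes):
        # minus-strand TSS at 30000: upstream extension covers (30000, 32001)
        up, _ = annotate_peaks([self._peak(31500, 31600)], genes)
        down, _ = annotate_peaks([self._peak(32500, 32600)], genes)
        assert up[0].gene_ids == ["minus_gene"]
        assert down[0].gene_ids == []

    def test_overlapping_genes_both_assigned(self, genes):
        wide = genes.copy()
        wide.loc[1, "tss"] = 12000
        wide.loc[1, "strand"] = "+"
        peaks, n = annotate_peaks([self._peak(11500, 12500)], wide, upstream_bp=2000)
        assert peaks[0].gene_ids == ["minus_gene", "plus_gene"]
        assert n == 2
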