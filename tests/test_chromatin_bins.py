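import numpy as np
import pandas as pd
import pytest

from te_insite.chromatin_bins import (assign_categories, bin_signal,
                                      compare_categories, consensus_coverage,
                                      coverage_track, library_sizes,
                                      make_filtered_bins)
from te_insite.genomic_core import (AlignmentRecord, Genome, GenomicInterval,
                                    InsertionSet, PipelineConfig,
                                    fragment_transform)
from te_insite.mappability import MappabilityTrack
from tests.conftest import random_genome, random_records


def uniform_track(genome, value=1.0):
    return MappabilityTrack(
        {c: np.full(n, value) for c, n in genome.lengths.items()}, kmer_length=50)


def het_config(**kwargs):
    return PipelineConfig(het_region=GenomicInterval("chr4", 0, 50_000), **kwargs)


class TestMakeFilteredBins:
    def test_tiling_counts(self):
        genome = Genome({"c": "A" * 10_000})
        bins = make_filtered_bins(genome, uniform_track(genome), het_config())
        assert len(bins) == 10
        assert list(bins["start"]) == list(range(0, 10_000, 1000))

    def test_partial_bin_dropped(self):
        genome = Genome({"c": "A" * 10_500})
        bins = make_filtered_bins(genome, uniform_track(genome), het_config())
        assert len(bins) == 10

    def test_short_chromosome_contributes_no_bins(self):
        genome = Genome({"c": "A" * 600})
        bins = make_filtered_bins(genome, uniform_track(genome), het_config())
        assert len(bins) == 0

    def test_mappability_threshold(self):
        genome = Genome({"c": "A" * 3000})
        vec = np.concatenate([np.full(1000, 0.4), np.full(1000, 0.6),
                              np.full(1000, 0.5)])
        track = MappabilityTrack({"c": vec}, kmer_length=50)
        bins = make_filtered_bins(genome, track, het_config())
        assert list(bins["start"]) == [1000]  # 0.4 and 0.5 (not > 0.5) removed

    def test_matches_loop_oracle(self, rng):
        genome = Genome({"c": "A" * 20_000})
        vec = rng.random(20_000)
        track = MappabilityTrack({"c": vec}, kmer_length=50)
        bins = make_filtered_bins(genome, track, het_config())
        oracle = [s for s in range(0, 20_000, 1000)
                  if np.mean(vec[s:s + 1000]) > 0.5]
        assert list(bins["start"]) == oracle
        for row in bins.itertuples():
            assert row.mean_mappability == pytest.approx(
                np.mean(vec[row.start:row.end]))


def bins_frame(starts, chrom="chr1", mappability=1.0):
    return pd.DataFrame({
        "chrom": chrom, "start": starts,
        "end": [s + 1000 for s in starts],
        "mean_mappability": mappability,
    })


class TestAssignCategories:
    def test_gap_rule_example(self):
        bins = bins_frame([0])
        insertions = InsertionSet([("gypsy", GenomicInterval("chr1", 1400, 1600))])
        out = assign_categories(bins, insertions, het_config())
        assert out["category"].iloc[0] == "near_upregulated_te"  # gap 500

    def test_beyond_radius_unassigned(self):
        bins = bins_frame([0])
        insertions = InsertionSet([("gypsy", GenomicInterval("chr1", 2400, 2600))])
        out = assign_categories(bins, insertions, het_config())
        assert out["category"].iloc[0] == "unassigned"

    def test_control_het_needs_distance(self):
        bins = bins_frame([1000, 20_000], chrom="chr4")
        insertions = InsertionSet([("gypsy", GenomicInterval("chr4", 4400, 4600))])
        out = assign_categories(bins, insertions, het_config())
        # bin at 1000 is within 10 kb of the insertion -> not control
        assert list(out["category"]) == ["unassigned", "control_het"]

    def test_control_requires_containment_in_het_region(self):
        bins = bins_frame([60_000], chrom="chr4")  # outside het region
        out = assign_categories(bins, InsertionSet([]), het_config())
        assert out["category"].iloc[0] == "unassigned"

    def test_missing_het_region_is_config_error(self):
        with pytest.raises(ValueError, match="het_region"):
            assign_categories(bins_frame([0]), InsertionSet([]), PipelineConfig())

    def test_priority_truth_table(self):
        """Exhaustive precedence oracle over all flag combinations."""
        cfg = het_config()
        for near_up in (False, True):
            for near_other in (False, True):
                for in_het_far in (False, True):
                    insertions = []
                    if near_up:
                        insertions.append(("gypsy", GenomicInterval("chr1", 1400, 1600)))
                    if near_other:
                        insertions.append(("Juan", GenomicInterval("chr1", 1300, 1500)))
                    chrom = "chr4" if in_het_far else "chr1"
                    if in_het_far and (near_up or near_other):
                        # relocate the insertions next to the het bin
                        insertions = [(f, GenomicInterval("chr4", iv.start, iv.end))
                                      for f, iv in insertions]
                    bins = bins_frame([0], chrom=chrom)
                    out = assign_categories(bins, InsertionSet(insertions), cfg)
                    if near_up:
                        expected = "near_upregulated_te"
                    elif near_other:
                        expected = "near_other_te"
                    elif in_het_far:
                        expected = "control_het"
                    else:
                        expected = "unassigned"
                    assert out["category"].iloc[0] == expected, (
                        near_up, near_other, in_het_far)


class TestBinSignal:
    @pytest.fixture
    def genome(self):
        return Genome({"chr1": "A" * 20_000, "chrM": "C" * 2000},
                      mito_name="chrM")

    def test_midpoint_counting(self, genome):
        bins = bins_frame([0, 1000])
        # + read at 100: fragment [100,360) midpoint 230 -> bin 0
        recs = [AlignmentRecord(GenomicInterval("chr1", 100, 150, "+"), 255, "s")
                for _ in range(3)]
        out = bin_signal(recs, bins, genome, het_config())
        assert out["count_s"].tolist() == [3, 0]

    def test_norm_signal_formula(self, genome):
        bins = bins_frame([0], mappability=0.5)
        recs = [AlignmentRecord(GenomicInterval("chr1", 100, 150, "+"), 255, "s")
                for _ in range(10)]
        out = bin_signal(recs, bins, genome, het_config())
        # count 10 / mappability 0.5 * 1e6 / library 10 = 2e6
        assert out["norm_s"].iloc[0] == pytest.approx(2e6)

    def test_mito_excluded_from_library(self, genome):
        bins = bins_frame([0])
        recs = [AlignmentRecord(GenomicInterval("chr1", 100, 150, "+"), 255, "s"),
                AlignmentRecord(GenomicInterval("chrM", 100, 150, "+"), 255, "s")]
        assert library_sizes(recs, genome) == {"s": 1}
        out = bin_signal(recs, bins, genome, het_config())
        assert out["norm_s"].iloc[0] == pytest.approx(1e6)

    def test_zero_library_rejected(self, genome):
        recs = [AlignmentRecord(GenomicInterval("chrM", 100, 150, "+"), 255, "s")]
        with pytest.raises(ValueError, match="zero retained"):
            bin_signal(recs, bins_frame([0]), genome, het_config())

    def test_conservation_and_midpoint_oracle(self, rng):
        genome = random_genome(rng, {"chr1": 30_000, "chr2": 20_000})
        cfg = het_config()
        records = random_records(rng, genome, 1000, samples=("a", "b"))
        track = uniform_track(genome)
        bins = make_filtered_bins(genome, track, cfg)
        out = bin_signal(records, bins, genome, cfg)

        # oracle: brute-force midpoint assignment of extended fragments
        expected = {("a"): 0, ("b"): 0}
        oracle_counts = np.zeros((len(bins), 2), dtype=int)
        keys = {(r.chrom, r.start): i for i, r in enumerate(bins.itertuples())}
        retained = {"a": 0, "b": 0}
        for rec in records:
            frag = fragment_transform(rec, cfg.fragment_length, True, genome)
            mid = (frag.start + frag.end) // 2
            for i, row in enumerate(bins.itertuples()):
                if row.chrom == frag.chrom and row.start <= mid < row.end:
                    oracle_counts[i, 0 if rec.sample == "a" else 1] += 1
                    retained[rec.sample] += 1
        np.testing.assert_array_equal(out["count_a"], oracle_counts[:, 0])
        np.testing.assert_array_equal(out["count_b"], oracle_counts[:, 1])
        # conservation: totals equal retained midpoint-inside fragments
        assert out["count_a"].sum() == retained["a"]
        assert out["count_b"].sum() == retained["b"]

    def test_condition_means(self, genome):
        bins = bins_frame([0])
        recs = [AlignmentRecord(GenomicInterval("chr1", 100, 150, "+"), 255, "r1"),
                AlignmentRecord(GenomicInterval("chr1", 200, 250, "+"), 255, "r2")]
        out = bin_signal(recs, bins, genome, het_config(),
                         conditions={"r1": "control", "r2": "control"})
        assert out["mean_control"].iloc[0] == pytest.approx(1e6)


class TestCompareCategories:
    def _table(self, kd, ctrl, category="near_upregulated_te"):
        return pd.DataFrame({"category": category, "kd": kd, "ctrl": ctrl})

    def test_identical_conditions(self, rng):
        vals = rng.random(100) + 0.5
        out = compare_categories(self._table(vals, vals), "kd", "ctrl")
        row = out[out["category"] == "near_upregulated_te"].iloc[0]
        assert row["median_fold_change"] == pytest.approx(1.0)
        assert row["p"] > 0.9

    def test_fourfold_depletion_detected(self, rng):
        ctrl = rng.random(500) * 10 + 20
        out = compare_categories(self._table(ctrl / 4, ctrl), "kd", "ctrl")
        row = out[out["category"] == "near_upregulated_te"].iloc[0]
        assert row["median_fold_change"] == pytest.approx(0.25, rel=0.02)
        assert row["p"] < 1e-10
        assert bool(row["significant"])

    def test_single_bin_category_is_na(self):
        out = compare_categories(self._table([1.0], [2.0]), "kd", "ctrl")
        row = out[out["category"] == "near_upregulated_te"].iloc[0]
        assert np.isnan(row["p"]) and not row["significant"]

    def test_antisymmetric_under_condition_swap(self, rng):
        table = self._table(rng.random(80) + 1, rng.random(80) + 2)
        fwd = compare_categories(table, "kd", "ctrl")
        rev = compare_categories(table, "ctrl", "kd")
        f = fwd[fwd["category"] == "near_upregulated_te"].iloc[0]
        r = rev[rev["category"] == "near_upregulated_te"].iloc[0]
        assert f["median_fold_change"] == pytest.approx(1 / r["median_fold_change"])
        assert f["p"] == pytest.approx(r["p"])

    def test_all_zero_category(self):
        out = compare_categories(self._table(np.zeros(10), np.zeros(10)),
                                 "kd", "ctrl")
        row = out[out["category"] == "near_upregulated_te"].iloc[0]
        assert row["median_fold_change"] == pytest.approx(1.0)
        assert row["p"] == 1.0


class TestCoverageTrack:
    def test_single_read_carries_one_million(self):
        genome = Genome({"c": "A" * 1000})
        rec = AlignmentRecord(GenomicInterval("c", 100, 150, "+"), 255, "s")
        tracks = coverage_track([rec], genome, mode="chip")
        vec = tracks["s"]["c"]
        # fragment [100,360) midpoint 230 -> centered read [205,255)
        assert vec[205:255].sum() == pytest.approx(50 * 1e6)
        assert np.count_nonzero(vec) == 50

    def test_total_mass_conserved(self):
        genome = Genome({"c": "A" * 2000})
        recs = [AlignmentRecord(GenomicInterval("c", 100, 150, "+"), 255, "s"),
                AlignmentRecord(GenomicInterval("c", 1000, 1050, "+"), 255, "s")]
        tracks = coverage_track(recs, genome, mode="rna")
        assert tracks["s"]["c"].sum() == pytest.approx(50 * 1e6)

    def test_rna_mode_uses_raw_spans(self):
        genome = Genome({"c": "A" * 1000})
        rec = AlignmentRecord(GenomicInterval("c", 100, 150, "+"), 255, "s")
        vec = coverage_track([rec], genome, mode="rna")["s"]["c"]
        assert np.all(vec[100:150] == 1e6) and vec[99] == 0 and vec[150] == 0

    def test_matches_accumulation_oracle(self, rng):
        genome = random_genome(rng, {"c": 5000})
        cfg = PipelineConfig()
        records = random_records(rng, genome, 200)
        tracks = coverage_track(records, genome, cfg, mode="chip")
        oracle = np.zeros(5000)
        for rec in records:
            iv = fragment_transform(rec, 260, True, genome)
            oracle[iv.start:iv.end] += 1
        oracle *= 1e6 / len(records)
        np.testing.assert_allclose(tracks["s1"]["c"], oracle)


class TestConsensusCoverage:
    def test_sense_read_counts(self):
        rec = AlignmentRecord(GenomicInterval("gypsy", 10, 60, "+"), 255, "s")
        tracks = consensus_coverage([rec], {"gypsy": 500}, sense_only=True)
        vec = tracks["s"]["gypsy"]
        assert np.all(vec[10:60] == 1e6) and vec.sum() == pytest.approx(50e6)

    def test_antisense_dropped_but_in_library(self):
        recs = [AlignmentRecord(GenomicInterval("gypsy", 10, 60, "+"), 255, "s"),
                AlignmentRecord(GenomicInterval("gypsy", 100, 150, "-"), 255, "s")]
        tracks = consensus_coverage(recs, {"gypsy": 500}, sense_only=True)
        vec = tracks["s"]["gypsy"]
        assert vec[100:150].sum() == 0
        assert np.all(vec[10:60] == 0.5e6)  # scaled by both retained reads

    def test_unknown_consensus_rejected(self):
        rec = AlignmentRecord(GenomicInterval("unknown", 0, 50, "+"), 255, "s")
        with pytest.raises(ValueError, match="unknown"):
            consensus_coverage([rec], {"gypsy": 500})

    def test_mixed_reads_match_oracle(self, rng):
        lengths = {"gypsy": 800, "mdg1": 600}
        records = []
        for _ in range(100):
            name = "gypsy" if rng.random() < 0.5 else "mdg1"
            start = int(rng.integers(0, lengths[name] - 50))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(AlignmentRecord(
                GenomicInterval(name, start, start + 50, strand), 255, "s"))
        tracks = consensus_coverage(records, lengths, sense_only=False)
        oracle = {n: np.zeros(l) for n, l in lengths.items()}
        for rec in records:
            oracle[rec.interval.chrom][rec.interval.start:rec.interval.end] += 1
        for name in lengths:
            np.testing.assert_allclose(tracks["s"][name],
                                       oracle[name] * 1e6 / 100)
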