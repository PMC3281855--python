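import itertools

import numpy as np
import pytest

from barcodekit.distance import DistanceMatrix, pairwise_matrix
from barcodekit.errors import ComputationError, ValidationError
from barcodekit.gap_analysis import (
    ComparisonClass,
    band_counts,
    barcode_gap_flags,
    boxplot_stats,
    classify_pair,
    fold_ratio,
    nearest_neighbor_distances,
    rank_summaries,
    round2,
    summaries_to_tsv,
    threshold_fraction,
)
from barcodekit.synthetic_data import SimulationConfig, plant_deep_split, simulate


def brute_force_classes(taxonomy):
    """Oracle: enumerate unordered pairs and classify each by shared ranks."""
    out = {}
    for a, b in itertools.combinations(taxonomy.index, 2):
        ta, tb = taxonomy.loc[a], taxonomy.loc[b]
        if ta["species"] == tb["species"]:
            cls = ComparisonClass.within_species
        elif ta["genus"] == tb["genus"]:
            cls = ComparisonClass.within_genus
        elif ta["family"] == tb["family"]:
            cls = ComparisonClass.within_family
        elif ta["order"] == tb["order"]:
            cls = ComparisonClass.within_order
        elif ta["class_"] == tb["class_"]:
            cls = ComparisonClass.within_class
        else:
            cls = None
        out[frozenset((a, b))] = cls
    return out


@pytest.fixture
def toy_matrix(toy_dataset):
    return pairwise_matrix(toy_dataset), toy_dataset.taxonomy


class TestClassifyPair:
    def test_shared_ranks(self, toy_dataset):
        tax = toy_dataset.taxonomy
        assert classify_pair(tax, "a1", "a2") == ComparisonClass.within_species
        assert classify_pair(tax, "a1", "b1") == ComparisonClass.within_genus
        assert classify_pair(tax, "a1", "c1") == ComparisonClass.within_family

    def test_matches_brute_force_on_simulation(self, sim_default):
        tax = sim_default.dataset.taxonomy
        oracle = brute_force_classes(tax)
        for pair, cls in oracle.items():
            a, b = sorted(pair)
            assert classify_pair(tax, a, b) == cls

    def test_unknown_id_rejected(self, toy_dataset):
        with pytest.raises(ValidationError):
            classify_pair(toy_dataset.taxonomy, "a1", "nope")

    def test_no_shared_class_is_none(self, taxonomy_frame):
        tax = taxonomy_frame([
            ("x", "S1", "G1", "F1", "O1", "Actinopterygii"),
            ("y", "S2", "G2", "F2", "O2", "Chondrichthyes"),
        ])
        assert classify_pair(tax, "x", "y") is None


class TestRankSummaries:
    def test_counts_two_species_two_specimens(self, toy_matrix):
        # SpA x2 and SpB x2 in GenX: 2 conspecific pairs each... see oracle
        matrix, tax = toy_matrix
        s = rank_summaries(matrix, tax)
        oracle = brute_force_classes(tax)
        for cls in ComparisonClass:
            n = sum(1 for c in oracle.values() if c == cls)
            if n:
                assert s[cls].n_comparisons == n

    def test_two_by_two_within_genus_four_pairs(self, taxonomy_frame):
        tax = taxonomy_frame([
            ("a1", "SpA", "G", "F", "O", "C"), ("a2", "SpA", "G", "F", "O", "C"),
            ("b1", "SpB", "G", "F", "O", "C"), ("b2", "SpB", "G", "F", "O", "C"),
        ])
        vals = np.full((4, 4), 0.10)
        np.fill_diagonal(vals, 0.0)
        m = DistanceMatrix(["a1", "a2", "b1", "b2"], vals)
        s = rank_summaries(m, tax)
        assert s[ComparisonClass.within_species].n_comparisons == 2
        assert s[ComparisonClass.within_genus].n_comparisons == 4

    def test_all_identical_sequences_zero_means(self, taxonomy_frame):
        tax = taxonomy_frame([
            ("a", "S1", "G", "F", "O", "C"), ("b", "S1", "G", "F", "O", "C"),
            ("c", "S2", "G", "F", "O", "C"),
        ])
        m = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        s = rank_summaries(m, tax)
        assert all(v.mean == 0.0 for v in s.values())

    def test_singleton_species_excluded_from_taxa_count(self, toy_matrix):
        matrix, tax = toy_matrix
        s = rank_summaries(matrix, tax)
        # all 3 toy species have 2 specimens
        assert s[ComparisonClass.within_species].n_taxa == 3

    def test_no_conspecific_pairs_omits_class(self, taxonomy_frame):
        tax = taxonomy_frame([
            ("a", "S1", "G", "F", "O", "C"), ("b", "S2", "G", "F", "O", "C"),
        ])
        m = DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]]))
        with pytest.warns(UserWarning, match="within_species"):
            s = rank_summaries(m, tax)
        assert ComparisonClass.within_species not in s
        assert s[ComparisonClass.within_genus].n_comparisons == 1

    def test_partition_completeness(self, sim_default):
        m = pairwise_matrix(sim_default.dataset)
        s = rank_summaries(m, sim_default.dataset.taxonomy)
        n = len(sim_default.dataset)
        assert sum(v.n_comparisons for v in s.values()) == n * (n - 1) // 2

    def test_rank_ordered_means_on_simulation(self, sim_default):
        m = pairwise_matrix(sim_default.dataset)
        s = rank_summaries(m, sim_default.dataset.taxonomy)
        means = [s[c].mean for c in list(ComparisonClass)[:4]]
        assert means == sorted(means)
        assert s[ComparisonClass.within_species].mean < 1.0  # percent

    def test_cumulative_convention(self, sim_default):
        m = pairwise_matrix(sim_default.dataset)
        tax = sim_default.dataset.taxonomy
        disjoint = rank_summaries(m, tax)
        cumulative = rank_summaries(m, tax, cumulative=True)
        n = len(sim_default.dataset)
        assert cumulative[ComparisonClass.within_order].n_comparisons == \
            n * (n - 1) // 2  # single order: everything nests inside
        assert disjoint[ComparisonClass.within_species].n_comparisons == \
            cumulative[ComparisonClass.within_species].n_comparisons

    def test_tsv_layout(self, toy_matrix, tmp_path):
        matrix, tax = toy_matrix
        summaries_to_tsv(rank_summaries(matrix, tax), tmp_path / "t1.tsv")
        lines = (tmp_path / "t1.tsv").read_text().splitlines()
        assert lines[0].split("\t") == [
            "comparisons_within", "taxa", "n_comparisons",
            "mean", "minimum", "maximum", "se"]


class TestBandCounts:
    def test_toy_bands(self, taxonomy_frame):
        tax = taxonomy_frame([
            ("a", "S1", "G", "F", "O", "C"), ("b", "S2", "G", "F", "O", "C"),
            ("c", "S3", "G", "F", "O", "C"),
        ])
        vals = np.array([
            [0.00, 0.03, 0.07],
            [0.03, 0.00, 0.12],
            [0.07, 0.12, 0.00],
        ])
        table = band_counts(DistanceMatrix(["a", "b", "c"], vals), tax)
        assert table.loc[("O", "F")].tolist() == [1, 1, 1]

    def test_exact_5_falls_in_middle_band(self, taxonomy_frame):
        tax = taxonomy_frame([
            ("a", "S1", "G", "F", "O", "C"), ("b", "S2", "G", "F", "O", "C"),
        ])
        vals = np.array([[0.0, 0.05], [0.05, 0.0]])
        table = band_counts(DistanceMatrix(["a", "b"], vals), tax)
        assert table.loc[("O", "F")].tolist() == [0, 1, 0]

    def test_totals_match_within_genus_count(self, sim_default):
        m = pairwise_matrix(sim_default.dataset)
        tax = sim_default.dataset.taxonomy
        table = band_counts(m, tax)
        s = rank_summaries(m, tax)
        assert int(table.to_numpy().sum()) == \
            s[ComparisonClass.within_genus].n_comparisons

    def test_family_without_congeners_excluded(self, taxonomy_frame):
        tax = taxonomy_frame([
            ("a", "S1", "G1", "F1", "O", "C"), ("b", "S2", "G1", "F1", "O", "C"),
            ("c", "S3", "G2", "F2", "O", "C"),  # lone genus in F2
        ])
        vals = np.full((3, 3), 0.08)
        np.fill_diagonal(vals, 0)
        table = band_counts(DistanceMatrix(["a", "b", "c"], vals), tax)
        assert ("O", "F2") not in table.index
        assert ("O", "F1") in table.index


class TestThresholdFraction:
    def test_strictly_below_with_rounding(self, taxonomy_frame):
        # 2 of 3 conspecific pairs below 1% -> 66.67
        tax = taxonomy_frame([
            ("a", "S", "G", "F", "O", "C"), ("b", "S", "G", "F", "O", "C"),
            ("c", "S", "G", "F", "O", "C"), ("d", "S2", "G", "F", "O", "C"),
        ])
        vals = np.zeros((4, 4))
        vals[0, 1] = vals[1, 0] = 0.002
        vals[0, 2] = vals[2, 0] = 0.005
        vals[1, 2] = vals[2, 1] = 0.015
        m = DistanceMatrix(["a", "b", "c", "d"], vals)
        below, total, pct = threshold_fraction(
            m, tax, ComparisonClass.within_species, 1.0)
        assert (below, total, pct) == (2, 3, 66.67)

    def test_all_zero_distances(self, taxonomy_frame):
        tax = taxonomy_frame([
            ("a", "S", "G", "F", "O", "C"), ("b", "S", "G", "F", "O", "C"),
        ])
        m = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        assert threshold_fraction(m, tax, ComparisonClass.within_species, 1.0) \
            == (1, 1, 100.0)

    def test_zero_threshold_strictly_below(self, taxonomy_frame):
        tax = taxonomy_frame([
            ("a", "S", "G", "F", "O", "C"), ("b", "S", "G", "F", "O", "C"),
        ])
        m = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        assert threshold_fraction(m, tax, ComparisonClass.within_species, 0.0) \
            == (0, 1, 0.0)

    def test_non_decreasing_in_threshold(self, sim_default):
        m = pairwise_matrix(sim_default.dataset)
        tax = sim_default.dataset.taxonomy
        pcts = [threshold_fraction(m, tax, ComparisonClass.within_genus, t)[2]
                for t in (1, 5, 10, 15, 20, 50)]
        assert pcts == sorted(pcts)


class TestNND:
    def test_brute_force_minima(self, sim_default):
        m = pairwise_matrix(sim_default.dataset)
        tax = sim_default.dataset.taxonomy
        results = {r.species: r for r in nearest_neighbor_distances(m, tax)}
        species = tax["species"]
        labels = m.labels
        for sp in species.unique():
            best = min(
                m.values[i, j]
                for i, a in enumerate(labels)
                for j, b in enumerate(labels)
                if species[a] == sp and species[b] != sp
            ) * 100.0
            assert results[sp].distance == pytest.approx(best)
            assert results[sp].nearest_neighbor != sp

    def test_identical_sequences_give_zero_nnd_both_ways(self, taxonomy_frame):
        tax = taxonomy_frame([
            ("a", "S1", "G", "F", "O", "C"), ("b", "S2", "G", "F", "O", "C"),
        ])
        m = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        results = nearest_neighbor_distances(m, tax)
        assert all(r.distance == 0.0 for r in results)

    def test_single_species_rejected(self, taxonomy_frame):
        tax = taxonomy_frame([
            ("a", "S", "G", "F", "O", "C"), ("b", "S", "G", "F", "O", "C"),
        ])
        m = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ComputationError, match="species"):
            nearest_neighbor_distances(m, tax)

    def test_nnd_bounded_by_congeneric_mean(self, sim_default):
        m = pairwise_matrix(sim_default.dataset)
        tax = sim_default.dataset.taxonomy
        results = {r.species: r.distance
                   for r in nearest_neighbor_distances(m, tax)}
        species = tax["species"].to_numpy()
        genus = tax["genus"].to_numpy()
        vals = m.values * 100.0
        for sp in np.unique(species):
            g = genus[species == sp][0]
            sel_sp = species == sp
            sel_congener = (genus == g) & ~sel_sp
            if sel_congener.any():
                congeneric = vals[np.ix_(sel_sp, sel_congener)]
                assert results[sp] <= congeneric.mean() + 1e-9


class TestFoldRatio:
    def test_printed_table_means(self):
        from barcodekit.gap_analysis import RankSummary
        s = {
            ComparisonClass.within_species: RankSummary(
                ComparisonClass.within_species, 199, 5814, 0.18, 0, 2.51, 0.01),
            ComparisonClass.within_genus: RankSummary(
                ComparisonClass.within_genus, 141, 5958, 13.55, 0, 25.35, 0.07),
        }
        assert fold_ratio(s) == pytest.approx(75.28, abs=0.01)

    def test_equal_means_is_one(self):
        from barcodekit.gap_analysis import RankSummary
        s = {
            cls: RankSummary(cls, 2, 2, 5.0, 1.0, 9.0, 0.5)
            for cls in (ComparisonClass.within_species,
                        ComparisonClass.within_genus)
        }
        assert fold_ratio(s) == 1.0

    def test_zero_intraspecific_mean_rejected(self):
        from barcodekit.gap_analysis import RankSummary
        s = {
            ComparisonClass.within_species: RankSummary(
                ComparisonClass.within_species, 1, 1, 0.0, 0, 0, 0),
            ComparisonClass.within_genus: RankSummary(
                ComparisonClass.within_genus, 1, 1, 13.0, 13, 13, 0),
        }
        with pytest.raises(ComputationError):
            fold_ratio(s)


class TestBoxplotStats:
    def test_symmetric_small_set(self):
        s = boxplot_stats([1, 2, 3, 4, 5])
        assert (s.q1, s.median, s.q3) == (2, 3, 4)
        assert s.iqr == 2
        assert (s.whisker_low, s.whisker_high) == (1, 5)
        assert s.mild_outliers == [] and s.extreme_outliers == []

    def test_constant_vector(self):
        s = boxplot_stats([7.0] * 10)
        assert s.iqr == 0 and s.mild_outliers == [] and s.extreme_outliers == []
        assert s.whisker_low == s.whisker_high == 7.0

    def test_extreme_outlier_classified(self):
        # with [1..5, 20]: q1=2.25, q3=4.75, IQR=2.5, extreme fence 12.25
        s = boxplot_stats([1, 2, 3, 4, 5, 20])
        assert s.extreme_outliers == [20.0]
        assert s.whisker_high == 5.0

    def test_mild_vs_extreme_boundaries(self):
        # [1..5, 10]: q1=2.25, q3=4.75, IQR=2.5 -> mild zone (8.5, 12.25]
        s = boxplot_stats([1, 2, 3, 4, 5, 10])
        assert s.mild_outliers == [10.0] and s.extreme_outliers == []
        assert s.whisker_high == 5.0

    def test_whiskers_clipped_to_data(self, rng):
        vals = rng.normal(10, 2, 200)
        s = boxplot_stats(vals)
        assert s.whisker_low in vals and s.whisker_high in vals


class TestBarcodeGapFlags:
    def test_deep_split_flagged(self, sim_clustered):
        sp = sim_clustered.dataset.records[0].species
        sd = plant_deep_split(sim_clustered, sp, 0.025, seed=13)
        m = pairwise_matrix(sd.dataset)
        flags = barcode_gap_flags(m, sd.dataset.taxonomy)
        assert flags.at[sp, "deep_intraspecific"]

    def test_clean_species_not_flagged(self, taxonomy_frame):
        tax = taxonomy_frame([
            ("a", "S1", "G", "F", "O", "C"), ("b", "S1", "G", "F", "O", "C"),
            ("c", "S2", "G", "F", "O", "C"),
        ])
        vals = np.array([
            [0.00, 0.00, 0.10],
            [0.00, 0.00, 0.10],
            [0.10, 0.10, 0.00],
        ])
        flags = barcode_gap_flags(DistanceMatrix(["a", "b", "c"], vals), tax)
        assert not flags["deep_intraspecific"].any()
        assert not flags["nnd_below_threshold"].any()

    def test_low_nnd_flagged(self, taxonomy_frame):
        tax = taxonomy_frame([
            ("a", "S1", "G", "F", "O", "C"), ("b", "S2", "G", "F", "O", "C"),
        ])
        vals = np.array([[0.0, 0.005], [0.005, 0.0]])
        flags = barcode_gap_flags(DistanceMatrix(["a", "b"], vals), tax)
        assert flags["nnd_below_threshold"].all()


def test_round2_is_half_even():
    assert round2(0.125) == 0.12
    assert round2(0.135) == 0.14  # float 0.135 is slightly above
    assert round2(98.434812) == 98.43
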