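"""Heterozygosity, match, identity, subpattern, and EcoRI statistics."""

import numpy as np
import pytest

from limerad import (
    classify_matrix,
    cluster_identity_counts,
    ecori_denovo_estimate,
    het_stats,
    pairwise_matches,
    subpattern_table,
    total_bases,
)
from limerad.io import PartitionError

from helpers import ACC, mat


class TestTotalBases:
    def test_rad_panel_size(self):
        assert total_bases(78_527, 41) == 3_219_607

    @pytest.mark.parametrize("n,l,expected", [(1, 41, 41), (10, 36, 360)])
    def test_small_products(self, n, l, expected):
        assert total_bases(n, l) == expected

    @pytest.mark.parametrize("n,l", [(0, 41), (10, 0), (-1, 41)])
    def test_nonpositive_rejected(self, n, l):
        with pytest.raises(ValueError):
            total_bases(n, l)


class TestHetStats:
    def test_counts_and_frequency(self):
        m = mat(["MMMM AAAA", "MAAA AAAA", "AAAC AAAC"])
        table = het_stats(m, total_bases=1000)
        assert table.loc["Bhutan-09015", "het_sites"] == 2
        assert table.loc["Bhutan-09024", "het_sites"] == 1
        assert table.loc["Bhutan-09005", "het_sites"] == 0
        assert table.loc["Bhutan-09015", "het_pct"] == pytest.approx(0.2)
        assert table.loc["Bhutan-09015", "het_pct_2dp"] == 0.20

    def test_zero_het_accession(self):
        table = het_stats(mat(["AAAA AAAC"]), total_bases=100)
        assert table.loc["Indonesia-88045", "het_pct_2dp"] == 0.00

    def test_monotone_in_count(self):
        low = het_stats(mat(["MAAA AAAC"]), 100).loc["Bhutan-09015", "het_pct"]
        high = het_stats(mat(["MAAA AAAC", "MAAA AAAC"]), 100).loc[
            "Bhutan-09015", "het_pct"
        ]
        assert high > low

    def test_bad_total_bases(self):
        with pytest.raises(ValueError):
            het_stats(mat(["MMMM AAAA"]), 0)


class TestPairwiseMatches:
    def test_self_identity_via_duplicate_column(self):
        rng = np.random.default_rng(6)
        col = rng.choice(list("ACGTMRWSYK"), size=50)
        dup = mat(["".join([c, c]) for c in col], accessions=["x", "x2"])
        t = pairwise_matches(dup)
        assert t.loc["x", "x2"] == 50  # identical copies match everywhere

    def test_hand_counted_pair(self):
        m = mat(["MM", "AM", "CC"], accessions=["x", "y"])
        t = pairwise_matches(m)
        assert t.loc["x", "y"] == 2
        assert t.loc["y", "x"] == 2

    def test_empty_subset(self):
        m = mat(["MM", "AM"], accessions=["x", "y"])
        t = pairwise_matches(m, site_subset=[])
        assert (t.values == 0).all()

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(7)
        calls = rng.choice(list("ACGTMRWSYK"), size=(60, 8))
        m = mat(["".join(r) for r in calls])
        subset = list(range(0, 60, 2))
        t = pairwise_matches(m, site_subset=subset)
        assert (t.values == t.values.T).all()
        assert (np.diag(t.values) == len(subset)).all()
        assert (t.values <= len(subset)).all()

    def test_unknown_accession(self):
        with pytest.raises(KeyError):
            pairwise_matches(mat(["MM", "AM"], accessions=["x", "y"]), accessions=["z"])


class TestClusterIdentity:
    def test_single_member_group_is_all_identical(self):
        from limerad.io import ClusterPartition

        part = ClusterPartition(
            cluster_order=("x", "y"), cluster_of={"a": "x", "b": "y", "c": "y"}
        )
        m = mat(["MAC", "CCA", "GGT"], accessions=["a", "b", "c"])
        same, diff = cluster_identity_counts(m, part, "x")
        assert (same, diff) == (3, 0)

    def test_hand_counted_group(self, partition):
        # Bhutanese-cluster calls per site: (M,M,M,M), (M,A,M,M), (C,C,C,C), (A,C,A,A)
        m = mat(["MMMM AAAA", "MAMM AAAA", "CCCC AAAA", "ACAA GGGG"])
        same, diff = cluster_identity_counts(m, partition, "Bhutanese")
        assert (same, diff) == (2, 2)

    def test_complement_property(self, partition):
        rng = np.random.default_rng(8)
        calls = rng.choice(list("ACGTMRWSYK"), size=(100, 8))
        m = mat(["".join(r) for r in calls])
        for group in ("Bhutanese", "Indonesian", "subcluster1", "subcluster2"):
            same, diff = cluster_identity_counts(m, partition, group)
            assert same + diff == m.n_sites


class TestSubpatternTable:
    def _table(self, patterns, partition, category):
        m = mat(patterns)
        report, filtered = classify_matrix(m, partition)
        return subpattern_table(filtered, partition, report, category)

    def test_category_e_rows_and_totals(self, partition):
        patterns = (
            ["YYYY YYCC"] * 3       # row (Y, Y, C): sub1 het, sub2 hom
            + ["YYYY CCYY"] * 2     # row (Y, C, Y): sub1 hom, sub2 het
            + ["MMMM MAMM"]         # sub1 non-uniform -> remainder
        )
        tab = self._table(patterns, partition, "E")
        rows = {
            (r.other_cluster, r.subcluster1, r.subcluster2): r.count
            for r in tab.rows.itertuples()
        }
        assert rows == {("Y", "Y", "C"): 3, ("Y", "C", "Y"): 2}
        assert tab.remainder_count == 1
        assert tab.sub1_het_sub2_hom == 3
        assert tab.sub1_hom_sub2_het == 2
        assert tab.category_count == 6

    def test_category_g_row(self, partition):
        tab = self._table(["AAAA MMCC"], partition, "G")
        assert tab.rows.iloc[0].tolist() == ["A", "M", "C", 1]
        assert (tab.sub1_het_sub2_hom, tab.sub1_hom_sub2_het) == (1, 0)

    def test_conservation_on_random_input(self, partition):
        rng = np.random.default_rng(9)
        calls = rng.choice(list("MAC"), size=(300, 8))
        m = mat(["".join(r) for r in calls])
        report, filtered = classify_matrix(m, partition)
        for cat in ("E", "G", "J"):
            tab = subpattern_table(filtered, partition, report, cat)
            assert tab.category_count == report.counts[cat]
            assert (
                tab.sub1_het_sub2_hom
                == tab.rows.loc[
                    tab.rows["subcluster1"].isin(list("MRWSYK"))
                    & ~tab.rows["subcluster2"].isin(list("MRWSYK")),
                    "count",
                ].sum()
            )

    def test_unsupported_category_rejected(self, partition):
        with pytest.raises(ValueError, match="no subcluster pattern"):
            self._table(["AAAA CCCC"], partition, "B")

    def test_requires_subclusters(self, partition):
        from limerad.io import ClusterPartition

        flat = ClusterPartition(
            cluster_order=partition.cluster_order,
            cluster_of=dict(partition.cluster_of),
        )
        m = mat(["MMMM MAMA"])
        report, filtered = classify_matrix(m, flat)
        with pytest.raises(PartitionError):
            subpattern_table(filtered, flat, report, "E")


class TestEcoriEstimate:
    def test_printed_scaling(self):
        assert ecori_denovo_estimate(3087) == 515  # 3087/6 = 514.5, half-up

    @pytest.mark.parametrize(
        "events,expected", [(6, 1), (0, 0), (3, 1), (2, 0), (36, 6)]
    )
    def test_rounding_half_up(self, events, expected):
        assert ecori_denovo_estimate(events) == expected

    def test_custom_window(self):
        assert ecori_denovo_estimate(100, site_length=5, flank_length=50) == 10

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ecori_denovo_estimate(-1)
        with pytest.raises(ValueError):
            ecori_denovo_estimate(10, site_length=0)
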