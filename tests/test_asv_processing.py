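import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from holo.asv_processing import (
    AsvTable,
    FilterConfig,
    aggregate_replicates,
    bray_curtis,
    filter_asvs,
    filter_colonies,
    group_correlated_asvs,
    hellinger,
    join_with_genotyped,
    process_community,
)

from .conftest import make_table


class TestAsvTable:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            make_table([[1, -1]])

    def test_rejects_unmapped_sample(self):
        df = pd.DataFrame([[1, 2]], index=["s0"], columns=["a0", "a1"])
        with pytest.raises(KeyError, match="no colony mapping"):
            AsvTable(df, colony_map=pd.Series({"other": "c1"}))

    def test_tsv_round_trip(self, tmp_path):
        t = make_table([[3, 0], [1, 2]])
        path = tmp_path / "counts.tsv"
        t.to_tsv(path)
        t2 = AsvTable.from_tsv(path)
        pd.testing.assert_frame_equal(t.counts, t2.counts, check_names=False)


class TestAggregateReplicates:
    def test_sums_within_colony(self):
        t = make_table([[3, 0], [1, 2], [0, 0]], colony_map=["c1", "c1", "c1"])
        agg = aggregate_replicates(t)
        assert agg.counts.loc["c1"].tolist() == [4, 2]

    def test_single_sample_colonies_identity(self):
        t = make_table([[1, 2], [3, 4]], colony_map=["c1", "c2"])
        agg = aggregate_replicates(t)
        assert agg.counts.to_numpy().tolist() == [[1, 2], [3, 4]]

    def test_total_reads_conserved(self, rng):
        counts = rng.integers(0, 50, size=(9, 5))
        t = make_table(counts, colony_map=[f"c{i % 3}" for i in range(9)])
        assert aggregate_replicates(t).counts.to_numpy().sum() == counts.sum()


class TestGroupCorrelatedAsvs:
    def test_identical_presence_merged(self):
        t = make_table([[5, 9], [1, 3], [0, 0], [0, 0]])
        gmap, grouped = group_correlated_asvs(t)
        assert gmap.asv_to_group == {"a0": "a0", "a1": "a0"}
        assert grouped.counts["a0"].tolist() == [14, 4, 0, 0]

    def test_complementary_presence_separate(self):
        t = make_table([[1, 0], [2, 0], [0, 3], [0, 4]])
        gmap, _ = group_correlated_asvs(t)
        assert len(gmap.group_members) == 2

    def test_chain_merges_transitively(self):
        # phi(a,b) = phi(b,c) = 0.845 > 0.8, phi(a,c) = 0.714 <= 0.8
        a = [1, 0, 1, 0, 1, 1, 1, 0, 1, 0, 0, 1]
        b = [1, 0, 1, 0, 0, 1, 1, 0, 1, 0, 0, 1]
        c = [1, 0, 1, 0, 0, 1, 1, 0, 1, 0, 0, 0]
        t = make_table(np.array([a, b, c]).T)
        corr = np.corrcoef(np.array([a, b, c], dtype=float))
        assert corr[0, 1] > 0.8 and corr[1, 2] > 0.8 and corr[0, 2] <= 0.8
        gmap, grouped = group_correlated_asvs(t)
        assert gmap.group_members == {"a0": ["a0", "a1", "a2"]}
        assert grouped.shape[1] == 1

    def test_constant_vectors_never_linked_by_correlation(self):
        # all-present vs all-absent vs variable: only identical constants merge
        t = make_table([[1, 0, 1, 1], [2, 0, 3, 1], [4, 0, 0, 1]])
        gmap, _ = group_correlated_asvs(t)
        assert gmap.asv_to_group["a0"] == gmap.asv_to_group["a3"]  # both all-present
        assert gmap.asv_to_group["a1"] != gmap.asv_to_group["a0"]  # all-absent apart
        assert gmap.asv_to_group["a2"] not in (
            gmap.asv_to_group["a0"],
            gmap.asv_to_group["a1"],
        )

    def test_group_id_is_smallest_member(self):
        t = make_table([[1, 1], [0, 0], [2, 3]], asvs=["zzz", "aaa"])
        gmap, grouped = group_correlated_asvs(t)
        assert list(gmap.group_members) == ["aaa"]
        assert list(grouped.counts.columns) == ["aaa"]


class TestFilters:
    def test_asv_too_few_colonies_dropped(self):
        counts = np.zeros((5, 1), dtype=int)
        counts[0, 0] = 5000
        counts[1, 0] = 5000
        t = make_table(counts)
        assert filter_asvs(t).shape[1] == 0

    def test_asv_exactly_100_reads_dropped(self):
        counts = np.array([[20], [20], [20], [20], [20]])
        t = make_table(counts)
        assert filter_asvs(t).shape[1] == 0  # 100 total, strict >100

    def test_asv_three_colonies_101_reads_kept(self):
        counts = np.array([[50], [50], [1], [0], [0]])
        t = make_table(counts)
        assert filter_asvs(t).shape[1] == 1  # inclusive >=3 colonies

    def test_colony_exactly_1000_reads_dropped(self):
        t = make_table([[250, 250, 250, 250], [500, 500, 500, 501]])
        kept = filter_colonies(t)
        assert kept.sample_ids == ["s1"]

    def test_colony_boundary_kept(self):
        t = make_table([[250, 250, 250, 251], [1, 1, 1, 0]])
        kept = filter_colonies(t)
        assert kept.sample_ids == ["s0"]  # 1001 reads, 4 nonzero ASVs

    def test_all_colonies_filtered_errors(self):
        t = make_table([[1, 1], [2, 2]])
        with pytest.raises(ValueError, match="review"):
            filter_colonies(t)

    def test_hand_run_filter_order_5x6(self):
        # colony-level table; filter_asvs then filter_colonies, once each
        counts = pd.DataFrame(
            {
                "A1": [300, 400, 400, 100, 0],   # 4 colonies, 1200 reads -> keep
                "A2": [2500, 2500, 0, 0, 0],     # 2 colonies -> drop
                "A3": [20, 20, 20, 20, 20],      # 100 reads, strict -> drop
                "A4": [50, 50, 1, 0, 0],         # 3 colonies, 101 reads -> keep
                "A5": [800, 700, 500, 0, 0],     # keep
                "A6": [50, 60, 100, 50, 0],      # keep
            },
            index=[f"C{i}" for i in range(1, 6)],
        )
        out = filter_colonies(filter_asvs(AsvTable(counts)))
        assert list(out.counts.columns) == ["A1", "A4", "A5", "A6"]
        # C4: 150 reads post-ASV-filter -> dropped; C5: all-zero -> dropped
        # C3: 1001 reads (>1000 strict) and 4 nonzero ASVs (>3 strict) -> kept
        assert out.sample_ids == ["C1", "C2", "C3"]
        assert out.shape == (3, 4)

    def test_filter_monotonicity(self, rng):
        counts = rng.integers(0, 200, size=(8, 10))
        t = make_table(counts)
        base = filter_asvs(t, FilterConfig(min_colonies_per_asv=2, min_reads_per_asv=50))
        stricter = filter_asvs(
            t, FilterConfig(min_colonies_per_asv=4, min_reads_per_asv=500)
        )
        assert stricter.shape[1] <= base.shape[1]


class TestHellinger:
    def test_row_1_1_2(self):
        h = hellinger(make_table([[1, 1, 2]]))
        assert h.iloc[0].tolist() == pytest.approx([0.5, 0.5, 0.70711], abs=1e-5)

    def test_single_taxon_row(self):
        h = hellinger(make_table([[5, 0, 0]]))
        assert h.iloc[0].tolist() == [1.0, 0.0, 0.0]

    def test_rows_have_unit_sum_of_squares(self, rng):
        counts = rng.integers(0, 30, size=(6, 8)) + 1
        h = hellinger(make_table(counts))
        assert np.allclose((h**2).sum(axis=1), 1.0)

    def test_zero_row_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            hellinger(make_table([[0, 0]]))


class TestBrayCurtis:
    def test_disjoint_supports(self):
        d = bray_curtis(pd.DataFrame([[2, 0], [0, 2]], index=["x", "y"]))
        assert d["x", "y"] == 1.0

    def test_identical_rows(self):
        d = bray_curtis(pd.DataFrame([[1, 2], [1, 2]], index=["x", "y"]))
        assert d["x", "y"] == 0.0

    def test_formula_arithmetic(self):
        d = bray_curtis(pd.DataFrame([[1, 1], [1, 3]], index=["x", "y"]))
        assert d["x", "y"] == pytest.approx(2 / 6)

    @given(
        arrays(
            np.float64,
            (5, 4),
            elements=st.floats(0, 100, allow_nan=False),
        ).filter(lambda m: (m.sum(axis=1) > 0).all())
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force(self, m):
        frame = pd.DataFrame(m, index=[f"r{i}" for i in range(5)])
        d = bray_curtis(frame)
        for i in range(5):
            for j in range(5):
                num = np.abs(m[i] - m[j]).sum()
                den = (m[i] + m[j]).sum()
                assert abs(d.values[i, j] - num / den) < 1e-12


class TestJoinWithGenotyped:
    def test_disjoint_errors(self):
        t = make_table([[1, 2]], colony_map=["c1"])
        with pytest.raises(ValueError, match="no overlap"):
            join_with_genotyped(t, ["c9"])

    def test_subset_restricts(self):
        t = make_table([[1, 2], [3, 4]], colony_map=["c1", "c2"])
        out = join_with_genotyped(t, ["c2", "c3"])
        assert out.sample_ids == ["s1"]

    def test_idempotent(self):
        t = make_table([[1, 2], [3, 4]], colony_map=["c1", "c2"])
        once = join_with_genotyped(t, ["c1"])
        twice = join_with_genotyped(once, ["c1"])
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestProcessCommunity:
    def _table(self, rng):
        counts = rng.integers(0, 800, size=(12, 8)) * (rng.random((12, 8)) < 0.6)
        return make_table(counts, colony_map=[f"c{i // 2}" for i in range(12)])

    def test_pipeline_runs_and_logs_order(self, rng):
        res = process_community(self._table(rng), mode="its2")
        assert res.group_map is not None
        assert "grouped" in res.log[0]
        assert "aggregated" in res.log[1]
        assert len(res.distances) == res.colony_table.shape[0]

    def test_16s_mode_skips_grouping(self, rng):
        res = process_community(self._table(rng), mode="16s")
        assert res.group_map is None

    def test_grouping_commutes_with_aggregation_for_exact_duplicates(self, rng):
        """Exact-duplicate presence vectors merge identically whether grouped
        at sample level before or after colony aggregation."""
        base = rng.integers(0, 50, size=(8, 3))
        counts = np.column_stack([base, base[:, 0] * 2])  # a3 duplicates a0's presence
        t = make_table(counts, colony_map=[f"c{i // 2}" for i in range(8)])
        g_then_a = aggregate_replicates(group_correlated_asvs(t)[1])
        a_then_g = group_correlated_asvs(aggregate_replicates(t))[1]
        pd.testing.assert_frame_equal(
            g_then_a.counts.sort_index(axis=1), a_then_g.counts.sort_index(axis=1)
        )
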