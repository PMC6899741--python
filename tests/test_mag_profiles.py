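"""MAG filtering, coverage normalization, z-scoring, clustering."""

import numpy as np
import pandas as pd
import pytest

from magfunc.abundance import AbundanceMatrix, Assay, Normalization
from magfunc.errors import ValidationError
from magfunc.kegg import KOAnnotationTable
from magfunc.mag_profiles import (CoverageMatrix, MagRecord, cluster_rows,
                                  filter_mags, ko_presence_query,
                                  normalize_mag_coverage, reorder_like,
                                  zscore_rows)
from magfunc.simulate import SimulationConfig, generate_mag_metadata


def rec(mag_id, completeness, redundancy, order="Methanococcales"):
    return MagRecord(mag_id, ("Archaea", "Euryarchaeota", "Methanococci",
                              order), completeness, redundancy)


class TestFilterMags:
    def test_strict_boundaries_exclude_threshold_values(self):
        records = [rec("a", 70.0, 5.0), rec("b", 70.1, 5.0),
                   rec("c", 90.0, 10.0), rec("d", 90.0, 9.9)]
        kept = filter_mags(records)
        assert [r.mag_id for r in kept] == ["b", "d"]

    def test_excluded_orders_removed_regardless_of_quality(self):
        records = [rec("a", 99.0, 1.0, order="Pseudomonadales"),
                   rec("b", 99.0, 1.0, order="Sphingomonadales"),
                   rec("c", 99.0, 1.0)]
        assert [r.mag_id for r in filter_mags(records)] == ["c"]

    def test_empty_exclusion_list_keeps_quality_filter_only(self):
        records = [rec("a", 99.0, 1.0, order="Pseudomonadales"),
                   rec("b", 60.0, 1.0)]
        assert [r.mag_id for r in filter_mags(records, excluded_orders=())] \
            == ["a"]

    def test_paper_scale_composition_retains_64_of_73(self):
        config = SimulationConfig(seed=0, n_mags=64, n_excluded_order=9)
        records, truth = generate_mag_metadata(config)
        assert len(records) == 73
        kept = filter_mags(records)
        assert len(kept) == 64
        assert not {r.mag_id for r in kept} & set(truth.excluded_order_mags)

    def test_idempotent_and_order_preserving(self):
        config = SimulationConfig(seed=1, n_quality_fail=5)
        records, _ = generate_mag_metadata(config)
        once = filter_mags(records)
        assert filter_mags(once) == once
        positions = {r.mag_id: i for i, r in enumerate(records)}
        assert [positions[r.mag_id] for r in once] == \
            sorted(positions[r.mag_id] for r in once)

    def test_out_of_range_percentages_rejected(self):
        with pytest.raises(ValidationError):
            rec("a", 101.0, 5.0)


class TestCoverageNormalization:
    def _cov(self, values, totals, samples=("S1", "S2")):
        df = pd.DataFrame(values, index=[f"M{i}" for i in range(len(values))],
                          columns=list(samples))
        return CoverageMatrix(df, pd.Series(totals, index=list(samples)),
                              assay=Assay.METAGENOME)

    def test_divides_by_library_size(self):
        norm = normalize_mag_coverage(self._cov([[50.0, 20.0]], [1_000_000, 2_000_000]))
        assert norm.df.iloc[0, 0] == pytest.approx(5e-5)
        assert norm.df.iloc[0, 1] == pytest.approx(1e-5)
        assert norm.normalization is Normalization.TOTAL_READS

    def test_zero_coverage_row_stays_zero(self):
        norm = normalize_mag_coverage(self._cov([[0.0, 0.0]], [10, 10]))
        assert (norm.df.to_numpy() == 0).all()

    def test_doubling_one_total_halves_only_that_column(self):
        base = normalize_mag_coverage(
            self._cov([[10.0, 10.0], [4.0, 4.0]], [100, 100]))
        changed = normalize_mag_coverage(
            self._cov([[10.0, 10.0], [4.0, 4.0]], [200, 100]))
        np.testing.assert_allclose(changed.df["S1"], base.df["S1"] / 2)
        np.testing.assert_allclose(changed.df["S2"], base.df["S2"])

    def test_zero_total_reads_names_the_sample(self):
        with pytest.raises(ValidationError, match="S2"):
            normalize_mag_coverage(self._cov([[1.0, 1.0]], [100, 0]))


class TestZScore:
    def _am(self, values, columns):
        df = pd.DataFrame(values, columns=columns)
        return AbundanceMatrix(df.clip(lower=0), assay=Assay.METAGENOME,
                               normalization=Normalization.TOTAL_READS)

    def test_three_point_row_maps_to_unit_steps(self):
        z = zscore_rows(self._am([[1.0, 2.0, 3.0]], ["a", "b", "c"]))
        np.testing.assert_allclose(z.df.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_rows_flagged_and_zeroed(self):
        z = zscore_rows(self._am([[4.0, 4.0, 4.0], [1.0, 2.0, 3.0]],
                                 ["a", "b", "c"]))
        assert z.constant_rows == (0,)
        assert (z.df.iloc[0] == 0).all()

    def test_rows_standardized_to_mean_zero_sd_one(self, rng):
        values = rng.random((20, 6))
        z = zscore_rows(self._am(values, list("abcdef")))
        np.testing.assert_allclose(z.df.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.df.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_zscore_is_idempotent_on_nonconstant_rows(self, rng):
        values = rng.random((5, 8))
        z1 = zscore_rows(self._am(values, list("abcdefgh")))
        z2 = zscore_rows(z1.df)
        np.testing.assert_allclose(z1.df.to_numpy(), z2.df.to_numpy(),
                                   atol=1e-9)

    def test_single_column_rejected(self):
        with pytest.raises(ValidationError):
            zscore_rows(self._am([[1.0]], ["a"]))


class TestClustering:
    def test_identical_rows_merge_first_at_height_zero(self):
        df = pd.DataFrame([[0.0, 0.0], [5.0, 5.0], [5.0, 5.0], [9.0, 1.0]],
                          index=list("abcd"), columns=["s1", "s2"])
        result = cluster_rows(df)
        first = result.linkage[0]
        assert {result.ids[int(first[0])], result.ids[int(first[1])]} == {"b", "c"}
        assert first[2] == 0.0

    def test_planted_pairs_stay_adjacent_in_leaf_order(self):
        df = pd.DataFrame([[0.0, 0.1], [0.1, 0.0], [10.0, 9.9], [9.9, 10.0]],
                          index=list("abcd"), columns=["s1", "s2"])
        order = cluster_rows(df).leaf_order
        pos = {m: i for i, m in enumerate(order)}
        assert abs(pos["a"] - pos["b"]) == 1
        assert abs(pos["c"] - pos["d"]) == 1

    def test_row_permutation_preserves_tree(self, rng):
        df = pd.DataFrame(rng.random((8, 4)), index=list("abcdefgh"))
        perm = rng.permutation(8)
        shuffled = df.iloc[perm]
        r1, r2 = cluster_rows(df), cluster_rows(shuffled)
        np.testing.assert_allclose(sorted(r1.linkage[:, 2]),
                                   sorted(r2.linkage[:, 2]), atol=1e-9)
        part1 = r1.cut(3)
        part2 = r2.cut(3)
        # same partition of ids up to label renaming
        groups1 = {frozenset(m for m, g in part1.items() if g == k)
                   for k in set(part1.values())}
        groups2 = {frozenset(m for m, g in part2.items() if g == k)
                   for k in set(part2.values())}
        assert groups1 == groups2

    def test_column_axis_clusters_samples(self):
        df = pd.DataFrame([[1.0, 1.0, 9.0], [1.1, 0.9, 8.8]],
                          index=["m1", "m2"], columns=["s1", "s2", "s3"])
        result = cluster_rows(df, axis="columns")
        assert set(result.ids) == {"s1", "s2", "s3"}
        first = result.linkage[0]
        assert {result.ids[int(first[0])], result.ids[int(first[1])]} == {"s1", "s2"}

    def test_fewer_than_two_items_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["m1"])
        with pytest.raises(ValidationError):
            cluster_rows(df)

    def test_newick_reparses_with_same_leaves(self, tmp_path, rng):
        from io import StringIO
        from Bio import Phylo
        df = pd.DataFrame(rng.random((6, 3)), index=list("abcdef"))
        result = cluster_rows(df)
        tree = Phylo.read(StringIO(result.to_newick()), "newick")
        assert {t.name for t in tree.get_terminals()} == set("abcdef")


class TestReorderAndQuery:
    def test_reorder_matches_reference_order(self):
        am = AbundanceMatrix(
            pd.DataFrame([[1.0], [2.0], [3.0]], index=list("abc"),
                         columns=["s"]),
            assay=Assay.METAGENOME, normalization=Normalization.TOTAL_READS)
        out = reorder_like(am, row_order=["c", "a", "b"])
        assert list(out.df.index) == ["c", "a", "b"]
        with pytest.raises(ValidationError):
            reorder_like(am, row_order=["z"])

    def test_marker_gene_presence_with_supporting_orfs(self):
        df = pd.DataFrame([("o1", "M1", "K00399"), ("o2", "M1", "K00399"),
                           ("o3", "M2", "K00001")],
                          columns=["orf_id", "mag_id", "ko_id"])
        table = KOAnnotationTable(df)
        out = ko_presence_query(table, ["K00399"], mag_ids=["M1", "M2"])
        m1 = out[(out.mag_id == "M1")].iloc[0]
        m2 = out[(out.mag_id == "M2")].iloc[0]
        assert m1.present and m1.orf_ids == ["o1", "o2"]
        assert not m2.present and m2.orf_ids == []

    def test_query_on_empty_table_reports_all_absent(self):
        df = pd.DataFrame(columns=["orf_id", "mag_id", "ko_id"], dtype=str)
        out = ko_presence_query(KOAnnotationTable(df), ["K00399"],
                                mag_ids=["M1"])
        assert not out["present"].any()
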