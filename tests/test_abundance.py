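"""Gene/transcript abundance normalization."""

import numpy as np
import pandas as pd
import pytest

from magfunc.abundance import (Assay, KeyGeneCatalog, ReadHitTable,
                               SingleCopyCOGSet, build_abundance_matrix,
                               mean_hits_per_annotation,
                               normalize_gene_abundance_mg,
                               normalize_transcript_abundance)
from magfunc.errors import DegenerateDenominatorError, ValidationError
from magfunc.simulate import (SimulationConfig, generate_key_gene_catalog,
                              generate_read_hits, generate_scg_set)


def make_table(rows, total=1_000_000, assay=Assay.METAGENOME, sample="S1"):
    df = pd.DataFrame(rows, columns=["orf_id", "annotation_id", "hits"])
    return ReadHitTable(sample, df, total, assay)


@pytest.fixture()
def scg3():
    return SingleCopyCOGSet(("COG1", "COG2", "COG3"), expected_size=3)


class TestMeanHits:
    @pytest.mark.parametrize("rows,annotation,expected", [
        ([("o1", "K00399", 10), ("o2", "K00399", 20)], "K00399", 15.0),
        ([("o1", "K00399", 10)], "K00001", 0.0),
        ([("o1", "K00399", 7)], "K00399", 7.0),
        # zero-hit ORFs are real observations and dilute the mean
        ([("o1", "K00399", 10), ("o2", "K00399", 0)], "K00399", 5.0),
    ])
    def test_same_annotation_hits_are_averaged(self, rows, annotation, expected):
        assert mean_hits_per_annotation(make_table(rows), annotation) == expected


class TestMetagenomeNormalization:
    def test_gene_over_scg_ratio(self, scg3):
        rows = [("g", "K00001", 10)] + [(f"s{i}", c, 5)
                                        for i, c in enumerate(scg3.cog_ids)]
        assert normalize_gene_abundance_mg(
            make_table(rows), ["K00001"], scg3) == 2.0

    def test_absent_gene_scores_zero(self, scg3):
        rows = [(f"s{i}", c, 5) for i, c in enumerate(scg3.cog_ids)]
        assert normalize_gene_abundance_mg(
            make_table(rows), ["K00001"], scg3) == 0.0

    def test_scale_invariance_under_uniform_count_scaling(self, scg3, rng):
        hits = rng.integers(1, 100, size=4)
        rows = [("g1", "K00001", int(hits[0]))] + [
            (f"s{i}", c, int(h)) for i, (c, h) in
            enumerate(zip(scg3.cog_ids, hits[1:]))]
        base = normalize_gene_abundance_mg(make_table(rows), ["K00001"], scg3)
        scaled_rows = [(o, a, h * 7) for o, a, h in rows]
        scaled = normalize_gene_abundance_mg(
            make_table(scaled_rows), ["K00001"], scg3)
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_all_zero_scg_raises_typed_error(self, scg3):
        rows = [("g", "K00001", 10)] + [(f"s{i}", c, 0)
                                        for i, c in enumerate(scg3.cog_ids)]
        with pytest.raises(DegenerateDenominatorError):
            normalize_gene_abundance_mg(make_table(rows), ["K00001"], scg3)

    def test_wrong_assay_rejected(self, scg3):
        table = make_table([("g", "K00001", 1)], assay=Assay.METATRANSCRIPTOME)
        with pytest.raises(ValidationError):
            normalize_gene_abundance_mg(table, ["K00001"], scg3)


class TestTranscriptNormalization:
    def test_hits_over_library_size(self):
        table = make_table([("g", "K00001", 100)], total=1_000_000,
                           assay=Assay.METATRANSCRIPTOME)
        assert normalize_transcript_abundance(table, ["K00001"]) == 1e-4

    def test_display_scale_multiplies(self):
        table = make_table([("g", "K00001", 100)], total=1_000_000,
                           assay=Assay.METATRANSCRIPTOME)
        assert normalize_transcript_abundance(
            table, ["K00001"], scale=1e6) == pytest.approx(100.0)

    def test_homogeneity_in_hits_and_total(self, rng):
        hits = int(rng.integers(1, 1000))
        t1 = make_table([("g", "K00001", hits)], total=2_000_000,
                        assay=Assay.METATRANSCRIPTOME)
        t2 = make_table([("g", "K00001", 3 * hits)], total=1_000_000,
                        assay=Assay.METATRANSCRIPTOME)
        v1 = normalize_transcript_abundance(t1, ["K00001"])
        v2 = normalize_transcript_abundance(t2, ["K00001"])
        assert v2 == pytest.approx(6 * v1, abs=1e-9)

    def test_zero_library_size_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            make_table([("g", "K00001", 1)], total=0,
                       assay=Assay.METATRANSCRIPTOME)


class TestMatrixAssembly:
    def _catalog(self):
        return KeyGeneCatalog(pd.DataFrame([
            {"category": "methane", "gene_name": "mcr", "ko_ids": ["K00399"]},
            {"category": "sulphur", "gene_name": "sox", "ko_ids": ["K17224"]},
        ]))

    def test_single_cell_matches_scalar_op(self, scg3):
        rows = [("g", "K00399", 10)] + [(f"s{i}", c, 5)
                                        for i, c in enumerate(scg3.cog_ids)]
        table = make_table(rows)
        matrix = build_abundance_matrix([table], self._catalog(), scg=scg3)
        assert matrix.df.loc["mcr", "S1"] == normalize_gene_abundance_mg(
            table, ["K00399"], scg3)

    def test_absent_gene_gives_all_zero_row(self, scg3):
        rows = [(f"s{i}", c, 5) for i, c in enumerate(scg3.cog_ids)]
        matrix = build_abundance_matrix([make_table(rows)], self._catalog(),
                                        scg=scg3)
        assert (matrix.df.loc["sox"] == 0).all()

    def test_mixed_assays_rejected(self, scg3):
        t1 = make_table([("g", "K00399", 1)], sample="S1")
        t2 = make_table([("g", "K00399", 1)], sample="S2",
                        assay=Assay.METATRANSCRIPTOME)
        with pytest.raises(ValidationError, match="mixed"):
            build_abundance_matrix([t1, t2], self._catalog(), scg=scg3)

    def test_row_order_of_input_table_is_irrelevant(self, scg3, rng):
        rows = [("g", "K00399", 10), ("g2", "K17224", 4)] + [
            (f"s{i}", c, 5) for i, c in enumerate(scg3.cog_ids)]
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        m1 = build_abundance_matrix([make_table(rows)], self._catalog(), scg=scg3)
        m2 = build_abundance_matrix([make_table(shuffled)], self._catalog(),
                                    scg=scg3)
        assert m1.df.equals(m2.df)

    def test_planted_abundances_recovered_exactly(self):
        config = SimulationConfig(seed=3, n_mg_samples=4, n_mt_samples=3)
        catalog = generate_key_gene_catalog(config)
        scg = generate_scg_set(config)
        mg, mt, truth = generate_read_hits(config, catalog, scg)
        m_mg = build_abundance_matrix(mg, catalog, scg=scg)
        m_mt = build_abundance_matrix(mt, catalog)
        np.testing.assert_allclose(
            m_mg.df.to_numpy(),
            truth.planted_gene_abundance_mg.loc[m_mg.df.index,
                                                m_mg.df.columns].to_numpy(),
            atol=1e-9)
        np.testing.assert_allclose(
            m_mt.df.to_numpy(),
            truth.planted_gene_abundance_mt.loc[m_mt.df.index,
                                                m_mt.df.columns].to_numpy(),
            atol=1e-12)

    def test_planted_fold_difference_between_samples(self):
        # construct exact counts: gene 3x more abundant in S2 than S1
        scg = SingleCopyCOGSet(("COG1", "COG2"), expected_size=2)
        t1 = make_table([("g", "K00001", 10), ("a", "COG1", 10),
                         ("b", "COG2", 10)], sample="S1")
        t2 = make_table([("g", "K00001", 60), ("a", "COG1", 20),
                         ("b", "COG2", 20)], sample="S2")
        catalog = KeyGeneCatalog(pd.DataFrame([
            {"category": "x", "gene_name": "g", "ko_ids": ["K00001"]}]))
        matrix = build_abundance_matrix([t1, t2], catalog, scg=scg)
        ratio = matrix.df.loc["g", "S2"] / matrix.df.loc["g", "S1"]
        assert ratio == pytest.approx(3.0, abs=1e-9)
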