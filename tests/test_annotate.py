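"""Database search, precursor-fragment linking, sugar assignment and the
Jaccard isomer score."""

import numpy as np
import pytest

from diaflav import annotate, chemcore, featdet
from diaflav.dbio import CompoundRecord
from diaflav.featdet import AlignedRow, AlignedTable

from test_featdet import feature


def table_of(rows, level=1, samples=("A",)):
    return AlignedTable(level, list(samples), rows)


def row_at(mz, rt, sample="A", height=1e5, sigma=0.02):
    f = feature(sample, mz, rt, height, sigma=sigma)
    return AlignedRow(mz, rt, {sample: f})


class TestSearchMs1:
    def test_quercetin_hexoside_via_deprotonation(self):
        db = [CompoundRecord("Isoquercitrin", 464.0955, rt=None, rt_wildcard=True)]
        table = table_of([row_at(463.0869, 2.55)])
        hits = annotate.search_ms1(table, db)
        assert hits
        assert hits[0].adduct.name == "[M-H]-"
        assert hits[0].ppm == pytest.approx(-2.9, abs=0.5)

    def test_no_match(self):
        db = [CompoundRecord("Isoquercitrin", 464.0955, rt_wildcard=True)]
        assert annotate.search_ms1(table_of([row_at(999.999, 1.0)]), db) == []

    def test_isobars_ranked_by_ppm(self):
        db = [
            CompoundRecord("Farther", 464.0965, rt_wildcard=True),
            CompoundRecord("Closer", 464.0955, rt_wildcard=True),
        ]
        hits = annotate.search_ms1(table_of([row_at(463.0880, 2.0)]), db)
        assert [h.record.name for h in hits] == ["Closer", "Farther"]
        assert [h.rank for h in hits] == [0, 1]

    def test_stable_under_db_permutation(self):
        db = [
            CompoundRecord("Farther", 464.0965, rt_wildcard=True),
            CompoundRecord("Closer", 464.0955, rt_wildcard=True),
        ]
        t = table_of([row_at(463.0880, 2.0)])
        fwd = [h.record.name for h in annotate.search_ms1(t, db)]
        rev = [h.record.name for h in annotate.search_ms1(t, db[::-1])]
        assert fwd == rev

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            annotate.search_ms1(table_of([]), [])


class TestSearchMs2:
    def test_kaempferol_heterolytic(self, fragment_db):
        hits = annotate.search_ms2(table_of([row_at(285.0386, 2.87)], level=2),
                                   fragment_db)
        assert hits[0].record.label == "Kaempferol [M-H]-"
        assert -6.7 <= hits[0].ppm <= -6.3

    def test_kaempferol_radical(self, fragment_db):
        hits = annotate.search_ms2(table_of([row_at(284.0321, 2.85)], level=2),
                                   fragment_db)
        assert hits[0].record.label == "Kaempferol [M-H].-"
        assert hits[0].record.cleavage == chemcore.HOMOLYTIC_O

    def test_no_match(self, fragment_db):
        assert annotate.search_ms2(table_of([row_at(150.0, 1.0)], level=2),
                                   fragment_db) == []


class TestLinking:
    CFG = featdet.DetectionConfig()

    def test_identical_traces_link_with_unit_correlation(self):
        ms1 = table_of([row_at(463.088, 2.55)])
        ms2 = table_of([row_at(301.035, 2.55, height=5e4)], level=2)
        pairs = annotate.link_precursor_fragment(ms1, ms2)
        assert len(pairs) == 1
        assert pairs[0].correlation == pytest.approx(1.0, abs=1e-9)
        assert pairs[0].nloss == pytest.approx(162.053, abs=1e-3)
        assert not pairs[0].intensity_warning

    def test_rt_offset_beyond_tolerance_not_linked(self):
        ms1 = table_of([row_at(463.088, 2.55)])
        ms2 = table_of([row_at(301.035, 2.75)], level=2)
        assert annotate.link_precursor_fragment(ms1, ms2, rt_tol=0.04) == []

    def test_fragment_above_precursor_flagged(self):
        ms1 = table_of([row_at(463.088, 2.55, height=1e4)])
        ms2 = table_of([row_at(301.035, 2.55, height=5e4)], level=2)
        pairs = annotate.link_precursor_fragment(ms1, ms2)
        assert pairs and pairs[0].intensity_warning

    def test_noisy_coeluting_pair_links_at_threshold(self):
        rng = np.random.default_rng(21)
        grid = 2.55 + np.linspace(-0.04, 0.04, 17)
        clean = 1e5 * np.exp(-0.5 * ((grid - 2.55) / 0.02) ** 2)
        f1 = featdet.Feature("A", 1, 463.088, 2.55, 1e5, 1.0, grid[0], grid[-1],
                             grid, clean * rng.uniform(0.9, 1.1, grid.size))
        f2 = featdet.Feature("A", 2, 301.035, 2.55, 5e4, 1.0, grid[0], grid[-1],
                             grid + 0.002,
                             0.5 * clean * rng.uniform(0.9, 1.1, grid.size))
        ms1 = table_of([AlignedRow(463.088, 2.55, {"A": f1})])
        ms2 = table_of([AlignedRow(301.035, 2.55, {"A": f2})], level=2)
        pairs = annotate.link_precursor_fragment(ms1, ms2, min_corr=0.8)
        assert len(pairs) == 1
        assert pairs[0].correlation > 0.9


def linked_pair(ms1_mz, ms2_mz, rt=2.5):
    ms1_row = row_at(ms1_mz, rt)
    ms2_row = row_at(ms2_mz, rt, height=4e4)
    return annotate.LinkedPair(0, 0, ms1_row, ms2_row, ms1_mz, ms2_mz, rt,
                               0.0, 1.0, 0.4, ms1_mz - ms2_mz)


class TestAssignGlycoside:
    def frag(self, db, label):
        rec = next(f for f in db if f.label == label)
        return annotate.Annotation(0, rec, rec.mz, 0.0)

    def test_quercetin_o_hexoside(self, fragment_db):
        pair = linked_pair(463.0869, 301.0319)
        g = annotate.assign_glycoside(pair, self.frag(fragment_db, "Quercetin [M-H]-"))
        assert g.bond == "O"
        assert g.report == "Quercetin O-hexoside"

    def test_radical_loss_corrected_by_one_hydrogen(self, fragment_db):
        # loss 163.06 only matches hexose after the radical correction
        pair = linked_pair(463.0880, 300.0276)
        g = annotate.assign_glycoside(pair, self.frag(fragment_db, "Quercetin [M-H].-"))
        assert g.bond == "O"
        assert g.report == "Quercetin O-hexoside"

    def test_apigenin_di_c(self, fragment_db):
        pair = linked_pair(563.1420, 353.0673)
        g = annotate.assign_glycoside(
            pair, self.frag(fragment_db, "Apigenin-di-etenol [M-H]-"))
        assert g.bond == "C"
        assert g.report == "Apigenin di-C-hexoside or C-hexoside-C-pentoside"

    def test_unmatched_loss_reported_numerically(self, fragment_db):
        pair = linked_pair(801.0354, 301.0354)
        g = annotate.assign_glycoside(pair, self.frag(fragment_db, "Quercetin [M-H]-"))
        assert g.bond == "unclassified"
        assert "500.0000" in g.report

    def test_bond_types_exclusive(self, fragment_db):
        # O-assignments always stem from bare/radical aglycone evidence,
        # C-assignments from residue fragments; never both on one pair
        for rec in fragment_db:
            pair = linked_pair(rec.mz + 162.0528, rec.mz)
            g = annotate.assign_glycoside(pair, annotate.Annotation(0, rec, rec.mz, 0.0))
            if g.bond == "O":
                assert g.cleavage in (chemcore.HETEROLYTIC_O, chemcore.HOMOLYTIC_O)
            if g.bond == "C":
                assert g.cleavage == chemcore.C_RESIDUE

    def test_requires_fragment_annotation(self):
        pair = linked_pair(463.0869, 301.0319)
        bogus = annotate.Annotation(0, CompoundRecord("x", 464.0955), 463.088, 0.0)
        with pytest.raises(ValueError, match="no MS2 aglycone annotation"):
            annotate.assign_glycoside(pair, bogus)


class TestJaccard:
    def test_identical(self):
        assert annotate.jaccard_isomer_score([1.0, 2.0], {"X": [1.0, 2.0]})[0][1] == 1.0

    def test_disjoint(self):
        assert annotate.jaccard_isomer_score([1.0], {"X": [5.0]})[0][1] == 0.0

    def test_partial_overlap(self):
        (name, score), = annotate.jaccard_isomer_score(
            [100.0, 200.0, 300.0], {"X": [100.0, 200.0, 400.0]})
        assert score == pytest.approx(0.5)

    def test_ranks_true_isomer_first(self):
        observed = [285.0404, 284.0326, 327.0510]
        candidates = {
            "Kaempferol": [285.0404, 284.0326, 327.0510],
            "Luteolin": [285.0404, 133.0295, 151.0037],
        }
        ranked = annotate.jaccard_isomer_score(observed, candidates)
        assert ranked[0][0] == "Kaempferol"

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            annotate.jaccard_isomer_score([], {"X": [1.0]})
        with pytest.raises(ValueError):
            annotate.jaccard_isomer_score([1.0], {})


class TestClassifyBackbone:
    def test_toy_counts(self, fragment_db):
        pairs = [linked_pair(447.0927, 285.0404), linked_pair(447.0927, 285.0404),
                 linked_pair(431.0978, 269.0455)]
        recs = {f.label: f for f in fragment_db}
        glyco = [
            annotate.assign_glycoside(
                pairs[0], annotate.Annotation(0, recs["Kaempferol [M-H]-"],
                                              285.0404, 0.0)),
            annotate.assign_glycoside(
                pairs[1], annotate.Annotation(0, recs["Kaempferol [M-H]-"],
                                              285.0404, 0.0)),
            annotate.assign_glycoside(
                pairs[2], annotate.Annotation(0, recs["Apigenin [M-H]-"],
                                              269.0455, 0.0)),
        ]
        counts = annotate.classify_backbone(glyco)
        assert counts.loc["A", ("Kaempferol", "flavonol")] == 2
        assert counts.loc["A", ("Apigenin", "flavone")] == 1

    def test_empty(self):
        assert annotate.classify_backbone([]).empty
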