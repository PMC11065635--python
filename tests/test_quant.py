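"""tRNA naming, occupancy, relative expression, aggregation, diversity."""

import numpy as np
import pandas as pd
import pytest

import trnapool as tp
from trnapool.quant import TRNANameError


class TestParseName:
    @pytest.mark.parametrize(
        "name,isotype,anticodon,group,copy",
        [
            ("tRNA-Ile-TAT-2-1", "Ile", "TAT", 2, 1),
            ("tRNA-Arg-TCT-4-1", "Arg", "TCT", 4, 1),
            ("Gly-GCC-1-2", "Gly", "GCC", 1, 2),
            ("tRNA-iMet-CAT-1-1", "iMet", "CAT", 1, 1),
        ],
    )
    def test_standard_dialects(self, name, isotype, anticodon, group, copy):
        rec = tp.parse_trna_gene_name(name)
        assert (rec.isotype, rec.anticodon, rec.transcript_group, rec.copy) == (
            isotype, anticodon, group, copy)
        assert not rec.is_trx

    def test_en_dash_normalised(self):
        rec = tp.parse_trna_gene_name("tRNA-Ile-TAT-2–1")
        assert rec.name == "tRNA-Ile-TAT-2-1"
        assert rec.copy == 1

    def test_trx_flagged_for_exclusion(self):
        rec = tp.parse_trna_gene_name("tRX-NNN-1-1")
        assert rec.is_trx

    @pytest.mark.parametrize("bad", ["", "banana", "tRNA-Ile-TAT", "Ile--1-1"])
    def test_unparseable_raises(self, bad):
        with pytest.raises(TRNANameError):
            tp.parse_trna_gene_name(bad)


class TestOccupancy:
    def _cm(self, a, b):
        counts = pd.DataFrame({"X_r1": [a], "X_r2": [b]}, index=["tRNA-Gly-GCC-1-1"])
        sheet = pd.DataFrame(
            {"cell_type": ["X", "X"], "replicate": [1, 2],
             "group": ["1", "1"], "class": ["neuronal", "neuronal"]},
            index=counts.columns)
        return tp.CountMatrix(counts, sheet)

    @pytest.mark.parametrize("a,b,expected", [
        (3, 5, True),      # >2 in both replicates
        (2, 100, False),   # strict inequality: 2 is not > 2
        (0, 0, False),
        (3, 2, False),
    ])
    def test_strict_rule_over_all_replicates(self, a, b, expected):
        table, any_ct = tp.classify_expressed(self._cm(a, b), min_reads=2)
        assert bool(table.loc["tRNA-Gly-GCC-1-1", "X"]) is expected
        assert bool(any_ct.iloc[0]) is expected

    def test_monotone_in_counts(self, toy_counts):
        base, _ = tp.classify_expressed(toy_counts)
        bumped = tp.CountMatrix(toy_counts.counts + 7, toy_counts.sample_sheet)
        more, _ = tp.classify_expressed(bumped)
        assert (more | ~base).all().all()  # expressed never flips off


class TestRelativeExpression:
    def test_simple_fractions(self):
        counts = pd.DataFrame({"s1": [30, 10, 60]},
                              index=["tRNA-Ala-AGC-1-1", "tRNA-Gly-GCC-1-1",
                                     "tRNA-Ile-TAT-1-1"])
        sheet = pd.DataFrame({"cell_type": ["X"], "replicate": [1],
                              "group": ["1"], "class": ["neuronal"]},
                             index=["s1"])
        expr = tp.relative_expression(tp.CountMatrix(counts, sheet))
        assert np.allclose(expr.values["s1"].values, [0.30, 0.10, 0.60])

    def test_cell_type_level_is_mean_of_replicate_fractions(self):
        counts = pd.DataFrame({"s1": [40, 60], "s2": [600, 400]},
                              index=["tRNA-Ala-AGC-1-1", "tRNA-Gly-GCC-1-1"])
        sheet = pd.DataFrame({"cell_type": ["X", "X"], "replicate": [1, 2],
                              "group": ["1", "1"], "class": ["neuronal"] * 2},
                             index=counts.columns)
        expr = tp.relative_expression(tp.CountMatrix(counts, sheet))
        ct = expr.cell_type_levels()
        assert np.allclose(ct["X"].values, [0.5, 0.5])

    def test_trx_excluded_before_normalisation(self, toy_counts):
        expr = tp.relative_expression(toy_counts, exclude_trx=True)
        assert "tRX-NNN-1-1" not in expr.values.index
        assert np.allclose(expr.values.sum(axis=0), 1.0, atol=1e-9)

    def test_fractions_sum_to_one(self, small_study):
        expr = tp.relative_expression(small_study.chip, exclude_trx=False)
        assert np.allclose(expr.values.sum(axis=0), 1.0, atol=1e-9)

    def test_all_zero_sample_is_an_error(self):
        counts = pd.DataFrame({"s1": [0, 0]},
                              index=["tRNA-Ala-AGC-1-1", "tRNA-Gly-GCC-1-1"])
        sheet = pd.DataFrame({"cell_type": ["X"], "replicate": [1],
                              "group": ["1"], "class": ["neuronal"]},
                             index=["s1"])
        with pytest.raises(ValueError, match="s1"):
            tp.relative_expression(tp.CountMatrix(counts, sheet))


class TestAggregate:
    def test_transcript_group_sums_members(self, toy_counts):
        expr = tp.relative_expression(toy_counts)
        grp = tp.aggregate(expr, "transcript_group")
        ile = grp.values.loc["Ile-TAT-2"]
        genes = expr.values.loc[["tRNA-Ile-TAT-2-1", "tRNA-Ile-TAT-2-2",
                                 "tRNA-Ile-TAT-2-3"]].sum()
        assert np.allclose(ile.values, genes.values)

    def test_isotype_totals_conserved(self, small_study):
        expr = tp.relative_expression(small_study.chip)
        for level in ("isoacceptor", "isotype", "transcript_group"):
            agg = tp.aggregate(expr, level, small_study.chip.records())
            assert np.allclose(agg.values.sum(axis=0),
                               expr.values.sum(axis=0), atol=1e-12)

    def test_aggregate_commutes_with_normalisation(self, small_study):
        # normalising then aggregating == aggregating counts then normalising
        cm = small_study.chip
        expr_then_agg = tp.aggregate(tp.relative_expression(cm, exclude_trx=False),
                                     "isoacceptor", cm.records())
        collapsed = cm.counts.groupby(
            [cm.records()[g].isoacceptor for g in cm.genes]).sum()
        direct = collapsed / collapsed.sum(axis=0)
        assert np.allclose(
            expr_then_agg.values.sort_index().values,
            direct.sort_index().values, atol=1e-12)


class TestCompositionAndDiversity:
    def _table(self, values, genes):
        df = pd.DataFrame({"ct": values}, index=genes)
        sheet = pd.DataFrame({"cell_type": ["ct"], "replicate": [1],
                              "group": ["1"], "class": ["neuronal"]},
                             index=["ct"])
        return tp.FamilyExpressionTable("gene", df, sheet)

    def test_within_family_fractions(self):
        t = self._table([0.90, 0.05, 0.05],
                        ["tRNA-Ile-TAT-1-1", "tRNA-Ile-TAT-2-1", "tRNA-Ile-TAT-3-1"])
        comp = tp.family_composition(t)
        assert np.allclose(comp["ct"].values, [0.90, 0.05, 0.05])

    def test_zero_total_family_is_undefined(self):
        t = self._table([0.0, 0.0, 1.0],
                        ["tRNA-Ile-TAT-1-1", "tRNA-Ile-TAT-2-1", "tRNA-Gly-GCC-1-1"])
        comp = tp.family_composition(t)
        assert comp.loc["tRNA-Ile-TAT-1-1", "ct"] != comp.loc["tRNA-Ile-TAT-1-1", "ct"]  # NaN

    @pytest.mark.parametrize("fracs,expected", [
        ([0.90, 0.05, 0.05], 1),   # 0.05 is not > 0.05 (strict)
        ([0.25, 0.25, 0.25, 0.25], 4),
        ([0.52, 0.48], 2),
    ])
    def test_contributor_counts(self, fracs, expected):
        genes = [f"tRNA-Ile-TAT-{i+1}-1" for i in range(len(fracs))]
        t = self._table(fracs, genes)
        comp = tp.family_composition(t)
        overall, per_family = tp.diversity_fraction(comp, threshold=0.05)
        assert per_family.loc["Ile-TAT", "ct"] == expected
        assert overall["ct"] == expected / len(fracs)


class TestCollapseIdentical:
    def test_members_summed_and_totals_preserved(self, toy_counts):
        collapsed = tp.collapse_identical(toy_counts)
        assert collapsed.counts.loc["Ile-TAT-2"].tolist() == \
            toy_counts.counts.iloc[:3].sum().tolist()
        assert (collapsed.counts.sum(axis=0) ==
                toy_counts.counts.sum(axis=0)).all()

    def test_row_count(self, toy_counts):
        collapsed = tp.collapse_identical(toy_counts)
        # 3 identical Ile-TAT-2 genes -> 1 row; Arg + tRX stay
        assert collapsed.counts.shape[0] == 3

    def test_collapse_then_aggregate_matches_direct(self, small_study):
        # collapsing identical-mature groups first must not change
        # isoacceptor-level counts
        cm = small_study.chip
        collapsed = tp.collapse_identical(cm)
        # collapsed units are named Iso-ANT-<group>; strip the group suffix
        keys = [u.rsplit("-", 1)[0] if not u.startswith("tRX") else u
                for u in collapsed.counts.index]
        via_collapse = collapsed.counts.groupby(keys).sum()
        orig_keys = [cm.records()[g].isoacceptor if not cm.records()[g].is_trx
                     else g for g in cm.genes]
        direct = cm.counts.groupby(orig_keys).sum()
        assert via_collapse.sort_index().equals(direct.sort_index())
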