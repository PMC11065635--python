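"""Codon counting, weighted usage, specificity sets, correlation, ratios."""

import numpy as np
import pandas as pd
import pytest

import trnapool as tp
from trnapool.codon import CdsPolicyError, codon_count_matrix, longest_cds_per_gene
from trnapool.genetic_code import SENSE_CODONS
from tests.conftest import (
    brute_force_pearson,
    brute_force_spearman,
    brute_force_weighted_usage,
)


class TestCodonCounts:
    def test_counts_exclude_terminal_stop(self):
        c = tp.codon_counts("ATGAAATAA")
        assert c[SENSE_CODONS.index("ATG")] == 1
        assert c[SENSE_CODONS.index("AAA")] == 1
        assert c.sum() == 2

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(CdsPolicyError, match="multiple of 3"):
            tp.codon_counts("ATGAA")

    def test_internal_stop_rejected(self):
        with pytest.raises(CdsPolicyError, match="internal stop"):
            tp.codon_counts("ATGTAAAAA")

    def test_tolerate_policy_keeps_what_it_can(self):
        c = tp.codon_counts("ATGTAAAAA", policy="tolerate")
        assert c[SENSE_CODONS.index("AAA")] == 1

    def test_matrix_collects_rejections(self):
        mat, rejected = codon_count_matrix(
            {"ok": "ATGAAATAA", "short": "ATGAA", "internal": "ATGTAAAAA"})
        assert list(mat.index) == ["ok"]
        assert set(rejected) == {"short", "internal"}

    def test_longest_cds_per_gene(self):
        cds = {"t1": "ATG" + "AAA" * 5, "t2": "ATG" + "AAA" * 9, "t3": "ATGCCC"}
        kept = longest_cds_per_gene(cds, {"t1": "g1", "t2": "g1", "t3": "g2"})
        assert set(kept) == {"t2", "t3"}


class TestWeightedUsage:
    def _mat(self, rows):
        return pd.DataFrame(rows).T.reindex(columns=list(SENSE_CODONS)).fillna(0)

    def test_two_transcript_example(self):
        mat = self._mat({"T1": {"AAA": 2}, "T2": {"GGG": 2}})
        usage = tp.weighted_codon_usage(mat, pd.Series({"T1": 10.0, "T2": 30.0}))
        assert usage.usage["AAA"] == pytest.approx(25.0)
        assert usage.usage["GGG"] == pytest.approx(75.0)

    def test_equal_tpm_equals_pooled_frequency(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.integers(0, 20, size=(30, 61)),
                           index=[f"t{i}" for i in range(30)],
                           columns=list(SENSE_CODONS))
        tpm = pd.Series(3.0, index=mat.index)
        usage = tp.weighted_codon_usage(mat, tpm)
        pooled = 100.0 * mat.sum(axis=0) / mat.values.sum()
        assert np.allclose(usage.usage.values, pooled.values, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(3, 25))
            mat = pd.DataFrame(rng.integers(0, 30, size=(n, 61)),
                               index=[f"t{i}" for i in range(n)],
                               columns=list(SENSE_CODONS))
            tpm = pd.Series(rng.random(n) * 100, index=mat.index)
            fast = tp.weighted_codon_usage(mat, tpm).usage
            slow = brute_force_weighted_usage(mat, tpm)
            assert np.allclose(fast.values, slow[fast.index].values, rtol=1e-12)

    def test_invariant_to_tpm_rescaling_and_zero_transcripts(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.integers(0, 30, size=(10, 61)),
                           index=[f"t{i}" for i in range(10)],
                           columns=list(SENSE_CODONS))
        tpm = pd.Series(rng.random(10), index=mat.index)
        u1 = tp.weighted_codon_usage(mat, tpm).usage
        u2 = tp.weighted_codon_usage(mat, tpm * 1234.5).usage
        assert np.allclose(u1.values, u2.values, atol=1e-12)
        mat2 = pd.concat([mat, mat.iloc[[0]].set_axis(["extra"])])
        tpm2 = pd.concat([tpm, pd.Series({"extra": 0.0})])
        u3 = tp.weighted_codon_usage(mat2, tpm2).usage
        assert np.allclose(u1.values, u3.values, atol=1e-12)

    def test_all_zero_tpm_is_error(self):
        mat = self._mat({"T1": {"AAA": 2}})
        with pytest.raises(ValueError):
            tp.weighted_codon_usage(mat, pd.Series({"T1": 0.0}))

    def test_usage_sums_to_100(self, small_study):
        mat, _ = codon_count_matrix(small_study.cds)
        for col in small_study.tpm.columns[:4]:
            u = tp.weighted_codon_usage(mat, small_study.tpm[col])
            assert abs(u.usage.sum() - 100.0) < 1e-6


class TestSpecificGeneSets:
    def test_fold_rule(self):
        a = pd.Series({"hi": 100.0, "mid": 40.0, "flat": 10.0})
        b = pd.Series({"hi": 1.0, "mid": 1.0, "flat": 10.0})
        set_a, set_b = tp.specific_gene_sets(a, b, fold=50, pseudo=0.01)
        assert set_a == {"hi"}          # ratio ~100
        assert "mid" not in set_a       # ratio ~40 < 50
        assert set_b == set()

    def test_planted_transcripts_recovered(self, small_study):
        truth = small_study.truth
        cts = list(truth.specific_transcripts)
        tpm = small_study.tpm
        cols = {ct: [c for c in tpm.columns if c.rsplit("_", 1)[0] == ct]
                for ct in cts}
        set_a, set_b = tp.specific_gene_sets(
            tpm[cols[cts[0]]].mean(axis=1), tpm[cols[cts[1]]].mean(axis=1))
        realized_a = {t for t, r in truth.realized_specificity[cts[0]].items()
                      if r >= 50}
        assert realized_a <= set_a


class TestCognateAndCorrelation:
    @pytest.mark.parametrize("anticodon,codon", [
        ("TAT", "ATA"), ("TCT", "AGA"), ("AGC", "GCT"),
    ])
    def test_reverse_complement(self, anticodon, codon):
        assert tp.anticodon_to_codon(anticodon) == codon

    def _usage(self, overrides):
        base = pd.Series(100.0 / 61, index=list(SENSE_CODONS))
        for c, v in overrides.items():
            base[c] = v
        base *= 100.0 / base.sum()
        return tp.CodonUsageVector(base)

    def test_monotone_levels_give_rho_one(self):
        usage = self._usage({"ATA": 5.0, "AGA": 3.0, "GCT": 1.0})
        levels = pd.Series({"Ile-TAT": usage.usage["ATA"] * 2,
                            "Arg-TCT": usage.usage["AGA"] * 2,
                            "Ala-AGC": usage.usage["GCT"] * 2})
        rho, pairs = tp.codon_anticodon_correlation(levels, usage)
        assert rho == pytest.approx(1.0)

    def test_wobble_only_codons_excluded(self):
        usage = self._usage({})
        levels = pd.Series({"Ile-TAT": 30.0, "Arg-TCT": 30.0, "Ala-AGC": 40.0})
        rho, pairs = tp.codon_anticodon_correlation(levels, usage)
        wobble_only = pairs[pairs.exclusion_reason == "wobble-only decoding"]
        assert len(wobble_only) == 61 - 3
        assert pairs["included"].sum() == 3

    def test_stop_cognate_family_excluded(self):
        # anticodon TTA reverse-complements to the stop TAA: no WC cognate
        usage = self._usage({})
        levels = pd.Series({"Ile-TAT": 20.0, "Arg-TCT": 20.0, "Ala-AGC": 20.0,
                            "Sec-TTA": 40.0}).rename(
                                index={"Sec-TTA": "SeC-TTA"})
        rho, pairs = tp.codon_anticodon_correlation(levels, usage)
        row = pairs[pairs.isoacceptor == "SeC-TTA"].iloc[0]
        assert not row.included and "stop" in row.exclusion_reason

    def test_matches_rank_oracle(self, small_study):
        mat, _ = codon_count_matrix(small_study.cds)
        usage = tp.weighted_codon_usage(mat, small_study.tpm.iloc[:, 0])
        expr = tp.aggregate(tp.relative_expression(small_study.chip),
                            "isoacceptor", small_study.chip.records())
        levels = expr.cell_type_levels().iloc[:, 0]
        rho, pairs = tp.codon_anticodon_correlation(levels, usage)
        inc = pairs[pairs["included"]]
        assert rho == pytest.approx(
            brute_force_spearman(inc["trna_pct"], inc["codon_pct"]), abs=1e-12)

    def test_too_few_pairs_is_error(self):
        usage = self._usage({})
        with pytest.raises(ValueError):
            tp.codon_anticodon_correlation(pd.Series({"Ile-TAT": 1.0}), usage)


class TestMatchedMismatched:
    def test_identical_distributions_give_p_one(self):
        m = pd.DataFrame(0.5, index=["A", "B", "C"], columns=["A", "B", "C"])
        u, p = tp.matched_mismatched_test(m)
        assert p == 1.0

    def test_shifted_diagonal_gives_small_p_exact_u(self):
        m = pd.DataFrame(0.1, index=list("ABCD"), columns=list("ABCD"))
        np.fill_diagonal(m.values, [0.9, 0.91, 0.92, 0.93])
        u, p = tp.matched_mismatched_test(m)
        # all 4 matched values exceed all 12 mismatched: U = 48, exact
        # two-sided p = 2 * C(4,4-choose)/C(16,4) = 2/1820*... enumerate:
        from itertools import combinations
        pooled = np.concatenate([np.full(12, 0.1), [0.9, 0.91, 0.92, 0.93]])
        exact_ge = 0
        total = 0
        for idx in combinations(range(16), 4):
            sel = pooled[list(idx)]
            rest = np.delete(pooled, list(idx))
            u_perm = sum((s > r) + 0.5 * (s == r) for s in sel for r in rest)
            total += 1
            if abs(u_perm - 24) >= abs(u - 24):
                exact_ge += 1
        assert u == 48
        assert p == pytest.approx(exact_ge / total, abs=0.02)

    def test_label_permutation_preserves_pooled_multiset(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.random((4, 4)), index=list("ABCD"),
                         columns=list("ABCD"))
        perm = list("CADB")
        mp = m.loc[perm, perm]
        assert sorted(m.values.ravel()) == sorted(mp.values.ravel())


class TestSupplyDemand:
    def test_ratio_examples(self):
        usage = tp.CodonUsageVector(pd.Series(
            {c: (1.0 if c == "ATA" else 2.0 if c == "AGA" else
                 97.0 / 59) for c in SENSE_CODONS}))
        levels = pd.Series({"Ile-TAT": 2.0, "Arg-TCT": 1.0})
        # pad to percentages of a full pool
        table = tp.supply_demand_ratio(levels, usage)
        assert table.loc["Ile-TAT", "ratio"] == pytest.approx(2.0)
        assert table.loc["Arg-TCT", "ratio"] == pytest.approx(0.5)

    def test_constructed_two_to_one_ratio(self):
        # build usage and levels so Ile-TAT's supply/demand is exactly
        # twice Arg-TCT's
        usage_vals = pd.Series(100.0 / 61, index=list(SENSE_CODONS))
        usage = tp.CodonUsageVector(usage_vals)
        u = 100.0 / 61
        levels = pd.Series({"Ile-TAT": 4 * u, "Arg-TCT": 2 * u})
        table = tp.supply_demand_ratio(levels, usage)
        r = table["ratio"]
        assert r["Ile-TAT"] / r["Arg-TCT"] == pytest.approx(2.0, abs=1e-9)

    def test_zero_usage_is_error(self):
        vals = pd.Series(0.0, index=list(SENSE_CODONS))
        vals["AAA"] = 100.0
        usage = tp.CodonUsageVector(vals)
        with pytest.raises(ValueError):
            tp.supply_demand_ratio(pd.Series({"Ile-TAT": 100.0}), usage)
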