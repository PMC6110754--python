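"""Consensus merging, substitution classification, protein-change parsing,
overlap tests, burden statistics, and correlation machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from itertools import combinations
from scipy import stats

import nrf2atlas as na
from nrf2atlas.catalogue import pearson_fisher

KEY = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Chromosome",
       "Start_Position", "Reference_Allele", "Tumor_Seq_Allele2"]


def _rec(case="TCGA-AA-0001", gene="NFE2L2", chrom="chr2", pos=100,
         ref="C", alt="A", **extra):
    return {"Tumor_Sample_Barcode": case, "Hugo_Symbol": gene,
            "Chromosome": chrom, "Start_Position": pos,
            "Reference_Allele": ref, "Tumor_Seq_Allele2": alt, **extra}


class TestMergeCallerCalls:
    def test_singleton_dropped_at_default_threshold(self):
        tables = {"MuSE": pd.DataFrame([_rec()])}
        assert na.merge_caller_calls(tables, min_callers=2).empty

    def test_min_callers_one_returns_all_unique_keys(self):
        tables = {
            "MuSE": pd.DataFrame([_rec(), _rec(pos=200)]),
            "VarScan2": pd.DataFrame([_rec()]),
        }
        out = na.merge_caller_calls(tables, min_callers=1)
        assert len(out) == 2
        assert set(out["n_callers"]) == {1, 2}

    def test_callers_column_is_union_of_reporters(self):
        tables = {c: pd.DataFrame([_rec()]) for c in ("MuSE", "MuTect2", "VarScan2")}
        out = na.merge_caller_calls(tables, min_callers=2)
        assert out.loc[0, "callers"] == "MuSE;MuTect2;VarScan2"

    def test_within_caller_duplicates_deduplicated_with_warning(self):
        tables = {"MuSE": pd.DataFrame([_rec(), _rec()])}
        with pytest.warns(UserWarning, match="duplicate"):
            out = na.merge_caller_calls(tables, min_callers=1)
        assert len(out) == 1 and out.loc[0, "n_callers"] == 1

    def test_unknown_caller_name_rejected(self):
        with pytest.raises(ValueError, match="unknown caller"):
            na.merge_caller_calls({"Strelka": pd.DataFrame([_rec()])})

    def test_monotone_in_min_callers(self, hotspot_cohort):
        _, sim, _ = hotspot_cohort
        tables = na.per_caller_tables(sim.maf)
        sizes = [len(na.merge_caller_calls(tables, min_callers=k))
                 for k in (1, 2, 3, 4)]
        assert sizes == sorted(sizes, reverse=True)

    def test_consensus_recovers_planted_truth_exactly(self, hotspot_cohort):
        # concordance 1.0 with singleton spurious calls: the >=2-caller
        # filter removes exactly the spurious set
        _, sim, consensus = hotspot_cohort
        got = set(map(tuple, consensus[KEY].itertuples(index=False)))
        want = set(map(tuple, sim.truth[KEY].itertuples(index=False)))
        assert got == want


class TestClassifySubstitution:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("A", "G", "transition"), ("G", "A", "transition"),
        ("C", "T", "transition"), ("T", "C", "transition"),
        ("C", "A", "transversion"), ("A", "T", "transversion"),
        ("G", "C", "transversion"), ("T", "G", "transversion"),
    ])
    def test_known_pairs(self, ref, alt, expected):
        assert na.classify_substitution(ref, alt) == expected

    @given(st.sampled_from("ACGT"), st.sampled_from("ACGT"))
    @settings(deadline=None)
    def test_complement_strand_invariance(self, ref, alt):
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        if ref == alt:
            with pytest.raises(ValueError):
                na.classify_substitution(ref, alt)
        else:
            assert na.classify_substitution(ref, alt) == \
                na.classify_substitution(comp[ref], comp[alt])

    @pytest.mark.parametrize("ref,alt", [("A", "A"), ("N", "A"), ("A", "N")])
    def test_invalid_inputs_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            na.classify_substitution(ref, alt)


class TestParseProteinChange:
    @pytest.mark.parametrize("hgvsp,expected", [
        ("p.R34G", ("R", 34, "G", "missense")),
        ("p.R34*", ("R", 34, "*", "nonsense")),
        ("p.D29H", ("D", 29, "H", "missense")),
        ("p.E82fs", ("E", 82, None, "frameshift")),
        ("p.L45L", ("L", 45, "L", "silent")),
        ("", (None, None, None, None)),
    ])
    def test_parses(self, hgvsp, expected):
        assert na.parse_protein_change(hgvsp) == expected

    def test_malformed_raises_and_table_annotation_flags(self):
        with pytest.raises(ValueError):
            na.parse_protein_change("R34G")
        table = pd.DataFrame([_rec(HGVSp_Short="garbage"),
                              _rec(pos=200, HGVSp_Short="p.R34G")])
        with pytest.warns(UserWarning, match="malformed"):
            ann = na.annotate_protein_changes(table)
        assert ann["protein_pos"].tolist() == [None, 34]


class TestMutantCaseSets:
    def test_empty_table_gives_empty_set(self):
        empty = pd.DataFrame(columns=KEY + ["Variant_Classification"])
        assert na.mutant_case_sets(empty, "NFE2L2") == set()

    def test_case_with_two_records_counts_once_and_silent_excluded(self):
        table = pd.DataFrame([
            _rec(Variant_Classification="Missense_Mutation"),
            _rec(pos=200, Variant_Classification="Missense_Mutation"),
            _rec(case="TCGA-AA-0002", Variant_Classification="Silent"),
        ])
        assert na.mutant_case_sets(table, "NFE2L2") == {"TCGA-AA-0001"}
        assert na.mutant_case_sets(table, "NFE2L2", nonsynonymous_only=False) == \
            {"TCGA-AA-0001", "TCGA-AA-0002"}

    def test_planted_mutant_cases_recovered(self, hotspot_cohort):
        _, sim, consensus = hotspot_cohort
        planted = set(sim.truth.loc[
            (sim.truth["Hugo_Symbol"] == "NFE2L2")
            & (sim.truth["Variant_Classification"] != "Silent"),
            "Tumor_Sample_Barcode"])
        assert na.mutant_case_sets(consensus, "NFE2L2") == planted


class TestOverlapTest:
    def test_hand_enumeration_n10(self):
        a, b = set(range(5)), {0, 1, 2, 3}
        res = na.overlap_test(a, b, 10)
        assert res.observed == 4
        assert res.p_value == pytest.approx(5 / 210)
        assert res.expected == pytest.approx(2.0)

    def test_disjoint_sets_give_p_one(self):
        res = na.overlap_test({"a"}, {"b"}, 10)
        assert res.observed == 0 and res.p_value == pytest.approx(1.0)

    def test_exact_p_equals_brute_force_enumeration_small_universe(self):
        universe = list(range(8))
        a = {0, 1, 2}
        n_b = 4
        k_obs = 2
        hits = total = 0
        for b in combinations(universe, n_b):
            total += 1
            hits += len(a & set(b)) >= k_obs
        res = na.overlap_test(a, set(universe[:1] + universe[4:7]), 8)
        assert res.observed == 1  # sanity of the constructed observed set
        p_exact = float(stats.hypergeom.sf(k_obs - 1, 8, 3, 4))
        assert p_exact == pytest.approx(hits / total)

    def test_montecarlo_within_three_se_of_exact(self):
        # cohort-scale instance: universe 10364, sets 226 and 222, overlap 12
        a, b = set(range(226)), set(range(214, 436))
        res = na.overlap_test(a, b, 10364)
        assert res.observed == 12
        assert res.expected == pytest.approx(226 * 222 / 10364)
        m = 100_000
        mc = na.overlap_test(a, b, 10364, mode="montecarlo", m=m, seed=4)
        se = np.sqrt(res.p_value * (1 - res.p_value) / m)
        assert abs(mc.p_value - res.p_value) < 3 * se + 2 / (m + 1)

    def test_universe_smaller_than_set_rejected(self):
        with pytest.raises(ValueError):
            na.overlap_test(set(range(5)), set(), 3)


class TestCaseBurden:
    def test_mixed_records_counted_by_definition(self):
        table = pd.DataFrame([
            _rec(ref="A", alt="G"),
            _rec(pos=200, ref="C", alt="A"),
            _rec(pos=300, ref="AT", alt="A"),  # deletion: unclassified
        ])
        out = na.case_burden(table)
        assert out.loc[0, ["n_total", "n_transition", "n_transversion"]].tolist() \
            == [3, 1, 1]

    def test_absent_cases_get_zero_rows(self):
        table = pd.DataFrame([_rec()])
        sheet = pd.DataFrame({"case_id": ["TCGA-AA-0001", "TCGA-AA-0002"],
                              "tissue": "tumor"})
        out = na.case_burden(table, sheet)
        assert out.set_index("case_id").loc["TCGA-AA-0002"].sum() == 0

    def test_pooled_tstv_fraction_matches_odds(self, hotspot_cohort):
        _, _, consensus = hotspot_cohort
        out = na.case_burden(consensus)
        ts, tv = out["n_transition"].sum(), out["n_transversion"].sum()
        n = ts + tv
        assert abs(ts / n - 2 / 3) < 4 * np.sqrt((2 / 9) / n)


class TestBurdenComparison:
    @staticmethod
    def _frame(act_burdens, inact_burdens, ttype="LUAD"):
        n = len(act_burdens) + len(inact_burdens)
        burden = pd.DataFrame({
            "case_id": [f"c{i}" for i in range(n)],
            "n_total": list(act_burdens) + list(inact_burdens),
            "n_transition": 0, "n_transversion": 0,
        })
        activated = pd.Series([True] * len(act_burdens) + [False] * len(inact_burdens))
        return burden, activated, pd.Series([ttype] * n)

    def test_identical_distributions_give_p_one(self):
        burden, act, tt = self._frame([5, 5, 5], [5, 5, 5])
        out = na.burden_comparison(burden, act, tt)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_exact_u_three_vs_three(self):
        # complete separation at 3v3: smallest attainable two-sided exact p
        burden, act, tt = self._frame([10, 11, 12], [1, 2, 3])
        out = na.burden_comparison(burden, act, tt)
        assert out.loc[0, "p_value"] == pytest.approx(0.1)
        assert out.loc[0, "median_active"] == 11

    def test_group_missing_skipped_with_warning(self):
        burden, act, tt = self._frame([1, 2], [])
        with pytest.warns(UserWarning, match="lacks one group"):
            out = na.burden_comparison(burden, act, tt)
        assert out.empty

    def test_shifted_burden_detected_with_power(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.poisson(15, size=40)
            b = rng.poisson(10, size=40)
            burden, act, tt = self._frame(a, b)
            out = na.burden_comparison(burden, act, tt)
            hits += out.loc[0, "p_value"] < 0.05
        assert hits >= 9


class TestCorrelation:
    def test_exact_linear_relation(self):
        res = pearson_fisher([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_hand_computed_r_and_fisher_p(self):
        res = pearson_fisher([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8)
        z = np.arctanh(0.8)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(z * np.sqrt(2)))

    def test_zero_variance_reported_absent_with_warning(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = pearson_fisher([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(res.r)

    def test_activation_correlates_with_transversion_burden(self):
        # 20 tumor types where activation tracks transversion burden
        rng = np.random.default_rng(0)
        tv = rng.uniform(1, 20, size=20)
        per_type = pd.DataFrame({
            "activation_fraction": 0.02 * tv + rng.normal(0, 0.03, 20),
            "median_tv": tv,
            "median_ts": rng.uniform(1, 20, size=20),
        })
        res = na.activation_mutation_correlation(per_type)
        assert res["transversion"].r > 0
        assert res["transversion"].p_value < 0.05

    def test_fewer_than_four_types_rejected(self):
        per_type = pd.DataFrame({"activation_fraction": [0.1, 0.2, 0.3],
                                 "median_tv": [1, 2, 3], "median_ts": [1, 2, 3]})
        with pytest.raises(ValueError):
            na.activation_mutation_correlation(per_type)
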