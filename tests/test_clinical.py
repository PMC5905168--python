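"""Subtyping, descriptive statistics, exact tests, variant sharing."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from tumourprint.clinical import (
    classify_subtype,
    descriptive_table,
    fisher_exact,
    load_atm_series_table,
    logistic_assoc,
    resolve_her2,
    variant_sharing,
)


class TestSubtype:
    @pytest.mark.parametrize(
        "er,pr,her2,ki67,expected",
        [
            ("+", "+", "-", 25, "luminal B"),
            ("+", "-", "-", 25, "luminal B"),     # PR does not matter
            ("+", "+", "-", 10, "luminal A"),
            ("+", "-", "-", 10, "luminal A"),
            ("+", "+", "+", 30, "luminal B/HER2+"),
            ("-", "-", "-", 40, "triple-negative"),
            ("-", "-", "+", 40, "HER2-overexpressing"),
            ("+", "+", "-", "unknown", "unknown"),
            ("unknown", "+", "-", 30, "unknown"),
            ("-", "+", "-", 30, "unknown"),        # outside the rule set
            ("+", "+", "+", 10, "unknown"),        # ER+/HER2+/low Ki-67
        ],
    )
    def test_rules(self, er, pr, her2, ki67, expected):
        rec = {"er": er, "pr": pr, "her2": her2, "ki67_pct": ki67}
        assert classify_subtype(rec) == expected

    def test_her2_resolution_via_ihc_and_fish(self):
        assert resolve_her2(None, 3, None) == "+"
        assert resolve_her2(None, 2, "yes") == "+"
        assert resolve_her2(None, 2, "no") == "-"
        assert resolve_her2(None, 2, None) == "unknown"
        assert resolve_her2(None, 1, None) == "-"

    def test_her2_2plus_fish_unknown_gives_unknown_subtype(self):
        rec = {"er": "+", "pr": "+", "her2": "unknown", "her2_ihc_score": 2,
               "fish_amplified": "unknown", "ki67_pct": 30}
        assert classify_subtype(rec) == "unknown"

    def test_exhaustive_grid_total_and_deterministic(self):
        """classify_subtype is total over the full categorical grid."""
        vals = ["+", "-", "unknown"]
        kis = [5, 25, "unknown"]
        for er, pr, her2, ki in itertools.product(vals, vals, vals, kis):
            rec = {"er": er, "pr": pr, "her2": her2, "ki67_pct": ki}
            s1 = classify_subtype(rec)
            s2 = classify_subtype(rec)
            assert s1 == s2
            assert isinstance(s1, str)


class TestDescriptiveTable:
    def test_series_table_reproduces_published_percentages(self):
        """The packaged 36-tumour series: ductal 86%, ER+ 97%, luminal B 46%
        and luminal A 36% among known."""
        table = descriptive_table(load_atm_series_table())
        get = lambda var, cat: table[
            (table["variable"] == var) & (table["category"] == cat)
        ].iloc[0]
        assert get("histology", "ductal")["pct"] == 86
        assert get("er", "+")["pct"] == 97
        assert get("subtype", "luminal B")["pct"] == 46
        assert get("subtype", "luminal A")["pct"] == 36
        assert get("subtype", "triple-negative")["count"] == 1

    def test_known_percentages_sum_to_100(self):
        table = descriptive_table(load_atm_series_table())
        for var, grp in table.groupby("variable"):
            known = grp[grp["category"] != "unknown"]
            assert abs(known["pct"].sum() - 100) <= 1, var

    def test_single_record_100pct(self):
        df = pd.DataFrame([{"histology": "ductal", "er": "+", "pr": "+",
                            "her2": "-", "ki67_pct": 30}])
        table = descriptive_table(df)
        row = table[(table["variable"] == "histology")
                    & (table["category"] == "ductal")].iloc[0]
        assert row["count"] == 1 and row["pct"] == 100

    def test_empty_cohort(self):
        assert len(descriptive_table(pd.DataFrame())) == 0


def enumeration_fisher_2xk(table):
    """Oracle: enumerate all tables with fixed margins and sum point
    probabilities <= observed."""
    t = np.asarray(table, int)
    row, col = t.sum(1), t.sum(0)

    def prob(tab):
        num = sum(math.lgamma(x + 1) for x in row) + \
            sum(math.lgamma(x + 1) for x in col) - math.lgamma(t.sum() + 1) - \
            sum(math.lgamma(x + 1) for x in tab.flat)
        return math.exp(num)

    p_obs = prob(t)
    total = 0.0
    ranges = [range(c + 1) for c in col]
    for top in itertools.product(*ranges):
        if sum(top) != row[0]:
            continue
        tab = np.array([list(top), list(col - np.array(top))])
        if (tab < 0).any():
            continue
        p = prob(tab)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestFisher:
    def test_worked_examples(self):
        assert fisher_exact([[3, 1], [1, 3]]) == pytest.approx(0.4857, abs=2e-4)
        assert fisher_exact([[10, 0], [0, 10]]) == pytest.approx(2 / 184756,
                                                                 rel=1e-6)
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        [[3, 1], [1, 3]], [[8, 2], [3, 7]], [[1, 9], [5, 5]],
        [[12, 4], [6, 14]], [[0, 7], [6, 2]],
    ])
    def test_matches_scipy_2x2(self, table):
        _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
        assert fisher_exact(table) == pytest.approx(p, rel=1e-9)

    @pytest.mark.parametrize("table", [
        [[3, 1, 4], [2, 5, 1]], [[6, 0, 2], [1, 4, 3]], [[2, 2, 2], [3, 0, 5]],
    ])
    def test_matches_enumeration_oracle_2x3(self, table):
        assert fisher_exact(table) == pytest.approx(
            enumeration_fisher_2xk(table), rel=1e-9)

    def test_zero_margin_warns_p1(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            assert fisher_exact([[0, 0], [3, 4]]) == 1.0


class TestLogistic:
    def test_null_association_or_one(self):
        rng = np.random.default_rng(1)
        group = np.repeat([0, 1], 100)
        outcome = np.tile([0, 1], 100)
        res = logistic_assoc(outcome, group)
        assert not res.separation
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_2x2_closed_form_or(self):
        """Counts 20/10 vs 10/20 give OR = (20*20)/(10*10) = 4 unadjusted."""
        outcome = np.concatenate([np.ones(20), np.zeros(10),
                                  np.ones(10), np.zeros(20)])
        group = np.concatenate([np.ones(30), np.zeros(30)])
        res = logistic_assoc(outcome, group)
        assert res.odds_ratio == pytest.approx(4.0, rel=1e-4)
        assert res.p_value < 0.05

    def test_adjustment_accepts_covariates(self):
        rng = np.random.default_rng(2)
        n = 200
        group = rng.integers(0, 2, n)
        age = rng.uniform(30, 70, n)
        sex = np.where(rng.random(n) < 0.9, "F", "M")
        logit = -2 + 1.2 * group + 0.02 * age
        outcome = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        res = logistic_assoc(outcome, group, sex=sex, age=age)
        assert not res.separation
        assert res.odds_ratio > 1

    def test_complete_separation_flagged(self):
        outcome = np.array([0] * 10 + [1] * 10)
        group = outcome.copy()
        res = logistic_assoc(outcome, group)
        assert res.separation
        assert res.p_value is None


def vdf(keys, genes=None):
    rows = []
    for i, k in enumerate(keys):
        rows.append({"chrom": "chr1", "pos": 100 + k, "ref": "A", "alt": "T",
                     "gene": (genes or {}).get(k, f"G{k}"),
                     "coding": k in (genes or {})})
    return pd.DataFrame(rows)


class TestVariantSharing:
    def test_worked_example(self):
        """Sets {A,B,C}, {B,C,D}, {C,E}: exactly-2 = 1, exactly-3 = 1."""
        sets = {"T1": vdf([1, 2, 3]), "T2": vdf([2, 3, 4]), "T3": vdf([3, 5])}
        out = variant_sharing(sets)
        assert out.set_index("shared_by")["n_variants"].to_dict() == \
            {1: 3, 2: 1, 3: 1}

    def test_identical_sets_all_shared(self):
        sets = {"T1": vdf([1, 2]), "T2": vdf([1, 2])}
        out = variant_sharing(sets)
        assert out.set_index("shared_by")["n_variants"].to_dict() == {1: 0, 2: 2}

    def test_disjoint_sets_all_private(self):
        sets = {"T1": vdf([1]), "T2": vdf([2]), "T3": vdf([3])}
        out = variant_sharing(sets)
        assert out.set_index("shared_by")["n_variants"].to_dict() == \
            {1: 3, 2: 0, 3: 0}

    def test_total_conservation(self):
        rng = np.random.default_rng(3)
        sets = {f"T{i}": vdf(sorted(rng.choice(50, size=20, replace=False)))
                for i in range(4)}
        out = variant_sharing(sets)
        distinct = len({(r.chrom, r.pos, r.ref, r.alt)
                        for df in sets.values() for r in df.itertuples()})
        assert out["n_variants"].sum() == distinct

    def test_duplicates_deduplicated_with_warning(self):
        df = pd.concat([vdf([1]), vdf([1])], ignore_index=True)
        with pytest.warns(UserWarning, match="duplicate"):
            out = variant_sharing({"T1": df})
        assert out["n_variants"].sum() == 1

    def test_gene_sharing_uses_coding_only(self, paper_bundle):
        sets = {t: df for t, df in paper_bundle.variants.groupby("sample")}
        out = variant_sharing(sets).set_index("shared_by")
        assert out.loc[2, "n_genes"] == 6   # six genes altered in two tumours
        assert out.loc[4, "n_variants"] == 0
        assert out.loc[3, "n_variants"] == 1
        assert out.loc[2, "n_variants"] == 10
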