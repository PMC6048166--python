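"""Candidate triangulation: t-test fidelity, recurrence filters, set algebra."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metscreen.candidates import (
    amplification_recurrence_filter,
    amplified_mutated_intersect,
    paired_differential_expression,
    passing_genes,
    triangulate,
    unpaired_differential_expression,
)


def paired_t_oracle(diffs):
    """Textbook paired t computed in exact rational arithmetic."""
    d = [Fraction(x).limit_denominator(10**12) for x in diffs]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    t = float(mean) / np.sqrt(float(var) / n)
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return t, p


def pooled_t_oracle(x1, x2):
    """Homoscedastic two-sample t in exact rational arithmetic."""
    a = [Fraction(v).limit_denominator(10**12) for v in x1]
    b = [Fraction(v).limit_denominator(10**12) for v in x2]
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    ss1 = sum((v - m1) ** 2 for v in a)
    ss2 = sum((v - m2) ** 2 for v in b)
    pooled = (ss1 + ss2) / (n1 + n2 - 2)
    se = np.sqrt(float(pooled) * (1 / n1 + 1 / n2))
    t = float(m2 - m1) / se
    p = 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return t, p


class TestPairedDE:
    def test_matches_exact_arithmetic_oracle(self, expr_3pairs):
        """Planted per-pair log2 differences {1.0, 1.1, 0.9} reproduce the
        textbook paired t statistic and p-value to 1e-10."""
        mat, pairs = expr_3pairs
        res = paired_differential_expression(mat, pairs).set_index("gene_id")
        # recover the exact log2 diffs the fixture planted
        log = np.log2(mat.values + 1.0)
        diffs = log[0, 3:] - log[0, :3]
        t_exp, p_exp = paired_t_oracle(diffs)
        assert res.loc["g_shift", "statistic"] == pytest.approx(t_exp, abs=1e-10)
        assert res.loc["g_shift", "p_value"] == pytest.approx(p_exp, abs=1e-10)
        assert res.loc["g_shift", "fold_change"] == pytest.approx(2.0 ** diffs.mean(), rel=1e-12)

    def test_identical_groups_give_p_one_flagged(self, expr_3pairs):
        mat, pairs = expr_3pairs
        mat = mat.copy()
        mat[["t1", "t2", "t3"]] = mat[["r1", "r2", "r3"]].values
        res = paired_differential_expression(mat, pairs)
        assert (res["p_value"] == 1.0).all()
        assert res["zero_variance"].all()
        assert not res["passes"].any()

    def test_rejects_degenerate_designs(self, expr_3pairs):
        mat, pairs = expr_3pairs
        with pytest.raises(ValueError, match="2 complete pairs"):
            paired_differential_expression(mat, pairs[:1])
        with pytest.raises(ValueError, match="bijective"):
            paired_differential_expression(mat, [("r1", "t1"), ("r1", "t2")])


class TestUnpairedDE:
    def test_matches_pooled_variance_oracle(self, rng):
        mat = pd.DataFrame(
            rng.lognormal(5, 1, size=(20, 6)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(6)],
        )
        groups = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        res = unpaired_differential_expression(mat, groups, "a", "b").set_index("gene_id")
        log = np.log2(mat.values + 1.0)
        for i, g in enumerate(mat.index):
            t_exp, p_exp = pooled_t_oracle(log[i, :3], log[i, 3:])
            assert res.loc[g, "statistic"] == pytest.approx(t_exp, abs=1e-10)
            assert res.loc[g, "p_value"] == pytest.approx(p_exp, abs=1e-10)

    def test_fold_change_exactly_at_threshold_fails_strict_rule(self):
        # group2 = 1.5x group1 on the log2(x+1) scale with tiny variance
        lo = np.array([100.0, 100.2, 99.8, 100.1])
        hi = (lo + 1.0) * 1.5 - 1.0  # exact 1.5 ratio after the +1 offset
        mat = pd.DataFrame([np.concatenate([lo, hi])], index=["g"],
                           columns=[f"s{i}" for i in range(8)])
        groups = {f"s{i}": ("a" if i < 4 else "b") for i in range(8)}
        res = unpaired_differential_expression(mat, groups, "a", "b", fc_threshold=1.5)
        assert res.loc[0, "p_value"] < 0.01
        assert res.loc[0, "fold_change"] == pytest.approx(1.5, rel=1e-9)
        assert not res.loc[0, "passes"]

    def test_large_shift_with_near_zero_variance_passes(self):
        lo = np.array([16.0, 16.0, 16.000001])
        hi = lo * 4.0
        mat = pd.DataFrame([np.concatenate([lo, hi])], index=["g"],
                           columns=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        res = unpaired_differential_expression(mat, groups, "a", "b")
        assert res.loc[0, "passes"]

    def test_null_type_I_error_and_p_uniformity(self):
        """10,000 null genes: rejection rate at p<0.01 inside the binomial CI
        and the p-value distribution is uniform (KS)."""
        rng = np.random.default_rng(7)
        n = 10_000
        mat = pd.DataFrame(
            2.0 ** rng.normal(8, 1, size=(n, 8)),
            index=[f"g{i}" for i in range(n)],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = {f"s{i}": ("a" if i < 4 else "b") for i in range(8)}
        res = unpaired_differential_expression(mat, groups, "a", "b")
        rate = (res["p_value"] < 0.01).mean()
        ci = 2.58 * np.sqrt(0.01 * 0.99 / n)  # 99% binomial interval
        assert abs(rate - 0.01) < ci + 1e-12
        ks = stats.kstest(res["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_threshold_monotonicity(self, rng):
        mat = pd.DataFrame(
            rng.lognormal(5, 1, size=(200, 6)),
            index=[f"g{i}" for i in range(200)],
            columns=[f"s{i}" for i in range(6)],
        )
        groups = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        loose = unpaired_differential_expression(mat, groups, "a", "b", 0.2, 1.2)
        tight = unpaired_differential_expression(mat, groups, "a", "b", 0.05, 2.0)
        assert passing_genes(tight) <= passing_genes(loose)


class TestAmplificationFilter:
    def test_recurrence_fraction_boundary(self, rng):
        """1.5x in 8/154 samples (~5.19%) is retained; 7/154 (~4.55%) is not."""
        n = 154
        base = np.full((2, n), 1.0)
        base[0, :8] = 1.5
        base[1, :7] = 1.5
        cna = pd.DataFrame(base, index=["kept", "dropped"], columns=[f"t{i}" for i in range(n)])
        kept = amplification_recurrence_filter(cna, 1.5, 0.05)
        assert kept == {"kept"}

    def test_all_diploid_is_empty(self):
        cna = pd.DataFrame(np.ones((5, 10)), index=list("abcde"))
        assert amplification_recurrence_filter(cna) == set()

    def test_matches_per_gene_counting_oracle(self, rng):
        cna = pd.DataFrame(
            rng.lognormal(0, 0.3, size=(50, 40)),
            index=[f"g{i}" for i in range(50)],
        )
        got = amplification_recurrence_filter(cna, 1.5, 0.1)
        expected = {
            g for g in cna.index
            if sum(v >= 1.5 for v in cna.loc[g]) / 40 >= 0.1
        }
        assert got == expected


class TestMutationIntersect:
    def test_requires_validated_missense(self):
        muts = pd.DataFrame(
            [
                {"gene_id": "A", "sample_id": "s1", "variant_class": "missense", "validated": True},
                {"gene_id": "B", "sample_id": "s1", "variant_class": "nonsense", "validated": True},
                {"gene_id": "C", "sample_id": "s2", "variant_class": "missense", "validated": False},
            ]
        )
        assert amplified_mutated_intersect({"A", "B", "C"}, muts) == {"A"}
        assert amplified_mutated_intersect({"A"}, muts.iloc[0:0]) == set()

    def test_matches_brute_force_record_scan(self, rng):
        genes = [f"g{i}" for i in range(30)]
        records = pd.DataFrame(
            {
                "gene_id": rng.choice(genes, 200),
                "sample_id": rng.choice([f"t{i}" for i in range(20)], 200),
                "variant_class": rng.choice(["missense", "nonsense", "silent"], 200),
                "validated": rng.choice([True, False], 200),
            }
        )
        amplified = set(rng.choice(genes, 15, replace=False))
        expected = set()
        for _, r in records.iterrows():
            if (
                r["gene_id"] in amplified
                and r["variant_class"] == "missense"
                and r["validated"]
            ):
                expected.add(r["gene_id"])
        assert amplified_mutated_intersect(amplified, records) == expected


class TestTriangulate:
    def test_disjoint_inputs_give_empty_table(self):
        out = triangulate({"a"}, {"b"}, {"c"}, set())
        assert out.empty

    def test_mutation_only_gene_flagged_correctly(self):
        out = triangulate(set(), set(), set(), {"X"})
        assert out["gene_id"].tolist() == ["X"]
        row = out.iloc[0]
        assert row["amplified_and_mutated"]
        assert not row[["de_up_a", "de_up_b", "amplified"]].any()

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_set_algebra_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        symbols = [f"G{i}" for i in range(200)]
        pick = lambda: set(rng.choice(symbols, size=rng.integers(0, 100)))
        a, b, amp, ampmut = pick(), pick(), pick(), pick()
        out = triangulate(a, b, amp, ampmut)
        expected = sorted((a & b & amp) | ampmut)
        assert out["gene_id"].tolist() == expected

    def test_orthology_mapping_and_unmapped_dropped(self):
        orth = pd.DataFrame(
            {"mouse": ["m1", "m2", "m2"], "human": ["H1", "H2", "H3"]}
        )
        out = triangulate({"m1", "m2", "m_unmapped"}, {"m1", "m2"},
                          {"H1", "H2", "H3"}, set(), orthology=orth)
        # m2 expands one-to-many to H2 and H3; m_unmapped is dropped
        assert out["gene_id"].tolist() == ["H1", "H2", "H3"]

    def test_invariant_to_input_ordering_and_duplicates(self):
        a = ["g2", "g1", "g1"]
        out1 = triangulate(a, ["g1", "g2"], ["g1", "g2"], ["g9"])
        out2 = triangulate(["g1", "g2"], ["g2", "g1"], ["g2", "g1"], ["g9", "g9"])
        pd.testing.assert_frame_equal(out1, out2)
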