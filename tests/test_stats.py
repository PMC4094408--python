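"""Normality gate, routed group comparisons, letters, and regressions."""

import numpy as np
import pandas as pd
import pytest

from mucofract.stats import (
    compact_letter_display,
    compare_groups,
    dunn_pairwise,
    fisher_lsd_pairwise,
    normality_gate,
    simple_regression,
)


def _table(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "v": np.concatenate(list(groups.values())),
            "g": np.repeat(list(groups), [len(x) for x in groups.values()]),
        }
    )


class TestNormalityGate:
    def test_gaussian_samples_usually_pass(self):
        hits = sum(
            normality_gate(np.random.default_rng(s).normal(0, 1, 200)).gate == "normal"
            for s in range(100)
        )
        assert hits >= 90

    def test_skewed_samples_fail(self):
        hits = sum(
            normality_gate(np.random.default_rng(s).exponential(1, 108)).gate == "non-normal"
            for s in range(100)
        )
        assert hits >= 99

    def test_tiny_or_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            normality_gate([3.0] * 10)


class TestCompareGroups:
    def test_identical_distributions_share_a_letter(self):
        shared = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            t = _table({g: rng.normal(0, 1, 27) for g in "ABCD"})
            res = compare_groups(t, "v", "g")
            common = set.intersection(*(set(v) for v in res.letters.values()))
            shared += bool(common)
        assert shared >= 90

    def test_shifted_group_earns_distinct_letter(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            groups = {g: rng.normal(0, 1, 27) for g in "ABC"}
            groups["D"] = rng.normal(3, 1, 27)  # 3 pooled SDs away
            res = compare_groups(_table(groups), "v", "g")
            others = set("".join(res.letters[g] for g in "ABC"))
            hits += not (set(res.letters["D"]) & others)
        assert hits >= 95

    def test_routing_matches_gate(self):
        rng = np.random.default_rng(3)
        normal = _table({g: rng.normal(0, 1, 30) for g in "AB"})
        skewed = _table({g: rng.exponential(1, 54) for g in "AB"})
        assert compare_groups(normal, "v", "g").test == "anova_fisher_lsd"
        assert compare_groups(skewed, "v", "g").test == "kruskal_wallis"

    def test_constant_data_errors_at_the_gate(self):
        t = _table({"A": np.ones(5), "B": np.ones(5)})
        with pytest.raises(ValueError, match="constant"):
            compare_groups(t, "v", "g")

    def test_undersized_groups_rejected(self):
        t = _table({"A": np.arange(5.0), "B": np.array([1.0])})
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(t, "v", "g")

    def test_kruskal_statistic_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        groups = {g: rng.exponential(scale, 40) for g, scale in zip("ABC", (1, 1.5, 2.5))}
        raw = compare_groups(_table(groups), "v", "g")
        cubed = compare_groups(
            _table({g: x**3 for g, x in groups.items()}), "v", "g"
        )
        assert raw.test == cubed.test == "kruskal_wallis"
        assert cubed.statistic == pytest.approx(raw.statistic, rel=1e-12)

    def test_permuted_labels_give_uniform_p(self):
        """Under label permutation the omnibus p-value is ~ Uniform(0,1)."""
        rng = np.random.default_rng(42)
        values = rng.normal(0, 1, 48)
        labels = np.repeat(list("ABCD"), 12)
        ps = []
        for _ in range(500):
            t = pd.DataFrame({"v": values, "g": rng.permutation(labels)})
            ps.append(compare_groups(t, "v", "g").p_value)
        from scipy.stats import kstest

        assert kstest(ps, "uniform").statistic < 0.05


class TestLetters:
    def test_significant_pairs_never_share_a_letter(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            names = list("ABCD")
            pw = pd.DataFrame(
                [
                    {"group_a": a, "group_b": b, "p": rng.random()}
                    for i, a in enumerate(names)
                    for b in names[i + 1 :]
                ]
            )
            letters = compact_letter_display(names, pw)
            for r in pw.itertuples():
                share = set(letters[r.group_a]) & set(letters[r.group_b])
                if r.p < 0.05:
                    assert not share
                assert letters[r.group_a]  # every group gets >= 1 letter

    def test_no_significance_means_one_shared_letter(self):
        pw = pd.DataFrame(
            [{"group_a": a, "group_b": b, "p": 0.9} for a, b in (("A", "B"), ("A", "C"), ("B", "C"))]
        )
        letters = compact_letter_display(["A", "B", "C"], pw)
        assert set(letters.values()) == {"a"}

    def test_pairwise_adjustments_are_conservative(self):
        rng = np.random.default_rng(7)
        groups = {g: rng.exponential(1, 25) for g in "ABCD"}
        raw = dunn_pairwise(groups)["p"].to_numpy()
        for method in ("bonferroni", "holm"):
            adj = dunn_pairwise(groups, adjust=method)["p"].to_numpy()
            assert (adj >= raw - 1e-12).all()

    def test_fisher_lsd_agrees_with_two_group_anova(self):
        rng = np.random.default_rng(11)
        groups = {"A": rng.normal(0, 1, 20), "B": rng.normal(1, 1, 20)}
        from scipy.stats import f_oneway

        p_anova = f_oneway(*groups.values()).pvalue
        p_lsd = fisher_lsd_pairwise(groups)["p"].iloc[0]
        assert p_lsd == pytest.approx(p_anova, rel=1e-9)


class TestRegression:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = simple_regression(x, 2 * x)
        assert res.beta_standardized == pytest.approx(1.0, abs=1e-12)
        assert res.p_value < 1e-10

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            simple_regression(np.ones(10), np.arange(10.0))

    def test_null_false_positive_rate_is_nominal(self):
        rng = np.random.default_rng(0)
        hits = sum(
            simple_regression(rng.normal(0, 1, 80), rng.normal(0, 1, 80)).p_value < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= hits / 1000 <= 0.07

    def test_standardized_effect_recovery(self):
        """True standardized slope -0.34 at n = 108 recovered within 0.1."""
        betas = []
        for s in range(21):
            rng = np.random.default_rng(100 + s)
            x = rng.normal(0, 1, 108)
            y = -0.34 * x + np.sqrt(1 - 0.34**2) * rng.normal(0, 1, 108)
            betas.append(simple_regression(x, y).beta_standardized)
        assert abs(np.median(betas) - (-0.34)) < 0.1
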