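"""Group summaries, t-vs-zero, ANOVA, LSD-t letters and family pooling."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from fprs import (
    IndexSample,
    anova_scenarios,
    family_pool,
    lsd_t,
    summarize,
    t_vs_zero,
)
from fprs.group_stats import GateViolationError, ZeroVarianceError


def sample(values, scenario="A1B", index="I", group="Pinus"):
    return IndexSample(np.asarray(values, float), group_label=group,
                       scenario_label=scenario, index_name=index)


def anova_ss_oracle(groups):
    """Matrix-free sums-of-squares one-way ANOVA."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = sps.f.sf(f, df_b, df_w)
    return f, p


class TestSummarize:
    def test_mean_std_n(self):
        s = summarize(sample([1.0, 2.0, 3.0]))
        assert (s.mean, s.std, s.n) == (2.0, 1.0, 3)

    def test_single_value_has_undefined_std(self):
        s = summarize(sample([4.2]))
        assert s.mean == 4.2 and s.std is None and s.n == 1

    def test_permutation_invariant(self, rng):
        v = rng.normal(size=12)
        a, b = summarize(sample(v)), summarize(sample(v[::-1]))
        assert a.mean == pytest.approx(b.mean)
        assert a.std == pytest.approx(b.std)


class TestTVsZero:
    def test_symmetric_sample_gives_t_zero(self):
        t, p, sig = t_vs_zero(sample([-1.0, 1.0]))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert sig == "ns"

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroVarianceError):
            t_vs_zero(sample([1.0, 1.0, 1.0]))

    def test_matches_textbook_formula(self):
        v = np.array([2.1, 1.9, 2.0, 2.2, 1.8])
        t, p, sig = t_vs_zero(sample(v))
        # independent evaluation of the one-sample t statistic
        t_ref = v.mean() / (v.std(ddof=1) / math.sqrt(len(v)))
        p_ref = 2 * sps.t.sf(abs(t_ref), len(v) - 1)
        assert t == pytest.approx(t_ref, abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-6)
        assert sig == "**"

    def test_significance_classes(self, rng):
        # marginal sample engineered near alpha = 0.05
        weak = sample([0.5, 1.5, -0.6, 1.2, 0.9, 1.1, -0.2, 0.8])
        _, p, sig = t_vs_zero(weak)
        expected = "**" if p < 0.01 else ("*" if p < 0.05 else "ns")
        assert sig == expected

    def test_type_one_error_calibration(self):
        """Empirical rejection rate under a zero-mean Gaussian null ~ 5%."""
        rng = np.random.default_rng(42)
        reps, n = 10_000, 10
        draws = rng.normal(size=(reps, n))
        tstat, pvals = sps.ttest_1samp(draws, 0.0, axis=1)
        # spot-check our scalar path agrees with the vectorized reference
        for i in range(5):
            t, p, _ = t_vs_zero(sample(draws[i]))
            assert p == pytest.approx(pvals[i])
        rate = float((pvals < 0.05).mean())
        assert abs(rate - 0.05) <= 0.01
        # p-values uniform under the null
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        g = [sample([1.0, 2.0, 3.0], scenario=s) for s in ("A1B", "A2", "B1")]
        f, p = anova_scenarios(g)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_groups_reduce_to_squared_t(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=6)
        f, p_f = anova_scenarios([sample(a, "A1B"), sample(b, "A2")])
        t, p_t = sps.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_separated_groups_highly_significant(self, rng):
        g = [
            sample(rng.normal(m, 0.01, size=6), scenario=s)
            for m, s in ((0, "A1B"), (0, "A2"), (10, "B1"))
        ]
        _, p = anova_scenarios(g)
        assert p < 1e-6

    def test_matches_sums_of_squares_oracle(self, rng):
        for _ in range(50):
            k = rng.integers(2, 5)
            sizes = rng.integers(2, 8, size=k)
            while sizes.sum() > 30:
                sizes = rng.integers(2, 8, size=k)
            arrays = [rng.normal(rng.normal(), 1.0, size=n) for n in sizes]
            groups = [sample(a, scenario=f"s{i}") for i, a in enumerate(arrays)]
            f, p = anova_scenarios(groups)
            f_ref, p_ref = anova_ss_oracle(arrays)
            assert f == pytest.approx(f_ref, rel=1e-9)
            assert p == pytest.approx(p_ref, rel=1e-9)

    def test_repeated_measures_variant_removes_species_effect(self, rng):
        base = rng.normal(size=10) * 5  # strong per-species block effect
        g1 = sample(base + rng.normal(0.0, 0.1, 10), "A1B")
        g2 = sample(base + rng.normal(1.0, 0.1, 10), "A2")
        _, p_plain = anova_scenarios([g1, g2])
        _, p_rm = anova_scenarios([g1, g2], repeated_measures=True)
        assert p_rm < p_plain  # blocking absorbs the species variance


class TestLsdT:
    def test_letters_separate_far_group(self, rng):
        a = sample(rng.normal(0.0, 0.05, 8), "A1B")
        b = sample(rng.normal(0.0, 0.05, 8), "A2")
        c = sample(rng.normal(5.0, 0.05, 8), "B1")
        comp = lsd_t([a, b, c])
        assert comp.performed
        assert comp.letters["A1B"] == comp.letters["A2"]
        assert comp.letters["B1"] != comp.letters["A1B"]

    def test_gate_blocks_on_nonsignificant_anova(self, rng):
        groups = [sample(rng.normal(0, 1, 8), s) for s in ("A1B", "A2", "B1")]
        comp = lsd_t(groups)
        assert not comp.performed
        assert comp.pairwise == {}
        with pytest.raises(GateViolationError):
            lsd_t(groups, strict=True)

    def test_letters_invariant_under_relabeling(self, rng):
        vals = [rng.normal(m, 0.05, 8) for m in (0.0, 0.0, 3.0)]
        comp1 = lsd_t([sample(v, s) for v, s in zip(vals, ("A1B", "A2", "B1"))])
        comp2 = lsd_t([sample(v, s) for v, s in zip(vals, ("x", "y", "z"))])
        assert [comp1.letters[s] for s in ("A1B", "A2", "B1")] == [
            comp2.letters[s] for s in ("x", "y", "z")
        ]

    def test_letters_never_contradict_pairwise_decisions(self, rng):
        for _ in range(30):
            k = int(rng.integers(2, 5))
            groups = [
                sample(rng.normal(rng.normal(0, 1.5), 1.0, 8), f"s{i}")
                for i in range(k)
            ]
            comp = lsd_t(groups)
            if not comp.performed:
                continue
            for (a, b), p in comp.pairwise.items():
                shares = set(comp.letters[a]) & set(comp.letters[b])
                if p < 0.10:
                    assert not shares, (a, b, p, comp.letters)
                else:
                    assert shares, (a, b, p, comp.letters)

    def test_pooled_mse_pairwise_p_matches_hand_formula(self, rng):
        arrays = [rng.normal(m, 1.0, 6) for m in (0.0, 1.2, 2.4)]
        groups = [sample(a, s) for a, s in zip(arrays, ("A1B", "A2", "B1"))]
        comp = lsd_t(groups)
        if comp.performed:
            n_tot = sum(len(a) for a in arrays)
            df = n_tot - 3
            mse = sum((len(a) - 1) * a.var(ddof=1) for a in arrays) / df
            se = math.sqrt(mse * (1 / 6 + 1 / 6))
            t = (arrays[0].mean() - arrays[1].mean()) / se
            p_ref = 2 * sps.t.sf(abs(t), df)
            assert comp.pairwise[("A1B", "A2")] == pytest.approx(p_ref, rel=1e-9)


class TestFamilyPool:
    def test_pooled_sizes_match_design(self):
        genera = [
            sample(np.zeros(n) + i, group=g)
            for i, (g, n) in enumerate(
                [("Abies", 12), ("Picea", 12), ("Larix", 6), ("Pinus", 16)]
            )
        ]
        pooled = family_pool(genera)
        assert pooled.n == 46
        assert pooled.group_label == "family"

    def test_pooled_mean_is_weighted_mean_of_genus_means(self, rng):
        genera = [sample(rng.normal(i, 1, n)) for i, n in enumerate((5, 9, 3))]
        pooled = family_pool(genera)
        weighted = sum(g.values.sum() for g in genera) / sum(g.n for g in genera)
        assert pooled.values.mean() == pytest.approx(weighted)

    def test_single_genus_pools_to_itself(self):
        g = sample([1.0, 2.0])
        assert np.array_equal(family_pool([g]).values, g.values)

    def test_mixed_indices_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            family_pool([sample([1.0], index="I"), sample([2.0], index="O")])
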