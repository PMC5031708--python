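"""Group-level edge inference: RM-ANOVA reduction, effect sizes, resampling."""

import numpy as np
import pytest

from nirscausal import (
    DegenerateInputError,
    PreconditionError,
    RaceAgeAnova,
    behavioral_anova,
    bootstrap_effect_size,
    nore,
    partial_eta_sq,
    pearson_r,
    permutation_null,
    posthoc_ttests,
    rm_anova_2xcontinuous,
    significance_decision,
)
from nirscausal.groupstats import perm_pvalue

# Nine published interaction edges of the emulated study: (from, to, F,
# partial eta^2) with df (1, 122); used to pin the eta^2 arithmetic.
PUBLISHED_INTERACTIONS = [
    (2, 18, 7.584, 0.0585),
    (4, 21, 7.975, 0.0614),
    (10, 19, 9.836, 0.0746),
    (25, 3, 8.223, 0.0632),
    (25, 19, 10.572, 0.0798),
    (31, 3, 12.15, 0.0906),
    (39, 5, 10.231, 0.0774),
    (40, 43, 7.216, 0.0558),
    (36, 5, 8.553, 0.0655),
]


def glm_oracle(own, other, age):
    """Independent stacked-GLM oracle: participant fixed effects + condition
    + condition-by-centered-age, F from residual-sum-of-squares drops against
    the within-subject error; age effect from the regression of participant
    means on age."""
    n = len(age)
    agec = age - age.mean()
    y = np.concatenate([own, other])
    cond = np.concatenate([np.full(n, 0.5), np.full(n, -0.5)])
    subj = np.vstack([np.eye(n), np.eye(n)])
    ca = cond * np.concatenate([agec, agec])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full = rss(np.column_stack([subj, cond, ca]))
    s2 = rss_full / (n - 2)
    f_race = (rss(np.column_stack([subj, ca])) - rss_full) / s2
    f_int = (rss(np.column_stack([subj, cond])) - rss_full) / s2
    # between-subject part
    m = 0.5 * (own + other)
    X = np.column_stack([np.ones(n), agec])
    beta, *_ = np.linalg.lstsq(X, m, rcond=None)
    rss_m = float(((m - X @ beta) ** 2).sum())
    rss_m0 = float(((m - m.mean()) ** 2).sum())
    f_age = (rss_m0 - rss_m) / (rss_m / (n - 2))
    return f_age, f_race, f_int


class TestRmAnova:
    def test_matches_glm_oracle_on_random_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 30))
            age = rng.uniform(3, 13, n)
            own = rng.normal(0.2, 0.1, n) + 0.01 * age
            other = rng.normal(0.2, 0.1, n)
            res = rm_anova_2xcontinuous(own, other, age)
            f_age, f_race, f_int = glm_oracle(own, other, age)
            assert res["age"].F == pytest.approx(f_age, abs=1e-8)
            assert res["race"].F == pytest.approx(f_race, abs=1e-8)
            assert res["interaction"].F == pytest.approx(f_int, abs=1e-8)
            for eff in res.values():
                assert eff.df1 == 1 and eff.df2 == n - 2
                assert eff.eta2 == pytest.approx(
                    partial_eta_sq(eff.F, 1, n - 2), abs=1e-12
                )

    def test_identical_conditions_give_zero_race_and_interaction(self, rng):
        age = rng.uniform(3, 13, 20)
        y = rng.normal(0, 1, 20)
        res = rm_anova_2xcontinuous(y, y, age)
        assert res["race"].F == 0 and res["interaction"].F == 0

    def test_preconditions(self, rng):
        with pytest.raises(PreconditionError):
            rm_anova_2xcontinuous([1, 2, 3], [1, 2, 3], [4, 5, 6])
        with pytest.raises(DegenerateInputError):
            rm_anova_2xcontinuous(rng.normal(size=6), rng.normal(size=6),
                                  np.full(6, 7.0))


class TestPartialEtaSq:
    @pytest.mark.parametrize("f, expected", [(10.572, 0.0798), (12.15, 0.0906),
                                             (0.0, 0.0)])
    def test_reference_values_df_122(self, f, expected):
        assert partial_eta_sq(f, 1, 122) == pytest.approx(expected, abs=5e-4)

    def test_negative_f_rejected(self):
        with pytest.raises(PreconditionError):
            partial_eta_sq(-1.0, 1, 10)


class TestBootstrap:
    def _data(self, rng, n=40):
        age = rng.uniform(3, 13, n)
        own = 0.1 + 0.02 * age + rng.normal(0, 0.05, n)
        other = 0.1 + rng.normal(0, 0.05, n)
        return own, other, age

    def test_full_fraction_single_draw_equals_plain_eta2(self, rng):
        own, other, age = self._data(rng)
        boot = bootstrap_effect_size(own, other, age, b=1, frac=1.0, seed=0)
        res = rm_anova_2xcontinuous(own, other, age)
        for eff in ("age", "race", "interaction"):
            assert boot[eff] == pytest.approx(res[eff].eta2, abs=1e-12)

    def test_deterministic_under_seed(self, rng):
        own, other, age = self._data(rng)
        b1 = bootstrap_effect_size(own, other, age, b=50, seed=99)
        b2 = bootstrap_effect_size(own, other, age, b=50, seed=99)
        assert b1 == b2

    def test_monte_carlo_error_shrinks_with_b(self, rng):
        """SD of the averaged effect size across seeds scales ~ 1/sqrt(B)."""
        own, other, age = self._data(rng, n=60)
        sds = []
        for b in (100, 400):
            vals = [bootstrap_effect_size(own, other, age, b=b, seed=s)["interaction"]
                    for s in range(20)]
            sds.append(np.std(vals))
        assert sds[1] == pytest.approx(sds[0] / 2, rel=0.5)

    def test_subsample_too_small_rejected(self, rng):
        own, other, age = self._data(rng, n=6)
        with pytest.raises(PreconditionError):
            bootstrap_effect_size(own, other, age, b=10, frac=0.5)


class TestPermutation:
    def test_extreme_rank_gives_add_one_p(self, rng):
        null = rng.random(499)
        assert perm_pvalue(2.0, null) == pytest.approx(1 / 500)
        assert perm_pvalue(-1.0, null) == pytest.approx(1.0)

    def test_perm_p_monotone_in_observed(self, rng):
        null = rng.random(200)
        obs = np.sort(rng.random(50))
        ps = [perm_pvalue(o, null) for o in obs]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_significance_decision_rules(self, rng):
        null = rng.random(1000)
        assert significance_decision(null.max() + 1, null)
        assert not significance_decision(np.median(null), null)
        with pytest.raises(PreconditionError):
            significance_decision(0.5, np.empty(0))

    def test_null_flip_exchangeability_small_n(self):
        """With the condition difference symmetric per participant, the
        interaction statistic's fair-coin-flip null matches the exhaustive
        2^N flip distribution (N = 10, full enumeration as the oracle)."""
        rng = np.random.default_rng(5)
        n = 10
        age = np.sort(rng.uniform(3, 13, n))
        d = rng.normal(0, 1, n)
        own = d / 2
        other = -d / 2
        agec = age - age.mean()

        def inter_eta2(dd):
            r = np.corrcoef(dd, agec)[0, 1]
            return r * r

        exhaustive = []
        for mask in range(2 ** n):
            signs = np.array([1 if mask >> k & 1 else -1 for k in range(n)])
            exhaustive.append(inter_eta2(signs * d))
        exhaustive = np.array(exhaustive)
        nulls = permutation_null(own, other, age, b=4000, frac=1.0, seed=3,
                                 effects=("interaction",),
                                 null_stat="subsample")["interaction"]
        qs = [0.25, 0.5, 0.75, 0.9]
        assert np.allclose(np.quantile(nulls, qs),
                           np.quantile(exhaustive, qs), atol=0.03)

    def test_null_pvalue_approximately_uniform(self):
        """On no-effect data, the interaction permutation p is ~ U(0, 1]."""
        ps = []
        for s in range(120):
            rng = np.random.default_rng(s)
            n = 40
            age = rng.uniform(3, 13, n)
            own = rng.normal(0, 1, n)
            other = rng.normal(0, 1, n)
            boot = bootstrap_effect_size(own, other, age, b=60, seed=rng)
            null = permutation_null(own, other, age, b=60, seed=rng,
                                    effects=("interaction",),
                                    b_inner=40)["interaction"]
            ps.append(perm_pvalue(boot["interaction"], null))
        ps = np.array(ps)
        # mean 0.5 and tail mass near nominal
        assert abs(ps.mean() - 0.5) < 0.08
        assert abs((ps <= 0.25).mean() - 0.25) < 0.12


class TestNoreAndCorrelation:
    def test_nore_is_elementwise_difference(self):
        np.testing.assert_allclose(nore([0.5, 0.4], [0.2, 0.4]), [0.3, 0.0])

    def test_pearson_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_pearson_constructed_orthogonal(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -2.0, 1.0, 0.5])
        y = y - np.polyval(np.polyfit(x, y, 1), x)  # residualize on x
        r, _ = pearson_r(x, y)
        assert abs(r) < 1e-12

    def test_pearson_matches_direct_formula(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        r, _ = pearson_r(x, y)
        direct = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert r == pytest.approx(direct, abs=1e-12)


class TestBehavioralAnova:
    def test_pure_age_effect_cohort(self, rng):
        from nirscausal import generate_behavior

        ages = rng.uniform(3.25, 13.49, 124)
        df = generate_behavior(ages, seed=4, own_advantage=0.0)
        res = behavioral_anova(df)
        assert res["age"].F > 30
        assert res["race"].F < 5
        assert res["interaction"].F < 5

    def test_identical_conditions(self, rng):
        import pandas as pd

        age = rng.uniform(3, 13, 10)
        acc = rng.uniform(0.4, 0.9, 10)
        df = pd.DataFrame({"age": age, "acc_own": acc, "acc_other": acc})
        res = behavioral_anova(df)
        assert res["race"].F == 0 and res["interaction"].F == 0

    def test_cohort_constructed_at_published_age_f(self):
        """A deterministic cohort built to yield age F = 88.72 exactly must
        report partial eta^2 = 0.42 at two decimals."""
        import pandas as pd

        n = 124
        age = np.linspace(3.25, 13.49, n)
        agec = age - age.mean()
        f_target = 88.72
        r2 = f_target / (f_target + n - 2)
        u = agec / np.linalg.norm(agec)
        w = np.cos(np.arange(n) * 2.1)
        w -= w.mean()
        w -= (w @ u) * u  # orthogonal to both intercept and age
        v = w / np.linalg.norm(w)
        own = 0.65 + 0.05 * (np.sqrt(r2) * u + np.sqrt(1 - r2) * v)
        res = behavioral_anova(
            pd.DataFrame({"age": age, "acc_own": own, "acc_other": own})
        )
        assert res["age"].F == pytest.approx(f_target, rel=1e-6)
        assert round(res["age"].eta2, 2) == 0.42


class TestPosthoc:
    def test_equal_conditions_give_zero_paired_t(self, rng):
        age = rng.uniform(3, 13, 30)
        y = rng.normal(0, 1, 30)
        res = posthoc_ttests(y, y, age)
        assert res.paired_t_younger[0] == 0
        assert res.paired_t_older[0] == 0

    def test_matches_textbook_formulas(self, rng):
        age = np.array([4.0, 5.0, 6.0, 9.0, 10.0, 12.0])
        own = np.array([0.3, 0.5, 0.2, 0.7, 0.9, 0.6])
        other = np.array([0.2, 0.4, 0.4, 0.5, 0.6, 0.8])
        res = posthoc_ttests(own, other, age, split=7.0)
        d = (own - other)[:3]
        t_pair = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert res.paired_t_younger[0] == pytest.approx(t_pair, abs=1e-12)
        a, b = own[:3], own[3:]
        sp = np.sqrt(((a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4))
        t_two = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 3 + 1 / 3))
        assert res.twosample_t_own[0] == pytest.approx(t_two, abs=1e-12)

    def test_sign_conventions(self, rng):
        """Paired t is own minus other; two-sample t is younger minus older."""
        age = np.concatenate([np.full(10, 4.0), np.full(10, 12.0)]) + \
            rng.normal(0, 0.1, 20)
        own = np.where(age < 8, 1.0, 0.0) + rng.normal(0, 0.01, 20)
        other = np.zeros(20) + rng.normal(0, 0.01, 20)
        res = posthoc_ttests(own, other, age)
        assert res.paired_t_younger[0] > 0  # own > other in younger group
        assert res.twosample_t_own[0] > 0  # younger > older for own


class TestModelObject:
    def test_fit_resampling_deterministic_and_consistent(self, rng):
        n = 40
        age = rng.uniform(3, 13, n)
        own = 0.1 + 0.03 * age + rng.normal(0, 0.03, n)
        other = 0.1 + rng.normal(0, 0.03, n)
        m = RaceAgeAnova(own, other, age)
        r1 = m.fit(b_boot=100, b_perm=100, seed=11)
        r2 = m.fit(b_boot=100, b_perm=100, seed=11)
        assert r1.boot_mean_eta2 == r2.boot_mean_eta2
        assert r1.perm_p == r2.perm_p
        assert r1.significant["interaction"]  # strong planted interaction
        assert "interaction" in r1.summary()
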