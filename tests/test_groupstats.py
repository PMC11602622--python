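import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ortune.groupstats import (
    dunnett_sf,
    friedman_with_dunn,
    kruskal_wallis_dunn,
    normality_report,
    rm_anova_gg_dunnett,
)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept deliberately separate from the
# package's code paths)


def oracle_friedman_stat(mat):
    ranks = np.apply_along_axis(sps.rankdata, 1, mat)
    n, k = mat.shape
    a = (ranks**2).sum()
    c = n * k * (k + 1) ** 2 / 4
    if a <= c:
        return 0.0
    return (k - 1) * ((ranks.sum(0) - n * (k + 1) / 2) ** 2).sum() / (a - c)


def oracle_friedman_exact_p(mat):
    obs = oracle_friedman_stat(mat)
    n, k = mat.shape
    perms = list(itertools.permutations(range(k)))
    hits = total = 0
    for combo in itertools.product(perms, repeat=n):
        permuted = np.array([mat[i, list(p)] for i, p in enumerate(combo)])
        if oracle_friedman_stat(permuted) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def oracle_kw_exact_p(groups):
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    obs = sps.kruskal(*groups).statistic
    hits = total = 0
    for perm in itertools.permutations(range(len(pooled))):
        arranged = pooled[list(perm)]
        parts = []
        start = 0
        for s in sizes:
            parts.append(arranged[start : start + s])
            start += s
        if sps.kruskal(*parts).statistic >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestFriedman:
    def test_identical_columns_stat_zero_p_one(self):
        mat = np.tile(np.arange(5.0)[:, None], (1, 4))
        res = friedman_with_dunn(mat)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_asymptotic_matches_scipy(self, rng):
        mat = rng.normal(size=(10, 5))
        res = friedman_with_dunn(mat)
        ref = sps.friedmanchisquare(*(mat[:, j] for j in range(5)))
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_exact_p_equals_bruteforce_enumeration(self, rng):
        mat = rng.normal(size=(4, 3))
        res = friedman_with_dunn(mat, method="exact")
        assert res.p_value == pytest.approx(oracle_friedman_exact_p(mat), abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        mat = rng.uniform(1, 2, size=(8, 4))
        r1 = friedman_with_dunn(mat)
        r2 = friedman_with_dunn(np.exp(mat))
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_planted_column_flagged_by_dunn(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(0, 0.01, size=(10, 4))
        mat[:, 2] += 10.0
        res = friedman_with_dunn(
            pd.DataFrame(mat, columns=["solvent", "a", "hit", "b"]), control="solvent"
        )
        comp = res.comparisons.set_index("comparison")
        assert comp.loc["hit vs solvent", "p_adj"] < 0.05
        assert comp.loc["a vs solvent", "p_adj"] > 0.2

    def test_missing_cells_rejected(self):
        mat = np.ones((4, 3))
        mat[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            friedman_with_dunn(mat)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        g = [np.array([1.0, 1.0, 1.0]), np.array([1.0, 1.0])]
        res = kruskal_wallis_dunn(g)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_asymptotic_matches_scipy(self, rng):
        groups = [rng.normal(size=n) for n in (8, 12, 10)]
        res = kruskal_wallis_dunn(groups)
        ref = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_exact_p_equals_bruteforce_enumeration(self, rng):
        groups = [rng.normal(size=3), rng.normal(size=2), rng.normal(size=2)]
        res = kruskal_wallis_dunn(groups, method="exact")
        assert res.p_value == pytest.approx(oracle_kw_exact_p(groups), abs=1e-10)

    def test_large_shift_all_pairs_significant(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(size=12)
        groups = [base, base + 100.0, base + 200.0]
        res = kruskal_wallis_dunn(groups)
        assert (res.comparisons["p_adj"] < 0.05).all()

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="n ="):
            kruskal_wallis_dunn([np.array([1.0, 2.0]), np.array([3.0])])

    def test_adjusted_monotone_in_raw(self, rng):
        groups = [rng.normal(loc=m, size=6) for m in (0.0, 0.3, 1.0, 2.0)]
        comp = kruskal_wallis_dunn(groups).comparisons
        order = comp.sort_values("p_raw")
        assert order["p_adj"].is_monotonic_increasing
        assert (comp["p_adj"] >= comp["p_raw"] - 1e-15).all()


class TestRMAnova:
    def test_matches_pingouin_gg(self, rng):
        pingouin = pytest.importorskip("pingouin")
        data = rng.normal(size=(9, 4)) + rng.normal(size=(9, 1))
        res = rm_anova_gg_dunnett(data)
        long = pd.DataFrame(
            {
                "y": data.ravel(),
                "animal": np.repeat(np.arange(9), 4),
                "cond": np.tile(np.arange(4), 9),
            }
        )
        ref = pingouin.rm_anova(
            data=long, dv="y", within="cond", subject="animal", correction=True
        )
        assert res.statistic == pytest.approx(float(ref["F"][0]), rel=1e-8)
        assert res.epsilon == pytest.approx(float(ref["eps"][0]), rel=1e-8)
        assert res.p_value == pytest.approx(float(ref["p_GG_corr"][0]), rel=1e-6)

    def test_small_table_hand_computed(self):
        # 3 animals x 3 conditions; classical RM sums of squares by hand
        data = np.array([[1.0, 2.0, 4.0], [2.0, 3.0, 4.0], [3.0, 5.0, 6.0]])
        col = data.mean(0)
        row = data.mean(1)
        grand = data.mean()
        ss_cond = 3 * ((col - grand) ** 2).sum()
        ss_err = ((data - col[None] - row[:, None] + grand) ** 2).sum()
        f_expected = (ss_cond / 2) / (ss_err / 4)
        res = rm_anova_gg_dunnett(data)
        assert res.statistic == pytest.approx(f_expected)

    def test_animal_offsets_only_gives_f_zero(self):
        data = np.tile(np.array([[1.0], [5.0], [9.0], [2.0]]), (1, 3))
        data = data + 0.0  # identical conditions, animal offsets only
        with pytest.raises(ValueError, match="zero within-animal"):
            rm_anova_gg_dunnett(data)

    def test_near_identical_conditions_high_p(self, rng):
        offsets = rng.normal(size=(10, 1)) * 5
        data = offsets + rng.normal(scale=1.0, size=(10, 3))
        res = rm_anova_gg_dunnett(data)
        assert res.p_value > 0.01  # no condition effect planted

    def test_epsilon_near_one_for_compound_symmetry(self):
        rng = np.random.default_rng(12)
        eps_values = []
        for i in range(20):
            data = rng.normal(size=(200, 4)) + rng.normal(size=(200, 1))
            eps_values.append(rm_anova_gg_dunnett(data).epsilon)
        assert np.mean(eps_values) > 0.95

    def test_dunnett_comparisons_present_and_bounded(self, rng):
        data = rng.normal(size=(12, 4))
        data[:, 1] += 3.0
        res = rm_anova_gg_dunnett(pd.DataFrame(data, columns=["solvent", "hit", "a", "b"]),
                                  control="solvent")
        comp = res.comparisons.set_index("comparison")
        assert comp.loc["hit vs solvent", "p_adj"] < 0.01
        assert (comp["p_adj"] <= 1.0).all() and (comp["p_adj"] >= comp["p_raw"] - 1e-12).all()


class TestDunnettProbability:
    @pytest.mark.parametrize(
        "t, m, df, expected",
        [
            # reference values from the equicorrelated multivariate-t
            # distribution (mvtnorm, abseps 1e-7)
            (2.5, 3, 12, 0.069035),
            (2.0, 2, 10, 0.127190),
            (3.2, 5, 30, 0.013836),
            (1.0, 3, 8, 0.643787),
            (2.79, 21, 45, 0.092428),
        ],
    )
    def test_matches_multivariate_t_reference(self, t, m, df, expected):
        assert dunnett_sf(t, m, df) == pytest.approx(expected, abs=1e-4)

    def test_reduces_to_t_for_single_comparison(self):
        p = dunnett_sf(2.2, m=1, df=15)
        assert p == pytest.approx(2 * sps.t.sf(2.2, 15), abs=1e-5)

    def test_monotone_in_t(self):
        ps = [dunnett_sf(t, 3, 20) for t in (0.5, 1.5, 2.5, 3.5)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestTypeIError:
    """Null calibration at designs matching the study layouts (smoke-sized
    here; the full 2000-replicate calibration runs in the acceptance suite)."""

    def test_friedman_near_nominal(self):
        rej = sum(
            friedman_with_dunn(np.random.default_rng(i).normal(size=(12, 22))).p_value < 0.05
            for i in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.08

    def test_kruskal_near_nominal(self):
        rej = sum(
            kruskal_wallis_dunn(
                [np.random.default_rng(1000 * i + j).normal(size=12) for j in range(4)]
            ).p_value
            < 0.05
            for i in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.08


def test_normality_report_flags_only(rng):
    report = normality_report({"gauss": rng.normal(size=50), "expo": rng.exponential(size=50)})
    assert set(report["sample"]) == {"gauss", "expo"}
    assert report.loc[report["sample"] == "expo", "p"].iloc[0] < 0.05
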