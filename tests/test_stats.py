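"""Statistics: ANOVA partitions vs independent oracles, Duncan letters vs a
brute-force studentized-range reimplementation, fold-change conventions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from homeoexpr.stats import (
    DegenerateDataError,
    UnbalancedDesignError,
    anova_duncan,
    duncan_critical_range,
    duncan_mrt,
    fold_change_log2,
    fold_change_rpkpm,
    one_way_anova,
    two_way_anova,
)


def _design(rng, a=3, b=2, n=4, effect_b=0.0):
    rows = []
    for i in range(a):
        for j in range(b):
            for _ in range(n):
                rows.append({"genotype": f"g{i}", "treatment": f"t{j}",
                             "value": rng.normal(j * effect_b, 1.0)})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_matches_statsmodels(self):
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(1)
        df = _design(rng, a=3, b=3, n=3, effect_b=0.5)
        res = two_way_anova(df)
        model = ols("value ~ C(genotype) * C(treatment)", data=df).fit()
        ref = anova_lm(model, typ=2)
        assert res.rows[0].F == pytest.approx(ref["F"].iloc[0], rel=1e-10)
        assert res.rows[1].F == pytest.approx(ref["F"].iloc[1], rel=1e-10)
        assert res.rows[2].F == pytest.approx(ref["F"].iloc[2], rel=1e-10)
        assert res.rows[2].p == pytest.approx(ref["PR(>F)"].iloc[2], rel=1e-10)

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(2)
        df = _design(rng)
        res1 = two_way_anova(df)
        df2 = df.assign(value=df["value"] + 1234.5)
        res2 = two_way_anova(df2)
        for r1, r2 in zip(res1.rows[:3], res2.rows[:3]):
            assert r1.F == pytest.approx(r2.F, rel=1e-9)

    def test_strong_effect_detected(self):
        """Effect of +10 sigma on one factor at n=10 is overwhelming."""
        rng = np.random.default_rng(3)
        df = _design(rng, a=2, b=2, n=10, effect_b=10.0)
        res = two_way_anova(df)
        assert res.p_value("treatment") < 1e-6

    def test_unbalanced_rejected(self):
        rng = np.random.default_rng(4)
        df = _design(rng).iloc[:-1]
        with pytest.raises(UnbalancedDesignError):
            two_way_anova(df)

    def test_degenerate_rejected(self):
        df = _design(np.random.default_rng(5)).assign(value=1.0)
        with pytest.raises(DegenerateDataError):
            two_way_anova(df)


class TestOneWayAnova:
    def test_matches_scipy_and_bruteforce(self):
        rng = np.random.default_rng(6)
        groups = {k: rng.normal(0, 1, 6) for k in "abc"}
        res = one_way_anova(groups)
        ref = sps.f_oneway(*groups.values())
        assert res.rows[0].F == pytest.approx(ref.statistic, rel=1e-10)
        assert res.rows[0].p == pytest.approx(ref.pvalue, rel=1e-10)
        # brute-force sums of squares
        allv = np.concatenate(list(groups.values()))
        ss_tot = ((allv - allv.mean()) ** 2).sum()
        ss_w = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        F = ((ss_tot - ss_w) / 2) / (ss_w / (len(allv) - 3))
        assert res.rows[0].F == pytest.approx(F, rel=1e-10)

    def test_two_groups_f_is_t_squared(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        res = one_way_anova({"x": x, "y": y})
        t = sps.ttest_ind(x, y)
        assert res.rows[0].F == pytest.approx(t.statistic ** 2, rel=1e-10)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateDataError):
            one_way_anova({"a": [1.0, 1.0], "b": [1.0, 1.0]})


# ---------------------------------------------------------------------------
# independent Duncan oracle: explicit pairwise sweep with containment
# ---------------------------------------------------------------------------

def oracle_duncan_letters(means: dict[str, float], n: int, mse: float,
                          df: int, alpha: float = 0.05) -> dict[str, frozenset]:
    """Brute-force Duncan letter sets, built from an explicit significance
    matrix and greedy letter covering (independent of the implementation's
    interval sweep).  Returns per-group frozensets of letter indices."""
    labels = sorted(means, key=lambda k: -means[k])
    vals = [means[k] for k in labels]
    k = len(labels)
    sig = {}
    for i in range(k):
        for j in range(i + 1, k):
            p = j - i + 1
            level = (1 - alpha) ** (p - 1)
            q = sps.studentized_range.ppf(level, p, df)
            sig[(i, j)] = (vals[i] - vals[j]) > q * np.sqrt(mse / n)
    # containment protection: a range inside a non-significant range is NS
    changed = True
    while changed:
        changed = False
        for (i, j), s in list(sig.items()):
            if not s:
                continue
            for (a, b), outer in sig.items():
                if not outer and a <= i and j <= b and (a, b) != (i, j):
                    sig[(i, j)] = False
                    changed = True
    # letters: maximal runs of mutually non-significant ordered means
    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and not any(
                sig.get((x, y), False) for x in range(i, j + 2)
                for y in range(x + 1, j + 2)):
            j += 1
        runs.append((i, j))
    maximal = [r for r in runs
               if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    maximal = sorted(set(maximal))
    out = {lab: set() for lab in labels}
    for li, (i, j) in enumerate(maximal):
        for idx in range(i, j + 1):
            out[labels[idx]].add(li)
    return {lab: frozenset(v) for lab, v in out.items()}


def _letters_to_sets(letters: dict[str, str]) -> dict[str, frozenset]:
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return {k: frozenset(alphabet.index(c) for c in v) for k, v in letters.items()}


class TestDuncan:
    def test_all_equal_means_share_letter(self):
        mrt = duncan_mrt({"a": 5.0, "b": 5.0, "c": 5.0}, 4, 1.0, 9)
        assert set(mrt.letters.values()) == {"a"}

    def test_two_distant_groups_get_distinct_letters(self):
        mrt = duncan_mrt({"hi": 100.0, "lo": 0.0}, 4, 1.0, 6)
        assert mrt.letters["hi"] == "a"
        assert mrt.letters["lo"] == "b"

    def test_critical_ranges_nondecreasing_in_span(self):
        for df in (6, 12, 30):
            ranges = [duncan_critical_range(p, df, 2.0, 5) for p in range(2, 7)]
            assert all(b >= a for a, b in zip(ranges, ranges[1:]))

    def test_never_separates_below_r2(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            k = int(rng.integers(3, 7))
            means = {f"g{i}": float(rng.normal(0, 2)) for i in range(k)}
            mrt = duncan_mrt(means, 5, 1.0, 20)
            r2 = mrt.critical_ranges[2]
            for a in means:
                for b in means:
                    if a < b and abs(means[a] - means[b]) <= r2:
                        assert set(mrt.letters[a]) & set(mrt.letters[b]), (a, b)

    @pytest.mark.parametrize("case", range(50))
    def test_letters_match_bruteforce_oracle(self, case):
        """Letter partitions agree with the independent brute-force
        studentized-range implementation on random 3-6 group problems."""
        rng = np.random.default_rng(100 + case)
        k = int(rng.integers(3, 7))
        n = int(rng.integers(3, 8))
        means = {f"g{i}": float(rng.normal(0, 1.5)) for i in range(k)}
        mse = float(rng.uniform(0.2, 2.0))
        df = k * (n - 1)
        mrt = duncan_mrt(means, n, mse, df)
        assert _letters_to_sets(mrt.letters) == oracle_duncan_letters(means, n, mse, df)

    def test_protected_by_omnibus(self):
        """A non-significant one-way ANOVA yields a single shared letter."""
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"group": np.repeat(list("abc"), 5),
                           "value": rng.normal(0, 1, 15)})
        anova, mrt = anova_duncan(df, factor="group")
        if anova.rows[0].p >= 0.05:
            assert set(mrt.letters.values()) == {"a"}


class TestFoldChanges:
    @pytest.mark.parametrize("t,c,pc,expected",
                             [(20.0, 10.0, 0.0, 2.0),
                              (7.0, 7.0, 0.0, 1.0),
                              (5.0, 0.0, 0.1, 51.0)])
    def test_rpkpm_ratio(self, t, c, pc, expected):
        assert fold_change_rpkpm(t, c, pc) == pytest.approx(expected)

    def test_rpkpm_negative_rejected(self):
        with pytest.raises(ValueError):
            fold_change_rpkpm(-1.0, 1.0)

    @pytest.mark.parametrize("t,c,bg,expected",
                             [(8.4, 7.4, 3.4, 2.0),    # 1 log2 unit = two-fold
                              (6.0, 6.0, 3.4, 1.0),
                              (4.4, 2.0, 3.4, 2.0)])   # control floored at background
    def test_log2_with_background_floor(self, t, c, bg, expected):
        assert fold_change_log2(t, c, bg) == pytest.approx(expected)
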