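"""Association statistics: Spearman, BH, Welch, exact r x c, median split."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from nddprs.ars import build_ars_table
from nddprs.errors import EnumerationCapError, ValidationError
from nddprs.stats import (bh_adjust, demographics_table, exact_rxc,
                          median_split, run_association_battery, spearman,
                          welch_t, welch_t_raw)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(1, 9, dtype=float)
        res = spearman(x, 2 * x + 1)
        assert res.rho == pytest.approx(1.0)

    def test_antitone_is_minus_one(self):
        x = np.arange(1, 9, dtype=float)
        res = spearman(x, x[::-1])
        assert res.rho == pytest.approx(-1.0)
        assert res.p < 0.01

    def test_exact_p_matches_full_enumeration_with_tie(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0])  # one tie
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 6.0])  # ties too
        res = spearman(x, y, method="exact")
        # oracle: enumerate all 7! pairings directly
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = total = 0
        for perm in itertools.permutations(ry):
            r = abs(np.corrcoef(rx, np.array(perm))[0, 1])
            hits += r >= obs - 1e-12
            total += 1
        assert res.p == pytest.approx(hits / total, abs=1e-12)

    def test_tie_handling_matches_scipy_rho(self, rng):
        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(0, 5, size=30).astype(float)
        res = spearman(x, y, method="t")
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_flagged(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert res.flagged and np.isnan(res.rho)

    @given(st.permutations(list(range(8))))
    def test_invariant_under_monotone_transform(self, perm):
        x = np.array(perm, dtype=float)
        y = np.arange(8, dtype=float)
        a = spearman(x, y, method="t")
        b = spearman(np.exp(x), y, method="t")  # strictly increasing transform
        assert a.rho == pytest.approx(b.rho, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)


class TestBH:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_worked_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_equal_p_fixed_point(self):
        np.testing.assert_allclose(bh_adjust([0.05] * 6), [0.05] * 6)

    def test_matches_minimum_over_tails_oracle(self, rng):
        for _ in range(300):
            m = int(rng.integers(1, 21))
            p = rng.random(m)
            got = bh_adjust(p)
            # oracle: q_i = min over j with p_j >= p_i of p_j * m / rank_j
            order = np.argsort(p)
            want = np.empty(m)
            for i in range(m):
                js = [j for j in range(m) if p[order[j]] >= p[order[i]] - 1e-15]
                want[order[i]] = min(min(p[order[j]] * m / (j + 1) for j in js), 1.0)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.2])


class TestWelch:
    def test_identical_groups(self):
        res = welch_t(5, 3.0, 1.0, 8, 3.0, 1.0)
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_summary_equals_raw(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 2, 17)
        a = welch_t_raw(x, y)
        b = welch_t(12, x.mean(), x.std(ddof=1), 17, y.mean(), y.std(ddof=1))
        assert a.t == pytest.approx(b.t) and a.p == pytest.approx(b.p)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert a.t == pytest.approx(ref.statistic)
        assert a.p == pytest.approx(ref.pvalue)

    def test_degenerate_zero_variance(self):
        res = welch_t(3, 1.0, 0.0, 3, 1.0, 0.0)
        assert res.p == 1.0 and res.flagged


class TestExactRxC:
    def test_two_by_two_matches_scipy_fisher(self, rng):
        for _ in range(60):
            t = rng.integers(0, 9, size=(2, 2))
            if t.sum() == 0:
                continue
            got = exact_rxc(t)
            want = sps.fisher_exact(t).pvalue
            assert got == pytest.approx(want, rel=1e-9), t

    def test_diagonal_table(self):
        from math import comb
        assert exact_rxc(np.array([[5, 0], [0, 5]])) == pytest.approx(2 / comb(10, 5))

    def test_zero_margin_degenerate(self):
        assert exact_rxc(np.array([[3, 4], [0, 0]])) == 1.0

    def test_three_by_three_against_direct_enumeration(self, rng):
        # oracle: independent enumeration via bounded cell products
        from math import lgamma

        def oracle(t):
            rs, cs = t.sum(1), t.sum(0)
            n = t.sum()
            const = (sum(lgamma(v + 1) for v in rs) + sum(lgamma(v + 1) for v in cs)
                     - lgamma(n + 1))

            def logp(cells):
                return const - sum(lgamma(v + 1) for v in cells)

            obs = logp(t.ravel())
            total = 0.0
            ranges = [range(min(rs[i], cs[j]) + 1) for i in range(len(rs) - 1)
                      for j in range(len(cs) - 1)]
            import itertools as it
            R, C = len(rs), len(cs)
            for inner in it.product(*ranges):
                tab = np.zeros((R, C), dtype=int)
                tab[:R - 1, :C - 1] = np.reshape(inner, (R - 1, C - 1))
                tab[:R - 1, C - 1] = rs[:R - 1] - tab[:R - 1, :C - 1].sum(1)
                tab[R - 1, :] = cs - tab[:R - 1, :].sum(0)
                if (tab < 0).any():
                    continue
                lp = logp(tab.ravel())
                if lp <= obs + 1e-12:
                    total += np.exp(lp)
            return min(total, 1.0)

        for _ in range(15):
            t = rng.integers(0, 5, size=(3, 3))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert exact_rxc(t) == pytest.approx(oracle(t), rel=1e-9), t

    def test_enumeration_cap(self):
        big = np.full((4, 4), 40)
        with pytest.raises(EnumerationCapError):
            exact_rxc(big, cap=1000)

    def test_monte_carlo_mode_close_to_exact(self):
        t = np.array([[8, 2], [3, 7]])
        exact = exact_rxc(t)
        mc = exact_rxc(t, method="mc", n_mc=20_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.02)


class TestMedianSplit:
    def test_nineteen_distinct_gives_9_10(self, rng):
        s = pd.Series(rng.normal(size=19))
        labels = median_split(s)
        assert labels.value_counts().to_dict() == {"low": 10, "high": 9}

    def test_even_split(self):
        labels = median_split(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert set(labels[labels == "high"].index) == {"c", "d"}

    def test_ties_at_median_go_low(self):
        labels = median_split(pd.Series([1.0, 2.0, 2.0, 2.0, 5.0]))
        assert (labels == "high").sum() == 1

    def test_all_identical_warns(self):
        labels = median_split(pd.Series([3.0, 3.0, 3.0]))
        assert (labels == "low").all() and labels.attrs["all_identical"]


class TestBattery:
    @staticmethod
    def _tables(n=19, seed=0):
        r = np.random.default_rng(seed)
        ids = [f"p{i}" for i in range(n)]
        clinical = pd.DataFrame({
            "id": ids, "sex": r.choice(["M", "F"], n),
            "age": r.integers(40, 90, n), "doi": r.integers(10, 60, n),
            "cpeq_3mo": r.lognormal(6, 0.5, n),
            "dibs_pos_max": r.integers(1, 15, n), "dibs_pos_3mo": r.integers(0, 10, n),
            "dibs_neg_max": r.integers(1, 8, n), "dibs_neg_3mo": r.integers(0, 6, n),
            "dibs_gen_max": r.integers(1, 8, n), "dibs_gen_3mo": r.integers(0, 6, n),
        })
        ars_tab = build_ars_table(clinical)
        prs = {"ADHD": pd.Series(r.normal(size=n), index=ids),
               "ASD": pd.Series(r.normal(size=n), index=ids)}
        return prs, ars_tab, clinical

    def test_twelve_cells_and_per_prs_families(self):
        prs, ars_tab, clinical = self._tables()
        out = run_association_battery(prs, ars_tab, clinical, family="per-prs")
        assert len(out) == 12
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        # per-family BH: adjusting within each PRS's six tests
        for name in prs:
            sub = out[out["prs"] == name]
            np.testing.assert_allclose(sub["p_adj"], bh_adjust(sub["p"]))

    def test_global_family(self):
        prs, ars_tab, clinical = self._tables()
        out = run_association_battery(prs, ars_tab, clinical, family="global")
        np.testing.assert_allclose(out["p_adj"], bh_adjust(out["p"]))

    def test_mismatched_ids_raise(self):
        prs, ars_tab, clinical = self._tables()
        bad = clinical.copy()
        bad["id"] = bad["id"].to_numpy()[::-1]  # permutation keeps the set equal
        shuffled = run_association_battery(prs, ars_tab, bad)  # set-equal is fine
        assert len(shuffled) == 12
        bad2 = clinical.copy()
        bad2.loc[0, "id"] = "intruder"
        with pytest.raises(ValidationError):
            run_association_battery(prs, ars_tab, bad2)

    def test_demographics_table_shape(self):
        prs, ars_tab, clinical = self._tables()
        groups = median_split(prs["ADHD"])
        demo = demographics_table(clinical, groups)
        assert {"sex", "age", "cpeq_3mo"} <= set(demo["variable"])
        sex_p = demo.loc[demo["variable"] == "sex", "p"].iloc[0]
        assert 0 <= sex_p <= 1
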