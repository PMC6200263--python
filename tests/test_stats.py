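"""Exact Wilcoxon, repeated-measures ANOVA and jackknife resampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from siprobe import jackknife, rm_anova, wilcoxon_exact
from siprobe.errors import InsufficientDataError


def brute_force_wilcoxon(d):
    """Enumerate all 2^n sign assignments directly (independent oracle)."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    n = d.size
    vs = np.array(
        [np.sum(ranks[np.array(signs, bool)]) for signs in itertools.product([0, 1], repeat=n)]
    )
    p = 2 * min((vs <= v_obs).mean(), (vs >= v_obs).mean())
    return v_obs, min(1.0, p)


class TestWilcoxonExact:
    def test_nine_all_positive(self):
        res = wilcoxon_exact(np.arange(1.0, 10.0))
        assert res.V == 45.0
        assert res.p_two_sided == pytest.approx(0.003906, abs=5e-7)
        assert res.method == "exact"

    def test_nine_with_v_six(self):
        # positives carry ranks 1+2+3 -> V = 6
        d = np.array([0.1, 0.2, 0.3, -4, -5, -6, -7, -8, -9.0])
        res = wilcoxon_exact(d)
        assert res.V == 6.0
        assert res.p_two_sided == pytest.approx(0.05469, abs=5e-6)

    def test_two_positive_pairs(self):
        res = wilcoxon_exact(np.array([1.0, 2.0]))
        assert res.V == 3.0
        assert res.p_two_sided == pytest.approx(0.5)

    def test_paired_input_and_zero_dropping(self):
        x = np.array([3.0, 5.0, 7.0, 2.0])
        y = np.array([1.0, 5.0, 3.0, 1.0])  # one zero difference dropped
        res = wilcoxon_exact(x, y)
        assert res.n_effective == 3
        assert res.V == 6.0

    def test_all_zero_differences_undefined(self):
        with pytest.raises(InsufficientDataError):
            wilcoxon_exact(np.zeros(5))

    def test_matches_brute_force_enumeration(self, rng):
        """200 random datasets at n <= 12, with and without ties."""
        for trial in range(200):
            n = int(rng.integers(2, 13))
            if trial % 3:
                d = rng.normal(size=n)
            else:  # integer-valued -> plenty of |d| ties
                d = rng.integers(-4, 5, size=n).astype(float)
            if np.all(d == 0):
                continue
            res = wilcoxon_exact(d)
            v_ref, p_ref = brute_force_wilcoxon(d)
            assert res.V == pytest.approx(v_ref)
            assert res.p_two_sided == pytest.approx(p_ref, abs=1e-12)

    def test_matches_scipy_when_no_ties(self, rng):
        for _ in range(30):
            d = rng.normal(size=int(rng.integers(5, 20)))
            ours = wilcoxon_exact(d)
            ref = sps.wilcoxon(d, method="exact", alternative="two-sided")
            v_pos = sps.rankdata(np.abs(d))[d > 0].sum()
            assert ours.V == pytest.approx(v_pos)
            assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-10)

    def test_null_symmetry_and_total_probability(self):
        """p(V) = p(n(n+1)/2 - V) and the enumeration sums to 1."""
        from siprobe.stats import _exact_signed_rank_p

        n = 8
        ranks = np.arange(1.0, n + 1)
        total = n * (n + 1) // 2
        for v in range(total + 1):
            assert _exact_signed_rank_p(ranks, v) == pytest.approx(
                _exact_signed_rank_p(ranks, total - v)
            )

    def test_large_n_falls_back_to_normal(self, rng):
        d = rng.normal(loc=0.3, size=40)
        with pytest.warns(UserWarning, match="normal"):
            res = wilcoxon_exact(d)
        assert res.method == "normal-approx"
        ref = sps.wilcoxon(d, method="approx", alternative="two-sided", correction=False)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    def test_null_rejection_rate_calibrated(self):
        """Exact test at alpha=0.05 rejects at the achievable exact level.

        With n=9 the achievable level nearest below 0.05 is 2*P(V>=42)=0.039;
        over 1,000 null replicates the rejection rate must sit inside the
        binomial 99% interval around it.
        """
        rng = np.random.default_rng(77)
        n, reps, alpha = 9, 1000, 0.05
        # achievable exact size at this n
        from siprobe.stats import _exact_signed_rank_p

        ranks = np.arange(1.0, n + 1)
        achievable = max(
            p
            for v in range(n * (n + 1) // 2 + 1)
            if (p := _exact_signed_rank_p(ranks, v)) <= alpha
        )
        rejections = sum(
            wilcoxon_exact(rng.normal(size=n)).p_two_sided <= alpha for _ in range(reps)
        )
        se = np.sqrt(achievable * (1 - achievable) / reps)
        assert abs(rejections / reps - achievable) < 2.58 * se + 1e-9


def inclusion_exclusion_anova(X, ks):
    """Independent RM-ANOVA oracle via classical uncorrected sums of squares.

    ``X`` is (n_subjects, prod(ks)) with columns in factor-product order.
    Returns {effect_tuple: (ss_effect, ss_error)} using the textbook
    marginal-totals construction with the subject treated as one more factor
    and each effect tested against its interaction with subject.
    """
    n = X.shape[0]
    factors = list(range(len(ks)))
    full = X.reshape([n] + list(ks))
    N = full.size

    def U(subset):  # subset of axes to KEEP (0 = subject, i+1 = factor i)
        axes = tuple(ax for ax in range(full.ndim) if ax not in subset)
        totals = full.sum(axis=axes) if axes else full
        per_cell = N / np.prod([full.shape[ax] for ax in subset]) if subset else N
        return float((np.asarray(totals) ** 2).sum() / per_cell)

    def ss(effect_axes):
        total = 0.0
        for r in range(len(effect_axes) + 1):
            for sub in itertools.combinations(effect_axes, r):
                total += (-1) ** (len(effect_axes) - len(sub)) * U(set(sub))
        return total

    out = {}
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            axes = tuple(i + 1 for i in combo)
            out[combo] = (ss(axes), ss((0,) + axes))
    return out


def random_long_table(rng, ks, n_subjects=9, names=None):
    names = names or [f"f{i}" for i in range(len(ks))]
    rows = []
    for s in range(n_subjects):
        for combo in itertools.product(*[range(k) for k in ks]):
            rows.append(
                {
                    "subject": f"S{s}",
                    **{names[i]: f"{names[i]}{v}" for i, v in enumerate(combo)},
                    "y": rng.normal(),
                }
            )
    return pd.DataFrame(rows), names


class TestRmAnova:
    @pytest.mark.parametrize("ks", [(3,), (2, 3), (2, 3, 3), (2, 3, 3, 3)])
    def test_matches_inclusion_exclusion_oracle(self, rng, ks):
        for _ in range(5):
            df, names = random_long_table(rng, ks)
            table = rm_anova(df, "y", names, "subject").set_index("effect")
            wide = df.pivot_table(index="subject", columns=names, values="y")
            oracle = inclusion_exclusion_anova(wide.to_numpy(), ks)
            for combo, (ss_e, ss_r) in oracle.items():
                effect = ":".join(names[i] for i in combo)
                row = table.loc[effect]
                assert row["ss"] == pytest.approx(ss_e, abs=1e-8)
                assert row["ss_error"] == pytest.approx(ss_r, abs=1e-8)
                df1 = np.prod([ks[i] - 1 for i in combo])
                f_ref = (ss_e / df1) / (ss_r / (df1 * 8))
                assert row["F"] == pytest.approx(f_ref, abs=1e-8)

    def test_matches_statsmodels_two_way(self, rng):
        from statsmodels.stats.anova import AnovaRM

        df, names = random_long_table(rng, (2, 3))
        ours = rm_anova(df, "y", names, "subject").set_index("effect")
        ref = AnovaRM(df, "y", "subject", within=names).fit().anova_table
        for effect, ref_row in ref.iterrows():
            row = ours.loc[effect.replace("*", ":")]
            assert row["F"] == pytest.approx(ref_row["F Value"], rel=1e-9)
            assert row["p"] == pytest.approx(ref_row["Pr > F"], rel=1e-9)

    def test_gg_epsilon_matches_pingouin(self, rng):
        import pingouin as pg

        df, names = random_long_table(rng, (4,))
        ours = rm_anova(df, "y", names, "subject")
        wide = df.pivot_table(index="subject", columns=names[0], values="y")
        eps_ref = pg.epsilon(wide, correction="gg")
        assert ours["eps_gg"].iloc[0] == pytest.approx(float(eps_ref), rel=1e-9)

    def test_identical_cells_give_zero_f(self):
        rows = [
            {"subject": f"S{s}", "A": a, "y": 3.0}
            for s in range(5)
            for a in ("a1", "a2", "a3")
        ]
        table = rm_anova(pd.DataFrame(rows), "y", ["A"], "subject")
        assert table["F"].iloc[0] == 0.0
        assert table["p"].iloc[0] == 1.0

    def test_two_level_factor_epsilon_is_one(self, rng):
        df, names = random_long_table(rng, (2,))
        table = rm_anova(df, "y", names, "subject")
        assert table["eps_gg"].iloc[0] == 1.0

    def test_two_level_f_equals_paired_t_squared(self, rng):
        df, names = random_long_table(rng, (2, 3))
        table = rm_anova(df, "y", names, "subject").set_index("effect")
        wide = df.pivot_table(index="subject", columns=names, values="y")
        collapsed = wide.T.groupby(level=0).mean().T  # average over the 3-level factor
        t_stat = sps.ttest_rel(collapsed.iloc[:, 0], collapsed.iloc[:, 1]).statistic
        assert table.loc[names[0], "F"] == pytest.approx(t_stat**2, rel=1e-9)

    def test_partial_eta_squared_range(self, rng):
        df, names = random_long_table(rng, (2, 3))
        table = rm_anova(df, "y", names, "subject")
        assert ((table["pes"] >= 0) & (table["pes"] <= 1)).all()

    def test_missing_cell_imputed_with_warning(self, rng):
        df, names = random_long_table(rng, (3,))
        df = df.drop(df[(df["subject"] == "S0") & (df[names[0]] == "f00")].index)
        with pytest.warns(UserWarning, match="imputed"):
            table = rm_anova(df, "y", names, "subject")
        assert np.isfinite(table["F"]).all()

    def test_too_few_subjects(self, rng):
        df, names = random_long_table(rng, (3,), n_subjects=2)
        with pytest.raises(InsufficientDataError):
            rm_anova(df, "y", names, "subject")


class TestJackknife:
    def _table(self, n=9):
        return pd.DataFrame(
            {"subject": [f"S{i}" for i in range(n)], "value": np.arange(n, dtype=float)}
        )

    def test_nine_subjects_nine_resamples_of_eight(self):
        report = jackknife(
            self._table(), "subject", lambda df: sorted(df["subject"].unique())
        )
        assert report.n_resamples == 9
        for run in report.runs:
            assert len(run.result) == 8
            assert run.left_out not in run.result

    def test_constant_analysis_identical_results(self):
        report = jackknife(self._table(), "subject", lambda df: 42.0)
        assert {run.result for run in report.runs} == {42.0}

    def test_failures_recorded_not_fatal(self):
        def failing(df):
            if "S3" not in set(df["subject"]):
                raise RuntimeError("boom")
            return 1.0

        report = jackknife(self._table(), "subject", failing,
                           significance=lambda r: r > 0)
        errors = [run for run in report.runs if run.error]
        assert len(errors) == 1 and errors[0].left_out == "S3"
        assert not report.consistent  # a failed resample cannot confirm the effect

    def test_strong_simulated_effect_significant_in_all_resamples(self, rng):
        """Effect far above noise survives every leave-one-out resample."""
        rows = []
        for s in range(9):
            base = rng.normal(scale=0.05)
            for cond, mean in (("low", 0.0), ("medium", 0.5), ("high", 1.0)):
                rows.append({"subject": f"S{s}", "condition": cond,
                             "y": mean + base + rng.normal(scale=0.05)})
        df = pd.DataFrame(rows)
        report = jackknife(
            df,
            "subject",
            lambda d: rm_anova(d, "y", ["condition"], "subject"),
            significance=lambda t: t["p_gg"].iloc[0] < 0.05,
        )
        assert report.consistent
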