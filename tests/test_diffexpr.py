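import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from oticrank.diffexpr import (
    GroupSummary,
    VariancePrior,
    bh_adjust,
    fit_variance_prior,
    fold_change,
    group_summary,
    max_reference_fold_change,
    moderated_t_test,
    reference_contrast,
)
from oticrank.matrix import ExpressionMatrix, SampleSheet, LOG2


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent step-up oracle: q_(i) = min_{j>=i} p_(j)·m/j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


def summary_from_values(values: dict[str, np.ndarray], n: dict[str, int]) -> GroupSummary:
    """Build a summary directly from per-group replicate arrays (probes × reps)."""
    means = pd.DataFrame({g: v.mean(axis=1) for g, v in values.items()})
    sds = pd.DataFrame({g: v.std(axis=1, ddof=1) for g, v in values.items()})
    return GroupSummary(means, sds, pd.Series(n))


class TestGroupSummary:
    def test_closed_form_means_and_sds(self, small_log2_matrix, two_group_sheet):
        s = group_summary(small_log2_matrix, two_group_sheet)
        assert s.means.loc["p1", "A"] == 3.0
        assert s.sds.loc["p1", "A"] == 0.0
        assert s.means.loc["p2", "A"] == 2.0  # replicates (1,2,3)
        assert s.sds.loc["p2", "A"] == pytest.approx(1.0)
        assert s.n["A"] == 3

    def test_group_below_two_samples_is_named_in_error(self, small_log2_matrix):
        sheet = SampleSheet(
            {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "lone", "b3": "B"},
            {"A": "target", "B": "reference", "lone": "reference"},
        )
        with pytest.raises(ValueError, match="lone"):
            group_summary(small_log2_matrix, sheet)

    def test_planted_means_recovered_within_sampling_error(self):
        rng = np.random.default_rng(11)
        n_probes, n_rep, sd = 2000, 3, 0.2
        truth = rng.uniform(6, 14, n_probes)
        values = pd.DataFrame(
            {f"s{j}": rng.normal(truth, sd) for j in range(n_rep)}
        )
        m = ExpressionMatrix(values=values, scale=LOG2)
        sheet = SampleSheet(
            {f"s{j}": "A" for j in range(n_rep)} | {"r1": "R", "r2": "R"},
            {"A": "target", "R": "reference"},
        )
        # add a dummy reference group so the sheet validates
        m.values["r1"] = rng.normal(truth, sd)
        m.values["r2"] = rng.normal(truth, sd)
        s = group_summary(m, sheet)
        within = np.abs(s.means["A"] - truth) < 3 * sd / np.sqrt(n_rep)
        assert within.mean() >= 0.99


class TestFoldChange:
    def test_identity_and_powers_of_two(self):
        assert fold_change(3.0, 3.0) == 1.0
        assert fold_change(5.0, 3.0) == 4.0

    def test_printed_top_probe_fold_recovered(self):
        # OV mean with the reference mean back-computed from the printed fold
        a = 10.97366167
        fold = 15.316797
        b = a - np.log2(fold)
        assert fold_change(a, b) == pytest.approx(fold, rel=1e-9)

    def test_reciprocal_product_is_one(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(10, 2, 100), rng.normal(10, 2, 100)
        np.testing.assert_allclose(fold_change(a, b) * fold_change(b, a), 1.0)


class TestMaxReferenceFoldChange:
    def make_summary(self):
        means = pd.DataFrame(
            {"T": [10.0, 10.0, 8.0], "R1": [7.0, 8.0, 9.0], "R2": [8.0, 8.0, 7.0]},
            index=["p1", "p2", "p3"],
        )
        sds = pd.DataFrame(0.1, index=means.index, columns=means.columns)
        return GroupSummary(means, sds, pd.Series({"T": 3, "R1": 3, "R2": 3}))

    def test_max_reference_chosen(self):
        out = max_reference_fold_change(self.make_summary(), "T", ["R1", "R2"])
        assert out.loc["p1", "fold_change"] == 4.0  # 2^(10-8) vs R2
        assert out.loc["p1", "chosen_reference"] == "R2"

    def test_tie_resolved_by_fixed_group_order(self):
        out = max_reference_fold_change(self.make_summary(), "T", ["R1", "R2"])
        assert out.loc["p2", "chosen_reference"] == "R1"
        assert out.loc["p2", "fold_change"] == 4.0

    def test_depletion_representable(self):
        out = max_reference_fold_change(self.make_summary(), "T", ["R1", "R2"])
        assert out.loc["p3", "fold_change"] == 0.5  # 2^(8-9) vs R1

    def test_conservative_vs_each_single_reference(self):
        rng = np.random.default_rng(1)
        means = pd.DataFrame(
            {g: rng.normal(10, 2, 50) for g in ["T", "R1", "R2", "R3"]}
        )
        sds = pd.DataFrame(0.1, index=means.index, columns=means.columns)
        s = GroupSummary(means, sds, pd.Series({g: 3 for g in means.columns}))
        refs = ["R1", "R2", "R3"]
        combined = max_reference_fold_change(s, "T", refs)["fold_change"]
        for r in refs:
            single = fold_change(means["T"], means[r])
            assert (combined <= single + 1e-12).all()

    def test_empty_reference_list_rejected(self):
        with pytest.raises(ValueError):
            max_reference_fold_change(self.make_summary(), "T", [])


class TestVariancePriorFit:
    def test_all_equal_variances_give_infinite_d0(self):
        prior = fit_variance_prior(np.full(100, 0.04), d_g=4)
        assert np.isinf(prior.d0)
        # bias-corrected geometric mean of identical values is the value
        expected = 0.04 * np.exp(-special.digamma(2.0) + np.log(2.0))
        assert prior.s0_sq == pytest.approx(expected, rel=1e-10)

    def test_two_value_mixture_moment_equations_satisfied(self):
        s_sq = np.tile([0.01, 1.0], 200)
        d_g = 4.0
        prior = fit_variance_prior(s_sq, d_g)
        assert np.isfinite(prior.d0) and prior.d0 > 0
        # independent check: fitted parameters reproduce the empirical
        # mean/variance of log s² through the theoretical expressions
        z = np.log(s_sq)
        half_d0, half_dg = prior.d0 / 2, d_g / 2
        mean_theory = (
            np.log(prior.s0_sq)
            + special.digamma(half_dg) - np.log(half_dg)
            - special.digamma(half_d0) + np.log(half_d0)
        )
        var_theory = special.polygamma(1, half_dg) + special.polygamma(1, half_d0)
        assert mean_theory == pytest.approx(z.mean(), abs=1e-8)
        assert var_theory == pytest.approx(z.var(ddof=1), abs=1e-8)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(42)
        d0, s0_sq, d_g, n = 4.0, 0.04, 4.0, 5000
        true_var = s0_sq * d0 / rng.chisquare(d0, n)
        s_sq = true_var * rng.chisquare(d_g, n) / d_g
        prior = fit_variance_prior(s_sq, d_g)
        assert prior.d0 == pytest.approx(d0, rel=0.30)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.15)

    def test_all_zero_variances_hard_error(self):
        with pytest.raises(ValueError, match="zero"):
            fit_variance_prior(np.zeros(100), d_g=4)

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError, match="50"):
            fit_variance_prior(np.full(10, 0.1), d_g=4)

    def test_limma_squeeze_var_cross_check(self, tmp_path):
        """Independent oracle: limma::fitFDist on the same variance sample."""
        import subprocess

        rng = np.random.default_rng(7)
        d0, s0_sq, d_g, n = 4.0, 0.04, 4.0, 2000
        true_var = s0_sq * d0 / rng.chisquare(d0, n)
        s_sq = true_var * rng.chisquare(d_g, n) / d_g
        np.savetxt(tmp_path / "s2.txt", s_sq)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f's2 <- scan("{tmp_path / "s2.txt"}", quiet=TRUE)\n'
            f'f <- fitFDist(s2, df1={d_g})\n'
            'cat(f$df2, f$scale, sep="\\n")\n'
        )
        res = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert res.returncode == 0, res.stderr
        r_d0, r_s0 = map(float, res.stdout.split())
        prior = fit_variance_prior(s_sq, d_g)
        assert prior.d0 == pytest.approx(r_d0, rel=0.10)
        assert prior.s0_sq == pytest.approx(r_s0, rel=0.05)


class TestModeratedT:
    def two_group_summary(self, mean_diff=2.0, sd=1.0, n=3):
        means = pd.DataFrame({"A": [mean_diff], "B": [0.0]})
        sds = pd.DataFrame({"A": [sd], "B": [sd]})
        return GroupSummary(means, sds, pd.Series({"A": n, "B": n}))

    def test_equal_means_give_t0_p1(self):
        s = self.two_group_summary(mean_diff=0.0)
        out = moderated_t_test(s, "A", "B", VariancePrior(4.0, 1.0))
        assert out["t_stat"].iloc[0] == 0.0
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_hand_example_formula(self):
        # means 2 vs 0, n=(3,3), pooled s²=1, prior (d0=4, s0²=1) → s̃²=1,
        # t = 2/sqrt(2/3) on 8 df
        s = self.two_group_summary()
        out = moderated_t_test(s, "A", "B", VariancePrior(4.0, 1.0))
        t_expected = 2.0 / np.sqrt(2.0 / 3.0)
        assert out["t_stat"].iloc[0] == pytest.approx(t_expected, rel=1e-12)
        assert out["df_total"].iloc[0] == 8
        assert out["p_value"].iloc[0] == pytest.approx(
            2 * stats.t.sf(t_expected, 8), rel=1e-12
        )

    def test_d0_zero_equals_ordinary_pooled_t(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1, 1, (20, 3))
        b = rng.normal(0, 1, (20, 3))
        s = summary_from_values({"A": a, "B": b}, {"A": 3, "B": 3})
        out = moderated_t_test(s, "A", "B", VariancePrior(0.0, 1.0))
        t_ref, p_ref = stats.ttest_ind(a, b, axis=1)
        np.testing.assert_allclose(out["t_stat"], t_ref, atol=1e-10)
        np.testing.assert_allclose(out["p_value"], p_ref, atol=1e-10)

    def test_d0_infinite_matches_normal_limit(self):
        s = self.two_group_summary(mean_diff=1.5, sd=2.0)
        prior = VariancePrior(np.inf, 0.25)
        out = moderated_t_test(s, "A", "B", prior)
        t_expected = 1.5 / (0.5 * np.sqrt(2.0 / 3.0))
        assert out["t_stat"].iloc[0] == pytest.approx(t_expected, abs=1e-10)
        assert out["p_value"].iloc[0] == pytest.approx(
            2 * stats.norm.sf(t_expected), abs=1e-10
        )

    def test_per_probe_reference_series(self):
        means = pd.DataFrame({"T": [10.0, 10.0], "R1": [9.0, 5.0], "R2": [5.0, 9.0]})
        sds = pd.DataFrame(1.0, index=means.index, columns=means.columns)
        s = GroupSummary(means, sds, pd.Series({"T": 3, "R1": 3, "R2": 3}))
        chosen = pd.Series(["R1", "R2"], index=means.index)
        out = moderated_t_test(s, "T", chosen, VariancePrior(4.0, 1.0))
        assert out["t_stat"].iloc[0] == pytest.approx(out["t_stat"].iloc[1])

    def test_single_replicate_group_rejected(self):
        means = pd.DataFrame({"A": [1.0], "B": [0.0]})
        sds = pd.DataFrame({"A": [0.1], "B": [0.0]})
        s = GroupSummary(means, sds, pd.Series({"A": 3, "B": 1}))
        with pytest.raises(ValueError):
            moderated_t_test(s, "A", "B", VariancePrior(4.0, 1.0))


class TestReferenceContrast:
    def test_identical_means_fold_one_direction_ns(self):
        means = pd.DataFrame({"R1": np.full(100, 8.0), "R2": np.full(100, 8.0)})
        sds = pd.DataFrame(0.2, index=means.index, columns=means.columns)
        s = GroupSummary(means, sds, pd.Series({"R1": 3, "R2": 3}))
        out = reference_contrast(s, "R1", "R2", VariancePrior(4.0, 0.04))
        assert (out["fold_change_abs"] == 1.0).all()
        assert (out["direction"] == "NS").all()

    def test_near_equal_references_small_abs_fold(self):
        # means differing by log2(1.13) give abs fold ≈ 1.13
        means = pd.DataFrame({"R1": [8.0 + np.log2(1.1328)], "R2": [8.0]})
        sds = pd.DataFrame(0.3, index=means.index, columns=means.columns)
        s = GroupSummary(means, sds, pd.Series({"R1": 3, "R2": 3}))
        out = reference_contrast(s, "R1", "R2", VariancePrior(4.0, 0.09))
        assert out["fold_change_abs"].iloc[0] == pytest.approx(1.1328, rel=1e-9)

    def test_planted_reference_specific_genes_detected(self):
        # 2.4-fold planted in one reference tissue, sd 0.15, n = 3: the
        # contrast should call the right direction at q < 0.05 for >= 90%
        rng = np.random.default_rng(13)
        n_probes, n_planted, sd = 2000, 100, 0.15
        base = rng.uniform(6, 14, n_probes)
        shift = np.zeros(n_probes)
        shift[:n_planted] = np.log2(2.4)
        a = np.column_stack([rng.normal(base + shift, sd) for _ in range(3)])
        b = np.column_stack([rng.normal(base, sd) for _ in range(3)])
        s = summary_from_values({"embryo": a, "periotic": b}, {"embryo": 3, "periotic": 3})
        out = reference_contrast(s, "embryo", "periotic", VariancePrior(4.0, sd**2))
        planted = out.iloc[:n_planted]
        hits = (planted["direction"] == "embryo").mean()
        assert hits >= 0.90


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_tied_values(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([0.05, 0.05]), [0.05, 0.05])

    def test_invalid_p_rejected(self):
        for bad in ([-0.1], [1.1], [np.nan]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 21))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_q_at_least_p_and_monotone_on_sorted(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
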