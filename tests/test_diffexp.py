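"""Blocked OLS fits, variance moderation, moderated t, BH, and set comparison."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from granudx import (
    DesignSpec,
    ExpressionMatrix,
    SampleTable,
    bh_adjust,
    classify_and_summarize,
    compare_signatures,
    ebayes_squeeze,
    fit_protein_models,
    moderated_t_test,
    run_differential_expression,
)
from granudx.containers import PROVENANCE_COMBAT, SCALE_LOG2, PeptideSupport
from granudx.diffexp import fold_change_phrase


def _log2_matrix(values, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    df = pd.DataFrame(
        values,
        index=[f"P{i}" for i in range(values.shape[0])],
        columns=samples or [f"S{i}" for i in range(values.shape[1])],
    )
    return ExpressionMatrix(df, scale=SCALE_LOG2)


def _samples(groups, batches=None):
    n = len(groups)
    return SampleTable(pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "group": groups,
        "batch": batches or ["b1"] * n,
    }))


class TestFitProteinModels:
    def test_hand_ols_single_batch(self):
        """case {4,6} vs ref {1,3}: beta=3, s2=2, df=2 by hand."""
        m = _log2_matrix([[1.0, 3.0, 4.0, 6.0]])
        samples = _samples(["healthy", "healthy", "case", "case"])
        fits = fit_protein_models(m, samples, DesignSpec(case="case"))
        assert fits.coef["P0"] == pytest.approx(3.0)
        assert fits.s2["P0"] == pytest.approx(2.0)
        assert fits.df["P0"] == 2
        # leverage of the contrast: 1/n1 + 1/n2 = 1
        assert fits.leverage == pytest.approx(1.0)

    def test_blocking_absorbs_batch_shift(self):
        rng = np.random.default_rng(0)
        base = rng.normal(20, 0.3, size=(40, 12))
        m1 = _log2_matrix(base)
        groups = ["case", "healthy"] * 6  # balanced within batches
        batches = ["A"] * 6 + ["B"] * 6
        samples = _samples(groups, batches)
        fits1 = fit_protein_models(m1, samples, DesignSpec(case="case"))
        shifted = base.copy()
        shifted[:, 6:] += 5.0
        fits2 = fit_protein_models(_log2_matrix(shifted), samples,
                                   DesignSpec(case="case"))
        np.testing.assert_allclose(fits1.coef, fits2.coef, atol=1e-10)

    def test_low_peptide_proteins_excluded(self):
        m = _log2_matrix([[1, 2, 3, 4], [1, 2, 3, 4]])
        samples = _samples(["healthy", "healthy", "case", "case"])
        peptides = PeptideSupport({"P0": 1, "P1": 2})
        fits = fit_protein_models(m, samples, DesignSpec(case="case"), peptides)
        assert "P0" in fits.excluded
        assert list(fits.coef.index) == ["P1"]

    def test_confounded_design_is_error(self):
        m = _log2_matrix([[1, 2, 3, 4]])
        samples = _samples(
            ["healthy", "healthy", "case", "case"], ["A", "A", "B", "B"]
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_protein_models(m, samples, DesignSpec(case="case"))

    def test_refuses_combat_adjusted_matrix(self):
        m = _log2_matrix([[1, 2, 3, 4]])
        m.provenance = PROVENANCE_COMBAT
        samples = _samples(["healthy", "healthy", "case", "case"])
        with pytest.raises(ValueError, match="unadjusted"):
            fit_protein_models(m, samples, DesignSpec(case="case"))

    def test_missing_values_complete_case_per_protein(self):
        m = _log2_matrix([[1.0, 3.0, 4.0, 6.0, np.nan, 20.0]])
        samples = _samples(["healthy", "healthy", "case", "case",
                            "healthy", "other"])
        fits = fit_protein_models(m, samples, DesignSpec(case="case"))
        # the "other" sample is outside the contrast; the NaN healthy sample
        # is dropped, leaving the 4-point hand example
        assert fits.coef["P0"] == pytest.approx(3.0)


class TestEbayesSqueeze:
    def test_recovers_simulated_hyperparameters(self):
        rng = np.random.default_rng(42)
        d0, s0sq, d, n = 4.0, 0.04, 70, 5000
        sigma_sq = d0 * s0sq / rng.chisquare(d0, size=n)
        s2 = sigma_sq * rng.chisquare(d, size=n) / d
        params, post = ebayes_squeeze(s2, np.full(n, d))
        assert params.d0 == pytest.approx(d0, rel=0.15)
        assert params.s0sq == pytest.approx(s0sq, rel=0.15)
        # posterior variances lie between prior scale and observed values
        assert np.all(post > 0)

    def test_posterior_is_precision_weighted_blend(self):
        rng = np.random.default_rng(1)
        sigma_sq = 4.0 * 0.1 / rng.chisquare(4.0, size=200)
        s2 = sigma_sq * rng.chisquare(10, 200) / 10
        params, post = ebayes_squeeze(s2, np.full(200, 10.0))
        assert np.isfinite(params.d0)
        manual = (params.d0 * params.s0sq + 10 * s2) / (params.d0 + 10)
        np.testing.assert_allclose(post, manual)

    def test_too_few_proteins_is_error(self):
        with pytest.raises(ValueError, match="10"):
            ebayes_squeeze([0.1] * 5, [10] * 5)

    def test_homogeneous_variances_give_infinite_d0(self):
        # all equal s2: no excess spread beyond chi-square sampling -> d0 = inf
        s2 = np.full(200, 0.5)
        params, post = ebayes_squeeze(s2, np.full(200, 50.0))
        assert np.isinf(params.d0)
        np.testing.assert_allclose(post, params.s0sq)

    def test_zero_variances_assigned_prior_scale(self):
        rng = np.random.default_rng(2)
        s2 = np.concatenate([rng.chisquare(10, 100) / 10 * 0.5, [0.0]])
        params, post = ebayes_squeeze(s2, np.full(101, 10.0))
        assert post.iloc[-1] == pytest.approx(params.s0sq)


class TestModeratedT:
    def test_zero_coefficient_gives_p_one(self):
        t, p = moderated_t_test([0.0], [1.0], 0.5, [10.0], d0=4.0)
        assert p[0] == pytest.approx(1.0)

    def test_known_t_quantile(self):
        # |t| = 2.0 at 10 df -> two-sided p = 0.0734
        p = 2 * stats.t.sf(2.0, 10)
        t, p_ours = moderated_t_test([2.0], [1.0], 1.0, [10.0], d0=0.0)
        assert p_ours[0] == pytest.approx(p, abs=1e-10)
        assert p_ours[0] == pytest.approx(0.0734, abs=5e-5)

    def test_d0_zero_equals_ordinary_t_test(self):
        """With no moderation the pipeline reproduces scipy's two-sample t."""
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
        m = _log2_matrix(np.concatenate([a, b]))
        samples = _samples(["healthy"] * 6 + ["case"] * 6)
        fits = fit_protein_models(m, samples, DesignSpec(case="case"))
        t, p = moderated_t_test(
            fits.coef, fits.s2, fits.leverage, fits.df, d0=0.0
        )
        ref = stats.ttest_ind(b, a)
        assert t[0] == pytest.approx(ref.statistic)
        assert p[0] == pytest.approx(ref.pvalue)

    def test_d0_infinite_is_fixed_variance_z(self):
        t, p = moderated_t_test([1.0], [0.25], 1.0, [5.0], d0=np.inf)
        assert p[0] == pytest.approx(2 * stats.norm.sf(2.0))

    def test_nonpositive_leverage_is_error(self):
        with pytest.raises(ValueError):
            moderated_t_test([1.0], [1.0], 0.0, [5.0], d0=1.0)


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_brute_force_step_up(self, p):
        """q_i = min over j with p_j >= p_i of m*p_j/rank_j, capped at 1."""
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        brute = np.empty(m)
        for pos, i in enumerate(order):
            candidates = [
                m * p[order[j]] / (j + 1) for j in range(pos, m)
            ]
            brute[i] = min(1.0, min(candidates))
        np.testing.assert_allclose(bh_adjust(p), brute, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)


class TestClassifyAndCompare:
    def _result(self, padj, lfc):
        return pd.DataFrame({
            "log2FC": lfc,
            "padj": padj,
            "significant": (np.asarray(padj) < 0.01)
            & (np.abs(np.asarray(lfc)) > 1),
        }, index=[f"P{i}" for i in range(len(padj))])

    def test_empty_significant_set(self):
        out = classify_and_summarize(self._result([0.5], [0.2]))
        assert (out["n_under"], out["n_over"]) == (0, 0)
        assert out["panel"].empty

    def test_fold_change_gate(self):
        out = classify_and_summarize(self._result([0.005], [-0.9]))
        assert (out["n_under"], out["n_over"]) == (0, 0)

    def test_under_over_split_and_panel_order(self):
        res = self._result([1e-5, 1e-4, 1e-3, 0.5], [-2.0, 3.0, -1.5, 2.0])
        copies = pd.Series([3.0, 7.0, 5.0, 6.0],
                           index=["P0", "P1", "P2", "P3"])
        out = classify_and_summarize(res, copies, top_k=3)
        assert (out["n_under"], out["n_over"]) == (2, 1)
        assert list(out["panel"].index) == ["P1", "P2", "P0"]  # copies desc

    def test_compare_signature_partitions(self, rng):
        assert compare_signatures({"x": {"A"}, "y": {"A"}}) == {("x", "y"): {"A"}}
        disjoint = compare_signatures({"x": {"A"}, "y": {"B"}})
        assert ("x", "y") not in disjoint
        sets = {
            n: set(rng.choice(50, size=rng.integers(5, 20), replace=False))
            for n in "abc"
        }
        partition = compare_signatures(sets)
        assert sum(len(v) for v in partition.values()) == len(
            set().union(*sets.values())
        )

    def test_fold_change_phrase(self):
        assert fold_change_phrase(-np.log2(84)) == "down-regulated 84.0-fold"


class TestEndToEnd:
    def test_null_cohort_p_uniformity(self, small_cohort, small_log2):
        """Healthy-vs-healthy split: raw p-values are uniform."""
        meta = small_cohort.samples.data.copy()
        healthy = meta["group"] == "healthy"
        meta.loc[meta.index[healthy][:15], "group"] = "pseudo"
        samples = SampleTable(meta)
        res = run_differential_expression(
            small_log2, samples, DesignSpec(case="pseudo"),
            small_cohort.peptides,
        )
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01
        assert res["significant"].sum() == 0


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_squeeze_matches_limma_reference(tmp_path, rng):
    """Independent oracle: limma::squeezeVar on the same variance vector."""
    d0, s0sq, d, n = 5.0, 0.1, 30, 400
    sigma_sq = d0 * s0sq / rng.chisquare(d0, size=n)
    s2 = sigma_sq * rng.chisquare(d, size=n) / d
    np.savetxt(tmp_path / "s2.txt", s2)
    rscript = tmp_path / "squeeze.R"
    rscript.write_text(
        f"""
        suppressMessages(library(limma))
        s2 <- scan("{tmp_path / 's2.txt'}")
        fit <- squeezeVar(s2, df={d})
        writeLines(c(as.character(fit$df.prior), as.character(fit$var.prior)))
        write(fit$var.post, "{tmp_path / 'post.txt'}", ncolumns=1)
        """
    )
    proc = subprocess.run(["Rscript", "--vanilla", str(rscript)],
                          check=True, capture_output=True, text=True)
    d0_ref, s0sq_ref = [float(x) for x in proc.stdout.split()[:2]]
    post_ref = np.loadtxt(tmp_path / "post.txt")
    params, post = ebayes_squeeze(s2, np.full(n, float(d)))
    assert params.d0 == pytest.approx(d0_ref, rel=1e-4)
    assert params.s0sq == pytest.approx(s0sq_ref, rel=1e-4)
    np.testing.assert_allclose(post, post_ref, rtol=1e-6)
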