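"""PCA, replicate correlation, TPM, z-score heatmap clustering, and ORA."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from granudx import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleTable,
    ora_enrichment,
    pca_profiles,
    protein_rna_correlation,
    replicate_correlation,
    tpm_from_counts,
    zscore_vs_healthy,
)
from granudx.containers import SCALE_LOG2


def _matrix(values, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    df = pd.DataFrame(
        values,
        index=[f"P{i}" for i in range(values.shape[0])],
        columns=samples or [f"S{i}" for i in range(values.shape[1])],
    )
    return ExpressionMatrix(df, scale=SCALE_LOG2)


class TestPCA:
    def test_identical_samples_coincide_on_pc1(self, rng):
        col = rng.normal(size=10)
        m = _matrix(np.column_stack([col, col, rng.normal(size=10)]))
        res = pca_profiles(m)
        assert res.scores.loc["S0", "PC1"] == pytest.approx(
            res.scores.loc["S1", "PC1"]
        )

    def test_rank_one_matrix_explains_everything(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=5)
        m = _matrix(np.outer(u, v))
        res = pca_profiles(m)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self, rng):
        """Scores and variance fractions vs a brute-force eigen oracle."""
        X = rng.normal(size=(50, 20))
        m = _matrix(X)
        res = pca_profiles(m, n_components=5)
        Xc = X - X.mean(axis=1, keepdims=True)
        cov = Xc.T @ Xc
        w, v = np.linalg.eigh(cov)
        w, v = w[::-1], v[:, ::-1]
        np.testing.assert_allclose(
            res.variance_fractions, (w / w.sum())[:5], atol=1e-8
        )
        for j in range(5):
            ours = res.scores.iloc[:, j].to_numpy()
            oracle = v[:, j] * np.sqrt(w[j])
            assert min(
                np.abs(ours - oracle).max(), np.abs(ours + oracle).max()
            ) < 1e-8

    def test_variance_fractions_monotone_and_bounded(self, rng):
        res = pca_profiles(_matrix(rng.normal(size=(30, 8))))
        vf = res.variance_fractions
        assert np.all(np.diff(vf) <= 1e-12)
        assert np.all((vf >= 0) & (vf <= 1)) and vf.sum() <= 1 + 1e-9

    def test_too_few_samples_is_error(self, rng):
        with pytest.raises(ValueError):
            pca_profiles(_matrix(rng.normal(size=(10, 2))))


class TestReplicateCorrelation:
    def test_duplicate_column_gives_unity(self, rng):
        col = rng.normal(size=20)
        m = _matrix(np.column_stack([col, col]))
        _, mean = replicate_correlation(m, sample_ids=["S0", "S1"])
        assert mean == pytest.approx(1.0)

    def test_anticorrelated_toy(self):
        x = np.array([1.0, 2.0, 3.0])
        m = _matrix(np.column_stack([x, -x]))
        _, mean = replicate_correlation(m, sample_ids=["S0", "S1"])
        assert mean == pytest.approx(-1.0)

    def test_requires_two_samples(self, rng):
        m = _matrix(rng.normal(size=(5, 1)))
        with pytest.raises(ValueError):
            replicate_correlation(m, sample_ids=["S0"])


class TestTPM:
    def test_hand_values(self):
        tpm = tpm_from_counts([10, 10], [1000, 2000])
        np.testing.assert_allclose(tpm, [666666.6667, 333333.3333], rtol=1e-6)

    def test_single_gene(self):
        assert tpm_from_counts([7], [500])[0] == pytest.approx(1e6)

    def test_sums_to_a_million(self, rng):
        tpm = tpm_from_counts(
            rng.integers(0, 1000, size=100), rng.integers(200, 9000, size=100)
        )
        assert tpm.sum() == pytest.approx(1e6)

    def test_all_zero_counts_is_error(self):
        with pytest.raises(ValueError):
            tpm_from_counts([0, 0], [100, 100])


class TestProteinRnaCorrelation:
    def test_proportional_series_correlate_fully(self):
        genes = [f"G{i}" for i in range(12)]
        prot = pd.Series(np.arange(1.0, 13.0), index=genes)
        r, n = protein_rna_correlation(prot, prot * 7.0)
        assert r == pytest.approx(1.0)
        assert n == 12

    def test_scale_invariance(self, rng):
        genes = [f"G{i}" for i in range(30)]
        a = pd.Series(rng.lognormal(2, 1, 30), index=genes)
        b = pd.Series(rng.lognormal(2, 1, 30), index=genes)
        r1, _ = protein_rna_correlation(a, b)
        r2, _ = protein_rna_correlation(a * 100, b * 0.01)
        assert r1 == pytest.approx(r2)

    def test_too_few_shared_genes_is_error(self):
        a = pd.Series([1.0] * 5, index=list("abcde"))
        with pytest.raises(ValueError):
            protein_rna_correlation(a, a)


def _cohort_table(n_healthy, n_patient):
    labels = ["healthy"] * n_healthy + ["case"] * n_patient
    return SampleTable(pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(len(labels))],
        "group": labels,
        "batch": "b1",
    }))


class TestZscoreHeatmap:
    def test_columns_standardized(self, rng):
        m = _matrix(rng.normal(20, 2, size=(40, 8)))
        out = zscore_vs_healthy(m, _cohort_table(5, 3))
        z = out["zscores"]
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=0), 1, atol=1e-12)

    def test_healthy_mean_sample_is_degenerate(self, rng):
        base = rng.normal(20, 2, size=(30, 4))
        mean_col = base[:, :3].mean(axis=1)  # 3 healthy samples
        m = _matrix(np.column_stack([base[:, :3], mean_col]))
        # the last sample IS the healthy mean -> all-zero column -> error
        table = _cohort_table(3, 1)
        with pytest.raises(ValueError, match="S3"):
            zscore_vs_healthy(m, table)

    def test_identical_patients_merge_first(self, rng):
        base = rng.normal(20, 1, size=(30, 6))
        base[:, 5] = base[:, 4]  # duplicate patient column
        m = _matrix(base)
        out = zscore_vs_healthy(m, _cohort_table(4, 2))
        first_merge = out["col_linkage"][0]
        assert {int(first_merge[0]), int(first_merge[1])} == {4, 5}
        assert first_merge[2] == pytest.approx(0.0, abs=1e-10)

    def test_merge_heights_match_brute_force_average_linkage(self, rng):
        """4-sample oracle: UPGMA merges computed by brute-force enumeration."""
        m = _matrix(rng.normal(20, 2, size=(12, 4)))
        out = zscore_vs_healthy(m, _cohort_table(2, 2))
        z = out["zscores"].to_numpy().T  # samples × proteins

        # brute-force UPGMA
        clusters = {i: [i] for i in range(4)}
        dist = {
            (i, j): np.linalg.norm(z[i] - z[j])
            for i, j in combinations(range(4), 2)
        }
        heights = []
        next_id = 4
        while len(clusters) > 1:
            (a, b), h = min(
                (
                    ((i, j), np.mean([
                        np.linalg.norm(z[p] - z[q])
                        for p in clusters[i] for q in clusters[j]
                    ]))
                    for i, j in combinations(sorted(clusters), 2)
                ),
                key=lambda kv: kv[1],
            )
            heights.append(h)
            clusters[next_id] = clusters.pop(a) + clusters.pop(b)
            next_id += 1
        np.testing.assert_allclose(out["col_linkage"][:, 2], heights, atol=1e-10)


class TestORA:
    def _sets(self, spec):
        c = GeneSetCollection()
        for name, members in spec.items():
            c.add(name, name, members)
        return c

    def test_foreground_equals_background_gives_p_one(self):
        bg = [f"G{i}" for i in range(10)]
        sets = self._sets({"S1": bg[:4]})
        res = ora_enrichment(bg, bg, sets)
        assert res.loc["S1", "p"] == pytest.approx(1.0)

    def test_hypergeometric_closed_form(self):
        """Full overlap of a 5-set in a 20-background: p = 1/C(20,5)."""
        bg = [f"G{i}" for i in range(20)]
        sets = self._sets({"S1": bg[:5]})
        res = ora_enrichment(bg[:5], bg, sets)
        from math import comb

        assert res.loc["S1", "p"] == pytest.approx(1 / comb(20, 5))
        assert res.loc["S1", "p"] == pytest.approx(6.45e-5, rel=1e-2)

    def test_bh_of_single_tested_set_is_raw_p(self):
        bg = [f"G{i}" for i in range(12)]
        sets = self._sets({"S1": bg[:4], "tiny": [bg[0]]})
        res = ora_enrichment(bg[:4], bg, sets)
        assert res.loc["S1", "padj"] == pytest.approx(res.loc["S1", "p"])
        assert np.isnan(res.loc["tiny", "p"])  # below min_overlap

    def test_matches_exhaustive_enumeration(self, rng):
        """Oracle: enumerate all foreground draws on a background of 12."""
        from itertools import combinations as comb_iter

        bg = [f"G{i}" for i in range(12)]
        set_members = list(rng.choice(bg, size=5, replace=False))
        fg = list(rng.choice(bg, size=4, replace=False))
        k_obs = len(set(fg) & set(set_members))
        total = 0
        at_least = 0
        for draw in comb_iter(range(12), 4):
            total += 1
            k = len({bg[i] for i in draw} & set(set_members))
            at_least += k >= k_obs
        res = ora_enrichment(fg, bg, self._sets({"S": set_members}), min_overlap=0)
        assert res.loc["S", "p"] == pytest.approx(at_least / total)

    def test_stray_foreground_is_error(self):
        with pytest.raises(ValueError, match="missing from background"):
            ora_enrichment(["X"], ["A", "B"], self._sets({"S": ["A"]}))

    def test_ease_penalty_is_more_conservative(self):
        bg = [f"G{i}" for i in range(20)]
        sets = self._sets({"S1": bg[:5]})
        plain = ora_enrichment(bg[:5], bg, sets)
        eased = ora_enrichment(bg[:5], bg, sets, ease=True)
        assert eased.loc["S1", "p"] > plain.loc["S1", "p"]
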