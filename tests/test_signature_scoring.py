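"""Z-score signature scoring and ANCOVA group comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import serdstudy as sd
from serdstudy.signature_scoring import compare_scores_ancova


def make_matrix(values, groups=None, covariate=None):
    df = pd.DataFrame(
        values,
        index=[f"G{i}" for i in range(values.shape[0])],
        columns=[f"s{i}" for i in range(values.shape[1])],
    )
    g = pd.Series(
        groups if groups is not None else ["a"] * df.shape[1], index=df.columns
    )
    c = pd.Series(covariate, index=df.columns) if covariate is not None else None
    return sd.ExpressionMatrix(values=df, groups=g, covariate=c)


class TestZScoreNormalize:
    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(3)
        z = sd.zscore_normalize(make_matrix(rng.normal(5, 2, (20, 12))))
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_constant_gene_dropped_with_warning(self):
        vals = np.vstack([np.ones(6), np.arange(6.0)])
        with pytest.warns(UserWarning, match="constant"):
            z = sd.zscore_normalize(make_matrix(vals))
        assert list(z.values.index) == ["G1"]

    def test_two_sample_conventions(self):
        vals = np.array([[1.0, 3.0]])
        z_pop = sd.zscore_normalize(make_matrix(vals), population_sd=True)
        np.testing.assert_allclose(z_pop.values.to_numpy()[0], [-1.0, 1.0])
        z_samp = sd.zscore_normalize(make_matrix(vals), population_sd=False)
        np.testing.assert_allclose(
            z_samp.values.to_numpy()[0], [-1 / np.sqrt(2), 1 / np.sqrt(2)]
        )

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            sd.zscore_normalize(make_matrix(np.ones((3, 1))))


def simple_signature(n_up=3, n_down=2):
    genes = [f"G{i}" for i in range(n_up + n_down)]
    return sd.GeneSignature(
        directions=pd.Series([1] * n_up + [-1] * n_down, index=genes)
    )


class TestScoreSignature:
    def test_zero_matrix_scores_zero(self):
        m = make_matrix(np.zeros((5, 4)))
        scores = sd.score_signature(m, simple_signature())
        np.testing.assert_allclose(scores, 0.0)

    def test_direction_flip_negates_scores(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(0, 1, (5, 6)))
        sig = simple_signature()
        np.testing.assert_allclose(
            sd.score_signature(m, sig), -sd.score_signature(m, sig.flipped())
        )

    def test_mirror_gene_pair_cancels(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, (4, 6))
        m = make_matrix(vals)
        sig = sd.GeneSignature(directions=pd.Series([1, -1], index=["G0", "G1"]))
        # G0 and G1 identical with opposite directions contribute zero
        m.values.loc["G1"] = m.values.loc["G0"]
        extended = sd.GeneSignature(
            directions=pd.Series([1, -1, 1], index=["G0", "G1", "G2"])
        )
        s_pair = sd.score_signature(m, extended)
        s_single = sd.score_signature(
            m, sd.GeneSignature(directions=pd.Series([1], index=["G2"]))
        )
        np.testing.assert_allclose(3 * s_pair, s_single, atol=1e-12)

    def test_absent_signature_rejected(self):
        m = make_matrix(np.zeros((3, 4)))
        sig = sd.GeneSignature(directions=pd.Series([1, 1], index=["X1", "X2"]))
        with pytest.raises(ValueError, match="no signature genes"):
            sd.score_signature(m, sig)

    def test_low_coverage_rejected(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(2, 4)))
        sig = sd.GeneSignature(
            directions=pd.Series([1, 1, 1, 1, -1], index=["G0", "X1", "X2", "X3", "X4"])
        )
        with pytest.warns(UserWarning, match="absent"):
            with pytest.raises(ValueError, match="coverage"):
                sd.score_signature(m, sig)

    def test_affine_transform_of_raw_matrix_absorbed(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(8, 2, (6, 10))
        sig = simple_signature()
        base = sd.score_signature(sd.zscore_normalize(make_matrix(vals)), sig)
        scaled = sd.score_signature(
            sd.zscore_normalize(make_matrix(3.0 * vals + 7.0)), sig
        )
        np.testing.assert_allclose(base, scaled, atol=1e-10)


def ancova_oracle(scores, groups, covariate):
    """Normal-equations ANCOVA oracle: F test for the group term."""
    y = np.asarray(scores, dtype=float)
    labels = sorted(set(groups))
    dummies = np.column_stack(
        [(np.asarray(groups) == g).astype(float) for g in labels[1:]]
    )
    cov = np.asarray(covariate, dtype=float)[:, None]
    X_full = np.hstack([np.ones((len(y), 1)), dummies, cov])
    X_red = np.hstack([np.ones((len(y), 1)), cov])

    def ssr(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    df_num = dummies.shape[1]
    df_den = len(y) - X_full.shape[1]
    f = ((ssr(X_red) - ssr(X_full)) / df_num) / (ssr(X_full) / df_den)
    return float(stats.f.sf(f, df_num, df_den))


class TestANCOVA:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = int(rng.integers(4, 10))
            groups = ["a"] * n + ["b"] * n
            scores = pd.Series(
                rng.normal(0, 1, 2 * n), index=[f"s{i}" for i in range(2 * n)]
            )
            cov = pd.Series(rng.normal(0, 1, 2 * n), index=scores.index)
            res = compare_scores_ancova(scores, pd.Series(groups, index=scores.index), cov)
            assert res.p_value == pytest.approx(
                ancova_oracle(scores, groups, cov), abs=1e-9
            )

    def test_constant_covariate_reduces_to_anova(self):
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.normal(0, 1, 12), index=[f"s{i}" for i in range(12)])
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=scores.index)
        const = pd.Series(np.ones(12), index=scores.index)
        res = compare_scores_ancova(scores, groups, const)
        f_anova = stats.f_oneway(scores[groups == "a"], scores[groups == "b"])
        assert res.p_value == pytest.approx(f_anova.pvalue, abs=1e-9)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(31)
        n = 10
        scores = pd.Series(
            np.concatenate([rng.normal(0, 1, n), rng.normal(2.0, 1, n)]),
            index=[f"s{i}" for i in range(2 * n)],
        )
        groups = pd.Series(["ctrl"] * n + ["trt"] * n, index=scores.index)
        cov = pd.Series(rng.normal(0, 1, 2 * n), index=scores.index)
        res = compare_scores_ancova(scores, groups, cov)
        assert res.p_value < 0.01
        assert res.delta == pytest.approx(2.0, abs=1.0)

    def test_small_groups_rejected(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=["s0", "s1", "s2"])
        groups = pd.Series(["a", "a", "b"], index=scores.index)
        with pytest.raises(ValueError, match="< 2 samples"):
            compare_scores_ancova(scores, groups)


class TestPlantedSignatureEffect:
    def test_planted_shift_yields_analytic_score_delta(self):
        """Induced genes +2z / repressed -2z in the treated group.

        After pooled z-scoring the per-gene group separation is
        shift / sqrt(1 + shift^2/4) (the planted shift inflates the
        pooled SD), and every signature gene contributes that amount
        with positive sign, so the expected score delta follows in
        closed form.
        """
        shift, n = 2.0, 20
        sig = sd.GeneSignature(
            directions=pd.Series(
                [1] * 12 + [-1] * 8, index=[f"G{i:05d}" for i in range(20)]
            )
        )
        m = sd.simulate_expression(
            n_genes=500,
            n_samples_per_group=n,
            signature=sig,
            shift=shift,
            noise=sd.NoiseModel(expression_sd=1.0, seed=42),
        )
        scores = sd.score_signature(sd.zscore_normalize(m), sig)
        res = compare_scores_ancova(scores, m.groups)
        expected = shift / np.sqrt(1 + shift**2 / 4)
        se = float(
            np.sqrt(
                scores[m.groups == "treated"].sem() ** 2
                + scores[m.groups == "control"].sem() ** 2
            )
        )
        assert res.delta == pytest.approx(expected, abs=3 * se)

    def test_null_shift_gives_null_delta(self):
        sig = simple_signature()
        deltas = []
        for seed in range(8):
            m = sd.simulate_expression(
                n_genes=200,
                n_samples_per_group=15,
                signature=sd.GeneSignature(
                    directions=pd.Series([1, 1, 1, -1, -1], index=[f"G{i:05d}" for i in range(5)])
                ),
                shift=0.0,
                noise=sd.NoiseModel(seed=seed),
            )
            scores = sd.score_signature(sd.zscore_normalize(m), sd.GeneSignature(
                directions=pd.Series([1, 1, 1, -1, -1], index=[f"G{i:05d}" for i in range(5)])
            ))
            deltas.append(
                scores[m.groups == "treated"].mean() - scores[m.groups == "control"].mean()
            )
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * max(se, 1e-3)
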