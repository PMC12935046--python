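import numpy as np
import pandas as pd
import pytest
from scipy import stats

from muscleomics import (
    DesignSpec,
    OmicsMatrix,
    adjust_bh_grouped,
    default_contrasts,
    estimate_sample_weights,
    fit_cell_means,
    moderate_variances,
    run_differential,
)
from muscleomics.differential import (
    ContrastSpec,
    DEFAULT_LEVELS,
    test_contrast as contrast_test,
)
from muscleomics.synthetic import SimConfig, simulate_omics_experiment

from conftest import make_matrix


def two_level_matrix(values_by_level):
    """Matrix over a reduced WT.SED / KI.SED design (3 replicates each)."""
    rows = []
    sample_ids = []
    meta = {"sex": [], "genotype": [], "timepoint": [], "replicate": []}
    for g, vals in values_by_level.items():
        for r, v in enumerate(vals):
            sample_ids.append(f"M_{g}_SED_r{r + 1}")
            meta["sex"].append("M")
            meta["genotype"].append(g)
            meta["timepoint"].append("SED")
            meta["replicate"].append(r + 1)
    values = pd.DataFrame(
        [sum(values_by_level.values(), [])], index=["f1"], columns=sample_ids
    )
    samples = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample_id"))
    return OmicsMatrix(values.astype(float), samples)


class TestFit:
    def test_exact_fit_two_levels(self):
        matrix = two_level_matrix({"WT": [1.0, 1.0, 1.0], "KI": [2.0, 2.0, 2.0]})
        design = DesignSpec(matrix.group_labels(), levels=("WT.SED", "KI.SED"))
        fit = fit_cell_means(matrix, design)
        assert fit.beta.loc["f1", "WT.SED"] == pytest.approx(1.0)
        assert fit.beta.loc["f1", "KI.SED"] == pytest.approx(2.0)
        assert fit.sigma2["f1"] == pytest.approx(0.0)

    def test_coefficients_equal_cell_means(self, small_matrix):
        fit = fit_cell_means(small_matrix)
        groups = small_matrix.group_labels()
        for level in DEFAULT_LEVELS:
            direct = small_matrix.values.loc[:, groups == level].mean(axis=1)
            np.testing.assert_allclose(fit.beta[level], direct, atol=1e-12)

    def test_residual_df(self, small_matrix):
        fit = fit_cell_means(small_matrix)
        assert fit.df_residual == 18 - 6

    def test_weight_scale_invariance(self, small_matrix):
        fit1 = fit_cell_means(small_matrix,
                              weights=pd.Series(1.0, index=small_matrix.sample_ids))
        fit2 = fit_cell_means(small_matrix,
                              weights=pd.Series(2.0, index=small_matrix.sample_ids))
        pd.testing.assert_frame_equal(fit1.beta, fit2.beta)
        contrast = default_contrasts()[0]
        mod1 = moderate_variances(fit1, robust=False)
        mod2 = moderate_variances(fit2, robust=False)
        t1 = contrast_test(mod1, fit1, contrast)["t"]
        t2 = contrast_test(mod2, fit2, contrast)["t"]
        np.testing.assert_allclose(t1, t2, rtol=1e-10)

    def test_missing_values_rejected(self, small_matrix):
        values = small_matrix.values.copy()
        values.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            fit_cell_means(OmicsMatrix(values, small_matrix.samples))


class TestSampleWeights:
    def test_homoscedastic_weights_near_one(self):
        exp = simulate_omics_experiment(SimConfig(n_features=2000, seed=10))
        w = estimate_sample_weights(exp.matrices["M"])
        assert (w > 0.8).all() and (w < 1.25).all()
        assert np.exp(np.mean(np.log(w))) == pytest.approx(1.0)

    def test_inflated_sample_gets_minimum_weight(self):
        config = SimConfig(n_features=1000,
                           inflated_samples=(("M_KI_EXH_r2", 4.0),), seed=11)
        exp = simulate_omics_experiment(config)
        w = estimate_sample_weights(exp.matrices["M"])
        assert w.idxmin() == "M_KI_EXH_r2"

    def test_identical_samples_identical_weights(self, rng):
        base = rng.normal(size=(100, 18))
        base[:, 1] = base[:, 0]  # replicate samples within the same cell
        matrix = make_matrix(base)
        w = estimate_sample_weights(matrix)
        assert w.iloc[0] == pytest.approx(w.iloc[1], rel=1e-6)


class TestModeration:
    def test_constant_variances_are_fixed_point(self, small_matrix):
        fit = fit_cell_means(small_matrix)
        fit.sigma2[:] = 0.25
        mod = moderate_variances(fit)
        np.testing.assert_allclose(mod.sigma2_post, 0.25, rtol=1e-12)

    def test_prior_parameter_recovery(self):
        rng = np.random.default_rng(12)
        d, d0_true, s0_true = 12, 4.0, 0.09
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(d, size=5000) / d
        fit = _fit_stub(s2, d)
        mod = moderate_variances(fit, robust=False)
        assert abs(mod.d0 - d0_true) / d0_true < 0.25
        assert abs(mod.s0_squared.iloc[0] - s0_true) / s0_true < 0.10

    def test_posterior_between_prior_and_observed(self, small_matrix):
        fit = fit_cell_means(small_matrix)
        mod = moderate_variances(fit)
        lo = np.minimum(fit.sigma2, mod.s0_squared)
        hi = np.maximum(fit.sigma2, mod.s0_squared)
        assert ((mod.sigma2_post >= lo - 1e-12) & (mod.sigma2_post <= hi + 1e-12)).all()

    def test_forced_infinite_d0_gives_prior(self, small_matrix):
        fit = fit_cell_means(small_matrix)
        mod = moderate_variances(fit, d0_override=np.inf)
        np.testing.assert_allclose(mod.sigma2_post, mod.s0_squared)

    def test_robust_ignores_outlying_variances(self, small_matrix):
        fit = fit_cell_means(small_matrix)
        plain = moderate_variances(fit, robust=False)
        fit.sigma2.iloc[0] = 1e6  # one wild feature
        robust = moderate_variances(fit, robust=True)
        assert abs(np.log(robust.s0_squared.iloc[-1] / plain.s0_squared.iloc[-1])) < 0.5


def _fit_stub(s2, d):
    """Minimal FitResult carrying only what moderation needs."""
    from muscleomics.differential import FitResult

    idx = pd.Index([f"f{i}" for i in range(len(s2))])
    return FitResult(
        beta=pd.DataFrame(0.0, index=idx, columns=list(DEFAULT_LEVELS)),
        sigma2=pd.Series(s2, index=idx),
        df_residual=d,
        cov_unscaled=np.eye(6) / 3,
        amean=pd.Series(20.0, index=idx),
        levels=DEFAULT_LEVELS,
        weights=pd.Series(1.0, index=[f"s{i}" for i in range(18)]),
    )


class TestContrasts:
    def test_null_contrast(self, small_matrix):
        fit = fit_cell_means(small_matrix)
        mod = moderate_variances(fit)
        null = ContrastSpec("null", (0.0,) * 6)
        table = contrast_test(mod, fit, null)
        assert (table["logFC"] == 0).all()
        assert (table["p"] == 1).all()

    def test_negated_contrast_flips_t(self, small_matrix):
        fit = fit_cell_means(small_matrix)
        mod = moderate_variances(fit)
        c = default_contrasts()[0]
        neg = ContrastSpec("neg", tuple(-x for x in c.coefficients))
        a = contrast_test(mod, fit, c)
        b = contrast_test(mod, fit, neg)
        np.testing.assert_allclose(a["t"], -b["t"])
        np.testing.assert_allclose(a["p"], b["p"])

    def test_unmoderated_t_matches_classical_oracle(self, rng):
        # d0 = 0 must reduce exactly to the ordinary least-squares t-test
        for _ in range(20):
            matrix = make_matrix(rng.normal(size=(5, 18)))
            fit = fit_cell_means(matrix)
            mod = moderate_variances(fit, d0_override=0.0)
            contrast = default_contrasts()[0]
            table = contrast_test(mod, fit, contrast)
            groups = matrix.group_labels()
            for feat in matrix.feature_ids:
                y = matrix.values.loc[feat]
                ki = y[groups == "KI.SED"]
                wt = y[groups == "WT.SED"]
                # classical t from the 6-cell linear model: pooled residual
                # variance over all cells, contrast of two cell means
                resid = y - y.groupby(groups).transform("mean")
                s2 = (resid**2).sum() / (18 - 6)
                se = np.sqrt(s2 * (1 / 3 + 1 / 3))
                t_oracle = (ki.mean() - wt.mean()) / se
                t_pkg = table.set_index("feature").loc[feat, "t"]
                assert abs(t_pkg - t_oracle) < 1e-10


class TestBH:
    def test_classic_example(self):
        table = pd.DataFrame({
            "p": [0.01, 0.02, 0.03],
            "family": ["other"] * 3,
        })
        out = adjust_bh_grouped(table)
        np.testing.assert_allclose(out["adj_p"], [0.03, 0.03, 0.03])

    def test_matches_bruteforce_definition(self, rng):
        for _ in range(100):
            m = int(rng.integers(3, 40))
            p = rng.uniform(size=m)
            table = pd.DataFrame({"p": p, "family": ["f"] * m})
            out = adjust_bh_grouped(table)["adj_p"].to_numpy()
            # brute force: adj_i = min_{j: p_j >= p_i} m * p_j / rank_j, capped
            order = np.argsort(p)
            expected = np.empty(m)
            running = np.inf
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, m * p[i] / rank)
                expected[i] = min(running, 1.0)
            np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_families_adjusted_separately(self):
        table = pd.DataFrame({
            "p": [0.04, 0.5, 0.04, 0.5],
            "family": ["exercise_vs_sed", "exercise_vs_sed", "other", "other"],
        })
        out = adjust_bh_grouped(table)
        fam_a = out[out.family == "exercise_vs_sed"]["adj_p"].to_numpy()
        fam_b = out[out.family == "other"]["adj_p"].to_numpy()
        np.testing.assert_allclose(fam_a, fam_b)

    def test_missing_family_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh_grouped(pd.DataFrame({"p": [0.1]}))


class TestEndToEnd:
    def test_moderated_detection_beats_classical(self):
        exp = simulate_omics_experiment(_planted_config(seed=21))
        matrix = exp.matrices["M"]
        truth = exp.truth.set_index("feature")
        planted = set(truth.index[~truth["is_null"]])

        fit = fit_cell_means(matrix)
        contrast = default_contrasts()[0]

        def detections(mod):
            table = contrast_test(mod, fit, contrast)
            table = adjust_bh_grouped(table)
            hits = table[(table["adj_p"] < 0.05)]["feature"]
            return len(set(hits) & planted)

        moderated = detections(moderate_variances(fit, robust=False))
        classical = detections(moderate_variances(fit, d0_override=0.0))
        assert moderated >= classical
        assert moderated > 0

    def test_run_differential_schema(self, small_matrix):
        table = run_differential(small_matrix)
        assert set(table.columns) == {
            "feature", "contrast", "logFC", "t", "df", "p", "adj_p", "family"
        }
        assert (table["adj_p"] >= table["p"] - 1e-15).all()
        assert table["contrast"].nunique() == 6


def _planted_config(seed):
    effects = {(f"F{i:04d}", "KI", "SED"): 1.0 for i in range(100)}
    return SimConfig(n_features=2000, effect_table=effects, seed=seed)
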