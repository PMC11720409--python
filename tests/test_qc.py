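"""PCA structure checks, outlier screening and the two CV formulas."""

import numpy as np
import pandas as pd
import pytest

import crossprot as cp
from crossprot.core import ExpressionMatrix, PlateMap, Platform, Scale


def _zmatrix(arr, platform=Platform.SOMA_A):
    arr = np.asarray(arr, dtype=float)
    df = pd.DataFrame(arr, index=[f"r{i}" for i in range(arr.shape[0])],
                      columns=[f"s{j}" for j in range(arr.shape[1])])
    return ExpressionMatrix(df, Scale.ZSCORED, platform)


def _plate_map(entries):
    return PlateMap(pd.DataFrame(entries,
                                 columns=["sample_id", "plate_id", "role"]))


class TestPCA:
    def test_rank_one_data_single_component(self):
        base = np.array([1.0, -0.5, 2.0, 0.25])
        m = _zmatrix(np.vstack([base, 2 * base, -base]))
        res = cp.run_pca(m)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)
        assert cp.pcs_for_variance(res) == 1

    def test_reconstruction_and_cumulative(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((15, 40))
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1,
                                                        keepdims=True)
        m = _zmatrix(X)
        res = cp.run_pca(m)
        frac = res.explained_variance_fraction
        assert (frac >= 0).all() and frac.sum() <= 1 + 1e-9
        assert (np.diff(res.cumulative_fraction) >= -1e-12).all()
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        centered = X.T - X.T.mean(axis=0, keepdims=True)
        assert np.allclose(recon, centered, atol=1e-8)

    def test_isotropic_data_flat_spectrum(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 500))
        m = _zmatrix((X - X.mean(axis=1, keepdims=True))
                     / X.std(axis=1, ddof=1, keepdims=True))
        frac = cp.run_pca(m).explained_variance_fraction
        assert frac.max() < 3 * frac.mean()

    @pytest.mark.parametrize("fractions, target, expected", [
        ((0.5, 0.3, 0.2), 0.95, 3),
        ((0.96, 0.04), 0.95, 1),
        ((0.6, 0.4), 1.0, 2),
    ])
    def test_pcs_for_variance_arithmetic(self, fractions, target, expected):
        res = cp.PCAResult(
            explained_variance_fraction=np.array(fractions),
            scores=pd.DataFrame(), loadings=pd.DataFrame())
        assert cp.pcs_for_variance(res, target) == expected

    def test_pcs_for_variance_bad_target(self):
        res = cp.PCAResult(np.array([1.0]), pd.DataFrame(), pd.DataFrame())
        with pytest.raises(ValueError):
            cp.pcs_for_variance(res, 0.0)


class TestTopLoadings:
    def test_absolute_ordering(self):
        res = cp.PCAResult(
            explained_variance_fraction=np.array([1.0]),
            scores=pd.DataFrame(),
            loadings=pd.DataFrame({"PC1": [0.9, -0.95, 0.1]},
                                  index=["rA", "rB", "rC"]))
        top = cp.top_loadings(res, 1, k=2)
        assert top["reagent_id"].tolist() == ["rB", "rA"]

    def test_k_zero_and_k_too_large(self):
        res = cp.PCAResult(
            explained_variance_fraction=np.array([1.0]),
            scores=pd.DataFrame(),
            loadings=pd.DataFrame({"PC1": [0.5, 0.4]}, index=["rA", "rB"]))
        assert cp.top_loadings(res, 1, k=0).empty
        assert len(cp.top_loadings(res, 1, k=10)) == 2

    def test_planted_dominant_reagent_recovered(self):
        rng = np.random.default_rng(6)
        X = 0.05 * rng.standard_normal((10, 100))
        X[3] = np.linspace(-3, 3, 100) + 0.01 * rng.standard_normal(100)
        m = _zmatrix(X / np.array([0.05] * 3 + [1.0] + [0.05] * 6)[:, None])
        res = cp.run_pca(m)
        assert cp.top_loadings(res, 1, k=1)["reagent_id"].iloc[0] == "r3"


class TestIQROutliers:
    def test_identical_scores_no_exclusion(self):
        scores = pd.DataFrame({"PC1": [1.0] * 6, "PC2": [2.0] * 6},
                              index=[f"s{i}" for i in range(6)])
        assert cp.iqr_outlier_samples(scores) == []

    def test_extreme_sample_excluded(self):
        scores = pd.DataFrame({"PC1": [0.0, 0.0, 0.0, 0.0, 100.0],
                               "PC2": [0.0] * 5},
                              index=[f"s{i}" for i in range(5)])
        assert cp.iqr_outlier_samples(scores) == ["s4"]

    def test_huge_fold_keeps_everything(self):
        rng = np.random.default_rng(7)
        scores = pd.DataFrame({"PC1": rng.standard_normal(30),
                               "PC2": rng.standard_normal(30)},
                              index=[f"s{i}" for i in range(30)])
        assert cp.iqr_outlier_samples(scores, fold=1e12) == []

    def test_nonpositive_fold_rejected(self):
        scores = pd.DataFrame({"PC1": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            cp.iqr_outlier_samples(scores, fold=0.0)


class TestCV:
    def _linear_matrix(self, rows, samples):
        df = pd.DataFrame(np.asarray(rows, dtype=float),
                          index=[f"r{i}" for i in range(len(rows))],
                          columns=samples)
        return ExpressionMatrix(df, Scale.LINEAR_RFU, Platform.SOMA_B)

    def test_zero_variance_calibrators(self):
        m = self._linear_matrix([[100.0, 100.0, 100.0, 100.0]],
                                ["c1", "c2", "c3", "c4"])
        pm = _plate_map([("c1", "p1", "CALIBRATOR"), ("c2", "p1", "CALIBRATOR"),
                         ("c3", "p2", "CALIBRATOR"), ("c4", "p2", "CALIBRATOR")])
        assert cp.intra_assay_cv(m, pm).iloc[0] == 0.0
        assert cp.inter_assay_cv(m, pm).iloc[0] == 0.0

    def test_linear_hand_computation(self):
        # one plate, calibrators 90/110: sd(n-1) = 14.1421, mean 100
        m = self._linear_matrix([[90.0, 110.0]], ["c1", "c2"])
        pm = _plate_map([("c1", "p1", "CALIBRATOR"), ("c2", "p1", "CALIBRATOR")])
        assert cp.intra_assay_cv(m, pm).iloc[0] == pytest.approx(0.141421,
                                                                 abs=1e-6)

    def test_npx_closed_form(self):
        # sigma_NPX = 1 -> sqrt(exp((ln 2)^2) - 1) ~ 0.7854
        vals = np.array([[-1.5, -0.5, 0.5, 1.5]])
        vals = vals / vals.std(ddof=1)  # unit SD
        df = pd.DataFrame(vals, index=["r0"], columns=list("abcd"))
        m = ExpressionMatrix(df, Scale.NPX_LOG2, Platform.OLINK)
        pm = _plate_map([(s, "p1", "CALIBRATOR") for s in "abcd"])
        expected = np.sqrt(np.exp(np.log(2.0) ** 2) - 1.0)
        assert cp.intra_assay_cv(m, pm).iloc[0] == pytest.approx(expected,
                                                                 abs=1e-9)
        assert expected == pytest.approx(0.7854, abs=5e-4)

    def test_inter_cv_by_construction(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 5, 32)
        vals = 100.0 + 5.0 * (vals - vals.mean()) / vals.std(ddof=1)
        samples = [f"c{i}" for i in range(32)]
        m = self._linear_matrix([vals], samples)
        pm = _plate_map([(s, f"p{i % 16}", "CALIBRATOR")
                         for i, s in enumerate(samples)])
        assert cp.inter_assay_cv(m, pm).iloc[0] == pytest.approx(0.05,
                                                                 abs=1e-9)

    def test_small_plate_skipped_with_warning(self):
        m = self._linear_matrix([[90.0, 110.0, 105.0]], ["c1", "c2", "c3"])
        pm = _plate_map([("c1", "p1", "CALIBRATOR"), ("c2", "p1", "CALIBRATOR"),
                         ("c3", "p2", "CALIBRATOR")])
        # p2 has a single calibrator -> intra uses p1 only
        assert cp.intra_assay_cv(m, pm).iloc[0] == pytest.approx(0.141421,
                                                                 abs=1e-6)

    def test_linear_cv_scale_invariant(self):
        rng = np.random.default_rng(9)
        vals = np.abs(rng.normal(100, 10, (5, 8))) + 1
        samples = [f"c{i}" for i in range(8)]
        pm = _plate_map([(s, f"p{i % 4}", "CALIBRATOR")
                         for i, s in enumerate(samples)])
        m1 = self._linear_matrix(vals, samples)
        m2 = self._linear_matrix(vals * 37.5, samples)
        assert np.allclose(cp.intra_assay_cv(m1, pm), cp.intra_assay_cv(m2, pm))
        assert np.allclose(cp.inter_assay_cv(m1, pm), cp.inter_assay_cv(m2, pm))

    def test_npx_cv_shift_invariant(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(3, 0.3, (5, 8))
        samples = [f"c{i}" for i in range(8)]
        pm = _plate_map([(s, f"p{i % 4}", "CALIBRATOR")
                         for i, s in enumerate(samples)])
        df1 = pd.DataFrame(vals, index=[f"r{i}" for i in range(5)],
                           columns=samples)
        m1 = ExpressionMatrix(df1, Scale.NPX_LOG2, Platform.OLINK)
        m2 = ExpressionMatrix(df1 + 11.0, Scale.NPX_LOG2, Platform.OLINK)
        assert np.allclose(cp.intra_assay_cv(m1, pm), cp.intra_assay_cv(m2, pm))
        assert np.allclose(cp.inter_assay_cv(m1, pm), cp.inter_assay_cv(m2, pm))

    def test_plate_shifts_force_inter_above_intra(self, small_study):
        # generator has tau_inter > sigma_intra: the directional property
        for plat in Platform:
            m = small_study.matrices[plat]
            pm = small_study.plate_maps[plat]
            intra = cp.intra_assay_cv(m, pm)
            inter = cp.inter_assay_cv(m, pm)
            assert inter.median() > intra.median()


class TestCVSummary:
    def test_constant_list(self):
        out = cp.cv_summary([0.07] * 10)
        assert all(v == pytest.approx(0.07)
                   for v in out["percentiles"].values())
        assert out["fraction_below_20pct"] == 1.0

    def test_median_of_even_grid(self):
        out = cp.cv_summary(np.linspace(0.01, 0.99, 99))
        assert out["percentiles"][50] == pytest.approx(0.50, abs=1e-12)

    def test_mannwhitney_reported(self):
        rng = np.random.default_rng(11)
        out = cp.cv_summary(rng.uniform(0, 0.2, 100),
                            rng.uniform(0.1, 0.4, 100))
        assert out["mannwhitney"]["p"] < 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cp.cv_summary([])


class TestPCPhenotypeScreen:
    def test_score_equal_to_age_perfect_correlation(self, small_study):
        pheno = small_study.cohort
        scores = pd.DataFrame(
            {"PC1": pheno.data["age"].to_numpy(dtype=float)},
            index=pheno.sample_ids)
        out = cp.pc_phenotype_screen(scores, pheno, top_k=1)
        row = out[(out["pc"] == "PC1") & (out["variable"] == "age")].iloc[0]
        assert row["estimate"] == pytest.approx(1.0)
        assert row["p"] < 1e-100 and row["stars"] == "***"

    def test_joint_model_recovers_planted_sign(self, small_study):
        pheno = small_study.cohort
        rng = np.random.default_rng(12)
        ptau = pheno.numeric_frame()["csf_ptau"]
        pc = 0.8 * (ptau - ptau.mean()) / ptau.std(ddof=1) \
            + 0.2 * rng.standard_normal(len(ptau))
        scores = pd.DataFrame({"PC1": pc.to_numpy()}, index=pheno.sample_ids)
        out = cp.pc_phenotype_screen(scores, pheno, top_k=1, mode="JOINT")
        row = out[out["variable"] == "csf_ptau"].iloc[0]
        assert row["estimate"] > 0 and row["p"] < 0.001

    def test_null_variable_rarely_strong(self, small_study):
        # independent noise PC at n = 300: |r| below 0.2 in the vast
        # majority of replicates
        pheno = small_study.cohort
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(40):
            scores = pd.DataFrame(
                {"PC1": rng.standard_normal(len(pheno.sample_ids))},
                index=pheno.sample_ids)
            out = cp.pc_phenotype_screen(scores, pheno, top_k=1)
            row = out[out["variable"] == "age"].iloc[0]
            hits += abs(row["estimate"]) < 0.2
        assert hits >= 38
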