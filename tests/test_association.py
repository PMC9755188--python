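"""The four association engines against dense independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from breedscan.association import (
    BreedPanel,
    WlsInputs,
    _gls_scan_fixed_r,
    _reml_loglik,
    assign_binary_phenotype,
    binary_casecontrol_scan,
    breed_average_dosage,
    broadcast_phenotype,
    build_covariates,
    haplotype_em,
    haplotype_scan,
    lmm_scan,
    reml_variance_ratio,
    wls_scan,
)
from breedscan.kinship import RelatednessMatrix, centered_grm
from breedscan.vcf_io import SampleMeta

from conftest import make_gm


def _panel(prev: dict, counts: dict) -> BreedPanel:
    return BreedPanel(pd.DataFrame({"dz": pd.Series(prev)}), pd.Series(counts))


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _dense_reml_loglik(r, K, y, X):
    """Direct dense evaluation of the restricted likelihood at fixed r."""
    n, c = X.shape
    V = r * K + np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    rss = float(y @ P @ y)
    return -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + (n - c) * np.log(rss)
    )


class TestReml:
    def test_fixed_r_matches_dense_objective(self, rng):
        n = 12
        dosages = rng.integers(0, 3, size=(n, 40)).astype(float)
        K = centered_grm(make_gm(dosages))
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        basis = K.eigen()
        yt, Xt = basis.eigenvectors.T @ y, basis.eigenvectors.T @ X
        rs = [1e-3, 0.1, 1.0, 10.0, 1e3]
        fast = [_reml_loglik(r, basis.eigenvalues, yt, Xt)[0] for r in rs]
        dense = [_dense_reml_loglik(r, K.K, y, X) for r in rs]
        # objectives agree up to one additive constant
        diffs = np.array(fast) - np.array(dense)
        assert np.max(np.abs(diffs - diffs[0])) < 1e-8

    def test_zero_k_degenerates_to_ols(self, rng):
        n = 20
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        fit = reml_variance_ratio(y, X, None)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        assert np.allclose(fit.alpha, beta)
        assert fit.variance_ratio == 0.0
        assert fit.sigma_e2 == pytest.approx(resid @ resid / (n - 2))

    def test_null_simulation_ratio_near_zero(self):
        # y carries no genetic effect; K is breed-structured so the variance
        # ratio is well identified and its REML estimate concentrates at zero
        from breedscan.simulate import SimConfig, generate_study

        hits = 0
        reps = 40
        for seed in range(reps):
            cfg = SimConfig(
                n_breeds=15, breed_sizes=[30] * 15, n_snps=500,
                fst_between_clade=0.2, fst_within_clade=0.25,
                seed=seed, n_causal=0, missing_rate=0.0,
            )
            gm, _, _ = generate_study(cfg)
            K = centered_grm(gm)
            y = np.random.default_rng(seed + 1000).normal(size=gm.n_samples)
            fit = reml_variance_ratio(y, np.ones((gm.n_samples, 1)), K)
            hits += fit.variance_ratio < 0.05
        assert hits >= 0.85 * reps


# ---------------------------------------------------------------------------
# LMM scan
# ---------------------------------------------------------------------------

def _dense_gls_oracle(r, K, y, W, x):
    """Explicit (X' V^-1 X)^-1 GLS solve for one SNP."""
    n = len(y)
    V = r * K + np.eye(n)
    Vi = np.linalg.inv(V)
    X = np.column_stack([W, x])
    XtViX = X.T @ Vi @ X
    coef = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ coef
    df = n - W.shape[1] - 1
    sigma2 = float(resid @ Vi @ resid) / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtViX)[-1, -1])
    fstat = (coef[-1] / se) ** 2
    return coef[-1], se, stats.f.sf(fstat, 1, df)


class TestLmmScan:
    def test_fixed_r_matches_dense_gls(self, rng):
        n = 12
        dosages = rng.integers(0, 3, size=(n, 8)).astype(float)
        gm = make_gm(dosages)
        K = centered_grm(gm)
        y = rng.normal(size=n)
        W = np.column_stack([np.ones(n), rng.normal(size=n)])
        basis = K.eigen()
        U, s = basis.eigenvectors, basis.eigenvalues
        beta, se, _, p, _ = _gls_scan_fixed_r(1.0, s, U.T @ y, U.T @ W, U.T @ dosages)
        for j in range(8):
            b0, s0, p0 = _dense_gls_oracle(1.0, K.K, y, W, dosages[:, j])
            assert beta[j] == pytest.approx(b0, abs=1e-8)
            assert se[j] == pytest.approx(s0, abs=1e-8)
            assert p[j] == pytest.approx(p0, abs=1e-8)

    def test_zero_k_equals_ols_scan(self, rng):
        n = 30
        dosages = rng.integers(0, 3, size=(n, 15)).astype(float)
        gm = make_gm(dosages)
        y = rng.normal(size=n)
        W = np.ones((n, 1))
        res_lmm = lmm_scan(gm, y, W, None)
        # OLS oracle per SNP
        for j in range(15):
            X = np.column_stack([W, dosages[:, j]])
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            sigma2 = resid @ resid / (n - 2)
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[-1, -1])
            p = stats.f.sf((coef[-1] / se) ** 2, 1, n - 2)
            assert res_lmm["p"][j] == pytest.approx(p, abs=1e-10)

    def test_collinear_snp_flagged_not_dropped(self, rng):
        n = 20
        dosages = rng.integers(0, 3, size=(n, 3)).astype(float)
        dosages[:, 1] = 1.0  # constant: collinear with intercept
        gm = make_gm(dosages)
        res = lmm_scan(gm, rng.normal(size=n), np.ones((n, 1)), None)
        assert len(res) == 3
        assert res["flags"][1] == "degenerate"
        assert res["p"][1] == 1.0

    def test_per_snp_r_close_to_shared_r_under_null(self, rng):
        n = 40
        dosages = rng.integers(0, 3, size=(n, 6)).astype(float)
        gm = make_gm(dosages)
        K = centered_grm(make_gm(rng.integers(0, 3, size=(n, 100)).astype(float)))
        y = rng.normal(size=n)
        W = np.ones((n, 1))
        fast = lmm_scan(gm, y, W, K, per_snp_r=False)
        full = lmm_scan(gm, y, W, K, per_snp_r=True)
        assert np.allclose(full["beta"], fast["beta"], rtol=0.2, atol=0.05)


class TestBinary:
    def test_partition_and_exclusions(self):
        panel = _panel(
            {"low1": 0.01, "low2": 0.02, "mid": 0.08, "hi1": 0.2, "hi2": 0.3},
            {"low1": 2, "low2": 2, "mid": 2, "hi1": 2, "hi2": 2},
        )
        samples = [SampleMeta(f"s{i}", breed=b) for i, b in enumerate(
            ["low1", "low2", "mid", "hi1", "hi2"]
        )]
        labels, excluded = assign_binary_phenotype(panel, "dz", 0.02, 0.15, samples)
        assert excluded == ["mid"]
        assert labels[0] == 0 and labels[1] == 0  # <= low_cut inclusive
        assert labels[3] == 1 and labels[4] == 1
        assert np.isnan(labels[2])

    def test_bad_cut_order_rejected(self):
        panel = _panel({"a": 0.01, "b": 0.3}, {"a": 1, "b": 1})
        with pytest.raises(ValueError, match="low_cut"):
            assign_binary_phenotype(panel, "dz", 0.2, 0.1, [])

    def test_stringent_subset_of_lenient(self):
        panel = _panel(
            {f"b{i}": p for i, p in enumerate([0.01, 0.03, 0.06, 0.1, 0.2, 0.4])},
            {f"b{i}": 1 for i in range(6)},
        )
        samples = [SampleMeta(f"s{i}", breed=f"b{i}") for i in range(6)]
        strict, _ = assign_binary_phenotype(panel, "dz", 0.02, 0.3, samples)
        lenient, _ = assign_binary_phenotype(panel, "dz", 0.05, 0.15, samples)
        assert set(np.flatnonzero(~np.isnan(strict))) <= set(
            np.flatnonzero(~np.isnan(lenient))
        )

    def test_empty_group_error_names_feasible_cuts(self):
        panel = _panel({"a": 0.10, "b": 0.20}, {"a": 1, "b": 1})
        with pytest.raises(ValueError, match="feasible"):
            assign_binary_phenotype(panel, "dz", 0.01, 0.05, [])

    def test_all_one_class_rejected(self, rng):
        gm = make_gm(rng.integers(0, 3, size=(6, 4)).astype(float))
        with pytest.raises(ValueError, match="cases and controls"):
            binary_casecontrol_scan(gm, np.zeros(6), np.ones((6, 1)), None)

    def test_equals_lmm_on_same_numeric_phenotype(self, rng):
        n = 24
        gm = make_gm(rng.integers(0, 3, size=(n, 10)).astype(float))
        K = centered_grm(make_gm(rng.integers(0, 3, size=(n, 60)).astype(float)))
        labels = (rng.random(n) < 0.5).astype(float)
        labels[0], labels[1] = 0.0, 1.0
        W = np.ones((n, 1))
        res_bin = binary_casecontrol_scan(gm, labels, W, K, per_snp_r=False)
        res_lmm = lmm_scan(gm, labels, W, K, per_snp_r=False)
        assert np.allclose(res_bin["p"], res_lmm["p"], atol=1e-12)

    def test_planted_fixed_variant_is_top_hit(self, rng):
        # dosage 2 in all case breeds, 0 in control breeds
        n_ctrl, n_case = 12, 12
        noise = rng.integers(0, 3, size=(n_ctrl + n_case, 30)).astype(float)
        planted = np.array([0.0] * n_ctrl + [2.0] * n_case)
        gm = make_gm(np.column_stack([noise, planted]))
        labels = np.array([0.0] * n_ctrl + [1.0] * n_case)
        res = binary_casecontrol_scan(gm, labels, np.ones((24, 1)), None)
        assert res["p"].idxmin() == 30


# ---------------------------------------------------------------------------
# Haplotype EM and scan
# ---------------------------------------------------------------------------

class TestHaplotypeEm:
    def test_single_homozygous_haplotype(self):
        block = np.tile([0.0, 2.0, 0.0, 2.0], (10, 1))
        win = haplotype_em(block)
        assert win.converged
        j = win.hap_labels.index("0101")
        assert win.frequencies[j] == pytest.approx(1.0)

    def test_double_heterozygote_symmetric_fixed_point(self):
        block = np.array([[1.0, 1.0, 0.0, 0.0]])
        win = haplotype_em(np.tile(block, (4, 1)))
        f = {lab: freq for lab, freq in zip(win.hap_labels, win.frequencies)}
        # cis (11|00) and trans (10|01) resolutions stay exchangeable
        assert f["1100"] == pytest.approx(f["0000"] + f["1100"] - f["0000"])
        assert f["1000"] == pytest.approx(f["0100"], abs=1e-9)
        assert f["1100"] == pytest.approx(f["0000"], abs=1e-9)

    def test_missing_individuals_excluded(self):
        block = np.array([[0, 0, 0, 0], [np.nan, 0, 0, 0], [2, 2, 2, 2]], float)
        win = haplotype_em(block)
        assert win.n_excluded == 1
        assert win.retained.tolist() == [0, 2]

    def test_all_missing_returns_none(self):
        assert haplotype_em(np.full((3, 4), np.nan)) is None

    def test_expected_dosages_sum_to_two(self, rng):
        block = rng.integers(0, 3, size=(20, 4)).astype(float)
        win = haplotype_em(block)
        assert np.allclose(win.expected_dosages.sum(axis=1), 2.0, atol=1e-6)

    def test_loglik_nondecreasing_over_iterations(self, rng):
        block = rng.integers(0, 3, size=(15, 4)).astype(float)
        logliks = [
            haplotype_em(block, tol=0.0, max_iter=k).loglik for k in range(1, 12)
        ]
        assert np.all(np.diff(logliks) >= -1e-9)


class TestHaplotypeScan:
    def test_window_count_formula(self, rng):
        dosages = rng.integers(0, 3, size=(25, 16)).astype(float)
        chroms = ["chr1"] * 10 + ["chr2"] * 4 + ["chr3"] * 2
        positions = list(range(100, 1100, 100)) + list(range(100, 500, 100)) + [100, 200]
        gm = make_gm(dosages, chroms=chroms, positions=positions)
        y = rng.normal(size=25)
        wins, snps = haplotype_scan(gm, y, np.zeros((25, 0)))
        per_chrom = wins.groupby("chrom").size().to_dict()
        assert per_chrom == {"chr1": 7, "chr2": 1}  # chr3 too short for any window
        assert len(snps) == 16

    def test_monomorphic_window_degenerate(self):
        dosages = np.tile([0.0, 0.0, 0.0, 0.0], (12, 1))
        gm = make_gm(dosages)
        wins, snps = haplotype_scan(gm, np.random.default_rng(0).normal(size=12),
                                    np.zeros((12, 0)))
        assert (wins["flags"] == "degenerate").all()
        assert (snps["p"] == 1.0).all()

    def test_omnibus_f_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 40
        block = rng.integers(0, 3, size=(n, 4)).astype(float)
        extra = rng.integers(0, 3, size=(n, 0)).astype(float)
        gm = make_gm(block)
        covar = rng.normal(size=(n, 2))
        y = rng.normal(size=n) + block[:, 0] * 0.5
        wins, _ = haplotype_scan(gm, y, covar)
        assert len(wins) == 1
        # oracle: two-model F via statsmodels on the same design
        win = haplotype_em(block)
        D = win.expected_dosages
        ref = int(np.argmax(D.sum(axis=0)))
        D = np.delete(D, ref, axis=1)
        X0 = sm.add_constant(covar)
        X1 = np.column_stack([X0, D])
        fit0 = sm.OLS(y, X0).fit()
        fit1 = sm.OLS(y, X1).fit()
        f, p, _ = fit1.compare_f_test(fit0)
        assert wins["stat"][0] == pytest.approx(f, rel=1e-8)
        assert wins["p"][0] == pytest.approx(p, rel=1e-8)


# ---------------------------------------------------------------------------
# Breed averages and WLS
# ---------------------------------------------------------------------------

class TestBreedAverage:
    def test_groupby_mean_oracle(self, rng):
        breeds = ["a"] * 4 + ["b"] * 3 + ["c"] * 5
        dosages = rng.integers(0, 3, size=(12, 20)).astype(float)
        dosages[rng.random(dosages.shape) < 0.1] = np.nan
        gm = make_gm(dosages, breeds=breeds)
        panel = _panel({"a": 0.1, "b": 0.2, "c": 0.3}, {"a": 4, "b": 3, "c": 5})
        inputs = breed_average_dosage(gm, panel)
        df = pd.DataFrame(dosages)
        df["breed"] = breeds
        oracle = df.groupby("breed").mean()
        kept = [int(v.vid[1:]) for v in inputs.variants]
        assert np.allclose(inputs.X, oracle.to_numpy()[:, kept], atol=1e-12)
        assert inputs.weights.sum() == pytest.approx(1.0)

    def test_breed_with_all_missing_snp_dropped(self):
        dosages = np.array([[1, 0], [1, np.nan], [1, np.nan]], dtype=float)
        gm = make_gm(dosages, breeds=["a", "b", "b"])
        panel = _panel({"a": 0.1, "b": 0.2, "c": 0.3}, {"a": 1, "b": 2, "c": 1})
        with pytest.raises(ValueError, match=">= 3 breeds"):
            breed_average_dosage(gm, panel)

    def test_single_breed_value(self):
        dosages = np.array([[0, 0], [1, 1], [2, 0], [1, 2], [1, 0], [1, 1]], float)
        gm = make_gm(dosages, breeds=["a", "a", "a", "b", "b", "c"])
        panel = _panel({"a": 0.1, "b": 0.2, "c": 0.05}, {"a": 3, "b": 2, "c": 1})
        inputs = breed_average_dosage(gm, panel)
        assert inputs.X[0, 0] == pytest.approx(1.0)  # mean of (0,1,2)


def _wls_oracle(X_design, y, w):
    Wm = np.diag(w)
    A = X_design.T @ Wm @ X_design
    coef = np.linalg.solve(A, X_design.T @ Wm @ y)
    resid = y - X_design @ coef
    df = len(y) - X_design.shape[1]
    sigma2 = float(resid @ Wm @ resid) / df
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    t = coef / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return coef[-1], se[-1], p[-1]


def _random_wls_inputs(rng, n_breeds=10, n_snps=6):
    X = rng.uniform(0, 2, size=(n_breeds, n_snps))
    from breedscan.kinship import centered_grm as _cg

    basis = _cg(X).eigen()
    w = rng.integers(1, 30, size=n_breeds).astype(float)
    from breedscan.vcf_io import Variant

    variants = [Variant("chr1", 100 + 10 * j, "A", "G", 30.0, vid=f"v{j}")
                for j in range(n_snps)]
    return WlsInputs(
        breeds=[f"b{i}" for i in range(n_breeds)],
        X=X,
        weights=w / w.sum(),
        pcs=basis,
        variants=variants,
    )


class TestWlsScan:
    def test_matches_weighted_normal_equations_oracle(self, rng):
        for _ in range(20):
            inputs = _random_wls_inputs(rng)
            y = rng.normal(size=10)
            res = wls_scan(inputs, y, n_pcs=1)
            design0 = np.column_stack([np.ones(10), inputs.pcs.top(1)])
            for j in range(6):
                b0, s0, p0 = _wls_oracle(
                    np.column_stack([design0, inputs.X[:, j]]), y, inputs.weights
                )
                assert res["beta"][j] == pytest.approx(b0, abs=1e-10)
                assert res["se"][j] == pytest.approx(s0, abs=1e-10)
                assert res["p"][j] == pytest.approx(p0, abs=1e-10)

    def test_equal_weights_zero_pcs_is_ols(self, rng):
        inputs = _random_wls_inputs(rng)
        inputs.weights = np.full(10, 0.1)
        y = rng.normal(size=10)
        res = wls_scan(inputs, y, n_pcs=0)
        for j in range(6):
            X = np.column_stack([np.ones(10), inputs.X[:, j]])
            coef = np.linalg.lstsq(X, y, rcond=None)[0]
            assert res["beta"][j] == pytest.approx(coef[-1], abs=1e-10)

    def test_weight_scale_invariance(self, rng):
        # weights are proportions: doubling every breed's count changes nothing
        breeds = ["a"] * 2 + ["b"] * 3 + ["c"] * 2 + ["d"] * 3 + ["e"] * 2
        dosages = rng.integers(0, 3, size=(12, 8)).astype(float)
        gm = make_gm(dosages, breeds=breeds)
        prev = {b: p for b, p in zip("abcde", [0.1, 0.2, 0.15, 0.3, 0.05])}
        p1 = _panel(prev, {b: breeds.count(b) for b in "abcde"})
        p2 = _panel(prev, {b: 2 * breeds.count(b) for b in "abcde"})
        i1 = breed_average_dosage(gm, p1)
        r1 = wls_scan(i1, p1.prevalence_of("dz"), n_pcs=1)
        r2 = wls_scan(i1, p2.prevalence_of("dz"), n_pcs=1)
        assert np.allclose(r1["p"], r2["p"], atol=1e-12)

    def test_constant_column_degenerate(self, rng):
        inputs = _random_wls_inputs(rng)
        inputs.X[:, 2] = 1.3
        res = wls_scan(inputs, rng.normal(size=10), n_pcs=1)
        assert res["flags"][2] == "degenerate"
        assert res["p"][2] == 1.0

    def test_too_few_breeds_rejected(self, rng):
        inputs = _random_wls_inputs(rng, n_breeds=6)
        with pytest.raises(ValueError, match="breeds"):
            wls_scan(inputs, rng.normal(size=6), n_pcs=5)


class TestPanelAndBroadcast:
    def test_percent_normalization(self):
        panel = _panel({"a": 10.8, "b": 0.5}, {"a": 3, "b": 2})
        assert panel.prevalence_of("dz")["a"] == pytest.approx(0.108)

    def test_weights_sum_to_one(self):
        panel = _panel({"a": 0.1, "b": 0.2}, {"a": 7, "b": 3})
        assert panel.weights.sum() == pytest.approx(1.0)

    def test_broadcast_assigns_breed_value(self):
        panel = _panel({"a": 0.1, "b": 0.2}, {"a": 1, "b": 2})
        samples = [SampleMeta("s1", "b"), SampleMeta("s2", "a"), SampleMeta("s3", "b")]
        y = broadcast_phenotype(panel, "dz", samples)
        assert y.tolist() == [0.2, 0.1, 0.2]

    def test_unknown_breed_rejected(self):
        panel = _panel({"a": 0.1}, {"a": 1})
        with pytest.raises(KeyError):
            broadcast_phenotype(panel, "dz", [SampleMeta("s1", "zzz")])

    def test_sex_covariate_coding(self):
        samples = [SampleMeta("s1", "a", "female"), SampleMeta("s2", "a", "male"),
                   SampleMeta("s3", "a", "unknown")]
        W = build_covariates(samples)
        assert W[:, 0].tolist() == [1, 1, 1]
        assert W[0, 1] == 0.0 and W[1, 1] == 1.0
        assert W[2, 1] == pytest.approx(0.5)  # unknown -> mean imputed
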