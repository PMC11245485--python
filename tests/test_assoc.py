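import numpy as np
import pytest
from scipy import stats

import stresshub as sh
from stresshub.assoc import (KinshipMLM, fit_null_reml, kinship_matrix,
                             ld_r2, scan_region)


def gls_f_oracle(y, X, g, K, delta):
    """Naive matrix-inversion GLS F-test at a fixed variance ratio."""
    n = len(y)
    V = K + delta * np.eye(n)
    Vi = np.linalg.inv(V)

    def rss(M):
        beta = np.linalg.solve(M.T @ Vi @ M, M.T @ Vi @ y)
        r = y - M @ beta
        return float(r @ Vi @ r)

    rss0 = rss(X)
    rss1 = rss(np.column_stack([X, g]))
    df2 = n - X.shape[1] - 1
    F = (rss0 - rss1) * df2 / rss1
    return float(stats.f.sf(F, 1, df2))


def _structured_panel(seed, n_acc=60, n_var=300):
    cfg = sh.SimConfig(seed=seed, n_accessions=n_acc // 3 + 1, n_variants=n_var)
    panel, _ = sh.simulate_genotypes(cfg)
    return panel.subset_accessions(panel.accession_ids[:n_acc])


class TestKinship:
    def test_duplicate_accessions_identical_relatedness(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=(200, 5)).astype(float)
        d[:, 1] = d[:, 0]
        K = kinship_matrix(d)
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-10)

    def test_unrelated_panel_off_diagonal_near_zero(self):
        # centering on sample frequencies forces mean(off) = -mean(diag)/(n-1),
        # which vanishes as the panel grows
        rng = np.random.default_rng(1)
        n = 100
        d = rng.binomial(2, rng.uniform(0.1, 0.9, size=(2000, 1)),
                         size=(2000, n)).astype(float)
        K = kinship_matrix(d)
        off = K[~np.eye(n, dtype=bool)]
        assert off.mean() == pytest.approx(-np.diag(K).mean() / (n - 1),
                                           abs=1e-3)
        assert abs(off.mean()) < 0.02
        assert np.allclose(np.diag(K), 1.0, atol=0.15)

    def test_symmetric_psd(self):
        panel = _structured_panel(2)
        K = kinship_matrix(panel.dosage_float())
        assert np.max(np.abs(K - K.T)) < 1e-10
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_all_monomorphic_errors(self):
        with pytest.raises(ValueError):
            kinship_matrix(np.zeros((10, 5)))


class TestNullREML:
    def test_identity_kinship_recovers_total_variance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(2.0, 1.5, size=120)
        fit = fit_null_reml(y, np.eye(120))
        total = fit.sigma_g2 + fit.sigma_e2
        assert total == pytest.approx(np.var(y, ddof=1), rel=0.05)

    def test_reml_optimum_beats_grid(self):
        panel = _structured_panel(4)
        K = kinship_matrix(panel.dosage_float())
        rng = np.random.default_rng(4)
        w, U = np.linalg.eigh(K)
        w = np.clip(w, 0, None)
        y = U @ (np.sqrt(0.5 * w) * rng.standard_normal(len(w))) \
            + np.sqrt(0.5) * rng.standard_normal(len(w))
        model = KinshipMLM(y, K)
        fit = model.fit()
        # optimality certificate over a 50-point delta grid
        Q, _ = np.linalg.qr(model.X)
        n, p = model.n, model.p
        for ld in np.linspace(-10, 10, 50):
            d = np.exp(ld)
            R = np.sum(fit.eta ** 2 / (fit.xi + d))
            ll = -0.5 * ((n - p) * np.log(2 * np.pi * R / (n - p)) + (n - p)
                         + np.sum(np.log(fit.xi + d)))
            assert fit.loglik >= ll - 1e-6

    def test_heritability_recovery(self):
        panel = _structured_panel(5, n_acc=90)
        K = kinship_matrix(panel.dosage_float())
        w, U = np.linalg.eigh(K)
        w = np.clip(w, 0, None)
        rng = np.random.default_rng(5)
        h2 = []
        for _ in range(40):
            y = U @ (np.sqrt(0.5 * w) * rng.standard_normal(len(w))) \
                + np.sqrt(0.5) * rng.standard_normal(len(w))
            h2.append(fit_null_reml(y, K).heritability)
        assert np.mean(h2) == pytest.approx(0.5, abs=0.08)

    def test_too_few_accessions_errors(self):
        with pytest.raises(ValueError):
            KinshipMLM(np.ones(5), np.eye(5))


class TestScan:
    def test_identity_kinship_equals_ols_f_test(self):
        rng = np.random.default_rng(6)
        n = 80
        y = rng.normal(size=n)
        G = rng.binomial(2, 0.4, size=(25, n)).astype(float)
        scan = scan_region(y, G, K=np.eye(n), maf_min=0.0)
        for i in range(len(scan)):
            g = G[i]
            X = np.column_stack([np.ones(n), g])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = np.sum((y - X @ beta) ** 2)
            rss0 = np.sum((y - y.mean()) ** 2)
            F = (rss0 - rss1) * (n - 2) / rss1
            p = stats.f.sf(F, 1, n - 2)
            assert scan["pvalue"].iloc[i] == pytest.approx(p, abs=1e-8)

    def test_agrees_with_naive_gls_oracle(self):
        panel = _structured_panel(7, n_acc=45, n_var=200)
        K = kinship_matrix(panel.dosage_float())
        rng = np.random.default_rng(7)
        y = rng.normal(size=45)
        null = fit_null_reml(y, K)
        scan = scan_region(y, panel, K=K, null=null, maf_min=0.05)
        X = np.ones((45, 1))
        d = panel.dosage_float()
        idx = {v: i for i, v in enumerate(panel.variant_ids)}
        checked = 0
        for _, row in scan.head(30).iterrows():
            if row["maf"] == 0:
                continue
            g = d[idx[row["variant_id"]]]
            p = gls_f_oracle(y, X, g, K, null.delta)
            assert row["pvalue"] == pytest.approx(p, abs=1e-8)
            checked += 1
        assert checked >= 10

    def test_location_scale_invariance(self):
        panel = _structured_panel(8, n_acc=48, n_var=150)
        K = kinship_matrix(panel.dosage_float())
        rng = np.random.default_rng(8)
        y = rng.normal(size=48)
        p1 = scan_region(y, panel, K=K)["pvalue"]
        p2 = scan_region(3.7 * y + 11.0, panel, K=K)["pvalue"]
        assert np.allclose(p1, p2, atol=1e-6)

    def test_monomorphic_variant_reported_not_significant(self):
        rng = np.random.default_rng(9)
        n = 40
        G = np.vstack([np.zeros(n), rng.binomial(2, 0.5, n)]).astype(float)
        scan = scan_region(rng.normal(size=n), G, K=np.eye(n), maf_min=0.0)
        row = scan[scan["maf"] == 0].iloc[0]
        assert row["pvalue"] == 1.0 and not row["significant"]

    def test_exact_mode_close_to_fixed_ratio(self):
        panel = _structured_panel(10, n_acc=40, n_var=60)
        K = kinship_matrix(panel.dosage_float())
        rng = np.random.default_rng(10)
        y = rng.normal(size=40)
        approx = scan_region(y, panel, K=K).head(12)
        exact = scan_region(y, panel, K=K, exact=True).head(12)
        la = np.log10(approx["pvalue"])
        le = np.log10(exact["pvalue"])
        # the fixed-ratio approximation tracks exact per-variant REML closely
        assert np.corrcoef(la, le)[0, 1] > 0.98
        assert np.max(np.abs(la - le)) < 1.0


class TestLD:
    def test_duplicate_and_repulsion_give_unit_r2(self):
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.4, 100).astype(float)
        M = ld_r2(np.vstack([g, g, 2 - g])).to_numpy()
        assert M[0, 1] == pytest.approx(1.0)
        assert M[0, 2] == pytest.approx(1.0)

    def test_independent_variants_mean_r2(self):
        n = 500
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            G = rng.binomial(2, 0.3, size=(20, n)).astype(float)
            M = ld_r2(G).to_numpy()
            vals.append(M[np.triu_indices(20, 1)].mean())
        assert np.mean(vals) == pytest.approx(1 / (n - 1), rel=0.2)

    def test_monomorphic_rows_are_missing(self):
        g = np.array([[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 1.0]])
        M = ld_r2(g).to_numpy()
        assert np.isnan(M[0, 1]) and np.isnan(M[0, 0])
        assert M[1, 1] == 1.0

    def test_missing_dropped_pairwise(self):
        rng = np.random.default_rng(12)
        a = rng.binomial(2, 0.5, 50).astype(float)
        b = a.copy()
        b[:5] = np.nan
        M = ld_r2(np.vstack([a, b])).to_numpy()
        assert M[0, 1] == pytest.approx(1.0)
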