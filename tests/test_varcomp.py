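"""REML estimation against brute-force and simulation oracles; BLUP algebra."""

import numpy as np
import pytest

import domcode as dc
from domcode.gblup import build_model_grms
from domcode.varcomp import classify_correlation, compare_effects, extract_effects


def _reml_loglik_grid(y, GA, GD, sigmas):
    """Direct evaluation of the restricted log-likelihood on a batch of
    (s2a, s2d, s2e) triples; independent of the fitting code."""
    n = len(y)
    X = np.ones((n, 1))
    out = np.empty(len(sigmas))
    batch = 4000
    for start in range(0, len(sigmas), batch):
        sig = sigmas[start:start + batch]
        V = (
            sig[:, 0, None, None] * GA
            + sig[:, 1, None, None] * GD
            + sig[:, 2, None, None] * np.eye(n)
        )
        L = np.linalg.cholesky(V)
        logdet = 2 * np.log(np.einsum("bii->bi", L)).sum(axis=1)
        rhs = np.broadcast_to(np.column_stack([y, X[:, 0]]), (len(sig), n, 2))
        sol = np.linalg.solve(V, rhs)
        viy, vix = sol[:, :, 0], sol[:, :, 1]
        xvx = np.einsum("bi,i->b", vix, X[:, 0])
        xvy = np.einsum("bi,i->b", viy, X[:, 0])
        ypy = np.einsum("bi,i->b", viy, y) - xvy**2 / xvx
        out[start:start + batch] = -0.5 * (
            (n - 1) * np.log(2 * np.pi) + logdet + np.log(xvx) + ypy
        )
    return out


def test_reml_matches_brute_force_grid_search():
    """At n = 30 the fitted optimum agrees with an exhaustive grid over the
    (s2a, s2d, s2e) simplex at resolution 0.02 var(y)."""
    cfg = dc.SimConfig(n_individuals=30, n_markers=120, n_qtl=30,
                       h2_a=0.4, h2_d=0.3, seed=17)
    geno = dc.simulate_genotypes(cfg)
    pheno, _ = dc.simulate_phenotypes(geno, cfg)
    y = pheno.iloc[:, 0].to_numpy()
    y = (y - y.mean()) / y.std()  # var(y) = 1, so grid step = 0.02
    GA, GD = build_model_grms(geno, "het")
    vals = np.concatenate([[1e-8], np.arange(0.02, 1.21, 0.02)])  # floor + steps
    grid = np.array(np.meshgrid(vals, vals, vals)).T.reshape(-1, 3)
    ll = _reml_loglik_grid(y, GA.matrix, GD.matrix, grid)
    best = grid[ll.argmax()]
    vc = dc.reml_fit(y, [GA, GD])
    assert vc.loglik >= ll.max() - 1e-6
    np.testing.assert_allclose(vc.sigmas, best, atol=0.02 + 1e-9)


def test_pure_noise_gives_near_zero_heritability():
    """Median additive-heritability estimate on null traits stays < 0.05."""
    cfg = dc.SimConfig(n_individuals=200, n_markers=400, n_qtl=10, seed=1)
    geno = dc.simulate_genotypes(cfg)
    GA, _ = build_model_grms(geno, "het")
    h2 = []
    rng = np.random.default_rng(100)
    for _ in range(20):
        y = rng.standard_normal(cfg.n_individuals)
        h2.append(dc.reml_fit(y, [GA]).h2_a)
    assert np.median(h2) < 0.05


def test_recovery_on_dominance_rich_trait():
    cfg = dc.SimConfig(n_individuals=800, n_markers=1500, n_qtl=100, seed=23)
    geno = dc.simulate_genotypes(cfg)
    pheno, _ = dc.simulate_phenotypes(geno, cfg)
    y = pheno.iloc[:, 0].to_numpy()
    GA, GD = build_model_grms(geno, "het")
    vc = dc.reml_fit(y, [GA, GD])
    assert vc.converged
    assert vc.h2_a == pytest.approx(cfg.h2_a, abs=0.12)
    assert vc.h2_d == pytest.approx(cfg.h2_d, abs=0.12)
    vc_a = dc.reml_fit(y, [GA])
    assert vc.loglik >= vc_a.loglik - 1e-6  # nested models


def test_shift_invariance(small_sim, small_grms):
    _, _, pheno, _ = small_sim
    GA, GD = small_grms
    y = pheno.iloc[:, 0].to_numpy()
    vc1 = dc.reml_fit(y, [GA, GD])
    vc2 = dc.reml_fit(y + 7.5, [GA, GD])
    np.testing.assert_allclose(vc1.sigmas, vc2.sigmas, rtol=1e-5, atol=1e-8)
    assert vc2.mu_hat - vc1.mu_hat == pytest.approx(7.5, abs=1e-6)


def test_heritability_ratios_consistent(small_sim, small_grms):
    _, _, pheno, _ = small_sim
    GA, GD = small_grms
    y = pheno.iloc[:, 0].to_numpy()
    vc = dc.reml_fit(y, [GA, GD])
    tot = vc.sigma2_a + vc.sigma2_d + vc.sigma2_e
    assert vc.h2_a == pytest.approx(vc.sigma2_a / tot, abs=1e-12)
    assert vc.h2_d == pytest.approx(vc.sigma2_d / tot, abs=1e-12)
    assert vc.h2_a + vc.h2_d <= 1.0
    assert vc.se_a > 0 and vc.se_e > 0


def test_blup_residual_reconstruction():
    """y - mu - g_a - g_d equals s2e V^{-1}(y - mu) at the REML optimum."""
    cfg = dc.SimConfig(n_individuals=50, n_markers=200, n_qtl=20, seed=31)
    geno = dc.simulate_genotypes(cfg)
    pheno, _ = dc.simulate_phenotypes(geno, cfg)
    y = pheno.iloc[:, 0].to_numpy()
    GA, GD = build_model_grms(geno, "het")
    vc = dc.reml_fit(y, [GA, GD])
    ev = extract_effects(y, vc, [GA, GD])
    r = y - ev.mu_hat
    V = vc.sigma2_a * GA.matrix + vc.sigma2_d * GD.matrix + vc.sigma2_e * np.eye(len(y))
    e_direct = vc.sigma2_e * np.linalg.solve(V, r)
    np.testing.assert_allclose(y - ev.mu_hat - ev.g_total, e_direct, atol=1e-6)


def test_zero_dominance_variance_shrinks_gd_to_zero():
    cfg = dc.SimConfig(n_individuals=300, n_markers=600, n_qtl=50, h2_d=0.0, seed=41)
    geno = dc.simulate_genotypes(cfg)
    pheno, _ = dc.simulate_phenotypes(geno, cfg)
    y = pheno.iloc[:, 0].to_numpy()
    GA, GD = build_model_grms(geno, "het")
    vc = dc.reml_fit(y, [GA, GD])
    ev = extract_effects(y, vc, [GA, GD])
    if vc.sigma2_d < 1e-4:
        assert np.max(np.abs(ev.g_d)) < 1e-3


def test_total_effects_correlate_across_encodings(small_sim):
    """Total genetic effects from het and orthogonal fits agree strongly on
    dominance-rich data (r > 0.9)."""
    _, geno, pheno, _ = small_sim
    y = pheno.iloc[:, 0].to_numpy()
    fits = {}
    for enc in ("het", "orthogonal"):
        GA, GD = build_model_grms(geno, enc)
        vc = dc.reml_fit(y, [GA, GD])
        fits[enc] = extract_effects(y, vc, [GA, GD])
    comp = compare_effects(fits)
    r = comp["g_total"][0].loc["het", "orthogonal"]
    assert r > 0.9
    assert comp["g_total"][1].loc["het", "orthogonal"] == "high"


def test_orthogonal_h2a_closest_to_additive_only():
    """The dominance-orthogonal encoding perturbs the additive share least
    (median over seeds)."""
    closer = []
    for seed in range(5):
        cfg = dc.SimConfig(n_individuals=400, n_markers=800, n_qtl=80,
                           h2_a=0.3, h2_d=0.25, seed=60 + seed)
        geno = dc.simulate_genotypes(cfg)
        pheno, _ = dc.simulate_phenotypes(geno, cfg)
        y = pheno.iloc[:, 0].to_numpy()
        GA, GD_het = build_model_grms(geno, "het")
        _, GD_ort = build_model_grms(geno, "orthogonal")
        h2_a_only = dc.reml_fit(y, [GA]).h2_a
        gap_het = abs(dc.reml_fit(y, [GA, GD_het]).h2_a - h2_a_only)
        gap_ort = abs(dc.reml_fit(y, [GA, GD_ort]).h2_a - h2_a_only)
        closer.append(gap_ort <= gap_het)
    assert np.median(closer) == 1.0


def test_compare_effects_classification():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(500)
    fits = {
        "a": dc.EffectVectors(g_a=x, g_d=x, mu_hat=0.0),
        "b": dc.EffectVectors(g_a=x.copy(), g_d=-x, mu_hat=0.0),
    }
    comp = compare_effects(fits)
    assert comp["g_a"][0].loc["a", "b"] == pytest.approx(1.0)
    assert comp["g_a"][1].loc["a", "b"] == "high"
    assert comp["g_d"][0].loc["a", "b"] == pytest.approx(-1.0)
    assert comp["g_d"][1].loc["a", "b"] == "low"
    assert classify_correlation(0.95) == "high"
    assert classify_correlation(0.7) == "moderate"
    assert classify_correlation(-0.2) == "low"
    with pytest.raises(ValueError, match="at least two"):
        compare_effects({"a": fits["a"]})
    with pytest.raises(ValueError, match="equal length"):
        compare_effects(
            {"a": fits["a"], "b": dc.EffectVectors(np.zeros(3), np.zeros(3), 0.0)}
        )


def test_reml_input_validation(small_grms):
    GA, GD = small_grms
    with pytest.raises(ValueError, match="zero variance"):
        dc.reml_fit(np.ones(GA.n), [GA])
    with pytest.raises(ValueError, match="one .*or two"):
        dc.reml_fit(np.random.default_rng(0).standard_normal(GA.n), [GA, GD, GA])
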