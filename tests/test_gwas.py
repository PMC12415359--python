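"""Two-step dominance scan: GLS algebra, invariances, planted signals."""

import numpy as np
import pytest

import domcode as dc
from domcode.gblup import build_model_grms
from domcode.gwas import adjust_phenotype, dominance_scan, significance_threshold
from domcode.io_qc import GenotypeData
from domcode.varcomp import EffectVectors, extract_effects


def _geno(g, prefix="m"):
    g = np.asarray(g, dtype=np.int8)
    n, m = g.shape
    return GenotypeData(
        g,
        np.array([f"{prefix}{j}" for j in range(m)]),
        np.array(["1"] * m),
        np.arange(1, m + 1),
        np.array(["A"] * m),
        np.array(["B"] * m),
        np.array([f"s{i}" for i in range(n)]),
    )


def test_adjust_phenotype_examples():
    ev = EffectVectors(g_a=np.array([0.5, 0.5]), g_d=np.zeros(2), mu_hat=0.0)
    np.testing.assert_allclose(adjust_phenotype([1.0, 2.0], ev), [0.5, 1.5])
    ev0 = EffectVectors(g_a=np.zeros(3), g_d=np.zeros(3), mu_hat=0.0)
    y = np.array([1.0, -1.0, 2.0])
    np.testing.assert_array_equal(adjust_phenotype(y, ev0), y)
    with pytest.raises(ValueError, match="length"):
        adjust_phenotype(y, ev)


def test_adjustment_enriches_dominance_signal(small_sim, small_grms):
    _, geno, pheno, truth = small_sim
    GA, GD = small_grms
    y = pheno.iloc[:, 0].to_numpy()
    vc = dc.reml_fit(y, [GA, GD])
    y_new = adjust_phenotype(y, extract_effects(y, vc, [GA, GD]))
    target = truth.g_d + (y - truth.g_a - truth.g_d)  # dominance + residual
    r_before = np.corrcoef(y, target)[0, 1]
    r_after = np.corrcoef(y_new, target)[0, 1]
    assert r_after > r_before


def test_significance_threshold():
    assert significance_threshold(47257) == pytest.approx(1.058e-6, rel=1e-3)
    assert significance_threshold(1) == 0.05
    assert significance_threshold(2000) == pytest.approx(2.5e-5)
    with pytest.raises(ValueError):
        significance_threshold(0)


def test_scan_reduces_to_ols_when_dominance_variance_zero():
    """With the GD influence removed (s2d=0, s2e=1) the GLS scan equals
    per-marker least squares."""
    rng = np.random.default_rng(7)
    g = rng.integers(0, 3, size=(150, 30))
    geno = _geno(g)
    y = rng.standard_normal(150)
    GD = build_model_grms(geno, "het")[1]
    from domcode.varcomp import VarianceComponents

    null_vc = VarianceComponents(
        sigma2_a=0.0, sigma2_d=None, sigma2_e=1.0, se_a=0, se_d=None, se_e=0,
        loglik=0, h2_a=0, h2_d=None, mu_hat=0, converged=True, n_iter=0, model="A",
    )
    res = dominance_scan(y, geno, "het", GD, null_vc=null_vc)
    for _, row in res.table.iloc[:10].iterrows():
        j = int(row["marker_id"][1:])
        x = (g[:, j] == 1).astype(float)
        X = np.column_stack([np.ones(150), x])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0][1]
        assert row["beta"] == pytest.approx(beta_ols, abs=1e-8)
        # known residual variance 1 -> Wald chi2 = b^2 / [ (X'X)^{-1} ]_22
        var_b = np.linalg.inv(X.T @ X)[1, 1]
        assert row["chisq"] == pytest.approx(beta_ols**2 / var_b, abs=1e-8)


def test_allele_flip_invariance():
    """Flipping allele labels (g -> 2-g, p -> 1-p) leaves the het scan
    untouched and preserves |statistic| for additive/orthogonal codings."""
    rng = np.random.default_rng(12)
    g = rng.binomial(2, 0.35, size=(300, 20))
    y = rng.standard_normal(300) + 0.5 * (g[:, 3] == 1)
    geno = _geno(g)
    geno_fl = _geno(2 - g)
    GD = build_model_grms(geno, "het")[1]
    GD_fl = build_model_grms(geno_fl, "het")[1]
    np.testing.assert_allclose(GD.matrix, GD_fl.matrix, atol=1e-10)
    for enc in ("het", "additive", "orthogonal"):
        res = dominance_scan(y, geno, enc, GD)
        res_fl = dominance_scan(y, geno_fl, enc, GD_fl, null_vc=res.null_vc)
        np.testing.assert_allclose(
            res.table["chisq"], res_fl.table["chisq"], rtol=1e-8, atol=1e-10
        )
        np.testing.assert_allclose(
            res.table["pvalue"], res_fl.table["pvalue"], rtol=1e-6, atol=1e-12
        )
        if enc == "het":
            np.testing.assert_allclose(
                res.table["beta"], res_fl.table["beta"], atol=1e-10
            )
        elif enc == "additive":
            np.testing.assert_allclose(
                res.table["beta"], -res_fl.table["beta"], atol=1e-10
            )


def test_monomorphic_marker_skipped():
    rng = np.random.default_rng(3)
    g = rng.integers(0, 3, size=(100, 10))
    g[:, 4] = 2  # monomorphic column
    geno = _geno(g)
    poly = geno.select_markers(np.array([j for j in range(10) if j != 4]))
    GD = build_model_grms(poly, "het")[1]
    y = rng.standard_normal(100)
    res = dominance_scan(y, geno, "het", GD)
    assert "m4" in res.skipped
    assert "m4" not in set(res.table["marker_id"])
    assert len(res.table) == 9


def test_planted_het_qtl_detected():
    """A strong heterozygote effect is found below the Bonferroni line."""
    rng = np.random.default_rng(77)
    n, m = 500, 400
    g = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m))
    het = (g[:, 100] == 1).astype(float)
    beta = np.sqrt(0.10 / het.var())  # QTL explains ~10% of variance
    y = beta * het + rng.standard_normal(n) * np.sqrt(0.9)
    geno = _geno(g)
    GD = build_model_grms(geno, "het")[1]
    res = dominance_scan(y, geno, "het", GD)
    row = res.table.set_index("marker_id").loc["m100"]
    assert row["pvalue"] < significance_threshold(m)
    assert bool(row["significant"])
    assert res.table["pvalue"].between(0, 1, inclusive="right").all()


def test_encodings_find_overlapping_but_distinct_loci():
    """Mixed-degree dominance architecture: the three encodings' significant
    sets share loci without coinciding."""
    rng = np.random.default_rng(55)
    n, m = 600, 300
    g = rng.binomial(2, rng.uniform(0.15, 0.5, m), size=(n, m))
    y = rng.standard_normal(n) * 0.6
    # overdominant loci (pure het effects) and directional-dominance loci
    for j, w in [(10, 0.45), (50, 0.45), (120, 0.45)]:
        x = (g[:, j] == 1).astype(float)
        y += w * (x - x.mean()) / x.std()
    for j, w in [(200, 0.45), (250, 0.45)]:
        x = (g[:, j] >= 1).astype(float)
        y += w * (x - x.mean()) / x.std()
    geno = _geno(g)
    sets = {}
    for enc in ("het", "carrier", "orthogonal"):
        GD = build_model_grms(geno, enc)[1]
        sets[enc] = set(dominance_scan(y, geno, enc, GD).significant_ids)
    assert set.union(*sets.values())  # something is found
    names = list(sets)
    assert any(sets[a] != sets[b] for a in names for b in names if a < b)
    assert any(sets[a] & sets[b] for a in names for b in names if a < b)
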