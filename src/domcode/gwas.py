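"""Two-step dominance GWAS under a dominance-GRM mixed model.

Step 1 removes the fitted additive BLUPs from the phenotype
(y_new = y - g_a), so the scan targets what the additive background cannot
explain.  Step 2 tests each marker's dominance-coded column X_d in

    y_new = 1 mu + X_d b + g_d + e,   g_d ~ N(0, G_D s2d), e ~ N(0, I s2e)

by generalized least squares with the variance components fixed at their
null-model (no-marker) REML estimates — the P3D strategy used by standard
mixed-model GWAS software.  The Wald statistic b^2/se^2 is referred to a
1-df chi-square; the genome-wide threshold defaults to Bonferroni
alpha / n_markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import eigh

from .encodings import encode, get_scheme
from .grm import GRM
from .io_qc import GenotypeData, allele_frequency
from .varcomp import EffectVectors, VarianceComponents, reml_fit

__all__ = [
    "GwasResult",
    "adjust_phenotype",
    "dominance_scan",
    "significance_threshold",
]


def adjust_phenotype(y, effects: EffectVectors) -> np.ndarray:
    """y_new = y - g_a: strip the fitted additive values from the phenotype."""
    y = np.asarray(y, dtype=float).ravel()
    g_a = np.asarray(effects.g_a, dtype=float).ravel()
    if y.shape != g_a.shape:
        raise ValueError("phenotype and additive-effect vectors differ in length")
    return y - g_a


def significance_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """Bonferroni genome-wide threshold alpha / n_markers."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return alpha / n_markers


@dataclass
class GwasResult:
    """Per-marker dominance association results plus scan metadata."""

    table: pd.DataFrame
    encoding: str
    threshold: float
    n: int
    null_vc: VarianceComponents
    skipped: dict = field(default_factory=dict)  # marker_id -> reason

    @property
    def significant_ids(self) -> list:
        t = self.table
        return t.loc[t["significant"], "marker_id"].tolist()


def dominance_scan(
    y_new,
    geno: GenotypeData,
    encoding,
    GD: GRM,
    alpha: float = 0.05,
    threshold: float | None = None,
    null_vc: VarianceComponents | None = None,
    eigen=None,
) -> GwasResult:
    """Mixed-model GLS scan of every marker under a dominance coding.

    ``GD`` is the dominance GRM of the same encoding being scanned.  The
    null variance components are estimated once on ``y_new`` (or supplied
    via ``null_vc``); ``eigen`` may pass a precomputed eigendecomposition of
    ``GD`` to share across many scans.  Monomorphic coded columns are
    skipped with a reason rather than reported.
    """
    scheme = get_scheme(encoding)
    y = np.asarray(y_new, dtype=float).ravel()
    n = y.size
    if geno.n_samples != n:
        raise ValueError("phenotype and genotypes differ in sample count")
    D = GD.matrix if isinstance(GD, GRM) else np.asarray(GD, float)
    if eigen is None:
        s, U = eigh(D)
    else:
        s, U = eigen
    s = np.maximum(s, 0.0)
    if null_vc is None:
        null_vc = reml_fit(y, [GD if isinstance(GD, GRM) else D], eigen=(s, U))
    s2d = null_vc.sigma2_a if null_vc.sigma2_d is None else null_vc.sigma2_d
    s2e = null_vc.sigma2_e
    v = s2d * s + s2e  # eigenvalues of V = s2d G_D + s2e I

    p = allele_frequency(geno)
    g = np.asarray(geno.genotypes)
    poly = (p > 0.0) & (p < 1.0) & (g.min(axis=0) != g.max(axis=0))
    X = np.zeros((n, geno.n_markers))
    if poly.any():
        X[:, poly] = encode(g[:, poly], scheme, p[poly])
    col_var = X.var(axis=0)
    ok = poly & (col_var > 1e-12)
    skipped = {
        str(geno.marker_ids[j]): "monomorphic coded column"
        for j in np.flatnonzero(~ok)
    }

    # rotate into the eigenbasis of V; all GLS pieces become diagonal sums
    yr = U.T @ y
    onr = U.T @ np.ones(n)
    Xr = U.T @ X[:, ok]
    iv = 1.0 / v
    a = float(onr @ (iv * onr))
    d0 = float(onr @ (iv * yr))
    b_ = Xr.T @ (iv * onr)
    c_ = np.einsum("ij,ij->j", Xr, iv[:, None] * Xr)
    e_ = Xr.T @ (iv * yr)
    det = a * c_ - b_**2
    good = det > 1e-12 * max(a, 1.0)
    beta = np.where(good, (a * e_ - b_ * d0) / det, np.nan)
    var_b = np.where(good, a / det, np.nan)
    se = np.sqrt(var_b)
    chisq = beta**2 / var_b
    pval = sps.chi2.sf(chisq, df=1)

    scan_idx = np.flatnonzero(ok)
    for j_local in np.flatnonzero(~good):
        mid = str(geno.marker_ids[scan_idx[j_local]])
        skipped[mid] = "collinear with the intercept"
    keep = good
    m_total = geno.n_markers
    if threshold is None:
        threshold = significance_threshold(m_total, alpha)
    idx = scan_idx[keep]
    table = pd.DataFrame(
        {
            "marker_id": geno.marker_ids[idx],
            "chrom": geno.chrom[idx],
            "bp": geno.bp[idx],
            "freq": p[idx],
            "beta": beta[keep],
            "se": se[keep],
            "chisq": chisq[keep],
            "pvalue": pval[keep],
        }
    )
    table["significant"] = table["pvalue"] < threshold
    return GwasResult(
        table=table,
        encoding=scheme.name,
        threshold=float(threshold),
        n=n,
        null_vc=null_vc,
        skipped=skipped,
    )
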