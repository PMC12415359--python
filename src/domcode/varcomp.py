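"""REML variance components and BLUP genetic effects for GBLUP models.

Fits the linear mixed models

    y = mu + g_a + e                 (additive-only)
    y = mu + g_a + g_d + e           (additive + dominance)

with g_a ~ N(0, G_A sigma2_a), g_d ~ N(0, G_D sigma2_d), e ~ N(0, I sigma2_e)
by restricted maximum likelihood.  Updates are average-information (AI) steps
with step-halving and an expectation-maximization fallback, which keeps every
step inside the parameter space and never decreases the restricted
likelihood in practice.  Single-GRM models are solved in the GRM's
eigenbasis, where every quantity is O(n) per iteration; two-GRM models use
dense Cholesky algebra.  Standard errors come from the inverse AI matrix at
the optimum.

Heritabilities are variance-share ratios: h2_a = s2a/(s2a+s2e) for the
additive-only model and h2_a = s2a/(s2a+s2d+s2e), h2_d = s2d/(s2a+s2d+s2e)
for the additive-dominance model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

from .grm import GRM

__all__ = [
    "VarianceComponents",
    "EffectVectors",
    "reml_fit",
    "extract_effects",
    "compare_effects",
    "classify_correlation",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_d: float | None
    sigma2_e: float
    se_a: float
    se_d: float | None
    se_e: float
    loglik: float
    h2_a: float
    h2_d: float | None
    mu_hat: float
    converged: bool
    n_iter: int
    model: str  # "A" or "AD"
    encoding: str = ""

    @property
    def sigmas(self) -> np.ndarray:
        if self.sigma2_d is None:
            return np.array([self.sigma2_a, self.sigma2_e])
        return np.array([self.sigma2_a, self.sigma2_d, self.sigma2_e])


@dataclass
class EffectVectors:
    """BLUPs of the individual genetic effects at the REML estimates."""

    g_a: np.ndarray
    g_d: np.ndarray
    mu_hat: float

    @property
    def g_total(self) -> np.ndarray:
        return self.g_a + self.g_d


def _as_matrix(K):
    return K.matrix if isinstance(K, GRM) else np.asarray(K, dtype=float)


def _encoding_of(grms) -> str:
    tags = [K.encoding for K in grms if isinstance(K, GRM)]
    return tags[-1] if tags else ""


# ---------------------------------------------------------------------------
# generic AI-REML driver


def _ai_reml(stats, sig0, floor, max_iter, tol):
    """Maximize the restricted likelihood over variance components.

    ``stats(sig)`` returns a dict with keys ll, trPK, yPKPy, AI, mu for the
    component vector ``sig`` (genetic components first, residual last).
    """
    sig = np.maximum(np.asarray(sig0, float), floor)
    st = stats(sig)
    n_eval = 1
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if it == 1:
            delta = sig**2 * (st["yPKPy"] - st["trPK"]) / st["n"]  # EM warm-up
        else:
            score = 0.5 * (st["yPKPy"] - st["trPK"])
            AI = st["AI"]
            # active-set AI step: components pushed below the floor are
            # clamped there and dropped from the Newton system
            free = np.ones(sig.size, dtype=bool)
            fixed_delta = np.zeros_like(sig)
            delta = np.zeros_like(sig)
            for _ in range(sig.size):
                idx = np.flatnonzero(free)
                if idx.size == 0:
                    delta = fixed_delta
                    break
                try:
                    step = np.linalg.solve(AI[np.ix_(idx, idx)], score[idx])
                except np.linalg.LinAlgError:
                    step = np.linalg.lstsq(AI[np.ix_(idx, idx)], score[idx],
                                           rcond=None)[0]
                delta = fixed_delta.copy()
                delta[idx] = step
                pinned = (sig + delta < floor) & free & (score < 0.0)
                if not pinned.any():
                    break
                fixed_delta[pinned] = floor - sig[pinned]
                free &= ~pinned
        accepted = False
        for half in range(16):
            cand = np.maximum(sig + delta / (2.0**half), floor)
            st_new = stats(cand)
            n_eval += 1
            if st_new["ll"] >= st["ll"] - 1e-10:
                accepted = True
                break
        if not accepted:  # guaranteed-ascent EM step
            cand = np.maximum(
                sig + sig**2 * (st["yPKPy"] - st["trPK"]) / st["n"], floor
            )
            st_new = stats(cand)
            n_eval += 1
        dll = st_new["ll"] - st["ll"]
        sig, st = cand, st_new
        if abs(dll) < tol and it > 1:
            converged = True
            break
    return sig, st, it, converged


def _se_from_ai(AI):
    try:
        cov = np.linalg.inv(AI)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(AI.shape[0], np.nan)
    return se


# ---------------------------------------------------------------------------
# single-GRM model in the eigenbasis


def _stats_eigen(yr, xr, s, n):
    def stats(sig):
        sg, se_ = sig
        v = sg * s + se_
        w = xr / v
        xvx = float(xr @ w)
        uy = float(w @ yr)
        Py = yr / v - w * (uy / xvx)
        ypy = float(yr @ Py)
        ll = -0.5 * ((n - 1) * _LOG2PI + np.log(v).sum() + np.log(xvx) + ypy)
        Ks = (s, np.ones_like(s))
        trPK = np.empty(2)
        yPKPy = np.empty(2)
        KPy = []
        for k, kdiag in enumerate(Ks):
            trPK[k] = float((kdiag / v).sum() - (w * kdiag) @ w / xvx)
            t = kdiag * Py
            KPy.append(t)
            yPKPy[k] = float(Py @ t)
        AI = np.empty((2, 2))
        for k in range(2):
            Pt = KPy[k] / v - w * float(w @ KPy[k]) / xvx
            for l in range(2):
                AI[k, l] = 0.5 * float(KPy[l] @ Pt)
        AI = (AI + AI.T) / 2.0
        return {
            "ll": ll, "trPK": trPK, "yPKPy": yPKPy, "AI": AI,
            "mu": uy / xvx, "n": n,
        }

    return stats


# ---------------------------------------------------------------------------
# dense multi-GRM model


def _stats_dense(y, X, Ks, n):
    def stats(sig):
        V = sig[-1] * np.eye(n)
        for s2, K in zip(sig[:-1], Ks):
            V += s2 * K
        c, low = cho_factor(V, lower=True)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        Vinv = cho_solve((c, low), np.eye(n))
        w = Vinv @ X[:, 0]
        xvx = float(X[:, 0] @ w)
        P = Vinv - np.outer(w, w) / xvx
        Py = P @ y
        ypy = float(y @ Py)
        ll = -0.5 * ((n - 1) * _LOG2PI + logdet + np.log(xvx) + ypy)
        all_K = list(Ks) + [None]  # None stands for the identity
        k_n = len(all_K)
        trPK = np.empty(k_n)
        yPKPy = np.empty(k_n)
        KPy = []
        for k, K in enumerate(all_K):
            if K is None:
                trPK[k] = float(np.trace(P))
                t = Py
            else:
                trPK[k] = float(np.sum(P * K))
                t = K @ Py
            KPy.append(t)
            yPKPy[k] = float(Py @ t)
        AI = np.empty((k_n, k_n))
        PKPy = [P @ t for t in KPy]
        for k in range(k_n):
            for l in range(k, k_n):
                AI[k, l] = AI[l, k] = 0.5 * float(KPy[k] @ PKPy[l])
        return {
            "ll": ll, "trPK": trPK, "yPKPy": yPKPy, "AI": AI,
            "mu": float(w @ y) / xvx, "n": n,
        }

    return stats


def reml_fit(
    y,
    grms,
    max_iter: int = 200,
    tol: float = 1e-8,
    eigen=None,
) -> VarianceComponents:
    """REML fit of the additive-only (one GRM) or additive+dominance
    (two GRMs, additive first) model with an intercept-only fixed part.

    ``eigen=(values, vectors)`` may supply a precomputed eigendecomposition
    for the single-GRM path (useful when refitting many phenotypes against
    one GRM).  Non-convergence after ``max_iter`` is flagged, not raised.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if isinstance(grms, (GRM, np.ndarray)):
        grms = [grms]
    grms = list(grms)
    if len(grms) not in (1, 2):
        raise ValueError("supply one (additive) or two (additive, dominance) GRMs")
    Ks = [_as_matrix(K) for K in grms]
    for K in Ks:
        if K.shape != (n, n):
            raise ValueError("GRM dimensions must match the phenotype length")
    vary = float(y.var())
    if vary <= 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-8 * vary
    n_gen = len(Ks)
    sig0 = np.array([0.5 * vary / n_gen] * n_gen + [0.5 * vary])

    if n_gen == 1:
        if eigen is None:
            s, U = eigh(Ks[0])
        else:
            s, U = eigen
        smin = s.min()
        if smin < -1e-8 * max(1.0, abs(s.max())):
            raise ValueError("GRM is not positive semi-definite within tolerance")
        s = np.maximum(s, 0.0)
        yr = U.T @ y
        xr = U.T @ np.ones(n)
        stats = _stats_eigen(yr, xr, s, n)
    else:
        for K in Ks:
            ev_min = float(np.linalg.eigvalsh(K)[0])
            if ev_min < -1e-6 * max(1.0, float(np.abs(K).max())):
                raise ValueError("GRM is not positive semi-definite within tolerance")
        stats = _stats_dense(y, np.ones((n, 1)), Ks, n)

    sig, st, n_iter, converged = _ai_reml(stats, sig0, floor, max_iter, tol)
    if not converged:
        warnings.warn("REML did not converge within max_iter", RuntimeWarning)
    se = _se_from_ai(st["AI"])
    tot = sig.sum()
    if n_gen == 1:
        return VarianceComponents(
            sigma2_a=float(sig[0]), sigma2_d=None, sigma2_e=float(sig[1]),
            se_a=float(se[0]), se_d=None, se_e=float(se[1]),
            loglik=float(st["ll"]),
            h2_a=float(sig[0] / tot), h2_d=None,
            mu_hat=float(st["mu"]), converged=converged, n_iter=n_iter,
            model="A", encoding=_encoding_of(grms),
        )
    return VarianceComponents(
        sigma2_a=float(sig[0]), sigma2_d=float(sig[1]), sigma2_e=float(sig[2]),
        se_a=float(se[0]), se_d=float(se[1]), se_e=float(se[2]),
        loglik=float(st["ll"]),
        h2_a=float(sig[0] / tot), h2_d=float(sig[1] / tot),
        mu_hat=float(st["mu"]), converged=converged, n_iter=n_iter,
        model="AD", encoding=_encoding_of(grms),
    )


def extract_effects(y, vc: VarianceComponents, grms) -> EffectVectors:
    """BLUPs g_k = sigma2_k K_k V^{-1} (y - mu) at the REML estimates."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if isinstance(grms, (GRM, np.ndarray)):
        grms = [grms]
    Ks = [_as_matrix(K) for K in grms]
    sig = vc.sigmas
    if len(Ks) != len(sig) - 1:
        raise ValueError("number of GRMs does not match the fitted model")
    V = sig[-1] * np.eye(n)
    for s2, K in zip(sig[:-1], Ks):
        V += s2 * K
    try:
        c = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        c = cho_factor(V + 1e-8 * np.trace(V) / n * np.eye(n), lower=True)
    Vinv1 = cho_solve(c, np.ones(n))
    mu = float(Vinv1 @ y) / float(Vinv1.sum())
    r = y - mu
    Vir = cho_solve(c, r)
    g = [s2 * (K @ Vir) for s2, K in zip(sig[:-1], Ks)]
    g_a = g[0]
    g_d = g[1] if len(g) > 1 else np.zeros(n)
    return EffectVectors(g_a=g_a, g_d=g_d, mu_hat=mu)


def classify_correlation(r: float) -> str:
    """High (0.9-1), moderate (0.5-0.9), low (<0.5, negatives included)."""
    if r >= 0.9:
        return "high"
    if r >= 0.5:
        return "moderate"
    return "low"


def compare_effects(fits: dict) -> dict:
    """Pearson correlations of g_a, g_d, and g_a+g_d across encodings.

    ``fits`` maps encoding name -> EffectVectors on the same individuals.
    Returns ``{"g_a": (corr df, class df), ...}``.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    names = list(fits)
    n = len(next(iter(fits.values())).g_a)
    for ev in fits.values():
        if len(ev.g_a) != n or len(ev.g_d) != n:
            raise ValueError("effect vectors must have equal length")
    out = {}
    for key, get in (
        ("g_a", lambda e: e.g_a),
        ("g_d", lambda e: e.g_d),
        ("g_total", lambda e: e.g_total),
    ):
        vecs = np.column_stack([get(fits[k]) for k in names])
        sd = vecs.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(vecs, rowvar=False)
        C = np.where(np.outer(sd > 0, sd > 0), C, np.nan)
        np.fill_diagonal(C, 1.0)
        corr = pd.DataFrame(C, index=names, columns=names)
        cls = corr.map(
            lambda r: classify_correlation(r) if np.isfinite(r) else "undefined"
        )
        out[key] = (corr, cls)
    return out
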