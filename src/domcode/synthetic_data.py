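"""Synthetic HWE genotypes and additive+dominance phenotypes.

The generator emulates the structure of a dense livestock SNP panel: n
individuals genotyped at m independent biallelic markers, each marker's
B-allele frequency drawn uniformly from a MAF window and genotypes sampled
Binomial(2, p) under Hardy-Weinberg equilibrium (no linkage disequilibrium,
no pedigree structure).  Phenotypes follow the additive-dominance mixed
model y = mu + g_a + g_d + e: a random subset of markers act as QTLs with
independent standard-normal additive effects a_i (on the allele count) and
heterozygote effects d_i (on the 0/1/0 indicator), and the three variance
shares are rescaled so that in-sample var(g_a)/var(y) and var(g_d)/var(y)
hit the target heritabilities exactly.  The residual is orthogonalized
against g_a and g_d in-sample, and its variance absorbs the (small) sample
covariance between the additive and dominance parts, so var(y) = 1 by
construction before the mean is added.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import GenotypeData, write_phenotypes, write_plink

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_phenotypes",
           "simulate_traits", "write_simulation"]


@dataclass
class SimConfig:
    """Study-scale defaults: n=1000 individuals, m=2000 markers, MAF in
    [0.05, 0.5], 100 QTLs, additive/dominance heritabilities 0.3/0.2."""

    n_individuals: int = 1000
    n_markers: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_qtl: int = 100
    h2_a: float = 0.3
    h2_d: float = 0.2
    mu: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_markers < 1:
            raise ValueError("n_individuals and n_markers must be positive")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if not (0 < self.n_qtl <= self.n_markers):
            raise ValueError("n_qtl must lie in [1, n_markers]")
        if not (0.0 <= self.h2_a < 1.0 and 0.0 <= self.h2_d < 1.0):
            raise ValueError("heritabilities must lie in [0, 1)")
        if self.h2_a + self.h2_d >= 1.0:
            raise ValueError("h2_a + h2_d must be < 1")


@dataclass
class SimTruth:
    """Ground truth of one simulated trait (for recovery tests)."""

    qtl_indices: np.ndarray
    a: np.ndarray  # additive effect per QTL, post-rescaling
    d: np.ndarray  # heterozygote effect per QTL, post-rescaling
    g_a: np.ndarray
    g_d: np.ndarray
    h2_a_realized: float
    h2_d_realized: float

    def effects_table(self, marker_ids) -> pd.DataFrame:
        """Per-marker (a, d) with zeros off the QTL set."""
        m = len(marker_ids)
        a = np.zeros(m)
        d = np.zeros(m)
        a[self.qtl_indices] = self.a
        d[self.qtl_indices] = self.d
        return pd.DataFrame({"marker_id": marker_ids, "a": a, "d": d})


def simulate_genotypes(config: SimConfig) -> GenotypeData:
    """Independent HWE genotypes; p ~ Uniform(maf_low, maf_high) per marker.

    Columns that come out monomorphic in-sample (possible at small n) are
    redrawn at the same frequency so every marker is usable downstream;
    still deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_markers
    p = rng.uniform(config.maf_low, config.maf_high, size=m)
    g = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    if n > 1:
        for _ in range(100):
            mono = np.flatnonzero(g.min(axis=0) == g.max(axis=0))
            if mono.size == 0:
                break
            g[:, mono] = rng.binomial(2, p[mono], size=(n, mono.size)).astype(np.int8)
    return GenotypeData(
        g,
        np.array([f"M{j + 1:06d}" for j in range(m)]),
        np.array(["1"] * m),
        np.arange(1, m + 1, dtype=np.int64) * 1000,
        np.array(["A"] * m),
        np.array(["B"] * m),
        np.array([f"S{i + 1:05d}" for i in range(n)]),
    )


def _trait_rng(config: SimConfig, trait: str):
    # stable per-trait stream: crc32 keeps it reproducible across sessions
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(trait.encode())])
    )


def simulate_phenotypes(
    geno: GenotypeData, config: SimConfig, trait: str = "trait"
):
    """One trait under y = mu + g_a + g_d + e with exact in-sample shares.

    Returns ``(PhenotypeTable, SimTruth)`` where the table is a one-column
    DataFrame indexed by sample ID.  Truth is parameterized on the raw
    allele count (additive) and the 0/1/0 heterozygote indicator
    (dominance).
    """
    rng = _trait_rng(config, trait)
    g = np.asarray(geno.genotypes, dtype=float)
    n = g.shape[0]
    qtl = np.sort(rng.choice(geno.n_markers, size=config.n_qtl, replace=False))
    za = g[:, qtl]
    zd = (g[:, qtl] == 1).astype(float)
    a = rng.standard_normal(config.n_qtl)
    d = rng.standard_normal(config.n_qtl)
    e0 = rng.standard_normal(n)

    def _scaled(z, eff, h2):
        if h2 == 0.0:
            return np.zeros(n), np.zeros(config.n_qtl)
        raw = z @ eff
        v = raw.var()
        if v <= 0.0:
            raise ValueError("degenerate genetic variance; increase n or n_qtl")
        s = np.sqrt(h2 / v)
        return raw * s, eff * s

    ga, a = _scaled(za, a, config.h2_a)
    gd, d = _scaled(zd, d, config.h2_d)
    cov_ad = float(np.mean(ga * gd) - ga.mean() * gd.mean())
    s2e = 1.0 - config.h2_a - config.h2_d - 2.0 * cov_ad
    if s2e <= 0.0:
        raise ValueError(
            "additive-dominance sample covariance leaves no residual variance; "
            "lower the heritability targets"
        )
    # orthogonalize the residual against [1, g_a, g_d] in-sample, then scale
    X = np.column_stack([np.ones(n), ga, gd])
    e = e0 - X @ np.linalg.lstsq(X, e0, rcond=None)[0]
    ve = e.var()
    if ve <= 0.0:
        raise ValueError("degenerate residual; need n larger than 3")
    e *= np.sqrt(s2e / ve)
    y = config.mu + ga + gd + e
    vy = y.var()
    truth = SimTruth(qtl, a, d, ga, gd, float(ga.var() / vy), float(gd.var() / vy))
    table = pd.DataFrame({trait: y}, index=pd.Index(geno.sample_ids, name="IID"))
    return table, truth


def simulate_traits(geno: GenotypeData, config: SimConfig, traits):
    """Several traits on the same genotypes, independent effect/noise draws."""
    tables, truths = [], {}
    for t in traits:
        tab, tr = simulate_phenotypes(geno, config, trait=t)
        tables.append(tab)
        truths[t] = tr
    return pd.concat(tables, axis=1), truths


def write_simulation(config: SimConfig, prefix, traits=("trait",)):
    """Simulate and write bed/bim/fam + phenotype TSV + per-trait truth TSV."""
    geno = simulate_genotypes(config)
    pheno, truths = simulate_traits(geno, config, traits)
    write_plink(geno, prefix)
    write_phenotypes(pheno, f"{prefix}.pheno.tsv")
    for t, tr in truths.items():
        tr.effects_table(geno.marker_ids).to_csv(
            f"{prefix}.{t}.truth.tsv", sep="\t", index=False
        )
    return geno, pheno, truths
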