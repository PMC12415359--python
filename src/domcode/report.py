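"""Orchestrate the full encoding-comparison study on one dataset.

For each trait, fits the additive-only model and the additive+dominance
model under every requested dominance encoding, then tabulates:

* heritabilities and restricted log-likelihoods (model-fit table),
* Pearson correlations of g_a / g_d / g_a+g_d across encodings, with
  high / moderate / low classes,
* repeated k-fold cross-validation accuracies per model,
* dominance GWAS scans per encoding with shared/unique significant-locus
  overlap counts,
* the analytic power table over allele frequencies.

Everything is written as plain TSV plus a JSON manifest holding the
configuration, seeds, and package versions, so the bundle is reproducible
from the manifest alone.  A failure in one stage is recorded in the
manifest and does not abort the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .encodings import get_scheme
from .gblup import build_model_grms, cross_validate
from .gwas import adjust_phenotype, dominance_scan
from .io_qc import GenotypeData, read_phenotypes, read_plink
from .power import PowerSpec, power_curve
from .varcomp import compare_effects, extract_effects, reml_fit

__all__ = ["StudyConfig", "run_study"]


@dataclass
class StudyConfig:
    bfile: str = ""
    pheno: str = ""
    traits: tuple = ()
    encodings: tuple = ("het", "carrier", "orthogonal")
    models: tuple = ("A", "AD")
    cv_folds: int = 5
    cv_repeats: int = 5
    seed: int = 0
    gwas_alpha: float = 0.05
    power_N: int = 1000
    power_beta: float = 1.0
    power_alpha_n: int = 0  # 0 -> use the dataset's marker count

    def __post_init__(self):
        if not self.encodings:
            raise ValueError("need at least one dominance encoding")


def _config_hash(config: StudyConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_study(config: StudyConfig, outdir, geno: GenotypeData = None, pheno=None) -> dict:
    """Run the comparison study; returns the bundle of in-memory results.

    ``geno``/``pheno`` may be passed directly (bypassing file paths) for
    programmatic use; otherwise they are loaded from ``config.bfile`` and
    ``config.pheno``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    errors = []
    if geno is None:
        geno = read_plink(config.bfile)
    if pheno is None:
        pheno = read_phenotypes(config.pheno)
    traits = list(config.traits) if config.traits else list(pheno.columns)
    pheno = pheno.loc[[s for s in geno.sample_ids if s in pheno.index]]
    if len(pheno) != geno.n_samples:
        raise ValueError("phenotype table does not cover every genotyped individual")

    grms = {}
    GA = None
    for enc in config.encodings:
        GA, GD = build_model_grms(geno, enc)
        grms[get_scheme(enc).name] = GD
    enc_names = list(grms)

    herit_rows, cv_rows, corr_rows, overlap_rows = [], [], [], []
    bundle = {"scans": {}, "fits": {}}
    for trait in traits:
        y = pheno[trait].to_numpy(dtype=float)
        fits = {}
        try:
            vc_a = reml_fit(y, [GA])
            herit_rows.append(
                dict(trait=trait, model="A", encoding="additive",
                     sigma2_a=vc_a.sigma2_a, sigma2_d=np.nan, sigma2_e=vc_a.sigma2_e,
                     se_a=vc_a.se_a, se_d=np.nan, se_e=vc_a.se_e,
                     h2_a=vc_a.h2_a, h2_d=np.nan, loglik=vc_a.loglik,
                     converged=vc_a.converged)
            )
            for enc in enc_names:
                vc = reml_fit(y, [GA, grms[enc]])
                fits[enc] = (vc, extract_effects(y, vc, [GA, grms[enc]]))
                herit_rows.append(
                    dict(trait=trait, model="AD", encoding=enc,
                         sigma2_a=vc.sigma2_a, sigma2_d=vc.sigma2_d,
                         sigma2_e=vc.sigma2_e, se_a=vc.se_a, se_d=vc.se_d,
                         se_e=vc.se_e, h2_a=vc.h2_a, h2_d=vc.h2_d,
                         loglik=vc.loglik, converged=vc.converged)
                )
            bundle["fits"][trait] = fits
        except Exception as exc:  # noqa: BLE001 - stage isolation
            errors.append({"stage": "varcomp", "trait": trait, "error": str(exc)})
            continue

        if len(fits) >= 2:
            comp = compare_effects({k: ev for k, (_, ev) in fits.items()})
            for key, (corr, cls) in comp.items():
                for i, j in combinations(corr.index, 2):
                    corr_rows.append(
                        dict(trait=trait, component=key, enc_i=i, enc_j=j,
                             r=corr.loc[i, j], cls=cls.loc[i, j])
                    )

        try:
            cv = cross_validate(y, (GA, None), model="A",
                                folds=config.cv_folds, repeats=config.cv_repeats,
                                seed=config.seed)
            cv_rows.append(dict(trait=trait, model="A", encoding="additive",
                                mean_r=cv.mean_accuracy))
            for enc in enc_names:
                cv = cross_validate(y, (GA, grms[enc]), model="AD",
                                    folds=config.cv_folds,
                                    repeats=config.cv_repeats, seed=config.seed)
                cv_rows.append(dict(trait=trait, model="AD", encoding=enc,
                                    mean_r=cv.mean_accuracy))
        except Exception as exc:  # noqa: BLE001
            errors.append({"stage": "cv", "trait": trait, "error": str(exc)})

        try:
            sig_sets = {}
            for enc in enc_names:
                vc, ev = fits[enc]
                y_new = adjust_phenotype(y, ev)
                res = dominance_scan(y_new, geno, enc, grms[enc],
                                     alpha=config.gwas_alpha)
                res.table.to_csv(outdir / f"gwas_{trait}_{enc}.tsv",
                                 sep="\t", index=False)
                sig_sets[enc] = set(res.significant_ids)
                bundle["scans"][(trait, enc)] = res
            for i, j in combinations(enc_names, 2):
                overlap_rows.append(
                    dict(trait=trait, enc_i=i, enc_j=j,
                         n_i=len(sig_sets[i]), n_j=len(sig_sets[j]),
                         shared=len(sig_sets[i] & sig_sets[j]))
                )
            overlap_rows.append(
                dict(trait=trait, enc_i="all", enc_j="all",
                     n_i=np.nan, n_j=np.nan,
                     shared=len(set.intersection(*sig_sets.values())))
            )
        except Exception as exc:  # noqa: BLE001
            errors.append({"stage": "gwas", "trait": trait, "error": str(exc)})

    alpha_n = config.power_alpha_n or geno.n_markers
    spec = PowerSpec(alpha=0.05 / alpha_n, N=config.power_N, beta=config.power_beta)
    power_tab = power_curve(spec, enc_names)

    herit = pd.DataFrame(herit_rows)
    corr = pd.DataFrame(corr_rows)
    cv_tab = pd.DataFrame(cv_rows)
    overlap = pd.DataFrame(overlap_rows)
    herit.to_csv(outdir / "heritability.tsv", sep="\t", index=False)
    corr.to_csv(outdir / "effect_correlations.tsv", sep="\t", index=False)
    cv_tab.to_csv(outdir / "cv_accuracy.tsv", sep="\t", index=False)
    overlap.to_csv(outdir / "gwas_overlap.tsv", sep="\t", index=False)
    power_tab.to_csv(outdir / "power.tsv", sep="\t", index=False)

    manifest = {
        "domcode_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "traits": traits,
        "n_samples": geno.n_samples,
        "n_markers": geno.n_markers,
        "errors": errors,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle.update(
        heritability=herit, correlations=corr, cv=cv_tab, overlap=overlap,
        power=power_tab, manifest=manifest,
    )
    return bundle
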