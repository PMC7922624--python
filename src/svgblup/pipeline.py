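"""End-to-end pipeline driver: each stage reads and writes disk artifacts.

Stages (in order): ``simulate`` -> ``svsets`` -> ``grm`` -> ``reml`` ->
``gwas`` -> ``impute_eval`` -> ``predict_cv``. Every stage writes TSV
outputs plus a JSON metadata sidecar (stage, parameters, seed, package
version), and depends only on the files earlier stages wrote, so a deleted
intermediate can be regenerated byte-identically by rerunning its stage
with the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as svio
from .assoc import (
    fdr,
    FDRQuery,
    meta_single_trait,
    mlma_scan,
    multi_trait_chi2,
    significance_thresholds,
    t_correlation,
)
from .cvpredict import CVScheme, run_cv
from .imputeval import make_folds, run_masking_cv, select_svs, threshold_summary, accuracy_by_maf
from .mixedmodel import make_spec, reml_fit, variance_ratios
from .relmat import build_grm
from .simdata import SimConfig, simulate_dataset
from .sv_catalog import build_validation_sets

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "svsets", "grm", "reml", "gwas", "impute_eval", "predict_cv")

DEMO_CONFIG: dict = {
    "outdir": "demo_run",
    "simulate": {
        "n_individuals": 500,
        "n_snp": 5000,
        "n_sv": 200,
        "seed": 20210219,
    },
    "impute_eval": {"k": 5, "seed": 11, "anchor": "start", "exclude_snps_in_sv": False, "w": 20},
    "gwas": {"traits": None},
    "predict_cv": {"k": 5, "repeats": 2, "seed": 17, "refit_vc": False},
}


def _write_meta(outdir: Path, stage: str, params: dict) -> None:
    meta = {"stage": stage, "params": params, "version": __version__}
    (outdir / f"{stage}.meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))


def _stage_simulate(outdir: Path, cfg: dict) -> None:
    sim_cfg = SimConfig(**cfg.get("simulate", {}))
    ds = simulate_dataset(sim_cfg)
    svio.write_dosage_tsv(ds.snp_genotypes, outdir / "snp_dosages.tsv")
    svio.write_dosage_tsv(ds.sv_truth, outdir / "sv_truth.tsv")
    svio.write_sv_vcf(ds.sv_genotypes, ds.sv_map, outdir / "sv_calls.vcf")
    svio.write_marker_map(ds.snp_map, outdir / "snp_map.tsv")
    svio.write_marker_map(ds.sv_map, outdir / "sv_map.tsv")
    svio.write_phenotypes(ds.phenotypes.values, outdir / "phenotypes.tsv")
    ds.phenotypes.components.to_csv(outdir / "true_components.tsv", sep="\t", index=False)
    svio.write_samples(ds.samples, outdir / "samples.tsv")
    _write_meta(outdir, "simulate", dataclasses.asdict(sim_cfg))


def _load_core(outdir: Path):
    snp = svio.read_dosage_tsv(outdir / "snp_dosages.tsv")
    sv_vcf, sv_map = svio.read_genotype_vcf(outdir / "sv_calls.vcf")
    snp_map = svio.read_marker_map(outdir / "snp_map.tsv")
    pheno = svio.read_phenotypes(outdir / "phenotypes.tsv")
    samples = svio.read_samples(outdir / "samples.tsv")
    return snp, sv_vcf, sv_map, snp_map, pheno, samples


def _primary(samples: pd.DataFrame) -> np.ndarray:
    return np.flatnonzero((samples["duplicate_of"] == "").to_numpy())


def _stage_svsets(outdir: Path, cfg: dict) -> None:
    from .simdata import SampleInfo

    snp, sv, sv_map, _, _, samples = _load_core(outdir)
    infos = [
        SampleInfo(
            id=r.id,
            sex=r.sex,
            breed_fraction=float(r.breed_fraction),
            sire_id=r.sire_id or None,
            duplicate_of=r.duplicate_of or None,
        )
        for r in samples.itertuples()
    ]
    from .sv_catalog import SVRecord

    records = [SVRecord(r.chrom, int(r.start), int(r.end), r.type, ("pipeline",)) for r in sv_map.itertuples()]
    calls = {}
    for i, sid in enumerate(sv.sample_ids):
        row = sv.codes[i]
        calls[sid] = [records[j] for j in np.flatnonzero((row == 1) | (row == 2))]
    sets = build_validation_sets(calls, infos)
    for name, recs in sets.items():
        df = pd.DataFrame(
            [{"chrom": r.chrom, "start": r.start, "end": r.end, "id": f"{name}_{i}", "type": r.sv_type}
             for i, r in enumerate(recs)]
        )
        if df.empty:
            df = pd.DataFrame(columns=["chrom", "start", "end", "id", "type"])
        svio.write_marker_map(df, outdir / f"validated_{name.lower()}.tsv")
    _write_meta(outdir, "svsets", {"sets": sorted(sets)})


def _stage_grm(outdir: Path, cfg: dict) -> None:
    snp, sv, _, _, _, samples = _load_core(outdir)
    idx = _primary(samples)
    g_snp = build_grm(snp.subset(individuals=idx))
    g_sv = build_grm(sv.subset(individuals=idx))
    svio.write_grm_tsv(g_snp, outdir / "grm_snp.tsv")
    svio.write_grm_tsv(g_sv, outdir / "grm_sv.tsv")
    _write_meta(outdir, "grm", {"n": int(idx.size), "m_snp": g_snp.n_markers, "m_sv": g_sv.n_markers})


def _traits(pheno: pd.DataFrame, cfg: dict) -> list[str]:
    names = [c for c in pheno.columns if c != "id"]
    wanted = cfg.get("gwas", {}).get("traits")
    return [t for t in names if wanted is None or t in wanted]


def _stage_reml(outdir: Path, cfg: dict) -> None:
    _, _, _, _, pheno, samples = _load_core(outdir)
    g_snp = svio.read_grm_tsv(outdir / "grm_snp.tsv")
    g_sv = svio.read_grm_tsv(outdir / "grm_sv.tsv")
    idx = _primary(samples)
    breed = samples["breed_fraction"].to_numpy(dtype=float)[idx]
    rows = []
    for trait in _traits(pheno, cfg):
        y = pheno[trait].to_numpy(dtype=float)
        for model, pairs in {
            "SNP": [(g_snp, "snp")],
            "SNP+SV": [(g_snp, "snp"), (g_sv, "sv")],
        }.items():
            spec = make_spec(y, pairs, covariates=breed, covariate_names=["breed_fraction"])
            vc = reml_fit(spec)
            ratios = variance_ratios(vc)
            for lab in vc.labels:
                rows.append(
                    {
                        "trait": trait,
                        "model": model,
                        "component": lab,
                        "estimate": vc.components[lab],
                        "se": vc.se[lab],
                        "loglik": vc.loglik,
                        "converged": vc.converged,
                        "snp_vs_p": ratios["snp_vs_p"],
                        "sv_vs_p": ratios["sv_vs_p"],
                        "genetic_vs_p": ratios["genetic_vs_p"],
                        "sv_vs_genetic": ratios["sv_vs_genetic"],
                    }
                )
    pd.DataFrame(rows).to_csv(outdir / "variance_components.tsv", sep="\t", index=False, float_format="%.10g")
    _write_meta(outdir, "reml", {"models": ["SNP", "SNP+SV"]})


def _stage_gwas(outdir: Path, cfg: dict) -> None:
    snp, sv, sv_map, snp_map, pheno, samples = _load_core(outdir)
    g_snp = svio.read_grm_tsv(outdir / "grm_snp.tsv")
    g_sv = svio.read_grm_tsv(outdir / "grm_sv.tsv")
    idx = _primary(samples)
    breed = samples["breed_fraction"].to_numpy(dtype=float)[idx]
    sex = samples["sex"].to_numpy()[idx]
    snp_map = snp_map.assign(**{"class": "SNP"})
    sv_map = sv_map.assign(**{"class": "SV"})
    info = pd.concat([snp_map, sv_map], ignore_index=True)
    dosages = np.column_stack([snp.codes[idx], sv.codes[idx]])
    scans = []
    for trait in _traits(pheno, cfg):
        y = pheno[trait].to_numpy(dtype=float)
        for cohort, mask in (("bulls", sex == "M"), ("cows", sex == "F")):
            sub = np.flatnonzero(mask)
            pairs = [
                (g_snp.matrix[np.ix_(sub, sub)], "snp"),
                (g_sv.matrix[np.ix_(sub, sub)], "sv"),
            ]
            spec = make_spec(y[sub], pairs, covariates=breed[sub], covariate_names=["breed_fraction"])
            vc = reml_fit(spec)
            scans.append(mlma_scan(spec, dosages[sub], vc, marker_info=info, trait=trait, cohort=cohort))
    gwas = pd.concat(scans, ignore_index=True)
    gwas.to_csv(outdir / "gwas.tsv", sep="\t", index=False, float_format="%.8g")

    # single-trait bull/cow meta plus an all-cohort-trait meta
    meta_rows = []
    for trait in _traits(pheno, cfg):
        bulls = gwas[(gwas["trait"] == trait) & (gwas["cohort"] == "bulls")]
        cows = gwas[(gwas["trait"] == trait) & (gwas["cohort"] == "cows")]
        res = meta_single_trait(bulls, cows)
        res.table["trait"] = trait
        meta_rows.append(res.table)
    meta = pd.concat(meta_rows, ignore_index=True)
    meta.to_csv(outdir / "meta_single_trait.tsv", sep="\t", index=False, float_format="%.8g")

    tables = [g for (_, _), g in gwas.groupby(["trait", "cohort"])]
    V = t_correlation(tables)
    tmat = pd.concat(
        [g.set_index("id")["t"].rename(f"{g['cohort'].iloc[0]}:{g['trait'].iloc[0]}") for g in tables],
        axis=1,
    )
    tmat = tmat[V.columns.tolist()]
    multi = multi_trait_chi2(tmat.to_numpy(), V, marker_ids=tmat.index.to_numpy())
    multi.table.to_csv(outdir / "meta_multi_trait.tsv", sep="\t", index=False, float_format="%.8g")

    # SV FDR at the exploratory threshold ladder (per trait, bull/cow meta)
    sv_ids = set(sv_map["id"])
    thr = significance_thresholds(int(dosages.shape[1]))
    fdr_rows = []
    n_sv_total = len(sv_ids)
    for trait in _traits(pheno, cfg):
        mt = meta[meta["trait"] == trait]
        sv_p = mt[mt["id"].isin(sv_ids)]["p"].to_numpy(dtype=float)
        for p_thr in thr.ladder:
            s = int(np.nansum(sv_p < p_thr))
            fdr_rows.append(
                {
                    "trait": trait,
                    "p_threshold": p_thr,
                    "n_significant_sv": s,
                    "n_sv": n_sv_total,
                    "fdr_percent": 100.0 * fdr(FDRQuery(P=p_thr, S=s, T=n_sv_total)) if s else np.nan,
                }
            )
    pd.DataFrame(fdr_rows).to_csv(outdir / "sv_fdr.tsv", sep="\t", index=False, float_format="%.6g")
    _write_meta(outdir, "gwas", {"bonferroni": thr.bonferroni, "n_tests": int(dosages.shape[1])})


def _stage_impute_eval(outdir: Path, cfg: dict) -> None:
    snp, sv, sv_map, snp_map, _, samples = _load_core(outdir)
    icfg = cfg.get("impute_eval", {})
    plan = make_folds(snp.n_individuals, k=icfg.get("k", 5), seed=icfg.get("seed", 0))
    truth = svio.read_dosage_tsv(outdir / "sv_truth.tsv")
    _, acc = run_masking_cv(
        snp,
        truth,
        snp_map,
        sv_map,
        plan,
        anchor=icfg.get("anchor", "start"),
        exclude_snps_in_sv=icfg.get("exclude_snps_in_sv", False),
        w=icfg.get("w", 20),
    )
    acc.to_csv(outdir / "imputation_accuracy.tsv", sep="\t", index=False, float_format="%.8g")
    threshold_summary(acc).to_csv(outdir / "imputation_thresholds.tsv", sep="\t", index=False, float_format="%.6g")
    accuracy_by_maf(acc).to_csv(outdir / "imputation_by_maf.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame({"sv_id": select_svs(acc)}).to_csv(outdir / "selected_svs.tsv", sep="\t", index=False)
    _write_meta(outdir, "impute_eval", dict(icfg))


def _stage_predict_cv(outdir: Path, cfg: dict) -> None:
    _, _, _, _, pheno, samples = _load_core(outdir)
    g_snp = svio.read_grm_tsv(outdir / "grm_snp.tsv")
    g_sv = svio.read_grm_tsv(outdir / "grm_sv.tsv")
    pcfg = cfg.get("predict_cv", {})
    idx = _primary(samples)
    breed = samples["breed_fraction"].to_numpy(dtype=float)[idx]
    scheme = CVScheme(k=pcfg.get("k", 10), repeats=pcfg.get("repeats", 10), seed=pcfg.get("seed", 0))
    rows = []
    for trait in _traits(pheno, cfg):
        y = pheno[trait].to_numpy(dtype=float)
        report = run_cv(
            y,
            {
                "SNP": [(g_snp.matrix, "snp")],
                "SNP+SV": [(g_snp.matrix, "snp"), (g_sv.matrix, "sv")],
            },
            scheme,
            covariates=breed,
            refit_vc=pcfg.get("refit_vc", True),
        )
        tab = report.table.assign(trait=trait)
        rows.append(tab)
    pd.DataFrame(pd.concat(rows, ignore_index=True)).to_csv(
        outdir / "prediction_accuracy.tsv", sep="\t", index=False, float_format="%.6g"
    )
    _write_meta(outdir, "predict_cv", dict(pcfg))


_STAGE_FN = {
    "simulate": _stage_simulate,
    "svsets": _stage_svsets,
    "grm": _stage_grm,
    "reml": _stage_reml,
    "gwas": _stage_gwas,
    "impute_eval": _stage_impute_eval,
    "predict_cv": _stage_predict_cv,
}

_STAGE_INPUTS = {
    "simulate": (),
    "svsets": ("snp_dosages.tsv", "sv_calls.vcf", "samples.tsv"),
    "grm": ("snp_dosages.tsv", "sv_calls.vcf"),
    "reml": ("grm_snp.tsv", "grm_sv.tsv", "phenotypes.tsv"),
    "gwas": ("grm_snp.tsv", "grm_sv.tsv", "phenotypes.tsv"),
    "impute_eval": ("snp_dosages.tsv", "sv_truth.tsv"),
    "predict_cv": ("grm_snp.tsv", "grm_sv.tsv", "phenotypes.tsv"),
}


def run_pipeline(config: dict | str, stages=None) -> Path:
    """Run the configured stages, writing artifacts under ``config['outdir']``.

    ``config`` is a dict or a YAML/JSON path; ``stages`` defaults to the
    full chain. A stage whose upstream artifacts are missing raises an
    error naming the stage and file.
    """
    if not isinstance(config, dict):
        config = svio.load_config(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in stages or ALL_STAGES:
        if stage not in _STAGE_FN:
            raise ValueError(f"unknown stage {stage!r}")
        for dep in _STAGE_INPUTS[stage]:
            if not (outdir / dep).exists():
                raise FileNotFoundError(f"stage {stage!r} requires missing artifact {dep!r}")
        log.info("running stage %s", stage)
        _STAGE_FN[stage](outdir, config)
    return outdir
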