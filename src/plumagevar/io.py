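"""Study-bundle I/O and the end-to-end pipeline.

A study bundle is a directory of plain CSV tables sharing individual ids:

- ``spectra.csv``     wavelength_nm + one column per sample/replicate
                      (``"<id>|rep<k>"``)
- ``genotypes.csv``   individual, locus, allele1, allele2
- ``social.csv``      individual, nest, site, social_mother, social_father,
                      year, sex, date, mass
- ``phenotypes.csv``  individual, stage, sex + trait columns
- ``adults.csv``      id, role, site
- ``pedigree_truth.csv`` (optional) generating truth
- ``truth.json``      (optional) generating parameters

``run_pipeline`` chains spectra -> color metrics, genotypes -> paternity
-> pedigree -> relatedness, the all-families and multibrood animal-model
fits, and the stage comparisons, writing report CSVs plus a run manifest.
"""

from __future__ import annotations

import json
import logging
import platform
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .animal_model import AnimalModel
from .colorspace import TetraColorMapper
from .paternity import PaternityClassifier, epy_summary
from .pedigree import build_pedigree
from .simulate import SimulationParams, SyntheticStudy, simulate_study

__all__ = ["StudyBundle", "write_bundle", "read_bundle", "run_pipeline", "multibrood_subset"]

log = logging.getLogger("plumagevar")

SCHEMA_VERSION = 1
REQUIRED = ("spectra.csv", "genotypes.csv", "social.csv", "phenotypes.csv")


@dataclass
class StudyBundle:
    path: Path
    spectra: pd.DataFrame
    genotypes: pd.DataFrame
    social: pd.DataFrame
    phenotypes: pd.DataFrame
    adults: pd.DataFrame | None = None
    pedigree_truth: pd.DataFrame | None = None
    truth: dict | None = None


def write_bundle(study: SyntheticStudy, path: str | Path) -> Path:
    """Write a synthetic study as a bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    study.spectra.to_csv(path / "spectra.csv", index=False)
    study.genotypes.to_csv(path / "genotypes.csv", index=False)
    study.social.to_csv(path / "social.csv", index=False)
    study.phenotypes.to_csv(path / "phenotypes.csv", index=False)
    study.adults.to_csv(path / "adults.csv", index=False)
    study.pedigree_truth.to_csv(path / "pedigree_truth.csv", index=False)
    truth = {"schema_version": SCHEMA_VERSION, "params": study.params.to_jsonable()}
    (path / "truth.json").write_text(json.dumps(truth, indent=1))
    return path


def read_bundle(path: str | Path) -> StudyBundle:
    """Read and validate a bundle: files present, ids consistent."""
    path = Path(path)
    missing = [f for f in REQUIRED if not (path / f).exists()]
    if missing:
        raise FileNotFoundError(f"bundle at {path} missing files: {missing}")
    spectra = pd.read_csv(path / "spectra.csv")
    genotypes = pd.read_csv(path / "genotypes.csv")
    social = pd.read_csv(path / "social.csv")
    phenotypes = pd.read_csv(path / "phenotypes.csv")
    adults = pd.read_csv(path / "adults.csv") if (path / "adults.csv").exists() else None
    ped_truth = (
        pd.read_csv(path / "pedigree_truth.csv")
        if (path / "pedigree_truth.csv").exists()
        else None
    )
    truth = (
        json.loads((path / "truth.json").read_text())
        if (path / "truth.json").exists()
        else None
    )
    geno_ids = set(genotypes["individual"].astype(str))
    offenders = sorted(
        set(social["individual"].astype(str))
        | set(social["social_mother"].astype(str))
        | set(social["social_father"].astype(str))
    )
    offenders = [i for i in offenders if i not in geno_ids]
    if offenders:
        raise ValueError(
            f"ids referenced in social.csv but missing from genotypes.csv: {offenders[:10]}"
        )
    pheno_off = [
        i for i in phenotypes["individual"].astype(str).unique()
        if i not in set(social["individual"].astype(str))
    ]
    if pheno_off:
        raise ValueError(
            f"ids in phenotypes.csv missing from social.csv: {pheno_off[:10]}"
        )
    for name, n in (("spectra", spectra), ("genotypes", genotypes), ("social", social)):
        log.info("read %s: %d rows", name, len(n))
    return StudyBundle(path, spectra, genotypes, social, phenotypes, adults, ped_truth, truth)


def multibrood_subset(social: pd.DataFrame) -> pd.DataFrame:
    """Offspring of mothers with >= 2 nests (within or across seasons)."""
    nests = social.groupby("social_mother")["nest"].nunique()
    keep = set(nests[nests >= 2].index)
    return social[social["social_mother"].isin(keep)]


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run the full analysis on a bundle (simulating one if requested).

    ``config`` sections (all optional): simulation (SimulationParams
    fields), bundle (path to an existing bundle), paternity
    (threshold, min_typed_loci), model (traits, fixed_terms), mcmc
    (n_iter, burn_in, thin, seed), seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    if "bundle" in config:
        bundle = read_bundle(config["bundle"])
    else:
        sim_cfg = dict(config.get("simulation", {}))
        sim_cfg.setdefault("seed", seed)
        params = SimulationParams(**sim_cfg)
        study = simulate_study(params)
        bundle = read_bundle(write_bundle(study, out_dir / "bundle"))

    # 1. spectra -> color metrics
    mapper = TetraColorMapper()
    metrics = mapper.fit(bundle.spectra).transform(bundle.spectra)
    metrics.to_csv(out_dir / "color_metrics.csv", index=False)
    log.info("color metrics computed for %d samples", len(metrics))

    # 2. paternity
    pat_cfg = config.get("paternity", {})
    clf = PaternityClassifier(
        threshold=int(pat_cfg.get("threshold", 2)),
        min_typed_loci=int(pat_cfg.get("min_typed_loci", 4)),
    )
    calls = clf.fit(bundle.genotypes).predict(bundle.social)
    calls.to_csv(out_dir / "paternity_calls.csv", index=False)
    summary, per_nest = epy_summary(calls)
    summary.to_csv(out_dir / "epy_summary.csv", index=False)
    per_nest.to_csv(out_dir / "epy_per_nest.csv")

    # 3. pedigree
    ped = build_pedigree(calls, bundle.social)
    ped.to_csv(out_dir / "pedigree.csv", index=False)

    # 4. animal models
    mcmc = config.get("mcmc", {})
    model_cfg = config.get("model", {})
    traits = tuple(model_cfg.get("traits", ("theta", "phi", "r_A", "brightness")))
    nestl = bundle.phenotypes[bundle.phenotypes["stage"] == "nestling"]
    data = nestl.merge(bundle.social, on=["individual", "sex"], how="inner")
    common = dict(
        traits=traits,
        fixed_terms=tuple(model_cfg.get("fixed_terms", ("year",))),
        n_iter=int(mcmc.get("n_iter", 20_000)),
        burn_in=int(mcmc.get("burn_in", 1_000)),
        thin=int(mcmc.get("thin", 10)),
        seed=int(mcmc.get("seed", seed)),
    )
    model_all = AnimalModel(random_terms=("additive", "nest"), **common)
    model_all.fit(data, ped)
    model_all.summary_.to_csv(out_dir / "variance_components_all.csv", index=False)
    if model_all.correlations_ is not None:
        model_all.correlations_.to_csv(out_dir / "genetic_correlations.csv", index=False)
    model_all.fixed_report_.to_csv(out_dir / "fixed_effects_all.csv", index=False)

    mb_social = multibrood_subset(bundle.social)
    maternal_fitted = False
    if mb_social.empty:
        warnings.warn("no mother has multiple broods; maternal model skipped")
    else:
        mb_data = data[data["individual"].isin(mb_social["individual"])]
        mb_calls = calls[calls["offspring"].isin(mb_social["individual"])]
        mb_ped = build_pedigree(mb_calls, mb_social)
        model_mb = AnimalModel(random_terms=("additive", "nest", "maternal"), **common)
        model_mb.fit(mb_data, mb_ped)
        model_mb.summary_.to_csv(out_dir / "variance_components_multibrood.csv", index=False)
        maternal_fitted = True

    # 5. stage comparisons
    from . import stage_compare

    pheno = bundle.phenotypes
    anova = stage_compare.anova_stage_sex(pheno)
    rows = []
    for metric, res in anova.items():
        for eff, d in res["anova"].items():
            rows.append({"metric": metric, "effect": eff, **d})
        for c in res["tukey"]:
            rows.append({"metric": metric, "effect": c["contrast"],
                         "difference": c["difference"], "lower": c["lower"],
                         "upper": c["upper"], "significant": c["significant"]})
    pd.DataFrame(rows).to_csv(out_dir / "stage_sex_anova.csv", index=False)

    wide = pheno.pivot(index="individual", columns="stage",
                       values=list(traits)).dropna()
    wide.columns = [f"{m}_{s}" for m, s in wide.columns]
    wide = wide.join(pheno[pheno["stage"] == "nestling"].set_index("individual")["sex"])
    rng = np.random.default_rng(seed)
    n_pairs = min(76, len(wide))
    paired = wide.iloc[rng.choice(len(wide), size=n_pairs, replace=False)]
    ancova = stage_compare.ancova_nestling_adult(paired, metrics=traits)
    ancova.to_csv(out_dir / "ancova_nestling_adult.csv", index=False)

    from . import __version__ as pkg_version

    manifest = {
        "package_version": pkg_version,
        "python": platform.python_version(),
        "seed": seed,
        "mcmc": common,
        "maternal_model_fitted": maternal_fitted,
        "n_offspring": int(len(bundle.social)),
        "n_color_samples": int(len(metrics)),
        "schema_version": SCHEMA_VERSION,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
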