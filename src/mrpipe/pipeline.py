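"""Pipeline orchestration: simulate -> QC -> validate -> associate -> meta -> MR.

Configured by a plain-text (YAML/JSON) mapping in which every analysis
threshold is a named key with the conventional default (F >= 10 for strong
instruments, heterogeneity p <= 0.05 switching to random effects,
Bonferroni family alpha 0.05, HWE flag threshold). Stage outputs are TSV/JSON
files that round-trip through the package readers, so stages can be rerun
individually against an existing output directory. Reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import meta as meta_mod
from . import qc as qc_mod
from .instruments import confounder_screen, exposure_table, pleiotropy_matrix
from .outcomes import associate_by_study
from .simulate import (
    BiomarkerSpec,
    ConfounderSpec,
    Cohort,
    OutcomeModel,
    SimulationConfig,
    SNPSpec,
    SurvivalModel,
    simulate_consortium,
)
from .wald import mr_report

__all__ = ["PipelineConfig", "PipelineError", "DependencyError", "run_pipeline", "make_fixture"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "validate", "associate", "meta", "mr")

DEFAULT_THRESHOLDS = {
    "f_stat": 10.0,
    "het_p": 0.05,
    "bonferroni_alpha": 0.05,
    "hwe_flag_p": 1e-6,
}


class PipelineError(RuntimeError):
    pass


class DependencyError(PipelineError):
    """A requested stage is missing its upstream inputs."""


def simulation_config_from_dict(d: dict[str, Any]) -> SimulationConfig:
    """Build a SimulationConfig from a plain (YAML-friendly) mapping."""
    snps = [SNPSpec(**s) for s in d.get("snps", [])]
    bios = [BiomarkerSpec(**b) for b in d.get("biomarkers", [])]
    confs = [ConfounderSpec(**c) for c in d.get("confounders", [])]
    outcome = OutcomeModel(**d["outcome"]) if "outcome" in d else None
    survival = None
    if "survival" in d:
        sv = dict(d["survival"])
        sv["genotype_log_hr"] = {
            k: tuple(v) for k, v in sv.get("genotype_log_hr", {}).items()
        }
        survival = SurvivalModel(**sv)
    ld = d.get("ld_r2")
    ld_df = None
    if ld is not None:
        ids = [s.id for s in snps]
        ld_df = pd.DataFrame(np.asarray(ld, dtype=float), index=ids, columns=ids)
    return SimulationConfig(
        n_individuals=int(d.get("n_individuals", 1000)),
        snps=snps,
        biomarkers=bios,
        effects={k: dict(v) for k, v in d.get("effects", {}).items()},
        ld_r2=ld_df,
        confounders=confs,
        outcome=outcome,
        survival=survival,
        n_studies=int(d.get("n_studies", 1)),
        between_study_tau2=float(d.get("between_study_tau2", 0.0)),
        dosage_noise=float(d.get("dosage_noise", 0.0)),
        n_pcs=int(d.get("n_pcs", 0)),
    )


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    out_dir: Path = Path("mrpipe_out")
    simulate: dict[str, Any] | None = None
    input_vcf: str | None = None
    input_phenotypes: str | None = None
    biomarker_columns: list[str] = field(default_factory=list)
    covariate_columns: list[str] = field(default_factory=list)
    transforms: dict[str, str] = field(default_factory=dict)  # biomarker -> none|log
    outcomes: list[str] = field(default_factory=lambda: ["case-control", "grade"])
    sd_table: dict[str, float] = field(default_factory=dict)  # exposure SDs for MR scaling
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages and self.simulate is None:
            if self.input_vcf is None or self.input_phenotypes is None:
                raise PipelineError("config needs either a simulation block or input paths")
        for key, default in DEFAULT_THRESHOLDS.items():
            self.thresholds.setdefault(key, default)
        for key in ("het_p", "bonferroni_alpha", "hwe_flag_p"):
            if not 0.0 < self.thresholds[key] < 1.0:
                raise PipelineError(f"threshold {key} must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_cohort_tables(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load (dosages, snp_info, biomarkers, covariates, phenotypes) from the
    configured inputs or from a previous simulate stage in out_dir."""
    vcf = cfg.input_vcf or str(cfg.out_dir / "data" / "cohort.vcf")
    pheno_path = cfg.input_phenotypes or str(cfg.out_dir / "data" / "cohort.pheno.tsv")
    if not Path(vcf).exists() or not Path(pheno_path).exists():
        raise DependencyError("no input data: run the simulate stage or provide input paths")
    dosages, snp_info = qc_mod.read_vcf(vcf)
    pheno = pd.read_csv(pheno_path, sep="\t", index_col=0)
    bio_cols = cfg.biomarker_columns or [
        c for c in pheno.columns
        if c not in ("disease", "grade_high", "stage_advanced", "time", "event", "study")
        and c not in cfg.covariate_columns
        and pd.api.types.is_numeric_dtype(pheno[c])
    ]
    biomarkers = pheno[bio_cols]
    covariates = pheno[cfg.covariate_columns] if cfg.covariate_columns else pheno[[]]
    pheno_cols = [c for c in ("disease", "grade_high", "stage_advanced", "time", "event", "study") if c in pheno.columns]
    return dosages, snp_info, biomarkers, covariates, pheno[pheno_cols]


def run_pipeline(config: PipelineConfig | dict[str, Any]) -> dict[str, Any]:
    """Run the configured stages, writing per-stage TSVs, a JSON summary and
    a run log under ``config.out_dir``. Returns the summary dict."""
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_dict(config)
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds
    summary: dict[str, Any] = {"seed": cfg.seed, "stages": list(cfg.stages), "thresholds": dict(th)}
    log_lines = [f"mrpipe run; seed={cfg.seed}; stages={','.join(cfg.stages)}"]

    cohort: Cohort | None = None
    if "simulate" in cfg.stages:
        if cfg.simulate is None:
            raise PipelineError("simulate stage requested without a simulation block")
        sim_cfg = simulation_config_from_dict(cfg.simulate)
        cohort = simulate_consortium(sim_cfg, seed=cfg.seed)
        paths = cohort.write(out / "data")
        log_lines.append(f"simulate: n={cohort.n}, studies={len(cohort.studies)}")
        summary["simulate"] = {"n": cohort.n, "n_studies": len(cohort.studies), "files": {k: str(v) for k, v in paths.items()}}
        if not cfg.biomarker_columns:
            cfg.biomarker_columns = list(cohort.biomarkers.columns)
        if not cfg.covariate_columns:
            cfg.covariate_columns = list(cohort.covariates.columns)

    need_data = set(cfg.stages) & {"qc", "validate", "associate"}
    if need_data:
        dosages, snp_info, biomarkers, covariates, phenotypes = _load_cohort_tables(cfg)
    kept_snps = list(dosages.columns) if need_data else []

    if "qc" in cfg.stages:
        qc_table = qc_mod.snp_qc_table(dosages, snp_info, hwe_threshold=th["hwe_flag_p"])
        qc_table.to_csv(out / "qc.tsv", sep="\t")
        dropped = qc_table.index[qc_table["monomorphic"]].tolist()
        for snp in dropped:
            log_lines.append(f"qc: dropped {snp} (monomorphic)")
        for snp in qc_table.index[qc_table["hwe_fail"]]:
            log_lines.append(f"qc: flagged {snp} (HWE p < {th['hwe_flag_p']:g})")
        kept_snps = [s for s in kept_snps if s not in dropped]
        summary["qc"] = {
            "n_snps": int(len(qc_table)),
            "n_dropped_monomorphic": len(dropped),
            "n_hwe_flagged": int(qc_table["hwe_fail"].sum()),
        }

    strong: list = []
    validated = None
    if "validate" in cfg.stages:
        controls = phenotypes.index[phenotypes["disease"] == 0]
        # exposure regressions run in disease-free individuals only
        vdos = dosages.loc[controls, kept_snps]
        vbio = biomarkers.loc[controls]
        vcov = covariates.loc[controls] if len(covariates.columns) else None
        pleio = pleiotropy_matrix(
            vdos, vbio, covariates=vcov, transforms=cfg.transforms, f_threshold=th["f_stat"]
        )
        validated = pleio
        tab = exposure_table(pleio.associations)
        tab["strong"] = tab["F"] >= th["f_stat"]
        tab.to_csv(out / "instruments.tsv", sep="\t", index=False)
        strong = [a for a in pleio.associations if a.f_stat >= th["f_stat"]]
        screens = []
        if vcov is not None:
            n_tests = len(kept_snps) * len(vcov.columns)
            for snp_id in kept_snps:
                screens.extend(
                    confounder_screen(
                        vdos[snp_id].to_numpy(dtype=float), vcov,
                        alpha=th["bonferroni_alpha"], n_tests=n_tests, snp=snp_id,
                    )
                )
            pd.DataFrame([vars(s) for s in screens]).to_csv(out / "confounder_screen.tsv", sep="\t", index=False)
        summary["validate"] = {
            "n_strong": len(strong),
            "strong": sorted({(a.snp, a.biomarker) for a in strong}),
            "pleiotropic_snps": sorted(pleio.pleiotropic_snps),
            "n_confounder_flags": sum(s.flagged for s in screens),
        }

    if "associate" in cfg.stages:
        frames = []
        for outcome in cfg.outcomes:
            frames.append(
                associate_by_study(
                    dosages[kept_snps], phenotypes, outcome,
                    covariates=covariates if len(covariates.columns) else None,
                )
            )
        assoc_df = pd.concat(frames, ignore_index=True)
        assoc_df.to_csv(out / "associations.tsv", sep="\t", index=False)
        summary["associate"] = {"n_fits": int(len(assoc_df)), "outcomes": list(cfg.outcomes)}

    if "meta" in cfg.stages:
        assoc_path = out / "associations.tsv"
        if not assoc_path.exists():
            raise DependencyError("meta stage requires the associate stage output")
        assoc_df = pd.read_csv(assoc_path, sep="\t")
        pooled = meta_mod.pool_table(assoc_df, het_p_threshold=th["het_p"])
        pooled.to_csv(out / "meta.tsv", sep="\t", index=False)
        summary["meta"] = {
            "n_pooled": int(len(pooled)),
            "n_random_effects": int((pooled["model"] == "random").sum()),
        }

    if "mr" in cfg.stages:
        if validated is None:
            raise DependencyError("mr stage requires the validate stage (no instrument output)")
        meta_path = out / "meta.tsv"
        if not meta_path.exists():
            raise DependencyError("mr stage requires the meta stage output")
        pooled = pd.read_csv(meta_path, sep="\t")
        pooled_map = {
            (str(r.snp), str(r.outcome)): (float(r.log_effect), float(r.se))
            for r in pooled.itertuples()
        }
        sd_table = dict(cfg.sd_table)
        if not sd_table:
            # default scaling SDs from the exposure (control) sample
            controls = phenotypes.index[phenotypes["disease"] == 0]
            for bio in biomarkers.columns:
                vals = biomarkers.loc[controls, bio].dropna()
                if cfg.transforms.get(bio) == "log":
                    vals = np.log(vals[vals > 0])
                sd_table[str(bio)] = float(vals.std(ddof=1))
        estimates = mr_report(
            strong, pooled_map, sd_table, f_threshold=th["f_stat"],
        )
        with open(out / "mr.json", "w") as fh:
            json.dump([e.to_dict() for e in estimates], fh, indent=2, sort_keys=True)
        summary["mr"] = {
            "n_estimates": len(estimates),
            "estimates": [
                {
                    "snp": e.snp, "exposure": e.exposure, "outcome": e.outcome,
                    "estimate": round(e.estimate, 6),
                    "ci_low": round(e.ci_low, 6), "ci_high": round(e.ci_high, 6),
                    "scale_sd": round(e.scale_sd, 6),
                }
                for e in estimates
            ],
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


# ---------------------------------------------------------------------------
# bundled mini-consortium fixture


def fixture_config(seed: int = 0, out_dir: str | Path = "fixture_out") -> PipelineConfig:
    """Configuration for a small 5-study consortium (~2,000 individuals,
    8 SNPs, 4 biomarkers) with one pleiotropic strong instrument: `snp_iv`
    raises biomarker B2 by ~95 ng/mL per allele (total SD 265; EAF 0.265,
    chosen so the variant explains ~5% of variance) and B4 more weakly."""
    snps = [
        {"id": "snp_iv", "effect_allele": "A", "other_allele": "G", "eaf": 0.265},
        {"id": "snp_2", "effect_allele": "C", "other_allele": "T", "eaf": 0.30},
        {"id": "snp_3", "effect_allele": "G", "other_allele": "A", "eaf": 0.45},
        {"id": "snp_4", "effect_allele": "T", "other_allele": "C", "eaf": 0.10},
        {"id": "snp_5", "effect_allele": "A", "other_allele": "C", "eaf": 0.20},
        {"id": "snp_6", "effect_allele": "G", "other_allele": "T", "eaf": 0.35},
        {"id": "snp_7", "effect_allele": "C", "other_allele": "G", "eaf": 0.40},
        {"id": "snp_8", "effect_allele": "T", "other_allele": "A", "eaf": 0.25},
    ]
    biomarkers = [
        {"name": "B1", "mean": 200.0, "sd": 50.0},
        {"name": "B2", "mean": 700.0, "sd": 265.0},
        {"name": "B3", "mean": 300.0, "sd": 150.0, "log_normal": True},
        {"name": "B4", "mean": 2500.0, "sd": 1000.0},
    ]
    effects = {
        "snp_iv": {"B2": 94.78, "B4": 170.0},  # pleiotropic instrument
        "snp_2": {"B1": 8.0},
        "snp_3": {"B3": 0.05},  # log-scale effect
    }
    sim = {
        "n_individuals": 400,
        "n_studies": 5,
        "between_study_tau2": 0.01,
        "snps": snps,
        "biomarkers": biomarkers,
        "effects": effects,
        "confounders": [
            {"name": "age", "mean": 62.0, "sd": 7.0, "effects": {"B1": -0.8}},
        ],
        "n_pcs": 2,
        "outcome": {
            "log_or": {"B2": 0.10 / 265.0},
            "prevalence": 0.5,
            "grade_log_or": {"B2": 0.14 / 265.0},
            "grade_high_frac": 0.3,
            "stage_log_or": {"B2": 0.05 / 265.0},
            "stage_adv_frac": 0.2,
        },
        "survival": {
            "log_hr": {"B2": 0.1 / 265.0},
            "baseline_hazard": 0.06,
            "censoring": 0.3,
        },
    }
    return PipelineConfig(
        stages=ALL_STAGES,
        seed=seed,
        out_dir=Path(out_dir),
        simulate=sim,
        transforms={"B3": "log"},
        outcomes=["case-control", "grade", "stage"],
        covariate_columns=["age", "PC1", "PC2"],
    )


def make_fixture(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the bundled mini-consortium to disk (VCF + phenotype TSV +
    the YAML config that generated it). Files parse through the readers in
    :mod:`mrpipe.qc`."""
    cfg = fixture_config(seed=seed, out_dir=out_dir)
    sim_cfg = simulation_config_from_dict(cfg.simulate)
    cohort = simulate_consortium(sim_cfg, seed=seed)
    paths = cohort.write(Path(out_dir) / "data")
    config_path = Path(out_dir) / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(
            {
                "seed": seed,
                "stages": list(ALL_STAGES),
                "out_dir": str(out_dir),
                "simulate": cfg.simulate,
                "transforms": cfg.transforms,
                "outcomes": cfg.outcomes,
                "covariate_columns": cfg.covariate_columns,
            },
            fh,
            sort_keys=False,
        )
    paths["config"] = config_path
    return paths
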