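"""Synthetic genotype–biomarker–outcome cohorts with known causal structure.

Every downstream stage of the pipeline (QC, instrument validation, outcome
association, meta-analysis, Wald-ratio estimation) is exercised against
cohorts generated here, where the true per-allele effects, the true causal
effects of each biomarker on disease, and the between-study heterogeneity
are all specified up front.

Model
-----
* Genotypes: two Bernoulli haplotypes per individual (exact Hardy-Weinberg
  sampling). LD between markers is induced via a Gaussian copula on the
  haplotype level, calibrated so the dosage correlation hits the target r²
  (a target of exactly 1 duplicates the column).
* Biomarkers: intercept + per-allele additive genetic effects + confounder
  effects + Gaussian residual, with the residual sized so the total SD
  matches the configured SD. Log-normal biomarkers are built on the natural
  log scale (betas are per-allele log-unit effects) and exponentiated; the
  log-scale location/scale are moment-matched to the configured mean/SD.
* Disease: logistic in the mean-centred biomarkers, plus optional direct
  (pleiotropic) SNP effects and a per-study log-odds shift drawn
  Normal(0, tau2) for multi-study consortia.
* Grade and stage: sampled among cases only (case-only contrasts).
* Survival: exponential hazards scaled by exp(log-HR x biomarker), with
  independent uniform censoring calibrated to the target censoring rate;
  optional per-genotype (non-additive) hazard terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SNPSpec",
    "BiomarkerSpec",
    "ConfounderSpec",
    "OutcomeModel",
    "SurvivalModel",
    "SimulationConfig",
    "Cohort",
    "InfeasibleLDError",
    "simulate_cohort",
    "simulate_consortium",
    "write_vcf",
]


class InfeasibleLDError(ValueError):
    """Target r² not achievable at the given allele frequencies."""

    def __init__(self, snp_a: str, snp_b: str, target: float, achievable: float):
        self.achievable = achievable
        super().__init__(
            f"LD r2={target:.3f} between {snp_a} and {snp_b} is infeasible at "
            f"these allele frequencies; maximum achievable r2 is {achievable:.3f}"
        )


@dataclass(frozen=True)
class SNPSpec:
    id: str
    effect_allele: str
    other_allele: str
    eaf: float

    def __post_init__(self) -> None:
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.id}: eaf must be in (0, 1)")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.id}: alleles must differ")


@dataclass(frozen=True)
class BiomarkerSpec:
    name: str
    mean: float
    sd: float
    log_normal: bool = False

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")
        if self.log_normal and self.mean <= 0:
            raise ValueError(f"{self.name}: log-normal biomarker needs mean > 0")


@dataclass(frozen=True)
class ConfounderSpec:
    name: str
    mean: float
    sd: float
    effects: dict[str, float] = field(default_factory=dict)  # biomarker -> per-unit effect
    outcome_log_or: float = 0.0  # optional direct effect on disease


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic outcome structure. All biomarker coefficients are log-OR per
    unit of the biomarker (ng/mL, or log-units for log-normal biomarkers)."""

    log_or: dict[str, float] = field(default_factory=dict)
    prevalence: float = 0.1
    grade_log_or: dict[str, float] = field(default_factory=dict)
    grade_high_frac: float = 0.3  # baseline P(high grade | case)
    stage_log_or: dict[str, float] = field(default_factory=dict)
    stage_adv_frac: float = 0.2  # baseline P(advanced | case)
    snp_log_or: dict[str, float] = field(default_factory=dict)  # direct pleiotropy


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential survival among cases; log-HR per unit biomarker."""

    log_hr: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.05  # events per year at mean biomarker levels
    censoring: float = 0.3  # target censored fraction
    # snp id -> (log-HR heterozygote, log-HR minor homozygote) vs major homozygote
    genotype_log_hr: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    n_individuals: int = 1000
    snps: list[SNPSpec] = field(default_factory=list)
    biomarkers: list[BiomarkerSpec] = field(default_factory=list)
    #: snp id -> biomarker name -> per-allele effect (ng/mL; log-units if log-normal)
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    ld_r2: pd.DataFrame | None = None  # pairwise target r², indexed by snp id
    confounders: list[ConfounderSpec] = field(default_factory=list)
    outcome: OutcomeModel | None = None
    survival: SurvivalModel | None = None
    n_studies: int = 1
    between_study_tau2: float = 0.0
    dosage_noise: float = 0.0  # Beta-noise concentration toward hard calls; 0 = hard calls
    n_pcs: int = 0  # nuisance principal-component covariates (pure noise)

    def beta(self, snp: str, biomarker: str) -> float:
        return self.effects.get(snp, {}).get(biomarker, 0.0)

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if self.between_study_tau2 < 0:
            raise ValueError("between_study_tau2 must be >= 0")
        seen = set()
        for s in self.snps:
            if s.id in seen:
                raise ValueError(f"duplicate snp id {s.id}")
            seen.add(s.id)
        known_bio = {b.name for b in self.biomarkers}
        for snp_id, per_bio in self.effects.items():
            if snp_id not in seen:
                raise ValueError(f"effects reference unknown snp {snp_id}")
            for bio in per_bio:
                if bio not in known_bio:
                    raise ValueError(f"effects reference unknown biomarker {bio}")
        if self.ld_r2 is not None:
            vals = self.ld_r2.to_numpy(dtype=float)
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise ValueError("ld_r2 targets must lie in [0, 1]")
        for b in self.biomarkers:
            gvar = self._genetic_variance(b)
            tvar = self._latent_sd(b) ** 2
            if gvar > tvar:
                raise ValueError(
                    f"{b.name}: implied genetic variance {gvar:.4g} exceeds "
                    f"total variance {tvar:.4g}"
                )

    def _latent_sd(self, b: BiomarkerSpec) -> float:
        # scale of the additive (possibly log) latent variable
        if b.log_normal:
            return float(np.sqrt(np.log1p((b.sd / b.mean) ** 2)))
        return b.sd

    def _genetic_variance(self, b: BiomarkerSpec) -> float:
        return float(
            sum(2 * s.eaf * (1 - s.eaf) * self.beta(s.id, b.name) ** 2 for s in self.snps)
        )


@dataclass
class Cohort:
    """Individual-level dataset: dosages, biomarkers, covariates, outcomes.

    `phenotypes` carries disease status, case-only grade/stage groups
    (NaN for controls), survival time/event (NaN where not simulated) and
    the study label.
    """

    dosages: pd.DataFrame
    biomarkers: pd.DataFrame
    covariates: pd.DataFrame
    phenotypes: pd.DataFrame
    snp_info: pd.DataFrame

    def __post_init__(self) -> None:
        if self.phenotypes["study"].isna().any():
            raise ValueError("missing study labels")
        d = self.dosages.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if np.nanmin(d) < 0 or np.nanmax(d) > 2:
                raise ValueError("dosages outside [0, 2]")
        t = self.phenotypes.get("time")
        if t is not None and (t.dropna() <= 0).any():
            raise ValueError("survival times must be positive")

    @property
    def n(self) -> int:
        return len(self.phenotypes)

    @property
    def studies(self) -> list[str]:
        return list(pd.unique(self.phenotypes["study"]))

    def concat(self, other: "Cohort") -> "Cohort":
        return Cohort(
            dosages=pd.concat([self.dosages, other.dosages]),
            biomarkers=pd.concat([self.biomarkers, other.biomarkers]),
            covariates=pd.concat([self.covariates, other.covariates]),
            phenotypes=pd.concat([self.phenotypes, other.phenotypes]),
            snp_info=self.snp_info,
        )

    def write(self, out_dir: str | Path, prefix: str = "cohort") -> dict[str, Path]:
        """Write genotypes (VCF with DS) and a phenotype TSV; round-trips
        through the readers in :mod:`mrpipe.qc`."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        vcf_path = out / f"{prefix}.vcf"
        write_vcf(self.dosages, self.snp_info, vcf_path)
        pheno = pd.concat([self.biomarkers, self.covariates, self.phenotypes], axis=1)
        pheno_path = out / f"{prefix}.pheno.tsv"
        pheno.to_csv(pheno_path, sep="\t", index_label="sample_id")
        return {"vcf": vcf_path, "phenotypes": pheno_path}


# ---------------------------------------------------------------------------
# genotype machinery


def _max_hap_corr(pa: float, pb: float) -> float:
    """Frechet upper bound on the correlation of two Bernoulli haplotypes."""
    lo, hi = (pa, pb) if pa <= pb else (pb, pa)
    return float(np.sqrt(lo * (1 - hi) / (hi * (1 - lo))))


def _latent_corr_for(pa: float, pb: float, target_r: float) -> float:
    """Latent Gaussian correlation giving Bernoulli correlation `target_r`."""
    if target_r <= 0:
        return 0.0
    za, zb = stats.norm.ppf(pa), stats.norm.ppf(pb)
    denom = np.sqrt(pa * (1 - pa) * pb * (1 - pb))

    def gap(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf([za, zb], mean=[0, 0], cov=[[1, rho], [rho, 1]])
        return (p11 - pa * pb) / denom - target_r

    hi = 0.999999
    if gap(hi) < 0:  # even near-comonotone latent cannot reach it
        return hi
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-8))


def _draw_genotypes(
    rng: np.random.Generator, n: int, config: SimulationConfig
) -> np.ndarray:
    snps = config.snps
    m = len(snps)
    p = np.array([s.eaf for s in snps])
    if config.ld_r2 is None:
        # independent markers: exact HWE via two Bernoulli haplotypes
        return (
            (rng.random((n, m)) < p).astype(np.int8) + (rng.random((n, m)) < p).astype(np.int8)
        ).astype(float)

    ids = [s.id for s in snps]
    target = np.eye(m)
    dup_of: dict[int, int] = {}  # column j duplicates column i (target r2 == 1)
    for i in range(m):
        for j in range(i + 1, m):
            try:
                t = float(config.ld_r2.loc[ids[i], ids[j]])
            except KeyError:
                t = np.nan
            if np.isnan(t):
                t = 0.0
            r = np.sqrt(t)
            max_r = _max_hap_corr(p[i], p[j])
            if t >= 1.0 - 1e-12:
                if abs(p[i] - p[j]) > 1e-9:
                    raise InfeasibleLDError(ids[i], ids[j], t, max_r**2)
                dup_of[j] = i
                r = 0.0
            elif r > max_r + 1e-9:
                raise InfeasibleLDError(ids[i], ids[j], t, max_r**2)
            target[i, j] = target[j, i] = r

    latent = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            if target[i, j] > 0:
                latent[i, j] = latent[j, i] = _latent_corr_for(p[i], p[j], target[i, j])
    # ensure a valid correlation matrix (eigenvalue clipping)
    w, v = np.linalg.eigh(latent)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        latent = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(latent))
        latent = latent / np.outer(d, d)
    chol = np.linalg.cholesky(latent)
    thresh = stats.norm.ppf(p)
    geno = np.zeros((n, m))
    for _ in range(2):  # two haplotypes
        z = rng.standard_normal((n, m)) @ chol.T
        geno += z < thresh
    for j, i in dup_of.items():
        geno[:, j] = geno[:, i]
    return geno


def _apply_dosage_noise(
    rng: np.random.Generator, geno: np.ndarray, eafs: np.ndarray, concentration: float
) -> np.ndarray:
    """Beta-weighted shrinkage of each hard call toward its expected dosage
    (2 x EAF), mimicking imputation uncertainty without biasing the EAF.
    Larger `concentration` = noisier dosages."""
    if concentration <= 0:
        return geno
    lam = rng.beta(1.0, 1.0 / concentration, size=geno.shape)
    return np.clip(geno * (1 - lam) + (2.0 * eafs) * lam, 0.0, 2.0)


# ---------------------------------------------------------------------------
# cohort generation


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _censoring_bound(mean_rate: float, target: float) -> float:
    """Upper bound U of Uniform(0, U) censoring giving ~`target` censored
    fraction against Exponential(mean_rate) event times."""
    if target <= 0:
        return np.inf

    def frac_censored(u: float) -> float:
        # P(C < T) with C ~ U(0,u), T ~ Exp(rate)
        return (1.0 - np.exp(-mean_rate * u)) / (mean_rate * u)

    lo, hi = 1e-6, 1e6
    if frac_censored(hi) > target:
        return hi
    return float(optimize.brentq(lambda u: frac_censored(u) - target, lo, hi, xtol=1e-9))


def _simulate_study(
    config: SimulationConfig,
    rng: np.random.Generator,
    study_label: str,
    study_shift: float,
    sample_offset: int = 0,
) -> Cohort:
    n = config.n_individuals
    snp_ids = [s.id for s in config.snps]
    eafs = np.array([s.eaf for s in config.snps])

    geno = _draw_genotypes(rng, n, config)
    dosage = _apply_dosage_noise(rng, geno, eafs, config.dosage_noise)
    geno_centred = geno - 2 * eafs  # true genotypes drive phenotypes

    conf_vals = {}
    for c in config.confounders:
        conf_vals[c.name] = rng.normal(c.mean, c.sd, size=n)

    bio_latent: dict[str, np.ndarray] = {}
    bio_obs: dict[str, np.ndarray] = {}
    bio_centred: dict[str, np.ndarray] = {}
    for b in config.biomarkers:
        latent_sd = config._latent_sd(b)
        betas = np.array([config.beta(s, b.name) for s in snp_ids])
        systematic = geno_centred @ betas
        for c in config.confounders:
            eff = c.effects.get(b.name, 0.0)
            if eff:
                systematic = systematic + eff * (conf_vals[c.name] - c.mean)
        sys_var = float(np.var(systematic))
        resid_var = latent_sd**2 - sys_var
        if resid_var < 0:
            raise ValueError(
                f"{b.name}: systematic variance {sys_var:.4g} exceeds total "
                f"variance {latent_sd**2:.4g}"
            )
        resid = rng.normal(0.0, np.sqrt(resid_var), size=n) if resid_var > 0 else 0.0
        if b.log_normal:
            sigma2 = latent_sd**2
            mu_log = np.log(b.mean) - sigma2 / 2.0
            latent = mu_log + systematic + resid
            obs = np.exp(latent)
            centred = latent - mu_log
        else:
            latent = b.mean + systematic + resid
            obs = latent
            centred = latent - b.mean
        bio_latent[b.name] = latent
        bio_obs[b.name] = obs
        bio_centred[b.name] = centred

    covs = dict(conf_vals)
    for k in range(config.n_pcs):
        covs[f"PC{k + 1}"] = rng.normal(0.0, 1.0, size=n)

    # disease; the study-level shift perturbs the per-allele genotype log-OR
    # (every SNP), so multi-study runs carry recoverable between-study
    # heterogeneity in the genotype-outcome effect
    om = config.outcome or OutcomeModel(prevalence=0.0)
    if config.outcome is not None:
        eta = np.full(n, _logit(om.prevalence))
        for bio, gamma in om.log_or.items():
            eta = eta + gamma * bio_centred[bio]
        for snp, gamma in om.snp_log_or.items():
            j = snp_ids.index(snp)
            eta = eta + gamma * geno_centred[:, j]
        if study_shift:
            eta = eta + study_shift * geno_centred.sum(axis=1)
        for c in config.confounders:
            if c.outcome_log_or:
                eta = eta + c.outcome_log_or * (conf_vals[c.name] - c.mean)
        disease = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    else:
        disease = np.zeros(n, dtype=int)

    # grade / stage among cases only
    grade = np.full(n, np.nan)
    stage = np.full(n, np.nan)
    cases = disease == 1
    if config.outcome is not None and cases.any():
        for target, log_ors, frac in (
            (grade, om.grade_log_or, om.grade_high_frac),
            (stage, om.stage_log_or, om.stage_adv_frac),
        ):
            eta_c = np.full(int(cases.sum()), _logit(frac))
            for bio, gamma in log_ors.items():
                eta_c = eta_c + gamma * bio_centred[bio][cases]
            target[cases] = (rng.random(eta_c.size) < 1.0 / (1.0 + np.exp(-eta_c))).astype(float)

    # survival among cases
    time = np.full(n, np.nan)
    event = np.full(n, np.nan)
    sm = config.survival
    if sm is not None and cases.any():
        log_rate = np.full(n, np.log(sm.baseline_hazard))
        for bio, lhr in sm.log_hr.items():
            log_rate = log_rate + lhr * bio_centred[bio]
        for snp, (lhr_het, lhr_hom) in sm.genotype_log_hr.items():
            j = snp_ids.index(snp)
            g = np.round(geno[:, j])
            log_rate = log_rate + lhr_het * (g == 1) + lhr_hom * (g == 2)
        rate = np.exp(log_rate[cases])
        t_event = rng.exponential(1.0 / rate)
        u = _censoring_bound(float(rate.mean()), sm.censoring)
        t_cens = rng.uniform(0.0, u, size=rate.size) if np.isfinite(u) else np.full(rate.size, np.inf)
        observed = np.minimum(t_event, t_cens)
        observed = np.maximum(observed, 1e-9)
        time[cases] = observed
        event[cases] = (t_event <= t_cens).astype(float)

    sample_ids = [f"{study_label}_I{sample_offset + i:06d}" for i in range(n)]
    snp_info = pd.DataFrame(
        {
            "effect_allele": [s.effect_allele for s in config.snps],
            "other_allele": [s.other_allele for s in config.snps],
            "eaf": eafs,
        },
        index=pd.Index(snp_ids, name="id"),
    )
    return Cohort(
        dosages=pd.DataFrame(dosage, index=sample_ids, columns=snp_ids),
        biomarkers=pd.DataFrame(bio_obs, index=sample_ids),
        covariates=pd.DataFrame(covs, index=sample_ids),
        phenotypes=pd.DataFrame(
            {
                "disease": disease,
                "grade_high": grade,
                "stage_advanced": stage,
                "time": time,
                "event": event,
                "study": study_label,
            },
            index=sample_ids,
        ),
        snp_info=snp_info,
    )


def simulate_cohort(config: SimulationConfig, seed: int) -> Cohort:
    """Generate a single-study cohort. Same config + seed => identical output."""
    config.validate()
    rng = np.random.default_rng(seed)
    return _simulate_study(config, rng, "study_1", 0.0)


def simulate_consortium(config: SimulationConfig, seed: int) -> Cohort:
    """Generate a multi-study cohort (`config.n_studies` studies of
    `config.n_individuals` each), with study-level disease log-odds shifts
    drawn Normal(0, between_study_tau2).

    With ``n_studies == 1`` and ``between_study_tau2 == 0`` this is
    identical to :func:`simulate_cohort` at the same seed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if config.between_study_tau2 > 0:
        shifts = rng.normal(0.0, np.sqrt(config.between_study_tau2), size=config.n_studies)
    else:
        shifts = np.zeros(config.n_studies)
    parts = [
        _simulate_study(config, rng, f"study_{s + 1}", float(shifts[s]))
        for s in range(config.n_studies)
    ]
    cohort = parts[0]
    for part in parts[1:]:
        cohort = cohort.concat(part)
    return cohort


# ---------------------------------------------------------------------------
# writers


def write_vcf(dosages: pd.DataFrame, snp_info: pd.DataFrame, path: str | Path) -> None:
    """Write dosages as a minimal VCF 4.2 with GT (hard call) and DS fields."""
    samples = list(dosages.index)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=mrpipe",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for pos, snp in enumerate(dosages.columns, start=1):
        ref = str(snp_info.loc[snp, "other_allele"])
        alt = str(snp_info.loc[snp, "effect_allele"])
        fields = []
        for d in dosages[snp].to_numpy(dtype=float):
            if np.isnan(d):
                fields.append("./.:.")
            else:
                fields.append(f"{gt_map[int(round(d))]}:{d:.4g}")
        lines.append(f"1\t{pos * 1000}\t{snp}\t{ref}\t{alt}\t.\tPASS\t.\tGT:DS\t" + "\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
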