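"""Instrument validation: per-SNP exposure regressions, strength diagnostics
(partial F, incremental R²), confounder screening and pleiotropy assessment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ExposureAssociation",
    "ScreenResult",
    "PleiotropyResult",
    "WEAK_INSTRUMENT_F",
    "exposure_regression",
    "classify_instrument",
    "confounder_screen",
    "pleiotropy_matrix",
    "exposure_table",
]

#: partial F below this flags a weak instrument
WEAK_INSTRUMENT_F = 10.0


@dataclass(frozen=True)
class ExposureAssociation:
    """Linear association of one biomarker with one SNP dosage.

    `beta` is the mean biomarker difference per effect allele, in ng/mL, or
    in natural-log units when `transform == "log"`. `f_stat` is the partial
    F for the dosage term; `r2` the incremental R² attributable to dosage
    over the covariates; `r2_adj` the adjusted version of the full-model R²
    in the no-covariate case (degrees-of-freedom-corrected variance
    explained).
    """

    snp: str
    biomarker: str
    beta: float
    se: float
    p: float
    ci_low: float
    ci_high: float
    f_stat: float
    r2: float
    r2_adj: float
    n: int
    transform: str = "none"
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must lie in [0, 1]")
        if self.f_stat < 0:
            raise ValueError("F must be non-negative")


@dataclass(frozen=True)
class ScreenResult:
    snp: str
    variable: str
    beta: float
    se: float
    p: float
    flagged: bool
    kind: str  # "continuous" | "binary"


@dataclass(frozen=True)
class PleiotropyResult:
    associations: list[ExposureAssociation]
    #: SNPs qualifying as strong instruments for two or more biomarkers
    pleiotropic_snps: tuple[str, ...] = field(default=())

    def table(self) -> pd.DataFrame:
        return exposure_table(self.associations)


def _complete_cases(*arrays: np.ndarray) -> np.ndarray:
    ok = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        if a.ndim == 1:
            ok &= ~np.isnan(a)
        else:
            ok &= ~np.isnan(a).any(axis=1)
    return ok


def exposure_regression(
    dosage: np.ndarray,
    biomarker: np.ndarray,
    covariates: pd.DataFrame | None = None,
    transform: str = "none",
    snp: str = "snp",
    biomarker_name: str = "biomarker",
) -> ExposureAssociation:
    """OLS of a (possibly log-transformed) biomarker on SNP dosage + covariates.

    The reported F is the partial F for the dosage term (the squared t of
    its coefficient), and R² is the incremental R² of dosage over the
    covariate-only model. Two-sided p-values use the t distribution.

    Raises
    ------
    ValueError
        fewer than 10 complete cases, monomorphic dosage, non-positive
        biomarker under log transform, or a singular design.
    """
    if transform not in ("none", "log"):
        raise ValueError("transform must be 'none' or 'log'")
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(biomarker, dtype=float)
    cov = covariates.to_numpy(dtype=float) if covariates is not None else None
    cov_names = tuple(covariates.columns) if covariates is not None else ()

    ok = _complete_cases(d, y) if cov is None else _complete_cases(d, y, cov)
    d, y = d[ok], y[ok]
    if cov is not None:
        cov = cov[ok]
    n = d.size
    if n < 10:
        raise ValueError(f"need >= 10 complete cases, got {n}")
    if np.ptp(d) == 0:
        raise ValueError("monomorphic SNP: exposure regression undefined")
    if transform == "log":
        if (y <= 0).any():
            raise ValueError("log transform requires strictly positive biomarker values")
        y = np.log(y)

    X = np.column_stack([np.ones(n), d] if cov is None else [np.ones(n), d, cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (collinear covariates)")
    fit = sm.OLS(y, X).fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])  # t-distributed
    ci = fit.conf_int()[1]
    f_partial = float(fit.tvalues[1] ** 2)

    if cov is None:
        r2_incr = float(fit.rsquared)
        r2_adj = float(fit.rsquared_adj)
    else:
        reduced = sm.OLS(y, np.column_stack([np.ones(n), cov])).fit()
        r2_incr = max(0.0, float(fit.rsquared - reduced.rsquared))
        r2_adj = float(fit.rsquared_adj)
    return ExposureAssociation(
        snp=snp,
        biomarker=biomarker_name,
        beta=beta,
        se=se,
        p=p,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        f_stat=f_partial,
        r2=min(1.0, r2_incr),
        r2_adj=r2_adj,
        n=int(n),
        transform=transform,
        covariates=cov_names,
    )


def classify_instrument(assoc: ExposureAssociation, threshold: float = WEAK_INSTRUMENT_F) -> str:
    """'strong' iff the partial F is at or above `threshold` (F < threshold
    is the evidence of weakness, so the boundary itself is strong)."""
    if not np.isfinite(assoc.f_stat):
        raise ValueError("F statistic is not finite")
    return "strong" if assoc.f_stat >= threshold else "weak"


def confounder_screen(
    dosage: np.ndarray,
    variables: pd.DataFrame,
    alpha: float = 0.05,
    n_tests: int | None = None,
    snp: str = "snp",
) -> list[ScreenResult]:
    """Regress each candidate confounder on dosage and flag associations
    surviving Bonferroni correction.

    Continuous variables use OLS; binary ({0,1}-valued) variables use
    logistic regression with dosage as the predictor. `n_tests` overrides
    the Bonferroni divisor (defaults to the number of variables screened)
    for multi-SNP screens where the divisor spans all SNP x variable tests.
    Constant variables are skipped with a warning.
    """
    d = np.asarray(dosage, dtype=float)
    results: list[tuple[str, float, float, float, str]] = []
    skipped = []
    for name in variables.columns:
        v = variables[name].to_numpy(dtype=float)
        ok = _complete_cases(d, v)
        dv, vv = d[ok], v[ok]
        if np.ptp(vv) == 0:
            skipped.append(name)
            continue
        X = sm.add_constant(dv)
        uniq = np.unique(vv)
        if uniq.size == 2 and set(uniq) <= {0.0, 1.0}:
            fit = sm.Logit(vv, X).fit(disp=0)
            kind = "binary"
        else:
            fit = sm.OLS(vv, X).fit()
            kind = "continuous"
        results.append((name, float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1]), kind))
    if skipped:
        warnings.warn(f"constant variables skipped in confounder screen: {skipped}")
    divisor = n_tests if n_tests is not None else len(results)
    threshold = alpha / divisor if divisor else alpha
    return [
        ScreenResult(snp=snp, variable=name, beta=b, se=s, p=p, flagged=p < threshold, kind=kind)
        for name, b, s, p, kind in results
    ]


def pleiotropy_matrix(
    dosages: pd.DataFrame,
    biomarkers: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    transforms: dict[str, str] | None = None,
    f_threshold: float = WEAK_INSTRUMENT_F,
) -> PleiotropyResult:
    """Exposure regression for every (SNP, biomarker) pair.

    A SNP strong (partial F >= `f_threshold`) for two or more biomarkers is
    marked pleiotropic — it cannot cleanly instrument any single one.
    """
    if biomarkers.shape[1] < 2:
        raise ValueError("pleiotropy assessment needs >= 2 biomarkers")
    transforms = transforms or {}
    assocs = []
    strong_count: dict[str, int] = {}
    for snp in dosages.columns:
        for bio in biomarkers.columns:
            a = exposure_regression(
                dosages[snp].to_numpy(dtype=float),
                biomarkers[bio].to_numpy(dtype=float),
                covariates=covariates,
                transform=transforms.get(bio, "none"),
                snp=str(snp),
                biomarker_name=str(bio),
            )
            assocs.append(a)
            if a.f_stat >= f_threshold:
                strong_count[str(snp)] = strong_count.get(str(snp), 0) + 1
    pleio = tuple(s for s, c in strong_count.items() if c >= 2)
    return PleiotropyResult(associations=assocs, pleiotropic_snps=pleio)


def exposure_table(assocs: list[ExposureAssociation]) -> pd.DataFrame:
    """Tidy per-(SNP, biomarker) table: beta, CI, p, F, R² (%)."""
    return pd.DataFrame(
        {
            "snp": [a.snp for a in assocs],
            "biomarker": [a.biomarker for a in assocs],
            "beta": [a.beta for a in assocs],
            "se": [a.se for a in assocs],
            "ci_low": [a.ci_low for a in assocs],
            "ci_high": [a.ci_high for a in assocs],
            "p": [a.p for a in assocs],
            "F": [a.f_stat for a in assocs],
            "r2_pct": [100.0 * a.r2 for a in assocs],
            "n": [a.n for a in assocs],
            "transform": [a.transform for a in assocs],
        }
    )
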