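"""Genotype-outcome association models.

Logistic regression (risk, case-only grade and stage contrasts) with
cluster-robust sandwich standard errors, and Cox proportional-hazards
survival models under additive or genotypic codings, with a Schoenfeld
residual check of the proportional-hazards assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test

__all__ = [
    "OutcomeAssociation",
    "CoxResult",
    "PHCheckResult",
    "SeparationError",
    "logistic_assoc",
    "cox_assoc",
    "ph_check",
    "associate_by_study",
]


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation: no finite ML estimate exists."""


@dataclass(frozen=True)
class OutcomeAssociation:
    """One genotype-outcome effect estimate on the log scale.

    `log_effect` is a log-OR (logistic) or log-HR (Cox) per effect allele
    under additive coding, or for one genotype class vs the major-homozygote
    reference under genotypic coding (`term` = "het" or "hom").
    For survival models `n_case` holds the event count and `n_control`
    the remaining (censored) count.
    """

    snp: str
    outcome: str
    coding: str  # "additive" | "genotypic"
    term: str  # "additive" | "het" | "hom"
    log_effect: float
    se: float
    p: float
    n_case: int
    n_control: int
    cluster: str | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if not np.isfinite(np.exp(self.log_effect)):
            raise ValueError("effect estimate overflows on the ratio scale")

    @property
    def effect(self) -> float:
        """OR or HR."""
        return float(np.exp(self.log_effect))

    def ci(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return (
            float(np.exp(self.log_effect - z * self.se)),
            float(np.exp(self.log_effect + z * self.se)),
        )


@dataclass
class CoxResult:
    """Cox fit: per-term associations plus the fitted lifelines model
    (kept for the proportional-hazards diagnostic)."""

    associations: list[OutcomeAssociation]
    fitter: CoxPHFitter
    data: pd.DataFrame
    coding: str

    @property
    def primary(self) -> OutcomeAssociation:
        return self.associations[0]


@dataclass(frozen=True)
class PHCheckResult:
    p: float
    n_events: int
    reliable: bool  # False when too few events for the score test


def _complete(df: pd.DataFrame) -> pd.DataFrame:
    return df.dropna()


def logistic_assoc(
    dosage: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    clusters: np.ndarray | None = None,
    snp: str = "snp",
    outcome_name: str = "case-control",
) -> OutcomeAssociation:
    """Per-allele log-OR from maximum-likelihood logistic regression.

    When `clusters` (e.g. study labels) are supplied the SE is the
    cluster-robust sandwich estimate; otherwise it is model-based.

    Raises
    ------
    SeparationError
        on perfect separation / non-convergence (no estimate is reported).
    ValueError
        when only one outcome class is present.
    """
    df = pd.DataFrame({"dosage": np.asarray(dosage, dtype=float), "y": np.asarray(outcome, dtype=float)})
    if covariates is not None:
        for c in covariates.columns:
            df[c] = covariates[c].to_numpy(dtype=float)
    cluster_name = None
    if clusters is not None:
        df["_cluster"] = np.asarray(clusters)
        cluster_name = "cluster"
    df = _complete(df)
    y = df.pop("y").to_numpy()
    groups = df.pop("_cluster").to_numpy() if clusters is not None else None
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome has a single class")
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X = sm.add_constant(df.to_numpy(dtype=float))

    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.filterwarnings("error", message=".*[Ss]eparation.*")
        try:
            model = sm.Logit(y, X)
            if groups is not None:
                fit = model.fit(disp=0, cov_type="cluster", cov_kwds={"groups": groups})
            else:
                fit = model.fit(disp=0)
        except Exception as exc:  # statsmodels raises/warns various separation signals
            raise SeparationError(f"logistic fit failed (separation?): {exc}") from exc
    if not fit.mle_retvals.get("converged", True) or abs(fit.params[1]) > 30:
        raise SeparationError("logistic fit did not converge to a finite estimate")

    n_case = int((y == 1).sum())
    n_control = int((y == 0).sum())
    return OutcomeAssociation(
        snp=snp,
        outcome=outcome_name,
        coding="additive",
        term="additive",
        log_effect=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        n_case=n_case,
        n_control=n_control,
        cluster=cluster_name,
    )


def cox_assoc(
    dosage: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    covariates: pd.DataFrame | None = None,
    clusters: np.ndarray | None = None,
    coding: str = "additive",
    snp: str = "snp",
    outcome_name: str = "mortality-all-cause",
) -> CoxResult:
    """Cox partial-likelihood fit of survival on genotype.

    Under `coding="additive"` the dosage enters linearly (log-HR per effect
    allele). Under `coding="genotypic"` indicator terms for heterozygotes
    and minor-allele homozygotes are fitted against the major-homozygote
    reference, exposing heterozygote-extreme hazard patterns that the
    additive model averages away. Cluster-robust SEs when `clusters` given.
    """
    if coding not in ("additive", "genotypic"):
        raise ValueError("coding must be 'additive' or 'genotypic'")
    df = pd.DataFrame(
        {
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=float),
            "dosage": np.asarray(dosage, dtype=float),
        }
    )
    if covariates is not None:
        for c in covariates.columns:
            df[c] = covariates[c].to_numpy(dtype=float)
    if clusters is not None:
        df["_cluster"] = np.asarray(clusters)
    df = _complete(df)
    if (df["time"] <= 0).any():
        raise ValueError("all survival times must be positive")
    if df["event"].sum() < 1:
        raise ValueError("no events observed")
    if np.ptp(df["dosage"].to_numpy()) == 0:
        raise ValueError("degenerate (constant) dosage")

    if coding == "genotypic":
        g = np.round(df.pop("dosage").to_numpy())
        df.insert(2, "het", (g == 1).astype(float))
        df.insert(3, "hom", (g == 2).astype(float))
        terms = ["het", "hom"]
    else:
        terms = ["dosage"]

    cph = CoxPHFitter()
    kwargs: dict = {}
    if clusters is not None:
        kwargs["cluster_col"] = "_cluster"
        kwargs["robust"] = True
    cph.fit(df, duration_col="time", event_col="event", **kwargs)

    n_events = int(df["event"].sum())
    n_censored = int(len(df) - n_events)
    assocs = [
        OutcomeAssociation(
            snp=snp,
            outcome=outcome_name,
            coding=coding,
            term=("additive" if t == "dosage" else t),
            log_effect=float(cph.params_[t]),
            se=float(cph.standard_errors_[t]),
            p=float(cph.summary.loc[t, "p"]),
            n_case=n_events,
            n_control=n_censored,
            cluster="cluster" if clusters is not None else None,
        )
        for t in terms
    ]
    return CoxResult(associations=assocs, fitter=cph, data=df, coding=coding)


def ph_check(fit: CoxResult, transform: str = "km") -> PHCheckResult:
    """Proportional-hazards diagnostic for the genotype term.

    Score test of scaled Schoenfeld residuals against a monotone transform
    of event time (`"km"` default; `"identity"` ("rank") and `"log"`
    available). p < 0.05 flags a violation. With fewer than 10 events the
    test is unreliable and flagged as such.
    """
    if transform not in ("km", "identity", "log"):
        raise ValueError("transform must be 'km', 'identity' or 'log'")
    tt = {"km": "km", "identity": "rank", "log": "log"}[transform]
    n_events = int(fit.data["event"].sum())
    data = fit.data.drop(columns=["_cluster"], errors="ignore")
    res = proportional_hazard_test(fit.fitter, data, time_transform=tt)
    term = "dosage" if fit.coding == "additive" else "het"
    p = float(res.summary.loc[term, "p"].min() if hasattr(res.summary.loc[term, "p"], "min") else res.summary.loc[term, "p"])
    return PHCheckResult(p=p, n_events=n_events, reliable=n_events >= 10)


def associate_by_study(
    dosages: pd.DataFrame,
    phenotypes: pd.DataFrame,
    outcome: str,
    covariates: pd.DataFrame | None = None,
    snps: list[str] | None = None,
) -> pd.DataFrame:
    """Fit the per-study logistic association for each SNP and return the
    meta-analysis input schema: study, snp, outcome, coding, beta, se, p,
    n_case, n_control.

    Outcome column semantics: "case-control" uses all rows, "grade" and
    "stage" are case-only contrasts (controls carry NaN and drop out).
    Studies where a fit fails (separation, single class) are skipped with
    a warning.
    """
    col = {
        "case-control": "disease",
        "grade": "grade_high",
        "stage": "stage_advanced",
    }.get(outcome, outcome)
    rows = []
    snps = snps if snps is not None else list(dosages.columns)
    for study, idx in phenotypes.groupby("study").groups.items():
        y = phenotypes.loc[idx, col].to_numpy(dtype=float)
        cov = covariates.loc[idx] if covariates is not None else None
        for snp in snps:
            d = dosages.loc[idx, snp].to_numpy(dtype=float)
            try:
                a = logistic_assoc(d, y, covariates=cov, snp=str(snp), outcome_name=outcome)
            except (SeparationError, ValueError) as exc:
                warnings.warn(f"study {study}, snp {snp}: {exc}")
                continue
            rows.append(
                {
                    "study": study,
                    "snp": str(snp),
                    "outcome": outcome,
                    "coding": "additive",
                    "beta": a.log_effect,
                    "se": a.se,
                    "p": a.p,
                    "n_case": a.n_case,
                    "n_control": a.n_control,
                }
            )
    return pd.DataFrame(rows)
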