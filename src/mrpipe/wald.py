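"""Two-sample ratio (Wald) instrumental-variable estimation.

Combines a SNP-exposure coefficient estimated in one sample with a
SNP-outcome log-OR (or log-HR) estimated in another into an SD-scaled
causal effect: ``causal log-effect = scale_sd * log_gy / beta_gx``.

Standard errors: the default first-order delta method ignores uncertainty
in the denominator (gene-exposure) coefficient; the second-order delta
method adds it; Fieller's theorem inverts the ratio test and can yield
asymmetric or unbounded intervals for weak instruments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .instruments import ExposureAssociation, WEAK_INSTRUMENT_F, classify_instrument

__all__ = ["WaldEstimate", "SummaryStat", "wald_ratio", "harmonize", "mr_report"]

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class WaldEstimate:
    """SD-scaled causal effect of an exposure on an outcome via one SNP.

    `causal_log_effect` is the log-OR/log-HR per `scale_sd` units of the
    exposure; `estimate` / `ci_low` / `ci_high` are on the ratio scale.
    `components` stores (beta_gx, se_gx, log_gy, se_gy): the gene-exposure
    and gene-outcome associations the ratio is built from.
    """

    exposure: str
    outcome: str
    snp: str
    scale_sd: float
    causal_log_effect: float
    se: float
    estimate: float
    ci_low: float
    ci_high: float
    se_method: str
    components: tuple[float, float, float, float]
    weak_instrument: bool = False

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["components"] = list(self.components)
        return d


@dataclass(frozen=True)
class SummaryStat:
    """One row of summary statistics (printed-numbers interface)."""

    snp: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None


def wald_ratio(
    beta_gx: float,
    se_gx: float,
    log_gy: float,
    se_gy: float,
    scale_sd: float,
    se_method: str = "first-order-delta",
    exposure: str = "exposure",
    outcome: str = "outcome",
    snp: str = "snp",
    alpha: float = 0.05,
) -> WaldEstimate:
    """Ratio IV estimate with an SD-scaled effect and confidence interval.

    Parameters
    ----------
    beta_gx, se_gx : float
        Gene-exposure effect per allele (exposure units) and its SE.
    log_gy, se_gy : float
        Gene-outcome log-OR/log-HR per allele and its SE.
    scale_sd : float
        Exposure SD used to express the causal effect per SD increase
        (supplied externally, from the exposure sample or literature).
    se_method : {"first-order-delta", "second-order-delta", "fieller"}

    Unit invariance: rescaling the exposure units multiplies `beta_gx` and
    `scale_sd` together and leaves the causal estimate unchanged.
    """
    if scale_sd <= 0:
        raise ValueError("scale_sd must be positive")
    if beta_gx == 0 or abs(beta_gx) < 1e-300:
        raise ValueError("beta_gx must be nonzero: ratio undefined")
    if se_method not in ("first-order-delta", "second-order-delta", "fieller"):
        raise ValueError(f"unknown se_method {se_method!r}")
    weak = se_gx > 0 and abs(beta_gx) / se_gx < 2
    if weak:
        warnings.warn(
            f"{snp}: |beta_gx|/se_gx = {abs(beta_gx) / se_gx:.2f} < 2 — weak instrument, "
            "ratio CI may be unreliable (consider se_method='fieller')"
        )

    point = scale_sd * log_gy / beta_gx
    se_first = scale_sd * se_gy / abs(beta_gx)
    if se_method == "second-order-delta":
        se = float(np.sqrt(se_first**2 + (scale_sd * log_gy * se_gx / beta_gx**2) ** 2))
    else:
        se = se_first

    from scipy.stats import norm

    zq = norm.ppf(1 - alpha / 2)
    if se_method == "fieller":
        a, b_ = beta_gx, log_gy
        disc = a**2 * se_gy**2 + b_**2 * se_gx**2 - zq**2 * se_gx**2 * se_gy**2
        denom = a**2 - zq**2 * se_gx**2
        if denom <= 0 or disc < 0:
            warnings.warn(f"{snp}: Fieller interval unbounded (weak instrument)")
            lo, hi = -np.inf, np.inf
        else:
            centre = a * b_ / denom
            half = zq * np.sqrt(disc) / denom
            lo, hi = scale_sd * (centre - half), scale_sd * (centre + half)
            if lo > hi:
                lo, hi = hi, lo
    else:
        lo, hi = point - zq * se, point + zq * se

    return WaldEstimate(
        exposure=exposure,
        outcome=outcome,
        snp=snp,
        scale_sd=float(scale_sd),
        causal_log_effect=float(point),
        se=float(se),
        estimate=float(np.exp(point)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        se_method=se_method,
        components=(float(beta_gx), float(se_gx), float(log_gy), float(se_gy)),
        weak_instrument=bool(weak),
    )


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize(exposure: SummaryStat, outcome: SummaryStat) -> tuple[SummaryStat, SummaryStat, dict]:
    """Align the outcome record to the exposure record's effect allele.

    Handles identical orientation, swapped effect/other alleles (outcome
    effect sign flips, EAF complemented) and opposite-strand records
    (alleles complemented first). Strand-ambiguous (A/T, C/G) pairs are
    aligned by letter but flagged, since strand cannot be resolved from
    alleles alone.

    Returns (exposure, aligned outcome, flags) where flags has keys
    `flipped` and `palindromic`.
    """
    e_ea, e_oa = exposure.effect_allele.upper(), exposure.other_allele.upper()
    o_ea, o_oa = outcome.effect_allele.upper(), outcome.other_allele.upper()
    flags = {"flipped": False, "palindromic": _is_palindromic(e_ea, e_oa)}
    if flags["palindromic"]:
        warnings.warn(f"{exposure.snp}: strand-ambiguous (palindromic) alleles")

    if (o_ea, o_oa) == (e_ea, e_oa):
        return exposure, outcome, flags
    if (o_ea, o_oa) == (e_oa, e_ea):
        flags["flipped"] = True
    else:
        # try the complementary strand
        c_ea, c_oa = _COMPLEMENT.get(o_ea), _COMPLEMENT.get(o_oa)
        if (c_ea, c_oa) == (e_ea, e_oa):
            pass  # same orientation, other strand
        elif (c_ea, c_oa) == (e_oa, e_ea):
            flags["flipped"] = True
        else:
            raise ValueError(
                f"{exposure.snp}: incompatible allele sets "
                f"{e_ea}/{e_oa} vs {o_ea}/{o_oa}"
            )
    if flags["flipped"]:
        outcome = SummaryStat(
            snp=outcome.snp,
            effect_allele=exposure.effect_allele,
            other_allele=exposure.other_allele,
            beta=-outcome.beta,
            se=outcome.se,
            eaf=None if outcome.eaf is None else 1.0 - outcome.eaf,
        )
    return exposure, outcome, flags


def mr_report(
    instruments: list[ExposureAssociation],
    pooled_outcomes: dict[tuple[str, str], tuple[float, float]],
    sd_table: dict[str, float],
    f_threshold: float = WEAK_INSTRUMENT_F,
    se_method: str = "first-order-delta",
) -> list[WaldEstimate]:
    """One Wald estimate per (strong instrument, exposure, outcome) triple.

    Parameters
    ----------
    instruments : validated gene-exposure associations.
    pooled_outcomes : (snp, outcome name) -> (log-effect, se), e.g. from
        meta-analysed per-study associations; log-HRs work identically.
    sd_table : exposure name -> SD used for scaling (external, never
        estimated from the outcome sample).

    Weak instruments (partial F below `f_threshold`) are excluded with a
    logged reason; estimates for different SNPs instrumenting the same
    exposure are reported separately, never pooled.
    """
    out: list[WaldEstimate] = []
    for assoc in instruments:
        if classify_instrument(assoc, threshold=f_threshold) == "weak":
            logger.info(
                "excluding %s as instrument for %s: F=%.2f < %.1f",
                assoc.snp, assoc.biomarker, assoc.f_stat, f_threshold,
            )
            continue
        if assoc.biomarker not in sd_table:
            logger.info("no SD available for exposure %s; skipped", assoc.biomarker)
            continue
        for (snp, outcome_name), (log_gy, se_gy) in pooled_outcomes.items():
            if snp != assoc.snp:
                continue
            out.append(
                wald_ratio(
                    beta_gx=assoc.beta,
                    se_gx=assoc.se,
                    log_gy=log_gy,
                    se_gy=se_gy,
                    scale_sd=sd_table[assoc.biomarker],
                    se_method=se_method,
                    exposure=assoc.biomarker,
                    outcome=outcome_name,
                    snp=assoc.snp,
                )
            )
    if not out:
        warnings.warn("no (strong instrument, outcome) pairs available for MR")
    return out
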