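"""Inverse-variance meta-analysis of per-study genotype-outcome estimates.

Fixed-effects pooling with Cochran Q / I² heterogeneity statistics, the
DerSimonian-Laird random-effects moment estimator (REML available), and
the heterogeneity-driven model-selection rule: fixed effects unless the
Q-test p-value is <= 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["MetaResult", "fixed_effects", "random_effects", "pool", "pool_table"]

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class MetaResult:
    est: float  # pooled log-effect
    se: float
    ci_low: float  # log scale
    ci_high: float
    q: float
    q_p: float
    i2: float  # percent, truncated at 0
    tau2: float
    model: str  # "fixed" | "random"
    k: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.i2 <= 100.0:
            raise ValueError("I2 must be a percentage in [0, 100]")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")

    @property
    def effect(self) -> float:
        """Pooled OR/HR."""
        return float(np.exp(self.est))

    def effect_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _check(estimates: Sequence[float], ses: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("no studies to pool")
    if b.shape != s.shape:
        raise ValueError("estimates and ses must have equal length")
    if (s <= 0).any() or not np.isfinite(s).all() or not np.isfinite(b).all():
        raise ValueError("all estimates must be finite with positive ses")
    return b, s


def _heterogeneity(b: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    k = b.size
    pooled = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - pooled) ** 2))
    q_p = float(stats.chi2.sf(q, df=k - 1)) if k > 1 else 1.0
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    return q, q_p, i2


def fixed_effects(estimates: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """Inverse-variance fixed-effects pooling with Cochran Q and I²."""
    b, s = _check(estimates, ses)
    w = 1.0 / s**2
    pooled = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q, q_p, i2 = _heterogeneity(b, w)
    return MetaResult(
        est=pooled,
        se=se,
        ci_low=pooled - Z95 * se,
        ci_high=pooled + Z95 * se,
        q=q,
        q_p=q_p,
        i2=i2,
        tau2=0.0,
        model="fixed",
        k=int(b.size),
    )


def _tau2_dl(b: np.ndarray, s: np.ndarray) -> float:
    w = 1.0 / s**2
    q, _, _ = _heterogeneity(b, w)
    k = b.size
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0


def _tau2_reml(b: np.ndarray, s: np.ndarray) -> float:
    def neg_restricted_ll(tau2: float) -> float:
        v = s**2 + tau2
        w = 1.0 / v
        mu = np.sum(w * b) / np.sum(w)
        return 0.5 * (np.sum(np.log(v)) + np.log(np.sum(w)) + np.sum(w * (b - mu) ** 2))

    upper = max(10.0 * np.var(b), 1e-6)
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, upper), method="bounded")
    return float(max(0.0, res.x))


def random_effects(
    estimates: Sequence[float], ses: Sequence[float], method: str = "dl"
) -> MetaResult:
    """Random-effects pooling.

    `method="dl"` (default) uses the DerSimonian-Laird moment estimator of
    the between-study variance tau²; `method="reml"` maximises the
    restricted likelihood instead. Q, its p-value and I² are computed with
    fixed-effects weights, as usual.
    """
    b, s = _check(estimates, ses)
    if b.size < 2:
        raise ValueError("random-effects pooling needs >= 2 studies")
    if method == "dl":
        tau2 = _tau2_dl(b, s)
    elif method == "reml":
        tau2 = _tau2_reml(b, s)
    else:
        raise ValueError("method must be 'dl' or 'reml'")
    q, q_p, i2 = _heterogeneity(b, 1.0 / s**2)
    w_star = 1.0 / (s**2 + tau2)
    pooled = float(np.sum(w_star * b) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    return MetaResult(
        est=pooled,
        se=se,
        ci_low=pooled - Z95 * se,
        ci_high=pooled + Z95 * se,
        q=q,
        q_p=q_p,
        i2=i2,
        tau2=float(tau2),
        model="random",
        k=int(b.size),
    )


def pool(per_study: pd.DataFrame, het_p_threshold: float = 0.05, method: str = "dl") -> MetaResult:
    """Pool one SNP-outcome association across studies.

    Runs the fixed-effects model; when the heterogeneity p-value is at or
    below `het_p_threshold` (no evidence of homogeneity) the estimate is
    recomputed under the random-effects model, and the model actually used
    is recorded. Rows with missing or non-positive SEs are dropped with a
    warning rather than failing the pool.

    `per_study` needs columns beta and se; if outcome/coding columns are
    present they must be homogeneous.
    """
    df = per_study
    for col in ("outcome", "coding"):
        if col in df.columns and df[col].nunique() > 1:
            raise ValueError(f"cannot pool mixed {col} values: {sorted(df[col].unique())}")
    ok = df["se"].notna() & (df["se"] > 0) & df["beta"].notna()
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} studies with undefined estimates")
    df = df[ok]
    fe = fixed_effects(df["beta"].to_numpy(), df["se"].to_numpy())
    if fe.k >= 2 and fe.q_p <= het_p_threshold:
        return random_effects(df["beta"].to_numpy(), df["se"].to_numpy(), method=method)
    return fe


def pool_table(
    per_study: pd.DataFrame, het_p_threshold: float = 0.05, method: str = "dl"
) -> pd.DataFrame:
    """Pool every (snp, outcome) group in a per-study association table.

    Returns one row per group with the pooled ratio-scale effect, CI, p,
    heterogeneity statistics and the model used.
    """
    rows = []
    for (snp, outcome), grp in per_study.groupby(["snp", "outcome"], sort=False):
        m = pool(grp, het_p_threshold=het_p_threshold, method=method)
        lo, hi = m.effect_ci()
        rows.append(
            {
                "snp": snp,
                "outcome": outcome,
                "effect": m.effect,
                "ci_low": lo,
                "ci_high": hi,
                "log_effect": m.est,
                "se": m.se,
                "p": float(2 * stats.norm.sf(abs(m.est / m.se))),
                "q": m.q,
                "q_p": m.q_p,
                "i2_pct": m.i2,
                "tau2": m.tau2,
                "model": m.model,
                "k": m.k,
            }
        )
    return pd.DataFrame(rows)
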