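"""Genotype QC: allele accounting, Hardy-Weinberg testing, LD r² and genotype I/O.

Dosages are additive effect-allele counts in [0, 2]; fractional values are
allowed (imputed data). Missing dosages are encoded as NaN and skipped
pairwise by every operation here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HWEResult",
    "AlleleStats",
    "SNPRecord",
    "hwe_test",
    "hwe_exact_test",
    "hard_call_counts",
    "allele_stats",
    "ld_r2",
    "ld_matrix",
    "snp_qc_table",
    "read_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
]

#: fractional dosages further than this from an integer are not hard-callable
HARD_CALL_TOL = 0.1


class HWEResult(NamedTuple):
    chi2: float
    p: float
    monomorphic: bool = False


class AlleleStats(NamedTuple):
    eaf: float
    maf: float
    call_rate: float
    monomorphic: bool


@dataclass(frozen=True)
class SNPRecord:
    """Per-SNP QC summary."""

    id: str
    effect_allele: str
    other_allele: str
    eaf: float
    maf: float
    call_rate: float
    hwe_chi2: float
    hwe_p: float
    monomorphic: bool
    hwe_fail: bool

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")


def hwe_test(counts: Sequence[float]) -> HWEResult:
    """1-df chi-square goodness-of-fit test against Hardy-Weinberg proportions.

    Parameters
    ----------
    counts : (n_AA, n_Aa, n_aa)
        Genotype counts, where A is either allele (the statistic is
        symmetric in allele labelling).

    Returns
    -------
    HWEResult
        chi2 statistic, upper-tail p-value, monomorphic flag. A monomorphic
        marker returns ``chi2=0, p=1, monomorphic=True``.
    """
    n_aa_, n_ab, n_bb = (float(c) for c in counts)
    if min(n_aa_, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_ + n_ab + n_bb
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p_hat = (2.0 * n_aa_ + n_ab) / (2.0 * n)
    if p_hat in (0.0, 1.0):
        return HWEResult(0.0, 1.0, True)
    q_hat = 1.0 - p_hat
    expected = np.array([n * p_hat**2, 2.0 * n * p_hat * q_hat, n * q_hat**2])
    observed = np.array([n_aa_, n_ab, n_bb])
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return HWEResult(chi2, float(stats.chi2.sf(chi2, df=1)), False)


def hwe_exact_test(counts: Sequence[int]) -> HWEResult:
    """Exact Hardy-Weinberg test (sum of probabilities <= observed).

    Preferred over the chi-square test for rare variants where expected
    cell counts are small. Statistic field of the result is NaN.
    """
    n_aa_, n_ab, n_bb = (int(round(c)) for c in counts)
    if min(n_aa_, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_ + n_ab + n_bb
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    n_rare = 2 * min(n_aa_, n_bb) + n_ab
    if n_rare == 0:
        return HWEResult(math.nan, 1.0, True)

    # P(n_het | n, n_rare) over all heterozygote counts with the same parity
    def log_prob(het: int) -> float:
        hom_r = (n_rare - het) // 2
        hom_c = n - hom_r - het
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_r + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_c + 1)
            + het * math.log(2.0)
            + math.lgamma(n_rare + 1)
            + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    log_probs = {h: log_prob(h) for h in hets}
    m = max(log_probs.values())
    total = sum(math.exp(v - m) for v in log_probs.values())
    obs = log_probs[n_ab]
    p = sum(math.exp(v - m) for v in log_probs.values() if v <= obs + 1e-12) / total
    return HWEResult(math.nan, min(1.0, p), False)


def hard_call_counts(dosages: np.ndarray, tol: float = HARD_CALL_TOL) -> tuple[int, int, int]:
    """Genotype counts (n2, n1, n0 effect-allele copies) from hard-callable dosages.

    Fractional dosages further than `tol` from an integer are excluded:
    HWE on posterior dosages is ill-defined, so the test runs on the
    confidently-called subset only.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    rounded = np.round(d)
    keep = np.abs(d - rounded) < tol
    calls = rounded[keep].astype(int)
    return int(np.sum(calls == 2)), int(np.sum(calls == 1)), int(np.sum(calls == 0))


def allele_stats(dosages: np.ndarray) -> AlleleStats:
    """Effect-allele frequency, MAF, call rate and monomorphism from dosages.

    eaf = mean(dosage)/2 over non-missing entries (missing = NaN).
    """
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise ValueError("empty dosage vector")
    ok = ~np.isnan(d)
    if not ok.any():
        raise ValueError("all dosages missing")
    obs = d[ok]
    if obs.min() < 0 or obs.max() > 2:
        raise ValueError("dosages must lie in [0, 2]")
    eaf = float(obs.mean() / 2.0)
    maf = min(eaf, 1.0 - eaf)
    mono = bool(np.all(obs == obs[0]))
    return AlleleStats(eaf, maf, float(ok.mean()), mono)


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Composite LD between two markers: squared Pearson correlation of dosages.

    Symmetric and invariant to allele flipping (replacing a vector v by
    2 - v leaves r² unchanged). Computed on pairwise-complete entries.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("need at least two complete pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("monomorphic marker: LD r2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_matrix(dosages: pd.DataFrame) -> pd.DataFrame:
    """Pairwise LD r² matrix for all marker columns."""
    cols = dosages.columns
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for cj in cols[i + 1 :]:
            r2 = ld_r2(dosages[ci].to_numpy(), dosages[cj].to_numpy())
            out.loc[ci, cj] = out.loc[cj, ci] = r2
    return out


def snp_qc_table(
    dosages: pd.DataFrame,
    snp_info: pd.DataFrame | None = None,
    hwe_threshold: float = 0.0,
    exact: bool = False,
) -> pd.DataFrame:
    """QC summary per SNP column: allele stats plus the HWE test.

    Markers violating HWE are *flagged*, not dropped — exclusion is the
    caller's decision via `hwe_threshold` (0 disables flagging).

    Parameters
    ----------
    dosages : DataFrame
        individuals x SNPs, NaN = missing.
    snp_info : DataFrame, optional
        indexed by SNP id with columns effect_allele / other_allele.
    hwe_threshold : float
        `hwe_fail` is set where hwe_p < threshold.
    exact : bool
        use the exact HWE test instead of chi-square.
    """
    rows = []
    for snp in dosages.columns:
        d = dosages[snp].to_numpy(dtype=float)
        st = allele_stats(d)
        counts = hard_call_counts(d)
        hwe = (hwe_exact_test if exact else hwe_test)((counts[0], counts[1], counts[2]))
        ea, oa = "E", "O"
        if snp_info is not None and snp in snp_info.index:
            ea = str(snp_info.loc[snp, "effect_allele"])
            oa = str(snp_info.loc[snp, "other_allele"])
        rows.append(
            SNPRecord(
                id=str(snp),
                effect_allele=ea,
                other_allele=oa,
                eaf=st.eaf,
                maf=st.maf,
                call_rate=st.call_rate,
                hwe_chi2=hwe.chi2,
                hwe_p=hwe.p,
                monomorphic=st.monomorphic or hwe.monomorphic,
                hwe_fail=bool(hwe.p < hwe_threshold),
            )
        )
    return pd.DataFrame([vars(r) for r in rows]).set_index("id")


# ---------------------------------------------------------------------------
# I/O


def read_vcf(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read genotypes from a VCF into a dosage table.

    The DS FORMAT field (imputed dosage of the ALT allele) is preferred when
    present; otherwise dosages are hard calls from GT. The ALT allele is
    taken as the effect allele.

    Returns
    -------
    (dosages, snp_info)
        dosages: individuals x SNPs DataFrame (NaN = missing);
        snp_info: per-SNP effect_allele / other_allele, indexed by id.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    dosage_cols: dict[str, np.ndarray] = {}
    info_rows = []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(len(samples))
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            col = np.full(len(samples), np.nan)
            for i, gt in enumerate(var.genotypes):
                alleles = gt[:-1]
                if -1 not in alleles:
                    col[i] = float(sum(alleles))
        dosage_cols[vid] = col
        info_rows.append(
            {"id": vid, "effect_allele": var.ALT[0] if var.ALT else ".", "other_allele": var.REF}
        )
    dosages = pd.DataFrame(dosage_cols, index=samples)
    snp_info = pd.DataFrame(info_rows).set_index("id")
    return dosages, snp_info


def read_dosage_tsv(path: str) -> pd.DataFrame:
    """Read the TSV dosage dialect: first column sample id, one column per SNP."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = [c for c in df.columns if ((df[c] < 0) | (df[c] > 2)).any()]
    if bad:
        raise ValueError(f"dosages outside [0, 2] in columns: {bad}")
    return df


def write_dosage_tsv(dosages: pd.DataFrame, path: str) -> None:
    dosages.to_csv(path, sep="\t", index_label="sample_id")
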