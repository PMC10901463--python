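"""eQTL-GWAS direction concordance and enrichment statistics.

If a screen hit's expression level causally affects pigmentation, alleles
that raise its expression should shift skin color in a consistent direction:
the sign of the lead melanocyte-eQTL slope should agree with the sign of the
same allele's GWAS skin-color effect (positive beta = darker). This module
selects lead eQTLs, harmonizes alleles between the two summary sets, tests
sign agreement with an exact binomial test, computes 2x2 Fisher enrichments,
and relates PBS-scan significance to GWAS effect sizes via Spearman
correlation and a stratified rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("melscreen")

__all__ = [
    "ConcordanceResult", "StratifiedTestResult",
    "select_lead_eqtl", "harmonize_and_filter", "sign_concordance_test",
    "binomial_two_sided", "fisher_enrichment",
    "pbs_gwas_correlation", "pbs_gwas_stratified",
]

AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def select_lead_eqtl(records: pd.DataFrame, p_cut: float = 0.01) -> pd.DataFrame:
    """Pick at most one lead eQTL per gene.

    Keeps records with ``p < p_cut``, then per gene takes the minimum p,
    breaking ties by smaller |distance| to the gene, then by (chrom, pos).
    Genes with no qualifying record are dropped.
    """
    df = records[records["p"] < p_cut].copy()
    if df.empty:
        return df
    df["_absdist"] = df["distance"].abs()
    df = df.sort_values(["gene_id", "p", "_absdist", "chrom", "pos"],
                        kind="mergesort")
    lead = df.groupby("gene_id", as_index=False).head(1).drop(columns="_absdist")
    return lead.reset_index(drop=True)


def harmonize_and_filter(eqtl: pd.DataFrame, gwas: pd.DataFrame,
                         gwas_p_cut: float = 0.01) -> pd.DataFrame:
    """Join eQTL and GWAS records on SNP and put both effects on one allele.

    If the GWAS effect allele is the eQTL's other allele (and vice versa),
    the GWAS beta sign is flipped; strand-ambiguous pairs (A/T, C/G) and
    pairs whose alleles match neither orientation are dropped with a logged
    count. Records are then filtered to ``gwas_p < gwas_p_cut``.

    Returns the harmonized EffectPair table: gene_id, snp_id, effect_allele,
    other_allele, eqtl_slope, eqtl_p, gwas_beta, gwas_p, harmonized.
    """
    merged = eqtl.merge(gwas, on="snp_id", suffixes=("_eqtl", "_gwas"))
    rows = []
    n_ambiguous = n_mismatch = 0
    for _, r in merged.iterrows():
        ea_e, oa_e = r["effect_allele_eqtl"], r["other_allele_eqtl"]
        ea_g, oa_g = r["effect_allele_gwas"], r["other_allele_gwas"]
        if frozenset((ea_e, oa_e)) in AMBIGUOUS_PAIRS:
            n_ambiguous += 1
            continue
        if (ea_g, oa_g) == (ea_e, oa_e):
            beta = r["beta"]
        elif (ea_g, oa_g) == (oa_e, ea_e):
            beta = -r["beta"]
        else:
            n_mismatch += 1
            continue
        rows.append({
            "gene_id": r["gene_id"], "snp_id": r["snp_id"],
            "effect_allele": ea_e, "other_allele": oa_e,
            "eqtl_slope": r["slope"], "eqtl_p": r["p_eqtl"],
            "gwas_beta": beta, "gwas_p": r["p_gwas"],
            "harmonized": True,
        })
    if n_ambiguous or n_mismatch:
        log.info("harmonize_and_filter: dropped %d strand-ambiguous and %d "
                 "allele-mismatched pair(s)", n_ambiguous, n_mismatch)
    out = pd.DataFrame(rows, columns=["gene_id", "snp_id", "effect_allele",
                                      "other_allele", "eqtl_slope", "eqtl_p",
                                      "gwas_beta", "gwas_p", "harmonized"])
    return out[out["gwas_p"] < gwas_p_cut].reset_index(drop=True)


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p as twice the smaller tail, capped at 1."""
    if not 0 <= k <= n:
        raise ValueError("k out of range")
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return float(min(2.0 * min(lower, upper), 1.0))


@dataclass
class ConcordanceResult:
    """Sign-agreement summary between eQTL slopes and GWAS betas."""

    n_pairs: int
    n_agree: int
    binomial_p: float


def sign_concordance_test(pairs: pd.DataFrame) -> ConcordanceResult:
    """Exact binomial test of eQTL/GWAS sign agreement against 50%.

    Pairs where either effect is exactly zero are dropped (logged); with no
    testable pairs remaining an error is raised.
    """
    slope = pairs["eqtl_slope"].to_numpy(dtype=float)
    beta = pairs["gwas_beta"].to_numpy(dtype=float)
    nonzero = (slope != 0) & (beta != 0)
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        log.warning("sign_concordance_test: dropped %d pair(s) with a zero effect",
                    n_dropped)
    slope, beta = slope[nonzero], beta[nonzero]
    n = slope.size
    if n == 0:
        raise ValueError("no testable pairs")
    k = int(np.sum(np.sign(slope) == np.sign(beta)))
    return ConcordanceResult(n, k, binomial_two_sided(k, n))


def fisher_enrichment(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher exact p for a 2x2 table.

    Layout: a = hits with property, b = hits without, c = non-hits with,
    d = non-hits without. OR = (a*d)/(b*c), reported as inf when b*c = 0
    with a*d > 0 and as NaN for 0/0. The p-value sums hypergeometric
    outcomes no more probable than the observed table.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("negative cell count")
    if b * c > 0:
        oddsr = (a * d) / (b * c)
    elif a * d > 0:
        oddsr = np.inf
    else:
        oddsr = np.nan
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(oddsr), float(p)


def pbs_gwas_correlation(join: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation between PBS significance and GWAS effect size.

    ``join`` needs columns pbs_neglogp (-log10 of the PBS empirical p) and
    gwas_beta. Midrank tie handling; p by the t approximation. Constant
    input on either axis gives (nan, nan) with a warning.
    """
    x = join["pbs_neglogp"].to_numpy(dtype=float)
    y = join["gwas_beta"].to_numpy(dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 SNPs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("pbs_gwas_correlation: constant input, correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class StratifiedTestResult:
    """Rank-sum comparison of GWAS betas between PBS-significance strata."""

    n_low_p: int
    n_high_p: int
    median_low_p: float
    median_high_p: float
    statistic: float
    p_value: float


def pbs_gwas_stratified(join: pd.DataFrame, pbs_p_cut: float = 0.01) -> StratifiedTestResult:
    """Two-sided Wilcoxon rank-sum test of GWAS betas across PBS strata.

    SNPs are split on PBS empirical p below vs at/above ``pbs_p_cut``
    (column ``pbs_p``, or derived from ``pbs_neglogp``); the normal
    approximation with tie correction and continuity correction is used.
    """
    if "pbs_p" in join.columns:
        p = join["pbs_p"].to_numpy(dtype=float)
    else:
        p = 10.0 ** (-join["pbs_neglogp"].to_numpy(dtype=float))
    beta = join["gwas_beta"].to_numpy(dtype=float)
    low = beta[p < pbs_p_cut]
    high = beta[p >= pbs_p_cut]
    if low.size == 0:
        raise ValueError(f"empty stratum: no SNPs with PBS p < {pbs_p_cut}")
    if high.size == 0:
        raise ValueError(f"empty stratum: no SNPs with PBS p >= {pbs_p_cut}")
    res = stats.mannwhitneyu(low, high, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return StratifiedTestResult(
        n_low_p=int(low.size), n_high_p=int(high.size),
        median_low_p=float(np.median(low)), median_high_p=float(np.median(high)),
        statistic=float(res.statistic), p_value=float(res.pvalue))
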