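"""Population-branch-statistic selection scan.

Per SNP, pairwise differentiation between three populations is measured with
Hudson's F_ST estimator, transformed to additive branch lengths
``T = -ln(1 - F)``, and combined into the population branch statistic for a
target population A,

    PBS_A = (T_AB + T_AC - T_BC) / 2,

which is large when the allele-frequency change is specific to A's history.
Genome-wide empirical p-values and top-quantile flags identify candidate
selected SNPs, which can be assigned to genes via +/-100 kb windows around
gene bodies.

The log base of T rescales PBS monotonically and leaves ranks, quantiles and
empirical p-values unchanged; natural log is used. Negative F estimates are
clamped to 0 and fixation to 1 - 1e-6 before the log, keeping T finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger("melscreen")

__all__ = [
    "FstResult", "hudson_fst", "branch_length", "compute_pbs",
    "genome_quantile_flags", "empirical_pbs_pvalue",
    "make_gene_windows", "annotate_gene_windows",
]

F_CLAMP_HI = 1.0 - 1e-6
POPS = ("A", "B", "C")
QUANTILE_LEVELS = (1e-4, 1e-3)


@dataclass
class FstResult:
    """Hudson F_ST estimate for one SNP and population pair."""

    raw: float        # ratio estimate, may be negative or exactly 1
    clamped: float    # in [0, 1 - 1e-6]
    numerator: float
    denominator: float
    monomorphic: bool = False


def hudson_fst(p1: float, n1: float, p2: float, n2: float) -> FstResult:
    """Hudson's F_ST for one SNP from two population allele frequencies.

    ``N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`` and
    ``D = p1(1-p2) + p2(1-p1)``; the ratio N/D is 0 when D = 0 (site
    monomorphic for the same allele in both populations, flagged).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("chromosome counts must be >= 2")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den > 0:
        raw = num / den
        mono = False
    else:
        raw = 0.0
        mono = True
    return FstResult(raw, float(np.clip(raw, 0.0, F_CLAMP_HI)), num, den, mono)


def _hudson_fst_arrays(p1, n1, p2, n2) -> np.ndarray:
    """Vectorized clamped Hudson F_ST."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    raw = np.divide(num, den, out=np.zeros_like(num, dtype=float), where=den > 0)
    return np.clip(raw, 0.0, F_CLAMP_HI)


def branch_length(F) -> np.ndarray | float:
    """Branch length ``T = -ln(1 - F)`` for clamped F in [0, 1)."""
    F = np.asarray(F, dtype=float)
    if np.any(F >= 1.0) or np.any(F < 0.0):
        raise ValueError("F must be in [0, 1); clamp upstream")
    out = -np.log1p(-F)
    return float(out) if out.ndim == 0 else out


def compute_pbs(freqs: pd.DataFrame, target: str = "A") -> pd.DataFrame:
    """Per-SNP pairwise F_ST, branch lengths and PBS for the target population.

    Parameters
    ----------
    freqs:
        Table with chrom, pos, and ``p_K``/``n_K`` columns for K in A, B, C.
    target:
        Population whose branch is scored; the raw (possibly negative) PBS
        is retained.

    Rows with a missing frequency in any population are skipped (counted in
    the log). Output adds fst_ab, fst_ac, fst_bc, t_ab, t_ac, t_bc and pbs.
    """
    if target not in POPS:
        raise ValueError(f"target must be one of {POPS}")
    required = [c for k in POPS for c in (f"p_{k}", f"n_{k}")]
    missing_cols = [c for c in required if c not in freqs.columns]
    if missing_cols:
        raise ValueError(f"frequency table lacks columns: {missing_cols}")

    df = freqs.copy()
    complete = df[[f"p_{k}" for k in POPS]].notna().all(axis=1)
    n_skip = int((~complete).sum())
    if n_skip:
        log.info("compute_pbs: skipped %d SNP(s) with a missing population frequency",
                 n_skip)
        df = df[complete].reset_index(drop=True)

    p = {k: df[f"p_{k}"].to_numpy(dtype=float) for k in POPS}
    n = {k: df[f"n_{k}"].to_numpy(dtype=float) for k in POPS}
    fst = {}
    t = {}
    for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
        fst[a + b] = _hudson_fst_arrays(p[a], n[a], p[b], n[b])
        t[a + b] = branch_length(fst[a + b])

    others = [k for k in POPS if k != target]
    def _t(x, y):
        return t[x + y] if x + y in t else t[y + x]
    pbs = (_t(target, others[0]) + _t(target, others[1]) - _t(*others)) / 2.0

    for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
        df[f"fst_{a.lower()}{b.lower()}"] = fst[a + b]
        df[f"t_{a.lower()}{b.lower()}"] = t[a + b]
    df["pbs"] = pbs
    return df


def empirical_pbs_pvalue(pbs_table: pd.DataFrame) -> pd.DataFrame:
    """Self-inclusive genome-wide rank p-value per SNP.

    ``p_i = #{j : PBS_j >= PBS_i} / N`` over the whole table, so the top SNP
    has p = 1/N and the minimum has p = 1.
    """
    if pbs_table.empty:
        raise ValueError("empty PBS table")
    df = pbs_table.copy()
    pbs = df["pbs"].to_numpy()
    df["p_emp"] = rankdata(-pbs, method="max") / pbs.size
    return df


def genome_quantile_flags(pbs_table: pd.DataFrame,
                          levels: tuple[float, ...] = QUANTILE_LEVELS) -> pd.DataFrame:
    """Flag SNPs in the top genome-wide PBS quantiles (ties included).

    For level q the threshold is the ceil(q*N)-th largest PBS; every SNP
    with PBS >= threshold is flagged. Column names: ``flag_1e4`` for 1e-4,
    ``flag_1e3`` for 1e-3 (generally the level in short scientific form).
    """
    if pbs_table.empty:
        raise ValueError("empty PBS table")
    df = pbs_table.copy()
    pbs = df["pbs"].to_numpy()
    n = pbs.size
    srt = np.sort(pbs)[::-1]
    for level in levels:
        k = max(int(np.ceil(level * n)), 1)
        thr = srt[min(k, n) - 1]
        name = f"flag_{level:.0e}".replace("e-0", "e").replace("e-", "e")
        df[name] = pbs >= thr
    return df


# ---------------------------------------------------------------------------
# Gene windows
# ---------------------------------------------------------------------------

def make_gene_windows(genes: pd.DataFrame, flank: int = 100_000) -> pd.DataFrame:
    """Build +/-flank windows around gene bodies (1-based, closed, clipped at 1).

    Input columns: gene_id, chrom, start, end (1-based inclusive).
    """
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene start after end")
    out = genes.copy()
    out["window_start"] = np.maximum(out["start"] - flank, 1)
    out["window_end"] = out["end"] + flank
    return out


def annotate_gene_windows(pbs_table: pd.DataFrame,
                          windows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign SNPs to every gene window containing them (closed intervals).

    Returns ``(snp_gene, per_gene)``: the first has one row per (SNP, gene)
    assignment; the second summarizes max PBS and min empirical p per gene.
    Raises if the two tables share no chromosome naming.
    """
    snp_chroms = set(pbs_table["chrom"].astype(str))
    win_chroms = set(windows["chrom"].astype(str))
    if snp_chroms.isdisjoint(win_chroms):
        raise ValueError(
            f"no shared chromosomes between SNPs ({sorted(snp_chroms)[:5]}) "
            f"and windows ({sorted(win_chroms)[:5]})")

    pieces = []
    for chrom, wchrom in windows.groupby(windows["chrom"].astype(str)):
        snps = pbs_table[pbs_table["chrom"].astype(str) == chrom]
        if snps.empty:
            continue
        pos = snps["pos"].to_numpy()
        for _, w in wchrom.iterrows():
            inside = (pos >= w["window_start"]) & (pos <= w["window_end"])
            if inside.any():
                sub = snps.loc[inside].copy()
                sub["gene_id"] = w["gene_id"]
                pieces.append(sub)
    if pieces:
        snp_gene = pd.concat(pieces, ignore_index=True)
        agg = {"pbs": "max"}
        if "p_emp" in snp_gene.columns:
            agg["p_emp"] = "min"
        per_gene = (snp_gene.groupby("gene_id").agg(n_snps=("pos", "size"), **{
            "max_pbs": pd.NamedAgg("pbs", "max"),
            **({"min_p_emp": pd.NamedAgg("p_emp", "min")} if "p_emp" in snp_gene else {}),
        }).reset_index())
    else:
        snp_gene = pbs_table.iloc[0:0].copy()
        snp_gene["gene_id"] = pd.Series(dtype=str)
        per_gene = pd.DataFrame(columns=["gene_id", "n_snps", "max_pbs"])
    return snp_gene, per_gene
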