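"""Expression-melanin correlation screening.

Correlates each screen-hit gene's expression (TPM) across donor melanocyte
samples with the samples' melanin content (OD400), assigns
Benjamini-Hochberg q-values to the two-sided Spearman p-values, and labels
genes positively correlated, negatively correlated, or not significant at
q < 0.1. Genes must be "measurable" — TPM > 0 in every sample — to enter
the test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("melscreen")

__all__ = [
    "filter_measurable", "correlate_expression_melanin", "classify_hits",
    "implied_rho_cutoff",
]


def filter_measurable(expr: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with TPM > 0 in every sample (rows = genes)."""
    keep = (expr > 0).all(axis=1)
    removed = int((~keep).sum())
    if removed:
        log.info("filter_measurable: removed %d gene(s) with a zero sample", removed)
    out = expr.loc[keep]
    if out.empty:
        raise ValueError("no measurable genes remain")
    return out


def correlate_expression_melanin(expr: pd.DataFrame, melanin: pd.DataFrame,
                                 exact: bool = False) -> pd.DataFrame:
    """Per-gene Spearman correlation with melanin content plus BH q-values.

    Parameters
    ----------
    expr:
        Genes x samples TPM matrix (index = gene ids, columns = sample ids).
    melanin:
        DataFrame with columns sample, od400; the sample set must equal the
        expression columns.
    exact:
        Use an exact permutation p-value instead of the default t
        approximation with n - 2 degrees of freedom (midrank ties either
        way). The approximation is accurate at the n = 30 scale of donor
        panels.

    Returns a DataFrame (gene_id, rho, p, q). Constant genes get NaN rho
    and p = 1 (never significant), with a warning.
    """
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    mel = melanin.set_index("sample")["od400"]
    if set(mel.index) != set(expr.columns):
        raise ValueError("melanin sample set does not match expression columns")
    m = mel.reindex(expr.columns).to_numpy(dtype=float)

    rhos = np.empty(len(expr))
    ps = np.empty(len(expr))
    n_constant = 0
    for i, (_, row) in enumerate(expr.iterrows()):
        x = row.to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(m == m[0]):
            rhos[i], ps[i] = np.nan, 1.0
            n_constant += 1
            continue
        if exact:
            res = stats.permutation_test(
                (x,), lambda xs: stats.spearmanr(xs, m).statistic,
                permutation_type="pairings", n_resamples=9999,
                alternative="two-sided", rng=0)
            rhos[i], ps[i] = stats.spearmanr(x, m).statistic, res.pvalue
        else:
            rho, p = stats.spearmanr(x, m)
            rhos[i], ps[i] = rho, p
    if n_constant:
        log.warning("correlate_expression_melanin: %d constant gene(s), "
                    "rho undefined", n_constant)
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    return pd.DataFrame({"gene_id": expr.index, "rho": rhos, "p": ps, "q": q})


def classify_hits(correlations: pd.DataFrame, q_cut: float = 0.1) -> tuple[pd.DataFrame, dict]:
    """Label genes positive / negative / ns at the q threshold.

    ``positive`` requires q < q_cut and rho > 0 (strict inequalities);
    ``negative`` q < q_cut and rho < 0; everything else ``ns``. Returns the
    labeled table and a summary dict with counts and the positive fraction.
    """
    df = correlations.copy()
    sig = df["q"] < q_cut
    df["class"] = np.where(sig & (df["rho"] > 0), "positive",
                           np.where(sig & (df["rho"] < 0), "negative", "ns"))
    counts = df["class"].value_counts().to_dict()
    n = len(df)
    summary = {
        "n_genes": n,
        "n_positive": int(counts.get("positive", 0)),
        "n_negative": int(counts.get("negative", 0)),
        "n_ns": int(counts.get("ns", 0)),
        "fraction_positive": counts.get("positive", 0) / n if n else float("nan"),
    }
    return df, summary


def implied_rho_cutoff(n_samples: int, n_tests: int, n_rejected: int,
                       alpha: float = 0.1) -> float:
    """|rho| rejection boundary implied by a BH outcome, via the t approximation.

    With ``n_rejected`` of ``n_tests`` Spearman tests rejected by BH at
    level ``alpha``, the step-up p threshold is ``alpha * n_rejected /
    n_tests``; inverting the two-sided t approximation (df = n_samples - 2)
    gives the corresponding |rho| boundary.
    """
    if not 0 < n_rejected <= n_tests:
        raise ValueError("n_rejected must be in (0, n_tests]")
    df = n_samples - 2
    p_thresh = alpha * n_rejected / n_tests
    t = stats.t.ppf(1.0 - p_thresh / 2.0, df)
    return float(t / np.sqrt(df + t * t))
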