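"""Gene-effect estimation from two-bin sorted sgRNA counts.

The model follows the CasTLE approach to pooled-screen analysis: each
guide's observed log2 enrichment ``e`` between the low and high sort bins is
the guide's (unknown, uniformly distributed) fraction of the gene's true
effect theta plus measurement noise whose distribution is learned empirically
from negative-control guides. For theta != 0 the per-guide likelihood is the
convolution of the control null with a Uniform(0, theta) effect,

    p_theta(e) = (1/|theta|) * integral_0^theta p0(e - t) dt,

and a gene's effect is estimated by maximizing the summed log likelihood of
its guides over a theta grid. The likelihood-ratio score
``S = 2 (L(theta_hat) - L(0))`` measures confidence; an empirical FDR is
assigned by scoring pseudo-genes resampled from control guides, and hits are
genes with positive effect below the FDR threshold in every replicate.

Sign convention: ``e = log2(f_low / f_high)``, so a knockout that lowers the
melanin proxy (low side scatter) has a positive effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import CLASS_NONTARGETING, CLASS_SAFE, CLASS_TARGETING

log = logging.getLogger("melscreen")

__all__ = [
    "EnrichmentProfile", "NullDensity", "GeneEffectResult",
    "compute_enrichments", "fit_null_density", "estimate_gene_effect",
    "gene_effect_table", "estimate_fdr", "intersect_replicates",
    "analyze_replicate", "default_theta_grid",
]

CHI2_95_DF1 = 3.841  # chi-square(1) 95% quantile, CI cutoff
DENSITY_FLOOR = 1e-10


def default_theta_grid(span: float = 8.0, n: int = 401) -> np.ndarray:
    """Effect grid in log2 units, symmetric about and including 0."""
    return np.linspace(-span, span, n)


# ---------------------------------------------------------------------------
# Enrichments
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentProfile:
    """Per-guide log2 bin-frequency ratios, centered on control guides."""

    table: pd.DataFrame        # guide_id, gene_id, class, enrichment
    pseudocount: float
    center_offset: float       # median control enrichment that was subtracted
    center_class: str          # control class actually used for centering

    def gene_enrichments(self, gene_id: str) -> np.ndarray:
        t = self.table
        return t.loc[t["gene_id"] == gene_id, "enrichment"].to_numpy()

    def control_enrichments(self, classes: tuple[str, ...] = (CLASS_SAFE, CLASS_NONTARGETING)) -> np.ndarray:
        t = self.table
        return t.loc[t["class"].isin(classes), "enrichment"].to_numpy()


def compute_enrichments(records: pd.DataFrame, pseudocount: float = 0.5,
                        center: bool = True) -> EnrichmentProfile:
    """Compute centered per-guide log2 enrichments from a count table.

    ``e_i = log2((c_low_i + pc) / (N_low + pc*G)) - log2((c_high_i + pc) /
    (N_high + pc*G))`` with G the number of guides; the median enrichment of
    safe-targeting controls (falling back to non-targeting, then both pooled)
    is subtracted so controls center at zero.

    Parameters
    ----------
    records:
        DataFrame with columns guide_id, gene_id, class, count_low,
        count_high. Class is one of targeting/safe/nontargeting.
    pseudocount:
        Added to every count and, times G, to the bin totals; keeps all
        enrichments finite.
    center:
        Subtract the median control enrichment (requires control guides).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if records.empty:
        raise ValueError("empty guide record table")
    if records["guide_id"].duplicated().any():
        raise ValueError("duplicate guide_id in record table")
    counts_low = records["count_low"].to_numpy(dtype=float)
    counts_high = records["count_high"].to_numpy(dtype=float)
    if (counts_low < 0).any() or (counts_high < 0).any():
        raise ValueError("negative counts")
    n_low, n_high = counts_low.sum(), counts_high.sum()
    if n_low <= 0 or n_high <= 0:
        raise ValueError("both bin totals must be positive")
    g = len(records)
    e = (np.log2((counts_low + pseudocount) / (n_low + pseudocount * g))
         - np.log2((counts_high + pseudocount) / (n_high + pseudocount * g)))

    offset = 0.0
    used = "none"
    if center:
        cls = records["class"].to_numpy()
        for candidate in (CLASS_SAFE, CLASS_NONTARGETING, "pooled"):
            if candidate == "pooled":
                mask = np.isin(cls, (CLASS_SAFE, CLASS_NONTARGETING))
            else:
                mask = cls == candidate
            if mask.sum() > 0:
                offset = float(np.median(e[mask]))
                used = candidate
                break
        else:  # pragma: no cover - loop always breaks or falls through
            pass
        if used == "none":
            raise ValueError("centering requested but the table has no control guides")
        e = e - offset

    table = pd.DataFrame({
        "guide_id": records["guide_id"].to_numpy(),
        "gene_id": records["gene_id"].to_numpy(),
        "class": records["class"].to_numpy(),
        "enrichment": e,
    })
    return EnrichmentProfile(table, pseudocount, offset, used)


# ---------------------------------------------------------------------------
# Empirical null
# ---------------------------------------------------------------------------

@dataclass
class NullDensity:
    """Control-guide enrichment null as a floored kernel density on a grid."""

    grid: np.ndarray        # ascending abscissae
    density: np.ndarray     # p0 >= floor, trapezoid-normalized
    cdf: np.ndarray         # cumulative trapezoid of density
    bandwidth: float

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def pdf_at(self, x: np.ndarray) -> np.ndarray:
        """Interpolated density, floored outside the grid support."""
        return np.interp(x, self.grid, self.density,
                         left=DENSITY_FLOOR, right=DENSITY_FLOOR)

    def cdf_at(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.grid, self.cdf, left=0.0, right=1.0)


def fit_null_density(control_enrichments: np.ndarray, min_controls: int = 50,
                     n_grid: int = 512) -> NullDensity:
    """Fit the empirical null from control-guide enrichments.

    Gaussian KDE with Silverman's rule-of-thumb bandwidth
    ``h = 0.9 * min(sd, IQR/1.34) * n^(-1/5)``, evaluated on a uniform grid
    spanning the data range +/- 3h, renormalized by the trapezoid rule and
    floored at 1e-10 so out-of-range enrichments keep finite log-likelihood.
    """
    x = np.asarray(control_enrichments, dtype=float)
    if x.size < min_controls:
        raise ValueError(
            f"need >= {min_controls} control enrichments to fit a null "
            f"(got {x.size}); add controls or pool safe and non-targeting guides")
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * scale * x.size ** (-0.2)
    if not np.isfinite(h) or h <= 0:
        raise ValueError("degenerate control enrichments (zero bandwidth)")

    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, n_grid)
    kde = stats.gaussian_kde(x, bw_method=h / sd)
    dens = np.maximum(kde(grid), DENSITY_FLOOR)
    dens = dens / np.trapezoid(dens, grid)
    dens = np.maximum(dens, DENSITY_FLOOR)
    cdf = np.concatenate([[0.0], np.cumsum(np.diff(grid) * (dens[1:] + dens[:-1]) / 2.0)])
    return NullDensity(grid, dens, cdf, h)


# ---------------------------------------------------------------------------
# Gene-effect likelihood
# ---------------------------------------------------------------------------

def _loglik_matrix(e_mat: np.ndarray, mask: np.ndarray, null: NullDensity,
                   theta_grid: np.ndarray) -> np.ndarray:
    """Log-likelihood L(theta) for padded enrichment rows.

    ``e_mat`` is genes x max_guides with invalid cells masked out. Returns a
    genes x len(theta_grid) matrix of natural-log likelihood sums.

    For |theta| larger than one null-grid step the uniform-convolution
    integral uses the interpolated CDF difference; for smaller |theta| a
    two-point trapezoid of interpolated densities, which matches the plain
    null density continuously as theta -> 0.
    """
    e = np.where(mask, e_mat, 0.0)
    out = np.empty((e_mat.shape[0], theta_grid.size))
    cdf_e = null.cdf_at(e)
    pdf_e = null.pdf_at(e)
    step = null.step
    for j, th in enumerate(theta_grid):
        if th == 0.0:
            p = pdf_e
        elif abs(th) <= step:
            p = 0.5 * (pdf_e + null.pdf_at(e - th))
        else:
            p = (cdf_e - null.cdf_at(e - th)) / th
        p = np.maximum(p, DENSITY_FLOOR)
        out[:, j] = np.sum(np.log(p), axis=1, where=mask)
    return out


@dataclass
class GeneEffectResult:
    """Maximum-likelihood effect and confidence score for one gene."""

    gene_id: str
    effect: float        # theta_hat, log2 units
    score: float         # 2*(L(theta_hat) - L(0)) >= 0
    ci: tuple[float, float]
    n_guides: int


def _result_from_loglik(gene_id: str, ll: np.ndarray, theta_grid: np.ndarray,
                        n_guides: int) -> GeneEffectResult:
    i0 = int(np.argmin(np.abs(theta_grid)))
    best_ll = ll.max()
    # tie-break the argmax toward smaller |theta|
    near = np.isclose(ll, best_ll, rtol=0.0, atol=1e-12)
    cand = np.flatnonzero(near)
    i_hat = cand[np.argmin(np.abs(theta_grid[cand]))]
    score = max(2.0 * (ll[i_hat] - ll[i0]), 0.0)
    inside = 2.0 * (ll[i_hat] - ll) <= CHI2_95_DF1
    lo = float(theta_grid[np.flatnonzero(inside)[0]])
    hi = float(theta_grid[np.flatnonzero(inside)[-1]])
    return GeneEffectResult(gene_id, float(theta_grid[i_hat]), float(score),
                            (lo, hi), n_guides)


def estimate_gene_effect(gene_enrichments: np.ndarray, null: NullDensity,
                         theta_grid: np.ndarray | None = None,
                         gene_id: str = "") -> GeneEffectResult:
    """Estimate one gene's effect from its guides' enrichments.

    The theta grid must span 0; the profile-likelihood 95% interval collects
    grid points within the chi-square(1) cutoff of the maximum.
    """
    e = np.asarray(gene_enrichments, dtype=float).reshape(1, -1)
    if e.size == 0:
        raise ValueError("gene has no guides")
    if theta_grid is None:
        theta_grid = default_theta_grid()
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.min() > 0 or theta_grid.max() < 0:
        raise ValueError("theta grid must span 0")
    outside = (e < null.grid[0]) | (e > null.grid[-1])
    if outside.any():
        log.warning("%d enrichment(s) outside the null grid; floor density used",
                    int(outside.sum()))
    ll = _loglik_matrix(e, np.ones_like(e, dtype=bool), null, theta_grid)[0]
    return _result_from_loglik(gene_id, ll, theta_grid, e.size)


def _pack_rows(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    width = max(len(g) for g in groups)
    mat = np.zeros((len(groups), width))
    mask = np.zeros((len(groups), width), dtype=bool)
    for i, g in enumerate(groups):
        mat[i, :len(g)] = g
        mask[i, :len(g)] = True
    return mat, mask


def gene_effect_table(profile: EnrichmentProfile, null: NullDensity,
                      theta_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Score every targeted gene in a replicate.

    Returns a DataFrame (gene_id, effect, score, ci_lo, ci_hi, n_guides)
    with one row per targeting gene.
    """
    if theta_grid is None:
        theta_grid = default_theta_grid()
    t = profile.table
    targeting = t[t["class"] == CLASS_TARGETING]
    genes = targeting["gene_id"].unique()
    groups = [targeting.loc[targeting["gene_id"] == g, "enrichment"].to_numpy()
              for g in genes]
    mat, mask = _pack_rows(groups)
    ll = _loglik_matrix(mat, mask, null, theta_grid)
    rows = []
    for i, g in enumerate(genes):
        r = _result_from_loglik(g, ll[i], theta_grid, int(mask[i].sum()))
        rows.append((g, r.effect, r.score, r.ci[0], r.ci[1], r.n_guides))
    return pd.DataFrame(rows, columns=["gene_id", "effect", "score",
                                       "ci_lo", "ci_hi", "n_guides"])


# ---------------------------------------------------------------------------
# Empirical FDR
# ---------------------------------------------------------------------------

def estimate_fdr(results: pd.DataFrame, null: NullDensity,
                 control_enrichments: np.ndarray, n_pseudo: int | None = None,
                 seed: int = 0, threshold: float = 0.1,
                 theta_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Attach empirical FDR and hit flags to a gene-effect table.

    Pseudo-genes are built by resampling control enrichments with
    replacement, their guide counts drawn from the real genes' guide-count
    distribution, and scored with the same likelihood. For each score s,
    ``FDR(s) = [(#pseudo >= s)/n_pseudo] / [(#real >= s)/n_real]``, capped at
    1 and monotonized by a running minimum from the top score down. A hit
    needs a positive effect and FDR below the threshold.
    """
    if theta_grid is None:
        theta_grid = default_theta_grid()
    n_real = len(results)
    if n_real == 0:
        raise ValueError("empty result table")
    if n_pseudo is None:
        n_pseudo = 10 * n_real
    rng = np.random.default_rng(seed)
    controls = np.asarray(control_enrichments, dtype=float)
    guide_counts = results["n_guides"].to_numpy()
    pseudo_sizes = rng.choice(guide_counts, size=n_pseudo, replace=True)
    width = int(pseudo_sizes.max())
    mat = controls[rng.integers(0, controls.size, size=(n_pseudo, width))]
    mask = np.arange(width)[None, :] < pseudo_sizes[:, None]
    ll = _loglik_matrix(mat, mask, null, theta_grid)
    i0 = int(np.argmin(np.abs(theta_grid)))
    pseudo_scores = 2.0 * (ll.max(axis=1) - ll[:, i0])
    pseudo_scores = np.maximum(pseudo_scores, 0.0)

    scores = results["score"].to_numpy()
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    # counts at or above each real score
    n_pseudo_ge = np.searchsorted(np.sort(pseudo_scores), sorted_scores, side="left")
    n_pseudo_ge = pseudo_scores.size - n_pseudo_ge
    n_real_ge = np.arange(1, n_real + 1)
    # ties among real scores: all tied genes share the count at the last tie
    for i in range(n_real - 2, -1, -1):
        if sorted_scores[i] == sorted_scores[i + 1]:
            n_real_ge[i] = n_real_ge[i + 1]
    fdr_sorted = np.minimum((n_pseudo_ge / pseudo_scores.size) / (n_real_ge / n_real), 1.0)
    # BH-style monotonization: each gene gets the minimum FDR over all
    # thresholds at or below its score, so FDR is non-increasing in score
    fdr_sorted = np.minimum.accumulate(fdr_sorted[::-1])[::-1]
    fdr = np.empty(n_real)
    fdr[order] = fdr_sorted

    out = results.copy()
    out["fdr"] = fdr
    out["hit"] = (out["effect"] > 0) & (out["fdr"] < threshold)
    return out


def intersect_replicates(tables: list[pd.DataFrame], threshold: float = 0.1) -> pd.DataFrame:
    """Genes called as hits in every replicate, sorted by min score.

    Each table must come from :func:`estimate_fdr` over the same gene
    universe. A gene qualifies if it has positive effect and FDR below the
    threshold in all replicates; output is sorted by the minimum
    cross-replicate score, descending.
    """
    if len(tables) < 2:
        raise ValueError("need at least two replicate tables")
    universe = set(tables[0]["gene_id"])
    for t in tables[1:]:
        diff = universe.symmetric_difference(t["gene_id"])
        if diff:
            raise ValueError(f"gene universes differ between replicates: "
                             f"{sorted(diff)[:10]}")
    hit_sets = [set(t.loc[(t["effect"] > 0) & (t["fdr"] < threshold), "gene_id"])
                for t in tables]
    common = set.intersection(*hit_sets)
    rows = []
    for g in common:
        scores = [float(t.loc[t["gene_id"] == g, "score"].iloc[0]) for t in tables]
        effects = [float(t.loc[t["gene_id"] == g, "effect"].iloc[0]) for t in tables]
        rows.append((g, min(scores), float(np.mean(effects))))
    out = pd.DataFrame(rows, columns=["gene_id", "min_score", "mean_effect"])
    return out.sort_values("min_score", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# Per-replicate convenience pipeline
# ---------------------------------------------------------------------------

def analyze_replicate(records: pd.DataFrame, pseudocount: float = 0.5,
                      n_pseudo: int | None = None, seed: int = 0,
                      threshold: float = 0.1,
                      theta_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Full single-replicate analysis: enrichments -> null -> effects -> FDR."""
    profile = compute_enrichments(records, pseudocount=pseudocount)
    controls = profile.control_enrichments((CLASS_SAFE,))
    if controls.size < 50:
        controls = profile.control_enrichments()
    null = fit_null_density(controls)
    table = gene_effect_table(profile, null, theta_grid)
    return estimate_fdr(table, null, controls, n_pseudo=n_pseudo, seed=seed,
                        threshold=threshold, theta_grid=theta_grid)
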