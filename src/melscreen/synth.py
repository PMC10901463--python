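"""Synthetic-data generators with known ground truth.

Each generator emulates the statistical structure one pipeline stage assumes:

* :func:`simulate_screen` — sgRNA read counts in the low/high tails of a
  FACS side-scatter sort, where side scatter proxies cellular melanin.
  A knockout that lowers melanin shifts its guides toward the low bin, so a
  melanin-promoting gene has a positive log2(low/high) enrichment.
* :func:`simulate_three_pop_freqs` — three-population allele frequencies
  under Balding-Nichols drift with a handful of loci given an extra
  frequency shift in one target population (planted selection).
* :func:`simulate_eqtl_gwas_pairs` — sign-linked eQTL slopes and GWAS
  effect sizes with configurable discordance.
* :func:`simulate_expression_melanin` — a TPM matrix whose log-expression
  tracks per-sample melanin content (OD400) for a planted subset of genes.

All generators are deterministic given their config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenSimConfig", "PopSimConfig", "PairSimConfig", "ExprSimConfig",
    "SimulatedScreen",
    "simulate_screen", "simulate_three_pop_freqs",
    "simulate_eqtl_gwas_pairs", "simulate_expression_melanin",
]

CLASS_TARGETING = "targeting"
CLASS_SAFE = "safe"
CLASS_NONTARGETING = "nontargeting"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# ---------------------------------------------------------------------------
# FACS-sort screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Configuration of the sorted-screen count generator.

    Parameters
    ----------
    n_genes:
        Number of targeted genes.
    guides_per_gene:
        Guides per targeted gene (library design).
    n_safe_controls, n_nontargeting:
        Numbers of safe-targeting and non-targeting control guides; controls
        have zero true effect.
    effect_dist:
        Mapping gene_id -> true effect theta (log2 units). Positive theta
        means the knockout lowers side scatter, i.e. enriches in the low
        bin. Genes absent from the mapping get theta = 0.
    depth:
        Expected reads per guide per bin.
    dispersion:
        Negative-binomial overdispersion alpha (variance = mu + alpha*mu^2);
        0 gives Poisson counts.
    n_replicates:
        Independent biological replicates; theta is shared, per-guide
        efficacies and counts are redrawn.
    abundance_log2_sd:
        Lognormal spread of baseline guide abundance (library skew).
    seed:
        Seed for the generator.
    """

    n_genes: int
    n_safe_controls: int = 1000
    n_nontargeting: int = 0
    guides_per_gene: int = 10
    effect_dist: Mapping[str, float] = field(default_factory=dict)
    depth: float = 500.0
    dispersion: float = 0.1
    n_replicates: int = 2
    abundance_log2_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genes > 0, "n_genes must be positive")
        _require(self.guides_per_gene >= 1, "guides_per_gene must be >= 1")
        _require(self.n_safe_controls >= 0 and self.n_nontargeting >= 0,
                 "control counts must be non-negative")
        _require(self.depth > 0, "depth must be positive")
        _require(self.dispersion >= 0, "dispersion must be non-negative")
        _require(self.n_replicates >= 1, "n_replicates must be >= 1")


@dataclass
class SimulatedScreen:
    """Output bundle of :func:`simulate_screen`."""

    replicates: list[pd.DataFrame]   # guide_id, gene_id, class, count_low, count_high
    gene_truth: pd.DataFrame         # gene_id, theta_true
    guide_truth: pd.DataFrame        # replicate, guide_id, gene_id, efficacy


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial draws with mean mu and variance mu + alpha*mu^2."""
    if alpha == 0:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mu)
    return rng.poisson(lam)


def simulate_screen(cfg: ScreenSimConfig) -> SimulatedScreen:
    """Simulate per-replicate sorted-bin sgRNA count tables with ground truth.

    For guide *i* of gene *g* with efficacy ``u_i ~ Uniform(0,1)`` the
    expected log2 ratio of bin frequencies is ``u_i * theta_true(g)``;
    control guides have theta = 0. Counts are negative-binomial around the
    bin-specific expectations at the configured depth.
    """
    rng = np.random.default_rng(cfg.seed)

    gene_ids = [f"gene{j:05d}" for j in range(cfg.n_genes)]
    theta = np.array([float(cfg.effect_dist.get(g, 0.0)) for g in gene_ids])
    unknown = set(cfg.effect_dist) - set(gene_ids)
    _require(not unknown, f"effect_dist names unknown genes: {sorted(unknown)[:5]}")

    guide_gene: list[str] = []
    guide_theta: list[float] = []
    guide_class: list[str] = []
    for g, th in zip(gene_ids, theta):
        guide_gene += [g] * cfg.guides_per_gene
        guide_theta += [th] * cfg.guides_per_gene
        guide_class += [CLASS_TARGETING] * cfg.guides_per_gene
    guide_gene += [CLASS_SAFE] * cfg.n_safe_controls
    guide_theta += [0.0] * cfg.n_safe_controls
    guide_class += [CLASS_SAFE] * cfg.n_safe_controls
    guide_gene += [CLASS_NONTARGETING] * cfg.n_nontargeting
    guide_theta += [0.0] * cfg.n_nontargeting
    guide_class += [CLASS_NONTARGETING] * cfg.n_nontargeting

    n_guides = len(guide_gene)
    guide_ids = [f"sg{i:06d}" for i in range(n_guides)]
    theta_vec = np.asarray(guide_theta)

    replicates = []
    truth_rows = []
    for rep in range(cfg.n_replicates):
        u = rng.uniform(0.0, 1.0, size=n_guides)
        shift = u * theta_vec
        abundance = 2.0 ** rng.normal(0.0, cfg.abundance_log2_sd, size=n_guides)
        f_low = abundance * 2.0 ** (shift / 2.0)
        f_high = abundance * 2.0 ** (-shift / 2.0)
        f_low /= f_low.sum()
        f_high /= f_high.sum()
        total = cfg.depth * n_guides
        count_low = _nb_counts(rng, total * f_low, cfg.dispersion)
        count_high = _nb_counts(rng, total * f_high, cfg.dispersion)
        replicates.append(pd.DataFrame({
            "guide_id": guide_ids,
            "gene_id": guide_gene,
            "class": guide_class,
            "count_low": count_low.astype(np.int64),
            "count_high": count_high.astype(np.int64),
        }))
        truth_rows.append(pd.DataFrame({
            "replicate": rep,
            "guide_id": guide_ids,
            "gene_id": guide_gene,
            "efficacy": u,
        }))

    gene_truth = pd.DataFrame({"gene_id": gene_ids, "theta_true": theta})
    return SimulatedScreen(replicates, gene_truth, pd.concat(truth_rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Three-population allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class PopSimConfig:
    """Balding-Nichols three-population frequency generator settings.

    Per SNP an ancestral frequency p is drawn uniformly from
    ``ancestral_freq_range`` and each population's frequency from
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with its drift parameter F.
    ``n_selected`` loci additionally receive a ``selection_shift`` increment
    in ``target_pop``, then frequencies are clipped to
    ``[1/(2n), 1 - 1/(2n)]``.
    """

    n_snps: int
    drift_F: tuple[float, float, float] = (0.01, 0.01, 0.01)
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    n_selected: int = 0
    selection_shift: float = 0.0
    target_pop: str = "A"
    sample_n: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_snps > 0, "n_snps must be positive")
        _require(all(0 < f < 1 for f in self.drift_F), "drift_F values must be in (0,1)")
        lo, hi = self.ancestral_freq_range
        _require(0 < lo < hi < 1, "ancestral_freq_range must be within (0,1)")
        _require(0 <= self.n_selected <= self.n_snps, "n_selected out of range")
        _require(self.target_pop in ("A", "B", "C"), "target_pop must be A, B or C")
        _require(self.sample_n >= 2, "sample_n must be >= 2")


def simulate_three_pop_freqs(cfg: PopSimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate per-SNP allele frequencies for populations A, B, C.

    Returns the frequency table (chrom, pos, ref, alt, p_A, n_A, ...) and the
    integer indices of the planted selected loci.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_snps)

    eps = 1.0 / (2.0 * cfg.sample_n)
    freqs = {}
    for pop, F in zip(("A", "B", "C"), cfg.drift_F):
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        freqs[pop] = np.clip(rng.beta(a, b), eps, 1.0 - eps)

    selected = rng.choice(cfg.n_snps, size=cfg.n_selected, replace=False)
    selected.sort()
    if cfg.n_selected:
        shifted = freqs[cfg.target_pop][selected] + cfg.selection_shift
        freqs[cfg.target_pop][selected] = np.clip(shifted, eps, 1.0 - eps)

    alleles = np.array(["A", "C", "G", "T"])
    ref = rng.integers(0, 4, size=cfg.n_snps)
    alt = (ref + rng.integers(1, 4, size=cfg.n_snps)) % 4

    df = pd.DataFrame({
        "chrom": "1",
        "pos": np.arange(1, cfg.n_snps + 1) * 1000,
        "ref": alleles[ref],
        "alt": alleles[alt],
    })
    for pop in ("A", "B", "C"):
        df[f"p_{pop}"] = freqs[pop]
        df[f"n_{pop}"] = 2 * cfg.sample_n
    return df, selected


# ---------------------------------------------------------------------------
# eQTL x GWAS effect pairs
# ---------------------------------------------------------------------------

def _wald_p(effect: np.ndarray, se: float) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(effect) / se)


@dataclass
class PairSimConfig:
    """Sign-linked eQTL/GWAS effect-pair generator settings.

    Each gene gets a lead-eQTL slope ``~ Normal(0, slope_sd^2)``; its GWAS
    effect is ``beta = s * link * slope + Normal(0, noise_sd^2)`` where the
    sign ``s`` flips with probability ``discord_prob``. The default
    ``p_model="wald"`` derives two-sided normal p-values from the effect
    magnitudes with standard errors ``slope_sd/2`` and
    ``(|link|*slope_sd + noise_sd)/2``, so p decreases with |effect|.
    ``flip_frac`` of the GWAS rows report the other allele as effect allele
    (with beta negated), exercising downstream harmonization.
    """

    n_genes: int
    slope_sd: float = 1.0
    link: float = 1.0
    noise_sd: float = 0.1
    discord_prob: float = 0.0
    p_model: str | Callable[[np.ndarray, float], np.ndarray] = "wald"
    flip_frac: float = 0.3
    ambiguous_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genes > 0, "n_genes must be positive")
        _require(0.0 <= self.discord_prob <= 1.0, "discord_prob must be in [0,1]")
        _require(self.slope_sd > 0, "slope_sd must be positive")
        _require(self.noise_sd >= 0, "noise_sd must be non-negative")
        _require(0.0 <= self.flip_frac <= 1.0, "flip_frac must be in [0,1]")
        _require(0.0 <= self.ambiguous_frac <= 1.0, "ambiguous_frac must be in [0,1]")


def simulate_eqtl_gwas_pairs(
    cfg: PairSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate matched eQTL and GWAS summary tables plus a truth table.

    Returns ``(eqtl, gwas, truth)``. ``eqtl`` has one lead record per gene
    (gene_id, snp_id, effect_allele, other_allele, slope, p, distance, chrom,
    pos); ``gwas`` is keyed by snp_id with its own allele orientation; truth
    records the concordance sign per gene.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes

    slope = rng.normal(0.0, cfg.slope_sd, size=n)
    s = np.where(rng.uniform(size=n) < cfg.discord_prob, -1.0, 1.0)
    beta = s * cfg.link * slope + rng.normal(0.0, cfg.noise_sd, size=n)

    if callable(cfg.p_model):
        eqtl_p = cfg.p_model(slope, cfg.slope_sd)
        gwas_p = cfg.p_model(beta, abs(cfg.link) * cfg.slope_sd + cfg.noise_sd)
    elif cfg.p_model == "wald":
        eqtl_p = _wald_p(slope, cfg.slope_sd / 2.0)
        gwas_p = _wald_p(beta, (abs(cfg.link) * cfg.slope_sd + cfg.noise_sd) / 2.0)
    else:
        raise ValueError(f"unknown p_model {cfg.p_model!r}")

    # unambiguous allele pairs by default; optionally plant A/T and C/G pairs
    pairs = np.array([("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")])
    ambiguous = np.array([("A", "T"), ("C", "G")])
    idx = rng.integers(0, len(pairs), size=n)
    ea = pairs[idx, 0].copy()
    oa = pairs[idx, 1].copy()
    amb_mask = rng.uniform(size=n) < cfg.ambiguous_frac
    if amb_mask.any():
        aidx = rng.integers(0, len(ambiguous), size=amb_mask.sum())
        ea[amb_mask] = ambiguous[aidx, 0]
        oa[amb_mask] = ambiguous[aidx, 1]

    gene_id = [f"gene{j:05d}" for j in range(n)]
    snp_id = [f"rs{j:06d}" for j in range(n)]
    pos = np.arange(1, n + 1) * 10_000
    eqtl = pd.DataFrame({
        "gene_id": gene_id,
        "snp_id": snp_id,
        "effect_allele": ea,
        "other_allele": oa,
        "slope": slope,
        "p": eqtl_p,
        "distance": rng.integers(0, 100_000, size=n),
        "chrom": "1",
        "pos": pos,
    })

    flip = rng.uniform(size=n) < cfg.flip_frac
    gwas = pd.DataFrame({
        "snp_id": snp_id,
        "effect_allele": np.where(flip, oa, ea),
        "other_allele": np.where(flip, ea, oa),
        "beta": np.where(flip, -beta, beta),
        "p": gwas_p,
    })

    truth = pd.DataFrame({
        "gene_id": gene_id,
        "snp_id": snp_id,
        "slope_true": slope,
        "beta_true": beta,
        "discordant": s < 0,
        "gwas_flipped": flip,
        "ambiguous": amb_mask,
    })
    return eqtl, gwas, truth


# ---------------------------------------------------------------------------
# Expression x melanin
# ---------------------------------------------------------------------------

@dataclass
class ExprSimConfig:
    """Expression-vs-melanin generator settings.

    Per-sample melanin content m (OD400) is drawn from ``melanin_dist``
    (default Uniform(0.1, 2.0), the plausible absorbance range of cultured
    melanocyte lysates). For gene g,
    ``log2 TPM_gs = a_g + b_g * m_s + eps`` with ``eps ~ Normal(0,
    noise_sd^2)``; b_g is positive for a ``frac_positive`` share of genes,
    negative for ``frac_negative``, zero otherwise, with |b_g| half-normal
    scaled by ``slope_sd``.
    """

    n_genes: int = 158
    n_samples: int = 30
    frac_positive: float = 107 / 158
    frac_negative: float = 12 / 158
    slope_sd: float = 1.0
    noise_sd: float = 1.0
    melanin_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genes > 0 and self.n_samples > 0, "counts must be positive")
        _require(self.frac_positive >= 0 and self.frac_negative >= 0,
                 "fractions must be non-negative")
        _require(self.frac_positive + self.frac_negative <= 1.0,
                 "frac_positive + frac_negative must be <= 1")
        _require(self.noise_sd >= 0, "noise_sd must be non-negative")


def simulate_expression_melanin(
    cfg: ExprSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a TPM matrix, per-sample melanin OD400 and a truth table.

    Returns ``(tpm, melanin, truth)``: TPM as genes x samples DataFrame
    (strictly positive), melanin as (sample, od400), truth as (gene_id,
    slope_true, class_true).
    """
    rng = np.random.default_rng(cfg.seed)
    samples = [f"donor{j:02d}" for j in range(cfg.n_samples)]
    genes = [f"gene{j:05d}" for j in range(cfg.n_genes)]

    if cfg.melanin_dist is not None:
        m = np.asarray(cfg.melanin_dist(rng, cfg.n_samples), dtype=float)
    else:
        m = rng.uniform(0.1, 2.0, size=cfg.n_samples)
    _require(m.shape == (cfg.n_samples,), "melanin_dist returned wrong shape")
    _require(np.all(m >= 0), "melanin OD400 must be non-negative")

    n_pos = int(round(cfg.frac_positive * cfg.n_genes))
    n_neg = int(round(cfg.frac_negative * cfg.n_genes))
    sign = np.zeros(cfg.n_genes)
    sign[:n_pos] = 1.0
    sign[n_pos:n_pos + n_neg] = -1.0
    rng.shuffle(sign)

    b = sign * np.abs(rng.normal(0.0, cfg.slope_sd, size=cfg.n_genes))
    a = rng.normal(5.0, 2.0, size=cfg.n_genes)
    log2_tpm = (a[:, None] + b[:, None] * m[None, :]
                + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples)))
    tpm = pd.DataFrame(2.0 ** log2_tpm, index=pd.Index(genes, name="gene_id"),
                       columns=samples)

    melanin = pd.DataFrame({"sample": samples, "od400": m})
    cls = np.where(sign > 0, "positive", np.where(sign < 0, "negative", "ns"))
    truth = pd.DataFrame({"gene_id": genes, "slope_true": b, "class_true": cls})
    return tpm, melanin, truth
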