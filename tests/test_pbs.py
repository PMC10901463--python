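"""Hudson F_ST, branch lengths, PBS, quantile flags and gene windows."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from melscreen import pbs as pb


def _freq_table(pa, pb_, pc, n=200):
    m = len(pa)
    return pd.DataFrame({
        "chrom": "1", "pos": np.arange(1, m + 1) * 100,
        "ref": "A", "alt": "G",
        "p_A": pa, "n_A": n, "p_B": pb_, "n_B": n, "p_C": pc, "n_C": n,
    })


class TestHudson:
    def test_no_differentiation_clamps_to_zero(self):
        r = pb.hudson_fst(0.5, 100, 0.5, 100)
        assert r.raw < 0 and r.clamped == 0.0

    def test_hand_evaluated_value(self):
        # N = 0.36 - 2*0.16/99, D = 0.68  ->  0.52466
        r = pb.hudson_fst(0.8, 100, 0.2, 100)
        assert r.clamped == pytest.approx(0.52466, abs=1e-4)

    def test_fixation_clamped_below_one(self):
        r = pb.hudson_fst(1.0, 10_000, 0.0, 10_000)
        assert r.raw == pytest.approx(1.0, abs=1e-3)
        assert r.clamped == 1.0 - 1e-6

    def test_monomorphic_flag(self):
        r = pb.hudson_fst(0.0, 100, 0.0, 100)
        assert r.clamped == 0.0 and r.monomorphic

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            pb.hudson_fst(0.5, 1, 0.5, 100)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(p1=st.floats(0, 1), p2=st.floats(0, 1),
           n1=st.integers(2, 1000), n2=st.integers(2, 1000))
    def test_clamped_in_bounds_and_raw_le_one(self, p1, p2, n1, n2):
        r = pb.hudson_fst(p1, n1, p2, n2)
        assert 0.0 <= r.clamped <= 1.0 - 1e-6
        assert r.raw <= 1.0 + 1e-12


class TestBranchLength:
    @pytest.mark.parametrize("f,t", [(0.0, 0.0), (0.5, math.log(2)),
                                     (0.52466, 0.74369)])
    def test_values(self, f, t):
        assert pb.branch_length(f) == pytest.approx(t, abs=1e-4)

    def test_rejects_f_at_one(self):
        with pytest.raises(ValueError):
            pb.branch_length(1.0)


class TestPbs:
    def test_equal_frequencies_give_zero(self):
        df = pb.compute_pbs(_freq_table([0.3], [0.3], [0.3]))
        assert df["pbs"][0] == 0.0

    def test_target_specific_shift(self):
        # A diverged from B = C: T_AB = T_AC ~ 0.7437, T_BC = 0
        df = pb.compute_pbs(_freq_table([0.8], [0.2], [0.2], n=100))
        assert df["pbs"][0] == pytest.approx(0.7437, abs=1e-3)

    def test_symmetric_tree_gives_half_t(self):
        df = pb.compute_pbs(_freq_table([0.8], [0.2], [0.5], n=100))
        t_ab, t_ac, t_bc = df.loc[0, ["t_ab", "t_ac", "t_bc"]]
        assert df["pbs"][0] == pytest.approx((t_ab + t_ac - t_bc) / 2, abs=1e-12)

    def test_pbs_identity_from_stored_branches(self):
        rng = np.random.default_rng(0)
        df = pb.compute_pbs(_freq_table(rng.uniform(0.05, 0.95, 200),
                                        rng.uniform(0.05, 0.95, 200),
                                        rng.uniform(0.05, 0.95, 200)))
        recomputed = (df["t_ab"] + df["t_ac"] - df["t_bc"]) / 2
        np.testing.assert_allclose(df["pbs"], recomputed, atol=1e-12)

    def test_swapping_other_populations_leaves_pbs(self):
        rng = np.random.default_rng(1)
        pa, pb_, pc = (rng.uniform(0.05, 0.95, 50) for _ in range(3))
        a = pb.compute_pbs(_freq_table(pa, pb_, pc), target="A")
        b = pb.compute_pbs(_freq_table(pa, pc, pb_), target="A")
        np.testing.assert_allclose(a["pbs"], b["pbs"], atol=1e-12)

    def test_missing_frequency_skipped(self):
        t = _freq_table([0.2, 0.4], [0.2, 0.4], [0.2, 0.4])
        t.loc[0, "p_B"] = np.nan
        out = pb.compute_pbs(t)
        assert len(out) == 1 and out["pos"].iloc[0] == 200


class TestQuantilesAndP:
    def test_threshold_arithmetic(self):
        rng = np.random.default_rng(2)
        df = pb.compute_pbs(_freq_table(*[rng.uniform(0.05, 0.95, 20_000)
                                          for _ in range(3)]))
        out = pb.genome_quantile_flags(df)
        # level 1e-3 of 20,000: the 20th largest is the threshold
        thr = np.sort(df["pbs"].to_numpy())[::-1][19]
        assert out["flag_1e3"].sum() >= 20
        assert (out.loc[out["flag_1e3"], "pbs"] >= thr).all()

    def test_all_ties_flagged(self):
        df = _freq_table([0.3] * 10, [0.3] * 10, [0.3] * 10)
        out = pb.genome_quantile_flags(pb.compute_pbs(df))
        assert out["flag_1e3"].all() and out["flag_1e4"].all()

    def test_empirical_p_is_self_inclusive_rank(self):
        df = _freq_table([0.9, 0.5, 0.3, 0.2], [0.2] * 4, [0.2] * 4)
        out = pb.empirical_pbs_pvalue(pb.compute_pbs(df))
        assert sorted(out["p_emp"]) == pytest.approx([0.25, 0.5, 0.75, 1.0])
        assert out.loc[out["pbs"].idxmax(), "p_emp"] == 0.25
        assert out.loc[out["pbs"].idxmin(), "p_emp"] == 1.0

    def test_neutral_windows_match_genome_rate(self):
        """Under pure drift, window SNPs exceed the top-1e-3 cut at ~1e-3."""
        from melscreen.synth import PopSimConfig, simulate_three_pop_freqs
        freqs, _ = simulate_three_pop_freqs(PopSimConfig(n_snps=20_000, seed=9))
        out = pb.genome_quantile_flags(pb.compute_pbs(freqs))
        windows = pb.make_gene_windows(pd.DataFrame({
            "gene_id": ["g1", "g2"], "chrom": "1",
            "start": [1_000_000, 9_000_000], "end": [1_050_000, 9_100_000]}))
        snp_gene, _ = pb.annotate_gene_windows(out, windows)
        frac = snp_gene["flag_1e3"].mean()
        n = len(snp_gene)
        assert n > 100
        assert frac <= 1e-3 + 3 * np.sqrt(1e-3 * (1 - 1e-3) / n)


class TestWindows:
    windows = pb.make_gene_windows(pd.DataFrame({
        "gene_id": ["g1"], "chrom": "1", "start": [500_000], "end": [600_000]}))

    def _one_snp(self, pos):
        return pd.DataFrame({"chrom": "1", "pos": [pos], "pbs": [1.0]})

    def test_closed_boundary_included(self):
        snp_gene, _ = pb.annotate_gene_windows(self._one_snp(400_000), self.windows)
        assert len(snp_gene) == 1

    def test_outside_boundary_excluded(self):
        snp_gene, _ = pb.annotate_gene_windows(self._one_snp(399_999), self.windows)
        assert len(snp_gene) == 0

    def test_overlapping_windows_multi_assign(self):
        win2 = pb.make_gene_windows(pd.DataFrame({
            "gene_id": ["g1", "g2"], "chrom": "1",
            "start": [500_000, 550_000], "end": [600_000, 650_000]}))
        snp_gene, per_gene = pb.annotate_gene_windows(self._one_snp(560_000), win2)
        assert sorted(snp_gene["gene_id"]) == ["g1", "g2"]
        assert len(per_gene) == 2

    def test_chromosome_mismatch_errors(self):
        bad = self._one_snp(560_000).assign(chrom="chr1")
        with pytest.raises(ValueError, match="chromosome"):
            pb.annotate_gene_windows(bad, self.windows)


def test_pipeline_matches_brute_force_formulas():
    """Vectorized PBS equals a scalar re-evaluation of the printed formulas."""
    rng = np.random.default_rng(42)
    m = 250
    pa, pb_, pc = (rng.uniform(0.01, 0.99, m) for _ in range(3))
    df = pb.compute_pbs(_freq_table(pa, pb_, pc, n=120))

    def brute(p1, p2, n=120):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n - 1) - p2 * (1 - p2) / (n - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        f = num / den if den > 0 else 0.0
        return -math.log(1.0 - min(max(f, 0.0), 1 - 1e-6))

    expected = [(brute(a, b) + brute(a, c) - brute(b, c)) / 2
                for a, b, c in zip(pa, pb_, pc)]
    np.testing.assert_allclose(df["pbs"], expected, atol=1e-10)
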