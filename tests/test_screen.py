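"""Enrichment computation, empirical null, convolution likelihood, FDR."""

import numpy as np
import pandas as pd
import pytest

from melscreen import screen as sc
from melscreen.synth import CLASS_SAFE, CLASS_TARGETING


def _records(count_low, count_high, classes=None, genes=None):
    n = len(count_low)
    return pd.DataFrame({
        "guide_id": [f"g{i}" for i in range(n)],
        "gene_id": genes if genes is not None else [f"gene{i}" for i in range(n)],
        "class": classes if classes is not None else [CLASS_TARGETING] * n,
        "count_low": count_low,
        "count_high": count_high,
    })


class TestEnrichments:
    def test_symmetric_counts_give_zero(self):
        rec = _records([10] * 20, [10] * 20)
        prof = sc.compute_enrichments(rec, center=False)
        np.testing.assert_allclose(prof.table["enrichment"], 0.0, atol=1e-12)

    def test_closed_form_with_zero_high_count(self):
        # one guide 15 vs 0 among guides that keep both bin totals equal:
        # e = log2(15.5/0.5) = log2(31), uncentered
        rec = _records([15, 5, 10], [0, 20, 10])
        prof = sc.compute_enrichments(rec, pseudocount=0.5, center=False)
        assert prof.table["enrichment"][0] == pytest.approx(np.log2(31.0))

    def test_all_control_table_centers_to_zero_median(self):
        rng = np.random.default_rng(0)
        rec = _records(rng.integers(1, 100, 60), rng.integers(1, 100, 60),
                       classes=[CLASS_SAFE] * 60, genes=[CLASS_SAFE] * 60)
        prof = sc.compute_enrichments(rec)
        assert np.median(prof.table["enrichment"]) == pytest.approx(0.0, abs=1e-12)
        assert prof.center_class == CLASS_SAFE

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            sc.compute_enrichments(_records([], []))
        with pytest.raises(ValueError, match="control"):
            sc.compute_enrichments(_records([1, 2], [3, 4]), center=True)


class TestNullDensity:
    def test_kde_matches_normal_mode(self):
        rng = np.random.default_rng(1)
        null = sc.fit_null_density(rng.normal(size=10_000))
        assert null.density.max() == pytest.approx(0.3989, rel=0.2)

    def test_normalized_and_floored(self):
        rng = np.random.default_rng(2)
        null = sc.fit_null_density(rng.normal(size=500))
        assert np.trapezoid(null.density, null.grid) == pytest.approx(1.0, abs=1e-3)
        assert (null.density >= 1e-10).all()
        assert null.grid.size >= 512

    def test_degenerate_and_small_inputs_error(self):
        with pytest.raises(ValueError, match="bandwidth"):
            sc.fit_null_density(np.zeros(100))
        with pytest.raises(ValueError, match="50"):
            sc.fit_null_density(np.random.default_rng(3).normal(size=20))


class TestGeneEffect:
    def test_null_data_at_mode(self, normal_null):
        r = sc.estimate_gene_effect(np.zeros(10), normal_null)
        assert r.effect == 0.0
        assert r.score == pytest.approx(0.0, abs=1e-9)
        assert r.ci[0] < 0 < r.ci[1]

    def test_ten_guides_at_two(self, normal_null):
        # dense independent grid search of the uniform-convolution
        # likelihood puts the optimum at ~2.87
        r = sc.estimate_gene_effect(np.full(10, 2.0), normal_null,
                                    np.linspace(-8, 8, 1601))
        assert r.effect == pytest.approx(2.87, abs=0.1)
        assert r.score > 0

    def test_single_guide_wide_ci(self, normal_null):
        r = sc.estimate_gene_effect(np.array([0.0]), normal_null)
        assert r.ci[0] < -1 and r.ci[1] > 1 and r.ci[0] <= r.effect <= r.ci[1]

    def test_continuity_at_zero_width(self, normal_null):
        """L(theta) -> L(0) as theta -> 0 (guide at the null mode)."""
        e = np.zeros((1, 1))
        ll = sc._loglik_matrix(e, np.ones_like(e, bool), normal_null,
                               np.array([0.0, 1e-4]))
        assert abs(ll[0, 1] - ll[0, 0]) < 1e-6

    def test_translation_equivariance(self, normal_null):
        """Shifting data and null together leaves the score unchanged."""
        shift = 1.7
        shifted = sc.NullDensity(normal_null.grid + shift, normal_null.density,
                                 normal_null.cdf, normal_null.bandwidth)
        e = np.array([1.2, 0.4, 2.0, -0.3])
        r0 = sc.estimate_gene_effect(e, normal_null)
        r1 = sc.estimate_gene_effect(e + shift, shifted)
        assert r1.score == pytest.approx(r0.score, abs=1e-9)
        assert r1.effect == pytest.approx(r0.effect, abs=1e-9)

    def test_theta_grid_must_span_zero(self, normal_null):
        with pytest.raises(ValueError, match="span 0"):
            sc.estimate_gene_effect(np.ones(3), normal_null, np.linspace(1, 4, 10))


@pytest.fixture(scope="module")
def fitted(planted_screen):
    sim, effects = planted_screen
    prof = sc.compute_enrichments(sim.replicates[0])
    controls = prof.control_enrichments((CLASS_SAFE,))
    null = sc.fit_null_density(controls)
    table = sc.gene_effect_table(prof, null)
    return sim, effects, prof, controls, null, table


class TestFdr:
    def test_fdr_monotone_in_score(self, fitted):
        *_, controls, null, table = fitted
        res = sc.estimate_fdr(table, null, controls, seed=1)
        srt = res.sort_values("score", ascending=False)
        assert (np.diff(srt["fdr"]) >= -1e-12).all()
        assert res["fdr"].between(0, 1).all()

    def test_fdr_deterministic(self, fitted):
        *_, controls, null, table = fitted
        a = sc.estimate_fdr(table, null, controls, seed=5)
        b = sc.estimate_fdr(table, null, controls, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_recovery_of_planted_effects(self, fitted):
        """Median effect estimate within 20% of the planted theta = 2."""
        sim, effects, *_ , table = fitted
        planted = table[table["gene_id"].isin(effects)]
        assert np.median(planted["effect"]) == pytest.approx(2.0, rel=0.2)

    def test_planted_genes_dominate_hits(self, fitted):
        sim, effects, prof, controls, null, table = fitted
        res = sc.estimate_fdr(table, null, controls, seed=2)
        hits = set(res.loc[res["hit"], "gene_id"])
        true_pos = len(hits & set(effects))
        assert true_pos >= 0.8 * len(effects)
        assert len(hits - set(effects)) <= 0.15 * max(len(hits), 1)


class TestIntersect:
    @staticmethod
    def _tab(genes, hits, scores=None):
        return pd.DataFrame({
            "gene_id": genes,
            "effect": [1.0 if g in hits else -0.5 for g in genes],
            "score": scores or [10.0] * len(genes),
            "fdr": [0.01 if g in hits else 0.9 for g in genes],
        })

    def test_set_intersection(self):
        genes = ["x", "y", "z"]
        out = sc.intersect_replicates([self._tab(genes, {"x", "y"}),
                                       self._tab(genes, {"y", "z"})])
        assert list(out["gene_id"]) == ["y"]

    def test_identical_replicates(self):
        genes = ["x", "y", "z"]
        t = self._tab(genes, {"x", "z"}, scores=[5.0, 1.0, 9.0])
        out = sc.intersect_replicates([t, t.copy()])
        assert list(out["gene_id"]) == ["z", "x"]  # sorted by min score desc

    def test_mismatched_universe_errors(self):
        with pytest.raises(ValueError, match="universes"):
            sc.intersect_replicates([self._tab(["x", "y"], set()),
                                     self._tab(["x", "q"], set())])
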