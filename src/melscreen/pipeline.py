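"""Multi-stage pipeline runner with a reproducibility manifest.

A pipeline config is a mapping with an optional ``out`` directory,
``log_level`` and a ``stages`` block. Recognized stages, run in dependency
order when present::

    stages:
      synth_screen: {n_genes: 50, n_effect: 5, theta: 2.0, seed: 1, ...}
      screen:       {fdr: 0.1, pseudocount: 0.5, seed: 2}
      synth_expr:   {n_genes: 158, n_samples: 30, seed: 3, ...}
      exprcorr:     {q: 0.1}
      synth_pops:   {n_snps: 10000, n_selected: 10, selection_shift: 0.4, seed: 4, ...}
      pbs:          {target: A}
      synth_pairs:  {n_genes: 50, seed: 5, ...}
      concord:      {eqtl_p: 0.01, gwas_p: 0.01}

Analysis stages read either the synthetic tables generated earlier in the
same run or explicit input paths (``counts``, ``tpm``/``melanin``,
``freqs``/``vcf``+``popmap``, ``eqtl``/``gwas``). Unknown stage names or
parameters are rejected. Every stochastic stage's seed is recorded in the
manifest together with output checksums and row counts, so identical
config + seeds reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import io, screen as screen_mod, pbs as pbs_mod, concord as concord_mod, \
    exprcorr as exprcorr_mod
from .synth import (ExprSimConfig, PairSimConfig, PopSimConfig, ScreenSimConfig,
                    simulate_eqtl_gwas_pairs, simulate_expression_melanin,
                    simulate_screen, simulate_three_pop_freqs)

log = logging.getLogger("melscreen")

STAGE_ORDER = ("synth_screen", "screen", "synth_expr", "exprcorr",
               "synth_pops", "pbs", "synth_pairs", "concord")


class PipelineError(RuntimeError):
    pass


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise PipelineError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _cfg_from_block(cls, block: dict, where: str):
    allowed = {f.name for f in dataclasses.fields(cls)} | {"n_effect", "theta"}
    _check_keys(block, allowed, where)
    return block


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and write outputs plus a manifest.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    _check_keys(config, {"out", "log_level", "stages"}, "config")
    stages = config.get("stages", {})
    _check_keys(stages, set(STAGE_ORDER), "stages")
    out = Path(out_dir or config.get("out", "melscreen_run"))
    out.mkdir(parents=True, exist_ok=True)
    if "log_level" in config:
        logging.getLogger("melscreen").setLevel(config["log_level"])

    manifest: dict = {"stages": [], "seeds": {}, "outputs": {}}
    state: dict = {}

    def _record(name: str, path: Path, n_rows: int) -> None:
        manifest["outputs"][str(path.relative_to(out))] = {
            "sha256": io.file_sha256(path), "rows": n_rows}

    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        block = dict(stages[stage] or {})
        try:
            if stage == "synth_screen":
                block = _cfg_from_block(ScreenSimConfig, block, stage)
                n_effect = block.pop("n_effect", 0)
                theta = block.pop("theta", 2.0)
                cfg = ScreenSimConfig(**block)
                if n_effect:
                    genes = [f"gene{j:05d}" for j in range(n_effect)]
                    cfg = dataclasses.replace(cfg, effect_dist={g: theta for g in genes})
                sim = simulate_screen(cfg)
                manifest["seeds"][stage] = cfg.seed
                for i, rep in enumerate(sim.replicates):
                    p = io.write_tsv(rep, out / f"screen_counts_rep{i + 1}.tsv")
                    _record(stage, p, len(rep))
                p = io.write_tsv(sim.gene_truth, out / "screen_truth.tsv")
                _record(stage, p, len(sim.gene_truth))
                state["screen_counts"] = sim.replicates
            elif stage == "screen":
                _check_keys(block, {"counts", "fdr", "pseudocount", "seed",
                                    "n_pseudo"}, stage)
                if "counts" in block:
                    reps = [io.read_tsv(p) for p in block["counts"]]
                elif "screen_counts" in state:
                    reps = state["screen_counts"]
                else:
                    raise PipelineError("screen stage: missing field 'counts' "
                                        "(and no synth_screen stage ran)")
                seed = int(block.get("seed", 0))
                manifest["seeds"][stage] = seed
                tables = []
                for i, rep in enumerate(reps):
                    t = screen_mod.analyze_replicate(
                        rep, pseudocount=float(block.get("pseudocount", 0.5)),
                        n_pseudo=block.get("n_pseudo"),
                        seed=seed + i, threshold=float(block.get("fdr", 0.1)))
                    tables.append(t)
                    p = io.write_tsv(t, out / f"screen_effects_rep{i + 1}.tsv")
                    _record(stage, p, len(t))
                if len(tables) >= 2:
                    hits = screen_mod.intersect_replicates(
                        tables, threshold=float(block.get("fdr", 0.1)))
                else:
                    t = tables[0]
                    hits = (t[t["hit"]]
                            .rename(columns={"score": "min_score",
                                             "effect": "mean_effect"})
                            [["gene_id", "min_score", "mean_effect"]]
                            .sort_values("min_score", ascending=False,
                                         ignore_index=True))
                p = io.write_tsv(hits, out / "screen_hits.tsv")
                _record(stage, p, len(hits))
                state["screen_hits"] = hits
            elif stage == "synth_expr":
                block = _cfg_from_block(ExprSimConfig, block, stage)
                cfg = ExprSimConfig(**block)
                tpm, melanin, truth = simulate_expression_melanin(cfg)
                manifest["seeds"][stage] = cfg.seed
                p = io.write_tsv(tpm.reset_index(), out / "tpm.tsv")
                _record(stage, p, len(tpm))
                p = io.write_tsv(melanin, out / "melanin.tsv")
                _record(stage, p, len(melanin))
                p = io.write_tsv(truth, out / "expr_truth.tsv")
                _record(stage, p, len(truth))
                state["tpm"], state["melanin"] = tpm, melanin
            elif stage == "exprcorr":
                _check_keys(block, {"tpm", "melanin", "q"}, stage)
                if "tpm" in block:
                    tpm = io.read_tsv(block["tpm"]).set_index("gene_id")
                    melanin = io.read_tsv(block["melanin"])
                elif "tpm" in state:
                    tpm, melanin = state["tpm"], state["melanin"]
                else:
                    raise PipelineError("exprcorr stage: missing field 'tpm'")
                expr = exprcorr_mod.filter_measurable(tpm)
                corr = exprcorr_mod.correlate_expression_melanin(expr, melanin)
                labeled, summary = exprcorr_mod.classify_hits(
                    corr, q_cut=float(block.get("q", 0.1)))
                p = io.write_tsv(labeled, out / "expr_correlations.tsv")
                _record(stage, p, len(labeled))
                io.write_json(summary, out / "expr_summary.json")
            elif stage == "synth_pops":
                block = _cfg_from_block(PopSimConfig, block, stage)
                cfg = PopSimConfig(**block)
                freqs, selected = simulate_three_pop_freqs(cfg)
                manifest["seeds"][stage] = cfg.seed
                p = io.write_tsv(freqs, out / "pop_freqs.tsv")
                _record(stage, p, len(freqs))
                io.write_json({"selected_indices": selected.tolist()},
                              out / "pop_truth.json")
                state["freqs"] = freqs
            elif stage == "pbs":
                _check_keys(block, {"freqs", "vcf", "popmap", "target",
                                    "windows"}, stage)
                if "vcf" in block:
                    popmap = io.read_popmap(block["popmap"])
                    freqs = io.read_vcf_frequencies(block["vcf"], popmap)
                elif "freqs" in block:
                    freqs = io.read_tsv(block["freqs"])
                elif "freqs" in state:
                    freqs = state["freqs"]
                else:
                    raise PipelineError("pbs stage: missing field 'freqs' or 'vcf'")
                table = pbs_mod.compute_pbs(freqs, target=block.get("target", "A"))
                table = pbs_mod.empirical_pbs_pvalue(table)
                table = pbs_mod.genome_quantile_flags(table)
                p = io.write_tsv(table, out / "pbs.tsv")
                _record(stage, p, len(table))
                if "windows" in block:
                    windows = pbs_mod.make_gene_windows(io.read_tsv(block["windows"]))
                    _, per_gene = pbs_mod.annotate_gene_windows(table, windows)
                    p = io.write_tsv(per_gene, out / "pbs_per_gene.tsv")
                    _record(stage, p, len(per_gene))
                state["pbs"] = table
            elif stage == "synth_pairs":
                block = _cfg_from_block(PairSimConfig, block, stage)
                cfg = PairSimConfig(**block)
                eqtl, gwas, truth = simulate_eqtl_gwas_pairs(cfg)
                manifest["seeds"][stage] = cfg.seed
                for name, df in (("eqtl", eqtl), ("gwas", gwas),
                                 ("pairs_truth", truth)):
                    p = io.write_tsv(df, out / f"{name}.tsv")
                    _record(stage, p, len(df))
                state["eqtl"], state["gwas"] = eqtl, gwas
            elif stage == "concord":
                _check_keys(block, {"eqtl", "gwas", "eqtl_p", "gwas_p"}, stage)
                if "eqtl" in block:
                    eqtl = io.read_tsv(block["eqtl"])
                    gwas = io.read_tsv(block["gwas"])
                elif "eqtl" in state:
                    eqtl, gwas = state["eqtl"], state["gwas"]
                else:
                    raise PipelineError("concord stage: missing field 'eqtl'")
                lead = concord_mod.select_lead_eqtl(
                    eqtl, p_cut=float(block.get("eqtl_p", 0.01)))
                pairs = concord_mod.harmonize_and_filter(
                    lead, gwas, gwas_p_cut=float(block.get("gwas_p", 0.01)))
                p = io.write_tsv(pairs, out / "effect_pairs.tsv")
                _record(stage, p, len(pairs))
                res = concord_mod.sign_concordance_test(pairs)
                io.write_json({"n_pairs": res.n_pairs, "n_agree": res.n_agree,
                               "binomial_p": res.binomial_p},
                              out / "concordance.json")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(
                f"stage {stage!r} failed: {exc} (outputs written so far are "
                f"partial; see {out})") from exc
        manifest["stages"].append(stage)
        log.info("stage %s done", stage)

    io.write_json(manifest, out / "manifest.json")
    return manifest
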