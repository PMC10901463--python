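"""Sorted-screen gene-effect estimation on a small simulated library.

Simulates two replicates of a FACS-sort screen in which 10 of 60 genes
truly promote melanin (knockout effect theta = 2 log2 units in the low
side-scatter bin), runs the full per-replicate analysis (enrichments,
control-guide null, convolution likelihood, empirical FDR) and intersects
hits across replicates.
"""

from melscreen import screen as sc
from melscreen.synth import ScreenSimConfig, simulate_screen

effects = {f"gene{j:05d}": 2.0 for j in range(10)}
cfg = ScreenSimConfig(n_genes=60, n_safe_controls=1000, effect_dist=effects,
                      depth=500.0, n_replicates=2, seed=42)
sim = simulate_screen(cfg)

tables = [sc.analyze_replicate(rep, seed=100 + i)
          for i, rep in enumerate(sim.replicates)]
hits = sc.intersect_replicates(tables, threshold=0.1)

print(f"{len(hits)} genes pass FDR < 10% in both replicates "
      f"(10 were planted at theta = 2):")
print(hits.head(12).to_string(index=False))
truth = sim.gene_truth.set_index("gene_id")["theta_true"]
tp = sum(truth[g] > 0 for g in hits["gene_id"])
print(f"\n{tp} of {len(hits)} called hits are planted positives; "
      "mean_effect is the cross-replicate average log2 effect "
      "(positive = knockout lowers the melanin proxy).")
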