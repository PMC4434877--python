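"""Detect sign-reversing regulator hubs in a simulated two-condition dataset.

Simulates 120 genes (3 TF hubs, 10 targets each, hub-target correlation +0.9
in the disease group flipping to -0.9 in controls, 8 samples per group), runs
the full differential co-expression comparison, and scores recovery against
the planted ground truth.
"""

from dcreg import RunConfig, SimulationConfig, recovery_score, run_comparison, simulate

expr, truth = simulate(SimulationConfig(seed=1))
print(f"simulated {len(expr.gene_ids)} genes x {len(expr.sample_ids)} samples; "
      f"planted hubs: {sorted(truth.planted_dcg_genes)}")

report = run_comparison(
    expr, "disease", "control", truth.planted_library,
    RunConfig(seed=2, n_permutations=500),
)

table = report.dcp_result.table
hubs = table[table.gene.isin(truth.planted_dcg_genes)]
print("\nper-hub dC statistic and permutation p-value:")
print(hubs.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

print(f"\ntrue DCGs (called by both DCp and DCe): {sorted(report.true_dcgs)}")
print(f"DRGs (true DCGs that are library TFs):  {sorted(report.drgs)}")

score = recovery_score(report, truth)
print(f"\nDCG sensitivity {score.dcg_sensitivity:.2f}  "
      f"false-discovery fraction {score.dcg_false_discovery:.2f}")
print("A sensitivity of 1.00 means every planted sign-reversing hub was "
      "recovered; a dC above 1.5 reflects correlations moving from +0.9 to "
      "-0.9 across most of the hub's neighborhood (a few chance links with "
      "small changes dilute it below the planted-link value of 1.8).")
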