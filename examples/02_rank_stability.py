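"""Rank candidate reference genes with the four stability algorithms.

Simulates a 2-variety x 3-tissue x 3-treatment RT-qPCR experiment
(3 biological x 3 technical replicates) with 3 planted stable and 9
planted unstable genes, then ranks the candidates per tissue with geNorm,
NormFinder, BestKeeper and the comparative dCt method, combined into a
geometric-mean comprehensive rank.  Lower values mean more stable.
"""

import refstab as rs

design = rs.SimulationDesign(seed=2023, stable_noise_sd=0.15, treatment_effect=1.0)
cq_table, truth = rs.simulate_cq_experiment(design)
aggregated = rs.aggregate_tech_reps(cq_table)

print("planted stable genes:", ", ".join(sorted(truth.stable_gene_ids)))
for tissue in aggregated.tissues:
    report = rs.rank_stability(aggregated, tissue)
    cols = ["genorm_m", "normfinder_rho", "bestkeeper_sd", "deltact_meansd",
            "comprehensive_rank"]
    print(f"\n=== {tissue} ===")
    print(report.table[cols].round(3).to_string())
    print(f"recommended references for {tissue}: {', '.join(report.top(3))}")
# The top-3 per tissue should be the planted STB genes; the least stable
# genes carry the largest planted condition shifts.
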