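"""Correlation oscillation between cell-cycle expression and T_rep.

For every timepoint of the synchronized time course, the Pearson r
between per-gene expression and per-gene replication time. Negative r at
S/G2 timepoints means genes up-regulated then replicate EARLY; positive r
at M/G1 means genes up-regulated then replicate late.
"""

import repliphase as rp

params = rp.SimulationParams(seed=42)
genes, oris, profile, expr, async_expr, truth = rp.simulate_dataset(params)

config = rp.RunConfig()
gene_trep = rp.pipeline.build_gene_trep(genes, oris, profile, config)

print("late-replicating stratum (first cycle):")
prof = rp.oscillation_profile(expr, gene_trep, alpha=0.05, gene_filter="late")
one_cycle = prof[prof.timepoint < params.cycle_length]
print(one_cycle.assign(r=one_cycle.r.round(3),
                       critical_r=one_cycle.critical_r.round(3))
      .to_string(index=False))

for flt in ("late", "early", "proximal", "distal"):
    p = rp.oscillation_profile(expr, gene_trep, alpha=0.05, gene_filter=flt)
    amp = rp.oscillation_amplitude(p, params.cycle_length)
    print(f"oscillation amplitude ({flt:8s}): {amp:.3f}")
# The trough in S/G2 crosses the significance threshold for the late and
# ORI-proximal strata only: the coupling lives near late-firing origins.
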