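"""T_rep versus the time of peak expression, and the decile view.

Ordering genes by when their transcript level peaks in the cycle and
sliding a 100-gene window over their T_rep shows when in the cycle the
early-replicating genes are expressed. The decile table slices the same
relationship the other way: median expression per T_rep decile.
"""

import repliphase as rp

params = rp.SimulationParams(seed=42)
genes, oris, profile, expr, async_expr, truth = rp.simulate_dataset(params)
gene_trep = rp.interpolate_trep(profile, genes)

peak = rp.peak_expression_time(expr)
ma = rp.trep_moving_average(gene_trep, peak, window=100)
trough = ma.loc[ma.mean_trep.idxmin()]
print(f"{len(ma)} windows of 100 genes ordered by peak expression time")
print(f"earliest mean T_rep {trough.mean_trep:.2f} +- {trough.se_trep:.2f} min "
      f"in the window peaking at {trough.center_peak_time:.0f} min "
      f"({rp.phase_label(trough.center_peak_time, params.cycle_length)})")
# The earliest-replicating window peaks in G2: transcript levels that crest
# just after S phase mark the genes whose S-phase transcription advanced
# their origins. (The generator only advances origins, so there is no
# equally sharp latest-T_rep crest.)

# The decile view, on data with an explicit monotone coupling: expression
# decreasing in T_rep among late-replicating genes, flat among early ones.
from repliphase.validate import monotone_coupled_dataset

gt_mono, expr_mono = monotone_coupled_dataset(seed=42)
deciles = rp.decile_median_expression(gt_mono, expr_mono)
print("\nT_rep decile -> median expression (monotone-coupled data):")
for _, row in deciles.iterrows():
    print(f"  decile {int(row.decile):2d} (median T_rep {row.median_trep:5.1f}) "
          f"-> {row.median_expression:+.3f}")
# Deciles 1-5 (early S) are flat; deciles 6-10 fall steadily — the
# signature shape of a coupling confined to late replication.
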