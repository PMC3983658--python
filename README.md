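# repliphase

Cell-cycle-phase-resolved association between transcription and DNA
replication timing.

## The problem

Eukaryotic genomes replicate on a reproducible temporal program: each
locus has a characteristic replication time **T_rep** (minutes into
S phase). Transcription and T_rep are famously correlated in metazoans,
but averaging expression over the whole cell cycle hides *when* the
relevant transcription happens. The sharper question this package
addresses: do genes transcribed **during S phase** replicate early, and
genes repressed in S phase replicate late — and is that association
concentrated near **late-firing replication origins (ORIs)**, as expected
if S-phase chromatin accessibility helps late origins recruit limiting
initiation factors (Cdc45/Sld3-class) recycled from the early firing
wave?

`repliphase` is for computational biologists who have (or want to
simulate) four kinds of data: a replication-timing profile, gene
annotations, origin locations, and cell-cycle-synchronized expression
time courses. It provides the full analysis chain plus a truth-tracked
synthetic-data generator so every stage is testable without downloads.

## The statistic at its core

For each timepoint *t* of a synchronized time course, compute the Pearson
correlation across genes

&nbsp;&nbsp;&nbsp;&nbsp;r(t) = corr( e_g(t), T_rep(g) )

where e_g(t) is the log2 expression ratio of gene *g* versus asynchronous
cells, and T_rep(g) is the profile linearly interpolated at the gene's
midpoint. Positive r(t): genes up-regulated at *t* replicate late;
negative: they replicate early. Plotted against *t*, r oscillates through
the cycle — the **oscillation profile** — with a trough in S/G2 and a
crest in M/G1 when S-phase transcription couples to origin firing.
Per-timepoint significance uses the exact t-inversion threshold
|r|* = t*/sqrt(n−2+t*²) with t* the two-tailed Student-t quantile at
level α and n−2 degrees of freedom (e.g. |r|* ≈ 0.107 at n = 800,
α = 0.0025). Strata sharpen the picture: genes split at halfway through
S phase (early/late T_rep) and by the distance from the gene's 5′ end to
the nearest origin (ORI-proximal/distal).

The generator closes the loop: origin base firing times are uniform on
the firing window; the firing of a late origin is advanced by
β · (mean S-phase transcriptional activity of genes within 5 kb), floored
at the time limiting initiation factors become available; T_rep is
rendered by constant-speed forks, T_rep(x) = min_i [fire_i + |x−x_i|/v];
expression is a per-gene cosine with known phase and amplitude. With
β = 0 the analysis must find nothing (null calibration); with the default
β the late and ORI-proximal strata must light up.

## Worked example

```python
import repliphase as rp

params = rp.SimulationParams(seed=42)
genes, oris, profile, expr, async_expr, truth = rp.simulate_dataset(params)

config = rp.RunConfig()
gene_trep = rp.pipeline.build_gene_trep(genes, oris, profile, config)
prof = rp.oscillation_profile(expr, gene_trep, alpha=0.05, gene_filter="late")
print(prof[prof.timepoint < 100].round(3).to_string(index=False))
```

prints (first cycle, late-replicating stratum):

```
 timepoint phase      r  n_pairs  critical_r  significant
       0.0    G1  0.053      949       0.064        False
      10.0    G1 -0.016      949       0.064        False
      20.0     S -0.070      949       0.064         True
      30.0     S -0.096      949       0.064         True
      40.0    G2 -0.067      949       0.064         True
      50.0    G2 -0.031      949       0.064        False
      60.0    G2  0.035      949       0.064        False
      70.0     M  0.073      949       0.064         True
      80.0     M  0.088      949       0.064         True
      90.0  M/G1  0.076      949       0.064         True
```

The trough sits in S/G2 and crosses the significance threshold (genes
up-regulated around the S/G2 transition replicate **early**); r turns
significantly positive through M into M/G1 (genes up-regulated there
replicate late). The same run gives oscillation amplitudes of 0.21 for
ORI-proximal versus 0.17 for distal genes and 0.19 for late versus 0.16
for early genes — the coupling lives near late origins, and this seed is
on the quiet end of the distribution (the 100-seed means are 0.26
proximal / 0.09 distal, 0.28 late / 0.11 early).

The `examples/` directory walks through each capability: dataset
generation, oscillation profiles, T_rep mapping and stratification,
moving averages and deciles, asynchronous expression with the copy-number
correction, and early-peak calling with active-origin selection. A thin
CLI wraps the same pipeline:

```
repliphase simulate --seed 7 --outdir data/
repliphase associate --dataset data/ --outdir results/
repliphase report results/
```

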