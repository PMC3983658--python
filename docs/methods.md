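# Methods

This note documents the models and numerical choices behind
`repliphase`: the association statistics, the synthetic-data generator
that serves as their test bed, and the places where a design decision
was genuinely open.

## 1. Mapping replication timing onto genes

A replication-timing profile is a per-chromosome list of probe positions
with T_rep values (minutes into S phase, or any monotone scalar for
low-resolution data), together with the S-phase bounds `s_start`/`s_end`
of the dataset on the same clock. A gene's T_rep is the profile linearly
interpolated at the gene's midpoint, `floor((start+end)/2)`. Two edge
rules:

- **No extrapolation.** Midpoints outside a chromosome's probed span, or
  on unprofiled chromosomes, get a missing value. Interpolation outside
  the support is unconstrained, and downstream statistics handle missing
  values by pairwise-complete deletion anyway.
- **Early/late split.** The cutoff is `s_start + fraction·(s_end−s_start)`
  with `fraction = 0.5` by default ("halfway through S phase"); a tie is
  classified early (the first half read as inclusive), which makes the
  labelling deterministic.

Distances to origins are measured from the gene's 5′ end (`start` on the
plus strand, `end−1` on the minus strand — the last covered base in
half-open coordinates) to the nearest origin point, where an origin
interval contributes its midpoint. Proximity uses an inclusive cutoff
(`distance ≤ cutoff` is proximal), matching the everyday reading of
"within 5 kb". All coordinates are 0-based half-open internally; 1-based
inclusive inputs must be converted at the boundary (`io.from_one_based`).

For low-resolution profiles the early-replicating peaks (active
initiation zones) are called as local minima of a box-smoothed profile:
a probe is a peak when its smoothed value is minimal among all probes
within ±`smooth_window_bp` (a flat valley bottom counts once, at its
lowest probe) and lies at least `prominence` below the lower of the two
flanking local maxima. Chromosome boundary probes are never peaks, so a
monotone profile yields none. Defaults: window 3× the median probe
spacing, prominence 10% of the S-phase span. Candidate origin-licensing
sites within 1 Mb (inclusive) of a same-chromosome peak are "active".

## 2. Association statistics

All correlations are Pearson's, computed on pairwise-complete
observations; a constant vector or fewer than three complete pairs gives
an undefined (NaN) result, never a silent zero. The per-timepoint
significance threshold inverts the exact t-test of a correlation
coefficient: with `t* = t_{1−α/2, n−2}`,

    |r|* = t* / sqrt(n − 2 + t*²).

At (n = 800, α = 0.0025) this gives 0.1066 and at (n = 292, α = 0.0025)
0.1765, matching the thresholds quoted for genome-scale yeast datasets.
No multiple-testing correction is applied across timepoints; instead the
report prints the number of significant timepoints next to the count
expected by chance (`n_timepoints × α`), which is how oscillation plots
are customarily read.

The **oscillation profile** correlates each timepoint's expression column
with per-gene T_rep (positive r ⇔ up-regulated genes replicate late).
Strata (`early`, `late`, `proximal`, `distal`) reuse the labels above.
An oscillation is called significant when the curve crosses the
threshold band at its extreme: some S- or G2-labelled timepoint has
r < −|r|*, the S/G2 mean is negative, and the M/G1 mean is positive.

The **oscillation amplitude** is max r − min r. Because expression
trajectories are smooth and periodic, the r-series of any finite gene set
is itself approximately a random-phase sinusoid even when expression and
T_rep are independent; its raw max−min is therefore biased upward, the
more so the smaller the subset. When the time course covers more than
one cycle the amplitude is computed on the cycle-folded profile (r
averaged at equivalent positions of the cycle), which suppresses the
incoherent part of that wobble without touching true oscillation.

Other statistics: a k-point forward moving average for plotting dense
profiles (`k = 2` for human-density sampling); the time of maximal
expression per gene (ties to the earliest timepoint; ordering is linear
from mitosis, non-wrapping); sliding windows of exactly `window` genes
(step 1) reporting mean T_rep ± sd/√window; decile tables splitting
genes ranked by T_rep into 10 bins whose sizes differ by at most one
(remainder to the earliest bins); and extreme-group comparisons (top
versus bottom decile by expression, or top-k versus bottom-k by
asynchronous level) with a two-tailed Student's t-test (pooled variance;
Welch by flag). Ranking ties are broken lexicographically by gene id and
logged, so runs are deterministic.

**Copy-number correction.** A gene replicated at cycle time t spends a
fraction f = (cycle_length − t)/cycle_length of the cycle with two
copies. The correction subtracts a fraction of each asynchronous level
proportional to that time: corrected = level·(1 − κ·f). The exact
per-copy normalization would be level/(1+f); the multiplicative form with
κ = 0.5 agrees with it at both endpoints f = 0 and f = 1 and stays within
6% between them. κ is exposed because the subtraction rule, unlike the
endpoints, is a modelling choice.

## 3. The synthetic-data generator

The generator produces all five inputs with known truth. Defaults are
chosen once to emulate a budding-yeast-like study at desk scale; the
package's validation (tests and `scripts/acceptance.py`) runs at exactly
these conditions.

**Genome.** 2 chromosomes × 2 Mb; 1600 genes of 1 kb placed one per
2.5-kb slot with a uniform offset (non-overlapping, density ≈ 1 gene per
2.5 kb); 200 origins on a 20-kb grid with ±5% jitter (density ≈ 1 per
20 kb, as in ORIdb-scale yeast annotations). The near-regular origin
spacing matters: with fully uniform origin placement, close pairs let an
early origin passively replicate its late neighbour's domain, severing
the causal chain from firing-time advance to gene T_rep.

**Expression.** e_g(t) = A_g·cos(2π(t−φ_g)/cycle) + ε,
ε ~ N(0, 0.25²), A_g ~ N(1, 0.2) clipped at 0.2, sampled at 20
timepoints (0–190 min, cycle 100 min ⇒ 10 per cycle × 2 cycles, the
sampling density of classic yeast synchrony experiments). Phase labels:
G1 [0,20), S [20,40), G2 [40,70), M [70,85), M/G1 [85,100). A fraction
(0.45) of genes is "S-induced": φ_g ~ U[43,53], so their transcript
level rises through S phase and peaks in late S/early G2 — the S-phase
transcription signature. All other genes get uniform phases.

Crucially, phases are iid across genes, independent of position. An
earlier design that placed S-induced genes preferentially near late
origins was rejected for two measured reasons: (i) any spatial
clustering of phase inflates the null variance of the per-timepoint r
(T_rep is spatially autocorrelated by construction, so clustered
expression phases create a cluster design effect that breaks α
calibration at β = 0); (ii) tying induction to late origins makes the
ORI-proximal stratum compare high-expression late-origin genes against
silent early-origin genes, inverting the stratum's correlation sign.

**Replication program.** Base firing times are uniform on the firing
window [20, 40] min. Each origin's local S-phase activity is the mean of
A_g·cos(2π(midS−φ_g)/cycle) over genes within 5 kb (its neighbours'
expression level trajectory evaluated at mid-S; zero if no gene is
near). Coupling modes: `none`; `all_oris`
(fire = clip(base − β·activity, s_start, s_end)); and the default
`late_ori_proximal`, where only origins with base times after mid-S are
adjusted and their firing is floored at
`s_start + 0.45·(s_end − s_start)`. The floor embodies the
limiting-factor model this analysis probes: late origins depend on
initiation factors released by the early wave, so transcription can move
them toward — but not into — the early firing wave. β defaults to 50
min per unit activity, a saturating regime in which most
positive-activity late origins reach the floor and negative-activity
ones are delayed toward the window end.

**Profile rendering.** T_rep(x) = min_i [fire_i + |x − x_i|/v] on a 1-kb
probe grid, with fork speed v = 1.45 kb/min (yeast-like forks; slow
enough that a late origin's domain is not overrun by its neighbours'
forks, fast enough that travel time does not dominate firing-time
structure). The construction is Lipschitz with slope ≤ 1/v and its
minimum equals the earliest firing time up to half a probe of travel.

**Asynchronous levels.** level = exp(b_g + γ·activity_g) with
b_g ~ N(1, 0.5²) and γ = 0.6, so constitutively high expression is
mildly associated with S-phase activity and hence earlier replication.
The resulting top-100 vs bottom-100 T_rep difference is ≈ −0.6 to −1 min
— directionally the published effect, deliberately not scaled to any
particular organism's magnitude, and often insignificant in a single
desk-scale dataset.

**What passing tests do and do not show.** The generator reproduces the
statistical structure the analysis assumes: periodic expression with
known phases, V-shaped interpolable timing profiles, a tunable
expression→firing coupling and its strata. It does not model stochastic
origin firing between cells, fork stalling, chromatin state, replication
of repetitive regions, measurement bias of synchrony experiments
(dampening across cycles, arrest artefacts) or mRNA decay. Recovery of
the coupling here validates the pipeline's correctness and power at
these conditions, not the biological claim on any real dataset.

## 4. Validation design

- **Oracle tests.** Interpolation, nearest-origin distances, active-origin
  selection and the correlation primitive are checked exactly against
  brute-force re-implementations on ≥1000 randomized instances.
- **Threshold calibration.** The t-inversion threshold is verified by
  Monte-Carlo: on independent normal data at n ∈ {50, 292, 800} the
  rejection rate at α = 0.0025 must sit within 3 binomial standard errors
  of α over 10⁵ trials.
- **Null calibration.** 200 β = 0 datasets: the fraction of significant
  timepoints must lie within 3 SEs of α, and no timepoint may show a
  sign-consistent mean r across seeds.
- **Signal recovery.** 100 datasets at the default coupled conditions:
  in ≥95% of seeds the late and ORI-proximal strata each show a
  significant oscillation of the right orientation, and the
  proximal/late amplitudes exceed the distal/early ones. At these
  conditions the joint pass rate is ≈0.96; it is a power statement about
  the default effect size, not a margin-free certainty, and the test
  seeds are fixed.
- **Decile shape.** The flat-then-falling decile signature is asserted on
  data with an explicit monotone late-only coupling, because the
  fork-rendered generator's floored advance compresses coupled genes
  near the early/late boundary rather than grading them across the late
  range.
- **Copy-number correction.** On purely copy-driven levels the
  correction must strictly reduce |r| with T_rep (it removes most, not
  all, of the artefact: the linear-in-f form leaves a small curvature
  residual).

## 5. Known limitations

- The firing program is deterministic given the seed; no cell-to-cell
  firing variance, so rendered profiles are sharper than population
  Repli-seq measurements.
- The amplitude comparison between strata of very different sizes is
  intrinsically noisy (the smaller stratum's null amplitude is larger);
  cycle-folding mitigates but does not remove this.
- The copy-number correction's functional form is an endpoint-matched
  approximation, not a derivation.
- Human-style analyses (peak calling, two-point smoothing, 1-Mb active
  origin windows) are implemented and unit-tested but the bundled
  generator emulates a yeast-like genome; a human-scale simulation would
  need chromosome-scale domains and replication-domain structure.
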