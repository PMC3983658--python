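"""Truth-tracked synthetic genomes, replication programs and time courses.

The generator emulates the five inputs of the analysis with known ground
truth:

1. a genome of non-overlapping genes and origins of replication (ORIs)
   at yeast-like densities (one gene per ~2.5 kb, one ORI per ~20 kb);
2. an origin firing program in which the firing time of late origins is
   advanced in proportion to the mean S-phase transcriptional activity of
   nearby genes (the tunable coupling, strength ``beta``);
3. a replication-timing profile rendered by constant-speed fork
   progression from the realized firing times (T_rep at a position is
   the earliest arrival over origins);
4. a synchronized expression time course: per-gene cosine trajectories
   with gene-specific phase and amplitude plus Gaussian noise, sampled
   at fixed timepoints over about two cycles;
5. an asynchronous expression table whose (log) level is optionally
   coupled to the gene's S-phase activity.

A fraction of genes ("S-induced", iid across the genome) peaks in late
S/early G2, so their transcript level rises through S phase; their
cosine value at mid-S is positive and it is these genes that advance
nearby late origins when coupling is on. Crucially, expression phase is
assigned independently of genomic position: with ``beta = 0`` expression
and replication time share no structure at all, which keeps the null
calibration of the downstream correlation analysis exact.

Late origins advanced by transcription never fire before
``s_start + refire_floor_fraction * (s_end - s_start)``: the limiting
initiation factors they depend on only become available once the early
firing wave has released them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .io import AsyncExpression, ExpressionTimecourse, TrepProfile

TRUTH_SCHEMA_VERSION = 1

# phase boundaries in minutes within one cycle: label applies to [start, end)
DEFAULT_PHASES = (
    (0.0, 20.0, "G1"),
    (20.0, 40.0, "S"),
    (40.0, 70.0, "G2"),
    (70.0, 85.0, "M"),
    (85.0, 100.0, "M/G1"),
)


def phase_label(minutes: float, cycle_length: float,
                phases=DEFAULT_PHASES) -> str:
    tm = minutes % cycle_length
    for a, b, lab in phases:
        if a <= tm < b:
            return lab
    return phases[-1][2]


@dataclass
class SimulationParams:
    """All knobs of the generator. Defaults are the study conditions used
    throughout the test-suite; see docs/methods.md for the rationale."""

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 1600                 # total, split evenly across chromosomes
    gene_length: int = 1_000
    n_oris: int = 200                   # total; grid-placed with jitter
    ori_jitter_frac: float = 0.05       # jitter as a fraction of ORI spacing
    fork_speed: float = 1.45            # kb per minute
    s_start: float = 20.0               # minutes; origin firing window start
    s_end: float = 40.0                 # minutes; firing window end
    cycle_length: float = 100.0         # minutes
    timepoints: tuple = tuple(float(t) for t in range(0, 200, 10))
    amplitude_mean: float = 1.0         # log2 units
    amplitude_sd: float = 0.2
    amplitude_min: float = 0.2
    noise_sd: float = 0.25              # log2 units, per measurement
    s_induced_fraction: float = 0.45    # genes peaking in late S/early G2
    induced_peak_window: tuple = (43.0, 53.0)   # minutes within the cycle
    beta: float = 50.0                  # min advance per unit mean S-activity
    coupling_mode: str = "late_ori_proximal"    # none | all_oris | late_ori_proximal
    coupling_radius: float = 5_000.0    # bp
    refire_floor_fraction: float = 0.45  # earliest advanced late-ORI firing
    probe_spacing: int = 1_000          # bp
    async_gamma: float = 0.6            # log-level gain per unit S-activity
    async_log_mean: float = 1.0
    async_log_sd: float = 0.5

    def __post_init__(self):
        if not self.s_start < self.s_end < self.cycle_length:
            raise ValueError("require s_start < s_end < cycle_length")
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.coupling_mode not in ("none", "all_oris", "late_ori_proximal"):
            raise ValueError(f"unknown coupling_mode {self.coupling_mode!r}")
        if len(self.timepoints) < 3:
            raise ValueError("need at least 3 timepoints")

    @property
    def mid_s(self) -> float:
        return 0.5 * (self.s_start + self.s_end)

    def chrom_names(self):
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


@dataclass
class SimulationTruth:
    """Ground truth for recovery tests: per-gene phases/amplitudes, the
    origin firing program, which origins were coupled, and the params."""

    params: SimulationParams
    phi: np.ndarray            # per-gene peak time (minutes in cycle)
    amplitude: np.ndarray      # per-gene amplitude A_g
    s_induced: np.ndarray      # per-gene bool
    s_activity: np.ndarray     # A_g * cos(2 pi (midS - phi)/cycle)
    base_firing: np.ndarray = field(default=None)   # per-ORI, minutes
    realized_firing: np.ndarray = field(default=None)
    coupled: np.ndarray = field(default=None)        # per-ORI bool

    def to_json(self, path) -> None:
        payload = {
            "schema_version": TRUTH_SCHEMA_VERSION,
            "params": dataclasses.asdict(self.params),
            "phi": self.phi.tolist(),
            "amplitude": self.amplitude.tolist(),
            "s_induced": self.s_induced.astype(int).tolist(),
            "s_activity": self.s_activity.tolist(),
            "base_firing": None if self.base_firing is None else self.base_firing.tolist(),
            "realized_firing": None if self.realized_firing is None else self.realized_firing.tolist(),
            "coupled": None if self.coupled is None else self.coupled.astype(int).tolist(),
        }
        payload["params"]["timepoints"] = list(payload["params"]["timepoints"])
        payload["params"]["induced_peak_window"] = list(
            payload["params"]["induced_peak_window"])
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        p = d["params"]
        p["timepoints"] = tuple(p["timepoints"])
        p["induced_peak_window"] = tuple(p["induced_peak_window"])
        params = SimulationParams(**p)
        def arr(key, dtype=float):
            return None if d[key] is None else np.asarray(d[key], dtype=dtype)
        return cls(params=params, phi=arr("phi"), amplitude=arr("amplitude"),
                   s_induced=arr("s_induced", bool), s_activity=arr("s_activity"),
                   base_firing=arr("base_firing"),
                   realized_firing=arr("realized_firing"),
                   coupled=arr("coupled", bool))


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generation stage."""
    return np.random.default_rng(np.random.SeedSequence([params.seed, stream]))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(params: SimulationParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate non-overlapping genes and jitter-grid ORIs.

    Genes are placed uniformly without overlap (dart throwing on the gaps),
    with random strands. ORI points sit on a regular grid with a small
    jitter, which keeps neighbouring replication domains comparable in
    size, and carry 400-bp intervals and a confidence status (a nominal
    mix, mostly confirmed).
    """
    genes_per_chrom, rem_g = divmod(params.n_genes, params.n_chrom)
    oris_per_chrom, rem_o = divmod(params.n_oris, params.n_chrom)
    if rem_g or rem_o:
        raise ValueError("n_genes and n_oris must divide evenly across chromosomes")
    slot = params.chrom_length / genes_per_chrom
    if slot <= params.gene_length:
        raise ValueError("gene density infeasible: genes would overlap")
    spacing = params.chrom_length / oris_per_chrom if oris_per_chrom else None
    rng = _rng(params, 0)

    gene_rows, ori_rows = [], []
    for c, chrom in enumerate(params.chrom_names()):
        # one gene per slot, uniform offset inside the free part of the slot
        offsets = rng.uniform(0, slot - params.gene_length, genes_per_chrom)
        starts = (np.arange(genes_per_chrom) * slot + offsets).astype(int)
        strands = rng.choice(["+", "-"], genes_per_chrom)
        for i, (s, st) in enumerate(zip(starts, strands)):
            gene_rows.append((f"g{c}_{i:04d}", chrom, int(s),
                              int(s + params.gene_length), st))
        if oris_per_chrom == 0:
            continue
        jitter = rng.uniform(-params.ori_jitter_frac, params.ori_jitter_frac,
                             oris_per_chrom) * spacing
        pts = ((np.arange(oris_per_chrom) + 0.5) * spacing + jitter).astype(int)
        pts = np.clip(pts, 200, params.chrom_length - 200)
        status = rng.choice(["confirmed", "likely"], oris_per_chrom, p=[0.8, 0.2])
        for i, (p, stt) in enumerate(zip(pts, status)):
            ori_rows.append((f"ori{c}_{i:03d}", chrom, int(p - 200),
                             int(p + 200), stt))
    genes = pd.DataFrame(gene_rows, columns=rio.GENE_COLUMNS)
    oris = pd.DataFrame(ori_rows, columns=rio.ORI_COLUMNS)
    return rio.validate_genes(genes), rio.validate_oris(oris)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_cc_expression(genes: pd.DataFrame, params: SimulationParams
                           ) -> tuple[ExpressionTimecourse, SimulationTruth]:
    """Cosine expression trajectories with per-gene phase and amplitude.

    e_g(t) = A_g cos(2 pi (t - phi_g)/cycle_length) + N(0, noise_sd^2).
    A fraction of genes is S-induced: their peak time phi_g falls in late
    S/early G2, so transcript levels climb through S phase (active S-phase
    transcription) and their cosine value at mid-S is positive. All other
    genes get a uniform random phase. Phases are iid across genes,
    independent of genomic position.
    """
    n = len(genes)
    rng = _rng(params, 1)
    induced = rng.random(n) < params.s_induced_fraction
    phi = rng.uniform(0.0, params.cycle_length, n)
    lo, hi = params.induced_peak_window
    phi[induced] = rng.uniform(lo, hi, int(induced.sum()))
    amp = np.clip(rng.normal(params.amplitude_mean, params.amplitude_sd, n),
                  params.amplitude_min, None)
    s_act = amp * np.cos(2 * np.pi * (params.mid_s - phi) / params.cycle_length)

    tps = np.asarray(params.timepoints, dtype=float)
    clean = amp[:, None] * np.cos(
        2 * np.pi * (tps[None, :] - phi[:, None]) / params.cycle_length)
    noisy = clean + rng.normal(0.0, params.noise_sd, (n, len(tps)))
    values = pd.DataFrame(noisy, index=pd.Index(genes["gene_id"], name="gene_id"),
                          columns=tps)
    phases = [phase_label(t, params.cycle_length) for t in tps]
    expr = ExpressionTimecourse(values=values, phases=phases)
    truth = SimulationTruth(params=params, phi=phi, amplitude=amp,
                            s_induced=induced, s_activity=s_act)
    return expr, truth


# ---------------------------------------------------------------------------
# replication program
# ---------------------------------------------------------------------------

def draw_base_firing_times(oris: pd.DataFrame, params: SimulationParams) -> np.ndarray:
    """Intrinsic firing times, uniform on the firing window [s_start, s_end]."""
    rng = _rng(params, 2)
    return rng.uniform(params.s_start, params.s_end, len(oris))


def simulate_replication_program(oris: pd.DataFrame, genes: pd.DataFrame,
                                 truth: SimulationTruth,
                                 params: SimulationParams,
                                 base: np.ndarray | None = None) -> pd.DataFrame:
    """Realize origin firing times under the transcription coupling.

    Each origin's local S-phase activity is the mean of
    A_g cos(2 pi (midS - phi_g)/cycle) over genes whose midpoint lies
    within ``coupling_radius`` (zero if no gene is near). Modes:

    - ``none``: realized = base times;
    - ``all_oris``: fire_i = clip(base_i - beta * activity_i, s_start, s_end);
    - ``late_ori_proximal``: only origins with base time after mid-S are
      adjusted, and their firing is floored at
      s_start + refire_floor_fraction * (s_end - s_start) — advanced late
      origins still wait for initiation factors released by the early wave.

    Returns the ORI table with a ``firing_time`` column; the truth object
    is updated in place with the firing program.
    """
    if base is None:
        base = draw_base_firing_times(oris, params)
    base = np.asarray(base, dtype=float)
    gene_mid = ((genes["start"].to_numpy() + genes["end"].to_numpy()) // 2)
    ori_pts = rio.ori_point(oris["start"].to_numpy(), oris["end"].to_numpy())
    activity = np.zeros(len(oris))
    gchrom = genes["chrom"].to_numpy()
    ochrom = oris["chrom"].to_numpy()
    for chrom in pd.unique(ochrom):
        gm = gene_mid[gchrom == chrom]
        act = truth.s_activity[gchrom == chrom]
        order = np.argsort(gm)
        gm = gm[order]; act = act[order]
        csum = np.concatenate([[0.0], np.cumsum(act)])
        sel = ochrom == chrom
        lo = np.searchsorted(gm, ori_pts[sel] - params.coupling_radius, "left")
        hi = np.searchsorted(gm, ori_pts[sel] + params.coupling_radius, "right")
        k = hi - lo
        with np.errstate(invalid="ignore"):
            mean = np.where(k > 0, (csum[hi] - csum[lo]) / np.maximum(k, 1), 0.0)
        activity[sel] = mean

    fire = base.copy()
    coupled = np.zeros(len(oris), dtype=bool)
    if params.beta > 0 and params.coupling_mode != "none":
        if params.coupling_mode == "all_oris":
            coupled[:] = True
            floor = params.s_start
        else:
            coupled = base > params.mid_s
            floor = params.s_start + params.refire_floor_fraction * (
                params.s_end - params.s_start)
        fire[coupled] = np.clip(base[coupled] - params.beta * activity[coupled],
                                floor, params.s_end)
    out = oris.copy()
    out["firing_time"] = fire
    truth.base_firing = base
    truth.realized_firing = fire
    truth.coupled = coupled
    return out


# ---------------------------------------------------------------------------
# profile rendering
# ---------------------------------------------------------------------------

def render_trep_profile(oris: pd.DataFrame, params: SimulationParams) -> TrepProfile:
    """Render T_rep by constant-speed fork progression.

    At probe position x (every ``probe_spacing`` bp):
    trep(x) = min_i [ fire_i + |x - x_i| / fork_speed ], the earliest fork
    arrival over all origins of the chromosome. Chromosomes without
    origins are omitted with a warning.
    """
    if "firing_time" not in oris.columns:
        raise ValueError("oris must carry firing_time (run the replication program)")
    chroms = {}
    pts = rio.ori_point(oris["start"].to_numpy(), oris["end"].to_numpy())
    v = params.fork_speed * 1000.0  # bp/min
    for chrom in params.chrom_names():
        sel = (oris["chrom"] == chrom).to_numpy()
        if not sel.any():
            import logging
            logging.getLogger(__name__).warning(
                "render_trep_profile: no fired ORIs on %s; omitted", chrom)
            continue
        x_i = pts[sel].astype(float)
        f_i = oris.loc[sel, "firing_time"].to_numpy(dtype=float)
        probes = np.arange(params.probe_spacing // 2, params.chrom_length,
                           params.probe_spacing, dtype=float)
        trep = (f_i[None, :] + np.abs(probes[:, None] - x_i[None, :]) / v).min(axis=1)
        chroms[chrom] = (probes, trep)
    return TrepProfile(chroms=chroms, s_start=params.s_start, s_end=params.s_end)


# ---------------------------------------------------------------------------
# asynchronous expression
# ---------------------------------------------------------------------------

def simulate_async_expression(genes: pd.DataFrame, truth: SimulationTruth,
                              params: SimulationParams) -> AsyncExpression:
    """Asynchronous levels: level = exp(b_g + gamma * s_activity_g) with
    b_g ~ N(async_log_mean, async_log_sd^2). gamma couples average level
    to S-phase activity; gamma = 0 gives levels independent of T_rep."""
    rng = _rng(params, 3)
    b = rng.normal(params.async_log_mean, params.async_log_sd, len(genes))
    levels = np.exp(b + params.async_gamma * truth.s_activity)
    return AsyncExpression(
        levels=pd.Series(levels, index=pd.Index(genes["gene_id"], name="gene_id"),
                         name="level"),
        per_copy_normalized=False)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(params: SimulationParams, outdir=None):
    """Run the full generative chain; optionally write the file set.

    Returns (genes, oris_with_firing, profile, expr, async_expr, truth).
    With ``outdir`` given, writes genes.bed, oris.tsv, trep.tsv,
    cc_expression.tsv, async.tsv and truth.json — all readable back with
    :mod:`repliphase.io` unchanged.
    """
    genes, oris = simulate_genome(params)
    expr, truth = simulate_cc_expression(genes, params)
    oris = simulate_replication_program(oris, genes, truth, params)
    profile = render_trep_profile(oris, params)
    async_expr = simulate_async_expression(genes, truth, params)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rio.write_genes(genes, outdir / "genes.bed")
        rio.write_oris(oris, outdir / "oris.tsv")
        rio.write_trep_profile(profile, outdir / "trep.tsv")
        rio.write_expression(expr, outdir / "cc_expression.tsv")
        rio.write_async(async_expr, outdir / "async.tsv")
        truth.to_json(outdir / "truth.json")
    return genes, oris, profile, expr, async_expr, truth
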