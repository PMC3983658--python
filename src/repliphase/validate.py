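"""Simulation-based validation of the analysis chain.

Bundles the end-to-end checks that the pipeline recovers the generative
truth: oscillation significance in the coupled strata, amplitude
contrasts between strata, null calibration at zero coupling, and the
decile shape on monotone-coupled data. Used by the test-suite and the
acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import oscillation_amplitude, oscillation_profile
from .pipeline import RunConfig, build_gene_trep
from .simulate import SimulationParams, simulate_dataset

SG2_PHASES = ("S", "G2")
MG1_PHASE = "M/G1"


def significant_oscillation(profile: pd.DataFrame) -> bool:
    """Is an oscillation profile significantly in the expected orientation?

    The trough must cross the per-timepoint significance threshold within
    S/G2 (r below -critical_r at some S- or G2-labelled timepoint, and
    negative on average there), and r must be positive on average at the
    M/G1 timepoints. This mirrors how oscillation plots are read: the
    curve is called significant when it exceeds the threshold band at its
    extremes.
    """
    ok = profile.dropna(subset=["r"])
    sg2 = ok[ok["phase"].isin(SG2_PHASES)]
    mg1 = ok[ok["phase"] == MG1_PHASE]
    if len(sg2) == 0 or len(mg1) == 0:
        return False
    trough_sig = bool((sg2["r"] < -sg2["critical_r"]).any())
    return trough_sig and sg2["r"].mean() < 0 and mg1["r"].mean() > 0


def recovery_trial(seed: int, alpha: float = 0.05,
                   params: SimulationParams | None = None) -> dict:
    """Simulate one dataset at the default coupled conditions and check the
    four recovery properties: (a) significant oscillation in the late-T_rep
    stratum, (b) in the ORI-proximal stratum, (c) proximal amplitude above
    distal, (d) late amplitude above early."""
    if params is None:
        params = SimulationParams(seed=seed)
    genes, oris, profile, expr, async_expr, truth = simulate_dataset(params)
    config = RunConfig(alpha=alpha,
                       ori_proximity_bp=params.coupling_radius,
                       s_start=params.s_start, s_end=params.s_end,
                       cycle_length=params.cycle_length)
    gene_trep = build_gene_trep(genes, oris, profile, config)
    profs = {flt: oscillation_profile(expr, gene_trep, alpha=alpha,
                                      gene_filter=flt)
             for flt in ("late", "early", "proximal", "distal")}
    amps = {flt: oscillation_amplitude(p, params.cycle_length)
            for flt, p in profs.items()}
    return {
        "late_significant": significant_oscillation(profs["late"]),
        "proximal_significant": significant_oscillation(profs["proximal"]),
        "amp_proximal_gt_distal": amps["proximal"] > amps["distal"],
        "amp_late_gt_early": amps["late"] > amps["early"],
        "amplitudes": amps,
    }


def null_trial(seed: int, alpha: float = 0.05) -> pd.DataFrame:
    """Full-set oscillation profile for an uncoupled (beta = 0) dataset."""
    params = SimulationParams(seed=seed, beta=0.0)
    genes, oris, profile, expr, async_expr, truth = simulate_dataset(params)
    config = RunConfig(alpha=alpha, s_start=params.s_start,
                       s_end=params.s_end, cycle_length=params.cycle_length)
    gene_trep = build_gene_trep(genes, oris, profile, config)
    return oscillation_profile(expr, gene_trep, alpha=alpha)


def monotone_coupled_dataset(seed: int, n: int = 400, trep_lo: float = 20.0,
                             trep_hi: float = 50.0, cutoff: float = 35.0,
                             slope: float = 0.07, noise_sd: float = 0.25,
                             baseline: float = 0.5):
    """Replication times with expression decreasing in T_rep only among
    late-replicating genes (flat among early ones), plus noise — the
    idealized shape behind the decile analysis.

    Returns (gene_trep DataFrame, expression Series).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    trep = rng.uniform(trep_lo, trep_hi, n)
    expr = baseline - slope * np.clip(trep - cutoff, 0.0, None) \
        + rng.normal(0.0, noise_sd, n)
    ids = pd.Index([f"g{i:04d}" for i in range(n)], name="gene_id")
    gene_trep = pd.DataFrame({"gene_id": ids, "trep": trep})
    return gene_trep, pd.Series(expr, index=ids)


def decile_shape_ok(table: pd.DataFrame) -> bool:
    """Fig-3A-like shape: medians strictly decreasing over deciles 6-10,
    flat (relative to the late-decile drop) over deciles 1-5."""
    med = table["median_expression"].to_numpy()
    late = med[5:]
    early = med[:5]
    strictly_decreasing = bool(np.all(np.diff(late) < 0))
    drop = late[0] - late[-1]
    flat_early = (early.max() - early.min()) < drop / 2
    return strictly_decreasing and flat_early


def copy_number_driven_levels(seed: int, n: int = 400,
                              cycle_length: float = 100.0,
                              trep_lo: float = 20.0, trep_hi: float = 48.0,
                              noise_sd: float = 0.05):
    """Asynchronous levels driven purely by copy number: level ~ (1 + f)
    with f the fraction of the cycle spent with two copies."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    trep = rng.uniform(trep_lo, trep_hi, n)
    f = (cycle_length - trep) / cycle_length
    levels = 3.0 * (1.0 + f) * np.exp(rng.normal(0.0, noise_sd, n))
    ids = pd.Index([f"g{i:04d}" for i in range(n)], name="gene_id")
    gene_trep = pd.DataFrame({"gene_id": ids, "trep": trep})
    return gene_trep, pd.Series(levels, index=ids)
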