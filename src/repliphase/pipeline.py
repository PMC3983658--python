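"""End-to-end association pipeline and run configuration.

Ties the stages together: read the five inputs, derive per-gene T_rep
and strata, compute oscillation profiles (all genes plus the early/late
and ORI-proximal/distal strata), the T_rep moving average over peak
expression times, the decile table at the configured G2 timepoint, and
the extreme-group comparisons. Writes plain TSV tables plus a JSON run
manifest (config, seed, input hashes, version) sufficient to reproduce
every output bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__, assoc, trep as trep_mod
from . import io as rio

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


@dataclass
class RunConfig:
    """Dataset-specific constants of the analysis.

    The defaults suit the synthetic datasets produced by
    :mod:`repliphase.simulate`; for real datasets every field is expected
    to come from the study design (e.g. which timepoint represents G2,
    the ORI-proximity cutoff chosen to split the gene list evenly).
    """

    genes: str = "genes.bed"
    oris: str = "oris.tsv"
    trep: str = "trep.tsv"
    cc_expression: str = "cc_expression.tsv"
    async_expression: str = "async.tsv"
    s_start: float = 20.0
    s_end: float = 40.0
    cycle_length: float = 100.0
    alpha: float = 0.05
    early_late_fraction: float = 0.5
    ori_proximity_bp: float = 5_000.0
    g2_timepoint: float = 50.0
    mg1_timepoint: float = 90.0
    moving_average_window: int = 100
    smoothing_k: int = 1
    t_test: str = "student"      # student | welch
    ori_statuses: tuple = ("confirmed", "likely")
    top_bottom_k: int = 100
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0.0 < self.early_late_fraction < 1.0:
            raise ConfigError("early_late_fraction must be in (0, 1)")
        if self.ori_proximity_bp <= 0:
            raise ConfigError("ori_proximity_bp must be positive")
        if not self.s_start < self.s_end:
            raise ConfigError("s_start must be < s_end")
        if self.moving_average_window < 2:
            raise ConfigError("moving_average_window must be >= 2")
        if self.smoothing_k < 1:
            raise ConfigError("smoothing_k must be >= 1")
        if self.t_test not in ("student", "welch"):
            raise ConfigError("t_test must be 'student' or 'welch'")
        if self.top_bottom_k < 2:
            raise ConfigError("top_bottom_k must be >= 2")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "ori_statuses" in d:
            d = dict(d, ori_statuses=tuple(d["ori_statuses"]))
        return cls(**d).validate()


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_gene_trep(genes, oris, profile, config: RunConfig) -> pd.DataFrame:
    """Per-gene T_rep, early/late label, ORI distance and proximity flag."""
    gt = trep_mod.interpolate_trep(profile, genes)
    gt = trep_mod.classify_early_late(gt, profile, config.early_late_fraction)
    gt = trep_mod.nearest_ori_distance(genes, oris, gt)
    gt = trep_mod.classify_ori_proximity(gt, config.ori_proximity_bp)
    n_missing = int(gt["trep"].isna().sum())
    if n_missing:
        logger.info("build_gene_trep: %d genes without T_rep (excluded downstream)",
                    n_missing)
    return gt


def associate(genes, oris, profile, expr, async_expr, config: RunConfig) -> dict:
    """Run every association analysis; returns a dict of result tables."""
    config.validate()
    equal_var = config.t_test == "student"
    gene_trep = build_gene_trep(genes, oris, profile, config)

    profiles = {}
    for name, flt in [("all", None), ("early", "early"), ("late", "late"),
                      ("proximal", "proximal"), ("distal", "distal")]:
        prof = assoc.oscillation_profile(expr, gene_trep, alpha=config.alpha,
                                         gene_filter=flt)
        prof.insert(0, "subset", name)
        profiles[name] = prof
    oscillation = pd.concat(profiles.values(), ignore_index=True)

    peak = assoc.peak_expression_time(expr)
    window = min(config.moving_average_window,
                 max(2, int(gene_trep["trep"].notna().sum())))
    moving_avg = assoc.trep_moving_average(gene_trep, peak, window)

    tps = expr.timepoints
    if config.g2_timepoint not in tps:
        raise ConfigError(f"g2_timepoint {config.g2_timepoint} not in the "
                          "expression time course")
    expr_g2 = expr.values[config.g2_timepoint]
    deciles = assoc.decile_median_expression(gene_trep, expr_g2)

    comparisons = []
    ext = assoc.decile_extremes_trep(gene_trep, expr_g2, equal_var=equal_var)
    ext.insert(0, "comparison", "induced_vs_repressed_G2")
    comparisons.append(ext)
    if config.mg1_timepoint in tps:
        ext2 = assoc.decile_extremes_trep(gene_trep,
                                          expr.values[config.mg1_timepoint],
                                          equal_var=equal_var)
        ext2.insert(0, "comparison", "induced_vs_repressed_MG1")
        comparisons.append(ext2)
    tb = assoc.compare_top_bottom_expression(async_expr, gene_trep,
                                             k=config.top_bottom_k,
                                             equal_var=equal_var)
    tb.insert(0, "comparison", f"async_top{config.top_bottom_k}_vs_bottom")
    comparisons.append(tb)
    comparisons = pd.concat(comparisons, ignore_index=True)

    return {"gene_trep": gene_trep, "oscillation_profile": oscillation,
            "moving_average": moving_avg, "decile_table": deciles,
            "comparisons": comparisons}


REPORT_TABLES = ["gene_trep", "oscillation_profile", "moving_average",
                 "decile_table", "comparisons"]


def run_associate(config: RunConfig, outdir) -> dict:
    """Load inputs per config, run :func:`associate`, write tables + manifest."""
    config.validate()
    for fieldname in ("genes", "oris", "trep", "cc_expression", "async_expression"):
        path = getattr(config, fieldname)
        if not Path(path).exists():
            raise ConfigError(f"{fieldname}: input file not found: {path}")
    genes = rio.read_genes(config.genes)
    oris = rio.read_oris(config.oris, statuses=config.ori_statuses)
    profile = rio.read_trep_profile(config.trep, config.s_start, config.s_end)
    expr = rio.read_expression(config.cc_expression)
    async_expr = rio.read_async(config.async_expression)

    results = associate(genes, oris, profile, expr, async_expr, config)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in REPORT_TABLES:
        rio.write_table(results[name], outdir / f"{name}.tsv")
    manifest = {
        "tool": "repliphase", "version": __version__,
        "config": {**dataclasses.asdict(config),
                   "ori_statuses": list(config.ori_statuses)},
        "seed": config.seed,
        "inputs": {f: _sha256(getattr(config, f2))
                   for f, f2 in [("genes", "genes"), ("oris", "oris"),
                                 ("trep", "trep"),
                                 ("cc_expression", "cc_expression"),
                                 ("async_expression", "async_expression")]},
        "outputs": REPORT_TABLES,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True),
                                          encoding="utf-8")
    return results


def summarize(outdir) -> str:
    """Plain-text summary of a results directory (the `report` command)."""
    outdir = Path(outdir)
    osc = pd.read_csv(outdir / "oscillation_profile.tsv", sep="\t")
    comp = pd.read_csv(outdir / "comparisons.tsv", sep="\t")
    alpha = 0.05
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        alpha = json.loads(manifest_path.read_text())["config"]["alpha"]
    lines = []
    for subset, grp in osc.groupby("subset", sort=False):
        ok = grp.dropna(subset=["r"])
        n_sig = int(ok["significant"].sum())
        exp_fp = len(ok) * alpha
        lines.append(
            f"{subset:9s} genes={int(ok['n_pairs'].max()) if len(ok) else 0:5d} "
            f"r range [{ok['r'].min():+.3f}, {ok['r'].max():+.3f}] "
            f"significant timepoints {n_sig}/{len(ok)} "
            f"(~{exp_fp:.1f} expected by chance)")
    for _, row in comp.iterrows():
        lines.append(
            f"{row['comparison']}: mean T_rep {row['mean1']:.2f} vs "
            f"{row['mean2']:.2f} min (diff {row['difference']:+.2f}, "
            f"p={row['p']:.3g}, n={int(row['n1'])}/{int(row['n2'])})")
    return "\n".join(lines)
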