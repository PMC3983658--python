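"""Readers, writers and validated containers for the pipeline's inputs.

All genomic coordinates are 0-based half-open (BED convention). Inputs in
1-based inclusive coordinates (GFF-style) must be converted at the boundary
with :func:`from_one_based`. Files are tab-separated UTF-8 text with ``NA``
for missing values.

Containers
----------
GeneTable / OriTable
    plain :class:`pandas.DataFrame` objects with fixed columns, checked by
    :func:`validate_genes` / :func:`validate_oris`.
TrepProfile
    per-chromosome sorted probe positions with replication times plus the
    S-phase bounds of the dataset, on the same time scale.
ExpressionTimecourse
    genes x timepoints matrix of log2 ratios versus asynchronous cells,
    with timepoint minutes and a cell-cycle phase label per timepoint.
AsyncExpression
    per-gene asynchronous expression level with a flag recording whether
    levels are already per-DNA-copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
ORI_COLUMNS = ["ori_id", "chrom", "start", "end", "status"]
ORI_STATUSES = frozenset({"confirmed", "likely", "dubious"})

MISSING = "NA"


class FormatError(ValueError):
    """Malformed input file (carries the offending line where known)."""


def from_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start - 1, end


# ---------------------------------------------------------------------------
# genes (BED)
# ---------------------------------------------------------------------------

def validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise FormatError(f"gene table lacks columns: {missing}")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicated gene_id: {dup!r}")
    if (genes["start"] >= genes["end"]).any():
        bad = genes.index[genes["start"] >= genes["end"]][0]
        raise FormatError(f"gene row {bad}: start >= end")
    if (genes["start"] < 0).any():
        raise FormatError("negative gene coordinates")
    bad_strand = ~genes["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(
            f"invalid strand value {genes.loc[bad_strand, 'strand'].iloc[0]!r}"
        )
    return genes


def read_genes(path) -> pd.DataFrame:
    """Read a BED file of gene loci into a GeneTable.

    BED6 expected; with fewer than 6 columns the strand defaults to ``+``
    (warning logged). Input order is preserved.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        defaulted = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates {start!r}/{end!r}"
                ) from None
            if start_i >= end_i:
                raise FormatError(f"{path}:{lineno}: start >= end")
            if len(parts) >= 6:
                strand = parts[5]
            else:
                strand = "+"
                defaulted += 1
            rows.append((name, chrom, start_i, end_i, strand))
    if defaulted:
        logger.warning("%s: %d records lack a strand column; defaulting to '+'",
                       path, defaulted)
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return validate_genes(genes)


def write_genes(genes: pd.DataFrame, path) -> None:
    validate_genes(genes)
    out = genes[["chrom", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = genes["strand"].to_numpy()
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# ORIs (TSV)
# ---------------------------------------------------------------------------

def validate_oris(oris: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ORI_COLUMNS if c not in oris.columns]
    if missing:
        raise FormatError(f"ORI table lacks columns: {missing}")
    if len(oris) and (oris["start"] >= oris["end"]).any():
        raise FormatError("ORI interval with start >= end")
    unknown = set(oris["status"]) - ORI_STATUSES
    if unknown:
        raise FormatError(f"unknown ORI status value(s): {sorted(unknown)}")
    return oris


def read_oris(path, statuses=("confirmed", "likely")) -> pd.DataFrame:
    """Read an ORIdb-style TSV and keep only rows with the given statuses.

    The default retains only confirmed and likely origins, dropping dubious
    ones. The number of dropped rows is logged.
    """
    statuses = set(statuses)
    unknown = statuses - ORI_STATUSES
    if unknown:
        raise ValueError(f"unknown status filter value(s): {sorted(unknown)}")
    oris = pd.read_csv(path, sep="\t", dtype={"ori_id": str, "chrom": str})
    if len(oris) == 0:
        logger.warning("%s: empty ORI table", path)
        cols = ORI_COLUMNS + (["firing_time"] if "firing_time" in oris.columns else [])
        return pd.DataFrame(columns=cols)
    validate_oris(oris)
    kept = oris[oris["status"].isin(statuses)].reset_index(drop=True)
    dropped = len(oris) - len(kept)
    if dropped:
        logger.info("%s: dropped %d ORIs outside statuses %s", path, dropped,
                    sorted(statuses))
    return kept


def write_oris(oris: pd.DataFrame, path) -> None:
    validate_oris(oris)
    oris.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def ori_point(start, end):
    """Point location of an ORI interval: floor((start+end)/2)."""
    return (np.asarray(start) + np.asarray(end)) // 2


# ---------------------------------------------------------------------------
# replication-timing profile (bedGraph-like TSV)
# ---------------------------------------------------------------------------

@dataclass
class TrepProfile:
    """Per-chromosome probe positions (bp, strictly increasing) with
    replication times (minutes into S phase, or a generic scalar), and the
    S-phase start/end of the dataset on the same scale."""

    chroms: dict = field(default_factory=dict)  # chrom -> (positions, trep)
    s_start: float = 0.0
    s_end: float = 1.0

    def __post_init__(self):
        if not self.s_start < self.s_end:
            raise ValueError("s_start must be < s_end")
        for chrom, (pos, trep) in self.chroms.items():
            pos = np.asarray(pos, dtype=float)
            trep = np.asarray(trep, dtype=float)
            if pos.ndim != 1 or pos.shape != trep.shape:
                raise ValueError(f"{chrom}: positions/trep shape mismatch")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions not strictly increasing")
            if not np.all(np.isfinite(trep)):
                raise ValueError(f"{chrom}: non-finite trep values")
            self.chroms[chrom] = (pos, trep)

    @property
    def n_probes(self) -> int:
        return sum(len(p) for p, _ in self.chroms.values())

    def trep_range(self) -> tuple[float, float]:
        lo = min(t.min() for _, t in self.chroms.values())
        hi = max(t.max() for _, t in self.chroms.values())
        return float(lo), float(hi)


def read_trep_profile(path, s_start: float, s_end: float) -> TrepProfile:
    """Read a (chrom, position, trep) TSV into a :class:`TrepProfile`.

    Rows may be unsorted; duplicate positions on a chromosome are collapsed
    to their mean with a warning.
    """
    if not s_start < s_end:
        raise ValueError("s_start must be < s_end")
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "position", "trep"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    if df["trep"].isna().any():
        bad = int(df.index[df["trep"].isna()][0]) + 2  # header is line 1
        raise FormatError(f"{path}:{bad}: non-numeric trep value")
    chroms = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("position", kind="stable")
        if grp["position"].duplicated().any():
            n_dup = int(grp["position"].duplicated().sum())
            logger.warning("%s: %s: %d duplicate probe positions collapsed to mean",
                           path, chrom, n_dup)
            grp = grp.groupby("position", as_index=False)["trep"].mean()
        chroms[str(chrom)] = (grp["position"].to_numpy(dtype=float),
                              grp["trep"].to_numpy(dtype=float))
    return TrepProfile(chroms=chroms, s_start=float(s_start), s_end=float(s_end))


def write_trep_profile(profile: TrepProfile, path) -> None:
    frames = []
    for chrom, (pos, trep) in sorted(profile.chroms.items()):
        frames.append(pd.DataFrame(
            {"chrom": chrom, "position": pos.astype(int), "trep": trep}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cell-cycle expression time course
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTimecourse:
    """Log2 expression ratios versus asynchronous cells.

    ``values`` is genes x timepoints (index gene_id, columns are timepoint
    minutes as floats); ``phases`` labels each timepoint with its
    approximate cell-cycle phase (G1, S, G2, M, M/G1).
    """

    values: pd.DataFrame
    phases: list

    def __post_init__(self):
        tps = self.timepoints
        if len(tps) < 3:
            raise ValueError("need at least 3 timepoints")
        if np.any(np.diff(tps) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if len(self.phases) != len(tps):
            raise ValueError("one phase label per timepoint required")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated gene_id: {dup!r}")

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


def read_expression(path) -> ExpressionTimecourse:
    """Read a timecourse TSV with a two-row header (minutes; phase label)."""
    with open(path, encoding="utf-8") as fh:
        header1 = fh.readline().rstrip("\n").split("\t")
        header2 = fh.readline().rstrip("\n").split("\t")
        if header1[0] != "gene_id" or header2[0] != "phase":
            raise FormatError(f"{path}: expected 'gene_id' then 'phase' header rows")
        try:
            minutes = [float(x) for x in header1[1:]]
        except ValueError:
            raise FormatError(f"{path}: non-numeric timepoint minutes") from None
        phases = header2[1:]
        df = pd.read_csv(fh, sep="\t", header=None, na_values=[MISSING])
    if df.shape[1] != len(minutes) + 1:
        raise FormatError(f"{path}: ragged rows")
    df = df.set_index(0)
    df.index.name = "gene_id"
    df.columns = minutes
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicated gene ids")
    if np.any(np.diff(minutes) <= 0):
        raise FormatError(f"{path}: timepoint minutes not strictly increasing")
    return ExpressionTimecourse(values=df.astype(float), phases=list(phases))


def write_expression(expr: ExpressionTimecourse, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        minutes = [f"{m:g}" for m in expr.timepoints]
        fh.write("\t".join(["gene_id"] + minutes) + "\n")
        fh.write("\t".join(["phase"] + list(expr.phases)) + "\n")
        expr.values.to_csv(fh, sep="\t", header=False, na_rep=MISSING,
                           float_format="%.6g")


# ---------------------------------------------------------------------------
# asynchronous expression
# ---------------------------------------------------------------------------

@dataclass
class AsyncExpression:
    """Per-gene asynchronous expression level (non-negative scalar)."""

    levels: pd.Series  # index gene_id
    per_copy_normalized: bool = False

    def __post_init__(self):
        if self.levels.index.duplicated().any():
            raise ValueError("duplicated gene ids in asynchronous table")
        vals = self.levels.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite asynchronous level")
        if (vals < 0).any():
            raise ValueError("negative asynchronous level")


def read_async(path) -> AsyncExpression:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    required = {"gene_id", "level"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    per_copy = bool(df["per_copy_normalized"].iloc[0]) if (
        "per_copy_normalized" in df.columns and len(df)) else False
    levels = df.set_index("gene_id")["level"].astype(float)
    return AsyncExpression(levels=levels, per_copy_normalized=per_copy)


def write_async(async_expr: AsyncExpression, path) -> None:
    df = pd.DataFrame({
        "gene_id": async_expr.levels.index,
        "level": async_expr.levels.to_numpy(),
        "per_copy_normalized": async_expr.per_copy_normalized,
    })
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING, float_format="%.6g")


def write_table(table: pd.DataFrame, path) -> None:
    """Write a generic result table as TSV with NA for missing cells."""
    table.to_csv(path, sep="\t", index=False, na_rep=MISSING, float_format="%.6g")
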