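"""Per-gene replication times and stratification labels.

Maps a replication-timing profile onto genes by linear interpolation to
each gene's midpoint, classifies genes as early/late replicating relative
to a cutoff inside S phase, computes distances from gene 5' ends to the
nearest replication origin, and calls early-replicating peaks (active
initiation zones) in low-resolution profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TrepProfile, ori_point

logger = logging.getLogger(__name__)


def gene_midpoint(start, end):
    """Midpoint of a gene interval, floor((start+end)/2)."""
    return (np.asarray(start) + np.asarray(end)) // 2


def five_prime_end(start, end, strand):
    """Position of the 5' end: ``start`` on '+', ``end``-1 on '-'.

    In half-open coordinates ``end - 1`` is the last covered base.
    """
    start = np.asarray(start)
    end = np.asarray(end)
    minus = np.asarray(strand) == "-"
    return np.where(minus, end - 1, start)


def interpolate_trep(profile: TrepProfile, genes: pd.DataFrame) -> pd.DataFrame:
    """Map replication times onto genes (GeneTrep table).

    The replication time at each gene's midpoint is obtained by linear
    interpolation between the two flanking probes; a midpoint exactly on a
    probe takes that probe's value. Midpoints outside the probed span of
    their chromosome, or on chromosomes absent from the profile, get a
    missing value (no extrapolation); counts are logged.
    """
    mid = gene_midpoint(genes["start"].to_numpy(), genes["end"].to_numpy())
    trep = np.full(len(genes), np.nan)
    n_no_chrom = n_outside = 0
    chrom_arr = genes["chrom"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        mask = chrom_arr == chrom
        if chrom not in profile.chroms:
            n_no_chrom += int(mask.sum())
            continue
        pos, values = profile.chroms[chrom]
        m = mid[mask].astype(float)
        inside = (m >= pos[0]) & (m <= pos[-1])
        n_outside += int((~inside).sum())
        interp = np.interp(m, pos, values)
        interp[~inside] = np.nan
        trep[mask] = interp
    if n_no_chrom or n_outside:
        logger.info("interpolate_trep: %d genes on unprofiled chromosomes, "
                    "%d outside the probed span (set to missing)",
                    n_no_chrom, n_outside)
    return pd.DataFrame({"gene_id": genes["gene_id"].to_numpy(), "trep": trep})


def classify_early_late(gene_trep: pd.DataFrame, profile: TrepProfile,
                        fraction: float = 0.5) -> pd.DataFrame:
    """Label genes early/late by a cutoff a given fraction into S phase.

    cutoff = s_start + fraction * (s_end - s_start); replication at or
    before the cutoff is "early" (the first part of S phase read as
    inclusive). Missing replication times stay unlabelled.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    cutoff = profile.s_start + fraction * (profile.s_end - profile.s_start)
    out = gene_trep.copy()
    trep = out["trep"].to_numpy(dtype=float)
    labels = np.where(trep <= cutoff, "early", "late")
    out["early_late"] = pd.array(labels, dtype="string")
    out.loc[np.isnan(trep), "early_late"] = pd.NA
    return out


def nearest_ori_distance(genes: pd.DataFrame, oris: pd.DataFrame,
                         gene_trep: pd.DataFrame | None = None) -> pd.DataFrame:
    """Distance (bp) from each gene's 5' end to the nearest ORI point.

    ORI points are interval midpoints. Genes on chromosomes with no ORI get
    a missing distance.
    """
    if gene_trep is None:
        gene_trep = pd.DataFrame({"gene_id": genes["gene_id"].to_numpy()})
    out = gene_trep.copy()
    five = five_prime_end(genes["start"].to_numpy(), genes["end"].to_numpy(),
                          genes["strand"].to_numpy()).astype(float)
    dist = np.full(len(genes), np.nan)
    chrom_arr = genes["chrom"].to_numpy()
    pts_all = ori_point(oris["start"].to_numpy(), oris["end"].to_numpy()) \
        if len(oris) else np.array([], dtype=int)
    for chrom in pd.unique(chrom_arr):
        mask = chrom_arr == chrom
        if len(oris) == 0:
            continue
        pts = np.sort(pts_all[(oris["chrom"] == chrom).to_numpy()]).astype(float)
        if len(pts) == 0:
            continue
        x = five[mask]
        idx = np.searchsorted(pts, x)
        left = np.abs(x - pts[np.clip(idx - 1, 0, len(pts) - 1)])
        right = np.abs(pts[np.clip(idx, 0, len(pts) - 1)] - x)
        dist[mask] = np.minimum(left, right)
    out["ori_distance"] = dist
    return out


def classify_ori_proximity(gene_trep: pd.DataFrame, cutoff_bp: float) -> pd.DataFrame:
    """Label genes ORI-proximal (distance <= cutoff) or distal (> cutoff)."""
    if not cutoff_bp > 0:
        raise ValueError("cutoff_bp must be positive")
    out = gene_trep.copy()
    d = out["ori_distance"].to_numpy(dtype=float)
    prox = pd.array(d <= cutoff_bp, dtype="boolean")
    prox[np.isnan(d)] = pd.NA
    out["ori_proximal"] = prox
    return out


@dataclass
class PeakSet:
    """Early-replicating peaks: local minima of the (smoothed) profile,
    indicating active initiation zones."""

    table: pd.DataFrame  # columns chrom, peak_position, peak_trep

    def __len__(self):
        return len(self.table)


def _box_smooth(pos: np.ndarray, values: np.ndarray, window_bp: float) -> np.ndarray:
    """Mean of values within +-window_bp of each probe position."""
    lo = np.searchsorted(pos, pos - window_bp, side="left")
    hi = np.searchsorted(pos, pos + window_bp, side="right")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def call_early_peaks(profile: TrepProfile, smooth_window_bp: float | None = None,
                     prominence: float | None = None) -> PeakSet:
    """Find early-replicating peaks in a replication-timing profile.

    The profile is box-smoothed over ``+-smooth_window_bp``; a peak is a
    probe whose smoothed value is a strict minimum among all probes within
    that window and lies at least ``prominence`` below the lower of its two
    flanking local maxima. Chromosome boundary probes are never peaks.

    Defaults: smoothing window 3x the median probe spacing; prominence
    10% of the S-phase span.
    """
    rows = []
    spacings = np.concatenate([np.diff(p) for p, _ in profile.chroms.values()
                               if len(p) > 1]) if profile.chroms else np.array([1.0])
    median_spacing = float(np.median(spacings)) if len(spacings) else 1.0
    if smooth_window_bp is None:
        smooth_window_bp = 3.0 * median_spacing
    if prominence is None:
        prominence = 0.1 * (profile.s_end - profile.s_start)
    if smooth_window_bp < median_spacing:
        logger.warning("smoothing window (%.0f bp) below median probe spacing "
                       "(%.0f bp)", smooth_window_bp, median_spacing)
    for chrom, (pos, trep) in sorted(profile.chroms.items()):
        if len(pos) < 3:
            continue
        sm = _box_smooth(pos, trep, smooth_window_bp)
        # local minimum within +-window; a flat valley bottom (equal smoothed
        # values at adjacent probes) counts as one minimum at its lowest probe
        lo = np.searchsorted(pos, pos - smooth_window_bp, side="left")
        hi = np.searchsorted(pos, pos + smooth_window_bp, side="right")
        flat_ok = []
        for i in range(1, len(pos) - 1):
            neighborhood = np.r_[sm[lo[i]:i], sm[i + 1:hi[i]]]
            if neighborhood.size and np.all(sm[i] <= neighborhood):
                flat_ok.append(i)
        candidates = []
        run = []
        for i in flat_ok:
            if run and i == run[-1] + 1:
                run.append(i)
            else:
                if run:
                    candidates.append(run[int(np.argmin(sm[run]))])
                run = [i]
        if run:
            candidates.append(run[int(np.argmin(sm[run]))])
        # a plateau minimum must still be strictly below something in range
        candidates = [i for i in candidates
                      if sm[i] < np.r_[sm[lo[i]:i], sm[i + 1:hi[i]]].max()]
        # prominence: depth below the lower flanking local maximum, where the
        # flanking maxima are taken between this minimum and the adjacent
        # candidate minima (or the chromosome ends)
        bounds = [0] + candidates + [len(pos) - 1]
        for j, i in enumerate(candidates):
            left_max = sm[bounds[j]:i + 1].max()
            right_max = sm[i:bounds[j + 2] + 1].max()
            if min(left_max, right_max) - sm[i] >= prominence:
                rows.append((chrom, int(pos[i]), float(trep[i])))
    table = pd.DataFrame(rows, columns=["chrom", "peak_position", "peak_trep"])
    return PeakSet(table=table)


def activate_oris(candidate_sites: pd.DataFrame, peaks: PeakSet,
                  window_bp: float = 1_000_000) -> pd.DataFrame:
    """Keep candidate ORI sites within ``window_bp`` of an early peak.

    Mirrors the definition of active origins in low-resolution human data:
    origin-licensing sites are retained only when they lie within the
    window of a same-chromosome early-replicating peak. Distances are
    compared inclusively. With no peaks at all an empty table is returned
    with a warning.
    """
    if len(peaks) == 0:
        logger.warning("activate_oris: no peaks; returning empty ORI set")
        return candidate_sites.iloc[0:0].copy()
    pts = ori_point(candidate_sites["start"].to_numpy(),
                    candidate_sites["end"].to_numpy()).astype(float)
    keep = np.zeros(len(candidate_sites), dtype=bool)
    chrom_arr = candidate_sites["chrom"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        mask = chrom_arr == chrom
        ppos = np.sort(peaks.table.loc[peaks.table["chrom"] == chrom,
                                       "peak_position"].to_numpy(dtype=float))
        if len(ppos) == 0:
            continue
        x = pts[mask]
        idx = np.searchsorted(ppos, x)
        left = np.abs(x - ppos[np.clip(idx - 1, 0, len(ppos) - 1)])
        right = np.abs(ppos[np.clip(idx, 0, len(ppos) - 1)] - x)
        keep[mask] = np.minimum(left, right) <= window_bp
    return candidate_sites[keep].reset_index(drop=True)
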