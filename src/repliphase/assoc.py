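"""Statistics linking cell-cycle transcription to replication timing.

The central object is the oscillation profile: the Pearson correlation
between per-gene expression at each timepoint of a synchronized time
course and per-gene replication time (T_rep). By convention positive r
means up-regulated genes replicate late; negative r means up-regulated
genes replicate early. Supporting statistics: per-timepoint significance
thresholds from the t distribution, moving averages of T_rep over genes
ordered by peak expression time, decile summaries, extreme-group
comparisons, a DNA copy-number correction for asynchronous expression,
and variance explained (r^2).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import AsyncExpression, ExpressionTimecourse

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlation primitives
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> tuple[float, int]:
    """Pearson correlation on pairwise-complete observations.

    Returns ``(r, n_pairs)``. With fewer than 3 complete pairs or a
    constant vector the result is undefined and flagged as ``nan`` (never
    silently zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return float("nan"), n
    xs, ys = x[ok], y[ok]
    dx = xs - xs.mean()
    dy = ys - ys.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return float("nan"), n
    return float(dx @ dy / np.sqrt(sxx * syy)), n


def critical_r(n: int, alpha: float) -> float:
    """|r| threshold at two-tailed level alpha for sample size n.

    Inverts the t test of a correlation coefficient:
    t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom, so the
    threshold is t*/sqrt(n-2+t*^2).
    """
    if n < 4:
        raise ValueError("critical_r requires n >= 4")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / np.sqrt(n - 2 + t * t))


def variance_explained(x, y) -> float:
    """Fraction of variance explained: the square of the Pearson r."""
    r, _ = pearson_r(x, y)
    return r * r


# ---------------------------------------------------------------------------
# oscillation profiles
# ---------------------------------------------------------------------------

def _filter_gene_ids(gene_trep: pd.DataFrame, gene_filter: str | None) -> pd.Index:
    gt = gene_trep.set_index("gene_id") if "gene_id" in gene_trep.columns else gene_trep
    if gene_filter is None:
        return gt.index
    if gene_filter in ("early", "late"):
        mask = gt["early_late"] == gene_filter
    elif gene_filter == "proximal":
        mask = gt["ori_proximal"] == True  # noqa: E712 (nullable boolean)
    elif gene_filter == "distal":
        mask = gt["ori_proximal"] == False  # noqa: E712
    else:
        raise ValueError(f"unknown gene_filter {gene_filter!r}")
    return gt.index[mask.fillna(False)]


def oscillation_profile(expr: ExpressionTimecourse, gene_trep: pd.DataFrame,
                        alpha: float = 0.05,
                        gene_filter: str | None = None) -> pd.DataFrame:
    """Per-timepoint correlation between expression and replication time.

    For every timepoint, the Pearson r between the expression of the
    (optionally filtered) genes at that timepoint and their T_rep, on
    pairwise-complete observations. Positive r: up-regulated genes
    replicate late. Each row carries the n used, the |r| significance
    threshold at ``alpha`` for that n, and a significance flag. Timepoints
    with fewer than 3 complete pairs are flagged as missing.

    ``gene_filter`` is one of None, 'early', 'late', 'proximal', 'distal',
    selecting strata prepared by :mod:`repliphase.trep`.
    """
    ids = _filter_gene_ids(gene_trep, gene_filter)
    gt = gene_trep.set_index("gene_id")
    common = expr.gene_ids.intersection(ids)
    dropped = len(ids) - len(common)
    if dropped:
        logger.info("oscillation_profile: %d genes absent from expression data",
                    dropped)
    trep = gt.loc[common, "trep"].to_numpy(dtype=float)
    values = expr.values.loc[common]
    rows = []
    for j, tp in enumerate(expr.timepoints):
        r, n = pearson_r(values.iloc[:, j].to_numpy(), trep)
        if np.isnan(r) or n < 3:
            rows.append((tp, expr.phases[j], np.nan, n, np.nan, False))
            continue
        crit = critical_r(n, alpha) if n >= 4 else np.nan
        rows.append((tp, expr.phases[j], r, n, crit,
                     bool(abs(r) > crit) if np.isfinite(crit) else False))
    return pd.DataFrame(rows, columns=["timepoint", "phase", "r", "n_pairs",
                                       "critical_r", "significant"])


def smooth_profile(r, k: int = 2) -> np.ndarray:
    """k-point forward moving average of a correlation series.

    Output length shrinks by k-1; k=1 is the identity. Used for plotting
    noisy profiles from densely sampled time courses.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    r = np.asarray(r, dtype=float)
    if k == 1:
        return r.copy()
    kernel = np.ones(k) / k
    return np.convolve(r, kernel, mode="valid")


def oscillation_amplitude(profile: pd.DataFrame,
                          cycle_length: float | None = None) -> float:
    """Amplitude (max r - min r) of an oscillation profile.

    With ``cycle_length`` given, the r series is first folded: timepoints
    at the same position in the cycle (modulo cycle_length) are averaged
    across cycles, which suppresses the spurious sinusoidal wobble a
    finite gene set produces even without true coupling.
    """
    r = profile["r"].to_numpy(dtype=float)
    if cycle_length is not None:
        pos = np.round(profile["timepoint"].to_numpy(dtype=float)
                       % cycle_length, 6)
        folded = pd.Series(r).groupby(pos).mean().to_numpy()
        r = folded
    r = r[np.isfinite(r)]
    if r.size == 0:
        return float("nan")
    return float(r.max() - r.min())


# ---------------------------------------------------------------------------
# peak expression time and moving averages
# ---------------------------------------------------------------------------

def peak_expression_time(expr: ExpressionTimecourse) -> pd.Series:
    """Timepoint (minutes) of maximal expression per gene.

    Ties are broken by the earliest timepoint; all-missing rows yield a
    missing value.
    """
    vals = expr.values.to_numpy(dtype=float)
    tps = expr.timepoints
    out = np.full(vals.shape[0], np.nan)
    has_data = ~np.all(~np.isfinite(vals), axis=1)
    masked = np.where(np.isfinite(vals), vals, -np.inf)
    idx = np.argmax(masked, axis=1)  # argmax returns the first maximum
    out[has_data] = tps[idx[has_data]]
    return pd.Series(out, index=expr.gene_ids, name="peak_time")


def trep_moving_average(gene_trep: pd.DataFrame, ordering: pd.Series,
                        window: int) -> pd.DataFrame:
    """Moving average of T_rep over genes ordered by peak expression time.

    ``ordering`` maps gene_id to peak expression time (minutes from
    release, i.e. from just after mitosis). Genes without T_rep or peak
    time are dropped; the rest are sorted by (peak time, gene_id) and
    averaged in sliding windows of exactly ``window`` consecutive genes
    (step 1, non-wrapping). Each window reports the center gene's peak
    time, the mean T_rep and its standard error sd/sqrt(window).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    gt = gene_trep.set_index("gene_id")
    df = pd.DataFrame({"trep": gt["trep"], "peak": ordering}).dropna()
    df = df.sort_index(kind="stable").sort_values("peak", kind="stable")
    if window > len(df):
        raise ValueError("window exceeds the number of ordered genes with T_rep")
    trep = df["trep"].to_numpy()
    peak = df["peak"].to_numpy()
    kernel = np.ones(window) / window
    means = np.convolve(trep, kernel, mode="valid")
    sq = np.convolve(trep ** 2, kernel, mode="valid")
    var = (sq - means ** 2) * window / (window - 1)
    var = np.clip(var, 0.0, None)
    se = np.sqrt(var / window)
    centers = peak[(window - 1) // 2: (window - 1) // 2 + len(means)]
    return pd.DataFrame({"window": np.arange(len(means)),
                         "center_peak_time": centers,
                         "mean_trep": means, "se_trep": se})


# ---------------------------------------------------------------------------
# deciles and group comparisons
# ---------------------------------------------------------------------------

def _decile_bins(n: int) -> np.ndarray:
    """Bin sizes for 10 near-equal bins; the remainder goes to the first bins."""
    size, rem = divmod(n, 10)
    return np.array([size + 1] * rem + [size] * (10 - rem))


def decile_median_expression(gene_trep: pd.DataFrame,
                             expr_at_timepoint: pd.Series) -> pd.DataFrame:
    """Median expression per T_rep decile.

    Genes with both T_rep and expression are ranked by increasing T_rep
    (ties broken by gene_id) and split into 10 bins whose sizes differ by
    at most one (the remainder enlarges the earliest bins). Decile 1 holds
    the earliest-replicating genes.
    """
    gt = gene_trep.set_index("gene_id")
    df = pd.DataFrame({"trep": gt["trep"], "expr": expr_at_timepoint}).dropna()
    if len(df) < 10:
        raise ValueError("need at least 10 genes with T_rep and expression")
    df = df.sort_index(kind="stable").sort_values("trep", kind="stable")
    sizes = _decile_bins(len(df))
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rows = []
    for d in range(10):
        chunk = df.iloc[bounds[d]:bounds[d + 1]]
        rows.append((d + 1, float(chunk["expr"].median()),
                     float(chunk["trep"].median()), len(chunk)))
    return pd.DataFrame(rows, columns=["decile", "median_expression",
                                       "median_trep", "n"])


def _group_comparison(trep1: np.ndarray, trep2: np.ndarray,
                      label1: str, label2: str,
                      equal_var: bool = True) -> pd.DataFrame:
    m1, m2 = trep1.mean(), trep2.mean()
    se1 = trep1.std(ddof=1) / np.sqrt(len(trep1))
    se2 = trep2.std(ddof=1) / np.sqrt(len(trep2))
    if np.allclose(trep1, trep1[0]) and np.allclose(trep2, trep2[0]) \
            and np.isclose(m1, m2):
        t, p = 0.0, 1.0  # identical constant groups: no evidence of difference
    else:
        t, p = stats.ttest_ind(trep1, trep2, equal_var=equal_var)
    return pd.DataFrame([{
        "group1": label1, "group2": label2,
        "mean1": m1, "mean2": m2, "se1": se1, "se2": se2,
        "difference": m1 - m2, "t": float(t), "p": float(p),
        "n1": len(trep1), "n2": len(trep2),
    }])


def decile_extremes_trep(gene_trep: pd.DataFrame, expr_at_timepoint: pd.Series,
                         equal_var: bool = True) -> pd.DataFrame:
    """Mean T_rep of the most-induced versus most-repressed decile.

    Genes are ranked by expression at the chosen timepoint; the top and
    bottom 10% are compared by a two-tailed t test on their T_rep
    (Student's pooled-variance test by default). Ties in the expression
    ranking are broken by gene_id and logged.
    """
    gt = gene_trep.set_index("gene_id")
    df = pd.DataFrame({"trep": gt["trep"], "expr": expr_at_timepoint}).dropna()
    if len(df) < 20:
        raise ValueError("need at least 20 genes for decile extremes")
    k = len(df) // 10
    if k < 2:
        raise ValueError("decile size below 2")
    if df["expr"].duplicated().any():
        logger.info("decile_extremes_trep: expression ties broken by gene_id")
    df = df.sort_index(kind="stable").sort_values("expr", kind="stable")
    bottom = df.iloc[:k]["trep"].to_numpy()
    top = df.iloc[-k:]["trep"].to_numpy()
    return _group_comparison(top, bottom, "induced", "repressed",
                             equal_var=equal_var)


def compare_top_bottom_expression(async_expr: AsyncExpression,
                                  gene_trep: pd.DataFrame, k: int = 100,
                                  equal_var: bool = True) -> pd.DataFrame:
    """Mean T_rep of the k highest- versus k lowest-expressed genes.

    Uses asynchronous expression levels; two-tailed t test on T_rep.
    Ties spanning the k-th rank are broken lexicographically by gene_id
    (logged), so results are deterministic.
    """
    gt = gene_trep.set_index("gene_id")
    df = pd.DataFrame({"trep": gt["trep"],
                       "level": async_expr.levels}).dropna()
    if len(df) < 2 * k:
        raise ValueError(f"need at least {2 * k} genes with T_rep and level")
    if df["level"].duplicated().any():
        logger.info("compare_top_bottom_expression: level ties broken by gene_id")
    df = df.sort_index(kind="stable").sort_values("level", kind="stable")
    bottom = df.iloc[:k]["trep"].to_numpy()
    top = df.iloc[-k:]["trep"].to_numpy()
    return _group_comparison(top, bottom, "top", "bottom", equal_var=equal_var)


# ---------------------------------------------------------------------------
# copy-number correction
# ---------------------------------------------------------------------------

def copy_number_correction(async_expr: AsyncExpression, gene_trep: pd.DataFrame,
                           cycle_length: float, kappa: float = 0.5) -> AsyncExpression:
    """Correct asynchronous levels for replication-driven copy number.

    A gene replicated at time t (on the whole-cycle clock) spends a
    fraction f = (cycle_length - t)/cycle_length of the cycle with two
    copies, inflating its apparent expression. The correction subtracts a
    fraction of each level proportional to that time:
    corrected = level * (1 - kappa * f). With kappa = 0.5 the correction
    agrees with exact per-copy normalization level/(1+f) at both
    endpoints f = 0 and f = 1.

    Genes without T_rep keep their level unchanged (no copy-number
    information). The result is flagged per-copy normalized.
    """
    if async_expr.per_copy_normalized:
        raise ValueError("levels are already per-copy normalized")
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    gt = gene_trep.set_index("gene_id")
    trep = gt["trep"].reindex(async_expr.levels.index)
    f = (cycle_length - trep) / cycle_length
    if ((f < 0) | (f > 1)).any():
        raise ValueError("copy-time fraction outside [0, 1]; "
                         "inconsistent cycle_length")
    factor = (1.0 - kappa * f).fillna(1.0)
    return AsyncExpression(levels=async_expr.levels * factor,
                           per_copy_normalized=True)
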