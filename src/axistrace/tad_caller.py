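"""TAD boundary detection and hierarchical domain assembly.

Each bin is scored with an insulation-style contrast: within a fixed
window on each side of the bin, pairwise-difference variances crossing the
bin (upstream x downstream pairs) are pooled into an inter-domain variance
and compared against the pooled intra-domain variance (pairs within a
side) by an upper-tail F test, per axis.  Axis p-values are combined with
the weighted aggregated Cauchy test and screened with BH FDR.

With thousands of traces the raw FDR profile saturates at 0/1, so peak
finding runs on an approximated profile in which the same variance ratios
are referred to an F(1, 1) distribution — a deliberately heavy-tailed
reference that keeps the profile graded.  Local minima of the approximate
FDR whose raw FDR clears the threshold are the boundaries.

Hierarchical TADs: level-0 intervals tile the region between consecutive
boundaries; boundaries are then removed one at a time in increasing order
of their Cauchy statistic, and each removal adds the merged interval
between the removed boundary's surviving neighbors at a level one higher
than the previous step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .axis_model import AxisWeights
from .stat_combine import bh_fdr, cauchy_combine, variance_ratio_pvalue
from .trace_io import AXES, GenomicBins
from .variance_field import VarianceField

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = [
    "bin", "p_x", "p_y", "p_z", "p", "stat", "fdr",
    "approx_p", "approx_fdr", "is_boundary",
]


@dataclass(frozen=True)
class TadConfig:
    """Tuning parameters of the boundary caller."""

    window_kb: float = 200.0        # window length on EACH side of the bin
    fdr_threshold: float = 0.1
    min_side_fraction: float = 0.5  # min available fraction of window bins per side

    def validate(self, resolution: int) -> None:
        if self.window_kb * 1000 < 2 * resolution:
            raise ValueError("window must span at least 2 bins")


def window_bins(cfg: TadConfig, resolution: int) -> int:
    return int(round(cfg.window_kb * 1000 / resolution))


def domain_partition(
    i: int, bins: GenomicBins, cfg: TadConfig = TadConfig()
) -> tuple[np.ndarray, np.ndarray] | None:
    """Upstream/downstream window bin sets for tested bin i, or None.

    U = {i-w..i-1}, D = {i+1..i+w}, clipped to the region; the tested bin
    belongs to neither side.  Bins with less than half of a side's window
    available (region ends) are excluded and return None.
    """
    w = window_bins(cfg, bins.resolution)
    u = np.arange(max(i - w, 0), i)
    d = np.arange(i + 1, min(i + w + 1, bins.p))
    need = cfg.min_side_fraction * w
    if u.size < need or d.size < need:
        return None
    return u, d


def _side_pairs(u: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(inter_j, inter_k, intra_j, intra_k) index arrays for the window."""
    inter_j, inter_k = np.meshgrid(u, d, indexing="ij")
    uj, uk = np.triu_indices(u.size, k=1)
    dj, dk = np.triu_indices(d.size, k=1)
    intra_j = np.concatenate([u[uj], d[dj]])
    intra_k = np.concatenate([u[uk], d[dk]])
    return inter_j.ravel(), inter_k.ravel(), intra_j, intra_k


def boundary_test(
    field: VarianceField,
    weights: AxisWeights,
    i: int,
    cfg: TadConfig = TadConfig(),
    approx: bool = False,
) -> dict | None:
    """Inter- vs intra-domain variance test for one bin, all axes.

    Per axis the pooled inter-domain variance is tested against the pooled
    intra-domain variance with an upper-tail F test (a boundary inflates
    cross-boundary differences).  With ``approx`` the same ratios are
    referred to F(1, 1).  Returns a result-row dict or None if the bin is
    excluded by window availability.
    """
    part = domain_partition(i, field.bins, cfg)
    if part is None:
        return None
    inter_j, inter_k, intra_j, intra_k = _side_pairs(*part)
    row: dict = {"bin": i}
    axis_p = np.full(3, np.nan)
    approx_p = np.full(3, np.nan)
    for a in range(3):
        s2_inter, df_inter = field.pooled_variance(a, inter_j, inter_k)
        s2_intra, df_intra = field.pooled_variance(a, intra_j, intra_k)
        if df_inter >= 1 and df_intra >= 1 and np.isfinite(s2_inter) and np.isfinite(s2_intra):
            axis_p[a] = variance_ratio_pvalue(s2_inter, df_inter, s2_intra, df_intra, tail="upper")
            approx_p[a] = variance_ratio_pvalue(s2_inter, 1, s2_intra, 1, tail="upper")
        row[f"p_{AXES[a]}"] = axis_p[a]
    row["p"], row["stat"] = cauchy_combine(axis_p, weights.w, return_stat=True)
    row["approx_p"] = cauchy_combine(approx_p, weights.w)
    return row


def boundary_profile(
    field: VarianceField,
    weights: AxisWeights,
    cfg: TadConfig = TadConfig(),
) -> pd.DataFrame:
    """Test every bin; BH-adjust the exact and F(1,1)-approximate p-values.

    Returns one row per bin (excluded bins carry NaN) with columns
    ``p_x..p_z, p, stat, fdr, approx_p, approx_fdr, is_boundary``.
    """
    rows = []
    for i in range(field.p):
        row = boundary_test(field, weights, i, cfg)
        if row is None:
            row = {"bin": i, "p_x": np.nan, "p_y": np.nan, "p_z": np.nan,
                   "p": np.nan, "stat": np.nan, "approx_p": np.nan}
        rows.append(row)
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    df["approx_fdr"] = bh_fdr(df["approx_p"].to_numpy())
    df["is_boundary"] = False
    return df[["bin", "p_x", "p_y", "p_z", "p", "stat", "fdr", "approx_p", "approx_fdr", "is_boundary"]]


def _local_minima(values: np.ndarray) -> list[int]:
    """Interior local minima with plateau handling (leftmost bin wins).

    Operates on the finite entries in sequence order: a run of equal
    values is one candidate minimum at its leftmost position, and counts
    only if both flanking finite neighbors are strictly greater.
    """
    idx = np.flatnonzero(np.isfinite(values))
    v = values[idx]
    minima: list[int] = []
    m = v.size
    start = 0
    while start < m:
        end = start
        while end + 1 < m and v[end + 1] == v[start]:
            end += 1
        left_greater = start > 0 and v[start - 1] > v[start]
        right_greater = end < m - 1 and v[end + 1] > v[start]
        if left_greater and right_greater:
            minima.append(int(idx[start]))
        start = end + 1
    return minima


def call_boundaries(profile: pd.DataFrame, cfg: TadConfig = TadConfig()) -> pd.DataFrame:
    """Mark boundary bins: approx-profile local minima with raw FDR < threshold.

    Peak finding runs on the F(1,1)-approximate p-value profile.  Its BH
    adjustment (``approx_fdr``, reported for inspection) is a monotone
    step-up transform of the same values, so true minima coincide — but
    the step-up min-accumulation ties neighboring values and can flatten
    moderate profiles into plateaus, so the un-adjusted profile is the
    stable peak-finding substrate.  Final boundaries are gated on the raw
    (exact-df) FDR.
    """
    profile = profile.copy()
    vals = profile["approx_p"].to_numpy(dtype=np.float64)
    minima = _local_minima(vals)
    fdr = profile["fdr"].to_numpy()
    flags = np.zeros(len(profile), dtype=bool)
    for i in minima:
        if np.isfinite(fdr[i]) and fdr[i] < cfg.fdr_threshold:
            flags[i] = True
    profile["is_boundary"] = flags
    return profile


@dataclass(frozen=True)
class TadInterval:
    """A (possibly merged) domain: bin interval [start, end] at a hierarchy level."""

    start: int
    end: int
    level: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("interval start must precede end")


def hierarchical_tads(
    boundaries,
    stats,
    region: tuple[int, int],
) -> list[TadInterval]:
    """Assemble the hierarchical TAD list from boundaries and their statistics.

    ``boundaries`` are boundary bin indices; ``stats`` their Cauchy
    statistics (larger = more significant); ``region`` the inclusive bin
    range (start, end) of the analyzed region.  Level-0 intervals tile the
    region between consecutive boundaries; each subsequent removal of the
    least-significant remaining boundary adds the merged interval between
    its surviving neighbors with the level incremented per removal.
    """
    start, end = region
    bnds = list(map(int, boundaries))
    sig = {b: s for b, s in zip(bnds, stats)}
    bnds.sort()
    if not bnds:
        return [TadInterval(start, end, 0)]
    cuts = [start] + bnds + [end]
    intervals = [TadInterval(a, b, 0) for a, b in zip(cuts[:-1], cuts[1:]) if a < b]
    level = 0
    remaining = sorted(bnds, key=lambda b: (sig[b], b))
    active = sorted(bnds)
    for b in remaining:
        level += 1
        pos = active.index(b)
        left = active[pos - 1] if pos > 0 else start
        right = active[pos + 1] if pos + 1 < len(active) else end
        active.pop(pos)
        intervals.append(TadInterval(left, right, level))
    return intervals


def tads_to_frames(
    profile: pd.DataFrame,
    intervals: list[TadInterval],
    bins: GenomicBins,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BED-style tables: boundary records and TAD intervals with levels."""
    starts, res = bins.starts, bins.resolution
    bsel = profile[profile["is_boundary"]]
    with np.errstate(divide="ignore"):
        score = -np.log10(bsel["p"].to_numpy(dtype=np.float64))
    bound = pd.DataFrame({
        "chrom": bins.chrom,
        "start": starts[bsel["bin"].to_numpy(dtype=int)],
        "end": starts[bsel["bin"].to_numpy(dtype=int)] + res,
        "score": score,
    })
    tads = pd.DataFrame({
        "chrom": bins.chrom,
        "start": [starts[t.start] for t in intervals],
        "end": [starts[t.end] + res for t in intervals],
        "level": [t.level for t in intervals],
    })
    return bound, tads


def call_tads(
    field: VarianceField,
    weights: AxisWeights,
    cfg: TadConfig = TadConfig(),
) -> tuple[pd.DataFrame, list[TadInterval]]:
    """Full domain pipeline: profile, boundary peaks, hierarchy."""
    cfg.validate(field.bins.resolution)
    profile = call_boundaries(boundary_profile(field, weights, cfg), cfg)
    bnd = profile.loc[profile["is_boundary"], "bin"].to_numpy(dtype=int)
    stats = profile.loc[profile["is_boundary"], "stat"].to_numpy(dtype=np.float64)
    intervals = hierarchical_tads(bnd, stats, (0, field.p - 1))
    return profile, intervals
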