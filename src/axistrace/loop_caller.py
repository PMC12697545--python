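"""Chromatin loop calling from normalized per-axis variance fields.

A loop is a bin pair in significantly closer spatial proximity than its
local genomic neighborhood.  For each tested pair (j, k) the local
background is the square (Chebyshev) ring of pairs whose anchors are
displaced 25-50 Kb from (j, k).  Per axis, the pair's normalized variance
is compared against the count-weighted pooled background variance with a
lower-tail F test; per-axis p-values are combined with the weighted
aggregated Cauchy test, screened at FDR < 0.1, clustered within 50 Kb,
reduced to per-cluster summits (minimum p), and finally filtered at
p < 1e-5 with optional population-contact-frequency filters.

Results are returned as a pandas DataFrame, one row per tested pair, with
per-axis p-values, combined p, FDR and the candidate/summit/final flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .axis_model import AxisWeights
from .stat_combine import bh_fdr, cauchy_combine, variance_ratio_pvalue
from .trace_io import AXES, GenomicBins, TraceDataset
from .variance_field import MIN_FILTERED_PAIRS, VarianceField

logger = logging.getLogger(__name__)

#: minimum usable background entries; pairs below this are not tested
MIN_BACKGROUND_ENTRIES = 3
#: minimum surviving differences at the tested entry (per axis)
MIN_TESTED_COUNT = 3

RESULT_COLUMNS = [
    "j", "k", "p_x", "p_y", "p_z", "df_x", "df_y", "df_z",
    "p", "stat", "fdr", "is_candidate", "cluster_id", "is_summit",
    "contact_freq", "is_final",
]


@dataclass(frozen=True)
class LoopConfig:
    """Tuning parameters of the loop caller (genomic units in Kb)."""

    background_min_kb: float = 25.0    # inner radius of the background ring
    background_max_kb: float = 50.0    # outer radius of the background ring
    min_separation_kb: float = 100.0   # smallest tested anchor separation
    fdr_threshold: float = 0.1         # candidate screen
    cluster_radius_kb: float = 50.0    # candidate grouping distance
    summit_p_cutoff: float = 1e-5      # final summit p-value filter
    contact_cutoff_nm: float = 500.0   # 3D distance defining a contact
    cluster_freq_min: float = 1.0 / 3.0   # min contact freq, cluster summits
    singleton_freq_min: float = 1.0 / 2.0  # min contact freq, singleton summits
    apply_frequency_filter: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.background_min_kb <= self.background_max_kb):
            raise ValueError("need 0 < background_min_kb <= background_max_kb")
        for name in ("fdr_threshold", "summit_p_cutoff", "cluster_freq_min", "singleton_freq_min"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


def _ring_radii(cfg: LoopConfig, resolution: int) -> tuple[int, int]:
    """Background ring radii in bins (inclusive)."""
    rmin = int(np.ceil(cfg.background_min_kb * 1000 / resolution))
    rmax = int(np.floor(cfg.background_max_kb * 1000 / resolution))
    return max(rmin, 1), max(rmax, 1)


def background_ring(
    j: int, k: int, bins: GenomicBins, cfg: LoopConfig = LoopConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (j', k') of the local background of pair (j, k).

    The ring contains pairs whose anchor displacement from (j, k) in
    Chebyshev metric lies between the 25 Kb and 50 Kb radii, restricted to
    valid in-range pairs with j' < k', excluding (j, k) itself and any pair
    closer to the diagonal than the inner radius.
    """
    if not j < k:
        raise ValueError("need j < k")
    p = bins.p
    rmin, rmax = _ring_radii(cfg, bins.resolution)
    dj = np.arange(-rmax, rmax + 1)
    jj, kk = np.meshgrid(j + dj, k + dj, indexing="ij")
    cheb = np.maximum(np.abs(jj - j), np.abs(kk - k))
    keep = (
        (cheb >= rmin) & (cheb <= rmax)
        & (jj >= 0) & (kk < p) & (jj < kk)
        & ((kk - jj) >= rmin)
    )
    return jj[keep], kk[keep]


def _axis_pvalue(
    field: VarianceField, a: int, j: int, k: int, bj: np.ndarray, bk: np.ndarray
) -> tuple[float, float]:
    """Lower-tail F p-value of entry (j, k) against its pooled ring, one axis."""
    v = field.V[a, j, k]
    c = field.C[a, j, k]
    if not np.isfinite(v) or c < MIN_TESTED_COUNT:
        return np.nan, np.nan
    s2_b, df_b = field.pooled_variance(a, bj, bk)
    if not np.isfinite(s2_b) or df_b < 1:
        return np.nan, np.nan
    return variance_ratio_pvalue(v, c - 1, s2_b, df_b, tail="lower"), float(c - 1)


def test_pair(
    field: VarianceField,
    weights: AxisWeights,
    j: int,
    k: int,
    cfg: LoopConfig = LoopConfig(),
) -> dict:
    """Test one bin pair against its local background on all three axes.

    Returns a result-row dict (p_x/p_y/p_z, dfs, combined p and statistic).
    Pairs with fewer than 3 valid background entries on every axis, or
    fewer than 3 surviving differences on every axis, come back untested
    (NaN p).
    """
    bj, bk = background_ring(j, k, field.bins, cfg)
    row: dict = {"j": j, "k": k}
    axis_p = np.full(3, np.nan)
    for a in range(3):
        if bj.size >= MIN_BACKGROUND_ENTRIES and \
                field.n_valid_entries(a, bj, bk) >= MIN_BACKGROUND_ENTRIES:
            p_a, df_a = _axis_pvalue(field, a, j, k, bj, bk)
        else:
            p_a, df_a = np.nan, np.nan
        axis_p[a] = p_a
        row[f"p_{AXES[a]}"] = p_a
        row[f"df_{AXES[a]}"] = df_a
    row["p"], row["stat"] = cauchy_combine(axis_p, weights.w, return_stat=True)
    return row


def call_candidates(
    field: VarianceField,
    weights: AxisWeights,
    cfg: LoopConfig = LoopConfig(),
) -> pd.DataFrame:
    """Test all eligible pairs and flag FDR < threshold candidates."""
    p = field.p
    res = field.bins.resolution
    min_sep = int(np.ceil(cfg.min_separation_kb * 1000 / res))
    rows = []
    for j in range(p):
        for k in range(j + min_sep, p):
            rows.append(test_pair(field, weights, j, k, cfg))
    if not rows:
        logger.warning("no testable bin pairs at min separation %s Kb", cfg.min_separation_kb)
        return pd.DataFrame(columns=RESULT_COLUMNS)
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    df["is_candidate"] = df["fdr"] < cfg.fdr_threshold
    df["cluster_id"] = -1
    df["is_summit"] = False
    df["contact_freq"] = np.nan
    df["is_final"] = False
    if not df["p"].notna().any():
        logger.warning("no pair could be tested (all NaN p-values)")
    return df


def cluster_summits(calls: pd.DataFrame, bins: GenomicBins, cfg: LoopConfig = LoopConfig()) -> pd.DataFrame:
    """Group candidates within the cluster radius; mark per-cluster summits.

    Candidates are nodes of a graph with edges between pairs whose anchor
    displacement (Chebyshev, genomic units) is at most the cluster radius;
    connected components are clusters and the minimum-p member of each
    (ties broken lexicographically on (j, k)) is the summit.
    """
    calls = calls.copy()
    cand = calls.index[calls["is_candidate"].fillna(False)].to_numpy()
    if cand.size == 0:
        return calls
    r = int(np.floor(cfg.cluster_radius_kb * 1000 / bins.resolution))
    jj = calls.loc[cand, "j"].to_numpy()
    kk = calls.loc[cand, "k"].to_numpy()
    m = cand.size
    parent = np.arange(m)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u in range(m):
        cheb = np.maximum(np.abs(jj - jj[u]), np.abs(kk - kk[u]))
        for v in np.flatnonzero((cheb <= r) & (np.arange(m) > u)):
            ru, rv = find(u), find(int(v))
            if ru != rv:
                parent[rv] = ru
    roots = np.array([find(u) for u in range(m)])
    _, cluster_ids = np.unique(roots, return_inverse=True)
    calls.loc[cand, "cluster_id"] = cluster_ids
    for cid in np.unique(cluster_ids):
        members = cand[cluster_ids == cid]
        sub = calls.loc[members, ["p", "j", "k"]].sort_values(
            ["p", "j", "k"], kind="stable"
        )
        calls.loc[sub.index[0], "is_summit"] = True
    return calls


def contact_frequency(ds: TraceDataset, j: int, k: int, cutoff_nm: float) -> float:
    """Fraction of co-observing traces with 3D distance(j, k) below cutoff."""
    both = ds.observed[:, j] & ds.observed[:, k]
    if not both.any():
        return float("nan")
    d = np.linalg.norm(ds.coords[both, j, :] - ds.coords[both, k, :], axis=1)
    return float(np.mean(d < cutoff_nm))


def finalize_loops(
    calls: pd.DataFrame, ds: TraceDataset, cfg: LoopConfig = LoopConfig()
) -> pd.DataFrame:
    """Apply the final summit p-value and contact-frequency filters."""
    calls = calls.copy()
    summits = calls.index[calls["is_summit"]]
    cluster_sizes = calls[calls["cluster_id"] >= 0].groupby("cluster_id").size()
    for idx in summits:
        row = calls.loc[idx]
        freq = contact_frequency(ds, int(row["j"]), int(row["k"]), cfg.contact_cutoff_nm)
        calls.loc[idx, "contact_freq"] = freq
        keep = row["p"] < cfg.summit_p_cutoff
        if keep and cfg.apply_frequency_filter:
            singleton = cluster_sizes.get(row["cluster_id"], 1) == 1
            cutoff = cfg.singleton_freq_min if singleton else cfg.cluster_freq_min
            keep = np.isfinite(freq) and freq >= cutoff
        calls.loc[idx, "is_final"] = bool(keep)
    return calls


def call_loops(
    ds: TraceDataset,
    field: VarianceField,
    weights: AxisWeights,
    cfg: LoopConfig = LoopConfig(),
) -> pd.DataFrame:
    """Full loop-calling pipeline: test, screen, cluster, finalize."""
    calls = call_candidates(field, weights, cfg)
    if calls.empty:
        return calls
    calls = cluster_summits(calls, field.bins, cfg)
    return finalize_loops(calls, ds, cfg)


def loops_to_bedpe(calls: pd.DataFrame, bins: GenomicBins, final_only: bool = True) -> pd.DataFrame:
    """Format loop calls as a BEDPE table (0-based half-open anchors)."""
    sel = calls[calls["is_final"]] if final_only else calls[calls["is_summit"]]
    starts, res = bins.starts, bins.resolution
    j = sel["j"].to_numpy(dtype=int)
    k = sel["k"].to_numpy(dtype=int)
    out = pd.DataFrame({
        "chrom1": bins.chrom, "start1": starts[j], "end1": starts[j] + res,
        "chrom2": bins.chrom, "start2": starts[k], "end2": starts[k] + res,
    })
    for col in ("p_x", "p_y", "p_z", "p", "fdr", "cluster_id", "is_summit", "contact_freq"):
        out[col] = sel[col].to_numpy()
    return out
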