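"""Genomic interval utilities: TSS counting, peak enrichment, loop consensus.

These back the compartment A/B labeling (TSS density), the boundary
validation statistics (log2 peak enrichment), and the construction of a
working loop truth from multiple reference loop lists.  All coordinates
are 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .trace_io import GenomicBins

logger = logging.getLogger(__name__)

BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


def read_tss_bed(path, chrom: str | None = None) -> pd.DataFrame:
    """Read a TSS BED file into a (chrom, position, strand) table.

    The TSS of a BED record is its start (the 5' end of the feature on the
    + strand is assumed pre-resolved by the annotation producer).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame({
        "chrom": df[0].astype(str),
        "position": df[1].astype(np.int64),
        "strand": df[5].astype(str) if df.shape[1] > 5 else ".",
    })
    if chrom is not None:
        out = out[out["chrom"] == chrom].reset_index(drop=True)
    if (out["position"] < 0).any():
        raise ValueError("negative TSS positions")
    return out


def read_tss_gtf(path, chrom: str | None = None, features=("transcript", "gene")) -> pd.DataFrame:
    """Extract TSS positions from a GTF: start for + strand, end-1 for -.

    GTF is 1-based closed; positions are converted to 0-based.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attr"],
    )
    df = df[df["feature"].isin(features)]
    pos = np.where(df["strand"] == "-", df["end"].to_numpy() - 1, df["start"].to_numpy() - 1)
    out = pd.DataFrame({
        "chrom": df["chrom"].astype(str).to_numpy(),
        "position": pos.astype(np.int64),
        "strand": df["strand"].to_numpy(),
    })
    if chrom is not None:
        out = out[out["chrom"] == chrom].reset_index(drop=True)
    return out


def count_tss(bins: GenomicBins, tss) -> np.ndarray:
    """Number of TSS positions falling in each bin (start <= pos < end).

    ``tss`` is either a (chrom, position, ...) table or a bare position
    array (assumed on the bins' chromosome).
    """
    if isinstance(tss, pd.DataFrame):
        chroms = tss["chrom"].unique()
        if len(chroms) and not set(chroms) <= {bins.chrom}:
            raise ValueError(
                f"TSS table on {sorted(set(chroms))}, bins on {bins.chrom}; filter first"
            )
        positions = tss["position"].to_numpy(dtype=np.int64)
    else:
        positions = np.asarray(tss, dtype=np.int64)
    counts = np.zeros(bins.p, dtype=np.int64)
    if positions.size == 0:
        return counts
    idx = np.searchsorted(bins.starts, positions, side="right") - 1
    ok = (idx >= 0) & (positions < bins.starts[np.clip(idx, 0, bins.p - 1)] + bins.resolution)
    np.add.at(counts, idx[ok], 1)
    return counts


def log2_enrichment(selected: np.ndarray, overlap: np.ndarray) -> float:
    """log2 fold change of peak overlap in a bin subset vs all bins.

    ``selected`` is a boolean mask (e.g. boundary bins), ``overlap`` a
    boolean per-bin peak-overlap indicator.  Returns log2(p1 / p) with
    p1 the overlap proportion among selected bins and p the overall
    proportion; -inf (with a warning) when no selected bin overlaps.
    """
    selected = np.asarray(selected, dtype=bool)
    overlap = np.asarray(overlap, dtype=bool)
    if selected.shape != overlap.shape:
        raise ValueError("selected and overlap masks must align")
    if not selected.any():
        raise ValueError("empty bin selection")
    p_all = overlap.mean()
    if p_all == 0:
        raise ValueError("no bin overlaps a peak; enrichment undefined")
    p1 = overlap[selected].mean()
    if p1 == 0:
        warnings.warn("no selected bin overlaps a peak; returning -inf", stacklevel=2)
        return float("-inf")
    return float(np.log2(p1 / p_all))


def _overlapping_bins(bins: GenomicBins, start: int, end: int) -> np.ndarray:
    """Indices of bins intersecting [start, end) (half-open)."""
    lo = np.searchsorted(bins.starts + bins.resolution, start, side="right")
    hi = np.searchsorted(bins.starts, end, side="left")
    return np.arange(lo, hi)


def reference_consensus(
    loop_lists: list[pd.DataFrame],
    bins: GenomicBins,
    min_support: int = 2,
) -> pd.DataFrame:
    """Bin pairs supported by at least ``min_support`` reference loop lists.

    Each BEDPE record marks every bin pair whose bins intersect its two
    anchors; within one list a pair is counted at most once (duplicated
    records do not add support).  Returns a (j, k, support) table with
    j < k, sorted.
    """
    if not loop_lists:
        raise ValueError("need at least one reference loop list")
    support: dict[tuple[int, int], int] = {}
    for table in loop_lists:
        seen: set[tuple[int, int]] = set()
        sub = table[(table["chrom1"] == bins.chrom) & (table["chrom2"] == bins.chrom)]
        for rec in sub.itertuples(index=False):
            b1 = _overlapping_bins(bins, int(rec.start1), int(rec.end1))
            b2 = _overlapping_bins(bins, int(rec.start2), int(rec.end2))
            for j in b1:
                for k in b2:
                    if j == k:
                        continue
                    seen.add((int(min(j, k)), int(max(j, k))))
        for pair in seen:
            support[pair] = support.get(pair, 0) + 1
    rows = [(j, k, s) for (j, k), s in support.items() if s >= min_support]
    rows.sort()
    return pd.DataFrame(rows, columns=["j", "k", "support"])


def read_bedpe(path) -> pd.DataFrame:
    """Read a BEDPE loop list (first six columns; extra columns kept)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns=dict(enumerate(BEDPE_COLUMNS)))
    df["chrom1"] = df["chrom1"].astype(str)
    df["chrom2"] = df["chrom2"].astype(str)
    return df


def match_pairs_with_shift(
    called: pd.DataFrame,
    reference: pd.DataFrame,
    shift_bins: int = 1,
) -> np.ndarray:
    """Which called (j, k) pairs match a reference pair within a bin shift.

    A call matches if both anchors are within ``shift_bins`` of a
    reference pair's anchors (the benchmarking convention of allowing one
    bin of slack).  Returns a boolean array over ``called`` rows.
    """
    ref = reference[["j", "k"]].to_numpy(dtype=int)
    out = np.zeros(len(called), dtype=bool)
    if ref.size == 0:
        return out
    cj = called["j"].to_numpy(dtype=int)
    ck = called["k"].to_numpy(dtype=int)
    for i in range(len(called)):
        dj = np.abs(ref[:, 0] - cj[i])
        dk = np.abs(ref[:, 1] - ck[i])
        out[i] = bool(np.any((dj <= shift_bins) & (dk <= shift_bins)))
    return out
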