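"""Reading, validation and preprocessing of chromatin tracing tables.

Chromatin tracing experiments (multiplexed DNA FISH, seqFISH+, ORCA, ...)
report one 3D coordinate per imaged genomic segment per chromosome copy.
The community exchange format is the 4DN FISH Omics Format for Chromatin
Tracing (FOF-CT) "core" table: a CSV with ``##``-prefixed header lines
followed by a column header and one row per localized spot.

This module parses such tables into a dense trace tensor
(``n`` traces x ``p`` bins x 3 axes, nm units, NaN = missing spot) with a
genomic bin table, and provides the two standard preprocessing steps:
duplicate-spot removal (keep first record) and per-trace centering.

Genomic coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns that must be present (case-insensitive match) in a FOF-CT core table
MANDATORY_COLUMNS = ("Trace_ID", "X", "Y", "Z", "Chrom", "Chrom_Start", "Chrom_End")

#: axis order used everywhere in the package
AXES = ("x", "y", "z")

NM_PER_UM = 1000.0


class FofctFormatError(ValueError):
    """Raised when a tracing table violates the expected format."""


class EmptyInputError(ValueError):
    """Raised when a tracing table contains no usable spot records."""


@dataclass(frozen=True)
class GenomicBins:
    """Ordered, uniform-width, non-overlapping bins on one chromosome."""

    chrom: str
    starts: np.ndarray  # bp, 0-based, sorted ascending
    resolution: int     # bp per bin

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        object.__setattr__(self, "starts", starts)
        if starts.size < 3:
            raise FofctFormatError(
                f"need at least 3 bins, got {starts.size} on {self.chrom}"
            )
        if np.any(np.diff(starts) <= 0):
            raise FofctFormatError("bin starts must be strictly increasing")
        if self.resolution <= 0:
            raise FofctFormatError("bin resolution must be positive")
        if np.any(np.diff(starts) < self.resolution):
            raise FofctFormatError("bins overlap: start spacing below resolution")

    @property
    def p(self) -> int:
        return int(self.starts.size)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.resolution

    def index_of(self, start: np.ndarray) -> np.ndarray:
        """Map bin start coordinates to bin indices (error on unknown starts)."""
        idx = np.searchsorted(self.starts, start)
        idx = np.clip(idx, 0, self.p - 1)
        if np.any(self.starts[idx] != start):
            bad = np.asarray(start)[self.starts[idx] != np.asarray(start)]
            raise FofctFormatError(f"coordinates do not match any bin start: {bad[:5]}")
        return idx

    def genomic_distance(self, j, k) -> np.ndarray:
        """1D genomic separation in bp between bins j and k (index distance)."""
        return np.abs(np.asarray(j) - np.asarray(k)) * self.resolution


@dataclass
class TraceDataset:
    """n traces x p bins x 3 axes of nm coordinates with a missing-spot mask.

    ``coords`` holds NaN where a spot was not observed; a spot is missing in
    all three axes or in none.  ``centered`` records whether per-trace
    per-axis mean subtraction has been applied.
    """

    coords: np.ndarray          # (n, p, 3) float64, nm
    trace_ids: np.ndarray       # (n,) str
    bins: GenomicBins
    centered: bool = False
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.trace_ids = np.asarray(self.trace_ids)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n, p, 3)")
        if self.coords.shape[0] != self.trace_ids.size:
            raise ValueError("trace_ids length must match coords first axis")
        if self.coords.shape[1] != self.bins.p:
            raise ValueError("coords second axis must match number of bins")
        if self.n < 1:
            raise EmptyInputError("dataset contains no traces")
        nan = np.isnan(self.coords)
        partial = nan.any(axis=2) & ~nan.all(axis=2)
        if partial.any():
            raise ValueError("a spot must be missing in all 3 axes or none")

    @property
    def n(self) -> int:
        return int(self.coords.shape[0])

    @property
    def p(self) -> int:
        return int(self.coords.shape[1])

    @property
    def missing(self) -> np.ndarray:
        """(n, p) boolean mask, True where the spot was not observed."""
        return np.isnan(self.coords[:, :, 0])

    @property
    def observed(self) -> np.ndarray:
        return ~self.missing

    def axis_index(self, axis: str | int) -> int:
        if isinstance(axis, str):
            try:
                return AXES.index(axis.lower())
            except ValueError:
                raise ValueError(f"axis must be one of {AXES}, got {axis!r}") from None
        if axis not in (0, 1, 2):
            raise ValueError("axis index must be 0, 1 or 2")
        return int(axis)


# ---------------------------------------------------------------------------
# FOF-CT parsing
# ---------------------------------------------------------------------------

def _split_header(text: str) -> tuple[list[str], str]:
    """Separate ``##`` header lines from the tabular body."""
    header: list[str] = []
    lines = text.splitlines()
    i = 0
    for i, line in enumerate(lines):
        if line.startswith("##"):
            header.append(line)
        elif line.strip() == "":
            continue
        else:
            break
    else:
        i += 1
    return header, "\n".join(lines[i:])


def _detect_unit(header_lines: list[str], default: str) -> str:
    """Infer the coordinate unit declared in the FOF-CT header."""
    joined = " ".join(header_lines).lower()
    if re.search(r"(xyz|coordinate)[ _]?unit[^a-z]*(micron|micrometer|um|µm)", joined):
        return "um"
    if re.search(r"(xyz|coordinate)[ _]?unit[^a-z]*nm", joined):
        return "nm"
    return default


def _extract_columns(header_lines: list[str], body: str) -> tuple[list[str], str]:
    """Find the column names, either from ``##columns=(...)`` or the body."""
    for line in header_lines:
        m = re.search(r"columns\s*=\s*\(([^)]*)\)", line, flags=re.IGNORECASE)
        if m:
            cols = [c.strip() for c in m.group(1).split(",") if c.strip()]
            return cols, body
    body_lines = body.splitlines()
    if not body_lines:
        raise EmptyInputError("no column header found in tracing table")
    first = body_lines[0].lstrip("#").strip()
    cols = [c.strip() for c in first.split(",")]
    return cols, "\n".join(body_lines[1:])


def _canonical(name: str) -> str:
    return name.strip().lower().replace(" ", "_")


def read_spot_table(path) -> tuple[pd.DataFrame, str]:
    """Parse a FOF-CT core (or plain CSV) file into a long spot table.

    Returns the table with canonical columns
    (trace_id, x, y, z, chrom, chrom_start, chrom_end) plus any extras,
    and the declared coordinate unit ("nm" or "um").
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise EmptyInputError(f"{path}: file is empty")
    header_lines, body = _split_header(text)
    unit = _detect_unit(header_lines, default="nm")
    columns, data_text = _extract_columns(header_lines, body)
    canon = {_canonical(c): i for i, c in enumerate(columns)}
    for col in MANDATORY_COLUMNS:
        if _canonical(col) not in canon:
            raise FofctFormatError(f"missing mandatory column: {col}")
    if not data_text.strip():
        raise EmptyInputError(f"{path}: no spot records")
    df = pd.read_csv(
        io.StringIO(data_text),
        header=None,
        names=[_canonical(c) for c in columns],
        float_precision="round_trip",
    )
    df = df.rename(columns={"x": "x", "y": "y", "z": "z"})
    df["trace_id"] = df["trace_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    return df, unit


def deduplicate_spots(spots: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop repeated (trace, bin) records, keeping the first in file order.

    Allele misalignment can record several 3D coordinates for the same
    imaged segment on the same trace; only the first is kept.
    Returns the deduplicated table and the number of removed records.
    """
    before = len(spots)
    out = spots.drop_duplicates(subset=["trace_id", "chrom", "chrom_start"], keep="first")
    removed = before - len(out)
    if removed:
        logger.info("removed %d duplicate spot record(s)", removed)
    return out, removed


def dataset_from_spots(
    spots: pd.DataFrame,
    chrom: str,
    unit: str = "nm",
    resolution: int | None = None,
) -> TraceDataset:
    """Assemble a TraceDataset for one chromosome from a long spot table."""
    sub = spots[spots["chrom"] == chrom]
    if sub.empty:
        raise EmptyInputError(f"no spots on chromosome {chrom!r}")
    sub, n_dup = deduplicate_spots(sub)

    pairs = sub[["chrom_start", "chrom_end"]].drop_duplicates().sort_values("chrom_start")
    widths = (pairs["chrom_end"] - pairs["chrom_start"]).to_numpy()
    if resolution is None:
        uniq = np.unique(widths)
        if uniq.size != 1:
            raise FofctFormatError(
                f"inconsistent bin widths on {chrom}: {uniq[:5].tolist()}"
            )
        resolution = int(uniq[0])
    elif np.any(widths != resolution):
        raise FofctFormatError("bin widths disagree with the requested resolution")
    bins = GenomicBins(chrom=chrom, starts=pairs["chrom_start"].to_numpy(), resolution=resolution)

    trace_ids = sub["trace_id"].drop_duplicates().to_numpy()
    tpos = {t: i for i, t in enumerate(trace_ids)}
    n, p = trace_ids.size, bins.p
    coords = np.full((n, p, 3), np.nan)
    rows = sub["trace_id"].map(tpos).to_numpy()
    cols = bins.index_of(sub["chrom_start"].to_numpy())
    xyz = sub[["x", "y", "z"]].to_numpy(dtype=np.float64)
    if unit == "um":
        xyz = xyz * NM_PER_UM
    elif unit != "nm":
        raise ValueError(f"unsupported coordinate unit {unit!r}")
    coords[rows, cols, :] = xyz
    ds = TraceDataset(coords=coords, trace_ids=trace_ids, bins=bins)
    ds.log["duplicates_removed"] = n_dup
    ds.log["unit"] = unit
    return ds


def read_fofct(
    path,
    chrom: str | None = None,
    unit: str | None = None,
    resolution: int | None = None,
) -> TraceDataset | dict[str, TraceDataset]:
    """Read a FOF-CT core CSV into TraceDataset(s).

    Parameters
    ----------
    path
        FOF-CT core table (``##`` header lines tolerated) or a plain CSV
        with the same columns.
    chrom
        Restrict to one chromosome and return a single TraceDataset.
        When omitted, a dict keyed by chromosome name is returned.
    unit
        Override the coordinate unit ("nm"/"um"); default is the unit
        declared in the header, else nm.
    """
    spots, file_unit = read_spot_table(path)
    use_unit = unit or file_unit
    if chrom is not None:
        return dataset_from_spots(spots, chrom, unit=use_unit, resolution=resolution)
    return {
        c: dataset_from_spots(spots, c, unit=use_unit, resolution=resolution)
        for c in spots["chrom"].unique()
    }


def write_fofct(ds: TraceDataset, path) -> None:
    """Write a TraceDataset as a FOF-CT core CSV (nm coordinates)."""
    with open(path, "w") as fh:
        fh.write("##FOF-CT_version=v0.1\n")
        fh.write("##XYZ_unit=nm\n")
        fh.write("##columns=(Trace_ID,X,Y,Z,Chrom,Chrom_Start,Chrom_End)\n")
        starts, res = ds.bins.starts, ds.bins.resolution
        obs = ds.observed
        for i, tid in enumerate(ds.trace_ids):
            for j in np.flatnonzero(obs[i]):
                x, y, z = (repr(float(v)) for v in ds.coords[i, j])
                fh.write(
                    f"{tid},{x},{y},{z},{ds.bins.chrom},{starts[j]},{starts[j] + res}\n"
                )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def deduplicate_dataset(ds: TraceDataset) -> TraceDataset:
    """TraceDataset-level deduplication hook.

    The dense tensor admits a single coordinate per (trace, bin), so a
    parsed dataset is already duplicate-free; duplicates are resolved
    keep-first at parse time (see :func:`deduplicate_spots`).
    """
    return ds


def center_traces(ds: TraceDataset) -> TraceDataset:
    """Subtract each trace's per-axis mean over observed spots.

    Traces without any observed spot are dropped with a warning.  Missing
    entries stay missing.  Idempotent.
    """
    keep = ds.observed.any(axis=1)
    if not keep.all():
        logger.warning("dropping %d trace(s) with zero observed spots", int((~keep).sum()))
    coords = ds.coords[keep]
    if coords.shape[0] == 0:
        raise EmptyInputError("no traces with observed spots remain")
    means = np.nanmean(coords, axis=1, keepdims=True)  # (n, 1, 3)
    centered = coords - means
    out = TraceDataset(
        coords=centered,
        trace_ids=ds.trace_ids[keep],
        bins=ds.bins,
        centered=True,
        log=dict(ds.log),
    )
    out.log["traces_dropped_empty"] = int((~keep).sum())
    return out


def filter_missingness(ds: TraceDataset, max_missing_frac: float = 1.0) -> TraceDataset:
    """Drop traces whose missing-spot fraction exceeds ``max_missing_frac``.

    Off by default (1.0 keeps everything): population-level feature calling
    tolerates missing spots through per-entry complete-pair counting.
    """
    frac = ds.missing.mean(axis=1)
    keep = frac <= max_missing_frac
    if keep.all():
        return ds
    if not keep.any():
        raise EmptyInputError("missingness filter removed every trace")
    out = replace(ds, coords=ds.coords[keep], trace_ids=ds.trace_ids[keep], log=dict(ds.log))
    out.log["traces_dropped_missingness"] = int((~keep).sum())
    return out
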