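"""Per-axis pairwise-difference variance fields.

For each axis a and bin pair (j, k), the differences x_ij - x_ik across
traces i carry the spatial-proximity signal: their variance is the axis
component of the squared 3D distance between bins j and k.  This module
condenses the n x p x p difference tensor into per-axis p x p sufficient
statistics through four steps:

1. robust raw variance per entry (median-based, Gaussian-consistent);
2. a lowess curve of variance against 1D genomic distance, giving the
   expected variance at each separation (polymer distance decay);
3. outlier filtering: differences farther than four expected standard
   deviations from zero are discarded as mismeasurements;
4. the filtered per-entry sample variance, re-fit with a second lowess
   curve and divided by it, removing the genomic-distance bias.

The result is a :class:`VarianceField`: normalized variance matrices V_a
(unit scale, entries ~1 under no structure), surviving-count matrices C_a,
and the distance curves.  All downstream tests consume only (V_a, C_a):
count-weighted pooling of normalized variances equals pooling the raw
filtered differences, so the n x p x p tensor never needs to be kept.
The per-pair streaming below holds O(p^2) per axis plus one n x p buffer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .trace_io import AXES, GenomicBins, TraceDataset

logger = logging.getLogger(__name__)

#: Gaussian consistency constant for median-of-squared-deviations-from-median,
#: 1 / Phi^-1(0.75)^2, putting the robust variance on the ordinary-variance scale
GAUSSIAN_CONSISTENCY = float(1.0 / norm.ppf(0.75) ** 2)  # ~2.1981

#: lowess smoothing fraction and robustifying iterations for both fits
LOWESS_FRAC = 0.3
LOWESS_IT = 3

#: floor for the expected-variance curve (nm^2); keeps SDs and ratios defined
VARIANCE_FLOOR = 1.0

#: differences beyond this many expected SDs from 0 are treated as outliers
Z_CUTOFF = 4.0

#: minimum complete pairs for a raw robust variance entry
MIN_RAW_PAIRS = 3
#: minimum surviving differences for a filtered variance entry
MIN_FILTERED_PAIRS = 2


class CurveEstimationError(ValueError):
    """Raised when no expected-variance curve can be fitted."""


@dataclass(frozen=True)
class VarianceCurve:
    """Expected variance as a function of 1D genomic distance (bp).

    Piecewise-linear through the lowess fit at the observed distances,
    linearly extrapolated beyond the ends, floored at a small positive
    value so square roots and ratios stay defined.
    """

    s: np.ndarray   # unique sorted genomic distances (bp)
    v: np.ndarray   # fitted expected variances (nm^2)
    floor: float = VARIANCE_FLOOR

    def __call__(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=np.float64)
        if self.s.size == 1:
            out = np.full(s.shape, self.v[0])
        else:
            out = np.interp(s, self.s, self.v)
            lo = s < self.s[0]
            if np.any(lo):
                slope = (self.v[1] - self.v[0]) / (self.s[1] - self.s[0])
                out = np.where(lo, self.v[0] + slope * (s - self.s[0]), out)
            hi = s > self.s[-1]
            if np.any(hi):
                slope = (self.v[-1] - self.v[-2]) / (self.s[-1] - self.s[-2])
                out = np.where(hi, self.v[-1] + slope * (s - self.s[-1]), out)
        return np.maximum(out, self.floor)


def fit_variance_curve(
    values: np.ndarray,
    distances: np.ndarray,
    frac: float = LOWESS_FRAC,
    it: int = LOWESS_IT,
) -> VarianceCurve:
    """Lowess fit of variance entries against 1D genomic distance.

    Each finite matrix entry contributes one point (no stratum averaging).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    distances = np.asarray(distances, dtype=np.float64).ravel()
    ok = np.isfinite(values) & np.isfinite(distances)
    if not ok.any():
        raise CurveEstimationError("no finite variance entries to fit")
    values, distances = values[ok], distances[ok]
    uniq = np.unique(distances)
    if uniq.size == 1:
        return VarianceCurve(s=uniq, v=np.array([values.mean()]))
    # with very few points widen the local window so each fit is determined
    frac_eff = min(1.0, max(frac, 5.0 / values.size))
    fitted = sm_lowess(values, distances, frac=frac_eff, it=it, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    s_u, inverse = np.unique(xs, return_inverse=True)
    v_u = np.bincount(inverse, weights=ys) / np.bincount(inverse)
    return VarianceCurve(s=s_u, v=v_u)


# ---------------------------------------------------------------------------
# raw robust variance
# ---------------------------------------------------------------------------

def robust_variance_matrix(ds: TraceDataset, axis: str | int) -> np.ndarray:
    """Raw p x p variance matrix of pairwise differences, median-based.

    Entry (j, k) is c * median_i[(d_i - median_i d_i)^2] with
    d_i = x_ij - x_ik over traces observing both spots and c the Gaussian
    consistency constant (~2.1981), so the robust value estimates the
    ordinary variance under Gaussian differences.  NaN on the diagonal and
    wherever fewer than 3 complete pairs exist.
    """
    if not ds.centered:
        raise ValueError("dataset must be centered")
    a = ds.axis_index(axis)
    X = ds.coords[:, :, a]
    p = ds.p
    out = np.full((p, p), np.nan)
    with np.errstate(invalid="ignore"):
        for j in range(p):
            D = X[:, j][:, None] - X  # (n, p)
            cnt = np.sum(~np.isnan(D), axis=0)
            med = np.nanmedian(D, axis=0)
            rv = GAUSSIAN_CONSISTENCY * np.nanmedian((D - med) ** 2, axis=0)
            rv[cnt < MIN_RAW_PAIRS] = np.nan
            out[j, :] = rv
    np.fill_diagonal(out, np.nan)
    return out


def expected_variance_curve(raw: np.ndarray, bins: GenomicBins) -> VarianceCurve:
    """Fit the expected-variance-vs-distance curve from a raw matrix."""
    p = raw.shape[0]
    ju, ku = np.triu_indices(p, k=1)
    return fit_variance_curve(raw[ju, ku], bins.genomic_distance(ju, ku))


def outlier_mask(ds: TraceDataset, axis: str | int, curve: VarianceCurve) -> np.ndarray:
    """Boolean n x p x p mask of retained pairwise differences.

    A difference d = x_ij - x_ik survives iff |d| <= 4 * sqrt(E(s_jk)): the
    Z-score is taken about 0 because pairwise differences are symmetric
    about 0 under random chromosome orientation.  Intended for inspection
    and small inputs; :func:`build_field` streams the same rule per pair.
    """
    a = ds.axis_index(axis)
    X = ds.coords[:, :, a]
    n, p = X.shape
    jj, kk = np.meshgrid(np.arange(p), np.arange(p), indexing="ij")
    thresh = Z_CUTOFF * np.sqrt(curve(ds.bins.genomic_distance(jj, kk)))
    D = X[:, :, None] - X[:, None, :]
    with np.errstate(invalid="ignore"):
        return np.abs(D) <= thresh[None, :, :]


# ---------------------------------------------------------------------------
# the assembled field
# ---------------------------------------------------------------------------

@dataclass
class VarianceField:
    """Per-axis normalized variance matrices and their sufficient statistics.

    Attributes
    ----------
    V : (3, p, p) float
        Normalized variance matrices (filtered variance / expected variance);
        symmetric, NaN on the diagonal and where untestable.
    C : (3, p, p) int
        Counts of surviving pairwise differences per entry.
    raw, filtered : (3, p, p) float
        Diagnostic intermediates: robust raw variance and filtered
        (mean-based) variance, nm^2.
    E_raw, E_filt : per-axis :class:`VarianceCurve`
        Distance curves from the first (robust) and second (filtered) fits.
    """

    V: np.ndarray
    C: np.ndarray
    raw: np.ndarray
    filtered: np.ndarray
    E_raw: list
    E_filt: list
    bins: GenomicBins

    @property
    def p(self) -> int:
        return self.bins.p

    def pooled_variance(self, axis: str | int, j_idx, k_idx) -> tuple[float, float]:
        """Count-weighted pooled normalized variance over a set of entries.

        Returns (pooled variance, degrees of freedom) with each entry
        contributing C-1 df:  s2 = sum (C-1) V / sum (C-1),  df = sum (C-1).
        Entries with C < 2 or non-finite V are skipped.  Equals the pooled
        sample variance of the underlying filtered differences (each entry
        normalized by its expected variance) about their entry means.
        """
        a = axis if isinstance(axis, int) else AXES.index(axis)
        v = self.V[a, j_idx, k_idx]
        c = self.C[a, j_idx, k_idx]
        ok = np.isfinite(v) & (c >= MIN_FILTERED_PAIRS)
        if not np.any(ok):
            return np.nan, 0.0
        wdf = (c[ok] - 1).astype(np.float64)
        return float(np.sum(wdf * v[ok]) / wdf.sum()), float(wdf.sum())

    def n_valid_entries(self, axis: str | int, j_idx, k_idx) -> int:
        a = axis if isinstance(axis, int) else AXES.index(axis)
        v = self.V[a, j_idx, k_idx]
        c = self.C[a, j_idx, k_idx]
        return int(np.sum(np.isfinite(v) & (c >= MIN_FILTERED_PAIRS)))


def _filtered_variance(
    X: np.ndarray, bins: GenomicBins, curve: VarianceCurve
) -> tuple[np.ndarray, np.ndarray]:
    """Filtered (mean-based) variance and surviving counts, streamed per bin."""
    n, p = X.shape
    filt = np.full((p, p), np.nan)
    counts = np.zeros((p, p), dtype=np.int64)
    with np.errstate(invalid="ignore"):
        for j in range(p):
            D = X[:, j][:, None] - X  # (n, p)
            s = bins.genomic_distance(j, np.arange(p))
            thresh = Z_CUTOFF * np.sqrt(curve(s))
            mask = np.abs(D) <= thresh  # NaN compares False
            c = mask.sum(axis=0)
            s1 = np.where(mask, D, 0.0).sum(axis=0)
            s2 = np.where(mask, D * D, 0.0).sum(axis=0)
            mean = np.divide(s1, c, out=np.zeros(p), where=c > 0)
            var = np.divide(
                s2 - c * mean**2,
                np.maximum(c - 1, 1),
                out=np.full(p, np.nan),
                where=c >= MIN_FILTERED_PAIRS,
            )
            filt[j, :] = var
            counts[j, :] = c
    np.fill_diagonal(filt, np.nan)
    np.fill_diagonal(counts, 0)
    return filt, counts


def build_field(ds: TraceDataset) -> VarianceField:
    """Run the full filtering/normalization pipeline on all three axes."""
    if not ds.centered:
        raise ValueError("dataset must be centered")
    p = ds.p
    V = np.full((3, p, p), np.nan)
    C = np.zeros((3, p, p), dtype=np.int64)
    raw_all = np.full((3, p, p), np.nan)
    filt_all = np.full((3, p, p), np.nan)
    curves_raw, curves_filt = [], []
    jj, kk = np.meshgrid(np.arange(p), np.arange(p), indexing="ij")
    s_mat = ds.bins.genomic_distance(jj, kk).astype(np.float64)
    ju, ku = np.triu_indices(p, k=1)
    for a, axis in enumerate(AXES):
        raw = robust_variance_matrix(ds, axis)
        e_raw = fit_variance_curve(raw[ju, ku], s_mat[ju, ku])
        filt, counts = _filtered_variance(ds.coords[:, :, a], ds.bins, e_raw)
        e_filt = fit_variance_curve(filt[ju, ku], s_mat[ju, ku])
        with np.errstate(invalid="ignore"):
            V[a] = filt / e_filt(s_mat)
        raw_all[a], filt_all[a], C[a] = raw, filt, counts
        curves_raw.append(e_raw)
        curves_filt.append(e_filt)
    return VarianceField(
        V=V, C=C, raw=raw_all, filtered=filt_all,
        E_raw=curves_raw, E_filt=curves_filt, bins=ds.bins,
    )
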