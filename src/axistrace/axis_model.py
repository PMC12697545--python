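"""Per-axis measurement-noise estimation and inverse-variance axis weights.

Model: an observed centered trace decomposes as signal plus axis-specific
noise, x = x_true + eps_x with x_true ~ N_p(0, K) shared across axes and
eps_a ~ N_p(0, sigma2_a I).  Imaging pipelines localize spots with different
precision along the optical axes, so sigma2_x, sigma2_y, sigma2_z differ.

Under a spiked-covariance view — the signal covariance K is low rank, so
most diagonal entries of the per-axis sample covariance are noise-dominated
— the noise variance of an axis is estimated by the median of the diagonal
of that axis's sample covariance matrix (the median over bins of the
per-bin variance across traces).  Weights are normalized inverse variances,
the classic inverse-variance weighting of meta-analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .trace_io import AXES, TraceDataset

logger = logging.getLogger(__name__)

#: minimum number of bins with a computable variance for a valid estimate
MIN_VALID_BINS = 3

#: below this many bins the low-rank identifiability assumption is dubious
SMALL_P_WARNING = 10


class NoiseEstimationError(ValueError):
    """Raised when per-axis noise variance cannot be estimated."""


@dataclass(frozen=True)
class AxisWeights:
    """Estimated per-axis noise variances (nm^2) and normalized weights.

    ``sigma2`` and ``w`` are length-3 arrays in (x, y, z) order with
    w proportional to 1/sigma2 and sum(w) == 1.
    """

    sigma2: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        sigma2 = np.asarray(self.sigma2, dtype=np.float64)
        w = np.asarray(self.w, dtype=np.float64)
        object.__setattr__(self, "sigma2", sigma2)
        object.__setattr__(self, "w", w)
        if sigma2.shape != (3,) or w.shape != (3,):
            raise ValueError("sigma2 and w must be length-3 (x, y, z)")
        if np.any(sigma2 <= 0) or np.any(w <= 0):
            raise ValueError("noise variances and weights must be positive")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    @classmethod
    def equal(cls) -> "AxisWeights":
        """Uniform weights (the unweighted-baseline comparator)."""
        return cls(sigma2=np.ones(3), w=np.full(3, 1.0 / 3.0))

    @classmethod
    def from_sigma2(cls, sigma2) -> "AxisWeights":
        sigma2 = np.asarray(sigma2, dtype=np.float64)
        if np.any(sigma2 <= 0):
            raise NoiseEstimationError("degenerate data: zero noise variance")
        inv = 1.0 / sigma2
        return cls(sigma2=sigma2, w=inv / inv.sum())

    def to_dict(self) -> dict[str, float]:
        d = {f"sigma2_{a}": float(s) for a, s in zip(AXES, self.sigma2)}
        d.update({f"w_{a}": float(v) for a, v in zip(AXES, self.w)})
        return d


def per_bin_variance(ds: TraceDataset, axis: str | int) -> np.ndarray:
    """Sample variance of one axis's coordinate across traces, per bin.

    Pairwise-complete: each bin uses its observed traces, denominator m-1.
    Bins with fewer than 2 observations are NaN.
    """
    a = ds.axis_index(axis)
    vals = ds.coords[:, :, a]  # (n, p)
    m = np.sum(~np.isnan(vals), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # df<=0 slices -> NaN
        var = np.nanvar(vals, axis=0, ddof=1)
    var[m < 2] = np.nan
    return var


def estimate_noise_variance(ds: TraceDataset, axis: str | int) -> float:
    """Median over bins of the per-bin variance of one axis (nm^2).

    This is the median of the diagonal of the axis's sample covariance
    matrix; under the low-rank signal assumption the majority of diagonal
    entries are noise-dominated, so the median tracks the noise variance.
    """
    if not ds.centered:
        raise ValueError("dataset must be centered before noise estimation")
    if ds.p < SMALL_P_WARNING:
        logger.warning(
            "only %d bins: the low-rank assumption behind the median-diagonal "
            "noise estimator may not hold", ds.p,
        )
    var = per_bin_variance(ds, axis)
    valid = np.isfinite(var)
    if valid.sum() < MIN_VALID_BINS:
        raise NoiseEstimationError(
            f"axis {axis}: only {int(valid.sum())} bin(s) with a computable variance"
        )
    return float(np.median(var[valid]))


def compute_axis_weights(ds: TraceDataset) -> AxisWeights:
    """Estimate noise variances on all three axes and normalize to weights.

    w_a = (1/sigma2_a) / sum_b (1/sigma2_b).
    """
    sigma2 = np.array([estimate_noise_variance(ds, a) for a in AXES])
    if np.any(sigma2 == 0):
        raise NoiseEstimationError("degenerate data: an axis has zero variance")
    return AxisWeights.from_sigma2(sigma2)
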