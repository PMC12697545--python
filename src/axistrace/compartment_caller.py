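"""A/B compartment assignment by weighted per-axis spectral clustering.

Compartments are modeled as a two-block structure: same-compartment bins
interact more, so their pairwise-difference variances are relatively
smaller.  Per axis, the normalized variance matrix is eigendecomposed and
the eigenvector of the second-largest |eigenvalue| is kept (the leading
one tracks residual distance decay); the three eigenvectors form a p x 3
embedding.  Rows are scaled by the axis weights — stretching the accurate
axes — and 2-means clustering in the weighted space yields the partition.
The cluster overlapping more transcription start sites is labeled A; with
no TSS annotation, the cluster with lower within-group variance is B
(condensed heterochromatin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .axis_model import AxisWeights
from .trace_io import GenomicBins
from .variance_field import VarianceField

logger = logging.getLogger(__name__)

#: refuse eigendecomposition when more than this fraction of entries is NaN
MAX_NAN_FRACTION = 0.2

KMEANS_RESTARTS = 10


class DegenerateEmbeddingError(ValueError):
    """Raised when the embedding carries no usable structure."""


@dataclass
class CompartmentCall:
    """Per-bin A/B labels plus the spectral embedding used for clustering."""

    labels: np.ndarray              # (p,) array of "A"/"B"
    embedding: np.ndarray           # (p, 3) per-axis second eigenvectors
    weighted_embedding: np.ndarray  # embedding * diag(w)
    assignment_basis: str           # "tss" or "variance"


def _impute_by_distance_stratum(V: np.ndarray) -> np.ndarray:
    """Replace NaNs by the mean of their |j-k| distance stratum.

    The diagonal (no data by construction) is set to 0, which only shifts
    the spectrum by a multiple of the identity and leaves eigenvectors
    unchanged.
    """
    p = V.shape[0]
    out = V.copy()
    idx = np.arange(p)
    offsets = np.abs(idx[:, None] - idx[None, :])
    global_mean = np.nanmean(V[offsets > 0]) if np.isfinite(V[offsets > 0]).any() else 0.0
    for d in range(1, p):
        sel = offsets == d
        vals = V[sel]
        miss = ~np.isfinite(vals)
        if miss.any():
            fill = np.nanmean(vals) if np.isfinite(vals).any() else global_mean
            vals[miss] = fill
            out[sel] = vals
    np.fill_diagonal(out, 0.0)
    return out


def axis_embedding(field: VarianceField) -> np.ndarray:
    """p x 3 matrix of per-axis second eigenvectors of the normalized field.

    Eigenpairs are ordered by decreasing |eigenvalue| (the normalized
    matrices are not positive semidefinite) and each kept eigenvector is
    sign-fixed so its first non-negligible component is positive.
    """
    p = field.p
    if p < 4:
        raise DegenerateEmbeddingError("need at least 4 bins for a spectral embedding")
    emb = np.empty((p, 3))
    off = ~np.eye(p, dtype=bool)
    for a in range(3):
        V = field.V[a]
        nan_frac = float(np.mean(~np.isfinite(V[off])))
        if nan_frac > MAX_NAN_FRACTION:
            raise DegenerateEmbeddingError(
                f"axis {a}: {nan_frac:.0%} of variance entries missing"
            )
        M = _impute_by_distance_stratum(V)
        M = 0.5 * (M + M.T)  # guard symmetry against imputation asymmetries
        evals, evecs = np.linalg.eigh(M)
        order = np.argsort(np.abs(evals))[::-1]
        vec = evecs[:, order[1]]
        if abs(evals[order[1]]) < 1e-12 * max(abs(evals[order[0]]), 1.0):
            logger.warning("axis %d: second eigenvalue ~0, embedding degenerate", a)
        nz = np.flatnonzero(np.abs(vec) > 1e-12)
        if nz.size and vec[nz[0]] < 0:
            vec = -vec
        emb[:, a] = vec
    return emb


def cluster_ab(
    embedding: np.ndarray,
    weights: AxisWeights,
    seed: int = 0,
) -> np.ndarray:
    """2-means partition of bins in the weight-scaled embedding space."""
    X = embedding * weights.w[None, :]
    if not np.isfinite(X).all():
        raise ValueError("embedding must be finite (impute before clustering)")
    if np.allclose(X, X[0], atol=1e-12):
        raise DegenerateEmbeddingError("all embedding rows identical; no partition exists")
    km = KMeans(n_clusters=2, n_init=KMEANS_RESTARTS, random_state=seed)
    return km.fit_predict(X)


def _within_group_variance(field: VarianceField, weights: AxisWeights, members: np.ndarray) -> float:
    """Axis-weight-averaged mean normalized variance over within-group pairs."""
    if members.size < 2:
        return np.inf
    ju, ku = np.triu_indices(members.size, k=1)
    j_idx, k_idx = members[ju], members[ku]
    total = 0.0
    for a in range(3):
        vals = field.V[a, j_idx, k_idx]
        vals = vals[np.isfinite(vals)]
        total += weights.w[a] * (float(np.mean(vals)) if vals.size else np.inf)
    return total


def assign_ab(
    partition: np.ndarray,
    bins: GenomicBins,
    tss_positions: np.ndarray | None,
    field: VarianceField,
    weights: AxisWeights | None = None,
    embedding: np.ndarray | None = None,
) -> CompartmentCall:
    """Label the 2-means partition as A/B compartments.

    With TSS positions, the group overlapping more TSSs is A (ties fall
    back to the variance rule).  Without, the group with lower within-group
    weighted variance is B.
    """
    from .genomic_annotation import count_tss  # local import to avoid a cycle

    weights = weights or AxisWeights.equal()
    groups = [np.flatnonzero(partition == g) for g in (0, 1)]
    basis = "variance"
    a_group: int | None = None
    if tss_positions is not None:
        counts = count_tss(bins, np.asarray(tss_positions))
        totals = [int(counts[g].sum()) for g in groups]
        if totals[0] != totals[1]:
            a_group = int(np.argmax(totals))
            basis = "tss"
    if a_group is None:
        wvar = [_within_group_variance(field, weights, g) for g in groups]
        a_group = int(np.argmax(wvar))  # lower variance group is B
    labels = np.where(partition == a_group, "A", "B")
    emb = embedding if embedding is not None else np.zeros((bins.p, 3))
    return CompartmentCall(
        labels=labels,
        embedding=emb,
        weighted_embedding=emb * weights.w[None, :],
        assignment_basis=basis,
    )


def call_compartments(
    field: VarianceField,
    weights: AxisWeights,
    tss_positions: np.ndarray | None = None,
    seed: int = 0,
    centromere: int | None = None,
) -> CompartmentCall:
    """Full compartment pipeline, optionally split at a centromere (bp).

    With ``centromere`` the embedding/clustering runs separately on the
    p and q arms (bins before/after the coordinate) and the per-arm labels
    are concatenated.
    """
    if centromere is not None:
        left = np.flatnonzero(field.bins.ends <= centromere)
        right = np.flatnonzero(field.bins.starts >= centromere)
        if left.size < 4 or right.size < 4:
            raise ValueError("each arm needs at least 4 bins")
        calls = [
            _call_on_subset(field, weights, sel, tss_positions, seed)
            for sel in (left, right)
        ]
        labels = np.full(field.p, "B", dtype=object)
        emb = np.zeros((field.p, 3))
        for sel, call in zip((left, right), calls):
            labels[sel] = call.labels
            emb[sel] = call.embedding
        return CompartmentCall(
            labels=labels.astype(str),
            embedding=emb,
            weighted_embedding=emb * weights.w[None, :],
            assignment_basis=calls[0].assignment_basis,
        )
    emb = axis_embedding(field)
    part = cluster_ab(emb, weights, seed=seed)
    return assign_ab(part, field.bins, tss_positions, field, weights, embedding=emb)


def _call_on_subset(
    field: VarianceField,
    weights: AxisWeights,
    sel: np.ndarray,
    tss_positions: np.ndarray | None,
    seed: int,
) -> CompartmentCall:
    sub_bins = GenomicBins(
        chrom=field.bins.chrom, starts=field.bins.starts[sel], resolution=field.bins.resolution
    )
    sub = VarianceField(
        V=field.V[:, sel[:, None], sel[None, :]],
        C=field.C[:, sel[:, None], sel[None, :]],
        raw=field.raw[:, sel[:, None], sel[None, :]],
        filtered=field.filtered[:, sel[:, None], sel[None, :]],
        E_raw=field.E_raw, E_filt=field.E_filt, bins=sub_bins,
    )
    emb = axis_embedding(sub)
    part = cluster_ab(emb, weights, seed=seed)
    return assign_ab(part, sub_bins, tss_positions, sub, weights, embedding=emb)
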