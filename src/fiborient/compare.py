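"""Collagen–elastic angular agreement and principal-axis similarity.

Two comparisons: (i) at each collagen bundle peak, the axial angular
difference between the collagen orientation and the elastic-fiber
orientation at the same depth, binned at 15° over [0°, 90°]; (ii) the
absolute cosine similarity between the first principal component axes of
a fiber network's coordinates before and after extension, which measures
whether the network merely dilates (similarity 1) or reorganizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .angles import angular_difference
from .orientation import OrientationProfile
from .peaks import PeakSet, classify_layer

__all__ = [
    "AgreementHistogram",
    "AxisVector",
    "angular_difference",
    "collagen_elastic_agreement",
    "principal_axis",
    "cosine_similarity",
]

AGREEMENT_BIN_DEG = 15.0


@dataclass
class AgreementHistogram:
    """Histogram of collagen–elastic axial differences, 15° bins on [0°, 90°]."""

    counts: np.ndarray  # 6 bins
    layer: str | None = None
    n_excluded_isotropic: int = 0
    bin_edges: np.ndarray = field(default_factory=lambda: np.arange(0.0, 90.1, AGREEMENT_BIN_DEG))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        t = self.total
        return self.counts / t if t else np.zeros_like(self.counts, dtype=float)

    @property
    def fraction_leq_15(self) -> float:
        """Share of peaks whose collagen–elastic difference is ≤ 15°."""
        return float(self.fractions[0]) if self.total else float("nan")


@dataclass
class AxisVector:
    """Unit axis (undirected: v and −v are the same axis), 2D or 3D."""

    vector: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if not self.degenerate and abs(np.linalg.norm(self.vector) - 1.0) > 1e-9:
            raise ValueError("axis vector must have unit norm")


def collagen_elastic_agreement(
    collagen_peaks: PeakSet,
    elastic_profile: OrientationProfile,
    layer: str | None = None,
) -> AgreementHistogram:
    """Bin collagen–elastic angular differences at collagen bundle depths.

    For each collagen peak (optionally restricted to one layer), the
    elastic orientation at the same z-index is paired with the peak's
    collagen orientation. Peaks whose elastic slice is isotropic are
    excluded from the histogram and counted in ``n_excluded_isotropic``.
    """
    z_to_row = {int(z): i for i, z in enumerate(elastic_profile.z_index)}
    counts = np.zeros(6, dtype=int)
    excluded = 0
    for i in range(len(collagen_peaks)):
        d = collagen_peaks.depth_um[i]
        if layer is not None and classify_layer(d) != layer:
            continue
        z = int(collagen_peaks.z_index[i])
        if z not in z_to_row:
            raise ValueError(f"elastic profile does not cover peak z-index {z}")
        row = z_to_row[z]
        if elastic_profile.isotropic[row]:
            excluded += 1
            continue
        diff = angular_difference(collagen_peaks.theta_deg[i], elastic_profile.theta_deg[row])
        b = min(int(diff // AGREEMENT_BIN_DEG), 5)
        counts[b] += 1
    return AgreementHistogram(counts=counts, layer=layer, n_excluded_isotropic=excluded)


def principal_axis(coords: np.ndarray, degenerate_rtol: float = 1e-9) -> AxisVector:
    """First principal component axis of a 2D/3D point cloud.

    The unit eigenvector of the coordinate covariance with the largest
    eigenvalue, sign-canonicalized so the first nonzero component is
    positive. A cloud whose top two eigenvalues coincide (within relative
    tolerance) has no preferred axis and is flagged degenerate.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] not in (2, 3):
        raise ValueError("coords must be (n, 2) or (n, 3)")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / (pts.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0:
        return AxisVector(vector=np.full(pts.shape[1], np.nan), degenerate=True)
    if (evals[-1] - evals[-2]) <= degenerate_rtol * evals[-1]:
        return AxisVector(vector=np.full(pts.shape[1], np.nan), degenerate=True)
    v = evecs[:, -1]
    for comp in v:
        if abs(comp) > 1e-12:
            if comp < 0:
                v = -v
            break
    return AxisVector(vector=v / np.linalg.norm(v))


def cosine_similarity(a: AxisVector, b: AxisVector) -> float:
    """|a·b| between two axes, in [0, 1]; NaN if either is degenerate."""
    if a.degenerate or b.degenerate:
        return float("nan")
    if a.vector.shape != b.vector.shape:
        raise ValueError("axes must share dimensionality")
    return float(np.clip(abs(np.dot(a.vector, b.vector)), 0.0, 1.0))
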