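"""Gaussian mode analysis of pooled bundle-orientation histograms.

Bundle orientations pooled over the 3×3 tiles of a 633 µm region are
binned on the axial domain [0°, 180°) and decomposed into 1–3 wrapped
Gaussian modes by nonlinear least squares. Model order K is the smallest
value whose Pearson chi-square goodness of fit is not rejected; modes are
numbered by descending peak height (Mode 1 = dominant direction). Derived
statistics: peak frequency (fitted height as % of total count), the
intermodal angle between Modes 1 and 2 (lattice-like organization when
two comparable modes ~60–90° apart exist), and the Mode-1 shift between
the superficial and deep reticular layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .angles import angular_difference, fold180
from .peaks import PeakSet, classify_layer

__all__ = [
    "AngularHistogram",
    "GaussianMode",
    "ModeFit",
    "pooled_orientation_histogram",
    "fit_gaussian_modes",
    "intermodal_angle",
    "layer_mode_shift",
]

_SIGMA_BOUNDS = (2.0, 45.0)  # degrees; wrapped evaluation valid for σ < 45°


@dataclass
class AngularHistogram:
    """Counts of axial orientations on [0°, 180°)."""

    bin_edges: np.ndarray  # len nbins+1, covering [0, 180]
    counts: np.ndarray
    layer: str | None = None
    empty: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have len(counts)+1 entries")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.empty = self.total == 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_angles(cls, angles_deg, bin_width: float = 10.0, layer: str | None = None):
        edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
        counts, _ = np.histogram(fold180(np.asarray(angles_deg, dtype=float)), bins=edges)
        return cls(bin_edges=edges, counts=counts, layer=layer)


@dataclass
class GaussianMode:
    center_deg: float  # [0, 180)
    height: float  # counts at the center
    sigma_deg: float
    peak_frequency: float  # height as % of total count N


@dataclass
class ModeFit:
    """Wrapped-Gaussian decomposition of an angular histogram."""

    modes: list[GaussianMode]  # sorted by descending height
    chi2: float
    dof: int
    p_value: float
    n_total: int
    fit_failed: bool = False
    under_determined: bool = False
    message: str = ""
    bin_width: float = 10.0

    @property
    def K(self) -> int:
        return len(self.modes)


def pooled_orientation_histogram(
    peaksets: Sequence[PeakSet],
    layer: str | None = None,
    bin_width: float = 10.0,
) -> AngularHistogram:
    """Pool bundle-peak orientations across tiles into one axial histogram.

    Peaks are filtered by reticular layer (via the 200 µm depth split)
    when ``layer`` is given; NaN orientations (isotropic peaks) are
    skipped. Zero surviving peaks yield a valid, flagged empty histogram.
    """
    thetas: list[float] = []
    for ps in peaksets:
        for i in range(len(ps)):
            if layer is not None and classify_layer(ps.depth_um[i]) != layer:
                continue
            t = ps.theta_deg[i]
            if np.isfinite(t):
                thetas.append(float(t))
    return AngularHistogram.from_angles(thetas, bin_width=bin_width, layer=layer)


def _wrapped_gaussian_sum(x: np.ndarray, *params: float) -> np.ndarray:
    """Sum of K wrapped Gaussians; each evaluated over its ±180° images."""
    out = np.zeros_like(x, dtype=float)
    for k in range(len(params) // 3):
        h, c, s = params[3 * k : 3 * k + 3]
        for m in (-1, 0, 1):
            out += h * np.exp(-((x - c + 180.0 * m) ** 2) / (2.0 * s**2))
    return out


def _initial_guesses(hist: AngularHistogram, K: int) -> list[float]:
    """Init from the K tallest circularly separated histogram maxima."""
    counts = hist.counts.astype(float)
    nb = len(counts)
    order = np.argsort(counts)[::-1]
    chosen: list[int] = []
    for i in order:
        if counts[i] <= 0:
            break
        sep = all(min((i - j) % nb, (j - i) % nb) >= 2 for j in chosen)
        if sep:
            chosen.append(int(i))
        if len(chosen) == K:
            break
    while len(chosen) < K:  # pad with spread-out positions
        chosen.append(int((chosen[-1] + nb // (K + 1)) % nb) if chosen else 0)
    params: list[float] = []
    for i in chosen:
        params += [max(counts[i], 1.0), float(hist.centers[i]), 1.5 * hist.bin_width]
    return params


def _axial_weighted_mean(centers: np.ndarray, weights: np.ndarray) -> float:
    doubled = np.deg2rad(2.0 * centers)
    m = np.arctan2(
        np.average(np.sin(doubled), weights=weights),
        np.average(np.cos(doubled), weights=weights),
    )
    return float(fold180(np.rad2deg(m) / 2.0))


def _merge_close_modes(modes: list[GaussianMode], min_sep: float) -> list[GaussianMode]:
    merged = list(modes)
    changed = True
    while changed and len(merged) > 1:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                if angular_difference(merged[i].center_deg, merged[j].center_deg) < min_sep:
                    a, b = merged[i], merged[j]
                    w = np.array([a.height, b.height])
                    c = _axial_weighted_mean(np.array([a.center_deg, b.center_deg]), w)
                    s = float(np.average([a.sigma_deg, b.sigma_deg], weights=w))
                    new = GaussianMode(center_deg=c, height=a.height + b.height, sigma_deg=s,
                                       peak_frequency=0.0)
                    merged = [m for k, m in enumerate(merged) if k not in (i, j)] + [new]
                    changed = True
                    break
            if changed:
                break
    return merged


def _chi2_of(hist: AngularHistogram, modes: list[GaussianMode], k_fitted: int):
    params: list[float] = []
    for m in modes:
        params += [m.height, m.center_deg, m.sigma_deg]
    expected = _wrapped_gaussian_sum(hist.centers, *params)
    # denominator floored so near-empty tail bins cannot dominate; the
    # numerator keeps the true expectation
    chi2 = float(np.sum((hist.counts - expected) ** 2 / np.maximum(expected, 0.5)))
    dof = max(1, len(hist.counts) - 3 * k_fitted - 1)
    return chi2, dof, float(stats.chi2.sf(chi2, dof))


def fit_gaussian_modes(
    hist: AngularHistogram,
    max_K: int = 3,
    alpha: float = 0.05,
) -> ModeFit:
    """Fit 1–``max_K`` wrapped Gaussian modes to an axial histogram.

    The histogram is first tested against the uniform (isotropic) model;
    if uniformity is not rejected at ``alpha`` there are no modes to
    report and the fit is flagged failed. Otherwise, for increasing K, a
    sum of K wrapped Gaussians is fit by Poisson-weighted nonlinear least
    squares (initialized at the K tallest separated histogram maxima); the
    smallest K whose Pearson chi-square (dof = bins − 3K − 1) gives
    p ≥ alpha is selected. Fitted centers closer than one bin are merged
    before ordering. If no K passes, the best-p fit is returned with
    ``fit_failed`` set. Mode order is descending height; peak frequency
    is the fitted height as a percentage of the total count.
    """
    N = hist.total
    if hist.empty:
        return ModeFit(modes=[], chi2=np.nan, dof=0, p_value=np.nan, n_total=0,
                       fit_failed=True, message="empty histogram", bin_width=hist.bin_width)
    under = N < 30
    nb = len(hist.counts)
    # isotropy pre-test: a distribution indistinguishable from uniform has no modes
    expected_u = np.full(nb, N / nb)
    chi2_u = float(np.sum((hist.counts - expected_u) ** 2 / expected_u))
    p_u = float(stats.chi2.sf(chi2_u, nb - 1))
    if p_u >= alpha:
        return ModeFit(modes=[], chi2=chi2_u, dof=nb - 1, p_value=p_u, n_total=N,
                       fit_failed=True, under_determined=under,
                       message="isotropic: uniformity not rejected", bin_width=hist.bin_width)

    best: ModeFit | None = None
    for K in range(1, max_K + 1):
        p0 = _initial_guesses(hist, K)
        lower = [0.0, -90.0, _SIGMA_BOUNDS[0]] * K
        upper = [10.0 * max(N, 1), 270.0, _SIGMA_BOUNDS[1]] * K
        try:
            popt, _ = curve_fit(
                _wrapped_gaussian_sum, hist.centers, hist.counts.astype(float),
                p0=p0, bounds=(lower, upper), maxfev=20000,
                sigma=np.sqrt(np.maximum(hist.counts, 1.0)), absolute_sigma=True,
            )
        except (RuntimeError, ValueError):
            continue
        modes = [
            GaussianMode(
                height=float(popt[3 * k]),
                center_deg=float(fold180(popt[3 * k + 1])),
                sigma_deg=float(popt[3 * k + 2]),
                peak_frequency=0.0,
            )
            for k in range(K)
            if popt[3 * k] > 1e-6
        ]
        modes = _merge_close_modes(modes, min_sep=hist.bin_width)
        if not modes:
            continue
        chi2, dof, p = _chi2_of(hist, modes, k_fitted=len(modes))
        modes.sort(key=lambda m: m.height, reverse=True)
        for m in modes:
            m.peak_frequency = 100.0 * m.height / N
        fit = ModeFit(modes=modes, chi2=chi2, dof=dof, p_value=p, n_total=N,
                      under_determined=under, bin_width=hist.bin_width)
        if p >= alpha:
            return fit
        if best is None or p > best.p_value:
            best = fit
    if best is None:
        return ModeFit(modes=[], chi2=np.nan, dof=0, p_value=np.nan, n_total=N,
                       fit_failed=True, under_determined=under,
                       message="optimizer failed for all K", bin_width=hist.bin_width)
    best.fit_failed = True
    best.message = f"no K <= {max_K} passed chi-square at alpha={alpha}"
    return best


def intermodal_angle(fit: ModeFit) -> float:
    """Axial angle between Modes 1 and 2 (degrees, (0, 90]); NaN if K < 2."""
    if fit.K < 2:
        return float("nan")
    return angular_difference(fit.modes[0].center_deg, fit.modes[1].center_deg)


def layer_mode_shift(fit_superficial: ModeFit, fit_deep: ModeFit) -> float:
    """Axial angle between the Mode-1 centers of two layers; NaN on failure."""
    if fit_superficial.fit_failed or fit_deep.fit_failed:
        return float("nan")
    if fit_superficial.K < 1 or fit_deep.K < 1:
        return float("nan")
    return angular_difference(
        fit_superficial.modes[0].center_deg, fit_deep.modes[0].center_deg
    )
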