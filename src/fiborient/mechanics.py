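"""Stress–strain analysis of soft-tissue uniaxial extension tests.

Dermis loaded in tension shows a compliant *toe* region, where wavy
(crimped) collagen fibers progressively straighten, followed by a stiff
linear region once fibers are load-bearing. Extrapolating the high-stress
linear segment back to zero stress gives the strain ε* at which the fiber
network is effectively straight; the corresponding stretch ratio
λ* = 1 + ε* is the *straightening stretch ratio* used to choose a
non-damaging degree of biaxial extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StressStrainCurve",
    "LinearFitResult",
    "compute_stress_strain",
    "linear_region_intercept",
]


@dataclass
class StressStrainCurve:
    """Engineering stress–strain samples from a uniaxial extension test."""

    strain: np.ndarray  # dimensionless engineering strain, strictly increasing
    stress: np.ndarray  # MPa, >= 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be 1D arrays of equal length")
        if self.strain.size >= 2 and not np.all(np.diff(self.strain) > 0):
            raise ValueError("strain must be strictly increasing")
        if np.any(self.stress < 0):
            raise ValueError("stress must be non-negative")

    def __len__(self) -> int:
        return self.strain.size


@dataclass
class LinearFitResult:
    """OLS fit of the high-stress linear region and its x-intercept."""

    slope: float  # MPa per unit strain
    intercept: float  # MPa
    r_squared: float
    x_intercept_strain: float  # ε*, dimensionless
    lambda_star: float  # 1 + ε*, stretch ratio at full straightening
    window: tuple[int, int]  # [start, stop) sample indices of the fitted window


def compute_stress_strain(
    force_n,
    displacement_mm,
    strip_width_mm: float,
    strip_thickness_mm: float,
    gauge_length_mm: float,
    meta: dict | None = None,
) -> StressStrainCurve:
    """Convert force–displacement samples to engineering stress–strain.

    Stress is force divided by the *initial* cross-section
    (width × thickness, giving MPa for N and mm); strain is displacement
    over the initial gauge length.
    """
    area = strip_width_mm * strip_thickness_mm
    if area <= 0 or gauge_length_mm <= 0:
        raise ValueError("strip geometry and gauge length must be positive")
    force = np.asarray(force_n, dtype=float)
    disp = np.asarray(displacement_mm, dtype=float)
    if force.shape != disp.shape:
        raise ValueError("force and displacement must have equal length")
    meta = dict(meta or {})
    meta.update(
        strip_width_mm=strip_width_mm,
        strip_thickness_mm=strip_thickness_mm,
        gauge_length_mm=gauge_length_mm,
    )
    return StressStrainCurve(strain=disp / gauge_length_mm, stress=force / area, meta=meta)


def linear_region_intercept(
    curve: StressStrainCurve, min_window_frac: float = 0.3
) -> LinearFitResult:
    """Fit the high-stress linear region and return its x-intercept strain.

    Among all sliding windows of length at least ``min_window_frac × n``
    whose stresses all lie in the upper half of the observed stress range,
    the window maximizing the R² of an ordinary least-squares line is
    selected (ties go to the longest window). The fitted line's
    x-intercept ε* = −intercept/slope estimates the straightening strain.

    Raises
    ------
    ValueError
        For fewer than 10 samples, a curve whose maximum stress is not
        reached near the end (non-monotone loading), or a non-positive
        best-fit slope (non-physical).
    """
    n = len(curve)
    if n < 10:
        raise ValueError("need at least 10 samples")
    stress, strain = curve.stress, curve.strain
    tail = max(1, n // 20)
    if int(np.argmax(stress)) < n - tail:
        raise ValueError("stress must reach its maximum at (or near) the last sample")

    half = 0.5 * (stress.min() + stress.max())
    eligible = stress >= half
    w_min = max(3, int(np.ceil(min_window_frac * n)))

    best: tuple[float, int, float, float, tuple[int, int]] | None = None
    for start in range(0, n - w_min + 1):
        if not eligible[start]:
            continue
        for stop in range(start + w_min, n + 1):
            if not eligible[stop - 1]:
                break
            x = strain[start:stop]
            y = stress[start:stop]
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            ss_tot = np.sum((y - y.mean()) ** 2)
            if ss_tot <= 0:
                continue
            r2 = 1.0 - float(np.sum(resid**2)) / float(ss_tot)
            length = stop - start
            key = (round(r2, 12), length)
            if best is None or key > (round(best[0], 12), best[1]):
                best = (r2, length, slope, intercept, (start, stop))
    if best is None:
        raise ValueError("no eligible high-stress window found")
    r2, _, slope, intercept, window = best
    if slope <= 0:
        raise ValueError("non-physical (non-positive) slope in the linear region")
    eps_star = -intercept / slope
    return LinearFitResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        x_intercept_strain=float(eps_star),
        lambda_star=float(1.0 + eps_star),
        window=window,
    )
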