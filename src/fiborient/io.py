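"""Reading and writing the pipeline's file formats.

Multi-page grayscale TIFF for z-stacks (ImageJ-style metadata carrying
µm/px and z-interval), CSV for orientation profiles / peaks / truth
tables / agreement histograms, JSON for mode fits and run manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .modes import ModeFit
from .orientation import OrientationProfile
from .peaks import PeakSet
from .stack import ImageStack

__all__ = [
    "write_stack_tiff",
    "read_stack_tiff",
    "write_profile_csv",
    "read_profile_csv",
    "write_peaks_csv",
    "read_peaks_csv",
    "mode_fit_to_dict",
    "write_json",
]


def write_stack_tiff(stack: ImageStack, path) -> None:
    """Write a stack as multi-page TIFF with µm calibration tags."""
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.data,
        imagej=True,
        resolution=(1.0 / stack.pixel_pitch, 1.0 / stack.pixel_pitch),
        metadata={"spacing": stack.z_interval, "unit": "um", "channel": stack.channel},
    )


def read_stack_tiff(path, pixel_pitch: float | None = None,
                    z_interval: float | None = None, channel: str = "collagen") -> ImageStack:
    """Read a multi-page TIFF; calibration from tags unless overridden."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if pixel_pitch is None:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                if num:
                    pixel_pitch = den / num
        if z_interval is None and tf.imagej_metadata:
            z_interval = tf.imagej_metadata.get("spacing")
        if channel == "collagen" and tf.imagej_metadata and "channel" in tf.imagej_metadata:
            channel = tf.imagej_metadata["channel"]
    if pixel_pitch is None or z_interval is None:
        raise ValueError(f"{path}: missing calibration tags; pass pixel_pitch/z_interval")
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data=data, pixel_pitch=float(pixel_pitch),
                      z_interval=float(z_interval), channel=channel)


def write_profile_csv(profile: OrientationProfile, path) -> None:
    profile.to_frame().to_csv(path, index=False)


def read_profile_csv(path, channel: str = "collagen") -> OrientationProfile:
    return OrientationProfile.from_frame(pd.read_csv(path), channel=channel)


def write_peaks_csv(peaks: PeakSet, path) -> None:
    peaks.to_frame().to_csv(path, index=False)


def read_peaks_csv(path) -> PeakSet:
    df = pd.read_csv(path)
    return PeakSet(
        z_index=df["z_index"].to_numpy(dtype=int),
        depth_um=df["depth_um"].to_numpy(dtype=float),
        theta_deg=df["theta_deg"].to_numpy(dtype=float),
        degree=df["degree"].to_numpy(dtype=float),
    )


def mode_fit_to_dict(fit: ModeFit) -> dict:
    return {
        "K": fit.K,
        "modes": [
            {
                "center_deg": m.center_deg,
                "height": m.height,
                "sigma_deg": m.sigma_deg,
                "peak_frequency_pct": m.peak_frequency,
            }
            for m in fit.modes
        ],
        "chi2": _jsonable(fit.chi2),
        "dof": fit.dof,
        "p_value": _jsonable(fit.p_value),
        "n_total": fit.n_total,
        "fit_failed": fit.fit_failed,
        "under_determined": fit.under_determined,
        "message": fit.message,
        "bin_width_deg": fit.bin_width,
    }


def _jsonable(x):
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
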