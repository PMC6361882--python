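"""Profile metrics for range verification.

The measurement protocol mirrors standard prompt-gamma evaluation: a 2-D
projection of the reconstructed (or true) origin image is smoothed with a
small 2.0 mm FWHM Gaussian, a central line profile is taken along (and
perpendicular to) the beam, the profile is normalized to a maximum of 1,
the peak is the location of the first value-1 sample, and the 80% / 50%
distal falloff positions are found by linear interpolation on the far
(deeper) side of the peak.  The width at 80% is the distance between the
outermost 0.8-level crossings bracketing the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Profile1D",
    "ProfileMetrics",
    "project_2d",
    "smooth_gaussian",
    "extract_profile",
    "measure",
    "repeat_stats",
]

_FWHM_TO_SIGMA = 1.0 / 2.355


@dataclass(frozen=True)
class Profile1D:
    """Normalized 1-D profile on a uniform grid (max value = 1)."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.shape != val.shape or pos.ndim != 1:
            raise ValueError("positions and values must be matching 1-D arrays")
        d = np.diff(pos)
        if pos.size > 1 and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise ValueError("positions must be strictly increasing and uniform")
        m = val.max()
        if m <= 0:
            raise ValueError("profile must have a positive maximum")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val / m)

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass(frozen=True)
class ProfileMetrics:
    """Peak and distal-falloff observables of one profile, mm.

    ``falloff80``/``falloff50`` are NaN when the level is never crossed
    on the distal side; ``width80`` is NaN when the profile never drops
    below 0.8 on either side of the peak.
    """

    peak: float
    falloff80: float
    falloff50: float
    width80: float


def project_2d(image3d: np.ndarray, axis: int = 0) -> np.ndarray:
    """Sum a 3-D image over one axis (mass-preserving projection)."""
    image3d = np.asarray(image3d)
    if image3d.ndim != 3:
        raise ValueError("expected a 3-D image")
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    return image3d.sum(axis=axis)


def smooth_gaussian(image2d: np.ndarray, fwhm_mm: float = 2.0,
                    bin_mm: float | tuple[float, float] = 1.0) -> np.ndarray:
    """Separable Gaussian post-smoothing with reflective boundaries.

    ``fwhm_mm`` is converted to a sigma in bins per axis; mass is
    preserved by the reflective boundary.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    image2d = np.asarray(image2d, dtype=float)
    if fwhm_mm == 0:
        return image2d.copy()
    if np.isscalar(bin_mm):
        bin_mm = (float(bin_mm), float(bin_mm))
    sigma = tuple(fwhm_mm * _FWHM_TO_SIGMA / b for b in bin_mm)
    return gaussian_filter(image2d, sigma=sigma, mode="reflect")


def extract_profile(image2d: np.ndarray, axis: int, index: int,
                    positions: np.ndarray | None = None) -> Profile1D:
    """Take one line of a 2-D image along ``axis`` at row/column
    ``index`` and normalize it to max 1."""
    image2d = np.asarray(image2d, dtype=float)
    if image2d.ndim != 2:
        raise ValueError("expected a 2-D image")
    line = image2d[index, :] if axis == 1 else image2d[:, index]
    if line.max() <= 0:
        raise ValueError("all-zero profile line")
    if positions is None:
        positions = np.arange(line.size, dtype=float)
    return Profile1D(positions=np.asarray(positions, dtype=float), values=line)


def _cross_down(pos, val, i, level):
    """Linear interpolation of the downward crossing between samples i, i+1."""
    return pos[i] + (val[i] - level) / (val[i] - val[i + 1]) * (pos[i + 1] - pos[i])


def _cross_up(pos, val, i, level):
    return pos[i] + (level - val[i]) / (val[i + 1] - val[i]) * (pos[i + 1] - pos[i])


def measure(profile: Profile1D, width_level: float = 0.8) -> ProfileMetrics:
    """Peak position, 80%/50% distal falloffs and width at ``width_level``.

    The peak is the first sample attaining the (normalized) maximum; ties
    between equal-maximum samples break to the shallowest position.  The
    distal falloff at level L is the first interpolated downward L-crossing
    beyond the peak.  The width is measured between the outermost
    ``width_level`` crossings bracketing the peak (profile edges are used
    when the profile never drops below the level on a side, and the width
    is then flagged NaN only if that happens on both sides).
    """
    pos = profile.positions
    val = profile.values
    peak_idx = int(np.argmax(val >= 1.0))
    peak = float(pos[peak_idx])

    def distal(level: float) -> float:
        for i in range(peak_idx, val.size - 1):
            if val[i] >= level > val[i + 1]:
                return float(_cross_down(pos, val, i, level))
        return float("nan")

    falloff80 = distal(0.8)
    falloff50 = distal(0.5)

    # outermost crossings of width_level bracketing the peak
    left = None
    for i in range(0, peak_idx):
        if val[i] < width_level <= val[i + 1]:
            left = float(_cross_up(pos, val, i, width_level))
            break
    right = None
    for i in range(val.size - 2, peak_idx - 1, -1):
        if val[i] >= width_level > val[i + 1]:
            right = float(_cross_down(pos, val, i, width_level))
            break
    if left is None and right is None:
        width = float("nan")
    else:
        l = left if left is not None else float(pos[0])
        r = right if right is not None else float(pos[-1])
        width = r - l
    return ProfileMetrics(peak=peak, falloff80=falloff80,
                          falloff50=falloff50, width80=width)


def repeat_stats(metric_lists: dict[str, list[float]]):
    """Mean and sample SD per metric over repeated runs.

    ``metric_lists`` maps a metric name to its per-repeat values (>= 2
    repeats each).  Returns ``{name: (mean, sd)}``.
    """
    out = {}
    for name, vals in metric_lists.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            raise ValueError("need at least 2 repeats")
        out[name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out
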