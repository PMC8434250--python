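"""Preprocessing chain for FT-Raman spectra.

The chain mirrors standard practice for fluorescence-contaminated Raman
traces of biological solids: average replicates, crop to the informative
range, subtract a baseline anchored on signal-free windows, normalize to a
reference band (the C-H deformation envelope at ~1460 cm^-1), and take a
Savitzky-Golay smoothed second derivative to locate overlapped band
centers.

All intensity transforms are homogeneous of degree one in the raw
intensities up to the normalization step, which removes the overall scale;
the full chain is therefore invariant to multiplying the input by any
positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .io import Spectrum

__all__ = [
    "BaselineModel",
    "NormalizationRecord",
    "ReplicateSDWarning",
    "average_replicates",
    "crop",
    "baseline_correct",
    "normalize_to_band",
    "resample_uniform",
    "second_derivative",
]

#: relative replicate scatter above which a warning is raised (the study's
#: replicate convention is N >= 3 with SD below 5% of the signal)
SD_WARN_FRACTION = 0.05

REF_BAND_CENTER = 1460.0
REF_SEARCH_WINDOW = (1450.0, 1470.0)


class ReplicateSDWarning(UserWarning):
    """Replicate scatter exceeds the 5 percent convention somewhere."""


@dataclass
class BaselineModel:
    """Fitted background model.

    ``kind`` is ``linear`` or ``polynomial``; ``coefficients`` are in
    ascending power order (numpy.polynomial convention); ``anchor_windows``
    are the [lo, hi] cm^-1 windows whose minimum-intensity points anchored
    the least-squares fit.
    """

    kind: str
    coefficients: list[float]
    anchor_windows: list[tuple[float, float]] = field(default_factory=list)

    def __call__(self, wavenumber: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(wavenumber, float), self.coefficients)


@dataclass
class NormalizationRecord:
    """Record of reference-band normalization (divisor is the peak height)."""

    ref_center: float
    search_window: tuple[float, float]
    divisor: float


def average_replicates(
    spectra: list[Spectrum], grid_step: float | None = None
) -> tuple[Spectrum, np.ndarray]:
    """Average replicate spectra on a common grid.

    Replicates are linearly interpolated onto a uniform grid spanning the
    intersection of their axis ranges, with step ``grid_step`` (default:
    median native spacing of the first replicate).  Returns the mean
    spectrum and the pointwise sample (n-1) standard deviation profile; a
    :class:`ReplicateSDWarning` is issued where the relative SD exceeds 5%
    of the local mean.
    """
    if not spectra:
        raise ValueError("need at least one replicate")
    lo = max(s.wavenumber[0] for s in spectra)
    hi = min(s.wavenumber[-1] for s in spectra)
    if hi <= lo:
        raise ValueError("replicate axes do not overlap")
    step = grid_step if grid_step is not None else spectra[0].step
    grid = np.arange(lo, hi + 0.5 * step, step)
    stack = np.vstack([s.interp(grid) for s in spectra])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(spectra) > 1 else np.zeros_like(mean)
    scale = np.maximum(np.abs(mean), 1e-12 * max(np.abs(mean).max(), 1.0))
    if len(spectra) > 1 and np.any(sd > SD_WARN_FRACTION * scale):
        worst = float(np.max(sd / scale))
        warnings.warn(
            f"replicate SD exceeds {SD_WARN_FRACTION:.0%} of local mean "
            f"(worst {worst:.1%})",
            ReplicateSDWarning,
            stacklevel=2,
        )
    meta = dict(spectra[0].meta)
    meta["history"] = list(meta.get("history", [])) + [
        f"average_replicates(n={len(spectra)}, step={step:g})"
    ]
    return Spectrum(grid, mean, meta), sd


def crop(s: Spectrum, region: tuple[float, float]) -> Spectrum:
    """Keep points with lo <= wavenumber <= hi (closed interval)."""
    lo, hi = region
    mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
    if not mask.any():
        raise ValueError(f"crop region [{lo}, {hi}] contains no points")
    meta = dict(s.meta)
    meta["history"] = list(meta.get("history", [])) + [f"crop([{lo:g}, {hi:g}])"]
    return Spectrum(s.wavenumber[mask], s.intensity[mask], meta)


def _anchor_points(s: Spectrum, anchor_windows) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for lo, hi in anchor_windows:
        mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
        if not mask.any():
            raise ValueError(f"anchor window [{lo}, {hi}] contains no points")
        i = np.argmin(s.intensity[mask])
        xs.append(s.wavenumber[mask][i])
        ys.append(s.intensity[mask][i])
    return np.array(xs), np.array(ys)


def baseline_correct(
    s: Spectrum,
    model_kind: str = "linear",
    anchor_windows: list[tuple[float, float]] | None = None,
    degree: int = 4,
) -> tuple[Spectrum, BaselineModel]:
    """Subtract a background fitted through anchor-window minima.

    The minimum-intensity point in each anchor window is taken as a
    background sample; a line (``model_kind="linear"``) or polynomial of
    ``degree`` <= 5 (``"polynomial"``) is least-squares fitted through those
    samples and subtracted.  Anchors default to the first and last 2% of
    the axis, a plain sloping-background correction.
    """
    if model_kind not in ("linear", "polynomial"):
        raise ValueError("model_kind must be 'linear' or 'polynomial'")
    if anchor_windows is None:
        span = s.wavenumber[-1] - s.wavenumber[0]
        w = max(0.02 * span, 2.0 * s.step)
        anchor_windows = [
            (s.wavenumber[0], s.wavenumber[0] + w),
            (s.wavenumber[-1] - w, s.wavenumber[-1]),
        ]
    xs, ys = _anchor_points(s, anchor_windows)
    if np.unique(xs).size < 2:
        raise ValueError("degenerate anchors: need >= 2 distinct wavenumbers")
    deg = 1 if model_kind == "linear" else min(degree, 5, np.unique(xs).size - 1)
    coeffs = np.polynomial.polynomial.polyfit(xs, ys, deg)
    model = BaselineModel(model_kind, list(coeffs), [tuple(w) for w in anchor_windows])
    corrected = s.replace(
        s.intensity - model(s.wavenumber),
        note=f"baseline_correct({model_kind}, {len(anchor_windows)} anchors)",
    )
    return corrected, model


def normalize_to_band(
    s: Spectrum,
    ref_center: float = REF_BAND_CENTER,
    search_window: tuple[float, float] = REF_SEARCH_WINDOW,
) -> tuple[Spectrum, NormalizationRecord]:
    """Divide intensities by the reference-band peak height.

    The divisor is the maximum intensity inside ``search_window`` (default
    1450-1470 cm^-1, catching the ~1460 cm^-1 C-H deformation band).  The
    divisor must be positive — a non-positive maximum signals a missing
    reference band.
    """
    lo, hi = search_window
    mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
    if not mask.any():
        raise ValueError(f"search window [{lo}, {hi}] outside spectrum axis")
    divisor = float(s.intensity[mask].max())
    if divisor <= 0:
        raise ValueError(
            f"reference band near {ref_center:g} cm^-1 has non-positive height {divisor:g}"
        )
    record = NormalizationRecord(ref_center, (lo, hi), divisor)
    out = s.replace(s.intensity / divisor, note=f"normalize_to_band({ref_center:g})")
    return out, record


def resample_uniform(s: Spectrum, step: float | None = None) -> Spectrum:
    """Linear resampling onto a uniform grid (default step: native median)."""
    step = step if step is not None else s.step
    grid = np.arange(s.wavenumber[0], s.wavenumber[-1] + 0.5 * step, step)
    return Spectrum(grid, s.interp(grid), dict(s.meta))


def second_derivative(s: Spectrum, smooth_window: int = 11, poly_order: int = 3) -> Spectrum:
    """Savitzky-Golay smoothed second derivative on the same (uniform) axis.

    Local minima of the result are candidate band centers for seeding a
    decomposition.  The input must be on a uniform grid (use
    :func:`resample_uniform` first); ``smooth_window`` is an odd point
    count > ``poly_order`` >= 2.
    """
    if smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    if poly_order < 2 or smooth_window <= poly_order:
        raise ValueError("need smooth_window > poly_order >= 2")
    if smooth_window > len(s):
        raise ValueError("smooth_window larger than spectrum")
    steps = np.diff(s.wavenumber)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("second_derivative requires a uniform grid; resample first")
    d2 = savgol_filter(
        s.intensity, smooth_window, poly_order, deriv=2, delta=float(steps[0])
    )
    return s.replace(d2, note=f"second_derivative(w={smooth_window}, p={poly_order})")
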