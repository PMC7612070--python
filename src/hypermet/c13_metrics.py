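"""Summary metrics for dynamic hyperpolarized 13C series.

The response analysis relies on three per-ROI quantities: the time-summed
pyruvate SNR, the time-summed lactate SNR, and the lactate-to-pyruvate
ratio (LAC/PYR) of the time-summed signals.  Images are assumed to come
from sum-of-squares (SOS) multi-channel magnitude reconstruction; a
spectral path covers the fallback acquisition where only dynamic spectra
(no images) exist.

Conventions
-----------
* LAC/PYR is the ROI mean of voxelwise ratios (the ROI-mean convention of
  the per-voxel parameter maps); the ratio-of-ROI-sums alternative is
  available behind ``method="ratio_of_sums"``.
* The noise of a time-summed image is taken as ``noise_sd * sqrt(n_frames)``
  (independent frame noise).
* Voxels whose summed pyruvate falls below ``floor`` (default 5x the
  summed-image noise) are excluded from LAC/PYR and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hp_simulator import DynamicC13Series

__all__ = [
    "C13Metrics",
    "SpectralSeries",
    "sos_combine",
    "estimate_noise_sd",
    "summed_snr",
    "lac_pyr",
    "lac_pyr_from_spectra",
    "compute_c13_metrics",
]

_RAYLEIGH_MEDIAN = np.sqrt(2.0 * np.log(2.0))  # median of Rayleigh(sigma=1)


@dataclass(frozen=True)
class C13Metrics:
    """Per-ROI 13C summary metrics."""

    summed_snr_pyr: float
    summed_snr_lac: float
    lac_pyr: float
    n_voxels: int
    n_excluded: int = 0
    roi_id: str = "roi"

    def __post_init__(self) -> None:
        if self.summed_snr_pyr < 0 or self.summed_snr_lac < 0:
            raise ValueError("summed SNRs must be >= 0")
        if self.lac_pyr < 0:
            raise ValueError("lac_pyr must be >= 0")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")


@dataclass
class SpectralSeries:
    """Per-timepoint magnitude spectra on a chemical-shift axis (ppm)."""

    ppm: np.ndarray
    spectra: np.ndarray  # (n_timepoints, n_points)
    frame_interval: float

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be monotone")
        if self.spectra.shape[1] != self.ppm.size:
            raise ValueError("spectra second axis must match ppm axis")
        if np.any(self.spectra < 0):
            raise ValueError("magnitude spectra must be nonnegative")


def sos_combine(per_channel_volumes: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Sum-of-squares combination of multi-channel magnitude volumes.

    ``out = sqrt(sum_c |v_c|^2)`` voxelwise; with one channel this is the
    identity on magnitudes.
    """
    vols = [np.asarray(v, dtype=float) for v in per_channel_volumes]
    if len(vols) == 0:
        raise ValueError("need at least one channel")
    shape = vols[0].shape
    if any(v.shape != shape for v in vols):
        raise ValueError("channel grids do not match")
    return np.sqrt(np.sum([np.abs(v) ** 2 for v in vols], axis=0))


def estimate_noise_sd(volume: np.ndarray, background_mask: np.ndarray,
                      rayleigh_correct: bool = False) -> float:
    """Robust noise SD from background magnitudes.

    Default: median-absolute-deviation scaled by 1.4826 (Gaussian-consistent
    robust SD).  With ``rayleigh_correct=True`` the underlying per-channel
    sigma of pure magnitude (Rayleigh) noise is recovered from the
    background median, ``sigma = median / sqrt(2 ln 2)``.
    """
    bg = np.asarray(volume, dtype=float)[np.asarray(background_mask, dtype=bool)]
    if bg.size == 0:
        raise ValueError("empty background mask")
    if rayleigh_correct:
        return float(np.median(bg) / _RAYLEIGH_MEDIAN)
    med = np.median(bg)
    return float(1.4826 * np.median(np.abs(bg - med)))


def _summed(signal: np.ndarray) -> np.ndarray:
    return signal.sum(axis=-1)


def summed_snr(series: DynamicC13Series, metabolite: str = "pyr",
               roi: np.ndarray | None = None,
               noise_sd: float | None = None) -> tuple[np.ndarray, float]:
    """Time-summed SNR map and its ROI mean for one metabolite.

    Per voxel: signal summed over frames divided by
    ``noise_sd * sqrt(n_frames)`` (SD of a sum of independent noise terms).
    The ROI value is the mean over ROI voxels.
    """
    sd = series.noise_sd if noise_sd is None else noise_sd
    if sd is None or sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if series.n_frames == 0:
        raise ValueError("series has zero frames")
    sig = {"pyr": series.pyr_signal, "lac": series.lac_signal}[metabolite]
    snr_map = _summed(sig) / (sd * np.sqrt(series.n_frames))
    if sig.ndim == 1:
        return snr_map, float(snr_map)
    mask = series.mask if roi is None else np.asarray(roi, dtype=bool)
    if mask is None or not mask.any():
        raise ValueError("voxelwise SNR requires a nonempty ROI")
    return snr_map, float(snr_map[mask].mean())


def lac_pyr(series: DynamicC13Series, roi: np.ndarray | None = None,
            noise_sd: float | None = None, floor: float | None = None,
            method: str = "mean_of_ratios") -> tuple[float, int]:
    """LAC/PYR of the time-summed signals over the ROI.

    Returns ``(ratio, n_excluded)``.  Voxels whose summed pyruvate is below
    ``floor`` are excluded; the default floor is five times the noise of
    the summed image (``5 * noise_sd * sqrt(n_frames)``), or 0 when no
    noise level is known.
    """
    if method not in ("mean_of_ratios", "ratio_of_sums"):
        raise ValueError(f"unknown method {method!r}")
    sd = series.noise_sd if noise_sd is None else noise_sd
    if floor is None:
        floor = 5.0 * sd * np.sqrt(series.n_frames) if sd and sd > 0 else 0.0

    pyr_sum = _summed(series.pyr_signal)
    lac_sum = _summed(series.lac_signal)
    if series.pyr_signal.ndim == 1:
        if pyr_sum <= max(floor, 0.0):
            raise ValueError("summed pyruvate below usable floor")
        return float(lac_sum / pyr_sum), 0

    mask = series.mask if roi is None else np.asarray(roi, dtype=bool)
    if mask is None or not mask.any():
        raise ValueError("voxelwise LAC/PYR requires a nonempty ROI")
    p = pyr_sum[mask]
    l = lac_sum[mask]
    keep = p > max(floor, 0.0)
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("all ROI voxels below the pyruvate floor")
    if method == "mean_of_ratios":
        ratio = float(np.mean(l[keep] / p[keep]))
    else:
        ratio = float(l[keep].sum() / p[keep].sum())
    return ratio, n_excluded


def lac_pyr_from_spectra(spec: SpectralSeries,
                         pyr_window: tuple[float, float],
                         lac_window: tuple[float, float]) -> float:
    """LAC/PYR from time-summed spectra (the low-temporal-resolution path).

    Spectra are summed over time and the magnitude integrated within each
    chemical-shift window; the result is the lactate/pyruvate integral
    ratio.  Windows must be disjoint and inside the axis.
    """
    pw = tuple(sorted(pyr_window))
    lw = tuple(sorted(lac_window))
    if max(pw[0], lw[0]) < min(pw[1], lw[1]):
        raise ValueError("pyruvate and lactate windows overlap")
    lo, hi = float(np.min(spec.ppm)), float(np.max(spec.ppm))
    for w in (pw, lw):
        if w[0] < lo or w[1] > hi:
            raise ValueError("integration window outside the spectral axis")

    ppm = spec.ppm
    total = spec.spectra.sum(axis=0)
    if ppm[0] > ppm[-1]:  # integrate on an ascending axis
        ppm, total = ppm[::-1], total[::-1]

    def integral(w: tuple[float, float]) -> float:
        grid = np.union1d(ppm, np.asarray(w))
        vals = np.interp(grid, ppm, total)
        sel = (grid >= w[0]) & (grid <= w[1])
        return float(np.trapezoid(vals[sel], grid[sel]))

    pyr_area = integral(pw)
    if pyr_area <= 0:
        raise ValueError("zero pyruvate integral")
    return integral(lw) / pyr_area


def compute_c13_metrics(series: DynamicC13Series,
                        roi: np.ndarray | None = None,
                        noise_sd: float | None = None,
                        roi_id: str = "roi",
                        method: str = "mean_of_ratios") -> C13Metrics:
    """All three 13C summary metrics for one ROI."""
    _, snr_p = summed_snr(series, "pyr", roi, noise_sd)
    _, snr_l = summed_snr(series, "lac", roi, noise_sd)
    ratio, n_excl = lac_pyr(series, roi, noise_sd, method=method)
    if series.is_voxelwise:
        mask = series.mask if roi is None else np.asarray(roi, dtype=bool)
        n_vox = int(mask.sum())
    else:
        n_vox = 1
    return C13Metrics(summed_snr_pyr=max(snr_p, 0.0),
                      summed_snr_lac=max(snr_l, 0.0),
                      lac_pyr=ratio, n_voxels=n_vox,
                      n_excluded=n_excl, roi_id=roi_id)
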