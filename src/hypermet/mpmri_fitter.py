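"""Quantitative proton-MRI stage: IVIM, Tofts DCE, iAUC90 and tumor volume.

Units follow field convention: b-values in s/mm^2, diffusivities in mm^2/s,
DCE rate constants in min^-1 (curve times in minutes), iAUC90 in
concentration x seconds, volumes in mL.  Concentration/enhancement curves
are consumed directly; signal-to-concentration conversion is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .hp_simulator import ivim_signal, tofts_conc

__all__ = [
    "IVIMParams",
    "DCEParams",
    "VolumeMeasure",
    "fit_ivim_segmented",
    "fit_tofts",
    "iauc90",
    "tumor_volume",
]


@dataclass(frozen=True)
class IVIMParams:
    """Intravoxel-incoherent-motion biexponential parameters."""

    f: float          # perfusion fraction, unitless
    d: float          # tissue diffusivity, mm^2/s
    d_star: float     # pseudo-diffusion, mm^2/s
    s0: float
    clipped: bool = False
    failed: bool = False

    def __post_init__(self) -> None:
        if not self.failed:
            if not 0.0 <= self.f <= 1.0:
                raise ValueError("f must be in [0, 1]")
            if self.d <= 0 or self.d_star <= self.d:
                raise ValueError("need d_star > d > 0")


@dataclass(frozen=True)
class DCEParams:
    """Standard Tofts parameters; kep = ktrans/ve by construction."""

    ktrans: float     # min^-1
    kep: float        # min^-1
    ve: float         # unitless fraction
    iauc90: float = 0.0
    uncertain: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.ve <= 1.0:
            raise ValueError("ve must be in (0, 1]")
        if abs(self.kep - self.ktrans / self.ve) > 1e-9 * max(1.0, self.kep):
            raise ValueError("kep must equal ktrans/ve")
        if self.iauc90 < 0:
            raise ValueError("iauc90 must be >= 0")


@dataclass(frozen=True)
class VolumeMeasure:
    n_voxels: int
    voxel_volume_ml: float
    volume_ml: float

    def __post_init__(self) -> None:
        if abs(self.volume_ml - self.n_voxels * self.voxel_volume_ml) > 1e-9:
            raise ValueError("volume must equal n_voxels * voxel_volume")


def fit_ivim_segmented(signals: np.ndarray, bvalues: np.ndarray,
                       b_threshold: float = 200.0,
                       refine: bool = True) -> IVIMParams:
    """Segmented IVIM fit with an optional joint polish.

    1. log-linear fit of S(b) for b >= ``b_threshold`` -> D and intercept;
    2. f = 1 - intercept / S(0);
    3. nonlinear fit of D* with (f, D) fixed;
    4. (``refine=True``) joint nonlinear least squares of (f, D, D*, S0)
       started from the segmented estimates.  The segmented step alone
       carries a systematic bias whenever the pseudo-diffusion component
       has not fully decayed at the threshold b-value; the polish removes
       it while keeping the segmented solution as a robust initializer.

    Parameters are clipped to their physical bounds with ``clipped=True``
    when clipping occurred; a monotone-increasing signal is flagged as a
    failed fit rather than forced through the model.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(bvalues, dtype=float)
    if s.shape != b.shape or s.ndim != 1:
        raise ValueError("signals and bvalues must be matching 1-D arrays")
    if len(np.unique(b)) < 4 or 0.0 not in b:
        raise ValueError("need >= 4 distinct b-values including b = 0")
    hi = b >= b_threshold
    if hi.sum() < 2:
        raise ValueError(f"need >= 2 b-values >= {b_threshold}")
    s0_meas = float(np.mean(s[b == 0]))
    if s0_meas <= 0 or np.any(s <= 0):
        raise ValueError("signals must be positive for a log-linear fit")
    if np.polyfit(b, np.log(s), 1)[0] > 0:  # signal rising with b: unphysical
        return IVIMParams(f=0.0, d=1e-9, d_star=2e-9, s0=s0_meas,
                          failed=True)

    slope, intercept_log = np.polyfit(b[hi], np.log(s[hi]), 1)
    d = -slope
    intercept = math.exp(intercept_log)
    clipped = False
    if d <= 0:
        d, clipped = 1e-6, True
    f = 1.0 - intercept / s0_meas
    if not 0.0 <= f <= 1.0:
        f, clipped = min(max(f, 0.0), 1.0), True

    if f < 1e-6:
        # degenerate monoexponential: D* unidentifiable, report a bound
        return IVIMParams(f=0.0, d=d, d_star=max(10 * d, 2 * d), s0=s0_meas,
                          clipped=clipped)

    def resid(log_dstar: np.ndarray) -> np.ndarray:
        return ivim_signal(b, f, d, math.exp(log_dstar[0]), s0_meas) - s

    res = least_squares(resid, x0=[math.log(max(10 * d, 5e-3))],
                        bounds=([math.log(d * 1.001)], [math.log(1.0)]))
    d_star = math.exp(float(res.x[0]))
    if d_star <= d:
        d_star, clipped = d * 1.001, True

    if refine:
        def resid_all(x: np.ndarray) -> np.ndarray:
            fr, dd, dst, s0 = x
            return ivim_signal(b, fr, dd, max(dst, dd * 1.0001), s0) - s

        res = least_squares(
            resid_all, x0=[f, d, max(d_star, 2 * d), s0_meas],
            bounds=([0.0, 1e-6, 1e-5, 0.0],
                    [1.0, 0.05, 1.0, 10 * s0_meas]))
        f, d, d_star, s0_meas = (float(v) for v in res.x)
        if d_star <= d:
            d_star, clipped = d * 1.001, True
    return IVIMParams(f=f, d=d, d_star=d_star, s0=s0_meas, clipped=clipped)


def fit_tofts(ct_curve: np.ndarray, aif: np.ndarray | str,
              times_min: np.ndarray,
              flat_tol: float = 1e-6) -> DCEParams:
    """Nonlinear least-squares standard-Tofts fit over (ktrans, ve).

    Bounds: ktrans in [0, 5] min^-1, ve in (0, 1].  ``aif`` is a plasma
    curve on the same time grid or ``"impulse"``.  A flat tissue curve
    yields ktrans ~ 0 with ``uncertain=True`` instead of an error.
    """
    ct = np.asarray(ct_curve, dtype=float)
    t = np.asarray(times_min, dtype=float)
    if ct.shape != t.shape or ct.ndim != 1:
        raise ValueError("curve and times must be matching 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if ct.size < 10:
        raise ValueError("need >= 10 samples for a Tofts fit")

    if float(np.ptp(ct)) < flat_tol * max(1.0, abs(float(ct.mean()))):
        return DCEParams(ktrans=0.0, kep=0.0, ve=0.5, uncertain=True)

    def resid(x: np.ndarray) -> np.ndarray:
        return tofts_conc(t, x[0], x[1], aif) - ct

    best = None
    for x0 in ([0.1, 0.3], [0.5, 0.6], [0.02, 0.15]):
        res = least_squares(resid, x0=x0,
                            bounds=([0.0, 1e-6], [5.0, 1.0]))
        if best is None or res.cost < best.cost:
            best = res
    ktrans, ve = float(best.x[0]), float(best.x[1])
    return DCEParams(ktrans=ktrans, kep=ktrans / ve, ve=ve,
                     uncertain=not best.success)


def iauc90(curve: np.ndarray, times_s: np.ndarray, injection_time_s: float,
           window_s: float = 90.0) -> float:
    """Integrated area under the enhancement curve over 90 s past injection.

    Baseline (mean of pre-injection samples) is subtracted; the trapezoidal
    integral runs over exactly ``window_s`` seconds with the end point
    linearly interpolated.  Times are in seconds.
    """
    c = np.asarray(curve, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if c.shape != t.shape or np.any(np.diff(t) <= 0):
        raise ValueError("curve/times mismatch or non-increasing times")
    t_end = injection_time_s + window_s
    if t[0] > injection_time_s or t[-1] < t_end:
        raise ValueError("samples do not cover the integration window")
    pre = t <= injection_time_s
    baseline = float(c[pre].mean()) if pre.any() else 0.0
    enh = c - baseline
    grid = np.union1d(t, [injection_time_s, t_end])
    vals = np.interp(grid, t, enh)
    sel = (grid >= injection_time_s) & (grid <= t_end)
    return float(np.trapezoid(vals[sel], grid[sel]))


def tumor_volume(mask: np.ndarray,
                 voxel_dims_mm: tuple[float, float, float]) -> VolumeMeasure:
    """Tumor volume in mL from a binary mask and voxel dimensions in mm."""
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be binary")
    if any(v <= 0 for v in voxel_dims_mm):
        raise ValueError("voxel dimensions must be positive")
    n = int(m.sum())
    vox_ml = float(np.prod(voxel_dims_mm)) / 1000.0  # mm^3 -> mL
    if n == 0:
        import warnings
        warnings.warn("empty tumor mask: volume 0", RuntimeWarning,
                      stacklevel=2)
    return VolumeMeasure(n_voxels=n, voxel_volume_ml=vox_ml,
                         volume_ml=n * vox_ml)
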