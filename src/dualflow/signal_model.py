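"""Variable flip angle T1 estimation and SPGR signal <-> concentration conversion.

The spoiled gradient-echo (SPGR) steady-state signal is

    S(alpha) = M0 * sin(alpha) * (1 - E1) / (1 - E1 * cos(alpha)),
    E1 = exp(-TR / T1),

with TR the repetition time and alpha the flip angle.  Native T1 is
estimated from a multi-flip-angle acquisition; dynamic frames are then
inverted for T1(t) and converted to gadolinium concentration through the
linear relaxivity relation  C(t) = (1/T1(t) - 1/T1_native) / r1.

TE/T2* effects are neglected (TE << T2*), as is B1 inhomogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AcquisitionParams",
    "T1MapVoxel",
    "spgr_signal",
    "fit_vfa_t1",
    "signal_to_concentration",
    "concentration_to_signal",
    "fit_vfa_t1_volume",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition settings for the dynamic and multi-flip-angle scans.

    Parameters
    ----------
    tr : float
        Repetition time in ms.
    flip_angles : tuple of float
        Precontrast variable-flip-angle set, degrees.
    dyn_flip_angle : float
        Flip angle of the dynamic series, degrees.
    frame_interval : float
        Temporal resolution of the dynamic series, seconds.
    n_frames : int
        Number of dynamic frames.
    relaxivity_r1 : float
        Longitudinal relaxivity of the contrast agent, s^-1 mM^-1.
    """

    tr: float = 4.2
    flip_angles: tuple = (5.0, 15.0, 20.0, 25.0, 30.0)
    dyn_flip_angle: float = 15.0
    frame_interval: float = 2.0
    n_frames: int = 130
    relaxivity_r1: float = 4.5

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        fas = np.asarray(self.flip_angles, dtype=float)
        if np.any(fas <= 0) or np.any(fas > 90) or not (0 < self.dyn_flip_angle <= 90):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.relaxivity_r1 <= 0:
            raise ValueError("relaxivity_r1 must be positive")

    @property
    def times_min(self) -> np.ndarray:
        """Frame mid-times in minutes, first frame at t = 0."""
        return np.arange(self.n_frames) * self.frame_interval / 60.0


@dataclass(frozen=True)
class T1MapVoxel:
    """Per-voxel native T1 (ms) and equilibrium signal M0 (a.u.)."""

    t1_native: float
    m0: float
    flagged: bool = False

    def __post_init__(self):
        if not self.flagged and (self.t1_native <= 0 or self.m0 <= 0):
            raise ValueError("t1_native and m0 must be positive for a valid voxel")


def spgr_signal(t1_ms, flip_angle_deg, tr_ms, m0=1.0):
    """SPGR steady-state signal S = M0 sin(a) (1-E1)/(1-E1 cos(a))."""
    t1_ms = np.asarray(t1_ms, dtype=float)
    a = np.deg2rad(flip_angle_deg)
    e1 = np.exp(-tr_ms / t1_ms)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def _linearized_vfa(signals, angles_rad, tr_ms):
    # S/sin(a) = E1 * S/tan(a) + M0 (1 - E1): ordinary least squares line
    y = signals / np.sin(angles_rad)
    x = signals / np.tan(angles_rad)
    slope, intercept = np.polyfit(x, y, 1)
    return slope, intercept


def fit_vfa_t1(signals, acq: AcquisitionParams) -> T1MapVoxel:
    """Estimate native T1 and M0 from multi-flip-angle SPGR signals.

    Uses the linearised (S/sin vs S/tan) estimate as a seed for a
    nonlinear least-squares refinement of the SPGR equation itself.

    Returns a flagged :class:`T1MapVoxel` (rather than raising) when the
    voxel admits no physical SPGR solution, e.g. identical signal at all
    angles or a linearised slope outside (0, 1).
    """
    signals = np.asarray(signals, dtype=float)
    angles = np.asarray(acq.flip_angles, dtype=float)
    if signals.shape != angles.shape:
        raise ValueError("one signal per flip angle required")
    if len(np.unique(angles)) < 2:
        raise ValueError("at least 2 distinct flip angles required")
    if np.any(signals < 0):
        raise ValueError("signals must be non-negative")
    if np.ptp(signals) == 0 or np.all(signals == 0):
        return T1MapVoxel(t1_native=np.nan, m0=np.nan, flagged=True)

    angles_rad = np.deg2rad(angles)
    slope, intercept = _linearized_vfa(signals, angles_rad, acq.tr)
    if not (0.0 < slope < 1.0) or intercept <= 0:
        return T1MapVoxel(t1_native=np.nan, m0=np.nan, flagged=True)
    t1_seed = -acq.tr / np.log(slope)
    m0_seed = intercept / (1.0 - slope)

    def resid(p):
        t1, m0 = p
        return spgr_signal(t1, angles, acq.tr, m0) - signals

    sol = least_squares(
        resid,
        x0=[t1_seed, m0_seed],
        bounds=([1.0, 1e-12], [20000.0, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    t1, m0 = sol.x
    if t1 <= 0 or m0 <= 0 or not np.isfinite(t1):
        return T1MapVoxel(t1_native=np.nan, m0=np.nan, flagged=True)
    return T1MapVoxel(t1_native=float(t1), m0=float(m0))


def fit_vfa_t1_volume(stack, acq: AcquisitionParams, mask=None):
    """Voxelwise VFA T1 fit over a (..., n_fa) signal stack.

    Returns (t1_map, m0_map, flag_map) arrays with the stack's spatial
    shape.  Voxels outside ``mask`` (or degenerate ones) are NaN/flagged.
    """
    stack = np.asarray(stack, dtype=float)
    spatial = stack.shape[:-1]
    t1 = np.full(spatial, np.nan)
    m0 = np.full(spatial, np.nan)
    flags = np.zeros(spatial, dtype=bool)
    it = np.ndindex(spatial)
    for idx in it:
        if mask is not None and not mask[idx]:
            continue
        vox = fit_vfa_t1(stack[idx], acq)
        flags[idx] = vox.flagged
        if not vox.flagged:
            t1[idx] = vox.t1_native
            m0[idx] = vox.m0
    return t1, m0, flags


def concentration_to_signal(conc_mM, t1map: T1MapVoxel, acq: AcquisitionParams):
    """Forward-simulate the dynamic SPGR signal for a concentration series.

    1/T1(t) = 1/T1_native + r1 * C(t) with r1 in s^-1 mM^-1 and T1 in ms.
    """
    conc = np.asarray(conc_mM, dtype=float)
    r1_ms = acq.relaxivity_r1 / 1000.0  # ms^-1 mM^-1
    inv_t1 = 1.0 / t1map.t1_native + r1_ms * conc
    return spgr_signal(1.0 / inv_t1, acq.dyn_flip_angle, acq.tr, t1map.m0)


def signal_to_concentration(
    signal_t,
    baseline_frames: int,
    t1map: T1MapVoxel,
    acq: AcquisitionParams,
    clamp_invalid: bool = True,
):
    """Convert a dynamic SPGR signal series to contrast-agent concentration (mM).

    M0 is recalibrated per voxel so that the mean baseline signal maps to
    the native T1 at the dynamic flip angle; each frame is then inverted
    for T1(t) and C(t) = (1/T1(t) - 1/T1_native)/r1.

    Frames whose signal admits no SPGR inversion (signal at or beyond the
    saturation bound) are flagged; with ``clamp_invalid`` they inherit the
    last valid concentration, otherwise NaN.  Returns (conc, flags).
    """
    s = np.asarray(signal_t, dtype=float)
    if not (1 <= baseline_frames < s.size):
        raise ValueError("baseline_frames must be >= 1 and < number of frames")
    if t1map.flagged:
        raise ValueError("cannot convert signal for a flagged T1 voxel")

    a = np.deg2rad(acq.dyn_flip_angle)
    e1_native = np.exp(-acq.tr / t1map.t1_native)
    f_native = np.sin(a) * (1.0 - e1_native) / (1.0 - e1_native * np.cos(a))
    s_base = float(np.mean(s[:baseline_frames]))
    if s_base <= 0:
        raise ValueError("non-positive baseline signal")
    m0 = s_base / f_native

    # invert S = M0 sin(a)(1-E1)/(1-E1 cos a)  ->  E1 = (1 - y)/(1 - y cos a),
    # y = S/(M0 sin a); valid while E1 in (0, 1)
    y = s / (m0 * np.sin(a))
    denom = 1.0 - y * np.cos(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (1.0 - y) / denom
    valid = (denom > 0) & (e1 > 0) & (e1 < 1) & (s > 0)
    conc = np.full_like(s, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1_t = -acq.tr / np.log(np.where(valid, e1, 0.5))
    r1_ms = acq.relaxivity_r1 / 1000.0
    conc[valid] = (1.0 / t1_t[valid] - 1.0 / t1map.t1_native) / r1_ms
    flags = ~valid
    if np.any(flags):
        warnings.warn(
            f"{int(flags.sum())} frame(s) outside the SPGR-invertible range",
            RuntimeWarning,
            stacklevel=2,
        )
        if clamp_invalid:
            last = 0.0
            for i in range(conc.size):
                if flags[i]:
                    conc[i] = last
                else:
                    last = conc[i]
    return conc, flags
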