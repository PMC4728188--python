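"""Spoiled gradient echo (SPGR) signal model, variable-flip-angle T1 mapping,
and signal-to-gadolinium-concentration conversion.

The SPGR steady-state signal is

    S = M0 * sin(a) * (1 - E1) / (1 - cos(a) * E1),    E1 = exp(-TR / T1)

with flip angle ``a`` and repetition time TR.  T2*-weighting (exp(-TE/T2*))
is treated as a constant absorbed into M0: TE is short in the acquisitions
this package targets, and the factor cancels in the baseline-ratio inversion
used for concentration conversion.

Concentration conversion exploits the linear relation between gadolinium
concentration and the longitudinal relaxation rate,

    R1(t) = 1/T1(t) = 1/T10 + r1 * C(t)

with relaxivity r1 in l mmol^-1 s^-1.  TR and T1 are carried in milliseconds
internally and converted to seconds only at the concentration step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AcquisitionParams",
    "T1Map",
    "ConcentrationSeries",
    "spgr_signal",
    "fit_t1_mfa",
    "fit_t1_volume",
    "signal_to_concentration",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition settings of an SPGR dynamic series.

    Parameters
    ----------
    tr : float
        Repetition time, milliseconds.
    te : float
        Echo time, milliseconds (metadata only; not used by the signal model).
    flip_angle : float
        Excitation flip angle, degrees, in (0, 90).
    frame_interval : float
        Time between dynamic frames, seconds.
    n_frames : int
        Number of dynamic frames (>= 2).
    """

    tr: float = 4.0
    te: float = 1.7
    flip_angle: float = 18.0
    frame_interval: float = 3.0
    n_frames: int = 181

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not 0 < self.flip_angle < 90:
            raise ValueError(f"flip_angle must be in (0, 90) degrees, got {self.flip_angle}")
        if self.frame_interval <= 0:
            raise ValueError(f"frame_interval must be positive, got {self.frame_interval}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")

    @property
    def frame_times(self) -> np.ndarray:
        """Frame mid-times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class T1Map:
    """Per-voxel longitudinal relaxation time and equilibrium signal scale.

    ``t1`` is in milliseconds, ``m0`` in arbitrary signal units; ``fit_ok``
    flags voxels where the multi-flip-angle fit succeeded and produced
    t1 in (0, t1_max].
    """

    t1: np.ndarray
    m0: np.ndarray
    fit_ok: np.ndarray

    def __post_init__(self) -> None:
        ok = self.fit_ok
        if np.any(self.t1[ok] <= 0):
            raise ValueError("t1 must be positive wherever fit_ok")
        if np.any(self.m0[ok] < 0):
            raise ValueError("m0 must be non-negative wherever fit_ok")


@dataclass
class ConcentrationSeries:
    """Gadolinium concentration time courses (mM) with per-frame validity.

    ``conc`` has time as the last axis.  ``valid`` is False where the SPGR
    inversion had no real solution (signal at or beyond the SPGR asymptote,
    or a non-positive exponential argument).  By construction the mean of
    the ``baseline_frames`` leading frames maps to zero concentration.
    """

    conc: np.ndarray
    valid: np.ndarray
    baseline_frames: int


def spgr_signal(m0, t1, acq: AcquisitionParams):
    """Evaluate the SPGR steady-state signal equation.

    Parameters
    ----------
    m0 : array_like
        Equilibrium signal scale (arbitrary units).
    t1 : array_like
        Longitudinal relaxation time, milliseconds, strictly positive.
    acq : AcquisitionParams
        Supplies TR (ms) and flip angle (degrees).

    Returns
    -------
    ndarray or float
        Signal intensity, same broadcast shape as ``m0`` and ``t1``.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be strictly positive")
    alpha = np.deg2rad(acq.flip_angle)
    e1 = np.exp(-acq.tr / t1)
    out = np.asarray(m0, dtype=float) * np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)
    return out if out.ndim else float(out)


def _despot1_init(signals: np.ndarray, flip_angles: np.ndarray, tr: float):
    # Linearised SPGR (S/sin a = E1 * S/tan a + M0 (1-E1)): slope gives E1.
    sin_a = np.sin(np.deg2rad(flip_angles))
    tan_a = np.tan(np.deg2rad(flip_angles))
    y = signals / sin_a
    x = signals / tan_a
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    e1 = float(np.clip(slope, 1e-8, 1.0 - 1e-8))
    t1 = -tr / np.log(e1)
    m0 = max(float(intercept) / (1.0 - e1), 1e-12)
    return t1, m0


def fit_t1_mfa(signals, flip_angles, tr: float, t1_max: float = 10_000.0):
    """Fit T1 and M0 from multi-flip-angle SPGR signals.

    Non-linear least squares against the SPGR equation, initialised from the
    linearised (DESPOT1) solution.

    Parameters
    ----------
    signals : array_like
        One non-negative signal per flip angle.
    flip_angles : array_like
        Flip angles in degrees; at least 3 distinct values.
    tr : float
        Repetition time, milliseconds.
    t1_max : float
        Fits with t1 outside (0, t1_max] ms are flagged not-ok.

    Returns
    -------
    (t1, m0, fit_ok) : (float, float, bool)
    """
    signals = np.asarray(signals, dtype=float)
    flip_angles = np.asarray(flip_angles, dtype=float)
    if len(np.unique(flip_angles)) < 3:
        raise ValueError("at least 3 distinct flip angles are required")
    if signals.shape != flip_angles.shape:
        raise ValueError("signals and flip_angles must have the same length")
    if np.any(signals < 0):
        raise ValueError("signals must be non-negative")
    if not np.any(signals > 0):
        return np.nan, np.nan, False

    t1_0, m0_0 = _despot1_init(signals, flip_angles, tr)
    t1_0 = float(np.clip(t1_0, 1.0, t1_max))
    alpha = np.deg2rad(flip_angles)

    def resid(x):
        t1, m0 = x
        e1 = np.exp(-tr / t1)
        return m0 * np.sin(alpha) * (1 - e1) / (1 - np.cos(alpha) * e1) - signals

    try:
        sol = least_squares(
            resid,
            x0=[t1_0, m0_0],
            bounds=([1e-3, 0.0], [np.inf, np.inf]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except Exception:
        return np.nan, np.nan, False
    t1, m0 = sol.x
    ok = bool(sol.success or sol.status > 0) and 0 < t1 <= t1_max
    return float(t1), float(m0), ok


def fit_t1_volume(mfa_stack, flip_angles, tr: float, mask=None, t1_max: float = 10_000.0) -> T1Map:
    """Voxelwise multi-flip-angle T1 mapping over a volume.

    Parameters
    ----------
    mfa_stack : ndarray
        Signals with flip angle as the last axis, shape (..., n_angles).
    flip_angles : array_like, degrees.
    tr : float, milliseconds.
    mask : ndarray of bool, optional
        Voxels to fit; outside voxels get t1=nan, fit_ok=False.
    """
    mfa_stack = np.asarray(mfa_stack, dtype=float)
    spatial = mfa_stack.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    t1 = np.full(spatial, np.nan)
    m0 = np.full(spatial, np.nan)
    ok = np.zeros(spatial, dtype=bool)
    for idx in zip(*np.nonzero(mask)):
        t1[idx], m0[idx], ok[idx] = fit_t1_mfa(mfa_stack[idx], flip_angles, tr, t1_max=t1_max)
    return T1Map(t1=t1, m0=m0, fit_ok=ok)


def signal_to_concentration(
    series,
    t10,
    acq: AcquisitionParams,
    r1: float,
    baseline_frames: int = 10,
) -> ConcentrationSeries:
    """Convert SPGR signal time courses to gadolinium concentration (mM).

    The equilibrium scale M0 is estimated per voxel from the mean of the
    pre-bolus baseline frames together with the pre-contrast T10; each frame's
    signal is then inverted through the SPGR equation for T1(t), and

        C(t) = (1/T1(t) - 1/T10) / r1

    with relaxation times in seconds for this step.  Frames where the
    inversion has no real solution (signal at or beyond the SPGR asymptote
    M0 sin(a)) are flagged ``valid=False`` and carry NaN concentration.

    Parameters
    ----------
    series : ndarray
        Signal with time as the last axis, shape (..., n_frames).
    t10 : array_like
        Pre-contrast T1, milliseconds; broadcastable to the spatial shape.
    acq : AcquisitionParams
    r1 : float
        Relaxivity, l mmol^-1 s^-1, positive.
    baseline_frames : int
        Number of leading pre-bolus frames averaged for the baseline (>= 1).
    """
    series = np.asarray(series, dtype=float)
    t10 = np.asarray(t10, dtype=float)
    if np.any(t10 <= 0):
        raise ValueError("t10 must be strictly positive")
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    if baseline_frames < 1:
        raise ValueError("baseline_frames must be >= 1")
    if baseline_frames > series.shape[-1]:
        raise ValueError("baseline_frames exceeds the number of frames")

    alpha = np.deg2rad(acq.flip_angle)
    sin_a, cos_a = np.sin(alpha), np.cos(alpha)
    e10 = np.exp(-acq.tr / t10)
    f10 = sin_a * (1 - e10) / (1 - cos_a * e10)

    s_base = series[..., :baseline_frames].mean(axis=-1)
    m0 = s_base / f10  # per-voxel equilibrium scale
    asymptote = (m0 * sin_a)[..., None]

    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (asymptote - series) / (asymptote - series * cos_a)
        valid = np.isfinite(e1) & (e1 > 0) & (e1 < 1)
        r1_of_t = np.where(valid, -np.log(np.where(valid, e1, 0.5)) / acq.tr, np.nan)  # ms^-1
        conc = (1000.0 * r1_of_t - 1000.0 / t10[..., None]) / r1
    conc = np.where(valid, conc, np.nan)
    return ConcentrationSeries(conc=conc, valid=valid, baseline_frames=baseline_frames)
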