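"""Arterial input functions: population model curve, individual measurement
from the dynamic series, and sample averaging across visits.

Three AIF forms drive the tissue model:

1. a *model* AIF — a first-pass bolus template (literature-shaped, scaled to
   the injected dose) concatenated with a biexponential plasma washout,
   rescaled for continuity at the junction;
2. an *individual* AIF — measured from an arterial mask (e.g. descending
   aorta) in each dynamic series, converted to plasma concentration with a
   hematocrit correction;
3. a *sample-average* AIF — the pointwise mean of several individual AIFs
   after aligning their bolus-arrival times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal import AcquisitionParams, signal_to_concentration

__all__ = [
    "ArterialInputFunction",
    "ModelAifParams",
    "model_aif",
    "measure_individual_aif",
    "sample_average_aif",
]

#: Default bolus first-pass template (times s, plasma [Gd] mM at 0.1 mmol/kg).
#: Gamma-variate-shaped default standing in for published blood-sampled
#: first-pass data; peak ~4 mM at 15 s after arrival.  A default, not a
#: measured curve: replace with study-specific data where available.
_DEFAULT_FIRST_PASS_TIMES = np.arange(0.0, 46.0, 1.5)
_T_PEAK, _GAMMA_SHAPE, _PEAK_CP = 15.0, 3.0, 4.0


def _gamma_variate(t, t_peak=_T_PEAK, shape=_GAMMA_SHAPE, peak=_PEAK_CP):
    # first-pass bolus plus a recirculation plateau rising to ~0.9 mM
    t = np.asarray(t, dtype=float)
    x = np.clip(t / t_peak, 0.0, None)
    bolus = peak * x**shape * np.exp(shape * (1.0 - x))
    recirc = 0.9 * -np.expm1(-np.clip(t, 0.0, None) / 25.0)
    return bolus + recirc


@dataclass(frozen=True)
class ArterialInputFunction:
    """Plasma gadolinium concentration versus time.

    Attributes
    ----------
    times : ndarray, seconds (strictly increasing).
    cp : ndarray, plasma [Gd] in mM (non-negative, finite).
    provenance : one of {"model", "individual", "sample_average"}.
    dose : float or None, mmol/kg (model form only).
    flagged : bool
        True when the construction emitted a data-quality warning.
    """

    times: np.ndarray
    cp: np.ndarray
    provenance: str
    dose: float | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        cp = np.asarray(self.cp, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "cp", cp)
        if times.ndim != 1 or times.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if cp.shape != times.shape:
            raise ValueError("cp and times must have the same shape")
        if not np.all(np.isfinite(cp)):
            raise ValueError("cp must be finite everywhere")
        if np.any(cp < -1e-12):
            raise ValueError("cp must be non-negative")
        if self.provenance not in {"model", "individual", "sample_average"}:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def interp(self, times) -> np.ndarray:
        """Linearly interpolate cp onto ``times`` (s); 0 before, last value after."""
        return np.interp(np.asarray(times, dtype=float), self.times, self.cp,
                         left=0.0, right=float(self.cp[-1]))

    def scaled(self, factor: float) -> "ArterialInputFunction":
        """Return a copy with cp multiplied by ``factor`` (e.g. 1/beta)."""
        return ArterialInputFunction(self.times, self.cp * factor, self.provenance,
                                     self.dose, self.flagged)

    def bolus_arrival(self, frac: float = 0.1) -> float:
        """Interpolated time at which cp first crosses ``frac`` of its peak."""
        return _bolus_arrival(self.times, self.cp, frac)


@dataclass(frozen=True)
class ModelAifParams:
    """Parameters of the population model AIF.

    The first-pass template (``first_pass_times``/``first_pass_cp``, seconds /
    mM at ``template_dose`` mmol/kg) describes the bolus shape relative to
    bolus arrival; washout after ``junction_time`` is the biexponential
    dose*(a1*exp(-m1*t) + a2*exp(-m2*t)) with amplitudes in kg/l and rates in
    min^-1, rescaled for continuity at the junction.  Defaults are
    literature-derived conventions, not study measurements.
    """

    first_pass_times: np.ndarray = field(
        default_factory=lambda: _DEFAULT_FIRST_PASS_TIMES.copy())
    first_pass_cp: np.ndarray = field(
        default_factory=lambda: _gamma_variate(_DEFAULT_FIRST_PASS_TIMES))
    template_dose: float = 0.1
    a1: float = 3.99
    a2: float = 4.78
    m1: float = 0.144
    m2: float = 0.0111
    junction_time: float = 45.0

    def __post_init__(self) -> None:
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("washout rates must be positive")
        fp_t = np.asarray(self.first_pass_times, dtype=float)
        object.__setattr__(self, "first_pass_times", fp_t)
        object.__setattr__(self, "first_pass_cp",
                           np.asarray(self.first_pass_cp, dtype=float))
        if self.junction_time > 0 and fp_t.size and self.junction_time > fp_t[-1] + 1e-9:
            raise ValueError("junction_time must lie within the first-pass template span")


def model_aif(params: ModelAifParams, dose: float, times, onset: float = 0.0) -> ArterialInputFunction:
    """Construct the population model AIF at the requested sample times.

    cp is zero before bolus arrival (``onset`` seconds); the first-pass
    template, linearly interpolated and scaled to ``dose``, applies up to
    ``junction_time`` past arrival; thereafter the biexponential washout,
    multiplied by a continuity factor matching the template value at the
    junction.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if dose <= 0:
        raise ValueError("dose must be positive")

    t = times - onset  # time since bolus arrival
    scale = dose / params.template_dose

    def washout(tau):
        tau_min = np.asarray(tau, dtype=float) / 60.0
        return dose * (params.a1 * np.exp(-params.m1 * tau_min)
                       + params.a2 * np.exp(-params.m2 * tau_min))

    tj = params.junction_time
    if tj > 0:
        template = np.interp(t, params.first_pass_times, params.first_pass_cp,
                             left=0.0, right=float(params.first_pass_cp[-1])) * scale
        cp_junction = float(np.interp(tj, params.first_pass_times,
                                      params.first_pass_cp)) * scale
        w_j = float(washout(tj))
        cont = cp_junction / w_j if w_j > 0 else 1.0
        cp = np.where(t <= tj, template, cont * washout(t))
    else:
        cp = washout(np.clip(t, 0.0, None))
    cp = np.where(t < 0, 0.0, cp)
    return ArterialInputFunction(times=times, cp=np.clip(cp, 0.0, None),
                                 provenance="model", dose=dose)


def measure_individual_aif(
    series,
    artery_mask,
    t10_blood: float,
    acq: AcquisitionParams,
    r1: float,
    hematocrit: float = 0.42,
    times=None,
    baseline_frames: int = 10,
) -> ArterialInputFunction:
    """Measure an individual AIF from an arterial mask in the dynamic series.

    Masked voxel signals are averaged per frame, converted to whole-blood
    gadolinium concentration through the SPGR inversion with the blood T10,
    and divided by (1 - hematocrit) to give plasma concentration.  If more
    than half the frames fail the conversion the AIF is flagged.

    Parameters
    ----------
    series : ndarray, 4-D signal (x, y, z, t).
    artery_mask : ndarray of bool, 3-D, non-empty, same spatial grid.
    t10_blood : float, ms — pre-contrast blood T1 (e.g. median of the T1 map
        within the mask).
    times : array_like, seconds; defaults to ``acq.frame_times``.
    """
    series = np.asarray(series, dtype=float)
    artery_mask = np.asarray(artery_mask).astype(bool)
    if artery_mask.shape != series.shape[:-1]:
        raise ValueError("artery_mask grid does not match the series")
    if not artery_mask.any():
        raise ValueError("artery_mask is empty")
    if not 0 <= hematocrit < 1:
        raise ValueError("hematocrit must be in [0, 1)")
    if times is None:
        times = np.arange(series.shape[-1]) * acq.frame_interval
    times = np.asarray(times, dtype=float)

    blood_signal = series[artery_mask].mean(axis=0)
    conv = signal_to_concentration(blood_signal, t10_blood, acq, r1,
                                   baseline_frames=baseline_frames)
    cb = conv.conc
    n_invalid = int((~conv.valid).sum())
    flagged = False
    if n_invalid > 0.5 * cb.size:
        warnings.warn(
            f"AIF conversion invalid in {n_invalid}/{cb.size} frames; AIF flagged",
            RuntimeWarning, stacklevel=2)
        flagged = True
    cb = np.where(conv.valid, cb, 0.0)
    cp = np.clip(cb / (1.0 - hematocrit), 0.0, None)
    return ArterialInputFunction(times=times, cp=cp, provenance="individual",
                                 flagged=flagged)


def _bolus_arrival(times, cp, frac=0.1):
    cp = np.asarray(cp, dtype=float)
    peak = cp.max()
    thresh = frac * peak
    above = np.nonzero(cp > thresh)[0]
    if peak <= 0 or above.size == 0:
        return np.nan
    i = above[0]
    if i == 0:
        return float(times[0])
    # linear interpolation of the crossing time
    t0, t1 = times[i - 1], times[i]
    c0, c1 = cp[i - 1], cp[i]
    return float(t0 + (thresh - c0) / (c1 - c0) * (t1 - t0))


def sample_average_aif(
    aifs,
    arrival_frac: float = 0.1,
    min_peak: float = 0.05,
) -> ArterialInputFunction:
    """Average several AIFs after aligning their bolus-arrival times.

    Each input is shifted in time so its bolus arrival (first crossing of
    ``arrival_frac`` of peak, linearly interpolated) coincides with that of
    the first usable AIF, interpolated onto that AIF's time grid, and the
    pointwise mean is returned.  AIFs with no detectable bolus (peak below
    ``min_peak`` mM) are excluded with a warning.
    """
    aifs = list(aifs)
    if len(aifs) < 2:
        raise ValueError("at least 2 AIFs are required")
    usable, arrivals = [], []
    for a in aifs:
        t_arr = _bolus_arrival(a.times, a.cp, arrival_frac)
        if not np.isfinite(t_arr) or a.cp.max() < min_peak:
            warnings.warn("excluding flat AIF with no detectable bolus",
                          RuntimeWarning, stacklevel=2)
            continue
        usable.append(a)
        arrivals.append(t_arr)
    if not usable:
        raise ValueError("no AIF with a detectable bolus")

    ref, t_ref = usable[0], arrivals[0]
    grid = ref.times
    stack = np.empty((len(usable), grid.size))
    for k, (a, t_arr) in enumerate(zip(usable, arrivals)):
        shift = t_arr - t_ref  # align arrival onto the reference
        stack[k] = np.interp(grid, a.times - shift, a.cp,
                             left=float(a.cp[0]), right=float(a.cp[-1]))
    return ArterialInputFunction(times=grid, cp=stack.mean(axis=0),
                                 provenance="sample_average")
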