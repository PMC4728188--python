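"""Digital reference phantom: synthetic MFA + dynamic SPGR series with known
tracer-kinetic ground truth.

Every voxel's tissue curve is built through the same physics the pipeline
inverts — extended Tofts uptake from a generation AIF, the linear
concentration/relaxation-rate relation, and the SPGR signal equation — so a
round trip through the full pipeline is exact in the noiseless limit.
Designed zones exercise each error category; a synthetic artery region
carries the generation AIF (as whole blood, hematocrit applied in reverse)
so individual-AIF measurement is testable end to end.

Noise is Gaussian on signal magnitude (not Rician): simple, and adequate at
the signal-to-noise regime exercised.  All randomness is fixed by the spec
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .aif import ArterialInputFunction, ModelAifParams, model_aif
from .errormap import ErrorCategory, OUTSIDE
from .signal import AcquisitionParams, spgr_signal
from .tofts import PKParams, etm_forward

__all__ = ["Zone", "PhantomSpec", "PhantomTruth", "PhantomData",
           "generate_phantom", "make_category_phantom", "DEFAULT_MFA_ANGLES"]

DEFAULT_MFA_ANGLES = (1.0, 3.0, 5.0, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class Zone:
    """A labelled rectangular region of the phantom tumour.

    ``kind`` is one of ``tissue`` (extended Tofts uptake from ``params``),
    ``no_uptake`` (zero concentration) or ``noise_burst`` (tissue uptake
    plus deterministic high-amplitude concentration spikes).
    """

    name: str
    x: tuple[int, int]
    y: tuple[int, int]
    params: PKParams | None
    kind: str = "tissue"
    t10: float = 1000.0
    m0_scale: float = 1.0  # proton-density factor relative to spec.m0

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.x[0]:self.x[1], self.y[0]:self.y[1], :] = True
        return m


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic phantom; the seed fixes all noise."""

    shape: tuple[int, int, int] = (32, 32, 3)
    zones: tuple[Zone, ...] = ()
    artery_x: tuple[int, int] = (8, 24)
    artery_y: tuple[int, int] = (27, 30)
    t10_blood: float = 1440.0
    hematocrit: float = 0.42
    m0: float = 1000.0
    noise_sd: float = 0.0
    mfa_noise_sd: float | None = None  # defaults to noise_sd / 2
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    mfa_angles: tuple[float, ...] = DEFAULT_MFA_ANGLES
    aif_params: ModelAifParams = field(default_factory=ModelAifParams)
    dose: float = 0.1
    bolus_arrival: float = 30.0
    r1: float = 3.6
    burst_amplitude: float = 25.0
    burst_period: int = 3
    seed: int = 0

    def validate(self) -> None:
        shape = self.shape
        cover = np.zeros(shape, dtype=bool)
        for z in self.zones:
            m = z.mask(shape)
            if (cover & m).any():
                raise ValueError(f"zone {z.name!r} overlaps another zone")
            cover |= m
        artery = np.zeros(shape, dtype=bool)
        artery[self.artery_x[0]:self.artery_x[1], self.artery_y[0]:self.artery_y[1], :] = True
        if (cover & artery).any():
            raise ValueError("artery region overlaps a tumour zone")


@dataclass
class PhantomTruth:
    """Ground truth aligned to the phantom grid."""

    ktrans: np.ndarray
    ve: np.ndarray
    vp: np.ndarray
    category: np.ndarray            # expected category when fit with the true AIF
    zone_labels: np.ndarray         # -1 outside, else index into spec.zones
    aif: ArterialInputFunction      # generation AIF (plasma)
    seed: int


@dataclass
class PhantomData:
    """Generated phantom: MFA stack, dynamic series, masks and truth."""

    mfa: np.ndarray                 # (x, y, z, n_angles)
    mfa_angles: tuple[float, ...]
    dynamic: np.ndarray             # (x, y, z, t)
    times: np.ndarray               # s
    tumour_mask: np.ndarray
    artery_mask: np.ndarray
    t10_map: np.ndarray             # true T10, ms (NaN outside masks)
    truth: PhantomTruth
    spec: PhantomSpec


def expected_category(zone: Zone, fit_aif_scale: float = 1.0,
                      thresholds=None) -> ErrorCategory:
    """Designed category of a zone when fitted with a scaled AIF.

    Fitting against ``fit_aif_scale * Cp`` rescales the recovered
    (Ktrans, ve, vp) by 1/scale while kep is invariant — the mechanism by
    which an artificially small AIF inflates ve past 1.
    """
    from .errormap import CheckThresholds

    thr = thresholds or CheckThresholds()
    if zone.kind == "noise_burst":
        return ErrorCategory.GD_SD_TOO_BIG
    if zone.kind == "no_uptake":
        return ErrorCategory.GD_TOO_SMALL
    p = zone.params
    s = fit_aif_scale
    ktrans, ve, vp = p.ktrans / s, p.ve / s, p.vp / s
    kep = 0.0 if ktrans == 0 else ktrans / ve
    if ve >= thr.ve_limit:
        return ErrorCategory.VE_GE_ONE
    if vp >= thr.vp_limit:
        return ErrorCategory.VP_GE_ONE
    if ktrans > thr.ktrans_max or kep > thr.kep_max:
        return ErrorCategory.PARAM_TOO_LARGE
    return ErrorCategory.GOOD


def generate_phantom(spec: PhantomSpec) -> PhantomData:
    """Synthesize the phantom described by ``spec``.

    Deterministic given ``spec.seed``: two specs differing only in seed share
    identical noiseless components and differ only in the noise draws.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape, acq = spec.shape, spec.acq
    times = acq.frame_times
    aif = model_aif(spec.aif_params, spec.dose, times, onset=spec.bolus_arrival)

    tumour_mask = np.zeros(shape, dtype=bool)
    artery_mask = np.zeros(shape, dtype=bool)
    artery_mask[spec.artery_x[0]:spec.artery_x[1],
                spec.artery_y[0]:spec.artery_y[1], :] = True

    ktrans = np.full(shape, np.nan)
    ve = np.full(shape, np.nan)
    vp = np.full(shape, np.nan)
    category = np.full(shape, OUTSIDE, dtype=np.int16)
    zone_labels = np.full(shape, -1, dtype=np.int16)
    t10_map = np.full(shape, np.nan)

    dynamic = np.zeros(shape + (acq.n_frames,))
    mfa = np.zeros(shape + (len(spec.mfa_angles),))

    burst = np.zeros(acq.n_frames)
    post = times >= spec.bolus_arrival
    idx_post = np.nonzero(post)[0]
    burst[idx_post[::spec.burst_period]] = spec.burst_amplitude

    for zi, zone in enumerate(spec.zones):
        m = zone.mask(shape)
        tumour_mask |= m
        zone_labels[m] = zi
        t10_map[m] = zone.t10
        if zone.kind == "no_uptake":
            ct = np.zeros(acq.n_frames)
            ktrans[m], ve[m], vp[m] = 0.0, 0.0, 0.0
        else:
            ct = etm_forward(zone.params, aif, times)
            ktrans[m] = zone.params.ktrans
            ve[m] = zone.params.ve
            vp[m] = zone.params.vp
            if zone.kind == "noise_burst":
                ct = ct + burst
        category[m] = int(expected_category(zone))
        m0_zone = spec.m0 * zone.m0_scale
        dynamic[m] = _spgr_dynamic(ct, zone.t10, m0_zone, acq, spec.r1)
        mfa[m] = _spgr_mfa(zone.t10, m0_zone, acq, spec.mfa_angles)

    # artery: generation AIF as whole blood
    cb = aif.cp * (1.0 - spec.hematocrit)
    t10_map[artery_mask] = spec.t10_blood
    dynamic[artery_mask] = _spgr_dynamic(cb, spec.t10_blood, spec.m0, acq, spec.r1)
    mfa[artery_mask] = _spgr_mfa(spec.t10_blood, spec.m0, acq, spec.mfa_angles)
    category[artery_mask] = OUTSIDE

    if spec.noise_sd > 0:
        dynamic = dynamic + rng.normal(0.0, spec.noise_sd, dynamic.shape)
        mfa_sd = spec.mfa_noise_sd if spec.mfa_noise_sd is not None else spec.noise_sd / 2
        if mfa_sd > 0:
            mfa = mfa + rng.normal(0.0, mfa_sd, mfa.shape)
        np.clip(dynamic, 0.0, None, out=dynamic)
        np.clip(mfa, 0.0, None, out=mfa)

    truth = PhantomTruth(ktrans=ktrans, ve=ve, vp=vp, category=category,
                         zone_labels=zone_labels, aif=aif, seed=spec.seed)
    return PhantomData(mfa=mfa, mfa_angles=spec.mfa_angles, dynamic=dynamic,
                       times=times, tumour_mask=tumour_mask,
                       artery_mask=artery_mask, t10_map=t10_map,
                       truth=truth, spec=spec)


def _spgr_dynamic(ct, t10, m0, acq, r1):
    r1_of_t = 1000.0 / t10 + r1 * ct            # s^-1
    t1_ms = 1000.0 / r1_of_t
    return spgr_signal(m0, t1_ms, acq)


def _spgr_mfa(t10, m0, acq, angles):
    return np.array([
        spgr_signal(m0, t10, replace(acq, flip_angle=a)) for a in angles])


# -- canonical category phantom ------------------------------------------

_GOOD = PKParams(ktrans=0.15, ve=0.25, vp=0.03)
_VE_A = PKParams(ktrans=0.25, ve=0.45, vp=0.03)   # ve>=1 when AIF scaled by 1/3
_VE_B = PKParams(ktrans=0.30, ve=0.60, vp=0.04)   # ve>=1 already at 1/2
_HOT = PKParams(ktrans=20.0, ve=0.60, vp=0.05)    # Ktrans>>10, kep=33>15


def make_category_phantom(noise_sd: float | None = None, seed: int = 0,
                          target_peak_snr: float = 20.0) -> PhantomSpec:
    """Canonical phantom whose zones realise the error-category repertoire.

    Zones (32x32x3 grid): a GOOD band; two moderate-uptake bands whose ve
    inflates past 1 only when fitting with a shrunken AIF (VE_GE_ONE
    mechanism); a no-uptake core (GD_TOO_SMALL); a deterministic
    high-variance band (GD_SD_TOO_BIG); and an extreme-rate band
    (PARAM_TOO_LARGE).  With the generation AIF the ve bands fit cleanly.

    ``noise_sd=None`` selects the design noise level: Gaussian signal noise
    with s.d. equal to the peak enhanced GOOD-zone signal divided by
    ``target_peak_snr``.  Pass 0.0 for a noiseless phantom.
    """
    zones = (
        Zone("good", (2, 12), (2, 24), _GOOD),
        Zone("ve_inflate_a", (12, 15), (2, 24), _VE_A),
        Zone("ve_inflate_b", (15, 17), (2, 24), _VE_B),
        # fluid-rich necrotic core: long T1, high proton density.  The
        # higher signal gain keeps the 0.01 mM mean-[Gd] check well clear
        # of the conversion noise floor at design noise.
        Zone("no_uptake", (17, 21), (2, 24), None, kind="no_uptake",
             t10=2000.0, m0_scale=2.0),
        Zone("noise_burst", (21, 25), (2, 24), _GOOD, kind="noise_burst",
             m0_scale=2.0),
        Zone("hot", (25, 30), (2, 24), _HOT),
    )
    spec = PhantomSpec(zones=zones, seed=seed, noise_sd=0.0)
    if noise_sd is None:
        acq = spec.acq
        ct = etm_forward(_GOOD, model_aif(spec.aif_params, spec.dose,
                                          acq.frame_times, onset=spec.bolus_arrival),
                         acq.frame_times)
        peak = float(_spgr_dynamic(ct, zones[0].t10, spec.m0, acq, spec.r1).max())
        noise_sd = peak / target_peak_snr
    return replace(spec, noise_sd=float(noise_sd))
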