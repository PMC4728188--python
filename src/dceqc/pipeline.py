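"""End-to-end analysis: MFA T1 mapping, concentration conversion, AIF
selection, voxelwise extended Tofts fitting and error-category mapping."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aif import ArterialInputFunction, measure_individual_aif, model_aif
from .config import PipelineConfig
from .errormap import ErrorCategoryMap, build_error_map
from .signal import ConcentrationSeries, T1Map, fit_t1_volume, signal_to_concentration
from .tofts import VolumeFitResults, fit_volume

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced for one dynamic series."""

    t1map: T1Map
    conc: ConcentrationSeries
    aif: ArterialInputFunction
    fits: VolumeFitResults
    error_map: ErrorCategoryMap

    def summary(self) -> str:
        return self.fits.summary()


def select_aif(config: PipelineConfig, times, series=None, artery_mask=None,
               t1map: T1Map | None = None, r1: float | None = None,
               aif_override: ArterialInputFunction | None = None,
               acq=None) -> ArterialInputFunction:
    """Build the AIF named by the config (or use the supplied override).

    ``average`` form requires an override (a pre-computed sample-average
    AIF), since averaging needs AIFs from several visits.
    """
    if aif_override is not None:
        return aif_override
    form = config.aif.form
    if form == "model":
        return model_aif(config.aif.model.to_params(), config.dose, times,
                         onset=config.aif.onset)
    if form == "individual":
        if series is None or artery_mask is None:
            raise ValueError("individual AIF needs the series and artery mask")
        t10_blood = config.aif.t10_blood
        if t10_blood is None:
            if t1map is None:
                raise ValueError("individual AIF needs a T1 map or aif.t10_blood")
            inside = t1map.t1[artery_mask & t1map.fit_ok]
            if inside.size == 0:
                raise ValueError("no valid T1 fits inside the artery mask")
            t10_blood = float(np.median(inside))
        return measure_individual_aif(
            series, artery_mask, t10_blood, acq, r1,
            hematocrit=config.hematocrit, times=times,
            baseline_frames=config.baseline_frames)
    raise ValueError("sample-average AIF must be supplied via aif_override")


def run_pipeline(dynamic, times, acq, mfa_stack, mfa_angles, tumour_mask,
                 artery_mask=None, config: PipelineConfig | None = None,
                 aif_override: ArterialInputFunction | None = None) -> PipelineResult:
    """Run the full voxelwise analysis.

    Parameters
    ----------
    dynamic : ndarray (x, y, z, t) signal series.
    times : frame times, s.
    acq : AcquisitionParams of the dynamic series.
    mfa_stack : ndarray (x, y, z, n_angles) multi-flip-angle signals.
    tumour_mask, artery_mask : boolean volumes.
    aif_override : use this AIF instead of the configured form.
    """
    config = config or PipelineConfig()
    tumour_mask = np.asarray(tumour_mask).astype(bool)
    fit_region = tumour_mask.copy()
    if artery_mask is not None:
        fit_region |= np.asarray(artery_mask).astype(bool)

    t1map = fit_t1_volume(mfa_stack, mfa_angles, acq.tr, mask=fit_region,
                          t1_max=config.t1_max)
    t10 = np.where(t1map.fit_ok, t1map.t1, np.nan)

    aif = select_aif(config, times, series=dynamic, artery_mask=artery_mask,
                     t1map=t1map, r1=config.r1, aif_override=aif_override,
                     acq=acq)

    conc = signal_to_concentration(dynamic, t10, acq, config.r1,
                                   baseline_frames=config.baseline_frames)
    fits = fit_volume(conc, tumour_mask, aif, times,
                      ctrl=config.solver.to_controls(),
                      thresholds=config.thresholds.to_thresholds())
    emap = build_error_map(fits.categories, tumour_mask,
                           palette=_palette_from_config(config))
    return PipelineResult(t1map=t1map, conc=conc, aif=aif, fits=fits,
                          error_map=emap)


def _palette_from_config(config: PipelineConfig):
    from .errormap import DEFAULT_PALETTE, ErrorCategory

    if config.palette is None:
        return DEFAULT_PALETTE
    pal = dict(DEFAULT_PALETTE)
    for name, colour in config.palette.items():
        pal[ErrorCategory[name]] = tuple(colour)
    return pal
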