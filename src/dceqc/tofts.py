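"""Extended Tofts model: forward evaluation and voxelwise non-linear fitting.

The tissue gadolinium concentration is modelled as

    Ct(t) = vp * Cp(t) + Ktrans * int_0^t Cp(u) exp(-kep (t - u)) du,
    kep = Ktrans / ve

with Ktrans (min^-1) the transfer constant, ve the fractional extravascular
extracellular volume, vp the fractional plasma volume and Cp(t) the arterial
plasma concentration (the AIF).  Times are seconds at the interface and
minutes inside the model so that Ktrans and kep carry their conventional
units.

The convolution integral is evaluated by an exact recursion that treats Cp
as piecewise-linear between samples — accurate at a few seconds' temporal
resolution, unlike a naive trapezoid on the convolution kernel.

Fitting follows the statsmodels convention: :class:`ExtendedToftsModel`
wraps one voxel's data and ``fit()`` returns an
:class:`ExtendedToftsResults` with estimates, standard errors, convergence
diagnostics and a ``summary()`` table.  Convergence is recorded as formal
(gradient) convergence or, failing that, the relative step size or relative
change in residuals falling below the tolerance; iterations are capped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .aif import ArterialInputFunction

__all__ = [
    "PKParams",
    "SolverControls",
    "ExtendedToftsModel",
    "ExtendedToftsResults",
    "etm_forward",
    "fit_etm",
    "fit_volume",
    "PKParameterMap",
    "VolumeFitResults",
]

_VE_FLOOR = 1e-9


@dataclass(frozen=True)
class PKParams:
    """Extended Tofts parameters: Ktrans (min^-1), ve and vp (fractions)."""

    ktrans: float
    ve: float
    vp: float

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError("ktrans must be non-negative")

    @property
    def kep(self) -> float:
        """Efflux rate constant Ktrans/ve, min^-1 (0 when Ktrans is 0)."""
        if self.ktrans == 0:
            return 0.0
        if self.ve <= 0:
            raise ValueError("ve must be positive when ktrans > 0")
        return self.ktrans / self.ve

    def as_array(self) -> np.ndarray:
        return np.array([self.ktrans, self.ve, self.vp])


@dataclass(frozen=True)
class SolverControls:
    """Non-linear least squares controls.

    ``rel_tol`` is applied to both the relative step size and the relative
    change in residuals; ``max_iter`` caps the iteration count.
    """

    rel_tol: float = 1e-6
    max_iter: int = 100
    gtol: float = 1e-8


def _exp_convolve(cp: np.ndarray, t_min: np.ndarray, kep: float) -> np.ndarray:
    """int_0^t Cp(u) exp(-kep (t-u)) du for piecewise-linear Cp, t in minutes."""
    n = t_min.size
    if n == 0:
        return np.zeros(0)
    dt = np.diff(t_min)
    c0, c1 = cp[:-1], cp[1:]
    kdt = kep * dt
    e = np.exp(-kdt)
    small = kdt < 1e-5
    with np.errstate(divide="ignore", invalid="ignore"):
        # g1 = (1 - e)/kep ; g2 = dt/kep - (1 - e)/kep**2   (per interval)
        g1 = np.where(small, dt * (1 - kdt / 2 + kdt**2 / 6), -np.expm1(-kdt) / max(kep, 1e-300))
        g2 = np.where(
            small,
            dt**2 * (0.5 - kdt / 3 + kdt**2 / 8),
            (kdt + np.expm1(-kdt)) / max(kep, 1e-300) ** 2,
        )
    # contribution of interval i to I at its right edge
    j = c0 * g1 + np.where(dt > 0, (c1 - c0) / np.where(dt > 0, dt, 1.0), 0.0) * g2
    out = np.empty(n)
    out[0] = 0.0
    if np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
        # uniform grid: I_i = e*I_{i-1} + j_i  is a first-order IIR filter
        out[1:] = lfilter([1.0], [1.0, -float(e[0])], j)
        # lfilter assumes zero initial state, which matches I_0 = 0
    else:
        acc = 0.0
        for i in range(n - 1):
            acc = acc * e[i] + j[i]
            out[i + 1] = acc
    return out


def etm_forward(params: PKParams, aif: ArterialInputFunction, times) -> np.ndarray:
    """Evaluate the extended Tofts model at ``times`` (seconds).

    Returns the tissue concentration trace in mM.  Raises if ve <= 0 while
    ktrans > 0 (kep undefined).
    """
    times = np.asarray(times, dtype=float)
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if params.ktrans > 0 and params.ve <= 0:
        raise ValueError("ve must be positive when ktrans > 0")
    cp = aif.interp(times)
    return _etm_eval(params.ktrans, params.ve, params.vp, cp, times / 60.0)


def _etm_eval(ktrans, ve, vp, cp, t_min):
    if ktrans == 0:
        return vp * cp
    kep = ktrans / max(ve, _VE_FLOOR)
    return vp * cp + ktrans * _exp_convolve(cp, t_min, kep)


_REASONS = {0: "max_iter", 1: "formal", 2: "residual_tol", 3: "step_tol", 4: "step_tol"}
_CONVERGED = {"formal", "residual_tol", "step_tol"}


class ExtendedToftsModel:
    """Extended Tofts model for one voxel's concentration trace.

    Parameters
    ----------
    ct : array_like
        Tissue concentration, mM, finite, at least 10 frames.
    times : array_like
        Frame times, seconds, strictly increasing.
    aif : ArterialInputFunction
        Arterial plasma concentration driving the model.
    """

    param_names = ("ktrans", "ve", "vp")

    def __init__(self, ct, times, aif: ArterialInputFunction):
        self.ct = np.asarray(ct, dtype=float)
        self.times = np.asarray(times, dtype=float)
        if self.ct.shape != self.times.shape:
            raise ValueError("ct and times must have the same shape")
        if self.ct.size < 10:
            raise ValueError("at least 10 frames are required")
        if not np.all(np.isfinite(self.ct)):
            raise ValueError("ct must be finite")
        self.aif = aif
        self._cp = aif.interp(self.times)
        self._t_min = self.times / 60.0

    def predict(self, params: PKParams) -> np.ndarray:
        return _etm_eval(params.ktrans, params.ve, params.vp, self._cp, self._t_min)

    def _residual(self, x):
        return _etm_eval(x[0], x[1], x[2], self._cp, self._t_min) - self.ct

    def fit(self, init: PKParams | None = None,
            ctrl: SolverControls | None = None) -> "ExtendedToftsResults":
        """Fit (Ktrans, ve, vp) by trust-region reflective least squares.

        All three parameters are bounded below by zero and unbounded above,
        so that non-physical estimates (ve >= 1, extreme Ktrans) are
        *reported* rather than clipped — downstream categorisation acts on
        them.
        """
        init = init or PKParams(ktrans=0.1, ve=0.2, vp=0.01)
        ctrl = ctrl or SolverControls()
        x0 = np.clip(init.as_array(), 1e-12, None)
        try:
            sol = least_squares(
                self._residual,
                x0=x0,
                bounds=(np.zeros(3), np.full(3, np.inf)),
                method="trf",
                xtol=ctrl.rel_tol,
                ftol=ctrl.rel_tol,
                gtol=ctrl.gtol,
                max_nfev=ctrl.max_iter * 4,
            )
        except Exception:
            return ExtendedToftsResults(
                model=self, params=init, converged=False,
                convergence_reason="failed", n_iter=0,
                residual_norm=np.nan, initial_guess=init, bse=None)
        params = PKParams(ktrans=float(sol.x[0]), ve=float(sol.x[1]), vp=float(sol.x[2]))
        reason = _REASONS.get(sol.status, "failed")
        resid = sol.fun
        bse = self._standard_errors(sol)
        return ExtendedToftsResults(
            model=self, params=params, converged=reason in _CONVERGED,
            convergence_reason=reason, n_iter=int(sol.njev),
            residual_norm=float(np.linalg.norm(resid)), initial_guess=init, bse=bse)

    def _standard_errors(self, sol):
        dof = self.ct.size - 3
        if dof <= 0:
            return None
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.pinv(jtj) * (2 * sol.cost / dof)
            return np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except Exception:
            return None


@dataclass
class ExtendedToftsResults:
    """Fit results for one voxel: estimates, uncertainty and diagnostics.

    ``converged`` is True iff ``convergence_reason`` is one of
    {"formal", "step_tol", "residual_tol"}; "max_iter" and "failed" are
    non-convergent outcomes.  ``residual_norm`` is in mM.
    """

    model: ExtendedToftsModel | None
    params: PKParams
    converged: bool
    convergence_reason: str
    n_iter: int
    residual_norm: float
    initial_guess: PKParams
    bse: np.ndarray | None = None

    @property
    def kep(self) -> float:
        p = self.params
        if p.ktrans == 0 or p.ve <= 0:
            return 0.0 if p.ktrans == 0 else np.inf
        return p.ktrans / p.ve

    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params)

    def summary(self) -> str:
        p = self.params
        bse = self.bse if self.bse is not None else [np.nan] * 3
        lines = [
            "Extended Tofts model fit",
            "========================",
            f"{'param':<8}{'estimate':>12}{'std err':>12}",
            f"{'Ktrans':<8}{p.ktrans:>12.5f}{bse[0]:>12.5f}   (min^-1)",
            f"{'ve':<8}{p.ve:>12.5f}{bse[1]:>12.5f}",
            f"{'vp':<8}{p.vp:>12.5f}{bse[2]:>12.5f}",
            f"{'kep':<8}{self.kep:>12.5f}{'':>12}   (min^-1, = Ktrans/ve)",
            "------------------------",
            f"converged: {self.converged} ({self.convergence_reason}), "
            f"iterations: {self.n_iter}, residual norm: {self.residual_norm:.3e} mM",
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Plot data and fitted curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.times, self.model.ct, ".", label="data")
        ax.plot(self.model.times, self.fittedvalues(), "-", label="eTM fit")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("[Gd] (mM)")
        ax.legend()
        return ax


def fit_etm(ct, aif: ArterialInputFunction, times, init: PKParams | None = None,
            ctrl: SolverControls | None = None) -> ExtendedToftsResults:
    """Functional wrapper: fit the extended Tofts model to one trace."""
    return ExtendedToftsModel(ct, times, aif).fit(init=init, ctrl=ctrl)


@dataclass
class PKParameterMap:
    """Voxelwise parameter maps (NaN where a voxel was not fitted)."""

    ktrans: np.ndarray
    ve: np.ndarray
    vp: np.ndarray
    kep: np.ndarray

    def as_dict(self) -> dict:
        return {"ktrans": self.ktrans, "ve": self.ve, "vp": self.vp, "kep": self.kep}


@dataclass
class VolumeFitResults:
    """Voxelwise fit of a masked volume: maps, categories and a fit table.

    ``categories`` uses the error-category integer codes (OUTSIDE outside the
    mask); ``table`` has one row per masked voxel with the estimates and
    convergence diagnostics.
    """

    maps: PKParameterMap
    categories: np.ndarray
    table: pd.DataFrame
    mask: np.ndarray

    def summary(self) -> str:
        from .errormap import category_tally

        tally = category_tally(self.categories, self.mask)
        n = int(self.mask.sum())
        lines = ["Voxelwise extended Tofts fit", "============================",
                 f"masked voxels: {n}"]
        for name, count in tally.items():
            lines.append(f"  {name:<16}{count:>7}  ({100 * count / n:5.1f} %)")
        good = self.table[self.table.category == "GOOD"]
        if len(good):
            lines.append(f"median Ktrans (GOOD voxels): {good.ktrans.median():.4f} min^-1")
        return "\n".join(lines)


def fit_volume(conc, mask, aif: ArterialInputFunction, times,
               ctrl: SolverControls | None = None, thresholds=None,
               baseline_frames: int | None = None) -> VolumeFitResults:
    """Fit the extended Tofts model to every masked voxel with QC checks.

    Pre-fit reliability checks (concentration s.d., non-real conversion,
    mean concentration) are applied first; voxels failing them are not
    fitted and carry null parameters plus their category.  Surviving voxels
    are fitted and post-fit checks assign the final category.

    Parameters
    ----------
    conc : ConcentrationSeries
        Voxelwise concentration volume, time last axis.
    mask : ndarray of bool
        Tumour ROI; must lie within the grid.
    """
    from .errormap import CheckThresholds, categorize_voxel, OUTSIDE, ErrorCategory

    thr = thresholds or CheckThresholds()
    ctrl = ctrl or SolverControls(rel_tol=thr.rel_tol, max_iter=thr.max_iter)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != conc.conc.shape[:-1]:
        raise ValueError("mask grid does not match the concentration volume")
    if not mask.any():
        raise ValueError("mask is empty")
    bf = conc.baseline_frames if baseline_frames is None else baseline_frames

    spatial = mask.shape
    cat = np.full(spatial, OUTSIDE, dtype=np.int16)
    maps = {k: np.full(spatial, np.nan) for k in ("ktrans", "ve", "vp", "kep")}
    rows = []
    times = np.asarray(times, dtype=float)

    for idx in zip(*np.nonzero(mask)):
        trace = conc.conc[idx]
        valid = conc.valid[idx]
        pre = categorize_voxel(trace, valid, fit=None, thr=thr, prefit_only=True,
                               baseline_frames=bf)
        fit = None
        if pre is None:  # pre-fit checks passed -> fit
            ct = np.where(valid, trace, 0.0)
            fit = ExtendedToftsModel(ct, times, aif).fit(ctrl=ctrl)
            maps["ktrans"][idx] = fit.params.ktrans
            maps["ve"][idx] = fit.params.ve
            maps["vp"][idx] = fit.params.vp
            maps["kep"][idx] = fit.kep
        category = categorize_voxel(trace, valid, fit=fit, thr=thr,
                                    baseline_frames=bf)
        cat[idx] = int(category)
        rows.append({
            "i": idx[0], "j": idx[1], "k": idx[2] if len(idx) > 2 else 0,
            "ktrans": fit.params.ktrans if fit else np.nan,
            "ve": fit.params.ve if fit else np.nan,
            "vp": fit.params.vp if fit else np.nan,
            "kep": fit.kep if fit else np.nan,
            "convergence_reason": fit.convergence_reason if fit else "",
            "n_iter": fit.n_iter if fit else 0,
            "residual_norm": fit.residual_norm if fit else np.nan,
            "category": ErrorCategory(int(category)).name,
        })
    table = pd.DataFrame(rows)
    return VolumeFitResults(maps=PKParameterMap(**maps), categories=cat,
                            table=table, mask=mask)
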