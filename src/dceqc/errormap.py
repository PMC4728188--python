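"""Ordered per-voxel reliability checks, error-category maps and
category-based masking.

In fitting the tracer-kinetic model to each voxel, a battery of checks is
applied *strictly in order*, and the voxel is labelled with the first check
it fails (or GOOD if none):

1. s.d. of the [Gd] trace >= ``gd_sd_max``          -> GD_SD_TOO_BIG
2. any non-real concentration value                 -> GD_NOT_REAL
3. mean [Gd] <= ``gd_mean_min``                     -> GD_TOO_SMALL
4. curve fit did not converge                       -> NON_CONVERGENCE
5. ve >= ``ve_limit``                               -> VE_GE_ONE
6. vp >= ``vp_limit``                               -> VP_GE_ONE
7. Ktrans > ``ktrans_max`` or kep > ``kep_max``     -> PARAM_TOO_LARGE

Checks 1-3 are pre-fit (a failing voxel is never fitted); 4-7 act on the
fit result.  The per-voxel codes form a colour-coded *error-category map*
used both as an at-a-glance quality-control image and as a mask for
histogram extraction from the parameter maps: by default GOOD and
GD_TOO_SMALL voxels are accepted, the latter contributing Ktrans = 0
(no uptake is a valid perfusion outcome).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "ErrorCategory",
    "OUTSIDE",
    "CheckThresholds",
    "DEFAULT_PALETTE",
    "categorize_voxel",
    "build_error_map",
    "ErrorCategoryMap",
    "mask_from_categories",
    "histogram_values",
    "category_report",
    "category_tally",
]


class ErrorCategory(IntEnum):
    """Per-voxel outcome of the ordered reliability checks."""

    GOOD = 0
    GD_SD_TOO_BIG = 1
    GD_NOT_REAL = 2
    GD_TOO_SMALL = 3
    NON_CONVERGENCE = 4
    VE_GE_ONE = 5
    VP_GE_ONE = 6
    PARAM_TOO_LARGE = 7


#: Sentinel code for voxels outside the ROI (never a category).
OUTSIDE = -1

#: Display colours.  Black/cyan/red/magenta/green follow the published
#: convention (VE_GE_ONE and VP_GE_ONE share green, as the maps merge them);
#: GD_NOT_REAL (yellow) and PARAM_TOO_LARGE (blue) have no published colour.
DEFAULT_PALETTE: dict[ErrorCategory, tuple[int, int, int]] = {
    ErrorCategory.GOOD: (0, 0, 0),
    ErrorCategory.GD_SD_TOO_BIG: (0, 255, 255),
    ErrorCategory.GD_NOT_REAL: (255, 255, 0),
    ErrorCategory.GD_TOO_SMALL: (255, 0, 0),
    ErrorCategory.NON_CONVERGENCE: (255, 0, 255),
    ErrorCategory.VE_GE_ONE: (0, 255, 0),
    ErrorCategory.VP_GE_ONE: (0, 255, 0),
    ErrorCategory.PARAM_TOO_LARGE: (0, 0, 255),
}

#: Default render colour for out-of-ROI voxels.
OUTSIDE_COLOUR = (255, 255, 255)


@dataclass(frozen=True)
class CheckThresholds:
    """Thresholds of the ordered check battery.

    Defaults: s.d. limit 5 mM, mean-[Gd] floor 0.01 mM, Ktrans limit
    10 min^-1, kep limit 15 min^-1, ve/vp limit 1, relative fit tolerance
    1e-6, 100 iterations.  ``post_pre_var_ratio_max`` enables an optional
    alternative noise test comparing post- to pre-bolus variance; it is off
    (None) by default.
    """

    gd_sd_max: float = 5.0
    gd_mean_min: float = 0.01
    ktrans_max: float = 10.0
    kep_max: float = 15.0
    ve_limit: float = 1.0
    vp_limit: float = 1.0
    rel_tol: float = 1e-6
    max_iter: int = 100
    post_pre_var_ratio_max: float | None = None

    def __post_init__(self) -> None:
        for name in ("gd_sd_max", "gd_mean_min", "ktrans_max", "kep_max",
                     "ve_limit", "vp_limit", "rel_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.max_iter <= 0:
            raise ValueError("max_iter must be strictly positive")


def categorize_voxel(conc, valid, fit, thr: CheckThresholds,
                     prefit_only: bool = False,
                     baseline_frames: int = 10) -> ErrorCategory | None:
    """Assign the error category for one voxel's trace and (optional) fit.

    Checks run strictly in order; the first failure wins.  With
    ``prefit_only=True`` only checks 1-3 (and the optional variance-ratio
    test) run, returning ``None`` if all pass — the caller then fits the
    voxel and calls again with the fit result.

    Raises ``RuntimeError`` if the pre-fit checks pass but no fit is
    supplied (contract violation).
    """
    conc = np.asarray(conc, dtype=float)
    valid = np.asarray(valid).astype(bool)
    finite = conc[valid]

    # 1. unreasonably variable [Gd]
    if finite.size >= 2 and np.std(finite) >= thr.gd_sd_max:
        return ErrorCategory.GD_SD_TOO_BIG
    # 2. non-real conversion in any frame
    if not valid.all():
        return ErrorCategory.GD_NOT_REAL
    # 3. no discernible uptake
    if finite.size == 0 or np.mean(finite) <= thr.gd_mean_min:
        return ErrorCategory.GD_TOO_SMALL
    # optional alternative noise test (off by default)
    if thr.post_pre_var_ratio_max is not None and baseline_frames >= 2:
        pre = np.var(conc[:baseline_frames])
        post = np.var(conc[baseline_frames:])
        if pre > 0 and post / pre >= thr.post_pre_var_ratio_max:
            return ErrorCategory.GD_SD_TOO_BIG

    if prefit_only:
        return None
    if fit is None:
        raise RuntimeError("pre-fit checks passed but no fit result was supplied")

    # 4. non-convergence of the curve fit
    if not fit.converged:
        return ErrorCategory.NON_CONVERGENCE
    p = fit.params
    # 5./6. non-physical fractional volumes
    if p.ve >= thr.ve_limit:
        return ErrorCategory.VE_GE_ONE
    if p.vp >= thr.vp_limit:
        return ErrorCategory.VP_GE_ONE
    # 7. unreasonably large rate constants
    kep = fit.kep if hasattr(fit, "kep") else (p.ktrans / p.ve if p.ve > 0 else 0.0)
    if p.ktrans > thr.ktrans_max or kep > thr.kep_max:
        return ErrorCategory.PARAM_TOO_LARGE
    return ErrorCategory.GOOD


def category_tally(categories: np.ndarray, mask: np.ndarray) -> dict[str, int]:
    """Count voxels per category inside the mask."""
    inside = categories[np.asarray(mask).astype(bool)]
    return {c.name: int((inside == c).sum()) for c in ErrorCategory}


@dataclass
class ErrorCategoryMap:
    """Integer-coded category volume with rendering and tallying.

    ``categories`` holds an :class:`ErrorCategory` code per masked voxel and
    the OUTSIDE sentinel elsewhere; the tally always sums to the masked
    voxel count.
    """

    categories: np.ndarray
    mask: np.ndarray
    palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    outside_colour: tuple = OUTSIDE_COLOUR

    @property
    def tally(self) -> dict[str, int]:
        return category_tally(self.categories, self.mask)

    def render_slice(self, k: int) -> np.ndarray:
        """Render axial slice ``k`` as an RGB uint8 image."""
        sl = self.categories[:, :, k]
        rgb = np.empty(sl.shape + (3,), dtype=np.uint8)
        rgb[...] = self.outside_colour
        for cat, colour in self.palette.items():
            rgb[sl == int(cat)] = colour
        return rgb

    def save_slices_png(self, out_dir, prefix: str = "error_map", scale: int = 8):
        """Write one PNG per axial slice; returns the written paths."""
        from pathlib import Path

        from PIL import Image

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for k in range(self.categories.shape[2]):
            img = Image.fromarray(self.render_slice(k)).resize(
                (self.categories.shape[1] * scale, self.categories.shape[0] * scale),
                Image.NEAREST)
            p = out_dir / f"{prefix}_z{k:02d}.png"
            img.save(p)
            paths.append(p)
        return paths


def build_error_map(categories: np.ndarray, mask: np.ndarray,
                    palette: dict | None = None) -> ErrorCategoryMap:
    """Assemble an :class:`ErrorCategoryMap` from per-voxel codes.

    Every masked voxel must carry a valid category code; voxels outside the
    mask are forced to the OUTSIDE sentinel.
    """
    categories = np.asarray(categories)
    mask = np.asarray(mask).astype(bool)
    if categories.shape != mask.shape:
        raise ValueError("categories and mask grids differ")
    codes = {int(c) for c in ErrorCategory}
    inside = categories[mask]
    if not set(np.unique(inside)).issubset(codes):
        raise ValueError("uncategorized or invalid code inside the mask")
    out = np.where(mask, categories, OUTSIDE).astype(np.int16)
    return ErrorCategoryMap(categories=out, mask=mask,
                            palette=dict(palette or DEFAULT_PALETTE))


DEFAULT_ACCEPTED = frozenset({ErrorCategory.GOOD, ErrorCategory.GD_TOO_SMALL})


def mask_from_categories(error_map: ErrorCategoryMap,
                         accepted=DEFAULT_ACCEPTED) -> np.ndarray:
    """Binary volume: True exactly where the category is in ``accepted``.

    The default accepts GOOD plus GD_TOO_SMALL — model convergence and
    no-discernible-uptake voxels combined give the 'valid tumour voxels'
    used for histogram assessment.
    """
    accepted = set(accepted)
    if not accepted:
        raise ValueError("accepted must be non-empty")
    out = np.zeros(error_map.categories.shape, dtype=bool)
    for cat in accepted:
        out |= error_map.categories == int(cat)
    return out


def histogram_values(param_map: np.ndarray, error_map: ErrorCategoryMap,
                     accepted=DEFAULT_ACCEPTED) -> np.ndarray:
    """Extract parameter values over the accepted-category mask.

    GD_TOO_SMALL voxels contribute 0 (no uptake is a valid perfusion
    outcome, Ktrans = 0) even though they were never fitted.
    """
    sel = mask_from_categories(error_map, accepted)
    vals = np.where(error_map.categories == int(ErrorCategory.GD_TOO_SMALL),
                    0.0, param_map)
    return vals[sel]


def category_report(maps: dict[str, ErrorCategoryMap]) -> pd.DataFrame:
    """Tabulate category counts and fractions across several maps.

    All maps must share the grid and mask (e.g. one per visit or per AIF
    form).  Returns a DataFrame indexed by map name with per-category counts,
    a ``total`` column, and fraction columns; pairwise count differences from
    the first map are appended as ``diff_<name>`` rows.
    """
    items = list(maps.items())
    if len(items) < 2:
        raise ValueError("at least 2 maps are required")
    ref_name, ref = items[0]
    for name, m in items[1:]:
        if m.categories.shape != ref.categories.shape or not np.array_equal(m.mask, ref.mask):
            raise ValueError(f"map {name!r} grid/mask differs from {ref_name!r}")
    rows = {}
    for name, m in items:
        t = m.tally
        t["total"] = int(m.mask.sum())
        rows[name] = t
    df = pd.DataFrame(rows).T
    for c in ErrorCategory:
        df[f"frac_{c.name}"] = df[c.name] / df["total"]
    for name, _ in items[1:]:
        df.loc[f"diff_{name}"] = df.loc[name] - df.loc[ref_name]
    return df
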