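"""Canopy photosynthetic saturation metrics.

Reduces per-leaf incident PAR to canopy-scale descriptors: the instantaneous
area-weighted percentage of leaf area at or above the saturating irradiance
E_k; its diurnal time integral H^A_sat (% leaf area x hour, ceiling 1200 for
a 12-hour day); the top-of-canopy H_sat (hours above E_k); distribution
histograms; wave-treatment statistics; H^A_sat surfaces over the LAI x
shading grid with isoclines; and equivalence queries along isoclines
(equivalent unshaded LAI, shading-shift sensitivity between surfaces).

The "at or above" comparison is inclusive (>= E_k); leaf saturation uses the
sum of both face incidences (thin two-sided photosynthetic leaves).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import RegularGridInterpolator
from skimage import measure

from .radiosity import LeafIrradianceField

HASAT_CEILING = 1200.0
DEFAULT_ISOCLINE_LEVELS = (50.0, 100.0, 200.0, 300.0, 400.0,
                           500.0, 600.0, 700.0, 800.0)


@dataclass(frozen=True)
class Ek:
    """Leaf-level saturating irradiance, umol quanta m^-2 s^-1.

    The plausible physiological band for the modelled species is 45-55 with
    midpoint 50.
    """

    value: float = 50.0

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("E_k must be positive")


@dataclass
class SaturationSeries:
    """Hourly % leaf area >= E_k and top-of-canopy PAR through a day."""

    hours: np.ndarray
    sat_fraction: np.ndarray      # percent of leaf area, per time point
    toc_par: np.ndarray           # umol quanta m^-2 s^-1, per time point

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype=float)
        self.sat_fraction = np.asarray(self.sat_fraction, dtype=float)
        self.toc_par = np.asarray(self.toc_par, dtype=float)
        if np.any(self.sat_fraction < -1e-9) or np.any(self.sat_fraction > 100 + 1e-9):
            raise ValueError("saturated fractions must lie in [0, 100]")


@dataclass
class HAsatSurface:
    """H^A_sat gridded over LAI x shading (%) for one E_k and wave mode."""

    lai_values: np.ndarray
    shading_values: np.ndarray    # percent
    values: np.ndarray            # (n_lai, n_shading), % leaf area x hour
    ek: Ek
    wave_mode: str = "low"
    sd: np.ndarray | None = None  # per-cell SD across movement snapshots

    def __post_init__(self) -> None:
        self.lai_values = np.asarray(self.lai_values, dtype=float)
        self.shading_values = np.asarray(self.shading_values, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.lai_values.size, self.shading_values.size):
            raise ValueError("surface shape does not match grid axes")

    def interpolate(self, lai: float, shading: float) -> float:
        interp = RegularGridInterpolator(
            (self.lai_values, self.shading_values), self.values,
            method="linear", bounds_error=True)
        return float(interp([[lai, shading]])[0])


def saturated_fraction(field: LeafIrradianceField, ek: Ek) -> float:
    """Area-weighted percent of leaf area irradiated at or above E_k."""
    if field.areas.size == 0 or field.total_area <= 0:
        raise ValueError("leaf field has zero leaf area")
    sat = field.areas[field.par >= ek.value].sum()
    return float(100.0 * sat / field.total_area)


def leaf_par_histogram(
    field: LeafIrradianceField, bin_edges: np.ndarray
) -> np.ndarray:
    """Area-fraction (%) distribution of leaf PAR over given bins.

    Fractions sum to 100 when the bins cover the observed range; the E_k
    markers conventionally plotted alongside sit at 45 and 55.
    """
    edges = np.asarray(bin_edges, dtype=float)
    h, _ = np.histogram(field.par, bins=edges, weights=field.areas)
    return 100.0 * h / field.total_area


def hasat(series: SaturationSeries) -> float:
    """Time integral of % leaf area above saturation, % leaf area x hour.

    Rectangle rule with 1-hour widths over the hourly daylight samples;
    night contributes zero, so a fully saturated 12-point day gives 1200.
    """
    return float(series.sat_fraction.sum())


def hsat_top(series: SaturationSeries, ek: Ek) -> float:
    """Hours of top-of-canopy irradiance at or above E_k (1-hour samples)."""
    return float(np.count_nonzero(series.toc_par >= ek.value))


def wave_average(values) -> tuple[float, float]:
    """Unweighted mean and sample SD across movement-snapshot results."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no snapshot values")
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else 0.0
    return float(arr.mean()), sd


def compare_wave_treatments(low, high) -> tuple[float, float, float]:
    """Paired t-test of low vs high wave metrics across design cells.

    Returns (mean difference low-high, t statistic, p value).  With zero
    variance of the differences and nonzero mean the p value is the limit
    case 0.0.
    """
    a = np.asarray(low, dtype=float).ravel()
    b = np.asarray(high, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("need >= 2 paired values")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 0.0, 1.0
        return float(d.mean()), float(np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(d.mean()), float(t), float(p)


def build_hasat_surface(
    results: dict[tuple[float, float], float],
    lai_values,
    shading_values,
    ek: Ek,
    wave_mode: str = "low",
    sd: dict[tuple[float, float], float] | None = None,
    monotone_tol: float = 1e-9,
) -> HAsatSurface:
    """Assemble an H^A_sat surface from per-cell diurnal integrals.

    Requires a complete LAI x shading grid; asserts the physical double
    monotonicity (H^A_sat non-increasing with both LAI and shading) and the
    [0, 1200] range.
    """
    lai_values = np.asarray(sorted(lai_values), dtype=float)
    shading_values = np.asarray(sorted(shading_values), dtype=float)
    missing = [(l, s) for l in lai_values for s in shading_values
               if (l, s) not in results]
    if missing:
        raise ValueError(f"missing grid cells: {missing}")
    vals = np.array([[results[(l, s)] for s in shading_values]
                     for l in lai_values])
    if np.any(vals < -monotone_tol) or np.any(vals > HASAT_CEILING + monotone_tol):
        raise ValueError("H^A_sat outside [0, 1200]")
    if np.any(np.diff(vals, axis=0) > monotone_tol):
        raise ValueError("H^A_sat increases with LAI; surface not monotone")
    if np.any(np.diff(vals, axis=1) > monotone_tol):
        raise ValueError("H^A_sat increases with shading; surface not monotone")
    sd_arr = None
    if sd is not None:
        sd_arr = np.array([[sd[(l, s)] for s in shading_values]
                           for l in lai_values])
    return HAsatSurface(lai_values=lai_values, shading_values=shading_values,
                        values=vals, ek=ek, wave_mode=wave_mode, sd=sd_arr)


def extract_isoclines(
    surface: HAsatSurface, levels=DEFAULT_ISOCLINE_LEVELS
) -> dict[float, list[np.ndarray]]:
    """Contour polylines of constant H^A_sat in (LAI, shading) space.

    Marching squares on the bilinear surface; each returned polyline is an
    (n, 2) array of (LAI, shading %) points.  Levels outside the surface
    range yield empty lists; a constant surface is rejected as degenerate.
    """
    vals = surface.values
    if np.ptp(vals) < 1e-12:
        raise ValueError("constant surface: isoclines are degenerate")
    out: dict[float, list[np.ndarray]] = {}
    for level in levels:
        if not (vals.min() <= level <= vals.max()):
            out[float(level)] = []
            continue
        contours = measure.find_contours(vals, level)
        polys = []
        for c in contours:
            lai = np.interp(c[:, 0], np.arange(surface.lai_values.size),
                            surface.lai_values)
            sh = np.interp(c[:, 1], np.arange(surface.shading_values.size),
                           surface.shading_values)
            polys.append(np.column_stack([lai, sh]))
        out[float(level)] = polys
    return out


@dataclass(frozen=True)
class EquivalentLai:
    """Unshaded-LAI equivalence query result."""

    value: float
    extrapolated: bool


def equivalent_unshaded_lai(
    surface: HAsatSurface, lai: float, shading: float
) -> EquivalentLai:
    """LAI at zero shading lying on the same H^A_sat isocline as (lai, shading).

    Solves H(L, 0) = H(lai, shading) by monotone interpolation of the
    unshaded column; a target below the column minimum is answered by linear
    extrapolation of the last two grid points and flagged as such.
    """
    target = surface.interpolate(lai, shading)
    col = surface.values[:, int(np.argmin(surface.shading_values))]
    lais = surface.lai_values
    # column is non-increasing in LAI; invert by interpolation on reversed axis
    if target >= col[0]:
        return EquivalentLai(float(lais[0]), False)
    if target < col[-1]:
        # extrapolate beyond the densest canopy on the grid
        slope = (col[-1] - col[-2]) / (lais[-1] - lais[-2])
        if slope >= 0:
            return EquivalentLai(float("inf"), True)
        value = lais[-1] + (target - col[-1]) / slope
        return EquivalentLai(float(value), True)
    value = np.interp(-target, -col, lais)
    return EquivalentLai(float(value), False)


def shading_equivalence_error(
    a: HAsatSurface, b: HAsatSurface
) -> tuple[float, np.ndarray]:
    """Maximum shading-shift (percentage points) mapping surface B onto A.

    For each grid cell of A, finds the shading level at which B's same-LAI
    column reproduces A's value (monotone interpolation along the shading
    axis); returns (max |shift|, per-cell shift array with NaN where A's
    value lies outside B's column range).
    """
    if (a.lai_values.shape != b.lai_values.shape
            or not np.allclose(a.lai_values, b.lai_values)
            or not np.allclose(a.shading_values, b.shading_values)):
        raise ValueError("surfaces must share the same grid")
    shifts = np.full(a.values.shape, np.nan)
    sh = a.shading_values
    for i in range(a.lai_values.size):
        col_b = b.values[i]
        lo, hi = col_b.min(), col_b.max()
        for j in range(sh.size):
            va = a.values[i, j]
            if not (lo <= va <= hi):
                continue
            s_star = np.interp(-va, -col_b, sh)
            shifts[i, j] = s_star - sh[j]
    finite = shifts[np.isfinite(shifts)]
    max_shift = float(np.abs(finite).max()) if finite.size else float("nan")
    return max_shift, shifts
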