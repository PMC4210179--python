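"""Hourly spectral light field at the top of the canopy.

Pipeline: clear-sky two-component (direct beam + Rayleigh/aerosol diffuse)
spectral model -> air-water interface (Snell refraction, per-bin Fresnel
transmission) -> plane-parallel water column (per-direction beam attenuation
by a + b_b with an isotropised single-scattering diffuse source term) ->
spectrally neutral shading multiplier.

Everything in this module is linear in radiance.  The output is azimuthally
averaged by construction: radiance depends on zenith angle only, which removes
any dependence on sun azimuth or canopy orientation.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np

from .bands import DirectionalRadiance, SpectralBands, ZenithGrid

WATER_REFRACTIVE_INDEX = 1.34

# Representative pure-water absorption (m^-1) at the 17 band centres
# 410..730 nm (clear oceanic water literature values, resampled).
_PURE_WATER_A = np.array(
    [
        0.00473, 0.00495, 0.00922, 0.0106, 0.0150,  # 410 430 450 470 490
        0.0325, 0.0434, 0.0565, 0.0695, 0.1351,     # 510 530 550 570 590
        0.2644, 0.2916, 0.3400, 0.4390, 0.5160,     # 610 630 650 670 690
        0.8270, 1.7990,                              # 710 730
    ]
)


@dataclass
class WaterIOPs:
    """Spectral inherent optical properties of the water column.

    ``absorption`` and ``backscatter`` are per-band (m^-1) on the 17-band
    grid; ``depth`` is the site water depth in metres.
    """

    absorption: np.ndarray
    backscatter: np.ndarray
    depth: float = 4.5

    def __post_init__(self) -> None:
        self.absorption = np.asarray(self.absorption, dtype=float)
        self.backscatter = np.asarray(self.backscatter, dtype=float)
        if np.any(self.absorption < 0) or np.any(self.backscatter < 0):
            raise ValueError("IOPs must be non-negative")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")

    @classmethod
    def reference(cls, bands: SpectralBands | None = None, depth: float = 4.5) -> "WaterIOPs":
        """Packaged reference IOP set for a moderately clear coastal site.

        Pure-water absorption plus a CDOM/detritus exponential and a small
        particulate backscatter; the CDOM magnitude is set so the column
        yields k_d(PAR) of 0.20 m^-1 over 0-4.5 m under midday clear sky.
        """
        bands = bands or SpectralBands()
        lam = bands.centres
        a_cdom = 0.1253 * np.exp(-0.015 * (lam - 440.0))
        a = _PURE_WATER_A + a_cdom
        bb = 0.0008 * (550.0 / lam) ** 4.3 + 0.0035
        return cls(absorption=a, backscatter=bb, depth=depth)

    @classmethod
    def absorbing_only(cls, absorption, depth: float = 4.5) -> "WaterIOPs":
        a = np.asarray(absorption, dtype=float)
        return cls(absorption=a, backscatter=np.zeros_like(a), depth=depth)


@dataclass(frozen=True)
class ShadingLevel:
    """Spectrally and directionally neutral shading: multiplier (1 - fraction)."""

    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction < 1.0):
            raise ValueError(f"shading fraction {self.fraction} outside [0, 1)")


# ---------------------------------------------------------------------------
# Solar geometry (NOAA/Spencer ephemeris)
# ---------------------------------------------------------------------------

def _spencer_terms(day_of_year: int, hour: float) -> tuple[float, float]:
    """Return (declination rad, equation of time minutes)."""
    g = 2.0 * math.pi / 365.0 * (day_of_year - 1 + (hour - 12.0) / 24.0)
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    return decl, eqtime


def refract_zenith(air_zenith_deg: float) -> float:
    """In-water zenith angle from Snell's law with n = 1.34."""
    s = math.sin(math.radians(air_zenith_deg)) / WATER_REFRACTIVE_INDEX
    return math.degrees(math.asin(min(1.0, s)))


def solar_position(
    latitude: float,
    longitude: float,
    date: _dt.date,
    hour_local: float,
    utc_offset: float = 8.0,
) -> tuple[float, float]:
    """Solar zenith angle in air and in water (deg) for a local clock hour.

    Returns (air_zenith, in_water_zenith); air zenith may exceed 90 deg when
    the sun is below the horizon (the radiance generator then emits zero).
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude outside [-90, 90]")
    doy = date.timetuple().tm_yday
    decl, eqtime = _spencer_terms(doy, hour_local)
    time_offset = eqtime + 4.0 * longitude - 60.0 * utc_offset
    tst = hour_local * 60.0 + time_offset
    ha = math.radians(tst / 4.0 - 180.0)
    lat = math.radians(latitude)
    cosz = math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.cos(ha)
    air_z = math.degrees(math.acos(max(-1.0, min(1.0, cosz))))
    return air_z, refract_zenith(min(air_z, 89.999))


def diurnal_zeniths(
    latitude: float, date: _dt.date, n_hours: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """Air zenith angles at ``n_hours`` hour-centres spanning daylight.

    Hours are defined in apparent solar time with the day's declination held
    fixed, so pairs symmetric about solar noon have *exactly* equal zeniths
    (the diurnal-symmetry property the factorial driver exploits).  Returns
    (apparent solar hours, air zenith deg).
    """
    doy = date.timetuple().tm_yday
    decl, _ = _spencer_terms(doy, 12.0)
    lat = math.radians(latitude)
    x = -math.tan(lat) * math.tan(decl)
    if x >= 1.0:
        return np.array([]), np.array([])  # polar night
    ha0 = math.acos(max(-1.0, x))  # sunrise hour angle, rad
    k = np.arange(n_hours)
    ha = -ha0 + (k + 0.5) / n_hours * 2.0 * ha0
    cosz = math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * np.cos(ha)
    zen = np.degrees(np.arccos(np.clip(cosz, -1.0, 1.0)))
    hours = 12.0 + np.degrees(ha) / 15.0
    return hours, zen


# ---------------------------------------------------------------------------
# Clear-sky spectral model
# ---------------------------------------------------------------------------

def _planck_shape(lam_nm: np.ndarray, t_kelvin: float = 5778.0) -> np.ndarray:
    lam = lam_nm * 1e-9
    h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    b = 1.0 / (lam**5 * (np.exp(h * c / (lam * kb * t_kelvin)) - 1.0))
    return b / b.max()


def _extraterrestrial_band_irradiance(bands: SpectralBands) -> np.ndarray:
    """Normal-incidence extraterrestrial irradiance per band, W m^-2.

    A 5778 K Planck shape scaled so the 400-740 nm total is 530 W m^-2
    (about 39% of the solar constant), adequate for a model whose results
    are interpreted relatively rather than as absolute dose.
    """
    shape = _planck_shape(bands.centres) * bands.widths
    return shape / shape.sum() * 530.0


def _airmass(zenith_deg: float) -> float:
    z = min(zenith_deg, 89.9)
    return 1.0 / (
        math.cos(math.radians(z)) + 0.50572 * (96.07995 - z) ** -1.6364
    )


def clear_sky_radiance(
    air_zenith_deg: float,
    bands: SpectralBands | None = None,
    zgrid: ZenithGrid | None = None,
    aerosol_beta: float = 0.08,
) -> DirectionalRadiance:
    """Above-water clear-sky radiance distribution, azimuthally averaged.

    Direct beam (Rayleigh + Angstrom aerosol extinction) is placed in the
    zenith bin containing the solar zenith; half of the scattered flux is
    returned as isotropic diffuse skylight spread over all bins.  Sun below
    the horizon yields all-zero radiance.
    """
    bands = bands or SpectralBands()
    zgrid = zgrid or ZenithGrid()
    rad = np.zeros((zgrid.n_bins, bands.n))
    if air_zenith_deg >= 90.0:
        return DirectionalRadiance(bands, zgrid, rad)

    lam_um = bands.centres / 1000.0
    tau = 0.008735 * lam_um**-4.08 + aerosol_beta * lam_um**-1.3
    m = _airmass(air_zenith_deg)
    e0 = _extraterrestrial_band_irradiance(bands)  # W m^-2 per band, normal
    cosz = math.cos(math.radians(air_zenith_deg))
    trans = np.exp(-tau * m)
    e_direct_h = e0 * trans * cosz                       # horizontal, per band
    e_diffuse_h = 0.5 * e0 * (1.0 - trans) * cosz        # isotropised half

    # diffuse: uniform radiance; sum(cos_weight) == pi exactly
    rad += (e_diffuse_h / (np.pi * bands.widths))[None, :]
    j = zgrid.bin_of(air_zenith_deg)
    rad[j] += e_direct_h / (zgrid.cos_weight[j] * bands.widths)
    return DirectionalRadiance(bands, zgrid, rad)


# ---------------------------------------------------------------------------
# Air-water interface and water column
# ---------------------------------------------------------------------------

def _fresnel_transmittance(air_zenith_deg: float, n: float = WATER_REFRACTIVE_INDEX) -> float:
    """Unpolarised Fresnel transmittance for air -> water."""
    ti = math.radians(min(air_zenith_deg, 89.999))
    tt = math.asin(math.sin(ti) / n)
    if ti < 1e-9:
        r = ((n - 1.0) / (n + 1.0)) ** 2
        return 1.0 - r
    rs = (math.sin(ti - tt) / math.sin(ti + tt)) ** 2
    rp = (math.tan(ti - tt) / math.tan(ti + tt)) ** 2
    return 1.0 - 0.5 * (rs + rp)


def transmit_interface(rad: DirectionalRadiance) -> DirectionalRadiance:
    """Refract an above-water distribution through the air-water interface.

    Per-bin planar flux is Fresnel-transmitted and re-binned at the refracted
    zenith angle; all in-water light lies within the Snell cone (< 48.6 deg).
    """
    zg, bands = rad.zgrid, rad.bands
    out = np.zeros_like(rad.radiance)
    for i in range(zg.n_bins):
        e_bin = rad.radiance[i] * zg.cos_weight[i]  # W m^-2 nm^-1
        if not np.any(e_bin):
            continue
        theta = zg.eff_zenith[i]
        t = _fresnel_transmittance(theta)
        j = zg.bin_of(refract_zenith(theta))
        out[j] += t * e_bin / zg.cos_weight[j]
    return DirectionalRadiance(bands, zg, out)


def propagate_water_column(
    rad: DirectionalRadiance,
    iops: WaterIOPs,
    depth: float,
    interface: bool = True,
    n_layers: int = 24,
) -> DirectionalRadiance:
    """Propagate a radiance distribution to ``depth`` metres below the surface.

    Each zenith bin is attenuated as a beam by exp(-(a+b_b) z / cos(theta));
    flux scattered out of the beams feeds an isotropised downward diffuse
    source (half of the scattered flux), itself attenuated to the target depth
    with a diffuse mean-path factor of 2.  With ``interface`` True the input
    is above-water radiance and is first refracted through the surface; with
    ``interface`` False the input is in-water radiance and ``depth`` 0 is the
    identity.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if interface:
        rad = transmit_interface(rad)
    zg, bands = rad.zgrid, rad.bands
    a, bb = iops.absorption, iops.backscatter
    c_ext = a + bb
    mu = np.cos(np.radians(zg.eff_zenith))  # (nbins,)
    e0 = rad.radiance * zg.cos_weight[:, None]  # per-bin planar flux, W m^-2 nm^-1

    atten = np.exp(-c_ext[None, :] * depth / mu[:, None])
    e_z = e0 * atten

    # single-scattering isotropised diffuse source
    e_scat = np.zeros(bands.n)
    if depth > 0 and np.any(bb > 0) and np.any(e0):
        zs = (np.arange(n_layers) + 0.5) / n_layers * depth
        dz = depth / n_layers
        for z in zs:
            beam = e0 * np.exp(-c_ext[None, :] * z / mu[:, None])
            ds = (beam / mu[:, None]).sum(axis=0) * bb * dz  # scattered flux
            e_scat += 0.5 * ds * np.exp(-2.0 * a * (depth - z))

    out = e_z / zg.cos_weight[:, None]
    # scattered light re-enters within the Snell cone (all downwelling light
    # underwater is confined there); uniform radiance over those bins
    cone = zg.eff_zenith <= math.degrees(math.asin(1.0 / WATER_REFRACTIVE_INDEX))
    w_cone = zg.cos_weight[cone].sum()
    out[cone] += e_scat[None, :] / w_cone
    return DirectionalRadiance(bands, zg, out)


def apply_shading(rad: DirectionalRadiance, level: ShadingLevel) -> DirectionalRadiance:
    """Spectrally neutral shading: every (bin, band) value times (1 - fraction)."""
    return rad.scaled(1.0 - level.fraction)


def azimuthal_average(radiance_za: np.ndarray, bands: SpectralBands, zgrid: ZenithGrid) -> DirectionalRadiance:
    """Average a (zenith, azimuth, band) radiance grid over azimuth.

    The per-zenith mean preserves the cosine-weighted planar irradiance
    exactly (the cosine weight does not depend on azimuth).
    """
    arr = np.asarray(radiance_za, dtype=float)
    if arr.ndim != 3 or arr.shape[0] != zgrid.n_bins or arr.shape[2] != bands.n:
        raise ValueError("expected (n_zenith, n_azimuth, n_band) radiance grid")
    return DirectionalRadiance(bands, zgrid, arr.mean(axis=1))


def compute_kd_par(depths: np.ndarray, par_values: np.ndarray) -> float:
    """Diffuse attenuation coefficient of planar PAR, m^-1.

    Least-squares slope of -ln(E_d) against depth; requires at least two
    depths with positive irradiance.
    """
    z = np.asarray(depths, dtype=float)
    e = np.asarray(par_values, dtype=float)
    if z.size < 2:
        raise ValueError("need at least two depths")
    if np.any(e <= 0):
        raise ValueError("irradiances must be positive")
    slope = np.polyfit(z, np.log(e), 1)[0]
    return float(-slope)


# ---------------------------------------------------------------------------
# Site convenience
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Site:
    """Study-site geometry: latitude/longitude, date and water depth."""

    latitude: float = -30.3095
    longitude: float = 115.0072
    date: _dt.date = field(default_factory=lambda: _dt.date(2005, 4, 27))
    depth: float = 4.5


def top_of_canopy_radiance(
    site: Site,
    air_zenith_deg: float,
    iops: WaterIOPs | None = None,
    bands: SpectralBands | None = None,
    zgrid: ZenithGrid | None = None,
) -> DirectionalRadiance:
    """Clear-sky radiance propagated to the top of the canopy."""
    bands = bands or SpectralBands()
    zgrid = zgrid or ZenithGrid()
    iops = iops or WaterIOPs.reference(bands, depth=site.depth)
    sky = clear_sky_radiance(air_zenith_deg, bands, zgrid)
    return propagate_water_column(sky, iops, site.depth, interface=True)
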