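"""Spectral band grid, zenith quadrature and PAR conversion.

The optical chain works on 17 contiguous 20 nm wavebands spanning 400-740 nm.
Photosynthetically available radiation (PAR) integrates the 400-700 nm subset
(15 bands); the two bands above 700 nm are carried for spectral completeness
only.  Directional quantities are binned over the downward hemisphere on a
fixed zenith-angle partition; radiance is azimuthally uniform by construction
(the boundary condition is azimuthally averaged before it reaches the canopy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Planck constant * speed of light * Avogadro number, J m / mol.
_HC_NA = 6.62607015e-34 * 2.99792458e8 * 6.02214076e23


@dataclass(frozen=True)
class SpectralBands:
    """17 contiguous 20 nm bands covering 400-740 nm."""

    edges: np.ndarray = field(
        default_factory=lambda: np.arange(400.0, 741.0, 20.0)
    )

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size != 18 or not np.allclose(np.diff(e), 20.0) or e[0] != 400.0:
            raise ValueError("band grid must be 17 x 20 nm bands over 400-740 nm")
        object.__setattr__(self, "edges", e)

    @property
    def n(self) -> int:
        return self.edges.size - 1

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def par_mask(self) -> np.ndarray:
        """Bands contributing to PAR (centre below 700 nm)."""
        return self.centres < 700.0


@dataclass(frozen=True)
class ZenithGrid:
    """Equal-angle zenith bins over the downward hemisphere.

    ``ring_omega`` is the solid angle of each azimuthal ring and ``cos_weight``
    the exact cosine-weighted ring factor pi*(cos^2(t0) - cos^2(t1)), so that a
    uniform radiance L yields a planar irradiance of exactly pi*L when summed.
    ``eff_zenith`` is the ring's irradiance-weighted mean zenith angle; facet
    illumination quadrature evaluates directions there so that the horizontal-
    facet integral is exact.
    """

    n_bins: int = 18

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, 90.0, self.n_bins + 1)

    @property
    def centres(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def ring_omega(self) -> np.ndarray:
        c = np.cos(np.radians(self.edges))
        return 2.0 * np.pi * (c[:-1] - c[1:])

    @property
    def cos_weight(self) -> np.ndarray:
        c = np.cos(np.radians(self.edges))
        return np.pi * (c[:-1] ** 2 - c[1:] ** 2)

    @property
    def eff_zenith(self) -> np.ndarray:
        """Zenith angle (deg) whose cosine equals the ring mean cosine."""
        c = np.cos(np.radians(self.edges))
        return np.degrees(np.arccos(0.5 * (c[:-1] + c[1:])))

    def bin_of(self, zenith_deg: float) -> int:
        if not (0.0 <= zenith_deg < 90.0):
            raise ValueError(f"zenith {zenith_deg} deg outside downward hemisphere")
        return min(int(zenith_deg / (90.0 / self.n_bins)), self.n_bins - 1)


@dataclass
class DirectionalRadiance:
    """Zenith-binned, azimuthally uniform spectral radiance.

    ``radiance`` has shape (n_zenith_bins, n_bands) in W m^-2 sr^-1 nm^-1.
    """

    bands: SpectralBands
    zgrid: ZenithGrid
    radiance: np.ndarray

    def __post_init__(self) -> None:
        self.radiance = np.asarray(self.radiance, dtype=float)
        if self.radiance.shape != (self.zgrid.n_bins, self.bands.n):
            raise ValueError("radiance shape does not match grids")
        if np.any(self.radiance < 0) or not np.all(np.isfinite(self.radiance)):
            raise ValueError("radiance must be finite and non-negative")

    def planar_irradiance(self) -> np.ndarray:
        """Planar downwelling irradiance per band, W m^-2 nm^-1."""
        return self.zgrid.cos_weight @ self.radiance

    def band_irradiance(self) -> np.ndarray:
        """Band-integrated planar downwelling irradiance, W m^-2 per band."""
        return self.planar_irradiance() * self.bands.widths

    def par(self) -> float:
        """Planar downwelling PAR, umol quanta m^-2 s^-1."""
        return to_par(self.band_irradiance(), self.bands)

    def scaled(self, factor: float) -> "DirectionalRadiance":
        return DirectionalRadiance(self.bands, self.zgrid, self.radiance * factor)


def to_par(band_irradiance: np.ndarray, bands: SpectralBands) -> float:
    """Convert band-integrated irradiance (W m^-2 per band) to PAR.

    Photon flux per band is E * lambda_c / (h c N_A); only 400-700 nm bands
    contribute.  Returns umol quanta m^-2 s^-1.
    """
    e = np.asarray(band_irradiance, dtype=float)
    if e.shape[-1] != bands.n:
        raise ValueError("band irradiance does not match band grid")
    lam_m = bands.centres * 1e-9
    factor = lam_m / _HC_NA * 1e6  # umol photons per J
    factor = np.where(bands.par_mask, factor, 0.0)
    return float(np.sum(e * factor, axis=-1))


def to_par_array(band_irradiance: np.ndarray, bands: SpectralBands) -> np.ndarray:
    """Vectorised :func:`to_par` over leading axes."""
    e = np.asarray(band_irradiance, dtype=float)
    lam_m = bands.centres * 1e-9
    factor = np.where(bands.par_mask, lam_m / _HC_NA * 1e6, 0.0)
    return e @ factor
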