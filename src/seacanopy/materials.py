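"""Lambertian surface optical properties per material id.

All surfaces are Lambertian reflectors and transmitters with band-wise
reflectance rho and transmittance tau, rho + tau <= 1 (the remainder is
absorbed).  Packaged defaults: a parametric green-peak seagrass leaf
(absorptance-dominated in 400-700 nm with a rise beyond 700 nm), an opaque
brown stem, and an opaque sand substrate with mean reflectance 0.33.
Leaf spectra are swappable from 2-column CSV (nm, value) files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import SpectralBands
from .morphology import ROLE_LEAF, ROLE_STEM, ROLE_SUBSTRATE


def _gauss(lam: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - mu) / sigma) ** 2)


def default_leaf_spectra(bands: SpectralBands) -> tuple[np.ndarray, np.ndarray]:
    """Parametric green leaf: rho/tau with a 550 nm peak and a >700 nm rise."""
    lam = bands.centres
    rho = 0.06 + 0.22 * _gauss(lam, 555.0, 40.0) + 0.25 * np.clip((lam - 700.0) / 40.0, 0.0, 1.0)
    tau = 0.03 + 0.17 * _gauss(lam, 555.0, 45.0) + 0.20 * np.clip((lam - 700.0) / 40.0, 0.0, 1.0)
    return rho, tau


def default_substrate_spectrum(bands: SpectralBands) -> np.ndarray:
    """Sand-like reflectance rising with wavelength, mean exactly 0.33."""
    lam = bands.centres
    rho = 0.20 + 0.30 * (lam - 400.0) / 340.0
    return rho * (0.33 / rho.mean())


@dataclass
class MaterialLibrary:
    """Per-material band-wise Lambertian reflectance and transmittance."""

    bands: SpectralBands
    rho: dict[int, np.ndarray] = field(default_factory=dict)
    tau: dict[int, np.ndarray] = field(default_factory=dict)

    def add(self, material_id: int, rho: np.ndarray, tau: np.ndarray) -> None:
        rho = np.asarray(rho, dtype=float)
        tau = np.asarray(tau, dtype=float)
        if rho.shape != (self.bands.n,) or tau.shape != (self.bands.n,):
            raise ValueError("spectra must match the band grid")
        if np.any(rho < 0) or np.any(tau < 0) or np.any(rho + tau > 1.0 + 1e-12):
            raise ValueError("need 0 <= rho, tau and rho + tau <= 1 per band")
        self.rho[material_id] = rho
        self.tau[material_id] = tau

    @classmethod
    def default(cls, bands: SpectralBands | None = None) -> "MaterialLibrary":
        bands = bands or SpectralBands()
        lib = cls(bands)
        l_rho, l_tau = default_leaf_spectra(bands)
        lib.add(ROLE_LEAF, l_rho, l_tau)
        lib.add(ROLE_STEM, np.full(bands.n, 0.15), np.zeros(bands.n))
        lib.add(ROLE_SUBSTRATE, default_substrate_spectrum(bands), np.zeros(bands.n))
        return lib

    @classmethod
    def black(cls, bands: SpectralBands | None = None) -> "MaterialLibrary":
        """rho = tau = 0 everywhere (no scattering)."""
        bands = bands or SpectralBands()
        lib = cls(bands)
        z = np.zeros(bands.n)
        for mid in (ROLE_SUBSTRATE, ROLE_STEM, ROLE_LEAF):
            lib.add(mid, z, z)
        return lib

    def arrays_for(self, material_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(rho, tau) stacked per facet, each (n_facets, n_bands)."""
        rho = np.empty((material_ids.size, self.bands.n))
        tau = np.empty_like(rho)
        for i, mid in enumerate(material_ids):
            try:
                rho[i] = self.rho[int(mid)]
                tau[i] = self.tau[int(mid)]
            except KeyError:
                raise KeyError(f"material id {int(mid)} not in library") from None
        return rho, tau


def resample_spectrum_csv(path, bands: SpectralBands) -> np.ndarray:
    """Read a 2-column (nm, value) CSV and average onto the band grid."""
    data = np.loadtxt(path, delimiter=",", comments="#")
    lam, val = data[:, 0], data[:, 1]
    out = np.empty(bands.n)
    for i in range(bands.n):
        lo, hi = bands.edges[i], bands.edges[i + 1]
        m = (lam >= lo) & (lam < hi)
        out[i] = val[m].mean() if m.any() else np.interp(bands.centres[i], lam, val)
    return out
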