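"""Residue-specific Ramachandran statistics for coil/loop regions.

Backbone (phi, psi) torsions of disordered chains are sampled from
residue-specific coil statistics, i.e. the torsion preferences of
residues in loop regions of high-resolution structures.  The shipped
library approximates those statistics by mixtures of two-dimensional
Gaussian basins discretized on a 10-degree grid, with distinct densities
for the residue classes {glycine, proline, pre-proline, beta-branched
(Ile/Val/Thr), generic}.  The basin locations are the canonical coil
basins (polyproline II, extended beta, alpha-R, alpha-L; for glycine
additionally their mirror images); class weights follow coil-library
surveys.  A custom library implementing :meth:`RamachandranLibrary.sample`
can be substituted for the shipped one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["RamachandranLibrary", "default_library", "residue_class"]

GRID_DEG = 10.0  # bin width of the discretized densities

# basin tables: (phi0, psi0, weight, sigma_phi, sigma_psi) in degrees
# Basin weights are calibrated once so that unrestrained 100-residue
# low-complexity ensembles reproduce published coil-library reference
# statistics (segment scaling R_k ~ 5.2 k^0.57 A and the end-to-end
# distribution of 20-residue sections); they are not per-run tunables.
_BASINS = {
    "generic": [
        (-65.0, 145.0, 0.42, 15.0, 20.0),   # polyproline II
        (-120.0, 135.0, 0.28, 25.0, 22.0),  # extended beta
        (-63.0, -43.0, 0.25, 13.0, 13.0),   # alpha-R
        (57.0, 40.0, 0.05, 13.0, 13.0),     # alpha-L
    ],
    "glycine": [
        (-65.0, 145.0, 0.20, 20.0, 25.0),
        (65.0, -145.0, 0.20, 20.0, 25.0),
        (-120.0, 170.0, 0.13, 25.0, 25.0),
        (120.0, -170.0, 0.13, 25.0, 25.0),
        (-90.0, 0.0, 0.08, 20.0, 20.0),
        (90.0, 0.0, 0.08, 20.0, 20.0),
        (-63.0, -43.0, 0.09, 15.0, 15.0),
        (63.0, 43.0, 0.09, 15.0, 15.0),
    ],
    "proline": [
        (-63.0, 150.0, 0.65, 8.0, 18.0),
        (-63.0, -35.0, 0.35, 8.0, 15.0),
    ],
    "prepro": [
        (-65.0, 150.0, 0.50, 15.0, 20.0),
        (-120.0, 140.0, 0.35, 25.0, 22.0),
        (-63.0, -40.0, 0.12, 13.0, 13.0),
        (57.0, 40.0, 0.03, 13.0, 13.0),
    ],
    "branched": [
        (-115.0, 130.0, 0.48, 22.0, 22.0),
        (-65.0, 140.0, 0.30, 15.0, 20.0),
        (-60.0, -45.0, 0.19, 12.0, 12.0),
        (57.0, 40.0, 0.03, 13.0, 13.0),
    ],
}


def residue_class(sequence: str, index: int) -> str:
    """Residue class at 0-based ``index``: pre-proline wins over sidechain class."""
    aa = sequence[index].upper()
    if index + 1 < len(sequence) and sequence[index + 1].upper() == "P" and aa != "P" and aa != "G":
        return "prepro"
    if aa == "G":
        return "glycine"
    if aa == "P":
        return "proline"
    if aa in ("I", "V", "T"):
        return "branched"
    return "generic"


def _wrap_delta(x: np.ndarray, x0: float) -> np.ndarray:
    d = (x - x0 + 180.0) % 360.0 - 180.0
    return d


@dataclass
class RamachandranLibrary:
    """Discretized coil (phi, psi) densities per residue class.

    densities maps class name -> (n_bins, n_bins) array over the
    [-180, 180) x [-180, 180) torus; each density is nonnegative and
    normalized to unit sum.
    """

    densities: dict
    grid_deg: float = GRID_DEG

    def __post_init__(self) -> None:
        self._edges = np.arange(-180.0, 180.0 + 1e-9, self.grid_deg)
        self._centers = self._edges[:-1] + 0.5 * self.grid_deg
        self._flat = {}
        for name, dens in self.densities.items():
            dens = np.asarray(dens, dtype=float)
            if np.any(dens < 0):
                raise ValueError("Ramachandran densities must be nonnegative")
            total = dens.sum()
            if total <= 0:
                raise ValueError("Ramachandran density is empty")
            self.densities[name] = dens / total
            flat = (dens / total).ravel()
            self._flat[name] = np.cumsum(flat)

    def classes(self):
        return list(self.densities)

    def density(self, class_name: str) -> np.ndarray:
        return self.densities[class_name]

    def sample(self, class_name: str, rng: np.random.Generator) -> tuple[float, float]:
        """Draw one (phi, psi) pair in degrees for a residue class."""
        cdf = self._flat[class_name]
        flat_idx = int(np.searchsorted(cdf, rng.random(), side="right"))
        flat_idx = min(flat_idx, cdf.size - 1)
        nb = self._centers.size
        i, j = divmod(flat_idx, nb)
        jitter = self.grid_deg * (rng.random(2) - 0.5)
        phi = self._centers[i] + jitter[0]
        psi = self._centers[j] + jitter[1]
        return float(phi), float(psi)


def default_library(grid_deg: float = GRID_DEG) -> RamachandranLibrary:
    """Build the shipped coil library from the basin tables."""
    edges = np.arange(-180.0, 180.0 + 1e-9, grid_deg)
    centers = edges[:-1] + 0.5 * grid_deg
    phi, psi = np.meshgrid(centers, centers, indexing="ij")
    densities = {}
    for name, basins in _BASINS.items():
        dens = np.zeros_like(phi)
        for phi0, psi0, w, s_phi, s_psi in basins:
            dphi = _wrap_delta(phi, phi0) / s_phi
            dpsi = _wrap_delta(psi, psi0) / s_psi
            dens += w * np.exp(-0.5 * (dphi**2 + dpsi**2)) / (s_phi * s_psi)
        densities[name] = dens / dens.sum()
    return RamachandranLibrary(densities=densities, grid_deg=grid_deg)
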