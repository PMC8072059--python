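"""Spin-label surrogate: mean label positions and label-label distributions.

A nitroxide label (MTSL) attached at an engineered cysteine samples a
cloud of sidechain rotamers.  Full rotamer libraries predict per-site
position clouds; for ensemble modelling of disordered chains only two
effects of the label matter: (i) the *mean* label position sits off the
backbone, roughly along the CA->CB direction, and (ii) the rotamer
spread *broadens* the label-label distance distribution relative to the
distribution of mean positions.  The surrogate models these with two
parameters: a radial offset of the mean position from CA and a per-site
positional spread.  A plug-in returning per-site position clouds can
replace the surrogate where a true rotamer library is available.

The default calibration reproduces the reference relation between a
CA-CA distribution with mean 27.0 A / sigma 8.2 A at 20-residue
separation and the corresponding label-label distribution with mean
29.7 A / sigma 10.8 A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .distributions import DistanceDistribution, default_grid
from .ensemble import Conformer, Ensemble
from .geometry import pseudo_cb_direction

__all__ = [
    "LabelSurrogateParams",
    "DEFAULT_LABEL_PARAMS",
    "predict_label_position",
    "label_distance",
    "label_distance_distribution",
]


@dataclass(frozen=True)
class LabelSurrogateParams:
    """Two-parameter spin-label surrogate.

    radial_offset : mean label displacement from CA along the pseudo-CB
        direction (A).
    sigma_label : per-site positional spread of the label cloud (A); the
        label-label distribution is broadened by a Gaussian of width
        sqrt(2) * sigma_label.
    """

    radial_offset: float = 8.3
    sigma_label: float = 3.9

    def __post_init__(self) -> None:
        if self.radial_offset < 0 or self.sigma_label < 0:
            raise ValueError("surrogate parameters must be nonnegative")

    @property
    def sigma_conv(self) -> float:
        """Width of the pairwise broadening kernel, sqrt(2) * sigma_label."""
        return math.sqrt(2.0) * self.sigma_label


DEFAULT_LABEL_PARAMS = LabelSurrogateParams()


def predict_label_position(
    conformer: Conformer,
    site: int,
    params: LabelSurrogateParams = DEFAULT_LABEL_PARAMS,
) -> np.ndarray:
    """Deterministic mean label position at a 1-based residue site.

    position = CA + radial_offset * u with u the ideal tetrahedral CB
    direction built from the local N, CA, C frame.  Residues without a
    complete frame (CA-only models, chain termini) fall back to CA.
    """
    n, ca, c = conformer.backbone_frame(site)
    if n is None or c is None or params.radial_offset == 0.0:
        return ca.copy()
    return ca + params.radial_offset * pseudo_cb_direction(n, ca, c)


def label_distance(
    conformer: Conformer,
    site_i: int,
    site_j: int,
    params: LabelSurrogateParams = DEFAULT_LABEL_PARAMS,
) -> float:
    """Mean-label to mean-label distance for one conformer (A)."""
    pi = predict_label_position(conformer, site_i, params)
    pj = predict_label_position(conformer, site_j, params)
    return float(np.linalg.norm(pi - pj))


def _histogram_on_grid(values: np.ndarray, weights: np.ndarray, r_axis: np.ndarray) -> np.ndarray:
    """Linear (triangular) binning of weighted samples onto a uniform grid."""
    dr = r_axis[1] - r_axis[0]
    pos = (values - r_axis[0]) / dr
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    p = np.zeros(r_axis.size)
    for idx, f, w in zip(i0, frac, weights):
        if idx < -1 or idx > r_axis.size - 1:
            continue
        if 0 <= idx < r_axis.size:
            p[idx] += w * (1.0 - f)
        if 0 <= idx + 1 < r_axis.size:
            p[idx + 1] += w * f
    return p


def label_distance_distribution(
    ensemble: Ensemble,
    site_i: int,
    site_j: int,
    r_axis: np.ndarray | None = None,
    params: LabelSurrogateParams = DEFAULT_LABEL_PARAMS,
) -> DistanceDistribution:
    """Label-label distance distribution of an ensemble.

    The population-weighted histogram of mean-label distances is
    convolved with a Gaussian broadening kernel of width
    sqrt(2) * sigma_label (the pairwise combination of the two per-site
    rotamer spreads) and normalized to unit sum.
    """
    if r_axis is None:
        r_axis = default_grid()
    r_axis = np.asarray(r_axis, dtype=float)
    values = np.array(
        [label_distance(c, site_i, site_j, params) for c in ensemble.conformers]
    )
    p = _histogram_on_grid(values, ensemble.populations, r_axis)
    if p.sum() <= 0:
        raise ValueError("no label distances fall on the requested grid")
    sigma_conv = params.sigma_conv
    if sigma_conv > 0:
        dr = r_axis[1] - r_axis[0]
        p = gaussian_filter1d(p, sigma_conv / dr, mode="constant")
    return DistanceDistribution(r_axis, p).normalize()
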