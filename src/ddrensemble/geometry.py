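"""Ideal peptide backbone geometry: NeRF atom placement and chain building.

Backbone conformers are built residue by residue from sampled (phi, psi)
torsions with ideal bond lengths and angles and trans peptide bonds
(omega = 180 deg).  Side chains are not built; the label surrogate and
the clash model operate at the CA level.
"""

from __future__ import annotations

import math

import numpy as np

# ideal backbone geometry (Angstrom, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0

#: CA-CA virtual bond length of a trans peptide
CA_CA_VIRTUAL = 3.8


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given atoms A, B, C with |CD|, angle(BCD), dihedral(ABCD)."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # colinear frame; pick an arbitrary perpendicular
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
            nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dihedral),
            bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(a, b, c, d) -> float:
    """Signed dihedral angle A-B-C-D in degrees."""
    b0 = a - b
    b1 = c - b
    b2 = d - c
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def first_residue() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical placement of N, CA, C of the first residue."""
    n = np.zeros(3)
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    return n, ca, c


def extend_residue(n_prev, ca_prev, c_prev, psi_prev: float, phi_next: float):
    """Grow the next residue's N, CA, C from the previous residue frame.

    psi_prev and phi_next are in degrees; the peptide bond is trans.
    """
    n_next = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi_prev)
    ca_next = place_atom(ca_prev, c_prev, n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
    c_next = place_atom(c_prev, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi_next)
    return n_next, ca_next, c_next


def carbonyl_oxygen(n, ca, c, psi: float) -> np.ndarray:
    """Carbonyl O of a residue, anti to the following amide nitrogen."""
    return place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)


def pseudo_cb_direction(n, ca, c) -> np.ndarray:
    """Unit vector from CA along the ideal tetrahedral CB direction.

    Constructed from the backbone frame: the direction makes equal
    (~110.5 deg) angles with the CA->N and CA->C bonds and points to the
    L-amino-acid side of the N-CA-C plane.
    """
    u1 = n - ca
    u1 /= np.linalg.norm(u1)
    u2 = c - ca
    u2 /= np.linalg.norm(u2)
    bisector = u1 + u2
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(u2, u1)
    perp /= np.linalg.norm(perp)
    # choose the in-plane/out-of-plane mix that gives angle(N-CA-CB) = 110.5 deg
    target = math.cos(math.radians(110.5))
    cos_half = float(np.dot(bisector, u1))
    c_mix = max(min(-target / cos_half, 1.0), -1.0)
    s_mix = math.sqrt(max(1.0 - c_mix * c_mix, 0.0))
    d = -c_mix * bisector + s_mix * perp
    return d / np.linalg.norm(d)


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """CA RMSD of two coordinate sets after optimal rigid superposition."""
    if x.shape != y.shape:
        raise ValueError("coordinate sets must have identical shapes")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    s = s.copy()
    s[-1] *= sign
    msd = (np.sum(xc**2) + np.sum(yc**2) - 2.0 * s.sum()) / x.shape[0]
    return math.sqrt(max(msd, 0.0))
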