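"""Conformer and ensemble containers.

A :class:`Conformer` holds the backbone coordinates of one model; an
:class:`Ensemble` is a list of conformers with populations that sum to
one.  Raw (Monte-Carlo generated) ensembles carry uniform populations;
refined ensembles carry the populations fitted against distance
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CA_CA_VIRTUAL

__all__ = ["Conformer", "Ensemble"]


@dataclass(eq=False)
class Conformer:
    """Backbone model of one chain conformation.

    ca is required (n_res, 3); n, c, o are optional (CA-only synthetic
    models omit them).  Residue numbering is 1-based construct numbering:
    residue ``i`` maps to array row ``i - 1``.
    """

    sequence: str
    ca: np.ndarray
    n: np.ndarray | None = None
    c: np.ndarray | None = None
    o: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.ndim != 2 or self.ca.shape[1] != 3:
            raise ValueError("ca must be an (n_res, 3) array")
        if len(self.sequence) != self.ca.shape[0]:
            raise ValueError("sequence length must match coordinate count")
        for name in ("n", "c", "o"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.ca.shape:
                    raise ValueError(f"{name} coordinates must match ca shape")
                setattr(self, name, arr)

    @property
    def n_res(self) -> int:
        return self.ca.shape[0]

    def backbone_frame(self, site: int):
        """(N, CA, C) coordinates at 1-based residue ``site``; N/C may be None."""
        idx = site - 1
        if idx < 0 or idx >= self.n_res:
            raise IndexError(f"residue {site} outside 1..{self.n_res}")
        n = None if self.n is None else self.n[idx]
        c = None if self.c is None else self.c[idx]
        return n, self.ca[idx], c

    def check_virtual_bonds(self, tol: float = 0.1) -> bool:
        d = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
        return bool(np.all(np.abs(d - CA_CA_VIRTUAL) <= tol))


@dataclass(eq=False)
class Ensemble:
    """Conformers plus populations summing to one."""

    conformers: list
    populations: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.conformers) == 0:
            raise ValueError("ensemble must contain at least one conformer")
        n = len(self.conformers)
        if self.populations is None:
            self.populations = np.full(n, 1.0 / n)
        else:
            self.populations = np.asarray(self.populations, dtype=float)
            if self.populations.shape != (n,):
                raise ValueError("populations must match the conformer count")
            if np.any(self.populations < -1e-12):
                raise ValueError("populations must be nonnegative")
            total = self.populations.sum()
            if total <= 0:
                raise ValueError("populations must have positive sum")
            self.populations = np.clip(self.populations, 0.0, None) / total

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def n_res(self) -> int:
        return self.conformers[0].n_res

    def ca_stack(self) -> np.ndarray:
        """(n_conf, n_res, 3) array of CA coordinates (equal-length chains)."""
        return np.stack([c.ca for c in self.conformers])

    def subset(self, indices, renormalize: bool = True) -> "Ensemble":
        indices = np.asarray(indices, dtype=int)
        pops = self.populations[indices]
        if renormalize:
            pops = pops / pops.sum()
        return Ensemble(
            [self.conformers[i] for i in indices], pops, dict(self.provenance)
        )
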