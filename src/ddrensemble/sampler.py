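"""Monte-Carlo generation of backbone conformers under distance restraints.

Chains are grown residue by residue with (phi, psi) torsions drawn from
residue-specific coil Ramachandran statistics and ideal trans-peptide
geometry.  Self-avoidance is enforced at the CA level.  Each Gaussian
distance restraint is tested as soon as backbone coordinates exist for
both of its sites: the mean spin-label position is predicted from the
backbone, and a Gaussian consistency score is accumulated; if the
running product of scores drops below the acceptance threshold the
conformer is discarded and a new one is started.  This early rejection
concentrates sampling on the restraint-consistent part of conformation
space.

Chains may be tethered to a folded domain: an anchor conformer supplies
fixed coordinates for an N-terminal stretch and the disordered tail is
grown from its last residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distributions import DistanceDistribution
from .ensemble import Conformer, Ensemble
from . import geometry as geom
from .labels import DEFAULT_LABEL_PARAMS, LabelSurrogateParams
from .rama import RamachandranLibrary, default_library, residue_class

__all__ = [
    "GaussianRestraint",
    "SamplingError",
    "restraint_probability",
    "sample_chain",
    "build_raw_ensemble",
]


@dataclass
class GaussianRestraint:
    """Site pair with Gaussian summary <r>, sigma_r (A) and optional full
    experimental distance distribution (used in ensemble fitting)."""

    site_i: int
    site_j: int
    mean: float
    sigma: float
    distribution: DistanceDistribution | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.site_i == self.site_j:
            raise ValueError("restraint sites must differ")
        if self.site_i > self.site_j:
            self.site_i, self.site_j = self.site_j, self.site_i
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


class SamplingError(RuntimeError):
    """Raised when the restart budget is exhausted; carries run statistics."""

    def __init__(self, message: str, stats: dict):
        super().__init__(message)
        self.stats = stats


def restraint_probability(distance: float, restraint: GaussianRestraint) -> float:
    """Max-normalized Gaussian consistency score of a distance.

    p = exp(-(d - <r>)^2 / (2 s^2)) with s = sqrt(2) sigma_r, so p = 1 at
    the restraint mean.  The sampler multiplies these scores over all
    evaluated restraints and rejects the conformer when the product drops
    below the acceptance threshold.
    """
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    s = math.sqrt(2.0) * restraint.sigma
    z = (distance - restraint.mean) / s
    return math.exp(-0.5 * z * z)


def _label_pos(n, ca, c, offset: float) -> np.ndarray:
    if offset == 0.0:
        return ca
    return ca + offset * geom.pseudo_cb_direction(n, ca, c)


@dataclass
class SamplerConfig:
    """Tunable sampling parameters."""

    threshold: float = 0.75  # minimum running product of restraint scores
    clash_ca: float = 4.0  # CA-CA clash cutoff for |i-j| >= 3 (A)
    clash_anchor: float = 3.5  # CA vs anchor heavy-atom cutoff (A)
    residue_retries: int = 50  # torsion redraws per residue before restart
    max_restarts: int = 2000  # chain restarts before sampling failure


class _ChainRestart(Exception):
    pass


def sample_chain(
    sequence: str,
    library: RamachandranLibrary | None = None,
    restraints: list | None = None,
    anchor: Conformer | None = None,
    rng: np.random.Generator | int | None = None,
    label_params: LabelSurrogateParams = DEFAULT_LABEL_PARAMS,
    config: SamplerConfig | None = None,
    _stats: dict | None = None,
) -> Conformer:
    """Grow one restraint-consistent backbone conformer.

    sequence is the full 1-based construct sequence; if an anchor is
    given its residues occupy positions 1..anchor.n_res with fixed
    coordinates and only the remainder is sampled.  Raises
    :class:`SamplingError` when the restart budget is exhausted.
    """
    if library is None:
        library = default_library()
    if config is None:
        config = SamplerConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    restraints = restraints or []
    n_res = len(sequence)
    if n_res == 0:
        raise ValueError("sequence must be non-empty")
    n_anchor = 0 if anchor is None else anchor.n_res
    if n_anchor >= n_res:
        raise ValueError("anchor covers the whole sequence; nothing to sample")
    if anchor is not None and (anchor.n is None or anchor.c is None):
        raise ValueError("anchor must provide full N/CA/C backbone coordinates")

    for r in restraints:
        if not (1 <= r.site_i <= n_res and 1 <= r.site_j <= n_res):
            raise ValueError(f"restraint sites ({r.site_i}, {r.site_j}) outside sequence")
    by_site: dict[int, list[GaussianRestraint]] = {}
    for r in restraints:
        by_site.setdefault(max(r.site_i, r.site_j), []).append(r)

    classes = [residue_class(sequence, i) for i in range(n_res)]

    anchor_atoms = None
    if anchor is not None:
        pieces = [anchor.ca, anchor.n, anchor.c]
        if anchor.o is not None:
            pieces.append(anchor.o)
        anchor_atoms = np.concatenate(pieces, axis=0)
        anchor_res = np.concatenate(
            [np.arange(1, n_anchor + 1)] * len(pieces)
        )

    stats = _stats if _stats is not None else {"restarts": 0, "retries": 0}

    def grow_once() -> Conformer:
        n_arr = np.zeros((n_res, 3))
        ca_arr = np.zeros((n_res, 3))
        c_arr = np.zeros((n_res, 3))
        o_arr = np.zeros((n_res, 3))
        if anchor is not None:
            n_arr[:n_anchor] = anchor.n
            ca_arr[:n_anchor] = anchor.ca
            c_arr[:n_anchor] = anchor.c
            if anchor.o is not None:
                o_arr[:n_anchor] = anchor.o
            start = n_anchor  # 0-based index of the first sampled residue
        else:
            n_arr[0], ca_arr[0], c_arr[0] = geom.first_residue()
            start = 1

        prob_product = 1.0

        def check_restraints(i0: int) -> float:
            # evaluate restraints whose later site is residue i0+1 (1-based)
            nonlocal prob_product
            for r in by_site.get(i0 + 1, ()):
                a, b = r.site_i - 1, r.site_j - 1
                pa = _label_pos(n_arr[a], ca_arr[a], c_arr[a], label_params.radial_offset)
                pb = _label_pos(n_arr[b], ca_arr[b], c_arr[b], label_params.radial_offset)
                d = float(np.linalg.norm(pa - pb))
                prob_product *= restraint_probability(d, r)
                if prob_product < config.threshold:
                    raise _ChainRestart
            return prob_product

        def clash(ca_new: np.ndarray, idx0: int) -> bool:
            # CA-CA clash for sequence separation >= 3
            upto = idx0 - 2  # residues 0..idx0-3 (0-based)
            if upto > 0:
                d2 = np.sum((ca_arr[:upto] - ca_new) ** 2, axis=1)
                if d2.min() < config.clash_ca**2:
                    return True
            if anchor_atoms is not None and idx0 >= n_anchor:
                sep_ok = (idx0 + 1) - anchor_res >= 3
                if np.any(sep_ok):
                    d2 = np.sum((anchor_atoms[sep_ok] - ca_new) ** 2, axis=1)
                    if d2.min() < config.clash_anchor**2:
                        return True
            return False

        # step through sampled residues; at 0-based step i we fix residue
        # i's (phi, psi): phi places C_i (unless anchored), psi places O_i
        # and pre-places N_{i+1}, CA_{i+1} (clash-checked)
        first_step = start - 1  # last fixed/canonical residue
        for i in range(first_step, n_res):
            anchored_c = i < n_anchor or (anchor is None and i == 0)
            placed = False
            for _ in range(config.residue_retries):
                phi, psi = library.sample(classes[i], rng)
                if not anchored_c:
                    c_arr[i] = geom.place_atom(
                        c_arr[i - 1], n_arr[i], ca_arr[i],
                        geom.BOND_CA_C, geom.ANGLE_N_CA_C, phi,
                    )
                if i + 1 < n_res:
                    n_next = geom.place_atom(
                        n_arr[i], ca_arr[i], c_arr[i],
                        geom.BOND_C_N, geom.ANGLE_CA_C_N, psi,
                    )
                    ca_next = geom.place_atom(
                        ca_arr[i], c_arr[i], n_next,
                        geom.BOND_N_CA, geom.ANGLE_C_N_CA, geom.OMEGA_TRANS,
                    )
                    if clash(ca_next, i + 1):
                        stats["retries"] += 1
                        continue
                    n_arr[i + 1] = n_next
                    ca_arr[i + 1] = ca_next
                if i >= n_anchor:
                    o_arr[i] = geom.carbonyl_oxygen(n_arr[i], ca_arr[i], c_arr[i], psi)
                placed = True
                break
            if not placed:
                raise _ChainRestart
            if i >= start - 1:
                check_restraints(i)

        conf = Conformer(
            sequence=sequence, ca=ca_arr, n=n_arr, c=c_arr, o=o_arr,
            provenance={"prob_product": prob_product},
        )
        return conf

    for restart in range(config.max_restarts + 1):
        try:
            conf = grow_once()
        except _ChainRestart:
            stats["restarts"] += 1
            continue
        conf.provenance["restarts"] = restart
        return conf
    raise SamplingError(
        f"no restraint-consistent conformer within {config.max_restarts} restarts "
        f"(threshold {config.threshold}); restraints may be geometrically "
        "unsatisfiable for this chain",
        stats,
    )


def build_raw_ensemble(
    sequence: str,
    library: RamachandranLibrary | None = None,
    restraints: list | None = None,
    anchor_models: list | None = None,
    n_target: int = 100,
    rng_seed: int | np.random.Generator = 0,
    label_params: LabelSurrogateParams = DEFAULT_LABEL_PARAMS,
    config: SamplerConfig | None = None,
) -> Ensemble:
    """Generate a raw ensemble of n_target conformers with uniform populations.

    Conformers are distributed round-robin across the anchor models (for
    a folded-domain tether supplied as a multi-model structure).  The run
    is fully deterministic for a fixed seed.  Sampling failures for
    individual conformers are recorded in the ensemble provenance; the
    call fails only if no conformer at all could be generated.
    """
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    if library is None:
        library = default_library()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    anchors = anchor_models if anchor_models else [None]
    stats = {"restarts": 0, "retries": 0}
    conformers = []
    failures = []
    for m in range(n_target):
        anchor = anchors[m % len(anchors)]
        try:
            conf = sample_chain(
                sequence,
                library,
                restraints,
                anchor=anchor,
                rng=rng,
                label_params=label_params,
                config=config,
                _stats=stats,
            )
        except SamplingError as err:
            failures.append({"index": m, "error": str(err)})
            continue
        conf.provenance["anchor_id"] = None if anchor is None else (m % len(anchors))
        conformers.append(conf)
    if not conformers:
        raise SamplingError("sampling produced no conformers", stats)
    attempts = len(conformers) + stats["restarts"]
    provenance = {
        "n_target": n_target,
        "restarts": stats["restarts"],
        "retries": stats["retries"],
        "acceptance_rate": len(conformers) / attempts,
        "failures": failures,
    }
    return Ensemble(conformers, provenance=provenance)
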