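"""File formats: distributions, traces, restraints, sequences, ensembles.

Boundary conventions: distance axes are nanometers in distribution and
restraint files and Angstrom in memory; trace time axes may be ns or us
on disk (auto-detected by magnitude) and are microseconds in memory;
residue numbering is 1-based construct numbering throughout.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder

from .deer import DeerTrace
from .distributions import DistanceDistribution
from .ensemble import Conformer, Ensemble
from .sampler import GaussianRestraint

__all__ = [
    "read_distribution",
    "write_distribution",
    "read_trace",
    "write_trace",
    "read_restraints",
    "write_restraints",
    "read_fasta",
    "read_ensemble",
    "write_ensemble",
    "InputFormatError",
]

NM_PER_ANGSTROM = 0.1


class InputFormatError(ValueError):
    """Malformed input file; message carries file and line context."""


def _data_lines(path):
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("%", "#")):
            continue
        yield lineno, line


# ---------------------------------------------------------------------------
# distance distributions: 4-column whitespace format, distances in nm
# ---------------------------------------------------------------------------

def read_distribution(path) -> DistanceDistribution:
    """Read a 4-column (r_nm, p, lower, upper) distribution file.

    2-column files are accepted; their bands default to the density
    itself.  Distances convert nm -> Angstrom on read.
    """
    rows = []
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) not in (2, 4):
            raise InputFormatError(f"{path}:{lineno}: expected 2 or 4 columns")
        try:
            rows.append([float(x) for x in parts])
        except ValueError as err:
            raise InputFormatError(f"{path}:{lineno}: {err}") from None
    if len(rows) < 2:
        raise InputFormatError(f"{path}: need at least 2 data rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise InputFormatError(f"{path}: inconsistent column count")
    arr = np.array(rows)
    r = arr[:, 0] / NM_PER_ANGSTROM
    if np.any(np.diff(r) <= 0):
        raise InputFormatError(f"{path}: distance axis is not strictly increasing")
    p = arr[:, 1]
    neg = np.where(p < 0)[0]
    if neg.size:
        raise InputFormatError(f"{path}: negative density at data row {neg[0] + 1}")
    if width == 4:
        lo, hi = arr[:, 2], arr[:, 3]
    else:
        lo, hi = p.copy(), p.copy()
    return DistanceDistribution(r, p, band_lo=lo, band_hi=hi)


def write_distribution(path, dist: DistanceDistribution) -> None:
    """Write the 4-column nm format; missing bands are copies of p."""
    lo = dist.band_lo if dist.band_lo is not None else dist.p
    hi = dist.band_hi if dist.band_hi is not None else dist.p
    data = np.column_stack([dist.r_axis * NM_PER_ANGSTROM, dist.p, lo, hi])
    header = "r_nm  P(r)  lower  upper"
    np.savetxt(path, data, fmt="%.10g", header=header)


# ---------------------------------------------------------------------------
# traces: 2-column (t, V)
# ---------------------------------------------------------------------------

def read_trace(path, time_unit: str = "auto") -> DeerTrace:
    """Read a 2-column (t, V) trace; unit 'ns', 'us' or 'auto'.

    Auto-detection treats a time span above 50 as nanoseconds.  The
    signal is normalized to 1 at zero time (the point closest to t = 0).
    """
    rows = []
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) < 2:
            raise InputFormatError(f"{path}:{lineno}: expected 2 columns")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as err:
            raise InputFormatError(f"{path}:{lineno}: {err}") from None
    if len(rows) < 4:
        raise InputFormatError(f"{path}: need at least 4 data rows")
    arr = np.array(rows)
    t, v = arr[:, 0], arr[:, 1]
    if time_unit == "auto":
        time_unit = "ns" if np.ptp(t) > 50.0 else "us"
    if time_unit == "ns":
        t = t / 1000.0
    elif time_unit != "us":
        raise ValueError("time_unit must be 'ns', 'us' or 'auto'")
    i0 = int(np.argmin(np.abs(t)))
    if v[i0] == 0:
        raise InputFormatError(f"{path}: zero signal at zero time")
    return DeerTrace(t, v / v[i0])


def write_trace(path, trace: DeerTrace, time_unit: str = "us") -> None:
    t = trace.t_axis * (1000.0 if time_unit == "ns" else 1.0)
    np.savetxt(path, np.column_stack([t, trace.v]), fmt="%.8g", header=f"t_{time_unit}  V(t)")


# ---------------------------------------------------------------------------
# restraint files: site_i site_j mean_nm sigma_nm [distribution_file]
# ---------------------------------------------------------------------------

def read_restraints(path) -> list:
    """Read a plain-text restraint list; distribution paths are resolved
    relative to the restraint file and loaded eagerly."""
    base = Path(path).parent
    restraints = []
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) not in (4, 5):
            raise InputFormatError(
                f"{path}:{lineno}: expected 'site_i site_j mean_nm sigma_nm [file]'"
            )
        try:
            site_i, site_j = int(parts[0]), int(parts[1])
            mean_nm, sigma_nm = float(parts[2]), float(parts[3])
        except ValueError as err:
            raise InputFormatError(f"{path}:{lineno}: {err}") from None
        dist = None
        if len(parts) == 5:
            dist = read_distribution(base / parts[4])
        try:
            restraints.append(
                GaussianRestraint(
                    site_i=site_i,
                    site_j=site_j,
                    mean=mean_nm / NM_PER_ANGSTROM,
                    sigma=sigma_nm / NM_PER_ANGSTROM,
                    distribution=dist,
                )
            )
        except ValueError as err:
            raise InputFormatError(f"{path}:{lineno}: {err}") from None
    if not restraints:
        raise InputFormatError(f"{path}: no restraints found")
    return restraints


def write_restraints(path, restraints, distribution_dir=None) -> None:
    """Write restraints; full distributions are written as sidecar files."""
    path = Path(path)
    lines = ["# site_i site_j mean_nm sigma_nm [distribution_file]"]
    for idx, r in enumerate(restraints):
        cols = f"{r.site_i} {r.site_j} {r.mean * NM_PER_ANGSTROM:.6g} {r.sigma * NM_PER_ANGSTROM:.6g}"
        if r.distribution is not None:
            ddir = Path(distribution_dir) if distribution_dir else path.parent
            ddir.mkdir(parents=True, exist_ok=True)
            fname = f"ddr_{r.site_i}_{r.site_j}_{idx}.dat"
            write_distribution(ddir / fname, r.distribution)
            rel = (ddir / fname).relative_to(path.parent) if ddir != path.parent else fname
            cols += f" {rel}"
        lines.append(cols)
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# sequences and ensembles
# ---------------------------------------------------------------------------

def read_fasta(path) -> str:
    """First sequence of a FASTA file, uppercase one-letter codes."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputFormatError(f"{path}: no FASTA records")
    return str(records[0].seq).upper()


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_AA1 = {v: k for k, v in _AA3.items()}


def read_ensemble(
    path_pdb, path_pop=None, residue_range: tuple[int, int] | None = None
) -> Ensemble:
    """Read a multi-model PDB plus optional population sidecar.

    Each MODEL becomes one conformer (N/CA/C/O records; CA required).
    ``residue_range=(lo, hi)`` truncates to that 1-based stretch on read
    (e.g. keeping only the folded residues of an anchor structure).  A
    missing population file yields uniform populations with a warning.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(path_pdb))
    conformers = []
    for model in structure:
        chains = list(model)
        residues = [r for ch in chains for r in ch if r.id[0] == " "]
        if residue_range is not None:
            lo, hi = residue_range
            residues = [r for r in residues if lo <= r.id[1] <= hi]
        if not residues:
            raise InputFormatError(f"{path_pdb}: model {model.id} has no residues")
        seq = "".join(_AA1.get(r.get_resname(), "X") for r in residues)
        coords = {}
        for name in ("N", "CA", "C", "O"):
            rows = []
            ok = True
            for r in residues:
                if name in r:
                    rows.append(r[name].get_coord())
                else:
                    ok = False
                    break
            coords[name] = np.array(rows, dtype=float) if ok else None
        if coords["CA"] is None:
            raise InputFormatError(f"{path_pdb}: model {model.id} lacks CA atoms")
        conformers.append(
            Conformer(
                sequence=seq,
                ca=coords["CA"],
                n=coords["N"],
                c=coords["C"],
                o=coords["O"],
                provenance={"model_id": model.id},
            )
        )
    populations = None
    if path_pop is not None and Path(path_pop).exists():
        rows = []
        for lineno, line in _data_lines(path_pop):
            parts = line.split()
            if len(parts) != 2:
                raise InputFormatError(f"{path_pop}:{lineno}: expected 'model_id population'")
            rows.append(float(parts[1]))
        if len(rows) != len(conformers):
            raise InputFormatError(
                f"{path_pop}: {len(rows)} rows for {len(conformers)} models"
            )
        populations = np.array(rows)
        if abs(populations.sum() - 1.0) > 1e-6:
            warnings.warn("populations do not sum to 1; renormalizing", stacklevel=2)
    elif path_pop is not None:
        warnings.warn(f"population file {path_pop} not found; using uniform", stacklevel=2)
    return Ensemble(conformers, populations)


def write_ensemble(path_pdb, ensemble: Ensemble, path_pop=None) -> None:
    """Write a multi-model PDB (one MODEL per conformer) plus populations."""
    builder = StructureBuilder()
    builder.init_structure("ens")
    for midx, conf in enumerate(ensemble.conformers):
        builder.init_model(midx)
        builder.init_chain("A")
        builder.init_seg(" ")
        for i, aa in enumerate(conf.sequence):
            builder.init_residue(_AA3.get(aa.upper(), "UNK"), " ", i + 1, " ")
            for name, arr, element in (
                ("N", conf.n, "N"),
                ("CA", conf.ca, "C"),
                ("C", conf.c, "C"),
                ("O", conf.o, "O"),
            ):
                if arr is None:
                    continue
                builder.init_atom(name, arr[i].astype(np.float32), 0.0, 1.0, " ", name, element=element)
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path_pdb))
    if path_pop is not None:
        lines = [
            f"{m} {p:.8g}" for m, p in enumerate(ensemble.populations)
        ]
        Path(path_pop).write_text("\n".join(lines) + "\n")
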