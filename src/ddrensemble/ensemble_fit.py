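"""Ensemble refinement: population fitting by overlap maximization.

Given a raw conformer pool and a set of distance-distribution restraints,
populations are fitted on the probability simplex to maximize the
geometric mean over restraints of the overlap

    o_m(p) = sum_r min{ (A_m p)_r , b_m(r) }

between the forward-modelled distribution ``A_m p`` (population-weighted
sum of per-conformer label distributions) and the experimental
distribution ``b_m``.  The objective ``sum_m log o_m`` is concave in p
(each o_m is a minimum of linear functions summed), so projected
(sub)gradient ascent with a monotone line search finds the global
optimum.  Conformers are admitted in blocks with adaptive block size,
and conformers below a population-fraction threshold are pruned between
blocks, which contracts the ensemble to its informative core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .distributions import DistanceDistribution, geometric_mean_overlap
from .ensemble import Ensemble
from .labels import DEFAULT_LABEL_PARAMS, LabelSurrogateParams, label_distance
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "FitOptions",
    "FitResult",
    "predict_restraint_distribution",
    "fit_populations",
]

_OVERLAP_FLOOR = 1e-6


def predict_restraint_distribution(
    ensemble: Ensemble,
    restraint,
    r_axis: np.ndarray | None = None,
    label_params: LabelSurrogateParams = DEFAULT_LABEL_PARAMS,
) -> DistanceDistribution:
    """Forward-modelled distribution P_pred = sum_i p_i P_i for a site pair."""
    if r_axis is None:
        if restraint.distribution is not None:
            r_axis = restraint.distribution.r_axis
        else:
            from .distributions import default_grid

            r_axis = default_grid()
    a = _conformer_distribution_matrix(ensemble.conformers, restraint, r_axis, label_params)
    p = a @ ensemble.populations
    return DistanceDistribution(np.asarray(r_axis, dtype=float), p).normalize()


def _conformer_distribution_matrix(
    conformers, restraint, r_axis, label_params: LabelSurrogateParams
) -> np.ndarray:
    """Columns are per-conformer label distributions on the restraint grid."""
    r_axis = np.asarray(r_axis, dtype=float)
    dr = r_axis[1] - r_axis[0]
    n_res = conformers[0].n_res
    if not (1 <= restraint.site_i <= n_res and 1 <= restraint.site_j <= n_res):
        raise ValueError(
            f"restraint sites ({restraint.site_i}, {restraint.site_j}) outside "
            f"modeled residues 1..{n_res}"
        )
    dists = np.array(
        [label_distance(c, restraint.site_i, restraint.site_j, label_params) for c in conformers]
    )
    a = np.zeros((r_axis.size, len(conformers)))
    pos = (dists - r_axis[0]) / dr
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    for col, (idx, f) in enumerate(zip(i0, frac)):
        if 0 <= idx < r_axis.size:
            a[idx, col] += 1.0 - f
        if 0 <= idx + 1 < r_axis.size:
            a[idx + 1, col] += f
    sigma_conv = label_params.sigma_conv
    if sigma_conv > 0:
        a = gaussian_filter1d(a, sigma_conv / dr, axis=0, mode="constant")
    col_sums = a.sum(axis=0)
    dead = col_sums <= 0
    if np.any(dead):
        # conformer's label distance falls off the grid entirely
        a[:, dead] = 0.0
        col_sums[dead] = 1.0
    a /= col_sums
    return a


# ---------------------------------------------------------------------------
# simplex solver
# ---------------------------------------------------------------------------

def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    ind = np.arange(1, v.size + 1)
    cond = u - css / ind > 0
    rho = ind[cond][-1]
    theta = css[cond][-1] / rho
    return np.clip(v - theta, 0.0, None)


def _objective(p, mats, targets):
    overlaps = np.array([np.minimum(a @ p, b).sum() for a, b in zip(mats, targets)])
    return float(np.sum(np.log(np.maximum(overlaps, _OVERLAP_FLOOR)))), overlaps


def _gradient(p, mats, targets):
    g = np.zeros_like(p)
    for a, b in zip(mats, targets):
        pred = a @ p
        o = float(np.minimum(pred, b).sum())
        active = pred < b  # subgradient of sum(min) wrt p
        g += (active @ a) / max(o, _OVERLAP_FLOOR)
    return g


def _maximize_on_simplex(mats, targets, p0, max_iter=400, tol=1e-10):
    p = _project_simplex(np.asarray(p0, dtype=float))
    f, _ = _objective(p, mats, targets)
    step = 1.0
    for _ in range(max_iter):
        g = _gradient(p, mats, targets)
        improved = False
        s = step
        for _ in range(30):
            q = _project_simplex(p + s * g)
            fq, _ = _objective(q, mats, targets)
            if fq > f + 1e-14:
                p, f = q, fq
                step = min(s * 2.0, 1e3)
                improved = True
                break
            s *= 0.5
        if not improved:
            break
        if s * np.linalg.norm(g) < tol:
            break
    return p, f


def _nnls_init(mats, targets, n):
    """Stacked nonnegative least squares as a cheap initializer."""
    a = np.vstack(mats)
    b = np.concatenate(targets)
    try:
        x, _ = nnls(a, b, maxiter=max(10 * n, 200))
    except Exception:
        return np.full(n, 1.0 / n)
    if x.sum() <= 0:
        return np.full(n, 1.0 / n)
    return x / x.sum()


@dataclass
class FitOptions:
    block_size: int = 100
    prune_frac: float = 0.01  # prune below this fraction of the max population
    max_iter: int = 400
    label_params: LabelSurrogateParams = field(default_factory=lambda: DEFAULT_LABEL_PARAMS)


@dataclass
class FitResult:
    ensemble: Ensemble | None
    mean_overlap: float
    overlaps: np.ndarray
    n_conformers: int
    history: list
    success: bool
    message: str = ""


def fit_populations(
    raw: Ensemble,
    restraints: list,
    options: FitOptions | None = None,
) -> FitResult:
    """Refine a raw ensemble against distance-distribution restraints.

    Maximizes the geometric mean overlap over the population simplex with
    block-iterative admission of conformers: fit the current block, prune
    conformers below ``prune_frac`` of the most populated one, admit the
    next block, re-fit.  When fewer than 10% of the specified block size
    are free for admission, the block size grows by 50%; when the
    retained count later drops, it resets to the specified value.  The
    returned populations are renormalized to unit sum.

    Restraints must carry full experimental distributions.  If every
    restraint has zero overlap with every conformer (disjoint supports)
    a failure result is returned rather than an exception.
    """
    if options is None:
        options = FitOptions()
    restraints = [r for r in restraints if r.distribution is not None]
    if not restraints:
        raise ValueError("need at least one restraint with a full distribution")

    # per-restraint matrices on the experimental grids
    mats_full = []
    targets = []
    for r in restraints:
        dist = r.distribution.normalize()
        mats_full.append(
            _conformer_distribution_matrix(
                raw.conformers, r, dist.r_axis, options.label_params
            )
        )
        targets.append(dist.p)

    n = len(raw)
    order = np.arange(n)
    block0 = options.block_size
    block = block0
    active: list[int] = []
    p_active = np.zeros(0)
    pos = 0
    history = []
    prev_retained = 0

    while pos < n or not active:
        free = block - len(active)
        if free < max(1, int(0.1 * block0)):
            block = int(round(block * 1.5))
            free = block - len(active)
        admit = order[pos : pos + free]
        pos += len(admit)
        if len(admit) == 0 and pos >= n:
            break
        active = list(active) + list(admit)
        mats = [m[:, active] for m in mats_full]
        if p_active.size:
            p0 = np.concatenate([p_active, np.zeros(len(admit))])
            # keep the warm start feasible but give new conformers a foothold
            p0 = 0.95 * p0 + 0.05 / len(active)
        else:
            p0 = _nnls_init(mats, targets, len(active))
            p0 = 0.9 * p0 + 0.1 / len(active)
        p_fit, _ = _maximize_on_simplex(mats, targets, p0, max_iter=options.max_iter)
        _, overlaps = _objective(p_fit, mats, targets)
        obar = geometric_mean_overlap(np.maximum(overlaps, _OVERLAP_FLOOR)) if np.all(
            overlaps > 0
        ) else 0.0
        # prune low-population conformers
        keep = p_fit >= options.prune_frac * p_fit.max()
        active = [a for a, k in zip(active, keep) if k]
        p_active = p_fit[keep]
        p_active = p_active / p_active.sum()
        history.append(
            {
                "admitted": int(len(admit)),
                "retained": len(active),
                "block": block,
                "mean_overlap": obar,
            }
        )
        if prev_retained and len(active) < prev_retained:
            block = block0
        prev_retained = len(active)
        if pos >= n:
            break

    # final re-fit on the retained set, iterated with pruning until the
    # population-fraction threshold holds at the optimum
    for _ in range(5):
        mats = [m[:, active] for m in mats_full]
        p_active, _ = _maximize_on_simplex(mats, targets, p_active, max_iter=options.max_iter)
        p_active = p_active / p_active.sum()
        keep = p_active >= options.prune_frac * p_active.max()
        if keep.all():
            break
        active = [a for a, k in zip(active, keep) if k]
        p_active = p_active[keep]
        p_active = p_active / p_active.sum()
    mats = [m[:, active] for m in mats_full]
    _, overlaps = _objective(p_active, mats, targets)
    if np.all(overlaps <= _OVERLAP_FLOOR):
        return FitResult(
            ensemble=None,
            mean_overlap=0.0,
            overlaps=overlaps,
            n_conformers=0,
            history=history,
            success=False,
            message="all restraint overlaps are zero (disjoint supports)",
        )
    if np.any(overlaps == 0):
        warnings.warn("a restraint has zero overlap with the fitted ensemble", stacklevel=2)
    obar = float(np.exp(np.mean(np.log(np.maximum(overlaps, _OVERLAP_FLOOR)))))
    refined = raw.subset(active, renormalize=False)
    refined.populations = p_active / p_active.sum()
    refined.provenance = dict(raw.provenance)
    refined.provenance.update(
        fit={"mean_overlap": obar, "n_restraints": len(restraints)}
    )
    return FitResult(
        ensemble=refined,
        mean_overlap=obar,
        overlaps=overlaps,
        n_conformers=len(active),
        history=history,
        success=True,
    )
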