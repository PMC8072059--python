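"""Forward DEER signal model and inversion to distance distributions.

The dipolar evolution signal of a 4-pulse DEER experiment on a pair of
nitroxide labels is modelled with a multi-pathway kernel

    K(t, r) = [L0 + l1 K0(t, r) + l2 K0(t - T02, r)]
              * exp(-k (l1 |t| + l2 |t - T02|))

where ``K0`` is the elementary powder-averaged dipolar kernel, ``L0`` the
unmodulated amplitude, ``l1``/``l2`` the amplitudes of the two modulated
dipolar pathways, ``T02`` the refocusing time of the second pathway, and
``k`` the exponential background decay rate (homogeneous 3D distribution
of remote labels).

Inversion of the measured trace to ``P(r)`` is ill-posed; it is done
either by parametric fitting (single Gaussian, SAW-nu, or multi-Gaussian
with AIC/BIC component-count selection) or by Tikhonov regularization
with nonnegativity, with the regularization parameter chosen by AIC, BIC
or the discrepancy (residual) principle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.special import fresnel

from .distributions import (
    DistanceDistribution,
    GaussianParams,
    SawNuParams,
    default_grid,
    gaussian_pdf,
    saw_nu_pdf,
)

__all__ = [
    "DeerTrace",
    "PathwayModel",
    "elementary_kernel",
    "multipathway_signal",
    "fit_parametric",
    "tikhonov",
]

#: dipolar frequency constant: nu_dd = 52.04 MHz at r = 1 nm (10 A)
DIPOLAR_MHZ_NM3 = 52.04


@dataclass(eq=False)
class DeerTrace:
    """Phase/zero-time corrected dipolar evolution trace V(t).

    t_axis is in microseconds (may start at or below zero); v is the real
    signal, normalized to 1 at zero time on load.
    """

    t_axis: np.ndarray
    v: np.ndarray
    noise_estimate: float | None = None

    def __post_init__(self) -> None:
        self.t_axis = np.asarray(self.t_axis, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t_axis.ndim != 1 or self.t_axis.shape != self.v.shape:
            raise ValueError("t_axis and v must be matching 1-D arrays")
        if np.any(np.diff(self.t_axis) <= 0):
            raise ValueError("t_axis must be strictly increasing")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("signal contains non-finite values")

    def estimate_noise(self) -> float:
        """Noise level from the second difference of the signal."""
        if self.noise_estimate is not None:
            return self.noise_estimate
        d2 = np.diff(self.v, 2)
        # second difference of white noise has variance 6 sigma^2
        return float(np.std(d2) / math.sqrt(6.0))


@dataclass(frozen=True)
class PathwayModel:
    """Amplitudes and background of the two-pathway DEER kernel."""

    lambda0: float = 0.7
    lambda1: float = 0.3
    lambda2: float = 0.0
    t02: float = 0.0  # refocusing time of the second pathway (us)
    k_bg: float = 0.0  # background decay rate (1/us)

    def __post_init__(self) -> None:
        if min(self.lambda0, self.lambda1, self.lambda2) < 0:
            raise ValueError("pathway amplitudes must be nonnegative")
        if self.lambda0 + self.lambda1 + self.lambda2 > 1.0 + 1e-6:
            raise ValueError("pathway amplitudes must sum to at most 1")
        if self.k_bg < 0:
            raise ValueError("background rate must be nonnegative")


def dipolar_frequency(r_angstrom: np.ndarray) -> np.ndarray:
    """Dipolar frequency nu_dd in MHz for distances in Angstrom."""
    r = np.asarray(r_angstrom, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    return DIPOLAR_MHZ_NM3 / (r / 10.0) ** 3


def elementary_kernel(t_axis: np.ndarray, r_axis: np.ndarray) -> np.ndarray:
    """Elementary dipolar kernel K0(t, r), shape (n_t, n_r).

    K0(t, r) = int_0^1 cos[(1 - 3 z^2) w_dd t] dz, evaluated with the
    Fresnel-integral closed form

        K0 = [cos(w t) C(kappa) + sin(w t) S(kappa)] / kappa,
        kappa = sqrt(6 w t / pi),

    which equals the powder average over label-pair orientations.  K0 is
    even in t and K0(0, r) = 1.
    """
    t = np.abs(np.asarray(t_axis, dtype=float))[:, None]  # us
    w = 2.0 * math.pi * dipolar_frequency(r_axis)[None, :]  # rad/us
    phi = w * t
    kappa = np.sqrt(6.0 * phi / math.pi)
    small = phi < 1e-9
    kappa_safe = np.where(small, 1.0, kappa)
    s, c = fresnel(kappa_safe)
    k0 = (np.cos(phi) * c + np.sin(phi) * s) / kappa_safe
    return np.where(small, 1.0, k0)


def pathway_kernel(
    t_axis: np.ndarray, r_axis: np.ndarray, model: PathwayModel
) -> np.ndarray:
    """Full multi-pathway kernel K(t, r) including background decay."""
    t = np.asarray(t_axis, dtype=float)
    k = model.lambda0 + model.lambda1 * elementary_kernel(t, r_axis)
    if model.lambda2 > 0:
        k = k + model.lambda2 * elementary_kernel(t - model.t02, r_axis)
    decay = np.exp(
        -model.k_bg * (model.lambda1 * np.abs(t) + model.lambda2 * np.abs(t - model.t02))
    )
    return k * decay[:, None]


def multipathway_signal(
    dist: DistanceDistribution, model: PathwayModel, t_axis: np.ndarray
) -> DeerTrace:
    """Forward-model the dipolar trace V(t) = sum_r P(r) K(t, r)."""
    p = dist.p / dist.p.sum()
    k = pathway_kernel(t_axis, dist.r_axis, model)
    return DeerTrace(np.asarray(t_axis, dtype=float), k @ p)


# ---------------------------------------------------------------------------
# parametric inversion
# ---------------------------------------------------------------------------

@dataclass
class ParametricFit:
    """Result of a joint distribution + pathway/background fit."""

    distribution: DistanceDistribution
    dist_params: object  # GaussianParams | SawNuParams | list of (weight, GaussianParams)
    pathway: PathwayModel
    residuals: np.ndarray
    rss: float
    n_params: int
    converged: bool
    n_components: int = 1
    criterion_values: dict | None = None

    def aic(self, n: int) -> float:
        return n * math.log(self.rss / n) + 2 * self.n_params

    def bic(self, n: int) -> float:
        return n * math.log(self.rss / n) + self.n_params * math.log(n)


def _model_signal(theta, t, r_axis, family, n_comp, fit_lambda2):
    """Unpack a parameter vector into a trace model; see _theta_layout."""
    i = 0
    if family == "gaussian" or family == "multi_gaussian":
        p = np.zeros_like(r_axis)
        weights = []
        for _ in range(n_comp):
            w, mean, sigma = theta[i], theta[i + 1], theta[i + 2]
            i += 3
            z = (r_axis - mean) / sigma
            comp = np.exp(-0.5 * z * z)
            s = comp.sum()
            if s > 0:
                p = p + w * comp / s
            weights.append(w)
        wsum = sum(weights)
        if wsum > 0:
            p = p / wsum
    elif family == "saw_nu":
        R, nu = theta[i], theta[i + 1]
        i += 2
        p = saw_nu_pdf(r_axis, SawNuParams(R=R, nu=nu)).p
    else:
        raise ValueError(f"unknown model family {family!r}")
    lam0, lam1, k_bg = theta[i], theta[i + 1], theta[i + 2]
    i += 3
    lam2, t02 = (theta[i], theta[i + 1]) if fit_lambda2 else (0.0, 0.0)
    # evaluate from raw floats: trial points may transiently violate the
    # amplitude-sum invariant enforced by PathwayModel
    k = lam0 + lam1 * elementary_kernel(t, r_axis)
    if lam2 > 0:
        k = k + lam2 * elementary_kernel(t - t02, r_axis)
    decay = np.exp(-k_bg * (lam1 * np.abs(t) + lam2 * np.abs(t - t02)))
    params = (lam0, lam1, lam2, t02, k_bg)
    return (k * decay[:, None]) @ p, p, params


def fit_parametric(
    trace: DeerTrace,
    model_family: str = "gaussian",
    r_axis: np.ndarray | None = None,
    n_max: int = 4,
    criterion: str = "bic",
    fit_lambda2: bool = False,
    n_starts: int = 4,
    seed: int = 0,
) -> ParametricFit:
    """Joint nonlinear fit of distribution and pathway/background parameters.

    model_family is 'gaussian', 'saw_nu' or 'multi_gaussian'; for the
    latter the component count is chosen over 1..n_max by AIC or BIC.
    Multi-start (randomized initializations) guards against local minima;
    non-convergence is flagged in the result, never silent.
    """
    if r_axis is None:
        r_axis = default_grid()
    r_axis = np.asarray(r_axis, dtype=float)
    t, v = trace.t_axis, trace.v
    n = t.size
    rng = np.random.default_rng(seed)

    def fit_one(family, n_comp):
        # layout: per-component (w, mean, sigma) | (R, nu); then L0, l1, k; [l2, T02]
        lo, hi, x0s = [], [], []
        base_mean = 0.5 * (r_axis[0] + r_axis[-1])
        span = r_axis[-1] - r_axis[0]
        if family in ("gaussian", "multi_gaussian"):
            for c in range(n_comp):
                lo += [0.0, r_axis[0], 1.0]
                hi += [1.0, r_axis[-1], span]
        else:
            lo += [5.0, 0.2]
            hi += [r_axis[-1], 0.95]
        lo += [0.0, 0.0, 0.0]
        hi += [1.0, 1.0, 2.0]
        if fit_lambda2:
            lo += [0.0, 0.5 * t[-1]]
            hi += [0.3, 1.2 * t[-1]]
        lo, hi = np.array(lo), np.array(hi)

        for s in range(n_starts):
            x0 = []
            if family in ("gaussian", "multi_gaussian"):
                for c in range(n_comp):
                    frac = (c + 0.5 + 0.3 * rng.standard_normal()) / n_comp
                    frac = min(max(frac, 0.05), 0.95)
                    x0 += [1.0 / n_comp, r_axis[0] + frac * span, 0.1 * span]
            else:
                x0 += [base_mean * (0.8 + 0.4 * rng.random()), 0.4 + 0.4 * rng.random()]
            mod_depth = max(1.0 - v.min(), 0.1)
            x0 += [max(1.0 - mod_depth, 0.05), min(mod_depth, 0.9), 0.05]
            if fit_lambda2:
                x0 += [0.02, t[-1]]
            x0 = np.clip(np.array(x0), lo, hi)

            def residual(theta):
                sig, _, _ = _model_signal(theta, t, r_axis, family, n_comp, fit_lambda2)
                return sig - v

            try:
                sol = least_squares(residual, x0, bounds=(lo, hi), max_nfev=400)
            except Exception:  # keep multi-start robust to degenerate starts
                continue
            yield sol

    def best_fit(family, n_comp):
        best = None
        for sol in fit_one(family, n_comp):
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            return None
        sig, p, (lam0, lam1, lam2, t02, k_bg) = _model_signal(
            best.x, t, r_axis, family, n_comp, fit_lambda2
        )
        amp_sum = lam0 + lam1 + lam2
        if amp_sum > 1.0:  # renormalize a marginally unphysical optimum
            lam0, lam1, lam2 = lam0 / amp_sum, lam1 / amp_sum, lam2 / amp_sum
        model = PathwayModel(
            lambda0=float(lam0), lambda1=float(lam1), lambda2=float(lam2),
            t02=float(t02), k_bg=float(k_bg),
        )
        res = sig - v
        n_params = best.x.size
        comps = None
        if family in ("gaussian", "multi_gaussian"):
            comps = []
            for c in range(n_comp):
                w, mean, sigma = best.x[3 * c : 3 * c + 3]
                comps.append((float(w), GaussianParams(mean=float(mean), sigma=float(sigma))))
            wsum = sum(w for w, _ in comps)
            comps = [(w / wsum, g) for w, g in comps]
            dist_params = comps[0][1] if n_comp == 1 else comps
        else:
            dist_params = SawNuParams(R=float(best.x[0]), nu=float(best.x[1]))
        dist = DistanceDistribution(r_axis, p).normalize()
        return ParametricFit(
            distribution=dist,
            dist_params=dist_params,
            pathway=model,
            residuals=res,
            rss=float(np.dot(res, res)),
            n_params=n_params,
            converged=bool(best.success),
            n_components=n_comp,
        )

    if model_family in ("gaussian", "saw_nu"):
        fit = best_fit(model_family, 1)
        if fit is None:
            raise RuntimeError("all fit starts failed")
        return fit

    if model_family != "multi_gaussian":
        raise ValueError(f"unknown model family {model_family!r}")

    crit_values = {}
    best_fit_obj, best_crit = None, np.inf
    for n_comp in range(1, n_max + 1):
        fit = best_fit("multi_gaussian", n_comp)
        if fit is None:
            continue
        crit = fit.aic(n) if criterion == "aic" else fit.bic(n)
        crit_values[n_comp] = crit
        if crit < best_crit - 1e-12:
            best_crit, best_fit_obj = crit, fit
    if best_fit_obj is None:
        raise RuntimeError("multi-Gaussian fit failed for all component counts")
    best_fit_obj.criterion_values = crit_values
    return best_fit_obj


# ---------------------------------------------------------------------------
# Tikhonov regularization
# ---------------------------------------------------------------------------

def _second_difference(n: int) -> np.ndarray:
    l = np.zeros((n - 2, n))
    for i in range(n - 2):
        l[i, i : i + 3] = (1.0, -2.0, 1.0)
    return l


def _tikhonov_solve(kmat, f, l, alpha):
    a = np.vstack([kmat, alpha * l])
    b = np.concatenate([f, np.zeros(l.shape[0])])
    p, _ = nnls(a, b)
    return p


def _effective_dof(kmat, l, alpha):
    # influence-matrix trace of the unconstrained regularized solution
    m = kmat.T @ kmat + alpha**2 * (l.T @ l)
    try:
        h = kmat @ np.linalg.solve(m, kmat.T)
    except np.linalg.LinAlgError:
        h = kmat @ np.linalg.lstsq(m, kmat.T, rcond=None)[0]
    return float(np.trace(h))


def tikhonov(
    trace: DeerTrace,
    alpha: float | str = "aic",
    model: PathwayModel | str = "fit",
    r_axis: np.ndarray | None = None,
    alpha_grid: np.ndarray | None = None,
) -> tuple[DistanceDistribution, float, dict]:
    """Tikhonov-regularized inversion of a DEER trace.

    Solves ``min ||K P - F||^2 + alpha^2 ||L P||^2`` subject to ``P >= 0``
    with L the second-difference operator, on the background-corrected
    dipolar signal F.  ``alpha`` may be a number or one of 'aic', 'bic',
    'residual' (discrepancy principle), evaluated over a log-spaced grid.
    ``model='fit'`` pre-fits pathway/background parameters with a single
    Gaussian model.

    Returns (distribution, alpha_used, diagnostics).
    """
    if r_axis is None:
        r_axis = default_grid()
    r_axis = np.asarray(r_axis, dtype=float)

    if model == "fit":
        pre = fit_parametric(trace, "gaussian", r_axis=r_axis)
        model = pre.pathway
    if not isinstance(model, PathwayModel):
        raise TypeError("model must be a PathwayModel or 'fit'")

    t, v = trace.t_axis, trace.v
    # background/unmodulated correction: F = (V / B - L0) / l1
    decay = np.exp(
        -model.k_bg
        * (model.lambda1 * np.abs(t) + model.lambda2 * np.abs(t - model.t02))
    )
    f = v / decay - model.lambda0
    kmat = model.lambda1 * elementary_kernel(t, r_axis)
    if model.lambda2 > 0:
        kmat = kmat + model.lambda2 * elementary_kernel(t - model.t02, r_axis)

    # ill-conditioning warning: less than one dipolar period observed
    nu_mode = dipolar_frequency(np.array([r_axis[np.argmax(kmat.sum(axis=0))]]))[0]
    t_span = t[-1] - max(t[0], 0.0)
    diagnostics: dict = {}
    l = _second_difference(r_axis.size)

    if isinstance(alpha, (int, float)):
        p = _tikhonov_solve(kmat, f, l, float(alpha))
        alpha_used = float(alpha)
    else:
        if alpha not in ("aic", "bic", "residual"):
            raise ValueError("alpha must be a number or 'aic'|'bic'|'residual'")
        if alpha_grid is None:
            alpha_grid = np.logspace(-3, 3, 25)
        n = t.size
        scores = []
        sols = []
        for a in alpha_grid:
            pa = _tikhonov_solve(kmat, f, l, a)
            res = kmat @ pa - f
            rss = float(np.dot(res, res))
            dof = _effective_dof(kmat, l, a)
            if alpha == "aic":
                score = n * math.log(max(rss, 1e-300) / n) + 2 * dof
            elif alpha == "bic":
                score = n * math.log(max(rss, 1e-300) / n) + dof * math.log(n)
            else:  # residual / discrepancy principle
                sigma = trace.estimate_noise()
                score = abs(rss - n * sigma**2)
            scores.append(score)
            sols.append(pa)
        best = int(np.argmin(scores))
        p = sols[best]
        alpha_used = float(alpha_grid[best])
        diagnostics["alpha_grid"] = np.asarray(alpha_grid)
        diagnostics["alpha_scores"] = np.asarray(scores)

    if p.sum() <= 0:
        raise RuntimeError("Tikhonov solution is identically zero")
    dist = DistanceDistribution(r_axis, p).normalize()
    mode_r = r_axis[int(np.argmax(dist.p))]
    if t_span * dipolar_frequency(np.array([mode_r]))[0] < 1.0:
        warnings.warn(
            "maximum observation time below one dipolar period at the "
            "distribution mode; long-distance shape is unreliable",
            stacklevel=2,
        )
    res = kmat @ p - f
    diagnostics.update(
        rss=float(np.dot(res, res)),
        residuals=res,
        model=model,
        nu_mode_mhz=float(nu_mode),
    )
    return dist, alpha_used, diagnostics
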