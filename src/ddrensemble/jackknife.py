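"""Jack-knife (leave-one-restraint-out) validation of a restraint set.

For each of the n_r restraints, a fresh raw ensemble is generated and
population-fitted with the remaining n_r - 1 restraints, and the
distance distribution of the omitted restraint is predicted from the
resulting ensemble.  Good agreement of every left-out prediction with
its experiment indicates that the restraint set is internally consistent
and large enough; a restraint whose left-out overlap falls far below the
others (flag rule: below median - 2 MAD) is an outlier candidate,
e.g. a label that biased the conformation.

The leave-one-out ensembles are then merged into a "super-ensemble"
basis — conformers consistent with at least n_r - 1 restraints — and a
final fit against the full restraint set on this enlarged basis usually
improves on the initial fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import overlap
from .ensemble import Ensemble
from .ensemble_fit import FitOptions, FitResult, fit_populations, predict_restraint_distribution
from .labels import DEFAULT_LABEL_PARAMS
from .sampler import SamplerConfig, SamplingError, build_raw_ensemble

__all__ = ["JackknifeReport", "run_jackknife", "build_super_ensemble", "final_refit"]


@dataclass
class JackknifeEntry:
    left_out_index: int
    predicted_distribution: object
    left_out_overlap: float
    n_conformers: int
    mean_overlap: float
    failed: bool = False
    message: str = ""


@dataclass
class JackknifeReport:
    entries: list
    outlier_flags: list = field(default_factory=list)

    @property
    def left_out_overlaps(self) -> np.ndarray:
        return np.array(
            [e.left_out_overlap for e in self.entries if not e.failed]
        )

    def flag_outliers(self) -> list:
        """Indices of restraints with left-out overlap < median - 2 MAD."""
        o = self.left_out_overlaps
        if o.size < 3:
            return []
        med = np.median(o)
        mad = np.median(np.abs(o - med))
        cut = med - 2.0 * mad
        flags = [
            e.left_out_index
            for e in self.entries
            if not e.failed and e.left_out_overlap < cut
        ]
        self.outlier_flags = flags
        return flags


def run_jackknife(
    sequence: str,
    library,
    restraints: list,
    anchor_models: list | None = None,
    n_target: int = 400,
    master_seed: int = 0,
    fit_options: FitOptions | None = None,
    sampler_config: SamplerConfig | None = None,
    label_params=DEFAULT_LABEL_PARAMS,
) -> tuple[JackknifeReport, list]:
    """Leave-one-restraint-out resampling over the full restraint set.

    Each of the n_r sub-runs generates a raw ensemble from the reduced
    restraint set, fits populations against it, and predicts the omitted
    distribution.  Sub-run seeds are spawned deterministically from the
    master seed, so the whole resampling is reproducible.  A sub-run
    sampling failure is recorded in its entry, not fatal.

    Returns (report, list of refined leave-one-out ensembles).
    """
    n_r = len(restraints)
    if n_r < 2:
        raise ValueError("jackknife needs at least 2 restraints")
    if fit_options is None:
        fit_options = FitOptions(label_params=label_params)
    seeds = np.random.SeedSequence(master_seed).spawn(n_r)
    entries = []
    ensembles = []
    for m in range(n_r):
        reduced = restraints[:m] + restraints[m + 1 :]
        rng = np.random.default_rng(seeds[m])
        try:
            raw = build_raw_ensemble(
                sequence,
                library,
                reduced,
                anchor_models=anchor_models,
                n_target=n_target,
                rng_seed=rng,
                label_params=label_params,
                config=sampler_config,
            )
        except SamplingError as err:
            entries.append(
                JackknifeEntry(m, None, float("nan"), 0, float("nan"), True, str(err))
            )
            continue
        fit = fit_populations(raw, reduced, fit_options)
        if not fit.success:
            entries.append(
                JackknifeEntry(m, None, float("nan"), 0, float("nan"), True, fit.message)
            )
            continue
        left_out = restraints[m]
        pred = predict_restraint_distribution(
            fit.ensemble, left_out, label_params=fit_options.label_params
        )
        o = overlap(pred, left_out.distribution.normalize())
        entries.append(
            JackknifeEntry(
                m, pred, float(o), fit.n_conformers, fit.mean_overlap
            )
        )
        ensembles.append(fit.ensemble)
    report = JackknifeReport(entries=entries)
    report.flag_outliers()
    return report, ensembles


def build_super_ensemble(leave_one_out_ensembles: list, initial_ensemble: Ensemble | None = None) -> Ensemble:
    """Merge leave-one-out ensembles (plus the initial fit) into one basis.

    Each sub-ensemble's populations are scaled by 1/(number of merged
    ensembles) and the result renormalized to unit sum.
    """
    pool = list(leave_one_out_ensembles)
    if initial_ensemble is not None:
        pool.append(initial_ensemble)
    if not pool:
        raise ValueError("need at least one ensemble to merge")
    conformers = []
    pops = []
    scale = 1.0 / len(pool)
    for ens in pool:
        conformers.extend(ens.conformers)
        pops.extend(scale * ens.populations)
    return Ensemble(conformers, np.array(pops), provenance={"merged_from": len(pool)})


def final_refit(
    super_basis: Ensemble, all_restraints: list, fit_options: FitOptions | None = None
) -> FitResult:
    """Fit the full restraint set on the merged conformer basis."""
    return fit_populations(super_basis, all_restraints, fit_options)
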