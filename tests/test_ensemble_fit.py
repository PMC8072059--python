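"""Population fitting by geometric-mean-overlap maximization."""

import itertools

import numpy as np
import pytest

import ddrensemble as dd
from ddrensemble.ensemble_fit import (
    FitOptions,
    _conformer_distribution_matrix,
    _objective,
    fit_populations,
    predict_restraint_distribution,
)
from ddrensemble.labels import DEFAULT_LABEL_PARAMS, label_distance_distribution


class TestPredictRestraintDistribution:
    def test_single_conformer_equals_label_distribution(self, three_conformer_truth):
        truth, restraints = three_conformer_truth
        single = dd.Ensemble([truth.conformers[0]])
        r = restraints[0]
        pred = predict_restraint_distribution(single, r)
        direct = label_distance_distribution(
            single, r.site_i, r.site_j, r.distribution.r_axis
        )
        assert dd.overlap(pred, direct) == pytest.approx(1.0, abs=1e-9)

    def test_5050_mixture_is_bimodal_with_equal_masses(self):
        c1 = dd.Conformer(sequence="AAA", ca=np.array([[0.0, 0, 0], [3.8, 0, 0], [25.0, 0, 0]]))
        c2 = dd.Conformer(sequence="AAA", ca=np.array([[0.0, 0, 0], [3.8, 0, 0], [45.0, 0, 0]]))
        ens = dd.Ensemble([c1, c2])
        r_axis = dd.default_grid(10, 60, 0.5)
        restraint = dd.GaussianRestraint(1, 3, mean=35.0, sigma=10.0)
        pred = predict_restraint_distribution(ens, restraint, r_axis)
        mid = r_axis.size // 2
        assert pred.p[: mid].sum() == pytest.approx(0.5, abs=0.01)
        assert pred.p[mid:].sum() == pytest.approx(0.5, abs=0.01)

    def test_matches_brute_force_population_sum(self, three_conformer_truth):
        truth, restraints = three_conformer_truth
        r = restraints[1]
        pred = predict_restraint_distribution(truth, r)
        brute = np.zeros(r.distribution.r_axis.size)
        for w, conf in zip(truth.populations, truth.conformers):
            single = dd.Ensemble([conf])
            brute += w * label_distance_distribution(
                single, r.site_i, r.site_j, r.distribution.r_axis
            ).p
        np.testing.assert_allclose(pred.p, brute / brute.sum(), atol=1e-12)

    def test_sites_outside_model_rejected(self, three_conformer_truth):
        truth, _ = three_conformer_truth
        bad = dd.GaussianRestraint(1, 99, mean=30.0, sigma=5.0)
        with pytest.raises(ValueError):
            predict_restraint_distribution(truth, bad, dd.default_grid())


class TestSelfRecovery:
    def test_populations_recovered_from_own_restraints(self, three_conformer_truth):
        truth, restraints = three_conformer_truth
        raw = dd.Ensemble(list(truth.conformers))  # uniform start
        res = fit_populations(raw, restraints, FitOptions(block_size=10))
        assert res.success
        assert res.mean_overlap >= 0.99
        np.testing.assert_allclose(
            res.ensemble.populations, [0.5, 0.3, 0.2], atol=0.05
        )

    def test_solver_matches_simplex_grid_search(self, three_conformer_truth):
        # exhaustive 0.01-resolution simplex enumeration as the oracle
        truth, restraints = three_conformer_truth
        raw = dd.Ensemble(list(truth.conformers))
        res = fit_populations(raw, restraints, FitOptions(block_size=10))
        mats = [
            _conformer_distribution_matrix(
                truth.conformers, r, r.distribution.r_axis, DEFAULT_LABEL_PARAMS
            )
            for r in restraints
        ]
        targets = [r.distribution.normalize().p for r in restraints]
        best = -np.inf
        steps = np.arange(0, 101)
        for a in steps:
            for b in range(0, 101 - a):
                p = np.array([a, b, 100 - a - b]) / 100.0
                f, _ = _objective(p, mats, targets)
                best = max(best, f)
        obar_grid = np.exp(best / len(restraints))
        assert res.mean_overlap >= obar_grid - 1e-3

    def test_duplicate_conformers_constrained_at_sum_level(self, three_conformer_truth):
        truth, restraints = three_conformer_truth
        res_plain = fit_populations(
            dd.Ensemble(list(truth.conformers)), restraints, FitOptions(block_size=10)
        )
        dup = dd.Ensemble(list(truth.conformers) + [truth.conformers[0]])
        res_dup = fit_populations(dup, restraints, FitOptions(block_size=10, prune_frac=0.0001))
        # population of conformer 0 splits arbitrarily between the twins;
        # only the sum is identifiable
        twin_sum = sum(
            p
            for conf, p in zip(res_dup.ensemble.conformers, res_dup.ensemble.populations)
            if conf is truth.conformers[0]
        )
        assert twin_sum == pytest.approx(res_plain.ensemble.populations[0], abs=0.05)
        assert res_dup.mean_overlap == pytest.approx(res_plain.mean_overlap, abs=1e-3)


class TestBlockIteration:
    def test_objective_never_decreases_across_blocks(self, truth_ensemble, truth_restraints):
        raw = dd.Ensemble(list(truth_ensemble.conformers))
        res = fit_populations(raw, truth_restraints, FitOptions(block_size=20))
        obars = [h["mean_overlap"] for h in res.history]
        assert all(b >= a - 1e-6 for a, b in zip(obars, obars[1:]))

    def test_block_growth_when_few_slots_free(self, truth_ensemble, truth_restraints):
        raw = dd.Ensemble(list(truth_ensemble.conformers))
        res = fit_populations(
            raw, truth_restraints, FitOptions(block_size=10, prune_frac=0.0)
        )
        # with pruning off the block must have grown beyond its nominal size
        assert any(h["block"] > 10 for h in res.history)

    def test_populations_sum_to_one(self, truth_ensemble, truth_restraints):
        raw = dd.Ensemble(list(truth_ensemble.conformers))
        res = fit_populations(raw, truth_restraints, FitOptions(block_size=25))
        assert abs(res.ensemble.populations.sum() - 1.0) < 1e-9
        assert np.all(res.ensemble.populations >= 0)

    def test_pruning_threshold_enforced(self, truth_ensemble, truth_restraints):
        raw = dd.Ensemble(list(truth_ensemble.conformers))
        res = fit_populations(raw, truth_restraints, FitOptions(block_size=25, prune_frac=0.01))
        pops = res.ensemble.populations
        assert pops.min() >= 0.01 * pops.max() - 1e-12


class TestFailureModes:
    def test_disjoint_supports_yield_failure_object(self):
        conf = dd.Conformer(
            sequence="AAA", ca=np.array([[0.0, 0, 0], [3.8, 0, 0], [20.0, 0, 0]])
        )
        raw = dd.Ensemble([conf])
        # experimental distribution far outside anything the conformer
        # can produce: support disjoint from the predicted one
        r_axis = dd.default_grid(10, 120, 0.5)
        p = np.zeros(r_axis.size)
        p[r_axis > 110] = 1.0
        far = dd.DistanceDistribution(r_axis, p).normalize()
        restraint = dd.GaussianRestraint(
            1, 3, mean=115.0, sigma=1.0, distribution=far
        )
        res = fit_populations(raw, [restraint], FitOptions(block_size=5))
        assert not res.success
        assert res.ensemble is None

    def test_requires_full_distributions(self, three_conformer_truth):
        truth, _ = three_conformer_truth
        bare = dd.GaussianRestraint(2, 20, mean=25.0, sigma=5.0)
        with pytest.raises(ValueError):
            fit_populations(dd.Ensemble(list(truth.conformers)), [bare])
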