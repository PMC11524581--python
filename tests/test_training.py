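"""Trainer, baselines, cross-validation, and the correlation-length sweep."""

import numpy as np
import pytest

from seqdyn import (
    AMINO_ACIDS,
    ModelParameters,
    OneResidueRegressor,
    SeqDynRegressor,
    SyntheticSpec,
    apply_uniform_scaling,
    default_true_params,
    fit_scale,
    generate_dataset,
    kfold_cv,
    loocv,
    null_model_eval,
    objective,
    one_residue_model,
    pooled_msr2,
    protein_stats,
    sweep_fixed_lcorr,
    train,
)
from seqdyn.records import ProteinRecord


def true_scales(dataset):
    return {r.id: r.scale for r in dataset}


class TestObjective:
    def test_zero_on_noiseless_generating_parameters(self, noiseless_dataset, true_params):
        assert objective(true_params, true_scales(noiseless_dataset), noiseless_dataset) == pytest.approx(0.0, abs=1e-20)

    def test_perturbing_q_strictly_increases_cost(self, noiseless_dataset, true_params):
        q = dict(true_params.q)
        q["G"] *= 1.1
        perturbed = ModelParameters(q=q, b=true_params.b)
        assert objective(perturbed, true_scales(noiseless_dataset), noiseless_dataset) > 0.0

    def test_invariant_to_dataset_ordering(self, noisy_dataset, true_params):
        scales = true_scales(noisy_dataset)
        forward = objective(true_params, scales, noisy_dataset)
        backward = objective(true_params, scales, list(reversed(noisy_dataset)))
        assert forward == pytest.approx(backward, rel=1e-14)


class TestFitScale:
    def test_exact_multiple(self, rng):
        u = rng.uniform(0.5, 2.0, 30)
        assert fit_scale(u, 2.5 * u) == pytest.approx(2.5)

    def test_residual_orthogonal_to_profile(self, rng):
        u = rng.uniform(0.5, 2.0, 50)
        m = rng.uniform(1.0, 5.0, 50)
        scale = fit_scale(u, m)
        assert np.dot(m - scale * u, u) == pytest.approx(0.0, abs=1e-9)

    def test_flat_profile_gives_mean(self):
        assert fit_scale(np.array([1.0, 1.0]), np.array([3.0, 5.0])) == pytest.approx(4.0)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            fit_scale(np.zeros(3), np.ones(3))


class TestTrain:
    def test_recovers_generating_parameters_noiseless(self, noiseless_dataset, true_params):
        result = train(noiseless_dataset)
        assert result.converged
        for aa in AMINO_ACIDS:
            assert result.params.q[aa] == pytest.approx(true_params.q[aa], abs=1e-2)
        assert result.params.b == pytest.approx(true_params.b, abs=1e-3)
        for record in noiseless_dataset:
            assert result.scales[record.id] == pytest.approx(record.scale, rel=1e-3)

    def test_refit_from_optimum_is_stationary(self, small_noisy_dataset):
        first = train(small_noisy_dataset)
        second = train(
            small_noisy_dataset,
            init_params=first.params,
            init_scales=first.scales,
        )
        assert second.cost == pytest.approx(first.cost, abs=1e-6)

    def test_uniform_scaling_doubles_scales_only(self, small_noisy_dataset):
        """x2 on every measurement leaves q and b unchanged, doubles scales —
        the invariance that justifies mixing temperatures and fields."""
        base = train(small_noisy_dataset)
        doubled_data = [apply_uniform_scaling(r, 2.0) for r in small_noisy_dataset]
        doubled = train(doubled_data)
        for aa in AMINO_ACIDS:
            assert doubled.params.q[aa] == pytest.approx(base.params.q[aa], abs=1e-4)
        assert doubled.params.b == pytest.approx(base.params.b, rel=1e-3)
        for pid in base.scales:
            assert doubled.scales[pid] == pytest.approx(2.0 * base.scales[pid], rel=1e-4)

    def test_deterministic_given_inputs(self, small_noisy_dataset):
        a = train(small_noisy_dataset)
        b = train(small_noisy_dataset)
        assert a.to_json() == b.to_json()

    def test_cost_equals_objective_at_returned_point(self, small_noisy_dataset):
        result = train(small_noisy_dataset)
        recomputed = objective(result.params, result.scales, small_noisy_dataset)
        assert result.cost == pytest.approx(recomputed, rel=1e-10)

    def test_nonconvergence_is_flagged_not_raised(self, small_noisy_dataset):
        result = train(small_noisy_dataset, max_iter=2)
        assert result.converged is False

    def test_single_protein_fit_warns_and_reproduces_profile(self, noiseless_dataset):
        with pytest.warns(UserWarning, match="single protein"):
            result = train(noiseless_dataset[:1])
        only = noiseless_dataset[0]
        assert result.per_protein_rmse[only.id] < 0.02

    def test_fit_result_round_trips_through_json(self, small_noisy_dataset):
        result = train(small_noisy_dataset)
        again = type(result).from_json(result.to_json())
        assert again.params.q == result.params.q
        assert again.cost == result.cost


class TestBaselines:
    def test_null_model_equals_sd(self, noisy_dataset):
        per, mean = null_model_eval(noisy_dataset)
        for record in noisy_dataset:
            assert per[record.id] == pytest.approx(protein_stats(record).sd_r2, rel=1e-14)
        assert mean == pytest.approx(np.mean(list(per.values())))

    def test_single_protein_mean_is_its_sd(self, noisy_dataset):
        _, mean = null_model_eval(noisy_dataset[:1])
        assert mean == pytest.approx(protein_stats(noisy_dataset[0]).sd_r2)

    def test_homopolymer_eval_rmse_equals_sd(self, noisy_dataset, rng):
        """One amino-acid type carries no shape: the one-residue prediction is
        flat, so its RMSE is the measured sd."""
        values = rng.uniform(1.0, 4.0, 50)
        homo = ProteinRecord(id="homo", sequence="G" * 50, measured_r2=values)
        per = one_residue_model(noisy_dataset, [homo])
        assert per["homo"] == pytest.approx(protein_stats(homo).sd_r2, rel=1e-10)

    def test_one_residue_equals_full_model_large_b_with_msr2_q(self, noisy_dataset):
        """With q pinned at msR2 and negligible coupling range, the full model
        collapses onto the one-residue baseline."""
        msr2 = pooled_msr2(noisy_dataset)
        q = {aa: msr2.msr2.get(aa, msr2.grand_mean) for aa in AMINO_ACIDS}
        collapsed = SeqDynRegressor()
        collapsed.q_ = np.array([q[aa] for aa in AMINO_ACIDS])
        collapsed.b_ = 1e8
        baseline = OneResidueRegressor().fit(noisy_dataset)
        for record in noisy_dataset[:5]:
            assert collapsed.heldout_rmse(record) == pytest.approx(
                baseline.heldout_rmse(record), rel=1e-4
            )

    def test_one_residue_rmse_scales_linearly_with_measurements(self, noisy_dataset):
        eval_base = noisy_dataset[:3]
        eval_scaled = [apply_uniform_scaling(r, 3.0) for r in eval_base]
        base = one_residue_model(noisy_dataset, eval_base)
        scaled = one_residue_model(noisy_dataset, eval_scaled)
        for pid in base:
            assert scaled[pid] == pytest.approx(3.0 * base[pid], rel=1e-10)


class TestLoocv:
    def test_noiseless_heldout_rmse_near_zero(self, noiseless_dataset):
        report = loocv(noiseless_dataset)
        assert len(report.per_protein_rmse_heldout) == len(noiseless_dataset)
        assert report.mean_rmse_heldout < 1e-4

    def test_heldout_not_better_than_insample_on_average(self, noisy_dataset):
        insample = np.mean(list(train(noisy_dataset).per_protein_rmse.values()))
        report = loocv(noisy_dataset)
        assert report.mean_rmse_heldout >= insample - 1e-6

    def test_jackknife_parameters_agree_with_full_training(self, noisy_dataset, true_params):
        """Mean leave-one-out parameters track the full-training parameters
        closely on a well-sized dataset (no single protein dominates)."""
        full = train(noisy_dataset)
        report = loocv(noisy_dataset)
        for aa in AMINO_ACIDS:
            jack = report.param_mean_sd[aa][0]
            assert abs(jack - full.params.q[aa]) / full.params.q[aa] <= 1e-2

    def test_requires_two_proteins(self, noiseless_dataset):
        with pytest.raises(ValueError):
            loocv(noiseless_dataset[:1])


class TestKfold:
    def test_fold_assignment_is_partition(self, small_noisy_dataset):
        report = kfold_cv(small_noisy_dataset, k=3, seed=4)
        assert sorted(report.per_protein_rmse_heldout) == sorted(r.id for r in small_noisy_dataset)
        assert len(report.fold_params) == 3

    def test_k_equal_n_reduces_to_loo_fold_structure(self, small_noisy_dataset):
        n = len(small_noisy_dataset)
        report = kfold_cv(small_noisy_dataset, k=n, seed=0)
        assert len(report.fold_params) == n

    def test_k_larger_than_n_rejected(self, small_noisy_dataset):
        with pytest.raises(ValueError):
            kfold_cv(small_noisy_dataset, k=len(small_noisy_dataset) + 1)

    def test_seed_fixes_fold_assignment(self, small_noisy_dataset):
        a = kfold_cv(small_noisy_dataset, k=3, seed=9)
        b = kfold_cv(small_noisy_dataset, k=3, seed=9)
        assert a.to_json() == b.to_json()

    def test_ttest_calibration_on_equal_true_q(self):
        """Two amino acids sharing the same true q should rarely be declared
        different: at the 0.05 level, a sound test rejects in only a small
        fraction of repeated experiments."""
        q = {aa: 1.0 for aa in AMINO_ACIDS}
        q.update(W=1.25, Y=1.2, R=1.15, L=1.1, G=0.85, S=0.9)
        q["E"] = q["K"] = 1.05  # the equal pair under test
        truth = ModelParameters(q=q, b=3.164e-2)
        rejections = 0
        for seed in range(5):
            data = generate_dataset(
                SyntheticSpec(
                    n_proteins=9,
                    length_range=(40, 70),
                    noise_sd=0.15,
                    true_params=truth,
                    seed=100 + seed,
                )
            )
            report = kfold_cv(data, k=3, seed=seed, q_pairs=[("E", "K")])
            _, p = report.t_tests["E-K"]
            rejections += p < 0.05
        # binomial(5, 0.05): >2 rejections has probability ~1e-3
        assert rejections <= 2


class TestSweep:
    def test_minimum_at_generating_correlation_length(self, noisy_dataset, true_params):
        grid = [0.0, 2.0, 4.0, 5.62, 8.0, 16.0]
        curve = sweep_fixed_lcorr(noisy_dataset, grid)
        best = min(curve, key=curve.get)
        target = min(grid, key=lambda v: abs(v - true_params.lcorr))
        assert best == target

    def test_zero_lcorr_matches_one_residue_model(self, noisy_dataset):
        curve = sweep_fixed_lcorr(noisy_dataset, [0.0])
        baseline = np.mean(list(one_residue_model(noisy_dataset, noisy_dataset).values()))
        # the fitted self-only model can edge below the msR2-pinned baseline
        assert curve[0.0] <= baseline * 1.02
        assert curve[0.0] == pytest.approx(baseline, rel=0.05)

    def test_large_lcorr_approaches_null_from_below(self, small_noisy_dataset):
        curve = sweep_fixed_lcorr(small_noisy_dataset, [200.0])
        _, null_mean = null_model_eval(small_noisy_dataset)
        assert curve[200.0] <= null_mean * (1 + 1e-6)
        assert curve[200.0] >= 0.5 * null_mean  # flat-factor limit, not a fit
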