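"""The four evaluations: matrix structure, seed consistency, randomization
trajectories, and remove-and-debias perturbation mechanics."""

import numpy as np
import pandas as pd
import pytest

import ecgxai.attribution as at
from ecgxai.experiments import (oracle_ranking, perturb_step, random_ranking,
                                run_cascading_randomization, run_inter_method,
                                run_perturbation, run_self_consistency)
from ecgxai.maps import rank_points_abs
from ecgxai.metrics import auroc

LIGHT = at.MethodConfig(ig_steps=16, sg_samples=4, shapley_segments=8,
                        shapley_samples=4, shap_baselines=2)
FAST_METHODS = ["saliency", "gradient_input", "deeplift", "gradcam"]


class TestInterMethod:
    def test_matrix_symmetric_with_unit_diagonal(self, af_setup):
        scores, matrix = run_inter_method(af_setup["clf"], af_setup["records"][:4],
                                          FAST_METHODS, LIGHT)
        m = matrix.to_numpy()
        np.testing.assert_allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert np.all(np.abs(m) <= 1 + 1e-12)
        assert scores.attrs["n_method_failures"] == 0

    def test_ig_and_gradientshap_converge_to_same_path_integral(self, af_setup):
        """With a single zero baseline and no noise, GradientSHAP estimates the
        same integral as IG, so their maps should agree almost perfectly."""
        from ecgxai.maps import similarity
        clf = af_setup["clf"]
        for x in af_setup["records"][:3]:
            ig = at.integrated_gradients(clf, x, None, 64)
            gs = at.gradientshap(clf, x, np.zeros((1,) + x.shape),
                                 n_samples=512, noise_sd=0.0, seed=0)
            assert similarity(ig, gs).value > 0.95

    def test_requires_two_methods(self, af_setup):
        with pytest.raises(ValueError):
            run_inter_method(af_setup["clf"], af_setup["records"][:2], ["saliency"])


class TestSelfConsistency:
    def test_identical_models_as_seed_pair_score_one(self, af_setup):
        models = {0: af_setup["clf"], 1: af_setup["clf"]}
        df = run_self_consistency(models, af_setup["records"][:4],
                                  ["saliency", "gradient_input", "deeplift"], LIGHT)
        assert np.allclose(df["value"], 1.0, atol=1e-12)

    def test_pair_count_is_s_choose_2(self, af_setup):
        models = {s: af_setup["clf"] for s in range(4)}
        df = run_self_consistency(models, af_setup["records"][:2],
                                  ["saliency"], LIGHT)
        assert len(df) == 2 * 1 * 6          # 2 records x 1 method x C(4,2)

    def test_untrained_models_show_low_signed_consistency(self):
        import ecgxai as ex
        cfg = ex.ModelConfig(n_conv_layers=4, base_channels=8, input_length=600,
                             dropout_rate=0.0)
        models = {s: ex.build_model(cfg, init_seed=s) for s in range(3)}
        rng = np.random.default_rng(0)
        records = [rng.normal(0, 0.3, (8, 600)) for _ in range(4)]
        df = run_self_consistency(models, records, ["gradient_input"], LIGHT)
        assert abs(df["value"].mean()) < 0.4

    def test_needs_at_least_two_seeds(self, af_setup):
        with pytest.raises(ValueError):
            run_self_consistency({0: af_setup["clf"]}, af_setup["records"][:1],
                                 ["saliency"])


class TestCascadingRandomization:
    @pytest.fixture(scope="class")
    def traj(self, af_setup):
        return run_cascading_randomization(
            af_setup["clf"], af_setup["records"], af_setup["labels"],
            ["integrated_gradients", "saliency"], seed=0, config=LIGHT)

    def test_step_zero_correlation_is_exactly_one(self, traj):
        step0 = traj.correlation[traj.correlation.step == 0]
        assert np.all(step0["mean"] == 1.0)
        assert np.all(step0["sd"] == 0.0)

    def test_step_zero_auroc_equals_trained_model(self, traj, af_setup):
        scores = af_setup["clf"].decision_function(np.stack(af_setup["records"]))
        assert traj.model_auroc[0] == auroc(scores, af_setup["labels"])

    def test_walks_every_layer_output_first(self, traj):
        assert traj.layer_names[0] == "head"
        assert len(traj.steps) == len(traj.layer_names) + 1 == 6

    def test_correlation_declines_from_trained_to_fully_randomized(self, af_setup):
        """Maps must depend on trained weights: mean |correlation| to the
        trained-model maps is materially below 1 at full randomization."""
        y = np.asarray(af_setup["labels"])
        keep = np.concatenate([np.flatnonzero(y == 1)[:4],
                               np.flatnonzero(y == 0)[:4]])
        recs = [af_setup["records"][i] for i in keep]
        finals = []
        for seed in range(3):
            t = run_cascading_randomization(
                af_setup["clf"], recs, y[keep],
                ["integrated_gradients"], seed=seed, config=LIGHT)
            c = t.correlation
            finals.append(float(c[c.step == c.step.max()]["mean"].iloc[0]))
        assert np.mean(np.abs(finals)) < 0.6
        assert np.mean(finals) < 0.6


class TestPerturbStep:
    def test_single_step_of_full_fraction_masks_everything(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(0, 1, (8, 20))
        ranking = rank_points_abs(sig)
        out, mask = perturb_step(sig, np.zeros_like(sig, bool), ranking,
                                 1.0, 0.0, rng)
        assert mask.all()

    def test_isolated_point_replaced_by_neighbour_midpoint(self):
        sig = np.tile(np.arange(10.0), (8, 1))
        sig[3, 5] = 100.0                     # spike ranks first
        ranking = rank_points_abs(sig)
        rng = np.random.default_rng(1)
        out, mask = perturb_step(sig, np.zeros_like(sig, bool), ranking,
                                 1 / 80, 0.0, rng)
        assert mask[3, 5] and mask.sum() == 1
        assert out[3, 5] == (sig[3, 4] + sig[3, 6]) / 2 == 5.0
        untouched = ~mask
        np.testing.assert_array_equal(out[untouched], sig[untouched])

    def test_boundary_points_use_nearest_unmasked_value(self):
        sig = np.tile(np.linspace(1, 2, 6), (8, 1))
        sig[0, 0] = -50.0
        sig[0, 5] = 50.0
        ranking = rank_points_abs(sig)
        rng = np.random.default_rng(2)
        out, mask = perturb_step(sig, np.zeros_like(sig, bool), ranking,
                                 2 / 48, 0.0, rng)
        assert mask[0, 0] and mask[0, 5]
        assert out[0, 0] == sig[0, 1]         # left edge: constant extension
        assert out[0, 5] == sig[0, 4]

    def test_mask_grows_by_constant_count_and_is_monotone(self):
        rng = np.random.default_rng(3)
        sig = rng.normal(0, 1, (8, 50))
        ranking = rank_points_abs(sig)
        mask = np.zeros_like(sig, bool)
        prev = mask
        sigs = sig
        for step in range(1, 11):
            sigs, mask = perturb_step(sigs, prev, ranking, 0.01, 0.25, rng)
            assert mask.sum() == step * int(np.ceil(0.01 * 400))
            assert np.all(mask | ~prev)      # superset of previous mask
            prev = mask

    def test_full_mask_rejected(self):
        sig = np.ones((8, 10))
        with pytest.raises(ValueError, match="full"):
            perturb_step(sig, np.ones_like(sig, bool), np.arange(80), 0.1, 0.0,
                         np.random.default_rng(0))

    def test_additive_and_unknown_noise_modes(self):
        sig = np.tile(np.arange(10.0), (8, 1))
        rng = np.random.default_rng(4)
        ranking = rank_points_abs(sig)
        out, _ = perturb_step(sig, np.zeros_like(sig, bool), ranking, 0.05, 0.0,
                              rng, mode="additive")
        assert np.all(np.isfinite(out))
        with pytest.raises(ValueError, match="mode"):
            perturb_step(sig, np.zeros_like(sig, bool), ranking, 0.05, 0.1,
                         rng, mode="uniform")


class TestRunPerturbation:
    def test_step_zero_auroc_matches_unperturbed_evaluation(self, af_setup):
        traj = run_perturbation(af_setup["clf"], af_setup["records"],
                                af_setup["labels"], ["saliency"], n_steps=2,
                                step_frac=0.01, noise_sd=0.25, seed=0, config=LIGHT)
        scores = af_setup["clf"].decision_function(np.stack(af_setup["records"]))
        assert traj.auroc_by_method["saliency"][0] == auroc(scores, af_setup["labels"])

    def test_cumulative_fraction_tracks_schedule(self, af_setup):
        y = np.asarray(af_setup["labels"])
        keep = np.concatenate([np.flatnonzero(y == 1)[:2],
                               np.flatnonzero(y == 0)[:2]])
        traj = run_perturbation(af_setup["clf"],
                                [af_setup["records"][i] for i in keep], y[keep],
                                ["saliency"], n_steps=3, step_frac=0.05,
                                noise_sd=0.25, seed=0, config=LIGHT)
        assert traj.cumulative_fraction == [0.0, 0.05, 0.1, 0.15]

    def test_infeasible_schedule_rejected(self, af_setup):
        with pytest.raises(ValueError):
            run_perturbation(af_setup["clf"], af_setup["records"][:2],
                             af_setup["labels"][:2], ["saliency"], n_steps=60,
                             step_frac=0.02, noise_sd=0.25, seed=0)


class TestRecomputeRankingMode:
    def test_recompute_mode_runs_and_shares_step_zero(self, af_setup):
        y = np.asarray(af_setup["labels"])
        keep = np.concatenate([np.flatnonzero(y == 1)[:2],
                               np.flatnonzero(y == 0)[:2]])
        recs = [af_setup["records"][i] for i in keep]
        fixed = run_perturbation(af_setup["clf"], recs, y[keep], ["saliency"],
                                 n_steps=2, step_frac=0.05, noise_sd=0.25,
                                 seed=1, config=LIGHT)
        redo = run_perturbation(af_setup["clf"], recs, y[keep], ["saliency"],
                                n_steps=2, step_frac=0.05, noise_sd=0.25,
                                seed=1, config=LIGHT, recompute_ranking=True)
        assert fixed.auroc_by_method["saliency"][0] == \
            redo.auroc_by_method["saliency"][0]
        assert len(redo.auroc_by_method["saliency"]) == 3
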