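"""Nested cross validation: partitioning, leakage guards, the recovery
property on linear-link data, and refinement."""

import numpy as np
import pytest

from jumppower import GeneratorConfig, ParamSpace, build_features, generate_dataset
from jumppower.ncv import (
    OptimizerSettings,
    evaluate_holdout,
    make_fold_plan,
    refine,
    run_ncv,
)
from jumppower.pipeline import AccelPowerPipeline, LeakageError


class TestFoldPlan:
    def test_sixty_participants_split_54_6(self):
        ids = [f"P{i:03d}" for i in range(60)]
        plan = make_fold_plan(ids, n_folds=10, n_reps=2, seed=1)
        assert len(plan.folds) == 20
        for f in plan.folds:
            assert len(f.train_ids) == 54 and len(f.val_ids) == 6

    def test_validation_folds_partition_cohort(self):
        ids = [f"P{i:03d}" for i in range(60)]
        plan = make_fold_plan(ids, n_folds=10, n_reps=2, seed=2)
        for rep in range(2):
            union = set()
            for f in plan.folds:
                if f.repetition == rep:
                    union |= set(f.val_ids)
            assert union == set(ids)

    def test_seeds_differ_sizes_fixed(self):
        ids = [f"P{i:03d}" for i in range(30)]
        p1 = make_fold_plan(ids, 5, 1, seed=1)
        p2 = make_fold_plan(ids, 5, 1, seed=2)
        assert [len(f.val_ids) for f in p1.folds] == [6] * 5
        assert any(f1.val_ids != f2.val_ids
                   for f1, f2 in zip(p1.folds, p2.folds))

    def test_deterministic_given_seed(self):
        ids = [f"P{i:03d}" for i in range(25)]
        assert make_fold_plan(ids, 5, 2, seed=3) == make_fold_plan(ids, 5, 2, seed=3)

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            make_fold_plan(["A", "B"], n_folds=10)


class TestLeakageGuards:
    def test_holdout_overlap_is_hard_failure(self, linear_link_features):
        feats = linear_link_features
        decoded = ParamSpace.for_family("LR").decode(
            np.array([12, 12, 12.0, 1, -6.0, 8, 1, 1, 2, -4.0])
        )
        pipe = AccelPowerPipeline(decoded, "LR").fit(feats)
        with pytest.raises(LeakageError):
            evaluate_holdout(pipe, feats, feats)  # holdout = training copy

    def test_fold_plans_always_disjoint(self):
        # every seeded plan keeps participants on one side of each boundary
        ids = [f"P{i:03d}" for i in range(60)]
        for seed in range(10):
            plan = make_fold_plan(ids, 10, 2, seed=seed)
            plan.check()
            for f in plan.folds:
                assert not set(f.train_ids) & set(f.val_ids)


@pytest.fixture(scope="module")
def scaled_ncv_result(linear_link_features):
    space = ParamSpace.for_family("LR")
    settings = OptimizerSettings(n_obs=40, refit_every=10, n_particles=10)
    return run_ncv(
        linear_link_features, space, "LR", settings=settings,
        n_folds=3, n_reps=1, seed=21,
    ), space


class TestRunNcv:
    def test_captures_signal_on_linear_link_surface(self, scaled_ncv_result,
                                                    linear_link_features):
        # at this miniature scale (14 participants, 40 observations/fold)
        # the estimate is noisy, but the model must capture most of the
        # latent signal: fold RMSE well below the no-signal level sd(y)
        result, _ = scaled_ncv_result
        mean, sd = result.ncv_estimate
        assert len(result.fold_results) == 3
        assert mean <= 0.5 * linear_link_features.y.std()

    def test_final_ensemble_trains_and_predicts(self, scaled_ncv_result,
                                                linear_link_features):
        result, space = scaled_ncv_result
        pred = result.final_pipeline.predict(linear_link_features)
        assert pred.shape == linear_link_features.y.shape
        decoded = space.decode(result.final_ensemble)
        assert decoded["n_fpc"] >= 1

    def test_holdout_consistency(self, scaled_ncv_result, linear_link_dataset,
                                 linear_link_features):
        # fresh participants from the same generator: the final ensemble's
        # independent error stays within 2x the NCV estimate
        result, _ = scaled_ncv_result
        cfg, _, _ = linear_link_dataset
        hold_cfg = GeneratorConfig(**{**cfg.__dict__, "seed": cfg.seed + 999,
                                      "n_participants": 4})
        _, hold_trials = generate_dataset(hold_cfg, "LB")
        hold_feats = build_features(hold_trials)
        hold_feats.participant_ids = np.array(
            ["H" + p for p in hold_feats.participant_ids]
        )
        err = evaluate_holdout(result.final_pipeline, linear_link_features,
                               hold_feats)
        mean, _ = result.ncv_estimate
        assert err <= 2.0 * mean

    def test_permuted_labels_lose_signal(self, linear_link_features):
        # null oracle: with permuted outcomes the model cannot beat the
        # outcome standard deviation
        feats = linear_link_features
        rng = np.random.default_rng(5)
        shuffled = feats.y.copy()
        rng.shuffle(shuffled)
        null = type(feats)(
            trial_ids=feats.trial_ids, participant_ids=feats.participant_ids,
            y=shuffled, resultant=feats.resultant, triaxial=feats.triaxial,
            flight_times=feats.flight_times, body_masses=feats.body_masses,
        )
        decoded = ParamSpace.for_family("LR").decode(
            np.array([12, 12, 12.0, 1, -6.0, 8, 1, 1, 2, -4.0])
        )
        mask = null.subset_mask(set(null.participant_ids[:60]))
        pipe = AccelPowerPipeline(decoded, "LR").fit(null, mask)
        pred = pipe.predict(null, ~mask)
        err = np.sqrt(np.mean((pred - null.y[~mask]) ** 2))
        assert err >= 0.75 * null.y.std()


class TestRefine:
    def _space(self):
        return ParamSpace.for_family("LR")

    def test_unanimous_categorical_frozen(self):
        space = self._space()
        base = np.array([12, 12, 12.0, 1, -6.0, 8, 1.0, 1, 2, -4.0])
        optima = []
        for k in range(8):
            x = base.copy()
            x[0] = 5 + k * 3          # t_pre scattered
            x[4] = -10 + 2.5 * k      # lam scattered
            x[9] = -9 + 2.2 * k       # lam_lr scattered
            optima.append(x)
        narrowed = refine(optima, space)
        assert "standardize" not in narrowed.names  # all "No" -> frozen
        assert "t_pre" in narrowed.names            # uniform scatter stays free
        assert "lam" in narrowed.names

    def test_rounds_never_regrow_parameters(self):
        space = self._space()
        rng = np.random.default_rng(11)
        free_counts = [space.ndim]
        for _ in range(4):
            lo, hi = space.bounds_arrays()
            optima = [space.round_vector(rng.uniform(lo, hi)) for _ in range(8)]
            space = refine(optima, space)
            free_counts.append(space.ndim)
        assert all(a >= b for a, b in zip(free_counts, free_counts[1:]))

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            refine([], self._space())
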