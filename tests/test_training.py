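"""Training loop: augmentation, schedule, determinism, learning progress,
and the leakage-free cross-validation protocol."""
import numpy as np
import pytest

from moeclock import (
    CountNormalizer,
    ExpressionMatrix,
    MoEAgeRegressor,
    TrainConfig,
    align_annotations,
    augment_gaussian,
    crossvalidate,
    lr_at,
    stratified_folds,
)
from moeclock.losses import LossConfig


class TestAugmentation:
    def test_zero_copies_is_identity(self, rng):
        X = rng.normal(size=(7, 3))
        out, idx = augment_gaussian(X, 0, 0.5, seed=1)
        np.testing.assert_array_equal(out, X)
        np.testing.assert_array_equal(idx, np.arange(7))

    def test_thirty_copies_of_ten_samples_gives_310_rows(self, rng):
        X = rng.normal(size=(10, 4))
        out, idx = augment_gaussian(X, 30, 0.5, seed=2)
        assert out.shape == (310, 4)
        assert idx.size == 310
        # labels replicate via the index map
        np.testing.assert_array_equal(idx[:10], np.arange(10))

    def test_zero_sd_copies_equal_sources(self, rng):
        X = rng.normal(size=(5, 3))
        out, idx = augment_gaussian(X, 2, 0.0, seed=3)
        np.testing.assert_array_equal(out, X[idx])

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            augment_gaussian(np.ones((2, 2)), 1, -0.1, seed=0)


def test_step_decay_schedule_exact():
    for e in range(50):
        assert lr_at(e, 5e-3, 0.8, 20) == 5e-3 * 0.8 ** (e // 20)


def _fit_kwargs(expr, ann, truth):
    table = align_annotations(expr, ann)
    return dict(
        X=expr.values,
        y=table["age"].to_numpy(float),
        status=table["status"].to_numpy(object),
        pool_indices=truth.pool.indices_in(expr.gene_ids),
    )


@pytest.fixture(scope="module")
def quick_cohort():
    from moeclock import CohortSpec, generate_cohort
    spec = CohortSpec(n_healthy=120, disease_groups=[("dz", 60, 10.0)], d_genes=200,
                      n_causal=30, pool_size=40, noise_sd=1.0, seed=1)
    return generate_cohort(spec)


def _quick_estimator(**overrides):
    base = dict(hidden_widths=(32, 16), dropout_rate=0.0, epochs=25, batch_size=64,
                aug_copies=2, aug_sd=0.5, decay_every=8, top_k=100, random_state=0)
    base.update(overrides)
    return MoEAgeRegressor(**base)


class TestFit:
    def test_validation_mae_halves_from_first_epoch(self, quick_cohort):
        expr, ann, truth = quick_cohort
        kw = _fit_kwargs(expr, ann, truth)
        est = _quick_estimator()
        est.fit(kw["X"], kw["y"], status=kw["status"], pool_indices=kw["pool_indices"],
                validation_data=(kw["X"], kw["y"]))
        vm = est.history_["val_mae"]
        assert vm[-1] < 0.5 * vm[0]

    def test_identical_seeds_identical_results(self, quick_cohort):
        expr, ann, truth = quick_cohort
        kw = _fit_kwargs(expr, ann, truth)
        preds = []
        for _ in range(2):
            est = _quick_estimator(epochs=4)
            est.fit(**kw)
            preds.append(est.predict(kw["X"]))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_ahk_term_descends_when_causal_genes_are_in_pool(self):
        from moeclock import CohortSpec, generate_cohort
        spec = CohortSpec(n_healthy=100, d_genes=120, n_causal=20, pool_size=20,
                          frac_causal_in_pool=1.0, noise_sd=0.5, seed=4)
        expr, ann, truth = spec, None, None
        expr, ann, truth = generate_cohort(spec)
        kw = _fit_kwargs(expr, ann, truth)
        est = _quick_estimator(gamma=500.0, epochs=15, pool_fraction=1.0, top_k=40)
        est.fit(**kw)
        ahk = est.history_["ahk"]
        assert ahk[-1] <= ahk[0]

    def test_history_lengths_match_epochs(self, quick_cohort):
        expr, ann, truth = quick_cohort
        est = _quick_estimator(epochs=3)
        est.fit(**_fit_kwargs(expr, ann, truth))
        assert len(est.history_["total"]) == 3
        assert est.history_["lr"][0] == pytest.approx(5e-3)

    def test_mae_decreases_as_expression_noise_vanishes(self):
        """With a noiseless age→expression map a near-perfect fit is possible;
        the learned model's error should fall monotonically with noise."""
        from moeclock import CohortSpec, generate_cohort, mae
        maes = []
        for noise in (2.0, 1.0, 0.0):
            spec = CohortSpec(n_healthy=150, d_genes=100, n_causal=25, pool_size=30,
                              noise_sd=noise, seed=6)
            expr, ann, truth = generate_cohort(spec)
            kw = _fit_kwargs(expr, ann, truth)
            tr, te = np.arange(100), np.arange(100, 150)
            est = _quick_estimator(gamma=0.0, epochs=30)
            est.fit(kw["X"][tr], kw["y"][tr], status=kw["status"][tr])
            maes.append(mae(est.predict(kw["X"][te]), kw["y"][te]))
        assert maes[0] >= maes[1] >= maes[2]

    def test_training_on_both_beats_healthy_only_when_healthy_is_scarce(self):
        """Adding margin-routed unhealthy samples should improve held-out
        healthy accuracy when few healthy samples are available."""
        from moeclock import CohortSpec, generate_cohort, mae
        spec = CohortSpec(n_healthy=90, disease_groups=[("dz", 160, 6.0)], d_genes=150,
                          n_causal=30, pool_size=40, noise_sd=1.0, seed=8)
        expr, ann, truth = generate_cohort(spec)
        kw = _fit_kwargs(expr, ann, truth)
        healthy_idx = np.flatnonzero(kw["status"] == "healthy")
        test_idx = healthy_idx[50:]
        train_healthy = healthy_idx[:50]
        train_both = np.concatenate([train_healthy,
                                     np.flatnonzero(kw["status"] == "unhealthy")])
        gaps = []
        for seed in (0, 1, 2):
            out = {}
            for name, tr in (("healthy", train_healthy), ("both", train_both)):
                est = _quick_estimator(gamma=0.0, epochs=30, random_state=seed)
                est.fit(kw["X"][tr], kw["y"][tr], status=kw["status"][tr])
                out[name] = mae(est.predict(kw["X"][test_idx]), kw["y"][test_idx])
            gaps.append(out["healthy"] - out["both"])
        assert np.mean(gaps) > 0

    def test_nan_input_rejected(self, quick_cohort):
        expr, ann, truth = quick_cohort
        kw = _fit_kwargs(expr, ann, truth)
        X = kw["X"].copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            _quick_estimator().fit(X, kw["y"])

    def test_sklearn_params_round_trip(self):
        est = MoEAgeRegressor(margin=7.0)
        params = est.get_params()
        assert params["margin"] == 7.0
        clone = MoEAgeRegressor(**params)
        assert clone.get_params() == params


class TestCrossValidation:
    def _tiny_setup(self):
        from moeclock import CohortSpec, generate_cohort
        spec = CohortSpec(n_healthy=40, disease_groups=[("dz", 20, 8.0)], d_genes=30,
                          n_causal=10, pool_size=10, noise_sd=1.0, seed=3)
        expr, ann, truth = generate_cohort(spec)
        cfg = TrainConfig(epochs=2, batch_size=32, aug_copies=0,
                          hidden_widths=(8,), loss=LossConfig(top_k=10))
        return expr, ann, truth, cfg

    def test_folds_partition_samples(self):
        expr, ann, truth, cfg = self._tiny_setup()
        assignment = stratified_folds(ann, n_folds=5, seed=0)
        assert assignment.size == 60
        counts = np.bincount(assignment, minlength=5)
        assert counts.sum() == 60 and np.all(counts > 0)

    def test_two_folds_on_ten_samples_are_disjoint_halves(self):
        from moeclock import SampleAnnotation
        ann = [SampleAnnotation(f"S{i}", 20.0 + 7 * i) for i in range(10)]
        assignment = stratified_folds(ann, n_folds=2, seed=1)
        assert sorted(np.bincount(assignment).tolist()) == [5, 5]

    def test_crossvalidate_report_and_leakage(self):
        expr, ann, truth, cfg = self._tiny_setup()
        norm = CountNormalizer(library_size="none", log1p=False)
        report = crossvalidate(expr, ann, truth.pool, cfg, n_folds=3, normalizer=norm)
        assert np.bincount(report.fold_assignment).sum() == expr.n_samples
        assert len(report.per_fold) == 3
        assert report.pooled["n"] == 40

        # leakage oracle: corrupting each test fold leaves that fold's
        # training-side normalization statistics unchanged
        corrupted = ExpressionMatrix(expr.values.copy(), expr.gene_ids, expr.sample_ids)
        for f in range(3):
            corrupted.values[report.fold_assignment == f] += 1e6
            fold_train = ExpressionMatrix(
                expr.values[report.fold_assignment != f], expr.gene_ids,
                [s for s, a in zip(expr.sample_ids, report.fold_assignment) if a != f])
            refit = CountNormalizer(library_size="none", log1p=False).fit(fold_train)
            np.testing.assert_array_equal(refit.model_.per_gene_center,
                                          report.normalizers[f].model_.per_gene_center)
            corrupted.values[report.fold_assignment == f] -= 1e6

    def test_fold_without_healthy_raises(self):
        from moeclock import SampleAnnotation
        vals = np.random.default_rng(0).normal(size=(8, 5))
        expr = ExpressionMatrix(vals, [f"G{j}" for j in range(5)],
                                [f"S{i}" for i in range(8)])
        ann = [SampleAnnotation(f"S{i}", 50.0, status="unhealthy", condition="dz")
               for i in range(8)]
        cfg = TrainConfig(epochs=1, aug_copies=0, hidden_widths=(4,))
        with pytest.raises(ValueError, match="healthy"):
            crossvalidate(expr, ann, None, cfg, n_folds=2,
                          normalizer=CountNormalizer(library_size="none", log1p=False))
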