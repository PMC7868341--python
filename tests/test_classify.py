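import hashlib

import numpy as np
import pytest
from scipy import linalg as sla

from phasestim import SynthConfig, generate_session
from phasestim.classify import (
    DEFAULT_BANDS,
    crossvalidate,
    csp_features,
    epoch_for_classification,
    fbcsp_features,
    fit_csp,
    fit_fbcsp,
)
from phasestim.spectral import car_reference

FS = 1000.0


def two_source_epochs(ratio=4.0, n_per_class=30, n_channels=4, n_samples=500,
                      seed=0):
    """Mixed sources where source 0's variance differs ``ratio``:1 by class."""
    rng = np.random.default_rng(seed)
    mix = rng.standard_normal((n_channels, n_channels))
    epochs, labels = [], []
    for cls, var0 in (("MI", 1.0), ("rest", ratio)):
        for _ in range(n_per_class):
            src = rng.standard_normal((n_channels, n_samples))
            src[0] *= np.sqrt(var0)
            epochs.append(mix @ src)
            labels.append(cls)
    return np.array(epochs), np.array(labels), mix


class TestEpoching:
    def test_epoch_geometry(self, small_session):
        cfg, rec, _ = small_session
        epochs, labels = epoch_for_classification(rec)
        assert epochs.shape == (cfg.n_trials, cfg.n_channels, 3500)
        assert len(labels) == cfg.n_trials
        assert list(labels) == [ev.label for ev in rec.events]

    def test_out_of_range_raises(self, small_session):
        _, rec, _ = small_session
        from phasestim import EEGRecording

        short = EEGRecording(
            data=rec.data[:, :5000].copy(),
            fs=rec.fs,
            channel_labels=list(rec.channel_labels),
            events=list(rec.events[:1]),
        )
        with pytest.raises(ValueError, match="range"):
            epoch_for_classification(short)

    def test_no_events_raises(self, pure_sine_recording):
        with pytest.raises(ValueError, match="events"):
            epoch_for_classification(pure_sine_recording)


class TestFitCSP:
    def test_identical_covariance_classes(self):
        rng = np.random.default_rng(1)
        epochs = rng.standard_normal((60, 4, 2000))
        labels = np.array(["MI", "rest"] * 30)
        model = fit_csp(epochs, labels)
        assert np.abs(model.eigenvalues - 0.5).max() < 0.1

    def test_discriminative_mixture_matches_brute_force(self):
        epochs, labels, _ = two_source_epochs(ratio=4.0)
        bp = epochs  # broadband sources; no filtering needed
        model = fit_csp(bp, labels, m_pairs=1)
        # top filter variance ratio between classes
        def var_along(w, cls):
            sel = bp[labels == cls]
            return np.mean([w @ (e @ e.T) @ w for e in sel])

        w = model.filters[:, -1]  # most rest-favoring direction
        r = var_along(w, "rest") / var_along(w, "MI")
        if r < 1:
            w = model.filters[:, 0]
            r = var_along(w, "rest") / var_along(w, "MI")
        assert r >= 3.5

        # brute-force generalized eigensolver oracle on the documented
        # estimator (trace-normalized per-trial covariances, class-averaged)
        covs = np.array([e @ e.T for e in bp])
        covs /= np.trace(covs, axis1=1, axis2=2)[:, None, None]
        ca = covs[labels == "MI"].mean(axis=0)
        cb = covs[labels == "rest"].mean(axis=0)
        evals = sla.eigvalsh(ca, ca + cb)
        np.testing.assert_allclose(
            np.sort(model.eigenvalues), np.sort(evals), atol=1e-8
        )

    def test_whitening_invariant(self):
        epochs, labels, _ = two_source_epochs(seed=2)
        model = fit_csp(epochs, labels, m_pairs=2)
        covs = np.array([e @ e.T for e in epochs])
        covs /= np.trace(covs, axis1=1, axis2=2)[:, None, None]
        comp = covs[:30].mean(axis=0) + covs[30:].mean(axis=0)
        gram = model.filters.T @ comp @ model.filters
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-6)

    def test_needs_two_classes(self):
        epochs = np.zeros((4, 2, 100))
        with pytest.raises(ValueError):
            fit_csp(epochs, np.array(["MI"] * 4))


class TestFeatures:
    def test_feature_count_default_config(self, small_session):
        _, rec, _ = small_session
        epochs, labels = epoch_for_classification(rec)
        model = fit_fbcsp(epochs, labels, rec.fs)
        feats = fbcsp_features(epochs, model)
        assert feats.shape == (len(labels), len(DEFAULT_BANDS) * 2 * 3)
        assert np.all(np.isfinite(feats))

    def test_scaling_invariance(self):
        epochs, labels, _ = two_source_epochs(seed=3)
        model = fit_csp(epochs, labels)
        f1 = csp_features(epochs[0], model)
        f2 = csp_features(epochs[0] * 12.5, model)
        np.testing.assert_allclose(f1, f2, atol=1e-10)


class TestCrossvalidate:
    def test_null_accuracy_near_chance(self):
        # single datasets scatter widely (and slightly below 0.5 -- the
        # classic CV pessimism on pure noise), so average a few seeds
        means = []
        for seed in (4, 5, 6):
            rng = np.random.default_rng(seed)
            epochs = rng.standard_normal((80, 4, 1000))
            labels = np.array(["MI", "rest"] * 40)
            means.append(
                crossvalidate(epochs, labels, FS, n_repeats=2,
                              seed=seed).mean_accuracy
            )
        assert np.mean(means) == pytest.approx(0.5, abs=0.07)

    def test_duplicated_distinct_epochs_perfect(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((4, 1000))
        b = 5.0 * rng.standard_normal((4, 1000))
        epochs = np.array([a] * 20 + [b] * 20)
        labels = np.array(["MI"] * 20 + ["rest"] * 20)
        report = crossvalidate(epochs, labels, FS, n_repeats=2, seed=0)
        assert report.mean_accuracy == 1.0

    def test_report_structure(self):
        rng = np.random.default_rng(6)
        epochs = rng.standard_normal((40, 3, 800))
        labels = np.array(["MI", "rest"] * 20)
        report = crossvalidate(epochs, labels, FS, n_repeats=2, n_folds=5, seed=1)
        assert report.fold_accuracies.shape == (10,)
        assert report.per_repeat_means.shape == (2,)
        assert report.mean_accuracy == pytest.approx(report.fold_accuracies.mean())

    def test_no_leakage_training_model_ignores_test_data(self):
        # CSP fitted on a training split is bit-identical no matter what the
        # held-out trials contain
        epochs, labels, _ = two_source_epochs(seed=7)
        train = np.arange(0, 50)
        model_a = fit_csp(epochs[train], labels[train])
        corrupted = epochs.copy()
        corrupted[50:] = 1e6
        model_b = fit_csp(corrupted[train], labels[train])
        h = lambda m: hashlib.sha256(m.filters.tobytes()).hexdigest()
        assert h(model_a) == h(model_b)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        epochs = rng.standard_normal((40, 3, 800))
        labels = np.array(["MI", "rest"] * 20)
        r1 = crossvalidate(epochs, labels, FS, n_repeats=2, n_folds=5, seed=3)
        r2 = crossvalidate(epochs, labels, FS, n_repeats=2, n_folds=5, seed=3)
        np.testing.assert_array_equal(r1.fold_accuracies, r2.fold_accuracies)


class TestNullOverSeeds:
    def test_erd_zero_ci_covers_chance(self):
        # accuracy on no-effect sessions is indistinguishable from 0.5
        means = []
        for seed in range(20):
            cfg = SynthConfig(n_trials=40, n_channels=6, erd_depth=0.0, seed=seed)
            rec = generate_session(cfg)
            epochs, labels = epoch_for_classification(car_reference(rec))
            rep = crossvalidate(epochs, labels, FS, n_repeats=1, seed=seed)
            means.append(rep.mean_accuracy)
        means = np.array(means)
        half = 1.96 * means.std(ddof=1) / np.sqrt(means.size)
        assert means.mean() - half <= 0.5 <= means.mean() + half
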