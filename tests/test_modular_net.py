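"""Modular network: architecture invariants, training, probing, gauge."""

import numpy as np
import pytest

from uhsr.errors import ConfigError, TrainingError, ValidationError
from uhsr.features import FEATURE_NAMES, features_matrix, rf_vector
from uhsr.modular_net import (
    FeatureGrouping, HyperParams, TrainedStage, build_network,
    canonicalize_sign, extract_latents, probe, stage1_grouping,
    stage2_grouping, stage3_grouping, train,
)
from uhsr.pipeline import compute_metrics

FAST = HyperParams(epochs=60, batch_size=128, seed=0)


@pytest.fixture(scope="module")
def trained_stage1(medium_dataset):
    X = features_matrix(medium_dataset.records)
    y = rf_vector(medium_dataset.records)
    hp = HyperParams(epochs=250, batch_size=256, seed=0, head_depth=0)
    stage = train(build_network(stage1_grouping(), hp), X, y, hp)
    return stage, X, y


class TestGrouping:
    def test_stage_shapes(self):
        assert [len(idx) for _, idx in stage1_grouping().groups] == [5, 18]
        assert [len(idx) for _, idx in stage2_grouping().groups] == [5, 2, 16]
        assert [len(idx) for _, idx in stage3_grouping().groups] == \
            [5, 2, 2, 3, 2, 5, 4]

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            FeatureGrouping(groups=(("a", (0, 1)), ("b", (1,) + tuple(range(2, 23)))),
                            latents=("za", "zb"))

    def test_incomplete_cover_rejected(self):
        with pytest.raises(ConfigError, match="incomplete cover"):
            FeatureGrouping(groups=(("solvent", tuple(range(5))),
                                    ("FG", tuple(range(5, 21)))),
                            latents=("psi", "beta"))

    def test_network_has_one_submodel_per_group(self):
        assert build_network(stage1_grouping(), FAST).k == 2
        assert build_network(stage3_grouping(), FAST).k == 7


class TestArchitecturalInvariants:
    def test_group_locality_exact(self, trained_stage1):
        stage, X, _ = trained_stage1
        a = X[0].copy()
        b = X[0].copy()
        b[:5] = X[1][:5]  # change only the solvent group
        za = stage.latents(a[None, :])[0]
        zb = stage.latents(b[None, :])[0]
        assert za[1] == zb[1]      # xi untouched by solvent perturbation
        assert za[0] != zb[0]

    def test_head_output_in_unit_interval(self, trained_stage1):
        stage, X, _ = trained_stage1
        pred = stage.predict(X)
        assert np.all((pred > 0) & (pred < 1))
        # far outside the data range the logistic may saturate in floats,
        # but never leaves [0, 1]
        wild = stage.predict(X * 50.0)
        assert np.all((wild >= 0) & (wild <= 1))

    def test_probe_zero_vector_is_bias_latent(self, trained_stage1):
        stage, _, _ = trained_stage1
        z1 = probe(stage, "solvent", np.zeros(5))
        z2 = probe(stage, "solvent", np.zeros(5))
        assert z1 == z2

    def test_probe_index_outside_group_rejected(self, trained_stage1):
        stage, _, _ = trained_stage1
        with pytest.raises(ConfigError):
            probe(stage, "solvent", "CtPh")
        with pytest.raises(ConfigError):
            probe(stage, "solvent", 7)


class TestTraining:
    def test_seeded_training_bit_identical(self, medium_dataset):
        X = features_matrix(medium_dataset.records[:400])
        y = rf_vector(medium_dataset.records[:400])
        runs = []
        for _ in range(2):
            hp = HyperParams(epochs=8, batch_size=128, seed=13)
            stage = train(build_network(stage1_grouping(), hp), X, y, hp)
            runs.append((stage.train_loss_trace, stage.val_loss_trace))
        assert runs[0][0] == runs[1][0]
        assert runs[0][1] == runs[1][1]

    def test_constant_target_converges_to_constant_predictor(
            self, medium_dataset):
        X = features_matrix(medium_dataset.records[:400])
        y = np.full(400, 0.5)
        hp = HyperParams(epochs=40, batch_size=128, seed=1)
        stage = train(build_network(stage1_grouping(), hp), X, y, hp)
        pred = stage.predict(X)
        assert np.mean((pred - 0.5) ** 2) < 1e-4  # converges to the constant
        # R2 against the constant target is undefined and must be flagged
        m = compute_metrics(y, pred)
        assert m.r2 is None and m.r2_undefined

    def test_too_few_batches_rejected(self, medium_dataset):
        X = features_matrix(medium_dataset.records[:100])
        y = rf_vector(medium_dataset.records[:100])
        with pytest.raises(TrainingError, match="2 batches"):
            train(build_network(stage1_grouping(), HyperParams(seed=0)),
                  X, y, HyperParams(seed=0))

    def test_empty_data_rejected(self):
        with pytest.raises(TrainingError):
            train(build_network(stage1_grouping(), FAST),
                  np.empty((0, 23)), np.empty(0), FAST)

    def test_recovery_on_held_out_data(self, trained_stage1, medium_dataset):
        stage, X, y = trained_stage1
        # noisy generator, affine-head stage: held-out fit should be strong
        m = compute_metrics(y[-200:], stage.predict(X[-200:]))
        assert m.r2 >= 0.9


class TestLatentGauge:
    def test_training_split_latents_standardized(self, trained_stage1):
        stage, X, _ = trained_stage1
        # recompute the training split the same way train() does
        rng = np.random.default_rng(np.random.SeedSequence([stage.hp.seed, 1]))
        perm = rng.permutation(len(X))
        n_val = max(1, int(round(len(X) * stage.hp.validation_fraction)))
        Z = stage.latents(X[perm[n_val:]])
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-6)

    def test_extract_latents_schema(self, trained_stage1, medium_dataset):
        stage, _, _ = trained_stage1
        df = extract_latents(stage, medium_dataset.records[:10])
        assert list(df.columns) == ["id", "psi", "xi"]
        assert len(df) == 10

    def test_canonicalize_sign_flips_and_is_idempotent(self, trained_stage1):
        stage, X, y = trained_stage1
        forced = TrainedStage(
            network=stage.network, grouping=stage.grouping, hp=stage.hp,
            shift=stage.shift, scale=stage.scale,
            sign=-np.ones_like(stage.sign),
            train_loss_trace=[], val_loss_trace=[], best_epoch=0)
        canon = canonicalize_sign(forced, X, y)
        z = canon.latents(X)
        assert np.corrcoef(z[:, 1], y)[0, 1] >= 0          # xi vs Rf
        meoh = X[:, FEATURE_NAMES.index("MeOH")]
        assert np.corrcoef(z[:, 0], meoh)[0, 1] >= 0       # psi vs MeOH
        again = canonicalize_sign(canon, X, y)
        np.testing.assert_array_equal(again.sign, canon.sign)

    def test_canonicalize_zero_variance_latent_rejected(self, trained_stage1):
        stage, X, y = trained_stage1
        broken = TrainedStage(
            network=stage.network, grouping=stage.grouping, hp=stage.hp,
            shift=stage.shift, scale=np.full_like(stage.scale, np.inf),
            sign=stage.sign.copy(), train_loss_trace=[], val_loss_trace=[],
            best_epoch=0)
        with pytest.raises(ValidationError):
            canonicalize_sign(broken, X, y)


def test_save_load_round_trip(tmp_path, trained_stage1):
    from uhsr.modular_net import load_stage, save_stage
    stage, X, _ = trained_stage1
    prefix = str(tmp_path / "stage1")
    save_stage(stage, prefix)
    back = load_stage(prefix)
    np.testing.assert_allclose(back.predict(X[:20]), stage.predict(X[:20]),
                               atol=1e-12)
    np.testing.assert_allclose(back.latents(X[:20]), stage.latents(X[:20]),
                               atol=1e-12)
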