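"""Assembled model-space inputs and the masked sequential autoencoder."""

import numpy as np
import pytest

from synthehr.autoencoder import (ModelBundle, TrainingConfig, assemble_inputs,
                                  encode_dataset, reconstruction_loss, train_autoencoder)
from synthehr.codec import CodecTrainingConfig, one_hot_block, train_codec
from synthehr.normalization import CohortNormalizer
from synthehr.schema import FeatureSchema

from conftest import tiny_config
from synthehr.toygen import generate_cohort


@pytest.fixture(scope="module")
def assembled():
    config = tiny_config(seed=11, n=200)
    dataset, masks, gt = generate_cohort(config)
    schema = gt["schema"]
    norm = CohortNormalizer.fit(dataset, masks, schema, seed=2)
    ss = [len(v) for v in schema.static_cat_vocabs]
    st = [len(v) for v in schema.temporal_cat_vocabs]
    sc, _ = train_codec(one_hot_block(dataset.static_cat, ss), ss,
                        config=CodecTrainingConfig(epochs=30, seed=2))
    tc, _ = train_codec(one_hot_block(dataset.temp_cat[masks.step_present.astype(bool)], st),
                        st, config=CodecTrainingConfig(epochs=20, seed=2))
    bundle = assemble_inputs(dataset, masks, norm, sc, tc, schema)
    return bundle, schema, dataset, masks


class TestAssemble:
    def test_all_channels_in_unit_ranges(self, assembled):
        bundle, *_ = assembled
        for name in ("static_num", "temp_num", "times"):
            arr = getattr(bundle, name)
            assert np.all((arr >= 0) & (arr <= 1)), name
        for name in ("mask_static_num", "mask_static_cat", "mask_temp_num",
                     "mask_temp_cat", "step_present"):
            arr = getattr(bundle, name)
            assert set(np.unique(arr)) <= {0.0, 1.0}, name
        assert np.all(np.abs(bundle.static_emb) <= 1)
        assert np.all(np.abs(bundle.temp_emb) <= 1)

    def test_missing_numeric_is_zero_with_mask_zero(self, assembled):
        bundle, schema, dataset, masks = assembled
        missing = bundle.mask_temp_num == 0
        assert np.all(bundle.temp_num[missing] == 0.0)

    def test_padded_steps_are_zero(self, assembled):
        bundle, *_ = assembled
        pad = bundle.step_present == 0
        assert np.all(bundle.temp_num[pad] == 0)
        assert np.all(bundle.times[pad] == 0)
        assert np.all(bundle.temp_emb[pad] == 0)

    def test_assembly_is_deterministic(self, assembled):
        bundle, schema, dataset, masks = assembled
        norm = CohortNormalizer.fit(dataset, masks, schema, seed=2)
        again = norm.normalize_temporal(dataset.temp_num, schema)
        twice = norm.normalize_temporal(dataset.temp_num, schema)
        assert np.array_equal(again, twice, equal_nan=True)


def one_entry_bundle(target_value, pred_value):
    """One patient, one observed static numeric, one temporal numeric, T=1."""
    def mk(sn):
        return ModelBundle(
            static_num=np.array([[sn]]),
            static_emb=np.zeros((1, 0)),
            mask_static_num=np.ones((1, 1)),
            mask_static_cat=np.ones((1, 0)),
            temp_num=np.zeros((1, 1, 1)),
            temp_emb=np.zeros((1, 1, 0)),
            times=np.zeros((1, 1)),
            mask_temp_num=np.ones((1, 1, 1)),
            mask_temp_cat=np.ones((1, 1, 0)),
            step_present=np.ones((1, 1)),
        )
    return mk(pred_value), mk(target_value)


class TestReconstructionLoss:
    def test_perfect_prediction_gives_zero(self):
        pred, target = one_entry_bundle(0.4, 0.4)
        assert reconstruction_loss(pred, target, lam=1.0) == 0.0

    def test_single_entry_closed_form(self):
        """Observed 0.4 predicted 0.6 with perfect masks: MSE term 0.04."""
        pred, target = one_entry_bundle(0.4, 0.6)
        assert reconstruction_loss(pred, target, lam=1.0) == pytest.approx(0.04)

    def test_masked_out_entries_do_not_contribute(self, assembled):
        """Perturbing any masked-out value leaves the loss bit-identical."""
        bundle, *_ = assembled
        pred = ModelBundle(**{f: np.copy(getattr(bundle, f))
                              for f in bundle.__dataclass_fields__})
        base = reconstruction_loss(pred, bundle, lam=1.3)
        tampered_target = ModelBundle(**{f: np.copy(getattr(bundle, f))
                                         for f in bundle.__dataclass_fields__})
        hidden = tampered_target.mask_temp_num == 0
        tampered_target.temp_num[hidden] = 123.0
        tampered_target.static_num[tampered_target.mask_static_num == 0] = -7.0
        pred.temp_num[hidden] = 55.0
        assert reconstruction_loss(pred, tampered_target, lam=1.3) == base

    def test_non_finite_prediction_rejected(self):
        pred, target = one_entry_bundle(0.4, 0.6)
        pred.static_num[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            reconstruction_loss(pred, target)


@pytest.fixture(scope="module")
def trained_ae(assembled):
    bundle, schema, *_ = assembled
    cfg = TrainingConfig(epochs=25, d_e=24, hidden=48, batch_size=64,
                         learning_rate=2e-3, seed=4)
    model, history = train_autoencoder(bundle, schema, cfg)
    return model, history, bundle, schema


class TestTraining:
    def test_smoothed_loss_decreases(self, trained_ae):
        _, history, *_ = trained_ae
        assert np.mean(history[-3:]) < np.mean(history[:3])

    def test_same_seed_identical_history(self, assembled, trained_ae):
        bundle, schema, *_ = assembled
        _, history, *_ = trained_ae
        cfg = TrainingConfig(epochs=25, d_e=24, hidden=48, batch_size=64,
                             learning_rate=2e-3, seed=4)
        _, history2 = train_autoencoder(bundle, schema, cfg)
        assert history == history2

    def test_internal_loss_matches_reference_loss(self, trained_ae):
        """The autodiff training loss equals the numpy reference on a batch."""
        model, _, bundle, schema = trained_ae
        batch = bundle.take(np.arange(16))
        internal = float(model.loss_graph(batch).data)
        pred = model.decode(model.encode(batch))
        reference = reconstruction_loss(pred, batch, lam=model.config.lam)
        assert internal == pytest.approx(reference, rel=1e-9)

    def test_reconstruction_error_floor_on_tiny_fixture(self, trained_ae):
        """Static numerics reconstruct well below the no-information floor;
        temporal numerics at this tiny budget stay near it (per-step values
        are mostly jitter the latent has no capacity to memorize)."""
        model, _, bundle, _ = trained_ae
        pred = model.decode(model.encode(bundle))
        m_s = bundle.mask_static_num
        mse_s = float((((pred.static_num - bundle.static_num) * m_s) ** 2).sum() / m_s.sum())
        var_s = float(np.var(bundle.static_num[m_s.astype(bool)]))
        assert mse_s < 0.6 * var_s
        m_t = bundle.mask_temp_num
        mse_t = float((((pred.temp_num - bundle.temp_num) * m_t) ** 2).sum() / m_t.sum())
        var_t = float(np.var(bundle.temp_num[m_t.astype(bool)]))
        assert mse_t < 1.1 * var_t


class TestEncodeDataset:
    def test_one_latent_row_per_patient(self, trained_ae):
        model, _, bundle, _ = trained_ae
        latents = encode_dataset(bundle, model)
        assert latents.latents.shape == (bundle.n_patients, model.config.d_e)
        assert latents.encoder_checksum

    def test_identical_records_identical_latents(self, trained_ae):
        model, _, bundle, _ = trained_ae
        dup = bundle.take(np.array([0, 0]))
        lat = encode_dataset(dup, model).latents
        assert np.array_equal(lat[0], lat[1])

    def test_width_mismatch_rejected(self, trained_ae):
        model, _, bundle, _ = trained_ae
        bad = ModelBundle(**{f: np.copy(getattr(bundle, f))
                             for f in bundle.__dataclass_fields__})
        bad.static_emb = np.zeros((bundle.n_patients, 9))
        with pytest.raises(ValueError, match="widths"):
            encode_dataset(bad, model)

    def test_latents_separate_outcome_groups(self, trained_small_model):
        """Latents carry outcome signal: a linear probe beats chance by 3
        null standard deviations (Mann-Whitney null sd of the AUC)."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score
        from sklearn.model_selection import train_test_split as sk_split

        model = trained_small_model["model"]
        tr, trm = trained_small_model["train"]
        schema = trained_small_model["schema"]
        bundle = assemble_inputs(tr, trm, model.normalizer, model.static_codec,
                                 model.temporal_codec, schema)
        lat = encode_dataset(bundle, model.autoencoder).latents
        y = tr.static_num[:, list(schema.static_numeric).index("mortality")]
        Xtr, Xte, ytr, yte = sk_split(lat, y, test_size=0.5, random_state=0, stratify=y)
        probe = LogisticRegression(max_iter=2000).fit(Xtr, ytr)
        auc = roc_auc_score(yte, probe.predict_proba(Xte)[:, 1])
        n1, n0 = int(yte.sum()), int((1 - yte).sum())
        null_sd = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert auc > 0.5 + 3 * null_sd
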