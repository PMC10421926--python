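"""End-to-end orchestration: training, the model container, evaluation.

Training follows the two-stage recipe: derive masks, one-hot categoricals,
train the static and temporal codecs, stochastic-normalize numerics and
times, train the masked sequential autoencoder, encode the cohort to
latents, train the WGAN-GP over latents.  Three ablation switches turn off
stochastic normalization (min-max scaling instead), mask modeling (masks
dropped from inputs/losses, missing numerics mean-imputed), or categorical
embedding (raw one-hot blocks passed through).

A trained model is saved as a directory container: schema + normalizer +
codec/autoencoder/generator weights + config + a manifest of content
hashes.  One master seed fans out to named substreams so each stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autoencoder import (Autoencoder, ModelBundle, TrainingConfig, assemble_inputs,
                          encode_dataset, train_autoencoder)
from .codec import CategoricalCodec, CodecTrainingConfig, IdentityCodec, one_hot_block, train_codec
from .data import EHRDataset, MaskSet
from .gan import Critic, GanPair, Generator, train_wgan_gp
from .normalization import CohortNormalizer, MinMaxNormalizer, load_normalizer
from .schema import FeatureSchema, load_schema, save_schema
from .synthesis import synthesize

logger = logging.getLogger(__name__)


def _savez(path, arrays, extra: dict | None = None):
    payload = {f"p{i:04d}": a for i, a in enumerate(arrays)}
    payload.update(extra or {})
    np.savez(path, **payload)


def _loadz(path) -> list[np.ndarray]:
    with np.load(path) as z:
        return [z[k] for k in sorted(k for k in z.files if k.startswith("p"))]


@dataclass
class PipelineConfig:
    seed: int = 0
    d_c_static: int | None = None
    d_c_temporal: int | None = None
    codec_epochs: int = 150
    training: TrainingConfig = field(default_factory=TrainingConfig)
    # ablation switches
    stochastic_norm: bool = True
    mask_modeling: bool = True
    categorical_embedding: bool = True

    def resolved_training(self) -> TrainingConfig:
        return dataclasses.replace(self.training, seed=self.seed)


@dataclass
class SynthesizerModel:
    """Trained bundle: everything needed for synthesis and evaluation."""

    schema: FeatureSchema
    normalizer: CohortNormalizer | MinMaxNormalizer
    static_codec: CategoricalCodec | IdentityCodec | None
    temporal_codec: CategoricalCodec | IdentityCodec | None
    autoencoder: Autoencoder
    gan: GanPair
    config: PipelineConfig
    logs: dict = field(default_factory=dict)

    def synthesize(self, m: int, seed: int = 0) -> tuple[EHRDataset, MaskSet]:
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 71])
        return synthesize(self.gan.generator, self.autoencoder, self.static_codec,
                          self.temporal_codec, self.normalizer, self.schema, m, rng)

    # --- container IO ------------------------------------------------
    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_schema(self.schema, out / "schema.yaml")
        self.normalizer.to_json(out / "normalizer.json")
        meta: dict = {"config": _config_to_dict(self.config), "logs_keys": sorted(self.logs)}
        for name, codec in (("static_codec", self.static_codec),
                            ("temporal_codec", self.temporal_codec)):
            if codec is None:
                meta[name] = None
            elif isinstance(codec, IdentityCodec):
                meta[name] = {"type": "identity", "scope": codec.scope,
                              "vocab_sizes": codec.vocab_sizes}
            else:
                meta[name] = {"type": "trained", "scope": codec.scope,
                              "vocab_sizes": codec.vocab_sizes, "d_c": codec.d_c}
                _savez(out / f"{name}.npz", codec.state_arrays())
        meta["autoencoder"] = {"d_cs": self.autoencoder.d_cs, "d_ct": self.autoencoder.d_ct,
                               "mask_modeling": self.autoencoder.mask_modeling}
        _savez(out / "autoencoder.npz", self.autoencoder.state_arrays())
        G = self.gan.generator
        meta["generator"] = {"d_z": G.d_z, "d_e": G.d_e,
                             "width": G.net.layers[0].W.data.shape[1], "depth": len(G.net.layers)}
        _savez(out / "generator.npz", G.state_arrays(),
               extra={"shift": G.shift.data, "scale": G.scale.data})
        _savez(out / "critic.npz", self.gan.critic.state_arrays())
        (out / "model.json").write_text(json.dumps(meta, indent=1))
        manifest = {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(out.iterdir()) if p.name != "manifest.json"}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return out

    @classmethod
    def load(cls, in_dir) -> "SynthesizerModel":
        src = Path(in_dir)
        schema = load_schema(src / "schema.yaml")
        normalizer = load_normalizer(src / "normalizer.json")
        meta = json.loads((src / "model.json").read_text())
        config = _config_from_dict(meta["config"])
        rng = np.random.default_rng(0)

        def load_codec(name):
            m = meta[name]
            if m is None:
                return None
            if m["type"] == "identity":
                return IdentityCodec(m["scope"], m["vocab_sizes"])
            codec = CategoricalCodec(m["scope"], m["vocab_sizes"], m["d_c"], rng)
            codec.load_state_arrays(_loadz(src / f"{name}.npz"))
            return codec

        static_codec = load_codec("static_codec")
        temporal_codec = load_codec("temporal_codec")
        ae = Autoencoder(schema, meta["autoencoder"]["d_cs"], meta["autoencoder"]["d_ct"],
                         config.resolved_training(), mask_modeling=meta["autoencoder"]["mask_modeling"])
        ae.load_state_arrays(_loadz(src / "autoencoder.npz"))
        gm = meta["generator"]
        with np.load(src / "generator.npz") as z:
            shift, scale = z["shift"], z["scale"]
        G = Generator(gm["d_z"], gm["d_e"], rng, width=gm["width"], depth=gm["depth"],
                      out_shift=shift, out_scale=scale)
        G.load_state_arrays(_loadz(src / "generator.npz"))
        D = Critic(gm["d_e"], rng)
        D.load_state_arrays(_loadz(src / "critic.npz"))
        return cls(schema, normalizer, static_codec, temporal_codec, ae,
                   GanPair(G, D, {}), config)


def _config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    d["training"] = TrainingConfig(**d["training"])
    return PipelineConfig(**d)


def train_pipeline(
    dataset: EHRDataset,
    masks: MaskSet,
    schema: FeatureSchema,
    config: PipelineConfig | None = None,
) -> SynthesizerModel:
    """Run the full two-stage training on a prepared (padded) cohort."""
    config = config or PipelineConfig()
    tcfg = config.resolved_training()
    logs: dict = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("normalization fit")
        norm_cls = CohortNormalizer if config.stochastic_norm else MinMaxNormalizer
        normalizer = norm_cls.fit(dataset, masks, schema, seed=config.seed)

        stage("categorical codecs")
        static_codec = temporal_codec = None
        if schema.static_categorical:
            sizes = [len(v) for v in schema.static_cat_vocabs]
            if config.categorical_embedding:
                oh = one_hot_block(dataset.static_cat, sizes)
                static_codec, hist = train_codec(
                    oh, sizes, d_c=config.d_c_static,
                    config=CodecTrainingConfig(epochs=config.codec_epochs, seed=config.seed + 10),
                    scope="static")
                logs["static_codec_loss"] = hist
            else:
                static_codec = IdentityCodec("static", sizes)
        if schema.temporal_categorical:
            sizes = [len(v) for v in schema.temporal_cat_vocabs]
            if config.categorical_embedding:
                obs_steps = masks.step_present.astype(bool)
                oh = one_hot_block(dataset.temp_cat[obs_steps], sizes)
                temporal_codec, hist = train_codec(
                    oh, sizes, d_c=config.d_c_temporal,
                    config=CodecTrainingConfig(epochs=config.codec_epochs, seed=config.seed + 11),
                    scope="temporal")
                logs["temporal_codec_loss"] = hist
            else:
                temporal_codec = IdentityCodec("temporal", sizes)

        stage("assemble model-space inputs")
        bundle = assemble_inputs(dataset, masks, normalizer, static_codec, temporal_codec,
                                 schema, impute_missing=not config.mask_modeling)

        stage("autoencoder training")
        ae, ae_hist = train_autoencoder(bundle, schema, tcfg, mask_modeling=config.mask_modeling)
        logs["autoencoder_loss"] = ae_hist

        stage("latent encoding")
        latents = encode_dataset(bundle, ae)

        stage("WGAN-GP training")
        gan = train_wgan_gp(latents, tcfg)
        logs["gan_critic_loss"] = gan.history["critic"]
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage with logs {sorted(logs)}: {err}") from err

    return SynthesizerModel(schema, normalizer, static_codec, temporal_codec, ae, gan,
                            config, logs)


def run_eval(
    model: SynthesizerModel,
    real_train: tuple[EHRDataset, MaskSet],
    real_holdout: tuple[EHRDataset, MaskSet],
    targets: list[str],
    attributes: list[str] | None = None,
    seed: int = 0,
    model_kinds: tuple[str, ...] = ("rf", "lr"),
    subset_features: int = 10,
    subset_trials: int = 6,
    oracle_mode: bool = False,
) -> dict:
    """Synthesize |train| records and run the full metric battery.

    ``oracle_mode`` replaces the synthetic cohort with the real holdout —
    the no-privacy-risk reference configuration.
    """
    from .fidelity import subset_utility_test, summary_table, tstr_utility
    from .privacy import attribute_inference, membership_inference, reidentification_risk

    schema = model.schema
    if oracle_mode:
        synth = real_holdout
    else:
        synth = model.synthesize(real_train[0].n_patients, seed=seed)

    report: dict = {"n_synth": synth[0].n_patients, "oracle_mode": oracle_mode}
    report["summary"] = summary_table(real_train, synth, schema).to_dict(orient="records")

    utility = {}
    for target in targets:
        utility[target] = {}
        for kind in model_kinds:
            res = tstr_utility(real_train, synth, real_holdout, schema, target,
                               model_kind=kind, seed=seed)
            utility[target][kind] = {src: {"auc": v[0], "ap": v[1]} for src, v in res.items()}
    report["utility"] = utility
    report["subset_test"] = subset_utility_test(
        real_train, synth, real_holdout, schema, targets,
        n_features=subset_features, n_trials=subset_trials, seed=seed,
    ).to_dict(orient="records")

    n_q = min(real_train[0].n_patients, real_holdout[0].n_patients)
    rng = np.random.default_rng(seed)
    tr_idx = rng.permutation(real_train[0].n_patients)[:n_q]
    ho_idx = rng.permutation(real_holdout[0].n_patients)[:n_q]
    tq = (real_train[0].take(tr_idx), real_train[1].take(tr_idx))
    hq = (real_holdout[0].take(ho_idx), real_holdout[1].take(ho_idx))
    mi = membership_inference(synth, tq, hq, schema)
    reid = reidentification_risk(synth, real_train, real_holdout, schema, seed=seed)
    report["privacy"] = {
        "membership_inference": dataclasses.asdict(mi),
        "reidentification": dataclasses.asdict(reid),
    }
    for attr in attributes or []:
        res = attribute_inference(synth, real_train, real_holdout, schema, attr)
        report["privacy"][f"attribute_inference_{attr}"] = dataclasses.asdict(res)
    return report
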