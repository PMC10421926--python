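"""Masked sequential autoencoder over assembled heterogeneous records.

The assembled model-space representation of a cohort keeps every channel
in [0, 1] (normalized numerics, times) or {0, 1} (masks), with categorical
features replaced by codec embeddings and missing/padded numerics set to
zero.  A GRU encoder consumes the per-step temporal concatenation, its
final state is fused with a feed-forward static branch, and a linear
projection yields a fixed-width latent per patient.  The decoder mirrors
this: static heads from the latent, plus a GRU unrolled for ``T_max``
steps (fed the latent at every step) emitting per-step values and mask
logits.

The reconstruction loss is mask-gated: binary cross entropy on every mask
channel (padded steps excluded via ``step_present``) plus
lambda-weighted mean squared error on values, where entries whose mask is
zero contribute exactly nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import xlogy

from .codec import one_hot_block
from .data import EHRDataset, MaskSet
from .nn import GRUCell, Linear, MLP, Adam, Module, Tensor, concat, getitem, grad, sigmoid, softplus, tanh, tmean, tsum
from .normalization import CohortNormalizer
from .schema import FeatureSchema


@dataclass
class ModelBundle:
    """Model-space arrays for a batch of patients (padded to T_max)."""

    static_num: np.ndarray      # (N, Sn) in [0,1], 0 where missing
    static_emb: np.ndarray      # (N, dcs)
    mask_static_num: np.ndarray  # (N, Sn)
    mask_static_cat: np.ndarray  # (N, Sc)
    temp_num: np.ndarray        # (N, T, Tn)
    temp_emb: np.ndarray        # (N, T, dct)
    times: np.ndarray           # (N, T)
    mask_temp_num: np.ndarray   # (N, T, Tn)
    mask_temp_cat: np.ndarray   # (N, T, Tc)
    step_present: np.ndarray    # (N, T)

    @property
    def n_patients(self) -> int:
        return self.static_num.shape[0]

    @property
    def n_steps(self) -> int:
        return self.times.shape[1]

    def take(self, idx) -> "ModelBundle":
        idx = np.asarray(idx)
        return ModelBundle(*(getattr(self, f.name)[idx] for f in self.__dataclass_fields__.values()))  # type: ignore[attr-defined]


@dataclass
class TrainingConfig:
    """Hyper-parameters for the autoencoder and the latent GAN."""

    lam: float = 1.0           # balance between mask BCE and value MSE
    d_e: int = 64              # latent width
    hidden: int = 128
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 40
    seed: int = 0
    # GAN fields
    eta: float = 10.0          # gradient-penalty weight
    critic_steps: int = 5
    d_z: int | None = None     # defaults to d_e
    gan_iters: int = 600
    gan_batch_size: int = 128
    gan_learning_rate: float = 1e-3
    gan_width: int = 256
    gan_depth: int = 3

    def __post_init__(self):
        if self.lam <= 0 or self.eta <= 0:
            raise ValueError("lam and eta must be positive")
        if min(self.d_e, self.hidden, self.batch_size, self.epochs) < 1:
            raise ValueError("dimensions, batch size and epochs must be >= 1")


def assemble_inputs(
    dataset: EHRDataset,
    masks: MaskSet,
    normalizer: CohortNormalizer,
    static_codec,
    temporal_codec,
    schema: FeatureSchema,
    impute_missing: bool = False,
) -> ModelBundle:
    """Normalize numerics, embed categoricals, zero out missing entries.

    ``impute_missing=True`` (the no-mask-modeling ablation) replaces missing
    numerics with the mean of the observed normalized values instead of 0.
    """
    sp = masks.step_present.astype(np.float64)
    sn = normalizer.normalize_static(dataset.static_num, schema)
    tn = normalizer.normalize_temporal(dataset.temp_num, schema)
    u = normalizer.normalize_times(dataset.times, masks.step_present)

    def fill(x, m):
        if impute_missing:
            out = np.array(x)
            for j in range(x.shape[-1]):
                col = x[..., j]
                obs = m[..., j].astype(bool)
                mean = col[obs].mean() if obs.any() else 0.0
                out[..., j] = np.where(obs, col, mean)
            return out
        return np.where(m.astype(bool), x, 0.0)

    sn = fill(np.nan_to_num(sn, nan=0.0) if not impute_missing else sn, masks.static_num)
    sn = np.nan_to_num(sn, nan=0.0)
    tn = fill(np.nan_to_num(tn, nan=0.0) if not impute_missing else tn, masks.temp_num)
    tn = np.nan_to_num(tn, nan=0.0)
    tn *= sp[:, :, None]  # padded steps are zero

    if static_codec is not None:
        s_oh = one_hot_block(dataset.static_cat, list(static_codec.vocab_sizes))
        s_emb = static_codec.encode(s_oh)
    else:
        s_emb = np.zeros((dataset.n_patients, 0))
    if temporal_codec is not None:
        t_oh = one_hot_block(dataset.temp_cat, list(temporal_codec.vocab_sizes))
        t_emb = temporal_codec.encode(t_oh)
        t_emb = t_emb * sp[:, :, None]
    else:
        t_emb = np.zeros(dataset.times.shape + (0,))

    return ModelBundle(
        static_num=sn,
        static_emb=s_emb,
        mask_static_num=masks.static_num.astype(np.float64),
        mask_static_cat=masks.static_cat.astype(np.float64),
        temp_num=tn,
        temp_emb=t_emb,
        times=u * sp,
        mask_temp_num=masks.temp_num.astype(np.float64) * sp[:, :, None],
        mask_temp_cat=masks.temp_cat.astype(np.float64) * sp[:, :, None],
        step_present=sp,
    )


def reconstruction_loss(pred: ModelBundle, target: ModelBundle, lam: float = 1.0,
                        mask_modeling: bool = True) -> float:
    """Mask-gated reconstruction loss (numpy reference implementation).

    Mask channels in ``pred`` hold probabilities; value channels hold
    normalized predictions.  Entries whose target mask is 0 and padded
    steps contribute exactly zero to every squared-error term.
    """
    for f in pred.__dataclass_fields__:
        if not np.all(np.isfinite(getattr(pred, f))):
            raise ValueError(f"non-finite predictions in {f}")

    def bce(p, t, gate=None):
        term = -(xlogy(t, p) + xlogy(1.0 - t, 1.0 - p))
        if gate is None:
            return term.mean() if term.size else 0.0
        total = gate.sum() * (term.shape[-1] if term.ndim == 3 else 1)
        if total == 0:
            return 0.0
        gated = term * (gate[..., None] if term.ndim == 3 else gate)
        return gated.sum() / total

    def gated_mse(p, t, m):
        if m.sum() == 0 or p.size == 0:
            return 0.0
        return float((((p - t) * m) ** 2).sum() / m.sum())

    sp = target.step_present
    loss = 0.0
    if mask_modeling:
        loss += bce(pred.mask_static_num, target.mask_static_num)
        loss += bce(pred.mask_static_cat, target.mask_static_cat)
        loss += bce(pred.mask_temp_num, target.mask_temp_num, gate=sp)
        loss += bce(pred.mask_temp_cat, target.mask_temp_cat, gate=sp)
    loss += bce(pred.step_present, sp)
    mse = gated_mse(pred.times, target.times, sp)
    m_sn = target.mask_static_num if mask_modeling else np.ones_like(target.static_num)
    m_tn = target.mask_temp_num if mask_modeling else sp[:, :, None] * np.ones_like(target.temp_num)
    mse += gated_mse(pred.static_num, target.static_num, m_sn)
    mse += gated_mse(pred.temp_num, target.temp_num, m_tn)
    if target.static_emb.size:
        mse += float(((pred.static_emb - target.static_emb) ** 2).mean())
    if target.temp_emb.size:
        mse += gated_mse(pred.temp_emb, target.temp_emb,
                         np.broadcast_to(sp[:, :, None], target.temp_emb.shape))
    return float(loss + lam * mse)


class Autoencoder(Module):
    """Encoder E (record -> latent e) and decoder F (latent -> record)."""

    def __init__(self, schema: FeatureSchema, d_cs: int, d_ct: int,
                 config: TrainingConfig, mask_modeling: bool = True):
        self.schema_hash = schema.content_hash()
        self.t_max = schema.max_seq_len
        self.Sn = len(schema.static_numeric)
        self.Sc = len(schema.static_categorical)
        self.Tn = len(schema.temporal_numeric)
        self.Tc = len(schema.temporal_categorical)
        self.d_cs, self.d_ct = d_cs, d_ct
        self.config = config
        self.mask_modeling = mask_modeling
        H, d_e = config.hidden, config.d_e
        rng = np.random.default_rng(config.seed)

        mask_t = (self.Tn + self.Tc) if mask_modeling else 0
        mask_s = (self.Sn + self.Sc) if mask_modeling else 0
        self.step_in = self.Tn + d_ct + 1 + mask_t + 1   # values, emb, time, masks, step_present
        self.static_in = self.Sn + d_cs + mask_s
        self.enc_gru = GRUCell(self.step_in, H, rng)
        self.enc_static = MLP([max(self.static_in, 1), H], rng)
        # mean-pool skip branch: step-averaged inputs bypass the recurrence
        self.enc_pool = Linear(self.step_in, H, rng)
        self.enc_proj = Linear(3 * H, d_e, rng)

        self.step_out = self.Tn + d_ct + 1 + (self.Tn + self.Tc) + 1
        self.static_out = self.Sn + d_cs + self.Sn + self.Sc
        self.dec_static = MLP([d_e, H, max(self.static_out, 1)], rng)
        self.dec_h0 = Linear(d_e, H, rng)
        self.dec_gru = GRUCell(d_e, H, rng)
        # head sees the hidden state plus a normalized step-position channel
        self.dec_head = Linear(H + 1, self.step_out, rng)

    # --- graph builders -------------------------------------------
    def _step_inputs(self, bundle: ModelBundle) -> list[np.ndarray]:
        parts = [bundle.temp_num, bundle.temp_emb, bundle.times[:, :, None]]
        if self.mask_modeling:
            parts += [bundle.mask_temp_num, bundle.mask_temp_cat]
        parts.append(bundle.step_present[:, :, None])
        return np.concatenate(parts, axis=2)

    def _static_inputs(self, bundle: ModelBundle) -> np.ndarray:
        parts = [bundle.static_num, bundle.static_emb]
        if self.mask_modeling:
            parts += [bundle.mask_static_num, bundle.mask_static_cat]
        x = np.concatenate(parts, axis=1)
        if x.shape[1] == 0:
            x = np.zeros((x.shape[0], 1))
        return x

    def encode_graph(self, bundle: ModelBundle) -> Tensor:
        x = self._step_inputs(bundle)           # (N, T, step_in), constant
        n, T, _ = x.shape
        h = self.enc_gru.init_state(n)
        for t in range(T):
            h = self.enc_gru.step(Tensor(np.ascontiguousarray(x[:, t, :])), h)
        h_s = self.enc_static(Tensor(self._static_inputs(bundle)))
        denom = np.maximum(bundle.step_present.sum(axis=1, keepdims=True), 1.0)
        h_p = tanh(self.enc_pool(Tensor(x.sum(axis=1) / denom)))
        return self.enc_proj(concat([h, h_p, h_s], axis=1))

    def decode_graph(self, e: Tensor, n_steps: int) -> dict[str, Tensor]:
        """Raw heads: values linear, masks as logits."""
        out: dict[str, Tensor] = {}
        s = self.dec_static(e)
        o = 0

        def cut(t, width, axis=1):
            nonlocal o
            idx = (slice(None), slice(o, o + width)) if axis == 1 else (slice(None), slice(None), slice(o, o + width))
            o += width
            return getitem(t, idx)

        out["static_num"] = cut(s, self.Sn)
        out["static_emb"] = cut(s, self.d_cs)
        out["mask_static_num_logit"] = cut(s, self.Sn)
        out["mask_static_cat_logit"] = cut(s, self.Sc)

        h = tanh(self.dec_h0(e))
        gx = self.dec_gru.x2h(e)  # decoder input is e at every step
        n = e.shape[0]
        per_step = []
        for t in range(n_steps):
            h = self.dec_gru.step(None, h, gx=gx)
            pos = Tensor(np.full((n, 1), (t + 1) / max(n_steps, 1)))
            per_step.append(self.dec_head(concat([h, pos], axis=1)))
        # stack as (N, T, step_out) via concat of reshaped steps
        from .nn import reshape

        n = e.shape[0]
        stacked = concat([reshape(p, (n, 1, self.step_out)) for p in per_step], axis=1)
        o = 0
        out["temp_num"] = cut(stacked, self.Tn, axis=2)
        out["temp_emb"] = cut(stacked, self.d_ct, axis=2)
        out["times"] = cut(stacked, 1, axis=2)
        out["mask_temp_num_logit"] = cut(stacked, self.Tn, axis=2)
        out["mask_temp_cat_logit"] = cut(stacked, self.Tc, axis=2)
        out["step_present_logit"] = cut(stacked, 1, axis=2)
        return out

    def loss_graph(self, bundle: ModelBundle) -> Tensor:
        e = self.encode_graph(bundle)
        out = self.decode_graph(e, bundle.n_steps)
        lam = self.config.lam
        sp = Tensor(bundle.step_present[:, :, None])

        def bce_logits(logit: Tensor, target: np.ndarray, gate: Tensor | None = None) -> Tensor:
            t = Tensor(target)
            term = softplus(logit) - logit * t
            if gate is None:
                return tmean(term) if target.size else Tensor(0.0)
            total = max(float(gate.data.sum()) * target.shape[-1], 1.0)
            return tsum(term * gate) * Tensor(1.0 / total)

        def mse(pred: Tensor, target: np.ndarray, m: np.ndarray) -> Tensor:
            if target.size == 0 or m.sum() == 0:
                return Tensor(0.0)
            mt = Tensor(m)
            d = (pred - Tensor(target)) * mt
            return tsum(d * d) * Tensor(1.0 / float(m.sum()))

        loss = bce_logits(out["step_present_logit"],
                          bundle.step_present[:, :, None])
        if self.mask_modeling:
            loss = loss + bce_logits(out["mask_static_num_logit"], bundle.mask_static_num)
            loss = loss + bce_logits(out["mask_static_cat_logit"], bundle.mask_static_cat)
            loss = loss + bce_logits(out["mask_temp_num_logit"], bundle.mask_temp_num, gate=sp)
            loss = loss + bce_logits(out["mask_temp_cat_logit"], bundle.mask_temp_cat, gate=sp)
        m_sn = bundle.mask_static_num if self.mask_modeling else np.ones_like(bundle.static_num)
        m_tn = (bundle.mask_temp_num if self.mask_modeling
                else bundle.step_present[:, :, None] * np.ones_like(bundle.temp_num))
        v = mse(out["times"], bundle.times[:, :, None], bundle.step_present[:, :, None])
        v = v + mse(out["static_num"], bundle.static_num, m_sn)
        v = v + mse(out["temp_num"], bundle.temp_num, m_tn)
        if self.d_cs:
            v = v + mse(out["static_emb"], bundle.static_emb, np.ones_like(bundle.static_emb))
        if self.d_ct:
            gate = np.broadcast_to(bundle.step_present[:, :, None], bundle.temp_emb.shape)
            v = v + mse(out["temp_emb"], bundle.temp_emb, np.ascontiguousarray(gate))
        return loss + Tensor(lam) * v

    # --- inference -------------------------------------------------
    def encode(self, bundle: ModelBundle) -> np.ndarray:
        return self.encode_graph(bundle).data

    def decode(self, e: np.ndarray) -> ModelBundle:
        """Latents -> ModelBundle-shaped outputs (mask channels as probabilities)."""
        from scipy.special import expit

        out = self.decode_graph(Tensor(e), self.t_max)
        sig = lambda t: expit(t.data)  # noqa: E731
        return ModelBundle(
            static_num=out["static_num"].data,
            static_emb=out["static_emb"].data,
            mask_static_num=sig(out["mask_static_num_logit"]),
            mask_static_cat=sig(out["mask_static_cat_logit"]),
            temp_num=out["temp_num"].data,
            temp_emb=out["temp_emb"].data,
            times=out["times"].data[:, :, 0],
            mask_temp_num=sig(out["mask_temp_num_logit"]),
            mask_temp_cat=sig(out["mask_temp_cat_logit"]),
            step_present=sig(out["step_present_logit"])[:, :, 0],
        )


@dataclass
class LatentDataset:
    """Encoder states, one row per patient, with an encoder provenance tag."""

    latents: np.ndarray
    encoder_checksum: str = ""

    def __post_init__(self):
        if not np.all(np.isfinite(self.latents)):
            raise ValueError("latents must be finite")


def train_autoencoder(
    bundle: ModelBundle,
    schema: FeatureSchema,
    config: TrainingConfig,
    mask_modeling: bool = True,
) -> tuple[Autoencoder, list[float]]:
    """Fit the masked autoencoder; returns (model, per-epoch loss history)."""
    model = Autoencoder(schema, bundle.static_emb.shape[1], bundle.temp_emb.shape[2],
                        config, mask_modeling=mask_modeling)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history: list[float] = []
    N = bundle.n_patients
    for _ in range(config.epochs):
        order = rng.permutation(N)
        epoch_loss = 0.0
        for start in range(0, N, config.batch_size):
            idx = order[start: start + config.batch_size]
            loss = model.loss_graph(bundle.take(idx))
            if not np.isfinite(loss.data):
                raise RuntimeError(f"autoencoder training diverged; history={history}")
            grads = grad(loss, model.parameters())
            opt.step([g.data for g in grads])
            epoch_loss += float(loss.data) * len(idx)
        history.append(epoch_loss / N)
    return model, history


def encode_dataset(bundle: ModelBundle, model: Autoencoder) -> LatentDataset:
    """One latent row per patient, deterministic for fixed weights."""
    exp_widths = (model.Sn, model.d_cs, model.Tn, model.d_ct)
    got = (bundle.static_num.shape[1], bundle.static_emb.shape[1],
           bundle.temp_num.shape[2], bundle.temp_emb.shape[2])
    if exp_widths != got:
        raise ValueError(f"bundle widths {got} do not match the trained model {exp_widths}")
    return LatentDataset(model.encode(bundle), model.checksum())
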