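"""End-to-end synthesis of cohorts from random vectors, plus the optional
bucket-ratio-matching post-processor.

The pipeline is: sample synthetic latents from the generator, decode them
with the trained decoder, realize the decoded mask probabilities, read the
sequence length off the ``step_present`` channel (threshold 0.5, leading
run of ones, floor 1), decode categorical embeddings through the frozen
codec heads, renormalize numerics and times through the fitted interval
maps, and emit entries with mask 0 as missing.  The mask channel is the
authoritative source of missingness: where it disagrees with a codec
head's missing slot, the mask wins.

Mask probabilities are by default *sampled* (m ~ Bernoulli(p)) rather than
thresholded at 0.5, and categorical heads are sampled from their softmax
distributions rather than argmax-decoded: the mask heads are trained with
binary cross entropy and the categorical heads with softmax cross entropy,
i.e. exactly the negative log-likelihoods of those conditional
distributions, so drawing from them is sampling from the fitted model.
Deterministic thresholding collapses missingness whenever the latent does
not resolve individual entries (which is the information-theoretic optimum
under missing-completely-at-random patterns).  ``mask_mode="threshold"``
and ``categorical_mode="argmax"`` restore the deterministic variants.
"""

from __future__ import annotations

import logging

import numpy as np

from .autoencoder import Autoencoder, ModelBundle
from .data import EHRDataset, MaskSet, derive_masks, validate_cohort
from .gan import Generator, sample_latents
from .normalization import TIME_KEY, CohortNormalizer
from .schema import FeatureSchema

logger = logging.getLogger(__name__)


def derive_sequence_lengths(step_present_probs: np.ndarray, t_max: int) -> np.ndarray:
    """Lengths from decoded step-present probabilities.

    Threshold at 0.5; the length is the leading run of ones, floored at 1
    (an admitted patient has at least one step).
    """
    on = np.asarray(step_present_probs) >= 0.5
    on = on[:, :t_max]
    # length of leading run of True per row
    first_off = np.where(~on, np.arange(on.shape[1])[None, :], on.shape[1])
    lengths = first_off.min(axis=1)
    return np.maximum(lengths, 1).astype(np.int64)


def synthesize(
    generator: Generator,
    autoencoder: Autoencoder,
    static_codec,
    temporal_codec,
    normalizer: CohortNormalizer,
    schema: FeatureSchema,
    m: int,
    rng: np.random.Generator,
    mask_mode: str = "sample",
    categorical_mode: str = "sample",
) -> tuple[EHRDataset, MaskSet]:
    """Generate ``m`` synthetic records satisfying every cohort invariant."""
    if m <= 0:
        raise ValueError("number of synthetic records must be positive")
    if mask_mode not in ("sample", "threshold") or categorical_mode not in ("sample", "argmax"):
        raise ValueError("mask_mode must be sample|threshold, categorical_mode sample|argmax")
    if autoencoder.schema_hash != schema.content_hash():
        raise ValueError("autoencoder was trained on a different schema")
    latents = sample_latents(generator, m, rng)
    if latents.shape[1] != autoencoder.config.d_e:
        raise ValueError("generator latent width does not match the autoencoder")
    dec: ModelBundle = autoencoder.decode(latents)
    T = schema.max_seq_len

    lengths = derive_sequence_lengths(dec.step_present, T)
    step_mask = np.arange(T)[None, :] < lengths[:, None]

    def realize(p: np.ndarray) -> np.ndarray:
        if mask_mode == "sample":
            return rng.random(p.shape) < p
        return p >= 0.5

    mask_modeling = autoencoder.mask_modeling
    if mask_modeling:
        m_sn = realize(dec.mask_static_num)
        m_tn = realize(dec.mask_temp_num) & step_mask[:, :, None]
    else:  # ablation: masks are not modeled, everything in-length is observed
        m_sn = np.ones_like(dec.mask_static_num, dtype=bool)
        m_tn = np.ones_like(dec.mask_temp_num, dtype=bool) & step_mask[:, :, None]

    static_num = np.full(dec.static_num.shape, np.nan)
    for j, name in enumerate(schema.static_numeric):
        col = normalizer.renormalize_feature(name, np.clip(dec.static_num[:, j], 0, 1))
        static_num[:, j] = np.where(m_sn[:, j], col, np.nan)

    temp_num = np.full(dec.temp_num.shape, np.nan)
    for j, name in enumerate(schema.temporal_numeric):
        col = normalizer.renormalize_feature(name, np.clip(dec.temp_num[:, :, j], 0, 1))
        temp_num[:, :, j] = np.where(m_tn[:, :, j], col, np.nan)

    times = normalizer.renormalize_feature(TIME_KEY, np.clip(dec.times, 0, 1))
    times = np.where(step_mask, times, 0.0)
    # generation does not guarantee temporal order; enforce it per record
    for i in range(m):
        L = lengths[i]
        times[i, :L] = np.sort(times[i, :L])

    def decode_cats(codec, emb):
        """(codes incl. -1 for the missing slot, forced in-vocabulary codes)."""
        if categorical_mode == "argmax":
            codes, obs = codec.decode(emb)
            return np.where(obs.astype(bool), codes, -1), codec.decode_forced(emb)
        K = len(codec.vocab_sizes)
        codes = np.zeros(emb.shape[:-1] + (K,), dtype=np.int64)
        forced = np.zeros_like(codes)
        for k, p in enumerate(codec.head_probs(emb)):
            V = codec.vocab_sizes[k]
            flat = p.reshape(-1, V + 1)
            u = rng.random((flat.shape[0], 1))
            drawn = (flat.cumsum(axis=1) < u).sum(axis=1).clip(0, V)
            cat_p = flat[:, :V]
            cat_p = cat_p / np.maximum(cat_p.sum(axis=1, keepdims=True), 1e-12)
            u2 = rng.random((flat.shape[0], 1))
            drawn_forced = (cat_p.cumsum(axis=1) < u2).sum(axis=1).clip(0, V - 1)
            codes[..., k] = np.where(drawn == V, -1, drawn).reshape(emb.shape[:-1])
            forced[..., k] = np.where(drawn == V, drawn_forced, drawn).reshape(emb.shape[:-1])
        return codes, forced

    # categoricals: codec decodes value + missing slot; mask channel overrides
    if static_codec is not None:
        codes, forced = decode_cats(static_codec, dec.static_emb)
        if mask_modeling:
            m_sc = realize(dec.mask_static_cat)
            static_cat = np.where(m_sc, np.where(codes >= 0, codes, forced), -1)
        else:
            static_cat = forced
    else:
        static_cat = np.zeros((m, 0), dtype=np.int64)

    if temporal_codec is not None:
        codes, forced = decode_cats(temporal_codec, dec.temp_emb)
        if mask_modeling:
            m_tc = realize(dec.mask_temp_cat) & step_mask[:, :, None]
            temp_cat = np.where(m_tc, np.where(codes >= 0, codes, forced), -1)
        else:
            temp_cat = np.where(step_mask[:, :, None], forced, -1)
    else:
        temp_cat = np.zeros((m, T, 0), dtype=np.int64)

    ids = np.array([f"synth{i:06d}" for i in range(m)], dtype=object)
    dataset = EHRDataset(ids, static_num, static_cat.astype(np.int64),
                         times, temp_num, temp_cat.astype(np.int64), lengths)
    masks = derive_masks(dataset)
    validate_cohort(dataset, masks, schema)
    return dataset, masks


def bucket_match_postprocess(
    real_values: np.ndarray,
    synth_values: np.ndarray,
    n_buckets: int = 200,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Reassign synthetic values so per-bucket proportions match the real sample.

    Buckets are real-sample quantile intervals.  The synthetic sample is
    ranked; bucket occupancy counts are allocated by largest remainder to
    match the real proportions exactly, and within each bucket values are
    drawn from the real sample's empirical distribution there.  The map is
    rank-preserving and has no trainable parameters.
    """
    real = np.asarray(real_values, dtype=np.float64)
    synth = np.asarray(synth_values, dtype=np.float64)
    real = real[~np.isnan(real)]
    synth_obs_idx = np.flatnonzero(~np.isnan(synth))
    if real.size == 0 or synth_obs_idx.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_buckets < 2:
        raise ValueError("need at least 2 buckets")
    rng = rng or np.random.default_rng(0)

    n_distinct = np.unique(real).size
    if n_buckets > n_distinct:
        logger.warning("bucket matching: %d buckets requested but only %d distinct "
                       "real values; buckets collapsed", n_buckets, n_distinct)
    edges = np.quantile(real, np.linspace(0, 1, n_buckets + 1))
    edges = np.unique(edges)  # collapse duplicate quantiles
    n_eff = len(edges) - 1
    # real occupancy per bucket [edges[k], edges[k+1]) with last bucket closed
    which = np.clip(np.searchsorted(edges, real, side="right") - 1, 0, n_eff - 1)
    real_counts = np.bincount(which, minlength=n_eff)
    props = real_counts / real.size

    M = synth_obs_idx.size
    # largest-remainder allocation of M slots to buckets
    raw = props * M
    alloc = np.floor(raw).astype(int)
    short = M - alloc.sum()
    if short > 0:
        order = np.argsort(-(raw - alloc), kind="stable")
        alloc[order[:short]] += 1

    # per-bucket real value pools
    pools = [np.sort(real[which == k]) for k in range(n_eff)]
    new_sorted = np.empty(M)
    pos = 0
    for k in range(n_eff):
        c = alloc[k]
        if c == 0:
            continue
        pool = pools[k]
        if pool.size == 0:  # empty real bucket cannot be allocated mass
            pool = real
        draws = pool[rng.integers(0, pool.size, size=c)]
        new_sorted[pos: pos + c] = np.sort(draws)
        pos += c

    # place back rank-preservingly into the synthetic order
    out = np.array(synth, dtype=np.float64)
    obs = synth[synth_obs_idx]
    rank = np.argsort(np.argsort(obs, kind="stable"), kind="stable")
    out[synth_obs_idx] = new_sorted[rank]
    return out
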