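"""Small GRU classifier for sequence-aware TSTR utility evaluation.

Consumes min-max scaled temporal values (missing set to 0) together with
the mask channels and static features; the final recurrent state joined
with the static vector feeds a logistic output.  Deliberately compact —
it is an evaluation probe, not a tuned clinical model.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .data import EHRDataset, MaskSet
from .nn import GRUCell, Linear, MLP, Adam, Module, Tensor, concat, grad, softplus, tmean
from .schema import FeatureSchema


class GruClassifier(Module):
    def __init__(self, step_in: int, static_in: int, hidden: int, rng: np.random.Generator):
        self.gru = GRUCell(step_in, hidden, rng)
        self.head = MLP([hidden + max(static_in, 1), hidden, 1], rng)

    def logits(self, steps: list[np.ndarray], static: np.ndarray) -> Tensor:
        h = self.gru.init_state(static.shape[0])
        for x in steps:
            h = self.gru.step(Tensor(x), h)
        return self.head(concat([h, Tensor(static)], axis=1))


def _prepare(dataset: EHRDataset, masks: MaskSet, schema: FeatureSchema,
             target: str, scale: dict | None):
    """Min-max scale on observed values; returns (steps, static, y, scale)."""
    sp = masks.step_present.astype(np.float64)
    tn = dataset.temp_num
    if scale is None:
        scale = {}
        for j, name in enumerate(schema.temporal_numeric):
            obs = tn[:, :, j][masks.temp_num[:, :, j].astype(bool)]
            scale[name] = (float(obs.min()), float(obs.max())) if obs.size else (0.0, 1.0)
        for j, name in enumerate(schema.static_numeric):
            obs = dataset.static_num[:, j][masks.static_num[:, j].astype(bool)]
            scale[name] = (float(obs.min()), float(obs.max())) if obs.size else (0.0, 1.0)
        u = dataset.times[sp.astype(bool)]
        scale["__time__"] = (float(u.min()), float(u.max())) if u.size else (0.0, 1.0)

    def mm(x, key):
        lo, hi = scale[key]
        return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)

    tn_s = np.stack([mm(tn[:, :, j], name) for j, name in enumerate(schema.temporal_numeric)],
                    axis=2) if len(schema.temporal_numeric) else np.zeros(tn.shape)
    tn_s = np.where(masks.temp_num.astype(bool), tn_s, 0.0)
    u_s = mm(dataset.times, "__time__") * sp
    x = np.concatenate([tn_s, masks.temp_num.astype(np.float64),
                        masks.temp_cat.astype(np.float64), u_s[:, :, None], sp[:, :, None]], axis=2)
    steps = [x[:, t, :] for t in range(x.shape[1])]

    static_parts, y = [], None
    for j, name in enumerate(schema.static_numeric):
        col = np.where(masks.static_num[:, j].astype(bool), mm(dataset.static_num[:, j], name), 0.0)
        if name == target:
            y = dataset.static_num[:, j]
            continue
        static_parts.append(col[:, None])
    for j, name in enumerate(schema.static_cat_names):
        codes = dataset.static_cat[:, j].astype(np.float64)
        if name == target:
            y = np.where(codes >= 0, codes, np.nan)
            continue
        V = len(schema.static_cat_vocabs[j])
        oh = np.zeros((len(codes), V + 1))
        idx = np.where(codes >= 0, codes, V).astype(int)
        oh[np.arange(len(codes)), idx] = 1.0
        static_parts.append(oh)
    static = np.concatenate(static_parts, axis=1) if static_parts else np.zeros((len(steps[0]), 1))
    if y is None:
        raise ValueError(f"target {target!r} is not a static feature")
    vals = np.unique(y[~np.isnan(y)])
    if len(vals) != 2:
        raise ValueError(f"target {target!r} is not binary")
    y = (y == vals.max()).astype(np.float64)
    return steps, static, y, scale


def gru_tstr(real_train, synth_train, real_test, schema: FeatureSchema,
             target: str, seed: int = 0, hidden: int = 32,
             epochs: int = 12, batch_size: int = 64) -> dict[str, tuple[float, float]]:
    results = {}
    for source, pair in (("real", real_train), ("synthetic", synth_train)):
        rng = np.random.default_rng(seed)
        steps, static, y, scale = _prepare(*pair, schema, target, None)
        te_steps, te_static, y_test, _ = _prepare(*real_test, schema, target, scale)
        if len(np.unique(y)) < 2:
            raise ValueError("training target is single-class")
        model = GruClassifier(steps[0].shape[1], static.shape[1], hidden, rng)
        opt = Adam(model.parameters(), lr=3e-3)
        N = len(y)
        for _ in range(epochs):
            order = rng.permutation(N)
            for start in range(0, N, batch_size):
                idx = order[start: start + batch_size]
                logit = model.logits([s[idx] for s in steps], static[idx])
                t = Tensor(y[idx][:, None])
                loss = tmean(softplus(logit) - logit * t)
                grads = grad(loss, model.parameters())
                opt.step([g.data for g in grads])
        p = 1.0 / (1.0 + np.exp(-model.logits(te_steps, te_static).data[:, 0]))
        results[source] = (float(roc_auc_score(y_test, p)), float(average_precision_score(y_test, p)))
    return results
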