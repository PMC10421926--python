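"""Privacy attack metrics: membership inference, re-identification risk,
and attribute inference.

All attacks operate on the flattened per-patient feature table, with a
combined distance: Euclidean on min-max scaled numeric columns plus
Hamming on categorical columns.  The membership adversary is given the
strongest threshold choice (accuracy-maximizing on the query pool itself),
so the reported accuracy is an upper bound on attack power; its ideal
value is 0.5.  The re-identification baseline replaces the synthetic set
with held-out real records — synthetic data adding no risk shows up as
risk close to that baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier

from .data import EHRDataset, MaskSet
from .fidelity import FlatCohort, flatten_features
from .schema import FeatureSchema

logger = logging.getLogger(__name__)

Cohort = tuple[EHRDataset, MaskSet]


@dataclass
class AttackResult:
    attack: str
    value: float
    ideal: float | None
    configuration: dict = field(default_factory=dict)
    query_sizes: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


# --- shared feature-space plumbing --------------------------------------


def _matrices(flat: FlatCohort, scale: dict | None):
    """(numeric matrix scaled to [0,1], categorical code matrix, scale)."""
    df = flat.frame
    num = df[flat.numeric_cols].to_numpy(dtype=np.float64) if flat.numeric_cols else np.zeros((len(df), 0))
    cat = df[flat.categorical_cols].to_numpy(dtype=np.float64) if flat.categorical_cols else np.zeros((len(df), 0))
    if scale is None:
        lo = np.nanmin(num, axis=0) if num.size else np.zeros(0)
        hi = np.nanmax(num, axis=0) if num.size else np.ones(0)
        mean = np.nanmean(num, axis=0) if num.size else np.zeros(0)
        scale = {"lo": np.where(np.isfinite(lo), lo, 0.0),
                 "hi": np.where(np.isfinite(hi), hi, 1.0),
                 "mean": np.where(np.isfinite(mean), mean, 0.0)}
    num = np.where(np.isnan(num), scale["mean"], num)
    span = np.maximum(scale["hi"] - scale["lo"], 1e-12)
    num = np.clip((num - scale["lo"]) / span, -1.0, 2.0)
    cat = np.where(np.isnan(cat), -1.0, cat)  # missing is its own category
    return num, cat, scale


def _pairwise_dist(num_a, cat_a, num_b, cat_b, block: int = 512) -> np.ndarray:
    """Combined distance matrix: Euclidean(numeric) + Hamming(categorical)."""
    n_a = num_a.shape[0]
    out = np.empty((n_a, num_b.shape[0]))
    for s in range(0, n_a, block):
        e = s + block
        d2 = ((num_a[s:e, None, :] - num_b[None, :, :]) ** 2).sum(axis=2)
        ham = (cat_a[s:e, None, :] != cat_b[None, :, :]).sum(axis=2) if cat_a.shape[1] else 0.0
        out[s:e] = np.sqrt(d2) + ham
    return out


def _best_balanced_accuracy(d_member: np.ndarray, d_non: np.ndarray) -> float:
    """Max over thresholds of balanced accuracy for 'distance < t => member'."""
    cands = np.unique(np.concatenate([d_member, d_non]))
    thresholds = np.concatenate([[-np.inf], (cands[:-1] + cands[1:]) / 2 if len(cands) > 1 else [],
                                 [np.inf]])
    best = 0.0
    for t in thresholds:
        tpr = (d_member < t).mean()
        tnr = (d_non >= t).mean()
        best = max(best, 0.5 * (tpr + tnr))
    return float(best)


# --- attacks -------------------------------------------------------------


def membership_inference(
    synth: Cohort,
    train_query: Cohort,
    holdout_query: Cohort,
    schema: FeatureSchema,
    distance: str = "euclidean_hamming",
) -> AttackResult:
    """Nearest-synthetic-distance membership attack, balanced accuracy."""
    if synth[0].n_patients == 0:
        raise ValueError("empty synthetic set")
    n_tr, n_ho = train_query[0].n_patients, holdout_query[0].n_patients
    if n_tr != n_ho:
        raise ValueError(f"queries must be balanced ({n_tr} train vs {n_ho} holdout)")
    f_synth = flatten_features(*synth, schema)
    num_s, cat_s, scale = _matrices(f_synth, None)
    num_t, cat_t, _ = _matrices(flatten_features(*train_query, schema), scale)
    num_h, cat_h, _ = _matrices(flatten_features(*holdout_query, schema), scale)
    d_tr = _pairwise_dist(num_t, cat_t, num_s, cat_s).min(axis=1)
    d_ho = _pairwise_dist(num_h, cat_h, num_s, cat_s).min(axis=1)
    acc = _best_balanced_accuracy(d_tr, d_ho)
    return AttackResult(
        attack="membership_inference", value=acc, ideal=0.5,
        configuration={"distance": distance, "threshold": "accuracy-maximizing"},
        query_sizes={"train": n_tr, "holdout": n_ho, "synthetic": synth[0].n_patients},
    )


def reidentification_risk(
    synth: Cohort,
    train: Cohort,
    holdout: Cohort,
    schema: FeatureSchema,
    known_fraction: float = 0.5,
    tolerance: float = 0.05,
    distance: str = "euclidean_hamming",
    seed: int = 0,
) -> AttackResult:
    """Partial-knowledge matching attack; returns risk and holdout baseline.

    For each training record the adversary knows a random ``known_fraction``
    of the flattened features, matches on them against the reference set,
    and succeeds if every unknown numeric agrees within ``tolerance``
    (min-max normalized units) and every unknown categorical matches
    exactly.  The baseline repeats the procedure with held-out real records
    as the reference.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    ids_tr = set(train[0].ids.tolist())
    if ids_tr & set(holdout[0].ids.tolist()):
        raise ValueError("train and holdout must be disjoint")
    degenerate = known_fraction >= 1.0
    if degenerate:
        logger.warning("re-identification with known_fraction=1 is vacuous: risk is 1 by convention")

    f_train = flatten_features(*train, schema)
    num_q, cat_q, scale = _matrices(f_train, None)
    n_num, n_cat = num_q.shape[1], cat_q.shape[1]
    n_feat = n_num + n_cat
    n_known = int(round(known_fraction * n_feat))

    def run(reference: Cohort) -> float:
        if degenerate:
            return 1.0
        rng = np.random.default_rng(seed)  # same known sets for risk and baseline
        num_r, cat_r, _ = _matrices(flatten_features(*reference, schema), scale)
        successes = 0
        for i in range(num_q.shape[0]):
            known = rng.permutation(n_feat)[:n_known]
            kn = known[known < n_num]
            kc = known[known >= n_num] - n_num
            un = np.setdiff1d(np.arange(n_num), kn)
            uc = np.setdiff1d(np.arange(n_cat), kc)
            d = _pairwise_dist(num_q[i: i + 1, kn], cat_q[i: i + 1, kc],
                               num_r[:, kn], cat_r[:, kc])[0]
            j = int(np.argmin(d))
            ok_num = np.all(np.abs(num_q[i, un] - num_r[j, un]) <= tolerance) if un.size else True
            ok_cat = np.all(cat_q[i, uc] == cat_r[j, uc]) if uc.size else True
            successes += int(ok_num and ok_cat)
        return successes / num_q.shape[0]

    risk = run(synth)
    baseline = run(holdout)
    return AttackResult(
        attack="reidentification", value=float(risk), ideal=float(baseline),
        configuration={"distance": distance, "known_fraction": known_fraction,
                       "tolerance": tolerance, "degenerate": degenerate},
        query_sizes={"train": train[0].n_patients, "holdout": holdout[0].n_patients,
                     "synthetic": synth[0].n_patients},
        extra={"baseline_risk": float(baseline)},
    )


def mean_pairwise_auc(y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray) -> float:
    """Mean of all pairwise one-vs-one AUCs (multi-class generalization)."""
    pairs = []
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            sel = np.isin(y_true, [classes[a], classes[b]])
            if len(np.unique(y_true[sel])) < 2:
                continue
            y_bin = (y_true[sel] == classes[b]).astype(int)
            a_ba = roc_auc_score(y_bin, proba[sel, b])
            a_ab = roc_auc_score(1 - y_bin, proba[sel, a])
            pairs.append(0.5 * (a_ba + a_ab))
    if not pairs:
        raise ValueError("no evaluable class pairs")
    return float(np.mean(pairs))


def attribute_inference(
    synth: Cohort,
    real_train: Cohort,
    real_eval: Cohort,
    schema: FeatureSchema,
    attribute: str,
    k: int = 5,
    distance: str = "euclidean_hamming",
) -> AttackResult:
    """kNN prediction of a sensitive attribute: synthetic- vs real-trained.

    Both classifiers exclude the attribute from the feature space and are
    scored on the real evaluation set; binary attributes report AUC,
    multi-class ones the mean pairwise AUC.  Synthetic-trained AUC at or
    below real-trained AUC indicates no added leakage.
    """
    if k < 1:
        raise ValueError("k must be >= 1")

    def xy(pair: Cohort, scale):
        flat = flatten_features(*pair, schema)
        df = flat.frame
        if attribute not in df.columns:
            raise ValueError(f"attribute {attribute!r} not present")
        y = df[attribute].to_numpy(dtype=np.float64)
        sub = FlatCohort(df.drop(columns=[attribute]),
                         [c for c in flat.numeric_cols if c != attribute],
                         [c for c in flat.categorical_cols if c != attribute])
        num, cat, scale = _matrices(sub, scale)
        X = np.concatenate([num, cat], axis=1)
        keep = ~np.isnan(y)
        return X, y, keep, scale

    X_ev, y_ev, keep_ev, scale = xy(real_eval, None)
    X_ev, y_ev = X_ev[keep_ev], y_ev[keep_ev]
    if len(np.unique(y_ev)) < 2:
        raise ValueError(f"attribute {attribute!r} is constant in the evaluation set")
    classes = np.unique(y_ev)

    def auc_for(pair: Cohort) -> float:
        X, y, keep, _ = xy(pair, scale)
        X, y = X[keep], y[keep]
        model = KNeighborsClassifier(n_neighbors=min(k, len(y)))
        model.fit(X, y)
        proba = model.predict_proba(X_ev)
        model_classes = model.classes_
        full = np.zeros((len(X_ev), len(classes)))
        for ci, c in enumerate(classes):
            pos = np.where(model_classes == c)[0]
            if pos.size:
                full[:, ci] = proba[:, pos[0]]
        if len(classes) == 2:
            return float(roc_auc_score((y_ev == classes[1]).astype(int), full[:, 1]))
        return mean_pairwise_auc(y_ev, full, classes)

    auc_synth = auc_for(synth)
    auc_real = auc_for(real_train)
    return AttackResult(
        attack="attribute_inference", value=auc_synth, ideal=auc_real,
        configuration={"attribute": attribute, "k": k, "distance": distance},
        query_sizes={"eval": int(len(y_ev))},
        extra={"auc_synthetic_trained": auc_synth, "auc_real_trained": auc_real},
    )
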