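"""Fidelity evaluation: per-feature statistical similarity, KS statistics,
train-on-synthetic/test-on-real (TSTR) utility, and the random-feature-
subset hypothesis test.

Conventions: KS statistics ignore missing entries; missing rates count
mask-0 slots over the slots within each record's true length (padding is
not a missingness event); TSTR always evaluates on the real held-out test
set, whichever source the model was trained on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .data import EHRDataset, MaskSet
from .schema import FeatureSchema

logger = logging.getLogger(__name__)


def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic, ignoring missing entries."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("KS statistic needs non-empty observed samples on both sides")
    return float(stats.ks_2samp(x, y, method="asymp").statistic)


# --- per-feature summary -------------------------------------------------


def _numeric_stats(values: np.ndarray, mask: np.ndarray, lengths: np.ndarray | None):
    obs = values[mask.astype(bool)]
    if lengths is None:
        denom = mask.shape[0]
    else:
        denom = int(lengths.sum())
    missing = 1.0 - (mask.sum() / denom if denom else 0.0)
    if obs.size == 0:
        return None, None, float(missing), obs
    return float(obs.mean()), float(obs.std()), float(missing), obs


def summary_table(
    real: tuple[EHRDataset, MaskSet],
    synth: tuple[EHRDataset, MaskSet],
    schema: FeatureSchema,
) -> pd.DataFrame:
    """Per-feature similarity rows comparing real and synthetic cohorts."""
    rd, rm = real
    sd, sm = synth
    rows = []

    def numeric_row(name, rv, rmask, rlen, sv, smask, slen, kind):
        r_mean, r_std, r_miss, r_obs = _numeric_stats(rv, rmask, rlen)
        s_mean, s_std, s_miss, s_obs = _numeric_stats(sv, smask, slen)
        flagged = r_obs.size == 0 and s_obs.size == 0
        ks = None
        if r_obs.size and s_obs.size:
            ks = ks_statistic(r_obs, s_obs)
        rows.append({
            "feature": name, "kind": kind,
            "real_mean": r_mean, "real_std": r_std, "real_missing_rate": r_miss,
            "synth_mean": s_mean, "synth_std": s_std, "synth_missing_rate": s_miss,
            "ks": ks, "flagged_never_observed": flagged,
        })

    for j, name in enumerate(schema.static_numeric):
        numeric_row(name, rd.static_num[:, j], rm.static_num[:, j], None,
                    sd.static_num[:, j], sm.static_num[:, j], None, "static_numeric")
    for j, name in enumerate(schema.temporal_numeric):
        numeric_row(name, rd.temp_num[:, :, j], rm.temp_num[:, :, j], rd.lengths,
                    sd.temp_num[:, :, j], sm.temp_num[:, :, j], sd.lengths, "temporal_numeric")

    def cat_rows(name, vocab, r_codes, r_mask, rlen, s_codes, s_mask, slen, kind):
        r_obs = r_codes[r_mask.astype(bool)]
        s_obs = s_codes[s_mask.astype(bool)]
        r_denom = r_mask.shape[0] if rlen is None else int(rlen.sum())
        s_denom = s_mask.shape[0] if slen is None else int(slen.sum())
        for k, cat in enumerate(vocab):
            rows.append({
                "feature": f"{name}={cat}", "kind": kind,
                "real_mean": float((r_obs == k).mean()) if r_obs.size else None,
                "real_std": None,
                "real_missing_rate": 1.0 - r_mask.sum() / r_denom,
                "synth_mean": float((s_obs == k).mean()) if s_obs.size else None,
                "synth_std": None,
                "synth_missing_rate": 1.0 - s_mask.sum() / s_denom,
                "ks": None,
                "flagged_never_observed": r_obs.size == 0 and s_obs.size == 0,
            })

    for j, (name, vocab) in enumerate(schema.static_categorical):
        cat_rows(name, vocab, rd.static_cat[:, j], rm.static_cat[:, j], None,
                 sd.static_cat[:, j], sm.static_cat[:, j], None, "static_categorical")
    for j, (name, vocab) in enumerate(schema.temporal_categorical):
        cat_rows(name, vocab, rd.temp_cat[:, :, j], rm.temp_cat[:, :, j], rd.lengths,
                 sd.temp_cat[:, :, j], sm.temp_cat[:, :, j], sd.lengths, "temporal_categorical")
    return pd.DataFrame(rows)


# --- flattening ----------------------------------------------------------


@dataclass
class FlatCohort:
    """Per-patient feature table for non-sequential models and attacks."""

    frame: pd.DataFrame
    numeric_cols: list[str]
    categorical_cols: list[str]


def flatten_features(
    dataset: EHRDataset,
    masks: MaskSet,
    schema: FeatureSchema,
    features: list[str] | None = None,
) -> FlatCohort:
    """Summarize each record into one row.

    Static features pass through; each temporal numeric contributes its
    last observed value, the mean of observed values and the observation
    count; each temporal categorical contributes its last observed code and
    count.  Sequence length is included.  Missing summaries are NaN (model
    wrappers impute with training means).
    """
    use = set(features) if features is not None else None
    cols: dict[str, np.ndarray] = {}
    numeric_cols: list[str] = []
    cat_cols: list[str] = []
    N, T = dataset.times.shape

    for j, name in enumerate(schema.static_numeric):
        if use is not None and name not in use:
            continue
        v = np.where(masks.static_num[:, j].astype(bool), dataset.static_num[:, j], np.nan)
        cols[name] = v
        numeric_cols.append(name)
    for j, (name, _) in enumerate(schema.static_categorical):
        if use is not None and name not in use:
            continue
        v = np.where(masks.static_cat[:, j].astype(bool),
                     dataset.static_cat[:, j].astype(np.float64), np.nan)
        cols[name] = v
        cat_cols.append(name)

    step_idx = np.arange(T)[None, :]
    for j, name in enumerate(schema.temporal_numeric):
        if use is not None and name not in use:
            continue
        m = masks.temp_num[:, :, j].astype(bool)
        vals = dataset.temp_num[:, :, j]
        count = m.sum(axis=1).astype(np.float64)
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0, np.nansum(np.where(m, vals, 0.0), axis=1) / np.maximum(count, 1), np.nan)
        last_pos = np.where(m, step_idx, -1).max(axis=1)
        last = np.where(last_pos >= 0, vals[np.arange(N), np.maximum(last_pos, 0)], np.nan)
        cols[f"{name}__last"] = last
        cols[f"{name}__mean"] = mean
        cols[f"{name}__count"] = count
        numeric_cols += [f"{name}__last", f"{name}__mean", f"{name}__count"]
    for j, (name, _) in enumerate(schema.temporal_categorical):
        if use is not None and name not in use:
            continue
        m = masks.temp_cat[:, :, j].astype(bool)
        codes = dataset.temp_cat[:, :, j]
        last_pos = np.where(m, step_idx, -1).max(axis=1)
        last = np.where(last_pos >= 0,
                        codes[np.arange(N), np.maximum(last_pos, 0)].astype(np.float64), np.nan)
        cols[f"{name}__last"] = last
        cols[f"{name}__count"] = m.sum(axis=1).astype(np.float64)
        cat_cols.append(f"{name}__last")
        numeric_cols.append(f"{name}__count")
    if use is None:
        cols["seq_len"] = dataset.lengths.astype(np.float64)
        numeric_cols.append("seq_len")
    return FlatCohort(pd.DataFrame(cols), numeric_cols, cat_cols)


def _target_vector(dataset: EHRDataset, masks: MaskSet, schema: FeatureSchema, target: str) -> np.ndarray:
    if target in schema.static_numeric:
        j = list(schema.static_numeric).index(target)
        y = dataset.static_num[:, j]
    elif target in schema.static_cat_names:
        j = schema.static_cat_names.index(target)
        y = dataset.static_cat[:, j].astype(np.float64)
        y[y < 0] = np.nan
    else:
        raise ValueError(f"target {target!r} must be a static feature")
    vals = np.unique(y[~np.isnan(y)])
    if len(vals) != 2:
        raise ValueError(f"target {target!r} is not binary (values {vals})")
    return (y == vals.max()).astype(np.float64)


def _fit_score(X_train, y_train, X_test, y_test, model_kind: str, seed: int):
    if len(np.unique(y_train)) < 2:
        raise ValueError("training target is single-class")
    means = np.nanmean(X_train, axis=0)
    means = np.where(np.isfinite(means), means, 0.0)
    Xtr = np.where(np.isnan(X_train), means, X_train)
    Xte = np.where(np.isnan(X_test), means, X_test)
    if model_kind == "rf":
        model = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    elif model_kind == "lr":
        model = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed))
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    model.fit(Xtr, y_train)
    p = model.predict_proba(Xte)[:, 1]
    return float(roc_auc_score(y_test, p)), float(average_precision_score(y_test, p))


def tstr_utility(
    real_train: tuple[EHRDataset, MaskSet],
    synth_train: tuple[EHRDataset, MaskSet],
    real_test: tuple[EHRDataset, MaskSet],
    schema: FeatureSchema,
    target: str,
    model_kind: str = "rf",
    seed: int = 0,
    features: list[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """(AUC, AP) for models trained on real vs synthetic, both scored on
    the real test set."""
    if model_kind == "gru":
        from .gru_model import gru_tstr

        return gru_tstr(real_train, synth_train, real_test, schema, target, seed)
    results = {}
    y_test = _target_vector(*real_test, schema, target)
    flat_test = flatten_features(*real_test, schema, features=features)
    Xte = flat_test.frame.drop(columns=[target], errors="ignore").to_numpy()
    for source, pair in (("real", real_train), ("synthetic", synth_train)):
        y = _target_vector(*pair, schema, target)
        flat = flatten_features(*pair, schema, features=features)
        X = flat.frame.drop(columns=[target], errors="ignore").to_numpy()
        results[source] = _fit_score(X, y, Xte, y_test, model_kind, seed)
    return results


def fidelity_pvalue(diffs, x_threshold: float) -> float:
    """One-sided one-sample t-test p-value for H0: mean difference >= X.

    A small p-value rejects H0 — i.e. supports that real- and
    synthetic-trained performance differ by less than X on average.
    """
    diffs = np.asarray(diffs, dtype=np.float64)
    if len(diffs) < 2:
        raise ValueError("the t-test needs at least 2 observations")
    if np.std(diffs) == 0:  # zero-variance limit
        return 0.0 if float(np.mean(diffs)) < x_threshold else 1.0
    return float(stats.ttest_1samp(diffs, popmean=x_threshold, alternative="less").pvalue)


def subset_utility_test(
    real_train: tuple[EHRDataset, MaskSet],
    synth_train: tuple[EHRDataset, MaskSet],
    real_test: tuple[EHRDataset, MaskSet],
    schema: FeatureSchema,
    targets: list[str],
    n_features: int = 30,
    n_trials: int = 10,
    x_threshold: float = 0.04,
    model_kind: str = "rf",
    seed: int = 0,
) -> pd.DataFrame:
    """Random-feature-subset fidelity test.

    For each trial, a random subset of ``n_features`` base features is
    drawn, models are trained on real and on synthetic data, and the
    absolute AUC/AP differences (scored on the real test set) recorded.
    The one-sided one-sample t-test evaluates H0: mean difference >= X;
    a small p-value rejects H0, i.e. supports fidelity within X.
    """
    if n_trials < 2:
        raise ValueError("the t-test needs at least 2 trials")
    rng = np.random.default_rng(seed)
    all_features = (list(schema.static_numeric) + schema.static_cat_names
                    + list(schema.temporal_numeric) + schema.temporal_cat_names)
    rows = []
    for target in targets:
        candidates = [f for f in all_features if f != target]
        if len(candidates) < n_features:
            raise ValueError(f"only {len(candidates)} candidate features for subsets of {n_features}")
        auc_diffs, ap_diffs = [], []
        trial = 0
        attempts = 0
        while trial < n_trials:
            attempts += 1
            if attempts > 5 * n_trials:
                raise RuntimeError("too many degenerate subset trials")
            subset = list(rng.choice(candidates, size=n_features, replace=False))
            try:
                res = tstr_utility(real_train, synth_train, real_test, schema, target,
                                   model_kind=model_kind, seed=seed + trial, features=subset)
            except ValueError as err:
                logger.warning("subset trial redrawn (%s)", err)
                continue
            auc_diffs.append(abs(res["real"][0] - res["synthetic"][0]))
            ap_diffs.append(abs(res["real"][1] - res["synthetic"][1]))
            trial += 1
        p_auc = fidelity_pvalue(auc_diffs, x_threshold)
        p_ap = fidelity_pvalue(ap_diffs, x_threshold)
        rows.append({"target": target, "metric": "auc", "mean_abs_diff": float(np.mean(auc_diffs)),
                     "p_value": p_auc, "x_threshold": x_threshold, "n_trials": n_trials})
        rows.append({"target": target, "metric": "ap", "mean_abs_diff": float(np.mean(ap_diffs)),
                     "p_value": p_ap, "x_threshold": x_threshold, "n_trials": n_trials})
    return pd.DataFrame(rows)
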