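"""Cohort containers and table IO.

A cohort is a pair of containers: :class:`EHRDataset` holds the values
(static numerics/categoricals, per-step times, temporal
numerics/categoricals, true sequence lengths) and :class:`MaskSet` holds
the aligned binary observed/missing indicators plus a per-step
``step_present`` channel that marks real (non-padding) steps.  Missing
numerics are stored as NaN and missing categoricals as code -1; the mask is
the authoritative record of missingness.

On disk a cohort is two delimited tables: a static table with one row per
patient, and a temporal long table with columns
``patient_id, step, time, feature, value`` where missing entries are simply
absent.  Every step contributes one row under the schema's time field so
that steps with no observed features (and tied timestamps) survive a
round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import FeatureSchema, SchemaError

logger = logging.getLogger(__name__)

ID_COL = "patient_id"
STEP_COL = "step"
FEATURE_COL = "feature"
VALUE_COL = "value"


@dataclass
class EHRDataset:
    ids: np.ndarray            # (N,) str
    static_num: np.ndarray     # (N, Sn) float, NaN = missing
    static_cat: np.ndarray     # (N, Sc) int codes, -1 = missing
    times: np.ndarray          # (N, T) float, 0 on padding
    temp_num: np.ndarray       # (N, T, Tn) float, NaN = missing/padding
    temp_cat: np.ndarray       # (N, T, Tc) int codes, -1 = missing/padding
    lengths: np.ndarray        # (N,) int, true sequence lengths

    @property
    def n_patients(self) -> int:
        return len(self.ids)

    @property
    def n_steps(self) -> int:
        return self.times.shape[1]

    def take(self, idx) -> "EHRDataset":
        idx = np.asarray(idx)
        return EHRDataset(
            ids=self.ids[idx],
            static_num=self.static_num[idx],
            static_cat=self.static_cat[idx],
            times=self.times[idx],
            temp_num=self.temp_num[idx],
            temp_cat=self.temp_cat[idx],
            lengths=self.lengths[idx],
        )

    def copy(self) -> "EHRDataset":
        return EHRDataset(*(np.copy(getattr(self, f)) for f in
                            ("ids", "static_num", "static_cat", "times",
                             "temp_num", "temp_cat", "lengths")))


@dataclass
class MaskSet:
    static_num: np.ndarray     # (N, Sn) {0,1}
    static_cat: np.ndarray     # (N, Sc)
    temp_num: np.ndarray       # (N, T, Tn)
    temp_cat: np.ndarray       # (N, T, Tc)
    step_present: np.ndarray   # (N, T), contiguous prefix of ones

    def take(self, idx) -> "MaskSet":
        idx = np.asarray(idx)
        return MaskSet(*(getattr(self, f)[idx] for f in
                         ("static_num", "static_cat", "temp_num", "temp_cat", "step_present")))

    def copy(self) -> "MaskSet":
        return MaskSet(*(np.copy(getattr(self, f)) for f in
                         ("static_num", "static_cat", "temp_num", "temp_cat", "step_present")))


def derive_masks(dataset: EHRDataset) -> MaskSet:
    """Build the observed/missing indicators implied by the value arrays."""
    N, T = dataset.times.shape
    step_present = (np.arange(T)[None, :] < dataset.lengths[:, None]).astype(np.uint8)
    return MaskSet(
        static_num=(~np.isnan(dataset.static_num)).astype(np.uint8),
        static_cat=(dataset.static_cat >= 0).astype(np.uint8),
        temp_num=((~np.isnan(dataset.temp_num)) & step_present[:, :, None].astype(bool)).astype(np.uint8),
        temp_cat=((dataset.temp_cat >= 0) & step_present[:, :, None].astype(bool)).astype(np.uint8),
        step_present=step_present,
    )


def validate_cohort(dataset: EHRDataset, masks: MaskSet, schema: FeatureSchema) -> None:
    """Assert every container invariant; raises ValueError on violation."""
    N = dataset.n_patients
    T = dataset.n_steps
    if dataset.static_num.shape != (N, len(schema.static_numeric)):
        raise ValueError("static numeric shape disagrees with schema")
    if dataset.static_cat.shape != (N, len(schema.static_categorical)):
        raise ValueError("static categorical shape disagrees with schema")
    if dataset.temp_num.shape != (N, T, len(schema.temporal_numeric)):
        raise ValueError("temporal numeric shape disagrees with schema")
    if dataset.temp_cat.shape != (N, T, len(schema.temporal_categorical)):
        raise ValueError("temporal categorical shape disagrees with schema")
    if np.any(dataset.lengths < 1) or np.any(dataset.lengths > schema.max_seq_len):
        raise ValueError("sequence lengths must lie in [1, max_seq_len]")
    if np.any(dataset.lengths > T):
        raise ValueError("length exceeds the padded time dimension")
    # step_present is the contiguous prefix of ones of length T(i)
    expected = (np.arange(T)[None, :] < dataset.lengths[:, None]).astype(np.uint8)
    if not np.array_equal(masks.step_present, expected):
        raise ValueError("step_present must be the prefix of ones of length T(i)")
    # mask <-> value consistency
    if not np.array_equal(masks.static_num, (~np.isnan(dataset.static_num)).astype(np.uint8)):
        raise ValueError("static numeric mask/value inconsistency")
    if not np.array_equal(masks.static_cat, (dataset.static_cat >= 0).astype(np.uint8)):
        raise ValueError("static categorical mask/value inconsistency")
    tn_obs = (~np.isnan(dataset.temp_num)).astype(np.uint8)
    if not np.array_equal(masks.temp_num, tn_obs):
        raise ValueError("temporal numeric mask/value inconsistency")
    tc_obs = (dataset.temp_cat >= 0).astype(np.uint8)
    if not np.array_equal(masks.temp_cat, tc_obs):
        raise ValueError("temporal categorical mask/value inconsistency")
    if np.any(masks.temp_num * (1 - masks.step_present[:, :, None])):
        raise ValueError("observed temporal numeric outside step_present")
    if np.any(masks.temp_cat * (1 - masks.step_present[:, :, None])):
        raise ValueError("observed temporal categorical outside step_present")
    # categorical codes within vocabulary
    for j, (name, vocab) in enumerate(schema.static_categorical):
        if np.any(dataset.static_cat[:, j] >= len(vocab)):
            raise ValueError(f"static categorical {name!r} has out-of-vocabulary codes")
    for j, (name, vocab) in enumerate(schema.temporal_categorical):
        if np.any(dataset.temp_cat[:, :, j] >= len(vocab)):
            raise ValueError(f"temporal categorical {name!r} has out-of-vocabulary codes")
    # times non-decreasing within the true length
    for i in range(N):
        t = dataset.times[i, : dataset.lengths[i]]
        if np.any(np.diff(t) < 0):
            raise ValueError(f"times for patient {dataset.ids[i]} are not non-decreasing")


# --- reading -------------------------------------------------------------


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_cohort(static_path, temporal_path, schema: FeatureSchema) -> tuple[EHRDataset, MaskSet]:
    """Load a cohort from a static table and a temporal long table."""
    static_df = pd.read_csv(static_path, sep=_sep_for(static_path), dtype={ID_COL: str},
                            float_precision="round_trip")
    temporal_df = pd.read_csv(
        temporal_path, sep=_sep_for(temporal_path),
        dtype={ID_COL: str, FEATURE_COL: str, VALUE_COL: str},
        float_precision="round_trip",
    )
    for col, df, which in ((ID_COL, static_df, "static"), (ID_COL, temporal_df, "temporal")):
        if col not in df.columns:
            raise SchemaError(f"{which} table lacks the {col!r} column")

    known = set(schema.temporal_numeric) | set(schema.temporal_cat_names) | {schema.time_name}
    unknown = sorted(set(temporal_df[FEATURE_COL].unique()) - known)
    if unknown:
        raise SchemaError(f"temporal features not in schema: {unknown}")

    static_df = static_df.sort_values(ID_COL, kind="stable").reset_index(drop=True)
    ids = static_df[ID_COL].to_numpy(dtype=object)
    id_index = {pid: i for i, pid in enumerate(ids)}
    missing_static = sorted(set(temporal_df[ID_COL].unique()) - set(ids))
    if missing_static:
        raise SchemaError(f"temporal rows for patients absent from the static table: {missing_static}")

    N = len(ids)
    Sn, Sc = len(schema.static_numeric), len(schema.static_categorical)
    Tn, Tc = len(schema.temporal_numeric), len(schema.temporal_categorical)

    static_num = np.full((N, Sn), np.nan)
    for j, name in enumerate(schema.static_numeric):
        if name in static_df.columns:
            static_num[:, j] = pd.to_numeric(static_df[name], errors="coerce").to_numpy()
    static_cat = np.full((N, Sc), -1, dtype=np.int64)
    for j, (name, vocab) in enumerate(schema.static_categorical):
        if name not in static_df.columns:
            continue
        lut = {v: k for k, v in enumerate(vocab)}
        col = static_df[name]
        for i, v in enumerate(col):
            if pd.isna(v) or v == "":
                continue
            v = str(v)
            if v not in lut:
                raise SchemaError(f"value {v!r} of static feature {name!r} not in vocabulary")
            static_cat[i, j] = lut[v]

    # group temporal rows into steps
    temporal_df = temporal_df.copy()
    temporal_df["_time"] = pd.to_numeric(temporal_df["time"], errors="raise")
    has_step = STEP_COL in temporal_df.columns
    per_patient: dict[str, pd.DataFrame] = {pid: g for pid, g in temporal_df.groupby(ID_COL, sort=False)}
    zero_rows = sorted(set(ids) - set(per_patient))
    if zero_rows:
        raise SchemaError(f"patients with zero temporal rows (T=0 is not allowed): {zero_rows}")

    lengths = np.zeros(N, dtype=np.int64)
    steps_per_patient: dict[str, pd.DataFrame] = {}
    for pid, g in per_patient.items():
        if has_step:
            g = g.assign(_step=g[STEP_COL].astype(int))
        else:
            g = g.sort_values("_time", kind="stable")
            uniq = pd.unique(g["_time"])
            rank = {t: k for k, t in enumerate(uniq)}
            g = g.assign(_step=g["_time"].map(rank))
        steps_per_patient[pid] = g
        lengths[id_index[pid]] = int(g["_step"].max()) + 1

    T = int(lengths.max()) if N else 1
    times = np.zeros((N, T))
    temp_num = np.full((N, T, Tn), np.nan)
    temp_cat = np.full((N, T, Tc), -1, dtype=np.int64)
    tn_index = {n: j for j, n in enumerate(schema.temporal_numeric)}
    tc_index = {n: j for j, n in enumerate(schema.temporal_cat_names)}
    tc_luts = {n: {v: k for k, v in enumerate(vocab)} for n, vocab in schema.temporal_categorical}

    for pid, g in steps_per_patient.items():
        i = id_index[pid]
        for step, time_v, feat, val in zip(g["_step"], g["_time"], g[FEATURE_COL], g[VALUE_COL]):
            times[i, step] = time_v
            if feat == schema.time_name:
                continue
            if feat in tn_index:
                temp_num[i, step, tn_index[feat]] = float(val)
            else:
                lut = tc_luts[feat]
                sval = str(val)
                if sval not in lut:
                    raise SchemaError(f"value {sval!r} of temporal feature {feat!r} not in vocabulary")
                temp_cat[i, step, tc_index[feat]] = lut[sval]

    dataset = EHRDataset(ids, static_num, static_cat, times, temp_num, temp_cat, lengths)
    masks = derive_masks(dataset)
    validate_cohort(dataset, masks, schema)
    return dataset, masks


# --- writing -------------------------------------------------------------


def write_cohort(dataset: EHRDataset, masks: MaskSet, schema: FeatureSchema, out_dir) -> dict[str, Path]:
    """Write the two-table representation; missing entries are omitted."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    static_cols: dict[str, list] = {ID_COL: list(dataset.ids)}
    for j, name in enumerate(schema.static_numeric):
        col = dataset.static_num[:, j]
        static_cols[name] = [repr(float(v)) if m else "" for v, m in zip(col, masks.static_num[:, j])]
    for j, (name, vocab) in enumerate(schema.static_categorical):
        col = dataset.static_cat[:, j]
        static_cols[name] = [vocab[v] if v >= 0 else "" for v in col]
    static_df = pd.DataFrame(static_cols)

    rows: list[tuple] = []
    for i in range(dataset.n_patients):
        pid = dataset.ids[i]
        for step in range(int(dataset.lengths[i])):
            t = repr(float(dataset.times[i, step]))
            rows.append((pid, step, t, schema.time_name, t))
            for j, name in enumerate(schema.temporal_numeric):
                if masks.temp_num[i, step, j]:
                    rows.append((pid, step, t, name, repr(float(dataset.temp_num[i, step, j]))))
            for j, (name, vocab) in enumerate(schema.temporal_categorical):
                code = dataset.temp_cat[i, step, j]
                if code >= 0:
                    rows.append((pid, step, t, name, vocab[code]))
    temporal_df = pd.DataFrame(rows, columns=[ID_COL, STEP_COL, "time", FEATURE_COL, VALUE_COL])

    static_path = out_dir / "static.csv"
    temporal_path = out_dir / "temporal.csv"
    static_df.to_csv(static_path, index=False)
    temporal_df.to_csv(temporal_path, index=False)
    return {"static": static_path, "temporal": temporal_path}


# --- filtering and padding ----------------------------------------------


def filter_outliers(
    dataset: EHRDataset,
    masks: MaskSet,
    schema: FeatureSchema,
    low_pct: float = 0.001,
    high_pct: float = 0.999,
    mode: str = "mask_value",
) -> tuple[EHRDataset, MaskSet]:
    """Remove numeric observations outside [low_pct, high_pct] percentiles.

    ``mask_value`` turns out-of-range observations into missing entries;
    ``drop_patient`` removes any patient carrying one.  Percentiles are
    computed per feature on observed values only.
    """
    if not (0 <= low_pct < high_pct <= 1):
        raise ValueError("need 0 <= low_pct < high_pct <= 1")
    if mode not in ("mask_value", "drop_patient"):
        raise ValueError(f"unknown mode {mode!r}")
    dataset, masks = dataset.copy(), masks.copy()
    drop = np.zeros(dataset.n_patients, dtype=bool)

    def apply(values: np.ndarray, mask: np.ndarray, name: str):
        obs = values[mask.astype(bool)]
        if obs.size < 2:
            logger.warning("outlier filter: feature %r has <2 observed values; skipped", name)
            return
        lo, hi = np.quantile(obs, [low_pct, high_pct])
        out = mask.astype(bool) & ((values < lo) | (values > hi))
        if mode == "mask_value":
            values[out] = np.nan
            mask[out] = 0
        else:
            axes = tuple(range(1, out.ndim))
            drop[np.any(out, axis=axes)] = True

    for j, name in enumerate(schema.static_numeric):
        apply(dataset.static_num[:, j], masks.static_num[:, j], name)
    for j, name in enumerate(schema.temporal_numeric):
        apply(dataset.temp_num[:, :, j], masks.temp_num[:, :, j], name)

    if mode == "drop_patient" and drop.any():
        keep = np.flatnonzero(~drop)
        dataset, masks = dataset.take(keep), masks.take(keep)
    return dataset, masks


def truncate_pad(dataset: EHRDataset, masks: MaskSet, t_max: int) -> tuple[EHRDataset, MaskSet]:
    """Keep the LAST ``t_max`` steps of longer sequences; pad all to ``t_max``."""
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    N, T = dataset.times.shape
    Tn, Tc = dataset.temp_num.shape[2], dataset.temp_cat.shape[2]
    times = np.zeros((N, t_max))
    temp_num = np.full((N, t_max, Tn), np.nan)
    temp_cat = np.full((N, t_max, Tc), -1, dtype=np.int64)
    lengths = np.minimum(dataset.lengths, t_max)
    for i in range(N):
        L = int(dataset.lengths[i])
        start = max(0, L - t_max)
        keep = L - start
        times[i, :keep] = dataset.times[i, start:L]
        temp_num[i, :keep] = dataset.temp_num[i, start:L]
        temp_cat[i, :keep] = dataset.temp_cat[i, start:L]
    out = EHRDataset(dataset.ids.copy(), dataset.static_num.copy(), dataset.static_cat.copy(),
                     times, temp_num, temp_cat, lengths)
    return out, derive_masks(out)


def train_test_split(
    dataset: EHRDataset, masks: MaskSet, test_fraction: float = 0.2, seed: int = 0
) -> tuple[tuple[EHRDataset, MaskSet], tuple[EHRDataset, MaskSet]]:
    """Per-patient random split (default 80/20) with a fixed seed."""
    rng = np.random.default_rng(seed)
    N = dataset.n_patients
    perm = rng.permutation(N)
    n_test = int(round(N * test_fraction))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return ((dataset.take(train_idx), masks.take(train_idx)),
            (dataset.take(test_idx), masks.take(test_idx)))
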