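"""Stochastic (frequency-proportional) normalization of numeric features.

Each unique observed value of a feature is assigned a sub-interval of
[0, 1] whose width equals that value's empirical frequency, in ascending
value order.  Normalization replaces a value by an independent uniform
draw from its interval; renormalization maps any point of [0, 1] back to
the unique value owning the interval that contains it.  The forward map
therefore produces an approximately Uniform(0,1) marginal — which a GAN
models far more easily than skewed or discrete-jump distributions — while
the inverse is exact on every observed value, for every seed.

Interval convention: half-open [lower, upper) with the final interval
closed at 1.0; a point sitting exactly on an interior boundary belongs to
the interval on its right.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import EHRDataset, MaskSet
from .schema import FeatureSchema

TIME_KEY = "__time__"


@dataclass(frozen=True)
class IntervalMap:
    """Per-feature map: ascending unique values and their [lower, upper) bounds."""

    values: np.ndarray   # ascending unique observed values
    lowers: np.ndarray
    uppers: np.ndarray

    def __post_init__(self):
        if len(self.values) == 0:
            raise ValueError("empty interval map")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("unique values must be strictly ascending")
        if self.lowers[0] != 0.0 or self.uppers[-1] != 1.0:
            raise ValueError("intervals must tile [0, 1]")
        if not np.array_equal(self.lowers[1:], self.uppers[:-1]):
            raise ValueError("intervals must be contiguous")


def fit_interval_map(values: np.ndarray) -> IntervalMap:
    """Fit the frequency-proportional intervals on an observed sample."""
    values = np.asarray(values, dtype=np.float64)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("cannot fit a normalizer on an empty (never observed) sample")
    uniq, counts = np.unique(values, return_counts=True)
    uppers = np.cumsum(counts) / values.size
    uppers[-1] = 1.0  # exact tiling regardless of rounding
    lowers = np.concatenate([[0.0], uppers[:-1]])
    return IntervalMap(values=uniq, lowers=lowers, uppers=uppers)


def stochastic_normalize(
    values: np.ndarray,
    imap: IntervalMap,
    rng: np.random.Generator,
    on_unknown: str = "error",
) -> np.ndarray:
    """Map each value to a uniform draw from its interval; NaN passes through.

    ``on_unknown='nearest'`` maps values absent from the fit to the nearest
    fitted unique value (synthesis-time robustness); the default raises.
    """
    values = np.asarray(values, dtype=np.float64)
    out = np.array(values, dtype=np.float64)
    obs = ~np.isnan(values)
    if not obs.any():
        return out
    v = values[obs]
    pos = np.searchsorted(imap.values, v)
    pos_clip = np.clip(pos, 0, len(imap.values) - 1)
    exact = imap.values[pos_clip] == v
    if not exact.all():
        if on_unknown == "error":
            bad = np.unique(v[~exact])[:5]
            raise ValueError(f"values not present in normalization params: {bad}")
        left = np.clip(pos - 1, 0, len(imap.values) - 1)
        use_left = np.abs(imap.values[left] - v) <= np.abs(imap.values[pos_clip] - v)
        pos_clip = np.where(exact, pos_clip, np.where(use_left, left, pos_clip))
    lo = imap.lowers[pos_clip]
    hi = imap.uppers[pos_clip]
    draw = rng.uniform(lo, hi)
    # guard against floating-point landing exactly on the open upper edge
    draw = np.where(draw >= hi, np.nextafter(hi, -np.inf), draw)
    out[obs] = draw
    return out


def renormalize(xhat: np.ndarray, imap: IntervalMap) -> np.ndarray:
    """Invert the normalization: interval search; inputs clipped to [0, 1]."""
    xhat = np.asarray(xhat, dtype=np.float64)
    out = np.array(xhat, dtype=np.float64)
    obs = ~np.isnan(xhat)
    if not obs.any():
        return out
    x = np.clip(xhat[obs], 0.0, 1.0)
    idx = np.searchsorted(imap.uppers, x, side="right")
    idx = np.clip(idx, 0, len(imap.values) - 1)
    out[obs] = imap.values[idx]
    return out


def _feature_rng(master_seed: int, name: str) -> np.random.Generator:
    """Named substream so per-feature draws are order-independent."""
    return np.random.default_rng([master_seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


class CohortNormalizer:
    """Bundle of per-feature interval maps for a whole cohort.

    Fits one map per static numeric feature, per temporal numeric feature,
    and one for the measurement time (pooled over steps), on observed
    training values only.
    """

    def __init__(self, maps: dict[str, IntervalMap], seed: int = 0):
        self.maps = maps
        self.seed = seed

    @classmethod
    def fit(cls, dataset: EHRDataset, masks: MaskSet, schema: FeatureSchema, seed: int = 0
            ) -> "CohortNormalizer":
        maps: dict[str, IntervalMap] = {}
        for j, name in enumerate(schema.static_numeric):
            obs = dataset.static_num[:, j][masks.static_num[:, j].astype(bool)]
            maps[name] = fit_interval_map(obs)
        for j, name in enumerate(schema.temporal_numeric):
            obs = dataset.temp_num[:, :, j][masks.temp_num[:, :, j].astype(bool)]
            maps[name] = fit_interval_map(obs)
        u = dataset.times[masks.step_present.astype(bool)]
        maps[TIME_KEY] = fit_interval_map(u)
        return cls(maps, seed=seed)

    def normalize_static(self, values: np.ndarray, schema: FeatureSchema) -> np.ndarray:
        out = np.array(values, dtype=np.float64)
        for j, name in enumerate(schema.static_numeric):
            out[:, j] = stochastic_normalize(values[:, j], self.maps[name],
                                             _feature_rng(self.seed, name))
        return out

    def normalize_temporal(self, values: np.ndarray, schema: FeatureSchema) -> np.ndarray:
        out = np.array(values, dtype=np.float64)
        for j, name in enumerate(schema.temporal_numeric):
            out[:, :, j] = stochastic_normalize(values[:, :, j], self.maps[name],
                                                _feature_rng(self.seed, name))
        return out

    def normalize_times(self, times: np.ndarray, step_present: np.ndarray) -> np.ndarray:
        masked = np.where(step_present.astype(bool), times, np.nan)
        out = stochastic_normalize(masked, self.maps[TIME_KEY],
                                   _feature_rng(self.seed, TIME_KEY))
        return np.where(step_present.astype(bool), out, 0.0)

    def renormalize_feature(self, name: str, xhat: np.ndarray) -> np.ndarray:
        return renormalize(xhat, self.maps[name])

    # serialization: bit-exact via float hex representation ---------------
    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "features": {
                name: [[float(v).hex(), float(l).hex(), float(u).hex()]
                       for v, l, u in zip(m.values, m.lowers, m.uppers)]
                for name, m in self.maps.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "CohortNormalizer":
        payload = json.loads(Path(path).read_text())
        maps = {}
        for name, rows in payload["features"].items():
            vals = np.array([float.fromhex(r[0]) for r in rows])
            lows = np.array([float.fromhex(r[1]) for r in rows])
            ups = np.array([float.fromhex(r[2]) for r in rows])
            maps[name] = IntervalMap(vals, lows, ups)
        return cls(maps, seed=payload["seed"])


class MinMaxNormalizer:
    """Plain min-max scaling to [0,1] — the no-stochastic-normalization
    ablation.  Same interface as :class:`CohortNormalizer`; the inverse is
    a linear map, so synthesized values are NOT restricted to the observed
    support (off-grid values can appear)."""

    def __init__(self, bounds: dict[str, tuple[float, float]], seed: int = 0):
        self.bounds = bounds
        self.seed = seed

    @classmethod
    def fit(cls, dataset: EHRDataset, masks: MaskSet, schema: FeatureSchema, seed: int = 0
            ) -> "MinMaxNormalizer":
        bounds: dict[str, tuple[float, float]] = {}
        for j, name in enumerate(schema.static_numeric):
            obs = dataset.static_num[:, j][masks.static_num[:, j].astype(bool)]
            if obs.size == 0:
                raise ValueError(f"feature {name!r} never observed")
            bounds[name] = (float(obs.min()), float(obs.max()))
        for j, name in enumerate(schema.temporal_numeric):
            obs = dataset.temp_num[:, :, j][masks.temp_num[:, :, j].astype(bool)]
            if obs.size == 0:
                raise ValueError(f"feature {name!r} never observed")
            bounds[name] = (float(obs.min()), float(obs.max()))
        u = dataset.times[masks.step_present.astype(bool)]
        bounds[TIME_KEY] = (float(u.min()), float(u.max()))
        return cls(bounds, seed=seed)

    def _scale(self, x, name):
        lo, hi = self.bounds[name]
        return (x - lo) / (hi - lo) if hi > lo else np.where(np.isnan(x), np.nan, 0.5)

    def normalize_static(self, values, schema):
        out = np.array(values, dtype=np.float64)
        for j, name in enumerate(schema.static_numeric):
            out[:, j] = self._scale(values[:, j], name)
        return out

    def normalize_temporal(self, values, schema):
        out = np.array(values, dtype=np.float64)
        for j, name in enumerate(schema.temporal_numeric):
            out[:, :, j] = self._scale(values[:, :, j], name)
        return out

    def normalize_times(self, times, step_present):
        out = self._scale(times, TIME_KEY)
        return np.where(step_present.astype(bool), out, 0.0)

    def renormalize_feature(self, name, xhat):
        lo, hi = self.bounds[name]
        return np.clip(xhat, 0.0, 1.0) * (hi - lo) + lo

    def to_json(self, path) -> None:
        payload = {"type": "minmax", "seed": self.seed,
                   "bounds": {k: [float(v[0]).hex(), float(v[1]).hex()]
                              for k, v in self.bounds.items()}}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "MinMaxNormalizer":
        payload = json.loads(Path(path).read_text())
        bounds = {k: (float.fromhex(v[0]), float.fromhex(v[1]))
                  for k, v in payload["bounds"].items()}
        return cls(bounds, seed=payload["seed"])


def load_normalizer(path):
    payload = json.loads(Path(path).read_text())
    if payload.get("type") == "minmax":
        return MinMaxNormalizer.from_json(path)
    return CohortNormalizer.from_json(path)
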