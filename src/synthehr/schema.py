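"""Feature schema: the declaration of every feature's category.

An EHR cohort is described by five kinds of features: static numeric,
static categorical, temporal numeric, temporal categorical, and the
measurement time of each temporal step.  The schema fixes names,
categorical vocabularies, and the maximum sequence length to which all
records are padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSchema:
    static_numeric: tuple[str, ...]
    static_categorical: tuple[tuple[str, tuple[str, ...]], ...]
    temporal_numeric: tuple[str, ...]
    temporal_categorical: tuple[tuple[str, tuple[str, ...]], ...]
    time_name: str = "time"
    max_seq_len: int = 50

    def __post_init__(self):
        names = (
            list(self.static_numeric)
            + [n for n, _ in self.static_categorical]
            + list(self.temporal_numeric)
            + [n for n, _ in self.temporal_categorical]
        )
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise SchemaError(f"duplicate feature name: {n!r}")
            seen.add(n)
        if self.time_name in seen:
            raise SchemaError(f"time field {self.time_name!r} collides with a feature name")
        for name, vocab in list(self.static_categorical) + list(self.temporal_categorical):
            if len(vocab) < 2:
                raise SchemaError(f"categorical feature {name!r} needs a vocabulary of >= 2 entries")
            if len(set(vocab)) != len(vocab):
                raise SchemaError(f"categorical feature {name!r} has duplicate vocabulary entries")
        if self.max_seq_len < 1:
            raise SchemaError("max_seq_len must be >= 1")

    # convenience accessors -----------------------------------------
    @property
    def static_cat_names(self) -> list[str]:
        return [n for n, _ in self.static_categorical]

    @property
    def temporal_cat_names(self) -> list[str]:
        return [n for n, _ in self.temporal_categorical]

    @property
    def static_cat_vocabs(self) -> list[tuple[str, ...]]:
        return [v for _, v in self.static_categorical]

    @property
    def temporal_cat_vocabs(self) -> list[tuple[str, ...]]:
        return [v for _, v in self.temporal_categorical]

    @property
    def temporal_names(self) -> list[str]:
        return list(self.temporal_numeric) + self.temporal_cat_names

    def vocab_of(self, name: str) -> tuple[str, ...]:
        for n, v in list(self.static_categorical) + list(self.temporal_categorical):
            if n == name:
                return v
        raise KeyError(name)

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


def _dedup(vocab: list) -> tuple[str, ...]:
    out: list[str] = []
    for v in vocab:
        s = str(v)
        if s not in out:
            out.append(s)
    return tuple(out)


def schema_from_dict(cfg: dict) -> FeatureSchema:
    def cat_list(key: str):
        items = cfg.get(key, []) or []
        out = []
        for item in items:
            if isinstance(item, dict):
                (name, vocab), = item.items()
            else:
                name, vocab = item
            vocab = _dedup(list(vocab))
            if not vocab:
                raise SchemaError(f"categorical feature {name!r} has an empty vocabulary")
            out.append((str(name), vocab))
        return tuple(out)

    return FeatureSchema(
        static_numeric=tuple(str(n) for n in (cfg.get("static_numeric", []) or [])),
        static_categorical=cat_list("static_categorical"),
        temporal_numeric=tuple(str(n) for n in (cfg.get("temporal_numeric", []) or [])),
        temporal_categorical=cat_list("temporal_categorical"),
        time_name=str(cfg.get("time_name", "time")),
        max_seq_len=int(cfg.get("max_seq_len", 50)),
    )


def schema_to_dict(schema: FeatureSchema) -> dict:
    return {
        "static_numeric": list(schema.static_numeric),
        "static_categorical": [{n: list(v)} for n, v in schema.static_categorical],
        "temporal_numeric": list(schema.temporal_numeric),
        "temporal_categorical": [{n: list(v)} for n, v in schema.temporal_categorical],
        "time_name": schema.time_name,
        "max_seq_len": schema.max_seq_len,
    }


def load_schema(path) -> FeatureSchema:
    """Read and validate a YAML schema config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"schema file {path} did not parse to a mapping")
    return schema_from_dict(cfg)


def save_schema(schema: FeatureSchema, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schema_to_dict(schema), fh, sort_keys=False)
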