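"""Delimited-text file formats and run configuration.

The long table travels as a TSV with one row per (sample, segment, formula)
record and the per-sample metadata (C475, DOC) repeated on each row — the
layout vendor tools export.  Wide feature tables are TSV matrices with a
``#``-prefixed provenance header (layout, filters, normalization, config
hash, seeds).  Run configurations round-trip through YAML.
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .tables import FeatureTable, LongTable

__all__ = [
    "read_long_table",
    "write_long_table",
    "read_feature_table",
    "write_feature_table",
    "RunConfig",
    "config_hash",
]

REQUIRED_COLUMNS = ["sample_id", "segment_start_min", "formula", "intensity",
                    "c475", "doc_umol_kg"]
OPTIONAL_COLUMNS = ["lon", "lat", "depth", "datetime"]


class SchemaError(ValueError):
    pass


def _offending(frame: pd.DataFrame, mask, what: str) -> str:
    rows = frame.index[mask][:10].tolist()
    return f"{what} at rows {rows}" + (" (first 10 shown)" if mask.sum() > 10 else "")


def read_long_table(path) -> LongTable:
    """Read and validate a TSV long table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns {missing}")
    problems = []
    neg = df["intensity"] < 0
    if neg.any():
        problems.append(_offending(df, neg, "negative intensity"))
    na = df[REQUIRED_COLUMNS].isna().any(axis=1)
    if na.any():
        problems.append(_offending(df, na, "missing value"))
    dup = df.duplicated(subset=["sample_id", "segment_start_min", "formula"])
    if dup.any():
        problems.append(_offending(df, dup, "duplicate (sample, segment, formula) key"))
    for col in ("c475", "doc_umol_kg"):
        nun = df.groupby("sample_id")[col].nunique()
        bad = nun[nun > 1].index.tolist()
        if bad:
            problems.append(f"inconsistent {col} within samples {bad[:10]}")
    if problems:
        raise SchemaError("; ".join(problems))
    meta_cols = ["c475", "doc_umol_kg"] + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    metadata = df.groupby("sample_id", sort=True)[meta_cols].first()
    records = df[["sample_id", "segment_start_min", "formula", "intensity"]].copy()
    return LongTable(records=records.reset_index(drop=True), metadata=metadata)


def write_long_table(long: LongTable, path, header_meta: dict | None = None) -> None:
    df = long.records.merge(
        long.metadata.reset_index(), on="sample_id", how="left"
    )
    cols = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df[cols].to_csv(fh, sep="\t", index=False)


def write_feature_table(table: FeatureTable, path, header_meta: dict | None = None) -> None:
    meta = {
        "layout": "time_aware" if table.time_aware else "time_agnostic",
        "filters": ",".join(table.filters) or "none",
        "normalization": table.normalization or "none",
    }
    meta.update(header_meta or {})
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        table.values.to_csv(fh, sep="\t", index_label="sample_id")


def read_feature_table(path) -> FeatureTable:
    header = {}
    with open(path) as fh:
        text = fh.read()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            k, _, v = line[1:].partition(":")
            header[k.strip()] = v.strip()
        else:
            body_lines.append(line)
    values = pd.read_csv(_io.StringIO("\n".join(body_lines)), sep="\t",
                         index_col="sample_id")
    filters = tuple(
        f for f in header.get("filters", "none").split(",") if f and f != "none"
    )
    norm = header.get("normalization", "none")
    return FeatureTable(
        values=values,
        time_aware=header.get("layout") == "time_aware",
        filters=filters,
        normalization=None if norm == "none" else norm,
    )


@dataclass
class RunConfig:
    """Serializable run configuration with derived per-stage seeds."""

    seed: int = 0
    input_path: str | None = None
    generator: dict = field(default_factory=dict)
    specs: list = field(default_factory=list)  # list of "format/elim/norm" keys
    families: list = field(default_factory=list)
    grid_overrides: dict = field(default_factory=dict)
    cv_folds: int = 10
    cv_repeats: int = 10
    rf_n_trees: int = 1000
    output_dir: str = "results"

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:12]
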