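"""Long-format LC-FTMS records and the two wide feature-table layouts.

A measurement campaign yields a tidy long table: one row per
(sample, retention-time segment, molecular formula) with a peak intensity,
plus per-sample metadata (the C475 fluorescence proxy and the DOC
concentration).  Models consume one of two wide layouts:

* *time-agnostic* — one column per molecular formula (MF); the entry is the
  mean intensity over the segments where the formula was detected in that
  sample, zero when absent everywhere;
* *time-aware* — one column per formula-at-segment combination (MFRT); the
  entry is the measured intensity or zero.

Both layouts have exactly one row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LongTable",
    "FeatureTable",
    "feature_key",
    "split_feature_key",
    "build_time_agnostic",
    "build_time_aware",
    "long_from_time_aware",
]

RECORD_COLUMNS = ["sample_id", "segment_start_min", "formula", "intensity"]


class TableError(ValueError):
    """Raised for structurally invalid long or wide tables."""


@dataclass
class LongTable:
    """Tidy records plus per-sample metadata.

    ``records`` has columns sample_id, segment_start_min, formula, intensity;
    ``metadata`` is indexed by sample_id and carries at least ``c475`` and
    ``doc_umol_kg``.
    """

    records: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise TableError(f"records missing columns {missing}")
        if self.records.empty:
            raise TableError("empty long table")
        if (self.records["intensity"] < 0).any():
            n = int((self.records["intensity"] < 0).sum())
            raise TableError(f"{n} negative intensities")
        dup = self.records.duplicated(
            subset=["sample_id", "segment_start_min", "formula"]
        )
        if dup.any():
            rows = self.records.index[dup][:10].tolist()
            raise TableError(f"duplicate (sample, segment, formula) keys at rows {rows}")
        for col in ("c475", "doc_umol_kg"):
            if col not in self.metadata.columns:
                raise TableError(f"metadata missing column {col!r}")
            if self.metadata[col].isna().any():
                bad = self.metadata.index[self.metadata[col].isna()][:10].tolist()
                raise TableError(f"missing {col} for samples {bad}")
        known = set(self.metadata.index)
        seen = set(self.records["sample_id"])
        orphan = sorted(seen - known)
        if orphan:
            raise TableError(f"records for samples without metadata: {orphan[:10]}")

    @property
    def sample_ids(self) -> list:
        return list(self.metadata.index)

    @property
    def c475(self) -> pd.Series:
        return self.metadata["c475"]

    @property
    def doc(self) -> pd.Series:
        return self.metadata["doc_umol_kg"]

    def sorted_records(self) -> pd.DataFrame:
        return (
            self.records.sort_values(["sample_id", "segment_start_min", "formula"])
            .reset_index(drop=True)
        )


@dataclass
class FeatureTable:
    """Samples x features matrix with provenance flags.

    ``values`` is indexed by sample_id; columns are formula labels
    (time-agnostic) or ``formula@segment`` keys (time-aware).  The
    provenance fields record the history of the table: layout, feature
    eliminations applied, and the normalization applied (at most one).
    """

    values: pd.DataFrame
    time_aware: bool
    filters: tuple = ()
    normalization: str | None = None

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            raise TableError("duplicate feature keys")
        self.filters = tuple(self.filters)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def segment_of(self, key: str) -> float:
        if not self.time_aware:
            raise TableError("time-agnostic table has no segment mapping")
        return split_feature_key(key)[1]

    def segments(self) -> np.ndarray:
        """Sorted distinct segment start times (time-aware only)."""
        return np.unique([self.segment_of(k) for k in self.values.columns])

    def ubiquitous_mask(self) -> pd.Series:
        """True for columns with a nonzero intensity in every sample."""
        return (self.values != 0).all(axis=0)

    def zero_fraction(self) -> float:
        return float((self.values.to_numpy() == 0).mean())

    def with_values(self, values: pd.DataFrame, *, add_filter=None, normalization=None):
        filters = self.filters + ((add_filter,) if add_filter else ())
        out = replace(self, values=values, filters=filters)
        if normalization is not None:
            out.normalization = normalization
        return out


def feature_key(formula: str, segment: float | None = None) -> str:
    if segment is None:
        return formula
    return f"{formula}@{segment:g}"


def split_feature_key(key: str):
    if "@" not in key:
        return key, None
    formula, seg = key.rsplit("@", 1)
    return formula, float(seg)


def _sample_index(long: LongTable) -> pd.Index:
    return pd.Index(long.metadata.index, name="sample_id")


def build_time_agnostic(long: LongTable) -> FeatureTable:
    """One column per formula; mean intensity over segments where present."""
    # canonical record order keeps float aggregation independent of input order
    rec = long.sorted_records()
    wide = (
        rec.groupby(["sample_id", "formula"], sort=True)["intensity"]
        .mean()
        .unstack(fill_value=0.0)
    )
    wide = wide.reindex(index=_sample_index(long), fill_value=0.0)
    wide = wide[sorted(wide.columns)].astype(float)
    wide.columns.name = None
    return FeatureTable(values=wide, time_aware=False)


def build_time_aware(long: LongTable) -> FeatureTable:
    """One column per (formula, segment) pair observed anywhere."""
    rec = long.sorted_records()
    keys = [
        feature_key(f, s)
        for f, s in zip(rec["formula"], rec["segment_start_min"])
    ]
    wide = (
        pd.DataFrame(
            {"sample_id": rec["sample_id"], "key": keys, "intensity": rec["intensity"]}
        )
        .pivot_table(index="sample_id", columns="key", values="intensity", fill_value=0.0)
    )
    wide = wide.reindex(index=_sample_index(long), fill_value=0.0)
    order = sorted(wide.columns, key=lambda k: split_feature_key(k))
    wide = wide[order].astype(float)
    wide.columns.name = None
    return FeatureTable(values=wide, time_aware=True)


def long_from_time_aware(table: FeatureTable, metadata: pd.DataFrame) -> LongTable:
    """Reconstruct the long table from a time-aware layout, dropping zeros."""
    if not table.time_aware:
        raise TableError("reconstruction requires a time-aware table")
    stacked = table.values.stack()
    stacked = stacked[stacked != 0]
    keys = [split_feature_key(k) for k in stacked.index.get_level_values(1)]
    records = pd.DataFrame(
        {
            "sample_id": stacked.index.get_level_values(0),
            "segment_start_min": [s for _, s in keys],
            "formula": [f for f, _ in keys],
            "intensity": stacked.to_numpy(),
        }
    ).reset_index(drop=True)
    return LongTable(records=records, metadata=metadata)
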