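"""Feature elimination, intensity normalizations, and target standardization.

Two feature eliminations address the ~80% zero-filling of the wide tables:

* *ubiquitous* — keep only features with a nonzero intensity in every sample;
* *no low variance* — drop features with more than 90% zero entries.

Four intensity treatments make samples comparable:

* DOC-N — divide each sample's intensities by its DOC concentration;
* SUM — divide each intensity by the summed intensities of its spectrum
  (the whole sample row for time-agnostic tables; the per-segment block for
  time-aware tables, since each segment is one summed mass spectrum);
* UBISUM — as SUM but the denominator sums only the ubiquitous features,
  giving a common ground between samples that is robust to contamination;
* ALR — additive log-ratio against the ubiquitous feature with the lowest
  intensity variance across samples, with one-third of the smallest nonzero
  intensity in the table as the zero replacement.

The C475 target is z-scored so positive values read as terrestrial-leaning.
Combined with the two table layouts this yields the 32 preprocessing
combinations enumerated by :func:`enumerate_specs`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import FeatureTable

__all__ = [
    "TABLE_FORMATS",
    "ELIMINATIONS",
    "NORMALIZATIONS",
    "PreprocessSpec",
    "enumerate_specs",
    "filter_ubiquitous",
    "filter_low_variance",
    "normalize_doc",
    "normalize_sum",
    "normalize_ubisum",
    "alr_transform",
    "TargetScaler",
    "zscore_target",
    "apply_elimination",
    "apply_normalization",
    "preprocess_table",
]

logger = logging.getLogger(__name__)

TABLE_FORMATS = ("time_aware", "time_agnostic")
ELIMINATIONS = ("none", "ubiquitous", "no_low_variance", "both")
NORMALIZATIONS = ("DOC-N", "SUM", "UBISUM", "ALR")


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessSpec:
    """One of the 32 table-format x elimination x normalization combinations."""

    table_format: str
    elimination: str
    normalization: str

    def __post_init__(self):
        if self.table_format not in TABLE_FORMATS:
            raise PreprocessError(f"unknown table format {self.table_format!r}")
        if self.elimination not in ELIMINATIONS:
            raise PreprocessError(f"unknown elimination {self.elimination!r}")
        if self.normalization not in NORMALIZATIONS:
            raise PreprocessError(f"unknown normalization {self.normalization!r}")

    @property
    def key(self) -> str:
        return f"{self.table_format}/{self.elimination}/{self.normalization}"


def enumerate_specs(eliminations=ELIMINATIONS) -> list:
    """All preprocessing combinations (32 by default, 16 per elimination branch)."""
    return [
        PreprocessSpec(fmt, elim, norm)
        for fmt in TABLE_FORMATS
        for elim in eliminations
        for norm in NORMALIZATIONS
    ]


def filter_ubiquitous(table: FeatureTable) -> FeatureTable:
    """Keep exactly the feature columns with no zero entry."""
    mask = table.ubiquitous_mask()
    if not mask.any():
        raise PreprocessError(
            "no ubiquitous features remain; the table needs a larger "
            "always-detected core"
        )
    return table.with_values(table.values.loc[:, mask], add_filter="ubiquitous")


def filter_low_variance(table: FeatureTable, max_zero_fraction: float = 0.9) -> FeatureTable:
    """Drop columns whose zero fraction strictly exceeds ``max_zero_fraction``."""
    zf = (table.values == 0).mean(axis=0)
    keep = zf <= max_zero_fraction
    return table.with_values(table.values.loc[:, keep], add_filter="no_low_variance")


def apply_elimination(table: FeatureTable, elimination: str) -> FeatureTable:
    if elimination == "none":
        return table
    if elimination == "ubiquitous":
        return filter_ubiquitous(table)
    if elimination == "no_low_variance":
        return filter_low_variance(table)
    if elimination == "both":
        return filter_ubiquitous(filter_low_variance(table))
    raise PreprocessError(f"unknown elimination {elimination!r}")


def normalize_doc(table: FeatureTable, doc: pd.Series) -> FeatureTable:
    """Divide each sample row by its DOC concentration (umol C / kg)."""
    doc = doc.reindex(table.values.index)
    bad = doc.index[doc.isna() | (doc <= 0)].tolist()
    if bad:
        raise PreprocessError(f"missing or non-positive DOC for samples {bad[:10]}")
    out = table.values.div(doc, axis=0)
    return table.with_values(out, normalization="DOC-N")


def _segment_blocks(table: FeatureTable):
    """Column index arrays grouped by segment start time (time-aware)."""
    segs = np.array([table.segment_of(k) for k in table.values.columns])
    return [(s, np.flatnonzero(segs == s)) for s in np.unique(segs)]


def _blockwise_divide(table: FeatureTable, denom_cols_mask, name: str) -> pd.DataFrame:
    """Divide each spectrum block by the summed intensities over ``denom_cols_mask``.

    A spectrum is the whole row for time-agnostic tables and each segment
    block for time-aware tables.
    """
    vals = table.values.to_numpy(dtype=float)
    out = np.empty_like(vals)
    if table.time_aware:
        for seg, cols in _segment_blocks(table):
            dcols = cols[denom_cols_mask[cols]]
            if dcols.size == 0:
                raise PreprocessError(
                    f"{name}: no denominator features in segment {seg:g}"
                )
            denom = vals[:, dcols].sum(axis=1)
            zero = np.flatnonzero(denom == 0)
            if zero.size:
                sample = table.values.index[zero[0]]
                raise PreprocessError(
                    f"{name}: all-zero spectrum for sample {sample!r} in segment {seg:g}"
                )
            out[:, cols] = vals[:, cols] / denom[:, None]
    else:
        dcols = np.flatnonzero(denom_cols_mask)
        if dcols.size == 0:
            raise PreprocessError(f"{name}: no denominator features")
        denom = vals[:, dcols].sum(axis=1)
        zero = np.flatnonzero(denom == 0)
        if zero.size:
            sample = table.values.index[zero[0]]
            raise PreprocessError(f"{name}: all-zero spectrum for sample {sample!r}")
        out = vals / denom[:, None]
    return pd.DataFrame(out, index=table.values.index, columns=table.values.columns)


def normalize_sum(table: FeatureTable) -> FeatureTable:
    """Divide each intensity by the summed intensities of its spectrum."""
    mask = np.ones(table.n_features, dtype=bool)
    out = _blockwise_divide(table, mask, "SUM")
    return table.with_values(out, normalization="SUM")


def normalize_ubisum(table: FeatureTable) -> FeatureTable:
    """Divide each intensity by the summed intensities of the ubiquitous features."""
    mask = table.ubiquitous_mask().to_numpy()
    if not mask.any():
        raise PreprocessError("UBISUM: table has no ubiquitous features")
    out = _blockwise_divide(table, mask, "UBISUM")
    return table.with_values(out, normalization="UBISUM")


def alr_transform(table: FeatureTable) -> FeatureTable:
    """Additive log-ratio against the lowest-variance ubiquitous feature.

    Zeros are replaced by one-third of the smallest nonzero intensity of the
    whole table before taking the ratio; a single table-wide replacement
    constant keeps the transform monotone across samples.  The reference
    column is retained (identically zero after the transform).  Variance
    ties are broken by lexicographic feature key.
    """
    mask = table.ubiquitous_mask()
    if not mask.any():
        raise PreprocessError("ALR: table has no ubiquitous features")
    ubiq = table.values.loc[:, mask]
    variances = ubiq.var(axis=0, ddof=1)
    min_var = variances.min()
    candidates = sorted(variances.index[variances == min_var])
    if len(candidates) > 1:
        logger.info("ALR reference tie broken lexicographically: %s", candidates[0])
    ref_key = candidates[0]

    vals = table.values.to_numpy(dtype=float)
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise PreprocessError("ALR: table has no nonzero intensities")
    replacement = nonzero.min() / 3.0
    filled = np.where(vals == 0, replacement, vals)
    ref = filled[:, table.values.columns.get_loc(ref_key)]
    out = np.log(filled / ref[:, None])
    out_df = pd.DataFrame(out, index=table.values.index, columns=table.values.columns)
    return table.with_values(out_df, normalization="ALR")


def apply_normalization(table: FeatureTable, normalization: str, doc=None) -> FeatureTable:
    if normalization == "DOC-N":
        if doc is None:
            raise PreprocessError("DOC-N requires per-sample DOC concentrations")
        return normalize_doc(table, doc)
    if normalization == "SUM":
        return normalize_sum(table)
    if normalization == "UBISUM":
        return normalize_ubisum(table)
    if normalization == "ALR":
        return alr_transform(table)
    raise PreprocessError(f"unknown normalization {normalization!r}")


def preprocess_table(table: FeatureTable, spec: PreprocessSpec, doc=None) -> FeatureTable:
    """Eliminate features, then normalize (build -> eliminate -> normalize)."""
    expected = spec.table_format == "time_aware"
    if table.time_aware != expected:
        raise PreprocessError(
            f"table layout mismatch: spec wants {spec.table_format}"
        )
    out = apply_elimination(table, spec.elimination)
    return apply_normalization(out, spec.normalization, doc=doc)


@dataclass(frozen=True)
class TargetScaler:
    """Mean/sd pair for the z-scored target with an exact inverse."""

    mean: float
    sd: float

    def transform(self, y):
        return (np.asarray(y, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def zscore_target(c475: pd.Series) -> tuple:
    """Standardize C475 (sample sd); positive values read as terrestrial.

    Returns the standardized series and the :class:`TargetScaler` holding
    the mean and sd for the exact inverse transform.
    """
    y = pd.Series(c475, dtype=float)
    sd = float(y.std(ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise PreprocessError("constant C475 target cannot be z-scored")
    mean = float(y.mean())
    scaler = TargetScaler(mean=mean, sd=sd)
    return (y - mean) / sd, scaler
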