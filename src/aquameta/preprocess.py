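"""Assay cleaning and feature assembly.

The cleaning pipeline has a fixed stage order:

    standardize_units -> drop_bounded -> merge_subspecies
    -> aggregate_replicates -> normalize_duration -> table build

After aggregation there is exactly one row per (species, chemical, duration)
cell, with the endpoint equal to the geometric mean of the raw replicate
values.  ``TableBuilder`` then joins chemical features, encodes taxonomy
(multi-task mode only), imputes missing descriptors with training medians
and drops constant columns, producing the :class:`ModelTable` consumed by
every learner.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CleaningReport",
    "PreprocessWarning",
    "standardize_units",
    "drop_bounded",
    "merge_subspecies",
    "aggregate_replicates",
    "normalize_duration",
    "clean_assays",
    "ModelTable",
    "TableBuilder",
    "build_model_table",
]

COL_SPECIES = "species_id"
COL_SUBSPECIES = "subspecies_id"
COL_CLASS = "class_name"
COL_PHYLUM = "phylum_name"
COL_CHEMICAL = "chemical_id"
COL_DURATION = "duration"
COL_DURATION_UNIT = "duration_unit"
COL_DURATION_DAYS = "duration_days"
COL_VALUE = "endpoint_value"
COL_UNITS = "endpoint_units"
COL_BOUND = "bound"

BOUND_EXACT = "exact"

#: multiplicative factors to the canonical concentration unit (mg/L, mass basis)
DEFAULT_UNIT_FACTORS: dict[str, float] = {
    "mg/L": 1.0,
    "g/L": 1000.0,
    "ug/L": 1e-3,
    "µg/L": 1e-3,
    "ng/L": 1e-6,
    "ppm": 1.0,   # dilute aqueous approximation
    "ppb": 1e-3,
}

DURATION_TO_DAYS: dict[str, float] = {
    "d": 1.0, "day": 1.0, "days": 1.0,
    "h": 1.0 / 24.0, "hr": 1.0 / 24.0, "hours": 1.0 / 24.0,
    "min": 1.0 / 1440.0,
    "w": 7.0, "wk": 7.0, "week": 7.0, "weeks": 7.0,
}


class PreprocessWarning(UserWarning):
    pass


@dataclasses.dataclass
class CleaningReport:
    """Row-drop and merge counters accumulated across cleaning stages."""

    dropped_units: int = 0
    dropped_bounded: int = 0
    dropped_duration: int = 0
    merged_subspecies_rows: int = 0
    aggregated_replicate_rows: int = 0


def _warn(message: str) -> None:
    warnings.warn(message, PreprocessWarning, stacklevel=3)


def standardize_units(
    records: pd.DataFrame,
    unit_factors: Mapping[str, float] | None = None,
    canonical_unit: str = "mg/L",
    report: CleaningReport | None = None,
) -> pd.DataFrame:
    """Convert endpoint values to one unit; drop rows with unknown units."""
    factors = DEFAULT_UNIT_FACTORS if unit_factors is None else dict(unit_factors)
    if canonical_unit not in factors:
        raise ValueError(f"canonical unit {canonical_unit!r} missing from unit table")
    scale = factors[canonical_unit]
    df = records.copy()
    known = df[COL_UNITS].map(lambda u: u in factors)
    n_dropped = int((~known).sum())
    if n_dropped:
        bad = sorted(df.loc[~known, COL_UNITS].unique())
        _warn(f"dropping {n_dropped} rows with unconvertible units {bad}")
    if report is not None:
        report.dropped_units += n_dropped
    df = df[known].copy()
    factor = df[COL_UNITS].map(factors).astype(float) / scale
    df[COL_VALUE] = df[COL_VALUE].astype(float) * factor
    df[COL_UNITS] = canonical_unit
    return df.reset_index(drop=True)


def drop_bounded(records: pd.DataFrame, report: CleaningReport | None = None) -> pd.DataFrame:
    """Keep only exact-valued endpoints (bounds '<', '>', 'between' removed)."""
    df = records.copy()
    if COL_BOUND not in df.columns:
        return df
    keep = df[COL_BOUND] == BOUND_EXACT
    n_dropped = int((~keep).sum())
    if report is not None:
        report.dropped_bounded += n_dropped
    out = df[keep].reset_index(drop=True)
    if len(out) == 0:
        _warn("all rows carried bounded endpoints; result is empty")
    return out


def _cell_key(df: pd.DataFrame) -> list[str]:
    key = [COL_SPECIES, COL_CHEMICAL]
    if COL_DURATION_DAYS in df.columns:
        key.append(COL_DURATION_DAYS)
    else:
        key.append(COL_DURATION)
        if COL_DURATION_UNIT in df.columns:
            key.append(COL_DURATION_UNIT)
    return key


_CARRY_FIRST = [COL_CLASS, COL_PHYLUM, COL_UNITS, COL_BOUND, "assay_id"]


def merge_subspecies(records: pd.DataFrame, report: CleaningReport | None = None) -> pd.DataFrame:
    """Fold subspecies into their parent species.

    Where a (species, chemical, duration) cell holds rows from more than one
    subspecies, each subspecies is first summarized by the geometric mean of
    its raw values and the cell value becomes the geometric mean of those
    summaries (i.e. the empirical mean on the log10 scale).  Cells without a
    subspecies conflict are left untouched so later replicate aggregation
    still sees the individual rows.  The subspecies column is removed, which
    makes the operation idempotent.
    """
    df = records.copy()
    if COL_SUBSPECIES not in df.columns:
        return df
    key = _cell_key(df)
    sub = df[COL_SUBSPECIES].fillna("__none__")
    n_distinct = sub.groupby([df[k] for k in key]).transform("nunique")
    conflict = n_distinct > 1
    plain = df[~conflict].drop(columns=[COL_SUBSPECIES])

    merged_rows = []
    if conflict.any():
        conflicted = df[conflict].copy()
        conflicted["__sub"] = sub[conflict]
        for cell, group in conflicted.groupby(key, sort=False):
            per_sub = group.groupby("__sub")[COL_VALUE].apply(
                lambda v: float(np.exp(np.log(v.astype(float)).mean())))
            row = group.iloc[0].drop(labels=["__sub", COL_SUBSPECIES]).copy()
            row[COL_VALUE] = float(np.exp(np.log(per_sub.to_numpy()).mean()))
            merged_rows.append(row)
        if report is not None:
            report.merged_subspecies_rows += int(conflict.sum()) - len(merged_rows)
    out = pd.concat([plain, pd.DataFrame(merged_rows)], ignore_index=True) if merged_rows else plain
    return out.reset_index(drop=True)


def aggregate_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate rows to one geometric-mean value per cell.

    Requires bounded rows to be gone already; a non-positive endpoint here is
    an upstream invariant violation and raises.
    """
    df = records.copy()
    if COL_BOUND in df.columns and (df[COL_BOUND] != BOUND_EXACT).any():
        raise ValueError("bounded rows must be removed before replicate aggregation")
    values = df[COL_VALUE].astype(float)
    if (values <= 0).any() or values.isna().any():
        raise ValueError("non-positive endpoint value reached replicate aggregation")
    key = _cell_key(df)
    carry = [c for c in _CARRY_FIRST if c in df.columns]
    agg: dict[str, object] = {COL_VALUE: lambda v: float(np.exp(np.log(v.astype(float)).mean()))}
    agg.update({c: "first" for c in carry})
    out = df.groupby(key, sort=False, as_index=False).agg(agg)
    return out.reset_index(drop=True)


def normalize_duration(records: pd.DataFrame, report: CleaningReport | None = None) -> pd.DataFrame:
    """Express durations in days; drop rows without a usable duration."""
    df = records.copy()
    if COL_DURATION_DAYS in df.columns:
        return df
    if COL_DURATION_UNIT in df.columns:
        factor = df[COL_DURATION_UNIT].map(DURATION_TO_DAYS)
    else:
        factor = pd.Series(1.0, index=df.index)  # assume days when no unit column
    days = df[COL_DURATION].astype(float) * factor
    bad = days.isna() | (days <= 0)
    n_dropped = int(bad.sum())
    if n_dropped:
        _warn(f"dropping {n_dropped} rows with missing/invalid duration")
    if report is not None:
        report.dropped_duration += n_dropped
    df = df[~bad].copy()
    df[COL_DURATION_DAYS] = days[~bad]
    df = df.drop(columns=[c for c in (COL_DURATION, COL_DURATION_UNIT) if c in df.columns])
    return df.reset_index(drop=True)


def clean_assays(
    records: pd.DataFrame,
    unit_factors: Mapping[str, float] | None = None,
    canonical_unit: str = "mg/L",
    report: CleaningReport | None = None,
) -> pd.DataFrame:
    """Run the full fixed-order cleaning pipeline."""
    df = standardize_units(records, unit_factors, canonical_unit, report)
    df = drop_bounded(df, report)
    df = merge_subspecies(df, report)
    df = aggregate_replicates(df)
    df = normalize_duration(df, report)
    return df


# ---------------------------------------------------------------------------
# model tables
# ---------------------------------------------------------------------------

MODE_SINGLE = "single_task"
MODE_MULTI = "multi_task"


@dataclasses.dataclass
class ModelTable:
    """Feature/target table with row metadata, the learners' substrate.

    ``blocks`` maps block names ("fingerprint", "physchem", "duration",
    "taxonomy") to ordered column tuples; ``fingerprint`` is a schema hash
    that fitted learners use to refuse mismatched inputs.
    """

    X: pd.DataFrame
    y: np.ndarray | None
    species: np.ndarray
    chemical: np.ndarray
    duration: np.ndarray
    blocks: dict[str, tuple[str, ...]]
    mode: str
    fingerprint: str

    def __len__(self) -> int:
        return len(self.X)

    def feature_matrix(self, exclude_blocks: Iterable[str] = ()) -> np.ndarray:
        exclude = set(exclude_blocks)
        cols: list[str] = []
        for name, block_cols in self.blocks.items():
            if name not in exclude:
                cols.extend(block_cols)
        return self.X[cols].to_numpy(dtype=float)

    def canonical_order(self) -> "ModelTable":
        """Rows sorted by (species, chemical, duration): fit-time determinism."""
        order = np.lexsort((self.duration, self.chemical.astype(str),
                            self.species.astype(str)))
        return ModelTable(
            X=self.X.iloc[order].reset_index(drop=True),
            y=None if self.y is None else self.y[order],
            species=self.species[order],
            chemical=self.chemical[order],
            duration=self.duration[order],
            blocks=self.blocks,
            mode=self.mode,
            fingerprint=self.fingerprint,
        )

    def subset(self, mask: np.ndarray) -> "ModelTable":
        mask = np.asarray(mask)
        return ModelTable(
            X=self.X.loc[mask].reset_index(drop=True),
            y=None if self.y is None else self.y[mask],
            species=self.species[mask],
            chemical=self.chemical[mask],
            duration=self.duration[mask],
            blocks=self.blocks,
            mode=self.mode,
            fingerprint=self.fingerprint,
        )


class TableBuilder:
    """Fit feature-assembly state on training rows, then transform any rows.

    All statistics that could leak information (imputation medians, constant
    column detection) are computed in :meth:`fit` from training rows only.
    Taxonomy one-hot categories come from the full taxonomy table, which is
    species metadata rather than assay data; species never seen in training
    simply have their indicator column dropped as constant, so prediction for
    them falls back to class/phylum information.
    """

    def __init__(self, mode: str = MODE_MULTI, fp_prefix: str = "fp_",
                 encoding: str = "one_hot", drop_constant: bool = True):
        if mode not in (MODE_SINGLE, MODE_MULTI):
            raise ValueError(f"unknown mode {mode!r}")
        if encoding not in ("one_hot", "ordinal"):
            raise ValueError(f"unknown encoding {encoding!r}")
        self.mode = mode
        self.fp_prefix = fp_prefix
        self.encoding = encoding
        self.drop_constant = drop_constant
        self._fitted = False

    # -- helpers ---------------------------------------------------------
    def _join(self, records: pd.DataFrame) -> pd.DataFrame:
        missing = ~records[COL_CHEMICAL].isin(self._chemicals.index)
        if missing.any():
            _warn(f"dropping {int(missing.sum())} rows whose chemical has no feature row")
            records = records[~missing]
        joined = records.join(self._chemicals, on=COL_CHEMICAL)
        return joined.reset_index(drop=True)

    def _encode_taxonomy(self, joined: pd.DataFrame) -> pd.DataFrame:
        parts = []
        species = joined[COL_SPECIES]
        for series, prefix, cats in (
            (species, "sp", self._species_cats),
            (species.map(self._species_to_class), "cls", self._class_cats),
            (species.map(self._species_to_phylum), "phy", self._phylum_cats),
        ):
            values = pd.Categorical(series, categories=cats)
            if self.encoding == "one_hot":
                dummies = pd.get_dummies(values, prefix=prefix, dtype=float)
                parts.append(dummies.set_axis(joined.index))
            else:
                parts.append(pd.DataFrame({f"{prefix}_code": values.codes.astype(float)},
                                          index=joined.index))
        return pd.concat(parts, axis=1)

    def _assemble(self, records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]], pd.DataFrame]:
        if len(records) == 0:
            raise ValueError("empty assay table")
        if COL_DURATION_DAYS not in records.columns:
            raise ValueError("records lack duration_days; run normalize_duration first")
        joined = self._join(records)
        blocks: dict[str, list[str]] = {
            "fingerprint": list(self._fp_cols),
            "physchem": list(self._pc_cols) + list(self._indicator_cols),
            "duration": ["log10_duration"],
        }
        X = joined[self._fp_cols + self._pc_cols + self._indicator_cols].copy()
        X = X.astype(float)
        X["log10_duration"] = np.log10(joined[COL_DURATION_DAYS].astype(float))
        if self.mode == MODE_MULTI:
            tax = self._encode_taxonomy(joined)
            blocks["taxonomy"] = list(tax.columns)
            X = pd.concat([X, tax], axis=1)
        return X, blocks, joined

    # -- public API ------------------------------------------------------
    def fit(self, records: pd.DataFrame, chemicals: pd.DataFrame,
            taxonomy: pd.DataFrame | None = None) -> "TableBuilder":
        if len(records) == 0:
            raise ValueError("cannot fit a TableBuilder on an empty assay table")
        chem = chemicals.set_index(COL_CHEMICAL) if COL_CHEMICAL in chemicals.columns else chemicals
        self._chemicals = chem
        feature_cols = [c for c in chem.columns]
        self._fp_cols = [c for c in feature_cols if c.startswith(self.fp_prefix)]
        self._pc_cols = [c for c in feature_cols
                         if not c.startswith(self.fp_prefix) and not c.endswith("_missing")]
        self._indicator_cols = [c for c in feature_cols if c.endswith("_missing")]

        if self.mode == MODE_MULTI:
            if taxonomy is None:
                raise ValueError("multi-task mode requires a taxonomy table")
            self._species_cats = list(pd.unique(taxonomy[COL_SPECIES]))
            self._class_cats = list(pd.unique(taxonomy[COL_CLASS]))
            self._phylum_cats = list(pd.unique(taxonomy[COL_PHYLUM]))
            self._species_to_class = dict(zip(taxonomy[COL_SPECIES], taxonomy[COL_CLASS]))
            self._species_to_phylum = dict(zip(taxonomy[COL_SPECIES], taxonomy[COL_PHYLUM]))

        X, blocks, joined = self._assemble(records)

        # imputation statistics from training rows only
        self._medians = {}
        for col in self._pc_cols:
            med = float(np.nanmedian(joined[col].astype(float))) if joined[col].notna().any() else 0.0
            self._medians[col] = med
        X = self._impute(X)

        if self.drop_constant:
            nunique = X.nunique(dropna=False)
            kept = [c for c in X.columns if nunique[c] > 1]
        else:
            kept = list(X.columns)
        self._kept_cols = kept
        self._blocks = {
            name: tuple(c for c in cols if c in set(kept))
            for name, cols in blocks.items()
        }
        digest = hashlib.sha1(("|".join([self.mode] + kept)).encode()).hexdigest()
        self._fingerprint = digest
        self._fitted = True
        return self

    def _impute(self, X: pd.DataFrame) -> pd.DataFrame:
        for col in self._pc_cols:
            values = X[col].to_numpy(dtype=float)
            mask = np.isnan(values)
            if mask.any():
                values[mask] = self._medians[col]
                X[col] = values
        return X

    def transform(self, records: pd.DataFrame) -> ModelTable:
        if not self._fitted:
            raise RuntimeError("TableBuilder.transform called before fit")
        X, _, joined = self._assemble(records)
        X = self._impute(X)
        X = X[self._kept_cols]
        if COL_VALUE in joined.columns and joined[COL_VALUE].notna().all():
            values = joined[COL_VALUE].astype(float)
            if (values <= 0).any():
                raise ValueError("non-positive endpoint value: log10 target undefined")
            y = np.log10(values.to_numpy())
        else:
            y = None
        return ModelTable(
            X=X,
            y=y,
            species=joined[COL_SPECIES].to_numpy(dtype=object),
            chemical=joined[COL_CHEMICAL].to_numpy(dtype=object),
            duration=joined[COL_DURATION_DAYS].to_numpy(dtype=float),
            blocks=dict(self._blocks),
            mode=self.mode,
            fingerprint=self._fingerprint,
        )

    def fit_transform(self, records: pd.DataFrame, chemicals: pd.DataFrame,
                      taxonomy: pd.DataFrame | None = None) -> ModelTable:
        return self.fit(records, chemicals, taxonomy).transform(records)


def build_model_table(records: pd.DataFrame, chemicals: pd.DataFrame,
                      taxonomy: pd.DataFrame | None = None,
                      mode: str = MODE_MULTI, **kwargs) -> ModelTable:
    """One-shot fit+transform convenience wrapper around :class:`TableBuilder`."""
    return TableBuilder(mode=mode, **kwargs).fit_transform(records, chemicals, taxonomy)
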