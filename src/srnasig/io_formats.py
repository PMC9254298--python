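"""Tabular input/output and validation.

All on-disk artifacts are plain tab-separated text (UTF-8, "." decimal):
a feature-by-sample count matrix, a feature annotation table, a sample
metadata table, differential-expression result tables, cross-validation
score tables and a JSON run summary.  Readers validate strictly and fail
loudly; in particular missing mandatory clinical covariates (age, sex,
BMI) are a hard error rather than being imputed, because every
differential-expression model adjusts for them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Canonical group labels, in fixed display order.
GROUPS = ("control", "T1D", "T2D", "LADA")

_GROUP_ALIASES = {g.lower(): g for g in GROUPS}

#: Recognised feature classes.  ``calibrator`` rows are synthetic spike-in
#: RNAs added in known amounts before library preparation; they carry
#: technical but not biological variation and are the basis of the
#: normalization factors.
FEATURE_CLASSES = (
    "mature_miRNA",
    "isomiR",
    "tRNA",
    "yRNA",
    "snRNA",
    "lncRNA",
    "antisense",
    "other",
    "calibrator",
)

MANDATORY_COVARIATES = ("age", "sex", "bmi")
SEXES = ("female", "male")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Non-negative integer feature x sample matrix.

    Parameters
    ----------
    counts
        DataFrame with feature ids as the index and sample ids as the
        columns.  Values must be non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        for name, labels in (("feature", idx), ("sample", cols)):
            dup = labels[labels.duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate {name} id: {dup[0]!r}")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValidationError("counts must be numeric")
            if np.any(~np.isfinite(values.astype(float))):
                raise ValidationError("counts contain non-finite values")
            neg = np.argwhere(values < 0)
            if len(neg):
                i, j = neg[0]
                raise ValidationError(
                    f"negative count at feature {idx[i]!r}, sample {cols[j]!r}"
                )
            frac = np.argwhere(values.astype(float) % 1 != 0)
            if len(frac):
                i, j = frac[0]
                raise ValidationError(
                    f"non-integer count at feature {idx[i]!r}, sample {cols[j]!r}"
                )
        self.counts = self.counts.astype(np.int64)

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_features(self, ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(ids)])

    def subset_samples(self, ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(ids)])


def validate_annotation(annotation: pd.DataFrame, counts: CountMatrix) -> pd.DataFrame:
    """Check a feature annotation table against a count matrix.

    The table is indexed by feature id and carries ``feature_class``,
    ``parent_id`` (the mature miRNA an isomiR belongs to) and
    ``fragment_length`` (nt, optional; needed for the tRNA-length
    covariate).
    """
    ann = annotation.copy()
    if ann.index.duplicated().any():
        dup = ann.index[ann.index.duplicated()][0]
        raise ValidationError(f"duplicate feature id in annotation: {dup!r}")
    missing = counts.feature_ids.difference(ann.index)
    if len(missing):
        raise ValidationError(f"annotation missing feature: {missing[0]!r}")
    ann = ann.reindex(counts.feature_ids)
    bad = set(ann["feature_class"]) - set(FEATURE_CLASSES)
    if bad:
        raise ValidationError(
            f"unknown feature class {sorted(bad)[0]!r}; allowed: {FEATURE_CLASSES}"
        )
    if "parent_id" not in ann.columns:
        ann["parent_id"] = pd.NA
    if "fragment_length" not in ann.columns:
        ann["fragment_length"] = np.nan
    is_iso = ann["feature_class"] == "isomiR"
    no_parent = is_iso & ann["parent_id"].isna()
    if no_parent.any():
        raise ValidationError(
            f"isomiR without parent_id: {ann.index[no_parent][0]!r}"
        )
    mature = set(ann.index[ann["feature_class"] == "mature_miRNA"])
    parents = ann.loc[is_iso, "parent_id"]
    orphan = parents[~parents.isin(mature)]
    if len(orphan):
        raise ValidationError(
            f"isomiR {orphan.index[0]!r} has parent {orphan.iloc[0]!r} "
            "which is not an annotated mature_miRNA"
        )
    fl = pd.to_numeric(ann["fragment_length"], errors="coerce")
    if ((fl <= 0) & fl.notna()).any():
        bad_id = ann.index[(fl <= 0) & fl.notna()][0]
        raise ValidationError(f"non-positive fragment_length for {bad_id!r}")
    ann["fragment_length"] = fl
    return ann


def normalize_group(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _GROUP_ALIASES:
        raise ValidationError(
            f"unknown group label {label!r}; allowed: {list(GROUPS)}"
        )
    return _GROUP_ALIASES[key]


def validate_samples(table: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Validate a sample metadata table (index: sample id).

    Mandatory columns: ``group``, ``age``, ``sex``, ``bmi``.  ``duration``
    (years since diagnosis) and any extra numeric covariates are optional.
    Group labels are normalized case-insensitively to the four canonical
    labels; a missing mandatory covariate is a hard error.
    """
    tab = table.copy()
    if tab.index.duplicated().any():
        dup = tab.index[tab.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id: {dup!r}")
    for col in ("group",) + MANDATORY_COVARIATES:
        if col not in tab.columns:
            raise ValidationError(f"sample table missing column {col!r}")
    tab["group"] = [normalize_group(g) for g in tab["group"]]
    sex = tab["sex"].astype(str).str.strip().str.lower()
    bad_sex = ~sex.isin(SEXES)
    if bad_sex.any():
        raise ValidationError(
            f"sample {tab.index[bad_sex][0]!r} has sex "
            f"{tab.loc[bad_sex, 'sex'].iloc[0]!r}; allowed: {SEXES}"
        )
    tab["sex"] = sex
    for col in ("age", "bmi"):
        vals = pd.to_numeric(tab[col], errors="coerce")
        if vals.isna().any():
            raise ValidationError(
                f"sample {tab.index[vals.isna()][0]!r} has missing or "
                f"non-numeric {col}"
            )
        if (vals <= 0).any():
            raise ValidationError(
                f"sample {tab.index[vals <= 0][0]!r} has non-positive {col}"
            )
        tab[col] = vals
    if "duration" in tab.columns:
        tab["duration"] = pd.to_numeric(tab["duration"], errors="coerce")
    if counts is not None:
        if set(tab.index) != set(counts.sample_ids):
            extra = set(tab.index) ^ set(counts.sample_ids)
            raise ValidationError(
                f"sample ids do not match count matrix (mismatch: {sorted(extra)[:3]})"
            )
        tab = tab.reindex(counts.sample_ids)
    return tab


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path, annotation_path) -> tuple[CountMatrix, pd.DataFrame]:
    """Read a count TSV plus its annotation TSV; returns validated objects."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    try:
        cm = CountMatrix(raw)
    except ValidationError:
        raise
    except (TypeError, ValueError) as exc:  # non-numeric cells
        raise ValidationError(f"count matrix {path}: {exc}") from exc
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype={0: str})
    ann = validate_annotation(ann, cm)
    return cm, ann


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def write_annotation(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    out.index.name = "feature_id"
    # keep fragment_length integral in the file where it is integral
    out.to_csv(path, sep="\t", float_format="%g")


def read_samples(path, counts: CountMatrix | None = None) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    return validate_samples(tab, counts)


def write_samples(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


DE_COLUMNS = ("logFC", "AveExpr", "t", "df_total", "p", "q")
CV_COLUMNS = ("label", "score", "fold_signature_size")


def write_de_results(de, path) -> None:
    """Write a differential-expression table (fixed column order)."""
    tab = de.table.copy()
    tab = tab.rename(
        columns={"log2fc": "logFC", "ave_expr": "AveExpr", "t_mod": "t"}
    )
    tab.index.name = "feature_id"
    tab[list(DE_COLUMNS)].to_csv(path, sep="\t", float_format="%.12g")


def read_de_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_cv_result(cv, tsv_path, json_path=None) -> None:
    """Write per-sample out-of-fold scores plus a JSON summary."""
    tab = cv.table.copy()
    tab.index.name = "sample_id"
    tab[list(CV_COLUMNS)].to_csv(tsv_path, sep="\t", float_format="%.12g")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(cv.summary(), fh, indent=2, sort_keys=True)


def read_config(path) -> dict:
    """Read a YAML run configuration (plain key-value mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} is not a mapping")
    return cfg
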