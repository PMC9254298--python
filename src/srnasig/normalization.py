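"""Spike-in calibrator normalization and expression transforms.

Scaling factors are estimated with the trimmed-mean-of-M-values (TMM)
procedure applied to the calibrator submatrix only, with calibrator
proportions taken relative to the *biological* library size (the column
sum over non-calibrator features).  Under that convention a sample whose
calibrators are over-represented per sequenced biological read — i.e. a
sample with low technical yield of biological RNA — receives a factor
below one, so effective library sizes track the amount of input RNA
rather than the number of sequenced reads.  That is precisely the
technical variation the spike-ins are added to control for.

The module also provides (log-)counts-per-million with the voom
convention (prior count 0.5, denominator ``lib + 1``), per-feature
z-scoring and group-mean summarisation used for heatmap displays.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import CountMatrix, ValidationError

logger = logging.getLogger(__name__)


def biological_library_size(cm: CountMatrix, annotation: pd.DataFrame) -> pd.Series:
    """Per-sample column sum over non-calibrator features."""
    keep = annotation.reindex(cm.feature_ids)["feature_class"] != "calibrator"
    return cm.counts.loc[keep.to_numpy()].sum(axis=0).astype(float)


def _tmm_pair(obs, ref, n_obs, n_ref, m_trim, a_trim):
    """Doubly trimmed, precision-weighted mean of M-values for one sample
    against the reference.  Mirrors the standard TMM recipe."""
    obs = obs.astype(float)
    ref = ref.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0:
        return 0.0
    if np.max(np.abs(log_r)) < 1e-6:
        return 0.0
    n = log_r.size
    lo_l = np.floor(n * m_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * a_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if keep.sum() < 2:
        logger.warning(
            "TMM trimming left <2 calibrators; falling back to untrimmed weighted mean"
        )
        keep = np.ones(n, dtype=bool)
    w = 1.0 / v[keep]
    return float(np.sum(w * log_r[keep]) / np.sum(w))


def calibrator_norm_factors(
    cm: CountMatrix,
    annotation: pd.DataFrame,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """TMM scaling factors computed on the calibrator submatrix.

    The reference sample is the column whose 75th percentile of
    calibrator proportions is closest to the mean across samples.
    Returned factors have geometric mean exactly 1; multiplying the
    biological library size by the factor gives the effective library
    size used everywhere downstream.
    """
    calib = annotation.index[annotation["feature_class"] == "calibrator"]
    if len(calib) < 2:
        raise ValidationError("need at least 2 calibrator features")
    if cm.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    C = cm.counts.loc[calib].to_numpy(float)
    lib = biological_library_size(cm, annotation).to_numpy()
    if np.any(lib <= 0):
        bad = cm.sample_ids[np.argmax(lib <= 0)]
        raise ValidationError(f"sample {bad!r} has zero biological library size")
    zero = C.sum(axis=0) == 0
    if zero.any():
        bad = cm.sample_ids[np.argmax(zero)]
        raise ValidationError(f"sample {bad!r} has all-zero calibrator counts")

    q75 = np.quantile(C / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    log_f = np.array([
        _tmm_pair(C[:, s], C[:, ref], lib[s], lib[ref], m_trim, a_trim)
        for s in range(C.shape[1])
    ])
    factors = 2.0 ** (log_f - log_f.mean())  # geometric mean 1
    return pd.Series(factors, index=cm.sample_ids, name="tmm_calibrator")


def cpm(
    counts: CountMatrix | pd.DataFrame,
    factors: pd.Series | None = None,
    lib_size: pd.Series | None = None,
    log: bool = False,
    prior: float | None = None,
) -> pd.DataFrame:
    """(Log2-)counts per million on effective library sizes.

    ``lib_size`` defaults to the column sums of the given matrix; pass
    the biological library size explicitly when the matrix is a feature
    subset.  The log transform is ``log2((count + prior) / (lib + 1) *
    1e6)`` with prior 0.5, exactly the transform the precision-weighting
    step builds on; the linear transform uses prior 0 by default.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if lib_size is None:
        lib_size = df.sum(axis=0).astype(float)
    lib = lib_size.reindex(df.columns).to_numpy(float)
    if factors is not None:
        lib = lib * factors.reindex(df.columns).to_numpy(float)
    if prior is None:
        prior = 0.5 if log else 0.0
    if prior < 0:
        raise ValidationError("prior must be >= 0")
    x = df.to_numpy(float)
    if log:
        out = np.log2((x + prior) / (lib + 1.0)[None, :] * 1e6)
    else:
        if np.any(lib <= 0):
            raise ValidationError("zero effective library size")
        out = (x + prior) / lib[None, :] * 1e6
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    res.attrs["scale"] = "log2cpm" if log else "cpm"
    return res


def zscore_rows(x: pd.DataFrame) -> pd.DataFrame:
    """Center each row and scale by its sample SD (n-1 denominator).

    Constant rows map to all-zero rows (not NaN) so that downstream
    heatmaps never propagate missing values.
    """
    if x.shape[1] < 2:
        raise ValidationError("z-scoring needs at least 2 samples")
    v = x.to_numpy(float)
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    out = np.where(sd > 0, (v - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    res = pd.DataFrame(out, index=x.index, columns=x.columns)
    res.attrs["scale"] = "zscore"
    return res


def group_means(x: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of each feature within each sample group."""
    groups = samples.reindex(x.columns)["group"]
    if groups.isna().any():
        missing = x.columns[groups.isna()][0]
        raise ValidationError(f"sample {missing!r} has no group assignment")
    present = [g for g in pd.unique(groups) if (groups == g).sum() > 0]
    cols = {g: x.loc[:, (groups == g).to_numpy()].mean(axis=1) for g in present}
    return pd.DataFrame(cols)
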