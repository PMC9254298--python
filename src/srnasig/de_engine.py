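"""Weighted linear-model differential expression with variance moderation.

The engine follows the voom + empirical-Bayes moderated-t workflow for
count data:

1. log2-cpm transform (prior 0.5, effective library sizes from the
   calibrator factors);
2. per-feature ordinary least squares on the design matrix, then a
   robust lowess fit (span 0.5) of the square-root residual standard
   deviation against mean log2 count — the mean-variance trend;
3. per-observation precision weights obtained by interpolating the trend
   at each observation's predicted log2 count and raising to the -4
   power (flat extrapolation outside the trend's support);
4. per-feature weighted least squares and empirical-Bayes shrinkage of
   the residual variances towards a common prior estimated by matching
   the first two moments of log s^2 (closed-form trigamma inversion),
   giving moderated t statistics with ``d0 + d_g`` degrees of freedom;
5. Benjamini-Hochberg step-up adjustment over the tested features.

Designs always contain an intercept and a treatment-coded group
indicator (second-named group = 1, so the reported log2 fold change is
second vs first), plus age, sex (female 0 / male 1) and BMI by default,
and optionally diabetes duration or the 30-33 nt fragment-length
abundance covariate used in the tRNA sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .io_formats import CountMatrix, ValidationError
from .normalization import biological_library_size, cpm

_DF_PRIOR_CAP = 1e7  # represents an infinite prior df


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class DesignMatrix:
    X: pd.DataFrame               # samples x coefficients
    contrast: str                 # name of the group-indicator column

    @property
    def sample_ids(self) -> pd.Index:
        return self.X.index


def _check_full_rank(X: pd.DataFrame) -> None:
    vals = X.to_numpy(float)
    for j, name in enumerate(X.columns):
        if name != "intercept" and np.ptp(vals[:, j]) == 0:
            raise ValidationError(f"design column {name!r} is constant")
    if np.linalg.matrix_rank(vals) < X.shape[1]:
        # name the first column that is linearly dependent on the ones before
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(vals[:, : j + 1]) < j + 1:
                raise ValidationError(
                    f"design column {X.columns[j]!r} is linearly dependent"
                )
        raise ValidationError("design matrix is rank deficient")


def build_design(
    samples: pd.DataFrame,
    comparison: tuple[str, str],
    covariates: tuple[str, ...] = (),
    extra: dict[str, pd.Series] | None = None,
) -> DesignMatrix:
    """Treatment-coded two-group design with additive covariates.

    The first-named group is the reference; the indicator column is 1
    for the second-named group.  ``extra`` supplies per-sample derived
    covariates (e.g. the fragment-length abundance) keyed by name.
    """
    group_a, group_b = comparison
    if group_a == group_b:
        raise ValidationError("comparison groups must differ")
    for g in comparison:
        if not (samples["group"] == g).any():
            raise ValidationError(f"group {g!r} has no samples")
    sel = samples[samples["group"].isin(comparison)]
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(sel)),
        f"group[{group_b}]": (sel["group"] == group_b).to_numpy(float),
    }
    extra = extra or {}
    for cov in covariates:
        if cov in extra:
            vals = extra[cov].reindex(sel.index)
        elif cov == "sex":
            vals = sel["sex"].map({"female": 0.0, "male": 1.0})
        elif cov in sel.columns:
            vals = pd.to_numeric(sel[cov], errors="coerce")
        else:
            raise ValidationError(f"unknown covariate {cov!r}")
        if vals.isna().any():
            bad = vals.index[vals.isna()][0]
            raise ValidationError(f"covariate {cov!r} missing for sample {bad!r}")
        cols[cov] = vals.to_numpy(float)
    X = pd.DataFrame(cols, index=sel.index)
    _check_full_rank(X)
    return DesignMatrix(X=X, contrast=f"group[{group_b}]")


def length_abundance_covariate(
    cm: CountMatrix,
    annotation: pd.DataFrame,
    length_range: tuple[int, int] = (30, 33),
) -> pd.Series:
    """log2(1 + total counts) of features with fragment length in the
    closed range, per sample.  Used to adjust tRNA-fragment contrasts for
    global length-composition differences between libraries."""
    lo, hi = length_range
    fl = annotation["fragment_length"]
    in_range = (fl >= lo) & (fl <= hi)
    if not in_range.any():
        raise ValidationError(
            f"no feature with fragment_length in [{lo}, {hi}]"
        )
    total = cm.counts.loc[in_range.index[in_range]].sum(axis=0)
    return np.log2(1.0 + total.astype(float)).rename(f"length{lo}_{hi}")


# ---------------------------------------------------------------------------
# expression filters


def filter_features(
    cm: CountMatrix,
    annotation: pd.DataFrame,
    factors: pd.Series,
    rule: str = "frac50",
    lib_size: pd.Series | None = None,
) -> CountMatrix:
    """Keep features with >= 1 cpm in all samples (``all_samples``, the
    mature-miRNA rule) or in at least half of them (``frac50``, the
    isomiR / other-sRNA rule).  Calibrators are always removed.  Both
    boundaries are inclusive.
    """
    if rule not in ("all_samples", "frac50"):
        raise ValidationError(f"unknown filter rule {rule!r}")
    ann = annotation.reindex(cm.feature_ids)
    biological = ann["feature_class"] != "calibrator"
    sub = cm.subset_features(cm.feature_ids[biological])
    if lib_size is None:
        lib_size = biological_library_size(cm, annotation)
    x = cpm(sub, factors=factors, lib_size=lib_size, log=False)
    frac = (x >= 1.0).mean(axis=1)
    threshold = 1.0 if rule == "all_samples" else 0.5
    keep = frac >= threshold
    if not keep.any():
        import logging

        logging.getLogger(__name__).warning(
            "expression filter %r removed every feature", rule
        )
    return CountMatrix(sub.counts.loc[keep])


# ---------------------------------------------------------------------------
# voom


@dataclass
class VoomFit:
    logcpm: pd.DataFrame          # features x samples, log2-cpm prior 0.5
    weights: np.ndarray           # features x samples, inverse-variance
    trend: tuple[np.ndarray, np.ndarray]  # (mean log2 count, sqrt-sd)


def voom(
    counts: CountMatrix,
    design: DesignMatrix,
    factors: pd.Series,
    lib_size: pd.Series | None = None,
    span: float = 0.5,
) -> VoomFit:
    """Estimate the mean-variance trend and per-observation weights."""
    X = design.X.to_numpy(float)
    sample_ids = design.sample_ids
    df = counts.counts[list(sample_ids)]
    n, p = X.shape
    if n - p < 1:
        raise ValidationError("voom needs positive residual degrees of freedom")
    if lib_size is None:
        lib_size = df.sum(axis=0).astype(float)
    lib = lib_size.reindex(sample_ids).to_numpy(float)
    fac = factors.reindex(sample_ids).to_numpy(float)
    eff = lib * fac

    y = np.log2((df.to_numpy(float) + 0.5) / (eff + 1.0)[None, :] * 1e6)

    # unweighted per-feature OLS, shared QR across features
    q, r = np.linalg.qr(X)
    coef = np.linalg.solve(r, q.T @ y.T)        # p x features
    fitted = X @ coef                           # n x features
    resid = y.T - fitted
    s = np.sqrt((resid ** 2).sum(axis=0) / (n - p))

    sx = y.mean(axis=1) + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    sy = np.sqrt(s)

    delta = 0.01 * (sx.max() - sx.min())
    trend = sm_lowess(sy, sx, frac=span, it=3, delta=delta, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    tx, uniq = np.unique(tx, return_index=True)
    ty = ty[uniq]

    # predicted log2 count per observation, then weight = trend^-4
    fitted_logcount = fitted + (np.log2(eff + 1.0) - np.log2(1e6))[:, None]
    w = np.interp(fitted_logcount.T, tx, ty) ** -4.0  # flat extrapolation
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValidationError("voom produced non-positive weights")

    logcpm = pd.DataFrame(y, index=df.index, columns=sample_ids)
    logcpm.attrs["scale"] = "log2cpm"
    return VoomFit(logcpm=logcpm, weights=w, trend=(tx, ty))


# ---------------------------------------------------------------------------
# moderated statistics


@dataclass
class DEResult:
    """Per-feature contrast estimates with moderated inference."""

    table: pd.DataFrame           # log2fc, ave_expr, t_mod, df_total, p, q
    s2_prior: float
    df_prior: float
    contrast: str = ""
    degenerate: bool = False      # all residual variances identical

    def significant(self, alpha: float = 0.05, adjusted: bool = True) -> pd.DataFrame:
        col = "q" if adjusted else "p"
        return self.table[self.table[col] < alpha]


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return _DF_PRIOR_CAP
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F distribution to the sample variances,
    returning (prior variance s0^2, prior df d0)."""
    s2 = np.maximum(s2, 0.0)
    med = np.median(s2)
    if med == 0:
        med = 1.0
    s2 = np.maximum(s2, 1e-5 * med)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = len(e)
    if n < 2:
        return float(np.exp(e_mean)), _DF_PRIOR_CAP
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var > 0:
        df_prior = 2.0 * _trigamma_inverse(e_var)
        df_prior = min(df_prior, _DF_PRIOR_CAP)
        s2_prior = np.exp(
            e_mean + digamma(df_prior / 2.0) - np.log(df_prior / 2.0)
        )
    else:
        # no excess spread in the variances beyond sampling noise:
        # infinite prior df, prior variance = mean sample variance
        df_prior = _DF_PRIOR_CAP
        s2_prior = float(np.mean(s2))
    return float(s2_prior), float(df_prior)


def fit_moderated(
    fit: VoomFit,
    design: DesignMatrix,
    contrast: str | None = None,
    df_prior_override: float | None = None,
    adjust: bool = True,
) -> DEResult:
    """Weighted least squares per feature plus empirical-Bayes moderation.

    ``df_prior_override`` forces the prior degrees of freedom (0 turns
    shrinkage off and recovers ordinary weighted t statistics; large
    values collapse every posterior variance onto the prior).
    """
    contrast = contrast or design.contrast
    X = design.X.to_numpy(float)
    names = list(design.X.columns)
    if contrast not in names:
        raise ValidationError(f"contrast {contrast!r} not in design columns {names}")
    j = names.index(contrast)
    Y = fit.logcpm[list(design.sample_ids)].to_numpy(float)  # features x n
    W = fit.weights
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom")

    # batched WLS: beta_g = (X' W_g X)^-1 X' W_g y_g
    xtwx = np.einsum("np,gn,nq->gpq", X, W, X)
    xtwy = np.einsum("np,gn,gn->gp", X, W, Y)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]   # features x p
    resid = Y - beta @ X.T
    s2 = np.einsum("gn,gn->g", W, resid ** 2) / df_resid
    cov_u = np.linalg.inv(xtwx)
    se_unit = np.sqrt(cov_u[:, j, j])                       # unscaled SE

    if df_prior_override is not None:
        df_prior = float(df_prior_override)
        s2_prior = float(np.exp(np.mean(np.log(np.maximum(s2, 1e-300)))))
        if df_prior > 0:
            s2_prior, _ = _fit_f_dist(s2, df_resid)
    else:
        s2_prior, df_prior = _fit_f_dist(s2, df_resid)
    degenerate = bool(np.allclose(s2, s2[0])) if len(s2) else False

    if df_prior >= _DF_PRIOR_CAP:
        s2_post = np.full_like(s2, s2_prior)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (df_prior * s2_prior + df_resid * s2) / (df_prior + df_resid)
        df_total = np.full_like(s2, df_resid + df_prior)
    # the moderated t cannot have more information than pooling every
    # feature's residual df, so cap the total df at that pooled value
    df_pooled = df_resid * len(s2)
    df_total = np.minimum(df_total, df_pooled)

    t_mod = beta[:, j] / (se_unit * np.sqrt(s2_post))
    pvals = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    table = pd.DataFrame(
        {
            "log2fc": beta[:, j],
            "ave_expr": Y.mean(axis=1),
            "t_mod": t_mod,
            "df_total": df_total,
            "s2_post": s2_post,
            "p": pvals,
            "q": bh_adjust(pvals) if adjust else np.nan,
        },
        index=fit.logcpm.index,
    )
    return DEResult(
        table=table,
        s2_prior=float(s2_prior),
        df_prior=float(df_prior),
        contrast=contrast,
        degenerate=degenerate,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# per-variable group screen (descriptive-table statistics)


def anova_screen(samples: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """One-way ANOVA of each clinical variable across the groups, with
    Bonferroni correction over the variables tested in the screen."""
    rows = []
    groups = samples["group"]
    for var in variables:
        vals = pd.to_numeric(samples[var], errors="coerce")
        chunks = [
            vals[groups == g].dropna().to_numpy()
            for g in pd.unique(groups)
        ]
        chunks = [c for c in chunks if len(c) >= 2]
        if len(chunks) < 2:
            raise ValidationError(f"variable {var!r}: need >= 2 groups with >= 2 samples")
        if all(np.ptp(c) == 0 for c in chunks):
            rows.append((var, np.nan, np.nan))
            continue
        f_stat, p = stats.f_oneway(*chunks)
        rows.append((var, float(f_stat), float(p)))
    out = pd.DataFrame(rows, columns=["variable", "F", "p"]).set_index("variable")
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(variables))
    return out


# ---------------------------------------------------------------------------
# convenience: full DE chain for one contrast


def run_de(
    cm: CountMatrix,
    annotation: pd.DataFrame,
    samples: pd.DataFrame,
    comparison: tuple[str, str],
    covariates: tuple[str, ...] = ("age", "sex", "bmi"),
    filter_rule: str = "frac50",
    factors: pd.Series | None = None,
    lib_size: pd.Series | None = None,
    extra: dict[str, pd.Series] | None = None,
) -> DEResult:
    """filter -> voom -> moderated t -> BH for a single group contrast."""
    from .normalization import calibrator_norm_factors

    if factors is None:
        factors = calibrator_norm_factors(cm, annotation)
    if lib_size is None:
        lib_size = biological_library_size(cm, annotation)
    design = build_design(samples, comparison, covariates, extra=extra)
    kept = filter_features(
        cm.subset_samples(design.sample_ids),
        annotation,
        factors,
        rule=filter_rule,
        lib_size=lib_size.reindex(design.sample_ids),
    )
    if kept.shape[0] == 0:
        raise ValidationError("expression filter removed every feature")
    fit = voom(kept, design, factors, lib_size=lib_size)
    return fit_moderated(fit, design)
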