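"""Cross-validated small-RNA signatures and ROC/AUC inference.

A signature is the set of features significant for one group contrast,
each carrying the sign of its training log2 fold change and its
training-set mean and SD on the log2-cpm scale.  A held-out sample is
scored by the direction-aligned standardised mean over the signature's
entries — a parameter-free rule that is monotone in every selected
feature and needs no tuning inside small training folds.

Validation is leave-one-out cross-validation with feature selection
nested inside every fold: the held-out sample never contributes to
filtering, model fitting or multiple-testing adjustment.  Normalization
factors are the exception by design — they are per-sample technical
quantities derived from the spike-in calibrators with no access to group
labels, so computing them once globally leaks nothing.

AUC uses the Mann-Whitney estimator (ties count one half), confidence
intervals come from the DeLong structural-components variance, and the
p-value against AUC = 0.5 is the one-sided normal approximation to the
Mann-Whitney U statistic with tie-corrected variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, ValidationError
from .normalization import biological_library_size, calibrator_norm_factors, cpm
from .de_engine import (
    DEResult,
    build_design,
    filter_features,
    fit_moderated,
    voom,
)


# ---------------------------------------------------------------------------
# signatures


@dataclass
class Signature:
    """Directed feature set with training-set standardisation parameters."""

    entries: pd.DataFrame         # index feature_id: direction, train_mean, train_sd
    contrast: str = ""
    alpha: float = 0.05

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def empty(self) -> bool:
        return len(self.entries) == 0


def build_signature(
    de: DEResult,
    train_logcpm: pd.DataFrame,
    alpha: float = 0.05,
    adjusted: bool = True,
) -> Signature:
    """Signature = features significant at ``alpha`` (BH-adjusted by
    default), directed by the sign of the training log2 fold change.
    Features with zero training SD are excluded; an empty signature is a
    legal value."""
    sig_rows = de.significant(alpha=alpha, adjusted=adjusted)
    ids = [f for f in sig_rows.index if f in train_logcpm.index]
    vals = train_logcpm.loc[ids]
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    direction = np.sign(sig_rows.loc[ids, "log2fc"])
    entries = pd.DataFrame(
        {"direction": direction, "train_mean": mean, "train_sd": sd}
    )
    # exclude effectively-constant features (sd at rounding-noise level)
    sd_floor = 1e-10 * (1.0 + entries["train_mean"].abs())
    entries = entries[(entries["train_sd"] > sd_floor) & (entries["direction"] != 0)]
    return Signature(entries=entries, contrast=de.contrast, alpha=alpha)


def score_sample(sig: Signature, sample_logcpm: pd.Series) -> float:
    """Direction-aligned standardised mean; empty signature scores 0."""
    if sig.empty:
        return 0.0
    missing = sig.entries.index.difference(sample_logcpm.index)
    if len(missing):
        raise ValidationError(f"sample is missing feature {missing[0]!r}")
    vals = sample_logcpm.reindex(sig.entries.index).to_numpy(float)
    z = (vals - sig.entries["train_mean"].to_numpy()) / sig.entries["train_sd"].to_numpy()
    return float(np.mean(sig.entries["direction"].to_numpy() * z))


# ---------------------------------------------------------------------------
# ROC / AUC


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels differ in length")
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be present")
    return pos, neg


def roc_curve(scores, labels) -> pd.DataFrame:
    """Staircase ROC with thresholds at every distinct score (ties
    grouped), anchored at (0, 0) and (1, 1).  Higher scores predict the
    positive class."""
    pos, neg = _split(scores, labels)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tp = np.cumsum(l_sorted)
    fp = np.cumsum(~l_sorted)
    # keep the last index of each tie block
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / len(pos)]
    fpr = np.r_[0.0, fp[distinct] / len(neg)]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(positive > negative) + 0.5 P(tie)."""
    pos, neg = _split(scores, labels)
    scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(scores)
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_ci_delong(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Wald interval on the AUC using the DeLong structural-components
    variance, truncated to [0, 1].  Perfect separation gives the
    degenerate interval (auc, auc)."""
    pos, neg = _split(scores, labels)
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("DeLong CI needs >= 2 samples per class")
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    a = psi.mean()
    v10 = psi.mean(axis=1)          # one component per positive
    v01 = psi.mean(axis=0)          # one component per negative
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    if var <= 0:
        return (float(a), float(a))
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return (float(max(0.0, a - half)), float(min(1.0, a + half)))


def auc_pvalue_mw(scores, labels) -> float:
    """One-sided p-value for H0: AUC = 0.5 against AUC > 0.5, from the
    normal approximation to Mann-Whitney U with tie-corrected variance."""
    pos, neg = _split(scores, labels)
    n1, n2 = len(pos), len(neg)
    n = n1 + n2
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(all_scores, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return 0.5
    z = (u - mean_u) / np.sqrt(var_u)
    return float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# leave-one-out cross-validation


@dataclass
class CVResult:
    """Out-of-fold scores and the ROC summary of one signature contrast."""

    table: pd.DataFrame           # index sample_id: label, score, fold_signature_size
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pos: int
    n_neg: int
    n_empty: int                  # folds with an empty signature (scored 0)
    settings: dict = field(default_factory=dict)
    seed: int | None = None

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_folds": int(len(self.table)),
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "n_empty_signatures": self.n_empty,
            "settings": self.settings,
            "seed": self.seed,
        }


def _assemble_cv(samples_sel, group_b, scores, sizes, n_empty, settings, seed):
    labels = (samples_sel["group"] == group_b).to_numpy()
    table = pd.DataFrame(
        {
            "label": samples_sel["group"].to_numpy(),
            "score": scores,
            "fold_signature_size": sizes,
        },
        index=samples_sel.index,
    )
    a = auc(scores, labels)
    lo, hi = auc_ci_delong(scores, labels)
    p = auc_pvalue_mw(scores, labels)
    return CVResult(
        table=table,
        auc=a,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
        n_empty=n_empty,
        settings=settings,
        seed=seed,
    )


def loocv(
    cm: CountMatrix,
    annotation: pd.DataFrame,
    samples: pd.DataFrame,
    comparison: tuple[str, str],
    covariates: tuple[str, ...] = ("age", "sex", "bmi"),
    filter_rule: str = "frac50",
    alpha: float = 0.05,
    adjusted: bool = True,
    nested: bool = True,
    factors: pd.Series | None = None,
    lib_size: pd.Series | None = None,
    extra: dict[str, pd.Series] | None = None,
    seed: int | None = None,
) -> CVResult:
    """Leave-one-out cross-validation of a signature for one contrast.

    With ``nested=True`` (the default and the statistically valid mode)
    the expression filter, the weighted fit, the BH adjustment and the
    signature standardisation are all recomputed on each fold's training
    samples.  ``nested=False`` selects the signature once on *all*
    samples and is provided only to demonstrate the optimistic bias that
    nesting avoids.
    """
    group_a, group_b = comparison
    sel = samples[samples["group"].isin(comparison)]
    if (sel["group"] == group_a).sum() < 2 or (sel["group"] == group_b).sum() < 2:
        raise ValidationError("each compared group needs >= 2 samples")
    if factors is None:
        factors = calibrator_norm_factors(cm, annotation)
    if lib_size is None:
        lib_size = biological_library_size(cm, annotation)
    # per-sample log2-cpm with globally determined technical factors; the
    # value for one sample depends only on that sample's own column
    biological = annotation.reindex(cm.feature_ids)["feature_class"] != "calibrator"
    logcpm_all = cpm(
        cm.counts.loc[biological.to_numpy()],
        factors=factors,
        lib_size=lib_size,
        log=True,
    )

    settings = {
        "comparison": list(comparison),
        "covariates": list(covariates),
        "filter_rule": filter_rule,
        "alpha": alpha,
        "adjusted": adjusted,
        "nested": nested,
    }

    def _fit_de(train_ids) -> tuple[DEResult, pd.Index]:
        sub_samples = samples.loc[train_ids]
        design = build_design(sub_samples, comparison, covariates, extra=extra)
        kept = filter_features(
            cm.subset_samples(train_ids),
            annotation,
            factors,
            rule=filter_rule,
            lib_size=lib_size.reindex(train_ids),
        )
        if kept.shape[0] == 0:
            return None, kept.feature_ids
        fit = voom(kept, design, factors, lib_size=lib_size)
        return fit_moderated(fit, design), kept.feature_ids

    scores = np.zeros(len(sel))
    sizes = np.zeros(len(sel), dtype=int)
    n_empty = 0

    if nested:
        for i, held_out in enumerate(sel.index):
            train_ids = sel.index.drop(held_out)
            if (samples.loc[train_ids, "group"] == group_a).sum() == 0 or (
                samples.loc[train_ids, "group"] == group_b
            ).sum() == 0:
                raise ValidationError("a training fold lost one group entirely")
            de, _ = _fit_de(train_ids)
            if de is None:
                sig = Signature(entries=pd.DataFrame(
                    columns=["direction", "train_mean", "train_sd"]))
            else:
                sig = build_signature(
                    de, logcpm_all[list(train_ids)], alpha=alpha, adjusted=adjusted
                )
            if sig.empty:
                n_empty += 1
            scores[i] = score_sample(sig, logcpm_all[held_out])
            sizes[i] = len(sig)
    else:
        de, _ = _fit_de(sel.index)
        if de is None:
            sig = Signature(entries=pd.DataFrame(
                columns=["direction", "train_mean", "train_sd"]))
        else:
            sig = build_signature(
                de, logcpm_all[list(sel.index)], alpha=alpha, adjusted=adjusted
            )
        n_empty = int(sig.empty) * len(sel)
        for i, s in enumerate(sel.index):
            scores[i] = score_sample(sig, logcpm_all[s])
            sizes[i] = len(sig)

    return _assemble_cv(sel, group_b, scores, sizes, n_empty, settings, seed)
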