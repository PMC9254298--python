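"""End-to-end orchestration: normalize -> filter -> DE -> signatures ->
LOOCV, per pairwise group contrast and per feature class, plus
simulation-based power estimation.

Feature classes are analysed separately with their own expression
filters: mature miRNAs require >= 1 cpm in every sample, while isomiRs
and the remaining small-RNA classes (tRNA, yRNA, snRNA, lncRNA,
antisense, other), being intrinsically less abundant, require >= 1 cpm
in at least half of the samples.  Library sizes and calibrator factors
are computed once from the full biological matrix and shared across
classes.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GROUPS,
    CountMatrix,
    ValidationError,
    normalize_group,
    read_counts,
    read_samples,
    write_cv_result,
    write_de_results,
)
from .normalization import biological_library_size, calibrator_norm_factors
from .de_engine import bh_adjust, build_design, filter_features, fit_moderated, voom
from .signature_cv import loocv
from .synthetic_data import SimParams, generate_dataset

logger = logging.getLogger(__name__)

OTHER_CLASSES = ("tRNA", "yRNA", "snRNA", "lncRNA", "antisense", "other")

#: per-class expression filter rules
CLASS_RULES = {
    "mature_miRNA": "all_samples",
    "isomiR": "frac50",
    "other_sRNA": "frac50",
}


def default_comparisons() -> list[tuple[str, str]]:
    """The six pairwise contrasts among control, T1D, T2D and LADA."""
    return list(itertools.combinations(GROUPS, 2))


@dataclass
class RunConfig:
    counts_path: str | None = None
    annotation_path: str | None = None
    samples_path: str | None = None
    sim: SimParams | None = None
    comparisons: list[tuple[str, str]] = field(default_factory=default_comparisons)
    covariates: tuple[str, ...] = ("age", "sex", "bmi")
    alpha: float = 0.05
    auc_threshold: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        self.comparisons = [
            (normalize_group(a), normalize_group(b)) for a, b in self.comparisons
        ]


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        cm, ann, samples, truth = generate_dataset(config.sim)
        return cm, ann, samples
    if not (config.counts_path and config.annotation_path and config.samples_path):
        raise ValidationError("config needs either simulation parameters or input paths")
    cm, ann = read_counts(config.counts_path, config.annotation_path)
    samples = read_samples(config.samples_path, cm)
    return cm, ann, samples


def _class_subsets(cm: CountMatrix, annotation: pd.DataFrame):
    cls = annotation["feature_class"]
    yield "mature_miRNA", cm.subset_features(cls.index[cls == "mature_miRNA"])
    yield "isomiR", cm.subset_features(cls.index[cls == "isomiR"])
    yield "other_sRNA", cm.subset_features(cls.index[cls.isin(OTHER_CLASSES)])


def run_full(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run every contrast x feature class; returns the report bundle.

    The report maps ``(comparison, class)`` to the DE table, the number
    of significant features and the LOOCV result, plus a summary table of
    signatures passing the AUC threshold.
    """
    cm, annotation, samples = _load_inputs(config)
    factors = calibrator_norm_factors(cm, annotation)
    lib_size = biological_library_size(cm, annotation)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    results = {}
    summary_rows = []
    for comparison in config.comparisons:
        comp_label = f"{comparison[0]}_vs_{comparison[1]}"
        for cls_name, sub in _class_subsets(cm, annotation):
            stage = f"{comp_label}/{cls_name}"
            rule = CLASS_RULES[cls_name]
            try:
                design = build_design(samples, comparison, config.covariates)
                kept = filter_features(
                    sub.subset_samples(design.sample_ids),
                    annotation,
                    factors,
                    rule=rule,
                    lib_size=lib_size.reindex(design.sample_ids),
                )
                logger.info(
                    "stage=%s features_in=%d features_kept=%d",
                    stage, sub.shape[0], kept.shape[0],
                )
                if kept.shape[0] < 10:
                    logger.warning("stage=%s too few features after filter; skipped", stage)
                    continue
                fit = voom(kept, design, factors, lib_size=lib_size)
                de = fit_moderated(fit, design)
                n_sig = int((de.table["q"] < config.alpha).sum())
                cv = loocv(
                    sub,
                    annotation,
                    samples,
                    comparison,
                    covariates=config.covariates,
                    filter_rule=rule,
                    alpha=config.alpha,
                    factors=factors,
                    lib_size=lib_size,
                    seed=config.seed,
                )
            except ValidationError as exc:
                raise ValidationError(f"stage {stage}: {exc}") from exc
            results[(comp_label, cls_name)] = {"de": de, "cv": cv, "n_significant": n_sig}
            summary_rows.append({
                "comparison": comp_label,
                "feature_class": cls_name,
                "n_significant": n_sig,
                "auc": cv.auc,
                "ci_low": cv.ci_low,
                "ci_high": cv.ci_high,
                "p_value": cv.p_value,
                "passes_threshold": bool(cv.auc > config.auc_threshold),
            })
            if out is not None:
                write_de_results(de, out / f"de_{comp_label}_{cls_name}.tsv")
                write_cv_result(
                    cv,
                    out / f"cv_{comp_label}_{cls_name}.tsv",
                    out / f"cv_{comp_label}_{cls_name}.json",
                )

    summary = pd.DataFrame(summary_rows)
    report = {
        "summary": summary,
        "results": results,
        "settings": {
            "comparisons": [list(c) for c in config.comparisons],
            "covariates": list(config.covariates),
            "alpha": config.alpha,
            "auc_threshold": config.auc_threshold,
            "seed": config.seed,
        },
        "norm_factors": factors,
    }
    if out is not None:
        summary.to_csv(out / "signatures_summary.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(
                {
                    "settings": report["settings"],
                    "signatures": summary.to_dict(orient="records"),
                },
                fh, indent=2, sort_keys=True,
            )
    return report


# ---------------------------------------------------------------------------
# power by simulation


def power_by_simulation(
    params: SimParams,
    n_grid: list[int],
    logfc_grid: list[float],
    replicates: int = 20,
    alpha: float = 0.05,
    comparison: tuple[str, str] | None = None,
    filter_rule: str = "frac50",
) -> pd.DataFrame:
    """Fraction of truly differential features detected at BH q < alpha,
    estimated by running the simulator and the DE engine end to end.

    Power is averaged over replicates; features removed by the
    expression filter count as missed.  Requires ``frac_de > 0``.
    """
    if params.frac_de <= 0:
        raise ValidationError("power is undefined with frac_de = 0")
    if replicates < 2:
        raise ValidationError("need >= 2 replicates for a Monte-Carlo SE")
    if comparison is None:
        ref = next(g for g in GROUPS if g != params.de_group)
        comparison = (ref, params.de_group)
    contrast_label = f"{comparison[0]}:{comparison[1]}"

    ss = np.random.SeedSequence(params.seed)
    # one seed per replicate, shared across all grid cells so that power
    # comparisons across (n, logfc) use common random numbers
    rep_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(replicates)]
    rows = []
    for n in n_grid:
        for lfc in logfc_grid:
            powers = []
            for rep in range(replicates):
                child = rep_seeds[rep]
                p = SimParams(**{**params.__dict__, "seed": child,
                                 "n_per_group": int(n), "logfc": float(lfc)})
                cm, ann, samples, truth = generate_dataset(p)
                factors = calibrator_norm_factors(cm, ann)
                lib = biological_library_size(cm, ann)
                design = build_design(samples, comparison, ("age", "sex", "bmi"))
                kept = filter_features(
                    cm.subset_samples(design.sample_ids), ann, factors,
                    rule=filter_rule, lib_size=lib.reindex(design.sample_ids),
                )
                fit = voom(kept, design, factors, lib_size=lib)
                de = fit_moderated(fit, design)
                if alpha <= 0:
                    detected = pd.Index([])
                else:
                    detected = de.table.index[de.table["q"] < alpha]
                tr = truth[(truth["contrast"] == contrast_label) & truth["is_de"]]
                n_true = len(tr)
                if n_true == 0:
                    raise ValidationError("no true positives in this replicate")
                powers.append(len(set(detected) & set(tr["feature_id"])) / n_true)
            powers = np.asarray(powers)
            rows.append({
                "n_per_group": int(n),
                "logfc": float(lfc),
                "alpha": alpha,
                "replicates": replicates,
                "power": float(powers.mean()),
                "mc_se": float(powers.std(ddof=1) / np.sqrt(replicates)),
            })
    return pd.DataFrame(rows)
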