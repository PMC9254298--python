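"""Synthetic serum sRNA-seq data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* four clinical groups (non-diabetic controls, adult-onset type 1
  diabetes, type 2 diabetes, LADA) with ``n_per_group`` samples each;
* negative-binomial counts (variance ``mu + phi * mu**2``, edgeR-style
  common dispersion) over isomiRs, tRNA fragments and other small RNAs,
  with per-sample sequencing-depth variation;
* mature miRNAs defined as the exact per-sample sum of their isomiRs
  (isomiRs are the primitive unit);
* ten spike-in calibrator RNAs whose expected counts track the input RNA
  amount but *not* the per-sample technical yield factor that multiplies
  all biological features — this is what makes calibrator-based
  normalization identifiable and testable;
* sparse group effects of a configurable log2 fold change assigned to a
  designated group, recorded feature-by-feature in a truth table;
* optional per-covariate expression effects (age/sex/BMI), which combine
  with the group-specific clinical distributions to create genuine
  confounding when switched on.

Clinical covariates are drawn from group-specific normal distributions
whose means and spreads match a serum cohort of adults with diabetes
(controls younger and leaner on average than the type 2 group, roughly
half of each group male, diabetes duration present only for the diabetes
groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import GROUPS, CountMatrix, ValidationError, validate_annotation, validate_samples

# group-specific clinical distributions: (age mean, age sd), male fraction,
# (bmi mean, bmi sd), (log duration mean, sd) or None for controls
_CLINICAL = {
    "control": ((52.8, 15.7), 0.47, (27.9, 4.2), None),
    "T2D": ((63.7, 11.2), 0.56, (30.6, 4.8), (1.8, 0.6)),
    "LADA": ((67.9, 9.3), 0.53, (29.0, 4.5), (2.3, 0.7)),
    "T1D": ((59.8, 11.8), 0.55, (27.4, 3.6), (2.4, 0.7)),
}


@dataclass
class SimParams:
    """Parameters of the synthetic cohort.

    ``logfc`` is the magnitude of true group effects in log2 units
    (default log2(1.5), the minimum fold change used in the study's power
    calculation).  ``dispersion`` is the biological negative-binomial
    dispersion phi; calibrators use the separate, much smaller
    ``calib_dispersion`` because spike-in variation is technical only.
    ``tech_sd`` is the standard deviation of the per-sample log2
    technical yield factor applied to biological features (calibrators
    deliberately do not carry it).  ``covariate_effects`` maps a
    covariate name (``age``, ``bmi`` or ``sex``) to a log2 effect per
    unit of the (centred) covariate, applied to a random
    ``covariate_frac`` subset of features.
    """

    seed: int = 0
    n_per_group: int = 50
    n_mature: int = 98
    isomirs_per_mirna: int = 2
    n_other: int = 296
    n_calibrators: int = 10
    frac_de: float = 0.0
    logfc: float = 0.5849625007211562  # log2(1.5)
    de_group: str = "T2D"
    dispersion: float = 0.1
    calib_dispersion: float = 0.005
    depth_mean: float = 2e6
    depth_cv: float = 0.3
    calib_frac: float = 0.02
    tech_sd: float = 0.3
    covariate_effects: dict = field(default_factory=dict)
    covariate_frac: float = 0.1

    def validate(self) -> None:
        if not 0 <= self.frac_de <= 1:
            raise ValidationError("frac_de must lie in [0, 1]")
        if self.dispersion < 0 or self.calib_dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.depth_mean <= 0:
            raise ValidationError("depth_mean must be > 0")
        if self.n_per_group < 3:
            raise ValidationError("n_per_group must be >= 3")
        if self.isomirs_per_mirna < 1:
            raise ValidationError("isomirs_per_mirna must be >= 1")
        if self.de_group not in GROUPS:
            raise ValidationError(f"de_group must be one of {GROUPS}")
        if not 0 < self.calib_frac < 1:
            raise ValidationError("calib_frac must lie in (0, 1)")


def _rnbinom(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + phi*mu^2."""
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _pairwise_contrasts() -> list[tuple[str, str]]:
    out = []
    for i, a in enumerate(GROUPS):
        for b in GROUPS[i + 1:]:
            out.append((a, b))
    return out


def generate_dataset(params: SimParams):
    """Simulate one cohort.

    Returns ``(CountMatrix, annotation, samples, truth)`` where ``truth``
    has one row per non-calibrator feature per pairwise contrast with the
    true log2 fold change (second-named group minus first) and an
    ``is_de`` flag.  The same seed always returns bit-identical output.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)

    # --- sample metadata -------------------------------------------------
    rows = []
    short = {"control": "ctrl", "T1D": "t1d", "T2D": "t2d", "LADA": "lada"}
    for g in GROUPS:
        (age_m, age_s), male_frac, (bmi_m, bmi_s), dur = _CLINICAL[g]
        for i in range(p.n_per_group):
            age = float(np.clip(rng.normal(age_m, age_s), 30.0, 90.0))
            sex = "male" if rng.random() < male_frac else "female"
            bmi = float(np.clip(rng.normal(bmi_m, bmi_s), 17.0, 50.0))
            duration = np.nan if dur is None else float(np.exp(rng.normal(*dur)))
            rows.append((f"{short[g]}_{i + 1:02d}", g, age, sex, bmi, duration))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "group", "age", "sex", "bmi", "duration"]
    ).set_index("sample_id")
    n_samples = len(samples)

    # --- feature layout --------------------------------------------------
    mature_ids = [f"miR-{i + 1}" for i in range(p.n_mature)]
    isomir_ids, isomir_parent = [], []
    for m in mature_ids:
        for k in range(p.isomirs_per_mirna):
            isomir_ids.append(f"{m}.iso{k + 1}")
            isomir_parent.append(m)
    n_trna = p.n_other // 2
    other_classes = ["tRNA"] * n_trna
    pool = ["yRNA", "snRNA", "lncRNA", "antisense", "other"]
    for i in range(p.n_other - n_trna):
        other_classes.append(pool[i % len(pool)])
    other_ids = [f"{cls}-{i + 1}" for i, cls in enumerate(other_classes)]
    calib_ids = [f"cal-{i + 1}" for i in range(p.n_calibrators)]

    ann_rows = []
    for m in mature_ids:
        ann_rows.append((m, "mature_miRNA", pd.NA, np.nan))
    for fid, par in zip(isomir_ids, isomir_parent):
        ann_rows.append((fid, "isomiR", par, np.nan))
    for fid, cls in zip(other_ids, other_classes):
        length = float(rng.integers(28, 37)) if cls == "tRNA" else np.nan
        ann_rows.append((fid, cls, pd.NA, length))
    for fid in calib_ids:
        ann_rows.append((fid, "calibrator", pd.NA, np.nan))
    annotation = pd.DataFrame(
        ann_rows, columns=["feature_id", "feature_class", "parent_id", "fragment_length"]
    ).set_index("feature_id")

    # primitive biological features: isomiRs + other sRNAs
    prim_ids = isomir_ids + other_ids
    n_prim = len(prim_ids)

    # long-tailed baseline abundances; isomiRs on average more abundant
    base_log2 = np.concatenate([
        rng.normal(1.0, 2.0, size=len(isomir_ids)),
        rng.normal(0.0, 2.0, size=len(other_ids)),
    ])
    prop = 2.0 ** base_log2
    prop /= prop.sum()

    # --- ground-truth group effects --------------------------------------
    # effects are assigned per "unit": a mature miRNA (shared by all of its
    # isomiRs, so the derived sum carries the same fold change) or a single
    # other sRNA, all targeting de_group vs every other group
    n_de_mature = int(round(p.frac_de * p.n_mature))
    n_de_other = int(round(p.frac_de * p.n_other))
    de_mature = list(rng.choice(p.n_mature, size=n_de_mature, replace=False))
    de_other = list(rng.choice(p.n_other, size=n_de_other, replace=False))
    unit_sign_mature = rng.choice([-1.0, 1.0], size=n_de_mature)
    unit_sign_other = rng.choice([-1.0, 1.0], size=n_de_other)

    # per-feature log2 offset in de_group (0 elsewhere)
    de_offset = np.zeros(n_prim)
    mature_offset = np.zeros(p.n_mature)
    for j, s in zip(de_mature, unit_sign_mature):
        mature_offset[j] = s * p.logfc
        for k in range(p.isomirs_per_mirna):
            de_offset[j * p.isomirs_per_mirna + k] = s * p.logfc
    for j, s in zip(de_other, unit_sign_other):
        de_offset[len(isomir_ids) + j] = s * p.logfc

    # --- covariate expression effects ------------------------------------
    cov_log2 = np.zeros((n_prim, n_samples))
    cov_features: dict[str, list[str]] = {}
    for name, beta in p.covariate_effects.items():
        if name == "sex":
            x = (samples["sex"] == "male").to_numpy(float)
        else:
            x = samples[name].to_numpy(float)
        x = x - x.mean()
        hit = rng.choice(n_prim, size=int(round(p.covariate_frac * n_prim)), replace=False)
        load = np.zeros(n_prim)
        load[hit] = beta
        cov_log2 += np.outer(load, x)
        cov_features[name] = [prim_ids[i] for i in sorted(hit)]

    # --- per-sample depth and technical yield ----------------------------
    sigma = np.sqrt(np.log1p(p.depth_cv ** 2))
    depth = p.depth_mean * np.exp(rng.normal(-0.5 * sigma ** 2, sigma, n_samples))
    tech = 2.0 ** rng.normal(0.0, p.tech_sd, n_samples)

    group_idx = samples["group"].to_numpy() == p.de_group

    # --- biological counts -----------------------------------------------
    log2_mu = (
        np.log2(prop)[:, None]
        + np.outer(de_offset, group_idx.astype(float))
        + cov_log2
        + np.log2(depth * (1.0 - p.calib_frac) * tech)[None, :]
    )
    mu = 2.0 ** log2_mu
    prim_counts = _rnbinom(rng, mu, p.dispersion)

    iso_counts = prim_counts[: len(isomir_ids)]
    other_counts = prim_counts[len(isomir_ids):]
    mature_counts = iso_counts.reshape(p.n_mature, p.isomirs_per_mirna, n_samples).sum(axis=1)

    # --- calibrator counts: track depth, NOT the technical factor --------
    conc = 2.0 ** np.linspace(-2.5, 2.5, p.n_calibrators)
    conc /= conc.sum()
    calib_mu = np.outer(conc, depth * p.calib_frac)
    calib_counts = _rnbinom(rng, calib_mu, p.calib_dispersion)

    counts = pd.DataFrame(
        np.vstack([mature_counts, iso_counts, other_counts, calib_counts]),
        index=mature_ids + isomir_ids + other_ids + calib_ids,
        columns=samples.index,
    )
    cm = CountMatrix(counts)
    annotation = validate_annotation(annotation, cm)
    samples = validate_samples(samples, cm)

    # --- truth table ------------------------------------------------------
    feat_offset = pd.Series(
        np.concatenate([mature_offset, de_offset]),
        index=mature_ids + prim_ids,
    )
    truth_rows = []
    for ga, gb in _pairwise_contrasts():
        eff = feat_offset * (float(gb == p.de_group) - float(ga == p.de_group))
        for fid, lfc in eff.items():
            truth_rows.append((fid, f"{ga}:{gb}", lfc, lfc != 0.0))
    truth = pd.DataFrame(
        truth_rows, columns=["feature_id", "contrast", "true_log2fc", "is_de"]
    )
    truth.attrs["covariate_features"] = cov_features

    # per-sample technical truth, useful for normalization tests
    samples = samples.copy()
    samples.attrs["true_log2_tech"] = pd.Series(np.log2(tech), index=samples.index)
    samples.attrs["true_depth"] = pd.Series(depth, index=samples.index)

    return cm, annotation, samples, truth


_FIXTURES = {
    "small": dict(
        seed=42, n_per_group=5, n_mature=10, isomirs_per_mirna=2,
        n_other=20, n_calibrators=10, frac_de=0.1, logfc=2.0,
    ),
    "medium": dict(
        seed=7, n_per_group=50, n_mature=98, isomirs_per_mirna=2,
        n_other=296, n_calibrators=10, frac_de=0.05, logfc=1.5,
    ),
}


def make_fixture(name: str, **overrides):
    """Canned fixed-seed datasets used throughout the test suite.

    ``small`` is 60 features x 20 samples (5 per group), ``medium`` is
    600 features x 200 samples (50 per group, the study's design size).
    """
    if name not in _FIXTURES:
        raise ValidationError(f"unknown fixture {name!r}; use one of {sorted(_FIXTURES)}")
    kw = dict(_FIXTURES[name])
    kw.update(overrides)
    return generate_dataset(SimParams(**kw))
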