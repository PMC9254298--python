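import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from srnasig import (
    CountMatrix,
    SimParams,
    ValidationError,
    anova_screen,
    bh_adjust,
    build_design,
    filter_features,
    fit_moderated,
    generate_dataset,
    length_abundance_covariate,
    voom,
)
from srnasig.de_engine import DesignMatrix, VoomFit


# ---------------------------------------------------------------------------
# expression filters


def _filter_fixture(cpm_values):
    """One target feature with exact cpm values plus a filler feature
    bringing every biological library size to 1e7."""
    counts = np.asarray([[int(v * 10) for v in cpm_values]])
    filler = (10_000_000 - counts.sum(axis=0))[None, :]
    df = pd.DataFrame(
        np.vstack([counts, filler]),
        index=["target", "filler"],
        columns=[f"S{i}" for i in range(len(cpm_values))],
    )
    ann = pd.DataFrame({"feature_class": ["other", "other"]}, index=df.index)
    ones = pd.Series(1.0, index=df.columns)
    return CountMatrix(df), ann, ones


@pytest.mark.parametrize(
    "cpm_values,rule,kept",
    [
        ((1.2, 1.5, 0.8, 2.0), "all_samples", False),
        ((1.0, 1.5, 0.8, 0.9), "frac50", True),   # 2/4 = 50%, boundary inclusive
        ((1.0, 1.0, 1.0, 1.0), "all_samples", True),  # exactly 1 cpm everywhere
        ((0.0, 0.0, 0.0, 0.0), "all_samples", False),
        ((0.0, 0.0, 0.0, 0.0), "frac50", False),
    ],
)
def test_cpm_filter_boundaries(cpm_values, rule, kept):
    cm, ann, ones = _filter_fixture(cpm_values)
    out = filter_features(cm, ann, ones, rule=rule)
    assert ("target" in out.feature_ids) == kept


def test_filter_always_removes_calibrators(small):
    cm, ann, _, _ = small
    ones = pd.Series(1.0, index=cm.sample_ids)
    out = filter_features(cm, ann, ones, rule="frac50")
    calib = ann.index[ann["feature_class"] == "calibrator"]
    assert len(out.feature_ids.intersection(calib)) == 0


# ---------------------------------------------------------------------------
# design matrices


def _four_samples():
    return pd.DataFrame(
        {
            "group": ["control", "control", "T2D", "T2D"],
            "age": [50.0, 60.0, 55.0, 65.0],
            "sex": ["male", "female", "female", "male"],
            "bmi": [25.0, 28.0, 31.0, 27.0],
            "duration": [np.nan, np.nan, 4.0, np.nan],
        },
        index=["s1", "s2", "s3", "s4"],
    )


def test_two_group_design_shape_and_coding():
    d = build_design(_four_samples(), ("control", "T2D"))
    assert d.X.shape == (4, 2)
    np.testing.assert_array_equal(
        d.X.to_numpy(), [[1, 0], [1, 0], [1, 1], [1, 1]]
    )
    assert d.contrast == "group[T2D]"


def test_design_with_clinical_covariates():
    samples, _ = _design_two_groups(6)
    samples["bmi"] = [25.0, 28.0, 31.0, 27.0, 24.0, 29.5]
    d = build_design(samples, ("control", "T2D"), ("age", "sex", "bmi"))
    assert d.X.shape == (6, 5)
    assert list(d.X.columns) == ["intercept", "group[T2D]", "age", "sex", "bmi"]
    np.testing.assert_array_equal(
        d.X["sex"], (samples["sex"] == "male").astype(float)
    )
    assert np.linalg.matrix_rank(d.X.to_numpy()) == 5


def test_missing_duration_covariate_is_error():
    with pytest.raises(ValidationError, match="duration.*s1"):
        build_design(_four_samples(), ("control", "T2D"), ("duration",))


def test_constant_covariate_named_in_error():
    samples = _four_samples()
    samples["bmi"] = 25.0
    with pytest.raises(ValidationError, match="bmi"):
        build_design(samples, ("control", "T2D"), ("bmi",))


def test_length_abundance_covariate():
    counts = pd.DataFrame(
        {"A": [10, 20, 7], "B": [0, 0, 0]},
        index=["t30", "t33", "t29"],
    )
    ann = pd.DataFrame(
        {
            "feature_class": ["tRNA", "tRNA", "tRNA"],
            "fragment_length": [30.0, 33.0, 29.0],
        },
        index=counts.index,
    )
    cov = length_abundance_covariate(CountMatrix(counts), ann, (30, 33))
    assert cov["A"] == pytest.approx(np.log2(31))  # closed range, 29 excluded
    assert cov["B"] == pytest.approx(0.0)          # log2(1 + 0)
    with pytest.raises(ValidationError):
        length_abundance_covariate(CountMatrix(counts), ann, (40, 45))


# ---------------------------------------------------------------------------
# voom


def _design_two_groups(n):
    groups = ["control"] * (n // 2) + ["T2D"] * (n - n // 2)
    samples = pd.DataFrame(
        {
            "group": groups,
            "age": 50.0 + np.arange(n),
            "sex": ["male", "female"] * (n // 2),
            "bmi": 25.0,
        },
        index=[f"s{i}" for i in range(n)],
    )
    return samples, build_design(samples, ("control", "T2D"))


def test_voom_weights_near_constant_for_homoskedastic_logcounts():
    """Counts whose log2 values have the same variance at every abundance
    should yield an essentially flat trend, hence near-constant weights."""
    rng = np.random.default_rng(5)
    n, g = 20, 300
    base = rng.uniform(4, 12, g)
    y = base[:, None] + rng.normal(0.0, 0.4, (g, n))
    counts = pd.DataFrame(
        np.round(2.0 ** y).astype(int), columns=[f"s{i}" for i in range(n)]
    )
    counts.index = [f"f{i}" for i in range(g)]
    _, design = _design_two_groups(n)
    ones = pd.Series(1.0, index=counts.columns)
    fixed_lib = pd.Series(1e6, index=counts.columns)  # decouple lib noise
    fit = voom(CountMatrix(counts), design, ones, lib_size=fixed_lib)
    w = fit.weights
    assert w.std() / w.mean() < 0.15


def test_voom_weights_increase_with_abundance_for_nb_counts():
    """Negative-binomial counts are noisier (on the log scale) when rare,
    so weights should rise with predicted abundance on average."""
    rng = np.random.default_rng(6)
    n, g = 20, 300
    mu = 2.0 ** rng.uniform(1, 10, g)
    r = 1 / 0.05
    counts = rng.negative_binomial(r, r / (r + mu[:, None]), (g, n))
    counts = pd.DataFrame(counts, columns=[f"s{i}" for i in range(n)])
    counts.index = [f"f{i}" for i in range(g)]
    _, design = _design_two_groups(n)
    ones = pd.Series(1.0, index=counts.columns)
    fit = voom(CountMatrix(counts), design, ones)
    mean_w = fit.weights.mean(axis=1)
    rho = stats.spearmanr(fit.logcpm.mean(axis=1), mean_w).statistic
    assert rho > 0.5


def test_voom_rejects_saturated_design():
    samples, _ = _design_two_groups(4)
    design = DesignMatrix(
        X=pd.DataFrame(np.eye(4), index=samples.index), contrast="0"
    )
    counts = pd.DataFrame(
        np.ones((12, 4), dtype=int) * 5, columns=samples.index
    )
    ones = pd.Series(1.0, index=samples.index)
    with pytest.raises(ValidationError, match="degrees of freedom"):
        voom(CountMatrix(counts), design, ones)


# ---------------------------------------------------------------------------
# moderated statistics


def _toy_fit(seed=0, n=6, g=40, weights=None):
    rng = np.random.default_rng(seed)
    y = pd.DataFrame(
        rng.normal(8, 1, (g, n)),
        index=[f"f{i}" for i in range(g)],
        columns=[f"s{i}" for i in range(n)],
    )
    _, design = _design_two_groups(n)
    y.columns = design.sample_ids
    w = np.ones((g, n)) if weights is None else weights
    fit = VoomFit(logcpm=y, weights=w, trend=(np.array([0.0, 1.0]), np.array([1.0, 1.0])))
    return fit, design


def test_moderation_off_recovers_classical_pooled_t():
    fit, design = _toy_fit()
    de = fit_moderated(fit, design, df_prior_override=0.0)
    y = fit.logcpm
    a = y.iloc[:, :3].to_numpy()
    b = y.iloc[:, 3:].to_numpy()
    t_classic = stats.ttest_ind(b, a, axis=1, equal_var=True)
    np.testing.assert_allclose(de.table["t_mod"], t_classic.statistic, atol=1e-10)
    np.testing.assert_allclose(de.table["p"], t_classic.pvalue, atol=1e-10)
    np.testing.assert_allclose(
        de.table["log2fc"], b.mean(axis=1) - a.mean(axis=1), atol=1e-12
    )


def test_full_shrinkage_collapses_posterior_variances():
    fit, design = _toy_fit()
    de = fit_moderated(fit, design, df_prior_override=1e7)
    np.testing.assert_allclose(de.table["s2_post"], de.s2_prior, rtol=1e-12)


def test_weight_rescaling_leaves_t_statistics_unchanged():
    fit, design = _toy_fit()
    de1 = fit_moderated(fit, design)
    fit2, _ = _toy_fit(weights=np.full(fit.weights.shape, 7.0))
    de2 = fit_moderated(fit2, design)
    np.testing.assert_allclose(de1.table["t_mod"], de2.table["t_mod"], atol=1e-10)


def test_degenerate_identical_variances_flagged():
    fit, design = _toy_fit()
    # make every feature's residuals identical
    y0 = fit.logcpm.iloc[0]
    fit.logcpm.iloc[:] = np.tile(y0.to_numpy(), (len(fit.logcpm), 1))
    de = fit_moderated(fit, design)
    assert de.degenerate
    assert de.df_prior >= 1e7


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_brute_force(p):
    """Literal step-up definition: q_i = min_{j : p_j-rank >= rank_i}
    min(1, p_(j) * m / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [
            min(1.0, p[order[j]] * m / (j + 1)) for j in range(pos, m)
        ]
        q[idx] = min(candidates)
    return q


@pytest.mark.parametrize(
    "p,expected",
    [
        ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
        ((0.005, 0.1), (0.01, 0.1)),
        ((0.73,), (0.73,)),
    ],
)
def test_bh_worked_examples(p, expected):
    np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)


@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
)
def test_bh_matches_brute_force(p):
    np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)


@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
)
def test_bh_invariants(p):
    q = bh_adjust(p)
    assert np.all(q >= np.asarray(p) - 1e-15)
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(q[order]) >= -1e-15)


def test_bh_rejects_invalid_pvalues():
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.2])
    with pytest.raises(ValidationError):
        bh_adjust([-0.1])


# ---------------------------------------------------------------------------
# clinical-variable ANOVA screen


def _screen_samples(a, b):
    n = len(a) + len(b)
    return pd.DataFrame(
        {
            "group": ["control"] * len(a) + ["T2D"] * len(b),
            "value": list(a) + list(b),
        },
        index=[f"s{i}" for i in range(n)],
    )


def test_anova_hand_worked_example():
    # groups (1,2,3) vs (4,5,6): SSB = 13.5, MSW = 1 -> F(1,4) = 13.5
    out = anova_screen(_screen_samples([1, 2, 3], [4, 5, 6]), ["value"])
    assert out.loc["value", "F"] == pytest.approx(13.5, abs=1e-9)
    assert out.loc["value", "p"] == pytest.approx(
        stats.f.sf(13.5, 1, 4), abs=1e-12
    )
    assert out.loc["value", "p"] == pytest.approx(0.0213, abs=5e-4)


def test_anova_identical_groups():
    out = anova_screen(_screen_samples([1, 2, 3], [1, 2, 3]), ["value"])
    assert out.loc["value", "F"] == pytest.approx(0.0, abs=1e-12)
    assert out.loc["value", "p"] == pytest.approx(1.0)


def test_bonferroni_multiplies_by_variable_count():
    samples = _screen_samples([1, 2, 3], [4, 5, 6])
    for i in range(4):
        samples[f"extra{i}"] = np.arange(6) * (i + 1) + np.r_[0, 1, 0, 1, 0, 1]
    variables = ["value"] + [f"extra{i}" for i in range(4)]
    out = anova_screen(samples, variables)
    np.testing.assert_allclose(
        out["p_bonferroni"], np.minimum(1.0, out["p"] * 5), atol=1e-12
    )


def test_anova_screen_on_simulated_cohort(medium):
    """Age differs between the simulated groups (as in the cohort it
    mimics), so the screen should flag it while sex stays null-ish."""
    _, _, samples, _ = medium
    samples = samples.assign(sex_num=(samples["sex"] == "male").astype(float))
    out = anova_screen(samples, ["age", "bmi", "sex_num"])
    assert out.loc["age", "p"] < 0.01


# ---------------------------------------------------------------------------
# covariate adjustment on confounded simulations


def test_covariate_adjustment_removes_age_confounding():
    """Age is both group-correlated and expression-active: the adjusted
    model should keep false positives on age-driven features near nominal
    while the unadjusted model inflates them."""
    hits_adj, hits_raw, totals = 0, 0, 0
    for seed in range(5):
        params = SimParams(
            seed=seed, n_per_group=20, n_mature=30, isomirs_per_mirna=2,
            n_other=100, frac_de=0.0, depth_mean=5e5,
            covariate_effects={"age": 0.06}, covariate_frac=0.2,
        )
        cm, ann, samples, truth = generate_dataset(params)
        age_features = set(truth.attrs["covariate_features"]["age"])
        from srnasig import run_de

        comparison = ("control", "LADA")  # largest age gap
        de_adj = run_de(cm, ann, samples, comparison,
                        covariates=("age", "sex", "bmi"))
        de_raw = run_de(cm, ann, samples, comparison, covariates=())
        for de, acc in ((de_adj, "adj"), (de_raw, "raw")):
            feats = [f for f in de.table.index if f in age_features]
            hits = int((de.table.loc[feats, "p"] < 0.05).sum())
            if acc == "adj":
                hits_adj += hits
                totals += len(feats)
            else:
                hits_raw += hits
    assert hits_raw > hits_adj
    assert hits_adj / max(totals, 1) < 0.25
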