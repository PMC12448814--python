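"""Mixed-model fitting, BLUPs, boundary handling and Satterthwaite ANOVA."""

import json
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from rhizomix.mixedlm import (MixedModelSpec, classical_anova, fit_mixed_model,
                              treatment_anova)


def one_way(n_groups=20, n_per=6, sd_u=3.0, sd_e=2.0, seed=5, mean=10.0):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sd_u, n_groups)
    rows = [
        {"variety": f"g{g:02d}", "value": mean + u[g] + rng.normal(0, sd_e)}
        for g in range(n_groups)
        for _ in range(n_per)
    ]
    return pd.DataFrame(rows)


ONE_WAY_SPEC = MixedModelSpec(
    response="value", fixed=(), random_group="variety",
    random_slope_on_treatment=False,
)


def two_factor(seed=42, n_groups=24, slope_sd=2.0, treat_effect=8.0, noise=3.0):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, 5, n_groups)
    s = rng.normal(0, slope_sd, n_groups)
    rows = []
    for g in range(n_groups):
        for b in range(3):
            for ti, k in enumerate(("R+", "R-")):
                date = (b + ti) % 2 + 1
                y = (50 + u[g] + (treat_effect + s[g]) * ti + [0, -1, 1][b]
                     + [0.5, -0.5][date - 1] + rng.normal(0, noise))
                rows.append({"variety": f"v{g:02d}", "block": b + 1,
                             "harvest_date": date, "treatment": k, "value": y})
    return pd.DataFrame(rows)


def test_balanced_one_way_blups_match_shrinkage_closed_form():
    data = one_way()
    fit = fit_mixed_model(data, ONE_WAY_SPEC)
    vc = fit.variance_components
    lam = vc["sigma2_intercept"] / (
        vc["sigma2_intercept"] + vc["sigma2_residual"] / 6
    )
    dev = data.groupby("variety")["value"].mean() - data["value"].mean()
    np.testing.assert_allclose(fit.blups["intercept"], lam * dev, atol=1e-6)


def test_blup_intercepts_sum_to_zero_in_balanced_case():
    fit = fit_mixed_model(one_way(seed=8), ONE_WAY_SPEC)
    assert abs(fit.blups["intercept"].sum()) < 1e-6


def test_no_between_group_signal_hits_boundary_with_singular_flag():
    rng = np.random.default_rng(2)
    vals = rng.normal(0, 1, 12)
    data = pd.DataFrame(
        [{"variety": f"g{g}", "value": v} for g in range(6) for v in vals]
    )
    fit = fit_mixed_model(data, ONE_WAY_SPEC)
    assert fit.singular
    assert fit.variance_components["sigma2_intercept"] < 1e-2
    assert fit.blups["intercept"].abs().max() < 1e-6


def test_fewer_than_two_groups_rejected():
    data = one_way(n_groups=1)
    with pytest.raises(ValueError, match="2 levels"):
        fit_mixed_model(data, ONE_WAY_SPEC)


def test_random_slope_variance_recovered_on_self_simulated_data():
    # parameter recovery, averaged over seeded replicates
    true_var = 4.0
    est = []
    for rep in range(30):
        data = two_factor(seed=100 + rep, n_groups=60, slope_sd=2.0, noise=2.0)
        fit = fit_mixed_model(data, MixedModelSpec(response="value"))
        est.append(fit.variance_components["sigma2_slope"])
    assert np.mean(est) == pytest.approx(true_var, rel=0.2)


def test_singular_random_slope_falls_back_to_intercept_only():
    data = two_factor(seed=1, n_groups=12, slope_sd=0.0, noise=3.0)
    fit = fit_mixed_model(data, MixedModelSpec(response="value"))
    assert "slope" not in fit.blups.columns or fit.singular


def test_zero_random_variance_f_matches_classical_anova():
    # identical observation multisets per group: between-group variance is 0,
    # the REML boundary; the mixed F must then equal the fixed-effects F
    pattern = [0.7, -0.3, 0.9, -1.3]  # sums to zero: every group mean equal
    rows = []
    for g in range(8):
        cells = [(1, "R+"), (2, "R+"), (1, "R-"), (2, "R-")]
        for i, (b, k) in enumerate(cells):
            rows.append({"variety": f"g{g}", "block": b, "treatment": k,
                         "value": 10.0 + 3.0 * (k == "R-") + 0.5 * b
                         + pattern[(i + g) % 4]})
    data = pd.DataFrame(rows)
    # residual noise is real, but group means coincide -> REML boundary
    spec = MixedModelSpec(response="value", fixed=("block", "treatment"),
                          random_group="variety",
                          random_slope_on_treatment=False)
    fit = fit_mixed_model(data, spec)
    anova = treatment_anova(fit).set_index("term")
    ols_anova = classical_anova(
        data, "value ~ C(block, Sum) + C(treatment, Treatment(reference='R+'))"
    )
    f_mixed = anova.loc["C(treatment, Treatment(reference='R+'))", "F"]
    f_ols = ols_anova.loc["C(treatment, Treatment(reference='R+'))", "F"]
    assert f_mixed == pytest.approx(f_ols, rel=1e-6)


def test_satterthwaite_matches_lmertest_oracle(tmp_path):
    """Independent cross-check of F, denominator df and p against lmerTest."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript unavailable; the lmerTest oracle cannot run")
    data = two_factor(seed=42)
    csv = tmp_path / "fixture.csv"
    data.to_csv(csv, index=False)
    rscript = textwrap.dedent(f"""
        suppressMessages({{library(lme4); library(lmerTest)}})
        d <- read.csv("{csv}")
        d$block <- factor(d$block); d$harvest_date <- factor(d$harvest_date)
        d$treatment <- relevel(factor(d$treatment), ref="R+")
        d$ti <- as.numeric(d$treatment != "R+")
        m <- lmer(value ~ block + harvest_date + treatment + (1 + ti | variety),
                  data=d, REML=TRUE)
        a <- as.data.frame(anova(m, type=3, ddf="Satterthwaite"))
        out <- list(F=a[["F value"]], df=a[["DenDF"]], p=a[["Pr(>F)"]],
                    rows=rownames(a))
        cat(jsonlite::toJSON(out, digits=12))
    """)
    res = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                         text=True, timeout=300)
    assert res.returncode == 0, res.stderr
    oracle = json.loads(res.stdout[res.stdout.index("{"):])
    fit = fit_mixed_model(data, MixedModelSpec(response="value"))
    mine = treatment_anova(fit)
    lut = {"block": "C(block, Sum)", "harvest_date": "C(harvest_date, Sum)",
           "treatment": "C(treatment, Treatment(reference='R+'))"}
    mine = mine.set_index("term")
    for row, f_r, df_r, p_r in zip(oracle["rows"], oracle["F"], oracle["df"],
                                   oracle["p"]):
        m = mine.loc[lut[row]]
        assert m["F"] == pytest.approx(f_r, rel=2e-3)
        assert m["df_den"] == pytest.approx(df_r, rel=0.03)
        assert m["p"] == pytest.approx(p_r, rel=0.05, abs=1e-12)


def test_type_one_error_calibrated_under_null_treatment_effect():
    # treatment effect simulated as 0; rejection rate at alpha=.05 stays
    # within the binomial envelope over seeded replicates
    n_rep, alpha = 250, 0.05
    rejections = 0
    spec = MixedModelSpec(response="value", fixed=("treatment",),
                          random_group="variety",
                          random_slope_on_treatment=False)
    for rep in range(n_rep):
        rng = np.random.default_rng(10_000 + rep)
        u = rng.normal(0, 1.0, 16)
        rows = [
            {"variety": f"g{g:02d}", "treatment": k,
             "value": u[g] + rng.normal(0, 1.0)}
            for g in range(16) for k in ("R+", "R-") for _ in range(2)
        ]
        fit = fit_mixed_model(pd.DataFrame(rows), spec)
        anova = treatment_anova(fit)
        p = anova.loc[anova["term"].str.contains("treatment"), "p"].iloc[0]
        rejections += p < alpha
    from scipy.stats import binom
    lo, hi = binom.ppf([0.005, 0.995], n_rep, alpha)
    assert lo <= rejections <= hi


def test_permuted_treatment_labels_give_uniformish_p():
    data = two_factor(seed=3, n_groups=12, treat_effect=6.0)
    rng = np.random.default_rng(0)
    spec = MixedModelSpec(response="value", fixed=("treatment",),
                          random_group="variety",
                          random_slope_on_treatment=False)
    ps = []
    for _ in range(60):
        perm = data.copy()
        perm["value"] = rng.permutation(perm["value"].to_numpy())
        fit = fit_mixed_model(perm, spec)
        anova = treatment_anova(fit)
        ps.append(anova.loc[anova["term"].str.contains("treatment"), "p"].iloc[0])
    assert 0.35 <= np.median(ps) <= 0.65
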