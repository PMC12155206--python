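"""Empirical-Bayes site harmonization: effect removal, preservation, shrinkage."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from neuropls.datatypes import FeatureMatrix
from neuropls.harmonize import (
    HarmonizationModel,
    apply_harmonization,
    fit_harmonization,
    harmonize,
)
from neuropls.synthetic import GeneratorConfig, generate_cohort


def _gen(n=200, n_sites=2, p=20, loc_sd=0.0, scale_sd=0.0, cov=None,
         signal=0.0, seed=0, **kw):
    cfg = GeneratorConfig(
        n_participants=n, n_sites=n_sites, features_per_modality={"GM": p},
        n_latent_factors=1 if signal else 0, signal_strength=signal,
        site_location_sd=loc_sd, site_scale_sd=scale_sd,
        covariate_effects=cov or {}, missing_cognition_rate=0.0, seed=seed, **kw)
    return generate_cohort(cfg)


def test_planted_location_shift_removed():
    """Two sites, +2 shift on every feature: post-adjustment site-mean
    differences shrink below 0.1."""
    cohort, _, feats, _ = _gen(n=200, seed=1)
    data = feats["GM"].data.copy()
    site = cohort["site"].to_numpy()
    data.loc[site == "site2"] += 2.0
    adj, _ = harmonize(FeatureMatrix(data, "GM"), cohort, [])
    delta = (adj.data[site == "site2"].mean() - adj.data[site == "site1"].mean()).abs()
    # a shift that is identical across features leaves the prior variance
    # tiny, so EB shrinks per-feature estimates toward the common shift and
    # per-feature sampling noise (~2/sqrt(n_site)) survives adjustment; the
    # planted +2 itself is gone
    assert delta.mean() < 0.1
    assert delta.max() < 0.3


def test_planted_scale_ratio_removed():
    cohort, _, feats, _ = _gen(n=200, seed=2)
    data = feats["GM"].data.copy()
    site = cohort["site"].to_numpy()
    data.loc[site == "site2"] *= np.sqrt(2.0)
    adj, _ = harmonize(FeatureMatrix(data, "GM"), cohort, [])
    ratio = adj.data[site == "site2"].var() / adj.data[site == "site1"].var()
    assert 0.8 <= ratio.median() <= 1.25


def test_no_site_effects_near_identity():
    cohort, _, feats, _ = _gen(n=200, n_sites=3, seed=3)
    adj, _ = harmonize(feats["GM"], cohort, [])
    for col in feats["GM"].data.columns:
        r = np.corrcoef(feats["GM"].data[col], adj.data[col])[0, 1]
        assert r > 0.99


def test_covariate_slope_preserved():
    """A planted age effect of 0.5 (per SD of age) survives harmonization."""
    cohort, _, feats, _ = _gen(n=400, n_sites=4, loc_sd=1.0, scale_sd=0.3,
                               cov={"age": 0.5}, seed=4)
    adj, _ = harmonize(feats["GM"], cohort, ["age", "sex"])
    age = cohort["age"].to_numpy()
    age_z = (age - age.mean()) / age.std()
    slopes = [np.polyfit(age_z, adj.data[c], 1)[0] for c in adj.data.columns]
    assert np.mean(slopes) == pytest.approx(0.5, abs=0.05)


def test_remove_covariates_flag_residualizes():
    cohort, _, feats, _ = _gen(n=300, n_sites=3, cov={"age": 0.5}, seed=5)
    adj, _ = harmonize(feats["GM"], cohort, ["age"], protect_covariates=False)
    age = cohort["age"].to_numpy()
    age_z = (age - age.mean()) / age.std()
    slopes = [np.polyfit(age_z, adj.data[c], 1)[0] for c in adj.data.columns]
    assert abs(np.mean(slopes)) < 0.05


def test_fit_apply_consistency():
    cohort, _, feats, _ = _gen(n=150, n_sites=3, loc_sd=0.8, scale_sd=0.3, seed=6)
    one_shot, model = harmonize(feats["GM"], cohort, [])
    again = apply_harmonization(model, feats["GM"], cohort)
    pd.testing.assert_frame_equal(one_shot.data, again.data)


def test_apply_to_new_participants():
    cohort, _, feats, _ = _gen(n=300, n_sites=3, loc_sd=1.0, seed=7)
    train = cohort.iloc[:200].reset_index(drop=True)
    test = cohort.iloc[200:].reset_index(drop=True)
    fm_train = feats["GM"].subset_participants(train["participant_id"])
    fm_test = feats["GM"].subset_participants(test["participant_id"])
    model = fit_harmonization(fm_train, train, [])
    adj_test = apply_harmonization(model, fm_test, test)
    # site-mean differences on held-out rows shrink
    site = test["site"].to_numpy()
    pre = fm_test.data.groupby(site).mean()
    post = adj_test.data.groupby(site).mean()
    assert (post.max() - post.min()).mean() < (pre.max() - pre.min()).mean() * 0.5


def test_unseen_site_rejected():
    cohort, _, feats, _ = _gen(n=100, n_sites=2, seed=8)
    model = fit_harmonization(feats["GM"], cohort, [])
    other = cohort.copy()
    other.loc[:, "site"] = "siteX"
    with pytest.raises(ValueError, match="siteX"):
        apply_harmonization(model, feats["GM"], other)


def test_single_site_identity_with_warning(caplog):
    cohort, _, feats, _ = _gen(n=80, n_sites=1, seed=9)
    with caplog.at_level("WARNING"):
        adj, model = harmonize(feats["GM"], cohort, [])
    assert model.identity
    pd.testing.assert_frame_equal(adj.data, feats["GM"].data)
    assert "single site" in caplog.text


def test_single_participant_site_rejected():
    cohort, _, feats, _ = _gen(n=50, n_sites=2, seed=10)
    cohort = cohort.copy()
    cohort.loc[cohort.index[0], "site"] = "site_tiny"
    with pytest.raises(ValueError, match="single participant"):
        fit_harmonization(feats["GM"], cohort, [])


def test_empirical_bayes_shrinks_small_site_toward_prior():
    """For a small site, posterior location estimates lie between the raw
    per-feature estimates and the pooled prior mean."""
    cohort, _, feats, _ = _gen(n=208, n_sites=2, loc_sd=0.6, seed=11)
    cohort = cohort.copy()
    keep = np.ones(len(cohort), dtype=bool)
    small_rows = np.flatnonzero(cohort["site"] == "site2")[8:]
    keep[small_rows] = False  # shrink site2 to 8 participants
    cohort = cohort.loc[keep].reset_index(drop=True)
    fm = feats["GM"].subset_participants(cohort["participant_id"])
    model = fit_harmonization(fm, cohort, [])
    i = model.sites.index("site2")
    # reconstruct the raw standardized site means
    X = fm.values()
    Z = (X - model.grand_mean) / np.sqrt(model.var_pooled)
    raw = Z[(cohort["site"] == "site2").to_numpy()].mean(axis=0)
    prior_mean = raw.mean()
    post = model.gamma_star[i]
    relevant = np.abs(raw - prior_mean) > 0.05
    between = ((post[relevant] - raw[relevant]) * (prior_mean - raw[relevant]) > 0)
    assert between.mean() > 0.9


def test_site_anova_calibrated_after_harmonization():
    """With no true site effects, harmonization does not create spurious
    site differences (per-feature ANOVA rejection at most nominal)."""
    from scipy import stats
    rates = []
    for s in range(10):
        cohort, _, feats, _ = _gen(n=200, n_sites=3, seed=100 + s)
        adj, _ = harmonize(feats["GM"], cohort, [])
        site = cohort["site"].to_numpy()
        groups = [adj.data[site == lab].to_numpy() for lab in np.unique(site)]
        p = np.array([stats.f_oneway(*[g[:, j] for g in groups]).pvalue
                      for j in range(adj.data.shape[1])])
        rates.append((p < 0.05).mean())
    assert np.mean(rates) <= 0.05 + 0.02


def test_model_serialization_roundtrip(tmp_path):
    cohort, _, feats, _ = _gen(n=120, n_sites=3, loc_sd=0.7, scale_sd=0.2,
                               cov={"age": 0.3}, seed=12)
    adj, model = harmonize(feats["GM"], cohort, ["age"])
    path = tmp_path / "model.yaml"
    model.to_yaml(path)
    loaded = HarmonizationModel.from_yaml(path)
    re_adj = apply_harmonization(loaded, feats["GM"], cohort)
    np.testing.assert_allclose(re_adj.data.to_numpy(), adj.data.to_numpy(),
                               atol=1e-10)


def test_matches_reference_combat_implementation(tmp_path):
    """Numerical agreement with the Bioconductor sva::ComBat reference on a
    small fixture (parametric priors, covariates protected)."""
    cohort, _, feats, _ = _gen(n=60, n_sites=3, p=8, loc_sd=0.8, scale_sd=0.3,
                               cov={"age": 0.3}, signal=0.1, seed=13)
    adj, _ = harmonize(feats["GM"], cohort, ["age", "sex"])
    feats["GM"].data.to_csv(tmp_path / "x.csv")
    cohort.to_csv(tmp_path / "c.csv", index=False)
    script = tmp_path / "combat.R"
    script.write_text(
        'suppressMessages(library(sva))\n'
        'x <- read.csv("x.csv", row.names=1)\n'
        'c <- read.csv("c.csv")\n'
        'mod <- model.matrix(~ age + sex, data=c)\n'
        'out <- ComBat(dat=t(as.matrix(x)), batch=c$site, mod=mod, par.prior=TRUE)\n'
        'write.csv(t(out), "r_out.csv")\n')
    subprocess.run(["Rscript", script.name], cwd=tmp_path, check=True,
                   capture_output=True)
    r_out = pd.read_csv(tmp_path / "r_out.csv", index_col=0)
    # both implementations iterate the EB posteriors to a 1e-4 relative
    # stopping rule, so agreement is bounded by the stopping point
    np.testing.assert_allclose(r_out.to_numpy(), adj.data.to_numpy(), atol=1e-4)
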