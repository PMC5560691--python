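"""Design construction, censored likelihood, and maximum-likelihood fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, stats

import censorq as cq
from censorq.datasets import CqValidationError
from censorq.model import Design, ModelSpec, build_design, censored_loglik, fit_ucnr

from conftest import grid_dataset


# ---------------------------------------------------------------------------
# likelihood values
# ---------------------------------------------------------------------------

def test_loglik_single_uncensored_at_mean():
    """One uncensored well exactly at its latent mean, sigma=1: the standard
    normal log density at zero."""
    ds = grid_dataset([[10.0, 10.0], [10.0, 10.0]], ["g1", "g2"])
    design = build_design(ds)
    theta = np.zeros(design.n_params)
    theta[0] = 10.0  # mu; everything else 0, log sigma = 0 -> sigma 1
    ll = censored_loglik(theta, ds)
    assert ll == pytest.approx(4 * -0.9189385332046727, abs=1e-9)


def test_loglik_censored_at_latent_mean_is_log_half():
    """A censored well whose bound equals the latent mean contributes
    ln(1/2), whatever sigma is."""
    vals = np.array([[10.0, 8.5], [9.0, 9.5]])
    cens = np.array([[True, False], [False, False]])
    ds = grid_dataset(vals, ["g1", "g2"], lod=10.0, censored=cens)
    for log_sigma in (-1.0, 0.0, 2.0):
        design = build_design(ds)
        theta = np.zeros(design.n_params)
        theta[0] = 10.0  # latent mean of every well = bound of the censored one
        theta[design.sl_logsigma] = log_sigma
        ll = censored_loglik(theta, ds)
        sigma = np.exp(log_sigma)
        expected_unc = sum(
            stats.norm.logpdf(v, loc=10.0, scale=sigma)
            for v in (8.5, 9.0, 9.5)
        )
        assert ll - expected_unc == pytest.approx(np.log(0.5), abs=1e-10)


def _loglik_quadrature_reference(design, theta):
    """Per-well evaluation: explicit density formula for observed wells,
    numerical integration of the standardized normal tail for censored
    wells (pure relative tolerance, well conditioned far into the tail)."""
    m = design.mean_of(theta)
    sig = design.sigma_of(theta)
    ll_ref = 0.0
    for r in range(len(design.y)):
        mu_r, s_r, y_r = m[r], sig[r], design.y[r]
        if design.censored[r]:
            z0 = (y_r - mu_r) / s_r
            tail, _ = integrate.quad(
                lambda z: np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi),
                z0, max(z0 + 45.0, 45.0), limit=400, epsabs=0.0, epsrel=1e-13,
            )
            ll_ref += np.log(tail)
        else:
            ll_ref += (-0.5 * np.log(2 * np.pi) - np.log(s_r)
                       - 0.5 * ((y_r - mu_r) / s_r) ** 2)
    return ll_ref


def test_loglik_matches_quadrature_oracle():
    """Random 20-well instances against the independent per-term oracle."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        I, J = 2, 10
        vals = rng.normal(30, 2, size=(I, J))
        cens = rng.random((I, J)) < 0.3
        lod = 33.0
        vals = np.minimum(vals, lod - 1e-3)
        vals[cens] = lod
        ds = grid_dataset(vals, ["g1"] * 5 + ["g2"] * 5, lod=lod, censored=cens)
        design = build_design(ds)
        theta = rng.normal(0, 0.5, design.n_params)
        theta[0] = 30.0
        ll = censored_loglik(theta, ds)
        assert ll == pytest.approx(_loglik_quadrature_reference(design, theta),
                                   abs=1e-10)


def test_loglik_rejects_nonfinite_parameters(small_complete):
    ds, _ = small_complete
    design = build_design(ds)
    theta = np.zeros(design.n_params)
    theta[0] = np.nan
    with pytest.raises(ValueError):
        censored_loglik(theta, ds)


# ---------------------------------------------------------------------------
# design structure
# ---------------------------------------------------------------------------

def test_free_parameter_count_and_rank_small_balanced():
    """I=2, J=4, K=2 balanced: 1 (mu) + 1 (alpha) + (J-K) (beta) + I(K-1)
    (interactions) mean parameters plus I noise scales, and the mean design
    has full column rank."""
    vals = [[20.0, 21.0, 22.0, 23.0], [25.0, 26.0, 27.0, 28.0]]
    ds = grid_dataset(vals, ["g1", "g1", "g2", "g2"])
    design = build_design(ds)
    I, J, K = 2, 4, 2
    assert design.n_mean == 1 + (I - 1) + (J - K) + I * (K - 1)
    assert design.n_params == design.n_mean + I
    assert np.linalg.matrix_rank(design.X) == design.n_mean


def test_reference_gene_design_full_rank():
    rng = np.random.default_rng(3)
    vals = rng.normal(25, 1, size=(6, 8))
    ds = grid_dataset(vals, ["g1"] * 4 + ["g2"] * 4)
    ds.targets.loc[["t0", "t1"], "is_reference"] = 1
    design = build_design(ds, ModelSpec(variant="reference_genes"))
    assert np.linalg.matrix_rank(design.X) == design.n_mean


def test_all_reference_targets_rejected():
    vals = [[20.0, 21.0], [25.0, 26.0]]
    ds = grid_dataset(vals, ["g1", "g2"])
    ds.targets["is_reference"] = 1
    with pytest.raises(CqValidationError):
        build_design(ds, ModelSpec(variant="reference_genes"))


def test_single_target_reduces_to_two_group_location_model():
    """With I=1 the per-sample effects are dropped, leaving intercept,
    one interaction and one noise scale."""
    rng = np.random.default_rng(0)
    vals = rng.normal(25, 1, size=(1, 12))
    ds = grid_dataset(vals, ["g1"] * 6 + ["g2"] * 6)
    design = build_design(ds)
    assert design.n_mean == 2  # mu + one group contrast
    assert design.n_params == 3


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_no_censoring_delta_equals_mod_group_differences(small_complete):
    """On complete data the fitted fold changes coincide with the sequential
    estimator: MOD-normalized group-mean differences."""
    ds, _ = small_complete
    fit = cq.fit_ucnr(ds)
    res = cq.delta_contrasts(fit).set_index("target_id")["delta_hat"]
    normalized, _ = cq.mod_normalize(ds)
    g = ds.samples["group"]
    mod_diff = (normalized[g.index[g == "g1"]].mean(axis=1)
                - normalized[g.index[g == "g2"]].mean(axis=1))
    assert np.max(np.abs(res - mod_diff)) < 1e-6


def test_single_target_fit_matches_brute_force_grid():
    """I=1, two groups, ~30% censoring: the ML solution agrees with an
    independent brute-force optimization of an independently coded
    likelihood over (m1, m2, log sigma)."""
    rng = np.random.default_rng(21)
    n = 30
    vals = rng.normal(30.0, 1.2, size=(1, 2 * n))
    vals[0, n:] -= 2.0
    lod = float(np.quantile(vals, 0.7))
    cens = vals >= lod
    vals[cens] = lod
    ds = grid_dataset(vals, ["g1"] * n + ["g2"] * n, lod=lod, censored=cens)
    fit = cq.fit_ucnr(ds)
    delta_fit = float(cq.delta_contrasts(fit)["delta_hat"].iloc[0])
    sigma_fit = float(fit.params.sigma.iloc[0])

    y = ds.data["cq"].to_numpy()
    c = ds.data["censored"].to_numpy()
    grp2 = (ds.data["group"] == "g2").to_numpy()

    def nll(p):
        m1, m2, ls = p
        mu = np.where(grp2, m2, m1)
        s = np.exp(ls)
        out = stats.norm.logpdf(y[~c], loc=mu[~c], scale=s).sum()
        out += stats.norm.logsf(y[c], loc=mu[c], scale=s).sum()
        return -out

    best = optimize.brute(nll, ((28, 32), (26, 30), (-1.5, 1.0)), Ns=25,
                          full_output=True, finish=optimize.fmin)
    m1, m2, ls = best[0]
    assert delta_fit == pytest.approx(m1 - m2, abs=1e-3)
    assert sigma_fit == pytest.approx(np.exp(ls), abs=1e-3)


def test_removal_rule_thresholds():
    rng = np.random.default_rng(5)
    vals = rng.normal(28, 1, size=(3, 10))
    cens = np.zeros((3, 10), bool)
    cens[0, :9] = True  # 90% censored
    cens[1, :] = True   # fully censored
    vals[cens] = 40.0
    ds = grid_dataset(vals, ["g1"] * 5 + ["g2"] * 5, lod=40.0, censored=cens)

    kept, removed = cq.remove_heavily_censored(ds, 0.8)
    assert set(removed["target_id"]) == {"t0", "t1"}
    assert kept.n_targets == 1
    # per-group censored counts recorded
    assert {"n_censored[g1]", "n_censored[g2]"} <= set(removed.columns)

    kept2, removed2 = cq.remove_heavily_censored(ds, 1.0)
    assert set(removed2["target_id"]) == {"t1"}

    clean = grid_dataset(rng.normal(28, 1, size=(3, 10)), ["g1"] * 5 + ["g2"] * 5)
    kept3, removed3 = cq.remove_heavily_censored(clean, 0.8)
    assert len(removed3) == 0 and kept3.n_targets == 3


def test_fit_loglik_not_below_initialization(small_censored):
    ds, _ = small_censored
    fit = cq.fit_ucnr(ds)
    assert fit.converged
    assert fit.loglik >= fit.loglik_init - 1e-8


def test_delta_invariant_under_relabeling(small_censored):
    """Reordering targets and samples (an alternative coding of the same
    model) leaves fold-change estimates and standard errors unchanged."""
    ds, _ = small_censored
    fit1 = cq.fit_ucnr(ds)
    r1 = cq.delta_contrasts(fit1, comparison=("g1", "g2")).set_index("target_id")

    rng = np.random.default_rng(9)
    perm = ds.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
    t_order = list(rng.permutation(ds.target_ids))
    s_order = list(rng.permutation(ds.sample_ids))
    ds2 = cq.make_dataset(
        perm[["sample_id", "target_id", "group", "cq", "censored"]],
        ds.lod,
        samples=ds.samples.loc[s_order],
        targets=ds.targets.loc[t_order],
    )
    fit2 = cq.fit_ucnr(ds2)
    r2 = cq.delta_contrasts(fit2, comparison=("g1", "g2")).set_index("target_id")
    for tid in r1.index:
        # agreement to optimizer precision (both runs stop at the same
        # gradient tolerance, approached from different codings)
        assert r1.loc[tid, "delta_hat"] == pytest.approx(r2.loc[tid, "delta_hat"], abs=1e-5)
        assert r1.loc[tid, "se"] == pytest.approx(r2.loc[tid, "se"], rel=1e-3)


def test_fully_censored_group_warns_but_fits():
    rng = np.random.default_rng(13)
    vals = rng.normal(28, 1, size=(5, 12))
    cens = np.zeros((5, 12), bool)
    cens[0, 6:] = True  # group g2 of t0 fully censored (50% overall)
    vals[cens] = 33.0
    ds = grid_dataset(vals, ["g1"] * 6 + ["g2"] * 6, lod=33.0, censored=cens)
    fit = cq.fit_ucnr(ds)
    assert any("fully censored" in w for w in fit.warnings)
    assert "t0" in list(cq.delta_contrasts(fit)["target_id"])


def test_parameter_recovery_improves_with_sample_size():
    """Mean absolute error of the fold-change estimate shrinks as per-group
    sample size grows (|delta|=2, sigma=1, 30% censoring)."""
    rng = np.random.default_rng(77)
    errors = {}
    for n in (10, 50):
        errs = []
        for _ in range(15):
            cfg = cq.SimConfig(n_targets=12, group_sizes=(n, n), n_de=4,
                               sigma_range=(1.0, 1.0))
            ds, truth = cq.generate_synthetic(cfg, rng=rng)
            dsc = cq.censor_at_fraction(ds, 0.30)
            fit = cq.fit_ucnr(dsc, compute_covariance=False)
            res = cq.delta_contrasts(fit).set_index("target_id")["delta_hat"]
            err = res - truth["delta"].reindex(res.index)
            errs.append(float(np.abs(err.mean())))
        errors[n] = float(np.mean(errs))
    assert errors[50] < errors[10]
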