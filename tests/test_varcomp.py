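import numpy as np
import pandas as pd
import pytest
from scipy import stats

import famomics as fo
from famomics.varcomp import (
    VarCompFit,
    block_structure,
    familial_test,
    fit_ae,
    fit_full,
    fit_null,
    genome_scan,
    heritability,
    loglik,
    summarize_scan,
)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def test_loglik_iid_closed_form(study_matrices):
    A, H, _ = study_matrices
    rng = np.random.default_rng(0)
    y = rng.standard_normal(48)
    ll = loglik(y, A, H, (0.0, 0.0, 0.0, 1.0))
    assert ll == pytest.approx(stats.norm.logpdf(y).sum(), abs=1e-10)


def test_loglik_scaling_change_of_variables(study_matrices):
    A, H, _ = study_matrices
    rng = np.random.default_rng(1)
    y = rng.standard_normal(48)
    base = loglik(y, A, H, (0.0, 0.4, 0.2, 0.4))
    c = 2.5
    scaled = loglik(c * y, A, H, (0.0, c**2 * 0.4, c**2 * 0.2, c**2 * 0.4))
    assert scaled == pytest.approx(base - 48 * np.log(c), abs=1e-8)


def test_loglik_singular_covariance_returns_neg_inf(study_matrices):
    A, H, _ = study_matrices
    y = np.zeros(48)
    assert loglik(y, A, H, (0.0, 0.0, 1.0, 0.0)) == -np.inf  # H blocks singular


def test_loglik_matches_dense_mvn_oracle():
    """Blockwise profiled computation agrees with scipy's dense MVN density
    on random small pedigrees and random parameters."""
    rng = np.random.default_rng(2)
    for _ in range(20):
        cfg = fo.SimulationConfig(
            n_families=2,
            children_per_family=(int(rng.integers(1, 3)), int(rng.integers(1, 3))),
            father_present=(True, bool(rng.integers(2))),
            seed=int(rng.integers(1e6)),
        )
        ped = fo.generate_pedigree(cfg)
        n = len(ped)
        A = fo.compute_additive(ped)
        H = fo.compute_household(ped)
        mu, vg, vc, ve = rng.uniform(-1, 1), rng.uniform(0, 2), rng.uniform(0, 2), rng.uniform(0.1, 2)
        y = rng.standard_normal(n)
        Sigma = vg * A.values + vc * H.values + ve * np.eye(n)
        expected = stats.multivariate_normal.logpdf(y, mean=np.full(n, mu), cov=Sigma)
        assert loglik(y, A, H, (mu, vg, vc, ve)) == pytest.approx(expected, abs=1e-8)


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------


def test_fit_null_closed_form():
    fit = fit_null(np.array([0.0, 0.0, 2.0, 2.0]))
    assert (fit.mu, fit.ve) == (1.0, 1.0)
    assert fit.vg == fit.vc == 0.0
    assert fit.loglik == pytest.approx(
        stats.norm.logpdf([0, 0, 2, 2], loc=1.0, scale=1.0).sum()
    )


def test_fit_null_consistency_large_n():
    rng = np.random.default_rng(3)
    fit = fit_null(rng.standard_normal(10_000))
    assert fit.ve == pytest.approx(1.0, abs=0.05)


def test_null_nested_in_full(study_matrices):
    A, H, bs = study_matrices
    rng = np.random.default_rng(4)
    for _ in range(5):
        y = rng.standard_normal(48)
        assert fit_full(y, A, H, bs).loglik >= fit_null(y).loglik - 1e-8


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------


def test_full_fit_null_data_components_near_zero(study_ped, study_matrices):
    A, H, bs = study_matrices
    cfg = fo.study_like_config(vg=0.0, vc=0.0, ve=1.0, n_features=200, seed=5)
    fm, _ = fo.simulate_features(study_ped, cfg)
    fits = [fit_full(fm.values[c].to_numpy(), A, H, bs) for c in fm.values.columns]
    assert np.median([f.vg for f in fits]) < 0.05
    assert np.median([f.vc for f in fits]) < 0.05
    # a substantial fraction of null fits lands exactly on the boundary
    frac_zero = np.mean([f.vg == 0.0 and f.vc == 0.0 for f in fits])
    assert frac_zero > 0.10


def test_full_fit_common_environment_limit(study_ped, study_matrices):
    """Almost-pure shared environment drives maximal heritability to ~1
    through the common-environment share."""
    A, H, bs = study_matrices
    cfg = fo.study_like_config(vg=0.0, vc=0.95, ve=0.05, n_features=20, seed=6)
    fm, _ = fo.simulate_features(study_ped, cfg)
    h2 = [heritability(fit_full(fm.values[c].to_numpy(), A, H, bs)) for c in fm.values.columns]
    assert np.mean([e.h2_max for e in h2]) > 0.8
    assert np.mean([e.c2 for e in h2]) > np.mean([e.h2_g for e in h2])


def test_zero_variance_feature_degenerate(study_matrices):
    A, H, bs = study_matrices
    fit = fit_full(np.full(48, 3.0), A, H, bs)
    assert fit.degenerate and not fit.converged
    assert fit.vg == fit.vc == 0.0 and fit.ve > 0


# ---------------------------------------------------------------------------
# AE model
# ---------------------------------------------------------------------------


def test_ae_agrees_with_full_when_no_common_environment():
    """Without true shared environment the AE and full models estimate the
    same polygenic variance on average (checked at 100 families, where the
    boundary noise of the 16-family design has died down)."""
    cfg = fo.study_like_config(n_families=100, vg=0.6, vc=0.0, ve=0.4, n_features=60, seed=7)
    ped = fo.generate_pedigree(cfg)
    A, H = fo.compute_additive(ped), fo.compute_household(ped)
    bs = block_structure(A, H)
    fm, _ = fo.simulate_features(ped, cfg)
    d = []
    for c in fm.values.columns:
        y = fm.values[c].to_numpy()
        d.append(fit_ae(y, A, bs).vg - fit_full(y, A, H, bs).vg)
    # for the typical feature the full fit lands on Vc = 0 and the two
    # models coincide; a boundary minority keeps the mean slightly apart
    assert abs(np.median(d)) < 0.05


def test_ae_absorbs_shared_environment(study_ped, study_matrices):
    """With true Vc > 0 the AE model inflates Vg on average (shared
    environment masquerades as relatedness in sib-heavy designs)."""
    A, H, bs = study_matrices
    cfg = fo.study_like_config(vg=0.3, vc=0.4, ve=0.3, n_features=200, seed=8)
    fm, _ = fo.simulate_features(study_ped, cfg)
    diffs = []
    for c in fm.values.columns:
        y = fm.values[c].to_numpy()
        diffs.append(fit_ae(y, A, bs).vg - fit_full(y, A, H, bs).vg)
    assert np.mean(diffs) > 0


# ---------------------------------------------------------------------------
# familial test & heritability
# ---------------------------------------------------------------------------


def test_familial_test_zero_when_boundary_fit():
    null = fit_null(np.array([1.0, -1.0, 0.5, -0.5]))
    full = VarCompFit(0.0, 0.0, null.ve, null.mu, null.loglik, True, "full", n=4)
    t = familial_test(full, null)
    assert (t.lrt, t.p) == (0.0, 1.0)
    tm = familial_test(full, null, boundary_mixture=True)
    assert tm.p == 1.0


def test_familial_test_mismatched_subjects():
    a = fit_null(np.zeros(4) + [0, 1, 2, 3])
    b = fit_null(np.array([0.0, 1.0, 2.0, 3.0, 4.0]))
    with pytest.raises(ValueError, match="same subjects"):
        familial_test(a, b)


def test_lrt_affine_invariance(study_matrices):
    A, H, bs = study_matrices
    rng = np.random.default_rng(9)
    y = rng.standard_normal(48)
    t1 = familial_test(fit_full(y, A, H, bs), fit_null(y))
    z = 3.0 * y - 7.0
    t2 = familial_test(fit_full(z, A, H, bs), fit_null(z))
    assert t1.lrt == pytest.approx(t2.lrt, abs=1e-4)


def test_heritability_worked_example():
    """Component shares 26.04% genetic + 57.60% common environment give a
    maximal heritability of 83.64%."""
    fit = VarCompFit(26.04, 57.60, 100 - 26.04 - 57.60, 0.0, 0.0, True, "full", n=48)
    h = heritability(fit)
    assert round(100 * h.h2_g, 2) == 26.04
    assert round(100 * h.c2, 2) == 57.60
    assert round(100 * h.h2_max, 2) == 83.64


def test_heritability_identity_random_fits():
    rng = np.random.default_rng(10)
    for _ in range(100):
        vg, vc, ve = rng.uniform(0, 1, 3)
        h = heritability(VarCompFit(vg, vc, ve + 1e-6, 0.0, 0.0, True, "full", n=10))
        assert h.h2_max == pytest.approx(h.h2_g + h.c2, abs=1e-10)
        assert 0 <= h.h2_max <= 1


def test_heritability_all_zero_errors():
    with pytest.raises(ValueError, match="zero"):
        heritability(VarCompFit(0.0, 0.0, 0.0, 0.0, 0.0, True, "full", n=4))


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------


def test_bh_adjustment_matches_definition():
    """BH on (0.01, 0.02, 0.03, 0.04, 0.2) gives (0.05, 0.05, 0.05, 0.05, 0.2)."""
    from statsmodels.stats.multitest import multipletests

    p = np.array([0.01, 0.02, 0.03, 0.04, 0.2])
    adj = multipletests(p, method="fdr_bh")[1]
    # brute-force step-up definition
    m = len(p)
    order = np.argsort(p)
    raw = p[order] * m / (np.arange(m) + 1)
    expected = np.minimum.accumulate(raw[::-1])[::-1][np.argsort(order)]
    assert np.allclose(adj, expected)
    assert np.allclose(adj, [0.05, 0.05, 0.05, 0.05, 0.2])


def test_genome_scan_mixed_simulation(study_ped):
    """80% null + 20% strongly familial features: significant features show
    higher mean maximal heritability than the full set, FDR column is
    monotone in p, and non-finite features are dropped."""
    cfg_null = fo.study_like_config(vg=0.0, vc=0.0, ve=1.0, n_features=160, seed=11)
    cfg_fam = fo.study_like_config(vg=0.6, vc=0.2, ve=0.2, n_features=40, seed=12)
    fm_n, _ = fo.simulate_features(study_ped, cfg_null)
    fm_f, _ = fo.simulate_features(study_ped, cfg_fam, prefix="fam")
    values = pd.concat([fm_n.values, fm_f.values], axis=1)
    values["broken"] = np.nan
    scan = genome_scan(values, study_ped)
    assert "broken" not in scan.index and len(scan) == 200
    summary = summarize_scan(scan)
    assert (
        summary.loc["significant", "h2_max_mean"] > summary.loc["all", "h2_max_mean"]
    )
    assert summary.loc["all", "n_h2max_zero"] > 0
    ordered = scan.sort_values("p")
    assert (np.diff(ordered["p_fdr"]) >= -1e-12).all()
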