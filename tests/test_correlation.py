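import numpy as np
import pandas as pd
import pytest

import famomics as fo
from famomics.correlation import (
    bonferroni,
    fisher_z_pvalue,
    genetic_correlation,
    phenotypic_screen,
)
from famomics.preprocess import residualize
from famomics.varcomp import block_structure


# ---------------------------------------------------------------------------
# Bonferroni arithmetic
# ---------------------------------------------------------------------------


def test_bonferroni_values():
    assert bonferroni(0.05, 1) == 0.05
    assert f"{bonferroni(0.05, 39):.3g}" == "0.00128"
    assert f"{bonferroni(0.05, 1211 * 6291):.3g}" == "6.56e-09"
    with pytest.raises(ValueError):
        bonferroni(0.05, 0)


# ---------------------------------------------------------------------------
# Fisher-Z p-values
# ---------------------------------------------------------------------------


def test_fisher_z_edge_cases():
    z, p = fisher_z_pvalue(0.0, 48)
    assert (z, p) == (0.0, 1.0)
    z1, p1 = fisher_z_pvalue(1.0, 48)
    assert np.isinf(z1) and p1 == 0.0


def test_fisher_z_monotonicity():
    rs = np.linspace(0.0, 0.95, 20)
    _, ps = fisher_z_pvalue(rs, 48)
    assert (np.diff(ps) < 0).all()  # decreasing in |r|
    p_small_n = fisher_z_pvalue(0.4, 20)[1]
    p_large_n = fisher_z_pvalue(0.4, 100)[1]
    assert p_large_n < p_small_n  # decreasing in n at fixed r


def test_fisher_z_matches_permutation_oracle():
    """The asymptotic p for r ~ 0.5 at n = 48 agrees with a permutation
    null within a factor of 1.5."""
    rng = np.random.default_rng(0)
    n = 48
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    xs = (x - x.mean()) / x.std()
    e = e - e.mean() - xs * (xs @ (e - e.mean())) / n  # orthogonal to xs
    ys = 0.5 * xs + np.sqrt(0.75) * e / e.std()  # empirical r exactly 0.5
    r_obs = np.corrcoef(xs, ys)[0, 1]
    assert r_obs == pytest.approx(0.5, abs=1e-12)
    _, p_asym = fisher_z_pvalue(r_obs, n)
    n_perm = 200_000
    ysn = (ys - ys.mean()) / ys.std()
    perms = np.array([xs @ rng.permutation(ysn) / n for _ in range(n_perm)])
    p_perm = (np.abs(perms) >= abs(r_obs)).mean() + 1.0 / n_perm
    assert p_asym / p_perm < 1.5 and p_perm / p_asym < 1.5


# ---------------------------------------------------------------------------
# phenotypic screen
# ---------------------------------------------------------------------------


def test_screen_grid_bookkeeping():
    """A 1211 x 6291 screen performs 7,618,401 tests at threshold 6.56e-9."""
    rng = np.random.default_rng(1)
    idx = [f"s{i}" for i in range(48)]
    a = pd.DataFrame(rng.standard_normal((48, 1211)), index=idx)
    b = pd.DataFrame(rng.standard_normal((48, 6291)), index=idx)
    res = phenotypic_screen(a, b, alpha=0.05, chunk=256)
    assert res.m_total == 7_618_401
    assert f"{res.bonferroni_threshold:.3g}" == "6.56e-09"
    assert res.n_significant == len(res.pairs.query("passes_bonferroni"))
    assert res.n_significant <= 5  # pure-noise grid: essentially none expected


def test_screen_self_correlation_diagonal():
    rng = np.random.default_rng(2)
    idx = [f"s{i}" for i in range(30)]
    a = pd.DataFrame(rng.standard_normal((30, 10)), index=idx,
                     columns=[f"f{j}" for j in range(10)])
    res = phenotypic_screen(a, a, alpha=0.05, report_threshold=1.1)
    diag = res.pairs[res.pairs.feature_a == res.pairs.feature_b]
    assert len(diag) == 10 and np.allclose(diag["r"], 1.0)


def test_screen_zero_variance_stays_in_denominator():
    rng = np.random.default_rng(3)
    idx = [f"s{i}" for i in range(20)]
    a = pd.DataFrame(rng.standard_normal((20, 5)), index=idx)
    a[0] = 2.0  # constant
    b = pd.DataFrame(rng.standard_normal((20, 4)), index=idx)
    res = phenotypic_screen(a, b)
    assert res.m_total == 20
    assert res.n_missing == 4
    assert res.bonferroni_threshold == 0.05 / 20


def test_screen_detects_planted_correlation():
    rng = np.random.default_rng(4)
    idx = [f"s{i}" for i in range(48)]
    x = rng.standard_normal(48)
    a = pd.DataFrame({"hit": x, "noise": rng.standard_normal(48)}, index=idx)
    b = pd.DataFrame({"twin": x + 0.05 * rng.standard_normal(48)}, index=idx)
    res = phenotypic_screen(a, b)
    assert res.n_significant == 1
    assert res.pairs.iloc[0][["feature_a", "feature_b"]].tolist() == ["hit", "twin"]


# ---------------------------------------------------------------------------
# bivariate genetic correlation
# ---------------------------------------------------------------------------


def test_identical_traits_full_correlation(study_ped, study_matrices):
    A, H, bs = study_matrices
    cfg = fo.study_like_config(vg=0.5, vc=0.2, ve=0.3, n_features=1, seed=5)
    fm, _ = fo.simulate_features(study_ped, cfg)
    y = fm.values.iloc[:, 0].to_numpy()
    fit = genetic_correlation(y, y.copy(), A, H, bs)
    assert fit.rho_g == pytest.approx(1.0, abs=1e-3)
    assert fit.rho_e == pytest.approx(1.0, abs=1e-3)


def test_rho_g_nested_likelihoods(study_ped, study_matrices):
    A, H, bs = study_matrices
    cfg = fo.study_like_config(rho_g=0.5, n_features=5, seed=6)
    fa, fb, _ = fo.simulate_bivariate(study_ped, cfg)
    for i in range(5):
        fit = genetic_correlation(
            fa.values.iloc[:, i].to_numpy(), fb.values.iloc[:, i].to_numpy(), A, H, bs
        )
        assert fit.lrt_rho_g >= 0.0
        assert 0.0 <= fit.p_rho_g <= 1.0


def test_zero_familial_variance_flags_rho_g(study_ped, study_matrices):
    A, H, bs = study_matrices
    rng = np.random.default_rng(7)
    y1 = rng.standard_normal(48)  # pure noise: no genetic variance
    y2 = rng.standard_normal(48)
    fit = genetic_correlation(y1, y2, A, H, bs)
    if not fit.rho_g_defined:
        assert np.isnan(fit.rho_g) and "genetic variance" in fit.reason
    else:  # noise can fit small vg; the flag logic still must be coherent
        assert np.isfinite(fit.rho_g)


def test_rho_g_null_calibration():
    """Under rho_g = 0 the df=1 LRT rejects at ~5%; checked over 120 pairs
    at 60 families so the interior-parameter asymptotics apply."""
    cfg = fo.study_like_config(
        n_families=60, n_features=120, vg=0.6, vc=0.2, ve=0.2,
        rho_g=0.0, rho_c=0.0, rho_e=0.0, seed=8,
    )
    ped = fo.generate_pedigree(cfg)
    fa, fb, _ = fo.simulate_bivariate(ped, cfg)
    A, H = fo.compute_additive(ped), fo.compute_household(ped)
    bs = block_structure(A, H)
    rej = np.mean(
        [
            genetic_correlation(
                fa.values.iloc[:, i].to_numpy(), fb.values.iloc[:, i].to_numpy(),
                A, H, bs,
            ).p_rho_g
            <= 0.05
            for i in range(120)
        ]
    )
    se = np.sqrt(0.05 * 0.95 / 120)
    assert abs(rej - 0.05) <= 2 * se


def test_cell_adjustment_reduces_confounded_correlations(study_ped):
    """Cross-omic hits driven by shared cell composition disappear once
    cell proportions enter the residualization design."""
    rng = np.random.default_rng(9)
    n = 48
    idx = list(study_ped.ids)
    frac = rng.dirichlet(np.ones(3), size=n)  # shared cell composition
    pc = frac[:, 0] - frac[:, 0].mean()
    cov = pd.DataFrame(
        {
            "sex": [i.sex for i in study_ped.individuals],
            "age": [i.age for i in study_ped.individuals],
        },
        index=idx,
    )
    cov_cells = cov.copy()
    cov_cells[["prop_a", "prop_b", "prop_c"]] = frac
    expr = pd.DataFrame(
        2.0 * np.outer(pc, rng.uniform(0.5, 1.5, 40)) + 0.3 * rng.standard_normal((n, 40)),
        index=idx,
    )
    meth = pd.DataFrame(
        2.0 * np.outer(pc, rng.uniform(0.5, 1.5, 40)) + 0.3 * rng.standard_normal((n, 40)),
        index=idx, columns=[f"m{j}" for j in range(40)],
    )
    counts = {}
    for label, c in (("raw", cov), ("adjusted", cov_cells)):
        ra, _ = residualize(fo.FeatureMatrix(expr), c)
        rb, _ = residualize(fo.FeatureMatrix(meth), c)
        counts[label] = phenotypic_screen(ra.values, rb.values).n_significant
    assert counts["adjusted"] < counts["raw"]
    assert counts["raw"] > 0
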