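"""Maximum-likelihood variance-components decomposition for family data.

Each feature y (one value per subject, already residualized on
covariates) is modelled as multivariate normal with mean ``mu`` and
covariance

    Sigma = Vg * A + Vc * H + Ve * I

where A is the additive relationship matrix (2 x kinship), H the
household indicator, Vg the polygenic variance, Vc the common-environment
variance shared by family members, and Ve the unique-environment
variance.  The familial-effect test compares this full model against the
null Vg = Vc = 0 by likelihood ratio.

Families are mutually unrelated, so Sigma is block-diagonal by family;
fits exploit this (batched Cholesky over same-sized family blocks), which
keeps genome scans over hundreds of families fast.  The mean is profiled
out by GLS inside the likelihood.  Variances are optimized on a softplus
scale; boundary submodels (Vg=0 and/or Vc=0) are fitted explicitly and a
boundary solution wins ties, so component estimates of exactly zero --
which dominate null features -- are representable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "VarCompFit",
    "HeritabilityEstimates",
    "FamilialTest",
    "BlockStructure",
    "block_structure",
    "loglik",
    "fit_full",
    "fit_null",
    "fit_ae",
    "familial_test",
    "heritability",
    "genome_scan",
    "summarize_scan",
]

_VE_FLOOR_REL = 1e-8  # relative floor on Ve, keeps Sigma positive definite
_TIE_TOL = 1e-6  # a boundary submodel within this loglik wins


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class VarCompFit:
    vg: float
    vc: float
    ve: float
    mu: float
    loglik: float
    converged: bool
    model: str  # "full" | "null" | "ae"
    n: int = 0
    degenerate: bool = False
    message: str = ""

    def __post_init__(self):
        if min(self.vg, self.vc, self.ve) < 0:
            raise ValueError("variance components must be nonnegative")


@dataclass
class HeritabilityEstimates:
    """Variance shares: maximal heritability (Vg+Vc)/(Vg+Vc+Ve), genetic
    heritability Vg/(Vg+Vc+Ve) and common-environment share Vc/(Vg+Vc+Ve)."""

    h2_max: float
    h2_g: float
    c2: float


@dataclass
class FamilialTest:
    lrt: float
    df: int
    p: float
    p_fdr: float | None = None


# ---------------------------------------------------------------------------
# block structure
# ---------------------------------------------------------------------------


@dataclass
class BlockStructure:
    """Family blocks of (A, H) grouped by block size for batched algebra.

    ``groups`` is a list of (indices, A_stack, H_stack) with indices of
    shape (m, k) and stacks of shape (m, k, k).
    """

    n: int
    groups: list = field(default_factory=list)


def _as_matrix(M) -> np.ndarray:
    return np.asarray(getattr(M, "values", M), dtype=float)


def block_structure(A, H) -> BlockStructure:
    """Connected components of the combined relationship graph, grouped by size."""
    A = _as_matrix(A)
    H = _as_matrix(H)
    n = A.shape[0]
    adj = sparse.csr_matrix((np.abs(A) + np.abs(H)) > 1e-12)
    ncomp, labels = connected_components(adj, directed=False)
    by_size: dict[int, list[np.ndarray]] = {}
    for c in range(ncomp):
        idx = np.flatnonzero(labels == c)
        by_size.setdefault(len(idx), []).append(idx)
    bs = BlockStructure(n=n)
    for k, idx_list in sorted(by_size.items()):
        idx = np.array(idx_list)  # (m, k)
        A_stack = A[idx[:, :, None], idx[:, None, :]]
        H_stack = H[idx[:, :, None], idx[:, None, :]]
        bs.groups.append((idx, A_stack, H_stack))
    return bs


class _Likelihood:
    """Profiled (over the mean) Gaussian log-likelihood on family blocks."""

    def __init__(self, y: np.ndarray, blocks: BlockStructure):
        self.blocks = blocks
        self.n = blocks.n
        self._y = [y[idx] for idx, _, _ in blocks.groups]  # each (m, k)

    def loglik(self, vg: float, vc: float, ve: float):
        """Return (loglik maximized over mu, mu_hat); (-inf, nan) if any
        block covariance is not positive definite."""
        logdet = 0.0
        yy = y1 = oo = 0.0
        for (idx, A, H), yb in zip(self.blocks.groups, self._y):
            k = A.shape[-1]
            Sig = vg * A + vc * H + ve * np.eye(k)
            try:
                L = np.linalg.cholesky(Sig)
            except np.linalg.LinAlgError:
                return -np.inf, np.nan
            rhs = np.stack([yb, np.ones_like(yb)], axis=-1)  # (m, k, 2)
            z = np.linalg.solve(L, rhs)
            logdet += 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
            zy, z1 = z[..., 0], z[..., 1]
            yy += float((zy * zy).sum())
            y1 += float((zy * z1).sum())
            oo += float((z1 * z1).sum())
        mu = y1 / oo
        quad = yy - y1 * y1 / oo
        ll = -0.5 * (self.n * np.log(2.0 * np.pi) + logdet + quad)
        return ll, mu


def loglik(y, A, H, params) -> float:
    """Dense multivariate-normal log density of ``y`` under the model.

    ``params`` = (mu, vg, vc, ve).  Computed via Cholesky factorization of
    ``vg*A + vc*H + ve*I``; a singular covariance yields ``-inf`` rather
    than an exception so optimizers can step through it.
    """
    y = np.asarray(y, dtype=float)
    mu, vg, vc, ve = params
    n = y.shape[0]
    Sigma = vg * _as_matrix(A) + vc * _as_matrix(H) + ve * np.eye(n)
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return -np.inf
    z = np.linalg.solve(L, y - mu)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + z @ z))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _softplus(x):
    return np.logaddexp(0.0, x)


def _inv_softplus(v):
    v = max(float(v), 1e-12)
    return v + np.log1p(-np.exp(-v)) if v > 1e-8 else np.log(np.expm1(v))


def _optimize_components(lik: _Likelihood, s2: float, free: tuple[str, ...], starts):
    """Maximize the profiled likelihood over the named free components.

    ``free`` is a subset of ("vg", "vc"); ve is always free with a
    positive floor.  Returns (vg, vc, ve, mu, loglik, success).
    """
    floor = _VE_FLOOR_REL * s2

    def unpack(x):
        v = {"vg": 0.0, "vc": 0.0}
        for name, xi in zip(free, x[:-1]):
            v[name] = s2 * _softplus(xi)
        ve = floor + s2 * _softplus(x[-1])
        return v["vg"], v["vc"], ve

    def nll(x):
        ll, _ = lik.loglik(*unpack(x))
        return 1e10 if not np.isfinite(ll) else -ll

    best = None
    any_success = False
    for fracs in starts:
        x0 = np.array(
            [_inv_softplus(max(f, 1e-6)) for f in fracs[:-1]]
            + [_inv_softplus(max(fracs[-1], 1e-6))]
        )
        res = optimize.minimize(nll, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
        any_success = any_success or bool(res.success)
    vg, vc, ve = unpack(best.x)
    ll, mu = lik.loglik(vg, vc, ve)
    return vg, vc, ve, mu, ll, any_success


_FULL_STARTS = [(1 / 3, 1 / 3, 1 / 3), (0.8, 0.1, 0.1), (1e-3, 1e-3, 1.0)]
_TWO_STARTS = [(0.5, 0.5), (0.8, 0.2), (1e-3, 1.0)]


def _degenerate_fit(y, model) -> VarCompFit:
    n = len(y)
    ve = _VE_FLOOR_REL
    return VarCompFit(
        vg=0.0, vc=0.0, ve=ve, mu=float(np.mean(y)), loglik=-np.inf,
        converged=False, model=model, n=n, degenerate=True,
        message="zero-variance feature",
    )


def fit_null(y) -> VarCompFit:
    """ML fit of the no-familial-resemblance model (Vg = Vc = 0).

    Closed form: mu = sample mean, Ve = ML variance (divisor n).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mu = float(y.mean())
    s2 = float(np.mean((y - mu) ** 2))
    degenerate = s2 <= 0
    ve = max(s2, _VE_FLOOR_REL)
    ll = float(-0.5 * n * (np.log(2.0 * np.pi * ve) + s2 / ve))
    return VarCompFit(
        vg=0.0, vc=0.0, ve=ve, mu=mu, loglik=ll, converged=True,
        model="null", n=n, degenerate=degenerate,
        message="zero-variance feature" if degenerate else "",
    )


def _fit(y, A, H, blocks, model: str) -> VarCompFit:
    y = np.asarray(y, dtype=float)
    s2 = float(np.var(y))
    if s2 <= 0:
        return _degenerate_fit(y, model)
    if blocks is None:
        blocks = block_structure(A, H)
    n_blocks = sum(idx.shape[0] for idx, _, _ in blocks.groups)
    if n_blocks < 2:
        raise ValueError("need at least 2 families")
    lik = _Likelihood(y, blocks)

    # candidates in order of increasing complexity; ties go to the simpler
    null = fit_null(y)
    candidates = [("null", (0.0, 0.0, null.ve, null.mu, null.loglik, True))]
    if model == "full":
        candidates.append(("vg", _optimize_components(lik, s2, ("vg",), _TWO_STARTS)))
        candidates.append(("vc", _optimize_components(lik, s2, ("vc",), _TWO_STARTS)))
        candidates.append(
            ("vg+vc", _optimize_components(lik, s2, ("vg", "vc"), _FULL_STARTS))
        )
    else:  # ae
        candidates.append(("vg", _optimize_components(lik, s2, ("vg",), _TWO_STARTS)))

    best_ll = max(c[1][4] for c in candidates)
    for name, (vg, vc, ve, mu, ll, ok) in candidates:  # simplest adequate wins
        if ll >= best_ll - _TIE_TOL:
            return VarCompFit(
                vg=vg, vc=vc, ve=ve, mu=mu, loglik=ll, converged=bool(ok),
                model=model, n=len(y), message=f"selected {name} parameterization",
            )
    raise AssertionError("unreachable")


def fit_full(y, A, H, blocks: BlockStructure | None = None) -> VarCompFit:
    """ML fit of the full model (Vg, Vc, Ve all free, nonnegative)."""
    return _fit(y, A, H, blocks, "full")


def fit_ae(y, A, blocks: BlockStructure | None = None) -> VarCompFit:
    """ML fit of the alternative genetic (AE) model: Vc fixed at zero."""
    A = _as_matrix(A)
    H = np.eye(A.shape[0])  # unused by the AE likelihood terms (vc = 0)
    return _fit(y, A, H, blocks, "ae")


def familial_test(
    full: VarCompFit, null: VarCompFit, boundary_mixture: bool = False
) -> FamilialTest:
    """Likelihood-ratio test of the familial effect (Vg = Vc = 0).

    Default reference distribution chi-square with df = 2 (conservative at
    the boundary); ``boundary_mixture`` switches to the
    1/4 chi2_0 + 1/2 chi2_1 + 1/4 chi2_2 mixture.
    """
    if full.n != null.n:
        raise ValueError("fits are not on the same subjects")
    lrt = 2.0 * (full.loglik - null.loglik)
    if lrt < -1e-8 and np.isfinite(lrt):
        logger.warning("negative LRT %.3g clamped to 0", lrt)
    lrt = max(lrt, 0.0)
    if boundary_mixture:
        p = 0.5 * stats.chi2.sf(lrt, 1) + 0.25 * stats.chi2.sf(lrt, 2)
        if lrt == 0.0:
            p = 1.0
    else:
        p = float(stats.chi2.sf(lrt, 2))
    return FamilialTest(lrt=float(lrt), df=2, p=float(min(p, 1.0)))


def heritability(fit: VarCompFit) -> HeritabilityEstimates:
    """The three variance shares of a converged fit."""
    total = fit.vg + fit.vc + fit.ve
    if total <= 0:
        raise ValueError("all variance components are zero")
    return HeritabilityEstimates(
        h2_max=(fit.vg + fit.vc) / total, h2_g=fit.vg / total, c2=fit.vc / total
    )


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------


def genome_scan(
    fm,
    ped=None,
    *,
    A=None,
    H=None,
    boundary_mixture: bool = False,
) -> pd.DataFrame:
    """Per-feature full-model fit, familial LRT and BH-FDR across features.

    ``fm`` is a FeatureMatrix or subjects x features DataFrame of
    residuals.  Returns one row per feature with columns feature_id, vg,
    vc, ve, h2_max, h2_g, c2, lrt, df, p, p_fdr, converged,
    boundary_zero, boundary_one.  Features with non-finite values are
    skipped (logged).
    """
    from .pedigree import compute_additive, compute_household  # cycle-free
    from .preprocess import as_values_frame

    values = as_values_frame(fm)
    if ped is not None:
        A = compute_additive(ped)
        H = compute_household(ped)
    if A is None or H is None:
        raise ValueError("provide either a pedigree or both A and H")
    blocks = block_structure(A, H)
    rows = []
    for fid in values.columns:
        y = values[fid].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            logger.warning("feature %s has non-finite values; skipped", fid)
            continue
        full = fit_full(y, A, H, blocks)
        null = fit_null(y)
        test = familial_test(full, null, boundary_mixture=boundary_mixture)
        h2 = heritability(full)
        rows.append(
            {
                "feature_id": fid,
                "vg": full.vg,
                "vc": full.vc,
                "ve": full.ve,
                "h2_max": h2.h2_max,
                "h2_g": h2.h2_g,
                "c2": h2.c2,
                "lrt": test.lrt,
                "df": test.df,
                "p": test.p,
                "converged": full.converged,
                "boundary_zero": h2.h2_max <= 0.0,
                "boundary_one": h2.h2_max >= 1.0 - 1e-6,
            }
        )
    scan = pd.DataFrame(rows).set_index("feature_id")
    scan["p_fdr"] = multipletests(scan["p"].to_numpy(), method="fdr_bh")[1]
    return scan


def summarize_scan(scan: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Mean +/- SD of the heritability shares over all features, features
    with a significant familial effect, and FDR-significant features;
    plus boundary counts."""
    subsets = {
        "all": scan,
        "significant": scan[scan["p"] <= alpha],
        "fdr_significant": scan[scan["p_fdr"] <= alpha],
    }
    rows = []
    for name, sub in subsets.items():
        row = {"subset": name, "n": len(sub)}
        for col in ("h2_max", "h2_g", "c2"):
            row[f"{col}_mean"] = float(sub[col].mean()) if len(sub) else np.nan
            row[f"{col}_sd"] = float(sub[col].std(ddof=1)) if len(sub) > 1 else np.nan
        row["n_h2max_zero"] = int(sub["boundary_zero"].sum()) if len(sub) else 0
        row["n_h2max_one"] = int(sub["boundary_one"].sum()) if len(sub) else 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("subset")
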