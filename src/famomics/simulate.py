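"""Family-structured omics simulation with known ground truth.

Generates nuclear-family pedigrees and feature matrices drawn from the
same variance-components model the estimators assume: each feature is
multivariate normal with covariance Vg*A + Vc*H + Ve*I over subjects,
optionally with covariate effects, cell-type mixing and detection
p-values layered on top.  The ``study_like_config`` preset reproduces the
cohort shape of the motivating study: 48 subjects in 16 families (16
mothers, 6 fathers, 26 children), which yields 13 sibling, 26
mother-offspring, 11 father-offspring, 6 spouse and 1072 fully unrelated
pairs.  One global seed expands into independent per-stage substreams so
stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconvolution import CellSignature
from .pedigree import Individual, Pedigree, compute_additive, compute_household
from .preprocess import FeatureMatrix

__all__ = [
    "SimulationConfig",
    "CellMixConfig",
    "study_like_config",
    "generate_pedigree",
    "simulate_covariates",
    "simulate_features",
    "simulate_bivariate",
    "make_signature",
    "simulate_mixture",
    "simulate_detection",
    "simulate_annotations",
]

# per-stage substream tags (order is part of the on-disk contract)
_STAGES = {
    "pedigree": 0,
    "covariates": 1,
    "features": 2,
    "bivariate": 3,
    "mixture": 4,
    "detection": 5,
    "signature": 6,
    "annotations": 7,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGES[stage]]))


# study-like composition: (n_children, father enrolled) per family.
# Reconstructed from the published totals: 16 mothers, 6 fathers, 26
# children; 13 sibling / 37 parent-offspring / 1078 unrelated-incl-spouse
# pairs.
_STUDY_COMPOSITION = (
    (3, True), (3, True), (3, False),
    (2, True), (2, False), (2, False), (2, False),
    (1, True), (1, True), (1, True),
    (1, False), (1, False), (1, False), (1, False), (1, False), (1, False),
)


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Variance shares default to the motivating study's mean decomposition
    over all expression probes (Vg = 0.156, Vc = 0.050, Ve = 0.794); the
    paired-feature genetic correlation defaults to 0.97, the mean absolute
    genetic correlation among its significant cross-omic pairs.  Covariate
    effects default to zero (none are reported) and are switched on by the
    pipeline preset to exercise residualization.
    """

    n_families: int = 16
    children_per_family: tuple[int, ...] | None = None
    father_present: tuple[bool, ...] | None = None
    vg: float = 0.156
    vc: float = 0.050
    ve: float = 0.794
    n_features: int = 500
    beta_sex: float = 0.0
    beta_age: float = 0.0
    beta_age2: float = 0.0
    beta_batch: float = 0.0
    rho_g: float = 0.97
    rho_c: float = 0.0
    rho_e: float = 0.0
    seed: int = 2018

    def __post_init__(self):
        if min(self.vg, self.vc, self.ve) < 0:
            raise ValueError("variance components must be nonnegative")
        if self.vg + self.vc + self.ve <= 0:
            raise ValueError("total variance must be positive")
        for r in (self.rho_g, self.rho_c, self.rho_e):
            if not -1.0 <= r <= 1.0:
                raise ValueError("correlations must lie in [-1, 1]")
        if self.n_families < 1 or self.n_features < 1:
            raise ValueError("counts must be positive")

    def composition(self) -> list[tuple[int, bool]]:
        """Per-family (children, father?) pairs, cycling the defaults."""
        if self.children_per_family is not None:
            kids = list(self.children_per_family)
            if len(kids) != self.n_families:
                raise ValueError("children_per_family length != n_families")
            dads = (
                list(self.father_present)
                if self.father_present is not None
                else [True] * self.n_families
            )
            if len(dads) != self.n_families:
                raise ValueError("father_present length != n_families")
            comp = list(zip(kids, dads))
        else:
            comp = [
                _STUDY_COMPOSITION[i % len(_STUDY_COMPOSITION)]
                for i in range(self.n_families)
            ]
        for kids_i, dad_i in comp:
            if kids_i < 0:
                raise ValueError("negative child count")
        return comp


def study_like_config(n_families: int = 16, **overrides) -> SimulationConfig:
    """The study-shaped preset; larger ``n_families`` cycles the 16-family
    composition pattern (used for asymptotic parameter-recovery checks)."""
    return SimulationConfig(n_families=n_families, **overrides)


@dataclass
class CellMixConfig:
    """Cell-type mixing: Dirichlet proportions over ``n_cell_types`` and
    additive Gaussian measurement noise on the mixed profile."""

    n_cell_types: int = 6
    n_signature_features: int = 120
    alpha: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self):
        if self.n_signature_features < self.n_cell_types:
            raise ValueError("need at least as many signature features as cell types")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


# ---------------------------------------------------------------------------
# pedigree & covariates
# ---------------------------------------------------------------------------


def generate_pedigree(config: SimulationConfig) -> Pedigree:
    """Deterministic (seeded) nuclear-family pedigree.

    Mothers are always enrolled; fathers per the composition.  Parent ages
    are uniform on [30, 55] years, children on [8, 18]; child sex is
    Bernoulli(1/2).  A family whose children would have no enrolled parent
    cannot arise (the mother is always present).
    """
    rng = _rng(config.seed, "pedigree")
    individuals: list[Individual] = []
    for fi, (n_children, has_father) in enumerate(config.composition(), start=1):
        fam = f"F{fi:03d}"
        mother = f"{fam}_M"
        father = f"{fam}_F" if has_father else None
        individuals.append(
            Individual(mother, fam, None, None, "female", float(rng.uniform(30, 55)))
        )
        if has_father:
            individuals.append(
                Individual(father, fam, None, None, "male", float(rng.uniform(30, 55)))
            )
        for ci in range(1, n_children + 1):
            sex = "male" if rng.random() < 0.5 else "female"
            individuals.append(
                Individual(
                    f"{fam}_C{ci}", fam, father, mother, sex, float(rng.uniform(8, 18))
                )
            )
    return Pedigree(individuals)


def simulate_covariates(
    ped: Pedigree, config: SimulationConfig, n_batches: int = 4, n_positions: int = 12
) -> pd.DataFrame:
    """Technical covariates: microarray batch and array position assigned
    round-robin in a seeded random subject order, plus sex/age from the
    pedigree."""
    rng = _rng(config.seed, "covariates")
    n = len(ped)
    order = rng.permutation(n)
    batch = np.empty(n, dtype=int)
    position = np.empty(n, dtype=int)
    batch[order] = np.arange(n) % n_batches
    position[order] = np.arange(n) % n_positions
    return pd.DataFrame(
        {
            "sex": [ind.sex for ind in ped.individuals],
            "age": [ind.age for ind in ped.individuals],
            "batch": batch,
            "position": position,
        },
        index=list(ped.ids),
    )


# ---------------------------------------------------------------------------
# feature simulation
# ---------------------------------------------------------------------------


def _family_covariance(ped: Pedigree, vg, vc, ve) -> np.ndarray:
    A = compute_additive(ped).values
    H = compute_household(ped).values
    return vg * A + vc * H + ve * np.eye(len(ped))


def _psd_factor(Sigma: np.ndarray, what: str) -> np.ndarray:
    """Symmetric square root via eigendecomposition; exact at singular
    limits (e.g. a pure shared-environment model)."""
    w, V = np.linalg.eigh(Sigma)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError(f"{what} covariance is not positive semidefinite")
    return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_features(
    ped: Pedigree,
    config: SimulationConfig,
    covariates: pd.DataFrame | None = None,
    prefix: str = "probe",
):
    """Draw ``n_features`` i.i.d. features from N(0, Vg*A + Vc*H + Ve*I)
    and add covariate effects.

    Returns (FeatureMatrix, truth DataFrame) where truth records the
    generating (vg, vc, ve) per feature.
    """
    rng = _rng(config.seed, "features")
    n = len(ped)
    Sigma = _family_covariance(ped, config.vg, config.vc, config.ve)
    L = _psd_factor(Sigma, "feature")
    Z = rng.standard_normal((n, config.n_features))
    Y = L @ Z
    if any((config.beta_sex, config.beta_age, config.beta_age2, config.beta_batch)):
        if covariates is None:
            covariates = simulate_covariates(ped, config)
        sex = (covariates["sex"].astype(str) == "male").to_numpy(float)
        age_c = covariates["age"].to_numpy(float)
        age_c = age_c - age_c.mean()
        batch = covariates["batch"].to_numpy(float)
        effect = (
            config.beta_sex * sex
            + config.beta_age * age_c
            + config.beta_age2 * age_c**2
            + config.beta_batch * (batch - batch.mean())
        )
        Y = Y + effect[:, None]
    ids = [f"{prefix}_{i:05d}" for i in range(1, config.n_features + 1)]
    fm = FeatureMatrix(pd.DataFrame(Y, index=list(ped.ids), columns=ids))
    truth = pd.DataFrame(
        {"vg": config.vg, "vc": config.vc, "ve": config.ve}, index=ids
    )
    return fm, truth


def simulate_bivariate(ped: Pedigree, config: SimulationConfig):
    """Paired features from the two-trait variance-components model.

    Both traits use the config's (vg, vc, ve); the cross-covariance is
    rho_g*vg*A + rho_c*vc*H + rho_e*ve*I.  Returns (FeatureMatrix A-set,
    FeatureMatrix B-set, truth DataFrame); pair i is column i of each set.
    """
    rng = _rng(config.seed, "bivariate")
    n = len(ped)
    A = compute_additive(ped).values
    H = compute_household(ped).values
    own = config.vg * A + config.vc * H + config.ve * np.eye(n)
    cross = (
        config.rho_g * config.vg * A
        + config.rho_c * config.vc * H
        + config.rho_e * config.ve * np.eye(n)
    )
    Sigma = np.block([[own, cross], [cross, own]])
    try:
        L = _psd_factor(Sigma, "bivariate")
    except ValueError as exc:
        raise ValueError(
            "bivariate covariance is not positive semidefinite for "
            f"(vg={config.vg}, vc={config.vc}, ve={config.ve}, "
            f"rho_g={config.rho_g}, rho_c={config.rho_c}, rho_e={config.rho_e})"
        ) from exc
    Z = rng.standard_normal((2 * n, config.n_features))
    Y = L @ Z
    ids_a = [f"probe_{i:05d}" for i in range(1, config.n_features + 1)]
    ids_b = [f"cg_{i:07d}" for i in range(1, config.n_features + 1)]
    fa = FeatureMatrix(pd.DataFrame(Y[:n], index=list(ped.ids), columns=ids_a))
    fb = FeatureMatrix(pd.DataFrame(Y[n:], index=list(ped.ids), columns=ids_b))
    truth = pd.DataFrame(
        {
            "feature_a": ids_a,
            "feature_b": ids_b,
            "rho_g": config.rho_g,
            "rho_c": config.rho_c,
            "rho_e": config.rho_e,
        }
    )
    return fa, fb, truth


# ---------------------------------------------------------------------------
# cell mixtures & detection
# ---------------------------------------------------------------------------


def make_signature(mix: CellMixConfig, seed: int = 2018) -> CellSignature:
    """Synthetic reference signature: lognormal background with per-type
    marker features boosted, guaranteeing full column rank."""
    rng = _rng(seed, "signature")
    k = mix.n_cell_types
    m = mix.n_signature_features
    S = rng.lognormal(mean=1.0, sigma=0.4, size=(m, k))
    marker_type = np.arange(m) % k
    S[np.arange(m), marker_type] *= rng.uniform(4.0, 8.0, size=m)
    types = [f"type{j+1}" for j in range(k)]
    feats = [f"sig_{i:04d}" for i in range(1, m + 1)]
    return CellSignature(pd.DataFrame(S, index=feats, columns=types))


def simulate_mixture(
    signature: CellSignature, mix: CellMixConfig, ped: Pedigree, seed: int | None = None
):
    """Bulk profiles = signature @ proportions + Gaussian noise.

    Proportions are Dirichlet(alpha) per subject (rows sum to one
    exactly).  Returns (FeatureMatrix of bulk profiles, true proportions
    DataFrame)."""
    if signature.matrix.shape[1] != mix.n_cell_types:
        raise ValueError("signature cell-type count disagrees with CellMixConfig")
    rng = _rng(seed if seed is not None else 2018, "mixture")
    subjects = list(ped.ids)
    k = mix.n_cell_types
    alpha = np.full(k, float(mix.alpha))
    P = rng.dirichlet(alpha, size=len(subjects))
    S = signature.matrix.to_numpy()
    B = P @ S.T
    if mix.noise_sd > 0:
        B = B + rng.normal(0.0, mix.noise_sd, size=B.shape)
    bulk = FeatureMatrix(
        pd.DataFrame(B, index=subjects, columns=signature.feature_ids)
    )
    props = pd.DataFrame(P, index=subjects, columns=signature.cell_types)
    return bulk, props


def simulate_detection(
    fm: FeatureMatrix,
    detected_fraction: float = 0.384,
    threshold: float = 0.05,
    detected_subject_fraction: float = 0.9,
    undetected_subject_fraction: float = 0.1,
    seed: int = 2018,
):
    """Attach detection p-values with a designated detected feature set.

    A ``detected_fraction`` of features gets p <= threshold in exactly
    ``round(detected_subject_fraction * n)`` subjects (randomly chosen);
    the rest in ``round(undetected_subject_fraction * n)``.  With the
    defaults the downstream 25%-of-subjects rule recovers the designated
    set exactly.  Returns (FeatureMatrix with detection attached,
    designated detected feature ids)."""
    rng = _rng(seed, "detection")
    n, m = fm.values.shape
    n_det_feat = int(round(detected_fraction * m))
    det_feat = np.zeros(m, dtype=bool)
    det_feat[rng.choice(m, size=n_det_feat, replace=False)] = True
    p = np.empty((n, m))
    k_hi = int(round(detected_subject_fraction * n))
    k_lo = int(round(undetected_subject_fraction * n))
    for j in range(m):
        k = k_hi if det_feat[j] else k_lo
        col = rng.uniform(threshold + 1e-9, 1.0, size=n)
        hit = rng.choice(n, size=k, replace=False)
        col[hit] = rng.uniform(0.0, threshold, size=k)
        p[:, j] = col
    det = pd.DataFrame(p, index=fm.values.index, columns=fm.values.columns)
    out = FeatureMatrix(fm.values, det, fm.annotations)
    detected_ids = list(fm.values.columns[det_feat])
    return out, detected_ids


def simulate_annotations(
    feature_ids,
    seed: int = 2018,
    n_chromosomes: int = 22,
    chrom_length: int = 50_000_000,
    feature_length: int = 1,
    build: str = "GRCh37",
) -> pd.DataFrame:
    """Random genomic positions (0-based half-open) for a feature set."""
    rng = _rng(seed, "annotations")
    feature_ids = list(feature_ids)
    chrom = rng.integers(1, n_chromosomes + 1, size=len(feature_ids))
    start = rng.integers(0, chrom_length - feature_length, size=len(feature_ids))
    df = pd.DataFrame(
        {
            "chromosome": [f"chr{c}" for c in chrom],
            "start": start,
            "end": start + feature_length,
        },
        index=feature_ids,
    )
    df.attrs["build"] = build
    return df
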