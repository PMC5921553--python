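"""Feature-matrix container, detection filtering, normalization and
covariate residualization.

The variance-components fits downstream expect residuals: features are
detection-filtered, log/quantile normalized, then regressed on technical
and biological covariates (batch, array position, sex, age, age^2,
sex x age terms, cell-type proportions); the per-feature OLS residuals are
what gets decomposed into Vg/Vc/Ve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "as_values_frame",
    "FilterReport",
    "ResidualizeReport",
    "detection_filter",
    "normalize",
    "residualize",
    "build_design",
]


def as_values_frame(obj) -> pd.DataFrame:
    """Coerce a FeatureMatrix or DataFrame-like to a subjects x features
    DataFrame, preserving labels."""
    if isinstance(obj, FeatureMatrix):
        return obj.values
    return pd.DataFrame(obj)


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with optional detection p-values and
    genomic annotations.

    ``values``: DataFrame, index = subject ids, columns = feature ids.
    ``detection``: same-shaped DataFrame of per-measurement detection
    p-values, or None.
    ``annotations``: DataFrame indexed by feature id with columns
    ``chromosome``, ``start``, ``end`` (0-based half-open) and optionally
    ``gene``; or None.
    """

    values: pd.DataFrame
    detection: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate subject ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.detection is not None:
            self.detection = pd.DataFrame(self.detection)
            if self.detection.shape != self.values.shape or not (
                self.detection.index.equals(self.values.index)
                and self.detection.columns.equals(self.values.columns)
            ):
                raise ValueError("detection matrix must shape-match values")
        if self.annotations is not None:
            self.annotations = pd.DataFrame(self.annotations)
            missing = self.values.columns.difference(self.annotations.index)
            if len(missing):
                raise ValueError(
                    f"{len(missing)} features lack annotations (e.g. {missing[0]!r})"
                )

    @property
    def subject_ids(self):
        return list(self.values.index)

    @property
    def feature_ids(self):
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_features(self, feature_ids) -> "FeatureMatrix":
        feature_ids = list(feature_ids)
        return FeatureMatrix(
            self.values[feature_ids],
            self.detection[feature_ids] if self.detection is not None else None,
            self.annotations.loc[feature_ids] if self.annotations is not None else None,
        )

    # -- i/o ----------------------------------------------------------------
    def write(self, path):
        """Write values to TSV (subjects as rows); detection p-values, when
        present, go to a sibling file with suffix ``.detp.tsv``."""
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="subject")
        if self.detection is not None:
            self.detection.to_csv(
                path.with_suffix(".detp.tsv"), sep="\t", index_label="subject"
            )

    @classmethod
    def read(cls, path, detection_path=None, annotations=None) -> "FeatureMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        det = (
            pd.read_csv(detection_path, sep="\t", index_col=0)
            if detection_path is not None
            else None
        )
        return cls(values, det, annotations)


@dataclass
class FilterReport:
    kept: int
    total: int

    @property
    def percent(self) -> float:
        return 100.0 * self.kept / self.total if self.total else float("nan")

    def __str__(self):
        return f"{self.kept} of {self.total} features kept ({self.percent:.1f}%)"


def detection_filter(
    fm: FeatureMatrix,
    p_threshold: float = 0.05,
    subject_fraction: float = 0.25,
    direction: str = "at_most",
) -> tuple[FeatureMatrix, FilterReport]:
    """Keep features detected in at least ``subject_fraction`` of subjects.

    ``direction`` sets what "detected" means for a single measurement:
    ``"at_most"`` (expression-array convention, detection p <= threshold)
    or ``"at_least"`` (p > threshold, for platforms whose p-value is a
    detection score rather than a background-signal probability).  The
    subject-fraction comparison is inclusive.
    """
    if fm.detection is None:
        raise ValueError("detection_filter requires a detection p-value matrix")
    if direction not in ("at_most", "at_least"):
        raise ValueError(f"direction must be 'at_most' or 'at_least', got {direction!r}")
    p = fm.detection.to_numpy(dtype=float)
    detected = p <= p_threshold if direction == "at_most" else p > p_threshold
    frac = detected.mean(axis=0)
    keep = frac >= subject_fraction
    report = FilterReport(kept=int(keep.sum()), total=fm.n_features)
    logger.info("detection_filter: %s", report)
    kept_ids = fm.values.columns[keep]
    return fm.select_features(kept_ids), report


def normalize(fm: FeatureMatrix, offset: float = 1.0, log: bool = True) -> FeatureMatrix:
    """log2(x + offset) then quantile normalization across subjects.

    Each subject's sorted values are replaced by the rank-wise mean over
    subjects; tied values within a subject receive the mean of the
    reference values at the tied positions.  This is a deliberately simple
    normalization contract (the full array-specific variance-stabilizing
    pipelines need raw bead-level data); it preserves within-subject rank
    order and makes the per-rank distribution identical across subjects.
    """
    if not all(np.issubdtype(dt, np.number) for dt in fm.values.dtypes):
        raise ValueError("normalize requires numeric values")
    x = fm.values.to_numpy(dtype=float)
    if log:
        shifted = x + offset
        if np.any(shifted <= 0):
            raise ValueError(
                "log step needs values + offset > 0; increase `offset`"
            )
        x = np.log2(shifted)
    n, m = x.shape
    order = np.argsort(x, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(x, order, axis=1)
    reference = sorted_vals.mean(axis=0)
    out = np.empty_like(x)
    ranks = np.empty(m, dtype=int)
    for i in range(n):
        ranks[order[i]] = np.arange(m)
        row = reference[ranks]
        # average reference values over tied raw values
        vals, inv, counts = np.unique(x[i], return_inverse=True, return_counts=True)
        if len(vals) < m:
            sums = np.bincount(inv, weights=row)
            row = (sums / counts)[inv]
        out[i] = row
    return FeatureMatrix(
        pd.DataFrame(out, index=fm.values.index, columns=fm.values.columns),
        fm.detection,
        fm.annotations,
    )


@dataclass
class ResidualizeReport:
    design_columns: list[str]
    dropped_columns: list[str] = field(default_factory=list)


def build_design(
    covariates: pd.DataFrame,
    *,
    categorical=("batch", "position"),
    sex_col: str = "sex",
    age_col: str = "age",
    cell_cols=None,
) -> pd.DataFrame:
    """Design matrix: intercept, batch/position dummies, sex, centered age,
    age^2, sex x age, sex x age^2, and all-but-one cell-proportion columns.

    Age is centered before squaring/interacting to reduce collinearity;
    one cell column is dropped because proportions sum to one.  Missing
    covariates are simply omitted from the design.
    """
    cov = covariates.copy()
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cov))}
    for c in categorical:
        if c in cov:
            d = pd.get_dummies(cov[c].astype("category"), prefix=c, drop_first=True)
            for name in d.columns:
                cols[str(name)] = d[name].to_numpy(dtype=float)
    sex = None
    if sex_col in cov:
        raw = cov[sex_col]
        if raw.dtype == object:
            sex = (raw.astype(str).str.lower().isin(["male", "m", "1"])).to_numpy(float)
        else:
            sex = raw.to_numpy(dtype=float)
        cols["sex"] = sex
    if age_col in cov:
        age = cov[age_col].to_numpy(dtype=float)
        age_c = age - age.mean()
        cols["age"] = age_c
        cols["age2"] = age_c**2
        if sex is not None:
            cols["sex_age"] = sex * age_c
            cols["sex_age2"] = sex * age_c**2
    if cell_cols is None:
        cell_cols = [c for c in cov.columns if str(c).startswith("prop_")]
    cell_cols = list(cell_cols)
    if cell_cols:
        props = cov[cell_cols].to_numpy(dtype=float)
        if np.any(props < -1e-9):
            raise ValueError("cell proportions must be nonnegative")
        drop = cell_cols[-1]  # sum-to-one redundancy
        for c in cell_cols:
            if c != drop:
                cols[str(c)] = cov[c].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=cov.index)


def _prune_collinear(X: pd.DataFrame, tol: float = 1e-8):
    """Greedy rank pruning: drop columns that add no new rank direction."""
    keep: list[str] = []
    dropped: list[str] = []
    M = np.empty((len(X), 0))
    for name in X.columns:
        cand = np.column_stack([M, X[name].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) > M.shape[1]:
            M = cand
            keep.append(name)
        else:
            dropped.append(name)
    return X[keep], dropped


def residualize(
    fm: FeatureMatrix,
    covariates: pd.DataFrame,
    *,
    return_model: bool = False,
    **design_kwargs,
):
    """Per-feature OLS residuals against the covariate design.

    Residuals are orthogonal to every retained design column; collinear
    columns are dropped with a warning.  Raises when fewer subjects than
    retained design columns remain.
    """
    if not fm.values.index.equals(pd.Index(covariates.index)):
        covariates = covariates.loc[fm.values.index]
    X = build_design(covariates, **design_kwargs)
    X, dropped = _prune_collinear(X)
    if dropped:
        warnings.warn(f"dropped collinear design column(s): {dropped}", stacklevel=2)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"{n} subjects cannot support a {k}-column design")
    Xm = X.to_numpy(dtype=float)
    Y = fm.values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(Xm, Y, rcond=None)
    resid = Y - Xm @ beta
    report = ResidualizeReport(design_columns=list(X.columns), dropped_columns=dropped)
    out = FeatureMatrix(
        pd.DataFrame(resid, index=fm.values.index, columns=fm.values.columns),
        None,
        fm.annotations,
    )
    if return_model:
        coefs = pd.DataFrame(beta, index=X.columns, columns=fm.values.columns)
        return out, report, coefs
    return out, report
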