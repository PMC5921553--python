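"""Reference-based blood cell-type deconvolution.

Bulk profiles are modelled as nonnegative mixtures of per-cell-type
reference signatures.  Coefficients are estimated by iteratively pruned
least squares: fit OLS, drop the most-negative coefficient, refit, until
all remaining coefficients are nonnegative (the classic
microarray-deconvolution scheme), then optionally renormalize to
proportions summing to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellSignature",
    "CellProportions",
    "estimate_proportions",
    "group_proportions",
]


@dataclass
class CellSignature:
    """Signature features x cell types reference matrix."""

    matrix: pd.DataFrame  # index = feature ids, columns = cell-type names

    def __post_init__(self):
        self.matrix = pd.DataFrame(self.matrix).astype(float)
        if self.matrix.isna().any().any():
            raise ValueError("signature contains missing values")
        if self.matrix.index.has_duplicates or self.matrix.columns.has_duplicates:
            raise ValueError("duplicate feature or cell-type ids in signature")
        if np.linalg.matrix_rank(self.matrix.to_numpy()) < self.matrix.shape[1]:
            raise ValueError("signature matrix is column rank-deficient")

    @property
    def cell_types(self):
        return list(self.matrix.columns)

    @property
    def feature_ids(self):
        return list(self.matrix.index)

    def write(self, path):
        self.matrix.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def read(cls, path) -> "CellSignature":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class CellProportions:
    """Subjects x cell types coefficient matrix (proportions when the
    sum-to-one constraint was applied)."""

    matrix: pd.DataFrame

    def __post_init__(self):
        self.matrix = pd.DataFrame(self.matrix).astype(float)
        if (self.matrix.to_numpy() < -1e-10).any():
            raise ValueError("proportions must be nonnegative")

    def write(self, path):
        self.matrix.to_csv(path, sep="\t", index_label="subject")


def _pruned_nnls(S: np.ndarray, b: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Least squares with iterative removal of the most-negative coefficient."""
    k = S.shape[1]
    active = list(range(k))
    coef = np.zeros(k)
    while active:
        sol, *_ = np.linalg.lstsq(S[:, active], b, rcond=None)
        worst = int(np.argmin(sol))
        if sol[worst] >= -tol:
            coef[:] = 0.0
            coef[active] = np.clip(sol, 0.0, None)
            return coef
        del active[worst]
    return coef


def estimate_proportions(
    bulk,
    signature: CellSignature,
    constrain_sum: bool = True,
) -> CellProportions:
    """Estimate per-subject cell-type coefficients from bulk profiles.

    ``bulk`` is a FeatureMatrix or subjects x features DataFrame; it is
    restricted to the features shared with the signature (the intersection
    must be at least the number of cell types).  With ``constrain_sum``
    the nonnegative coefficients are renormalized to proportions.
    All-zero profiles yield a zero row with a warning.
    """
    from .preprocess import as_values_frame

    values = as_values_frame(bulk)
    common = values.columns.intersection(signature.matrix.index)
    k = len(signature.cell_types)
    if len(common) < k:
        raise ValueError(
            f"only {len(common)} bulk features overlap the signature; "
            f"need at least the {k} cell types"
        )
    S = signature.matrix.loc[common].to_numpy()
    B = values[common].to_numpy(dtype=float)
    out = np.zeros((B.shape[0], k))
    for i, b in enumerate(B):
        if not np.any(b):
            warnings.warn(
                f"all-zero profile for subject {values.index[i]!r}; zero row returned",
                stacklevel=2,
            )
            continue
        coef = _pruned_nnls(S, b)
        if constrain_sum:
            total = coef.sum()
            coef = coef / total if total > 0 else coef
        out[i] = coef
    return CellProportions(
        pd.DataFrame(out, index=values.index, columns=signature.cell_types)
    )


def group_proportions(props: CellProportions, grouping: dict) -> CellProportions:
    """Sum cell-type proportions into reporting classes (e.g. 17 leukocyte
    subsets into lymphocytes/neutrophils/monocytes).  Row sums are
    preserved; every cell type must be mapped."""
    unmapped = [c for c in props.matrix.columns if c not in grouping]
    if unmapped:
        raise KeyError(f"cell type(s) without a class mapping: {unmapped}")
    classes = pd.Index(dict.fromkeys(grouping[c] for c in props.matrix.columns))
    grouped = pd.DataFrame(0.0, index=props.matrix.index, columns=classes)
    for cell, cls in ((c, grouping[c]) for c in props.matrix.columns):
        grouped[cls] += props.matrix[cell]
    return CellProportions(grouped)
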