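"""Pedigree data model, relationship matrices and relative-pair summaries.

Nuclear-family pedigrees are the unit of analysis: all relationship
structure (the additive matrix ``2*kinship`` used for the polygenic
variance component and the household indicator matrix used for the
common-environment component) is derived from parent links recorded in a
LINKAGE/PED-dialect text file.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "RelationshipMatrix",
    "PairClass",
    "PedigreeError",
    "DuplicateIdError",
    "DanglingParentError",
    "PedigreeCycleError",
    "ParentSexError",
    "read_pedigree",
    "compute_additive",
    "compute_household",
    "classify_pairs",
    "pair_counts",
    "pair_correlations",
]


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class DuplicateIdError(PedigreeError):
    """An individual id occurs more than once."""


class DanglingParentError(PedigreeError):
    """A parent id does not refer to any individual in the pedigree."""


class PedigreeCycleError(PedigreeError):
    """An individual is its own ancestor."""


class ParentSexError(PedigreeError):
    """A mother is not female or a father is not male."""


_MISSING = {"", "0", "na", "nan", "none", "."}


def _norm_sex(value) -> str:
    s = str(value).strip().lower()
    if s in {"2", "f", "female"}:
        return "female"
    if s in {"1", "m", "male"}:
        return "male"
    raise PedigreeError(f"unrecognised sex code: {value!r}")


def _norm_parent(value) -> str | None:
    s = str(value).strip()
    return None if s.lower() in _MISSING else s


@dataclass(frozen=True)
class Individual:
    """One pedigree member; parents are ``None`` for founders."""

    id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "female" | "male"
    age: float

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.id!r}")
        if not np.isfinite(self.age) or self.age < 0:
            raise PedigreeError(f"invalid age {self.age!r} for {self.id!r}")


class Pedigree:
    """An ordered, validated collection of individuals.

    Subject order is fixed at construction and shared by every matrix
    derived from the pedigree.
    """

    def __init__(self, individuals):
        self.individuals: tuple[Individual, ...] = tuple(individuals)
        ids = [ind.id for ind in self.individuals]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise DuplicateIdError(f"duplicate individual id(s): {sorted(dupes)}")
        self._index = {ind.id: k for k, ind in enumerate(self.individuals)}
        self._validate()

    # -- container protocol -------------------------------------------------
    def __len__(self):
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __getitem__(self, individual_id: str) -> Individual:
        return self.individuals[self._index[individual_id]]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.individuals)

    def index_of(self, individual_id: str) -> int:
        return self._index[individual_id]

    @property
    def family_ids(self) -> tuple[str, ...]:
        """Distinct family ids in order of first appearance."""
        seen = dict.fromkeys(ind.family_id for ind in self.individuals)
        return tuple(seen)

    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for ind in self.individuals:
            fams.setdefault(ind.family_id, []).append(ind.id)
        return fams

    # -- validation ---------------------------------------------------------
    def _validate(self):
        for ind in self.individuals:
            for role, pid, want in (
                ("father", ind.father_id, "male"),
                ("mother", ind.mother_id, "female"),
            ):
                if pid is None:
                    continue
                if pid not in self._index:
                    raise DanglingParentError(
                        f"{ind.id!r} references missing {role} {pid!r}"
                    )
                parent = self[pid]
                if parent.sex != want:
                    raise ParentSexError(
                        f"{role} {pid!r} of {ind.id!r} is not {want}"
                    )
                if parent.family_id != ind.family_id:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.id!r} belongs to a different family"
                    )
        self.topological_order()  # raises PedigreeCycleError on cycles

    def topological_order(self) -> list[int]:
        """Indices with every parent before its children (Kahn's algorithm)."""
        n = len(self.individuals)
        children: dict[int, list[int]] = {i: [] for i in range(n)}
        ndeps = np.zeros(n, dtype=int)
        for i, ind in enumerate(self.individuals):
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    children[self._index[pid]].append(i)
                    ndeps[i] += 1
        queue = [i for i in range(n) if ndeps[i] == 0]
        order: list[int] = []
        while queue:
            i = queue.pop(0)
            order.append(i)
            for c in children[i]:
                ndeps[c] -= 1
                if ndeps[c] == 0:
                    queue.append(c)
        if len(order) != n:
            bad = [self.individuals[i].id for i in range(n) if ndeps[i] > 0]
            raise PedigreeCycleError(f"parent links contain a cycle through {bad}")
        return order

    # -- i/o ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": [i.family_id for i in self.individuals],
                "id": [i.id for i in self.individuals],
                "father": [i.father_id or "0" for i in self.individuals],
                "mother": [i.mother_id or "0" for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "age": [i.age for i in self.individuals],
            }
        )

    def write(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    """Read a whitespace/tab-delimited pedigree file.

    Columns: FamilyID, IndividualID, FatherID, MotherID, Sex, Age
    (LINKAGE/PED dialect; ``0`` or empty = missing parent; header optional;
    sex coded 1/2 or m/f). Subject order follows file order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 6:
        raise PedigreeError(
            f"{path}: expected 6 columns (family id father mother sex age), "
            f"got {df.shape[1]}"
        )
    first = df.iloc[0]
    try:
        float(first.iloc[5])
        _norm_sex(first.iloc[4])
    except (ValueError, PedigreeError):
        df = df.iloc[1:].reset_index(drop=True)  # header row
    individuals = [
        Individual(
            id=str(r.iloc[1]).strip(),
            family_id=str(r.iloc[0]).strip(),
            father_id=_norm_parent(r.iloc[2]),
            mother_id=_norm_parent(r.iloc[3]),
            sex=_norm_sex(r.iloc[4]),
            age=float(r.iloc[5]),
        )
        for _, r in df.iterrows()
    ]
    return Pedigree(individuals)


@dataclass
class RelationshipMatrix:
    """Symmetric subjects x subjects matrix, additive (2*kinship) or household."""

    values: np.ndarray
    ids: tuple[str, ...]
    kind: str  # "additive" | "household"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.ids = tuple(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("relationship matrix must be symmetric")
        if self.kind not in ("additive", "household"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "household":
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, [0.0, 1.0])):
                raise ValueError("household matrix entries must be 0/1")
            if not np.all(np.diag(self.values) == 1.0):
                raise ValueError("household diagonal must be 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def write(self, path):
        self.to_frame().to_csv(path, sep="\t")


def _implicit_parents(ped: Pedigree, share_unrecorded: bool):
    """Per-individual (mother, father) node indices, adding implicit
    founder parents shared by same-family children of one recorded parent.

    A child with a recorded mother but no recorded father gets an implicit
    father node keyed by (family, mother) — full sibs through an
    unenrolled parent, the situation of a family study that phenotypes the
    mother and children only.  Symmetrically for unrecorded mothers.  With
    ``share_unrecorded=False`` every missing parent is a unique unrelated
    founder (i.e. contributes nothing) and no nodes are added.
    """
    n = len(ped)
    mothers: list[int | None] = []
    fathers: list[int | None] = []
    phantoms: dict[tuple, int] = {}

    def phantom(key):
        if key not in phantoms:
            phantoms[key] = n + len(phantoms)
        return phantoms[key]

    for ind in ped.individuals:
        m = ped.index_of(ind.mother_id) if ind.mother_id is not None else None
        f = ped.index_of(ind.father_id) if ind.father_id is not None else None
        if share_unrecorded:
            if f is None and m is not None:
                f = phantom(("father", ind.family_id, ind.mother_id))
            elif m is None and f is not None:
                m = phantom(("mother", ind.family_id, ind.father_id))
        mothers.append(m)
        fathers.append(f)
    return mothers, fathers, len(phantoms)


def compute_kinship(ped: Pedigree, share_unrecorded_fathers: bool = True) -> np.ndarray:
    """Recursive kinship coefficients Phi.

    Founders are unrelated and non-inbred; Phi(i,i) = (1 + Phi(mother, father)) / 2,
    and for i a non-founder processed after its parents
    Phi(i,j) = (Phi(mother_i, j) + Phi(father_i, j)) / 2, a missing parent
    contributing 0 (an unrelated founder).  By default children of the
    same recorded mother whose father is unrecorded share one implicit
    founder father (and symmetrically), so they are full siblings; set
    ``share_unrecorded_fathers=False`` for strict unique-founder
    semantics, under which they are half siblings.
    """
    n = len(ped)
    mothers, fathers, n_ph = _implicit_parents(ped, share_unrecorded_fathers)
    total = n + n_ph
    K = np.zeros((total, total))
    order = list(range(n, total)) + ped.topological_order()  # phantoms are founders
    processed: list[int] = []
    for i in order:
        m = mothers[i] if i < n else None
        f = fathers[i] if i < n else None
        for j in processed:
            k = 0.0
            if m is not None:
                k += K[m, j]
            if f is not None:
                k += K[f, j]
            K[i, j] = K[j, i] = 0.5 * k
        kmf = K[m, f] if (m is not None and f is not None) else 0.0
        K[i, i] = 0.5 * (1.0 + kmf)
        processed.append(i)
    return K[:n, :n]


def compute_additive(
    ped: Pedigree, share_unrecorded_fathers: bool = True
) -> RelationshipMatrix:
    """Additive (numerator) relationship matrix A = 2*Phi."""
    return RelationshipMatrix(
        2.0 * compute_kinship(ped, share_unrecorded_fathers), ped.ids, "additive"
    )


def compute_household(ped: Pedigree) -> RelationshipMatrix:
    """Household indicator: 1 when two subjects share a family id."""
    fams = np.array([ind.family_id for ind in ped.individuals])
    H = (fams[:, None] == fams[None, :]).astype(float)
    return RelationshipMatrix(H, ped.ids, "household")


# ---------------------------------------------------------------------------
# relative pairs
# ---------------------------------------------------------------------------

#: classes with no natural member ordering (double-entered in summaries)
SYMMETRIC_CLASSES = frozenset({"sibling", "spouse", "unrelated"})


@dataclass(frozen=True)
class PairClass:
    """Most-specific relationship label for one unordered subject pair.

    For the asymmetric parent-offspring classes the pair is ordered
    (parent, child).
    """

    label: str
    ids: tuple[str, str]


def classify_pairs(ped: Pedigree) -> list[PairClass]:
    """Label every unordered subject pair.

    Labels: ``sibling`` (same mother and same father, including both-absent
    fathers when the mother is shared), ``mother-offspring``,
    ``father-offspring``, ``spouse`` (co-parents of at least one child),
    and ``unrelated`` otherwise.  ``parent-offspring`` is the union of the
    two offspring classes and is reported by :func:`pair_counts`.  The
    labelling targets two-generation nuclear families; more exotic
    relationships (half-sibs, grandparents) fall through to ``unrelated``.
    """
    couples = {
        (ind.mother_id, ind.father_id)
        for ind in ped.individuals
        if ind.mother_id is not None and ind.father_id is not None
    }
    out: list[PairClass] = []
    for a, b in itertools.combinations(ped.individuals, 2):
        if a.mother_id == b.id:
            out.append(PairClass("mother-offspring", (b.id, a.id)))
        elif b.mother_id == a.id:
            out.append(PairClass("mother-offspring", (a.id, b.id)))
        elif a.father_id == b.id:
            out.append(PairClass("father-offspring", (b.id, a.id)))
        elif b.father_id == a.id:
            out.append(PairClass("father-offspring", (a.id, b.id)))
        elif (
            a.mother_id is not None
            and a.mother_id == b.mother_id
            and a.father_id == b.father_id
        ):
            out.append(PairClass("sibling", (a.id, b.id)))
        elif (a.id, b.id) in couples or (b.id, a.id) in couples:
            out.append(PairClass("spouse", (a.id, b.id)))
        else:
            out.append(PairClass("unrelated", (a.id, b.id)))
    return out


def pair_counts(pairs) -> dict[str, int]:
    """Counts per class plus the derived parent-offspring union and the
    unrelated-including-spouses pool used for correlation summaries."""
    pairs = list(pairs)
    counts = Counter(p.label for p in pairs)
    out = {
        k: counts.get(k, 0)
        for k in ("sibling", "mother-offspring", "father-offspring", "spouse", "unrelated")
    }
    out["parent-offspring"] = out["mother-offspring"] + out["father-offspring"]
    out["unrelated_incl_spouse"] = out["unrelated"] + out["spouse"]
    out["total"] = len(pairs)
    return out


def _class_members(pairs, label, pool_spouses):
    if label == "parent-offspring":
        sel = [p for p in pairs if p.label in ("mother-offspring", "father-offspring")]
    elif label == "unrelated" and pool_spouses:
        sel = [p for p in pairs if p.label in ("unrelated", "spouse")]
    else:
        sel = [p for p in pairs if p.label == label]
    return sel


def _corr_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of two equally shaped matrices.

    Columns with zero variance on either side come back NaN.
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=0) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan
    return r


def pair_correlations(
    values,
    pairs,
    *,
    per_feature: bool = True,
    double_entry: bool = True,
    pool_spouses: bool = True,
    min_pairs: int = 3,
    classes=("sibling", "mother-offspring", "father-offspring", "parent-offspring", "spouse", "unrelated"),
) -> pd.DataFrame:
    """Mean +/- SD of absolute Pearson correlations between relative pairs.

    ``values`` is a subjects x features DataFrame (index = subject ids).
    Default reading (``per_feature=True``): for each feature, correlate the
    member-1 value against the member-2 value across the pairs of a class,
    then average ``|r|`` over features.  ``per_feature=False`` instead
    correlates the two members' whole profiles per pair and averages over
    pairs.  Symmetric classes (sibling, spouse, unrelated) are
    double-entered by default so the result does not depend on an arbitrary
    within-pair ordering.  Spouse pairs are pooled into ``unrelated``
    (also reported separately) unless ``pool_spouses=False``.
    """
    values = pd.DataFrame(values)
    rows = []
    for label in classes:
        sel = _class_members(pairs, label, pool_spouses)
        if len(sel) < min_pairs:
            warnings.warn(
                f"pair class {label!r} has {len(sel)} < {min_pairs} pairs; skipped",
                stacklevel=2,
            )
            continue
        i1 = [p.ids[0] for p in sel]
        i2 = [p.ids[1] for p in sel]
        x = values.loc[i1].to_numpy(dtype=float)
        y = values.loc[i2].to_numpy(dtype=float)
        if double_entry and label in SYMMETRIC_CLASSES | {"unrelated"}:
            x, y = np.vstack([x, y]), np.vstack([y, x])
        if per_feature:
            r = _corr_columns(x, y)
        else:
            r = _corr_columns(x.T, y.T)
        ok = np.isfinite(r)
        rows.append(
            {
                "class": label,
                "n_pairs": len(sel),
                "mean_abs_r": float(np.mean(np.abs(r[ok]))) if ok.any() else np.nan,
                "sd_abs_r": float(np.std(np.abs(r[ok]), ddof=1)) if ok.sum() > 1 else np.nan,
                "n_used": int(ok.sum()),
                "n_skipped": int((~ok).sum()),
            }
        )
    columns = ["class", "n_pairs", "mean_abs_r", "sd_abs_r", "n_used", "n_skipped"]
    return pd.DataFrame(rows, columns=columns).set_index("class")
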