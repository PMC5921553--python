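import numpy as np
import pytest

import famomics as fo
from famomics.pedigree import Individual, Pedigree
from famomics.varcomp import block_structure


@pytest.fixture(scope="session")
def study_ped():
    return fo.generate_pedigree(fo.study_like_config(seed=2018))


@pytest.fixture(scope="session")
def study_matrices(study_ped):
    A = fo.compute_additive(study_ped)
    H = fo.compute_household(study_ped)
    return A, H, block_structure(A, H)


@pytest.fixture
def trio_ped():
    return Pedigree(
        [
            Individual("mom", "f1", None, None, "female", 40.0),
            Individual("dad", "f1", None, None, "male", 42.0),
            Individual("kid", "f1", "dad", "mom", "male", 10.0),
        ]
    )


@pytest.fixture
def three_gen_ped():
    """Grandparents -> two parents (sibs by one shared parent) -> grandchild."""
    return Pedigree(
        [
            Individual("gm", "f1", None, None, "female", 70.0),
            Individual("gf", "f1", None, None, "male", 72.0),
            Individual("mom", "f1", "gf", "gm", "female", 40.0),
            Individual("aunt", "f1", "gf", "gm", "female", 38.0),
            Individual("halfsib", "f1", None, "gm", "male", 35.0),
            Individual("dad", "f1", None, None, "male", 41.0),
            Individual("kid", "f1", "dad", "mom", "female", 12.0),
        ]
    )


def gene_drop_kinship(ped, n_drops=100_000, seed=0, share_unrecorded=True):
    """Monte-Carlo kinship oracle: drop two unique founder alleles through
    the pedigree and estimate P(IBD) for a random allele from each of two
    individuals.  Independent of the recursive implementation.  With
    ``share_unrecorded`` a child with one recorded parent draws its other
    allele from an implicit founder shared within (family, recorded
    parent), matching the full-sibling convention."""
    rng = np.random.default_rng(seed)
    n = len(ped)
    order = ped.topological_order()
    mat = np.zeros((n, n_drops), dtype=np.int64)
    pat = np.zeros((n, n_drops), dtype=np.int64)
    next_allele = 1
    phantom_alleles = {}
    for i in order:
        ind = ped.individuals[i]
        for arr, pid, role, other in (
            (mat, ind.mother_id, "mother", ind.father_id),
            (pat, ind.father_id, "father", ind.mother_id),
        ):
            if pid is not None:
                p = ped.index_of(pid)
                pick = rng.integers(0, 2, size=n_drops, dtype=np.int64)
                arr[i] = np.where(pick == 0, mat[p], pat[p])
            elif share_unrecorded and other is not None:
                key = (role, ind.family_id, other)
                if key not in phantom_alleles:
                    a1, a2 = next_allele, next_allele + 1
                    next_allele += 2
                    pick = rng.integers(0, 2, size=n_drops, dtype=np.int64)
                    phantom_alleles[key] = (
                        np.where(pick == 0, a1, a2),
                        np.where(pick == 0, a2, a1),
                    )
                # independent meiosis from the shared implicit parent
                pick = rng.integers(0, 2, size=n_drops, dtype=np.int64)
                g1, g2 = phantom_alleles[key]
                arr[i] = np.where(pick == 0, g1, g2)
            else:
                arr[i] = next_allele  # unique founder allele
                next_allele += 1
    K = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ibd = (
                (mat[i] == mat[j]).mean()
                + (mat[i] == pat[j]).mean()
                + (pat[i] == mat[j]).mean()
                + (pat[i] == pat[j]).mean()
            ) / 4.0
            K[i, j] = K[j, i] = ibd
    return K
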