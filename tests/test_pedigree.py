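import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import famomics as fo
from famomics.pedigree import (
    DanglingParentError,
    DuplicateIdError,
    Individual,
    Pedigree,
    PedigreeCycleError,
    classify_pairs,
    compute_additive,
    compute_household,
    pair_correlations,
    pair_counts,
    read_pedigree,
)
from conftest import gene_drop_kinship


# ---------------------------------------------------------------------------
# parsing & validation
# ---------------------------------------------------------------------------


def test_read_trio_file(tmp_path):
    p = tmp_path / "trio.ped"
    p.write_text("f1 mom 0 0 2 40\nf1 dad 0 0 1 42\nf1 kid dad mom 1 10\n")
    ped = read_pedigree(p)
    assert len(ped) == 3
    assert ped["kid"].mother_id == "mom" and ped["kid"].father_id == "dad"
    assert ped["mom"].sex == "female"


def test_read_with_header_roundtrip(tmp_path, study_ped):
    p = tmp_path / "study.ped"
    study_ped.write(p)
    again = read_pedigree(p)
    assert again.ids == study_ped.ids
    assert len(again) == 48 and len(again.family_ids) == 16


@pytest.mark.parametrize(
    "rows,err,fragment",
    [
        ("f1 kid ghost 0 1 10", DanglingParentError, "ghost"),
        ("f1 a 0 0 1 10\nf1 a 0 0 1 11", DuplicateIdError, "a"),
        ("f1 a b 0 1 10\nf1 b a 0 1 11", PedigreeCycleError, None),
    ],
)
def test_validation_errors_name_offender(tmp_path, rows, err, fragment):
    p = tmp_path / "bad.ped"
    p.write_text(rows + "\n")
    with pytest.raises(err, match=fragment):
        read_pedigree(p)


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------


def test_additive_trio_entries(trio_ped):
    A = compute_additive(trio_ped).values
    m, d, k = (trio_ped.index_of(i) for i in ("mom", "dad", "kid"))
    assert A[m, k] == A[d, k] == pytest.approx(0.5)
    assert A[m, m] == A[k, k] == pytest.approx(1.0)
    assert A[m, d] == 0.0


def test_additive_three_generations(three_gen_ped):
    A = compute_additive(three_gen_ped).values
    ix = three_gen_ped.index_of
    assert A[ix("mom"), ix("aunt")] == pytest.approx(0.5)  # full sibs
    assert A[ix("gm"), ix("kid")] == pytest.approx(0.25)  # grandparent
    assert A[ix("mom"), ix("halfsib")] == pytest.approx(0.25)  # half sibs
    K = gene_drop_kinship(three_gen_ped, n_drops=200_000, seed=1)
    assert np.abs(2 * K - A).max() < 0.01


def _random_pedigree(rng, n):
    inds = []
    for i in range(n):
        sex = "male" if rng.integers(2) else "female"
        mother = father = None
        males = [x.id for x in inds if x.sex == "male"]
        females = [x.id for x in inds if x.sex == "female"]
        if females and rng.random() < 0.6:
            mother = str(rng.choice(females))
        if males and rng.random() < 0.6:
            father = str(rng.choice(males))
        inds.append(Individual(f"i{i}", "fam", father, mother, sex, 30.0))
    return Pedigree(inds)


@settings(max_examples=12, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=4, max_value=10))
def test_additive_matches_gene_dropping(seed, n):
    """Recursive kinship equals the Monte-Carlo gene-dropping oracle on
    random small pedigrees, and the additive matrix stays PSD."""
    ped = _random_pedigree(np.random.default_rng(seed), n)
    A = compute_additive(ped).values
    K = gene_drop_kinship(ped, n_drops=100_000, seed=seed + 1)
    assert np.abs(2 * K - A).max() < 0.01
    assert np.linalg.eigvalsh(A).min() >= -1e-8
    assert np.all((A >= 0) & (A <= 2))


def test_household_structure(study_ped):
    H = compute_household(study_ped)
    fam = np.array([i.family_id for i in study_ped.individuals])
    same = fam[:, None] == fam[None, :]
    assert np.array_equal(H.values.astype(bool), same)
    # block-diagonal with 16 blocks
    from scipy.sparse.csgraph import connected_components
    from scipy import sparse

    ncomp, _ = connected_components(sparse.csr_matrix(H.values), directed=False)
    assert ncomp == 16


# ---------------------------------------------------------------------------
# pair classification
# ---------------------------------------------------------------------------


def test_classify_trio(trio_ped):
    labels = {p.ids: p.label for p in classify_pairs(trio_ped)}
    assert labels[("mom", "kid")] == "mother-offspring"
    assert labels[("dad", "kid")] == "father-offspring"
    assert labels[("mom", "dad")] == "spouse"


def test_study_pair_bookkeeping(study_ped):
    counts = pair_counts(classify_pairs(study_ped))
    assert counts["total"] == 48 * 47 // 2 == 1128
    assert counts["mother-offspring"] == 26
    assert counts["sibling"] == 13
    assert counts["parent-offspring"] == 37
    assert counts["unrelated_incl_spouse"] == 1078
    assert (
        counts["sibling"] + counts["parent-offspring"] + counts["spouse"] + counts["unrelated"]
        == counts["total"]
    )


# ---------------------------------------------------------------------------
# pair correlations
# ---------------------------------------------------------------------------


def test_pair_correlations_null_closed_form(study_ped):
    """On independent features the unrelated-class mean |r| follows the
    folded-null closed form sqrt(2 / (pi * (P - 1)))."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.standard_normal((48, 800)), index=list(study_ped.ids)
    )
    pairs = classify_pairs(study_ped)
    table = pair_correlations(values, pairs)
    P = table.loc["unrelated", "n_pairs"]
    expected = np.sqrt(2.0 / (np.pi * (P - 1)))
    assert table.loc["unrelated", "mean_abs_r"] == pytest.approx(expected, rel=0.2)


def test_pair_correlations_family_signal(study_ped):
    """With half the variance polygenic, siblings correlate more than
    unrelated pairs."""
    cfg = fo.study_like_config(vg=0.5, vc=0.0, ve=0.5, n_features=500, seed=3)
    fm, _ = fo.simulate_features(study_ped, cfg)
    table = pair_correlations(fm.values, classify_pairs(study_ped))
    assert table.loc["sibling", "mean_abs_r"] > table.loc["unrelated", "mean_abs_r"]


def test_pair_correlations_zero_variance_feature(study_ped):
    rng = np.random.default_rng(0)
    values = pd.DataFrame(rng.standard_normal((48, 5)), index=list(study_ped.ids))
    values[0] = 1.0  # constant feature: correlation undefined
    table = pair_correlations(values, classify_pairs(study_ped))
    assert (table["n_skipped"] >= 1).all()
    assert (table["n_used"] == 4).all()


def test_pair_correlations_order_invariant(study_ped):
    rng = np.random.default_rng(7)
    values = pd.DataFrame(rng.standard_normal((48, 50)), index=list(study_ped.ids))
    pairs = classify_pairs(study_ped)
    base = pair_correlations(values, pairs)
    perm = values.sample(frac=1.0, random_state=1)  # relabel subject order
    again = pair_correlations(perm, pairs)
    pd.testing.assert_frame_equal(base, again)


def test_pair_correlations_skips_small_classes(trio_ped):
    values = pd.DataFrame(
        np.random.default_rng(0).standard_normal((3, 10)),
        index=["mom", "dad", "kid"],
    )
    with pytest.warns(UserWarning, match="pairs; skipped"):
        table = pair_correlations(values, classify_pairs(trio_ped))
    assert len(table) == 0
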