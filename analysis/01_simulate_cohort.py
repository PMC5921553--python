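#!/usr/bin/env python
"""Simulate the study-shaped cohort: 48 subjects in 16 nuclear families,
expression-like and methylation-like feature panels with a planted
familial fraction, detection p-values, covariates and a cell-type
mixture.  Writes everything under results/data/ for the later stages."""

from pathlib import Path

import numpy as np
import pandas as pd

import famomics as fo
from famomics import preprocess, simulate

SEED = 7
N_FEATURES = 500          # per omic, scaled down from the study's panels
PLANTED_FRACTION = 0.2    # features carrying a real familial signal
OUT = Path("results/data")


def simulate_omic(ped, cov, prefix, seed):
    n_planted = int(PLANTED_FRACTION * N_FEATURES)
    planted_cfg = fo.study_like_config(
        n_features=n_planted, vg=0.5, vc=0.3, ve=0.2,
        beta_sex=0.3, beta_age=0.02, beta_batch=0.3, seed=seed,
    )
    null_cfg = fo.study_like_config(
        n_features=N_FEATURES - n_planted, vg=0.0, vc=0.0, ve=1.0,
        beta_sex=0.3, beta_age=0.02, beta_batch=0.3, seed=seed + 1000,
    )
    fm_p, _ = simulate.simulate_features(ped, planted_cfg, cov, prefix=prefix)
    fm_n, _ = simulate.simulate_features(ped, null_cfg, cov, prefix=prefix)
    fm_n.values.columns = [f"{prefix}_null_{i:05d}" for i in range(fm_n.n_features)]
    values = pd.concat([fm_p.values, fm_n.values], axis=1)
    raw = preprocess.FeatureMatrix(2.0 ** (values + 8.0))  # array-intensity scale
    raw, detected = simulate.simulate_detection(raw, detected_fraction=0.384, seed=seed)
    truth = pd.DataFrame(
        {"planted": values.columns.isin(fm_p.values.columns)}, index=values.columns
    )
    return raw, truth


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    ped = fo.generate_pedigree(fo.study_like_config(seed=SEED))
    ped.write(OUT / "pedigree.ped")
    counts = fo.pair_counts(fo.classify_pairs(ped))
    print(f"pedigree: {len(ped)} subjects, {len(ped.family_ids)} families")
    print(f"  sibling pairs {counts['sibling']}, mother-offspring "
          f"{counts['mother-offspring']}, parent-offspring {counts['parent-offspring']}, "
          f"unrelated (incl. spouses) {counts['unrelated_incl_spouse']}")

    cov = simulate.simulate_covariates(ped, fo.study_like_config(seed=SEED))
    cov.to_csv(OUT / "covariates.tsv", sep="\t", index_label="subject")

    for omic, prefix, seed in (("expression", "probe", SEED), ("methylation", "cg", SEED + 1)):
        raw, truth = simulate_omic(ped, cov, prefix, seed)
        raw.write(OUT / f"{omic}.tsv")
        truth.to_csv(OUT / f"{omic}.truth.tsv", sep="\t", index_label="feature")
        print(f"{omic}: {raw.n_features} features "
              f"({int(truth['planted'].sum())} planted familial)")

    mix = simulate.CellMixConfig()
    sig = simulate.make_signature(mix, seed=SEED)
    sig.write(OUT / "cell_signature.tsv")
    bulk, props = simulate.simulate_mixture(sig, mix, ped, seed=SEED)
    bulk.write(OUT / "cell_bulk.tsv")
    props.to_csv(OUT / "cell_true_proportions.tsv", sep="\t", index_label="subject")
    print(f"cell mixture: {mix.n_cell_types} types, "
          f"{mix.n_signature_features} signature features")


if __name__ == "__main__":
    main()
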