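#!/usr/bin/env python
"""Cross-omic analysis on features with a significant familial effect:
Fisher-Z phenotypic correlation screen with Bonferroni control, then
bivariate genetic correlations for the top pairs."""

from pathlib import Path

import pandas as pd

import famomics as fo
from famomics import preprocess, varcomp
from famomics.correlation import genetic_correlation, phenotypic_screen

OUT = Path("results")
ALPHA = 0.05
N_BIVARIATE = 15


def main():
    ped = fo.read_pedigree(OUT / "data/pedigree.ped")
    resid, sig_ids = {}, {}
    for omic in ("expression", "methylation"):
        resid[omic] = preprocess.FeatureMatrix.read(
            OUT / f"preprocess/{omic}.residuals.tsv"
        )
        scan = pd.read_csv(OUT / f"scan_{omic}.tsv", sep="\t", index_col=0)
        sig_ids[omic] = scan.index[scan["p"] <= ALPHA]

    a = resid["expression"].values[list(sig_ids["expression"])]
    b = resid["methylation"].values[list(sig_ids["methylation"])]
    screen = phenotypic_screen(a, b, alpha=ALPHA, report_threshold=ALPHA / 100)
    screen.pairs.to_csv(OUT / "phenotypic_pairs.tsv", sep="\t", index=False)
    print(f"screen: {a.shape[1]} x {b.shape[1]} features = {screen.m_total} tests, "
          f"Bonferroni threshold {screen.bonferroni_threshold:.3g}")
    print(f"  {screen.n_significant} pairs pass Bonferroni")

    A = fo.compute_additive(ped)
    H = fo.compute_household(ped)
    blocks = varcomp.block_structure(A, H)
    top = screen.pairs.nsmallest(min(N_BIVARIATE, len(screen.pairs)), "p")
    rows = []
    for _, pr in top.iterrows():
        fit = genetic_correlation(
            resid["expression"].values[pr.feature_a].to_numpy(),
            resid["methylation"].values[pr.feature_b].to_numpy(),
            A, H, blocks,
        )
        rows.append({
            "feature_a": pr.feature_a, "feature_b": pr.feature_b,
            "r_phenotypic": pr.r, "rho_g": fit.rho_g, "rho_c": fit.rho_c,
            "rho_e": fit.rho_e, "p_rho_g": fit.p_rho_g,
            "converged": fit.converged, "reason": fit.reason,
        })
    bivar = pd.DataFrame(rows)
    bivar.to_csv(OUT / "genetic_correlations.tsv", sep="\t", index=False)
    if len(bivar):
        conv = bivar[bivar.converged & bivar.rho_g.notna()]
        print(f"bivariate fits: {len(conv)}/{len(bivar)} converged with a defined rho_g")
        if len(conv):
            print(f"  mean |rho_g| of converged fits: {conv.rho_g.abs().mean():.2f}, "
                  f"{int((conv.p_rho_g <= ALPHA).sum())} significant at p <= {ALPHA}")
    else:
        print("bivariate fits: no screened pairs to follow up")


if __name__ == "__main__":
    main()
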