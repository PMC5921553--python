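#!/usr/bin/env python
"""Detection-filter, normalize, deconvolve and residualize the simulated
cohort.  Residuals (the inputs of the variance-components fits) go to
results/preprocess/."""

from pathlib import Path

import numpy as np
import pandas as pd

from famomics import deconvolution, preprocess

DATA = Path("results/data")
OUT = Path("results/preprocess")

GROUPING = {  # six simulated leukocyte types -> three reporting classes
    "type1": "lymphocytes", "type2": "lymphocytes", "type3": "lymphocytes",
    "type4": "lymphocytes", "type5": "monocytes", "type6": "neutrophils",
}


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cov = pd.read_csv(DATA / "covariates.tsv", sep="\t", index_col=0)

    sig = deconvolution.CellSignature.read(DATA / "cell_signature.tsv")
    bulk = preprocess.FeatureMatrix.read(DATA / "cell_bulk.tsv")
    props = deconvolution.estimate_proportions(bulk, sig)
    grouped = deconvolution.group_proportions(props, GROUPING)
    grouped.write(OUT / "cell_proportions.tsv")
    true_props = pd.read_csv(DATA / "cell_true_proportions.tsv", sep="\t", index_col=0)
    mae = np.abs(props.matrix.to_numpy() - true_props.to_numpy()).mean()
    print(f"deconvolution: mean absolute error per proportion {mae:.4f}")

    cov_full = cov.join(grouped.matrix.add_prefix("prop_"))
    for omic in ("expression", "methylation"):
        fm = preprocess.FeatureMatrix.read(
            DATA / f"{omic}.tsv", DATA / f"{omic}.detp.tsv"
        )
        fm, rep = preprocess.detection_filter(fm, 0.05, 0.25)
        print(f"{omic}: {rep}")
        fm = preprocess.normalize(fm)
        resid, rrep = preprocess.residualize(fm, cov_full)
        resid.write(OUT / f"{omic}.residuals.tsv")
        print(f"  residualized on {len(rrep.design_columns)} design columns"
              + (f" (dropped {rrep.dropped_columns})" if rrep.dropped_columns else ""))


if __name__ == "__main__":
    main()
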