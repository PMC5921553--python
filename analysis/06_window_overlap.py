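#!/usr/bin/env python
"""How often do familially significant methylation sites fall near
familially significant transcripts?  Counts CpG sites within +/-2 kb and
+/-5 kb of extended transcript regions (simulated annotations)."""

from pathlib import Path

import pandas as pd

from famomics.pipeline import window_overlap
from famomics.simulate import simulate_annotations

OUT = Path("results")
SEED = 7


def main():
    sig = {}
    for omic in ("expression", "methylation"):
        scan = pd.read_csv(OUT / f"scan_{omic}.tsv", sep="\t", index_col=0)
        sig[omic] = scan.index[scan["p"] <= 0.05]
    tx = simulate_annotations(sig["expression"], seed=SEED, feature_length=2000)
    cg = simulate_annotations(sig["methylation"], seed=SEED + 1)
    rows = {}
    for kb in (2, 5):
        per_chrom, total = window_overlap(tx, cg, window_bp=kb * 1000)
        rows[f"within_{kb}kb"] = per_chrom
        print(f"+/-{kb} kb: {total} of {len(cg)} significant CpG-like sites "
              f"overlap {len(tx)} significant transcript regions")
    pd.DataFrame(rows).to_csv(OUT / "window_overlap.tsv", sep="\t")


if __name__ == "__main__":
    main()
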