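#!/usr/bin/env python
"""PCA ordination of the normalized profiles and the gradient test.

Ordinates the study's strains in normalized motif-abundance space, writes
the PC scores and explained-variance fractions, and runs the euclidean
distance-to-fungi test: a "gradient" verdict means non-planctomycete
bacteria sit farther from the fungal centroid than planctomycetes do, i.e.
the planctomycete abundance profiles are intermediate.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import pandas as pd

from nlscan.gradient import gradient_test, pca
from nlscan.proteome import read_metadata

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    x = pd.read_csv(ROOT / "normalized.tsv", sep="\t", index_col="motif")
    meta = read_metadata(ROOT / "study" / "metadata.tsv")

    ordination = pca(x)
    ordination.scores.to_csv(ROOT / "pca_scores.tsv", sep="\t",
                             index_label="strain_id", float_format="%.6g")
    pd.DataFrame(
        {"component": ordination.scores.columns,
         "explained_variance_ratio": ordination.explained_variance_ratio}
    ).to_csv(ROOT / "pca_variance.tsv", sep="\t", index=False,
             float_format="%.6g")
    evr = ordination.explained_variance_ratio
    print(f"PC1 explains {evr[0]:.1%}, PC2 {evr[1]:.1%} of profile variance")

    report = gradient_test(x, meta)
    (ROOT / "gradient_report.json").write_text(
        json.dumps({"group_distances": report.group_distances,
                    "verdict": report.verdict}, indent=2, sort_keys=True) + "\n")
    print("mean euclidean distance to the fungal centroid, by group:")
    for group, dist in sorted(report.group_distances.items(), key=lambda kv: -kv[1]):
        print(f"  {group:16s} {dist:.3f}")
    print(f"verdict: {report.verdict}")


if __name__ == "__main__":
    main()
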