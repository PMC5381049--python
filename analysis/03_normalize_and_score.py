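#!/usr/bin/env python
"""Q-normalize the abundance matrix and complexity-score the motifs.

Divides each strain's counts by log10(N_i * G_i), writes the normalized
matrix and the per-strain Q profile, then scores every motif on length,
diversity and origin and writes the score table sorted from simple to
complex.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import pandas as pd

from nlscan.dialect import fixture_motifs
from nlscan.proteome import read_metadata
from nlscan.scan import AbundanceMatrix
from nlscan.scoring import normalize_matrix, q_index, score_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    meta = read_metadata(ROOT / "study" / "metadata.tsv")
    counts = pd.read_csv(ROOT / "abundance.tsv", sep="\t", index_col="motif")
    totals = pd.read_csv(ROOT / "abundance_summary.tsv", sep="\t",
                         index_col="strain_id")["bearing_proteins"]
    a = AbundanceMatrix(counts=counts, bearing_totals=totals)

    normalized = normalize_matrix(a, meta)
    normalized.to_csv(ROOT / "normalized.tsv", sep="\t", index_label="motif",
                      float_format="%.6g")

    by_id = {m.strain_id: m for m in meta}
    q = pd.Series(
        {
            sid: q_index(int(totals[sid]), by_id[sid].gene_count,
                         by_id[sid].genome_size_bp)
            for sid in counts.columns
        },
        name="Q",
    ).sort_index()
    q.to_csv(ROOT / "q_profile.tsv", sep="\t", index_label="strain_id",
             float_format="%.6g")
    print("per-strain Q index (bearing proteins / log10(N*G)):")
    print(q.round(3).to_string())

    scores = score_table(fixture_motifs(), a, meta)
    scores.to_csv(ROOT / "complexity_scores.tsv", sep="\t", index=False,
                  float_format="%.6g")
    print("\nmotifs from simple to complex (length + diversity + origin):")
    print(scores.to_string(index=False))


if __name__ == "__main__":
    main()
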