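#!/usr/bin/env python
"""Generate the synthetic comparative study used by the downstream analyses.

Four taxonomic groups (non-planctomycete bacteria, planctomycetes, archaea,
fungi) with planted per-motif carrier rates that mirror the qualitative
presence/absence structure of a real NLS survey: simple basic motifs shared
by all bacteria, two motifs private to planctomycetes, three private to
fungi, and a bipartite motif present everywhere.  Writes one FASTA per
strain, the metadata TSV and the planted ground truth under
results/study/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from nlscan.proteome import write_fasta, write_metadata
from nlscan.simulate import generate_study, study_preset

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    profiles = study_preset(n_strains=5, proteins_per_strain=100)
    proteomes, meta, truth = generate_study(profiles, seed=SEED)
    for proteome in proteomes:
        write_fasta(list(proteome.proteins), OUT / f"{proteome.metadata.strain_id}.fasta")
    write_metadata(meta, OUT / "metadata.tsv")
    truth_json = {
        sid: [
            {"protein_id": s.protein_id, "motif": s.motif, "offset": s.offset}
            for s in sites
        ]
        for sid, sites in sorted(truth.sites.items())
    }
    (OUT / "truth.json").write_text(json.dumps(truth_json, indent=2) + "\n")
    n_prot = sum(len(p.proteins) for p in proteomes)
    n_planted = sum(len(v) for v in truth.sites.values())
    print(f"wrote {len(proteomes)} strains ({n_prot} proteins) to {OUT}")
    print(f"planted {n_planted} motif carriers (ground truth in truth.json)")


if __name__ == "__main__":
    main()
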