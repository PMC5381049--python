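#!/usr/bin/env python
"""Cluster NLS-bearing proteins into families and summarise group sharing.

Two parts.  First, the motif-bearing proteins of the simulated study are
clustered with k-mer-cosine + MCL: since their backgrounds are independent
random sequences, they form (as they should) almost exclusively orphan
families — a negative control showing the clustering does not hallucinate
structure.  Second, a planted-family fixture (mutated copies of common
ancestors distributed across groups, with motifs planted per group) runs the
full family logic: recovery of the planted partition, the Venn-style
group-sharing counts and the motif-transition classification with its
complexity ranges.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import numpy as np

from nlscan.dialect import fixture_motifs, scan_sequence
from nlscan.families import (
    family_motif_transition,
    group_sharing,
    mcl,
    pairwise_similarity,
)
from nlscan.proteome import ProteinRecord, StrainProteome, read_fasta, read_metadata
from nlscan.scan import AbundanceMatrix, bearing_proteins
from nlscan.scoring import score_table
from nlscan.simulate import generate_family_fixture

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1042


def study_part() -> None:
    meta = read_metadata(ROOT / "study" / "metadata.tsv")
    by_id = {m.strain_id: m for m in meta}
    proteomes = [
        StrainProteome(metadata=by_id[p.stem], proteins=tuple(read_fasta(p)))
        for p in sorted((ROOT / "study").glob("*.fasta"))
    ]
    motifs = fixture_motifs()
    bearing: list[ProteinRecord] = []
    for proteome in proteomes:
        ids = set()
        for motif in motifs:
            ids |= bearing_proteins(proteome, motif)
        bearing.extend(r for r in proteome.proteins if r.protein_id in ids)
    part = mcl(pairwise_similarity(bearing))
    part.to_frame().to_csv(ROOT / "families.tsv", sep="\t", index=False)
    n_orphan = len(part.orphans)
    print(f"study: {len(bearing)} bearing proteins -> {len(part.families)} "
          f"families, {n_orphan} orphans")
    print("(independent random backgrounds should be nearly all orphans: "
          f"{'yes' if n_orphan >= 0.95 * len(part.families) else 'NO'})")


def fixture_part() -> None:
    designs = (
        ("bacteria", "bacteria", "planctomycetes"),          # same motif
        ("bacteria", "planctomycetes", "planctomycetes"),    # motif turnover
        ("planctomycetes", "fungi", "fungi"),                # reaches eukaryotes
        ("archaea", "planctomycetes"),
        ("fungi", "fungi", "fungi"),
    )
    proteins, meta, truth = generate_family_fixture(seed=SEED, family_designs=designs)
    part = mcl(pairwise_similarity(proteins))
    recovered = set(part.families.values()) >= set(truth.families.values())
    print(f"\nfixture: planted {len(truth.families)} families, "
          f"recovered exactly: {recovered}")

    sharing = group_sharing(part, proteins, meta)
    sharing_json = {
        "+".join(sorted(c)): {"families": v[0], "proteins": v[1]}
        for c, v in sorted(sharing.combination_counts.items(),
                           key=lambda kv: sorted(kv[0]))
    }
    (ROOT / "group_sharing.json").write_text(
        json.dumps(sharing_json, indent=2, sort_keys=True) + "\n")
    print("group sharing (families; proteins):")
    for combo, v in sharing_json.items():
        print(f"  {combo}: {v['families']}; {v['proteins']}")

    # Plant a motif per member according to its group, then classify the
    # cross-group families by motif conservation vs. turnover.
    group_motif = {"bacteria": "PRRRK", "archaea": "RKRKK",
                   "planctomycetes": "KR.{10}KKKL",
                   "fungi": "K[RK]{3,5}.{11,18}[RK]K.{2,3}K"}
    motifs = fixture_motifs()
    by_text = {m.source_text: m for m in motifs}
    group_of = {m.strain_id: m.group for m in meta}
    rng = np.random.default_rng(SEED)

    def sample_expansion(pattern) -> str:
        chars = []
        for e in pattern.elements:
            pool = sorted(e.residues) if e.residues else sorted("ACDEFGHIKLMNPQRSTVWY")
            r = int(rng.integers(e.repeat_min, e.repeat_max + 1))
            chars.extend(pool[int(rng.integers(len(pool)))] for _ in range(r))
        return "".join(chars)

    planted: list[ProteinRecord] = []
    same_motif_family = truth.families["fam01"]
    for rec in proteins:
        grp = group_of[rec.strain_id]
        text = "PRRRK" if rec.protein_id in same_motif_family else group_motif[grp]
        exp = sample_expansion(by_text[text])
        planted.append(ProteinRecord(rec.protein_id, rec.strain_id,
                                     exp + rec.sequence[len(exp):]))
    hits = {
        r.protein_id: {m.source_text for m in motifs if scan_sequence(m, r.sequence)}
        for r in planted
    }
    counts = pd.DataFrame(0, index=[m.source_text for m in motifs],
                          columns=[m.strain_id for m in meta])
    for r in planted:
        for text in hits[r.protein_id]:
            counts.loc[text, r.strain_id] += 1
    a = AbundanceMatrix(counts=counts, bearing_totals=counts.sum(axis=0))
    composite = dict(zip(*(lambda t: (t["motif"], t["composite"]))(
        score_table(motifs, a, meta))))
    transitions = family_motif_transition(part, hits, planted, meta, composite)
    transitions.to_csv(ROOT / "family_transitions.tsv", sep="\t", index=False,
                       float_format="%.6g")
    print("\ncross-group family classification:")
    print(transitions.to_string(index=False))


def main() -> None:
    study_part()
    fixture_part()


if __name__ == "__main__":
    main()
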