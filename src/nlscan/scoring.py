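"""Q-index normalization and the three-component motif-complexity score.

Two quantities live here:

* the **Q index**, Q_i = M_i / log10(N_i * G_i): a strain's NLS-bearing
  protein count M_i normalized by the (log) product of its gene count N_i
  and genome size G_i in bp, so strains of very different genome scale can
  be compared.  The larger Q, the more motif-bearing proteins a strain
  harbors relative to its genomic capacity.
* the **complexity score** of a motif: length + diversity + origin, used to
  arrange motifs from simple to complex.
    - length: nominal residue length of the motif;
    - diversity: number of distinct residue letters, plus a reward of +1
      per wildcard element and +0.5 per residue-class element;
    - origin: 0 for motifs confined to planctomycetes (the control group)
      or absent everywhere; -5 for motifs found only in non-planctomycete
      prokaryotes; 5 + (mean eukaryotic abundance)/10 for motifs detected
      in at least one eukaryotic (fungal) strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .dialect import MotifPattern, nominal_length
from .proteome import EUKARYOTE_GROUPS, StrainMetadata
from .scan import AbundanceMatrix

__all__ = [
    "QProfile",
    "ComplexityScore",
    "q_index",
    "q_profiles",
    "normalize_matrix",
    "diversity_score",
    "origin_score",
    "complexity",
    "score_table",
]


@dataclass(frozen=True)
class QProfile:
    strain_id: str
    M: int
    Q: float


@dataclass(frozen=True)
class ComplexityScore:
    motif: str
    length_score: int
    diversity_score: float
    origin_score: float

    @property
    def composite(self) -> float:
        return self.length_score + self.diversity_score + self.origin_score


def q_index(M: int, N: int, G: int) -> float:
    """Q = M / log10(N * G).

    ``N`` is the gene count, ``G`` the genome size in bp.  Requires
    N * G > 1 so the denominator is positive.
    """
    if N < 1 or G < 1 or N * G <= 1:
        raise ValueError(f"invalid normalization denominator: N={N}, G={G}")
    return M / math.log10(N * G)


def q_profiles(a: AbundanceMatrix, meta: list[StrainMetadata]) -> list[QProfile]:
    """Per-strain Q index from bearing-protein totals and metadata."""
    by_id = {m.strain_id: m for m in meta}
    out = []
    for sid in a.strains:
        if sid not in by_id:
            raise ValueError(f"no metadata for strain {sid!r}")
        m = by_id[sid]
        M = int(a.bearing_totals[sid])
        out.append(QProfile(strain_id=sid, M=M, Q=q_index(M, m.gene_count, m.genome_size_bp)))
    return out


def normalize_matrix(a: AbundanceMatrix, meta: list[StrainMetadata]) -> pd.DataFrame:
    """Apply the Q normalization per motif: divide each strain's column of
    counts by log10(N_i * G_i)."""
    by_id = {m.strain_id: m for m in meta}
    missing = [sid for sid in a.strains if sid not in by_id]
    if missing:
        raise ValueError(f"no metadata for strain(s) {missing}")
    denom = pd.Series(
        {
            sid: math.log10(by_id[sid].gene_count * by_id[sid].genome_size_bp)
            for sid in a.strains
        }
    )
    return a.counts.div(denom, axis=1)


def diversity_score(p: MotifPattern) -> float:
    """Residue-type diversity with wildcard/class rewards.

    Counts distinct residue letters appearing in literals or classes, then
    rewards structural flexibility: +1 per wildcard element, +0.5 per class
    element.
    """
    letters: set[str] = set()
    wildcards = 0
    classes = 0
    for e in p.elements:
        if e.kind == "wildcard":
            wildcards += 1
        elif e.kind == "residue_class":
            classes += 1
            letters |= e.residues
        else:
            letters |= e.residues
    return len(letters) + 1.0 * wildcards + 0.5 * classes


def origin_score(
    p: MotifPattern, a: AbundanceMatrix, meta: list[StrainMetadata]
) -> float:
    """Evolutionary-origin component of the complexity score.

    Planctomycetes are the control (0).  Presence in any eukaryotic strain
    earns 5 plus one tenth of the motif's mean abundance over all eukaryotic
    strains (zeros included).  Presence confined to non-planctomycete
    prokaryotes (bacteria or archaea, never planctomycetes or eukaryotes) is
    penalised at -5 regardless of abundance.
    """
    name = p.source_text
    if name not in a.counts.index:
        raise ValueError(f"motif {name!r} not present in abundance matrix")
    by_id = {m.strain_id: m for m in meta}
    row = a.counts.loc[name]
    present_groups = {
        by_id[sid].group for sid in a.strains if row[sid] > 0
    }
    eukaryote = set(EUKARYOTE_GROUPS)
    if present_groups & eukaryote:
        euk_strains = [sid for sid in a.strains if by_id[sid].group in eukaryote]
        return 5.0 + float(row[euk_strains].mean()) / 10.0
    if present_groups and "planctomycetes" not in present_groups:
        return -5.0
    return 0.0


def complexity(
    p: MotifPattern, a: AbundanceMatrix, meta: list[StrainMetadata]
) -> ComplexityScore:
    """Assemble the per-motif complexity score (length + diversity + origin)."""
    return ComplexityScore(
        motif=p.source_text,
        length_score=nominal_length(p),
        diversity_score=diversity_score(p),
        origin_score=origin_score(p, a, meta),
    )


def score_table(
    motifs: list[MotifPattern], a: AbundanceMatrix, meta: list[StrainMetadata]
) -> pd.DataFrame:
    """Score every motif and sort ascending by composite (simple -> complex).

    Ties broken by motif text so the ordering is deterministic.
    """
    scores = [complexity(p, a, meta) for p in motifs]
    df = pd.DataFrame(
        [
            (s.motif, s.length_score, s.diversity_score, s.origin_score, s.composite)
            for s in scores
        ],
        columns=["motif", "length", "diversity", "origin", "composite"],
    )
    return df.sort_values(["composite", "motif"], kind="mergesort").reset_index(drop=True)
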