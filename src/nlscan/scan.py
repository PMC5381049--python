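"""Motif x strain abundance matrices of NLS- and NES-bearing proteins.

Abundance here counts *bearing proteins*: a protein carrying five occurrences
of a motif contributes one to that motif's count, and a protein carrying
several different motifs contributes one to each motif's count but only once
to the strain total M_i (the union over motifs of distinct bearing proteins).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .dialect import MotifPattern, nes_consensus, scan_sequence
from .proteome import StrainProteome

__all__ = ["AbundanceMatrix", "bearing_proteins", "abundance_matrix", "nes_scan"]


@dataclass(frozen=True)
class AbundanceMatrix:
    """Counts of motif-bearing proteins per strain.

    ``counts`` is a motif x strain integer DataFrame (rows indexed by motif
    source text, columns by strain id, both in input order);
    ``bearing_totals`` holds M_i, the number of distinct proteins in strain i
    bearing at least one match of *any* motif.
    """

    counts: pd.DataFrame
    bearing_totals: pd.Series

    @property
    def motifs(self) -> list[str]:
        return list(self.counts.index)

    @property
    def strains(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def nls_types(self) -> pd.Series:
        """Per-strain number of motif types with at least one bearing protein."""
        return (self.counts > 0).sum(axis=0).rename("nls_types")

    def summary(self) -> pd.DataFrame:
        """Per-strain summary: M_i and motif-type count."""
        return pd.DataFrame(
            {"bearing_proteins": self.bearing_totals, "nls_types": self.nls_types}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="motif")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceMatrix":
        """Load a counts TSV; bearing totals are unrecoverable from the matrix
        alone and are reloaded as the (upper-bound) column sums."""
        counts = pd.read_csv(path, sep="\t", index_col="motif")
        return cls(counts=counts, bearing_totals=counts.sum(axis=0).rename("M"))


def bearing_proteins(proteome: StrainProteome, pattern: MotifPattern) -> set[str]:
    """Ids of proteins in the strain with >= 1 match of ``pattern``."""
    return {
        rec.protein_id
        for rec in proteome.proteins
        if scan_sequence(pattern, rec.sequence)
    }


def abundance_matrix(
    proteomes: list[StrainProteome], motifs: list[MotifPattern]
) -> AbundanceMatrix:
    """Scan every strain with every motif and tabulate bearing-protein counts."""
    if not proteomes or not motifs:
        raise ValueError("need at least one strain and one motif")
    motif_names = [m.source_text for m in motifs]
    strain_ids = [p.metadata.strain_id for p in proteomes]
    counts = pd.DataFrame(0, index=motif_names, columns=strain_ids, dtype=int)
    totals = pd.Series(0, index=strain_ids, dtype=int, name="M")
    for proteome in proteomes:
        sid = proteome.metadata.strain_id
        union: set[str] = set()
        for motif in motifs:
            ids = bearing_proteins(proteome, motif)
            counts.loc[motif.source_text, sid] = len(ids)
            union |= ids
        totals[sid] = len(union)
    return AbundanceMatrix(counts=counts, bearing_totals=totals)


def nes_scan(proteomes: list[StrainProteome]) -> dict[str, set[str]]:
    """Per-strain ids of proteins bearing the leucine-rich NES consensus."""
    consensus = nes_consensus()
    return {
        p.metadata.strain_id: bearing_proteins(p, consensus) for p in proteomes
    }
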