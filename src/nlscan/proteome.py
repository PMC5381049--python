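"""Protein FASTA pools and strain metadata tables.

A study is a set of strains; each strain contributes a predicted protein
pool (one FASTA file) and one metadata row giving its taxonomic group,
genome size G_i (bp) and gene count N_i — the quantities entering the
Q-index denominator log10(N_i * G_i).  Metadata travels in a separate TSV
because genome size and gene count come from genome reports, not from the
FASTA itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GROUPS",
    "ProteinRecord",
    "StrainMetadata",
    "StrainProteome",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
]

#: Recognised taxonomic group labels.
GROUPS = ("bacteria", "planctomycetes", "archaea", "fungi")

#: Group labels counted as eukaryotic.
EUKARYOTE_GROUPS = ("fungi",)


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    strain_id: str
    sequence: str


@dataclass(frozen=True)
class StrainMetadata:
    strain_id: str
    group: str
    genome_size_bp: int
    gene_count: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group {self.group!r} for strain {self.strain_id}; "
                f"expected one of {GROUPS}"
            )
        if self.gene_count < 1:
            raise ValueError(f"strain {self.strain_id}: gene_count must be >= 1")
        if self.genome_size_bp < 1:
            raise ValueError(f"strain {self.strain_id}: genome_size_bp must be >= 1")


@dataclass(frozen=True)
class StrainProteome:
    metadata: StrainMetadata
    proteins: tuple[ProteinRecord, ...]

    def __post_init__(self) -> None:
        for rec in self.proteins:
            if rec.strain_id != self.metadata.strain_id:
                raise ValueError(
                    f"protein {rec.protein_id} carries strain {rec.strain_id!r}, "
                    f"expected {self.metadata.strain_id!r}"
                )


def _normalize_sequence(seq: str) -> str:
    return seq.upper().replace("*", "")


def read_fasta(path: str | Path, strain_id: str | None = None) -> list[ProteinRecord]:
    """Read a protein FASTA into records.

    The first whitespace-delimited header token is the protein id.  Sequences
    are uppercased, '*' stop marks stripped and line wraps joined.  If
    ``strain_id`` is omitted the file stem is used.
    """
    path = Path(path)
    sid = strain_id if strain_id is not None else path.stem
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise ValueError(f"{path}: record {i}: malformed header (no id)")
        seq = _normalize_sequence(str(rec.seq))
        if not seq:
            raise ValueError(f"{path}: record {i} ({rec.id}): empty sequence")
        if rec.id in seen:
            raise ValueError(f"{path}: record {i}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(protein_id=rec.id, strain_id=sid, sequence=seq))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width`` columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


_META_COLUMNS = ["strain_id", "group", "genome_size_bp", "gene_count"]


def read_metadata(path: str | Path) -> list[StrainMetadata]:
    """Read the strain metadata TSV (strain_id, group, genome_size_bp, gene_count)."""
    df = pd.read_csv(path, sep="\t", dtype={"strain_id": str, "group": str})
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    return [
        StrainMetadata(
            strain_id=row.strain_id,
            group=row.group,
            genome_size_bp=int(row.genome_size_bp),
            gene_count=int(row.gene_count),
        )
        for row in df.itertuples(index=False)
    ]


def write_metadata(meta: list[StrainMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [(m.strain_id, m.group, m.genome_size_bp, m.gene_count) for m in meta],
        columns=_META_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
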