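from __future__ import annotations

import numpy as np
import pytest

from nlscan.dialect import fixture_motifs, nes_consensus
from nlscan.proteome import ProteinRecord, StrainMetadata, StrainProteome

STD = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def motifs():
    """The 16 curated NLS motifs shipped with the package."""
    return fixture_motifs()


@pytest.fixture(scope="session")
def all_patterns(motifs):
    """Fixture motifs plus the NES consensus."""
    return [*motifs, nes_consensus()]


def random_sequences(seed: int, n: int, length: int = 60) -> list[str]:
    """Random test sequences: a mix of uniform-composition and K/R-enriched
    sequences (the latter so basic motifs actually get hits), plus a few with
    ambiguity letters."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(STD))
    basic = np.array(list("KRKRKKRP" + STD))  # K/R-heavy alphabet
    with_x = np.array(list(STD + "XBZ"))
    seqs = []
    for i in range(n):
        alphabet = (letters, basic, with_x)[i % 3]
        seqs.append("".join(rng.choice(alphabet, size=length)))
    return seqs


def planted_sequences(p, seed: int, n: int, length: int = 60) -> list[str]:
    """Random sequences with one sampled concrete expansion of ``p`` spliced
    in, so matcher tests see true positives.  The sampler walks the parsed
    elements directly and never touches the scanning code."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(STD))
    out = []
    for _ in range(n):
        chars = []
        for e in p.elements:
            r = int(rng.integers(e.repeat_min, e.repeat_max + 1))
            pool = sorted(e.residues) if e.residues else list(STD)
            chars.extend(pool[int(rng.integers(len(pool)))] for _ in range(r))
        exp = "".join(chars)
        pad = max(length, len(exp) + 6)
        seq = "".join(rng.choice(letters, size=pad))
        off = int(rng.integers(0, pad - len(exp) + 1))
        out.append(seq[:off] + exp + seq[off + len(exp):])
    return out


def make_proteome(strain_id: str, group: str, sequences: dict[str, str],
                  genome_size: int = 5_000_000, genes: int = 4000) -> StrainProteome:
    meta = StrainMetadata(strain_id=strain_id, group=group,
                         genome_size_bp=genome_size, gene_count=genes)
    proteins = tuple(
        ProteinRecord(pid, strain_id, seq) for pid, seq in sequences.items()
    )
    return StrainProteome(metadata=meta, proteins=proteins)
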