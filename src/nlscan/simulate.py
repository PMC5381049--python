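"""Synthetic group-structured proteomes with planted motif ground truth.

The generator emulates the statistical skeleton of a comparative NLS survey:
strains belong to taxonomic groups, each group has an expected per-motif
bearing-protein count (a Poisson rate per strain), backgrounds are drawn
residue-wise from a fixed composition, and a recorded ground truth lists
exactly which proteins carry which motifs at which offsets.

Exactness of the truth is enforced, not assumed: after planting, every
protein is rescanned with the full motif set; background proteins that match
anything, and carrier proteins that match anything beyond their planted
motifs (a planted basic cluster next to accidental background lysines can
complete a bipartite pattern), are regenerated until the scan agrees with
the record.  Consequently ``abundance_matrix`` on a generated study equals
the planted counts exactly, which is what makes the downstream stages
testable without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dialect import (
    STANDARD_RESIDUES,
    MotifPattern,
    fixture_motifs,
    length_bounds,
    scan_sequence,
)
from .proteome import GROUPS, ProteinRecord, StrainMetadata, StrainProteome

__all__ = [
    "GroupProfile",
    "PlantedSite",
    "GroundTruth",
    "SimulationError",
    "default_background",
    "generate_strain",
    "generate_study",
    "gradient_preset",
    "study_preset",
    "generate_family_fixture",
]

_LETTERS = tuple(sorted(STANDARD_RESIDUES))
_MAX_ATTEMPTS = 100


class SimulationError(RuntimeError):
    """Raised when a motif-free background cannot be achieved."""


def default_background() -> dict[str, float]:
    """Background residue frequencies: uniform with K and R down-weighted x0.5.

    Down-weighting the basic residues keeps accidental K/R-rich motif hits
    rare; the regeneration loop guarantees exact truth regardless.
    """
    weights = {aa: 1.0 for aa in _LETTERS}
    weights["K"] = 0.5
    weights["R"] = 0.5
    total = sum(weights.values())
    return {aa: w / total for aa, w in weights.items()}


@dataclass(frozen=True)
class GroupProfile:
    """Generator settings for one taxonomic group.

    ``motif_lambda`` maps motif text to the expected number of distinct
    carrier proteins per strain (Poisson rate); motifs absent from the map
    get rate 0.  Protein lengths are normal(mean, sd) truncated at
    ``length_min``; genome size and gene count are drawn uniformly from the
    given ranges for each strain's metadata row.
    """

    group: str
    motif_lambda: Mapping[str, float]
    n_strains: int = 5
    proteins_per_strain: int = 100
    length_mean: float = 160.0
    length_sd: float = 40.0
    length_min: int = 60
    background_freq: Mapping[str, float] | None = None
    genome_size_range: tuple[int, int] = (3_000_000, 8_000_000)
    gene_count_range: tuple[int, int] = (3000, 7000)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if any(lam < 0 for lam in self.motif_lambda.values()):
            raise ValueError("motif rates must be >= 0")


@dataclass(frozen=True)
class PlantedSite:
    protein_id: str
    motif: str
    offset: int
    expansion: str


@dataclass
class GroundTruth:
    """Planted carriers per strain per motif, plus optional family labels."""

    sites: dict[str, list[PlantedSite]] = field(default_factory=dict)
    families: dict[str, frozenset[str]] = field(default_factory=dict)

    def carrier_ids(self, strain_id: str, motif: str) -> set[str]:
        return {
            s.protein_id for s in self.sites.get(strain_id, []) if s.motif == motif
        }

    def carrier_count(self, strain_id: str, motif: str) -> int:
        return len(self.carrier_ids(strain_id, motif))

    def bearing_total(self, strain_id: str) -> int:
        return len({s.protein_id for s in self.sites.get(strain_id, [])})


def _sample_expansion(p: MotifPattern, rng: np.random.Generator) -> str:
    """One concrete string matching ``p``: repeat counts uniform over their
    ranges, class/wildcard residues uniform over their allowed sets."""
    chars: list[str] = []
    for e in p.elements:
        r = int(rng.integers(e.repeat_min, e.repeat_max + 1))
        choices = _LETTERS if e.kind == "wildcard" else tuple(sorted(e.residues))
        for _ in range(r):
            chars.append(choices[int(rng.integers(len(choices)))])
    return "".join(chars)


def _draw_background(
    rng: np.random.Generator, length: int, letters: Sequence[str], probs: np.ndarray
) -> str:
    return "".join(rng.choice(letters, size=length, p=probs))


def _scan_hits(seq: str, motifs: Sequence[MotifPattern]) -> set[str]:
    return {m.source_text for m in motifs if scan_sequence(m, seq)}


def generate_strain(
    profile: GroupProfile,
    strain_id: str,
    seed: int | np.random.SeedSequence,
    motifs: Sequence[MotifPattern] | None = None,
) -> tuple[StrainProteome, GroundTruth]:
    """Generate one strain: background proteins plus planted motif carriers.

    Per motif, Poisson(lambda) distinct carriers receive one sampled
    expansion at a uniform offset (overwritten in place, so lengths are
    preserved); carriers are disjoint across motifs.  Every protein is then
    rescanned against the full motif set and regenerated (fresh background,
    fresh expansion and offset) until its hits equal its planted set, up to
    100 attempts.
    """
    motifs = list(motifs) if motifs is not None else fixture_motifs()
    rng = np.random.default_rng(seed)
    max_len = max(length_bounds(m)[1] for m in motifs)
    if profile.length_min < max_len + 2:
        raise ValueError(
            f"length_min {profile.length_min} too short for motifs up to "
            f"{max_len} residues (need >= {max_len + 2})"
        )
    freq = dict(profile.background_freq or default_background())
    letters = tuple(sorted(freq))
    probs = np.array([freq[aa] for aa in letters], dtype=float)
    probs = probs / probs.sum()

    genome_size = int(rng.integers(*profile.genome_size_range, endpoint=True))
    gene_count = int(rng.integers(*profile.gene_count_range, endpoint=True))
    meta = StrainMetadata(
        strain_id=strain_id,
        group=profile.group,
        genome_size_bp=genome_size,
        gene_count=gene_count,
    )

    n = profile.proteins_per_strain
    lengths = rng.normal(profile.length_mean, profile.length_sd, size=n)
    lengths = np.maximum(np.rint(lengths).astype(int), profile.length_min)

    # Poisson carrier draws, disjoint across motifs.
    carrier_counts = {
        m.source_text: int(rng.poisson(profile.motif_lambda.get(m.source_text, 0.0)))
        for m in motifs
    }
    total = sum(carrier_counts.values())
    if total > n:
        raise SimulationError(
            f"strain {strain_id}: {total} carriers requested but only {n} proteins"
        )
    chosen = rng.choice(n, size=total, replace=False)
    planted: dict[int, MotifPattern] = {}
    cursor = 0
    for m in motifs:
        for idx in chosen[cursor : cursor + carrier_counts[m.source_text]]:
            planted[int(idx)] = m
        cursor += carrier_counts[m.source_text]

    proteins: list[ProteinRecord] = []
    sites: list[PlantedSite] = []
    for i in range(n):
        pid = f"{strain_id}_p{i:04d}"
        length = int(lengths[i])
        motif = planted.get(i)
        expected = {motif.source_text} if motif is not None else set()
        for attempt in range(_MAX_ATTEMPTS):
            seq = _draw_background(rng, length, letters, probs)
            site = None
            if motif is not None:
                expansion = _sample_expansion(motif, rng)
                offset = int(rng.integers(0, length - len(expansion) + 1))
                seq = seq[:offset] + expansion + seq[offset + len(expansion):]
                site = PlantedSite(
                    protein_id=pid,
                    motif=motif.source_text,
                    offset=offset,
                    expansion=expansion,
                )
            if _scan_hits(seq, motifs) == expected:
                proteins.append(ProteinRecord(pid, strain_id, seq))
                if site is not None:
                    sites.append(site)
                break
        else:
            raise SimulationError(
                f"strain {strain_id}, protein {pid}: could not achieve the "
                f"planted motif set in {_MAX_ATTEMPTS} attempts"
            )
    truth = GroundTruth(sites={strain_id: sites})
    return StrainProteome(metadata=meta, proteins=tuple(proteins)), truth


def generate_study(
    profiles: Sequence[GroupProfile],
    seed: int,
    motifs: Sequence[MotifPattern] | None = None,
) -> tuple[list[StrainProteome], list[StrainMetadata], GroundTruth]:
    """Generate a multi-group study: ``n_strains`` strains per profile.

    Per-strain seeds are spawned from ``seed`` so the whole study is
    reproducible and strains are independent.
    """
    if len(profiles) < 2:
        raise ValueError("a study needs at least two group profiles")
    motifs = list(motifs) if motifs is not None else fixture_motifs()
    total_strains = sum(p.n_strains for p in profiles)
    children = np.random.SeedSequence(seed).spawn(total_strains)
    proteomes: list[StrainProteome] = []
    truth = GroundTruth()
    k = 0
    for profile in profiles:
        for s in range(profile.n_strains):
            sid = f"{profile.group}-{s + 1:02d}"
            proteome, strain_truth = generate_strain(profile, sid, children[k], motifs)
            proteomes.append(proteome)
            truth.sites.update(strain_truth.sites)
            k += 1
    meta = [p.metadata for p in proteomes]
    return proteomes, meta, truth


_BACTERIA_LAMBDA = {
    "PRRRK": 3.0,
    "RKRKK": 2.5,
    "RPRRK": 2.0,
    "KRPRP": 1.5,
    "RKRRR": 1.5,
    "QRKRQK": 1.0,
    "[KR]{4}.{20,24}K{1,4}.K": 1.0,
}

_FUNGI_LAMBDA = {
    "PRRRK": 8.0,
    "RKRKK": 6.0,
    "RPRRK": 5.0,
    "KRPRP": 4.0,
    "RKRRR": 5.0,
    "P.KKKRK": 3.0,
    "TKRS...M": 2.0,
    "KR.{10}KKKL": 2.0,
    "KAKRQR": 2.0,
    "QRKRQK": 2.0,
    "GKKRSKA": 3.0,
    "IKYFKKFPKD": 2.0,
    "K[RK]{3,5}.{11,18}[RK]K.{2,3}K": 2.0,
    "[KR]{4}.{20,24}K{1,4}.K": 2.0,
}


def _mix(a: Mapping[str, float], b: Mapping[str, float], w: float) -> dict[str, float]:
    keys = set(a) | set(b)
    return {k: (1 - w) * a.get(k, 0.0) + w * b.get(k, 0.0) for k in sorted(keys)}


def gradient_preset(
    n_strains: int = 5, proteins_per_strain: int = 100
) -> list[GroupProfile]:
    """Three-group study in which the planctomycete rate profile is the
    midpoint 0.5*bacteria + 0.5*fungi, so the bacteria -> planctomycetes ->
    fungi abundance gradient is recoverable by construction."""
    plancto = _mix(_BACTERIA_LAMBDA, _FUNGI_LAMBDA, 0.5)
    return [
        GroupProfile(
            group="bacteria",
            motif_lambda=_BACTERIA_LAMBDA,
            n_strains=n_strains,
            proteins_per_strain=proteins_per_strain,
            genome_size_range=(3_000_000, 6_000_000),
            gene_count_range=(3000, 5500),
        ),
        GroupProfile(
            group="planctomycetes",
            motif_lambda=plancto,
            n_strains=n_strains,
            proteins_per_strain=proteins_per_strain,
            genome_size_range=(5_000_000, 9_000_000),
            gene_count_range=(4000, 7000),
        ),
        GroupProfile(
            group="fungi",
            motif_lambda=_FUNGI_LAMBDA,
            n_strains=n_strains,
            proteins_per_strain=proteins_per_strain,
            genome_size_range=(25_000_000, 40_000_000),
            gene_count_range=(9000, 14000),
        ),
    ]


def study_preset(
    n_strains: int = 5, proteins_per_strain: int = 100
) -> list[GroupProfile]:
    """Four-group study with presence/absence structure: two motifs private
    to planctomycetes, three private to fungi, one shared by non-planctomycete
    bacteria and fungi only, and a bipartite motif present everywhere."""
    plancto = {
        "PRRRK": 4.0,
        "RKRKK": 3.0,
        "RPRRK": 2.5,
        "KRPRP": 2.0,
        "RKRRR": 3.0,
        "P.KKKRK": 1.0,
        "KR.{10}KKKL": 1.0,
        "KAKRQR": 1.0,
        "RRKGKEK": 1.0,
        "KRKRRP": 1.0,
        "[KR]{4}.{20,24}K{1,4}.K": 1.5,
    }
    archaea = {"PRRRK": 1.0, "RKRKK": 1.0, "[KR]{4}.{20,24}K{1,4}.K": 0.5}
    return [
        GroupProfile(
            group="bacteria",
            motif_lambda=_BACTERIA_LAMBDA,
            n_strains=n_strains,
            proteins_per_strain=proteins_per_strain,
            genome_size_range=(3_000_000, 6_000_000),
            gene_count_range=(3000, 5500),
        ),
        GroupProfile(
            group="planctomycetes",
            motif_lambda=plancto,
            n_strains=n_strains,
            proteins_per_strain=proteins_per_strain,
            genome_size_range=(5_000_000, 9_000_000),
            gene_count_range=(4000, 7000),
        ),
        GroupProfile(
            group="archaea",
            motif_lambda=archaea,
            n_strains=max(2, n_strains - 3),
            proteins_per_strain=proteins_per_strain,
            genome_size_range=(2_000_000, 5_000_000),
            gene_count_range=(2000, 5000),
        ),
        GroupProfile(
            group="fungi",
            motif_lambda=_FUNGI_LAMBDA,
            n_strains=n_strains,
            proteins_per_strain=proteins_per_strain,
            genome_size_range=(25_000_000, 40_000_000),
            gene_count_range=(9000, 14000),
        ),
    ]


_DEFAULT_FAMILY_DESIGNS: tuple[tuple[str, ...], ...] = (
    ("bacteria", "bacteria", "planctomycetes"),
    ("planctomycetes", "fungi", "fungi"),
    ("bacteria", "planctomycetes", "fungi"),
    ("fungi", "fungi", "fungi"),
    ("archaea", "planctomycetes"),
)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [aa for aa in _LETTERS if aa != chars[i]]
        chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def generate_family_fixture(
    seed: int,
    family_designs: Sequence[Sequence[str]] = _DEFAULT_FAMILY_DESIGNS,
    length: int = 120,
    mutation_rate: float = 0.05,
) -> tuple[list[ProteinRecord], list[StrainMetadata], GroundTruth]:
    """Planted protein families for clustering tests.

    Each design entry lists the group of every member of one family; members
    are point-mutated copies (substitution rate ``mutation_rate``) of a
    random family ancestor.  One strain is emitted per group, with plausible
    metadata, so group-sharing summaries can be checked against the design.
    """
    rng = np.random.default_rng(seed)
    groups_used = sorted({g for design in family_designs for g in design})
    unknown = [g for g in groups_used if g not in GROUPS]
    if unknown:
        raise ValueError(f"unknown groups in family design: {unknown}")
    meta = [
        StrainMetadata(
            strain_id=f"{g}-01",
            group=g,
            genome_size_bp=int(rng.integers(3_000_000, 30_000_000)),
            gene_count=int(rng.integers(3000, 10000)),
        )
        for g in groups_used
    ]
    proteins: list[ProteinRecord] = []
    truth = GroundTruth()
    probs = np.full(len(_LETTERS), 1.0 / len(_LETTERS))
    for fi, design in enumerate(family_designs, start=1):
        ancestor = _draw_background(rng, length, _LETTERS, probs)
        member_ids = []
        for mi, group in enumerate(design, start=1):
            pid = f"fam{fi:02d}_m{mi}"
            seq = _mutate(ancestor, mutation_rate, rng)
            proteins.append(ProteinRecord(pid, f"{group}-01", seq))
            member_ids.append(pid)
        truth.families[f"fam{fi:02d}"] = frozenset(member_ids)
    return proteins, meta, truth
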