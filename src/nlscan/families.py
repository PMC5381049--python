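"""Protein family clustering and cross-group family summaries.

Families are built the way ortholog-grouping pipelines do it: an
all-against-all similarity graph followed by Markov clustering (MCL).  The
similarity backend here is cosine similarity of k-mer count vectors — a
deterministic, alignment-free stand-in for reciprocal BLASTp scores that
behaves equivalently on the clustering side (high within-family similarity,
near-zero between unrelated sequences).  The backend is pluggable: ``mcl``
accepts any :class:`SimilarityGraph`.

Downstream summaries follow the comparative logic of the study design:
which taxonomic group combinations share families (Venn counts, orphans
excluded) and how motif complexity shifts within families that span groups.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.metrics.pairwise import cosine_similarity

from .proteome import ProteinRecord, StrainMetadata

__all__ = [
    "SimilarityGraph",
    "FamilyPartition",
    "FamilyGroupSummary",
    "pairwise_similarity",
    "mcl",
    "group_sharing",
    "family_motif_transition",
]


@dataclass(frozen=True)
class SimilarityGraph:
    """Undirected weighted similarity graph over protein ids."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def weight(self, a: str, b: str) -> float:
        return self.graph[a][b]["weight"] if self.graph.has_edge(a, b) else 0.0


@dataclass(frozen=True)
class FamilyPartition:
    """Exact partition of protein ids into families."""

    assignment: dict[str, str]
    families: dict[str, frozenset[str]]

    @property
    def orphans(self) -> set[str]:
        """Family ids of single-member (orphan) families."""
        return {fid for fid, members in self.families.items() if len(members) == 1}

    def non_orphan_families(self) -> dict[str, frozenset[str]]:
        return {f: m for f, m in self.families.items() if len(m) > 1}

    def to_frame(self) -> pd.DataFrame:
        orphans = self.orphans
        rows = [
            (pid, fid, fid in orphans)
            for pid, fid in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows, columns=["protein_id", "family_id", "orphan"])


@dataclass(frozen=True)
class FamilyGroupSummary:
    """Venn-style counts of families shared between taxonomic groups.

    ``family_groups`` maps each non-orphan family to the set of groups its
    members come from; ``combination_counts`` maps each observed group
    combination to (family count, protein count).
    """

    family_groups: dict[str, frozenset[str]]
    combination_counts: dict[frozenset[str], tuple[int, int]]


def _kmer_counts(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def pairwise_similarity(
    proteins: Iterable[ProteinRecord], k: int = 3, threshold: float = 0.5
) -> SimilarityGraph:
    """All-against-all cosine similarity of k-mer count vectors.

    Edges are kept when similarity >= ``threshold``.  Sequences shorter than
    ``k`` have an all-zero k-mer vector: their nodes are kept but get no
    edges.  Self-loops are never emitted.
    """
    records = list(proteins)
    if len(records) < 2:
        raise ValueError("need at least two proteins")
    ids = [r.protein_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in similarity input")
    counters = [_kmer_counts(r.sequence, k) for r in records]
    vocab: dict[str, int] = {}
    rows, cols, vals = [], [], []
    for i, counter in enumerate(counters):
        for kmer, count in counter.items():
            j = vocab.setdefault(kmer, len(vocab))
            rows.append(i)
            cols.append(j)
            vals.append(count)
    g = nx.Graph()
    g.add_nodes_from(ids)
    if vocab:
        mat = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(records), len(vocab)), dtype=float
        )
        sim = cosine_similarity(mat)
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                w = float(sim[i, j])
                if w >= threshold and w > 0:
                    g.add_edge(ids[i], ids[j], weight=min(w, 1.0))
    return SimilarityGraph(graph=g)


def mcl(
    g: SimilarityGraph,
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> FamilyPartition:
    """Markov clustering of the similarity graph.

    Classic MCL: add self-loops (weight = max incident edge weight, 1.0 for
    isolated nodes), column-normalize, then alternate expansion (matrix
    squaring) and inflation (entrywise power ``inflation`` followed by
    column renormalization) until the largest entry change drops below
    ``tol`` or ``max_iter`` rounds.  Clusters are read off the attractors;
    a node attracted to several clusters is assigned deterministically by
    merging (attractor systems sharing a node form one cluster).  Family
    ids are numbered F0001, F0002, ... by lexicographically smallest member.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = g.nodes  # sorted for determinism
    n = len(nodes)
    if n == 0:
        return FamilyPartition(assignment={}, families={})
    index = {node: i for i, node in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, data in g.graph.edges(data=True):
        w = float(data["weight"])
        m[index[a], index[b]] = w
        m[index[b], index[a]] = w
    incident_max = m.max(axis=0)
    np.fill_diagonal(m, np.where(incident_max > 0, incident_max, 1.0))
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded**inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        if np.abs(inflated - m).max() < tol:
            m = inflated
            break
        m = inflated
    # Interpret: attractors are rows with non-negligible diagonal mass; each
    # column is attracted to the rows carrying its mass.
    eps = 1e-5
    attractors = [i for i in range(n) if m[i, i] > eps]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for j in range(n):
        pulls = [i for i in attractors if m[i, j] > eps]
        for i in pulls:
            union(i, j)
    clusters: dict[int, list[str]] = defaultdict(list)
    for j in range(n):
        clusters[find(j)].append(nodes[j])
    members_sorted = sorted(
        (sorted(mem) for mem in clusters.values()), key=lambda mem: mem[0]
    )
    assignment: dict[str, str] = {}
    families: dict[str, frozenset[str]] = {}
    for idx, mem in enumerate(members_sorted, start=1):
        fid = f"F{idx:04d}"
        families[fid] = frozenset(mem)
        for node in mem:
            assignment[node] = fid
    return FamilyPartition(assignment=assignment, families=families)


def group_sharing(
    part: FamilyPartition,
    proteins: Iterable[ProteinRecord],
    meta: list[StrainMetadata],
) -> FamilyGroupSummary:
    """Venn counts of group combinations over non-orphan families."""
    group_by_strain = {m.strain_id: m.group for m in meta}
    strain_by_protein = {p.protein_id: p.strain_id for p in proteins}
    family_groups: dict[str, frozenset[str]] = {}
    combo_families: dict[frozenset[str], int] = defaultdict(int)
    combo_proteins: dict[frozenset[str], int] = defaultdict(int)
    for fid, members in sorted(part.non_orphan_families().items()):
        groups = set()
        for pid in members:
            if pid not in strain_by_protein:
                raise ValueError(f"protein {pid!r} has no strain record")
            strain = strain_by_protein[pid]
            if strain not in group_by_strain:
                raise ValueError(f"strain {strain!r} has no metadata")
            groups.add(group_by_strain[strain])
        combo = frozenset(groups)
        family_groups[fid] = combo
        combo_families[combo] += 1
        combo_proteins[combo] += len(members)
    return FamilyGroupSummary(
        family_groups=family_groups,
        combination_counts={
            combo: (combo_families[combo], combo_proteins[combo])
            for combo in combo_families
        },
    )


#: Cross-group family categories.
SHARED_SAME_MOTIF = "shared_same_motif"
PROKARYOTE_SHARED_DIFFERENT = "prokaryote_shared_different_motif"
EUK_ARCHAEA_SHARED_DIFFERENT = "eukaryote_archaea_shared_different_motif"


def family_motif_transition(
    part: FamilyPartition,
    protein_motifs: Mapping[str, frozenset[str] | set[str]],
    proteins: Iterable[ProteinRecord],
    meta: list[StrainMetadata],
    composite_scores: Mapping[str, float],
) -> pd.DataFrame:
    """Classify cross-group families by motif conservation vs. turnover.

    Families whose members span >= 2 taxonomic groups are labelled:

    * ``shared_same_motif`` — every group carries the same set of motif
      types (motif conserved across the group boundary);
    * ``prokaryote_shared_different_motif`` — groups are all prokaryotic
      (bacteria/planctomycetes) and their motif sets differ;
    * ``eukaryote_archaea_shared_different_motif`` — the family reaches
      archaea or a eukaryotic group and motif sets differ.

    Single-group families are excluded.  Per family the composite-complexity
    range (min, max) of all motifs seen in it is reported, so a complexity
    increase across the boundary is visible as a wide range.
    """
    group_by_strain = {m.strain_id: m.group for m in meta}
    strain_by_protein = {p.protein_id: p.strain_id for p in proteins}
    rows = []
    for fid, members in sorted(part.non_orphan_families().items()):
        motifs_by_group: dict[str, set[str]] = defaultdict(set)
        for pid in members:
            group = group_by_strain[strain_by_protein[pid]]
            motifs_by_group[group] |= set(protein_motifs.get(pid, ()))
        if len(motifs_by_group) < 2:
            continue
        group_sets = list(motifs_by_group.values())
        all_motifs = sorted(set().union(*group_sets))
        if not all_motifs:
            continue
        if all(s == group_sets[0] for s in group_sets[1:]):
            category = SHARED_SAME_MOTIF
        elif set(motifs_by_group) <= {"bacteria", "planctomycetes"}:
            category = PROKARYOTE_SHARED_DIFFERENT
        else:
            category = EUK_ARCHAEA_SHARED_DIFFERENT
        composites = [composite_scores[m] for m in all_motifs if m in composite_scores]
        rows.append(
            (
                fid,
                category,
                ";".join(sorted(motifs_by_group)),
                ";".join(all_motifs),
                min(composites) if composites else float("nan"),
                max(composites) if composites else float("nan"),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "category",
            "groups",
            "motifs",
            "complexity_min",
            "complexity_max",
        ],
    )
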