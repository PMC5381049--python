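"""PCA ordination of strain abundance profiles and the group-gradient test.

The central comparative claim this module tests: in normalized NLS-bearing
protein abundance space, planctomycete strains sit *between* non-planctomycete
bacteria and fungi — their mean euclidean distance to the fungal centroid is
smaller than that of the other bacteria.  PCA is used for ordination
(visualising dissimilarity), the distance test itself runs in the full
normalized-profile space so no component cutoff enters the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .proteome import StrainMetadata

__all__ = ["Ordination", "GradientReport", "pca", "gradient_test"]

GRADIENT = "gradient"
NO_GRADIENT = "no gradient"


@dataclass(frozen=True)
class Ordination:
    """Strain coordinates in principal-component space.

    ``scores`` is strains x components (PC1, PC2, ...); ``loadings`` is
    components x motifs; ``explained_variance_ratio`` the per-component
    fraction of total variance.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


@dataclass(frozen=True)
class GradientReport:
    """Mean euclidean distance of each group's strains to the fungal centroid."""

    group_distances: dict[str, float]
    verdict: str


def pca(x: pd.DataFrame) -> Ordination:
    """Principal components of strain profiles.

    ``x`` is a motif x strain matrix (as written by the normalization step);
    strains are the observations.  Motif dimensions are mean-centered (no
    variance scaling — all entries share units after Q normalization) and
    decomposed by SVD.  Sign convention: within each component the loading
    of largest magnitude is made positive.  Components with numerically zero
    singular values are dropped.
    """
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least two strains")
    strains = list(x.columns)
    motifs = list(x.index)
    data = x.to_numpy(dtype=float).T  # strains x motifs
    centered = data - data.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    keep = s > max(1e-12, 1e-9 * s[0] if s.size else 0.0)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    for k in range(s.size):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u * s
    total = float((s**2).sum())
    evr = (s**2) / total if total > 0 else np.zeros_like(s)
    comp_names = [f"PC{i + 1}" for i in range(s.size)]
    return Ordination(
        scores=pd.DataFrame(scores, index=strains, columns=comp_names),
        loadings=pd.DataFrame(vt, index=comp_names, columns=motifs),
        explained_variance_ratio=evr,
    )


def gradient_test(x: pd.DataFrame, meta: list[StrainMetadata]) -> GradientReport:
    """Distance-to-fungi gradient across taxonomic groups.

    Computes the fungal centroid in full normalized-profile space and the
    mean euclidean distance of each group's strains to it.  Verdict
    ``"gradient"`` iff bacteria lie strictly farther from fungi than
    planctomycetes do (both groups must be present).
    """
    by_id = {m.strain_id: m for m in meta}
    missing = [sid for sid in x.columns if sid not in by_id]
    if missing:
        raise ValueError(f"no metadata for strain(s) {missing}")
    groups = {sid: by_id[sid].group for sid in x.columns}
    fungal = [sid for sid in x.columns if groups[sid] == "fungi"]
    if not fungal:
        raise ValueError("gradient test requires at least one fungal strain")
    profiles = x.to_numpy(dtype=float)
    col = {sid: i for i, sid in enumerate(x.columns)}
    centroid = profiles[:, [col[sid] for sid in fungal]].mean(axis=1)
    dist_by_group: dict[str, list[float]] = {}
    for sid in x.columns:
        d = float(np.linalg.norm(profiles[:, col[sid]] - centroid))
        dist_by_group.setdefault(groups[sid], []).append(d)
    means = {g: float(np.mean(ds)) for g, ds in sorted(dist_by_group.items())}
    if "bacteria" in means and "planctomycetes" in means:
        verdict = GRADIENT if means["bacteria"] > means["planctomycetes"] else NO_GRADIENT
    else:
        verdict = NO_GRADIENT
    return GradientReport(group_distances=means, verdict=verdict)
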