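"""Base-composition diagnostics: CLR transform, Aitchison distances, UPGMA.

tRNA base compositions are compositional data; comparing groups by Euclidean
distance of centered-log-ratio (CLR) transformed proportions (the Aitchison
distance) and clustering by UPGMA exposes compositional convergence between
groups — the bias that attracts A+T-converged genomes toward unrelated
A+T-rich clades under total-sequence methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .dataset import NUCLEOTIDES, TDNADataset

__all__ = [
    "CompositionVector",
    "composition",
    "clr",
    "distance_matrix",
    "upgma",
    "CLR_LOG_BASE",
]

#: The logarithm used by :func:`clr`. Any base yields proportional CLR vectors
#: and distances scaled by a constant, so clustering topology is unaffected.
CLR_LOG_BASE = "e"

_SMOOTH = 0.5  # added to zero base counts so the CLR is defined


@dataclass
class CompositionVector:
    """Base counts and (smoothed, strictly positive) proportions of a group of
    tDNAs."""

    group: str
    counts: Dict[str, int]
    proportions: Dict[str, float]


def composition(dataset: TDNADataset, group_by: str = "clade") -> List[CompositionVector]:
    """Base composition over ungapped residues, aggregated by clade or genome.

    Zero counts are smoothed by +0.5 before proportions are computed.
    """
    if not dataset.records:
        raise ValueError("empty dataset")
    if group_by not in ("clade", "genome"):
        raise ValueError("group_by must be 'clade' or 'genome'")
    groups: Dict[str, Dict[str, int]] = {}
    for rec in dataset.records:
        if group_by == "genome":
            g = rec.genome_id
        else:
            g = dataset.taxon_of.get(rec.genome_id, rec.genome_id)
        cnt = groups.setdefault(g, {b: 0 for b in NUCLEOTIDES})
        for ch in rec.seq:
            if ch in cnt:
                cnt[ch] += 1
    out = []
    for g in sorted(groups):
        cnt = groups[g]
        if sum(cnt.values()) == 0:
            raise ValueError(f"group {g!r} has no ungapped residues")
        smoothed = {b: (n if n > 0 else _SMOOTH) for b, n in cnt.items()}
        tot = sum(smoothed.values())
        out.append(
            CompositionVector(g, cnt, {b: v / tot for b, v in smoothed.items()})
        )
    return out


def clr(v: CompositionVector) -> np.ndarray:
    """Centered log-ratio transform ln(p_i / geometric mean p), over A,C,G,T;
    components sum to zero."""
    p = np.array([v.proportions[b] for b in NUCLEOTIDES], dtype=float)
    if np.any(p <= 0):
        raise ValueError("proportions must be strictly positive")
    logp = np.log(p)
    return logp - logp.mean()


def distance_matrix(vectors: Sequence[CompositionVector]) -> np.ndarray:
    """Pairwise Aitchison (Euclidean-on-CLR) distances between groups."""
    if len(vectors) < 2:
        raise ValueError("need at least 2 groups")
    Z = np.array([clr(v) for v in vectors])
    diff = Z[:, None, :] - Z[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def upgma(d: np.ndarray, labels: Sequence[str]) -> str:
    """UPGMA clustering of a distance matrix; returns a Newick string with
    ultrametric branch lengths.

    Ties are broken deterministically by label order (labels are sorted before
    linkage and the input matrix is permuted to match).
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
        raise ValueError("distance matrix / label size mismatch")
    if not np.allclose(d, d.T) or np.any(d < 0):
        raise ValueError("distance matrix must be symmetric and non-negative")
    order = sorted(range(len(labels)), key=lambda i: str(labels[i]))
    labs = [str(labels[i]) for i in order]
    dp = d[np.ix_(order, order)]
    if len(labs) == 1:
        return f"{labs[0]}:0;"
    Z = linkage(squareform(dp, checks=False), method="average")

    # node -> (newick string, node height, smallest contained leaf label)
    nodes: Dict[int, tuple] = {i: (labs[i], 0.0, labs[i]) for i in range(len(labs))}
    n = len(labs)
    for i, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        if nodes[a][2] > nodes[b][2]:  # child order: smallest leaf label first
            a, b = b, a
        (sa, ha, ma), (sb, hb, mb) = nodes[a], nodes[b]
        height = h / 2.0  # ultrametric node height
        nodes[n + i] = (
            f"({sa}:{height - ha:.10g},{sb}:{height - hb:.10g})",
            height,
            min(ma, mb),
        )
    root = nodes[n + len(Z) - 1][0]
    return root + ";"
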