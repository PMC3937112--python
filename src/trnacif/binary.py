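"""Binary CIF-based phyloclassification of genomes.

A genome is scored by the mean, over its tDNAs, of the summed differences in
function-logo letter heights of the features each tDNA presents, looked up at
the tDNA's own functional class, between two taxon sets.  Positive scores
favor taxon set A, negative favor B.  Leave-one-out cross-validation rebuilds
a training genome's own side's logo without its tDNAs before scoring.
"""

from __future__ import annotations

from typing import Dict, Optional

import pandas as pd

from .dataset import TDNADataset
from .logo import FunctionLogo, build_logo, features_of

__all__ = ["score_binary", "class_breakout", "loocv_binary"]


def _tdna_score(rec, sprinzl, logoA: FunctionLogo, logoB: FunctionLogo, use_pairs: bool) -> float:
    s = 0.0
    for f in features_of(rec.seq, sprinzl, use_pairs):
        s += logoA.height(f, rec.cls) - logoB.height(f, rec.cls)
    return s


def score_binary(
    genome: TDNADataset,
    logoA: FunctionLogo,
    logoB: FunctionLogo,
    use_pairs: Optional[bool] = None,
) -> float:
    """Per-tDNA mean CIF-match score (bits per tDNA) of one genome against two
    logos; features absent from a logo contribute height 0 on that side."""
    if not genome.records:
        raise ValueError("empty genome")
    if use_pairs is None:
        use_pairs = logoA.use_pairs and logoB.use_pairs
    total = sum(
        _tdna_score(r, genome.sprinzl, logoA, logoB, use_pairs) for r in genome.records
    )
    return total / len(genome.records)


def class_breakout(
    genome: TDNADataset,
    logoA: FunctionLogo,
    logoB: FunctionLogo,
    use_pairs: Optional[bool] = None,
) -> Dict[str, float]:
    """Per-class mean score contributions: each class's entry averages the
    per-tDNA sums over that class's tDNAs.  Count-weighted, the entries sum to
    the genome total."""
    if not genome.records:
        raise ValueError("empty genome")
    if use_pairs is None:
        use_pairs = logoA.use_pairs and logoB.use_pairs
    sums: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for r in genome.records:
        sums[r.cls] = sums.get(r.cls, 0.0) + _tdna_score(
            r, genome.sprinzl, logoA, logoB, use_pairs
        )
        counts[r.cls] = counts.get(r.cls, 0) + 1
    return {c: sums[c] / counts[c] for c in sums}


def loocv_binary(
    datasetA: TDNADataset,
    datasetB: TDNADataset,
    query_genomes: Optional[TDNADataset] = None,
    use_pairs: bool = True,
    correction: str = "mc",
    mc_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-out cross-validated binary scores.

    Each genome of A (resp. B) is scored against logos rebuilt from its own
    side with its tDNAs removed; query genomes outside A and B are scored
    against the full logos.  Returns a DataFrame with columns genome_id,
    score, n_tdnas, side.
    """
    genomesA = set(datasetA.genome_ids)
    genomesB = set(datasetB.genome_ids)
    overlap = genomesA & genomesB
    if overlap:
        raise ValueError(f"genomes present in both taxon sets: {sorted(overlap)!r}")

    kwargs = dict(use_pairs=use_pairs, correction=correction, mc_reps=mc_reps, seed=seed)
    logoA_full = build_logo(datasetA, **kwargs)
    logoB_full = build_logo(datasetB, **kwargs)

    def _logo_without(dataset: TDNADataset, genome_id: str) -> FunctionLogo:
        rest = dataset.exclude([genome_id])
        if not rest.records:
            return FunctionLogo.empty(use_pairs)
        return build_logo(rest, **kwargs)

    rows = []

    def _add(gid: str, part: TDNADataset, lA: FunctionLogo, lB: FunctionLogo, side: str):
        rows.append(
            {
                "genome_id": gid,
                "score": score_binary(part, lA, lB, use_pairs),
                "n_tdnas": len(part.records),
                "side": side,
            }
        )

    for gid, part in datasetA.by_genome().items():
        _add(gid, part, _logo_without(datasetA, gid), logoB_full, "A")
    for gid, part in datasetB.by_genome().items():
        _add(gid, part, logoA_full, _logo_without(datasetB, gid), "B")
    if query_genomes is not None:
        for gid, part in query_genomes.by_genome().items():
            _add(gid, part, logoA_full, logoB_full, "query")
    return pd.DataFrame(rows, columns=["genome_id", "score", "n_tdnas", "side"])
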