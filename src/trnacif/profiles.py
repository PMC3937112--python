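"""Total-tDNA-sequence binary classifiers (controls for the CIF classifier).

A genome is scored by the mean, over its tDNAs, of log-odds of the tDNA's
features under class-specific sequence profiles built from two taxon sets,
plus a class-prior log-odds term.  Four treatments of features unobserved in
one or both training sets are provided:

* ``zero``  - a feature term contributes only when the feature was observed in
  the tDNA's class in *both* sets; otherwise it contributes 0.
* ``skip``  - unscoreable features are omitted and the per-tDNA feature sum is
  divided by the number of scored features (per-feature mean), so they
  neither dilute nor zero-pad the score.
* ``pseudo`` - frequencies are Laplace-smoothed with a pseudocount (default 1)
  over the feature's state alphabet, so every term is defined.
* ``small`` - zero frequencies are replaced by a small constant eps, by
  default 1/(2 x largest class count over both sets), smaller than any
  observable nonzero frequency.

All logarithms are base 2; scores are in bits per tDNA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import pandas as pd

from .dataset import TDNADataset
from .logo import Feature, count_features, features_of

__all__ = ["ClassProfiles", "build_profiles", "score_profile", "loocv_profile"]

METHODS = ("zero", "skip", "pseudo", "small")


@dataclass
class ClassProfiles:
    """Class-specific feature frequencies of a taxon set: ``q[(class, f)]`` is
    the relative frequency of feature f among that class's tDNAs, ``r[class]``
    the class frequency in the set."""

    taxon: str
    q: Dict[Tuple[str, Feature], float] = field(default_factory=dict)
    r: Dict[str, float] = field(default_factory=dict)
    n_class: Dict[str, int] = field(default_factory=dict)
    n_feat_class: Dict[Tuple[Feature, str], int] = field(default_factory=dict)
    use_pairs: bool = True

    @staticmethod
    def empty(taxon: str = "", use_pairs: bool = True) -> "ClassProfiles":
        return ClassProfiles(taxon, {}, {}, {}, {}, use_pairs)


def build_profiles(
    dataset: TDNADataset, taxon: str = "", use_pairs: bool = True
) -> ClassProfiles:
    """Build class-specific sequence profiles from a taxon set."""
    counts = count_features(dataset, use_pairs)
    q = {
        (c, f): n / counts.n_class[c] for (f, c), n in counts.n_feat_class.items()
    }
    r = {c: n / counts.n_total for c, n in counts.n_class.items()}
    return ClassProfiles(taxon, q, r, dict(counts.n_class), dict(counts.n_feat_class), use_pairs)


def _alphabet_size(f: Feature) -> int:
    return 4 if f.kind == "single" else 16


def _smoothed_q(prof: ClassProfiles, c: str, f: Feature, pseudocount: float) -> float:
    n = prof.n_feat_class.get((f, c), 0)
    return (n + pseudocount) / (prof.n_class.get(c, 0) + _alphabet_size(f) * pseudocount)


def score_profile(
    genome: TDNADataset,
    profA: ClassProfiles,
    profB: ClassProfiles,
    method: str = "zero",
    eps: Optional[float] = None,
    pseudocount: float = 1.0,
) -> float:
    """Log-odds score (bits per tDNA, positive favoring taxon set A) of one
    genome under two class-profile models."""
    if not genome.records:
        raise ValueError("empty genome")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    use_pairs = profA.use_pairs and profB.use_pairs
    if method == "small" and eps is None:
        max_n = max([1] + list(profA.n_class.values()) + list(profB.n_class.values()))
        eps = 1.0 / (2.0 * max_n)

    def _prior(c: str) -> float:
        rA, rB = profA.r.get(c, 0.0), profB.r.get(c, 0.0)
        if method == "pseudo":
            nA = sum(profA.n_class.values())
            nB = sum(profB.n_class.values())
            rA = (profA.n_class.get(c, 0) + pseudocount) / (nA + 22 * pseudocount)
            rB = (profB.n_class.get(c, 0) + pseudocount) / (nB + 22 * pseudocount)
        elif method == "small":
            rA = rA if rA > 0 else eps
            rB = rB if rB > 0 else eps
        elif rA <= 0 or rB <= 0:
            warnings.warn(
                f"class {c!r} absent from a profile; class-prior term set to 0",
                stacklevel=2,
            )
            return 0.0
        return math.log2(rA) - math.log2(rB)

    total = 0.0
    for rec in genome.records:
        c = rec.cls
        t_score = _prior(c)
        feats = features_of(rec.seq, genome.sprinzl, use_pairs)
        if method in ("zero", "skip"):
            terms = []
            for f in feats:
                qA = profA.q.get((c, f), 0.0)
                qB = profB.q.get((c, f), 0.0)
                if qA > 0 and qB > 0:
                    terms.append(math.log2(qA) - math.log2(qB))
                elif method == "zero":
                    terms.append(0.0)
            if method == "zero":
                t_score += sum(terms)
            elif terms:
                t_score += sum(terms) / len(terms)
        elif method == "pseudo":
            for f in feats:
                t_score += math.log2(_smoothed_q(profA, c, f, pseudocount)) - math.log2(
                    _smoothed_q(profB, c, f, pseudocount)
                )
        else:  # small
            for f in feats:
                qA = profA.q.get((c, f), 0.0) or eps
                qB = profB.q.get((c, f), 0.0) or eps
                t_score += math.log2(qA) - math.log2(qB)
        total += t_score
    return total / len(genome.records)


def loocv_profile(
    datasetA: TDNADataset,
    datasetB: TDNADataset,
    query_genomes: Optional[TDNADataset] = None,
    method: str = "zero",
    use_pairs: bool = True,
    eps: Optional[float] = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Leave-one-out cross-validated profile scores; contract as
    :func:`trnacif.binary.loocv_binary` with profiles rebuilt excluding the
    scored genome."""
    genomesA = set(datasetA.genome_ids)
    genomesB = set(datasetB.genome_ids)
    overlap = genomesA & genomesB
    if overlap:
        raise ValueError(f"genomes present in both taxon sets: {sorted(overlap)!r}")
    profA_full = build_profiles(datasetA, "A", use_pairs)
    profB_full = build_profiles(datasetB, "B", use_pairs)

    def _without(dataset: TDNADataset, gid: str, taxon: str) -> ClassProfiles:
        rest = dataset.exclude([gid])
        if not rest.records:
            return ClassProfiles.empty(taxon, use_pairs)
        return build_profiles(rest, taxon, use_pairs)

    rows = []

    def _add(gid, part, pA, pB, side):
        rows.append(
            {
                "genome_id": gid,
                "score": score_profile(part, pA, pB, method, eps, pseudocount),
                "n_tdnas": len(part.records),
                "side": side,
            }
        )

    for gid, part in datasetA.by_genome().items():
        _add(gid, part, _without(datasetA, gid, "A"), profB_full, "A")
    for gid, part in datasetB.by_genome().items():
        _add(gid, part, profA_full, _without(datasetB, gid, "B"), "B")
    if query_genomes is not None:
        for gid, part in query_genomes.by_genome().items():
            _add(gid, part, profA_full, profB_full, "query")
    return pd.DataFrame(rows, columns=["genome_id", "score", "n_tdnas", "side"])
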