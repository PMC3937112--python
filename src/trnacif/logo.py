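"""Function-logo estimation and Class-Informative Feature (CIF) extraction.

A *feature* is a nucleotide at a Sprinzl position (or an ordered nucleotide
pair at a canonical stem pairing) in a structurally aligned tDNA.  A function
logo assigns every observed feature a stack of functional-class letters: the
stack height is the information (in bits) the feature carries about tRNA
functional class, corrected for biased class sampling and finite sample size,
and each letter's height is that information times the normalized odds ratio
of the feature appearing in that class.  A CIF is a single letter of such a
logo whose height clears a threshold: a feature over-represented in, and
informative about, one functional class within a taxon set of genomes.

The sample-size correction subtracts the expected apparent information of a
feature seen ``n`` times under the null that classes are drawn i.i.d. from
the background class distribution, estimated by seeded Monte Carlo and cached
per sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .dataset import GAP, NUCLEOTIDES, TDNADataset

__all__ = [
    "Feature",
    "FeatureCounts",
    "FunctionLogo",
    "CIFSet",
    "count_features",
    "background_distribution",
    "feature_information",
    "build_logo",
    "extract_cifs",
    "permutation_pvalue",
    "export_logo_table",
    "import_logo_table",
]

_NUC = frozenset(NUCLEOTIDES)


class Feature(NamedTuple):
    """A single-position or paired nucleotide feature.

    ``kind`` is "single" or "paired"; ``pos`` is a Sprinzl label (single) or a
    (5', 3') label pair; ``state`` is one nucleotide or an ordered two-letter
    nucleotide string.
    """

    kind: str
    pos: object
    state: str

    def positions(self) -> Tuple[str, ...]:
        return (self.pos,) if self.kind == "single" else tuple(self.pos)

    def anchor(self) -> str:
        """The column a feature is attributed to for site resampling: its own
        column for single features, the 5' member for paired features."""
        return self.pos if self.kind == "single" else self.pos[0]

    def __str__(self) -> str:
        if self.kind == "single":
            return f"{self.state}{self.pos}"
        return f"{self.state[0]}{self.pos[0]}:{self.state[1]}{self.pos[1]}"


@dataclass
class FeatureCounts:
    """Empirical feature/class co-occurrence counts for a taxon set."""

    n_total: int
    n_class: Dict[str, int]
    n_feat: Dict[Feature, int]
    n_feat_class: Dict[Tuple[Feature, str], int]


def features_of(seq: str, dataset_or_sprinzl, use_pairs: bool = True) -> List[Feature]:
    """Enumerate the features presented by one aligned sequence.

    Gaps and ambiguity codes yield no features; a paired feature requires both
    member columns ungapped and unambiguous.
    """
    sprinzl = getattr(dataset_or_sprinzl, "sprinzl", dataset_or_sprinzl)
    feats: List[Feature] = []
    for lab, base in zip(sprinzl.labels, seq):
        if base in _NUC:
            feats.append(Feature("single", lab, base))
    if use_pairs:
        idx = sprinzl.index
        for a, b in sprinzl.pair_list:
            x, y = seq[idx[a]], seq[idx[b]]
            if x in _NUC and y in _NUC:
                feats.append(Feature("paired", (a, b), x + y))
    return feats


def count_features(dataset: TDNADataset, use_pairs: bool = True) -> FeatureCounts:
    """Count features and feature-class co-occurrences over a dataset."""
    if not dataset.records:
        raise ValueError("empty dataset")
    n_class: Dict[str, int] = {}
    n_feat: Dict[Feature, int] = {}
    n_feat_class: Dict[Tuple[Feature, str], int] = {}
    for rec in dataset.records:
        n_class[rec.cls] = n_class.get(rec.cls, 0) + 1
        for f in features_of(rec.seq, dataset.sprinzl, use_pairs):
            n_feat[f] = n_feat.get(f, 0) + 1
            key = (f, rec.cls)
            n_feat_class[key] = n_feat_class.get(key, 0) + 1
    return FeatureCounts(len(dataset.records), n_class, n_feat, n_feat_class)


def background_distribution(counts: FeatureCounts) -> Dict[str, float]:
    """Empirical class frequencies of the taxon set (the logo background)."""
    if counts.n_total <= 0:
        raise ValueError("empty counts")
    return {c: n / counts.n_total for c, n in counts.n_class.items()}


def _entropy_bits(probs: Iterable[float]) -> float:
    return float(-sum(p * math.log2(p) for p in probs if p > 0.0))


class SampleSizeCorrection:
    """Seeded Monte-Carlo estimate of the expected apparent information
    ``e(n)`` of a feature sampled ``n`` times from the background, cached per
    sample size.  Each n uses an independent child RNG so the cache is
    order-independent."""

    def __init__(self, background: Dict[str, float], mc_reps: int = 1000, seed: int = 0):
        self.p = np.array([background[c] for c in sorted(background)], dtype=float)
        self.h_bg = _entropy_bits(self.p)
        self.mc_reps = int(mc_reps)
        self.seed = int(seed)
        self._cache: Dict[int, float] = {}

    def __call__(self, n: int) -> float:
        n = int(n)
        e = self._cache.get(n)
        if e is None:
            rng = np.random.default_rng([self.seed, n])
            draws = rng.multinomial(n, self.p, size=self.mc_reps)
            freq = draws / n
            h = -xlogy(freq, freq).sum(axis=1) / math.log(2)
            e = max(0.0, self.h_bg - float(h.mean()))
            self._cache[n] = e
        return e


def feature_information(
    counts: FeatureCounts,
    f: Feature,
    correction: str = "mc",
    mc_reps: int = 1000,
    seed: int = 0,
    _corr: Optional[SampleSizeCorrection] = None,
) -> float:
    """Corrected information (bits) of a feature about functional class:
    ``max(0, H(background) - H(P(class|f)) - e(n_f))``."""
    n_f = counts.n_feat.get(f, 0)
    if n_f <= 0:
        raise KeyError(f"unseen feature {f}")
    bg = background_distribution(counts)
    post = {c: counts.n_feat_class.get((f, c), 0) / n_f for c in bg}
    raw = _entropy_bits(bg.values()) - _entropy_bits(post.values())
    if correction == "none":
        e = 0.0
    elif correction == "mc":
        corr = _corr if _corr is not None else SampleSizeCorrection(bg, mc_reps, seed)
        e = corr(n_f)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return max(0.0, raw - e)


@dataclass
class FunctionLogo:
    """The estimated function logo of a taxon set.

    ``heights`` maps (feature, class) to letter heights in bits (only
    strictly positive entries are stored); ``info`` maps each feature to its
    corrected stack information; ``background`` is the empirical class
    distribution; ``sample_sizes`` records each feature's count.
    """

    background: Dict[str, float]
    info: Dict[Feature, float]
    heights: Dict[Tuple[Feature, str], float]
    sample_sizes: Dict[Feature, int]
    correction: str = "none"
    use_pairs: bool = True

    def height(self, f: Feature, c: str) -> float:
        return self.heights.get((f, c), 0.0)

    def features(self) -> Set[Feature]:
        return set(self.info)

    @staticmethod
    def empty(use_pairs: bool = True) -> "FunctionLogo":
        """Logo of an empty taxon set: every height is zero."""
        return FunctionLogo({}, {}, {}, {}, "none", use_pairs)


def _stack(
    bg: Dict[str, float],
    n_f: int,
    class_counts: Dict[str, int],
    e: float,
) -> Tuple[float, Dict[str, float]]:
    """Stack information and per-class letter heights for one feature.

    Letter heights split the corrected information by the normalized odds
    ratio w(c|f) = (P(c|f)/p(c)) / sum_c' (P(c'|f)/p(c')).
    """
    post = {c: class_counts.get(c, 0) / n_f for c in bg}
    raw = _entropy_bits(bg.values()) - _entropy_bits(post.values())
    info = max(0.0, raw - e)
    if info <= 0.0:
        return 0.0, {}
    odds = {c: post[c] / bg[c] for c in bg if bg[c] > 0}
    tot = sum(odds.values())
    heights = {c: info * w / tot for c, w in odds.items() if w > 0}
    return info, heights


def build_logo(
    dataset: TDNADataset,
    use_pairs: bool = True,
    correction: str = "mc",
    mc_reps: int = 1000,
    seed: int = 0,
) -> FunctionLogo:
    """Estimate the function logo of a taxon set of tDNAs."""
    counts = count_features(dataset, use_pairs)
    bg = background_distribution(counts)
    if correction == "mc":
        corr = SampleSizeCorrection(bg, mc_reps, seed)
    elif correction == "none":
        corr = None
    else:
        raise ValueError(f"unknown correction {correction!r}")

    class_counts_of: Dict[Feature, Dict[str, int]] = {}
    for (f, c), n in counts.n_feat_class.items():
        class_counts_of.setdefault(f, {})[c] = n

    info: Dict[Feature, float] = {}
    heights: Dict[Tuple[Feature, str], float] = {}
    for f, n_f in counts.n_feat.items():
        e = corr(n_f) if corr is not None else 0.0
        stack_info, letter = _stack(bg, n_f, class_counts_of.get(f, {}), e)
        info[f] = stack_info
        for c, h in letter.items():
            heights[(f, c)] = h
    return FunctionLogo(bg, info, heights, dict(counts.n_feat), correction, use_pairs)


@dataclass
class CIFSet:
    """The thresholded CIFs of a function logo: all letters with height at or
    above ``threshold_bits`` (strictly positive when the threshold is 0)."""

    threshold_bits: float
    members: Set[Tuple[Feature, str, float]] = field(default_factory=set)

    def features(self) -> Set[Feature]:
        return {f for f, _, _ in self.members}

    def positions(self) -> Set[str]:
        """All Sprinzl labels touched by member features."""
        out: Set[str] = set()
        for f, _, _ in self.members:
            out.update(f.positions())
        return out

    def __len__(self) -> int:
        return len(self.members)


def extract_cifs(logo: FunctionLogo, threshold_bits: float = 0.0) -> CIFSet:
    """Extract the CIF set of a logo at a height threshold (bits)."""
    if threshold_bits < 0:
        raise ValueError("threshold must be non-negative")
    members = {
        (f, c, h)
        for (f, c), h in logo.heights.items()
        if h >= threshold_bits and h > 0.0
    }
    return CIFSet(threshold_bits, members)


def filter_logo(logo: FunctionLogo, threshold_bits: float) -> FunctionLogo:
    """Truncate a logo to letters with height >= threshold (used by the
    reduced multiway models)."""
    heights = {k: h for k, h in logo.heights.items() if h >= threshold_bits}
    feats = {f for f, _ in heights}
    return FunctionLogo(
        dict(logo.background),
        {f: logo.info[f] for f in feats},
        heights,
        {f: logo.sample_sizes[f] for f in feats},
        logo.correction,
        logo.use_pairs,
    )


def permutation_pvalue(
    dataset: TDNADataset,
    f: Feature,
    c: str,
    reps: int = 999,
    seed: int = 0,
    use_pairs: bool = True,
) -> float:
    """Permutation p-value of a letter height under shuffling of class labels
    across tDNAs: ``(1 + #{permuted height >= observed}) / (reps + 1)``.

    Heights are compared uncorrected: the sample-size correction depends only
    on the feature's count, which label permutation preserves, so corrected
    and uncorrected orderings coincide.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    counts = count_features(dataset, use_pairs)
    if (f, c) not in counts.n_feat_class:
        raise KeyError(f"unseen feature/class {(f, c)}")
    bg = background_distribution(counts)
    n_f = counts.n_feat[f]

    labels = np.array([r.cls for r in dataset.records])
    carriers = np.array(
        [
            i
            for i, r in enumerate(dataset.records)
            if f in set(features_of(r.seq, dataset.sprinzl, use_pairs))
        ]
    )

    def height_of(lab: np.ndarray) -> float:
        vals, cnt = np.unique(lab[carriers], return_counts=True)
        _, letter = _stack(bg, n_f, dict(zip(vals.tolist(), cnt.tolist())), 0.0)
        return letter.get(c, 0.0)

    observed = height_of(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        hits += height_of(rng.permutation(labels)) >= observed
    return (1 + hits) / (reps + 1)


def _pos_key(f: Feature) -> str:
    return f.pos if f.kind == "single" else f"{f.pos[0]}:{f.pos[1]}"


def export_logo_table(logo: FunctionLogo, path) -> None:
    """Write a logo as a TSV of (position, state, class, height_bits,
    info_bits, n), sorted by position then descending height."""
    rows = [
        {
            "position": _pos_key(f),
            "state": f.state,
            "class": c,
            "height_bits": h,
            "info_bits": logo.info[f],
            "n": logo.sample_sizes[f],
        }
        for (f, c), h in logo.heights.items()
    ]
    df = pd.DataFrame(
        rows, columns=["position", "state", "class", "height_bits", "info_bits", "n"]
    )
    if len(df):
        df = df.sort_values(
            ["position", "height_bits"], ascending=[True, False], kind="stable"
        )
    df.to_csv(path, sep="\t", index=False)


def import_logo_table(path) -> pd.DataFrame:
    """Read back a logo table written by :func:`export_logo_table`."""
    return pd.read_csv(path, sep="\t", dtype={"position": str, "state": str, "class": str})
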