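"""Clade-structured synthetic tDNA data with planted CIFs.

The generator emulates the structure the CIF machinery exploits in real
genomic tRNA data, without any download:

* a shared gap pattern and a small set of universal *class-diagnostic* sites
  (an anticodon analog) at which the 22 class templates differ — these mimic
  universal identity elements, informative about class in every clade;
* per-clade *body* states at all sites where the class templates agree,
  drawn to match the clade's target G+C content and shared by all classes in
  the clade — these carry compositional signal but, being identical across
  classes, contribute nothing to a function logo;
* *planted clade CIFs*: (feature, class) pairs imposed on the clade's genes
  of that class with probability ``cif_fidelity`` — the clade-specific
  signatures the classifiers must recover;
* i.i.d. per-site substitution noise at rate ``background_noise`` with
  replacement bases matching the clade's G+C bias.

:func:`converge` then emulates compositional convergence: G/C bases of chosen
genomes are rewritten to A/T at unprotected sites, the synthetic analog of
the A+T drift that pulls streamlined genomes toward unrelated A+T-rich clades
under total-sequence methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .dataset import AlignedTDNA, GAP, NUCLEOTIDES, TDNADataset
from .logo import CIFSet, Feature
from .sprinzl import SprinzlMap, default_sprinzl_map

__all__ = [
    "CladeSpec",
    "GeneratorConfig",
    "build_class_templates",
    "generate",
    "converge",
    "DIAGNOSTIC_SITES",
]

#: Universal class-diagnostic Sprinzl sites (anticodon triplet + discriminator).
DIAGNOSTIC_SITES = ("34", "35", "36", "73")

_CLASSES_ORDERED = tuple(sorted("ACDEFGHIKLMNPQRSTVWY") + ["X", "J"])


@dataclass
class CladeSpec:
    """Specification of one synthetic clade."""

    name: str
    n_genomes: int
    genes_per_class: Dict[str, int]
    gc_bias: float = 0.60
    planted_cifs: List[Tuple[Feature, str]] = field(default_factory=list)
    cif_fidelity: float = 0.95

    def __post_init__(self):
        if not (0.0 < self.gc_bias < 1.0):
            raise ValueError("gc_bias must be in (0, 1)")
        if not (0.5 <= self.cif_fidelity <= 1.0):
            raise ValueError("cif_fidelity must be in [0.5, 1]")


@dataclass
class GeneratorConfig:
    """Full generator configuration: coordinate map, clades, per-class master
    templates, substitution noise and the master seed."""

    sprinzl: SprinzlMap
    clades: List[CladeSpec]
    class_templates: Dict[str, str]
    background_noise: float = 0.02
    seed: int = 0

    def __post_init__(self):
        ncol = len(self.sprinzl)
        for c, t in self.class_templates.items():
            if len(t) != ncol:
                raise ValueError(f"template for class {c!r} has wrong length")


def build_class_templates(
    sprinzl: Optional[SprinzlMap] = None,
    classes: Sequence[str] = _CLASSES_ORDERED,
    seed: int = 0,
) -> Dict[str, str]:
    """Master per-class templates: a shared random body (G+C 0.5), a gap at
    position -1, and class-specific states at the diagnostic sites.

    The anticodon-analog states enumerate base-4 codes so any two classes
    differ at one or more diagnostic sites.
    """
    sprinzl = sprinzl or default_sprinzl_map()
    rng = np.random.default_rng([seed, 777])
    body = rng.choice(list(NUCLEOTIDES), size=len(sprinzl))
    templates = {}
    diag_idx = [sprinzl.column(s) for s in DIAGNOSTIC_SITES if s in sprinzl.index]
    gap_idx = [sprinzl.column("-1")] if "-1" in sprinzl.index else []
    for i, c in enumerate(classes):
        t = body.copy()
        code = [(i // 1) % 4, (i // 4) % 4, (i // 16) % 4, i % 4]
        for j, col in enumerate(diag_idx):
            t[col] = NUCLEOTIDES[code[j]]
        for col in gap_idx:
            t[col] = GAP
        templates[c] = "".join(t)
    return templates


def _noise_dist(gc_bias: float) -> np.ndarray:
    return np.array(
        [(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2]
    )


def generate(
    config: GeneratorConfig,
) -> Tuple[TDNADataset, Dict[str, str], Dict[str, List[Tuple[Feature, str]]]]:
    """Generate a clade-structured dataset.

    Returns ``(dataset, truth, planted)``: the dataset (with ``taxon_of`` set
    to the true clade labels), the genome -> clade truth map, and the planted
    CIF list per clade.  Output is byte-identical for a fixed seed.
    """
    sprinzl = config.sprinzl
    ncol = len(sprinzl)
    templates = {c: list(t) for c, t in config.class_templates.items()}
    classes = sorted(templates)

    # columns where all class templates agree on a nucleotide: the shared body
    body_cols = [
        j
        for j in range(ncol)
        if len({templates[c][j] for c in classes}) == 1
        and templates[classes[0]][j] != GAP
    ]

    records: List[AlignedTDNA] = []
    truth: Dict[str, str] = {}
    planted_out: Dict[str, List[Tuple[Feature, str]]] = {}

    for ci, clade in enumerate(config.clades):
        rng = np.random.default_rng([config.seed, ci])
        planted_out[clade.name] = list(clade.planted_cifs)

        # planted feature -> column indices and states; validate positions
        plant_by_class: Dict[str, List[Tuple[List[int], str]]] = {}
        planted_cols: set = set()
        seen_states: Dict[Tuple[str, str], str] = {}
        for f, cls in clade.planted_cifs:
            cols = [sprinzl.column(p) for p in f.positions()]
            for col, pos in zip(cols, f.positions()):
                if all(templates[c][col] == GAP for c in classes):
                    raise ValueError(
                        f"planted feature {f} at gapped template position {pos}"
                    )
            for pos, s in zip(f.positions(), f.state):
                prev = seen_states.get((pos, s))
                if prev is not None and prev != cls:
                    warnings.warn(
                        f"planted feature state {s}{pos} collides across classes "
                        f"{prev!r} and {cls!r} in clade {clade.name!r}",
                        stacklevel=2,
                    )
                seen_states[(pos, s)] = cls
            plant_by_class.setdefault(cls, []).append((cols, f.state))
            planted_cols.update(cols)

        # at this clade's own planted columns the body equilibrium excludes
        # the planted state, so the planted feature stays the class's marker
        # rather than part of the clade background
        avoid: Dict[int, set] = {}
        for lst in plant_by_class.values():
            for cols, state in lst:
                for col, s in zip(cols, state):
                    avoid.setdefault(col, set()).add(s)

        # body sites: per-gene i.i.d. draws from the clade's compositional
        # equilibrium (G+C = gc_bias).  Shared across classes in distribution,
        # these sites carry the clade's composition but no class information;
        # their softness is what gives class profiles composition-reflecting
        # frequencies, as within-clade sequence variation does in real data.
        noise_p = _noise_dist(clade.gc_bias)
        plain_body = [j for j in body_cols if j not in avoid]
        avoid_body = [j for j in body_cols if j in avoid]
        avoid_dists = {}
        for j in avoid_body:
            p = noise_p.copy()
            for s in avoid[j]:
                p[NUCLEOTIDES.index(s)] = 0.0
            avoid_dists[j] = p / p.sum()

        template_cols = [
            j
            for j in range(ncol)
            if j not in body_cols and templates[classes[0]][j] != GAP
        ]
        for gi in range(clade.n_genomes):
            gid = f"{clade.name}_g{gi + 1}"
            truth[gid] = clade.name
            for cls in classes:
                n_genes = clade.genes_per_class.get(cls, 0)
                for k in range(n_genes):
                    seq = list(templates[cls])
                    draws = rng.choice(4, size=len(plain_body), p=noise_p)
                    for j, d in zip(plain_body, draws):
                        seq[j] = NUCLEOTIDES[d]
                    for j in avoid_body:
                        seq[j] = NUCLEOTIDES[int(rng.choice(4, p=avoid_dists[j]))]
                    # substitution noise at template-retained (class) sites
                    for j in template_cols:
                        if seq[j] != GAP and rng.random() < config.background_noise:
                            seq[j] = NUCLEOTIDES[int(rng.choice(4, p=noise_p))]
                    # planted CIF states imposed last (fidelity exact)
                    for cols, state in plant_by_class.get(cls, []):
                        if rng.random() < clade.cif_fidelity:
                            for col, s in zip(cols, state):
                                seq[col] = s
                    records.append(
                        AlignedTDNA(gid, f"{gid}_{cls}{k + 1}", cls, "".join(seq))
                    )
    dataset = TDNADataset(sprinzl, records, dict(truth))
    return dataset, truth, planted_out


def _protected_positions(protect) -> set:
    if protect is None:
        return set()
    if isinstance(protect, CIFSet):
        return protect.positions()
    out = set()
    for item in protect:
        if isinstance(item, Feature):
            out.update(item.positions())
        elif isinstance(item, tuple) and len(item) >= 1 and isinstance(item[0], Feature):
            out.update(item[0].positions())
        else:
            out.add(str(item))
    return out


def converge(
    dataset: TDNADataset,
    genomes: Iterable[str],
    at_shift: float,
    protect=None,
    seed: int = 0,
) -> TDNADataset:
    """Drive the named genomes' tRNA genes A+T-rich.

    At each unprotected, ungapped site of the named genomes' genes, a G or C
    is rewritten to A or T (equiprobably) with probability ``at_shift``.
    ``protect`` may be a :class:`CIFSet`, an iterable of planted
    (Feature, class) pairs or Features, or an iterable of Sprinzl labels;
    protected positions are untouched.
    """
    if not (0.0 <= at_shift <= 1.0):
        raise ValueError("at_shift must be in [0, 1]")
    genomes = set(genomes)
    unknown = genomes - set(dataset.genome_ids)
    if unknown:
        raise ValueError(f"unknown genome(s): {sorted(unknown)!r}")
    protected = _protected_positions(protect)
    prot_idx = {dataset.sprinzl.column(p) for p in protected if p in dataset.sprinzl.index}
    rng = np.random.default_rng(seed)
    records = []
    for rec in dataset.records:
        if rec.genome_id not in genomes:
            records.append(rec)
            continue
        seq = list(rec.seq)
        for j, b in enumerate(seq):
            if j in prot_idx or b not in ("G", "C"):
                continue
            if rng.random() < at_shift:
                seq[j] = "A" if rng.random() < 0.5 else "T"
        records.append(AlignedTDNA(rec.genome_id, rec.gene_id, rec.cls, "".join(seq)))
    return TDNADataset(dataset.sprinzl, records, dict(dataset.taxon_of))
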