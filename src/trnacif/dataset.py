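"""Core containers for structurally aligned tRNA gene (tDNA) data.

A genome is represented by the multiset of tDNA sequences it contains; each
tDNA carries a functional-class label drawn from a 22-letter alphabet: the 20
IUPAC amino-acid letters for aminoacylation classes, "X" for initiator tRNAs,
and "J" for the CAU-anticodon isoleucine class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

from .sprinzl import SprinzlMap

__all__ = ["CLASS_ALPHABET", "GAP", "NUCLEOTIDES", "AlignedTDNA", "TDNADataset"]

#: The 22 tRNA functional classes: 20 amino acids + initiator (X) + Ile-CAU (J).
CLASS_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | frozenset("XJ")

GAP = "-"
NUCLEOTIDES = ("A", "C", "G", "T")
_NUC_SET = frozenset(NUCLEOTIDES)

# IUPAC ambiguity codes accepted on input; they yield no features.
_AMBIGUITY = frozenset("RYSWKMBDHVN")


@dataclass(frozen=True)
class AlignedTDNA:
    """One aligned tRNA gene: genome of origin, gene id, functional class,
    and a gap-containing sequence over the dataset's Sprinzl columns."""

    genome_id: str
    gene_id: str
    cls: str
    seq: str

    def __post_init__(self):
        if self.cls not in CLASS_ALPHABET:
            raise ValueError(f"illegal class symbol {self.cls!r}")
        bad = set(self.seq) - _NUC_SET - {GAP} - _AMBIGUITY
        if bad:
            raise ValueError(f"illegal sequence character(s) {sorted(bad)!r}")


@dataclass
class TDNADataset:
    """A multiset of aligned tDNAs sharing one Sprinzl map, optionally with a
    genome -> clade assignment."""

    sprinzl: SprinzlMap
    records: List[AlignedTDNA] = field(default_factory=list)
    taxon_of: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ncol = len(self.sprinzl)
        for r in self.records:
            if len(r.seq) != ncol:
                raise ValueError(
                    f"sequence length {len(r.seq)} of {r.genome_id}|{r.gene_id} "
                    f"does not match the {ncol}-column Sprinzl map"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TDNADataset):
            return NotImplemented
        return (
            self.sprinzl.labels == other.sprinzl.labels
            and self.sprinzl.pair_list == other.sprinzl.pair_list
            and self.records == other.records
            and self.taxon_of == other.taxon_of
        )

    @property
    def genome_ids(self) -> List[str]:
        """Genome ids in order of first appearance."""
        seen: Dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.genome_id, None)
        return list(seen)

    def restrict(self, genome_ids: Iterable[str]) -> "TDNADataset":
        """Sub-dataset containing only the named genomes (record order kept)."""
        keep = set(genome_ids)
        return TDNADataset(
            self.sprinzl,
            [r for r in self.records if r.genome_id in keep],
            {g: c for g, c in self.taxon_of.items() if g in keep},
        )

    def exclude(self, genome_ids: Iterable[str]) -> "TDNADataset":
        """Sub-dataset with the named genomes removed."""
        drop = set(genome_ids)
        return TDNADataset(
            self.sprinzl,
            [r for r in self.records if r.genome_id not in drop],
            {g: c for g, c in self.taxon_of.items() if g not in drop},
        )

    def by_genome(self) -> Dict[str, "TDNADataset"]:
        """Split into one single-genome dataset per genome id."""
        out: Dict[str, TDNADataset] = {}
        for r in self.records:
            out.setdefault(
                r.genome_id, TDNADataset(self.sprinzl, [], dict(self.taxon_of))
            ).records.append(r)
        return out
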