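"""Readers, writers and partitioning for aligned tDNA datasets.

Two on-disk formats are supported:

* **tDNA table** (TSV): line 1 is ``#SPRINZL<TAB>label1<TAB>label2...``;
  each data line is ``genome_id<TAB>gene_id<TAB>class<TAB>sequence``.
* **Stockholm 1.0** with a per-column ``#=GC SPRINZL`` annotation giving
  comma-separated Sprinzl labels; sequence names encode
  ``genome_id|gene_id|class``.

Sequences are stored as DNA (U is normalized to T), upper-case, with "-" as
the only gap character ("." is normalized on read).  The tDNA gene, not the
mature tRNA, is the unit of analysis.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, Optional, TextIO, Tuple, Union

from Bio import AlignIO

from .dataset import CLASS_ALPHABET, AlignedTDNA, TDNADataset
from .sprinzl import SprinzlMap, default_sprinzl_map

__all__ = [
    "read_tdna_table",
    "write_tdna_table",
    "read_stockholm",
    "read_taxon_map",
    "partition",
]

log = logging.getLogger(__name__)

_VALID_SEQ = frozenset("ACGT-RYSWKMBDHVN")


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T").replace(".", "-")


def _validate_row(
    genome_id: str, gene_id: str, cls: str, seq: str, ncol: int, where: str
) -> AlignedTDNA:
    cls = cls.upper()
    if cls not in CLASS_ALPHABET:
        raise ValueError(f"{where}: illegal class symbol {cls!r}")
    seq = _normalize_seq(seq)
    if len(seq) != ncol:
        raise ValueError(
            f"{where}: sequence length {len(seq)} does not match "
            f"{ncol}-label header"
        )
    bad = set(seq) - _VALID_SEQ
    if bad:
        raise ValueError(f"{where}: illegal sequence character(s) {sorted(bad)!r}")
    return AlignedTDNA(genome_id, gene_id, cls, seq)


def read_tdna_table(
    path, strict: bool = True, pair_list: Optional[tuple] = None
) -> TDNADataset:
    """Read a tab-delimited tDNA table.

    Parameters
    ----------
    path
        File path (or open text handle).
    strict
        If True (default) any malformed row raises ``ValueError`` naming the
        row; otherwise offending rows are skipped with a logged warning.
    pair_list
        Optional pairing override.  If the header's labels equal the default
        Sprinzl map's, the canonical pair list is attached automatically.
    """
    close = False
    if hasattr(path, "read"):
        fh: TextIO = path
    else:
        fh = open(path, "r", encoding="utf-8")
        close = True
    try:
        header = fh.readline().rstrip("\n")
        fields = header.split("\t")
        if not header or fields[0] != "#SPRINZL" or len(fields) < 2:
            raise ValueError("malformed header: expected '#SPRINZL<TAB>label...'")
        labels = tuple(fields[1:])
        default = default_sprinzl_map()
        if pair_list is not None:
            sprinzl = SprinzlMap(labels, pair_list)
        elif labels == default.labels:
            sprinzl = default
        else:
            sprinzl = SprinzlMap(labels)
        records = []
        seen = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                if len(parts) != 4:
                    raise ValueError(f"row {lineno}: expected 4 fields, got {len(parts)}")
                rec = _validate_row(*parts, len(sprinzl), f"row {lineno}")
                key = (rec.genome_id, rec.gene_id)
                if key in seen:
                    raise ValueError(f"row {lineno}: duplicate gene {key!r}")
                seen.add(key)
            except ValueError as exc:
                if strict:
                    raise
                log.warning("skipping malformed row: %s", exc)
                continue
            records.append(rec)
        return TDNADataset(sprinzl, records)
    finally:
        if close:
            fh.close()


def write_tdna_table(dataset: TDNADataset, path) -> None:
    """Write a dataset as a tDNA table; round-trips bit-exactly through
    :func:`read_tdna_table`."""
    close = False
    if hasattr(path, "write"):
        fh: TextIO = path
    else:
        fh = open(path, "w", encoding="utf-8", newline="\n")
        close = True
    try:
        fh.write("#SPRINZL\t" + "\t".join(dataset.sprinzl.labels) + "\n")
        for r in dataset.records:
            fh.write(f"{r.genome_id}\t{r.gene_id}\t{r.cls}\t{r.seq}\n")
    finally:
        if close:
            fh.close()


def read_stockholm(path, coord_line_tag: str = "SPRINZL") -> TDNADataset:
    """Read a Stockholm 1.0 alignment whose ``#=GC <coord_line_tag>`` line
    gives comma-separated Sprinzl labels and whose sequence names encode
    ``genome_id|gene_id|class``."""
    # The coordinate annotation is a comma-separated label list, not a
    # one-character-per-column string, so it is extracted here and removed
    # from the text handed to Biopython's Stockholm parser.
    coord: Optional[str] = None
    kept_lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith(f"#=GC {coord_line_tag}"):
                coord = line.split(None, 2)[2].strip()
            else:
                kept_lines.append(line)
    if coord is None:
        raise ValueError(f"missing '#=GC {coord_line_tag}' coordinate annotation")
    labels = tuple(coord.split(","))
    default = default_sprinzl_map()
    sprinzl = default if labels == default.labels else SprinzlMap(labels)

    from io import StringIO

    aln = AlignIO.read(StringIO("".join(kept_lines)), "stockholm")
    records = []
    seen = set()
    for rec in aln:
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"sequence name {rec.id!r} not parseable as genome_id|gene_id|class"
            )
        tdna = _validate_row(*parts, str(rec.seq), len(sprinzl), f"sequence {rec.id!r}")
        key = (tdna.genome_id, tdna.gene_id)
        if key in seen:
            raise ValueError(f"duplicate gene {key!r}")
        seen.add(key)
        records.append(tdna)
    return TDNADataset(sprinzl, records)


def read_taxon_map(path) -> Dict[str, str]:
    """Read a two-column TSV of genome_id -> clade."""
    out: Dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"taxon map row {lineno}: expected 2 fields")
            out[parts[0]] = parts[1]
    return out


def partition(
    dataset: TDNADataset, taxa: Dict[str, str]
) -> Tuple[Dict[str, TDNADataset], TDNADataset]:
    """Partition a dataset by clade.

    Returns ``(parts, unassigned)`` where ``parts`` maps each clade label to
    the sub-dataset of its genomes and ``unassigned`` holds records of genomes
    absent from ``taxa``.  Every record lands in exactly one output.
    """
    if any(not c for c in taxa.values()):
        raise ValueError("empty clade label in taxon map")
    known_genomes = set(dataset.genome_ids)
    for g in taxa:
        if g not in known_genomes:
            warnings.warn(f"taxon map genome {g!r} has no records", stacklevel=2)
    parts: Dict[str, TDNADataset] = {}
    unassigned = TDNADataset(dataset.sprinzl, [], {})
    for clade in dict.fromkeys(taxa.values()):
        parts[clade] = TDNADataset(dataset.sprinzl, [], {})
    for r in dataset.records:
        clade = taxa.get(r.genome_id)
        if clade is None:
            unassigned.records.append(r)
        else:
            parts[clade].records.append(r)
            parts[clade].taxon_of[r.genome_id] = clade
    return parts, unassigned
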