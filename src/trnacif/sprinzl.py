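"""Sprinzl coordinate maps for structurally aligned tRNA genes.

tRNA structural sites are conventionally enumerated by *Sprinzl coordinates*:
the positions -1, 1..76 of the canonical cloverleaf, with insertion labels
(e.g. "17a", "e11") for the variable regions.  Columns of a structural
alignment are identified by these label strings, never by integer offsets,
so that homologous sites can be compared across tRNAs and across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

__all__ = ["SprinzlMap", "default_sprinzl_map"]


@dataclass(frozen=True)
class SprinzlMap:
    """Ordered Sprinzl column labels plus the canonical secondary-structure pairing.

    Parameters
    ----------
    labels
        One label per alignment column, in column order.  Labels are arbitrary
        non-empty strings; the standard set is "-1", "1" .. "76" plus insertion
        labels such as "17a" or "e11".
    pair_list
        Ordered (5', 3') label pairs designating canonical stem pairings,
        used for paired features.  Every label must occur in ``labels`` and
        in at most one pair.
    """

    labels: Tuple[str, ...]
    pair_list: Tuple[Tuple[str, str], ...] = ()
    index: dict = field(init=False, repr=False, compare=False)

    def __init__(self, labels: Sequence[str], pair_list: Sequence[Tuple[str, str]] = ()):
        labels = tuple(str(x) for x in labels)
        pair_list = tuple((str(a), str(b)) for a, b in pair_list)
        if len(set(labels)) != len(labels):
            raise ValueError("Sprinzl labels must be unique")
        if any(not x for x in labels):
            raise ValueError("Sprinzl labels must be non-empty")
        seen = set()
        label_set = set(labels)
        for a, b in pair_list:
            for x in (a, b):
                if x not in label_set:
                    raise ValueError(f"pair label {x!r} not among alignment labels")
                if x in seen:
                    raise ValueError(f"label {x!r} occurs in more than one pair")
                seen.add(x)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "pair_list", pair_list)
        object.__setattr__(self, "index", {lab: i for i, lab in enumerate(labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def column(self, label: str) -> int:
        """Column index of a Sprinzl label."""
        return self.index[label]


# Canonical cloverleaf stems (5' label, 3' label), acceptor / D / anticodon / T.
_CANONICAL_PAIRS = (
    [(str(i), str(73 - i)) for i in range(1, 8)]          # acceptor stem 1:72 .. 7:66
    + [(str(i), str(35 - i)) for i in range(10, 14)]      # D stem 10:25 .. 13:22
    + [(str(i), str(70 - i)) for i in range(27, 32)]      # anticodon stem 27:43 .. 31:39
    + [(str(i), str(114 - i)) for i in range(49, 54)]     # T stem 49:65 .. 53:61
)


def default_sprinzl_map() -> SprinzlMap:
    """The standard 77-column map: position -1 followed by 1..76, with the
    canonical acceptor/D/anticodon/T-stem pair list."""
    labels = ["-1"] + [str(i) for i in range(1, 77)]
    return SprinzlMap(labels, _CANONICAL_PAIRS)
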