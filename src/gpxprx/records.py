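"""Core record types shared across the package.

A :class:`ProteinRecord` is one protein sequence plus optional metadata:
a taxon label, a phylum assignment (used by the phylogeny stage) and, for
synthetic benchmark data, the planted ground-truth class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

#: The 20 canonical amino acids, one-letter codes, alphabetical.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Letters accepted in a protein sequence: canonical residues plus
#: selenocysteine ('U', IUPAC) and unknown ('X').
SEQUENCE_ALPHABET = set(AA20) | {"U", "X"}

GAP = "-"


class GpxClass(str, enum.Enum):
    """The three sequence classes of the Gpx/Prx decision rule.

    TRX_GPXLIKE_PRX
        Thioredoxin-dependent, Gpx-like peroxiredoxin: peroxidatic Cys,
        conserved resolving Cys, no dimer/oligomerization interface loops.
    CANONICAL_GSH_GPX
        Canonical glutathione-dependent Gpx: selenocysteine (or Cys) at the
        peroxidatic site, no resolving Cys, interface loops present.
    AMBIGUOUS
        Anything the two patterns above do not cover (e.g. 1-Cys-like
        sequences with a peroxidatic Cys but no resolving Cys and no loops).
    """

    TRX_GPXLIKE_PRX = "TRX_GPXLIKE_PRX"
    CANONICAL_GSH_GPX = "CANONICAL_GSH_GPX"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass
class ProteinRecord:
    """One protein sequence with optional labels.

    Parameters
    ----------
    id :
        Non-empty identifier, unique within a collection.
    sequence :
        Amino-acid string over the 20 canonical letters plus ``U`` and ``X``.
        Unaligned records must not contain gap characters.
    taxon_label, phylum :
        Optional taxonomy metadata.
    truth_class :
        Planted ground-truth class for synthetic records, if known.
    """

    id: str
    sequence: str
    taxon_label: Optional[str] = None
    phylum: Optional[str] = None
    truth_class: Optional[GpxClass] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid sequence characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_sequence(self, sequence: str) -> "ProteinRecord":
        return replace(self, sequence=sequence)


def check_unique_ids(records) -> None:
    """Raise ``ValueError`` naming the first duplicated id, if any."""
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
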