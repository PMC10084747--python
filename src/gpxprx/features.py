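"""Reference-anchored feature extraction and the three-criterion
classification of Gpx-like sequences.

A sequence is called a TRX-dependent, Gpx-like peroxiredoxin when
(i) the peroxidatic residue is Cys (not selenocysteine),
(ii) a resolving Cys is present in the "Cys block" on helix alpha-1a, and
(iii) the dimer-interface loop ("PGGG" functional helix) and the C-terminal
oligomerization loop are both absent.
A selenocysteine at the peroxidatic site — or a Cys with no resolving Cys
but both interface loops — marks a canonical GSH-dependent Gpx; everything
else is ambiguous (1-Cys-like patterns, degraded sites).

All positions are expressed in the reference numbering of a user-chosen
reference row of the alignment (the classic Gpx numbering with the
peroxidatic site at 61, Gln95/Trp150/Asn151 completing the catalytic
tetrad, and the resolving Cys at 107).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .alignment import Alignment
from .records import GAP, GpxClass

log = logging.getLogger(__name__)


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceSites:
    """Diagnostic positions and regions, in reference coordinates.

    Defaults follow the classic Gpx numbering: catalytic tetrad at
    61/95/150/151, resolving Cys at 107 inside a Cys-block window 103–113,
    TRX-binding residues Pro97/Phe106/Tyr111, GSH-binding residues
    Arg57/Arg185/Met147 (bovine numbering carried over as reference-map
    positions), and placeholder dimer-loop / oligomerization-loop intervals
    126–146 and 155–175.  For real data the loop intervals must come from
    the user's own region definitions; synthetic cohorts use the
    generator's planted coordinates, which default to the same values.
    """

    peroxidatic: int = 61
    gln: int = 95
    trp: int = 150
    asn: int = 151
    resolving: int = 107
    cys_block: Tuple[int, int] = (103, 113)
    trx_binding: Tuple[int, int, int] = (97, 106, 111)
    gsh_binding: Tuple[int, int, int] = (57, 185, 147)
    dimer_loop: Tuple[int, int] = (126, 146)
    oligo_loop: Tuple[int, int] = (155, 175)
    pggg_motif: str = "PGGG"
    pggg_max_mismatch: int = 1
    oligo_min_insert: int = 8
    max_region_gap_fraction: float = 0.5

    @property
    def tetrad(self) -> Tuple[int, int, int, int]:
        return (self.peroxidatic, self.gln, self.trp, self.asn)


DEFAULT_SITES = ReferenceSites()


@dataclass
class ColumnMap:
    """Bijection from reference residue numbering to alignment columns.

    Reference position ``k`` is the k-th non-gap residue of the reference
    row (1-based); ``ref_to_col[k]`` is its 1-based alignment column.
    ``regions`` are named intervals in reference coordinates.
    """

    reference_id: str
    ref_to_col: Dict[int, int]
    regions: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    @property
    def reference_length(self) -> int:
        return len(self.ref_to_col)

    def col(self, ref_pos: int) -> int:
        if ref_pos not in self.ref_to_col:
            raise FeatureError(
                f"reference position {ref_pos} beyond reference length "
                f"{self.reference_length}"
            )
        return self.ref_to_col[ref_pos]

    def region_col_span(self, name: str) -> Tuple[int, int]:
        """Column interval covered by a named region (inclusive)."""
        start, end = self.regions[name]
        return self.col(start), self.col(end)


def map_reference_columns(
    aln: Alignment,
    reference_id: str,
    regions: Optional[Dict[str, Tuple[int, int]]] = None,
    sites: ReferenceSites = DEFAULT_SITES,
) -> ColumnMap:
    """Build the reference-position -> alignment-column map.

    ``regions`` defaults to the cys_block / dimer_loop / oligo_loop
    intervals of ``sites``.
    """
    if reference_id not in aln.rows:
        raise FeatureError(f"reference row {reference_id!r} not in alignment")
    row = aln.rows[reference_id]
    ref_to_col: Dict[int, int] = {}
    k = 0
    for c, ch in enumerate(row, start=1):
        if ch != GAP:
            k += 1
            ref_to_col[k] = c
    if not ref_to_col:
        raise FeatureError(f"reference row {reference_id!r} is all gaps")
    if regions is None:
        regions = {
            "cys_block": sites.cys_block,
            "dimer_loop": sites.dimer_loop,
            "oligo_loop": sites.oligo_loop,
        }
    return ColumnMap(reference_id, ref_to_col, dict(regions))


@dataclass
class FeatureProfile:
    """Diagnostic features of one aligned sequence, in reference coordinates."""

    seq_id: str
    peroxidatic_residue: str
    tetrad_residues: Tuple[str, str, str, str]
    tetrad_ok: bool
    resolving_cys: bool
    resolving_residue: str
    has_dimer_loop: bool
    has_oligo_loop: bool
    trx_residues: Tuple[str, str, str]
    gsh_residues: Tuple[str, str, str]
    unalignable: bool = False


def _letter(row: str, colmap: ColumnMap, ref_pos: int) -> str:
    return row[colmap.col(ref_pos) - 1]


def _hamming_le(a: str, b: str, k: int) -> bool:
    return sum(x != y for x, y in zip(a, b)) <= k


def extract_features(
    aln: Alignment,
    colmap: ColumnMap,
    seq_id: str,
    sites: ReferenceSites = DEFAULT_SITES,
) -> FeatureProfile:
    """Read the diagnostic letters and loop-domain evidence for one row.

    - resolving Cys: a ``C`` at the resolving position or anywhere in the
      Cys-block window.
    - dimer loop: a PGGG-like match (<= ``pggg_max_mismatch`` mismatches) in
      the degapped dimer-loop region, provided the row covers the region
      (region gap fraction < ``max_region_gap_fraction``).
    - oligomerization loop: an ungapped insertion of >=
      ``oligo_min_insert`` residues within the oligo-loop column span at
      columns where the reference row is gapped.
    """
    if seq_id not in aln.rows:
        raise FeatureError(f"{seq_id!r} not in alignment")
    row = aln.rows[seq_id]
    ref_row = aln.rows[colmap.reference_id]

    tetrad = tuple(_letter(row, colmap, p) for p in sites.tetrad)
    trx = tuple(_letter(row, colmap, p) for p in sites.trx_binding)
    gsh = tuple(_letter(row, colmap, p) for p in sites.gsh_binding)
    resolving_residue = _letter(row, colmap, sites.resolving)

    diagnostic = list(sites.tetrad) + [sites.resolving] + list(sites.trx_binding)
    if all(_letter(row, colmap, p) == GAP for p in diagnostic):
        return FeatureProfile(
            seq_id, GAP, tetrad, False, False, GAP, False, False, trx, gsh,
            unalignable=True,
        )

    block_lo, block_hi = colmap.regions.get("cys_block", sites.cys_block)
    block_letters = [
        _letter(row, colmap, p)
        for p in range(block_lo, min(block_hi, colmap.reference_length) + 1)
    ]
    resolving_cys = resolving_residue == "C" or "C" in block_letters

    # dimer loop: PGGG-like motif within the region, row must cover region
    has_dimer = False
    if "dimer_loop" in colmap.regions:
        lo, hi = colmap.region_col_span("dimer_loop")
        segment = row[lo - 1 : hi]
        gap_frac = segment.count(GAP) / len(segment) if segment else 1.0
        if gap_frac < sites.max_region_gap_fraction:
            degapped = segment.replace(GAP, "")
            motif = sites.pggg_motif
            for i in range(len(degapped) - len(motif) + 1):
                if _hamming_le(degapped[i : i + len(motif)], motif,
                               sites.pggg_max_mismatch):
                    has_dimer = True
                    break

    # oligomerization loop: run of >= oligo_min_insert residues where the
    # reference is gapped, inside the oligo-loop column span
    has_oligo = False
    if "oligo_loop" in colmap.regions:
        lo, hi = colmap.region_col_span("oligo_loop")
        run = 0
        for c in range(lo - 1, hi):
            if ref_row[c] == GAP and row[c] != GAP:
                run += 1
                if run >= sites.oligo_min_insert:
                    has_oligo = True
                    break
            else:
                run = 0

    return FeatureProfile(
        seq_id=seq_id,
        peroxidatic_residue=tetrad[0],
        tetrad_residues=tetrad,
        tetrad_ok=(tetrad[1] == "Q" and tetrad[2] == "W" and tetrad[3] == "N"),
        resolving_cys=resolving_cys,
        resolving_residue=resolving_residue,
        has_dimer_loop=has_dimer,
        has_oligo_loop=has_oligo,
        trx_residues=trx,
        gsh_residues=gsh,
    )


@dataclass
class ClassificationResult:
    seq_id: str
    gpx_class: GpxClass
    peroxidatic_cys_conserved: bool  # criterion i
    resolving_cys_present: bool      # criterion ii
    interface_domains_absent: bool   # criterion iii
    evidence: str = ""


def classify(profile: FeatureProfile) -> ClassificationResult:
    """Apply the three-criterion decision rule to one feature profile.

    TRX-dependent Gpx-like Prx  <=> all three criteria hold.
    Canonical GSH-dependent Gpx <=> selenocysteine at the peroxidatic site,
    or peroxidatic Cys with no resolving Cys and both interface loops
    present.  Everything else (including a peroxidatic residue that is
    neither C nor U) is ambiguous.
    """
    if profile.unalignable:
        raise FeatureError(
            f"{profile.seq_id!r} is unalignable at every diagnostic column; "
            "inspect the alignment before classifying"
        )
    c1 = profile.peroxidatic_residue == "C"
    c2 = profile.resolving_cys
    c3 = not profile.has_dimer_loop and not profile.has_oligo_loop
    if c1 and c2 and c3:
        cls = GpxClass.TRX_GPXLIKE_PRX
        note = "peroxidatic Cys + resolving Cys, no interface loops"
    elif profile.peroxidatic_residue == "U" or (c1 and not c2 and not c3):
        cls = GpxClass.CANONICAL_GSH_GPX
        note = (
            "selenocysteine at peroxidatic site"
            if profile.peroxidatic_residue == "U"
            else "peroxidatic Cys without resolving Cys, interface loops present"
        )
    else:
        cls = GpxClass.AMBIGUOUS
        note = "criteria pattern matches neither class"
    return ClassificationResult(
        seq_id=profile.seq_id,
        gpx_class=cls,
        peroxidatic_cys_conserved=c1,
        resolving_cys_present=c2,
        interface_domains_absent=c3,
        evidence=note,
    )


@dataclass
class CohortSummary:
    """Class counts and diagnostic fractions over a classified cohort."""

    n: int
    class_counts: Dict[GpxClass, int]
    oligo_loop_fraction: float
    dimer_loop_fraction: float
    resolving_cys_fraction: float

    @property
    def class_fractions(self) -> Dict[GpxClass, float]:
        return {k: v / self.n for k, v in self.class_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": k.value,
                "count": self.class_counts.get(k, 0),
                "fraction": round(self.class_counts.get(k, 0) / self.n, 4),
            }
            for k in GpxClass
        ]
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        lines = [f"cohort of {self.n} sequences"]
        for k in GpxClass:
            c = self.class_counts.get(k, 0)
            lines.append(f"  {k.value:<20s} {c:4d}  ({c / self.n:.1%})")
        lines.append(f"  oligomerization loop  {self.oligo_loop_fraction:.1%}")
        lines.append(f"  dimer loop            {self.dimer_loop_fraction:.1%}")
        lines.append(f"  resolving Cys         {self.resolving_cys_fraction:.1%}")
        return "\n".join(lines)


def summarize_cohort(
    results: Sequence[ClassificationResult],
    profiles: Sequence[FeatureProfile],
) -> CohortSummary:
    if not results:
        raise FeatureError("cannot summarize an empty cohort")
    counts: Dict[GpxClass, int] = {}
    for r in results:
        counts[r.gpx_class] = counts.get(r.gpx_class, 0) + 1
    n = len(results)
    alive = [p for p in profiles if not p.unalignable]
    denom = len(alive) if alive else 1
    return CohortSummary(
        n=n,
        class_counts=counts,
        oligo_loop_fraction=sum(p.has_oligo_loop for p in alive) / denom,
        dimer_loop_fraction=sum(p.has_dimer_loop for p in alive) / denom,
        resolving_cys_fraction=sum(p.resolving_cys for p in alive) / denom,
    )


def results_to_frame(
    results: Sequence[ClassificationResult],
    profiles: Sequence[FeatureProfile],
) -> pd.DataFrame:
    """Per-sequence TSV layout: id, class, criteria, diagnostic letters."""
    prof = {p.seq_id: p for p in profiles}
    rows = []
    for r in results:
        p = prof[r.seq_id]
        rows.append(
            {
                "id": r.seq_id,
                "class": r.gpx_class.value,
                "peroxidatic_cys": r.peroxidatic_cys_conserved,
                "resolving_cys": r.resolving_cys_present,
                "interface_absent": r.interface_domains_absent,
                "peroxidatic_residue": p.peroxidatic_residue,
                "tetrad": "".join(p.tetrad_residues),
                "trx_residues": "".join(p.trx_residues),
                "gsh_residues": "".join(p.gsh_residues),
                "dimer_loop": p.has_dimer_loop,
                "oligo_loop": p.has_oligo_loop,
            }
        )
    return pd.DataFrame(rows)
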