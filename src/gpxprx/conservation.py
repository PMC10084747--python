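"""Per-column consensus-proportion conservation profiling and
conserved-domain segmentation.

The profile reports, for every alignment column, the consensus residue,
the consensus residue *group* (a cell of a fixed physicochemical
partition, greedily extended from the modal letter) and the fraction of
non-gap rows whose letter falls in that group.  Maximal runs of columns
above a proportion threshold form conserved domains; coverage is the
fraction of the reference length they span.  This is plain consensus
counting, not evolutionary-rate scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment import Alignment
from .features import ColumnMap
from .records import GAP

#: Physicochemical grouping used to report residue types such as "Leu/Val"
#: or "Ser/Thr": aliphatic/aromatic-hydrophobic, aromatic, hydroxyl,
#: acidic, basic, amide, small, and cysteine/proline as singletons.
DEFAULT_GROUPING: Tuple[FrozenSet[str], ...] = tuple(
    frozenset(s) for s in ("ILVMF", "WY", "ST", "DE", "KRH", "NQ", "AG", "C", "P")
)


def _group_of(letter: str, grouping: Sequence[FrozenSet[str]]) -> FrozenSet[str]:
    for cell in grouping:
        if letter in cell:
            return cell
    return frozenset(letter)  # U, X and anything else: singleton


def column_consensus(
    aln: Alignment,
    column: int,
    grouping: Sequence[FrozenSet[str]] = DEFAULT_GROUPING,
    grouped: bool = True,
    min_letter_fraction: float = 0.05,
) -> Tuple[FrozenSet[str], float]:
    """Consensus group and proportion for one 1-based column.

    Single-residue mode (``grouped=False``) reports the modal letter's
    frequency among non-gap rows.  Grouped mode starts from the modal
    letter and greedily adds other letters from the same partition cell, in
    descending frequency (ties alphabetical), while each added letter
    contributes at least ``min_letter_fraction``.  An all-gap column
    reports ``(frozenset(), 0.0)`` by convention.
    """
    letters = [c for c in aln.column(column) if c != GAP]
    if not letters:
        return frozenset(), 0.0
    counts: Dict[str, int] = {}
    for c in letters:
        counts[c] = counts.get(c, 0) + 1
    n = len(letters)
    modal = min(counts, key=lambda c: (-counts[c], c))
    if not grouped:
        return frozenset(modal), counts[modal] / n
    cell = _group_of(modal, grouping)
    group = {modal}
    candidates = sorted(
        (c for c in counts if c in cell and c != modal),
        key=lambda c: (-counts[c], c),
    )
    for c in candidates:
        if counts[c] / n >= min_letter_fraction:
            group.add(c)
    prop = sum(counts[c] for c in group) / n
    return frozenset(group), prop


@dataclass
class ConservationProfile:
    """Per-column consensus groups, proportions and gap fractions."""

    consensus: List[str]               # modal letter per column ('' if all-gap)
    groups: List[FrozenSet[str]]
    proportions: np.ndarray
    gap_fractions: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.consensus)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(1, self.n_columns + 1),
                "consensus": self.consensus,
                "group": ["/".join(sorted(g)) for g in self.groups],
                "proportion": np.round(self.proportions, 4),
                "gap_fraction": np.round(self.gap_fractions, 4),
            }
        )


def conservation_profile(
    aln: Alignment,
    grouping: Sequence[FrozenSet[str]] = DEFAULT_GROUPING,
    grouped: bool = True,
    min_letter_fraction: float = 0.05,
) -> ConservationProfile:
    """Apply :func:`column_consensus` to every column of the alignment."""
    n_rows = aln.n_rows
    consensus: List[str] = []
    groups: List[FrozenSet[str]] = []
    props = np.zeros(aln.n_columns)
    gaps = np.zeros(aln.n_columns)
    for col in range(1, aln.n_columns + 1):
        letters = aln.column(col)
        gaps[col - 1] = letters.count(GAP) / n_rows
        grp, prop = column_consensus(aln, col, grouping, grouped, min_letter_fraction)
        groups.append(grp)
        props[col - 1] = prop
        nongap = [c for c in letters if c != GAP]
        if nongap:
            counts: Dict[str, int] = {}
            for c in nongap:
                counts[c] = counts.get(c, 0) + 1
            consensus.append(min(counts, key=lambda c: (-counts[c], c)))
        else:
            consensus.append("")
    return ConservationProfile(consensus, groups, props, gaps)


@dataclass
class DomainSegment:
    """A conserved run of alignment columns."""

    start_col: int
    end_col: int
    start_ref: Optional[int]
    end_ref: Optional[int]
    mean_proportion: float
    n_residues: int

    @property
    def n_columns(self) -> int:
        return self.end_col - self.start_col + 1


def conserved_domains(
    profile: ConservationProfile,
    threshold: float = 0.7,
    min_run: int = 5,
    max_break: int = 2,
    max_gap_fraction: float = 0.5,
    colmap: Optional[ColumnMap] = None,
) -> Tuple[List[DomainSegment], float]:
    """Segment the profile into conserved domains and report coverage.

    A column is *conserved* when its proportion >= ``threshold`` and its
    gap fraction <= ``max_gap_fraction``.  Adjacent conserved runs are
    merged across at most ``max_break`` consecutive below-threshold
    columns; columns failing the gap criterion break runs unconditionally.
    Segments start and end on conserved columns; those spanning fewer than
    ``min_run`` columns are discarded.  Coverage is total segment residues
    over the reference length (with a column map) or over the number of
    columns (without).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if min_run < 1 or max_break < 0:
        raise ValueError("min_run must be >= 1 and max_break >= 0")
    n = profile.n_columns
    conserved = (profile.proportions >= threshold) & (
        profile.gap_fractions <= max_gap_fraction
    )
    hard = profile.gap_fractions > max_gap_fraction

    runs: List[Tuple[int, int]] = []  # 0-based inclusive
    i = 0
    while i < n:
        if not conserved[i]:
            i += 1
            continue
        start = i
        end = i
        j = i + 1
        soft = 0
        while j < n:
            if conserved[j]:
                end = j
                soft = 0
            elif hard[j]:
                break
            else:
                soft += 1
                if soft > max_break:
                    break
            j += 1
        runs.append((start, end))
        i = end + 1

    col_to_ref: Dict[int, int] = {}
    if colmap is not None:
        col_to_ref = {c: r for r, c in colmap.ref_to_col.items()}

    segments: List[DomainSegment] = []
    total_residues = 0
    for start, end in runs:
        if end - start + 1 < min_run:
            continue
        cols = range(start + 1, end + 2)
        if colmap is not None:
            refs = [col_to_ref[c] for c in cols if c in col_to_ref]
            n_res = len(refs)
            start_ref = refs[0] if refs else None
            end_ref = refs[-1] if refs else None
        else:
            n_res = end - start + 1
            start_ref = end_ref = None
        total_residues += n_res
        segments.append(
            DomainSegment(
                start_col=start + 1,
                end_col=end + 1,
                start_ref=start_ref,
                end_ref=end_ref,
                mean_proportion=float(profile.proportions[start : end + 1].mean()),
                n_residues=n_res,
            )
        )
    denom = colmap.reference_length if colmap is not None else n
    coverage = total_residues / denom if denom else 0.0
    return segments, coverage


def residue_report(
    profile: ConservationProfile,
    colmap: ColumnMap,
    positions: Sequence[int],
    annotations: Optional[Dict[int, str]] = None,
) -> pd.DataFrame:
    """Consensus group and proportion at chosen reference positions.

    The layout mirrors a printed conservation table: consensus residue,
    percent conservation of its residue-type group, and a free-text
    annotation.  Positions beyond the reference are flagged unmapped.
    """
    annotations = annotations or {}
    rows = []
    for pos in positions:
        if pos not in colmap.ref_to_col:
            rows.append(
                {
                    "ref_position": pos,
                    "consensus": "",
                    "group": "",
                    "proportion": np.nan,
                    "annotation": annotations.get(pos, ""),
                    "mapped": False,
                }
            )
            continue
        col = colmap.ref_to_col[pos]
        rows.append(
            {
                "ref_position": pos,
                "consensus": profile.consensus[col - 1],
                "group": "/".join(sorted(profile.groups[col - 1])),
                "proportion": round(float(profile.proportions[col - 1]), 4),
                "annotation": annotations.get(pos, ""),
                "mapped": True,
            }
        )
    return pd.DataFrame(rows)
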