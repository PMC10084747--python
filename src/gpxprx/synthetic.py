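"""Synthetic Gpx-like protein families with planted ground truth.

The generator builds a neutral scaffold sequence, plants the diagnostic
features of one of the three sequence classes on it (peroxidatic Cys vs
selenocysteine, resolving Cys in the Cys block, TRX- vs GSH-binding residue
sets, presence/absence of the "PGGG" dimer loop and of a C-terminal
oligomerization-loop insertion), and then diverges copies by uniform
per-site substitution at unprotected sites.  Every record carries its
planted class, so downstream alignment, feature extraction, classification,
conservation and phylogeny stages can be tested without external data.

The mutation process is substitution-only (no indels beyond the planted
loop deletions/insertion) and the background is uniform over the 20
canonical amino acids — a deliberately conservative null for consensus
statistics, not a realistic evolutionary model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .features import DEFAULT_SITES, ReferenceSites
from .records import AA20, GpxClass, ProteinRecord

#: Default phylum labels scattered round-robin across synthetic cohorts.
DEFAULT_PHYLA = (
    "Proteobacteria",
    "Firmicutes",
    "Actinobacteria",
    "Bacteroidetes",
)

#: Length of the planted oligomerization-loop insertion (canonical class).
OLIGO_INSERT_LENGTH = 10


class ScaffoldError(ValueError):
    pass


@dataclass(frozen=True)
class ScaffoldSpec:
    """Coordinates of the planted diagnostic features, in scaffold numbering.

    Defaults mirror :data:`gpxprx.features.DEFAULT_SITES` so that one
    coordinate convention is shared by the generator and the classifier.
    """

    length: int = 190
    tetrad_positions: Tuple[int, int, int, int] = DEFAULT_SITES.tetrad
    resolving_cys_position: int = DEFAULT_SITES.resolving
    cys_block: Tuple[int, int] = DEFAULT_SITES.cys_block
    trx_binding_positions: Tuple[int, int, int] = DEFAULT_SITES.trx_binding
    gsh_binding_positions: Tuple[int, int, int] = DEFAULT_SITES.gsh_binding
    dimer_loop_region: Tuple[int, int] = DEFAULT_SITES.dimer_loop
    oligo_loop_region: Tuple[int, int] = DEFAULT_SITES.oligo_loop
    seed: int = 0

    def validate(self) -> None:
        def _check_pos(name: str, pos: int) -> None:
            if not 1 <= pos <= self.length:
                raise ScaffoldError(f"{name}={pos} outside [1, {self.length}]")

        for i, p in enumerate(self.tetrad_positions):
            _check_pos(f"tetrad_positions[{i}]", p)
        if len(set(self.tetrad_positions)) != 4:
            raise ScaffoldError("tetrad_positions must be four distinct positions")
        _check_pos("resolving_cys_position", self.resolving_cys_position)
        for i, p in enumerate(self.trx_binding_positions):
            _check_pos(f"trx_binding_positions[{i}]", p)
        for i, p in enumerate(self.gsh_binding_positions):
            _check_pos(f"gsh_binding_positions[{i}]", p)
        for name in ("cys_block", "dimer_loop_region", "oligo_loop_region"):
            lo, hi = getattr(self, name)
            _check_pos(f"{name}[0]", lo)
            _check_pos(f"{name}[1]", hi)
            if lo > hi:
                raise ScaffoldError(f"{name} interval reversed: ({lo}, {hi})")
        for name in ("dimer_loop_region", "oligo_loop_region"):
            lo, hi = getattr(self, name)
            hit = [p for p in self.tetrad_positions if lo <= p <= hi]
            if hit:
                raise ScaffoldError(
                    f"{name} ({lo}-{hi}) overlaps tetrad positions {hit}"
                )

    def diagnostic_positions(self) -> Set[int]:
        """Scaffold positions whose letters define a class.

        Includes the whole Cys-block window: a chance Cys anywhere in the
        window would read as a resolving Cys downstream.
        """
        out: Set[int] = set(self.tetrad_positions)
        out.add(self.resolving_cys_position)
        out.update(range(self.cys_block[0], self.cys_block[1] + 1))
        out.update(self.trx_binding_positions)
        out.update(self.gsh_binding_positions)
        return out

    def sites(self) -> ReferenceSites:
        """The classifier-side view of these coordinates."""
        t = self.tetrad_positions
        return replace(
            DEFAULT_SITES,
            peroxidatic=t[0],
            gln=t[1],
            trp=t[2],
            asn=t[3],
            resolving=self.resolving_cys_position,
            cys_block=self.cys_block,
            trx_binding=self.trx_binding_positions,
            gsh_binding=self.gsh_binding_positions,
            dimer_loop=self.dimer_loop_region,
            oligo_loop=self.oligo_loop_region,
        )


@dataclass
class LabeledFamily:
    """Synthetic records plus the pristine scaffold used as alignment reference."""

    records: List[ProteinRecord]
    divergence: float
    scaffold: ScaffoldSpec
    reference: Optional[ProteinRecord] = None

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.truth_class is None:
                raise ScaffoldError(f"record {rec.id!r} has no truth class")

    def __len__(self) -> int:
        return len(self.records)

    def truth(self) -> Dict[str, GpxClass]:
        return {r.id: r.truth_class for r in self.records}


def make_scaffold(spec: ScaffoldSpec) -> ProteinRecord:
    """Random scaffold of ``spec.length`` with neutral Ala at all diagnostic
    positions (to be overwritten by :func:`plant_class`).  Deterministic
    given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    letters = [AA20[i] for i in rng.integers(0, len(AA20), size=spec.length)]
    for pos in spec.diagnostic_positions():
        letters[pos - 1] = "A"
    return ProteinRecord(id="scaffold", sequence="".join(letters))


def _planted_letters(spec: ScaffoldSpec, class_label: GpxClass) -> Dict[int, str]:
    """Substitutions (scaffold position -> letter) planted for a class."""
    t = spec.tetrad_positions
    out = {t[1]: "Q", t[2]: "W", t[3]: "N"}
    if class_label is GpxClass.TRX_GPXLIKE_PRX:
        out[t[0]] = "C"
        out[spec.resolving_cys_position] = "C"
        for pos, letter in zip(spec.trx_binding_positions, "PFY"):
            out[pos] = letter
    elif class_label is GpxClass.CANONICAL_GSH_GPX:
        out[t[0]] = "U"
        out[spec.resolving_cys_position] = "S"
        for pos, letter in zip(spec.gsh_binding_positions, "RRM"):
            out[pos] = letter
        for i, letter in enumerate("PGGG"):
            out[_pggg_start(spec) + i] = letter
    elif class_label is GpxClass.AMBIGUOUS:
        out[t[0]] = "C"
        out[spec.resolving_cys_position] = "S"
    else:
        raise ScaffoldError(f"unknown class label {class_label!r}")
    return out


def _pggg_start(spec: ScaffoldSpec) -> int:
    """Scaffold position where the PGGG motif is planted (mid dimer loop)."""
    lo, hi = spec.dimer_loop_region
    return lo + (hi - lo - 3) // 2


def _oligo_insert_after(spec: ScaffoldSpec) -> int:
    """Scaffold position after which the oligomerization insertion is planted."""
    lo, hi = spec.oligo_loop_region
    return (lo + hi) // 2


def _deleted_positions(spec: ScaffoldSpec, class_label: GpxClass) -> Set[int]:
    if class_label is GpxClass.CANONICAL_GSH_GPX:
        return set()
    out: Set[int] = set()
    for lo, hi in (spec.dimer_loop_region, spec.oligo_loop_region):
        out.update(range(lo, hi + 1))
    return out


def planted_position_map(spec: ScaffoldSpec, class_label: GpxClass) -> Dict[int, int]:
    """Scaffold position -> position in the planted sequence (surviving sites)."""
    deleted = _deleted_positions(spec, class_label)
    ins_after = _oligo_insert_after(spec) if class_label is GpxClass.CANONICAL_GSH_GPX else None
    out: Dict[int, int] = {}
    new = 0
    for pos in range(1, spec.length + 1):
        if pos in deleted:
            continue
        new += 1
        out[pos] = new
        if ins_after is not None and pos == ins_after:
            new += OLIGO_INSERT_LENGTH
    return out


def plant_class(
    scaffold: ProteinRecord,
    spec: ScaffoldSpec,
    class_label: GpxClass,
    seed: Optional[int] = None,
) -> ProteinRecord:
    """Overwrite the scaffold's diagnostic sites with one class's features.

    TRX-like: peroxidatic Cys, resolving Cys, TRX-binding P/F/Y, both loop
    regions deleted.  Canonical: selenocysteine, no resolving Cys,
    GSH-binding R/R/M, PGGG in the dimer loop, a 10-residue insertion in the
    oligomerization loop.  Ambiguous: peroxidatic Cys, no resolving Cys, no
    loops (1-Cys-like).
    """
    if not isinstance(class_label, GpxClass):
        raise ScaffoldError(f"unknown class label {class_label!r}")
    spec.validate()
    letters = list(scaffold.sequence)
    if len(letters) != spec.length:
        raise ScaffoldError(
            f"scaffold length {len(letters)} != spec.length {spec.length}"
        )
    for pos, letter in _planted_letters(spec, class_label).items():
        letters[pos - 1] = letter
    deleted = _deleted_positions(spec, class_label)
    if deleted:
        letters = [c for i, c in enumerate(letters, start=1) if i not in deleted]
    if class_label is GpxClass.CANONICAL_GSH_GPX:
        rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
        insert = "".join(AA20[i] for i in rng.integers(0, len(AA20), size=OLIGO_INSERT_LENGTH))
        # insertion position in the (un-deleted) planted sequence
        at = _oligo_insert_after(spec)
        letters = letters[:at] + list(insert) + letters[at:]
    return ProteinRecord(
        id=f"{class_label.value.lower()}_parent",
        sequence="".join(letters),
        truth_class=class_label,
    )


def protected_positions(spec: ScaffoldSpec, class_label: GpxClass) -> Set[int]:
    """Positions (in planted-sequence coordinates) that mutation must spare.

    Covers all diagnostic scaffold positions that survive planting, plus the
    planted PGGG motif for the canonical class.
    """
    pmap = planted_position_map(spec, class_label)
    keep = set(spec.diagnostic_positions())
    if class_label is GpxClass.CANONICAL_GSH_GPX:
        keep.update(range(_pggg_start(spec), _pggg_start(spec) + 4))
    return {pmap[p] for p in keep if p in pmap}


def mutate_family(
    record: ProteinRecord,
    n: int,
    rate: float,
    protected: Iterable[int] = (),
    seed: int = 0,
    spec: Optional[ScaffoldSpec] = None,
    id_prefix: Optional[str] = None,
) -> LabeledFamily:
    """``n`` mutated copies of ``record`` at per-site substitution ``rate``.

    Each unprotected site substitutes independently with probability
    ``rate`` to a uniformly chosen *different* canonical residue.  Truth
    labels are copied from the parent.  Deterministic given ``seed``.
    """
    if not 0.0 <= rate < 1.0:
        raise ScaffoldError(f"rate must be in [0, 1), got {rate}")
    L = len(record.sequence)
    protected = set(protected)
    bad = [p for p in protected if not 1 <= p <= L]
    if bad:
        raise ScaffoldError(f"protected positions outside [1, {L}]: {sorted(bad)[:5]}")
    rng = np.random.default_rng(seed)
    prefix = id_prefix or record.id
    mutable = np.array([p - 1 for p in range(1, L + 1) if p not in protected], dtype=int)
    records: List[ProteinRecord] = []
    for k in range(n):
        letters = list(record.sequence)
        hits = mutable[rng.random(mutable.size) < rate]
        for i in hits:
            current = letters[i]
            choices = [c for c in AA20 if c != current]
            letters[i] = choices[int(rng.integers(0, len(choices)))]
        records.append(
            ProteinRecord(
                id=f"{prefix}_{k:03d}",
                sequence="".join(letters),
                truth_class=record.truth_class,
            )
        )
    return LabeledFamily(
        records=records,
        divergence=rate,
        scaffold=spec if spec is not None else ScaffoldSpec(length=L),
    )


_CLASS_PREFIX = {
    GpxClass.TRX_GPXLIKE_PRX: "trx",
    GpxClass.CANONICAL_GSH_GPX: "gpx",
    GpxClass.AMBIGUOUS: "amb",
}


def synthesize_cohort(
    spec: ScaffoldSpec,
    n_trx: int,
    n_canonical: int,
    n_ambiguous: int = 0,
    divergence: float = 0.0,
    seed: int = 0,
    phyla: Sequence[str] = DEFAULT_PHYLA,
) -> LabeledFamily:
    """A mixed cohort with planted classes, protected diagnostics and
    round-robin phylum labels; the pristine scaffold rides along as the
    alignment reference (``family.reference``)."""
    spec.validate()
    scaffold = make_scaffold(spec)
    counts = {
        GpxClass.TRX_GPXLIKE_PRX: n_trx,
        GpxClass.CANONICAL_GSH_GPX: n_canonical,
        GpxClass.AMBIGUOUS: n_ambiguous,
    }
    records: List[ProteinRecord] = []
    for offset, (label, n) in enumerate(counts.items()):
        if n <= 0:
            continue
        parent = plant_class(scaffold, spec, label)
        fam = mutate_family(
            parent,
            n,
            divergence,
            protected=protected_positions(spec, label),
            seed=seed * 7919 + offset,
            spec=spec,
            id_prefix=_CLASS_PREFIX[label],
        )
        records.extend(fam.records)
    for i, rec in enumerate(records):
        rec.phylum = phyla[i % len(phyla)]
    return LabeledFamily(
        records=records,
        divergence=divergence,
        scaffold=spec,
        reference=scaffold.with_sequence(scaffold.sequence),
    )


def emit_truth_table(family: LabeledFamily, path: str | Path) -> None:
    """TSV of record id, truth class and phylum label; losslessly readable
    back with :func:`read_truth_table`."""
    if not family.records:
        raise ScaffoldError("cannot emit a truth table for an empty family")
    df = pd.DataFrame(
        {
            "id": [r.id for r in family.records],
            "truth_class": [r.truth_class.value for r in family.records],
            "phylum": [r.phylum or "" for r in family.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    expected = ["id", "truth_class", "phylum"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df
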