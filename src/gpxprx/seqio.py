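"""FASTA I/O, length filtering and cd-hit-style greedy identity clustering.

The clustering reproduces the classic non-redundant-set construction:
records are sorted longest-first, each record joins the first existing
representative it matches above the identity threshold, otherwise it founds
a new cluster.  Identity is fractional identity on the optimal global
alignment (see :mod:`gpxprx.alignment`); a "similarity" mode counting
positively scoring substitution pairs is also available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alignment import global_align, percent_similarity
from .records import GAP, GpxClass, ProteinRecord

log = logging.getLogger(__name__)


class FastaError(ValueError):
    pass


def _line_of_header(path: Path, rec_id: str) -> Optional[int]:
    """1-based line number of the FASTA header for ``rec_id``, if findable."""
    try:
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if line.startswith(">") and line[1:].split()[0] == rec_id:
                return lineno
    except OSError:
        pass
    return None


def read_fasta(path: str | Path) -> List[ProteinRecord]:
    """Read protein FASTA, order-preserving.

    Headers are parsed as ``id [key=value ...]``; recognized tags are
    ``taxon=``, ``phylum=`` and ``class=`` (a :class:`GpxClass` name).
    ``U`` (selenocysteine) and ``X`` are accepted.  Empty sequences and
    duplicate ids are parse errors reported with the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"no such file: {path}")
    records: List[ProteinRecord] = []
    seen: set = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        lineno = _line_of_header(path, rid)
        where = f"{path}:{lineno}" if lineno else str(path)
        if rid in seen:
            raise FastaError(f"{where}: duplicate record id {rid!r}")
        seen.add(rid)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaError(f"{where}: record {rid!r} has an empty sequence")
        tags: Dict[str, str] = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                k, _, v = token.partition("=")
                tags[k] = v
        truth = None
        if "class" in tags:
            try:
                truth = GpxClass(tags["class"])
            except ValueError as exc:
                raise FastaError(
                    f"{where}: unknown class tag {tags['class']!r}"
                ) from exc
        try:
            records.append(
                ProteinRecord(
                    id=rid,
                    sequence=seq,
                    taxon_label=tags.get("taxon"),
                    phylum=tags.get("phylum"),
                    truth_class=truth,
                )
            )
        except ValueError as exc:
            raise FastaError(f"{where}: {exc}") from exc
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records with metadata tags in the header."""
    with open(path, "w") as fh:
        for rec in records:
            tags = []
            if rec.taxon_label:
                tags.append(f"taxon={rec.taxon_label}")
            if rec.phylum:
                tags.append(f"phylum={rec.phylum}")
            if rec.truth_class:
                tags.append(f"class={rec.truth_class.value}")
            header = " ".join([rec.id] + tags)
            fh.write(f">{header}\n{rec.sequence}\n")


def filter_by_length(
    records: Sequence[ProteinRecord],
    min_len: Optional[int] = None,
    max_len: Optional[int] = None,
) -> List[ProteinRecord]:
    """Keep records with ``min_len <= length <= max_len``.

    When bounds are omitted they default to 0.5x / 2x the median input
    length (rounded), a conservative "too short or too long" rule.
    """
    records = list(records)
    if not records:
        return []
    if min_len is None or max_len is None:
        median = float(np.median([len(r) for r in records]))
        if min_len is None:
            min_len = int(round(0.5 * median))
        if max_len is None:
            max_len = int(round(2.0 * median))
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [r for r in records if min_len <= len(r) <= max_len]
    removed = len(records) - len(kept)
    if removed:
        log.info("length filter [%d, %d]: removed %d of %d records",
                 min_len, max_len, removed, len(records))
    if not kept:
        log.warning("length filter removed every record")
    return kept


def pairwise_identity(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: str = "blosum62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    mode: str = "identity",
) -> float:
    """Fractional identity (or positive-scoring similarity) of the optimal
    global alignment of ``a`` and ``b``.  Symmetric; in [0, 1]."""
    pw = global_align(a, b, matrix, gap_open, gap_extend)
    if mode == "identity":
        return pw.identity()
    if mode == "similarity":
        # positive-scoring fraction over *all* columns, to keep the scale
        # comparable with identity (gapped columns count against).
        sim_cols = percent_similarity(pw, "similarity") / 100.0
        ungapped = sum(
            x != GAP and y != GAP for x, y in zip(pw.aligned_a, pw.aligned_b)
        )
        return sim_cols * ungapped / pw.n_columns if pw.n_columns else 0.0
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ClusterSet:
    """Greedy clustering result: (representative id, member ids) per cluster."""

    clusters: List[Tuple[str, List[str]]]
    threshold: float

    @property
    def representatives(self) -> List[str]:
        return [rep for rep, _ in self.clusters]

    def membership(self) -> Dict[str, str]:
        """id -> representative id."""
        out: Dict[str, str] = {}
        for rep, members in self.clusters:
            for m in members:
                out[m] = rep
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"representative": rep, "member": m}
            for rep, members in self.clusters
            for m in members
        ]
        return pd.DataFrame(rows, columns=["representative", "member"])


def greedy_cluster(
    records: Sequence[ProteinRecord],
    threshold: float,
    mode: str = "identity",
    matrix: str = "blosum62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> ClusterSet:
    """cd-hit-style greedy clustering at a fractional identity threshold.

    Records are visited longest-first (ties broken lexicographically by id);
    each joins the first representative with identity strictly above
    ``threshold``, else founds a new cluster.  Representatives are returned
    in founding order.  Deterministic for a fixed input; *not* invariant
    under permutation of equal-length inputs (documented greedy behavior).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    order = sorted(records, key=lambda r: (-len(r), r.id))
    reps: List[ProteinRecord] = []
    members: List[List[str]] = []
    for rec in order:
        for k, rep in enumerate(reps):
            ident = pairwise_identity(rec, rep, matrix, gap_open, gap_extend, mode)
            if ident > threshold:
                members[k].append(rec.id)
                break
        else:
            reps.append(rec)
            members.append([rec.id])
    return ClusterSet(
        clusters=[(rep.id, mem) for rep, mem in zip(reps, members)],
        threshold=threshold,
    )


def write_cluster_table(
    clusters: ClusterSet,
    records: Sequence[ProteinRecord],
    path: str | Path,
    **identity_kwargs,
) -> None:
    """TSV of representative, member, identity-to-representative."""
    by_id = {r.id: r for r in records}
    rows = []
    for rep, mems in clusters.clusters:
        for m in mems:
            ident = (
                1.0
                if m == rep
                else pairwise_identity(by_id[m], by_id[rep], **identity_kwargs)
            )
            rows.append({"representative": rep, "member": m, "identity": round(ident, 4)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
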