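"""Lift alignments from personalized-haplotype to reference coordinates.

A chain decomposes the haplotype into match blocks (shared with the
reference), haplotype-only runs (insertions relative to the reference)
and reference-only runs (bases deleted from the haplotype). Lifting an
alignment rewrites its CIGAR so read bases over haplotype-only runs
become I ops, spanned reference-only runs become D ops, and match
stretches are preserved; the query-consuming length never changes. Reads
lying entirely inside a haplotype insertion have no reference-coordinate
home and are reported unliftable (and emitted as unmapped downstream, so
read counts stay auditable).

Reconciliation picks, per read, the best of several lifted candidates by
mapping quality, then alignment score, then a fixed source order
(hap1 < hap2 < rescue) — deterministic and independent of input order.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .alignments import (AlignmentRecord, Cigar, cigar_str, merge_cigar,
                         query_length, reference_span)
from .personalize import Chain

__all__ = [
    "InsideInsertion",
    "LiftResult",
    "lift_position",
    "lift_alignment",
    "reconcile_alignments",
    "UNMAPPED_FLAG",
]

UNMAPPED_FLAG = 0x4

_LABEL_RANK = {"hap1": 0, "hap2": 1, "rescue": 2}


@dataclass(frozen=True)
class InsideInsertion:
    """Marker for a haplotype position with no reference image; ``flank``
    is the reference coordinate immediately left of the insertion run."""

    flank: int


@dataclass(frozen=True)
class LiftResult:
    """A lifted record, or an unliftable marker with its reason."""

    record: AlignmentRecord | None
    reason: str | None = None  # "fully-inside-insertion" | "off-chain"

    @property
    def lifted(self) -> bool:
        return self.record is not None


# chain decomposition: ("M", s_start, s_end, t_start) match runs,
# ("I", s_start, s_end, t_start) haplotype-only runs,
# ("D", s_point, length, t_start) reference-only runs at a source point.
@functools.lru_cache(maxsize=32)
def _chain_items(chain: Chain):
    items: list[tuple] = []
    s = t = 0
    for b in chain.blocks:
        if b.size:
            items.append(("M", s, s + b.size, t))
            s += b.size
            t += b.size
        if b.d_source:
            items.append(("I", s, s + b.d_source, t))
            s += b.d_source
        if b.d_target:
            items.append(("D", s, b.d_target, t))
            t += b.d_target
    return tuple(items)


def lift_position(chain: Chain, pos: int) -> int | InsideInsertion:
    """Map one haplotype offset to a reference offset.

    Inside match blocks the map is block-offset arithmetic; inside a
    haplotype-only run the position has no image and the flanking
    reference coordinate is returned as an :class:`InsideInsertion`.
    """
    if not 0 <= pos < chain.source_length:
        raise IndexError(
            f"position {pos} outside haplotype [0, {chain.source_length})"
        )
    for item in _chain_items(chain):
        kind, s0, x, t0 = item
        if kind == "M" and s0 <= pos < x:
            return t0 + (pos - s0)
        if kind == "I" and s0 <= pos < x:
            return InsideInsertion(flank=t0)
    raise AssertionError("chain does not cover its own source span")


def _consume(items, idx: int, hpos: int, n: int, emit, *, started: list):
    """Advance ``n`` haplotype bases from ``hpos`` through the chain,
    calling ``emit(kind, length, tpos)`` per piece. Returns (idx, hpos)."""
    while n > 0:
        kind, s0, x, t0 = items[idx]
        if kind == "D":
            # reference-only run at source point s0: interior crossings only
            if started[0]:
                emit("D", x, t0)
            idx += 1
            continue
        if hpos >= (x if kind != "D" else s0):
            idx += 1
            continue
        if hpos < s0:
            raise IndexError("alignment runs off the chain")
        take = min(n, x - hpos)
        if kind == "M":
            emit("M", take, t0 + (hpos - s0))
            started[0] = True
        else:
            emit("I", take, t0)
        hpos += take
        n -= take
        if hpos == x:
            idx += 1
    return idx, hpos


def lift_alignment(chain: Chain, rec: AlignmentRecord) -> LiftResult:
    """Lift one alignment through a chain, rewriting its CIGAR.

    MAPQ and alignment score are carried through unchanged. Read bases
    over haplotype insertions become I ops (soft-clip-free, preserving
    allele evidence); spanned reference deletions gain D ops; reads fully
    inside an insertion are unliftable.
    """
    rec.validate_query_length()
    if rec.is_unmapped:
        return LiftResult(None, "off-chain")
    if rec.target_name != chain.source_name:
        raise ValueError(
            f"alignment targets {rec.target_name!r} but chain source is "
            f"{chain.source_name!r}"
        )
    hap_span = reference_span(rec.cigar)
    if rec.pos < 0 or rec.pos + hap_span > chain.source_length:
        return LiftResult(None, "off-chain")

    items = _chain_items(chain)
    # first spanning item at or after rec.pos
    idx = 0
    while idx < len(items):
        kind, s0, x, _ = items[idx]
        end = x if kind != "D" else s0
        if end > rec.pos:
            break
        idx += 1

    pieces: list[tuple[str, int, int]] = []  # (op, length, tpos)
    started = [False]

    def emit(op: str, length: int, tpos: int) -> None:
        pieces.append((op, length, tpos))

    hpos = rec.pos
    for op, n in rec.cigar:
        if op == "S":
            pieces.append(("S", n, -1))
        elif op == "I":
            pieces.append(("I", n, -1))
        elif op == "M":
            idx, hpos = _consume(items, idx, hpos, n, emit, started=started)
        elif op == "D":
            # haplotype bases skipped by the read: matches lift to D,
            # insertion bases vanish (they do not exist on the reference)
            def emit_del(kind: str, length: int, tpos: int) -> None:
                if kind in ("M", "D"):
                    pieces.append(("D", length, tpos))

            idx, hpos = _consume(items, idx, hpos, n, emit_del, started=started)
        else:
            raise ValueError(f"unsupported CIGAR op {op!r} in {rec.read_id}")

    ref_start = next((t for p, _, t in pieces if p == "M"), None)
    if ref_start is None:
        return LiftResult(None, "fully-inside-insertion")
    cigar = merge_cigar([(p, n) for p, n, _ in pieces])
    while cigar and cigar[0][0] == "D":
        cigar.pop(0)
    while cigar and cigar[-1][0] == "D":
        cigar.pop()
    new = replace(rec, target_name=chain.target_name, pos=ref_start, cigar=cigar)
    if query_length(new.cigar) != query_length(rec.cigar):
        raise AssertionError(
            f"liftover broke query-length conservation for {rec.read_id}: "
            f"{cigar_str(rec.cigar)} -> {cigar_str(new.cigar)}"
        )
    return LiftResult(new)


def reconcile_alignments(
    candidates: Sequence[AlignmentRecord | LiftResult],
) -> AlignmentRecord:
    """Select the best reference-coordinate candidate for one read.

    Ordering: mapping quality (descending), then alignment score
    (descending), then source label (hap1 < hap2 < rescue), then
    coordinates — a total order, so the result is independent of
    candidate permutation. With zero liftable candidates an unmapped
    record is emitted rather than dropping the read.
    """
    records = []
    read_id = None
    for c in candidates:
        rec = c.record if isinstance(c, LiftResult) else c
        if rec is not None:
            read_id = read_id or rec.read_id
        if rec is None or rec.is_unmapped:
            continue
        records.append(rec)
    if not records:
        if read_id is None:
            raise ValueError("reconcile needs at least one candidate")
        return AlignmentRecord(
            read_id=read_id, target_name="*", pos=-1, cigar=[], mapq=0,
            align_score=0, flags=UNMAPPED_FLAG, source_label="none",
        )
    if len({r.read_id for r in records}) != 1:
        raise ValueError("reconcile received candidates for different reads")

    def key(r: AlignmentRecord):
        return (
            -r.mapq,
            -r.align_score,
            _LABEL_RANK.get(r.source_label, len(_LABEL_RANK)),
            r.source_label,
            r.target_name,
            r.pos,
            cigar_str(r.cigar),
        )

    return min(records, key=key)
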