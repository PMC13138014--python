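"""Read-alignment records and SAM text I/O.

An :class:`AlignmentRecord` is a read placement against *some* sequence —
a personalized haplotype, the reference, or a rescue assembly — identified
by ``source_label``. CIGARs are lists of ``(op, length)`` with op in
``{M, I, D, S}``; positions are 0-based internally and 1-based in emitted
SAM per the standard.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "AlignmentRecord",
    "Cigar",
    "parse_cigar",
    "cigar_str",
    "query_length",
    "reference_span",
    "read_sam",
    "write_sam",
]

Cigar = list[tuple[str, int]]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = {"M", "I", "S", "=", "X"}
_TARGET_OPS = {"M", "D", "N", "=", "X"}


def parse_cigar(text: str) -> Cigar:
    if text == "*":
        return []
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text)]
    if sum(n for _, n in ops) == 0 or "".join(f"{n}{op}" for op, n in ops) != text:
        raise ValueError(f"malformed CIGAR {text!r}")
    return ops


def cigar_str(cigar: Cigar) -> str:
    return "".join(f"{n}{op}" for op, n in cigar) if cigar else "*"


def query_length(cigar: Cigar) -> int:
    """Bases of the read consumed by the CIGAR (M/I/S/=/X)."""
    return sum(n for op, n in cigar if op in _QUERY_OPS)


def reference_span(cigar: Cigar) -> int:
    """Bases of the target consumed by the CIGAR (M/D/N/=/X)."""
    return sum(n for op, n in cigar if op in _TARGET_OPS)


def merge_cigar(cigar: Cigar) -> Cigar:
    """Coalesce adjacent ops of the same kind and drop zero-length ops."""
    out: Cigar = []
    for op, n in cigar:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


@dataclass(frozen=True)
class AlignmentRecord:
    """One read placement in haplotype or reference coordinates."""

    read_id: str
    target_name: str
    pos: int  # 0-based leftmost target position
    cigar: Cigar
    mapq: int = 60
    align_score: int = 0
    flags: int = 0
    source_label: str = "hap1"  # hap1 | hap2 | rescue | ref
    seq: str | None = None

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & 0x4)

    @property
    def end(self) -> int:
        """0-based exclusive end on the target."""
        return self.pos + reference_span(self.cigar)

    def validate_query_length(self) -> None:
        if self.seq is not None and not self.is_unmapped:
            qlen = query_length(self.cigar)
            if qlen != len(self.seq):
                raise ValueError(
                    f"CIGAR of {self.read_id} consumes {qlen} query bases "
                    f"but the read is {len(self.seq)} bases"
                )


# ---------------------------------------------------------------------------
# SAM I/O (pysam; plain-text SAM so every artifact stays human-readable)

_SOURCE_TAG = "XS"  # winning source label set by reconciliation
_LABEL_TAG = "XH"  # source label of the record itself


def write_sam(
    path: str | Path,
    records: Iterable[AlignmentRecord],
    contigs: Mapping[str, int],
    *,
    header_comments: Sequence[str] = (),
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in contigs.items()],
        "CO": list(header_comments),
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.flag = rec.flags
            if rec.is_unmapped:
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
                a.cigarstring = None
            else:
                a.reference_id = out.header.get_tid(rec.target_name)
                if a.reference_id < 0:
                    raise ValueError(
                        f"alignment targets {rec.target_name!r}, absent from header"
                    )
                a.reference_start = rec.pos
                a.mapping_quality = rec.mapq
                a.cigarstring = cigar_str(rec.cigar)
            if rec.seq is not None:
                a.query_sequence = rec.seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            a.set_tag("AS", rec.align_score)
            a.set_tag(_LABEL_TAG, rec.source_label)
            out.write(a)


def read_sam(path: str | Path, *, default_label: str = "hap1") -> list[AlignmentRecord]:
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_secondary or a.is_supplementary:
                continue
            label = a.get_tag(_LABEL_TAG) if a.has_tag(_LABEL_TAG) else default_label
            score = int(a.get_tag("AS")) if a.has_tag("AS") else 0
            out.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    target_name="*" if a.is_unmapped else a.reference_name,
                    pos=-1 if a.is_unmapped else a.reference_start,
                    cigar=[] if a.is_unmapped else parse_cigar(a.cigarstring),
                    mapq=a.mapping_quality,
                    align_score=score,
                    flags=a.flag,
                    source_label=str(label),
                    seq=a.query_sequence,
                )
            )
    return out
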