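"""Aligner adapters: external command templates and truth re-expression.

Re-implementing a read aligner is out of scope for this package, so the
alignment slot is filled one of two ways:

* an **external command template** (e.g. ``bwa index`` + ``bwa mem``) run
  through a shell, producing SAM that is parsed back in; or
* the **truth path**: simulator truth alignments (exact placements on
  the donor haplotypes) re-expressed against another sequence via chains
  — first lifted to reference coordinates through the truth chains, then
  optionally pushed into a personalized haplotype through the inverted
  personalization chain. No external tool is needed, which keeps the
  default pipeline self-contained and deterministic.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from pathlib import Path
from typing import Mapping, Sequence

from .alignments import AlignmentRecord, read_sam
from .liftover import LiftResult, lift_alignment
from .personalize import Chain, invert_chain

__all__ = [
    "BWA_TEMPLATE",
    "align_with_command",
    "rescore_against",
    "reexpress_alignments",
    "AlignerError",
]

logger = logging.getLogger(__name__)

#: Default external-aligner template (single thread for determinism).
BWA_TEMPLATE = (
    "bwa index {ref} > /dev/null 2>&1 && "
    "bwa mem -v 1 -t 1 {ref} {reads} > {out} 2> /dev/null"
)


class AlignerError(RuntimeError):
    pass


def align_with_command(
    template: str,
    ref_fasta: str | Path,
    reads_fastq: str | Path,
    out_sam: str | Path,
    *,
    label: str,
) -> list[AlignmentRecord]:
    """Run an aligner command template with ``{ref}``, ``{reads}`` and
    ``{out}`` placeholders; parse the SAM it writes, tagging each record
    with ``label``."""
    cmd = template.format(
        ref=shlex.quote(str(ref_fasta)),
        reads=shlex.quote(str(reads_fastq)),
        out=shlex.quote(str(out_sam)),
    )
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise AlignerError(
            f"aligner command exited with status {proc.returncode}: "
            f"{proc.stderr.strip()[:500]}"
        )
    from dataclasses import replace

    records = read_sam(out_sam, default_label=label)
    return [replace(r, source_label=label) for r in records]


def rescore_against(
    rec: AlignmentRecord, target: str, *,
    mismatch: int = 2, gap_open: int = 3, gap_extend: int = 1,
) -> AlignmentRecord:
    """Recompute ``align_score`` for a record by comparing its read bases
    to the target sequence through its CIGAR (match +1, mismatch -2, gap
    -3 -1/base). Used by the truth path, where candidate placements on
    the two haplotypes must be ranked."""
    from dataclasses import replace

    if rec.is_unmapped or rec.seq is None:
        return rec
    score = 0
    qpos, tpos = 0, rec.pos
    for op, n in rec.cigar:
        if op == "M":
            for i in range(n):
                score += 1 if rec.seq[qpos + i] == target[tpos + i] else -mismatch
            qpos += n
            tpos += n
        elif op == "I":
            score -= gap_open + gap_extend * n
            qpos += n
        elif op == "D":
            score -= gap_open + gap_extend * n
            tpos += n
        elif op == "S":
            qpos += n
    return replace(rec, align_score=score)


def reexpress_alignments(
    records: Sequence[AlignmentRecord],
    source_chains: Mapping[str, Chain],
    *,
    target_chain: Chain | None = None,
    label: str | None = None,
    target_seq: str | None = None,
) -> tuple[list[AlignmentRecord], int]:
    """Re-express alignments in another coordinate system via chains.

    Each record is lifted through ``source_chains[record.target_name]``
    into reference coordinates; if ``target_chain`` is given (a haplotype
    -> reference chain), the record is then pushed *into* that haplotype
    through the inverted chain. Records that cannot be lifted are counted
    and dropped. With ``target_seq``, alignment scores are recomputed
    against the destination sequence.
    """
    out: list[AlignmentRecord] = []
    dropped = 0
    inv = invert_chain(target_chain) if target_chain is not None else None
    for rec in records:
        if rec.is_unmapped:
            dropped += 1
            continue
        chain = source_chains.get(rec.target_name)
        if chain is None:
            raise KeyError(f"no chain for alignment target {rec.target_name!r}")
        if rec.target_name != chain.source_name:
            # chains may be keyed by a SAM-local alias of the source sequence
            from dataclasses import replace

            rec = replace(rec, target_name=chain.source_name)
        res = lift_alignment(chain, rec)
        if res.record is not None and inv is not None:
            res = lift_alignment(inv, res.record)
        if res.record is None:
            dropped += 1
            continue
        rec2 = res.record
        if label is not None:
            from dataclasses import replace

            rec2 = replace(rec2, source_label=label)
        if target_seq is not None:
            rec2 = rescore_against(rec2, target_seq)
        out.append(rec2)
    if dropped:
        logger.info("reexpress: %d reads had no image in the target (dropped)",
                    dropped)
    return out, dropped
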