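"""Personalized diploid reference construction with coordinate chains.

Given a reference and a phased call set, this module substitutes each
haplotype's alleles into the reference to produce two haplotype-specific
sequences, and records the induced coordinate shifts as chain files so
that alignments against the personalized haplotypes can later be lifted
back to reference coordinates.

Coordinate conventions: 0-based half-open internally; VCF is 1-based on
disk; chains use the UCSC dialect (``chain`` header line followed by
``size d_source d_target`` triples, 0-based half-open, ``+`` strand only)
with the personalized haplotype as *source* and the reference as
*target*, because downstream lifting moves haplotype alignments back to
reference coordinates. SNV substitutions stay inside match blocks —
chains encode coordinate shifts, not sequence identity.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .variants import PhasedVariant, read_vcf, read_fasta, write_fasta

__all__ = [
    "EditPlan",
    "ChainBlock",
    "Chain",
    "DiploidReference",
    "plan_edits",
    "apply_edits",
    "build_diploid_reference",
    "write_chain",
    "parse_chain",
    "invert_chain",
    "write_diploid_reference",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChainBlock:
    """A run of ``size`` aligned bases followed by a gap: ``d_source``
    source-only bases (haplotype insertion) and ``d_target`` target-only
    bases (deletion from the haplotype)."""

    size: int
    d_source: int = 0
    d_target: int = 0


@dataclass(frozen=True)
class Chain:
    """Piecewise-colinear coordinate map source (haplotype) -> target
    (reference), spanning both sequences end to end."""

    source_name: str
    source_length: int
    target_name: str
    target_length: int
    blocks: tuple[ChainBlock, ...]

    def __post_init__(self) -> None:
        src = sum(b.size + b.d_source for b in self.blocks)
        tgt = sum(b.size + b.d_target for b in self.blocks)
        if src != self.source_length:
            raise ValueError(
                f"chain blocks span {src} source bases, expected {self.source_length}"
            )
        if tgt != self.target_length:
            raise ValueError(
                f"chain blocks span {tgt} target bases, expected {self.target_length}"
            )
        for i, b in enumerate(self.blocks):
            if b.size < 0 or b.d_source < 0 or b.d_target < 0:
                raise ValueError("negative chain block field")
            if b.size == 0 and i != len(self.blocks) - 1:
                raise ValueError("zero-size block before the terminal block")
        if self.blocks and (self.blocks[-1].d_source or self.blocks[-1].d_target):
            raise ValueError("terminal block must end without a gap")


@dataclass(frozen=True)
class EditPlan:
    """Sorted, non-overlapping replacements of reference intervals for one
    haplotype. ``replacement`` may be empty (pure deletion)."""

    edits: tuple[tuple[int, int, str], ...]  # (ref_start, ref_end, replacement)

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end, _ in self.edits:
            if end < start:
                raise ValueError(f"edit interval [{start},{end}) is inverted")
            if start < prev_end:
                raise ValueError("edit plan contains overlapping edits")
            prev_end = end

    @property
    def length_delta(self) -> int:
        return sum(len(rep) - (end - start) for start, end, rep in self.edits)


@dataclass(frozen=True)
class DiploidReference:
    """Two personalized haplotype sequence sets with their chains.

    Sequences are named ``{contig}_hap{1,2}``; ``chains[h]`` maps each
    haplotype sequence name to its chain back to the reference contig.
    """

    hap1: Mapping[str, str]
    hap2: Mapping[str, str]
    chain1: Mapping[str, Chain]
    chain2: Mapping[str, Chain]
    provenance: str

    def haps(self, h: int) -> Mapping[str, str]:
        return self.hap1 if h == 1 else self.hap2

    def chains(self, h: int) -> Mapping[str, Chain]:
        return self.chain1 if h == 1 else self.chain2


def plan_edits(
    reference: str,
    calls: Sequence[PhasedVariant],
    hap_index: int,
    *,
    chrom: str = "ref",
) -> EditPlan:
    """One edit per call whose haplotype-``hap_index`` allele is ALT.

    Calls must be position-sorted with REF alleles matching the reference
    (mismatch fails naming the locus). Calls overlapping an earlier kept
    edit are dropped with a warning — leftmost wins, a deterministic and
    auditable policy for inputs whose upstream normalization is unknown.
    Symbolic ALTs (``<DEL>`` etc.) are rejected: only sequence-resolved
    alleles are applied.
    """
    edits: list[tuple[int, int, str]] = []
    prev_pos = -1
    prev_end = -1
    for v in calls:
        if v.pos < prev_pos:
            raise ValueError(f"calls not sorted at {v.chrom}:{v.pos + 1}")
        prev_pos = v.pos
        if v.alt.startswith("<") or not set(v.alt) <= set("ACGTNacgtn"):
            raise ValueError(
                f"symbolic/non-sequence ALT {v.alt!r} at {v.chrom}:{v.pos + 1}"
            )
        if v.pos < 0 or v.pos + len(v.ref) > len(reference):
            raise ValueError(f"variant at {v.chrom}:{v.pos + 1} out of bounds")
        if reference[v.pos : v.pos + len(v.ref)] != v.ref:
            raise ValueError(
                f"REF mismatch at {v.chrom}:{v.pos + 1}: VCF says {v.ref!r}, "
                f"reference has {reference[v.pos:v.pos + len(v.ref)]!r}"
            )
        if v.allele(hap_index) == 0:
            continue
        if v.pos < prev_end:
            logger.warning(
                "dropping variant at %s:%d overlapping a kept edit (leftmost wins)",
                chrom, v.pos + 1,
            )
            continue
        edits.append((v.pos, v.pos + len(v.ref), v.alt))
        prev_end = v.pos + len(v.ref)
    return EditPlan(tuple(edits))


def apply_edits(
    reference: str,
    plan: EditPlan,
    *,
    source_name: str = "hap",
    target_name: str = "ref",
) -> tuple[str, Chain]:
    """Apply an edit plan, returning the haplotype and its chain.

    Unedited stretches become match blocks. Per edit the shared left
    anchor (common prefix of the replaced interval and the replacement)
    extends the match; a same-length residual is a substitution and also
    extends the match (SNVs produce no chain gap); otherwise the residual
    lengths become the ``d_target`` (reference-only) and ``d_source``
    (haplotype-only) gap at that junction.
    """
    parts: list[str] = []
    blocks: list[ChainBlock] = []
    match_run = 0
    cursor = 0
    for start, end, rep in plan.edits:
        match_run += start - cursor
        removed = reference[start:end]
        cp = 0
        for a, b in zip(removed, rep):
            if a != b:
                break
            cp += 1
        d_res = len(removed) - cp
        r_res = len(rep) - cp
        match_run += cp
        if d_res == r_res:
            match_run += d_res  # pure substitution, no coordinate shift
        else:
            blocks.append(ChainBlock(match_run, d_source=r_res, d_target=d_res))
            match_run = 0
        parts.append(reference[cursor:start])
        parts.append(rep)
        cursor = end
    parts.append(reference[cursor:])
    match_run += len(reference) - cursor
    blocks.append(ChainBlock(match_run))
    hap = "".join(parts)
    chain = Chain(source_name, len(hap), target_name, len(reference), tuple(blocks))
    assert len(hap) == len(reference) + plan.length_delta
    return hap, chain


def build_diploid_reference(
    reference: Mapping[str, str],
    calls: Sequence[PhasedVariant],
) -> DiploidReference:
    """Run plan + apply per haplotype per contig.

    Every call must be phased (this stage is only meaningful downstream of
    phasing). Contigs without calls get identity haplotypes and
    single-block identity chains.
    """
    for v in calls:
        if not v.phased:
            raise ValueError(
                f"unphased genotype at {v.chrom}:{v.pos + 1}; personalization "
                "requires phased calls"
            )
    by_chrom: dict[str, list[PhasedVariant]] = {c: [] for c in reference}
    for v in calls:
        if v.chrom not in by_chrom:
            raise ValueError(f"call on unknown contig {v.chrom!r}")
        by_chrom[v.chrom].append(v)

    haps: list[dict[str, str]] = [{}, {}]
    chains: list[dict[str, Chain]] = [{}, {}]
    for chrom, seq in reference.items():
        chrom_calls = sorted(by_chrom[chrom], key=lambda v: v.pos)
        for h in (1, 2):
            plan = plan_edits(seq, chrom_calls, h, chrom=chrom)
            hap, chain = apply_edits(
                seq, plan, source_name=f"{chrom}_hap{h}", target_name=chrom
            )
            haps[h - 1][f"{chrom}_hap{h}"] = hap
            chains[h - 1][f"{chrom}_hap{h}"] = chain

    digest = hashlib.sha256(
        "".join(f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}:{v.genotype}" for v in calls).encode()
    ).hexdigest()[:16]
    return DiploidReference(haps[0], haps[1], chains[0], chains[1], digest)


# ---------------------------------------------------------------------------
# Chain file dialect


def write_chain(path: str | Path, chains: Iterable[Chain]) -> None:
    """Emit chains in the UCSC dialect used throughout this package:
    header ``chain score sName sSize + sStart sEnd tName tSize + tStart
    tEnd id`` then ``size d_source d_target`` triples, terminal line a
    bare size, records separated by blank lines."""
    lines: list[str] = []
    for i, ch in enumerate(chains, start=1):
        score = sum(b.size for b in ch.blocks)
        lines.append(
            f"chain {score} {ch.source_name} {ch.source_length} + 0 "
            f"{ch.source_length} {ch.target_name} {ch.target_length} + 0 "
            f"{ch.target_length} {i}"
        )
        for b in ch.blocks[:-1]:
            lines.append(f"{b.size} {b.d_source} {b.d_target}")
        lines.append(str(ch.blocks[-1].size))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_chain(path: str | Path) -> list[Chain]:
    """Strict re-parser: block arithmetic must re-derive both sequence
    lengths (enforced by the Chain constructor)."""
    chains: list[Chain] = []
    header: list[str] | None = None
    blocks: list[ChainBlock] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("chain"):
            if header is not None:
                chains.append(_finish_chain(header, blocks))
            header = line.split()
            if len(header) != 13:
                raise ValueError(f"malformed chain header: {raw!r}")
            blocks = []
        else:
            fields = line.split()
            if header is None:
                raise ValueError("chain data before any chain header")
            if len(fields) == 3:
                blocks.append(ChainBlock(int(fields[0]), int(fields[1]), int(fields[2])))
            elif len(fields) == 1:
                blocks.append(ChainBlock(int(fields[0])))
            else:
                raise ValueError(f"malformed chain block line: {raw!r}")
    if header is not None:
        chains.append(_finish_chain(header, blocks))
    return chains


def _finish_chain(header: list[str], blocks: list[ChainBlock]) -> Chain:
    _, _, s_name, s_size, s_strand, s_start, s_end, t_name, t_size, t_strand, \
        t_start, t_end, _ = header
    if s_strand != "+" or t_strand != "+":
        raise ValueError("only + strand chains are supported")
    if int(s_start) != 0 or int(s_end) != int(s_size) or int(t_start) != 0 \
            or int(t_end) != int(t_size):
        raise ValueError("chains must span both sequences end to end")
    return Chain(s_name, int(s_size), t_name, int(t_size), tuple(blocks))


def invert_chain(chain: Chain) -> Chain:
    """Swap source and target roles (reference -> haplotype direction)."""
    return Chain(
        source_name=chain.target_name,
        source_length=chain.target_length,
        target_name=chain.source_name,
        target_length=chain.source_length,
        blocks=tuple(
            ChainBlock(b.size, d_source=b.d_target, d_target=b.d_source)
            for b in chain.blocks
        ),
    )


def write_diploid_reference(dr: DiploidReference, out_prefix: str | Path) -> dict[str, Path]:
    """Emit ``hap1.fasta``/``hap2.fasta`` and ``hap1.chain``/``hap2.chain``."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for h in (1, 2):
        fa = Path(f"{out_prefix}.hap{h}.fasta")
        ch = Path(f"{out_prefix}.hap{h}.chain")
        write_fasta(fa, dr.haps(h),
                    header_comments=[f"imputefirst-personalize source={dr.provenance}"])
        write_chain(ch, dr.chains(h).values())
        paths[f"hap{h}_fasta"] = fa
        paths[f"hap{h}_chain"] = ch
    return paths
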