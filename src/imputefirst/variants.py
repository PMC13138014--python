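"""Shared variant types and minimal VCF/FASTA/FASTQ text I/O.

The atom of every call set in this package — truth sets, panels, rough
genotype calls, imputed diploids — is a biallelic, sequence-resolved
:class:`PhasedVariant`. Coordinates are 0-based half-open internally;
VCF is read and written 1-based per the standard.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

__all__ = [
    "PhasedVariant",
    "Site",
    "read_vcf",
    "write_vcf",
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "sequence_digest",
]

#: (chrom, pos, ref, alt) — the identity of a biallelic site.
Site = tuple[str, int, str, str]


@dataclass(frozen=True)
class PhasedVariant:
    """One biallelic VCF record with per-haplotype allele indices.

    ``genotype`` holds the two allele indices (0 = REF, 1 = ALT); when
    ``phased`` the order is (haplotype 1, haplotype 2) and is meaningful.
    ``qual`` carries the caller confidence where one exists (``None`` for
    truth/panel records). ``pos`` is the 0-based reference offset of the
    first REF base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: tuple[int, int]
    phased: bool = True
    qual: float | None = None
    depth: int | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if not all(a in (0, 1) for a in self.genotype):
            raise ValueError(
                f"biallelic contract violated at {self.chrom}:{self.pos}: "
                f"genotype {self.genotype}"
            )

    @property
    def site(self) -> Site:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def length_delta(self) -> int:
        """len(ALT) - len(REF): 0 for SNVs, >0 insertions, <0 deletions."""
        return len(self.alt) - len(self.ref)

    def allele(self, hap_index: int) -> int:
        """Allele index on haplotype 1 or 2 (requires phased genotype)."""
        if hap_index not in (1, 2):
            raise ValueError("hap_index must be 1 or 2")
        return self.genotype[hap_index - 1]


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    path: str | Path,
    variants: Iterable[PhasedVariant],
    contigs: Mapping[str, int],
    *,
    sample: str = "SAMPLE",
    header_comments: Sequence[str] = (),
) -> None:
    """Write a single-sample VCF 4.2 with phased (``|``) or unphased GT."""
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##{c}" for c in header_comments]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for v in variants:
        sep = "|" if v.phased else "/"
        gt = f"{v.genotype[0]}{sep}{v.genotype[1]}"
        qual = "." if v.qual is None else f"{v.qual:g}"
        info = "." if v.depth is None else f"DP={v.depth}"
        lines.append(
            f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t{qual}\t.\t{info}\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_gt(gt_field: tuple[int | None, ...], phased: bool) -> tuple[tuple[int, int], bool]:
    if len(gt_field) != 2 or any(a is None for a in gt_field):
        raise ValueError(f"non-diploid or missing genotype {gt_field!r}")
    return (int(gt_field[0]), int(gt_field[1])), phased


def read_vcf(
    path: str | Path,
    *,
    require_phased: bool = False,
    sample: str | int = 0,
) -> list[PhasedVariant]:
    """Read biallelic records for one sample from a VCF via pysam.

    Multi-allelic records are rejected (the package's biallelic contract);
    with ``require_phased``, the first unphased GT fails loudly naming the
    record, since downstream consensus construction is only meaningful on
    phased calls.
    """
    out: list[PhasedVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        sample_name = (
            list(vf.header.samples)[sample] if isinstance(sample, int) else sample
        )
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} is not biallelic"
                )
            call = rec.samples[sample_name]
            phased = bool(call.phased)
            if require_phased and not phased:
                raise ValueError(
                    f"unphased genotype at {rec.chrom}:{rec.pos} "
                    f"({'/'.join(str(a) for a in call['GT'])})"
                )
            genotype, phased = _parse_gt(tuple(call["GT"]), phased)
            depth = rec.info.get("DP") if "DP" in rec.info else None
            out.append(
                PhasedVariant(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    genotype=genotype,
                    phased=phased,
                    qual=rec.qual,
                    depth=depth,
                )
            )
    return out


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(
    path: str | Path,
    sequences: Mapping[str, str],
    *,
    width: int = 70,
    header_comments: Sequence[str] = (),
) -> None:
    # Provenance goes in the description field of each header line: the
    # old-style ';' FASTA comment is rejected by faidx-style indexers.
    desc = (" " + "; ".join(header_comments)) if header_comments else ""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}{desc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    import pyfaidx

    with pyfaidx.Fasta(str(path), as_raw=True, rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], *, qual_char: str = "I") -> None:
    """Write (name, sequence) pairs with a constant base quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")


def sequence_digest(sequences: Mapping[str, str] | str) -> str:
    """Stable short digest used for provenance stamping."""
    h = hashlib.sha256()
    if isinstance(sequences, str):
        h.update(sequences.encode())
    else:
        for name in sorted(sequences):
            h.update(name.encode())
            h.update(sequences[name].encode())
    return h.hexdigest()[:16]
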