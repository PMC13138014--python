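"""Rough genotyping: pileup, binomial-likelihood calls, QUAL/DP filtering.

This is the first stage of personalization. Because it typically runs on a
low-coverage subsample of the reads, its calls are *rough* — not accurate
by themselves — but they carry enough signal for a downstream imputation
engine. The caller here is a deliberately simple maximum-likelihood
binomial model behind a VCF interface, so any external caller can be
substituted.

Pileup conventions: each aligned M/=/X base contributes one count at its
reference position; an insertion contributes one ``+SEQ`` token and a
deletion one ``-LEN`` token, both anchored at the reference base
immediately left of the event (VCF-style left anchoring). ``depth`` of a
column is the sum of all its contributions.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

from .alignments import AlignmentRecord
from .variants import PhasedVariant, write_vcf, read_vcf

__all__ = [
    "PileupColumn",
    "RoughCall",
    "pileup_from_alignments",
    "call_rough_genotypes",
    "filter_rough_calls",
    "write_rough_vcf",
    "read_rough_vcf",
    "DEFAULT_MIN_QUAL",
    "DEFAULT_MAX_DEPTH",
]

#: Record-level filter thresholds: QUAL below 20 or DP exceeding 100 is
#: dropped; the boundary values themselves pass (strict "below"/"exceeding").
DEFAULT_MIN_QUAL = 20.0
DEFAULT_MAX_DEPTH = 100

#: Phred cap so a zero posterior error at high depth stays finite.
QUAL_CAP = 99.0


@dataclass(frozen=True)
class PileupColumn:
    chrom: str
    pos: int
    base_counts: Mapping[str, int]

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


@dataclass(frozen=True)
class RoughCall:
    """One unphased diploid call with its confidence and depth."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: tuple[int, int]
    qual: float
    depth: int

    def __post_init__(self) -> None:
        if self.qual < 0:
            raise ValueError("qual must be >= 0")
        if not all(a in (0, 1) for a in self.genotype):
            raise ValueError("genotype indices must be 0 or 1")

    @property
    def site(self):
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


def pileup_from_alignments(
    records: Iterable[AlignmentRecord],
    reference: Mapping[str, str],
) -> Iterator[PileupColumn]:
    """One column per covered position, in coordinate order.

    Bases contribute according to the CIGAR: M consumes both sequences and
    contributes the read base; I contributes a ``+SEQ`` token at the
    preceding reference base; D contributes a ``-LEN`` token at the
    preceding reference base; soft-clipped and unaligned bases contribute
    nothing. A leading I/D with no preceding aligned base is skipped.
    """
    counts: dict[tuple[str, int], Counter] = defaultdict(Counter)
    for rec in records:
        if rec.is_unmapped:
            continue
        if rec.target_name not in reference:
            raise KeyError(
                f"alignment {rec.read_id} targets {rec.target_name!r}, "
                "absent from the reference set"
            )
        if rec.seq is None:
            raise ValueError(f"alignment {rec.read_id} carries no sequence")
        rec.validate_query_length()
        qpos, tpos = 0, rec.pos
        for op, n in rec.cigar:
            if op in ("M", "=", "X"):
                for i in range(n):
                    counts[(rec.target_name, tpos + i)][rec.seq[qpos + i]] += 1
                qpos += n
                tpos += n
            elif op == "I":
                # anchor only when this read aligns the anchor base itself;
                # a leading I (read starts inside the insertion) would hang
                # an unanchored token on a base the read never saw
                if tpos > rec.pos:
                    counts[(rec.target_name, tpos - 1)][f"+{rec.seq[qpos:qpos+n]}"] += 1
                qpos += n
            elif op == "D":
                if tpos > rec.pos:
                    counts[(rec.target_name, tpos - 1)][f"-{n}"] += 1
                tpos += n
            elif op in ("S", "H"):
                if op == "S":
                    qpos += n
            else:
                raise ValueError(f"unsupported CIGAR op {op!r} in {rec.read_id}")
    for (chrom, pos) in sorted(counts):
        yield PileupColumn(chrom, pos, dict(counts[(chrom, pos)]))


def _alleles_from_key(key: str, chrom: str, pos: int,
                      reference: Mapping[str, str]) -> tuple[str, str]:
    """REF/ALT strings for a pileup key (base, +SEQ or -LEN) at a column."""
    anchor = reference[chrom][pos]
    if key.startswith("+"):
        return anchor, anchor + key[1:]
    if key.startswith("-"):
        length = int(key[1:])
        return reference[chrom][pos : pos + length + 1], anchor
    return anchor, key


def call_rough_genotypes(
    columns: Iterable[PileupColumn],
    reference: Mapping[str, str],
    error_rate: float = 0.01,
) -> Iterator[RoughCall]:
    """Maximum-likelihood diploid calls under a binomial read model.

    Per column with a non-reference allele observed, the most frequent
    non-reference key becomes the candidate ALT; each informative read
    shows ALT with probability ``error_rate`` under 0/0, one half under
    0/1 and ``1 - error_rate`` under 1/1. The emitted genotype maximizes
    the likelihood; ``qual`` is the phred-scaled posterior error under a
    flat genotype prior, capped at 99. Zero-depth columns emit nothing.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    for col in columns:
        ref_base = reference[col.chrom][col.pos]
        non_ref = {k: c for k, c in col.base_counts.items() if k != ref_base}
        if not non_ref:
            continue
        # candidate ALT support, aggregated per category: insertion tokens
        # at one anchor all support "an insertion here" (a read error inside
        # the inserted sequence must not split the evidence); same for
        # deletions; base substitutions stay per-base.
        support: dict[str, int] = {}
        for key, c in non_ref.items():
            cat = key[0] if key[0] in "+-" else key
            support[cat] = support.get(cat, 0) + c
        cat = min(support, key=lambda x: (-support[x], x))
        k = support[cat]
        if cat in "+-":
            # allele sequence from the best-supported token in the category
            alt_key = min((x for x in non_ref if x[0] == cat),
                          key=lambda x: (-non_ref[x], x))
            # reads carrying the indel also contributed their anchor base
            r = max(col.base_counts.get(ref_base, 0) - k, 0)
        else:
            alt_key = cat
            r = col.base_counts.get(ref_base, 0)
        n = r + k
        if n == 0:
            continue
        loglik = {}
        for gt, p_alt in (((0, 0), error_rate), ((0, 1), 0.5),
                          ((1, 1), 1.0 - error_rate)):
            loglik[gt] = k * math.log(p_alt) + r * math.log1p(-p_alt)
        best = min(loglik, key=lambda g: (-loglik[g], g))
        denom = sum(math.exp(v - loglik[best]) for v in loglik.values())
        p_err = 1.0 - 1.0 / denom
        qual = QUAL_CAP if p_err <= 0 else min(-10.0 * math.log10(p_err), QUAL_CAP)
        ref_a, alt_a = _alleles_from_key(alt_key, col.chrom, col.pos, reference)
        yield RoughCall(col.chrom, col.pos, ref_a, alt_a, best, qual, col.depth)


def filter_rough_calls(
    calls: Iterable[RoughCall],
    min_qual: float = DEFAULT_MIN_QUAL,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> list[RoughCall]:
    """Drop records with QUAL below ``min_qual`` or DP exceeding
    ``max_depth``; boundary values pass. Order preserved; pure subset."""
    if min_qual < 0 or max_depth < 0:
        raise ValueError("filter thresholds must be >= 0")
    return [c for c in calls if c.qual >= min_qual and c.depth <= max_depth]


# ---------------------------------------------------------------------------
# VCF interface


def write_rough_vcf(path, calls: Sequence[RoughCall],
                    contigs: Mapping[str, int], **kw) -> None:
    variants = [
        PhasedVariant(c.chrom, c.pos, c.ref_allele, c.alt_allele,
                      tuple(sorted(c.genotype)), phased=False,
                      qual=c.qual, depth=c.depth)
        for c in calls
    ]
    write_vcf(path, variants, contigs, **kw)


def read_rough_vcf(path) -> list[RoughCall]:
    return [
        RoughCall(v.chrom, v.pos, v.ref, v.alt, v.genotype,
                  v.qual if v.qual is not None else 0.0,
                  v.depth if v.depth is not None else 0)
        for v in read_vcf(path)
    ]
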