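"""Evaluation statistics for personalized-reference workflows.

Implements the accounting used to score a personalization pipeline:

* **Allele-level (ALT) confusion** — every diploid call is a pair of
  individual allele calls. A called ALT with at least one true ALT at the
  site is a TP; a called REF with at least one true REF is a TN; a called
  ALT against hom-REF truth is one FP; a called REF against hom-ALT truth
  is one FN. Totals always sum to 2 x |sites|.
* **HET-level confusion** — per site: called HET and truly HET is a TP;
  FP/FN/TN defined accordingly. Totals sum to |sites|.
* **Pivot-window accuracy** — for every polymorphic site (the *pivot*),
  the window holds the pivot plus all polymorphic sites to its left
  within 200 bp; a window is correct iff a single haplotype-label
  orientation (identity or swap) makes every member site's phased
  genotype match truth. Windows are stratified by member count
  (1-5, 6-10, 11+).
* **Allelic balance at HETs** — per HET site, the fraction of informative
  overlapping reads supporting the ALT allele; 0.5 means no reference
  bias. Balances are binned by allele length delta (SNVs at zero,
  deletions negative, insertions positive, clamped at +/-30).
* **QUAL-threshold ROC table** — counts and precision/recall of a scored
  call set against truth at a grid of QUAL thresholds.

The evaluation site universe is the panel's polymorphic sites; calls or
truth missing at a site count as homozygous REF — the only closure that
keeps the accounting totals fixed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignments import AlignmentRecord
from .variants import PhasedVariant, Site

__all__ = [
    "ConfusionCounts",
    "PRF",
    "Window",
    "WindowStratumResult",
    "SiteBalance",
    "BalanceBin",
    "genotype_map",
    "allele_alt_confusion",
    "het_confusion",
    "prf_from_counts",
    "build_pivot_windows",
    "window_accuracy",
    "site_allelic_balance",
    "bias_length_bins",
    "qual_roc_table",
    "read_bed",
    "restrict_to_regions",
    "WINDOW_BP",
    "STRATA",
]

WINDOW_BP = 200
STRATA = ("1-5", "6-10", "11+")

GenotypeMap = Mapping[Site, tuple[int, int]]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PRF:
    """Precision/recall/F1; ``None`` marks an undefined ratio (zero
    denominator) rather than silently coercing to 0."""

    precision: float | None
    recall: float | None
    f1: float | None


def genotype_map(variants: Iterable[PhasedVariant]) -> dict[Site, tuple[int, int]]:
    """Index phased variants by site identity for the evaluation ops."""
    return {v.site: v.genotype for v in variants}


def _check_gt(gt: tuple[int, int]) -> tuple[int, int]:
    if not all(a in (0, 1) for a in gt):
        raise ValueError(f"allele index outside {{0,1}} in genotype {gt}")
    return gt


def allele_alt_confusion(
    calls: GenotypeMap, truth: GenotypeMap, sites: Sequence[Site]
) -> ConfusionCounts:
    """Allele-by-allele confusion with the ALT calls as the positive class.

    Each called allele contributes exactly one count, so
    ``tp + fp + fn + tn == 2 * len(sites)``.
    """
    tp = fp = fn = tn = 0
    for site in sites:
        call = _check_gt(tuple(calls.get(site, (0, 0))))
        true = _check_gt(tuple(truth.get(site, (0, 0))))
        for allele in call:
            if allele == 1:
                if 1 in true:
                    tp += 1
                else:
                    fp += 1
            else:
                if 0 in true:
                    tn += 1
                else:
                    fn += 1
    counts = ConfusionCounts(tp, fp, fn, tn)
    assert counts.total == 2 * len(sites)
    return counts


def het_confusion(
    calls: GenotypeMap, truth: GenotypeMap, sites: Sequence[Site]
) -> ConfusionCounts:
    """Site-level confusion with HET as the positive class; totals sum to
    ``len(sites)``."""
    tp = fp = fn = tn = 0
    for site in sites:
        call_het = len(set(_check_gt(tuple(calls.get(site, (0, 0)))))) == 2
        true_het = len(set(_check_gt(tuple(truth.get(site, (0, 0)))))) == 2
        if call_het and true_het:
            tp += 1
        elif call_het:
            fp += 1
        elif true_het:
            fn += 1
        else:
            tn += 1
    counts = ConfusionCounts(tp, fp, fn, tn)
    assert counts.total == len(sites)
    return counts


def prf_from_counts(counts: ConfusionCounts) -> PRF:
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    f1 = None
    if p is not None and r is not None and (p + r) > 0:
        f1 = 2 * p * r / (p + r)
    elif p is not None and r is not None:
        f1 = 0.0
    return PRF(p, r, f1)


# ---------------------------------------------------------------------------
# Pivot windows


@dataclass(frozen=True)
class Window:
    pivot: Site
    members: tuple[Site, ...]

    @property
    def stratum(self) -> str:
        n = len(self.members)
        return "1-5" if n <= 5 else ("6-10" if n <= 10 else "11+")


@dataclass(frozen=True)
class WindowStratumResult:
    stratum: str
    n_windows: int
    n_correct: int

    @property
    def accuracy(self) -> float | None:
        return self.n_correct / self.n_windows if self.n_windows else None


def build_pivot_windows(
    sites: Sequence[Site], window: int = WINDOW_BP
) -> list[Window]:
    """One window per polymorphic site: the pivot plus every site to its
    left within ``window`` bp (member positions p with
    ``pivot - window <= p <= pivot``). Sites must be sorted and unique
    per chromosome."""
    by_chrom: dict[str, list[Site]] = defaultdict(list)
    for s in sites:
        group = by_chrom[s[0]]
        if group and s[1] <= group[-1][1]:
            raise ValueError(f"sites not sorted/unique at {s[0]}:{s[1]}")
        group.append(s)
    windows: list[Window] = []
    for chrom_sites in by_chrom.values():
        positions = [s[1] for s in chrom_sites]
        lo = 0
        for i, pivot in enumerate(chrom_sites):
            while positions[lo] < pivot[1] - window:
                lo += 1
            windows.append(Window(pivot, tuple(chrom_sites[lo : i + 1])))
    return windows


def window_accuracy(
    imputed: GenotypeMap,
    truth: GenotypeMap,
    windows: Sequence[Window],
) -> list[WindowStratumResult]:
    """Fraction of windows whose every member site is correctly genotyped
    *and* phased, per stratum.

    Haplotype labels are globally arbitrary, so a window counts as
    correct when either the identity or the swapped label assignment —
    applied consistently across the whole window — reproduces truth at
    every member site. Missing entries count as hom-REF.
    """
    tallies = {s: [0, 0] for s in STRATA}  # stratum -> [n, correct]
    for w in windows:
        call_gts = [tuple(imputed.get(s, (0, 0))) for s in w.members]
        true_gts = [tuple(truth.get(s, (0, 0))) for s in w.members]
        ok_identity = all(c == t for c, t in zip(call_gts, true_gts))
        ok_swap = all((c[1], c[0]) == t for c, t in zip(call_gts, true_gts))
        tallies[w.stratum][0] += 1
        if ok_identity or ok_swap:
            tallies[w.stratum][1] += 1
    return [WindowStratumResult(s, n, c) for s, (n, c) in tallies.items()]


# ---------------------------------------------------------------------------
# Allelic balance


@dataclass(frozen=True)
class SiteBalance:
    variant: PhasedVariant
    n_alt: int
    n_ref: int

    @property
    def balance(self) -> float:
        return self.n_alt / (self.n_alt + self.n_ref)


def _walk(rec: AlignmentRecord):
    """Per-read alignment geometry: ref_pos -> read base for M runs, plus
    insertion junctions (anchor_ref_pos -> length) and deletion runs
    (start_ref_pos -> length)."""
    bases: dict[int, str] = {}
    insertions: dict[int, int] = {}
    deletions: dict[int, int] = {}
    qpos, tpos = 0, rec.pos
    for op, n in rec.cigar:
        if op == "M":
            for i in range(n):
                bases[tpos + i] = rec.seq[qpos + i]
            qpos += n
            tpos += n
        elif op == "I":
            insertions[tpos - 1] = insertions.get(tpos - 1, 0) + n
            qpos += n
        elif op == "D":
            deletions[tpos] = n
            tpos += n
        elif op == "S":
            qpos += n
    return bases, insertions, deletions


def _classify(rec: AlignmentRecord, v: PhasedVariant) -> str:
    """REF / ALT / uninformative for one read at one HET site."""
    bases, insertions, deletions = _walk(rec)
    delta = v.length_delta
    if delta == 0 and len(v.ref) == 1:  # SNV
        base = bases.get(v.pos)
        if base == v.alt:
            return "ALT"
        if base == v.ref:
            return "REF"
        return "uninformative"
    if delta > 0:  # insertion anchored at v.pos
        ins_len = insertions.get(v.pos)
        spans = v.pos in bases and (v.pos + 1 in bases or ins_len is not None)
        if ins_len == delta:
            return "ALT"
        if spans and ins_len is None:
            return "REF"
        return "uninformative"
    # deletion: deleted reference bases are [v.pos + 1, v.pos + 1 - delta)
    del_len = deletions.get(v.pos + 1)
    if del_len == -delta and v.pos in bases:
        return "ALT"
    locus = range(v.pos, v.pos + len(v.ref))
    if all(p in bases for p in locus):
        return "REF"
    return "uninformative"


def site_allelic_balance(
    alignments: Sequence[AlignmentRecord],
    het_sites: Sequence[PhasedVariant],
) -> tuple[list[SiteBalance], int]:
    """Per-HET-site allelic balance from reference-coordinate alignments.

    Each overlapping read is classified by direct base/CIGAR comparison at
    the locus; uninformative reads (neither allele matches) are excluded
    from the denominator. Returns the per-site balances plus the count of
    sites omitted for having no informative reads.
    """
    mapped = sorted((r for r in alignments if not r.is_unmapped),
                    key=lambda r: (r.target_name, r.pos))
    starts_by_chrom: dict[str, list[int]] = defaultdict(list)
    recs_by_chrom: dict[str, list[AlignmentRecord]] = defaultdict(list)
    max_span = 0
    for r in mapped:
        starts_by_chrom[r.target_name].append(r.pos)
        recs_by_chrom[r.target_name].append(r)
        max_span = max(max_span, r.end - r.pos)

    import bisect

    out: list[SiteBalance] = []
    omitted = 0
    for v in het_sites:
        recs = recs_by_chrom.get(v.chrom, [])
        starts = starts_by_chrom.get(v.chrom, [])
        locus_end = v.pos + len(v.ref)
        lo = bisect.bisect_left(starts, v.pos - max_span)
        hi = bisect.bisect_right(starts, locus_end)
        n_alt = n_ref = 0
        for r in recs[lo:hi]:
            if r.end <= v.pos:
                continue
            cls = _classify(r, v)
            if cls == "ALT":
                n_alt += 1
            elif cls == "REF":
                n_ref += 1
        if n_alt + n_ref == 0:
            omitted += 1
        else:
            out.append(SiteBalance(v, n_alt, n_ref))
    return out, omitted


@dataclass(frozen=True)
class BalanceBin:
    length_key: int  # len(ALT) - len(REF), clamped to [-30, 30]
    mean_balance: float
    q25: float
    q75: float
    n_variants: int


def bias_length_bins(balances: Sequence[SiteBalance]) -> list[BalanceBin]:
    """Aggregate per-site balances by allele length delta.

    SNVs sit at zero, deletions to the left, insertions to the right;
    variants longer than 30 bp share the +/-30 bin. Quartiles use linear
    interpolation between order statistics.
    """
    groups: dict[int, list[float]] = defaultdict(list)
    for sb in balances:
        key = int(np.clip(sb.variant.length_delta, -30, 30))
        groups[key].append(sb.balance)
    bins = []
    for key in sorted(groups):
        vals = np.asarray(groups[key])
        bins.append(
            BalanceBin(
                length_key=key,
                mean_balance=float(vals.mean()),
                q25=float(np.percentile(vals, 25)),
                q75=float(np.percentile(vals, 75)),
                n_variants=len(vals),
            )
        )
    return bins


# ---------------------------------------------------------------------------
# QUAL-threshold ROC table


def qual_roc_table(
    calls: Sequence[PhasedVariant],
    truth: Sequence[PhasedVariant],
    thresholds: Sequence[float],
) -> list[dict]:
    """Counts and precision/recall when keeping calls with QUAL >= t.

    Truth matching is exact: site identity (chrom, pos, REF, ALT) plus
    unordered genotype. ``tp`` and ``fp`` are non-increasing in t. The
    table reports counts and precision/recall; with no negative-site
    universe an FPR denominator is not computable, and TPR equals recall.
    """
    truth_keys = {(v.site, tuple(sorted(v.genotype))) for v in truth}
    rows = []
    for t in thresholds:
        kept = [c for c in calls if (c.qual or 0.0) >= t]
        tp = sum(
            ((c.site, tuple(sorted(c.genotype))) in truth_keys) for c in kept
        )
        fp = len(kept) - tp
        fn = len(truth_keys) - tp
        p = tp / (tp + fp) if tp + fp else None
        r = tp / (tp + fn) if tp + fn else None
        rows.append(
            {"threshold": t, "tp": tp, "fp": fp, "fn": fn,
             "precision": p, "recall": r}
        )
    return rows


# ---------------------------------------------------------------------------
# Region restriction (single optional BED)


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Three-column BED (0-based half-open intervals)."""
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        regions.append((chrom, int(start), int(end)))
    return regions


def restrict_to_regions(
    variants: Iterable[PhasedVariant], regions: Sequence[tuple[str, int, int]]
) -> list[PhasedVariant]:
    """Keep variants whose start falls inside a region (high-confidence
    evaluation restriction)."""
    return [
        v for v in variants
        if any(c == v.chrom and s <= v.pos < e for c, s, e in regions)
    ]
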