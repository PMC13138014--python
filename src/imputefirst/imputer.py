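"""Phased diploid imputation from rough genotype calls and a haplotype panel.

Rough, sparse genotype calls are not accurate by themselves — the point of
this stage is that a phased haplotype panel carries enough linkage
information to turn them into a complete phased diploid call set. The
heavyweight HMM/PBWT engines used in production (Beagle, GLIMPSE) are
consumed through an adapter contract (:func:`run_external_imputer`); the
built-in imputer is a minimal, exhaustively-scored stand-in that selects,
per chunk of consecutive sites, the ordered pair of panel haplotypes most
consistent with the weighted rough calls, then stitches chunks by
haplotype identity.

Panel hygiene matters: imputing a donor against a panel containing the
donor (or family) yields unrealistically accurate results, so
:func:`exclude_samples` removes both haplotype rows of every excluded
sample before imputation.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .variants import PhasedVariant, Site, read_vcf

__all__ = [
    "PanelMatrix",
    "exclude_samples",
    "impute_phased_genotypes",
    "run_external_imputer",
    "ExternalImputerError",
]

logger = logging.getLogger(__name__)

#: Rough-call weight cap: one overconfident call must not dominate a chunk.
QUAL_WEIGHT_CAP = 50.0
#: Sites examined on each side of a chunk junction when stitching.
STITCH_FLANK = 10


@dataclass(frozen=True)
class PanelMatrix:
    """A phased multi-sample haplotype panel over biallelic sites.

    ``haplotypes`` is an (H x S) allele-index matrix with two consecutive
    rows per sample (rows 2k and 2k+1 belong to ``sample_ids[k]``).
    """

    sites: tuple[Site, ...]
    haplotypes: np.ndarray
    sample_ids: Sequence[str]

    def __post_init__(self) -> None:
        H, S = self.haplotypes.shape
        if H != 2 * len(self.sample_ids):
            raise ValueError(
                f"{H} haplotype rows but {len(self.sample_ids)} samples "
                "(two rows per sample required)"
            )
        if S != len(self.sites):
            raise ValueError("haplotype matrix width != number of sites")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("panel allele indices must be 0 or 1")
        per_chrom: dict[str, int] = {}
        for chrom, pos, _, _ in self.sites:
            if chrom in per_chrom and pos <= per_chrom[chrom]:
                raise ValueError(f"panel sites not strictly increasing in {chrom}")
            per_chrom[chrom] = pos

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    # -- I/O ---------------------------------------------------------------

    def to_vcf(self, path: str | Path, *, contigs: Mapping[str, int],
               header_comments: Sequence[str] = ()) -> None:
        lines = ["##fileformat=VCFv4.2"]
        lines += [f"##{c}" for c in header_comments]
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.sample_ids))
        for j, (chrom, pos, ref, alt) in enumerate(self.sites):
            gts = "\t".join(
                f"{self.haplotypes[2 * k, j]}|{self.haplotypes[2 * k + 1, j]}"
                for k in range(len(self.sample_ids))
            )
            lines.append(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_vcf(cls, path: str | Path) -> "PanelMatrix":
        import pysam

        sites: list[Site] = []
        columns: list[list[int]] = []
        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
            for rec in vf:
                if rec.alts is None or len(rec.alts) != 1:
                    raise ValueError(f"panel record {rec.chrom}:{rec.pos} not biallelic")
                sites.append((rec.chrom, rec.pos - 1, rec.ref, rec.alts[0]))
                col: list[int] = []
                for s in samples:
                    call = rec.samples[s]
                    if not call.phased:
                        raise ValueError(
                            f"unphased panel genotype at {rec.chrom}:{rec.pos} ({s})"
                        )
                    col.extend(int(a) for a in call["GT"])
                columns.append(col)
        haps = np.array(columns, dtype=np.int8).T if columns else np.zeros(
            (2 * len(samples), 0), dtype=np.int8
        )
        return cls(sites=tuple(sites), haplotypes=haps, sample_ids=samples)


def exclude_samples(panel: PanelMatrix, excluded_ids: Iterable[str]) -> PanelMatrix:
    """Drop both haplotype rows of every excluded sample.

    Ids absent from the panel are warned about, not fatal; removing every
    sample is fatal because an empty panel cannot impute anything.
    """
    excluded = set(excluded_ids)
    missing = excluded - set(panel.sample_ids)
    for m in sorted(missing):
        logger.warning("exclude_samples: id %r not present in the panel", m)
    keep = [k for k, s in enumerate(panel.sample_ids) if s not in excluded]
    if not keep:
        raise ValueError("excluding these samples would leave an empty panel")
    rows = np.concatenate([[2 * k, 2 * k + 1] for k in keep])
    return replace(
        panel,
        haplotypes=panel.haplotypes[rows],
        sample_ids=[panel.sample_ids[k] for k in keep],
    )


# ---------------------------------------------------------------------------
# Built-in imputer


def _rough_by_site(rough: Iterable, panel_sites: Sequence[Site]):
    """Index rough calls by panel site; calls off the panel are counted and
    ignored. Returns (allele-sum target, weight) arrays over panel sites."""
    site_index = {s: j for j, s in enumerate(panel_sites)}
    target = np.full(len(panel_sites), -1, dtype=np.int8)  # -1 = no call
    weight = np.zeros(len(panel_sites))
    off_panel = 0
    for call in rough:
        site = (call.chrom, call.pos, call.ref_allele, call.alt_allele) \
            if hasattr(call, "ref_allele") else call.site
        j = site_index.get(site)
        if j is None:
            off_panel += 1
            continue
        g = call.genotype
        qual = call.qual if call.qual is not None else QUAL_WEIGHT_CAP
        target[j] = g[0] + g[1]  # binary multiset {g1,g2} is its sum
        weight[j] = min(float(qual), QUAL_WEIGHT_CAP)
    if off_panel:
        logger.info("impute: ignored %d rough calls at non-panel sites", off_panel)
    return target, weight


def impute_phased_genotypes(
    rough: Iterable,
    panel: PanelMatrix,
    chunk_size: int = 100,
) -> list[PhasedVariant]:
    """Impute a complete phased diploid over all panel sites.

    Sites are partitioned into consecutive chunks of ``chunk_size`` (per
    chromosome). Within a chunk every ordered pair of panel haplotypes is
    scored by weighted agreement with the rough calls — a rough genotype
    {g1,g2} agrees with pair (a,b) at a site iff the unordered allele pair
    matches (for binary alleles: equal allele sums); weight =
    ``min(qual, 50)``; sites without a call contribute 0 — and the best
    pair wins, ties broken toward the lowest (row, row) index pair.
    Adjacent chunks are stitched by choosing the orientation (keep/swap)
    that maximizes allele agreement between the paired rows over the 10
    sites flanking the junction on each side.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if panel.n_haplotypes < 2 or not panel.sites:
        raise ValueError("panel must carry at least two haplotypes and one site")

    target, weight = _rough_by_site(rough, panel.sites)
    H = panel.n_haplotypes
    haps = panel.haplotypes
    # pairsum[a, b, s] = allele sum of the ordered pair at site s
    pairsum = haps[:, None, :].astype(np.int16) + haps[None, :, :]

    out: list[PhasedVariant] = []
    # chunk within chromosomes so junction flanks never span a contig break
    chrom_bounds: list[tuple[int, int]] = []
    start = 0
    for j in range(1, len(panel.sites) + 1):
        if j == len(panel.sites) or panel.sites[j][0] != panel.sites[start][0]:
            chrom_bounds.append((start, j))
            start = j

    for cstart, cend in chrom_bounds:
        prev_pair: tuple[int, int] | None = None
        prev_chunk_end = cstart
        for lo in range(cstart, cend, chunk_size):
            hi = min(lo + chunk_size, cend)
            called = target[lo:hi] >= 0
            if called.any():
                agree = (pairsum[:, :, lo:hi] == target[lo:hi]) & called
                scores = (agree * weight[lo:hi]).sum(axis=2)
            else:
                scores = np.zeros((H, H))
            # the diploid is a pair of *distinct* panel rows (each sample
            # contributes two rows, so homozygous stretches are expressible
            # through identical row content); self-pairs are excluded
            np.fill_diagonal(scores, -1.0)
            best = np.unravel_index(int(np.argmax(scores)), scores.shape)
            a, b = int(best[0]), int(best[1])  # row-major argmax = lowest tie

            if prev_pair is not None:
                p1, p2 = prev_pair
                fl = list(range(max(prev_chunk_end - STITCH_FLANK, cstart),
                                prev_chunk_end)) + \
                     list(range(lo, min(lo + STITCH_FLANK, hi)))
                keep = int((haps[p1, fl] == haps[a, fl]).sum()
                           + (haps[p2, fl] == haps[b, fl]).sum())
                swap = int((haps[p1, fl] == haps[b, fl]).sum()
                           + (haps[p2, fl] == haps[a, fl]).sum())
                if swap > keep:
                    a, b = b, a
            for j in range(lo, hi):
                chrom, pos, ref, alt = panel.sites[j]
                out.append(PhasedVariant(chrom, pos, ref, alt,
                                         (int(haps[a, j]), int(haps[b, j]))))
            prev_pair = (a, b)
            prev_chunk_end = hi
    return out


# ---------------------------------------------------------------------------
# External-engine adapter


class ExternalImputerError(RuntimeError):
    """The external imputation command failed or produced invalid output."""

    def __init__(self, message: str, *, exit_status: int | None = None):
        super().__init__(message)
        self.exit_status = exit_status


def run_external_imputer(
    rough_vcf: str | Path,
    panel_vcf: str | Path,
    adapter_command: str,
    *,
    workdir: str | Path | None = None,
) -> list[PhasedVariant]:
    """Run an external imputation engine through a command template.

    ``adapter_command`` is a shell template with ``{rough}``, ``{panel}``
    and ``{out}`` placeholders. The adapter must write a phased VCF over
    the panel sites; unphased genotypes, unparseable output, or a nonzero
    exit each raise a distinct :class:`ExternalImputerError`.
    """
    workdir = Path(workdir) if workdir is not None else Path(rough_vcf).parent
    out_path = workdir / "imputed.external.vcf"
    cmd = adapter_command.format(
        rough=shlex.quote(str(rough_vcf)),
        panel=shlex.quote(str(panel_vcf)),
        out=shlex.quote(str(out_path)),
    )
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise ExternalImputerError(
            f"imputer adapter exited with status {proc.returncode}: "
            f"{proc.stderr.strip()[:500]}",
            exit_status=proc.returncode,
        )
    if not out_path.exists():
        raise ExternalImputerError(f"adapter produced no output at {out_path}")
    try:
        imputed = read_vcf(out_path, require_phased=True)
    except ValueError as exc:
        raise ExternalImputerError(f"invalid adapter output: {exc}") from exc
    panel_sites = {s for s in (v.site for v in read_vcf_sites(panel_vcf))}
    got_sites = {v.site for v in imputed}
    missing = panel_sites - got_sites
    if missing:
        raise ExternalImputerError(
            f"adapter output is missing {len(missing)} panel sites "
            f"(first: {sorted(missing)[0]})"
        )
    return imputed


def read_vcf_sites(path: str | Path) -> list[PhasedVariant]:
    """Panel sites as placeholder variants (first sample's GT, used only
    for site identity)."""
    return read_vcf(path)
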