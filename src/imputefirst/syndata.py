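"""Synthetic diploid truth sets, haplotype panels, and sequencing reads.

Everything downstream — genotyping, imputation, consensus construction,
liftover, and the evaluation statistics — is exercised end-to-end on data
from this module: a random reference, a phased diploid "donor" carrying
SNVs, small indels, and structural variants (>= 50 bp by the usual
convention), a panel of haplotypes related to the donor by a mosaic /
discordance process, and fixed-length error-bearing reads with truth
alignments so no external aligner is needed to run the pipeline.

Conventions (documented in docs/methods.md):

* ``coverage`` is per-haplotype fold coverage: each of the two haplotypes
  is sampled at ``coverage`` x, so the diploid genome yields about
  ``2 * coverage * ref_length`` sequenced bases in expectation.
* Reads are single-end, fixed-length, forward-strand, with substitution
  errors only.
* Variants never overlap on the reference (at least one unedited base
  separates consecutive variant spans), keeping consensus construction
  unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignments import AlignmentRecord, write_sam
from .imputer import PanelMatrix
from .variants import PhasedVariant, write_fasta, write_fastq, write_vcf

__all__ = ["SimConfig", "TruthSample", "simulate_truth", "simulate_panel",
           "simulate_reads", "write_dataset"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class DensityError(ValueError):
    """Requested variant density does not fit on the reference."""


@dataclass(frozen=True)
class SimConfig:
    """Experiment knobs for one synthetic dataset.

    Defaults describe the standard desk-scale condition: a 100 kb
    reference, human-like site spacing (one variant per ~450 bp), a
    mostly-heterozygous donor, a 20-haplotype panel a couple of percent
    discordant from the donor, and 30x Illumina-like reads (100 bp,
    0.1% substitution error). Coverage is the knob swept in experiments,
    from far below 1x (imputation rescues the calls) up to 30x.
    """

    ref_length: int = 100_000
    n_snv: int = 160
    n_indel: int = 60
    n_sv: int = 6
    het_fraction: float = 0.7
    indel_max: int = 10
    sv_min: int = 50
    panel_haplotypes: int = 20
    panel_discordance: float = 0.02
    recomb_rate: float = 1e-5
    coverage: float = 30.0
    read_length: int = 100
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {"n_snv": self.n_snv, "n_indel": self.n_indel, "n_sv": self.n_sv,
                  "ref_length": self.ref_length, "read_length": self.read_length,
                  "indel_max": self.indel_max, "panel_haplotypes": self.panel_haplotypes}
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name, p in {"het_fraction": self.het_fraction,
                        "panel_discordance": self.panel_discordance,
                        "recomb_rate": self.recomb_rate,
                        "error_rate": self.error_rate}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.sv_min < 50:
            raise ValueError(f"sv_min must be >= 50 (SV convention), got {self.sv_min}")
        if self.ref_length <= self.read_length:
            raise ValueError("ref_length must exceed read_length")
        if self.panel_haplotypes and (self.panel_haplotypes < 2 or self.panel_haplotypes % 2):
            raise ValueError("panel_haplotypes must be an even count >= 2")

    @property
    def n_variants(self) -> int:
        return self.n_snv + self.n_indel + self.n_sv


@dataclass(frozen=True)
class TruthSample:
    """A reference plus the phased diploid donor derived from it.

    Invariant: applying each variant's haplotype-h allele to ``reference``
    reproduces ``hap_sequences[h-1]`` exactly; variants are sorted by
    position and non-overlapping on the reference.
    """

    reference: str
    variants: tuple[PhasedVariant, ...]
    hap_sequences: tuple[str, str]

    @property
    def het_variants(self) -> tuple[PhasedVariant, ...]:
        return tuple(v for v in self.variants if v.is_het)


_CHROM = "ref"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _place_spans(rng: np.random.Generator, cfg: SimConfig,
                 spans: Sequence[int]) -> list[int]:
    """Place variant spans left-to-right with >= 1 unedited base between
    them and clear of both reference ends, randomizing the slack."""
    n = len(spans)
    if n == 0:
        return []
    margin = 1
    min_gap = 1
    need = sum(spans) + (n - 1) * min_gap + 2 * margin
    free = cfg.ref_length - need
    if free < 0:
        raise DensityError(
            f"{n} variants spanning {sum(spans)} bases (+ gaps) do not fit "
            f"on a {cfg.ref_length} base reference"
        )
    # pos_i = margin + sorted_slack_i + sum_{j<i}(span_j + min_gap)
    slack = np.sort(rng.integers(0, free + 1, size=n))
    positions: list[int] = []
    acc = 0
    for i, span in enumerate(spans):
        positions.append(margin + int(slack[i]) + acc)
        acc += span + min_gap
    return positions


def simulate_truth(cfg: SimConfig) -> TruthSample:
    """Draw a reference and a phased diploid donor.

    Exactly ``round(het_fraction * n_variants)`` variants are heterozygous
    (phase drawn uniformly); the remainder are homozygous-ALT. Deletions
    and insertions are VCF-style left-anchored. Deterministic per seed.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    reference = _random_seq(rng, cfg.ref_length)

    # Variant blueprint: (kind, length); span on the reference includes the
    # left anchor base for indels/SVs so placements cannot collide.
    kinds: list[tuple[str, int]] = [("snv", 1) for _ in range(cfg.n_snv)]
    for _ in range(cfg.n_indel):
        kinds.append(("indel", int(rng.integers(1, cfg.indel_max + 1))))
    for _ in range(cfg.n_sv):
        kinds.append(("sv", int(rng.integers(cfg.sv_min, cfg.sv_min + 51))))
    rng.shuffle(kinds)  # type: ignore[arg-type]

    is_insertion = rng.random(len(kinds)) < 0.5
    spans = []
    for (kind, length), ins in zip(kinds, is_insertion):
        if kind == "snv":
            spans.append(1)
        else:
            spans.append(1 if ins else length + 1)
    positions = _place_spans(rng, cfg, spans)

    n = len(kinds)
    n_het = round(cfg.het_fraction * n)
    het_mask = np.zeros(n, dtype=bool)
    het_mask[rng.permutation(n)[:n_het]] = True

    variants: list[PhasedVariant] = []
    for i, ((kind, length), pos) in enumerate(zip(kinds, positions)):
        anchor = reference[pos]
        if kind == "snv":
            alt_base = rng.choice([b for b in "ACGT" if b != anchor])
            ref_a, alt_a = anchor, str(alt_base)
        elif is_insertion[i]:
            ref_a, alt_a = anchor, anchor + _random_seq(rng, length)
        else:
            ref_a, alt_a = reference[pos : pos + length + 1], anchor
        if het_mask[i]:
            gt = (1, 0) if rng.random() < 0.5 else (0, 1)
        else:
            gt = (1, 1)
        variants.append(PhasedVariant(_CHROM, pos, ref_a, alt_a, gt))
    variants.sort(key=lambda v: v.pos)

    haps = tuple(_apply_alleles(reference, variants, h) for h in (1, 2))
    return TruthSample(reference, tuple(variants), haps)  # type: ignore[arg-type]


def _apply_alleles(reference: str, variants: Sequence[PhasedVariant], hap: int) -> str:
    """Independent left-to-right consensus used only by the simulator
    (the personalize module re-derives haplotypes with its own machinery)."""
    parts: list[str] = []
    cursor = 0
    for v in variants:
        if v.allele(hap) == 0:
            continue
        parts.append(reference[cursor : v.pos])
        parts.append(v.alt)
        cursor = v.pos + len(v.ref)
    parts.append(reference[cursor:])
    return "".join(parts)


# ---------------------------------------------------------------------------
# Panel


def simulate_panel(truth: TruthSample, cfg: SimConfig) -> PanelMatrix:
    """Build a phased multi-sample panel related to the truth diploid.

    Each panel haplotype is a mosaic of the two truth haplotypes: the
    source haplotype switches between consecutive sites with probability
    ``1 - (1 - recomb_rate)**distance``, and each copied allele is flipped
    with probability ``panel_discordance``. The first two rows source from
    truth haplotype 1 and 2 respectively, so the zero-noise panel always
    contains both truth haplotypes; remaining rows start from a random
    haplotype. Panel sites coincide with the truth sites.
    """
    if cfg.panel_haplotypes < 2:
        raise ValueError("panel_haplotypes must be >= 2")
    rng = np.random.default_rng([cfg.seed, 1])
    sites = [v.site for v in truth.variants]
    positions = np.array([v.pos for v in truth.variants])
    truth_alleles = np.array([[v.allele(1), v.allele(2)] for v in truth.variants],
                             dtype=np.int8)

    rows = np.empty((cfg.panel_haplotypes, len(sites)), dtype=np.int8)
    for k in range(cfg.panel_haplotypes):
        source = k if k < 2 else int(rng.integers(2))
        for j in range(len(sites)):
            if j > 0:
                dist = int(positions[j] - positions[j - 1])
                p_switch = 1.0 - (1.0 - cfg.recomb_rate) ** dist
                if rng.random() < p_switch:
                    source ^= 1
            allele = int(truth_alleles[j, source])
            if rng.random() < cfg.panel_discordance:
                allele ^= 1
            rows[k, j] = allele
    sample_ids = [f"panel{s}" for s in range(cfg.panel_haplotypes // 2)]
    return PanelMatrix(sites=tuple(sites), haplotypes=rows, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# Reads


def simulate_reads(
    truth: TruthSample, cfg: SimConfig
) -> tuple[list[tuple[str, str]], list[AlignmentRecord]]:
    """Sample fixed-length reads from both haplotypes with truth alignments.

    Per haplotype the read count is Poisson with mean
    ``coverage * hap_length / read_length``; starts are uniform. The truth
    SAM records haplotype of origin (``hap1``/``hap2``), 0-based start and
    an exact ``{L}M`` CIGAR against the source haplotype; the ``AS`` tag is
    ``read_length - 2 * n_errors`` (a match-bonus/mismatch-penalty score
    consistent with how reconciliation ranks candidates).
    """
    if cfg.coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng([cfg.seed, 2])
    reads: list[tuple[str, str]] = []
    records: list[AlignmentRecord] = []
    serial = 0
    for h, hap_seq in enumerate(truth.hap_sequences, start=1):
        if cfg.read_length > len(hap_seq):
            raise ValueError(
                f"read_length {cfg.read_length} exceeds haplotype {h} length "
                f"{len(hap_seq)}"
            )
        mean_reads = cfg.coverage * len(hap_seq) / cfg.read_length
        n_reads = int(rng.poisson(mean_reads))
        starts = rng.integers(0, len(hap_seq) - cfg.read_length + 1, size=n_reads)
        for start in np.sort(starts):
            start = int(start)
            seq = hap_seq[start : start + cfg.read_length]
            n_err = int(rng.binomial(cfg.read_length, cfg.error_rate))
            if n_err:
                seq_arr = list(seq)
                err_pos = rng.choice(cfg.read_length, size=n_err, replace=False)
                for p in err_pos:
                    seq_arr[p] = str(rng.choice([b for b in "ACGT" if b != seq_arr[p]]))
                seq = "".join(seq_arr)
            name = f"read{serial:06d}"
            serial += 1
            reads.append((name, seq))
            records.append(
                AlignmentRecord(
                    read_id=name,
                    target_name=f"hap{h}",
                    pos=start,
                    cigar=[("M", cfg.read_length)],
                    mapq=60,
                    align_score=cfg.read_length - 2 * n_err,
                    flags=0,
                    source_label=f"hap{h}",
                    seq=seq,
                )
            )
    return reads, records


# ---------------------------------------------------------------------------
# File emission


def write_dataset(outdir: str | Path, cfg: SimConfig) -> dict[str, Path]:
    """Generate one dataset and emit every artifact in standard formats.

    Writes ``ref.fa``, ``truth.vcf``, ``panel.vcf``, ``haps.fa``,
    ``reads.fq`` and ``truth.sam`` with the generation parameters echoed
    into the file headers. Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(cfg)
    panel = simulate_panel(truth, cfg)
    reads, truth_aln = simulate_reads(truth, cfg)

    params = [f"imputefirst-syndata {k}={v}" for k, v in vars(cfg).items()]
    coverage_note = ("imputefirst-syndata coverage convention: per-haplotype "
                     "fold coverage (each haplotype sampled at cfg.coverage)")
    paths = {
        "ref": outdir / "ref.fa",
        "truth_vcf": outdir / "truth.vcf",
        "panel_vcf": outdir / "panel.vcf",
        "haps": outdir / "haps.fa",
        "reads": outdir / "reads.fq",
        "truth_sam": outdir / "truth.sam",
    }
    write_fasta(paths["ref"], {_CHROM: truth.reference}, header_comments=params[:1])
    write_fasta(paths["haps"],
                {"hap1": truth.hap_sequences[0], "hap2": truth.hap_sequences[1]})
    write_vcf(paths["truth_vcf"], truth.variants,
              {_CHROM: len(truth.reference)}, sample="truth",
              header_comments=params)
    panel.to_vcf(paths["panel_vcf"], contigs={_CHROM: len(truth.reference)},
                 header_comments=params)
    write_fastq(paths["reads"], reads)
    write_sam(paths["truth_sam"], truth_aln,
              {f"hap{h}": len(s) for h, s in enumerate(truth.hap_sequences, 1)},
              header_comments=params + [coverage_note])
    return paths
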