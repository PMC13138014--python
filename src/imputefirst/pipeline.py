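"""Two-phase workflow orchestration: personalization, then downstream.

Phase A (personalization): subsample the reads, align them to the bare
reference, call rough genotypes, filter, impute a phased diploid against
the panel, and build the personalized diploid reference with chains.

Phase B (downstream): place the *full* read set on each personalized
haplotype, lift the alignments back to reference coordinates through the
chains, reconcile the per-read candidates, and evaluate: ALT/HET
confusion and precision/recall, pivot-window accuracy (for both the
rough and the imputed call set, so the gain from imputation is measured
by the run itself), allelic balance at HET sites, and a QUAL-threshold
ROC table.

The aligner slot is a command template; the default ``truth`` path
re-expresses the simulator's truth alignments through chains instead, so
no external aligner is required. Every run writes a JSON manifest
(parameters, seed, output digests, record counts); rerunning from the
same manifest reproduces byte-identical evaluation tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .alignments import AlignmentRecord, write_sam
from .aligners import BWA_TEMPLATE, align_with_command, reexpress_alignments
from .evalsuite import (ConfusionCounts, WindowStratumResult,
                        allele_alt_confusion, bias_length_bins,
                        build_pivot_windows, genotype_map, het_confusion,
                        prf_from_counts, qual_roc_table, site_allelic_balance,
                        window_accuracy)
from .genotyper import (DEFAULT_MAX_DEPTH, DEFAULT_MIN_QUAL, RoughCall,
                        call_rough_genotypes, filter_rough_calls,
                        pileup_from_alignments, write_rough_vcf)
from .imputer import (PanelMatrix, exclude_samples, impute_phased_genotypes,
                      run_external_imputer)
from .liftover import lift_alignment, reconcile_alignments, UNMAPPED_FLAG
from .personalize import (build_diploid_reference, write_diploid_reference)
from .syndata import SimConfig, simulate_panel, simulate_reads, simulate_truth
from .variants import (PhasedVariant, write_fasta, write_fastq, write_vcf)

__all__ = ["PipelineConfig", "PipelineResult", "subsample_reads", "run_pipeline"]

logger = logging.getLogger(__name__)

ROC_THRESHOLDS = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters for one end-to-end run.

    ``sim.coverage`` is the full downstream read depth;
    ``personalization_coverage`` is the depth used for rough genotyping
    (the subsample fraction is their ratio). ``aligner`` is either the
    literal ``"truth"`` or a shell template with ``{ref}``, ``{reads}``,
    ``{out}`` placeholders.
    """

    outdir: str
    sim: SimConfig = SimConfig()
    personalization_coverage: float = 5.0
    genotyper_error_rate: float = 0.01
    min_qual: float = DEFAULT_MIN_QUAL
    max_depth: int = DEFAULT_MAX_DEPTH
    chunk_size: int = 100
    excluded_samples: tuple[str, ...] = ()
    imputer_adapter: str | None = None
    aligner: str = "truth"
    window_bp: int = 200
    seed: int = 0
    input_dir: str | None = None  # pre-generated dataset instead of sim

    def __post_init__(self) -> None:
        if self.personalization_coverage <= 0:
            raise ValueError("personalization_coverage must be > 0")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")

    def validate_paths(self) -> None:
        """Fail before any stage if referenced inputs are missing."""
        if self.input_dir is not None:
            base = Path(self.input_dir)
            required = ["ref.fa", "truth.vcf", "panel.vcf", "reads.fq", "truth.sam"]
            missing = [f for f in required if not (base / f).exists()]
            if missing:
                raise FileNotFoundError(
                    f"input_dir {base} is missing {', '.join(missing)}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = SimConfig(**raw.pop("sim", {}))
        if "excluded_samples" in raw:
            raw["excluded_samples"] = tuple(raw["excluded_samples"])
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    run_dir: Path
    n_reads: int
    n_sampled: int
    n_rough_calls: int
    n_filtered_calls: int
    alt_confusion: ConfusionCounts
    het_confusion: ConfusionCounts
    window_imputed: list[WindowStratumResult]
    window_rough: list[WindowStratumResult]
    imputed_concordance: float
    mean_abs_bias: float | None
    n_mapped: int
    n_unmapped: int


def subsample_reads(
    reads: Sequence[tuple[str, str]], fraction: float, seed: int
) -> list[tuple[str, str]]:
    """Retain each read independently with probability ``fraction``,
    preserving order; deterministic per seed."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < fraction
    return [r for r, k in zip(reads, keep) if k]


def subsample_fastq(in_fq: str | Path, out_fq: str | Path,
                    fraction: float, seed: int) -> int:
    """File-level subsampling; returns the retained read count."""
    import pysam

    reads = [(e.name, e.sequence) for e in pysam.FastxFile(str(in_fq))]
    kept = subsample_reads(reads, fraction, seed)
    write_fastq(out_fq, kept)
    return len(kept)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    """Deterministic TSV emission (atomic: tmp + rename)."""
    def fmt(x) -> str:
        if x is None:
            return "NA"
        if isinstance(x, float):
            return f"{x:.6g}"
        return str(x)

    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text("\t".join(header) + "\n"
                   + "".join("\t".join(fmt(x) for x in row) + "\n" for row in rows))
    tmp.replace(path)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow; any stage failure halts the run naming
    the stage, and that stage's partial outputs are quarantined."""
    config.validate_paths()
    run_dir = Path(config.outdir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "imputefirst",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    stage_paths: list[Path] = []

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                stage_paths.clear()
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    for p in stage_paths:
                        if p.exists():
                            p.rename(p.with_suffix(p.suffix + ".quarantine"))
                    raise StageError(name, exc) from exc
                logger.info("stage %-12s %6.2fs", name,
                            time.perf_counter() - self.t0)
                return False

        return _Ctx()

    def out(name: str) -> Path:
        p = run_dir / name
        stage_paths.append(p)
        return p

    # -- inputs ------------------------------------------------------------
    with stage("syndata"):
        if config.input_dir is not None:
            from .variants import read_fasta, read_vcf
            from .alignments import read_sam
            import pysam

            base = Path(config.input_dir)
            reference = read_fasta(base / "ref.fa")
            truth_variants = read_vcf(base / "truth.vcf", require_phased=True)
            panel = PanelMatrix.from_vcf(base / "panel.vcf")
            reads = [(e.name, e.sequence)
                     for e in pysam.FastxFile(str(base / "reads.fq"))]
            truth_records = read_sam(base / "truth.sam")
        else:
            truth = simulate_truth(config.sim)
            panel = simulate_panel(truth, config.sim)
            reads, truth_records = simulate_reads(truth, config.sim)
            reference = {"ref": truth.reference}
            truth_variants = list(truth.variants)
        # provenance map of the truth diploid (chains truth-hap <-> ref),
        # used by the truth aligner path
        truth_dr = build_diploid_reference(reference, truth_variants)
        truth_chain_by_sam_name = {
            f"hap{h}": next(iter(truth_dr.chains(h).values())) for h in (1, 2)
        }
        ref_fa = out("ref.fa")
        write_fasta(ref_fa, reference)
        manifest["stages"]["syndata"] = {
            "n_reads": len(reads), "n_truth_variants": len(truth_variants),
            "panel_haplotypes": panel.n_haplotypes,
        }

    # -- phase A: personalization -----------------------------------------
    with stage("subsample"):
        fraction = min(config.personalization_coverage / config.sim.coverage, 1.0)
        sampled = subsample_reads(reads, fraction, seed=config.seed + 101)
        sampled_names = {n for n, _ in sampled}
        write_fastq(out("sampled.fq"), sampled)
        manifest["stages"]["subsample"] = {
            "fraction": fraction, "n_sampled": len(sampled)}

    with stage("rough_align"):
        if config.aligner == "truth":
            subset = [r for r in truth_records if r.read_id in sampled_names]
            rough_aln, _ = reexpress_alignments(
                subset, truth_chain_by_sam_name, label="ref")
        else:
            rough_aln = align_with_command(
                config.aligner, ref_fa, run_dir / "sampled.fq",
                out("rough_align.sam"), label="ref")
        write_sam(out("rough_align.sam"),
                  rough_aln, {c: len(s) for c, s in reference.items()})
        manifest["stages"]["rough_align"] = {"n_alignments": len(rough_aln)}

    with stage("genotype"):
        columns = pileup_from_alignments(rough_aln, reference)
        rough_calls = list(call_rough_genotypes(
            columns, reference, config.genotyper_error_rate))
        filtered = filter_rough_calls(rough_calls, config.min_qual,
                                      config.max_depth)
        contigs = {c: len(s) for c, s in reference.items()}
        write_rough_vcf(out("rough.vcf"), rough_calls, contigs)
        write_rough_vcf(out("filtered.vcf"), filtered, contigs)
        manifest["stages"]["genotype"] = {
            "n_rough": len(rough_calls), "n_filtered": len(filtered)}

    with stage("impute"):
        work_panel = panel
        if config.excluded_samples:
            work_panel = exclude_samples(panel, config.excluded_samples)
        if config.imputer_adapter is not None:
            panel_vcf = out("panel.used.vcf")
            work_panel.to_vcf(panel_vcf, contigs=contigs)
            imputed = run_external_imputer(
                run_dir / "filtered.vcf", panel_vcf, config.imputer_adapter,
                workdir=run_dir)
        else:
            imputed = impute_phased_genotypes(filtered, work_panel,
                                              config.chunk_size)
        write_vcf(out("imputed.vcf"), imputed, contigs, sample="imputed")
        manifest["stages"]["impute"] = {"n_imputed": len(imputed)}

    with stage("personalize"):
        pers = build_diploid_reference(
            reference, [v for v in imputed if v.genotype != (0, 0)])
        pers_paths = write_diploid_reference(pers, run_dir / "pers")
        for p in pers_paths.values():
            stage_paths.append(p)
        manifest["stages"]["personalize"] = {
            "hap_lengths": {n: len(s) for h in (1, 2)
                            for n, s in pers.haps(h).items()}}

    # -- phase B: downstream ----------------------------------------------
    with stage("downstream_align"):
        hap_alignments: dict[int, list[AlignmentRecord]] = {}
        for h in (1, 2):
            hap_name, hap_seq = next(iter(pers.haps(h).items()))
            hap_chain = pers.chains(h)[hap_name]
            if config.aligner == "truth":
                aln, _ = reexpress_alignments(
                    truth_records, truth_chain_by_sam_name,
                    target_chain=hap_chain, label=f"hap{h}",
                    target_seq=hap_seq)
            else:
                reads_fq = run_dir / "reads.full.fq"
                if not reads_fq.exists():
                    write_fastq(reads_fq, reads)
                aln = align_with_command(
                    config.aligner, pers_paths[f"hap{h}_fasta"], reads_fq,
                    out(f"aln_hap{h}.sam"), label=f"hap{h}")
            hap_alignments[h] = aln
        manifest["stages"]["downstream_align"] = {
            f"hap{h}": len(a) for h, a in hap_alignments.items()}

    with stage("lift"):
        candidates: dict[str, list] = defaultdict(list)
        for h in (1, 2):
            hap_name = next(iter(pers.haps(h)))
            chain = pers.chains(h)[hap_name]
            lifted: list[AlignmentRecord] = []
            for rec in hap_alignments[h]:
                if rec.is_unmapped:
                    continue
                if rec.target_name != chain.source_name:
                    rec = replace(rec, target_name=chain.source_name)
                res = lift_alignment(chain, rec)
                if res.record is not None:
                    lifted.append(res.record)
                    candidates[rec.read_id].append(res.record)
            write_sam(out(f"lifted_hap{h}.sam"), lifted,
                      {c: len(s) for c, s in reference.items()})
        manifest["stages"]["lift"] = {
            "n_liftable_reads": len(candidates)}

    with stage("reconcile"):
        reconciled: list[AlignmentRecord] = []
        for name, _seq in reads:
            cands = candidates.get(name)
            if cands:
                reconciled.append(reconcile_alignments(cands))
            else:
                reconciled.append(AlignmentRecord(
                    read_id=name, target_name="*", pos=-1, cigar=[],
                    mapq=0, align_score=0, flags=UNMAPPED_FLAG,
                    source_label="none"))
        n_unmapped = sum(r.is_unmapped for r in reconciled)
        n_mapped = len(reconciled) - n_unmapped
        assert n_mapped + n_unmapped == len(reads), "read conservation broken"
        write_sam(out("reconciled.sam"), reconciled,
                  {c: len(s) for c, s in reference.items()})
        manifest["stages"]["reconcile"] = {
            "mapped": n_mapped, "unmapped": n_unmapped}

    with stage("evaluate"):
        sites = list(panel.sites)
        truth_map = genotype_map(truth_variants)
        imputed_map = genotype_map(imputed)
        rough_map = {c.site: tuple(sorted(c.genotype)) for c in filtered}

        alt_cm = allele_alt_confusion(imputed_map, truth_map, sites)
        het_cm = het_confusion(imputed_map, truth_map, sites)
        alt_prf = prf_from_counts(alt_cm)
        het_prf = prf_from_counts(het_cm)
        rows = []
        for label, cm, prf in (("ALT", alt_cm, alt_prf), ("HET", het_cm, het_prf)):
            rows.append([label, cm.tp, cm.fp, cm.fn, cm.tn,
                         prf.precision, prf.recall, prf.f1])
        _write_tsv(out("genotype_eval.tsv"),
                   ["level", "tp", "fp", "fn", "tn", "precision", "recall", "f1"],
                   rows)

        windows = build_pivot_windows(sites, config.window_bp)
        win_imputed = window_accuracy(imputed_map, truth_map, windows)
        win_rough = window_accuracy(rough_map, truth_map, windows)
        _write_tsv(out("window_accuracy.tsv"),
                   ["callset", "stratum", "n_windows", "n_correct", "accuracy"],
                   [["imputed", w.stratum, w.n_windows, w.n_correct, w.accuracy]
                    for w in win_imputed]
                   + [["rough", w.stratum, w.n_windows, w.n_correct, w.accuracy]
                      for w in win_rough])

        het_truth = [v for v in truth_variants if v.is_het]
        balances, n_omitted = site_allelic_balance(reconciled, het_truth)
        bins = bias_length_bins(balances)
        _write_tsv(out("balance_bins.tsv"),
                   ["length", "mean_balance", "q25", "q75", "n"],
                   [[b.length_key, b.mean_balance, b.q25, b.q75, b.n_variants]
                    for b in bins])
        mean_abs_bias = (
            float(np.mean([abs(b.balance - 0.5) for b in balances]))
            if balances else None)

        rough_variants = [
            PhasedVariant(c.chrom, c.pos, c.ref_allele, c.alt_allele,
                          tuple(sorted(c.genotype)), phased=False,
                          qual=c.qual, depth=c.depth)
            for c in rough_calls if c.genotype != (0, 0)]
        truth_calls = [v for v in truth_variants if v.genotype != (0, 0)]
        roc = qual_roc_table(rough_variants, truth_calls, ROC_THRESHOLDS)
        _write_tsv(out("roc.tsv"),
                   ["threshold", "tp", "fp", "fn", "precision", "recall"],
                   [[r["threshold"], r["tp"], r["fp"], r["fn"],
                     r["precision"], r["recall"]] for r in roc])

        concord = sum(
            tuple(sorted(imputed_map.get(s, (0, 0))))
            == tuple(sorted(truth_map.get(s, (0, 0)))) for s in sites
        ) / len(sites) if sites else float("nan")
        manifest["stages"]["evaluate"] = {
            "n_sites": len(sites),
            "imputed_concordance": concord,
            "balance_sites_omitted": n_omitted,
        }

    for table in ("genotype_eval.tsv", "window_accuracy.tsv",
                  "balance_bins.tsv", "roc.tsv"):
        manifest["stages"].setdefault("digests", {})[table] = _sha256(
            run_dir / table)
    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        run_dir=run_dir,
        n_reads=len(reads),
        n_sampled=len(sampled),
        n_rough_calls=len(rough_calls),
        n_filtered_calls=len(filtered),
        alt_confusion=alt_cm,
        het_confusion=het_cm,
        window_imputed=win_imputed,
        window_rough=win_rough,
        imputed_concordance=concord,
        mean_abs_bias=mean_abs_bias,
        n_mapped=n_mapped,
        n_unmapped=n_unmapped,
    )
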