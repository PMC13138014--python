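# Methods

This note records the models, conventions, and design choices behind
`imputefirst`, in the order the pipeline runs them.

## Synthetic data model (`syndata`)

The generator emulates the minimal structure the method needs: a random
uniform-composition reference; a phased diploid donor with `n_snv` SNVs,
`n_indel` short indels (1 to `indel_max` bp) and `n_sv` structural variants
(insertions/deletions of `sv_min` to `sv_min`+50 bp, `sv_min` ≥ 50 by the
usual SV convention); a haplotype panel related to the donor; and
fixed-length single-end reads with independent substitution errors.

Key conventions:

* **Variant placement** is non-overlapping with at least one unedited base
  between variant spans and one base of margin at each reference end, with
  the slack distributed uniformly at random. Infeasible densities fail
  loudly naming the constraint.
* **Heterozygosity**: exactly `round(het_fraction · n)` variants are HET
  (phase uniform); the rest are homozygous-ALT. The default
  `het_fraction = 0.7` reflects that most variant sites in a human genome
  relative to a reference are heterozygous.
* **Panel model**: each panel haplotype copies one donor haplotype,
  switching source between consecutive sites with probability
  1 − (1 − `recomb_rate`)^distance and flipping each copied allele with
  probability `panel_discordance`. Rows 0 and 1 deterministically source
  from haplotypes 1 and 2, so a zero-noise panel always contains the truth
  pair — the lever used by imputation-recovery tests. Defaults
  (`panel_discordance = 0.02`, `recomb_rate = 10⁻⁵`/bp, 20 haplotypes)
  give a panel that is close to, but not identical with, the donor.
* **Coverage** means per-haplotype fold coverage: each haplotype receives
  Poisson(`coverage` · haplotype_length / `read_length`) reads, so the
  diploid genome is sequenced at 2 × `coverage`. The convention is echoed
  in the truth SAM header. Default reads are 100 bp at 0.1 % substitution
  error (Illumina-like); `coverage` is the experimental knob, swept from
  far below 1× (imputation-rescue regime) to 30×.
* Reads are forward-strand only, single-end, fixed-length, substitution
  errors only. Reverse strands, paired ends, and indel errors would add
  plumbing without exercising any computation this package is about.

What the generator does **not** emulate: sequencing-technology error
profiles (quality ramps, homopolymer errors), GC/coverage bias, repeats
and low-complexity sequence (the uniform-random reference is essentially
unmappable-ambiguity-free), multiallelic and nested variant records, and
population structure beyond the two-source mosaic. Consequently, passing
tests demonstrate the *mechanics* — coordinate bookkeeping, likelihoods,
accounting identities, and the qualitative bias/recovery effects — not
performance on real genomes, where repeat-induced mismapping and panel
mis-specification dominate.

## Rough genotyping (`genotyper`)

The pileup walks CIGARs: M/=/X bases contribute the read base at their
reference position; each I op contributes one `+SEQ` token and each D op
one `-LEN` token at the reference base immediately left of the event
(VCF-style left anchoring). Column depth is the sum of all contributions.
Indel tokens are only anchored when the read aligns the anchor base
itself; a read that *starts* inside an insertion carries no usable anchor.

The caller is a deliberately simple, replaceable stand-in behind a VCF
interface. Per column with non-reference evidence, support is aggregated
per category — any insertion token supports "insertion here" (the allele
string is taken from the best-supported token), likewise deletions, while
base substitutions stay per-base. This matters for long insertions: a
sequencing error inside the inserted sequence must not fragment the
evidence. With k ALT and r REF informative reads, genotype likelihoods
are binomial with per-read ALT probability `error_rate` (0/0), ½ (0/1),
and 1 − `error_rate` (1/1); the maximum-likelihood genotype is emitted
with `qual` = phred-scaled posterior error under a flat prior, capped at
99 to keep high-depth calls finite.

The record filter keeps calls with QUAL ≥ 20 and DP ≤ 100 — strictly
"below 20" and "exceeding 100" are removed, so both boundary values pass.
The filter reads the VCF `QUAL` column (the QUAL/DP attributes are
record-level, not a nonstandard INFO copy).

Limitation: SV insertions near or above the read length cannot have their
full allele sequence spanned by any read, so the called ALT string is
truncated even when the genotype class is correct. This is faithful to
short-read genotyping; recovering such alleles is precisely the
imputation stage's job.

## Imputation (`imputer`)

Production engines (Beagle, GLIMPSE) are consumed through an adapter
contract: a shell template with `{rough}`, `{panel}`, `{out}`
placeholders whose output must be a phased VCF covering all panel sites
(unphased genotypes, missing sites, or a nonzero exit each fail with a
distinct error).

The built-in imputer is a minimal, exhaustively-scored reference point,
O(H²·S) per chunk — fine for desk-scale panels, no PBWT machinery:

* Sites are chunked consecutively (`chunk_size` = 100 by default) within
  each chromosome.
* Every ordered pair of **distinct** panel rows is scored per chunk:
  a rough genotype {g₁,g₂} agrees with row pair (a,b) at a site iff the
  unordered allele pairs match — for biallelic sites, iff the allele sums
  are equal. Each agreement adds `min(qual, 50)`; the cap stops one
  overconfident call from dominating a chunk. Uncalled sites contribute 0.
* Self-pairs are excluded so a two-haplotype panel always returns that
  pair; homozygous stretches remain expressible because every sample
  contributes two rows. Ties break toward the lowest (row, row) pair, so
  an evidence-free chunk deterministically returns rows (0, 1).
* Adjacent chunks are stitched by choosing the orientation (keep or swap)
  that maximizes allele agreement between the paired rows over the 10
  sites flanking the junction on each side — a small-scale analogue of
  ligating windowed phased calls.

Panel hygiene: `exclude_samples` removes both haplotype rows of every
excluded sample id before imputation (imputing a donor against a panel
containing the donor or family gives unrealistically good results).
Relatedness is *not* inferred; exclusion takes an explicit id list.

## Personalization (`personalize`)

`plan_edits` turns phased calls into per-haplotype edit plans: one edit
per non-reference allele, REF alleles verified against the reference
(mismatch fails naming the locus), symbolic ALTs rejected, overlapping
records resolved leftmost-wins with a warning — a deterministic,
auditable substitute for upstream normalization whose behavior is
otherwise unspecified.

`apply_edits` builds the haplotype and its chain in one pass. Unedited
stretches extend the current match block; per edit, the shared left
anchor extends the match, a same-length residual is a substitution and
also extends the match (SNVs produce **no** chain gap — chains encode
coordinate shifts, not sequence identity), and otherwise the residual
lengths become the gap: `d_target` reference-only bases and `d_source`
haplotype-only bases at that junction.

Chain dialect: `chain <score> <sourceName> <sourceSize> + 0 <sourceSize>
<targetName> <targetSize> + 0 <targetSize> <id>` followed by
`size d_source d_target` triples and a bare terminal size — 0-based
half-open, `+` strand, source = personalized haplotype, target =
reference (lifting moves alignments *back* to reference coordinates).
The strict re-parser re-derives both sequence lengths from block
arithmetic; `invert_chain` swaps the roles. Haplotype sequences are named
`{contig}_hap{1,2}`.

## Liftover and reconciliation (`liftover`)

`lift_position` maps match-block positions by offset arithmetic and
returns an inside-insertion marker (with the flanking reference
coordinate) for haplotype-only positions.

`lift_alignment` rewrites CIGARs by streaming the read's
haplotype-consuming ops through the chain decomposition: match overlap
stays M, haplotype-insertion overlap becomes I (soft-clip-free, so allele
evidence survives for the balance measurement), and interior crossings of
reference-only runs gain D. Read-side I/S ops pass through; read-side D
ops over haplotype insertions vanish (those bases do not exist on the
reference). At a junction carrying both gap kinds, I is emitted before D.
Leading/trailing D ops are trimmed and the start position is the first
match base's image. Query-consuming length is asserted unchanged on every
record. Reads fully inside an insertion are unliftable and surface as
unmapped records rather than disappearing, keeping read counts auditable.

`reconcile_alignments` orders candidates by mapping quality, then
alignment score, then source label (hap1 < hap2 < rescue), then
coordinates — a total order, so the choice is deterministic and
permutation-invariant. MAPQ precedes score because that is the natural
reading of ranking "based on mapping quality and alignment score".

## Evaluation (`evalsuite`)

The site universe is the panel's polymorphic sites; calls or truth
missing at a site count as homozygous REF — the only closure that keeps
the accounting totals fixed (allele-level totals = 2·|sites|, HET totals
= |sites|, asserted on every run).

* **ALT accounting** (per allele call): ALT call with ≥ 1 true ALT → TP;
  REF call with ≥ 1 true REF → TN; ALT against hom-REF truth → FP; REF
  against hom-ALT truth → FN.
* **HET accounting** (per site): called HET and truly HET → TP; the other
  three cells accordingly.
* **Windows**: per-window label orientation (identity or swap applied to
  all member sites) — haplotype labels are globally arbitrary, and
  whether the original comparison fixed one global orientation is not
  determinable; per-window orientation is the implemented and documented
  interpretation.
* **Allelic balance**: reads are classified at a HET site by direct
  base/CIGAR comparison (SNV: base match at the locus; insertion: an I op
  of the right length at the anchor junction; deletion: a D op covering
  the deleted interval; REF support requires spanning the locus with M
  and no indel). Uninformative reads are excluded from the denominator;
  sites with no informative reads are omitted with a count. This is a
  simplified substitute for context-aware read assignment: it will call
  a read uninformative where a realigner might still rescue it, which is
  conservative for both routes being compared.
* **Length bins**: key = clamp(len(ALT) − len(REF), ±30); per bin the
  mean, 25th/75th percentiles (linear interpolation between order
  statistics, fixed for reproducibility), and count.
* **ROC table**: calls kept at QUAL ≥ t per threshold; truth matching is
  exact (site identity + unordered genotype). Without a negative-site
  universe an FPR denominator is undefined, so the table reports counts
  and precision/recall, with TPR = recall; the axis choice is left to
  plotting.

## Pipeline (`pipeline`, `bias`, CLI)

Stages run in order — subsample → align (reference) → genotype → filter →
impute → personalize → align (haplotypes) → lift → reconcile → evaluate —
each writing standard-format files into the run directory plus a JSON
manifest (parameters, seed, record counts, table digests). A stage
failure halts the run naming the stage and renames that stage's partial
outputs to `*.quarantine`. Two runs from the same configuration produce
byte-identical evaluation tables (TSVs are emitted with fixed float
formatting and no timestamps).

The aligner slot is a command template with `{ref}`, `{reads}`, `{out}`.
The default `truth` path needs no aligner: the simulator's truth
alignments are re-expressed through chains — truth haplotype → reference
via the truth-call chains, then reference → personalized haplotype via
the inverted personalization chain — and rescored against the destination
sequence (match +1, mismatch −2, gap −3 −1/bp) so reconciliation has a
meaningful key. The reference-bias experiment (`bias` module) instead
runs a real aligner (BWA-MEM, single-threaded for determinism) for both
routes, because truth alignments are bias-free by construction and would
show nothing.

Subsampling retains each read independently with probability `fraction`
(order preserved, seeded), matching how coverage titration is normally
done.

## Problem sizes

Defaults and test sizes are desk-scale by design: references of 10–100 kb,
hundreds of variant sites, panels of 20 haplotypes, coverages of 0.1–30×.
The test suite and the acceptance script each complete in well under a
minute on one CPU. At these sizes every stochastic check uses explicit
tolerance arithmetic (3 binomial/Poisson standard deviations) or
aggregates over seeded replicates.

## Known limitations

* Biallelic, sequence-resolved records only; multiallelic or symbolic
  alleles are rejected rather than decomposed.
* The built-in imputer has no recombination penalty or genetic map; it is
  a correctness reference, not a performance proxy for HMM/PBWT engines.
* Single-contig orchestration in the pipeline (the library modules are
  multi-contig capable).
* The truth-alignment path sidesteps mapping ambiguity entirely; any
  conclusion about aligner behavior must come from the external-aligner
  path.
* Balance classification requires exact indel length/placement agreement
  after liftover; aligners that left-shift indels differently than the
  chain junctions may lose some informative reads.
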