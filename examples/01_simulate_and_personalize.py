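"""Simulate a diploid donor and build its personalized reference.

Generates a 50 kb reference with SNVs, indels and SVs, then substitutes
the phased alleles back into the reference to obtain the two
haplotype-specific sequences plus chain files describing the coordinate
shifts. The haplotypes rebuilt from the truth VCF must equal the
simulator's haplotypes byte for byte — the consensus round trip.
"""

from imputefirst.personalize import build_diploid_reference
from imputefirst.syndata import SimConfig, simulate_truth

cfg = SimConfig(ref_length=50_000, n_snv=80, n_indel=30, n_sv=4, seed=1)
truth = simulate_truth(cfg)
print(f"reference: {len(truth.reference)} bp, "
      f"{len(truth.variants)} variants "
      f"({sum(v.is_het for v in truth.variants)} HET)")

diploid = build_diploid_reference({"ref": truth.reference},
                                  list(truth.variants))
for h in (1, 2):
    hap = diploid.haps(h)[f"ref_hap{h}"]
    chain = diploid.chains(h)[f"ref_hap{h}"]
    exact = hap == truth.hap_sequences[h - 1]
    print(f"haplotype {h}: {len(hap)} bp "
          f"({len(hap) - len(truth.reference):+d} vs reference), "
          f"{len(chain.blocks)} chain blocks, round-trip exact: {exact}")

# Each chain block pairs a run of haplotype bases with reference bases;
# the gaps between blocks are exactly the applied indels.
b = diploid.chain1["ref_hap1"].blocks[0]
print(f"first chain block: {b.size} matched bases, then "
      f"{b.d_source} haplotype-only / {b.d_target} reference-only bases")
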