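"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive expectations by construction
bookkeeping (per-base provenance, brute-force counting) rather than by
calling the code paths they check.
"""

from __future__ import annotations

import pytest

from imputefirst.syndata import SimConfig, simulate_truth
from imputefirst.variants import PhasedVariant


def provenance_map(reference: str, variants, hap: int) -> list[int | None]:
    """Per-base provenance oracle: for each haplotype position, the
    reference position it descends from, or ``None`` for inserted bases.

    Built by walking the edits directly: unedited bases map one-to-one;
    a same-length substitution maps positionally; otherwise the shared
    left anchor maps positionally and the residual replacement bases are
    insertions. Independent of the chain machinery.
    """
    out: list[int | None] = []
    cursor = 0
    for v in sorted(variants, key=lambda v: v.pos):
        if v.allele(hap) == 0:
            continue
        out.extend(range(cursor, v.pos))
        if len(v.ref) == len(v.alt):
            out.extend(range(v.pos, v.pos + len(v.alt)))
        else:
            cp = 0
            for a, b in zip(v.ref, v.alt):
                if a != b:
                    break
                cp += 1
            out.extend(range(v.pos, v.pos + cp))
            out.extend([None] * (len(v.alt) - cp))
        cursor = v.pos + len(v.ref)
    out.extend(range(cursor, len(reference)))
    return out


def make_variant(pos: int, ref: str, alt: str, gt=(1, 0), chrom: str = "ref",
                 **kw) -> PhasedVariant:
    return PhasedVariant(chrom, pos, ref, alt, tuple(gt), **kw)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(ref_length=20_000, n_snv=40, n_indel=15, n_sv=2,
                     coverage=10.0, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return simulate_truth(small_cfg)
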