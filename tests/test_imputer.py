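"""Panel hygiene, built-in pair-scoring imputation, external adapter."""

from __future__ import annotations

import numpy as np
import pytest

from imputefirst.genotyper import RoughCall
from imputefirst.imputer import (ExternalImputerError, PanelMatrix,
                                 exclude_samples, impute_phased_genotypes,
                                 run_external_imputer)
from imputefirst.syndata import SimConfig, simulate_panel, simulate_truth
from imputefirst.variants import write_vcf


def make_panel(rows, sites=None, n_samples=None):
    rows = np.asarray(rows, dtype=np.int8)
    n_sites = rows.shape[1]
    sites = sites or tuple(("ref", 10 * (j + 1), "A", "C") for j in range(n_sites))
    n_samples = n_samples or rows.shape[0] // 2
    return PanelMatrix(sites=tuple(sites), haplotypes=rows,
                       sample_ids=[f"s{k}" for k in range(n_samples)])


class TestExcludeSamples:
    def test_removes_both_rows(self):
        panel = make_panel(np.zeros((6, 4)))
        out = exclude_samples(panel, ["s1"])
        assert out.haplotypes.shape == (4, 4)
        assert out.sample_ids == ["s0", "s2"]

    def test_absent_id_warns_not_fails(self, caplog):
        panel = make_panel(np.zeros((4, 3)))
        with caplog.at_level("WARNING"):
            out = exclude_samples(panel, ["ghost"])
        assert out.haplotypes.shape == (4, 3)
        assert any("ghost" in r.message for r in caplog.records)

    def test_excluding_all_fails(self):
        panel = make_panel(np.zeros((4, 3)))
        with pytest.raises(ValueError, match="empty panel"):
            exclude_samples(panel, ["s0", "s1"])

    def test_row_identity_removed(self):
        """The excluded sample's exact haplotype rows are gone — the
        testable form of the no-leakage requirement."""
        rng = np.random.default_rng(1)
        rows = rng.integers(0, 2, size=(8, 20)).astype(np.int8)
        rows[2] = 1  # distinctive rows for sample s1
        rows[3] = 0
        panel = make_panel(rows)
        out = exclude_samples(panel, ["s1"])
        assert not any((r == rows[2]).all() or (r == rows[3]).all()
                       for r in out.haplotypes)


def rough(site, gt, qual=50.0):
    chrom, pos, ref, alt = site
    return RoughCall(chrom, pos, ref, alt, gt, qual, 10)


class TestBuiltinImputer:
    def test_truth_pair_recovery_is_exact(self):
        """With the truth pair in the panel and error-free rough calls at
        20% of sites, the imputed diploid equals truth everywhere; a
        brute-force scoring oracle confirms the truth pair uniquely
        maximizes agreement."""
        # discordance high enough that no other panel row shadows the
        # truth haplotypes on the scored-site subset (identifiability)
        cfg = SimConfig(ref_length=10_000, n_snv=200, n_indel=0, n_sv=0,
                        panel_haplotypes=20, panel_discordance=0.2,
                        recomb_rate=1e-4, seed=13)
        truth = simulate_truth(cfg)
        panel = simulate_panel(truth, cfg)
        # plant the exact truth pair as rows 0/1 (discordance noised them)
        truth_rows = np.array([[v.allele(h) for v in truth.variants]
                               for h in (1, 2)], dtype=np.int8)
        haps = panel.haplotypes.copy()
        haps[0], haps[1] = truth_rows[0], truth_rows[1]
        panel = PanelMatrix(panel.sites, haps, panel.sample_ids)

        rng = np.random.default_rng(13)
        chosen = rng.permutation(len(panel.sites))[:40]  # 20% of 200
        calls = [rough(panel.sites[j], tuple(sorted(truth_rows[:, j])))
                 for j in sorted(chosen)]

        # brute-force oracle: exhaustive pair scores over all sites
        target = {panel.sites[j]: truth_rows[0, j] + truth_rows[1, j]
                  for j in sorted(chosen)}
        H = haps.shape[0]
        scores = np.zeros((H, H))
        for a in range(H):
            for b in range(H):
                if a == b:
                    continue
                scores[a, b] = sum(
                    50.0 for j, s in enumerate(panel.sites)
                    if s in target and haps[a, j] + haps[b, j] == target[s])
        best = scores.max()
        winners = {frozenset(p) for p in zip(*np.where(scores == best))}
        assert winners == {frozenset({0, 1})}  # truth pair uniquely optimal

        imputed = impute_phased_genotypes(calls, panel, chunk_size=100)
        got = {v.site: tuple(sorted(v.genotype)) for v in imputed}
        want = {v.site: tuple(sorted(v.genotype)) for v in truth.variants}
        assert got == want

    def test_no_rough_calls_lowest_pair(self):
        rng = np.random.default_rng(2)
        panel = make_panel(rng.integers(0, 2, size=(6, 10)).astype(np.int8))
        imputed = impute_phased_genotypes([], panel, chunk_size=5)
        for j, v in enumerate(imputed):
            assert v.genotype == (int(panel.haplotypes[0, j]),
                                  int(panel.haplotypes[1, j]))

    def test_two_haplotype_panel_returns_that_pair(self):
        panel = make_panel([[1, 1, 1, 0], [0, 0, 1, 1]])
        calls = [rough(panel.sites[0], (1, 1))]  # would favour a self-pair
        imputed = impute_phased_genotypes(calls, panel, chunk_size=10)
        got = [tuple(v.genotype) for v in imputed]
        assert got in ([(1, 0), (1, 0), (1, 1), (0, 1)],
                       [(0, 1), (0, 1), (1, 1), (1, 0)])

    def test_completeness(self):
        rng = np.random.default_rng(3)
        panel = make_panel(rng.integers(0, 2, size=(8, 57)).astype(np.int8))
        imputed = impute_phased_genotypes([], panel, chunk_size=10)
        assert len(imputed) == 57
        assert [v.site for v in imputed] == list(panel.sites)
        assert all(v.phased for v in imputed)

    def test_chunk_size_validation(self):
        panel = make_panel(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            impute_phased_genotypes([], panel, chunk_size=0)

    def _replicate_concordance(self, seed, density):
        cfg = SimConfig(ref_length=10_000, n_snv=200, n_indel=0, n_sv=0,
                        panel_haplotypes=20, panel_discordance=0.0,
                        recomb_rate=1e-4, seed=seed)
        truth = simulate_truth(cfg)
        panel = simulate_panel(truth, cfg)
        truth_gts = {v.site: tuple(sorted(v.genotype)) for v in truth.variants}
        rng = np.random.default_rng(seed + 1000)
        chosen = rng.permutation(len(panel.sites))[
            : int(density * len(panel.sites))]
        calls = [rough(panel.sites[j],
                       tuple(sorted(truth.variants[j].genotype)))
                 for j in sorted(chosen)]
        imputed = impute_phased_genotypes(calls, panel, chunk_size=100)
        got = {v.site: tuple(sorted(v.genotype)) for v in imputed}
        return np.mean([got[s] == truth_gts[s] for s in truth_gts])

    def test_concordance_nondecreasing_in_density(self):
        for seed in (31, 32, 33):
            concs = [self._replicate_concordance(seed, d)
                     for d in (0.01, 0.1, 0.5)]
            assert concs == sorted(concs)


class TestExternalAdapter:
    def _setup(self, tmp_path, truth, cfg):
        panel = simulate_panel(truth, cfg)
        rough_vcf = tmp_path / "rough.vcf"
        panel_vcf = tmp_path / "panel.vcf"
        write_vcf(rough_vcf, truth.variants[:5],
                  {"ref": cfg.ref_length}, sample="rough")
        panel.to_vcf(panel_vcf, contigs={"ref": cfg.ref_length})
        return panel, rough_vcf, panel_vcf

    def test_identity_adapter(self, tmp_path, small_truth, small_cfg):
        _, rough_vcf, panel_vcf = self._setup(tmp_path, small_truth, small_cfg)
        good = tmp_path / "good.vcf"
        write_vcf(good, small_truth.variants, {"ref": small_cfg.ref_length})
        imputed = run_external_imputer(
            rough_vcf, panel_vcf, f"cp {good} {{out}}", workdir=tmp_path)
        assert [(v.site, v.genotype) for v in imputed] == \
            [(v.site, v.genotype) for v in small_truth.variants]

    def test_unphased_output_fails(self, tmp_path, small_truth, small_cfg):
        _, rough_vcf, panel_vcf = self._setup(tmp_path, small_truth, small_cfg)
        bad = tmp_path / "bad.vcf"
        from dataclasses import replace

        write_vcf(bad, [replace(v, phased=False) for v in small_truth.variants],
                  {"ref": small_cfg.ref_length})
        with pytest.raises(ExternalImputerError, match="[Uu]nphased"):
            run_external_imputer(rough_vcf, panel_vcf,
                                 f"cp {bad} {{out}}", workdir=tmp_path)

    def test_nonzero_exit_carries_status(self, tmp_path, small_truth, small_cfg):
        _, rough_vcf, panel_vcf = self._setup(tmp_path, small_truth, small_cfg)
        with pytest.raises(ExternalImputerError) as exc:
            run_external_imputer(rough_vcf, panel_vcf, "exit 3",
                                 workdir=tmp_path)
        assert exc.value.exit_status == 3

    def test_missing_panel_sites_fail(self, tmp_path, small_truth, small_cfg):
        _, rough_vcf, panel_vcf = self._setup(tmp_path, small_truth, small_cfg)
        partial = tmp_path / "partial.vcf"
        write_vcf(partial, small_truth.variants[:3],
                  {"ref": small_cfg.ref_length})
        with pytest.raises(ExternalImputerError, match="missing"):
            run_external_imputer(rough_vcf, panel_vcf,
                                 f"cp {partial} {{out}}", workdir=tmp_path)
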