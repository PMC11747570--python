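"""Generators: exact set sizes, determinism, and planted structure."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import pearsonr

from vaxtope.categorize import categorize_variants
from vaxtope.elispot_stats import magnitude
from vaxtope.synthetic_data import (
    ConfigError,
    SimulationConfig,
    simulate_elispot,
    simulate_expression,
    simulate_hla_alleles,
    simulate_proteins,
    simulate_variant_sets,
)


class TestVariantSets:
    def test_high_burden_scenario_reproduces_category_counts(self):
        """A 9652-variant vaccine set sharing 19.5% with the tumor splits
        into 7770 vaccine-only and 1882 shared variants."""
        cfg = SimulationConfig(
            seed=7, n_vaccine_variants=9652, tv_fraction=0.195, n_tumor_private=1591
        )
        vaccine, germline, tumor = simulate_variant_sets(cfg)
        table = categorize_variants(vaccine, germline, tumor)
        assert table.counts == {"V": 7770, "TV": 1882, "T": 1591}

    def test_zero_fraction_gives_empty_tv(self):
        cfg = SimulationConfig(seed=1, n_vaccine_variants=50, tv_fraction=0.0, n_tumor_private=5)
        table = categorize_variants(*simulate_variant_sets(cfg))
        assert table.counts == {"V": 50, "TV": 0, "T": 5}

    def test_same_seed_reproduces_identical_lists(self):
        cfg = SimulationConfig(seed=3, n_vaccine_variants=30, n_tumor_private=5)
        assert simulate_variant_sets(cfg) == simulate_variant_sets(cfg)

    def test_exact_counts_for_random_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(10, 400))
            frac = float(rng.uniform(0, 1))
            cfg = SimulationConfig(
                seed=int(rng.integers(1000)),
                n_vaccine_variants=n,
                tv_fraction=frac,
                n_tumor_private=int(rng.integers(0, 50)),
            )
            vaccine, germline, tumor = simulate_variant_sets(cfg)
            germ = {v.genomic_key for v in germline}
            vac = {v.genomic_key for v in vaccine} - germ
            tum = {v.genomic_key for v in tumor} - germ
            assert len(vac) == n
            assert len(vac & tum) == round(frac * n)
            assert len(tum - vac) == cfg.n_tumor_private

    def test_invalid_fraction_is_config_error(self):
        with pytest.raises(ConfigError):
            SimulationConfig(tv_fraction=1.5)


class TestExpression:
    def test_combined_sums_to_one_million(self):
        cfg = SimulationConfig(seed=5)
        profile = simulate_expression(cfg, [f"G{i}" for i in range(100)])
        assert sum(profile.combined_tpm.values()) == pytest.approx(1e6, rel=1e-6)

    def test_single_gene_takes_all_mass(self):
        profile = simulate_expression(SimulationConfig(seed=5), ["ONLY"])
        assert profile.combined_tpm["ONLY"] == pytest.approx(1e6)

    def test_seeded_reproducibility(self):
        cfg = SimulationConfig(seed=11)
        genes = ["A", "B", "C"]
        assert (
            simulate_expression(cfg, genes).combined_tpm
            == simulate_expression(cfg, genes).combined_tpm
        )

    def test_empty_gene_list_errors(self):
        with pytest.raises(ConfigError):
            simulate_expression(SimulationConfig(), [])


class TestELISpot:
    def _peptides(self, cfg, n, seed=99):
        rng = np.random.default_rng(seed)
        tpms = rng.lognormal(cfg.tpm_log_mean, cfg.tpm_log_sd, size=n)
        return [(f"PEP{i:04d}A", float(t)) for i, t in enumerate(tpms)]

    def test_null_effect_correlation_within_null_band(self):
        cfg = SimulationConfig(seed=21, elispot_effect_corr=0.0)
        peptides = self._peptides(cfg, 200)
        assays = simulate_elispot(cfg, peptides)
        mags = [magnitude(a) for a in assays]
        r, _ = pearsonr(np.log1p([t for _, t in peptides]), mags)
        assert abs(r) < 1.96 / np.sqrt(200 - 3)  # Fisher-z null band

    def test_planted_correlation_recovered_within_fisher_band(self):
        cfg = SimulationConfig(seed=22, elispot_effect_corr=0.2)
        peptides = self._peptides(cfg, 200)
        assays = simulate_elispot(cfg, peptides)
        mags = [magnitude(a) for a in assays]
        r, _ = pearsonr(np.log1p([t for _, t in peptides]), mags)
        assert 0.0615 < r < 0.334  # 95% interval around rho=0.2 at n=200

    def test_zero_control_mean_gives_all_zero_control_wells(self):
        cfg = SimulationConfig(seed=23, elispot_ctrl_mean=0.0)
        assays = simulate_elispot(cfg, self._peptides(cfg, 10))
        assert all(c == 0 for a in assays for c in a.ctrl_counts)

    def test_non_immunogenic_peptides_get_no_effect(self):
        cfg = SimulationConfig(seed=24)
        peptides = self._peptides(cfg, 300)
        assays = simulate_elispot(cfg, peptides, immunogenic=[False] * 300)
        mags = np.array([magnitude(a) for a in assays])
        assert abs(mags.mean()) < 3  # stim and ctrl share one distribution


class TestHLA:
    def test_homozygous_patient_has_duplicate_slots(self):
        cfg = SimulationConfig(seed=31, homozygous_class_I=True)
        _, haplotype, _ = simulate_hla_alleles(cfg)
        assert len(haplotype.class_I) == 6
        assert len(set(haplotype.class_I)) == 3

    def test_heterozygous_patient_has_six_distinct_slots(self):
        cfg = SimulationConfig(seed=31, homozygous_class_I=False)
        _, haplotype, _ = simulate_hla_alleles(cfg)
        assert len(set(haplotype.class_I)) == 6

    def test_proteins_are_consistent_with_variants(self):
        cfg = SimulationConfig(seed=41, n_vaccine_variants=20, n_tumor_private=0)
        vaccine, _, _ = simulate_variant_sets(cfg)
        proteins = simulate_proteins(vaccine, cfg)
        for v in vaccine:
            protein = proteins[v.transcript]
            if v.ref_aa:
                assert (
                    protein[v.protein_pos - 1 : v.protein_pos - 1 + len(v.ref_aa)]
                    == v.ref_aa
                )
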