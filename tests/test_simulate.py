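"""Synthetic cohort generator: determinism, bookkeeping, calibration."""

import numpy as np
import pytest

from homburden import CohortConfig, generate_cohort
from homburden.simulate import ConfigError


class TestDeterminism:
    def test_fixed_seed_bit_identical(self):
        cfg = CohortConfig(
            n_cases=50, n_controls=60, n_genes=80, target_set_size=10, seed=42
        )
        m1, t1 = generate_cohort(cfg)
        m2, t2 = generate_cohort(cfg)
        assert m1.equals(m2)
        assert t1.target_genes == t2.target_genes
        assert t1.planted_calls == t2.planted_calls

    def test_different_seeds_differ(self):
        base = dict(n_cases=50, n_controls=60, n_genes=80, target_set_size=10)
        m1, _ = generate_cohort(CohortConfig(seed=1, **base))
        m2, _ = generate_cohort(CohortConfig(seed=2, **base))
        assert not np.array_equal(m1.geno, m2.geno)


class TestPlanting:
    def test_planted_carriers_recoverable_before_qc(self):
        cfg = CohortConfig(
            n_cases=200,
            n_controls=200,
            n_genes=300,
            target_set_size=30,
            planted_case_hom_excess=6,
            seed=5,
        )
        matrix, truth = generate_cohort(cfg)
        target = set(truth.target_genes)
        in_target = matrix.variants["gene"].isin(target).to_numpy()
        hom_case = (matrix.geno[in_target][:, matrix.is_case] == 2).any(axis=0)
        assert hom_case.sum() >= 6
        assert len(truth.planted_case_carriers) == 6
        assert truth.planted_control_carriers == []
        # planted carriers are real subjects, all cases
        ids = set(matrix.subject_ids[matrix.is_case])
        assert set(truth.planted_case_carriers) <= ids
        # planted calls are clean hom-alt with high GQ
        for v, s in truth.planted_calls:
            assert matrix.geno[v, s] == 2
            assert matrix.gq[v, s] >= 20
            assert matrix.ref_reads[v, s] == 0
            assert matrix.variants.at[v, "gene"] in target

    def test_plants_sit_at_ultra_rare_sites(self):
        cfg = CohortConfig(
            n_cases=100,
            n_controls=100,
            n_genes=200,
            target_set_size=20,
            planted_case_hom_excess=3,
            seed=9,
        )
        _, truth = generate_cohort(cfg)
        for v, _ in truth.planted_calls:
            assert truth.true_freqs[v] < cfg.plant_max_freq


class TestSpectrum:
    def test_zero_frequency_gives_all_reference(self):
        cfg = CohortConfig(
            n_cases=30,
            n_controls=30,
            n_genes=40,
            target_set_size=5,
            maf_spectrum={"kind": "fixed", "value": 0.0},
            seed=0,
        )
        matrix, _ = generate_cohort(cfg)
        assert (matrix.geno == 0).all()

    def test_observed_frequency_converges(self):
        """Observed alt frequencies approach configured ones as 1/sqrt(n)."""
        f = 0.3
        for n in (100, 1000):
            cfg = CohortConfig(
                n_cases=n,
                n_controls=n,
                n_genes=20,
                target_set_size=5,
                variants_per_gene=5.0,
                maf_spectrum={"kind": "fixed", "value": f},
                seed=3,
            )
            matrix, _ = generate_cohort(cfg)
            obs = matrix.geno.mean(axis=1) / 2
            se = np.sqrt(f * (1 - f) / (2 * 2 * n))
            assert np.abs(obs - f).max() < 5 * se

    def test_loguniform_places_mass_below_ultrarare(self):
        cfg = CohortConfig(
            n_cases=10, n_controls=10, n_genes=500, target_set_size=5, seed=1
        )
        _, truth = generate_cohort(cfg)
        assert (truth.true_freqs < 1e-3).mean() > 0.2


class TestArtefacts:
    def test_contamination_rate_matches_config(self):
        cfg = CohortConfig(
            n_cases=400,
            n_controls=400,
            n_genes=200,
            target_set_size=10,
            maf_spectrum={"kind": "fixed", "value": 0.3},  # many hom calls
            contamination_rate=0.05,
            seed=13,
        )
        matrix, truth = generate_cohort(cfg)
        hom = matrix.geno == 2
        total = matrix.ref_reads + matrix.alt_reads
        contaminated = hom & (total > 0) & (matrix.ref_reads / np.maximum(total, 1) > 0.05)
        n_hom = hom.sum()
        rate = contaminated.sum() / n_hom
        se = np.sqrt(0.05 * 0.95 / n_hom)
        assert abs(rate - 0.05) < 4 * se
        assert contaminated.sum() == truth.n_contaminated_calls

    def test_low_gq_rate_matches_config(self):
        cfg = CohortConfig(
            n_cases=200,
            n_controls=200,
            n_genes=100,
            target_set_size=10,
            missing_rate=0.03,
            seed=17,
        )
        matrix, truth = generate_cohort(cfg)
        low = matrix.gq < 20
        n = matrix.gq.size
        se = np.sqrt(0.03 * 0.97 / n)
        assert abs(low.mean() - 0.03) < 4 * se
        assert low.sum() == truth.n_low_gq_calls


class TestNullExchangeability:
    def test_case_control_diff_centred_at_zero(self):
        """Without planting, the target-set carrier-frequency difference
        shows no systematic sign over many seeds."""
        signs = []
        for seed in range(200):
            cfg = CohortConfig(
                n_cases=60,
                n_controls=60,
                n_genes=60,
                target_set_size=15,
                variants_per_gene=4.0,
                maf_spectrum={"kind": "loguniform", "min": 1e-3, "max": 0.3},
                contamination_rate=0.0,
                missing_rate=0.0,
                seed=seed,
            )
            matrix, truth = generate_cohort(cfg)
            in_t = matrix.variants["gene"].isin(truth.target_genes).to_numpy()
            hom = (matrix.geno[in_t] == 2).any(axis=0)
            d = hom[matrix.is_case].mean() - hom[~matrix.is_case].mean()
            if d != 0:
                signs.append(d > 0)
        assert len(signs) > 50
        frac = np.mean(signs)
        se = np.sqrt(0.25 / len(signs))
        assert abs(frac - 0.5) < 4 * se


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_cases=0),
            dict(n_genes=-5),
            dict(contamination_rate=1.5),
            dict(missing_rate=-0.1),
            dict(missing_rate=float("nan")),
            dict(planted_case_hom_excess=-1),
            dict(maf_spectrum={"kind": "loguniform", "min": 0.0, "max": 0.5}),
            dict(maf_spectrum={"kind": "waffle"}),
            dict(variants_per_gene=0.0),
            dict(target_set_size=500),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        base = dict(n_cases=20, n_controls=20, n_genes=50, target_set_size=5)
        base.update(kwargs)
        with pytest.raises(ConfigError):
            generate_cohort(CohortConfig(**base))
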