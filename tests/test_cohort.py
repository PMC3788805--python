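"""Synthetic cohort generator: determinism, distributions, composition."""

import dataclasses

import numpy as np
import pytest

from mrst2.cohort import (CohortConfig, GroupParams, sample_cohort,
                          synthesize_metabolite_series, synthesize_water_series)
from mrst2.cohort import _ELDERLY_T2, _YOUNG_T2


def zero_sd(table):
    return {k: (m, 0.0) for k, (m, _) in table.items()}


def config_with(young=None, elderly=None, **kwargs):
    base = CohortConfig()
    return dataclasses.replace(base, young=young or base.young,
                               elderly=elderly or base.elderly, **kwargs)


class TestSampling:
    def test_default_cohort_has_18_young_and_14_elderly(self):
        records = sample_cohort(CohortConfig())
        assert sum(r.group == "young" for r in records) == 18
        assert sum(r.group == "elderly" for r in records) == 14
        assert len({r.subject_id for r in records}) == 32

    def test_zero_sd_pins_every_subject_to_the_group_mean(self):
        cfg = config_with(
            young=GroupParams(n=5, t2_ms=zero_sd(_YOUNG_T2), csf_fraction=(0.09, 0.0),
                              water_t2_tissue=(52.0, 0.0)),
            elderly=GroupParams(n=4, t2_ms=zero_sd(_ELDERLY_T2), csf_fraction=(0.25, 0.0),
                                water_t2_tissue=(47.0, 0.0)))
        for rec in sample_cohort(cfg):
            table = _YOUNG_T2 if rec.group == "young" else _ELDERLY_T2
            assert rec.true_t2["NAA"] == table["NAA"][0]
            assert rec.true_csf_fraction in (0.09, 0.25)

    def test_same_master_seed_reproduces_the_cohort(self):
        a = sample_cohort(CohortConfig(master_seed=7))
        b = sample_cohort(CohortConfig(master_seed=7))
        assert a == b
        c = sample_cohort(CohortConfig(master_seed=8))
        assert a != c

    def test_invalid_group_size_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            config_with(young=GroupParams(n=0, t2_ms=_YOUNG_T2, csf_fraction=(0.09, 0.03),
                                          water_t2_tissue=(52.0, 2.0)))

    def test_group_means_converge_to_configured_means(self):
        # law of large numbers at n = 2000, tolerance 3 standard errors
        n = 2000
        cfg = config_with(
            young=GroupParams(n=n, t2_ms=_YOUNG_T2, csf_fraction=(0.09, 0.03),
                              water_t2_tissue=(52.0, 2.0)),
            elderly=GroupParams(n=2, t2_ms=_ELDERLY_T2, csf_fraction=(0.25, 0.11),
                                water_t2_tissue=(47.0, 4.0)),
            master_seed=11)
        young = [r for r in sample_cohort(cfg) if r.group == "young"]
        for channel, (mean, sd) in _YOUNG_T2.items():
            observed = np.mean([r.true_t2[channel] for r in young])
            assert abs(observed - mean) < 3 * sd / np.sqrt(n)

    def test_truncation_keeps_t2_positive_and_csf_in_unit_interval(self):
        cfg = config_with(
            elderly=GroupParams(n=200, t2_ms={"NAA": (5.0, 10.0)},
                                csf_fraction=(0.25, 0.4), water_t2_tissue=(47.0, 4.0)),
            young=GroupParams(n=2, t2_ms={"NAA": (208.0, 18.0)},
                              csf_fraction=(0.09, 0.03), water_t2_tissue=(52.0, 2.0)),
            master_seed=3)
        for rec in sample_cohort(cfg):
            assert rec.true_t2["NAA"] >= 1.0
            assert 0.0 <= rec.true_csf_fraction <= 1.0


class TestMetaboliteSynthesis:
    def test_noise_free_singlet_series_decays_with_the_configured_t2(self, basis):
        # creatine only (two singlet moieties sharing the tCr T2 channel)
        t2 = 160.0
        cfg = config_with(
            young=GroupParams(n=1, t2_ms={"tCr": (t2, 0.0)}, csf_fraction=(0.09, 0.0),
                              water_t2_tissue=(52.0, 0.0)),
            elderly=GroupParams(n=1, t2_ms={"tCr": (t2, 0.0)}, csf_fraction=(0.25, 0.0),
                                water_t2_tissue=(47.0, 0.0)),
            concentrations={"Cr": 5.0}, noise_sd=0.0, mm_scale=0.0)
        sub = sample_cohort(cfg)[0]
        series = synthesize_metabolite_series(sub, basis, cfg)
        win = (series.spectra[10.0].ppm > 2.9) & (series.spectra[10.0].ppm < 3.15)
        a10 = np.sum(series.spectra[10.0].values.real[win])
        a180 = np.sum(series.spectra[180.0].values.real[win])
        assert a10 / a180 == pytest.approx(np.exp(-10 / t2) / np.exp(-180 / t2), rel=1e-6)

    def test_infinite_t2_and_zero_noise_make_singlet_spectra_te_invariant(self, basis):
        cfg = config_with(
            young=GroupParams(n=1, t2_ms={"tCr": (1e12, 0.0)}, csf_fraction=(0.09, 0.0),
                              water_t2_tissue=(52.0, 0.0)),
            elderly=GroupParams(n=1, t2_ms={"tCr": (1e12, 0.0)}, csf_fraction=(0.25, 0.0),
                                water_t2_tissue=(47.0, 0.0)),
            concentrations={"Cr": 5.0}, noise_sd=0.0, mm_scale=0.0)
        sub = sample_cohort(cfg)[0]
        series = synthesize_metabolite_series(sub, basis, cfg)
        ref = series.spectra[10.0].values
        for te in (20.0, 80.0, 180.0):
            np.testing.assert_allclose(series.spectra[te].values, ref, atol=1e-9)

    def test_elderly_naa_singlet_decays_faster_than_young(self, basis):
        cfg = CohortConfig(noise_sd=0.0, master_seed=5)
        cfg_zero = config_with(
            young=GroupParams(n=1, t2_ms=zero_sd(_YOUNG_T2), csf_fraction=(0.09, 0.0),
                              water_t2_tissue=(52.0, 0.0)),
            elderly=GroupParams(n=1, t2_ms=zero_sd(_ELDERLY_T2), csf_fraction=(0.25, 0.0),
                                water_t2_tissue=(47.0, 0.0)),
            noise_sd=0.0)
        records = sample_cohort(cfg_zero)
        ratios = {}
        for rec in records:
            series = synthesize_metabolite_series(rec, basis, cfg_zero)
            s10, s180 = series.spectra[10.0], series.spectra[180.0]
            win = (s10.ppm > 1.95) & (s10.ppm < 2.06)
            ratios[rec.group] = (np.sum(s180.values.real[win])
                                 / np.sum(s10.values.real[win]))
        assert ratios["elderly"] < ratios["young"]

    def test_compound_without_basis_moieties_raises(self, basis):
        cfg = config_with(concentrations={"NAA": 12.0, "Lactate": 1.0})
        sub = sample_cohort(cfg)[0]
        with pytest.raises(KeyError, match="Lactate"):
            synthesize_metabolite_series(sub, basis, cfg)

    def test_same_seed_gives_identical_spectra(self, basis):
        cfg = CohortConfig(master_seed=9)
        sub = sample_cohort(cfg)[0]
        a = synthesize_metabolite_series(sub, basis, cfg)
        b = synthesize_metabolite_series(sub, basis, cfg)
        for te in a.spectra:
            assert np.array_equal(a.spectra[te].values, b.spectra[te].values)


class TestWaterSynthesis:
    def test_zero_csf_fraction_gives_pure_monoexponential(self):
        cfg = config_with(
            young=GroupParams(n=1, t2_ms=_YOUNG_T2, csf_fraction=(0.0, 0.0),
                              water_t2_tissue=(52.0, 0.0)),
            water_noise_frac=0.0)
        sub = sample_cohort(cfg)[0]
        w = synthesize_water_series(sub, cfg)
        expected = cfg.water_s0 * np.exp(-w.te_ms / 52.0)
        np.testing.assert_allclose(w.integrals, expected, rtol=1e-12)

    def test_te_zero_extrapolation_equals_s0(self):
        cfg = dataclasses.replace(CohortConfig(), water_noise_frac=0.0,
                                  water_te_list=(1e-9, 10, 50, 200, 1500, 5000))
        sub = sample_cohort(cfg)[0]
        w = synthesize_water_series(sub, cfg)
        assert w.integrals[0] == pytest.approx(cfg.water_s0, rel=1e-6)

    def test_longest_te_signal_is_csf_dominated_for_young_defaults(self):
        cfg = config_with(
            young=GroupParams(n=1, t2_ms=_YOUNG_T2, csf_fraction=(0.09, 0.0),
                              water_t2_tissue=(52.0, 0.0)),
            water_noise_frac=0.0)
        sub = sample_cohort(cfg)[0]
        w = synthesize_water_series(sub, cfg)
        csf_term = cfg.water_s0 * 0.09 * np.exp(-5000.0 / cfg.t2_csf_fixed)
        assert csf_term / w.integrals[-1] > 0.99
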