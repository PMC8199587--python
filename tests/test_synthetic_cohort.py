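import math

import numpy as np
import pytest
from scipy import stats

from nmrfp import CohortSpec, SurvivalSimParams, delta_to_mean_shift, generate_cohort
from nmrfp.signatures import load_signatures
from nmrfp.synthetic_cohort import (
    _sample_concentrations_given,
    sample_concentrations,
    simulate_survival,
    synthesize_spectrum,
)
from nmrfp.univariate import cliffs_delta


class TestDeltaToMeanShift:
    def test_zero_delta_zero_shift(self):
        assert delta_to_mean_shift(0.0, 2.5) == 0.0

    def test_antisymmetry(self):
        assert delta_to_mean_shift(-0.4, 1.3) == pytest.approx(-delta_to_mean_shift(0.4, 1.3))

    def test_monte_carlo_calibration(self):
        # oracle: brute-force Cliff's delta between two shifted normal samples
        shift = delta_to_mean_shift(0.330, 1.0)
        rng = np.random.default_rng(42)
        x = rng.normal(shift, 1.0, 100_000)
        y = rng.normal(0.0, 1.0, 100_000)
        assert cliffs_delta(x, y) == pytest.approx(0.330, abs=0.01)

    @pytest.mark.parametrize("bad", [1.0, -1.0, 1.2])
    def test_unattainable_or_invalid_delta(self, bad):
        with pytest.raises(ValueError):
            delta_to_mean_shift(bad, 1.0)


class TestSampleConcentrations:
    def test_zero_deltas_make_groups_exchangeable(self):
        spec = CohortSpec(target_deltas={}, background_effect_sd=0.0)
        spec.target_deltas = {s.name: 0.0 for s in spec.signatures}
        rng = np.random.default_rng(0)
        a = np.array([sample_concentrations(spec, "eCRC_free", rng)["Glutamine"]
                      for _ in range(800)])
        b = np.array([sample_concentrations(spec, "mCRC", rng)["Glutamine"]
                      for _ in range(800)])
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_full_mixture_matches_metastatic(self):
        spec = CohortSpec(relapsed_metastatic_fraction=1.0)
        rng = np.random.default_rng(1)
        rel = np.array([sample_concentrations(spec, "eCRC_relapsed", rng)["Glutamine"]
                        for _ in range(800)])
        met = np.array([sample_concentrations(spec, "mCRC", rng)["Glutamine"]
                        for _ in range(800)])
        assert stats.ks_2samp(rel, met).pvalue > 0.01

    def test_unknown_metabolite_in_deltas_rejected(self):
        with pytest.raises(ValueError, match="Unobtainium"):
            CohortSpec(target_deltas={"Unobtainium": 0.3})

    def test_delta_calibration_all_metabolites(self):
        # empirical Cliff's delta on true concentrations matches the targets
        spec = CohortSpec()
        rng = np.random.default_rng(7)
        n = 2000
        free = {s.name: np.empty(n) for s in spec.signatures}
        met = {s.name: np.empty(n) for s in spec.signatures}
        for i in range(n):
            for name, v in _sample_concentrations_given(spec, False, rng).items():
                free[name][i] = v
            for name, v in _sample_concentrations_given(spec, True, rng).items():
                met[name][i] = v
        for sig in spec.signatures:
            d = cliffs_delta(free[sig.name], met[sig.name])
            assert d == pytest.approx(spec.target_deltas[sig.name], abs=0.05), sig.name


class TestSynthesizeSpectrum:
    def _clean_spec(self, **kw):
        defaults = dict(noise_sd=0.0, miscalibration_sd=0.0, dilution_sd=0.0,
                        water_amplitude=0.0, ethanol_probability=0.0,
                        n_background_signals=0, n_points=4096)
        defaults.update(kw)
        return CohortSpec(**defaults)

    def test_zero_concentrations_flat_spectrum(self):
        spec = self._clean_spec()
        conc = {s.name: 0.0 for s in spec.signatures}
        sp = synthesize_spectrum(conc, "NOESY", spec, np.random.default_rng(0))
        np.testing.assert_array_equal(sp.intensity, 0.0)

    def test_linearity_in_concentration(self):
        spec = self._clean_spec()
        conc = {s.name: s.base_concentration for s in spec.signatures}
        rng = np.random.default_rng(0)
        sp1 = synthesize_spectrum(conc, "NOESY", spec, rng, dilution=1.0)
        sp2 = synthesize_spectrum({k: 2 * v for k, v in conc.items()}, "NOESY", spec,
                                  rng, dilution=1.0)
        np.testing.assert_allclose(sp2.intensity, 2 * sp1.intensity, rtol=1e-12)

    def test_noiseless_signal_nonnegative(self):
        spec = self._clean_spec()
        conc = {s.name: s.base_concentration for s in spec.signatures}
        sp = synthesize_spectrum(conc, "CPMG", spec, np.random.default_rng(0))
        assert sp.intensity.min() >= 0.0

    def test_quant_window_integral_proportional(self):
        # numeric-integration oracle: captured fraction of an area-normalized
        # Lorentzian inside the window, via the arctan antiderivative
        spec = self._clean_spec(n_points=16384)
        sig = next(s for s in spec.signatures if s.name == "Formate")
        (center, height, width), (lo, hi) = sig.peaks[0], sig.quant_window
        captured = (math.atan((hi - center) / (width / 2))
                    - math.atan((lo - center) / (width / 2))) / math.pi
        from nmrfp.univariate import quantify_metabolites

        for conc_val in (0.5, 2.0):
            conc = {s.name: 0.0 for s in spec.signatures}
            conc["Formate"] = conc_val
            sp = synthesize_spectrum(conc, "NOESY", spec, np.random.default_rng(0),
                                     dilution=1.0, miscalibration=0.0)
            sp.sample_id = "x"
            got = quantify_metabolites([sp], spec.signatures).loc["x", "Formate"]
            assert got == pytest.approx(conc_val * height * captured, rel=0.01)

    def test_pulse_sequence_attenuation(self):
        spec = self._clean_spec()
        conc = {s.name: s.base_concentration for s in spec.signatures}
        rng = np.random.default_rng(0)
        spectra = {seq: synthesize_spectrum(conc, seq, spec, rng, dilution=1.0,
                                            miscalibration=0.0)
                   for seq in ("NOESY", "CPMG", "Diffusion")}
        x = spectra["NOESY"].ppm
        # lipoprotein CH2n region (macromolecule): suppressed under CPMG
        lip = (x > 1.25) & (x < 1.33)
        assert spectra["CPMG"].intensity[lip].sum() < 0.5 * spectra["NOESY"].intensity[lip].sum()
        # formate (small molecule): suppressed under diffusion editing
        small = (x > 8.42) & (x < 8.46)
        assert spectra["Diffusion"].intensity[small].sum() < 0.5 * spectra["NOESY"].intensity[small].sum()

    def test_negative_concentration_rejected(self):
        spec = self._clean_spec()
        conc = {s.name: s.base_concentration for s in spec.signatures}
        conc["Lactate"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            synthesize_spectrum(conc, "NOESY", spec, np.random.default_rng(0))


class TestSimulateSurvival:
    def test_null_hazard_ratio_independent_of_risk(self):
        params = SurvivalSimParams(log_hr_high_risk=0.0)
        rng = np.random.default_rng(0)
        lo = [simulate_survival(0.0, params, rng).rfi_months for _ in range(1000)]
        hi = [simulate_survival(1.0, params, rng).rfi_months for _ in range(1000)]
        assert stats.ks_2samp(lo, hi).pvalue > 0.01

    def test_zero_censoring_horizon(self):
        params = SurvivalSimParams(admin_censor_months=0.0)
        rec = simulate_survival(1.0, params, np.random.default_rng(0))
        assert rec.rfi_months == 0.0 and rec.rfi_event == 0
        assert rec.os_months == 0.0 and rec.os_event == 0
        assert rec.css_months is None

    def test_endpoint_consistency(self):
        params = SurvivalSimParams()
        rng = np.random.default_rng(1)
        for _ in range(500):
            rec = simulate_survival(rng.random(), params, rng)
            assert rec.rfi_months >= 0 and rec.dfs_months >= 0 and rec.os_months >= 0
            # DFS is relapse-or-death, whichever first: never after OS time
            assert rec.dfs_months <= rec.os_months + 1e-9
            if rec.css_months is not None:
                assert rec.rfi_event == 1
            if rec.rfi_event == 0 and rec.css_months is not None:
                raise AssertionError("CSS defined without an observed relapse")


class TestGenerateCohort:
    def test_determinism_byte_identical(self, tmp_path, small_spec):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(small_spec, outdir=d1)
        generate_cohort(small_spec, outdir=d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2 and len(files1) == 3 * 24 + 1
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_default_cohort_size(self, default_cohort):
        assert len(default_cohort.subjects) == 169
        assert sum(len(v) for v in default_cohort.spectra.values()) == 507

    def test_single_metastatic_subject(self):
        spec = CohortSpec(n_ecrc_free=0, n_ecrc_relapsed=0, n_mcrc=1, n_points=1024)
        cohort = generate_cohort(spec)
        assert len(cohort.subjects) == 1
        assert sum(len(v) for v in cohort.spectra.values()) == 3
        assert cohort.clinical["rfi_months"].isna().all()

    def test_group_survival_invariants(self, default_cohort):
        clin = default_cohort.clinical
        rel = clin[clin.group == "eCRC_relapsed"]
        free = clin[clin.group == "eCRC_free"]
        met = clin[clin.group == "mCRC"]
        assert (rel.rfi_event == 1).all()
        assert (free.rfi_event == 0).all()
        assert met.rfi_months.isna().all() and met.css_months.isna().all()
        # CSS defined exactly for relapsed subjects
        assert rel.css_months.notna().all()
        assert free.css_months.isna().all()

    def test_stage_correlated_with_latent_risk(self, default_cohort):
        clin = default_cohort.clinical
        ecrc = clin[clin.group != "mCRC"]
        p_iii_high = (ecrc[ecrc.latent_risk == 1].stage == "III").mean()
        p_iii_low = (ecrc[ecrc.latent_risk == 0].stage == "III").mean()
        assert p_iii_high > p_iii_low

    def test_signature_library_contract(self):
        sigs = load_signatures()
        assert len(sigs) == 32
        for s in sigs:
            assert s.quant_window[0] < s.quant_window[1]
            assert all(0.2 <= c <= 10.0 for c, _, _ in s.peaks)
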