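"""Synthetic-data generators: round-trip identities and recovery targets."""

import numpy as np
import pytest

from txnkinetics import (
    ConfigurationError,
    KineticParams,
    SynthFishSpec,
    SynthFrapSpec,
    expected_fish_ratio,
    gen_fish_table,
    gen_frap_dataset,
    normalize_frap,
    select_model,
)
from txnkinetics.curves import RecoveryCurve, get_schedule


class TestFrapGenerator:
    def test_noiseless_round_trip_recovers_truth(self):
        spec = SynthFrapSpec(noise_sd=0.0, acq_bleach_rate=0.0, day_sd=0.0,
                             n_cells=2, seed=1)
        traces, truth = gen_frap_dataset(spec)
        curve = normalize_frap(traces[0])
        cell = truth["cells"][0]
        t, y = curve.post()
        expected = cell["y0"] + sum(
            a * (1 - np.exp(-k * t)) for a, k in zip(cell["amplitudes"], cell["rates"])
        )
        assert np.allclose(y, expected, atol=1e-9)

    def test_acquisition_bleaching_corrected_exactly(self):
        clean = gen_frap_dataset(
            SynthFrapSpec(noise_sd=0.0, acq_bleach_rate=0.0, day_sd=0.0, n_cells=1, seed=2)
        )[0][0]
        bleached = gen_frap_dataset(
            SynthFrapSpec(noise_sd=0.0, acq_bleach_rate=0.01, day_sd=0.0, n_cells=1, seed=2)
        )[0][0]
        assert not np.allclose(clean.roi, bleached.roi)  # raw traces differ...
        assert np.allclose(  # ...but normalization cancels the decay
            normalize_frap(clean).mean, normalize_frap(bleached).mean, atol=1e-9
        )

    def test_seed_determinism(self):
        a, _ = gen_frap_dataset(SynthFrapSpec(n_cells=3, seed=9))
        b, _ = gen_frap_dataset(SynthFrapSpec(n_cells=3, seed=9))
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.roi, tb.roi)

    def test_noise_magnitude_matches_requested_sd(self):
        """Sample sd of the normalized residuals within 10% of noise_sd."""
        sd = 0.05
        spec = SynthFrapSpec(noise_sd=sd, day_sd=0.0, n_cells=10, seed=3)
        traces, truth = gen_frap_dataset(spec)
        resid = []
        for tr, cell in zip(traces, truth["cells"]):
            curve = normalize_frap(tr)
            t, y = curve.post()
            model = cell["y0"] + sum(
                a * (1 - np.exp(-k * t)) for a, k in zip(cell["amplitudes"], cell["rates"])
            )
            resid.extend(y - model)
        resid = np.asarray(resid)
        assert len(resid) >= 1000
        assert np.std(resid) == pytest.approx(sd, rel=0.10)

    def test_day_effect_scales_amplitudes(self):
        spec = SynthFrapSpec(noise_sd=0.0, day_sd=0.2, n_cells=8, n_days=3, seed=4)
        _, truth = gen_frap_dataset(spec)
        amps = {c["day"]: c["amplitudes"] for c in truth["cells"]}
        assert len({round(a[0], 9) for a in amps.values()}) > 1

    def test_day_structure_covers_multiple_days(self):
        _, truth = gen_frap_dataset(SynthFrapSpec(n_cells=12, n_days=3, seed=5))
        assert len({c["day"] for c in truth["cells"]}) >= 2

    def test_simulator_model_end_to_end(self, gene_e3):
        spec = SynthFrapSpec(
            model="simulator", gene=gene_e3,
            model_params=KineticParams(dt=0.5),
            schedule=get_schedule("sf-frap"), noise_sd=0.01, n_cells=2,
            n_sites_per_cell=2, seed=6,
        )
        traces, truth = gen_frap_dataset(spec)
        assert len(traces) == 2
        curve = normalize_frap(traces[0])
        assert curve.prebleach_mean() == pytest.approx(1.0, abs=0.05)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_frap_dataset(SynthFrapSpec(noise_sd=-1.0))
        with pytest.raises(ConfigurationError):
            gen_frap_dataset(SynthFrapSpec(model="simulator", gene=None))

    def test_end_to_end_biexponential_recovery(self):
        """Mean of 10 noisy cells -> model selection finds both populations."""
        spec = SynthFrapSpec(noise_sd=0.02, day_sd=0.0, n_cells=10, seed=7)
        traces, truth = gen_frap_dataset(spec)
        curves = [normalize_frap(tr) for tr in traces]
        mat = np.vstack([c.mean for c in curves])
        mean_curve = RecoveryCurve(
            times=curves[0].times, mean=mat.mean(axis=0),
            sem=mat.std(axis=0, ddof=1) / np.sqrt(len(curves)), n=len(curves),
            schedule=get_schedule("mrna-frap"), n_prebleach=6,
        )
        fit = select_model(mean_curve)
        assert fit.n_components == 2
        cell = truth["cells"][0]
        assert fit.rates[0] == pytest.approx(cell["rates"][0], rel=0.10)
        assert fit.rates[1] == pytest.approx(cell["rates"][1], rel=0.10)


class TestFishGenerator:
    def test_zero_noise_equals_simulator_output(self, gene_e3, no_pause_params):
        spec = SynthFishSpec(gene=gene_e3, params=no_pause_params,
                             n_sites=30, lognormal_noise_sd=0.0, seed=1)
        table = gen_fish_table(spec)
        assert np.allclose(table["intron_channel"], table["true_intron"])
        assert np.allclose(table["ratio"], table["true_ratio"])

    def test_same_seed_identical(self, gene_e3, no_pause_params):
        spec = SynthFishSpec(gene=gene_e3, params=no_pause_params, n_sites=20, seed=2)
        assert gen_fish_table(spec).equals(gen_fish_table(spec))

    def test_median_ratio_tracks_oracle_under_noise(self, gene_e3, no_pause_params):
        """Lognormal channel noise is median-preserving."""
        spec = SynthFishSpec(gene=gene_e3, params=no_pause_params,
                             n_sites=300, lognormal_noise_sd=0.2, seed=3)
        table = gen_fish_table(spec)
        oracle = expected_fish_ratio(gene_e3, no_pause_params)
        assert np.median(table["ratio"]) == pytest.approx(oracle, rel=0.10)

    def test_invalid_spec_rejected(self, gene_e3, no_pause_params):
        with pytest.raises(ConfigurationError):
            gen_fish_table(SynthFishSpec(gene=gene_e3, params=no_pause_params, n_sites=0))
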