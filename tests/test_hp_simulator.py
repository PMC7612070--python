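"""Forward-model correctness of the synthetic-data generator."""

import numpy as np
import pytest

from hypermet import (
    AcquisitionScheme,
    CohortConfig,
    ExchangeParams,
    gamma_variate,
    ivim_signal,
    make_image_series,
    simulate_cohort,
    simulate_dce,
    simulate_exchange,
    simulate_expression_survival,
    simulate_ivim,
    tofts_conc,
)
from conftest import euler_exchange


class TestSimulateExchange:
    def test_no_exchange_no_lactate(self, scheme):
        ser = simulate_exchange(ExchangeParams(k_pl=0.0), scheme)
        assert np.all(ser.lac_signal == 0.0)
        assert ser.pyr_signal.max() > 0

    def test_magnetization_conserved_without_loss(self):
        """With no relaxation and no inflow, exchange only moves
        magnetization between pools: Mp + Ml is constant in time."""
        from hypermet.hp_simulator import _propagate

        params = ExchangeParams(k_pl=0.02, r1_pyr=1e-15, r1_lac=1e-15,
                                aif_amplitude=0.0)
        rng = np.random.default_rng(0)
        mp, ml = 1.0, 0.0
        t = 0.0
        for dt in rng.uniform(0.5, 6.0, 50):
            mp, ml = _propagate(mp, ml, t, t + dt, params)
            t += dt
            assert abs(mp + ml - 1.0) < 1e-9

    def test_matrix_exponential_matches_fine_euler(self, scheme):
        """Propagator equivalence on 100 random physiological draws."""
        rng = np.random.default_rng(42)
        n = 100
        draws = {
            "k_pl": rng.uniform(0.001, 0.05, n),
            "r1_pyr": rng.uniform(1 / 45, 1 / 20, n),
            "r1_lac": rng.uniform(1 / 40, 1 / 15, n),
        }
        pyr_ref, lac_ref = euler_exchange(draws, scheme, dt=1e-3)
        for i in range(n):
            params = ExchangeParams(k_pl=draws["k_pl"][i],
                                    r1_pyr=draws["r1_pyr"][i],
                                    r1_lac=draws["r1_lac"][i])
            ser = simulate_exchange(params, scheme)
            for got, ref in ((ser.pyr_signal, pyr_ref[i]),
                             (ser.lac_signal, lac_ref[i])):
                err = np.max(np.abs(got - ref)) / ref.max()
                assert err < 1e-3

    def test_early_lactate_slope_scaling(self, scheme):
        """On a constant pyruvate plateau the early lactate signal grows at
        ~ k_pl * Mp per frame, modulated by the two flip-angle factors."""
        import math

        # plateau driver: no inflow, huge pyruvate pool, negligible decay
        params = ExchangeParams(k_pl=0.0064, r1_pyr=1e-9, r1_lac=1e-9,
                                aif_amplitude=0.0)
        plateau_scheme = AcquisitionScheme(flip_pyr=0.01, flip_lac=0.01,
                                           n_frames=5)
        ser = simulate_exchange(params, plateau_scheme, m0=(1.0, 0.0))
        mp = ser.pyr_signal / math.sin(math.radians(0.01))
        ml = ser.lac_signal / math.sin(math.radians(0.01))
        slope = (ml[1] - ml[0]) / plateau_scheme.frame_interval
        # the discrete slope sees the interval-average pyruvate pool, so
        # agreement is to a few percent, not exact
        assert slope == pytest.approx(params.k_pl * mp[0], rel=4e-2)

    def test_summed_lactate_monotone_in_kpl(self, scheme):
        sums = []
        for k in [0.001, 0.003, 0.0064, 0.01, 0.02, 0.05]:
            ser = simulate_exchange(ExchangeParams(k_pl=k), scheme)
            sums.append(ser.lac_signal.sum())
        assert np.all(np.diff(sums) > 0)

    def test_invalid_parameters_rejected(self, scheme):
        with pytest.raises(ValueError):
            ExchangeParams(k_pl=-0.01)
        with pytest.raises(ValueError):
            ExchangeParams(r1_pyr=0.0)
        with pytest.raises(ValueError):
            ExchangeParams(k_pl=np.nan)
        with pytest.raises(ValueError):
            simulate_exchange(ExchangeParams(), scheme, duration=10.0)

    def test_scheme_invariants(self):
        with pytest.raises(ValueError):
            AcquisitionScheme(flip_pyr=0.0)
        with pytest.raises(ValueError):
            AcquisitionScheme(flip_lac=95.0)
        with pytest.raises(ValueError):
            AcquisitionScheme(tr=4.0, frame_interval=2.0)
        with pytest.raises(ValueError):
            AcquisitionScheme(n_frames=1)


class TestMakeImageSeries:
    def test_noiseless_voxels_proportional_to_input(self, noiseless_series):
        vol = make_image_series(noiseless_series, shape=(16, 16, 8),
                                noise_sd=0.0)
        tc = noiseless_series.pyr_signal
        inroi = vol.pyr_signal[vol.mask]
        ref = tc / tc.max()
        for voxel in inroi[:10]:
            assert np.allclose(voxel / voxel.max(), ref, atol=1e-12)

    def test_background_rayleigh_mean(self, noiseless_series):
        """Pure-noise background magnitude mean is sigma * sqrt(pi/2)."""
        vol = make_image_series(noiseless_series, shape=(30, 30, 10),
                                noise_sd=1.0, seed=7)
        bg = vol.pyr_signal[~vol.mask]
        assert bg.size > 1e5
        assert bg.mean() == pytest.approx(np.sqrt(np.pi / 2), rel=5e-3)

    def test_roi_round_trips_through_nifti(self, noiseless_series, tmp_path):
        """A ~125-voxel ROI (the study's median tumor size) survives the
        NIfTI write/read cycle with an identical mask count."""
        from hypermet import load_series_nifti, write_series_nifti

        vol = make_image_series(noiseless_series, shape=(20, 20, 12),
                                roi_radius_vox=3.1, noise_sd=0.05, seed=1)
        assert 100 <= int(vol.mask.sum()) <= 150
        paths = write_series_nifti(vol, tmp_path)
        back = load_series_nifti(paths["pyr"], paths["lac"], paths["mask"],
                                 paths["sidecar"])
        assert int(back.mask.sum()) == int(vol.mask.sum())
        assert np.allclose(back.pyr_signal, vol.pyr_signal)
        assert back.scheme.flip_lac == vol.scheme.flip_lac

    def test_oversized_roi_rejected(self, noiseless_series):
        with pytest.raises(ValueError):
            make_image_series(noiseless_series, shape=(4, 4, 4),
                              roi_radius_vox=3.0)


class TestIvimDceForward:
    def test_ivim_f0_is_monoexponential(self):
        b = np.array([0.0, 50, 100, 200, 400, 800])
        tab = simulate_ivim(0.0, 1e-3, 1e-2, 1.0, b)
        assert np.allclose(tab["signal"], np.exp(-b * 1e-3))

    def test_ivim_matches_direct_formula(self):
        b = np.array([0.0, 50, 100, 200, 400, 800])
        tab = simulate_ivim(0.1, 1.0e-3, 1.0e-2, 1.0, b)
        expected = 0.1 * np.exp(-b * 1e-2) + 0.9 * np.exp(-b * 1e-3)
        assert np.allclose(tab["signal"], expected)
        assert tab["signal"][0] == pytest.approx(1.0)

    def test_ivim_rejects_unidentifiable(self):
        with pytest.raises(ValueError):
            simulate_ivim(0.1, 1e-2, 1e-3, 1.0, [0, 100, 500])

    def test_dce_zero_ktrans_is_zero(self):
        t = np.linspace(0, 5, 50)
        tab = simulate_dce(0.0, 0.4, "impulse", t)
        assert np.allclose(tab["conc"], 0.0)

    def test_dce_impulse_closed_form(self):
        t = np.linspace(0, 5, 100)
        ct = tofts_conc(t, 0.2, 0.4, "impulse")
        assert np.allclose(ct, 0.2 * np.exp(-0.5 * t), rtol=1e-12)

    def test_dce_kep_identity_in_metadata(self):
        t = np.linspace(0, 5, 50)
        tab = simulate_dce(0.3, 0.6, "impulse", t)
        assert np.allclose(tab["kep_true"], tab["ktrans_true"] / tab["ve_true"])

    def test_dce_rejects_bad_ve(self):
        with pytest.raises(ValueError):
            tofts_conc(np.linspace(0, 5, 20), 0.2, 0.0, "impulse")

    def test_gamma_variate_peak(self):
        t = np.linspace(0, 100, 100001)
        u = gamma_variate(t, amplitude=2.5, arrival=8.0, shape=3.0, rate=4.0)
        assert u.max() == pytest.approx(2.5, rel=1e-6)
        assert t[np.argmax(u)] == pytest.approx(8.0 + 3.0 * 4.0, abs=0.01)
        assert np.all(u[t <= 8.0] == 0.0)


class TestSimulateCohort:
    def test_planted_label_counts(self):
        df = simulate_cohort(CohortConfig(seed=1))
        assert len(df) == 7
        assert int(df["pcr_label"].sum()) == 3
        assert int(df["parp_flag"].sum()) == 2
        assert df["days_to_followup"].between(7, 11).all()

    def test_seeded_determinism_bit_identical(self):
        a = simulate_cohort(CohortConfig(seed=5))
        b = simulate_cohort(CohortConfig(seed=5))
        assert a.equals(b)
        c = simulate_cohort(CohortConfig(seed=6))
        assert not a.equals(c)

    def test_response_structure(self):
        """Non-PARP responders rise >= +20% in LAC/PYR, non-PARP
        nonresponders stay below; the PARP nonresponder violates the rule."""
        df = simulate_cohort(CohortConfig(seed=3))
        pct = 100 * (df["followup_lacpyr"] - df["baseline_lacpyr"]) \
            / df["baseline_lacpyr"]
        soc = ~df["parp_flag"]
        assert (pct[soc & df["pcr_label"]] >= 20).all()
        assert (pct[soc & ~df["pcr_label"]] < 20).all()
        parp_nonresp = df["parp_flag"] & ~df["pcr_label"]
        assert (pct[parp_nonresp] >= 20).all()

    def test_missing_kpl_patient(self):
        df = simulate_cohort(CohortConfig(seed=2))
        assert df["baseline_kpl"].isna().sum() == 1

    def test_impossible_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=5, n_responders=6)


class TestExpressionSurvival:
    def test_high_tail_has_worse_survival(self):
        df = simulate_expression_survival(800, hazard_ratio=2.5, seed=11)
        hi = df[df["high_expression_true"] == 1]
        lo = df[df["high_expression_true"] == 0]
        assert len(hi) == pytest.approx(0.15 * 800, abs=2)
        assert hi["os_months"].median() < lo["os_months"].median()

    def test_determinism_and_gene_columns(self):
        a = simulate_expression_survival(100, genes=("LDHA", "CAIX"),
                                         gene_corr=0.5, seed=4)
        b = simulate_expression_survival(100, genes=("LDHA", "CAIX"),
                                         gene_corr=0.5, seed=4)
        assert a.equals(b)
        assert {"LDHA", "CAIX", "os_months", "os_event"} <= set(a.columns)
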