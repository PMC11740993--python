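"""Forward simulators: mass balance, determinism, presets, serialisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from pfaspartition import (
    DialysisDesign,
    SSLMLayout,
    default_layout,
    make_series_preset,
    simulate_dialysis,
    simulate_sslm,
)
from pfaspartition.synthetic import (
    load_dialysis_assays,
    load_sslm_assays,
    save_dialysis_assays,
    save_sslm_assays,
)


class TestSSLMSimulator:
    def test_single_vial_mass_balance_by_hand(self):
        # spike 10 ng, V_lipid 1 uL, V_water 1 mL, K_MW = 1000:
        # 10 = C*1 + 1000*C*0.001  =>  C = 5 ng/mL, bound mass 5 ng
        layout = SSLMLayout(lipid_volumes=(1.0,), water_volume=1.0, spike_mass=10.0)
        assay = simulate_sslm("X", 3.0, layout=layout, noise_sd=0.0, replicates=1)
        assert assay.measured_aqueous[0, 0] == pytest.approx(5.0, rel=1e-12)

    def test_no_loss_means_zero_rinse(self):
        assay = simulate_sslm("X", 3.0, noise_sd=0.0, surface_loss_frac=0.0, seed=0)
        assert np.all(assay.rinse_mass == 0.0)

    def test_same_seed_same_assay(self):
        a = simulate_sslm("PFOA", 3.5, noise_sd=0.1, surface_loss_frac=0.2, seed=42)
        b = simulate_sslm("PFOA", 3.5, noise_sd=0.1, surface_loss_frac=0.2, seed=42)
        np.testing.assert_array_equal(a.measured_aqueous, b.measured_aqueous)
        np.testing.assert_array_equal(a.rinse_mass, b.rinse_mass)
        c = simulate_sslm("PFOA", 3.5, noise_sd=0.1, surface_loss_frac=0.2, seed=43)
        assert not np.array_equal(a.measured_aqueous, c.measured_aqueous)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        log_kmw=st.floats(0.0, 6.0),
        loss=st.floats(0.0, 0.8),
    )
    def test_noiseless_mass_conservation_in_every_vial(self, log_kmw, loss):
        assay = simulate_sslm("X", log_kmw, noise_sd=0.0, surface_loss_frac=loss,
                              replicates=1)
        lay = assay.layout
        c = assay.measured_aqueous[:, 0]
        v_lip_ml = np.array(lay.lipid_volumes) * 1e-3
        aqueous = c * lay.water_volume
        membrane = (10.0 ** log_kmw) * c * v_lip_ml
        wall = assay.rinse_mass[:, 0]
        np.testing.assert_allclose(aqueous + membrane + wall, lay.spike_mass,
                                   rtol=1e-10)

    def test_invalid_layouts_rejected(self):
        with pytest.raises(ValueError):
            SSLMLayout(lipid_volumes=(2.0, 1.0))  # not increasing
        with pytest.raises(ValueError):
            SSLMLayout(lipid_volumes=(1.0,), water_volume=-1.0)
        with pytest.raises(ValueError):
            simulate_sslm("X", 3.0, surface_loss_frac=1.5)

    def test_default_ladder_spans_printed_endpoints(self):
        lay = default_layout()
        assert len(lay.lipid_volumes) == 6
        assert lay.lipid_volumes[0] == pytest.approx(0.067)
        assert lay.lipid_volumes[-1] == pytest.approx(2.166)


class TestDialysisSimulator:
    def test_noiseless_free_conc_satisfies_mass_balance(self):
        design = DialysisDesign()
        assay = simulate_dialysis("X", 1e-6, 1.5, design=design, noise_sd=0.0)
        v_tot, n_hsa = design.total_volume_l, design.n_hsa_mol
        for i, ratio in enumerate(design.ratios):
            n_tot = ratio * n_hsa
            c = assay.measured_free[i, 0]
            residual = n_tot - c * v_tot - n_hsa * 1.5 * c / (1e-6 + c)
            assert abs(residual) / n_tot < 1e-10
            # cross-check against an independent scalar root-finder
            f = lambda x: n_tot - x * v_tot - n_hsa * 1.5 * x / (1e-6 + x)
            c_ref = brentq(f, 1e-18, n_tot / v_tot, xtol=1e-25, rtol=1e-14)
            assert c == pytest.approx(c_ref, rel=1e-9)

    def test_no_binding_limit_free_equals_control(self):
        assay = simulate_dialysis("X", 1e6, 1.0, noise_sd=0.0)
        np.testing.assert_allclose(assay.measured_free[:, 0], assay.control_free,
                                   rtol=1e-6)

    def test_noiseless_bound_increases_with_dose(self):
        design = DialysisDesign()
        assay = simulate_dialysis("X", 1e-7, 1.0, design=design, noise_sd=0.0)
        n_tot = np.array(design.ratios) * design.n_hsa_mol
        bound = n_tot - assay.measured_free[:, 0] * design.total_volume_l
        assert np.all(np.diff(bound) > 0)

    def test_same_seed_same_assay(self):
        a = simulate_dialysis("PFOS", 1e-6, 1.0, noise_sd=0.05, seed=7)
        b = simulate_dialysis("PFOS", 1e-6, 1.0, noise_sd=0.05, seed=7)
        np.testing.assert_array_equal(a.measured_free, b.measured_free)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_dialysis("X", -1e-6, 1.0)
        with pytest.raises(ValueError):
            DialysisDesign(ratios=(1.0, 1.0))


class TestSeriesPresets:
    def test_pfca_preset_is_an_exact_line_of_thirteen_homologs(self, registry):
        series = make_series_preset("PFCA", registry=registry)
        assert len(series) == 13
        fcs = np.array([c.fc_n for c, _ in series])
        truths = np.array([t for _, t in series])
        np.testing.assert_allclose(truths, -1.0 + 0.36 * fcs, atol=1e-12)

    def test_pfsa_preset_has_eight_homologs_with_published_slope(self, registry):
        series = make_series_preset("PFSA", registry=registry)
        assert len(series) == 8
        diffs = np.diff([t for _, t in series])
        np.testing.assert_allclose(diffs, 0.37, atol=1e-12)

    def test_zero_slope_gives_flat_series(self, registry):
        series = make_series_preset("PFCA", slope=0.0, intercept=2.0,
                                    registry=registry)
        assert all(t == 2.0 for _, t in series)

    def test_class_without_series_raises(self, registry):
        with pytest.raises(ValueError, match="custom"):
            make_series_preset("custom", registry=registry)

    def test_known_homologs_resolve_to_registry_entries(self, registry):
        series = dict(
            (c.acronym, c) for c, _ in make_series_preset("PFCA", registry=registry)
        )
        assert "PFOA" in series          # FC7 carboxylate
        assert "PFCA-FC14" in series     # registry has no FC14 carboxylate
        assert series["PFCA-FC14"].molecular_formula["C"] == 15


class TestSerialisation:
    def test_sslm_csv_round_trip_with_truth_sidecar(self, tmp_path):
        assays = [
            simulate_sslm(a, t, noise_sd=0.05, surface_loss_frac=s, seed=i)
            for i, (a, t, s) in enumerate(
                [("PFOA", 1.5, 0.0), ("8:2 diPAP", 4.4, 0.3)]
            )
        ]
        path = tmp_path / "sslm.csv"
        save_sslm_assays(assays, path)
        again = load_sslm_assays(path)
        assert [a.compound for a in again] == [a.compound for a in assays]
        for orig, back in zip(assays, again):
            np.testing.assert_allclose(back.measured_aqueous, orig.measured_aqueous)
            np.testing.assert_allclose(back.rinse_mass, orig.rinse_mass)
            assert back.truth["true_log_kmw"] == orig.truth["true_log_kmw"]

    def test_dialysis_csv_round_trip(self, tmp_path):
        assays = [simulate_dialysis("PFOS", 1e-6, 1.0, noise_sd=0.05, seed=3)]
        path = tmp_path / "dialysis.csv"
        save_dialysis_assays(assays, path)
        again = load_dialysis_assays(path)
        np.testing.assert_allclose(again[0].measured_free, assays[0].measured_free)
        np.testing.assert_allclose(again[0].control_free, assays[0].control_free)
        assert again[0].truth["true_kd"] == 1e-6
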