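"""Phase-image segmentation, dry-mass conversion, SGR, GR metric and GR50."""

import numpy as np
import pandas as pd
import pytest

from acralpdx import qpi as qk
from acralpdx import synthdata as sd


class TestSegmentation:
    def test_two_disjoint_blobs_two_labels(self, disjoint_phase_image):
        img, _ = disjoint_phase_image
        _, n = qk.segment_cells(img)
        assert n == 2

    def test_touching_blobs_split_by_watershed(self):
        img, truth = sd.gen_phase_image(
            [((64, 90), 18, 500.0), ((64, 124), 18, 600.0)],
            shape=(128, 224), allow_overlap=True,
        )
        _, n = qk.segment_cells(img)
        assert n == len(truth) == 2

    def test_blank_image_zero_labels(self):
        _, n = qk.segment_cells(np.zeros((64, 64)))
        assert n == 0

    def test_count_accuracy_over_random_disjoint_layouts(self):
        # grid-placed blobs with jitter: counts must be right >= 95%
        correct = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cells = []
            for r in (40, 120):
                for c in (40, 120, 200):
                    if rng.random() < 0.7:
                        jitter = rng.integers(-6, 7, size=2)
                        cells.append(
                            ((r + jitter[0], c + jitter[1]),
                             int(rng.integers(12, 18)),
                             float(rng.uniform(300, 900)))
                        )
            if not cells:
                continue
            img, truth = sd.gen_phase_image(cells, shape=(160, 240))
            _, n = qk.segment_cells(img)
            correct += n == len(truth)
        assert correct / n_seeds >= 0.95


class TestMassFromPhase:
    def test_inverse_construction_one_pg(self):
        # alpha = 0.18 um^3/pg, so an integrated OPL*area of 0.18 um^3 is 1 pg
        phase = np.full((3, 3), 0.18 / 9)
        assert qk.mass_from_phase(phase) == pytest.approx(1.0)

    def test_zero_phase_zero_mass(self):
        assert qk.mass_from_phase(np.zeros((5, 5))) == 0.0

    def test_linearity_in_pixel_area(self):
        phase = np.random.default_rng(0).uniform(0, 1, (8, 8))
        m1 = qk.mass_from_phase(phase, qk.QPIConfig(pixel_area=1.0))
        m2 = qk.mass_from_phase(phase, qk.QPIConfig(pixel_area=2.0))
        assert m2 == pytest.approx(2 * m1)

    def test_radians_path_equals_opl_path(self):
        lam = 0.532
        opl = np.random.default_rng(1).uniform(0, 0.5, (6, 6))
        radians = opl * 2 * np.pi / lam
        direct = qk.mass_from_phase(opl, qk.QPIConfig(phase_units="opl_um"))
        converted = qk.mass_from_phase(
            radians, qk.QPIConfig(phase_units="radians", wavelength_um=lam)
        )
        assert converted == pytest.approx(direct)

    def test_radians_without_wavelength_rejected(self):
        with pytest.raises(ValueError):
            qk.QPIConfig(phase_units="radians")

    def test_mass_conservation_on_fixture(self, disjoint_phase_image):
        img, _ = disjoint_phase_image
        labels, _ = qk.segment_cells(img)
        per_cell = qk.image_masses(img, labels)["mass_pg"].sum()
        whole = qk.mass_from_phase(img)
        assert per_cell == pytest.approx(whole, rel=0.01)


class TestSGR:
    def test_doubling_in_24h(self):
        t = np.linspace(0, 24, 9)
        m = 100.0 * 2 ** (t / 24)
        assert qk.specific_growth_rate(t, m) == pytest.approx(
            np.log(2) / 24, abs=1e-12
        )

    def test_constant_mass_zero(self):
        assert qk.specific_growth_rate([0, 1, 2], [50.0] * 3) == 0.0

    def test_population_mean_recovered(self, qpi_spec):
        tracks, truth = sd.gen_cell_mass_tracks(qpi_spec)
        sgr = qk.sgr_population(tracks)
        merged = sgr.groupby("dose_uM")["sgr"].mean().reset_index().merge(
            truth, on="dose_uM"
        )
        np.testing.assert_allclose(
            merged["sgr"], merged["truth_mean_sgr"], atol=0.002
        )

    def test_short_tracks_excluded_with_warning(self, qpi_spec):
        tracks, _ = sd.gen_cell_mass_tracks(qpi_spec)
        first = tracks["cell"] == tracks["cell"].iloc[0]
        short = tracks.loc[~first | (tracks["time_h"] < 1.0)]
        with pytest.warns(UserWarning, match="excluded"):
            out = qk.sgr_population(short, min_track_frames=5)
        assert tracks["cell"].iloc[0] not in set(out["cell"])


class TestNormalizedMassVelocity:
    def test_constant_total_mass_zero_velocity(self):
        assert qk.normalized_mass_velocity([0, 24, 48], [5.0, 5.0, 5.0]) == 0.0

    def test_linear_growth_closed_form(self):
        t = np.linspace(0, 72, 10)
        m = 1.0 + t / 72  # 1 -> 2 over 72 h
        assert qk.normalized_mass_velocity(t, m) == pytest.approx(1 / 72)

    def test_mass_halving_negative_velocity(self):
        t = np.linspace(0, 72, 10)
        m = 1.0 - t / 144
        assert qk.normalized_mass_velocity(t, m) < 0

    def test_zero_initial_mass_rejected(self):
        with pytest.raises(ValueError):
            qk.normalized_mass_velocity([0, 1], [0.0, 1.0])


class TestGRMetric:
    def test_formula_identities(self):
        assert qk.gr_metric(0.02, 0.02) == pytest.approx(1.0)
        assert qk.gr_metric(0.0, 0.02) == pytest.approx(0.0)
        assert qk.gr_metric(-0.02, 0.02) == pytest.approx(-0.5)

    def test_nongrowing_control_not_evaluable(self):
        assert np.isnan(qk.gr_metric(0.01, 0.0))
        assert np.isnan(qk.gr_metric(0.01, -0.005))


class TestFitGR50:
    def test_noiseless_logistic_recovered_within_one_percent(self):
        doses = np.array([0.0, 0.01, 0.1, 1.0, 10.0, 100.0])
        gr = -0.3 + (1 - -0.3) / (1 + (doses / 1.0) ** 1.0)
        fit = qk.fit_gr50(doses, gr)
        assert fit.gr50_estimable
        assert fit.gr50 == pytest.approx(1.0, rel=0.01)
        assert fit.gr_inf == pytest.approx(-0.3, abs=0.02)

    def test_flat_high_gr_flagged_non_estimable(self):
        doses = [0.0, 0.1, 1.0, 10.0, 100.0]
        fit = qk.fit_gr50(doses, [1.0, 0.98, 0.95, 0.93, 0.92])
        assert not fit.gr50_estimable
        assert fit.gr50 is None

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            qk.fit_gr50([0.0, 1.0, 10.0], [1.0, 0.5, 0.0])

    def test_fitted_curve_monotone_when_gr_monotone(self):
        doses = np.array([0.0, 0.01, 0.1, 1.0, 10.0, 100.0])
        gr = -0.5 + 1.5 / (1 + (doses / 0.5) ** 1.5)
        fit = qk.fit_gr50(doses, gr)
        grid = np.geomspace(1e-3, 1e3, 200)
        curve = qk._gr_logistic(grid, fit.gr_inf, fit.gr50, fit.hill)
        assert (np.diff(curve) <= 1e-12).all()

    def test_end_to_end_recovery_from_tracks(self, qpi_spec):
        tracks, _ = sd.gen_cell_mass_tracks(qpi_spec)
        sgr = qk.sgr_population(tracks)
        mean_sgr = sgr.groupby("dose_uM")["sgr"].mean()
        k_ctrl = mean_sgr[0.0]
        gr = {d: qk.gr_metric(k, k_ctrl) for d, k in mean_sgr.items()}
        fit = qk.fit_gr50(list(gr), list(gr.values()))
        assert fit.gr50_estimable
        assert fit.gr50 == pytest.approx(qpi_spec.true_gr50, rel=0.25)


class TestResponseDescriptors:
    def _windows(self, treated_sgr_by_time, control_sgr=0.02, n_cells=20,
                 spread=0.0):
        rng = np.random.default_rng(0)
        rows = []
        for t, mu in treated_sgr_by_time.items():
            for dose, m in [(0.0, control_sgr), (10.0, mu)]:
                for i in range(n_cells):
                    rows.append(
                        {
                            "dose_uM": dose,
                            "window_time_h": t,
                            "cell": f"{dose}_{i}",
                            "sgr": m + (rng.normal(0, spread) if spread else 0),
                        }
                    )
        return pd.DataFrame(rows)

    def test_treated_identical_to_control(self):
        out = qk.response_descriptors(
            self._windows({0.0: 0.02, 24.0: 0.02, 48.0: 0.02})
        )
        treated = out.loc[out["dose_uM"] == 10.0].iloc[0]
        assert treated["depth_of_response"] == pytest.approx(1.0)
        assert np.isnan(treated["time_of_response_h"])

    def test_instant_full_arrest(self):
        out = qk.response_descriptors(
            self._windows({0.0: 0.0, 24.0: 0.0, 48.0: 0.0})
        )
        treated = out.loc[out["dose_uM"] == 10.0].iloc[0]
        assert treated["depth_of_response"] == pytest.approx(0.0)
        assert treated["time_of_response_h"] == 0.0

    def test_bimodal_population_more_heterogeneous(self):
        rng = np.random.default_rng(3)
        base = {"dose_uM": 10.0, "window_time_h": 48.0}
        unimodal = pd.DataFrame(
            [{**base, "cell": f"u{i}", "sgr": rng.normal(0.01, 0.002)}
             for i in range(100)]
        )
        bimodal = pd.DataFrame(
            [{**base, "cell": f"b{i}",
              "sgr": (0.02 if i % 2 else 0.0) + rng.normal(0, 0.002)}
             for i in range(100)]
        )
        ctrl = pd.DataFrame(
            [{"dose_uM": 0.0, "window_time_h": 48.0, "cell": f"c{i}",
              "sgr": 0.02} for i in range(10)]
        )
        het_uni = qk.response_descriptors(pd.concat([ctrl, unimodal]))
        het_bi = qk.response_descriptors(pd.concat([ctrl, bimodal]))
        h_uni = het_uni.loc[het_uni["dose_uM"] == 10.0,
                            "heterogeneity"].iloc[0]
        h_bi = het_bi.loc[het_bi["dose_uM"] == 10.0, "heterogeneity"].iloc[0]
        assert h_bi > h_uni
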