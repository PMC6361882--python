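import numpy as np
import pytest
from scipy import stats

from pgoe import EnergyWindows, analytic_profile_metrics
from pgoe.simulate import (
    DEFAULT_TRIPLE_FRACTION,
    EmissionModel,
    events_from_origins,
    generate_dataset,
    simulate_event,
)


class TestDepthPdf:
    def test_rectangular_limit_falloff_at_cutoff(self):
        """With no peak, no slope and a hard cutoff the density is a
        rectangle and the 50% crossing of the (lightly smoothed) profile
        sits at the cutoff."""
        m = EmissionModel(line_energy=6.13, p0=1.0, p1=0.0, amplitude=0.0,
                          peak_z=90.0, falloff_offset=10.0, sigmoid_scale=0.0)
        pm = analytic_profile_metrics(m, smoothing_fwhm=0.2)
        assert pm.falloff50 == pytest.approx(m.falloff_center, abs=0.02)

    def test_density_nonnegative_and_normalizable(self):
        m = EmissionModel.preset("16O")
        z = np.linspace(*m.depth_range, 40_001)
        f = m.depth_pdf(z)
        assert np.all(f >= 0)
        area = np.trapezoid(f, z)
        assert area > 0
        assert np.trapezoid(f / area, z) == pytest.approx(1.0, abs=1e-6)

    def test_crossings_match_bisection_oracle(self):
        """80%/50% distal crossings agree with an independent 1-D
        root-finding oracle on the smoothed density to 0.001 mm."""
        from scipy.ndimage import gaussian_filter1d
        from scipy.optimize import brentq

        m = EmissionModel.preset("16O")
        dz = 0.002
        z = np.arange(m.depth_range[0], m.depth_range[1] + dz / 2, dz)
        f = gaussian_filter1d(m.depth_pdf(z), sigma=2.0 / 2.355 / dz, mode="nearest")
        f = f / f.max()
        zpk = z[np.argmax(f)]

        def crossing(level):
            g = lambda zz: np.interp(zz, z, f) - level
            return brentq(g, zpk, zpk + 30.0, xtol=1e-6)

        pm = analytic_profile_metrics(m, smoothing_fwhm=2.0, dz=dz)
        assert pm.falloff80 == pytest.approx(crossing(0.8), abs=1e-3)
        assert pm.falloff50 == pytest.approx(crossing(0.5), abs=1e-3)


class TestSampleOrigin:
    def test_zero_transverse_sigma_on_axis(self, rng):
        m = EmissionModel.preset("16O")
        m = EmissionModel(**{**m.__dict__, "sigma_t": 0.0})
        pts = m.sample_origin(rng, 100)
        assert np.all(pts[:, :2] == 0.0)

    def test_depth_distribution_ks(self, rng):
        """Empirical depth CDF matches the target CDF (KS test at
        alpha = 0.01)."""
        m = EmissionModel.preset("16O")
        pts = m.sample_origin(rng, 100_000)
        z_grid, cdf = m._depth_cdf_grid()
        res = stats.kstest(pts[:, 2], lambda q: np.interp(q, z_grid, cdf))
        assert res.pvalue > 0.01

    def test_transverse_variance(self, rng):
        m = EmissionModel.preset("16O")
        pts = m.sample_origin(rng, 100_000)
        assert np.isclose(pts[:, 0].var(), m.sigma_t**2, rtol=0.03)
        assert np.isclose(pts[:, 1].var(), m.sigma_t**2, rtol=0.03)


class TestSimulateEvent:
    def test_blur_off_cone_contains_origin(self, geometry, energy_model, rng):
        from pgoe.kinematics import build_cone, event_total_energy

        m = EmissionModel.preset("16O")
        n_ok = 0
        for origin in m.sample_origin(rng, 300):
            ev = simulate_event(origin, 6.13, geometry, energy_model, rng,
                                blur=False, quantize=False)
            if ev is None:
                continue
            cone = build_cone(ev, event_total_energy(ev))
            assert cone.angular_residual(origin) < 1e-9
            n_ok += 1
        assert n_ok >= 295

    def test_forced_kinds(self, geometry, energy_model, rng):
        m = EmissionModel.preset("16O")
        origin = m.sample_origin(rng, 1)[0]
        assert simulate_event(origin, 6.13, geometry, energy_model, rng,
                              kind="double").n_interactions == 2
        assert simulate_event(origin, 6.13, geometry, energy_model, rng,
                              kind="triple").n_interactions == 3

    def test_default_double_triple_mix(self, geometry, energy_model, rng):
        m = EmissionModel.preset("16O")
        origins = m.sample_origin(rng, 8000)
        data, _, _ = events_from_origins(origins, 6.13, geometry, energy_model, rng)
        frac3 = np.mean(data.n_interactions == 3)
        assert frac3 == pytest.approx(DEFAULT_TRIPLE_FRACTION, abs=0.02)


class TestDatasets:
    def test_requested_count_and_labels(self, o16_blurred_small):
        from pgoe.kinematics import select_events

        data, _, manifest = o16_blurred_small
        assert len(data) == 6000
        assert set(data.species) == {"16O"}
        # all generated events survive their own line's selection
        kept, tally = select_events(data.to_events()[:300], EnergyWindows())
        assert len(kept) == 300
        assert all(ev.species_label == "16O" for ev in kept)

    def test_same_seed_byte_identical_files(self, tmp_path):
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        generate_dataset("16O", d1, n_events=800, seed=5)
        generate_dataset("16O", d2, n_events=800, seed=5)
        assert (d1 / "events.pglm.csv").read_bytes() == (d2 / "events.pglm.csv").read_bytes()
        assert (d1 / "ground_truth.img").read_bytes() == (d2 / "ground_truth.img").read_bytes()

    def test_different_seed_differs(self, tmp_path):
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        generate_dataset("16O", d1, n_events=500, seed=1)
        generate_dataset("16O", d2, n_events=500, seed=2)
        assert (d1 / "events.pglm.csv").read_bytes() != (d2 / "events.pglm.csv").read_bytes()

    def test_manifest_records_conditions(self, o16_blurred_small):
        _, _, manifest = o16_blurred_small
        assert manifest["species"] == "16O"
        assert manifest["n_doubles"] + manifest["n_triples"] == manifest["n_events"]
        assert manifest["emission_model"]["line_energy"] == 6.13

    def test_ground_truth_histogram_total(self, o16_blurred_small):
        data, truth, _ = o16_blurred_small
        # all true origins of accepted events land in the (projected) VOI
        assert truth.histogram.sum() == len(data)

    def test_annihilation_background_fully_rejected(self, geometry,
                                                    energy_model, rng):
        """With 511 keV photons mixed into the batches, the 1 MeV cut and
        line windows keep only genuine line events."""
        from pgoe.simulate import _total_energies, generate_events

        m = EmissionModel.preset("16O")
        data, _, n_att = generate_events(m, 400, geometry, energy_model, rng,
                                         background_fraction=0.3)
        assert len(data) == 400
        assert np.all(np.abs(_total_energies(data) - 6.13) <= 0.2 + 1e-9)

    def test_background_free_stream_unchanged_by_flag_default(self, geometry,
                                                              energy_model):
        """background_fraction=0 consumes no extra random draws, so
        seeded datasets are unchanged by the feature."""
        from pgoe.simulate import generate_events

        m = EmissionModel.preset("16O")
        d1, _, _ = generate_events(m, 300, geometry, energy_model,
                                   np.random.default_rng(9))
        d2, _, _ = generate_events(m, 300, geometry, energy_model,
                                   np.random.default_rng(9),
                                   background_fraction=0.0)
        assert np.array_equal(d1.positions, d2.positions, equal_nan=True)
        assert np.array_equal(d1.energies, d2.energies, equal_nan=True)
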