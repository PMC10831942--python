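import numpy as np
import pytest
from scipy import integrate

from smlmdiff import (
    HistogramPDF,
    build_pdf,
    eval_mixture,
    find_peak_D,
    fit_mixture_global,
    population_shift,
)
from smlmdiff.mixtures import MixtureModel, _gauss


def model_of(centers, width, fractions):
    c = np.atleast_2d(centers).astype(float)
    f = np.atleast_2d(fractions).astype(float)
    return MixtureModel(
        centers=c, widths=np.full_like(c, width), fractions=f,
        labels=["d%d" % i for i in range(c.shape[0])], shared_centers=True, shared_width=True,
    )


class TestBuildPDF:
    def test_single_bin(self):
        pdf = build_pdf(np.full(10, -2.05))
        assert pdf.edges[0] == pytest.approx(-2.2)
        assert pdf.edges[-1] == pytest.approx(-2.0)
        assert pdf.density.tolist() == [pytest.approx(5.0)]

    def test_area_normalization(self):
        rng = np.random.default_rng(0)
        pdf = build_pdf(rng.normal(-1.5, 0.7, 1234))
        assert (pdf.density * pdf.bin_width).sum() == pytest.approx(1.0, abs=1e-9)
        # edges aligned to multiples of 0.2
        np.testing.assert_allclose(np.round(pdf.edges / 0.2) * 0.2, pdf.edges, atol=1e-9)

    def test_counts_to_densities(self):
        vals = np.concatenate([np.full(7, -1.05), np.full(3, -0.45)])
        pdf = build_pdf(vals)
        occupied = sorted(pdf.density[pdf.density > 0])
        assert occupied == [pytest.approx(1.5), pytest.approx(3.5)]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_pdf(np.array([]))


class TestEvalMixture:
    def test_peak_density_closed_form(self):
        m = model_of([-1.0], 0.43, [1.0])
        assert eval_mixture(m, -1.0)[()] == pytest.approx(1.0 / (0.43 * np.sqrt(2 * np.pi)), rel=1e-12)

    def test_symmetry_about_center(self):
        for c in (-2.63, -1.14):
            m = model_of([c], 0.43, [1.0])
            assert eval_mixture(m, c - 0.43) == pytest.approx(eval_mixture(m, c + 0.43), rel=1e-12)

    def test_integrates_to_one(self):
        m = model_of([-2.63, -1.86, -1.14], 0.43, [0.4, 0.35, 0.25])
        total, _ = integrate.quad(lambda x: float(eval_mixture(m, x)), -8, 4, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_invalid_fractions_rejected(self):
        m = model_of([-1.0], 0.43, [0.7])
        with pytest.raises(ValueError):
            eval_mixture(m, 0.0)


class TestFitMixtureGlobal:
    def test_noiseless_self_consistency(self):
        # a histogram synthesized exactly from the model is recovered to 1e-3
        centers, width, fr = np.array([-2.63, -1.86, -1.14]), 0.43, np.array([0.5, 0.3, 0.2])
        edges = np.arange(-21, 2) * 0.2
        x = 0.5 * (edges[:-1] + edges[1:])
        density = sum(f * _gauss(x, c, width) for c, f in zip(centers, fr))
        pdf = HistogramPDF(edges=edges, density=density, n=100_000)
        m = fit_mixture_global(pdf, 3, seed=0, loss="density")
        np.testing.assert_allclose(m.centers[0], centers, atol=1e-3)
        np.testing.assert_allclose(m.widths[0], width, atol=1e-3)
        np.testing.assert_allclose(m.fractions[0], fr, atol=1e-3)

    @pytest.mark.parametrize("loss", ["density", "ml"])
    def test_sampled_recovery_within_tolerance(self, loss):
        centers, width, fr = np.array([-2.63, -1.86, -1.14]), 0.43, np.array([0.4, 0.35, 0.25])
        rng = np.random.default_rng(0)
        comp = rng.choice(3, size=30_000, p=fr)
        pdf = build_pdf(rng.normal(centers[comp], width))
        m = fit_mixture_global(pdf, 3, seed=0, loss=loss)
        assert np.abs(m.centers[0] - centers).max() < 0.05
        assert abs(m.widths[0, 0] - width) < 0.03
        assert np.abs(m.fractions[0] - fr).max() < 0.03
        assert m.stderr is not None and np.isfinite(m.stderr).all()

    def test_sharing_contract_across_datasets(self):
        centers, width = np.array([-2.6, -1.2]), 0.4
        rng = np.random.default_rng(1)
        pdfs = []
        for fr in ([0.7, 0.3], [0.2, 0.8]):
            comp = rng.choice(2, size=10_000, p=fr)
            pdfs.append(build_pdf(rng.normal(centers[comp], width)))
        m = fit_mixture_global(pdfs, 2, seed=0)
        np.testing.assert_array_equal(m.centers[0], m.centers[1])
        np.testing.assert_array_equal(m.widths[0], m.widths[1])
        assert m.fractions[0, 0] > m.fractions[1, 0]  # fractions stay free

    def test_single_component_matches_sample_mean(self):
        rng = np.random.default_rng(2)
        d = rng.normal(-1.0, 0.4, 5_000)
        m = fit_mixture_global(build_pdf(d), 1, seed=0)
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(m.centers[0, 0] - d.mean()) < 2 * se + 0.01

    def test_J_exceeding_occupied_bins_rejected(self):
        with pytest.raises(ValueError, match="occupied"):
            fit_mixture_global(build_pdf(np.full(5, -1.0)), 3)


class TestFindPeakD:
    def test_symmetric_peak_position(self):
        edges = np.arange(-16, 10) * 0.2
        x = 0.5 * (edges[:-1] + edges[1:])
        pdf = HistogramPDF(edges=edges, density=_gauss(x, -0.26, 0.43), n=1000)
        peak = find_peak_D(pdf)
        assert peak.D_pk == pytest.approx(10**-0.26, rel=1e-6)

    def test_only_bins_above_half_max_used(self):
        edges = np.arange(-16, 10) * 0.2
        x = 0.5 * (edges[:-1] + edges[1:])
        density = _gauss(x, -0.26, 0.43)
        peak = find_peak_D(HistogramPDF(edges=edges, density=density, n=1000))
        n_above = int((density > 0.5 * density.max()).sum())
        assert peak.n_points == n_above

    def test_bimodal_uses_dominant_lobe_only(self):
        edges = np.arange(-21, 10) * 0.2
        x = 0.5 * (edges[:-1] + edges[1:])
        density = 0.35 * _gauss(x, -2.6, 0.3) + 0.65 * _gauss(x, -0.3, 0.3)
        peak = find_peak_D(HistogramPDF(edges=edges, density=density, n=1000))
        assert peak.center == pytest.approx(-0.3, abs=0.05)
        # qualifying points restricted to the dominant lobe
        assert peak.n_points <= int((x > -1.5).sum())

    def test_too_few_points_rejected(self):
        edges = np.arange(0, 4) * 0.2
        pdf = HistogramPDF(edges=edges, density=np.array([0.1, 5.0, 0.1]), n=10)
        with pytest.raises(ValueError):
            find_peak_D(pdf)


class TestPopulationShift:
    def test_cavin1_gain_to_population_2(self):
        # immobile fraction 87% -> 57%, population 2 appears at 25%
        shift = population_shift([0.87, 0.0, 0.13], [0.57, 0.25, 0.18])
        assert round(shift["gain_pct"][2]) == 29

    def test_caveolin3_population_1_loss(self):
        # immobile fraction 39% -> 12%
        shift = population_shift([0.39, 0.26, 0.35], [0.12, 0.52, 0.36])
        assert round(shift["loss_pop1_pct"]) == 69

    def test_identical_vectors_no_shift(self):
        shift = population_shift([0.5, 0.3, 0.2], [0.5, 0.3, 0.2])
        assert shift["loss_pop1_pct"] == 0.0
        assert all(v == 0.0 for v in shift["gain_pct"].values())

    def test_zero_initial_population_rejected(self):
        with pytest.raises(ValueError):
            population_shift([0.0, 1.0], [0.5, 0.5])


class TestEndToEnd:
    def test_pipeline_recovers_fractions_at_wide_separation(self):
        # populations separated by >= 1.1 decades are resolved by the global
        # fit with fraction errors below 0.07 after the full chain
        # simulate -> estimate -> histogram -> fit
        from smlmdiff import PopulationSpec, SimulationConfig, estimate_all, simulate_trajectories

        pops = [PopulationSpec(0.001, 0.4, "p1"), PopulationSpec(0.014, 0.35, "p2"), PopulationSpec(0.2, 0.25, "p3")]
        cfg = SimulationConfig(
            populations=pops, sigma_loc=30.0, dt=0.03, mean_track_len=8.0,
            n_molecules=30_000, fov=(30.0, 30.0), n_frames=6_000, seed=5,
        )
        locs, _ = simulate_trajectories(cfg)
        locs = locs.rename(columns={"molecule_id": "traj_id"})
        est = estimate_all(locs, 0.03)
        m = fit_mixture_global(build_pdf(est["D_log"].to_numpy()), 3, seed=0)
        np.testing.assert_allclose(m.fractions[0], [0.4, 0.35, 0.25], atol=0.07)
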