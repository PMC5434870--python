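import numpy as np
import pytest

from entasis.constants import KB_KCAL_MOL_K
from entasis.energetics import (
    driving_force,
    gap_statistics,
    reorganization_energy,
    strain_energy,
    variance_lambda,
)
from entasis.errors import (
    DegenerateGeometryError,
    DimensionError,
    DomainError,
    StateLabelError,
)
from entasis.geometry import InternalCoordinateSpec, geometry_summary
from entasis.surrogate import (
    TwoStateModel,
    analytic_reference,
    default_site_template,
    default_two_state_model,
    embed_trajectory,
    sample_state,
    synthetic_gap_series,
    two_state_energies,
)

from oracles import brute_force_two_state_references

T = 300.0
KBT = KB_KCAL_MOL_K * T


@pytest.fixture
def model_1d() -> TwoStateModel:
    """Equal-curvature 1-D benchmark: k = 1, d = 2, eps = 5."""
    return TwoStateModel(k_red=[1.0], k_ox=[1.0], displacement_d=[2.0],
                         offset_eps=5.0)


class TestTwoStateEnergies:
    def test_reduced_minimum(self, model_1d):
        e_red, e_ox, delta = two_state_energies(model_1d, [0.0])
        assert e_red == 0.0
        assert e_ox == pytest.approx(0.5 * 1.0 * 4.0 + 5.0)
        assert delta == pytest.approx(e_ox - e_red)

    def test_oxidized_minimum(self, model_1d):
        e_red, e_ox, _ = two_state_energies(model_1d, [2.0])
        assert e_ox == pytest.approx(5.0)
        assert e_red == pytest.approx(2.0)

    def test_equal_k_gap_linear_in_x(self, model_1d):
        xs = np.linspace(-3, 3, 7)[:, None]
        _, _, delta = two_state_energies(model_1d, xs)
        slopes = np.diff(delta) / np.diff(xs[:, 0])
        np.testing.assert_allclose(slopes, -1.0 * 2.0)  # -k*d

    def test_dimension_mismatch(self, model_1d):
        with pytest.raises(DimensionError):
            two_state_energies(model_1d, [0.0, 1.0])


class TestAnalyticReference:
    def test_equal_curvature_closed_form(self, model_1d):
        ref = analytic_reference(model_1d, T)
        assert ref.lambda_red == pytest.approx(2.0)
        assert ref.lambda_ox == pytest.approx(2.0)
        assert ref.lambda_eq3 == pytest.approx(2.0)
        assert ref.delta_g_mean_based == pytest.approx(5.0)
        assert ref.strain_red_on_ox == pytest.approx(2.0)

    def test_coincident_minima_all_zero(self):
        m = TwoStateModel([2.0, 3.0], [2.0, 3.0], [0.0, 0.0], offset_eps=1.5)
        ref = analytic_reference(m, T)
        assert ref.lambda_red == ref.lambda_ox == 0.0
        assert ref.lambda_eq3 == pytest.approx(0.0)
        assert ref.delta_g_mean_based == pytest.approx(1.5)

    def test_unequal_curvature_matches_brute_force_minimization(self):
        k_red, k_ox, d, eps = 0.8, 2.5, 1.3, 4.0
        m = TwoStateModel([k_red], [k_ox], [d], eps)
        ref = analytic_reference(m, T)
        oracle = brute_force_two_state_references(k_red, k_ox, d, eps)
        assert ref.lambda_red == pytest.approx(oracle["lambda_red"], abs=1e-6)
        assert ref.lambda_ox == pytest.approx(oracle["lambda_ox"], abs=1e-6)
        assert ref.strain_red_on_ox == pytest.approx(
            oracle["strain_red_on_ox"], abs=1e-6)
        assert ref.delta_g_minimum == pytest.approx(
            oracle["delta_g_minimum"], abs=1e-6)

    def test_unequal_curvature_means_match_sampling(self):
        m = TwoStateModel([0.8], [2.5], [1.3], 4.0)
        ref = analytic_reference(m, T)
        for state, mean_ref, var_ref in [
            ("reduced", ref.mean_gap_red, ref.var_gap_red),
            ("oxidized", ref.mean_gap_ox, ref.var_gap_ox),
        ]:
            _, series = sample_state(m, state, T, 50_000, seed=5)
            st = gap_statistics(series)
            se = np.sqrt(var_ref / st.n_frames)
            assert abs(st.mean_delta_e - mean_ref) < 3 * se
            assert st.sd_delta_e ** 2 == pytest.approx(var_ref, rel=0.05)


class TestSampleState:
    def test_seed_determinism(self, model_1d):
        s1, g1 = sample_state(model_1d, "reduced", T, 100, seed=42)
        s2, g2 = sample_state(model_1d, "reduced", T, 100, seed=42)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(g1.delta_e, g2.delta_e)

    def test_reduced_state_variance(self, model_1d):
        n = 50_000
        samples, _ = sample_state(model_1d, "reduced", T, n, seed=1)
        target = KBT / 1.0  # ~0.596 A^2
        se = target * np.sqrt(2.0 / (n - 1))
        assert abs(samples.var(ddof=1) - target) < 3 * se

    def test_oxidized_state_mean_at_displacement(self, model_1d):
        n = 50_000
        samples, _ = sample_state(model_1d, "oxidized", T, n, seed=2)
        se = np.sqrt(KBT / 1.0 / n)
        assert abs(samples.mean() - 2.0) < 3 * se

    def test_unknown_state_rejected(self, model_1d):
        with pytest.raises(StateLabelError):
            sample_state(model_1d, "neutral", T, 10, seed=0)

    def test_metropolis_moments_match_exact(self, model_1d):
        n = 50_000
        exact, _ = sample_state(model_1d, "reduced", T, n, seed=3)
        chain, _ = sample_state(model_1d, "reduced", T, n, seed=4,
                                sampler="metropolis", burn_in=2000)
        # an MCMC chain is autocorrelated: use an effective-sample-size
        # scaled standard error (integrated autocorrelation time tau)
        x = chain[:, 0]
        ac = np.correlate(x - x.mean(), x - x.mean(), "full")[n - 1:] / np.arange(n, 0, -1)
        ac /= ac[0]
        tau = 1 + 2 * ac[1:200].sum()
        n_eff = n / max(tau, 1.0)
        sigma2 = KBT
        se_mean = np.sqrt(sigma2 / n_eff) + np.sqrt(sigma2 / n)
        assert abs(chain.mean() - exact.mean()) < 3 * se_mean
        se_var = sigma2 * np.sqrt(2 / n_eff) + sigma2 * np.sqrt(2 / n)
        assert abs(chain.var(ddof=1) - exact.var(ddof=1)) < 3 * se_var

    def test_metropolis_displaced_start_equilibrates_after_discard(self, model_1d):
        # deliberately bad start far up the wall, no burn-in: the early
        # window is transient, the tail is equilibrated
        _, series = sample_state(model_1d, "reduced", T, 20_000, seed=6,
                                 sampler="metropolis", start=[8.0])
        full = gap_statistics(series)
        tail = gap_statistics(series, discard_before=series.times[5000])
        ref = analytic_reference(model_1d, T)
        assert abs(tail.mean_delta_e - ref.mean_gap_red) \
            < abs(full.mean_delta_e - ref.mean_gap_red)


class TestParameterRecovery:
    """Headline property: the linear-response estimators recover the
    model's closed-form lambda, driving force and strain from samples."""

    def test_equal_curvature_recovery(self, model_1d):
        n = 50_000
        _, red = sample_state(model_1d, "reduced", T, n, seed=10)
        _, ox = sample_state(model_1d, "oxidized", T, n, seed=11)
        st_red, st_ox = gap_statistics(red), gap_statistics(ox)
        ref = analytic_reference(model_1d, T)

        se_mean = np.sqrt(ref.var_gap_red / n)  # equal k: same var per state
        se_comb = 0.5 * np.sqrt(2) * se_mean

        lam = reorganization_energy(st_red, st_ox)
        assert abs(lam - 2.0) < 3 * se_comb

        dg = driving_force(st_red, st_ox)
        assert abs(dg - 5.0) < 3 * se_comb

        for st in (st_red, st_ox):
            lam_var = variance_lambda(st, T)
            se_var = ref.var_gap_red * np.sqrt(2.0 / (n - 1)) / (2 * KBT)
            assert abs(lam_var - 2.0) < 3 * se_var

    def test_strain_recovery_from_average_geometry(self, model_1d):
        n = 50_000
        samples, _ = sample_state(model_1d, "reduced", T, n, seed=12)
        avg_x = samples.mean(axis=0)
        _, e_ox_avg, _ = two_state_energies(model_1d, avg_x)
        _, e_ox_min, _ = two_state_energies(model_1d,
                                            model_1d.displacement_d)
        res = strain_energy(e_ox_avg, e_ox_min)
        # strain is quadratic in the mean-position error: tolerance from
        # propagating 3 SE of the mean through k_ox*d*delta
        se = 3 * np.sqrt(KBT / 1.0 / n) * 1.0 * 2.0
        assert res.strain == pytest.approx(2.0, abs=3 * se)


class TestEmbedTrajectory:
    def test_zero_samples_identity(self):
        template = default_site_template()
        traj = embed_trajectory(np.zeros((3, 4)), template)
        for frame in traj.frames:
            np.testing.assert_allclose(frame.coords,
                                       template.structure.coords, atol=1e-12)

    def test_single_bond_stretch_shifts_measured_length(self):
        template = default_site_template()
        sample = np.array([[0.1, 0.0, 0.0, 0.0]])
        traj = embed_trajectory(sample, template)
        spec = InternalCoordinateSpec("distance", (0, 1), "Cu-S(cys)")
        from entasis.geometry import internal_coordinate
        got = internal_coordinate(traj.frames[0], spec)
        assert got == pytest.approx(2.16 + 0.1, abs=1e-9)

    def test_angle_perturbation_changes_angle_by_sample(self):
        template = default_site_template()
        template = type(template)(template.structure,
                                  (("angle", (1, 0, 2)),))
        traj = embed_trajectory(np.array([[5.0]]), template)
        from entasis.geometry import internal_coordinate
        spec = InternalCoordinateSpec("angle", (1, 0, 2), "S-Cu-S")
        before = internal_coordinate(template.structure, spec)
        after = internal_coordinate(traj.frames[0], spec)
        assert after - before == pytest.approx(5.0, abs=1e-9)

    def test_gaussian_bond_noise_roundtrip_through_geometry_summary(self):
        rng = np.random.default_rng(13)
        n, sigma = 2000, 0.05
        template = default_site_template()
        samples = np.zeros((n, 4))
        samples[:, 0] = rng.normal(0, sigma, n)
        traj = embed_trajectory(samples, template)
        df = geometry_summary(traj, [
            InternalCoordinateSpec("distance", (0, 1), "Cu-S(cys)")])
        assert df.loc[0, "mean"] == pytest.approx(2.16,
                                                  abs=3 * sigma / np.sqrt(n))
        assert df.loc[0, "rms"] == pytest.approx(sigma, rel=0.10)

    def test_collapsing_perturbation_rejected(self):
        template = default_site_template()
        sample = np.array([[-2.1, 0.0, 0.0, 0.0]])  # drives S into Cu
        with pytest.raises(DegenerateGeometryError):
            embed_trajectory(sample, template)


class TestSyntheticGapSeries:
    def test_zero_sd_constant(self):
        gs = synthetic_gap_series(82.5, 0.0, 10, seed=0, state="reduced")
        np.testing.assert_array_equal(gs.delta_e, np.full(10, 82.5))

    def test_seed_determinism(self):
        a = synthetic_gap_series(0.0, 1.0, 50, seed=9, state="oxidized")
        b = synthetic_gap_series(0.0, 1.0, 50, seed=9, state="oxidized")
        np.testing.assert_array_equal(a.delta_e, b.delta_e)

    def test_statistics_recovered(self):
        mean, sd, n = 82.5, 11.2, 4000
        gs = synthetic_gap_series(mean, sd, n, seed=14, state="reduced")
        st = gap_statistics(gs)
        assert abs(st.mean_delta_e - mean) < 3 * sd / np.sqrt(n)
        assert abs(st.sd_delta_e - sd) < 3 * sd / np.sqrt(2 * (n - 1))

    def test_invalid_parameters(self):
        with pytest.raises(DomainError):
            synthetic_gap_series(0.0, -1.0, 10, seed=0)
        with pytest.raises(DomainError):
            synthetic_gap_series(0.0, 1.0, 0, seed=0)


def test_default_model_fluctuations_in_realistic_band():
    """The default site model's thermal bond fluctuations should sit in
    the 0.04-0.30 A range typical of metal-ligand stretches at 300 K."""
    m = default_two_state_model()
    sigma = np.sqrt(KBT / m.k_red)
    assert (sigma >= 0.04).all() and (sigma <= 0.30).all()
    ref = analytic_reference(m, T)
    assert ref.lambda_eq3 > 0
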