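import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specklemode.photon_mc import (
    Source,
    fluence_at_planes,
    fresnel_reflectance,
    run_transport,
    sample_free_path,
    sample_hg_deflection,
)
from specklemode.tissue_optics import DepthPlanes, LayeredTissue, make_layer


def absorber(mu_a=1.0, thickness_um=10_000.0, n=1.0):
    return LayeredTissue(layers=(make_layer(n, mu_a, 0.0, 0.0, thickness_um),))


class TestFreePath:
    def test_closed_form_examples(self):
        assert sample_free_path(1.0, np.exp(-1.0)) == pytest.approx(1.0)
        assert sample_free_path(2.0, 1.0) == pytest.approx(0.0)

    def test_mean_is_inverse_mu_t(self, rng):
        u = rng.random(200_000)
        paths = -np.log(1 - u) / 10.0  # same transform as the sampler
        sampled = np.array([sample_free_path(10.0, x) for x in u[:1000] if x > 0])
        assert sampled.mean() == pytest.approx(0.1, rel=0.15)
        assert paths.mean() == pytest.approx(0.1, abs=3 * 0.1 / np.sqrt(len(paths)))

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            sample_free_path(0.0, 0.5)
        with pytest.raises(ValueError):
            sample_free_path(1.0, 0.0)


class TestHenyeyGreenstein:
    def test_isotropic_branch(self):
        assert sample_hg_deflection(0.0, 0.75) == pytest.approx(0.5)

    def test_inverse_cdf_value(self):
        # u = 0.5 makes 1 - g + 2gu = 1 at g = 0.9
        expected = (1 + 0.9**2 - (1 - 0.9**2) ** 2) / (2 * 0.9)
        assert expected == pytest.approx(0.98550, abs=1e-5)
        assert sample_hg_deflection(0.9, 0.5) == pytest.approx(expected)

    def test_sample_mean_equals_g(self, rng):
        g = 0.82
        u = rng.random(200_000)
        cos = np.array([sample_hg_deflection(g, x) for x in u])
        se = cos.std(ddof=1) / np.sqrt(len(cos))
        assert abs(cos.mean() - g) < 3 * se

    @given(g=st.floats(-0.99, 0.99), u=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_result_is_valid_cosine(self, g, u):
        assert -1.0 <= sample_hg_deflection(g, u) <= 1.0


class TestFresnel:
    def test_matched_indices(self):
        assert fresnel_reflectance(1.4, 1.4, 0.3) == 0.0

    def test_normal_incidence(self):
        assert fresnel_reflectance(1.0, 1.5, 1.0) == pytest.approx(0.04)

    def test_total_internal_reflection(self):
        # critical angle for 1.5 -> 1.0 is ~41.8 deg; take 60 deg incidence
        assert fresnel_reflectance(1.5, 1.0, np.cos(np.deg2rad(60))) == 1.0

    @given(
        n1=st.floats(1.0, 2.0),
        n2=st.floats(1.0, 2.0),
        c=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded(self, n1, n2, c):
        assert 0.0 <= fresnel_reflectance(n1, n2, c) <= 1.0


class TestTransport:
    def test_beer_lambert_transmission(self):
        tal = run_transport(absorber(), Source.pencil("top"), 100_000, 1,
                            score_fluence=False)
        expected = np.exp(-1.0)
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(tal.escaped_bottom - expected) < 3 * se
        assert tal.escaped_top == 0.0

    def test_transparent_slab(self):
        void = LayeredTissue(layers=(make_layer(1.0, 0, 0, 0, 100),))
        tal = run_transport(void, Source.pencil("top"), 5_000, 2, score_fluence=False)
        assert tal.escaped_bottom == 1.0
        assert tal.absorbed == 0.0

    def test_transparent_isotropic_point_escapes_half_up(self):
        void = LayeredTissue(layers=(make_layer(1.0, 0, 0, 0, 100),))
        tal = run_transport(void, Source.isotropic_point(50), 50_000, 3,
                            score_fluence=False)
        se = np.sqrt(0.25 / 50_000)
        assert abs(tal.escaped_top - 0.5) < 3 * se
        assert tal.escaped_top + tal.escaped_bottom == pytest.approx(1.0)

    def test_conservation_dermis(self, dermis_tallies):
        assert abs(dermis_tallies.conservation_residual) < 5e-3

    def test_conservation_isotropic_point(self, dermis_preset):
        tissue, _, _ = dermis_preset
        tal = run_transport(tissue, Source.isotropic_point(260), 100_000, 7,
                            score_fluence=False)
        assert abs(tal.conservation_residual) < 5e-3

    def test_deterministic_given_seed(self, dermis_preset):
        tissue, _, _ = dermis_preset
        a = run_transport(tissue, Source.pencil("top"), 20_000, 99)
        b = run_transport(tissue, Source.pencil("top"), 20_000, 99)
        np.testing.assert_array_equal(a.fluence_z, b.fluence_z)
        np.testing.assert_array_equal(a.fluence_rz, b.fluence_rz)
        assert a.escaped_top == b.escaped_top
        assert a.absorbed == b.absorbed

    def test_reciprocity_of_symmetric_slab(self, dermis_preset):
        """Escape up from depth z mirrors escape down from depth D - z."""
        tissue, _, _ = dermis_preset
        n = 100_000
        up = run_transport(tissue, Source.isotropic_point(120), n, 11,
                           score_fluence=False).escaped_top
        down = run_transport(tissue, Source.isotropic_point(400), n, 12,
                             score_fluence=False).escaped_bottom
        se = np.sqrt(2 * 0.25 / n)
        assert abs(up - down) < 3 * se + 0.01

    def test_rejects_bad_inputs(self, dermis_preset):
        tissue, _, _ = dermis_preset
        with pytest.raises(ValueError):
            run_transport(tissue, Source.pencil("top"), 0, 1)
        with pytest.raises(ValueError):
            run_transport(tissue, Source.pencil("top"), 10, 1, fluence_bin_um=-1)
        with pytest.raises(ValueError):
            run_transport(tissue, Source.isotropic_point(999), 10, 1)


class TestFluence:
    def test_beer_lambert_depth_profile(self):
        """In a pure absorber the planar fluence is exp(-mu_a z)."""
        tissue = absorber(mu_a=2.0, thickness_um=10_000)
        tal = run_transport(tissue, Source.pencil("top"), 100_000, 21)
        planes = DepthPlanes((0, 2500, 5000))
        fr = fluence_at_planes(tal, planes, "top", weighting="planar")
        # ratios relative to the entry bin; bin centres offset by half a bin
        for depth, value in zip(planes.depths_um[1:], fr.values[1:]):
            expected = np.exp(-2.0 * depth / 1e4)
            assert value == pytest.approx(expected, rel=0.05)

    def test_entry_fluence_with_backscatter_buildup(self, dermis_tallies):
        """Scattering builds the near-surface fluence up to >= the incident level."""
        assert dermis_tallies.fluence_z[0] >= 0.9

    def test_transparent_medium_flat_ratios(self):
        void = LayeredTissue(layers=(make_layer(1.0, 0, 0, 0, 500),))
        tal = run_transport(void, Source.pencil("top"), 2_000, 5)
        planes = DepthPlanes((0, 250, 500))
        for weighting in ("axis", "planar"):
            fr = fluence_at_planes(tal, planes, "top", weighting=weighting)
            np.testing.assert_allclose(fr.values, 1.0, rtol=1e-9)

    def test_entry_plane_self_normalizes(self, dermis_tallies, dermis_preset):
        _, planes, _ = dermis_preset
        fr = fluence_at_planes(dermis_tallies, planes, "top")
        assert fr.values[0] == 1.0

    def test_near_axis_flux_decays_with_depth(self, dermis_tallies, dermis_preset):
        _, planes, _ = dermis_preset
        fr = fluence_at_planes(dermis_tallies, planes, "top")
        assert np.all(np.diff(fr.values) < 0)

    def test_unscored_tallies_raise(self, dermis_preset):
        tissue, planes, _ = dermis_preset
        tal = run_transport(tissue, Source.pencil("top"), 1_000, 1, score_fluence=False)
        with pytest.raises(ValueError):
            fluence_at_planes(tal, planes, "top")
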