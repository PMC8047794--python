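"""OAM channel rates, 2D convolution and the dichroic figure of merit."""

import dataclasses

import numpy as np
import pytest
from scipy import integrate, special

from oameels import (
    BeamParameters,
    FixtureSpec,
    OAMStick,
    Transition,
    TransitionSet,
    VolumetricGrid,
    annular_amplitude,
    compute_kinematics,
    compute_sticks,
    convolve_2d,
    dichroism,
    dichroism_sticks,
    direct_matrix_element_oracle,
    mirror_cube,
    multipole_cube,
    radial_matrix_element,
    stick_rate,
)
from oameels.rates import NumericalControls, channel_rate, transverse_multipoles

from conftest import chiral_blob_grid

BEAM = BeamParameters()  # 60 keV, 200 mrad, annulus 7 x 3 bohr, l in [-3, 3]
KIN = compute_kinematics(BEAM)


class TestRadialMatrixElement:
    radii = (np.arange(100) + 0.5) * 0.12

    def test_zero_profile_gives_zero(self):
        assert radial_matrix_element(self.radii, np.zeros(100), BEAM, 2, 0.5) == 0

    def test_zero_k_perp_nonzero_l_vanishes(self):
        prof = np.exp(-self.radii) + 0j
        assert radial_matrix_element(self.radii, prof, BEAM, 1, 0.0) == 0
        assert radial_matrix_element(self.radii, prof, BEAM, -3, 0.0) == 0

    def test_monopole_small_k_limit_matches_quadrature(self):
        c = 1.7
        prof = np.full(100, c, dtype=complex)
        m = radial_matrix_element(self.radii, prof, BEAM, 0, 1e-6)
        expected, _ = integrate.quad(
            lambda r: float(annular_amplitude(r, BEAM)) * c * r,
            self.radii[0], self.radii[-1],
        )
        assert m.real == pytest.approx(expected, rel=1e-3)

    def test_negative_k_perp_rejected(self):
        with pytest.raises(ValueError):
            radial_matrix_element(self.radii, np.ones(100) + 0j, BEAM, 0, -0.1)


class TestSelectionRule:
    def test_pure_positive_harmonic_feeds_only_l_minus_m(self):
        # exp(+i 2 phi) content -> scattered OAM lands only in l = -2
        grid = multipole_cube(FixtureSpec(kind="multipole", m=2, parity="exp",
                                          npoints=48, spacing=0.35))
        comps = transverse_multipoles(grid, BEAM, 5.0)
        rates = {l: channel_rate(comps, BEAM, KIN, l) for l in BEAM.l_values}
        assert rates[-2] > 0
        for l, r in rates.items():
            if l != -2:
                assert r < 1e-6 * rates[-2]

    def test_restricted_content_leaks_nowhere_else(self):
        # cos(m phi) has content {+m, -m}: only l = -+m channels fire
        grid = multipole_cube(FixtureSpec(kind="multipole", m=3, parity="cos",
                                          npoints=48, spacing=0.35))
        comps = transverse_multipoles(grid, BEAM, 5.0)
        rates = {l: channel_rate(comps, BEAM, KIN, l) for l in BEAM.l_values}
        peak = max(rates.values())
        for l in (-2, -1, 0, 1, 2):
            assert rates[l] < 1e-6 * peak
        assert rates[3] > 0 and rates[-3] > 0


class TestOracleEquivalence:
    #: smooth fields x active (l, k_perp) pairs; amplitudes well above the
    #: 1e-3-of-peak floor where the 1% bound applies
    cases = [
        (
            FixtureSpec(kind="multipole", m=1, parity="cos", npoints=32,
                        spacing=0.5, radial_scale=2.0, z_sigma=1.5),
            [(1, 0.3), (-1, 0.6), (1, 1.0)],
        ),
        (
            FixtureSpec(kind="multipole", m=2, parity="sin", npoints=32,
                        spacing=0.5, radial_scale=2.5, z_sigma=2.0),
            [(2, 0.3), (-2, 0.6), (2, 1.0)],
        ),
        (None, [(0, 0.3), (1, 0.6), (-2, 1.0)]),  # chiral blob field
    ]

    @pytest.mark.parametrize("spec, pairs", cases)
    def test_pipeline_matches_direct_riemann_sum(self, spec, pairs, compact_beam):
        grid = chiral_blob_grid() if spec is None else multipole_cube(spec)
        comps = transverse_multipoles(grid, compact_beam, 5.0)
        for l, k in pairs:
            m_pipe = radial_matrix_element(comps.radii, comps.component(-l),
                                           compact_beam, l, k)
            oracle = direct_matrix_element_oracle(grid, compact_beam, l, k, 5.0)
            assert abs(m_pipe - oracle / (2 * np.pi)) < 0.01 * abs(oracle / (2 * np.pi))

    def test_zero_field_gives_zero(self, compact_beam):
        grid = VolumetricGrid([-2, -2, -2], np.diag([0.5] * 3), np.zeros((9, 9, 9)))
        assert direct_matrix_element_oracle(grid, compact_beam, 1, 0.5, 5.0) == 0

    def test_all_phases_unity_limit(self, compact_beam):
        # l = 0, k_perp = 0, omega -> 0: reduces to int V a d^3r
        # (single positive blob so the volume integral is far from zero)
        grid = chiral_blob_grid(n_blobs=1)
        oracle = direct_matrix_element_oracle(grid, compact_beam, 0, 0.0, 1e-8)
        x, y = grid.x_coords, grid.y_coords
        rho = np.hypot(x[:, None], y[None, :])
        expected = np.sum(
            annular_amplitude(rho, compact_beam)[:, :, None] * grid.values
        ) * 0.5**3
        assert oracle == pytest.approx(expected, rel=1e-10)

    def test_channel_rate_pipeline_vs_oracle_integration(self):
        # integrate |M|^2 k dk both ways on a 32^3 grid: within 1%.
        # alpha = 60 mrad keeps k_max ~ 4.1 bohr^-1, below the Nyquist
        # limit pi/spacing of the Riemann-sum oracle on this grid
        beam = BeamParameters(r0=3.0, dr=1.0, alpha_mrad=60.0)
        grid = chiral_blob_grid()
        kin = compute_kinematics(beam)
        comps = transverse_multipoles(grid, beam, 5.0)
        compact_beam = beam
        l = 1
        ks = np.linspace(0.0, kin.k_max, 300)
        direct = np.array(
            [direct_matrix_element_oracle(grid, compact_beam, l, k, 5.0) for k in ks]
        ) / (2 * np.pi)
        rate_oracle = np.trapezoid(np.abs(direct) ** 2 * ks, ks)
        rate_pipe = channel_rate(comps, compact_beam, kin, l, n_k=300)
        assert rate_pipe == pytest.approx(rate_oracle, rel=0.01)


class TestStickBookkeeping:
    def small_transitions(self):
        g1 = multipole_cube(FixtureSpec(kind="multipole", m=1, parity="cos",
                                        npoints=24, spacing=0.6))
        g2 = multipole_cube(FixtureSpec(kind="multipole", m=2, parity="cos",
                                        npoints=24, spacing=0.6))
        return TransitionSet([Transition(1, 5.0, grid=g1), Transition(2, 6.1, grid=g2)])

    def test_one_stick_per_transition_and_channel(self):
        sticks = compute_sticks(self.small_transitions(), BEAM)
        assert len(sticks) == 14
        assert {s.energy_ev for s in sticks if s.n == 1} == {5.0}
        assert {s.l for s in sticks if s.n == 2} == set(range(-3, 4))

    def test_per_l_rates_independent_across_transitions(self):
        ts = self.small_transitions()
        sticks_joint = compute_sticks(ts, BEAM)
        solo = stick_rate(ts.entries[0], BEAM, 1)
        joint = next(s for s in sticks_joint if s.n == 1 and s.l == 1)
        assert joint.rate == pytest.approx(solo.rate, rel=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="no transitions"):
            compute_sticks(TransitionSet([]), BEAM)

    def test_quadratic_response(self):
        g = multipole_cube(FixtureSpec(kind="multipole", m=1, parity="cos",
                                       npoints=24, spacing=0.6))
        g3 = VolumetricGrid(g.origin, g.step, 3.0 * g.values, g.atoms, g.comments)
        r1 = stick_rate(Transition(1, 5.0, grid=g), BEAM, 1).rate
        r3 = stick_rate(Transition(1, 5.0, grid=g3), BEAM, 1).rate
        assert r3 == pytest.approx(9.0 * r1, rel=1e-10)

    def test_tiny_loss_restores_plus_minus_symmetry(self):
        # for a real potential at p ~ 0 the -+m components are conjugate,
        # so rate(+l) = rate(-l)
        grid = chiral_blob_grid(n=24, spacing=0.6)
        t = Transition(1, 1e-6, grid=grid)
        beam = BeamParameters(r0=3.0, dr=1.0)
        for l in (1, 2, 3):
            rp = stick_rate(t, beam, +l).rate
            rm = stick_rate(t, beam, -l).rate
            assert rp == pytest.approx(rm, rel=1e-6)

    def test_mirror_covariance(self):
        # reflection through a plane containing the axis swaps +l <-> -l
        grid = chiral_blob_grid(n=24, spacing=0.6)
        mirrored = mirror_cube(grid, "xz")
        beam = BeamParameters(r0=3.0, dr=1.0)
        for l in BEAM.l_values:
            r = stick_rate(Transition(1, 5.0, grid=grid), beam, l).rate
            r_mir = stick_rate(Transition(1, 5.0, grid=mirrored), beam, -l).rate
            assert r_mir == pytest.approx(r, rel=1e-6)

    def test_normalization_scales_peak_to_one(self):
        sticks = compute_sticks(self.small_transitions(), BEAM, normalize=True)
        assert max(s.rate for s in sticks) == pytest.approx(1.0, abs=1e-15)


class TestConvolution:
    def test_single_stick_marginal_widths(self):
        sticks = [OAMStick(1, 5.0, 0, 2.0)]
        e_axis = np.linspace(4.0, 6.0, 801)
        l_axis = np.linspace(-4.0, 4.0, 801)
        spec = convolve_2d(sticks, de=0.1, dl=0.5, energy_axis=e_axis, l_axis=l_axis)
        e_marg = np.trapezoid(spec.intensity, l_axis, axis=1)
        sigma_e = np.sqrt(np.trapezoid(e_marg * (e_axis - 5.0) ** 2, e_axis)
                          / np.trapezoid(e_marg, e_axis))
        assert sigma_e == pytest.approx(0.1, rel=1e-3)
        l_marg = np.trapezoid(spec.intensity, e_axis, axis=0)
        sigma_l = np.sqrt(np.trapezoid(l_marg * l_axis**2, l_axis)
                          / np.trapezoid(l_marg, l_axis))
        assert sigma_l == pytest.approx(0.5, rel=1e-3)

    def test_total_intensity_conserves_stick_mass(self):
        sticks = [OAMStick(1, 5.0, -1, 1.0), OAMStick(1, 5.0, 1, 0.5),
                  OAMStick(2, 5.8, 2, 0.25)]
        e_axis = np.linspace(5.0 - 0.8, 5.8 + 0.8, 1601)   # 8 sigma padding
        l_axis = np.linspace(-1 - 4.0, 2 + 4.0, 1601)
        spec = convolve_2d(sticks, 0.1, 0.5, e_axis, l_axis)
        total = np.trapezoid(np.trapezoid(spec.intensity, l_axis, axis=1), e_axis)
        assert total == pytest.approx(1.75, rel=1e-6)

    def test_linearity_in_sticks(self):
        one = [OAMStick(1, 5.0, 1, 0.7)]
        two = one + [OAMStick(2, 5.0, 1, 0.7)]
        e_axis = np.linspace(4, 6, 201)
        l_axis = np.linspace(-3, 3, 201)
        s1 = convolve_2d(one, 0.1, 0.5, e_axis, l_axis)
        s2 = convolve_2d(two, 0.1, 0.5, e_axis, l_axis)
        np.testing.assert_allclose(s2.intensity, 2.0 * s1.intensity, rtol=1e-14)

    def test_fwhm_flag_narrows_kernel(self):
        sticks = [OAMStick(1, 5.0, 0, 1.0)]
        e_axis = np.linspace(4, 6, 2001)
        l_axis = np.linspace(-3, 3, 201)
        s_sigma = convolve_2d(sticks, 0.1, 0.5, e_axis, l_axis)
        s_fwhm = convolve_2d(sticks, 0.1, 0.5, e_axis, l_axis, resolution_is_fwhm=True)
        assert s_fwhm.intensity.max() > 2.0 * s_sigma.intensity.max()

    def test_clipped_axes_warn(self):
        sticks = [OAMStick(1, 5.0, 0, 1.0)]
        with pytest.warns(UserWarning, match="clip"):
            convolve_2d(sticks, 0.1, 0.5, np.linspace(4.99, 5.01, 11),
                        np.linspace(-0.1, 0.1, 11))


class TestDichroism:
    def test_two_to_one_ratio_gives_33_percent(self):
        sticks = [OAMStick(1, 5.0, 1, 2.0), OAMStick(1, 5.0, -1, 1.0)]
        d = dichroism(sticks, 1)
        defined = d.values[~d.mask]
        np.testing.assert_allclose(defined, 100.0 / 3.0, rtol=1e-10)
        assert dichroism_sticks(sticks, 1)[0][2] == pytest.approx(100.0 / 3.0)

    def test_achiral_mirror_symmetric_potential_has_zero_dichroism(self):
        grid = multipole_cube(FixtureSpec(kind="multipole", m=1, parity="cos",
                                          npoints=32, spacing=0.5))
        sticks = compute_sticks(TransitionSet([Transition(1, 5.0, grid=grid)]),
                                BeamParameters(r0=3.0, dr=1.0))
        d = dichroism(sticks, 1)
        assert np.all(np.abs(d.values[~d.mask]) < 1e-6)

    def test_enantiomer_pair_gives_mirror_spectra(self):
        grid = chiral_blob_grid(n=24, spacing=0.6)
        beam = BeamParameters(r0=3.0, dr=1.0)
        s_l = compute_sticks(TransitionSet([Transition(1, 5.0, grid=grid)]), beam)
        s_d = compute_sticks(
            TransitionSet([Transition(1, 5.0, grid=mirror_cube(grid, "xz"))]), beam
        )
        axis = np.linspace(4.5, 5.5, 101)
        d_l = dichroism(s_l, 1, energy_axis=axis)
        d_r = dichroism(s_d, 1, energy_axis=axis)
        ok = ~(d_l.mask | d_r.mask)
        assert ok.any()
        np.testing.assert_allclose(d_l.values[ok], -d_r.values[ok], atol=1e-6)

    def test_empty_channels_are_masked_not_zero(self):
        sticks = [OAMStick(1, 5.0, 1, 1.0), OAMStick(1, 5.0, -1, 1.0)]
        d = dichroism(sticks, 1, energy_axis=np.linspace(0.0, 10.0, 101))
        assert d.mask[0] and d.mask[-1]          # far tails undefined
        assert np.all(np.isnan(d.values[d.mask]))
        center = np.argmin(np.abs(d.energies - 5.0))
        assert not d.mask[center]
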