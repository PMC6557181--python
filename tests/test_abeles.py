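"""Matrix-formalism reflectivity engine against closed-form oracles and
physical invariants."""

import numpy as np
import pytest

import reflift as rl
from reflift.abeles import (
    LayerStack,
    nevot_croce_reflectivity,
    reflectivity,
    resolution_offsets,
    smear_resolution,
    wavevector,
)

SI = 2.07e-6
D2O = 6.35e-6
QC_SI_D2O = 4 * np.sqrt(np.pi * (D2O - SI))  # ~0.01467 1/A


def fresnel_reflectivity(q, rho0, rho1):
    """Closed-form single-interface Fresnel R, independent of the engine."""
    q = np.asarray(q, dtype=float)
    k0 = q / 2
    k1 = np.sqrt((q / 2) ** 2 - 4 * np.pi * (rho1 - rho0) + 0j)
    return np.abs((k0 - k1) / (k0 + k1)) ** 2


def slab_reflectivity(q, rho0, rho1, rho2, t):
    """Closed-form two-interface interference formula (Parratt for one
    slab), independent of the matrix product."""
    q = np.asarray(q, dtype=float)
    k0 = q / 2 + 0j
    k1 = np.sqrt((q / 2) ** 2 - 4 * np.pi * (rho1 - rho0) + 0j)
    k2 = np.sqrt((q / 2) ** 2 - 4 * np.pi * (rho2 - rho0) + 0j)
    r01 = (k0 - k1) / (k0 + k1)
    r12 = (k1 - k2) / (k1 + k2)
    ph = np.exp(2j * k1 * t)
    return np.abs((r01 + r12 * ph) / (1 + r01 * r12 * ph)) ** 2


class TestWavevector:
    def test_zero_contrast_gives_half_q(self):
        q = np.array([0.01, 0.1, 0.3])
        np.testing.assert_allclose(wavevector(q, SI, SI), q / 2)

    def test_evanescent_below_critical_edge(self):
        k = wavevector(0.01, D2O, SI)
        assert 0.01 < QC_SI_D2O  # the radicand is negative here
        assert k.real == pytest.approx(0.0, abs=1e-18)
        assert k.imag > 0

    def test_high_q_asymptote(self):
        q = 50 * QC_SI_D2O
        assert wavevector(q, D2O, SI).real == pytest.approx(q / 2, rel=1e-2)


class TestReflectivity:
    def test_single_interface_matches_fresnel(self):
        stack = LayerStack(np.zeros(0), np.array([SI, D2O]))
        q = np.geomspace(0.005, 0.3, 60)
        np.testing.assert_allclose(
            reflectivity(stack, q), fresnel_reflectivity(q, SI, D2O),
            rtol=1e-10, atol=1e-300,
        )

    def test_total_reflection_below_critical_edge(self):
        stack = LayerStack(np.zeros(0), np.array([SI, D2O]))
        q = np.linspace(0.002, 0.95 * QC_SI_D2O, 20)
        np.testing.assert_allclose(reflectivity(stack, q), 1.0, rtol=1e-12)

    def test_uniform_medium_reflects_nothing(self):
        stack = LayerStack(np.array([40.0, 60.0]), np.full(4, 3e-6))
        assert np.all(reflectivity(stack, np.geomspace(0.01, 0.3, 30)) == 0)

    def test_single_slab_matches_two_interface_formula(self):
        stack = LayerStack(np.array([50.0]), np.array([SI, 4e-6, D2O]))
        q = np.geomspace(0.004, 0.3, 80)
        np.testing.assert_allclose(
            reflectivity(stack, q), slab_reflectivity(q, SI, 4e-6, D2O, 50.0),
            rtol=1e-10,
        )

    def test_nonpositive_q_rejected(self):
        stack = LayerStack(np.zeros(0), np.array([SI, D2O]))
        with pytest.raises(ValueError):
            reflectivity(stack, np.array([-0.1]))

    def test_energy_bound_on_random_stacks(self):
        rng = np.random.default_rng(42)
        q = np.geomspace(0.003, 0.4, 25)
        for _ in range(1000):
            L = rng.integers(0, 8)
            stack = LayerStack(
                rng.uniform(5, 300, L), rng.uniform(-1e-6, 7e-6, L + 2)
            )
            r = reflectivity(stack, q)
            assert np.all(r >= 0) and np.all(r <= 1 + 1e-12)

    def test_reciprocity_of_reversed_stacks(self):
        # |R| is direction-independent for lossless media once the waves in
        # both half-spaces propagate, i.e. above every critical edge
        rng = np.random.default_rng(7)
        for _ in range(50):
            L = rng.integers(1, 6)
            thick = rng.uniform(10, 200, L)
            slds = rng.uniform(-0.5e-6, 6.5e-6, L + 2)
            qc = 4 * np.sqrt(np.pi * (slds.max() - min(slds[0], slds[-1])))
            q = np.geomspace(1.3 * qc, 0.4, 40)
            # q is measured in the fronting medium: the reversed experiment
            # probes the same mode at the energy-matched momentum transfer
            q_rev = 2 * np.sqrt((q / 2) ** 2 + 4 * np.pi * (slds[0] - slds[-1]))
            fwd = reflectivity(LayerStack(thick, slds), q)
            rev = reflectivity(LayerStack(thick[::-1], slds[::-1]), q_rev)
            np.testing.assert_allclose(fwd, rev, rtol=1e-8, atol=1e-14)


class TestNevotCroce:
    def test_zero_roughness_is_identity(self):
        thick = np.array([50.0, 80.0])
        slds = np.array([SI, 5e-6, 1e-6, D2O])
        sharp = LayerStack(thick, slds)
        rough = LayerStack(thick, slds, roughnesses=np.zeros(3))
        q = np.geomspace(0.005, 0.3, 50)
        np.testing.assert_allclose(
            nevot_croce_reflectivity(rough, q), reflectivity(sharp, q), rtol=1e-12
        )

    def test_single_interface_gaussian_damping(self):
        sig = 6.0
        stack = LayerStack(np.zeros(0), np.array([SI, D2O]), np.array([sig]))
        q = np.geomspace(5 * QC_SI_D2O, 0.3, 30)
        k0 = q / 2
        k1 = np.sqrt((q / 2) ** 2 - 4 * np.pi * (D2O - SI))
        expected = fresnel_reflectivity(q, SI, D2O) * np.exp(-4 * k0 * k1 * sig**2)
        np.testing.assert_allclose(
            nevot_croce_reflectivity(stack, q), expected, rtol=1e-10
        )

    def test_damping_monotone_in_roughness(self):
        q = np.array([0.1])
        prev = np.inf
        for sig in np.arange(0.0, 21.0, 2.0):
            stack = LayerStack(np.zeros(0), np.array([SI, D2O]), np.array([sig]))
            r = float(nevot_croce_reflectivity(stack, q)[0])
            assert r <= prev
            prev = r

    def test_negative_roughness_rejected(self):
        with pytest.raises(ValueError):
            LayerStack(np.zeros(0), np.array([SI, D2O]), np.array([-1.0]))

    def test_missing_roughness_rejected(self):
        stack = LayerStack(np.zeros(0), np.array([SI, D2O]))
        with pytest.raises(ValueError):
            nevot_croce_reflectivity(stack, np.array([0.1]))


class TestResolutionSmearing:
    def test_weights_normalised(self):
        for p in (3, 9, 17, 33):
            _, w = resolution_offsets(p)
            assert w.sum() == pytest.approx(1.0, rel=1e-14)

    def test_even_p_rejected(self):
        with pytest.raises(ValueError):
            resolution_offsets(16)

    def test_constant_curve_unchanged(self):
        q = np.geomspace(0.01, 0.3, 50)
        smeared = smear_resolution(q, np.full(50, 0.37), dq_over_q=0.1)
        np.testing.assert_allclose(smeared, 0.37, rtol=1e-12)

    def test_zero_resolution_is_identity(self):
        q = np.geomspace(0.01, 0.3, 50)
        R = np.exp(-q * 30)
        np.testing.assert_allclose(smear_resolution(q, R, 0.0), R)

    def test_kiessig_fringe_contrast_reduced_at_coarse_resolution(self):
        # 500 A slab: fringe spacing 2 pi / 500 ~ 0.0126 1/A
        stack = LayerStack(np.array([500.0]), np.array([SI, 4e-6, D2O]))
        q = np.geomspace(0.03, 0.2, 4000)
        R = reflectivity(stack, q)

        def contrast(dq):
            s = smear_resolution(q, R, dq)
            band = (q > 0.05) & (q < 0.15)
            y = np.log(q[band] ** 4 * s[band])  # detrend the q^-4 decay
            return y.max() - y.min()

        assert contrast(0.10) < 0.35 * contrast(0.01)


class TestForwardCurve:
    def test_output_matches_grid_length(self, truth_model, d2o_curve):
        r = rl.forward_curve(truth_model, d2o_curve)
        assert r.shape == d2o_curve.q.shape

    def test_no_contrast_anywhere_gives_zero(self):
        c = 3e-6
        q = np.geomspace(0.01, 0.25, 40)
        curve = rl.ContrastCurve(q=q, R=np.ones(40), rho_fronting=c, rho_solvent=c)
        model = rl.InterfacialModel(
            D=100.0, rho=np.full(10, c), h=np.zeros(10), sigma=4.0,
            rho_min=0.0, rho_max=1e-5,
        )
        np.testing.assert_allclose(rl.forward_curve(model, curve), 0.0, atol=1e-25)

    def test_erf_profile_agrees_with_nevot_croce_stack(self):
        """The same structure expressed as an erf-smoothed sub-layer model and
        as a rough slab stack must give matching smeared curves."""
        q = np.geomspace(0.008, 0.25, 120)
        stack_sys = rl.GroundTruthSystem(
            name="check",
            thicknesses=[50.0, 50.0, 50.0],
            dry_slds=[5e-6, 0.0, 2e-6],
            hydrations=[0.0, 0.0, 0.0],
            roughnesses=[5.0] * 4,
        )
        curves = rl.render_contrast_series(stack_sys, q_grid=q)
        d2o = curves[0]
        # model boundaries aligned with the slab interfaces: D=150, N=45
        model = rl.InterfacialModel(
            D=150.0,
            rho=np.repeat([5e-6, 0.0, 2e-6], 15),
            h=np.zeros(45),
            sigma=5.0,
        )
        rfit = rl.forward_curve(model, d2o)
        err = np.abs(np.log(rfit) - np.log(d2o.R))
        assert np.max(err) < 0.08
        assert np.sqrt(np.mean(err**2)) < 0.03
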