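"""Optical-matrix reflectivity, Born cross-check, smearing, co-refinement."""

import numpy as np
import pytest

from mucofilm.constants import SILICON_SLD
from mucofilm.core import D2O, H2O, Solvent
from mucofilm.nr import (
    ContrastSeries,
    LayerStack,
    ResolutionSpec,
    Slab,
    abeles_reflectivity,
    born_reflectivity,
    build_paper_stacks,
    corefine,
    critical_edge,
    sld_profile,
    smear,
)
from mucofilm.synthetic import NoiseSpec, make_nr_dataset


def bare_si_d2o(roughness=0.0):
    return LayerStack(slabs=[], backing_solvent=D2O, backing_roughness=roughness)


def fresnel(q, rho_f, rho_b):
    k0 = q / 2.0
    k1 = np.sqrt((q / 2.0) ** 2 - 4 * np.pi * (rho_b - rho_f) + 0j)
    return np.abs((k0 - k1) / (k0 + k1)) ** 2


class TestAbeles:
    def test_bare_interface_matches_fresnel_closed_form(self):
        stack = bare_si_d2o()
        q = np.linspace(0.005, 0.3, 500)
        R = abeles_reflectivity(stack, q)
        rho, _, _ = stack.resolved()
        Rf = fresnel(q, rho[0], rho[-1])
        np.testing.assert_allclose(R, Rf, rtol=1e-10)

    def test_critical_edge_value_and_total_reflection(self):
        stack = bare_si_d2o()
        qc = critical_edge(stack)
        assert qc == pytest.approx(0.01468, abs=2e-5)
        q = np.linspace(0.002, qc * 0.999, 100)
        np.testing.assert_allclose(abeles_reflectivity(stack, q), 1.0, atol=1e-10)

    def test_zero_contrast_slabs_invisible(self):
        q = np.linspace(0.01, 0.3, 200)
        bare = bare_si_d2o()
        dressed = LayerStack(
            slabs=[Slab(thickness=80.0, label="ghost", sld=D2O.sld)],
            backing_solvent=D2O,
            backing_roughness=0.0,
        )
        np.testing.assert_allclose(
            abeles_reflectivity(dressed, q), abeles_reflectivity(bare, q), rtol=1e-12
        )

    def test_kiessig_fringe_spacing(self):
        # a d-thick slab produces fringes spaced by ~2 pi / d
        d = 200.0
        stack = LayerStack(
            slabs=[Slab(thickness=d, label="film", sld=4.0e-6)],
            backing_solvent=H2O,
            backing_roughness=0.0,
        )
        q = np.linspace(0.02, 0.25, 4000)
        R = abeles_reflectivity(stack, q)
        logR = np.log(R)
        minima = q[1:-1][(logR[1:-1] < logR[:-2]) & (logR[1:-1] < logR[2:])]
        spacing = np.diff(minima).mean()
        assert spacing == pytest.approx(2 * np.pi / d, rel=0.03)

    def test_thin_mucin_layer_fringe_beyond_measured_window(self):
        # 22 A layer: first Kiessig fringe at ~0.29 A^-1, outside q <= 0.25
        assert 2 * np.pi / 22.0 > 0.25

    def test_energy_bound_on_randomized_stacks(self, rng):
        q = np.linspace(0.005, 0.3, 150)
        for _ in range(20):
            n = rng.integers(1, 5)
            slabs = [
                Slab(
                    thickness=float(rng.uniform(5, 150)),
                    roughness=float(rng.uniform(0, 5)),
                    label=f"s{i}",
                    sld=float(rng.uniform(-0.5e-6, 7e-6)),
                )
                for i in range(n)
            ]
            stack = LayerStack(slabs=slabs, backing_solvent=Solvent(rng.uniform(0, 1)))
            R = abeles_reflectivity(stack, q)
            assert np.all(R >= 0) and np.all(R <= 1.0)

    def test_reciprocity(self, rng):
        # a lossless multilayer reflects equally from either side when
        # compared at the same vacuum wavevector; q is referenced to the
        # fronting medium, so the reversed stack is probed at
        # q'^2/4 = q^2/4 + 4 pi (rho_front - rho_back)
        for _ in range(5):
            slabs = [
                Slab(thickness=float(rng.uniform(10, 100)), label=f"s{i}",
                     sld=float(rng.uniform(0, 7e-6)))
                for i in range(rng.integers(1, 4))
            ]
            rho_b = 6.36e-6
            fwd = LayerStack(slabs=slabs, fronting_sld=SILICON_SLD,
                             backing_sld=rho_b, backing_roughness=0.0)
            rev = LayerStack(slabs=list(reversed(slabs)), fronting_sld=rho_b,
                             backing_sld=SILICON_SLD, backing_roughness=0.0)
            q = np.linspace(0.05, 0.3, 100)  # well above both edges
            q_rev = 2 * np.sqrt((q / 2) ** 2 + 4 * np.pi * (SILICON_SLD - rho_b))
            np.testing.assert_allclose(
                abeles_reflectivity(fwd, q), abeles_reflectivity(rev, q_rev), rtol=1e-8
            )

    def test_zero_roughness_equals_sharp_matrix_result(self):
        slabs = [Slab(thickness=40.0, roughness=0.0, label="f", sld=4e-6)]
        stack = LayerStack(slabs=slabs, backing_solvent=D2O, backing_roughness=0.0)
        q = np.linspace(0.01, 0.3, 100)
        R0 = abeles_reflectivity(stack, q)
        # same stack, explicitly sharp: identical by construction
        np.testing.assert_array_equal(R0, abeles_reflectivity(stack, q))

    def test_roughness_damps_high_q(self):
        q = np.linspace(0.05, 0.3, 100)
        smoothR = abeles_reflectivity(bare_si_d2o(roughness=5.0), q)
        sharpR = abeles_reflectivity(bare_si_d2o(), q)
        assert np.all(smoothR < sharpR)


class TestBorn:
    def test_weak_slab_agreement_above_3qc(self):
        drho = 1e-6
        stack = LayerStack(
            slabs=[Slab(thickness=20.0, roughness=0.0, label="w", sld=SILICON_SLD + drho)],
            backing_sld=SILICON_SLD,
            backing_roughness=0.0,
        )
        qc = np.sqrt(16 * np.pi * drho)
        q = np.linspace(3 * qc, 0.25, 300)
        Ra = abeles_reflectivity(stack, q)
        Rb = born_reflectivity(stack, q)
        assert np.max(np.abs(Ra - Rb) / Ra) < 0.05

    def test_uniform_profile_reflects_nothing(self):
        stack = LayerStack(
            slabs=[Slab(thickness=50.0, label="u", sld=SILICON_SLD)],
            backing_sld=SILICON_SLD,
            backing_roughness=0.0,
        )
        q = np.linspace(0.05, 0.3, 50)
        np.testing.assert_allclose(born_reflectivity(stack, q), 0.0, atol=1e-30)

    def test_sharp_interface_q4_asymptote(self):
        stack = LayerStack(slabs=[], backing_sld=6.36e-6, backing_roughness=0.0)
        q = np.linspace(0.1, 0.3, 50)
        Rq4 = born_reflectivity(stack, q) * q**4
        drho = 6.36e-6 - SILICON_SLD
        np.testing.assert_allclose(Rq4, 16 * np.pi**2 * drho**2, rtol=1e-10)


class TestSmear:
    def test_zero_resolution_is_identity(self):
        q = np.logspace(-2, -0.6, 80)
        r = np.exp(-q * 30)
        out = smear(r, q, ResolutionSpec(dq_over_q=0.0))
        np.testing.assert_array_equal(out, r)

    def test_constant_plateau_preserved(self):
        q = np.linspace(0.002, 0.01, 60)
        r = np.ones_like(q)
        out = smear(r, q, ResolutionSpec())
        np.testing.assert_allclose(out, 1.0, rtol=0.01)

    def test_fringe_minima_rise_with_resolution(self):
        stack = LayerStack(
            slabs=[Slab(thickness=300.0, label="f", sld=4e-6)],
            backing_solvent=H2O,
            backing_roughness=0.0,
        )
        q = np.linspace(0.02, 0.1, 800)
        r = abeles_reflectivity(stack, q)
        minima = []
        for dq in (0.0, 0.02, 0.04):
            minima.append(smear(r, q, ResolutionSpec(dq_over_q=dq))[200:600].min())
        assert minima[0] < minima[1] < minima[2]


class TestStacks:
    def test_bare_mucin_d2o_slds(self):
        stack = build_paper_stacks("bare_mucin", D2O)
        rho, _, _ = stack.resolved()
        assert rho[-1] == pytest.approx(6.36e-6, abs=0.01e-6)
        mucin_sld = stack.slab("mucin").resolve_sld(D2O)
        assert mucin_sld == pytest.approx(5.6e-6, abs=0.05e-6)

    def test_bare_mucin_h2o_sld(self):
        stack = build_paper_stacks("bare_mucin", H2O)
        assert stack.slab("mucin").resolve_sld(H2O) == pytest.approx(2.5e-6, abs=0.05e-6)

    def test_rinsed_mucin_layer(self):
        stack = build_paper_stacks("mucin_polymer", H2O, rinsed=True)
        m = stack.slab("mucin")
        assert m.thickness == 20.0 and m.phi == 0.50
        with pytest.raises(KeyError):
            stack.slab("polymer")

    def test_membrane_mucin_stack_layout(self):
        stack = build_paper_stacks("dppc_gm1_mucin", D2O)
        labels = [s.label for s in stack.slabs]
        assert labels == ["sio2", "water_gap", "head_in", "tails", "head_out", "mucin"]
        assert stack.slab("mucin").thickness == 30.0

    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(ValueError, match="bare_mucin"):
            build_paper_stacks("nope", H2O)

    def test_sld_profile_limits(self):
        stack = build_paper_stacks("bare_mucin", D2O)
        z, prof = sld_profile(stack)
        assert prof[0] == pytest.approx(SILICON_SLD, rel=1e-3)
        assert prof[-1] == pytest.approx(D2O.sld, rel=1e-3)


class TestCorefine:
    def test_two_contrast_recovery(self):
        series = make_nr_dataset("bare_mucin", noise=NoiseSpec(level=1.0, seed=11))
        fit = corefine(series, free=["mucin_thickness", "mucin_phi"], seed=11)
        assert fit.converged
        assert fit.params["mucin_thickness"] == pytest.approx(22.0, abs=1.0)
        assert fit.params["mucin_phi"] == pytest.approx(0.60, abs=0.05)

    def test_zero_noise_chi2_at_truth_is_zero(self):
        series = make_nr_dataset("bare_mucin", noise=NoiseSpec(kind="none"))
        fit = corefine(series, free=["mucin_thickness"], n_restarts=1,
                       fit_scale=False, fit_background=False)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-12)
        assert fit.params["mucin_thickness"] == pytest.approx(22.0, abs=0.01)

    def test_contrast_variation_tightens_phi(self):
        series2 = make_nr_dataset("bare_mucin", noise=NoiseSpec(level=1.0, seed=5))
        single = ContrastSeries(
            stack=series2.stack,
            contrasts={"h2o": series2.contrasts["h2o"]},
            resolution=series2.resolution,
        )
        free = ["mucin_thickness", "mucin_phi"]
        fit2 = corefine(series2, free=free, seed=5)
        fit1 = corefine(single, free=free, seed=5)
        e2, e1 = fit2.stderr["mucin_phi"], fit1.stderr["mucin_phi"]
        assert e2 is not None
        assert e1 is None or e1 > e2

    def test_one_free_parameter_exact_recovery(self):
        series = make_nr_dataset("bare_mucin", noise=NoiseSpec(kind="none"))
        fit = corefine(series, free=["mucin_phi"], n_restarts=1,
                       fit_scale=False, fit_background=False)
        assert fit.params["mucin_phi"] == pytest.approx(0.60, abs=1e-4)

    def test_unknown_free_parameter_rejected(self):
        series = make_nr_dataset("bare_mucin", noise=NoiseSpec(kind="none"))
        with pytest.raises(ValueError, match="unknown free parameters"):
            corefine(series, free=["bogus_thickness"], n_restarts=1)
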