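"""Compartmental discretization, membrane assignment, impedance solutions."""

import math

import numpy as np
import pytest

from pcarbor.passive import (
    HUMAN_SPINES,
    MOUSE_SPINES,
    PassiveParams,
    SpineSpec,
    assign_passive,
    cm_spiny,
    cylinder_model,
    discretize,
    realized_spine_density,
    rin_step_protocol,
    scaffold_spines,
    transfer_impedance,
    transfer_impedance_many,
)
from pcarbor.synthetic import HUMAN, MOUSE, generate_morphology

from .conftest import make_morphology, straight_points


class TestCmSpiny:
    def test_large_diameter_asymptote(self):
        assert cm_spiny(100.0) == pytest.approx(2.120503, abs=1e-9)

    def test_strictly_decreasing(self):
        # strictly decreasing over the physiological range; the exponential
        # term saturates below float precision only far beyond real diameters
        d = np.linspace(0.1, 4.0, 200)
        assert np.all(np.diff(cm_spiny(d)) < 0)
        assert np.all(np.diff(cm_spiny(np.linspace(4.0, 20.0, 50))) <= 0)

    def test_spot_value(self):
        # direct evaluation at d = 0.5 µm
        expected = 11.510294 ** (-1.376463 * 0.5) + 2.120503
        assert cm_spiny(0.5) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.3066, abs=5e-4)


class TestDiscretize:
    def test_compartment_count(self):
        m = make_morphology(
            [(0, "dendrite", straight_points((0, 0, 0), (100, 0, 0), 1.0))]
        )
        model = discretize(m, max_seg_length=10.0)
        assert np.count_nonzero(model.stype == "dendrite") == 10

    def test_membrane_area_conserved(self, mouse_morph):
        from pcarbor.morphometrics import surface_area

        model = discretize(mouse_morph, 5.0)
        # point soma -> equivalent cylinder has the same (sphere) area
        expected = surface_area(mouse_morph, "all") * 1e-8
        assert model.total_area_cm2() == pytest.approx(expected, rel=1e-3)

    def test_refinement_changes_rin_below_one_percent(self, mouse_morph):
        p = PassiveParams()
        r1 = rin_step_protocol(assign_passive(discretize(mouse_morph, 10.0), p))
        r2 = rin_step_protocol(assign_passive(discretize(mouse_morph, 5.0), p))
        assert abs(r1 - r2) / r2 < 0.01

    def test_bad_seg_length_rejected(self, mouse_morph):
        with pytest.raises(ValueError):
            discretize(mouse_morph, 0.0)


class TestAssignPassive:
    def test_explicit_mode_uses_uniform_dendritic_cm(self, mouse_morph):
        model = discretize(mouse_morph, 5.0)
        imp = assign_passive(model, PassiveParams(spine_mode="implicit"))
        exp = assign_passive(model, PassiveParams(spine_mode="explicit"))
        dend = model.stype == "dendrite"
        thin = dend & (model.diameter_um < 1.6)
        cm_imp = imp.c_m[thin] / imp.area_cm2[thin] * 1e6
        cm_exp = exp.c_m[thin] / exp.area_cm2[thin] * 1e6
        assert np.allclose(cm_exp, 2.0)
        assert np.all(cm_imp > 2.0)  # spine compensation always adds capacitance

    def test_soma_constants(self, mouse_model):
        s = mouse_model.soma_index
        a = mouse_model.area_cm2[s]
        assert mouse_model.g_m[s] == pytest.approx(0.003 * a)
        assert mouse_model.c_m[s] == pytest.approx(1.0 * a * 1e-6)


class TestCableOracle:
    def test_sealed_cylinder_matches_coth_form(self):
        # independent closed form: Z = R_inf * coth(L / lambda) at DC
        params = PassiveParams()
        L_um, d_um, n = 1000.0, 2.0, 1000
        model = cylinder_model(L_um, d_um, n, params)
        z = transfer_impedance(model, 0, frequency_hz=0.0).input_mohm
        Rm = 1.0 / params.Gm_other
        d_cm = d_um * 1e-4
        rm = Rm / (math.pi * d_cm)  # Ω·cm
        ra = 4.0 * params.Ra / (math.pi * d_cm**2)  # Ω/cm
        lam = math.sqrt(rm / ra)
        z_analytic = math.sqrt(rm * ra) / math.tanh(L_um * 1e-4 / lam) / 1e6
        assert z == pytest.approx(z_analytic, rel=0.005)


class TestImpedance:
    def test_single_compartment_dc_impedance(self):
        params = PassiveParams()
        model = cylinder_model(10.0, 2.0, 1, params, Gm=params.Gm_soma)
        z = transfer_impedance(model, 0, 0.0).input_mohm
        expected = 1.0 / (params.Gm_soma * model.area_cm2[0]) / 1e6
        assert z == pytest.approx(expected, rel=1e-9)

    def test_reciprocity(self, mouse_model):
        rng = np.random.default_rng(0)
        idx = rng.choice(mouse_model.n, size=4, replace=False)
        for i, j in zip(idx[:2], idx[2:]):
            zi = transfer_impedance(mouse_model, int(i), 10.0)
            zj = transfer_impedance(mouse_model, int(j), 10.0)
            assert zi.magnitude_mohm[j] == pytest.approx(
                zj.magnitude_mohm[i], rel=1e-9
            )

    def test_magnitude_decays_away_from_source(self, mouse_model):
        src = mouse_model.n - 1  # a distal compartment
        prof = transfer_impedance(mouse_model, src, 10.0)
        z = prof.magnitude_mohm
        # orient every edge away from the source: ancestors of the source
        # point rootward, everything else pointward
        ancestors = set()
        k = src
        while k != -1:
            ancestors.add(k)
            k = mouse_model.parent[k]
        for i in range(mouse_model.n):
            p = mouse_model.parent[i]
            if p == -1:
                continue
            if i in ancestors:
                assert z[p] <= z[i] * (1 + 1e-9)
            else:
                assert z[i] <= z[p] * (1 + 1e-9)

    def test_input_impedance_bounds_transfers(self, mouse_model):
        prof = transfer_impedance(mouse_model, 0, 10.0)
        assert prof.input_mohm == pytest.approx(prof.magnitude_mohm.max())
        assert np.all(prof.magnitude_mohm > 0)

    def test_magnitude_decreases_with_frequency(self, mouse_model):
        zs = [
            transfer_impedance(mouse_model, 0, f).input_mohm
            for f in (10.0, 100.0, 1000.0)
        ]
        assert zs[0] > zs[1] > zs[2]

    def test_many_sources_match_single_solves(self, mouse_model):
        sources = [0, mouse_model.n // 2]
        many = transfer_impedance_many(mouse_model, sources, 10.0)
        for prof in many:
            single = transfer_impedance(mouse_model, prof.source, 10.0)
            assert np.allclose(prof.magnitude_mohm, single.magnitude_mohm)


class TestSpines:
    def make_spiny_section_model(self, length=50.0, diameter=0.5):
        m = make_morphology(
            [(0, "dendrite",
              straight_points((0, 0, 0), (length, 0, 0), diameter))]
        )
        params = PassiveParams(spine_mode="explicit")
        return assign_passive(discretize(m, 5.0, params), params), params

    def test_density_two_gives_expected_counts(self):
        model, params = self.make_spiny_section_model(50.0)
        out = scaffold_spines(model, MOUSE_SPINES, seed=0, params=params)
        assert out.n_spines == 100
        assert out.n == model.n + 200  # neck + head per spine

    def test_realized_density_on_synthetic_tree(self, mouse_morph):
        params = PassiveParams(spine_mode="explicit")
        model = assign_passive(discretize(mouse_morph, 5.0, params), params)
        out = scaffold_spines(model, MOUSE_SPINES, seed=3, params=params)
        assert realized_spine_density(out) == pytest.approx(2.0, abs=0.01)

    def test_total_area_includes_spines(self):
        model, params = self.make_spiny_section_model(50.0)
        out = scaffold_spines(model, MOUSE_SPINES, seed=0, params=params)
        spine_area = 100 * (
            math.pi * MOUSE_SPINES.head_diameter * MOUSE_SPINES.head_length
            + math.pi * MOUSE_SPINES.neck_diameter * MOUSE_SPINES.neck_length
        ) * 1e-8
        assert out.total_area_cm2() == pytest.approx(
            model.total_area_cm2() + spine_area, rel=1e-3
        )

    def test_spines_lower_input_impedance_at_all_frequencies(self):
        model, params = self.make_spiny_section_model(50.0)
        out = scaffold_spines(model, HUMAN_SPINES, seed=1, params=params)
        for f in (0.0, 10.0, 100.0):
            z_bare = transfer_impedance(model, 0, f).input_mohm
            z_spiny = transfer_impedance(out, 0, f).input_mohm
            assert z_spiny < z_bare

    def test_same_seed_reproduces_attachments(self):
        model, params = self.make_spiny_section_model(50.0)
        a = scaffold_spines(model, MOUSE_SPINES, seed=9, params=params)
        b = scaffold_spines(model, MOUSE_SPINES, seed=9, params=params)
        assert np.array_equal(a.parent, b.parent)

    def test_zero_density_is_a_noop_with_warning(self):
        model, params = self.make_spiny_section_model(50.0)
        spec = SpineSpec(0.35, 1.0, 0.7, 0.2, density=0.0)
        out = scaffold_spines(model, spec, seed=0, params=params)
        assert out.n == model.n
        assert "spine_warning" in out.meta


class TestRinProtocol:
    def test_single_compartment(self):
        params = PassiveParams()
        model = cylinder_model(20.0, 20.0, 1, params, Gm=params.Gm_soma)
        model.stype[0] = "soma"
        expected = 1.0 / (params.Gm_soma * model.area_cm2[0]) / 1e6
        assert rin_step_protocol(model) == pytest.approx(expected, rel=1e-9)

    def test_equals_dc_input_impedance_at_soma(self, mouse_model):
        rin = rin_step_protocol(mouse_model)
        dc = transfer_impedance(
            mouse_model, mouse_model.soma_index, 0.0
        ).input_mohm
        assert rin == pytest.approx(dc, rel=1e-3)

    def test_human_rin_below_mouse_rin(self):
        # longer dendritic trees have lower input resistance
        p = PassiveParams()
        for seed in (0, 1, 2):
            rm = rin_step_protocol(
                assign_passive(discretize(generate_morphology(MOUSE, seed), 10.0), p)
            )
            rh = rin_step_protocol(
                assign_passive(discretize(generate_morphology(HUMAN, seed), 10.0), p)
            )
            assert rh < rm
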