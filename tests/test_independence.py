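"""Co-stimulation counts, independent elements, capacity, ROI grids."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcarbor.independence import (
    build_roi_grid,
    capacity,
    capacity_sci,
    costimulated_count,
    independence_analysis,
    independence_summary,
    sample_sources,
)
from pcarbor.passive import (
    PassiveParams,
    assign_passive,
    discretize,
    transfer_impedance,
)

from .conftest import make_morphology, straight_points


@pytest.fixture(scope="module")
def spiny_model(mouse_morph=None):
    from pcarbor.synthetic import MOUSE, generate_morphology

    morph = generate_morphology(MOUSE, 7)
    return assign_passive(discretize(morph, 10.0), PassiveParams())


class TestSampleSources:
    def test_stride_over_spiny_sections(self, spiny_model):
        n_spiny = len(spiny_model.spiny_sections())
        sources = sample_sources(spiny_model, stride=20)
        assert len(sources) == -(-n_spiny // 20)  # ceil

    def test_stride_one_hits_every_section(self, spiny_model):
        assert len(sample_sources(spiny_model, 1)) == len(
            spiny_model.spiny_sections()
        )

    def test_deterministic(self, spiny_model):
        assert sample_sources(spiny_model, 20) == sample_sources(spiny_model, 20)

    def test_bad_stride_rejected(self, spiny_model):
        with pytest.raises(ValueError):
            sample_sources(spiny_model, 0)

    def test_no_spiny_dendrites_is_an_error(self):
        thick = make_morphology(
            [(0, "dendrite", straight_points((0, 0, 0), (50, 0, 0), 3.0))]
        )
        model = assign_passive(discretize(thick, 5.0), PassiveParams())
        with pytest.raises(Exception, match="spiny"):
            sample_sources(model, 1)


class TestCostimulatedCount:
    def test_zero_threshold_counts_everything(self, spiny_model):
        src = sample_sources(spiny_model, 20)[0]
        prof = transfer_impedance(spiny_model, src, 10.0)
        n = costimulated_count(prof, spiny_model, threshold_mohm=0.0)
        assert n == len(spiny_model.spiny_sections())

    def test_threshold_above_input_leaves_only_the_source(self, spiny_model):
        src = sample_sources(spiny_model, 20)[0]
        prof = transfer_impedance(spiny_model, src, 10.0)
        n = costimulated_count(
            prof, spiny_model, threshold_mohm=prof.input_mohm * 1.01
        )
        assert n == 1

    def test_monotone_in_threshold(self, spiny_model):
        src = sample_sources(spiny_model, 20)[0]
        prof = transfer_impedance(spiny_model, src, 10.0)
        counts = [
            costimulated_count(prof, spiny_model, thr)
            for thr in (1.0, 5.0, 10.0, 50.0, 500.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_two_branch_toy_matches_dense_nodal_oracle(self):
        # soma with two thin branches; the oracle solves the same nodal
        # system densely with plain numpy, independent of the sparse path
        m = make_morphology(
            [
                (0, "dendrite",
                 straight_points((0, 0, 0), (0, 200, 0), 0.5, n=5)),
                (0, "dendrite",
                 straight_points((0, 0, 0), (0, -200, 0), 0.5, n=5)),
            ]
        )
        params = PassiveParams()
        model = assign_passive(discretize(m, 20.0, params), params)
        src = model.section_compartments[model.spiny_sections()[0]][0]
        prof = transfer_impedance(model, src, 10.0)

        n = model.n
        Y = np.zeros((n, n), dtype=complex)
        omega = 2 * np.pi * 10.0
        for i in range(n):
            Y[i, i] += model.g_m[i] + 1j * omega * model.c_m[i]
            p = model.parent[i]
            if p >= 0:
                g = model.g_axial[i]
                Y[i, i] += g
                Y[p, p] += g
                Y[i, p] -= g
                Y[p, i] -= g
        rhs = np.zeros(n, dtype=complex)
        rhs[src] = 1.0
        z_dense = np.abs(np.linalg.solve(Y, rhs)) / 1e6
        assert np.allclose(prof.magnitude_mohm, z_dense, rtol=1e-9)
        for thr in (1.0, prof.input_mohm / 2, prof.input_mohm * 2):
            hot = z_dense >= thr
            oracle = len(
                {int(s) for s in np.unique(model.section_id[hot])
                 if s in set(model.spiny_sections())} | {int(model.section_id[src])}
            )
            assert costimulated_count(prof, model, thr) == oracle


class TestIndependenceSummary:
    def test_mouse_printed_inputs(self):
        counts = [31, 31, 31, 32, 31]  # mean 31.2
        res = independence_summary(counts, 250)
        assert res.mean_count == pytest.approx(31.2)
        assert res.n_independent == pytest.approx(8.0, abs=0.05)
        assert res.capacity == 256

    def test_human_printed_inputs(self):
        counts = [15] * 7 + [14] * 3  # mean 14.7
        res = independence_summary(counts, 750)
        assert res.n_independent == pytest.approx(51.0, abs=0.1)
        assert res.capacity == 2**51

    def test_fully_coupled_tree(self):
        res = independence_summary([100, 100], 100)
        assert res.n_independent == 1.0
        assert res.capacity == 2

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            independence_summary([], 10)

    def test_count_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            independence_summary([20], 10)


class TestCapacity:
    @pytest.mark.parametrize("n, expected", [(0, 1), (8, 256),
                                             (51, 2251799813685248)])
    def test_exact_powers(self, n, expected):
        assert capacity(n) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            capacity(-1)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(n=st.integers(0, 600))
    def test_log2_inverts_capacity_exactly(self, n):
        k = capacity(n)
        assert k.bit_length() - 1 == n
        assert capacity(n + 1) > k  # strict monotonicity

    def test_scientific_form_truncates_mantissa(self):
        assert capacity_sci(capacity(51)) == "2.2e15"
        assert capacity_sci(256) == "2.5e2"
        assert capacity_sci(8) == "8"


class TestRoiGrid:
    def two_by_two_morph(self):
        # spiny dendrites spanning a 60x60 µm footprint
        return make_morphology(
            [
                (0, "dendrite",
                 straight_points((-29, -29, 0), (29, -29, 0), 0.5, n=30)),
                (0, "dendrite",
                 straight_points((-29, 29, 0), (29, 29, 0), 0.5, n=30)),
            ]
        )

    def test_four_cells_for_60um_extent(self):
        grid = build_roi_grid(self.two_by_two_morph(), cell_side=30.0)
        assert grid.n_cells == 4

    def test_membership_partitions_all_spiny_points(self):
        m = self.two_by_two_morph()
        grid = build_roi_grid(m, cell_side=30.0)
        members = [p for cell in grid.cells.values() for p in cell]
        total_points = sum(len(s.points) for s in m.dendrites())
        assert len(members) == total_points
        assert len(set(members)) == total_points  # no duplicates

    def test_thirty_percent_subsample_is_reproducible(self):
        m = make_morphology(
            [(0, "dendrite",
              straight_points((0, 0, 0), (25, 0, 0), 0.5, n=100))]
        )
        grid = build_roi_grid(m, cell_side=30.0)
        cell = next(iter(grid.cells))
        sub1 = grid.subsample(cell, 0.3, seed=1)
        sub2 = grid.subsample(cell, 0.3, seed=1)
        assert len(sub1) == 30
        assert sub1 == sub2

    def test_degenerate_extent_rejected(self):
        m = make_morphology(
            [(0, "dendrite",
              [p for p in straight_points((0, 0, 0), (0, 0, 1e-12), 0.5)])]
        )
        with pytest.raises(Exception):
            build_roi_grid(m, cell_side=30.0)


def test_analysis_is_internally_consistent(spiny_model):
    res = independence_analysis(spiny_model, stride=20)
    assert res.n_sources == len(sample_sources(spiny_model, 20))
    assert 1 <= min(res.counts) and max(res.counts) <= res.n_spiny_dendrites
    assert res.n_independent == pytest.approx(
        res.n_spiny_dendrites / res.mean_count
    )
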