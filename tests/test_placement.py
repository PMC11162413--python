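"""Layout constraints, fitness, and the evolutionary search."""

import numpy as np
import pytest

from macchiato.catalog import device_for, paper_gate_catalog, pinned_design
from macchiato.placement import (
    EAConfig,
    LayoutNode,
    LayoutSpec,
    fitness,
    geometric_feasibility_report,
    optimize_layout,
    simulate_layout,
)


def _gate(label):
    return next(g for g in paper_gate_catalog() if g.label == label)


def _layout(nodes, bounds=(35.0, 35.0)):
    return LayoutSpec(tuple(LayoutNode(r, i, p) for r, i, p in nodes), bounds=bounds)


@pytest.fixture(scope="module")
def or_gate():
    return _gate("OR")


@pytest.fixture(scope="module")
def or_design(or_gate):
    return pinned_design(or_gate)


@pytest.fixture(scope="module")
def or_device(or_gate, coarse_grid):
    return device_for(or_gate, grid=coarse_grid)


class TestLayoutSpec:
    def test_off_lattice_rejected(self):
        with pytest.raises(ValueError, match="lattice"):
            _layout([("input", "A", (1.0, 0.0))])

    def test_separation_enforced(self):
        with pytest.raises(ValueError, match="apart"):
            _layout([("input", "A", (0.0, 0.0)), ("input", "B", (0.0, 0.0))])

    def test_bounds_enforced(self):
        with pytest.raises(ValueError, match="bounds"):
            _layout([("input", "A", (36.0, 0.0))])


class TestFitness:
    def test_receiver_far_from_inputs_nonpositive(self, or_design, or_device):
        lay = _layout(
            [
                ("input", "A", (0.0, 0.0)),
                ("input", "B", (9.0, 0.0)),
                ("receiver", "R0", (31.5, 31.5)),
            ]
        )
        assert fitness(lay, or_design, or_device) <= 0.0

    def test_good_or_layout_positive_and_deterministic(self, or_design, or_device):
        lay = _layout(
            [
                ("input", "A", (13.5, 18.0)),
                ("input", "B", (22.5, 18.0)),
                ("receiver", "R0", (18.0, 18.0)),
            ]
        )
        f1 = fitness(lay, or_design, or_device)
        f2 = fitness(lay, or_design, or_device)
        assert f1 > 0
        assert f1 == f2


class TestOptimizeLayout:
    def test_or_gate_end_to_end(self, or_design, or_device):
        ea = EAConfig(population=12, generations=8, seed=5)
        layout, trace = optimize_layout(or_design, ea, or_device)
        res = simulate_layout(layout, or_design, or_device)
        assert res.truth_table.outputs == or_design.target.outputs
        assert res.score > 1

    def test_reproducible_with_same_seed(self, or_design, or_device):
        ea = EAConfig(population=10, generations=5, seed=11)
        lay1, tr1 = optimize_layout(or_design, ea, or_device)
        lay2, tr2 = optimize_layout(or_design, ea, or_device)
        assert tr1 == tr2
        assert [n.position for n in lay1.nodes] == [n.position for n in lay2.nodes]

    def test_best_fitness_monotone_elitism(self, or_design, or_device):
        ea = EAConfig(population=10, generations=8, seed=2)
        _, trace = optimize_layout(or_design, ea, or_device)
        assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_beats_random_layouts(self, or_design, or_device, coarse_grid):
        from macchiato.placement import _design_ids_roles, _lattice_size, _repair, _to_layout

        ea = EAConfig(population=12, generations=8, seed=3)
        layout, trace = optimize_layout(or_design, ea, or_device)
        rng = np.random.default_rng(99)
        ids_roles = _design_ids_roles(or_design)
        nlat = _lattice_size(or_device)
        cache = {}
        best_random = -np.inf
        for _ in range(100):
            g = _repair(
                rng.integers(0, nlat, size=(len(ids_roles), 2)), or_device, rng
            )
            lay = _to_layout(g, ids_roles, or_device)
            best_random = max(
                best_random, fitness(lay, or_design, or_device, field_cache=cache)
            )
        assert trace[-1] >= best_random

    def test_xor_beats_random_layouts(self, coarse_grid):
        from macchiato.placement import _design_ids_roles, _lattice_size, _repair, _to_layout

        gate = _gate("XOR")
        design = pinned_design(gate)
        cfg = device_for(gate, grid=coarse_grid)
        ea = EAConfig(population=12, generations=8, seed=3)
        _, trace = optimize_layout(design, ea, cfg)
        rng = np.random.default_rng(7)
        ids_roles = _design_ids_roles(design)
        nlat = _lattice_size(cfg)
        cache = {}
        best_random = max(
            fitness(
                _to_layout(
                    _repair(rng.integers(0, nlat, size=(3, 2)), cfg, rng),
                    ids_roles,
                    cfg,
                ),
                design,
                cfg,
                field_cache=cache,
            )
            for _ in range(100)
        )
        assert trace[-1] >= best_random


class TestFeasibilityReport:
    def test_single_receiver_open_lattice_no_flags(self, or_design, or_device):
        ea = EAConfig(population=12, generations=8, seed=5)
        layout, _ = optimize_layout(or_design, ea, or_device)
        reports = geometric_feasibility_report(or_design, layout, or_device)
        assert len(reports) == 1
        assert reports[0].matches_design
        assert len(reports[0].achieved_contributions) == 2

    def test_conflicting_design_is_flagged(self, or_design, or_device):
        # receiver stranded far from both inputs cannot express its table
        lay = _layout(
            [
                ("input", "A", (0.0, 0.0)),
                ("input", "B", (9.0, 0.0)),
                ("receiver", "R0", (31.5, 31.5)),
            ]
        )
        reports = geometric_feasibility_report(or_design, lay, or_device)
        assert not reports[0].matches_design
        assert reports[0].mismatched_states

    def test_empty_design_empty_report(self, or_device):
        from macchiato.logic import tt_from_hex
        from macchiato.minimize import MacchiatoDesign

        empty = MacchiatoDesign(target=tt_from_hex(0, 2), receivers=())
        assert geometric_feasibility_report(empty, _layout([]), or_device) == []
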