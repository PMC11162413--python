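"""Reaction-diffusion solver, colony response, gate maps and predictions."""

import numpy as np
import pytest

from macchiato.axis import ActivationFunction
from macchiato.simulator import (
    ColonySpec,
    DoseResponse,
    SimGrid,
    SourceSpec,
    colony_dynamics,
    committed_fold_change,
    gate_map,
    predict_gate,
    simulate_field,
    total_amount,
)


class TestGridValidation:
    def test_stability_guard_names_limit(self):
        with pytest.raises(ValueError, match="spacing\\^2"):
            SimGrid(spacing=0.25, dt=1.0, D=1.4)

    def test_position_outside_domain(self):
        grid = SimGrid(extent=(10, 10), spacing=0.5, dt=0.04)
        with pytest.raises(ValueError, match="outside"):
            grid.index_of((12.0, 5.0))


class TestDiffusionField:
    def test_mass_conservation_no_flux(self, fine_grid):
        snaps = simulate_field(
            fine_grid, [SourceSpec((17.5, 17.5), dose=7.5)], 6.0,
            snapshot_times=[1.0, 3.0, 6.0],
        )
        for f in snaps.values():
            assert total_amount(fine_grid, f) == pytest.approx(7.5, rel=1e-6)
            assert f.min() >= 0.0

    def test_absorbing_boundary_loses_mass(self):
        grid = SimGrid(extent=(10, 10), spacing=0.5, dt=0.04, boundary="absorbing")
        snaps = simulate_field(grid, [SourceSpec((5, 5), dose=1.0)], 20.0)
        assert total_amount(grid, snaps[20.0]) < 0.5

    def test_superposition(self, coarse_grid):
        a = SourceSpec((13.5, 17.5), dose=7.5)
        b = SourceSpec((22.5, 17.5), dose=7.5)
        fa = simulate_field(coarse_grid, [a], 4.0)[4.0]
        fb = simulate_field(coarse_grid, [b], 4.0)[4.0]
        fab = simulate_field(coarse_grid, [a, b], 4.0)[4.0]
        assert np.allclose(fa + fb, fab, atol=1e-12)

    def test_matches_analytic_gaussian_kernel(self, fine_grid):
        dose, t, D = 7.5, 3.0, fine_grid.D
        f = simulate_field(fine_grid, [SourceSpec((17.5, 17.5), dose=dose)], t)[t]
        ys, xs = fine_grid.coords()
        yy, xx = np.meshgrid(ys, xs, indexing="ij")
        r2 = (xx - 17.5) ** 2 + (yy - 17.5) ** 2
        kernel = dose / (4 * np.pi * D * t) * np.exp(-r2 / (4 * D * t))
        rmse = np.sqrt(np.mean((f - kernel) ** 2))
        assert rmse < 0.01 * kernel.max()

    def test_decay_reduces_mass(self):
        grid = SimGrid(extent=(20, 20), spacing=0.5, dt=0.04, decay_rate=0.5)
        snaps = simulate_field(grid, [SourceSpec((10, 10), dose=1.0)], 2.0)
        # forward-Euler decay: matches exp(-kt) to first order in dt
        assert total_amount(grid, snaps[2.0]) == pytest.approx(
            np.exp(-0.5 * 2.0), rel=2e-2
        )

    def test_sender_source_accumulates(self, coarse_grid):
        s = SourceSpec((17.5, 17.5), "sender", dose=0.0, production_rate=1.25)
        snaps = simulate_field(coarse_grid, [s], 6.0, snapshot_times=[3.0, 6.0])
        m3 = total_amount(coarse_grid, snaps[3.0])
        m6 = total_amount(coarse_grid, snaps[6.0])
        assert m3 == pytest.approx(1.25 * 3, rel=1e-6)
        assert m6 == pytest.approx(1.25 * 6, rel=1e-6)


class TestColonyDynamics:
    def _colony(self, kind="highpass", **kw):
        dr = DoseResponse(kind) if kind != "bandpass" else DoseResponse(
            "bandpass", K_act=0.005, n_act=8, K_rep=0.0175, n_rep=12
        )
        return ColonySpec((0.0, 0.0), dr, **kw)

    def test_zero_concentration_gives_basal_accumulation(self):
        col = self._colony()
        times = np.linspace(0, 20, 201)
        fl = colony_dynamics(col, times, np.zeros_like(times))
        # pure basal expression: fluorescence = basal * integrated biomass
        expected = col.response.basal * np.trapezoid(col.biomass(times), times)
        assert fl[-1] == pytest.approx(expected, rel=1e-3)

    def test_monotone_nondecreasing(self):
        col = self._colony()
        times = np.linspace(0, 20, 201)
        conc = 0.05 * np.exp(-((times - 5) ** 2))
        fl = colony_dynamics(col, times, conc)
        assert (np.diff(fl) >= -1e-12).all()

    def test_saturating_concentration_approaches_vmax_rate(self):
        col = self._colony()
        times = np.linspace(0, 20, 201)
        fl = colony_dynamics(col, times, np.full_like(times, 100.0))
        expected = col.response.v_max * np.trapezoid(col.biomass(times), times)
        assert fl[-1] == pytest.approx(expected, rel=1e-2)

    def test_bandpass_peaks_at_intermediate_dose(self):
        dr = DoseResponse("bandpass", K_act=0.005, n_act=8, K_rep=0.0175, n_rep=12)
        mid = np.sqrt(dr.K_act * dr.K_rep)
        assert dr.rate(mid) > dr.rate(0.0)
        assert dr.rate(mid) > dr.rate(100 * dr.K_rep)

    def test_commitment_freezes_late_changes(self):
        col = self._colony(commit_time=6.0)
        times = np.linspace(0, 20, 201)
        base = np.full_like(times, 0.05)
        late_spike = base.copy()
        late_spike[times > 10] = 5.0  # after commitment: must not matter
        fl_a = colony_dynamics(col, times, base)
        fl_b = colony_dynamics(col, times, late_spike)
        assert fl_a[-1] == pytest.approx(fl_b[-1], rel=1e-9)


class TestGateMap:
    def test_far_pixel_is_false(self, coarse_grid):
        act = ActivationFunction("highpass", 0.009)
        codes = gate_map(
            coarse_grid, [(13.5, 13.5), (22.5, 13.5)], act, t_read=6.0
        )
        assert codes[coarse_grid.index_of((34.0, 34.0))] == 0x0

    def test_or_to_and_transition_with_separation(self, coarse_grid):
        act = ActivationFunction("highpass", 0.009)
        seq = []
        for sep in (9.0, 13.5, 18.0, 22.5):
            codes = gate_map(
                coarse_grid,
                [(17.5 - sep / 2, 17.5), (17.5 + sep / 2, 17.5)],
                act,
                t_read=6.0,
            )
            seq.append(int(codes[coarse_grid.index_of((17.5, 17.5))]))
        assert 0x7 in seq and 0x1 in seq  # OR near, AND far
        assert seq.index(0x1) > seq.index(0x7)
        # monotone: never back to OR after reaching AND
        after_and = seq[seq.index(0x1):]
        assert 0x7 not in after_and

    def test_bandpass_map_contains_xor(self, coarse_grid):
        act = ActivationFunction("bandpass", 0.0026, 0.027)
        codes = gate_map(
            coarse_grid, [(13.5, 17.5), (21.5 + 0.5, 17.5)], act, t_read=6.0
        )
        assert (codes == 0x6).any()

    def test_ring_radius_grows_with_dose(self, coarse_grid):
        act = ActivationFunction("bandpass", 0.0026, 0.027)
        radii = []
        for dose in (2.0, 7.5, 20.0):
            codes = gate_map(coarse_grid, [(17.5, 17.5)], act, t_read=6.0, dose=dose)
            on = np.argwhere(codes == 0x1)  # ON only when the input is present
            ys, xs = coarse_grid.coords()
            d = np.hypot(ys[on[:, 0]] - 17.5, xs[on[:, 1]] - 17.5)
            radii.append(d.max())
        assert radii[0] < radii[1] < radii[2]

    def test_pixel_gates_realizable_with_same_kind(self, coarse_grid):
        from macchiato.axis import realizable_codes

        act = ActivationFunction("bandpass", 0.0026, 0.027)
        codes = gate_map(
            coarse_grid, [(13.5, 17.5), (22.0, 17.5)], act, t_read=6.0
        )
        ok = realizable_codes(2, {"bandpass"})
        assert {int(c) for c in np.unique(codes)} <= set(ok)


class TestPredictGate:
    def test_or_layout(self, coarse_grid):
        dr = DoseResponse("highpass", K_act=0.034, n_act=4)
        col = ColonySpec((17.5, 17.5), dr)
        sources = [
            SourceSpec((13.5, 17.5), dose=7.5),
            SourceSpec((21.5 + 0.5, 17.5), dose=7.5),
        ]
        res = predict_gate(coarse_grid, sources, [col], t_read=20.0)
        assert res.truth_table.to_hex() == 0x7
        assert res.score > 1
        assert res.fold_changes[0][0] == 1.0

    def test_all_off_fold_changes_are_one(self, coarse_grid):
        dr = DoseResponse("highpass", K_act=0.034, n_act=4)
        cols = [ColonySpec((10, 10), dr), ColonySpec((20, 20), dr)]
        sources = [SourceSpec((13.5, 13.5)), SourceSpec((22.5, 22.5))]
        res = predict_gate(coarse_grid, sources, cols)
        assert all(f == 1.0 for f in res.fold_changes[0])

    def test_committed_fold_change_ratio(self):
        dr = DoseResponse("highpass", K_act=0.034, n_act=4)
        col = ColonySpec((0, 0), dr)
        assert committed_fold_change(col, 0.0) == pytest.approx(1.0)
        assert committed_fold_change(col, 1.0) == pytest.approx(
            float(dr.rate(1.0) / dr.rate(0.0))
        )
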