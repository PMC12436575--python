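"""The gated remodeling algorithm: stimulus, Euler update, gate, full loop."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteogrow import (PoreSpec, PorousDomain, RemodelingParams,
                       compute_stimulus, density_to_modulus, euler_update,
                       extract_anchor_submesh, find_pore_islands,
                       gate_eligibility, ingrowth_metrics, mesh_domain,
                       run_ingrowth)
from osteogrow.ingrowth import _GROW_EPS
from osteogrow.porous_geometry import VOID

P = RemodelingParams()


class TestStimulus:
    def test_reference_stimulus_at_bone_density(self):
        # U = 0.004 J/cm^3 at rho = 1 g/cm^3 gives exactly the homeostatic k
        assert compute_stimulus(np.array([0.004]), np.array([1.0]))[0] == P.k

    def test_arithmetic_and_zero(self):
        np.testing.assert_allclose(
            compute_stimulus(np.array([0.0008, 0.0]), np.array([0.2, 0.5])),
            [0.004, 0.0])

    def test_density_floored_before_division(self):
        S = compute_stimulus(np.array([1.0]), np.array([1e-9]), rho_min=0.01)
        assert S[0] == pytest.approx(100.0)


class TestEulerUpdate:
    def test_apposition_branch_hand_value(self):
        rho = euler_update(np.array([0.01]), np.array([0.0050]), P)
        assert rho[0] == pytest.approx(0.01 + 0.01 * (0.0050 - 0.0044), abs=1e-12)

    def test_lazy_zone_is_a_no_op(self):
        for S in (0.0037, 0.0040, 0.0042, 0.00439):
            assert euler_update(np.array([0.5]), np.array([S]), P)[0] == 0.5

    def test_resorption_clamped_at_lower_bound(self):
        rho = euler_update(np.array([0.01]), np.array([0.0010]), P)
        assert rho[0] == P.rho_min  # raw update would fall below the bound

    def test_resorption_branch_hand_value(self):
        rho = euler_update(np.array([0.5]), np.array([0.0010]), P)
        assert rho[0] == pytest.approx(0.5 + 0.01 * (0.0010 - 0.0036), abs=1e-12)

    def test_step_limiter_caps_stiff_updates(self):
        rho = euler_update(np.array([0.01]), np.array([1e4]), P)
        assert rho[0] == pytest.approx(0.01 + P.max_density_step)
        loose = RemodelingParams(max_density_step=None)
        assert euler_update(np.array([0.01]), np.array([1e4]), loose)[0] == P.rho_max

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(rho=st.floats(0.01, 1.7), S=st.floats(0, 10),
           S2=st.floats(0, 10))
    def test_bounds_and_monotonicity(self, rho, S, S2):
        a = euler_update(np.array([rho]), np.array([S]), P)[0]
        b = euler_update(np.array([rho]), np.array([S2]), P)[0]
        assert P.rho_min <= a <= P.rho_max
        if S <= S2:
            assert a <= b + 1e-15


class TestDensityModulusLaw:
    def test_calibration_points(self):
        assert density_to_modulus(0.01) == pytest.approx(0.05, rel=1e-12)
        assert density_to_modulus(0.8) == pytest.approx(1940.48, rel=1e-12)

    def test_intermediate_value_hand_checked(self):
        # gamma = ln(1940.48/0.05)/ln(80) = 2.4113; E(0.4) = 1940.48 * 2^-gamma
        assert density_to_modulus(0.4) == pytest.approx(364.6, rel=2e-3)

    def test_floor_below_dummy(self):
        assert density_to_modulus(0.001) == 0.05


class TestGate:
    def _base(self, fan_mesh):
        rho0 = np.full(6, 0.01)
        iface = np.array([0])  # element 0 plays the bone-interface element
        return rho0, iface

    def test_first_iteration_interface_only(self, fan_mesh):
        rho0, iface = self._base(fan_mesh)
        el = gate_eligibility(1, fan_mesh, rho0, rho0, iface, P)
        assert el[0] and el.sum() == 1

    def test_neighbor_growth_unlocks_fan_center(self, fan_mesh):
        rho0, iface = self._base(fan_mesh)
        prev = gate_eligibility(1, fan_mesh, rho0, rho0, iface, P)
        rho = rho0.copy()
        rho[1] = 0.02  # neighbour 1 of the central element has grown
        el = gate_eligibility(2, fan_mesh, rho, rho0, iface, P, prev)
        assert el[3]  # element 3 neighbours {1, 2, 5}
        assert not el[4]  # element 4 does not neighbour element 1

    def test_strict_gate_needs_25_percent_rise(self, fan_mesh):
        rho0, iface = self._base(fan_mesh)
        params = RemodelingParams(alpha_gate=1.25)
        prev = gate_eligibility(1, fan_mesh, rho0, rho0, iface, params)
        rho = rho0.copy()
        rho[1] = 1.2 * 0.01  # only a 20% rise: below the 1.25 threshold
        el = gate_eligibility(2, fan_mesh, rho, rho0, iface, params, prev)
        assert not el[3]
        rho[1] = 1.26 * 0.01
        el = gate_eligibility(2, fan_mesh, rho, rho0, iface, params, prev)
        assert el[3]

    def test_eligibility_is_permanent(self, fan_mesh):
        rho0, iface = self._base(fan_mesh)
        prev = gate_eligibility(1, fan_mesh, rho0, rho0, iface, P)
        rho = rho0.copy()
        rho[1] = 0.02
        el2 = gate_eligibility(2, fan_mesh, rho, rho0, iface, P, prev)
        rho[1] = 0.01  # density falls back; eligibility must persist
        el3 = gate_eligibility(3, fan_mesh, rho, rho0, iface, P, el2)
        assert np.all(el3 >= el2)


def _void_bfs_layers(mesh, sources):
    """Independent oracle: adjacency-graph distance through VOID elements."""
    layer = {int(s): 0 for s in sources}
    dq = deque(layer)
    while dq:
        e = dq.popleft()
        for n in mesh.neighbors(e):
            n = int(n)
            if mesh.region[n] == VOID and n not in layer:
                layer[n] = layer[e] + 1
                dq.append(n)
    return layer


class TestRunIngrowth:
    def test_zero_load_means_zero_growth(self, small_porous):
        _, mesh = small_porous
        sub = extract_anchor_submesh(mesh)
        hist = run_ingrowth(sub, 0.0, RemodelingParams(max_iterations=5))
        assert np.all(hist.grown_count == 0)
        assert np.all(hist.depth_mm == 0.0)
        assert np.all(hist.added_mass_g == 0.0)

    def test_densities_bounded_and_growth_monotone(self, small_ingrowth):
        sub, params, hist = small_ingrowth
        assert hist.rho_final.min() >= params.rho_min - 1e-12
        assert hist.rho_final.max() <= params.rho_max + 1e-12
        assert np.all(np.diff(hist.grown_count) >= 0)
        assert np.all(np.diff(hist.eligible_count) >= 0)

    def test_front_speed_bounded_by_adjacency_layers(self, small_porous):
        _, mesh = small_porous
        sub = extract_anchor_submesh(mesh)
        iters = (1, 3, 6, 10)
        hist = run_ingrowth(sub, 22.0, RemodelingParams(max_iterations=10),
                            snapshot_iterations=iters)
        iface_void = [int(e) for e in np.unique(sub.boundary_sets["INTERFACE"].elem)
                      if sub.region[e] == VOID]
        layers = _void_bfs_layers(sub, iface_void)
        for it in iters:
            rho = hist.snapshots[it]
            grown = np.where((sub.region == VOID)
                             & (rho > hist.rho_initial + _GROW_EPS))[0]
            for g in grown:
                assert layers[int(g)] <= it - 1

    def test_sequential_connectivity_no_isolated_nucleation(self, small_ingrowth):
        sub, _, hist = small_ingrowth
        grown = set(np.where((sub.region == VOID) &
                             (hist.rho_final > hist.rho_initial + _GROW_EPS))[0].tolist())
        iface_void = {int(e) for e in np.unique(sub.boundary_sets["INTERFACE"].elem)
                      if sub.region[e] == VOID}
        seen = set(iface_void & (grown | iface_void))
        dq = deque(seen)
        while dq:
            e = dq.popleft()
            for n in sub.neighbors(e):
                n = int(n)
                if n in grown and n not in seen:
                    seen.add(n)
                    dq.append(n)
        assert grown <= seen

    def test_gate_dominance_strict_subset_of_relaxed(self, small_porous):
        _, mesh = small_porous
        sub = extract_anchor_submesh(mesh)
        iters = (2, 5, 8)
        h1 = run_ingrowth(sub, 22.0, RemodelingParams(max_iterations=8),
                          snapshot_iterations=iters)
        h2 = run_ingrowth(sub, 22.0,
                          RemodelingParams(max_iterations=8, alpha_gate=1.5),
                          snapshot_iterations=iters)
        for it in iters:
            g1 = (sub.region == VOID) & (h1.snapshots[it] > h1.rho_initial + _GROW_EPS)
            g2 = (sub.region == VOID) & (h2.snapshots[it] > h2.rho_initial + _GROW_EPS)
            assert np.all(g2 <= g1)  # strict-gate growth is a subset
            assert h2.depth_mm[it - 1] <= h1.depth_mm[it - 1] + 1e-12

    def test_pore_islands_never_grow(self):
        spec = PoreSpec(600.0, 100.0, 0.05, rng_seed=0)
        dom = PorousDomain(
            spec, anchor_radius=2.0, slice_thickness=2.0,
            bone_layer_thickness=0.5,
            pores=np.array([[1.35, 1.35, 0.6], [0.6, 0.6, 0.5]]),
            achieved_porosity=0.05)
        mesh = mesh_domain(dom, 0.1)
        sub = extract_anchor_submesh(mesh)
        islands = find_pore_islands(sub)
        assert len(islands) == 1
        hist = run_ingrowth(sub, 22.0, RemodelingParams(max_iterations=12))
        island = islands[0]
        np.testing.assert_array_equal(hist.rho_final[island],
                                      hist.rho_initial[island])

    def test_history_at_accessor(self, small_ingrowth):
        _, _, hist = small_ingrowth
        last = hist.iterations[-1]
        assert hist.at(5, "depth_mm") == hist.depth_mm[4]
        assert hist.at(10 * last, "depth_mm") == hist.depth_mm[-1]


class TestMetrics:
    def test_no_growth_all_zero(self, small_porous):
        _, mesh = small_porous
        sub = extract_anchor_submesh(mesh)
        rho = np.where(sub.region == VOID, 0.01, 1.2)
        depth = np.zeros(sub.n_elems)
        m = ingrowth_metrics(rho, rho.copy(), sub, depth)
        assert m["grown_count"] == 0
        assert m["depth_mm"] == 0.0
        assert m["filled_volume_ratio"] == 0.0
        assert m["added_mass_g"] == 0.0

    def test_single_element_added_mass(self, small_porous):
        _, mesh = small_porous
        sub = extract_anchor_submesh(mesh)
        void_ids = np.where(sub.region == VOID)[0]
        rho0 = np.where(sub.region == VOID, 0.01, 1.2)
        rho = rho0.copy()
        e = void_ids[0]
        rho[e] = 0.8
        m = ingrowth_metrics(rho, rho0, sub, np.zeros(sub.n_elems))
        v_cm3 = sub.volumes[e] / 1000.0
        assert m["added_mass_g"] == pytest.approx(0.79 * v_cm3, rel=1e-12)
        assert m["grown_count"] == 1

    def test_fill_threshold_variants(self, small_porous):
        _, mesh = small_porous
        sub = extract_anchor_submesh(mesh)
        void_ids = np.where(sub.region == VOID)[0]
        rho0 = np.where(sub.region == VOID, 0.01, 1.2)
        rho = rho0.copy()
        rho[void_ids[0]] = 0.2   # grown but below half bone density
        rho[void_ids[1]] = 0.8
        m_any = ingrowth_metrics(rho, rho0, sub, np.zeros(sub.n_elems))
        m_thr = ingrowth_metrics(rho, rho0, sub, np.zeros(sub.n_elems),
                                 fill_threshold=0.4)
        assert m_any["filled_volume_ratio"] > m_thr["filled_volume_ratio"] > 0
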