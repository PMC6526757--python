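"""Reduced-order network solver: resistances, lesion losses, solves, FFR, WSS."""

import math

import numpy as np
import pytest
from scipy import optimize

from ssikit.coronary_model import CoronaryTree, Segment, summed_lengths
from ssikit.errors import DegenerateNetworkError
from ssikit.hemo_solver import (
    LesionGeometry,
    compute_ffr,
    compute_wss_max,
    lesion_loss_coefficients,
    poiseuille_resistance,
    segment_resistance,
    solve_pulsatile,
    solve_steady,
    stenosis_pressure_drop,
)
from ssikit.lpm_boundary import (
    OutletBoundary,
    PerfusionParams,
    allocate_resistances,
    distribute_to_outlets,
)
from ssikit.synthetic_fixtures import TreeGenParams, generate_tree, generate_waveform
from ssikit.virtual_stenosis import apply_stenosis, default_sites


def lesion(severity, d_ref=3.0, length=10.0, seg="LAD_0", position=0.5):
    return LesionGeometry(seg, position, severity, length, d_ref)


def build_network(seed, severity=50.0, site_index=None):
    """Synthetic tree with length-calibrated outlets and one lesion."""
    params = PerfusionParams()
    tree = generate_tree(TreeGenParams(seed=seed))
    alloc = allocate_resistances(summed_lengths(tree, 1.5), params)
    outlets = distribute_to_outlets(tree, alloc)
    sites = default_sites(tree)
    site = sites[(seed if site_index is None else site_index) % len(sites)]
    lesions = [apply_stenosis(tree, site, severity)] if severity is not None else []
    return tree, outlets, lesions, params


class TestSegmentResistance:
    def test_hand_unit_conversion(self):
        # independent chain: CGS (dyn, cm) then to clinical units
        mu_poise = 0.035  # 0.0035 Pa*s
        l_cm, d_cm = 1.0, 0.3
        r_cgs = 128.0 * mu_poise * l_cm / (math.pi * d_cm**4)  # dyn*s/cm^5
        r_clinical = r_cgs * (1.0 / 1333.22)  # dyn/cm^2 -> mmHg; cm^3 = mL
        assert poiseuille_resistance(10.0, 3.0, 0.0035) == pytest.approx(
            r_clinical, rel=1e-10
        )

    def test_linear_in_length(self):
        r1 = poiseuille_resistance(10.0, 3.0, 0.0035)
        assert poiseuille_resistance(20.0, 3.0, 0.0035) == pytest.approx(2 * r1)

    def test_inverse_fourth_power_in_diameter(self):
        r1 = poiseuille_resistance(10.0, 3.0, 0.0035)
        assert poiseuille_resistance(10.0, 1.5, 0.0035) == pytest.approx(16 * r1)

    def test_segment_uses_mean_diameter(self):
        seg = Segment("s", "LAD", None, 10.0, 3.0, 2.0)
        assert segment_resistance(seg, 0.0035) == pytest.approx(
            poiseuille_resistance(10.0, 2.5, 0.0035)
        )


class TestStenosisPressureDrop:
    def test_zero_severity_is_plain_poiseuille(self, params):
        les = lesion(0.0)
        for q in (0.1, 1.0, 4.0):
            expected = poiseuille_resistance(10.0, 3.0, params.mu) * q
            assert stenosis_pressure_drop(les, q, params) == pytest.approx(
                expected, rel=1e-12
            )

    def test_zero_flow_zero_drop(self, params):
        assert stenosis_pressure_drop(lesion(50.0), 0.0, params) == 0.0

    def test_odd_in_flow_direction(self, params):
        les = lesion(50.0)
        assert stenosis_pressure_drop(les, -2.0, params) == pytest.approx(
            -stenosis_pressure_drop(les, 2.0, params)
        )

    def test_quadratic_coefficient_matches_polynomial_fit(self, params):
        les = lesion(50.0)
        q = np.linspace(0.1, 5.0, 40)
        dp = np.array([stenosis_pressure_drop(les, qi, params) for qi in q])
        # convex increasing
        assert np.all(np.diff(dp) > 0)
        assert np.all(np.diff(dp, 2) > -1e-12)
        coeffs = np.polyfit(q, dp, 2)
        a, b = lesion_loss_coefficients(les, params)
        assert coeffs[0] == pytest.approx(b, rel=1e-6)
        assert coeffs[1] == pytest.approx(a, rel=1e-6)
        assert coeffs[2] == pytest.approx(0.0, abs=1e-9)

    def test_severity_at_or_above_100_invalid(self):
        with pytest.raises(ValueError):
            lesion(100.0)


class TestSolveSteady:
    def test_series_circuit_closed_form(self, single_lad_tree, params):
        r_out = 40.0
        outlets = [OutletBoundary("LAD_0", resistance=r_out)]
        state = solve_steady(single_lad_tree, outlets, [], 90.0, params)
        r_seg = segment_resistance(single_lad_tree.segments[0], params.mu)
        q_expected = 90.0 / (r_seg + r_out)
        assert state.segment_flows["LAD_0"] == pytest.approx(q_expected, rel=1e-12)
        assert state.nodal_pressures["LAD_0"] == pytest.approx(
            90.0 - r_seg * q_expected, rel=1e-12
        )

    def test_zero_severity_lesion_is_null(self, params):
        tree, outlets, _, _ = build_network(seed=4, severity=None)
        site = default_sites(tree)[2]
        base = solve_steady(tree, outlets, [], 90.0, params)
        nul = solve_steady(tree, outlets, [apply_stenosis(tree, site, 0.0)], 90.0, params)
        for sid in base.nodal_pressures:
            assert nul.nodal_pressures[sid] == pytest.approx(
                base.nodal_pressures[sid], rel=1e-12
            )
            assert nul.segment_flows[sid] == pytest.approx(
                base.segment_flows[sid], rel=1e-12, abs=1e-15
            )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_junction_conservation(self, seed, params):
        tree, outlets, lesions, params = build_network(seed)
        state = solve_steady(tree, outlets, lesions, 90.0, params)
        kids = tree.children_map()
        out_r = {ob.outlet_segment_id: ob.resistance for ob in outlets}
        for s in tree.segments:
            inflow = state.segment_flows[s.id]
            out = sum(state.segment_flows[c.id] for c in kids[s.id])
            if s.id in out_r and math.isfinite(out_r[s.id]):
                out += (state.nodal_pressures[s.id] - params.venous_pressure) / out_r[s.id]
            assert abs(inflow - out) < 1e-9

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_pressure_monotone_along_paths(self, seed, params):
        tree, outlets, lesions, params = build_network(seed)
        state = solve_steady(tree, outlets, lesions, 90.0, params)
        for s in tree.segments:
            prox = (
                state.nodal_pressures[s.parent_id]
                if s.parent_id
                else state.inlet_pressure
            )
            if state.segment_flows[s.id] > 0:
                assert state.nodal_pressures[s.id] < prox

    def test_all_closed_outlets_degenerate(self, single_lad_tree, params):
        outlets = [OutletBoundary("LAD_0", resistance=math.inf)]
        with pytest.raises(DegenerateNetworkError):
            solve_steady(single_lad_tree, outlets, [], 90.0, params)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_independent_root_finder(self, seed):
        tree, outlets, lesions, params = build_network(seed)
        state = solve_steady(tree, outlets, lesions, 90.0, params)
        oracle = oracle_solve(tree, outlets, lesions, 90.0, params)
        for sid, p in oracle.items():
            assert state.nodal_pressures[sid] == pytest.approx(p, rel=1e-8)


def oracle_solve(tree, outlets, lesions, inlet, params):
    """Independent brute-force solve: scipy root on conservation residuals,
    with segment flows recovered by bisecting the pressure-drop law."""
    segs = list(tree.segments)
    idx = {s.id: i for i, s in enumerate(segs)}
    out_r = {ob.outlet_segment_id: ob.resistance for ob in outlets}
    les_by_seg = {l.site_segment_id: l for l in lesions}
    kids = tree.children_map()

    def seg_drop(s, q):
        dp = segment_resistance(s, params.mu) * q
        les = les_by_seg.get(s.id)
        if les is not None:
            dp -= poiseuille_resistance(les.lesion_length_mm, les.d_reference_mm, params.mu) * q
            dp += stenosis_pressure_drop(les, q, params)
        return dp

    def seg_flow(s, dp):
        if dp == 0.0:
            return 0.0
        hi = 10.0 * abs(dp) / segment_resistance(s, params.mu) + 1.0
        return optimize.brentq(
            lambda q: seg_drop(s, q) - dp, -hi, hi, xtol=1e-14, rtol=1e-15
        )

    def residual(x):
        f = np.zeros(len(segs))
        for i, s in enumerate(segs):
            prox = inlet if s.parent_id is None else x[idx[s.parent_id]]
            q = seg_flow(s, prox - x[i])
            f[i] += q
            for c in kids[s.id]:
                f[i] -= seg_flow(c, x[i] - x[idx[c.id]])
            r_out = out_r.get(s.id, math.inf)
            if math.isfinite(r_out):
                f[i] -= (x[i] - params.venous_pressure) / r_out
        return f

    sol = None
    for frac in (0.9, 0.7, 0.5, 0.95, 0.3):
        cand = optimize.root(
            residual, np.full(len(segs), inlet * frac), method="hybr", tol=1e-13
        )
        if cand.success and np.max(np.abs(residual(cand.x))) < 1e-10:
            sol = cand
            break
    assert sol is not None, "oracle root-finder did not converge"
    return {s.id: sol.x[i] for i, s in enumerate(segs)}


class TestWss:
    def test_zero_flow_zero_wss(self):
        assert compute_wss_max(3.0, 0.0, 0.0035) == 0.0

    def test_inverse_cube_law_at_fixed_flow(self):
        w0 = compute_wss_max(3.0, 2.0, 0.0035)
        w50 = compute_wss_max(1.5, 2.0, 0.0035)
        assert w50 == pytest.approx(8.0 * w0, rel=1e-12)

    def test_hand_value(self):
        # tau = 32 mu q / (pi d^3), q = 2 mL/s = 2e-6 m^3/s, d = 3 mm
        expected = 32 * 0.0035 * 2e-6 / (math.pi * 0.003**3)
        assert compute_wss_max(3.0, 2.0, 0.0035) == pytest.approx(expected, rel=1e-12)


class TestFfr:
    def test_no_lesion_short_fat_segment_ffr_near_one(self, params):
        tree = CoronaryTree("p", [Segment("LAD_0", "LAD", None, 1.0, 4.5, 4.5)])
        outlets = [OutletBoundary("LAD_0", resistance=30.0)]
        state = solve_steady(tree, outlets, [], 90.0, params)
        assert compute_ffr(state, "LAD_0") == pytest.approx(1.0, abs=1e-3)

    def test_series_divider_closed_form(self, single_lad_tree, params):
        r_out = 40.0
        outlets = [OutletBoundary("LAD_0", resistance=r_out)]
        state = solve_steady(single_lad_tree, outlets, [], 90.0, params)
        r_seg = segment_resistance(single_lad_tree.segments[0], params.mu)
        assert compute_ffr(state, "LAD_0") == pytest.approx(
            r_out / (r_seg + r_out), rel=1e-12
        )

    def test_unknown_site_raises(self, single_lad_tree, params):
        outlets = [OutletBoundary("LAD_0", resistance=40.0)]
        state = solve_steady(single_lad_tree, outlets, [], 90.0, params)
        with pytest.raises(KeyError):
            compute_ffr(state, "nope")


class TestPulsatile:
    def test_constant_waveform_equals_steady(self, params):
        tree, outlets, lesions, params = build_network(seed=2)
        wf = generate_waveform(90.0 + 1e-9, 90.0 - 1e-9, 60.0, 32)
        pres = solve_pulsatile(tree, outlets, lesions, wf, params)
        steady = solve_steady(tree, outlets, lesions, 90.0, params)
        for sid in steady.nodal_pressures:
            assert pres.mean_pressures[sid] == pytest.approx(
                steady.nodal_pressures[sid], rel=1e-8
            )

    def test_linear_network_cycle_mean_equals_mean_pressure_solve(self, params):
        tree, outlets, _, params = build_network(seed=2, severity=None)
        wf = generate_waveform(120.0, 80.0, 70.0, 64)
        pres = solve_pulsatile(tree, outlets, [], wf, params)
        steady = solve_steady(tree, outlets, [], pres.mean_inlet_pressure, params)
        for sid in steady.nodal_pressures:
            assert pres.mean_flows[sid] == pytest.approx(
                steady.segment_flows[sid], rel=1e-12, abs=1e-14
            )

    def test_lesion_jensen_gap(self, params):
        # the lesion drop is superlinear in flow, so the cycle-averaged distal
        # pressure sags below the mean-pressure solve: FFR from cycle-averaged
        # pressures <= FFR at the mean inlet pressure
        tree, outlets, lesions, params = build_network(seed=3, severity=50.0)
        wf = generate_waveform(120.0, 80.0, 70.0, 64)
        pres = solve_pulsatile(tree, outlets, lesions, wf, params)
        sid = lesions[0].site_segment_id
        ffr_cycle = compute_ffr(pres, sid, params.venous_pressure)
        steady = solve_steady(tree, outlets, lesions, pres.mean_inlet_pressure, params)
        ffr_mean = compute_ffr(steady, sid, params.venous_pressure)
        assert ffr_cycle <= ffr_mean
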