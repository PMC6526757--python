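"""Reduced-order (0D network) coronary hemodynamics solver.

Each segment is a hydraulic resistor (Poiseuille, mean diameter); a
stenosis adds an empirical Young-type loss with a viscous term and a
turbulent-expansion term quadratic in flow:

    dP = K_v * (mu/d_ref) * V  +  K_t * (rho/2) * (A_ref/A_min - 1)^2 * V*|V|

with V the mean velocity at the reference (healthy) cross-section,
K_v = 32 * (L/d_ref) * (A_ref/A_min)^2 and K_t = 1.52.  At zero severity the
turbulent term vanishes and the viscous term reduces exactly to the
Poiseuille drop of the lesioned length, so a 0% lesion is hydraulically
null.

Nodal pressures solve mass conservation at every junction against
resistive outlet boundaries (optionally with pressure-switched
collaterals) by a damped Newton iteration.  Pulsatile inflow is handled
quasi-statically: the network holds no volume, so each waveform sample is
an independent steady solve.

Wall shear stress at a site is the Poiseuille wall value at the minimal
lumen, tau = 32*mu*|q| / (pi*d_min^3); the fractional flow reserve is the
ratio of lesion-distal to aortic pressure over the venous reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .coronary_model import CoronaryTree, Segment
from .errors import DegenerateNetworkError, SolverConvergenceError
from .lpm_boundary import OutletBoundary, PerfusionParams, collateral_adjust
from .units import CLINICAL_R_PER_SI_R, DYN_CM2_PER_PA, M3_PER_ML, M_PER_MM, PA_PER_MMHG

logger = logging.getLogger(__name__)

#: empirical turbulent-loss coefficient of the stenosis model
DEFAULT_KT = 1.52
#: viscous-loss prefactor (Poiseuille-consistent)
DEFAULT_KV_PREFACTOR = 32.0

DEFAULT_MAX_ITER = 100
DEFAULT_REL_TOL = 1e-10


@dataclass(frozen=True)
class LesionGeometry:
    """An axisymmetric virtual stenosis anchored inside one segment.

    ``severity_pct`` is the percent *diameter* reduction; the minimal lumen
    diameter is ``d_reference * (1 - severity/100)``.
    """

    site_segment_id: str
    position: float  # fraction in [0, 1] from the proximal end
    severity_pct: float
    lesion_length_mm: float
    d_reference_mm: float

    def __post_init__(self):
        if not 0.0 <= self.position <= 1.0:
            raise ValueError("position must be in [0, 1]")
        if not 0.0 <= self.severity_pct < 100.0:
            raise ValueError("severity_pct must be in [0, 100)")
        if self.lesion_length_mm <= 0:
            raise ValueError("lesion_length_mm must be > 0")
        if self.d_reference_mm <= 0:
            raise ValueError("d_reference_mm must be > 0")

    @property
    def d_min_mm(self) -> float:
        return self.d_reference_mm * (1.0 - self.severity_pct / 100.0)


@dataclass
class FlowState:
    """Solved network state: distal-node pressures and segment flows."""

    nodal_pressures: dict[str, float]  # mmHg at each segment's distal node
    segment_flows: dict[str, float]  # mL/s through each segment
    inlet_pressure: float  # mmHg applied at every artery root
    time: float = 0.0  # s; 0 for steady solves
    iterations: int = 0
    residual: float = 0.0


@dataclass
class HemoResult:
    """Headline quantities of one lesioned solve."""

    ffr: float
    wss_max_pa: float
    lesion_flow_ml_s: float
    state: FlowState

    @property
    def wss_max_dyn_cm2(self) -> float:
        return self.wss_max_pa * DYN_CM2_PER_PA


@dataclass
class PulsatileResult:
    """Per-sample states plus cycle-averaged pressures and flows."""

    times: list[float]
    states: list[FlowState]
    mean_pressures: dict[str, float] = field(default_factory=dict)
    mean_flows: dict[str, float] = field(default_factory=dict)
    mean_inlet_pressure: float = 0.0


# ---- elementary resistances -------------------------------------------


def poiseuille_resistance(length_mm: float, diameter_mm: float, mu: float) -> float:
    """Poiseuille resistance 128*mu*L/(pi*d^4) in clinical units (mmHg*s/mL)."""
    l_m = length_mm * M_PER_MM
    d_m = diameter_mm * M_PER_MM
    r_si = 128.0 * mu * l_m / (math.pi * d_m**4)
    return r_si * CLINICAL_R_PER_SI_R


def segment_resistance(segment: Segment, mu: float) -> float:
    """Hydraulic resistance of a segment at its mean diameter (mmHg*s/mL)."""
    return poiseuille_resistance(segment.length_mm, segment.mean_diameter_mm, mu)


def lesion_loss_coefficients(
    lesion: LesionGeometry,
    params: PerfusionParams,
    kt: float = DEFAULT_KT,
    kv_prefactor: float = DEFAULT_KV_PREFACTOR,
) -> tuple[float, float]:
    """Linear and quadratic loss coefficients (a, b) of a lesion.

    The lesion pressure drop is ``dP = a*q + b*q*|q|`` with q in mL/s and
    dP in mmHg.  ``b`` is exactly zero at 0% severity.
    """
    d_ref = lesion.d_reference_mm * M_PER_MM
    d_min = lesion.d_min_mm * M_PER_MM
    l_eff = lesion.lesion_length_mm * M_PER_MM
    a_ref = math.pi * d_ref**2 / 4.0
    area_ratio = (d_ref / d_min) ** 2  # A_ref / A_min

    k_v = kv_prefactor * (l_eff / d_ref) * area_ratio**2
    # dP_visc = K_v * mu * V / d_ref, V = q/A_ref  ->  a_si per (m^3/s)
    a_si = k_v * params.mu / (d_ref * a_ref)
    b_si = kt * (params.rho / 2.0) * (area_ratio - 1.0) ** 2 / a_ref**2

    a = a_si * M3_PER_ML / PA_PER_MMHG
    b = b_si * M3_PER_ML**2 / PA_PER_MMHG
    return a, b


def stenosis_pressure_drop(
    lesion: LesionGeometry,
    q_ml_s: float,
    params: PerfusionParams,
    kt: float = DEFAULT_KT,
    kv_prefactor: float = DEFAULT_KV_PREFACTOR,
) -> float:
    """Pressure drop (mmHg) across a lesion carrying flow q (mL/s, signed)."""
    a, b = lesion_loss_coefficients(lesion, params, kt=kt, kv_prefactor=kv_prefactor)
    return a * q_ml_s + b * q_ml_s * abs(q_ml_s)


def compute_wss_max(d_min_mm: float, q_ml_s: float, mu: float) -> float:
    """Poiseuille wall shear stress (Pa) at the minimal lumen: 32*mu*|q|/(pi*d^3)."""
    d_m = d_min_mm * M_PER_MM
    q_si = abs(q_ml_s) * M3_PER_ML
    return 32.0 * mu * q_si / (math.pi * d_m**3)


# ---- steady network solve ---------------------------------------------


class _Network:
    """Flattened arrays for the Newton iteration."""

    def __init__(
        self,
        tree: CoronaryTree,
        outlets: list[OutletBoundary],
        lesions: list[LesionGeometry],
        params: PerfusionParams,
    ):
        tree.validate()
        lesion_by_seg: dict[str, LesionGeometry] = {}
        for les in lesions:
            if les.site_segment_id in lesion_by_seg:
                raise ValueError(f"multiple lesions on segment {les.site_segment_id!r}")
            tree.segment(les.site_segment_id)  # raises on unknown id
            lesion_by_seg[les.site_segment_id] = les

        # topological (root-first) ordering
        kids = tree.children_map()
        ordered: list[Segment] = []
        for artery in tree.arteries():
            stack = [tree.root(artery)]
            while stack:
                seg = stack.pop()
                ordered.append(seg)
                stack.extend(reversed(kids[seg.id]))
        self.segments = ordered
        self.index = {s.id: i for i, s in enumerate(ordered)}
        n = len(ordered)
        self.parent = np.full(n, -1, dtype=int)
        self.lin = np.zeros(n)  # linear coefficient c (mmHg*s/mL)
        self.quad = np.zeros(n)  # quadratic coefficient b (mmHg*s^2/mL^2)

        for i, seg in enumerate(ordered):
            if seg.parent_id is not None:
                self.parent[i] = self.index[seg.parent_id]
            r_seg = segment_resistance(seg, params.mu)
            les = lesion_by_seg.get(seg.id)
            if les is None:
                self.lin[i] = r_seg
            else:
                if les.lesion_length_mm > seg.length_mm:
                    raise ValueError(
                        f"lesion length {les.lesion_length_mm} mm exceeds segment "
                        f"{seg.id!r} length {seg.length_mm} mm"
                    )
                a, b = lesion_loss_coefficients(les, params)
                r_rest = r_seg - poiseuille_resistance(
                    les.lesion_length_mm, les.d_reference_mm, params.mu
                )
                self.lin[i] = max(r_rest, 0.0) + a
                self.quad[i] = b

        self.outlet: list[OutletBoundary | None] = [None] * n
        for ob in outlets:
            self.outlet[self.index[ob.outlet_segment_id]] = ob
        if not any(
            ob is not None and math.isfinite(ob.resistance) for ob in self.outlet
        ):
            raise DegenerateNetworkError("no finite outlet resistance; network cannot flow")


def _edge_flow(dp: np.ndarray, c: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flow and differential conductance of dP = c*q + b*q|q| edges (vectorised).

    Uses the cancellation-safe root 2|dP| / (c + sqrt(c^2 + 4 b |dP|)).
    """
    absdp = np.abs(dp)
    disc = np.sqrt(c * c + 4.0 * b * absdp)
    q = np.sign(dp) * 2.0 * absdp / (c + disc)
    g = 1.0 / (c + 2.0 * b * np.abs(q))
    return q, g


def solve_steady(
    tree: CoronaryTree,
    outlets: list[OutletBoundary],
    lesions: list[LesionGeometry],
    inlet_pressure: float,
    params: PerfusionParams,
    max_iter: int = DEFAULT_MAX_ITER,
    rel_tol: float = DEFAULT_REL_TOL,
) -> FlowState:
    """Solve the steady resistive network for nodal pressures and flows.

    The unknowns are the pressures at each segment's distal node; artery
    roots see ``inlet_pressure`` at their proximal node and outlets drain
    to ``params.venous_pressure``.  Convergence: max junction residual
    below ``rel_tol`` relative to the largest flow (damped Newton,
    step halved while the residual norm would increase).
    """
    net = _Network(tree, outlets, lesions, params)
    n = len(net.segments)
    pv = params.venous_pressure
    x = np.full(n, float(inlet_pressure))

    def residual(xv: np.ndarray):
        prox = np.where(net.parent >= 0, xv[net.parent], inlet_pressure)
        q, g = _edge_flow(prox - xv, net.lin, net.quad)
        q_out = np.zeros(n)
        g_out = np.zeros(n)
        for i, ob in enumerate(net.outlet):
            if ob is None:
                continue
            r_eff = collateral_adjust(ob, xv[i])
            if math.isfinite(r_eff):
                q_out[i] = (xv[i] - pv) / r_eff
                g_out[i] = 1.0 / r_eff
        f = q - q_out
        np.subtract.at(f, net.parent[net.parent >= 0], q[net.parent >= 0])
        return f, q, g, g_out

    def jacobian(g: np.ndarray, g_out: np.ndarray) -> np.ndarray:
        jac = np.zeros((n, n))
        for i in range(n):
            jac[i, i] -= g[i] + g_out[i]
            p = net.parent[i]
            if p >= 0:
                jac[i, p] += g[i]
                jac[p, i] += g[i]
                jac[p, p] -= g[i]
        return jac

    f, q, g, g_out = residual(x)
    norm = float(np.max(np.abs(f))) if n else 0.0
    it = 0
    for it in range(1, max_iter + 1):
        scale = max(1.0, float(np.max(np.abs(q))) if n else 0.0)
        if norm <= rel_tol * scale:
            break
        jac = jacobian(g, g_out)
        try:
            dx = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError as exc:
            raise SolverConvergenceError(f"singular Jacobian at iteration {it}", norm) from exc
        lam = 1.0
        while True:
            f_new, q_new, g_new, g_out_new = residual(x + lam * dx)
            norm_new = float(np.max(np.abs(f_new)))
            if norm_new <= norm or lam < 1e-8:
                break
            lam *= 0.5  # damping: halve the step while the residual increases
        x = x + lam * dx
        f, q, g, g_out = f_new, q_new, g_new, g_out_new
        norm = norm_new
    else:
        raise SolverConvergenceError(
            f"no convergence in {max_iter} iterations (residual {norm:.3e} mL/s)", norm
        )

    logger.info("steady solve converged in %d iterations, residual %.3e mL/s", it, norm)
    return FlowState(
        nodal_pressures={s.id: float(x[i]) for i, s in enumerate(net.segments)},
        segment_flows={s.id: float(q[i]) for i, s in enumerate(net.segments)},
        inlet_pressure=float(inlet_pressure),
        time=0.0,
        iterations=it,
        residual=norm,
    )


def solve_pulsatile(
    tree: CoronaryTree,
    outlets: list[OutletBoundary],
    lesions: list[LesionGeometry],
    waveform,
    params: PerfusionParams,
) -> PulsatileResult:
    """Quasi-static pulsatile solve: one steady solve per waveform sample.

    The purely resistive network holds no state, so the exact pulsatile
    response is the sample-wise steady response.  Cycle averages are the
    arithmetic means over the (uniform) samples.
    """
    times = list(np.asarray(waveform.times_s, dtype=float))
    pressures = np.asarray(waveform.pressures_mmHg, dtype=float)
    if len(times) < 32:
        raise ValueError("waveform must have at least 32 samples per cycle")
    states = []
    for t, p in zip(times, pressures):
        st = solve_steady(tree, outlets, lesions, float(p), params)
        st.time = float(t)
        states.append(st)
    seg_ids = states[0].segment_flows.keys()
    mean_pressures = {
        sid: float(np.mean([st.nodal_pressures[sid] for st in states])) for sid in seg_ids
    }
    mean_flows = {
        sid: float(np.mean([st.segment_flows[sid] for st in states])) for sid in seg_ids
    }
    return PulsatileResult(
        times=times,
        states=states,
        mean_pressures=mean_pressures,
        mean_flows=mean_flows,
        mean_inlet_pressure=float(np.mean(pressures)),
    )


def compute_ffr(
    state: FlowState | PulsatileResult,
    site_segment_id: str,
    venous_pressure: float = 0.0,
) -> float:
    """FFR at the node just distal to a site's segment.

    Steady mode uses the solved pressures directly; for a pulsatile result
    both numerator and denominator are cycle-averaged.
    """
    if isinstance(state, PulsatileResult):
        p_d = state.mean_pressures[site_segment_id]
        p_in = state.mean_inlet_pressure
    else:
        if site_segment_id not in state.nodal_pressures:
            raise KeyError(f"unknown segment id {site_segment_id!r}")
        p_d = state.nodal_pressures[site_segment_id]
        p_in = state.inlet_pressure
    return (p_d - venous_pressure) / (p_in - venous_pressure)
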