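"""Virtual stenosis method: graded lesions at candidate sites.

For each candidate site the tree is re-solved with an axisymmetric virtual
lesion at 0, 25 and 50 % diameter reduction (the default grid), collecting
(severity, FFR, WSSmax) triples.  Outlet boundary conditions are
calibrated once from the lesion-free tree and held fixed across the
severity sweep — the lumped-parameter calibration depends only on vessel
lengths, which a virtual lesion does not change — so the sweep isolates
the lesion's hemodynamic effect.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import pandas as pd

from .coronary_model import (
    DEFAULT_DIAMETER_THRESHOLD_MM,
    CoronaryTree,
    summed_lengths,
)
from .hemo_solver import (
    FlowState,
    HemoResult,
    LesionGeometry,
    PulsatileResult,
    compute_ffr,
    compute_wss_max,
    solve_pulsatile,
    solve_steady,
)
from .lpm_boundary import (
    CollateralConfig,
    OutletBoundary,
    PerfusionParams,
    allocate_resistances,
    distribute_to_outlets,
)
from .units import DYN_CM2_PER_PA

DEFAULT_SEVERITIES = (0.0, 25.0, 50.0)
DEFAULT_LESION_LENGTH_MM = 10.0
DEFAULT_SITE_FRACTIONS = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class CandidateSite:
    """A potential stenosis location: a segment and a fractional position."""

    site_id: str
    segment_id: str
    position: float

    def __post_init__(self):
        if not 0.0 <= self.position <= 1.0:
            raise ValueError("position must be in [0, 1]")


@dataclass(frozen=True)
class SweepPoint:
    severity_pct: float
    ffr: float
    wss_max_pa: float
    lesion_flow_ml_s: float

    @property
    def wss_max_dyn_cm2(self) -> float:
        return self.wss_max_pa * DYN_CM2_PER_PA


@dataclass
class SeveritySweepResult:
    """Ordered (severity, FFR, WSSmax) points for one candidate site."""

    site: CandidateSite
    points: list[SweepPoint]
    solver_mode: str = "steady"  # "steady" or "pulsatile"


def default_sites(tree: CoronaryTree, fractions=DEFAULT_SITE_FRACTIONS) -> list[CandidateSite]:
    """Candidate sites along each artery's main trunk.

    The main trunk is the root-to-leaf path of greatest cumulative length;
    sites sit at 25/50/75 % of that length by default, with deterministic
    ids like ``"LAD_p50"``.
    """
    tree.validate()
    kids = tree.children_map()
    sites: list[CandidateSite] = []
    for artery in tree.arteries():
        # deepest path by cumulative length
        best_path: list = []
        best_len = -1.0

        def walk(seg, path, acc):
            nonlocal best_path, best_len
            path = path + [seg]
            acc += seg.length_mm
            children = kids[seg.id]
            if not children:
                if acc > best_len:
                    best_len = acc
                    best_path = path
                return
            for c in children:
                walk(c, path, acc)

        walk(tree.root(artery), [], 0.0)

        for f in fractions:
            target = f * best_len
            cum = 0.0
            for seg in best_path:
                if cum + seg.length_mm >= target:
                    position = (target - cum) / seg.length_mm
                    sites.append(
                        CandidateSite(
                            site_id=f"{artery}_p{round(f * 100):d}",
                            segment_id=seg.id,
                            position=position,
                        )
                    )
                    break
                cum += seg.length_mm
    return sites


def apply_stenosis(
    tree: CoronaryTree,
    site: CandidateSite,
    severity_pct: float,
    lesion_length_mm: float = DEFAULT_LESION_LENGTH_MM,
) -> LesionGeometry:
    """Build the lesion geometry for a site at a given percent diameter reduction.

    Pure function: the tree is not modified.  The reference diameter is the
    healthy (linearly interpolated) lumen at the site; the lesion length is
    clipped to the host segment.
    """
    if not 0.0 <= severity_pct < 100.0:
        raise ValueError(f"severity_pct must be in [0, 100), got {severity_pct}")
    seg = tree.segment(site.segment_id)
    return LesionGeometry(
        site_segment_id=site.segment_id,
        position=site.position,
        severity_pct=severity_pct,
        lesion_length_mm=min(lesion_length_mm, seg.length_mm),
        d_reference_mm=tree.diameter_at(site.segment_id, site.position),
    )


def severity_sweep(
    tree: CoronaryTree,
    site: CandidateSite,
    severities,
    outlets: list[OutletBoundary],
    inlet_pressure: float,
    params: PerfusionParams,
    mode: str = "steady",
    waveform=None,
    lesion_length_mm: float = DEFAULT_LESION_LENGTH_MM,
) -> SeveritySweepResult:
    """Run one solver pass per severity at a fixed site with fixed boundaries."""
    severities = [float(s) for s in severities]
    if any(b <= a for a, b in zip(severities, severities[1:])):
        raise ValueError("severities must be strictly increasing")
    if mode not in ("steady", "pulsatile"):
        raise ValueError(f"mode must be 'steady' or 'pulsatile', got {mode!r}")
    if mode == "pulsatile" and waveform is None:
        raise ValueError("pulsatile mode requires a waveform")

    points = []
    for sev in severities:
        lesion = apply_stenosis(tree, site, sev, lesion_length_mm=lesion_length_mm)
        try:
            res = _solve_one(tree, outlets, lesion, inlet_pressure, params, mode, waveform)
        except Exception as exc:
            raise type(exc)(
                f"site {site.site_id!r}, severity {sev}%: {exc}"
            ) from exc
        points.append(
            SweepPoint(
                severity_pct=sev,
                ffr=res.ffr,
                wss_max_pa=res.wss_max_pa,
                lesion_flow_ml_s=res.lesion_flow_ml_s,
            )
        )
    return SeveritySweepResult(site=site, points=points, solver_mode=mode)


def _solve_one(tree, outlets, lesion, inlet_pressure, params, mode, waveform) -> HemoResult:
    if mode == "steady":
        state: FlowState = solve_steady(tree, outlets, [lesion], inlet_pressure, params)
        q = state.segment_flows[lesion.site_segment_id]
        return HemoResult(
            ffr=compute_ffr(state, lesion.site_segment_id, params.venous_pressure),
            wss_max_pa=compute_wss_max(lesion.d_min_mm, q, params.mu),
            lesion_flow_ml_s=q,
            state=state,
        )
    pres: PulsatileResult = solve_pulsatile(tree, outlets, [lesion], waveform, params)
    # spatiotemporal maximum: peak over cycle samples of the throat WSS
    wss = max(
        compute_wss_max(lesion.d_min_mm, st.segment_flows[lesion.site_segment_id], params.mu)
        for st in pres.states
    )
    return HemoResult(
        ffr=compute_ffr(pres, lesion.site_segment_id, params.venous_pressure),
        wss_max_pa=wss,
        lesion_flow_ml_s=pres.mean_flows[lesion.site_segment_id],
        state=pres.states[0],
    )


def evaluate_sites(
    tree: CoronaryTree,
    params: PerfusionParams,
    sites: list[CandidateSite] | None = None,
    severities=DEFAULT_SEVERITIES,
    diameter_threshold_mm: float = DEFAULT_DIAMETER_THRESHOLD_MM,
    mode: str = "steady",
    waveform=None,
    collateral: CollateralConfig | None = None,
    inlet_pressure: float | None = None,
    lesion_length_mm: float = DEFAULT_LESION_LENGTH_MM,
) -> list[SeveritySweepResult]:
    """Full virtual-stenosis pass: calibrate boundaries once, sweep every site."""
    tree.validate()
    if sites is None:
        sites = default_sites(tree)
    lengths = summed_lengths(tree, diameter_threshold_mm)
    alloc = allocate_resistances(lengths, params)
    outlets = distribute_to_outlets(tree, alloc, collateral)
    if inlet_pressure is None:
        inlet_pressure = tree.inlet_pressure_ref or params.inlet_pressure
    return [
        severity_sweep(
            tree,
            site,
            severities,
            outlets,
            inlet_pressure,
            params,
            mode=mode,
            waveform=waveform,
            lesion_length_mm=lesion_length_mm,
        )
        for site in sites
    ]


def sweeps_to_dataframe(sweeps: list[SeveritySweepResult]) -> pd.DataFrame:
    """Flatten sweep results to the CSV column convention."""
    rows = [
        {
            "site_id": sw.site.site_id,
            "severity_pct": p.severity_pct,
            "ffr": p.ffr,
            "wss_max_pa": p.wss_max_pa,
            "wss_max_dyn_cm2": p.wss_max_dyn_cm2,
            "lesion_flow_ml_s": p.lesion_flow_ml_s,
        }
        for sw in sweeps
        for p in sw.points
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "severity_pct",
            "ffr",
            "wss_max_pa",
            "wss_max_dyn_cm2",
            "lesion_flow_ml_s",
        ],
    )


def tree_fingerprint(tree: CoronaryTree) -> str:
    """SHA-256 of the serialised tree; used to assert sweep purity."""
    doc = {
        "patient_id": tree.patient_id,
        "segments": [
            [s.id, s.artery, s.parent_id, s.length_mm, s.d_prox_mm, s.d_dist_mm, s.territory]
            for s in tree.segments
        ],
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()
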