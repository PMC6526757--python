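"""Vessel-length-calibrated lumped-parameter outlet boundaries.

The microvascular bed downstream of each epicardial artery is modelled as a
pure resistance, allocated from the artery's summed vessel length: a longer
artery feeds more myocardium and therefore sees *less* downstream
resistance,

    R_LAD = k / l_LAD,        R_LCX = k / l_LCX,
    R_RCA = alpha*k / (l_RCA)_RV  +  k / (l_RCA)_LV,

where the RCA resistance is the series sum of a right-ventricle-territory
term (up-weighted by ``alpha > 1``, the typical LV/RV muscle-volume ratio,
because RV-feeding length contributes less flow demand) and a
left-ventricle-territory term.  The proportionality constant ``k`` follows
from requiring that the three arteries in parallel carry the total
hyperemic coronary flow Q under the aorta-to-venous pressure difference dP:

    k = (dP/Q) * [ l_LAD + l_LCX + l_RV*l_LV / (l_RV + alpha*l_LV) ].

Per-artery resistance is then distributed to that artery's terminal
segments by the same length principle, applied recursively down the tree,
so that the parallel combination of the outlet resistances reproduces the
artery's allocated value exactly.

An optional collateral pathway is modelled as an on-off switched resistance
in parallel with an outlet: it engages when the local distal pressure falls
below a threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .coronary_model import ARTERIES, CoronaryTree, Segment, SummedLengths
from .errors import DegenerateNetworkError, TopologyError

DEFAULT_ALPHA = 3.45
"""Default LV/RV weighting constant for the RCA resistance split."""


@dataclass(frozen=True)
class PerfusionParams:
    """Physiologic parameters of the hyperemic perfusion model.

    delta_P : mmHg
        Pressure difference between the aorta and the coronary veins.
    Q_total : mL/s
        Total hyperemic coronary flow.
    alpha : dimensionless, > 1
        LV/RV muscle-volume ratio weighting the RCA territory split.
    mu : Pa*s
        Dynamic blood viscosity.
    rho : kg/m^3
        Blood density.
    venous_pressure : mmHg
        Coronary venous reference pressure.
    """

    delta_P: float = 90.0
    Q_total: float = 14.0
    alpha: float = DEFAULT_ALPHA
    mu: float = 0.0035
    rho: float = 1060.0
    venous_pressure: float = 0.0

    def __post_init__(self):
        if self.delta_P <= 0:
            raise ValueError("delta_P must be > 0")
        if self.Q_total <= 0:
            raise ValueError("Q_total must be > 0")
        if self.alpha <= 1:
            raise ValueError("alpha must be > 1")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")

    @property
    def inlet_pressure(self) -> float:
        """Mean aortic pressure implied by delta_P over the venous reference (mmHg)."""
        return self.venous_pressure + self.delta_P

    @classmethod
    def from_config(cls, cfg: dict) -> "PerfusionParams":
        """Build from the JSON config key convention (``delta_P_mmHg`` etc.)."""
        return cls(
            delta_P=cfg.get("delta_P_mmHg", cls.delta_P),
            Q_total=cfg.get("Q_total_mL_s", cls.Q_total),
            alpha=cfg.get("alpha", cls.alpha),
            mu=cfg.get("mu_Pa_s", cls.mu),
            rho=cfg.get("rho_kg_m3", cls.rho),
            venous_pressure=cfg.get("venous_pressure_mmHg", cls.venous_pressure),
        )


@dataclass(frozen=True)
class CollateralConfig:
    """On-off collateral switch settings (disabled by default)."""

    enabled: bool = False
    threshold_mmHg: float = 30.0
    resistance_factor: float = 10.0  # collateral R = factor x outlet R

    def __post_init__(self):
        if self.threshold_mmHg <= 0:
            raise ValueError("threshold_mmHg must be > 0")
        if self.resistance_factor <= 0:
            raise ValueError("resistance_factor must be > 0")


@dataclass(frozen=True)
class ResistanceAllocation:
    """Per-artery resistances (mmHg*s/mL) and the calibration constant k.

    ``R_RCA`` is the series sum of its RV- and LV-territory components.
    Arteries with zero qualifying summed length get an infinite-resistance
    sentinel (no flow) so that network assembly stays uniform.
    """

    k: float
    R_LAD: float
    R_LCX: float
    R_RCA: float
    R_RCA_RV: float
    R_RCA_LV: float

    def resistance(self, artery: str) -> float:
        return {"RCA": self.R_RCA, "LAD": self.R_LAD, "LCX": self.R_LCX}[artery]


@dataclass(frozen=True)
class OutletBoundary:
    """Resistive boundary at one terminal segment, with optional collateral."""

    outlet_segment_id: str
    resistance: float  # mmHg*s/mL; may be +inf (closed outlet)
    collateral_enabled: bool = False
    collateral_threshold_mmHg: float = 30.0
    collateral_resistance: float = math.inf

    def __post_init__(self):
        if self.resistance <= 0:
            raise ValueError("resistance must be > 0")
        if self.collateral_enabled and not self.collateral_resistance > 0:
            raise ValueError("collateral_resistance must be > 0 when enabled")


def _rca_length_term(lengths: SummedLengths, alpha: float) -> float:
    """Effective RCA length l_RV*l_LV/(l_RV + alpha*l_LV); 0 if either part is absent."""
    lrv, llv = lengths.l_rca_rv, lengths.l_rca_lv
    if lrv <= 0 or llv <= 0:
        return 0.0
    return lrv * llv / (lrv + alpha * llv)


def compute_k(lengths: SummedLengths, params: PerfusionParams) -> float:
    """Calibration constant k (mmHg*s*mm/mL) from the pressure-flow relation."""
    bracket = lengths.l_lad + lengths.l_lcx + _rca_length_term(lengths, params.alpha)
    if bracket <= 0:
        raise DegenerateNetworkError("all summed lengths are zero; network carries no flow")
    return params.delta_P / params.Q_total * bracket


def allocate_resistances(lengths: SummedLengths, params: PerfusionParams) -> ResistanceAllocation:
    """Allocate per-artery outlet resistances from summed vessel lengths."""
    k = compute_k(lengths, params)
    r_lad = k / lengths.l_lad if lengths.l_lad > 0 else math.inf
    r_lcx = k / lengths.l_lcx if lengths.l_lcx > 0 else math.inf
    r_rv = params.alpha * k / lengths.l_rca_rv if lengths.l_rca_rv > 0 else math.inf
    r_lv = k / lengths.l_rca_lv if lengths.l_rca_lv > 0 else math.inf
    r_rca = r_rv + r_lv  # series chain; open if either branch is absent
    return ResistanceAllocation(
        k=k, R_LAD=r_lad, R_LCX=r_lcx, R_RCA=r_rca, R_RCA_RV=r_rv, R_RCA_LV=r_lv
    )


def _downstream_length(tree: CoronaryTree, seg: Segment, kids, cache: dict[str, float]) -> float:
    if seg.id in cache:
        return cache[seg.id]
    total = seg.length_mm + sum(_downstream_length(tree, c, kids, cache) for c in kids[seg.id])
    cache[seg.id] = total
    return total


def distribute_to_outlets(
    tree: CoronaryTree,
    alloc: ResistanceAllocation,
    collateral: CollateralConfig | None = None,
) -> list[OutletBoundary]:
    """Split each artery's resistance over its terminal segments.

    Conductance is divided at every junction in proportion to the
    downstream total vessel length of each daughter branch, extending the
    per-artery length principle into the tree; the parallel combination of
    the resulting outlet resistances equals the allocated artery resistance
    by construction.
    """
    collateral = collateral or CollateralConfig()
    kids = tree.children_map()
    cache: dict[str, float] = {}
    boundaries: list[OutletBoundary] = []

    for artery in ARTERIES:
        segs = [s for s in tree.segments if s.artery == artery]
        if not segs:
            continue
        r_artery = alloc.resistance(artery)
        terminals = tree.terminals(artery)
        if math.isfinite(r_artery) and not terminals:
            raise TopologyError(f"artery {artery} has finite resistance but no terminal segment")
        g_artery = 0.0 if math.isinf(r_artery) else 1.0 / r_artery

        # conductance share of each terminal via recursive length-weighted split
        shares: dict[str, float] = {}

        def descend(seg: Segment, share: float) -> None:
            children = kids[seg.id]
            if not children:
                shares[seg.id] = share
                return
            weights = [_downstream_length(tree, c, kids, cache) for c in children]
            wsum = sum(weights)
            for c, w in zip(children, weights):
                descend(c, share * (w / wsum))

        descend(tree.root(artery), 1.0)

        for term in terminals:
            g = g_artery * shares[term.id]
            resistance = math.inf if g == 0.0 else 1.0 / g
            coll_r = (
                collateral.resistance_factor * resistance
                if collateral.enabled and math.isfinite(resistance)
                else math.inf
            )
            boundaries.append(
                OutletBoundary(
                    outlet_segment_id=term.id,
                    resistance=resistance,
                    collateral_enabled=collateral.enabled,
                    collateral_threshold_mmHg=collateral.threshold_mmHg,
                    collateral_resistance=coll_r,
                )
            )
    return boundaries


def collateral_adjust(outlet: OutletBoundary, distal_pressure_mmHg: float) -> float:
    """Effective outlet resistance given the current distal pressure.

    The collateral pathway switches on (parallel resistance) only when the
    distal pressure drops below the threshold; otherwise the nominal outlet
    resistance is returned unchanged.
    """
    if not outlet.collateral_enabled or distal_pressure_mmHg >= outlet.collateral_threshold_mmHg:
        return outlet.resistance
    r, rc = outlet.resistance, outlet.collateral_resistance
    if math.isinf(r):
        return rc
    if math.isinf(rc):
        return r
    return r * rc / (r + rc)
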