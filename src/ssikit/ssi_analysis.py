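"""Stenosis susceptibility index (SSI): slope analysis, ranking, concordance.

As a virtual lesion at a site grows, FFR falls and WSSmax rises.  The SSI
is the magnitude of the slope of WSSmax (y) against FFR (x) across the
severity sweep,

    SSI = (WSSmax_stenosed - WSSmax_baseline) / (FFR_baseline - FFR_stenosed),

estimated by ordinary least squares over the sweep points.  A *small* SSI
means severe narrowing is needed before wall shear reaches the
vasodilation-triggering level, so plaque can accumulate: the minimum-SSI
site is the predicted most susceptible location.  Under the normalisation
WSSmax_baseline = 0, FFR_baseline = 1 the two-point slope reduces to the
simplified ratio SSI = WSSmax / (1 - FFR).

The concordance reporter compares predicted minimum-SSI sites with
clinically treated (PCI) sites, per vessel and per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .coronary_model import ARTERIES, CoronaryTree
from .errors import AlignmentError, DegenerateFitError
from .units import DYN_CM2_PER_PA
from .virtual_stenosis import CandidateSite, SeveritySweepResult

_ARTERY_ORDER = {a: i for i, a in enumerate(ARTERIES)}


@dataclass(frozen=True)
class SSIRecord:
    """SSI of one candidate site.

    ``ssi`` carries the units of the WSS axis per unit FFR (dyn/cm^2 per
    FFR unit by default).  ``r_squared`` is reported only for slope fits
    with at least three points.
    """

    site: CandidateSite
    artery: str
    ssi: float
    r_squared: float | None
    points: tuple
    method: str = "slope_fit"  # "slope_fit" or "simplified"
    wss_units: str = "dyn/cm2"


@dataclass
class SiteRanking:
    """Per-artery minimum-SSI records and the global minimum."""

    per_artery: dict[str, SSIRecord]
    global_min: SSIRecord
    tied: bool = False


@dataclass(frozen=True)
class PatientObservation:
    """Clinical ground truth for one patient.

    ``pci_sites`` maps each treated artery to the identifier of the site
    where PCI was performed; ``evaluated_arteries`` lists the arteries for
    which an SSI prediction exists (an artery can be absent, e.g. not
    reconstructed).
    """

    patient_id: str
    mi_observed: bool
    pci_sites: Mapping[str, str] = field(default_factory=dict)
    evaluated_arteries: frozenset = frozenset(ARTERIES)

    def __post_init__(self):
        for a in list(self.pci_sites) + list(self.evaluated_arteries):
            if a not in ARTERIES:
                raise ValueError(f"unknown artery {a!r}")


@dataclass
class ConcordanceReport:
    """Vessel- and patient-level agreement between minimum-SSI and PCI sites.

    ``per_vessel_rate`` / ``per_patient_rate`` are percentages (unrounded
    internally; display rounding to one decimal via :meth:`summary`).
    ``per_vessel_rate`` is ``None`` when no vessel was treated (undefined
    denominator, deliberately not reported as 0).
    """

    n_patients: int
    n_patients_matched: int
    n_vessels_treated: int
    n_vessels_matched: int
    mi_count: int

    @property
    def per_patient_rate(self) -> float | None:
        if self.n_patients == 0:
            return None
        return 100.0 * self.n_patients_matched / self.n_patients

    @property
    def per_vessel_rate(self) -> float | None:
        if self.n_vessels_treated == 0:
            return None
        return 100.0 * self.n_vessels_matched / self.n_vessels_treated

    def summary(self) -> dict:
        rnd = lambda v: None if v is None else round(v, 1)
        return {
            "per_patient_rate_pct": rnd(self.per_patient_rate),
            "per_vessel_rate_pct": rnd(self.per_vessel_rate),
            "n_patients": self.n_patients,
            "n_patients_matched": self.n_patients_matched,
            "n_vessels_treated": self.n_vessels_treated,
            "n_vessels_matched": self.n_vessels_matched,
            "mi_count": self.mi_count,
        }


# ---- SSI computation ---------------------------------------------------


def ssi_from_sweep(
    sweep: SeveritySweepResult,
    artery: str | None = None,
    wss_units: str = "dyn/cm2",
) -> SSIRecord:
    """SSI as the negated OLS slope of WSSmax against FFR over a sweep.

    FFR decreases while WSS rises with severity, so the raw slope is
    negative; the SSI sign convention reports its magnitude as positive.
    """
    if len(sweep.points) < 2:
        raise ValueError("need at least 2 sweep points for a slope")
    factor = {"dyn/cm2": DYN_CM2_PER_PA, "pa": 1.0}[wss_units.lower().replace("^", "")]
    x = np.array([p.ffr for p in sweep.points])
    y = np.array([p.wss_max_pa * factor for p in sweep.points])
    if np.ptp(x) == 0.0:
        raise DegenerateFitError(
            f"site {sweep.site.site_id!r}: FFR identical across the sweep; slope undefined"
        )
    if len(x) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        r_squared = None
    else:
        fit = stats.linregress(x, y)
        slope = fit.slope
        r_squared = float(fit.rvalue**2)
    return SSIRecord(
        site=sweep.site,
        artery=artery or "",
        ssi=float(-slope),
        r_squared=r_squared,
        points=tuple(sweep.points),
        method="slope_fit",
        wss_units=wss_units,
    )


def ssi_simplified(wss_max_stenosed: float, ffr_stenosed: float) -> float:
    """Simplified ratio SSI = WSSmax / (1 - FFR) under the (1, 0) baseline."""
    if ffr_stenosed >= 1.0:
        raise ValueError(f"ffr_stenosed must be < 1, got {ffr_stenosed}")
    return wss_max_stenosed / (1.0 - ffr_stenosed)


def records_from_sweeps(
    sweeps: Sequence[SeveritySweepResult],
    tree: CoronaryTree,
    wss_units: str = "dyn/cm2",
) -> list[SSIRecord]:
    """SSI records for a batch of sweeps, artery labels resolved from the tree."""
    return [
        ssi_from_sweep(sw, artery=tree.segment(sw.site.segment_id).artery, wss_units=wss_units)
        for sw in sweeps
    ]


def rank_sites(records: Sequence[SSIRecord]) -> SiteRanking:
    """Per-artery and global minimum-SSI sites.

    Ties on the SSI value are broken by artery order (RCA, LAD, LCX) and
    then by the proximal-most site position; exact ties set ``tied``.
    """
    if not records:
        raise ValueError("rank_sites requires at least one record")

    def key(r: SSIRecord):
        return (r.ssi, _ARTERY_ORDER.get(r.artery, len(ARTERIES)), r.site.position)

    per_artery: dict[str, SSIRecord] = {}
    for rec in sorted(records, key=key):
        per_artery.setdefault(rec.artery, rec)
    global_min = min(per_artery.values(), key=key)
    tied = sum(1 for r in records if r.ssi == global_min.ssi) > 1
    return SiteRanking(per_artery=per_artery, global_min=global_min, tied=tied)


# ---- clinical concordance ---------------------------------------------


def concordance_report(
    predictions: Mapping[str, Mapping[str, str]],
    observations: Sequence[PatientObservation],
) -> ConcordanceReport:
    """Compare per-artery minimum-SSI site predictions with PCI ground truth.

    ``predictions`` maps patient_id -> artery -> predicted minimum-SSI site
    id.  A treated vessel matches when the predicted site for its artery is
    the PCI site; a patient matches when *every* treated vessel matches.
    """
    n_vessels = n_vessels_matched = 0
    n_patients_matched = 0
    mi_count = 0
    for obs in observations:
        if obs.patient_id not in predictions:
            raise AlignmentError(f"no predictions for patient {obs.patient_id!r}")
        pred = predictions[obs.patient_id]
        if obs.mi_observed:
            mi_count += 1
        patient_ok = True
        for artery, pci_site in obs.pci_sites.items():
            if artery not in obs.evaluated_arteries:
                raise AlignmentError(
                    f"patient {obs.patient_id!r}: treated artery {artery} was not evaluated"
                )
            if artery not in pred:
                raise AlignmentError(
                    f"patient {obs.patient_id!r}: no prediction for treated artery {artery}"
                )
            n_vessels += 1
            if pred[artery] == pci_site:
                n_vessels_matched += 1
            else:
                patient_ok = False
        if patient_ok:
            n_patients_matched += 1
    return ConcordanceReport(
        n_patients=len(observations),
        n_patients_matched=n_patients_matched,
        n_vessels_treated=n_vessels,
        n_vessels_matched=n_vessels_matched,
        mi_count=mi_count,
    )
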