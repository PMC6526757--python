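"""Deterministic synthetic inputs: coronary trees, inlet waveforms, and the
pilot-cohort concordance fixture.

The tree generator emulates the morphometry that matters to the resistance
model — per-artery summed lengths, branch counts, tapering diameters, and
the RCA territory split — not true anatomic shape.  All generators are
pure functions of their parameters (fixed seed, identical output).

The cohort fixture encodes the published pilot study's per-patient
per-artery minimum-SSI values, MI flags and PCI match marks, so the
ranking and concordance reporters are testable without any patient data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np

from .coronary_model import CoronaryTree, Segment
from .ssi_analysis import PatientObservation, SSIRecord
from .virtual_stenosis import CandidateSite


@dataclass(frozen=True)
class TreeGenParams:
    """Morphometric ranges for the synthetic tree generator.

    ``n_branches_per_artery`` counts segments per artery (1 = a bare
    trunk).  Lengths in mm; diameters in mm.  ``rca_rv_fraction`` is the
    fraction of cumulative RCA length tagged as right-ventricle-feeding.
    Diameters are floored at 1.7/1.6 mm (prox/dist) so every generated
    segment qualifies at the default 1.5 mm summed-length threshold.
    """

    seed: int = 0
    n_branches_per_artery: int = 3
    trunk_length_mm: tuple[float, float] = (40.0, 120.0)
    branch_length_mm: tuple[float, float] = (20.0, 60.0)
    root_diameter_mm: tuple[float, float] = (2.5, 4.5)
    taper_ratio: tuple[float, float] = (0.6, 0.9)
    rca_rv_fraction: float = 0.55

    def __post_init__(self):
        if not 1 <= self.n_branches_per_artery <= 6:
            raise ValueError("n_branches_per_artery must be in 1..6")
        for name in ("trunk_length_mm", "branch_length_mm", "root_diameter_mm", "taper_ratio"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} range must be positive and ordered")
        if not 0.0 < self.rca_rv_fraction < 1.0:
            raise ValueError("rca_rv_fraction must be in (0, 1)")


_D_PROX_FLOOR = 1.7
_D_DIST_FLOOR = 1.6


def generate_tree(params: TreeGenParams) -> CoronaryTree:
    """Generate a valid seeded three-artery tree."""
    rng = np.random.default_rng(params.seed)
    segments: list[Segment] = []
    for artery in ("RCA", "LAD", "LCX"):
        art_segs: list[Segment] = []
        d_prox = float(rng.uniform(*params.root_diameter_mm))
        d_dist = max(d_prox * float(rng.uniform(*params.taper_ratio)), _D_DIST_FLOOR)
        trunk = Segment(
            id=f"{artery}_0",
            artery=artery,
            parent_id=None,
            length_mm=float(rng.uniform(*params.trunk_length_mm)),
            d_prox_mm=d_prox,
            d_dist_mm=min(d_dist, d_prox),
            territory="RV" if artery == "RCA" else "NA",
        )
        art_segs.append(trunk)
        for i in range(1, params.n_branches_per_artery):
            parent = art_segs[int(rng.integers(0, len(art_segs)))]
            d_prox = max(parent.d_dist_mm * float(rng.uniform(0.85, 0.98)), _D_PROX_FLOOR)
            d_dist = max(d_prox * float(rng.uniform(*params.taper_ratio)), _D_DIST_FLOOR)
            art_segs.append(
                Segment(
                    id=f"{artery}_{i}",
                    artery=artery,
                    parent_id=parent.id,
                    length_mm=float(rng.uniform(*params.branch_length_mm)),
                    d_prox_mm=d_prox,
                    d_dist_mm=min(d_dist, d_prox),
                    territory="RV" if artery == "RCA" else "NA",
                )
            )
        if artery == "RCA":
            art_segs = _tag_rca_territories(art_segs, params.rca_rv_fraction)
        segments.extend(art_segs)
    tree = CoronaryTree(patient_id=f"synthetic_{params.seed}", segments=segments)
    tree.validate()
    return tree


def _tag_rca_territories(segs: list[Segment], rv_fraction: float) -> list[Segment]:
    """Tag RCA segments RV/LV by cumulative length; force both when >=2 segments."""
    total = sum(s.length_mm for s in segs)
    tagged: list[Segment] = []
    cum = 0.0
    for s in segs:
        mid = cum + 0.5 * s.length_mm
        territory = "RV" if mid < rv_fraction * total else "LV"
        tagged.append(Segment(**{**s.__dict__, "territory": territory}))
        cum += s.length_mm
    if len(tagged) >= 2:
        territories = {s.territory for s in tagged}
        if territories == {"RV"}:
            tagged[-1] = Segment(**{**tagged[-1].__dict__, "territory": "LV"})
        elif territories == {"LV"}:
            tagged[0] = Segment(**{**tagged[0].__dict__, "territory": "RV"})
    return tagged


# ---- inlet pressure waveform ------------------------------------------


@dataclass(frozen=True)
class InletWaveform:
    """One cardiac cycle of aortic pressure, sampled uniformly over the period."""

    times_s: tuple
    pressures_mmHg: tuple
    sbp: float
    dbp: float
    heart_rate_bpm: float

    @property
    def period_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    @property
    def mean_pressure(self) -> float:
        return float(np.mean(self.pressures_mmHg))


#: fraction of the period spent in systole
_SYSTOLE_FRACTION = 1.0 / 3.0
#: diastolic exponential decay constants per diastole duration
_DECAY_CONSTANT = 5.0


def _raw_shape(t_frac: np.ndarray) -> np.ndarray:
    """Unit-amplitude cycle shape on t/T in [0, 1): half-sine rise, exp decay."""
    s = np.empty_like(t_frac)
    sys_mask = t_frac < _SYSTOLE_FRACTION
    s[sys_mask] = np.sin(np.pi * t_frac[sys_mask] / (2.0 * _SYSTOLE_FRACTION))
    dia = (t_frac[~sys_mask] - _SYSTOLE_FRACTION) / (1.0 - _SYSTOLE_FRACTION)
    s[~sys_mask] = np.exp(-_DECAY_CONSTANT * dia)
    return s


def generate_waveform(
    sbp: float, dbp: float, heart_rate_bpm: float, n_samples: int = 64
) -> InletWaveform:
    """Parametric arterial pressure waveform scaled to the given SBP/DBP.

    Two-phase shape: half-sine systolic rise over the first third of the
    period, exponential diastolic decay over the rest, affinely rescaled so
    the sampled maximum is exactly ``sbp`` and the minimum exactly ``dbp``.
    The resulting mean is close to the clinical estimate DBP + PP/3.
    """
    if not sbp > dbp > 0:
        raise ValueError("require sbp > dbp > 0")
    if heart_rate_bpm <= 0:
        raise ValueError("heart_rate_bpm must be > 0")
    if n_samples < 32:
        raise ValueError("n_samples must be >= 32")
    period = 60.0 / heart_rate_bpm
    t_frac = np.arange(n_samples) / n_samples
    s = _raw_shape(t_frac)
    s = (s - s.min()) / (s.max() - s.min())
    p = dbp + (sbp - dbp) * s
    return InletWaveform(
        times_s=tuple(t_frac * period),
        pressures_mmHg=tuple(p),
        sbp=sbp,
        dbp=dbp,
        heart_rate_bpm=heart_rate_bpm,
    )


def waveform_analytic_mean(sbp: float, dbp: float) -> float:
    """Closed-form cycle mean of the parametric waveform (independent of HR)."""
    # systole: mean of sin(pi u / 2) over u in [0,1] is 2/pi
    mean_sys = 2.0 / np.pi
    # diastole: mean of exp(-c v) over v in [0,1]
    c = _DECAY_CONSTANT
    mean_dia = (1.0 - np.exp(-c)) / c
    mean_shape = _SYSTOLE_FRACTION * mean_sys + (1.0 - _SYSTOLE_FRACTION) * mean_dia
    return dbp + (sbp - dbp) * mean_shape


# ---- pilot cohort fixture ---------------------------------------------

# Per-case, per-artery minimum SSI (None = artery not evaluated), MI flag,
# and per-treated-artery match mark (True = minimum-SSI site co-localised
# with the PCI site, False = it did not).
_COHORT = {
    "I": {"ssi": {"RCA": 546.0, "LAD": 581.0, "LCX": 543.0}, "mi": True,
          "treated": {"RCA": True, "LCX": True}},
    "II": {"ssi": {"RCA": 412.0, "LAD": 329.0, "LCX": 239.0}, "mi": True,
           "treated": {"LAD": True, "LCX": True}},
    "III": {"ssi": {"RCA": 792.0, "LAD": 874.0, "LCX": 429.0}, "mi": False,
            "treated": {"LCX": True}},
    "IV": {"ssi": {"RCA": 729.0, "LAD": 793.0, "LCX": None}, "mi": False,
           "treated": {"RCA": True}},
    "V": {"ssi": {"RCA": 468.0, "LAD": 755.0, "LCX": 877.0}, "mi": True,
          "treated": {"LAD": False}},
    "VI": {"ssi": {"RCA": 520.0, "LAD": 980.0, "LCX": 532.0}, "mi": True,
           "treated": {"LAD": False}},
    "VII": {"ssi": {"RCA": 1171.0, "LAD": 1238.0, "LCX": 1400.0}, "mi": False,
            "treated": {"RCA": True}},
}


def table1_fixture() -> tuple[dict[str, dict[str, float | None]], list[PatientObservation]]:
    """Encoded pilot-cohort table: per-artery minimum SSI values and observations.

    PCI site identifiers are synthetic labels: for a matched vessel the
    predicted and PCI site ids coincide, for a mismatched vessel they
    differ, reproducing the published match marks exactly.
    """
    min_ssi = {case: dict(entry["ssi"]) for case, entry in _COHORT.items()}
    observations = []
    for case, entry in _COHORT.items():
        pci_sites = {
            artery: _pci_site_id(case, artery, matched)
            for artery, matched in entry["treated"].items()
        }
        evaluated = frozenset(a for a, v in entry["ssi"].items() if v is not None)
        observations.append(
            PatientObservation(
                patient_id=case,
                mi_observed=entry["mi"],
                pci_sites=pci_sites,
                evaluated_arteries=evaluated,
            )
        )
    return min_ssi, observations


def _pci_site_id(case: str, artery: str, matched: bool) -> str:
    return f"{case}_{artery}_lesion" if matched else f"{case}_{artery}_pci"


def table1_predictions() -> dict[str, dict[str, str]]:
    """Synthetic per-artery minimum-SSI site ids consistent with the match marks."""
    preds: dict[str, dict[str, str]] = {}
    for case, entry in _COHORT.items():
        preds[case] = {
            artery: f"{case}_{artery}_lesion"
            for artery, v in entry["ssi"].items()
            if v is not None
        }
    return preds


def table1_minima_records(case_id: str) -> list[SSIRecord]:
    """Per-artery minimum-SSI records of one fixture case, ready for ranking.

    The values are treated as unitless labels for ranking/reporting; no
    hemodynamic meaning is attached to their magnitudes here.
    """
    entry = _COHORT[case_id]
    records = []
    for artery, value in entry["ssi"].items():
        if value is None:
            continue
        records.append(
            SSIRecord(
                site=CandidateSite(
                    site_id=f"{case_id}_{artery}_min", segment_id=f"{case_id}_{artery}", position=0.0
                ),
                artery=artery,
                ssi=value,
                r_squared=None,
                points=(),
                method="slope_fit",
                wss_units="unitless",
            )
        )
    return records


def load_table1_observations_csv() -> list[PatientObservation]:
    """Load the packaged observations CSV (same content as :func:`table1_fixture`)."""
    path = resources.files("ssikit.data") / "table1_observations.csv"
    return observations_from_csv_text(path.read_text(encoding="utf-8"))


def observations_from_csv_text(text: str) -> list[PatientObservation]:
    """Parse observations from CSV (patient_id, mi, artery, treated, pci_site_id)."""
    by_patient: dict[str, dict] = {}
    for row in csv.DictReader(text.splitlines()):
        pid = row["patient_id"]
        rec = by_patient.setdefault(
            pid, {"mi": row["mi"].strip().upper() == "Y", "pci": {}, "evaluated": set()}
        )
        artery = row["artery"]
        rec["evaluated"].add(artery)
        if str(row["treated"]).strip() == "1":
            rec["pci"][artery] = row["pci_site_id"]
    return [
        PatientObservation(
            patient_id=pid,
            mi_observed=rec["mi"],
            pci_sites=rec["pci"],
            evaluated_arteries=frozenset(rec["evaluated"]),
        )
        for pid, rec in by_patient.items()
    ]


def observations_to_csv_rows(
    observations: list[PatientObservation],
) -> list[dict[str, str]]:
    """Flatten observations to CSV rows (one row per evaluated artery)."""
    rows = []
    for obs in observations:
        for artery in ("RCA", "LAD", "LCX"):
            if artery not in obs.evaluated_arteries:
                continue
            treated = artery in obs.pci_sites
            rows.append(
                {
                    "patient_id": obs.patient_id,
                    "mi": "Y" if obs.mi_observed else "N",
                    "artery": artery,
                    "treated": "1" if treated else "0",
                    "pci_site_id": obs.pci_sites.get(artery, ""),
                }
            )
    return rows
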