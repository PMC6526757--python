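"""Reduced (centerline-graph) coronary tree model.

A coronary tree is a forest of up to three rooted trees, one per main
epicardial artery (RCA, LAD, LCX).  Each :class:`Segment` is a straight
vessel piece with a length and linearly tapering diameter; RCA segments
additionally carry a perfusion-territory tag (right- or left-ventricular)
because the outlet resistance model treats the two RCA territories
differently.

The module also computes the per-artery *summed lengths*: the total length
of segments whose proximal diameter exceeds a configurable threshold.
These lengths calibrate the lumped-parameter outlet resistances — the
physiological rationale being that longer epicardial vessels feed more
myocardial mass and therefore face less microvascular resistance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import TopologyError, TreeValidationError

ARTERIES = ("RCA", "LAD", "LCX")
TERRITORIES = ("RV", "LV", "NA")

#: sanity bound on intra-segment diameter expansion (distal/proximal)
DEFAULT_MAX_EXPANSION_RATIO = 1.5

#: default diameter threshold (mm) for summed-length qualification
DEFAULT_DIAMETER_THRESHOLD_MM = 1.5


@dataclass(frozen=True)
class Segment:
    """One straight centerline piece of a coronary artery.

    ``parent_id is None`` marks the root segment of its artery.  Diameters
    taper linearly from the proximal to the distal end.  ``territory`` is
    meaningful only for RCA segments (``"RV"`` or ``"LV"``); LAD/LCX
    segments carry ``"NA"``.
    """

    id: str
    artery: str
    parent_id: str | None
    length_mm: float
    d_prox_mm: float
    d_dist_mm: float
    territory: str = "NA"

    def diameter_at(self, position: float) -> float:
        """Diameter (mm) at a fractional position in [0, 1] from the proximal end."""
        if not 0.0 <= position <= 1.0:
            raise ValueError(f"position must be in [0, 1], got {position}")
        return self.d_prox_mm + (self.d_dist_mm - self.d_prox_mm) * position

    @property
    def mean_diameter_mm(self) -> float:
        return 0.5 * (self.d_prox_mm + self.d_dist_mm)


@dataclass
class CoronaryTree:
    """A patient's coronary segment forest (one rooted tree per artery)."""

    patient_id: str
    segments: list[Segment] = field(default_factory=list)
    #: aortic mean pressure (mmHg) to apply at the artery roots; set at solve time
    inlet_pressure_ref: float | None = None

    # ---- lookups -------------------------------------------------------

    def segment(self, segment_id: str) -> Segment:
        try:
            return self._index()[segment_id]
        except KeyError:
            raise KeyError(f"unknown segment id {segment_id!r}") from None

    def _index(self) -> dict[str, Segment]:
        return {s.id: s for s in self.segments}

    def children_map(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {s.id: [] for s in self.segments}
        for s in self.segments:
            if s.parent_id is not None:
                out[s.parent_id].append(s)
        return out

    def arteries(self) -> tuple[str, ...]:
        present = {s.artery for s in self.segments}
        return tuple(a for a in ARTERIES if a in present)

    def root(self, artery: str) -> Segment:
        roots = [s for s in self.segments if s.artery == artery and s.parent_id is None]
        if len(roots) != 1:
            raise TopologyError(f"artery {artery} has {len(roots)} roots, expected 1")
        return roots[0]

    def terminals(self, artery: str | None = None) -> list[Segment]:
        """Segments with no children (outlet segments), optionally per artery."""
        kids = self.children_map()
        segs = [s for s in self.segments if not kids[s.id]]
        if artery is not None:
            segs = [s for s in segs if s.artery == artery]
        return segs

    def diameter_at(self, segment_id: str, position: float) -> float:
        return self.segment(segment_id).diameter_at(position)

    # ---- validation ----------------------------------------------------

    def validate(self, max_expansion_ratio: float = DEFAULT_MAX_EXPANSION_RATIO) -> None:
        """Check every structural and geometric invariant; raise on violation."""
        seen: set[str] = set()
        for s in self.segments:
            if s.id in seen:
                raise TreeValidationError(f"duplicate segment id {s.id!r}")
            seen.add(s.id)
            if s.artery not in ARTERIES:
                raise TreeValidationError(
                    f"segment {s.id!r}: artery must be one of {ARTERIES}, got {s.artery!r}"
                )
            for fname in ("length_mm", "d_prox_mm", "d_dist_mm"):
                val = getattr(s, fname)
                if not (isinstance(val, (int, float)) and math.isfinite(val) and val > 0):
                    raise TreeValidationError(
                        f"segment {s.id!r}: {fname} must be a positive finite number, got {val!r}"
                    )
            if s.d_dist_mm > s.d_prox_mm * max_expansion_ratio:
                raise TreeValidationError(
                    f"segment {s.id!r}: d_dist_mm exceeds {max_expansion_ratio} x d_prox_mm"
                )
            if s.territory not in TERRITORIES:
                raise TreeValidationError(
                    f"segment {s.id!r}: territory must be one of {TERRITORIES}, got {s.territory!r}"
                )
            if s.artery == "RCA" and s.territory not in ("RV", "LV"):
                raise TreeValidationError(
                    f"segment {s.id!r}: RCA segments require territory RV or LV"
                )
            if s.artery != "RCA" and s.territory != "NA":
                raise TreeValidationError(
                    f"segment {s.id!r}: non-RCA segments must have territory NA"
                )

        index = self._index()
        for s in self.segments:
            if s.parent_id is None:
                continue
            if s.parent_id == s.id:
                raise TopologyError(f"segment {s.id!r} is its own parent")
            parent = index.get(s.parent_id)
            if parent is None:
                raise TopologyError(f"segment {s.id!r}: parent {s.parent_id!r} does not exist")
            if parent.artery != s.artery:
                raise TopologyError(
                    f"segment {s.id!r} ({s.artery}) attached to parent of artery {parent.artery}"
                )

        # one root per present artery
        for artery in self.arteries():
            n_roots = sum(
                1 for s in self.segments if s.artery == artery and s.parent_id is None
            )
            if n_roots != 1:
                raise TopologyError(f"artery {artery} has {n_roots} root segments, expected 1")

        # cycle / orphan-chain detection by parent walks
        for s in self.segments:
            visited = {s.id}
            cur = s
            while cur.parent_id is not None:
                if cur.parent_id in visited:
                    raise TopologyError(f"cycle detected through segment {s.id!r}")
                visited.add(cur.parent_id)
                cur = index[cur.parent_id]


@dataclass(frozen=True)
class SummedLengths:
    """Per-artery total length (mm) of segments with proximal diameter above threshold.

    RCA length is split into the right-ventricle- and left-ventricle-feeding
    parts, which the resistance model weights differently.
    """

    l_lad: float
    l_lcx: float
    l_rca_rv: float
    l_rca_lv: float
    diameter_threshold_mm: float


def summed_lengths(
    tree: CoronaryTree, diameter_threshold_mm: float = DEFAULT_DIAMETER_THRESHOLD_MM
) -> SummedLengths:
    """Sum segment lengths per artery (RCA split by territory).

    A segment qualifies when its *proximal* diameter strictly exceeds the
    threshold; non-qualifying segments are excluded entirely.  Empty
    arteries yield zero.
    """
    if diameter_threshold_mm <= 0:
        raise ValueError("diameter_threshold_mm must be > 0")
    acc = {"LAD": 0.0, "LCX": 0.0, "RCA_RV": 0.0, "RCA_LV": 0.0}
    for s in tree.segments:
        if s.d_prox_mm <= diameter_threshold_mm:
            continue
        key = s.artery if s.artery != "RCA" else f"RCA_{s.territory}"
        acc[key] += s.length_mm
    return SummedLengths(
        l_lad=acc["LAD"],
        l_lcx=acc["LCX"],
        l_rca_rv=acc["RCA_RV"],
        l_rca_lv=acc["RCA_LV"],
        diameter_threshold_mm=diameter_threshold_mm,
    )


def path_to_root(tree: CoronaryTree, segment_id: str) -> list[str]:
    """Root-first chain of segment ids from the artery root to ``segment_id``."""
    index = tree._index()
    if segment_id not in index:
        raise KeyError(f"unknown segment id {segment_id!r}")
    chain: list[str] = []
    cur: Segment | None = index[segment_id]
    seen: set[str] = set()
    while cur is not None:
        if cur.id in seen:
            raise TopologyError(f"cycle detected through segment {segment_id!r}")
        seen.add(cur.id)
        chain.append(cur.id)
        cur = index[cur.parent_id] if cur.parent_id is not None else None
    chain.reverse()
    return chain


# ---- file format -------------------------------------------------------

_SEGMENT_KEYS = ("id", "artery", "parent_id", "length_mm", "d_prox_mm", "d_dist_mm", "territory")


def _segment_to_dict(s: Segment) -> dict:
    return {
        "id": s.id,
        "artery": s.artery,
        "parent_id": s.parent_id,
        "length_mm": s.length_mm,
        "d_prox_mm": s.d_prox_mm,
        "d_dist_mm": s.d_dist_mm,
        "territory": s.territory,
    }


def save_tree(tree: CoronaryTree, path: str | Path) -> None:
    """Write a tree to the project JSON format (UTF-8, 2-space indent, fixed key order)."""
    tree.validate()
    doc = {
        "patient_id": tree.patient_id,
        "segments": [_segment_to_dict(s) for s in tree.segments],
    }
    Path(path).write_text(json.dumps(doc, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")


def load_tree(path: str | Path) -> CoronaryTree:
    """Read and validate a tree from the project JSON format."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise TreeValidationError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "patient_id" not in doc or "segments" not in doc:
        raise TreeValidationError(f"{path}: expected object with 'patient_id' and 'segments'")
    segments = []
    for i, raw in enumerate(doc["segments"]):
        if not isinstance(raw, dict):
            raise TreeValidationError(f"segment #{i}: expected an object")
        sid = raw.get("id", f"#{i}")
        for key in _SEGMENT_KEYS:
            if key not in raw and key != "territory":
                raise TreeValidationError(f"segment {sid!r}: missing field {key!r}")
        territory = raw.get("territory")
        segments.append(
            Segment(
                id=str(raw["id"]),
                artery=raw["artery"],
                parent_id=raw["parent_id"],
                length_mm=raw["length_mm"],
                d_prox_mm=raw["d_prox_mm"],
                d_dist_mm=raw["d_dist_mm"],
                territory="NA" if territory is None else territory,
            )
        )
    tree = CoronaryTree(patient_id=str(doc["patient_id"]), segments=segments)
    tree.validate()
    return tree


def split_segment(tree: CoronaryTree, segment_id: str, fraction: float) -> CoronaryTree:
    """Return a new tree with one segment split in two at ``fraction`` of its length.

    Diameters at the split point follow the linear taper, so the split is
    geometrically neutral: summed lengths and hydraulics are unchanged up to
    discretisation of the mean diameter.  Used mainly by invariance tests.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    seg = tree.segment(segment_id)
    d_mid = seg.diameter_at(fraction)
    prox_part = Segment(
        id=f"{seg.id}__a",
        artery=seg.artery,
        parent_id=seg.parent_id,
        length_mm=seg.length_mm * fraction,
        d_prox_mm=seg.d_prox_mm,
        d_dist_mm=d_mid,
        territory=seg.territory,
    )
    dist_part = Segment(
        id=f"{seg.id}__b",
        artery=seg.artery,
        parent_id=prox_part.id,
        length_mm=seg.length_mm * (1.0 - fraction),
        d_prox_mm=d_mid,
        d_dist_mm=seg.d_dist_mm,
        territory=seg.territory,
    )
    new_segments: list[Segment] = []
    for s in tree.segments:
        if s.id == segment_id:
            new_segments.extend([prox_part, dist_part])
        elif s.parent_id == segment_id:
            new_segments.append(
                Segment(
                    id=s.id,
                    artery=s.artery,
                    parent_id=dist_part.id,
                    length_mm=s.length_mm,
                    d_prox_mm=s.d_prox_mm,
                    d_dist_mm=s.d_dist_mm,
                    territory=s.territory,
                )
            )
        else:
            new_segments.append(s)
    out = CoronaryTree(patient_id=tree.patient_id, segments=new_segments)
    out.validate()
    return out
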