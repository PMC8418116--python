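"""Vessel centerline/radius geometry and coronary-tree topology.

A vessel segment is a 1D arc-length parameterisation of the lumen: at each
centerline position (mm from the segment inlet) we store the local lumen
radius (mm).  This is the only geometric information the reduced-order
pressure-drop engine consumes; 3D coordinates, if present upstream, are
ignored.  Trees are binary: an internal node either continues into one
child segment or bifurcates into exactly two.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, InvalidArgumentError, UnsupportedTopologyError

__all__ = [
    "VesselSegment",
    "StenosisSpec",
    "CoronaryTree",
    "make_straight_vessel",
    "apply_stenosis",
    "percent_diameter_stenosis",
    "reference_radius",
    "read_centerline",
    "write_centerline",
    "read_tree",
]

#: Fraction of arc length at each end of a segment treated as disease-free
#: when estimating the reference (healthy) caliber.
REFERENCE_END_FRACTION = 0.10


@dataclass(frozen=True)
class VesselSegment:
    """A coronary segment as (arc position, radius) samples, both in mm.

    ``arc_mm`` must be strictly increasing and ``radius_mm`` strictly
    positive; at least two samples are required.
    """

    segment_id: str
    arc_mm: np.ndarray
    radius_mm: np.ndarray
    label: str = ""

    def __post_init__(self):
        arc = np.asarray(self.arc_mm, dtype=float)
        radius = np.asarray(self.radius_mm, dtype=float)
        object.__setattr__(self, "arc_mm", arc)
        object.__setattr__(self, "radius_mm", radius)
        if arc.ndim != 1 or radius.shape != arc.shape:
            raise InvalidArgumentError("arc_mm and radius_mm must be 1D arrays of equal length")
        if arc.size < 2:
            raise InvalidArgumentError("a segment needs at least 2 centerline samples")
        if not np.all(np.diff(arc) > 0):
            raise InvalidArgumentError("arc positions must be strictly increasing")
        if not np.all(radius > 0):
            raise InvalidArgumentError("all radii must be positive")

    @property
    def length_mm(self) -> float:
        return float(self.arc_mm[-1] - self.arc_mm[0])

    @property
    def n_samples(self) -> int:
        return int(self.arc_mm.size)


@dataclass(frozen=True)
class StenosisSpec:
    """Parametric focal narrowing.

    ``area_stenosis`` is the fractional lumen-area reduction at the throat
    (0.70 = "70% area stenosis"); the narrowing spans
    [center - length/2, center + length/2] along the segment arc.
    """

    center_mm: float
    length_mm: float
    area_stenosis: float

    def __post_init__(self):
        if not 0.0 <= self.area_stenosis < 1.0:
            raise InvalidArgumentError("area_stenosis must lie in [0, 1)")
        if self.length_mm <= 0:
            raise InvalidArgumentError("stenosis length must be positive")


def make_straight_vessel(
    diameter_mm: float, length_mm: float, n_samples: int, segment_id: str = "vessel", label: str = ""
) -> VesselSegment:
    """Uniform straight tube: constant radius at evenly spaced arc positions."""
    if diameter_mm <= 0 or length_mm <= 0:
        raise InvalidArgumentError("diameter and length must be positive")
    if n_samples < 2:
        raise InvalidArgumentError("need at least 2 samples")
    arc = np.linspace(0.0, length_mm, n_samples)
    radius = np.full(n_samples, diameter_mm / 2.0)
    return VesselSegment(segment_id, arc, radius, label)


def apply_stenosis(segment: VesselSegment, spec: StenosisSpec) -> VesselSegment:
    """Superimpose a cosine-tapered narrowing on a segment.

    Within the stenosis window the radius is scaled by
    ``1 - (1 - sqrt(1 - sa)) * (1 + cos(2*pi*(z - center)/length)) / 2``
    so the throat area is exactly ``(1 - sa)`` times the local healthy
    area, with a smooth (C1) blend to the unmodified profile at the window
    edges.  A sample is inserted at the throat position if not already on
    the grid, so the minimal radius is attained exactly.
    """
    half = spec.length_mm / 2.0
    lo, hi = spec.center_mm - half, spec.center_mm + half
    if lo < segment.arc_mm[0] - 1e-12 or hi > segment.arc_mm[-1] + 1e-12:
        raise InvalidArgumentError("stenosis window must lie within the segment")
    if spec.area_stenosis == 0.0:
        return segment

    arc = segment.arc_mm
    radius = segment.radius_mm
    if not np.any(np.isclose(arc, spec.center_mm, rtol=0.0, atol=1e-12)):
        # local healthy radius at the throat, before narrowing
        r_center = float(np.interp(spec.center_mm, arc, radius))
        idx = int(np.searchsorted(arc, spec.center_mm))
        arc = np.insert(arc, idx, spec.center_mm)
        radius = np.insert(radius, idx, r_center)

    depth = 1.0 - math.sqrt(1.0 - spec.area_stenosis)
    in_window = (arc >= lo - 1e-12) & (arc <= hi + 1e-12)
    taper = np.ones_like(radius)
    z = arc[in_window]
    taper[in_window] = 1.0 - depth * (1.0 + np.cos(2.0 * np.pi * (z - spec.center_mm) / spec.length_mm)) / 2.0
    return replace(segment, arc_mm=arc, radius_mm=radius * taper)


def reference_radius(segment: VesselSegment) -> float:
    """Healthy-caliber estimate: mean radius over the proximal and distal
    10% of arc length (assumed disease-free)."""
    arc = segment.arc_mm
    span = segment.length_mm
    ends = (arc <= arc[0] + REFERENCE_END_FRACTION * span) | (arc >= arc[-1] - REFERENCE_END_FRACTION * span)
    return float(segment.radius_mm[ends].mean())


def percent_diameter_stenosis(segment: VesselSegment) -> float:
    """Fractional diameter stenosis: 1 - min(radius)/reference radius."""
    return 1.0 - float(segment.radius_mm.min()) / reference_radius(segment)


def lumen_volume_mm3(segment: VesselSegment) -> float:
    """Lumen volume by summing conical frusta between successive samples."""
    r = segment.radius_mm
    dz = np.diff(segment.arc_mm)
    r0, r1 = r[:-1], r[1:]
    return float(np.sum(np.pi / 3.0 * dz * (r0**2 + r0 * r1 + r1**2)))


# ---------------------------------------------------------------------------
# Centerline CSV I/O: header `arc_mm,radius_mm`, '#' comments, '.' decimal.

def read_centerline(path: str | Path, segment_id: str | None = None, label: str = "") -> VesselSegment:
    path = Path(path)
    arcs: list[float] = []
    radii: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].lstrip().startswith("#")]
    if not rows:
        raise FormatError(f"{path}: empty centerline file")
    header = [c.strip().lower() for c in rows[0]]
    try:
        i_arc, i_rad = header.index("arc_mm"), header.index("radius_mm")
    except ValueError:
        raise FormatError(f"{path}: header must contain arc_mm and radius_mm columns") from None
    for n, row in enumerate(rows[1:], start=1):
        try:
            a, r = float(row[i_arc]), float(row[i_rad])
        except (ValueError, IndexError):
            raise FormatError(f"{path}: unparseable numeric fields", row=n) from None
        if r <= 0:
            raise FormatError(f"{path}: non-positive radius {r}", row=n)
        if arcs and a <= arcs[-1]:
            raise FormatError(f"{path}: arc positions must be strictly increasing", row=n)
        arcs.append(a)
        radii.append(r)
    if len(arcs) < 2:
        raise FormatError(f"{path}: need at least 2 centerline samples")
    return VesselSegment(segment_id or path.stem, np.array(arcs), np.array(radii), label)


def write_centerline(segment: VesselSegment, path: str | Path) -> None:
    """Write a centerline CSV (9 significant digits, LF line endings)."""
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write("arc_mm,radius_mm\n")
        for a, r in zip(segment.arc_mm, segment.radius_mm):
            fh.write(f"{a:.9g},{r:.9g}\n")


# ---------------------------------------------------------------------------
# Coronary tree

@dataclass(frozen=True)
class CoronaryTree:
    """Binary tree of vessel segments.

    ``children`` maps a segment id to its ordered child ids (1 = simple
    continuation, 2 = bifurcation); leaves are absent or map to [].
    """

    segments: dict[str, VesselSegment]
    root: str
    children: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        ids = set(self.segments)
        if self.root not in ids:
            raise InvalidArgumentError(f"root {self.root!r} is not a known segment")
        parent: dict[str, str] = {}
        for pid, kids in self.children.items():
            if pid not in ids:
                raise InvalidArgumentError(f"unknown parent id {pid!r}")
            if len(kids) > 2:
                raise UnsupportedTopologyError(f"node {pid!r} has {len(kids)} children; at most 2 supported")
            for kid in kids:
                if kid not in ids:
                    raise InvalidArgumentError(f"unknown child id {kid!r}")
                if kid in parent:
                    raise InvalidArgumentError(f"segment {kid!r} has two parents")
                parent[kid] = pid
        if self.root in parent:
            raise InvalidArgumentError("root must have no parent")
        # reachability doubles as the acyclicity check on this parent structure
        seen = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise InvalidArgumentError("cycle detected in tree topology")
            seen.add(node)
            stack.extend(self.children.get(node, []))
        orphans = ids - seen
        if orphans:
            raise InvalidArgumentError(f"segments unreachable from root (extra roots?): {sorted(orphans)}")

    def child_segments(self, segment_id: str) -> list[VesselSegment]:
        return [self.segments[c] for c in self.children.get(segment_id, [])]


def read_tree(path: str | Path) -> CoronaryTree:
    """Read tree JSON: {"segments": [{"id","label","centerline_file"}, ...],
    "root": id, "children": {id: [id, ...]}}.  Centerline paths are
    resolved relative to the JSON file."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from None
    try:
        entries = doc["segments"]
        root = doc["root"]
    except (KeyError, TypeError):
        raise FormatError(f"{path}: tree JSON needs 'segments' and 'root'") from None
    segments = {}
    for entry in entries:
        seg = read_centerline(path.parent / entry["centerline_file"], segment_id=entry["id"], label=entry.get("label", ""))
        segments[entry["id"]] = seg
    children = {k: list(v) for k, v in doc.get("children", {}).items()}
    return CoronaryTree(segments=segments, root=root, children=children)
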