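"""Skeleton decomposition into vessel segments and oblique classification.

A vessel is modelled as the set of skeleton polylines joining bifurcation
points (>= 3 skeleton neighbours) and free ends.  Each segment gets a
chord orientation in [0, 180) measured from the horizontal with y UP
(image row index increases downward, so theta = atan2(-d_row, d_col)),
and is classified against the hemifield drainage bands: in the right-eye
frame, natural venous drainage runs toward the upper-temporal vortex vein
in the upper hemifield (95-175 deg) and toward the lower-temporal vortex
vein in the lower hemifield (5-85 deg); the opposite band is "unnatural"
and a 5-degree guard band around horizontal/vertical is "neither".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

OBLIQUE_CLASSES = ("natural", "unnatural", "neither")

#: Natural drainage band per hemifield, degrees (inclusive bounds).
UPPER_NATURAL_BAND = (95.0, 175.0)
LOWER_NATURAL_BAND = (5.0, 85.0)


@dataclass(frozen=True)
class VesselSegment:
    """A skeleton polyline between branch points and/or free ends."""

    path: tuple[tuple[int, int], ...]  # (row, col) pixels, ordered
    length_px: float  # step length: 1 per 4-neighbour step, sqrt(2) diagonal
    orientation_deg: float  # chord orientation in [0, 180)
    region: str = ""  # "upper" | "lower"
    oblique_class: str = ""

    @property
    def endpoints(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return self.path[0], self.path[-1]


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

#: Circular neighbourhood order (clockwise from north) for run counting.
_CIRCULAR = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    padded = np.pad(skel.astype(np.uint8), 1)
    count = np.zeros_like(padded, dtype=np.int8)
    for dr, dc in _OFFSETS:
        count += np.roll(np.roll(padded, dr, axis=0), dc, axis=1)
    return count[1:-1, 1:-1] * skel


def _branch_runs(skel: np.ndarray) -> np.ndarray:
    """Per-pixel number of distinct neighbour runs around the 8-ring.

    A run is a maximal block of consecutive skeleton neighbours in the
    circular order; its count equals the number of separate branches
    meeting at the pixel (diagonal pairs belonging to the same branch
    count once, unlike the raw neighbour count).
    """
    padded = np.pad(np.asarray(skel, bool), 1)
    ring = np.stack(
        [
            np.roll(np.roll(padded, -dr, axis=0), -dc, axis=1)[1:-1, 1:-1]
            for dr, dc in _CIRCULAR
        ]
    )
    nxt = np.roll(ring, -1, axis=0)
    transitions = (~ring & nxt).sum(axis=0)
    return transitions * skel


def find_branch_points(skel: np.ndarray) -> set[tuple[int, int]]:
    """Skeleton pixels where >= 3 separate branches meet (8-connectivity)."""
    runs = _branch_runs(np.asarray(skel, bool))
    rows, cols = np.nonzero(runs >= 3)
    return {(int(r), int(c)) for r, c in zip(rows, cols)}


def find_free_ends(skel: np.ndarray) -> set[tuple[int, int]]:
    """Skeleton pixels with exactly 1 skeleton neighbour."""
    counts = _neighbor_count(np.asarray(skel, bool))
    rows, cols = np.nonzero(counts == 1)
    return {(int(r), int(c)) for r, c in zip(rows, cols)}


def segment_orientation(p0: tuple[int, int], p1: tuple[int, int]) -> float:
    """Chord orientation between two pixels, degrees in [0, 180).

    Measured from the horizontal axis with y increasing upward
    (d_y = -d_row), so an up-right chord is 45 deg and a down-right
    chord 135 deg.
    """
    if p0 == p1:
        raise ValueError("coincident endpoints have no orientation")
    theta = math.degrees(math.atan2(-(p1[0] - p0[0]), p1[1] - p0[1])) % 180.0
    return theta


def _path_length(path: list[tuple[int, int]]) -> float:
    length = 0.0
    for (r0, c0), (r1, c1) in zip(path, path[1:]):
        length += math.sqrt(2.0) if (r0 != r1 and c0 != c1) else 1.0
    return length


def extract_segments(skel: np.ndarray) -> list[VesselSegment]:
    """Partition a skeleton into maximal branch-to-branch segments.

    Interior pixels of a segment have exactly two skeleton neighbours;
    endpoints are branch points or free ends.  Isolated cycles (every
    pixel degree 2) are returned as a single closed segment.  Segments
    whose chord degenerates (closed loops) get orientation from their
    longest chord approximation and are rarely relevant on real masks.
    """
    skel = np.asarray(skel, bool)
    counts = _neighbor_count(skel)
    runs = _branch_runs(skel)
    # graph nodes: branch points, free ends, isolated pixels
    node_mask = skel & ((runs >= 3) | (counts <= 1))
    nodes = {(int(r), int(c)) for r, c in zip(*np.nonzero(node_mask))}
    on = {(int(r), int(c)) for r, c in zip(*np.nonzero(skel))}

    def adjacent(p, q):
        return abs(p[0] - q[0]) <= 1 and abs(p[1] - q[1]) <= 1

    def nbrs(p):
        r, c = p
        return [
            (r + dr, c + dc) for dr, dc in _OFFSETS if (r + dr, c + dc) in on
        ]

    def step(prev, cur, allowed=None):
        """Next pixel of the walk.

        Preference order: skip diagonal shortcuts around ``prev``; then
        terminate at a node if one is reachable; then rook moves before
        diagonal moves (stable deterministic tie-break by coordinates).
        """
        cands = [p for p in nbrs(cur) if p != prev]
        if allowed is not None:
            cands = [p for p in cands if p in allowed]
        primary = [p for p in cands if prev is None or not adjacent(p, prev)]
        pool = primary or cands
        if not pool:
            return None
        return min(
            pool,
            key=lambda p: (
                p not in nodes,
                abs(p[0] - cur[0]) + abs(p[1] - cur[1]) > 1,
                p,
            ),
        )

    segments: list[VesselSegment] = []
    visited_edges: set[frozenset] = set()
    visited_px: set[tuple[int, int]] = set()

    for node in sorted(nodes):
        for nxt in sorted(nbrs(node)):
            edge = frozenset((node, nxt))
            if edge in visited_edges:
                continue
            path = [node, nxt]
            visited_edges.add(edge)
            prev, cur = node, nxt
            seen = set(path)
            while cur not in nodes:
                visited_px.add(cur)
                nxt2 = step(prev, cur)
                if nxt2 is None:
                    break  # degenerate; treat cur as an endpoint
                visited_edges.add(frozenset((cur, nxt2)))
                path.append(nxt2)
                prev, cur = cur, nxt2
                if cur in seen:
                    break  # closed back on the walk (nodeless loop)
                seen.add(cur)
            segments.append(_make_segment(path, skel.shape[0]))

    # leftovers: nodeless cycles, plus staircase pixels bypassed by the
    # shortcut rule; walk them as their own (usually tiny) segments so the
    # union of segment paths covers every non-isolated skeleton pixel
    covered = {p for s in segments for p in s.path}
    remaining = on - covered - nodes
    while remaining:
        start = sorted(remaining)[0]
        path = [start]
        prev, cur = None, start
        while True:
            nxt2 = step(prev, cur, allowed=remaining - set(path))
            if nxt2 is None:
                break
            path.append(nxt2)
            prev, cur = cur, nxt2
        remaining -= set(path)
        if len(path) == 1:
            # lone bypassed pixel: anchor it to an adjacent covered pixel
            anchors = [p for p in nbrs(start) if p in covered or p in nodes]
            if not anchors:
                continue  # truly isolated; no segment
            path = [sorted(anchors)[0], start]
        closed = (
            path + [start]
            if len(path) > 2 and adjacent(path[-1], start) and path[0] == start
            else path
        )
        segments.append(_make_segment(closed, skel.shape[0]))
        covered |= set(path)
    return segments


def _make_segment(path: list[tuple[int, int]], height: int) -> VesselSegment:
    p0, p1 = path[0], path[-1]
    if p0 == p1 and len(path) > 2:  # closed loop: orient by farthest pixel
        far = max(path, key=lambda p: (p[0] - p0[0]) ** 2 + (p[1] - p0[1]) ** 2)
        theta = segment_orientation(p0, far) if far != p0 else 0.0
    else:
        theta = segment_orientation(p0, p1)
    mid = path[(len(path) - 1) // 2]
    region = "upper" if mid[0] < height // 2 else "lower"
    return VesselSegment(
        path=tuple(path),
        length_px=_path_length(path),
        orientation_deg=theta,
        region=region,
    )


def classify_oblique(orientation_deg: float, region: str) -> str:
    """Natural / unnatural / neither for one segment orientation.

    Upper hemifield: [95, 175] natural, [5, 85] unnatural; lower
    hemifield the reverse; orientations within 5 deg of horizontal or
    vertical are "neither".
    """
    theta = orientation_deg % 180.0
    in_upper_band = UPPER_NATURAL_BAND[0] <= theta <= UPPER_NATURAL_BAND[1]
    in_lower_band = LOWER_NATURAL_BAND[0] <= theta <= LOWER_NATURAL_BAND[1]
    if not in_upper_band and not in_lower_band:
        return "neither"
    if region == "upper":
        return "natural" if in_upper_band else "unnatural"
    if region == "lower":
        return "natural" if in_lower_band else "unnatural"
    raise ValueError(f"unknown region {region!r}")


def classify_segments(
    segments: list[VesselSegment], min_segment_px: int = 5
) -> list[VesselSegment]:
    """Attach oblique classes; drop sub-threshold segments from statistics."""
    out = []
    for seg in segments:
        if len(seg.path) < min_segment_px:
            continue
        out.append(
            replace(seg, oblique_class=classify_oblique(seg.orientation_deg, seg.region))
        )
    return out


def oblique_ratios(
    segments: list[VesselSegment], regions: tuple[str, ...] = ("upper", "lower")
) -> dict[str, float]:
    """Length-weighted natural/unnatural percentages per hemifield.

    Denominator = total length of classified (natural + unnatural)
    segments in the hemifield; "neither" segments are excluded entirely.
    Empty hemifields yield 0 with a logged warning.
    """
    out = {}
    for region in regions:
        nat = sum(
            s.length_px for s in segments
            if s.region == region and s.oblique_class == "natural"
        )
        unnat = sum(
            s.length_px for s in segments
            if s.region == region and s.oblique_class == "unnatural"
        )
        total = nat + unnat
        if total == 0:
            logger.warning("no classified oblique segments in %s hemifield", region)
            out[f"{region}_natural_pct"] = 0.0
            out[f"{region}_unnatural_pct"] = 0.0
        else:
            out[f"{region}_natural_pct"] = 100.0 * nat / total
            out[f"{region}_unnatural_pct"] = 100.0 * unnat / total
    return out


def midline_crossing_ratios(
    segments: list[VesselSegment], height: int
) -> tuple[float, float]:
    """Fractions of midline-crossing segments per diagonal axis.

    Among segments whose path spans the watershed row H/2: the first
    value is the fraction oriented along the upper-temporal to
    lower-nasal axis (95-175 deg in the OD frame), the second along the
    upper-nasal to lower-temporal axis (5-85 deg).  No crossers -> (0, 0).
    """
    mid = height // 2
    crossers = [
        s for s in segments
        if min(p[0] for p in s.path) < mid <= max(p[0] for p in s.path)
    ]
    if not crossers:
        return 0.0, 0.0
    n = len(crossers)
    f_tn = sum(
        1 for s in crossers
        if UPPER_NATURAL_BAND[0] <= s.orientation_deg <= UPPER_NATURAL_BAND[1]
    )
    f_nt = sum(
        1 for s in crossers
        if LOWER_NATURAL_BAND[0] <= s.orientation_deg <= LOWER_NATURAL_BAND[1]
    )
    return f_tn / n, f_nt / n
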