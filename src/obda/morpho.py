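"""Morphometrics: Sholl profiles, soma-size classification, AIS prevalence.

Sholl analysis is performed in two dimensions on the projection plane, with
a fixed first circle radius of 10 um and 5 um increments.  Soma-size class
boundaries follow the mean +/- 2 SD construction: the small-cell upper
bound comes from the confirmed AIS-positive soma-area distribution minus
two standard deviations, the big-cell lower bound from the confirmed
AIS-negative distribution plus two standard deviations, and both are
strict (boundary and in-between areas stay unclassified).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "NeuriteTree",
    "ShollProfile",
    "SizeCutoffs",
    "PrevalenceInputs",
    "SwcFormatError",
    "read_swc",
    "write_swc",
    "sholl_profile",
    "derive_size_cutoffs",
    "assign_size_class",
    "prevalence_estimate",
]

FIRST_RADIUS_UM = 10.0
RADIUS_STEP_UM = 5.0
_ON_CIRCLE_TOL = 1e-9


class SwcFormatError(ValueError):
    """Malformed SWC input (orphan nodes, cycles, bad columns)."""


@dataclass
class NeuriteTree:
    """A 2-D projected neurite reconstruction.

    ``branches`` are polylines of (x, y) nodes in um; each polyline starts
    at its attachment point (the soma centre or a node of a parent branch).
    """

    soma_xy: np.ndarray
    branches: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.soma_xy = np.asarray(self.soma_xy, dtype=float).reshape(2)
        self.branches = [np.asarray(b, dtype=float).reshape(-1, 2)
                         for b in self.branches]
        coords = [self.soma_xy] + [b.ravel() for b in self.branches]
        if not all(np.all(np.isfinite(c)) for c in coords):
            raise ValueError("non-finite coordinates in tree")

    def segments(self) -> Iterable[tuple[np.ndarray, np.ndarray]]:
        for b in self.branches:
            for i in range(len(b) - 1):
                yield b[i], b[i + 1]

    def max_radius(self) -> float:
        r = 0.0
        for b in self.branches:
            if len(b):
                r = max(r, float(np.max(np.linalg.norm(b - self.soma_xy, axis=1))))
        return r


@dataclass
class ShollProfile:
    radii_um: np.ndarray
    counts: np.ndarray
    auc_um: float
    furthest_intersection_um: float
    max_intersections: int
    radius_at_max_um: float


@dataclass(frozen=True)
class SizeCutoffs:
    small_max_um2: float = 70.0
    big_min_um2: float = 99.0

    def __post_init__(self) -> None:
        if not self.small_max_um2 < self.big_min_um2:
            raise ValueError("small cutoff must be below big cutoff")


@dataclass(frozen=True)
class PrevalenceInputs:
    n_ais_positive: int
    n_th_estimated: float | None = None
    th_density_per_mm3: float | None = None
    gl_volume_mm3: float | None = None

    def denominator(self) -> float:
        if self.n_th_estimated is not None:
            return float(self.n_th_estimated)
        if self.th_density_per_mm3 is None or self.gl_volume_mm3 is None:
            raise ValueError("need n_th_estimated or density x volume")
        if self.gl_volume_mm3 <= 0:
            raise ValueError("volume must be positive")
        return self.th_density_per_mm3 * self.gl_volume_mm3


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path: str | Path) -> NeuriteTree:
    """Read a standard 7-column SWC file as a 2-D projected tree.

    Only x and y are used (z is discarded).  The soma is the root node
    (parent -1).  Orphan parents and cycles raise :class:`SwcFormatError`
    with the offending line number.
    """
    nodes: dict[int, tuple[float, float, int]] = {}
    lines: dict[int, int] = {}
    root_id = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 7:
                raise SwcFormatError(f"line {lineno}: expected 7 columns")
            try:
                nid, ntype = int(parts[0]), int(parts[1])
                x, y = float(parts[2]), float(parts[3])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcFormatError(f"line {lineno}: {exc}") from exc
            if nid in nodes:
                raise SwcFormatError(f"line {lineno}: duplicate node id {nid}")
            nodes[nid] = (x, y, parent)
            lines[nid] = lineno
            if parent == -1 and root_id is None:
                root_id = nid
    if root_id is None:
        raise SwcFormatError("no root node (parent -1) found")

    for nid, (_, _, parent) in nodes.items():
        if parent != -1 and parent not in nodes:
            raise SwcFormatError(
                f"line {lines[nid]}: node {nid} references missing parent {parent}")
    # cycle check by walking to the root from every node
    for nid in nodes:
        seen = set()
        cur = nid
        while cur != -1:
            if cur in seen:
                raise SwcFormatError(f"line {lines[nid]}: cycle involving node {cur}")
            seen.add(cur)
            cur = nodes[cur][2]

    soma_xy = np.array(nodes[root_id][:2])
    children: dict[int, list[int]] = {nid: [] for nid in nodes}
    for nid, (_, _, parent) in nodes.items():
        if parent != -1:
            children[parent].append(nid)

    # split the tree into polylines at the root and at branch points
    branches: list[np.ndarray] = []

    def _walk(start: int) -> None:
        for child in children[start]:
            pts = [nodes[start][:2]]
            cur = child
            while True:
                pts.append(nodes[cur][:2])
                kids = children[cur]
                if len(kids) == 1:
                    cur = kids[0]
                else:
                    break
            branches.append(np.asarray(pts, dtype=float))
            _walk(cur)

    _walk(root_id)
    return NeuriteTree(soma_xy=soma_xy, branches=branches)


def write_swc(tree: NeuriteTree, path: str | Path) -> None:
    """Write a tree as standard 7-column SWC (z = 0, radius = 0.5)."""
    rows = []
    coord_ids: dict[tuple[float, float], int] = {}

    def _get_id(xy: np.ndarray, ntype: int, parent: int) -> int:
        key = (round(float(xy[0]), 9), round(float(xy[1]), 9))
        if key in coord_ids:
            return coord_ids[key]
        nid = len(rows) + 1
        rows.append((nid, ntype, float(xy[0]), float(xy[1]), 0.0, 0.5, parent))
        coord_ids[key] = nid
        return nid

    _get_id(tree.soma_xy, 1, -1)
    for b in tree.branches:
        parent = _get_id(b[0], 3, -1)  # attachment must already exist
        for pt in b[1:]:
            parent = _get_id(pt, 3, parent)
    with open(path, "w") as fh:
        fh.write("# generated by obda\n")
        for r in rows:
            fh.write(f"{r[0]} {r[1]} {r[2]:.6f} {r[3]:.6f} {r[4]:.1f} {r[5]:.2f} {r[6]}\n")


# ---------------------------------------------------------------------------
# Sholl analysis


def _segment_circle_crossings(p1: np.ndarray, p2: np.ndarray,
                              centre: np.ndarray, radius: float) -> int:
    """Number of crossings of segment p1->p2 with the circle |p - c| = R.

    Intersection parameters come from the exact quadratic; roots are counted
    in the half-open interval (0, 1] so a polyline vertex lying exactly on
    the circle is counted once (by the incoming segment only).  A tangential
    touch (double root) counts once.
    """
    d = p2 - p1
    f = p1 - centre
    a = float(d @ d)
    if a == 0.0:
        return 0
    b = 2.0 * float(f @ d)
    c = float(f @ f) - radius * radius
    disc = b * b - 4 * a * c
    scale = max(radius * radius, 1.0)
    if disc < -_ON_CIRCLE_TOL * scale:
        return 0
    tol = math.sqrt(max(disc, 0.0))
    roots: list[float]
    if disc <= _ON_CIRCLE_TOL * scale:
        roots = [-b / (2 * a)]          # tangential: one touch
    else:
        roots = [(-b - tol) / (2 * a), (-b + tol) / (2 * a)]
    t_eps = 1e-12
    return sum(1 for t in roots if t_eps < t <= 1.0 + t_eps)


def sholl_profile(tree: NeuriteTree,
                  first_radius_um: float = FIRST_RADIUS_UM,
                  step_um: float = RADIUS_STEP_UM) -> ShollProfile:
    """Count neurite crossings on concentric circles around the soma.

    Circles are placed at ``first_radius_um + k*step_um`` for every radius
    not exceeding the furthest node from the soma centre.  The area under
    the count-versus-radius curve uses the trapezoid rule over all computed
    radii.  Trees entirely inside the first circle give an empty profile
    with zero summaries.
    """
    max_r = tree.max_radius()
    radii = []
    r = first_radius_um
    while r <= max_r + _ON_CIRCLE_TOL:
        radii.append(r)
        r += step_um
    radii_arr = np.asarray(radii)
    if len(radii_arr) == 0:
        return ShollProfile(radii_um=radii_arr, counts=np.empty(0, dtype=int),
                            auc_um=0.0, furthest_intersection_um=0.0,
                            max_intersections=0, radius_at_max_um=0.0)

    counts = np.zeros(len(radii_arr), dtype=int)
    for p1, p2 in tree.segments():
        for i, radius in enumerate(radii_arr):
            counts[i] += _segment_circle_crossings(p1, p2, tree.soma_xy, radius)

    nonzero = np.flatnonzero(counts)
    furthest = float(radii_arr[nonzero[-1]]) if len(nonzero) else 0.0
    max_int = int(np.max(counts)) if len(counts) else 0
    radius_at_max = float(radii_arr[int(np.argmax(counts))]) if max_int else 0.0
    auc = float(np.trapezoid(counts, radii_arr)) if len(radii_arr) > 1 else 0.0
    return ShollProfile(radii_um=radii_arr, counts=counts, auc_um=auc,
                        furthest_intersection_um=furthest,
                        max_intersections=max_int,
                        radius_at_max_um=radius_at_max)


# ---------------------------------------------------------------------------
# soma-size classes and prevalence


def derive_size_cutoffs(mean_um2: float, sd_um2: float,
                        direction: Literal["minus", "plus"]) -> int:
    """Mean -/+ two standard deviations, rounded to the nearest integer.

    ``minus`` gives an upper bound for small cells from the AIS-positive
    distribution; ``plus`` gives a lower bound for big cells from the
    AIS-negative distribution.
    """
    if sd_um2 < 0:
        raise ValueError("sd must be nonnegative")
    if direction == "minus":
        value = mean_um2 - 2.0 * sd_um2
    elif direction == "plus":
        value = mean_um2 + 2.0 * sd_um2
    else:
        raise ValueError("direction must be 'minus' or 'plus'")
    return int(math.floor(value + 0.5))


def assign_size_class(area_um2: float,
                      cutoffs: SizeCutoffs = SizeCutoffs(),
                      ) -> Literal["small", "big", "unclassified"]:
    """Strict small/big assignment; boundary and in-between areas stay out."""
    if not area_um2 > 0:
        raise ValueError("soma area must be positive")
    if area_um2 < cutoffs.small_max_um2:
        return "small"
    if area_um2 > cutoffs.big_min_um2:
        return "big"
    return "unclassified"


def prevalence_estimate(inputs: PrevalenceInputs) -> float:
    """Lower-bound AIS-positive prevalence as a percentage (one decimal).

    The denominator is either given directly or estimated as TH-positive
    density times glomerular-layer volume.
    """
    if inputs.n_ais_positive < 0:
        raise ValueError("counts must be nonnegative")
    denom = inputs.denominator()
    if denom <= 0:
        raise ValueError("zero or negative denominator")
    return round(100.0 * inputs.n_ais_positive / denom, 1)
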