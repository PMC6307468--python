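"""Parametric model of a cable bacterium filament envelope.

A filament is modeled as a chain of cells whose envelope is the parallel
concatenation of ``N_R`` standard ridge compartments running the full length
of the filament.  Transverse sections come in two kinds:

* **mid-cell** — the envelope is a circle of perimeter ``N_R * delta_R``
  carrying ``N_R`` half-circular ridge compartments on its outside, each
  with a periplasmic fiber (diameter ``d_fiber``) in its core;
* **junction** — a "cartwheel": each ridge compartment appears as a circular
  bulb (diameter ``delta_B``, faintly stained core ``delta_C``) sitting on a
  stalk (width ``delta_S``); the stalks/spokes merge pairwise while radiating
  inward until they terminate at a central node.

Fibers are continuous along the filament: fiber ``k`` occupies ridge
compartment ``k`` in every section, which is what makes the fiber network a
candidate conductor for the long-distance electron transport these bacteria
perform.

Coordinates: filament axis = z; section plane = (x, y), origin at the
section centroid; all lengths in nanometers.  No pixel discretization
happens at this layer (see :mod:`cablemorph.synthetic` for rasterization).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import List, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from cablemorph import geometry as geom

__all__ = [
    "FilamentGeometryParams",
    "CrossSectionGeometry",
    "FilamentModel",
    "AreaConservationReport",
    "build_filament",
    "bulb_center_radius",
    "cross_section",
    "area_conservation_report",
]

#: Default parameters follow the thin-filament reference specimen used for
#: the published 3D reconstruction: 15 ridges of 231 nm, bulbs of 103 nm on
#: 68 nm stalks, 50 nm periplasmic fibers, ~2.2 um cells.
_SF1_DEFAULTS = dict(
    N_R=15,
    delta_R=231.0,
    d_fiber=50.0,
    delta_B=103.0,
    delta_C=50.0,
    delta_S=68.0,
    cell_length=2220.0,
)


@dataclass(frozen=True)
class FilamentGeometryParams:
    """Ground-truth envelope parameterization (all lengths nm, areas nm^2).

    Parameters
    ----------
    N_R : int
        Number of ridge compartments (>= 3).
    delta_R : float
        Ridge width: envelope perimeter per compartment, so the mid-cell
        perimeter is ``P = N_R * delta_R``.
    d_fiber : float
        Periplasmic fiber diameter.
    delta_B, delta_C : float
        Junction bulb diameter and bulb core diameter (``delta_C < delta_B``).
    delta_S : float
        Stalk/spoke width at junctions.
    cell_length : float
        Longitudinal cell length (junction-to-junction spacing).
    n_cells : int
        Number of cells in the modeled stretch of filament.
    valley_gap : float
        Gap between adjacent ridge compartments (the inter-ridge valley);
        the compartment half-circle has chord ``delta_R - valley_gap``.
    lining_width : float
        Thickness of the darkly stained compartment lining (rendered, not
        measured; the published sections show but do not quantify it).
    junction_half_width : float
        Axial half-extent of the junction (cartwheel) zone; defaults to
        ``delta_B`` when None.
    ridge_area : float, optional
        Measured mid-cell compartment cross-sectional area.  When absent
        the geometric half-disc area ``pi * (chord/2)^2 / 2`` is used by
        :func:`area_conservation_report`.
    """

    N_R: int = _SF1_DEFAULTS["N_R"]
    delta_R: float = _SF1_DEFAULTS["delta_R"]
    d_fiber: float = _SF1_DEFAULTS["d_fiber"]
    delta_B: float = _SF1_DEFAULTS["delta_B"]
    delta_C: float = _SF1_DEFAULTS["delta_C"]
    delta_S: float = _SF1_DEFAULTS["delta_S"]
    cell_length: float = _SF1_DEFAULTS["cell_length"]
    n_cells: int = 1
    valley_gap: float = 20.0
    lining_width: float = 10.0
    junction_half_width: Optional[float] = None
    ridge_area: Optional[float] = None

    def __post_init__(self) -> None:
        if self.N_R < 3:
            raise ValueError(f"N_R must be >= 3, got {self.N_R}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        for name in ("delta_R", "d_fiber", "delta_B", "delta_C", "delta_S",
                     "cell_length"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.delta_C >= self.delta_B:
            raise ValueError(
                f"bulb core delta_C = {self.delta_C} must be smaller than "
                f"bulb delta_B = {self.delta_B}"
            )
        if self.d_fiber > self.delta_B:
            raise ValueError(
                f"fiber diameter {self.d_fiber} cannot exceed bulb diameter "
                f"{self.delta_B}"
            )
        if not 0.0 <= self.valley_gap < self.delta_R:
            raise ValueError(
                f"valley_gap must lie in [0, delta_R), got {self.valley_gap}"
            )

    # -- derived scalars ---------------------------------------------------

    @property
    def perimeter(self) -> float:
        """Mid-cell envelope perimeter ``P = N_R * delta_R`` (nm)."""
        return self.N_R * self.delta_R

    @property
    def d_ESD(self) -> float:
        """Equivalent spherical diameter ``P / pi`` (nm)."""
        return self.perimeter / math.pi

    @property
    def envelope_radius(self) -> float:
        """Radius of the mid-cell envelope circle (nm)."""
        return self.perimeter / (2.0 * math.pi)

    @property
    def ridge_chord(self) -> float:
        """Chord (diameter) of one half-circular ridge compartment (nm)."""
        return self.delta_R - self.valley_gap

    @property
    def junction_halfwidth(self) -> float:
        return self.delta_B if self.junction_half_width is None else self.junction_half_width

    @property
    def filament_length(self) -> float:
        return self.n_cells * self.cell_length

    def scaled(self, c: float) -> "FilamentGeometryParams":
        """All length parameters multiplied by ``c`` (areas scale as c^2)."""
        return FilamentGeometryParams(
            N_R=self.N_R,
            delta_R=self.delta_R * c,
            d_fiber=self.d_fiber * c,
            delta_B=self.delta_B * c,
            delta_C=self.delta_C * c,
            delta_S=self.delta_S * c,
            cell_length=self.cell_length * c,
            n_cells=self.n_cells,
            valley_gap=self.valley_gap * c,
            lining_width=self.lining_width * c,
            junction_half_width=(None if self.junction_half_width is None
                                 else self.junction_half_width * c),
            ridge_area=(None if self.ridge_area is None
                        else self.ridge_area * c * c),
        )


@dataclass
class CrossSectionGeometry:
    """Polygonal transverse section, nm coordinates, origin at the centroid.

    ``ridge_regions`` holds one closed polyline per ridge compartment:
    half-discs at mid-cell, circular bulbs at a junction.  ``spokes`` holds
    the center lines of the cartwheel spoke tree (junction only); every bulb
    connects via exactly one spoke path to the central node at the origin.
    """

    kind: Literal["mid_cell", "junction"]
    envelope_outline: np.ndarray
    ridge_regions: List[np.ndarray]
    fiber_centers: np.ndarray
    spokes: List[np.ndarray] = field(default_factory=list)
    params: Optional[FilamentGeometryParams] = None
    z: float = 0.0

    def to_json(self) -> str:
        """Serialize parameters and polyline coordinate arrays."""
        payload = {
            "kind": self.kind,
            "z_nm": self.z,
            "params": asdict(self.params) if self.params is not None else None,
            "envelope_outline": self.envelope_outline.tolist(),
            "ridge_regions": [r.tolist() for r in self.ridge_regions],
            "fiber_centers": self.fiber_centers.tolist(),
            "spokes": [s.tolist() for s in self.spokes],
        }
        return json.dumps(payload, sort_keys=True)

    def vertex_table(self) -> pd.DataFrame:
        """All vertices as a tidy table (element, index, vertex, x_nm, y_nm)."""
        rows = []
        def add(element: str, idx: int, arr: np.ndarray) -> None:
            for v, (x, y) in enumerate(np.asarray(arr, dtype=float)):
                rows.append((element, idx, v, x, y))
        add("envelope_outline", 0, self.envelope_outline)
        for i, r in enumerate(self.ridge_regions):
            add("ridge_region", i, r)
        add("fiber_center", 0, self.fiber_centers)
        for i, s in enumerate(self.spokes):
            add("spoke", i, s)
        return pd.DataFrame(rows, columns=["element", "index", "vertex",
                                           "x_nm", "y_nm"])


@dataclass(frozen=True)
class FilamentModel:
    """A built filament: parameters plus junction positions along the axis.

    Junctions sit at ``z = 0, L, 2L, ..., n_cells * L`` (both filament ends
    are junctions).  Fiber ``k`` occupies ridge compartment ``k`` in every
    section, making fibers indexable identically along the filament.
    """

    params: FilamentGeometryParams
    junction_positions: np.ndarray

    @property
    def length(self) -> float:
        return float(self.junction_positions[-1])

    @property
    def interior_junctions(self) -> np.ndarray:
        return self.junction_positions[1:-1]

    def to_json(self) -> str:
        return json.dumps(
            {"params": asdict(self.params),
             "junction_positions_nm": self.junction_positions.tolist()},
            sort_keys=True,
        )


@dataclass
class AreaConservationReport:
    """Per-ridge junction-bulb to mid-cell compartment area ratios."""

    ratios: np.ndarray
    mean: float
    sd: float
    A_B: float
    A_R: float


def bulb_center_radius(params: FilamentGeometryParams) -> float:
    """Radius of the circle carrying the junction bulb centers.

    Bulbs are preferentially placed tangent to the envelope circle from the
    inside (center radius ``R - delta_B / 2``).  When the measured bulb
    diameter is too large for that ring (neighbors would overlap), the ring
    is widened to the mutually tangent radius ``delta_B / (2 sin(pi/N_R))``;
    if even that exceeds the envelope radius the arrangement is infeasible.
    """
    R = params.envelope_radius
    half_angle = math.pi / params.N_R
    tangent_inside = R - 0.5 * params.delta_B
    mutually_tangent = 0.5 * params.delta_B / math.sin(half_angle)
    r_b = max(tangent_inside, mutually_tangent)
    if tangent_inside <= 0 or r_b > R:
        raise ValueError(
            f"packing violation: N_R = {params.N_R} bulbs of diameter "
            f"{params.delta_B} nm do not fit on the junction circumference "
            f"(envelope radius {R:.1f} nm, required bulb-center radius "
            f"{r_b:.1f} nm)"
        )
    return r_b


def _check_packing(params: FilamentGeometryParams) -> None:
    """Geometric feasibility of placing N_R bulbs and ridges on the envelope."""
    R = params.envelope_radius
    half_angle = math.pi / params.N_R
    bulb_center_radius(params)  # raises when bulbs cannot be arranged
    ridge_spacing = 2.0 * R * math.sin(half_angle)
    if ridge_spacing < params.ridge_chord:
        raise ValueError(
            "packing violation: ridge compartments of chord "
            f"{params.ridge_chord:.1f} nm overlap (center spacing "
            f"{ridge_spacing:.1f} nm)"
        )
    if params.d_fiber > params.ridge_chord / 2.0:
        raise ValueError(
            f"packing violation: fiber diameter {params.d_fiber} nm does not "
            f"fit inside a ridge compartment of chord {params.ridge_chord:.1f} nm"
        )


def build_filament(params: FilamentGeometryParams) -> FilamentModel:
    """Assemble a filament model, validating geometric feasibility.

    Raises ``ValueError`` naming the violated packing constraint when the
    requested dimensions are infeasible (e.g. bulbs wider than their angular
    allotment on the junction circumference).
    """
    _check_packing(params)
    junctions = np.arange(params.n_cells + 1, dtype=float) * params.cell_length
    return FilamentModel(params=params, junction_positions=junctions)


def _ridge_angles(N_R: int, phase: float = 0.0) -> np.ndarray:
    return phase + 2.0 * math.pi * np.arange(N_R) / N_R


def _circle(center: np.ndarray, radius: float, n: int) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    pts = center + radius * np.c_[np.cos(t), np.sin(t)]
    return np.vstack([pts, pts[:1]])  # closed


def _half_disc(center: np.ndarray, chord: float, radial: np.ndarray,
               n: int) -> np.ndarray:
    """Closed half-disc polygon: flat side through ``center`` along the
    tangent, arc of radius ``chord/2`` bulging in the ``radial`` direction."""
    tangent = np.array([-radial[1], radial[0]])
    phi = np.linspace(0.0, math.pi, n)
    pts = (center
           + 0.5 * chord * np.outer(np.cos(phi), tangent)
           + 0.5 * chord * np.outer(np.sin(phi), radial))
    return np.vstack([pts, pts[:1]])


def _spoke_tree(leaf_points: np.ndarray) -> List[np.ndarray]:
    """Binary-merge spoke tree from bulb centers to the central node.

    Adjacent branches merge pairwise (balanced binary merging) while
    radiating inward; an odd branch at any level is carried to the next.
    The surviving root is joined to the section center, so every leaf has
    exactly one path to the central node and the edge set is a tree.
    """
    spokes: List[np.ndarray] = []
    nodes = [np.asarray(p, dtype=float) for p in leaf_points]
    while len(nodes) > 1:
        nxt: List[np.ndarray] = []
        for i in range(0, len(nodes) - 1, 2):
            parent = 0.5 * (nodes[i] + nodes[i + 1]) * 0.7
            spokes.append(np.vstack([nodes[i], parent]))
            spokes.append(np.vstack([nodes[i + 1], parent]))
            nxt.append(parent)
        if len(nodes) % 2 == 1:
            nxt.append(nodes[-1])
        nodes = nxt
    root = nodes[0]
    if np.hypot(*root) > 1e-9:
        spokes.append(np.vstack([root, np.zeros(2)]))
    return spokes


def cross_section(model: FilamentModel, z: float,
                  vertices_per_region: int = 64,
                  phase: float = 0.0) -> CrossSectionGeometry:
    """Transverse section geometry at longitudinal coordinate ``z`` (nm).

    The section is a junction (cartwheel) when ``z`` lies within the
    junction half-width of a junction position, otherwise mid-cell.

    ``vertices_per_region`` controls polyline density; the envelope outline
    gets ``N_R * vertices_per_region`` vertices so its polygonal perimeter
    converges to ``N_R * delta_R`` as density increases.
    """
    p = model.params
    if not 0.0 <= z <= model.length:
        raise ValueError(
            f"z = {z} nm outside the filament extent [0, {model.length}] nm"
        )
    dist = np.min(np.abs(model.junction_positions - z))
    kind: Literal["mid_cell", "junction"] = (
        "junction" if dist <= p.junction_halfwidth else "mid_cell"
    )

    R = p.envelope_radius
    angles = _ridge_angles(p.N_R, phase)
    radial = np.c_[np.cos(angles), np.sin(angles)]
    n_env = max(p.N_R * vertices_per_region, 64)
    outline = _circle(np.zeros(2), R, n_env)

    if kind == "mid_cell":
        centers = R * radial
        regions = [_half_disc(centers[k], p.ridge_chord, radial[k],
                              vertices_per_region) for k in range(p.N_R)]
        fibers = (R + 0.25 * p.ridge_chord) * radial
        spokes: List[np.ndarray] = []
    else:
        bulb_r = bulb_center_radius(p)
        centers = bulb_r * radial
        regions = [_circle(centers[k], 0.5 * p.delta_B, vertices_per_region)
                   for k in range(p.N_R)]
        fibers = centers.copy()
        spokes = _spoke_tree(centers)

    return CrossSectionGeometry(
        kind=kind,
        envelope_outline=outline,
        ridge_regions=regions,
        fiber_centers=fibers,
        spokes=spokes,
        params=p,
        z=float(z),
    )


def area_conservation_report(model: FilamentModel) -> AreaConservationReport:
    """Junction-bulb area over mid-cell compartment area, per ridge.

    A ratio near 1 expresses that each compartment changes shape at the
    junction (half-circular to circular bulb) while conserving its amount
    of periplasmic material.  Uses the measured ``ridge_area`` when the
    parameterization carries one, otherwise the geometric half-disc area.
    """
    p = model.params
    A_B = geom.bulb_area(p.delta_B)
    A_R = (p.ridge_area if p.ridge_area is not None
           else 0.5 * math.pi * (0.5 * p.ridge_chord) ** 2)
    ratios = np.full(p.N_R, A_B / A_R)
    sd = float(np.std(ratios, ddof=1)) if p.N_R > 1 else float("nan")
    return AreaConservationReport(
        ratios=ratios, mean=float(ratios.mean()), sd=sd, A_B=A_B, A_R=A_R
    )
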