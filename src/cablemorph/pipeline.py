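"""Measurement pipeline for height maps and transverse-section images.

Applies the published measurement procedures to AFM-like topography rasters
and FIB-SEM-like section images:

* transverse profiles give the filament width ``W`` (outermost
  substrate-to-filament crossings at a height threshold), apex height ``H``,
  and inter-ridge valleys (prominence-filtered local minima);
* junctions are longitudinal positions that are simultaneously local maxima
  of the smoothed height profile and local minima of the width profile;
  cell length ``L`` is the junction spacing;
* the per-cell perimeter follows from the half-ellipse model
  ``P = half_ellipse_perimeter(W, H)`` with flattening ``2H/W`` and
  ``d_ESD = P / pi``;
* section images yield the ridge count, the traced envelope perimeter
  (with circular-arc extrapolation when the outline is truncated at the
  image border), compartment areas, and bulb/core/stalk calipers.

The pipeline reads only rasters and pixel sizes — never the generator's
attached ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.signal import find_peaks
from skimage import measure as skmeasure
from skimage.morphology import medial_axis

from cablemorph import geometry as geom
from cablemorph.synthetic import LABELS, HeightMap, SectionImage

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ProfileMeasurement",
    "MeasurementRecord",
    "SummaryTable",
    "EmptyProfileError",
    "InsufficientRidgesError",
    "SegmentationError",
    "extract_profile",
    "afm_ridge_width",
    "segment_cells",
    "afm_filament_morphometrics",
    "section_ridge_count",
    "section_perimeter",
    "section_compartment_metrics",
    "summarize",
    "compare_groups",
]


class EmptyProfileError(ValueError):
    """No filament found at the requested position (all below threshold)."""


class InsufficientRidgesError(ValueError):
    """Fewer than two inter-ridge valleys in the profile."""


class SegmentationError(ValueError):
    """The section image could not be segmented into compartments."""


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable measurement thresholds (all lengths nm).

    ``height_threshold_mult`` — the filament/substrate threshold is this
    many noise standard deviations above the fitted substrate plane (with
    ``min_threshold_nm`` as a floor for noise-free data).
    ``valley_prominence_nm`` — minimum prominence for an inter-ridge valley
    (one third of the ~30 nm valley depth).
    ``smooth_window_nm`` — moving-average window applied to the axial
    height/width profiles before junction detection.
    ``min_junction_spacing_nm`` — minimum admissible junction spacing.
    """

    height_threshold_mult: float = 3.0
    min_threshold_nm: float = 1.0
    valley_prominence_nm: float = 10.0
    smooth_window_nm: float = 250.0
    junction_prominence_nm: float = 20.0
    min_junction_spacing_nm: float = 1000.0
    min_run_px: int = 3


@dataclass
class ProfileMeasurement:
    """One transverse profile: position, width, height, valley positions (nm)."""

    z: float
    W: float
    H: float
    valley_positions: np.ndarray
    kind: Literal["mid_cell", "junction"] = "mid_cell"

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError("profile width must be positive")
        if self.H < 0:
            raise ValueError("profile height must be non-negative")
        v = np.asarray(self.valley_positions, dtype=float)
        if v.size > 1 and not np.all(np.diff(v) > 0):
            raise ValueError("valley positions must be strictly increasing")
        self.valley_positions = v


@dataclass
class MeasurementRecord:
    """One filament's measurements with derivation provenance.

    ``cells`` holds one row per cell (W1/H1 mid-cell, W2/H2 junction, per-cell
    P, d_ESD, AFM valley-to-valley ridge width, cell length).  ``derived``
    stores filament-level values that are mutually consistent by
    construction: ``d_ESD = P / pi`` exactly and ``delta_R = P / N_R`` when
    both are present.
    """

    filament_id: str
    modality: Literal["afm", "fibsem"]
    cells: pd.DataFrame
    derived: geom.DerivedMorphometrics
    cell_length: Optional[float] = None
    group: Optional[str] = None
    provenance: Dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.cells.copy()
        df.insert(0, "filament_id", self.filament_id)
        df.insert(1, "modality", self.modality)
        if self.group is not None:
            df.insert(2, "group", self.group)
        return df


@dataclass
class SummaryTable:
    """Per-group mean, sample SD (n-1 denominator) and N for each parameter."""

    table: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string()


# ---------------------------------------------------------------------------
# height-map primitives
# ---------------------------------------------------------------------------

def _fit_substrate_plane(values: np.ndarray, border: int = 3
                         ) -> Tuple[np.ndarray, float]:
    """Least-squares plane over the border pixels; returns (plane, noise SD).

    The substrate noise SD is estimated from the border residuals; when the
    border shows clipping at the substrate plane (heights stored >= 0), the
    half-normal correction recovers the underlying Gaussian SD.
    """
    n_rows, n_cols = values.shape
    mask = np.zeros(values.shape, dtype=bool)
    mask[:border, :] = mask[-border:, :] = True
    mask[:, :border] = mask[:, -border:] = True
    rr, cc = np.nonzero(mask)
    A = np.c_[rr, cc, np.ones(rr.size)]
    coef, *_ = np.linalg.lstsq(A, values[mask], rcond=None)
    RR, CC = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    plane = coef[0] * RR + coef[1] * CC + coef[2]
    resid = values[mask] - plane[mask]
    sd = float(np.std(resid))
    if np.mean(values[mask] <= 1e-9) > 0.05:
        # clipped at 0: SD of max(N(0, s), 0) is 0.5838 s
        sd = float(np.std(values[mask])) / 0.5838
    return plane, sd


def _threshold(noise_sd: float, config: PipelineConfig) -> float:
    return max(config.height_threshold_mult * noise_sd,
               config.min_threshold_nm)


def _longest_run(above: np.ndarray, min_run: int) -> Optional[Tuple[int, int]]:
    """Start/stop (inclusive) of the longest True run of length >= min_run."""
    idx = np.flatnonzero(np.diff(np.r_[0, above.astype(np.int8), 0]))
    if idx.size == 0:
        return None
    starts, stops = idx[::2], idx[1::2] - 1
    lengths = stops - starts + 1
    k = int(np.argmax(lengths))
    if lengths[k] < min_run:
        return None
    return int(starts[k]), int(stops[k])


def align_heightmap(hm: HeightMap, config: PipelineConfig = PipelineConfig()
                    ) -> HeightMap:
    """Rotate the raster so the filament axis runs along the columns.

    The axis orientation is estimated from the second moments of the
    above-threshold mask; rotations below 0.5 degrees are skipped (the
    raster is returned unchanged).  Interpolation is bilinear.
    """
    values = hm.values.astype(float)
    plane, noise_sd = _fit_substrate_plane(values)
    mask = (values - plane) > _threshold(noise_sd, config)
    if not mask.any():
        return hm
    rr, cc = np.nonzero(mask)
    x = cc - cc.mean()
    y = rr - rr.mean()
    mu20, mu02, mu11 = (x * x).mean(), (y * y).mean(), (x * y).mean()
    angle = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)  # axis vs column dir
    if abs(math.degrees(angle)) < 0.5:
        return hm
    rotated = ndimage.rotate(values, math.degrees(angle), reshape=True,
                             order=1, cval=0.0)
    rotated = np.clip(rotated, 0.0, None)
    prov = dict(hm.provenance)
    prov["aligned_rotation_deg"] = math.degrees(angle)
    return HeightMap(values=rotated.astype(np.float32),
                     pixel_size=hm.pixel_size, provenance=prov)


def extract_profile(hm: HeightMap, z: float,
                    config: PipelineConfig = PipelineConfig()
                    ) -> ProfileMeasurement:
    """Measure one transverse profile at longitudinal position ``z`` (nm).

    ``W`` is the distance between the two outermost substrate-to-filament
    crossings at the height threshold (longest contiguous run above it),
    ``H`` the profile maximum, and valleys the prominence-filtered local
    minima between ridge peaks inside the filament extent.

    Raises :class:`EmptyProfileError` when no filament is present at ``z``.
    """
    px = hm.pixel_size
    col = int(round(z / px - 0.5))
    if not 0 <= col < hm.values.shape[1]:
        raise ValueError(f"z = {z} nm outside the map extent")
    values = hm.values.astype(float)
    plane, noise_sd = _fit_substrate_plane(values)
    profile = values[:, col] - plane[:, col]
    smooth = ndimage.uniform_filter1d(profile, size=3)
    thr = _threshold(noise_sd, config)
    run = _longest_run(smooth > thr, config.min_run_px)
    if run is None:
        raise EmptyProfileError(f"no filament found at z = {z} nm")
    i0, i1 = run
    W = (i1 - i0) * px
    segment = smooth[i0:i1 + 1]
    H = float(segment.max())
    valleys, _ = find_peaks(-segment, prominence=config.valley_prominence_nm)
    # parabolic sub-pixel refinement of each valley position
    refined = []
    for v in valleys:
        if 0 < v < segment.size - 1:
            a, b, c = segment[v - 1], segment[v], segment[v + 1]
            denom = a - 2 * b + c
            shift = 0.5 * (a - c) / denom if abs(denom) > 1e-12 else 0.0
            refined.append(v + float(np.clip(shift, -0.5, 0.5)))
        else:
            refined.append(float(v))
    valley_nm = (np.asarray(refined) + i0 + 0.5) * px
    return ProfileMeasurement(z=float(z), W=float(W), H=H,
                              valley_positions=np.sort(valley_nm))


def afm_ridge_width(profile: ProfileMeasurement
                    ) -> Tuple[np.ndarray, float]:
    """Per-ridge valley-to-valley widths and their mean (nm).

    The ridge compartment width is the distance between the two valleys
    surrounding an individual ridge.  The mean is robust against missed
    valleys (shallow valleys near the filament edge can fall below the
    prominence threshold): each spacing is interpreted as an integer
    multiple of the base spacing and the mean is the total span divided by
    the total multiple count.  All raw spacings are returned unmodified.
    Raises :class:`InsufficientRidgesError` with fewer than two valleys.
    """
    if profile.valley_positions.size < 2:
        raise InsufficientRidgesError(
            f"profile at z = {profile.z} nm has "
            f"{profile.valley_positions.size} valleys; need >= 2"
        )
    widths = np.diff(profile.valley_positions)
    s = float(np.percentile(widths, 10))  # near-minimal spacing as seed
    for _ in range(2):
        k = np.maximum(1, np.round(widths / s))
        s = float(widths.sum() / k.sum())
    return widths, s


@dataclass
class CellSegmentation:
    """Junction positions and per-cell extents along the filament axis (nm)."""

    junction_z: np.ndarray          # all detected junctions
    interior_junction_z: np.ndarray
    cell_spans: List[Tuple[float, float]]
    cell_length: Optional[float]
    fallback: bool = False


def _smooth_axial(x: np.ndarray, window_px: int) -> np.ndarray:
    return ndimage.uniform_filter1d(x, size=max(3, window_px))


def segment_cells(hm: HeightMap,
                  config: PipelineConfig = PipelineConfig()
                  ) -> CellSegmentation:
    """Locate cell junctions along the filament and derive cell extents.

    Junctions are longitudinal positions that are local maxima of the
    smoothed axial height profile and coincide (within the smoothing
    window) with local minima of the axial width profile; remaining
    candidates are ranked by the height criterion.  Cell length is the mean
    spacing of consecutive junctions.  When no junction is found the whole
    filament is treated as a single cell (fallback, with a warning).
    """
    px = hm.pixel_size
    values = hm.values.astype(float)
    plane, noise_sd = _fit_substrate_plane(values)
    corrected = values - plane
    thr = _threshold(noise_sd, config)
    mask = ndimage.uniform_filter1d(corrected, size=3, axis=0) > thr

    H_z = corrected.max(axis=0)
    W_z = mask.sum(axis=0).astype(float) * px
    occupied = np.flatnonzero(W_z > 0)
    if occupied.size == 0:
        raise EmptyProfileError("no filament found in the height map")
    window_px = int(round(config.smooth_window_nm / px))
    H_s = _smooth_axial(H_z, window_px)
    W_s = _smooth_axial(W_z, window_px)

    distance = max(3, int(round(config.min_junction_spacing_nm / px)))
    peaks, _ = find_peaks(H_s, prominence=config.junction_prominence_nm,
                          distance=distance)
    w_minima, _ = find_peaks(-W_s, prominence=0.0, distance=max(3, distance // 2))
    match_px = max(window_px, 3)
    # a junction must be a height maximum AND coincide with a width minimum
    confirmed = [pk for pk in peaks
                 if w_minima.size
                 and np.min(np.abs(w_minima - pk)) <= 2 * match_px]
    peaks = np.asarray(confirmed, dtype=int)

    z0 = (occupied[0] + 0.5) * px
    z1 = (occupied[-1] + 0.5) * px
    junction_z = (peaks + 0.5) * px

    if junction_z.size == 0:
        logger.warning("no junctions found; treating the filament as a "
                       "single cell")
        return CellSegmentation(
            junction_z=np.array([]), interior_junction_z=np.array([]),
            cell_spans=[(z0, z1)], cell_length=None, fallback=True)

    spacing = float(np.mean(np.diff(junction_z))) if junction_z.size > 1 else None
    edge_tol = 0.25 * spacing if spacing else config.smooth_window_nm
    interior = junction_z[(junction_z > z0 + edge_tol)
                          & (junction_z < z1 - edge_tol)]

    bounds = np.unique(np.r_[z0, junction_z, z1])
    spans = [(float(a), float(b)) for a, b in zip(bounds[:-1], bounds[1:])
             if (b - a) > (0.5 * spacing if spacing
                           else config.min_junction_spacing_nm)]
    return CellSegmentation(junction_z=junction_z,
                            interior_junction_z=interior,
                            cell_spans=spans, cell_length=spacing)


def afm_filament_morphometrics(hm: HeightMap, filament_id: str = "",
                               group: Optional[str] = None,
                               config: PipelineConfig = PipelineConfig(),
                               align: bool = True) -> MeasurementRecord:
    """Full AFM measurement chain for one filament.

    Per cell: mid-cell W1/H1 and junction W2/H2, the half-ellipse perimeter
    ``P`` (flattening ``2 H1 / W1``), ``d_ESD = P / pi``, and the
    valley-to-valley ridge width.  Filament-level derived values are the
    per-cell means, with ``d_ESD`` recomputed from the mean ``P`` so the
    stored record is exactly self-consistent.
    """
    if align:
        hm = align_heightmap(hm, config)
    seg = segment_cells(hm, config)
    rows = []
    for (a, b) in seg.cell_spans:
        z_mid = 0.5 * (a + b)
        try:
            prof = extract_profile(hm, z_mid, config)
        except EmptyProfileError:
            continue
        prof.kind = "mid_cell"
        spec = geom.HalfEllipseSpec(W=prof.W, H=min(prof.H, prof.W / 2.0))
        P = geom.half_ellipse_perimeter(spec)
        try:
            _, dr = afm_ridge_width(prof)
        except InsufficientRidgesError:
            dr = float("nan")
        rows.append({
            "z_mid_nm": z_mid, "W1_nm": prof.W, "H1_nm": prof.H,
            "epsilon": spec.epsilon, "P_nm": P,
            "d_ESD_nm": geom.equivalent_spherical_diameter(P),
            "delta_R_afm_nm": dr, "cell_length_nm": b - a,
        })
    if not rows:
        raise EmptyProfileError(f"no measurable cells in {filament_id!r}")
    cells = pd.DataFrame(rows)

    jr = []
    for zj in seg.junction_z:
        try:
            prof = extract_profile(hm, zj, config)
        except EmptyProfileError:
            continue
        prof.kind = "junction"
        jr.append({"z_nm": zj, "W2_nm": prof.W, "H2_nm": prof.H})
    junctions = pd.DataFrame(jr)
    if len(junctions):
        cells["W2_nm"] = junctions["W2_nm"].mean()
        cells["H2_nm"] = junctions["H2_nm"].mean()

    P_mean = float(cells["P_nm"].mean())
    derived = geom.DerivedMorphometrics(
        P=P_mean,
        d_ESD=P_mean / math.pi,
        delta_R=float(cells["delta_R_afm_nm"].mean())
        if cells["delta_R_afm_nm"].notna().any() else None,
    )
    return MeasurementRecord(
        filament_id=filament_id, modality="afm", cells=cells,
        derived=derived, cell_length=seg.cell_length, group=group,
        provenance={
            "n_junctions": int(seg.junction_z.size),
            "fallback_single_cell": seg.fallback,
            "derivations": {
                "P": "mean over cells of half_ellipse_perimeter(W1, H1)",
                "d_ESD": "P / pi",
                "delta_R": "mean valley-to-valley spacing (AFM definition)",
            },
        },
    )


# ---------------------------------------------------------------------------
# section-image measurements
# ---------------------------------------------------------------------------

def _section_kind(img: SectionImage) -> str:
    if (img.label_raster == LABELS["bulb"]).any():
        return "junction"
    return "mid_cell"


def _dark_mask(img: SectionImage) -> np.ndarray:
    """Fallback segmentation of dark (stained) structures from intensity.

    Three-class Otsu separates heavily stained material (lining, spokes,
    bulbs) from cytoplasm and from background/unstained cores; a plain
    two-class split would land on the cytoplasm/background boundary.
    """
    from skimage.filters import threshold_multiotsu
    thr = threshold_multiotsu(img.intensity_raster, classes=3)[0]
    return img.intensity_raster < thr


_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _count_blobs(mask: np.ndarray, max_erosions: int = 10) -> int:
    """Count blob regions, splitting touching neighbors by erosion.

    Bulbs packed shoulder-to-shoulder around a junction touch at tangency
    points and merge into one connected raster component.  The mask is
    eroded iteratively and the maximum component count over erosion levels
    is returned: erosion separates tangential contacts but never splits the
    convex compartment/bulb regions themselves.  Speck components below a
    fifth of the median area are ignored at each level.
    """
    best = 0
    cur = mask
    for _ in range(max_erosions + 1):
        lab, n = ndimage.label(cur, structure=_FOUR)
        if n == 0:
            break
        areas = ndimage.sum_labels(np.ones_like(lab), lab,
                                   np.arange(1, n + 1))
        keep = areas[areas > 0.2 * np.median(areas)]
        if np.median(keep) < 9:
            # blobs this small are about to fragment into specks; deeper
            # erosion levels are no longer trustworthy
            break
        best = max(best, int(keep.size))
        cur = ndimage.binary_erosion(cur, structure=_FOUR)
    return best


def section_ridge_count(img: SectionImage) -> int:
    """Count ridge compartments (mid-cell) or bulbs (junction) in a section.

    A compartment region is the stained lining together with its enclosed
    fiber core (the core may fill most of a small compartment); at a
    junction the bulbs (incl. cores) are counted.
    """
    labels = img.label_raster
    if labels is not None and labels.max() > 0:
        if _section_kind(img) == "junction":
            mask = (labels == LABELS["bulb"]) | (labels == LABELS["fiber_core"])
        else:
            mask = (labels == LABELS["lining"]) | (labels == LABELS["fiber_core"])
        n = _count_blobs(mask)
    else:
        # intensity fallback: stained compartment linings are dark; no
        # erosion splitting (thin lining shells would fragment)
        n = _count_blobs(_dark_mask(img), max_erosions=0)
    if n == 0:
        raise SegmentationError("no compartments found in section image")
    return n


def _contour_length(contour: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(contour, axis=0).T)))


def _smooth_contour(contour: np.ndarray, closed: bool, window: int = 9
                    ) -> np.ndarray:
    """Moving-average the marching-squares contour to remove the pixel
    staircase, which otherwise inflates the traced length by ~5 %."""
    if contour.shape[0] <= window:
        return contour
    mode = "wrap" if closed else "nearest"
    return ndimage.uniform_filter1d(contour, size=window, axis=0, mode=mode)


def _fit_circle(points: np.ndarray) -> Tuple[np.ndarray, float]:
    """Algebraic (Kasa) circle fit: returns (center, radius) in px coords."""
    x, y = points[:, 1], points[:, 0]
    A = np.c_[2 * x, 2 * y, np.ones(x.size)]
    b = x ** 2 + y ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0], sol[1]
    r = math.sqrt(sol[2] + cx ** 2 + cy ** 2)
    return np.array([cy, cx]), r


def section_perimeter(img: SectionImage) -> float:
    """Envelope perimeter of a section (nm), the traced cell circumference.

    The cell body (cytoplasm with internal structures filled) is contoured
    at sub-pixel resolution.  If the outline is truncated at the image
    border, the visible arc length ``L`` and its subtended angle ``theta``
    are measured and the perimeter extrapolated as ``P = L * 2 pi / theta``;
    with less than 10 % of the outline visible a warning is logged.
    """
    labels = img.label_raster
    if labels is not None and labels.max() > 0:
        if _section_kind(img) == "junction":
            # bulbs sit tangent inside the envelope: the cell body is the
            # filled union of all stained structures
            body = ndimage.binary_fill_holes(labels != LABELS["background"])
        else:
            # ridge compartments protrude beyond the envelope circle; the
            # traced circumference is the cell-body (cytoplasm) outline
            body = ndimage.binary_fill_holes(labels == LABELS["cytoplasm"])
    else:
        body = ndimage.binary_fill_holes(~_dark_mask(img))
    px = img.pixel_size
    contours = skmeasure.find_contours(body.astype(float), 0.5)
    if not contours:
        raise SegmentationError("no envelope outline found")
    contour = max(contours, key=_contour_length)

    n_rows, n_cols = body.shape
    on_border = ((contour[:, 0] < 1.0) | (contour[:, 0] > n_rows - 2)
                 | (contour[:, 1] < 1.0) | (contour[:, 1] > n_cols - 2))
    if not on_border.any():
        return _contour_length(_smooth_contour(contour, closed=True)) * px

    # truncated outline: keep the longest off-border stretch as the arc
    keep = ~on_border
    runs = np.flatnonzero(np.diff(np.r_[0, keep.astype(np.int8), 0]))
    best = None
    for s, e in zip(runs[::2], runs[1::2]):
        if best is None or (e - s) > (best[1] - best[0]):
            best = (s, e)
    arc = contour[best[0]:best[1]]
    if arc.shape[0] < 8:
        raise SegmentationError("visible outline too short to extrapolate")
    arc = _smooth_contour(arc, closed=False)
    L = _contour_length(arc) * px
    center, _ = _fit_circle(arc)
    ang = np.unwrap(np.arctan2(arc[:, 0] - center[0], arc[:, 1] - center[1]))
    theta = float(abs(ang[-1] - ang[0]))
    theta = min(theta, 2.0 * math.pi)
    if theta < 0.1 * 2.0 * math.pi:
        logger.warning("less than 10%% of the outline visible; perimeter "
                       "extrapolation is unreliable")
    return geom.perimeter_from_arc(
        geom.ArcObservation(L_arc=L, theta=theta))


@dataclass
class CompartmentMetrics:
    """Per-compartment geometry of one section (nm / nm^2; NaN = unresolved)."""

    kind: str
    A_R: Optional[np.ndarray] = None       # mid-cell compartment areas
    delta_B: Optional[np.ndarray] = None   # bulb diameters
    delta_C: Optional[np.ndarray] = None   # bulb core diameters
    delta_S: Optional[float] = None        # stalk/spoke width

    def means(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for name in ("A_R", "delta_B", "delta_C"):
            v = getattr(self, name)
            out[name] = float(np.nanmean(v)) if v is not None and len(v) else float("nan")
        out["delta_S"] = self.delta_S if self.delta_S is not None else float("nan")
        return out


def _component_equivalent_diameters(mask: np.ndarray, px: float) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.array([[0, 1, 0],
                                                     [1, 1, 1],
                                                     [0, 1, 0]]))
    if n == 0:
        return np.array([])
    areas = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
    return np.sqrt(4.0 * areas / math.pi) * px


def section_compartment_metrics(img: SectionImage) -> CompartmentMetrics:
    """Measure compartment areas and bulb/core/stalk calipers from a section.

    Mid-cell: per-compartment pixel area (compartment = lining plus enclosed
    fiber core).  Junction: bulb diameter from the equivalent-circle
    diameter of each bulb region (incl. core), core diameter likewise, and
    the stalk width as twice the median medial-axis half-width of the spoke
    mask.  Unresolvable components yield NaN values, not failure.
    """
    labels = img.label_raster
    px = img.pixel_size
    if labels is None or labels.max() == 0:
        raise SegmentationError("section has no label raster; intensity-only "
                                "compartment metrics are not supported")
    kind = _section_kind(img)
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if kind == "mid_cell":
        mask = (labels == LABELS["lining"]) | (labels == LABELS["fiber_core"])
        lab, n = ndimage.label(mask, structure=four)
        if n == 0:
            return CompartmentMetrics(kind=kind, A_R=np.array([]))
        areas = ndimage.sum_labels(np.ones_like(lab), lab,
                                   np.arange(1, n + 1)) * px ** 2
        return CompartmentMetrics(kind=kind, A_R=np.asarray(areas))

    # a bulb region is the bulb plus its (lighter) core, painted on top
    bulb_full = (labels == LABELS["bulb"]) | (labels == LABELS["fiber_core"])
    _, n_merged = ndimage.label(bulb_full, structure=_FOUR)
    n_bulbs = _count_blobs(bulb_full)
    if n_bulbs and n_merged < n_bulbs:
        # bulbs packed shoulder-to-shoulder touch and merge; the equivalent
        # diameter then comes from the mean per-bulb area
        area = float(bulb_full.sum()) / n_bulbs
        delta_B = np.full(n_bulbs, math.sqrt(4.0 * area / math.pi) * px)
    else:
        delta_B = _component_equivalent_diameters(bulb_full, px)
    delta_C = _component_equivalent_diameters(labels == LABELS["fiber_core"], px)
    spoke_mask = labels == LABELS["spoke"]
    delta_S = None
    if spoke_mask.any():
        skel, dist = medial_axis(spoke_mask, return_distance=True)
        widths = dist[skel]
        if widths.size:
            delta_S = float(2.0 * np.median(widths) * px)
    return CompartmentMetrics(kind=kind, delta_B=delta_B, delta_C=delta_C,
                              delta_S=delta_S)


# ---------------------------------------------------------------------------
# aggregation & statistics
# ---------------------------------------------------------------------------

_SUMMARY_FIELDS = ("P", "d_ESD", "delta_R", "A_R", "delta_B", "delta_C",
                   "delta_S")


def summarize(records: Sequence[MeasurementRecord],
              group_by: str = "group") -> SummaryTable:
    """Aggregate measurement records into a per-group mean / SD / N table.

    SD is the sample standard deviation (n-1 denominator); a group with one
    record reports SD as missing.  Records without a group label fall into
    group ``"all"``; empty groups are omitted with a warning.
    """
    rows = []
    for rec in records:
        row: Dict = {"group": rec.group or "all",
                     "filament_id": rec.filament_id,
                     "cell_length": rec.cell_length}
        for f in _SUMMARY_FIELDS:
            row[f] = getattr(rec.derived, f)
        rows.append(row)
    if not rows:
        raise ValueError("no records to summarize")
    df = pd.DataFrame(rows)
    params = ["cell_length", *_SUMMARY_FIELDS]
    out = []
    for grp, sub in df.groupby("group"):
        for p in params:
            vals = sub[p].dropna().astype(float)
            if vals.empty:
                continue
            out.append({
                "group": grp, "parameter": p,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "N": int(len(vals)),
            })
    return SummaryTable(table=pd.DataFrame(out))


def compare_groups(a: Iterable[float], b: Iterable[float]
                   ) -> Tuple[float, float]:
    """Welch two-sample t-test; returns (t statistic, two-sided p-value).

    The Welch formulation does not assume equal variances; the degenerate
    case of two zero-variance samples is resolved directly (t = 0, p = 1
    when the means coincide, otherwise p = 0).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
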