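"""Synthetic microscopy data with attached ground truth.

Two imaging modes are emulated, matching the two quantitative modalities
used to characterize cable bacterium envelopes:

* **AFM-like height maps** of air-dried filaments.  Air-dried filaments
  adhere to the mica substrate and deflate into a half-ellipse transverse
  profile (width ``W``, apex height ``H``), corrugated by the parallel ridge
  compartments, with a swell (higher, slightly narrower) at every cell
  junction.  The raster holds heights in nm above the substrate plane (0).
* **FIB-SEM-like transverse sections** rasterized from the parametric
  envelope model: half-circular ridge compartments with dark lining and a
  light fiber core at mid-cell; the cartwheel of stalked bulbs at junctions.

Every rendered artifact carries the exact generator parameters and seed in
its provenance, plus a ground-truth block the measurement pipeline never
reads.  Rendering is geometric with idealized contrast — no tip-convolution
or beam physics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from cablemorph.envelope import (
    CrossSectionGeometry,
    FilamentGeometryParams,
    FilamentModel,
    build_filament,
    cross_section,
)
from cablemorph.geometry import HalfEllipseSpec, half_ellipse_perimeter

__all__ = [
    "DeflationParams",
    "HeightMap",
    "SectionImage",
    "FixtureConfig",
    "render_afm_heightmap",
    "render_section_image",
    "make_fixture_suite",
    "LABELS",
]

#: semantic labels of the section label raster
LABELS = {
    "background": 0,
    "cytoplasm": 1,
    "lining": 2,       # ridge compartment incl. its dark lining
    "fiber_core": 3,   # periplasmic fiber / bulb core (lightly stained)
    "bulb": 4,
    "spoke": 5,
}

#: default stain intensities per label (arbitrary units in [0, 1];
#: osmium-stained material is dark, unstained cores light)
DEFAULT_CONTRAST = {
    "background": 0.85,
    "cytoplasm": 0.55,
    "lining": 0.15,
    "fiber_core": 0.75,
    "bulb": 0.20,
    "spoke": 0.15,
}


@dataclass(frozen=True)
class DeflationParams:
    """How an air-dried filament collapses onto the substrate.

    ``mid_cell_height_W_ratio`` fixes the half-ellipse aspect ``H/W`` at
    mid-cell (default 0.87/3.71, the thick-filament value).  Junctions
    resist deflation: they are ``junction_height_factor`` times higher
    (default 1.30) and ``junction_width_factor`` times as wide (default
    0.89, i.e. 11 % narrower).  ``perimeter_shrink`` is the ratio of the
    air-dried to the embedded envelope perimeter (air-drying shrinks
    filaments; ~0.63 for thick filaments); the deflated width follows from
    perimeter conservation of the shrunken envelope.
    """

    mid_cell_height_W_ratio: float = 0.87 / 3.71
    junction_height_factor: float = 1.30
    junction_width_factor: float = 0.89
    noise_sd: float = 5.0
    seed: int = 0
    perimeter_shrink: float = 0.63
    corrugation_depth: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mid_cell_height_W_ratio <= 0.5:
            raise ValueError("mid_cell_height_W_ratio must lie in (0, 0.5] "
                             "(H cannot exceed W/2 for a half-ellipse)")
        if self.junction_height_factor < 1.0:
            raise ValueError("junction_height_factor must be >= 1")
        if not 0.0 < self.junction_width_factor <= 1.0:
            raise ValueError("junction_width_factor must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.perimeter_shrink <= 1.0:
            raise ValueError("perimeter_shrink must lie in (0, 1]")
        if self.corrugation_depth < 0:
            raise ValueError("corrugation_depth must be >= 0")


@dataclass
class HeightMap:
    """2D topography raster: heights in nm above the substrate (= 0) plane.

    ``provenance`` records the generator parameters, seed, and — for
    synthetic maps — a ``truth`` block with the exact deflated geometry.
    """

    values: np.ndarray
    pixel_size: float
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.values = np.asarray(self.values, dtype=np.float32)

    @property
    def truth(self) -> Optional[Dict]:
        return self.provenance.get("truth")

    def save(self, path: str | Path) -> Path:
        """Write a 32-bit float TIFF (nm values) plus a JSON sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.values)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(
            {"pixel_size_nm": self.pixel_size, "provenance": self.provenance},
            sort_keys=True, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "HeightMap":
        path = Path(path)
        values = tifffile.imread(path)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        return cls(values=values, pixel_size=meta["pixel_size_nm"],
                   provenance=meta.get("provenance", {}))


@dataclass
class SectionImage:
    """Rasterized transverse section: exact label raster + stain intensity.

    The label raster is the rasterized ground truth (one integer code per
    structure class, see :data:`LABELS`); the intensity raster mimics
    back-scattered-electron contrast of an osmium/uranyl-stained section.
    """

    label_raster: np.ndarray
    intensity_raster: np.ndarray
    pixel_size: float
    truth: Optional[CrossSectionGeometry] = None
    provenance: Dict = field(default_factory=dict)

    def save(self, stem: str | Path) -> Tuple[Path, Path]:
        """Write ``<stem>_labels.png`` (16-bit) and ``<stem>_intensity.tif``
        plus a JSON sidecar with pixel size, provenance, and truth geometry."""
        stem = Path(stem)
        label_path = stem.parent / (stem.name + "_labels.png")
        int_path = stem.parent / (stem.name + "_intensity.tif")
        iio.imwrite(label_path, self.label_raster.astype(np.uint16))
        tifffile.imwrite(int_path, self.intensity_raster.astype(np.float32))
        sidecar = stem.parent / (stem.name + ".json")
        sidecar.write_text(json.dumps(
            {"pixel_size_nm": self.pixel_size,
             "provenance": self.provenance,
             "truth": json.loads(self.truth.to_json()) if self.truth else None},
            sort_keys=True, indent=1))
        return label_path, int_path

    @classmethod
    def load(cls, stem: str | Path) -> "SectionImage":
        stem = Path(stem)
        labels = iio.imread(stem.parent / (stem.name + "_labels.png"))
        intensity = tifffile.imread(stem.parent / (stem.name + "_intensity.tif"))
        meta = json.loads((stem.parent / (stem.name + ".json")).read_text())
        return cls(label_raster=np.asarray(labels, dtype=np.int32),
                   intensity_raster=intensity,
                   pixel_size=meta["pixel_size_nm"],
                   provenance=meta.get("provenance", {}))


# ---------------------------------------------------------------------------
# AFM height maps
# ---------------------------------------------------------------------------

def deflated_mid_cell_geometry(model: FilamentModel,
                               deflation: DeflationParams) -> Tuple[float, float]:
    """Mid-cell (W, H) of the air-dried filament, nm.

    The collapsed envelope keeps its (shrunken) perimeter: W solves
    ``half_ellipse_perimeter(W, H = ratio * W) = shrink * N_R * delta_R``.
    Since that perimeter is linear in W at fixed aspect, the solution is
    closed-form.
    """
    p_target = deflation.perimeter_shrink * model.params.perimeter
    ratio = deflation.mid_cell_height_W_ratio
    per_unit_width = half_ellipse_perimeter(HalfEllipseSpec(W=1.0, H=ratio))
    W = p_target / per_unit_width
    return W, ratio * W


def render_afm_heightmap(model: FilamentModel,
                         deflation: DeflationParams,
                         pixel_size: float,
                         rotation_deg: float = 0.0,
                         margin: float = 500.0) -> HeightMap:
    """Render an AFM-like height map of an air-dried filament.

    The filament lies along the raster's row axis (columns = longitudinal
    coordinate), optionally rotated in-plane by ``rotation_deg``.  Each
    transverse profile is a half-ellipse of width W(z) and height H(z);
    W and H swell smoothly toward every junction per ``deflation``.  The top
    surface carries a raised-cosine ridge corrugation whose crest-to-crest
    spacing is the ridge width projected onto the deflated perimeter
    (``shrink * delta_R``), with valleys of ``corrugation_depth``.  Additive
    Gaussian noise (``noise_sd``, seeded) is applied and heights clipped at
    the substrate plane.
    """
    p = model.params
    spacing = deflation.perimeter_shrink * p.delta_R
    if pixel_size > spacing / 4.0:
        raise ValueError(
            f"pixel_size = {pixel_size} nm too coarse to resolve the ridge "
            f"corrugation: must be <= projected ridge spacing / 4 = "
            f"{spacing / 4.0:.1f} nm (Nyquist-style sampling constraint)"
        )
    W_mid, H_mid = deflated_mid_cell_geometry(model, deflation)
    W_jct = deflation.junction_width_factor * W_mid
    H_jct = deflation.junction_height_factor * H_mid
    L = model.length
    theta = math.radians(rotation_deg)

    # raster large enough for the rotated filament plus substrate margin
    diag = math.hypot(L, W_mid)
    span_z = abs(L * math.cos(theta)) + abs(W_mid * math.sin(theta))
    span_x = abs(L * math.sin(theta)) + abs(W_mid * math.cos(theta))
    if rotation_deg == 0.0:
        span_z, span_x = L, W_mid
    else:
        span_z, span_x = min(span_z, diag), min(span_x, diag)
    n_cols = int(math.ceil((span_z + 2 * margin) / pixel_size))
    n_rows = int(math.ceil((span_x + 2 * margin) / pixel_size))

    # physical pixel-center coordinates (0-based, pixel-center convention)
    xs = (np.arange(n_cols) + 0.5) * pixel_size
    ys = (np.arange(n_rows) + 0.5) * pixel_size
    X, Y = np.meshgrid(xs, ys)  # X: along columns, Y: along rows
    cx, cy = xs.mean(), ys.mean()
    u = np.array([math.cos(theta), math.sin(theta)])   # filament axis
    n = np.array([-math.sin(theta), math.cos(theta)])  # transverse
    # filament frame: z_f in [0, L] along axis, x_f transverse offset
    dX, dY = X - cx, Y - cy
    z_f = dX * u[0] + dY * u[1] + L / 2.0
    x_f = dX * n[0] + dY * n[1]

    # axial modulation: smooth swell within 2 * junction half-width
    T = 2.0 * p.junction_halfwidth
    dist = np.min(np.abs(z_f[..., None] - model.junction_positions[None, None, :]),
                  axis=-1)
    t = 0.5 * (1.0 + np.cos(math.pi * np.minimum(dist, T) / T))
    W_z = W_mid + (W_jct - W_mid) * t
    H_z = H_mid + (H_jct - H_mid) * t

    inside = (z_f >= 0.0) & (z_f <= L) & (np.abs(x_f) <= W_z / 2.0)
    # half-ellipse base profile
    rel = np.zeros_like(x_f)
    np.divide(2.0 * x_f, W_z, out=rel, where=inside)
    taper = np.sqrt(np.clip(1.0 - rel ** 2, 0.0, 1.0))
    base = H_z * taper
    # raised-cosine ridge corrugation, tapered so valleys never undercut
    corr = -0.5 * deflation.corrugation_depth \
        * (1.0 - np.cos(2.0 * math.pi * x_f / spacing)) * taper
    heights = np.where(inside, base + corr, 0.0)

    rng = np.random.default_rng(deflation.seed)
    if deflation.noise_sd > 0:
        heights = heights + rng.normal(0.0, deflation.noise_sd, heights.shape)
    heights = np.clip(heights, 0.0, None).astype(np.float32)

    truth = {
        "W_mid_nm": W_mid,
        "H_mid_nm": H_mid,
        "W_junction_nm": W_jct,
        "H_junction_nm": H_jct,
        "ridge_spacing_nm": spacing,
        "cell_length_nm": p.cell_length,
        "n_cells": p.n_cells,
        "junction_z_nm": model.junction_positions.tolist(),
        "filament_origin_px": [float(cx / pixel_size - (L / 2.0) * u[0] / pixel_size),
                               float(cy / pixel_size - (L / 2.0) * u[1] / pixel_size)],
        "rotation_deg": rotation_deg,
        "params": asdict(p),
    }
    provenance = {
        "generator": "render_afm_heightmap",
        "deflation": asdict(deflation),
        "pixel_size_nm": pixel_size,
        "rotation_deg": rotation_deg,
        "margin_nm": margin,
        "seed": deflation.seed,
        "truth": truth,
    }
    return HeightMap(values=heights, pixel_size=pixel_size,
                     provenance=provenance)


# ---------------------------------------------------------------------------
# FIB-SEM-like transverse sections
# ---------------------------------------------------------------------------

def _paint_disks(label: np.ndarray, X: np.ndarray, Y: np.ndarray,
                 centers: np.ndarray, radius: float, code: int) -> None:
    for cxy in np.atleast_2d(centers):
        m = (X - cxy[0]) ** 2 + (Y - cxy[1]) ** 2 <= radius ** 2
        label[m] = code


def _paint_segment(label: np.ndarray, X: np.ndarray, Y: np.ndarray,
                   a: np.ndarray, b: np.ndarray, halfwidth: float,
                   code: int) -> None:
    """Paint a ribbon of given half-width along segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    px, py = X - a[0], Y - a[1]
    if denom < 1e-12:
        d2 = px ** 2 + py ** 2
    else:
        t = np.clip((px * ab[0] + py * ab[1]) / denom, 0.0, 1.0)
        d2 = (px - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2
    label[d2 <= halfwidth ** 2] = code


def render_section_image(model: FilamentModel, z: float, pixel_size: float,
                         stain_contrast: Optional[Dict[str, float]] = None,
                         rotation_deg: float = 0.0,
                         noise_sd: float = 0.02,
                         seed: int = 0,
                         margin: float = 100.0) -> SectionImage:
    """Rasterize the transverse section at ``z`` into label + intensity rasters.

    The label raster is the exact rasterized truth (pixel-center point
    sampling of the analytic geometry).  Stain contrast: compartment lining
    and spokes dark, cytoplasm intermediate, bulb/fiber cores light,
    mimicking osmium staining.  ``rotation_deg`` rotates the cartwheel /
    ridge pattern in-plane.
    """
    p = model.params
    if pixel_size > p.delta_S / 3.0:
        raise ValueError(
            f"pixel_size = {pixel_size} nm too coarse to resolve stalks: "
            f"must be <= delta_S / 3 = {p.delta_S / 3.0:.1f} nm"
        )
    geomsec = cross_section(model, z, phase=math.radians(rotation_deg))
    R = p.envelope_radius
    extent = R + 0.5 * p.ridge_chord + margin
    npx = int(math.ceil(2.0 * extent / pixel_size))
    coords = (np.arange(npx) + 0.5) * pixel_size - extent
    X, Y = np.meshgrid(coords, coords)
    r2 = X ** 2 + Y ** 2

    label = np.zeros((npx, npx), dtype=np.int32)
    label[r2 <= R ** 2] = LABELS["cytoplasm"]

    if geomsec.kind == "mid_cell":
        chord = p.ridge_chord
        angles = math.radians(rotation_deg) + 2.0 * math.pi * np.arange(p.N_R) / p.N_R
        for k in range(p.N_R):
            rx, ry = math.cos(angles[k]), math.sin(angles[k])
            cxy = np.array([R * rx, R * ry])
            near = (X - cxy[0]) ** 2 + (Y - cxy[1]) ** 2 <= (0.5 * chord) ** 2
            # compartments sit on the envelope circle, bulging outward; the
            # inner boundary is the circle arc so the cell body stays a disk
            label[near & (r2 > R ** 2)] = LABELS["lining"]
        _paint_disks(label, X, Y, geomsec.fiber_centers, 0.5 * p.d_fiber,
                     LABELS["fiber_core"])
    else:
        for s in geomsec.spokes:
            _paint_segment(label, X, Y, s[0], s[-1], 0.5 * p.delta_S,
                           LABELS["spoke"])
        _paint_disks(label, X, Y, geomsec.fiber_centers, 0.5 * p.delta_B,
                     LABELS["bulb"])
        _paint_disks(label, X, Y, geomsec.fiber_centers, 0.5 * p.delta_C,
                     LABELS["fiber_core"])

    contrast = dict(DEFAULT_CONTRAST)
    if stain_contrast:
        contrast.update(stain_contrast)
    lut = np.empty(max(LABELS.values()) + 1, dtype=np.float32)
    for name, code in LABELS.items():
        lut[code] = contrast[name]
    intensity = lut[label]
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.shape)
    intensity = np.clip(intensity, 0.0, 1.0).astype(np.float32)

    provenance = {
        "generator": "render_section_image",
        "z_nm": float(z),
        "kind": geomsec.kind,
        "pixel_size_nm": pixel_size,
        "rotation_deg": rotation_deg,
        "noise_sd": noise_sd,
        "seed": seed,
        "params": asdict(p),
    }
    return SectionImage(label_raster=label, intensity_raster=intensity,
                        pixel_size=pixel_size, truth=geomsec,
                        provenance=provenance)


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

#: Per-class study conditions.  Each class provides the envelope parameters
#: of its two reference filaments and the class deflation behavior observed
#: by AFM: thick intact filaments (BF), thin intact filaments (SF), and
#: SDS+EDTA-extracted filaments (EF), whose junctions stand out nearly three
#: times higher (320 nm vs 120 nm) than the collapsed mid-cell sheath.
CLASS_SPECS: Dict[str, Dict] = {
    "BF": {
        "filaments": [
            dict(N_R=61, delta_R=205.0, delta_B=124.0, delta_C=57.0,
                 delta_S=82.0, cell_length=4930.0, ridge_area=11e3),
            dict(N_R=58, delta_R=213.0, delta_B=117.0, delta_C=46.0,
                 delta_S=59.0, cell_length=4930.0, ridge_area=16e3),
        ],
        "deflation": dict(mid_cell_height_W_ratio=0.87 / 3.71,
                          junction_height_factor=1.13 / 0.87,
                          junction_width_factor=0.89,
                          perimeter_shrink=0.63),
        "pixel_size": 20.0,
        "sections": True,
    },
    "SF": {
        "filaments": [
            dict(N_R=15, delta_R=231.0, delta_B=103.0, delta_C=50.0,
                 delta_S=68.0, cell_length=2220.0, ridge_area=9e3),
            dict(N_R=16, delta_R=126.0, delta_B=111.0, delta_C=50.0,
                 delta_S=49.0, cell_length=2220.0, ridge_area=5e3),
        ],
        "deflation": dict(mid_cell_height_W_ratio=0.19 / 0.85,
                          junction_height_factor=0.24 / 0.19,
                          junction_width_factor=0.66 / 0.85,
                          perimeter_shrink=0.567),
        "pixel_size": 10.0,
        "sections": True,
    },
    "EF": {
        "filaments": [
            dict(N_R=62, delta_R=120.0, delta_B=86.0, delta_C=24.0,
                 delta_S=63.0, cell_length=3850.0),
            dict(N_R=52, delta_R=140.0, delta_B=92.0, delta_C=40.0,
                 delta_S=48.0, cell_length=3850.0),
        ],
        "deflation": dict(mid_cell_height_W_ratio=0.12 / 3.78,
                          junction_height_factor=320.0 / 120.0,
                          junction_width_factor=3.05 / 3.78,
                          perimeter_shrink=0.853),
        "pixel_size": 12.0,
        "sections": False,
    },
}


@dataclass(frozen=True)
class FixtureConfig:
    """Configuration of the standard synthetic fixture set."""

    seed: int = 0
    n_cells: int = 3
    noise_sd: float = 5.0
    classes: Tuple[str, ...] = ("BF", "SF", "EF")
    section_pixel_size: float = 12.0
    corrugation_depth: float = 30.0


def fixture_filaments(config: FixtureConfig
                      ) -> List[Tuple[str, str, FilamentModel, DeflationParams, float]]:
    """Enumerate (filament_id, class, model, deflation, afm_pixel_size).

    Seeds are split deterministically from ``config.seed`` per filament.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(sum(len(CLASS_SPECS[c]["filaments"])
                            for c in config.classes))
    out = []
    i = 0
    for cls in config.classes:
        spec = CLASS_SPECS[cls]
        for j, fil in enumerate(spec["filaments"], start=1):
            seed = int(children[i].generate_state(1)[0] % (2 ** 31))
            i += 1
            params = FilamentGeometryParams(n_cells=config.n_cells, **fil)
            model = build_filament(params)
            deflation = DeflationParams(
                noise_sd=config.noise_sd, seed=seed,
                corrugation_depth=config.corrugation_depth,
                **spec["deflation"])
            out.append((f"{cls}{j}", cls, model, deflation,
                        spec["pixel_size"]))
    return out


def make_fixture_suite(config: FixtureConfig,
                       out_dir: str | Path) -> Dict:
    """Generate the standard fixture set on disk.

    Per filament: an AFM-like height map (float TIFF + JSON sidecar); for
    intact classes additionally a mid-cell and a junction section render
    (16-bit PNG labels + float TIFF intensity + sidecar).  A ``truth.csv``
    holds one row per (filament, cell) with the exact generator geometry.

    Returns a manifest dict with written paths and the truth table.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out_dir}: {exc}") from exc

    manifest: Dict = {"heightmaps": {}, "sections": {}, "config": asdict(config)}
    truth_rows = []
    for fid, cls, model, deflation, px in fixture_filaments(config):
        hm = render_afm_heightmap(model, deflation, pixel_size=px)
        path = out_dir / f"{fid}_afm.tif"
        hm.save(path)
        manifest["heightmaps"][fid] = str(path)

        if CLASS_SPECS[cls]["sections"]:
            p = model.params
            z_mid = model.junction_positions[0] + 0.5 * p.cell_length
            z_jct = model.junction_positions[1]
            paths = {}
            for tag, z in (("mid", z_mid), ("junction", z_jct)):
                img = render_section_image(
                    model, z, pixel_size=config.section_pixel_size,
                    seed=deflation.seed)
                stem = out_dir / f"{fid}_section_{tag}"
                img.save(stem)
                paths[tag] = str(stem)
            manifest["sections"][fid] = paths

        t = hm.truth
        for cell in range(model.params.n_cells):
            truth_rows.append({
                "filament_id": fid,
                "class": cls,
                "cell_index": cell,
                "z_mid_nm": (cell + 0.5) * model.params.cell_length,
                "cell_length_nm": model.params.cell_length,
                "W_mid_nm": t["W_mid_nm"],
                "H_mid_nm": t["H_mid_nm"],
                "W_junction_nm": t["W_junction_nm"],
                "H_junction_nm": t["H_junction_nm"],
                "ridge_spacing_nm": t["ridge_spacing_nm"],
                "N_R": model.params.N_R,
                "delta_R_nm": model.params.delta_R,
                "delta_B_nm": model.params.delta_B,
                "seed": deflation.seed,
            })
    truth = pd.DataFrame(truth_rows)
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path, index=False)
    manifest["truth_csv"] = str(truth_path)
    manifest["truth"] = truth
    return manifest
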