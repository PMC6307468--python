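"""Parametric envelope model: packing, sections, spoke tree, conservation."""

import math

import networkx as nx
import numpy as np
import pytest

from cablemorph.envelope import (
    FilamentGeometryParams,
    area_conservation_report,
    build_filament,
    bulb_center_radius,
    cross_section,
)
from cablemorph.geometry import bulb_area


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a closed polyline (oracle for region areas)."""
    x, y = poly[:-1, 0], poly[:-1, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polyline_length(poly: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))


def test_default_model_matches_thin_filament_reference(sf1_model):
    p = sf1_model.params
    assert p.perimeter == pytest.approx(3465.0)          # 15 x 231 nm
    assert p.d_ESD == pytest.approx(3465.0 / math.pi)


def test_thick_filament_diameter(bf1_model):
    assert bf1_model.params.d_ESD == pytest.approx(3980.0, rel=2e-3)


def test_single_cell_has_only_end_junctions():
    m = build_filament(FilamentGeometryParams(n_cells=1))
    assert m.junction_positions.tolist() == [0.0, m.params.cell_length]
    assert m.interior_junctions.size == 0


def test_infeasible_bulb_packing_raises_named_error():
    with pytest.raises(ValueError, match="packing"):
        build_filament(FilamentGeometryParams(
            N_R=20, delta_R=50.0, delta_B=160.0, delta_C=40.0))


def test_oversized_fiber_raises_named_error():
    with pytest.raises(ValueError, match="packing"):
        build_filament(FilamentGeometryParams(d_fiber=150.0, delta_B=160.0))


def test_bulbs_pushed_outward_when_tangent_ring_too_tight():
    """Measured thin-filament dimensions force a mutually tangent bulb ring."""
    p = FilamentGeometryParams(N_R=16, delta_R=126.0, delta_B=111.0,
                               delta_C=50.0, delta_S=49.0)
    r_b = bulb_center_radius(p)
    assert r_b == pytest.approx(0.5 * 111.0 / math.sin(math.pi / 16))
    assert r_b > p.envelope_radius - 0.5 * p.delta_B
    assert r_b <= p.envelope_radius


def test_cross_section_kind_switches_at_junction_halfwidth(sf1_model):
    L = sf1_model.params.cell_length
    hw = sf1_model.params.junction_halfwidth
    assert cross_section(sf1_model, L).kind == "junction"
    assert cross_section(sf1_model, L + hw * 0.99).kind == "junction"
    assert cross_section(sf1_model, L + hw * 1.5).kind == "mid_cell"
    assert cross_section(sf1_model, 0.5 * L).kind == "mid_cell"


def test_cross_section_rejects_out_of_range_z(sf1_model):
    with pytest.raises(ValueError):
        cross_section(sf1_model, -1.0)
    with pytest.raises(ValueError):
        cross_section(sf1_model, sf1_model.length + 1.0)


def test_mid_cell_section_structure(sf1_model):
    sec = cross_section(sf1_model, 0.5 * sf1_model.params.cell_length)
    p = sf1_model.params
    assert len(sec.ridge_regions) == p.N_R
    assert sec.fiber_centers.shape == (p.N_R, 2)
    half_disc_area = 0.5 * math.pi * (0.5 * p.ridge_chord) ** 2
    for region in sec.ridge_regions:
        assert polygon_area(region) == pytest.approx(half_disc_area, rel=2e-3)


def test_junction_section_bulb_areas(bf1_model):
    sec = cross_section(bf1_model, bf1_model.params.cell_length)
    assert sec.kind == "junction"
    expected = bulb_area(bf1_model.params.delta_B)
    for region in sec.ridge_regions:
        assert polygon_area(region) == pytest.approx(expected, rel=2e-3)
    # per-bulb area ~12.1e3 nm^2, inside the mid-cell compartment range
    assert expected == pytest.approx(12.1e3, rel=1e-2)


def test_envelope_outline_perimeter_converges_to_n_r_delta_r(sf1_model):
    """Polygonal outline length approaches N_R * delta_R with density."""
    target = sf1_model.params.perimeter
    errors = []
    for density in (8, 32, 128):
        sec = cross_section(sf1_model, 0.0, vertices_per_region=density)
        errors.append(abs(polyline_length(sec.envelope_outline) - target))
    assert errors[0] < 0.02 * target
    assert errors[2] < errors[1] < errors[0]


def test_spoke_tree_is_connected_acyclic_with_leaf_per_bulb(bf1_model):
    sec = cross_section(bf1_model, 0.0)
    g = nx.Graph()
    for seg in sec.spokes:
        g.add_edge(tuple(np.round(seg[0], 6)), tuple(np.round(seg[-1], 6)))
    assert nx.is_connected(g)
    assert g.number_of_edges() == g.number_of_nodes() - 1  # acyclic
    leaves = {n for n in g.nodes if g.degree[n] == 1 and n != (0.0, 0.0)}
    bulb_centers = {tuple(np.round(c, 6)) for c in sec.fiber_centers}
    assert leaves == bulb_centers
    assert (0.0, 0.0) in g.nodes  # central node


def test_fibers_keep_identity_along_filament(sf1_model):
    """Fiber k stays in compartment k: no tangential swaps between sections."""
    zs = np.linspace(0.0, sf1_model.length, 40)
    prev = cross_section(sf1_model, zs[0]).fiber_centers
    for z in zs[1:]:
        cur = cross_section(sf1_model, z).fiber_centers
        # nearest neighbor of each fiber in the next section is itself
        d = np.linalg.norm(prev[:, None, :] - cur[None, :, :], axis=-1)
        assert np.array_equal(np.argmin(d, axis=1), np.arange(len(cur)))
        ang_prev = np.arctan2(prev[:, 1], prev[:, 0])
        ang_cur = np.arctan2(cur[:, 1], cur[:, 0])
        assert np.allclose(ang_prev, ang_cur)
        prev = cur


def test_lengths_scale_linearly_and_areas_quadratically(bf1_model):
    c = 2.5
    scaled = build_filament(bf1_model.params.scaled(c))
    sec = cross_section(bf1_model, 0.5 * bf1_model.params.cell_length)
    sec_s = cross_section(scaled, 0.5 * scaled.params.cell_length)
    for a, b in zip(sec.ridge_regions, sec_s.ridge_regions):
        assert polygon_area(b) == pytest.approx(c ** 2 * polygon_area(a),
                                                rel=1e-9)
    r = area_conservation_report(bf1_model)
    r_s = area_conservation_report(scaled)
    assert r_s.A_B == pytest.approx(c ** 2 * r.A_B, rel=1e-12)
    assert r_s.mean == pytest.approx(r.mean, rel=1e-12)


def test_area_conservation_exact_match_gives_unit_ratios():
    p = FilamentGeometryParams(N_R=12, delta_R=200.0, delta_B=120.0,
                               delta_C=50.0, delta_S=60.0,
                               ridge_area=bulb_area(120.0))
    rep = area_conservation_report(build_filament(p))
    assert np.allclose(rep.ratios, 1.0)
    assert rep.mean == pytest.approx(1.0)


def test_area_conservation_thick_filament_ratios(bf1_model):
    """Bulb and compartment hold comparable periplasmic material."""
    rep = area_conservation_report(bf1_model)
    assert len(rep.ratios) == 61
    assert rep.mean == pytest.approx(bulb_area(124.0) / 11e3, rel=1e-12)
    assert rep.mean == pytest.approx(1.09, abs=0.02)
    # second thick filament: larger compartments, ratio below 1
    bf2 = build_filament(FilamentGeometryParams(
        N_R=58, delta_R=213.0, delta_B=117.0, delta_C=46.0, delta_S=59.0,
        ridge_area=16e3))
    rep2 = area_conservation_report(bf2)
    assert rep2.mean == pytest.approx(bulb_area(117.0) / 16e3, rel=1e-12)


def test_section_serialization_round_trip(sf1_model):
    import json
    sec = cross_section(sf1_model, 0.0)
    payload = json.loads(sec.to_json())
    assert payload["kind"] == "junction"
    assert len(payload["ridge_regions"]) == sf1_model.params.N_R
    table = sec.vertex_table()
    assert set(table["element"]) == {"envelope_outline", "ridge_region",
                                     "fiber_center", "spoke"}
    assert (table["element"] == "ridge_region").sum() == sum(
        len(r) for r in sec.ridge_regions)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        FilamentGeometryParams(N_R=2)
    with pytest.raises(ValueError):
        FilamentGeometryParams(delta_C=120.0, delta_B=100.0)
    with pytest.raises(ValueError):
        FilamentGeometryParams(n_cells=0)
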