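import numpy as np
import pytest

from vtsim.config import CellParams, CompartmentSpec, CytoskeletonParams
from vtsim.geometry import (Filament, GeometryError, StructureField, build_cell,
                            generate_cytoskeleton, trace_field_line)


def _cell(radius=5.0, nucleus_radius=0.0, nucleus_center=(0, 0, 0)):
    return build_cell(CellParams(radius=radius, nucleus_radius=nucleus_radius,
                                 nucleus_center=nucleus_center))


class TestBuildCell:
    def test_valid_offset_nucleus(self):
        cell = _cell(5.0, 1.5, (2.0, 0.0, 0.0))
        assert cell.cell_radius == 5.0
        assert cell.contains(np.array([[4.0, 0, 0]]))[0]
        assert not cell.contains(np.array([[2.0, 0, 0]]))[0]  # in nucleus

    def test_nucleus_larger_than_cell_rejected(self):
        with pytest.raises(GeometryError):
            _cell(5.0, 6.0)

    def test_zero_nucleus_radius_valid(self):
        cell = _cell(5.0, 0.0)
        assert cell.contains(np.zeros((1, 3)))[0]


TWO_COMP = [CompartmentSpec(id="C1", center=(3.0, 0, 0), radius=0.5),
            CompartmentSpec(id="C2", center=(-3.0, 0, 0), radius=0.5)]


class TestGenerateCytoskeleton:
    def test_none_style_empty(self, rng):
        fils = generate_cytoskeleton(CytoskeletonParams(style="none"),
                                     _cell(), TWO_COMP, rng)
        assert fils == []

    def test_radial_rays_pass_through_centre(self, rng):
        p = CytoskeletonParams(style="radial", n_filaments=64)
        fils = generate_cytoskeleton(p, _cell(), [], rng)
        assert len(fils) == 64
        for f in fils:
            assert np.linalg.norm(f.vertices[0]) < 1e-12

    def test_direct_bundle_parallel_to_axis(self, rng):
        p = CytoskeletonParams(style="direct", n_filaments=16, bundle_radius=0.2)
        fils = generate_cytoskeleton(p, _cell(), TWO_COMP, rng)
        assert len(fils) == 16
        for f in fils:
            d = f.vertices[-1] - f.vertices[0]
            d /= np.linalg.norm(d)
            assert abs(abs(d[0]) - 1.0) < 0.05  # roughly x-aligned
        # axial chord: length close to the surface-to-surface distance
        axial = [f.length for f in fils if
                 np.linalg.norm(f.vertices[0][1:]) < 0.05]
        for L in axial:
            assert L == pytest.approx(6.0 - 0.5 - 0.5, abs=0.05)

    def test_dipole_axis_seed_reaches_target(self):
        # independent oracle: brute-force integration of the two-point-charge
        # field from the donor-facing axis point must land on the target
        c1, c2 = np.array([3.0, 0, 0]), np.array([-3.0, 0, 0])
        seed = c1 + np.array([-0.55, 0.0, 0.0])
        pts = trace_field_line(seed, c1, 0.55, c2, 4.95, step=0.01)
        assert np.linalg.norm(pts[-1] - c2) <= 0.56

    def test_dipole_focusing_property(self, rng):
        p = CytoskeletonParams(style="dipole", n_filaments=60)
        fils = generate_cytoskeleton(p, _cell(), TWO_COMP, rng)
        target = np.array([-3.0, 0, 0])
        # standoff seeding: ends must reach the target sphere vicinity
        reached = sum(np.linalg.norm(f.vertices[-1] - target) < 0.8 for f in fils)
        assert reached >= 0.95 * len(fils)

    def test_all_filaments_inside_cell(self, rng):
        cell = _cell()
        for style in ("random", "direct", "linear", "dipole", "radial",
                      "polarized"):
            p = CytoskeletonParams(style=style, n_filaments=12)
            for f in generate_cytoskeleton(p, cell, TWO_COMP, rng):
                for s in np.linspace(0, f.length, max(int(f.length / 0.001), 2)):
                    assert np.linalg.norm(f.point_at(s)) <= cell.cell_radius + 1e-9

    def test_unknown_style_rejected(self, rng):
        with pytest.raises(Exception):
            generate_cytoskeleton(CytoskeletonParams(style="helix"),
                                  _cell(), TWO_COMP, rng)

    def test_polarized_biased_to_pole(self, rng):
        p = CytoskeletonParams(style="polarized", n_filaments=200,
                               pole=(-1.0, 0, 0), polarization=5.0)
        fils = generate_cytoskeleton(p, _cell(), [], rng)
        ends = np.array([f.vertices[-1] for f in fils])
        ends /= np.linalg.norm(ends, axis=1, keepdims=True)
        assert (ends @ np.array([-1.0, 0, 0])).mean() > 0.5


class TestDistanceQueries:
    def test_point_on_vertex_distance_zero(self):
        f = Filament(0, np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        sf = StructureField(_cell(), [f])
        hit = sf.nearest_filament(np.array([1.0, 0.0, 0.0]))
        assert hit.distance == pytest.approx(0.0, abs=1e-12)

    def test_centre_with_radial_filaments_distance_zero(self, rng):
        p = CytoskeletonParams(style="radial", n_filaments=8)
        fils = generate_cytoskeleton(p, _cell(), [], rng)
        sf = StructureField(_cell(), fils)
        hit = sf.distance_to_structures(np.zeros(3))
        assert hit.kind == "filament"
        assert hit.distance == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_segment_scan(self, rng):
        # oracle: brute force over every segment of every filament
        p = CytoskeletonParams(style="random", n_filaments=6, length=3.0)
        cell = _cell()
        fils = generate_cytoskeleton(p, cell, [], rng)
        sf = StructureField(cell, fils)

        def brute(pt):
            best = np.inf
            for f in fils:
                for a, b in zip(f.vertices[:-1], f.vertices[1:]):
                    ab = b - a
                    t = np.clip(np.dot(pt - a, ab) / np.dot(ab, ab), 0, 1)
                    best = min(best, np.linalg.norm(a + t * ab - pt))
            return best

        for _ in range(50):
            pt = rng.uniform(-2, 2, 3)
            hit = sf.nearest_filament(pt)
            assert hit.distance == pytest.approx(brute(pt), rel=1e-9)

    def test_membrane_and_nucleus_distances(self):
        cell = _cell(5.0, 1.0, (0.0, 0.0, 0.0))
        sf = StructureField(cell, [])
        hit = sf.distance_to_structures(np.array([4.5, 0, 0]))
        assert hit.kind == "membrane"
        assert hit.distance == pytest.approx(0.5)
        hit = sf.distance_to_structures(np.array([1.2, 0, 0]))
        assert hit.kind == "nucleus"
        assert hit.distance == pytest.approx(0.2)


class TestFilament:
    def test_arc_length_parameterization(self):
        f = Filament(0, np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 1.0, 0]]))
        assert f.length == pytest.approx(2.0)
        assert f.point_at(1.5) == pytest.approx([1.0, 0.5, 0.0])
        assert f.tangent_at(0.5) == pytest.approx([1.0, 0.0, 0.0])
        assert f.tangent_at(1.5) == pytest.approx([0.0, 1.0, 0.0])

    def test_degenerate_vertices_rejected(self):
        with pytest.raises(GeometryError):
            Filament(0, np.array([[0.0, 0, 0], [0.0, 0, 0]]))
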