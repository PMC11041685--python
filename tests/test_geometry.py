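"""Assembly generators: counts, symmetry, self-similarity, reference fractals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fractasm.geometry import (
    GeometryParams,
    ParameterError,
    GeometryError,
    build_compact_triangle,
    build_hexamer,
    build_sierpinski,
    chaos_game,
    pascal_parity,
    sierpinski_lattice_cells,
    subdivision_triangles,
    subunit_count,
)

LOG3_LOG2 = math.log(3) / math.log(2)


class TestHexamer:
    def test_counts(self, hexamer):
        assert hexamer.n_subunits == 6
        assert len(hexamer.dimers) == 3
        assert len(hexamer.hexamers) == 1
        assert hexamer.fractal_bonds == []

    def test_monomer_ring_radius_is_rg(self, hexamer, params):
        # all six monomers are equidistant from the centroid
        pts = hexamer.monomer_positions()
        ctr = pts.mean(axis=0)
        r = np.linalg.norm(pts - ctr, axis=1)
        assert np.allclose(r, params.ring_radius, atol=1e-12)

    def test_d3_symmetry_under_120_rotation(self, hexamer):
        pts = hexamer.monomer_positions()[:, :2]
        ctr = pts.mean(axis=0)
        th = math.radians(120.0)
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        rotated = (pts - ctr) @ R.T + ctr
        # rotated set equals original set within 1e-9 nm
        d = np.linalg.norm(rotated[:, None, :] - pts[None, :, :], axis=2)
        assert (d.min(axis=1) < 1e-9).all()

    def test_corner_directions_at_120_degrees(self, hexamer):
        dirs = [d.corner_direction for d in hexamer.dimers]
        for i in range(3):
            cosang = np.dot(dirs[i], dirs[(i + 1) % 3])
            assert cosang == pytest.approx(math.cos(math.radians(120)), abs=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            GeometryParams(hexamer_width=-1)
        with pytest.raises(ParameterError):
            GeometryParams(monomer_radius=0)
        with pytest.raises(ParameterError):
            GeometryParams(dihedral_level1=200)


class TestSierpinski:
    @pytest.mark.parametrize(
        "level,n_hex,n_sub,n_bonds",
        [(0, 1, 6, 0), (1, 3, 18, 3), (2, 9, 54, 12), (3, 27, 162, 39)],
    )
    def test_counts(self, level, n_hex, n_sub, n_bonds):
        a = build_sierpinski(level)
        assert len(a.hexamers) == n_hex
        assert a.n_subunits == n_sub
        assert len(a.dimers) == 3 * n_hex
        # bond count follows (3^k - 1) * 3 / 2
        assert len(a.fractal_bonds) == n_bonds == (3 ** level - 1) * 3 // 2

    def test_level0_equals_hexamer(self, hexamer):
        a = build_sierpinski(0)
        assert np.allclose(a.monomer_positions(), hexamer.monomer_positions())

    def test_level1_has_nine_dimers(self, level1):
        assert len(level1.dimers) == 9

    def test_edge_spans_2k_hexamer_widths(self, params):
        for k in (1, 2, 3):
            a = build_sierpinski(k, params)
            c = a.hexamer_centers()
            bottom = c[np.isclose(c[:, 1], 0.0)]
            extent = bottom[:, 0].max() - bottom[:, 0].min() + params.hexamer_width
            assert extent == pytest.approx(2 ** k * params.hexamer_width)

    def test_self_similarity_of_sub_blocks(self, params):
        # the three sub-blocks of level k are pure translates of level k-1
        for k in (1, 2, 3):
            sub = np.array(
                sorted(map(tuple, build_sierpinski(k - 1, params).hexamer_centers()))
            )
            whole = build_sierpinski(k, params).hexamer_centers()
            n = len(sub)
            s = 2 ** (k - 1) * params.hexamer_width
            offsets = [
                np.zeros(3),
                np.array([s, 0.0, 0.0]),
                np.array([s / 2, s * math.sqrt(3) / 2, 0.0]),
            ]
            blocks = [whole[i * n : (i + 1) * n] for i in range(3)]
            matched = set()
            for off in offsets:
                for bi, blk in enumerate(blocks):
                    shifted = np.array(sorted(map(tuple, blk - off)))
                    if np.abs(shifted - sub).max() < 1e-9:
                        matched.add(bi)
            assert matched == {0, 1, 2}

    def test_central_void(self, params):
        # the centroid of level >= 2 lies inside the large central void
        for k in (2, 3):
            a = build_sierpinski(k, params)
            ctr = a.hexamer_centers().mean(axis=0)
            dists = np.linalg.norm(a.monomer_positions() - ctr, axis=1)
            assert dists.min() > params.hexamer_width / 2

    def test_bonds_reference_distinct_dimers_of_distinct_hexamers(self, level2):
        used = set()
        for a, b in level2.fractal_bonds:
            assert a not in used and b not in used
            used |= {a, b}
            assert level2.dimers[a].hexamer_id != level2.dimers[b].hexamer_id

    def test_bonded_pair_has_one_participating_monomer_per_dimer(self, level1):
        for a, b in level1.fractal_bonds:
            for d_id in (a, b):
                d = level1.dimers[d_id]
                flags = [level1.monomers[m].participates for m in d.monomer_ids]
                assert sum(flags) == 1

    def test_no_excessive_monomer_overlap(self, level2, params):
        # coarse spheres of adjacent hexamers may interdigitate, but no
        # deeper than the stated 1.2 nm tolerance
        pts = level2.monomer_positions()
        hex_of = np.array([level2.dimers[m.dimer_id].hexamer_id for m in level2.monomers])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        inter = hex_of[:, None] != hex_of[None, :]
        overlap = 2 * params.monomer_radius - d[inter]
        assert overlap.max() <= 1.2 + 1e-9

    def test_negative_level_rejected(self):
        with pytest.raises(ParameterError):
            build_sierpinski(-1)


class TestCompactTriangle:
    def test_36mer_counts_and_edge(self, params):
        a = build_compact_triangle(3, params)
        assert len(a.hexamers) == 6
        assert a.n_subunits == 36
        assert a.fractal_bonds == []
        c = a.hexamer_centers()
        bottom = c[np.isclose(c[:, 1], 0.0)]
        extent = bottom[:, 0].max() - bottom[:, 0].min() + params.hexamer_width
        assert extent == pytest.approx(30.0)

    def test_rows1_is_single_hexamer(self):
        assert build_compact_triangle(1).n_subunits == 6

    def test_rows2_centers_match_level1(self, level1):
        a = build_compact_triangle(2)
        got = np.array(sorted(map(tuple, a.hexamer_centers())))
        want = np.array(sorted(map(tuple, level1.hexamer_centers())))
        assert np.allclose(got, want)

    def test_invalid_rows(self):
        with pytest.raises(ParameterError):
            build_compact_triangle(0)


class TestSubunitCount:
    @pytest.mark.parametrize("level,expected", [(0, 6), (1, 18), (2, 54), (3, 162)])
    def test_series(self, level, expected):
        assert subunit_count(level) == expected

    @pytest.mark.parametrize("level", [0, 1, 2, 3, 4])
    def test_matches_generator(self, level):
        assert subunit_count(level) == build_sierpinski(level).n_subunits

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            subunit_count(-1)


class TestChaosGame:
    def test_points_inside_convex_hull(self):
        pts = chaos_game(5000, seed=3)
        v = np.array([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2]])
        # barycentric coordinates all in [0, 1]
        T = np.array([v[0] - v[2], v[1] - v[2]]).T
        lam = np.linalg.solve(T, (pts - v[2]).T).T
        bary = np.column_stack([lam, 1 - lam.sum(axis=1)])
        assert (bary > -1e-12).all() and (bary < 1 + 1e-12).all()

    def test_deterministic_by_seed(self):
        a = chaos_game(1000, seed=42)
        b = chaos_game(1000, seed=42)
        assert np.array_equal(a, b)
        c = chaos_game(1000, seed=43)
        assert not np.array_equal(a, c)

    def test_collinear_vertices_rejected(self):
        with pytest.raises(GeometryError):
            chaos_game(10, seed=0, vertices=np.array([[0, 0], [1, 1], [2, 2]]))

    def test_burn_in_discarded(self):
        # with burn_in=0 the first point depends on the (fixed) start
        pts0 = chaos_game(5, seed=0, burn_in=0)
        pts10 = chaos_game(5, seed=0, burn_in=10)
        assert not np.allclose(pts0, pts10[:5])


class TestPascalParity:
    def test_first_rows_against_brute_force(self):
        mask = pascal_parity(64)
        for r in range(64):
            for c in range(r + 1):
                assert mask[r, c] == (math.comb(r, c) % 2 == 1)

    def test_four_rows_have_nine_odd_entries(self):
        assert pascal_parity(4).sum() == 9

    def test_row3_all_odd(self):
        assert pascal_parity(4)[3, :4].all()

    @pytest.mark.parametrize("k", range(1, 9))
    def test_power_of_two_rows_give_3k_entries(self, k):
        assert pascal_parity(2 ** k).sum() == 3 ** k

    def test_invalid_rows(self):
        with pytest.raises(ParameterError):
            pascal_parity(0)


class TestSubdivision:
    def test_triangle_count(self):
        assert subdivision_triangles(0).shape == (1, 3, 2)
        assert subdivision_triangles(4).shape == (81, 3, 2)

    def test_total_area_scales_by_three_quarters(self):
        def area(tris):
            a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
            return 0.5 * np.abs(np.cross(b - a, c - a)).sum()

        a0 = area(subdivision_triangles(0))
        a3 = area(subdivision_triangles(3))
        assert a3 == pytest.approx(a0 * (3 / 4) ** 3)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(level=st.integers(min_value=0, max_value=5))
def test_lattice_cell_count_is_power_of_three(level):
    assert len(sierpinski_lattice_cells(level)) == 3 ** level
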