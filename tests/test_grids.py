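"""Density gridding: kernel, geometry, rendering, transforms, steric overlap."""

import numpy as np
import pytest

from gridmol.atom_types import TypedAtom, TypedStruct, type_atom
from gridmol.grids import (
    DensityGrid, GridSpec, RigidTransform, coordinate_gradient, grid_coordinates,
    kernel, load_grid, molecule_to_grid, random_transform, save_grid, steric_overlap,
)


def _carbon(coord, scheme):
    return TypedAtom(coord, type_atom("C", False, False, False, 0, scheme))


class TestKernel:
    def test_unit_at_zero(self):
        assert kernel(0.0, 1.0) == 1.0

    def test_zero_beyond_cutoff(self):
        assert kernel(2.0, 1.0) == 0.0

    def test_gaussian_value(self):
        assert kernel(0.5, 1.0) == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_monotone_nonincreasing(self):
        d = np.linspace(0, 3, 200)
        v = kernel(d, 1.0)
        assert np.all(np.diff(v) <= 1e-15)
        assert np.all((v >= 0) & (v <= 1))

    @pytest.mark.parametrize("d,r", [(-0.1, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_invalid_inputs(self, d, r):
        with pytest.raises(ValueError):
            kernel(d, r)


class TestGeometry:
    def test_default_spec_has_48_points(self):
        assert GridSpec().points_per_axis == 48

    def test_corner_coordinates(self):
        coords = grid_coordinates(GridSpec())
        assert np.allclose(coords[0, 0, 0], (-11.75, -11.75, -11.75))
        assert np.allclose(coords[47, 47, 47], (11.75, 11.75, 11.75))

    def test_small_spec_points(self, small_spec):
        assert small_spec.points_per_axis == 12


class TestRendering:
    def test_single_atom_at_center(self, lig_scheme):
        spec = GridSpec(n_channels=18)
        struct = TypedStruct([_carbon((0.0, 0.0, 0.0), lig_scheme)], lig_scheme)
        grid = molecule_to_grid(struct, spec)
        # center voxel: default 48-point grid has no lattice point exactly at
        # the center of an even-count axis... use an odd spec instead
        spec = GridSpec(side=10.0, resolution=1.0, n_channels=18)  # 11 points
        grid = molecule_to_grid(struct, spec)
        c_chan = lig_scheme.elements.index("C")
        assert grid.values[c_chan, 5, 5, 5] == pytest.approx(1.0)
        for ch in range(11):
            if ch != c_chan:
                assert np.all(grid.values[ch] == 0)

    def test_empty_struct_zero_grid(self, lig_scheme):
        grid = molecule_to_grid(TypedStruct([], lig_scheme), GridSpec())
        assert np.all(grid.values == 0)

    def test_two_atom_superposition(self, lig_scheme):
        spec = GridSpec(side=10.0, resolution=1.0, n_channels=18)
        p = np.array([0.0, 0.0, 0.0])
        struct = TypedStruct(
            [_carbon(p + (0.4, 0, 0), lig_scheme), _carbon(p - (0.4, 0, 0), lig_scheme)],
            lig_scheme,
        )
        grid = molecule_to_grid(struct, spec)
        c_chan = lig_scheme.elements.index("C")
        assert grid.values[c_chan, 5, 5, 5] == pytest.approx(2 * np.exp(-2 * 0.16), abs=1e-12)

    def test_additivity(self, lig_scheme, rng):
        spec = GridSpec(side=10.0, resolution=1.0, n_channels=18)
        atoms = [_carbon(rng.uniform(-4, 4, 3), lig_scheme) for _ in range(6)]
        full = molecule_to_grid(TypedStruct(atoms, lig_scheme), spec)
        a = molecule_to_grid(TypedStruct(atoms[:3], lig_scheme), spec)
        b = molecule_to_grid(TypedStruct(atoms[3:], lig_scheme), spec)
        assert np.allclose(full.values, a.values + b.values, atol=1e-12)

    def test_boundedness(self, lig_scheme, rng):
        spec = GridSpec(side=6.0, resolution=0.5, n_channels=18)
        atoms = [_carbon(rng.uniform(-1, 1, 3), lig_scheme) for _ in range(5)]
        grid = molecule_to_grid(TypedStruct(atoms, lig_scheme), spec)
        assert grid.values.max() <= 5.0

    def test_channel_mismatch_rejected(self, lig_scheme):
        struct = TypedStruct([_carbon((0, 0, 0), lig_scheme)], lig_scheme)
        with pytest.raises(ValueError):
            molecule_to_grid(struct, GridSpec(n_channels=4))

    def test_rotation_equivariance_analytic(self, lig_scheme, rng):
        """Density of the rotated structure at lattice point p equals the
        analytic density of the original at R^-1 p (kernel-sum oracle)."""
        spec = GridSpec(side=10.0, resolution=1.0, n_channels=18)
        coords = rng.uniform(-2.5, 2.5, size=(4, 3))
        struct = TypedStruct([_carbon(c, lig_scheme) for c in coords], lig_scheme)
        tf = random_transform(7, max_translation=0.0)

        def analytic(points, atom_coords):
            d = np.linalg.norm(points[None] - atom_coords[:, None], axis=-1)
            return kernel(d, spec.atomic_radius).sum(axis=0)

        grid_rot = molecule_to_grid(struct, spec, tf)
        c_chan = lig_scheme.elements.index("C")
        pts = grid_coordinates(spec)
        for idx in [(5, 5, 5), (4, 6, 5), (3, 3, 7)]:
            p = pts[idx]
            expected = analytic((tf.rotation.T @ p)[None], coords)[0]
            assert grid_rot.values[(c_chan,) + idx] == pytest.approx(expected, abs=1e-12)


class TestRandomTransform:
    def test_determinism(self):
        a = random_transform(42, 2.0)
        b = random_transform(42, 2.0)
        assert np.array_equal(a.rotation, b.rotation)
        assert np.array_equal(a.translation, b.translation)

    def test_zero_translation(self):
        tf = random_transform(1, 0.0)
        assert np.all(tf.translation == 0)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_uniformity(self):
        """Mean of R @ v over many uniform rotations shrinks like 1/sqrt(n)."""
        v = np.array([1.0, 0.0, 0.0])
        n = 4000
        mean = np.mean([random_transform(s, 0.0).rotation @ v for s in range(n)], axis=0)
        assert np.linalg.norm(mean) < 4.0 / np.sqrt(n)

    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(rotation=np.diag([1.0, 1.0, -1.0]))


class TestStericOverlap:
    def _grid_with_atom(self, coord, scheme, spec):
        return molecule_to_grid(TypedStruct([_carbon(coord, scheme)], scheme), spec)

    def test_disjoint_supports(self, lig_scheme, rec_scheme):
        spec_l = GridSpec(side=10.0, resolution=1.0, n_channels=18)
        a = self._grid_with_atom((-4, 0, 0), rec_scheme, spec_l)
        b = self._grid_with_atom((4, 0, 0), lig_scheme, spec_l)
        assert steric_overlap(a, b) == 0.0

    def test_self_overlap_matches_bruteforce(self, lig_scheme):
        spec = GridSpec(side=10.0, resolution=1.0, n_channels=18)
        g = self._grid_with_atom((0.3, -0.2, 0.1), lig_scheme, spec)
        expected = float(np.sum(g.values.sum(axis=0) * g.values.sum(axis=0)))
        assert steric_overlap(g, g) == pytest.approx(expected)

    def test_symmetry(self, lig_scheme, rec_scheme, rng):
        spec = GridSpec(side=10.0, resolution=1.0, n_channels=18)
        a = self._grid_with_atom(rng.uniform(-2, 2, 3), rec_scheme, spec)
        b = self._grid_with_atom(rng.uniform(-2, 2, 3), lig_scheme, spec)
        assert steric_overlap(a, b) == pytest.approx(steric_overlap(b, a))

    def test_zero_ligand(self, lig_scheme, rec_scheme):
        spec = GridSpec(side=10.0, resolution=1.0, n_channels=18)
        a = self._grid_with_atom((0, 0, 0), rec_scheme, spec)
        zero = DensityGrid(np.zeros(spec.shape), spec)
        assert steric_overlap(a, zero) == 0.0

    def test_geometry_mismatch(self, lig_scheme):
        a = DensityGrid(np.zeros(GridSpec(n_channels=1).shape), GridSpec(n_channels=1))
        spec2 = GridSpec(side=10.0, resolution=1.0, n_channels=1)
        b = DensityGrid(np.zeros(spec2.shape), spec2)
        with pytest.raises(ValueError):
            steric_overlap(a, b)


def test_coordinate_gradient_matches_finite_differences(lig_scheme, rng):
    """Analytic d L2 / d coords vs central differences at 1e-5 tolerance."""
    spec = GridSpec(side=8.0, resolution=0.5, n_channels=18)
    ref_atoms = [_carbon(rng.uniform(-2, 2, 3), lig_scheme) for _ in range(3)]
    ref = molecule_to_grid(TypedStruct(ref_atoms, lig_scheme), spec)
    coords = np.array([a.coordinate for a in ref_atoms]) + rng.normal(0, 0.2, (3, 3))
    tvs = np.array([a.type_vector for a in ref_atoms])

    def loss(c):
        g = molecule_to_grid(
            TypedStruct([TypedAtom(x, t) for x, t in zip(c, tvs)], lig_scheme), spec
        )
        return np.sum((g.values - ref.values) ** 2)

    model = molecule_to_grid(
        TypedStruct([TypedAtom(x, t) for x, t in zip(coords, tvs)], lig_scheme), spec
    )
    grad = coordinate_gradient(model.values - ref.values, spec, coords, tvs)
    h = 1e-6
    for a in range(3):
        for ax in range(3):
            cp, cm = coords.copy(), coords.copy()
            cp[a, ax] += h
            cm[a, ax] -= h
            fd = (loss(cp) - loss(cm)) / (2 * h)
            assert grad[a, ax] == pytest.approx(fd, abs=1e-5, rel=1e-4)


def test_grid_serialization_roundtrip(tmp_path, lig_scheme):
    spec = GridSpec(center=(1.0, -2.0, 0.5), side=6.0, resolution=0.5, n_channels=18)
    struct = TypedStruct([_carbon((1.2, -1.8, 0.3), lig_scheme)], lig_scheme)
    grid = molecule_to_grid(struct, spec)
    grid.channel_labels = lig_scheme.channel_labels()
    save_grid(grid, tmp_path / "g")
    loaded = load_grid(tmp_path / "g")
    assert np.array_equal(loaded.values, grid.values)
    assert loaded.spec == grid.spec
    assert loaded.channel_labels == grid.channel_labels
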