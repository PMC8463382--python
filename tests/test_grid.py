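"""Cube I/O, difference densities, and charge-partition integrals."""

import numpy as np
import pytest

from conftest import gaussian_cube_text
from neetkit.grid import (CubeAtom, DensityGrid, group_localization,
                          integrate_total, partition_charges, read_cube,
                          subtract_density, write_cube)
from neetkit.synthetic import gen_gaussian_density, gen_redox_pair


def unit_grid(values, atoms=()):
    counts = np.asarray(values).shape
    return DensityGrid(origin=np.zeros(3), axes=np.eye(3),
                       values=np.asarray(values, float),
                       atoms=[CubeAtom(s, float(z), p) for s, z, p in atoms])


class TestCubeIO:
    def test_constant_field_integral(self, tmp_path):
        grid = unit_grid(np.ones((2, 2, 2)), atoms=[("H", 1, (0, 0, 0))])
        assert integrate_total(grid) == pytest.approx(8.0)
        path = tmp_path / "c.cube"
        write_cube(grid, path)
        back = read_cube(path)
        assert integrate_total(back) == pytest.approx(8.0)

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = unit_grid(rng.normal(size=(3, 4, 5)),
                         atoms=[("Fe", 26, (1.0, 2.0, 3.0))])
        grid.is_orbital = True
        path = tmp_path / "mo.cube"
        write_cube(grid, path)
        back = read_cube(path)
        assert back.is_orbital
        assert np.allclose(back.values, grid.values, atol=1e-4)
        assert np.allclose(back.origin, grid.origin)
        assert back.atoms[0].symbol == "Fe"

    def test_angstrom_dialect_matches_bohr_twin(self, tmp_path):
        # one analytic density written in both unit dialects
        pos = np.array([[0.0, 0.0, 0.0]])
        grid, _ = gen_gaussian_density(pos, [1.0], [1.0], counts=(24, 24, 24))
        step = grid.axes[0, 0]
        atoms = [(1, pos[0])]
        for name, ang in (("bohr.cube", False), ("ang.cube", True)):
            (tmp_path / name).write_text(gaussian_cube_text(
                grid.origin, step, grid.counts, atoms, grid.values,
                angstrom=ang))
        gb = read_cube(tmp_path / "bohr.cube")
        ga = read_cube(tmp_path / "ang.cube")
        assert integrate_total(ga) == pytest.approx(integrate_total(gb),
                                                    abs=1e-6)

    def test_truncated_value_block_errors(self, tmp_path):
        text = gaussian_cube_text((0, 0, 0), 1.0, (2, 2, 2),
                                  [(1, (0, 0, 0))], np.ones(8))
        lines = text.strip().split("\n")
        (tmp_path / "bad.cube").write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(ValueError, match="expected 8"):
            read_cube(tmp_path / "bad.cube")


class TestSubtract:
    def test_self_difference_is_zero(self):
        g = unit_grid(np.full((3, 3, 3), 2.0), atoms=[("H", 1, (0, 0, 0))])
        d = subtract_density(g, g)
        assert integrate_total(d) == 0.0

    def test_subtract_then_add_recovers(self):
        rng = np.random.default_rng(1)
        a = unit_grid(rng.random((3, 3, 3)), atoms=[("H", 1, (0, 0, 0))])
        b = unit_grid(rng.random((3, 3, 3)), atoms=[("H", 1, (0, 0, 0))])
        d = subtract_density(a, b)
        assert np.array_equal(d.values + b.values, a.values)

    def test_one_extra_electron(self):
        ox, red, _ = gen_redox_pair()
        d = subtract_density(red, ox)
        assert integrate_total(d) == pytest.approx(1.0, abs=1e-3)

    def test_mismatched_lattice_rejected(self):
        a = unit_grid(np.ones((3, 3, 3)), atoms=[("H", 1, (0, 0, 0))])
        b = unit_grid(np.ones((3, 3, 3)), atoms=[("H", 1, (0, 0, 0))])
        b.origin = b.origin + 0.5
        with pytest.raises(ValueError, match="lattice"):
            subtract_density(a, b)


class TestIntegrate:
    def test_unit_gaussian(self):
        grid, truth = gen_gaussian_density([[0.0, 0.0, 0.0]], [1.0], [1.0],
                                           counts=(40, 40, 40))
        assert integrate_total(grid) == pytest.approx(1.0, abs=1e-4)

    def test_linearity_of_mixture(self):
        grid, _ = gen_gaussian_density([[-2.0, 0, 0], [2.0, 0, 0]],
                                       [0.6, 0.4], [1.0], counts=(40, 40, 40))
        assert integrate_total(grid) == pytest.approx(1.0, abs=2e-4)

    def test_zero_grid(self):
        assert integrate_total(unit_grid(np.zeros((4, 4, 4)))) == 0.0


class TestPartition:
    def test_two_atom_gaussians_recovered(self):
        pos = np.array([[-3.0, 0, 0], [3.0, 0, 0]])
        grid, _ = gen_gaussian_density(pos, [0.6, 0.4], [0.5],
                                       counts=(40, 40, 40))
        grid.atoms = [CubeAtom("Fe", 26.0, pos[0]), CubeAtom("S", 16.0, pos[1])]
        t = partition_charges(grid)
        assert t.per_atom[0] == pytest.approx(0.6, abs=1e-3)
        assert t.per_atom[1] == pytest.approx(0.4, abs=1e-3)

    def test_single_atom_gets_everything(self):
        rng = np.random.default_rng(2)
        g = unit_grid(rng.normal(size=(5, 5, 5)), atoms=[("H", 1, (2, 2, 2))])
        t = partition_charges(g)
        assert t.per_atom[0] == pytest.approx(integrate_total(g), abs=1e-12)

    def test_zero_density_all_zero(self):
        g = unit_grid(np.zeros((4, 4, 4)),
                      atoms=[("H", 1, (0, 0, 0)), ("H", 1, (3, 3, 3))])
        t = partition_charges(g)
        assert all(v == 0 for v in t.per_atom.values())

    def test_empty_selection_errors(self):
        g = unit_grid(np.ones((3, 3, 3)), atoms=[("H", 1, (0, 0, 0))])
        with pytest.raises(ValueError, match="empty"):
            partition_charges(g, selection=[])

    def test_conservation_on_random_densities(self):
        # exhaustive+exclusive partition: per-atom sums equal the total
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n_atoms = rng.integers(1, 6)
            atoms = [("H", 1, rng.uniform(0, 9, 3)) for _ in range(n_atoms)]
            g = unit_grid(rng.normal(size=(10, 10, 10)), atoms=atoms)
            t = partition_charges(g)
            assert sum(t.per_atom.values()) == pytest.approx(
                integrate_total(g), abs=1e-10)

    def test_partition_linearity(self):
        rng = np.random.default_rng(3)
        atoms = [("H", 1, rng.uniform(0, 5, 3)) for _ in range(3)]
        v1, v2 = rng.normal(size=(2, 6, 6, 6))
        t1 = partition_charges(unit_grid(v1, atoms))
        t2 = partition_charges(unit_grid(v2, atoms))
        t12 = partition_charges(unit_grid(2 * v1 + 3 * v2, atoms))
        for k in t12.per_atom:
            assert t12.per_atom[k] == pytest.approx(
                2 * t1.per_atom[k] + 3 * t2.per_atom[k], abs=1e-10)

    def test_spheres_scheme_unassigned_balance(self):
        pos = np.array([[-3.0, 0, 0], [3.0, 0, 0]])
        grid, _ = gen_gaussian_density(pos, [0.6, 0.4], [0.5],
                                       counts=(32, 32, 32))
        grid.atoms = [CubeAtom("Fe", 26.0, pos[0]), CubeAtom("S", 16.0, pos[1])]
        t = partition_charges(grid, scheme="spheres", radius=2.5)
        assert t.per_atom[0] + t.per_atom[1] + t.unassigned == pytest.approx(
            t.total, abs=1e-10)
        assert t.per_atom[0] == pytest.approx(0.6, abs=5e-3)

    def test_refinement_convergence(self):
        # |dQ - analytic| decreases monotonically as the grid is refined
        pos = np.array([[-3.0, 0, 0], [3.0, 0, 0]])
        errs = []
        for counts in (20, 40, 80):
            grid, _ = gen_gaussian_density(pos, [0.6, 0.4], [1.0],
                                           counts=(counts,) * 3)
            grid.atoms = [CubeAtom("A", 1.0, pos[0]), CubeAtom("B", 1.0, pos[1])]
            t = partition_charges(grid)
            analytic_cross = 0.4 * 0.5 * _erfc_tail(3.0, 1.0) \
                - 0.6 * 0.5 * _erfc_tail(3.0, 1.0)
            errs.append(abs(t.per_atom[0] - (0.6 + analytic_cross)))
        assert errs[0] > errs[1] > errs[2]


def _erfc_tail(half_distance, sigma):
    from scipy.special import erfc
    return erfc(half_distance / (np.sqrt(2) * sigma))


class TestGroupLocalization:
    def test_all_on_one_atom(self):
        pos = np.array([[-3.0, 0, 0], [3.0, 0, 0]])
        grid, _ = gen_gaussian_density(pos, [1.0, 0.0], [0.5],
                                       counts=(32, 32, 32))
        grid.atoms = [CubeAtom("Fe", 26.0, pos[0]), CubeAtom("Fe", 26.0, pos[1])]
        frac = group_localization(grid, {"a": [0], "b": [1]})
        assert frac["a"] == pytest.approx(1.0, abs=1e-3)
        assert frac["b"] == pytest.approx(0.0, abs=1e-3)

    def test_uniform_symmetric_split(self):
        g = unit_grid(np.ones((8, 8, 8)),
                      atoms=[("A", 1, (2.0, 3.5, 3.5)), ("B", 1, (5.0, 3.5, 3.5))])
        frac = group_localization(g, {"a": [0], "b": [1]})
        assert frac["a"] == pytest.approx(0.5)
        assert frac["b"] == pytest.approx(0.5)

    def test_mixture_fractions(self):
        pos = np.array([[-3.0, 0, 0], [3.0, 0, 0]])
        grid, _ = gen_gaussian_density(pos, [0.9, 0.1], [0.5],
                                       counts=(40, 40, 40))
        grid.atoms = [CubeAtom("Fe", 26.0, pos[0]), CubeAtom("N", 7.0, pos[1])]
        frac = group_localization(grid, {"fe": [0], "n": [1]})
        assert frac["fe"] == pytest.approx(0.9, abs=2e-3)
        assert frac["n"] == pytest.approx(0.1, abs=2e-3)

    def test_nonpositive_total_errors(self):
        g = unit_grid(np.zeros((3, 3, 3)), atoms=[("H", 1, (0, 0, 0))])
        with pytest.raises(ValueError, match="non-positive"):
            group_localization(g, {"a": [0]})

    def test_overlapping_groups_error(self):
        g = unit_grid(np.ones((3, 3, 3)),
                      atoms=[("H", 1, (0, 0, 0)), ("H", 1, (2, 2, 2))])
        with pytest.raises(ValueError, match="overlap"):
            group_localization(g, {"a": [0, 1], "b": [1]})
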