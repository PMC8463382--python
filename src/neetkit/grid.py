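"""Gaussian-cube I/O and voxel-grid algebra.

Supports the analysis of one-electron reduction of [2Fe-2S] clusters:
the difference density between reduced and oxidized states,
``delta_rho = rho_red - rho_ox``, is integrated around selected atoms to
give per-atom charge changes (``dQ``), and orbital cubes are reduced to
per-group localization fractions (e.g. "fraction of the HOMO on the
His-bound iron").

All grids are held in atomic units (Bohr, e/Bohr^3) regardless of the
unit dialect of the file they were read from.  Integration is a midpoint
Riemann sum: each stored value owns one voxel of volume
``|det(axis_vectors)|``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .units import ANGSTROM_BOHR

__all__ = [
    "CubeAtom",
    "DensityGrid",
    "ChargeTable",
    "read_cube",
    "write_cube",
    "subtract_density",
    "integrate_total",
    "partition_charges",
    "group_localization",
]

# Minimal symbol table for cube atom records (extend as needed).
_Z_TO_SYMBOL = {
    1: "H", 6: "C", 7: "N", 8: "O", 16: "S", 26: "Fe",
    2: "He", 3: "Li", 9: "F", 11: "Na", 12: "Mg", 15: "P", 17: "Cl",
    19: "K", 20: "Ca", 30: "Zn",
}
_SYMBOL_TO_Z = {v: k for k, v in _Z_TO_SYMBOL.items()}


@dataclass(frozen=True)
class CubeAtom:
    """One atom record of a cube file (position in Bohr)."""

    symbol: str
    nuclear_charge: float
    position: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass
class DensityGrid:
    """A scalar field on a regular (possibly non-orthogonal) voxel lattice.

    Parameters
    ----------
    origin : (3,) array, Bohr
    axes : (3, 3) array, Bohr — row ``i`` is the step vector of axis ``i``.
    values : ndarray of shape ``counts`` (e/Bohr^3 for densities).
    atoms : embedded atom list sharing the grid's coordinate frame.
    is_orbital : True for molecular-orbital cubes (negative-natoms dialect).
    """

    origin: np.ndarray
    axes: np.ndarray
    values: np.ndarray
    atoms: list[CubeAtom] = field(default_factory=list)
    is_orbital: bool = False

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if any(c < 1 for c in self.values.shape):
            raise ValueError("every axis needs at least one voxel")
        if self.voxel_volume <= 0:
            raise ValueError("axis vectors are singular (zero voxel volume)")

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.axes)))

    def voxel_positions(self) -> np.ndarray:
        """Cartesian position of every sample point, shape (Nvox, 3), Bohr."""
        nx, ny, nz = self.counts
        idx = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        return self.origin + idx @ self.axes

    def atom_positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms]).reshape(-1, 3)

    def same_lattice(self, other: "DensityGrid", tol: float = 1e-6) -> bool:
        return (self.counts == other.counts
                and np.allclose(self.origin, other.origin, atol=tol)
                and np.allclose(self.axes, other.axes, atol=tol))


@dataclass
class ChargeTable:
    """Per-atom charge integrals from an exhaustive, exclusive partition.

    ``per_atom`` maps atom index -> integrated charge (e); voxels not
    assigned to any reported atom are pooled in ``unassigned`` so that
    ``sum(per_atom.values()) + unassigned == total`` by construction.
    """

    per_atom: dict[int, float]
    total: float
    scheme: str
    unassigned: float = 0.0

    def check_conservation(self, tol: float = 1e-10) -> None:
        s = sum(self.per_atom.values()) + self.unassigned
        if abs(s - self.total) > tol:
            raise AssertionError(
                f"partition not exhaustive: sum {s!r} != total {self.total!r}")

    def to_dataframe(self, atoms: list[CubeAtom] | None = None):
        import pandas as pd
        rows = []
        for i, q in sorted(self.per_atom.items()):
            el = atoms[i].symbol if atoms else ""
            rows.append({"atom_index": i, "element": el, "dQ_e": q})
        return pd.DataFrame(rows, columns=["atom_index", "element", "dQ_e"])


# ---------------------------------------------------------------------------
# cube I/O

def read_cube(path) -> DensityGrid:
    """Read a Gaussian cube file into a :class:`DensityGrid` (always Bohr).

    Both sign dialects are honored: a negative atom count marks a
    molecular-orbital cube (one extra header record listing MO indices);
    negative voxel counts mean origin/axes are given in Angstrom.
    """
    with open(path) as fh:
        text = fh.read().split("\n")
    if len(text) < 6:
        raise ValueError(f"{path}: not a cube file (fewer than 6 lines)")
    # lines 0-1 are comments
    head = text[2].split()
    natoms_raw = int(head[0])
    is_orbital = natoms_raw < 0
    natoms = abs(natoms_raw)
    origin = np.array([float(x) for x in head[1:4]])

    axes = np.zeros((3, 3))
    counts = np.zeros(3, dtype=int)
    angstrom = False
    for i in range(3):
        rec = text[3 + i].split()
        n = int(rec[0])
        if n < 0:
            angstrom = True
        counts[i] = abs(n)
        axes[i] = [float(x) for x in rec[1:4]]
    if angstrom:
        origin = origin * ANGSTROM_BOHR
        axes = axes * ANGSTROM_BOHR

    atoms = []
    for i in range(natoms):
        rec = text[6 + i].split()
        z = int(float(rec[0]))
        pos = np.array([float(x) for x in rec[2:5]])
        if angstrom:
            pos = pos * ANGSTROM_BOHR
        atoms.append(CubeAtom(_Z_TO_SYMBOL.get(z, f"Z{z}"), float(rec[1]), pos))

    cursor = 6 + natoms
    if is_orbital:
        mo_rec = text[cursor].split()
        if int(mo_rec[0]) != 1:
            raise ValueError(f"{path}: only single-MO cubes are supported "
                             f"(header lists {mo_rec[0]} orbitals)")
        cursor += 1

    tokens = " ".join(text[cursor:]).split()
    flat = np.array(tokens, dtype=float)
    nexp = int(np.prod(counts))
    if flat.size != nexp:
        raise ValueError(
            f"{path}: truncated value block — expected {nexp} values, "
            f"found {flat.size}")
    values = flat.reshape(tuple(counts))  # x outer, z inner
    return DensityGrid(origin, axes, values, atoms, is_orbital=is_orbital)


def write_cube(grid: DensityGrid, path, comment: str = "neetkit density cube") -> None:
    """Write a grid in the Bohr dialect (positive counts; natoms sign
    encodes the orbital flag)."""
    nx, ny, nz = grid.counts
    sign = -1 if grid.is_orbital else 1
    with open(path, "w") as fh:
        fh.write(comment + "\n")
        fh.write("values in e/Bohr^3, x-outer z-inner order\n")
        fh.write(f"{sign * len(grid.atoms):5d} "
                 + " ".join(f"{v:12.6f}" for v in grid.origin) + "\n")
        for i in range(3):
            fh.write(f"{grid.counts[i]:5d} "
                     + " ".join(f"{v:12.6f}" for v in grid.axes[i]) + "\n")
        for a in grid.atoms:
            z = _SYMBOL_TO_Z.get(a.symbol, 0)
            fh.write(f"{z:5d} {a.nuclear_charge:12.6f} "
                     + " ".join(f"{v:12.6f}" for v in a.position) + "\n")
        if grid.is_orbital:
            fh.write("    1    1\n")
        flat = grid.values.reshape(nx * ny, nz)
        for row in range(nx * ny):
            vals = flat[row]
            for k in range(0, nz, 6):
                fh.write(" ".join(f"{v: .5E}" for v in vals[k:k + 6]) + "\n")


# ---------------------------------------------------------------------------
# grid algebra

def subtract_density(red: DensityGrid, ox: DensityGrid) -> DensityGrid:
    """Voxel-wise difference density (reduced minus oxidized).

    Lattices must coincide (origin/axes/counts within 1e-6 Bohr) and carry
    the same atom list; mismatches raise rather than silently resampling,
    since resampling would change the downstream charge integrals.
    """
    if not red.same_lattice(ox):
        raise ValueError("cube lattices differ (origin/axes/counts); "
                         "refusing to resample")
    if len(red.atoms) != len(ox.atoms) or any(
            a.symbol != b.symbol or not np.allclose(a.position, b.position, atol=1e-6)
            for a, b in zip(red.atoms, ox.atoms)):
        raise ValueError("atom lists differ between the two cubes")
    return replace(red, values=red.values - ox.values,
                   atoms=list(red.atoms), is_orbital=False)


def integrate_total(grid: DensityGrid) -> float:
    """Total integral of the field: sum of values times voxel volume (e)."""
    return float(grid.values.sum() * grid.voxel_volume)


def _nearest_atom_assignment(grid: DensityGrid, positions: np.ndarray) -> np.ndarray:
    """Index of the closest atom for every voxel; ties -> lowest index
    (np.argmin returns the first minimum)."""
    vox = grid.voxel_positions()
    d = cdist(vox, positions)
    return np.argmin(d, axis=1)


def partition_charges(grid: DensityGrid, scheme: str = "nearest-atom",
                      selection: list[int] | None = None,
                      radius: float | None = None) -> ChargeTable:
    """Integrate the field around atoms: the per-atom ``dQ`` table.

    ``nearest-atom`` assigns every voxel to its closest atom (Voronoi,
    exhaustive — the default; conservation is exact by construction).
    ``spheres`` assigns voxels within ``radius`` (Bohr) of any *selected*
    atom to the closest selected atom; the remainder is reported as
    unassigned.
    """
    if not grid.atoms:
        raise ValueError("grid carries no atoms to partition around")
    nat = len(grid.atoms)
    if selection is None:
        selection = list(range(nat))
    if len(selection) == 0:
        raise ValueError("empty atom selection")
    if any(i < 0 or i >= nat for i in selection):
        raise IndexError("selection index out of range")

    vol = grid.voxel_volume
    flat = grid.values.ravel() * vol
    total = float(flat.sum())

    if scheme == "nearest-atom":
        owner = _nearest_atom_assignment(grid, grid.atom_positions())
        sums = np.bincount(owner, weights=flat, minlength=nat)
        sel = set(selection)
        per_atom = {i: float(sums[i]) for i in selection}
        unassigned = float(sum(sums[i] for i in range(nat) if i not in sel))
    elif scheme == "spheres":
        if radius is None or radius <= 0:
            raise ValueError("spheres scheme requires radius > 0 (Bohr)")
        pos = grid.atom_positions()[selection]
        vox = grid.voxel_positions()
        d = cdist(vox, pos)
        nearest = np.argmin(d, axis=1)
        inside = d[np.arange(len(vox)), nearest] <= radius
        per_atom = {}
        for k, i in enumerate(selection):
            per_atom[i] = float(flat[inside & (nearest == k)].sum())
        unassigned = float(flat[~inside].sum())
    else:
        raise ValueError(f"unknown partition scheme {scheme!r}")

    table = ChargeTable(per_atom=per_atom, total=total,
                        scheme=scheme, unassigned=unassigned)
    table.check_conservation(tol=1e-9)
    return table


def group_localization(grid: DensityGrid,
                       groups: dict[str, list[int]]) -> dict[str, float]:
    """Fraction of an orbital density carried by each named atom group.

    Uses the nearest-atom partition; fractions over *all* atoms sum to 1,
    so disjoint groups covering all atoms have fractions summing to 1.
    """
    total = integrate_total(grid)
    if total <= 0:
        raise ValueError("non-positive total density; cannot form fractions")
    seen: set[int] = set()
    for name, idx in groups.items():
        if seen & set(idx):
            raise ValueError(f"group {name!r} overlaps a previous group")
        seen |= set(idx)
    table = partition_charges(grid, scheme="nearest-atom")
    return {name: sum(table.per_atom[i] for i in idx) / total
            for name, idx in groups.items()}
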