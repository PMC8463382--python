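"""Cluster force-field parameter derivation: Seminario bond force
constants from a Cartesian Hessian, and restrained electrostatic-potential
(RESP) charge fitting on Merz-Kollman probe shells.

Energy convention
-----------------
Bond parameters are emitted under the AMBER convention
``E = K_r (r - R_min)^2`` (no 1/2 factor), with K_r in kJ/mol/nm^2 and
R_min in nm.  The Seminario eigen-sum of the interatomic Hessian block
yields a d2E/dr2-scale spring constant, so the emitted K_r is half that
sum after unit conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import (ANGSTROM_BOHR, BOHR_NM,
                    HARTREE_PER_BOHR2_TO_KJMOL_NM2)

__all__ = [
    "HessianMatrix",
    "BondParam",
    "ESPGrid",
    "seminario_bond_constant",
    "esp_fit_charges",
    "mk_probe_shells",
    "hessian_from_fchk",
    "write_fchk",
    "VDW_RADII",
]


@dataclass
class HessianMatrix:
    """A 3N x 3N Cartesian second-derivative matrix (Hartree/Bohr^2) with
    the coordinates (Bohr) and labels of its N atoms."""

    matrix: np.ndarray
    coords: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        n3 = self.matrix.shape[0]
        if self.matrix.shape != (n3, n3) or n3 % 3:
            raise ValueError("Hessian must be square with dimension 3N")
        if n3 != 3 * len(self.coords):
            raise ValueError("Hessian dimension inconsistent with atom count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("Hessian is not symmetric to 1e-8")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def block(self, i: int, j: int) -> np.ndarray:
        return self.matrix[3 * i:3 * i + 3, 3 * j:3 * j + 3]


@dataclass
class BondParam:
    """One bond's equilibrium length and force constant.

    Convention: ``E = K_r (r - R_min)^2`` with K_r in kJ/mol/nm^2, R_min nm.
    """

    atoms: tuple[int, int]
    R_min: float
    K_r: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.R_min <= 0:
            raise ValueError("R_min must be positive")
        if self.K_r < 0:
            raise ValueError("K_r must be non-negative")


def _seminario_one_direction(block: np.ndarray, u: np.ndarray) -> float:
    lam, vec = np.linalg.eig(-block)
    lam = np.real(lam)
    vec = np.real(vec)
    return float(sum(abs(lam[m]) * abs(vec[:, m] @ u) for m in range(3)))


def seminario_bond_constant(hessian: HessianMatrix, i: int, j: int) -> BondParam:
    """Seminario bond force constant between atoms ``i`` and ``j``.

    The 3x3 interatomic block H_ij is negated and eigendecomposed; the
    spring constant is the eigenvalue sum weighted by the projection of
    each eigenvector on the unit bond vector, averaged over the i->j and
    j->i blocks.  Negative eigenvalue contributions enter by absolute
    value (standard MCPB practice; recorded in ``meta``).
    """
    if i == j:
        raise ValueError("need two distinct atoms")
    n = hessian.n_atoms
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError("atom index out of range")
    rij = hessian.coords[j] - hessian.coords[i]
    dist = np.linalg.norm(rij)
    u = rij / dist
    bij = hessian.block(i, j)
    bji = hessian.block(j, i)
    if np.linalg.norm(bij) < 1e-10:
        raise ValueError(f"atoms {i} and {j} not coupled in the Hessian")
    k_ij = _seminario_one_direction(bij, u)
    k_ji = _seminario_one_direction(bji, u)
    k_raw = 0.5 * (k_ij + k_ji)   # Hartree/Bohr^2, d2E/dr2 scale
    K_r = 0.5 * k_raw * HARTREE_PER_BOHR2_TO_KJMOL_NM2
    return BondParam(
        atoms=(i, j), R_min=dist * BOHR_NM, K_r=K_r,
        meta={"k_ij_kJmol_nm2": 0.5 * k_ij * HARTREE_PER_BOHR2_TO_KJMOL_NM2,
              "k_ji_kJmol_nm2": 0.5 * k_ji * HARTREE_PER_BOHR2_TO_KJMOL_NM2,
              "eigenvalue_policy": "absolute",
              "convention": "E = K_r (r - R_min)^2"})


# ---------------------------------------------------------------------------
# RESP

@dataclass
class ESPGrid:
    """ESP probe points (Bohr, Hartree/e) around a molecule.

    ``sym_classes`` groups atom indices constrained to equal charge;
    atoms not listed form singleton classes.  ``elements`` lets the fit
    exempt hydrogens from the restraint.
    """

    points: np.ndarray
    potentials: np.ndarray
    atom_positions: np.ndarray
    total_charge: float
    elements: list[str] | None = None
    sym_classes: list[list[int]] = field(default_factory=list)

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.potentials = np.asarray(self.potentials, float).ravel()
        self.atom_positions = np.asarray(self.atom_positions, float).reshape(-1, 3)
        if len(self.points) != len(self.potentials):
            raise ValueError("points and potentials differ in length")
        if len(self.points) < len(self.atom_positions):
            raise ValueError("need at least as many probe points as atoms")


def _class_ids(n_atoms: int, sym_classes: list[list[int]]) -> np.ndarray:
    cid = -np.ones(n_atoms, dtype=int)
    nxt = 0
    for cls in sym_classes:
        for a in cls:
            if cid[a] != -1:
                raise ValueError(f"atom {a} in two symmetry classes")
            cid[a] = nxt
        nxt += 1
    for a in range(n_atoms):
        if cid[a] == -1:
            cid[a] = nxt
            nxt += 1
    return cid


def esp_fit_charges(grid: ESPGrid, restraint_strength: float = 0.0005,
                    restraint_b: float = 0.1,
                    two_stage: bool = False,
                    max_iter: int = 500, tol: float = 1e-8) -> np.ndarray:
    """Restrained ESP charges reproducing the probe potentials.

    Minimizes ``sum_p (V_p - sum_a q_a / r_pa)^2
    + a * sum_a (sqrt(q_a^2 + b^2) - b)`` subject to the total-charge
    constraint and symmetry-class equalities, by iterated reweighted
    linear (KKT) solves.  Hydrogens are excluded from the restraint but
    included in the fit.  Deterministic; converges when the charge update
    drops below ``tol``.
    """
    n = len(grid.atom_positions)
    r = np.linalg.norm(grid.points[:, None, :] - grid.atom_positions[None, :, :],
                       axis=-1)
    if (r < 1e-8).any():
        p, a = np.argwhere(r < 1e-8)[0]
        raise ValueError(f"probe point {p} coincides with atom {a}")
    A = 1.0 / r                                       # (P, n)
    cid = _class_ids(n, grid.sym_classes)
    ncls = cid.max() + 1
    M = np.zeros((n, ncls))
    M[np.arange(n), cid] = 1.0                        # atom -> class map
    Ac = A @ M                                        # (P, ncls)
    AtA = Ac.T @ Ac
    Atv = Ac.T @ grid.potentials
    sizes = M.sum(axis=0)
    restrained = np.ones(n, bool)
    if grid.elements is not None:
        restrained = np.array([e.upper() != "H" for e in grid.elements])
    w_cls = (M * restrained[:, None]).sum(axis=0)     # restrained atoms per class

    q = np.zeros(ncls)
    for _ in range(max_iter):
        diag = np.zeros(ncls)
        if restraint_strength > 0:
            diag = restraint_strength * w_cls / np.sqrt(q ** 2 + restraint_b ** 2)
        K = np.zeros((ncls + 1, ncls + 1))
        K[:ncls, :ncls] = AtA + np.diag(diag)
        K[:ncls, ncls] = sizes
        K[ncls, :ncls] = sizes
        rhs = np.concatenate([Atv, [grid.total_charge]])
        try:
            sol = np.linalg.solve(K, rhs)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular ESP design matrix: {err}") from err
        q_new = sol[:ncls]
        if np.max(np.abs(q_new - q)) < tol:
            q = q_new
            break
        q = q_new
    charges = M @ q
    if two_stage and grid.elements is not None:
        # stage 2: refit only hydrogens (and their classes) with heavy
        # atoms frozen; rarely needed for cluster models, kept simple.
        heavy = ~np.array([e.upper() == "H" for e in grid.elements])
        frozen_v = A[:, heavy] @ charges[heavy]
        sub = ESPGrid(points=grid.points, potentials=grid.potentials - frozen_v,
                      atom_positions=grid.atom_positions[~heavy],
                      total_charge=grid.total_charge - charges[heavy].sum(),
                      elements=[e for e, h in zip(grid.elements, heavy) if not h])
        charges[~heavy] = esp_fit_charges(sub, restraint_strength, restraint_b)
    return charges


# Bondi van der Waals radii (Angstrom); Fe per MCPB-style usage.
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80, "F": 1.47, "CL": 1.75, "FE": 1.30}


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def mk_probe_shells(elements: list[str], positions_ang: np.ndarray,
                    scales=(1.4, 1.6, 1.8, 2.0), density: float = 1.0,
                    radii: dict | None = None,
                    seed: int | None = None) -> np.ndarray:
    """Merz-Kollman probe shells: Fibonacci-spiral points on scaled
    van der Waals spheres, pruned of points inside any other atom's shell
    at the same scale.  Returns positions in Bohr.

    ``density`` is in points per Angstrom^2; ``seed`` applies a random
    global rotation to the spiral (deterministic for a fixed seed; no
    rotation when None).
    """
    positions_ang = np.asarray(positions_ang, float).reshape(-1, 3)
    radii = radii or VDW_RADII
    try:
        rv = np.array([radii[e.upper()] for e in elements])
    except KeyError as err:
        raise ValueError(f"no van der Waals radius for element {err}") from err
    rot = np.eye(3)
    if seed is not None:
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rot = q * np.sign(np.linalg.det(q))
    points = []
    for scale in scales:
        shell_r = scale * rv
        for a, (pos, r) in enumerate(zip(positions_ang, shell_r)):
            npts = max(4, int(round(density * 4 * np.pi * r ** 2)))
            pts = pos + (_fibonacci_sphere(npts) @ rot.T) * r
            keep = np.ones(len(pts), bool)
            for b, (pos_b, r_b) in enumerate(zip(positions_ang, shell_r)):
                if b == a:
                    continue
                keep &= np.linalg.norm(pts - pos_b, axis=1) >= r_b - 1e-9
            points.append(pts[keep])
    return np.vstack(points) * ANGSTROM_BOHR


# ---------------------------------------------------------------------------
# formatted-checkpoint-style I/O

def hessian_from_fchk(path) -> HessianMatrix:
    """Read atom labels, coordinates and the lower-triangular Cartesian
    force constants from a formatted-checkpoint-style text file."""
    labels: list[str] = []
    coords: np.ndarray | None = None
    tri: np.ndarray | None = None

    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("Atom labels"):
            n = int(line.split("N=")[1])
            vals = []
            while len(vals) < n:
                i += 1
                vals.extend(lines[i].split())
            labels = vals[:n]
        elif line.startswith("Current cartesian coordinates"):
            n = int(line.split("N=")[1])
            vals = []
            while len(vals) < n:
                i += 1
                vals.extend(float(x) for x in lines[i].split())
            coords = np.array(vals[:n]).reshape(-1, 3)
        elif line.startswith("Cartesian Force Constants"):
            n = int(line.split("N=")[1])
            vals = []
            while len(vals) < n:
                i += 1
                vals.extend(float(x) for x in lines[i].split())
            tri = np.array(vals[:n])
        i += 1
    if coords is None or tri is None:
        raise ValueError(f"{path}: missing coordinates or force-constant block")
    n3 = 3 * len(coords)
    if len(tri) != n3 * (n3 + 1) // 2:
        raise ValueError(
            f"{path}: force-constant block has {len(tri)} values, "
            f"expected 3N(3N+1)/2 = {n3 * (n3 + 1) // 2}")
    H = np.zeros((n3, n3))
    idx = np.tril_indices(n3)
    H[idx] = tri
    H = H + H.T - np.diag(np.diag(H))
    if not labels:
        labels = [f"A{k}" for k in range(len(coords))]
    return HessianMatrix(matrix=H, coords=coords, labels=labels)


def write_fchk(hessian: HessianMatrix, path) -> None:
    """Write the checkpoint-style text consumed by :func:`hessian_from_fchk`."""
    n3 = hessian.matrix.shape[0]
    tri = hessian.matrix[np.tril_indices(n3)]
    flat = hessian.coords.ravel()
    with open(path, "w") as fh:
        fh.write("neetkit synthetic checkpoint\n")
        fh.write(f"Atom labels                                N={len(hessian.labels):12d}\n")
        for k in range(0, len(hessian.labels), 5):
            fh.write(" ".join(f"{s:>12s}" for s in hessian.labels[k:k + 5]) + "\n")
        fh.write(f"Current cartesian coordinates              R   N={flat.size:12d}\n")
        for k in range(0, flat.size, 5):
            fh.write("".join(f"{v:16.8E}" for v in flat[k:k + 5]) + "\n")
        fh.write(f"Cartesian Force Constants                  R   N={tri.size:12d}\n")
        for k in range(0, tri.size, 5):
            fh.write("".join(f"{v:16.8E}" for v in tri[k:k + 5]) + "\n")
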