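"""Seeded synthetic-data generators with known ground truth.

Every input class the pipeline consumes has a generator here: analytic
atom-centered Gaussian densities (with closed-form per-atom integrals),
finite-difference Hessians of harmonic toy molecules, MSAs with planted
covarying column pairs, conformer sets with planted basins hidden behind
random rigid motions, exponential decay traces with known rate and
noise, and a mock NEET-like structure carrying an ideal-geometry
3Cys:1His [2Fe-2S] site.  Generators take an explicit seed, use one
private random stream per call (never global state), and emit a
machine-readable ground-truth record alongside the data.
"""

from __future__ import annotations

import json
import os

import numpy as np

from .coevolution import ALPHABET, Alignment
from .cluster import ConformationSet
from .grid import CubeAtom, DensityGrid, write_cube
from .kinetics import DecayTrace
from .params import HessianMatrix, write_fchk
from .units import ANGSTROM_BOHR

__all__ = [
    "gen_gaussian_density",
    "gen_redox_pair",
    "gen_harmonic_hessian",
    "gen_msa",
    "gen_conformers",
    "gen_decay_traces",
    "gen_arrhenius_panel",
    "gen_mock_neet_structure",
    "simulate_all",
]


# ---------------------------------------------------------------------------
# volumetric densities

def gen_gaussian_density(atom_positions, weights, sigmas,
                         origin=None, counts=(40, 40, 40),
                         spacing=None, span_sigmas: float = 6.0):
    """Sum of normalized isotropic Gaussians sampled on a regular grid.

    ``atom_positions`` (A, 3) Bohr; ``weights`` in e; ``sigmas`` Bohr.
    The grid must span at least ``span_sigmas`` standard deviations
    beyond the outermost atom on every axis (truncation would silently
    bias the integrals).  Returns (DensityGrid, truth) where truth maps
    atom index to its analytic integral (= weight).
    """
    pos = np.asarray(atom_positions, float).reshape(-1, 3)
    weights = np.asarray(weights, float)
    sigmas = np.broadcast_to(np.asarray(sigmas, float), weights.shape)
    margin = span_sigmas * sigmas.max()
    lo_req = pos.min(axis=0) - margin
    hi_req = pos.max(axis=0) + margin
    if origin is None or spacing is None:
        origin = lo_req
        spacing = (hi_req - lo_req) / (np.array(counts) - 1)
    origin = np.asarray(origin, float)
    spacing = np.broadcast_to(np.asarray(spacing, float), (3,))
    hi = origin + spacing * (np.array(counts) - 1)
    if (origin > lo_req + 1e-9).any() or (hi < hi_req - 1e-9).any():
        raise ValueError(
            f"grid [{origin}, {hi}] does not span {span_sigmas} sigma "
            f"beyond the outermost atom ([{lo_req}, {hi_req}])")
    axes = np.diag(spacing)
    grid = DensityGrid(origin, axes, np.zeros(counts),
                       atoms=[CubeAtom("X", 0.0, p) for p in pos])
    vox = grid.voxel_positions()
    vals = np.zeros(len(vox))
    for p, w, s in zip(pos, weights, sigmas):
        r2 = ((vox - p) ** 2).sum(axis=1)
        vals += w * np.exp(-r2 / (2 * s * s)) / ((2 * np.pi) ** 1.5 * s ** 3)
    grid.values = vals.reshape(counts)
    truth = {"per_atom_integral": {i: float(w) for i, w in enumerate(weights)},
             "total": float(weights.sum())}
    return grid, truth


#: default site-like atom layout (Bohr): Fe_Y-analog, two bridging-S
#: analogs, an N-His analog, plus two spectator atoms
SITE_ATOMS = np.array([
    [0.0, 0.0, 0.0],    # Fe_Y analog
    [3.2, 2.4, 0.0],    # S_1 analog
    [3.2, -2.4, 0.0],   # S_2 analog
    [-3.4, 0.0, 1.2],   # N_His analog
    [6.4, 0.0, 0.0],    # Fe_X analog
    [0.0, 0.0, -4.0],   # S_Cys analog
])
SITE_ELEMENTS = ["Fe", "S", "S", "N", "Fe", "S"]

#: where the extra electron goes on reduction (sums to 1.0 e): mostly the
#: His-bound iron, the bridging sulfurs, a little on the His nitrogen
DEFAULT_REDOX_WEIGHTS = (0.5, 0.2, 0.2, 0.1, 0.0, 0.0)


def gen_redox_pair(atom_positions=None, extra_electron_weights=None,
                   counts=(40, 40, 40), sigma: float = 0.5):
    """An (oxidized, reduced) cube pair whose difference is exactly one
    planted electron distributed over the atoms with known weights.

    The oxidized density is a fixed baseline (one broad Gaussian per
    atom); the reduced density adds narrow Gaussians carrying the planted
    one-electron weights.  Returns (ox, red, truth).
    """
    pos = SITE_ATOMS if atom_positions is None else \
        np.asarray(atom_positions, float).reshape(-1, 3)
    w = np.asarray(DEFAULT_REDOX_WEIGHTS[:len(pos)]
                   if extra_electron_weights is None
                   else extra_electron_weights, float)
    if len(w) != len(pos):
        raise ValueError("one weight per atom required")
    baseline = np.full(len(pos), 2.0)
    ox, _ = gen_gaussian_density(pos, baseline, 0.8, counts=counts)
    elements = SITE_ELEMENTS if atom_positions is None else ["X"] * len(pos)
    ox.atoms = [CubeAtom(e, 0.0, p) for e, p in zip(elements, pos)]

    extra, _ = gen_gaussian_density(pos, w, sigma, origin=ox.origin,
                                    counts=counts,
                                    spacing=np.diag(ox.axes))
    red = DensityGrid(ox.origin.copy(), ox.axes.copy(),
                      ox.values + extra.values, atoms=list(ox.atoms))
    truth = {"extra_electron_weights": {i: float(x) for i, x in enumerate(w)},
             "total_extra_e": float(w.sum())}
    return ox, red, truth


# ---------------------------------------------------------------------------
# harmonic Hessians

def gen_harmonic_hessian(coords_bohr, bonds, angles=(), labels=None,
                         step: float = 1e-4) -> tuple[HessianMatrix, dict]:
    """Finite-difference Hessian of a harmonic bond/angle toy model.

    ``bonds``: (i, j, k_kJmol_nm2, r0_bohr) under E = k (r - r0)^2;
    ``angles``: (i, j, k, k_kJmol_rad2, theta0_rad) with j the vertex,
    E = k (theta - theta0)^2.  Energies are converted to Hartree so the
    Hessian comes out in Hartree/Bohr^2.  Central differences with the
    given step, then symmetrized.  Returns (HessianMatrix, truth).
    """
    from .units import BOHR_NM, HARTREE_KJMOL
    x0 = np.asarray(coords_bohr, float).reshape(-1, 3)
    n = len(x0)

    def energy(x):
        x = x.reshape(-1, 3)
        e = 0.0
        for i, j, k, r0 in bonds:
            k_au = k / HARTREE_KJMOL * BOHR_NM ** 2   # Hartree/Bohr^2
            r = np.linalg.norm(x[j] - x[i])
            e += k_au * (r - r0) ** 2
        for i, j, k, kang, th0 in angles:
            v1 = x[i] - x[j]
            v2 = x[k] - x[j]
            c = np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                        -1.0, 1.0)
            if abs(c) > 0.999:
                import warnings
                warnings.warn("near-linear angle; Hessian may be unstable")
            th = np.arccos(c)
            e += (kang / HARTREE_KJMOL) * (th - th0) ** 2
        return e

    flat = x0.ravel()
    m = flat.size
    H = np.zeros((m, m))
    for p in range(m):
        for q in range(p, m):
            xpp = flat.copy(); xpp[p] += step; xpp[q] += step
            xpm = flat.copy(); xpm[p] += step; xpm[q] -= step
            xmp = flat.copy(); xmp[p] -= step; xmp[q] += step
            xmm = flat.copy(); xmm[p] -= step; xmm[q] -= step
            H[p, q] = (energy(xpp) - energy(xpm) - energy(xmp) + energy(xmm)) \
                / (4 * step * step)
            H[q, p] = H[p, q]
    H = 0.5 * (H + H.T)
    labels = labels or [f"A{i}" for i in range(n)]
    truth = {"bonds": [{"atoms": [int(i), int(j)], "K_r": float(k),
                        "r0_bohr": float(r0)} for i, j, k, r0 in bonds]}
    return HessianMatrix(matrix=H, coords=x0, labels=labels), truth


# ---------------------------------------------------------------------------
# alignments

def gen_msa(n_seqs: int = 200, length: int = 100, seed: int = 0,
            background=None, planted_pairs=(), n_identity_clusters: int = 0,
            mutation_rate: float = 0.1):
    """MSA with i.i.d. columns except planted covarying column pairs.

    ``planted_pairs``: (i, j, coupling) with coupling in [0, 1]; column j
    copies a fixed random bijection of column i with probability
    ``coupling`` and is drawn from the background otherwise (coupling 1
    is a deterministic mapping, 0 is independence).  With
    ``n_identity_clusters`` > 0 sequences are grouped into star
    phylogeny clusters: each cluster copies a parent sequence with
    per-site mutation probability ``mutation_rate``.  Returns
    (Alignment, truth).
    """
    rng = np.random.default_rng(seed)
    bg = np.full(20, 1 / 20.0) if background is None else \
        np.asarray(background, float) / np.sum(background)
    cols = {i for i, j, _ in planted_pairs} | {j for i, j, _ in planted_pairs}
    if len(cols) != 2 * len(planted_pairs):
        raise ValueError("planted column indices collide")

    if n_identity_clusters > 0:
        parents = rng.choice(20, size=(n_identity_clusters, length), p=bg)
        assign = rng.integers(0, n_identity_clusters, size=n_seqs)
        codes = parents[assign]
        mut = rng.random((n_seqs, length)) < mutation_rate
        codes = np.where(mut, rng.choice(20, size=(n_seqs, length), p=bg),
                         codes)
    else:
        codes = rng.choice(20, size=(n_seqs, length), p=bg)

    mappings = {}
    for i, j, coupling in planted_pairs:
        perm = rng.permutation(20)
        mappings[(i, j)] = perm
        follow = rng.random(n_seqs) < coupling
        codes[follow, j] = perm[codes[follow, i]]
    aln = Alignment(codes=codes.astype(np.int8),
                    ids=[f"seq{k}" for k in range(n_seqs)],
                    ref_id="seq0",
                    ref_numbering=np.arange(1, length + 1))
    truth = {"planted_pairs": [[int(i), int(j), float(c)]
                               for i, j, c in planted_pairs],
             "seed": int(seed)}
    return aln, truth


# ---------------------------------------------------------------------------
# conformer ensembles

def gen_conformers(base_coords_nm, n_basins: int = 3,
                   frames_per_basin: int = 4, basin_scale: float = 0.3,
                   spread: float = 0.01, seed: int = 0):
    """Frames drawn around planted conformational basins, each frame
    hidden behind a random rigid motion (clustering must undo it).

    Basin centres are the base structure plus a random per-atom
    displacement field of scale ``basin_scale`` nm (basin 0 is the base
    itself); frames add isotropic noise of ``spread`` nm.  Returns
    (ConformationSet, truth) with the planted basin label per frame.
    """
    rng = np.random.default_rng(seed)
    base = np.asarray(base_coords_nm, float).reshape(-1, 3)
    n = len(base)
    centres = [base]
    for _ in range(n_basins - 1):
        centres.append(base + rng.normal(0, basin_scale, size=(n, 3)))
    frames, labels = [], []
    for b, centre in enumerate(centres):
        for _ in range(frames_per_basin):
            x = centre + rng.normal(0, spread, size=(n, 3))
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            rot = q * np.sign(np.linalg.det(q))
            x = x @ rot.T + rng.normal(0, 1.0, size=3)
            frames.append(x)
            labels.append(b)
    order = rng.permutation(len(frames))
    conf = ConformationSet(coords=np.stack(frames)[order])
    truth = {"basin_labels": [int(labels[k]) for k in order],
             "n_basins": n_basins}
    return conf, truth


# ---------------------------------------------------------------------------
# decay traces

def gen_decay_traces(panel, n_points: int = 60, t_end: float = 180.0,
                     sigma: float = 0.01, seed: int = 0):
    """Noisy first-order-plus-plateau traces with known parameters.

    ``panel``: iterable of (label, temperature_K, k_per_min, plateau_c).
    A(t) = c + (1 - c) exp(-k t) + N(0, sigma).  Returns (traces, truth).
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_end, n_points)
    traces, truth_rows = [], []
    for label, temp, k, c in panel:
        clean = c + (1 - c) * np.exp(-k * t)
        noisy = clean + rng.normal(0, sigma, size=n_points)
        traces.append(DecayTrace(time_min=t, absorbance=noisy,
                                 temperature_K=float(temp), label=str(label)))
        truth_rows.append({"label": str(label), "temperature_K": float(temp),
                           "k_per_min": float(k), "plateau": float(c)})
    return traces, {"panel": truth_rows, "sigma": sigma, "seed": int(seed)}


def gen_arrhenius_panel(label: str = "WT-reduced",
                        temps=(310.0, 313.0, 315.0, 318.0),
                        k_ref: float = 0.02, alpha: float = 0.25):
    """Arrhenius-like rate ladder: k(T) = k_ref * exp(alpha (T - T0)),
    strictly increasing in temperature (mirrors the loss of reduced-state
    stability from 310 to 318 K).  Returns a panel for gen_decay_traces."""
    t0 = temps[0]
    return [(label, T, k_ref * float(np.exp(alpha * (T - t0))), 0.1)
            for T in temps]


# ---------------------------------------------------------------------------
# mock structure

def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def gen_mock_neet_structure(seed: int = 0, extra_residue_distance=None):
    """A small synthetic scaffold carrying an ideal-geometry 3Cys:1His
    [2Fe-2S] site, a distal loop, and (optionally) one extra residue at a
    controlled distance from the cluster.

    Synthetic stand-in for a NEET-like coordinate file: the cluster core
    and donor distances are planted exactly; the polypeptide frame is
    geometrically plausible but not physically refined.  Returns
    (pdb_text, truth).  Ligands: Cys10, Cys12, Cys16 (2 on Fe_X, 1 on
    Fe_Y) and His19 (N on Fe_Y); Gly fillers 11, 13-15, 17-18; distal
    loop Gly30-36 ~20 A away; contact-plant Gly33 pulled to ~4 A of
    Gly11.  ``extra_residue_distance`` plants Gly25 with its CA exactly
    that many Angstrom from Fe_X.
    """
    fe_x = np.array([0.0, 0.0, 0.0])
    fe_y = np.array([2.7, 0.0, 0.0])
    s1 = np.array([1.35, 1.75, 0.0])
    s2 = np.array([1.35, -1.75, 0.0])
    d_cys = 2.25
    d_his = 2.00
    sg10 = fe_x + d_cys * _unit([-1, 1, 1])
    sg12 = fe_x + d_cys * _unit([-1, -1, -1])
    sg16 = fe_y + d_cys * _unit([1, 1, -1])
    ne2 = fe_y + d_his * _unit([1, -1, 1])

    centre = np.array([1.35, 0.0, 0.0])
    atoms = []   # (name, element, xyz, resname, resid)

    def add(name, el, xyz, resname, resid):
        atoms.append((name, el, np.asarray(xyz, float), resname, resid))

    # cluster as a HETATM residue
    for nm, el, xyz in (("FE1", "FE", fe_x), ("FE2", "FE", fe_y),
                        ("S1", "S", s1), ("S2", "S", s2)):
        add(nm, el, xyz, "FES", 1)

    def backbone(resid, resname, ca, tangent, outward):
        add("N", "N", ca - 1.2 * tangent, resname, resid)
        add("CA", "C", ca, resname, resid)
        add("C", "C", ca + 1.2 * tangent, resname, resid)
        add("O", "O", ca + 1.2 * tangent + 1.2 * outward, resname, resid)

    lig_res = {10: ("CYS", sg10), 12: ("CYS", sg12), 16: ("CYS", sg16),
               19: ("HIS", ne2)}
    step_deg = 24.0
    for k, resid in enumerate(range(10, 20)):
        theta = np.deg2rad(100.0 + step_deg * k)
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        ca = centre + 9.0 * radial
        resname, donor = lig_res.get(resid, ("GLY", None))
        backbone(resid, resname, ca, tangent, radial)
        if donor is None:
            continue
        cb = donor + 1.8 * _unit(ca - donor)
        add("CB", "C", cb, resname, resid)
        if resname == "CYS":
            add("SG", "S", donor, resname, resid)
        else:
            fe_dir = _unit(ne2 - fe_y)
            perp = _unit(np.cross(fe_dir, [0.0, 0.0, 1.0]))
            add("NE2", "N", ne2, resname, resid)
            ce1 = ne2 + 1.35 * _unit(fe_dir + perp)
            cd2 = ne2 + 1.35 * _unit(fe_dir - perp)
            add("CE1", "C", ce1, resname, resid)
            add("CD2", "C", cd2, resname, resid)
            add("ND1", "N", ce1 + 1.35 * fe_dir, resname, resid)
            add("CG", "C", cd2 + 1.50 * fe_dir, resname, resid)

    if extra_residue_distance is not None:
        d = float(extra_residue_distance)
        ca = fe_x + np.array([0.0, 0.0, -d])
        add("CA", "C", ca, "GLY", 25)
        add("N", "N", ca + [0.0, 1.2, -0.6], "GLY", 25)
        add("C", "C", ca + [0.0, -1.2, -0.6], "GLY", 25)
        add("O", "O", ca + [0.0, -2.0, -1.2], "GLY", 25)

    # distal loop ~20 A from the cluster
    ca11 = None
    for name, el, xyz, resname, resid in atoms:
        if resid == 11 and name == "CA":
            ca11 = xyz
    for k, resid in enumerate(range(30, 37)):
        theta = np.deg2rad(60.0 + 11.0 * k)
        radial = np.array([np.cos(theta), np.sin(theta), 0.15])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        ca = centre + 20.0 * _unit(radial)
        if resid == 33:   # contact plant: pulled to 4 A of residue 11's CA
            ca = ca11 + np.array([0.0, 0.0, 4.0])
        backbone(resid, "GLY", ca, tangent, radial)

    lines = []
    for serial, (name, el, xyz, resname, resid) in enumerate(atoms, start=1):
        record = "HETATM" if resname == "FES" else "ATOM  "
        name4 = f" {name:<3s}" if len(name) < 4 else name[:4]
        lines.append(
            f"{record}{serial:5d} {name4} {resname:<3s} A{resid:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {el:>2s}")
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    truth = {
        "ligand_residues": {"CYS": [10, 12, 16], "HIS": [19]},
        "donor_atoms": {"10": "SG", "12": "SG", "16": "SG", "19": "NE2"},
        "coordination_class": "3Cys:1His",
        "bond_lengths_nm": {
            "FeX-S1": float(np.linalg.norm(fe_x - s1)) / 10,
            "FeX-S2": float(np.linalg.norm(fe_x - s2)) / 10,
            "FeY-S1": float(np.linalg.norm(fe_y - s1)) / 10,
            "FeY-S2": float(np.linalg.norm(fe_y - s2)) / 10,
            "FeX-SCys1": d_cys / 10, "FeX-SCys2": d_cys / 10,
            "FeY-SCys3": d_cys / 10, "FeY-NHis": d_his / 10,
        },
        "extra_residue": None if extra_residue_distance is None else
            {"resid": 25, "distance_A": float(extra_residue_distance)},
        "distal_pair_res": [10, 31],
        "contact_pair_res": [11, 33],
    }
    return pdb_text, truth


# ---------------------------------------------------------------------------
# bundle writer

def simulate_all(outdir, seed: int = 0) -> dict:
    """Write one synthetic input bundle for every pipeline stage, plus a
    truth.json sidecar.  Returns the truth record."""
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth: dict = {"seed": int(seed)}

    ox, red, t = gen_redox_pair()
    write_cube(ox, os.path.join(outdir, "ox.cube"))
    write_cube(red, os.path.join(outdir, "red.cube"))
    truth["redox_pair"] = t

    pdb_text, t = gen_mock_neet_structure(seed=seed)
    with open(os.path.join(outdir, "mock.pdb"), "w") as fh:
        fh.write(pdb_text)
    truth["structure"] = t

    # harmonic Fe-S-like 3-atom toy for the Seminario stage: two stretches
    # of Table-1 magnitude plus a weak bend (first-order Seminario regime)
    coords = np.array([[0.0, 0.0, 0.0],
                       [4.25, 0.0, 0.0],
                       [-1.0, 4.1, 0.0]])
    bonds = [(0, 1, 25000.0, 4.25), (0, 2, 18000.0,
                                     float(np.linalg.norm(coords[2])))]
    angles = [(1, 0, 2, 100.0, float(np.arccos(
        _unit(coords[1]) @ _unit(coords[2]))))]
    hess, t = gen_harmonic_hessian(coords, bonds, angles,
                                   labels=["FE", "S1", "S2"])
    write_fchk(hess, os.path.join(outdir, "model.fchk"))
    truth["hessian"] = t

    # ESP probe data from planted charges
    q_true = np.array([0.5, -0.75, -0.75])   # Fe(II)-thiolate-like, net -1
    pts = rng.normal(0, 1, size=(200, 3))
    pts = coords.mean(axis=0) + pts / np.linalg.norm(
        pts, axis=1, keepdims=True) * rng.uniform(8, 14, size=(200, 1))
    r = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=-1)
    V = (1.0 / r) @ q_true
    with open(os.path.join(outdir, "esp.dat"), "w") as fh:
        fh.write("# x_bohr y_bohr z_bohr V_hartree_per_e\n")
        for p, v in zip(pts, V):
            fh.write(f"{p[0]:.8f} {p[1]:.8f} {p[2]:.8f} {v:.10e}\n")
    with open(os.path.join(outdir, "esp_atoms.dat"), "w") as fh:
        fh.write("# element x_bohr y_bohr z_bohr\n")
        for el, p in zip(["FE", "S", "S"], coords):
            fh.write(f"{el} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n")
    truth["esp"] = {"charges": q_true.tolist(),
                    "total_charge": float(q_true.sum())}

    # MSA with one planted fully-coupled pair mapped to the distal residues
    distal = truth["structure"]["distal_pair_res"]
    contact = truth["structure"]["contact_pair_res"]
    first_res = 10
    L = 30
    pairs = [(distal[0] - first_res, distal[1] - first_res, 1.0),
             (contact[0] - first_res, contact[1] - first_res, 1.0)]
    aln, t = gen_msa(n_seqs=150, length=L, seed=seed, planted_pairs=pairs)
    with open(os.path.join(outdir, "msa.fasta"), "w") as fh:
        for sid, row in zip(aln.ids, aln.codes):
            seq = "".join(ALPHABET[c] if c < 20 else "-" for c in row)
            fh.write(f">{sid}\n{seq}\n")
    t["first_residue_number"] = first_res
    truth["msa"] = t

    # conformer trajectory around the mock backbone
    from .sites import load_structure
    import io
    structure = load_structure(io.StringIO(pdb_text), "mock")
    bb = []
    for chain in next(structure.get_models()):
        for res in chain:
            for atom in res:
                if atom.get_name() in ("N", "CA", "C"):
                    bb.append(atom.coord)
    base_nm = np.array(bb, dtype=float) / 10.0
    conf, t = gen_conformers(base_nm, n_basins=3, frames_per_basin=4,
                             seed=seed)
    with open(os.path.join(outdir, "traj.pdb"), "w") as fh:
        for m, frame in enumerate(conf.coords, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            serial = 1
            for k in range(0, len(frame), 3):
                for name, xyz in zip(("N", "CA", "C"), frame[k:k + 3] * 10):
                    fh.write(f"ATOM  {serial:5d}  {name:<3s} GLY A{k // 3 + 1:4d}"
                             f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                             f"  1.00  0.00           {name[0]}\n")
                    serial += 1
            fh.write("ENDMDL\n")
    truth["conformers"] = t

    # decay-trace panel: labile oxidized, Arrhenius reduced, inert H87C
    panel = [("WT-oxidized", 310.0, 0.05, 0.05)]
    panel += gen_arrhenius_panel("WT-reduced")
    panel += [("H87C", T, 0.0, 1.0) for T in (310.0, 313.0, 315.0, 318.0)]
    traces, t = gen_decay_traces(panel, seed=seed)
    with open(os.path.join(outdir, "traces.csv"), "w") as fh:
        fh.write("time_min,A458,temperature_K,label\n")
        for tr in traces:
            for tt, aa in zip(tr.time_min, tr.absorbance):
                fh.write(f"{tt:.4f},{aa:.6f},{tr.temperature_K:.1f},{tr.label}\n")
    truth["kinetics"] = t

    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
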