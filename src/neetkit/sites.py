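"""[2Fe-2S] site detection, QM model truncation, and redox geometry tables.

NEET proteins carry a [2Fe-2S] cluster with an unusual 3Cys:1His
coordination: one iron (Fe_X) is ligated by two cysteine thiolates, the
other (Fe_Y, surface-exposed, the one reduced) by one cysteine and one
histidine nitrogen.  This module detects such sites in a PDB structure,
builds the three standard truncated cluster models used for quantum
chemistry (side chains only / +connecting backbone / +4-Angstrom shell),
measures the eight canonical metal-ligand bonds, and compares
oxidized/reduced bond tables.

Distances are reported in nanometres; PDB coordinates are Angstrom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ClusterSite",
    "TruncatedModel",
    "GeometryTable",
    "load_structure",
    "detect_cluster_sites",
    "build_model",
    "bond_geometry",
    "redox_delta_report",
    "superpose_rmsd",
    "kabsch",
]

FE_DONOR_CUTOFF = 2.6   # Angstrom; covers the longest reported bond (0.246 nm)
FE_FE_CUTOFF = 3.5      # Angstrom; Fe-Fe in a [2Fe-2S] rhombus is ~2.7
MODEL3_SHELL = 4.0      # Angstrom; residue-inclusion shell around the cluster

AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
BACKBONE = {"N", "CA", "C", "O", "OXT"}


def load_structure(path, name: str = "structure"):
    """Parse a PDB file (first model used downstream)."""
    from Bio.PDB import PDBParser
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PDBParser(QUIET=True).get_structure(name, path)


def _first_model(structure):
    if hasattr(structure, "get_models"):
        return next(structure.get_models())
    return structure


def _element(atom) -> str:
    el = (atom.element or "").strip().upper()
    if not el:
        el = atom.get_name().strip()[0].upper()
    return el


@dataclass
class ClusterSite:
    """A detected [2Fe-2S] centre with its protein ligands."""

    fe_x: object            # Bio.PDB Atom: the 2-Cys iron
    fe_y: object            # the His-bound iron (None if class lacks His)
    bridge_s: list          # the two inorganic sulfurs S_1, S_2
    ligands: list           # (residue, donor_atom) pairs
    coordination_class: str
    his_protonation: str = "unknown"

    def donor_atoms_of(self, fe) -> list:
        return [d for (_, d) in self.ligands
                if np.linalg.norm(d.coord - fe.coord) <= FE_DONOR_CUTOFF]

    @property
    def core_atoms(self) -> list:
        core = [self.fe_x] + self.bridge_s
        if self.fe_y is not None:
            core.insert(1, self.fe_y)
        return core


@dataclass
class TruncatedModel:
    """A truncated QM model of a cluster site.

    ``atoms`` are (atom_name, element, coord_A, resname, resid) records for
    atoms taken from the structure; ``caps`` are synthetic terminal atoms
    added at standard geometry (methyl hydrogens for level 1, acetyl/N-methyl
    groups for levels 2 and 3).
    """

    level: int
    atoms: list = field(default_factory=list)
    caps: list = field(default_factory=list)
    net_charge: int = 0
    spin_label: str = ""

    def atom_keys(self) -> set:
        """(resid, atom_name) keys of non-cap atoms — used for nesting checks."""
        return {(a[4], a[0]) for a in self.atoms}

    def to_pdb(self, path, manifest_path=None) -> None:
        with open(path, "w") as fh:
            serial = 1
            for name, el, xyz, resname, resid in self.atoms:
                fh.write(_pdb_line(serial, name, resname, resid, xyz, el))
                serial += 1
            for name, el, xyz, kind in self.caps:
                fh.write(_pdb_line(serial, name, kind, 0, xyz, el, het=True))
                serial += 1
            fh.write("END\n")
        if manifest_path:
            with open(manifest_path, "w") as fh:
                fh.write(f"level\t{self.level}\n")
                fh.write(f"net_charge\t{self.net_charge}\n")
                fh.write(f"spin_label\t{self.spin_label}\n")
                for name, el, xyz, kind in self.caps:
                    fh.write(f"cap\t{kind}\t{name}\n")


def _pdb_line(serial, name, resname, resid, xyz, element, het=False, chain="A"):
    record = "HETATM" if het else "ATOM  "
    name4 = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"{record}{serial:5d} {name4} {resname:<3.3s} {chain}{resid:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
            f"{element:>2.2s}\n")


# ---------------------------------------------------------------------------
# detection

def detect_cluster_sites(structure) -> list[ClusterSite]:
    """Find [2Fe-2S] sites: Fe pairs sharing two inorganic bridging sulfurs.

    Bridging sulfurs are non-protein S atoms within ``FE_DONOR_CUTOFF`` of
    both irons; protein S/N/O atoms within the same cutoff of either iron
    are ligand donors.  Fe_Y is the iron whose donor set contains a His
    nitrogen.  Fe atoms without two shared bridges are logged and skipped.
    """
    model = _first_model(structure)
    fe_atoms, s_inorganic, protein_atoms = [], [], []
    for chain in model:
        for res in chain:
            is_protein = res.get_resname().strip() in AMINO3
            for atom in res:
                el = _element(atom)
                if el == "FE":
                    fe_atoms.append(atom)
                elif el == "S" and not is_protein:
                    s_inorganic.append(atom)
                if is_protein:
                    protein_atoms.append((res, atom))

    sites: list[ClusterSite] = []
    used: set[int] = set()
    for i in range(len(fe_atoms)):
        for j in range(i + 1, len(fe_atoms)):
            a, b = fe_atoms[i], fe_atoms[j]
            if id(a) in used or id(b) in used:
                continue
            if np.linalg.norm(a.coord - b.coord) > FE_FE_CUTOFF:
                continue
            bridges = [s for s in s_inorganic
                       if np.linalg.norm(s.coord - a.coord) <= FE_DONOR_CUTOFF
                       and np.linalg.norm(s.coord - b.coord) <= FE_DONOR_CUTOFF]
            if len(bridges) < 2:
                log.info("Fe pair without 2 shared bridging S — not [2Fe-2S], skipped")
                continue
            bridges = sorted(bridges, key=lambda s: s.get_name())[:2]
            ligands = []
            for res, atom in protein_atoms:
                if _element(atom) not in {"S", "N", "O"}:
                    continue
                if atom.get_name() in BACKBONE:
                    continue
                dmin = min(np.linalg.norm(atom.coord - a.coord),
                           np.linalg.norm(atom.coord - b.coord))
                if dmin <= FE_DONOR_CUTOFF:
                    ligands.append((res, atom))
            fe_x, fe_y = a, b
            his_fe = None
            for res, atom in ligands:
                if res.get_resname() == "HIS" and _element(atom) == "N":
                    d_a = np.linalg.norm(atom.coord - a.coord)
                    d_b = np.linalg.norm(atom.coord - b.coord)
                    his_fe = a if d_a < d_b else b
            if his_fe is not None:
                fe_y = his_fe
                fe_x = b if his_fe is a else a
            n_cys = sum(1 for r, _ in ligands if r.get_resname() == "CYS")
            n_his = sum(1 for r, d in ligands
                        if r.get_resname() == "HIS" and _element(d) == "N")
            if n_cys == 3 and n_his == 1:
                cls = "3Cys:1His"
            elif n_cys == 4:
                cls = "4Cys"
            else:
                cls = f"{n_cys}Cys:{n_his}His"
            sites.append(ClusterSite(
                fe_x=fe_x, fe_y=fe_y if his_fe is not None else None,
                bridge_s=bridges, ligands=ligands, coordination_class=cls))
            used.update({id(a), id(b)})
    return sites


# ---------------------------------------------------------------------------
# truncated QM models

_SIDECHAIN_EXCLUDE = BACKBONE | {"CB"}  # CB handled explicitly (start of side chain)

# formal cluster charge for the 3Cys:1His site with thiolate ligands
FORMAL_CHARGE = {"oxidized": -2, "reduced": -3}


def _residue_atoms(res, names=None):
    out = []
    for atom in res:
        if names is not None and atom.get_name() not in names:
            continue
        out.append((atom.get_name(), _element(atom).capitalize(),
                    np.array(atom.coord, dtype=float),
                    res.get_resname(), res.get_id()[1]))
    return out


def _sidechain_names(res):
    return [a.get_name() for a in res
            if a.get_name() not in BACKBONE and not a.get_name().startswith("H")]


def _cap_h(position, toward, dist=1.09):
    v = toward - position
    n = np.linalg.norm(v)
    if n < 1e-9:
        v, n = np.array([1.0, 0, 0]), 1.0
    return position + v / n * dist


def build_model(site: ClusterSite, structure, level: int,
                state: str = "oxidized") -> TruncatedModel:
    """Build truncation level 1, 2 or 3 of a detected cluster site.

    Level 1: cluster core + ligand side chains from C-beta, each C-beta
    capped to a methyl by an added hydrogen (no backbone atoms at all).
    Level 2: level-1 residues in full, plus backbone N/CA/C/O of residues
    spanning between consecutive ligands of the same chain (their side
    chains replaced by an H at the C-beta position); termini capped
    ACE/NME.  Level 3: cluster core + every residue with any atom within
    4 Angstrom of any core atom, capped ACE/NME.  Added hydrogens use
    standard bond lengths.
    """
    if level not in (1, 2, 3):
        raise ValueError("level must be 1, 2 or 3")
    model = TruncatedModel(level=level,
                           net_charge=FORMAL_CHARGE.get(state, -2),
                           spin_label="antiferromagnetic S=0" if state == "oxidized"
                           else "antiferromagnetic S=1/2")
    # cluster core
    for atom in site.core_atoms:
        model.atoms.append((atom.get_name(), _element(atom).capitalize(),
                            np.array(atom.coord, dtype=float), "FES", 0))

    ligand_residues = sorted({id(r): r for r, _ in site.ligands}.values(),
                             key=lambda r: r.get_id()[1])

    if level == 1:
        for res in ligand_residues:
            names = _sidechain_names(res)
            model.atoms.extend(_residue_atoms(res, names))
            if "CB" in res and "CA" in res:
                h = _cap_h(np.array(res["CB"].coord), np.array(res["CA"].coord))
                model.caps.append(("HCB", "H", h, "CAP"))
        return model

    # levels 2 and 3 share the ACE/NME capping of contiguous segments
    if level == 2:
        chain_res = {}
        for res in ligand_residues:
            chain_res.setdefault(res.get_parent().get_id(), []).append(res)
        included: dict[int, tuple] = {}
        for chain_id, ligs in chain_res.items():
            chain = ligs[0].get_parent()
            by_num = {r.get_id()[1]: r for r in chain if r.get_resname() in AMINO3}
            for res in ligs:
                included[res.get_id()[1]] = (res, "full")
            for a, b in zip(ligs, ligs[1:]):
                lo, hi = a.get_id()[1], b.get_id()[1]
                gaps = [n for n in range(lo + 1, hi) if n not in by_num]
                if gaps:
                    raise ValueError(
                        f"chain break inside level-2 span {lo}-{hi}: "
                        f"missing residues {gaps}")
                for n in range(lo + 1, hi):
                    included.setdefault(n, (by_num[n], "backbone"))
        for num in sorted(included):
            res, kind = included[num]
            if kind == "full":
                model.atoms.extend(_residue_atoms(res))
            else:
                missing = [n for n in ("N", "CA", "C", "O") if n not in res]
                if missing:
                    raise ValueError(
                        f"chain break: residue {num} lacks backbone atoms {missing}")
                model.atoms.extend(_residue_atoms(res, set(BACKBONE)))
                if "CB" in res:  # side chain replaced by H at the C-beta site
                    h = _cap_h(np.array(res["CA"].coord), np.array(res["CB"].coord),
                               dist=1.09)
                    model.caps.append(("HB", "H", h, "CAP"))
        _cap_segments(model, included)
        return model

    # level 3
    core_xyz = np.array([a.coord for a in site.core_atoms], dtype=float)
    struct_model = _first_model(structure)
    included3: dict[int, object] = {}
    for chain in struct_model:
        for res in chain:
            if res.get_resname() not in AMINO3:
                continue
            xyz = np.array([a.coord for a in res], dtype=float)
            d = np.linalg.norm(xyz[:, None, :] - core_xyz[None, :, :], axis=-1)
            if d.min() <= MODEL3_SHELL:
                included3[res.get_id()[1]] = res
    for num in sorted(included3):
        model.atoms.extend(_residue_atoms(included3[num]))
    _cap_segments(model, {n: (r, "full") for n, r in included3.items()})
    return model


def _cap_segments(model: TruncatedModel, included: dict) -> None:
    """Add ACE/NME caps at the termini of each contiguous residue segment."""
    nums = sorted(included)
    for k, num in enumerate(nums):
        res = included[num][0] if isinstance(included[num], tuple) else included[num]
        start = k == 0 or nums[k - 1] != num - 1
        end = k == len(nums) - 1 or nums[k + 1] != num + 1
        if start and "N" in res and "CA" in res:
            n, ca = np.array(res["N"].coord), np.array(res["CA"].coord)
            c_pos = n + (n - ca) / np.linalg.norm(n - ca) * 1.33
            ch3 = c_pos + (c_pos - n) / np.linalg.norm(c_pos - n) * 1.52
            model.caps.append(("C", "C", c_pos, "ACE"))
            model.caps.append(("CH3", "C", ch3, "ACE"))
        if end and "C" in res and "CA" in res:
            c, ca = np.array(res["C"].coord), np.array(res["CA"].coord)
            n_pos = c + (c - ca) / np.linalg.norm(c - ca) * 1.33
            ch3 = n_pos + (n_pos - c) / np.linalg.norm(n_pos - c) * 1.47
            model.caps.append(("N", "N", n_pos, "NME"))
            model.caps.append(("CH3", "C", ch3, "NME"))


# ---------------------------------------------------------------------------
# geometry tables

CANONICAL_BONDS = ["FeX-S1", "FeX-S2", "FeX-SCys1", "FeX-SCys2",
                   "FeY-S1", "FeY-S2", "FeY-SCys3", "FeY-NHis"]


@dataclass
class GeometryTable:
    """Bond table (R in nm, optional K_r in kJ/mol/nm^2) for one redox state."""

    df: pd.DataFrame        # columns: bond, R_nm, optionally K_r
    state: str = ""
    source: str = ""

    def __post_init__(self):
        if self.df["bond"].duplicated().any():
            raise ValueError("duplicate bond labels in geometry table")
        if (self.df["R_nm"] <= 0).any():
            raise ValueError("non-positive bond length")

    @classmethod
    def from_csv(cls, path, state="", source=""):
        return cls(pd.read_csv(path), state=state, source=str(source))

    def to_csv(self, path):
        self.df.to_csv(path, index=False)


def bond_geometry(site: ClusterSite) -> GeometryTable:
    """The eight canonical metal-ligand distances of a 3Cys:1His site, nm.

    Cys donors are numbered by residue number; Cys1/Cys2 ligate Fe_X and
    Cys3 ligates Fe_Y.  Missing donors drop their row with a warning.
    """
    if site.fe_y is None:
        raise ValueError("site lacks a His-bound iron; canonical table undefined")
    fx, fy = np.array(site.fe_x.coord), np.array(site.fe_y.coord)
    s1, s2 = (np.array(s.coord) for s in site.bridge_s)

    cys = sorted([(r, d) for r, d in site.ligands if r.get_resname() == "CYS"],
                 key=lambda rd: rd[0].get_id()[1])
    cys_x, cys_y = [], []
    for r, d in cys:
        if np.linalg.norm(d.coord - fx) <= np.linalg.norm(d.coord - fy):
            cys_x.append((r, d))
        else:
            cys_y.append((r, d))
    his = [(r, d) for r, d in site.ligands
           if r.get_resname() == "HIS" and _element(d) == "N"]

    def nm(a, b):
        return float(np.linalg.norm(a - b)) / 10.0

    rows = [("FeX-S1", nm(fx, s1)), ("FeX-S2", nm(fx, s2)),
            ("FeY-S1", nm(fy, s1)), ("FeY-S2", nm(fy, s2))]
    for k, (r, d) in enumerate(cys_x[:2], start=1):
        rows.append((f"FeX-SCys{k}", nm(fx, np.array(d.coord))))
    if cys_y:
        rows.append(("FeY-SCys3", nm(fy, np.array(cys_y[0][1].coord))))
    if his:
        rows.append(("FeY-NHis", nm(fy, np.array(his[0][1].coord))))
    present = {b for b, _ in rows}
    for b in CANONICAL_BONDS:
        if b not in present:
            warnings.warn(f"donor for bond {b} missing; row omitted")
    order = {b: i for i, b in enumerate(CANONICAL_BONDS)}
    rows.sort(key=lambda r: order.get(r[0], 99))
    return GeometryTable(pd.DataFrame(rows, columns=["bond", "R_nm"]))


def redox_delta_report(ox: GeometryTable, red: GeometryTable) -> pd.DataFrame:
    """Per-bond reduced-minus-oxidized differences and ratios.

    Returns columns: bond, R_ox, R_red, dR_nm, and when force constants are
    present K_ox, K_red, K_ratio plus a ``weakened`` flag
    (bond lengthens and its force constant drops).
    """
    a = ox.df.set_index("bond")
    b = red.df.set_index("bond")
    unmatched = set(a.index) ^ set(b.index)
    if unmatched:
        raise ValueError(f"bond labels do not match: {sorted(unmatched)}")
    out = pd.DataFrame({
        "R_ox": a["R_nm"], "R_red": b.loc[a.index, "R_nm"],
    })
    out["dR_nm"] = out["R_red"] - out["R_ox"]
    if "K_r" in a.columns and "K_r" in b.columns:
        out["K_ox"] = a["K_r"]
        out["K_red"] = b.loc[a.index, "K_r"]
        out["K_ratio"] = out["K_red"] / out["K_ox"]
        out["weakened"] = (out["dR_nm"] > 0) & (out["K_ratio"] < 1)
    return out.reset_index().rename(columns={"index": "bond"})


# ---------------------------------------------------------------------------
# superposition

def kabsch(A: np.ndarray, B: np.ndarray):
    """Optimal rotation R and translation t minimizing ||(B @ R.T + t) - A||.

    Returns (R, t); proper rotation enforced (no reflection).
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - cb @ R.T
    return R, t


def superpose_rmsd(A: np.ndarray, B: np.ndarray,
                   selection=None) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares superposition of B onto A; RMSD in the units of the input.

    ``selection`` restricts the fit (and the RMSD) to the given point
    indices.  Requires at least 3 non-collinear points.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if selection is not None:
        A, B = A[list(selection)], B[list(selection)]
    if A.shape != B.shape:
        raise ValueError("coordinate sets differ in shape")
    if len(A) < 3:
        raise ValueError("need at least 3 points for superposition")
    if np.linalg.matrix_rank(A - A.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("points are collinear; rotation is ill-defined")
    R, t = kabsch(A, B)
    Bfit = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((Bfit - A) ** 2, axis=1))))
    return rmsd, R, t
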