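"""End-to-end orchestration: config validation, stage execution, report
assembly.

The run mirrors the three-pronged design of the underlying study —
electronic-structure charge analysis and force-field parameters,
sequence-based allostery screening against a representative structure,
trajectory clustering, and lability kinetics — over whatever inputs the
config enables.  The summary report only aggregates per-stage output
files; every number in it is traceable to a stage file.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, fields, asdict

import numpy as np

log = logging.getLogger("neetkit.pipeline")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Fully-resolved pipeline configuration.

    Paths may be empty, which disables the corresponding stage; numeric
    thresholds default to the study's stated values (nearest-atom charge
    partition, 0.7 / 30% coevolution thresholds, 0.11 nm clustering
    cutoff, 0.2-total-loss lability rule).
    """

    # stage inputs
    red_cube: str = ""
    ox_cube: str = ""
    structure_pdb: str = ""
    hessian_fchk: str = ""
    esp_dat: str = ""
    esp_atoms_dat: str = ""
    msa_fasta: str = ""
    traj_pdb: str = ""
    traces_csv: str = ""
    # thresholds
    partition_scheme: str = "nearest-atom"
    sphere_radius_bohr: float = 0.0
    model_shell_A: float = 4.0
    score_min: float = 0.7
    top_fraction: float = 0.30
    min_seq_sep: int = 5
    min_distance_A: float = 5.0
    msa_first_residue: int = 1
    cluster_cutoff_nm: float = 0.11
    esp_net_charge: float = 0.0
    esp_restraint: float = 0.0005
    seminario_bonds: str = "0-1,0-2"
    # run control
    seed: int = 0
    outdir: str = "neetkit_out"

    def enabled_stages(self) -> list[str]:
        stages = []
        if self.red_cube and self.ox_cube:
            stages.append("charges")
        if self.hessian_fchk:
            stages.append("seminario")
        if self.esp_dat and self.esp_atoms_dat:
            stages.append("resp")
        if self.msa_fasta and self.structure_pdb:
            stages.append("coevolution")
        if self.traj_pdb:
            stages.append("clustering")
        if self.traces_csv:
            stages.append("kinetics")
        return stages


_FLOAT_KEYS = {f.name for f in fields(RunConfig) if f.type == "float"}
_INT_KEYS = {f.name for f in fields(RunConfig) if f.type == "int"}
_PATH_KEYS = {"red_cube", "ox_cube", "structure_pdb", "hessian_fchk",
              "esp_dat", "esp_atoms_dat", "msa_fasta", "traj_pdb",
              "traces_csv"}


def validate_config(path) -> RunConfig:
    """Parse and validate a plain ``key = value`` config file.

    Unknown keys error (catching typos); referenced input files must
    exist; thresholds must lie in their documented ranges.  Every
    resolved value, default or explicit, is echoed to the log.
    """
    known = {f.name for f in fields(RunConfig)}
    raw: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ConfigError(f"{path}:{ln}: unknown key {key!r}")
            raw[key] = val
    kwargs: dict = {}
    for key, val in raw.items():
        if key in _FLOAT_KEYS:
            kwargs[key] = float(val)
        elif key in _INT_KEYS:
            kwargs[key] = int(val)
        else:
            kwargs[key] = val
    cfg = RunConfig(**kwargs)

    if not 0 < cfg.top_fraction <= 1:
        raise ConfigError(f"top_fraction = {cfg.top_fraction} outside (0, 1]")
    if not 0 <= cfg.score_min <= 1:
        raise ConfigError(f"score_min = {cfg.score_min} outside [0, 1]")
    if cfg.cluster_cutoff_nm <= 0:
        raise ConfigError("cluster_cutoff_nm must be positive")
    if cfg.partition_scheme not in ("nearest-atom", "spheres"):
        raise ConfigError(f"unknown partition_scheme {cfg.partition_scheme!r}")
    missing = [k for k in _PATH_KEYS
               if getattr(cfg, k) and not os.path.exists(getattr(cfg, k))]
    if missing:
        raise ConfigError("missing input files: " + ", ".join(
            f"{k}={getattr(cfg, k)}" for k in missing))
    for f in fields(RunConfig):
        log.info("config %s = %r%s", f.name, getattr(cfg, f.name),
                 "" if f.name in raw else "  (default)")
    return cfg


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        for key, val in asdict(cfg).items():
            fh.write(f"{key} = {val}\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every enabled stage in dependency order.

    Independent branches continue past a failed stage; the return dict
    maps stage name to "ok"/"failed: ..." and a summary report is written
    to ``<outdir>/summary.txt``.  Raises StageError at the end if any
    stage failed.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    status: dict[str, str] = {}
    summary: list[str] = ["neetkit pipeline summary", ""]
    for f in fields(RunConfig):
        summary.append(f"config {f.name} = {getattr(cfg, f.name)}")
    summary.append("")

    def stage(name, fn):
        try:
            lines = fn()
            status[name] = "ok"
            summary.append(f"[{name}] ok")
            summary.extend("  " + s for s in lines)
        except Exception as err:   # pragma: no cover - defensive
            status[name] = f"failed: {err}"
            summary.append(f"[{name}] FAILED: {err}")
            log.error("stage %s failed: %s", name, err)

    enabled = cfg.enabled_stages()

    if "charges" in enabled:
        def _charges():
            from .grid import read_cube, subtract_density, \
                integrate_total, partition_charges
            red = read_cube(cfg.red_cube)
            ox = read_cube(cfg.ox_cube)
            delta = subtract_density(red, ox)
            kwargs = {}
            if cfg.partition_scheme == "spheres":
                kwargs["radius"] = cfg.sphere_radius_bohr
            table = partition_charges(delta, scheme=cfg.partition_scheme,
                                      **kwargs)
            df = table.to_dataframe(delta.atoms)
            out = os.path.join(cfg.outdir, "dq.csv")
            df.to_csv(out, index=False)
            return [f"total dQ = {integrate_total(delta):.6f} e -> {out}"]
        stage("charges", _charges)

    if "seminario" in enabled:
        def _seminario():
            from .params import hessian_from_fchk, seminario_bond_constant
            hess = hessian_from_fchk(cfg.hessian_fchk)
            out = os.path.join(cfg.outdir, "bond_params.csv")
            lines = []
            with open(out, "w") as fh:
                fh.write("atom_i,atom_j,R_min_nm,K_r_kJmol_nm2\n")
                for pair in cfg.seminario_bonds.split(","):
                    i, j = (int(x) for x in pair.split("-"))
                    bp = seminario_bond_constant(hess, i, j)
                    fh.write(f"{i},{j},{bp.R_min:.6f},{bp.K_r:.2f}\n")
                    lines.append(f"bond {i}-{j}: R_min {bp.R_min:.4f} nm, "
                                 f"K_r {bp.K_r:.1f} kJ/mol/nm^2")
            return lines + [f"-> {out}"]
        stage("seminario", _seminario)

    if "resp" in enabled:
        def _resp():
            from .params import ESPGrid, esp_fit_charges
            data = np.loadtxt(cfg.esp_dat)
            elements, pos = [], []
            with open(cfg.esp_atoms_dat) as fh:
                for line in fh:
                    if line.startswith("#") or not line.strip():
                        continue
                    parts = line.split()
                    elements.append(parts[0])
                    pos.append([float(x) for x in parts[1:4]])
            grid = ESPGrid(points=data[:, :3], potentials=data[:, 3],
                           atom_positions=np.array(pos),
                           total_charge=cfg.esp_net_charge,
                           elements=elements)
            q = esp_fit_charges(grid, restraint_strength=cfg.esp_restraint)
            out = os.path.join(cfg.outdir, "resp_charges.csv")
            with open(out, "w") as fh:
                fh.write("atom_index,element,q_e\n")
                for k, (el, qq) in enumerate(zip(elements, q)):
                    fh.write(f"{k},{el},{qq:.8f}\n")
            return [f"fitted {len(q)} charges, sum {q.sum():.6f} e -> {out}"]
        stage("resp", _resp)

    if "coevolution" in enabled:
        def _coevo():
            from .coevolution import (Alignment, coevolution_matrix,
                                      sequence_weights, strong_pairs)
            from .sites import load_structure
            aln = Alignment.from_file(cfg.msa_fasta, "fasta",
                                      ref_start=cfg.msa_first_residue)
            aln.weights = sequence_weights(aln)
            mat = coevolution_matrix(aln)
            np.savetxt(os.path.join(cfg.outdir, "coevolution_matrix.txt"),
                       mat.scores, fmt="%.6f")
            structure = load_structure(cfg.structure_pdb)
            report = strong_pairs(mat, structure, aln.ref_numbering,
                                  score_min=cfg.score_min,
                                  top_fraction=cfg.top_fraction,
                                  min_seq_sep=cfg.min_seq_sep,
                                  min_distance_A=cfg.min_distance_A)
            out = os.path.join(cfg.outdir, "strong_pairs.tsv")
            report.to_tsv(out)
            return [f"{len(report.pairs)} strong distal pairs -> {out}"]
        stage("coevolution", _coevo)

    if "clustering" in enabled:
        def _cluster():
            from .cluster import (gromos_cluster, pairwise_rmsd,
                                  read_multimodel_pdb, representatives)
            conf = read_multimodel_pdb(cfg.traj_pdb)
            D = pairwise_rmsd(conf)
            result = gromos_cluster(D, cfg.cluster_cutoff_nm)
            reps = representatives(result, conf)
            out = os.path.join(cfg.outdir, "clusters.tsv")
            with open(out, "w") as fh:
                fh.write("frame\tcluster\tis_representative\n")
                for c, members in enumerate(result.clusters):
                    for f_ in members:
                        fh.write(f"{f_}\t{c}\t"
                                 f"{int(f_ == result.representatives_idx[c])}\n")
            return [f"{len(result.clusters)} clusters "
                    f"(cutoff {cfg.cluster_cutoff_nm} nm), "
                    f"top occupancy {reps[0]['occupancy']:.2f} -> {out}"]
        stage("clustering", _cluster)

    if "kinetics" in enabled:
        def _kinetics():
            from .kinetics import read_traces_csv, temperature_panel
            traces = read_traces_csv(cfg.traces_csv)
            panel = temperature_panel(traces)
            out = os.path.join(cfg.outdir, "lability.tsv")
            with open(out, "w") as fh:
                fh.write("# first-order-plus-plateau fit; 'labile' rule: "
                         "exponential wins AICc and total loss >= 0.2 "
                         "(toolkit operationalization)\n")
                panel["table"].to_csv(fh, sep="\t", index=False)
            lines = [f"{len(traces)} traces -> {out}"]
            for label, mono in panel["monotone_rate_in_T"].items():
                lines.append(f"monotone k(T) [{label}]: {mono}")
            return lines
        stage("kinetics", _kinetics)

    write_config(cfg, os.path.join(cfg.outdir, "resolved_config.txt"))
    with open(os.path.join(cfg.outdir, "summary.txt"), "w") as fh:
        fh.write("\n".join(summary) + "\n")
    failed = [k for k, v in status.items() if v != "ok"]
    if failed:
        raise StageError(f"stages failed: {failed}")
    return status
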