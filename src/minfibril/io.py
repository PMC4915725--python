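"""File formats: LAMMPS-dialect particle data files, trajectory dumps
(LAMMPS dump and XYZ), tabular results, and run configuration.

The data file uses the ``molecular`` atom style (id mol type x y z) with
Masses, Bond Coeffs, Angle Coeffs and PairIJ Coeffs sections carrying the
published parameter set.  Model bookkeeping that the dialect cannot express
(molecule registry, gap slabs, broken-bond flags, crosslink kinds,
mineralization record) is stored in a trailing ``# minfibril-meta`` comment
block holding one JSON document, so read(write(m)) reproduces the model
field-for-field, rupture history included.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import yaml

from .model import (
    FibrilModel,
    MoleculeInfo,
    PairTable,
    SimulationBox,
)

META_TAG = "# minfibril-meta: "


class ParseError(ValueError):
    """Malformed data file; carries the offending line number."""

    def __init__(self, path, lineno: int, msg: str):
        super().__init__(f"{path}:{lineno}: {msg}")
        self.lineno = lineno


# --------------------------------------------------------------------------
# particle-system data file
# --------------------------------------------------------------------------


def write_particle_system(model: FibrilModel, path) -> None:
    """Write the model as a LAMMPS data file (bonds + angles dialect)."""
    path = Path(path)
    n = model.n_beads
    # bond types: one per distinct parameter row + kind
    bond_keys: list[tuple] = []
    bond_type = np.zeros(len(model.bond_ij), int)
    for m in range(len(model.bond_ij)):
        key = (int(model.bond_kind[m]), *np.round(model.bond_params[m], 8))
        if key not in bond_keys:
            bond_keys.append(key)
        bond_type[m] = bond_keys.index(key) + 1
    angle_keys: list[tuple] = []
    angle_type = np.zeros(len(model.angle_ijk), int)
    for m in range(len(model.angle_ijk)):
        key = (round(float(model.angle_phi0[m]), 6), round(float(model.angle_k[m]), 8))
        if key not in angle_keys:
            angle_keys.append(key)
        angle_type[m] = angle_keys.index(key) + 1

    L = model.box.lengths
    lines = ["minfibril mesoscale mineralized collagen fibril", ""]
    lines.append(f"{n} atoms")
    lines.append(f"{len(model.bond_ij)} bonds")
    lines.append(f"{len(model.angle_ijk)} angles")
    lines.append("")
    lines.append("2 atom types")
    lines.append(f"{max(1, len(bond_keys))} bond types")
    lines.append(f"{max(1, len(angle_keys))} angle types")
    lines.append("")
    lines.append(f"0.0 {L[0]:.10g} xlo xhi")
    lines.append(f"0.0 {L[1]:.10g} ylo yhi")
    lines.append(f"0.0 {L[2]:.10g} zlo zhi")
    lines.append("")
    lines.append("Masses")
    lines.append("")
    lines.append(f"1 {model.mass_collagen:.10g}")
    lines.append(f"2 {model.mass_mineral:.10g}")
    lines.append("")
    if bond_keys:
        lines.append("Bond Coeffs  # kind r0 r1 rbreak kT0 kT1")
        lines.append("")
        for t, key in enumerate(bond_keys, 1):
            kind, r0, r1, rb, k0, k1 = key
            lines.append(f"{t} {kind} {r0:.10g} {r1:.10g} {rb:.10g} {k0:.10g} {k1:.10g}")
        lines.append("")
    if angle_keys:
        lines.append("Angle Coeffs  # kB phi0")
        lines.append("")
        for t, (phi0, kB) in enumerate(angle_keys, 1):
            lines.append(f"{t} {kB:.10g} {phi0:.10g}")
        lines.append("")
    pt = model.pair_table
    lines.append("PairIJ Coeffs  # epsilon sigma cutoff")
    lines.append("")
    for i in range(2):
        for j in range(i, 2):
            lines.append(
                f"{i + 1} {j + 1} {pt.epsilon[i, j]:.10g} "
                f"{pt.sigma[i, j]:.10g} {pt.cutoff[i, j]:.10g}"
            )
    lines.append("")
    lines.append("Atoms  # molecular")
    lines.append("")
    for i in range(n):
        p = model.positions[i]
        lines.append(
            f"{i + 1} {int(model.molecule_id[i]) + 1} {int(model.species[i]) + 1} "
            f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}"
        )
    lines.append("")
    lines.append("Velocities")
    lines.append("")
    for i in range(n):
        v = model.velocities[i]
        lines.append(f"{i + 1} {v[0]:.10g} {v[1]:.10g} {v[2]:.10g}")
    lines.append("")
    if len(model.bond_ij):
        lines.append("Bonds")
        lines.append("")
        for m in range(len(model.bond_ij)):
            lines.append(
                f"{m + 1} {bond_type[m]} {model.bond_ij[m, 0] + 1} "
                f"{model.bond_ij[m, 1] + 1}"
            )
        lines.append("")
    if len(model.angle_ijk):
        lines.append("Angles")
        lines.append("")
        for m in range(len(model.angle_ijk)):
            a = model.angle_ijk[m]
            lines.append(f"{m + 1} {angle_type[m]} {a[0] + 1} {a[1] + 1} {a[2] + 1}")
        lines.append("")

    meta = {
        "axial_index": model.axial_index.tolist(),
        "molecules": [
            dict(
                start=mo.start,
                n_beads=mo.n_beads,
                stagger_class=mo.stagger_class,
                x_start=mo.x_start,
                x_end=mo.x_end,
            )
            for mo in model.molecules
        ],
        "terminal_planes": model.terminal_planes.tolist(),
        "gap_slabs": model.gap_slabs.tolist(),
        "D_period": model.D_period,
        "periods": model.periods,
        "diameter": model.diameter,
        "mineral_wt": model.mineral_wt,
        "mass_collagen": model.mass_collagen,
        "mass_mineral": model.mass_mineral,
        "gap_count": model.gap_count,
        "overlap_count": model.overlap_count,
        "L_ref": model.box.L_ref,
        "periodic": model.box.periodic.tolist(),
        "broken_bonds": np.flatnonzero(model.bond_broken).tolist(),
        "pair_shift": bool(pt.shift),
    }
    lines.append(META_TAG + json.dumps(meta))
    lines.append("")
    path.write_text("\n".join(lines))


def read_particle_system(path) -> FibrilModel:
    """Read a data file written by :func:`write_particle_system`."""
    path = Path(path)
    raw = path.read_text().splitlines()
    meta = None
    for ln in raw:
        if ln.startswith(META_TAG):
            meta = json.loads(ln[len(META_TAG):])
    counts = {}
    types = {}
    box = np.zeros(3)
    i = 1  # skip title line

    def err(lineno, msg):
        raise ParseError(path, lineno + 1, msg)

    # header
    while i < len(raw):
        ln = raw[i].split("#")[0].strip()
        if not ln:
            i += 1
            continue
        parts = ln.split()
        if len(parts) >= 2 and parts[1] in ("atoms", "bonds", "angles"):
            counts[parts[1]] = int(parts[0])
        elif len(parts) >= 3 and parts[1] == "atom" and parts[2] == "types":
            types["atom"] = int(parts[0])
        elif len(parts) >= 3 and parts[2] == "types":
            types[parts[1]] = int(parts[0])
        elif len(parts) == 4 and parts[2] == "xlo":
            box[0] = float(parts[1]) - float(parts[0])
        elif len(parts) == 4 and parts[2] == "ylo":
            box[1] = float(parts[1]) - float(parts[0])
        elif len(parts) == 4 and parts[2] == "zlo":
            box[2] = float(parts[1]) - float(parts[0])
        else:
            break
        i += 1
    if "atoms" not in counts:
        err(i, "missing atom count in header")
    n = counts["atoms"]
    nb = counts.get("bonds", 0)
    na = counts.get("angles", 0)

    masses = {}
    bond_coeffs = {}
    angle_coeffs = {}
    pair_coeffs = {}
    positions = np.zeros((n, 3))
    velocities = np.zeros((n, 3))
    species = np.zeros(n, np.int8)
    molecule_id = np.full(n, -1, np.int32)
    bond_ij = np.zeros((nb, 2), np.int32)
    bond_tp = np.zeros(nb, int)
    angle_ijk = np.zeros((na, 3), np.int32)
    angle_tp = np.zeros(na, int)
    seen = set()

    while i < len(raw):
        header = raw[i].split("#")[0].strip()
        if not header:
            i += 1
            continue
        section = raw[i].split("#")[0].strip()
        i += 1
        rows_expected = {
            "Masses": types.get("atom", 2),
            "Bond Coeffs": types.get("bond", 0),
            "Angle Coeffs": types.get("angle", 0),
            "PairIJ Coeffs": 3,
            "Atoms": n,
            "Velocities": n,
            "Bonds": nb,
            "Angles": na,
        }
        if section not in rows_expected:
            err(i - 1, f"unknown section {section!r}")
        seen.add(section)
        got = 0
        while i < len(raw) and got < rows_expected[section]:
            ln = raw[i].split("#")[0].strip()
            if not ln:
                i += 1
                continue
            parts = ln.split()
            try:
                if section == "Masses":
                    masses[int(parts[0])] = float(parts[1])
                elif section == "Bond Coeffs":
                    bond_coeffs[int(parts[0])] = [float(x) for x in parts[1:7]]
                elif section == "Angle Coeffs":
                    angle_coeffs[int(parts[0])] = [float(x) for x in parts[1:3]]
                elif section == "PairIJ Coeffs":
                    pair_coeffs[(int(parts[0]), int(parts[1]))] = [
                        float(x) for x in parts[2:5]
                    ]
                elif section == "Atoms":
                    a = int(parts[0]) - 1
                    molecule_id[a] = int(parts[1]) - 1
                    species[a] = int(parts[2]) - 1
                    positions[a] = [float(parts[3]), float(parts[4]), float(parts[5])]
                elif section == "Velocities":
                    a = int(parts[0]) - 1
                    velocities[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
                elif section == "Bonds":
                    b = int(parts[0]) - 1
                    bond_tp[b] = int(parts[1])
                    bond_ij[b] = [int(parts[2]) - 1, int(parts[3]) - 1]
                elif section == "Angles":
                    b = int(parts[0]) - 1
                    angle_tp[b] = int(parts[1])
                    angle_ijk[b] = [
                        int(parts[2]) - 1,
                        int(parts[3]) - 1,
                        int(parts[4]) - 1,
                    ]
            except (ValueError, IndexError):
                err(i, f"malformed {section} row")
            got += 1
            i += 1
    required = {"Masses", "Atoms"}
    if nb:
        required |= {"Bonds", "Bond Coeffs"}
    if na:
        required |= {"Angles", "Angle Coeffs"}
    missing = required - seen
    if missing:
        err(len(raw) - 1, f"missing section(s): {', '.join(sorted(missing))}")

    bond_params = np.zeros((nb, 5))
    bond_kind = np.zeros(nb, np.int8)
    for b in range(nb):
        c = bond_coeffs[bond_tp[b]]
        bond_kind[b] = int(c[0])
        bond_params[b] = c[1:6]
    angle_phi0 = np.zeros(na)
    angle_k = np.zeros(na)
    for b in range(na):
        kB, phi0 = angle_coeffs[angle_tp[b]]
        angle_phi0[b] = phi0
        angle_k[b] = kB

    pt = PairTable()
    for (ti, tj), (eps, sig, rc) in pair_coeffs.items():
        pt.epsilon[ti - 1, tj - 1] = pt.epsilon[tj - 1, ti - 1] = eps
        pt.sigma[ti - 1, tj - 1] = pt.sigma[tj - 1, ti - 1] = sig
        pt.cutoff[ti - 1, tj - 1] = pt.cutoff[tj - 1, ti - 1] = rc

    mdl = FibrilModel(
        positions=positions,
        velocities=velocities,
        species=species,
        molecule_id=molecule_id,
        axial_index=np.full(n, -1, np.int32),
        bond_ij=bond_ij,
        bond_params=bond_params,
        bond_kind=bond_kind,
        bond_broken=np.zeros(nb, bool),
        angle_ijk=angle_ijk,
        angle_phi0=angle_phi0,
        angle_k=angle_k,
        pair_table=pt,
        box=SimulationBox(lengths=box),
        mass_collagen=masses.get(1, 1324.0),
        mass_mineral=masses.get(2, 1548.0),
    )
    if meta is not None:
        mdl.axial_index = np.asarray(meta["axial_index"], np.int32)
        mdl.molecules = [MoleculeInfo(**mo) for mo in meta["molecules"]]
        mdl.terminal_planes = np.asarray(meta["terminal_planes"])
        mdl.gap_slabs = np.asarray(meta["gap_slabs"]).reshape(-1, 2)
        mdl.D_period = meta["D_period"]
        mdl.periods = meta["periods"]
        mdl.diameter = meta["diameter"]
        mdl.mineral_wt = meta["mineral_wt"]
        mdl.mass_collagen = meta["mass_collagen"]
        mdl.mass_mineral = meta["mass_mineral"]
        mdl.gap_count = meta["gap_count"]
        mdl.overlap_count = meta["overlap_count"]
        mdl.box.L_ref = meta["L_ref"]
        mdl.box.periodic = np.asarray(meta["periodic"], bool)
        broken = np.asarray(meta["broken_bonds"], int)
        if len(broken):
            mdl.bond_broken[broken] = True
        mdl.pair_table.shift = bool(meta.get("pair_shift", False))
    else:
        # best effort without metadata: molecule registry from contiguity
        mdl.box.L_ref = box[0]
    return mdl


# --------------------------------------------------------------------------
# trajectory output
# --------------------------------------------------------------------------


def write_dump(frames: Iterable, path, model: FibrilModel | None = None,
               strain_field: bool = False) -> int:
    """LAMMPS-style dump of trajectory frames with stored positions.

    Returns the number of frames written.  Frames without positions are
    skipped.  With ``strain_field`` (and a model) a per-bead bond-strain
    column is appended for visualization.
    """
    from .observables import per_bead_strain

    path = Path(path)
    nwritten = 0
    cols = "id mol type x y z" + (" c_strain" if strain_field else "")
    with open(path, "w") as fh:
        for fr in frames:
            if fr.positions is None:
                continue
            n = len(fr.positions)
            fh.write("ITEM: TIMESTEP\n%d\n" % fr.step)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % n)
            fh.write("ITEM: BOX BOUNDS pp ff ff\n")
            for d in range(3):
                fh.write("0.0 %.10g\n" % fr.box_lengths[d])
            fh.write(f"ITEM: ATOMS {cols}\n")
            strains = None
            if strain_field and model is not None:
                tmp = model.copy()
                tmp.positions = fr.positions
                if fr.bond_broken is not None:
                    tmp.bond_broken = fr.bond_broken
                strains = per_bead_strain(tmp)
            for i in range(n):
                x, y, z = fr.positions[i]
                mol = int(model.molecule_id[i]) + 1 if model is not None else 0
                sp = int(model.species[i]) + 1 if model is not None else 1
                row = f"{i + 1} {mol} {sp} {x:.6g} {y:.6g} {z:.6g}"
                if strain_field:
                    row += " %.6g" % (strains[i] if strains is not None else 0.0)
                fh.write(row + "\n")
            nwritten += 1
    return nwritten


def write_xyz(frames: Iterable, path, model: FibrilModel | None = None) -> int:
    """Minimal XYZ trajectory (element C for collagen, P for mineral)."""
    path = Path(path)
    nwritten = 0
    with open(path, "w") as fh:
        for fr in frames:
            if fr.positions is None:
                continue
            n = len(fr.positions)
            fh.write(f"{n}\n")
            fh.write(f"step={fr.step} strain={fr.strain:.6g}\n")
            for i in range(n):
                sp = "P" if model is not None and model.species[i] else "C"
                x, y, z = fr.positions[i]
                fh.write(f"{sp} {x:.6g} {y:.6g} {z:.6g}\n")
            nwritten += 1
    return nwritten


def frames_to_table(trajectory) -> "pandas.DataFrame":
    """Per-frame observables as a DataFrame keyed by step/strain."""
    import pandas as pd

    rows = [
        dict(
            step=fr.step,
            time_fs=fr.time,
            strain=fr.strain,
            stress_GPa=fr.stress_axial,
            temperature_K=fr.temperature,
            energy_total=fr.energy_total,
            broken_bonds=fr.broken_bonds,
        )
        for fr in trajectory.frames
    ]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Serializable run configuration (geometry, mineral, crosslinks, engine)."""

    geometry: dict = field(default_factory=dict)
    mineralization: dict = field(default_factory=dict)
    crosslink: Optional[dict] = None
    engine: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def build_specs(self):
        from .geometry import CrosslinkSpec, GeometrySpec, MineralizationSpec
        from .model import EngineConfig

        g = GeometrySpec(**self.geometry)
        m = MineralizationSpec(**self.mineralization)
        c = CrosslinkSpec(**self.crosslink) if self.crosslink is not None else None
        e = EngineConfig(seed=self.seed, **self.engine)
        return g, m, c, e
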