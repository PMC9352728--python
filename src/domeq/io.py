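"""Readers and writers for the plain-text formats of the pipeline.

* DEER traces: two whitespace-separated columns (time_us, amplitude)
  with ``#`` comments; an optional third column carries the per-point
  noise estimate. The reader normalizes the maximum to 1 and records
  the scale factor on the returned trace.
* Distance distributions: two columns (r_A, density_per_A).
* Relaxation-rate tables: CSV with header residue,R2_para,R2_dia[,R1,R2].
* Distance restraints: upper-limit (.upl) and lower-limit (.lol) rows
  "resnum resname atom resnum resname atom distance weight"; the parser
  round-trips the writer's output exactly.
* Ensembles: multi-model PDB (MODEL/ENDMDL) with state labels and
  populations in REMARK 400 records.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .forward import DeerTrace, DistanceDistribution, DistanceGrid
from .restraints import Conformer, DistanceRestraint, TwoStateEnsemble

__all__ = [
    "write_deer_ascii",
    "read_deer_ascii",
    "write_distribution",
    "read_distribution",
    "read_rates_csv",
    "write_rates_csv",
    "write_restraints",
    "read_restraints",
    "write_ensemble_pdb",
    "read_ensemble_pdb",
]


def write_deer_ascii(path: "str | Path", trace: DeerTrace) -> None:
    header = "DEER trace: time_us amplitude" + (
        " noise_sigma" if trace.noise_sigma else "")
    cols = [trace.time, trace.signal]
    if trace.noise_sigma:
        cols.append(np.full_like(trace.time, trace.noise_sigma))
    np.savetxt(path, np.column_stack(cols), fmt="%.6f", header=header)


def read_deer_ascii(path: "str | Path") -> DeerTrace:
    """Read a two- or three-column DEER trace; amplitude is rescaled so
    its maximum is 1 and the applied factor is stored as ``trace.scale``."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    time, signal = data[:, 0], data[:, 1]
    noise = float(data[0, 2]) if data.shape[1] > 2 else 0.0
    scale = float(np.max(signal))
    if scale <= 0:
        raise ValueError(f"{path}: nonpositive amplitudes")
    return DeerTrace(time, signal / scale, noise_sigma=noise / scale, scale=scale)


def write_distribution(path: "str | Path", dist: DistanceDistribution) -> None:
    np.savetxt(path, np.column_stack([dist.grid.r, dist.density]),
               fmt="%.6f", header="r_A density_per_A")


def read_distribution(path: "str | Path") -> DistanceDistribution:
    data = np.loadtxt(path, comments="#")
    r, dens = data[:, 0], data[:, 1]
    steps = np.diff(r)
    if not np.allclose(steps, steps[0], atol=1e-6):
        raise ValueError(f"{path}: distance grid must be uniform")
    grid = DistanceGrid(float(r[0]), float(r[-1]), len(r))
    return DistanceDistribution(grid, np.clip(dens, 0.0, None)).normalized()


def read_rates_csv(path: "str | Path") -> pd.DataFrame:
    table = pd.read_csv(path)
    if not {"residue", "R2_para", "R2_dia"}.issubset(table.columns):
        raise ValueError(f"{path}: need columns residue,R2_para,R2_dia[,R1,R2]")
    return table


def write_rates_csv(path: "str | Path", table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


_RESTRAINT_FMT = "{:4d} {:<4s} {:<4s} {:4d} {:<4s} {:<4s} {:8.2f} {:8.3f}\n"


def _restraint_rows(restraints: list[DistanceRestraint], which: str) -> str:
    buf = _io.StringIO()
    for r in restraints:
        value = r.upper if which == "upper" else r.lower
        buf.write(_RESTRAINT_FMT.format(
            r.atom_a[0], r.res_name_a, r.atom_a[1],
            r.atom_b[0], r.res_name_b, r.atom_b[1],
            value, r.weight,
        ))
    return buf.getvalue()


def write_restraints(restraints: list[DistanceRestraint],
                     upl_path: "str | Path",
                     lol_path: "str | Path | None" = None) -> None:
    """Write upper limits (.upl) and optionally lower limits (.lol)."""
    Path(upl_path).write_text(_restraint_rows(restraints, "upper"))
    if lol_path is not None:
        Path(lol_path).write_text(_restraint_rows(restraints, "lower"))


def read_restraints(upl_path: "str | Path",
                    lol_path: "str | Path | None" = None,
                    kind: str = "NOE") -> list[DistanceRestraint]:
    """Parse .upl (and optional matching .lol) rows into restraints.

    Without a .lol file the lower limit defaults to 1 A. The restraint
    kind is not part of the file format and must be supplied.
    """

    def _parse(path: "str | Path") -> list[tuple]:
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 7:
                raise ValueError(f"{path}: malformed restraint row {line!r}")
            rows.append((int(f[0]), f[1], f[2], int(f[3]), f[4], f[5],
                         float(f[6]), float(f[7]) if len(f) > 7 else None))
        return rows

    upper_rows = _parse(upl_path)
    lower_rows = _parse(lol_path) if lol_path is not None else None
    if lower_rows is not None and len(lower_rows) != len(upper_rows):
        raise ValueError("upper- and lower-limit files differ in length")
    out = []
    for i, row in enumerate(upper_rows):
        resi_a, name_a, atom_a, resi_b, name_b, atom_b, upper, weight = row
        lower = lower_rows[i][6] if lower_rows is not None else 1.0
        out.append(DistanceRestraint(
            atom_a=(resi_a, atom_a), atom_b=(resi_b, atom_b), kind=kind,
            lower=lower, upper=upper, weight=weight,
            res_name_a=name_a, res_name_b=name_b,
        ))
    return out


def _conformer_to_model(conf: Conformer, serial: int) -> gemmi.Model:
    model = gemmi.Model(str(serial))
    chain_a = gemmi.Chain("A")
    chain_b = gemmi.Chain("B")
    for resi in sorted({r for r, _ in conf.coords}):
        res = gemmi.Residue()
        res.name = conf.res_name(resi)
        res.seqid = gemmi.SeqId(resi, " ")
        for atom_name in ("CA", "CB"):
            key = (resi, atom_name)
            if key not in conf.coords:
                continue
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element("C")
            x, y, z = conf.coords[key]
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            res.add_atom(atom)
        (chain_a if resi < 50 else chain_b).add_residue(res)
    model.add_chain(chain_a)
    model.add_chain(chain_b)
    return model


def write_ensemble_pdb(path: "str | Path", ensemble: TwoStateEnsemble) -> None:
    """Write a two-state ensemble as a multi-model PDB with REMARK 400
    records carrying the state label of each model and the populations."""
    st = gemmi.Structure()
    st.name = "two-state ensemble"
    remarks = []
    for s, pop in zip(ensemble.states, ensemble.populations):
        remarks.append(f"REMARK 400 STATE {s} POPULATION {pop:.4f}")
    for i, (conf, label) in enumerate(zip(ensemble.conformers, ensemble.state_labels), 1):
        remarks.append(f"REMARK 400 MODEL {i} STATE {label}")
        st.add_model(_conformer_to_model(conf, i))
    st.raw_remarks = remarks
    st.setup_entities()
    st.write_pdb(str(path))


def read_ensemble_pdb(path: "str | Path") -> TwoStateEnsemble:
    st = gemmi.read_structure(str(path))
    populations: dict[int, float] = {}
    model_states: dict[int, int] = {}
    for line in st.raw_remarks:
        fields = line.split()
        if len(fields) >= 6 and fields[2] == "STATE" and fields[4] == "POPULATION":
            populations[int(fields[3])] = float(fields[5])
        elif len(fields) >= 6 and fields[2] == "MODEL" and fields[4] == "STATE":
            model_states[int(fields[3])] = int(fields[5])
    conformers, labels = [], []
    for i, model in enumerate(st, 1):
        coords: dict[tuple[int, str], np.ndarray] = {}
        names: dict[int, str] = {}
        for chain in model:
            for res in chain:
                for atom in res:
                    coords[(res.seqid.num, atom.name)] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z])
                names[res.seqid.num] = res.name
        conformers.append(Conformer(coords, names))
        labels.append(model_states.get(i, 1))
    states = sorted(set(labels))
    pops = np.array([populations.get(s, 1.0 / len(states)) for s in states])
    pops = pops / pops.sum()
    return TwoStateEnsemble(conformers, labels, pops)
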