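"""Trajectory and topology I/O.

Two trajectory carriers are supported:

* a plain-text frames format (``.traj``), self-contained and
  byte-stable under a read/write round trip;
* standard binary formats (XTC/DCD...) read through MDAnalysis, with
  bead identities supplied by a bead-table CSV.

Text format
-----------
::

    # lipidfp-traj 1
    # dt <ps> replicate <id>
    # nbeads <n>
    # bead <index> <kind> <mol_id> <species> <label> <is_head>
    ...
    t <ps> box <Lx> <Ly> <Lz>
    <index> <x> <y> <z>
    ...

Coordinates are written with shortest round-trip ``repr`` so that
reading a file and writing it again reproduces it byte for byte.
"""

from __future__ import annotations

import warnings
from pathlib import Path
import numpy as np
import pandas as pd

from .core import BeadTable, Frame, ProteinModel, Trajectory

__all__ = [
    "write_text_trajectory",
    "read_text_trajectory",
    "read_mdanalysis_trajectory",
    "read_trajectory",
    "write_bead_table",
    "read_bead_table",
    "write_pdb",
    "write_sidecar",
]

_FORMAT_TAG = "# lipidfp-traj 1"


def _fmt(x: float) -> str:
    return repr(float(x))


def write_text_trajectory(traj: Trajectory, path: str | Path) -> None:
    bt = traj.bead_table
    lines = [
        _FORMAT_TAG,
        f"# dt {_fmt(traj.dt)} replicate {traj.replicate_id}",
        f"# nbeads {traj.n_beads}",
    ]
    for i in range(traj.n_beads):
        lines.append(
            f"# bead {i} {bt.kind[i]} {bt.mol_id[i]} {bt.species[i]} "
            f"{bt.label[i]} {int(bt.is_head[i])}"
        )
    for f in traj.frames:
        lines.append(
            f"t {_fmt(f.time)} box {_fmt(f.box[0])} {_fmt(f.box[1])} {_fmt(f.box[2])}"
        )
        for i, (x, y, z) in enumerate(np.asarray(f.coords, dtype=float)):
            lines.append(f"{i} {_fmt(x)} {_fmt(y)} {_fmt(z)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_text_trajectory(path: str | Path) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _FORMAT_TAG:
        raise ValueError(f"{path}: not a lipidfp text trajectory")
    _, _, dt_s, _, replicate = lines[1].split()
    dt = float(dt_s)
    nbeads = int(lines[2].split()[-1])
    kind, mol_id, species, label, is_head = [], [], [], [], []
    cursor = 3
    for _ in range(nbeads):
        parts = lines[cursor].split()
        # "# bead i kind mol species label head"
        kind.append(parts[3])
        mol_id.append(int(parts[4]))
        species.append(parts[5])
        label.append(parts[6])
        is_head.append(bool(int(parts[7])))
        cursor += 1
    bt = BeadTable(
        np.array(kind, dtype=object), np.array(mol_id),
        np.array(species, dtype=object), np.array(label, dtype=object),
        np.array(is_head),
    )
    frames: list[Frame] = []
    while cursor < len(lines):
        parts = lines[cursor].split()
        if parts[0] != "t":
            raise ValueError(f"{path}: expected frame header at line {cursor + 1}")
        time = float(parts[1])
        box = np.array([float(parts[3]), float(parts[4]), float(parts[5])])
        cursor += 1
        coords = np.empty((nbeads, 3))
        for i in range(nbeads):
            p = lines[cursor].split()
            coords[int(p[0])] = (float(p[1]), float(p[2]), float(p[3]))
            cursor += 1
        frames.append(Frame(time=time, box=box, coords=coords))
    return Trajectory(frames, dt=dt, bead_table=bt, replicate_id=replicate)


def write_bead_table(bt: BeadTable, path: str | Path) -> None:
    pd.DataFrame(
        dict(kind=bt.kind, mol_id=bt.mol_id, species=bt.species,
             label=bt.label, is_head=bt.is_head.astype(int))
    ).to_csv(path, index=False)


def read_bead_table(path: str | Path) -> BeadTable:
    df = pd.read_csv(path)
    return BeadTable(
        df["kind"].to_numpy(dtype=object),
        df["mol_id"].to_numpy(dtype=int),
        df["species"].to_numpy(dtype=object),
        df["label"].to_numpy(dtype=object),
        df["is_head"].to_numpy(dtype=bool),
    )


def read_mdanalysis_trajectory(
    topology: str | Path,
    trajectory: str | Path,
    bead_table: str | Path,
    dt: float | None = None,
    replicate_id: str = "rep0",
) -> Trajectory:
    """Read a binary trajectory (XTC/DCD/...) through MDAnalysis.

    ``bead_table`` is a CSV as written by :func:`write_bead_table`; its
    row order must match the atom order of the topology.
    """
    import MDAnalysis as mda

    bt = read_bead_table(bead_table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology), str(trajectory))
    if len(u.atoms) != len(bt):
        raise ValueError(
            f"bead table covers {len(bt)} beads but topology has {len(u.atoms)}"
        )
    frames = []
    for ts in u.trajectory:
        frames.append(
            Frame(time=float(ts.time), box=np.asarray(ts.dimensions[:3], dtype=float),
                  coords=ts.positions.astype(float))
        )
    if dt is None:
        dt = frames[1].time - frames[0].time if len(frames) > 1 else 1.0
    return Trajectory(frames, dt=dt, bead_table=bt, replicate_id=replicate_id)


def read_trajectory(
    path: str | Path,
    topology: str | Path | None = None,
    bead_table: str | Path | None = None,
    **kwargs,
) -> Trajectory:
    """Dispatch on file suffix: ``.traj`` text format, else MDAnalysis."""
    p = Path(path)
    if p.suffix == ".traj":
        return read_text_trajectory(p)
    if topology is None or bead_table is None:
        raise ValueError(
            "binary trajectories need `topology` and `bead_table` paths"
        )
    return read_mdanalysis_trajectory(topology, p, bead_table, **kwargs)


# ---------------------------------------------------------------------------
# topology output
# ---------------------------------------------------------------------------

def write_pdb(model: ProteinModel, path: str | Path) -> None:
    """Write the model's beads as a PDB through MDAnalysis."""
    import MDAnalysis as mda

    n = model.n_beads
    resindex = model.bead_residue
    segids = np.array([r.subunit for r in model.residues], dtype=object)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=n, n_residues=model.n_residues,
            n_segments=len(model.subunits),
            atom_resindex=resindex,
            residue_segindex=[model.subunits.index(r.subunit) for r in model.residues],
            trajectory=True,
        )
        u.add_TopologyAttr("names", model.bead_labels)
        u.add_TopologyAttr("resids", [r.index for r in model.residues])
        u.add_TopologyAttr("resnames", [r.name for r in model.residues])
        u.add_TopologyAttr("segids", model.subunits)
        u.add_TopologyAttr("chainIDs", [str(s)[:1] for s in segids[resindex]])
        u.atoms.positions = model.bead_coords
        u.atoms.write(str(path))


def write_sidecar(model: ProteinModel, path: str | Path) -> None:
    rows = [
        dict(chain=r.subunit, resnum=r.index, resname=r.name,
             charge=r.charge, helix="" if r.helix is None else r.helix,
             subunit=r.subunit)
        for r in model.residues
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
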