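"""Trajectory superposition, leaflet-resolved 2D density and height maps,
RMSD and RMSF.

All maps live on an (x, y) grid anchored at the origin of the reference
frame's box; density values are mean bead counts per frame per bin
(divide by ``bin_size**2`` for A^-2).  Superposition is a full 3D
least-squares fit of the chosen protein beads onto the reference model,
with the same rigid transform applied to every bead, lipids included.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import ProteinModel, Trajectory
from .contacts import LEAFLET_CYTOPLASMIC, LEAFLET_LUMINAL, leaflet_assign
from .geometry import apply_transform, kabsch

__all__ = [
    "DensityGrid",
    "fit_frames",
    "density_map",
    "height_map",
    "rmsd_series",
    "rmsf",
    "render_grid",
]


@dataclass
class DensityGrid:
    """A 2D map over the membrane plane.

    ``values[i, j]`` covers the bin with x in
    ``[origin[0] + i*bin_size, origin[0] + (i+1)*bin_size)`` and the
    corresponding y slice.  For density maps the values are mean counts
    per frame per bin; for height maps they are mean z in A with NaN
    marking never-occupied bins.
    """

    bin_size: float
    origin: tuple[float, float]
    values: np.ndarray
    leaflet: str
    selection: str
    n_frames: int
    kind: str = "density"

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.values.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.bin_size
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.bin_size
        return x, y

    def peak_xy(self) -> tuple[float, float]:
        """Coordinates of the maximum-value bin centre."""
        i, j = np.unravel_index(np.nanargmax(self.values), self.values.shape)
        x, y = self.bin_centers()
        return float(x[i]), float(y[j])

    def total(self) -> float:
        return float(np.nansum(self.values))

    def save(self, path: str | Path) -> None:
        header = (
            f"bin_size: {self.bin_size}\norigin: {self.origin[0]} {self.origin[1]}\n"
            f"leaflet: {self.leaflet}\nselection: {self.selection}\n"
            f"n_frames: {self.n_frames}\nkind: {self.kind}"
        )
        np.savetxt(path, self.values, header=header)

    @classmethod
    def load(cls, path: str | Path) -> "DensityGrid":
        meta: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                k, _, v = line[1:].strip().partition(":")
                meta[k.strip()] = v.strip()
        values = np.loadtxt(path)
        ox, oy = (float(t) for t in meta["origin"].split())
        return cls(
            bin_size=float(meta["bin_size"]), origin=(ox, oy),
            values=np.atleast_2d(values), leaflet=meta["leaflet"],
            selection=meta["selection"], n_frames=int(meta["n_frames"]),
            kind=meta.get("kind", "density"),
        )


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _selection_and_reference(
    traj: Trajectory, model: ProteinModel, selection: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    prot = np.flatnonzero(traj.bead_table.protein_mask)
    if prot.size != model.n_beads:
        raise ValueError(
            "trajectory protein bead count does not match the model; "
            "superposition requires matching bead order"
        )
    if selection is None:
        sel = prot
        ref = model.bead_coords
    else:
        sel = np.asarray(selection, dtype=int)
        inv = {int(b): i for i, b in enumerate(prot)}
        try:
            ref = model.bead_coords[[inv[int(b)] for b in sel]]
        except KeyError as e:
            raise ValueError(f"selection bead {e} is not a protein bead") from e
    if sel.size < 3:
        raise ValueError("superposition needs >= 3 selection beads")
    return sel, ref


def fit_frames(
    traj: Trajectory,
    model: ProteinModel,
    selection: np.ndarray | None = None,
) -> Trajectory:
    """Rigidly superpose every frame onto the reference model.

    ``selection`` is a set of trajectory bead indices (default: all
    protein beads, the coarse-grained backbone); each frame's optimal
    rotation + translation is applied to all beads, so lipid densities
    accumulate in the protein frame of reference.
    """
    from .core import Frame

    sel, ref = _selection_and_reference(traj, model, selection)
    frames = []
    for f in traj.frames:
        R, t = kabsch(f.coords[sel].astype(float), ref)
        frames.append(
            Frame(time=f.time, box=f.box.copy(),
                  coords=apply_transform(f.coords, R, t))
        )
    return Trajectory(frames, traj.dt, traj.bead_table, traj.replicate_id)


def rmsd_series(
    traj: Trajectory,
    model: ProteinModel,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (A) of the selection after optimal superposition."""
    sel, ref = _selection_and_reference(traj, model, selection)
    out = np.empty(len(traj))
    for i, f in enumerate(traj.frames):
        P = f.coords[sel].astype(float)
        R, t = kabsch(P, ref)
        d = apply_transform(P, R, t) - ref
        out[i] = np.sqrt((d ** 2).sum(axis=1).mean())
    return out


def rmsf(
    traj: Trajectory,
    model: ProteinModel,
    selection: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
) -> dict[tuple[str, int], float]:
    """Per-residue RMSF (A) about the time-mean position after
    superposing every frame onto the reference.

    ``fit_selection`` optionally restricts the superposition anchor
    (e.g. a rigid core) while fluctuations are measured on
    ``selection``; by default both are the full protein selection.
    """
    sel, _ = _selection_and_reference(traj, model, selection)
    fit_sel, fit_ref = _selection_and_reference(
        traj, model, selection if fit_selection is None else fit_selection
    )
    aligned = np.empty((len(traj), sel.size, 3))
    for i, f in enumerate(traj.frames):
        R, t = kabsch(f.coords[fit_sel].astype(float), fit_ref)
        aligned[i] = apply_transform(f.coords[sel].astype(float), R, t)
    mean_pos = aligned.mean(axis=0)
    per_bead = np.sqrt(((aligned - mean_pos) ** 2).sum(axis=2).mean(axis=0))
    prot = np.flatnonzero(traj.bead_table.protein_mask)
    inv = {int(b): i for i, b in enumerate(prot)}
    out: dict[tuple[str, int], list[float]] = {}
    for b, v in zip(sel, per_bead):
        rec = model.residues[model.bead_residue[inv[int(b)]]]
        out.setdefault(rec.key, []).append(float(v))
    return {k: float(np.mean(v)) for k, v in out.items()}


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------

def _head_selection(traj: Trajectory, species: Sequence[str] | None) -> np.ndarray:
    bt = traj.bead_table
    idx = np.flatnonzero(bt.head_mask)
    if species is not None:
        idx = idx[np.isin(bt.species[idx], list(species))]
    if idx.size == 0:
        raise ValueError("empty bead selection for the map")
    return idx


def density_map(
    aligned: Trajectory,
    species: Sequence[str] | None = None,
    bin_size: float = 2.0,
    leaflet: str = "both",
    leaflet_source: Trajectory | None = None,
) -> DensityGrid:
    """Mean per-frame (x, y) histogram of selected headgroup beads.

    ``leaflet`` is ``both``, ``cytoplasmic`` or ``luminal``; leaflet
    labels are computed per frame from ``leaflet_source`` (the
    *pre-alignment* trajectory — alignment may tilt frames) or, failing
    that, from ``aligned`` itself.  Beads that leave the grid extent
    after alignment are dropped, so the conservation identity
    ``sum(values) == mean selected count`` holds exactly only while all
    beads stay inside.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if leaflet not in ("both", LEAFLET_CYTOPLASMIC, LEAFLET_LUMINAL):
        raise ValueError(f"unknown leaflet {leaflet!r}")
    idx = _head_selection(aligned, species)
    box = aligned.frames[0].box
    nx = max(1, int(np.ceil(box[0] / bin_size)))
    ny = max(1, int(np.ceil(box[1] / bin_size)))
    acc = np.zeros((nx, ny))
    source = leaflet_source or aligned
    bt = aligned.bead_table
    for fi, f in enumerate(aligned.frames):
        take = idx
        if leaflet != "both":
            labels = leaflet_assign(source.frames[fi], source.bead_table)
            keep = np.array([labels[int(m)] == leaflet for m in bt.mol_id[idx]])
            take = idx[keep]
        xy = f.coords[take, :2].astype(float)
        H, _, _ = np.histogram2d(
            xy[:, 0], xy[:, 1], bins=(nx, ny),
            range=[[0.0, nx * bin_size], [0.0, ny * bin_size]],
        )
        acc += H
    sel_desc = "heads:" + (",".join(species) if species else "all")
    return DensityGrid(
        bin_size=bin_size, origin=(0.0, 0.0), values=acc / len(aligned),
        leaflet=leaflet, selection=sel_desc, n_frames=len(aligned),
    )


def height_map(
    traj: Trajectory,
    leaflet: str,
    bin_size: float = 2.0,
    species: Sequence[str] | None = None,
) -> DensityGrid:
    """Mean headgroup z per (x, y) bin for one leaflet; NaN where no
    bead ever visited the bin."""
    if leaflet not in (LEAFLET_CYTOPLASMIC, LEAFLET_LUMINAL):
        raise ValueError("height_map needs an explicit leaflet")
    idx = _head_selection(traj, species)
    box = traj.frames[0].box
    nx = max(1, int(np.ceil(box[0] / bin_size)))
    ny = max(1, int(np.ceil(box[1] / bin_size)))
    zsum = np.zeros((nx, ny))
    count = np.zeros((nx, ny))
    bt = traj.bead_table
    seen = False
    for f in traj.frames:
        labels = leaflet_assign(f, bt)
        keep = np.array([labels[int(m)] == leaflet for m in bt.mol_id[idx]])
        take = idx[keep]
        if take.size:
            seen = True
        xyz = f.coords[take].astype(float)
        rng = [[0.0, nx * bin_size], [0.0, ny * bin_size]]
        H, _, _ = np.histogram2d(xyz[:, 0], xyz[:, 1], bins=(nx, ny), range=rng)
        Z, _, _ = np.histogram2d(xyz[:, 0], xyz[:, 1], bins=(nx, ny), range=rng,
                                 weights=xyz[:, 2])
        zsum += Z
        count += H
    if not seen:
        raise ValueError(f"no headgroup beads in leaflet {leaflet!r}")
    with np.errstate(invalid="ignore"):
        values = zsum / count
    sel_desc = "heads:" + (",".join(species) if species else "all")
    return DensityGrid(
        bin_size=bin_size, origin=(0.0, 0.0), values=values,
        leaflet=leaflet, selection=sel_desc, n_frames=len(traj), kind="height",
    )


def render_grid(grid: DensityGrid, path: str | Path, cmap: str = "viridis") -> None:
    """Simple PNG rendering of a map (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = grid.bin_centers()
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.pcolormesh(x, y, grid.values.T, cmap=cmap, shading="nearest")
    fig.colorbar(im, ax=ax, label=grid.kind)
    ax.set_xlabel("x (A)")
    ax.set_ylabel("y (A)")
    ax.set_title(f"{grid.kind}: {grid.selection} [{grid.leaflet}]")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
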