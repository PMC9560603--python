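"""Per-residue, per-species lipid contact fingerprints.

A contact is a (residue, lipid molecule, frame) triple in which the
minimum-image distance between *any* bead of the residue and the
lipid's headgroup bead is at or below the cutoff; bead multiplicity
within one residue-lipid-frame never counts more than once.  Default
cutoffs follow the resolution of the data: 5.5 A for coarse-grained
beads, 4.0 A for atomistic coordinates.

Raw counts are normalised by dividing by the total number of frames
(replicates concatenated) and the copy number of that lipid species in
the bilayer, giving a dimensionless per-frame, per-copy contact
probability in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BilayerComposition, Frame, ProteinModel, Trajectory

__all__ = [
    "CUTOFF_CG",
    "CUTOFF_AT",
    "LEAFLET_CYTOPLASMIC",
    "LEAFLET_LUMINAL",
    "ContactTable",
    "count_contacts",
    "normalize",
    "windowed_contacts",
    "AnnulusSeries",
    "annulus_count",
    "fold_enrichment",
    "leaflet_assign",
]

CUTOFF_CG = 5.5
CUTOFF_AT = 4.0

LEAFLET_CYTOPLASMIC = "cytoplasmic"   # lower z
LEAFLET_LUMINAL = "luminal"           # upper z


@dataclass
class ContactTable:
    """Residue x species contact statistics.

    ``raw[i, j]`` is the total contact count of residue ``residue_keys[i]``
    with species ``species[j]``; ``normalized`` holds
    ``raw / (total_frames * copies(species))`` once :func:`normalize` has
    been applied.  ``meta`` records cutoff, frame counts, copy numbers,
    replicate ids and the resolution tag.
    """

    residue_keys: list[tuple[str, int]]
    species: list[str]
    raw: np.ndarray
    normalized: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)
        if self.raw.shape != (len(self.residue_keys), len(self.species)):
            raise ValueError("raw shape must be (n_residues, n_species)")
        if np.any(self.raw < 0):
            raise ValueError("raw counts must be non-negative")

    def species_column(self, name: str, normalized: bool = False) -> np.ndarray:
        j = self.species.index(name)
        values = self.normalized if normalized else self.raw
        if values is None:
            raise ValueError("table has no normalized values yet")
        return values[:, j]

    def residue_row(self, key: tuple[str, int]) -> int:
        return self.residue_keys.index((key[0], int(key[1])))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (sub, resnum) in enumerate(self.residue_keys):
            for j, sp in enumerate(self.species):
                row = dict(subunit=sub, resnum=resnum, species=sp,
                           raw=int(self.raw[i, j]))
                if self.normalized is not None:
                    row["normalized"] = float(self.normalized[i, j])
                rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        header = "".join(
            f"# {k}: {v}\n" for k, v in sorted(self.meta.items(), key=str)
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

def _validate_cutoff(traj: Trajectory, cutoff: float) -> None:
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    min_box = min(float(f.box.min()) for f in traj.frames)
    if cutoff >= min_box / 2.0:
        raise ValueError(
            f"cutoff {cutoff} A >= half the smallest box dimension "
            f"({min_box / 2.0} A); minimum-image convention invalid"
        )


def _iter_frame_pairs(
    traj: Trajectory,
    model: ProteinModel,
    cutoff: float,
    species_filter: Sequence[str] | None = None,
    frame_indices: np.ndarray | None = None,
):
    """Per-frame unique (residue, lipid molecule) contact pairs.

    Shared kernel for counting ops: distances are minimum-image on the
    frame's orthorhombic box (periodic KD-tree); a pair appears once
    per frame however many residue beads or head beads are involved.
    Yields ``(frame_idx, codes)`` with ``codes = res_row * n_mols + mol_pos``;
    callers get the selection metadata from :func:`_pair_selections`.
    """
    from scipy.spatial import cKDTree

    (prot_idx, res_of_bead, head_idx, mol_pos_of_head, n_mols
     ) = _pair_selections(traj, model, species_filter)[:5]
    frame_indices = (
        np.arange(len(traj)) if frame_indices is None else np.asarray(frame_indices)
    )
    last_P: np.ndarray | None = None
    last_box: np.ndarray | None = None
    tree_p = None
    for fi in frame_indices:
        f = traj.frames[fi]
        box = np.asarray(f.box, dtype=float)
        P = f.coords[prot_idx]
        if (tree_p is None or last_box is None or not np.array_equal(box, last_box)
                or not np.array_equal(P, last_P)):
            last_P, last_box = P, box
            tree_p = cKDTree(np.mod(P.astype(float), box), boxsize=box)
        H = np.mod(f.coords[head_idx].astype(float), box)
        tree_h = cKDTree(H, boxsize=box)
        neighbours = tree_h.query_ball_tree(tree_p, cutoff)
        codes: set[int] = set()
        for hi, js in enumerate(neighbours):
            if js:
                base = int(mol_pos_of_head[hi])
                for j in js:
                    codes.add(int(res_of_bead[j]) * n_mols + base)
        yield fi, np.fromiter(codes, dtype=np.int64, count=len(codes))


def _pair_selections(
    traj: Trajectory, model: ProteinModel, species_filter: Sequence[str] | None
):
    bt = traj.bead_table
    prot_idx = np.flatnonzero(bt.protein_mask)
    if prot_idx.size == 0:
        raise ValueError("trajectory has no protein beads")
    res_of_bead = np.array(
        [model.residue_index((s.split(":")[0], int(s.split(":")[1])))
         for s in bt.species[prot_idx]]
    )
    head_idx = np.flatnonzero(bt.head_mask)
    if species_filter is not None:
        head_idx = head_idx[np.isin(bt.species[head_idx], list(species_filter))]
    if head_idx.size == 0:
        raise ValueError("no lipid headgroup beads selected")
    mols = bt.mol_id[head_idx]
    uniq_mols, mol_pos_of_head = np.unique(mols, return_inverse=True)
    mol_species = np.empty(uniq_mols.size, dtype=object)
    mol_species[mol_pos_of_head] = bt.species[head_idx]
    return (prot_idx, res_of_bead, head_idx, mol_pos_of_head,
            uniq_mols.size, uniq_mols, mol_species)


def count_contacts(
    traj: Trajectory,
    model: ProteinModel,
    cutoff: float = CUTOFF_CG,
    species_filter: Sequence[str] | None = None,
    frame_indices: np.ndarray | None = None,
    resolution: str = "CG",
) -> ContactTable:
    """Raw residue x species contact counts over a trajectory.

    Every (residue, lipid molecule) pair contributes at most one count
    per frame.  ``species_filter`` restricts the lipid species counted;
    ``frame_indices`` restricts the frames (used by
    :func:`windowed_contacts`).
    """
    _validate_cutoff(traj, cutoff)
    *_, n_mols, uniq_mols, mol_species = _pair_selections(
        traj, model, species_filter
    )
    pair_counts = np.zeros(model.n_residues * n_mols, dtype=np.int64)
    n_frames = 0
    for _, codes in _iter_frame_pairs(traj, model, cutoff, species_filter,
                                      frame_indices):
        n_frames += 1
        if codes.size:
            np.add.at(pair_counts, codes, 1)
    pair_counts = pair_counts.reshape(model.n_residues, n_mols)
    species_order = list(pd.unique(mol_species))
    raw = np.stack(
        [pair_counts[:, np.flatnonzero(mol_species == sp)].sum(axis=1)
         for sp in species_order], axis=1,
    )
    return ContactTable(
        residue_keys=model.residue_keys(),
        species=species_order,
        raw=raw,
        meta=dict(cutoff=cutoff, total_frames=n_frames,
                  replicate_ids=[traj.replicate_id], resolution=resolution),
    )


def normalize(
    tables: Sequence[ContactTable], composition: BilayerComposition
) -> ContactTable:
    """Concatenate replicates and normalise.

    Raw counts are summed over replicates and divided by
    ``total_frames * copies(species)``; the result is the per-frame,
    per-copy contact probability, bounded by [0, 1].
    """
    if not tables:
        raise ValueError("need at least one table")
    first = tables[0]
    for t in tables[1:]:
        if t.residue_keys != first.residue_keys or t.species != first.species:
            raise ValueError("tables must share model residues and species")
        if t.meta.get("cutoff") != first.meta.get("cutoff"):
            raise ValueError("tables must share the contact cutoff")
    raw = np.sum([t.raw for t in tables], axis=0)
    total_frames = int(sum(t.meta.get("total_frames", 0) for t in tables))
    copies = {}
    for sp in first.species:
        c = composition.copies(sp)
        if c == 0:
            raise ValueError(
                f"species {sp!r} present in contact table but has 0 copies "
                "in the composition"
            )
        copies[sp] = c
    divisor = total_frames * np.array([copies[sp] for sp in first.species])
    normalized = raw / divisor
    replicate_ids = [r for t in tables for r in t.meta.get("replicate_ids", [])]
    meta = dict(first.meta, total_frames=total_frames, copies=copies,
                replicate_ids=replicate_ids)
    return ContactTable(first.residue_keys, list(first.species), raw,
                        normalized=normalized, meta=meta)


def windowed_contacts(
    traj: Trajectory,
    model: ProteinModel,
    cutoff: float,
    windows: Sequence[tuple[float, float]],
    **kwargs,
) -> list[ContactTable]:
    """One raw contact table per time window ``[t_start, t_end]`` (ps,
    inclusive); used for convergence checks over growing windows."""
    times = traj.times
    tables = []
    for t_start, t_end in windows:
        if t_start > t_end:
            raise ValueError(f"window ({t_start}, {t_end}) is reversed")
        idx = np.flatnonzero((times >= t_start) & (times <= t_end))
        if idx.size == 0:
            raise ValueError(f"window ({t_start}, {t_end}) contains no frames")
        tables.append(count_contacts(traj, model, cutoff,
                                     frame_indices=idx, **kwargs))
    return tables


@dataclass
class AnnulusSeries:
    """Per-frame count of distinct lipids touching the protein surface."""

    counts: np.ndarray
    times: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    @property
    def std(self) -> float:
        return float(self.counts.std())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(time_ps=self.times, n_lipids=self.counts))


def annulus_count(
    traj: Trajectory,
    model: ProteinModel,
    cutoff: float = CUTOFF_CG,
    species_filter: Sequence[str] | None = None,
) -> AnnulusSeries:
    """Number of distinct lipid molecules whose headgroup bead is within
    the cutoff of any protein bead, per frame (the lipid annulus)."""
    _validate_cutoff(traj, cutoff)
    n_mols = _pair_selections(traj, model, species_filter)[4]
    counts = np.zeros(len(traj), dtype=int)
    for fi, codes in _iter_frame_pairs(traj, model, cutoff, species_filter):
        counts[fi] = np.unique(codes % n_mols).size
    return AnnulusSeries(counts=counts, times=traj.times)


def fold_enrichment(
    table: ContactTable,
    species_a: str,
    species_b: str,
    residue_set: Sequence[tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-residue and aggregate contact enrichment of species A over B.

    Ratios use the copy-number-normalised contacts.  A zero denominator
    with a non-zero numerator is flagged ``unbounded``; 0/0 is
    ``undefined``; both are excluded from per-residue summaries.  The
    aggregate is the ratio of normalised-contact sums over the residue
    set (NaN if both sums vanish, inf if only B's does).
    """
    if table.normalized is None:
        raise ValueError("fold_enrichment needs a normalised table")
    for sp in (species_a, species_b):
        if sp not in table.species:
            raise KeyError(f"species {sp!r} missing from contact table")
    a = table.species_column(species_a, normalized=True)
    b = table.species_column(species_b, normalized=True)
    keys = table.residue_keys
    if residue_set is not None:
        wanted = {(s, int(r)) for s, r in residue_set}
        rows = [i for i, k in enumerate(keys) if k in wanted]
        if not rows:
            raise ValueError("residue_set matches no residues in the table")
        a, b = a[rows], b[rows]
        keys = [keys[i] for i in rows]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = a / b
    status = np.where(
        b > 0, "ok", np.where(a > 0, "unbounded", "undefined")
    )
    df = pd.DataFrame(
        dict(subunit=[k[0] for k in keys], resnum=[k[1] for k in keys],
             normalized_a=a, normalized_b=b, ratio=ratio, status=status)
    )
    sa, sb = float(a.sum()), float(b.sum())
    if sb > 0:
        aggregate = sa / sb
    else:
        aggregate = float("inf") if sa > 0 else float("nan")
    return df, aggregate


def leaflet_assign(frame: Frame, bead_table) -> dict[int, str]:
    """Assign each lipid molecule to a leaflet for one frame.

    The bilayer midplane is the mean z of all lipid headgroup beads in
    the frame; molecules at or below it are ``cytoplasmic`` (exact ties
    included), above it ``luminal``.
    """
    head = bead_table.head_mask
    if not head.any():
        raise ValueError("frame has no lipid headgroup beads")
    z = frame.coords[head, 2].astype(float)
    mols = bead_table.mol_id[head]
    mid = z.mean()
    out: dict[int, str] = {}
    # a molecule with several head beads follows its mean head z
    df = pd.DataFrame(dict(mol=mols, z=z)).groupby("mol")["z"].mean()
    for m, zm in df.items():
        out[int(m)] = LEAFLET_CYTOPLASMIC if zm <= mid else LEAFLET_LUMINAL
    return out
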