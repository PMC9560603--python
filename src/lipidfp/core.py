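"""Domain types for membrane protein-lipid analysis.

Conventions used throughout the package:

* coordinates are in Angstrom, times in ps (residence durations are
  reported in ns);
* the membrane normal is +z and the lower-z leaflet is designated
  ``cytoplasmic``, the upper-z leaflet ``luminal``;
* residue numbering is 1-based and follows the PDB;
* boxes are orthorhombic.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_TM_HELICES",
    "LipidSpecies",
    "BilayerComposition",
    "ResidueRecord",
    "ProteinModel",
    "Frame",
    "BeadTable",
    "Trajectory",
    "STUDY_LIPIDS",
    "build_composition",
    "tonoplast_composition",
    "load_topology",
    "bw_label",
]

#: Number of transmembrane helices per subunit in membrane-integral
#: pyrophosphatases; helix ids are validated against this range.
N_TM_HELICES = 16


# ---------------------------------------------------------------------------
# lipids and compositions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species characterised by its headgroup bead and formal charge.

    Parameters
    ----------
    name:
        Short identifier, e.g. ``"POPA"``; unique within a composition.
    head_bead:
        Bead label used for contact and density selection (the phosphate
        bead for phospholipids in coarse-grained representations).
    charge:
        Integer formal charge of the headgroup in units of e.  Anionic
        species have negative charge; the species studied here span 0
        to -5.
    tails:
        Free-text acyl tail descriptor, informational only.
    """

    name: str
    head_bead: str = "PO4"
    charge: int = 0
    tails: str = ""

    def __post_init__(self) -> None:
        if not (-5 <= self.charge <= 0):
            raise ValueError(
                f"species {self.name!r}: formal charge {self.charge} outside "
                "the supported range [-5, 0]"
            )

    @property
    def anionic(self) -> bool:
        return self.charge < 0


#: The lipid species used across the simulated bilayers: zwitterionic
#: phospholipids and sterol/sphingolipid (charge 0), the monoanionic
#: POPG/POPS, dianionic POPA and the polyanionic PIP2.
STUDY_LIPIDS: dict[str, LipidSpecies] = {
    sp.name: sp
    for sp in (
        LipidSpecies("CHOL", head_bead="ROH", charge=0, tails="C(d18:1/18:0)"),
        LipidSpecies("DPCE", head_bead="AM1", charge=0, tails="C(d18:1/18:0)"),
        LipidSpecies("POPE", charge=0, tails="C16:0/18:1"),
        LipidSpecies("POPC", charge=0, tails="C16:0/18:1"),
        LipidSpecies("POPG", charge=-1, tails="C16:0/18:1"),
        LipidSpecies("POPS", charge=-1, tails="C16:0/18:1"),
        LipidSpecies("POPA", charge=-2, tails="C16:0/18:1"),
        LipidSpecies("PIP2", charge=-5, tails="C16:1(9c)/C18:1(9c)"),
    )
}


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer copies according to ``fractions``.

    Floors the ideal counts then hands the remaining units to the
    entries with the largest fractional remainder; ties are broken by
    listed order.
    """
    ideal = fractions * total
    counts = np.floor(ideal + 1e-9).astype(int)
    leftover = total - int(counts.sum())
    if leftover > 0:
        remainder = ideal - counts
        # stable sort => listed order wins ties
        order = np.argsort(-remainder, kind="stable")
        counts[order[:leftover]] += 1
    return counts


@dataclass(frozen=True)
class BilayerComposition:
    """A realised bilayer composition.

    ``entries`` is an ordered list of ``(species, mole_percent)``;
    ``per_leaflet_counts`` maps species name to ``(upper, lower)`` copy
    numbers once the composition has been realised for a total copy
    number (upper = luminal, lower = cytoplasmic).
    """

    entries: tuple[tuple[LipidSpecies, float], ...]
    per_leaflet_counts: dict[str, tuple[int, int]]

    @property
    def species(self) -> tuple[LipidSpecies, ...]:
        return tuple(sp for sp, _ in self.entries)

    def get_species(self, name: str) -> LipidSpecies:
        for sp, _ in self.entries:
            if sp.name == name:
                return sp
        raise KeyError(f"species {name!r} not in composition")

    def copies(self, name: str) -> int:
        up, lo = self.per_leaflet_counts[name]
        return up + lo

    @property
    def total(self) -> int:
        return sum(self.copies(sp.name) for sp in self.species)

    def anionic_mole_percent(self) -> float:
        """Summed mole percent of all species with negative formal charge."""
        return float(sum(pct for sp, pct in self.entries if sp.anionic))

    def anionic_names(self) -> list[str]:
        return [sp.name for sp in self.species if sp.anionic]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp, pct in self.entries:
            up, lo = self.per_leaflet_counts[sp.name]
            rows.append(
                dict(species=sp.name, head_bead=sp.head_bead, charge=sp.charge,
                     mole_percent=pct, upper=up, lower=lo, total=up + lo)
            )
        return pd.DataFrame(rows)


def build_composition(
    entries: Sequence[tuple[LipidSpecies, float]],
    total: int,
    leaflet_split: float = 0.5,
) -> BilayerComposition:
    """Realise integer per-species, per-leaflet lipid copy numbers.

    Mole percentages must sum to 100.  Copy numbers are apportioned by
    largest-remainder rounding so they sum exactly to ``total``;
    ``leaflet_split`` is the fraction of each species placed in the
    upper (luminal) leaflet, apportioned with the same rounding rule.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0.0 <= leaflet_split <= 1.0):
        raise ValueError("leaflet_split must lie in [0, 1]")
    names = [sp.name for sp, _ in entries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species name in composition entries")
    pcts = np.asarray([pct for _, pct in entries], dtype=float)
    if np.any(pcts < 0):
        raise ValueError("mole percents must be non-negative")
    s = pcts.sum()
    if abs(s - 100.0) > 1e-6:
        raise ValueError(f"mole percents must sum to 100, got {s!r}")

    counts = _largest_remainder(pcts / s, total)
    # split each species across leaflets, again by largest remainder so
    # the upper-leaflet grand total matches round(total * split)
    total_upper = int(math.floor(total * leaflet_split + 0.5))
    ideal_upper = counts * leaflet_split
    upper = np.floor(ideal_upper + 1e-9).astype(int)
    leftover = total_upper - int(upper.sum())
    if leftover > 0:
        remainder = ideal_upper - upper
        order = np.argsort(-remainder, kind="stable")
        k = 0
        for idx in order:
            if k == leftover:
                break
            if upper[idx] < counts[idx]:
                upper[idx] += 1
                k += 1
    lower = counts - upper
    per_leaflet = {
        name: (int(u), int(lo)) for name, u, lo in zip(names, upper, lower)
    }
    return BilayerComposition(
        entries=tuple((sp, float(pct)) for sp, pct in entries),
        per_leaflet_counts=per_leaflet,
    )


def tonoplast_composition(total: int = 400, leaflet_split: float = 0.5) -> BilayerComposition:
    """The plant tonoplast-like composition used for the *V. radiata* enzyme.

    29% cholesterol, 25% POPC, 17% POPE, 17% ceramide hexoside, 6% PIP2,
    3% POPG, 2% POPS and 1% POPA (12% anionic in total).
    """
    percents = [
        ("CHOL", 29.0), ("POPC", 25.0), ("POPE", 17.0), ("DPCE", 17.0),
        ("PIP2", 6.0), ("POPG", 3.0), ("POPS", 2.0), ("POPA", 1.0),
    ]
    return build_composition(
        [(STUDY_LIPIDS[n], p) for n, p in percents], total, leaflet_split
    )


# ---------------------------------------------------------------------------
# protein model
# ---------------------------------------------------------------------------

@dataclass
class ResidueRecord:
    """One protein residue with the metadata the analysis needs."""

    index: int                      # 1-based residue number (PDB resnum)
    name: str                       # 3-letter code
    subunit: str                    # chain id
    helix: int | None = None        # TM helix id, 1..N_TM_HELICES, or None
    charge: int = 0                 # formal side-chain charge (e)
    bw_label: str | None = None     # Ballesteros-Weinstein "h.pos" label
    ref_position: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )                               # representative reference coordinate (A)

    def __post_init__(self) -> None:
        if self.helix is not None and not (1 <= self.helix <= N_TM_HELICES):
            raise ValueError(
                f"helix id {self.helix} outside [1, {N_TM_HELICES}] for "
                f"residue {self.subunit}:{self.index}"
            )
        self.ref_position = np.asarray(self.ref_position, dtype=float)

    @property
    def key(self) -> tuple[str, int]:
        return (self.subunit, self.index)


class ProteinModel:
    """A (usually homodimeric) protein with per-residue beads.

    Parameters
    ----------
    residues:
        Ordered residue records.
    bead_coords:
        ``(n_beads, 3)`` reference coordinates in Angstrom.
    bead_residue:
        For each bead, the index into ``residues`` it belongs to.
    bead_labels:
        Bead names (e.g. ``"BB"``); defaults to ``"BB"`` for all beads.
    """

    def __init__(
        self,
        residues: Sequence[ResidueRecord],
        bead_coords: np.ndarray,
        bead_residue: np.ndarray,
        bead_labels: Sequence[str] | None = None,
    ) -> None:
        self.residues: list[ResidueRecord] = list(residues)
        self.bead_coords = np.asarray(bead_coords, dtype=float).reshape(-1, 3)
        self.bead_residue = np.asarray(bead_residue, dtype=int)
        if self.bead_coords.shape[0] != self.bead_residue.shape[0]:
            raise ValueError("bead_coords and bead_residue length mismatch")
        if len(self.residues) == 0:
            raise ValueError("model needs at least one residue")
        if self.bead_residue.size and (
            self.bead_residue.min() < 0
            or self.bead_residue.max() >= len(self.residues)
        ):
            raise ValueError("bead_residue indices out of range")
        if not np.all(np.isfinite(self.bead_coords)):
            raise ValueError("reference coordinates must be finite")
        self.bead_labels = (
            list(bead_labels) if bead_labels is not None
            else ["BB"] * self.bead_coords.shape[0]
        )
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subunit, resnum) in residues")
        self._key_index = {k: i for i, k in enumerate(keys)}

    # -- basic queries ----------------------------------------------------
    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_beads(self) -> int:
        return self.bead_coords.shape[0]

    @property
    def subunits(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.subunit, None)
        return list(seen)

    def residue_index(self, key: tuple[str, int]) -> int:
        return self._key_index[(key[0], int(key[1]))]

    def residue(self, key: tuple[str, int]) -> ResidueRecord:
        return self.residues[self.residue_index(key)]

    def beads_of(self, key: tuple[str, int]) -> np.ndarray:
        """Bead indices belonging to one residue."""
        return np.flatnonzero(self.bead_residue == self.residue_index(key))

    def residue_keys(self) -> list[tuple[str, int]]:
        return [r.key for r in self.residues]

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "residues": [
                {
                    "index": r.index, "name": r.name, "subunit": r.subunit,
                    "helix": r.helix, "charge": r.charge,
                    "bw_label": r.bw_label,
                    "ref_position": [float(x) for x in r.ref_position],
                }
                for r in self.residues
            ],
            "bead_coords": self.bead_coords.tolist(),
            "bead_residue": self.bead_residue.tolist(),
            "bead_labels": self.bead_labels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProteinModel":
        residues = [
            ResidueRecord(
                index=r["index"], name=r["name"], subunit=r["subunit"],
                helix=r["helix"], charge=r["charge"], bw_label=r["bw_label"],
                ref_position=np.asarray(r["ref_position"], dtype=float),
            )
            for r in d["residues"]
        ]
        return cls(
            residues,
            np.asarray(d["bead_coords"], dtype=float),
            np.asarray(d["bead_residue"], dtype=int),
            d.get("bead_labels"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ProteinModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinModel):
            return NotImplemented
        return self.to_dict() == other.to_dict()


# ---------------------------------------------------------------------------
# trajectory containers
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    """One trajectory frame: time (ps), orthorhombic box (A), bead coords (A)."""

    time: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.coords = np.asarray(self.coords)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_beads, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box components must be positive")


@dataclass
class BeadTable:
    """Per-bead identity for a trajectory.

    ``kind`` is ``"protein"`` or ``"lipid"``; ``mol_id`` numbers lipid
    molecules (protein beads carry -1); ``species`` is the lipid species
    name or, for protein beads, the residue key as ``"chain:resnum"``;
    ``label`` is the bead name and ``is_head`` flags lipid headgroup
    beads.
    """

    kind: np.ndarray
    mol_id: np.ndarray
    species: np.ndarray
    label: np.ndarray
    is_head: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.kind)
        for arr_name in ("mol_id", "species", "label", "is_head"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError("bead table columns must have equal length")
        self.kind = np.asarray(self.kind, dtype=object)
        self.mol_id = np.asarray(self.mol_id, dtype=int)
        self.species = np.asarray(self.species, dtype=object)
        self.label = np.asarray(self.label, dtype=object)
        self.is_head = np.asarray(self.is_head, dtype=bool)

    def __len__(self) -> int:
        return len(self.kind)

    @property
    def protein_mask(self) -> np.ndarray:
        return self.kind == "protein"

    @property
    def head_mask(self) -> np.ndarray:
        return (self.kind == "lipid") & self.is_head

    def protein_residue_keys(self) -> list[tuple[str, int]]:
        keys = []
        for s in self.species[self.protein_mask]:
            chain, resnum = s.split(":")
            keys.append((chain, int(resnum)))
        return keys


class Trajectory:
    """Time-ordered frames plus the bead identity table."""

    def __init__(
        self,
        frames: Sequence[Frame],
        dt: float,
        bead_table: BeadTable,
        replicate_id: str = "rep0",
    ) -> None:
        if dt <= 0:
            raise ValueError("dt must be positive")
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        n = frames[0].coords.shape[0]
        times = [f.time for f in frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        for f in frames:
            if f.coords.shape[0] != n:
                raise ValueError("coordinate count must be constant")
        if len(bead_table) != n:
            raise ValueError("bead_table must cover every coordinate index")
        self.frames = frames
        self.dt = float(dt)
        self.bead_table = bead_table
        self.replicate_id = replicate_id

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_beads(self) -> int:
        return self.frames[0].coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.asarray([f.time for f in self.frames])

    def coords_array(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Stack coordinates as ``(n_frames, n_sel, 3)``."""
        if indices is None:
            return np.stack([f.coords for f in self.frames])
        return np.stack([f.coords[indices] for f in self.frames])

    def boxes(self) -> np.ndarray:
        return np.stack([f.box for f in self.frames])

    def subset_frames(self, frame_idx: Iterable[int]) -> "Trajectory":
        frames = [self.frames[i] for i in frame_idx]
        return Trajectory(frames, self.dt, self.bead_table, self.replicate_id)


# ---------------------------------------------------------------------------
# topology ingestion
# ---------------------------------------------------------------------------

def _read_sidecar(sidecar_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(sidecar_path, comment="#")
    required = {"chain", "resnum"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"sidecar {sidecar_path} must have columns {sorted(required)}"
        )
    dup = df.duplicated(subset=["chain", "resnum"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (chain, resnum) in sidecar: ({row['chain']}, {row['resnum']})"
        )
    return df


def load_topology(
    pdb_path: str | Path, sidecar_path: str | Path | None = None
) -> ProteinModel:
    """Build a :class:`ProteinModel` from a PDB file plus a metadata sidecar.

    The PDB supplies chains, residue numbers/names and reference
    coordinates; the sidecar CSV (columns ``chain, resnum`` and
    optionally ``resname, charge, helix, subunit``) supplies formal
    side-chain charges and TM helix assignments.  Residues missing from
    the sidecar get charge 0 and no helix; sidecar rows that match no
    PDB residue are reported with a warning.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guesses masses noisily
        u = mda.Universe(str(pdb_path))

    residues: list[ResidueRecord] = []
    bead_coords: list[np.ndarray] = []
    bead_residue: list[int] = []
    bead_labels: list[str] = []
    for i, res in enumerate(u.residues):
        chain = str(res.segid).strip() or str(
            getattr(res.atoms[0], "chainID", "A")
        ).strip() or "A"
        positions = res.atoms.positions.astype(float)
        residues.append(
            ResidueRecord(
                index=int(res.resid), name=str(res.resname), subunit=chain,
                ref_position=positions.mean(axis=0),
            )
        )
        for atom, pos in zip(res.atoms, positions):
            bead_coords.append(pos)
            bead_residue.append(i)
            bead_labels.append(str(atom.name))

    model = ProteinModel(
        residues, np.asarray(bead_coords), np.asarray(bead_residue), bead_labels
    )

    if sidecar_path is not None:
        df = _read_sidecar(sidecar_path)
        unmatched = []
        for _, row in df.iterrows():
            key = (str(row["chain"]), int(row["resnum"]))
            try:
                rec = model.residue(key)
            except KeyError:
                unmatched.append(key)
                continue
            if "charge" in df.columns and not pd.isna(row.get("charge")):
                rec.charge = int(row["charge"])
            if "helix" in df.columns and not pd.isna(row.get("helix")):
                helix = int(row["helix"])
                if not (1 <= helix <= N_TM_HELICES):
                    raise ValueError(
                        f"helix id {helix} outside [1, {N_TM_HELICES}] "
                        f"for sidecar row {key}"
                    )
                rec.helix = helix
        if unmatched:
            warnings.warn(
                f"{len(unmatched)} sidecar row(s) matched no PDB residue: "
                f"{unmatched[:5]}", stacklevel=2,
            )
    return model


# ---------------------------------------------------------------------------
# Ballesteros-Weinstein labelling
# ---------------------------------------------------------------------------

def bw_label(
    model: ProteinModel,
    helix_defs: Sequence[tuple[int, int, int, int]],
) -> ProteinModel:
    """Assign Ballesteros-Weinstein ``helix.position`` labels.

    ``helix_defs`` rows are ``(helix_id, start, end, anchor)`` in residue
    numbers; the anchor residue is position ``.50`` of its helix and every
    residue in ``[start, end]`` is labelled ``helix.(50 + resnum - anchor)``.
    Spans apply to every subunit; residues outside all spans keep their
    existing label (``None`` unless previously set).  Returns the model
    (labels are assigned in place and the model returned for chaining).
    """
    spans: list[tuple[int, int, int, int]] = []
    for helix_id, start, end, anchor in helix_defs:
        if not (1 <= helix_id <= N_TM_HELICES):
            raise ValueError(f"helix id {helix_id} outside [1, {N_TM_HELICES}]")
        if start > end:
            raise ValueError(f"helix {helix_id}: start {start} > end {end}")
        if not (start <= anchor <= end):
            raise ValueError(
                f"helix {helix_id}: anchor {anchor} outside span [{start}, {end}]"
            )
        spans.append((helix_id, start, end, anchor))
    for (h1, s1, e1, _), (h2, s2, e2, _) in zip(spans, spans[1:]):
        pass  # overlap checked pairwise below
    for i, (h1, s1, e1, _) in enumerate(spans):
        for h2, s2, e2, _ in spans[i + 1:]:
            if s1 <= e2 and s2 <= e1:
                raise ValueError(
                    f"helix spans {h1} and {h2} overlap"
                )
    for rec in model.residues:
        for helix_id, start, end, anchor in spans:
            if start <= rec.index <= end:
                rec.bw_label = f"{helix_id}.{50 + rec.index - anchor}"
                rec.helix = helix_id
                break
    return model
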