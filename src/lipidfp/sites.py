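"""Binding-site identification, occupancy and residence kinetics.

Sites are found by the top-percentile rule on the normalised contact
fingerprint (default: top 5% of residues ranked by summed anionic
contacts), grouped by single-linkage clustering of inter-residue bead
distances in the reference structure, and classified as interfacial
(straddling or adjacent to the dimer interface) or distal.  Kinetics
use a dual-cutoff scheme so that a lipid rattling around the binding
distance is not split into spurious short events: an event starts when
a lipid comes within ``r_on`` and ends only when it leaves ``r_off``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .contacts import ContactTable, _validate_cutoff
from .core import ProteinModel, Trajectory

__all__ = [
    "BindingSite",
    "ResidenceStats",
    "OccupancySeries",
    "select_top_residues",
    "cluster_sites",
    "classify_sites",
    "site_occupancy",
    "residence_times",
]

ResKey = tuple[str, int]


@dataclass
class BindingSite:
    """A detected lipid binding site: a cluster of high-contact residues."""

    site_id: str
    residues: tuple[ResKey, ...]
    site_class: str = "unclassified"     # interfacial | distal | unclassified
    subunit_breakdown: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("site must contain at least one residue")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicate residues in site")

    def to_dict(self) -> dict:
        return dict(
            site_id=self.site_id, site_class=self.site_class,
            residues=[list(r) for r in self.residues],
            subunit_breakdown=self.subunit_breakdown,
        )


# ---------------------------------------------------------------------------
# selection and clustering
# ---------------------------------------------------------------------------

def select_top_residues(
    table: ContactTable,
    percentile: float = 5.0,
    species: Sequence[str] | None = None,
) -> list[ResKey]:
    """Residues in the top ``percentile`` % of summed normalised contacts.

    Residues are ranked by their normalised contacts summed over the
    given species (typically the anionic set; default: every species in
    the table).  The top ``ceil(p% * n)`` residues are returned in rank
    order; residues exactly tied with the last selected value are all
    included.
    """
    if not (0.0 < percentile <= 100.0):
        raise ValueError("percentile must lie in (0, 100]")
    if table.normalized is None:
        raise ValueError("select_top_residues needs a normalised table")
    if species is None:
        cols = np.arange(len(table.species))
    else:
        missing = [s for s in species if s not in table.species]
        if missing:
            raise KeyError(f"species {missing} missing from contact table")
        cols = np.array([table.species.index(s) for s in species])
    scores = table.normalized[:, cols].sum(axis=1)
    n = len(scores)
    k = math.ceil(percentile / 100.0 * n)
    order = np.argsort(-scores, kind="stable")
    threshold = scores[order[k - 1]]
    selected = [i for i in order if scores[i] >= threshold]
    return [table.residue_keys[i] for i in selected]


def _residue_min_dist(model: ProteinModel, keys: Sequence[ResKey]) -> np.ndarray:
    """Pairwise minimum bead-bead distance between residues, reference frame."""
    bead_sets = [model.bead_coords[model.beads_of(k)] for k in keys]
    n = len(keys)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.sqrt(
                ((bead_sets[i][:, None, :] - bead_sets[j][None, :, :]) ** 2)
                .sum(axis=2)
            ).min()
            out[i, j] = out[j, i] = d
    return out


def cluster_sites(
    selected: Sequence[ResKey],
    model: ProteinModel,
    linkage_cutoff: float = 8.0,
    min_size: int = 2,
) -> tuple[list[BindingSite], list[list[ResKey]]]:
    """Group selected residues into spatial clusters (candidate sites).

    Single-linkage at ``linkage_cutoff`` on the minimum inter-residue
    bead distance in the reference structure: two residues join the
    same site if connected by a chain of pairs each within the cutoff.
    Clusters smaller than ``min_size`` are dropped and returned
    separately for reporting.
    """
    keys = [(k[0], int(k[1])) for k in selected]
    if not keys:
        raise ValueError("empty residue selection")
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate residues in selection")
    dist = _residue_min_dist(model, keys)
    adj = csr_matrix(dist <= linkage_cutoff)
    n_comp, labels = connected_components(adj, directed=False)
    clusters: list[list[ResKey]] = [[] for _ in range(n_comp)]
    for key, lab in zip(keys, labels):
        clusters[lab].append(key)
    clusters.sort(key=lambda c: (-len(c), sorted(c)))
    sites, dropped = [], []
    for c in clusters:
        if len(c) >= min_size:
            sites.append(
                BindingSite(site_id=f"site{len(sites) + 1}", residues=tuple(c))
            )
        else:
            dropped.append(c)
    return sites, dropped


def classify_sites(
    sites: Sequence[BindingSite],
    model: ProteinModel,
    interface_distance: float = 10.0,
) -> list[BindingSite]:
    """Label each site interfacial or distal.

    A site is interfacial if it contains residues of at least two
    subunits, or if every one of its residues lies within
    ``interface_distance`` of some bead of another subunit; otherwise
    it is distal.  With a single-subunit model no classification is
    possible and all sites stay unclassified.
    """
    subs = model.subunits
    if len(subs) < 2:
        warnings.warn("model has a single subunit; sites left unclassified",
                      stacklevel=2)
        return [
            BindingSite(s.site_id, s.residues, "unclassified",
                        _breakdown(s.residues))
            for s in sites
        ]
    bead_sub = np.array(
        [model.residues[i].subunit for i in model.bead_residue], dtype=object
    )
    out = []
    for s in sites:
        breakdown = _breakdown(s.residues)
        if len(breakdown) >= 2:
            cls = "interfacial"
        else:
            (own_sub,) = breakdown
            other = model.bead_coords[bead_sub != own_sub]
            near_all = True
            for key in s.residues:
                beads = model.bead_coords[model.beads_of(key)]
                d = np.sqrt(
                    ((beads[:, None, :] - other[None, :, :]) ** 2).sum(axis=2)
                ).min()
                if d > interface_distance:
                    near_all = False
                    break
            cls = "interfacial" if near_all else "distal"
        out.append(BindingSite(s.site_id, s.residues, cls, breakdown))
    return out


def _breakdown(residues: Sequence[ResKey]) -> dict[str, int]:
    out: dict[str, int] = {}
    for sub, _ in residues:
        out[sub] = out.get(sub, 0) + 1
    return out


# ---------------------------------------------------------------------------
# occupancy and residence
# ---------------------------------------------------------------------------

def _min_dist_series(
    traj: Trajectory,
    model: ProteinModel,
    keys: Sequence[ResKey],
    species_filter: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame minimum distance from each lipid molecule to any bead of
    the given residues.  Returns (dmin (F, n_mols), mol_ids, species)."""
    bt = traj.bead_table
    prot = np.flatnonzero(bt.protein_mask)
    wanted = {f"{s}:{r}" for s, r in keys}
    key_beads = prot[np.isin(bt.species[prot], list(wanted))]
    if key_beads.size == 0:
        raise ValueError("no trajectory beads belong to the given residues")
    heads = np.flatnonzero(bt.head_mask)
    if species_filter is not None:
        heads = heads[np.isin(bt.species[heads], list(species_filter))]
    if heads.size == 0:
        raise ValueError("no lipid headgroup beads selected")
    mols = bt.mol_id[heads]
    order = np.argsort(mols, kind="stable")
    heads, mols = heads[order], mols[order]
    mol_starts = np.flatnonzero(np.r_[True, mols[1:] != mols[:-1]])
    uniq = mols[mol_starts]
    species = bt.species[heads][mol_starts]

    F = len(traj)
    dmin = np.empty((F, uniq.size), dtype=np.float32)
    chunk = max(1, int(4e6 / max(key_beads.size * heads.size, 1)))
    for lo in range(0, F, chunk):
        frames = range(lo, min(lo + chunk, F))
        P = np.stack([traj.frames[i].coords[key_beads] for i in frames]).astype(np.float32)
        H = np.stack([traj.frames[i].coords[heads] for i in frames]).astype(np.float32)
        B = np.stack([traj.frames[i].box for i in frames]).astype(np.float32)
        d2 = np.zeros((len(P), key_beads.size, heads.size), dtype=np.float32)
        for axis in range(3):
            dx = P[:, :, None, axis] - H[:, None, :, axis]
            L = B[:, axis][:, None, None]
            dx -= L * np.round(dx / L)
            d2 += dx * dx
        d_head = np.sqrt(d2.min(axis=1))          # (F_chunk, n_heads)
        # reduce heads to molecules (heads sorted by mol id)
        dmin[lo:lo + len(P)] = np.minimum.reduceat(d_head, mol_starts, axis=1)
    return dmin, uniq, species


@dataclass
class OccupancySeries:
    """Per-frame count of distinct lipids bound at a site."""

    counts: np.ndarray
    times: np.ndarray
    cutoff: float

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    def histogram(self) -> dict[int, float]:
        """Fraction of frames with each simultaneous lipid count."""
        vals, freq = np.unique(self.counts, return_counts=True)
        return {int(v): float(f) / len(self.counts) for v, f in zip(vals, freq)}


def site_occupancy(
    traj: Trajectory,
    model: ProteinModel,
    site: BindingSite | Sequence[ResKey],
    cutoff: float = 5.5,
    species_filter: Sequence[str] | None = None,
) -> OccupancySeries:
    """Distinct lipid molecules within ``cutoff`` of any site residue,
    per frame; each lipid counts once however many residues it touches."""
    _validate_cutoff(traj, cutoff)
    keys = site.residues if isinstance(site, BindingSite) else tuple(site)
    dmin, _, _ = _min_dist_series(traj, model, keys, species_filter)
    counts = (dmin <= cutoff).sum(axis=1)
    return OccupancySeries(counts=counts.astype(int), times=traj.times,
                           cutoff=cutoff)


@dataclass
class ResidenceStats:
    """Contact-event durations for one residue or site.

    ``events`` are durations in ns; ``censored`` flags events still open
    at the final frame, which are excluded from the mean (they only put
    a lower bound on their duration) but included in the max.
    """

    key: str
    events: list[float]
    censored: list[bool]
    occupancy_histogram: dict[int, float]
    r_on: float
    r_off: float
    gap_frames: int

    @property
    def mean_residence(self) -> float:
        complete = [d for d, c in zip(self.events, self.censored) if not c]
        return float(np.mean(complete)) if complete else float("nan")

    @property
    def max_residence(self) -> float:
        return float(max(self.events)) if self.events else float("nan")

    @property
    def n_events(self) -> int:
        return len(self.events)


def _events_from_distances(
    d: np.ndarray, r_on: float, r_off: float, gap_frames: int
) -> list[tuple[int, int, bool]]:
    """Dual-cutoff event detection on one lipid's distance series.

    Returns (start_frame, end_frame_exclusive, censored) triples.  An
    event opens at the first frame at or below ``r_on`` and closes at
    the first frame of a run beyond ``r_off`` longer than
    ``gap_frames``; shorter excursions beyond ``r_off`` are bridged.
    """
    state = np.where(d <= r_on, 0, np.where(d > r_off, 2, 1)).astype(np.int8)
    # run-length encode
    boundaries = np.flatnonzero(np.r_[True, state[1:] != state[:-1]])
    run_states = state[boundaries]
    run_lens = np.diff(np.r_[boundaries, state.size])
    events: list[tuple[int, int, bool]] = []
    in_event = False
    start = 0
    for st, b, ln in zip(run_states, boundaries, run_lens):
        if not in_event:
            if st == 0:
                in_event, start = True, int(b)
        else:
            if st == 2 and ln > gap_frames:
                events.append((start, int(b), False))
                in_event = False
    if in_event:
        events.append((start, int(state.size), True))
    return events


def residence_times(
    traj: Trajectory,
    model: ProteinModel,
    key: BindingSite | ResKey | Sequence[ResKey],
    r_on: float = 5.5,
    r_off: float = 10.0,
    gap_frames: int = 0,
    species_filter: Sequence[str] | None = None,
) -> ResidenceStats:
    """Dual-cutoff residence-time estimation for a residue or site.

    ``r_off >= r_on`` suppresses single-frame flicker at the contact
    boundary; with ``r_off == r_on`` the estimator degenerates to naive
    contact runs.  Durations are in ns (frames x dt).
    """
    if r_off < r_on:
        raise ValueError("r_off must be >= r_on")
    if gap_frames < 0:
        raise ValueError("gap_frames must be >= 0")
    if isinstance(key, BindingSite):
        keys = key.residues
        desc = key.site_id
    elif key and isinstance(key[0], str):
        keys = (key,)                                 # single residue key
        desc = f"{key[0]}:{key[1]}"
    else:
        keys = tuple(key)
        desc = "+".join(f"{s}:{r}" for s, r in keys)
    dmin, mols, _ = _min_dist_series(traj, model, keys, species_filter)
    dt_ns = traj.dt / 1000.0
    events: list[float] = []
    censored: list[bool] = []
    for j in range(mols.size):
        for start, end, cens in _events_from_distances(
            dmin[:, j], r_on, r_off, gap_frames
        ):
            events.append((end - start) * dt_ns)
            censored.append(cens)
    counts = (dmin <= r_on).sum(axis=1)
    vals, freq = np.unique(counts, return_counts=True)
    hist = {int(v): float(f) / dmin.shape[0] for v, f in zip(vals, freq)}
    return ResidenceStats(
        key=desc, events=events, censored=censored,
        occupancy_histogram=hist, r_on=r_on, r_off=r_off, gap_frames=gap_frames,
    )
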