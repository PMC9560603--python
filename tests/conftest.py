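"""Shared fixtures: planted-truth synthetic runs and brute-force oracles.

The expensive default-scale runs (20,000 recorded frames) are computed
once per session and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import lipidfp as L
from lipidfp.core import STUDY_LIPIDS, build_composition
from lipidfp.pipeline import RunConfig, run
from lipidfp.synth import default_config, default_sites, plant_affinity_ratio


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and independent of the
# library kernels: plain python loops, float64 minimum image)
# ---------------------------------------------------------------------------

def min_image_dist(a, b, box):
    d = 0.0
    for ax in range(3):
        dx = float(a[ax]) - float(b[ax])
        L = float(box[ax])
        dx -= L * round(dx / L)
        d += dx * dx
    return d ** 0.5


def brute_force_contacts(traj, model, cutoff, species_filter=None):
    """(residue_key, species) -> raw count, by exhaustive triple loop."""
    bt = traj.bead_table
    counts: dict[tuple[tuple[str, int], str], int] = {}
    prot = [(i, tuple(bt.species[i].split(":"))) for i in range(len(bt))
            if bt.kind[i] == "protein"]
    heads = [i for i in range(len(bt)) if bt.kind[i] == "lipid" and bt.is_head[i]
             and (species_filter is None or bt.species[i] in species_filter)]
    mols = sorted({int(bt.mol_id[i]) for i in heads})
    for f in traj.frames:
        for key_s in {k for _, k in prot}:
            key = (key_s[0], int(key_s[1]))
            beads = [i for i, k in prot if (k[0], int(k[1])) == key]
            for m in mols:
                mheads = [i for i in heads if bt.mol_id[i] == m]
                sp = bt.species[mheads[0]]
                touching = any(
                    min_image_dist(f.coords[b], f.coords[h], f.box) <= cutoff
                    for b in beads for h in mheads
                )
                if touching:
                    counts[(key, sp)] = counts.get((key, sp), 0) + 1
    return counts


def brute_force_annulus(traj, cutoff):
    """Per-frame distinct-lipid counts touching any protein bead."""
    bt = traj.bead_table
    prot = [i for i in range(len(bt)) if bt.kind[i] == "protein"]
    heads = [i for i in range(len(bt)) if bt.kind[i] == "lipid" and bt.is_head[i]]
    out = []
    for f in traj.frames:
        mols = set()
        for h in heads:
            if any(min_image_dist(f.coords[p], f.coords[h], f.box) <= cutoff
                   for p in prot):
                mols.add(int(bt.mol_id[h]))
        out.append(len(mols))
    return out


def brute_force_occupancy(traj, model, residue_keys, cutoff):
    """Per-frame distinct lipids within cutoff of any listed residue."""
    bt = traj.bead_table
    wanted = {f"{s}:{r}" for s, r in residue_keys}
    beads = [i for i in range(len(bt))
             if bt.kind[i] == "protein" and bt.species[i] in wanted]
    heads = [i for i in range(len(bt)) if bt.kind[i] == "lipid" and bt.is_head[i]]
    out = []
    for f in traj.frames:
        mols = set()
        for h in heads:
            if any(min_image_dist(f.coords[b], f.coords[h], f.box) <= cutoff
                   for b in beads):
                mols.add(int(bt.mol_id[h]))
        out.append(len(mols))
    return out


def brute_force_events(distances, r_on, r_off, gap_frames):
    """Exhaustive frame-by-frame dual-cutoff state machine."""
    events = []
    in_event = False
    start = 0
    i = 0
    n = len(distances)
    while i < n:
        d = distances[i]
        if not in_event:
            if d <= r_on:
                in_event, start = True, i
            i += 1
        else:
            if d > r_off:
                j = i
                while j < n and distances[j] > r_off:
                    j += 1
                if j - i > gap_frames:
                    events.append((start, i, False))
                    in_event = False
                i = j
            else:
                i += 1
    if in_event:
        events.append((start, n, True))
    return events


def toy_system(res_positions, lipid_frames, box=(40.0, 40.0, 40.0),
               species=None, dt=100.0, charges=None):
    """Small hand-built model + trajectory.

    ``res_positions``: (n_res, 3) static protein bead positions (one bead
    per residue, chain A, resnums 1..n).  ``lipid_frames``: (n_frames,
    n_lip, 3) head bead coordinates.  ``species``: per-lipid species
    names (default POPA).
    """
    from lipidfp.core import (
        BeadTable, Frame, ProteinModel, ResidueRecord, Trajectory,
    )

    res_positions = np.asarray(res_positions, dtype=float)
    lipid_frames = np.asarray(lipid_frames, dtype=float)
    n_res = len(res_positions)
    n_lip = lipid_frames.shape[1]
    species = list(species) if species is not None else ["POPA"] * n_lip
    charges = list(charges) if charges is not None else [0] * n_res
    residues = [
        ResidueRecord(i + 1, "ALA", "A", charge=charges[i],
                      ref_position=res_positions[i])
        for i in range(n_res)
    ]
    model = ProteinModel(residues, res_positions, np.arange(n_res))
    bt = BeadTable(
        kind=np.array(["protein"] * n_res + ["lipid"] * n_lip, dtype=object),
        mol_id=np.r_[np.full(n_res, -1), np.arange(n_lip)],
        species=np.array([f"A:{i + 1}" for i in range(n_res)] + species,
                         dtype=object),
        label=np.array(["BB"] * n_res + ["PO4"] * n_lip, dtype=object),
        is_head=np.array([False] * n_res + [True] * n_lip),
    )
    frames = [
        Frame(time=i * dt, box=np.asarray(box, dtype=float),
              coords=np.vstack([res_positions, lipid_frames[i]]))
        for i in range(len(lipid_frames))
    ]
    return model, Trajectory(frames, dt=dt, bead_table=bt)


# ---------------------------------------------------------------------------
# session-scoped planted-truth runs
# ---------------------------------------------------------------------------

PLANTED_KEYS = frozenset(
    {("A", r) for r in L.synth.DISTAL_RESNUMS}
    | {("B", r) for r in L.synth.DISTAL_RESNUMS}
    | {(s, r) for s in "AB" for r in L.synth.INTERFACIAL_RESNUMS}
)

INTERFACIAL_1_KEYS = [("A", 189), ("A", 205), ("B", 248), ("B", 249)]


@pytest.fixture(scope="session")
def scaffold_model():
    return L.generate_scaffold(260, default_sites())


def _wt_config(seed: int) -> RunConfig:
    toggles = dict(contacts=True, sites=True, kinetics=(seed == 1),
                   density=(seed == 1), windows=(seed == 1))
    return RunConfig(synth=default_config(seed=seed), seed=seed,
                     toggles=toggles)


@pytest.fixture(scope="session")
def wt_results():
    """Wild-type default-scale pipeline runs, seeds 1-3."""
    return {seed: run(_wt_config(seed)) for seed in (1, 2, 3)}


@pytest.fixture(scope="session")
def ko_result():
    """Seed-1 run with the first interfacial site knocked out."""
    cfg = default_config(seed=1)
    cfg = L.knockout(cfg, INTERFACIAL_1_KEYS)
    return run(RunConfig(synth=cfg, seed=1,
                         toggles=dict(contacts=True, sites=True,
                                      kinetics=False, density=False,
                                      windows=False)))


@pytest.fixture(scope="session")
def affinity_recovery():
    """Planted 3:1 POPA:POPG affinity, measured fold-enrichment, seeds 1-3.

    Two species, 100 copies each; well depths calibrated so the
    quadrature-predicted stationary contact ratio is exactly 3, then the
    dynamics + contact pipeline must recover it.
    """
    comp = build_composition(
        [(STUDY_LIPIDS["POPA"], 50.0), (STUDY_LIPIDS["POPG"], 50.0)], 200
    )
    sites = default_sites(species_affinity={"POPA": 1.0, "POPG": 1.0})
    model = L.generate_scaffold(260, sites)
    base = default_config(seed=1, composition=comp, sites=sites)
    planted = sorted(PLANTED_KEYS)
    calibrated = plant_affinity_ratio(base, model, "POPA", "POPG", 3.0)
    ratios = []
    from dataclasses import replace

    for seed in (1, 2, 3):
        cfg = replace(calibrated, seed=seed)
        traj = L.simulate(cfg, model)
        table = L.normalize([L.count_contacts(traj, model, 5.5)], comp)
        _, aggregate = L.fold_enrichment(table, "POPA", "POPG",
                                         residue_set=planted)
        ratios.append(aggregate)
    return ratios


# ---------------------------------------------------------------------------
# stationary-state checks of the simulator (shared by unit + acceptance)
# ---------------------------------------------------------------------------

def single_well_system(depth, seed=1, n_steps=40_000, write_every=40,
                       dt_ps=10.0, diffusion_coeff=0.05):
    """One residue, one Gaussian well, far from the footprint: the
    minimal system whose stationary state is known up to quadrature."""
    from lipidfp.core import ProteinModel, ResidueRecord
    from lipidfp.synth import SiteSpec, SynthConfig

    pos = np.array([150.0, 100.0, 32.0])
    model = ProteinModel(
        [ResidueRecord(1, "LYS", "A", charge=1, ref_position=pos)],
        pos.reshape(1, 3), np.array([0]),
    )
    comp = build_composition([(STUDY_LIPIDS["POPA"], 100.0)], 100,
                             leaflet_split=0.0)
    site = SiteSpec("w", (("A", 1),), {"POPA": depth}, well_width=6.0)
    cfg = SynthConfig(box=(200.0, 200.0, 100.0), composition=comp,
                      sites=(site,), n_steps=n_steps, dt_ps=dt_ps,
                      write_every=write_every,
                      diffusion_coeff=diffusion_coeff, seed=seed)
    return cfg, model


def disc_counts(traj, n_prot, centre, radius):
    xy = np.stack([f.coords[n_prot:, :2] for f in traj.frames]).astype(float)
    d = np.sqrt(((xy - np.asarray(centre)) ** 2).sum(-1))
    return (d <= radius).sum(axis=1)


@pytest.fixture(scope="session")
def flat_density_check():
    """Zero-depth well: observed vs uniform-expected occupancy of the
    would-be site disc.  Frames are written 2.4 ns apart: 2D disc
    occupancy decorrelates slowly (diffusive re-entries), and at this
    spacing the deviation statistic is unit-variance across seeds, so
    Poisson standard errors are valid."""
    from lipidfp.synth import potential_grid, simulate

    cfg, model = single_well_system(0.0, seed=11, n_steps=240_000,
                                    write_every=240)
    traj = simulate(cfg, model)
    counts = disc_counts(traj, 1, (150.0, 100.0), 6.0)
    x, y, U = potential_grid(cfg, model, "POPA")
    w = np.exp(-np.where(np.isfinite(U), U, np.inf))
    X, Y = np.meshgrid(x, y)
    frac = w[(X - 150.0) ** 2 + (Y - 100.0) ** 2 <= 36.0].sum() / w.sum()
    expected_total = frac * 100 * len(traj)
    return dict(observed=float(counts.sum()), expected=float(expected_total),
                poisson_se=float(np.sqrt(expected_total)))


@pytest.fixture(scope="session")
def boltzmann_well_check():
    """2 kT well: measured occupancy ratio (well disc vs equal-area bulk
    patch) vs the quadrature of exp(-U), pooled over seeds 1-3, with a
    batch-mean standard error."""
    from lipidfp.synth import potential_grid, simulate

    ratios, batch_means = [], []
    expected = None
    for seed in (1, 2, 3):
        cfg, model = single_well_system(2.0, seed=seed, n_steps=100_000,
                                        write_every=2)
        traj = simulate(cfg, model)
        burn = len(traj) // 10
        cin = disc_counts(traj, 1, (150.0, 100.0), 6.0)[burn:]
        cbk = disc_counts(traj, 1, (60.0, 40.0), 6.0)[burn:]
        ratios.append(cin.mean() / cbk.mean())
        nb, bs = 10, len(cin) // 10
        batch_means += [
            cin[i * bs:(i + 1) * bs].mean() / cbk[i * bs:(i + 1) * bs].mean()
            for i in range(nb)
        ]
        if expected is None:
            x, y, U = potential_grid(cfg, model, "POPA")
            w = np.exp(-np.where(np.isfinite(U), U, np.inf))
            X, Y = np.meshgrid(x, y)
            m_in = (X - 150.0) ** 2 + (Y - 100.0) ** 2 <= 36.0
            m_bk = (X - 60.0) ** 2 + (Y - 40.0) ** 2 <= 36.0
            expected = w[m_in].sum() / w[m_bk].sum()
    se = float(np.std(batch_means, ddof=1) / np.sqrt(len(batch_means)))
    return dict(measured=float(np.mean(ratios)), expected=float(expected),
                se=se)


def planted_site_recovered(detected_sites, site_spec, min_fraction=0.9):
    """True if some detected site contains >= min_fraction of the planted
    site's residues and carries the expected class label."""
    want = set(site_spec.residue_keys)
    want_class = ("interfacial" if site_spec.site_id.startswith("interfacial")
                  else "distal")
    need = int(np.ceil(min_fraction * len(want)))
    for s in detected_sites:
        if len(want & set(s.residues)) >= need and s.site_class == want_class:
            return True
    return False
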