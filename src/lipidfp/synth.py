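"""Seeded synthetic membrane trajectories with planted binding sites.

This module replaces multi-microsecond coarse-grained MD with a
Brownian-dynamics surrogate whose stationary statistics are known by
construction, so that every downstream analysis (contact fingerprints,
density maps, site detection, kinetics) can be validated against a
planted ground truth.

The physical picture is deliberately minimal:

* a static pseudo-homodimeric protein occupies a repulsive disc of
  radius ``protein_footprint_radius`` in the middle of a periodic
  bilayer patch;
* lipids are single headgroup beads diffusing in two independent 2D
  leaflet planes (no flip-flop), integrated with the Euler-Maruyama
  scheme for overdamped Langevin dynamics;
* anionic species are attracted to planted clusters of cationic
  residues through Gaussian potential wells (depth in kT, per species),
  placed in one leaflet only;
* a knockout mode zeroes the wells of chosen residues, emulating
  charge-neutralising K->A double-site mutants.

Energies are expressed in units of kT, so the stationary density is
``exp(-U)`` and can be cross-checked by direct quadrature
(:func:`stationary_contact_rate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    STUDY_LIPIDS,
    BeadTable,
    BilayerComposition,
    Frame,
    ProteinModel,
    ResidueRecord,
    Trajectory,
    build_composition,
)

__all__ = [
    "SiteSpec",
    "SynthConfig",
    "DISTAL_RESNUMS",
    "INTERFACIAL_RESNUMS",
    "default_sites",
    "default_composition",
    "mixed_anionic_composition",
    "default_config",
    "generate_scaffold",
    "simulate",
    "knockout",
    "lipid_layout",
    "potential_grid",
    "stationary_contact_rate",
    "plant_affinity_ratio",
]

# footprint soft-core: harmonic spring constant (kT/A^2) inside the disc,
# with a reflecting wall at R - FOOTPRINT_TOL so no bead penetrates deeper
FOOTPRINT_K = 1.0
FOOTPRINT_TOL = 0.5


@dataclass(frozen=True)
class SiteSpec:
    """A planted lipid binding site.

    ``well_depth_per_species`` maps species name to the per-residue
    Gaussian well depth in kT (attractive; missing species feel no
    well).  ``anchor_deg`` positions the site on the protein rim when
    the scaffold is generated (angle about the dimer axis, subunit A
    occupying (-90, 90) degrees).
    """

    site_id: str
    residue_keys: tuple[tuple[str, int], ...]
    well_depth_per_species: dict[str, float]
    well_width: float = 6.0
    leaflet: str = "lower"
    anchor_deg: float | None = None

    def __post_init__(self) -> None:
        if not self.residue_keys:
            raise ValueError(f"site {self.site_id}: residue_keys empty")
        if self.well_width <= 0:
            raise ValueError(f"site {self.site_id}: well_width must be > 0")
        if any(d < 0 for d in self.well_depth_per_species.values()):
            raise ValueError(f"site {self.site_id}: well depths must be >= 0")
        if self.leaflet not in ("lower", "upper"):
            raise ValueError(f"site {self.site_id}: leaflet must be lower|upper")


@dataclass(frozen=True)
class SynthConfig:
    """Full description of one synthetic run; output is a pure function
    of this object (see the RNG stream note in :func:`simulate`)."""

    box: tuple[float, float, float]
    composition: BilayerComposition
    sites: tuple[SiteSpec, ...]
    n_steps: int = 20_000
    dt_ps: float = 40.0
    write_every: int = 1
    diffusion_coeff: float = 0.02      # A^2/ps, lateral lipid diffusion
    seed: int = 0
    protein_footprint_radius: float = 30.0
    knockouts: tuple[tuple[str, int], ...] = ()
    leaflet_offset: float = 18.0       # headgroup plane |z - midplane| (A)
    z_jitter: float = 1.0              # per-frame headgroup z noise sigma (A)

    def __post_init__(self) -> None:
        if min(self.box) <= 0 or self.n_steps <= 0 or self.dt_ps <= 0:
            raise ValueError("box, n_steps and dt_ps must be positive")
        if self.write_every <= 0 or self.diffusion_coeff <= 0:
            raise ValueError("write_every and diffusion_coeff must be positive")
        if self.protein_footprint_radius <= 0 or self.leaflet_offset <= 0:
            raise ValueError("footprint radius and leaflet offset must be positive")
        site_keys = {k for s in self.sites for k in s.residue_keys}
        unknown = [k for k in self.knockouts if k not in site_keys]
        if unknown:
            raise ValueError(f"knockout keys not in any site: {unknown}")

    @property
    def leaflet_z(self) -> dict[str, float]:
        zmid = self.box[2] / 2.0
        return {"lower": zmid - self.leaflet_offset,
                "upper": zmid + self.leaflet_offset}


# ---------------------------------------------------------------------------
# default planted layout
# ---------------------------------------------------------------------------

#: Residue numbers of the nine-residue distal site (per subunit) and the
#: four-residue interfacial sites of the default scaffold.  The numbers
#: are scaffold-internal identifiers, not positions in any real protein.
DISTAL_RESNUMS = (27, 28, 43, 96, 100, 104, 120, 151, 152)
INTERFACIAL_RESNUMS = (189, 205, 248, 249)

#: Relative per-species affinity scale for the planted wells.  POPA-like
#: dianionic lipids bind strongest among the glycerophospholipids,
#: POPG/POPS weaker, PIP2 strongest, zwitterionic species not at all.
DEFAULT_SPECIES_AFFINITY = {"POPA": 1.0, "POPG": 0.5, "POPS": 0.4, "PIP2": 1.2}


def default_sites(
    species_affinity: dict[str, float] | None = None,
    distal_depth: float = 1.0,
    interfacial_depth: float = 0.8,
) -> tuple[SiteSpec, ...]:
    """The default planted-site layout.

    Two symmetric nine-residue distal sites (one per subunit, deep and
    wide wells: large capacity, slow exchange) and two four-residue
    interfacial sites straddling the subunit boundary (shallower,
    narrower wells: small capacity, fast exchange), all in the lower
    (cytoplasmic) leaflet.
    """
    aff = DEFAULT_SPECIES_AFFINITY if species_affinity is None else species_affinity

    def depths(base: float) -> dict[str, float]:
        return {name: base * scale for name, scale in aff.items()}

    i1, i2, i3, i4 = INTERFACIAL_RESNUMS
    return (
        SiteSpec("distal_A", tuple(("A", r) for r in DISTAL_RESNUMS),
                 depths(distal_depth), well_width=6.0, leaflet="lower",
                 anchor_deg=0.0),
        SiteSpec("distal_B", tuple(("B", r) for r in DISTAL_RESNUMS),
                 depths(distal_depth), well_width=6.0, leaflet="lower",
                 anchor_deg=180.0),
        SiteSpec("interfacial_1",
                 (("A", i1), ("A", i2), ("B", i3), ("B", i4)),
                 depths(interfacial_depth), well_width=4.0, leaflet="lower",
                 anchor_deg=90.0),
        SiteSpec("interfacial_2",
                 (("B", i1), ("B", i2), ("A", i3), ("A", i4)),
                 depths(interfacial_depth), well_width=4.0, leaflet="lower",
                 anchor_deg=270.0),
    )


def default_composition(total: int = 200) -> BilayerComposition:
    """80% POPE / 20% POPA, the workhorse anionic test bilayer."""
    return build_composition(
        [(STUDY_LIPIDS["POPE"], 80.0), (STUDY_LIPIDS["POPA"], 20.0)], total
    )


def mixed_anionic_composition(total: int = 200) -> BilayerComposition:
    """70% POPE with 10% each of POPA, POPG and POPS (equal anionic mix)."""
    return build_composition(
        [(STUDY_LIPIDS["POPE"], 70.0), (STUDY_LIPIDS["POPA"], 10.0),
         (STUDY_LIPIDS["POPG"], 10.0), (STUDY_LIPIDS["POPS"], 10.0)],
        total,
    )


def default_config(
    seed: int,
    composition: BilayerComposition | None = None,
    sites: tuple[SiteSpec, ...] | None = None,
    n_steps: int = 20_000,
    **overrides,
) -> SynthConfig:
    """The default test-scale run: 200 x 200 A patch, 30 A footprint,
    40 ps steps, 20,000 recorded frames."""
    return SynthConfig(
        box=(200.0, 200.0, 100.0),
        composition=composition or default_composition(),
        sites=default_sites() if sites is None else sites,
        n_steps=n_steps,
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# scaffold generation
# ---------------------------------------------------------------------------

def _subunit_of_angle(theta_deg: float) -> str:
    t = theta_deg % 360.0
    return "A" if (t < 90.0 or t > 270.0) else "B"


def generate_scaffold(
    n_residues_per_subunit: int = 260,
    site_layout: Sequence[SiteSpec] = (),
    box: tuple[float, float, float] = (200.0, 200.0, 100.0),
    footprint_radius: float = 30.0,
    leaflet_offset: float = 18.0,
    site_arc_spacing: float = 5.0,
    ring_step: float = 3.0,
    ring_arc_spacing: float = 1.2,
    guard_distance: float = 10.0,
) -> ProteinModel:
    """Deterministic pseudo-homodimer scaffold.

    Two subunits (A occupying angles (-90, 90) degrees about the dimer
    axis, B the opposite half) are laid out as beads on concentric
    rings inside the protein footprint, one bead per residue.  Site
    residues are cationic (+1, named LYS) and sit on the footprint rim
    at their site's anchor angle, in their site's leaflet plane;
    background residues (charge 0, named ALA) fill inner rings with
    alternating leaflet-plane z.  Background residues that would land
    within ``guard_distance`` of a planted site in the same leaflet are
    moved to the other leaflet plane, so the planted enrichment is not
    aliased onto unplanted residues.

    The scaffold is schematic plumbing: it reproduces the *statistical*
    situation of a homodimer with rim-exposed binding residues, not any
    real protein geometry.
    """
    cx, cy = box[0] / 2.0, box[1] / 2.0
    zmid = box[2] / 2.0
    z_of = {"lower": zmid - leaflet_offset, "upper": zmid + leaflet_offset}
    R = footprint_radius

    site_positions: dict[tuple[str, int], np.ndarray] = {}
    site_leaflet: dict[tuple[str, int], str] = {}
    for i_site, site in enumerate(site_layout):
        anchor = (site.anchor_deg if site.anchor_deg is not None
                  else i_site * 360.0 / max(len(site_layout), 1))
        m = len(site.residue_keys)
        dtheta = math.degrees(site_arc_spacing / R)
        slots = [anchor + (j - (m - 1) / 2.0) * dtheta for j in range(m)]
        by_sub: dict[str, list[float]] = {"A": [], "B": []}
        for ang in slots:
            by_sub[_subunit_of_angle(ang)].append(ang)
        want: dict[str, list[tuple[str, int]]] = {"A": [], "B": []}
        for key in site.residue_keys:
            if key in site_positions:
                raise ValueError(f"residue {key} appears in more than one site")
            want.setdefault(key[0], []).append(key)
        for sub in ("A", "B"):
            if len(want.get(sub, [])) != len(by_sub[sub]):
                raise ValueError(
                    f"site {site.site_id}: cannot place {len(want.get(sub, []))} "
                    f"residue(s) of subunit {sub} at anchor {anchor} deg "
                    f"({len(by_sub[sub])} slot(s) fall in that subunit's half)"
                )
            for key, ang in zip(want[sub], sorted(by_sub[sub])):
                rad = math.radians(ang)
                site_positions[key] = np.array(
                    [cx + R * math.cos(rad), cy + R * math.sin(rad),
                     z_of[site.leaflet]]
                )
                site_leaflet[key] = site.leaflet

    for (sub, resnum) in site_positions:
        if sub not in ("A", "B"):
            raise ValueError(f"scaffold subunits are A and B, got {sub!r}")
        if not (1 <= resnum <= n_residues_per_subunit):
            raise ValueError(
                f"site residue number {resnum} outside 1..{n_residues_per_subunit}"
            )

    site_xyz_by_leaflet = {
        leaf: np.array([p for k, p in site_positions.items()
                        if site_leaflet[k] == leaf]).reshape(-1, 3)
        for leaf in ("lower", "upper")
    }

    # background ring slots per subunit, outer rings first
    def ring_slots(sub: str, n_needed: int) -> list[tuple[float, float]]:
        base = 0.0 if sub == "A" else 180.0
        slots: list[tuple[float, float]] = []
        r = R - ring_step
        while r > 0 and len(slots) < n_needed:
            arc = math.pi * r * (160.0 / 180.0)   # 10 deg margin each side
            n_max = max(1, int(arc / ring_arc_spacing))
            n_here = min(n_max, n_needed - len(slots))
            for j in range(n_here):
                frac = (j + 0.5) / n_here
                slots.append((r, base - 80.0 + frac * 160.0))
            r -= ring_step
        if len(slots) < n_needed:
            raise ValueError(
                f"scaffold geometry cannot host {n_needed} background "
                f"residues per subunit; reduce n_residues_per_subunit"
            )
        return slots

    residues: list[ResidueRecord] = []
    coords: list[np.ndarray] = []
    for sub in ("A", "B"):
        background = [r for r in range(1, n_residues_per_subunit + 1)
                      if (sub, r) not in site_positions]
        slots = ring_slots(sub, len(background))
        bg_pos: dict[int, np.ndarray] = {}
        for k, (resnum, (r, ang)) in enumerate(zip(background, slots)):
            preferred = "lower" if k % 2 == 0 else "upper"
            rad = math.radians(ang)
            xy = np.array([cx + r * math.cos(rad), cy + r * math.sin(rad)])
            leaf = preferred
            for candidate in (preferred, "upper" if preferred == "lower" else "lower"):
                pts = site_xyz_by_leaflet[candidate]
                if pts.size == 0:
                    leaf = candidate
                    break
                d = np.sqrt(((pts[:, :2] - xy) ** 2).sum(axis=1)).min()
                if d >= guard_distance:
                    leaf = candidate
                    break
            bg_pos[resnum] = np.array([xy[0], xy[1], z_of[leaf]])

        for resnum in range(1, n_residues_per_subunit + 1):
            key = (sub, resnum)
            if key in site_positions:
                pos = site_positions[key]
                residues.append(ResidueRecord(
                    index=resnum, name="LYS", subunit=sub, charge=1,
                    ref_position=pos,
                ))
            else:
                pos = bg_pos[resnum]
                residues.append(ResidueRecord(
                    index=resnum, name="ALA", subunit=sub, charge=0,
                    ref_position=pos,
                ))
            coords.append(pos)

    return ProteinModel(
        residues, np.asarray(coords), np.arange(len(residues)),
        ["BB"] * len(residues),
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def lipid_layout(config: SynthConfig) -> pd.DataFrame:
    """The deterministic lipid ordering of :func:`simulate`.

    Lower-leaflet lipids come first, then upper-leaflet; within a
    leaflet, species follow composition order.  Columns: ``mol_id``,
    ``species``, ``leaflet``.
    """
    rows = []
    mol = 0
    for leaf, slot in (("lower", 1), ("upper", 0)):
        for sp in config.composition.species:
            n = config.composition.per_leaflet_counts[sp.name][slot]
            for _ in range(n):
                rows.append(dict(mol_id=mol, species=sp.name, leaflet=leaf))
                mol += 1
    return pd.DataFrame(rows)


def _well_arrays(
    config: SynthConfig, model: ProteinModel, leaflet: str
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Well centres (nw, 2), widths (nw,), per-species depth rows (nw,).

    Knocked-out residues contribute a zero-depth well (kept in the
    arrays so indices stay stable)."""
    centres, widths = [], []
    depth_rows: dict[str, list[float]] = {
        sp.name: [] for sp in config.composition.species
    }
    ko = set(config.knockouts)
    for site in config.sites:
        if site.leaflet != leaflet:
            continue
        for key in site.residue_keys:
            rec = model.residue(key)
            centres.append(rec.ref_position[:2])
            widths.append(site.well_width)
            for name in depth_rows:
                d = 0.0 if key in ko else site.well_depth_per_species.get(name, 0.0)
                depth_rows[name].append(d)
    c = np.asarray(centres, dtype=float).reshape(-1, 2)
    w = np.asarray(widths, dtype=float)
    return c, w, {k: np.asarray(v, dtype=float) for k, v in depth_rows.items()}


def _min_image_xy(d: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    return d - box_xy * np.round(d / box_xy)


def simulate(config: SynthConfig, model: ProteinModel) -> Trajectory:
    """Integrate the overdamped Langevin dynamics and record frames.

    RNG stream order (single ``numpy.random.default_rng(seed)``):

    1. initial xy positions, lower leaflet then upper, rejection-sampled
       uniformly outside the footprint;
    2. z jitter of the initial frame (all lipids, layout order);
    3. per integration step: one ``(n_lipids, 2)`` normal draw (layout
       order), then, if the step is recorded, one ``(n_lipids,)`` z
       jitter draw.

    Raises if the free-diffusion RMS step exceeds half the narrowest
    well width (the Euler-Maruyama step would not resolve the wells).
    """
    D, dt = config.diffusion_coeff, config.dt_ps
    rms_step = math.sqrt(4.0 * D * dt)
    min_width = min((s.well_width for s in config.sites), default=np.inf)
    if rms_step > min_width / 2.0:
        raise ValueError(
            f"dt too large: RMS free step {rms_step:.2f} A exceeds half the "
            f"narrowest well width ({min_width / 2.0:.2f} A); reduce dt_ps "
            "or diffusion_coeff"
        )

    box = np.asarray(config.box, dtype=float)
    box_xy = box[:2]
    centre_xy = box_xy / 2.0
    R = config.protein_footprint_radius
    r_wall = R - FOOTPRINT_TOL
    layout = lipid_layout(config)
    n_lip = len(layout)
    leaf_arr = layout["leaflet"].to_numpy()
    species_arr = layout["species"].to_numpy()
    z_of = config.leaflet_z

    rng = np.random.default_rng(config.seed)

    # positions, lower then upper, rejection sampling outside footprint
    pos = np.empty((n_lip, 2))
    for leaf in ("lower", "upper"):
        idx = np.flatnonzero(leaf_arr == leaf)
        placed = 0
        while placed < len(idx):
            cand = rng.uniform(0.0, box_xy, size=(len(idx) - placed, 2))
            rel = cand - centre_xy
            ok = (rel ** 2).sum(axis=1) >= R * R
            n_ok = int(ok.sum())
            pos[idx[placed:placed + n_ok]] = cand[ok]
            placed += n_ok

    # per-leaflet well arrays and per-lipid depth matrices
    leaf_data: dict[str, dict] = {}
    for leaf in ("lower", "upper"):
        idx = np.flatnonzero(leaf_arr == leaf)
        centres, widths, depth_rows = _well_arrays(config, model, leaf)
        depths = (
            np.stack([depth_rows[s] for s in species_arr[idx]])
            if centres.shape[0] and len(idx)
            else np.zeros((len(idx), centres.shape[0]))
        )
        leaf_data[leaf] = dict(
            idx=idx, centres=centres, inv_w2=1.0 / widths ** 2 if widths.size else widths,
            depths=depths,
        )

    # protein beads (static) + lipid beads
    n_prot = model.n_beads
    prot_coords = model.bead_coords.astype(np.float32)
    prot_keys = [f"{r.subunit}:{r.index}"
                 for r in (model.residues[i] for i in model.bead_residue)]
    bt = BeadTable(
        kind=np.array(["protein"] * n_prot + ["lipid"] * n_lip, dtype=object),
        mol_id=np.concatenate([np.full(n_prot, -1),
                               layout["mol_id"].to_numpy()]),
        species=np.array(
            prot_keys
            + [config.composition.get_species(s).name for s in species_arr],
            dtype=object,
        ),
        label=np.array(
            [model.bead_labels[i] for i in range(n_prot)]
            + [config.composition.get_species(s).head_bead for s in species_arr],
            dtype=object,
        ),
        is_head=np.array([False] * n_prot + [True] * n_lip),
    )

    z_plane = np.array([z_of[l] for l in leaf_arr])

    def forces(p: np.ndarray, data: dict) -> np.ndarray:
        f = np.zeros_like(p)
        centres, depths = data["centres"], data["depths"]
        if centres.shape[0]:
            disp = _min_image_xy(centres[None, :, :] - p[:, None, :], box_xy)
            d2 = (disp ** 2).sum(axis=2)
            g = depths * np.exp(-0.5 * d2 * data["inv_w2"])
            f += np.einsum("nw,nwk,w->nk", g, disp, data["inv_w2"])
        rel = p - centre_xy
        r = np.sqrt((rel ** 2).sum(axis=1))
        inside = r < R
        if inside.any():
            push = FOOTPRINT_K * (R - r[inside]) / np.maximum(r[inside], 1e-12)
            f[inside] += push[:, None] * rel[inside]
        return f

    def wall_and_wrap(p: np.ndarray) -> np.ndarray:
        rel = _min_image_xy(p - centre_xy, box_xy)
        r = np.sqrt((rel ** 2).sum(axis=1))
        deep = r < r_wall
        if deep.any():
            # mirror reflection at the wall; degenerate overshoots clamp
            r_new = 2.0 * r_wall - r[deep]
            r_new = np.clip(r_new, r_wall, None)
            p[deep] = centre_xy + rel[deep] * (r_new / np.maximum(r[deep], 1e-12))[:, None]
        return np.mod(p, box_xy)

    frames: list[Frame] = []

    def record(step: int) -> None:
        jitter = rng.standard_normal(n_lip) * config.z_jitter
        coords = np.empty((n_prot + n_lip, 3), dtype=np.float32)
        coords[:n_prot] = prot_coords
        coords[n_prot:, :2] = pos
        coords[n_prot:, 2] = z_plane + jitter
        frames.append(Frame(time=step * dt, box=box.copy(), coords=coords))

    record(0)
    sigma = math.sqrt(2.0 * D * dt)
    for step in range(1, config.n_steps + 1):
        xi = rng.standard_normal((n_lip, 2))
        for leaf in ("lower", "upper"):
            data = leaf_data[leaf]
            idx = data["idx"]
            if not len(idx):
                continue
            p = pos[idx]
            p = p + D * dt * forces(p, data) + sigma * xi[idx]
            pos[idx] = wall_and_wrap(p)
        if step % config.write_every == 0:
            record(step)

    return Trajectory(
        frames, dt=dt * config.write_every, bead_table=bt,
        replicate_id=f"synth-seed{config.seed}",
    )


def knockout(
    config: SynthConfig, residue_keys: Sequence[tuple[str, int]]
) -> SynthConfig:
    """Return a config whose listed residues contribute zero wells.

    Emulates charge-neutralising double-site mutants: binding at the
    knocked-out residues is abolished while intact sites are untouched.
    Idempotent; unknown keys raise.
    """
    keys = [(str(s), int(r)) for s, r in residue_keys]
    site_keys = {k for s in config.sites for k in s.residue_keys}
    unknown = [k for k in keys if k not in site_keys]
    if unknown:
        raise KeyError(f"knockout keys not in any site: {unknown}")
    merged = tuple(dict.fromkeys(tuple(config.knockouts) + tuple(keys)))
    return replace(config, knockouts=merged)


# ---------------------------------------------------------------------------
# stationary-state quadrature (calibration and oracle)
# ---------------------------------------------------------------------------

def potential_grid(
    config: SynthConfig,
    model: ProteinModel,
    species_name: str,
    leaflet: str = "lower",
    grid: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Potential energy surface U(x, y) in kT for one species/leaflet.

    Returns bin-centre coordinate vectors ``x``, ``y`` and the ``(ny, nx)``
    energy array; points inside the reflecting wall are ``+inf``.
    Includes the footprint soft-core term, so ``exp(-U)`` is the
    stationary density up to normalisation.
    """
    box = np.asarray(config.box, dtype=float)
    nx = int(round(box[0] / grid))
    ny = int(round(box[1] / grid))
    x = (np.arange(nx) + 0.5) * (box[0] / nx)
    y = (np.arange(ny) + 0.5) * (box[1] / ny)
    X, Y = np.meshgrid(x, y)
    centres, widths, depth_rows = _well_arrays(config, model, leaflet)
    U = np.zeros_like(X)
    depths = depth_rows.get(species_name)
    if depths is None:
        raise KeyError(f"species {species_name!r} not in composition")
    for (cxw, cyw), w, d in zip(centres, widths, depths):
        if d == 0.0:
            continue
        dx = X - cxw
        dx -= box[0] * np.round(dx / box[0])
        dy = Y - cyw
        dy -= box[1] * np.round(dy / box[1])
        U -= d * np.exp(-0.5 * (dx * dx + dy * dy) / (w * w))
    cx, cy = box[0] / 2.0, box[1] / 2.0
    r = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
    R = config.protein_footprint_radius
    soft = r < R
    U[soft] += 0.5 * FOOTPRINT_K * (R - r[soft]) ** 2
    U[r < R - FOOTPRINT_TOL] = np.inf
    return x, y, U


def stationary_contact_rate(
    config: SynthConfig,
    model: ProteinModel,
    species_name: str,
    residue_keys: Sequence[tuple[str, int]],
    cutoff: float,
    leaflet: str = "lower",
    grid: float = 0.5,
) -> float:
    """Predicted per-copy contact probability from the Boltzmann weight.

    Direct quadrature of ``exp(-U)`` over the union of contact discs
    around the listed residues (radius shrunk by each residue's offset
    from the leaflet headgroup plane), divided by the quadrature over
    the whole accessible leaflet.  Independent of the dynamics: this is
    the stationary answer the simulator must approach.
    """
    x, y, U = potential_grid(config, model, species_name, leaflet, grid)
    X, Y = np.meshgrid(x, y)
    box = np.asarray(config.box, dtype=float)
    z_plane = config.leaflet_z[leaflet]
    region = np.zeros_like(U, dtype=bool)
    for key in residue_keys:
        p = model.residue(key).ref_position
        dz = p[2] - z_plane
        r2 = cutoff * cutoff - dz * dz
        if r2 <= 0:
            continue
        dx = X - p[0]
        dx -= box[0] * np.round(dx / box[0])
        dy = Y - p[1]
        dy -= box[1] * np.round(dy / box[1])
        region |= dx * dx + dy * dy <= r2
    w = np.exp(-U)
    w[~np.isfinite(U)] = 0.0
    total = w.sum()
    if total == 0:
        raise ValueError("no accessible area in leaflet")
    return float(w[region].sum() / total)


def plant_affinity_ratio(
    config: SynthConfig,
    model: ProteinModel,
    species_a: str,
    species_b: str,
    ratio: float,
    cutoff: float = 5.5,
    grid: float = 0.5,
) -> SynthConfig:
    """Rescale species-A well depths so the *stationary* A:B contact
    ratio over all planted residues equals ``ratio``.

    The depths follow ``kT * ln``-style scaling: a multiplier on A's
    depths is solved for (Brent's method) so that the quadrature-predicted
    per-copy contact rates satisfy ``rate_A / rate_B = ratio``.  This is
    the planted truth the dynamics + contact pipeline must recover.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    all_keys = [k for s in config.sites for k in s.residue_keys]

    def with_scale(m: float) -> SynthConfig:
        sites = tuple(
            replace(s, well_depth_per_species={
                **s.well_depth_per_species,
                species_a: s.well_depth_per_species.get(species_a, 0.0) * m,
            })
            for s in config.sites
        )
        return replace(config, sites=sites)

    rate_b = stationary_contact_rate(config, model, species_b, all_keys, cutoff,
                                     grid=grid)

    def objective(log_m: float) -> float:
        cfg = with_scale(math.exp(log_m))
        rate_a = stationary_contact_rate(cfg, model, species_a, all_keys,
                                         cutoff, grid=grid)
        return math.log(rate_a / rate_b) - math.log(ratio)

    log_m = brentq(objective, math.log(1e-3), math.log(50.0), xtol=1e-6)
    return with_scale(math.exp(log_m))
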