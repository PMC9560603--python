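"""Configuration-driven end-to-end runs.

A :class:`RunConfig` describes either a synthetic run (a
:class:`~lipidfp.synth.SynthConfig`) or a set of input files (PDB +
sidecar + trajectory + composition), plus analysis toggles.  The
executor runs generate/load -> contacts -> normalise -> density ->
sites -> kinetics as toggled, writes the artifacts and a manifest with
parameter echoes and output checksums; identical config + seed gives
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import (
    CUTOFF_AT,
    CUTOFF_CG,
    LEAFLET_CYTOPLASMIC,
    AnnulusSeries,
    ContactTable,
    annulus_count,
    count_contacts,
    normalize,
    windowed_contacts,
)
from .core import (
    STUDY_LIPIDS,
    BilayerComposition,
    LipidSpecies,
    ProteinModel,
    Trajectory,
    build_composition,
    load_topology,
)
from .density import DensityGrid, density_map, fit_frames, height_map
from .sites import (
    BindingSite,
    OccupancySeries,
    ResidenceStats,
    classify_sites,
    cluster_sites,
    residence_times,
    select_top_residues,
    site_occupancy,
)
from .synth import SynthConfig, default_config, generate_scaffold, simulate
from .trajio import read_trajectory

__all__ = [
    "RunConfig",
    "RunResult",
    "run",
    "compare_runs",
    "composition_from_csv",
]


def composition_from_csv(
    path: str | Path, total: int, leaflet_split: float = 0.5
) -> BilayerComposition:
    """Composition file: CSV with columns species, percent (or
    mole_percent) and optionally charge, head_bead (defaults come from
    the built-in species table)."""
    df = pd.read_csv(path, comment="#")
    if "percent" not in df.columns and "mole_percent" in df.columns:
        df = df.rename(columns={"mole_percent": "percent"})
    entries = []
    for _, row in df.iterrows():
        name = str(row["species"])
        base = STUDY_LIPIDS.get(name)
        sp = LipidSpecies(
            name=name,
            head_bead=str(row.get("head_bead", base.head_bead if base else "PO4")),
            charge=int(row.get("charge", base.charge if base else 0)),
        )
        entries.append((sp, float(row["percent"])))
    return build_composition(entries, total, leaflet_split)


@dataclass
class RunConfig:
    """Exactly one of ``synth`` or ``inputs`` must be set.

    ``inputs`` keys: ``topology`` (PDB), ``sidecar`` (CSV),
    ``trajectories`` (list of paths), ``bead_table`` (CSV, for binary
    trajectories), ``composition`` (CSV) and ``total_lipids``.
    """

    synth: SynthConfig | None = None
    inputs: dict | None = None
    resolution: str = "CG"                    # sets the default cutoff
    toggles: dict = field(default_factory=lambda: dict(
        contacts=True, density=True, sites=True, kinetics=True, windows=False,
    ))
    outdir: str | Path | None = None
    seed: int = 0
    n_residues_per_subunit: int = 260
    cutoff: float | None = None               # override resolution default
    percentile: float = 5.0
    bin_size: float = 2.0
    linkage_cutoff: float = 8.0
    min_site_size: int = 2
    interface_distance: float = 10.0
    r_on: float = 5.5
    r_off: float = 10.0
    gap_frames: int = 0

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.inputs is None):
            raise ValueError("exactly one of synth / inputs must be given")
        if self.resolution not in ("CG", "AT"):
            raise ValueError("resolution must be CG or AT")

    @property
    def effective_cutoff(self) -> float:
        if self.cutoff is not None:
            return self.cutoff
        return CUTOFF_CG if self.resolution == "CG" else CUTOFF_AT

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        synth = None
        if "synth" in doc:
            s = doc.pop("synth")
            from .synth import default_composition, mixed_anionic_composition

            comp_name = s.pop("composition", "pa20")
            total = s.pop("total_lipids", 200)
            comp = (mixed_anionic_composition(total) if comp_name == "mix10"
                    else default_composition(total))
            synth = default_config(
                seed=s.pop("seed", doc.get("seed", 0)), composition=comp, **s
            )
        return cls(synth=synth, **doc)


@dataclass
class RunResult:
    """Everything a run produced, plus the manifest."""

    config: RunConfig
    model: ProteinModel
    trajectories: list[Trajectory]
    contact_table: ContactTable | None = None
    annulus: AnnulusSeries | None = None
    density: dict[str, DensityGrid] = field(default_factory=dict)
    sites: list[BindingSite] = field(default_factory=list)
    dropped_clusters: list = field(default_factory=list)
    occupancy: dict[str, OccupancySeries] = field(default_factory=dict)
    residence: dict[str, ResidenceStats] = field(default_factory=dict)
    window_correlation: float | None = None
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _anionic_species(table: ContactTable, composition: BilayerComposition) -> list[str]:
    anionic = set(composition.anionic_names())
    return [s for s in table.species if s in anionic]


def run(config: RunConfig, log: bool = False) -> RunResult:
    """Execute the toggled pipeline stages; see module docstring."""

    def say(msg: str) -> None:
        if log:
            print(f"[lipidfp] {msg}")

    collected_warnings: list[str] = []

    # ---- stage: generate or load -------------------------------------
    try:
        if config.synth is not None:
            say("generating scaffold and synthetic trajectory")
            model = generate_scaffold(
                n_residues_per_subunit=config.n_residues_per_subunit,
                site_layout=config.synth.sites,
                box=config.synth.box,
                footprint_radius=config.synth.protein_footprint_radius,
                leaflet_offset=config.synth.leaflet_offset,
            )
            trajs = [simulate(config.synth, model)]
            composition = config.synth.composition
        else:
            say("loading topology and trajectories")
            inp = config.inputs
            model = load_topology(inp["topology"], inp.get("sidecar"))
            composition = composition_from_csv(
                inp["composition"], int(inp["total_lipids"]),
                float(inp.get("leaflet_split", 0.5)),
            )
            trajs = [
                read_trajectory(p, inp.get("topology"), inp.get("bead_table"))
                for p in inp["trajectories"]
            ]
    except Exception as e:
        raise RuntimeError(f"stage 'load': {e}") from e

    result = RunResult(config=config, model=model, trajectories=trajs)
    cutoff = config.effective_cutoff
    t = config.toggles

    # ---- stage: contacts ---------------------------------------------
    if t.get("contacts") or t.get("sites") or t.get("kinetics"):
        say(f"counting contacts at {cutoff} A over "
            f"{sum(len(tr) for tr in trajs)} frames")
        try:
            tables = [count_contacts(tr, model, cutoff,
                                     resolution=config.resolution)
                      for tr in trajs]
            result.contact_table = normalize(tables, composition)
            result.annulus = annulus_count(trajs[0], model, cutoff)
        except Exception as e:
            raise RuntimeError(f"stage 'contacts': {e}") from e

    if t.get("windows"):
        say("windowed convergence check")
        try:
            tr = trajs[0]
            t_end = float(tr.times[-1])
            half, full = windowed_contacts(
                tr, model, cutoff, [(0.0, t_end / 2.0), (0.0, t_end)]
            )
            a = normalize([half], composition)
            b = normalize([full], composition)
            anionic = _anionic_species(b, composition)
            cols = [b.species.index(s) for s in anionic] or list(
                range(len(b.species)))
            va = a.normalized[:, cols].sum(axis=1)
            vb = b.normalized[:, cols].sum(axis=1)
            result.window_correlation = float(np.corrcoef(va, vb)[0, 1])
        except Exception as e:
            raise RuntimeError(f"stage 'windows': {e}") from e

    # ---- stage: density ----------------------------------------------
    if t.get("density"):
        say("fitting frames and computing density/height maps")
        try:
            tr = trajs[0]
            aligned = fit_frames(tr, model)
            anionic = composition.anionic_names() or None
            result.density["anionic_cytoplasmic"] = density_map(
                aligned, species=anionic, bin_size=config.bin_size,
                leaflet=LEAFLET_CYTOPLASMIC, leaflet_source=tr,
            )
            result.density["height_cytoplasmic"] = height_map(
                tr, LEAFLET_CYTOPLASMIC, bin_size=config.bin_size,
            )
        except Exception as e:
            raise RuntimeError(f"stage 'density': {e}") from e

    # ---- stage: sites -------------------------------------------------
    if t.get("sites") or t.get("kinetics"):
        say("selecting top residues and clustering sites")
        try:
            table = result.contact_table
            anionic = _anionic_species(table, composition) or None
            selected = select_top_residues(table, config.percentile, anionic)
            sites, dropped = cluster_sites(
                selected, model, config.linkage_cutoff, config.min_site_size
            )
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                result.sites = classify_sites(sites, model,
                                              config.interface_distance)
            collected_warnings += [str(w.message) for w in wlist]
            result.dropped_clusters = dropped
            if dropped:
                collected_warnings.append(
                    f"{len(dropped)} cluster(s) below min_size dropped"
                )
        except Exception as e:
            raise RuntimeError(f"stage 'sites': {e}") from e

    # ---- stage: kinetics ----------------------------------------------
    if t.get("kinetics"):
        say("occupancy and residence kinetics per site")
        try:
            tr = trajs[0]
            anionic = composition.anionic_names() or None
            for site in result.sites:
                result.occupancy[site.site_id] = site_occupancy(
                    tr, model, site, cutoff, species_filter=anionic
                )
                stats = residence_times(
                    tr, model, site, r_on=config.r_on, r_off=config.r_off,
                    gap_frames=config.gap_frames, species_filter=anionic,
                )
                result.residence[site.site_id] = stats
                n_cens = sum(stats.censored)
                if n_cens:
                    collected_warnings.append(
                        f"{site.site_id}: {n_cens} censored residence event(s)"
                    )
        except Exception as e:
            raise RuntimeError(f"stage 'kinetics': {e}") from e

    # ---- manifest and artifacts ----------------------------------------
    result.manifest = _write_outputs(config, result, collected_warnings)
    return result


def _params_dict(config: RunConfig) -> dict:
    return dict(
        resolution=config.resolution, cutoff=config.effective_cutoff,
        percentile=config.percentile, bin_size=config.bin_size,
        linkage_cutoff=config.linkage_cutoff, min_site_size=config.min_site_size,
        interface_distance=config.interface_distance, r_on=config.r_on,
        r_off=config.r_off, gap_frames=config.gap_frames, seed=config.seed,
        synth_seed=None if config.synth is None else config.synth.seed,
        n_residues_per_subunit=config.n_residues_per_subunit,
    )


def _write_outputs(config: RunConfig, result: RunResult,
                   collected_warnings: list[str]) -> dict:
    manifest = dict(
        package="lipidfp", version=__version__,
        params=_params_dict(config),
        leaflet_convention="lower z = cytoplasmic; wells planted in lower leaflet",
        warnings=collected_warnings,
        outputs={},
    )
    if result.window_correlation is not None:
        manifest["window_correlation"] = result.window_correlation
    manifest["n_sites"] = len(result.sites)
    manifest["sites"] = [s.to_dict() for s in result.sites]

    if config.outdir is None:
        result.manifest = manifest
        return manifest
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if result.contact_table is not None:
        p = out / "contacts.csv"
        result.contact_table.write_csv(p)
        written.append(p)
    if result.annulus is not None:
        p = out / "annulus.csv"
        with open(p, "w") as fh:
            fh.write(f"# cutoff: {config.effective_cutoff}\n"
                     f"# mean: {result.annulus.mean}\n"
                     f"# std: {result.annulus.std}\n")
            result.annulus.to_frame().to_csv(fh, index=False)
        written.append(p)
    for name, grid in result.density.items():
        p = out / f"{name}.dat"
        grid.save(p)
        written.append(p)
    if result.sites:
        p = out / "sites.json"
        p.write_text(json.dumps(
            dict(
                thresholds=dict(percentile=config.percentile,
                                linkage_cutoff=config.linkage_cutoff,
                                min_site_size=config.min_site_size,
                                interface_distance=config.interface_distance),
                sites=[_site_json(s, result.model) for s in result.sites],
            ), indent=2, sort_keys=True,
        ))
        written.append(p)
    if result.residence:
        rows = []
        for sid, st in result.residence.items():
            occ = result.occupancy.get(sid)
            rows.append(dict(
                site_id=sid, n_events=st.n_events,
                mean_residence_ns=st.mean_residence,
                max_residence_ns=st.max_residence,
                censored_events=sum(st.censored),
                mean_occupancy="" if occ is None else occ.mean,
                r_on=st.r_on, r_off=st.r_off, gap_frames=st.gap_frames,
            ))
        p = out / "residence.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)

    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(written)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def _site_json(site: BindingSite, model: ProteinModel) -> dict:
    d = site.to_dict()
    d["residues"] = [
        dict(subunit=s, resnum=r,
             bw_label=model.residue((s, r)).bw_label)
        for s, r in site.residues
    ]
    return d


# ---------------------------------------------------------------------------
# run comparison (wild-type vs knockout, replicate stability)
# ---------------------------------------------------------------------------

def compare_runs(a: RunResult, b: RunResult) -> dict:
    """Per-residue normalised-contact deltas and site-set differences.

    Both runs must share the protein model (same residue keys).  Site
    identity is by residue membership, not by site_id.
    """
    ta, tb = a.contact_table, b.contact_table
    if ta is None or tb is None:
        raise ValueError("both runs need contact tables")
    if ta.residue_keys != tb.residue_keys:
        raise ValueError("runs use different models; cannot compare")
    common = [s for s in ta.species if s in tb.species]
    deltas = pd.DataFrame(
        dict(subunit=[k[0] for k in ta.residue_keys],
             resnum=[k[1] for k in ta.residue_keys])
    )
    for sp in common:
        deltas[sp] = (ta.species_column(sp, normalized=True)
                      - tb.species_column(sp, normalized=True))
    sets_a = {frozenset(s.residues) for s in a.sites}
    sets_b = {frozenset(s.residues) for s in b.sites}
    return dict(
        deltas=deltas,
        only_in_a=[sorted(s) for s in sets_a - sets_b],
        only_in_b=[sorted(s) for s in sets_b - sets_a],
    )
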