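# Methods

This note documents the models, estimators, parameter choices and
limitations of `lipidfp`.  Conventions throughout: coordinates in Å,
times in ps (residence durations reported in ns), energies in units of
kT, orthorhombic boxes, membrane normal along +z, lower-z leaflet
designated *cytoplasmic* and upper-z *luminal*.  All outputs echo these
conventions and every analysis threshold into their headers/manifests.

## Contact fingerprints

A contact is a (residue, lipid molecule, frame) triple: the
minimum-image distance between *any* bead of the residue and the
lipid's headgroup bead is at or below the cutoff.  One triple counts
once however many residue beads or head beads are involved — counting
granularity at the bead level would make the statistic depend on the
bead model rather than on the interaction.  Default cutoffs are 5.5 Å
for coarse-grained data and 4.0 Å for atomistic data, overridable
everywhere.  Minimum-image distances are defined only for cutoffs below
half the smallest box dimension; larger cutoffs are rejected, as are
triclinic boxes.

Normalisation divides the summed raw counts (replicates concatenated)
by `N_frames × N_s`, the number of analysed frames times the copy
number of that species in the bilayer, giving a per-frame, per-copy
contact probability bounded by [0, 1].  Dividing by copy number (not by
the number of species) is the reading that makes profiles comparable
across bilayer compositions; both divisors give identical residue
rankings, so site detection is insensitive to the choice.

The kernel uses periodic KD-trees per frame (float64), with the static
protein tree memoised; it is exact, and the test suite pins it to a
brute-force all-pairs enumeration on small systems.

## Binding-site detection

Residues are ranked by their normalised contacts summed over a species
set (by default the anionic species); the top `ceil(p% · n)` residues
are selected (default p = 5), with exact ties at the threshold all
included.  Selected residues are grouped by single-linkage clustering
on the minimum inter-residue bead distance in the reference structure,
cutoff 8 Å, and clusters below 2 residues are dropped but reported.
The clustering step is this package's own procedural choice: the rule
is parameter-transparent, reproduces the expected four-site topology on
the reference scaffold, and its two parameters are echoed into every
output.  A site is *interfacial* if it contains residues of at least
two subunits, or if every one of its residues lies within 10 Å of the
partner subunit; otherwise *distal*.  Pooled (rather than per-species)
ranking is the default because the fingerprint of interest is the
anionic enrichment as a whole; per-species selection is available by
argument.

## Kinetics

Site occupancy is the number of distinct lipid molecules within the
cutoff of at least one site residue, per frame.  Residence times use a
dual-cutoff estimator: an event opens at the first frame at or below
`r_on` (default 5.5 Å) and closes at the first excursion beyond `r_off`
(default 10 Å) longer than `gap_frames` (default 0).  The wider exit
cutoff keeps a lipid rattling across the contact boundary from being
split into spurious short events — the same role played by the
residence tools commonly used in this field, whose exact settings vary;
with `r_off = r_on` the estimator degenerates to naive contact runs.
Events still open at the last frame are right-censored: they are
excluded from the mean (they only bound their duration from below) but
included in the max.  Shrinking `r_off` toward `r_on` can only split
events, never merge them; the suite checks this monotonicity along with
an exhaustive state-machine oracle.

## Superposition and maps

Frames are rigidly superposed onto the protein reference by the
closed-form least-squares (Kabsch/SVD) solution with the reflection
excluded; the full 3D rotation is used because the membrane plane is
itself noisy in z.  At least three non-collinear anchor beads are
required.  The same transform is applied to all beads, so lipid
densities accumulate in the protein frame.  Density maps are mean
headgroup-bead counts per frame per (x, y) bin (bin size 2 Å, grid
anchored at the reference box origin; divide by bin area for Å⁻²);
leaflet filtering uses the *pre-alignment* z, since alignment may tilt
a frame.  Leaflet assignment per frame: the midplane is the mean z of
all headgroup beads; molecules at or below it are cytoplasmic (exact
ties cytoplasmic, so the degenerate all-equal case is defined).  Height
maps are per-bin mean headgroup z with NaN for never-visited bins.
RMSF is measured about each bead's time-mean position after
superposition, optionally with a separate rigid-core fit selection.

## The synthetic-data generator

The generator replaces multi-microsecond coarse-grained MD with the
*statistical situation* those simulations put the analysis in; it makes
no attempt at physical realism (no tails, no explicit electrostatics,
no protein dynamics, no flip-flop).

**Scaffold.**  A pseudo-homodimer: subunit A occupies angles (−90°,
90°) about the dimer axis, B the other half.  One bead per residue.
Planted site residues (charge +1, named LYS) sit on the footprint rim
(radius 30 Å) at their site's anchor angle, in their site's leaflet
plane; background residues (charge 0) fill inner concentric rings with
alternating leaflet z.  The default layout plants the study topology:
two distal sites of 9 residues (anchors 0° and 180°, one per subunit)
and two interfacial sites of 4 residues each contributing 2 per subunit
(anchors 90° and 270°), 26 cationic residues in all.  With the default
260 residues per subunit the planted residues are exactly 5 % of the
520 — the same situation in which a top-5 % rule isolates the real
sites.  Background residues that would land within 10 Å of a planted
site in the same leaflet are moved to the other leaflet plane;
otherwise the wells' enrichment would alias onto unplanted neighbours
and no detector could tell planted from adjacent.  This is the
deliberate recoverability-by-construction of a synthetic benchmark, and
is exactly what passing tests do and do not show: they validate the
estimators against a known truth, not the geometry of any real protein.
Scaffold residue numbers are internal identifiers.

**Dynamics.**  Lipids are single headgroup beads diffusing in two
independent 2D periodic leaflet planes, integrated by Euler–Maruyama
for overdamped Langevin dynamics: `dx = D F dt + sqrt(2 D dt) ξ` with
forces from (i) Gaussian wells of depth ε_s (kT, per species) and width
σ centred at planted residue xy positions, in that site's leaflet only,
knocked-out residues contributing zero; and (ii) a protein footprint
soft core, harmonic with k = 1 kT/Å² inside the disc plus a mirror
reflection at R − 0.5 Å, so no bead ever penetrates deeper than the
0.5 Å tolerance while the region outside the wall still samples
`exp(−U)`.  The integrator refuses steps whose free RMS displacement
`sqrt(4 D dt)` exceeds half the narrowest well width.  Recorded z is
the leaflet plane plus per-frame Gaussian jitter (σ = 1 Å).  A single
seeded generator drives everything, with a documented stream order
(initial positions lower-then-upper leaflet, initial z jitter, then per
step one xy-noise block and, on recorded steps, one z-jitter block), so
identical configs give bitwise-identical trajectories.

**Defaults and why.**  Box 200 × 200 Å (Lz 100 Å), footprint radius
30 Å, leaflet planes at midplane ± 18 Å, dt 40 ps with every step
recorded and 20 000 steps — minutes on one CPU while leaving hundreds
of independent well-exchange events.  Diffusion coefficient
0.02 Å²/ps ≈ 2×10⁻⁷ cm²/s, the right order for coarse-grained lipid
lateral diffusion, and stable at dt 40 ps with the narrowest (4 Å)
wells.  200 lipids (100 per leaflet), 80 % POPE / 20 % POPA by default;
compositions are realised by largest-remainder rounding (ties by listed
order), which conserves totals exactly — the tonoplast-like mixture
(29 % cholesterol, 25 % POPC, 17 % POPE, 17 % ceramide hexoside, 6 %
PIP₂, 3 % POPG, 2 % POPS, 1 % POPA; 12 % anionic) realises 400 lipids
as 116/100/68/68/24/12/8/4.  Species affinity is encoded as per-species
well depth: relative scales POPA 1.0, POPG 0.5, POPS 0.4, PIP₂ 1.2,
zwitterionic species 0 (distal base depth 1.0 kT and width 6 Å;
interfacial 0.8 kT and 4 Å, giving the large/slow vs small/fast
contrast).  These depths are free parameters of the benchmark, not
estimates of real lipid affinities, which are unknown.

**Stationary-state oracle.**  Because the planted potential is known,
the stationary density is `exp(−U)` and any occupancy or contact rate
can be predicted by direct quadrature on a 0.5 Å grid (footprint wall
included).  `plant_affinity_ratio` uses this to *calibrate* species
depths so the predicted stationary contact ratio between two species
equals a requested value (solved by Brent's method on a depth
multiplier); the dynamics plus the full contact pipeline must then
recover that ratio, which is the package's parameter-recovery check
(3:1 planted, recovered within 25 % at the default scale, three seeds).

**Statistical tolerances.**  The flat-density check (zero-depth wells)
writes frames 400 ps apart — beyond the ~180 ps diffusive
decorrelation time of the site region — and asserts agreement with the
uniform expectation within 3 Poisson standard errors.  The 2 kT-well
check compares the measured well/bulk occupancy ratio, pooled over
three seeds with the first 10 % of each run discarded as burn-in,
against the quadrature prediction within 4 batch-mean standard errors
plus a 3 % allowance for the Euler–Maruyama discretisation bias (weak
order 1; at `D dt = 0.5 Å²` and the well's maximal gradient the
predicted log-density error is ~1–2 %).

## Degenerate inputs and tie-breaks

Empty windows, empty selections, zero-copy species present in a
contact table, cutoffs at or beyond the minimum-image bound, `r_off <
r_on`, anchors outside helix spans, overlapping spans, duplicate
sidecar keys and single-subunit classification are all explicit errors
or documented fallbacks (monomer sites stay unclassified, with a
warning).  Exact midplane ties are cytoplasmic; selection ties at the
percentile threshold are all included; composition rounding ties follow
listed species order; clusters below the minimum size are reported, not
silently dropped.

## Ballesteros–Weinstein labels

Labels are derived from user-supplied helix definitions `(helix, start,
end, anchor)`, the anchor being position .50; residue `r` in a span
gets `helix.(50 + r − anchor)`.  Published helix spans for the proteins
of interest are not available in machine-readable form, so labels are
fixture-driven — the utility guarantees consistency with any chosen
anchors rather than reproducing a specific published assignment.

## Known limitations

* The generator's annulus (~6 lipids at default density) is smaller
  than a real first lipid shell, because lipids are points at far below
  physical area density; annulus *counting* is exact (oracle-tested),
  but absolute annulus sizes, occupancies and residence times from
  synthetic runs are in benchmark units only.
* Single-bead lipids cannot exhibit tail effects, curvature coupling or
  specific headgroup chemistry; the POPA-over-POPG/POPS preference is
  planted, standing in for a physical origin the underlying science has
  not resolved.
* After a knockout, the top-percentile rule still selects a fixed
  number of residues, so its tail picks up a few noise residues; with
  the minimum cluster size of 2, a spurious two-residue cluster can
  appear at some seeds.  The planted sites themselves are recovered or
  lost exactly as planted; reports should therefore be read through
  site membership, not raw site counts.
* Superposition assumes a rigid reference; large conformational change
  would demand a core selection (supported via `fit_selection`).
* Binary trajectory reading (XTC/DCD) requires an MDAnalysis-readable
  topology plus a bead-table CSV; bead order must match.
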