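# Methods

`hepamet` simulates the seeding, growth, dormancy, and reawakening of
colorectal-cancer micrometastases in centimeter-scale 2-D virtual liver
tissue. The model couples three ingredients: a quasi-steady/diffusive
hybrid oxygen field, off-lattice agent mechanics with elasto-plastic
tethering of the parenchyma to its extracellular matrix (ECM), and
pressure- and oxygen-gated tumor cell cycling. This note records the model
equations, the parameter choices and their rationale, the numerical
scheme, what the synthetic data do and do not emulate, and known
limitations.

## Tissue synthesis

Hepatic lobules are approximated by the Voronoi tessellation of randomly
placed central veins (CVs). CVs are dropped as a Poisson process with mean
density 2e-6 per um^2 (one per 0.5 mm^2). Pairs closer than a merge
threshold are replaced, closest pair first, by their midpoint until all
pairwise distances exceed the threshold; this removes degenerate sliver
lobules. The tessellation is clipped exactly to the rectangular domain by
tessellating the CVs together with their mirror images across the four
domain edges. The remaining space is filled with hexagonally packed
parenchyma agents (radius 15 um) — coarse-grained patches of hepatocyte
cords and sinusoids, not individual cells — omitting lattice sites within
26.5 um of a CV (the CV lumen radius). Voronoi vertices act as
portal-triad proxy points.

**Merge threshold.** The target tissue has a mean lobule equivalent
diameter of ~800 um, which fixes the CV density; the merge threshold must
leave that anchor intact. A threshold of 400 um (half the lobule diameter)
removes a third of the veins and inflates the mean interior equivalent
diameter to ~950 um. The default is therefore **200 um** (a quarter of the
lobule diameter): merging stays a minor correction (~10% of veins) and the
mean interior equivalent diameter lands at ~800 um. "Interior" lobules are
those whose region does not touch the domain boundary; clipped boundary
regions are excluded from all summary statistics.

**Confluent spacing.** Parenchyma agents are laid out at spacing
`2 R x 0.95`, marginally inside the adhesion-repulsion equilibrium
(`~0.952 x` the radius sum for the default potentials), and a short
mechanics-only burn-in (60 simulated minutes) relaxes the lattice before
tumor seeding; anchors are then reset to the relaxed positions so the
homeostatic tissue carries zero ECM deformation.

## Oxygen field

Interstitial flow in intact liver parenchyma is fast and advective, so
oxygen there is quasi-steady; inside a micrometastasis flow is stagnant
and transport is diffusive. The field therefore lives on a regular grid
(voxel edge 20 um) in two regimes:

* **Intact voxels** are Dirichlet nodes pinned to an analytic single-lobule
  profile: sigma(x) = sigma_cv + (sigma_pt - sigma_cv) g(u), where u in
  [0, 1] is the normalized position of the voxel center along the ray from
  its lobule's central vein through the point to the lobule boundary, and
  g is a pluggable shape (linear by default; an exponential-saturation
  alternative is provided). Endpoints are sigma_cv = 38 mmHg at the vein
  outlet and sigma_pt = 60 mmHg at the lobule boundary, so the perfused
  tissue spans 38-60 mmHg. A tissue without veins is uniform at sigma_pt.
* **Disrupted voxels** — any voxel that has ever contained a tumor cell
  center — lose their Dirichlet node permanently (the flag survives cell
  death and movement) and evolve by the reaction-diffusion law

      d rho/dt = D lap(rho) - lambda rho
                 + sum_i delta(x - x_i) W_i [S_i (rho*_i - rho) - U_i rho]

  with zero-flux outer boundaries, D = 1e5 um^2/min, bulk decay
  lambda = 0.01/min, and per-cell rates scaled by cell volume over voxel
  volume (thin-slab volumes, thickness 30 um).

**Numerics.** First-order operator splitting per dimension with implicit
tridiagonal sweeps, each sweep carrying half the bulk decay; cell
sources/sinks are folded in by a backward-Euler per-voxel update before
the sweeps. The scheme is unconditionally stable, first-order in time and
second-order in space; at dt = 0.01 min and dx = 20 um the relative error
against closed-form decay/uptake/source solutions at 60 min is ~0.3%.
Dirichlet voxels are carried as identity rows inside the tridiagonal
systems — they are exact at every step and decouple the intact tissue, so
the solve is cropped to the disrupted neighborhood. Steady states iterate
the stepper until the maximum relative change falls below 1e-5 per minute
(cap 1e6 steps). The steady field inherits an O(dt) bias from the
splitting (~lambda dt/2 plus uptake dt/2 relative), below 2% at the
default step.

**Uptake calibration.** The per-cell oxygen uptake rate is not printed in
the source material. The default U_cell = 3.5/min was set from the
diffusion length L = sqrt(D / U_total) so that a static 2-mm tumor keeps a
400-500 um viable rim before its bin-mean oxygen crosses the 5 mmHg
necrotic threshold, and an 800-um tumor stays entirely viable — the two
quantitative oxygenation anchors. With this value a ~1-mm static tumor's
core sits near 9-10 mmHg, i.e. just above threshold; necrosis in growing
tumors first appears at diameters somewhat above 1 mm.

## Mechanics

Cells are inertialess off-lattice agents. A pair at center distance d with
radii R_i, R_j contributes equal and opposite velocities along the
separation axis: repulsion c_rep (1 - d/R_rep)^2 for d < R_rep = R_i + R_j
and adhesion c_adh (1 - d/R_adh)^2 for d < R_adh = 1.25 R_rep, with
c_rep = 10 um/min and c_adh = 0.4 um/min (the reference framework's
defaults; none of the calibrated results depend on their absolute values,
only on the equilibrium spacing they imply). Coincident centers separate
along a seeded random direction.

**Pressure.** The dimensionless compressive pressure on a cell is
p = sum_j (1 - d_ij/R_rep,ij)_+^2 / P_scale with
P_scale = 12 (1 - phi)^2, where phi is the equilibrium spacing as a
fraction of the radius sum, found once by root bracketing. By
construction a cell with 12 equal neighbors at confluent spacing (dense
3-D packing) reads exactly 1 and the 2-D analogue with 6 neighbors reads
exactly 0.5.

**Elasto-plastic ECM tethering.** Each parenchyma agent i is anchored at
x_ECM,i. Its deformation is d_i = ||x_ECM,i - x_i||; displacement is
resisted elastically, dx_i/dt += r_E (x_ECM,i - x_i), while the anchor
itself creeps plastically toward the agent,
dx_ECM,i/dt = r_P (x_i - x_ECM,i). An agent whose deformation exceeds the
tolerance d_max undergoes apoptosis (deterministic threshold; the death
uses the same shrink model as tumor apoptosis, since strained parenchyma
is rendered as apoptotic). The swept triplet is r_E in {0.05, 0.1, 0.2}
/min (minutes-scale elastic response), r_P in {0.0005, 0.001, 0.002} /min
(hours-scale plastic relaxation), d_max in {0.75, 1.5, 3} um (~5-20% of
the agent radius). Tumor cells carry no anchors.

**Integration.** Pair forces advance positions by forward Euler at
dt_mech (default 0.1 min) with a per-step displacement cap of a quarter
radius (a step exceeding one radius aborts as unstable). The elastic
tether and the plastic creep are then applied as *exact* exponential
relaxations over the step (an exponential integrator): an isolated
anchored agent reproduces the closed forms e^{-r_E t}, e^{-r_P t}, and
the coupled decay e^{-(r_E + r_P) t} to machine precision, and the stiff
spring never limits the stable step size. The neighbor list is a k-d-tree
pair query with a 4-um Verlet skin, rebuilt when accumulated drift could
change the interaction set; pairs are kept in canonical order so force
accumulation is bit-reproducible.

## Phenotype

Tumor cells follow the Ki67-advanced cycle: quiescent (Ki67-) cells enter
a premitotic Ki67+ phase at rate

    r01(sigma, p) = r01_max
                    x clamp((sigma - sigma_H) / (sigma_sat - sigma_H), 0, 1)
                    x min{1, max{(p2 - p) / (p2 - p1), 0}}

with p1 = 0 and p2 = 1: cycling is unrestricted at zero pressure and fully
arrested at p >= 1. Premitotic cells grow toward double volume over
T_K1 = 13 h, then divide into two postmitotic Ki67+ daughters (placed
symmetrically about the mother along a seeded random axis, separation one
mother radius, volume conserved) which return to quiescence after
T_K2 = 2.5 h. The maximal entry rate r01_max = 1/(3.62 h) and the phase
durations follow the reference framework's breast-epithelium calibration;
the implied mean cycle time is 1/r01 + T_K1 + T_K2 ~ 19 h at full oxygen
and zero pressure. Below the hypoxic threshold sigma_H = 5 mmHg cells
necrose stochastically at rate r_N_max clamp((sigma_H - sigma)/sigma_H)
with r_N_max = 1/(6 h). Dead cells shrink exponentially (apoptotic over
T_apop = 8.6 h, necrotic over T_lysis = 6 h; rate 3/duration so <5% of
resting volume remains after one duration) and are removed below 5% of
resting volume; shrinking necrotic cells act as a local pressure release.
Oxygen is sampled at the cell's containing voxel without interpolation.
Parenchyma agents have zero cycling and zero background apoptosis
(homeostatic tissue); they die only through the strain rule. Necrotic
swelling/calcification sub-stages are omitted — only the pressure-release
role of necrotic shrinkage matters to the tissue-scale dynamics.

## Orchestration

A macro-step (dt_phen = 6 min) executes: (1) refresh permanently disrupted
voxels from tumor cell positions; (2) advance the oxygen field in implicit
sub-steps; (3) advance mechanics in dt_mech sub-steps (static cells are
frozen); (4) recompute pressures and sample oxygen; (5) phenotype — cycle
entry, necrosis, volume update, divisions, strain-triggered parenchyma
death, removal of fully shrunk cells. Diffusion runs before mechanics
before phenotype so phenotype always consumes the freshest sigma and p.
Scheduled parameter events (the reawakening protocol) swap the
biomechanical triplet at their trigger time. A (config, seed) pair fully
determines the trajectory; named RNG streams separate tissue generation
from simulation stochasticity, and checkpoints (versioned binary
containers) restore bit-compatible trajectories.

Seeding is either one quiescent tumor cell at the domain center (growth
studies; any overlapping parenchyma agent is removed rather than
compressed, matching the static study's convention) or confluent static
disks (steady-state oxygenation study, mechanics/cycling/necrosis
disabled).

## Study protocols and problem sizes

The published campaign simulated 90-180 days in 0.5-1 cm tissues with 270
runs; that is cluster-scale. The packaged defaults reproduce those
protocols; the test suite and the acceptance script run them at reduced
sizes, chosen once as the smallest scales at which each observable is
meaningful:

* **Static oxygenation**: full printed scale — 1 cm^2 tissue, ten disks
  of 250 um-2 mm (and a single 800-um disk), solved to steady state.
* **Biomechanics sweep**: 0.1 cm domain, 10 simulated days, 3 seeds per
  d_max value at (r_E, r_P) = (0.05, 0.0005)/min. At this scale final
  tumor areas at d_max = 0.75/1.5/3 um separate by factors of ~1.5-30.
* **Dormancy/reawakening**: 0.1 cm domain, 12-day stage 1 at
  (0.2, 0.0005, 3), three 12-day stage-2 branches (I control, II
  r_E -> 0.05, III d_max -> 1.5) from a byte-identical checkpoint,
  3 seeds.
* **Arrest-fraction dynamics**: 0.15 cm domain, 20 days at
  (0.05, 0.0005, 0.75).
* Scaled growth runs use dt_mech = 1 min and 12 diffusion sub-steps per
  macro-step (the implicit solver is unconditionally stable; the oxygen
  field is quasi-steady relative to the 6-min macro-step), while the
  solver-accuracy checks use the reference dt = 0.01 min.

**Scaled-down dormancy caveat.** At the 0.1-cm scale the dormant tumor
arrests at ~70-80 um (tens of cells, ~10 occupied voxels). Two published
observations degrade at that size. First, "dormancy" measured as <10%
relative area growth is granular: a single division that claims one new
voxel adds ~10%, and slow plastic creep (r_P > 0) lets even the control
branch accrete a few voxels over weeks, so the control can exceed a 10%
relative-growth band that a full-scale tumor (thousands of voxels) would
not. Second, branch III's reawakening operates through a strain-death
avalanche: parenchyma deformations near the rim must cross the lowered
d_max = 1.5 um. The static deformation around a dormant tumor scales with
the rim contact force over r_E and measures only ~0.2-0.4 um at this
tumor size; transient division pushes cross the threshold only rarely.
Branch II's softening (r_E -> 0.05) instead acts immediately at any size.
Both altered branches reliably outgrow the control, but the *relative*
ranking of II and III at desk scale can invert the full-scale result; the
acceptance suite states the published ordering and is expected to be
sensitive to this size effect.

## Synthetic data: what it does and does not emulate

The generator reproduces lobule-scale geometry statistics (CV density,
~800-um lobules, confluent parenchyma packing) and the 38-60 mmHg
perfusion range. It does not represent sinusoid/hepatic-cord
microstructure, vessel network topology, 3-D lobule geometry, anisotropic
ECM fibers, or non-parenchymal cell types (immune cells, fibroblasts,
endothelium). Passing tests therefore demonstrate the mechanobiologic
feedback logic at tissue scale, not fidelity to any particular liver's
microanatomy.

## Numerical choices and degenerate inputs

Tolerances: steady-state 1e-5/min; mechanics step cap 0.25 R with a hard
abort at 1 R; dead-cell removal at 5% resting volume; strain death is a
strict threshold. Tie-breaks: coincident centers use a seeded random
direction; the division axis is a seeded random angle. Degenerate inputs:
zero CV density yields a lobule-free tissue with a constant field at
sigma_pt; a point exactly on a lobule boundary belongs to its
nearest-vein region; empty tissues and empty populations render and
serialize as valid (empty) artifacts.

## Known limitations

* 2-D (thin 3-D) only; the slab thickness enters volume scalings alone.
* One substrate (oxygen); no interstitial fluid pressure or advection
  solve — the quasi-steady Dirichlet profile embodies the advective limit.
* No tumor-cell motility, polarity, or background apoptosis; dormancy is
  maintained purely mechanically, so very long control runs eventually
  escape through plastic creep.
* The analytic perfusion profile's shape between its pinned endpoints is
  a modeling choice (linear default); only the endpoints are constrained
  by data.
* Desk-scale protocol sizes alter the quantitative dormancy/reawakening
  comparisons as described above.
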