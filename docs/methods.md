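# Methods

## Model overview

`gagbind` models the association of a rigid, highly anionic glycan with a
rigid amyloid fibril as overdamped diffusion in a screened electrostatic
field, followed by geometric binding detection and pose-level analysis.
The chain of stages mirrors the standard multiscale workflow for
fibril–polyanion binding prediction (BD sampling of binding modes, then
refinement and contact analysis of bound poses), with every cluster-scale
component replaced by an exactly testable desk-scale counterpart.

## Synthetic structures

**Fibril.** A cross-section template assigns each residue a CA position,
fixed side-chain offsets for the charged/reference atoms (Lys NZ; Arg CZ,
NH1, NH2; Asp/Glu one carboxylate oxygen), a formal charge (K/R → +1,
D/E → −1, else 0), and a solvent-exposure flag. The fibril is the template
stacked `n_layers` times along z with a rise of 4.8 Å (configurable;
optional per-layer twist, default 0°, and an optional second protofilament
as a rigid copy). Identical residues therefore form perfect axial ladders,
and the layer-centroid spacing equals the rise to floating-point
precision. The packaged tau-like template covers core residues 306–378
of the standard tau sequence; with K370 flagged buried, its exposed basic
residues are K311, K317, K321, K331, K340, K343, K347, R349, K353, K369,
K375. Exposure is declared in the template rather than computed (no SASA):
at this level of idealization exposure is a modelling input, not a
derived quantity. `read_pdb` assigns layers chain-per-layer when chains
are distinct, otherwise by binning the projection onto the principal axis
at the rise spacing.

**Glycan.** A linear chain of alternating units — odd 1-based indices are
glucosamine, even are iduronic acid — spaced `repeat_rise`/2 apart
(default repeat 8.7 Å per disaccharide, the helical heparin repeat). Each
glucosamine carries an N-sulfamido group (sulfur S2) and a 6-O-sulfate
(S6); each iduronic acid a 2-O-sulfate (S2) and its ring carboxylate. Each
of these heparin charged groups (HCGs) is assigned one formal charge of
−1 e located at the centroid of its terminal oxygens, so a fully sulfated
chain of n saccharides has 2n HCGs and net charge −2n e. The paper-style
desulfation variants remove all 2-O- or all 6-O-sulfates (n/2 groups
each). Formal unit charges are a deliberate simplification: they preserve
the electrostatic steering physics without a force field, and make the
superposition/closed-form tests exact.

## Electrostatics

Debye–Hückel screened Coulomb in units of kcal/mol, Å, e, ps:

    phi(r)   = sum_i k q_i exp(-kappa r_i) / (eps r_i),
    kappa^2  = 8 pi l_B I_n,    l_B = k / (eps k_B T)

with k = e²/(4πε₀) = 332.0637 kcal·Å/(mol·e²) and I_n the ionic strength
in Å⁻³. Defaults (310.15 K, ε = 78, relative viscosity 1, 150 mM) give a
Debye length of 7.99 Å. Zero ionic strength is signalled as an infinite
Debye length (pure Coulomb mode). Beads additionally interact through a
soft excluded-volume wall E = ε_w (σ/r)¹² with σ = 4 Å (two 2 Å contact
radii) and ε_w = 1 kcal/mol; pair distances are clamped at 0.5 Å so
transient overlaps give large but finite forces. Forces are the exact
analytic gradients (tested against central differences at 10⁻⁴ relative
error). A trilinear-interpolation potential grid with OpenDX export is
provided for visualization and far-field evaluation; off-grid queries
fall back to the direct sum.

Linearized screening in a uniform dielectric replaces a nonlinear
Poisson–Boltzmann solve on the molecular surface. This keeps the
mechanism (charge complementarity, acidic-neighbour interference,
salt-dependent range) while discarding dielectric-boundary and
desolvation effects — interaction energies here are comparative scores,
not transferable free energies.

## Brownian dynamics

Rigid-body Ermak–McCammon propagation of the glycan around a fixed
fibril:

    dr = (D_t / k_B T) F dt + sqrt(2 D_t dt) xi,
    dw = (D_r / k_B T) T dt + sqrt(2 D_r dt) xi_r,

with D_t and D_r from Stokes–Einstein(–Debye) at a configurable
hydrodynamic radius (default 8 Å for the octasaccharide, an
order-of-magnitude choice for a short GAG) and the water viscosity at the
configured temperature times the relative viscosity. Trajectories start
uniformly on the b-sphere with uniform random orientation and end on
reaction, on crossing the q-sphere (escape), or at the step cap (recorded
as its own status — Table denominators always count every trajectory).
Defaults: b = fibril bounding radius + 3 Debye lengths (quasi-
centrosymmetric field at b), q = 10 b, timestep 1.0 ps far / 0.01 ps
whenever any glycan sulfur is within the 15 Å near shell (2× the reaction
distance, so timestep refinement engages before reaction testing can
succeed), step cap 10⁷.

**Reaction criterion.** Binding is declared when at least 3 pairs of
glycan sulfurs (S2/S6 of each unit) and fibril reference atoms (NZ of
exposed Lys, CZ of exposed Arg, every layer) are simultaneously within
7.5 Å. The bound site is the residue number (pooled over layers) owning
the most pairs, ties broken toward the lowest residue number.

**Reproducibility.** Each trajectory consumes its own RNG substream keyed
by (seed, fibril index, glycan index, replicate), so ensembles are
deterministic and independent of execution order and of the vectorized
batching used by `run_ensemble` (single-trajectory and batched paths are
bit-identical; tested). The NAM formula
k = k_D(b)β / (1 − (1−β) k_D(b)/k_D(q)), k_D(r) = 4πD_t r, converts bound
fractions to association rates.

## Pose analysis

The fibril axis is the unit vector from the third-layer centroid to the
third-to-last-layer centroid (first/last layers when those coincide, i.e.
fewer than 6 layers); the glycan axis runs from the first to the last
ring centroid. A bound pose is *aligned* when the angle between the axes
(folded to [0°, 90°]) is ≤ 45°, inclusive, with a 10⁻⁹ ° grace against
arccos rounding. Aligned poses are described by the vector of each
sulfur's distance to the nearest atom of the binding residue set (all
layers; composite sites such as K317+K321 are supported as site groups).
Pairwise distance-RMSDs between these vectors feed Ward agglomerative
clustering. Ward runs on the precomputed distance matrix through the
Lance–Williams update — distance-RMSD is not Euclidean in general, so
this is the accepted "Ward on precomputed distances" extension — with
deterministic relabelling by first appearance and medoids found by
exhaustive within-cluster scan. The default k = 10 clusters is a config
value, not an inferred quantity.

**Refinement stand-in.** Medoid poses are locally minimized by rigid-body
steepest descent on the screened-Coulomb + wall energy (fixed small steps
along force/torque, fixed iteration cap). This preserves the
dock-then-refine shape of the workflow; it is explicitly not molecular
dynamics and adds no flexibility or solvent detail.

## Contact statistics

A salt bridge is a cationic nitrogen (Lys NZ, Arg NH1/NH2) within 4.5 Å
(inclusive — "within" is fixed to ≤ to avoid platform-dependent float
edges) of an HCG oxygen; sulfamido oxygens count as HCG oxygens. Contacts
are recorded at residue × layer × HCG granularity, so each ladder rung
counts separately in the unique-residue statistic (required for medians
like "six rungs of one ladder bound"), while an HCG counts once however
many residues it touches. Medians over frames use the lower median for
even-length samples, matching integer count reporting; NH1/NH2 of one
arginine pool to one residue-level contact. Contact-frequency maps give,
per (glycan unit, group type) × residue, the fraction of frames with at
least one contact pooled over layers (cells are means of per-frame
indicators, hence in [0, 1]); sulfamido groups occupy their own column
block by default with a flag to drop them for sulfate/carboxylate-only
figure parity. In the pipeline, contact statistics are computed on the
refined medoid poses when refinement ran (raw BD endpoints react at
7.5 Å, before 4.5 Å salt bridges form), and on raw reacted endpoints
otherwise.

## Site statistics and density maps

Binding tables report, per site or site group, the reacted count over the
full trajectory denominator, the percentage, and the one-standard-error
binomial half-width 100·√(p(1−p)/n). The 1-SE convention is pinned by a
regression test: it reproduces published half-widths of this table type
(e.g. 24.2 ± 0.1 for 48,463/200,000) where a 1.96 multiplier does not.
Printed values round the half-width to one significant figure and the
percentage to the same decimal place. The energy-versus-contacts
relationship is summarized by an ordinary least-squares slope (kcal/mol
per contact) with its standard error; both per-pose and per-trajectory
aggregation are possible since the regression takes plain (count, energy)
pairs.

Density maps deposit one count per glycan sulfur of each reacted final
pose into half-open 1.0 Å voxels (boundary points to the higher index);
out-of-grid points go to an explicit overflow tally so in-grid + overflow
always equals the number of deposited points. Gaussian smoothing pads the
grid by 6σ before filtering, conserving mass to better than 10⁻⁶
relative. Grids export to the OpenDX scalar-field dialect readable by
PyMOL/VMD/ChimeraX.

## Test-system and run-size choices

The standard steering test system is a `REAAAK` × 8-layer fibril: an Arg
ladder directly flanked by a Glu ladder, plus a lone Lys ladder — the
minimal geometry exhibiting the acidic-neighbour interference rule. BD
test ensembles use 150 trajectories per glycan variant, q = 2b, a 15,000
step cap, and a 0.1 ps near timestep: at one charge bead per formal
charge, 0.1 ps resolves the 7.5 Å reaction shell with ~0.03 Å diffusive
substeps, so the 0.01 ps default (kept for the package's defaults) is not
needed for these beads. Under these conditions the reacted fraction rises
from 0.29 (tetrasaccharide) to 0.47 (octasaccharide) and from 0.39
(6-O-desulfated) to 0.47 (fully sulfated), and the Lys ladder outbinds
the Glu-flanked Arg ladder roughly 2:1 — the qualitative trends the
method exists to capture.

## What passing tests do and do not show

The generators produce perfectly rigid, perfectly in-register structures
with formal charges and no internal flexibility; real fibrils twist, real
heparin is conformationally dynamic and only statistically sulfated, and
real electrostatics involve dielectric boundaries and ion correlation.
Passing tests therefore validate the machinery (propagation statistics,
criterion logic, clustering, table arithmetic, conservation laws) and the
qualitative electrostatic mechanism, not quantitative binding
probabilities or energies for any particular experimental fibril.
Known limitations: no hydrodynamic interactions, no flexible-chain BD, no
desolvation or nonlinear screening, refinement is a local rigid-body
minimizer, and association rates are diffusion-theory quantities at the
model's bead resolution, not calibrated to experiment.
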