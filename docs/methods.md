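# Methods

This note documents the models implemented in `fretassist`, the default
parameters and why they were chosen, the numerical choices that affect
results, and what the synthetic test systems do and do not establish.

## Dye model: accessible volumes

A dye tethered by a flexible linker is represented by the set of
sterically allowed dye positions (accessible volume, AV) on a regular
grid centered at the attachment atom and covering a sphere of radius
(linker length + largest dye radius). A grid point is accessible when

* a sphere of the dye radius placed there overlaps no protein heavy
  atom's van-der-Waals sphere (radii C 1.7, N 1.55, O 1.52, S 1.8 Å,
  1.7 Å otherwise), and
* the shortest obstacle-avoiding path from the attachment point, computed
  by Dijkstra's algorithm over the 26-connected graph of grid nodes that
  clear the linker half-width, is no longer than the linker.

The flood fill is seeded from free nodes within
max(3 Å, 2·spacing, width/2 + spacing) of the attachment, each carrying
its Euclidean offset as initial cost; the attachment atom itself is
excluded from the obstacle set because the linker replaces it. If no free
node exists in that shell the site is buried and the AV is empty — callers
must treat the site as unlabelable.

Defaults: grid spacing 0.9 Å; linker 20 Å × 4.5 Å width; three dye radii
3.5/4.5/1.5 Å combined as a union with one third of the total weight per
radius (renormalized if a radius variant is empty). These are
configuration defaults for typical long-linker organic dyes and are
overridable per site. The accessible contact volume (ACV) variant
re-weights accessible points whose distance to the nearest vdW surface is
within (contact-layer thickness + smallest dye radius) — 3 Å layer by
default — so that their total weight equals a user-supplied contact
fraction; the fraction has no default because it is calibrated from
residual anisotropy in practice. Both the equal-weight union and the
layer criterion are this package's own explicit conventions.

Observables: `mean_RDA` is the weighted mean over point-pair distances,
evaluated exhaustively when the pair product is ≤10⁶ and otherwise by
weighted Monte-Carlo sampling (100 000 pairs, fixed documented seed
1234567; guided sampling uses 20 000, which keeps the estimator error
well below 0.1 Å on the toy clouds). `Rmp` is the distance between mean
positions; mean_RDA ≥ Rmp always (Jensen).

Distance uncertainties propagate an absolute efficiency error
ΔE = 0.06 — the typical single-molecule value — through the inverse of
E(R) = 1/(1+(R/R₀)⁶): ΔR = ΔE·(1+(R/R₀)⁶)²·R₀⁶/(6R⁵), clamped to
[0.5, 30] Å. The clamp prevents infinite χ² weights for pairs far outside
the sensitive range around R₀ and thereby encodes the design preference
for pairs measured near the Förster radius.

## Quality statistics

χ² is the standard weighted sum of squared distance residuals;
N_dof = N_measurements − N_fit.param. p-values are upper-tail integrals of
the χ² density (`scipy.stats.chi2.sf`). The normalized chi-squared is

    χ²ₙ = χ² / Invχ²(P = 1 − 0.68, N_dof)

where Invχ² is the **upper-tail quantile** of the chi-squared
distribution — the value whose survival probability is 1 − confidence.
(A literal inverse-chi-squared *density* would contradict the defining
property that χ²ₙ = 1 exactly at the 68% bound for every N_dof; the
quantile reading is the consistent one and is what the package
implements.) χ²ᵣ and χ²ₙ are refused, not silently computed, when
N_dof ≤ 0: a model with as many fitted parameters as measurements is not
overdetermined, and the error message directs the user to add
cross-validation pairs.

Screening selects conformers with χ²ₙ < 1 (one sigma) and reports the
ensemble converged when all pairwise Cα RMSDs in the selection are below
3 Å; both thresholds are configuration defaults. Screening uses the
`mean_RDA` observable, since experiments report distribution averages.

## Superposition and lDDT

Cα RMSD uses the closed-form least-squares (SVD) superposition with a
reflection guard; with superposition the score is invariant under rigid
motions to ~1e-6 Å (floating-point SVD noise). The first altloc variant
(highest occupancy) is kept, insertion codes are part of the topology
key, HETATM records are excluded from the Cα selection, and conformers
must match exactly — there is no gap tolerance.

lDDT is superposition-free: for every Cα pair within the 15 Å inclusion
radius **of the reference**, the distance is conserved at tolerance t if
|d_model − d_ref| < t; the score averages the conserved fraction over
t ∈ {0.5, 1, 2, 4} Å. Per-residue scores attribute each pair to both of
its residues; residues with no included pair score NaN. Granularity is
reported as residues per FRET pair ("1:x", one decimal).

## Pair selection

⟨⟨RMSD⟩⟩ makes every conformer the reference in turn: its model distances
play the experiment, with uncertainties from the ΔE propagation evaluated
at the reference's own distances (so insensitive pairs are automatically
down-weighted), χ² and p follow for all conformers, and the p-weighted
mean of the reference's RMSD row (self term included with p = 1,
RMSD = 0) is averaged over references.

During selection N_fit.param defaults to 0, so N_dof equals the subset
size. The three algorithms are deterministic given pool order; all ties
resolve to the lowest pair id. The entropy selector discretizes distances
into fixed 3 Å bins (about one typical ΔR) from the pooled minimum and
uses plug-in (maximum-likelihood) entropies; the first pick maximizes the
marginal entropy, later picks maximize the minimum conditional entropy
against the chosen set. Routing: requests below six pairs use greedy
forward selection, larger requests the entropy selector; backward
elimination runs only on explicit request and warns above 10 000
conformers.

The greedy-forward uncertainty trace falls while informative pairs remain
but may tick up once only redundant candidates are left, because each
added pair also raises N_dof; this is expected behavior of the statistic,
and the regression tests pin the decreasing region on the fixtures.

Complexity heuristic: if the no-measurement baseline (the plain mean of
the RMSD matrix, i.e. p ≡ 1) already meets the target, the model needs
zero fit parameters. Otherwise stage 1 selects pairs with
N_fit.param = 0 until the target ⟨⟨RMSD⟩⟩ is reached; the count estimates
N_fit.param. Stage 2 re-runs the selection with that value held fixed,
seeded with the stage-1 pairs (they are the fitted coordinates; smaller
subsets would leave the statistic undefined), and its count is the
recommended number of measurements — always larger than the estimate, so
N_dof > 0. Pairs whose AV is empty on any conformer are dropped for all
conformers and logged; user-supplied site exclusions (accessibility,
function, conservation) are honored from a CSV, never predicted.

## Guided sampling

One proposal equals one Metropolis decision. Scores are χ²ₙ; acceptance
is exp((χ²ₙ,prev − χ²ₙ,curr)/kT) compared against a uniform draw, with
kT = 0 the greedy limit. The annealing schedule is piecewise-linear
triangular — floor 10⁻³ → peak 1.0 χ²ₙ-units → floor, two cycles by
default; endpoints and cycle count are the published operating points,
the linear ramp shape is this package's reproducibility choice. During
guidance all guiding pairs are effectively fitted, so the run scores with
N_fit.param = 0 for *relative* ranking only; the statistically meaningful
quality is the optional validation score of the best conformer on a
held-out measurement set with N_fit.param equal to the number of guiding
pairs. AVs are cached per site and reused only when every atom within
the grid's reach of the attachment is at an identical position — a purely
conservative optimization that cannot change results.

The built-in proposal engine rotates the second rigid segment of a hinge
protein about a random axis through the hinge Cα by a uniform angle
within ±max_step, redrawing proposals that bring inter-segment Cα pairs
closer than 3 Å (the hinge ±2 residues are covalently connected and
exempt) up to a bounded retry count, after which the move stalls in
place and is flagged.

## RMP restraints

Pseudoatoms sit at AV mean positions and are anchored to the Cα and Cβ
atoms of the attachment residue and its ±2 neighbors (ten anchors
mid-chain; fewer at chain ends and across glycines). Restraint targets
convert the measured average distance to a mean-position target,
R_exp = R_ref − (mean_RDA − Rmp) evaluated on the generation conformer,
because forces act between mean positions while experiments average over
the dye distributions.

Each restraint is harmonic (k = F_max/ΔR before tuning) within one
standard error of R_exp and constant at k·ΔR ≤ F_max = 50 pN beyond, with
a continuous force at the crossover. Tuning scales constants down by a
common per-pseudoatom factor — iterated to a fixed point, since a
restraint takes the most restrictive factor of its two ends — so that the
vector sum of cap forces along the current geometry never exceeds F_max
at any pseudoatom; collinear restraints share the budget (two parallel
restraints halve, two orthogonal ones scale by 1/√2). Anchor constants
are ten times the largest tuned restraint constant at their pseudoatom.

DISANG dialect (documented for bit-reproducibility): FRET restraints use
r2 = R_exp − ΔR, r3 = R_exp + ΔR, r1 = max(0, r2 − 2ΔR), r4 = r3 + 2ΔR,
with rk2 = rk3 chosen so the parabola reaches the cap force at r1/r4;
anchors are plain harmonic bonds with a ±10 Å formal linear region.
AMBER's rk is the E = rk·(r−r2)² convention (force 2·rk·Δr), written in
kcal mol⁻¹ Å⁻², using 1 kcal mol⁻¹ Å⁻² = 69.48 pN/Å at the gradient
level. Within the flat bottom (±1σ, where the measurement cannot
distinguish distances) the emitted file applies no force; the in-memory
force model is the stricter harmonic-linear profile used for analysis and
tuning. MD execution is out of scope: the intended protocol regenerates
pseudoatoms and restraints from a fresh snapshot every ~2 ns (the
`restraints` command is re-runnable on any snapshot), and the sidecar
lists the topology requirements (pseudoatoms massless-coupled, excluded
from nonbonded interactions) as a checklist rather than enforcing them.

## Synthetic test systems

The hinge toy is two internally rigid ideal helices (2.3 Å radius, 1.5 Å
rise, 100° twist — 3.8 Å Cα virtual bonds) joined at a hinge residue,
with pseudo-Cβ stubs pointing away from the helix axis; the single
parameter θ rotates the second segment about a fixed axis through the
hinge Cα. Toy study conditions, chosen once: 20 residues per segment;
dye linker 10 Å × 3 Å width with a single 2 Å dye radius on a 1 Å grid
(small AV grids, every clash/path code path exercised); Förster radius
30 Å, matching the toy's inter-dye distance range the way an
experimentalist matches a dye pair to the expected distances; ΔE = 0.06.
The benchmark target sits at a 90° bend with seed conformers 10–40° away
on both sides, because distance sensitivity to bending vanishes near the
straight conformation (the end-to-end distance is stationary at θ = 0)
and real hinge studies operate between distinct bent states. Guided
recovery is measured on the scalar bend angle: inter-dye distances
constrain bend magnitude strongly but are nearly blind to the azimuthal
cone direction of a bend and to twist of a helix about its own axis along
an elongated molecule, so those soft modes are not part of the recovery
metric. The bend readout itself carries a small geometric bias (≲2° at
large bends) that cancels when two conformers are compared.

What the toys do not establish: realism of side-chain packing (residues
are Cα+Cβ only, vdW 1.7 Å), AV accuracy against explicit-dye simulations,
performance on experimental uncertainty structure beyond the Gaussian
ΔE model, or behavior of the proposal interface with a real geometric
simulation engine. The RMSD checks against the open/closed crystal pairs
of adenylate kinase and the LAO-binding protein require the PDB entries,
which cannot ship with the package; the corresponding tests report the
required inputs when the files are absent.

## Numerical choices and limitations

* Chi-squared functions come from scipy; the χ²ₙ normalization, AV
  geometry, selection statistics and restraint mechanics are implemented
  here and validated against independent oracles (quadrature, Monte-Carlo
  draws, brute-force enumeration, exhaustive search) in the test suite.
* All stochastic operations take explicit seeds and are reproducible
  bit-for-bit; seed-free operations are deterministic given input order.
* Problem sizes in the test suite (≤20-conformer ensembles, ≤10-pair
  pools, 150-iteration guided runs, 10-seed recovery experiments) are
  chosen so the full suite runs on one CPU in a few minutes while still
  exercising every statistical property at meaningful power.
* Ensemble-averaged multi-state fitting, Bayesian conformer weighting,
  κ² orientation modeling beyond a fixed R₀, photophysics and mmCIF
  input are out of scope.
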