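# fretassist

Design, screening, guidance and restraint generation for FRET-assisted
structural modeling of proteins.

Single-molecule FRET experiments report sparse sets of inter-dye distances
R_DA with quantitative uncertainties. Combined with computational
conformational sampling they can resolve state-specific structures of
flexible, multidomain proteins — but only if the experiment is designed
well (which labeling sites? how many pairs?) and the resulting models are
assessed with defensible statistics. `fretassist` implements that whole
loop for ensembles of candidate conformers:

1. **Dye simulation.** Each labeled site is modeled by the accessible
   volume (AV) of a dye on a flexible linker: a grid search for all
   sterically allowed dye positions whose obstacle-avoiding linker path
   from the attachment atom fits the linker length. Observables are the
   distribution-averaged inter-dye distance (mean R_DA) or the
   mean-position distance (R_mp); an accessible-contact-volume (ACV)
   variant models surface sticking. Distance uncertainties follow from
   propagating an absolute efficiency error ΔE (0.06 by default) through
   E(R) = 1/(1 + (R/R₀)⁶).

2. **Statistics.** A conformer is scored against a measurement set by

       χ² = Σᵢ ((R_conf⁽ⁱ⁾ − R_ref⁽ⁱ⁾) / ΔR_ref⁽ⁱ⁾)²,   N_dof = N_meas − N_fit.param

   with p-values from the χ² survival function. Because a fixed confidence
   level maps to different reduced χ²ᵣ = χ²/N_dof as N_dof changes, models
   are compared on the **normalized chi-squared**
   χ²ₙ = χ² / Invχ²(P = 1−0.68, N_dof), which equals 1 at the one-sigma
   confidence bound for *any* N_dof. Conformers with χ²ₙ < 1 form the
   FRET-selected ensemble; the workflow is converged when their pairwise
   Cα RMSD stays below 3 Å.

3. **Experiment design.** The expected model uncertainty of a candidate
   pair set is the double average
   ⟨⟨RMSD⟩⟩ = (1/N) Σ_ref (Σ_conf p·RMSD / Σ_conf p), where each conformer
   in turn plays the reference and p-values weight the pairwise RMSD
   matrix. Greedy forward selection, greedy backward elimination and a
   conditional-entropy (minimum-redundancy) selector minimize ⟨⟨RMSD⟩⟩;
   a two-stage heuristic estimates the effective number of fit parameters
   and the recommended number of measurements including cross-validation.

4. **Guided sampling.** A Metropolis–Hastings wrapper accepts proposed
   conformers with P = exp((χ²ₙ,prev − χ²ₙ,curr)/kT), annealing kT in
   triangular cycles between ~0 and 1 χ²ₙ-units (two cycles by default)
   over a pluggable proposal engine (a rigid two-segment hinge mover is
   built in).

5. **Restraints for MD.** For restrained all-atom refinement the package
   emits restrained-mean-position (RMP) pseudoatoms: one per site at the
   AV mean position, anchored to the Cα/Cβ atoms of the attachment residue
   ±2 neighbors (ten anchors mid-chain), with harmonic-linear distance
   restraints capped at F_max = 50 pN beyond one standard error and
   per-pseudoatom force constants tuned for collinearity. Output is an
   AMBER-dialect NMR restraint file (DISANG) plus a JSON sidecar.

Everything is testable offline: `synthetic_fixtures` generates two-segment
hinge-bending toy proteins with labeling sites and simulated reference
distances.

## Worked example

```python
from fretassist.synthetic_fixtures import (
    HingeToySpec, make_benchmark_case, make_hinge_conformer, hinge_angle)
from fretassist.structure_io import rmsd_matrix
from fretassist.pair_selection import select_greedy_forward
from fretassist.screening import screen_ensemble
from fretassist.guided_sampling import ToyHingeEngine, make_schedule, run_guided

spec = HingeToySpec()
case = make_benchmark_case(spec, target_theta=90.0,
                           seed_thetas=[50, 65, 80, 100, 110, 120], seed=1)

rmat = rmsd_matrix(case.ensemble)
trace = select_greedy_forward(case.pool, rmat, max_pairs=4)
result, selection = screen_ensemble(case.ensemble, case.pairs,
                                    case.measurements, grid_spacing=1.0)
engine = ToyHingeEngine(spec.segment1, spec.segment2, spec.hinge_res_id,
                        max_angle_step=8.0)
run = run_guided(make_hinge_conformer(spec, 130.0), engine, case.pairs,
                 case.measurements, make_schedule(150), seed=101,
                 grid_spacing=1.0)
```

prints (abridged):

```
  +A:7:CB--A:35:CB: expected uncertainty <<RMSD>> = 0.16 A
  +A:7:CB--A:40:CB: expected uncertainty <<RMSD>> = 0.13 A
conformer    chi2     p  chi2_r  chi2_n  selected
 theta=50 205.850 0.000  22.872  19.816     False
 theta=80  16.523 0.057   1.836   1.591     False
theta=100  21.290 0.011   2.366   2.049     False
theta=120 194.759 0.000  21.640  18.748     False
guided run: best chi2_n = 0.001, hinge angle 88.9 deg (target 88.8 deg)
```

Read: the greedy selector ranks cross-hinge pairs by how far they push the
expected model uncertainty down. Screening shows that *no* conformer of
the prior ensemble reaches χ²ₙ < 1 (the best, θ = 80°, sits at 1.59 — more
than one sigma from the data), so the workflow branches into FRET-guided
refinement, which starts 40° away and converges onto the target hinge
angle with χ²ₙ ≈ 0 (the measurements here are noise-free).

The same steps are available from the shell:

```sh
fretassist fixtures --out fx
fretassist simulate-data --pdb fx/hinge_ensemble.pdb --pairs fx/pairs.csv \
    --r0 30 --grid-spacing 1.0 --out sim
fretassist screen --ensemble fx/hinge_ensemble.pdb --pairs fx/pairs.csv \
    --measurements sim/measurements.csv --r0 30 --grid-spacing 1.0 --out scr
```

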