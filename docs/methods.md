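# Methods

## The problem

Saturation transfer difference (STD) NMR maps the binding epitope of a
weakly bound ligand: selective saturation of protein protons leaks into the
bound ligand through dipolar cross-relaxation, and the per-proton STD
intensities, in relative terms, report which ligand protons face the
protein.  The least biased per-proton observable is the initial slope STD0
of the saturation build-up curve, because at t → 0 differential ligand
T1 relaxation, rebinding and saturation-extent artifacts have not yet
accumulated.  `stdmat` predicts relative STD0 epitopes directly from the 3D
coordinates of a protein–ligand complex and scores models — crystal
structures, docking poses, MD frames — against experimental epitopes with
the NOE R-factor.

## Reduced-matrix initial slopes

The full description of an STD experiment on a two-site exchange system is
a coupled relaxation + exchange master equation for the magnetization of
every proton in both free and bound species.  `stdmat.full_matrix_oracle`
implements exactly that (below), but the package's working method is a
drastic and exact-at-t=0 reduction: at the instant saturation begins, every
spin except the clamped (saturated) protein protons still sits at thermal
equilibrium, so the only non-zero time derivatives are those driven
directly by the clamped spins.  The initial slope of ligand proton k is
therefore

    STD0_k = - ( Σ_j σ_kj · I0_E2',j ) / I0_L,k

where σ_kj is the cross-relaxation rate between bound-ligand proton k and
saturated bound protein proton j, I0_E2' is the thermal-equilibrium
intensity of the saturated bound pool (∝ the complex concentration [PL])
and I0_L is the observed ligand intensity (∝ total ligand, since free and
bound pools are both detected and in fast exchange on the detection
timescale).  The module assembles this as a matrix M of cross-relaxation
row-blocks into the saturated set, scaled by the saturated pool's
equilibrium intensity; the bound-ligand rows of M give the epitope.
Free-protein and bound-unsaturated-protein row-blocks are assembled too
(they are needed by the oracle and document the structure of the
approximation) but do not enter the ligand epitope.

Consequences, stated as design positions rather than accidents:

* **Exchange kinetics drop out.**  The initial slope does not depend on
  kon/koff, only on the equilibrium populations.  This is what removes the
  main parameter-fitting burden of full-matrix approaches.
* **Relayed (protein-mediated spin-diffusion) pathways are absent** from
  STD0 by construction — they are second order in time.  This is the key
  physical approximation: it is exact for the initial slope and only the
  initial slope.
* **Absolute scale is arbitrary.**  STD0 scales linearly with [PL]; all
  comparisons use relative epitopes normalized to the strongest proton
  (= 100 %), so the global proportionality constant and any self-consistent
  spectral-density convention cancel.
* Sign convention: in the slow-tumbling regime of a protein-sized complex
  σ < 0, and STD0 as defined above is positive (saturation transfer).  If a
  user forces extreme-narrowing parameters the calculated slopes can turn
  non-positive, and normalization refuses with "no saturation pathway".

## Relaxation rates

Rates use the unnormalized Lorentzian spectral density
J(ω) = τc/(1 + ω²τc²) with the dipolar prefactor
q = (μ0/4π)² γH⁴ ħ² / 10 (CODATA constants via `scipy.constants`):

    σ(r)  = q r⁻⁶ (6 J(2ω0) − J(0))
    ρ(i)  = Σ_j q r_ij⁻⁶ (6 J(2ω0) + 3 J(ω0) + J(0))

A single isotropic correlation time describes the whole bound complex (the
method takes exactly one τc input, e.g. 34.5 ns for a ~70 kDa sialidase
domain or 10 ns for a bromodomain); ligand internal motion is not modeled.
Methyl protons are treated as three explicit point spins at their
instantaneous coordinates — no model-free internal-motion correction — with
an optional ⟨r⁻⁶⟩ arithmetic averaging over the three protons
(`methyl_averaging`) for sensitivity analysis; the per-group rate sum is
conserved by that averaging.  Distances below 0.5 Å are rejected as steric
clashes rather than silently producing huge rates.

## Spin-system construction

Inputs are two PDB files (protein, ligand; the ligand file may hold many
MODEL blocks = docking poses) parsed with Biopython in strict mode.  Both
must be protonated upstream; the package never adds hydrogens.  All ligand
file atoms are ligand — no HETATM guessing.  Saturated protons are chosen
by the "all protein methyl protons" rule (ALA/VAL/LEU/ILE/THR/MET and
ACE/NME caps, by residue/atom-name dictionary in AMBER/PDBv3 naming; THR
HG1 is a hydroxyl and excluded) or by an explicit `resid:atomname` list.
Protein protons farther than the cutoff (default 12 Å, the 10–12 Å range
appropriate for these systems) from every ligand proton are pruned, per
structure and per frame.  Exchangeable ligand protons (nearest bonded heavy
atom O/N/S) are kept as spins but dropped from epitope comparison by
default, since their experimental STD0 in H2O is unreliable; an explicit
`epitope_key` overrides this.  Degenerate protons (methyls, equivalent
pairs) are merged by arithmetic mean of absolute STD0 before
renormalization.

## Binding thermodynamics

1:1 stoichiometry only.  [PL] is the physical root of
x² − (P+L+Kd)x + PL = 0, evaluated in the cancellation-safe conjugate form
2PL/(s + √(s²−4PL)); mass-balance and Kd residuals hold to 1e-9 relative
across twelve orders of magnitude of inputs (property-tested).

## Scoring

Experimental epitopes come in either as relative STD0 percentages or as
long-format build-up tables fitted to STD(t) = STDmax(1 − e^(−ksat t))
with `scipy.optimize.curve_fit` (initialization: STDmax0 = max observed
STD, ksat0 = 1/t at half-max, both bounded positive), STD0 = STDmax·ksat.
Agreement is the NOE R-factor

    R = sqrt( Σ_k W_k (STD0exp_k − STD0cal_k)² / Σ_k W_k (STD0exp_k)² )

on relative values over the shared proton keys, W_k = 1 by default;
R < 0.3 (strict) classifies a model as in good agreement.  Fewer than 4
matched protons triggers a warning: with very few or overlapped resonances
both false-positive and false-negative validations become likely.

## Full-matrix oracle

`full_matrix_oracle` propagates the complete Solomon + two-site-exchange
generator over four pools (free/bound × ligand/protein) with the saturated
protein protons hard-clamped at zero intensity in both states, via a dense
augmented matrix exponential, capped at 40 spins.  Free ligand tumbles with
τc_free (default 0.5 ns); the free protein keeps the bound τc (a free
protein is still a protein).  Free-species geometry equals bound geometry
(no conformational change).  Initial slopes are extracted by
Richardson-refined forward differences with a linear-regime guard
(t1 ≤ 0.01/max|eig|).  The oracle exists to validate the reduced matrix —
the initial slope of the full solution is analytically independent of the
exchange rates, and the test suite verifies agreement within 2 % per proton
across a koff ladder of 10²–10⁵ s⁻¹ — and to demonstrate why single-time
STD factors (which are biased by differential auto-relaxation) can validate
the wrong model when initial slopes would not.  It is a validation tool,
not a full STD simulator: no partial saturation, no NOESY-style intensity
normalization.

## Trajectory mode

Topology + trajectory are read with MDAnalysis (AMBER prmtop with
NetCDF/DCD, or multi-model PDB).  Coordinates are used as stored: frames
must be pre-imaged.  The saturated set and the cutoff pruning are
recomputed per frame, since binding-pocket composition changes as side
chains adapt; epitope vectors are aligned across frames by proton key,
never by index.  A frame is *dissociated* exactly when no saturated protein
proton survives the pruning — the condition under which STD0 is undefined —
and gets no R-factor.  Frames with R below a threshold can be exported as a
multi-model PDB.  Ligand RMSD versus a reference frame superposes the
reference's heavy binding-site atoms (default within 6 Å of the ligand) and
then measures heavy-atom ligand RMSD without further fitting.

## Synthetic fixtures and what they do / do not show

The fixture generator scripts small rigid geometries (an isolated
ligand–source proton pair; two ligand protons against one source; a single
methyl facing a probe proton; an ALA–VAL–GLY tripeptide with a 4-proton
ligand over the valine side chain; docking-pose sets and 10-frame
trajectories with displaced/rotated ligand segments).  Ground-truth
sidecars are computed by straight-line brute force (pairwise distances,
r⁻⁶ sums, plain RMSD) without importing the analysis modules, and all
randomness sits behind one seeded generator, so identical spec + seed gives
byte-identical files.  These fixtures exercise bookkeeping, geometry and
the relaxation algebra exactly; they do not emulate conformational
flexibility, realistic force-field motion, spectral overlap, partial
saturation or noise sources of real spectra, so passing tests demonstrate
correctness of the method's arithmetic and plumbing, not the accuracy of
the physical model on real complexes — that is what scoring real structures
against measured epitopes is for.

## Numerical choices and problem sizes

* PDB coordinate precision (3 decimals) bounds fixture round-trips; the
  corresponding tolerance is 1e-3 Å.
* Build-up fits use 8-point grids spanning several 1/ksat; noiseless
  recovery is verified at 1e-6 relative, and the noisy-recovery study uses
  2 % Gaussian noise with 100 seeded replicates.
* Oracle validations run on 2–13-spin systems, where the matrix
  exponential costs microseconds; static scoring of realistic systems is
  vectorized over proton pairs (`scipy.spatial.distance.cdist`) and takes
  well under a second for a 300-residue protein at a 12 Å cutoff.
* Ties in the static-mode ranking are broken by model index; sorting is
  stable.

## Known limitations

Single isotropic τc; no anisotropic diffusion, CSA or cross-correlated
relaxation; hard (complete) saturation of the selected protons with no
frequency-offset selectivity; no ligand T1 leakage term in the reduced
slopes (an external-leakage hook exists in the auto-relaxation rate but
defaults to 0); 1:1 binding only; no fitting of τc or Kd to data; PDB v3
naming assumed for methyl identification; no mmCIF input.
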