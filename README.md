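# stdmat

Fast prediction of STD NMR initial slopes (STD0) from 3D models of
low-affinity protein–ligand complexes, and quantitative scoring of static
structures, docking-pose ensembles and MD trajectories against experimental
binding epitopes via the NOE R-factor.

## Who this is for

Saturation transfer difference (STD) NMR is a routine ligand-observed
experiment for weak binders (Kd ~ μM–mM), the regime of fragment-based
drug discovery and protein–carbohydrate recognition.  The experiment
yields a *binding epitope*: per-proton relative STD0 values (strongest
proton = 100 %) reporting which ligand protons contact the protein.
`stdmat` answers the inverse question — *does a candidate 3D model of the
complex reproduce the measured epitope?* — fast enough to rescore hundreds
of docking poses or every frame of an MD trajectory.

## Method in brief

At zero saturation time every spin except the directly saturated protein
protons is at thermal equilibrium, so the initial slope of each ligand
proton's STD build-up depends only on its direct dipolar cross-relaxation
with the saturated set.  For ligand proton *k*:

    STD0_k = − ( Σ_j σ_kj · I0_E2′,j ) / I0_L,k
    σ(r)   = q r⁻⁶ ( 6J(2ω0) − J(0) ),   J(ω) = τc / (1 + ω²τc²)

with I0_E2′ ∝ [PL] from the 1:1 binding quadratic and I0_L ∝ [L]total.
This "reduced matrix" bypasses the full relaxation/exchange build-up
simulation: no kinetic rate constants, no time propagation — a complex
scores in well under a second.  Agreement with experiment is the NOE
R-factor

    R = sqrt( Σ_k W_k (STD0exp_k − STD0cal_k)² / Σ_k W_k (STD0exp_k)² )

on relative epitopes (W_k = 1); R < 0.3 indicates a validated model.  A
full two-site-exchange solver (`stdmat.full_matrix_oracle`) is included as
an independent brute-force check of the reduced slopes on small spin
systems.  See `docs/methods.md` for assumptions, parameters and limits.

Inputs: protein PDB + ligand PDB (multi-MODEL = docking poses), or AMBER
topology + trajectory (via MDAnalysis); the experimental epitope as a
two-column table (proton key, relative STD0 %) or a long-format build-up
table (key, t_sat, STD), which is fitted to STD(t) = STDmax(1 − e^(−ksat·t)),
STD0 = STDmax·ksat.  Structures must be protonated upstream — no hydrogens
are added.  Experimental parameters: spectrometer frequency (MHz), bound
τc (ns), protein/ligand concentrations (μM), Kd (μM), cutoff (Å).

## Worked example

Generate the bundled miniature complex (ALA-VAL-GLY tripeptide + 4-proton
ligand), use its closed-form r⁻⁶ epitope as the "experimental" input, and
score the structure:

```sh
stdmat fixtures mini_complex --out fx
python - <<'PY'
import json
t = json.load(open("fx/ground_truth.json"))
open("exp_epitope.tsv", "w").write(
    "".join(f"{k}\t{v:.4f}\n" for k, v in t["relative_epitope"].items()))
PY
stdmat static --protein fx/protein.pdb --ligand fx/ligand.pdb \
       --epitope exp_epitope.tsv --tau-c-ns 34.5 --kd-um 2000 \
       --protein-conc-um 20 --ligand-conc-um 1000
```

prints

```
INFO bound ligand fraction 0.0066 ([PL]=6.637 uM)
 model  r_factor  n_matched classification error
     0     0.000          4           good
```

Reading: at 20 μM protein, 1 mM ligand and Kd = 2 mM, 6.637 μM of complex
is formed (0.66 % of the ligand is bound — typical STD conditions).  The
single ligand model reproduces all four experimental proton values exactly
(the fixture's epitope *is* the r⁻⁶ prediction), so the NOE R-factor is
0.000, far below the 0.3 validation threshold.  With a multi-MODEL ligand
file, one row per pose is printed sorted by R-factor, which is how docking
poses are ranked.  `stdmat dynamic --topology ... --trajectory ...`
produces the per-frame R-factor time series instead, with dissociated
frames (no saturated protein proton within the cutoff) marked `NA`, and
can export sub-threshold frames as a multi-model PDB.

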