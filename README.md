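# tyrgate

Conformational dynamics of the FimH tyrosine gate and the binding
thermodynamics of its mannoside antagonists, as a tested, reusable
analysis pipeline.

FimH is the adhesin at the tip of *E. coli* type-1 fimbriae; its lectin
domain binds mannose, and the entrance to the binding pocket is flanked
by a hydrophobic clamp — the *tyrosine gate* of Tyr48 and Tyr137,
bridged by Ile52 — that grips the aglycon of synthetic mannoside
antagonists such as *n*-heptyl α-D-mannopyranoside (HM) and
4-biphenyl α-D-mannoside (BF). `tyrgate` implements the desk-scale
analysis layer used to study how gate mutations (Y48A, Y137A)
reshape conformation and affinity:

* **Trajectory analysis** — multi-model PDB I/O with a declarative atom
  selection language; backbone φ/ψ extraction; periodic dihedral
  distributions and signed circular mode shifts between ligand-free and
  ligand-bound states; GROMOS (Daura) conformational clustering of the
  gate side chains at an RMSD cutoff (default 1.5 Å); joint
  distance–probability maps of the Ile52 side-chain centre of mass
  against both tyrosines; per-atom r.m.s.f. and bound-minus-free
  Δr.m.s.f. ligand flexibility profiles after mannose-ring alignment;
  rigid dihedral-scan geometry grids (±n·step) for external QM engines.
* **Thermodynamics** — ΔG = RT ln K_d and TΔS = ΔH − ΔG decompositions
  (R = 8.314 J mol⁻¹ K⁻¹, T = 298.15 K by default), relative affinities
  rK_d, the Wiseman c-value c = M_t(0)/K_d with its 10–600 fittable
  window, exact single-site ITC isotherm fitting, four-parameter
  logistic IC₅₀ fitting with relative IC₅₀, and the two-state
  linear-extrapolation unfolding fit with midpoint D₁/₂ = |ΔG_fold|/m.
* **Synthetic data** — every input the pipeline consumes can be
  generated with known ground truth: idealized toy peptides with
  prescribed φ/ψ, trajectories sampling von Mises dihedral wells or
  discrete conformer mixtures, ligand trajectory pairs with per-atom
  fluctuation amplitudes, and ITC/unfolding/dose–response curves.

MD force-field simulation, QM energy evaluation and crystallographic
refinement are out of scope; the pipeline analyses their outputs.

## Worked example

```python
import numpy as np
from tyrgate import Selection, daura_cluster, binding_thermo as bt
from tyrgate import synthetic_data as sd

# thermodynamic fingerprint of n-heptyl mannoside binding to WT FimH
dG = bt.dG_from_Kd(28.9e-9)                  # Kd = 28.9 nM at 298.15 K
TdS = bt.TdS(dH=-50.3, dG=dG)
print(f"dG  = {bt.round_half_away(dG, 1):.1f} kJ/mol")
print(f"TdS = {bt.round_half_away(TdS, 1):.1f} kJ/mol")
print(f"rKd(Y137A/WT) = {bt.round_half_away(bt.relative_Kd(206.4e-9, 28.9e-9), 1):.1f}")

# cluster a synthetic tyrosine-gate conformer mixture
template = sd.build_toy_peptide("AYA", start_resid=47)
spec = sd.TrajectorySpec(
    template=template, n_frames=1000,
    conformers=[{(48, "phi"): -140.0, (48, "psi"): 140.0},
                {(48, "phi"): -60.0, (48, "psi"): -45.0},
                {(48, "phi"): 60.0, (48, "psi"): 45.0}],
    weights=[0.5, 0.3, 0.2], sigma=0.02, seed=1,
)
traj, truth = sd.generate_trajectory(spec)
gate = Selection(resids={48}, sidechain=True, heavy_only=True)
result = daura_cluster(traj, gate, None, cutoff=1.5)
print("cluster populations (%):", result.populations)
```

prints

```
dG  = -43.0 kJ/mol
TdS = -7.3 kJ/mol
rKd(Y137A/WT) = 7.1
cluster populations (%): [50.0, 30.0, 20.0]
```

The ΔG/TΔS pair is the enthalpy-driven fingerprint of HM binding to the
wild-type lectin domain; the 7.1-fold K_d ratio quantifies the affinity
loss caused by removing the Tyr137 side chain. The clustering run
recovers a known 50/30/20 three-conformer gate mixture exactly at the
1.5 Å cutoff.

## Command line

The same operations are available as subcommands, each writing CSV
tables and a reproducibility manifest:

```sh
tyrgate simulate --kind mixture --n-frames 1000 --seed 1 --out fixtures/
tyrgate cluster --traj fixtures/mixture.pdb \
    --sel "resid 48 and sidechain and noh" --out clusters/
tyrgate dihedrals --traj free.pdb --state-tag ligand_free \
    --traj bound.pdb --state-tag HM_bound --resids 136-138 --out shifts/
tyrgate flex --traj bound.pdb --traj water.pdb --sel noh \
    --align-sel "name C1 C2 C3 C4 C5 O5" --out flex/
tyrgate thermo --binding-table table3.csv --out thermo/
```

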