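# caspfold

Analysis toolkit for conformational ensembles of caspase-family proteases:
typed residue-interaction networks with degree and betweenness centrality,
essential dynamics (coordinate PCA and free-energy landscapes with
metastable-state extraction), and global equilibrium-unfolding
thermodynamics — plus a synthetic-data generator so every stage can be
validated end-to-end by parameter recovery, without MD trajectories or
wet-lab data.

## Who this is for

Caspases (and structurally similar protein families) interconvert between
monomeric, dimeric and active conformations, and their stability and
allosteric regulation are shaped by conserved cores of non-covalent
interactions. This package supports three complementary analyses of that
picture:

1. **Residue-interaction networks (RIN).** Each residue is a node; edges are
   van der Waals, hydrophobic and electrostatic atom–atom contacts within a
   4 Å heavy-atom cutoff, counted per frame and averaged over the ensemble.
   Degree centrality DC(v) = Σ_e w_e over incident edges measures how densely
   a residue is packed; betweenness centrality BC(v) = Σ_{s<t} σ_st(v)/σ_st
   (unnormalized, edge length 1/w) measures how often it bridges shortest
   communication paths. Per-residue metrics can be partitioned by structural
   region or ConSurf conservation bin (high 8–9, intermediate 6–7, variable
   1–5), classified into hubs (DC > 20 **and** BC > 1000 by default), and
   averaged per alignment column across a family of homologs.

2. **Essential dynamics.** Frames are Kabsch-superposed, the coordinate
   covariance is eigendecomposed, and the trajectory is projected onto
   PC1/PC2. The free-energy landscape is G = −RT ln(P/P_max) on a 2D
   histogram (empty bins masked); its persistent local minima are the
   metastable states, each with a representative frame.

3. **Equilibrium-unfolding thermodynamics.** Linear extrapolation method:
   ΔG_i(urea) = ΔG°_i − m_i·[urea], K_i = exp(−ΔG_i/RT). Two-state (N ⇌ U)
   and three-state monomer (N ⇌ I ⇌ U) models, with observed signal the
   population-weighted sum of per-probe species baselines. Global fits share
   ΔG°, m across probes, concentrations and directions (variable projection +
   Latin-hypercube multistart), report standard errors and AIC, and a
   concentration-dependence check flags whether the mechanism is consistent
   with a monomer. Single-exponential fits of limited-proteolysis band
   intensities give apparent cleavage rate constants.

## Worked example

Fit synthetic three-state unfolding data (three probes, 2/6/8 µM protein,
0–9 M urea, 2 % Gaussian noise) generated from the `"21M"` preset
(ΔG°₁ = 1.0, ΔG°₂ = 2.7 kcal/mol):

```python
from caspfold import synthetic, thermo

datasets = synthetic.make_unfolding_datasets(
    synthetic.PRESETS["21M"], noise_sd_fraction=0.02, seed=11)
fit = thermo.global_fit(datasets, "three_state", n_starts=25, seed=11)
print([round(g, 2) for g in fit.params.dG_list],
      [round(m, 2) for m in fit.params.m_list], round(fit.total_dG, 2))

report = thermo.concentration_dependence_test(datasets)
print(report.concentration_independent)
```

prints

```
[1.04, 2.89] [0.54, 0.73] 3.93
True
```

i.e. the fit recovers the generating free energies (1.0 and 2.7 kcal/mol,
total 3.7) and m-values (0.5, 0.7 kcal·mol⁻¹·M⁻¹) within the noise, and the
normalized curves overlay across protein concentrations as a monomer model
requires.

The same workflow is available from the shell, end to end:

```
caspfold pipeline run --demo --out demo_run --seed 7
```

which simulates a toy ensemble, builds the network, computes the PC1/PC2
free-energy landscape (one basin at G = 0 for this unimodal demo), fits the
folding data (ΔG° = [1.10, 2.78] kcal/mol at this seed), and writes every
artifact plus a hashed manifest under `demo_run/`. See `caspfold --help`
for the individual `simulate`, `rin`, `fel`, `foldfit` and `rin-average`
subcommands.

## Layout

- `caspfold.synthetic` — toy ensembles with planted orthonormal modes,
  unfolding-curve presets, conservation and region tables
- `caspfold.ensemble` — the multi-frame coordinate container, multi-model
  PDB I/O
- `caspfold.rin` — contact detection and typing, network construction,
  DC/BC, hub classification, family averaging
- `caspfold.dynamics` — superposition, PCA, projections, free-energy
  landscape, basins
- `caspfold.thermo` — folding models, global fitting, concentration
  dependence, proteolysis kinetics
- `caspfold.pipeline` / `caspfold.cli` — YAML-configured orchestration and
  the `caspfold` command

Methodological details and design rationale are in `docs/methods.md`.
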