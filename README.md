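# memdyn

Conformational-dynamics analysis for membrane-receptor MD ensembles — the
kind of question asked of a seven-transmembrane (TM1–TM7 + H8) GPCR bundle
in a lipid bilayer: which helices are rigid and which flexible, is the
secondary structure intact, how hydrated is the hydrophobic core, what is
the dominant collective motion and is it converged, and which helices move
in concert.

The package implements the full analysis chain as a library with an
orchestration layer, plus a synthetic-ensemble generator with planted
ground truth so every stage is testable against exact answers:

* **Superposition & fluctuations** — Kabsch fit of every frame onto the
  conformation at time 0; per-helix RMSD(t); Cα RMSF with replica
  mean ± SD over runs R0–R2.
* **Secondary structure** — dictionary-style assignment from backbone
  H-bonds via the Kabsch–Sander energy
  `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol`,
  α-helix from consecutive i→i+4 turns; per-segment helix counts.
* **Contacts & H-bonds** — heavy-atom contact occupancies for a focal
  residue; geometric donor–H–acceptor hydrogen-bond detection.
* **Membrane profiles** — number density along the bilayer normal
  normalized by `dz·A_average`; hydrophobic-core and interface detection;
  hydration by integrating the water profile over (−10, 10) Å.
* **Essential dynamics** — Cα covariance `C = ⟨Δx Δxᵀ⟩`, PCA, projections
  `p_i(t) = v_i·(x(t) − ⟨x⟩)`, cosine content
  `CC = (2/T)(∫cos(πt/T)p dt)²/∫p²dt` (CC → 1 flags random-diffusion-like,
  unconverged sampling), porcupine-style PC1 motion fields, and
  regression-plane parametrization with replica/phenotype dummies.
* **Correlation networks** — DCCM
  `c_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩)`, |c| ≥ 0.7 edges, Girvan–Newman
  decomposition by iterative removal of the maximum-betweenness edge,
  modularity `Q = Σ_k (e_kk − a_k²)`, communities of ≥ 10 Cα atoms, and
  segment-to-segment connectivity verdicts (e.g. TM2 : TM5).

Input is a PDB topology (plus a segment→residue-range config), and DCD /
XTC / plain-text frame-table trajectories (Å, ps; see
`docs/frame_table_format.md`). `docs/methods.md` documents every model,
default and numerical choice.

## Worked example

`analysis/` holds the numbered study drivers. `01_generate_ensembles.py`
builds an idealized 7-helix bundle and samples two phenotypes of harmonic
Cα ensembles (3 replicas × 600 frames at 100 ps): *functional* with a
planted TM2–TM5 correlation block (ρ = 0.9) emulating concerted
inter-helix motion, and *dysfunctional* with no coupling. The later
scripts then recover exactly what was planted:

```text
$ python analysis/02_fluctuations.py        # excerpt
functional:
segment  rmsd_median_A  rmsf_mean_A  rmsf_sd_A regime
    TM1       1.206558     0.876240   0.006438  rigid
    TM2       0.686099     0.642614   0.006758  rigid
    ...
```

All helices sit in the rigid regime (RMSF < 1 Å, consistent with the
planted σ = 0.5 Å per coordinate, 3D RMSF σ√3 ≈ 0.87 Å); the coupled
TM2/TM5 pair reads lower because part of its shared motion is absorbed by
the superposition fit (see `docs/methods.md`, "gauge").

```text
$ python analysis/05_essential_dynamics.py  # excerpt
functional: PC1 carries 7.8% of the Cα variance
  R0: cosine content of PC1 projection = 0.005
drift-only ensemble: cosine content = 0.998 (close to 1: random diffusion,
unconverged sampling)
```

Stationary ensembles give CC ≈ 0 (converged); the drift-only ensemble
drives the diagnostic to ≈ 1.

```text
$ python analysis/06_network_communities.py
functional: Q = 0.000, reported communities {0: 24}, TM2:TM5 connected = True
dysfunctional: Q = 0.000, reported communities {}, TM2:TM5 connected = False

connectivity matrix:
   pair  functional  dysfunctional
TM2:TM5        True          False
```

The planted TM2–TM5 coupling surfaces as one 24-Cα community containing
both helices — the connectivity verdict a study would use to distinguish a
signalling-competent from a decoupled receptor — while the null plant
yields no reportable community at all.

Intermediate trajectories live under `scratch/` (regenerable, not shipped);
tidy CSV tables land under `results/`.

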