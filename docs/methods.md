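# Methods

`memdyn` analyses the conformational dynamics of membrane-receptor
ensembles — typically the seven-transmembrane (TM1–TM7 + H8) helix bundle
of a class-A GPCR in a lipid bilayer — from topology + trajectory input.
Because such production trajectories are rarely shareable, the package
pairs every analysis stage with a synthetic-ensemble generator that plants
the statistical structure the stage is supposed to detect, so correctness
is established against exact ground truth rather than by eyeballing plots.

## Coordinate model and superposition

Coordinates are in Å, times in ps, boxes orthorhombic `(Lx, Ly, Lz)`;
residue numbers are author-provided (1-based biological numbering, e.g. a
358–646 TM range), atom indices internal and 0-based. Internal motion is
separated from rigid-body motion by a mass-unweighted Kabsch fit of every
frame onto the conformation at time 0 of its own run (SVD of the 3×3
cross-covariance; the smallest singular direction is sign-flipped when the
determinant is negative, so the rotation is always proper). Unweighted
fitting is the reproducible default for Cα-only analyses, where weighting
is immaterial; no iterated mean-structure reference is used.

A consequence worth knowing: the fit defines a gauge. Any collective mode
with a nonzero net translation/rotation component is partially absorbed by
the fit — a mode shared by a fraction *f* of the fitted atoms keeps only
(1−f) of its shared displacement, so pairwise correlations inside such a
block are attenuated by (1−f)². With a planted block correlation ρ = 0.9
spanning 2/7 of the atoms, an all-atom fit recovers ≈ 0.81, while fitting
on the complement (a "rigid-core" fit frame) recovers ≈ 0.87–0.90.
Fit and measure selections are therefore independent arguments everywhere
(default: fit on the full analysis selection); parameter-recovery tests use
the rigid-core fit. The same mechanism lowers the apparent RMSF of
correlated blocks under an all-atom fit — visible in the worked example,
where the coupled TM2/TM5 helices show ~0.64 Å versus ~0.87 Å elsewhere.

## Fluctuation statistics

* `rmsd_series(traj, fit, measure)` — per-frame RMSD against frame 0;
  fitting and measuring selections may differ (e.g. fit the whole TM
  domain, measure one helix). Frame 0 is exactly 0.
* `rmsf(traj, fit, measure, replicas)` — per-atom root-mean-square
  displacement about the time-mean position after fitting; replica
  statistics are the unweighted mean ± SD over runs (R0, R1, R2), each run
  contributing one value per atom regardless of length. `Σ rmsf²` equals
  the trace of the post-fit covariance over the same frames (tested).

## Essential dynamics

The Cα covariance `C = ⟨Δx Δxᵀ⟩` (3N×3N, Å², population normalization) is
accumulated after superposition, with a frame stride parameter defaulting
to 4 ps; eigen-decomposition gives orthonormal modes sorted by descending
variance. Projections are `p_i(t) = v_i · (x(t) − ⟨x⟩)` with each frame
re-fitted to the model's reference.

**Cosine content.** For a projection over total time T,

    CC = (2/T) · (∫₀ᵀ cos(πt/T) p(t) dt)² / ∫₀ᵀ p(t)² dt,

integrals by the trapezoid rule over the actual frame times. This is the
standard single half-period (i = 1) essential-dynamics convergence
diagnostic: CC ≈ 1 means PC1 is indistinguishable from random diffusion
(unconverged sampling); CC is invariant to scaling of p and affine
rescaling of t. Drift-only synthetic ensembles (independent per-atom
random walks of the mean) reproduce the diagnostic regime: the median PC1
cosine content across 50 ensembles exceeds 0.99.

**Motion fields.** The displacement field along a component spans the 1st
to 99th percentile of the projection (robust to single-frame outliers;
trajectory min/max would be noise-dominated), `(p₉₉ − p₁)·v_i` reshaped per
atom, plus the two extreme conformations. Reversing the percentiles
negates the field; a projection span below 1e−10 Å warns and returns a
zero field.

**Regression planes.** Designated Cα motions (any scalar response, e.g.
the z-component of the PC1 field at bilayer-interface atoms) are
parametrized as `response = b0 + b1·x + b2·y + Σ group offsets` by OLS with
treatment-coded dummies (first group is baseline). Group offsets are
tested two-sided at α = 0.05 with Holm correction across offsets — a
procedure choice; any multiplicity rule would do, Holm is assumption-free.
A rank-deficient design is an error that names the collinear columns.

## Dynamical cross-correlation and community networks

`c_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩)` with Δr the 3D displacement from
each atom's time mean, frames at a 100-ps stride. The diagonal is exactly
1; values are clipped to [−1, 1] against rounding; an atom with variance
≤ 1e−12 Å² is an error naming the atom.

The network wires residue pairs with `|c_ij| ≥ cutoff` (default 0.7). The
absolute value is deliberate so strongly anti-correlated pairs also
communicate; a minimum sequence separation (default 2) suppresses trivial
backbone-neighbor edges; an optional contact mask intersects edges with a
physical contact map for the contact-filtered variant of the recipe.
Correlation-only is the default because it is the minimal stated method;
both modes exist.

Girvan–Newman proceeds by removing the edge of maximal betweenness
(unweighted shortest paths — edges are present/absent after the cutoff;
weights are kept for reporting only), recomputing betweenness after every
removal, and recording Newman–Girvan modularity `Q = Σ_k (e_kk − a_k²)` of
the connected-component partition *measured on the original graph*. Ties
in betweenness are broken by lexicographic edge id, so the trace is
reproducible. The returned partition is the earliest one attaining the
maximal Q; an edgeless graph yields singleton communities with Q defined
as 0. Betweenness is cross-checked against exhaustive shortest-path
enumeration on all graphs ≤ 12 nodes, and Q against an independent
modularity implementation. Optimal Q on realistic protein networks
typically falls in 0.4–0.7; the package reports Q but never asserts that
band (a single dense planted block legitimately gives Q = 0).

Reporting filters communities below 10 Cα atoms (the partition itself is
unchanged). The connectivity verdict between segments A and B is true when
an inter-community edge links an A-dominated to a B-dominated community,
or one reported community is dominated by both jointly. "Dominated" means
plurality of members, with ties counting for every tied segment — without
the tie rule a symmetric A∪B community (the natural outcome of a planted
A–B block, which forms a single clique) could never support the verdict.

## Secondary structure, contacts, hydrogen bonds

Backbone H-bonds use the Kabsch–Sander electrostatic energy
`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol < −0.5`, with
the amide H rebuilt 1.0 Å from N opposite the bisector of the C(i−1)–N–CA
angle (first residues and chain breaks carry no H). α/3₁₀/π helices come
from consecutive i→i+4 / i+3 / i+5 turn patterns; strand marks isolated
bridge patterns (no ladder merging); turn and bend (70° CA-curvature) fill
in; priority H > E > G > I > T > S > C. This reproduces the
dictionary-based method without a binary dependency; full 8-class fidelity
on pathological geometry is out of scope. On an ideal 20-residue helix the
assignment matches both the hand-applied turn-pattern rule (18 helix
residues) and an independent DSSP implementation.

Contacts: residue pairs are in contact when the minimum heavy-atom
distance between the focal residue's atoms and the partner's is ≤ 4.5 Å
(a common heavy-atom convention; exposed as a parameter). H-bonds use the
geometric 3.5 Å donor–acceptor / 120° donor–H–acceptor criterion;
chemically equivalent acceptors (carboxylate oxygens) are tracked as
separate triplets. Hydrogens are identified by covalent proximity
(< 1.25 Å) in frame 0.

## Membrane density and hydration

Number densities are histogrammed along z with 1-Å bins, origin at the
bilayer midplane (midpoint of the two leaflet mean-z planes of the
phosphate-like group when given, else the box origin), normalized by
`dz · A_average` with the time-averaged lateral area — so integrating any
group's profile recovers its atom count exactly (tested to 1e−6 relative).
Hydration of the hydrophobic core is the bin-sum of water density × bin
volume over a z interval, default (−10, 10) Å. This caption-literal
integration is the operational definition; a lateral mask around the helix
bundle axis would be a stricter "interhelical" count and is left as an
extension. Bilayer topology: the core is the symmetric interval holding
the central 90% of methyl density (extended to whole-bin edges); each
interface is the half-maximum extent of the corresponding phosphate
leaflet peak; a phosphate distribution without two leaflets is an error.

## Synthetic ensembles — what they emulate and what they do not

`make_bundle_reference` builds ideal α-helices (φ = −57°, ψ = −47°, ideal
bond geometry via natural-extension-reference-frame placement; consecutive
Cα–Cα ≈ 3.80 Å) arranged antiparallel on a circle with ~10 Å inter-axis
spacing, segments TM1..TM7 (+H8), residues numbered from 358 by default.

`sample_ensemble` draws i.i.d. Gaussian displacements per coordinate
(σ default 0.5 Å, i.e. 3D RMSF ≈ 0.87 Å — the "rigid helix" regime;
loop-like flexibility would be σ ≳ 1.2 Å). A correlation block
(segA, segB, ρ) is realised by one shared latent factor with loading √ρ on
every atom of segA ∪ segB, giving pairwise correlation ρ for *all* pairs
inside the union — the only simple construction that is positive
semi-definite for arbitrary block sizes (ρ only on cross pairs is not PSD
beyond a few atoms; the per-axis covariance is eigenvalue-checked at floor
−1e−10 before sampling regardless). Optional drift adds a slow random walk
(per-axis step SD `√(2 D dt)`) to atom means, independent per atom or
shared, optionally restricted to segments. Axes are independent and
identically structured, matching what an isotropic dot-product correlation
(the DCCM) can recover.

`make_membrane_box` places pseudo-atom slabs (water O, phosphate-like P,
methyl-like C) uniformly in their z intervals, defaults emulating a bilayer
with a −10..10 Å hydrophobic core, 15..25 Å interfaces, and water outside;
25 frames by default so profile statistics resemble a time average (a
single frame would make half-maximum interface detection Poisson-fragile,
which is a property of the estimator worth preserving, not hiding).

What the generator does *not* emulate: bonded force-field geometry under
thermal noise (i.i.d. jitter at σ = 0.5 Å disrupts ideal backbone H-bonds,
so per-frame helicity counts on jittered ensembles reflect the planted
correlation structure — internally rigid blocks stay helical, uncorrelated
ones do not — rather than real helix stability), lipid conformers,
electrostatics, or anisotropic fluctuations. Passing tests therefore
establish the correctness of the estimators and decision rules, not the
biophysics of any particular receptor.

## Problem sizes and determinism

Test and acceptance runs use a 7×12-residue bundle (84 Cα), 20 000-frame
ensembles for parameter recovery, 1 200-frame ensembles for the
planted-partition pipeline, and 50-seed batches for distributional claims;
the analysis scripts use 3 × 600 frames per phenotype. All generators are
pure functions of (spec, seed); the pipeline writes every table with fixed
float formatting and sorted JSON keys, so a rerun with the same config and
seed is byte-identical.

## Known limitations

* Girvan–Newman recomputes betweenness after every removal (O(E²V) per
  component); intended for the ≤ a-few-hundred-node networks this analysis
  produces, not for large graphs.
* Secondary-structure strand/bend classes are minimal; only the helix
  classes are load-bearing for the reported counts.
* The XTC container quantizes to 0.001 nm; round trips are exact only in
  the frame-table format.
* The connectivity verdict is defined on the *reported* (size-filtered)
  communities; lowering `min_community_size` can flip a verdict on
  marginal systems — it is a reporting threshold, not a physical one.
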