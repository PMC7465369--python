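# Methods

## Problem

When a protein translocates along double-stranded DNA — a polymerase
elongating a primer, or a protein sliding by one-dimensional diffusion — it
can collide with proteins already bound to the duplex. For DNA glycosylases,
which initiate base excision repair and then linger on their abasic product,
such collisions can either dislodge the enzyme (productive hand-off) or be
blocked (roadblock). This package implements the two computational halves of
that question: a geometric procedure that predicts *where* two protein–DNA
complexes first touch when one slides along the helix into the other, and a
kinetic model that predicts *how* displacement shows up in a two-substrate
cleavage assay.

## DNA-guided helical-slide docking

### Guide

The docking coordinate system is an ideal straight B-DNA "fiber" duplex:
per-base-pair orthonormal frames on a common axis (global z), frame k at
(0, 0, k·rise) with axes rotated k·twist about z. Defaults are the canonical
fiber values rise = 3.38 Å/bp, twist = 36°/bp, length 60 bp (long enough for
two placed complexes plus the full slide without end effects); all three are
configurable. Frames are sequence-independent. A full-atom idealized duplex
can be generated on the frames (backbone at fiber-like radii — phosphorus
track ≈ 8.9 Å, C1' ≈ 5.9 Å — with planar ring-only bases); it serves for
visual output and synthetic fixtures, while docking itself consumes only the
frames and the P/C1' template positions.

### Placement

Each complex is placed by a Kabsch (SVD) least-squares superposition of a
*short, straight* segment of its bound DNA onto the corresponding guide base
pairs. The default superposition subset is P + C1' per residue — the
phosphate track plus the glycosidic attachment point, the minimal
determinants of helical register; all-backbone is available. Only short
segments are fit because both partners of interest kink their DNA; the fit
RMSD is always recorded and a warning raised above 2 Å. 5'-terminal residues
carry no phosphate; a missing P is therefore tolerated on the terminal pairs
of a selection and an error everywhere else.

### Contact criterion

"Surfaces touch" is operationalized as probe-expanded van der Waals contact:
the minimum over atom pairs of d − r_a − r_b − 2·p with water probe
p = 1.4 Å, i.e. the solvent-accessible surfaces meet when the gap ≤ 0
(inclusive). Radii are a Bondi-style heavy-atom table (unknown elements
1.70 Å); hydrogens are dropped on input. The minimum gap is computed exactly
with a KD-tree: the nearest-center query gives a bound, and only candidate
pairs that could beat it (within bound + r_max,a + r_max,b + 2p) are
enumerated — near-linear cost, verified equal to the all-pairs brute force.

### Slide and interface

The mobile complex (the glycosylase, by convention) advances in exact 1-bp
screw steps (rotate twist, translate rise — a one-parameter group, so
sliding is rigid by construction). The first step k with gap ≤ 0 is the
first-contact step; the interface is every residue on either side owning an
atom pair within a margin (default 1.0 Å) beyond touch at that pose. Only
protein atoms participate in contact detection by default: on a shared guide
the two DNA tracks coincide and would register trivial DNA–DNA contacts.
The scan is purely geometric — no scoring, flexibility, or electrostatics.

Degenerate inputs: collinear superposition sets raise a rank error;
complexes placed on different guides are rejected; a mobile complex that
already overlaps the stationary one reports first contact at step 0.

## Kinetic model

### Mechanism

Per substrate pool, mass action in nM and minutes:

    i.   E + S  → E·S       k_on      binding
    ii.  E·S    → E–S*      k_schiff  covalent (Schiff-base) intermediate
    iii. E–S*   → E·P       k_beta    β-elimination (strand nicked)
    iv.  E–S*   → E·P       k_hyd     hydrolysis (abasic product)
    v.   E·P    → E + P     k_rel     product release

Steps iii/iv compete; the cumulative flux through iii on the secondary
substrate is the cleaved-product signal the gel assay reads. The
borohydride-trappable species is E–S* on the primary substrate, normalized
by the total bound label at the start of the time course.

### Displacement

A displacing protein accelerates *release only* (the covalent
intermediate's decay is unaffected by traffic proteins — hydrolysis rates
are displacer-independent in the model, matching the observation that
polymerases leave the Schiff-base decay unchanged):

    k_rel_eff = k_rel · (1 + (f_disp − 1)·[D]/([D] + K_disp))

which reduces to k_rel at [D] = 0 and to f_disp·k_rel at saturation.

### Two-substrate assay

Enzyme (10 nM) pre-binds unlabeled primary substrate (20 nM); at 2 min the
labeled secondary substrate (100 nM) and the displacer appear, and the model
integrates to 20 min. Displacement manifests as faster recycling of enzyme
onto the secondary pool and hence more cleaved product; the enhancement
ratio is cleaved product with displacer ÷ without, at the evaluation time.
Rebinding of released enzyme to remaining primary substrate is allowed
(mass action decides the competition). A grid point equal to the addition
time reports the post-addition state.

### Defaults

The measurements constrain half-lives and fold-effects, not a complete rate
set; the shipped defaults are: k_on = 0.1 nM⁻¹min⁻¹ (fast protein–DNA
association), k_schiff = 5 min⁻¹ (excision fast relative to downstream
steps), k_hyd = ln2/3.2 min⁻¹ (measured intermediate half-life, faster end
of the 3.2–7.8 min range), k_rel = ln2/17 min⁻¹ (product-complex half-life
~17 min), k_beta = 0.05 min⁻¹ (minor nicking branch; the enhancement ratio
is insensitive to the branch fraction since it cancels between the two
arms), f_disp = 10 (the release acceleration reported for the AP
endonuclease that stimulates this glycosylase), K_disp = 1 nM. Every
acceptance-level computation states its rates explicitly.

Note: the intermediate-decay range 3.2–7.8 is sometimes quoted with
inconsistent units (min vs. min⁻¹); it is treated throughout this package
as half-lives in minutes.

### Integration and the stochastic cross-check

Deterministic trajectories use LSODA at rtol 1e-10 / atol 1e-12; total
enzyme and each substrate pool are conserved to < 1e-9 nM at all output
times. The addition event is handled as a two-phase integration with the
phase-boundary state evaluated exactly. An independent Gillespie
direct-method engine (counts at a configurable molecules-per-nM scale,
default 1e4 ⇒ 1e5 enzyme molecules; user seed) simulates the identical
network; ODE and stochastic trajectories are required to agree within a
3-sigma Poisson-style Monte-Carlo band in the test suite. Obstacle
classification by release half-life: < 1 min labile (fast-cycling
glycosylase-like), 1–60 min slow-turnover (the displacement-assay regime),
> 1 h quasi-immovable (nuclease-roadblock-like); k_rel = 0 reports an
infinite half-life.

## Curve fitting

Exponential decay y = A·e^(−kt) (optional floating offset C, both variants
exposed since the original analysis does not state which was used) is fit by
nonlinear least squares initialized from a log-linear regression, so
noiseless data are recovered to machine precision; t½ = ln2/k with its
standard error propagated as (ln2/k²)·se(k). The one-site isotherm defaults
to the depletion-aware quadratic form

    FB = ((L0 + T + Kd) − sqrt((L0 + T + Kd)² − 4·L0·T)) / (2·L0)

because the labeled species (30 nM) is not in trace excess relative to the
measured Kd (~400–600 nM); the simple hyperbola is available and agrees with
the quadratic within 5% once L0 ≤ Kd/20. Standard errors come from the
Jacobian-based covariance, with an optional seeded bootstrap. Fits are
unweighted by default; weights are accepted. A Kd outside the titrated
range is flagged as extrapolated; a flat titration is reported as
unconverged/unbounded, never as a spurious finite Kd.

## Synthetic data

Generators are seed-deterministic and return their generating truth as
metadata. Toy complexes pair an ideal duplex with either a single on-axis
sphere of stated contact radius (closed-form collision geometry:
first contact k = ceil((separation − r_a − r_b − 2p)/rise), inclusive at
exact touch) or an off-axis carbon-atom stub for non-degenerate interface
tests. Decay time courses sample the 2–40 min trapping window (default
grid 2, 5, 10, 20, 40 min) with additive Gaussian noise σ = 0.03;
titrations use a 16-point two-fold serial dilution from 10 µM with
multiplicative log-normal noise σ = 0.05 (thermophoresis-like); cleavage
datasets pair with/without-displacer arms on a 2–20 min grid.

What the generators do *not* emulate: real structures' non-ideal DNA
geometry and heterogeneous atom composition (toy complexes are rigid
idealizations — passing docking tests shows the procedure's geometry is
correct, not that a particular crystal-structure interface is); gel
quantitation artifacts (band overlap, background); thermophoresis physics
beyond the isotherm; and any sequence dependence. Recovery tests therefore
validate the estimators under the stated noise models, not instrument-
specific error structure.

## Problem sizes

The test suite and the acceptance script run at the sizes the analyses
themselves use: 100 fit replicates per recovery experiment, 40-point ODE
grids, 500-atom contact fixtures, and a Gillespie scale of 500–2000
molecules/nM for the dual-route check — comfortably small for a single CPU
while keeping Monte-Carlo bands tight enough to detect percent-level bias
(the band that caught the phase-handoff integration bug during
development).

## Known limitations

- The guide is straight; complexes that kink DNA are represented faithfully
  only over the short fitted segment, which is the point of the procedure,
  but no curvature propagation is attempted.
- Interface prediction is contact geometry only; no energetics, so residue
  lists near the margin cutoff are sensitive to the radius table and probe.
- The kinetic model does not resolve elongation vs. diffusion modes of the
  displacer (a mode label is carried for reporting only) and contains no
  spatial model of one-dimensional sliding.
- Quantities the package reports (enhancement ratios, recovered Kd and
  half-lives, contact steps) are all computed by the tests and the
  acceptance script at run time; no empirical value is hard-coded.
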