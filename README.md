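# dnatraffic

Molecular traffic on DNA: what happens when a protein moving along the
double helix — a polymerase elongating a primer, or a protein sliding by
passive one-dimensional diffusion — runs into an enzyme already bound there?
DNA glycosylases, which initiate base excision repair, excise a damaged base
and then remain clamped on their abasic product for minutes; whether passing
traffic can dislodge them (and where the two protein surfaces collide)
shapes how repair is handed off along the pathway.

`dnatraffic` implements the two computational pieces of this question as a
tested pipeline:

* **DNA-guided helical-slide docking.** Two protein–DNA complexes are
  superposed onto a shared ideal straight B-DNA guide (per-base-pair frames
  with rise 3.38 Å and twist 36°) through short straight segments of their
  bound DNA (Kabsch least squares on the P + C1′ track). One complex then
  slides along the guide in exact 1-bp screw steps until the
  solvent-accessible surfaces touch — min over atom pairs of
  d − r_a − r_b − 2·p ≤ 0 with water probe p = 1.4 Å — and the residues
  lining the first contact on both partners are reported as the predicted
  collision interface. Purely geometric: no scoring, no flexibility.

* **Multistep glycosylase kinetics.** A mass-action model of the
  bifunctional glycosylase mechanism — binding, covalent (Schiff-base)
  intermediate, competing β-elimination and hydrolysis, slow product
  release — drives a two-substrate displacement assay: enzyme pre-bound to
  an unlabeled primary substrate, then challenged with a labeled secondary
  substrate plus a displacing protein. Displacement acts only on product
  release, k_rel,eff = k_rel·(1 + (f_disp − 1)·[D]/([D] + K_disp)), and
  shows up as accelerated cleavage of the secondary substrate. A seeded
  Gillespie engine simulates the identical network as an independent check.

* **Curve analysis.** Exponential-decay fits (trapping time courses, with
  t½ = ln2/k and propagated errors) and one-site binding isotherms
  (depletion-aware quadratic form by default, because the labeled species at
  30 nM is not in trace excess next to Kd ≈ 400–600 nM).

* **Synthetic data.** Seed-deterministic generators for toy complexes with
  closed-form collision geometry, decay and titration datasets with stated
  noise, and paired cleavage time courses — every stage is testable without
  downloads, and every generator emits its generating truth as metadata.

See `docs/methods.md` for the model details, parameter defaults and
limitations.

## Worked example

```python
import numpy as np
import dnatraffic as dt
from dnatraffic.structures_io import DnaSegmentSpec
from dnatraffic.synthetic_data import ToyComplexSpec, make_toy_complex

guide = dt.build_guide(n_bp=60)
toy = lambda seed: make_toy_complex(
    ToyComplexSpec(dna_n_bp=20, protein_radius=5.0, anchor_bp=10, seed=seed),
    guide)[0]
seg = DnaSegmentSpec([(("A", i), ("B", 21 - i)) for i in range(3, 8)],
                     role="downstream-5bp")
placed_pol = dt.place_on_guide(toy(1), seg, guide, register=5)
placed_gly = dt.place_on_guide(toy(0), seg, guide, register=17)
result = dt.slide_to_contact(placed_pol, placed_gly, guide,
                             dt.ContactParams(), direction=-1, max_steps=30)
print("first contact after", result.first_contact_step, "bp steps")
print("gap trace (A):", [round(g, 2) for g in result.gap_trace])
```

```
first contact after 9 bp steps
gap trace (A): [27.76, 24.38, 21.0, 17.62, 14.24, 10.86, 7.48, 4.1, 0.72, -2.66]
```

Two 5-Å model proteins anchored 12 bp apart touch after 9 approach steps:
the gap shrinks by one 3.38-Å rise per step and first crosses zero
(probe-expanded contact at center distance 5 + 5 + 2.8 = 12.8 Å) at step 9,
exactly the closed-form prediction.

```python
from dnatraffic.scheme_kinetics import (RateSet, build_two_substrate_scheme,
                                        enhancement_ratio, integrate_timecourse)
t = np.linspace(0.5, 20, 40)
with_disp = build_two_substrate_scheme(RateSet(f_disp=10.0, disp_conc=1e4),
                                       e0=10, s1_0=20, s2_0=100)
without = build_two_substrate_scheme(RateSet(f_disp=1.0), e0=10, s1_0=20, s2_0=100)
ratio = enhancement_ratio(integrate_timecourse(with_disp, t),
                          integrate_timecourse(without, t), t_eval=20.0)
print(f"cleavage enhancement at 20 min: {ratio:.2f}-fold")
```

```
cleavage enhancement at 20 min: 4.40-fold
```

At the standard assay mix (10 nM enzyme, 20 nM primary substrate, 100 nM
secondary substrate added at 2 min), a displacer that accelerates product
release ten-fold produces 4.4× more cleaved secondary substrate by 20 min —
the model's account of why displacement is visible on a gel.

```python
from dnatraffic.synthetic_data import make_titration, NoiseSpec
from dnatraffic.curve_fitting import fit_one_site_binding
curve, truth = make_titration(390.0, labeled_conc=30.0,
                              noise=NoiseSpec("multiplicative-lognormal", 0.05, seed=1))
fit = fit_one_site_binding(curve, depletion="quadratic")
print(f"Kd = {fit.estimates['Kd']:.0f} +/- {fit.standard_errors['Kd']:.0f} nM"
      f"  (truth {truth['kd']:.0f} nM)")
```

```
Kd = 407 +/- 25 nM  (truth 390 nM)
```

## Command line

A `dnatraffic` console script wraps the library: `guide-build` (ideal duplex
as PDB), `dock-slide` (full sliding-docking run → JSON interface report, TSV
gap trace, PDB contact pose), `simulate` (ODE or stochastic time course),
`fit-decay` / `fit-binding`, `synth` (dataset generators), `run` (staged
config with a SHA-256 manifest for bit-for-bit reproducibility), and
`fetch-pdb` (network helper to download named PDB entries for real-structure
runs, e.g. a glycosylase–DNA and a polymerase–DNA complex).

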