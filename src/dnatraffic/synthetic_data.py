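"""Seeded generators for every input the pipeline consumes.

Four generators, each deterministic under its seed and each returning its
generating truth as machine-readable metadata so recovery tests can close
the loop:

* toy protein–DNA complexes with closed-form collision geometry, for the
  sliding-docking procedure;
* first-order trapping decay time courses on the experimental 2–40 min
  sampling window;
* one-site binding titrations at a stated labeled-species concentration
  (30 nM, thermophoresis-style), with ligand depletion in the truth model;
* paired two-substrate cleavage time courses (with/without displacer) from
  the kinetic scheme, with gel-style noise.

Noise defaults: multiplicative log-normal σ = 0.05 for titrations,
additive Gaussian σ = 0.03 for gel-derived fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curve_fitting import DecayData, TitrationCurve, fraction_bound_quadratic
from .errors import GenerationError, ParameterError
from .helix_guide import HelicalGuide, build_guide, build_guide_atoms
from .scheme_kinetics import (
    RateSet,
    TwoSubstrateScheme,
    build_two_substrate_scheme,
    enhancement_ratio,
    integrate_timecourse,
)
from .structures_io import AtomRecord, StructureModel

LN2 = math.log(2.0)

#: Sampling grids mirroring the assay protocols (minutes).
DECAY_T_GRID = (2.0, 5.0, 10.0, 20.0, 40.0)
CLEAVAGE_T_GRID = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 15.0, 20.0)

#: Default 16-point two-fold serial dilution, nM (spans > 4 decades).
DEFAULT_LADDER = tuple(10000.0 / 2 ** i for i in range(16))

DEFAULT_LABELED_CONC = 30.0  # nM labeled species in the titration


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model applied to a generated dataset."""

    kind: str = "additive-gaussian"   # or "multiplicative-lognormal"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("additive-gaussian", "multiplicative-lognormal"):
            raise ParameterError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")

    def apply(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, float)
        if self.sigma == 0:
            return v.copy()
        rng = np.random.default_rng(self.seed)
        if self.kind == "additive-gaussian":
            return v + rng.normal(0.0, self.sigma, size=v.shape)
        return v * np.exp(rng.normal(0.0, self.sigma, size=v.shape))


@dataclass(frozen=True)
class ToyComplexSpec:
    """A pseudo-protein of known geometry anchored on an ideal duplex."""

    dna_n_bp: int = 40
    protein_shape: str = "sphere-cluster"     # or "helix-bundle-stub"
    protein_radius: float = 5.0               # Å, effective contact radius
    anchor_bp: int = 10                       # base pair the protein sits over
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protein_shape not in ("sphere-cluster", "helix-bundle-stub"):
            raise ParameterError(f"unknown protein shape {self.protein_shape!r}")
        if self.protein_radius <= 0:
            raise ParameterError("protein_radius must be > 0")
        if not (0 <= self.anchor_bp < self.dna_n_bp):
            raise ParameterError("anchor_bp must lie within the duplex")


def predicted_first_contact_step(radius_a: float, radius_b: float,
                                 separation_bp: int, rise: float,
                                 probe_radius: float = 1.4) -> int:
    """Closed-form first-contact step for two on-axis spherical proteins.

    Contact after k approach steps requires
    (separation_bp − k)·rise ≤ r_a + r_b + 2·probe; the smallest such k ≥ 0
    is ceil((separation − contact distance)/rise), clamped at 0 when the
    spheres already touch.
    """
    s = separation_bp * rise
    contact = radius_a + radius_b + 2.0 * probe_radius
    if s <= contact:
        return 0
    return int(math.ceil((s - contact) / rise - 1e-12))


def make_toy_complex(spec: ToyComplexSpec,
                     guide: HelicalGuide | None = None,
                     ) -> tuple[StructureModel, dict]:
    """Ideal duplex plus a rigidly attached pseudo-protein.

    The sphere-cluster shape is a single dummy atom on the helix axis at the
    anchor base pair's frame origin, with its van der Waals radius set to the
    full protein radius — so contact predictions stay closed-form. The
    helix-bundle-stub is a short off-axis cluster of carbon-radius atoms for
    less degenerate interface tests. Returns (model, metadata); metadata
    carries the generating truth. Note that PDB files carry no per-atom
    radii: a sphere-cluster written to disk and re-read gets the carbon vdW
    radius, so closed-form predictions for re-read models must use that.
    """
    if guide is None:
        guide = build_guide(n_bp=spec.dna_n_bp)
    if guide.n_bp < spec.dna_n_bp:
        raise ParameterError("guide shorter than requested duplex")
    sub = build_guide(n_bp=spec.dna_n_bp, rise=guide.rise, twist=guide.twist)
    dna = build_guide_atoms(sub, seed=spec.seed)
    atoms = list(dna.atoms)
    serial = max(a.serial for a in atoms)
    frame = guide.frames[spec.anchor_bp]

    if spec.protein_shape == "sphere-cluster":
        serial += 1
        atoms.append(AtomRecord(serial, "X1", "C", "SPH", 1, "P",
                                frame.origin.copy(), spec.protein_radius))
    else:
        rng = np.random.default_rng(spec.seed)
        r_atom = 1.70
        n_at = 12
        offsets = rng.normal(0.0, spec.protein_radius / 4.0, size=(n_at, 3))
        offsets = np.clip(offsets, -spec.protein_radius / 2, spec.protein_radius / 2)
        # clear of the duplex: backbone reaches ~10 Å from the axis, plus
        # vdW + probe expansion on both sides
        center = frame.origin + frame.axes @ np.array(
            [17.0 + spec.protein_radius / 2.0, 0.0, 0.0])
        for i in range(n_at):
            serial += 1
            pos = center + offsets[i]
            atoms.append(AtomRecord(serial, f"X{i + 1}", "C", "STB",
                                    1 + i // 6, "P", pos, r_atom))
        # the stub must not clash with its own DNA
        from .guided_docking import ContactParams, min_surface_gap
        prot = atoms[len(dna.atoms):]
        if min_surface_gap(dna.atoms, prot, ContactParams()) < 0:
            raise GenerationError("pseudo-protein overlaps its own duplex")

    model = StructureModel(atoms, source_id=f"toy-{spec.protein_shape}-{spec.seed}")
    meta = {
        "spec": {
            "dna_n_bp": spec.dna_n_bp,
            "protein_shape": spec.protein_shape,
            "protein_radius": spec.protein_radius,
            "anchor_bp": spec.anchor_bp,
            "seed": spec.seed,
        },
        "rise": guide.rise,
        "twist": guide.twist,
        "protein_chain": "P",
    }
    return model, meta


def predicted_contact_between(meta_a: dict, meta_b: dict,
                              register_a: int, register_b: int,
                              probe_radius: float = 1.4) -> int:
    """Closed-form first-contact step between two sphere-cluster toys.

    Both complexes placed on one guide at the given registers; the mobile one
    slides from register_b toward register_a.
    """
    sa, sb = meta_a["spec"], meta_b["spec"]
    if not (sa["protein_shape"] == sb["protein_shape"] == "sphere-cluster"):
        raise ParameterError("closed form requires two sphere-cluster toys")
    sep = abs((register_a + sa["anchor_bp"]) - (register_b + sb["anchor_bp"]))
    return predicted_first_contact_step(sa["protein_radius"],
                                        sb["protein_radius"], sep,
                                        meta_a["rise"], probe_radius)


def make_decay_timecourse(half_life: float,
                          t_grid=DECAY_T_GRID,
                          noise: NoiseSpec = NoiseSpec(),
                          ) -> tuple[DecayData, dict]:
    """First-order decay fraction = exp(−t·ln2/t½) with noise applied.

    Values are reported unclipped (noise may push them outside [0, 1], as
    gel quantitation does).
    """
    if half_life <= 0:
        raise ParameterError("half_life must be > 0")
    t = np.asarray(t_grid, float)
    truth = np.exp(-t * LN2 / half_life)
    data = DecayData(times=t, fraction=noise.apply(truth))
    meta = {"half_life": half_life, "t_grid": list(t),
            "noise": {"kind": noise.kind, "sigma": noise.sigma,
                      "seed": noise.seed}}
    return data, meta


def make_titration(kd: float, labeled_conc: float = DEFAULT_LABELED_CONC,
                   ladder=DEFAULT_LADDER,
                   noise: NoiseSpec = NoiseSpec(kind="multiplicative-lognormal",
                                                sigma=0.05),
                   baseline: float = 0.0, amplitude: float = 1.0,
                   ) -> tuple[TitrationCurve, dict]:
    """One-site titration with ligand depletion in the generating model."""
    if kd <= 0:
        raise ParameterError("kd must be > 0")
    T = np.asarray(ladder, float)
    if np.any(T <= 0):
        raise ParameterError("ladder concentrations must be positive")
    d = np.diff(T)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ParameterError("ladder must be a monotone serial dilution")
    fb = fraction_bound_quadratic(T, kd, labeled_conc)
    signal = baseline + amplitude * fb
    curve = TitrationCurve(ligand_total=T, signal=noise.apply(signal),
                           labeled_conc=labeled_conc)
    meta = {"kd": kd, "labeled_conc": labeled_conc,
            "baseline": baseline, "amplitude": amplitude,
            "ladder": list(T),
            "noise": {"kind": noise.kind, "sigma": noise.sigma,
                      "seed": noise.seed}}
    return curve, meta


def make_cleavage_dataset(rates: RateSet, e0: float = 10.0, s1_0: float = 20.0,
                          s2_0: float = 100.0, s2_added_at: float = 2.0,
                          t_points=CLEAVAGE_T_GRID,
                          noise: NoiseSpec = NoiseSpec(sigma=0.03),
                          ) -> tuple[pd.DataFrame, dict]:
    """Paired cleavage time courses with and without the displacer.

    ``rates`` carries the displacement parameters (f_disp, disp_conc); the
    no-displacer arm reruns the identical scheme with f_disp = 1. Cleaved
    fractions are relative to the secondary-substrate pool; noise is applied
    independently (fresh substreams of the one seed) to the two arms.
    """
    t = np.asarray(t_points, float)
    with_d = build_two_substrate_scheme(rates, e0, s1_0, s2_0, s2_added_at)
    no_d = build_two_substrate_scheme(
        RateSet(**{**rates.__dict__, "f_disp": 1.0}),
        e0, s1_0, s2_0, s2_added_at)
    tc_w = integrate_timecourse(with_d, t)
    tc_n = integrate_timecourse(no_d, t)
    frac_w = tc_w.species("P2_cleaved") / s2_0
    frac_n = tc_n.species("P2_cleaved") / s2_0
    sub_w = NoiseSpec(noise.kind, noise.sigma, noise.seed * 2 + 1)
    sub_n = NoiseSpec(noise.kind, noise.sigma, noise.seed * 2 + 2)
    table = pd.DataFrame({
        "time_min": t,
        "cleaved_with_displacer": sub_w.apply(frac_w),
        "cleaved_without_displacer": sub_n.apply(frac_n),
    })
    meta = {
        "rates": {k: getattr(rates, k) for k in (
            "k_on", "k_schiff", "k_beta", "k_hyd", "k_rel",
            "f_disp", "disp_conc", "K_disp")},
        "e0": e0, "s1_0": s1_0, "s2_0": s2_0, "s2_added_at": s2_added_at,
        "noiseless_ratio_at_end": enhancement_ratio(tc_w, tc_n, float(t[-1])),
        "noise": {"kind": noise.kind, "sigma": noise.sigma, "seed": noise.seed},
    }
    return table, meta
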