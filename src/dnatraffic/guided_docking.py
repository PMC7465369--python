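"""DNA-guided helical-slide docking of two protein–DNA complexes.

Both complexes are superposed onto a shared ideal B-DNA guide through short
straight segments of their bound DNA (Kabsch least squares on the P+C1'
track). One complex — by convention the glycosylase — is then slid along the
guide in 1-bp screw steps toward the other until their solvent-accessible
surfaces touch. "Touch" is operationalized as probe-expanded van der Waals
contact: the minimum over atom pairs of

    gap = d(a, b) − r_a − r_b − 2·probe_radius

reaching ≤ 0 (water probe 1.4 Å by default). The residues lining the first
contact on both partners are the predicted collision interface.

The procedure is purely geometric: rigid bodies, no scoring, no flexibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError, RankError
from .helix_guide import HelicalGuide, Transform, step_transform, \
    strand_template_coords
from .structures_io import (
    AtomRecord,
    DnaSegmentSpec,
    NUCLEOTIDE_NAMES,
    StructureModel,
    select_dna_segment,
)


@dataclass
class ContactParams:
    """Parameters of the surface-contact criterion."""

    probe_radius: float = 1.4          # Å; water probe of the solvation surface
    vdw_table: dict[str, float] | None = None   # optional element→radius override
    include_dna_atoms: bool = False    # include DNA atoms in contact detection

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ParameterError("probe_radius must be >= 0")

    def radius_of(self, atom: AtomRecord) -> float:
        if self.vdw_table is not None and atom.element in self.vdw_table:
            return self.vdw_table[atom.element]
        return atom.vdw_radius


@dataclass
class PlacedComplex:
    """A complex rigidly placed on the guide via its DNA segment."""

    model: StructureModel
    placement: Transform
    alignment_rmsd: float
    guide_register: int
    segment_spec: DnaSegmentSpec
    guide_id: tuple = ()

    def placed_atoms(self, include_dna: bool) -> list[AtomRecord]:
        """Atoms in guide coordinates; protein only unless include_dna."""
        out = []
        for a in self.model.atoms:
            if not include_dna and a.residue_name in NUCLEOTIDE_NAMES:
                continue
            out.append(AtomRecord(a.serial, a.atom_name, a.element,
                                  a.residue_name, a.residue_number, a.chain_id,
                                  self.placement.apply(a.position),
                                  a.vdw_radius))
        return out

    def placed_model(self) -> StructureModel:
        return self.model.transformed(self.placement.rotation,
                                      self.placement.translation)


@dataclass
class DockingResult:
    """Outcome of a 1-bp sliding scan."""

    first_contact_step: int | None
    gap_trace: list[float]
    interface_A: list[tuple[str, int, str]]   # (chain, number, name), stationary
    interface_B: list[tuple[str, int, str]]   # mobile
    geometry_label: str = ""
    params: dict = field(default_factory=dict)


def superpose_kabsch(mobile: np.ndarray,
                     target: np.ndarray) -> tuple[Transform, float]:
    """Least-squares optimal rigid superposition (Kabsch, SVD form).

    Returns the proper-rotation transform mapping ``mobile`` onto ``target``
    and the post-fit RMSD. Reflections are excluded by construction.
    """
    m = np.asarray(mobile, float)
    t = np.asarray(target, float)
    if m.shape != t.shape or m.ndim != 2 or m.shape[1] != 3:
        raise ParameterError(f"point sets must both be N×3, got {m.shape} vs {t.shape}")
    if len(m) < 3:
        raise ParameterError("need at least 3 points for superposition")
    cm, ct = m.mean(axis=0), t.mean(axis=0)
    mm, tt = m - cm, t - ct
    h = mm.T @ tt
    u, s, vt = np.linalg.svd(h)
    # collinear sets leave the rotation about the line undetermined
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise RankError("point set is (near-)collinear; superposition is degenerate")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ct - rot @ cm
    rmsd = float(np.sqrt(np.mean(np.sum((mm @ rot.T - tt) ** 2, axis=1))))
    return Transform(rot, trans), rmsd


def guide_segment_coords(guide: HelicalGuide, register: int,
                         labels: Sequence[tuple[int, int, str]]) -> np.ndarray:
    """Guide-frame target coordinates matching a segment selection.

    ``labels`` come from :func:`select_dna_segment`; pair index i of the
    selection maps to guide frame ``register + i``.
    """
    rows = []
    for (i, strand, name) in labels:
        frame = guide.frames[register + i]
        local = strand_template_coords(name, strand)
        rows.append(frame.axes @ local + frame.origin)
    return np.array(rows, float)


def place_on_guide(model: StructureModel, spec: DnaSegmentSpec,
                   guide: HelicalGuide, register: int,
                   atom_subset: str = "P+C1'",
                   rmsd_warn_threshold: float = 2.0) -> PlacedComplex:
    """Rigidly place a complex on the guide by fitting its DNA segment.

    Only the short straight segment is fit (both glycosylase and polymerase
    kink their DNA, so a whole-duplex fit would be meaningless); the fit RMSD
    is recorded and a warning raised when it exceeds the threshold.
    """
    n_seg = len(spec.pairs)
    if register < 0 or register + n_seg > guide.n_bp:
        raise ParameterError(
            f"register {register} + segment {n_seg} bp exceeds guide ({guide.n_bp} bp)"
        )
    sel = select_dna_segment(model, spec, atom_subset=atom_subset)
    target = guide_segment_coords(guide, register, sel.labels)
    transform, rmsd = superpose_kabsch(sel.coords, target)
    if rmsd > rmsd_warn_threshold:
        warnings.warn(
            f"DNA-segment alignment RMSD {rmsd:.2f} Å exceeds "
            f"{rmsd_warn_threshold:.2f} Å; the segment may not be straight",
            stacklevel=2,
        )
    return PlacedComplex(model=model, placement=transform, alignment_rmsd=rmsd,
                         guide_register=register, segment_spec=spec,
                         guide_id=guide.guide_id)


def _pair_gap_arrays(atoms: Sequence[AtomRecord], params: ContactParams):
    pos = np.array([a.position for a in atoms], float)
    rad = np.array([params.radius_of(a) for a in atoms], float)
    return pos, rad


def min_surface_gap(atoms_a: Sequence[AtomRecord], atoms_b: Sequence[AtomRecord],
                    params: ContactParams) -> float:
    """Minimum probe-expanded surface gap between two atom sets, Å.

    Exact: a KD-tree prunes to the candidate pairs that could beat the
    nearest-center bound, then gaps are evaluated pairwise. ≤ 0 means the
    solvent-accessible surfaces touch or interpenetrate.
    """
    if not len(atoms_a) or not len(atoms_b):
        raise ParameterError("both atom lists must be non-empty")
    pa, ra = _pair_gap_arrays(atoms_a, params)
    pb, rb = _pair_gap_arrays(atoms_b, params)
    two_probe = 2.0 * params.probe_radius
    tree = cKDTree(pb)
    d1, j1 = tree.query(pa, k=1)
    best = float(np.min(d1 - ra - rb[j1] - two_probe))
    # a farther pair with larger radii could still beat `best`
    search = best + float(ra.max() + rb.max()) + two_probe
    if search <= 0:
        return best  # no pair at non-negative distance can do better
    pairs = cKDTree(pa).query_ball_tree(tree, r=search)
    for i, js in enumerate(pairs):
        if not js:
            continue
        js = np.asarray(js)
        d = np.linalg.norm(pb[js] - pa[i], axis=1)
        g = d - ra[i] - rb[js] - two_probe
        gmin = float(g.min())
        if gmin < best:
            best = gmin
    return best


def interface_residues(atoms_a: Sequence[AtomRecord], atoms_b: Sequence[AtomRecord],
                       params: ContactParams, cutoff_margin: float = 1.0,
                       ) -> tuple[list[tuple[str, int, str]], list[tuple[str, int, str]]]:
    """Residues on each side owning an atom pair with gap ≤ cutoff_margin.

    Each residue is reported once as (chain, author number, residue name),
    sorted by chain then number.
    """
    if not len(atoms_a) or not len(atoms_b):
        return [], []
    pa, ra = _pair_gap_arrays(atoms_a, params)
    pb, rb = _pair_gap_arrays(atoms_b, params)
    two_probe = 2.0 * params.probe_radius
    search = cutoff_margin + float(ra.max() + rb.max()) + two_probe
    tree_b = cKDTree(pb)
    pairs = cKDTree(pa).query_ball_tree(tree_b, r=search)
    res_a: set[tuple[str, int, str]] = set()
    res_b: set[tuple[str, int, str]] = set()
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(pb[j] - pa[i]))
            if d - ra[i] - rb[j] - two_probe <= cutoff_margin:
                a, b = atoms_a[i], atoms_b[j]
                res_a.add((a.chain_id, a.residue_number, a.residue_name))
                res_b.add((b.chain_id, b.residue_number, b.residue_name))
    key = lambda r: (r[0], r[1])
    return sorted(res_a, key=key), sorted(res_b, key=key)


def slide_to_contact(stationary: PlacedComplex, mobile: PlacedComplex,
                     guide: HelicalGuide, params: ContactParams,
                     direction: int = 1, max_steps: int = 40,
                     cutoff_margin: float = 1.0,
                     geometry_label: str = "") -> DockingResult:
    """Slide the mobile complex in 1-bp steps until first surface contact.

    Scans k = 0, 1, ... max_steps; the first k with gap ≤ 0 (inclusive) is
    the first-contact step. Interface residues are evaluated at that pose.
    Only protein atoms participate unless ``params.include_dna_atoms`` — on a
    shared guide the DNA tracks coincide and would register trivial contacts.
    """
    if stationary.guide_id != guide.guide_id or mobile.guide_id != guide.guide_id:
        raise ParameterError("both complexes must be placed on the given guide")
    if direction not in (1, -1):
        raise ParameterError("direction must be +1 or -1")
    stat_atoms = stationary.placed_atoms(include_dna=params.include_dna_atoms)
    mob_base = mobile.placed_atoms(include_dna=params.include_dna_atoms)
    base_pos = np.array([a.position for a in mob_base], float)

    gap_trace: list[float] = []
    first_contact: int | None = None
    contact_atoms_m: list[AtomRecord] | None = None
    for k in range(max_steps + 1):
        tr = step_transform(guide, k, sign=direction)
        moved = [
            AtomRecord(a.serial, a.atom_name, a.element, a.residue_name,
                       a.residue_number, a.chain_id, p, a.vdw_radius)
            for a, p in zip(mob_base, tr.apply(base_pos))
        ]
        gap = min_surface_gap(stat_atoms, moved, params)
        gap_trace.append(gap)
        if gap <= 0.0:
            first_contact = k
            contact_atoms_m = moved
            break

    if first_contact is None:
        return DockingResult(None, gap_trace, [], [],
                             geometry_label=geometry_label,
                             params={"probe_radius": params.probe_radius,
                                     "direction": direction,
                                     "max_steps": max_steps})
    iface_a, iface_b = interface_residues(stat_atoms, contact_atoms_m, params,
                                          cutoff_margin=cutoff_margin)
    return DockingResult(first_contact, gap_trace, iface_a, iface_b,
                         geometry_label=geometry_label,
                         params={"probe_radius": params.probe_radius,
                                 "direction": direction,
                                 "max_steps": max_steps,
                                 "cutoff_margin": cutoff_margin})
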