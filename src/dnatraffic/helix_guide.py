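"""Ideal straight B-DNA guide: per-base-pair frames and the 1-bp step.

The guide plays the role of the "fiber model" duplex onto which both
protein–DNA complexes are superposed: a straight helix defined entirely by a
uniform rise (Å/bp) and twist (deg/bp) about the global z axis, with frame 0
at the origin. Sliding a complex along the guide by k base pairs is the screw
transform: rotate k·twist about z, translate k·rise along z.

A full-atom idealized duplex can be generated on the frames for visual
output and for synthetic test fixtures; docking itself only needs frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .structures_io import AtomRecord, StructureModel, vdw_radius

#: Canonical fiber B-DNA helical parameters.
DEFAULT_RISE = 3.38     # Å per bp
DEFAULT_TWIST = 36.0    # degrees per bp
DEFAULT_N_BP = 60


@dataclass(frozen=True)
class Transform:
    """Rigid-body transform x -> R x + t (rotation 3×3, translation Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    @staticmethod
    def identity() -> "Transform":
        return Transform(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Transform":
        rt = self.rotation.T
        return Transform(rt, -rt @ self.translation)


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class BasePairFrame:
    """Orthonormal right-handed frame of one base pair.

    Columns of ``axes`` are the local x (into the major groove), y (along the
    strand-1 → strand-2 C1' direction) and z (helix axis) unit vectors.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        ax = np.asarray(self.axes, float)
        if not np.allclose(ax.T @ ax, np.eye(3), atol=1e-9):
            raise ParameterError("frame axes must be orthonormal")
        if np.linalg.det(ax) < 0:
            raise ParameterError("frame axes must be right-handed")


@dataclass
class HelicalGuide:
    """Straight ideal duplex as a list of per-base-pair frames."""

    n_bp: int
    rise: float
    twist: float
    frames: list[BasePairFrame] = field(default_factory=list)

    @property
    def guide_id(self) -> tuple[int, float, float]:
        return (self.n_bp, self.rise, self.twist)


def build_guide(n_bp: int = DEFAULT_N_BP, rise: float = DEFAULT_RISE,
                twist: float = DEFAULT_TWIST) -> HelicalGuide:
    """Build the guide: frame k at (0, 0, k·rise), rotated k·twist about z."""
    if n_bp < 1:
        raise ParameterError(f"n_bp must be >= 1, got {n_bp}")
    if rise <= 0:
        raise ParameterError(f"rise must be > 0, got {rise}")
    if not (0 < twist <= 360):
        raise ParameterError(f"twist must be in (0, 360], got {twist}")
    frames = [
        BasePairFrame(origin=np.array([0.0, 0.0, k * rise]),
                      axes=_rot_z(k * twist))
        for k in range(n_bp)
    ]
    return HelicalGuide(n_bp=n_bp, rise=rise, twist=twist, frames=frames)


def step_transform(guide: HelicalGuide, k: int, sign: int = 1) -> Transform:
    """Screw transform advancing a placed object by ``k`` bp steps.

    Rotation by k·sign·twist about z composed with translation k·sign·rise
    along z; step 0 is the identity. The rotation and translation commute, so
    the transform is a one-parameter group in k.
    """
    if sign not in (1, -1):
        raise ParameterError("sign must be +1 or -1")
    n = k * sign
    return Transform(_rot_z(n * guide.twist),
                     np.array([0.0, 0.0, n * guide.rise]))


# --------------------------------------------------------------------------
# Full-atom idealized duplex
# --------------------------------------------------------------------------

def _polar(r: float, phi_deg: float, z: float) -> np.ndarray:
    a = np.deg2rad(phi_deg)
    return np.array([r * np.cos(a), r * np.sin(a), z])


# Idealized sugar-phosphate backbone of strand 1 in the base-pair frame,
# (radius Å, azimuth deg, z offset Å). Radii follow fiber B-DNA conventions
# (phosphorus track at ~8.9 Å, C1' at ~5.9 Å); azimuths/offsets are an
# idealization adequate for a straight guide, not a refined nucleotide.
_BACKBONE_TEMPLATE: list[tuple[str, str, tuple[float, float, float]]] = [
    ("P",   "P", (8.91, -94.0, -0.9)),
    ("OP1", "O", (9.85, -99.0, -0.3)),
    ("OP2", "O", (9.60, -89.0, -1.9)),
    ("O5'", "O", (8.55, -85.0, -0.2)),
    ("C5'", "C", (8.25, -79.0, 0.3)),
    ("C4'", "C", (7.35, -73.5, 0.1)),
    ("O4'", "O", (6.60, -70.5, 0.9)),
    ("C3'", "C", (7.05, -70.0, -1.1)),
    ("O3'", "O", (7.55, -64.5, -1.7)),
    ("C2'", "C", (6.00, -64.5, -0.7)),
    ("C1'", "C", (5.90, -61.0, 0.2)),
]

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_RING_SIZES = {"A": 9, "G": 9, "C": 6, "T": 6}  # ring atoms incl. glycosidic N

_PURINE_RING = ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6")
_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


def _base_ring_coords(base: str) -> list[tuple[str, str, np.ndarray]]:
    """Planar idealized ring atoms for one base, in the bp frame (strand 1).

    The glycosidic nitrogen sits at the end of the C1' direction; further
    ring atoms are laid out as fused regular polygons (bond 1.39 Å) marching
    toward the helix axis, giving a flat, correctly sized base stand-in.
    """
    g = _polar(4.58, -55.0, 0.1)              # glycosidic N
    center_bp = np.array([1.0, 0.3, 0.1])     # roughly the bp midpoint
    u = center_bp - g
    u = u / np.linalg.norm(u)
    bond = 1.39

    def polygon(start: np.ndarray, toward: np.ndarray, n: int) -> list[np.ndarray]:
        # regular n-gon with one vertex at `start`, center offset along `toward`
        center = start + bond * toward
        perp = np.cross(np.array([0.0, 0.0, 1.0]), toward)
        perp /= np.linalg.norm(perp)
        out = []
        for i in range(n):
            ang = 2 * np.pi * i / n
            out.append(center + bond * (np.cos(ang) * (start - center) / bond
                                        + np.sin(ang) * perp))
        return out

    names = _PURINE_RING if base in ("A", "G") else _PYRIMIDINE_RING
    if base in ("A", "G"):
        penta = polygon(g, u, 5)              # N9 C8 N7 C5 C4
        hexa = polygon(penta[3], u, 6)        # fused six-ring grown from C5
        pts = penta + [hexa[2], hexa[3], hexa[4], hexa[5]]  # N3 C2 N1 C6
    else:
        pts = polygon(g, u, 6)
    coords = []
    for name, p in zip(names, pts):
        coords.append((name, name[0], np.asarray(p)))
    return coords


def _nucleotide_template(base: str) -> list[tuple[str, str, np.ndarray]]:
    atoms = [(n, el, _polar(*c)) for n, el, c in _BACKBONE_TEMPLATE]
    atoms.extend(_base_ring_coords(base))
    return atoms


_DYAD = np.diag([1.0, -1.0, -1.0])  # strand-2 = dyad flip about local x


def strand_template_coords(atom_name: str, strand: int) -> np.ndarray:
    """Template position of a backbone atom in the bp frame, either strand."""
    for name, _el, c in _BACKBONE_TEMPLATE:
        if name == atom_name:
            p = _polar(*c)
            return p if strand == 1 else _DYAD @ p
    raise ParameterError(f"no template coordinate for atom {atom_name!r}")


def build_guide_atoms(guide: HelicalGuide, sequence: str | None = None,
                      seed: int = 0) -> StructureModel:
    """Full-atom idealized duplex on the guide frames.

    Chain A is strand 1 (residues 1..n in frame order); chain B is strand 2,
    antiparallel (residue j of B pairs with residue n+1−j of A). The two
    5'-terminal residues (A:1 and B:1) carry no phosphate group.
    """
    n = guide.n_bp
    if sequence is None:
        rng = np.random.default_rng(seed)
        sequence = "".join(rng.choice(list("ACGT"), size=n))
    sequence = sequence.upper()
    if len(sequence) != n:
        raise ParameterError(f"sequence length {len(sequence)} != n_bp {n}")
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ParameterError(f"invalid base character(s): {sorted(bad)}")

    atoms: list[AtomRecord] = []
    serial = 0

    def emit(chain: str, resnum: int, resname: str, local: np.ndarray,
             name: str, element: str, frame: BasePairFrame) -> None:
        nonlocal serial
        serial += 1
        pos = frame.axes @ local + frame.origin
        atoms.append(AtomRecord(serial, name, element, resname, resnum,
                                chain, pos, vdw_radius(element)))

    # strand 1 / chain A, 5' -> 3' along increasing frame index
    for k in range(n):
        base = sequence[k]
        frame = guide.frames[k]
        for name, el, local in _nucleotide_template(base):
            if k == 0 and name in ("P", "OP1", "OP2"):
                continue
            emit("A", k + 1, "D" + base, local, name, el, frame)
    # strand 2 / chain B, 5' -> 3' along decreasing frame index
    for j in range(n):
        k = n - 1 - j                     # paired frame index
        base = _COMPLEMENT[sequence[k]]
        frame = guide.frames[k]
        for name, el, local in _nucleotide_template(base):
            if j == 0 and name in ("P", "OP1", "OP2"):
                continue
            emit("B", j + 1, "D" + base, _DYAD @ local, name, el, frame)
    return StructureModel(atoms, source_id=f"guide-{n}bp")


def phosphate_chord_length(rise: float, twist: float,
                           p_radius: float | None = None) -> float:
    """Closed-form distance between successive P atoms on one strand.

    A point at cylindrical radius r advancing one step moves by
    sqrt(rise² + 4 r² sin²(twist/2)).
    """
    if p_radius is None:
        p_radius = _BACKBONE_TEMPLATE[0][2][0]
    return float(np.sqrt(rise ** 2
                         + 4 * p_radius ** 2 * np.sin(np.deg2rad(twist) / 2) ** 2))
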