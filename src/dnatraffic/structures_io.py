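"""Macromolecular structure I/O and atom selection.

Reads PDB/mmCIF files into a light-weight :class:`StructureModel`, writes
placed complexes back out as PDB, and provides the two selections the
DNA-guided docking procedure needs: the short straight DNA segment used for
superposition (phosphate + C1' track by default) and the heavy-atom protein
surface of a complex.

Residues are addressed by author numbering throughout, because interface
residues are conventionally reported that way (e.g. the POLβ thumb loop
302–306). Hydrogens are dropped on input; the van der Waals table is
heavy-atom (Bondi radii).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptyModelError,
    FormatError,
    MissingAtomError,
    NonNucleotideError,
    ParameterError,
    SelectorError,
)

# Bondi-style heavy-atom van der Waals radii, Å.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "ZN": 1.39,
    "MN": 1.61,
    "FE": 1.52,
    "CA": 2.31,
}
#: Radius assigned to elements absent from the table.
DEFAULT_VDW_RADIUS = 1.70

#: Residue names recognized as nucleotides (DNA + RNA, common variants).
NUCLEOTIDE_NAMES = frozenset(
    {"DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "U", "I",
     "8OG", "OXG"}  # 8-oxoguanine variants seen in lesion-containing DNA
)
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

BACKBONE_ATOMS = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'",
                  "O3'", "C2'", "C1'")


def vdw_radius(element: str) -> float:
    """Bondi radius of an element symbol; unknown symbols get the default."""
    return VDW_RADII.get(element.upper().strip(), DEFAULT_VDW_RADIUS)


@dataclass
class AtomRecord:
    """One heavy atom with its identity, position (Å) and vdW radius (Å)."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    vdw_radius: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ParameterError(
                f"atom {self.atom_name}: position must be a finite 3-vector"
            )
        if self.vdw_radius <= 0:
            raise ParameterError(f"atom {self.atom_name}: vdw_radius must be > 0")

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass
class StructureModel:
    """An ordered collection of atoms; the unit the docking operates on."""

    atoms: list[AtomRecord]
    source_id: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.atom_name)
            if key in seen:
                raise ParameterError(
                    f"duplicate atom {key} in model {self.source_id!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def atom(self, chain_id: str, residue_number: int, atom_name: str) -> AtomRecord:
        for a in self.atoms:
            if (a.chain_id, a.residue_number, a.atom_name) == (
                chain_id, residue_number, atom_name,
            ):
                return a
        raise SelectorError(
            f"atom {atom_name} of {chain_id}/{residue_number} not in model"
        )

    def residue_atoms(self, chain_id: str, residue_number: int) -> list[AtomRecord]:
        out = [a for a in self.atoms
               if a.chain_id == chain_id and a.residue_number == residue_number]
        if not out:
            raise SelectorError(f"residue {chain_id}/{residue_number} not in model")
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    source_id: str | None = None) -> "StructureModel":
        """A copy with every position mapped through x -> R x + t."""
        rot = np.asarray(rotation, float)
        tr = np.asarray(translation, float)
        atoms = [
            AtomRecord(a.serial, a.atom_name, a.element, a.residue_name,
                       a.residue_number, a.chain_id, rot @ a.position + tr,
                       a.vdw_radius)
            for a in self.atoms
        ]
        return StructureModel(atoms, source_id or self.source_id)


@dataclass
class DnaSegmentSpec:
    """Selector for the short straight duplex segment used for alignment.

    ``pairs`` lists base pairs in segment order; each entry is
    ``((chain1, resnum1), (chain2, resnum2))``. The two strands must run
    antiparallel: as strand-1 numbers ascend by 1 per pair, strand-2 numbers
    descend by 1 (or vice versa).
    """

    pairs: list[tuple[tuple[str, int], tuple[str, int]]]
    role: Literal["downstream-5bp", "shoulder-6bp", "other"] = "other"

    def __post_init__(self) -> None:
        n = len(self.pairs)
        if n < 1:
            raise ParameterError("segment spec needs at least one base pair")
        if self.role == "downstream-5bp" and n != 5:
            raise ParameterError(f"role downstream-5bp requires 5 pairs, got {n}")
        if self.role == "shoulder-6bp" and n != 6:
            raise ParameterError(f"role shoulder-6bp requires 6 pairs, got {n}")
        if n > 1:
            s1 = [p[0][1] for p in self.pairs]
            s2 = [p[1][1] for p in self.pairs]
            d1 = {b - a for a, b in zip(s1, s1[1:])}
            d2 = {b - a for a, b in zip(s2, s2[1:])}
            if d1 not in ({1}, {-1}) or d2 not in ({1}, {-1}):
                raise ParameterError("segment strands must be contiguous")
            if d1 == d2:
                raise ParameterError(
                    "segment strands must be antiparallel "
                    "(residue numbers must run in opposite directions)"
                )


def read_structure(path: str | Path,
                   format: Literal["pdb", "mmcif", "auto"] = "auto",
                   include_waters: bool = False) -> StructureModel:
    """Read the first model of a PDB or mmCIF file.

    Alternate locations are resolved to the highest-occupancy conformer;
    hydrogens and (by default) waters are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"{path.name}: no models")
    model = st[0]

    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            resname = res.name.strip()
            if not include_waters and (res.is_water() or resname in WATER_NAMES):
                continue
            # resolve altlocs to the highest-occupancy conformer per atom name
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                if at.element.name.upper() in ("H", "D"):
                    continue
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in res:  # preserve file order
                kept = best.get(at.name)
                if kept is None or kept is not at:
                    continue
                atoms.append(AtomRecord(
                    serial=at.serial,
                    atom_name=at.name,
                    element=at.element.name.upper(),
                    residue_name=resname,
                    residue_number=res.seqid.num,
                    chain_id=chain.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    vdw_radius=vdw_radius(at.element.name),
                ))
    if not atoms:
        raise EmptyModelError(f"{path.name}: first model has no (heavy) atoms")
    return StructureModel(atoms, source_id=path.stem)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = model.source_id or "model"
    md = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple[str, int], gemmi.Residue] = {}
    for a in model.atoms:
        ch = chain_map.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            md.add_chain(ch)
            chain_map[a.chain_id] = md[len(md) - 1]
            ch = chain_map[a.chain_id]
        key = (a.chain_id, a.residue_number)
        res = res_map.get(key)
        if res is None:
            r = gemmi.Residue()
            r.name = a.residue_name
            r.seqid = gemmi.SeqId(a.residue_number, " ")
            ch.add_residue(r)
            res_map[key] = ch[len(ch) - 1]
            res = res_map[key]
        at = gemmi.Atom()
        at.name = a.atom_name
        at.serial = a.serial
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        at.occ = 1.0
        res.add_atom(at)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass
class SegmentCoordinates:
    """Ordered, labelled coordinates of a DNA segment selection.

    ``labels[i]`` is ``(pair_index, strand, atom_name)`` for row ``i`` of
    ``coords``; rows are ordered by pair index, then strand (1, 2), then the
    atom order of the requested subset.
    """

    labels: list[tuple[int, int, str]]
    coords: np.ndarray


ATOM_SUBSETS: dict[str, tuple[str, ...]] = {
    "P+C1'": ("P", "C1'"),
    "all-backbone": BACKBONE_ATOMS,
}


def select_dna_segment(model: StructureModel, spec: DnaSegmentSpec,
                       atom_subset: str = "P+C1'") -> SegmentCoordinates:
    """Extract the superposition coordinates of a duplex segment.

    A missing named atom raises, with one structural exception: ``P`` (and its
    ``OP1``/``OP2`` partners) is genuinely absent on 5'-terminal residues, so
    a missing phosphate is tolerated on the first and last base pair of the
    selection and the corresponding rows are simply omitted.
    """
    if atom_subset not in ATOM_SUBSETS:
        raise ParameterError(
            f"unknown atom subset {atom_subset!r}; options: {sorted(ATOM_SUBSETS)}"
        )
    wanted = ATOM_SUBSETS[atom_subset]
    phosphate = {"P", "OP1", "OP2"}
    labels: list[tuple[int, int, str]] = []
    rows: list[np.ndarray] = []
    last = len(spec.pairs) - 1
    for i, pair in enumerate(spec.pairs):
        for strand, (chain_id, resnum) in enumerate(pair, start=1):
            res_atoms = model.residue_atoms(chain_id, resnum)  # SelectorError if absent
            resname = res_atoms[0].residue_name
            if resname not in NUCLEOTIDE_NAMES:
                raise NonNucleotideError(
                    f"{chain_id}/{resnum} ({resname}) is not a nucleotide"
                )
            by_name = {a.atom_name: a for a in res_atoms}
            for name in wanted:
                at = by_name.get(name)
                if at is None:
                    if name in phosphate and i in (0, last):
                        continue  # 5'-terminal residues carry no phosphate
                    raise MissingAtomError(
                        f"atom {name} missing from {chain_id}/{resnum} ({resname})"
                    )
                labels.append((i, strand, name))
                rows.append(at.position)
    return SegmentCoordinates(labels, np.array(rows, dtype=float))


def select_protein_atoms(model: StructureModel,
                         chains: Iterable[str]) -> list[AtomRecord]:
    """All heavy non-nucleotide, non-water atoms of the named chains.

    Emits a warning (and returns an empty list) when the selection contains
    no protein atoms, e.g. when a DNA-only chain was named.
    """
    chain_set = set(chains)
    known = set(model.chains())
    missing = chain_set - known
    if missing:
        raise SelectorError(f"unknown chain(s) {sorted(missing)}; model has {sorted(known)}")
    out = [a for a in model.atoms
           if a.chain_id in chain_set
           and a.residue_name not in NUCLEOTIDE_NAMES
           and a.residue_name not in WATER_NAMES]
    if not out:
        warnings.warn(
            f"chains {sorted(chain_set)} contain no protein atoms", stacklevel=2
        )
    return out


def segment_spec_from_dict(cfg: dict) -> DnaSegmentSpec:
    """Build a DnaSegmentSpec from the flat config-file form.

    Expected keys::

        role: downstream-5bp | shoulder-6bp | other
        strand1: {chain: A, start: 3, end: 7}
        strand2: {chain: B, start: 18, end: 14}
    """
    try:
        s1, s2 = cfg["strand1"], cfg["strand2"]
        c1, a1, b1 = s1["chain"], int(s1["start"]), int(s1["end"])
        c2, a2, b2 = s2["chain"], int(s2["start"]), int(s2["end"])
    except (KeyError, TypeError) as exc:
        raise ParameterError(f"malformed segment config: {exc}") from exc
    step1 = 1 if b1 >= a1 else -1
    step2 = 1 if b2 >= a2 else -1
    r1 = list(range(a1, b1 + step1, step1))
    r2 = list(range(a2, b2 + step2, step2))
    if len(r1) != len(r2):
        raise ParameterError("strand1 and strand2 ranges differ in length")
    pairs = [((c1, m), (c2, n)) for m, n in zip(r1, r2)]
    return DnaSegmentSpec(pairs=pairs, role=cfg.get("role", "other"))
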