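"""Coordinate handling: PDB reading, amide-proton placement, NH vectors, superposition.

Author residue numbering is preserved end-to-end; nothing here renumbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

#: Default N-H bond length used when building amide protons, in Angstrom.
DEFAULT_NH_LENGTH = 1.02


@dataclass(frozen=True)
class AtomRecord:
    """One atom with author identifiers and Cartesian coordinates (Angstrom)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    altloc: str | None = None
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Structure:
    """An ordered collection of atoms plus sequence and gap bookkeeping.

    ``gaps`` holds author residue numbers missing from the coordinates within
    the observed numbering range of each chain — loops without electron
    density in a crystal structure show up here, and they are first-class:
    downstream selections and run-based classifications must not bridge them.
    """

    atoms: list[AtomRecord] = field(default_factory=list)
    sequence: dict[int, str] = field(default_factory=dict)
    gaps: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str, str | None]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.atom_name, a.altloc)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)
        present = {a.residue_number for a in self.atoms}
        if self.gaps & present:
            raise ValueError("gaps overlap residues that have atoms")

    # -- lookup helpers -------------------------------------------------

    def residue_numbers(self) -> list[int]:
        out: list[int] = []
        for a in self.atoms:
            if not out or a.residue_number != out[-1]:
                if a.residue_number not in out:
                    out.append(a.residue_number)
        return out

    def atom(self, residue_number: int, atom_name: str, chain_id: str | None = None) -> AtomRecord | None:
        for a in self.atoms:
            if a.residue_number == residue_number and a.atom_name == atom_name:
                if chain_id is None or a.chain_id == chain_id:
                    return a
        return None

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every position mapped through x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [replace(a, position=R @ a.position + t) for a in self.atoms]
        return Structure(atoms=atoms, sequence=dict(self.sequence), gaps=set(self.gaps))


@dataclass(frozen=True)
class BondVector:
    """Unit N->H bond direction for one residue."""

    residue_number: int
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"direction must be unit length, |d| = {n}")
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid-body fit of one structure onto another."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


def read_structure(path: str | Path, model_index: int = 0) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path:
        PDB-format text file.
    model_index:
        0-based index into the MODEL records; 0 (the first model) by default.

    Altloc policy: where alternate locations exist, the highest-occupancy one
    is kept; ties go to altloc 'A' (then alphabetical). Gaps are recorded from
    discontinuities in the author numbering within each chain.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if model_index < 0 or model_index >= len(st):
        raise IndexError(f"model_index {model_index} out of range ({len(st)} models in {path})")
    model = st[model_index]

    atoms: list[AtomRecord] = []
    sequence: dict[int, str] = {}
    gaps: set[int] = set()
    for chain in model:
        numbers_seen: list[int] = []
        for res in chain:
            num = res.seqid.num
            sequence[num] = res.name
            if num not in numbers_seen:
                numbers_seen.append(num)
            # group alternate locations by atom name, keep the winner
            by_name: dict[str, list] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            for name, alts in by_name.items():
                chosen = max(alts, key=lambda a: (a.occ, -ord(_altloc_char(a) or "A")))
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=num,
                        residue_name=res.name,
                        atom_name=name,
                        element=chosen.element.name,
                        position=np.array([chosen.pos.x, chosen.pos.y, chosen.pos.z]),
                        altloc=_altloc_char(chosen),
                        occupancy=min(max(chosen.occ, 0.0), 1.0),
                    )
                )
        if numbers_seen:
            lo, hi = min(numbers_seen), max(numbers_seen)
            gaps.update(set(range(lo, hi + 1)) - set(numbers_seen))
    if not atoms:
        raise StructureFormatError(f"model {model_index} of {path} contains no atoms")
    return Structure(atoms=atoms, sequence=sequence, gaps=gaps)


def _altloc_char(atom) -> str | None:
    c = atom.altloc
    if not c or c == "\x00":
        return None
    return c


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as PDB text (via gemmi)."""
    # gemmi's add_* methods copy by value, so assemble bottom-up
    grouped: dict[str, dict[tuple[int, str], list[AtomRecord]]] = {}
    for a in structure.atoms:
        grouped.setdefault(a.chain_id, {}).setdefault(
            (a.residue_number, a.residue_name), []
        ).append(a)
    st = gemmi.Structure()
    model = gemmi.Model(1)
    for chain_id, residues in grouped.items():
        chain = gemmi.Chain(chain_id)
        for (num, resname), recs in residues.items():
            r = gemmi.Residue()
            r.name = resname
            r.seqid = gemmi.SeqId(num, " ")
            for rec in recs:
                atom = gemmi.Atom()
                atom.name = rec.atom_name
                atom.pos = gemmi.Position(*rec.position)
                atom.element = gemmi.Element(rec.element)
                atom.occ = rec.occupancy
                if rec.altloc:
                    atom.altloc = rec.altloc
                r.add_atom(atom)
            chain.add_residue(r)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def place_amide_hydrogens(structure: Structure, nh_length: float = DEFAULT_NH_LENGTH) -> Structure:
    """Add backbone amide protons with idealized planar geometry.

    For each non-proline residue i that lacks an H atom, the proton is placed
    in the C(i-1)-N(i)-CA(i) plane along the external bisector of the C-N-CA
    angle, at ``nh_length`` Angstrom from N. The construction makes the
    H-N-C and H-N-CA angles equal, the textbook sp2 idealization of the
    peptide-bond nitrogen. Residues already carrying an H, prolines, and the
    first residue of each chain (no preceding carbonyl) are left untouched;
    residues with missing geometry are skipped with a warning.
    """
    new_atoms = list(structure.atoms)
    by_residue: dict[tuple[str, int], dict[str, AtomRecord]] = {}
    for a in structure.atoms:
        by_residue.setdefault((a.chain_id, a.residue_number), {})[a.atom_name] = a

    for (chain_id, num), named in sorted(by_residue.items()):
        resname = next(iter(named.values())).residue_name
        if resname == "PRO" or "H" in named:
            continue
        prev = by_residue.get((chain_id, num - 1))
        if prev is None:
            continue  # chain start / gap: no preceding carbonyl
        if "N" not in named or "CA" not in named or "C" not in prev:
            logger.warning("cannot place H on %s %s%d: incomplete backbone", resname, chain_id, num)
            continue
        n = named["N"].position
        u_c = prev["C"].position - n
        u_ca = named["CA"].position - n
        u_c = u_c / np.linalg.norm(u_c)
        u_ca = u_ca / np.linalg.norm(u_ca)
        bis = -(u_c + u_ca)
        norm = np.linalg.norm(bis)
        if norm < 1e-6:
            logger.warning("degenerate C-N-CA geometry at %s%d; H not placed", chain_id, num)
            continue
        h_pos = n + nh_length * bis / norm
        new_atoms.append(
            AtomRecord(
                chain_id=chain_id,
                residue_number=num,
                residue_name=resname,
                atom_name="H",
                element="H",
                position=h_pos,
            )
        )
    return Structure(atoms=new_atoms, sequence=dict(structure.sequence), gaps=set(structure.gaps))


def nh_bond_vectors(structure: Structure) -> list[BondVector]:
    """Unit N->H vectors for every residue possessing both N and H atoms."""
    by_residue: dict[int, dict[str, np.ndarray]] = {}
    for a in structure.atoms:
        if a.atom_name in ("N", "H"):
            by_residue.setdefault(a.residue_number, {})[a.atom_name] = a.position
    out: list[BondVector] = []
    for num in sorted(by_residue):
        named = by_residue[num]
        if "N" in named and "H" in named:
            d = named["H"] - named["N"]
            out.append(BondVector(residue_number=num, direction=d / np.linalg.norm(d)))
    return out


MatchRule = Callable[[AtomRecord], bool]


def _default_match(atom: AtomRecord) -> bool:
    return atom.element != "H"


def superpose(
    mobile: Structure,
    reference: Structure,
    selection: MatchRule | None = None,
) -> Superposition:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``reference``.

    Atoms are paired by the intersection of (chain_id, residue_number,
    atom_name); ``selection`` further restricts which atoms participate
    (default: heavy atoms only). The returned transform maps mobile
    coordinates onto the reference frame, x -> R x + t, and is always a
    proper rotation.
    """
    if selection is None:
        selection = _default_match
    ref_index = {
        (a.chain_id, a.residue_number, a.atom_name): a.position
        for a in reference.atoms
        if selection(a)
    }
    pairs_mob: list[np.ndarray] = []
    pairs_ref: list[np.ndarray] = []
    for a in mobile.atoms:
        if not selection(a):
            continue
        key = (a.chain_id, a.residue_number, a.atom_name)
        if key in ref_index:
            pairs_mob.append(a.position)
            pairs_ref.append(ref_index[key])
    n = len(pairs_mob)
    if n < 3:
        raise ValueError(f"superposition needs >= 3 matched atom pairs, found {n}")
    X = np.array(pairs_mob)
    Y = np.array(pairs_ref)
    xc = X.mean(axis=0)
    yc = Y.mean(axis=0)
    X0 = X - xc
    Y0 = Y - yc
    # collinearity check: centered coordinates must span a plane
    s = np.linalg.svd(X0, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("matched atoms are (near-)collinear; superposition is degenerate")
    rot, rssd = Rotation.align_vectors(Y0, X0)
    R = rot.as_matrix()
    t = yc - R @ xc
    rmsd = float(math.sqrt(rssd**2 / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def superposition_report(sup: Superposition) -> str:
    """TSV report of a superposition (atom count, rmsd, rotation, translation)."""
    lines = ["field\tvalue", f"n_atoms\t{sup.n_atoms}", f"rmsd_angstrom\t{sup.rmsd:.4f}"]
    for i in range(3):
        lines.append("rotation_row%d\t%s" % (i, "\t".join(f"{v:.6f}" for v in sup.rotation[i])))
    lines.append("translation\t" + "\t".join(f"{v:.4f}" for v in sup.translation))
    return "\n".join(lines) + "\n"
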