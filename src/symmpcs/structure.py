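"""Structure container and PDB input/output.

A deliberately small in-memory model: ordered chains of numbered residues
of named atoms with coordinates in angstrom.  Parsing and writing of PDB
files is delegated to gemmi; this module adds the operations the PCS
workflow needs: completing partially resolved chains by superposition and
building amide protons on X-ray coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import DegenerateGeometryError, InvalidArgumentError, ParseError
from .geometry import apply_rigid, kabsch_superpose

log = logging.getLogger(__name__)

__all__ = ["Atom", "Residue", "Chain", "Structure", "read_pdb", "write_pdb",
           "complete_chains", "build_amide_protons"]

#: Amide N-H bond length used when building protons, angstrom.
NH_BOND_LENGTH = 1.02


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coord, dtype=float).reshape(3)
        if not np.all(np.isfinite(c)):
            raise InvalidArgumentError(f"non-finite coordinates for atom {self.name}")
        self.coord = c


@dataclass
class Residue:
    number: int
    name: str
    atoms: dict[str, Atom] = field(default_factory=dict)

    def add(self, atom: Atom) -> None:
        if atom.name in self.atoms:
            raise InvalidArgumentError(
                f"duplicate atom {atom.name} in residue {self.number}"
            )
        self.atoms[atom.name] = atom


@dataclass
class Chain:
    id: str
    residues: dict[int, Residue] = field(default_factory=dict)

    def add(self, residue: Residue) -> None:
        if residue.number in self.residues:
            raise InvalidArgumentError(
                f"duplicate residue {residue.number} in chain {self.id}"
            )
        self.residues[residue.number] = residue

    def sorted_residues(self) -> list[Residue]:
        return [self.residues[n] for n in sorted(self.residues)]


class Structure:
    """Ordered chains of residues of atoms; (chain, residue, atom) unique."""

    def __init__(self) -> None:
        self.chains: dict[str, Chain] = {}

    def add_chain(self, chain: Chain) -> None:
        if chain.id in self.chains:
            raise InvalidArgumentError(f"duplicate chain {chain.id}")
        self.chains[chain.id] = chain

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def find_coord(self, chain: str, residue: int, atom: str) -> np.ndarray | None:
        ch = self.chains.get(chain)
        if ch is None:
            return None
        res = ch.residues.get(int(residue))
        if res is None:
            return None
        at = res.atoms.get(atom)
        return None if at is None else at.coord

    def shared_residues(self, chain_a: str, chain_b: str) -> list[int]:
        a = self.chains.get(chain_a)
        b = self.chains.get(chain_b)
        if a is None or b is None:
            missing = chain_a if a is None else chain_b
            raise InvalidArgumentError(f"chain {missing} not present in structure")
        return sorted(set(a.residues) & set(b.residues))

    def copy(self) -> "Structure":
        out = Structure()
        for cid, ch in self.chains.items():
            nc = Chain(id=cid)
            for res in ch.sorted_residues():
                nr = Residue(number=res.number, name=res.name)
                for at in res.atoms.values():
                    nr.add(Atom(name=at.name, element=at.element, coord=at.coord.copy()))
                nc.add(nr)
            out.add_chain(nc)
        return out

    def all_coords(self) -> np.ndarray:
        pts = [
            at.coord
            for ch in self.chains.values()
            for res in ch.residues.values()
            for at in res.atoms.values()
        ]
        if not pts:
            raise InvalidArgumentError("structure has no atoms")
        return np.array(pts)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        coords = self.all_coords()
        return coords.min(axis=0), coords.max(axis=0)


def read_pdb(path: str) -> Structure:
    """Read a PDB file (model 1, ATOM/HETATM records).

    Alternate locations are collapsed to the highest-occupancy atom per
    name.  Insertion codes are rejected; multi-model files use model 1.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"no models in {path}")
    model = st[0]
    out = Structure()
    for ch in model:
        chain = Chain(id=ch.name)
        for res in ch:
            if res.seqid.icode not in ("", " ", "\0"):
                raise ParseError(
                    f"insertion code {res.seqid.icode!r} at {ch.name}/{res.seqid.num} "
                    "is not supported"
                )
            residue = Residue(number=res.seqid.num, name=res.name)
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                residue.add(
                    Atom(
                        name=atom.name,
                        element=atom.element.name,
                        coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                )
            if residue.atoms:
                chain.add(residue)
        if chain.residues:
            out.add_chain(chain)
    if not out.chains:
        raise ParseError(f"no atoms found in {path}")
    return out


def write_pdb(structure: Structure, path: str) -> None:
    """Write the structure as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = "symmpcs"
    model = gemmi.Model("1")
    for cid, ch in structure.chains.items():
        gch = gemmi.Chain(cid)
        for res in ch.sorted_residues():
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, " ")
            for at in res.atoms.values():
                ga = gemmi.Atom()
                ga.name = at.name
                ga.element = gemmi.Element(at.element or at.name[0])
                ga.pos = gemmi.Position(*at.coord)
                ga.occ = 1.0
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def complete_chains(structure: Structure, reference_chain: str) -> Structure:
    """Fill residues missing from non-reference chains.

    For each other chain, a copy of the complete reference chain is
    superposed onto it using shared C-alpha pairs (least squares) and the
    residues absent from the target chain are filled in with transformed
    reference coordinates.  Atoms already present are never altered.
    """
    if reference_chain not in structure.chains:
        raise InvalidArgumentError(f"reference chain {reference_chain} not in structure")
    ref = structure.chains[reference_chain]
    union: set[int] = set()
    for ch in structure.chains.values():
        union |= set(ch.residues)
    missing_from_ref = sorted(union - set(ref.residues))
    if missing_from_ref:
        raise InvalidArgumentError(
            f"reference chain {reference_chain} lacks residues "
            f"{missing_from_ref} present elsewhere"
        )
    out = structure.copy()
    for cid, target in out.chains.items():
        if cid == reference_chain:
            continue
        missing = sorted(set(ref.residues) - set(target.residues))
        if not missing:
            continue
        pairs_ref, pairs_tgt = [], []
        for num in sorted(set(ref.residues) & set(target.residues)):
            a = ref.residues[num].atoms.get("CA")
            b = target.residues[num].atoms.get("CA")
            if a is not None and b is not None:
                pairs_ref.append(a.coord)
                pairs_tgt.append(b.coord)
        if len(pairs_ref) < 3:
            raise DegenerateGeometryError(
                f"chains {reference_chain}/{cid} share fewer than 3 C-alpha pairs"
            )
        R, t, rmsd = kabsch_superpose(np.array(pairs_ref), np.array(pairs_tgt))
        log.info("completing chain %s from %s: %d residues, superposition rmsd %.3f A",
                 cid, reference_chain, len(missing), rmsd)
        for num in missing:
            src = ref.residues[num]
            nr = Residue(number=num, name=src.name)
            for at in src.atoms.values():
                nr.add(Atom(name=at.name, element=at.element,
                            coord=apply_rigid(R, t, at.coord)))
            target.add(nr)
    return out


def build_amide_protons(structure: Structure) -> Structure:
    """Add backbone amide H atoms to a proton-less (X-ray) structure.

    H is placed on N at 1.02 angstrom along the in-plane direction opposite
    to the bisector of the C(i-1)-N and CA-N bonds, i.e. trans to both
    heavy-atom bonds in the peptide plane.  Prolines (no amide H) and chain
    N-termini (no preceding carbonyl) are skipped; residues that already
    carry an H are left untouched; residues with missing backbone atoms are
    skipped with a warning.
    """
    out = structure.copy()
    for chain in out.chains.values():
        residues = chain.sorted_residues()
        for prev, res in zip(residues[:-1], residues[1:]):
            if res.name == "PRO" or "H" in res.atoms:
                continue
            if res.number != prev.number + 1:
                continue  # chain break: treat as N-terminus
            n = res.atoms.get("N")
            ca = res.atoms.get("CA")
            c_prev = prev.atoms.get("C")
            if n is None or ca is None or c_prev is None:
                log.warning(
                    "cannot build H for %s %d: missing backbone atoms", chain.id, res.number
                )
                continue
            u1 = c_prev.coord - n.coord
            u2 = ca.coord - n.coord
            u1 = u1 / np.linalg.norm(u1)
            u2 = u2 / np.linalg.norm(u2)
            d = -(u1 + u2)
            norm = np.linalg.norm(d)
            if norm < 1e-8:
                log.warning(
                    "cannot build H for %s %d: collinear backbone", chain.id, res.number
                )
                continue
            res.add(Atom(name="H", element="H", coord=n.coord + NH_BOND_LENGTH * d / norm))
    return out
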