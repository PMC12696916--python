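"""Backbone-only structure model and a minimal PDB reader/writer.

The pipeline only needs amino-acid identities and the four backbone heavy
atoms (N, CA, C, O) per residue, so the data model is deliberately small.
Reading and writing of the PDB format is delegated to gemmi; only the first
model and first conformer are used, and nonstandard residues are mapped to
the placeholder code 'X'.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, List, Tuple

import gemmi
import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"
BACKBONE_ATOMS = ("N", "CA", "C", "O")

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


@dataclass
class Residue:
    """One residue: 1-based index in its chain, one-letter code, backbone atoms."""

    seq_index: int
    aa: str
    atoms: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def eligible(self) -> bool:
        """True if all four backbone atoms are present (required for mining)."""
        return all(name in self.atoms for name in BACKBONE_ATOMS)

    def __post_init__(self) -> None:
        if self.aa not in AA20 and self.aa != "X":
            raise ValueError(f"invalid amino-acid code {self.aa!r}")


@dataclass
class Chain:
    chain_id: str
    residues: List[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __post_init__(self) -> None:
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"chain {self.chain_id}: seq_index must be strictly increasing"
            )


@dataclass
class Structure:
    structure_id: str
    chains: List[Chain] = field(default_factory=list)

    def iter_residues(self) -> Iterator[Tuple[Chain, Residue]]:
        for chain in self.chains:
            for res in chain.residues:
                yield chain, res

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def n_eligible(self) -> int:
        return sum(1 for _, r in self.iter_residues() if r.eligible)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly moved copy: x -> R @ x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        chains = []
        for chain in self.chains:
            residues = [
                Residue(
                    r.seq_index,
                    r.aa,
                    {k: rotation @ v + translation for k, v in r.atoms.items()},
                )
                for r in chain.residues
            ]
            chains.append(Chain(chain.chain_id, residues))
        return Structure(self.structure_id, chains)


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid() and info.is_standard():
        code = info.one_letter_code.upper()
        if code in AA20:
            return code
    return "X"


def read_pdb(path) -> Structure:
    """Read a PDB file (ATOM records, first model/conformer) into a Structure.

    Residues lacking any backbone atom are retained but flagged ineligible;
    nonstandard residues map to 'X'.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unreadable PDB file {path}: {exc}") from exc
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise ValueError(f"no ATOM records in {path}")
    model = st[0]
    chains: List[Chain] = []
    for gchain in model:
        residues: List[Residue] = []
        for gres in gchain:
            atoms: Dict[str, np.ndarray] = {}
            for atom in gres:
                if atom.name in BACKBONE_ATOMS and atom.name not in atoms:
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                    )
            if not atoms:
                continue
            residues.append(Residue(gres.seqid.num, _one_letter(gres.name), atoms))
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains:
        raise ValueError(f"no ATOM records in {path}")
    return Structure(path.stem, chains)


def write_pdb(structure: Structure, path) -> None:
    """Write backbone ATOM records (3-decimal coordinates, chain ids preserved)."""
    if structure.n_residues == 0:
        raise ValueError("nothing to write: structure has no residues")
    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = _ONE_TO_THREE[res.aa]
            gres.seqid = gemmi.SeqId(res.seq_index, " ")
            for name in BACKBONE_ATOMS:
                if name not in res.atoms:
                    continue
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                xyz = res.atoms[name]
                atom.pos = gemmi.Position(float(xyz[0]), float(xyz[1]), float(xyz[2]))
                gres.add_atom(atom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write PDB file {path}: {exc}") from exc
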