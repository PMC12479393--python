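"""Structure and sequence I/O.

Reads PDB/mmCIF files into light-weight per-chain records carrying the
two anchor atoms everything downstream needs (Cβ, falling back to Cα for
glycine and for residues with incomplete side chains), and reads/writes
FASTA target lists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as _cif_get_structure, set_structure as _cif_set_structure

logger = logging.getLogger(__name__)

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues, mapped to their parent code
    "MSE": "M", "SEP": "S", "TPO": "T", "PTR": "Y", "CSO": "C",
    "HYP": "P", "MLY": "K", "M3L": "K", "CME": "C", "KCX": "K",
    "LLP": "K", "PCA": "E", "SEC": "C", "PYL": "K",
}

AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when no polymer chain survives filtering."""


class FastaError(ValueError):
    """Raised for malformed FASTA input."""


@dataclass
class ChainRecord:
    """One polymer chain reduced to its per-residue anchor geometry.

    ``cb_coords`` holds the Cβ position for each residue, with Cα
    substituted at glycines and at residues whose Cβ is missing from the
    coordinates.  Residues missing both atoms are dropped on read.
    """

    chain_id: str
    sequence: str
    residue_numbers: list[int]
    cb_coords: np.ndarray  # (L, 3) float64, Å
    ca_coords: np.ndarray  # (L, 3) float64, Å
    com: np.ndarray = field(default=None)  # (3,) centre of mass of chain atoms

    def __post_init__(self) -> None:
        self.cb_coords = np.asarray(self.cb_coords, dtype=np.float64).reshape(-1, 3)
        self.ca_coords = np.asarray(self.ca_coords, dtype=np.float64).reshape(-1, 3)
        self.residue_numbers = [int(n) for n in self.residue_numbers]
        n = len(self.sequence)
        if not (len(self.residue_numbers) == len(self.cb_coords) == len(self.ca_coords) == n):
            raise ValueError(
                f"chain {self.chain_id}: inconsistent lengths "
                f"(seq {n}, numbers {len(self.residue_numbers)}, "
                f"cb {len(self.cb_coords)}, ca {len(self.ca_coords)})"
            )
        if any(b <= a for a, b in zip(self.residue_numbers, self.residue_numbers[1:])):
            raise ValueError(f"chain {self.chain_id}: residue numbers not strictly increasing")
        if self.com is None:
            self.com = self.ca_coords.mean(axis=0) if n else np.zeros(3)
        self.com = np.asarray(self.com, dtype=np.float64).reshape(3)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Complex:
    """An ordered collection of chains from one structure."""

    chains: list[ChainRecord]
    source_format: str = "pdb"

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("a Complex must contain at least one chain")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain IDs: {ids}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def get_chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in complex (have {self.chain_ids})")


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    return "pdb"


def _load_atom_array(path: Path) -> tuple[struc.AtomArray, str]:
    fmt = _guess_format(path)
    readers = [(fmt, None)] + [(f, None) for f in ("pdb", "mmcif") if f != fmt]
    last_err: Exception | None = None
    for candidate, _ in readers:
        try:
            if candidate == "pdb":
                arr = PDBFile.read(str(path)).get_structure(model=1, altloc="first")
            else:
                arr = _cif_get_structure(CIFFile.read(str(path)), model=1, altloc="first")
            return arr, candidate
        except Exception as exc:  # try the other dialect before giving up
            last_err = exc
    raise StructureFormatError(f"cannot parse {path} as PDB or mmCIF: {last_err}")


def read_structure(path: str | Path, min_chain_length: int = 1) -> Complex:
    """Read a PDB/mmCIF file into a :class:`Complex`.

    Only protein residues are kept (waters, ions and ligands are
    excluded); the first model and the first altloc are used.  Chains
    shorter than ``min_chain_length`` residues are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    atoms, fmt = _load_atom_array(path)
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"{path}: no protein residues found")

    chains: list[ChainRecord] = []
    for chain_id in np.unique(atoms.chain_id).tolist():
        chain_atoms = atoms[atoms.chain_id == chain_id]
        record = _chain_from_atoms(str(chain_id), chain_atoms)
        if record is not None and len(record) >= min_chain_length:
            chains.append(record)
    if not chains:
        raise EmptyStructureError(
            f"{path}: no polymer chain of length >= {min_chain_length}"
        )
    return Complex(chains=chains, source_format=fmt)


def _chain_from_atoms(chain_id: str, chain_atoms: struc.AtomArray) -> ChainRecord | None:
    seq_chars: list[str] = []
    numbers: list[int] = []
    cb: list[np.ndarray] = []
    ca: list[np.ndarray] = []
    last_num: int | None = None
    starts = struc.get_residue_starts(chain_atoms, add_exclusive_stop=True)
    for start, stop in zip(starts[:-1], starts[1:]):
        res = chain_atoms[start:stop]
        res_id = int(res.res_id[0])
        res_name = str(res.res_name[0])
        one = AA_3TO1.get(res_name, "X")
        ca_sel = res[res.atom_name == "CA"]
        cb_sel = res[res.atom_name == "CB"]
        ca_xyz = ca_sel.coord[0] if ca_sel.array_length() else None
        cb_xyz = cb_sel.coord[0] if cb_sel.array_length() else None
        if one == "G":
            cb_xyz = ca_xyz  # Cα stands in for Cβ at glycine
        if cb_xyz is None and ca_xyz is not None:
            logger.warning("chain %s residue %s%d lacks CB; using CA", chain_id, res_name, res_id)
            cb_xyz = ca_xyz
        if ca_xyz is None and cb_xyz is None:
            logger.warning("chain %s residue %s%d lacks CA and CB; dropped", chain_id, res_name, res_id)
            continue
        if ca_xyz is None:
            ca_xyz = cb_xyz
        if last_num is not None and res_id <= last_num:
            logger.warning(
                "chain %s residue %d does not increase numbering (last %d); dropped",
                chain_id, res_id, last_num,
            )
            continue
        last_num = res_id
        seq_chars.append(one)
        numbers.append(res_id)
        ca.append(np.asarray(ca_xyz, dtype=np.float64))
        cb.append(np.asarray(cb_xyz, dtype=np.float64))
    if not seq_chars:
        return None
    com = chain_atoms.coord.astype(np.float64).mean(axis=0)
    return ChainRecord(
        chain_id=chain_id,
        sequence="".join(seq_chars),
        residue_numbers=numbers,
        cb_coords=np.stack(cb),
        ca_coords=np.stack(ca),
        com=com,
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (header, sequence).

    Order and duplicates are preserved (duplicate sequences denote
    homomeric copies).  Sequences must use one-letter amino-acid codes;
    ``X`` is permitted.
    """
    path = Path(path)
    text = path.read_text()
    entries: list[tuple[str, list[str]]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            entries.append((line[1:].strip(), []))
        else:
            if not entries:
                raise FastaError(f"{path}: sequence data before first header")
            entries[-1][1].append(line)
    if not entries:
        raise FastaError(f"{path}: no FASTA records found")
    result: list[tuple[str, str]] = []
    for header, parts in entries:
        seq = "".join(parts).upper()
        if not seq:
            raise FastaError(f"{path}: record {header!r} has an empty sequence")
        bad = set(seq) - VALID_AA
        if bad:
            raise FastaError(f"{path}: record {header!r} has invalid characters {sorted(bad)}")
        result.append((header, seq))
    return result


def write_fasta(entries: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def complex_to_atom_array(complex: Complex) -> struc.AtomArray:
    """Expand a Complex into a biotite AtomArray of CA/CB anchor atoms."""
    n_atoms = sum(
        len(c) + sum(1 for aa in c.sequence if aa != "G") for c in complex.chains
    )
    arr = struc.AtomArray(n_atoms)
    i = 0
    for chain in complex.chains:
        for pos, aa in enumerate(chain.sequence):
            res_name = AA_1TO3.get(aa, "UNK")
            atoms = [("CA", chain.ca_coords[pos])]
            if aa != "G":
                atoms.append(("CB", chain.cb_coords[pos]))
            for name, xyz in atoms:
                arr.coord[i] = xyz
                arr.chain_id[i] = chain.chain_id
                arr.res_id[i] = chain.residue_numbers[pos]
                arr.res_name[i] = res_name
                arr.atom_name[i] = name
                arr.element[i] = "C"
                arr.hetero[i] = False
                i += 1
    return arr


def write_structure(complex: Complex, path: str | Path, format: str | None = None) -> None:
    """Write a Complex as PDB or mmCIF (anchor atoms only).

    Round-trips through :func:`read_structure` preserve chain IDs,
    sequences, residue numbers and coordinates to 1e-3 Å.
    """
    path = Path(path)
    if format is None:
        format = _guess_format(path)
    if format not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown format {format!r}")
    arr = complex_to_atom_array(complex)
    if format == "pdb":
        pdb_file = PDBFile()
        pdb_file.set_structure(arr)
        pdb_file.write(str(path))
    else:
        cif_file = CIFFile()
        _cif_set_structure(cif_file, arr)
        cif_file.write(str(path))
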