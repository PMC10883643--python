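"""Domain model for cleaned protein structures and benchmark cases.

A benchmark case pairs one *bound* antibody-antigen complex with candidate
*unbound* structures of its components.  Structures are kept deliberately
minimal: only coordinate (ATOM) content survives parsing, because the
benchmark files themselves are distributed that way — no heteroatoms,
no anisotropic records, no waters.

Residue identity is ``(chain id, residue number, insertion code)`` and the
author's numbering is preserved verbatim; nothing here renumbers.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "ChainRole",
    "StructureModel",
    "ComplexCase",
    "PairingState",
    "PDBParseError",
    "read_structure",
    "write_structure",
    "extract_minimal_case",
    "truncate_unbound",
    "split_interfaces",
    "align_sequences",
]

# 3-letter -> 1-letter, with common nonstandard residues mapped to their
# nearest standard parent (MSE->M etc.); unknowns become 'X'.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # nonstandard parents
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K", "M3L": "K",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    """Raised when a coordinate line cannot be parsed; names the line."""


class ChainRole(str, Enum):
    HEAVY = "heavy"
    LIGHT = "light"
    SINGLE_DOMAIN = "single_domain"
    ANTIGEN = "antigen"
    UNKNOWN = "unknown"


class PairingState(str, Enum):
    """Availability of experimentally solved unbound partners.

    UU: both antibody and antigen have unbound structures; UB: antibody
    only; BU: antigen only; BB: neither.
    """

    UU = "UU"
    UB = "UB"
    BU = "BU"
    BB = "BB"


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray  # (3,) in Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    serial: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be 3 finite values")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    name: str
    number: int
    insertion_code: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def id(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def ca(self) -> Optional[AtomRecord]:
        for atom in self.atoms:
            if atom.name == "CA" and not atom.is_hydrogen:
                return atom
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def get_atom(self, name: str) -> Optional[AtomRecord]:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)
    role: ChainRole = ChainRole.UNKNOWN

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue_by_id(self, res_id: tuple[int, str]) -> Optional[Residue]:
        for r in self.residues:
            if r.id == res_id:
                return r
        return None

    def copy(self) -> "Chain":
        return copy.deepcopy(self)


@dataclass
class StructureModel:
    id: str
    chains: list[Chain] = field(default_factory=list)
    resolution: Optional[float] = None
    release_date: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"structure {self.id!r}: duplicate chain ids {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(
            f"structure {self.id!r} has no chain {chain_id!r}; "
            f"available: {[c.id for c in self.chains]}"
        )

    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def subset(self, chain_ids: Sequence[str], new_id: Optional[str] = None) -> "StructureModel":
        """Deep copy restricted to the named chains, in the given order."""
        chains = [self.chain(cid).copy() for cid in chain_ids]
        return StructureModel(
            id=new_id or self.id,
            chains=chains,
            resolution=self.resolution,
            release_date=self.release_date,
        )

    def copy(self) -> "StructureModel":
        return copy.deepcopy(self)


@dataclass
class ComplexCase:
    """One bound interface plus its candidate unbound component structures."""

    case_id: str
    bound: StructureModel
    antibody_chain_ids: list[str]
    antigen_chain_ids: list[str]
    unbound_antibody: list[StructureModel] = field(default_factory=list)
    unbound_antigen: list[StructureModel] = field(default_factory=list)
    pairing_state: PairingState = PairingState.BB
    metrics: Optional[object] = None  # InterfaceMetrics, set downstream
    difficulty: Optional[str] = None

    def __post_init__(self) -> None:
        if set(self.antibody_chain_ids) & set(self.antigen_chain_ids):
            raise ValueError(
                f"case {self.case_id!r}: antibody and antigen chain id sets overlap"
            )

    def antibody_model(self) -> StructureModel:
        return self.bound.subset(self.antibody_chain_ids, new_id=f"{self.case_id}_ab")

    def antigen_model(self) -> StructureModel:
        return self.bound.subset(self.antigen_chain_ids, new_id=f"{self.case_id}_ag")


# ---------------------------------------------------------------------------
# PDB reading / writing (ATOM subset only)
# ---------------------------------------------------------------------------

def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed {what} field {text.strip()!r}") from None


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if not stripped:
        return ""
    # column-aligned names start with digit for hydrogens like 1HB
    if stripped[0].isdigit():
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in ("FE", "ZN", "MG", "SE"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def read_structure(
    pdb_text: str,
    altloc_policy: str = "highest_occupancy",
    structure_id: str = "model",
) -> StructureModel:
    """Parse PDB text keeping only ATOM-derived protein content.

    HETATM, ANISOU and water records are dropped, only the first model of a
    multi-model file is read, and alternate locations are collapsed
    according to ``altloc_policy``:

    - ``"highest_occupancy"`` (default): keep the altloc with the highest
      occupancy; ties broken by the alphabetically first altloc id.
    - ``"first"``: keep the first altloc encountered in file order.

    Hydrogens are retained in the model but flagged (``AtomRecord.is_hydrogen``)
    so that all distance-based computations can exclude them.
    """
    if altloc_policy not in ("highest_occupancy", "first"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")

    chains: dict[str, Chain] = {}
    order: list[str] = []
    in_first_model = True
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "ENDMDL":
            in_first_model = False
        if not in_first_model or rec != "ATOM":
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: ATOM record too short for coordinates")
        res_name = line[17:20].strip()
        if res_name in _WATER_NAMES:
            continue
        atom_name = line[12:16].strip()
        altloc = line[16].strip()
        chain_id = line[21]
        try:
            res_number = int(line[22:26])
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: malformed residue number {line[22:26].strip()!r}"
            ) from None
        icode = line[26].strip()
        x = _parse_float(line[30:38], "x coordinate", lineno)
        y = _parse_float(line[38:46], "y coordinate", lineno)
        z = _parse_float(line[46:54], "z coordinate", lineno)
        occ_field = line[54:60].strip()
        occupancy = _parse_float(occ_field, "occupancy", lineno) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(atom_name)
        try:
            serial = int(line[6:11])
        except ValueError:
            serial = 0

        atom = AtomRecord(
            name=atom_name,
            element=element,
            coords=np.array([x, y, z]),
            occupancy=min(max(occupancy, 0.0), 1.0),
            altloc=altloc,
            serial=serial,
        )
        if chain_id not in chains:
            chains[chain_id] = Chain(id=chain_id)
            order.append(chain_id)
        chain = chains[chain_id]
        if chain.residues and chain.residues[-1].id == (res_number, icode) and (
            chain.residues[-1].name == res_name
        ):
            chain.residues[-1].atoms.append(atom)
        else:
            chain.residues.append(
                Residue(name=res_name, number=res_number, insertion_code=icode, atoms=[atom])
            )

    model = StructureModel(id=structure_id, chains=[chains[c] for c in order])
    if model.n_atoms() == 0:
        raise PDBParseError("no ATOM records found: empty model")
    _collapse_altlocs(model, altloc_policy)
    return model


def _collapse_altlocs(model: StructureModel, policy: str) -> None:
    for chain in model.chains:
        for residue in chain.residues:
            seen: dict[str, AtomRecord] = {}
            collapsed: list[AtomRecord] = []
            for atom in residue.atoms:
                prev = seen.get(atom.name)
                if prev is None:
                    seen[atom.name] = atom
                    collapsed.append(atom)
                    continue
                if policy == "first":
                    continue
                better = atom.occupancy > prev.occupancy or (
                    atom.occupancy == prev.occupancy and atom.altloc < prev.altloc
                )
                if better:
                    collapsed[collapsed.index(prev)] = atom
                    seen[atom.name] = atom
            for atom in collapsed:
                atom.altloc = ""
            residue.atoms = collapsed


def write_structure(model: StructureModel) -> str:
    """Serialize a model to PDB ATOM records with TER between chains.

    Chain ids and author residue numbering are preserved.  Coordinates must
    fit the fixed-width %8.3f field (|x| < 10000 Angstrom).
    """
    if not model.chains or model.n_atoms() == 0:
        raise ValueError(f"structure {model.id!r}: nothing to write (empty chain list)")
    lines: list[str] = []
    serial = 0
    for chain in model.chains:
        for residue in chain.residues:
            for atom in residue.atoms:
                serial += 1
                if np.any(np.abs(atom.coords) >= 10000.0):
                    raise ValueError(
                        f"atom {atom.name!r} in {chain.id}/{residue.number}: coordinate "
                        "exceeds PDB fixed-width field"
                    )
                name = atom.name
                # standard alignment: 1-3 char names start in column 14
                padded = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {padded:<4s}{'':1s}{residue.name:>3s} "
                    f"{chain.id}{residue.number:4d}{residue.insertion_code:1s}   "
                    f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2s}"
                )
        serial += 1
        last = chain.residues[-1]
        lines.append(
            f"TER   {serial:5d}      {last.name:>3s} {chain.id}{last.number:4d}"
            f"{last.insertion_code:1s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Case preparation
# ---------------------------------------------------------------------------

def extract_minimal_case(
    model: StructureModel,
    antibody_ids: Sequence[str],
    antigen_ids: Sequence[str],
    case_id: Optional[str] = None,
) -> ComplexCase:
    """Reduce a structure to the fewest chains that reflect the binding.

    Only the named antibody and antigen chains survive; everything else
    (crystallographic neighbours, extra copies) is dropped.  The pairing
    state starts at BB: unbound structures are attached downstream.
    """
    wanted = list(antibody_ids) + list(antigen_ids)
    available = set(model.chain_ids())
    missing = [c for c in wanted if c not in available]
    if missing:
        raise KeyError(
            f"chain(s) {missing} not in structure {model.id!r}; "
            f"available: {sorted(available)}"
        )
    bound = model.subset(wanted, new_id=case_id or model.id)
    for cid in antigen_ids:
        bound.chain(cid).role = ChainRole.ANTIGEN
    return ComplexCase(
        case_id=case_id or model.id,
        bound=bound,
        antibody_chain_ids=list(antibody_ids),
        antigen_chain_ids=list(antigen_ids),
        pairing_state=PairingState.BB,
    )


_ALIGNER: Optional[PairwiseAligner] = None


def _aligner() -> PairwiseAligner:
    # global end-gap-free alignment; BLOSUM62 handles mismatches sensibly
    global _ALIGNER
    if _ALIGNER is None:
        a = PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        a.open_end_insertion_score = 0.0
        a.extend_end_insertion_score = 0.0
        a.open_end_deletion_score = 0.0
        a.extend_end_deletion_score = 0.0
        a.mode = "global"
        _ALIGNER = a
    return _ALIGNER


def align_sequences(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Aligned (index_a, index_b) column pairs from a global end-gap-free
    alignment.  Only match/mismatch columns are returned; gaps are skipped."""
    if not seq_a or not seq_b:
        return []
    alignment = _aligner().align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        pairs.extend(zip(range(a_start, a_end), range(b_start, b_end)))
    return pairs


def truncate_unbound(unbound: Chain, bound: Chain) -> Chain:
    """Trim an unbound chain to the residues aligned to the bound chain.

    Unbound crystal structures frequently carry extra domains or tags;
    for docking only the portion matching the bound sequence is kept.
    The input chain is not modified.
    """
    pairs = align_sequences(bound.sequence, unbound.sequence)
    if not pairs:
        raise ValueError(
            f"no alignment overlap between bound chain {bound.id!r} and "
            f"unbound chain {unbound.id!r}"
        )
    keep = {b for _, b in pairs}
    out = Chain(id=unbound.id, role=unbound.role)
    out.residues = [copy.deepcopy(r) for i, r in enumerate(unbound.residues) if i in keep]
    return out


def split_interfaces(
    model: StructureModel,
    interface_defs: Sequence[tuple[Sequence[str], Sequence[str]]],
) -> list[ComplexCase]:
    """One independent ComplexCase per antibody/antigen interface definition.

    Some complexes carry two distinct antibody-antigen interfaces; each
    becomes its own case, suffixed ``_1``, ``_2``, ... in input order.
    The cases are deep copies: mutating one never touches another.
    """
    cases = []
    for i, (ab_ids, ag_ids) in enumerate(interface_defs, start=1):
        cases.append(
            extract_minimal_case(model, ab_ids, ag_ids, case_id=f"{model.id}_{i}")
        )
    return cases
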