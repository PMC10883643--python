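"""Conformational-change metrics between bound and unbound structures.

The quantities computed here drive docking-difficulty classification:

- **I-RMSD** — Calpha RMSD over *interface residues* (residues with any
  non-hydrogen atom within 10 A of the binding partner), computed after a
  least-squares superposition of the unbound structure onto the bound one
  fitted on those same interface Calpha atoms.  Reported per side
  (antibody / antigen) and for the entire interface (each component fitted
  on its own interface, deviations pooled).
- **f_non-nat** — the fraction of residue-residue contacts (5 A threshold)
  of the superposed unbound pair that are absent from the bound (native)
  contact set.
- **dASA** — solvent-accessible surface area buried on binding:
  SASA(antibody) + SASA(antigen) - SASA(complex), components taken in
  their bound conformation (Shrake-Rupley numerical SASA).
- **CDR RMSD** — per-CDR Calpha RMSD after superposition on the antibody
  framework (non-CDR) Calpha atoms; CDR boundaries follow a Chothia-style
  numbering annotation supplied as input.

Hydrogens are excluded from every distance-based computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import Chain, ChainRole, ComplexCase, StructureModel, align_sequences

__all__ = [
    "Superposition",
    "ResidueMap",
    "InterfaceDefinition",
    "ContactSet",
    "InterfaceMetrics",
    "CDRAnnotation",
    "kabsch_superpose",
    "mapped_rmsd",
    "interface_residues",
    "contacts",
    "i_rmsd",
    "f_non_nat",
    "sasa",
    "delta_asa",
    "cdr_rmsd",
    "framework_block_ranges",
    "compute_case_metrics",
]

#: residue identity across a model: (chain id, residue number, insertion code)
ResidueKey = tuple[str, int, str]

INTERFACE_CUTOFF = 10.0
CONTACT_CUTOFF = 5.0

#: Chothia-numbered framework residue ranges masked ("blocked") during
#: antibody docking so predicted interfaces favour the CDRs.  ``None`` as a
#: range end means "to the chain terminus".
_BLOCK_RANGES = {
    "heavy": [(6, 22), (39, 46), (81, 91), (106, None)],
    "light": [(7, 20), (38, 44), (76, 85), (101, None)],
}


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass
class Superposition:
    """Rigid transform mapping a mobile coordinate set onto a reference.

    ``apply(x)`` returns ``x @ rotation.T + translation``.
    """

    rotation: np.ndarray  # (3, 3), proper rotation
    translation: np.ndarray  # (3,)
    fit_rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares rigid fit of ``coords_b`` onto ``coords_a`` (Kabsch).

    Both arrays are (N, 3) with N >= 3 and matched row order.  The rotation
    is always proper (det = +1); reflections are rejected by the usual sign
    correction on the smallest singular value.  Degenerate (collinear)
    point sets leave the rotation about the line axis undetermined and are
    an error.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate arrays must both be (N, 3); got {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points for a superposition, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    at, bt = a - ca, b - cb
    for name, pts in (("reference", at), ("mobile", bt)):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise ValueError(f"{name} point set is degenerate (collinear); fit undetermined")
    h = bt.T @ at
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ca - rot @ cb
    fitted = bt @ rot.T + ca
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - a) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, fit_rmsd=rmsd)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((np.asarray(a) - np.asarray(b)) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Residue correspondence
# ---------------------------------------------------------------------------

@dataclass
class ResidueMap:
    """Sequence-alignment-derived residue correspondence between two models.

    ``pairs`` holds (residue key in model a, residue key in model b); the
    mapping is injective in both directions.
    """

    pairs: list[tuple[ResidueKey, ResidueKey]] = field(default_factory=list)

    def __post_init__(self) -> None:
        a_keys = [p[0] for p in self.pairs]
        b_keys = [p[1] for p in self.pairs]
        if len(set(a_keys)) != len(a_keys) or len(set(b_keys)) != len(b_keys):
            raise ValueError("residue map must be injective in both directions")

    def __len__(self) -> int:
        return len(self.pairs)

    def a_to_b(self) -> dict[ResidueKey, ResidueKey]:
        return dict(self.pairs)

    def b_to_a(self) -> dict[ResidueKey, ResidueKey]:
        return {b: a for a, b in self.pairs}

    @classmethod
    def from_models(
        cls,
        model_a: StructureModel,
        model_b: StructureModel,
        chain_pairs: Optional[Sequence[tuple[str, str]]] = None,
    ) -> "ResidueMap":
        """Align chains of two models and collect matched residue pairs.

        Chains are paired by shared id where possible, otherwise by order.
        Only match/mismatch alignment columns enter the map.
        """
        if chain_pairs is None:
            b_ids = set(model_b.chain_ids())
            if all(c in b_ids for c in model_a.chain_ids()):
                chain_pairs = [(c, c) for c in model_a.chain_ids()]
            else:
                chain_pairs = list(zip(model_a.chain_ids(), model_b.chain_ids()))
        pairs: list[tuple[ResidueKey, ResidueKey]] = []
        for ca_id, cb_id in chain_pairs:
            chain_a = model_a.chain(ca_id)
            chain_b = model_b.chain(cb_id)
            for ia, ib in align_sequences(chain_a.sequence, chain_b.sequence):
                ra = chain_a.residues[ia]
                rb = chain_b.residues[ib]
                pairs.append(
                    ((ca_id, ra.number, ra.insertion_code), (cb_id, rb.number, rb.insertion_code))
                )
        return cls(pairs=pairs)


def _residue_index(model: StructureModel) -> dict[ResidueKey, "object"]:
    index = {}
    for chain in model.chains:
        for res in chain.residues:
            index[(chain.id, res.number, res.insertion_code)] = res
    return index


def mapped_rmsd(
    a: StructureModel,
    b: StructureModel,
    rmap: ResidueMap,
    atom_selection: str = "CA",
) -> float:
    """RMSD between two models over mapped residues after superposition.

    ``atom_selection`` is ``"CA"`` (default), ``"backbone"`` (N, CA, C, O)
    or ``"all"`` (all shared heavy atoms).  The fit and the reported RMSD
    use the same selection.
    """
    if len(rmap) == 0:
        raise ValueError("empty residue map")
    idx_a, idx_b = _residue_index(a), _residue_index(b)
    coords_a, coords_b = [], []
    for key_a, key_b in rmap.pairs:
        res_a, res_b = idx_a.get(key_a), idx_b.get(key_b)
        if res_a is None or res_b is None:
            continue
        if atom_selection == "CA":
            names: Iterable[str] = ("CA",)
        elif atom_selection == "backbone":
            names = ("N", "CA", "C", "O")
        elif atom_selection == "all":
            names = sorted(
                {at.name for at in res_a.heavy_atoms()} & {at.name for at in res_b.heavy_atoms()}
            )
        else:
            raise ValueError(f"unknown atom selection {atom_selection!r}")
        for name in names:
            at_a, at_b = res_a.get_atom(name), res_b.get_atom(name)
            if at_a is not None and at_b is not None and not at_a.is_hydrogen:
                coords_a.append(at_a.coords)
                coords_b.append(at_b.coords)
    if len(coords_a) < 3:
        raise ValueError(
            f"only {len(coords_a)} mapped atom(s) with selection {atom_selection!r}; "
            "at least 3 required for superposition"
        )
    sup = kabsch_superpose(np.array(coords_a), np.array(coords_b))
    return sup.fit_rmsd


# ---------------------------------------------------------------------------
# Interface definition and contacts
# ---------------------------------------------------------------------------

@dataclass
class InterfaceDefinition:
    antibody_side: set[ResidueKey]
    antigen_side: set[ResidueKey]
    cutoff: float

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.antibody_side & self.antigen_side:
            raise ValueError("interface sides must be disjoint")


@dataclass
class ContactSet:
    pairs: set[tuple[ResidueKey, ResidueKey]]
    cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)


def _side_atoms(
    model: StructureModel, chain_ids: Sequence[str]
) -> tuple[np.ndarray, list[ResidueKey]]:
    coords, keys = [], []
    for cid in chain_ids:
        chain = model.chain(cid)
        for res in chain.residues:
            key = (cid, res.number, res.insertion_code)
            for atom in res.heavy_atoms():
                coords.append(atom.coords)
                keys.append(key)
    return (np.array(coords) if coords else np.empty((0, 3))), keys


def _cross_pairs(
    ab_coords: np.ndarray,
    ab_keys: list[ResidueKey],
    ag_coords: np.ndarray,
    ag_keys: list[ResidueKey],
    cutoff: float,
) -> set[tuple[ResidueKey, ResidueKey]]:
    tree_ab = cKDTree(ab_coords)
    tree_ag = cKDTree(ag_coords)
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    for i, neighbours in enumerate(tree_ab.query_ball_tree(tree_ag, r=cutoff)):
        for j in neighbours:
            pairs.add((ab_keys[i], ag_keys[j]))
    return pairs


def interface_residues(case: ComplexCase, cutoff: float = INTERFACE_CUTOFF) -> InterfaceDefinition:
    """Residues with any heavy atom within ``cutoff`` of the other side.

    Computed on the bound complex; the default 10 A cutoff defines the
    interface used for I-RMSD.
    """
    ab_coords, ab_keys = _side_atoms(case.bound, case.antibody_chain_ids)
    ag_coords, ag_keys = _side_atoms(case.bound, case.antigen_chain_ids)
    if ab_coords.shape[0] == 0 or ag_coords.shape[0] == 0:
        raise ValueError(f"case {case.case_id!r}: a side has no heavy atoms")
    pairs = _cross_pairs(ab_coords, ab_keys, ag_coords, ag_keys, cutoff)
    return InterfaceDefinition(
        antibody_side={p[0] for p in pairs},
        antigen_side={p[1] for p in pairs},
        cutoff=cutoff,
    )


def contacts(case: ComplexCase, cutoff: float = CONTACT_CUTOFF) -> ContactSet:
    """Residue-residue contacts across the interface (5 A default)."""
    ab_coords, ab_keys = _side_atoms(case.bound, case.antibody_chain_ids)
    ag_coords, ag_keys = _side_atoms(case.bound, case.antigen_chain_ids)
    if ab_coords.shape[0] == 0 or ag_coords.shape[0] == 0:
        raise ValueError(f"case {case.case_id!r}: a side has no heavy atoms")
    return ContactSet(
        pairs=_cross_pairs(ab_coords, ab_keys, ag_coords, ag_keys, cutoff), cutoff=cutoff
    )


# ---------------------------------------------------------------------------
# I-RMSD and f_non-nat
# ---------------------------------------------------------------------------

def _default_maps(case: ComplexCase) -> tuple[ResidueMap, ResidueMap]:
    if not case.unbound_antibody or not case.unbound_antigen:
        raise ValueError(f"case {case.case_id!r}: both unbound components required")
    ab_map = ResidueMap.from_models(case.antibody_model(), case.unbound_antibody[0])
    ag_map = ResidueMap.from_models(case.antigen_model(), case.unbound_antigen[0])
    return ab_map, ag_map


def _interface_ca_fit(
    case: ComplexCase,
    side: str,
    iface: InterfaceDefinition,
    rmap: ResidueMap,
    unbound: StructureModel,
) -> tuple[Superposition, np.ndarray, np.ndarray]:
    """Fit the unbound component onto the bound one over interface Calpha."""
    side_keys = iface.antibody_side if side == "antibody" else iface.antigen_side
    bound_idx = _residue_index(case.bound)
    unbound_idx = _residue_index(unbound)
    fwd = rmap.a_to_b()
    bound_coords, unbound_coords = [], []
    for key in sorted(side_keys):
        if key not in fwd:
            continue
        res_b = bound_idx.get(key)
        res_u = unbound_idx.get(fwd[key])
        if res_b is None or res_u is None:
            continue
        ca_b, ca_u = res_b.ca, res_u.ca
        if ca_b is None or ca_u is None:
            continue
        bound_coords.append(ca_b.coords)
        unbound_coords.append(ca_u.coords)
    if len(bound_coords) < 3:
        raise ValueError(
            f"case {case.case_id!r}: only {len(bound_coords)} interface Calpha mapped "
            f"on the {side} side; cannot superpose"
        )
    bound_arr = np.array(bound_coords)
    unbound_arr = np.array(unbound_coords)
    sup = kabsch_superpose(bound_arr, unbound_arr)
    return sup, bound_arr, unbound_arr


def i_rmsd(
    case: ComplexCase,
    side: str = "combined",
    cutoff: float = INTERFACE_CUTOFF,
    ab_map: Optional[ResidueMap] = None,
    ag_map: Optional[ResidueMap] = None,
) -> float:
    """Interface Calpha RMSD between bound and (primary) unbound structures.

    ``side`` selects the antibody interface, the antigen interface, or the
    entire interface (``"combined"``): each component is fitted on its own
    interface Calpha set and the squared deviations are pooled over both
    sides in the bound frame.
    """
    if side not in ("antibody", "antigen", "combined"):
        raise ValueError(f"unknown side {side!r}")
    if ab_map is None or ag_map is None:
        auto_ab, auto_ag = _default_maps(case)
        ab_map = ab_map or auto_ab
        ag_map = ag_map or auto_ag
    iface = interface_residues(case, cutoff)

    sides = ["antibody", "antigen"] if side == "combined" else [side]
    sq_sum, n = 0.0, 0
    for s in sides:
        rmap = ab_map if s == "antibody" else ag_map
        unbound = case.unbound_antibody[0] if s == "antibody" else case.unbound_antigen[0]
        sup, bound_arr, unbound_arr = _interface_ca_fit(case, s, iface, rmap, unbound)
        fitted = sup.apply(unbound_arr)
        sq_sum += float(np.sum((fitted - bound_arr) ** 2))
        n += bound_arr.shape[0]
    return float(np.sqrt(sq_sum / n))


def f_non_nat(
    case: ComplexCase,
    contact_cutoff: float = CONTACT_CUTOFF,
    interface_cutoff: float = INTERFACE_CUTOFF,
    ab_map: Optional[ResidueMap] = None,
    ag_map: Optional[ResidueMap] = None,
) -> float:
    """Fraction of non-native contacts of the superposed unbound pair.

    Each unbound component is placed in the bound frame by its interface
    Calpha fit; contacts of the resulting model pair at ``contact_cutoff``
    are compared (via the residue maps) with the bound contact set.  The
    returned value is |model contacts not native| / |model contacts|.  An
    unbound pair forming no contact at all returns 1.0 by convention (with
    a warning): everything it would need is non-native.
    """
    native = contacts(case, contact_cutoff)
    if len(native) == 0:
        raise ValueError(f"case {case.case_id!r}: bound complex has no contacts (no interface)")
    if ab_map is None or ag_map is None:
        auto_ab, auto_ag = _default_maps(case)
        ab_map = ab_map or auto_ab
        ag_map = ag_map or auto_ag
    iface = interface_residues(case, interface_cutoff)

    placed: dict[str, tuple[np.ndarray, list[ResidueKey]]] = {}
    for s, rmap, unbound in (
        ("antibody", ab_map, case.unbound_antibody[0]),
        ("antigen", ag_map, case.unbound_antigen[0]),
    ):
        sup, _, _ = _interface_ca_fit(case, s, iface, rmap, unbound)
        coords, keys = _side_atoms(unbound, unbound.chain_ids())
        back = rmap.b_to_a()
        # express model residues in bound numbering where mapped; unmapped
        # residues keep a sentinel key and can only produce non-native contacts
        keys = [back.get(k, ("*unmapped*", k[1], k[2])) for k in keys]
        placed[s] = (sup.apply(coords), keys)

    ab_coords, ab_keys = placed["antibody"]
    ag_coords, ag_keys = placed["antigen"]
    model_pairs = _cross_pairs(ab_coords, ab_keys, ag_coords, ag_keys, contact_cutoff)
    if not model_pairs:
        warnings.warn(
            f"case {case.case_id!r}: superposed unbound pair forms no contacts; "
            "f_non_nat reported as 1.0 by convention",
            stacklevel=2,
        )
        return 1.0
    non_native = sum(1 for p in model_pairs if p not in native.pairs)
    return non_native / len(model_pairs)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

def sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[dict[ResidueKey, float], float]:
    """Shrake-Rupley solvent-accessible surface area, per residue and total.

    Heavy atoms only; element-based van der Waals radii.  ``n_points`` is
    the number of sphere sample points per atom; the default gives
    sub-percent convergence on protein-sized inputs.
    """
    import biotite.structure as struc
    from biotite.structure.info import vdw_radius_single

    records = []
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.heavy_atoms():
                radius = None
                try:
                    radius = vdw_radius_single(atom.element)
                except Exception:
                    radius = None
                if radius is None:
                    raise ValueError(
                        f"no van der Waals radius for element {atom.element!r} "
                        f"(atom {atom.name!r} in {chain.id}/{res.number})"
                    )
                records.append((chain.id, res, atom))
    if not records:
        raise ValueError(f"structure {model.id!r}: no heavy atoms")

    arr = struc.AtomArray(len(records))
    arr.coord = np.array([a.coords for _, _, a in records])
    arr.chain_id = np.array([c for c, _, _ in records])
    arr.res_id = np.array([r.number for _, r, _ in records])
    arr.ins_code = np.array([r.insertion_code for _, r, _ in records])
    arr.res_name = np.array([r.name for _, r, _ in records])
    arr.atom_name = np.array([a.name for _, _, a in records])
    arr.element = np.array([a.element for _, _, a in records])
    arr.hetero = np.zeros(len(records), dtype=bool)

    values = struc.sasa(arr, probe_radius=probe, point_number=n_points, vdw_radii="Single")
    per_residue: dict[ResidueKey, float] = {}
    for (cid, res, _), v in zip(records, values):
        if np.isnan(v):
            v = 0.0
        key = (cid, res.number, res.insertion_code)
        per_residue[key] = per_residue.get(key, 0.0) + float(v)
    total = float(np.nansum(values))
    return per_residue, total


def delta_asa(case: ComplexCase, probe: float = 1.4, n_points: int = 960) -> float:
    """Surface area buried on binding, components in bound conformation."""
    _, area_ab = sasa(case.antibody_model(), probe, n_points)
    _, area_ag = sasa(case.antigen_model(), probe, n_points)
    _, area_complex = sasa(case.bound, probe, n_points)
    return area_ab + area_ag - area_complex


# ---------------------------------------------------------------------------
# CDR RMSD and framework blocks
# ---------------------------------------------------------------------------

@dataclass
class CDRAnnotation:
    """Chothia-style CDR boundaries per antibody chain.

    ``ranges`` maps chain id -> {"CDR1": (start, end), ...} with inclusive
    residue-number ranges.  The numbering is an input produced by an
    external numbering tool (or by the fixture generator); it is never
    inferred here.  CDR3 must be present for every annotated chain.
    """

    ranges: dict[str, dict[str, tuple[int, int]]]

    def __post_init__(self) -> None:
        for chain_id, cdrs in self.ranges.items():
            if "CDR3" not in cdrs:
                raise ValueError(f"chain {chain_id!r}: CDR3 annotation missing")
            for name, (start, end) in cdrs.items():
                if end < start:
                    raise ValueError(f"chain {chain_id!r} {name}: empty range {start}-{end}")

    def in_any_cdr(self, chain_id: str, number: int) -> bool:
        for start, end in self.ranges.get(chain_id, {}).values():
            if start <= number <= end:
                return True
        return False


def cdr_rmsd(
    case: ComplexCase,
    annotation: CDRAnnotation,
    ab_map: Optional[ResidueMap] = None,
) -> dict[str, Optional[float]]:
    """Per-CDR Calpha RMSD after framework superposition.

    The unbound antibody is fitted onto the bound one over the framework
    (non-CDR) Calpha atoms of the annotated chains; each CDR's RMSD is then
    measured in that frame without refitting.  A CDR whose residues cannot
    be resolved in the unbound structure is reported as None; the others
    are still computed.  Keys are ``"<chain>.<CDR>"``.
    """
    if not case.unbound_antibody:
        raise ValueError(f"case {case.case_id!r}: no unbound antibody")
    bound_ab = case.antibody_model()
    unbound = case.unbound_antibody[0]
    if ab_map is None:
        ab_map = ResidueMap.from_models(bound_ab, unbound)
    bound_idx = _residue_index(case.bound)
    unbound_idx = _residue_index(unbound)
    fwd = ab_map.a_to_b()

    def ca_pair(key: ResidueKey):
        if key not in fwd:
            return None
        rb, ru = bound_idx.get(key), unbound_idx.get(fwd[key])
        if rb is None or ru is None or rb.ca is None or ru.ca is None:
            return None
        return rb.ca.coords, ru.ca.coords

    framework_b, framework_u = [], []
    for cid in annotation.ranges:
        chain = bound_ab.chain(cid)
        for res in chain.residues:
            if annotation.in_any_cdr(cid, res.number):
                continue
            pair = ca_pair((cid, res.number, res.insertion_code))
            if pair is not None:
                framework_b.append(pair[0])
                framework_u.append(pair[1])
    if len(framework_b) < 3:
        raise ValueError(f"case {case.case_id!r}: fewer than 3 framework Calpha mapped")
    sup = kabsch_superpose(np.array(framework_b), np.array(framework_u))

    out: dict[str, Optional[float]] = {}
    for cid, cdrs in annotation.ranges.items():
        chain = bound_ab.chain(cid)
        for name, (start, end) in sorted(cdrs.items()):
            cb, cu = [], []
            for res in chain.residues:
                if start <= res.number <= end:
                    pair = ca_pair((cid, res.number, res.insertion_code))
                    if pair is not None:
                        cb.append(pair[0])
                        cu.append(pair[1])
            label = f"{cid}.{name}"
            if not cb:
                out[label] = None
                continue
            out[label] = _rmsd(np.array(cb), sup.apply(np.array(cu)))
    return out


def framework_block_ranges(role) -> list[tuple[int, Optional[int]]]:
    """Chothia-numbered framework ranges blocked during antibody docking.

    Heavy chain: 6-22, 39-46, 81-91, 106-end.
    Light chain: 7-20, 38-44, 76-85, 101-end.
    Defined for antibody chains only; any other role is an error.
    """
    name = role.value if isinstance(role, ChainRole) else str(role)
    if name not in _BLOCK_RANGES:
        raise ValueError(f"framework block ranges defined for heavy/light chains only, not {name!r}")
    return list(_BLOCK_RANGES[name])


# ---------------------------------------------------------------------------
# Aggregate per-case metrics
# ---------------------------------------------------------------------------

@dataclass
class InterfaceMetrics:
    rmsd_ab: float
    rmsd_ag: float
    i_rmsd_ab: float
    i_rmsd_ag: float
    i_rmsd_combined: float
    f_non_nat: float
    delta_asa: Optional[float] = None
    cdr_rmsd: dict[str, Optional[float]] = field(default_factory=dict)


def compute_case_metrics(
    case: ComplexCase,
    annotation: Optional[CDRAnnotation] = None,
    interface_cutoff: float = INTERFACE_CUTOFF,
    contact_cutoff: float = CONTACT_CUTOFF,
    with_delta_asa: bool = True,
    sasa_points: int = 960,
) -> InterfaceMetrics:
    """All conformational-change metrics for the primary unbound pair."""
    ab_map, ag_map = _default_maps(case)
    metrics = InterfaceMetrics(
        rmsd_ab=mapped_rmsd(case.antibody_model(), case.unbound_antibody[0], ab_map),
        rmsd_ag=mapped_rmsd(case.antigen_model(), case.unbound_antigen[0], ag_map),
        i_rmsd_ab=i_rmsd(case, "antibody", interface_cutoff, ab_map, ag_map),
        i_rmsd_ag=i_rmsd(case, "antigen", interface_cutoff, ab_map, ag_map),
        i_rmsd_combined=i_rmsd(case, "combined", interface_cutoff, ab_map, ag_map),
        f_non_nat=f_non_nat(case, contact_cutoff, interface_cutoff, ab_map, ag_map),
    )
    if with_delta_asa:
        metrics.delta_asa = delta_asa(case, n_points=sasa_points)
    if annotation is not None:
        metrics.cdr_rmsd = cdr_rmsd(case, annotation, ab_map)
    case.metrics = metrics
    return metrics
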