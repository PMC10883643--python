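"""Synthetic antibody-antigen fixtures with controlled conformational change.

Real benchmark cases come from crystal structures; these generators build
small poly-alanine complexes with the same shape of data (bound complex,
unbound components, CDR annotation) and — crucially — *known* expected
metrics, so every pipeline stage can be verified against its construction
parameters.

Geometry: each chain is an idealized alpha-helix (1.5 A rise, 2.3 A radius,
100 deg/residue) decorated with N, C, O, CB atoms at fixed local offsets.
The antigen helix runs parallel to the antibody helix at a controlled
approach distance, so a genuine 5 A contact interface exists.

Perturbations applied to the unbound copies:

- ``none`` — unbound equals bound up to a global rigid motion (which every
  metric must ignore): all RMSD-family metrics are exactly 0.
- ``rigid_shift`` — each interface residue is displaced by exactly
  ``magnitude`` Angstrom along the inter-chain axis, with per-residue signs
  scaled so the displacement field has zero net translation and zero
  cross-covariance with the interface coordinates.  This makes the identity
  superposition *exactly* optimal, hence the post-fit I-RMSD equals
  ``magnitude`` analytically.  (A literal rigid translation would be
  absorbed by the superposition and read as 0.)
- ``hinge_rotation`` — the distal half of the antibody chain rotates about
  a hinge residue by ``magnitude`` degrees: large overall RMSD, interface
  mostly intact.
- ``cdr_displacement`` — the CDR3 residues translate rigidly by
  ``magnitude`` Angstrom: after framework superposition the CDR3 RMSD
  equals ``magnitude`` exactly, CDR1/CDR2 stay at 0.

Redundancy families reuse the same orthogonal-displacement construction at
whole-complex scale, so pairwise structural RMSDs are known in closed form,
and mutate sequences at a controlled rate to steer the identity criterion.
BLAST is never run: the emitted E-values are synthetic stand-ins
(1e-80 within a family), flagged as such.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .homology import AlignmentHit
from .metrics import CDRAnnotation, interface_residues
from .redundancy import RedundancyVerdict, complex_redundant, sequence_redundant
from .structure import (
    AtomRecord,
    Chain,
    ChainRole,
    ComplexCase,
    PairingState,
    Residue,
    StructureModel,
    align_sequences,
)

__all__ = [
    "FixtureSpec",
    "ToyFixture",
    "FamilyFixture",
    "generate_toy_case",
    "generate_redundant_family",
    "pairwise_identity",
]

_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TWIST = np.deg2rad(100.0)
_CLASH_DISTANCE = 1.2

#: CDR ranges (residue numbers) used for generated antibody chains
_TOY_CDRS = {"CDR1": (10, 14), "CDR2": (25, 29), "CDR3": (40, 47)}

_STANDARD_AA = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]


@dataclass
class FixtureSpec:
    """Construction parameters for a synthetic complex.

    ``approach`` is the surface-to-surface gap between the two helices in
    Angstrom (default 4.5, inside the 5 A contact threshold).
    ``perturbation`` is one of none / rigid_shift / hinge_rotation /
    cdr_displacement with ``magnitude`` in Angstrom (degrees for the
    hinge).  ``seed`` fixes all randomness; identical specs produce
    byte-identical structure files.
    """

    n_antibody: int = 60
    n_antigen: int = 60
    approach: float = 4.5
    perturbation: str = "none"
    magnitude: float = 0.0
    perturb_side: str = "both"  # antibody | antigen | both (rigid_shift only)
    n_copies: int = 2
    mutation_rate: float = 0.0
    conformational_rms: Sequence[float] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if self.perturbation not in ("none", "rigid_shift", "hinge_rotation", "cdr_displacement"):
            raise ValueError(f"unknown perturbation {self.perturbation!r}")
        if self.perturb_side not in ("antibody", "antigen", "both"):
            raise ValueError(f"unknown perturb_side {self.perturb_side!r}")


@dataclass
class ToyFixture:
    case: ComplexCase
    annotation: CDRAnnotation
    expected: dict


@dataclass
class FamilyFixture:
    cases: list[ComplexCase]
    hits: list[AlignmentHit]
    verdicts: list[RedundancyVerdict]
    expected_graph: nx.Graph


# ---------------------------------------------------------------------------
# Chain construction
# ---------------------------------------------------------------------------

def _helix_chain(
    chain_id: str,
    n_res: int,
    origin: np.ndarray,
    role: ChainRole,
    residue_names: Optional[Sequence[str]] = None,
    phase: float = 0.0,
) -> Chain:
    chain = Chain(id=chain_id, role=role)
    for i in range(n_res):
        angle = phase + i * _HELIX_TWIST
        radial = np.array([np.cos(angle), np.sin(angle), 0.0])
        tangent = np.array([-np.sin(angle), np.cos(angle), 0.0])
        axis = np.array([0.0, 0.0, 1.0])
        ca = origin + _HELIX_RADIUS * radial + np.array([0.0, 0.0, i * _HELIX_RISE])
        name = residue_names[i] if residue_names is not None else "ALA"
        atoms = [
            AtomRecord("N", "N", ca - 0.9 * tangent - 0.9 * axis),
            AtomRecord("CA", "C", ca),
            AtomRecord("C", "C", ca + 0.9 * tangent + 0.7 * axis),
            AtomRecord("O", "O", ca + 1.2 * tangent + 1.6 * axis),
            AtomRecord("CB", "C", ca + 0.8 * radial + 0.9 * axis),
        ]
        chain.residues.append(
            Residue(name=name, number=i + 1, insertion_code="", atoms=atoms)
        )
    return chain


def _build_bound(spec: FixtureSpec, case_id: str, antibody_names=None, antigen_names=None) -> ComplexCase:
    ab_origin = np.zeros(3)
    # antigen helix axis offset along +x so the surface gap equals `approach`;
    # phases point the first CA of each helix toward the partner
    axis_sep = 2 * _HELIX_RADIUS + spec.approach
    ag_origin = np.array([axis_sep, 0.0, 0.0])
    ab = _helix_chain("H", spec.n_antibody, ab_origin, ChainRole.SINGLE_DOMAIN,
                      antibody_names, phase=0.0)
    ag = _helix_chain("A", spec.n_antigen, ag_origin, ChainRole.ANTIGEN,
                      antigen_names, phase=np.pi)
    bound = StructureModel(id=case_id, chains=[ab, ag])
    case = ComplexCase(
        case_id=case_id,
        bound=bound,
        antibody_chain_ids=["H"],
        antigen_chain_ids=["A"],
    )
    ab_xyz = np.array([a.coords for r in ab.residues for a in r.atoms])
    ag_xyz = np.array([a.coords for r in ag.residues for a in r.atoms])
    dmin = np.min(np.linalg.norm(ab_xyz[:, None, :] - ag_xyz[None, :, :], axis=-1))
    if dmin < _CLASH_DISTANCE:
        raise ValueError(
            f"impossible geometry: chains overlap (closest approach {dmin:.2f} A); "
            "increase the approach distance"
        )
    return case


# ---------------------------------------------------------------------------
# Displacement fields orthogonal to rigid-body modes
# ---------------------------------------------------------------------------

def _orthogonal_signs(coords: np.ndarray) -> np.ndarray:
    """Per-point scalars with unit RMS, zero sum and zero coordinate
    cross-covariance.

    For displacements ``delta_i = c_i * u`` with these constraints the
    Kabsch cross-covariance matrix of (original, displaced) coordinates
    stays symmetric positive-definite, so the identity transform is the
    exact optimal superposition and the post-fit RMSD is RMS(c) exactly.
    """
    n = coords.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 points to build the displacement field, got {n}")
    # constraints: sum(c)=0 and sum(c * centered coords)=0 (3 components)
    centered = coords - coords.mean(axis=0)
    constraints = np.vstack([np.ones(n), centered.T])  # (4, n)
    w = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n)])
    # project onto the null space of the constraints
    sol, *_ = np.linalg.lstsq(constraints.T, w, rcond=None)
    w = w - constraints.T @ sol
    rms = np.sqrt(np.mean(w**2))
    if rms < 1e-9:
        raise ValueError("degenerate geometry: no displacement field available")
    return w / rms


def _displace_interface(
    model: StructureModel,
    chain_ids: Sequence[str],
    interface_keys: set,
    magnitude: float,
    direction: np.ndarray,
) -> None:
    """Shift every interface residue of the named chains by a per-residue
    signed multiple of ``direction`` so the field RMS equals ``magnitude``
    and no rigid motion can absorb it (see _orthogonal_signs)."""
    targets = []
    for cid in chain_ids:
        for res in model.chain(cid).residues:
            if (cid, res.number, res.insertion_code) in interface_keys:
                targets.append(res)
    ca_coords = np.array([r.ca.coords for r in targets])
    signs = _orthogonal_signs(ca_coords)
    u = direction / np.linalg.norm(direction)
    for res, c in zip(targets, signs):
        shift = magnitude * c * u
        for atom in res.atoms:
            atom.coords = atom.coords + shift


def _apply_global_motion(model: StructureModel, rng: np.random.Generator) -> None:
    """Random proper rotation + translation; metrics must be invariant."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.uniform(-20, 20, size=3)
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.coords = rot @ atom.coords + trans


# ---------------------------------------------------------------------------
# Toy cases
# ---------------------------------------------------------------------------

def generate_toy_case(spec: FixtureSpec, case_id: str = "toy") -> ToyFixture:
    """Bound complex plus perturbed unbound components with known metrics.

    The returned fixture carries the CDR annotation for the antibody chain
    and an ``expected`` dict holding the metric values implied by the
    construction (exact for rigid_shift and cdr_displacement).
    """
    rng = np.random.default_rng(spec.seed)
    case = _build_bound(spec, case_id)

    unbound_ab = case.antibody_model()
    unbound_ab.id = f"{case_id}_ab_unbound"
    unbound_ag = case.antigen_model()
    unbound_ag.id = f"{case_id}_ag_unbound"

    expected: dict = {
        "perturbation": spec.perturbation,
        "magnitude": spec.magnitude,
        "i_rmsd_antibody": 0.0,
        "i_rmsd_antigen": 0.0,
        "i_rmsd_combined": 0.0,
        "f_non_nat": 0.0 if spec.perturbation in ("none", "cdr_displacement") else None,
        "cdr_rmsd": {"H.CDR1": 0.0, "H.CDR2": 0.0, "H.CDR3": 0.0},
    }

    if spec.perturbation == "rigid_shift" and spec.magnitude > 0:
        iface = interface_residues(case)
        direction = np.array([1.0, 0.0, 0.0])  # inter-chain axis
        if spec.perturb_side in ("antibody", "both"):
            _displace_interface(unbound_ab, ["H"], iface.antibody_side, spec.magnitude, direction)
            expected["i_rmsd_antibody"] = spec.magnitude
        if spec.perturb_side in ("antigen", "both"):
            _displace_interface(unbound_ag, ["A"], iface.antigen_side, spec.magnitude, direction)
            expected["i_rmsd_antigen"] = spec.magnitude
        if spec.perturb_side == "both":
            expected["i_rmsd_combined"] = spec.magnitude
        else:
            n_ab = len(iface.antibody_side)
            n_ag = len(iface.antigen_side)
            n_hit = n_ab if spec.perturb_side == "antibody" else n_ag
            expected["i_rmsd_combined"] = spec.magnitude * np.sqrt(n_hit / (n_ab + n_ag))
        expected["cdr_rmsd"] = None  # CDRs overlap the interface; not controlled
    elif spec.perturbation == "hinge_rotation" and spec.magnitude > 0:
        chain = unbound_ab.chain("H")
        hinge_idx = len(chain.residues) // 2
        hinge = chain.residues[hinge_idx].ca.coords.copy()
        theta = np.deg2rad(spec.magnitude)
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        for res in chain.residues[hinge_idx:]:
            for atom in res.atoms:
                atom.coords = rot @ (atom.coords - hinge) + hinge
        expected["i_rmsd_antibody"] = None  # depends on how much interface moved
        expected["i_rmsd_combined"] = None
        expected["f_non_nat"] = None
        expected["cdr_rmsd"] = None
    elif spec.perturbation == "cdr_displacement" and spec.magnitude > 0:
        start, end = _TOY_CDRS["CDR3"]
        shift = spec.magnitude * np.array([1.0, 0.0, 0.0])
        for res in unbound_ab.chain("H").residues:
            if start <= res.number <= end:
                for atom in res.atoms:
                    atom.coords = atom.coords + shift
        expected["cdr_rmsd"] = {"H.CDR1": 0.0, "H.CDR2": 0.0, "H.CDR3": spec.magnitude}
        expected["i_rmsd_antibody"] = None  # CDR3 may intersect the interface
        expected["i_rmsd_combined"] = None
        expected["f_non_nat"] = None

    _apply_global_motion(unbound_ab, rng)
    _apply_global_motion(unbound_ag, rng)

    case.unbound_antibody = [unbound_ab]
    case.unbound_antigen = [unbound_ag]
    case.pairing_state = PairingState.UU

    annotation = CDRAnnotation(ranges={"H": dict(_TOY_CDRS)})
    return ToyFixture(case=case, annotation=annotation, expected=expected)


# ---------------------------------------------------------------------------
# Redundancy families
# ---------------------------------------------------------------------------

def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical residues over aligned (non-gap) columns."""
    pairs = align_sequences(seq_a, seq_b)
    if not pairs:
        return 0.0
    matches = sum(1 for i, j in pairs if seq_a[i] == seq_b[j])
    return matches / len(pairs)


def generate_redundant_family(spec: FixtureSpec, family_id: str = "fam") -> FamilyFixture:
    """A family of complexes with controlled pairwise redundancy.

    Copy ``k`` mutates the base sequences at ``mutation_rate`` and carries
    a conformational displacement of RMS ``conformational_rms[k]`` (0 for
    the base) built from the same rigid-mode-orthogonal field scaled per
    copy, so the pairwise whole-complex Calpha RMSD between copies i and j
    is exactly ``|rms_i - rms_j|``.

    The emitted hits carry *synthetic* E-values (1e-80 within the family)
    because no sequence search is run; identities are computed from the
    actual mutated sequences.  Expected verdicts and the expected
    redundancy graph follow from these construction parameters.
    """
    if spec.n_copies < 2:
        raise ValueError("a family needs at least 2 copies")
    rng = np.random.default_rng(spec.seed)
    rms = list(spec.conformational_rms) or [0.0] * spec.n_copies
    if len(rms) != spec.n_copies:
        raise ValueError("conformational_rms must have one entry per copy")

    base = _build_bound(spec, f"{family_id}_0")
    base_names = {
        cid: [r.name for r in base.bound.chain(cid).residues] for cid in ("H", "A")
    }

    # one shared displacement direction/field so pairwise RMSDs are exact
    all_ca = np.array(
        [r.ca.coords for c in base.bound.chains for r in c.residues]
    )
    signs = _orthogonal_signs(all_ca)
    u = np.array([0.0, 1.0, 0.0])

    cases: list[ComplexCase] = []
    for k in range(spec.n_copies):
        names = {}
        for cid, base_seq in base_names.items():
            seq = list(base_seq)
            if k > 0 and spec.mutation_rate > 0:
                n_mut = int(round(spec.mutation_rate * len(seq)))
                positions = rng.choice(len(seq), size=n_mut, replace=False)
                for p in positions:
                    choices = [a for a in _STANDARD_AA if a != seq[p]]
                    seq[p] = choices[rng.integers(len(choices))]
            names[cid] = seq
        member = _build_bound(spec, f"{family_id}_{k}", names["H"], names["A"])
        if rms[k] > 0:
            i = 0
            for chain in member.bound.chains:
                for res in chain.residues:
                    shift = rms[k] * signs[i] * u
                    for atom in res.atoms:
                        atom.coords = atom.coords + shift
                    i += 1
        cases.append(member)

    hits: list[AlignmentHit] = []
    verdicts: list[RedundancyVerdict] = []
    g = nx.Graph()
    g.add_nodes_from(c.case_id for c in cases)
    for i in range(len(cases)):
        for j in range(i + 1, len(cases)):
            flags = []
            for cid in ("H", "A"):
                ident = pairwise_identity(
                    cases[i].bound.chain(cid).sequence, cases[j].bound.chain(cid).sequence
                )
                hit = AlignmentHit(
                    query_id=f"{cases[i].case_id}:{cid}",
                    subject_id=f"{cases[j].case_id}:{cid}",
                    identity=ident,
                    coverage=1.0,
                    e_value=1e-80,  # synthetic: no sequence search is run
                )
                hits.append(hit)
                flags.append(sequence_redundant(hit))
            expected_rmsd = abs(rms[i] - rms[j])
            seq_ok = all(flags)
            redundant = complex_redundant(flags, expected_rmsd) if seq_ok else False
            verdicts.append(
                RedundancyVerdict(
                    pair=(cases[i].case_id, cases[j].case_id),
                    sequence_redundant=seq_ok,
                    rmsd=expected_rmsd if seq_ok else None,
                    redundant=redundant,
                )
            )
            if redundant:
                g.add_edge(cases[i].case_id, cases[j].case_id)

    return FamilyFixture(cases=cases, hits=hits, verdicts=verdicts, expected_graph=g)
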