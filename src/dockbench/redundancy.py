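"""Pairwise redundancy verdicts, the redundancy graph, and its pruning.

Two complexes are redundant when every corresponding chain type passes the
sequence criteria (identity > 60%, E-value < 1e-30, both strict) AND the
whole-complex Calpha RMSD after least-squares superposition is below 5 A.
High sequence identity alone is not enough: near-identical sequences can
adopt markedly different quaternary arrangements, so the structural check
is mandatory whenever the sequence check passes.

Redundant pairs become edges of an undirected graph over case ids.  The
graph is made edge-free by iteratively deleting a node of maximum degree
(the greedy heuristic of the benchmark-curation pipeline); survivors form
an independent set of the original graph.  Incremental updates compare new
cases against the stored, already edge-free set and re-prune only the
affected connected components.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .homology import AlignmentHit

__all__ = [
    "RedundancyVerdict",
    "sequence_redundant",
    "complex_redundant",
    "build_graph",
    "prune_max_degree",
    "update_benchmark",
    "UpdateResult",
    "write_verdicts_csv",
    "write_removal_log",
]

SEQ_IDENTITY_MIN = 0.60
SEQ_EVALUE_MAX = 1e-30
RMSD_MAX = 5.0


@dataclass(frozen=True)
class RedundancyVerdict:
    """Outcome of comparing two complexes.

    ``rmsd`` may be missing when the sequence check already failed (the
    structural comparison is then unnecessary); a redundant verdict always
    implies both checks passed.
    """

    pair: tuple[str, str]
    sequence_redundant: bool
    rmsd: Optional[float]
    redundant: bool

    def __post_init__(self) -> None:
        if self.redundant:
            if not self.sequence_redundant:
                raise ValueError(f"{self.pair}: redundant requires sequence redundancy")
            if self.rmsd is None or not self.rmsd < RMSD_MAX:
                raise ValueError(f"{self.pair}: redundant requires RMSD < {RMSD_MAX} A")


def sequence_redundant(
    best_hit: AlignmentHit,
    identity_min: float = SEQ_IDENTITY_MIN,
    evalue_max: float = SEQ_EVALUE_MAX,
) -> bool:
    """True iff identity > 60% and E-value < 1e-30, both strict."""
    return best_hit.identity > identity_min and best_hit.e_value < evalue_max


def complex_redundant(
    seq_flags: Iterable[bool],
    rmsd: Optional[float],
    rmsd_max: float = RMSD_MAX,
) -> bool:
    """Combine per-chain-type sequence flags with the structural check.

    ``seq_flags`` carries one boolean per chain type (heavy, light,
    antigen) of the pair being compared; every one must be true.  When all
    flags pass, the RMSD is required — a missing value is an error because
    the verdict then genuinely depends on the structure comparison.
    """
    flags = list(seq_flags)
    if not flags:
        raise ValueError("no chain-type flags supplied")
    if not all(flags):
        return False
    if rmsd is None:
        raise ValueError("sequence criteria met but no RMSD supplied; structure comparison required")
    return rmsd < rmsd_max


def build_graph(
    verdicts: Iterable[RedundancyVerdict],
    nodes: Iterable[str],
) -> nx.Graph:
    """Undirected graph with an edge per redundant pair.

    Isolated nodes are preserved (they are the already-non-redundant
    cases); duplicate and reversed pairs collapse onto a single edge;
    self-comparisons never create loops.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for v in verdicts:
        a, b = v.pair
        if a == b:
            continue
        if a not in g or b not in g:
            raise KeyError(f"verdict pair {v.pair} not drawn from node set")
        if v.redundant:
            g.add_edge(a, b)
    return g


def prune_max_degree(
    g,
    seed: Optional[int] = None,
) -> tuple[set[str], list[dict]]:
    """Iteratively delete a maximum-degree node until all degrees are 0.

    ``g`` is an undirected graph, given either as a ``networkx.Graph`` or
    as an adjacency mapping ``{node: iterable of neighbours}`` (symmetrized
    automatically).  Ties among maximum-degree nodes are broken
    lexicographically by node id when ``seed`` is None (reproducible
    default), or uniformly at random with the given seed.  Returns the
    surviving node set and an ordered removal log; isolated nodes are never
    removed, so the log is empty on an edgeless graph and the survivors
    always form an independent set of the input graph.
    """
    if isinstance(g, nx.Graph):
        adj = {n: set(g.adj[n]) for n in g.nodes}
    else:
        adj = {n: set(neigh) for n, neigh in g.items()}
        for n in list(adj):
            adj[n].discard(n)
            for m in adj[n]:
                adj.setdefault(m, set()).add(n)
    rng = random.Random(seed) if seed is not None else None
    log: list[dict] = []
    step = 0
    while True:
        max_deg = max((len(neigh) for neigh in adj.values()), default=0)
        if max_deg == 0:
            break
        candidates = [n for n, neigh in adj.items() if len(neigh) == max_deg]
        if rng is not None:
            victim = rng.choice(sorted(candidates, key=str))
        else:
            victim = min(candidates, key=str)
        step += 1
        log.append({"step": step, "removed": victim, "degree": max_deg})
        for m in adj.pop(victim):
            adj[m].discard(victim)
    return set(adj), log


@dataclass
class UpdateResult:
    retained: set[str]
    removal_log: list[dict]
    added: list[str]
    unresolved: list[str]


def update_benchmark(
    stored: Iterable[str],
    new_cases: Iterable[str],
    pair_redundant: Callable[[str, str], bool],
    screen: Optional[Callable[[str], bool]] = None,
    seed: Optional[int] = None,
) -> UpdateResult:
    """Incrementally fold new cases into a stored non-redundant set.

    ``pair_redundant(a, b)`` must return the full redundancy verdict
    (sequence + structure) for a pair; it is called for new-vs-stored and
    new-vs-new pairs only — the stored set is trusted to be edge-free.
    ``screen``, when given, is the unbound-availability filter applied to
    new cases before any comparison.

    A new case similar to nothing establishes its own non-redundant group
    and is added outright.  A new case similar to some cases joins their
    connected component, and max-degree pruning is re-run on that
    component's subgraph only.  A failure inside ``pair_redundant`` flags
    the new case unresolved: it is withheld from the update rather than
    silently added.
    """
    stored_ids = list(dict.fromkeys(stored))
    candidates = [c for c in new_cases if screen is None or screen(c)]

    g = nx.Graph()
    g.add_nodes_from(stored_ids)
    unresolved: list[str] = []
    accepted_new: list[str] = []
    for nc in candidates:
        if nc in g:
            continue  # already stored
        try:
            edges = []
            for other in stored_ids + accepted_new:
                if pair_redundant(nc, other):
                    edges.append(other)
        except Exception:
            unresolved.append(nc)
            continue
        g.add_node(nc)
        g.add_edges_from((nc, o) for o in edges)
        accepted_new.append(nc)

    retained: set[str] = set()
    removal_log: list[dict] = []
    for component in nx.connected_components(g):
        sub = g.subgraph(component)
        if sub.number_of_edges() == 0:
            retained.update(component)
        else:
            kept, log = prune_max_degree(sub, seed=seed)
            retained.update(kept)
            removal_log.extend(log)

    added = [c for c in accepted_new if c in retained and c not in set(stored_ids)]
    return UpdateResult(
        retained=retained, removal_log=removal_log, added=added, unresolved=unresolved
    )


def write_verdicts_csv(verdicts: Sequence[RedundancyVerdict], path: str) -> None:
    rows = [
        {
            "case_a": v.pair[0],
            "case_b": v.pair[1],
            "sequence_redundant": v.sequence_redundant,
            "rmsd": v.rmsd,
            "redundant": v.redundant,
        }
        for v in verdicts
    ]
    pd.DataFrame(
        rows, columns=["case_a", "case_b", "sequence_redundant", "rmsd", "redundant"]
    ).to_csv(path, index=False)


def write_removal_log(log: Sequence[Mapping], path: str) -> None:
    """Removal log as JSON lines, one audit record per deleted node."""
    with open(path, "w") as fh:
        for entry in log:
            fh.write(json.dumps(dict(entry)) + "\n")
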