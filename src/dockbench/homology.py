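"""Screening of sequence-search hits for unbound partner structures.

A bound complex qualifies for the benchmark only if each of its chains has
an experimentally solved unbound counterpart.  Candidates come from a
BLAST-style search of each bound chain against the full sequence database;
a hit is accepted when identity > 93%, query coverage > 80% and
E-value < 1e-5 (all strict).  Per-side availability then places the complex
into one of four pairing states: unbound-unbound (UU), unbound-bound (UB),
bound-unbound (BU) or bound-bound (BB).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

import pandas as pd

from .structure import PairingState

__all__ = [
    "AlignmentHit",
    "UnboundCandidateSet",
    "accept_unbound_hit",
    "collect_unbound_candidates",
    "categorize_case",
    "read_blast_tabular",
    "write_candidates_csv",
]

#: default acceptance thresholds for unbound-structure hits
IDENTITY_MIN = 0.93
COVERAGE_MIN = 0.80
EVALUE_MAX = 1e-5

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One sequence-search result between a bound chain and a candidate.

    ``identity`` and ``coverage`` are fractions in [0, 1]; coverage is the
    aligned span of the query (bound) chain over its full length.
    """

    query_id: str
    subject_id: str
    identity: float
    coverage: float
    e_value: float
    query_range: tuple[int, int] = (0, 0)
    subject_range: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage {self.coverage} outside [0, 1]")
        if self.e_value < 0:
            raise ValueError(f"E-value {self.e_value} negative")


@dataclass
class UnboundCandidateSet:
    """Accepted unbound candidates for one bound chain, best first."""

    query_id: str
    accepted_hits: list[AlignmentHit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.accepted_hits)

    def subject_ids(self) -> list[str]:
        return [h.subject_id for h in self.accepted_hits]


def accept_unbound_hit(
    hit: AlignmentHit,
    identity_min: float = IDENTITY_MIN,
    coverage_min: float = COVERAGE_MIN,
    evalue_max: float = EVALUE_MAX,
) -> bool:
    """True iff the hit passes all three unbound-structure criteria.

    All inequalities are strict: identity > identity_min, coverage >
    coverage_min, E-value < evalue_max.  A hit exactly at a boundary fails.
    """
    return (
        hit.identity > identity_min
        and hit.coverage > coverage_min
        and hit.e_value < evalue_max
    )


def read_blast_tabular(
    source: Union[str, TextIO],
    query_lengths: Mapping[str, int],
) -> list[AlignmentHit]:
    """Parse BLAST tabular output (outfmt 6 default columns) into hits.

    ``query_lengths`` maps query ids to full query lengths; the tabular
    layout does not carry them, and coverage is computed as the aligned
    query span (qend - qstart + 1) over the full query length.  Percent
    identity is converted to a fraction.
    """
    if isinstance(source, str) and "\t" in source:
        handle: Union[str, TextIO] = io.StringIO(source)
    else:
        handle = source
    df = pd.read_csv(handle, sep="\t", names=BLAST_COLUMNS, comment="#")
    hits: list[AlignmentHit] = []
    for row in df.itertuples(index=False):
        qid = str(row.qseqid)
        if qid not in query_lengths:
            raise KeyError(f"no query length provided for {qid!r}")
        qlen = query_lengths[qid]
        span = int(row.qend) - int(row.qstart) + 1
        coverage = min(max(span / qlen, 0.0), 1.0)
        hits.append(
            AlignmentHit(
                query_id=qid,
                subject_id=str(row.sseqid),
                identity=float(row.pident) / 100.0,
                coverage=coverage,
                e_value=float(row.evalue),
                query_range=(int(row.qstart), int(row.qend)),
                subject_range=(int(row.sstart), int(row.send)),
            )
        )
    return hits


def collect_unbound_candidates(
    hits: Iterable[AlignmentHit],
    query_id: str,
    identity_min: float = IDENTITY_MIN,
    coverage_min: float = COVERAGE_MIN,
    evalue_max: float = EVALUE_MAX,
) -> UnboundCandidateSet:
    """Filter, deduplicate and rank the unbound candidates for one chain.

    Hits for other queries are ignored; an unknown query simply yields an
    empty set.  Multiple HSPs against the same subject are collapsed to
    the one with the highest identity (ties: lowest E-value).  The result
    is sorted by identity descending, then E-value ascending.
    """
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if hit.query_id != query_id:
            continue
        if not accept_unbound_hit(hit, identity_min, coverage_min, evalue_max):
            continue
        prev = best.get(hit.subject_id)
        if prev is None or (hit.identity, -hit.e_value) > (prev.identity, -prev.e_value):
            best[hit.subject_id] = hit
    ranked = sorted(best.values(), key=lambda h: (-h.identity, h.e_value, h.subject_id))
    return UnboundCandidateSet(query_id=query_id, accepted_hits=ranked)


def categorize_case(
    ab_candidates: Mapping[str, UnboundCandidateSet],
    ag_candidates: Mapping[str, UnboundCandidateSet],
) -> PairingState:
    """Pairing state from per-chain candidate availability.

    A side is *complete* when every one of its bound chains has at least
    one accepted unbound candidate (a heavy+light antibody needs both
    chains to pass independently).

    UU: both sides complete; UB: antibody only; BU: antigen only; BB:
    neither.  The four states are exhaustive and mutually exclusive.
    """
    if not ab_candidates or not ag_candidates:
        raise ValueError("need at least one candidate set per side")
    ab_ok = all(len(s) > 0 for s in ab_candidates.values())
    ag_ok = all(len(s) > 0 for s in ag_candidates.values())
    if ab_ok and ag_ok:
        return PairingState.UU
    if ab_ok:
        return PairingState.UB
    if ag_ok:
        return PairingState.BU
    return PairingState.BB


def write_candidates_csv(
    sets: Sequence[UnboundCandidateSet],
    path: str,
) -> None:
    """Write accepted candidates to CSV, one row per (query, subject)."""
    rows = [
        {
            "query_id": s.query_id,
            "subject_id": h.subject_id,
            "identity": h.identity,
            "coverage": h.coverage,
            "e_value": h.e_value,
        }
        for s in sets
        for h in s.accepted_hits
    ]
    pd.DataFrame(rows, columns=["query_id", "subject_id", "identity", "coverage", "e_value"]).to_csv(
        path, index=False
    )
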