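"""Docking-difficulty classification and benchmark composition tables.

Cases are labelled from the entire-interface I-RMSD and f_non-nat:

- **Rigid**:     I-RMSD < 1.5 A and f_non-nat < 0.40
- **Difficult**: I-RMSD > 2.2 A
- **Medium**:    everything else

All inequalities are strict, exactly as the criteria are printed; the
three regions partition the (I-RMSD, f_non-nat) quarter-plane, so the
label is total and unambiguous (boundary values such as I-RMSD = 1.5 or
2.2 fall to Medium).

Composition summaries cross-tabulate labels against antibody type (sdAb:
single-domain antibody; mAb: conventional heavy+light monoclonal) and
report percentages to two decimals with half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ClassificationCriteria",
    "BenchmarkSummary",
    "VersionComparison",
    "classify_case",
    "summarize_benchmark",
    "compare_versions",
    "percent_share",
    "percent_increase",
    "render_summary_table",
]

LABELS = ("Rigid", "Medium", "Difficult")
ANTIBODY_TYPES = ("sdAb", "mAb")


@dataclass(frozen=True)
class ClassificationCriteria:
    rigid_irmsd_max: float = 1.5
    rigid_fnn_max: float = 0.40
    difficult_irmsd_min: float = 2.2

    def __post_init__(self) -> None:
        if not self.rigid_irmsd_max < self.difficult_irmsd_min:
            raise ValueError("Rigid I-RMSD bound must lie below the Difficult bound")


def _round2(value: float) -> float:
    """Two-decimal half-up rounding (matches how the tables are printed)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def percent_share(count: float, total: float) -> float:
    """count/total as a percentage, two decimals, half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    return _round2(100.0 * count / total)


def percent_increase(old: float, new: float) -> Optional[float]:
    """(new - old)/old as a percentage; undefined (None) when old is 0."""
    if old == 0:
        return None
    return _round2(100.0 * (new - old) / old)


def classify_case(
    i_rmsd: float,
    f_non_nat: float,
    criteria: ClassificationCriteria = ClassificationCriteria(),
) -> str:
    """Difficulty label from entire-interface I-RMSD and f_non-nat."""
    if i_rmsd < 0 or f_non_nat < 0:
        raise ValueError(f"metrics must be non-negative, got ({i_rmsd}, {f_non_nat})")
    if i_rmsd < criteria.rigid_irmsd_max and f_non_nat < criteria.rigid_fnn_max:
        return "Rigid"
    if i_rmsd > criteria.difficult_irmsd_min:
        return "Difficult"
    return "Medium"


@dataclass
class BenchmarkSummary:
    """Counts and percentage arithmetic for a labelled benchmark."""

    counts: dict[str, int]
    cross: dict[tuple[str, str], int]  # (label, antibody type) -> count
    total: int
    percentages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("category counts must sum to total")
        if not self.percentages:
            self.percentages = {
                label: percent_share(n, self.total) for label, n in self.counts.items()
            }

    def type_total(self, ab_type: str) -> int:
        return sum(n for (_, t), n in self.cross.items() if t == ab_type)

    def share_by_type(self, label: str, ab_type: str) -> float:
        """Share of ``label`` cases within one antibody type (two decimals)."""
        denom = self.type_total(ab_type)
        return percent_share(self.cross.get((label, ab_type), 0), denom)

    @classmethod
    def from_counts(
        cls, cross: Mapping[tuple[str, str], int]
    ) -> "BenchmarkSummary":
        counts: dict[str, int] = {}
        for (label, _), n in cross.items():
            counts[label] = counts.get(label, 0) + n
        return cls(counts=counts, cross=dict(cross), total=sum(counts.values()))


def summarize_benchmark(
    entries: Sequence[tuple[str, Optional[str], str]],
) -> BenchmarkSummary:
    """Summary from (case_id, difficulty label, antibody type) triples.

    Every entry must be labelled and carry an antibody type; an unlabelled
    case is an error naming the case.
    """
    if not entries:
        raise ValueError("no cases to summarize")
    cross: dict[tuple[str, str], int] = {}
    for case_id, label, ab_type in entries:
        if label not in LABELS:
            raise ValueError(f"case {case_id!r}: missing or unknown difficulty label {label!r}")
        if ab_type not in ANTIBODY_TYPES:
            raise ValueError(f"case {case_id!r}: unknown antibody type {ab_type!r}")
        cross[(label, ab_type)] = cross.get((label, ab_type), 0) + 1
    return BenchmarkSummary.from_counts(cross)


@dataclass
class VersionComparison:
    """Per-field counts of two benchmark versions and their growth."""

    fields: dict[str, tuple[int, int, Optional[float]]]  # name -> (old, new, % increase)

    def increase(self, name: str) -> Optional[float]:
        return self.fields[name][2]


def compare_versions(
    old: Mapping[str, int],
    new: Mapping[str, int],
) -> VersionComparison:
    """Percent growth per field between two versions' counts.

    Field sets must match; a field counting 0 in the old version has an
    undefined increase, reported as None rather than a number.
    """
    if set(old) != set(new):
        raise ValueError(f"field sets differ: {sorted(old)} vs {sorted(new)}")
    fields = {
        name: (old[name], new[name], percent_increase(old[name], new[name]))
        for name in old
    }
    return VersionComparison(fields=fields)


def render_summary_table(summary: BenchmarkSummary) -> str:
    """Plain-text composition table (category x antibody type)."""
    rows = []
    for label in LABELS:
        if label not in summary.counts:
            continue
        rows.append(
            {
                "Category": label,
                "Cases": summary.counts[label],
                "Share %": f"{summary.percentages[label]:.2f}",
                "sdAb": summary.cross.get((label, "sdAb"), 0),
                "mAb": summary.cross.get((label, "mAb"), 0),
            }
        )
    rows.append(
        {
            "Category": "All",
            "Cases": summary.total,
            "Share %": "100.00",
            "sdAb": summary.type_total("sdAb"),
            "mAb": summary.type_total("mAb"),
        }
    )
    return pd.DataFrame(rows).to_string(index=False)


def summary_to_csv(summary: BenchmarkSummary, path: str) -> None:
    rows = [
        {
            "category": label,
            "count": summary.counts[label],
            "share_pct": summary.percentages[label],
            "sdAb": summary.cross.get((label, "sdAb"), 0),
            "mAb": summary.cross.get((label, "mAb"), 0),
        }
        for label in summary.counts
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
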