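"""Set-overlap summaries for differential-expression gene signatures.

Compares two gene-identifier lists (e.g. genes modulated by two related
stimuli) as a Venn diagram in numbers: intersection size, per-set shared
fractions, unique counts. Identifiers are trimmed and upper-cased before
comparison; no alias resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GeneSet", "OverlapSummary", "read_gene_list", "overlap_summary"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    @staticmethod
    def from_iterable(name: str, ids) -> "GeneSet":
        members = frozenset(
            g.strip().upper() for g in ids if g and g.strip()
        )
        return GeneSet(name=name, members=members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OverlapSummary:
    size_a: int
    size_b: int
    intersection: int
    unique_a: int
    unique_b: int
    fraction_of_a: float | None  # None when A is empty (undefined, not 0)
    fraction_of_b: float | None

    @property
    def union(self) -> int:
        return self.unique_a + self.unique_b + self.intersection

    def percent_of_a(self, digits: int = 1) -> float | None:
        return (
            None
            if self.fraction_of_a is None
            else round(100 * self.fraction_of_a, digits)
        )

    def percent_of_b(self, digits: int = 1) -> float | None:
        return (
            None
            if self.fraction_of_b is None
            else round(100 * self.fraction_of_b, digits)
        )


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """Read a newline-delimited gene-identifier file."""
    with open(path) as fh:
        ids = [line for line in fh.read().splitlines()]
    return GeneSet.from_iterable(name or str(path), ids)


def overlap_summary(a: GeneSet, b: GeneSet) -> OverlapSummary:
    """Exact Venn arithmetic between two gene sets."""
    inter = len(a.members & b.members)
    return OverlapSummary(
        size_a=len(a),
        size_b=len(b),
        intersection=inter,
        unique_a=len(a) - inter,
        unique_b=len(b) - inter,
        fraction_of_a=None if len(a) == 0 else inter / len(a),
        fraction_of_b=None if len(b) == 0 else inter / len(b),
    )
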