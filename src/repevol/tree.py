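"""The fixed unrooted 4-taxon tree with mating-system branch labels.

Topology is ((A, B), (C, D)) where A, B are the self-compatible (SC) tips and
C, D the self-incompatible (SI) tips; the single internal branch joins the
two cherries. Five branches total. Branch lengths are expected substitutions
per codon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

SC = "SC"
SI = "SI"
INTERNAL = "INTERNAL"

#: Branch order used throughout: the four tips then the internal branch.
BRANCH_NAMES = ("A", "B", "C", "D", "internal")

DEFAULT_TAXA = ("lycopersicum", "pimpinellifolium", "pennellii", "habrochaites")


@dataclass(frozen=True)
class LabeledTree:
    """((A,B),(C,D)) with per-branch class labels and lengths."""

    taxa: tuple[str, str, str, str] = DEFAULT_TAXA
    lengths: tuple[float, float, float, float, float] = (0.01, 0.01, 0.01, 0.01, 0.01)
    classes: tuple[str, str, str, str, str] = (SC, SC, SI, SI, INTERNAL)

    def __post_init__(self):
        if len(self.taxa) != 4 or len(self.lengths) != 5 or len(self.classes) != 5:
            raise ValueError("tree requires 4 taxa and 5 labeled branches")
        if any(t < 0 for t in self.lengths):
            raise ValueError("branch lengths must be non-negative")

    @property
    def branch_classes(self) -> dict[str, str]:
        return dict(zip(BRANCH_NAMES, self.classes))

    @property
    def branch_lengths(self) -> dict[str, float]:
        return dict(zip(BRANCH_NAMES, self.lengths))

    def with_lengths(self, lengths) -> "LabeledTree":
        return replace(self, lengths=tuple(float(t) for t in lengths))

    def merged_classes(self, scheme: str) -> tuple[str, ...]:
        """Branch classes under a rate scheme.

        ``M0``: one class everywhere; ``TWO_RATIO``: internal branch counted
        as SI; ``THREE_RATIO``: SC / SI / INTERNAL kept distinct.
        """
        if scheme == "M0":
            return tuple("ALL" for _ in self.classes)
        if scheme == "TWO_RATIO":
            return tuple(SI if c == INTERNAL else c for c in self.classes)
        if scheme == "THREE_RATIO":
            return tuple(self.classes)
        raise ValueError(f"unknown scheme {scheme!r}")

    def newick(self) -> str:
        a, b, c, d = self.taxa
        ta, tb, tc, td, ti = self.lengths
        return f"(({a}:{ta:g},{b}:{tb:g}):{ti:g},({c}:{tc:g},{d}:{td:g}):0);"
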