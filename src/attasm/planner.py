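"""Merge-tree construction and operation-count accounting.

A hierarchical assembly of N fragments is planned as a balanced k-ary merge
tree: 2^N fragments assemble in N parallel cycles for binary merging, i.e.
O(log N) rounds. The operation ledger prices a plan in the ten wet-lab
operation categories (liquid/plate incubations, plasmid/DNA extraction,
digestion, ligation, isothermal assembly, conjugation, electroporation, PCR
verification) from per-node, per-merge and per-extraction cost tables carried
by the strategy template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CATEGORIES",
    "MergeNode",
    "MergeTree",
    "OpLedger",
    "build_merge_tree",
    "cycle_count",
    "count_ops",
]

#: ledger categories, in conventional reporting order
CATEGORIES = (
    "incubation_liquid",
    "plasmid_extraction",
    "digestion",
    "dna_extraction",
    "ligation",
    "gibson_assembly",
    "conjugation",
    "electroporation",
    "pcr_verification",
    "incubation_plate",
)

CATEGORY_LABELS = {
    "incubation_liquid": "Incubation (liquid)",
    "plasmid_extraction": "Plasmid Extraction",
    "digestion": "Digestion",
    "dna_extraction": "DNA Extraction",
    "ligation": "Ligation",
    "gibson_assembly": "Gibson Assembly",
    "conjugation": "Conjugation",
    "electroporation": "Electroporation",
    "pcr_verification": "PCR Verification",
    "incubation_plate": "Incubation (plate)",
}


@dataclass
class MergeNode:
    """A node of the merge tree: a leaf (payload index) or an internal merge.

    ``chromosome_side`` designates which child stays on the host chromosome
    during an integrating strategy; by convention the last (rightmost) child,
    so that payloads prepend and leaf order equals final payload order.
    For swap strategies the same index is read as the extension anchor.
    """

    children: list["MergeNode"] = field(default_factory=list)
    leaf: int | None = None
    chromosome_side: int = -1

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.depth() for c in self.children)

    def leaf_indices(self) -> list[int]:
        if self.is_leaf:
            return [self.leaf]
        out: list[int] = []
        for c in self.children:
            out.extend(c.leaf_indices())
        return out


@dataclass
class MergeTree:
    leaves: list[str]  # payload ids, in target order
    root: MergeNode
    arity: int = 2

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def internal_nodes(self) -> list[MergeNode]:
        out: list[MergeNode] = []

        def walk(node: MergeNode) -> None:
            if node.is_leaf:
                return
            out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def stats(self) -> dict[str, int]:
        """Basis quantities for the cost model."""
        internal = self.internal_nodes()
        # a "merge" is one junction: a k-child node creates k - 1 junctions
        # sequentially; single-reaction k-ary chemistries price per
        # internal_node instead
        merges = sum(len(n.children) - 1 for n in internal)
        psn = 0  # plasmid-side internal nodes
        for node in internal:
            cs = node.chromosome_side % len(node.children)
            for i, c in enumerate(node.children):
                if i != cs and not c.is_leaf:
                    psn += 1
        extractions = (psn + 1) if merges else 0
        return {
            "leaf": self.n_leaves,
            "node": self.n_leaves + merges,
            "merge": merges,
            "internal_node": len(internal),
            "extraction": extractions,
            "nonfinal_extraction": psn,
            "plasmid_side_internal": psn,
        }


def build_merge_tree(
    payloads: int | list[str], arity: int = 2
) -> MergeTree:
    """Balanced k-ary merge tree preserving leaf order (deeper-left filling).

    For k = 2 this gives exactly n - 1 merges and depth ceil(log2 n).
    """
    if isinstance(payloads, int):
        if payloads < 1:
            raise ValueError("need at least one payload")
        ids = [f"P{i+1}" for i in range(payloads)]
    else:
        ids = list(payloads)
        if not ids:
            raise ValueError("need at least one payload")
    if arity < 2:
        raise ValueError("arity must be >= 2")

    def build(lo: int, hi: int) -> MergeNode:
        n = hi - lo
        if n == 1:
            return MergeNode(leaf=lo)
        levels = math.ceil(math.log(n, arity))
        child_cap = arity ** (levels - 1)
        children: list[MergeNode] = []
        pos = lo
        while pos < hi:
            step = min(child_cap, hi - pos)
            children.append(build(pos, pos + step))
            pos += step
        return MergeNode(children=children)

    return MergeTree(ids, build(0, len(ids)), arity)


def cycle_count(tree: MergeTree) -> int:
    """Parallel assembly rounds: the depth of the merge tree."""
    return tree.root.depth()


@dataclass
class OpLedger:
    """Counts in the ten operation categories for a planned assembly."""

    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})

    def __post_init__(self) -> None:
        for c in CATEGORIES:
            self.counts.setdefault(c, 0)
        bad = {k: v for k, v in self.counts.items() if v < 0}
        if bad:
            raise ValueError(f"negative operation counts: {bad}")

    def __getitem__(self, category: str) -> int:
        return self.counts[category]

    def add(self, category: str, n: int = 1) -> None:
        if category not in self.counts:
            raise KeyError(f"unknown operation category {category!r}")
        self.counts[category] += n

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(self.counts[c] for c in CATEGORIES)

    def to_tsv(self) -> str:
        lines = ["operation\tcount"]
        for c in CATEGORIES:
            lines.append(f"{CATEGORY_LABELS[c]}\t{self.counts[c]}")
        return "\n".join(lines) + "\n"

    def __eq__(self, other: object) -> bool:
        if isinstance(other, OpLedger):
            return self.as_tuple() == other.as_tuple()
        return NotImplemented


def count_ops(template, tree: MergeTree) -> OpLedger:
    """Price a merge tree under a strategy template's cost tables.

    ledger = sum over basis quantities (leaves, nodes, merges, extractions,
    non-final extractions, plasmid-side internal nodes) of
    basis_value x per-basis category costs. Deterministic.
    """
    costs = getattr(template, "op_costs", None)
    if not costs:
        raise ValueError(f"template {getattr(template, 'name', template)!r} has no cost table")
    stats = tree.stats()
    ledger = OpLedger()
    for basis, table in costs.items():
        if basis not in stats:
            raise ValueError(f"unknown cost basis {basis!r}")
        mult = stats[basis]
        for category, coeff in table.items():
            ledger.add(category, coeff * mult)
    return ledger
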