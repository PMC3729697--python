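"""Maximum-parsimony clade trees from variant profiles.

Builds a rooted haplotype tree by greedy agglomeration: the variant shared by
the most samples founds a clade, recursively, with recurrent-prone sites
down-weighted in tie-breaks so that stable variants structure the tree the
way hand-curation against the reference phylogeny would.  Edges carry the
mutations they imply; reversions (``@``) are introduced in a refinement pass
when and only when they lower the total mutation count.  Replaying edge
mutations from the root to any tip reproduces that tip's (masked) profile
exactly — the central well-formedness invariant, asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Iterator, Mapping, Sequence

from .variants import (
    DEFAULT_MASK,
    MtVariant,
    SiteMask,
    VarClass,
    VariantProfile,
    apply_mask,
)

__all__ = [
    "PhyloNode",
    "CladePhylogeny",
    "HomoplasyReport",
    "default_site_weights",
    "build_tree",
    "detect_subclades",
    "homoplasy_scan",
    "write_newick",
    "write_edge_table",
]


class PhyloNode:
    """A node of a rooted clade tree; ``edge_mutations`` sit on the edge to
    its parent (empty for the root)."""

    __slots__ = ("name", "children", "parent", "edge_mutations", "label")

    def __init__(self, name: str | None = None):
        self.name = name  # sample_id for tips
        self.children: list[PhyloNode] = []
        self.parent: PhyloNode | None = None
        self.edge_mutations: list[MtVariant] = []
        self.label: str | None = None  # optional haplogroup label

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "PhyloNode") -> "PhyloNode":
        child.parent = self
        self.children.append(child)
        return child

    def walk(self) -> Iterator["PhyloNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def tips(self) -> list["PhyloNode"]:
        return [n for n in self.walk() if n.is_tip]


@dataclass
class CladePhylogeny:
    """A rooted tree with edge-attached mutations and sample tips."""

    root: PhyloNode
    root_reference: str = "rCRS"

    def walk(self) -> Iterator[PhyloNode]:
        return self.root.walk()

    def tips(self) -> list[PhyloNode]:
        return self.root.tips()

    def total_mutations(self) -> int:
        return sum(len(n.edge_mutations) for n in self.walk())

    def replay(self, node: PhyloNode) -> frozenset[MtVariant]:
        """Accumulate edge mutations root->node with back-mutation
        cancellation; for a tip this reproduces its input profile."""
        chain: list[PhyloNode] = []
        cur: PhyloNode | None = node
        while cur is not None:
            chain.append(cur)
            cur = cur.parent
        state: dict[tuple[int, int | None], MtVariant] = {}
        for n in reversed(chain):
            for v in n.edge_mutations:
                if v.var_class is VarClass.BACK_MUTATION and v.site in state:
                    del state[v.site]
                else:
                    state[v.site] = v
        return frozenset(state.values())

    def find(self, label: str) -> PhyloNode:
        for n in self.walk():
            if n.label == label or n.name == label:
                return n
        raise KeyError(f"no node labelled {label!r}")


@dataclass(frozen=True)
class HomoplasyReport:
    position: int
    occurrences: int


_DEFAULT_WEIGHTS: dict[int, float] | None = None


def default_site_weights() -> dict[int, float]:
    """Shipped stability weights: 1.0 everywhere except known recurrent
    sites, which count for less when choosing defining variants."""
    global _DEFAULT_WEIGHTS
    if _DEFAULT_WEIGHTS is None:
        text = resources.files("mitophylo.data").joinpath("hotspots.tsv").read_text()
        w = {}
        for line in text.splitlines():
            if not line or line.startswith("#") or line.startswith("position"):
                continue
            pos, weight, _ = line.split("\t")
            w[int(pos)] = float(weight)
        _DEFAULT_WEIGHTS = w
    return dict(_DEFAULT_WEIGHTS)


def build_tree(
    profiles: Sequence[VariantProfile],
    mask: SiteMask = DEFAULT_MASK,
    weights: Mapping[int, float] | None = None,
    root_reference: str | None = None,
) -> CladePhylogeny:
    """Greedy weighted maximum-parsimony construction.

    Repeatedly founds the subclade defined by the unexplained variant with
    the highest weighted sharing count (carriers x site weight, so recurrent
    hotspots need proportionally broader support to define a clade); ties
    broken by higher site weight, then lower position, then token.  Samples
    whose variants are exhausted attach
    as tips where they stand.  A final bottom-up pass pulls a variant above a
    node and plants reversions on the non-carrying branches whenever that
    strictly lowers the mutation count.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    refs = {p.reference for p in profiles}
    if len(refs) > 1:
        raise ValueError(f"profiles mix references {sorted(refs)}")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_ids: {dupes}")
    if weights is None:
        weights = default_site_weights()

    remaining: dict[str, set[MtVariant]] = {
        p.sample_id: set(apply_mask(p, mask).variants) for p in profiles
    }

    def pick(members: list[str]) -> MtVariant | None:
        counts: dict[MtVariant, int] = {}
        for sid in members:
            for v in remaining[sid]:
                counts[v] = counts.get(v, 0) + 1
        best = None
        best_key = None
        for v, c in counts.items():
            if c < 2:
                continue
            w = weights.get(v.position, 1.0)
            # weighted sharing count: a recurrent-prone site must be shared by
            # proportionally more samples to found a clade
            key = (c * w, w, -v.position, v.render())
            if best_key is None or key > best_key:
                best, best_key = v, key
        return best

    def grow(node: PhyloNode, members: list[str]) -> None:
        rest = [sid for sid in members if remaining[sid]]
        for sid in members:
            if not remaining[sid]:
                node.add_child(PhyloNode(sid))
        while rest:
            v = pick(rest)
            if v is None:
                for sid in rest:
                    tip = node.add_child(PhyloNode(sid))
                    tip.edge_mutations = sorted(remaining[sid])
                    remaining[sid].clear()
                break
            carriers = [sid for sid in rest if v in remaining[sid]]
            child = node.add_child(PhyloNode())
            shared = set.intersection(*(remaining[sid] for sid in carriers))
            child.edge_mutations = sorted(shared)
            for sid in carriers:
                remaining[sid] -= shared
            grow(child, carriers)
            rest = [sid for sid in rest if sid not in carriers and remaining[sid]]

    root = PhyloNode()
    # samples identical to the reference attach directly under the root
    grow(root, sorted(remaining))
    _collapse_unary(root)
    _refine_reversions(root)
    ref = root_reference or profiles[0].reference
    return CladePhylogeny(root, ref)


def _collapse_unary(root: PhyloNode) -> None:
    """Merge internal nodes with a single child into their child's edge."""
    for node in list(root.walk()):
        for child in list(node.children):
            while len(child.children) == 1 and child.name is None:
                (gc,) = child.children
                gc.edge_mutations = child.edge_mutations + gc.edge_mutations
                gc.parent = node
                node.children[node.children.index(child)] = gc
                child = gc


def _refine_reversions(root: PhyloNode) -> None:
    """Pull a variant above a node, planting ``@`` reversions on the
    branches that lack it, when that strictly reduces the mutation count."""
    post = list(root.walk())[::-1]
    for node in post:
        if len(node.children) < 2:
            continue
        counts: dict[MtVariant, int] = {}
        for c in node.children:
            for v in set(c.edge_mutations):
                if v.var_class is not VarClass.BACK_MUTATION:
                    counts[v] = counts.get(v, 0) + 1
        for v, c in sorted(counts.items()):
            d = len(node.children) - c
            if c > 1 + d and node.parent is not None:
                back = MtVariant(v.position, VarClass.BACK_MUTATION)
                if any(
                    b.position == v.position
                    for ch in node.children
                    for b in ch.edge_mutations
                    if b.var_class is VarClass.BACK_MUTATION
                ):
                    continue
                for ch in node.children:
                    if v in ch.edge_mutations:
                        ch.edge_mutations.remove(v)
                    else:
                        ch.edge_mutations = sorted(ch.edge_mutations + [back])
                node.edge_mutations = sorted(node.edge_mutations + [v])


def detect_subclades(
    tree: CladePhylogeny, min_tips: int = 2
) -> list[tuple[PhyloNode, list[MtVariant]]]:
    """Internal nodes with >=min_tips descendant tips and >=1 defining edge
    mutation, ordered by descending tip count (then preorder)."""
    if min_tips < 2:
        raise ValueError("min_tips must be >= 2")
    out = []
    for idx, node in enumerate(tree.walk()):
        if node is tree.root or node.is_tip:
            continue
        ntips = len(node.tips())
        if ntips >= min_tips and node.edge_mutations:
            out.append((ntips, idx, node))
    out.sort(key=lambda t: (-t[0], t[1]))
    return [(n, list(n.edge_mutations)) for _, _, n in out]


def homoplasy_scan(tree: CladePhylogeny) -> list[HomoplasyReport]:
    """Positions mutated on >=2 independent edges (reversions included)."""
    per_pos: dict[int, int] = {}
    for node in tree.walk():
        for pos in {v.position for v in node.edge_mutations}:
            per_pos[pos] = per_pos.get(pos, 0) + 1
    return [
        HomoplasyReport(pos, c)
        for pos, c in sorted(per_pos.items(), key=lambda t: (-t[1], t[0]))
        if c >= 2
    ]


def label_nodes(tree: CladePhylogeny, defs=None) -> None:
    """Label internal nodes with the haplogroup their reconstructed
    haplotype classifies to; paraphyletic tips keep the parent label + '*'."""
    from .haplogroups import classify, default_definitions

    defs = defs or default_definitions()
    for node in tree.walk():
        if node.is_tip:
            continue
        hap = VariantProfile(
            "node", tree.replay(node), reference=tree.root_reference
        )
        node.label = classify(hap, defs).best_clade
    for node in tree.walk():
        if node.is_tip and not node.edge_mutations and node.parent is not None:
            pass  # identical to its parent node haplotype; implicitly that clade
        elif node.is_tip and node.parent is not None and node.parent.label:
            node.label = node.parent.label + "*"


# ---------------------------------------------------------------------------
# Output formats


def _newick(node: PhyloNode) -> str:
    muts = "|".join(v.render() for v in node.edge_mutations)
    name = node.name or node.label or ""
    comment = f"[&muts={muts}]" if muts else ""
    body = ""
    if node.children:
        body = "(" + ",".join(_newick(c) for c in node.children) + ")"
    return f"{body}{name}:{len(node.edge_mutations)}{comment}"


def write_newick(tree: CladePhylogeny, path=None) -> str:
    """Newick with mutation annotations in comment blocks; branch lengths
    are edge mutation counts."""
    s = _newick(tree.root).rsplit(":", 1)[0] + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def write_edge_table(tree: CladePhylogeny, path=None):
    """Tabular edge list (parent, child, mutations) with stable node ids."""
    import pandas as pd

    ids = {id(n): i for i, n in enumerate(tree.walk())}
    rows = []
    for n in tree.walk():
        if n.parent is None:
            continue
        rows.append(
            {
                "parent": ids[id(n.parent)],
                "child": ids[id(n)],
                "name": n.name or "",
                "label": n.label or "",
                "mutations": " ".join(v.render() for v in n.edge_mutations),
            }
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
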