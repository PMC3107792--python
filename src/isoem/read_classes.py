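"""Online union-find over the read-isoform compatibility graph.

Reads are inserted one at a time; the forest simultaneously tracks connected
components of the bipartite compatibility graph and collapses equivalent
reads (same isoform set, proportional weights) into read classes stored at
the LCA of their isoforms' nodes. No path compression is performed during
insertion — it would change tree topology and break the LCA guarantee — but
the final collection phase may compress freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

Entry = tuple[str, float]
Signature = tuple[tuple[str, float], ...]


def canonical_signature(entries: Sequence[Entry]) -> Signature:
    """Canonical form of a weight vector: sorted by isoform id, weights
    scaled so the maximum is 1 and rounded to 9 significant digits. Two
    reads are equivalent iff their signatures are equal."""
    if not entries:
        raise ValueError("entries must be non-empty")
    wmax = max(w for _, w in entries)
    if wmax <= 0:
        raise ValueError("weights must be positive")
    return tuple(
        (iso, float(f"{w / wmax:.9g}")) for iso, w in sorted(entries)
    )


@dataclass
class ReadClass:
    """A collapsed set of equivalent reads: multiplicity m plus the shared
    (isoform, weight) entries in canonical form."""

    multiplicity: float
    entries: Signature


class _Node:
    __slots__ = ("iso", "parent", "height", "classes", "mark")

    def __init__(self, iso: str):
        self.iso = iso
        self.parent: "_Node | None" = None
        self.height = 0
        self.classes: dict[Signature, ReadClass] = {}
        self.mark = 0


@dataclass
class Component:
    isoforms: list[str]
    classes: list[ReadClass] = field(default_factory=list)

    @property
    def total_multiplicity(self) -> float:
        return sum(c.multiplicity for c in self.classes)


class CompatibilityForest:
    """Union-find forest whose trees are compatibility components and whose
    nodes carry hash tables of read classes."""

    def __init__(self) -> None:
        self._nodes: dict[str, _Node] = {}
        self._mark_epoch = 0
        self.reads_added = 0
        self.reads_collapsed = 0

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def n_classes(self) -> int:
        return sum(len(n.classes) for n in self._nodes.values())

    def _node(self, iso: str) -> _Node:
        node = self._nodes.get(iso)
        if node is None:
            node = _Node(iso)
            self._nodes[iso] = node
        return node

    @staticmethod
    def _root(node: _Node) -> _Node:
        while node.parent is not None:
            node = node.parent
        return node

    def add_read(self, entries: Sequence[Entry], bias_weight: float = 1.0) -> None:
        """Insert one read's compatibility entries with multiplicity
        ``bias_weight`` (1 unless hexamer-bias reweighting is on)."""
        sig = canonical_signature(entries)
        nodes = [self._node(iso) for iso, _ in sig]
        roots: dict[int, _Node] = {}
        for n in nodes:
            r = self._root(n)
            roots[id(r)] = r
        self.reads_added += 1

        if len(roots) > 1:
            # isoforms span multiple trees: unite them (taller root wins) and
            # store the necessarily-new class at the union root
            it = iter(roots.values())
            top = next(it)
            for r in it:
                if r.height > top.height:
                    top.parent = r
                    top = r
                elif r.height < top.height:
                    r.parent = top
                else:  # tie: smaller isoform-id root wins, height grows
                    if r.iso < top.iso:
                        top, r = r, top
                    r.parent = top
                    top.height += 1
            top.classes[sig] = ReadClass(bias_weight, sig)
            return

        lca = self._lca(nodes)
        existing = lca.classes.get(sig)
        if existing is not None:
            existing.multiplicity += bias_weight
            self.reads_collapsed += 1
        else:
            lca.classes[sig] = ReadClass(bias_weight, sig)

    def _lca(self, nodes: list[_Node]) -> _Node:
        """LCA of nodes known to share a tree, by marking root paths."""
        self._mark_epoch += 1
        epoch = self._mark_epoch
        cur: _Node | None = nodes[0]
        while cur is not None:
            cur.mark = epoch
            cur = cur.parent
        lca = nodes[0]
        for n in nodes[1:]:
            cur = n
            while cur.mark != epoch:
                cur.mark = epoch
                cur = cur.parent  # type: ignore[assignment]
                assert cur is not None, "nodes not in one tree"
            # cur (the meeting point) and the running lca are always
            # comparable: every marked node is either an ancestor or a
            # descendant of the running lca. The new lca is whichever of the
            # two is the ancestor.
            lca = self._ancestor_of_pair(lca, cur)
        return lca

    @staticmethod
    def _ancestor_of_pair(a: _Node, b: _Node) -> _Node:
        """Of two nodes where one is an ancestor of the other, return the
        ancestor."""
        cur: _Node | None = a
        while cur is not None:
            if cur is b:
                return b  # b is an ancestor of (or equal to) a
            cur = cur.parent
        return a

    def collect(self) -> list[Component]:
        """Components with their concatenated read classes. Applies path
        compression (safe once no more reads will be added)."""
        comps: dict[int, Component] = {}
        for node in self._nodes.values():
            root = self._root(node)
            # compress: point every node on the path straight at the root
            cur = node
            while cur is not root:
                nxt = cur.parent
                cur.parent = root
                cur = nxt
            comp = comps.get(id(root))
            if comp is None:
                comp = comps[id(root)] = Component(isoforms=[])
            comp.isoforms.append(node.iso)
            comp.classes.extend(node.classes.values())
        out = list(comps.values())
        for comp in out:
            comp.isoforms.sort()
        out.sort(key=lambda c: c.isoforms[0])
        return out

    def max_height(self) -> int:
        return max((n.height for n in self._nodes.values()), default=0)


def build_forest(
    weighted: Iterable,
    bias_weights: Iterable[float] | None = None,
) -> CompatibilityForest:
    """Build a forest from a stream of WeightedCompatibility objects."""
    forest = CompatibilityForest()
    if bias_weights is None:
        for wc in weighted:
            forest.add_read(wc.entries)
    else:
        for wc, b in zip(weighted, bias_weights):
            forest.add_read(wc.entries, bias_weight=b)
    return forest


def components_bruteforce(weighted: list) -> list[set[str]]:
    """Connected components of the bipartite read-isoform graph by plain
    graph traversal; oracle for the union-find path."""
    adj: dict[str, set[str]] = {}
    for wc in weighted:
        isos = [iso for iso, _ in wc.entries]
        for iso in isos:
            adj.setdefault(iso, set()).update(isos)
    seen: set[str] = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        comps.append(comp)
    return comps
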