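"""Tree handling: Newick I/O, support collapsing, RF distance, neighbor
joining, and tanglegram leaf ordering.

Trees are plain :class:`dendropy.Tree` objects.  Bootstrap-style support
values follow the IQ-TREE convention of numeric internal-node labels and
are interpreted as the support of the edge above the labelled node.
"""

from __future__ import annotations

import io
import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from dendropy.calculate import treecompare

log = logging.getLogger(__name__)

__all__ = [
    "read_newick",
    "read_newick_file",
    "write_newick",
    "support_of",
    "collapse_low_support",
    "rf_distance",
    "DistanceMatrix",
    "neighbor_joining",
    "tanglegram_order",
]


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(text: str, taxon_namespace=None) -> dendropy.Tree:
    """Parse one Newick string; numeric internal labels are edge supports.

    Raises ``ValueError`` naming the problem for malformed input, including
    duplicate leaf labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            taxon_namespace=taxon_namespace,
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise ValueError(f"Newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate leaf labels: {dup}")
    return tree


def read_newick_file(path, taxon_namespace=None) -> list[dendropy.Tree]:
    """Read a one-Newick-per-line tree file."""
    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace()
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            trees.append(read_newick(line, taxon_namespace=taxon_namespace))
    return trees


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize to a single-line Newick string (supports kept as labels)."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return s.strip()


def support_of(node) -> float | None:
    """Support of the edge above ``node`` (numeric node label), else None."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# Support-based collapsing


def collapse_low_support(
    tree: dendropy.Tree, min_support: float = 10.0, inclusive: bool = False
) -> dendropy.Tree:
    """Contract internal edges whose support falls below ``min_support``.

    ``inclusive=True`` collapses edges with support equal to the threshold
    as well (support <= min_support); the default is a strict ``<``.  Edges
    without a numeric support label are retained.  Children of a collapsed
    edge reattach to the grandparent, creating polytomies; the leaf set is
    never changed.
    """
    out = tree.clone(depth=1)
    to_collapse = []
    for node in out.postorder_internal_node_iter(exclude_seed_node=True):
        sup = support_of(node)
        if sup is None:
            continue
        if sup < min_support or (inclusive and sup == min_support):
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


# ---------------------------------------------------------------------------
# Robinson–Foulds


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """Symmetric-difference RF distance on the shared leaf set.

    Trees with unequal leaf sets are first restricted to the intersection
    (logged); fewer than four shared leaves is an error.  Returns
    ``(count, normalized)`` with ``normalized = count / (2 (n - 3))``.
    """
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    shared = l1 & l2
    if len(shared) < 4:
        raise ValueError(
            f"need >= 4 shared leaves for RF distance, got {len(shared)}"
        )
    if shared != l1 or shared != l2:
        log.info("rf_distance: restricting to %d shared leaves", len(shared))
    tns = dendropy.TaxonNamespace()
    a = read_newick(write_newick(t1), taxon_namespace=tns)
    b = read_newick(write_newick(t2), taxon_namespace=tns)
    a = a.extract_tree_with_taxa_labels(shared)
    b = b.extract_tree_with_taxa_labels(shared)
    a.encode_bipartitions()
    b.encode_bipartitions()
    count = treecompare.symmetric_difference(a, b)
    n = len(shared)
    return int(count), count / (2.0 * (n - 3)) if n > 3 else 0.0


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass
class DistanceMatrix:
    """Symmetric distances with labelled rows/columns."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.values < 0):
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
        return cls(header, np.array(rows))


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster representative labels (the smallest leaf label in each
    cluster).  Negative branch lengths are clamped to zero with the deficit
    transferred to the sister branch, the usual practice for keeping output
    trees valid.
    """
    n0 = len(d.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    tns = dendropy.TaxonNamespace(sorted(d.labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for lab in d.labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(nd)
    reps = list(d.labels)  # cluster representative = smallest member label
    D = d.values.astype(float).copy()
    active = list(range(n0))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                pair_key = tuple(sorted((reps[active[ai]], reps[active[aj]])))
                cand = (q, pair_key, ai, aj)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        vj = dij - vi
        # clamp negatives, moving length to the sister edge
        if vi < 0:
            vj += -vi
            vi = 0.0
        if vj < 0:
            vi += -vj
            vj = 0.0
        parent = dendropy.Node()
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new cluster to the rest
        new_row = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = new_row
        D[active, i] = new_row
        D[i, i] = 0.0
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    vi = max(0.0, 0.5 * (dij + dik - djk))
    vj = max(0.0, 0.5 * (dij + djk - dik))
    vk = max(0.0, 0.5 * (dik + djk - dij))
    root = dendropy.Node()
    for idx, v in ((i, vi), (j, vj), (k, vk)):
        nodes[idx].edge.length = v
        root.add_child(nodes[idx])
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Tanglegram leaf ordering


def _leaf_orders(node, cap):
    """All leaf orderings reachable by child rotations below ``node``."""
    if node.is_leaf():
        return [[node.taxon.label]]
    child_orders = [_leaf_orders(ch, cap) for ch in node.child_nodes()]
    out = []
    for perm in itertools.permutations(range(len(child_orders))):
        for combo in itertools.product(*(child_orders[i] for i in perm)):
            out.append([lab for part in combo for lab in part])
            if len(out) > cap:
                raise OverflowError
    return out


def _crossings(order1, order2) -> int:
    """Number of intersecting leaf-connector pairs (inversion count)."""
    pos = {lab: i for i, lab in enumerate(order2)}
    seq = [pos[lab] for lab in order1 if lab in pos]
    inv = 0
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            if seq[i] > seq[j]:
                inv += 1
    return inv


def _current_order(node):
    return [lf.taxon.label for lf in node.leaf_iter()]


def _barycenter_pass(tree, other_order):
    """Rotate children of every node to sort by mean position in the other
    tree's current leaf order; returns the new leaf order."""
    pos = {lab: i for i, lab in enumerate(other_order)}

    def mean_pos(node):
        vals = [pos[lab] for lab in _current_order(node) if lab in pos]
        return sum(vals) / len(vals) if vals else 0.0

    for node in tree.postorder_internal_node_iter():
        children = list(node.child_nodes())
        children.sort(key=mean_pos)
        node.set_child_nodes(children)
    return _current_order(tree.seed_node)


def tanglegram_order(
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    method: str = "auto",
    max_exact: int = 4096,
    max_sweeps: int = 20,
):
    """Leaf orderings minimizing connector crossings between two rooted trees.

    Only internal-node rotations are allowed.  For small trees (joint
    rotation space up to ``max_exact`` orderings per tree) the search is
    exhaustive and therefore exact; otherwise alternating barycenter sweeps
    run until no improvement.  The result is never worse than the input
    ordering.  Returns ``(leaf_order_1, leaf_order_2, crossing_count)``.
    """
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if not (l1 & l2):
        raise ValueError("trees share no leaves")
    if method not in ("auto", "exact", "barycenter"):
        raise ValueError(f"unknown method {method!r}")

    o1 = _current_order(t1.seed_node)
    o2 = _current_order(t2.seed_node)
    best = (_crossings(o1, o2), o1, o2)

    if method in ("auto", "exact"):
        try:
            all1 = _leaf_orders(t1.seed_node, max_exact)
            all2 = _leaf_orders(t2.seed_node, max_exact)
        except OverflowError:
            if method == "exact":
                raise ValueError("tree too large for exact tanglegram search")
            all1 = None
        if all1 is not None:
            for a in all1:
                for b in all2:
                    c = _crossings(a, b)
                    if c < best[0]:
                        best = (c, a, b)
                    if best[0] == 0:
                        return best[1], best[2], 0
            return best[1], best[2], best[0]

    w1 = t1.clone(depth=1)
    w2 = t2.clone(depth=1)
    for _ in range(max_sweeps):
        o1n = _barycenter_pass(w1, _current_order(w2.seed_node))
        o2n = _barycenter_pass(w2, o1n)
        c = _crossings(o1n, o2n)
        if c < best[0]:
            best = (c, o1n, o2n)
        else:
            break
    return best[1], best[2], best[0]
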