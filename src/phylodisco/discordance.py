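"""Quartet-based species-tree estimation and per-branch discordance.

A species tree's internal branch induces a quadripartition A|B||C|D of the
taxa; over a set of equally weighted gene trees, each quartet drawn one
leaf per cluster supports one of the three pairings.  The relative
frequencies of the three pairings — ``f_main`` for the species-tree
pairing AB|CD and ``f_alt1``/``f_alt2`` for the alternatives — quantify
discordance.  Under the multispecies coalescent a branch of length ``T``
coalescent units expects ``f_main = 1 - (2/3) exp(-T)`` and each
alternative ``(1/3) exp(-T)``; a branch whose single dominant pairing
exceeds 1/3 (equal representation of all three) is the working notion of
a resolved relationship.

The species-tree search maximizes the total quartet agreement score with
the gene trees, exhaustively for up to 7 taxa and by nearest-neighbor-
interchange (NNI) hill climbing from a distance-based starting tree
otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._splits import TaxonRegistry, quartet_state, tree_splits
from .treeops import DistanceMatrix, neighbor_joining, read_newick, write_newick

__all__ = [
    "GeneTreeSet",
    "BranchFrequencyTable",
    "quartet_topology",
    "quartet_score",
    "infer_species_tree",
    "branch_frequencies",
    "classify_discordance",
]

_TOPO_NAMES = ("main", "alt1", "alt2")


class GeneTreeSet:
    """Equally weighted gene trees over (possibly) overlapping leaf sets.

    Wraps the trees together with a shared taxon registry and cached
    bitmask split encodings so quartet tallies avoid re-walking trees.
    """

    def __init__(self, trees, locus_ids=None):
        self.trees = list(trees)
        if locus_ids is None:
            locus_ids = [f"locus{i + 1}" for i in range(len(self.trees))]
        if len(locus_ids) != len(self.trees):
            raise ValueError("locus_ids length mismatch")
        self.locus_ids = list(locus_ids)
        labels = set()
        for t in self.trees:
            labels.update(lf.taxon.label for lf in t.leaf_node_iter())
        self.registry = TaxonRegistry(labels)
        self._encoded = [tree_splits(t, self.registry) for t in self.trees]
        self._quartet_counts = None

    def __len__(self):
        return len(self.trees)

    @classmethod
    def from_file(cls, path) -> "GeneTreeSet":
        from .treeops import read_newick_file

        return cls(read_newick_file(path))

    @classmethod
    def from_newicks(cls, newicks, locus_ids=None) -> "GeneTreeSet":
        tns = dendropy.TaxonNamespace()
        return cls(
            [read_newick(s, taxon_namespace=tns) for s in newicks], locus_ids
        )

    @property
    def taxa(self) -> list[str]:
        return list(self.registry.labels)

    def quartet_counts(self) -> dict:
        """``{(i<j<k<l): [n_ij|kl, n_ik|jl, n_il|jk]}`` over all gene trees.

        Indices refer to the shared registry; unresolved quartets are not
        counted.  Cached after the first call.
        """
        if self._quartet_counts is None:
            counts: dict = {}
            for presence, splits in self._encoded:
                idxs = [
                    i
                    for i in range(len(self.registry))
                    if presence & (1 << i)
                ]
                for quad in itertools.combinations(idxs, 4):
                    st = quartet_state(
                        splits, *(1 << i for i in quad)
                    )
                    if st < 0:
                        continue
                    if quad not in counts:
                        counts[quad] = [0, 0, 0]
                    counts[quad][st] += 1
            self._quartet_counts = counts
        return self._quartet_counts


# ---------------------------------------------------------------------------
# Quartet primitives


def quartet_topology(tree: dendropy.Tree, taxa) -> str:
    """Induced unrooted topology of four taxa in ``tree``.

    Returns ``"a,b|c,d"`` (each side sorted, sides ordered) or
    ``"unresolved"`` for a star restriction.  All four taxa must occur in
    the tree.
    """
    taxa = sorted(taxa)
    if len(set(taxa)) != 4:
        raise ValueError("need exactly four distinct taxa")
    present = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in present]
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    reg = TaxonRegistry(present)
    _, splits = tree_splits(tree, reg)
    st = quartet_state(splits, *(reg.bit(t) for t in taxa))
    if st < 0:
        return "unresolved"
    a, b, c, d = taxa
    pairs = {0: ((a, b), (c, d)), 1: ((a, c), (b, d)), 2: ((a, d), (b, c))}[st]
    sides = sorted(",".join(p) for p in pairs)
    return "|".join(sides)


def _candidate_states(splits, quartets):
    """Topology index of each quartet under a candidate's splits."""
    return {
        quad: quartet_state(splits, *(1 << i for i in quad))
        for quad in quartets
    }


def quartet_score(candidate: dendropy.Tree, gene_trees: GeneTreeSet) -> int:
    """Total number of gene-tree quartets agreeing with ``candidate``.

    Sums over gene trees and over every 4-taxon subset present in both the
    candidate and the gene tree; each tree carries equal weight.  Runs in
    O(C(n,4)) per tree, which is the intended desk scale (n <= ~15).
    """
    counts = gene_trees.quartet_counts()
    reg = gene_trees.registry
    cand_presence, cand_splits = tree_splits(candidate, reg)
    score = 0
    for quad, cnt in counts.items():
        qmask = 0
        for i in quad:
            qmask |= 1 << i
        if qmask & cand_presence != qmask:
            continue
        st = quartet_state(cand_splits, *(1 << i for i in quad))
        if st >= 0:
            score += cnt[st]
    return score


# ---------------------------------------------------------------------------
# Topology enumeration and NNI (internal, adjacency representation)


def _enumerate_topologies(n: int):
    """Yield every unrooted binary topology on taxa 0..n-1 as edge lists.

    Trees are grown by inserting taxon m into each edge of each smaller
    tree; nodes >= n are internal.  (2n-5)!! topologies for n taxa.
    """
    base = [(0, n), (1, n), (2, n)]
    stack = [(base, 3, n + 1)]
    while stack:
        edges, m, next_internal = stack.pop()
        if m == n:
            yield edges
            continue
        for ei in range(len(edges)):
            u, v = edges[ei]
            w = next_internal
            new_edges = edges[:ei] + edges[ei + 1 :] + [(u, w), (v, w), (m, w)]
            stack.append((new_edges, m + 1, next_internal + 1))


def _edges_to_splits(edges, n):
    """Nontrivial splits (leaf bitmasks) of an edge-list topology."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def side_mask(u, v):
        # leaves reachable from v without crossing edge (u, v)
        seen = {u, v}
        stack = [v]
        m = 0
        while stack:
            x = stack.pop()
            if x < n:
                m |= 1 << x
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return m

    full = (1 << n) - 1
    splits = []
    for u, v in edges:
        if u >= n and v >= n:
            m = side_mask(u, v)
            if 2 <= bin(m).count("1") <= n - 2:
                splits.append(m)
    return splits


def _edges_to_newick(edges, labels):
    n = len(labels)
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    start = adj[0][0]  # internal neighbor of leaf 0

    def rec(u, parent):
        if u < n:
            return labels[u]
        parts = sorted(rec(v, u) for v in adj[u] if v != parent)
        return "(" + ",".join(parts) + ")"

    parts = sorted([labels[0]] + [rec(v, start) for v in adj[start] if v != 0])
    return "(" + ",".join(parts) + ");"


def _score_edges(edges, n, counts):
    splits = _edges_to_splits(edges, n)
    score = 0
    for quad, cnt in counts.items():
        st = quartet_state(splits, *(1 << i for i in quad))
        if st >= 0:
            score += cnt[st]
    return score


def _nni_neighbors(edges, n):
    """All topologies one NNI move away."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    out = []
    eset = {tuple(sorted(e)) for e in edges}
    for u, v in edges:
        if u < n or v < n:
            continue
        a_nbrs = [x for x in adj[u] if x != v]
        b_nbrs = [x for x in adj[v] if x != u]
        b = a_nbrs[1]
        for c in b_nbrs:
            # swap subtree at b (neighbor of u) with subtree at c (of v)
            new = set(eset)
            new.discard(tuple(sorted((u, b))))
            new.discard(tuple(sorted((v, c))))
            new.add(tuple(sorted((u, c))))
            new.add(tuple(sorted((v, b))))
            out.append([tuple(e) for e in new])
    return out


def _tree_to_edges(tree: dendropy.Tree, reg: TaxonRegistry):
    """Unrooted edge-list encoding of a dendropy tree (suppressing any
    degree-2 root)."""
    n = len(reg)
    next_id = [n]
    ids = {}

    def nid(node):
        if node not in ids:
            if node.is_leaf():
                ids[node] = reg.index[node.taxon.label]
            else:
                ids[node] = next_id[0]
                next_id[0] += 1
        return ids[node]

    edges = []
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            edges.append((nid(node), nid(ch)))
    root = tree.seed_node
    if len(root.child_nodes()) == 2:
        a, b = (nid(c) for c in root.child_nodes())
        r = nid(root)
        edges = [e for e in edges if r not in e] + [(a, b)]
    return edges


def _random_topology(n, rng):
    edges = [(0, n), (1, n), (2, n)]
    nxt = n + 1
    for m in range(3, n):
        ei = int(rng.integers(len(edges)))
        u, v = edges.pop(ei)
        edges += [(u, nxt), (v, nxt), (m, nxt)]
        nxt += 1
    return edges


def _mean_path_distance(gene_trees: GeneTreeSet) -> DistanceMatrix:
    """Average normalized topological (path-edge) distance between taxa
    across gene trees; pairs never co-occurring get the matrix maximum."""
    reg = gene_trees.registry
    n = len(reg)
    tot = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for tree in gene_trees.trees:
        leaves = [lf for lf in tree.leaf_node_iter()]
        if len(leaves) < 2:
            continue
        # path lengths via repeated upward walks (trees are small)
        depth = {}
        parent = {}
        for node in tree.preorder_node_iter():
            parent[node] = node.parent_node
            depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1
        diam = 0
        pairs = []
        for x, y in itertools.combinations(leaves, 2):
            a, b = x, y
            while a is not b:
                if depth[a] < depth[b]:
                    b = parent[b]
                else:
                    a = parent[a]
            d = depth[x] + depth[y] - 2 * depth[a]
            pairs.append((reg.index[x.taxon.label], reg.index[y.taxon.label], d))
            diam = max(diam, d)
        for i, j, d in pairs:
            tot[i, j] += d / diam
            tot[j, i] += d / diam
            cnt[i, j] += 1
            cnt[j, i] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    fill = np.nanmax(mean) if np.isfinite(np.nanmax(mean)) else 1.0
    mean = np.where(np.isnan(mean), fill, mean)
    np.fill_diagonal(mean, 0.0)
    mean = 0.5 * (mean + mean.T)
    return DistanceMatrix(list(reg.labels), mean)


def infer_species_tree(
    gene_trees: GeneTreeSet,
    mode: str = "auto",
    n_restarts: int = 3,
    seed: int = 0,
) -> dendropy.Tree:
    """Topology maximizing the quartet score over the gene-tree set.

    ``mode="exhaustive"`` scores every unrooted topology (feasible for
    n <= 7 taxa); ``mode="nni_hillclimb"`` hill-climbs by NNI from a
    neighbor-joining tree on mean normalized path distances, plus
    ``n_restarts`` random restarts; ``"auto"`` picks exhaustive for
    n <= 7.  Ties are broken by the lexicographically smallest Newick
    string, making the result deterministic.
    """
    reg = gene_trees.registry
    n = len(reg)
    if n < 4:
        raise ValueError("need at least 4 taxa to infer a species tree")
    counts = gene_trees.quartet_counts()
    if mode == "auto":
        mode = "exhaustive" if n <= 7 else "nni_hillclimb"
    if mode not in ("exhaustive", "nni_hillclimb"):
        raise ValueError(f"unknown mode {mode!r}")

    labels = list(reg.labels)
    best_score, best_newick = -1, None

    def consider(edges):
        nonlocal best_score, best_newick
        s = _score_edges(edges, n, counts)
        if s > best_score:
            best_score, best_newick = s, _edges_to_newick(edges, labels)
        elif s == best_score:
            nwk = _edges_to_newick(edges, labels)
            if nwk < best_newick:
                best_newick = nwk

    if mode == "exhaustive":
        for edges in _enumerate_topologies(n):
            consider(edges)
    else:
        rng = np.random.default_rng(seed)
        starts = [_tree_to_edges(neighbor_joining(_mean_path_distance(gene_trees)), reg)]
        starts += [_random_topology(n, rng) for _ in range(n_restarts)]
        for edges in starts:
            cur, cur_score = edges, _score_edges(edges, n, counts)
            improved = True
            while improved:
                improved = False
                for nb in _nni_neighbors(cur, n):
                    s = _score_edges(nb, n, counts)
                    if s > cur_score:
                        cur, cur_score = nb, s
                        improved = True
            consider(cur)

    tree = read_newick(best_newick)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Branch frequencies


@dataclass
class BranchRow:
    branch_id: str
    clusters: tuple  # (A, B, C, D) label tuples; branch pairing is AB|CD
    f_main: float
    f_alt1: float
    f_alt2: float
    n_quartets_resolved: int


@dataclass
class BranchFrequencyTable:
    """Per-internal-branch topology frequencies for a species tree."""

    rows: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "branch_id": [r.branch_id for r in self.rows],
                "cluster_a": [",".join(r.clusters[0]) for r in self.rows],
                "cluster_b": [",".join(r.clusters[1]) for r in self.rows],
                "cluster_c": [",".join(r.clusters[2]) for r in self.rows],
                "cluster_d": [",".join(r.clusters[3]) for r in self.rows],
                "f_main": [r.f_main for r in self.rows],
                "f_alt1": [r.f_alt1 for r in self.rows],
                "f_alt2": [r.f_alt2 for r in self.rows],
                "n_quartets_resolved": [r.n_quartets_resolved for r in self.rows],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_long(self) -> pd.DataFrame:
        """Bar-plot-ready long format: one row per branch x topology."""
        recs = []
        for r in self.rows:
            for name, f in zip(_TOPO_NAMES, (r.f_main, r.f_alt1, r.f_alt2)):
                recs.append(
                    {
                        "branch_id": r.branch_id,
                        "topology": name,
                        "frequency": f,
                        "n_quartets_resolved": r.n_quartets_resolved,
                    }
                )
        return pd.DataFrame(recs)


def _quadripartitions(species_tree: dendropy.Tree, reg: TaxonRegistry):
    """(branch_id, (Amask, Bmask, Cmask, Dmask)) for each internal branch.

    A and B are the clusters below the branch's child node; C and D
    partition the rest of the taxa.  Raises for non-binary trees.
    """
    masks = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            masks[node] = reg.bit(node.taxon.label)
        else:
            ch = node.child_nodes()
            n_ch = 3 if node.parent_node is None else 2
            if len(ch) > n_ch or (node.parent_node is not None and len(ch) != 2):
                raise ValueError(
                    "species tree must be binary; resolve polytomies first"
                )
            masks[node] = 0
            for c in ch:
                masks[node] |= masks[c]
    full = masks[species_tree.seed_node]
    root = species_tree.seed_node
    root_children = root.child_nodes()
    quads = []
    bid = 0
    for node in species_tree.preorder_internal_node_iter(exclude_seed_node=True):
        ch = node.child_nodes()
        a, b = masks[ch[0]], masks[ch[1]]
        rest = full ^ masks[node]
        if bin(rest).count("1") < 2:
            continue  # trivial on the unrooted tree
        parent = node.parent_node
        if parent is root and len(root_children) == 2:
            sib = next(c for c in root_children if c is not node)
            if sib.is_leaf():
                continue  # other side is a single leaf: not internal
            sch = sib.child_nodes()
            c_m, d_m = masks[sch[0]], masks[sch[1]]
            if node is root_children[1]:
                continue  # same unrooted edge as the first root child
        else:
            sibs = [c for c in parent.child_nodes() if c is not node]
            c_m = masks[sibs[0]]
            d_m = full ^ masks[parent]
            if len(sibs) == 2:  # parent is a trifurcating (unrooted) root
                d_m = masks[sibs[1]]
        bid += 1
        quads.append((f"b{bid}", (a, b, c_m, d_m)))
    return quads


def branch_frequencies(
    species_tree: dendropy.Tree,
    gene_trees: GeneTreeSet,
    max_exact: int = 10**6,
    n_subsample: int = 10**5,
    seed: int = 0,
) -> BranchFrequencyTable:
    """Quadripartition topology frequencies for every internal branch.

    For each internal branch with clusters A|B vs C|D, every quartet made
    of one leaf per cluster (restricted to leaves present in the gene
    tree) is tallied as main (AB|CD), alt1 (AC|BD) or alt2 (AD|BC);
    unresolved quartets are excluded from the denominator.  When a branch
    has more than ``max_exact`` quartets in total, ``n_subsample``
    uniformly sampled quartets are used instead (seeded).
    """
    reg = gene_trees.registry
    present_sp = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    missing = [t for t in gene_trees.taxa if t not in present_sp]
    if missing:
        raise ValueError(f"species tree lacks gene-tree taxa: {missing}")
    quads = _quadripartitions(species_tree, reg)
    rng = np.random.default_rng(seed)
    table = BranchFrequencyTable()

    for branch_id, (am, bm, cm, dm) in quads:
        per_tree = []
        total = 0
        for presence, splits in gene_trees._encoded:
            A = [1 << i for i in range(len(reg)) if am & presence & (1 << i)]
            B = [1 << i for i in range(len(reg)) if bm & presence & (1 << i)]
            C = [1 << i for i in range(len(reg)) if cm & presence & (1 << i)]
            D = [1 << i for i in range(len(reg)) if dm & presence & (1 << i)]
            n = len(A) * len(B) * len(C) * len(D)
            if n:
                per_tree.append((splits, A, B, C, D, n))
                total += n
        tally = [0, 0, 0]
        if total <= max_exact:
            for splits, A, B, C, D, _n in per_tree:
                for ba in A:
                    for bb in B:
                        for bc in C:
                            for bd in D:
                                st = quartet_state(splits, ba, bb, bc, bd)
                                if st >= 0:
                                    tally[st] += 1
        elif per_tree:
            weights = np.array([p[5] for p in per_tree], dtype=float)
            weights /= weights.sum()
            picks = rng.choice(len(per_tree), size=n_subsample, p=weights)
            for ti in picks:
                splits, A, B, C, D, _n = per_tree[ti]
                ba = A[rng.integers(len(A))]
                bb = B[rng.integers(len(B))]
                bc = C[rng.integers(len(C))]
                bd = D[rng.integers(len(D))]
                st = quartet_state(splits, ba, bb, bc, bd)
                if st >= 0:
                    tally[st] += 1
        n_res = sum(tally)
        if n_res:
            fr = [t / n_res for t in tally]
        else:
            fr = [0.0, 0.0, 0.0]
        table.rows.append(
            BranchRow(
                branch_id,
                tuple(
                    tuple(reg.labels_of(m)) for m in (am, bm, cm, dm)
                ),
                fr[0],
                fr[1],
                fr[2],
                n_res,
            )
        )
    return table


# ---------------------------------------------------------------------------
# Classification


def classify_discordance(
    table: BranchFrequencyTable, threshold: float = 1.0 / 3.0
) -> tuple[pd.DataFrame, dict]:
    """Label branches by how dominant their main topology is.

    ``single_dominant``: exactly one of the three frequencies exceeds
    ``threshold`` (the paper-style 1/3 line of equal representation);
    ``contested``: two or more exceed it; ``uninformative``: no resolved
    quartets.  Returns the per-branch table plus a summary with the count
    and percentage of single-dominant branches among informative ones.
    """
    recs = []
    for r in table.rows:
        if r.n_quartets_resolved == 0:
            label = "uninformative"
        else:
            n_above = sum(f > threshold for f in (r.f_main, r.f_alt1, r.f_alt2))
            label = "single_dominant" if n_above == 1 else "contested"
        recs.append(
            {
                "branch_id": r.branch_id,
                "f_main": r.f_main,
                "f_alt1": r.f_alt1,
                "f_alt2": r.f_alt2,
                "n_quartets_resolved": r.n_quartets_resolved,
                "label": label,
            }
        )
    df = pd.DataFrame(recs)
    informative = df[df["label"] != "uninformative"]
    n_sd = int((informative["label"] == "single_dominant").sum())
    summary = {
        "n_branches": len(df),
        "n_informative": len(informative),
        "n_single_dominant": n_sd,
        "pct_single_dominant": (
            100.0 * n_sd / len(informative) if len(informative) else float("nan")
        ),
    }
    return df, summary
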