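"""Synthetic data with the statistical structure the pipeline assumes.

Four generators cover the inputs of the downstream stages:

* a Yule species tree with branch lengths in coalescent units,
* gene trees under the multispecies coalescent (MSC) on that species tree,
  with i.i.d. missing taxa — the source of incomplete-lineage-sorting
  discordance whose per-branch expectation is the closed form
  ``f_main = 1 - (2/3) exp(-T)`` for an internal branch of length ``T``,
* Jukes–Cantor sequence alignments along a gene tree,
* per-scaffold read-depth profiles for diploid-like, tetraploid-like and
  partially genome-doubled samples, mimicking mapping of resequencing data
  against an allotetraploid reference whose divergent subgenome is absent
  from diploids,
* consensus sequences with IUPAC ambiguity codes from two-ribotype
  mixtures, as seen in nrDNA assemblies of polyploids.

Every generator takes an integer seed and is bit-reproducible for a fixed
seed and configuration; one ``numpy`` generator is drawn per invocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
import yaml

from .treeops import read_newick

__all__ = [
    "SimConfig",
    "sim_species_tree",
    "sim_gene_trees",
    "sim_alignment",
    "sim_coverage_profiles",
    "sim_ribotype_mixture",
    "DEFAULT_BLOCK_SPEC",
    "IUPAC_PAIR",
]


# two-allele IUPAC codes, keyed by the unordered base pair
IUPAC_PAIR = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

# scaffold blocks: (class, n_scaffolds, base depth multiplier)
DEFAULT_BLOCK_SPEC = [
    ("conserved_all", 30, 1.0),
    ("doubled_block", 45, 1.0),
    ("tetraploid_only", 125, 1.0),
]

# sample-class x scaffold-class mean relative copy number
_CLASS_FACTORS = {
    "diploid_like": {"conserved_all": 1.0, "tetraploid_only": 0.0, "doubled_block": 1.0},
    "tetraploid_like": {"conserved_all": 1.0, "tetraploid_only": 1.0, "doubled_block": 1.0},
    "doubled_subset": {"conserved_all": 1.0, "tetraploid_only": 1.0, "doubled_block": 2.0},
}


@dataclass
class SimConfig:
    """Bundled generator settings, YAML round-trippable."""

    n_taxa: int = 6
    n_loci: int = 100
    seed: int = 0
    birth_rate: float = 1.0
    locus_length: int = 1000
    substitution_rate: float = 0.01
    missing_taxon_prob: float = 0.0
    block_spec: list = field(default_factory=lambda: [list(b) for b in DEFAULT_BLOCK_SPEC])
    noise_cv: float = 0.2
    base_depth: float = 15.0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.missing_taxon_prob <= 1.0:
            raise ValueError("missing_taxon_prob must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Species tree


def sim_species_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Yule (pure-birth) species tree; branch lengths in coalescent units.

    The process starts from the root bifurcation and splits a uniformly
    chosen extant tip after Exp(k * birth_rate) waiting times until
    ``n_taxa`` tips exist; tips are then extended to the present so the
    tree is ultrametric.  Leaves are labelled ``t01, t02, ...`` in left-to-
    right order.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    # node = [birth_time, children]
    root = [0.0, []]
    tips = []
    for _ in range(2):
        ch = [0.0, []]
        root[1].append(ch)
        tips.append(ch)
    t = 0.0
    while len(tips) < n_taxa:
        k = len(tips)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = rng.integers(k)
        parent = tips.pop(idx)
        parent[0] = t
        for _ in range(2):
            ch = [t, []]
            parent[1].append(ch)
            tips.append(ch)
    t_final = t + rng.exponential(1.0 / (len(tips) * birth_rate))
    width = len(str(n_taxa))
    counter = [0]

    def newick(node, parent_time):
        if not node[1]:
            counter[0] += 1
            return f"t{counter[0]:0{width}d}:{t_final - parent_time:.10g}"
        inner = ",".join(newick(ch, node[0]) for ch in node[1])
        return f"({inner}):{node[0] - parent_time:.10g}"

    s = "(" + ",".join(newick(ch, 0.0) for ch in root[1]) + ");"
    tree = read_newick(s)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Multispecies coalescent


def _node_heights(tree: dendropy.Tree) -> dict:
    """Height above the leaves for every node (ultrametric assumption; for
    non-ultrametric input the max over children is used)."""
    h = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            h[node] = 0.0
        else:
            h[node] = max(
                h[ch] + (ch.edge.length or 0.0) for ch in node.child_nodes()
            )
    return h


def _coalesce(lineages, t0, duration, rng):
    """Exponential-rate pairwise coalescence of ``lineages`` starting at
    absolute time ``t0`` within a window of length ``duration``.

    Each lineage is ``(subtree, time)`` where subtree is a nested tuple of
    leaf labels.  Rate is k(k-1)/2 per coalescent unit for k lineages.
    """
    t = t0
    lineages = list(lineages)
    while len(lineages) > 1:
        k = len(lineages)
        w = rng.exponential(2.0 / (k * (k - 1)))
        if t + w > t0 + duration:
            break
        t += w
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        a = lineages[i]
        b = lineages.pop(j)
        lineages[i] = ((a, b), t)
    return lineages


def _lineage_newick(lineage) -> str:
    def rec(node, parent_t):
        s, tt = node
        if isinstance(s, str):
            return f"{s}:{parent_t:.10g}"
        a, b = s
        return f"({rec(a, tt)},{rec(b, tt)}):{parent_t - tt:.10g}"

    s, tt = lineage
    if isinstance(s, str):
        return f"{s}:0;"
    a, b = s
    return f"({rec(a, tt)},{rec(b, tt)});"


def sim_gene_trees(
    species_tree: dendropy.Tree,
    n_loci: int,
    missing_taxon_prob: float = 0.0,
    seed: int = 0,
) -> list[dendropy.Tree]:
    """Simulate gene trees under the MSC on a species tree in coalescent units.

    One lineage is sampled per species; within each species-tree branch
    the k entering lineages coalesce with Exp(k(k-1)/2) waiting times and
    any lineages still distinct above the root merge in an unbounded root
    branch.  Each leaf is then independently dropped with
    ``missing_taxon_prob``; loci left with fewer than 4 leaves are kept
    but flagged via ``tree.informative = False``.

    Gene-tree branch lengths are emitted in coalescent units.
    """
    if not 0.0 <= missing_taxon_prob <= 1.0:
        raise ValueError("missing_taxon_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    heights = _node_heights(species_tree)
    # flatten species tree into postorder instructions
    post = list(species_tree.postorder_node_iter())
    labels = sorted(lf.taxon.label for lf in species_tree.leaf_node_iter())
    tns = dendropy.TaxonNamespace(labels)
    trees = []
    for _ in range(n_loci):
        keep = {
            lab
            for lab in labels
            if missing_taxon_prob == 0.0 or rng.random() >= missing_taxon_prob
        }
        surviving = {}
        for node in post:
            if node.is_leaf():
                lab = node.taxon.label
                pool = [(lab, 0.0)] if lab in keep else []
            else:
                pool = []
                for ch in node.child_nodes():
                    pool.extend(surviving[ch])
            if node.parent_node is None:
                pool = _coalesce(pool, heights[node], np.inf, rng)
            else:
                pool = _coalesce(
                    pool, heights[node], node.edge.length or 0.0, rng
                )
            surviving[node] = pool
        final = surviving[post[-1]]
        if not final:
            gt = dendropy.Tree(taxon_namespace=tns)
            gt.informative = False
            trees.append(gt)
            continue
        gt = read_newick(_lineage_newick(final[0]), taxon_namespace=tns)
        gt.is_rooted = True
        gt.informative = len(keep) >= 4
        trees.append(gt)
    return trees


# ---------------------------------------------------------------------------
# Sequence simulation (Jukes–Cantor)


def sim_alignment(
    gene_tree: dendropy.Tree,
    locus_length: int,
    substitution_rate: float = 1.0,
    seed: int = 0,
) -> dict[str, str]:
    """Evolve sequences along ``gene_tree`` under Jukes–Cantor.

    Branch lengths are multiplied by ``substitution_rate`` to convert them
    to expected substitutions per site (pass 1.0 if they already are).
    Returns ``{leaf label: sequence}``; all sequences share length
    ``locus_length`` so the result is a gap-free alignment.
    """
    if substitution_rate < 0:
        raise ValueError("substitution_rate must be >= 0")
    if locus_length < 1:
        raise ValueError("locus_length must be >= 1")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    states = {}
    out = {}
    for node in gene_tree.preorder_node_iter():
        if node.parent_node is None:
            seq = rng.integers(0, 4, size=locus_length, dtype=np.int8)
        else:
            d = (node.edge.length or 0.0) * substitution_rate
            p_diff = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            seq = states[node.parent_node].copy()
            hit = rng.random(locus_length) < p_diff
            n_hit = int(hit.sum())
            if n_hit:
                # uniform over the three other bases
                seq[hit] = (seq[hit] + rng.integers(1, 4, size=n_hit, dtype=np.int8)) % 4
        states[node] = seq
        if node.is_leaf():
            out[node.taxon.label] = alphabet[seq].tobytes().decode()
    return out


# ---------------------------------------------------------------------------
# Coverage profiles


def sim_coverage_profiles(
    sample_classes,
    block_spec=None,
    noise_cv: float = 0.2,
    seed: int = 0,
    base_depth: float = 15.0,
):
    """Per-scaffold mean mapping depths for synthetic samples.

    ``sample_classes`` is either a mapping ``{sample_id: class}`` or a list
    of class names (ids are generated as ``S001, ...``).  Classes are
    ``diploid_like`` (no reads on the tetraploid-only subgenome),
    ``tetraploid_like`` (uniform coverage) and ``doubled_subset`` (twice
    the depth on a block of conserved scaffolds).  Depths are the class
    mean times ``base_depth`` with multiplicative gamma noise of the given
    coefficient of variation; a zero class mean stays exactly zero.

    Returns ``(depths, scaffolds, truth)``:
    ``depths`` samples x scaffolds DataFrame of raw depths,
    ``scaffolds`` DataFrame (scaffold, length, class),
    ``truth`` DataFrame (sample, true_class).
    """
    if block_spec is None:
        block_spec = DEFAULT_BLOCK_SPEC
    if isinstance(sample_classes, dict):
        items = list(sample_classes.items())
    else:
        width = max(3, len(str(len(sample_classes))))
        items = [
            (f"S{i + 1:0{width}d}", c) for i, c in enumerate(sample_classes)
        ]
    for _, c in items:
        if c not in _CLASS_FACTORS:
            raise ValueError(f"unknown sample class {c!r}")
    for cls_name, n, _mult in block_spec:
        if cls_name not in ("conserved_all", "tetraploid_only", "doubled_block"):
            raise ValueError(f"unknown scaffold class {cls_name!r}")
        if n < 1:
            raise ValueError("block sizes must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")

    rng = np.random.default_rng(seed)
    scaff_ids, scaff_cls, scaff_mult = [], [], []
    i = 0
    for cls_name, n, mult in block_spec:
        for _ in range(n):
            i += 1
            scaff_ids.append(f"scf{i:05d}")
            scaff_cls.append(cls_name)
            scaff_mult.append(float(mult))
    lengths = rng.integers(1200, 50000, size=len(scaff_ids))
    scaff_mult = np.asarray(scaff_mult)

    rows = []
    for sid, cls in items:
        fac = np.array([_CLASS_FACTORS[cls][c] for c in scaff_cls])
        mean = base_depth * scaff_mult * fac
        if noise_cv > 0:
            shape = 1.0 / (noise_cv**2)
            noise = rng.gamma(shape, 1.0 / shape, size=mean.size)
        else:
            noise = np.ones_like(mean)
        rows.append(np.where(mean > 0, mean * noise, 0.0))

    depths = pd.DataFrame(rows, index=[s for s, _ in items], columns=scaff_ids)
    depths.index.name = "sample"
    scaffolds = pd.DataFrame(
        {"scaffold": scaff_ids, "length": lengths, "class": scaff_cls}
    )
    truth = pd.DataFrame(
        {"sample": [s for s, _ in items], "true_class": [c for _, c in items]}
    )
    return depths, scaffolds, truth


# ---------------------------------------------------------------------------
# Ribotype mixtures


def sim_ribotype_mixture(
    base_sequence: str, n_variant_sites: int, seed: int = 0
) -> str:
    """Inject two-allele IUPAC ambiguity codes at random positions.

    Exactly ``n_variant_sites`` positions of ``base_sequence`` are replaced
    by the IUPAC code uniting the resident base with a distinct random
    base, emulating a consensus over two divergent nrDNA ribotypes.
    """
    n = len(base_sequence)
    if n_variant_sites > n:
        raise ValueError("n_variant_sites exceeds sequence length")
    if n_variant_sites < 0:
        raise ValueError("n_variant_sites must be >= 0")
    rng = np.random.default_rng(seed)
    seq = list(base_sequence.upper())
    eligible = [i for i, b in enumerate(seq) if b in "ACGT"]
    if n_variant_sites > len(eligible):
        raise ValueError("not enough unambiguous A/C/G/T sites to vary")
    pos = rng.choice(len(eligible), size=n_variant_sites, replace=False)
    for p in sorted(int(x) for x in pos):
        i = eligible[p]
        others = [b for b in "ACGT" if b != seq[i]]
        alt = others[rng.integers(3)]
        seq[i] = IUPAC_PAIR[frozenset((seq[i], alt))]
    return "".join(seq)
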