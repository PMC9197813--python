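"""Bitmask encodings of tree bipartitions.

Every taxon is assigned a bit in a shared registry; a bipartition (split) is
stored as the integer mask of the leaf set on one side.  Quartet topologies
are then resolved by scanning a tree's splits for one that pairs exactly two
of the four query taxa, which is the inner loop of all quartet tallies.
"""

from __future__ import annotations


class TaxonRegistry:
    """Stable label -> bit-index mapping shared across a tree set."""

    def __init__(self, labels):
        self.labels = sorted(set(labels))
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        self.full_mask = (1 << len(self.labels)) - 1

    def __len__(self):
        return len(self.labels)

    def bit(self, label: str) -> int:
        return 1 << self.index[label]

    def mask(self, labels) -> int:
        m = 0
        for lab in labels:
            m |= 1 << self.index[lab]
        return m

    def labels_of(self, mask: int):
        return [lab for lab in self.labels if mask & (1 << self.index[lab])]


def tree_splits(tree, registry: TaxonRegistry):
    """Return (presence_mask, splits) for a dendropy tree.

    ``splits`` holds one mask per internal edge, each restricted to the
    leaves actually present in the tree; trivial splits (one leaf, or all
    but one) are dropped.  Works identically for rooted and unrooted trees
    because only the induced bipartitions matter.
    """
    masks = {}
    presence = 0
    splits = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            # childless placeholder or taxon outside the registry: absent
            if node.taxon is None or node.taxon.label not in registry.index:
                masks[node] = 0
                continue
            b = registry.bit(node.taxon.label)
            masks[node] = b
            presence |= b
        else:
            m = 0
            for ch in node.child_nodes():
                m |= masks[ch]
            masks[node] = m
    n_present = bin(presence).count("1")
    seen = set()
    for node in tree.postorder_internal_node_iter(exclude_seed_node=True):
        m = masks[node]
        size = bin(m).count("1")
        if size < 2 or n_present - size < 2:
            continue
        # canonicalize on the side not containing the lowest present bit
        low = presence & -presence
        key = m if not (m & low) else (presence ^ m)
        if key in seen:
            continue
        seen.add(key)
        splits.append(m)
    return presence, splits


def quartet_state(splits, ba: int, bb: int, bc: int, bd: int) -> int:
    """Induced topology of quartet (a,b,c,d) given as single-bit masks.

    Returns 0 for ab|cd, 1 for ac|bd, 2 for ad|bc, -1 if unresolved.
    """
    q = ba | bb | bc | bd
    for m in splits:
        pair = m & q
        if bin(pair).count("1") != 2:
            continue
        if pair == ba | bb or pair == bc | bd:
            return 0
        if pair == ba | bc or pair == bb | bd:
            return 1
        if pair == ba | bd or pair == bb | bc:
            return 2
    return -1
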