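"""Shared helpers for the test suite (kept free of package internals)."""


def random_newick(labels, rng):
    """Random binary topology over ``labels`` by sequential joining."""
    parts = list(labels)
    rng.shuffle(parts)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(int(j))
        a = parts.pop(int(i))
        parts.append(f"({a},{b})")
    return parts[0] + ";"
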