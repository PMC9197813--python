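"""MinHash (Mash-style) sketching and genome distance estimation.

A sketch keeps the ``s`` smallest 64-bit hashes of the distinct canonical
k-mers of a sample (bottom-s MinHash).  The Jaccard similarity of two
k-mer sets is estimated from the merged bottom-s region of two sketches,
and converted to a per-site distance with the Mash formula

    d = -(1/k) * ln( 2j / (1 + j) )

which inverts the expected k-mer survival rate under a Poisson model of
substitutions.  Hashing uses a seeded SplitMix64-style 64-bit finalizer;
any fixed, documented 64-bit hash serves the purpose.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass

import numpy as np

from .treeops import DistanceMatrix, neighbor_joining

__all__ = [
    "Sketch",
    "sketch_sequences",
    "sketch_fasta",
    "jaccard_estimate",
    "mash_distance",
    "mash_matrix",
    "mash_tree",
    "canonical_kmer_set",
]

_COMP = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def _mix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Vectorized SplitMix64 finalizer, xor-seeded."""
    z = x.astype(np.uint64) ^ np.uint64(seed * 0x9E3779B97F4A7C15 % (1 << 64))
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@dataclass
class Sketch:
    """Bottom-s set of hashed canonical k-mers for one sample."""

    k: int
    s: int
    hash_seed: int
    hashes: np.ndarray  # sorted ascending, <= s distinct uint64 values
    n_kmers_total: int  # distinct canonical k-mers observed

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "k": self.k,
                    "s": self.s,
                    "hash_seed": self.hash_seed,
                    "n_kmers_total": self.n_kmers_total,
                    "hashes": [int(h) for h in self.hashes],
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "Sketch":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["k"],
            d["s"],
            d["hash_seed"],
            np.array(d["hashes"], dtype=np.uint64),
            d["n_kmers_total"],
        )


def _canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of canonical k-mers (2 bits/base); N windows dropped."""
    b = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(b.size, 255, dtype=np.uint8)
    for i, base in enumerate(b"ACGT"):
        code[b == base] = i
    n = b.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    c64 = code.astype(np.uint64)
    for j in range(k):
        win = code[j : j + n]
        valid &= win <= 3
        fwd |= c64[j : j + n] << np.uint64(2 * (k - 1 - j))
        rev |= (np.uint64(3) - np.minimum(c64[j : j + n], 3)) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    return canon[valid]


def sketch_sequences(
    sequences,
    k: int = 21,
    s: int = 1000,
    hash_seed: int = 42,
    min_kmer_count: int = 1,
) -> Sketch:
    """Bottom-s MinHash sketch of one sample's sequence content.

    ``sequences`` is an iterable of A/C/G/T/N strings (reads or contigs);
    each k-mer is replaced by the smaller of itself and its reverse
    complement before hashing, so sketches are strand- and order-
    invariant.  ``min_kmer_count`` > 1 drops low-copy k-mers (a crude
    sequencing-error filter for raw reads).
    """
    if s <= 0:
        raise ValueError("sketch size s must be positive")
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be a positive odd integer")
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing")
    chunks = [_canonical_kmer_codes(sq, k) for sq in sequences]
    allk = (
        np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
    )
    if min_kmer_count > 1:
        uniq, counts = np.unique(allk, return_counts=True)
        uniq = uniq[counts >= min_kmer_count]
    else:
        uniq = np.unique(allk)
    if uniq.size == 0:
        warnings.warn("no usable k-mers: empty sketch", stacklevel=2)
    hashes = np.sort(_mix64(uniq, hash_seed))
    return Sketch(k, s, hash_seed, hashes[:s].copy(), int(uniq.size))


def sketch_fasta(path, **kwargs) -> Sketch:
    """Sketch a FASTA/FASTQ file (gzip allowed; format sniffed)."""
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        first = fh.read(1)
        fh.seek(0)
        fmt = "fastq" if first == "@" else "fasta"
        seqs = [str(rec.seq) for rec in SeqIO.parse(fh, fmt)]
    return sketch_sequences(seqs, **kwargs)


def jaccard_estimate(a: Sketch, b: Sketch) -> float:
    """Jaccard similarity estimated from the merged bottom-s region."""
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    if a.hash_seed != b.hash_seed:
        raise ValueError("hash seed mismatch")
    s = min(a.s, b.s)
    union = np.union1d(a.hashes, b.hashes)[:s]
    if union.size == 0:
        return 0.0
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    n_shared = int(np.isin(union, shared, assume_unique=True).sum())
    return n_shared / union.size


def mash_distance(j: float, k: int) -> float:
    """Mash distance from a Jaccard estimate; capped at 1.0 for j = 0."""
    if not 0.0 <= j <= 1.0:
        raise ValueError("jaccard must be in [0, 1]")
    if j == 0.0:
        return 1.0
    if j == 1.0:
        return 0.0
    return -np.log(2.0 * j / (1.0 + j)) / k


def mash_matrix(sketches, labels) -> DistanceMatrix:
    """All-pairs Mash distance matrix."""
    n = len(sketches)
    if n != len(labels):
        raise ValueError("labels length mismatch")
    m = np.zeros((n, n))
    for i in range(n):
        for jx in range(i + 1, n):
            d = mash_distance(
                jaccard_estimate(sketches[i], sketches[jx]), sketches[i].k
            )
            m[i, jx] = m[jx, i] = d
    return DistanceMatrix(list(labels), m)


def mash_tree(sketches, labels):
    """Neighbor-joining tree on all-pairs Mash distances."""
    if len(sketches) < 3:
        raise ValueError("need at least 3 sketches")
    return neighbor_joining(mash_matrix(sketches, labels))


def canonical_kmer_set(sequences, k: int) -> set[str]:
    """Exact canonical k-mer set, computed naively on strings.

    Quadratically slower than sketching; intended as an independent
    reference for validating Jaccard estimates on small inputs.
    """
    out = set()
    for sq in sequences:
        sq = sq.upper()
        for i in range(len(sq) - k + 1):
            km = sq[i : i + k]
            if any(c not in "ACGT" for c in km):
                continue
            out.add(min(km, revcomp(km)))
    return out
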