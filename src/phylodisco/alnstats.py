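"""Consensus calling, locus filtering and alignment summary statistics.

Consensus sequences are called from pre-summarized per-site majority
bases with depths (sites under the depth threshold become N), loci are
dropped when too few samples retain a usable consensus, and alignments
are summarized by length, mean pairwise identity, the fraction of
columns identical across all sequences, GC content and IUPAC-ambiguity
accounting.  N is treated as missing data, not as an ambiguity: only the
two/three-allele codes R,Y,S,W,K,M,B,D,H,V carry allele information (in
nrDNA consensus sequences they flag divergent ribotypes retained within
an individual).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConsensusRecord",
    "AlignmentStats",
    "call_consensus",
    "consensus_from_depth_table",
    "filter_locus_set",
    "alignment_summary",
    "read_fasta_alignment",
    "write_fasta",
]

AMBIGUITY_CODES = set("RYSWKMBDHV")


@dataclass
class ConsensusRecord:
    sample_id: str
    locus_id: str
    sequence: str
    callable_fraction: float


@dataclass
class AlignmentStats:
    n_sequences: int
    alignment_length: int
    mean_pairwise_identity: float  # percent
    pct_identical_sites: float  # percent
    gc_content: float  # percent
    ambiguity_counts: dict  # per-sequence residue counts
    n_ambiguous_columns: int  # distinct columns containing any ambiguity
    n_ambiguous_residues: int
    ungapped_lengths: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_sequences": self.n_sequences,
                    "alignment_length": self.alignment_length,
                    "mean_pairwise_identity": self.mean_pairwise_identity,
                    "pct_identical_sites": self.pct_identical_sites,
                    "gc_content": self.gc_content,
                    "n_ambiguous_columns": self.n_ambiguous_columns,
                    "n_ambiguous_residues": self.n_ambiguous_residues,
                }
            ]
        )


# ---------------------------------------------------------------------------
# Consensus


def call_consensus(bases, depths, min_depth: int = 3):
    """Per-site consensus: bases at depth < ``min_depth`` become N.

    ``bases`` is a string or base list, ``depths`` the matching per-site
    read depths.  Returns ``(sequence, callable_fraction)``.
    """
    bases = list(bases)
    depths = list(depths)
    if len(bases) != len(depths):
        raise ValueError("bases and depths differ in length")
    if any(d < 0 for d in depths):
        raise ValueError("negative depth")
    seq = [
        b.upper() if d >= min_depth else "N" for b, d in zip(bases, depths)
    ]
    callable_frac = (
        sum(d >= min_depth for d in depths) / len(depths) if depths else 0.0
    )
    return "".join(seq), callable_frac


def consensus_from_depth_table(df: pd.DataFrame, min_depth: int = 3):
    """ConsensusRecords from a long table (sample, locus, pos, base, depth).

    ``pos`` is 1-based and must cover each locus contiguously.
    """
    required = {"sample", "locus", "pos", "base", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"depth table missing columns: {sorted(missing)}")
    records = []
    for (sample, locus), grp in df.groupby(["sample", "locus"], sort=True):
        grp = grp.sort_values("pos")
        expected = np.arange(1, len(grp) + 1)
        if not np.array_equal(grp["pos"].values, expected):
            raise ValueError(
                f"non-contiguous positions for ({sample}, {locus})"
            )
        seq, frac = call_consensus(
            grp["base"].tolist(), grp["depth"].tolist(), min_depth
        )
        records.append(ConsensusRecord(sample, locus, seq, frac))
    return records


def filter_locus_set(
    records, min_samples: int = 3, min_callable: float = 0.0
):
    """Drop all-N consensus sequences, then under-sampled loci.

    A sample's consensus is unusable when it is entirely N (no callable
    sites) or its callable fraction is below ``min_callable``; loci with
    fewer than ``min_samples`` usable samples are removed.  Returns
    ``(kept_records, report)`` where the report counts casualties of each
    filter.
    """
    records = list(records)
    by_locus: dict = {}
    n_unusable = 0
    for rec in records:
        usable = (
            rec.callable_fraction >= min_callable
            and any(c != "N" for c in rec.sequence)
        )
        if not usable:
            n_unusable += 1
            continue
        by_locus.setdefault(rec.locus_id, []).append(rec)
    kept, dropped_loci = [], []
    for locus, recs in sorted(by_locus.items()):
        if len(recs) < min_samples:
            dropped_loci.append(locus)
        else:
            kept.extend(recs)
    report = {
        "n_input_records": len(records),
        "n_unusable_samples": n_unusable,
        "n_loci_dropped": len(dropped_loci),
        "dropped_loci": dropped_loci,
        "n_loci_kept": len(by_locus) - len(dropped_loci),
    }
    return kept, report


# ---------------------------------------------------------------------------
# Alignment statistics


def _as_pairs(alignment):
    if isinstance(alignment, dict):
        return list(alignment.items())
    return [(name, str(seq)) for name, seq in alignment]


def alignment_summary(
    alignment,
    identical_sites_mode: str = "strict",
    pairwise_gap_mode: str = "exclude",
) -> AlignmentStats:
    """Summary statistics for an equal-length alignment.

    ``alignment`` is a mapping or sequence of (name, sequence) with gaps
    as ``-``.  Conventions (each configurable because the originating
    GUI tools leave them underspecified):

    * mean pairwise identity: mean over unordered pairs of identical
      columns / comparable columns x 100; ``pairwise_gap_mode="exclude"``
      compares only columns where both have a non-gap, ``"include"``
      counts every column (shared gaps match).
    * identical sites: ``"strict"`` requires every sequence non-gap and
      identical in the column; ``"ignore_gaps"`` requires all non-gap
      residues identical (and at least one residue).
    * GC content: (G + C + S) / (A + C + G + T + S) x 100; other
      ambiguity codes, N and gaps are excluded from the denominator.
    * ambiguity counts cover R,Y,S,W,K,M,B,D,H,V only.
    """
    pairs = _as_pairs(alignment)
    if not pairs:
        raise ValueError("empty alignment")
    if identical_sites_mode not in ("strict", "ignore_gaps"):
        raise ValueError(f"unknown identical_sites_mode {identical_sites_mode!r}")
    if pairwise_gap_mode not in ("exclude", "include"):
        raise ValueError(f"unknown pairwise_gap_mode {pairwise_gap_mode!r}")
    length = len(pairs[0][1])
    for name, seq in pairs:
        if len(seq) != length:
            raise ValueError(
                f"sequence {name!r} length {len(seq)} != {length}"
            )
    arr = np.array(
        [list(seq.upper()) for _, seq in pairs], dtype="U1"
    )
    n, L = arr.shape

    # pairwise identity
    idents = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arr[i], arr[j]
            if pairwise_gap_mode == "exclude":
                comp = (a != "-") & (b != "-")
                denom = int(comp.sum())
                same = int(((a == b) & comp).sum())
            else:
                denom = L
                same = int((a == b).sum())
            idents.append(100.0 * same / denom if denom else float("nan"))
    mean_pi = float(np.nanmean(idents)) if idents else float("nan")

    # identical sites
    if identical_sites_mode == "strict":
        no_gap = (arr != "-").all(axis=0)
        all_same = (arr == arr[0]).all(axis=0)
        n_ident = int((no_gap & all_same).sum())
    else:
        n_ident = 0
        for col in arr.T:
            residues = col[col != "-"]
            if residues.size and (residues == residues[0]).all():
                n_ident += 1
    pct_ident = 100.0 * n_ident / L

    # GC
    flat = arr.ravel()
    gc = int(np.isin(flat, list("GCS")).sum())
    denom = int(np.isin(flat, list("ACGTS")).sum())
    gc_content = 100.0 * gc / denom if denom else float("nan")

    # ambiguity accounting
    amb = np.isin(arr, list(AMBIGUITY_CODES))
    amb_per_seq = {
        name: int(amb[i].sum()) for i, (name, _) in enumerate(pairs)
    }
    n_amb_cols = int(amb.any(axis=0).sum())

    ungapped = {
        name: int((arr[i] != "-").sum()) for i, (name, _) in enumerate(pairs)
    }
    return AlignmentStats(
        n_sequences=n,
        alignment_length=L,
        mean_pairwise_identity=mean_pi,
        pct_identical_sites=pct_ident,
        gc_content=gc_content,
        ambiguity_counts=amb_per_seq,
        n_ambiguous_columns=n_amb_cols,
        n_ambiguous_residues=int(amb.sum()),
        ungapped_lengths=ungapped,
    )


# ---------------------------------------------------------------------------
# FASTA helpers


def read_fasta_alignment(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
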