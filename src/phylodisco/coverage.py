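"""Coverage-profile analysis for ploidy and subgenome inference.

Per-scaffold mean mapping depths against an allotetraploid reference are
length-filtered, normalized to a per-sample mean of 1, optionally
restricted to a conserved-scaffold list, clustered by pairwise Manhattan
(L1) distance, and converted to rule-based ploidy calls: diploid-like
samples have near-zero depth on the tetraploid-only subgenome, genome-
doubled samples show roughly twice the average depth over a block of
conserved scaffolds, tetraploid-like samples sit near 1 everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .treeops import DistanceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "CoverageMatrix",
    "PloidyThresholds",
    "load_depth_table",
    "filter_and_normalize",
    "linkage_to_newick",
    "manhattan_cluster",
    "call_ploidy",
    "heatmap_export",
]

_KNOWN_CLASSES = ("conserved_all", "tetraploid_only", "doubled_block", "other")


@dataclass
class CoverageMatrix:
    """Samples x scaffolds depth matrix with scaffold metadata."""

    depths: pd.DataFrame  # rows = samples, columns = scaffolds
    lengths: pd.Series  # scaffold -> bp
    classes: pd.Series  # scaffold -> class label
    normalized: bool = False

    def __post_init__(self):
        self.lengths = self.lengths.reindex(self.depths.columns)
        self.classes = self.classes.reindex(self.depths.columns).fillna("other")
        if (self.depths.values < 0).any():
            raise ValueError("negative depths")
        if (self.lengths < 0).any():
            raise ValueError("negative scaffold lengths")

    @property
    def samples(self) -> list[str]:
        return list(self.depths.index)

    @property
    def scaffolds(self) -> list[str]:
        return list(self.depths.columns)

    def to_tsv(self, path) -> None:
        long = self.depths.stack().rename("depth").reset_index()
        long.columns = ["sample", "scaffold", "depth"]
        long["length"] = self.lengths.reindex(long["scaffold"]).values
        long["class"] = self.classes.reindex(long["scaffold"]).values
        long[["sample", "scaffold", "length", "class", "depth"]].to_csv(
            path, sep="\t", index=False
        )


def load_depth_table(source, classes: pd.Series | None = None) -> CoverageMatrix:
    """Build a CoverageMatrix from a long-format depth table.

    ``source`` is a TSV path or DataFrame with columns sample, scaffold,
    length, depth (and optionally class).  Missing (sample, scaffold)
    pairs are imputed as depth 0 with a logged count; duplicate pairs and
    negative values are errors naming the offending rows.
    """
    df = (
        pd.read_csv(source, sep="\t", comment="#")
        if not isinstance(source, pd.DataFrame)
        else source.copy()
    )
    required = {"sample", "scaffold", "length", "depth"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"depth table missing columns: {sorted(missing_cols)}")
    dup = df.duplicated(subset=["sample", "scaffold"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["sample", "scaffold"]].drop_duplicates()
        raise ValueError(
            "duplicate (sample, scaffold) rows: "
            + "; ".join(f"({r.sample}, {r.scaffold})" for r in pairs.itertuples())
        )
    bad = df[(df["depth"] < 0) | (df["length"] < 0)]
    if len(bad):
        raise ValueError(
            f"negative depth/length in rows: {bad.index.tolist()}"
        )
    lengths = df.groupby("scaffold")["length"].first()
    conflicting = df.groupby("scaffold")["length"].nunique()
    if (conflicting > 1).any():
        raise ValueError(
            f"conflicting lengths for scaffolds: "
            f"{conflicting[conflicting > 1].index.tolist()}"
        )
    wide = df.pivot(index="sample", columns="scaffold", values="depth")
    n_imputed = int(wide.isna().sum().sum())
    if n_imputed:
        log.warning("imputed %d missing (sample, scaffold) pairs as 0", n_imputed)
    wide = wide.fillna(0.0).sort_index()
    wide = wide[sorted(wide.columns)]
    if classes is None:
        if "class" in df.columns:
            classes = df.groupby("scaffold")["class"].first()
        else:
            classes = pd.Series("other", index=wide.columns)
    return CoverageMatrix(wide, lengths, classes)


def filter_and_normalize(
    m: CoverageMatrix,
    min_len: int = 1000,
    conserved_ids=None,
    normalize_after_restriction: bool = False,
) -> CoverageMatrix:
    """Length-filter, normalize per sample to mean 1, restrict columns.

    Scaffolds of length <= ``min_len`` are dropped (strictly "longer
    than" the threshold).  Each sample's depths are divided by its mean
    over the retained scaffolds — by default before any restriction to
    ``conserved_ids``, matching a pipeline that normalizes genome-wide
    and only then zooms in on the conserved set; pass
    ``normalize_after_restriction=True`` for the other order.  Samples
    with zero mean depth are dropped with a warning.
    """
    keep = m.lengths[m.lengths > min_len].index
    depths = m.depths[keep.intersection(m.depths.columns)]
    if conserved_ids is not None:
        conserved = [c for c in depths.columns if c in set(conserved_ids)]
    else:
        conserved = list(depths.columns)
    if normalize_after_restriction:
        depths = depths[conserved]
    means = depths.mean(axis=1)
    zero = means[means == 0].index
    if len(zero):
        log.warning("dropping samples with zero mean depth: %s", list(zero))
        depths = depths.drop(index=zero)
        means = means.drop(index=zero)
    depths = depths.div(means, axis=0)
    if not normalize_after_restriction:
        depths = depths[conserved]
    return CoverageMatrix(
        depths, m.lengths.reindex(depths.columns),
        m.classes.reindex(depths.columns), normalized=True,
    )


def manhattan_cluster(m: CoverageMatrix, linkage: str = "average"):
    """Hierarchical clustering of samples by L1 depth-profile distance.

    Returns ``(distance_matrix, linkage_matrix, leaf_order)``.  Samples
    are sorted by ID before clustering so ties resolve deterministically.
    """
    if len(m.samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    if linkage not in ("average", "single", "complete", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    depths = m.depths.sort_index()
    condensed = pdist(depths.values, metric="cityblock")
    Z = sch.linkage(condensed, method=linkage)
    order = [depths.index[i] for i in sch.leaves_list(Z)]
    dm = DistanceMatrix(list(depths.index), squareform(condensed))
    return dm, Z, order


def linkage_to_newick(Z, labels) -> str:
    """Render a scipy linkage matrix as a Newick string with heights."""
    Z = np.asarray(Z)
    n = len(labels)

    def rec(i, parent_h):
        if i < n:
            return f"{labels[i]}:{parent_h:.6g}"
        a, b, h, _ = Z[int(i) - n]
        return (
            f"({rec(int(a), h / 2)},{rec(int(b), h / 2)}):"
            f"{(parent_h - h / 2):.6g}"
        )

    top = Z[-1][2] / 2
    a, b = int(Z[-1][0]), int(Z[-1][1])
    return f"({rec(a, top)},{rec(b, top)});"


@dataclass
class PloidyThresholds:
    """Tunable cutoffs for the rule-based ploidy caller."""

    diploid_median_max: float = 0.25  # "no (or nearly no) reads mapping"
    doubled_depth_min: float = 1.6  # "double the average genome coverage"
    doubled_frac_min: float = 0.20
    tetraploid_band: tuple = (0.5, 1.5)
    band_edges: tuple = (0.25, 1.5, 1.6)  # reporting bands <, [..], >


def call_ploidy(
    m: CoverageMatrix, thresholds: PloidyThresholds | None = None
) -> pd.DataFrame:
    """Rule-based ploidy class per sample from a normalized matrix.

    Rules fire in order: ``diploid_like`` when the median normalized
    depth over tetraploid_only scaffolds is below ``diploid_median_max``;
    ``doubled_subset`` when at least ``doubled_frac_min`` of conserved
    (non-tetraploid_only) scaffolds exceed ``doubled_depth_min``;
    ``tetraploid_like`` when the overall median sits in
    ``tetraploid_band``; otherwise ``ambiguous``.
    """
    if not m.normalized:
        raise ValueError("call_ploidy requires a normalized matrix")
    th = thresholds or PloidyThresholds()
    tet_only = [c for c in m.scaffolds if m.classes[c] == "tetraploid_only"]
    conserved = [c for c in m.scaffolds if m.classes[c] != "tetraploid_only"]
    if not tet_only:
        log.warning(
            "no tetraploid_only scaffolds defined; diploid rule skipped"
        )
    lo, mid, hi = th.band_edges
    recs = []
    for sample in m.samples:
        row = m.depths.loc[sample]
        med_tet = float(row[tet_only].median()) if tet_only else float("nan")
        frac_high = (
            float((row[conserved] > th.doubled_depth_min).mean())
            if conserved
            else 0.0
        )
        med_all = float(row.median())
        if tet_only and med_tet < th.diploid_median_max:
            cls = "diploid_like"
        elif conserved and frac_high >= th.doubled_frac_min:
            cls = "doubled_subset"
        elif th.tetraploid_band[0] <= med_all <= th.tetraploid_band[1]:
            cls = "tetraploid_like"
        else:
            cls = "ambiguous"
        recs.append(
            {
                "sample": sample,
                "class": cls,
                "median_tetraploid_only_depth": med_tet,
                "frac_below_low": float((row < lo).mean()),
                "frac_mid_band": float(((row >= lo) & (row <= mid)).mean()),
                "frac_above_high": float((row > hi).mean()),
            }
        )
    return pd.DataFrame(recs)


def heatmap_export(
    m: CoverageMatrix, leaf_order, clip: float = 2.0
) -> pd.DataFrame:
    """Long-format (sample, scaffold, value) table for heatmap rendering.

    Values are clipped at ``clip`` for display; rows follow the
    dendrogram leaf order.
    """
    missing = [s for s in leaf_order if s not in m.depths.index]
    if missing:
        raise ValueError(f"leaf_order references unknown samples: {missing}")
    recs = []
    for sample in leaf_order:
        row = m.depths.loc[sample]
        for scaffold, v in row.items():
            recs.append(
                {
                    "sample": sample,
                    "scaffold": scaffold,
                    "value": min(float(v), clip),
                }
            )
    return pd.DataFrame(recs)
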