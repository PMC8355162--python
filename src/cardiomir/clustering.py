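"""Pearson correlation of fold-change profiles and UPGMA clustering.

The miRNA treatments are compared by the Pearson correlation of their
per-gene log2 fold-change vectors and ordered by agglomerative clustering
with the average-linkage (UPGMA) criterion on a Euclidean metric.  The
UPGMA implementation is written out explicitly because reproducible leaf
orderings require a deterministic tie-break (the lexicographically smallest
label pair among minimal distances), which off-the-shelf linkage routines
do not guarantee.

Distances default to Euclidean on the fold-change vectors themselves; the
``on_correlation`` switch clusters rows of the correlation matrix instead
(both conventions are in circulation for fold-change heatmaps).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cardiomir.exceptions import ConfigurationError, NumericalError

log = logging.getLogger(__name__)

_METRICS = {
    "euclidean": lambda x, y: float(np.sqrt(np.sum((x - y) ** 2))),
    "cityblock": lambda x, y: float(np.sum(np.abs(x - y))),
}


def _as_frame(profiles) -> pd.DataFrame:
    """Profiles as a genes x labels DataFrame (mapping of vectors accepted)."""
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in profiles.items()})


def pearson_matrix(profiles) -> pd.DataFrame:
    """Pairwise Pearson correlation of log2 fold-change profiles.

    Gene rows with a missing value in either member of a pair are dropped
    pairwise (and logged).  A constant profile has no defined correlation
    and raises.
    """
    frame = _as_frame(profiles)
    if frame.shape[1] < 2:
        raise ConfigurationError("need at least two profiles")
    labels = list(frame.columns)
    out = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        pair = frame[[a, b]].dropna()
        if len(pair) < 3:
            raise NumericalError(f"fewer than 3 shared genes for {a!r} vs {b!r}")
        dropped = len(frame) - len(pair)
        if dropped:
            log.info("pearson %s vs %s: dropped %d genes with missing values", a, b, dropped)
        x = pair[a].to_numpy()
        y = pair[b].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise NumericalError(f"constant profile in pair ({a!r}, {b!r})")
        r = float(np.corrcoef(x, y)[0, 1])
        out.loc[a, b] = out.loc[b, a] = r
    return out


@dataclass
class LinkageTree:
    """Ordered UPGMA merge events over labelled leaves.

    merges: (members_a, members_b, height, size) with members as sorted
    label tuples; heights are non-decreasing for a metric input.
    """

    labels: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float, int]]

    @property
    def leaf_order(self) -> list[str]:
        """Dendrogram leaf ordering implied by the merge sequence."""
        order: dict[tuple[str, ...], list[str]] = {
            (lab,): [lab] for lab in self.labels
        }
        final = [self.labels[0]] if len(self.labels) == 1 else []
        for a, b, _, _ in self.merges:
            merged = order.pop(a) + order.pop(b)
            order[tuple(sorted(a + b))] = merged
            final = merged
        return final

    def to_newick(self) -> str:
        """Ultrametric Newick string with branch lengths height/2 - child/2."""
        height_of: dict[tuple[str, ...], float] = {(lab,): 0.0 for lab in self.labels}
        newick_of: dict[tuple[str, ...], str] = {(lab,): lab for lab in self.labels}
        last = (self.labels[0],) if self.labels else ()
        for a, b, height, _ in self.merges:
            branch_a = height / 2 - height_of[a] / 2
            branch_b = height / 2 - height_of[b] / 2
            key = tuple(sorted(a + b))
            newick_of[key] = (
                f"({newick_of.pop(a)}:{branch_a:.6g},{newick_of.pop(b)}:{branch_b:.6g})"
            )
            height_of[key] = height
            last = key
        return newick_of[last] + ";"

    def merge_table(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_a": ";".join(a),
                "cluster_b": ";".join(b),
                "height": h,
                "size": s,
            }
            for a, b, h, s in self.merges
        ]
        return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "height", "size"])


def average_linkage_tree(
    profiles,
    metric: str = "euclidean",
    on_correlation: bool = False,
) -> LinkageTree:
    """UPGMA tree over profiles with deterministic tie-breaking.

    Inter-cluster distance is the unweighted mean of all pairwise metric
    distances between the original members (classic UPGMA).  Among minimal
    distances the lexicographically smallest pair of cluster signatures is
    merged first, so permuting the input order relabels but never reshapes
    the tree.
    """
    if metric not in _METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}; options: {sorted(_METRICS)}")
    dist = _METRICS[metric]
    frame = _as_frame(profiles)
    if on_correlation:
        frame = pearson_matrix(frame)  # rows of the correlation matrix as profiles
        frame = frame.T
    labels = list(frame.columns)
    if len(labels) < 2:
        raise ConfigurationError("need at least two profiles")
    vectors = {lab: frame[lab].to_numpy(dtype=float) for lab in labels}
    # pairwise leaf distances; UPGMA averages these within cluster pairs
    d_leaf = {
        frozenset((a, b)): dist(vectors[a], vectors[b])
        for a, b in itertools.combinations(labels, 2)
    }
    clusters: dict[tuple[str, ...], list[str]] = {(lab,): [lab] for lab in labels}
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float, int]] = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            pairs = [
                d_leaf[frozenset((x, y))] for x in clusters[a] for y in clusters[b]
            ]
            d = float(np.mean(pairs))
            key = (d, a, b)
            if best is None or key < best:
                best = key
        d, a, b = best
        members = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, d, len(members)))
        clusters[tuple(sorted(a + b))] = members
    return LinkageTree(labels=labels, merges=merges)


def fc_profiles(de_records: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long-form DE table into a genes x miRNAs log2fc matrix."""
    return de_records.pivot(index="gene_id", columns="mirna", values="log2fc")
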