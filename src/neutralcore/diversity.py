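"""Rarefaction and alpha/beta diversity over feature tables.

Alpha metrics: observed richness, Shannon entropy (bits by default), Pielou
evenness, Faith phylogenetic diversity. Beta metrics: weighted UniFrac
(phylogenetic, abundance-weighted) and Bray-Curtis. Phylogenetic metrics
delegate to scikit-bio; rarefaction is an exact multivariate-hypergeometric
draw (subsampling reads without replacement).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.diversity import beta_diversity

from .datamodel import FeatureTable
from .simulate import stage_rng

__all__ = [
    "rarefy",
    "observed_features",
    "shannon_entropy",
    "pielou_evenness",
    "faith_pd",
    "weighted_unifrac",
    "bray_curtis",
    "alpha_diversity_table",
]


def rarefy(table: FeatureTable, depth: int, seed: int = 0) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Deterministic given the seed; a sample below ``depth`` is an error —
    drop under-sequenced samples first (``drop_low_depth_samples``).
    """
    sizes = table.library_sizes()
    shallow = sizes.index[sizes < depth].tolist()
    if shallow:
        raise ValueError(
            f"samples below rarefaction depth {depth}: {shallow}; drop them first"
        )
    rng = stage_rng(seed, "rarefy")
    counts = table.counts
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth, method="marginals")
    frame = pd.DataFrame(out, index=table.sample_ids, columns=table.taxon_ids)
    return FeatureTable(frame, table.taxonomy)


def observed_features(sample_counts: np.ndarray | pd.Series) -> int:
    """Number of taxa with a nonzero count."""
    return int(np.count_nonzero(np.asarray(sample_counts)))


def shannon_entropy(sample_counts: np.ndarray | pd.Series, base: float = 2.0) -> float:
    """Shannon entropy H' = -sum q_i log_base q_i over nonzero frequencies."""
    counts = np.asarray(sample_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero sample has no entropy")
    q = counts[counts > 0] / total
    return float(-(q * (np.log(q) / np.log(base))).sum()) + 0.0  # avoid -0.0


def pielou_evenness(
    sample_counts: np.ndarray | pd.Series, base: float = 2.0
) -> float:
    """Evenness E = H'/log_base(S); undefined (NaN) below 2 observed taxa."""
    s = observed_features(sample_counts)
    if s < 2:
        return float("nan")
    return shannon_entropy(sample_counts, base) / (np.log(s) / np.log(base))


def faith_pd(
    sample_counts: np.ndarray | pd.Series,
    taxon_ids: list[str],
    tree: TreeNode,
    include_root: bool = True,
) -> float:
    """Faith phylogenetic diversity: branch length of the minimal rooted
    subtree spanning the observed taxa.

    The root-connecting path is included by default (the convention of the
    dominant toolchains); ``include_root=False`` subtracts the path from the
    observed taxa's most recent common ancestor up to the root.
    """
    counts = np.asarray(sample_counts)
    pd_value = float(_skbio_faith_pd(counts, taxa=taxon_ids, tree=tree))
    if not include_root:
        observed = [t for t, c in zip(taxon_ids, counts) if c > 0]
        if observed:
            if len(observed) == 1:
                mrca = tree.find(observed[0])
            else:
                mrca = tree.lowest_common_ancestor(observed)
            node, to_root = mrca, 0.0
            while node.parent is not None:
                to_root += node.length or 0.0
                node = node.parent
            pd_value -= to_root
    return pd_value


def weighted_unifrac(
    table: FeatureTable, tree: TreeNode, normalized: bool = False
) -> skbio.DistanceMatrix:
    """Weighted UniFrac between all sample pairs.

    Unnormalized by default: d(X,Y) = sum_b l_b |x_b - y_b| with x_b the
    fraction of X's reads descending branch b; the normalized variant
    divides by sum_b l_b (x_b + y_b), bounding d in [0, 1].
    """
    _require_positive_depth(table)
    return beta_diversity(
        "weighted_unifrac",
        table.counts,
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree,
        normalized=normalized,
        validate=True,
    )


def bray_curtis(table: FeatureTable) -> skbio.DistanceMatrix:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y) over taxa."""
    _require_positive_depth(table)
    condensed = pdist(table.counts.astype(float), metric="braycurtis")
    return skbio.DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def _require_positive_depth(table: FeatureTable) -> None:
    sizes = table.library_sizes()
    empty = sizes.index[sizes == 0].tolist()
    if empty:
        raise ValueError(f"zero-read samples: {empty}")


def alpha_diversity_table(
    table: FeatureTable,
    tree: TreeNode | None = None,
    base: float = 2.0,
) -> pd.DataFrame:
    """Per-sample alpha diversity: observed S, Shannon H', Pielou E, and —
    when a tree is given — Faith PD."""
    records = []
    for sid in table.sample_ids:
        counts = table.data.loc[sid]
        rec = {
            "sample_id": sid,
            "observed": observed_features(counts),
            "shannon": shannon_entropy(counts, base),
            "pielou": pielou_evenness(counts, base),
        }
        if tree is not None:
            rec["faith_pd"] = faith_pd(counts.to_numpy(), table.taxon_ids, tree)
        records.append(rec)
    return pd.DataFrame(records).set_index("sample_id")
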