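"""Ranked core-microbiome selection from Bray-Curtis contributions.

Taxa are ranked by occupancy (ties by mean relative abundance, then ID) and
admitted into the core as long as each next rank adds at least a threshold
relative increase (default 5%) to the explained mean Bray-Curtis
dissimilarity. Contributions use a fixed full-pair denominator so they are
additive and the cumulative curve reaches exactly 1 at full rank. The core
prefix can then be intersected with the neutral model's over-occupant taxa
to prioritize putatively selected community members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import FeatureTable
from .neutral import OccupancyAbundanceTable

__all__ = [
    "CoreSelection",
    "rank_taxa",
    "bray_curtis_contribution_curve",
    "select_core_members",
    "build_core_selection",
    "over_occupant_core",
    "compare_core_sets",
    "aggregate_class_abundance",
]


@dataclass
class CoreSelection:
    """Ranked taxa with the cumulative contribution curve and core flags."""

    frame: pd.DataFrame  # rank-ordered: occupancy, mean_abundance, E_k, delta_k, core
    threshold: float

    @property
    def core_taxa(self) -> list[str]:
        return list(self.frame.index[self.frame["core"]])

    @property
    def core_size(self) -> int:
        return int(self.frame["core"].sum())


def rank_taxa(oa: OccupancyAbundanceTable) -> list[str]:
    """Deterministic ranking: occupancy desc, mean abundance desc, ID asc."""
    frame = oa.frame
    if frame.empty:
        raise ValueError("empty occupancy-abundance table")
    ordered = frame.sort_values(
        by=["occupancy", "mean_abundance"], ascending=[False, False], kind="stable"
    )
    # resolve remaining ties lexicographically on taxon ID
    ordered = (
        ordered.reset_index()
        .sort_values(
            by=["occupancy", "mean_abundance", "taxon_id"],
            ascending=[False, False, True],
            kind="stable",
        )
        .set_index("taxon_id")
    )
    return list(ordered.index)


def bray_curtis_contribution_curve(
    table: FeatureTable, ranking: list[str]
) -> pd.DataFrame:
    """Cumulative contribution of ranked taxa to mean Bray-Curtis dissimilarity.

    For each rank k, the partial numerator sums |x_i - y_i| over the top-k
    taxa while keeping the full-pair denominator, so per-taxon contributions
    are additive; E_k is the mean partial dissimilarity over all unordered
    sample pairs divided by the mean full dissimilarity. delta_k is the
    relative increase of E_k over E_{k-1} (delta_1 = E_1, the first taxon's
    own share).
    """
    missing = sorted(set(ranking) - set(table.taxon_ids))
    if missing:
        raise ValueError(f"ranking names taxa absent from table: {missing[:5]}")
    counts = table.data[ranking].to_numpy(dtype=float)
    n = counts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    iu, ju = np.triu_indices(n, k=1)
    denom = counts.sum(axis=1)[iu] + counts.sum(axis=1)[ju]
    if (denom == 0).any():
        raise ValueError("zero-read samples present")
    # mean over pairs of |x_t - y_t| / denom, per taxon, in column chunks
    n_taxa = counts.shape[1]
    contrib = np.empty(n_taxa)
    chunk = max(1, int(2e7 // max(len(iu), 1)))
    for start in range(0, n_taxa, chunk):
        block = counts[:, start : start + chunk]
        diff = np.abs(block[iu] - block[ju]) / denom[:, None]
        contrib[start : start + chunk] = diff.mean(axis=0)
    total = contrib.sum()
    if total == 0:
        raise ValueError("no dissimilarity to partition: all samples identical")
    e_k = np.cumsum(contrib) / total
    delta = np.empty(n_taxa)
    delta[0] = e_k[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        delta[1:] = (e_k[1:] - e_k[:-1]) / e_k[:-1]
    return pd.DataFrame(
        {
            "rank": np.arange(1, n_taxa + 1),
            "E_k": e_k,
            "delta_k": delta,
        },
        index=pd.Index(ranking, name="taxon_id"),
    )


def select_core_members(curve: pd.DataFrame, threshold: float = 0.05) -> pd.Series:
    """Prefix rule: the first-ranked taxon anchors the core; subsequent
    ranks are admitted while each delta_k >= threshold, stopping at the
    first failure (later large increments are not reconsidered).

    delta_1 = E_1 is the top taxon's own share of total dissimilarity,
    typically ~1% in a diverse community; requiring it to clear the relative
    threshold would empty the core whenever no single taxon dominates, so
    rank 1 is always admitted (with a warning when its share is below the
    threshold) and the relative-increase rule applies from rank 2.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    delta = curve["delta_k"].to_numpy()
    core = np.zeros(len(delta), dtype=bool)
    core[0] = True
    if delta[0] < threshold:
        warnings.warn(
            "first-ranked taxon's own share is below the threshold; it anchors "
            "the core regardless",
            stacklevel=2,
        )
    for k in range(1, len(delta)):
        if delta[k] >= threshold:
            core[k] = True
        else:
            break
    return pd.Series(core, index=curve.index, name="core")


def build_core_selection(
    table: FeatureTable,
    oa: OccupancyAbundanceTable,
    threshold: float = 0.05,
    partition: pd.DataFrame | None = None,
) -> CoreSelection:
    """Convenience wrapper: rank, curve, core flags, over-occupant flags."""
    ranking = rank_taxa(oa)
    curve = bray_curtis_contribution_curve(table, ranking)
    core = select_core_members(curve, threshold)
    frame = curve.join(oa.frame)
    frame["core"] = core
    if partition is not None:
        frame["partition"] = partition["partition"].reindex(frame.index)
        frame["over_occupant_core"] = frame["core"] & (frame["partition"] == "above")
    return CoreSelection(frame, threshold)


def over_occupant_core(
    core_taxa: set[str] | list[str], partition: pd.DataFrame
) -> set[str]:
    """Core members that also sit above the neutral prediction band."""
    above = set(partition.index[partition["partition"] == "above"])
    return set(core_taxa) & above


def compare_core_sets(
    set_a: set[str] | list[str], set_b: set[str] | list[str]
) -> dict[str, set[str]]:
    """Euler-style partition of two core sets into shared/unique members."""
    a, b = set(set_a), set(set_b)
    return {"shared": a & b, "unique_a": a - b, "unique_b": b - a}


def aggregate_class_abundance(
    table: FeatureTable,
    taxa: set[str] | list[str],
    taxonomy: dict[str, str] | None = None,
    class_rank_index: int = 2,
) -> pd.Series:
    """Mean relative abundance of a taxon subset grouped at class level.

    Lineages are semicolon-delimited rank strings; the class field (index 2,
    kingdom;phylum;class;...) is extracted lazily, with missing or short
    lineages mapped to "Unclassified". The returned per-class sums conserve
    the subset's total mean relative abundance.
    """
    taxonomy = taxonomy if taxonomy is not None else (table.taxonomy or {})
    taxa = [t for t in taxa if t in table.taxon_ids]
    if not taxa:
        return pd.Series(dtype=float)
    rel = table.relative_abundance()[taxa].mean(axis=0)

    def class_of(taxon: str) -> str:
        lineage = taxonomy.get(taxon, "")
        parts = [p.strip() for p in lineage.split(";")] if lineage else []
        if len(parts) > class_rank_index and parts[class_rank_index]:
            return parts[class_rank_index]
        return "Unclassified"

    classes = pd.Series({t: class_of(t) for t in taxa})
    return rel.groupby(classes).sum().sort_values(ascending=False)
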