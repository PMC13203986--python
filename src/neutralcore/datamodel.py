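"""Shared data model and readers/writers for amplicon analysis artifacts.

The canonical in-memory objects are thin wrappers over the containers the
field already uses: a pandas DataFrame of integer counts (samples as rows),
a pandas DataFrame of sample metadata, an :class:`skbio.TreeNode` for the
rooted phylogeny, and :class:`skbio.DistanceMatrix` for pairwise
dissimilarities.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
from skbio import TreeNode

logger = logging.getLogger("neutralcore")

CONDITIONS = ("uninvaded", "invaded", "rhizosphere")

__all__ = [
    "CONDITIONS",
    "FeatureTable",
    "SampleMetadata",
    "AnalysisConfig",
    "ValidationReport",
    "read_feature_table",
    "write_feature_table",
    "read_tree_newick",
    "read_metadata",
    "write_metadata",
    "validate_alignment",
    "drop_low_depth_samples",
    "write_distance_matrix",
    "read_distance_matrix",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full analysis, defaulting to the study's printed settings.

    rarefaction_depth
        Reads retained per sample after subsampling without replacement.
    n_permutations
        Permutations for PERMANOVA / PERMDISP p-values.
    nmds_dimensions
        Target dimensionality k of the non-metric ordination.
    core_threshold
        Minimum relative increase in explained Bray-Curtis dissimilarity a
        ranked taxon must contribute to stay in the core prefix.
    ci_method
        Prediction band used to partition taxa around the neutral fit:
        ``wilson95`` (Wilson score interval) or ``two_sd``.
    shannon_log_base
        Base of the logarithm in Shannon entropy (bits by default).
    unifrac_normalized
        Whether weighted UniFrac is divided by its maximum attainable value.
    """

    rarefaction_depth: int = 4000
    rng_seed: int = 0
    n_permutations: int = 999
    nmds_dimensions: int = 3
    core_threshold: float = 0.05
    ci_method: str = "wilson95"
    shannon_log_base: float = 2.0
    unifrac_normalized: bool = False
    abundance_mode: str = "occupied_only"

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if not 0.0 < self.core_threshold < 1.0:
            raise ValueError("core_threshold must lie in (0, 1)")
        if self.nmds_dimensions < 2:
            raise ValueError("nmds_dimensions must be >= 2")
        if self.ci_method not in ("wilson95", "two_sd"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")
        if self.abundance_mode not in ("occupied_only", "all_samples"):
            raise ValueError(f"unknown abundance_mode {self.abundance_mode!r}")

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def config_hash(self) -> str:
        payload = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


class FeatureTable:
    """Samples x taxa table of non-negative integer counts.

    Parameters
    ----------
    data
        DataFrame with sample IDs as the index and taxon IDs as columns.
        Values must be non-negative integers.
    taxonomy
        Optional map taxon_id -> semicolon-delimited lineage string, stored
        verbatim; rank extraction is lazy.
    """

    def __init__(self, data: pd.DataFrame, taxonomy: Mapping[str, str] | None = None):
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("feature table needs at least one sample and one taxon")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon IDs: {dupes}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0):
                bad = np.argwhere(values != np.round(values))
                i, j = bad[0]
                raise ValueError(
                    "non-integer count "
                    f"{values[i, j]!r} at sample {data.index[i]!r}, taxon {data.columns[j]!r}"
                )
            data = data.astype(np.int64)
            values = data.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)
            i, j = bad[0]
            raise ValueError(
                f"negative count at sample {data.index[i]!r}, taxon {data.columns[j]!r}"
            )
        self._data = data.astype(np.int64)
        self._data.index = self._data.index.astype(str)
        self._data.columns = self._data.columns.astype(str)
        self.taxonomy = dict(taxonomy) if taxonomy else None

    # -- accessors -------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self._data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self._data.shape[1]

    def library_sizes(self) -> pd.Series:
        return self._data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        sizes = self._data.sum(axis=1).to_numpy()
        if (sizes == 0).any():
            raise ValueError("cannot normalize a zero-read sample")
        return self._data.div(self._data.sum(axis=1), axis=0)

    def filter_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self._data.loc[list(sample_ids)], self.taxonomy)

    def drop_empty_taxa(self) -> "FeatureTable":
        keep = self._data.columns[(self._data > 0).any(axis=0)]
        return FeatureTable(self._data[keep], self.taxonomy)

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self._data.equals(other._data)

    def __repr__(self) -> str:
        return f"FeatureTable({self.n_samples} samples x {self.n_taxa} taxa)"


class SampleMetadata:
    """Per-sample design information: year, location, condition, plot.

    (year, location) pairs define the blocking structure used by the
    restricted permutation schemes; condition is case-folded onto the
    three-level enum {uninvaded, invaded, rhizosphere}.
    """

    REQUIRED = ("year", "location", "condition")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs in metadata: {dupes}")
        frame = frame.copy()
        frame.index = frame.index.astype(str)
        frame["condition"] = frame["condition"].astype(str).str.strip().str.casefold()
        bad = sorted(set(frame["condition"]) - set(CONDITIONS))
        if bad:
            raise ValueError(f"unknown condition values: {bad}")
        frame["year"] = frame["year"].astype(int)
        frame["location"] = frame["location"].astype(str)
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def blocks(self) -> pd.Series:
        """Block label per sample: one block per (year, location) pair."""
        return (
            self.frame["year"].astype(str) + "/" + self.frame["location"]
        ).rename("block")

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)])

    def covariate_columns(self) -> list[str]:
        skip = set(self.REQUIRED) | {"plot"}
        return [
            c
            for c in self.frame.columns
            if c not in skip and pd.api.types.is_numeric_dtype(self.frame[c])
        ]

    def __repr__(self) -> str:
        return f"SampleMetadata({len(self.frame)} samples)"


@dataclass
class ValidationReport:
    taxa_missing_from_tree: list[str] = field(default_factory=list)
    samples_missing_from_metadata: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.taxa_missing_from_tree or self.samples_missing_from_metadata)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_feature_table(
    path: str | Path,
    fmt: str = "tsv",
    orientation: str = "auto",
    taxonomy_column: str = "taxonomy",
) -> FeatureTable:
    """Read a feature table from TSV (plain or BIOM-style with ``#OTU ID``).

    ``orientation`` is ``"samples"`` (rows are samples), ``"taxa"``
    (rows are taxa, the convention of most denoisers' exports; transposed on
    read), or ``"auto"``: BIOM-style headers imply taxa-as-rows, otherwise
    samples-as-rows is assumed.
    """
    path = Path(path)
    if fmt not in ("tsv", "biom-tsv"):
        raise ValueError(f"unknown format {fmt!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    lines = [ln for ln in lines if not ln.startswith("# ")]
    if lines and lines[0].startswith("#OTU ID"):
        lines[0] = lines[0][1:]  # biom convention: header comment marker
        if orientation == "auto":
            orientation = "taxa"
    if not lines or len(lines) < 2:
        raise ValueError("no taxa parsed: table body is empty")
    header = lines[0].split("\t")
    ncol = len(header)
    rows, index = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != ncol:
            raise ValueError(
                f"ragged row at line {lineno}: expected {ncol} fields, got {len(parts)}"
            )
        index.append(parts[0])
        rows.append(parts[1:])
    frame = pd.DataFrame(rows, index=index, columns=header[1:])
    taxonomy = None
    if taxonomy_column in frame.columns:
        taxonomy = frame[taxonomy_column].to_dict()
        frame = frame.drop(columns=[taxonomy_column])
    numeric = frame.apply(pd.to_numeric, axis=0)
    if orientation == "auto":
        orientation = "samples"
    if orientation == "taxa":
        numeric = numeric.T
        logger.info("read_feature_table: transposed taxa-as-rows input %s", path.name)
    numeric.index.name = None
    numeric.columns.name = None
    return FeatureTable(numeric, taxonomy)


def write_feature_table(
    table: FeatureTable, path: str | Path, config: AnalysisConfig | None = None
) -> None:
    """Write samples-as-rows TSV; a leading ``# `` comment records provenance."""
    path = Path(path)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# neutralcore config={config.config_hash()} seed={config.rng_seed}\n")
        table.data.to_csv(fh, sep="\t", index_label="sample-id")


def read_tree_newick(path: str | Path) -> TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0 (warned)."""
    tree = TreeNode.read(str(path), format="newick")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        warnings.warn(
            f"{n_missing} branches lacked lengths; treated as 0", stacklevel=2
        )
    return tree


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    frame.columns = [c.replace("-", "_") for c in frame.columns]
    frame.index.name = None
    return SampleMetadata(frame)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.frame.to_csv(path, sep="\t", index_label="sample-id")


def write_distance_matrix(dm: skbio.DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample-id"
    )


def read_distance_matrix(path: str | Path) -> skbio.DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return skbio.DistanceMatrix(frame.to_numpy(), ids=list(frame.index))


# ---------------------------------------------------------------------------
# validation and filtering
# ---------------------------------------------------------------------------

def validate_alignment(
    table: FeatureTable,
    tree: TreeNode | None,
    metadata: SampleMetadata | None,
    strict: bool = False,
) -> ValidationReport:
    """Cross-check the three inputs: every table taxon used by phylogenetic
    metrics must be a tree leaf, every sample should appear in the metadata.

    The tree may be a superset of the table's taxa (references commonly are).
    """
    report = ValidationReport()
    if tree is not None:
        leaves = {t.name for t in tree.tips()}
        report.taxa_missing_from_tree = sorted(set(table.taxon_ids) - leaves)
    if metadata is not None:
        known = set(metadata.sample_ids)
        report.samples_missing_from_metadata = sorted(set(table.sample_ids) - known)
    if not report.ok:
        msg = (
            f"taxa absent from tree: {report.taxa_missing_from_tree[:10]}; "
            f"samples absent from metadata: {report.samples_missing_from_metadata[:10]}"
        )
        if strict:
            raise ValueError(f"alignment check failed: {msg}")
        warnings.warn(msg, stacklevel=2)
    return report


def drop_low_depth_samples(
    table: FeatureTable, depth: int
) -> tuple[FeatureTable, list[str]]:
    """Remove samples whose library size falls below ``depth``.

    Returns the filtered table and the omitted sample IDs, mirroring the
    common practice of discarding under-sequenced samples before rarefying.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    sizes = table.library_sizes()
    keep = sizes.index[sizes >= depth].tolist()
    dropped = sizes.index[sizes < depth].tolist()
    if not keep:
        raise ValueError(f"all {table.n_samples} samples fall below depth {depth}")
    if dropped:
        logger.info("dropped %d samples below depth %d: %s", len(dropped), depth, dropped)
    return table.filter_samples(keep), dropped
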