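"""Synthetic soil-community generator mirroring a two-year invasion survey.

The generator produces feature tables, metadata, and random phylogenies with
the statistical structure the downstream analysis assumes: a lognormal
metacommunity, Sloan-neutral local assembly at a condition-specific
migration rate, Dirichlet-perturbed per-location source pools, a shared
compositional shift plus dispersion contraction in invaded cells, and an
optional set of "selected" taxa whose occupancy is inflated above the
neutral expectation. Defaults emulate the survey design the analysis
targets: 2019 = 6 locations x {uninvaded, invaded} x 10 plots and
2022 = 6 locations x {uninvaded, invaded, rhizosphere} x 10 plots
(300 samples), 4,000 reads per sample, migration rates in the
bacterial-soil range.

All randomness flows from one master seed; each stage derives a child
``numpy.random.Generator`` via ``SeedSequence(master, spawn_key)`` so any
stage is independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datamodel import FeatureTable, SampleMetadata
from .neutral import predicted_occupancy

__all__ = [
    "MetacommunityProfile",
    "SimulationSpec",
    "stage_rng",
    "simulate_metacommunity",
    "simulate_neutral_local_communities",
    "inject_selected_taxa",
    "simulate_invasion_design",
    "simulate_random_tree",
]

_STAGE_KEYS = {
    "metacommunity": 1,
    "local": 2,
    "inject": 3,
    "design": 4,
    "tree": 5,
    "rarefy": 6,
    "shift": 7,
}


def stage_rng(master_seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    """Child generator for a named stage, derived deterministically.

    ``SeedSequence(master_seed, spawn_key=(stage_code, extra))`` — the same
    master seed and stage always yield the same stream, independent of the
    order stages run in.
    """
    key = _STAGE_KEYS.get(stage)
    if key is None:
        raise KeyError(f"unknown stage {stage!r}")
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key, extra)))


@dataclass(frozen=True)
class MetacommunityProfile:
    """Source-pool relative abundances, sorted descending, summing to 1."""

    taxon_ids: tuple[str, ...]
    abundances: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.abundances, float)
        if np.any(p <= 0):
            raise ValueError("metacommunity abundances must be positive")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("metacommunity abundances must sum to 1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def series(self) -> pd.Series:
        return pd.Series(self.abundances, index=list(self.taxon_ids))


def simulate_metacommunity(
    n_taxa: int, mu: float = 0.0, sigma: float = 2.0, seed: int = 0
) -> MetacommunityProfile:
    """Lognormal rank-abundance source pool, normalized and sorted."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = stage_rng(seed, "metacommunity")
    raw = rng.lognormal(mean=mu, sigma=sigma, size=n_taxa)
    raw = np.sort(raw)[::-1]
    p = raw / raw.sum()
    width = len(str(n_taxa))
    ids = tuple(f"ASV{i + 1:0{width}d}" for i in range(n_taxa))
    return MetacommunityProfile(ids, p)


def _neutral_counts(
    p: np.ndarray, n_samples: int, N: int, m: float, rng: np.random.Generator
) -> np.ndarray:
    """Beta-distributed local frequencies, multinomial read sampling."""
    a = np.maximum(N * m * p, 1e-12)
    b = np.maximum(N * m * (1.0 - p), 1e-12)
    freqs = rng.beta(a, b, size=(n_samples, len(p)))
    totals = freqs.sum(axis=1, keepdims=True)
    # a row of all-zero frequencies is theoretically possible at tiny N*m
    totals[totals == 0] = 1.0
    return rng.multinomial(N, freqs / totals)


def simulate_neutral_local_communities(
    profile: MetacommunityProfile,
    n_samples: int,
    N: int,
    m: float,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> FeatureTable:
    """Assemble ``n_samples`` local communities of depth ``N`` neutrally.

    Per sample and taxon the local relative abundance is drawn from
    ``Beta(N*m*p_i, N*m*(1-p_i))``; reads are then drawn multinomially so
    every row sums to exactly ``N``.
    """
    if not 0.0 < m <= 1.0:
        raise ValueError("m must lie in (0, 1]")
    if N < 1 or n_samples < 1:
        raise ValueError("N and n_samples must be >= 1")
    rng = stage_rng(seed, "local")
    counts = _neutral_counts(np.asarray(profile.abundances), n_samples, N, m, rng)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    frame = pd.DataFrame(counts, index=list(sample_ids), columns=list(profile.taxon_ids))
    return FeatureTable(frame)


def inject_selected_taxa(
    table: FeatureTable,
    profile: MetacommunityProfile,
    taxa: Sequence[str],
    inflation: float,
    m: float,
    seed: int = 0,
) -> FeatureTable:
    """Force chosen taxa to be over-occupant relative to the neutral law.

    Each taxon's target occupancy is ``min(1, inflation * o_hat)`` where
    ``o_hat`` is its neutral predicted occupancy at migration rate ``m``.
    The taxon's existing reads are redistributed evenly over the enlarged
    occupied set (extra samples drawn at random), so its presence pattern
    changes while its total (all-sample mean) abundance does not —
    isolating the over-occupancy signal from differential abundance. Rows
    that gained a presence have their remaining taxa resampled
    multinomially so every row sum stays at the table's depth.
    """
    if inflation < 1:
        raise ValueError("inflation must be >= 1")
    missing = sorted(set(taxa) - set(table.taxon_ids))
    if missing:
        raise ValueError(f"taxa not in table: {missing}")
    if inflation == 1.0:
        return FeatureTable(table.data.copy(), table.taxonomy)
    sizes = table.library_sizes().to_numpy()
    if len(np.unique(sizes)) != 1:
        raise ValueError("inject_selected_taxa requires a uniform-depth table")
    N = int(sizes[0])
    rng = stage_rng(seed, "inject")
    data = table.data.to_numpy().copy()
    cols = {t: j for j, t in enumerate(table.taxon_ids)}
    p = profile.series()
    n = table.n_samples
    selected_cols: list[int] = []
    touched_rows: set[int] = set()
    for taxon in taxa:
        j = cols[taxon]
        o_hat = predicted_occupancy(float(p[taxon]), m, N)
        target_k = int(round(min(1.0, inflation * o_hat) * n))
        occupied = np.flatnonzero(data[:, j] > 0)
        total = int(data[:, j].sum())
        target_k = min(target_k, total)  # cannot occupy more samples than reads
        if len(occupied) >= target_k:
            if len(occupied) == n:
                warnings.warn(
                    f"taxon {taxon} already occupies every sample; no-op", stacklevel=2
                )
            continue
        absent = np.flatnonzero(data[:, j] == 0)
        add = rng.choice(absent, size=target_k - len(occupied), replace=False)
        members = np.concatenate([occupied, add])
        base, rem = divmod(total, target_k)
        alloc = np.full(target_k, base, dtype=np.int64)
        if rem:
            alloc[rng.choice(target_k, size=rem, replace=False)] += 1
        data[members, j] = alloc
        selected_cols.append(j)
        touched_rows.update(members.tolist())
    if selected_cols:
        sel = np.array(sorted(set(selected_cols)))
        others = np.setdiff1d(np.arange(data.shape[1]), sel)
        base_p = np.asarray(profile.abundances)[others]
        for i in sorted(touched_rows):
            remainder = N - int(data[i, sel].sum())
            weights = data[i, others].astype(float)
            if weights.sum() == 0:
                weights = base_p
            data[i, others] = rng.multinomial(remainder, weights / weights.sum())
    frame = pd.DataFrame(data, index=table.sample_ids, columns=table.taxon_ids)
    return FeatureTable(frame, table.taxonomy)


@dataclass(frozen=True)
class SimulationSpec:
    """Design and effect sizes of a simulated invasion survey.

    The default design is the study layout the pipeline analyzes:
    two years, six locations per year, 10 plots per condition cell, with
    rhizosphere sampled only in the second year; 4,000 reads per sample.
    Migration rates default to the bacterial-soil range of the fitted
    neutral models (0.042-0.050). ``dispersion_contraction`` multiplies the
    between-sample spread of invaded communities (biotic homogenization);
    ``condition_shift`` scales a lognormal compositional shift shared by
    invaded and rhizosphere cells; ``selected_inflation`` is the occupancy
    inflation applied to ``n_selected`` mid-occupancy taxa.
    """

    n_taxa: int = 5000
    reads_per_sample: int = 4000
    plots_per_cell: int = 10
    design: Mapping[int, tuple[tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=lambda: {
            2019: (
                ("L01", "L02", "L03", "L04", "L05", "L06"),
                ("uninvaded", "invaded"),
            ),
            2022: (
                ("L07", "L08", "L09", "L10", "L11", "L12"),
                ("uninvaded", "invaded", "rhizosphere"),
            ),
        }
    )
    migration: Mapping[str, float] = field(
        default_factory=lambda: {
            "uninvaded": 0.043,
            "invaded": 0.050,
            "rhizosphere": 0.042,
        }
    )
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    location_concentration: float = 500.0
    condition_shift: float = 0.3
    dispersion_contraction: float = 0.7
    n_selected: int = 25
    selected_inflation: float = 2.0
    omit_samples: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        for cond, m in self.migration.items():
            if not 0.0 < m <= 1.0:
                raise ValueError(f"migration rate for {cond} must lie in (0, 1]")
        if self.selected_inflation < 1:
            raise ValueError("selected_inflation must be >= 1")
        if not 0.0 < self.dispersion_contraction <= 1.0:
            raise ValueError("dispersion_contraction must lie in (0, 1]")
        if not self.design:
            raise ValueError("empty design")

    @classmethod
    def null(cls, m: float = 0.045, **kwargs) -> "SimulationSpec":
        """A no-effect design: equal migration, no shift, no contraction,
        no selected taxa — conditions are exchangeable within location."""
        return cls(
            migration={"uninvaded": m, "invaded": m, "rhizosphere": m},
            condition_shift=0.0,
            dispersion_contraction=1.0,
            n_selected=0,
            **kwargs,
        )

    def n_samples(self) -> int:
        total = sum(
            len(locs) * len(conds) * self.plots_per_cell
            for locs, conds in self.design.values()
        )
        return total - self.omit_samples


def _contracted_nm(N: int, m: float, contraction: float) -> float:
    """Effective N*m reproducing a ``contraction``-fold shrink of the
    between-sample frequency SD: Var = p(1-p)/(N*m+1)."""
    return ((N * m + 1.0) / contraction**2 - 1.0) / N


def simulate_invasion_design(
    spec: SimulationSpec,
) -> tuple[FeatureTable, SampleMetadata, dict]:
    """Simulate the full survey: table, metadata, and the ground truth.

    Location signal comes from Dirichlet-perturbed metacommunities (taxa
    remain shared across locations); invaded and rhizosphere cells share one
    multiplicative compositional shift; invaded cells are additionally
    homogenized by the dispersion-contraction factor. Ground truth records
    true migration rates, the selected taxa, and the effect sizes.
    """
    seed = spec.rng_seed
    profile = simulate_metacommunity(
        spec.n_taxa, spec.lognormal_mu, spec.lognormal_sigma, seed
    )
    base_p = np.asarray(profile.abundances)
    N = spec.reads_per_sample

    shift_rng = stage_rng(seed, "shift")
    if spec.condition_shift > 0:
        shift_vec = np.exp(spec.condition_shift * shift_rng.standard_normal(spec.n_taxa))
    else:
        shift_vec = np.ones(spec.n_taxa)

    design_rng = stage_rng(seed, "design")
    rows, meta_rows, ids = [], [], []
    for year, (locations, conditions) in sorted(spec.design.items()):
        for loc in locations:
            alpha = np.maximum(spec.location_concentration * base_p, 1e-8)
            p_loc = design_rng.dirichlet(alpha)
            p_loc = np.maximum(p_loc, 1e-12)
            p_loc = p_loc / p_loc.sum()
            for cond in conditions:
                p_cell = p_loc
                if cond in ("invaded", "rhizosphere"):
                    p_cell = p_loc * shift_vec
                    p_cell = p_cell / p_cell.sum()
                m = spec.migration[cond]
                if cond == "invaded" and spec.dispersion_contraction < 1.0:
                    m_eff = _contracted_nm(N, m, spec.dispersion_contraction)
                    m_eff = min(m_eff, 1.0)
                else:
                    m_eff = m
                counts = _neutral_counts(
                    p_cell, spec.plots_per_cell, N, m_eff, design_rng
                )
                rows.append(counts)
                for plot in range(1, spec.plots_per_cell + 1):
                    sid = f"{year}.{loc}.{cond}.{plot:02d}"
                    ids.append(sid)
                    meta_rows.append(
                        {"year": year, "location": loc, "condition": cond, "plot": f"P{plot:02d}"}
                    )
    counts = np.vstack(rows)
    frame = pd.DataFrame(counts, index=ids, columns=list(profile.taxon_ids))
    table = FeatureTable(frame)

    selected: list[str] = []
    if spec.n_selected > 0:
        m_ref = spec.migration["uninvaded"]
        o_hat = predicted_occupancy(base_p, m_ref, N)
        candidates = np.flatnonzero((o_hat >= 0.2) & (o_hat <= 0.6))
        pick_rng = stage_rng(seed, "inject", extra=1)
        chosen = pick_rng.choice(
            candidates, size=min(spec.n_selected, len(candidates)), replace=False
        )
        selected = [profile.taxon_ids[j] for j in sorted(chosen)]
        table = inject_selected_taxa(
            table, profile, selected, spec.selected_inflation, m_ref, seed
        )

    if spec.omit_samples > 0:
        omit_rng = stage_rng(seed, "design", extra=1)
        drop = omit_rng.choice(ids, size=spec.omit_samples, replace=False)
        keep = [s for s in ids if s not in set(drop)]
        table = table.filter_samples(keep)
        meta_frame = pd.DataFrame(meta_rows, index=ids).loc[keep]
    else:
        meta_frame = pd.DataFrame(meta_rows, index=ids)

    metadata = SampleMetadata(meta_frame)
    ground_truth = {
        "migration": dict(spec.migration),
        "selected_taxa": selected,
        "selected_inflation": spec.selected_inflation,
        "condition_shift": spec.condition_shift,
        "dispersion_contraction": spec.dispersion_contraction,
        "n_taxa": spec.n_taxa,
        "reads_per_sample": N,
        "rng_seed": seed,
    }
    return table, metadata, ground_truth


def simulate_random_tree(taxon_ids: Sequence[str], seed: int = 0) -> TreeNode:
    """Random bifurcating rooted tree over ``taxon_ids`` with exponential
    branch lengths (mean 1); supports the phylogenetic metrics."""
    if len(taxon_ids) < 2:
        raise ValueError("need at least 2 taxa")
    rng = stage_rng(seed, "tree")
    nodes = [TreeNode(name=str(t), length=float(rng.exponential())) for t in taxon_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = TreeNode(children=[a, b], length=float(rng.exponential()))
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root
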