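"""Sloan neutral community model: occupancy-abundance fitting and partition.

The model treats each local community as a sample of ``N`` reads whose
underlying relative abundance for a taxon with metacommunity frequency ``p``
follows ``Beta(N*m*p, N*m*(1-p))`` — the continuous large-community limit of
neutral birth/death/immigration dynamics, where ``m`` is the migration
(immigration) rate coupling the local community to the source pool. A taxon
is detected when its local frequency exceeds the detection limit
``d = 1/N``, so its expected occupancy across samples is the upper tail of
that beta law. Fitting a single ``m`` to all taxa's observed occupancies by
least squares, and asking which taxa sit above or below the prediction band,
partitions the community into neutrally assembled, putatively selected
(over-occupant), and dispersal-limited (under-occupant) fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import beta as beta_dist

from .datamodel import FeatureTable

__all__ = [
    "OccupancyAbundanceTable",
    "NeutralFit",
    "occupancy_abundance",
    "predicted_occupancy",
    "fit_migration_rate",
    "classify_neutral_partition",
    "partition_counts",
]

_M_BOUNDS = (1e-6, 1.0)
_M_STARTS = (0.001, 0.01, 0.1, 0.5)


@dataclass
class OccupancyAbundanceTable:
    """Per-taxon occupancy and mean relative abundance at uniform depth N.

    ``frame`` columns: ``occupancy`` (fraction of samples with count > 0)
    and ``mean_abundance`` (mean relative abundance, either over occupied
    samples only or over all samples, per ``abundance_mode``).
    """

    frame: pd.DataFrame
    n_samples: int
    depth: int
    abundance_mode: str

    @property
    def detection_limit(self) -> float:
        return 1.0 / self.depth

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class NeutralFit:
    """Result of fitting the single-parameter neutral occupancy curve."""

    m: float
    r_squared: float
    table: OccupancyAbundanceTable
    predicted: pd.Series
    at_bounds: bool
    sse: float

    @property
    def n_taxa(self) -> int:
        return len(self.predicted)


def occupancy_abundance(
    table: FeatureTable, abundance_mode: str = "occupied_only"
) -> OccupancyAbundanceTable:
    """Compute per-taxon occupancy and mean relative abundance.

    Requires a rarefied table (uniform library size); taxa observed nowhere
    are dropped. ``abundance_mode='occupied_only'`` averages relative
    abundance over the samples where the taxon is present;
    ``'all_samples'`` averages over every sample (the convention of the
    widely used reference implementation).
    """
    if abundance_mode not in ("occupied_only", "all_samples"):
        raise ValueError(f"unknown abundance_mode {abundance_mode!r}")
    sizes = table.library_sizes().to_numpy()
    if len(np.unique(sizes)) != 1:
        raise ValueError(
            "library sizes are not uniform; rarefy to a common depth first"
        )
    depth = int(sizes[0])
    counts = table.counts
    present = counts > 0
    occupancy = present.mean(axis=0)
    keep = occupancy > 0
    rel = counts / depth
    if abundance_mode == "occupied_only":
        with np.errstate(invalid="ignore"):
            mean_ab = np.where(
                present.sum(axis=0) > 0,
                rel.sum(axis=0) / np.maximum(present.sum(axis=0), 1),
                0.0,
            )
    else:
        mean_ab = rel.mean(axis=0)
    frame = pd.DataFrame(
        {"occupancy": occupancy[keep], "mean_abundance": mean_ab[keep]},
        index=pd.Index(np.asarray(table.taxon_ids)[keep], name="taxon_id"),
    )
    return OccupancyAbundanceTable(frame, table.n_samples, depth, abundance_mode)


def predicted_occupancy(
    p: np.ndarray | float, m: float, N: int, d: float | None = None
) -> np.ndarray | float:
    """Neutral expectation of occupancy for metacommunity frequency ``p``.

    ``1 - BetaCDF(d; N*m*p, N*m*(1-p))``: the probability that the local
    relative abundance of a taxon exceeds the detection limit ``d`` (one
    read out of ``N`` by default).
    """
    if not 0.0 < m <= 1.0:
        raise ValueError("m must lie in (0, 1]")
    if d is None:
        d = 1.0 / N
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("p must lie strictly in (0, 1)")
    a = N * m * p_arr
    b = N * m * (1.0 - p_arr)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("degenerate beta parameters")
    out = beta_dist.sf(d, a, b)
    return float(out) if np.isscalar(p) else out


def fit_migration_rate(
    oa: OccupancyAbundanceTable,
    init_m: float | None = None,
    bounds: tuple[float, float] = _M_BOUNDS,
) -> NeutralFit:
    """Estimate the migration rate by least squares on the occupancy curve.

    Minimizes ``sum_i (o_i - o_hat_i(m))^2`` over ``m`` with bounded scalar
    optimization from several starting brackets; the best SSE wins.
    R-squared is computed against the mean-occupancy null and may be
    negative when occupancy carries no abundance signal.
    """
    if len(oa) < 10:
        raise ValueError("need at least 10 taxa to fit the neutral curve")
    if len(oa) < 50:
        warnings.warn("fewer than 50 taxa; the fit may be unstable", stacklevel=2)
    o = oa.frame["occupancy"].to_numpy()
    p = oa.frame["mean_abundance"].to_numpy()
    N, d = oa.depth, oa.detection_limit

    def sse(m: float) -> float:
        pred = beta_dist.sf(d, N * m * p, N * m * (1.0 - p))
        return float(np.sum((o - pred) ** 2))

    starts = list(_M_STARTS)
    if init_m is not None:
        starts.insert(0, init_m)
    best_m, best_sse = None, np.inf
    lo, hi = bounds
    edges = sorted(set([lo] + [s for s in starts if lo < s < hi] + [hi]))
    for left, right in zip(edges[:-1], edges[1:]):
        res = optimize.minimize_scalar(
            sse, bounds=(left, right), method="bounded", options={"xatol": 1e-10}
        )
        if res.fun < best_sse:
            best_sse, best_m = float(res.fun), float(res.x)
    if best_m is None or not np.isfinite(best_sse):
        raise RuntimeError("migration-rate optimization failed to converge")
    at_bounds = bool(
        np.isclose(best_m, lo, rtol=0, atol=1e-9)
        or np.isclose(best_m, hi, rtol=0, atol=1e-9)
    )
    pred = beta_dist.sf(d, N * best_m * p, N * best_m * (1.0 - p))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    r2 = 1.0 - best_sse / ss_tot if ss_tot > 0 else np.nan
    return NeutralFit(
        m=best_m,
        r_squared=r2,
        table=oa,
        predicted=pd.Series(pred, index=oa.frame.index, name="predicted_occupancy"),
        at_bounds=at_bounds,
        sse=best_sse,
    )


def _wilson_interval(p_hat: np.ndarray, n: int, z: float = 1.959963984540054):
    """Wilson score interval for a proportion ``p_hat`` observed over n trials."""
    denom = 1.0 + z**2 / n
    center = (p_hat + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2))
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


def classify_neutral_partition(
    fit: NeutralFit, ci_method: str = "wilson95"
) -> pd.DataFrame:
    """Label each taxon above / neutral / below the neutral prediction band.

    ``wilson95`` draws the band as the Wilson score 95% interval around the
    predicted occupancy at the study's sample count; ``two_sd`` uses plus or
    minus two binomial standard deviations (the plotted-band convention).
    Returns the occupancy-abundance frame with ``predicted``, ``lower``,
    ``upper`` and ``partition`` columns.
    """
    pred = fit.predicted.to_numpy()
    n = fit.table.n_samples
    if ci_method == "wilson95":
        lower, upper = _wilson_interval(pred, n)
    elif ci_method == "two_sd":
        sd = np.sqrt(pred * (1.0 - pred) / n)
        lower = np.clip(pred - 2 * sd, 0, 1)
        upper = np.clip(pred + 2 * sd, 0, 1)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    o = fit.table.frame["occupancy"].to_numpy()
    partition = np.where(o > upper, "above", np.where(o < lower, "below", "neutral"))
    out = fit.table.frame.copy()
    out["predicted"] = pred
    out["lower"] = lower
    out["upper"] = upper
    out["partition"] = partition
    return out


def partition_counts(partition: pd.DataFrame) -> pd.Series:
    """Counts per partition label, always reporting all three labels."""
    counts = partition["partition"].value_counts()
    return counts.reindex(["above", "neutral", "below"], fill_value=0)
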