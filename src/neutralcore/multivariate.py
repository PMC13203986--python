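"""Community-level statistics on distance matrices and alpha diversity.

The centerpiece is a nested PERMANOVA with restricted (blocked)
permutations: sequential sums of squares of a Gower-centered distance matrix
over Year -> Location-in-Year -> Condition-in-Location-in-Year, with
permutation p-values computed by exchanging samples only within their
(year, location) block — so the condition effect is tested against the
within-location null while spatial structure stays fixed. Dispersion
homogeneity (PERMDISP) and non-metric multidimensional scaling support the
biotic-homogenization analysis; Kruskal-Wallis, Spearman, and REML
mixed-model contrasts cover the univariate side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy import stats
from sklearn.manifold import MDS

from .datamodel import SampleMetadata

__all__ = [
    "PermanovaResult",
    "DispersionResult",
    "OrdinationResult",
    "AlphaContrastResult",
    "nested_permanova",
    "permdisp",
    "nmds",
    "kruskal_wallis_by_group",
    "spearman_assoc",
    "alpha_mixed_model_contrasts",
]


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()

def _codes(labels: pd.Series) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(labels, sort=True)
    return codes.astype(np.int64), len(uniques)


def _group_trace(g: np.ndarray, codes: np.ndarray, k: int) -> float:
    """tr(H G) for the hat matrix H of a one-hot group design (incl. mean)."""
    w = np.zeros((len(codes), k))
    w[np.arange(len(codes)), codes] = 1.0
    counts = w.sum(axis=0)
    a = g @ w
    return float(((w * a).sum(axis=0) / counts).sum())


def _block_permutations(
    blocks: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Index arrays permuting positions only within identical block labels."""
    n = len(blocks)
    perms = np.tile(np.arange(n), (n_perm, 1))
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        for r in range(n_perm):
            perms[r, idx] = rng.permutation(idx)
    return perms


# ---------------------------------------------------------------------------
# nested PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    terms: list[str]
    df: list[int]
    ss: list[float]
    r_squared: list[float]
    pseudo_f: list[float]
    p_values: list[float]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, df, ss, r2, f, p in zip(
            self.terms, self.df, self.ss, self.r_squared, self.pseudo_f, self.p_values
        ):
            rows.append({"term": name, "df": df, "SS": ss, "R2": r2, "F": f, "P": p})
        rows.append(
            {
                "term": "Residual",
                "df": self.residual_df,
                "SS": self.residual_ss,
                "R2": self.residual_ss / self.total_ss,
                "F": np.nan,
                "P": np.nan,
            }
        )
        rows.append(
            {
                "term": "Total",
                "df": self.residual_df + sum(self.df),
                "SS": self.total_ss,
                "R2": 1.0,
                "F": np.nan,
                "P": np.nan,
            }
        )
        return pd.DataFrame(rows).set_index("term")


def nested_permanova(
    dist: skbio.DistanceMatrix,
    metadata: SampleMetadata,
    terms: tuple[str, ...] = ("year", "location", "condition"),
    blocks: tuple[str, ...] | None = ("year", "location"),
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential PERMANOVA over a nested design with blocked permutations.

    ``terms`` are metadata columns, nested cumulatively: the k-th term's
    groups are the distinct combinations of ``terms[:k+1]``, so with the
    default the partition is Year, then Location within Year, then Condition
    within Location within Year. Degrees of freedom follow the group counts
    (e.g. condition df = sum over (year, location) cells of levels - 1).
    p-values come from re-deriving every term's pseudo-F after shuffling
    samples within blocks; ``blocks=None`` permutes freely. The +1
    convention ``p = (1 + #{F* >= F}) / (1 + n_perm)`` keeps p off zero.
    """
    meta = metadata.subset(list(dist.ids)).frame
    g = _gower_center(dist.data.astype(float))
    n = g.shape[0]
    total_ss = float(np.trace(g))
    rng = np.random.default_rng(seed)

    # cumulative nested labels: term k groups = combinations of terms[:k+1]
    combo = meta[terms[0]].astype(str)
    term_codes, term_k = [], []
    for t, col in enumerate(terms):
        if t > 0:
            combo = combo + "/" + meta[col].astype(str)
        # a term level with <2 samples makes the cell unestimable
        sizes = combo.value_counts()
        thin = sizes[sizes < 2].index.tolist()
        if thin:
            raise ValueError(f"design cell(s) with <2 samples for term {col!r}: {thin}")
        codes, k = _codes(combo)
        term_codes.append(codes)
        term_k.append(k)

    traces = [_group_trace(g, c, k) for c, k in zip(term_codes, term_k)]
    prev_tr, prev_k = 0.0, 1  # grand-mean projection contributes 0 on centered G
    ss, df = [], []
    for tr_k, k in zip(traces, term_k):
        ss.append(tr_k - prev_tr)
        df.append(k - prev_k)
        prev_tr, prev_k = tr_k, k
    residual_ss = total_ss - traces[-1]
    residual_df = n - term_k[-1]
    if residual_df <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    ms_res = residual_ss / residual_df
    pseudo_f = [(s / d) / ms_res for s, d in zip(ss, df)]
    r2 = [s / total_ss for s in ss]

    if blocks is not None:
        block_labels = meta[list(blocks)].astype(str).agg("/".join, axis=1).to_numpy()
    else:
        block_labels = np.zeros(n, dtype=int)
    perms = _block_permutations(np.asarray(block_labels), n_perm, rng)

    # sanity: permutations must never move a sample across blocks
    assert all(
        (np.asarray(block_labels)[perms[r]] == np.asarray(block_labels)).all()
        for r in range(min(n_perm, 5))
    )

    exceed = np.zeros(len(terms))
    for r in range(n_perm):
        pi = perms[r]
        traces_p = [
            _group_trace(g, c[pi], k) for c, k in zip(term_codes, term_k)
        ]
        prev = 0.0
        ss_p = []
        for tr_k in traces_p:
            ss_p.append(tr_k - prev)
            prev = tr_k
        res_p = total_ss - traces_p[-1]
        ms_res_p = res_p / residual_df
        for t in range(len(terms)):
            f_star = (ss_p[t] / df[t]) / ms_res_p
            if f_star >= pseudo_f[t] - 1e-12:
                exceed[t] += 1
    p_values = [(1.0 + e) / (1.0 + n_perm) for e in exceed]

    names = []
    for t, col in enumerate(terms):
        names.append(col if t == 0 else f"{col} in " + " in ".join(terms[:t][::-1]))
    return PermanovaResult(
        terms=names,
        df=df,
        ss=ss,
        r_squared=r2,
        pseudo_f=pseudo_f,
        p_values=p_values,
        residual_df=residual_df,
        residual_ss=residual_ss,
        total_ss=total_ss,
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    distances: pd.Series
    group_means: pd.Series
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    n_permutations: int


def _pcoa_axes(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes split into real (positive-eigenvalue) and
    imaginary (negative-eigenvalue) subspaces."""
    g = _gower_center(d)
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = np.abs(vals).max() * 1e-10 if len(vals) else 0.0
    pos = vals > tol
    neg = vals < -tol
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag


def _spatial_median(x: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Weiszfeld iteration for the geometric (L1) median."""
    if x.shape[0] == 0 or x.shape[1] == 0:
        return np.zeros(x.shape[1])
    c = x.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(x - c, axis=1)
        if np.any(d < 1e-12):  # median coincides with a point
            return c
        w = 1.0 / d
        c_new = (x * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(c_new - c) < tol:
            return c_new
        c = c_new
    return c


def permdisp(
    dist: skbio.DistanceMatrix,
    groups: pd.Series,
    center: str = "spatial_median",
    n_perm: int = 999,
    seed: int = 0,
    blocks: pd.Series | None = None,
) -> DispersionResult:
    """Permutational test of multivariate dispersion homogeneity.

    Samples are embedded by principal coordinates; each sample's distance to
    its group center (spatial median by default, centroid optional) is
    computed with the imaginary-axis correction for negative eigenvalues
    (squared real-part distance minus squared imaginary-part distance,
    floored at zero) — never by truncating negative axes. The F statistic on
    those distances has (k-1, n-k) df; its p-value comes from permuting
    group labels (freely by default, within ``blocks`` when given).
    """
    if center not in ("spatial_median", "centroid"):
        raise ValueError(f"unknown center {center!r}")
    groups = groups.loc[list(dist.ids)]
    labels, k = _codes(groups)
    n = len(labels)
    sizes = np.bincount(labels, minlength=k)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        bad = [groups.unique()[i] for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"singleton group(s): {bad}")
    real, imag = _pcoa_axes(dist.data.astype(float))

    dists = np.empty(n)
    for gidx in range(k):
        members = np.flatnonzero(labels == gidx)
        if center == "centroid":
            c_r = real[members].mean(axis=0)
            c_i = imag[members].mean(axis=0) if imag.size else np.zeros(0)
        else:
            c_r = _spatial_median(real[members])
            c_i = _spatial_median(imag[members]) if imag.size else np.zeros(0)
        d2 = ((real[members] - c_r) ** 2).sum(axis=1)
        if imag.size:
            d2 = d2 - ((imag[members] - c_i) ** 2).sum(axis=1)
        dists[members] = np.sqrt(np.maximum(d2, 0.0))

    def f_stat(z: np.ndarray, lab: np.ndarray) -> float:
        grand = z.mean()
        means = np.array([z[lab == gi].mean() for gi in range(k)])
        ss_b = float((sizes * (means - grand) ** 2).sum())
        ss_w = float(sum(((z[lab == gi] - means[gi]) ** 2).sum() for gi in range(k)))
        if ss_w == 0:
            return np.inf
        return (ss_b / (k - 1)) / (ss_w / (n - k))

    f_obs = f_stat(dists, labels)
    rng = np.random.default_rng(seed)
    if blocks is not None:
        perms = _block_permutations(blocks.loc[list(dist.ids)].to_numpy(), n_perm, rng)
    else:
        perms = np.vstack([rng.permutation(n) for _ in range(n_perm)])
    exceed = sum(
        1 for r in range(n_perm) if f_stat(dists, labels[perms[r]]) >= f_obs - 1e-12
    )
    p = (1.0 + exceed) / (1.0 + n_perm)
    group_names = pd.factorize(groups, sort=True)[1]
    means = pd.Series(
        [dists[labels == gi].mean() for gi in range(k)], index=group_names
    )
    return DispersionResult(
        distances=pd.Series(dists, index=list(dist.ids)),
        group_means=means,
        f_statistic=f_obs,
        df_between=k - 1,
        df_within=n - k,
        p_value=p,
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    converged: bool
    n_restarts: int


def nmds(
    dist: skbio.DistanceMatrix,
    k: int = 3,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric multidimensional scaling (rank-based stress-1 minimization).

    Best of ``n_restarts`` random initializations; non-convergence is
    reported in the ``converged`` flag, never raised.
    """
    if k >= len(dist.ids):
        raise ValueError("k must be smaller than the number of samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MDS(
            n_components=k,
            metric_mds=False,
            dissimilarity="precomputed",
            n_init=n_restarts,
            max_iter=max_iter,
            eps=tol,
            random_state=np.random.default_rng(seed).integers(2**31),
            normalized_stress=True,
        )
        coords = model.fit_transform(dist.data.astype(float))
    frame = pd.DataFrame(
        coords, index=list(dist.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        coordinates=frame,
        stress=float(model.stress_),
        converged=bool(model.n_iter_ < max_iter),
        n_restarts=n_restarts,
    )


def stress1(dissimilarity: np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against input dissimilarities,
    with disparities from isotonic regression on the dissimilarity order."""
    from scipy.spatial.distance import pdist
    from sklearn.isotonic import IsotonicRegression

    d_in = dissimilarity[np.triu_indices_from(dissimilarity, k=1)]
    d_out = pdist(coordinates)
    order = np.argsort(d_in, kind="stable")
    disparities = np.empty_like(d_out)
    disparities[order] = IsotonicRegression().fit_transform(
        np.arange(len(d_in)), d_out[order]
    )
    return float(np.sqrt(((d_out - disparities) ** 2).sum() / (d_out**2).sum()))


# ---------------------------------------------------------------------------
# univariate statistics
# ---------------------------------------------------------------------------

def kruskal_wallis_by_group(
    values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray
) -> tuple[float, int, float]:
    """Rank-based Kruskal-Wallis test; returns (H, df, p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if np.all(values == values[0]):
        return 0.0, len(samples) - 1, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), len(samples) - 1, float(p)


def spearman_assoc(
    x: pd.Series | np.ndarray, y: pd.Series | np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation with tie handling; (rho, asymptotic p).

    Zero variance in either vector leaves rho undefined -> (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# mixed-model contrasts for alpha diversity
# ---------------------------------------------------------------------------

@dataclass
class AlphaContrastResult:
    means: pd.Series
    contrasts: pd.DataFrame
    condition_wald_chi2: float
    condition_wald_p: float
    model: str


def alpha_mixed_model_contrasts(
    alpha: pd.Series,
    metadata: SampleMetadata,
    year: int,
) -> AlphaContrastResult:
    """Condition effect on an alpha-diversity metric within one year.

    Fits a REML linear mixed model with condition as a fixed effect and a
    random intercept per sampling location, then reports all pairwise
    condition mean contrasts with Tukey-adjusted p-values (studentized-range
    distribution on the residual degrees of freedom). With a single
    location the random effect is dropped (warning) and an ordinary linear
    model is used. Years are modeled independently because rhizosphere
    sampling is unbalanced across years.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    meta = metadata.frame
    keep = meta.index[meta["year"] == year]
    keep = [s for s in keep if s in alpha.index]
    if not keep:
        raise ValueError(f"no samples for year {year}")
    df = pd.DataFrame(
        {
            "value": alpha.loc[keep].astype(float),
            "condition": meta.loc[keep, "condition"],
            "location": meta.loc[keep, "location"],
        }
    ).dropna()
    conditions = sorted(df["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    n_loc = df["location"].nunique()
    k = len(conditions)

    if n_loc > 1:
        model_name = "mixed"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(
                "value ~ C(condition)", df, groups=df["location"]
            ).fit(reml=True)
        resid_df = len(df) - k - (n_loc - 1)
    else:
        warnings.warn(
            "single location: random effect dropped, ordinary linear model used",
            stacklevel=2,
        )
        model_name = "ols"
        fit = smf.ols("value ~ C(condition)", df).fit()
        resid_df = int(fit.df_resid)
    resid_df = max(resid_df, 2)

    # condition means from treatment-coded fixed effects
    names = list(fit.params.index)
    fixed = [nm for nm in names if nm == "Intercept" or nm.startswith("C(condition)")]
    beta = fit.params[fixed]
    cov = pd.DataFrame(fit.cov_params()).loc[fixed, fixed]
    design = {}
    for cond in conditions:
        row = pd.Series(0.0, index=fixed)
        row["Intercept"] = 1.0
        key = f"C(condition)[T.{cond}]"
        if key in row.index:
            row[key] = 1.0
        design[cond] = row
    means = pd.Series({c: float(design[c] @ beta) for c in conditions})

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = conditions[i], conditions[j]
            lvec = design[b] - design[a]
            est = float(lvec @ beta)
            se = float(np.sqrt(lvec @ cov.to_numpy() @ lvec))
            t = est / se if se > 0 else np.inf
            q = abs(t) * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, resid_df))
            rows.append(
                {"contrast": f"{b} - {a}", "estimate": est, "se": se,
                 "df": resid_df, "t": t, "p_tukey": p}
            )
    contrasts = pd.DataFrame(rows).set_index("contrast")

    cond_terms = [nm for nm in fixed if nm != "Intercept"]
    if cond_terms:
        L = np.zeros((len(cond_terms), len(names)))
        for r, nm in enumerate(cond_terms):
            L[r, names.index(nm)] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wt = fit.wald_test(L, scalar=True)
        chi2 = float(wt.statistic) * len(cond_terms) if model_name == "ols" else float(wt.statistic)
        wald_p = float(stats.chi2.sf(chi2, len(cond_terms)))
    else:
        chi2, wald_p = np.nan, np.nan
    return AlphaContrastResult(
        means=means,
        contrasts=contrasts,
        condition_wald_chi2=chi2,
        condition_wald_p=wald_p,
        model=model_name,
    )
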