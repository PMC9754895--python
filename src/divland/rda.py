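"""Genotype/copy-number-environment association.

Redundancy analysis (RDA) regresses a column-centered multivariate response
(sample x variant dosages, or sample x gene copy numbers) on standardized
environmental predictors and decomposes the fitted values by SVD. The
constrained eigenvalues are squared singular values over (n - 1) and the
proportion of response variance explained is their sum over the total
response variance. Axis significance comes from permuting predictor rows
and comparing eigenvalues (add-one empirical tail, sequential stopping).
Outlier variants load more than 3 SD from the mean on a significant axis
and are assigned the predictor with the largest |Pearson r| to their
dosage; |r| > 0.6 flags a strong association.

Supporting steps mirror a standard landscape-genomics workflow: greedy
removal of autocorrelated predictors (|r| >= 0.7), PLINK-style LD pruning
(r^2 > 0.4 within 20-kb windows advanced two markers per step), and Mantel
isolation-by-distance / by-environment tests of linearized F_ST
(F_ST / (1 - F_ST)) between populations against haversine geographic and
Euclidean environmental distances.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from divland.genotypes import GenotypeTable
from divland.windows import site_fst_components

__all__ = [
    "filter_predictors",
    "ld_prune",
    "RdaResult",
    "fit_rda",
    "test_axes",
    "assign_predictors",
    "call_outlier_variants",
    "haversine_km",
    "mantel_test",
    "pairwise_population_fst",
    "mantel_ibd_ibe",
]

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------- predictors

def filter_predictors(env: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Drop autocorrelated predictors until all pairwise |r| < threshold.

    Greedy: repeatedly drop the predictor with the most partners at
    |Pearson r| >= threshold; ties broken by larger mean |r| to all others,
    then lexicographically. Constant predictors are dropped first with a
    warning. Deterministic.
    """
    env = env.copy()
    constant = [c for c in env.columns if env[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant predictors: {constant}")
        env = env.drop(columns=constant)
    if env.shape[1] < 2:
        return env
    while True:
        corr = env.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        partners = (corr >= threshold).sum(axis=0)
        if partners.max() == 0:
            return env
        worst = partners.max()
        tied = sorted(partners.index[partners == worst])
        if len(tied) > 1:
            mean_r = corr.loc[tied].mean(axis=1)
            tied = sorted(mean_r.index[mean_r == mean_r.max()])
        env = env.drop(columns=tied[0])


# ------------------------------------------------------------------ pruning

def _impute_center(X):
    """Column-wise mean-impute NaNs, then center columns."""
    X = np.array(X, dtype=float)
    mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mean, inds[1])
    return X - X.mean(axis=0)


def ld_prune(
    gt: GenotypeTable,
    r2_threshold: float = 0.4,
    window_bp: int = 20_000,
    step_markers: int = 2,
) -> np.ndarray:
    """Indices of SNPs kept after sliding-window LD pruning.

    Windows of ``window_bp`` start at every ``step_markers``-th marker;
    within a window the later-position member of any pair with dosage r^2
    above the threshold is removed, and removals accumulate genome-wide.
    Because consecutive windows overlap in all but their newest markers,
    this is evaluated incrementally: each marker is tested, in position
    order, against the surviving markers of the first window that contains
    it (equivalently, the kept markers within the preceding ``window_bp``,
    at the start-granularity set by ``step_markers``). Deterministic.
    """
    removed = np.zeros(gt.n_variants, dtype=bool)
    for c in pd.unique(gt.chrom):
        idx = np.flatnonzero(gt.chrom == c)
        pos = gt.pos[idx]
        X = _impute_center(gt.dosage[idx].T).T  # variants x samples, centered
        norms = np.sqrt((X**2).sum(axis=1))
        n = len(idx)
        starts = np.arange(0, n, step_markers)
        # first window start whose bp span reaches marker j
        start_of = np.searchsorted(pos[starts] + window_bp, pos, side="right")
        for j in range(1, n):
            if norms[j] == 0:
                continue
            lo = starts[start_of[j]] if start_of[j] < len(starts) else j
            if lo >= j:
                continue
            cand = np.arange(lo, j)
            cand = cand[~removed[idx[cand]] & (norms[cand] > 0)]
            if cand.size == 0:
                continue
            r = (X[cand] @ X[j]) / (norms[cand] * norms[j])
            if np.any(r * r > r2_threshold):
                removed[idx[j]] = True
    return np.flatnonzero(~removed)


# --------------------------------------------------------------------- RDA

@dataclass
class RdaResult:
    """Fitted redundancy analysis.

    eigenvalues: constrained-axis eigenvalues (non-increasing).
    proportion: per-axis share of the total response variance.
    variant_scores: (variants x axes) loadings (right singular vectors
        scaled by singular values).
    sample_scores: (samples x axes) site scores.
    total_variance: total response variance (sum of column variances).
    predictors: predictor names used in the fit.
    axis_p: per-axis permutation p-values (set by :func:`test_axes`).
    """

    eigenvalues: np.ndarray
    proportion: np.ndarray
    variant_scores: np.ndarray
    sample_scores: np.ndarray
    total_variance: float
    predictors: list
    axis_p: np.ndarray | None = None

    @property
    def proportion_explained(self) -> float:
        return float(self.proportion.sum())


def _standardize(X):
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant predictor column; filter predictors first")
    return (X - X.mean(axis=0)) / sd


def fit_rda(response, env, standardize_response: bool = False) -> RdaResult:
    """Redundancy analysis of a (samples x variants) response on predictors.

    The response is mean-imputed and column-centered (optionally
    standardized); predictors are standardized. Raises on rank-deficient
    predictor matrices.
    """
    env_df = pd.DataFrame(env)
    X = _standardize(env_df.to_numpy(dtype=float))
    n, q = X.shape
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("predictor matrix is rank-deficient after filtering")
    Y = _impute_center(np.asarray(response, dtype=float))
    if standardize_response:
        sd = Y.std(axis=0, ddof=1)
        Y = Y / np.where(sd == 0, 1.0, sd)
    if Y.shape[0] != n:
        raise ValueError("response and env sample counts differ")

    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    F = X @ B
    U, s, Vt = np.linalg.svd(F, full_matrices=False)
    rank = min(q, Y.shape[1])
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]

    eig = s**2 / (n - 1)
    total_var = float((Y**2).sum() / (n - 1))
    return RdaResult(
        eigenvalues=eig,
        proportion=eig / total_var if total_var > 0 else eig * 0.0,
        variant_scores=Vt.T * s,
        sample_scores=U * s,
        total_variance=total_var,
        predictors=list(env_df.columns),
    )


def test_axes(
    response,
    env,
    n_perm: int = 999,
    alpha: float = 0.01,
    seed: int = 0,
    standardize_response: bool = False,
):
    """Permutation test of constrained axes (sequential stopping).

    Permutes the rows of the predictor matrix, refits, and compares each
    axis eigenvalue to its null draws (add-one empirical tail). Axes are
    assessed in order and testing stops after the first non-significant
    axis. Returns ``(rda, p_values)`` where ``p_values[k]`` is NaN for
    untested axes; ``rda.axis_p`` is set.
    """
    env_df = pd.DataFrame(env)
    n, q = env_df.shape
    if n < q + 2:
        raise ValueError("need n_samples >= n_predictors + 2")
    rda = fit_rda(response, env_df, standardize_response=standardize_response)

    # permutation nulls need only the constrained eigenvalues: project the
    # response onto the permuted predictors' orthonormal basis and take
    # singular values of the small q x m matrix
    X = _standardize(env_df.to_numpy(dtype=float))
    Y = _impute_center(np.asarray(response, dtype=float))
    if standardize_response:
        sd = Y.std(axis=0, ddof=1)
        Y = Y / np.where(sd == 0, 1.0, sd)
    rank = len(rda.eigenvalues)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, rank))
    for b in range(n_perm):
        perm = rng.permutation(n)
        Q, _ = np.linalg.qr(X[perm])
        s = np.linalg.svd(Q.T @ Y, compute_uv=False)
        null[b] = s[:rank] ** 2 / (n - 1)
    p = np.full(len(rda.eigenvalues), np.nan)
    for k in range(len(rda.eigenvalues)):
        p[k] = (np.count_nonzero(null[:, k] >= rda.eigenvalues[k]) + 1.0) / (
            n_perm + 1.0
        )
        if p[k] >= alpha:
            break
    rda.axis_p = p
    return rda, p


def assign_predictors(response_columns, env, r_threshold: float = 0.6) -> pd.DataFrame:
    """Best-correlated predictor per variant column.

    ``response_columns`` is (samples x variants); for each variant the
    predictor maximizing |Pearson r| with its (imputed, centered) values is
    returned, with ``strong`` flagging |r| > ``r_threshold``.
    """
    env_df = pd.DataFrame(env)
    Y = _impute_center(np.asarray(response_columns, dtype=float))
    E = _standardize(env_df.to_numpy(dtype=float))
    if Y.shape[1] == 0:
        return pd.DataFrame(columns=["predictor", "r", "strong"])
    rows = []
    for v in range(Y.shape[1]):
        y = Y[:, v]
        if y.std() == 0:
            rows.append({"predictor": None, "r": np.nan, "strong": False})
            continue
        rs = np.array([np.corrcoef(y, E[:, j])[0, 1] for j in range(E.shape[1])])
        best = int(np.argmax(np.abs(rs)))
        rows.append(
            {
                "predictor": env_df.columns[best],
                "r": float(rs[best]),
                "strong": bool(abs(rs[best]) > r_threshold),
            }
        )
    return pd.DataFrame(rows)


def call_outlier_variants(
    rda: RdaResult,
    response,
    env,
    significant_axes=None,
    sd_mult: float = 3.0,
    r_threshold: float = 0.6,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """3-SD loading outliers on significant axes with predictor assignment.

    ``significant_axes`` defaults to the axes with ``rda.axis_p < alpha``.
    For each outlier variant, the predictor maximizing |Pearson r| with the
    variant's (imputed) values is assigned; ``strong`` flags |r| above
    ``r_threshold``. Outlier status uses strict ``|z| > sd_mult`` on any
    significant axis.
    """
    env_df = pd.DataFrame(env)
    if significant_axes is None:
        if rda.axis_p is None:
            raise ValueError("run test_axes first or pass significant_axes")
        significant_axes = [
            k for k, p in enumerate(rda.axis_p) if p == p and p < alpha
        ]
    scores = rda.variant_scores
    if len(scores) < 100:
        warnings.warn("fewer than 100 variants; loading SD is unstable")
    z = np.zeros((scores.shape[0], len(significant_axes)))
    for j, k in enumerate(significant_axes):
        load = scores[:, k]
        sd = load.std()
        if sd == 0:
            continue
        z[:, j] = (load - load.mean()) / sd
    out_mask = (np.abs(z) > sd_mult).any(axis=1) if z.size else np.zeros(
        scores.shape[0], dtype=bool
    )

    out_idx = np.flatnonzero(out_mask)
    Y = np.asarray(response, dtype=float)
    assigned = assign_predictors(Y[:, out_idx], env_df, r_threshold=r_threshold)
    assigned.insert(0, "variant_index", out_idx)
    assigned.insert(
        1, "max_abs_z", [float(np.abs(z[v]).max()) for v in out_idx]
    )
    return assigned.loc[assigned["predictor"].notna()].reset_index(drop=True)


# ------------------------------------------------------------------ Mantel

def haversine_km(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = (
        np.sin((la2 - la1) / 2.0) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2
    )
    return float(2.0 * radius * np.arcsin(np.sqrt(h)))


def mantel_test(dist_x, dist_y, n_perm: int = 999, seed: int = 0, exact: bool | None = None):
    """One-tailed Mantel correlation between two distance matrices.

    r is the Pearson correlation of the lower triangles; p permutes the
    row/column order of the second matrix (add-one, one-tailed r_null >= r).
    With ``exact=True`` (default for <= 6 units) all n! permutations are
    enumerated and p is the exact fraction with r_null >= r.
    """
    Dx = np.asarray(dist_x, dtype=float)
    Dy = np.asarray(dist_y, dtype=float)
    n = Dx.shape[0]
    if Dx.shape != (n, n) or Dy.shape != (n, n):
        raise ValueError("distance matrices must be square and same size")
    il = np.tril_indices(n, k=-1)
    x = Dx[il]

    def _r(perm):
        y = Dy[np.ix_(perm, perm)][il]
        if x.std() == 0 or y.std() == 0:
            return np.nan
        return np.corrcoef(x, y)[0, 1]

    r_obs = _r(np.arange(n))
    if exact is None:
        exact = n <= 6
    if exact:
        rs = np.array([_r(np.array(p)) for p in itertools.permutations(range(n))])
        p = float(np.count_nonzero(rs >= r_obs - 1e-12) / len(rs))
    else:
        rng = np.random.default_rng(seed)
        hits = sum(
            _r(rng.permutation(n)) >= r_obs - 1e-12 for _ in range(n_perm)
        )
        p = (hits + 1.0) / (n_perm + 1.0)
    return float(r_obs), p


def pairwise_population_fst(gt: GenotypeTable, snp_index=None) -> pd.DataFrame:
    """Weir-Cockerham ratio-of-sums F_ST between every pair of populations.

    Uses the table's ``populations`` labels; optionally restricted to a SNP
    index subset. Returns a symmetric DataFrame.
    """
    if gt.populations is None:
        raise ValueError("GenotypeTable has no population labels")
    sub = gt if snp_index is None else gt.subset_variants(snp_index)
    pops = pd.unique(gt.populations)
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for p1, p2 in itertools.combinations(pops, 2):
        d1 = sub.dosage[:, gt.populations == p1]
        d2 = sub.dosage[:, gt.populations == p2]
        a, d, valid = site_fst_components(d1, d2)
        den = d[valid].sum()
        fst = a[valid].sum() / den if den != 0 else np.nan
        mat.loc[p1, p2] = mat.loc[p2, p1] = fst
    return mat


def mantel_ibd_ibe(
    pop_fst: pd.DataFrame,
    pop_coords: pd.DataFrame,
    pop_env: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Mantel tests of linearized F_ST against geographic and env distance.

    ``pop_fst`` is a population x population F_ST matrix; ``pop_coords``
    has lat/lon per population; ``pop_env`` holds population-mean predictor
    values (standardized internally). Pairs with F_ST = 1 cannot be
    linearized and are excluded with a warning (their rows/columns are
    dropped). Requires >= 4 populations.
    """
    pops = list(pop_fst.index)
    F = pop_fst.to_numpy(dtype=float)
    bad = np.zeros(len(pops), dtype=bool)
    bad_pair = (F >= 1.0) | np.isnan(F)
    np.fill_diagonal(bad_pair, False)
    if bad_pair.any():
        warnings.warn(
            "F_ST = 1 or undefined pair(s): cannot linearize, dropping "
            "populations"
        )
        while bad_pair[np.ix_(~bad, ~bad)].any():
            counts = (bad_pair & ~bad[None, :]).sum(axis=1)
            counts[bad] = -1
            bad[np.argmax(counts)] = True
    keep = ~bad
    pops = [p for p, k in zip(pops, keep) if k]
    if len(pops) < 4:
        raise ValueError("need >= 4 populations after exclusions")
    F = F[np.ix_(keep, keep)]
    lin = F / (1.0 - F)
    np.fill_diagonal(lin, 0.0)

    coords = pop_coords.loc[pops]
    geo = np.zeros_like(lin)
    for i, j in itertools.combinations(range(len(pops)), 2):
        geo[i, j] = geo[j, i] = haversine_km(
            coords.iloc[i]["lat"], coords.iloc[i]["lon"],
            coords.iloc[j]["lat"], coords.iloc[j]["lon"],
        )

    E = pop_env.loc[pops].to_numpy(dtype=float)
    sd = E.std(axis=0, ddof=1)
    E = (E - E.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    env_d = np.sqrt(((E[:, None, :] - E[None, :, :]) ** 2).sum(axis=2))

    r_geo, p_geo = mantel_test(geo, lin, n_perm=n_perm, seed=seed)
    r_env, p_env = mantel_test(env_d, lin, n_perm=n_perm, seed=seed + 1)
    return {
        "r_geo": r_geo,
        "p_geo": p_geo,
        "r_env": r_env,
        "p_env": p_env,
        "n_populations": len(pops),
    }
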