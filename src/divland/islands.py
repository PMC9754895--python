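"""Genomic-island detection by permutation and FDR.

Candidate windows are the top fraction (default 1%) of non-excluded windows
by F_ST, ties at the cutoff included. For each candidate, a null F_ST
distribution is built by repeatedly drawing the window's SNP count from the
genome-wide pool of per-site Weir-Cockerham components (uniformly, without
replacement) and recombining them as a ratio of sums; the empirical p-value
uses the add-one convention p = (#{null >= observed} + 1) / (n_perm + 1).
Benjamini-Hochberg correction is applied over the candidate set only, and
outliers (q < fdr) that overlap or book-end on a chromosome are merged into
island regions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "permutation_null",
    "call_outliers",
    "merge_islands",
    "island_background_tests",
]


def _draw_without_replacement(rng, pool_size, n_draw, n_perm):
    """(n_perm, n_draw) index matrix; rows are uniform distinct subsets.

    Samples with replacement and redraws rows containing duplicates, which
    is exact rejection sampling of distinct tuples and fast when
    n_draw << pool_size.
    """
    if n_draw > pool_size:
        raise ValueError(f"cannot draw {n_draw} sites from a pool of {pool_size}")
    if n_draw * 4 > pool_size:
        # dense draws: take the first n_draw entries of full row permutations
        keys = rng.random((n_perm, pool_size))
        return np.argsort(keys, axis=1)[:, :n_draw]
    idx = rng.integers(0, pool_size, size=(n_perm, n_draw))
    while True:
        srt = np.sort(idx, axis=1)
        bad = np.flatnonzero((np.diff(srt, axis=1) == 0).any(axis=1))
        if bad.size == 0:
            return idx
        idx[bad] = rng.integers(0, pool_size, size=(bad.size, n_draw))


def permutation_null(observed_fst, n_snps, pool, n_perm=10_000, rng=None, seed=None):
    """Empirical p-value for one window against the genome-wide SNP pool.

    ``pool`` is the dict from :func:`divland.windows.site_component_pool`.
    Each permutation draws ``n_snps`` sites without replacement and computes
    the ratio-of-sums F_ST.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    a, d = pool["a"], pool["d"]
    idx = _draw_without_replacement(rng, len(a), n_snps, n_perm)
    idx.sort(axis=1)  # order-independent float sums: same subset, same value
    null = a[idx].sum(axis=1) / d[idx].sum(axis=1)
    return (np.count_nonzero(null >= observed_fst) + 1.0) / (n_perm + 1.0)


def call_outliers(
    windows: pd.DataFrame,
    pool: dict,
    top_fraction: float = 0.01,
    n_perm: int = 10_000,
    fdr: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Select top-F_ST candidate windows, permutation-test them, BH-correct.

    Returns the candidate windows with ``p``, ``q`` and ``outlier`` columns
    (outlier iff q < fdr), sorted by genomic position.
    """
    usable = windows.loc[~windows["excluded"] & windows["fst"].notna()].copy()
    if len(usable) < 100:
        raise ValueError("need >= 100 non-excluded windows for a top-1% scan")
    if n_perm < 1.0 / fdr:
        warnings.warn(
            f"n_perm={n_perm} gives p-value resolution coarser than fdr={fdr}"
        )
    k = max(1, int(np.ceil(top_fraction * len(usable))))
    cutoff = np.sort(usable["fst"].to_numpy())[::-1][k - 1]
    cand = usable.loc[usable["fst"] >= cutoff].copy()

    rng = np.random.default_rng(seed)
    cand["p"] = [
        permutation_null(row.fst, row.n_snps, pool, n_perm=n_perm, rng=rng)
        for row in cand.itertuples()
    ]
    cand["q"] = multipletests(cand["p"].to_numpy(), method="fdr_bh")[1]
    cand["outlier"] = cand["q"] < fdr
    return cand.sort_values(["chrom", "start"]).reset_index(drop=True)


def merge_islands(outlier_windows: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended outlier windows into island regions.

    Input rows need chrom/start/end (1-based inclusive) and fst; adjacent
    windows with ``next.start <= current.end + 1`` on the same chromosome
    are unioned. Returns regions with member window count and mean fst.
    """
    if len(outlier_windows) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_windows", "mean_fst"])
    df = outlier_windows.sort_values(["chrom", "start"])
    regions = []
    cur = None
    for row in df.itertuples():
        if cur is not None and row.chrom == cur["chrom"] and row.start <= cur["end"] + 1:
            cur["end"] = max(cur["end"], row.end)
            cur["fsts"].append(row.fst)
        else:
            if cur is not None:
                regions.append(cur)
            cur = {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "fsts": [row.fst],
            }
    regions.append(cur)
    return pd.DataFrame(
        {
            "chrom": [r["chrom"] for r in regions],
            "start": [r["start"] for r in regions],
            "end": [r["end"] for r in regions],
            "n_windows": [len(r["fsts"]) for r in regions],
            "mean_fst": [float(np.mean(r["fsts"])) for r in regions],
        }
    )


def _in_regions(chrom, start, end, regions: pd.DataFrame) -> np.ndarray:
    """Window midpoint-in-region membership mask."""
    mid = (np.asarray(start) + np.asarray(end)) / 2.0
    chrom = np.asarray(chrom)
    member = np.zeros(len(mid), dtype=bool)
    for reg in regions.itertuples():
        member |= (chrom == reg.chrom) & (mid >= reg.start) & (mid <= reg.end)
    return member


def island_background_tests(
    windows: pd.DataFrame,
    islands: pd.DataFrame,
    pi_column: str = "pi_pooled",
) -> dict:
    """Compare island-member vs background windows; test chromosome bias.

    Two-sided Mann-Whitney U for dxy, pi, rho and rho/pi between windows
    whose midpoint lies in an island region and the remaining non-excluded
    windows, plus a chi-square goodness-of-fit of outlier-window counts per
    chromosome against expectation proportional to analyzed windows.
    """
    if len(islands) < 1:
        raise ValueError("no islands to test")
    usable = windows.loc[~windows["excluded"]].copy()
    member = _in_regions(
        usable["chrom"].to_numpy(), usable["start"].to_numpy(),
        usable["end"].to_numpy(), islands,
    )
    if (~member).sum() < 10:
        raise ValueError("need >= 10 background windows")

    out = {}
    for key, col in [
        ("dxy", "dxy"), ("pi", pi_column), ("rho", "rho"),
        ("rho_over_pi", "rho_over_pi"),
    ]:
        x = usable.loc[member, col].dropna().to_numpy()
        y = usable.loc[~member, col].dropna().to_numpy()
        if len(x) == 0 or len(y) == 0:
            out[key] = {"p": np.nan, "median_island": np.nan, "median_background": np.nan}
            continue
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        out[key] = {
            "p": float(res.pvalue),
            "median_island": float(np.median(x)),
            "median_background": float(np.median(y)),
        }

    chroms = pd.unique(usable["chrom"])
    if len(chroms) >= 2:
        n_windows = usable.groupby("chrom").size().reindex(chroms).to_numpy()
        obs = (
            usable.assign(member=member)
            .groupby("chrom")["member"].sum().reindex(chroms).to_numpy()
            .astype(float)
        )
        expected = obs.sum() * n_windows / n_windows.sum()
        chi2, p = stats.chisquare(obs, expected)
        out["chrom_enrichment"] = {"chi2": float(chi2), "p": float(p)}
    else:
        out["chrom_enrichment"] = None
    return out
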