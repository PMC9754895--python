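"""Sliding-window population-genomic landscapes.

Per-window statistics over 20-kb windows advanced in 5-kb steps (defaults):

* pi per species -- unbiased per-site heterozygosity ``n/(n-1) * 2 p (1-p)``
  summed over SNPs and divided by window length in bp;
* F_ST -- Weir & Cockerham (1984) variance components combined as a ratio
  of sums over sites (the "weighted" convention); negative site components
  are retained, not clamped;
* D_XY -- mean per-bp pairwise difference between species,
  ``sum_sites [pA (1-pB) + pB (1-pA)] / window length``, which equals the
  average over all inter-species sequence pairs of their per-bp difference;
* rho -- a moment estimate of the population-scaled recombination rate
  4*Ne*r per bp, inverted from the mean pairwise dosage r^2 via the
  expectation E[r^2] ~ 1/(2 + rho*d) after subtracting the 1/(2n) sampling
  floor (a documented stand-in for regression-based estimators).

Windows with fewer than ``min_snps`` SNPs are emitted but flagged excluded.
All genotypes are unphased dosages; missing calls are handled per site and
a site is skipped for a statistic when a species has fewer than two
non-missing diploids.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from divland.genotypes import GenotypeTable

__all__ = [
    "site_fst_components",
    "site_pi_terms",
    "site_dxy_terms",
    "window_stats",
    "window_rho",
    "stat_correlations",
    "site_component_pool",
]


def _site_summary(dosage):
    """Per-site diploid count, alt frequency and observed het proportion."""
    called = ~np.isnan(dosage)
    n = called.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dosage, axis=1) / (2.0 * n)
        h = np.nansum(dosage == 1.0, axis=1) / n
    return n, p, h


def site_fst_components(dosages_A, dosages_B):
    """Weir-Cockerham (1984) variance components per biallelic site.

    Parameters are (sites x samples) dosage arrays for the two species
    (a single site may be passed as shape (1, n)). Returns ``(a, d, valid)``
    where ``a`` is the among-population component, ``d = a + b + c`` the
    total, and ``valid`` marks sites with at least two non-missing diploids
    in each species. Monomorphic sites yield (0, 0). The per-site ratio
    ``a/d`` can be negative; window estimates combine ratio-of-sums.
    """
    dosages_A = np.atleast_2d(np.asarray(dosages_A, dtype=float))
    dosages_B = np.atleast_2d(np.asarray(dosages_B, dtype=float))
    n1, p1, h1 = _site_summary(dosages_A)
    n2, p2, h2 = _site_summary(dosages_B)
    valid = (n1 >= 2) & (n2 >= 2)

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    a = np.where(valid, a, 0.0)
    d = np.where(valid, a + b + c, 0.0)
    # monomorphic across both species: zero information
    mono = valid & ((pbar == 0.0) | (pbar == 1.0))
    a = np.where(mono, 0.0, a)
    d = np.where(mono, 0.0, d)
    return a, d, valid


def site_pi_terms(dosage):
    """Per-site unbiased heterozygosity ``2 p (1-p) n/(n-1)`` (n alleles).

    Sites with fewer than two non-missing diploids contribute 0 and are
    flagged invalid.
    """
    n_dip, p, _ = _site_summary(np.atleast_2d(dosage))
    valid = n_dip >= 2
    n_al = 2.0 * n_dip
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = n_al / (n_al - 1.0) * 2.0 * p * (1.0 - p)
    return np.where(valid, pi, 0.0), valid


def site_dxy_terms(dosages_A, dosages_B):
    """Per-site expected between-species difference ``pA(1-pB) + pB(1-pA)``."""
    nA, pA, _ = _site_summary(np.atleast_2d(dosages_A))
    nB, pB, _ = _site_summary(np.atleast_2d(dosages_B))
    valid = (nA >= 1) & (nB >= 1)
    term = pA * (1.0 - pB) + pB * (1.0 - pA)
    return np.where(valid, term, 0.0), valid


def _window_starts(max_pos, window_bp, step_bp):
    last_start = max(1, int(max_pos) - window_bp + 1)
    n = (last_start - 1) // step_bp + 1
    return 1 + step_bp * np.arange(n, dtype=np.int64)


def window_stats(
    gt: GenotypeTable,
    window_bp: int = 20_000,
    step_bp: int = 5_000,
    min_snps: int = 10,
    with_rho: bool = True,
    rho_maf: float = 0.1,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Sliding-window pi (per species and pooled), F_ST, D_XY, rho.

    Returns one row per window with 1-based inclusive coordinates and an
    ``excluded`` flag for windows with fewer than ``min_snps`` SNPs. The
    ``rho_over_pi`` column divides rho by pooled pi (NaN where undefined).
    """
    if window_bp <= 0 or step_bp <= 0 or window_bp < step_bp:
        raise ValueError("require window_bp >= step_bp > 0")

    mA, mB = gt.species_masks()
    dA, dB = gt.dosage[:, mA], gt.dosage[:, mB]
    a, d, _ = site_fst_components(dA, dB)
    piA, _ = site_pi_terms(dA)
    piB, _ = site_pi_terms(dB)
    piP, _ = site_pi_terms(gt.dosage)
    dxy, _ = site_dxy_terms(dA, dB)

    rows = []
    for c in pd.unique(gt.chrom):
        cmask = gt.chrom == c
        pos = gt.pos[cmask]
        idx = np.flatnonzero(cmask)
        cs = {
            k: np.concatenate(([0.0], np.cumsum(v[cmask])))
            for k, v in dict(a=a, d=d, piA=piA, piB=piB, piP=piP, dxy=dxy).items()
        }
        max_pos = (
            chrom_lengths[c] if chrom_lengths and c in chrom_lengths else pos.max()
        )
        for start in _window_starts(max_pos, window_bp, step_bp):
            end = start + window_bp - 1
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n_snps = hi - lo
            ssum = {k: v[hi] - v[lo] for k, v in cs.items()}
            fst = ssum["a"] / ssum["d"] if ssum["d"] != 0 else np.nan
            rho = np.nan
            if with_rho and n_snps >= 2:
                rho = window_rho(
                    gt.dosage[idx[lo:hi]], gt.pos[idx[lo:hi]], maf=rho_maf
                )
            pi_pooled = ssum["piP"] / window_bp
            rows.append(
                {
                    "chrom": c,
                    "start": int(start),
                    "end": int(end),
                    "n_snps": int(n_snps),
                    "pi_A": ssum["piA"] / window_bp,
                    "pi_B": ssum["piB"] / window_bp,
                    "pi_pooled": pi_pooled,
                    "fst": fst,
                    "dxy": ssum["dxy"] / window_bp,
                    "rho": rho,
                    "rho_over_pi": rho / pi_pooled if pi_pooled > 0 else np.nan,
                    "excluded": bool(n_snps < min_snps),
                }
            )
    return pd.DataFrame(rows)


def window_rho(dosage, pos, maf: float = 0.1) -> float:
    """Moment estimate of rho = 4*Ne*r per bp for one window.

    Uses SNPs with pooled minor-allele frequency >= ``maf``; computes mean
    pairwise squared dosage correlation (Rogers-Huff style, mean-imputed
    missing calls), subtracts the 1/(2 n) finite-sample floor, and inverts
    ``E[r^2] = 1/(2 + rho * d)`` at the mean pairwise distance d. Clamped
    at 0 when the corrected mean r^2 >= 0.5; NaN (no estimate) when fewer
    than two SNPs qualify or the corrected r^2 is non-positive.
    """
    dosage = np.atleast_2d(np.asarray(dosage, dtype=float))
    pos = np.asarray(pos)
    n_called = (~np.isnan(dosage)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dosage, axis=1) / (2.0 * n_called)
    keep = (np.minimum(p, 1 - p) >= maf) & (n_called >= 2)
    if keep.sum() < 2:
        return np.nan
    X = dosage[keep]
    mean = np.nanmean(X, axis=1)
    X = np.where(np.isnan(X), mean[:, None], X)
    sd = X.std(axis=1)
    ok = sd > 0
    if ok.sum() < 2:
        return np.nan
    X = X[ok]
    r2 = np.corrcoef(X) ** 2
    iu = np.triu_indices(len(X), k=1)
    mean_r2 = r2[iu].mean()
    pdist = np.abs(pos[keep][ok][:, None] - pos[keep][ok][None, :])[iu]
    dbar = pdist.mean()
    nbar = n_called[keep][ok].mean()
    corrected = mean_r2 - 1.0 / (2.0 * nbar)
    if corrected <= 0:
        return np.nan
    if corrected >= 0.5:
        return 0.0
    return (1.0 / corrected - 2.0) / dbar


def stat_correlations(windows: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation matrix over (fst, dxy, pi_pooled, rho).

    Uses non-excluded windows with all four statistics present; requires at
    least 10 such windows. A statistic that is constant yields NaN for its
    pairs (diagonal stays 1).
    """
    cols = ["fst", "dxy", "pi_pooled", "rho"]
    df = windows.loc[~windows["excluded"], cols].dropna()
    if len(df) < 10:
        raise ValueError("need >= 10 complete non-excluded windows")
    mat = np.ones((4, 4))
    for i in range(4):
        for j in range(i + 1, 4):
            x, y = df[cols[i]].to_numpy(), df[cols[j]].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r = np.nan
            else:
                r = stats.spearmanr(x, y).statistic
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=cols, columns=cols)


def site_component_pool(gt: GenotypeTable, min_snps: int = 10) -> dict:
    """Genome-wide per-site WC components for the island permutation null.

    Returns arrays ``a``, ``d``, ``chrom``, ``pos`` restricted to sites that
    are valid and informative (``d != 0``).
    """
    mA, mB = gt.species_masks()
    a, d, valid = site_fst_components(gt.dosage[:, mA], gt.dosage[:, mB])
    keep = valid & (d != 0)
    return {
        "a": a[keep],
        "d": d[keep],
        "chrom": gt.chrom[keep],
        "pos": gt.pos[keep],
    }
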