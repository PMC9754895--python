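"""Copy-number differentiation between species (V_ST and CNDG calling).

Gene copy numbers are assigned from per-individual CNV segments as the
overlap-length-weighted mean of segment copy numbers, with uncovered gene
sequence counted at the diploid baseline of 2; genes untouched by any
segment in any individual are not copy-number genes (CNGs) and are excluded
from outlier ranking.

V_ST compares within-species to total copy-number variance:

    V_ST = [V_total - (V_A * N_A + V_B * N_B) / N_total] / V_total

with population variances (divisor N). Genes in the top 5% of V_ST are
outliers; each is permutation-tested by shuffling individual species labels
(group sizes preserved), and outliers with permutation p <= alpha are
copy-number differentiated genes (CNDGs).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["gene_copy_numbers", "vst", "vst_vector", "call_cndg"]

BASELINE_CN = 2.0


def gene_copy_numbers(
    segments_by_individual: dict,
    gene_models: pd.DataFrame,
    baseline: float = BASELINE_CN,
) -> pd.DataFrame:
    """Per-gene per-individual copy number from CNV segments.

    Parameters
    ----------
    segments_by_individual : dict
        sample -> DataFrame(chrom, start, end, copy_number), 1-based
        inclusive, sorted and non-overlapping within a sample.
    gene_models : DataFrame
        gene_id, chrom, start, end (1-based inclusive).

    Returns a (gene x sample) copy-number frame with an ``is_cng``
    column-level attribute stored in ``frame.attrs["is_cng"]`` marking genes
    overlapped by at least one segment in at least one individual.
    """
    genes = gene_models.reset_index(drop=True)
    samples = list(segments_by_individual)
    cn = np.full((len(genes), len(samples)), baseline, dtype=float)
    touched = np.zeros(len(genes), dtype=bool)

    for j, s in enumerate(samples):
        segs = segments_by_individual[s]
        if segs is None or len(segs) == 0:
            continue
        if (segs["copy_number"] < 0).any():
            raise ValueError(f"negative copy number in segments for {s}")
        for c, seg_c in segs.groupby("chrom"):
            gsel = genes.index[genes["chrom"] == c]
            if len(gsel) == 0:
                continue
            s0 = seg_c["start"].to_numpy()
            s1 = seg_c["end"].to_numpy()
            scn = seg_c["copy_number"].to_numpy(dtype=float)
            for gi in gsel:
                g0, g1 = genes.at[gi, "start"], genes.at[gi, "end"]
                ov = np.minimum(s1, g1) - np.maximum(s0, g0) + 1
                hit = ov > 0
                if not hit.any():
                    continue
                touched[gi] = True
                glen = g1 - g0 + 1
                covered = ov[hit].sum()
                cn[gi, j] = (
                    (ov[hit] * scn[hit]).sum() + (glen - covered) * baseline
                ) / glen

    out = pd.DataFrame(cn, index=genes["gene_id"], columns=samples)
    out.attrs["is_cng"] = pd.Series(touched, index=genes["gene_id"])
    return out


def vst(cn_A, cn_B, ddof: int = 0) -> float:
    """V_ST for one gene from the two species' copy-number vectors.

    Returns NaN when the total variance is zero (uninformative gene);
    raises if either group has fewer than two individuals.
    """
    cn_A = np.asarray(cn_A, dtype=float)
    cn_B = np.asarray(cn_B, dtype=float)
    if len(cn_A) < 2 or len(cn_B) < 2:
        raise ValueError("need >= 2 individuals per species")
    v_total = np.var(np.concatenate([cn_A, cn_B]), ddof=ddof)
    if v_total == 0:
        return np.nan
    n_a, n_b = len(cn_A), len(cn_B)
    v_within = (np.var(cn_A, ddof=ddof) * n_a + np.var(cn_B, ddof=ddof) * n_b) / (
        n_a + n_b
    )
    return (v_total - v_within) / v_total


def vst_vector(cn: np.ndarray, mask_A: np.ndarray, mask_B: np.ndarray, ddof=0):
    """Vectorized V_ST over genes; ``cn`` is (genes x individuals)."""
    both = mask_A | mask_B
    v_total = np.var(cn[:, both], axis=1, ddof=ddof)
    n_a, n_b = int(mask_A.sum()), int(mask_B.sum())
    v_within = (
        np.var(cn[:, mask_A], axis=1, ddof=ddof) * n_a
        + np.var(cn[:, mask_B], axis=1, ddof=ddof) * n_b
    ) / (n_a + n_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (v_total - v_within) / v_total
    return np.where(v_total == 0, np.nan, out)


def call_cndg(
    cn_table: pd.DataFrame,
    species: np.ndarray,
    top_fraction: float = 0.05,
    n_perm: int = 1_000,
    alpha: float = 0.01,
    seed: int = 0,
    cng_only: bool = True,
) -> pd.DataFrame:
    """Rank genes by V_ST, permutation-test the top fraction, call CNDGs.

    ``cn_table`` is the (gene x sample) frame from
    :func:`gene_copy_numbers`; ``species`` gives one of two labels per
    sample (column order). Outliers are the top ``top_fraction`` of genes
    with defined V_ST; each outlier's p-value comes from ``n_perm`` label
    permutations preserving group sizes (add-one convention, >= compare).
    """
    species = np.asarray(species)
    labels = np.unique(species)
    if labels.size != 2:
        raise ValueError("species must take exactly two values")
    if n_perm < 1.0 / alpha:
        warnings.warn(f"n_perm={n_perm} cannot resolve p-values near alpha={alpha}")
    mask_A = species == labels[0]
    mask_B = species == labels[1]
    cn = cn_table.to_numpy(dtype=float)

    keep = np.ones(len(cn_table), dtype=bool)
    if cng_only and "is_cng" in cn_table.attrs:
        keep = cn_table.attrs["is_cng"].to_numpy(dtype=bool)

    v = vst_vector(cn, mask_A, mask_B)
    res = pd.DataFrame(
        {
            "gene_id": cn_table.index,
            "vst": v,
            "is_cng": keep,
        }
    )
    defined = keep & ~np.isnan(v)
    if defined.sum() < 20:
        raise ValueError("need >= 20 genes with defined V_ST")
    k = max(1, int(np.ceil(top_fraction * defined.sum())))
    cutoff = np.sort(v[defined])[::-1][k - 1]
    res["top_flag"] = defined & (v >= cutoff)

    rng = np.random.default_rng(seed)
    top_idx = np.flatnonzero(res["top_flag"].to_numpy())
    cn_top = cn[top_idx]
    exceed = np.zeros(len(top_idx))
    n = len(species)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        null = vst_vector(cn_top, mask_A[perm], mask_B[perm])
        exceed += null >= v[top_idx]
    p = (exceed + 1.0) / (n_perm + 1.0)

    res["perm_p"] = np.nan
    res.loc[res.index[top_idx], "perm_p"] = p
    res["cndg"] = res["top_flag"] & (res["perm_p"] <= alpha)
    return res
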