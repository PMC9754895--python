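"""HKA-style positive-selection scan.

For each gene and focal species, the count of SNPs polymorphic within the
focal species (N1) and of fixed loci between the species (per-site
Weir-Cockerham F_ST >= 0.95; N2) inside the gene is compared to the
genome-wide counts with a Pearson chi-square on the 2x2 table
[[N1_gene, N2_gene], [N1_genome, N2_genome]] (1 df, no continuity
correction). A gene is a positively selected gene (PSG) when the HKA
p-value is <= alpha and it carries more than one nonsynonymous site.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from divland.genotypes import GenotypeTable
from divland.windows import site_fst_components

__all__ = ["classify_sites", "hka_test", "call_psg", "island_enrichment"]

FIXED_FST_THRESHOLD = 0.95


def classify_sites(gt: GenotypeTable, fixed_threshold: float = FIXED_FST_THRESHOLD):
    """Per-site classes: polymorphic within each species, fixed between.

    Returns a dict with boolean arrays ``poly_A``, ``poly_B`` (0 < allele
    frequency < 1 among the species' non-missing alleles) and ``fixed``
    (site F_ST >= threshold; sites with negative or undefined ratios are
    not fixed). A site can be both polymorphic-within and fixed-between.
    """
    mA, mB = gt.species_masks()
    dA, dB = gt.dosage[:, mA], gt.dosage[:, mB]

    def _poly(d):
        called = ~np.isnan(d)
        n = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(d, axis=1) / (2.0 * n)
        return (n >= 1) & (p > 0) & (p < 1)

    a, den, valid = site_fst_components(dA, dB)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den != 0, a / den, -np.inf)
    return {
        "poly_A": _poly(dA),
        "poly_B": _poly(dB),
        "fixed": valid & (den != 0) & (ratio >= fixed_threshold),
    }


def hka_test(n1_gene: int, n2_gene: int, n1_genome: int, n2_genome: int):
    """Pearson chi-square of gene vs genome polymorphism:divergence ratio.

    Returns ``(chi2, p)``; proportional rows give (0, 1). Warns when any
    expected count is below 5. Raises if the gene has no sites or a
    marginal is zero.
    """
    table = np.array(
        [[n1_gene, n2_gene], [n1_genome, n2_genome]], dtype=float
    )
    if table[0].sum() == 0:
        raise ValueError("gene has no classified sites")
    if (table.sum(axis=0) == 0).any() or table[1].sum() == 0:
        raise ValueError("zero marginal in HKA table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        warnings.warn("HKA expected count < 5; chi-square approximation is weak")
    chi2 = ((table - expected) ** 2 / expected).sum()
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def _gene_site_counts(gt, genes, class_mask):
    """Count True sites of ``class_mask`` inside each gene (sorted genes)."""
    counts = np.zeros(len(genes), dtype=int)
    for c in pd.unique(genes["chrom"]):
        snp_sel = gt.chrom == c
        pos = gt.pos[snp_sel]
        cls = class_mask[snp_sel]
        cum = np.concatenate(([0], np.cumsum(cls)))
        gsel = genes["chrom"] == c
        lo = np.searchsorted(pos, genes.loc[gsel, "start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, genes.loc[gsel, "end"].to_numpy(), side="right")
        counts[np.flatnonzero(gsel.to_numpy())] = cum[hi] - cum[lo]
    return counts


def call_psg(
    gt: GenotypeTable,
    gene_models: pd.DataFrame,
    nonsyn_counts: pd.Series,
    alpha: float = 0.01,
    exclude_self: bool = True,
    pooled: bool = False,
    fixed_threshold: float = FIXED_FST_THRESHOLD,
) -> pd.DataFrame:
    """Run the HKA scan per focal species and apply the PSG filter.

    Parameters
    ----------
    nonsyn_counts : Series
        gene_id -> nonsynonymous fixed-site count (genes absent count 0).
    exclude_self : bool
        Subtract the focal gene's own counts from the genome margins.
    pooled : bool
        Pool both species' polymorphism into a single N1 (one test per
        gene) instead of the default per-species tests.

    Returns one row per (gene, focal species): counts, chi2, p, psg flag
    (p <= alpha and nonsyn count >= 2). Genes with no classified sites get
    NaN statistics.
    """
    genes = gene_models.sort_values(["chrom", "start"]).reset_index(drop=True)
    cls = classify_sites(gt, fixed_threshold=fixed_threshold)
    n2 = _gene_site_counts(gt, genes, cls["fixed"])
    n2_tot = int(cls["fixed"].sum())

    if pooled:
        focal = {"pooled": cls["poly_A"] | cls["poly_B"]}
    else:
        a, b = gt.species_labels
        focal = {a: cls["poly_A"], b: cls["poly_B"]}

    rows = []
    for sp, poly in focal.items():
        n1 = _gene_site_counts(gt, genes, poly)
        n1_tot = int(poly.sum())
        for gi, g in genes.iterrows():
            n1_g, n2_g = int(n1[gi]), int(n2[gi])
            n1_bg = n1_tot - n1_g if exclude_self else n1_tot
            n2_bg = n2_tot - n2_g if exclude_self else n2_tot
            ns = int(nonsyn_counts.get(g.gene_id, 0))
            if n1_g + n2_g == 0 or n1_bg + n2_bg == 0 or (n1_g + n1_bg) == 0 or (
                n2_g + n2_bg
            ) == 0:
                chi2 = p = np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    chi2, p = hka_test(n1_g, n2_g, n1_bg, n2_bg)
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "focal_species": sp,
                    "n1_gene": n1_g,
                    "n2_gene": n2_g,
                    "n1_genome": n1_bg,
                    "n2_genome": n2_bg,
                    "chi2": chi2,
                    "p": p,
                    "nonsyn_count": ns,
                    "psg": bool(p == p and p <= alpha and ns > 1),
                }
            )
    return pd.DataFrame(rows)


def island_enrichment(
    psg_results: pd.DataFrame,
    islands: pd.DataFrame,
    gene_models: pd.DataFrame,
) -> dict:
    """Chi-square test of PSG concentration inside genomic islands.

    A gene is "in island" when its midpoint falls inside a region; the 2x2
    table crosses PSG status (a gene is PSG if flagged for any focal
    species) with island membership over all genes.
    """
    if len(islands) == 0:
        raise ValueError("no islands provided")
    genes = gene_models.reset_index(drop=True)
    mid = (genes["start"].to_numpy() + genes["end"].to_numpy()) / 2.0
    in_island = np.zeros(len(genes), dtype=bool)
    for reg in islands.itertuples():
        in_island |= (
            (genes["chrom"].to_numpy() == reg.chrom)
            & (mid >= reg.start)
            & (mid <= reg.end)
        )
    if in_island.sum() == 0:
        raise ValueError("no genes inside islands")
    psg_ids = set(psg_results.loc[psg_results["psg"], "gene_id"])
    is_psg = genes["gene_id"].isin(psg_ids).to_numpy()
    table = np.array(
        [
            [(is_psg & in_island).sum(), (is_psg & ~in_island).sum()],
            [(~is_psg & in_island).sum(), (~is_psg & ~in_island).sum()],
        ]
    )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "chi2": float(chi2),
        "p": float(p),
        "n_psg_in_islands": int(table[0, 0]),
        "n_genes_in_islands": int(in_island.sum()),
        "table": table.tolist(),
    }
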