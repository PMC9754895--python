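"""Genotype container and VCF / metadata input-output.

The central in-memory object is :class:`GenotypeTable`: a biallelic SNP
dosage matrix (variants x samples, values 0/1/2 with NaN for missing
genotypes) plus positions and a two-species sample partition. VCF parsing
goes through cyvcf2; writing emits minimal VCFv4.2 with GT-only FORMAT,
one ALT per record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF


@dataclass
class GenotypeTable:
    """Biallelic diploid genotypes for samples from exactly two species.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, column order of ``dosage``.
    species : ndarray of str
        Species label per sample; must take exactly two distinct values.
    chrom, pos : ndarray
        Variant chromosome and 1-based position, sorted within chromosome.
    ref, alt : ndarray of str
        Reference and single alternate allele per variant.
    dosage : ndarray, shape (n_variants, n_samples)
        Alternate-allele count 0/1/2 as float; NaN encodes a missing call.
    populations : ndarray of str, optional
        Population label per sample (used by Mantel tests).
    """

    samples: list
    species: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    populations: np.ndarray | None = None

    def __post_init__(self):
        self.species = np.asarray(self.species)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.pos)} variants x {len(self.samples)} samples"
            )
        labels = np.unique(self.species)
        if labels.size != 2:
            raise ValueError(f"expected exactly two species labels, got {list(labels)}")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def species_labels(self) -> tuple:
        """The two species labels, lexicographically sorted (A, B)."""
        u = np.unique(self.species)
        return str(u[0]), str(u[1])

    def species_masks(self) -> tuple:
        """Boolean sample masks ``(mask_A, mask_B)`` in label-sorted order."""
        a, b = self.species_labels
        return self.species == a, self.species == b

    def variant_ids(self) -> np.ndarray:
        return np.array([f"{c}:{p}" for c, p in zip(self.chrom, self.pos)])

    def subset_variants(self, index) -> "GenotypeTable":
        return GenotypeTable(
            samples=self.samples,
            species=self.species,
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosage=self.dosage[index],
            populations=self.populations,
        )


def read_vcf(vcf_path, samples_tsv) -> GenotypeTable:
    """Load a biallelic-SNP VCF and a sample-metadata TSV.

    ``samples_tsv`` must have columns sample, species, population (lat/lon
    optional). Multiallelic or non-SNP records are skipped.
    """
    meta = pd.read_csv(samples_tsv, sep="\t", dtype=str)
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    meta = meta.set_index("sample")
    missing = [s for s in vcf_samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples in VCF but not in metadata: {missing}")
    meta = meta.loc[vcf_samples]

    chrom, pos, ref, alt, rows = [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = rec.gt_types.astype(float)
        row = np.where(gt == 3, 2.0, gt)
        row[gt == 2] = np.nan
        rows.append(row)
    vcf.close()

    dosage = np.array(rows) if rows else np.empty((0, len(vcf_samples)))
    pops = (
        meta["population"].to_numpy(dtype=str)
        if "population" in meta.columns
        else None
    )
    return GenotypeTable(
        samples=vcf_samples,
        species=meta["species"].to_numpy(dtype=str),
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosage=dosage,
        populations=pops,
    )


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gt: GenotypeTable, path, contig_lengths=None) -> None:
    """Write a minimal VCFv4.2 (GT-only, one ALT per record)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=divland\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gt.samples)
            + "\n"
        )
        for i in range(gt.n_variants):
            calls = [
                "./." if np.isnan(d) else _GT_CODE[d] for d in gt.dosage[i]
            ]
            fh.write(
                f"{gt.chrom[i]}\t{gt.pos[i]}\t{gt.chrom[i]}:{gt.pos[i]}\t"
                f"{gt.ref[i]}\t{gt.alt[i]}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_samples_tsv(path, samples, species, populations, lat, lon) -> None:
    pd.DataFrame(
        {
            "sample": samples,
            "species": species,
            "population": populations,
            "lat": lat,
            "lon": lon,
        }
    ).to_csv(path, sep="\t", index=False)


def read_genes_bed(path) -> pd.DataFrame:
    """Read gene models from BED (0-based half-open) into a 1-based frame."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start0", "end0", "gene_id"]
    )
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["chrom"],
            "start": df["start0"] + 1,
            "end": df["end0"],
        }
    )
    return out


def write_genes_bed(path, genes: pd.DataFrame) -> None:
    """Write gene models (1-based inclusive frame) as BED 0-based half-open."""
    with Path(path).open("w") as fh:
        for _, g in genes.iterrows():
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")
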