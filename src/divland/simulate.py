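"""Synthetic two-species resequencing design.

Generates genotype, CNV, environmental and annotation data with the
statistical structure the downstream analyses assume, so the whole
pipeline runs and is testable with no external data.

Model
-----
Allele frequencies follow the Balding-Nichols model: an ancestral
frequency p is drawn per SNP from a symmetric Beta(0.8, 0.8) truncated to
[0.05, 0.95] (producing a U-shaped site-F_ST distribution with a
fixed-difference mass), and each species' frequency is drawn from
Beta(p (1-F)/F, (1-p)(1-F)/F), with F the background differentiation
outside planted islands and a higher value inside them. Haplotypes are
built per 20-kb block by sampling from K founder haplotypes (small K
inside islands), so islands carry both elevated F_ST and stronger LD /
lower rho. Island mutation-input density is additionally thinned (default
factor 0.6), emulating the diversity loss of linked selection; together
with the loss of sites fixed for the same allele in both species this
leaves islands with reduced per-bp pi and D_XY despite their large
per-site divergence. Diploid genotypes are unordered pairs of
haplotypes; genotype calls are masked at a configurable missing rate.

Planted signals recorded in :class:`SyntheticTruth`: island coordinates,
copy-number differentiated genes (species copy-number means differing by
two copies), positive-selection genes (elevated fixed-difference density
plus >= 2 nonsynonymous sites), and environment-associated SNPs whose
dosage is a noisy copy of annual precipitation. Everything is a stand-in:
the generator makes no attempt at demographic realism (no bottlenecks,
gene-flow pulses or mutation-model detail).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from divland.genotypes import (
    GenotypeTable,
    write_vcf,
    write_samples_tsv,
    write_genes_bed,
)

__all__ = ["SimulationConfig", "SyntheticTruth", "SimulationResult", "simulate",
           "generate_annotation", "generate_env", "generate_genotypes",
           "generate_cnv"]


def _default_islands():
    return [("chr1", 1_000_001, 1_040_000), ("chr1", 3_000_001, 3_040_000),
            ("chr2", 2_000_001, 2_040_000)]


def _default_env_specs():
    # name -> (species-A mean, species-B mean, individual SD); units are
    # SD-scale z values of the underlying predictor
    return {
        "SSF": (0.0, 0.0, 1.0),
        "Sp": (1.5, 0.0, 1.0),
        "SR": (0.0, 0.0, 1.0),
        "MaT": (0.0, 0.0, 1.0),
        "MiT": (0.0, 3.0, 1.0),
        "MDR": (1.5, 0.0, 1.0),
        "AP": (0.0, 3.0, 1.0),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-species design.

    Defaults emulate the study conditions: 26 + 14 diploids in 12 + 4
    populations, heterogeneous differentiation (background F = 0.2 with
    islands at F = 0.9), seven environmental predictors four of which are
    species-separated, plus one deliberately collinear extra predictor.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 5_000_000
    n_samples_A: int = 26
    n_samples_B: int = 14
    n_populations_A: int = 12
    n_populations_B: int = 4
    snp_density: float = 0.003
    background_fst: float = 0.2
    island_fst: float = 0.9
    island_regions: list = field(default_factory=_default_islands)
    founder_haplotypes_background: int | None = 30
    founder_haplotypes_island: int | None = 4
    island_diversity_factor: float = 0.6
    block_bp: int = 20_000
    ancestral_beta: tuple = (0.8, 0.8)
    ancestral_trunc: tuple = (0.05, 0.95)
    n_genes: int = 1_000
    genic_fraction: float = 0.6
    n_cng: int = 400
    n_cndg: int = 20
    cndg_copy_shift: float = 2.0
    cnv_noise_sd: float = 0.4
    n_psg: int = 30
    psg_fixed_fraction: float = 0.6
    n_env_snps: int = 30
    env_snp_noise_sd: float = 0.55
    env_predictor_specs: dict = field(default_factory=_default_env_specs)
    env_collinear: tuple = ("MaTx", "MaT", 0.9)
    missing_rate: float = 0.02

    def validate(self) -> None:
        if not (0 < self.background_fst < 1) or not (0 < self.island_fst < 1):
            raise ValueError("F parameters must be in (0, 1)")
        if self.island_fst <= self.background_fst:
            raise ValueError("island_fst must exceed background_fst")
        if not (0 <= self.missing_rate <= 0.2):
            raise ValueError("missing_rate must be in [0, 0.2]")
        for n in (self.n_chromosomes, self.chrom_length_bp, self.n_samples_A,
                  self.n_samples_B, self.n_populations_A, self.n_populations_B,
                  self.n_genes):
            if n <= 0:
                raise ValueError("all counts must be positive")
        if self.n_cndg > self.n_cng or self.n_cng > self.n_genes:
            raise ValueError("need n_cndg <= n_cng <= n_genes")
        chroms = self.chrom_names()
        seen = []
        for c, s, e in self.island_regions:
            if c not in chroms:
                raise ValueError(f"island on unknown chromosome {c}")
            if not (1 <= s <= e <= self.chrom_length_bp):
                raise ValueError(f"island {c}:{s}-{e} outside chromosome bounds")
            for c2, s2, e2 in seen:
                if c == c2 and s <= e2 and s2 <= e:
                    raise ValueError("island regions overlap")
            seen.append((c, s, e))

    def chrom_names(self) -> list:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def rng(self, stream: int) -> np.random.Generator:
        """Substream generator: one global seed, fixed offsets per stage."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests; ids refer to emitted records."""

    ancestral_freq: np.ndarray
    freq_A: np.ndarray
    freq_B: np.ndarray
    is_island_snp: np.ndarray
    island_regions: list
    psg_genes: list
    cng_genes: list
    cndg_genes: list
    env_snp_ids: list
    snp_ids: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "ancestral_freq": np.round(self.ancestral_freq, 6).tolist(),
            "freq_A": np.round(self.freq_A, 6).tolist(),
            "freq_B": np.round(self.freq_B, 6).tolist(),
            "is_island_snp": self.is_island_snp.astype(int).tolist(),
            "island_regions": [list(r) for r in self.island_regions],
            "psg_genes": list(self.psg_genes),
            "cng_genes": list(self.cng_genes),
            "cndg_genes": list(self.cndg_genes),
            "env_snp_ids": list(self.env_snp_ids),
            "snp_ids": self.snp_ids.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class SimulationResult:
    genotypes: GenotypeTable
    truth: SyntheticTruth
    genes: pd.DataFrame
    nonsyn: pd.Series
    env: pd.DataFrame
    sample_coords: pd.DataFrame
    segments: dict
    cn_truth: pd.DataFrame
    config: SimulationConfig


# ------------------------------------------------------------- annotation

def generate_annotation(config: SimulationConfig):
    """Non-overlapping sorted gene models plus planted-PSG assignment.

    Genes are laid out on a regular grid covering ``genic_fraction`` of
    each chromosome (the complement, at least 10% of the genome, is
    intergenic). Returns ``(genes, psg_gene_ids)`` where genes has
    1-based inclusive coordinates and a ``psg`` flag column.
    """
    config.validate()
    rng = config.rng(1)
    chroms = config.chrom_names()
    per_chrom = int(np.ceil(config.n_genes / len(chroms)))
    rows = []
    gid = 0
    for c in chroms:
        n_here = min(per_chrom, config.n_genes - gid)
        spacing = config.chrom_length_bp // n_here
        glen = int(spacing * config.genic_fraction)
        for k in range(n_here):
            start = k * spacing + 1 + (spacing - glen) // 2
            rows.append(
                {"gene_id": f"g{gid:05d}", "chrom": c, "start": start,
                 "end": start + glen - 1}
            )
            gid += 1
    genes = pd.DataFrame(rows)
    psg = rng.choice(genes["gene_id"], size=config.n_psg, replace=False)
    genes["psg"] = genes["gene_id"].isin(psg)
    return genes, sorted(psg.tolist())


def generate_nonsyn(config: SimulationConfig, genes: pd.DataFrame) -> pd.Series:
    """Per-gene nonsynonymous fixed-site counts (planted PSGs get >= 2)."""
    rng = config.rng(2)
    counts = rng.poisson(0.7, size=len(genes))
    psg_mask = genes["psg"].to_numpy()
    counts[psg_mask] = 2 + rng.poisson(2.0, size=int(psg_mask.sum()))
    return pd.Series(counts, index=genes["gene_id"], name="nonsyn_count")


# ------------------------------------------------------------ environment

def generate_env(config: SimulationConfig):
    """Sample metadata, coordinates and environmental predictors.

    Populations sit in two latitude bands (species A north of species B);
    predictors are species mean + population offset + individual noise in
    SD units, and one extra predictor is generated collinear with another
    (|r| >= 0.7) to exercise the autocorrelation filter.

    Returns ``(samples, species, populations, coords, env)``.
    """
    config.validate()
    rng = config.rng(3)
    samples, species, populations = [], [], []
    for i in range(config.n_samples_A):
        samples.append(f"A{i + 1:02d}")
        species.append("species_A")
        populations.append(f"popA{i % config.n_populations_A + 1:02d}")
    for i in range(config.n_samples_B):
        samples.append(f"B{i + 1:02d}")
        species.append("species_B")
        populations.append(f"popB{i % config.n_populations_B + 1:02d}")
    species = np.array(species)
    populations = np.array(populations)

    pop_names = list(dict.fromkeys(populations))
    pop_coord = {}
    for p in pop_names:
        if p.startswith("popA"):
            k = int(p[4:]) - 1
            lat = 30.0 + 5.0 * (k / max(1, config.n_populations_A - 1))
            lon = 100.0 + 20.0 * rng.random()
        else:
            k = int(p[4:]) - 1
            lat = 24.0 + 4.0 * (k / max(1, config.n_populations_B - 1))
            lon = 102.0 + 18.0 * rng.random()
        pop_coord[p] = (lat, lon)
    coords = pd.DataFrame(
        {
            "sample": samples,
            "lat": [pop_coord[p][0] for p in populations],
            "lon": [pop_coord[p][1] for p in populations],
        }
    ).set_index("sample")

    is_A = species == "species_A"
    env = {}
    pop_offsets = {
        (name, p): rng.normal(0.0, 0.3)
        for name in config.env_predictor_specs for p in pop_names
    }
    for name, (mu_a, mu_b, sd) in config.env_predictor_specs.items():
        base = np.where(is_A, mu_a, mu_b).astype(float)
        base += np.array([pop_offsets[(name, p)] for p in populations])
        env[name] = base + rng.normal(0.0, sd, size=len(samples))
    env = pd.DataFrame(env, index=samples)

    extra, source, r = config.env_collinear
    if extra:
        z = (env[source] - env[source].mean()) / env[source].std()
        noise = rng.normal(0.0, 1.0, size=len(samples))
        env[extra] = r * z + np.sqrt(1.0 - r**2) * noise

    return samples, species, populations, coords, env


# -------------------------------------------------------------- genotypes

def _truncated_beta(rng, a, b, lo, hi, size):
    out = rng.beta(a, b, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _island_lookup(config):
    by_chrom = {}
    for i, (c, s, e) in enumerate(config.island_regions):
        by_chrom.setdefault(c, []).append((s, e, i))
    return by_chrom


def _sample_positions(config, rng):
    """SNP positions per chromosome; islands thinned by the diversity factor."""
    islands = _island_lookup(config)
    chrom_arr, pos_arr, island_id = [], [], []
    for c in config.chrom_names():
        regions = sorted(islands.get(c, []))
        cursor = 1
        segs = []  # (start, end, island index or -1)
        for s, e, i in regions:
            if cursor < s:
                segs.append((cursor, s - 1, -1))
            segs.append((s, e, i))
            cursor = e + 1
        if cursor <= config.chrom_length_bp:
            segs.append((cursor, config.chrom_length_bp, -1))
        cpos, cid = [], []
        for s, e, i in segs:
            dens = config.snp_density * (
                config.island_diversity_factor if i >= 0 else 1.0
            )
            n = rng.poisson((e - s + 1) * dens)
            p = np.unique(rng.integers(s, e + 1, size=n))
            cpos.append(p)
            cid.append(np.full(len(p), i))
        cpos = np.concatenate(cpos) if cpos else np.array([], dtype=int)
        cid = np.concatenate(cid) if cid else np.array([], dtype=int)
        order = np.argsort(cpos)
        chrom_arr.append(np.full(len(cpos), c, dtype=object))
        pos_arr.append(cpos[order])
        island_id.append(cid[order])
    return (
        np.concatenate(chrom_arr),
        np.concatenate(pos_arr),
        np.concatenate(island_id),
    )


def _species_dosage(rng, freq, block_id, n_dip, k_by_block):
    """Sample diploid dosages per block: founder-haplotype or binomial."""
    m = len(freq)
    out = np.empty((m, n_dip))
    for b in np.unique(block_id):
        sel = block_id == b
        f = freq[sel]
        K = k_by_block[b]
        if K is None:
            out[sel] = rng.binomial(2, f[:, None], size=(int(sel.sum()), n_dip))
        else:
            founders = (rng.random((K, int(sel.sum()))) < f[None, :]).astype(float)
            h1 = rng.integers(0, K, size=n_dip)
            h2 = rng.integers(0, K, size=n_dip)
            out[sel] = (founders[h1] + founders[h2]).T
    return out


def generate_genotypes(config: SimulationConfig):
    """Genotypes, planted truth and supporting tables.

    Returns a :class:`SimulationResult` without CNV data (``segments`` and
    ``cn_truth`` empty); :func:`simulate` fills those in. Sites monomorphic
    across the pooled sample are dropped from the emitted table.
    """
    config.validate()
    genes, psg_ids = generate_annotation(config)
    nonsyn = generate_nonsyn(config, genes)
    samples, species, populations, coords, env = generate_env(config)
    rng = config.rng(4)

    chrom, pos, island_id = _sample_positions(config, rng)
    m = len(pos)
    lo, hi = config.ancestral_trunc
    a_beta, b_beta = config.ancestral_beta
    p_anc = _truncated_beta(rng, a_beta, b_beta, lo, hi, m)

    F = np.where(island_id >= 0, config.island_fst, config.background_fst)
    shape_a = p_anc * (1.0 - F) / F
    shape_b = (1.0 - p_anc) * (1.0 - F) / F
    freq_A = rng.beta(shape_a, shape_b)
    freq_B = rng.beta(shape_a, shape_b)

    # planted selective sweeps: force a fraction of SNPs inside PSG genes
    # to be (near-)fixed differences, orientation chosen per gene
    psg_genes = genes.loc[genes["psg"]]
    for g in psg_genes.itertuples():
        sel = (chrom == g.chrom) & (pos >= g.start) & (pos <= g.end)
        if not sel.any():
            continue
        hit = sel & (rng.random(m) < config.psg_fixed_fraction)
        flip = rng.random() < 0.5
        freq_A[hit] = 0.99 if flip else 0.01
        freq_B[hit] = 0.01 if flip else 0.99

    # block structure: islands are single blocks with few founders
    block_id = np.empty(m, dtype=object)
    k_by_block = {}
    for c in config.chrom_names():
        cmask = chrom == c
        bg = cmask & (island_id < 0)
        bids = pos[bg] // config.block_bp
        block_id[bg] = [f"{c}:bg:{b}" for b in bids]
        for b in np.unique(bids):
            k_by_block[f"{c}:bg:{b}"] = config.founder_haplotypes_background
    for i, (c, s, e) in enumerate(config.island_regions):
        sel = island_id == i
        block_id[sel] = f"isl:{i}"
        k_by_block[f"isl:{i}"] = config.founder_haplotypes_island

    dos_A = _species_dosage(rng, freq_A, block_id, config.n_samples_A, k_by_block)
    dos_B = _species_dosage(rng, freq_B, block_id, config.n_samples_B, k_by_block)
    dosage = np.hstack([dos_A, dos_B])

    # planted environment-associated SNPs: genic, outside PSG genes and
    # islands; dosage rewritten as a noisy copy of annual precipitation
    ap = env["AP"].to_numpy()
    z_ap = (ap - ap.mean()) / ap.std()
    genic = np.zeros(m, dtype=bool)
    for c in pd.unique(genes["chrom"]):
        gsub = genes.loc[(genes["chrom"] == c) & ~genes["psg"]]
        cmask = chrom == c
        cpos = pos[cmask]
        inside = np.zeros(len(cpos), dtype=bool)
        starts = gsub["start"].to_numpy()
        ends = gsub["end"].to_numpy()
        j = np.searchsorted(starts, cpos, side="right") - 1
        ok = j >= 0
        inside[ok] = cpos[ok] <= ends[j[ok]]
        genic[cmask] = inside
    candidates = np.flatnonzero(genic & (island_id < 0))
    n_env = min(config.n_env_snps, len(candidates))
    env_snp_idx = rng.choice(candidates, size=n_env, replace=False)
    for v in env_snp_idx:
        raw = 1.0 + 0.9 * z_ap + rng.normal(0.0, config.env_snp_noise_sd,
                                            size=len(samples))
        dosage[v] = np.clip(np.round(raw), 0, 2)

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    # ensure planted env SNPs stay polymorphic after masking
    for v in env_snp_idx:
        row = dosage[v]
        called = row[~np.isnan(row)]
        if called.size and (called.min() == called.max()):
            row[0], row[-1] = 0.0, 2.0

    called = ~np.isnan(dosage)
    ac = np.nansum(dosage, axis=1)
    poly = (ac > 0) & (ac < 2 * called.sum(axis=1))
    keep = np.flatnonzero(poly)

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=m)]
    alt_off = rng.integers(1, 4, size=m)
    alt = bases[(np.char.find("ACGT", ref.astype(str)) + alt_off) % 4]

    gt = GenotypeTable(
        samples=samples,
        species=species,
        chrom=chrom[keep],
        pos=pos[keep],
        ref=ref[keep].astype(object),
        alt=alt[keep].astype(object),
        dosage=dosage[keep],
        populations=populations,
    )
    snp_ids = gt.variant_ids()
    kept_set = {int(i): n for n, i in enumerate(keep)}
    env_ids = [
        snp_ids[kept_set[int(v)]] for v in env_snp_idx if int(v) in kept_set
    ]
    truth = SyntheticTruth(
        ancestral_freq=p_anc[keep],
        freq_A=freq_A[keep],
        freq_B=freq_B[keep],
        is_island_snp=(island_id[keep] >= 0),
        island_regions=list(config.island_regions),
        psg_genes=psg_ids,
        cng_genes=[],
        cndg_genes=[],
        env_snp_ids=env_ids,
        snp_ids=snp_ids,
    )
    return SimulationResult(
        genotypes=gt, truth=truth, genes=genes, nonsyn=nonsyn, env=env,
        sample_coords=coords, segments={}, cn_truth=pd.DataFrame(),
        config=config,
    )


# ------------------------------------------------------------------- CNV

def generate_cnv(config: SimulationConfig, genes: pd.DataFrame, samples, species):
    """Per-individual CNV segments and the underlying copy-number truth.

    ``n_cng`` genes carry copy-number variation; of these, ``n_cndg``
    differ between species by ``cndg_copy_shift`` copies. Individual copy
    numbers are integers around the gene mean; segments are emitted only
    where the copy number departs from the diploid baseline, exactly
    covering the gene span.

    Returns ``(segments_by_individual, cn_truth, cng_ids, cndg_ids)``.
    """
    config.validate()
    rng = config.rng(5)
    species = np.asarray(species)
    is_A = species == np.unique(species)[0]

    cng_ids = sorted(
        rng.choice(genes["gene_id"], size=config.n_cng, replace=False).tolist()
    )
    cndg_ids = sorted(rng.choice(cng_ids, size=config.n_cndg, replace=False).tolist())
    cndg_set = set(cndg_ids)

    cn = pd.DataFrame(2.0, index=genes["gene_id"], columns=list(samples))
    for gid in cng_ids:
        if gid in cndg_set:
            flip = rng.random() < 0.5
            mu_a = 2.0 + (config.cndg_copy_shift if flip else 0.0)
            mu_b = 2.0 + (0.0 if flip else config.cndg_copy_shift)
        else:
            mu_a = mu_b = float(rng.choice([1, 2, 3, 4], p=[0.2, 0.4, 0.2, 0.2]))
        mu = np.where(is_A, mu_a, mu_b)
        vals = np.round(mu + rng.normal(0.0, config.cnv_noise_sd, size=len(samples)))
        cn.loc[gid] = np.maximum(vals, 0.0)

    gene_lu = genes.set_index("gene_id")
    segments = {}
    for j, s in enumerate(samples):
        rows = []
        for gid in cng_ids:
            v = cn.at[gid, s]
            if v != 2.0:
                g = gene_lu.loc[gid]
                rows.append(
                    {"chrom": g["chrom"], "start": int(g["start"]),
                     "end": int(g["end"]), "copy_number": float(v)}
                )
        seg = pd.DataFrame(rows, columns=["chrom", "start", "end", "copy_number"])
        segments[s] = seg.sort_values(["chrom", "start"]).reset_index(drop=True)
    return segments, cn, cng_ids, cndg_ids


# ---------------------------------------------------------------- driver

def simulate(config: SimulationConfig, outdir=None) -> SimulationResult:
    """Run the full generator; optionally write the file bundle.

    Files written under ``outdir``: genotypes.vcf, samples.tsv, genes.bed
    (0-based half-open), nonsyn.tsv, env.tsv, cnv/<sample>.tsv and
    truth.json. Identical config (including seed) reproduces identical
    bytes.
    """
    res = generate_genotypes(config)
    segments, cn, cng_ids, cndg_ids = generate_cnv(
        config, res.genes, res.genotypes.samples, res.genotypes.species
    )
    res.segments = segments
    res.cn_truth = cn
    res.truth.cng_genes = cng_ids
    res.truth.cndg_genes = cndg_ids

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lengths = {c: config.chrom_length_bp for c in config.chrom_names()}
        write_vcf(res.genotypes, outdir / "genotypes.vcf", contig_lengths=lengths)
        write_samples_tsv(
            outdir / "samples.tsv",
            res.genotypes.samples,
            res.genotypes.species,
            res.genotypes.populations,
            res.sample_coords["lat"].to_numpy(),
            res.sample_coords["lon"].to_numpy(),
        )
        write_genes_bed(outdir / "genes.bed", res.genes)
        res.nonsyn.rename_axis("gene_id").reset_index().to_csv(
            outdir / "nonsyn.tsv", sep="\t", index=False
        )
        res.env.rename_axis("sample").reset_index().to_csv(
            outdir / "env.tsv", sep="\t", index=False, float_format="%.6f"
        )
        cnv_dir = outdir / "cnv"
        cnv_dir.mkdir(exist_ok=True)
        for s, seg in res.segments.items():
            seg.to_csv(cnv_dir / f"{s}.tsv", sep="\t", index=False)
        res.truth.to_json(outdir / "truth.json")
    return res
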