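"""Pipeline orchestration: validated inputs, staged run, manifest.

A :class:`RunConfig` (usually parsed from YAML) names the input files and
every stage parameter; :func:`run_all` executes the stages in order
(windows -> islands -> cnv-vst -> hka -> rda), writes each stage's output
tables under the run directory and records a manifest with parameter echo
and per-file SHA-256 hashes, so a rerun with the same config reproduces
identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from divland import cnv as cnv_mod
from divland import hka as hka_mod
from divland import islands as islands_mod
from divland import rda as rda_mod
from divland import windows as windows_mod
from divland.genotypes import read_vcf, read_genes_bed

logger = logging.getLogger("divland")

__all__ = ["RunConfig", "validate_inputs", "run_all"]


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    vcf: str
    samples: str
    genes: str | None = None
    nonsyn: str | None = None
    cnv_dir: str | None = None
    env: str | None = None
    outdir: str = "divland_run"
    seed: int = 0
    # windows
    window_bp: int = 20_000
    step_bp: int = 5_000
    min_snps: int = 10
    # islands
    top_fraction: float = 0.01
    island_n_perm: int = 10_000
    island_fdr: float = 0.01
    # cnv
    cnv_top_fraction: float = 0.05
    cnv_n_perm: int = 1_000
    cnv_alpha: float = 0.01
    # hka
    hka_alpha: float = 0.01
    # rda
    prune_r2: float = 0.4
    prune_window_bp: int = 20_000
    prune_step_markers: int = 2
    env_r_threshold: float = 0.7
    rda_n_perm: int = 999
    rda_alpha: float = 0.01
    sd_mult: float = 3.0
    assign_r_threshold: float = 0.6
    mantel_n_perm: int = 999
    # stage switches
    stages: list = field(
        default_factory=lambda: ["windows", "islands", "cnv", "hka", "rda"]
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def validate(self) -> None:
        for name, val, lo, hi in [
            ("top_fraction", self.top_fraction, 0, 1),
            ("cnv_top_fraction", self.cnv_top_fraction, 0, 1),
            ("island_fdr", self.island_fdr, 0, 1),
            ("cnv_alpha", self.cnv_alpha, 0, 1),
            ("hka_alpha", self.hka_alpha, 0, 1),
            ("rda_alpha", self.rda_alpha, 0, 1),
            ("prune_r2", self.prune_r2, 0, 1),
            ("env_r_threshold", self.env_r_threshold, 0, 1),
        ]:
            if not (lo < val <= hi):
                raise ValueError(f"{name}={val} outside ({lo}, {hi}]")
        if self.sd_mult <= 0 or self.window_bp < self.step_bp:
            raise ValueError("bad window geometry or sd_mult")


def validate_inputs(config: RunConfig) -> list:
    """Cross-check the input bundle; returns a list of itemized problems.

    Checks that referenced files exist, VCF sample ids are covered by the
    metadata, exactly two species labels are present, gene models are
    sorted, and the environment table covers all samples. An empty list
    means the bundle is clean.
    """
    problems = []
    config.validate()
    for name in ("vcf", "samples", "genes", "nonsyn", "env"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            problems.append(f"{name}: file not found: {p}")
    if problems:
        return problems

    meta = pd.read_csv(config.samples, sep="\t", dtype=str)
    from cyvcf2 import VCF

    vcf = VCF(config.vcf)
    vcf_samples = list(vcf.samples)
    vcf.close()
    known = set(meta["sample"])
    for s in vcf_samples:
        if s not in known:
            problems.append(f"samples.tsv: VCF sample '{s}' missing from metadata")
    n_species = meta["species"].nunique()
    if n_species != 2:
        problems.append(
            f"samples.tsv: expected exactly 2 species labels, found {n_species}"
        )
    if config.genes:
        genes = read_genes_bed(config.genes)
        for c, sub in genes.groupby("chrom"):
            if not sub["start"].is_monotonic_increasing:
                problems.append(f"genes.bed: unsorted gene starts on {c}")
    if config.env:
        env = pd.read_csv(config.env, sep="\t")
        missing = known - set(env["sample"].astype(str))
        if missing:
            problems.append(f"env.tsv: samples without predictors: {sorted(missing)}")
    if config.cnv_dir and "cnv" in config.stages and not Path(config.cnv_dir).is_dir():
        problems.append(f"cnv_dir: not a directory: {config.cnv_dir}")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    problems = validate_inputs(config)
    if problems:
        raise ValueError("input validation failed:\n" + "\n".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"parameters": asdict(config), "stages": {}, "outputs": {}}

    gt = read_vcf(config.vcf, config.samples)
    genes = read_genes_bed(config.genes) if config.genes else None

    def _stage(name, fn):
        t0 = time.time()
        fn()
        dt = time.time() - t0
        manifest["stages"][name] = {"seconds": round(dt, 3)}
        logger.info("stage %s finished in %.2fs", name, dt)

    windows = None
    pool = None

    if "windows" in config.stages:
        def _windows():
            nonlocal windows, pool
            windows = windows_mod.window_stats(
                gt, window_bp=config.window_bp, step_bp=config.step_bp,
                min_snps=config.min_snps,
            )
            pool = windows_mod.site_component_pool(gt)
            path = outdir / "windows.tsv"
            windows.to_csv(path, sep="\t", index=False)
            manifest["stages"].setdefault("windows", {})
        _stage("windows", _windows)

    islands = None
    if "islands" in config.stages:
        def _islands():
            nonlocal islands
            cand = islands_mod.call_outliers(
                windows, pool, top_fraction=config.top_fraction,
                n_perm=config.island_n_perm, fdr=config.island_fdr,
                seed=config.seed,
            )
            islands = islands_mod.merge_islands(cand.loc[cand["outlier"]])
            cand.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
            islands.to_csv(outdir / "islands.tsv", sep="\t", index=False)
            with (outdir / "islands.bed").open("w") as fh:
                for r in islands.itertuples():
                    fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")
            if len(islands):
                tests = islands_mod.island_background_tests(windows, islands)
                (outdir / "island_tests.json").write_text(
                    json.dumps(tests, indent=1, default=float)
                )
        _stage("islands", _islands)

    if "cnv" in config.stages and config.cnv_dir and Path(config.cnv_dir).is_dir():
        def _cnv():
            segs = {}
            for s in gt.samples:
                p = Path(config.cnv_dir) / f"{s}.tsv"
                segs[s] = (
                    pd.read_csv(p, sep="\t") if p.exists() else pd.DataFrame(
                        columns=["chrom", "start", "end", "copy_number"]
                    )
                )
            cn = cnv_mod.gene_copy_numbers(segs, genes)
            res = cnv_mod.call_cndg(
                cn, gt.species, top_fraction=config.cnv_top_fraction,
                n_perm=config.cnv_n_perm, alpha=config.cnv_alpha,
                seed=config.seed,
            )
            cn.rename_axis("gene_id").to_csv(outdir / "cn_matrix.tsv", sep="\t")
            res.to_csv(outdir / "vst.tsv", sep="\t", index=False)
            res.loc[res["cndg"]].to_csv(outdir / "cndg.tsv", sep="\t", index=False)
        _stage("cnv", _cnv)

    if "hka" in config.stages and genes is not None and config.nonsyn:
        def _hka():
            ns = pd.read_csv(config.nonsyn, sep="\t").set_index("gene_id")[
                "nonsyn_count"
            ]
            psg = hka_mod.call_psg(gt, genes, ns, alpha=config.hka_alpha)
            psg.to_csv(outdir / "psg.tsv", sep="\t", index=False)
            if islands is not None and len(islands):
                try:
                    enr = hka_mod.island_enrichment(psg, islands, genes)
                    (outdir / "psg_island_enrichment.json").write_text(
                        json.dumps(enr, default=float)
                    )
                except ValueError:
                    pass
        _stage("hka", _hka)

    if "rda" in config.stages and config.env:
        def _rda():
            env = pd.read_csv(config.env, sep="\t").set_index("sample").loc[
                gt.samples
            ]
            env = env.drop(columns=[c for c in ("lat", "lon") if c in env.columns])
            env = rda_mod.filter_predictors(env, threshold=config.env_r_threshold)
            kept = rda_mod.ld_prune(
                gt, r2_threshold=config.prune_r2,
                window_bp=config.prune_window_bp,
                step_markers=config.prune_step_markers,
            )
            sub = gt.subset_variants(kept)
            Y = sub.dosage.T
            rda, p = rda_mod.test_axes(
                Y, env, n_perm=config.rda_n_perm, alpha=config.rda_alpha,
                seed=config.seed,
            )
            outl = rda_mod.call_outlier_variants(
                rda, Y, env, sd_mult=config.sd_mult,
                r_threshold=config.assign_r_threshold, alpha=config.rda_alpha,
            )
            ids = sub.variant_ids()
            if len(outl):
                outl["variant_id"] = ids[outl["variant_index"].to_numpy()]
            outl.to_csv(outdir / "rda_outliers.tsv", sep="\t", index=False)
            summary = {
                "n_pruned_snps": int(len(kept)),
                "predictors": list(env.columns),
                "proportion_explained": rda.proportion_explained,
                "axis_p": [None if np.isnan(x) else float(x) for x in p],
            }
            (outdir / "rda_summary.json").write_text(json.dumps(summary))

            # Mantel IBD/IBE: environment-associated outlier SNPs vs the
            # neutral intergenic set, both as linearized population F_ST
            if gt.populations is not None and genes is not None:
                meta = pd.read_csv(config.samples, sep="\t")
                if {"lat", "lon"} <= set(meta.columns):
                    meta = meta.set_index("sample").loc[gt.samples]
                    pop_coords = meta.groupby("population")[["lat", "lon"]].mean()
                    env_full = pd.read_csv(config.env, sep="\t").set_index(
                        "sample"
                    ).loc[gt.samples]
                    env_full = env_full[list(env.columns)]
                    pop_env = env_full.groupby(gt.populations).mean()

                    genic = np.zeros(gt.n_variants, dtype=bool)
                    for g in genes.itertuples():
                        genic |= (
                            (gt.chrom == g.chrom)
                            & (gt.pos >= g.start)
                            & (gt.pos <= g.end)
                        )
                    mantel = {}
                    sets = {"neutral_intergenic": np.flatnonzero(~genic)}
                    if len(outl):
                        sets["env_associated"] = kept[
                            outl["variant_index"].to_numpy()
                        ]
                    for name, snp_idx in sets.items():
                        if len(snp_idx) < 2:
                            continue
                        fst = rda_mod.pairwise_population_fst(gt, snp_idx)
                        try:
                            mantel[name] = rda_mod.mantel_ibd_ibe(
                                fst, pop_coords, pop_env,
                                n_perm=config.mantel_n_perm, seed=config.seed,
                            )
                        except ValueError as err:
                            mantel[name] = {"error": str(err)}
                    (outdir / "mantel.json").write_text(
                        json.dumps(mantel, default=float)
                    )
        _stage("rda", _rda)

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
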