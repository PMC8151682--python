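"""End-to-end orchestration: QC -> adjust -> select -> annotate -> effects
-> venn -> enrich, from one config, with per-stage seeds and a manifest.

The master seed fans out to per-stage seeds through a stable hash of the
stage name, so any stage can be re-run in isolation with the same draw.
The manifest records row counts and SHA-256 hashes of every output file;
re-running an identical config must reproduce identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import adjust, annotate, boruta, effects, io_qc, simulate
from .enrich import enrich as run_enrichment, read_gmt

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "derive_seed", "run_all", "demo_fixture"]

STAGES = ["qc", "adjust", "select", "annotate", "effects", "venn", "enrich"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage seed = low 31 bits of sha256("<master>:<stage>")."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    genotypes: str
    phenotypes: str
    gff3: str
    gmt: str
    outdir: str
    traits: tuple = simulate.DEFAULT_TRAITS
    snp_call_rate: float = 0.99
    animal_call_rate: float = 0.95
    autosomes: tuple = tuple(str(c) for c in range(1, 29))
    boruta: boruta.BorutaConfig = field(default_factory=boruta.BorutaConfig)
    window_bp: int = 5_000
    enrichment_method: str = "BH"
    seed: int = 0

    def __post_init__(self):
        if not self.traits:
            raise ValueError("traits must be non-empty")
        if isinstance(self.boruta, dict):
            self.boruta = boruta.BorutaConfig(**self.boruta)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("genotypes", "phenotypes", "gff3", "gmt"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def record(stage: str, **counts):
        manifest["stages"][stage] = counts
        logger.info("stage %s: %s", stage, counts)

    # --- qc -----------------------------------------------------------------
    g = io_qc.read_genotypes(config.genotypes)
    pheno = io_qc.read_phenotypes(config.phenotypes)
    g, report = io_qc.apply_qc(
        g, config.snp_call_rate, config.animal_call_rate, config.autosomes
    )
    lines = (
        pheno.set_index("hen_id")["line"].reindex(g.sample_ids).to_numpy()
    )
    g = io_qc.naive_impute(g, lines, seed=derive_seed(config.seed, "impute"))
    g = io_qc.orient_minor_allele(g)
    report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    record("qc", snps=g.n_snps, animals=g.n_samples)

    pheno = pheno[pheno["hen_id"].isin(g.sample_ids)].reset_index(drop=True)
    missing_traits = [t for t in config.traits if t not in pheno.columns]
    if missing_traits:
        raise ValueError(f"traits not in phenotype file: {missing_traits}")

    # --- adjust -------------------------------------------------------------
    fits = {t: adjust.fit_adjustment_model(pheno, t) for t in config.traits}
    pheno = adjust.attach_residuals(pheno, fits)
    pd.concat(
        [f.summary_frame().assign(trait=t) for t, f in fits.items()], ignore_index=True
    ).to_csv(outdir / "adjustment_fits.tsv", sep="\t", index=False)
    pheno.to_csv(outdir / "adjusted_phenotypes.csv", index=False)
    record("adjust", traits=len(fits), hens=len(pheno))

    # --- select -------------------------------------------------------------
    confirmed: dict[str, list] = {}
    status_frames = []
    for i, t in enumerate(config.traits):
        cfg = boruta.BorutaConfig(
            perc=config.boruta.perc,
            alpha=config.boruta.alpha,
            max_iter=config.boruta.max_iter,
            n_trees=config.boruta.n_trees,
            correction=config.boruta.correction,
            seed=derive_seed(config.seed, f"select:{t}"),
            resolve_tentative=config.boruta.resolve_tentative,
        )
        res = boruta.boruta_run(g, pheno.set_index("hen_id")[f"resid_{t}"], cfg)
        confirmed[t] = res.confirmed
        status_frames.append(res.to_frame(g.snps).assign(trait=t))
    pd.concat(status_frames, ignore_index=True).to_csv(
        outdir / "boruta_status.tsv", sep="\t", index=False
    )
    record("select", **{t: len(v) for t, v in confirmed.items()})

    # --- annotate -----------------------------------------------------------
    genes = annotate.read_gff3(config.gff3)
    gene_hits: dict[str, pd.DataFrame] = {}
    hit_frames = []
    for t in config.traits:
        snps_t = g.snps[g.snps["snp_id"].isin(confirmed[t])]
        hits = annotate.map_snps_to_genes(snps_t, genes, config.window_bp)
        gene_hits[t] = hits
        hit_frames.append(hits.assign(trait=t))
    pd.concat(hit_frames, ignore_index=True).to_csv(
        outdir / "gene_hits.tsv", sep="\t", index=False
    )
    record("annotate", **{t: int(h["gene_id"].nunique()) for t, h in gene_hits.items()})

    # --- effects ------------------------------------------------------------
    smr_frames, drm_frames = [], []
    n_effects = 0
    for t in config.traits:
        near = gene_hits[t]["snp_id"].unique()
        smr_rs, drm_rs = [], []
        for sid in near:
            try:
                smr_rs.append(effects.fit_smr(g, pheno, sid, t))
                drm_rs.append(effects.fit_drm(g, pheno, sid, t))
            except ValueError as exc:
                logger.warning("effects for %s/%s skipped: %s", sid, t, exc)
        n_effects += len(drm_rs)
        if smr_rs or drm_rs:
            smr_tab, drm_tab = effects.effects_report(smr_rs, drm_rs)
            smr_frames.append(smr_tab)
            drm_frames.append(drm_tab)
    (pd.concat(smr_frames, ignore_index=True) if smr_frames else pd.DataFrame()).to_csv(
        outdir / "smr_effects.tsv", sep="\t", index=False
    )
    (pd.concat(drm_frames, ignore_index=True) if drm_frames else pd.DataFrame()).to_csv(
        outdir / "drm_effects.tsv", sep="\t", index=False
    )
    record("effects", snp_trait_combinations=n_effects)

    # --- venn ---------------------------------------------------------------
    sets = {t: set(h["gene_id"]) for t, h in gene_hits.items()}
    venn = annotate.venn_counts(sets)
    with open(outdir / "venn_counts.tsv", "w") as fh:
        fh.write("region\tcount\n")
        for combo in sorted(venn, key=lambda c: (len(c), c)):
            fh.write("&".join(combo) + f"\t{venn[combo]}\n")
    record("venn", regions=len(venn))

    # --- enrich -------------------------------------------------------------
    collection = read_gmt(config.gmt)
    n_sig = {}
    for t in config.traits:
        if not sets[t] & collection.universe:
            logger.warning("no %s genes inside the gene-set universe; skipping", t)
            n_sig[t] = 0
            continue
        table = run_enrichment(sets[t], collection, method=config.enrichment_method)
        table.to_csv(outdir / f"enrichment_{t}.tsv", sep="\t", index=False)
        n_sig[t] = int(table["significant"].sum())
    record("enrich", **n_sig)

    for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.csv")):
        manifest["files"][p.name] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def demo_fixture(
    outdir,
    seed: int = 0,
    n_hens: int = 524,
    n_snps: int = 2_000,
    n_qtl: int = 5,
    n_genes: int = 40,
    n_sets: int = 10,
    missing_rate: float = 0.002,
) -> dict:
    """Write a small simulated dataset plus a ready-to-run pipeline config.

    Returns a dict of the paths written.  Planted QTL effects default to
    the generator's (clearly supra-polygenic) a=8 N, d=2 N so that the
    selection stage has signals to find at desk scale.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = simulate.SimConfig(
        n_hens=n_hens, n_snps=n_snps, n_qtl=n_qtl,
        qtl_a=(8.0,) * n_qtl, qtl_d=(2.0,) * n_qtl,
        missing_rate=missing_rate, seed=derive_seed(seed, "simulate"),
    )
    g = simulate.simulate_genotypes(cfg)
    pheno, truth = simulate.simulate_phenotypes(g, cfg)
    genes, sets = simulate.simulate_gene_annotation(g, truth, cfg, n_genes=n_genes, n_sets=n_sets)

    paths = dict(
        genotypes=outdir / "genotypes.vcf",
        phenotypes=outdir / "phenotypes.csv",
        gff3=outdir / "genes.gff3",
        gmt=outdir / "gene_sets.gmt",
        truth=outdir / "truth.json",
        config=outdir / "pipeline.yaml",
    )
    simulate.write_vcf(g, paths["genotypes"])
    io_qc.write_phenotypes(pheno, paths["phenotypes"])
    simulate.write_gff3(genes, paths["gff3"])
    simulate.write_gmt(sets, paths["gmt"])
    truth.to_json(paths["truth"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            dict(
                genotypes=str(paths["genotypes"]),
                phenotypes=str(paths["phenotypes"]),
                gff3=str(paths["gff3"]),
                gmt=str(paths["gmt"]),
                outdir=str(outdir / "results"),
                seed=seed,
                boruta=dict(n_trees=300, max_iter=50),
            ),
            fh,
        )
    return {k: str(v) for k, v in paths.items()}
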