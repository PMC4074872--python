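"""End-to-end orchestration of the ecotype-differentiation analysis.

Stages: genotype calling and filtering -> allele frequencies ->
windowed FST scan and cross-population composite-likelihood scan ->
top-quantile intersection into ecotype differentiated regions (EDRs)
-> differentiated SNPs (EDSs) and genes (EDGs) -> per-population
SFS-CLR sweep scans and EDG population assignment -> category
enrichment; independently, NJ phylogenetics, PCA/admixture structure
and phenotype statistics.  The pipeline is deterministic under a fixed
seed and writes a manifest of outputs with checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ecodiff import diff_scan, enrichment, genotyping, io, phylo, simulate, structure, sweep_scan
from ecodiff.genotyping import GenotypeMatrix, PopulationFrequencies
from ecodiff.intervals import Region, point_interval_distance

log = logging.getLogger("ecodiff")


@dataclass
class PipelineConfig:
    """Every stage parameter, with the analysis' standard defaults."""

    # inputs (None -> simulate synthetic data from sim_* settings)
    vcf: str | None = None
    populations_tsv: str | None = None
    gff3: str | None = None
    categories_tsv: str | None = None
    phenotypes_tsv: str | None = None

    # scan parameters
    window: int = 20_000
    step: int = 2_000
    fst_quantile: float = 0.005
    xpclr_window_cm: float = 0.1
    xpclr_grid: int = 2_000
    xpclr_max_snps: int = 150
    xpclr_quantile: float = 0.005
    cm_per_mb: float = 4.0
    clr_grid: int = 1_000
    clr_quantile: float = 0.05
    gene_flank: int = 10_000
    eds_min_diff: float = 0.6
    edg_flank: int = 1_000
    min_called: int = 10
    structure_min_called: int = 100
    bootstrap_replicates: int = 100
    # the tree is built on a subsample: all-pairs ML distances over the
    # full panel are quadratic in samples and the bootstrap multiplies that
    phylo_max_samples: int = 20
    phylo_max_sites: int = 400
    admixture_k: int = 2
    em_max_iter: int = 10_000
    em_tol: float = 1e-6
    seed: int = 0

    # synthetic-data settings used when no VCF is given
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def assign_edgs(
    edrs: list[Region],
    genes: pd.DataFrame,
    eds: pd.DataFrame,
    flank: int = 1_000,
) -> pd.DataFrame:
    """Ecotype differentiated genes: genes overlapping an EDR.

    Each EDG is classed by its nearest differentiated SNP: ``genic``
    when an EDS falls inside the gene body, ``flank`` when the nearest
    EDS lies within ``flank`` bp of either gene end (strand ignored),
    otherwise ``unclassified``.  Raises when the chromosome names of
    the inputs are disjoint.
    """
    if len(edrs) and len(genes):
        region_chroms = {r.chrom for r in edrs}
        gene_chroms = set(genes["chrom"].unique())
        if not region_chroms & gene_chroms:
            raise ValueError(
                f"chromosome name mismatch: regions on {sorted(region_chroms)}, "
                f"genes on {sorted(gene_chroms)}"
            )
    rows = []
    for g in genes.itertuples():
        hit = [
            r for r in edrs
            if r.chrom == g.chrom and g.start < r.end and r.start < g.end
        ]
        if not hit:
            continue
        cls = "unclassified"
        best = None
        sub = eds[eds["chrom"] == g.chrom]
        for pos in sub["pos"]:
            dist = point_interval_distance(int(pos) - 1, int(g.start), int(g.end))
            if best is None or dist < best:
                best = dist
        if best is not None:
            if best == 0:
                cls = "genic"
            elif best <= flank:
                cls = "flank"
        rows.append((g.gene_id, g.chrom, int(g.start), int(g.end), cls))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "eds_class"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    freqs: PopulationFrequencies
    fst_windows: pd.DataFrame
    xpclr_scores: pd.DataFrame
    fst_regions: list[Region]
    xpclr_regions: list[Region]
    edrs: list[Region]
    eds: pd.DataFrame
    edgs: pd.DataFrame
    clr_scores: dict[str, pd.DataFrame]
    sweep_regions: dict[str, list[Region]]
    selected_genes: dict[str, set]
    assignments: list
    enrichment: pd.DataFrame
    manifest: dict


def run_scans(
    freqs: PopulationFrequencies,
    genes: pd.DataFrame | None,
    config: PipelineConfig,
) -> dict:
    """The genomic core: FST + XP-CLR -> EDR -> EDS/EDG -> CLR assignment."""
    fst_sites = diff_scan.fst_sites(freqs)
    fst_windows = diff_scan.window_scan(fst_sites, window=config.window, step=config.step)
    fst_regions = diff_scan.call_top_regions(
        fst_windows, quantile=config.fst_quantile, source="fst", merge_gap=config.step
    )
    xpclr_scores = diff_scan.xpclr_scan(
        freqs,
        objective="pop1",
        window_cm=config.xpclr_window_cm,
        grid=config.xpclr_grid,
        max_snps=config.xpclr_max_snps,
        cm_per_mb=config.cm_per_mb,
    )
    xpclr_regions = diff_scan.call_top_regions(
        xpclr_scores, quantile=config.xpclr_quantile, source="xpclr", grid=config.xpclr_grid
    )
    edrs = diff_scan.intersect_to_edrs(fst_regions, xpclr_regions)
    edrs = diff_scan.attach_member_snps(edrs, freqs)
    eds = diff_scan.identify_eds(freqs, edrs, min_diff=config.eds_min_diff)

    out = {
        "fst_windows": fst_windows,
        "xpclr_scores": xpclr_scores,
        "fst_regions": fst_regions,
        "xpclr_regions": xpclr_regions,
        "edrs": edrs,
        "eds": eds,
        "clr_scores": {},
        "sweep_regions": {},
        "selected_genes": {},
        "edgs": pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "eds_class"]),
        "assignments": [],
    }
    if genes is not None and len(genes):
        out["edgs"] = assign_edgs(edrs, genes, eds, flank=config.edg_flank)

    for tag, p, mask in (("pop1", freqs.p1, freqs.mask1), ("pop2", freqs.p2, freqs.mask2)):
        ok = ~mask
        pop_sites = freqs.sites.loc[ok, ["chrom", "pos"]].copy()
        pop_sites["p"] = p[ok]
        try:
            sfs = sweep_scan.background_sfs(p[ok])
        except ValueError:
            continue
        scores = sweep_scan.clr_scan(
            pop_sites, sfs, grid=config.clr_grid, cm_per_mb=config.cm_per_mb
        )
        regions, selected = sweep_scan.call_sweep_regions(
            scores,
            genes=genes,
            quantile=config.clr_quantile,
            gene_flank=config.gene_flank,
            grid=config.clr_grid,
            source=f"clr_{tag}",
        )
        out["clr_scores"][tag] = scores
        out["sweep_regions"][tag] = regions
        out["selected_genes"][tag] = selected
    if len(out["edgs"]):
        out["assignments"] = sweep_scan.assign_edg_population(
            out["edgs"]["gene_id"].tolist(),
            out["selected_genes"].get("pop1", set()),
            out["selected_genes"].get("pop2", set()),
        )
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Run every stage and write outputs + manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # --- inputs -----------------------------------------------------------
    if config.vcf is not None:
        for name, p in (("vcf", config.vcf), ("gff3", config.gff3)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        pops = io.read_populations_tsv(config.populations_tsv) if config.populations_tsv else {}
        matrix = io.read_vcf(config.vcf, populations=pops)
        genes = io.read_gff3(config.gff3) if config.gff3 else None
        categories = io.read_table(config.categories_tsv) if config.categories_tsv else None
        phen = io.read_table(config.phenotypes_tsv) if config.phenotypes_tsv else None
    else:
        sim_cfg = simulate.SimConfig(seed=config.seed, **config.sim)
        freqs_df, _ = simulate.simulate_frequencies(sim_cfg)
        matrix, table, _ = simulate.simulate_genotype_matrix(freqs_df, sim_cfg)
        matrix = simulate.call_matrix_from_table(table, matrix.populations)
        genes, categories = simulate.simulate_genes_and_categories(sim_cfg)
        phen, _ = simulate.simulate_phenotypes(sim_cfg)
    log.info("inputs ready: %d sites x %d samples", matrix.n_sites, matrix.n_samples)

    # --- genomic scans ----------------------------------------------------
    freqs = genotyping.population_allele_frequencies(matrix, min_called=config.min_called)
    scans = run_scans(freqs, genes, config)

    # --- structure & phylogenetics ---------------------------------------
    struct_matrix = genotyping.select_structure_snps(matrix, config.structure_min_called)
    results_extra = {}
    if struct_matrix.n_sites >= 10 and matrix.n_samples >= 4:
        pca_res = structure.pca(struct_matrix)
        results_extra["pca"] = pca_res
        fit = structure.admixture_em(
            struct_matrix,
            k=config.admixture_k,
            max_iter=config.em_max_iter,
            tol=config.em_tol,
            seed=config.seed,
        )
        results_extra["admixture"] = fit
        pd.DataFrame(
            fit.q, index=struct_matrix.samples,
            columns=[f"Q{k + 1}" for k in range(fit.q.shape[1])],
        ).to_csv(outdir / "admixture_q.tsv", sep="\t")
        pd.DataFrame(
            pca_res.coords, index=pca_res.samples,
            columns=[f"PC{k + 1}" for k in range(pca_res.coords.shape[1])],
        ).to_csv(outdir / "pca_coords.tsv", sep="\t")

    if config.phylo_max_samples >= 4 and struct_matrix.n_sites >= 10:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 99]))
        samp_idx = np.sort(
            rng.choice(
                matrix.n_samples,
                size=min(config.phylo_max_samples, matrix.n_samples),
                replace=False,
            )
        )
        site_idx = np.sort(
            rng.choice(
                struct_matrix.n_sites,
                size=min(config.phylo_max_sites, struct_matrix.n_sites),
                replace=False,
            )
        )
        sub = GenotypeMatrix(
            sites=struct_matrix.sites.iloc[site_idx].reset_index(drop=True),
            samples=[matrix.samples[i] for i in samp_idx],
            populations=matrix.populations[samp_idx],
            dosage=struct_matrix.dosage[np.ix_(site_idx, samp_idx)],
        )
        cons = phylo.bootstrap_consensus(
            sub, replicates=config.bootstrap_replicates, seed=config.seed
        )
        io.write_newick(cons, outdir / "consensus.nwk")
        results_extra["consensus"] = cons

    # --- outputs ----------------------------------------------------------
    io.write_frequencies_tsv(freqs, outdir / "frequencies.tsv")
    scans["fst_windows"].to_csv(outdir / "fst_windows.tsv", sep="\t", index=False)
    scans["xpclr_scores"].to_csv(outdir / "xpclr_scores.tsv", sep="\t", index=False)
    io.write_bed(scans["edrs"], outdir / "edrs.bed")
    scans["eds"].to_csv(outdir / "eds.tsv", sep="\t", index=False)
    scans["edgs"].to_csv(outdir / "edgs.tsv", sep="\t", index=False)
    for tag, regions in scans["sweep_regions"].items():
        io.write_bed(regions, outdir / f"sweeps_{tag}.bed")
    if scans["assignments"]:
        pd.DataFrame([dataclasses.asdict(a) for a in scans["assignments"]]).to_csv(
            outdir / "edg_assignments.tsv", sep="\t", index=False
        )

    enr = pd.DataFrame()
    if categories is not None and genes is not None and len(scans["edgs"]):
        enr = enrichment.enrichment_table(
            set(scans["edgs"]["gene_id"]), categories, set(genes["gene_id"])
        )
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    if phen is not None and len(phen):
        from ecodiff import phenotypes as phen_mod

        phen_mod.summary_table(phen).to_csv(outdir / "phenotype_summary.tsv", sep="\t", index=False)

    manifest = {
        "config": dataclasses.asdict(config),
        "elapsed_s": round(time.time() - t0, 3),
        "n_sites": int(matrix.n_sites),
        "n_samples": int(matrix.n_samples),
        "outputs": {
            p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        freqs=freqs,
        fst_windows=scans["fst_windows"],
        xpclr_scores=scans["xpclr_scores"],
        fst_regions=scans["fst_regions"],
        xpclr_regions=scans["xpclr_regions"],
        edrs=scans["edrs"],
        eds=scans["eds"],
        edgs=scans["edgs"],
        clr_scores=scans["clr_scores"],
        sweep_regions=scans["sweep_regions"],
        selected_genes=scans["selected_genes"],
        assignments=scans["assignments"],
        enrichment=enr,
        manifest=manifest,
    )
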