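"""Synthetic two-population SNP data with planted sweeps and ground truth.

The generator emulates the statistical structure of a low-coverage
resequencing contrast between two crop ecotypes: two populations of ~84
and ~82 accessions, biallelic SNPs with background Nei FST around
0.06-0.13, about 67% missing genotypes per accession, per-site depths in
6..300, planted sweep loci with large allele-frequency differentials and
a site-frequency spectrum skewed toward high-frequency derived alleles
in the swept population, a non-overlapping gene track with category
labels (optionally enriched inside sweeps), and ecotype-structured
phenotypes whose group means default to the reference trait table in
:mod:`ecodiff.phenotypes`.

Background allele frequencies follow the Balding-Nichols model: an
ancestral frequency ``p ~ Uniform(0.05, 0.95)`` and per-population
frequencies ``Beta(p(1-F')/F', (1-p)(1-F')/F')``.  The configured
``fst_background`` is the *realized* two-population Nei FST, not the raw
beta dispersion: with only two demes the per-site Nei estimator averages
to roughly half the dispersion, so the generator calibrates the beta
parameter against the target once, by deterministic Monte-Carlo
bisection (see :func:`beta_dispersion_for_fst`).

Every output is bit-identical under a fixed seed, and a
:class:`SimTruth` object records true frequencies, sweep intervals, true
dosages, ancestry and phenotype effects so every downstream caller can
be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from ecodiff import genotyping
from ecodiff.genotyping import MISSING, GenotypeMatrix
from ecodiff.phenotypes import REFERENCE_TRAIT_TABLE


@dataclass(frozen=True)
class SweepLocus:
    """A planted selective sweep.

    ``differential`` is the minimum between-population allele-frequency
    difference enforced inside the locus; ``sfs_skew >= 1`` pushes the
    swept population's derived-allele frequencies toward fixation
    (``x -> x**(1/sfs_skew)``).  ``swept_pop`` names the population the
    sweep occurred in.
    """

    chrom: str
    center: int
    width: int
    differential: float = 0.9
    sfs_skew: float = 3.0
    swept_pop: str = "pop1"

    def __post_init__(self) -> None:
        if not 0 <= self.differential <= 1:
            raise ValueError("differential must be in [0, 1]")
        if self.sfs_skew <= 0:
            raise ValueError("sfs_skew must be > 0")
        if self.swept_pop not in ("pop1", "pop2"):
            raise ValueError("swept_pop must be 'pop1' or 'pop2'")

    @property
    def start(self) -> int:  # 0-based half-open
        return max(0, self.center - self.width // 2)

    @property
    def end(self) -> int:
        return self.center + self.width // 2


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults for the synthetic two-ecotype data set.

    Defaults mirror the emulated study conditions: 84 + 82 accessions,
    background FST 0.06, 67% missing genotypes, depths 6..300, and a
    genotype-rule concordance of 96% (the reported Sanger validation
    rate, used here as a realism default).  The genome itself is desk
    scale: 2 chromosomes x 2 Mb with 8,000 SNPs.
    """

    n_pop1: int = 84  # upland
    n_pop2: int = 82  # irrigated
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    n_snps: int = 8_000
    fst_background: float = 0.06
    sweep_loci: tuple[SweepLocus, ...] = ()
    missing_rate: float = 0.67
    depth_range: tuple[int, int] = (6, 300)
    seed: int = 0
    genotype_concordance: float = 0.96
    consensus_path_rate: float = 0.10  # fraction of calls routed via the consensus genotype
    bad_site_rate: float = 0.0  # fraction of sites violating the site filters

    def __post_init__(self) -> None:
        if not 0 <= self.fst_background < 1:
            raise ValueError("fst_background must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 < self.genotype_concordance <= 1:
            raise ValueError("genotype_concordance must be in (0, 1]")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] < 0:
            raise ValueError("invalid depth_range")
        loci = tuple(
            SweepLocus(*l) if not isinstance(l, SweepLocus) else l for l in self.sweep_loci
        )
        object.__setattr__(self, "sweep_loci", loci)
        for locus in loci:
            if locus.width >= self.chrom_length:
                raise ValueError("sweep width must be smaller than chrom_length")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def n_samples(self) -> int:
        return self.n_pop1 + self.n_pop2


@dataclass
class SimTruth:
    """Ground truth sufficient to score every downstream caller."""

    sites: pd.DataFrame  # chrom, pos, ref, alt, in_sweep
    p1: np.ndarray  # true ref-allele frequency, pop1
    p2: np.ndarray
    sweep_intervals: list[SweepLocus]
    true_dosage: np.ndarray | None = None  # before missingness/call errors
    bad_sites: np.ndarray | None = None  # sites violating the site filters
    ancestry: np.ndarray | None = None  # true Q for admixture scenarios
    phenotype_means: dict | None = None


# ---------------------------------------------------------------------------
# Balding-Nichols calibration


def _draw_balding_nichols(
    anc: np.ndarray, dispersion: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-population frequencies, redrawn per site until jointly polymorphic."""
    a = anc * (1 - dispersion) / dispersion
    b = (1 - anc) * (1 - dispersion) / dispersion
    p1 = rng.beta(a, b)
    p2 = rng.beta(a, b)
    for _ in range(200):
        pbar = 0.5 * (p1 + p2)
        mono = pbar * (1 - pbar) == 0
        if not mono.any():
            break
        p1[mono] = rng.beta(a[mono], b[mono])
        p2[mono] = rng.beta(a[mono], b[mono])
    return p1, p2


def _realized_nei_fst(dispersion: float, rng: np.random.Generator, n: int) -> float:
    p = rng.uniform(0.05, 0.95, n)
    p1, p2 = _draw_balding_nichols(p, dispersion, rng)
    pbar = 0.5 * (p1 + p2)
    ht = 2 * pbar * (1 - pbar)
    num = 0.5 * (p1 - p2) ** 2
    ok = ht > 0
    return float(np.mean(num[ok] / ht[ok]))


@lru_cache(maxsize=None)
def beta_dispersion_for_fst(target: float, n: int = 150_000) -> float:
    """Beta dispersion whose realized two-population Nei FST equals ``target``.

    Calibrated by bisection on a fixed-seed Monte-Carlo evaluation of
    the realized mean per-site Nei FST (true frequencies, no sampling
    noise); deterministic and cached per target.
    """
    if target <= 0:
        return 0.0
    lo, hi = target, min(0.999, max(0.2, 6 * target))
    rng = np.random.default_rng(20140611)
    if _realized_nei_fst(hi, rng, n) < target:
        hi = 0.999
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        rng = np.random.default_rng(20140611)
        if _realized_nei_fst(mid, rng, n) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Frequencies


def _site_positions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per = np.full(config.n_chrom, config.n_snps // config.n_chrom)
    per[: config.n_snps % config.n_chrom] += 1
    frames = []
    for chrom, k in zip(config.chrom_names, per):
        pos = np.sort(rng.choice(config.chrom_length, size=k, replace=False)) + 1
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    sites = pd.concat(frames, ignore_index=True)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, len(sites))
    alt_idx = (ref_idx + rng.integers(1, 4, len(sites))) % 4
    sites["ref"] = bases[ref_idx]
    sites["alt"] = bases[alt_idx]
    return sites


def simulate_frequencies(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw per-site true allele frequencies for both populations.

    Returns a frame with ``chrom, pos, ref, alt, p1, p2`` (reference
    allele frequencies) and the matching :class:`SimTruth`.  Background
    sites follow the calibrated Balding-Nichols model; sites inside a
    sweep locus get a between-population differential of at least the
    configured value, with the swept population's derived allele pushed
    toward fixation by the SFS skew.
    """
    rng = np.random.default_rng(config.seed)
    sites = _site_positions(config, rng)
    n = len(sites)

    anc = rng.uniform(0.05, 0.95, n)
    disp = beta_dispersion_for_fst(config.fst_background)
    if disp == 0.0:
        p1 = anc.copy()
        p2 = anc.copy()
    else:
        # every emitted site is a SNP: monomorphic draws are rejected
        # (at high dispersion the beta draws can hit 0/1 in both demes)
        p1, p2 = _draw_balding_nichols(anc, disp, rng)

    in_sweep = np.zeros(n, dtype=bool)
    chrom_arr = sites["chrom"].to_numpy()
    pos0 = sites["pos"].to_numpy() - 1
    for locus in config.sweep_loci:
        sel = (chrom_arr == locus.chrom) & (pos0 >= locus.start) & (pos0 < locus.end)
        in_sweep |= sel
        k = int(sel.sum())
        if k == 0:
            continue
        # The unswept population keeps the derived allele at a moderate
        # ancestral-like frequency within the band the differential allows;
        # the swept population's derived allele is pushed near fixation and
        # further skewed upward (x -> x**(1/sfs_skew)).
        band = 1 - locus.differential
        x_other = rng.uniform(min(0.05, band / 2), band, k)
        x_swept = x_other + locus.differential + rng.uniform(0, 1, k) * (band - x_other)
        x_swept = x_swept ** (1.0 / locus.sfs_skew)
        if locus.swept_pop == "pop1":
            p1[sel], p2[sel] = 1 - x_swept, 1 - x_other
        else:
            p2[sel], p1[sel] = 1 - x_swept, 1 - x_other

    freqs = sites.copy()
    freqs["p1"] = p1
    freqs["p2"] = p2
    truth_sites = sites.copy()
    truth_sites["in_sweep"] = in_sweep
    truth = SimTruth(
        sites=truth_sites, p1=p1.copy(), p2=p2.copy(),
        sweep_intervals=list(config.sweep_loci),
    )
    return freqs, truth


# ---------------------------------------------------------------------------
# Genotypes and raw call records


@dataclass
class CallTable:
    """Column-oriented stream of per-(site, sample) raw call evidence.

    Arrays are shaped ``(n_sites, n_samples)`` (site-level fields are
    per-site).  ``iter_records`` yields :class:`SiteCallRecord` objects;
    :func:`call_matrix_from_table` applies the genotype decision rules
    in bulk.
    """

    sites: pd.DataFrame
    samples: list[str]
    q_best: np.ndarray
    q_second: np.ndarray
    q_consensus: np.ndarray
    best_base: np.ndarray  # byte codes into "ACGT"
    second_base: np.ndarray
    consensus_genotype: np.ndarray  # IUPAC codes, str dtype
    depth: np.ndarray
    copy_number: np.ndarray  # per site
    site_quality: np.ndarray  # per site

    def iter_records(self):
        chroms = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        for i in range(len(self.sites)):
            for j in range(len(self.samples)):
                yield j, genotyping.SiteCallRecord(
                    chrom=chroms[i],
                    pos=int(pos[i]),
                    best_base=str(self.best_base[i, j]),
                    second_base=str(self.second_base[i, j]),
                    q_best=float(self.q_best[i, j]),
                    q_second=float(self.q_second[i, j]),
                    q_consensus=float(self.q_consensus[i, j]),
                    consensus_genotype=str(self.consensus_genotype[i, j]),
                    depth=int(self.depth[i, j]),
                    copy_number=float(self.copy_number[i]),
                    site_quality=float(self.site_quality[i]),
                )


def _iupac_codes(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    het = np.array(
        [genotyping.IUPAC[frozenset((r, a))] for r, a in zip(ref, alt)], dtype="U1"
    )
    return het


def simulate_genotype_matrix(
    freqs: pd.DataFrame, config: SimConfig, emit_records: bool = True
) -> tuple[GenotypeMatrix, CallTable | None, SimTruth]:
    """Draw genotypes binomially from population frequencies, with evidence.

    Returns the true genotype matrix (missingness applied), a
    :class:`CallTable` of raw evidence constructed so that the genotype
    decision rules recover the true genotype for ~``genotype_concordance``
    of determinable calls, and a truth object carrying the pre-missing
    dosages and the flagged filter-violating sites.  With
    ``emit_records=False`` (frequency-level analyses that skip the raw
    evidence) the call table is None; the matrix is unaffected.
    """
    if not ((freqs["p1"].between(0, 1)).all() and (freqs["p2"].between(0, 1)).all()):
        raise ValueError("frequencies must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_sites = len(freqs)
    n1, n2 = config.n_pop1, config.n_pop2
    samples = [f"U{i + 1:03d}" for i in range(n1)] + [f"I{i + 1:03d}" for i in range(n2)]
    populations = np.array(["pop1"] * n1 + ["pop2"] * n2, dtype=object)

    p = np.concatenate(
        [
            np.repeat(freqs["p1"].to_numpy()[:, None], n1, axis=1),
            np.repeat(freqs["p2"].to_numpy()[:, None], n2, axis=1),
        ],
        axis=1,
    )
    true_dosage = rng.binomial(2, p).astype(np.int8)
    missing = rng.random(true_dosage.shape) < config.missing_rate
    dosage = np.where(missing, np.int8(MISSING), true_dosage)

    sites = freqs[["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    matrix = GenotypeMatrix(sites=sites, samples=samples, populations=populations, dosage=dosage)

    table = (
        _build_call_table(sites, samples, true_dosage, missing, config, rng)
        if emit_records
        else None
    )

    bad = np.zeros(n_sites, dtype=bool)
    if table is not None and config.bad_site_rate > 0:
        bad = rng.random(n_sites) < config.bad_site_rate
        kind = rng.integers(0, 3, n_sites)
        table.site_quality[bad & (kind == 0)] = rng.uniform(0, 14.9, int((bad & (kind == 0)).sum()))
        table.copy_number[bad & (kind == 1)] = rng.uniform(1.6, 3.0, int((bad & (kind == 1)).sum()))
        lo = bad & (kind == 2)
        table.depth[lo] = rng.integers(0, genotyping.DEPTH_MIN, (int(lo.sum()), len(samples)))

    truth_sites = sites.copy()
    truth = SimTruth(
        sites=truth_sites,
        p1=freqs["p1"].to_numpy().copy(),
        p2=freqs["p2"].to_numpy().copy(),
        sweep_intervals=list(config.sweep_loci),
        true_dosage=true_dosage,
        bad_sites=bad,
    )
    return matrix, table, truth


def _build_call_table(
    sites: pd.DataFrame,
    samples: list[str],
    true_dosage: np.ndarray,
    missing: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> CallTable:
    n_sites, n_samp = true_dosage.shape
    ref = sites["ref"].to_numpy()
    alt = sites["alt"].to_numpy()
    het_code = _iupac_codes(ref, alt)

    # reported genotype: true with prob concordance, a perturbed one otherwise
    wrong = (~missing) & (rng.random(true_dosage.shape) >= config.genotype_concordance)
    reported = true_dosage.copy()
    # hets miscalled as a random homozygote, homozygotes miscalled as het
    flip_to = np.where(
        true_dosage == 1, np.where(rng.random(true_dosage.shape) < 0.5, 0, 2), 1
    ).astype(np.int8)
    reported[wrong] = flip_to[wrong]

    is_het = reported == 1
    ref_mat = np.broadcast_to(ref[:, None], reported.shape)
    alt_mat = np.broadcast_to(alt[:, None], reported.shape)
    hom_base = np.where(reported == 2, ref_mat, alt_mat)
    other = np.where(reported == 2, alt_mat, ref_mat)

    best_base = np.where(is_het, ref_mat, hom_base).astype("U1")
    second_base = np.where(is_het, alt_mat, other).astype("U1")

    q_best = rng.uniform(25, 40, reported.shape)
    q_second = np.where(is_het, rng.uniform(20, 35, reported.shape), rng.uniform(0, 15, reported.shape))
    q_consensus = rng.uniform(0, 15, reported.shape)

    # a fraction of determinable calls carry the evidence only in the
    # consensus genotype (both base qualities below the threshold)
    via_cons = (~missing) & (rng.random(reported.shape) < config.consensus_path_rate)
    q_best = np.where(via_cons, rng.uniform(0, 19.9, reported.shape), q_best)
    q_second = np.where(via_cons, rng.uniform(0, 19.9, reported.shape), np.minimum(q_second, q_best - 0.1))
    q_second = np.clip(q_second, 0, None)
    q_consensus = np.where(via_cons, rng.uniform(25, 40, reported.shape), q_consensus)

    cons_geno = np.where(
        is_het,
        np.broadcast_to(het_code[:, None], reported.shape),
        hom_base,
    ).astype("U1")

    # undeterminable entries: every quality below the acceptance threshold
    q_best = np.where(missing, rng.uniform(0, 19.9, reported.shape), q_best)
    q_second = np.where(missing, rng.uniform(0, 15, reported.shape), q_second)
    q_consensus = np.where(missing, rng.uniform(0, 19.9, reported.shape), q_consensus)

    depth = rng.integers(config.depth_range[0], config.depth_range[1] + 1, reported.shape)
    copy_number = rng.uniform(0.5, 1.45, n_sites)
    site_quality = rng.uniform(20, 60, n_sites)

    return CallTable(
        sites=sites,
        samples=list(samples),
        q_best=q_best,
        q_second=q_second,
        q_consensus=q_consensus,
        best_base=best_base,
        second_base=second_base,
        consensus_genotype=cons_geno,
        depth=depth,
        copy_number=copy_number,
        site_quality=site_quality,
    )


def call_matrix_from_table(table: CallTable, populations: np.ndarray) -> GenotypeMatrix:
    """Apply the genotype decision rules to a raw call table in bulk."""
    ref = table.sites["ref"].to_numpy()
    alt = table.sites["alt"].to_numpy()
    shape = table.q_best.shape
    ref_mat = np.broadcast_to(ref[:, None], shape)
    alt_mat = np.broadcast_to(alt[:, None], shape)
    best_is_ref = table.best_base == ref_mat
    second_is_ref = table.second_base == ref_mat
    best_valid = best_is_ref | (table.best_base == alt_mat)
    second_valid = second_is_ref | (table.second_base == alt_mat)

    het_code = _iupac_codes(ref, alt)
    cons = table.consensus_genotype
    cons_dosage = np.full(shape, MISSING, dtype=np.int8)
    cons_dosage[cons == ref_mat] = 2
    cons_dosage[cons == alt_mat] = 0
    cons_dosage[cons == np.broadcast_to(het_code[:, None], shape)] = 1

    dosage = genotyping.call_genotypes_vectorized(
        table.q_best,
        table.q_second,
        table.q_consensus,
        best_is_ref,
        second_is_ref,
        best_valid,
        second_valid,
        cons_dosage,
    )
    return GenotypeMatrix(
        sites=table.sites.copy(),
        samples=list(table.samples),
        populations=populations,
        dosage=dosage,
    )


# ---------------------------------------------------------------------------
# Genes, categories, phenotypes, admixture


def simulate_genes_and_categories(
    config: SimConfig,
    n_genes: int | None = None,
    category: str = "focal",
    category_fraction: float = 0.10,
    enrichment_fold: float = 1.0,
    gene_length: tuple[int, int] = (1_000, 5_000),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tile non-overlapping genes over the chromosomes and label categories.

    Genes in ``category`` occur with probability ``category_fraction``
    outside sweep loci and ``enrichment_fold`` times that inside them
    (capped at 1).  Returns ``(genes, categories)`` where genes have
    columns ``chrom, start, end, strand, gene_id`` (0-based half-open)
    sorted and non-overlapping, and categories map ``gene_id`` to
    ``category``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    if n_genes is None:
        # rice-like density: roughly one gene per 12 kb
        n_genes = max(config.n_chrom, config.n_chrom * config.chrom_length // 12_000)
    per = np.full(config.n_chrom, n_genes // config.n_chrom)
    per[: n_genes % config.n_chrom] += 1
    rows = []
    gid = 0
    for chrom, k in zip(config.chrom_names, per):
        lengths = rng.integers(gene_length[0], gene_length[1] + 1, k)
        slack = config.chrom_length - int(lengths.sum())
        if slack <= k:
            raise ValueError("chromosome too short for requested gene count")
        gaps = rng.multinomial(slack - k, np.full(k + 1, 1.0 / (k + 1))) + 1
        start = 0
        for i in range(k):
            start += int(gaps[i])
            end = start + int(lengths[i])
            gid += 1
            rows.append((chrom, start, end, "+" if rng.random() < 0.5 else "-", f"G{gid:05d}"))
            start = end
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])

    in_sweep = np.zeros(len(genes), dtype=bool)
    for locus in config.sweep_loci:
        sel = (
            (genes["chrom"] == locus.chrom)
            & (genes["start"] < locus.end)
            & (genes["end"] > locus.start)
        )
        in_sweep |= sel.to_numpy()
    p_in = min(1.0, enrichment_fold * category_fraction)
    prob = np.where(in_sweep, p_in, category_fraction)
    labelled = rng.random(len(genes)) < prob
    categories = pd.DataFrame(
        {"gene_id": genes.loc[labelled, "gene_id"].to_numpy(), "category": category}
    )
    return genes, categories


def simulate_phenotypes(
    config: SimConfig,
    trait_table: dict | None = None,
    sd_scale: float = 1.0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw per-accession trait values, normal around the group means.

    ``trait_table`` maps trait -> {(environment, ecotype): (mean, sd)}
    and defaults to the reference table of printed group summaries.
    ``sd_scale=0`` yields exactly the configured means.
    """
    trait_table = trait_table if trait_table is not None else REFERENCE_TRAIT_TABLE
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    upland = [f"U{i + 1:03d}" for i in range(config.n_pop1)]
    irrigated = [f"I{i + 1:03d}" for i in range(config.n_pop2)]
    rows = []
    for trait, cells in trait_table.items():
        for (env, eco), (mean, sd) in cells.items():
            accs = upland if eco == "upland" else irrigated
            vals = rng.normal(mean, sd * sd_scale, len(accs))
            rows.extend(
                (acc, eco, env, trait, float(v)) for acc, v in zip(accs, vals)
            )
    table = pd.DataFrame(rows, columns=["accession", "ecotype", "environment", "trait", "value"])
    truth = SimTruth(
        sites=pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]),
        p1=np.empty(0),
        p2=np.empty(0),
        sweep_intervals=[],
        phenotype_means=trait_table,
    )
    return table, truth


def simulate_admixed_genotypes(
    ancestral_freqs: np.ndarray,
    q: np.ndarray,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Genotypes for admixed individuals with known ancestry proportions.

    ``ancestral_freqs`` is (K, n_sites) reference-allele frequencies per
    source population; ``q`` is (n_samples, K) ancestry fractions.  Each
    allele copy is drawn from the individual's mixture frequency
    ``(q @ F)``.
    """
    q = np.asarray(q, dtype=float)
    f = np.asarray(ancestral_freqs, dtype=float)
    if q.shape[1] != f.shape[0]:
        raise ValueError("q columns must match freq rows (K)")
    if not np.allclose(q.sum(axis=1), 1.0):
        raise ValueError("each q row must sum to 1")
    rng = np.random.default_rng(seed)
    p = q @ f  # (n_samples, n_sites)
    dosage = rng.binomial(2, p).T.astype(np.int8)  # (n_sites, n_samples)
    if missing_rate > 0:
        dosage = np.where(rng.random(dosage.shape) < missing_rate, np.int8(MISSING), dosage)
    n_sites = f.shape[1]
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_sites + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    samples = [f"S{i + 1:03d}" for i in range(q.shape[0])]
    matrix = GenotypeMatrix(
        sites=sites,
        samples=samples,
        populations=np.array(["other"] * len(samples), dtype=object),
        dosage=dosage,
    )
    truth = SimTruth(
        sites=sites, p1=f[0], p2=f[-1], sweep_intervals=[], ancestry=q.copy()
    )
    return matrix, truth


def default_sweep_loci(config: SimConfig, n_per_chrom: int = 1) -> tuple[SweepLocus, ...]:
    """Evenly spaced sweep loci, one (or more) per chromosome, swept in pop1."""
    loci = []
    for chrom in config.chrom_names:
        for i in range(n_per_chrom):
            center = int((i + 1) * config.chrom_length / (n_per_chrom + 1))
            loci.append(SweepLocus(chrom=chrom, center=center, width=60_000))
    return tuple(loci)


def with_sweeps(config: SimConfig, n_per_chrom: int = 1) -> SimConfig:
    return replace(config, sweep_loci=default_sweep_loci(config, n_per_chrom))
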