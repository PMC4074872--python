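# Methods

`ecodiff` reimplements, as a tested library, the comparative-genomics
workflow used to contrast two diverged crop ecotypes — the motivating
system is upland (dry-land) versus irrigated (paddy) rice — from
low-coverage population resequencing. This note documents the models,
the numerical choices, and what the synthetic data generator does and
does not emulate.

## Genotype determination from low-coverage calls

Input is per-site, per-accession consensus-caller evidence: best and
second-best base with Phred-scale average qualities, a consensus
genotype (IUPAC) with its quality, read depth, site quality and a
nearby copy-number score. Sites are kept iff site quality ≥ 15, copy
number ≤ 1.5 and 6 ≤ depth ≤ 300 (boundary depths kept; only strict
violations of "less than 6 or larger than 300" are removed). Genotypes
are accepted only at Phred ≥ 20 (error rate ≤ 1%):

| q_best | q_second | q_consensus | call |
|---|---|---|---|
| ≥ 20 | < 20 | – | homozygous best base |
| ≥ 20 | ≥ 20 | – | heterozygous best/second |
| < 20 | < 20 | ≥ 20 | consensus genotype |
| < 20 | < 20 | < 20 | missing |

A call whose bases are inconsistent with the site's ref/alt pair is
missing (with a warning for the consensus path). Dosage counts
reference alleles (0/1/2). Allele frequencies are allele-counting
estimates over non-missing calls; a site is masked for a population
unless **strictly more than** `min_called` (default 10) individuals are
genotyped — of the two phrasings such rules are usually written with,
the stricter one is adopted and the threshold is configurable. The
structure-SNP subset analogously keeps sites called in more than 100
samples.

## Windowed Nei FST

Per site, with p̄ = (p₁+p₂)/2, H_T = 2p̄(1−p̄) and
H_S = [2p₁(1−p₁) + 2p₂(1−p₂)]/2,

    FST = (H_T − H_S) / H_T  (0 when H_T = 0).

This is Nei's G_ST without sample-size correction, the scan default. A
corrected variant (within-population heterozygosities scaled by
2n/(2n−1)) is available behind a flag; it is the right choice when
comparing estimates against a known simulated dispersion, because at
the ~27 genotyped individuals per site that 67% missingness leaves, the
uncorrected estimator is inflated by roughly +0.01. Window values are
unweighted means over the SNPs in 20-kb windows tiled every 2 kb from
position 1; empty windows are omitted.

## Cross-population composite likelihood (XP-CLR-style)

At each grid point (2-kb spacing) the score contrasts a sweep model
against neutral drift for the objective population's frequencies given
the reference population's, over the ≤ 150 SNPs nearest the grid point
within a 0.1-cM window (constant 4 cM/Mb map by default — a rice-scale
genome average — overridable by a map file):

* **Neutral:** p_obj ~ Normal(p_ref, ω·p_ref(1−p_ref) + v_samp), with ω
  the genome-wide method-of-moments drift dispersion and v_samp the
  binomial sampling variance (+1e−4 floor).
* **Sweep of scale s (Morgans):** a lineage at map distance r escapes
  with probability c = 1 − exp(−r/s); the mean is pulled toward
  fixation of one allele, μ = c·p_ref + (1−c)·B with B ∈ {0,1}
  maximised per site, and the drift variance shrinks by c².

The score is 2·max_s Σ(log L₁ − log L₀), maximised over a 12-point
geometric grid of s (10⁻⁵–5·10⁻³ Morgans) and floored at 0; s → 0
collapses the sweep model onto the null, so scores are non-negative by
construction. This is a deliberately simplified reimplementation of the
published cross-population composite-likelihood idea — no LD
down-weighting, normal approximation throughout — with the printed
window/grid/SNP-count parameters as defaults.

## Single-population SFS composite likelihood (SweepFinder-style)

The background site-frequency spectrum is the genome-wide empirical
distribution of minor-allele frequencies, folded by default (ancestral
states unknown), binned into 20 equal bins over (0, 0.5] with a 0.5
pseudo-count per bin. At each grid point (1-kb spacing) and sweep scale
α (Morgans), a site at map distance d escapes with probability
e = 1 − exp(−d/α) and its frequency is modelled by the mixture
e·background + (1−e)·extreme, where the extreme component decays
geometrically (ratio 0.25) from the most extreme bin. The score is the
maximised log-likelihood-ratio sum over sites within 50 kb, doubled and
floored at 0 (α → 0 nests the null). Distances are floored at half a
base pair so a site exactly on a grid point still escapes in the null
limit. On a flat (uniform-frequency) background the sweep model can
never win and every score is exactly 0 — the degenerate all-tied case;
on realistic population-model backgrounds ~20% of grid points score
positive and the empirical top-5% threshold is well defined.

## Region calling

Thresholds are empirical top-quantile values: the largest
⌊n·q⌋ windows/grid points, with all values tied at the threshold
included (deterministic and permutation-invariant). Significant
windows become intervals and are merged when overlapping, book-ended,
or within one step (2 kb); significant grid points become their grid
cells, merged within two grid steps. Ecotype differentiated regions
(EDRs) are the interval intersection of the top-5‰ FST and top-5‰
XP-CLR regions. EDSs are SNPs inside an EDR with |p₁ − p₂| **strictly**
greater than 0.6; EDGs are genes overlapping an EDR, classed by their
nearest EDS as genic / within-1-kb flank (strand ignored) /
unclassified. Genes within 10 kb (inclusive) of a top-5% CLR grid
point in a population are that population's potential selection
targets; EDGs are then labelled upland-only / irrigated-only / both /
unassigned — an exhaustive, disjoint partition.

Coordinates are 0-based half-open internally (BED convention); VCF
positions and GFF3 intervals are converted at the I/O boundary, and the
converters are property-tested as inverse pairs.

## Phylogenetics

Pairwise distances use the F84 substitution model with ts/tv ratio 2.0,
empirical base frequencies from each pair's shared sites, no rate
variation and uniform site weights. Genotypes enter as nucleotide
observations: homozygotes as their base, heterozygotes as half weight
on each allele, missing sites pairwise-deleted. The distance is the
maximiser of the count-table likelihood Σ C_ij log(π_i P_ij(t)), with
P(t) from the eigendecomposition of the reversible F84 rate matrix
(transition excess solved from the requested ts/tv ratio and clamped at
0 when the frequencies cannot support it — the F81 limit). With equal
frequencies and ratio 0.5 the model reduces to Jukes–Cantor, which the
tests exploit as a closed-form oracle.

Trees are Saitou–Nei neighbor joining, deterministic (Q-criterion ties
break to the lowest-index pair), with negative branch lengths clamped
to 0 and the deficit moved to the sibling branch; trees are unrooted.
Bootstrap resamples SNP columns with replacement; the consensus keeps
bipartitions in strictly more than 50% of replicates (strict majority
rule, via dendropy) with integer percentage supports. The pipeline
builds its tree on a seeded subsample (20 samples × 400 sites by
default) because all-pairs ML distances are quadratic in samples and
the bootstrap multiplies that hundredfold; the `phylo` subcommand runs
any panel in full.

## Population structure

PCA mean-imputes missing dosages per site, centres, scales by
√(p(1−p)), drops zero-variance sites and takes the SVD. Admixture is
the frequentist binomial mixture: each of an individual's two allele
copies at site j is drawn with probability Σ_k q_ik f_kj. EM ascends
the log-likelihood monotonically (asserted per iteration in tests);
missing genotypes are skipped. Defaults: max 10,000 iterations,
relative log-likelihood tolerance 1e−6, 5 random restarts (seeds
derived from the user seed) keeping the best likelihood; frequencies
are clipped to [1e−9, 1−1e−9] to keep the likelihood finite. K = 1 has
the closed-form optimum (q ≡ 1, f = mean dosage / 2), which EM reaches
in one step. Label switching in evaluations is resolved by greedy
column matching against truth.

## Phenotype statistics

Long-format table: one value per (accession, ecotype, environment,
trait). Group cells are mean ± sample SD; the between-ecotype column is
|mean_upland − mean_irrigated| and its percentage of the
irrigated-ecotype mean; between-environment changes are signed
percentages of the irrigated-condition mean. Rounding is
half-away-from-zero at one decimal — the convention that reproduces
every legible reference cell exactly. Student's equal-variance t is the
default two-sample test (Welch behind a flag; zero-variance equal-mean
input returns P = 1 by convention); trait correlations are Pearson with
the t-transform P value, paired by accession.

## Enrichment

For a gene category, the 2×2 table [[a, b−a], [c−a, (d−b)−(c−a)]]
(category×EDG against the genome background; genes counted once) is
tested by chi-square without continuity correction; fold =
(a/b)/(c/d). Raw P values by default, Benjamini–Hochberg behind a
flag. A warning is logged when an expected cell drops below 1. With
study-scale EDG counts (~150) the asymptotic test is mildly
anti-conservative (empirical null rejection ~0.08 at α = 0.05); the
calibration check therefore uses a table with expected in-category
count 40, where the empirical rate is ~0.05.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes: 84 +
82 accessions, ~67% missing genotypes per accession, depths 6–300,
background Nei FST ≈ 0.06 (0.13 and 0.55 are the within-subspecies and
between-subspecies scales of the system), and genotype evidence built
so the decision rules recover the truth for 96% of determinable calls
(the reported validation rate, used as a realism default). The default
genome is desk scale — 2 chromosomes × 2 Mb with 8,000 SNPs — and
experiments size it up as needed.

Background frequencies follow the Balding–Nichols model with the
ancestral frequency uniform on (0.05, 0.95). The configured
`fst_background` is defined as the **realized** mean per-site Nei FST:
with two demes the per-site G_ST averages to roughly half the beta
dispersion, so the generator calibrates the dispersion once per target
by deterministic fixed-seed bisection. Jointly monomorphic draws are
redrawn per site (every emitted site is a SNP), and the calibration
uses the identical conditional.

Planted sweeps: inside a locus the unswept population keeps the derived
allele at a moderate ancestral-like frequency within the band the
differential allows; the swept population's derived allele sits at
least `differential` above it and is further skewed toward fixation by
x → x^(1/sfs_skew). This gives the swept population the near-fixed SFS
signature while leaving the other population's spectrum close to
background — which is what lets the single-population scans assign
sweeps to the correct population. At extreme differentials (≥ 0.9) the
band forces the unswept population low as well; that regime genuinely
produces "selected in both" labels, consistent with how such scans
behave on strongly differentiated loci.

What the generator does **not** emulate: linkage disequilibrium and
recombination (sites are drawn independently; there are no haplotypes),
read-level errors (evidence qualities are drawn directly), indels and
multiallelic sites, gene-length or density biases, and ascertainment
beyond joint polymorphism. Passing tests therefore demonstrate the
statistical machinery — estimator recovery, ranking, calling,
calibration — on data with the assumed moment structure, not robustness
to LD, batch effects or real ascertainment schemes.

## Experiment sizes

The acceptance checks run at: 10,000 SNPs × (80+80) samples for FST
recovery (three dispersion levels); 50 replicates of a 4-chromosome ×
4-Mb genome (32,000 SNPs) with two 40-kb sweeps for sweep recovery —
the planted sweeps occupy ~0.5% of the genome, matching the emulated
study's density of differentiated regions and below the 5‰ calling
quantile, which is a prerequisite of quantile-based calling; 60
samples × 5,000 SNPs for admixture recovery; 16 samples × 300 SNPs ×
100 bootstrap replicates for the population-split support; 1,000
replicates for each null-calibration check. The full acceptance script
completes in about a minute on one CPU.

## Known limitations

* The XP-CLR and CLR scores are faithful-in-spirit simplifications:
  no LD weighting, normal/mixture approximations, fixed parameter
  grids. Scores are comparable within a scan (quantile calling), not
  across implementations.
* The genetic map defaults to a constant 4 cM/Mb; supply a map file for
  anything map-sensitive.
* F84 distances assume sites are independent and identically weighted;
  heterozygote ambiguity handling (half weight per allele) is this
  package's choice.
* The admixture EM can need many iterations near K-overfitted optima;
  restarts mitigate but do not eliminate local maxima.
* Chi-square enrichment is asymptotic; with few expected in-category
  genes prefer the logged warning seriously (an exact test is not
  provided).
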