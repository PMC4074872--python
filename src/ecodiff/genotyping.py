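"""Site filters, genotype decision rules and allele-frequency estimation.

The genotype data this module expects come from low-coverage population
resequencing where a consensus caller reports, per site and accession,
the best and second-best base with Phred-scale average qualities plus a
consensus genotype.  Genotypes are determined by quality decision rules
(a call is only accepted when supported at Phred >= 20, i.e. an error
rate of at most 1%):

* best base quality >= 20 and second-best < 20  -> homozygous best base;
* best and second-best both >= 20               -> heterozygous best/second;
* both < 20 but consensus quality >= 20         -> the consensus genotype;
* otherwise the genotype is missing.

Sites themselves are pre-filtered on site quality (>= 15), nearby copy
number (<= 1.5) and read depth (6..300 inclusive).  Allele frequencies
per population are estimated by allele counting over non-missing calls
and a site is masked for a population unless strictly more than
``min_called`` individuals were genotyped there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

# filter thresholds
SITE_QUALITY_MIN = 15.0
COPY_NUMBER_MAX = 1.5
DEPTH_MIN = 6
DEPTH_MAX = 300
# genotype-quality acceptance threshold (Phred 20 ~ error rate <= 1%)
GQ_MIN = 20.0

BASES = ("A", "C", "G", "T")

# IUPAC ambiguity codes for unordered base pairs (homozygotes map to the base)
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("AC"): "M", frozenset("GT"): "K",
    frozenset("CG"): "S", frozenset("AT"): "W",
}
IUPAC_TO_PAIR = {code: tuple(sorted(bases)) for bases, code in IUPAC.items()}
IUPAC_TO_PAIR.update({b: (b, b) for b in BASES})


@dataclass(frozen=True)
class SiteCallRecord:
    """Per-site per-accession raw consensus-caller evidence."""

    chrom: str
    pos: int  # 1-based
    best_base: str
    second_base: str
    q_best: float
    q_second: float
    q_consensus: float
    consensus_genotype: str  # IUPAC code
    depth: int
    copy_number: float
    site_quality: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("q_best", "q_second", "q_consensus", "site_quality"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass
class GenotypeMatrix:
    """Biallelic sites x samples reference-allele dosage matrix.

    ``dosage`` holds values in {0, 1, 2} or :data:`MISSING` (-1), shape
    ``(n_sites, n_samples)``.  ``sites`` is a DataFrame with columns
    ``chrom, pos, ref, alt`` (pos 1-based), strictly increasing within
    each chromosome.  ``populations`` labels every sample as ``pop1``,
    ``pop2`` or ``other``.
    """

    sites: pd.DataFrame
    samples: list[str]
    populations: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValueError("dosage shape does not match sites x samples")
        if len(self.populations) != len(self.samples):
            raise ValueError("population labels must cover all samples")
        pos = self.sites["pos"].to_numpy()
        chrom = self.sites["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (pos[1:] <= pos[:-1])):
            raise ValueError("site order must be strictly increasing within chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, population: str) -> np.ndarray:
        return np.flatnonzero(self.populations == population)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=self.samples,
            populations=self.populations,
            dosage=self.dosage[idx],
        )


@dataclass
class PopulationFrequencies:
    """Per-site reference-allele frequency and call count per population.

    ``p1``/``p2`` are defined (non-NaN) only where the corresponding
    mask is clear; ``mask1``/``mask2`` is True where a site is unusable
    for that population (too few genotyped individuals).
    """

    sites: pd.DataFrame
    p1: np.ndarray
    n1: np.ndarray
    p2: np.ndarray
    n2: np.ndarray
    mask1: np.ndarray
    mask2: np.ndarray

    @property
    def unmasked(self) -> np.ndarray:
        """Sites usable in both populations."""
        return ~(self.mask1 | self.mask2)

    def to_frame(self) -> pd.DataFrame:
        df = self.sites.copy()
        df["p1"], df["n1"], df["p2"], df["n2"] = self.p1, self.n1, self.p2, self.n2
        df["mask1"], df["mask2"] = self.mask1, self.mask2
        return df


def site_filter_reason(site_quality, copy_number, depth) -> str | None:
    """Return the rejection reason for a site, or None if it passes.

    A site is kept iff site_quality >= 15, copy_number <= 1.5 and
    6 <= depth <= 300 (boundary depths are kept: only strict violations
    of "less than 6 or larger than 300" are removed).
    """
    if site_quality is None or copy_number is None or depth is None:
        return "incomplete"
    if site_quality < SITE_QUALITY_MIN:
        return "quality"
    if copy_number > COPY_NUMBER_MAX:
        return "copy_number"
    if depth < DEPTH_MIN or depth > DEPTH_MAX:
        return "depth"
    return None


def filter_sites(records) -> tuple[list, list]:
    """Split records into kept and rejected; rejections carry a reason.

    Returns ``(kept_records, rejection_log)`` where the log is a list of
    ``(record, reason)`` with reason in {"quality", "copy_number",
    "depth", "incomplete"}.
    """
    kept, log = [], []
    for rec in records:
        try:
            reason = site_filter_reason(rec.site_quality, rec.copy_number, rec.depth)
        except AttributeError:
            reason = "incomplete"
        if reason is None:
            kept.append(rec)
        else:
            log.append((rec, reason))
    return kept, log


def _genotype_pair(record: SiteCallRecord) -> tuple[str, str] | None:
    """Apply the quality decision rules; return the unordered base pair or None."""
    if record.q_best >= GQ_MIN and record.q_second < GQ_MIN:
        return (record.best_base, record.best_base)
    if record.q_best >= GQ_MIN and record.q_second >= GQ_MIN:
        return tuple(sorted((record.best_base, record.second_base)))
    if record.q_consensus >= GQ_MIN:
        pair = IUPAC_TO_PAIR.get(record.consensus_genotype)
        return pair  # None for codes we cannot decode
    return None


def call_genotype(record: SiteCallRecord, ref: str, alt: str) -> int:
    """Determine the reference-allele dosage for one record.

    Returns 0/1/2, or :data:`MISSING` when no genotype passes the
    quality rules or when the called bases are inconsistent with the
    site's ref/alt pair.
    """
    pair = _genotype_pair(record)
    if pair is None:
        return MISSING
    allowed = {ref, alt}
    if not set(pair) <= allowed:
        if record.q_best < GQ_MIN and record.q_second < GQ_MIN:
            warnings.warn(
                f"consensus genotype {record.consensus_genotype} at "
                f"{record.chrom}:{record.pos} inconsistent with {ref}/{alt}",
                stacklevel=2,
            )
        return MISSING
    return int(pair[0] == ref) + int(pair[1] == ref)


def call_genotypes_vectorized(
    q_best: np.ndarray,
    q_second: np.ndarray,
    q_consensus: np.ndarray,
    best_is_ref: np.ndarray,
    second_is_ref: np.ndarray,
    best_valid: np.ndarray,
    second_valid: np.ndarray,
    cons_dosage: np.ndarray,
) -> np.ndarray:
    """Array version of :func:`call_genotype` for bulk calling.

    Base identities are pre-resolved against ref/alt: ``best_is_ref`` /
    ``second_is_ref`` flag whether the best/second base equals the
    reference allele, ``*_valid`` whether it is one of ref/alt, and
    ``cons_dosage`` holds the ref-dosage encoded by the consensus IUPAC
    genotype (or MISSING when not decodable against ref/alt).
    """
    hom = (q_best >= GQ_MIN) & (q_second < GQ_MIN)
    het = (q_best >= GQ_MIN) & (q_second >= GQ_MIN)
    cons = (q_best < GQ_MIN) & (q_second < GQ_MIN) & (q_consensus >= GQ_MIN)

    out = np.full(q_best.shape, MISSING, dtype=np.int8)
    out[hom & best_valid] = (2 * best_is_ref)[hom & best_valid]
    ok_het = het & best_valid & second_valid
    out[ok_het] = (best_is_ref.astype(np.int8) + second_is_ref)[ok_het]
    out[cons] = cons_dosage[cons]
    return out


def population_allele_frequencies(
    matrix: GenotypeMatrix, min_called: int = 10
) -> PopulationFrequencies:
    """Estimate per-site reference-allele frequencies per population.

    ``p = sum(dosage) / (2 n)`` over non-missing calls (heterozygotes
    contribute one allele copy).  A site is masked for a population
    unless strictly more than ``min_called`` individuals carry a
    genotype there — the stricter of the two phrasings the headline SNP
    set can be defined with; pass ``min_called=9`` for "at least 10".
    """
    out: dict[str, np.ndarray] = {}
    for tag, pop in (("1", "pop1"), ("2", "pop2")):
        idx = matrix.sample_indices(pop)
        sub = matrix.dosage[:, idx] if len(idx) else np.empty((matrix.n_sites, 0), np.int8)
        called = sub != MISSING
        n = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, sub, 0).sum(axis=1) / (2.0 * n)
        mask = n <= min_called
        p = np.where(mask, np.nan, p)
        out["p" + tag], out["n" + tag], out["mask" + tag] = p, n, mask
    return PopulationFrequencies(sites=matrix.sites.copy(), **out)


def select_structure_snps(matrix: GenotypeMatrix, min_total_called: int = 100) -> GenotypeMatrix:
    """Subset to sites genotyped in strictly more than ``min_total_called`` samples.

    Site order is preserved.  This is the SNP subset used for population
    structure inference (PCA / admixture), where per-site call counts
    must be high enough for stable covariance estimates.
    """
    counts = (matrix.dosage != MISSING).sum(axis=1)
    return matrix.take_sites(np.flatnonzero(counts > min_total_called))


def drop_singletons(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Remove sites where the minor allele occurs exactly once overall."""
    d = matrix.dosage
    called = d != MISSING
    ref = np.where(called, d, 0).sum(axis=1)
    total = 2 * called.sum(axis=1)
    alt = total - ref
    keep = (np.minimum(ref, alt) != 1)
    return matrix.take_sites(np.flatnonzero(keep))
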