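"""Single-population SFS composite-likelihood sweep scan and gene assignment.

A selective sweep locally distorts the site frequency spectrum (SFS):
hitchhiking drives linked variants toward fixation or loss, leaving an
excess of extreme-frequency alleles near the swept site while the
genome-wide background spectrum is unaffected.  The scan compares, at
every grid point (1-kb spacing by default), a sweep-distorted spectrum
against the genome-wide empirical background:

* the background SFS is the binned empirical spectrum of minor-allele
  frequencies (folded by default — ancestral states are unknown);
* under a sweep of map-scale ``alpha`` (Morgans), a lineage at map
  distance ``d`` from the grid point escapes the sweep with probability
  ``e = 1 - exp(-d/alpha)``; the site's frequency is then drawn from the
  mixture ``e * background + (1 - e) * extreme``, where the extreme
  component concentrates geometrically on the most extreme (lowest
  minor-allele-frequency) bins;
* the likelihood ratio ``LR = 2 max_alpha [sum log P_sweep - sum log
  P_background]`` is maximised over a grid of ``alpha`` values and
  floored at 0 (``alpha -> 0`` makes every lineage escape, collapsing
  the sweep model onto the background).

Top-quantile grid points (default top 5%) merged within two grid steps
form sweep regions; genes within 10 kb of a significant grid point are
the potential selection targets.  Running the scan separately in each
population assigns differentiated genes to the population(s) they were
selected in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ecodiff.diff_scan import DEFAULT_CM_PER_MB, top_quantile_threshold
from ecodiff.intervals import Region, merge_regions

DEFAULT_GRID = 1_000
DEFAULT_QUANTILE = 0.05
DEFAULT_GENE_FLANK = 10_000


@dataclass
class SFS:
    """A binned site frequency spectrum (proportions sum to 1)."""

    proportions: np.ndarray
    bin_edges: np.ndarray
    folded: bool = True

    @property
    def n_bins(self) -> int:
        return len(self.proportions)

    @property
    def occupied_bins(self) -> int:
        return int(np.sum(self.proportions > 0))

    def bin_of(self, freq: np.ndarray) -> np.ndarray:
        """Bin index for an allele frequency (folded to MAF if needed)."""
        f = np.asarray(freq, dtype=float)
        if self.folded:
            # round so p and 1-p fold to bit-identical minor frequencies
            f = np.round(np.minimum(f, 1 - f), 12)
        idx = np.searchsorted(self.bin_edges, f, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


def background_sfs(
    p: np.ndarray, n_bins: int = 20, folded: bool = True, min_snps: int = 100
) -> SFS:
    """Genome-wide empirical frequency spectrum of one population.

    ``p`` are per-site allele frequencies (reference-allele frequencies
    are fine: the folded spectrum uses minor-allele frequencies).
    Monomorphic sites are excluded.  Bins are equal width over (0, 0.5]
    when folded, (0, 1) otherwise, with a small uniform pseudo-count so
    empty bins keep non-zero probability.
    """
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    p = p[(p > 0) & (p < 1)]
    if len(p) < min_snps:
        raise ValueError(f"need >= {min_snps} polymorphic SNPs, got {len(p)}")
    top = 0.5 if folded else 1.0
    f = np.round(np.minimum(p, 1 - p), 12) if folded else p
    edges = np.linspace(0, top, n_bins + 1)
    counts, _ = np.histogram(f, bins=edges)
    props = (counts + 0.5) / (counts.sum() + 0.5 * n_bins)
    return SFS(proportions=props, bin_edges=edges, folded=folded)


def _extreme_spectrum(n_bins: int, decay: float = 0.25) -> np.ndarray:
    w = decay ** np.arange(n_bins)
    return w / w.sum()


def clr_scan(
    freqs: pd.DataFrame,
    background: SFS,
    grid: int = DEFAULT_GRID,
    cm_per_mb: float = DEFAULT_CM_PER_MB,
    window_bp: int = 50_000,
    alpha_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Composite likelihood ratio for a sweep at every grid point.

    ``freqs`` needs columns ``chrom, pos, p`` (allele frequency in the
    scanned population, masked sites already removed).  Sites within
    ``window_bp`` of the grid point enter the composite likelihood.
    Returns ``chrom, pos, score, n_snps`` with ``score >= 0``.
    """
    if background.occupied_bins < 2:
        raise ValueError("degenerate background SFS (single occupied bin)")
    if alpha_grid is None:
        # sweep map-scale in Morgans: ~0.25 kb to ~0.5 Mb at 4 cM/Mb
        alpha_grid = np.geomspace(1e-6, 2e-3, 10)
    ext = _extreme_spectrum(background.n_bins)

    out = []
    for chrom, grp in freqs.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=float)
        p = grp["p"].to_numpy(dtype=float)
        poly = (p > 0) & (p < 1)
        pos, p = pos[poly], p[poly]
        if len(pos) == 0:
            continue
        bins = background.bin_of(p)
        log_bg = np.log(background.proportions[bins])
        p_bg = background.proportions[bins]
        p_ext = ext[bins]
        grid_pos = np.arange(grid, int(pos.max()) + grid, grid, dtype=float)
        lo = np.searchsorted(pos, grid_pos - window_bp)
        hi = np.searchsorted(pos, grid_pos + window_bp, side="right")
        for g in range(len(grid_pos)):
            sl = slice(lo[g], hi[g])
            if hi[g] - lo[g] < 2:
                continue
            # distance floored at half a base pair so a site exactly on the
            # grid point still escapes in the alpha -> 0 (null) limit
            d = np.maximum(np.abs(pos[sl] - grid_pos[g]), 0.5) * cm_per_mb / 1e8  # Morgans
            e = 1.0 - np.exp(-d[None, :] / alpha_grid[:, None])  # (A, snps)
            p_sweep = e * p_bg[None, sl] + (1 - e) * p_ext[None, sl]
            ll = np.sum(np.log(p_sweep) - log_bg[None, sl], axis=1)
            score = 2.0 * max(0.0, float(ll.max()))
            out.append((chrom, int(grid_pos[g]), score, int(hi[g] - lo[g])))
    return pd.DataFrame(out, columns=["chrom", "pos", "score", "n_snps"])


def call_sweep_regions(
    scores: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    quantile: float = DEFAULT_QUANTILE,
    gene_flank: int = DEFAULT_GENE_FLANK,
    grid: int = DEFAULT_GRID,
    source: str = "clr",
) -> tuple[list[Region], set[str]]:
    """Call top-quantile grid points into sweep regions and select genes.

    Consecutive significant grid points within two grid steps are joined
    into regions.  A gene (frame with ``chrom, start, end, gene_id``,
    0-based half-open) is selected iff its interval lies within
    ``gene_flank`` bp of any significant grid point (distance 0 when the
    point falls inside the gene).  Returns ``(regions, selected gene
    ids)``; with no significant points both are empty.
    """
    if len(scores) == 0:
        return [], set()
    thr = top_quantile_threshold(scores["score"].to_numpy(), quantile)
    sig = scores[scores["score"].to_numpy() >= thr]
    regions = merge_regions(
        [
            Region(
                chrom=r.chrom,
                start=max(0, int(r.pos) - 1 - grid // 2),
                end=int(r.pos) - 1 + grid // 2,
                source={source},
            )
            for r in sig.itertuples()
        ],
        max_gap=2 * grid,
    )
    selected: set[str] = set()
    if genes is not None and len(sig):
        for chrom, grp in sig.groupby("chrom", sort=False):
            pts = np.sort(grp["pos"].to_numpy(dtype=float)) - 1  # 0-based
            sub = genes[genes["chrom"] == chrom]
            if not len(sub) or not len(pts):
                continue
            start = sub["start"].to_numpy(dtype=float)
            end = sub["end"].to_numpy(dtype=float)
            dist = np.full(len(sub), np.inf)
            inside = np.zeros(len(sub), dtype=bool)
            for k, (s, e) in enumerate(zip(start, end)):
                i = np.searchsorted(pts, s)
                j = np.searchsorted(pts, e, side="left")
                if i < j:  # a point inside [s, e)
                    inside[k] = True
                    continue
                cand = []
                if i > 0:
                    cand.append(s - pts[i - 1])
                if i < len(pts):
                    cand.append(pts[i] - (e - 1))
                dist[k] = min(cand)
            sel = inside | (dist <= gene_flank)
            selected.update(sub.loc[sel.astype(bool), "gene_id"].tolist())
    return regions, selected


@dataclass(frozen=True)
class SweepAssignment:
    gene_id: str
    label: str  # upland_only | irrigated_only | both | unassigned


def assign_edg_population(
    edgs,
    upland_selected: set[str],
    irrigated_selected: set[str],
) -> list[SweepAssignment]:
    """Assign each differentiated gene to the population(s) it was selected in.

    The labels partition the input: ``upland_only``, ``irrigated_only``,
    ``both``, or ``unassigned`` when the gene is in neither selected
    set.
    """
    out = []
    for gene in edgs:
        in_up = gene in upland_selected
        in_ir = gene in irrigated_selected
        if in_up and in_ir:
            label = "both"
        elif in_up:
            label = "upland_only"
        elif in_ir:
            label = "irrigated_only"
        else:
            label = "unassigned"
        out.append(SweepAssignment(gene_id=gene, label=label))
    return out
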