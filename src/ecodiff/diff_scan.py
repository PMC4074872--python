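"""Windowed Nei FST and cross-population composite-likelihood scans.

The two-population differentiation scan combines:

* per-site Nei FST (``G_ST``): with ``pbar = (p1 + p2)/2``,
  ``H_T = 2 pbar (1 - pbar)``, ``H_S = p1(1-p1) + p2(1-p2)`` and
  ``FST = (H_T - H_S)/H_T`` (0 for monomorphic sites).  No sample-size
  correction by default; a corrected within-population heterozygosity
  (``2pqn/(n-1)``) is available behind a flag.
* a sliding-window average of per-site values (20-kb windows, 2-kb
  step by default), unweighted over the SNPs each window contains;
* a cross-population composite likelihood ratio score on a grid
  (0.1 cM window, 2-kb grid, at most 150 SNPs per window by default).
  Under neutral drift the objective population's frequency at a site is
  modelled as Normal around the reference population's frequency with
  variance ``omega * p(1-p)`` (omega estimated genome-wide by the method
  of moments) plus binomial sampling noise.  Under a sweep centred at
  the grid point, a lineage at map distance ``r`` escapes the sweep with
  probability ``c = 1 - exp(-r/s)`` (``s`` = sweep scale in Morgans):
  the expected frequency is pulled from the neutral expectation toward
  fixation of one allele, ``mu = c p + (1-c) B`` with ``B in {0, 1}``
  maximised per site, and the drift variance shrinks by ``c**2``.  The
  score is twice the composite log-likelihood ratio maximised over a
  grid of ``s`` values; ``s -> 0`` collapses the sweep model onto the
  null, so scores are non-negative.

Top-quantile windows/grid points (default top 5 per mille) are converted
to intervals, merged when overlapping, book-ended, or within one step,
and the FST/XP-CLR intersection defines the ecotype differentiated
regions (EDRs).  SNPs inside an EDR whose between-population frequency
difference strictly exceeds 0.6 are the ecotype differentiated SNPs
(EDSs).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ecodiff.genotyping import PopulationFrequencies
from ecodiff.intervals import Region, intersect_regions, merge_regions

DEFAULT_WINDOW = 20_000
DEFAULT_STEP = 2_000
DEFAULT_QUANTILE = 0.005
DEFAULT_CM_PER_MB = 4.0  # genome-average recombination rate used when no map is given
EDS_MIN_DIFF = 0.6


def fst_per_site(p1, n1, p2, n2, corrected: bool = False):
    """Nei FST between two populations at one or many sites.

    ``p1``/``p2`` are allele frequencies; ``n1``/``n2`` the genotyped
    sample sizes (used only when ``corrected=True``).  Monomorphic sites
    (H_T = 0) return 0.  Accepts scalars or arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    pbar = 0.5 * (p1 + p2)
    ht = 2 * pbar * (1 - pbar)
    h1 = 2 * p1 * (1 - p1)
    h2 = 2 * p2 * (1 - p2)
    if corrected:
        n1 = np.asarray(n1, dtype=float)
        n2 = np.asarray(n2, dtype=float)
        h1 = h1 * 2 * n1 / (2 * n1 - 1)
        h2 = h2 * 2 * n2 / (2 * n2 - 1)
    hs = 0.5 * (h1 + h2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), 0.0)
    if corrected:
        fst = np.clip(fst, None, 1.0)
    return fst if fst.ndim else float(fst)


def fst_sites(freqs: PopulationFrequencies, corrected: bool = False) -> pd.DataFrame:
    """Per-site FST over sites unmasked in both populations."""
    keep = freqs.unmasked
    df = freqs.sites.loc[keep, ["chrom", "pos"]].reset_index(drop=True)
    df["value"] = fst_per_site(
        freqs.p1[keep], freqs.n1[keep], freqs.p2[keep], freqs.n2[keep], corrected=corrected
    )
    return df


def window_scan(
    site_values: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Average per-site values in sliding windows tiled from position 1.

    ``site_values`` must have columns ``chrom, pos, value`` sorted by
    (chrom, pos); windows with zero SNPs are omitted.  Returns a frame
    with ``chrom, start, end`` (1-based inclusive), ``value`` (the
    unweighted mean) and ``n_snps``.
    """
    pos_all = site_values["pos"].to_numpy()
    chrom_all = site_values["chrom"].to_numpy()
    same = chrom_all[1:] == chrom_all[:-1]
    if np.any(same & (pos_all[1:] < pos_all[:-1])):
        raise ValueError("site values must be sorted by (chrom, pos)")

    frames = []
    for chrom, grp in site_values.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        val = grp["value"].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(val)])
        last_start = ((max(pos) - 1) // step) * step + 1
        starts = np.arange(1, last_start + 1, step)
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, starts + window - 1, side="right")
        n = hi - lo
        keep = n > 0
        mean = (csum[hi[keep]] - csum[lo[keep]]) / n[keep]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts[keep],
                    "end": starts[keep] + window - 1,
                    "value": mean,
                    "n_snps": n[keep],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "value", "n_snps"])
    return pd.concat(frames, ignore_index=True)


def estimate_drift_variance(freqs: PopulationFrequencies, objective: str = "pop1") -> float:
    """Method-of-moments genome-wide drift dispersion omega.

    ``omega = mean[(p_obj - p_ref)^2 / (p_ref (1 - p_ref))]`` over
    unmasked sites with the reference frequency clipped away from 0/1.
    """
    keep = freqs.unmasked
    p_obj, p_ref = (freqs.p1, freqs.p2) if objective == "pop1" else (freqs.p2, freqs.p1)
    p_ref = np.clip(p_ref[keep], 0.02, 0.98)
    p_obj = p_obj[keep]
    v = p_ref * (1 - p_ref)
    return float(np.mean((p_obj - p_ref) ** 2 / v))


def xpclr_scan(
    freqs: PopulationFrequencies,
    objective: str = "pop1",
    window_cm: float = 0.1,
    grid: int = 2_000,
    max_snps: int = 150,
    cm_per_mb: float = DEFAULT_CM_PER_MB,
    genetic_map: pd.DataFrame | None = None,
    omega: float | None = None,
    s_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cross-population composite likelihood ratio scores on a grid.

    Returns a frame with ``chrom, pos`` (grid point, 1-based),
    ``score`` (non-negative) and ``n_snps``.  Grid points with fewer
    than 2 usable SNPs in the window are skipped.  ``genetic_map``, if
    given, must have columns ``pos, cm`` per chromosome (physical bp to
    cumulative centimorgans); otherwise a constant ``cm_per_mb`` rate is
    used.
    """
    if omega is None:
        omega = estimate_drift_variance(freqs, objective)
    omega = max(omega, 1e-4)
    if s_grid is None:
        # sweep map-scale in Morgans, from ~0.25 kb to ~125 kb at 4 cM/Mb
        s_grid = np.geomspace(1e-5, 5e-3, 12)

    keep = freqs.unmasked
    sites = freqs.sites.loc[keep].reset_index(drop=True)
    if objective == "pop1":
        p_obj_all, p_ref_all = freqs.p1[keep], freqs.p2[keep]
        n_obj_all = freqs.n1[keep]
    else:
        p_obj_all, p_ref_all = freqs.p2[keep], freqs.p1[keep]
        n_obj_all = freqs.n2[keep]

    out = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        loc = grp.index.to_numpy()
        pos = grp["pos"].to_numpy().astype(float)
        if genetic_map is not None:
            gm = genetic_map[genetic_map["chrom"] == chrom]
            cm = np.interp(pos, gm["pos"].to_numpy(), gm["cm"].to_numpy())
        else:
            cm = pos * cm_per_mb / 1e6
        p_obj = p_obj_all[loc]
        p_ref = np.clip(p_ref_all[loc], 0.01, 0.99)
        n_obj = np.maximum(n_obj_all[loc], 1)
        v_ref = p_ref * (1 - p_ref)
        v_samp = v_ref / (2 * n_obj) + 1e-4

        grid_pos = np.arange(grid, int(pos.max()) + grid, grid, dtype=float)
        grid_cm = grid_pos * cm_per_mb / 1e6
        if genetic_map is not None:
            grid_cm = np.interp(grid_pos, gm["pos"].to_numpy(), gm["cm"].to_numpy())

        half = window_cm / 2
        lo = np.searchsorted(cm, grid_cm - half)
        hi = np.searchsorted(cm, grid_cm + half, side="right")
        for g in range(len(grid_pos)):
            i0, i1 = lo[g], hi[g]
            if i1 - i0 < 2:
                continue
            sl = slice(i0, i1)
            r = np.abs(cm[sl] - grid_cm[g]) / 100.0  # Morgans
            if i1 - i0 > max_snps:
                order = np.argsort(r)[:max_snps]
                sel = np.sort(order)
                r = r[sel]
                po, pr = p_obj[sl][sel], p_ref[sl][sel]
                vr, vs = v_ref[sl][sel], v_samp[sl][sel]
            else:
                po, pr, vr, vs = p_obj[sl], p_ref[sl], v_ref[sl], v_samp[sl]

            var0 = omega * vr + vs
            ll0 = -0.5 * (np.log(var0) + (po - pr) ** 2 / var0)

            c = 1.0 - np.exp(-r[None, :] / s_grid[:, None])  # (S, snps)
            var1 = (c**2) * omega * vr[None, :] + vs[None, :]
            mu_up = c * pr[None, :] + (1 - c)  # sweep fixes ref allele (B=1)
            mu_dn = c * pr[None, :]  # sweep removes it (B=0)
            dev = np.minimum((po - mu_up) ** 2, (po - mu_dn) ** 2)
            ll1 = -0.5 * (np.log(var1) + dev / var1)
            score = 2.0 * max(0.0, float(np.max(np.sum(ll1 - ll0[None, :], axis=1))))
            out.append((chrom, int(grid_pos[g]), score, int(len(po))))

    return pd.DataFrame(out, columns=["chrom", "pos", "score", "n_snps"])


def top_quantile_threshold(values: np.ndarray, quantile: float = DEFAULT_QUANTILE) -> float:
    """Empirical threshold retaining the top ``quantile`` fraction of values.

    With n values, the largest ``floor(n * quantile)`` of them (plus
    ties at the threshold) are at or above the returned value.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 1 / quantile:
        warnings.warn(
            f"only {len(values)} values for a top-{quantile} threshold; "
            "threshold taken from the full sort",
            stacklevel=2,
        )
    k = max(1, int(np.floor(len(values) * quantile)))
    return float(np.sort(values)[-k])


def call_top_regions(
    stats: pd.DataFrame,
    quantile: float = DEFAULT_QUANTILE,
    source: str = "fst",
    merge_gap: int | None = None,
    grid: int | None = None,
) -> list[Region]:
    """Convert top-quantile windows or grid points into merged regions.

    ``stats`` is either a window frame (columns ``start``/``end``,
    1-based inclusive) or a grid frame (column ``pos``; each significant
    point becomes its grid cell, requiring ``grid``).  Values tied with
    the threshold are included.  Intervals overlapping, book-ended, or
    separated by at most ``merge_gap`` bp are merged (default: one
    2-kb step for windows, two grid steps for grid scans).
    """
    if "start" in stats.columns:
        values = stats["value"].to_numpy()
        thr = top_quantile_threshold(values, quantile)
        sig = stats[values >= thr]
        regions = [
            Region(chrom=r.chrom, start=int(r.start) - 1, end=int(r.end), source={source})
            for r in sig.itertuples()
        ]
        gap = DEFAULT_STEP if merge_gap is None else merge_gap
    else:
        if grid is None:
            pos = np.sort(stats["pos"].unique())
            grid = int(np.min(np.diff(pos))) if len(pos) > 1 else 1
        values = stats["score"].to_numpy()
        thr = top_quantile_threshold(values, quantile)
        sig = stats[values >= thr]
        regions = [
            Region(
                chrom=r.chrom,
                start=max(0, int(r.pos) - 1 - grid // 2),
                end=int(r.pos) - 1 + grid // 2,
                source={source},
            )
            for r in sig.itertuples()
        ]
        gap = 2 * grid if merge_gap is None else merge_gap
    return merge_regions(regions, max_gap=gap)


def intersect_to_edrs(
    fst_regions: list[Region], xpclr_regions: list[Region]
) -> list[Region]:
    """Ecotype differentiated regions: the FST x XP-CLR interval intersection."""
    return intersect_regions(fst_regions, xpclr_regions)


def attach_member_snps(regions: list[Region], freqs: PopulationFrequencies) -> list[Region]:
    """Attach the (chrom, pos) of unmasked SNPs falling inside each region."""
    keep = freqs.unmasked
    chrom = freqs.sites["chrom"].to_numpy()[keep]
    pos0 = freqs.sites["pos"].to_numpy()[keep] - 1
    for region in regions:
        sel = (chrom == region.chrom) & (pos0 >= region.start) & (pos0 < region.end)
        region.member_snps = [
            (region.chrom, int(p) + 1) for p in pos0[sel]
        ]
    return regions


def identify_eds(
    freqs: PopulationFrequencies,
    edrs: list[Region],
    min_diff: float = EDS_MIN_DIFF,
) -> pd.DataFrame:
    """Ecotype differentiated SNPs inside EDRs.

    A SNP qualifies iff it lies in some EDR, is unmasked in both
    populations, and its absolute frequency difference strictly exceeds
    ``min_diff`` (a difference of exactly 0.6 does not qualify).
    Returns ``chrom, pos, p1, p2, diff``.
    """
    keep = freqs.unmasked
    chrom = freqs.sites["chrom"].to_numpy()
    pos = freqs.sites["pos"].to_numpy()
    diff = np.abs(freqs.p1 - freqs.p2)
    in_edr = np.zeros(len(chrom), dtype=bool)
    for region in edrs:
        in_edr |= (chrom == region.chrom) & (pos - 1 >= region.start) & (pos - 1 < region.end)
    sel = in_edr & keep & (diff > min_diff)
    return pd.DataFrame(
        {
            "chrom": chrom[sel],
            "pos": pos[sel],
            "p1": freqs.p1[sel],
            "p2": freqs.p2[sel],
            "diff": diff[sel],
        }
    ).reset_index(drop=True)
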