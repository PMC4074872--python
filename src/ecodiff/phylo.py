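"""Pairwise F84 distances, neighbor-joining trees and bootstrap consensus.

Accessions are compared over their shared (pairwise-deletion) SNP
genotypes, treated as nucleotide observations: a homozygote contributes
its base, a heterozygote contributes both alleles at half weight
(ambiguity-code treatment), and missing genotypes are excluded for that
pair.  The F84 substitution model (unequal base frequencies, a
transition/transversion bias, fixed ts/tv ratio 2.0, no rate variation
across sites and uniform site weights) is fitted per pair by maximising
the likelihood of the 4x4 substitution count table over the branch
length; base frequencies are empirical from the pair's shared sites.

Trees are built with the Saitou-Nei neighbor-joining algorithm
(deterministic: ties on the Q criterion break toward the lowest index
pair; a negative branch length is clamped to zero with the deficit
moved to the sibling branch) and are unrooted.  Bootstrap resamples
sites with replacement; the consensus keeps bipartitions occurring in
strictly more than half the replicates (strict majority rule), with
integer support percentages on internal edges.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from ecodiff.genotyping import MISSING, GenotypeMatrix

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
PURINES = (0, 2)  # A, G
PYRIMIDINES = (1, 3)  # C, T
TS_TV_RATIO = 2.0


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with informative-site counts."""

    labels: list[str]
    values: np.ndarray
    n_shared: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)


def genotypes_to_base_weights(matrix: GenotypeMatrix) -> np.ndarray:
    """Per (site, sample) distribution over ACGT; NaN rows mark missing.

    Dosage 2 -> the ref base, 0 -> the alt base, 1 -> half weight on
    each allele, missing -> NaN.
    Shape (n_sites, n_samples, 4).
    """
    ref = np.array([BASE_INDEX[b] for b in matrix.sites["ref"]])
    alt = np.array([BASE_INDEX[b] for b in matrix.sites["alt"]])
    n_sites, n_samples = matrix.dosage.shape
    w = np.zeros((n_sites, n_samples, 4))
    d = matrix.dosage
    rows = np.arange(n_sites)[:, None]
    safe = np.where(d == MISSING, 0, d).astype(float)
    w[rows, np.arange(n_samples)[None, :], ref[:, None]] = safe / 2.0
    w[rows, np.arange(n_samples)[None, :], alt[:, None]] += 1 - safe / 2.0
    w[d == MISSING] = np.nan
    return w


def _f84_rate_matrix(pi: np.ndarray, ratio: float = TS_TV_RATIO) -> np.ndarray:
    """F84 rate matrix with unit expected substitution rate.

    The within-group (transition) excess ``b`` is solved from the
    requested expected transition/transversion ratio given the base
    frequencies; when the frequencies cannot support the ratio the
    excess is clamped at zero (pure F81).
    """
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    denom = piA * piG / piR + piC * piT / piY
    b = (ratio * piR * piY - piA * piG - piC * piT) / denom if denom > 0 else 0.0
    b = max(b, 0.0)
    q = np.tile(pi, (4, 1)).astype(float)
    for grp in (PURINES, PYRIMIDINES):
        pg = pi[list(grp)].sum()
        i, j = grp
        if pg > 0:
            q[i, j] += b * pi[j] / pg
            q[j, i] += b * pi[i] / pg
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -np.sum(pi * np.diag(q))
    return q / rate


def _f84_ml_from_counts(counts: np.ndarray, ratio: float = TS_TV_RATIO) -> float:
    """ML branch length for a 4x4 substitution count table under F84."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("zero shared sites: distance undefined")
    off = total - np.trace(counts)
    if off == 0:
        return 0.0
    pi = (counts.sum(axis=0) + counts.sum(axis=1)) / (2 * total)
    pi = np.clip(pi, 1e-6, None)
    pi = pi / pi.sum()
    q = _f84_rate_matrix(pi, ratio)
    # reversible: symmetrise and eigendecompose once, then P(t) is cheap
    d_half = np.sqrt(pi)
    sym = (q * d_half[:, None]) / d_half[None, :]
    lam, u = np.linalg.eigh((sym + sym.T) / 2)
    left = u / d_half[:, None]
    right = u * d_half[:, None]

    def neg_ll(t: float) -> float:
        p = left @ (np.exp(lam * t)[:, None] * right.T)
        p = np.clip(p, 1e-300, None)
        return -float(np.sum(counts * np.log(pi[:, None] * p)))

    res = minimize_scalar(neg_ll, bounds=(1e-9, 20.0), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def f84_distance(w_i: np.ndarray, w_j: np.ndarray, ratio: float = TS_TV_RATIO) -> tuple[float, int]:
    """F84 ML distance between two base-weight sequences.

    ``w_i``/``w_j`` are (n_sites, 4) weight arrays (NaN = missing);
    sites missing in either sequence are dropped (pairwise deletion).
    Returns ``(distance, n_shared_sites)``; raises when no site is
    shared.
    """
    ok = ~(np.isnan(w_i[:, 0]) | np.isnan(w_j[:, 0]))
    n_shared = int(ok.sum())
    if n_shared == 0:
        raise ValueError("zero shared sites: distance undefined")
    counts = w_i[ok].T @ w_j[ok]
    counts = (counts + counts.T) / 2  # unordered pair
    return _f84_ml_from_counts(counts, ratio), n_shared


def distance_matrix(
    matrix: GenotypeMatrix, site_idx: np.ndarray | None = None, ratio: float = TS_TV_RATIO
) -> DistanceMatrix:
    """All-pairs F84 distances (pairwise deletion, uniform site weights)."""
    w = genotypes_to_base_weights(matrix)
    if site_idx is not None:
        w = w[site_idx]
    n = matrix.n_samples
    dist = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        shared[i, i] = int(np.sum(~np.isnan(w[:, i, 0])))
        for j in range(i + 1, n):
            d, k = f84_distance(w[:, i, :], w[:, j, :], ratio)
            dist[i, j] = dist[j, i] = d
            shared[i, j] = shared[j, i] = k
    return DistanceMatrix(labels=list(matrix.samples), values=dist, n_shared=shared)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree.

    Deterministic: on Q-criterion ties the lowest-index pair (row-major)
    is joined.  A negative branch length is clamped to zero and its
    deficit moved to the sibling branch (itself floored at zero).
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dm.values.astype(float).copy()
    # newick fragments per active node
    nodes = list(dm.labels)
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        qmat = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(qmat, np.inf)
        flat = int(np.argmin(qmat))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        # distances from the new node to the remaining taxa
        k_idx = [a for a in active if a not in (i, j)]
        dk = 0.5 * (d[i, k_idx] + d[j, k_idx] - dij)
        d[i, k_idx] = dk
        d[k_idx, i] = dk
        nodes[i] = new
        active.remove(j)

    if len(active) == 2:
        i, j = active
        newick = f"({nodes[i]},{nodes[j]}:{max(d[i, j], 0.0):.10g});"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap and consensus


def bootstrap_trees(
    matrix: GenotypeMatrix,
    replicates: int = 100,
    seed: int = 0,
    ratio: float = TS_TV_RATIO,
) -> list[dendropy.Tree]:
    """NJ trees from site-resampled replicates (bootstrap over SNPs)."""
    if matrix.n_sites < 10:
        raise ValueError("need >= 10 sites to bootstrap")
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(replicates):
        idx = rng.integers(0, matrix.n_sites, matrix.n_sites)
        dm = distance_matrix(matrix, site_idx=idx, ratio=ratio)
        trees.append(nj_tree(dm))
    return trees


def bootstrap_consensus(
    matrix: GenotypeMatrix,
    replicates: int = 100,
    seed: int = 0,
    min_freq: float = 0.5,
    ratio: float = TS_TV_RATIO,
) -> dendropy.Tree:
    """Strict-majority-rule consensus of bootstrap NJ trees.

    Bipartitions appearing in strictly more than ``min_freq`` of the
    replicates are kept; internal edges carry integer support
    percentages.  The tree is unrooted.
    """
    trees = bootstrap_trees(matrix, replicates=replicates, seed=seed, ratio=ratio)
    ns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=ns)
    for t in trees:
        tl.append(
            dendropy.Tree.get(
                data=t.as_string(schema="newick"),
                schema="newick",
                taxon_namespace=ns,
                preserve_underscores=True,
            )
        )
    cons = tl.consensus(min_freq=min_freq + 1e-9, is_bipartitions_updated=False)
    cons.is_rooted = False
    for node in cons.internal_nodes():
        freq = getattr(node, "support", None)
        if freq is None and node.label is not None:
            try:
                freq = float(node.label)
            except ValueError:
                freq = None
        if freq is not None:
            node.label = str(int(round(freq * 100)))
    return cons


def bipartition_support(tree: dendropy.Tree, group: set[str]) -> int | None:
    """Support (%) of the bipartition splitting ``group`` from the rest.

    Returns None when the consensus does not contain that bipartition.
    """
    all_taxa = {t.label for t in tree.taxon_namespace}
    other = all_taxa - group
    for node in tree.internal_nodes():
        leaves = {l.taxon.label for l in node.leaf_iter()}
        if leaves == group or leaves == other:
            if node.label is not None:
                return int(float(node.label))
            return None
    return None


def tree_to_newick(tree: dendropy.Tree) -> str:
    buf = _io.StringIO()
    tree.write(file=buf, schema="newick", suppress_rooting=True)
    return buf.getvalue().strip()
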