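"""Population structure: PCA, neighbour-joining trees, Hudson and
Patterson F_ST estimators, and the two-individual F_ST resampling null.

F_ST aggregation is ratio-of-averages (sum of per-site numerators over sum
of per-site denominators), which avoids the bias of averaging per-site
ratios.  Estimates are reported signed; small negative values are expected
sampling noise under panmixia and are not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import MISSING, CohortFrame, DiplotypeSet


# ---------------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PcaResult:
    coordinates: np.ndarray  # n_samples x n_components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    n_sites_used: int


def pca(
    diplo: DiplotypeSet,
    n_components: int = 10,
    patterson_scaling: bool = True,
) -> PcaResult:
    """Principal components of the diplotype matrix.

    Sites are mean-centred; with ``patterson_scaling`` each site is divided
    by sqrt(p(1-p)) where p is the sample allele frequency.  Sites with any
    missing call or no variation are dropped.  Coordinates are deterministic
    up to sign.
    """
    if diplo.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    g = diplo.matrix.astype(float)
    complete = (diplo.matrix != MISSING).all(axis=1)
    g = g[complete]
    mean = g.mean(axis=1, keepdims=True)
    p = mean / 2.0
    variable = (p[:, 0] > 0) & (p[:, 0] < 1)
    g = g[variable]
    p = p[variable]
    x = g - 2.0 * p
    if patterson_scaling:
        x = x / np.sqrt(p * (1.0 - p))
    # samples are observations: SVD of the samples x sites matrix
    u, s, _ = np.linalg.svd(x.T, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    coords = u[:, :n_components] * s[:n_components]
    var = s**2 / (diplo.n_samples - 1)
    return PcaResult(
        coordinates=coords,
        explained_variance=var[:n_components],
        explained_variance_ratio=var[:n_components] / var.sum(),
        n_sites_used=x.shape[0],
    )


# ---------------------------------------------------------------------------
# distances and neighbour joining


def pairwise_distance_matrix(diplo: DiplotypeSet, metric: str = "cityblock") -> np.ndarray:
    """Manhattan distance between samples over pairwise-complete sites.

    d(i, j) = sum over sites non-missing in both of |g_i - g_j|.
    """
    if metric != "cityblock":
        raise ValueError("only the city-block (Manhattan) metric is supported")
    if diplo.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = diplo.matrix.astype(np.int16)
    ok = g != MISSING
    n = diplo.n_samples
    if ok.all():
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(g.T.astype(float), metric="cityblock"))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[:, i] & ok[:, j]
            if not both.any():
                raise ValueError(
                    f"samples {diplo.samples[i]} and {diplo.samples[j]} share "
                    "no non-missing sites"
                )
            d[i, j] = d[j, i] = np.abs(g[both, i] - g[both, j]).sum()
    return d


@dataclass
class TreeNode:
    """Node of an (unrooted) NJ tree; the root is a trifurcation."""

    label: str | None = None
    length: float = 0.0
    children: list = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick_part() + ";"

    def _newick_part(self) -> str:
        if self.is_leaf():
            return f"{self.label}:{self.length:.10g}"
        inner = ",".join(c._newick_part() for c in self.children)
        if self.length or self.label:
            return f"({inner}){self.label or ''}:{self.length:.10g}"
        return f"({inner})"


def neighbor_joining(dist: np.ndarray, labels: list[str]) -> TreeNode:
    """Saitou-Nei neighbour joining.

    Exact on additive distance matrices.  Negative branch lengths are
    clamped to zero with the excess moved to the sibling branch, keeping
    the path length between the joined pair.  Ties in the Q matrix break
    on the smallest (i, j) pair for reproducibility.
    """
    d = np.array(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if len(labels) != n:
        raise ValueError("one label per row required")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in labels]

    while len(nodes) > 3:
        m = d.shape[0]
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) among minima for deterministic output
        flat = np.flatnonzero(q == q.min())
        i, j = divmod(int(flat[0]), m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.empty((m - 1, m - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = new_d[keep]
        d_next[-1, -1] = 0.0
        d = d_next
        nodes = [nodes[k] for k in keep] + [parent]

    # connect the last three nodes at a central point (three-point formulas)
    a = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    b = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    c = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    lengths = [a, b, c]
    for k in range(3):
        nodes[k].length = max(lengths[k], 0.0)
    return TreeNode(children=nodes)


# ---------------------------------------------------------------------------
# F_ST


def _freqs(ac: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ac = np.asarray(ac, dtype=float)
    n = ac.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ac[:, 1] / n
    return p, n


def hudson_fst(ac_a: np.ndarray, ac_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Hudson's F_ST from per-site (ref, alt) allele counts.

    Per site: N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    D = p1(1-p2) + p2(1-p1).  Returns per-site (N, D) and the
    ratio-of-averages estimate; sites with D = 0 are excluded from sums.
    """
    p1, n1 = _freqs(ac_a)
    p2, n2 = _freqs(ac_b)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need at least 2 sampled alleles per population per site")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    fst = float(num[keep].sum() / den[keep].sum()) if keep.any() else float("nan")
    return num, den, fst


def patterson_fst(ac_a: np.ndarray, ac_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Patterson's F_ST from per-site (ref, alt) allele counts.

    With unbiased heterozygosity h = p(1-p) n/(n-1):
    N = (p1-p2)^2 - h1/n1 - h2/n2, D = N + h1 + h2; aggregate sum(N)/sum(D).
    """
    p1, n1 = _freqs(ac_a)
    p2, n2 = _freqs(ac_b)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need at least 2 sampled alleles per population per site")
    h1 = p1 * (1 - p1) * n1 / (n1 - 1)
    h2 = p2 * (1 - p2) * n2 / (n2 - 1)
    num = (p1 - p2) ** 2 - h1 / n1 - h2 / n2
    den = num + h1 + h2
    keep = den > 0
    fst = float(num[keep].sum() / den[keep].sum()) if keep.any() else float("nan")
    return num, den, fst


_ESTIMATORS = {"hudson": hudson_fst, "patterson": patterson_fst}


def windowed_fst(
    ac_a: np.ndarray,
    ac_b: np.ndarray,
    windows,
    estimator: str = "hudson",
) -> np.ndarray:
    """Ratio-of-averages F_ST per window (windows index the site axis)."""
    fn = _ESTIMATORS[estimator]
    out = np.empty(len(windows))
    for k, w in enumerate(windows):
        sl = slice(w.snp_start, w.snp_end)
        _, _, out[k] = fn(ac_a[sl], ac_b[sl])
    return out


# ---------------------------------------------------------------------------
# resampling null


@dataclass(frozen=True)
class FstNull:
    """Null distributions of two-individual pairwise F_ST.

    Each iteration draws a fresh pair of individuals (two from the same
    population for the within distributions, one from each for between)
    and a fresh random set of SNPs, then computes pairwise F_ST treating
    each individual's two haplotypes as a population of two alleles.
    """

    within_a: np.ndarray
    within_b: np.ndarray
    between: np.ndarray
    n_snps: int
    seed: int
    p_within_a_vs_between: float
    p_within_b_vs_between: float
    u_within_a_vs_between: float
    u_within_b_vs_between: float


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U from rank sums with midrank ties.

    Exact by enumeration for combined samples of at most 12 values without
    ties; normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fst_resampling_null(
    diplo: DiplotypeSet,
    frame: CohortFrame,
    pop_a_query,
    pop_b_query,
    n_snps: int = 1000,
    n_iter: int = 1000,
    estimator: str = "patterson",
    seed: int = 0,
) -> FstNull:
    """Within/between-population two-individual F_ST null distributions.

    Within-population F_ST is computed between two randomly selected
    individuals of the same population; between-population F_ST between one
    random individual from each.  Both the pair and the ``n_snps`` SNP set
    are redrawn every iteration; distributions are compared with two-sided
    Mann-Whitney U tests (within-A vs between and within-B vs between).
    """
    frame.check_samples(diplo.samples)
    order = {s: i for i, s in enumerate(diplo.samples)}
    idx_a = np.array(
        [order[s] for s in frame.table["sample_id"].iloc[frame.indices_where(pop_a_query)]]
    )
    idx_b = np.array(
        [order[s] for s in frame.table["sample_id"].iloc[frame.indices_where(pop_b_query)]]
    )
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("each population needs at least 2 individuals")
    complete = (diplo.matrix != MISSING).all(axis=1)
    eligible = np.flatnonzero(complete)
    if eligible.size < n_snps:
        raise ValueError(
            f"only {eligible.size} complete sites available, need {n_snps}"
        )
    fn = _ESTIMATORS[estimator]
    rng = np.random.default_rng(seed)
    g = diplo.matrix

    def pair_fst(i: int, j: int, sites: np.ndarray) -> float:
        gi = g[sites, i].astype(np.int64)
        gj = g[sites, j].astype(np.int64)
        ac_i = np.stack([2 - gi, gi], axis=1)
        ac_j = np.stack([2 - gj, gj], axis=1)
        return fn(ac_i, ac_j)[2]

    within_a = np.empty(n_iter)
    within_b = np.empty(n_iter)
    between = np.empty(n_iter)
    for it in range(n_iter):
        sites = rng.choice(eligible, size=n_snps, replace=False)
        ia = rng.choice(idx_a, size=2, replace=False)
        ib = rng.choice(idx_b, size=2, replace=False)
        within_a[it] = pair_fst(ia[0], ia[1], sites)
        within_b[it] = pair_fst(ib[0], ib[1], sites)
        between[it] = pair_fst(rng.choice(idx_a), rng.choice(idx_b), sites)

    u_a, p_a = mann_whitney_u(within_a, between)
    u_b, p_b = mann_whitney_u(within_b, between)
    return FstNull(
        within_a=within_a,
        within_b=within_b,
        between=between,
        n_snps=n_snps,
        seed=seed,
        p_within_a_vs_between=p_a,
        p_within_b_vs_between=p_b,
        u_within_a_vs_between=u_a,
        u_within_b_vs_between=u_b,
    )
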