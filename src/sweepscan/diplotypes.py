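"""Diplotype clustering at candidate loci.

Diplotypes (per-sample {0,1,2} allele counts) across a locus are grouped
by complete-linkage hierarchical clustering on the city-block (Manhattan)
distance.  Clusters are then summarised: size, tag-SNP allele frequencies,
metadata composition and mean heterozygosity — swept clusters show both a
high tag frequency and reduced heterozygosity.

The linkage is computed by a deterministic agglomerative pass: at each step
the pair of clusters with the smallest maximum pairwise member distance is
merged, ties broken on the smallest cluster indices, so dendrograms are
reproducible.  The merge table uses the scipy convention (original
observations 0..n-1, the cluster formed at step k numbered n+k), so scipy's
dendrogram and cutting utilities apply directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, CohortFrame, DiplotypeSet


@dataclass(frozen=True)
class TagSnp:
    """A single variant marking carriage of a swept haplotype."""

    name: str  # e.g. "Cyp9k1-G454A"
    contig: str
    position: int  # bp, 1-based
    alt: str = "T"


#: Locus intervals surveyed for sweeps (contig, bp_start, bp_end), 1-based.
CANDIDATE_LOCI = {
    "RP1": ("2RL", 8_685_464, 8_692_407),
    "Cyp9k1": ("X", 8_440_000, 8_451_000),
    "Gste2": ("2RL", 76_406_705, 76_407_655),
    "TMC": ("3RL", 67_925_771, 67_931_656),
    "Dgk": ("X", 13_590_000, 13_690_044),
}


def extract_locus(data, interval: tuple[int, int]):
    """Subset a DiplotypeSet/HaplotypeSet to sites with
    bp_start <= position <= bp_end (order preserved)."""
    lo, hi = interval
    if hi < lo:
        raise ValueError(f"empty interval [{lo}, {hi}]")
    pos = data.variants.positions
    index = np.flatnonzero((pos >= lo) & (pos <= hi))
    if index.size == 0:
        raise ValueError(
            f"no sites in {data.variants.contig}:{lo}-{hi}"
        )
    return data.take_sites(index)


def complete_linkage(dist: np.ndarray) -> np.ndarray:
    """Complete-linkage agglomerative clustering of a distance matrix.

    Returns an (n-1) x 4 scipy-style linkage matrix [i, j, height, size];
    heights are monotone non-decreasing (a property of complete linkage).
    """
    d = np.array(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    active = list(range(n))  # cluster ids, in creation order
    sizes = {i: 1 for i in range(n)}
    # inter-cluster distances, keyed on active positions
    cur = d.copy()
    np.fill_diagonal(cur, np.inf)
    merges = np.empty((n - 1, 4))
    for step in range(n - 1):
        m = cur.shape[0]
        flat = np.argmin(cur)
        height = cur.flat[flat]
        # smallest (i, j) among tied minima, by active order
        ties = np.argwhere(cur == height)
        ties = ties[ties[:, 0] < ties[:, 1]]
        i, j = min(map(tuple, ties))
        ci, cj = active[i], active[j]
        new_id = n + step
        merges[step] = (min(ci, cj), max(ci, cj), height, sizes[ci] + sizes[cj])
        sizes[new_id] = sizes[ci] + sizes[cj]
        # complete linkage: distance to the merged cluster is the max
        new_row = np.maximum(cur[i], cur[j])
        keep = [k for k in range(m) if k not in (i, j)]
        nxt = np.empty((m - 1, m - 1))
        nxt[:-1, :-1] = cur[np.ix_(keep, keep)]
        nxt[-1, :-1] = nxt[:-1, -1] = new_row[keep]
        nxt[-1, -1] = np.inf
        cur = nxt
        active = [active[k] for k in keep] + [new_id]
    assert np.all(np.diff(merges[:, 2]) >= -1e-9), "heights must be monotone"
    return merges


def cut_clusters(
    linkage: np.ndarray, height: float | None = None, k: int | None = None
) -> np.ndarray:
    """Flat cluster labels (1-based, scipy convention) from a linkage.

    Exactly one of ``height`` (cut distance) or ``k`` (cluster count) must
    be given.
    """
    from scipy.cluster.hierarchy import fcluster

    if (height is None) == (k is None):
        raise ValueError("give exactly one of height or k")
    n = linkage.shape[0] + 1
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        return fcluster(linkage, t=k, criterion="maxclust")
    return fcluster(linkage, t=height, criterion="distance")


def sample_heterozygosity(diplo: DiplotypeSet) -> np.ndarray:
    """Per-sample fraction of non-missing locus sites that are heterozygous.

    NaN for samples with no non-missing site.
    """
    g = diplo.matrix
    ok = g != MISSING
    n_ok = ok.sum(axis=0)
    het = ((g == 1) & ok).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n_ok > 0, het / np.maximum(n_ok, 1), np.nan)


def annotate_clusters(
    assignment: np.ndarray,
    locus: DiplotypeSet,
    tags: list[TagSnp],
    frame: CohortFrame,
    fields: tuple[str, ...] = ("country", "region", "round", "arm"),
) -> pd.DataFrame:
    """Per-cluster summary: size, tag-allele frequencies, metadata
    composition fractions and mean heterozygosity."""
    frame.check_samples(locus.samples)
    meta = frame.table.set_index("sample_id").loc[list(locus.samples)].reset_index()
    positions = locus.variants.positions
    tag_rows = {}
    for tag in tags:
        hits = np.flatnonzero(positions == tag.position)
        if hits.size == 0:
            raise ValueError(
                f"tag {tag.name} at {tag.contig}:{tag.position} absent from locus"
            )
        tag_rows[tag.name] = int(hits[0])
    het = sample_heterozygosity(locus)
    rows = []
    for cluster in np.unique(assignment):
        members = np.flatnonzero(assignment == cluster)
        row = {"cluster": cluster, "size": int(members.size)}
        for name, site in tag_rows.items():
            g = locus.matrix[site, members]
            ok = g != MISSING
            row[f"tag_{name}"] = (
                float(g[ok].sum() / (2 * ok.sum())) if ok.any() else np.nan
            )
        for field in fields:
            values = meta[field].iloc[members]
            comp = values.value_counts(normalize=True).to_dict()
            row[f"composition_{field}"] = {str(k): float(v) for k, v in comp.items()}
        row["mean_heterozygosity"] = float(np.nanmean(het[members]))
        rows.append(row)
    return pd.DataFrame(rows)
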