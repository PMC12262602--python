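"""Windowed diversity statistics: nucleotide diversity, Watterson's theta,
and Tajima's D on phased haplotypes.

Per-site values divide by the total number of sites in the window
(segregating or not), the usual per-site diversity convention.  Tajima's D
uses the 1989 constants computed from the haplotype sample size; it is
undefined (NaN) in windows with no segregating sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HaplotypeSet, ScanTrack, WindowSpec


@dataclass(frozen=True)
class DiversityRow:
    window: WindowSpec
    pi_per_site: float
    theta_w_per_site: float
    tajimas_d: float  # NaN when S == 0
    n_haplotypes: int
    n_segregating: int


def _site_pi(alt_counts: np.ndarray, n: int) -> np.ndarray:
    """Per-site mean pairwise difference, unbiased: 2p(1-p) * n/(n-1)."""
    p = alt_counts / n
    return 2.0 * p * (1.0 - p) * n / (n - 1)


def nucleotide_diversity(matrix: np.ndarray) -> float:
    """Per-site nucleotide diversity of a sites x haplotypes {0,1} window.

    pi = sum over sites of 2 p (1 - p) n/(n-1), divided by the number of
    sites in the window (monomorphic sites included in the denominator).
    """
    n = matrix.shape[1]
    if n < 2:
        raise ValueError("nucleotide diversity needs at least 2 haplotypes")
    if matrix.shape[0] == 0:
        return 0.0
    alt = matrix.sum(axis=1)
    return float(_site_pi(alt, n).sum() / matrix.shape[0])


def watterson_theta(S: int, n_haplotypes: int, L: int) -> float:
    """Watterson's estimator per site: S / a1 / L with a1 = sum 1/i."""
    if n_haplotypes < 2:
        raise ValueError("Watterson's theta needs at least 2 haplotypes")
    if L < 1:
        raise ValueError("window length must be at least 1 site")
    a1 = np.sum(1.0 / np.arange(1, n_haplotypes))
    return float(S / a1 / L)


def _tajima_constants(n: int) -> tuple[float, float]:
    """e1, e2 of Tajima (1989), from the haplotype sample size n."""
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(matrix: np.ndarray) -> float:
    """Tajima's D for one window of the sites x haplotypes {0,1} matrix.

    D = (pi - thetaW) / sqrt(e1 S + e2 S (S - 1)), both statistics on the
    whole-window scale.  Returns NaN when no site segregates.
    """
    n = matrix.shape[1]
    if n < 2:
        raise ValueError("Tajima's D needs at least 2 haplotypes")
    alt = matrix.sum(axis=1)
    seg = (alt > 0) & (alt < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    pi = _site_pi(alt[seg], n).sum()
    a1 = np.sum(1.0 / np.arange(1, n))
    theta_w = S / a1
    e1, e2 = _tajima_constants(n)
    return float((pi - theta_w) / np.sqrt(e1 * S + e2 * S * (S - 1)))


def diversity_window(matrix: np.ndarray, window: WindowSpec) -> DiversityRow:
    n = matrix.shape[1]
    alt = matrix.sum(axis=1)
    seg = (alt > 0) & (alt < n)
    S = int(seg.sum())
    L = matrix.shape[0]
    return DiversityRow(
        window=window,
        pi_per_site=nucleotide_diversity(matrix),
        theta_w_per_site=watterson_theta(S, n, L),
        tajimas_d=tajimas_d(matrix),
        n_haplotypes=n,
        n_segregating=S,
    )


def diversity_scan(
    hapset: HaplotypeSet, windows: list[WindowSpec]
) -> tuple[ScanTrack, ScanTrack, ScanTrack]:
    """Per-window (pi, thetaW, D) tracks for one cohort."""
    if hapset.n_haplotypes < 2:
        raise ValueError("cohort must contain at least 2 haplotypes")
    rows = [
        diversity_window(hapset.matrix[w.snp_start : w.snp_end], w) for w in windows
    ]
    return (
        ScanTrack("pi", windows, [r.pi_per_site for r in rows]),
        ScanTrack("theta_w", windows, [r.theta_w_per_site for r in rows]),
        ScanTrack("tajimas_d", windows, [r.tajimas_d for r in rows]),
    )


def diversity_table(rows: list[DiversityRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [r.window.contig for r in rows],
            "bp_start": [r.window.bp_start for r in rows],
            "bp_end": [r.window.bp_end for r in rows],
            "pi": [r.pi_per_site for r in rows],
            "theta_w": [r.theta_w_per_site for r in rows],
            "tajimas_d": [r.tajimas_d for r in rows],
            "S": [r.n_segregating for r in rows],
            "n_haplotypes": [r.n_haplotypes for r in rows],
        }
    )
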