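"""Haplotype-homozygosity selection scans.

Garud's H statistics summarise the haplotype frequency spectrum of a
window: H1 = sum p_i^2 is the haplotype homozygosity, H12 pools the top
two haplotypes and is sensitive to both hard and soft sweeps, H123 pools
the top three, and H2/H1 helps distinguish hard from soft sweeps.  H1X is
the cross-cohort analogue, sum over shared haplotypes of the product of
their frequencies, and detects sweeps shared between cohorts.

The temporal contrast is dH12 = H12(post) - H12(pre) per window: positive
values mean reduced haplotype diversity after the intervention.  Peaks are
windows exceeding three times the gap between the genome-wide median and
98th percentile; per-window significance comes from permuting individual
(pre/post) labels, keeping both haplotypes of an individual together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CohortFrame, HaplotypeSet, ScanTrack, WindowSpec


# ---------------------------------------------------------------------------
# haplotype frequency spectra and H statistics


def hap_freq_spectrum(matrix: np.ndarray) -> np.ndarray:
    """Distinct-haplotype frequencies of a sites x haplotypes window,
    sorted descending.  Haplotypes are compared over the full window."""
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValueError("need a sites x haplotypes matrix with >= 2 haplotypes")
    if matrix.shape[0] == 0:
        raise ValueError("empty window")
    _, counts = np.unique(np.ascontiguousarray(matrix.T), axis=0, return_counts=True)
    freqs = np.sort(counts)[::-1] / matrix.shape[1]
    return freqs


def garud_h(freqs: np.ndarray) -> tuple[float, float, float, float]:
    """(H1, H12, H123, H2/H1) from a descending haplotype frequency spectrum.

    H1 = sum p_i^2; H12 = (p1+p2)^2 + sum_{i>=3} p_i^2;
    H123 = (p1+p2+p3)^2 + sum_{i>=4} p_i^2; H2/H1 = (H1 - p1^2)/H1.
    Absent ranks count as frequency zero.
    """
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty spectrum")
    sq = p**2
    h1 = float(sq.sum())
    p1 = p[0]
    p2 = p[1] if p.size > 1 else 0.0
    p3 = p[2] if p.size > 2 else 0.0
    h12 = float((p1 + p2) ** 2 + sq[2:].sum())
    h123 = float((p1 + p2 + p3) ** 2 + sq[3:].sum())
    h2_h1 = float((h1 - p1**2) / h1)
    return h1, h12, h123, h2_h1


def _window_keys(matrix: np.ndarray) -> np.ndarray:
    """Integer id per haplotype column, equal ids iff identical sequences."""
    cols = np.ascontiguousarray(matrix.T)
    _, inverse = np.unique(cols, axis=0, return_inverse=True)
    return inverse


def joint_hap_freqs(matrix_a: np.ndarray, matrix_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Frequencies of each distinct haplotype in two cohorts, jointly keyed.

    Both matrices must cover the identical window sites.  Returns
    ``(freq_a, freq_b)`` aligned on the union of observed haplotypes.
    """
    if matrix_a.shape[0] != matrix_b.shape[0]:
        raise ValueError("cohort windows cover different site sets")
    na, nb = matrix_a.shape[1], matrix_b.shape[1]
    ids = _window_keys(np.concatenate([matrix_a, matrix_b], axis=1))
    k = ids.max() + 1
    freq_a = np.bincount(ids[:na], minlength=k) / na
    freq_b = np.bincount(ids[na:], minlength=k) / nb
    return freq_a, freq_b


def h1x(matrix_a: np.ndarray, matrix_b: np.ndarray) -> float:
    """Cross-cohort haplotype homozygosity: sum_h f_A(h) f_B(h)."""
    freq_a, freq_b = joint_hap_freqs(matrix_a, matrix_b)
    return float(np.dot(freq_a, freq_b))


# ---------------------------------------------------------------------------
# scans


def h12_scan(hapset: HaplotypeSet, windows: list[WindowSpec], statistic: str = "h12") -> ScanTrack:
    """Per-window Garud H statistic track for one cohort."""
    if hapset.n_haplotypes < 2:
        raise ValueError("cohort must contain at least 2 haplotypes")
    which = {"h1": 0, "h12": 1, "h123": 2, "h2_h1": 3}[statistic]
    values = np.empty(len(windows))
    for k, w in enumerate(windows):
        freqs = hap_freq_spectrum(hapset.matrix[w.snp_start : w.snp_end])
        values[k] = garud_h(freqs)[which]
    return ScanTrack(statistic, windows, values)


def h1x_scan(hapset_a: HaplotypeSet, hapset_b: HaplotypeSet, windows: list[WindowSpec]) -> ScanTrack:
    """Per-window H1X between two cohorts over identical windows."""
    values = np.empty(len(windows))
    for k, w in enumerate(windows):
        sl = slice(w.snp_start, w.snp_end)
        values[k] = h1x(hapset_a.matrix[sl], hapset_b.matrix[sl])
    return ScanTrack("h1x", windows, values)


def top_quantile_threshold(values: np.ndarray, q: float = 0.01) -> float:
    """The (1-q) empirical quantile of all window values, pooled over
    contigs, with linear interpolation.  q=0.01 gives the top-1% rule."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty track")
    return float(np.quantile(values, 1.0 - q, method="linear"))


# ---------------------------------------------------------------------------
# peaks


@dataclass(frozen=True)
class Peak:
    contig: str
    window_start: int  # half-open indices into the track's window list
    window_end: int
    bp_start: int
    bp_end: int
    summit_window: int
    summit_value: float


@dataclass(frozen=True)
class PeakSet:
    peaks: tuple
    threshold: float

    def __len__(self) -> int:
        return len(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": [p.contig for p in self.peaks],
                "bp_start": [p.bp_start for p in self.peaks],
                "bp_end": [p.bp_end for p in self.peaks],
                "summit_window": [p.summit_window for p in self.peaks],
                "summit_value": [p.summit_value for p in self.peaks],
            }
        )


def call_peaks(track: ScanTrack, threshold: float, max_gap_windows: int = 0) -> PeakSet:
    """Group above-threshold windows into peaks.

    A peak is a maximal run of windows with value >= threshold; runs on the
    same contig separated by at most ``max_gap_windows`` below-threshold
    windows are merged.  The summit is the window with the largest value.
    Peaks never span contigs.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    values = track.values
    contigs = np.array([w.contig for w in track.windows])
    above = np.flatnonzero(values >= threshold)
    peaks = []
    run: list[int] = []
    for idx in above:
        if run and (
            contigs[idx] != contigs[run[-1]] or idx - run[-1] > max_gap_windows + 1
        ):
            peaks.append(run)
            run = []
        run.append(int(idx))
    if run:
        peaks.append(run)
    out = []
    for run in peaks:
        start, end = run[0], run[-1] + 1
        segment = values[start:end]
        summit = start + int(np.argmax(segment))
        out.append(
            Peak(
                contig=str(contigs[start]),
                window_start=start,
                window_end=end,
                bp_start=track.windows[start].bp_start,
                bp_end=track.windows[end - 1].bp_end,
                summit_window=summit,
                summit_value=float(values[summit]),
            )
        )
    return PeakSet(tuple(out), float(threshold))


# ---------------------------------------------------------------------------
# temporal contrast


def delta_h12(track_pre: ScanTrack, track_post: ScanTrack) -> ScanTrack:
    """dH12 = H12(post) - H12(pre) per window; positive = reduced haplotype
    diversity after the intervention.  Window lists must match exactly."""
    if track_pre.windows != track_post.windows:
        raise ValueError("pre and post tracks must share identical windows")
    return ScanTrack(
        "delta_h12", track_pre.windows, track_post.values - track_pre.values
    )


def delta_peak_threshold(delta_values: np.ndarray) -> float:
    """Peak threshold for dH12: 3 x (98th percentile - median) of the
    genome-wide dH12 distribution."""
    values = np.asarray(delta_values, dtype=float)
    if values.size == 0:
        raise ValueError("empty track")
    return float(3.0 * (np.percentile(values, 98) - np.median(values)))


@dataclass
class DeltaResult:
    """Per-window dH12 with permutation significance.

    ``p_values`` are two-sided with the add-one convention, so they lie in
    (0, 1]; ``peak`` flags |dH12| beyond the genome-wide peak threshold
    (positive and negative flagged separately); ``significant`` flags
    p < alpha.
    """

    windows: list
    delta: np.ndarray
    p_values: np.ndarray
    peak_positive: np.ndarray
    peak_negative: np.ndarray
    significant: np.ndarray
    threshold: float
    n_perm: int
    alpha: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": [w.contig for w in self.windows],
                "bp_start": [w.bp_start for w in self.windows],
                "bp_end": [w.bp_end for w in self.windows],
                "delta_h12": self.delta,
                "p_value": self.p_values,
                "peak_positive": self.peak_positive,
                "peak_negative": self.peak_negative,
                "significant": self.significant,
            }
        )


def _h12_from_counts(counts: np.ndarray, n: int) -> float:
    top = np.sort(counts)[::-1] / n
    if top.size == 1:
        return float(top[0] ** 2)
    return float((top[0] + top[1]) ** 2 + (top[2:] ** 2).sum())


def delta_permutation_test(
    hapset: HaplotypeSet,
    frame: CohortFrame,
    pre_query,
    post_query,
    windows: list[WindowSpec],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
    signed: bool = False,
) -> DeltaResult:
    """Permutation test of dH12 between a pre and a post cohort.

    Individuals (both haplotypes together) are shuffled between the pre and
    post groups, preserving group sizes; dH12 is recomputed for every
    window under each of ``n_perm`` permutations using one shared label
    shuffle per permutation (windows are not permuted independently).  The
    two-sided p-value per window is (1 + #{|d_perm| >= |d_obs|}) /
    (1 + n_perm); with ``signed`` the comparison uses signed exceedance
    in the direction of the observed value instead of |d|.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    frame.check_samples(hapset.samples)
    order = {s: i for i, s in enumerate(hapset.samples)}
    meta_ids = frame.table["sample_id"]
    idx_pre = np.array([order[s] for s in meta_ids.iloc[frame.indices_where(pre_query)]])
    idx_post = np.array([order[s] for s in meta_ids.iloc[frame.indices_where(post_query)]])
    if idx_pre.size < 1 or idx_post.size < 1:
        raise ValueError("both cohorts must contain at least 2 haplotypes")
    n_pre, n_post = idx_pre.size, idx_post.size
    pooled = np.concatenate([idx_pre, idx_post])

    # per-window haplotype ids for the pooled cohort, columns ordered as
    # (sample, haplotype) pairs: sample k occupies columns 2k, 2k+1
    cols = hapset.sample_columns(pooled)
    sub = hapset.matrix[:, cols]
    window_ids = []
    for w in windows:
        ids = _window_keys(sub[w.snp_start : w.snp_end])
        window_ids.append(ids.reshape(-1, 2))  # one row per pooled sample

    def delta_for(assign_pre: np.ndarray) -> np.ndarray:
        """dH12 per window for a boolean pre-assignment over pooled samples."""
        out = np.empty(len(windows))
        for k, ids in enumerate(window_ids):
            m = ids.max() + 1
            pre_counts = np.bincount(ids[assign_pre].ravel(), minlength=m)
            post_counts = np.bincount(ids[~assign_pre].ravel(), minlength=m)
            out[k] = _h12_from_counts(post_counts, 2 * n_post) - _h12_from_counts(
                pre_counts, 2 * n_pre
            )
        return out

    observed_assign = np.zeros(n_pre + n_post, dtype=bool)
    observed_assign[:n_pre] = True
    observed = delta_for(observed_assign)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(windows))
    for _ in range(n_perm):
        perm = rng.permutation(n_pre + n_post)
        assign = np.zeros(n_pre + n_post, dtype=bool)
        assign[perm[:n_pre]] = True
        d = delta_for(assign)
        if signed:
            exceed += np.where(observed >= 0, d >= observed, d <= observed)
        else:
            exceed += np.abs(d) >= np.abs(observed)
    p = (1.0 + exceed) / (1.0 + n_perm)

    threshold = delta_peak_threshold(observed)
    return DeltaResult(
        windows=windows,
        delta=observed,
        p_values=p,
        peak_positive=observed > threshold,
        peak_negative=observed < -threshold,
        significant=p < alpha,
        threshold=threshold,
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
    )
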