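"""Core data model: variants, haplotype/diplotype matrices, cohorts, windows.

Conventions
-----------
* Genomic positions are 1-based inclusive, as in VCF.
* Window indices into the site axis are half-open ``[snp_start, snp_end)``.
* Haplotype matrices are ``n_sites x n_haplotypes`` with entries in {0, 1};
  haplotype columns ``2*i`` and ``2*i + 1`` belong to sample ``i``.
* Diplotype matrices are ``n_sites x n_samples`` with entries in {0, 1, 2}
  and ``MISSING`` (= -1) for missing calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "region",
    "round",
    "arm",
    "household",
    "country",
    "year",
)


@dataclass(frozen=True)
class PositionedVariants:
    """Biallelic SNPs on a single contig, positions strictly ascending."""

    contig: str
    positions: np.ndarray  # int64, bp, 1-based
    ref: np.ndarray  # allele codes, dtype '<U...'
    alt: np.ndarray

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "ref", np.asarray(self.ref))
        object.__setattr__(self, "alt", np.asarray(self.alt))
        if positions.ndim != 1:
            raise ValueError("positions must be one-dimensional")
        if len(self.ref) != len(positions) or len(self.alt) != len(positions):
            raise ValueError("ref/alt length must match positions")
        if positions.size > 1 and not np.all(np.diff(positions) > 0):
            raise ValueError(
                f"positions on {self.contig} must be strictly ascending"
            )

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def take(self, index: np.ndarray) -> "PositionedVariants":
        return PositionedVariants(
            self.contig, self.positions[index], self.ref[index], self.alt[index]
        )


@dataclass(frozen=True)
class HaplotypeSet:
    """Phased binary haplotypes: sites x (2 * n_samples)."""

    variants: PositionedVariants
    matrix: np.ndarray  # int8, {0,1}
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        matrix = np.ascontiguousarray(self.matrix, dtype=np.int8)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "samples", tuple(self.samples))
        if matrix.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if matrix.shape[0] != self.variants.n_sites:
            raise ValueError("row count must equal number of sites")
        if matrix.shape[1] != 2 * len(self.samples):
            raise ValueError("column count must be 2 x sample count")
        bad = (matrix != 0) & (matrix != 1)
        if bad.any():
            raise ValueError("haplotype entries must be strictly binary")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[1]

    def sample_columns(self, sample_index: np.ndarray) -> np.ndarray:
        """Haplotype column indices for the given sample indices."""
        sample_index = np.asarray(sample_index)
        return np.repeat(2 * sample_index, 2) + np.tile([0, 1], len(sample_index))

    def take_samples(self, sample_index: np.ndarray) -> "HaplotypeSet":
        cols = self.sample_columns(sample_index)
        return HaplotypeSet(
            self.variants,
            self.matrix[:, cols],
            tuple(np.asarray(self.samples)[sample_index]),
        )

    def take_sites(self, index: np.ndarray) -> "HaplotypeSet":
        return HaplotypeSet(self.variants.take(index), self.matrix[index], self.samples)

    def to_diplotypes(self) -> "DiplotypeSet":
        counts = self.matrix[:, 0::2] + self.matrix[:, 1::2]
        return DiplotypeSet(self.variants, counts, self.samples)


@dataclass(frozen=True)
class DiplotypeSet:
    """Per-sample alternate-allele counts: sites x n_samples, {0,1,2} or MISSING."""

    variants: PositionedVariants
    matrix: np.ndarray  # int8
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        matrix = np.ascontiguousarray(self.matrix, dtype=np.int8)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "samples", tuple(self.samples))
        if matrix.ndim != 2:
            raise ValueError("diplotype matrix must be 2-D")
        if matrix.shape[0] != self.variants.n_sites:
            raise ValueError("row count must equal number of sites")
        if matrix.shape[1] != len(self.samples):
            raise ValueError("column count must equal sample count")
        bad = ~np.isin(matrix, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("diplotype entries must be in {0,1,2} or missing")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def take_samples(self, sample_index: np.ndarray) -> "DiplotypeSet":
        return DiplotypeSet(
            self.variants,
            self.matrix[:, sample_index],
            tuple(np.asarray(self.samples)[sample_index]),
        )

    def take_sites(self, index: np.ndarray) -> "DiplotypeSet":
        return DiplotypeSet(self.variants.take(index), self.matrix[index], self.samples)

    def allele_counts(self, sample_index: np.ndarray | None = None) -> np.ndarray:
        """Per-site (ref, alt) allele counts over non-missing calls."""
        g = self.matrix if sample_index is None else self.matrix[:, sample_index]
        ok = g != MISSING
        alt = np.where(ok, g, 0).sum(axis=1)
        total = 2 * ok.sum(axis=1)
        return np.stack([total - alt, alt], axis=1)


class CohortFrame:
    """Validated per-sample trial metadata.

    Wraps a :class:`pandas.DataFrame` with one row per sample and the columns
    sample_id, region, round, arm, household, country, year.  Sample ids are
    unique; ``region`` must be one of {East, West} and ``arm`` one of
    {PBO, nonPBO}.
    """

    REGIONS = ("East", "West")
    ARMS = ("PBO", "nonPBO")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        table = table.reset_index(drop=True).copy()
        dup = table["sample_id"][table["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id values: {sorted(set(dup))}")
        bad_region = set(table["region"]) - set(self.REGIONS)
        if bad_region:
            raise ValueError(f"unknown region levels: {sorted(bad_region)}")
        bad_arm = set(table["arm"]) - set(self.ARMS)
        if bad_arm:
            raise ValueError(f"unknown arm levels: {sorted(bad_arm)}")
        table["year"] = table["year"].astype(int)
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.table["sample_id"])

    def check_samples(self, samples: Sequence[str]) -> None:
        """Require a one-to-one match between genotype and metadata samples."""
        geno = set(samples)
        meta = set(self.sample_ids)
        if geno != meta:
            raise ValueError(
                "metadata/genotype sample mismatch; "
                f"only in genotypes: {sorted(geno - meta)}, "
                f"only in metadata: {sorted(meta - geno)}"
            )

    def indices_where(self, query: str | Callable[[pd.DataFrame], pd.Series] | dict) -> np.ndarray:
        """Row indices of samples matching a query.

        ``query`` may be a pandas query string (``"region == 'East'"``), a
        dict of exact field matches, or a callable returning a boolean mask.
        """
        if isinstance(query, str):
            mask = self.table.eval(query)
        elif isinstance(query, dict):
            mask = pd.Series(True, index=self.table.index)
            for key, value in query.items():
                if key not in self.table.columns:
                    raise KeyError(f"unknown metadata field: {key}")
                mask &= self.table[key] == value
        else:
            mask = query(self.table)
        idx = np.flatnonzero(np.asarray(mask, dtype=bool))
        if idx.size == 0:
            warnings.warn(f"cohort query {query!r} matched no samples", stacklevel=2)
        return idx

    def subset(self, index: np.ndarray) -> "CohortFrame":
        return CohortFrame(self.table.iloc[index])


@dataclass(frozen=True)
class WindowSpec:
    contig: str
    snp_start: int  # half-open index into the site axis
    snp_end: int
    bp_start: int  # 1-based inclusive genomic span
    bp_end: int

    @property
    def n_snps(self) -> int:
        return self.snp_end - self.snp_start

    @property
    def span_bp(self) -> int:
        return self.bp_end - self.bp_start + 1


@dataclass
class ScanTrack:
    """One statistic value per ordered genomic window."""

    statistic: str
    windows: list[WindowSpec]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.windows):
            raise ValueError("one value per window required")

    def __len__(self) -> int:
        return len(self.windows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": [w.contig for w in self.windows],
                "bp_start": [w.bp_start for w in self.windows],
                "bp_end": [w.bp_end for w in self.windows],
                "n_snps": [w.n_snps for w in self.windows],
                self.statistic: self.values,
            }
        )

    def to_bed(self, path) -> None:
        """BED-compatible TSV: contig, 0-based start, end, value."""
        frame = self.to_frame()
        out = pd.DataFrame(
            {
                "contig": frame["contig"],
                "start": frame["bp_start"] - 1,
                "end": frame["bp_end"],
                "value": frame[self.statistic],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# ingestion


def read_metadata(path) -> CohortFrame:
    """Read a TSV/CSV metadata table into a validated :class:`CohortFrame`."""
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "household": str})
    return CohortFrame(table)


def read_vcf(
    path,
    contig: str | None = None,
    region: tuple[int, int] | None = None,
    require_phased: bool = True,
):
    """Read biallelic SNPs from a VCF into haplotype and diplotype matrices.

    Multiallelic records, indels and non-SNP records are dropped (the count
    is logged).  Haplotypes are taken from phased GT fields; with
    ``require_phased`` an unphased heterozygote raises an error naming the
    first offending record.  Missing calls are missing in the diplotype
    matrix and force the site to be treated as missing for haplotypes.

    Returns ``(PositionedVariants, HaplotypeSet | None, DiplotypeSet)``;
    the haplotype set is ``None`` when ``require_phased`` is false and any
    retained site is unphased.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = tuple(vcf.samples)
    if contig is None:
        seqnames = vcf.seqnames
        if len(seqnames) != 1:
            raise ValueError(
                f"VCF has contigs {seqnames}; specify which one to read"
            )
        contig = seqnames[0]
    elif vcf.seqnames and contig not in vcf.seqnames:
        raise ValueError(f"contig {contig!r} not present in {path}")

    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    hap_rows: list[np.ndarray] = []
    dip_rows: list[np.ndarray] = []
    n_dropped = 0
    phased_ok = True

    if region is not None:
        records = vcf(f"{contig}:{region[0]}-{region[1]}")
    else:
        records = (v for v in vcf if v.CHROM == contig)

    for v in records:
        if v.CHROM != contig:
            continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        gt = np.asarray(v.genotype.array())  # columns: allele1, allele2, phased
        a1, a2, phased = gt[:, 0], gt[:, 1], gt[:, 2]
        het_unphased = (phased == 0) & (a1 >= 0) & (a2 >= 0) & (a1 != a2)
        if het_unphased.any():
            if require_phased:
                bad = samples[int(np.flatnonzero(het_unphased)[0])]
                raise ValueError(
                    f"unphased heterozygous GT at {v.CHROM}:{v.POS} "
                    f"(sample {bad}); phased haplotypes required"
                )
            phased_ok = False
        missing = (a1 < 0) | (a2 < 0)
        hap = np.empty(2 * len(samples), dtype=np.int8)
        hap[0::2] = np.where(missing, 0, a1)
        hap[1::2] = np.where(missing, 0, a2)
        dip = np.where(missing, MISSING, a1 + a2).astype(np.int8)
        # haplotype rows for sites with missing calls are unusable; mark via dip
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        hap_rows.append(hap)
        dip_rows.append(dip)

    if n_dropped:
        logger.info("dropped %d non-biallelic-SNP records from %s", n_dropped, path)

    variants = PositionedVariants(
        contig,
        np.array(positions, dtype=np.int64),
        np.array(refs),
        np.array(alts),
    )
    n_sites = variants.n_sites
    hap_matrix = (
        np.vstack(hap_rows) if hap_rows else np.empty((0, 2 * len(samples)), np.int8)
    )
    dip_matrix = (
        np.vstack(dip_rows) if dip_rows else np.empty((0, len(samples)), np.int8)
    )
    diplo = DiplotypeSet(variants, dip_matrix, samples)
    haplo = HaplotypeSet(variants, hap_matrix, samples) if phased_ok else None
    assert n_sites == diplo.n_sites
    return variants, haplo, diplo


def write_vcf(path, hapset: HaplotypeSet, diplo: DiplotypeSet | None = None) -> None:
    """Write phased biallelic SNPs as minimal uncompressed VCF v4.2.

    When ``diplo`` is given, its missing entries are emitted as ``.|.``;
    otherwise all genotypes come from the haplotype matrix.
    """
    variants = hapset.variants
    samples = hapset.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        end = int(variants.positions[-1]) if variants.n_sites else 1
        fh.write(f"##contig=<ID={variants.contig},length={end + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i in range(variants.n_sites):
            row = hapset.matrix[i]
            gts = []
            for j in range(len(samples)):
                if diplo is not None and diplo.matrix[i, j] == MISSING:
                    gts.append(".|.")
                else:
                    gts.append(f"{row[2 * j]}|{row[2 * j + 1]}")
            fh.write(
                f"{variants.contig}\t{variants.positions[i]}\t.\t"
                f"{variants.ref[i]}\t{variants.alt[i]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# cohort selection and windowing


def select_cohort(data, frame: CohortFrame, query):
    """Subset a HaplotypeSet or DiplotypeSet to the samples matching ``query``.

    Returns ``(subset, subframe)`` with metadata alignment preserved.
    """
    frame.check_samples(data.samples)
    order = {s: i for i, s in enumerate(data.samples)}
    idx = frame.indices_where(query)
    sample_index = np.array(
        [order[s] for s in frame.table["sample_id"].iloc[idx]], dtype=int
    )
    return data.take_samples(sample_index), frame.subset(idx)


def make_windows(
    variants: PositionedVariants,
    window_snps: int = 500,
    step_snps: int | None = None,
    keep_partial: bool = False,
) -> list[WindowSpec]:
    """Windows of a fixed number of SNPs along one contig.

    Non-overlapping by default (``step_snps = window_snps``); the trailing
    partial window is dropped unless ``keep_partial``.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    step = window_snps if step_snps is None else step_snps
    if step < 1:
        raise ValueError("step_snps must be >= 1")
    n = variants.n_sites
    if n < window_snps:
        if not keep_partial or n == 0:
            warnings.warn(
                f"{n} sites is fewer than one {window_snps}-SNP window",
                stacklevel=2,
            )
            return []
    windows = []
    pos = variants.positions
    for start in range(0, n, step):
        end = min(start + window_snps, n)
        if end - start < window_snps:
            if keep_partial and end - start >= 2:
                windows.append(
                    WindowSpec(
                        variants.contig, start, end, int(pos[start]), int(pos[end - 1])
                    )
                )
            break
        windows.append(
            WindowSpec(variants.contig, start, end, int(pos[start]), int(pos[end - 1]))
        )
    return windows


def segregating_mask(
    matrix: np.ndarray,
    column_index: np.ndarray | None = None,
    alleles_per_column: int = 1,
) -> np.ndarray:
    """Boolean mask of sites segregating within the given columns.

    Works on haplotype (0/1, ``alleles_per_column=1``) or diplotype
    (0/1/2 with missing, ``alleles_per_column=2``) matrices: a site
    segregates when its non-missing alternate-allele count is strictly
    between zero and the total allele count.
    """
    sub = matrix if column_index is None else matrix[:, column_index]
    if sub.shape[1] == 0:
        raise ValueError("cohort is empty")
    ok = sub != MISSING
    alt = np.where(ok, sub, 0).sum(axis=1)
    total = alleles_per_column * ok.sum(axis=1)
    return (alt > 0) & (alt < total)
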