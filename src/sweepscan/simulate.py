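"""Synthetic cohort generator.

Produces phased haplotypes, diplotypes and trial metadata with the
statistical structure the downstream analyses assume:

* a neutral background with site frequencies drawn from the standard
  neutral site-frequency spectrum (P(i) proportional to 1/i), sites in
  linkage equilibrium;
* weak regional differentiation between an East and a West population,
  implemented as independent logit-scale perturbations of the shared
  site frequencies with variance ``d`` (``d = 0`` is panmixia);
* household structure: samples grouped into households within each
  (region, round, arm) cell, with a normal logit-scale household effect
  of scale ``sigma_h`` inducing within-household allele correlation;
* hard or soft selective sweeps injected at named loci, with the swept
  core-haplotype frequency set per (round, arm) cohort, identity eroding
  linearly with distance from the sweep centre, and a tag SNP fixed
  alternate on every core haplotype.

Everything is deterministic under the design seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CohortFrame, HaplotypeSet, PositionedVariants, write_vcf

ROUNDS = ("baseline", "round5")
ARMS = ("PBO", "nonPBO")
REGIONS = ("East", "West")


@dataclass(frozen=True)
class SweepConfig:
    """One injected selective sweep.

    ``n_core_haplotypes = 1`` gives a hard sweep, ``>= 2`` a soft sweep.
    ``freq_by_cohort`` maps (round, arm) to the total swept-haplotype
    frequency in that cohort.  ``erosion_rate`` is the per-site reversion
    probability at the window edge; it grows linearly from 0 at the centre.
    """

    name: str
    contig: str
    center: int  # bp
    half_width: int  # bp
    freq_by_cohort: dict
    n_core_haplotypes: int = 1
    erosion_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.n_core_haplotypes < 1:
            raise ValueError("need at least one core haplotype")
        for key, f in self.freq_by_cohort.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"sweep frequency for {key} outside [0,1]")

    def frequency(self, round_: str, arm: str) -> float:
        return float(self.freq_by_cohort.get((round_, arm), 0.0))


def _default_sweeps() -> list:
    """Five sweeps at the resistance-locus geometry surveyed in Uganda.

    RP1 and Cyp9k1 carry the strongest signals; Gste2, TMC and Dgk are
    weaker.  Pre-to-post frequency shifts differ by net arm: RP1 rises in
    the nonPBO arm but falls under PBO, Cyp9k1 and TMC rise under PBO,
    Dgk falls in both arms, Gste2 rises in both.
    """
    return [
        SweepConfig(
            name="RP1",
            contig="2RL",
            center=8_688_900,
            half_width=600_000,
            erosion_rate=0.2,
            freq_by_cohort={
                ("baseline", "PBO"): 0.60,
                ("round5", "PBO"): 0.45,
                ("baseline", "nonPBO"): 0.60,
                ("round5", "nonPBO"): 0.75,
            },
        ),
        SweepConfig(
            name="Gste2",
            contig="2RL",
            center=76_407_180,
            half_width=600_000,
            erosion_rate=0.2,
            freq_by_cohort={
                ("baseline", "PBO"): 0.30,
                ("round5", "PBO"): 0.45,
                ("baseline", "nonPBO"): 0.30,
                ("round5", "nonPBO"): 0.40,
            },
        ),
        SweepConfig(
            name="TMC",
            contig="3RL",
            center=67_928_700,
            half_width=600_000,
            erosion_rate=0.2,
            freq_by_cohort={
                ("baseline", "PBO"): 0.30,
                ("round5", "PBO"): 0.45,
                ("baseline", "nonPBO"): 0.30,
                ("round5", "nonPBO"): 0.30,
            },
        ),
        SweepConfig(
            name="Cyp9k1",
            contig="X",
            center=8_445_500,
            half_width=250_000,
            erosion_rate=0.2,
            freq_by_cohort={
                ("baseline", "PBO"): 0.50,
                ("round5", "PBO"): 0.70,
                ("baseline", "nonPBO"): 0.50,
                ("round5", "nonPBO"): 0.55,
            },
        ),
        SweepConfig(
            name="Dgk",
            contig="X",
            center=13_640_000,
            half_width=250_000,
            erosion_rate=0.2,
            freq_by_cohort={
                ("baseline", "PBO"): 0.45,
                ("round5", "PBO"): 0.25,
                ("baseline", "nonPBO"): 0.45,
                ("round5", "nonPBO"): 0.35,
            },
        ),
    ]


@dataclass
class SimDesign:
    """Full specification of one synthetic cohort.

    ``n_per_cell`` samples are drawn for every (region, round, arm) cell.
    ``contigs`` maps contig name to (length_bp, n_sites).  Defaults emulate
    a two-region, two-round, two-arm cluster-randomised trial with five
    sweeps at the surveyed resistance loci, weak regional differentiation
    and modest household clustering.
    """

    n_per_cell: int = 25
    contigs: dict = field(
        default_factory=lambda: {
            "2RL": (90_000_000, 9_000),
            "3RL": (80_000_000, 8_000),
            "X": (18_000_000, 6_000),
        }
    )
    household_mean_size: float = 3.0
    sigma_h: float = 0.25
    d: float = 0.01
    sweeps: list = field(default_factory=_default_sweeps)
    seed: int = 0
    regions: tuple = REGIONS
    rounds: tuple = ROUNDS
    arms: tuple = ARMS

    def __post_init__(self) -> None:
        if self.n_per_cell <= 0:
            raise ValueError("n_per_cell must be positive")
        if self.d < 0 or self.sigma_h < 0:
            raise ValueError("d and sigma_h must be non-negative")
        if self.household_mean_size <= 0:
            raise ValueError("household mean size must be positive")
        for name, (length, n_sites) in self.contigs.items():
            if length <= 0 or n_sites <= 0:
                raise ValueError(f"contig {name}: counts must be positive")


@dataclass
class SimulatedCohort:
    """Simulator output: one HaplotypeSet per contig plus shared metadata."""

    haplotypes: dict  # contig -> HaplotypeSet
    frame: CohortFrame
    truth: dict

    def diplotypes(self, contig: str):
        return self.haplotypes[contig].to_diplotypes()

    @property
    def contigs(self) -> tuple:
        return tuple(self.haplotypes)


def sample_neutral_frequencies(n_sites: int, n_haplotypes_2n: int, rng) -> np.ndarray:
    """Per-site derived-allele frequencies under the standard neutral SFS.

    The derived-allele count i is drawn from P(i) proportional to 1/i for
    i = 1 .. 2n-1, so every frequency lies strictly in (0, 1).
    """
    if n_haplotypes_2n < 4:
        raise ValueError("need at least 4 haplotypes (2n >= 4)")
    rng = np.random.default_rng(rng)
    i = np.arange(1, n_haplotypes_2n)
    w = 1.0 / i
    counts = rng.choice(i, size=n_sites, p=w / w.sum())
    return counts / n_haplotypes_2n


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _make_metadata(design: SimDesign, rng) -> CohortFrame:
    rows = []
    hh_counter = 0
    sample_counter = 0
    for region in design.regions:
        for round_ in design.rounds:
            for arm in design.arms:
                n = design.n_per_cell
                assigned = 0
                while assigned < n:
                    size = 1 + rng.poisson(design.household_mean_size - 1.0)
                    size = min(size, n - assigned)
                    hh_counter += 1
                    hh = f"HH{hh_counter:04d}"
                    for _ in range(size):
                        sample_counter += 1
                        rows.append(
                            {
                                "sample_id": f"S{sample_counter:05d}",
                                "region": region,
                                "round": round_,
                                "arm": arm,
                                "household": hh,
                                "country": "Uganda",
                                "year": 2021 if round_ == design.rounds[0] else 2023,
                            }
                        )
                    assigned += size
    return CohortFrame(pd.DataFrame(rows))


def _simulate_contig(
    design: SimDesign,
    contig: str,
    frame: CohortFrame,
    rng,
) -> HaplotypeSet:
    length, n_sites = design.contigs[contig]
    table = frame.table
    n_samples = len(table)
    positions = np.sort(rng.choice(np.arange(1, length + 1), size=n_sites, replace=False))
    variants = PositionedVariants(
        contig,
        positions,
        np.full(n_sites, "A"),
        np.full(n_sites, "T"),
    )
    p = sample_neutral_frequencies(n_sites, 2 * n_samples, rng)
    logit_p = _logit(p)
    # regional differentiation: independent logit perturbation per region
    p_region = {}
    for region in design.regions:
        eps = rng.normal(0.0, np.sqrt(design.d), size=n_sites) if design.d > 0 else 0.0
        p_region[region] = _expit(logit_p + eps)

    matrix = np.empty((n_sites, 2 * n_samples), dtype=np.int8)
    households = table["household"].to_numpy()
    regions = table["region"].to_numpy()
    for hh in pd.unique(households):
        members = np.flatnonzero(households == hh)
        base = p_region[regions[members[0]]]
        if design.sigma_h > 0:
            u = rng.normal(0.0, design.sigma_h, size=n_sites)
            p_hh = _expit(_logit(base) + u)
        else:
            p_hh = base
        cols = np.repeat(2 * members, 2) + np.tile([0, 1], len(members))
        draws = rng.random((n_sites, len(cols))) < p_hh[:, None]
        matrix[:, cols] = draws.astype(np.int8)
    return HaplotypeSet(variants, matrix, tuple(table["sample_id"]))


def inject_sweep(
    hapset: HaplotypeSet,
    frame: CohortFrame,
    config: SweepConfig,
    seed,
) -> tuple[HaplotypeSet, dict]:
    """Overwrite haplotypes in the sweep window with core haplotypes.

    In each (round, arm) cohort a fraction ``f`` of haplotypes (rounded to
    the nearest count) is replaced by copies of the core haplotype(s); when
    several cores exist, carriers are split evenly among them.  Per site,
    a carrier reverts to its original background allele with probability
    ``erosion_rate * distance / half_width``, so core identity decays
    toward the flanks.  The site nearest the centre is the tag SNP: fixed
    alternate on every core haplotype.

    Returns the modified set and a truth record (window site range, tag
    position, realised carrier counts per cohort).
    """
    rng = np.random.default_rng(seed)
    variants = hapset.variants
    if variants.contig != config.contig:
        raise ValueError(
            f"sweep {config.name} is on {config.contig}, data on {variants.contig}"
        )
    pos = variants.positions
    lo, hi = config.center - config.half_width, config.center + config.half_width
    in_window = np.flatnonzero((pos >= lo) & (pos <= hi))
    if in_window.size == 0:
        raise ValueError(f"sweep window {config.name} [{lo},{hi}] contains no sites")
    tag_site = int(in_window[np.argmin(np.abs(pos[in_window] - config.center))])

    matrix = hapset.matrix.copy()
    # core templates drawn once from the background allele frequencies
    window_rows = matrix[in_window]
    bg_freq = window_rows.mean(axis=1)
    cores = (rng.random((config.n_core_haplotypes, in_window.size)) < bg_freq).astype(
        np.int8
    )
    cores[:, in_window == tag_site] = 1

    dist = np.abs(pos[in_window] - config.center) / config.half_width
    revert_p = np.clip(config.erosion_rate * dist, 0.0, 1.0)

    table = frame.table
    carriers_by_cohort = {}
    for (round_, arm), f in config.freq_by_cohort.items():
        members = np.flatnonzero(
            (table["round"] == round_).to_numpy() & (table["arm"] == arm).to_numpy()
        )
        if members.size == 0:
            continue
        cols = np.repeat(2 * members, 2) + np.tile([0, 1], len(members))
        n_carriers = int(round(f * len(cols)))
        chosen = rng.choice(cols, size=n_carriers, replace=False)
        core_of = rng.integers(0, config.n_core_haplotypes, size=n_carriers)
        for k in range(config.n_core_haplotypes):
            group = chosen[core_of == k]
            if group.size == 0:
                continue
            block = np.broadcast_to(
                cores[k][:, None], (in_window.size, group.size)
            ).copy()
            if config.erosion_rate > 0:
                revert = rng.random(block.shape) < revert_p[:, None]
                block[revert] = matrix[np.ix_(in_window, group)][revert]
            matrix[np.ix_(in_window, group)] = block
        carriers_by_cohort[f"{round_}/{arm}"] = int(n_carriers)

    truth = {
        "name": config.name,
        "contig": config.contig,
        "center": int(config.center),
        "half_width": int(config.half_width),
        "site_start": int(in_window[0]),
        "site_end": int(in_window[-1]) + 1,
        "tag_position": int(pos[tag_site]),
        "n_core_haplotypes": config.n_core_haplotypes,
        "carriers": carriers_by_cohort,
        "freq_by_cohort": {
            f"{r}/{a}": f for (r, a), f in config.freq_by_cohort.items()
        },
    }
    return HaplotypeSet(variants, matrix, hapset.samples), truth


def simulate_cohorts(design: SimDesign) -> SimulatedCohort:
    """Simulate the full multi-contig cohort described by ``design``."""
    root = np.random.SeedSequence(design.seed)
    meta_seed, *contig_seeds = root.spawn(1 + 2 * len(design.contigs))
    rng_meta = np.random.default_rng(meta_seed)
    frame = _make_metadata(design, rng_meta)

    haplotypes = {}
    sweep_truth = []
    for i, contig in enumerate(design.contigs):
        rng = np.random.default_rng(contig_seeds[2 * i])
        hapset = _simulate_contig(design, contig, frame, rng)
        sweep_rng = np.random.default_rng(contig_seeds[2 * i + 1])
        for sweep in design.sweeps:
            if sweep.contig != contig:
                continue
            hapset, truth = inject_sweep(
                hapset, frame, sweep, sweep_rng.integers(2**31)
            )
            sweep_truth.append(truth)
        haplotypes[contig] = hapset

    truth = {
        "seed": int(design.seed),
        "d": design.d,
        "sigma_h": design.sigma_h,
        "n_per_cell": design.n_per_cell,
        "sweeps": sweep_truth,
    }
    return SimulatedCohort(haplotypes, frame, truth)


def write_outputs(sim: SimulatedCohort, outdir) -> dict:
    """Write per-contig VCFs, the metadata TSV and the truth sidecar JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": {}, "metadata": str(outdir / "metadata.tsv")}
    for contig, hapset in sim.haplotypes.items():
        path = outdir / f"{contig}.vcf"
        write_vcf(path, hapset)
        paths["vcf"][contig] = str(path)
    sim.frame.table.to_csv(paths["metadata"], sep="\t", index=False)
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(sim.truth, fh, indent=2, sort_keys=True)
    paths["truth"] = str(truth_path)
    return paths
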