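"""Shared fixtures: small simulated cohorts and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from sweepscan import CohortFrame, DiplotypeSet, HaplotypeSet, PositionedVariants
from sweepscan.simulate import SimDesign, SweepConfig, simulate_cohorts


def make_variants(contig="2RL", positions=None, n=None):
    if positions is None:
        positions = np.arange(1, n + 1) * 10
    positions = np.asarray(positions, dtype=np.int64)
    return PositionedVariants(
        contig, positions, np.full(len(positions), "A"), np.full(len(positions), "T")
    )


def make_hapset(matrix, contig="2RL", positions=None):
    matrix = np.asarray(matrix, dtype=np.int8)
    variants = make_variants(contig, positions, n=matrix.shape[0])
    samples = tuple(f"S{i:03d}" for i in range(matrix.shape[1] // 2))
    return HaplotypeSet(variants, matrix, samples)


def make_diploset(matrix, contig="2RL", positions=None):
    matrix = np.asarray(matrix, dtype=np.int8)
    variants = make_variants(contig, positions, n=matrix.shape[0])
    samples = tuple(f"S{i:03d}" for i in range(matrix.shape[1]))
    return DiplotypeSet(variants, matrix, samples)


def make_frame(samples, region="East", round_="baseline", arm="PBO", household=None):
    n = len(samples)
    return CohortFrame(
        pd.DataFrame(
            {
                "sample_id": list(samples),
                "region": [region] * n,
                "round": [round_] * n,
                "arm": [arm] * n,
                "household": household or [f"H{i // 3}" for i in range(n)],
                "country": ["Uganda"] * n,
                "year": [2021] * n,
            }
        )
    )


@pytest.fixture(scope="session")
def small_sim():
    """One-contig cohort with a single hard sweep shifting 0.3 -> 0.6."""
    design = SimDesign(
        n_per_cell=20,
        contigs={"2RL": (4_000_000, 2_000)},
        regions=("East",),
        arms=("PBO",),
        d=0.0,
        sigma_h=0.0,
        sweeps=[
            SweepConfig(
                name="focal",
                contig="2RL",
                center=2_000_000,
                half_width=500_000,
                erosion_rate=0.1,
                freq_by_cohort={
                    ("baseline", "PBO"): 0.3,
                    ("round5", "PBO"): 0.6,
                },
            )
        ],
        seed=11,
    )
    return simulate_cohorts(design)


@pytest.fixture(scope="session")
def neutral_sim():
    """Panmictic neutral cohort: no sweeps, no structure, no households."""
    design = SimDesign(
        n_per_cell=15,
        contigs={"2RL": (4_000_000, 3_000)},
        d=0.0,
        sigma_h=0.0,
        sweeps=[],
        seed=7,
    )
    return simulate_cohorts(design)
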