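"""Per-SNP temporal association test with household clustering.

Each SNP's per-sample alternate-allele count (0-2 of 2 trials) is
modelled by a binomial GLM with logit link and survey round as the only
covariate; dependence of mosquitoes collected in the same household is
absorbed by a household-cluster-robust (sandwich) variance, and the
round effect is tested with a two-sided Wald test.  Benjamini-Hochberg
FDR is applied over all tested SNPs.

Only SNPs with no missing calls are tested, and monomorphic SNPs are
excluded (their round effect is undefined).  Under complete separation
(a round monomorphic while the other segregates) the Wald statistic is
unstable, so the p-value falls back to a likelihood-ratio test and the
row is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import MISSING, CohortFrame, DiplotypeSet


@dataclass(frozen=True)
class SnpTestRow:
    site: int
    position: int
    freq_pre: float
    freq_post: float
    effect: float  # log-odds of the post round on the alternate allele
    p_value: float
    separation: bool


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _fit_site(
    y: np.ndarray, x: np.ndarray, households: np.ndarray
) -> tuple[float, float, bool]:
    """(effect, p, separation_flag) for one site; y = alt counts of 2."""
    exog = sm.add_constant(x)
    endog = np.column_stack([y, 2 - y])
    fam = sm.families.Binomial()
    separated = (y[x == 0].sum() in (0, 2 * (x == 0).sum())) or (
        y[x == 1].sum() in (0, 2 * (x == 1).sum())
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, exog, family=fam)
        if separated:
            # Wald SE diverges under separation: use a likelihood-ratio test
            fit = model.fit(maxiter=25)
            null = sm.GLM(endog, exog[:, :1], family=fam).fit()
            lr = 2.0 * (fit.llf - null.llf)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            return float(fit.params[1]), p, True
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": households})
    return float(fit.params[1]), float(fit.pvalues[1]), False


def snp_round_test(
    diplo: DiplotypeSet,
    frame: CohortFrame,
    site: int,
    rounds: tuple[str, str] = ("baseline", "round5"),
    cluster_robust: bool = True,
) -> SnpTestRow:
    """Test one SNP for an allele-frequency change between two rounds."""
    frame.check_samples(diplo.samples)
    meta = frame.table.set_index("sample_id").loc[list(diplo.samples)]
    in_rounds = meta["round"].isin(rounds).to_numpy()
    g = diplo.matrix[site, in_rounds].astype(float)
    if (g == MISSING).any():
        raise ValueError(f"site {site} has missing calls; only complete sites are tested")
    x = (meta["round"].to_numpy()[in_rounds] == rounds[1]).astype(float)
    if x.sum() == 0 or x.sum() == x.size:
        raise ValueError("both rounds must be represented")
    alt = g.sum()
    if alt == 0 or alt == 2 * g.size:
        raise ValueError(f"site {site} is monomorphic; round effect undefined")
    households = meta["household"].to_numpy()[in_rounds]
    if not cluster_robust:
        households = np.arange(g.size)  # every sample its own cluster
    effect, p, separated = _fit_site(g, x, households)
    return SnpTestRow(
        site=site,
        position=int(diplo.variants.positions[site]),
        freq_pre=float(g[x == 0].sum() / (2 * (x == 0).sum())),
        freq_post=float(g[x == 1].sum() / (2 * (x == 1).sum())),
        effect=effect,
        p_value=p,
        separation=separated,
    )


def gwas_scan(
    diplo: DiplotypeSet,
    frame: CohortFrame,
    rounds: tuple[str, str] = ("baseline", "round5"),
    fdr_alpha: float = 0.05,
    cluster_robust: bool = True,
) -> pd.DataFrame:
    """Per-SNP round-association scan with BH-FDR over all tested sites.

    Tests every segregating site with no missing calls; returns one row
    per tested site with raw and adjusted p-values and a ``discovery``
    flag at adjusted p < ``fdr_alpha``.
    """
    frame.check_samples(diplo.samples)
    meta = frame.table.set_index("sample_id").loc[list(diplo.samples)]
    in_rounds = meta["round"].isin(rounds).to_numpy()
    x = (meta["round"].to_numpy()[in_rounds] == rounds[1]).astype(float)
    if x.sum() == 0 or x.sum() == x.size:
        raise ValueError("both rounds must be represented")
    households = meta["household"].to_numpy()[in_rounds]
    if not cluster_robust:
        households = np.arange(int(in_rounds.sum()))
    g_all = diplo.matrix[:, in_rounds]
    complete = (g_all != MISSING).all(axis=1)
    alt = g_all.sum(axis=1)
    segregating = (alt > 0) & (alt < 2 * g_all.shape[1])
    testable = np.flatnonzero(complete & segregating)

    rows = []
    for site in testable:
        g = g_all[site].astype(float)
        effect, p, separated = _fit_site(g, x, households)
        rows.append(
            {
                "site": int(site),
                "position": int(diplo.variants.positions[site]),
                "freq_pre": float(g[x == 0].sum() / (2 * (x == 0).sum())),
                "freq_post": float(g[x == 1].sum() / (2 * (x == 1).sum())),
                "effect": effect,
                "p_value": p,
                "separation": separated,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "site",
            "position",
            "freq_pre",
            "freq_post",
            "effect",
            "p_value",
            "separation",
        ],
    )
    table["p_adjusted"] = bh_fdr(table["p_value"].to_numpy()) if len(table) else []
    table["discovery"] = table["p_adjusted"] < fdr_alpha if len(table) else []
    return table
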