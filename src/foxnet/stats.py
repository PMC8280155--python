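"""Shared statistics: exact Mann-Whitney U and Pfaffl RT-qPCR quantification.

The Mann-Whitney test here is *exact* in the small-sample regime the
imaging and qPCR experiments live in (group sizes around 4-12): the null
distribution of the U statistic is obtained by exhaustively enumerating
all C(n+m, n) equally likely assignments of the pooled (mid)ranks to the
first group, which handles ties exactly. Above 25 pooled observations a
tie-corrected normal approximation takes over, flagged as such.

Pfaffl's method expresses a target transcript's relative abundance as
``E_target**dCt_target / E_ref**dCt_ref`` where E is the amplification
efficiency in fold-per-cycle (2.0 = perfect doubling) and dCt is the
control-minus-treated threshold-cycle difference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "MwuResult",
    "PfafflInput",
    "mwu_exact_two_tailed",
    "pfaffl_ratio",
    "pfaffl_from_table",
]

#: Pooled sample size up to which the exact enumeration branch is used.
EXACT_LIMIT = 25


@dataclass(frozen=True)
class MwuResult:
    """Two-tailed Mann-Whitney U result."""

    u_statistic: float
    p_two_tailed: float
    exact: bool

    def __post_init__(self) -> None:
        if not 0 < self.p_two_tailed <= 1:
            raise ValueError("p must lie in (0, 1]")


def _ranksum_distribution(doubled_ranks: Sequence[int], n: int
                          ) -> dict[int, int]:
    """Counts of size-``n`` subsets of the pooled ranks by (doubled) rank sum.

    Dynamic programming over the multiset of midranks; equivalent to full
    enumeration of all C(N, n) subsets but polynomial time. Ranks are
    doubled so tied midranks (k + 0.5) stay integral.
    """
    # table[j] maps doubled rank sum -> number of size-j subsets
    table: list[dict[int, int]] = [{0: 1}] + [dict() for _ in range(n)]
    for rank in doubled_ranks:
        for j in range(min(n, len(table) - 1), 0, -1):
            lower = table[j - 1]
            target = table[j]
            for total, count in lower.items():
                key = total + rank
                target[key] = target.get(key, 0) + count
    return table[n]


def mwu_exact_two_tailed(x: Sequence[float], y: Sequence[float],
                         two_tailed: str = "doubled") -> MwuResult:
    """Two-tailed Mann-Whitney U test, exact for small pooled samples.

    U is computed from midranks (ties earn 0.5 credit). For
    ``n + m <= 25`` the p-value is exact over all rank assignments; the
    default two-tailed rule doubles the smaller one-sided tail and caps
    at 1 (``two_tailed="doubled"``); ``"tail_sum"`` instead sums the
    probability of both tails at least as extreme as observed.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if two_tailed not in ("doubled", "tail_sum"):
        raise ValueError(f"unknown two_tailed rule {two_tailed!r}")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r_x = ranks[:n].sum()
    u_obs = r_x - n * (n + 1) / 2.0

    if n + m <= EXACT_LIMIT:
        doubled = np.rint(ranks * 2).astype(int)
        dist = _ranksum_distribution(doubled, n)
        total = math.comb(n + m, n)
        assert sum(dist.values()) == total
        # doubled U = doubled rank sum - n(n+1)
        offset = n * (n + 1)
        u2_obs = int(round(2 * u_obs))
        p_low = sum(c for s, c in dist.items() if s - offset <= u2_obs) / total
        p_high = sum(c for s, c in dist.items() if s - offset >= u2_obs) / total
        if two_tailed == "doubled":
            p = min(1.0, 2.0 * min(p_low, p_high))
        else:
            u2_mirror = 2 * n * m - u2_obs
            lo, hi = min(u2_obs, u2_mirror), max(u2_obs, u2_mirror)
            p = sum(
                c
                for s, c in dist.items()
                if s - offset <= lo or s - offset >= hi
            ) / total
            p = min(1.0, p)
        return MwuResult(float(u_obs), float(p), exact=True)

    # tie-corrected normal approximation with continuity correction
    big_n = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (big_n * (big_n - 1))
    sigma2 = n * m / 12.0 * (big_n + 1 - tie_term)
    mu = n * m / 2.0
    if sigma2 <= 0:  # all observations identical
        logger.info("constant pooled sample; p = 1.0")
        return MwuResult(float(u_obs), 1.0, exact=False)
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    p = max(p, np.finfo(float).tiny)
    return MwuResult(float(u_obs), float(p), exact=False)


# ---------------------------------------------------------------------------
# Pfaffl relative quantification


def _normalise_efficiency(e: float) -> float:
    """Accept efficiency as fold-per-cycle (1.95) or percent (95)."""
    if e > 3.0:  # percent scale
        logger.info("interpreting efficiency %.3g as percent", e)
        e = 1.0 + e / 100.0
    if not 1.0 < e <= 2.2:
        raise ValueError(
            f"amplification efficiency {e} outside (1, 2.2] fold-per-cycle"
        )
    return e


@dataclass(frozen=True)
class PfafflInput:
    """Inputs of the Pfaffl ratio for one target/reference pair.

    Efficiencies are fold-per-cycle in (1, 2.2]; percent values
    (e.g. 95 for 95%) are auto-converted. Delta-Ct values are
    control-minus-treated threshold cycles.
    """

    e_target: float
    delta_ct_target: float
    e_ref: float
    delta_ct_ref: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "e_target", _normalise_efficiency(self.e_target))
        object.__setattr__(self, "e_ref", _normalise_efficiency(self.e_ref))


def pfaffl_ratio(input: PfafflInput) -> float:
    """Efficiency-corrected expression ratio, always positive."""
    return (
        input.e_target**input.delta_ct_target
        / input.e_ref**input.delta_ct_ref
    )


def pfaffl_from_table(
    table: pd.DataFrame,
    target_gene: str,
    control_sample: str,
    treated_sample: str,
    reference_combination: str = "geometric_mean",
) -> float:
    """Pfaffl ratio from a long-format qPCR table.

    Expected columns ``sample, gene, ct, efficiency, is_reference``;
    replicate Ct rows are averaged. With several reference transcripts
    the per-reference ratios are combined by their geometric mean
    (``reference_combination="geometric_mean"``), or the references'
    mean delta-Ct can be used instead (``"mean_delta_ct"``).
    """
    required = {"sample", "gene", "ct", "efficiency", "is_reference"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"qPCR table lacks columns {sorted(missing)}")
    if reference_combination not in ("geometric_mean", "mean_delta_ct"):
        raise ValueError(
            f"unknown reference_combination {reference_combination!r}"
        )

    def mean_ct(gene: str, sample: str) -> float:
        rows = table[(table["gene"] == gene) & (table["sample"] == sample)]
        if rows.empty:
            raise ValueError(f"no Ct rows for gene {gene!r}, sample {sample!r}")
        return float(rows["ct"].mean())

    def efficiency(gene: str) -> float:
        values = table.loc[table["gene"] == gene, "efficiency"].unique()
        return _normalise_efficiency(float(values[0]))

    truthy = table["is_reference"].astype(str).str.lower().isin(
        ("1", "true", "yes")
    )
    references = sorted(table.loc[truthy, "gene"].unique())
    if not references:
        raise ValueError("qPCR table declares no reference transcript")
    if target_gene in references:
        raise ValueError(f"target {target_gene!r} is marked as a reference")

    d_ct_target = mean_ct(target_gene, control_sample) - mean_ct(
        target_gene, treated_sample
    )
    e_target = efficiency(target_gene)
    ratios = []
    d_cts = []
    for ref in references:
        d_ct_ref = mean_ct(ref, control_sample) - mean_ct(ref, treated_sample)
        d_cts.append(d_ct_ref)
        ratios.append(
            pfaffl_ratio(
                PfafflInput(e_target, d_ct_target, efficiency(ref), d_ct_ref)
            )
        )
    if reference_combination == "geometric_mean":
        return float(np.exp(np.mean(np.log(ratios))))
    mean_e_ref = float(np.mean([efficiency(r) for r in references]))
    return pfaffl_ratio(
        PfafflInput(e_target, d_ct_target, mean_e_ref, float(np.mean(d_cts)))
    )
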