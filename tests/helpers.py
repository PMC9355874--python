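"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: exact rational binomial
tail sums, brute-force BH step-up, naive greedy clumping, and closed-form
2x2 statistics.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd


def binom_lower_tail_exact(alt: int, depth: int, p0: Fraction) -> Fraction:
    """P(X <= alt) for X ~ Binomial(depth, p0) as an exact rational."""
    q0 = 1 - p0
    return sum(
        Fraction(comb(depth, k)) * p0 ** k * q0 ** (depth - k)
        for k in range(alt + 1)
    )


def bh_stepup_naive(pvals) -> np.ndarray:
    """Textbook Benjamini-Hochberg q-values: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


def greedy_clump_naive(rows: pd.DataFrame, r2: pd.DataFrame,
                       p_threshold: float, r2_threshold: float):
    """Reference greedy clumping: list of (lead_snp, member_snps) tuples."""
    elig = rows[rows["p_value"] < p_threshold]
    order = elig.sort_values(
        [c for c in ("p_value", "chrom", "bp", "snp_id") if c in elig.columns],
        kind="mergesort")["snp_id"].tolist()
    out = []
    remaining = list(order)
    while remaining:
        lead = remaining[0]
        members = [s for s in remaining
                   if float(r2.loc[lead, s]) >= r2_threshold or s == lead]
        out.append((lead, sorted(members)))
        remaining = [s for s in remaining if s not in set(members)]
    return out


def chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-squared statistic for a 2x2 table without correction."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def retained_pairs(result) -> set[tuple[str, str]]:
    return set(zip(result.retained["sample_id"], result.retained["variant_key"]))


def breakdown_instruments(theta: float, n: int, invalid_fraction: float,
                          alpha: float, seed: int) -> pd.DataFrame:
    """Harmonized instruments with directional pleiotropy in the oriented frame.

    Instruments are oriented so gamma > 0 (as harmonization leaves them up to
    allele labelling) with heterogeneous precision; the invalid subset carries
    a constant positive direct effect alpha on the outcome, pushing its Wald
    ratios above theta.  Invalid instruments are spread evenly across the
    weight ranking so that the valid subset keeps the majority of the
    inverse-variance weight — the premise under which the weighted median is
    consistent.
    """
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.05, 0.25, n)
    sigma_x = np.full(n, 0.003)
    sigma_y = rng.uniform(0.005, 0.03, n)
    n_invalid = round(invalid_fraction * n)
    weights = gamma ** 2 / sigma_y ** 2
    # pleiotropic instruments drawn from the weaker 70% of the weight ranking,
    # keeping a clear majority of inverse-variance weight valid
    pool = np.argsort(weights)[: int(0.7 * n)]
    invalid = np.zeros(n, dtype=bool)
    invalid[rng.permutation(pool)[:n_invalid]] = True
    Gamma = theta * gamma + np.where(invalid, alpha, 0.0) + rng.normal(0.0, sigma_y)
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(n)],
        "gamma": gamma + rng.normal(0.0, sigma_x),
        "sigma_x": sigma_x,
        "Gamma": Gamma,
        "sigma_y": sigma_y,
    })
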