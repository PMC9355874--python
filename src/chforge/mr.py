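"""Two-sample Mendelian randomization: harmonization and estimation.

Implements the standard summary-statistics toolkit used to appraise causal
risk factors: effect-allele harmonization between exposure and outcome GWAS
(allele swaps, strand flips, palindromic ambiguity resolved by allele
frequency), per-SNP Wald ratios, fixed-effect inverse-variance-weighted (IVW)
pooling (the primary estimator), MR-Egger regression with its pleiotropy
intercept, and the weighted-median estimator with a parametric bootstrap
standard error.  Instrument selection greedily LD-clumps significant rows.

Notation: γ_j (``gamma``) is the SNP-exposure effect with SE σ_xj, Γ_j
(``Gamma``) the SNP-outcome effect with SE σ_yj; the causal effect is the
slope relating Γ to γ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .errors import InsufficientInstrumentsError

__all__ = [
    "MREstimate",
    "harmonize",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "select_instruments",
    "mr_all_methods",
]

_Z95 = 1.959963984540054
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Effect-allele-frequency window inside which a palindromic SNP's strand
#: cannot be inferred from frequency and the SNP is dropped.
AMBIGUITY_WINDOW = (0.42, 0.58)


@dataclass
class MREstimate:
    """A causal-effect estimate from one MR method."""

    method: str
    beta: float
    se: float
    p_value: float
    ci_low: float
    ci_high: float
    n_snps: int
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snps: int,
                     **kw) -> "MREstimate":
        beta, se = float(beta), float(se)
        p = 2.0 * float(norm.sf(abs(beta) / se)) if se > 0 else float("nan")
        return cls(method=method, beta=beta, se=se, p_value=p,
                   ci_low=beta - _Z95 * se, ci_high=beta + _Z95 * se,
                   n_snps=n_snps, **kw)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindrome_policy: str = "infer",
              ambiguity_window: tuple[float, float] = AMBIGUITY_WINDOW,
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align outcome effects to the exposure effect allele.

    Input tables need columns ``snp, effect_allele, other_allele, eaf, beta,
    se``.  Swapped outcome alleles flip the sign of Γ and complement the
    frequency; strand flips are resolved by base complement; palindromic
    (A/T, G/C) SNPs are resolved by comparing allele frequencies when both
    lie outside the ambiguity window (``palindrome_policy='infer'``) and
    dropped otherwise (or always, with ``palindrome_policy='drop'``).

    Returns ``(instruments, drop_log)`` where instruments has columns
    ``snp, gamma, sigma_x, Gamma, sigma_y, eaf`` and the drop log records one
    ``(snp, reason)`` row per excluded SNP.
    """
    if palindrome_policy not in ("infer", "drop"):
        raise ValueError("palindrome_policy must be 'infer' or 'drop'")
    lo, hi = ambiguity_window
    merged = exposure.merge(outcome, on="snp", suffixes=("_x", "_y"))
    kept, drops = [], []
    for r in merged.itertuples():
        ea_x = str(r.effect_allele_x).upper()
        oa_x = str(r.other_allele_x).upper()
        ea_y = str(r.effect_allele_y).upper()
        oa_y = str(r.other_allele_y).upper()
        if not ea_x or not oa_x or not ea_y or not oa_y or "NAN" in (ea_x, oa_x, ea_y, oa_y):
            drops.append((r.snp, "missing_alleles"))
            continue
        Gamma, eaf_y = float(r.beta_y), float(r.eaf_y)

        if _is_palindromic(ea_x, oa_x):
            if palindrome_policy == "drop":
                drops.append((r.snp, "palindrome_dropped"))
                continue
            if {ea_y, oa_y} != {ea_x, oa_x}:
                drops.append((r.snp, "allele_mismatch"))
                continue
            if (ea_y, oa_y) == (oa_x, ea_x):       # label swap first
                Gamma, eaf_y = -Gamma, 1.0 - eaf_y
            eaf_x = float(r.eaf_x)
            if (lo <= eaf_x <= hi) or (lo <= eaf_y <= hi):
                drops.append((r.snp, "palindrome_ambiguous"))
                continue
            if (eaf_x < 0.5) != (eaf_y < 0.5):     # opposite strand reported
                Gamma, eaf_y = -Gamma, 1.0 - eaf_y
        else:
            if (ea_y, oa_y) == (ea_x, oa_x):
                pass
            elif (ea_y, oa_y) == (oa_x, ea_x):
                Gamma, eaf_y = -Gamma, 1.0 - eaf_y
            else:
                ea_c = _COMPLEMENT.get(ea_y, "?")
                oa_c = _COMPLEMENT.get(oa_y, "?")
                if (ea_c, oa_c) == (ea_x, oa_x):
                    pass
                elif (ea_c, oa_c) == (oa_x, ea_x):
                    Gamma, eaf_y = -Gamma, 1.0 - eaf_y
                else:
                    drops.append((r.snp, "allele_mismatch"))
                    continue
        kept.append((r.snp, float(r.beta_x), float(r.se_x), Gamma,
                     float(r.se_y), eaf_y))
    instruments = pd.DataFrame(
        kept, columns=["snp", "gamma", "sigma_x", "Gamma", "sigma_y", "eaf"])
    drop_log = pd.DataFrame(drops, columns=["snp", "reason"])
    return instruments, drop_log


def wald_ratio(inst, second_order_se: bool = False) -> MREstimate:
    """Single-instrument causal estimate Γ/γ.

    The first-order standard error is σ_y/|γ|; the second-order (delta
    method) option adds the γ-uncertainty term Γ²σ_x²/γ⁴.
    """
    gamma = float(inst["gamma"]) if not np.isscalar(inst) else inst
    Gamma = float(inst["Gamma"])
    sigma_y = float(inst["sigma_y"])
    if gamma == 0:
        raise ZeroDivisionError("Wald ratio undefined for gamma = 0")
    beta = Gamma / gamma
    se = sigma_y / abs(gamma)
    if second_order_se:
        sigma_x = float(inst["sigma_x"])
        se = np.sqrt(sigma_y ** 2 / gamma ** 2
                     + Gamma ** 2 * sigma_x ** 2 / gamma ** 4)
    return MREstimate.from_beta_se("wald", beta, se, 1)


def _as_arrays(instruments: pd.DataFrame):
    g = instruments["gamma"].to_numpy(dtype=float)
    G = instruments["Gamma"].to_numpy(dtype=float)
    sy = instruments["sigma_y"].to_numpy(dtype=float)
    return g, G, sy


def ivw(instruments: pd.DataFrame, random_effects: bool = False,
        min_snps_random: int = 3) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    β̂ = Σ γΓ/σ_y² / Σ γ²/σ_y², identical to σ_y⁻²-weighted least squares
    through the origin.  With ``random_effects=True`` the standard error is
    inflated multiplicatively by √(Q/(m−1)) when the heterogeneity exceeds 1
    and at least ``min_snps_random`` instruments are available.
    """
    if len(instruments) == 0:
        raise InsufficientInstrumentsError("IVW requires >= 1 instrument")
    g, G, sy = _as_arrays(instruments)
    w = 1.0 / sy ** 2
    denom = np.sum(w * g ** 2)
    beta = np.sum(w * g * G) / denom
    se = np.sqrt(1.0 / denom)
    m = len(g)
    if random_effects and m >= min_snps_random:
        q = float(np.sum(w * (G - beta * g) ** 2))
        phi = q / (m - 1)
        if phi > 1.0:
            se *= np.sqrt(phi)
    return MREstimate.from_beta_se("ivw", beta, se, m)


def mr_egger(instruments: pd.DataFrame) -> MREstimate:
    """MR-Egger weighted regression Γ = β₀ + β·γ with weights σ_y⁻².

    Instruments are first oriented so γ > 0 (flipping Γ accordingly).  The
    slope estimates the causal effect; the intercept the average directional
    pleiotropy.  Standard errors use a multiplicative random-effects scale
    floored at 1.
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError("MR-Egger requires >= 3 instruments")
    g, G, sy = _as_arrays(instruments)
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    X = sm.add_constant(g)
    w = 1.0 / sy ** 2
    fit = sm.WLS(G, X, weights=w).fit()
    # fixed (unit-scale) SEs from (X'WX)^-1, inflated by the residual scale
    # when it exceeds 1 (multiplicative random effects, floored at 1)
    xtwx_inv = np.linalg.inv(X.T @ (X * w[:, None]))
    scale_mult = max(1.0, float(np.sqrt(fit.scale)))
    se_int, se_slope = np.sqrt(np.diag(xtwx_inv)) * scale_mult
    b0, b1 = fit.params
    est = MREstimate.from_beta_se("egger", b1, se_slope, len(g))
    est.egger_intercept = float(b0)
    est.intercept_se = float(se_int)
    est.intercept_p = 2.0 * float(norm.sf(abs(b0) / se_int)) if se_int > 0 else float("nan")
    return est


def weighted_median(instruments: pd.DataFrame, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted-median estimate (consistent when >=50% of weight is valid).

    Wald ratios are ordered; the estimate interpolates the ratio at which the
    standardized cumulative inverse-variance weight crosses one half.  The
    standard error comes from a parametric bootstrap that redraws γ̂ and Γ̂
    from their reported sampling distributions.
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError("weighted median requires >= 3 instruments")
    g, G, sy = _as_arrays(instruments)
    sx = instruments["sigma_x"].to_numpy(dtype=float)

    def _wm(gv, Gv) -> float:
        ratio = Gv / gv
        w = gv ** 2 / sy ** 2
        order = np.argsort(ratio)
        ratio, wo = ratio[order], w[order]
        wo = wo / wo.sum()
        s = np.cumsum(wo) - wo / 2.0
        return float(np.interp(0.5, s, ratio))

    beta = _wm(g, G)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _wm(g + rng.normal(0.0, sx), G + rng.normal(0.0, sy))
    se = float(np.std(boots, ddof=1))
    return MREstimate.from_beta_se("weighted_median", beta, se, len(g))


def select_instruments(sumstats: pd.DataFrame, p_threshold: float,
                       ld: "pd.DataFrame", r2_threshold: float = 0.001,
                       ) -> pd.DataFrame:
    """Significant, LD-independent rows to serve as genetic instruments.

    Rows with ``p_value`` below ``p_threshold`` are greedily clumped at
    ``r2 < r2_threshold`` (delegating to :func:`chforge.gwas.ld_clump`);
    the clump leads are returned.  An empty result triggers a warning.
    """
    import warnings

    from .gwas import ld_clump

    loci = ld_clump(sumstats, ld, p_threshold=p_threshold,
                    r2_threshold=r2_threshold)
    if not loci:
        warnings.warn("no variants pass the instrument p-value threshold",
                      stacklevel=2)
        return sumstats.iloc[0:0]
    leads = pd.DataFrame([lc.lead for lc in loci])
    return leads.reset_index(drop=True)


def mr_all_methods(instruments: pd.DataFrame, n_boot: int = 1000,
                   seed: int = 0) -> list[MREstimate]:
    """IVW (primary), MR-Egger and weighted median on one instrument set.

    Falls back to a single Wald ratio when only one instrument survives.
    """
    if len(instruments) == 0:
        raise InsufficientInstrumentsError("no instruments")
    if len(instruments) == 1:
        return [wald_ratio(instruments.iloc[0])]
    out = [ivw(instruments)]
    if len(instruments) >= 3:
        out.append(mr_egger(instruments))
        out.append(weighted_median(instruments, n_boot=n_boot, seed=seed))
    return out
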