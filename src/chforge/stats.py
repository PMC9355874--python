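"""Cohort characterization and prevalent-trait association for CH callsets.

Covers prevalence tables with exact binomial confidence intervals, empirical
cumulative distributions of carrier age, per-gene age-shift tests (two-sided
Wilcoxon rank-sum against a reference gene), female:male carrier ratios with
a 2x2 chi-squared test against non-CH controls, per-gene VAF summaries, and
logistic prevalent-trait models with Benjamini-Hochberg FDR across a family
of tests.

Model conventions follow the source study: logistic regression with CH (or a
CH subtype) as outcome; age, sex, smoking status, sequencing batch and ten
principal components as the standard covariate set; blood-count/biochemistry
predictors log10-transformed; non-convergence reported as a status rather
than raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency, mannwhitneyu
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .errors import ChforgeError

__all__ = [
    "AssociationResult",
    "prevalence_table",
    "age_ecdf",
    "age_shift_tests",
    "sex_ratio_test",
    "vaf_summary",
    "prevalent_assoc",
    "bh_fdr",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "sex", "smoking", "batch",
                      *(f"pc{i}" for i in range(1, 11)))

#: Wilcoxon group-size bound for exact enumeration (normal approx. above).
_EXACT_WILCOXON_MAX_N = 25


@dataclass
class AssociationResult:
    """One fitted trait-CH association."""

    trait: str
    subgroup: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_cases: int
    n_controls: int
    status: str = "ok"            # ok | failed (separation / non-convergence)
    q_value: float | None = None
    #: log-odds coefficient scale of the OR (per unit, or per log10 unit).
    per_unit: str = "unit"


def _merged(callset: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.DataFrame:
    return phenotypes.merge(callset[["sample_id", "ch_status", "genes",
                                     "max_vaf", "clone_class"]],
                            on="sample_id", how="left")


def prevalence_table(callset: pd.DataFrame, phenotypes: pd.DataFrame,
                     age_bins: list[tuple[int, int]] | None = None,
                     strata: str | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Carrier prevalence per age bin (and optional stratum) with exact CIs.

    Prevalence is carriers/participants per cell; confidence intervals are
    Clopper-Pearson.  Empty cells are reported with NaN prevalence (not zero).
    """
    df = _merged(callset, phenotypes)
    df["ch_status"] = df["ch_status"].eq(True)
    if age_bins is None:
        lo, hi = int(df["age"].min()), int(df["age"].max())
        edges = list(range(lo - lo % 5, hi + 6, 5))
        age_bins = [(a, b - 1) for a, b in zip(edges[:-1], edges[1:])]
    groups = df.groupby(strata) if strata else [("all", df)]
    rows = []
    for stratum, sub in groups:
        for lo, hi in age_bins:
            cell = sub[(sub["age"] >= lo) & (sub["age"] <= hi)]
            n, k = len(cell), int(cell["ch_status"].sum())
            if n == 0:
                rows.append((stratum, lo, hi, 0, 0, np.nan, np.nan, np.nan))
                continue
            lo_ci, hi_ci = proportion_confint(k, n, alpha=alpha, method="beta")
            rows.append((stratum, lo, hi, n, k, k / n, lo_ci, hi_ci))
    return pd.DataFrame(rows, columns=["stratum", "age_lo", "age_hi", "n",
                                       "carriers", "prevalence", "ci_low",
                                       "ci_high"])


def _gene_carrier_mask(df: pd.DataFrame, gene: str) -> pd.Series:
    genes = df["genes"].fillna("")
    return genes.str.split(",").apply(lambda gs: gene in gs)


def age_ecdf(callset: pd.DataFrame, phenotypes: pd.DataFrame,
             genes: list[str] | None = None) -> pd.DataFrame:
    """Empirical cumulative distribution of carrier age, overall and per gene."""
    df = _merged(callset, phenotypes)
    df["ch_status"] = df["ch_status"].eq(True)
    out = []

    def _ecdf(label: str, ages: np.ndarray) -> None:
        ages = np.sort(ages)
        if len(ages) == 0:
            return
        cdf = np.arange(1, len(ages) + 1) / len(ages)
        out.append(pd.DataFrame({"group": label, "age": ages, "ecdf": cdf}))

    _ecdf("overall", df.loc[df["ch_status"], "age"].to_numpy())
    if genes is None:
        genes = sorted({g for gs in df["genes"].dropna() for g in gs.split(",") if g})
    for gene in genes:
        _ecdf(gene, df.loc[_gene_carrier_mask(df, gene), "age"].to_numpy())
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["group", "age", "ecdf"])


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have <= 25 observations and no ties;
    otherwise the tie- and continuity-corrected normal approximation (the two
    branches agree to ~5x10⁻³ around the switch point).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    exact = no_ties and len(x) <= _EXACT_WILCOXON_MAX_N and len(y) <= _EXACT_WILCOXON_MAX_N
    method = "exact" if exact else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def age_shift_tests(callset: pd.DataFrame, phenotypes: pd.DataFrame,
                    reference_gene: str = "DNMT3A",
                    genes: list[str] | None = None) -> pd.DataFrame:
    """Median carrier-age shift of each gene relative to a reference gene.

    The shift is the difference in median carrier age (gene minus reference);
    the p-value is a two-sided Wilcoxon rank-sum test.  Genes without
    carriers are excluded with a warning.
    """
    df = _merged(callset, phenotypes)
    ref_ages = df.loc[_gene_carrier_mask(df, reference_gene), "age"].to_numpy()
    if len(ref_ages) == 0:
        raise ChforgeError(f"reference gene {reference_gene!r} has no carriers")
    if genes is None:
        genes = sorted({g for gs in df["genes"].dropna() for g in gs.split(",")
                        if g and g != reference_gene})
    rows = []
    for gene in genes:
        ages = df.loc[_gene_carrier_mask(df, gene), "age"].to_numpy()
        if len(ages) == 0:
            warnings.warn(f"gene {gene} has no carriers; excluded", stacklevel=2)
            continue
        shift = float(np.median(ages) - np.median(ref_ages))
        rows.append((gene, len(ages), shift, wilcoxon_rank_sum(ages, ref_ages)))
    return pd.DataFrame(rows, columns=["gene", "n_carriers", "median_age_shift",
                                       "p_value"])


def sex_ratio_test(callset: pd.DataFrame, phenotypes: pd.DataFrame,
                   gene: str | None = None,
                   yates_correction: bool = False) -> dict:
    """Female:male carrier ratio vs non-CH controls, 2x2 chi-squared (1 df).

    ``gene=None`` compares all CH carriers with controls.  A zero male
    carrier count yields an infinite ratio; the test is still computed from
    the contingency table.
    """
    df = _merged(callset, phenotypes)
    df["ch_status"] = df["ch_status"].eq(True)
    carrier = _gene_carrier_mask(df, gene) if gene else df["ch_status"]
    control = ~df["ch_status"]
    f_car = int(((df["sex"] == "female") & carrier).sum())
    m_car = int(((df["sex"] == "male") & carrier).sum())
    f_ctl = int(((df["sex"] == "female") & control).sum())
    m_ctl = int(((df["sex"] == "male") & control).sum())
    table = np.array([[f_car, m_car], [f_ctl, m_ctl]])
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        chi2, p = np.nan, np.nan
    else:
        chi2, p, _, _ = chi2_contingency(table, correction=yates_correction)
    return {
        "gene": gene or "overall",
        "f_carriers": f_car, "m_carriers": m_car,
        "ratio": f_car / m_car if m_car else float("inf"),
        "control_ratio": f_ctl / m_ctl if m_ctl else float("inf"),
        "chi2": float(chi2), "p_value": float(p),
    }


def vaf_summary(mutations: pd.DataFrame) -> pd.DataFrame:
    """Per-gene median, mean and sd of VAF over retained mutations.

    The sd is NaN for singleton genes (flagged by ``n == 1``).
    """
    g = mutations.groupby("gene")["vaf"]
    out = pd.DataFrame({
        "n": g.size(),
        "median_vaf": g.median(),
        "mean_vaf": g.mean(),
        "sd_vaf": g.std(ddof=1),
    }).reset_index()
    return out.sort_values("n", ascending=False, kind="mergesort").reset_index(drop=True)


_CATEGORICAL = ("sex", "smoking", "batch", "centre")


def _design(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for col in columns:
        if col in _CATEGORICAL or df[col].dtype == object:
            dummies = pd.get_dummies(df[col], prefix=col, drop_first=True)
            X = pd.concat([X, dummies.astype(float)], axis=1)
        else:
            X[col] = pd.to_numeric(df[col])
    return X


def _outcome_vector(df: pd.DataFrame, subgroup: str) -> pd.Series:
    """CH outcome for a subgroup: 'overall', a gene symbol, 'large' or 'small'."""
    ch = df["ch_status"].eq(True)
    if subgroup == "overall":
        return ch
    if subgroup in ("large", "small"):
        is_sub = df["clone_class"].eq(subgroup) & ch
    else:
        is_sub = _gene_carrier_mask(df, subgroup) & ch
    keep = is_sub | ~ch            # carriers of other subtypes excluded
    return is_sub.where(keep)


def prevalent_assoc(callset: pd.DataFrame, phenotypes: pd.DataFrame,
                    trait: str,
                    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                    transform: str | None = None,
                    subgroup: str = "overall",
                    min_complete: int = 50) -> AssociationResult:
    """Logistic model of CH status on one trait plus covariates.

    ``transform='log10'`` models the trait per log10 unit (the convention for
    blood counts and biochemistry).  Subgroup outcomes compare carriers of
    that subtype against non-CH controls.  Separation or non-convergence is
    reported via ``status='failed'`` with NaN estimates, never raised.
    """
    df = _merged(callset, phenotypes)
    y = _outcome_vector(df, subgroup)
    covariates = tuple(c for c in covariates if c != trait and c in df.columns)
    use = df[[trait, *covariates]].copy()
    if transform == "log10":
        vals = pd.to_numeric(use[trait])
        vals = vals.where(vals > 0)
        use[trait] = np.log10(vals)
    keep = use.notna().all(axis=1) & y.notna()
    use, y = use[keep], y[keep].astype(float)
    if len(use) < min_complete:
        raise ChforgeError(
            f"only {len(use)} complete cases for trait {trait!r} "
            f"(minimum {min_complete})")

    X = sm.add_constant(_design(use, [trait, *covariates]), has_constant="add")
    trait_col = trait
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    per_unit = "log10_unit" if transform == "log10" else "unit"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y.to_numpy(), X.to_numpy(dtype=float)).fit(
                disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False):
            raise RuntimeError("no convergence")
        j = list(X.columns).index(trait_col)
        beta, se = fit.params[j], fit.bse[j]
        if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
            raise RuntimeError("degenerate fit")
        return AssociationResult(
            trait=trait, subgroup=subgroup,
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.959963984540054 * se)),
            ci_high=float(np.exp(beta + 1.959963984540054 * se)),
            p_value=float(fit.pvalues[j]),
            n_cases=n_cases, n_controls=n_controls, per_unit=per_unit)
    except Exception:
        return AssociationResult(
            trait=trait, subgroup=subgroup, odds_ratio=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"), p_value=float("nan"),
            n_cases=n_cases, n_controls=n_controls, status="failed",
            per_unit=per_unit)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one family of tests."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ChforgeError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def attach_fdr(results: list[AssociationResult]) -> list[AssociationResult]:
    """Attach BH q-values to one family of association results in place."""
    ok = [r for r in results if r.status == "ok" and np.isfinite(r.p_value)]
    if ok:
        qs = bh_fdr([r.p_value for r in ok])
        for r, q in zip(ok, qs):
            r.q_value = float(q)
    return results


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Tidy one-row-per-test table (trait, subgroup, OR, CI, p, q, n)."""
    return pd.DataFrame([{
        "trait": r.trait, "subgroup": r.subgroup, "odds_ratio": r.odds_ratio,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "p_value": r.p_value,
        "q_value": r.q_value, "n_cases": r.n_cases, "n_controls": r.n_controls,
        "status": r.status, "per_unit": r.per_unit,
    } for r in results])
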