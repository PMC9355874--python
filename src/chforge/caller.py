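"""CH driver-mutation filtering and per-individual call assembly.

Somatic variant calls from a tumor-only caller are noisy: they mix true
clonal-hematopoiesis drivers with germline heterozygous variants that escaped
the population filter and with sequencing artifacts.  This module implements
a multi-stage decision procedure that separates them using read support,
population allele frequency, cohort recurrence, curated driver evidence
(hotspots, COSMIC hematological counts, consequence whitelists) and an exact
binomial test against the germline expectation (alt fraction 0.5 for diploid
sites, 0.95 for copy-number-one sites), then assembles per-individual CH
status with gene subtypes and a large/small clone-size class at VAF 0.1.

Stage order::

    basic_qc -> candidate_selection -> novel_variant_gate -> driver_evidence
             -> germline_rescue -> cohort_exclusions -> assemble_callset

Each stage emits one :class:`FilterDecision` row per record it examines, so
``|kept| + |dropped|`` equals the stage's input size and every dropped record
carries exactly one terminal reason code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import binom

from .errors import MalformedRecordError
from .resources import DriverResource

__all__ = [
    "FilterConfig",
    "FilterResult",
    "binomial_germline_pvalue",
    "basic_qc",
    "candidate_selection",
    "novel_variant_gate",
    "driver_evidence",
    "germline_rescue",
    "cohort_exclusions",
    "assemble_callset",
    "run_filter_chain",
]

_LOF = frozenset({"frameshift", "nonsense", "splice_site"})

STAGES = ("qc", "candidate", "novel_gate", "driver_evidence",
          "germline_rescue", "cohort_exclusion", "lof_exclusion")


@dataclass
class FilterConfig:
    """Thresholds of the filtering procedure (defaults are the study values)."""

    min_alt_reads: int = 2
    require_both_strands: bool = True
    min_depth_snv: int = 7
    min_depth_indel: int = 10
    max_pop_maf: float = 1e-3
    novel_max_pop_maf: float = 5e-5
    novel_min_cohort_count: int = 4
    min_cosmic_heme: int = 7
    binom_alpha: float = 1e-3
    binom_null_diploid: float = 0.5
    binom_null_cn1: float = 0.95
    exclusion_maf: float = 5e-5
    exclusion_mean_vaf: float = 0.2
    exclusion_max_vaf: float = 0.1
    germline_min_pass_elsewhere: int = 2
    large_clone_vaf: float = 0.1
    #: Default parse of the cohort VAF-profile exclusion:
    #: MAF>=exclusion_maf AND (mean VAF > 0.2 OR max VAF < 0.1).  When False
    #: the population-frequency clause gates only the mean-VAF arm:
    #: (MAF>=exclusion_maf AND mean VAF > 0.2) OR max VAF < 0.1.
    rule_a_maf_gates_both: bool = True


@dataclass
class FilterResult:
    """Output bundle of :func:`run_filter_chain`."""

    retained: pd.DataFrame
    decisions: pd.DataFrame
    callset: pd.DataFrame
    mutations: pd.DataFrame
    stage_counts: dict[str, tuple[int, int]] = field(default_factory=dict)


def binomial_germline_pvalue(alt_depth, depth, copy_number=2,
                             cfg: FilterConfig | None = None):
    """Lower-tail exact binomial probability of the observed alt support.

    Tests the germline null that the alt fraction equals the heterozygous
    expectation (0.5 diploid, 0.95 at copy number one): small p means the alt
    count is too low for a germline variant, i.e. consistent with a somatic
    clone.  Accepts scalars or arrays; returns p in (0, 1].
    """
    cfg = cfg or FilterConfig()
    alt = np.asarray(alt_depth)
    dp = np.asarray(depth)
    if np.any(dp < 1):
        raise MalformedRecordError("depth must be >= 1 for the binomial test")
    if np.any((alt < 0) | (alt > dp)):
        raise MalformedRecordError("alt_depth must lie in [0, depth]")
    p0 = np.where(np.asarray(copy_number) == 1,
                  cfg.binom_null_cn1, cfg.binom_null_diploid)
    # floor at the smallest positive normal float: the true tail probability
    # is always > 0, but can underflow at extreme depths
    p = np.maximum(binom.cdf(alt, dp, p0), np.finfo(float).tiny)
    return float(p) if p.ndim == 0 else p


def _decisions(calls: pd.DataFrame, kept: pd.Series, stage: str,
               reason: pd.Series) -> pd.DataFrame:
    out = pd.DataFrame({
        "sample_id": calls["sample_id"].to_numpy(),
        "variant_key": calls["variant_key"].to_numpy(),
        "stage": stage,
        "kept": kept.to_numpy(dtype=bool),
        "reason": np.where(kept.to_numpy(dtype=bool), "ok",
                           reason.to_numpy(dtype=object)),
    })
    return out


# ------------------------------------------------------------------ stages

def basic_qc(calls: pd.DataFrame, cfg: FilterConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read-support and population-frequency screen (per record).

    Keeps a record iff alt reads >= ``min_alt_reads`` on both strands, depth
    meets the class-specific minimum (SNV vs indel/substitution) and the
    population MAF is below ``max_pop_maf``.
    """
    if (calls["depth"] <= 0).any():
        raise MalformedRecordError("record with depth <= 0")
    min_depth = np.where(calls["var_class"].eq("SNV"),
                         cfg.min_depth_snv, cfg.min_depth_indel)
    ok_alt = calls["alt_depth"] >= cfg.min_alt_reads
    if cfg.require_both_strands:
        ok_strand = (calls["alt_fwd"] >= 1) & (calls["alt_rev"] >= 1)
    else:
        ok_strand = pd.Series(True, index=calls.index)
    ok_depth = calls["depth"] >= min_depth
    ok_maf = calls["pop_maf"] < cfg.max_pop_maf
    kept = ok_alt & ok_strand & ok_depth & ok_maf
    reason = pd.Series("ok", index=calls.index, dtype=object)
    reason[~ok_maf] = "pop_maf"
    reason[~ok_depth] = "depth"
    reason[~ok_strand] = "strand"
    reason[~ok_alt] = "alt_reads"
    dec = _decisions(calls, kept, "qc", reason)
    return calls[kept], dec


def candidate_selection(calls: pd.DataFrame, cfg: FilterConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select PASS calls and germline-flagged calls recurrently PASS elsewhere.

    A germline-flagged call is a candidate only when the same variant carries
    the PASS flag in at least ``germline_min_pass_elsewhere`` other samples;
    calls with any other caller filter are never candidates.
    """
    n_pass = (calls["caller_filter"].eq("PASS")
              .groupby(calls["variant_key"]).transform("sum"))
    is_pass = calls["caller_filter"].eq("PASS")
    is_germ = calls["caller_filter"].eq("germline")
    kept = is_pass | (is_germ & (n_pass >= cfg.germline_min_pass_elsewhere))
    reason = pd.Series("ok", index=calls.index, dtype=object)
    reason[is_germ & ~kept] = "germline_unsupported"
    reason[~is_pass & ~is_germ] = "caller_filter_other"
    dec = _decisions(calls, kept, "candidate", reason)
    return calls[kept], dec


def novel_variant_gate(calls: pd.DataFrame, cfg: FilterConfig,
                       cohort_counts: pd.Series | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recurrence gate for variants absent from COSMIC and dbSNP.

    Novel variants must be carried by at least ``novel_min_cohort_count``
    samples (counted after QC) and have population MAF below
    ``novel_max_pop_maf``; known variants pass through untouched.
    """
    if cohort_counts is None:
        cohort_counts = calls.groupby("variant_key")["sample_id"].nunique()
    counts = calls["variant_key"].map(cohort_counts).fillna(0).astype(int)
    known = calls["is_known"].astype(bool)
    ok_count = counts >= cfg.novel_min_cohort_count
    ok_maf = calls["pop_maf"] < cfg.novel_max_pop_maf
    kept = known | (ok_count & ok_maf)
    reason = pd.Series("ok", index=calls.index, dtype=object)
    reason[~known & ~ok_maf] = "novel_pop_maf"
    reason[~known & ~ok_count] = "novel_low_cohort_count"
    dec = _decisions(calls, kept, "novel_gate", reason)
    return calls[kept], dec


def driver_evidence(calls: pd.DataFrame, res: DriverResource,
                    cfg: FilterConfig) -> pd.Series:
    """Evidence class per record: ``hotspot`` | ``cosmic`` | ``whitelist`` | ``none``.

    COSMIC evidence uses the larger of the resource count and the record's
    own annotation, so annotated tables work without a cosmic TSV.
    """
    panel_genes = {g for g, *_ in res.whitelist_rules}
    unknown = set()
    out = []
    for rec in calls.itertuples():
        key = rec.variant_key
        if res.is_hotspot(key):
            out.append("hotspot")
            continue
        if max(res.cosmic_count(key), int(rec.cosmic_heme_count)) >= cfg.min_cosmic_heme:
            out.append("cosmic")
            continue
        gene = str(rec.gene).upper()
        if panel_genes and gene not in panel_genes:
            unknown.add(gene)
            out.append("none")
            continue
        if res.whitelist_match(gene, rec.consequence, int(rec.pos)):
            out.append("whitelist")
        else:
            out.append("none")
    if unknown:
        warnings.warn(f"gene symbols absent from driver resources: {sorted(unknown)}",
                      stacklevel=2)
    return pd.Series(out, index=calls.index, dtype=object)


def _driver_evidence_stage(calls: pd.DataFrame, res: DriverResource,
                           cfg: FilterConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    ev = driver_evidence(calls, res, cfg)
    kept = ev.ne("none")
    reason = pd.Series("no_driver_evidence", index=calls.index, dtype=object)
    dec = _decisions(calls, kept, "driver_evidence", reason)
    return calls[kept].assign(evidence=ev[kept]), dec


def germline_rescue(calls: pd.DataFrame, cfg: FilterConfig,
                    res: DriverResource) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decide whether germline-flagged calls of each variant are somatic.

    Hotspot variants are always included.  Otherwise germline-flagged calls
    survive only when the variant is flagged germline in fewer samples than
    it is flagged PASS, and at least one call of the variant rejects the
    germline binomial null at ``binom_alpha``.  PASS calls are untouched.
    """
    p = binomial_germline_pvalue(calls["alt_depth"].to_numpy(),
                                 calls["depth"].to_numpy(),
                                 calls["copy_number"].to_numpy(), cfg)
    pser = pd.Series(np.atleast_1d(p), index=calls.index)
    n_germ = calls["caller_filter"].eq("germline").groupby(calls["variant_key"]).transform("sum")
    n_pass = calls["caller_filter"].eq("PASS").groupby(calls["variant_key"]).transform("sum")
    any_sig = pser.lt(cfg.binom_alpha).groupby(calls["variant_key"]).transform("any")
    is_germ = calls["caller_filter"].eq("germline")
    is_hot = calls["variant_key"].map(res.is_hotspot)
    kept = ~is_germ | is_hot | ((n_germ < n_pass) & any_sig)
    reason = pd.Series("germline_rescue_failed", index=calls.index, dtype=object)
    dec = _decisions(calls, kept, "germline_rescue", reason)
    return calls[kept], dec


def cohort_exclusions(calls: pd.DataFrame, cfg: FilterConfig,
                      res: DriverResource) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort-level VAF-profile and loss-of-function exclusions.

    Both rules apply only to variants absent from COSMIC and the hotspot
    list.  The VAF-profile rule drops variants whose population MAF reaches
    ``exclusion_maf`` and whose carrier VAFs look germline-like (mean > 0.2)
    or noise-like (max < 0.1).  The LoF rule additionally requires at least
    one carrier of a truncating variant to reject the germline binomial null.
    """
    if calls.empty:
        empty = pd.DataFrame(columns=["sample_id", "variant_key", "stage",
                                      "kept", "reason"])
        return calls, empty

    p = binomial_germline_pvalue(calls["alt_depth"].to_numpy(),
                                 calls["depth"].to_numpy(),
                                 calls["copy_number"].to_numpy(), cfg)
    pser = pd.Series(np.atleast_1d(p), index=calls.index)

    g = calls.groupby("variant_key")
    stats = pd.DataFrame({
        "mean_vaf": g["vaf"].mean(),
        "max_vaf": g["vaf"].max(),
        "pop_maf": g["pop_maf"].max(),
        "cosmic_rec": g["cosmic_heme_count"].max(),
        "consequence": g["consequence"].first(),
        "any_sig": pser.lt(cfg.binom_alpha).groupby(calls["variant_key"]).any(),
    })
    stats["in_cosmic"] = [
        res.in_cosmic(k) or c > 0 for k, c in zip(stats.index, stats["cosmic_rec"])
    ]
    stats["hotspot"] = [res.is_hotspot(k) for k in stats.index]
    unprotected = ~stats["in_cosmic"] & ~stats["hotspot"]

    if cfg.rule_a_maf_gates_both:
        drop_a = (unprotected
                  & (stats["pop_maf"] >= cfg.exclusion_maf)
                  & ((stats["mean_vaf"] > cfg.exclusion_mean_vaf)
                     | (stats["max_vaf"] < cfg.exclusion_max_vaf)))
    else:
        drop_a = (unprotected
                  & (((stats["pop_maf"] >= cfg.exclusion_maf)
                      & (stats["mean_vaf"] > cfg.exclusion_mean_vaf))
                     | (stats["max_vaf"] < cfg.exclusion_max_vaf)))

    kept_a = ~calls["variant_key"].map(drop_a)
    dec_a = _decisions(calls, kept_a, "cohort_exclusion",
                       pd.Series("vaf_profile", index=calls.index, dtype=object))
    calls = calls[kept_a]

    drop_b = (unprotected
              & stats["consequence"].isin(_LOF)
              & ~stats["any_sig"])
    kept_b = ~calls["variant_key"].map(drop_b)
    dec_b = _decisions(calls, kept_b, "lof_exclusion",
                       pd.Series("lof_no_somatic_support", index=calls.index,
                                 dtype=object))
    return calls[kept_b], pd.concat([dec_a, dec_b], ignore_index=True)


def assemble_callset(retained: pd.DataFrame, cfg: FilterConfig,
                     sample_ids: Iterable[str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate retained mutations into per-individual CH calls.

    Clone class is ``large`` iff the individual's *maximum* VAF reaches
    ``large_clone_vaf``; gene-subtype membership is non-exclusive (a carrier
    of both DNMT3A and TET2 mutations belongs to both subtypes).  Returns
    ``(callset, mutations)``.
    """
    dup = retained.duplicated(subset=["sample_id", "variant_key"])
    if dup.any():
        warnings.warn(f"deduplicating {int(dup.sum())} repeated (sample, variant) records",
                      stacklevel=2)
        retained = retained[~dup]

    mutations = retained[["sample_id", "gene", "vaf", "variant_key",
                          "consequence", "var_class"]].reset_index(drop=True)
    if len(retained):
        g = retained.groupby("sample_id")
        per = pd.DataFrame({
            "max_vaf": g["vaf"].max(),
            "n_mutations": g.size(),
            "genes": g["gene"].agg(lambda s: ",".join(sorted(set(s)))),
        }).reset_index()
    else:
        per = pd.DataFrame(columns=["sample_id", "max_vaf", "n_mutations", "genes"])
    per["ch_status"] = True
    per["clone_class"] = np.where(per["max_vaf"] >= cfg.large_clone_vaf,
                                  "large", "small")

    if sample_ids is not None:
        frame = pd.DataFrame({"sample_id": list(sample_ids)})
        per = frame.merge(per, on="sample_id", how="left")
        per["ch_status"] = per["ch_status"].eq(True)
        per["n_mutations"] = per["n_mutations"].fillna(0).astype(int)
        per["genes"] = per["genes"].fillna("")
    cols = ["sample_id", "ch_status", "genes", "n_mutations", "max_vaf",
            "clone_class"]
    return per[cols], mutations


def run_filter_chain(calls: pd.DataFrame, cfg: FilterConfig | None = None,
                     res: DriverResource | None = None,
                     sample_ids: Iterable[str] | None = None) -> FilterResult:
    """Run all filter stages and assemble the callset, with a full audit trail."""
    from .resources import default_resources

    cfg = cfg or FilterConfig()
    res = res if res is not None else default_resources()
    if "variant_key" not in calls.columns:
        from .resources import variant_key as _vk
        calls = calls.assign(variant_key=[
            _vk(c, p, r, a) for c, p, r, a in zip(calls["chrom"], calls["pos"],
                                                  calls["ref"], calls["alt"])])

    decisions: list[pd.DataFrame] = []
    counts: dict[str, tuple[int, int]] = {}

    cur, dec = basic_qc(calls, cfg)
    decisions.append(dec)
    counts["qc"] = (len(calls), len(cur))
    qc_counts = cur.groupby("variant_key")["sample_id"].nunique()

    prev = cur
    cur, dec = candidate_selection(prev, cfg)
    decisions.append(dec)
    counts["candidate"] = (len(prev), len(cur))

    prev = cur
    cur, dec = novel_variant_gate(prev, cfg, cohort_counts=qc_counts)
    decisions.append(dec)
    counts["novel_gate"] = (len(prev), len(cur))

    prev = cur
    cur, dec = _driver_evidence_stage(prev, res, cfg)
    decisions.append(dec)
    counts["driver_evidence"] = (len(prev), len(cur))

    prev = cur
    cur, dec = germline_rescue(prev, cfg, res)
    decisions.append(dec)
    counts["germline_rescue"] = (len(prev), len(cur))

    prev = cur
    cur, dec = cohort_exclusions(prev, cfg, res)
    decisions.append(dec)
    counts["cohort_exclusion"] = (len(prev), len(cur))

    callset, mutations = assemble_callset(cur, cfg, sample_ids=sample_ids)
    audit = pd.concat(decisions, ignore_index=True) if decisions else pd.DataFrame()
    return FilterResult(retained=cur.reset_index(drop=True), decisions=audit,
                        callset=callset, mutations=mutations,
                        stage_counts=counts)
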