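"""Filtering decision procedure: per-stage rules, audit and recovery."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import helpers
from chforge.caller import (
    FilterConfig,
    assemble_callset,
    basic_qc,
    binomial_germline_pvalue,
    candidate_selection,
    cohort_exclusions,
    driver_evidence,
    germline_rescue,
    novel_variant_gate,
    run_filter_chain,
)
from chforge.errors import MalformedRecordError
from chforge.resources import DriverResource
from chforge.simulate import SimulationConfig, simulate_cohort, simulate_variant_calls


def make_calls(rows: list[dict]) -> pd.DataFrame:
    """Build a variant-call frame, filling sane defaults."""
    defaults = dict(
        sample_id="s1", chrom="1", pos=100, ref="A", alt="G", gene="DNMT3A",
        var_class="SNV", consequence="missense", depth=40, alt_depth=8,
        alt_fwd=4, alt_rev=4, caller_filter="PASS", pop_maf=0.0,
        cosmic_heme_count=10, is_known=True, copy_number=2,
    )
    full = []
    for row in rows:
        d = {**defaults, **row}
        if "vaf" not in d:
            d["vaf"] = d["alt_depth"] / d["depth"] if d["depth"] else 0.0
        full.append(d)
    df = pd.DataFrame(full)
    df["variant_key"] = (df["chrom"].astype(str) + ":" + df["pos"].astype(str)
                         + ":" + df["ref"] + ":" + df["alt"])
    return df


class TestBasicQC:
    @pytest.mark.parametrize("row, kept, reason", [
        (dict(alt_depth=2, alt_fwd=1, alt_rev=1, depth=7), True, "ok"),
        (dict(alt_depth=5, alt_fwd=5, alt_rev=0), False, "strand"),
        (dict(var_class="indel", depth=9), False, "depth"),
        (dict(pop_maf=0.002), False, "pop_maf"),
        (dict(alt_depth=1, alt_fwd=1, alt_rev=0), False, "alt_reads"),
        (dict(var_class="substitution", depth=9), False, "depth"),
        (dict(depth=7), True, "ok"),
    ])
    def test_rule_table(self, filter_cfg, row, kept, reason):
        calls = make_calls([row])
        kept_df, dec = basic_qc(calls, filter_cfg)
        assert (len(kept_df) == 1) == kept
        assert dec["reason"].iloc[0] == reason

    def test_zero_depth_is_malformed(self, filter_cfg):
        with pytest.raises(MalformedRecordError):
            basic_qc(make_calls([dict(depth=0, alt_depth=0, alt_fwd=0,
                                      alt_rev=0, vaf=0.0)]), filter_cfg)


class TestCandidateSelection:
    def test_pass_call_is_candidate(self, filter_cfg):
        kept, _ = candidate_selection(make_calls([{}]), filter_cfg)
        assert len(kept) == 1

    @pytest.mark.parametrize("n_pass_elsewhere, expected", [(2, True), (1, False)])
    def test_germline_needs_two_pass_elsewhere(self, filter_cfg,
                                               n_pass_elsewhere, expected):
        rows = [dict(sample_id="g", caller_filter="germline")]
        rows += [dict(sample_id=f"p{i}") for i in range(n_pass_elsewhere)]
        kept, _ = candidate_selection(make_calls(rows), filter_cfg)
        assert ("g" in set(kept["sample_id"])) == expected

    def test_other_filter_never_candidate(self, filter_cfg):
        rows = [dict(sample_id="o", caller_filter="other")]
        rows += [dict(sample_id=f"p{i}") for i in range(3)]
        kept, dec = candidate_selection(make_calls(rows), filter_cfg)
        assert "o" not in set(kept["sample_id"])
        assert set(dec.loc[~dec["kept"], "reason"]) == {"caller_filter_other"}


class TestNovelVariantGate:
    @pytest.mark.parametrize("row, count, kept", [
        (dict(is_known=False, pop_maf=1e-6), 4, True),
        (dict(is_known=False, pop_maf=1e-6), 3, False),
        (dict(is_known=False, pop_maf=1e-4), 4, False),
        (dict(is_known=True), 1, True),
    ])
    def test_rule_table(self, filter_cfg, row, count, kept):
        calls = make_calls([row])
        counts = pd.Series({calls["variant_key"].iloc[0]: count})
        kept_df, _ = novel_variant_gate(calls, filter_cfg, cohort_counts=counts)
        assert (len(kept_df) == 1) == kept


class TestDriverEvidence:
    @pytest.fixture()
    def res(self):
        return DriverResource(
            hotspots={"1:100:A:G"},
            whitelist_rules=[("DNMT3A", frozenset({"frameshift", "nonsense",
                                                   "splice_site"}), 1, 10_000)],
            cosmic_counts={"1:200:C:T": 9},
        )

    def test_hotspot_wins(self, res, filter_cfg):
        ev = driver_evidence(make_calls([dict(pos=100)]), res, filter_cfg)
        assert ev.iloc[0] == "hotspot"

    @pytest.mark.parametrize("count, expected", [(7, "cosmic"), (6, "none")])
    def test_cosmic_threshold_boundary(self, res, filter_cfg, count, expected):
        calls = make_calls([dict(pos=300, cosmic_heme_count=count)])
        assert driver_evidence(calls, res, filter_cfg).iloc[0] == expected

    def test_truncating_whitelist_match(self, res, filter_cfg):
        calls = make_calls([dict(pos=400, ref="A", alt="AT",
                                 var_class="indel", consequence="frameshift",
                                 cosmic_heme_count=0)])
        assert driver_evidence(calls, res, filter_cfg).iloc[0] == "whitelist"

    def test_unknown_gene_warns_and_gets_none(self, res, filter_cfg):
        calls = make_calls([dict(gene="NOTAGENE", pos=500, cosmic_heme_count=0)])
        with pytest.warns(UserWarning, match="NOTAGENE"):
            ev = driver_evidence(calls, res, filter_cfg)
        assert ev.iloc[0] == "none"


class TestBinomialGermlineTest:
    def test_closed_forms(self):
        assert binomial_germline_pvalue(0, 10, 2) == pytest.approx(0.5 ** 10)
        assert binomial_germline_pvalue(10, 20, 2) >= 0.5

    @pytest.mark.parametrize("alt, depth, cn", [(5, 40, 2), (15, 20, 1)])
    def test_matches_exact_rational_sum(self, alt, depth, cn):
        p0 = Fraction(19, 20) if cn == 1 else Fraction(1, 2)
        oracle = float(helpers.binom_lower_tail_exact(alt, depth, p0))
        got = binomial_germline_pvalue(alt, depth, cn)
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_boundary_significance_against_alpha(self, filter_cfg):
        # alt=5/depth=40 is clearly somatic; alt=15/20 at CN=1 is not (at 0.001)
        assert binomial_germline_pvalue(5, 40, 2) < filter_cfg.binom_alpha
        assert binomial_germline_pvalue(15, 20, 1) > filter_cfg.binom_alpha

    @given(st.integers(1, 500), st.data())
    def test_oracle_equivalence_across_depths(self, depth, data):
        alt = data.draw(st.integers(0, depth))
        cn = data.draw(st.sampled_from([1, 2]))
        p0 = Fraction(19, 20) if cn == 1 else Fraction(1, 2)
        exact = helpers.binom_lower_tail_exact(alt, depth, p0)
        got = binomial_germline_pvalue(alt, depth, cn)
        assert got > 0
        if exact >= Fraction(1, 10**300):   # representable in double precision
            assert got == pytest.approx(float(exact), rel=1e-10)

    def test_zero_depth_rejected(self):
        with pytest.raises(MalformedRecordError):
            binomial_germline_pvalue(0, 0, 2)


class TestGermlineRescue:
    def _group(self, n_germ, n_pass, somatic_alt=5):
        rows = [dict(sample_id=f"g{i}", caller_filter="germline",
                     alt_depth=20, alt_fwd=10, alt_rev=10)
                for i in range(n_germ)]
        rows += [dict(sample_id=f"p{i}", alt_depth=somatic_alt,
                      alt_fwd=somatic_alt // 2 + somatic_alt % 2,
                      alt_rev=somatic_alt // 2)
                 for i in range(n_pass)]
        return make_calls(rows)

    def test_minority_germline_with_somatic_signal_included(self, filter_cfg):
        res = DriverResource()
        kept, _ = germline_rescue(self._group(2, 3), filter_cfg, res)
        assert len(kept) == 5

    def test_majority_germline_excluded_regardless_of_p(self, filter_cfg):
        res = DriverResource()
        kept, _ = germline_rescue(self._group(5, 2), filter_cfg, res)
        assert set(kept["caller_filter"]) == {"PASS"}

    def test_no_somatic_signal_excluded(self, filter_cfg):
        res = DriverResource()
        calls = self._group(1, 3, somatic_alt=20)   # all calls near VAF 0.5
        kept, _ = germline_rescue(calls, filter_cfg, res)
        assert set(kept["caller_filter"]) == {"PASS"}

    def test_hotspot_always_included(self, filter_cfg):
        res = DriverResource(hotspots={"1:100:A:G"})
        calls = self._group(10, 1, somatic_alt=20)
        kept, _ = germline_rescue(calls, filter_cfg, res)
        assert len(kept) == 11


class TestCohortExclusions:
    def _group(self, vafs, pop_maf, consequence="missense", cosmic=0,
               alt_for_vaf=True):
        rows = []
        for i, v in enumerate(vafs):
            alt = max(1, round(40 * v))
            rows.append(dict(sample_id=f"s{i}", depth=40, alt_depth=alt,
                             alt_fwd=alt // 2 + alt % 2, alt_rev=alt // 2,
                             vaf=v, pop_maf=pop_maf, consequence=consequence,
                             cosmic_heme_count=cosmic))
        return make_calls(rows)

    def test_high_mean_vaf_variant_dropped(self, filter_cfg):
        res = DriverResource()
        calls = self._group([0.25, 0.25], pop_maf=1e-4)
        kept, dec = cohort_exclusions(calls, filter_cfg, res)
        assert kept.empty
        assert set(dec.loc[~dec["kept"], "reason"]) == {"vaf_profile"}

    def test_intermediate_profile_kept(self, filter_cfg):
        res = DriverResource()
        # mean VAF 0.15 and max VAF 0.30: neither clause of the profile rule
        calls = self._group([0.30, 0.10, 0.05], pop_maf=1e-4)
        kept, _ = cohort_exclusions(calls, filter_cfg, res)
        assert len(kept) == 3

    def test_low_maf_exempt_from_vaf_profile(self, filter_cfg):
        res = DriverResource()
        calls = self._group([0.25, 0.25], pop_maf=1e-6)
        kept, _ = cohort_exclusions(calls, filter_cfg, res)
        assert len(kept) == 2

    def test_hotspot_exempt(self, filter_cfg):
        res = DriverResource(hotspots={"1:100:A:G"})
        calls = self._group([0.25, 0.25], pop_maf=1e-4)
        kept, _ = cohort_exclusions(calls, filter_cfg, res)
        assert len(kept) == 2

    def test_alternative_parse_drops_small_clones_regardless_of_maf(self):
        cfg = FilterConfig(rule_a_maf_gates_both=False)
        res = DriverResource()
        calls = self._group([0.05, 0.06], pop_maf=0.0)
        kept, _ = cohort_exclusions(calls, cfg, res)
        assert kept.empty
        kept_default, _ = cohort_exclusions(calls, FilterConfig(), res)
        assert len(kept_default) == 2

    def test_lof_without_somatic_support_dropped(self, filter_cfg):
        res = DriverResource()
        calls = self._group([0.45, 0.5], pop_maf=0.0, consequence="nonsense")
        kept, dec = cohort_exclusions(calls, filter_cfg, res)
        assert kept.empty
        assert set(dec.loc[~dec["kept"], "reason"]) == {"lof_no_somatic_support"}

    def test_lof_with_one_significant_carrier_kept(self, filter_cfg):
        res = DriverResource()
        calls = self._group([0.45, 0.1], pop_maf=0.0, consequence="nonsense")
        kept, _ = cohort_exclusions(calls, filter_cfg, res)
        assert len(kept) == 2

    def test_empty_group_noop(self, filter_cfg):
        res = DriverResource()
        calls = make_calls([{}]).iloc[0:0]
        kept, dec = cohort_exclusions(calls, filter_cfg, res)
        assert kept.empty and dec.empty


class TestAssembleCallset:
    def test_clone_class_uses_max_vaf(self, filter_cfg):
        calls = make_calls([
            dict(sample_id="x", pos=1, vaf=0.08, alt_depth=3, alt_fwd=2, alt_rev=1),
            dict(sample_id="x", pos=2, vaf=0.15, alt_depth=6, alt_fwd=3, alt_rev=3),
        ])
        callset, _ = assemble_callset(calls, filter_cfg)
        assert callset.loc[0, "clone_class"] == "large"

    def test_boundary_vaf_is_small(self, filter_cfg):
        calls = make_calls([dict(vaf=0.099)])
        callset, _ = assemble_callset(calls, filter_cfg)
        assert callset.loc[0, "clone_class"] == "small"
        calls = make_calls([dict(vaf=0.1)])
        callset, _ = assemble_callset(calls, filter_cfg)
        assert callset.loc[0, "clone_class"] == "large"

    def test_non_carriers_counted_as_controls(self, filter_cfg):
        calls = make_calls([dict(sample_id="x")])
        callset, _ = assemble_callset(calls, filter_cfg,
                                      sample_ids=["x", "y", "z"])
        assert len(callset) == 3
        assert callset.set_index("sample_id")["ch_status"].to_dict() == {
            "x": True, "y": False, "z": False}

    def test_multi_gene_carrier_in_both_subtypes(self, filter_cfg):
        calls = make_calls([
            dict(sample_id="x", pos=1, gene="DNMT3A"),
            dict(sample_id="x", pos=2, gene="TET2"),
        ])
        callset, _ = assemble_callset(calls, filter_cfg)
        assert callset.loc[0, "genes"] == "DNMT3A,TET2"

    def test_duplicates_deduplicated_with_warning(self, filter_cfg):
        calls = make_calls([dict(sample_id="x"), dict(sample_id="x")])
        with pytest.warns(UserWarning, match="deduplicat"):
            callset, mutations = assemble_callset(calls, filter_cfg)
        assert len(mutations) == 1


class TestFullChain:
    def test_audit_complete_at_every_stage(self, small_cohort, resources):
        _, pheno, _, calls = small_cohort
        result = run_filter_chain(calls, FilterConfig(), resources,
                                  sample_ids=pheno["sample_id"])
        dec = result.decisions
        by_stage = {s: sub for s, sub in dec.groupby("stage")}
        # every examined record gets a verdict: |kept| + |dropped| = |input|
        for stage in ("qc", "candidate", "novel_gate", "driver_evidence",
                      "germline_rescue"):
            n_in, n_kept = result.stage_counts[stage]
            assert len(by_stage[stage]) == n_in
            assert by_stage[stage]["kept"].sum() == n_kept
        n_in, n_kept = result.stage_counts["cohort_exclusion"]
        assert len(by_stage["cohort_exclusion"]) == n_in
        n_after_a = int(by_stage["cohort_exclusion"]["kept"].sum())
        assert len(by_stage["lof_exclusion"]) == n_after_a
        assert by_stage["lof_exclusion"]["kept"].sum() == n_kept
        assert (dec.loc[~dec["kept"], "reason"] != "ok").all()
        assert (dec.loc[dec["kept"], "reason"] == "ok").all()

    def test_each_dropped_record_has_single_terminal_reason(self, small_cohort,
                                                            resources):
        _, _, _, calls = small_cohort
        result = run_filter_chain(calls, FilterConfig(), resources)
        dropped = result.decisions[~result.decisions["kept"]]
        per_record = dropped.groupby(["sample_id", "variant_key"]).size()
        assert (per_record == 1).all()

    def test_tightening_qc_never_retains_more(self, small_cohort, resources):
        _, _, _, calls = small_cohort
        base = len(run_filter_chain(calls, FilterConfig(), resources).retained)
        tighter = [
            FilterConfig(min_alt_reads=3),
            FilterConfig(min_depth_snv=10, min_depth_indel=14),
            FilterConfig(max_pop_maf=1e-4),
            FilterConfig(min_alt_reads=4, min_depth_snv=12, max_pop_maf=1e-5),
        ]
        for cfg in tighter:
            assert len(run_filter_chain(calls, cfg, resources).retained) <= base

    def test_chain_idempotent_on_own_output(self, small_cohort, resources):
        _, _, _, calls = small_cohort
        cfg = FilterConfig()
        first = run_filter_chain(calls, cfg, resources)
        cols = [c for c in first.retained.columns if c != "evidence"]
        second = run_filter_chain(first.retained[cols], cfg, resources)
        assert helpers.retained_pairs(first) == helpers.retained_pairs(second)

    def test_recovery_on_default_synthetic_cohort(self):
        cfg = SimulationConfig(n_individuals=10_000, seed=17)
        pheno, truth = simulate_cohort(cfg)
        calls = simulate_variant_calls(truth, cfg)
        result = run_filter_chain(calls, sample_ids=pheno["sample_id"])
        kept = helpers.retained_pairs(result)
        by_origin = {
            origin: sub.apply(lambda r: (r.sample_id, r.variant_key) in kept,
                              axis=1).mean()
            for origin, sub in calls.groupby("origin")
        }
        assert by_origin["germline_het"] <= 0.01
        assert by_origin["artifact"] == 0.0
        # downstream of the read-support screen, drivers are lost only to the
        # two rules designed to be conservative about germline look-alikes:
        # the caller-flag recurrence requirement and the truncating-variant
        # binomial-support rule
        dec = result.decisions.merge(
            calls[["sample_id", "variant_key", "origin"]].drop_duplicates(),
            on=["sample_id", "variant_key"], how="left")
        drv_drops = dec[(dec["origin"] == "driver") & ~dec["kept"]
                        & (dec["stage"] != "qc")]
        assert set(drv_drops["reason"]) <= {"germline_unsupported",
                                            "germline_rescue_failed",
                                            "lof_no_somatic_support"}
        qc_kept, _ = basic_qc(calls, FilterConfig())
        drv = qc_kept[qc_kept["origin"] == "driver"]
        downstream = drv.apply(
            lambda r: (r.sample_id, r.variant_key) in kept, axis=1).mean()
        assert downstream >= 0.90
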