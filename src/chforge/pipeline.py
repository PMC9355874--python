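"""Reproducible orchestration: simulate → call → characterize → assoc → MR → clump.

A :class:`RunConfig` (plain YAML) toggles stages and overrides generator or
filter parameters; :func:`run_pipeline` executes the enabled stages in order,
writes tidy TSV outputs plus a manifest recording the config hash, seeds and
per-stage row counts, and skips downstream stages when a stage fails.
Re-running an identical config reproduces byte-identical result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .caller import FilterConfig, run_filter_chain
from .errors import ValidationError
from .mr import harmonize, mr_all_methods
from .gwas import ld_clump, loci_table, prioritize_genes, significance_filter, EVIDENCE_CHANNELS
from .resources import default_resources
from .simulate import (
    LDSimConfig,
    MRSimConfig,
    SimulationConfig,
    simulate_cohort,
    simulate_gwas_sumstats,
    simulate_mr_dataset,
    simulate_variant_calls,
    write_cohort,
    write_variant_calls,
)
from . import stats

__all__ = ["RunConfig", "SCHEMAS", "validate_inputs", "run_pipeline"]

ALL_STAGES = ("simulate", "call", "characterize", "assoc", "mr", "clump")

SCHEMAS: dict[str, dict] = {
    "phenotypes": {
        "required": ["sample_id", "age", "sex"],
        "numeric": ["age"],
        "unique": ["sample_id"],
    },
    "variant_calls": {
        "required": ["sample_id", "chrom", "pos", "ref", "alt", "gene",
                     "var_class", "consequence", "depth", "alt_depth",
                     "alt_fwd", "alt_rev", "caller_filter", "pop_maf"],
        "numeric": ["pos", "depth", "alt_depth", "alt_fwd", "alt_rev",
                    "pop_maf"],
        "unique": [],
    },
    "callset": {
        "required": ["sample_id", "ch_status"],
        "numeric": [],
        "unique": ["sample_id"],
    },
    "sumstats": {
        "required": ["snp", "effect_allele", "other_allele", "eaf", "beta",
                     "se", "p"],
        "numeric": ["eaf", "beta", "se", "p"],
        "unique": ["snp"],
    },
}


@dataclass
class ValidationReport:
    """Schema-check outcome: one message per violation."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def raise_if_fatal(self) -> None:
        if not self.ok:
            raise ValidationError("; ".join(self.violations))


def validate_inputs(tables: dict[str, pd.DataFrame],
                    schemas: dict[str, dict] | None = None) -> ValidationReport:
    """Check named tables against their schemas.

    Reports missing columns, non-numeric values in numeric columns and key
    collisions.  Unknown table names are reported as violations.
    """
    schemas = schemas if schemas is not None else SCHEMAS
    report = ValidationReport()
    for name, df in tables.items():
        schema = schemas.get(name)
        if schema is None:
            report.violations.append(f"{name}: no schema registered")
            continue
        for col in schema.get("required", []):
            if col not in df.columns:
                report.violations.append(f"{name}: missing column '{col}'")
        for col in schema.get("numeric", []):
            if col in df.columns and not pd.to_numeric(df[col], errors="coerce").notna().all():
                report.violations.append(f"{name}: non-numeric values in '{col}'")
        for col in schema.get("unique", []):
            if col in df.columns and df[col].duplicated().any():
                dupes = df.loc[df[col].duplicated(), col].iloc[0]
                report.violations.append(
                    f"{name}: duplicate key in '{col}' (e.g. {dupes!r})")
    return report


@dataclass
class RunConfig:
    """One pipeline run: stage toggles, parameter overrides, seed, outputs."""

    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    outdir: str = "chforge_run"
    simulation: dict = field(default_factory=dict)
    mr_sim: dict = field(default_factory=dict)
    gwas_sim: dict = field(default_factory=dict)
    filter_overrides: dict = field(default_factory=dict)
    #: Binary/quantitative trait names to test in the assoc stage (must be
    #: columns of the phenotype table, e.g. injected generator traits).
    assoc_traits: tuple[str, ...] = ()
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "assoc_traits" in raw:
            raw["assoc_traits"] = tuple(raw["assoc_traits"])
        return cls(**raw)

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["assoc_traits"] = list(d["assoc_traits"])
        d.pop("outdir", None)       # hash describes the analysis, not the destination
        d.pop("log_level", None)
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return len(df)


def _simulate_evidence(loci, seed: int) -> pd.DataFrame:
    """Synthetic per-locus evidence matrix for the prioritization vote."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                       spawn_key=(4,)))
    rows = []
    for i, lc in enumerate(loci):
        for j in range(3):
            gene = f"GENE{i + 1:02d}{chr(ord('A') + j)}"
            votes = rng.random(len(EVIDENCE_CHANNELS)) < (0.45 if j == 0 else 0.15)
            rows.append({"locus": f"locus_{i + 1:02d}", "gene": gene,
                         **dict(zip(EVIDENCE_CHANNELS, votes))})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; return the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}

    def _record(stage: str, status: str, rows: dict[str, int] | None = None) -> None:
        manifest["stages"][stage] = {"status": status, "rows": rows or {}}

    failed = False
    for stage in ALL_STAGES:
        if stage not in config.stages:
            _record(stage, "disabled")
            continue
        if failed:
            _record(stage, "skipped")
            continue
        try:
            rows = _run_stage(stage, config, state, outdir)
            _record(stage, "ok", rows)
        except Exception as exc:   # stage failure: mark and skip downstream
            _record(stage, f"failed: {exc}")
            failed = True

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _run_stage(stage: str, config: RunConfig, state: dict, outdir: Path) -> dict[str, int]:
    rows: dict[str, int] = {}
    if stage == "simulate":
        sim_cfg = SimulationConfig(**config.simulation, seed=config.seed)
        pheno, truth = simulate_cohort(sim_cfg)
        calls = simulate_variant_calls(truth, sim_cfg)
        write_cohort(pheno, truth, outdir)
        write_variant_calls(calls, outdir, vcf=len(calls) <= 50_000)
        state.update(pheno=pheno, truth=truth, calls=calls, sim_cfg=sim_cfg)
        rows = {"phenotypes": len(pheno), "variant_calls": len(calls)}

    elif stage == "call":
        pheno, calls = state["pheno"], state["calls"]
        validate_inputs({"phenotypes": pheno,
                         "variant_calls": calls}).raise_if_fatal()
        fcfg = FilterConfig(**config.filter_overrides)
        res = default_resources()
        result = run_filter_chain(calls, fcfg, res,
                                  sample_ids=pheno["sample_id"])
        rows["callset"] = _write(result.callset, outdir / "callset.tsv")
        rows["mutations"] = _write(result.mutations, outdir / "mutations.tsv")
        rows["audit"] = _write(result.decisions, outdir / "filter_audit.tsv")
        state["callset"], state["mutations"] = result.callset, result.mutations
        state["stage_counts"] = result.stage_counts

    elif stage == "characterize":
        callset, pheno = state["callset"], state["pheno"]
        prev = stats.prevalence_table(callset, pheno)
        rows["prevalence"] = _write(prev, outdir / "prevalence.tsv")
        vafs = stats.vaf_summary(state["mutations"])
        rows["vaf_summary"] = _write(vafs, outdir / "vaf_summary.tsv")
        top = vafs["gene"].iloc[0] if len(vafs) else None
        if top is not None:
            shifts = stats.age_shift_tests(callset, pheno, reference_gene=top)
            rows["age_shifts"] = _write(shifts, outdir / "age_shifts.tsv")
        ecdf = stats.age_ecdf(callset, pheno)
        rows["age_ecdf"] = _write(ecdf, outdir / "age_ecdf.tsv")

    elif stage == "assoc":
        callset, pheno = state["callset"], state["pheno"]
        traits = config.assoc_traits or ("age",)
        results = [stats.prevalent_assoc(callset, pheno, t) for t in traits]
        stats.attach_fdr(results)
        rows["associations"] = _write(stats.association_table(results),
                                      outdir / "associations.tsv")

    elif stage == "mr":
        mr_cfg = MRSimConfig(**config.mr_sim, seed=config.seed)
        exposure, outcome, theta = simulate_mr_dataset(mr_cfg)
        instruments, drop_log = harmonize(exposure, outcome)
        estimates = mr_all_methods(instruments, seed=config.seed)
        est_df = pd.DataFrame([{
            "method": e.method, "beta": e.beta, "se": e.se, "p": e.p_value,
            "ci_low": e.ci_low, "ci_high": e.ci_high, "n_snps": e.n_snps,
            "egger_intercept": e.egger_intercept,
            "intercept_se": e.intercept_se, "true_theta": theta,
        } for e in estimates])
        rows["mr_estimates"] = _write(est_df, outdir / "mr_estimates.tsv")
        rows["mr_drops"] = _write(drop_log, outdir / "mr_drop_log.tsv")

    elif stage == "clump":
        ld_cfg = LDSimConfig(**config.gwas_sim, seed=config.seed)
        sumstats, ld = simulate_gwas_sumstats(ld_cfg)
        eligible = significance_filter(sumstats, mode="common")
        loci = ld_clump(eligible, ld)
        rows["loci"] = _write(loci_table(loci), outdir / "loci.tsv")
        evidence = _simulate_evidence(loci, config.seed)
        ranked = prioritize_genes(evidence) if len(evidence) else {}
        pri = pd.DataFrame([
            {"locus": locus, "rank": i + 1, "gene": g, "votes": v}
            for locus, genes in sorted(ranked.items())
            for i, (g, v) in enumerate(genes)
        ], columns=["locus", "rank", "gene", "votes"])
        rows["prioritized_genes"] = _write(pri, outdir / "prioritized_genes.tsv")
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return rows
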