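"""Synthetic cohorts, variant-call tables and summary statistics with known truth.

Every downstream stage of the package (driver-mutation filtering, cohort
statistics, Mendelian randomization, LD clumping) is exercised against data
from this module, so each generator records its ground truth:

* :func:`simulate_cohort` draws a phenotype table and per-individual CH truth
  from a logistic model in age and sex (plus optional injected trait effects);
* :func:`simulate_variant_calls` turns the truth into read-count level variant
  records — true drivers, germline heterozygous contaminants and strand-biased
  sequencing artifacts — labelled with their origin;
* :func:`simulate_mr_dataset` draws two-sample MR summary statistics with a
  configurable causal effect and pleiotropy;
* :func:`simulate_gwas_sumstats` draws LD-blocked GWAS summary statistics with
  known causal variants plus the matching pairwise r² matrix.

A single integer seed expands into independent per-generator substreams, so
generators can be re-run individually without perturbing one another.
Identical configuration + seed yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .errors import ConfigError
from .resources import (
    DEFAULT_GENE_FREQUENCIES,
    PanelLayout,
    default_panel_layout,
    variant_key,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "MRSimConfig",
    "LDSimConfig",
    "simulate_cohort",
    "simulate_variant_calls",
    "simulate_mr_dataset",
    "simulate_gwas_sumstats",
    "write_cohort",
    "write_variant_calls",
]

_SUBSTREAMS = {"cohort": 0, "variants": 1, "mr": 2, "gwas": 3, "evidence": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator substream derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_SUBSTREAMS[stream],))
    )


# --------------------------------------------------------------------------
# Cohort + variant-call simulation
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of the synthetic CH cohort.

    The defaults emulate a large adult biobank cohort: ages 38-72 (55%
    female), overall CH prevalence 5.45%, a 6.7% increase in CH odds per
    year of age, ten driver genes with frequencies decreasing in the
    panel's rank order, clone sizes (VAF) from a Beta(2, 8) (median ≈ 0.18,
    the scale reported for exome-detected CH clones) and ~40x sequencing
    depth.  ``n_individuals`` defaults to a desk-scale 10,000.
    """

    n_individuals: int = 10_000
    age_range: tuple[int, int] = (38, 72)
    female_fraction: float = 0.55
    #: Log-odds of CH at the youngest age for a male never-carrier of any
    #: injected trait.  ``None`` ⇒ solved so that the marginal carrier
    #: fraction matches ``target_prevalence``.
    baseline_log_odds: float | None = None
    target_prevalence: float = 0.0545
    age_log_or_per_year: float = math.log(1.067)
    sex_log_or: float = 0.0
    gene_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_FREQUENCIES))
    vaf_distribution: tuple[float, float] = (2.0, 8.0)
    depth_mean: float = 40.0
    #: Expected germline-het contaminant calls per sample.
    contamination_rate: float = 0.3
    #: Expected strand-biased artifact calls per sample.
    artifact_rate: float = 0.1
    #: Fraction of true driver calls mislabelled 'germline' by the caller.
    germline_mislabel_fraction: float = 0.05
    #: Fraction of contaminant calls the caller misses (labels 'PASS').
    contaminant_pass_fraction: float = 0.10
    #: Probability that a carrier receives a second, independent mutation
    #: (the published callset has 11,697 mutations in 10,924 carriers ≈ 1.07).
    extra_mutation_rate: float = 0.07
    #: Injected binary trait effects: name -> (marginal prevalence, log-OR on CH).
    binary_trait_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: Injected quantitative trait effects: name -> (mean, sd, log-OR per unit).
    quant_trait_effects: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be positive")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ConfigError("female_fraction must lie in [0, 1]")
        if self.age_range[0] > self.age_range[1]:
            raise ConfigError("age_range must be (min, max)")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        for rate_name in ("contamination_rate", "artifact_rate",
                          "germline_mislabel_fraction", "contaminant_pass_fraction",
                          "extra_mutation_rate"):
            if getattr(self, rate_name) < 0:
                raise ConfigError(f"{rate_name} must be non-negative")
        freqs = np.asarray(list(self.gene_frequencies.values()), dtype=float)
        if (freqs < 0).any() or not math.isclose(freqs.sum(), 1.0, abs_tol=1e-8):
            raise ConfigError("gene_frequencies must be non-negative and sum to 1")
        a, b = self.vaf_distribution
        if a <= 0 or b <= 0:
            raise ConfigError("vaf_distribution Beta shapes must be positive")
        if self.baseline_log_odds is None and not (0 < self.target_prevalence < 1):
            raise ConfigError("target_prevalence must lie in (0, 1)")
        for name, (prev, _) in self.binary_trait_effects.items():
            if not (0 < prev < 1):
                raise ConfigError(f"binary trait {name!r}: prevalence must be in (0,1)")
        for name, (_, sd, _) in self.quant_trait_effects.items():
            if sd <= 0:
                raise ConfigError(f"quantitative trait {name!r}: sd must be positive")


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort.

    ``individuals`` holds one row per participant (``sample_id``, ``true_ch``);
    ``mutations`` one row per true driver clone (``sample_id``, ``gene``,
    ``true_vaf``).  Variant-record origins (driver / germline_het / artifact)
    are carried in the ``origin`` column of the simulated call table.
    """

    individuals: pd.DataFrame
    mutations: pd.DataFrame

    def carriers(self) -> pd.Series:
        return self.individuals.loc[self.individuals["true_ch"], "sample_id"]


def _solve_baseline(offsets: np.ndarray, target: float) -> float:
    """Intercept that sets the mean logistic probability to ``target``."""
    def gap(b0: float) -> float:
        return float(expit(b0 + offsets).mean() - target)
    return float(brentq(gap, -30.0, 30.0, xtol=1e-12))


def simulate_cohort(cfg: SimulationConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Draw the phenotype table and CH truth for one cohort.

    Returns ``(phenotypes, truth)``.  The phenotype table has columns
    ``sample_id, age, sex, smoking, batch, pc1..pc10`` plus any injected
    traits; CH is sampled from a logistic model in age, sex and the injected
    trait effects.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "cohort")
    n = cfg.n_individuals
    age_min, age_max = cfg.age_range

    sample_id = np.array([f"S{i:06d}" for i in range(1, n + 1)])
    age = rng.integers(age_min, age_max + 1, size=n)
    female = rng.random(n) < cfg.female_fraction
    smoking = rng.choice(["never", "former", "current"], size=n, p=[0.55, 0.34, 0.11])
    batch = rng.choice(["50k", "150k"], size=n, p=[0.25, 0.75])
    pcs = rng.standard_normal((n, 10))

    pheno = pd.DataFrame({
        "sample_id": sample_id,
        "age": age,
        "sex": np.where(female, "female", "male"),
        "smoking": smoking,
        "batch": batch,
    })
    for j in range(10):
        pheno[f"pc{j + 1}"] = pcs[:, j]

    offsets = (cfg.age_log_or_per_year * (age - age_min)
               + cfg.sex_log_or * female.astype(float))
    for name, (prev, log_or) in sorted(cfg.binary_trait_effects.items()):
        x = (rng.random(n) < prev).astype(int)
        pheno[name] = x
        offsets = offsets + log_or * x
    for name, (mean, sd, log_or) in sorted(cfg.quant_trait_effects.items()):
        x = rng.normal(mean, sd, size=n)
        pheno[name] = x
        offsets = offsets + log_or * (x - mean)

    if cfg.baseline_log_odds is None:
        b0 = _solve_baseline(offsets, cfg.target_prevalence)
    else:
        b0 = cfg.baseline_log_odds
    true_ch = rng.random(n) < expit(b0 + offsets)

    genes = np.array(sorted(cfg.gene_frequencies))
    gene_p = np.array([cfg.gene_frequencies[g] for g in genes])
    carrier_idx = np.flatnonzero(true_ch)
    a, b = cfg.vaf_distribution
    rows = []
    for i in carrier_idx:
        n_mut = 1 + int(rng.random() < cfg.extra_mutation_rate)
        for _ in range(n_mut):
            rows.append((sample_id[i],
                         str(rng.choice(genes, p=gene_p)),
                         float(rng.beta(a, b))))
    mutations = pd.DataFrame(rows, columns=["sample_id", "gene", "true_vaf"])

    truth = TruthTable(
        individuals=pd.DataFrame({"sample_id": sample_id, "true_ch": true_ch}),
        mutations=mutations,
    )
    return pheno, truth


_CALL_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "var_class",
    "consequence", "depth", "alt_depth", "alt_fwd", "alt_rev", "vaf",
    "caller_filter", "pop_maf", "cosmic_heme_count", "is_known",
    "copy_number", "origin", "true_vaf",
]


def simulate_variant_calls(
    truth: TruthTable,
    cfg: SimulationConfig,
    layout: PanelLayout | None = None,
) -> pd.DataFrame:
    """Emit read-count level variant records for a simulated cohort.

    Driver records draw ``depth ~ Poisson(depth_mean)`` (floored at 1),
    ``alt ~ Binomial(depth, VAF)`` and split alt reads evenly between strands;
    a configurable fraction is mislabelled ``germline`` by the caller.
    Contaminants are germline het sites (``alt ~ Binomial(depth, 0.5)``)
    usually flagged ``germline``; artifacts put all alt reads on one strand.
    Records with zero alt reads are not emitted (no caller would report them).
    """
    cfg.validate()
    if layout is None:
        layout = default_panel_layout()
    rng = _rng(cfg.seed, "variants")
    rows: list[tuple] = []

    def _depth() -> int:
        return max(1, int(rng.poisson(cfg.depth_mean)))

    # --- true drivers -----------------------------------------------------
    for rec in truth.mutations.itertuples():
        gene = rec.gene
        u = rng.random()
        if u < 0.50:
            site = layout.hotspot_sites[gene][rng.integers(len(layout.hotspot_sites[gene]))]
        elif u < 0.85:
            site = layout.cosmic_sites[gene][rng.integers(len(layout.cosmic_sites[gene]))]
        else:
            site = layout.whitelist_sites[gene][rng.integers(len(layout.whitelist_sites[gene]))]
        depth = _depth()
        alt = int(rng.binomial(depth, rec.true_vaf))
        if alt == 0:
            continue
        fwd = int(rng.binomial(alt, 0.5))
        flt = "germline" if rng.random() < cfg.germline_mislabel_fraction else "PASS"
        # Whitelist-only truncating sites are catalogued somatic variants
        # (dbSNP-known) even though absent from the COSMIC haematology counts.
        rows.append((rec.sample_id, site.chrom, site.pos, site.ref, site.alt,
                     gene, site.var_class, site.consequence, depth, alt, fwd,
                     alt - fwd, alt / depth, flt, 0.0, site.cosmic_heme_count,
                     True, 2, "driver", rec.true_vaf))

    # --- germline het contaminants ---------------------------------------
    n_germ_sites = len(layout.germline_sites)
    for sid in truth.individuals["sample_id"]:
        for _ in range(int(rng.poisson(cfg.contamination_rate))):
            site = layout.germline_sites[rng.integers(n_germ_sites)]
            depth = _depth()
            alt = int(rng.binomial(depth, 0.5))
            if alt == 0:
                continue
            fwd = int(rng.binomial(alt, 0.5))
            flt = "PASS" if rng.random() < cfg.contaminant_pass_fraction else "germline"
            rows.append((sid, site.chrom, site.pos, site.ref, site.alt,
                         site.gene, site.var_class, site.consequence, depth,
                         alt, fwd, alt - fwd, alt / depth, flt,
                         layout.germline_mafs[site.key], 0, True, 2,
                         "germline_het", np.nan))

    # --- strand-biased artifacts ------------------------------------------
    n_art_sites = len(layout.artifact_sites)
    for sid in truth.individuals["sample_id"]:
        for _ in range(int(rng.poisson(cfg.artifact_rate))):
            site = layout.artifact_sites[rng.integers(n_art_sites)]
            depth = _depth()
            alt = 1 + int(rng.binomial(depth - 1, 0.04))
            fwd = alt if rng.random() < 0.5 else 0
            rows.append((sid, site.chrom, site.pos, site.ref, site.alt,
                         site.gene, site.var_class, site.consequence, depth,
                         alt, fwd, alt - fwd, alt / depth, "PASS", 0.0, 0,
                         False, 2, "artifact", np.nan))

    calls = pd.DataFrame(rows, columns=_CALL_COLUMNS)
    if len(calls):
        calls["variant_key"] = [
            variant_key(c, p, r, a)
            for c, p, r, a in zip(calls["chrom"], calls["pos"],
                                  calls["ref"], calls["alt"])
        ]
    else:
        calls["variant_key"] = pd.Series(dtype=str)
    return calls


# --------------------------------------------------------------------------
# Two-sample MR simulation
# --------------------------------------------------------------------------

@dataclass
class MRSimConfig:
    """Generative model for two-sample MR summary statistics.

    SNP-exposure effects γ_j ~ N(0, ``gamma_scale``²) are reported with
    standard error ``sigma_x``; SNP-outcome effects Γ_j = θ·γ_j + α_j are
    reported with standard error ``sigma_y``, where the direct (pleiotropic)
    effects α_j are nonzero for a configurable fraction of instruments and
    drawn independently of γ_j (InSIDE holds).  Alleles are assigned with
    random strand/allele orientation and occasional palindromes so that
    harmonization is genuinely exercised.
    """

    n_instruments: int = 100
    theta: float = 0.0
    gamma_scale: float = 0.05
    sigma_x: float = 0.004
    sigma_y: float = 0.02
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    invalid_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_instruments < 3:
            raise ConfigError("n_instruments must be >= 3 (MR-Egger minimum)")
        if min(self.gamma_scale, self.sigma_x, self.sigma_y) <= 0:
            raise ConfigError("gamma_scale, sigma_x and sigma_y must be positive")
        if self.pleiotropy_sd < 0:
            raise ConfigError("pleiotropy_sd must be non-negative")
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ConfigError("invalid_fraction must lie in [0, 1]")


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("A", "T"), ("G", "C")]   # last two are palindromic
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def simulate_mr_dataset(
    cfg: MRSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Draw exposure and outcome summary statistics plus the true θ.

    Both tables carry columns ``snp, effect_allele, other_allele, eaf, beta,
    se, p, n``.  Outcome rows are randomly re-oriented (allele swap and/or
    strand flip) relative to the exposure so that harmonization has work to
    do; palindromic SNPs keep concordant frequencies so the frequency rule
    can resolve them when unambiguous.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "mr")
    m = cfg.n_instruments

    gamma = rng.normal(0.0, cfg.gamma_scale, size=m)
    alpha = np.zeros(m)
    invalid = rng.random(m) < cfg.invalid_fraction
    if cfg.pleiotropy_sd > 0 or cfg.pleiotropy_mean != 0.0:
        alpha[invalid] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd,
                                    size=int(invalid.sum()))
    gamma_hat = gamma + rng.normal(0.0, cfg.sigma_x, size=m)
    Gamma_hat = cfg.theta * gamma + alpha + rng.normal(0.0, cfg.sigma_y, size=m)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    eaf = rng.uniform(0.05, 0.95, size=m)
    snp = np.array([f"rs{i + 1:06d}" for i in range(m)])

    exposure = pd.DataFrame({
        "snp": snp, "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": gamma_hat, "se": cfg.sigma_x,
        "p": 2 * norm.sf(np.abs(gamma_hat) / cfg.sigma_x),
        "n": 500_000,
    })

    out_ea, out_oa = ea.copy(), oa.copy()
    out_eaf = eaf.copy()
    out_beta = Gamma_hat.copy()
    swap = rng.random(m) < 0.5
    flip = rng.random(m) < 0.5
    for j in range(m):
        if swap[j]:
            out_ea[j], out_oa[j] = out_oa[j], out_ea[j]
            out_beta[j] = -out_beta[j]
            out_eaf[j] = 1.0 - out_eaf[j]
        if flip[j]:
            out_ea[j] = _COMPLEMENT[out_ea[j]]
            out_oa[j] = _COMPLEMENT[out_oa[j]]
    outcome = pd.DataFrame({
        "snp": snp, "effect_allele": out_ea, "other_allele": out_oa,
        "eaf": out_eaf, "beta": out_beta, "se": cfg.sigma_y,
        "p": 2 * norm.sf(np.abs(out_beta) / cfg.sigma_y),
        "n": 200_000,
    })
    return exposure, outcome, float(cfg.theta)


# --------------------------------------------------------------------------
# LD-blocked GWAS summary statistics
# --------------------------------------------------------------------------

@dataclass
class LDSimConfig:
    """Block-diagonal LD structure for clumping and instrument-selection tests.

    Within a block, the correlation between variants i and j is
    ``sqrt(within_block_r2) ** |i - j|`` (AR(1)); between blocks it is zero.
    Causal variants receive ``effect_size``; tagging variants inherit the
    signal attenuated by their correlation with the causal variant(s).
    """

    n_blocks: int = 8
    block_size: int = 5
    within_block_r2: float = 0.6
    causal_per_block: int = 1
    effect_size: float = 0.3
    n_samples: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_blocks < 1 or self.block_size < 1:
            raise ConfigError("n_blocks and block_size must be positive")
        if not (0.0 <= self.within_block_r2 <= 1.0):
            raise ConfigError("within_block_r2 must lie in [0, 1]")
        if self.causal_per_block < 0:
            raise ConfigError("causal_per_block must be non-negative")
        if self.block_size < self.causal_per_block:
            raise ConfigError("block_size must be >= causal_per_block")
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")


def simulate_gwas_sumstats(cfg: LDSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw GWAS rows and the matching block-diagonal r² matrix.

    Returns ``(rows, ld_r2)`` where ``rows`` has columns ``snp_id, chrom, bp,
    beta, se, p_value, maf, info, block, is_causal`` and ``ld_r2`` is a square
    DataFrame of pairwise r² indexed by snp_id.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "gwas")
    B, S = cfg.n_blocks, cfg.block_size
    r_adj = math.sqrt(cfg.within_block_r2)

    n_var = B * S
    snp_ids = np.array([f"snp{b + 1:03d}_{i + 1:02d}"
                        for b in range(B) for i in range(S)])
    block = np.repeat(np.arange(B), S)
    within = np.tile(np.arange(S), B)
    chrom = (block % 22 + 1).astype(str)
    bp = 1_000_000 * (block + 1) + within * 5_000 + 1

    maf = rng.uniform(0.05, 0.5, size=n_var)
    info = rng.uniform(0.7, 1.0, size=n_var)
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_samples)

    beta_true = np.zeros(n_var)
    causal = np.zeros(n_var, dtype=bool)
    for b in range(B):
        if cfg.causal_per_block == 0:
            continue
        picks = rng.choice(S, size=cfg.causal_per_block, replace=False)
        for i in picks:
            causal[b * S + i] = True
    # tagging: attenuate by the signed correlation with each causal variant
    for b in range(B):
        idx = np.arange(b * S, (b + 1) * S)
        c_idx = idx[causal[idx]]
        for i in idx:
            beta_true[i] = sum(cfg.effect_size * r_adj ** abs(i - c)
                               for c in c_idx)

    beta_hat = beta_true + rng.normal(0.0, se)
    z = beta_hat / se
    p = 2 * norm.sf(np.abs(z))

    rows = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "bp": bp,
        "beta": beta_hat, "se": se, "p_value": p,
        "maf": maf, "info": info, "block": block, "is_causal": causal,
    })

    r2 = np.zeros((n_var, n_var))
    for b in range(B):
        idx = np.arange(b * S, (b + 1) * S)
        for i in idx:
            for j in idx:
                r2[i, j] = (r_adj ** abs(i - j)) ** 2
    np.fill_diagonal(r2, 1.0)
    ld = pd.DataFrame(r2, index=snp_ids, columns=snp_ids)
    return rows, ld


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------

def write_cohort(pheno: pd.DataFrame, truth: TruthTable, outdir: str | Path) -> None:
    """Write phenotypes and truth tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False,
                 float_format="%.10g")
    truth.individuals.to_csv(outdir / "truth_individuals.tsv", sep="\t",
                             index=False)
    truth.mutations.to_csv(outdir / "truth_mutations.tsv", sep="\t",
                           index=False, float_format="%.10g")


def write_variant_calls(calls: pd.DataFrame, outdir: str | Path,
                        vcf: bool = True) -> None:
    """Write the variant-call table as TSV and (optionally) minimal VCF."""
    from .vcfio import write_vcf  # local import to keep pysam optional here
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls.to_csv(outdir / "variant_calls.tsv", sep="\t", index=False,
                 float_format="%.10g")
    if vcf:
        write_vcf(calls, outdir / "variant_calls.vcf")
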