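"""Post-GWAS utilities: lead variants, thresholds and target-gene voting.

Lead-variant definition follows the study's conventions: genome-wide
eligibility requires P < 5x10⁻⁸, imputation quality > 0.6 and MAF > 1% for
the common scan (P < 10⁻⁹, quality > 0.8, MAF 0.2-1% for the rare scan), and
loci are formed by greedy LD clumping at r² < 0.05 — the smallest-p eligible
variant seeds a locus that absorbs every variant correlated with it at or
above the threshold.  Gene-level significance uses Bonferroni thresholds,
and target genes are ranked by a seven-channel evidence vote (gene-level
association, summary-based MR with colocalization, protein-interaction hub
status, variant-to-gene lookup, fine-mapped gene-body overlap, accessible
chromatin with correlated expression, and missense annotation), listing
genes nominated by at least two channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ChforgeError

__all__ = [
    "Locus",
    "EVIDENCE_CHANNELS",
    "as_ld_matrix",
    "significance_filter",
    "ld_clump",
    "bonferroni_threshold",
    "prioritize_genes",
    "loci_table",
]

#: The seven boolean evidence channels of the prioritization vote.
EVIDENCE_CHANNELS = (
    "magma", "smr_heidi", "ppi_hub", "variant_to_gene",
    "gene_body_overlap", "atac_expression", "missense",
)

GWS_P = 5e-8
RARE_P = 1e-9


@dataclass
class Locus:
    """One clumped locus: the lead row plus its absorbed members."""

    lead: pd.Series
    members: pd.DataFrame

    @property
    def lead_snp(self) -> str:
        return str(self.lead["snp_id"])

    @property
    def min_p(self) -> float:
        return float(self.lead["p_value"])

    @property
    def n_members(self) -> int:
        return len(self.members)


def as_ld_matrix(ld: pd.DataFrame) -> pd.DataFrame:
    """Coerce square or long-format (snp1, snp2, r2) LD input to a square frame."""
    if {"snp1", "snp2", "r2"}.issubset(ld.columns):
        snps = sorted(set(ld["snp1"]) | set(ld["snp2"]))
        mat = pd.DataFrame(0.0, index=snps, columns=snps)
        for r in ld.itertuples():
            mat.loc[r.snp1, r.snp2] = r.r2
            mat.loc[r.snp2, r.snp1] = r.r2
        np.fill_diagonal(mat.values, 1.0)
        return mat
    if not ld.index.equals(ld.columns):
        raise ChforgeError("square LD matrix must share index and columns")
    vals = ld.to_numpy(dtype=float)
    if (vals < -1e-9).any() or (vals > 1 + 1e-9).any():
        raise ChforgeError("r² values must lie in [0, 1]")
    if not np.allclose(vals, vals.T, atol=1e-9):
        raise ChforgeError("LD matrix must be symmetric")
    return ld


def significance_filter(rows: pd.DataFrame, mode: str = "common") -> pd.DataFrame:
    """Eligibility screen for the common or rare association scan.

    Common: p < 5x10⁻⁸, imputation quality > 0.6, MAF > 1%.
    Rare: p < 10⁻⁹, quality > 0.8, MAF in [0.2%, 1%).  All inequalities are
    strict exactly as printed (a row at p = 5x10⁻⁸ is not eligible).
    """
    if mode == "common":
        keep = ((rows["p_value"] < GWS_P) & (rows["info"] > 0.6)
                & (rows["maf"] > 0.01))
    elif mode == "rare":
        keep = ((rows["p_value"] < RARE_P) & (rows["info"] > 0.8)
                & (rows["maf"] >= 0.002) & (rows["maf"] < 0.01))
    else:
        raise ValueError("mode must be 'common' or 'rare'")
    return rows[keep]


def ld_clump(rows: pd.DataFrame, ld: pd.DataFrame,
             p_threshold: float = GWS_P,
             r2_threshold: float = 0.05) -> list[Locus]:
    """Greedy LD clumping of eligible rows into loci.

    Repeatedly the smallest-p unassigned row (ties broken by chromosome,
    position, then snp id) becomes a lead and absorbs every unassigned row
    with r² >= ``r2_threshold`` to it, so leads are pairwise r² below the
    threshold.  Raises if an eligible row is missing from the LD matrix.
    """
    ld = as_ld_matrix(ld)
    eligible = rows[rows["p_value"] < p_threshold].copy()
    if eligible.empty:
        return []
    missing = set(eligible["snp_id"]) - set(ld.index)
    if missing:
        raise ChforgeError(f"rows missing from LD matrix: {sorted(missing)}")
    sort_cols = [c for c in ("p_value", "chrom", "bp", "snp_id")
                 if c in eligible.columns]
    eligible = eligible.sort_values(sort_cols, kind="mergesort")
    unassigned = list(eligible.index)
    loci: list[Locus] = []
    while unassigned:
        lead_idx = unassigned[0]
        lead = eligible.loc[lead_idx]
        lead_snp = str(lead["snp_id"])
        member_idx = [i for i in unassigned
                      if float(ld.loc[lead_snp, str(eligible.loc[i, "snp_id"])])
                      >= r2_threshold]
        if lead_idx not in member_idx:          # r2(lead, lead) = 1 always
            member_idx.insert(0, lead_idx)
        loci.append(Locus(lead=lead, members=eligible.loc[member_idx]))
        unassigned = [i for i in unassigned if i not in set(member_idx)]
    return loci


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha/m."""
    if m < 1:
        raise ChforgeError("number of tests must be >= 1")
    return alpha / m


def prioritize_genes(evidence: pd.DataFrame,
                     channels: tuple[str, ...] = EVIDENCE_CHANNELS,
                     min_votes: int = 2) -> dict[str, list[tuple[str, int]]]:
    """Rank candidate target genes per locus by evidence votes.

    ``evidence`` has one row per (locus, gene) with boolean channel columns.
    Genes with at least ``min_votes`` nominations are listed per locus,
    ranked by vote count (descending) with alphabetical tie-break; when no
    gene reaches the threshold but exactly one channel nominated exactly one
    gene in the locus, that single gene is listed.  The first-ranked gene is
    the most likely target.
    """
    if evidence.empty:
        return {}
    missing = [c for c in channels if c not in evidence.columns]
    if missing:
        raise ChforgeError(f"evidence matrix missing channels: {missing}")
    out: dict[str, list[tuple[str, int]]] = {}
    for locus, sub in evidence.groupby("locus"):
        votes = sub[list(channels)].astype(bool).sum(axis=1)
        tally = (pd.DataFrame({"gene": sub["gene"], "votes": votes})
                 .groupby("gene")["votes"].max())
        listed = tally[tally >= min_votes]
        if listed.empty:
            nominated = tally[tally >= 1]
            if len(nominated) == 1 and int(tally.sum()) == 1:
                listed = nominated
        ranked = sorted(listed.items(), key=lambda kv: (-kv[1], kv[0]))
        out[str(locus)] = [(g, int(v)) for g, v in ranked]
    return out


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    """Tidy per-locus summary (locus id, lead, member count, min p)."""
    return pd.DataFrame([{
        "locus_id": f"locus_{i + 1:02d}",
        "lead": lc.lead_snp,
        "chrom": lc.lead.get("chrom"),
        "bp": lc.lead.get("bp"),
        "n_members": lc.n_members,
        "min_p": lc.min_p,
    } for i, lc in enumerate(loci)])
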